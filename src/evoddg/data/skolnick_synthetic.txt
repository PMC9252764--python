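# SYNTHETIC surrogate pairwise contact potential (sequence-neighbour term).
# This is NOT the published Skolnick quasichemical potential: that table is
# not printed in the citing literature available here.  Values are a
# synthetic stand-in built from a hydrophobicity + charge decomposition
# e(a,b) = -0.30*(q_a+q_b) - 0.50*q_a*q_b + 0.25*c_a*c_b, q = KD/4.5,
# reproducing the qualitative structure of quasichemical contact potentials
# (hydrophobic attraction, like-charge repulsion).  Replace this file with
# the genuine published table (same whitespace dialect) for production use.
   A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V
A  -0.32   0.38   0.27   0.27  -0.40   0.27   0.27  -0.08   0.24  -0.62  -0.54   0.31  -0.33  -0.43   0.06  -0.03  -0.04  -0.02   0.02  -0.59
R   0.38   0.35   0.14  -0.11   0.41   0.14  -0.11   0.28   0.28   0.50   0.47   0.38   0.38   0.42   0.23   0.26   0.27   0.26   0.24   0.49
N   0.27   0.14   0.16   0.16   0.28   0.16   0.16   0.23   0.17   0.32   0.31   0.16   0.27   0.29   0.20   0.22   0.22   0.22   0.21   0.32
D   0.27  -0.11   0.16   0.41   0.28   0.16   0.41   0.23   0.05   0.32   0.31  -0.09   0.27   0.29   0.20   0.22   0.22   0.22   0.21   0.32
C  -0.40   0.41   0.28   0.28  -0.49   0.28   0.28  -0.12   0.24  -0.74  -0.65   0.33  -0.41  -0.53   0.04  -0.06  -0.08  -0.05   0.00  -0.71
Q   0.27   0.14   0.16   0.16   0.28   0.16   0.16   0.23   0.17   0.32   0.31   0.16   0.27   0.29   0.20   0.22   0.22   0.22   0.21   0.32
E   0.27  -0.11   0.16   0.41   0.28   0.16   0.41   0.23   0.05   0.32   0.31  -0.09   0.27   0.29   0.20   0.22   0.22   0.22   0.21   0.32
G  -0.08   0.28   0.23   0.23  -0.12   0.23   0.23   0.05   0.21  -0.23  -0.19   0.25  -0.08  -0.13   0.12   0.07   0.07   0.08   0.10  -0.21
H   0.24   0.28   0.17   0.05   0.24   0.17   0.05   0.21   0.24   0.27   0.26   0.29   0.24   0.25   0.19   0.20   0.20   0.20   0.20   0.27
I  -0.62   0.50   0.32   0.32  -0.74   0.32   0.32  -0.23   0.27  -1.10  -0.98   0.39  -0.64  -0.80  -0.02  -0.16  -0.18  -0.14  -0.07  -1.05
L  -0.54   0.47   0.31   0.31  -0.65   0.31   0.31  -0.19   0.26  -0.98  -0.86   0.37  -0.56  -0.70   0.00  -0.12  -0.14  -0.11  -0.04  -0.93
K   0.31   0.38   0.16  -0.09   0.33   0.16  -0.09   0.25   0.29   0.39   0.37   0.39   0.32   0.34   0.21   0.24   0.24   0.23   0.22   0.38
M  -0.33   0.38   0.27   0.27  -0.41   0.27   0.27  -0.08   0.24  -0.64  -0.56   0.32  -0.34  -0.44   0.06  -0.04  -0.05  -0.02   0.02  -0.60
F  -0.43   0.42   0.29   0.29  -0.53   0.29   0.29  -0.13   0.25  -0.80  -0.70   0.34  -0.44  -0.57   0.03  -0.08  -0.09  -0.06  -0.01  -0.76
P   0.06   0.23   0.20   0.20   0.04   0.20   0.20   0.12   0.19  -0.02   0.00   0.21   0.06   0.03   0.15   0.13   0.13   0.13   0.14  -0.01
S  -0.03   0.26   0.22   0.22  -0.06   0.22   0.22   0.07   0.20  -0.16  -0.12   0.24  -0.04  -0.08   0.13   0.09   0.09   0.10   0.11  -0.14
T  -0.04   0.27   0.22   0.22  -0.08   0.22   0.22   0.07   0.20  -0.18  -0.14   0.24  -0.05  -0.09   0.13   0.09   0.08   0.09   0.11  -0.16
W  -0.02   0.26   0.22   0.22  -0.05   0.22   0.22   0.08   0.20  -0.14  -0.11   0.23  -0.02  -0.06   0.13   0.10   0.09   0.10   0.12  -0.13
Y   0.02   0.24   0.21   0.21   0.00   0.21   0.21   0.10   0.20  -0.07  -0.04   0.22   0.02  -0.01   0.14   0.11   0.11   0.12   0.13  -0.06
V  -0.59   0.49   0.32   0.32  -0.71   0.32   0.32  -0.21   0.27  -1.05  -0.93   0.38  -0.60  -0.76  -0.01  -0.14  -0.16  -0.13  -0.06  -1.00
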
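# SYNTHETIC surrogate pairwise contact potential (spatial-neighbour term).
# This is NOT the published Bastolla-Vendruscolo potential: that table is
# not printed in the citing literature available here.  Values are a
# synthetic stand-in built from a hydrophobicity + charge decomposition
# e(a,b) = -0.20*(q_a+q_b) - 0.60*q_a*q_b + 0.30*c_a*c_b, q = KD/4.5.
# Replace this file with the genuine published table (same whitespace
# dialect) for production use.
   A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V
A  -0.26   0.36   0.26   0.26  -0.32   0.26   0.26  -0.04   0.23  -0.52  -0.45   0.30  -0.27  -0.35   0.08  -0.00  -0.01   0.01   0.05  -0.49
R   0.36   0.10  -0.11  -0.41   0.42  -0.11  -0.41   0.16   0.07   0.60   0.54   0.15   0.37   0.45   0.06   0.13   0.14   0.12   0.08   0.57
N   0.26  -0.11  -0.05  -0.05   0.30  -0.05  -0.05   0.13  -0.03   0.42   0.38  -0.08   0.27   0.32   0.06   0.11   0.11   0.10   0.08   0.40
D   0.26  -0.41  -0.05   0.25   0.30  -0.05   0.25   0.13  -0.18   0.42   0.38  -0.38   0.27   0.32   0.06   0.11   0.11   0.10   0.08   0.40
C  -0.32   0.42   0.30   0.30  -0.41   0.30   0.30  -0.06   0.27  -0.64  -0.56   0.35  -0.34  -0.44   0.08  -0.02  -0.03  -0.00   0.04  -0.61
Q   0.26  -0.11  -0.05  -0.05   0.30  -0.05  -0.05   0.13  -0.03   0.42   0.38  -0.08   0.27   0.32   0.06   0.11   0.11   0.10   0.08   0.40
E   0.26  -0.41  -0.05   0.25   0.30  -0.05   0.25   0.13  -0.18   0.42   0.38  -0.38   0.27   0.32   0.06   0.11   0.11   0.10   0.08   0.40
G  -0.04   0.16   0.13   0.13  -0.06   0.13   0.13   0.03   0.12  -0.13  -0.11   0.14  -0.04  -0.07   0.07   0.04   0.04   0.05   0.06  -0.12
H   0.23   0.07  -0.03  -0.18   0.27  -0.03  -0.18   0.12   0.06   0.37   0.33   0.10   0.24   0.28   0.06   0.10   0.11   0.10   0.08   0.35
I  -0.52   0.60   0.42   0.42  -0.64   0.42   0.42  -0.13   0.37  -1.00  -0.88   0.49  -0.54  -0.70   0.08  -0.06  -0.08  -0.04   0.03  -0.95
L  -0.45   0.54   0.38   0.38  -0.56   0.38   0.38  -0.11   0.33  -0.88  -0.77   0.44  -0.47  -0.61   0.08  -0.04  -0.06  -0.03   0.04  -0.83
K   0.30   0.15  -0.08  -0.38   0.35  -0.08  -0.38   0.14   0.10   0.49   0.44   0.20   0.31   0.37   0.06   0.12   0.12   0.11   0.08   0.47
M  -0.27   0.37   0.27   0.27  -0.34   0.27   0.27  -0.04   0.24  -0.54  -0.47   0.31  -0.28  -0.37   0.08  -0.00  -0.01   0.01   0.05  -0.51
F  -0.35   0.45   0.32   0.32  -0.44   0.32   0.32  -0.07   0.28  -0.70  -0.61   0.37  -0.37  -0.48   0.08  -0.02  -0.04  -0.01   0.04  -0.66
P   0.08   0.06   0.06   0.06   0.08   0.06   0.06   0.07   0.06   0.08   0.08   0.06   0.08   0.08   0.07   0.07   0.07   0.07   0.07   0.08
S  -0.00   0.13   0.11   0.11  -0.02   0.11   0.11   0.04   0.10  -0.06  -0.04   0.12  -0.00  -0.02   0.07   0.05   0.05   0.05   0.06  -0.05
T  -0.01   0.14   0.11   0.11  -0.03   0.11   0.11   0.04   0.11  -0.08  -0.06   0.12  -0.01  -0.04   0.07   0.05   0.05   0.05   0.06  -0.07
W   0.01   0.12   0.10   0.10  -0.00   0.10   0.10   0.05   0.10  -0.04  -0.03   0.11   0.01  -0.01   0.07   0.05   0.05   0.06   0.06  -0.03
Y   0.05   0.08   0.08   0.08   0.04   0.08   0.08   0.06   0.08   0.03   0.04   0.08   0.05   0.04   0.07   0.06   0.06   0.06   0.07   0.03
V  -0.49   0.57   0.40   0.40  -0.61   0.40   0.40  -0.12   0.35  -0.95  -0.83   0.47  -0.51  -0.66   0.08  -0.05  -0.07  -0.03   0.03  -0.90
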
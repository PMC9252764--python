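# Methods

## Model

`evoddg` predicts the change in unfolding free energy upon substitution,
ΔΔG = ΔG_variant − ΔG_wild-type (kcal/mol; negative destabilises), as a
fixed linear combination of profile-weighted difference scores. The
underlying assumptions are:

1. **Evolution encodes stability.** The per-position amino-acid
   frequencies of a multiple sequence alignment (the *profile*) weight
   every score, so substitutions toward residues that homologs tolerate
   score near zero and substitutions against the family consensus score
   strongly.
2. **Differences, not states.** Every score is a difference of the form
   g(m) − g(w) under a weighting that does not depend on the direction
   of the substitution. This makes the predictor *exactly*
   anti-symmetric: scoring m→w under the same profile (and, in structure
   mode, the same wild-type structure) yields the exact IEEE negation of
   w→m. The test suite asserts this with `==`, not a tolerance.
3. **Untrained combination.** The combination weights (0.30/0.43/0.27 in
   sequence mode; 0.20/0.29/0.18/0.33 with structure, each set summing
   to 1) are fixed a priori in proportion to the scores' typical scales;
   no parameter of this package is ever fitted to ΔΔG data. The weighted
   sum is reported directly as kcal/mol with no further calibration.
4. **Wild-type structure only.** The 5 Å contact environment and the
   solvent accessibility are computed on the wild-type structure; no
   mutant modelling or side-chain repacking. Because the modulation
   factor (1.1 − ac) is also taken from the wild-type structure, a
   reverse variant evaluated against its *own* (mutant) structure would
   not negate exactly — the documented partial anti-symmetry loss of any
   structure-conditioned score. Under a fixed structure, as computed
   here, the negation is exact.

## Parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| sequence window (per side) | 2 | residues | neighbour-potential context W(j); ±2 positions, site excluded, clipped at termini |
| contact radius | 5.0 | Å | sphere around the variant site |
| contact rule | `heavy_min` | — | minimum heavy-atom–heavy-atom distance; `ca`/`cb` available |
| SASA probe radius | 1.4 | Å | water probe |
| SASA quadrature | 256 | points/atom | golden-spiral Shrake–Rupley |
| accessibility offset | 1.1 | — | modulation factor (1.1 − ac); ac=0.1 ⇒ factor 1 |
| display rounding | 1 | decimal | classification (↑/↓/=) applied after rounding |

The "2-residue sequence window" is read as ±2 positions (up to four
neighbours); this keeps the context symmetric and degrades gracefully at
the termini, and it is configurable (`window=`). The contact rule uses
minimum heavy-atom distance between residues because it is robust to
missing side-chain atoms; Cα/Cβ center-atom rules are exposed as
configuration for comparison.

## Parameter tables

BLOSUM62 and the Kyte–Doolittle scale are bundled as whitespace text
files (BLAST matrix dialect) and pinned by checksum in the tests;
BLOSUM62 is additionally cross-checked value-by-value against the copy
Biopython distributes. The two pairwise contact potentials (the
sequence-neighbour and spatial-neighbour terms) are **synthetic
surrogates**, constructed from a hydrophobicity + charge decomposition
(e(a,b) = −α(q_a+q_b) − βq_a q_b + γc_a c_b with q the scaled
Kyte–Doolittle value, c the formal charge; coefficients in the file
headers). This reproduces the qualitative structure of quasichemical
contact potentials — hydrophobic attraction dominating, like-charge
repulsion — but not the published numeric tables, which are not
reprinted in the accessible literature. `load_table` accepts a file path
in the same dialect, so dropping in a genuine published potential
requires no code change. All correctness guarantees (anti-symmetry,
identity-zero, oracle equivalences, monotone modulation) are independent
of the numeric content of these tables.

## Profiles

Frequencies are raw counts over the standard 20 amino acids: gaps and
nonstandard codes are excluded from numerator *and* denominator
(`count_gaps=True` switches to gaps-in-denominator), no pseudocounts and
no sequence redundancy weighting — the method is deliberately simple and
untrained. All-gap columns fall back to one-hot on the query residue. A
single sequence gives a one-hot profile, flagged low-information so the
CLI can warn. A3M lowercase insert states are removed and rows are
projected onto the query's match columns; positions are 1-based in the
query, matching variant strings like `T7W`.

## Structure handling

PDB files are parsed with gemmi: first model, requested chain only
(scores and accessibility are single-chain quantities), hydrogens and
waters dropped, alternate locations resolved to the highest-occupancy
conformer (ties toward altloc `A`), author numbering and insertion codes
preserved (variant tokens like `T27AW` address residue 27A). Nonstandard
residues are kept for geometry but never scored. The chain sequence is
mapped onto the query by exact identity over the aligned region, with
leading/trailing overhang allowed; mismatches raise with positions
listed.

Solvent accessibility uses an internal Shrake–Rupley implementation
(fixed golden-spiral quadrature, vdW radii C 1.70 / N 1.55 / O 1.52 /
S 1.80 / P 1.80, else 1.80 Å) normalised by the Rost–Sander maximum
accessibility constants and clamped to [0, 1]; an isolated residue
exceeds its folded-state maximum and clamps to 1. The test suite
cross-checks totals against Biopython's independent Shrake–Rupley (0.4%
agreement on the fixtures at 960 points). A `dssp` backend shells out to
an external `mkdssp`/`dssp` executable behind the same interface when
one is installed; it is untested plumbing, not a dependency.

## Synthetic data

The fixtures module generates every test input. Alignments: a random
query plus homolog rows sampled per position from a
Dirichlet-categorical scheme — Dirichlet weight `conservation` (default
10) on the query residue and 0.5 elsewhere, gap rate 0.1 — so column
conservation is controlled from near-uniform to exactly one-hot.
Structures: idealised alanine heavy-atom geometry placed to control one
property at a time — an isolated residue, a pair whose minimum
heavy-atom distance is set to 0.01 Å by bisection, a residue buried
under two concentric shells, random clusters for oracle tests, and an
insertion-code fixture numbered 27/27A/28.

What passing on these fixtures shows: the algebra, geometry and
bookkeeping of the method are correct, to machine precision where
exactness is claimed. What it does not show: predictive accuracy on real
proteins, which depends on deep hhblits-quality alignments, real
structures, and the genuine published potentials — none of which the
synthetic generator emulates (it makes no attempt to mimic experimental
ΔΔG distributions).

## Numerical choices

* Anti-symmetry is exact because each score is evaluated as a weighted
  sum of elementwise differences; negating the difference negates every
  addend and hence the floating-point sum exactly.
* The multi-site combiner max(s) + min(s) − mean(s) collapses to the
  single value for M=1 and the mean for M=2; permutation invariance is
  exact for max/min and holds to one ulp for the mean (summation order).
* Classification rounds to the display precision first, so |ΔΔG| < 0.05
  kcal/mol is reported neutral (=); there is no epsilon band beyond the
  rounding.
* Degenerate inputs: empty contact environments score 0; single-residue
  proteins have an empty sequence window and score 0 on the neighbour
  term; unmapped environment neighbours are skipped with a logged
  warning rather than failing the prediction.

## Problem sizes

The acceptance script exercises 1000 random profile/variant pairs for
sequence anti-symmetry, 100 random 8-residue structures for the contact
oracle (with 50 structure-mode anti-symmetry cases), 200 identity
variants, all 380 ordered residue pairs for the substitution-score
oracle and 50 random alignments for profile normalisation; the whole run
takes a few seconds on one CPU.

## Known limitations

* The surrogate contact potentials limit quantitative realism of s_Sk
  and s_BV until replaced with published tables.
* No mutant-structure modelling; no mmCIF input; no network fetching of
  PDB entries; substitutions only (no indels, no HGVS syntax).
* Generating the multiple sequence alignment is out of scope: the
  package consumes a precomputed A3M/aligned FASTA (deep alignments,
  e.g. hhblits against a clustered UniProt release, give the profiles
  the method was designed around).
* Predictions from one-hot (single-sequence) profiles are supported but
  carry far less information; the CLI warns when it falls back to them.
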
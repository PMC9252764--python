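# evoddg

Untrained, anti-symmetric prediction of protein stability change upon
amino acid substitution — ΔΔG = ΔG_variant − ΔG_wild-type, in kcal/mol,
with negative values destabilising.

`evoddg` is for people who need a fast, transparent ΔΔG baseline:
protein engineers triaging candidate substitutions, variant-effect
analysts who want an evolutionary/energetic sanity check next to trained
predictors, and method developers who need an honest benchmark whose
parameters cannot have been overfitted — every weight is fixed a priori,
nothing is trained.

## The method

Each substitution w→m at query position *j* is scored against the
per-position amino-acid frequency profile *f* of a multiple sequence
alignment of the protein:

* **s_Bl** = Σ_a f_j(a)·[B(a,m) − B(a,w)] — change in BLOSUM62
  substitution score, profile-weighted (evolutionary conservation);
* **s_Sk** = Σ_{k∈W(j)} Σ_a f_k(a)·[P_Sk(a,m) − P_Sk(a,w)] — change in
  pair-potential energy with the sequence neighbours, W(j) = positions
  within ±2 of *j*;
* **s_Hp** = f_j(m)·K(m) − f_j(w)·K(w) — profile-weighted
  Kyte–Doolittle hydropathy change;
* **s_BV** (structure mode) = Σ_{r∈sphere} Σ_a f_pos(r)(a)·[P_BV(a,m) −
  P_BV(a,w)] — change in contact-potential energy with every residue
  within a 5 Å heavy-atom sphere of the site, on the wild-type structure.

The predictions are fixed linear combinations,

    ΔΔG[SEQ] = 0.30·s_Bl + 0.43·s_Sk + 0.27·s_Hp
    ΔΔG[3D]  = (1.1 − ac) · (0.20·s_Bl + 0.29·s_Sk + 0.18·s_Hp + 0.33·s_BV)

where *ac* is the relative solvent accessibility of the site (exposed
sites perturb stability less). Multi-site variants combine their
per-substitution predictions s = (s_1 … s_M) as

    ΔΔG_mult = max(s) + min(s) − mean(s).

Every score is exactly anti-symmetric by construction: the reverse
substitution m→w gets exactly −ΔΔG under the same profile. See
`docs/methods.md` for assumptions, parameter details and limitations —
in particular, the two bundled contact potentials are clearly-labelled
synthetic surrogates that you can replace with published tables.

## Worked example

Generate a toy alignment and a toy structure (any aligned FASTA / A3M
and PDB file work the same way):

```python
from evoddg.fixtures import FixtureSpec, make_msa, write_msa, write_structure
write_msa(make_msa(FixtureSpec(seed=7, n_sequences=40, length=20)), "toy.fasta")
write_structure(FixtureSpec(structure_geometry=("buried_core", 16)), "core.pdb")
```

Sequence-mode prediction for a single and a double variant:

```
$ evoddg --mode seq --msa toy.fasta --variants "T7W" --variants "S6L,Y1M"
VARIANT	S_BL	S_SK	S_HP	DDG_SEQ	DDG_SEQ_FULL	EFFECT	COMPONENTS_SEQ
T7W	-1.6757	0.0477	0.1730	-0.4	-0.435487992	↓	-0.4355
S6L,Y1M	-3.8684|-3.0571	-1.1056|-0.6697	0.6263|0.6829	-1.2	-1.243800258	↓	-1.4668|-1.0208
```

`T7W` is predicted mildly destabilising (ΔΔG[SEQ] = −0.4 kcal/mol, ↓):
the profile disfavours tryptophan at position 7 (negative s_Bl), barely
offset by the neighbour-potential and hydropathy terms. The double
variant's row shows the per-substitution scores separated by `|`; its
−1.2 kcal/mol is max+min−mean of the two component predictions (for two
sites, their mean).

Structure mode on a deliberately buried site:

```
$ evoddg --mode 3d --pdb core.pdb --chain A --variants "A1W"
VARIANT	S_BL	S_SK	S_HP	S_BV	REL_ACC	DDG_3D	DDG_3D_FULL	EFFECT	COMPONENTS_3D
A1W	-7.0000	0.6000	-1.8000	4.5900	0.0000	-0.0	-0.03883	=	-0.0388
```

With no alignment supplied the profile is one-hot (the CLI warns), the
site is fully buried (REL_ACC 0.00, modulation factor 1.1), and the
opposing substitution and contact terms nearly cancel: ΔΔG[3D] rounds to
0.0 and the variant is classified neutral (=). `--mode both` adds the
ΔΔG[SEQ] columns; `--ascii` switches ↑/↓/= to +/-/=; `--details
FILE` writes per-site JSON records (profile frequencies at the site, 5 Å
contacts, accessibility).

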
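"""Sequence-based, profile-weighted substitution scores.

Three anti-symmetric scores per substitution w→m at query position j with
profile column f_j:

* substitution score   s_Bl = Σ_a f_j(a) · [B(a,m) − B(a,w)]
* neighbour potential  s_Sk = Σ_{k∈W(j)} Σ_a f_k(a) · [P_Sk(a,m) − P_Sk(a,w)]
  over the sequence window W(j) = {k : 0 < |k−j| ≤ window}
* hydropathy           s_Hp = f_j(m)·K(m) − f_j(w)·K(w)

Each score is exactly negated when wild-type and mutant are swapped under
the same profile, so the predictor is anti-symmetric by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .msa import SequenceProfile
from .params import AA_INDEX, load_table
from .variants import VariantSpec


@dataclass
class ScoreBreakdown:
    """The individual scores behind one substitution's prediction."""

    s_bl: float
    s_sk: float
    s_hp: float
    s_bv: float | None = None
    rel_acc: float | None = None


def _indices(v: VariantSpec) -> tuple[int, int]:
    for res in (v.wt, v.mut):
        if res not in AA_INDEX:
            raise ValidationError(f"variant {v}: nonstandard residue {res!r}")
    return AA_INDEX[v.wt], AA_INDEX[v.mut]


def score_blosum(profile: SequenceProfile, v: VariantSpec, pos: int | None = None) -> float:
    """Profile-weighted BLOSUM62 difference between mutant and wild type.

    ``pos`` overrides the profile position (used when variant numbering is
    structural); defaults to ``v.pos``.
    """
    iw, im = _indices(v)
    f = profile.column(pos if pos is not None else v.pos)
    blosum = load_table("blosum62")
    return float(np.dot(f, blosum.values[:, im] - blosum.values[:, iw]))


def score_skolnick(
    profile: SequenceProfile,
    query: str,
    v: VariantSpec,
    window: int = 2,
    pos: int | None = None,
) -> float:
    """Change in pair-potential energy with the sequence neighbours.

    Sums the profile-weighted potential difference over positions within
    ``window`` residues on either side of the site (site itself excluded,
    clipped to the sequence bounds); a single-residue protein scores 0.
    """
    iw, im = _indices(v)
    j = pos if pos is not None else v.pos
    if not 1 <= j <= len(query):
        raise ValidationError(f"variant {v}: position {j} outside sequence")
    pot = load_table("skolnick")
    diff = pot.values[:, im] - pot.values[:, iw]
    total = 0.0
    for k in range(max(1, j - window), min(len(query), j + window) + 1):
        if k == j:
            continue
        total += float(np.dot(profile.column(k), diff))
    return total


def score_hydrophobicity(
    profile: SequenceProfile, v: VariantSpec, pos: int | None = None
) -> float:
    """Profile-weighted hydropathy difference f(m)·K(m) − f(w)·K(w)."""
    iw, im = _indices(v)
    f = profile.column(pos if pos is not None else v.pos)
    kd = load_table("kyte_doolittle").values
    return float(f[im] * kd[im]) - float(f[iw] * kd[iw])


def sequence_breakdown(
    profile: SequenceProfile,
    query: str,
    v: VariantSpec,
    window: int = 2,
    pos: int | None = None,
) -> ScoreBreakdown:
    """All three sequence scores for one substitution."""
    return ScoreBreakdown(
        s_bl=score_blosum(profile, v, pos=pos),
        s_sk=score_skolnick(profile, query, v, window=window, pos=pos),
        s_hp=score_hydrophobicity(profile, v, pos=pos),
    )
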
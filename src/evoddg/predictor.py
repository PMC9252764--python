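"""Combining scores into a ΔΔG prediction.

Sign convention: ΔΔG = ΔG_variant − ΔG_wild-type, in kcal/mol; negative
values destabilise.  The sequence predictor is the fixed linear
combination

    ΔΔG[SEQ] = 0.30·s_Bl + 0.43·s_Sk + 0.27·s_Hp

and the structure predictor adds a contact-sphere term and a solvent-
accessibility modulation (exposed sites perturb stability less):

    ΔΔG[3D] = (1.1 − ac) · (0.20·s_Bl + 0.29·s_Sk + 0.18·s_Hp + 0.33·s_BV)

The weights are fixed a priori (proportional to score scales, normalised
to sum to 1) — nothing is fitted, which is what makes the predictor both
untrained and exactly anti-symmetric in sequence mode.  A multi-site
variant combines its per-substitution predictions s = (s_1 … s_M) as

    s_mult = max(s) + min(s) − mean(s)

so the extreme substitutions dominate, centred on the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import ConfigError, ValidationError
from .msa import SequenceProfile
from .seqscores import ScoreBreakdown, sequence_breakdown
from .structure import (
    StructureModel,
    accessibility_map,
    find_environment,
    score_bastolla,
)
from .variants import MultiVariant, VariantSpec, parse_variant_line

#: Fixed linear-combination weights, sequence mode (sum to 1).
WEIGHTS_SEQ = {"s_bl": 0.30, "s_sk": 0.43, "s_hp": 0.27}
#: Fixed linear-combination weights, structure mode (sum to 1).
WEIGHTS_3D = {"s_bl": 0.20, "s_sk": 0.29, "s_hp": 0.18, "s_bv": 0.33}
#: Accessibility modulation is (ACC_OFFSET - ac); ac=0.1 gives factor 1.
ACC_OFFSET = 1.1

MODES = ("SEQ", "3D", "BOTH")


@dataclass
class Prediction:
    """Final ΔΔG for one (multi-)variant in one mode."""

    variant: MultiVariant
    mode: str  # SEQ or 3D
    ddg: float  # kcal/mol, full precision
    effect: str  # increase / decrease / neutral (after display rounding)
    breakdowns: list[ScoreBreakdown]
    components: list[float]  # per-substitution ddg (length 1 for singles)
    details: list[dict] = field(default_factory=list)


def combine_seq(b: ScoreBreakdown) -> float:
    """Sequence-mode linear combination, kcal/mol."""
    return (
        WEIGHTS_SEQ["s_bl"] * b.s_bl
        + WEIGHTS_SEQ["s_sk"] * b.s_sk
        + WEIGHTS_SEQ["s_hp"] * b.s_hp
    )


def combine_3d(b: ScoreBreakdown) -> float:
    """Structure-mode combination with accessibility modulation, kcal/mol."""
    if b.s_bv is None or b.rel_acc is None:
        raise ConfigError(
            "structure-mode combination needs s_bv and rel_acc in the breakdown"
        )
    total = (
        WEIGHTS_3D["s_bl"] * b.s_bl
        + WEIGHTS_3D["s_sk"] * b.s_sk
        + WEIGHTS_3D["s_hp"] * b.s_hp
        + WEIGHTS_3D["s_bv"] * b.s_bv
    )
    return (ACC_OFFSET - b.rel_acc) * total


def combine_multi(components: Sequence[float]) -> float:
    """max + min − mean of the per-substitution predictions.

    Collapses to the single value for M=1 and to the mean for M=2.
    """
    if not components:
        raise ValidationError("cannot combine an empty list of predictions")
    return max(components) + min(components) - sum(components) / len(components)


def classify(ddg: float, decimals: int = 1) -> str:
    """Effect class after rounding for display: increase / decrease / neutral."""
    r = round(ddg, decimals)
    if r > 0:
        return "increase"
    if r < 0:
        return "decrease"
    return "neutral"


def _resolve_site(
    v: VariantSpec,
    profile: SequenceProfile,
    query: str,
    model: StructureModel | None,
    check_wt: bool = True,
):
    """Return (sequence position for profile lookup, structure residue or None)."""
    if model is not None:
        res = model.get(v.pos, v.icode)
        if not res.is_standard:
            raise ValidationError(f"variant {v}: residue {res.label} is nonstandard")
        if check_wt and res.one_letter != v.wt:
            raise ValidationError(
                f"variant {v}: structure has {res.one_letter} at {v.pos_label}, "
                f"not {v.wt}"
            )
        if res.seq_pos is None:
            raise ValidationError(
                f"variant {v}: residue {v.pos_label} is not mapped to the sequence"
            )
        seq_pos = res.seq_pos
    else:
        if v.icode:
            raise ValidationError(
                f"variant {v}: insertion codes need a structure (3D/BOTH mode)"
            )
        res, seq_pos = None, v.pos
    if not 1 <= seq_pos <= len(query):
        raise ValidationError(f"variant {v}: position {seq_pos} outside sequence")
    if check_wt and query[seq_pos - 1] != v.wt:
        raise ValidationError(
            f"variant {v}: expected wild-type {v.wt} at sequence position "
            f"{seq_pos}, found {query[seq_pos - 1]}"
        )
    return seq_pos, res


def predict(
    profile: SequenceProfile,
    variant: str | VariantSpec | MultiVariant,
    model: StructureModel | None = None,
    mode: str = "SEQ",
    query: str | None = None,
    window: int = 2,
    radius: float = 5.0,
    contact_rule: str = "heavy_min",
    decimals: int = 1,
    sasa_backend: str = "internal",
    sasa_points: int = 256,
    check_wt: bool = True,
) -> list[Prediction]:
    """Predict ΔΔG for one (multi-)variant.

    ``mode`` is SEQ, 3D, or BOTH; 3D/BOTH require ``model`` (whose residues
    must be mapped onto the profile's query sequence) and interpret variant
    positions as author residue numbers with optional insertion codes.
    ``check_wt=False`` skips the wild-type-residue consistency check, which
    is needed when scoring a reverse variant against the unchanged wild-type
    profile/structure (the anti-symmetry setting).  Returns one Prediction
    per requested mode.
    """
    mode = mode.upper()
    if mode not in MODES:
        raise ConfigError(f"unknown mode {mode!r}: expected one of {MODES}")
    if mode in ("3D", "BOTH") and model is None:
        raise ConfigError(f"mode {mode} requires a structure model")
    if isinstance(variant, str):
        variant = parse_variant_line(variant, allow_identity=True)
    elif isinstance(variant, VariantSpec):
        variant = MultiVariant(variants=(variant,))
    query = query if query is not None else profile.query

    want_3d = mode in ("3D", "BOTH")
    acc = (
        accessibility_map(model, n_points=sasa_points, backend=sasa_backend)
        if want_3d
        else {}
    )

    breakdowns: list[ScoreBreakdown] = []
    details: list[dict] = []
    for v in variant:
        seq_pos, res = _resolve_site(v, profile, query, model, check_wt=check_wt)
        b = sequence_breakdown(profile, query, v, window=window, pos=seq_pos)
        detail = {
            "variant": str(v),
            "seq_pos": seq_pos,
            "wt_freq": profile.freq(seq_pos, v.wt),
            "mut_freq": profile.freq(seq_pos, v.mut),
        }
        if want_3d:
            env = find_environment(model, res, radius=radius, contact_rule=contact_rule)
            b.s_bv = score_bastolla(profile, env, v)
            b.rel_acc = acc[res.key]
            detail["contacts"] = [n.label for n in env.neighbors]
            detail["rel_acc"] = b.rel_acc
        breakdowns.append(b)
        details.append(detail)

    out = []
    for m in ("SEQ", "3D"):
        if m == "SEQ" and mode == "3D" or m == "3D" and not want_3d:
            continue
        comb = combine_seq if m == "SEQ" else combine_3d
        components = [comb(b) for b in breakdowns]
        ddg = combine_multi(components)
        out.append(
            Prediction(
                variant=variant,
                mode=m,
                ddg=ddg,
                effect=classify(ddg, decimals=decimals),
                breakdowns=breakdowns,
                components=components,
                details=details,
            )
        )
    return out
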
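"""Parsing and validation of variant strings.

A single substitution is written ``<wt><position><mut>``, e.g. ``T7W``.
In structure mode the position is the author residue number of the PDB
chain and may carry an insertion code (``T27AW`` = wild-type T at residue
27A, mutated to W).  Multi-site variants are comma-separated on one line:
``T7W, K6L``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from .errors import ValidationError

_TOKEN = re.compile(r"^([A-Z])([0-9]+)([A-Z]?)([A-Z])$")


@dataclass(frozen=True)
class VariantSpec:
    """One substitution: wild-type residue, position, variant residue.

    ``pos`` is 1-based in the query sequence, or the author residue number
    in structure mode, where ``icode`` may hold a PDB insertion code.
    """

    wt: str
    pos: int
    mut: str
    icode: str = ""

    @property
    def pos_label(self) -> str:
        return f"{self.pos}{self.icode}"

    def __str__(self) -> str:
        return f"{self.wt}{self.pos}{self.icode}{self.mut}"

    def reverse(self) -> "VariantSpec":
        return VariantSpec(wt=self.mut, pos=self.pos, mut=self.wt, icode=self.icode)


@dataclass(frozen=True)
class MultiVariant:
    """Ordered list of substitutions at pairwise-distinct positions."""

    variants: tuple[VariantSpec, ...]

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValidationError("empty multi-variant")
        seen: dict[str, VariantSpec] = {}
        for v in self.variants:
            if v.pos_label in seen:
                raise ValidationError(
                    f"duplicated position {v.pos_label} in multi-variant "
                    f"({seen[v.pos_label]}, {v})"
                )
            seen[v.pos_label] = v

    def __iter__(self) -> Iterator[VariantSpec]:
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    def __str__(self) -> str:
        return ",".join(str(v) for v in self.variants)


def parse_variant_token(token: str, allow_identity: bool = False) -> VariantSpec:
    token = token.strip().upper()
    m = _TOKEN.match(token)
    if not m:
        raise ValidationError(
            f"malformed variant token {token!r}: expected <wt><position><mut>, e.g. T7W"
        )
    wt, pos, icode, mut = m.groups()
    v = VariantSpec(wt=wt, pos=int(pos), mut=mut, icode=icode)
    if wt == mut and not allow_identity:
        raise ValidationError(f"variant {token!r}: wild-type and mutant are identical")
    return v


def parse_variant_line(line: str, allow_identity: bool = False) -> MultiVariant:
    """Parse one line into a MultiVariant; commas separate multi-site
    substitutions, whitespace around them is tolerated."""
    line = line.strip()
    if not line:
        raise ValidationError("empty variant line")
    return MultiVariant(
        variants=tuple(
            parse_variant_token(tok, allow_identity=allow_identity)
            for tok in line.split(",")
        )
    )


def parse_variants_file(path: str | Path) -> list[MultiVariant]:
    """One (multi-)variant per line; '#' starts a comment; blank lines skipped."""
    out = []
    for i, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            out.append(parse_variant_line(line))
        except ValidationError as e:
            raise ValidationError(f"{path}:{i}: {e}") from e
    if not out:
        raise ValidationError(f"{path}: no variants found")
    return out


def validate_against_sequence(mv: MultiVariant, sequence: str) -> MultiVariant:
    """Check every wild-type residue against the query sequence (1-based)."""
    for v in mv:
        if v.icode:
            raise ValidationError(
                f"variant {v}: insertion codes are only meaningful in structure mode"
            )
        if not 1 <= v.pos <= len(sequence):
            raise ValidationError(
                f"variant {v}: position {v.pos} outside sequence of length {len(sequence)}"
            )
        found = sequence[v.pos - 1]
        if found != v.wt:
            raise ValidationError(
                f"variant {v}: expected wild-type {v.wt} at position {v.pos}, "
                f"sequence has {found}"
            )
    return mv
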
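"""Multiple sequence alignments and per-position amino-acid profiles.

The profile — the frequency of each amino acid at each query position of
the alignment — is the weighting object of every score in the predictor.
Coordinates are 1-based in the query sequence throughout, matching variant
strings like ``T7W``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .errors import ParseError, ValidationError
from .params import AA_INDEX, AMINO_ACIDS

GAP_CHARS = frozenset("-.")


@dataclass
class Msa:
    """Alignment normalized to query coordinates: equal-length rows, no
    insert states, gap-free query row."""

    sequences: list[str]
    ids: list[str] = field(default_factory=list)
    query_index: int = 0

    @property
    def query(self) -> str:
        return self.sequences[self.query_index]

    @property
    def depth(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])


@dataclass
class SequenceProfile:
    """Per-position amino-acid frequencies over the standard 20 residues.

    ``freqs[j - 1]`` is the frequency vector (``AMINO_ACIDS`` order) at
    query position ``j``; ``depth`` counts the non-gap standard residues
    that entered each column.  Columns with depth 0 fall back to one-hot on
    the query residue.
    """

    query: str
    freqs: np.ndarray = field(repr=False)  # (L, 20)
    depth: np.ndarray = field(repr=False)  # (L,)
    single_sequence: bool = False  # one-hot fallback, low information

    @property
    def length(self) -> int:
        return len(self.query)

    def column(self, pos: int) -> np.ndarray:
        """Frequency vector at 1-based query position ``pos``."""
        if not 1 <= pos <= self.length:
            raise ValidationError(
                f"position {pos} outside sequence of length {self.length}"
            )
        return self.freqs[pos - 1]

    def freq(self, pos: int, aa: str) -> float:
        idx = AA_INDEX.get(aa)
        if idx is None:
            raise ValidationError(f"nonstandard residue {aa!r}")
        return float(self.column(pos)[idx])

    def to_tsv(self, path_or_handle) -> None:
        """Write position, query residue, depth and the 20 frequency columns."""
        handle = (
            open(path_or_handle, "w")
            if isinstance(path_or_handle, (str, Path))
            else path_or_handle
        )
        close = isinstance(path_or_handle, (str, Path))
        try:
            handle.write("pos\tres\tdepth\t" + "\t".join(AMINO_ACIDS) + "\n")
            for j in range(self.length):
                row = "\t".join(f"{v:.6g}" for v in self.freqs[j])
                handle.write(f"{j + 1}\t{self.query[j]}\t{int(self.depth[j])}\t{row}\n")
        finally:
            if close:
                handle.close()


def _normalize_a3m(row: str) -> str:
    # lowercase letters are insert states relative to the query; '.' pads them
    return "".join(c for c in row if not c.islower() and c != ".")


def read_msa(path: str | Path, dialect: str = "auto") -> Msa:
    """Read an alignment in A3M or aligned-FASTA dialect.

    A3M lowercase insert columns are removed, every row is projected onto
    the query's (first row by default) match columns, and the result is
    validated: equal row lengths, gap-free query.
    """
    if dialect not in {"a3m", "aligned_fasta", "auto"}:
        raise ParseError(f"unknown MSA dialect {dialect!r}")
    text = Path(path).read_text()
    if text.lstrip().startswith(">"):
        records = list(SeqIO.parse(io.StringIO(text), "fasta"))
        seqs = [str(r.seq) for r in records]
        ids = [r.id for r in records]
    else:
        # tolerate bare sequence lines (no FASTA headers)
        seqs = [ln.strip() for ln in text.splitlines() if ln.strip()]
        ids = [f"row{i + 1}" for i in range(len(seqs))]
    if not seqs:
        raise ParseError(f"{path}: empty alignment")

    if dialect == "auto":
        dialect = "a3m" if any(c.islower() or c == "." for s in seqs for c in s) else "aligned_fasta"
    if dialect == "a3m":
        seqs = [_normalize_a3m(s) for s in seqs]
    seqs = [s.upper() for s in seqs]

    length = len(seqs[0])
    for i, s in enumerate(seqs):
        if len(s) != length:
            raise ParseError(
                f"{path}: row {i + 1} ({ids[i]}) has length {len(s)} after "
                f"{dialect} normalization, expected {length} (query row)"
            )
    # project all rows onto the query's non-gap columns
    keep = [j for j, c in enumerate(seqs[0]) if c not in GAP_CHARS]
    if len(keep) < length:
        seqs = ["".join(s[j] for j in keep) for s in seqs]
    if any(c in GAP_CHARS for c in seqs[0]):
        raise ParseError(f"{path}: query row still contains gaps after projection")
    return Msa(sequences=seqs, ids=ids, query_index=0)


def build_profile(msa: Msa, count_gaps: bool = False) -> SequenceProfile:
    """Column-wise amino-acid frequencies of the alignment.

    Gaps and nonstandard codes are excluded from the numerator; by default
    they are excluded from the denominator too (frequencies over the
    observed standard residues).  ``count_gaps=True`` keeps gaps in the
    denominator instead.
    """
    query = msa.query
    L = len(query)
    counts = np.zeros((L, 20))
    gap_counts = np.zeros(L)
    for row in msa.sequences:
        for j, c in enumerate(row):
            idx = AA_INDEX.get(c)
            if idx is not None:
                counts[j, idx] += 1
            elif c in GAP_CHARS:
                gap_counts[j] += 1
    depth = counts.sum(axis=1)
    denom = depth + gap_counts if count_gaps else depth
    freqs = np.zeros_like(counts)
    ok = denom > 0
    freqs[ok] = counts[ok] / denom[ok, None]
    for j in np.nonzero(~(depth > 0))[0]:  # empty column: one-hot on the query
        idx = AA_INDEX.get(query[j])
        if idx is None:
            raise ValidationError(
                f"nonstandard query residue {query[j]!r} at position {j + 1}"
            )
        freqs[j, idx] = 1.0
    return SequenceProfile(query=query, freqs=freqs, depth=depth)


def single_sequence_profile(sequence: str) -> SequenceProfile:
    """One-hot profile from a bare sequence (no alignment; low information)."""
    sequence = sequence.upper()
    freqs = np.zeros((len(sequence), 20))
    for j, c in enumerate(sequence):
        idx = AA_INDEX.get(c)
        if idx is None:
            raise ValidationError(f"nonstandard residue {c!r} at position {j + 1}")
        freqs[j, idx] = 1.0
    return SequenceProfile(
        query=sequence,
        freqs=freqs,
        depth=np.ones(len(sequence)),
        single_sequence=True,
    )
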
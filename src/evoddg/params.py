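"""Fixed parameter tables: substitution matrix, pair potentials, hydropathy scale.

All scores in this package are weighted combinations of lookups into four
tables over the 20 standard amino acids:

* BLOSUM62 — evolutionary substitution scores;
* a pairwise contact potential for sequence neighbours ("skolnick" slot);
* the Kyte–Doolittle hydropathy scale;
* a pairwise contact potential for spatial neighbours
  ("bastolla_vendruscolo" slot).

The two contact-potential slots ship with synthetic surrogate tables (see
the data file headers for their construction); ``load_table`` also accepts
a path so genuine published tables in the same whitespace dialect can be
substituted without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import ConfigError

#: Canonical ordering of the 20 standard amino acids (BLAST matrix order).
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

_BUNDLED = {
    "blosum62": "blosum62.txt",
    "skolnick": "skolnick_synthetic.txt",
    "kyte_doolittle": "kyte_doolittle.txt",
    "bastolla_vendruscolo": "bastolla_vendruscolo_synthetic.txt",
}


def _check_residue(a: str) -> int:
    idx = AA_INDEX.get(a)
    if idx is None:
        raise ConfigError(
            f"nonstandard amino-acid code {a!r}: tables cover only the 20 "
            f"standard residues; map or skip nonstandard residues upstream"
        )
    return idx


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric 20x20 score table indexed by one-letter residue pairs.

    Used both for the BLOSUM62 substitution matrix and for the energy-like
    pair potentials (the algebra is identical; only the interpretation of
    the values differs).
    """

    name: str
    values: np.ndarray = field(repr=False)  # (20, 20), AMINO_ACIDS order

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (20, 20):
            raise ConfigError(f"table {self.name}: expected 20x20, got {v.shape}")
        if not np.array_equal(v, v.T):
            ij = np.argwhere(v != v.T)[0]
            raise ConfigError(
                f"table {self.name}: not symmetric at "
                f"({AMINO_ACIDS[ij[0]]},{AMINO_ACIDS[ij[1]]})"
            )

    def lookup(self, a: str, b: str) -> float:
        return float(self.values[_check_residue(a), _check_residue(b)])

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return self.lookup(*pair)

    def column(self, b: str) -> np.ndarray:
        """Score of every amino acid (in ``AMINO_ACIDS`` order) against ``b``."""
        return self.values[:, _check_residue(b)]


# pair potentials share the container; alias kept for intent at call sites
PairPotential = SubstitutionMatrix


@dataclass(frozen=True)
class HydrophobicityScale:
    name: str
    values: np.ndarray = field(repr=False)  # (20,), AMINO_ACIDS order

    def __post_init__(self) -> None:
        if self.values.shape != (20,):
            raise ConfigError(f"scale {self.name}: expected 20 values")

    def lookup(self, a: str) -> float:
        return float(self.values[_check_residue(a)])

    def __getitem__(self, a: str) -> float:
        return self.lookup(a)

    @property
    def vector(self) -> np.ndarray:
        return self.values


def _data_text(filename: str) -> str:
    return resources.files("evoddg.data").joinpath(filename).read_text()


def _parse_matrix(text: str, name: str) -> SubstitutionMatrix:
    """Parse whitespace-delimited square matrix with a header row of codes
    (BLAST matrix dialect), '#' comments ignored."""
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split()
    if sorted(header) != sorted(AMINO_ACIDS):
        raise ConfigError(f"table {name}: header must list the 20 standard residues")
    vals = np.full((20, 20), np.nan)
    for ln in lines[1:]:
        parts = ln.split()
        i = _check_residue(parts[0])
        if len(parts) != 21:
            raise ConfigError(f"table {name}: row {parts[0]} has {len(parts) - 1} values")
        for col_code, v in zip(header, parts[1:]):
            vals[i, _check_residue(col_code)] = float(v)
    if np.isnan(vals).any():
        raise ConfigError(f"table {name}: incomplete (missing rows)")
    return SubstitutionMatrix(name=name, values=vals)


def _parse_scale(text: str, name: str) -> HydrophobicityScale:
    vals = np.full(20, np.nan)
    for ln in text.splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        code, v = ln.split()
        vals[_check_residue(code)] = float(v)
    if np.isnan(vals).any():
        raise ConfigError(f"scale {name}: incomplete")
    return HydrophobicityScale(name=name, values=vals)


@lru_cache(maxsize=None)
def load_table(name: str) -> SubstitutionMatrix | HydrophobicityScale:
    """Load a bundled table by slot name, or any table file by path.

    ``name`` is one of ``blosum62``, ``skolnick``, ``kyte_doolittle``,
    ``bastolla_vendruscolo``, or a path to a file in the same whitespace
    dialect (matrix if it has a header row of 20 codes, scale otherwise).
    """
    if name in _BUNDLED:
        text = _data_text(_BUNDLED[name])
    elif Path(name).is_file():
        text = Path(name).read_text()
    else:
        raise ConfigError(
            f"unknown table {name!r}: expected one of {sorted(_BUNDLED)} or a file path"
        )
    first = next(
        ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")
    )
    if len(first.split()) >= 20:
        return _parse_matrix(text, name)
    return _parse_scale(text, name)
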
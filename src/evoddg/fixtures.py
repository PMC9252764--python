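"""Deterministic synthetic inputs: toy alignments and toy structures.

Every test input is generated here, with controlled properties (column
conservation, inter-residue distances, burial) and full determinism from a
seed.  Toy structures use an idealised alanine heavy-atom template; only
distances and exposure are controlled, not stereochemical realism.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .msa import Msa
from .params import AMINO_ACIDS

# idealised alanine heavy atoms, CA at the origin (Å)
_TEMPLATE_ATOMS = ["N", "CA", "C", "O", "CB"]
_TEMPLATE_ELEMENTS = ["N", "C", "C", "O", "C"]
_TEMPLATE_COORDS = np.array(
    [
        [-0.525, 1.363, 0.000],  # N
        [0.000, 0.000, 0.000],  # CA
        [1.526, 0.000, 0.000],  # C
        [2.147, 1.060, 0.000],  # O
        [-0.507, -0.775, -1.222],  # CB
    ]
)


@dataclass
class FixtureSpec:
    """Parameters of a synthetic input; same seed → same output."""

    seed: int = 0
    n_sequences: int = 50
    length: int = 25
    conservation: float = 10.0  # Dirichlet weight on the query residue
    gap_fraction: float = 0.1
    structure_geometry: object = "isolated"  # or ("pair_at_distance", d), ...


def make_msa(spec: FixtureSpec) -> Msa:
    """Sample a toy alignment around a random query sequence.

    Per-position residue probabilities are Dirichlet-distributed with
    weight ``conservation`` on the query residue and 0.5 elsewhere, so
    large values give near one-hot columns and small values near-uniform
    ones; homolog rows then sample from those probabilities, with gaps at
    rate ``gap_fraction``.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    query = "".join(rng.choice(list(AMINO_ACIDS), size=L))
    alpha = np.full((L, 20), 0.5)
    for j, c in enumerate(query):
        alpha[j, AMINO_ACIDS.index(c)] = spec.conservation
    probs = np.array([rng.dirichlet(alpha[j]) for j in range(L)])
    rows = [query]
    for _ in range(spec.n_sequences - 1):
        chars = [
            "-"
            if rng.random() < spec.gap_fraction
            else AMINO_ACIDS[rng.choice(20, p=probs[j])]
            for j in range(L)
        ]
        rows.append("".join(chars))
    ids = ["query"] + [f"homolog{i}" for i in range(1, len(rows))]
    return Msa(sequences=rows, ids=ids, query_index=0)


def write_msa(msa: Msa, path: str | Path) -> Path:
    """Write an alignment as aligned FASTA."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in zip(msa.ids, msa.sequences):
            fh.write(f">{name}\n{seq}\n")
    return path


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)).min())


def _pair_offset(d: float) -> float:
    """Translation along x putting the pair's minimum heavy-atom distance at d."""
    lo, hi = 0.0, d + 10.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _min_dist(_TEMPLATE_COORDS, _TEMPLATE_COORDS + [mid, 0, 0]) < d:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _residue(number: int, icode: str, coords: np.ndarray) -> gemmi.Residue:
    res = gemmi.Residue()
    res.name = "ALA"
    res.seqid = gemmi.SeqId(number, icode or " ")
    for name, el, xyz in zip(_TEMPLATE_ATOMS, _TEMPLATE_ELEMENTS, coords):
        a = gemmi.Atom()
        a.name = name
        a.element = gemmi.Element(el)
        a.occ = 1.0
        a.b_iso = 20.0
        a.pos = gemmi.Position(*xyz)
        res.add_atom(a)
    return res


def make_structure(spec: FixtureSpec) -> str:
    """Emit PDB text for the requested toy geometry.

    * ``"isolated"`` — a single fully exposed residue;
    * ``("pair_at_distance", d)`` — two residues whose minimum heavy-atom
      distance equals d to within 0.01 Å;
    * ``("buried_core", n_shell)`` — a central residue enclosed by two
      concentric shells of residues (n_shell on the inner one);
    * ``("random_cluster", n)`` — n residues scattered in a box, for
      brute-force contact-oracle tests;
    * ``"insertion_codes"`` — three residues numbered 27, 27A, 28.
    """
    geom = spec.structure_geometry
    kind, arg = (geom, None) if isinstance(geom, str) else geom
    placements: list[tuple[int, str, np.ndarray]] = []
    if kind == "isolated":
        placements = [(1, "", _TEMPLATE_COORDS)]
    elif kind == "pair_at_distance":
        t = _pair_offset(float(arg))
        placements = [
            (1, "", _TEMPLATE_COORDS),
            (2, "", _TEMPLATE_COORDS + [t, 0.0, 0.0]),
        ]
    elif kind == "buried_core":
        n_shell = int(arg)
        placements = [(1, "", _TEMPLATE_COORDS)]
        num = 2
        for radius, n in ((4.8, n_shell), (8.2, 2 * n_shell)):
            for direction in _fibonacci_sphere(n):
                placements.append((num, "", _TEMPLATE_COORDS + radius * direction))
                num += 1
    elif kind == "random_cluster":
        rng = np.random.default_rng(spec.seed)
        n = int(arg)
        centers = rng.uniform(-8.0, 8.0, size=(n, 3))
        placements = [
            (i + 1, "", _TEMPLATE_COORDS + centers[i]) for i in range(n)
        ]
    elif kind == "insertion_codes":
        placements = [
            (27, "", _TEMPLATE_COORDS),
            (27, "A", _TEMPLATE_COORDS + [4.0, 0.0, 0.0]),
            (28, "", _TEMPLATE_COORDS + [8.0, 0.0, 0.0]),
        ]
    else:
        raise ValueError(f"unknown structure geometry {geom!r}")

    st = gemmi.Structure()
    st.name = f"fixture_{kind}_seed{spec.seed}"
    st.add_model(gemmi.Model("1"))
    chain = gemmi.Chain("A")
    for number, icode, coords in placements:
        chain.add_residue(_residue(number, icode, coords))
    st[0].add_chain(chain)
    return st.make_pdb_string()


def write_structure(spec: FixtureSpec, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(make_structure(spec))
    return path
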
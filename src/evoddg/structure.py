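"""Structure handling: chain extraction, contact environment, accessibility.

The structure-based score looks at the spatial environment of the variant
site — every residue with a heavy atom within a cutoff sphere (default
5 Å) of the site's heavy atoms on the *wild-type* structure — and at the
site's relative solvent accessibility, computed with a Shrake–Rupley
numeric SASA (1.4 Å probe) normalised by per-residue-type maximum
accessibility constants.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import ConfigError, ParseError, ValidationError
from .msa import SequenceProfile
from .params import AA_INDEX, load_table
from .variants import VariantSpec

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# van der Waals radii (Å) for heavy elements; generic fallback for others
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
DEFAULT_VDW = 1.80

# Maximum accessible surface area per residue type (Å^2), Rost & Sander
# (1994) constants; used to normalise SASA to relative accessibility.
MAX_ACC = {
    "A": 106.0, "R": 248.0, "N": 157.0, "D": 163.0, "C": 135.0,
    "Q": 198.0, "E": 194.0, "G": 84.0, "H": 184.0, "I": 169.0,
    "L": 164.0, "K": 205.0, "M": 188.0, "F": 197.0, "P": 136.0,
    "S": 130.0, "T": 142.0, "W": 227.0, "Y": 222.0, "V": 142.0,
}

PROBE_RADIUS = 1.4  # Å, water probe


@dataclass
class StructureResidue:
    """One residue of the extracted chain, author numbering preserved."""

    number: int
    icode: str
    name: str  # 3-letter code
    one_letter: str | None  # None for nonstandard types
    atom_names: list[str]
    coords: np.ndarray  # (n_atoms, 3) heavy-atom coordinates, Å
    elements: list[str]
    seq_pos: int | None = None  # 1-based query-sequence position, if mapped

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)

    @property
    def label(self) -> str:
        return f"{self.name}{self.number}{self.icode}"

    @property
    def is_standard(self) -> bool:
        return self.one_letter is not None


@dataclass
class StructureModel:
    """A single extracted chain: ordered residues plus a sequence mapping."""

    chain_id: str
    residues: list[StructureResidue]
    seq_map: dict[tuple[int, str], int] = field(default_factory=dict)

    @property
    def sequence(self) -> str:
        """One-letter sequence of the standard residues, chain order."""
        return "".join(r.one_letter for r in self.residues if r.is_standard)

    def get(self, number: int, icode: str = "") -> StructureResidue:
        for r in self.residues:
            if r.key == (number, icode):
                return r
        raise ValidationError(
            f"residue {number}{icode} not found in chain {self.chain_id}"
        )


@dataclass
class ResidueEnvironment:
    """Contact sphere around a variant site on the wild-type structure."""

    center: StructureResidue
    neighbors: list[StructureResidue]
    radius: float
    rel_acc: float | None = None


def _select_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate locations: keep, per atom name, the highest
    occupancy; ties broken toward altloc 'A' (lexicographically first)."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
        elif (atom.occ, -ord(atom.altloc or "\x00")) > (
            prev.occ, -ord(prev.altloc or "\x00")
        ):
            by_name[atom.name] = atom
    return list(by_name.values())


def read_structure(path: str | Path, chain: str) -> StructureModel:
    """Extract one chain from a PDB file.

    First model only; hydrogens and waters dropped; altlocs resolved to the
    highest-occupancy conformer; author residue numbering and insertion
    codes preserved.  Nonstandard (incl. HETATM) residues are retained for
    geometry but flagged so scoring skips them.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as e:
        raise ParseError(f"{path}: cannot parse PDB: {e}") from e
    if len(st) == 0:
        raise ParseError(f"{path}: no models in file")
    model = st[0]
    gchain = None
    for ch in model:
        if ch.name == chain:
            gchain = ch
            break
    if gchain is None:
        raise ParseError(
            f"{path}: chain {chain!r} not found (available: "
            f"{[c.name for c in model]})"
        )
    residues: list[StructureResidue] = []
    for res in gchain:
        if res.is_water():
            continue
        atoms = [a for a in _select_altlocs(res) if not a.element.is_hydrogen]
        if not atoms:
            continue
        icode = res.seqid.icode.strip()
        residues.append(
            StructureResidue(
                number=res.seqid.num,
                icode=icode,
                name=res.name,
                one_letter=THREE_TO_ONE.get(res.name),
                atom_names=[a.name for a in atoms],
                coords=np.array([[a.pos.x, a.pos.y, a.pos.z] for a in atoms]),
                elements=[a.element.name for a in atoms],
            )
        )
    if not any(r.is_standard for r in residues):
        raise ParseError(f"{path}: chain {chain!r} has no standard residues")
    m = StructureModel(chain_id=chain, residues=residues)
    # default mapping: chain order onto its own sequence
    map_to_sequence(m, m.sequence)
    return m


def map_to_sequence(model: StructureModel, query: str) -> StructureModel:
    """Map structure residues onto 1-based positions of ``query``.

    The chain's one-letter sequence must match the query exactly over the
    aligned region; either may overhang the other at the ends.  Mismatches
    raise with the offending positions listed.
    """
    chain_seq = model.sequence
    std = [r for r in model.residues if r.is_standard]
    offset = None
    if len(chain_seq) <= len(query):
        idx = query.find(chain_seq)
        if idx >= 0:
            offset = idx  # chain residue i -> query pos idx + i + 1
    else:
        idx = chain_seq.find(query)
        if idx >= 0:
            offset = -idx
    if offset is None:
        # report the best sliding alignment for diagnostics
        best_off, best_mm = 0, None
        for off in range(-len(chain_seq) + 1, len(query)):
            mm = [
                i for i in range(len(chain_seq))
                if 0 <= off + i < len(query) and chain_seq[i] != query[off + i]
            ]
            overlap = sum(1 for i in range(len(chain_seq)) if 0 <= off + i < len(query))
            if overlap and (best_mm is None or len(mm) < len(best_mm)):
                best_off, best_mm = off, mm
        raise ValidationError(
            "chain sequence does not match the query sequence; best alignment "
            f"(offset {best_off}) mismatches at chain positions "
            f"{[i + 1 for i in (best_mm or [])][:10]}"
        )
    model.seq_map = {}
    for i, r in enumerate(std):
        qpos = offset + i
        r.seq_pos = qpos + 1 if 0 <= qpos < len(query) else None
        if r.seq_pos is not None:
            model.seq_map[r.key] = r.seq_pos
    return model


def find_environment(
    model: StructureModel,
    site: StructureResidue | tuple[int, str],
    radius: float = 5.0,
    contact_rule: str = "heavy_min",
) -> ResidueEnvironment:
    """Residues in the contact sphere around the variant site.

    ``heavy_min`` (default): a residue is a neighbour when its minimum
    heavy-atom distance to any heavy atom of the site is ≤ ``radius``.
    ``ca``/``cb`` use the distance between the named atoms instead (CB
    falling back to CA for glycine).
    """
    if not isinstance(site, StructureResidue):
        site = model.get(*site)
    if site.coords.size == 0:
        raise ValidationError(f"residue {site.label} has no heavy-atom coordinates")

    def _point(r: StructureResidue, atom: str) -> np.ndarray | None:
        for name, xyz in zip(r.atom_names, r.coords):
            if name == atom:
                return xyz[None, :]
        if atom == "CB":  # glycine fallback
            return _point(r, "CA")
        return None

    neighbors = []
    for r in model.residues:
        if r is site or r.key == site.key:
            continue
        if contact_rule == "heavy_min":
            a, b = site.coords, r.coords
        else:
            atom = contact_rule.upper()
            a, b = _point(site, atom), _point(r, atom)
            if a is None or b is None:
                continue
        if b.size and cdist(a, b).min() <= radius:
            neighbors.append(r)
    return ResidueEnvironment(center=site, neighbors=neighbors, radius=radius)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def shrake_rupley(
    coords: np.ndarray,
    elements: list[str],
    probe: float = PROBE_RADIUS,
    n_points: int = 256,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake–Rupley method.

    Each atom's solvent-extended sphere (vdW + probe) is sampled with a
    fixed quadrature of ``n_points``; a sample point is accessible when it
    lies outside every other atom's extended sphere.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.array([VDW_RADII.get(e, DEFAULT_VDW) for e in elements]) + probe
    sphere = _sphere_points(n_points)
    tree = cKDTree(coords)
    areas = np.zeros(len(coords))
    rmax = radii.max()
    for i in range(len(coords)):
        pts = coords[i] + radii[i] * sphere
        cand = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax) if j != i]
        if cand:
            d = cdist(pts, coords[cand])
            accessible = (d >= radii[cand]).all(axis=1)
        else:
            accessible = np.ones(n_points, dtype=bool)
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return areas


def _residue_sasa_internal(
    model: StructureModel, probe: float, n_points: int
) -> dict[tuple[int, str], float]:
    coords = np.vstack([r.coords for r in model.residues])
    elements = [e for r in model.residues for e in r.elements]
    areas = shrake_rupley(coords, elements, probe=probe, n_points=n_points)
    out, i = {}, 0
    for r in model.residues:
        n = len(r.coords)
        out[r.key] = float(areas[i : i + n].sum())
        i += n
    return out


def _residue_sasa_dssp(model: StructureModel) -> dict[tuple[int, str], float]:
    """Per-residue SASA via an external DSSP executable, if installed."""
    exe = shutil.which("mkdssp") or shutil.which("dssp")
    if exe is None:
        raise ConfigError("no DSSP executable (mkdssp/dssp) found on PATH")
    st = gemmi.Structure()
    st.add_model(gemmi.Model("1"))
    ch = gemmi.Chain(model.chain_id or "A")
    for r in model.residues:
        res = gemmi.Residue()
        res.name = r.name
        res.seqid = gemmi.SeqId(r.number, r.icode or " ")
        for name, el, xyz in zip(r.atom_names, r.elements, r.coords):
            a = gemmi.Atom()
            a.name, a.element, a.occ = name, gemmi.Element(el), 1.0
            a.pos = gemmi.Position(*xyz)
            res.add_atom(a)
        ch.add_residue(res)
    st[0].add_chain(ch)
    with tempfile.TemporaryDirectory() as tmp:
        pdb = Path(tmp, "chain.pdb")
        pdb.write_text(st.make_pdb_string())
        out = subprocess.run(
            [exe, str(pdb)], capture_output=True, text=True, check=True
        ).stdout
    sasa: dict[tuple[int, str], float] = {}
    in_table = False
    for line in out.splitlines():
        if line.startswith("  #  RESIDUE"):
            in_table = True
            continue
        if in_table and len(line) > 38 and line[13] != "!":
            num = int(line[5:10])
            icode = line[10].strip()
            sasa[(num, icode)] = float(line[34:38])
    return sasa


def accessibility_map(
    model: StructureModel,
    probe: float = PROBE_RADIUS,
    n_points: int = 256,
    backend: str = "internal",
) -> dict[tuple[int, str], float]:
    """Relative solvent accessibility in [0, 1] for every standard residue.

    SASA of each residue divided by its residue-type maximum-accessibility
    constant; ratios above 1 (possible for small or terminal residues) are
    clamped to 1.
    """
    if backend == "internal":
        sasa = _residue_sasa_internal(model, probe, n_points)
    elif backend == "dssp":
        sasa = _residue_sasa_dssp(model)
    else:
        raise ConfigError(f"unknown SASA backend {backend!r}")
    return {
        r.key: min(1.0, max(0.0, sasa[r.key] / MAX_ACC[r.one_letter]))
        for r in model.residues
        if r.is_standard and r.key in sasa
    }


def relative_accessibility(
    model: StructureModel,
    site: StructureResidue | tuple[int, str],
    probe: float = PROBE_RADIUS,
    n_points: int = 256,
    backend: str = "internal",
) -> float:
    """Relative solvent accessibility of one site (see ``accessibility_map``)."""
    if not isinstance(site, StructureResidue):
        site = model.get(*site)
    if not site.is_standard:
        raise ValidationError(f"residue {site.label}: no accessibility constant")
    return accessibility_map(model, probe, n_points, backend)[site.key]


def score_bastolla(
    profile: SequenceProfile, env: ResidueEnvironment, v: VariantSpec
) -> float:
    """Profile-weighted pair-potential change against the contact sphere.

    Σ over neighbours r, Σ_a f_{pos(r)}(a) · [P_BV(a,m) − P_BV(a,w)];
    neighbours without a sequence mapping (or nonstandard) are skipped with
    a warning.  Anti-symmetric under wt↔mut; empty environment scores 0.
    """
    for res in (v.wt, v.mut):
        if res not in AA_INDEX:
            raise ValidationError(f"variant {v}: nonstandard residue {res!r}")
    pot = load_table("bastolla_vendruscolo")
    diff = pot.values[:, AA_INDEX[v.mut]] - pot.values[:, AA_INDEX[v.wt]]
    total = 0.0
    for r in env.neighbors:
        if not r.is_standard or r.seq_pos is None:
            logger.warning(
                "environment of %s: neighbour %s has no sequence mapping; skipped",
                env.center.label, r.label,
            )
            continue
        total += float(np.dot(profile.column(r.seq_pos), diff))
    return total
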
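"""Chain extraction, contact environments, accessibility, structure score."""

import numpy as np
import pytest
from Bio.PDB import PDBParser
from Bio.PDB.SASA import ShrakeRupley

from evoddg import (
    ParseError,
    ValidationError,
    VariantSpec,
    find_environment,
    load_table,
    map_to_sequence,
    read_structure,
    relative_accessibility,
    score_bastolla,
    shrake_rupley,
)
from evoddg.fixtures import FixtureSpec, make_structure
from evoddg.structure import ResidueEnvironment
from .conftest import onehot_profile, structure_from_geometry

TWO_CHAIN_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 20.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00 20.00           C
TER
ATOM      3  CA  TRP B   1       0.000  20.00   0.000  1.00 20.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A  10       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA ASER A  10       1.000   0.000   0.000  0.40  0.00           C
ATOM      3  CA BSER A  10       1.200   0.000   0.000  0.60  0.00           C
ATOM      4  CB ASER A  10       2.000   1.000   0.000  0.50  0.00           C
ATOM      5  CB BSER A  10       2.000   1.200   0.000  0.50  0.00           C
ATOM      6  HB  SER A  10       2.000   2.000   0.000  1.00  0.00           H
HETATM    7  O   HOH A  90       8.000   8.000   8.000  1.00  0.00           O
END
"""


class TestReadStructure:
    def test_requested_chain_only(self, tmp_path):
        path = tmp_path / "two.pdb"
        path.write_text(TWO_CHAIN_PDB)
        model = read_structure(path, "A")
        assert [r.name for r in model.residues] == ["ALA", "GLY"]
        assert read_structure(path, "B").sequence == "W"

    def test_missing_chain_errors(self, tmp_path):
        path = tmp_path / "two.pdb"
        path.write_text(TWO_CHAIN_PDB)
        with pytest.raises(ParseError, match="chain 'Z' not found"):
            read_structure(path, "Z")

    def test_insertion_codes_preserved(self, tmp_path):
        model = structure_from_geometry(tmp_path, "insertion_codes")
        assert [r.key for r in model.residues] == [(27, ""), (27, "A"), (28, "")]
        assert model.get(27, "A").seq_pos == 2

    def test_altloc_resolved_to_highest_occupancy_ties_to_A(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(ALTLOC_PDB)
        (res,) = read_structure(path, "A").residues
        atoms = dict(zip(res.atom_names, res.coords))
        assert atoms["CA"][0] == pytest.approx(1.2)  # occupancy 0.6 wins
        assert atoms["CB"][1] == pytest.approx(1.0)  # tie -> altloc A
        assert "HB" not in atoms  # hydrogens dropped

    def test_waters_dropped_and_no_standard_residues_errors(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(ALTLOC_PDB)
        assert len(read_structure(path, "A").residues) == 1  # HOH gone
        bad = tmp_path / "wat.pdb"
        bad.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\nEND\n"
        )
        with pytest.raises(ParseError, match="no standard residues"):
            read_structure(bad, "A")


class TestSequenceMapping:
    def test_chain_inside_longer_query(self, tmp_path):
        model = structure_from_geometry(tmp_path, ("pair_at_distance", 4.0))
        map_to_sequence(model, "GGAAG")  # chain AA at offset 2
        assert model.seq_map == {(1, ""): 3, (2, ""): 4}

    def test_query_inside_longer_chain_leaves_overhang_unmapped(self, tmp_path):
        model = structure_from_geometry(tmp_path, "insertion_codes")  # AAA
        map_to_sequence(model, "AA")
        assert model.get(28, "").seq_pos is None

    def test_mismatch_reports_positions(self, tmp_path):
        model = structure_from_geometry(tmp_path, ("pair_at_distance", 4.0))
        with pytest.raises(ValidationError, match="does not match"):
            map_to_sequence(model, "GWG")


def brute_force_neighbors(model, site_key, radius):
    """Independent all-pairs heavy-atom distance scan."""
    site = model.get(*site_key)
    out = set()
    for r in model.residues:
        if r.key == site.key:
            continue
        dmin = min(
            float(np.linalg.norm(a - b)) for a in site.coords for b in r.coords
        )
        if dmin <= radius:
            out.add(r.key)
    return out


class TestFindEnvironment:
    def test_pair_within_radius(self, tmp_path):
        model = structure_from_geometry(tmp_path, ("pair_at_distance", 4.0))
        env = find_environment(model, (1, ""), radius=5.0)
        assert [r.key for r in env.neighbors] == [(2, "")]

    def test_pair_beyond_radius(self, tmp_path):
        model = structure_from_geometry(tmp_path, ("pair_at_distance", 6.0))
        assert find_environment(model, (1, ""), radius=5.0).neighbors == []

    def test_isolated_site_has_empty_environment(self, tmp_path):
        model = structure_from_geometry(tmp_path, "isolated")
        assert find_environment(model, (1, "")).neighbors == []

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle_on_random_clusters(self, tmp_path, seed):
        model = structure_from_geometry(
            tmp_path, ("random_cluster", 10), seed=seed, name=f"r{seed}.pdb"
        )
        for site in model.residues:
            got = {r.key for r in find_environment(model, site.key).neighbors}
            assert got == brute_force_neighbors(model, site.key, 5.0)

    def test_contact_relation_is_symmetric(self, tmp_path):
        model = structure_from_geometry(tmp_path, ("random_cluster", 12), seed=99)
        for a in model.residues:
            for b in find_environment(model, a.key).neighbors:
                back = {r.key for r in find_environment(model, b.key).neighbors}
                assert a.key in back

    def test_ca_contact_rule(self, tmp_path):
        # CA atoms sit exactly 3.8 Å apart in the two-chain fixture geometry
        model = structure_from_geometry(tmp_path, ("pair_at_distance", 6.0))
        env = find_environment(model, (1, ""), radius=5.0, contact_rule="ca")
        ca1 = dict(zip(model.residues[0].atom_names, model.residues[0].coords))["CA"]
        ca2 = dict(zip(model.residues[1].atom_names, model.residues[1].coords))["CA"]
        expected = np.linalg.norm(ca1 - ca2) <= 5.0
        assert bool(env.neighbors) == expected


class TestAccessibility:
    def test_isolated_residue_fully_exposed(self, tmp_path):
        model = structure_from_geometry(tmp_path, "isolated")
        assert relative_accessibility(model, (1, "")) >= 0.8

    def test_buried_core_below_exposed_threshold(self, tmp_path):
        model = structure_from_geometry(tmp_path, ("buried_core", 24))
        assert relative_accessibility(model, (1, "")) < 0.2

    def test_burial_monotone_under_added_shell(self, tmp_path):
        iso = structure_from_geometry(tmp_path, "isolated", name="iso.pdb")
        partial = structure_from_geometry(
            tmp_path, ("buried_core", 6), name="part.pdb"
        )
        full = structure_from_geometry(tmp_path, ("buried_core", 24), name="full.pdb")
        a = relative_accessibility(iso, (1, ""))
        b = relative_accessibility(partial, (1, ""))
        c = relative_accessibility(full, (1, ""))
        assert a > b > c

    def test_clamped_to_unit_interval(self, tmp_path):
        # raw SASA of an isolated alanine exceeds the folded-state maximum
        model = structure_from_geometry(tmp_path, "isolated")
        assert relative_accessibility(model, (1, "")) == 1.0

    def test_agrees_with_biopython_shrake_rupley(self, tmp_path):
        """Independent numeric oracle: same algorithm family, independent
        implementation and point set."""
        path = tmp_path / "oracle.pdb"
        path.write_text(
            make_structure(FixtureSpec(seed=4, structure_geometry=("random_cluster", 8)))
        )
        model = read_structure(path, "A")
        coords = np.vstack([r.coords for r in model.residues])
        elements = [e for r in model.residues for e in r.elements]
        mine = shrake_rupley(coords, elements, n_points=960).sum()
        s = PDBParser(QUIET=True).get_structure("o", str(path))
        sr = ShrakeRupley(n_points=960)
        sr.compute(s, level="S")
        assert mine == pytest.approx(s.sasa, rel=0.02)


class TestBastollaScore:
    def test_empty_environment_scores_zero(self, tmp_path):
        model = structure_from_geometry(tmp_path, "isolated")
        env = find_environment(model, (1, ""))
        prof = onehot_profile("A")
        assert score_bastolla(prof, env, VariantSpec("A", 1, "W")) == 0.0

    def test_single_neighbor_single_lookup(self, tmp_path):
        model = structure_from_geometry(tmp_path, ("pair_at_distance", 4.0))
        prof = onehot_profile("AG")  # neighbour column is one-hot G
        model.get(2, "").one_letter = "G"  # relabel the toy residue, then map
        map_to_sequence(model, "AG")
        env = find_environment(model, (1, ""))
        pot = load_table("bastolla_vendruscolo")
        got = score_bastolla(prof, env, VariantSpec("A", 1, "W"))
        assert got == pytest.approx(pot.lookup("G", "W") - pot.lookup("G", "A"))

    def test_antisymmetric_and_unmapped_neighbor_skipped(self, tmp_path, rng):
        model = structure_from_geometry(tmp_path, ("random_cluster", 6), seed=2)
        prof = onehot_profile(model.sequence)
        env = find_environment(model, (1, ""))
        direct = score_bastolla(prof, env, VariantSpec("A", 1, "W"))
        reverse = score_bastolla(prof, env, VariantSpec("W", 1, "A"))
        assert direct == -reverse
        # strip the mapping of one neighbour: its term must vanish
        if env.neighbors:
            dropped = env.neighbors[0]
            dropped.seq_pos = None
            partial_env = ResidueEnvironment(
                center=env.center, neighbors=env.neighbors, radius=env.radius
            )
            pruned = score_bastolla(prof, partial_env, VariantSpec("A", 1, "W"))
            env2 = ResidueEnvironment(
                center=env.center, neighbors=env.neighbors[1:], radius=env.radius
            )
            assert pruned == score_bastolla(prof, env2, VariantSpec("A", 1, "W"))
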
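"""Gaussian distance-restraint generation versus brute-force oracles."""

import numpy as np
import pytest

from swapsmith.restraints import (
    DEFAULT_CA_CUTOFF,
    DEFAULT_LIGAND_CUTOFF,
    DEFAULT_SIGMA,
    TIGHT_LIGAND_CUTOFF,
    DistanceRestraint,
    DomainDefinition,
    RestraintSet,
    intra_domain_restraints,
    ligand_restraints,
    map_restraints_to_model,
)
from swapsmith.structure import (
    AtomRecord,
    ProteinStructure,
    Residue,
    ResidueRangeSet,
)


def ca_structure(positions, start=1, chain="A"):
    residues = []
    for i, (x, y, z) in enumerate(positions):
        n = start + i
        residues.append(
            Residue(chain, n, "", "ALA",
                    [AtomRecord(n, "CA", "", "ALA", chain, n, "",
                                float(x), float(y), float(z), 1.0, "C")])
        )
    return ProteinStructure(residues, title="fixture")


def brute_force_count(structure, ranges, cutoff):
    """Independent O(n²) enumeration of intra-domain Cα pairs < cutoff."""
    cas = [
        r.ca.coords for r in structure.residues
        if r.ca is not None and ranges.contains(r.chain_id, r.res_seq)
    ]
    count = 0
    for i in range(len(cas)):
        for j in range(i + 1, len(cas)):
            if np.linalg.norm(cas[i] - cas[j]) < cutoff:
                count += 1
    return count


def random_two_domain_fixture(rng, n1, n2, spread):
    coords = rng.uniform(0, spread, size=(n1 + n2, 3))
    s = ca_structure(coords)
    dom = DomainDefinition(
        scaffold=ResidueRangeSet.from_string(f"A:1-{n1}"),
        transport=ResidueRangeSet.from_string(f"A:{n1 + 1}-{n1 + n2}"),
    )
    return s, dom


class TestIntraDomainRestraints:
    def test_collinear_five_residue_example(self):
        # Cα at 0, 10, 20, 30 and 70 Å: the 60 and 70 Å pairs fall outside
        # a strict 60 Å cutoff, leaving 8 restraints
        s = ca_structure([(d, 0, 0) for d in (0, 10, 20, 30, 70)])
        dom = DomainDefinition(
            scaffold=ResidueRangeSet.from_string("A:1-5"),
            transport=ResidueRangeSet.from_string("A:100-101"),
        )
        rset = intra_domain_restraints(s, dom, cutoff=60.0)
        assert len(rset) == 8
        assert rset.counts == {"scaffold": 8}

    def test_single_residue_domain_yields_nothing(self):
        s = ca_structure([(0, 0, 0), (5, 0, 0)])
        dom = DomainDefinition(
            scaffold=ResidueRangeSet.from_string("A:1-1"),
            transport=ResidueRangeSet.from_string("A:2-2"),
        )
        assert len(intra_domain_restraints(s, dom)) == 0

    def test_no_cross_domain_terms(self):
        rng = np.random.default_rng(7)
        n1, n2 = 9, 13
        s, dom = random_two_domain_fixture(rng, n1, n2, spread=20.0)
        rset = intra_domain_restraints(s, dom)  # everything well inside 60 Å
        assert len(rset) == n1 * (n1 - 1) // 2 + n2 * (n2 - 1) // 2
        for r in rset:
            same_scaffold = all(
                dom.scaffold.contains(a[0], a[1]) for a in (r.atom_a, r.atom_b)
            )
            same_transport = all(
                dom.transport.contains(a[0], a[1]) for a in (r.atom_a, r.atom_b)
            )
            assert same_scaffold or same_transport

    @pytest.mark.parametrize("seed", range(8))
    def test_counts_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(5, 40, size=2)
        s, dom = random_two_domain_fixture(rng, int(n1), int(n2), spread=90.0)
        rset = intra_domain_restraints(s, dom)
        expected = brute_force_count(s, dom.scaffold, 60.0) + brute_force_count(
            s, dom.transport, 60.0
        )
        assert len(rset) == expected

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(11)
        s, dom = random_two_domain_fixture(rng, 20, 20, spread=100.0)
        sizes = [
            len(intra_domain_restraints(s, dom, cutoff=c))
            for c in (20.0, 40.0, 60.0, 120.0)
        ]
        assert sizes == sorted(sizes)

    def test_targets_reproduce_measured_distances(self):
        rng = np.random.default_rng(3)
        s, dom = random_two_domain_fixture(rng, 10, 10, spread=30.0)
        cas = {r.key: r.ca.coords for r in s.residues}
        for r in intra_domain_restraints(s, dom):
            d = np.linalg.norm(
                cas[(r.atom_a[0], r.atom_a[1], "")] - cas[(r.atom_b[0], r.atom_b[1], "")]
            )
            assert r.target == pytest.approx(d, abs=1e-6)
            assert r.sigma == DEFAULT_SIGMA

    def test_missing_ca_warns_and_skips(self):
        s = ca_structure([(0, 0, 0), (5, 0, 0), (10, 0, 0)])
        s.residues[1].atoms = []  # strip the Cα
        dom = DomainDefinition(
            scaffold=ResidueRangeSet.from_string("A:1-3"),
            transport=ResidueRangeSet.from_string("A:10-11"),
        )
        with pytest.warns(UserWarning, match="lack a C"):
            rset = intra_domain_restraints(s, dom)
        assert len(rset) == 1

    def test_defaults_are_the_published_parameters(self):
        assert DEFAULT_CA_CUTOFF == 60.0
        assert DEFAULT_SIGMA == 0.1
        assert DEFAULT_LIGAND_CUTOFF == 5.0
        assert TIGHT_LIGAND_CUTOFF == 3.5


def ligand_complex():
    """One Na+ 3.4 Å from a single protein atom, plus more shells further out."""
    residues = [
        Residue("A", 1, "", "ALA",
                [AtomRecord(1, "CA", "", "ALA", "A", 1, "", 0.0, 0.0, 0.0, 1.0, "C"),
                 AtomRecord(2, "CB", "", "ALA", "A", 1, "", 1.5, 0.0, 0.0, 1.0, "C"),
                 AtomRecord(3, "HB1", "", "ALA", "A", 1, "", 3.0, 0.2, 0.0, 1.0, "H")]),
        Residue("A", 2, "", "GLY",
                [AtomRecord(4, "CA", "", "GLY", "A", 2, "", 7.5, 0.0, 0.0, 1.0, "C")]),
        Residue("A", 500, "", "NA",
                [AtomRecord(5, "NA", "", "NA", "A", 500, "", 4.9, 0.0, 0.0, 1.0, "Na")],
                is_hetatm=True),
        Residue("A", 600, "", "HOH",
                [AtomRecord(6, "O", "", "HOH", "A", 600, "", 4.9, 3.0, 0.0, 1.0, "O")],
                is_hetatm=True),
    ]
    return ProteinStructure(residues, title="ligand fixture")


class TestLigandRestraints:
    def test_single_contact_within_cutoff(self):
        s = ligand_complex()
        rset = ligand_restraints(s, ["NA"], cutoff=3.5)
        # Na at 4.9: distance 3.4 to CB (at 1.5), 4.9 to CA, 2.6 to CA of Gly
        # -> pairs strictly < 3.5: CB (3.4) and Gly CA (2.6)
        assert len(rset) == 2
        partners = {r.atom_b for r in rset}
        assert ("A", 1, "CB") in partners and ("A", 2, "CA") in partners

    def test_hydrogens_and_waters_excluded(self):
        s = ligand_complex()
        rset = ligand_restraints(s, ["NA"], cutoff=6.0)
        atoms = {r.atom_b for r in rset} | {r.atom_a for r in rset}
        assert all("H" not in a[2] or a[2] == "OH" for a in atoms)
        assert not any(a[1] == 600 for a in atoms)  # water never implicit

    def test_larger_cutoff_is_superset(self):
        s = ligand_complex()
        tight = {
            (r.atom_a, r.atom_b)
            for r in ligand_restraints(s, ["NA"], cutoff=TIGHT_LIGAND_CUTOFF)
        }
        loose = {
            (r.atom_a, r.atom_b)
            for r in ligand_restraints(s, ["NA"], cutoff=DEFAULT_LIGAND_CUTOFF)
        }
        assert tight <= loose and len(loose) > len(tight)

    def test_named_pairs_bypass_cutoff_and_reach_water(self):
        s = ligand_complex()
        named = [
            (("A", 500, "NA"), ("A", 2, "CA")),
            (("A", 500, "NA"), ("A", 600, "O")),  # crystallographic water
        ]
        rset = ligand_restraints(s, ["NA"], cutoff=0.1, named_pairs=named)
        assert len(rset) == 2
        water = [r for r in rset if r.atom_b == ("A", 600, "O")][0]
        assert water.target == pytest.approx(np.hypot(0.0, 3.0))

    def test_empty_ligand_selection_rejected(self):
        with pytest.raises(ValueError, match="matched no residue"):
            ligand_restraints(ligand_complex(), ["XYZ"])


class TestRestraintSet:
    def test_duplicate_pairs_rejected(self):
        r = DistanceRestraint(("A", 1, "CA"), ("A", 2, "CA"), 5.0, 0.1, "scaffold")
        flipped = DistanceRestraint(("A", 2, "CA"), ("A", 1, "CA"), 5.0, 0.1, "scaffold")
        with pytest.raises(ValueError, match="duplicate"):
            RestraintSet([r, flipped])

    def test_invalid_restraints_rejected(self):
        with pytest.raises(ValueError):
            DistanceRestraint(("A", 1, "CA"), ("A", 1, "CA"), 5.0, 0.1, "x")
        with pytest.raises(ValueError):
            DistanceRestraint(("A", 1, "CA"), ("A", 2, "CA"), -1.0, 0.1, "x")
        with pytest.raises(ValueError):
            DistanceRestraint(("A", 1, "CA"), ("A", 2, "CA"), 5.0, 0.0, "x")

    def test_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        s, dom = random_two_domain_fixture(rng, 8, 8, spread=25.0)
        rset = intra_domain_restraints(s, dom)
        p = tmp_path / "r.tsv"
        rset.to_tsv(p)
        back = RestraintSet.from_tsv(p)
        assert len(back) == len(rset)
        assert back.counts == rset.counts
        for a, b in zip(rset, back):
            assert b.target == pytest.approx(a.target, abs=1e-6)

    def test_mapping_to_model_numbering_drops_unaligned(self):
        r1 = DistanceRestraint(("A", 1, "CA"), ("A", 2, "CA"), 5.0, 0.1, "scaffold")
        r2 = DistanceRestraint(("A", 1, "CA"), ("A", 3, "CA"), 7.0, 0.1, "scaffold")
        mapping = {("A", 1, ""): ("A", 101, ""), ("A", 2, ""): ("A", 102, "")}
        with pytest.warns(UserWarning, match="dropped"):
            mapped = map_restraints_to_model(RestraintSet([r1, r2]), mapping)
        assert len(mapped) == 1
        assert mapped.restraints[0].atom_a == ("A", 101, "CA")
        assert mapped.restraints[0].atom_b == ("A", 102, "CA")
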
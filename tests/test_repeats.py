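"""Repeat alignment, swap-alignment construction, template assembly, refinement."""

import numpy as np
import pytest

from swapsmith.repeats import (
    PairwiseAlignment,
    RepeatDefinition,
    SwapAlignment,
    align_repeats,
    assemble_swapped_template,
    assign_ss_ca,
    build_swap_alignment,
    parse_dssp,
    refine_alignment,
)
from swapsmith.structure import ResidueRangeSet, select_residues
from swapsmith.synthetic import ToySpec, make_toy_transporter


def ru_structures(toy, truth):
    return (
        select_residues(toy, truth.repeat_def.ru1),
        select_residues(toy, truth.repeat_def.ru2),
    )


class TestAlignRepeats:
    def test_self_alignment_is_identity_with_tm_one(self, toy_clean):
        toy, truth = toy_clean
        ru1, _ = ru_structures(toy, truth)
        aln, tf, tm = align_repeats(ru1, ru1)
        assert tm == pytest.approx(1.0, abs=1e-9)
        assert all(a == b for a, b in aln.pair_list)
        assert len(aln.pair_list) == len(ru1)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-8)

    def test_recovers_ground_truth_correspondence(self):
        # mild asymmetry: the raw structural alignment alone resolves the
        # register (the harsher default conditions additionally need the
        # secondary-structure gap refinement; see the pipeline test below)
        toy, truth = make_toy_transporter(
            ToySpec(asymmetry_angle_deg=10.0, asymmetry_shift_A=2.0, seed=0)
        )
        ru1, ru2 = ru_structures(toy, truth)
        aln, _, tm = align_repeats(ru1, ru2)
        truthmap = dict(truth.correspondence)
        hits = sum(1 for a, b in aln.pair_list if truthmap.get(a) == b)
        assert hits / len(truth.correspondence) >= 0.9
        assert 0 < tm <= 1

    def test_refined_pipeline_recovers_correspondence_under_full_asymmetry(
        self, toy_pipeline
    ):
        toy, truth, result = toy_pipeline
        truthmap = dict(truth.correspondence)
        ru1_pairs = [
            (t, s)
            for (t, s), lab in zip(
                result.swap_alignment.columns, result.swap_alignment.block_labels
            )
            if lab == "RU1->RU2" and t is not None and s is not None
        ]
        hits = sum(1 for a, b in ru1_pairs if truthmap.get(a) == b)
        assert hits / len(truthmap) >= 0.9

    def test_symmetric_under_argument_swap(self, toy_default):
        toy, truth = toy_default
        ru1, ru2 = ru_structures(toy, truth)
        fwd, _, _ = align_repeats(ru1, ru2)
        rev, _, _ = align_repeats(ru2, ru1)
        fwd_pairs = set(fwd.pair_list)
        rev_pairs = {(a, b) for b, a in rev.pair_list}
        assert len(fwd_pairs.symmetric_difference(rev_pairs)) <= 4

    def test_pair_list_strictly_increasing(self, toy_default):
        toy, truth = toy_default
        ru1, ru2 = ru_structures(toy, truth)
        aln, _, _ = align_repeats(ru1, ru2)
        n1 = [a[1] for a, _ in aln.pair_list]
        n2 = [b[1] for _, b in aln.pair_list]
        assert n1 == sorted(n1) and len(set(n1)) == len(n1)
        assert n2 == sorted(n2) and len(set(n2)) == len(n2)
        # degapping reproduces the sources
        assert aln.gapped_seq1.replace("-", "") == ru1.sequence()
        assert aln.gapped_seq2.replace("-", "") == ru2.sequence()

    def test_short_repeats_rejected(self, toy_clean):
        toy, truth = toy_clean
        ru1, _ = ru_structures(toy, truth)
        tiny = select_residues(toy, ResidueRangeSet.from_string("A:1-5"))
        with pytest.raises(ValueError, match="at least 10"):
            align_repeats(tiny, ru1)


class TestBuildSwapAlignment:
    def test_symmetric_toy_gives_gapless_alignment(self, toy_symmetric):
        toy, truth = toy_symmetric
        ru1, ru2 = ru_structures(toy, truth)
        pa, _, _ = align_repeats(ru1, ru2)
        aln = build_swap_alignment(toy, truth.repeat_def, pa)
        ru_cols = [
            (t, s) for (t, s), lab in zip(aln.columns, aln.block_labels)
            if lab in ("RU1->RU2", "RU2->RU1")
        ]
        assert all(t is not None and s is not None for t, s in ru_cols)

    def test_column_bookkeeping(self, toy_pipeline):
        toy, truth, result = toy_pipeline
        aln = result.swap_alignment
        n_target = len(aln.target_order())
        template_only = sum(1 for t, _ in aln.columns if t is None)
        assert len(aln.columns) == n_target + template_only
        assert len(aln.target_gapped) == len(aln.template_gapped)
        # degapped rows reproduce the sequences
        assert aln.target_gapped.replace("-", "") == toy.sequence()

    def test_blocks_are_swapped(self, toy_pipeline):
        toy, truth, result = toy_pipeline
        aln = result.swap_alignment
        rep = truth.repeat_def
        for (t, s), lab in zip(aln.columns, aln.block_labels):
            if lab == "RU1->RU2" and t is not None and s is not None:
                assert rep.ru1.contains(*t[:2]) and rep.ru2.contains(*s[:2])
            if lab == "RU2->RU1" and t is not None and s is not None:
                assert rep.ru2.contains(*t[:2]) and rep.ru1.contains(*s[:2])
            if lab == "peripheral" and t is not None:
                assert s == t  # peripheral aligns to itself

    def test_swap_involution_restores_original_mapping(self, toy_default):
        toy, truth = toy_default
        ru1, ru2 = ru_structures(toy, truth)
        pa, _, _ = align_repeats(ru1, ru2)
        rep = truth.repeat_def
        aln = build_swap_alignment(toy, rep, pa)
        swapped_rep = RepeatDefinition(
            ru1=rep.ru2, ru2=rep.ru1, peripheral=rep.peripheral
        )
        aln2 = build_swap_alignment(toy, swapped_rep, pa.transposed())
        m1 = dict(aln.pairs())
        m2 = dict(aln2.pairs())
        for t, s in m1.items():
            assert m2.get(s) == t  # swapping the swap is the identity

    def test_missing_repeats_rejected(self, toy_default):
        toy, _ = toy_default
        rep = RepeatDefinition(
            ru1=ResidueRangeSet.from_string("Q:1-20"),
            ru2=ResidueRangeSet.from_string("Q:30-50"),
        )
        pa = PairwiseAlignment("", "", [], [], [])
        with pytest.raises(ValueError, match="absent"):
            build_swap_alignment(toy, rep, pa)


class TestAssembleSwappedTemplate:
    def test_block_order_and_atom_conservation(self, toy_clean):
        toy, truth = toy_clean
        rep = truth.repeat_def
        tpl = assemble_swapped_template(toy, rep)
        # first residue of the template is the first residue of RU2
        first = tpl.structure.residues[0]
        assert rep.ru2.contains(first.chain_id, first.res_seq)
        assert first.res_seq == min(
            r.res_seq for r in toy.residues if rep.ru2.contains("A", r.res_seq)
        )
        n_repeat_atoms = sum(
            len(r.atoms) for r in toy.residues
            if rep.category(r.chain_id, r.res_seq) in ("RU1", "RU2")
        )
        assert tpl.n_atoms == n_repeat_atoms
        # renumbering is consecutive from 1
        assert sorted(tpl.new_numbering.values()) == list(
            range(1, len(tpl.structure) + 1)
        )

    def test_peripheral_requires_initial_model(self, toy_default):
        toy, truth = toy_default
        with pytest.raises(ValueError, match="initial model"):
            assemble_swapped_template(toy, truth.repeat_def)

    def test_peripheral_reoriented_onto_swapped_position(self):
        spec = ToySpec(noise_A=0.0, seed=0)
        toy, truth = make_toy_transporter(spec)
        from swapsmith.builder import run_repeat_swap

        result = run_repeat_swap(toy, truth.repeat_def)
        peri = truth.repeat_def.peripheral
        tpl_peri = np.vstack([
            r.ca.coords for r in result.template.structure.residues
            if peri.contains(r.chain_id, r.res_seq)
        ])
        base_peri = np.vstack([
            r.ca.coords for r in truth._noiseless.residues
            if peri.contains(r.chain_id, r.res_seq)
        ])
        target = truth.symmetry_op.apply(base_peri)
        rmsd = float(np.sqrt(((tpl_peri - target) ** 2).sum(axis=1).mean()))
        assert rmsd < 1.0

    def test_symmetric_toy_template_matches_original_after_symmetry(self, toy_symmetric):
        toy, truth = toy_symmetric
        tpl = assemble_swapped_template(toy, truth.repeat_def)
        orig_ca = {r.key: r.ca.coords for r in toy.residues}
        truthmap = dict(truth.correspondence)
        truthmap.update({b: a for a, b in truth.correspondence})
        moved = []
        expected = []
        for r in tpl.structure.residues:
            moved.append(truth.symmetry_op.apply(r.ca.coords))
            expected.append(orig_ca[truthmap[r.key]])
        rmsd = float(np.sqrt(((np.array(moved) - np.array(expected)) ** 2).sum(1).mean()))
        assert rmsd < 0.1


class TestRefineAlignment:
    def _toy_alignment(self):
        """A hand-built block with one helix flanked by loops."""
        # template residues 1..12: loops at 1-3 and 10-12, helix at 4-9
        keys = [("A", i, "") for i in range(1, 13)]
        t_keys = [("A", i + 100, "") for i in range(1, 12)]
        ss = "---HHHHHH---"
        # target has a gap against template residue 6 (mid-helix)
        cols = []
        ti = 0
        for i, s_key in enumerate(keys):
            if i == 5:  # template residue 6 unpaired -> gap in target row
                cols.append((None, s_key))
                continue
            cols.append((t_keys[ti], s_key))
            ti += 1
        letters = {k: "A" for k in keys}
        letters.update({k: "A" for k in t_keys})
        aln = SwapAlignment(cols, ["RU1->RU2"] * len(cols), letters)
        return aln, ss

    def test_gapless_alignment_unchanged(self, toy_symmetric):
        toy, truth = toy_symmetric
        ru1, ru2 = ru_structures(toy, truth)
        pa, _, _ = align_repeats(ru1, ru2)
        aln = build_swap_alignment(toy, truth.repeat_def, pa)
        ss = "H" * len(aln.template_order())
        refined = refine_alignment(aln, ss)
        assert refined.columns == aln.columns

    def test_mid_helix_gap_moves_to_nearer_loop(self):
        aln, ss = self._toy_alignment()
        refined = refine_alignment(aln, ss)
        t_row = refined.target_gapped
        gap_col = t_row.index("-")
        # helix occupies columns 3..8; the gap must leave it
        assert not 3 <= gap_col <= 8
        # mid-helix gap at column 5 is 3 columns from the N-loop and 4 from
        # the C-loop: the N-terminal side wins
        assert gap_col < 3

    def test_pair_count_conserved(self, toy_pipeline):
        toy, truth, result = toy_pipeline
        aln = result.swap_alignment  # already refined by the pipeline
        ss = "H" * len(aln.template_order())
        refined = refine_alignment(aln, ss)
        assert len(refined.pairs()) == len(aln.pairs())

    def test_ss_length_checked(self):
        aln, _ = self._toy_alignment()
        with pytest.raises(ValueError, match="length"):
            refine_alignment(aln, "HH")

    def test_conservation_diagnostics_are_advisory(self):
        aln, ss = self._toy_alignment()
        cons = {k: 0.1 for k in aln.template_order()}
        cons[("A", 6, "")] = 9.9  # highly conserved but unaligned
        refined = refine_alignment(aln, ss, conservation=cons)
        assert any("conservation" in d for d in refined.diagnostics)
        assert len(refined.pairs()) == len(aln.pairs())


class TestSecondaryStructure:
    def test_toy_helices_marked_h_linkers_not(self, toy_clean):
        toy, truth = toy_clean
        ss = assign_ss_ca(toy)
        res = toy.ca_residues()
        helix_frac = []
        linker_frac = []
        for r, c in zip(res, ss):
            cat = truth.repeat_def.category(r.chain_id, r.res_seq)
            in_transport = truth.domain_def.transport.contains(r.chain_id, r.res_seq)
            in_scaffold = truth.domain_def.scaffold.contains(r.chain_id, r.res_seq)
            if in_transport or in_scaffold:
                helix_frac.append(c == "H")
            elif cat == "linker":
                linker_frac.append(c == "H")
        assert np.mean(helix_frac) > 0.7  # helix interiors detected
        assert np.mean(linker_frac) < 0.3  # straight linkers are not helix

    def test_parse_dssp_maps_codes(self, tmp_path):
        text = (
            "== some dssp header ==\n"
            "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC\n"
            "    1    4 A M  H  >  S+\n"
            "    2    5 A K  G  <  S+\n"
            "    3    6 A V  E     -\n"
            "    4    7 A L        -\n"
            "    5        !*            \n"
            "    6    9 B G  I   > S+\n"
        )
        p = tmp_path / "toy.dssp"
        p.write_text(text)
        ss = parse_dssp(p)
        assert ss[("A", 4, "")] == "H"
        assert ss[("A", 5, "")] == "H"  # 3-10 helix collapses to H
        assert ss[("A", 6, "")] == "E"
        assert ss[("A", 7, "")] == "-"
        assert ss[("B", 9, "")] == "H"  # pi helix collapses to H
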
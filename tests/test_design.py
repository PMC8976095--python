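"""Switch assembly, constraint filtering, scoring, ranking, trigger cutting."""

import warnings

import pytest

from toeholdkit import design, rnafold
from toeholdkit.design import (
    DesignError,
    ScoreWeights,
    SwitchArchitecture,
    TriggerWindow,
    build_switch,
    build_trigger,
    check_constraints,
    enumerate_candidates,
    rank_and_select,
    score_candidate,
)
from toeholdkit.seqcore import reverse_complement
from toeholdkit.synthgen import GeneFamilySpec, synth_gene_family

from conftest import make_gene, random_rna

ARCH = SwitchArchitecture()


def window_on(gene, start, arch=ARCH):
    return TriggerWindow(gene, start, gene.sequence[start : start + arch.sensing_len])


class TestArchitecture:
    def test_default_geometry(self):
        assert ARCH.stem_arm_len == 23
        assert ARCH.stem_bottom_unpaired == 3
        assert ARCH.rbs_motif in ARCH.loop_seq
        assert len(ARCH.linker_seq) % 3 == 0

    def test_loop_without_rbs_rejected(self):
        with pytest.raises(DesignError, match="RBS"):
            SwitchArchitecture(loop_seq="AAAAAAAAAAA")

    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "arch.yaml"
        p.write_text("sensing_len: 35\ntoehold_len: 10\n")
        arch = SwitchArchitecture.from_yaml(p)
        assert arch.toehold_len == 10 and arch.stem_arm_len == 25


class TestBuildSwitch:
    def test_poly_a_window_gives_poly_u_sensing_region(self):
        gene = make_gene("A" * 35)
        sw = build_switch(window_on(gene, 0), ARCH)
        assert sw.sensing_region == "U" * 35

    def test_assembled_length_is_architectural_sum(self, rng):
        gene = make_gene(random_rna(rng, 80))
        sw = build_switch(window_on(gene, 10), ARCH)
        expected = (
            ARCH.sensing_len
            + len(ARCH.loop_seq)
            + ARCH.pre_start_stem_len
            + 3
            + ARCH.post_start_stem_len
            + len(ARCH.linker_seq)
        )
        assert len(sw.full_sequence) == expected
        assert len(sw.designed_structure) == expected

    def test_designed_stem_pairs_are_watson_crick(self, rng):
        gene = make_gene(random_rna(rng, 60))
        sw = build_switch(window_on(gene, 5), ARCH)
        pairs = rnafold.validate_dotbracket(sw.designed_structure, sw.full_sequence)
        assert len(pairs) == ARCH.pre_start_stem_len + ARCH.post_start_stem_len
        for i, j in pairs:
            assert sw.full_sequence[i] + sw.full_sequence[j] in {"AU", "UA", "CG", "GC"}

    def test_sensing_region_is_reverse_complement_of_window(self, rng):
        gene = make_gene(random_rna(rng, 100))
        for start in (0, 30, 65):
            sw = build_switch(window_on(gene, start), ARCH)
            assert sw.sensing_region == reverse_complement(gene.sequence[start : start + 35])

    def test_start_codon_at_architecture_offset(self, rng):
        gene = make_gene(random_rna(rng, 50))
        sw = build_switch(window_on(gene, 0), ARCH)
        aug = ARCH.aug_offset
        assert sw.full_sequence[aug : aug + 3] == "AUG"


class TestConstraints:
    def test_in_frame_stop_detected(self):
        # sensing region position 15..25 reappears (reverse-complemented back to
        # the window sequence) right after the AUG; a window whose positions
        # 10..20 (gene orientation) encode a stop in that frame must fail.
        # Build one directly: force UAA two codons after AUG.
        gene = make_gene("A" * 60)
        sw = build_switch(window_on(gene, 0), ARCH)
        seq = list(sw.full_sequence)
        aug = ARCH.aug_offset
        seq[aug + 3 : aug + 6] = "UGA"
        sw.full_sequence = "".join(seq)
        passed, reasons = check_constraints(sw, ARCH)
        assert not passed
        assert any("in-frame stop" in r for r in reasons)

    def test_all_pass_candidate_has_no_reasons(self, rng):
        gene = make_gene("ACGU" * 15)
        sw = build_switch(window_on(gene, 0), ARCH)
        passed, reasons = check_constraints(sw, ARCH)
        assert passed and reasons == []

    def test_gc_bounds_are_soft_unless_strict(self):
        gene = make_gene("A" * 35)  # sensing region GC = 0
        sw = build_switch(window_on(gene, 0), ARCH)
        passed, reasons = check_constraints(sw, ARCH)
        assert passed and any("GC" in r for r in reasons)
        passed_strict, _ = check_constraints(sw, ARCH, strict=True)
        assert not passed_strict


class TestEnumerate:
    def test_gene_equal_to_window_yields_at_most_one(self):
        gene = make_gene("ACGU" * 8 + "ACG")  # 35 nt
        cands = enumerate_candidates(gene, ARCH, score=False)
        assert len(cands) <= 1

    def test_short_gene_warns_and_returns_empty(self):
        gene = make_gene("ACGUACGU")
        with pytest.warns(UserWarning, match="shorter than sensing_len"):
            assert enumerate_candidates(gene, ARCH) == []

    def test_candidates_match_independent_codon_scan(self, rng):
        """Windows whose stem complement creates an in-frame stop are absent."""
        gene = make_gene(random_rna(rng, 200))
        cands = enumerate_candidates(gene, ARCH, score=False)
        assert len(cands) <= 166
        emitted = {c.window.start for c in cands}
        stops = {"UAA", "UAG", "UGA"}
        for start in range(166):
            sw = build_switch(window_on(gene, start), ARCH)
            orf = sw.full_sequence[ARCH.aug_offset :]
            has_stop = any(
                orf[off : off + 3] in stops for off in range(3, len(orf) - 2, 3)
            )
            assert (start in emitted) == (not has_stop)
        for c in cands:
            assert c.sensing_region == reverse_complement(c.window.sequence)


class TestScoring:
    def test_components_match_independent_recomputation(self, unit_model):
        gene = make_gene("GGAUACGUAGCAUCGAUCGGAUUACGCAUGGCACUAAGCAUCGAUGGCAU")
        cands = enumerate_candidates(gene, ARCH, step=7, model=unit_model)
        assert cands
        sw = cands[0]
        comp = sw.score_components
        # fidelity: overlap of MFE pairs with designed stem pairs
        designed = set(rnafold.validate_dotbracket(sw.designed_structure, sw.full_sequence))
        mfe = set(rnafold.fold_mfe(sw.full_sequence, unit_model).pairs)
        assert comp["hairpin_fidelity"] == pytest.approx(len(designed & mfe) / len(designed))
        # accessibility: unpaired fraction of the window inside the gene fold
        ctx = rnafold.fold_mfe(gene.sequence, unit_model)
        paired = {i for p in ctx.pairs for i in p}
        win = range(sw.window.start, sw.window.start + 35)
        assert comp["toehold_accessibility"] == pytest.approx(
            sum(1 for i in win if i not in paired) / 35
        )
        # activation: scaled hybridization gain
        dup = rnafold.duplex_delta_g(sw.full_sequence, sw.window.sequence, unit_model)
        assert comp["delta_delta_g"] == pytest.approx(dup.delta_delta_g)
        w = ScoreWeights()
        assert sw.score == pytest.approx(
            w.hairpin_fidelity * comp["hairpin_fidelity"]
            + w.toehold_accessibility * comp["toehold_accessibility"]
            + w.activation * comp["activation"]
        )

    def test_refuses_constraint_failures(self):
        gene = make_gene("A" * 60)
        sw = build_switch(window_on(gene, 0), ARCH)
        seq = list(sw.full_sequence)
        aug = ARCH.aug_offset
        seq[aug + 3 : aug + 6] = "UAA"
        sw.full_sequence = "".join(seq)
        with pytest.raises(DesignError, match="constraint-failing"):
            score_candidate(sw, gene.record)


class TestRanking:
    def _cands(self, scores_starts):
        gene = make_gene("ACGU" * 40)
        out = []
        for score, start in scores_starts:
            sw = build_switch(window_on(gene, start), ARCH)
            sw.score = score
            out.append(sw)
        return out

    def test_descending_with_start_tiebreak(self):
        cands = self._cands([(0.5, 10), (0.9, 40), (0.5, 2)])
        sel = rank_and_select(cands, 3)
        assert [(s.score, s.window.start) for s in sel] == [(0.9, 40), (0.5, 2), (0.5, 10)]
        assert [s.rank for s in sel] == [1, 2, 3]

    def test_fewer_candidates_than_k(self):
        sel = rank_and_select(self._cands([(0.1, 0), (0.2, 5)]), 3)
        assert len(sel) == 2

    def test_rerun_is_permutation_stable(self):
        cands = self._cands([(0.3, 1), (0.3, 9), (0.7, 4)])
        first = [s.id for s in rank_and_select(list(reversed(cands)), 3)]
        second = [s.id for s in rank_and_select(cands, 3)]
        assert first == second

    def test_invalid_k(self):
        with pytest.raises(DesignError):
            rank_and_select([], 0)

    def test_three_markers_top3_yield_nine_switches(self, small_family, unit_model):
        selected = []
        for marker in small_family.spec.markers:
            gene = small_family.gene("sp00", marker)
            cands = enumerate_candidates(gene, ARCH, step=10, model=unit_model)
            selected += rank_and_select(cands, 3)
        assert len(selected) == 9


class TestBuildTrigger:
    def test_gene_of_trigger_length_returned_whole(self, rng):
        gene = make_gene(random_rna(rng, 120))
        trig = build_trigger(gene, window_on(gene, 40))
        assert trig.sequence == gene.sequence and trig.binding_site_offset == 40

    def test_window_at_origin_clips_left(self, rng):
        gene = make_gene(random_rna(rng, 300))
        trig = build_trigger(gene, window_on(gene, 0))
        assert trig.sequence == gene.sequence[0:120] and trig.binding_site_offset == 0

    def test_centered_placement(self, rng):
        gene = make_gene(random_rna(rng, 300))
        trig = build_trigger(gene, window_on(gene, 100))
        assert trig.sequence == gene.sequence[57:177]
        assert trig.binding_site_offset == 43

    def test_short_gene_flags_truncation(self, rng):
        gene = make_gene(random_rna(rng, 80))
        with pytest.warns(UserWarning, match="returning whole gene"):
            trig = build_trigger(gene, window_on(gene, 10))
        assert trig.truncated and trig.sequence == gene.sequence

    def test_explicit_offset(self, rng):
        gene = make_gene(random_rna(rng, 300))
        trig = build_trigger(gene, window_on(gene, 100), offset=10)
        assert trig.binding_site_offset == 10
        assert trig.sequence == gene.sequence[90:210]

    def test_overlapping_windows_share_trigger_coverage(self, rng):
        """A trigger cut for one window fully contains nearby selected sites."""
        gene = make_gene(random_rna(rng, 300))
        w1, w2 = window_on(gene, 100), window_on(gene, 120)
        trig = build_trigger(gene, w1)
        start = 57  # trigger span [57, 177)
        assert start <= w2.start and w2.start + 35 <= start + 120
        assert w2.sequence in trig.sequence
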
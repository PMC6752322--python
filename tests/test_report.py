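"""Phasing, allele summaries, interruptions, classification, cohort tables."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from noamp import (
    InputError,
    MarkerCall,
    assign_alleles,
    classify_sample,
    cohort_summary,
    control_locus_call,
    decide_phase,
    detect_interruptions,
    phase_method_from_genotypes,
    summarize_allele,
    unphased_genotype,
)
from noamp.io import fixture_to_reports, load_cohort_fixture
from noamp.report import PHASE_BOTH, PHASE_CTC, PHASE_NONE, PHASE_SNP


def markers(pairs):
    return [MarkerCall(sec_tract_len=c, snp_allele=s) for c, s in pairs]


class TestDecidePhase:
    def test_snp_split_phases_by_snp(self):
        calls = markers([(13, "A")] * 10 + [(13, "T")] * 8)
        phase = decide_phase(calls)
        assert phase.method == PHASE_SNP
        assert {k[1] for k in phase.allele_keys} == {"A", "T"}

    def test_tract_split_phases_by_ctc(self):
        calls = markers([(10, "T")] * 9 + [(13, "T")] * 11)
        phase = decide_phase(calls)
        assert phase.method == PHASE_CTC
        assert {k[0] for k in phase.allele_keys} == {10, 13}

    def test_both_markers_informative_prefers_conjunction(self):
        calls = markers([(13, "A")] * 10 + [(14, "T")] * 9)
        phase = decide_phase(calls)
        assert phase.method == PHASE_BOTH
        assert set(phase.allele_keys) == {(13, "A"), (14, "T")}

    def test_homozygous_sample_cannot_phase(self):
        calls = markers([(12, "T")] * 20)
        assert decide_phase(calls).method == PHASE_NONE

    def test_minor_fraction_floor_resists_miscalls(self):
        # 5% stray SNP calls must not fake heterozygosity
        calls = markers([(13, "T")] * 38 + [(13, "A")] * 2)
        assert decide_phase(calls).method == PHASE_NONE

    def test_empty_call_set_rejected(self):
        with pytest.raises(InputError):
            decide_phase([])

    def test_genotype_rule_reproduces_published_phase_column(self):
        """The heterozygosity rule rederives every printed phase label."""
        label = {"None": PHASE_NONE, "SNP": PHASE_SNP, "CTC": PHASE_CTC,
                 "CTC length and SNP": PHASE_BOTH}
        for sample in load_cohort_fixture():
            derived = phase_method_from_genotypes(
                sample.snp_genotype,
                (sample.alleles[0].ctc, sample.alleles[1].ctc),
            )
            assert derived == label[sample.phase_method], sample.sample_id


class TestAssignAlleles:
    def _run_calls(self, ctg18, haplotypes, sim):
        from noamp import (
            build_template_pool,
            estimate_max_repeat,
            match_templates,
            select_ontarget,
        )

        config, result = sim
        sel = select_ontarget(
            [(r.read_id, r.sequence) for r in result.reads], [ctg18]
        )
        anchored = sel.accepted["TCF4"]
        pool = build_template_pool(
            ctg18, estimate_max_repeat(anchored, ctg18), list(haplotypes)
        )
        calls = [
            c for c in (
                match_templates(r, pool, ctg18) for r in anchored
            )
            if not hasattr(c, "best_similarity")
        ]
        return result.truth.set_index("read_id"), calls

    def test_noise_free_assignment_matches_truth(self, ctg18, haplotypes, sim_noisefree):
        truth, calls = self._run_calls(ctg18, haplotypes, sim_noisefree)
        phase = decide_phase(calls)
        assignment = assign_alleles(calls, phase)
        assert not assignment.unassigned
        for group_ix, group in enumerate(assignment.groups):
            for call in group:
                assert int(truth.loc[call.read_id].allele) == group_ix

    def test_undetermined_marker_goes_unassigned(self):
        from noamp import ReadCall

        def call(read_id, snp):
            return ReadCall(
                read_id=read_id, repeat_len=20, similarity=1.0, edits=0,
                template_id="t", template_haplotype=None,
                markers=MarkerCall(sec_tract_len=None, snp_allele=snp),
                passed_stringency={},
            )

        calls = [call(f"a{i}", "A") for i in range(5)]
        calls += [call(f"t{i}", "T") for i in range(5)]
        calls.append(call("und", None))
        phase = decide_phase(calls)
        assert phase.method == PHASE_SNP
        assignment = assign_alleles(calls, phase)
        assert [c.read_id for c in assignment.unassigned] == ["und"]

    def test_unphased_sample_is_a_contract_violation(self):
        from noamp.report import PhaseDecision

        with pytest.raises(InputError):
            assign_alleles([], PhaseDecision(PHASE_NONE))


class TestSummarizeAllele:
    def test_worked_example(self):
        s = summarize_allele([71, 71, 72, 90])
        assert (s.mode_len, s.mean_len, s.size_range, s.max_len) == (71, 76, 19, 90)

    def test_singleton(self):
        s = summarize_allele([50])
        assert s.mode_len == s.mean_len == 50
        assert s.size_range == 0
        assert s.expanded is True  # >=50 is the inclusive disease threshold

    def test_mode_ties_break_to_smallest(self):
        assert summarize_allele([10, 10, 30, 30, 20]).mode_len == 10

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            summarize_allele([])

    @given(st.lists(st.integers(1, 2000), min_size=1, max_size=200))
    @settings(max_examples=80, deadline=None)
    def test_order_invariants(self, lengths):
        s = summarize_allele(lengths)
        assert s.min_len <= s.mode_len <= s.max_len
        assert s.min_len <= s.mean_len <= s.max_len
        assert s.size_range == s.max_len - s.min_len >= 0

    def test_stable_vs_mosaic_alleles(self, ctg18, haplotypes, sim_noisy):
        """Spread-0 alleles report zero range; dispersed expansions do not."""
        _, result = sim_noisy
        on = result.truth[~result.truth.offtarget]
        stable = summarize_allele(list(on[on.allele == 0].true_len))
        mosaic = summarize_allele(list(on[on.allele == 1].true_len))
        assert stable.size_range == 0
        assert mosaic.size_range > 0


class TestUnphasedGenotype:
    def test_bimodal_histogram_recovers_both_modes(self, ctg18, haplotypes):
        from noamp import AlleleModel, SimConfig, simulate_sample

        config = SimConfig(
            locus=ctg18,
            alleles=(
                AlleleModel(76, 1.5, haplotypes[0]),
                AlleleModel(141, 2.5, haplotypes[1]),
            ),
            n_reads=250,
            error_sub_rate=0.0, error_ins_rate=0.0, error_del_rate=0.0,
            offtarget_fraction=0.0, seed=17,
        )
        lengths = list(simulate_sample(config).truth.true_len)
        modes = unphased_genotype(lengths)
        assert len(modes) == 2
        assert abs(modes[0] - 76) <= 1
        assert abs(modes[1] - 141) <= 1

    def test_unimodal_returns_single_mode(self):
        assert unphased_genotype([30] * 40 + [31] * 5) == [30]

    def test_close_peaks_merge(self):
        lengths = [20] * 30 + [23] * 28  # separated by less than min_separation
        assert len(unphased_genotype(lengths, min_separation=5)) == 1

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            unphased_genotype([])


class TestDetectInterruptions:
    def _group(self, ctg18, hap, tract, n_reads, n_interrupted):
        """Build reads with a GTG at triplet 9 of a 17-unit repeat tract."""
        from noamp import anchor_read, build_template_pool, match_templates

        pure = "CTG" * tract
        interrupted = "CTG" * 8 + "GTG" + "CTG" * (tract - 9)
        pool = build_template_pool(ctg18, 30, [hap])
        calls, anchored = [], {}
        for i in range(n_reads):
            body = interrupted if i < n_interrupted else pure
            seq = ctg18.flank1 + body + ctg18.flank2(hap)
            read = anchor_read(f"r{i}", seq, ctg18)
            anchored[read.read_id] = read
            call = match_templates(read, pool, ctg18, min_similarity=0.9)
            calls.append(call)
        return calls, anchored

    def test_pure_tract_reports_nothing(self, ctg18, haplotypes):
        calls, anchored = self._group(ctg18, haplotypes[0], 17, 10, 0)
        report = detect_interruptions(calls, anchored, ctg18)
        assert report.assessable
        assert report.interruptions == []

    def test_consensus_interruption_called_with_position_and_motif(
        self, ctg18, haplotypes
    ):
        calls, anchored = self._group(ctg18, haplotypes[0], 17, 10, 10)
        report = detect_interruptions(calls, anchored, ctg18)
        assert report.assessable
        assert report.tract_len == 17
        [hit] = report.interruptions
        assert hit.motif == "GTG"
        assert hit.triplet_index == 9
        assert hit.support >= 0.8

    def test_half_support_not_called(self, ctg18, haplotypes):
        calls, anchored = self._group(ctg18, haplotypes[0], 17, 10, 5)
        report = detect_interruptions(calls, anchored, ctg18)
        assert report.assessable
        assert report.interruptions == []

    def test_too_few_reads_not_assessable(self, ctg18, haplotypes):
        calls, anchored = self._group(ctg18, haplotypes[0], 17, 3, 3)
        report = detect_interruptions(calls, anchored, ctg18, min_support=5)
        assert not report.assessable


class TestClassification:
    @pytest.mark.parametrize(
        "modes,category",
        [((12, 15), "A"), ((50, 12), "B"), ((70, 175), "C"), ((49, 49), "A"),
         ((50, 50), "C")],
    )
    def test_threshold_semantics(self, modes, category):
        assert classify_sample(modes, 50) == category

    @pytest.mark.parametrize(
        "modes,flags",
        [((30, 28), (False, False)), ((56, 20), (True, False)),
         ((55, 55), (False, False))],
    )
    def test_control_threshold_is_strict(self, modes, flags):
        assert control_locus_call(modes, 55) == flags

    def test_cohort_control_locus_has_no_expansions(self):
        reports = fixture_to_reports(load_cohort_fixture())
        assert not any(
            any(r.control_calls["FMR1"]["expanded"]) for r in reports
        )


class TestCohortSummary:
    def test_category_counts_partition_cohort(self):
        reports = fixture_to_reports(load_cohort_fixture())
        summary = cohort_summary(reports)
        assert sum(summary.category_counts.values()) == summary.n_samples == 11

    def test_phased_alleles_twice_phased_samples(self):
        summary = cohort_summary(fixture_to_reports(load_cohort_fixture()))
        assert summary.phased_alleles == 2 * summary.phased_samples

    def test_single_sample_cohort_means_are_identity(self):
        reports = fixture_to_reports(load_cohort_fixture())[:1]
        summary = cohort_summary(reports)
        assert summary.mean_on_target == {"TCF4": 761, "FMR1": 204}

    def test_empty_cohort_rejected(self):
        with pytest.raises(InputError):
            cohort_summary([])
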
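"""Marker calling, template matching and the stringency filter."""

import numpy as np
import pytest
from Bio import Align
from hypothesis import given, settings
from hypothesis import strategies as st

from noamp import (
    MarkerCall,
    MarkerHaplotype,
    MatchRejection,
    ReadCall,
    anchor_read,
    apply_stringency,
    build_template_pool,
    call_markers,
    match_templates,
)
from noamp.errors import InputError


def edit_distance_oracle():
    """Unit-cost global edit distance via an aligner independent of edlib."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 0
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return lambda a, b: int(-aligner.score(a, b))


def perfect_read(locus, n, hap):
    return locus.flank1 + locus.repeat_unit * n + locus.flank2(hap)


class TestCallMarkers:
    @pytest.mark.parametrize("tract,snp", [(13, "T"), (8, "A")])
    def test_noise_free_markers_read_exactly(self, ctg18, tract, snp):
        hap = MarkerHaplotype(sec_tract_len=tract, ctt_index=min(6, tract), snp_allele=snp)
        read = anchor_read("r", perfect_read(ctg18, 40, hap), ctg18)
        call = call_markers(read, ctg18)
        assert call == MarkerCall(sec_tract_len=tract, snp_allele=snp)

    def test_deletion_in_tract_undetermines_length_not_snp(self, ctg18, haplotypes):
        hap = haplotypes[0]
        seq = perfect_read(ctg18, 40, hap)
        # delete one base inside the CTC tract (tract starts right after the repeat)
        tract_start = len(ctg18.flank1) + 3 * 40
        seq = seq[: tract_start + 4] + seq[tract_start + 5 :]
        read = anchor_read("r", seq, ctg18)
        call = call_markers(read, ctg18)
        assert call.sec_tract_len is None
        assert call.snp_allele == hap.snp_allele

    def test_off_model_snp_base_is_undetermined(self, ctg18, haplotypes):
        seq = perfect_read(ctg18, 30, haplotypes[0])
        layout = ctg18.flank2_layout
        snp_pos = (
            len(ctg18.flank1) + 90 + 3 * haplotypes[0].sec_tract_len
            + len(layout.spacer_to_snp)
        )
        assert seq[snp_pos] == "A"
        seq = seq[:snp_pos] + "G" + seq[snp_pos + 1 :]
        call = call_markers(anchor_read("r", seq, ctg18), ctg18)
        assert call.snp_allele is None
        assert call.sec_tract_len == haplotypes[0].sec_tract_len


class TestMatchTemplates:
    def test_exact_read_gets_perfect_similarity(self, ctg18, haplotypes):
        pool = build_template_pool(ctg18, 40, list(haplotypes))
        read = anchor_read("r", perfect_read(ctg18, 23, haplotypes[0]), ctg18)
        call = match_templates(read, pool, ctg18)
        assert isinstance(call, ReadCall)
        assert call.repeat_len == 23
        assert call.similarity == 1.0
        assert call.template_haplotype == haplotypes[0]

    def test_read_below_threshold_rejected(self, ctg18, haplotypes):
        seq = list(perfect_read(ctg18, 23, haplotypes[0]))
        rng = np.random.default_rng(9)
        # ~3% corruption pushes best similarity well below 0.99
        for pos in rng.choice(len(seq), size=len(seq) // 30, replace=False):
            seq[pos] = "ACGT"[rng.integers(4)]
        read = anchor_read("r", "".join(seq), ctg18)
        res = match_templates(read, pool=build_template_pool(ctg18, 40, list(haplotypes)),
                              locus=ctg18, min_similarity=0.99)
        assert isinstance(res, MatchRejection)
        assert res.best_similarity < 0.99

    def test_equidistant_read_breaks_tie_to_smaller_length(self, ctg18, haplotypes):
        """A read the same edit count from lengths 70 and 71 is called 70."""
        hap = haplotypes[0]
        seq = ctg18.flank1 + "CTG" * 70 + "AG" + ctg18.flank2(hap)
        dist = edit_distance_oracle()
        d70 = dist(seq, perfect_read(ctg18, 70, hap))
        d71 = dist(seq, perfect_read(ctg18, 71, hap))
        assert d70 == d71 == 2  # confirmed tie
        read = anchor_read("r", seq, ctg18)
        pool = build_template_pool(ctg18, 80, [hap])
        call = match_templates(read, pool, ctg18, min_similarity=0.9)
        assert call.repeat_len == 70

    def test_matches_brute_force_search(self, ctg18, haplotypes):
        """Best-match equals exhaustive minimum edit distance over the pool."""
        dist = edit_distance_oracle()
        pool = build_template_pool(ctg18, 25, list(haplotypes))  # 50 templates
        rng = np.random.default_rng(13)
        for trial in range(12):
            true_len = int(rng.integers(1, 26))
            hap = haplotypes[rng.integers(2)]
            seq = list(perfect_read(ctg18, true_len, hap))
            for pos in rng.choice(len(seq), size=rng.integers(0, 6), replace=False):
                seq[pos] = "ACGT"[rng.integers(4)]
            seq = "".join(seq)
            read = anchor_read(f"t{trial}", seq, ctg18)
            call = match_templates(read, pool, ctg18, min_similarity=0.5, window=None)
            insert = read.oriented_sequence[
                read.flank1_span[0] : read.flank2_span[1]
            ]
            distances = [dist(insert, t.sequence) for t in pool]
            best = min(distances)
            assert call.edits == best
            # first pool entry achieving the optimum (the documented tie rule)
            assert pool[distances.index(best)].template_id == call.template_id

    def test_longer_alleles_accumulate_more_edits_at_equal_error_rate(
        self, ctg18, haplotypes, sim_noisy
    ):
        """Stringency interacts with length: longer reads expose more bases to
        error, so expanded-allele reads carry more edits and clear a fixed
        similarity threshold less often than short-allele reads."""
        from noamp import select_ontarget, estimate_max_repeat

        _, result = sim_noisy
        sel = select_ontarget([(r.read_id, r.sequence) for r in result.reads], [ctg18])
        anchored = sel.accepted["TCF4"]
        pool = build_template_pool(
            ctg18, estimate_max_repeat(anchored, ctg18), list(haplotypes)
        )
        truth = result.truth.set_index("read_id")
        edits = {0: [], 1: []}
        passed = {0: [], 1: []}
        for read in anchored:
            call = match_templates(read, pool, ctg18, min_similarity=0.5)
            allele = int(truth.loc[read.read_id].allele)
            edits[allele].append(call.edits)
            passed[allele].append(call.similarity >= 0.99)
        assert np.mean(edits[1]) > np.mean(edits[0])
        assert np.mean(passed[1]) < np.mean(passed[0])


class TestApplyStringency:
    def _calls(self, sims):
        return [
            ReadCall(
                read_id=f"r{i}", repeat_len=20, similarity=s, edits=0,
                template_id="t", template_haplotype=None,
                markers=MarkerCall(None, None),
                passed_stringency={},
            )
            for i, s in enumerate(sims)
        ]

    def test_threshold_counting(self):
        calls = self._calls([1.0, 0.995, 0.991])
        assert len(apply_stringency(calls, 0.999)) == 1
        assert len(apply_stringency(calls, 0.99)) == 3

    def test_invalid_threshold_rejected(self):
        with pytest.raises(InputError):
            apply_stringency([], 0.0)

    @given(
        sims=st.lists(st.floats(0.5, 1.0), max_size=30),
        t1=st.floats(0.5, 1.0),
        t2=st.floats(0.5, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_threshold(self, sims, t1, t2):
        lo, hi = sorted((t1, t2))
        calls = self._calls(sims)
        kept_hi = {c.read_id for c in apply_stringency(calls, hi)}
        kept_lo = {c.read_id for c in apply_stringency(calls, lo)}
        assert kept_hi <= kept_lo
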
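import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dirtseq.coverage_engine import AlignmentRecord, AlignmentStore
from dirtseq.dirt_core import (
    DEGENERATE_P,
    DetectionConfig,
    bh_adjust,
    continuity_check,
    filter_expressed_pairs,
    intron_contrast_test,
    run_dirt,
    write_call_table,
)
from dirtseq.genome_model import assemble_pairs
from dirtseq.intervals import GenomicInterval
from dirtseq.coverage_engine import CoverageTrack

from conftest import brute_force_bh, mk_gene, mk_trna


def micro_locus(n_introns=2, gap=20, chrom="c"):
    """tRNA upstream of a gene with the requested intron count."""
    trna = mk_trna("tRNA-Gly-GCC-1-1", chrom, 100, 172)
    exons, pos = [], 172 + gap
    for _ in range(n_introns + 1):
        exons.append((pos, pos + 100))
        pos += 150
    gene = mk_gene("g1", chrom, exons)
    (pair,) = assemble_pairs([trna], [gene])
    return pair


def covering_reads(region, n, prefix, mapq=60):
    return [
        AlignmentRecord(f"{prefix}{i}", region, mapq=mapq) for i in range(n)
    ]


def replicate_store(pair, n_intergenic, n_trna=5, n_pcg=12, skip_base=None):
    """A replicate with reads on the tRNA, the gene and the gap.

    ``skip_base`` leaves one intergenic base uncovered (offset from the
    gap start).
    """
    records = []
    records += covering_reads(pair.trna.interval, n_trna, "t")
    records += covering_reads(pair.pcg.exons[0], n_pcg, "p")
    ig = pair.intergenic
    if skip_base is None:
        records += covering_reads(ig, n_intergenic, "i")
    else:
        cut = ig.start + skip_base
        left = GenomicInterval(ig.chrom, ig.start, cut)
        right = GenomicInterval(ig.chrom, cut + 1, ig.end)
        for part, tag in ((left, "il"), (right, "ir")):
            if part.length:
                records += covering_reads(part, n_intergenic, tag)
    return AlignmentStore.from_records(records)


class TestFilterExpressedPairs:
    def setup_method(self):
        self.pair = micro_locus()

    def test_trna_zero_dropped(self):
        assert filter_expressed_pairs(
            [self.pair], {"tRNA-Gly-GCC-1-1": 0}, {"g1": 100}
        ) == []

    def test_pcg_threshold_boundary(self):
        kept9 = filter_expressed_pairs([self.pair], {"tRNA-Gly-GCC-1-1": 1}, {"g1": 9})
        kept10 = filter_expressed_pairs([self.pair], {"tRNA-Gly-GCC-1-1": 1}, {"g1": 10})
        assert kept9 == []
        assert kept10 == [self.pair]

    def test_empty_input(self):
        assert filter_expressed_pairs([], {}, {}) == []

    def test_unknown_feature_errors(self):
        with pytest.raises(KeyError, match="g1"):
            filter_expressed_pairs([self.pair], {"tRNA-Gly-GCC-1-1": 1}, {})


class TestIntronContrastTest:
    def test_clear_positive_contrast(self):
        res = intron_contrast_test([10, 12, 11, 13], [1, 2, 1, 2])
        assert res.direction == 1
        assert res.p_value < 0.01
        # independent oracle: direct t statistic + t CDF evaluation
        d = np.array([10, 12, 11, 13], float) - np.array([1, 2, 1, 2], float)
        t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert res.p_value == pytest.approx(stats.t.sf(t, len(d) - 1), rel=1e-12)

    def test_identical_vectors(self):
        res = intron_contrast_test([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert res.p_value == 1.0
        assert res.direction == 0

    def test_negative_direction(self):
        res = intron_contrast_test([1, 1, 1], [5, 5, 6])
        assert res.direction == -1
        assert res.p_value > 0.5

    def test_constant_positive_differences_flagged(self):
        res = intron_contrast_test([5, 6, 7], [2, 3, 4])
        assert res.degenerate
        assert res.direction == 1
        assert res.p_value == DEGENERATE_P

    def test_constant_negative_differences(self):
        res = intron_contrast_test([2, 3, 4], [5, 6, 7])
        assert res.degenerate
        assert res.p_value == 1.0

    def test_too_few_replicates(self):
        with pytest.raises(ValueError):
            intron_contrast_test([1.0], [0.0])

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            intron_contrast_test([1, 2], [1, 2, 3])


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value_identity(self):
        assert bh_adjust([0.2]).tolist() == [0.2]

    def test_empty(self):
        assert bh_adjust([]).size == 0

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200))
    def test_matches_brute_force(self, ps):
        p = np.array(ps)
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), rtol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
    def test_elementwise_bounds(self, ps):
        p = np.array(ps)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        assert (q <= 1.0).all()

    def test_large_random_vector_against_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.random(1000)
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), rtol=1e-12)


class TestContinuityCheck:
    def test_all_covered(self):
        track = CoverageTrack(GenomicInterval("c", 0, 4), np.array([1, 1, 2, 3]))
        assert continuity_check(track)

    def test_single_gap_fails(self):
        track = CoverageTrack(GenomicInterval("c", 0, 3), np.array([1, 0, 5]))
        assert not continuity_check(track)

    def test_empty_vacuous(self):
        track = CoverageTrack(GenomicInterval("c", 0, 0), np.zeros(0, dtype=int))
        assert continuity_check(track)


class TestDetectionConfig:
    def test_defaults(self):
        cfg = DetectionConfig()
        assert (cfg.trna_min_reads, cfg.pcg_min_reads) == (1, 10)
        assert cfg.fdr_alpha == 0.05
        assert cfg.mapq_min == 10
        assert cfg.max_distance is None

    def test_invalid(self):
        with pytest.raises(ValueError):
            DetectionConfig(fdr_alpha=0.0)
        with pytest.raises(ValueError):
            DetectionConfig(trna_min_reads=-1)


class TestRunDirt:
    def _stores(self, pair, per_rep_intergenic, **kw):
        return [
            replicate_store(pair, n, **kw) for n in per_rep_intergenic
        ]

    def test_clean_pair_is_dicistronic(self):
        pair = micro_locus(n_introns=2)
        stores = self._stores(pair, [10, 12, 11, 13])
        calls = run_dirt([pair], {"g": stores})["g"]
        (call,) = calls
        assert call.verdict == "dicistronic"
        assert len(call.p_values) == 2
        assert all(q >= p for q, p in zip(call.q_values, call.p_values))

    def test_single_intron_gene_is_tested(self):
        pair = micro_locus(n_introns=1)
        stores = self._stores(pair, [10, 12, 11, 13])
        (call,) = run_dirt([pair], {"g": stores})["g"]
        assert len(call.p_values) == 1
        assert call.verdict == "dicistronic"

    def test_intronless_gene_untestable(self):
        pair = micro_locus(n_introns=0)
        stores = self._stores(pair, [10, 12, 11, 13])
        (call,) = run_dirt([pair], {"g": stores})["g"]
        assert call.verdict == "untestable"
        assert "intronless" in call.reason

    def test_one_uncovered_base_rejects_continuity(self):
        pair = micro_locus(n_introns=2, gap=20)
        stores = self._stores(pair, [10, 12, 11, 13], skip_base=7)
        (call,) = run_dirt([pair], {"g": stores})["g"]
        assert call.verdict == "rejected_continuity"

    def test_unexpressed_trna_rejected(self):
        pair = micro_locus()
        stores = self._stores(pair, [10, 12, 11, 13], n_trna=0)
        (call,) = run_dirt([pair], {"g": stores})["g"]
        assert call.verdict == "rejected_expression"

    def test_low_pcg_count_rejected(self):
        pair = micro_locus()
        # 2 reads/replicate * 4 replicates = 8 < 10
        stores = self._stores(pair, [10, 12, 11, 13], n_pcg=2)
        (call,) = run_dirt([pair], {"g": stores})["g"]
        assert call.verdict == "rejected_expression"

    def test_no_intergenic_signal_rejected_by_test(self):
        pair = micro_locus()
        stores = self._stores(pair, [0, 0, 0, 0])
        (call,) = run_dirt([pair], {"g": stores})["g"]
        assert call.verdict in ("rejected_test", "rejected_direction")

    def test_fewer_than_two_replicates_untestable(self, caplog):
        pair = micro_locus()
        stores = self._stores(pair, [10])
        (call,) = run_dirt([pair], {"g": stores})["g"]
        assert call.verdict == "untestable"

    def test_adjacent_pair_untestable(self):
        pair = micro_locus(gap=0)
        assert pair.intergenic.length == 0
        stores = self._stores(pair, [0, 0, 0, 0])
        (call,) = run_dirt([pair], {"g": stores})["g"]
        assert call.verdict == "untestable"
        assert "adjacent" in call.reason

    def test_alpha_extremes(self):
        pair = micro_locus()
        stores = self._stores(pair, [10, 12, 11, 13])
        high = run_dirt([pair], {"g": stores}, DetectionConfig(fdr_alpha=0.999))["g"]
        low = run_dirt([pair], {"g": stores}, DetectionConfig(fdr_alpha=1e-12))["g"]
        assert high[0].verdict == "dicistronic"
        assert low[0].verdict == "rejected_test"

    def test_verdict_monotone_in_intergenic_coverage(self):
        """Adding constant positive intergenic coverage never unmakes a call."""
        pair = micro_locus()
        base = [10, 12, 11, 13]
        (before,) = run_dirt([pair], {"g": self._stores(pair, base)})["g"]
        assert before.verdict == "dicistronic"
        boosted = [n + 5 for n in base]
        (after,) = run_dirt([pair], {"g": self._stores(pair, boosted)})["g"]
        assert after.verdict == "dicistronic"

    def test_deterministic_call_table(self):
        import io

        pair = micro_locus()
        stores = self._stores(pair, [10, 12, 11, 13])
        outs = []
        for _ in range(2):
            calls = run_dirt([pair], {"g": stores})
            buf = io.StringIO()
            write_call_table(calls, buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_groups_independent(self):
        pair = micro_locus()
        good = self._stores(pair, [10, 12, 11, 13])
        bad = self._stores(pair, [0, 0, 0, 0])
        calls = run_dirt([pair], {"good": good, "bad": bad})
        assert calls["good"][0].verdict == "dicistronic"
        assert calls["bad"][0].verdict != "dicistronic"

    def test_max_distance_drops_pair(self):
        pair = micro_locus(gap=500)
        stores = self._stores(pair, [10, 12, 11, 13])
        calls = run_dirt([pair], {"g": stores}, DetectionConfig(max_distance=100))
        assert calls["g"] == []
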
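"""Interval algebra, the Poisson window caller, promoters, differential."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sng4kit.core_io import GenomicInterval, Peak, TSSRecord, CopyNumberRecord
from sng4kit.peaks_diff import (
    PeakCallConfig,
    annotate_copy_number,
    call_peaks,
    define_promoters,
    differential_promoter_enrichment,
    fisher_exact_two_sided,
    merge_intervals,
    overlap_fraction,
)


def peak(chrom, start, end, name=None):
    return Peak(GenomicInterval(chrom, start, end), name)


def uniform_frags(rng, n, length, chrom="chr1"):
    lengths = np.clip(
        np.round(rng.lognormal(5.2, 0.45, n)), 30, 1000
    ).astype(int)
    mids = rng.integers(0, length, n)
    s = np.clip(mids - lengths // 2, 0, length - lengths)
    return pd.DataFrame(
        {"chrom": chrom, "start": s, "end": s + lengths,
         "barcode": "bulk", "read_support": 1}
    )


class TestMergeIntervals:
    def test_book_ended_merge(self):
        merged = merge_intervals([peak("chr1", 0, 10), peak("chr1", 10, 20)])
        assert [(p.start, p.end) for p in merged] == [(0, 20)]

    def test_disjoint_unchanged(self):
        merged = merge_intervals([peak("chr1", 0, 10), peak("chr1", 20, 30)])
        assert [(p.start, p.end) for p in merged] == [(0, 10), (20, 30)]

    def test_multiple_sets_union(self):
        merged = merge_intervals(
            [peak("chr1", 0, 15)], [peak("chr1", 10, 30), peak("chr2", 0, 5)]
        )
        assert [(p.chrom, p.start, p.end) for p in merged] == [
            ("chr1", 0, 30), ("chr2", 0, 5)
        ]

    def test_idempotent_and_bp_conservation(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(1, 20)
            starts = rng.integers(0, 5000, n)
            peaks = [
                peak("chr1", int(s), int(s) + int(w))
                for s, w in zip(starts, rng.integers(1, 200, n))
            ]
            merged = merge_intervals(peaks)
            again = merge_intervals(merged)
            assert [(p.start, p.end) for p in merged] == \
                [(p.start, p.end) for p in again]
            total_in = sum(p.end - p.start for p in peaks)
            total_out = sum(p.end - p.start for p in merged)
            assert total_out <= total_in
            disjoint = all(
                a.end < b.start for a, b in zip(merged, merged[1:])
            )
            if total_out == total_in:
                # equality iff inputs were already disjoint (non-book-ended)
                srt = sorted((p.start, p.end) for p in peaks)
                assert all(a[1] < b[0] for a, b in zip(srt, srt[1:]))


class TestOverlapFraction:
    def test_identical_sets(self):
        a = [peak("chr1", 0, 10), peak("chr1", 50, 60)]
        assert overlap_fraction(a, a) == 1.0

    def test_disjoint_sets(self):
        assert overlap_fraction(
            [peak("chr1", 0, 10)], [peak("chr2", 0, 10)]
        ) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        q = [peak("chr1", int(s), int(s) + 30)
             for s in np.sort(rng.choice(5000, 10, replace=False)) * 50]
        r = [peak("chr1", int(s), int(s) + 40)
             for s in np.sort(rng.choice(5000, 12, replace=False)) * 50]
        expected = np.mean([
            any(qp.start < rp.end and rp.start < qp.end for rp in r)
            for qp in q
        ])
        assert overlap_fraction(q, r) == pytest.approx(expected)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            overlap_fraction([], [peak("chr1", 0, 10)])


class TestCallPeaks:
    def test_spike_in_recovered_once(self):
        """A single region at ~50x background density yields exactly one
        merged peak covering it."""
        rng = np.random.default_rng(0)
        bg = uniform_frags(rng, 20_000, 1_000_000)
        spike_s = rng.integers(400_000, 400_300, 600)
        spike = pd.DataFrame(
            {"chrom": "chr1", "start": spike_s, "end": spike_s + 150,
             "barcode": "bulk", "read_support": 1}
        )
        frags = pd.concat([bg, spike], ignore_index=True)
        called = call_peaks(frags, {"chr1": 1_000_000})
        assert len(called) == 1
        assert called[0].start < 400_000 and called[0].end > 400_300

    def test_empty_chromosome_no_peaks(self):
        rng = np.random.default_rng(1)
        frags = uniform_frags(rng, 5000, 500_000)
        called = call_peaks(frags, {"chr1": 500_000, "chrM": 20_000})
        assert all(p.chrom == "chr1" for p in called)

    def test_min_qscore_monotone(self):
        rng = np.random.default_rng(2)
        bg = uniform_frags(rng, 20_000, 1_000_000)
        spikes = []
        for s0 in (100_000, 500_000, 800_000):
            s = rng.integers(s0, s0 + 300, 200)
            spikes.append(pd.DataFrame(
                {"chrom": "chr1", "start": s, "end": s + 150,
                 "barcode": "bulk", "read_support": 1}
            ))
        frags = pd.concat([bg] + spikes, ignore_index=True)
        sizes = {"chr1": 1_000_000}
        counts = [
            len(call_peaks(frags, sizes, PeakCallConfig(min_qscore=q)))
            for q in (2.0, 50.0, 200.0, 400.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_empty_library_rejected(self):
        empty = pd.DataFrame(
            columns=["chrom", "start", "end", "barcode", "read_support"]
        )
        with pytest.raises(ValueError):
            call_peaks(empty, {"chr1": 1000})

    def test_unknown_chromosome_rejected(self):
        frags = pd.DataFrame(
            {"chrom": ["chrX"], "start": [0], "end": [100],
             "barcode": ["b"], "read_support": [1]}
        )
        with pytest.raises(ValueError, match="chrX"):
            call_peaks(frags, {"chr1": 1000})

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PeakCallConfig(window=10, step=20)


class TestPromoters:
    def test_plus_strand_window(self):
        (iv,) = define_promoters([TSSRecord("g", "chr1", 5000, "+")]).values()
        assert (iv.start, iv.end) == (4000, 5100)

    def test_minus_strand_mirrored(self):
        (iv,) = define_promoters([TSSRecord("g", "chr1", 5000, "-")]).values()
        assert (iv.start, iv.end) == (4900, 6000)

    def test_clipped_at_chromosome_start(self):
        (iv,) = define_promoters([TSSRecord("g", "chr1", 500, "+")]).values()
        assert (iv.start, iv.end) == (0, 600)

    def test_clipped_at_chromosome_end(self):
        (iv,) = define_promoters(
            [TSSRecord("g", "chr1", 980, "-")], {"chr1": 1000}
        ).values()
        assert (iv.start, iv.end) == (880, 1000)


class TestFisher:
    def test_matches_scipy_on_small_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 26, 4)
            mine = fisher_exact_two_sided(int(a), int(b), int(c), int(d))
            ref = stats.fisher_exact([[a, b], [c, d]]).pvalue
            assert mine == pytest.approx(ref, abs=1e-10)

    def test_degenerate_table(self):
        assert fisher_exact_two_sided(0, 0, 0, 0) == 1.0


class TestDifferential:
    def _promoters(self, genes):
        return {
            g: GenomicInterval("chr1", 1000 * i, 1000 * i + 500)
            for i, g in enumerate(genes)
        }

    def test_log2fc_pseudocount_formula(self):
        df = differential_promoter_enrichment(
            {"g": 100}, {"g": 10}, 10_000, 10_000, self._promoters(["g"]),
        )
        assert df["log2fc"].iloc[0] == pytest.approx(np.log2(101 / 11))
        assert df["log2fc"].iloc[0] == pytest.approx(3.199, abs=1e-3)

    def test_null_is_filtered_out(self):
        df = differential_promoter_enrichment(
            {"g": 50}, {"g": 50}, 10_000, 10_000, self._promoters(["g"]),
        )
        assert len(df) == 0
        full = differential_promoter_enrichment(
            {"g": 50}, {"g": 50}, 10_000, 10_000, self._promoters(["g"]),
            return_all=True,
        )
        assert full["log2fc"].iloc[0] == 0.0
        assert full["p_value"].iloc[0] == pytest.approx(1.0)

    def test_antisymmetric_in_clusters(self):
        genes = ["g1", "g2", "g3"]
        ca = {"g1": 200, "g2": 30, "g3": 75}
        cb = {"g1": 40, "g2": 90, "g3": 75}
        fwd = differential_promoter_enrichment(
            ca, cb, 50_000, 50_000, self._promoters(genes), return_all=True
        )
        rev = differential_promoter_enrichment(
            cb, ca, 50_000, 50_000, self._promoters(genes), return_all=True
        )
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"])
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"])

    def test_ranked_by_p_then_fold_change(self):
        ca = {"g1": 500, "g2": 60, "g3": 5}
        cb = {"g1": 50, "g2": 10, "g3": 60}
        df = differential_promoter_enrichment(
            ca, cb, 100_000, 100_000, self._promoters(["g1", "g2", "g3"]),
        )
        assert df["p_value"].is_monotonic_increasing

    def test_zero_totals_rejected(self):
        with pytest.raises(ValueError):
            differential_promoter_enrichment(
                {"g": 1}, {"g": 1}, 0, 10, self._promoters(["g"])
            )


class TestCopyNumber:
    def _records(self, genes):
        return pd.DataFrame({"gene_id": genes})

    def test_fraction_arithmetic(self):
        genes = [f"g{i}" for i in range(50)]
        cn = [CopyNumberRecord(g, 2.0 if i < 14 else 1.0)
              for i, g in enumerate(genes)]
        annotated, frac = annotate_copy_number(self._records(genes), cn)
        assert frac == pytest.approx(0.28)
        assert annotated["cn_high"].sum() == 14

    def test_empty_table_gives_nan(self):
        annotated, frac = annotate_copy_number(self._records(["g1"]), [])
        assert np.isnan(frac)
        assert annotated["cn_value"].isna().all()

    def test_threshold_above_all(self):
        cn = [CopyNumberRecord("g1", 1.0)]
        _, frac = annotate_copy_number(
            self._records(["g1"]), cn, cn_threshold=5.0
        )
        assert frac == 0.0
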
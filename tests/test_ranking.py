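"""Window percentiles, outlier calling, sharing, aggregation, gene mapping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coldscan.ranking import (
    aggregate_regions,
    cross_test_overlap,
    empirical_percentiles,
    intersect_external_loci,
    map_windows_to_genes,
    seed_list_test,
    sharing_fraction,
    top_windows,
)


def window_table(stats_, n_snps=None, start_step=200_000, chrom="1"):
    n = len(stats_)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * start_step,
            "end": (np.arange(n) + 1) * start_step,
            "n_snps": n_snps if n_snps is not None else np.full(n, 20),
            "stat": stats_,
        }
    )


class TestEmpiricalPercentiles:
    def test_single_bin_quartiles(self):
        out = empirical_percentiles(window_table([1.0, 2.0, 3.0, 4.0]))
        assert sorted(out["percentile"]) == pytest.approx([0.25, 0.5, 0.75, 1.0])

    def test_all_ties_share_max(self):
        out = empirical_percentiles(window_table([5.0] * 8))
        assert (out["percentile"] == 1.0).all()

    def test_empty_table(self):
        out = empirical_percentiles(window_table([]))
        assert out.empty

    def test_density_binning_decorrelates_snp_count(self, rng):
        # statistic made artificially dependent on n_snps: denser windows
        # get systematically larger values
        n = 4000
        n_snps = rng.integers(10, 200, n)
        stat = n_snps * 0.01 + rng.random(n)
        out = empirical_percentiles(window_table(stat.tolist(), n_snps=n_snps))
        rho = stats.spearmanr(out["percentile"], out["n_snps"]).statistic
        assert abs(rho) < 0.05

    def test_null_calibration(self, rng):
        out = empirical_percentiles(window_table(rng.random(10_000).tolist()))
        flagged = top_windows(out, frac=0.01)
        assert flagged["top1"].mean() == pytest.approx(0.01, abs=0.003)


class TestTopWindows:
    def test_top_fraction_count(self, rng):
        out = empirical_percentiles(window_table(rng.random(1000).tolist()))
        assert top_windows(out, frac=0.01)["top1"].sum() == 10

    def test_monotone_in_fraction(self, rng):
        out = empirical_percentiles(window_table(rng.random(500).tolist()))
        top1 = top_windows(out, frac=0.01)
        top5 = top_windows(out, frac=0.05)
        assert set(np.flatnonzero(top1["top1"])) <= set(np.flatnonzero(top5["top1"]))

    def test_frac_one_returns_everything(self, rng):
        out = empirical_percentiles(window_table(rng.random(50).tolist()))
        assert top_windows(out, frac=1.0)["top1"].all()

    def test_outgroup_exclusion(self, rng):
        out = empirical_percentiles(window_table(rng.random(1000).tolist()))
        flagged = top_windows(out, frac=0.01)
        # outgroup ranks identical to the test population: every candidate
        # is in the outgroup top 5% and must be excluded
        excluded = top_windows(out, frac=0.01, outgroup_table=out)
        assert excluded["top1"].sum() == 0
        assert excluded["excluded_by_outgroup"].sum() == flagged["top1"].sum()

    def test_no_outgroup_no_exclusions(self, rng):
        out = empirical_percentiles(window_table(rng.random(200).tolist()))
        assert not top_windows(out)["excluded_by_outgroup"].any()

    def test_mismatched_grid_rejected(self, rng):
        out = empirical_percentiles(window_table(rng.random(100).tolist()))
        other = empirical_percentiles(
            window_table(rng.random(100).tolist(), start_step=100_000)
        )
        with pytest.raises(ValueError, match="grid"):
            top_windows(out, outgroup_table=other)


class TestSharing:
    def test_identical_tables_share_fully(self, rng):
        out = empirical_percentiles(window_table(rng.random(1000).tolist()))
        assert sharing_fraction(out, out) == 1.0

    def test_disjoint_supports_share_nothing(self):
        ramp = np.arange(1000, dtype=float)
        a = empirical_percentiles(window_table(ramp.tolist()))
        b = empirical_percentiles(window_table(ramp[::-1].tolist()))
        # opposite ramps: X's top windows sit at Y's bottom
        assert sharing_fraction(a, b) == 0.0

    def test_independent_statistics_near_null(self, rng):
        fracs = []
        for _ in range(5):
            a = empirical_percentiles(window_table(rng.random(10_000).tolist()))
            b = empirical_percentiles(window_table(rng.random(10_000).tolist()))
            fracs.append(sharing_fraction(a, b))
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.02)

    def test_invariant_to_row_order(self, rng):
        a = empirical_percentiles(window_table(rng.random(500).tolist()))
        b = empirical_percentiles(window_table(rng.random(500).tolist()))
        perm = rng.permutation(len(a))
        assert sharing_fraction(a, b) == sharing_fraction(
            a.iloc[perm].reset_index(drop=True), b
        )


class TestAggregation:
    def test_clustered_windows_single_region(self):
        # seven significant windows inside one 3-Mb region: the hotspot
        # pattern expected from a strongly swept locus
        top = window_table([1.0] * 7, start_step=200_000)
        top["start"] += 66_000_000
        top["end"] += 66_000_000
        regions = aggregate_regions(top)
        assert regions.loc[0, "n_windows"] == 7
        assert regions.loc[0, "region_start"] == 66_000_000

    def test_spread_windows_count_one_each(self):
        top = window_table([1.0] * 4, start_step=5_000_000)
        regions = aggregate_regions(top)
        assert (regions["n_windows"] == 1).all() and len(regions) == 4

    def test_empty_top_set(self):
        assert aggregate_regions(window_table([])).empty


class TestGeneMapping:
    GENES = pd.DataFrame(
        {
            "chrom": ["1", "1", "1"],
            "start": [150_000, 400_000, 999_000],
            "end": [250_000, 401_000, 1_000_000],
            "gene_id": ["G1", "G2", "G3"],
            "strand": "+",
        }
    )

    def test_overlap_mapped(self):
        wins = window_table([1.0], start_step=400_000)
        wins["start"], wins["end"] = [200_000], [400_000]
        mapping = map_windows_to_genes(wins, self.GENES)
        assert mapping[("1", 200_000, 400_000)] == ["G1"]

    def test_boundary_touch_not_mapped(self):
        wins = pd.DataFrame(
            {"chrom": "1", "start": [250_000], "end": [400_000],
             "n_snps": 1, "stat": 1.0}
        )
        mapping = map_windows_to_genes(wins, self.GENES)
        # G1 ends at 250k (half-open) and G2 starts at 400k: neither overlaps
        assert mapping[("1", 250_000, 400_000)] == []

    def test_window_without_genes(self):
        wins = pd.DataFrame(
            {"chrom": "1", "start": [600_000], "end": [800_000],
             "n_snps": 1, "stat": 1.0}
        )
        assert map_windows_to_genes(wins, self.GENES)[("1", 600_000, 800_000)] == []


class TestCrossTestOverlap:
    def test_identical_lists_all_shared(self):
        t = window_table([1.0] * 3)
        out = cross_test_overlap({"ihs": t, "xpehh": t})
        assert len(out) == 3 and (out["n_tests"] == 2).all()

    def test_disjoint_lists_nothing(self):
        a = window_table([1.0] * 2)
        b = window_table([1.0] * 2)
        b["start"] += 10_000_000
        b["end"] += 10_000_000
        assert cross_test_overlap({"a": a, "b": b}).empty

    def test_cross_grid_interval_overlap_reported_once(self):
        pbs100 = pd.DataFrame(
            {"chrom": "1", "start": [100_000], "end": [200_000],
             "n_snps": 5, "stat": 1.0}
        )
        hap200 = pd.DataFrame(
            {"chrom": "1", "start": [0], "end": [200_000],
             "n_snps": 20, "stat": 1.0}
        )
        out = cross_test_overlap({"pbs": pbs100, "ihs": hap200})
        assert len(out) == 1
        assert out.loc[0, ["start", "end"]].tolist() == [100_000, 200_000]


class TestSeedListTest:
    def _setup(self, rng, n_top=10, n_all=1000, seeded_top=True):
        allw = window_table(rng.random(n_all).tolist())
        top = allw.iloc[:n_top].copy()
        wg = {}
        for i, (_, w) in enumerate(allw.iterrows()):
            key = (w["chrom"], int(w["start"]), int(w["end"]))
            wg[key] = [f"SEED{i}"] if (seeded_top and i < n_top) else [f"BG{i}"]
        seeds = [f"SEED{i}" for i in range(n_top)]
        return top, allw, wg, seeds

    def test_no_hits_p_one(self, rng):
        top, allw, wg, _ = self._setup(rng)
        hits, p = seed_list_test(top, allw, wg, ["ABSENT"])
        assert hits == 0 and p == 1.0

    def test_perfect_enrichment_significant(self, rng):
        top, allw, wg, seeds = self._setup(rng)
        hits, p = seed_list_test(top, allw, wg, seeds)
        assert hits == 10 and p < 0.01

    def test_empty_seed_list_rejected(self, rng):
        top, allw, wg, _ = self._setup(rng)
        with pytest.raises(ValueError, match="empty"):
            seed_list_test(top, allw, wg, [])


class TestExternalLoci:
    def _hits(self, positions, ranks):
        return pd.DataFrame({"chrom": "1", "pos_bp": positions, "rank": ranks})

    def test_no_hits(self):
        top = window_table([1.0] * 4)
        assert intersect_external_loci(self._hits([10], [1.0]), top) == 0.0

    def test_every_window_hit(self):
        top = window_table([1.0] * 4)
        pos = (top["start"] + 100).tolist()
        assert intersect_external_loci(
            self._hits(pos, [1e-5] * 4), top
        ) == 1.0

    def test_half_hit_and_rank_filter(self):
        top = window_table([1.0] * 4)
        pos = (top["start"] + 100).tolist()
        frac = intersect_external_loci(
            self._hits(pos, [1e-5, 1e-5, 1.0, 1.0]), top
        )
        assert frac == 0.5
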
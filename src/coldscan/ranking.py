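"""Density-binned empirical window ranking and candidate-region calling.

SNP-dense windows systematically reach more extreme window statistics, so
windows are first grouped into equal-occupancy bins by SNP count and
ranked within their bin; the empirical percentile (average rank over bin
size, ties sharing the mean rank) is then comparable genome-wide.  Top-1%
outliers form the candidate set, optionally excluding windows that are
also outliers (top 5%) in an outgroup population.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import empty_window_table


def empirical_percentiles(table: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Assign density bins and within-bin empirical percentiles.

    Bins are equal-occupancy by ``n_snps``; the effective bin count is
    capped so each bin holds at least 20 windows (small tables collapse to
    one bin), keeping the within-bin percentile meaningful.
    """
    if table.empty:
        return empty_window_table()
    out = table.copy().reset_index(drop=True)
    n = len(out)
    k = max(1, min(n_bins, n // 20))
    if k == 1:
        out["bin"] = 0
    else:
        out["bin"] = pd.qcut(
            out["n_snps"].rank(method="first"), q=k, labels=False, duplicates="drop"
        ).astype(int)
    out["percentile"] = np.nan
    for b, sub in out.groupby("bin"):
        # ties share the maximum rank so the top percentile is exactly 1.0
        ranks = stats.rankdata(sub["stat"].to_numpy(), method="max")
        out.loc[sub.index, "percentile"] = ranks / len(sub)
    for col, default in (
        ("top1", False),
        ("top5", False),
        ("excluded_by_outgroup", False),
    ):
        out[col] = default
    return out


def top_windows(
    table: pd.DataFrame,
    frac: float = 0.01,
    outgroup_table: pd.DataFrame | None = None,
    outgroup_frac: float = 0.05,
) -> pd.DataFrame:
    """Flag top-``frac`` windows; optionally drop outgroup outliers.

    With an outgroup table (same window grid), candidate windows whose
    outgroup percentile exceeds 1−``outgroup_frac`` are flagged
    ``excluded_by_outgroup`` and removed from the candidate (top1) set.
    Returns the full table with flags set; filter on ``top1`` for the
    candidate list.
    """
    out = table.copy().reset_index(drop=True)
    out["top1"] = out["percentile"] > 1 - frac
    out["top5"] = out["percentile"] > 1 - max(frac, 0.05)
    out["excluded_by_outgroup"] = False
    if outgroup_table is not None:
        key = ["chrom", "start", "end"]
        og = outgroup_table[key + ["percentile"]].rename(
            columns={"percentile": "og_pct"}
        )
        merged = out.merge(og, on=key, how="left", validate="one_to_one")
        if merged["og_pct"].isna().any() or len(outgroup_table) != len(out):
            raise ValueError("outgroup table is not on the same window grid")
        excl = (merged["og_pct"] > 1 - outgroup_frac) & out["top1"]
        out["excluded_by_outgroup"] = excl.to_numpy()
        out.loc[out["excluded_by_outgroup"], "top1"] = False
    return out


def sharing_fraction(tableX: pd.DataFrame, tableY: pd.DataFrame,
                     frac_top: float = 0.01, frac_other: float = 0.05) -> float:
    """Fraction of X's top-1% windows that are in Y's top 5%.

    Both tables must carry percentiles on a common window grid.
    """
    key = ["chrom", "start", "end"]
    x_top = tableX[tableX["percentile"] > 1 - frac_top]
    if x_top.empty:
        return 0.0
    y_top = tableY[tableY["percentile"] > 1 - frac_other]
    shared = x_top.merge(y_top[key], on=key, how="inner")
    return len(shared) / len(x_top)


def aggregate_regions(
    top: pd.DataFrame, region_bp: int = 3_000_000
) -> pd.DataFrame:
    """Count significant windows per non-overlapping ``region_bp`` region.

    Regions are anchored at coordinate 0; a window belongs to the region
    containing its start.  Returns counts sorted descending, so the first
    row is the densest cluster of signals.
    """
    if top.empty:
        return pd.DataFrame(columns=["chrom", "region_start", "region_end", "n_windows"])
    df = top.copy()
    df["region_start"] = (df["start"] // region_bp) * region_bp
    counts = (
        df.groupby(["chrom", "region_start"])
        .size()
        .reset_index(name="n_windows")
    )
    counts["region_end"] = counts["region_start"] + region_bp
    return counts[["chrom", "region_start", "region_end", "n_windows"]].sort_values(
        "n_windows", ascending=False, ignore_index=True
    )


def map_windows_to_genes(
    windows: pd.DataFrame, annotation: pd.DataFrame
) -> dict[tuple[str, int, int], list[str]]:
    """Multimap window → genes whose half-open intervals intersect it."""
    out: dict[tuple[str, int, int], list[str]] = {}
    for _, w in windows.iterrows():
        genes = annotation[
            (annotation["chrom"] == w["chrom"])
            & (annotation["start"] < w["end"])
            & (annotation["end"] > w["start"])
        ]["gene_id"].tolist()
        out[(w["chrom"], int(w["start"]), int(w["end"]))] = genes
    return out


def cross_test_overlap(top_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Intervals present in at least two tests' top-window sets.

    Different window grids (100-kb PBS vs 200-kb haplotype windows) are
    reconciled by interval intersection; each overlapping interval is
    reported once with the list of supporting tests.
    """
    events = []
    for test, tbl in top_tables.items():
        for _, w in tbl.iterrows():
            events.append((str(w["chrom"]), int(w["start"]), int(w["end"]), test))
    rows = []
    seen = set()
    for i, (c1, s1, e1, t1) in enumerate(events):
        tests = {t1}
        lo, hi = s1, e1
        for c2, s2, e2, t2 in events:
            if t2 == t1 or c2 != c1:
                continue
            if s2 < e1 and e2 > s1:
                tests.add(t2)
                lo, hi = max(lo, s2), min(hi, e2)
        if len(tests) >= 2:
            key = (c1, lo, hi)
            if key not in seen:
                seen.add(key)
                rows.append(
                    {
                        "chrom": c1,
                        "start": lo,
                        "end": hi,
                        "tests": ",".join(sorted(tests)),
                        "n_tests": len(tests),
                    }
                )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "tests", "n_tests"])


def seed_list_test(
    top: pd.DataFrame,
    all_windows: pd.DataFrame,
    window_genes: dict[tuple[str, int, int], list[str]],
    seed_genes: list[str],
) -> tuple[int, float]:
    """One-sided Fisher exact test for seed-gene windows among top windows.

    The 2×2 table counts windows containing at least one seed gene in the
    top set vs the rest of the ranked universe; returns (hits, p).
    """
    if not seed_genes:
        raise ValueError("seed gene list is empty")
    seed = set(seed_genes)

    def has_seed(w) -> bool:
        return bool(seed & set(window_genes.get((w["chrom"], int(w["start"]), int(w["end"])), [])))

    top_keys = {(w["chrom"], int(w["start"]), int(w["end"])) for _, w in top.iterrows()}
    k = sum(has_seed(w) for _, w in top.iterrows())
    K = sum(has_seed(w) for _, w in all_windows.iterrows())
    n, N = len(top), len(all_windows)
    if k == 0:
        return 0, 1.0
    table = [[k, n - k], [K - k, (N - n) - (K - k)]]
    _, p = stats.fisher_exact(table, alternative="greater")
    return int(k), float(p)


def intersect_external_loci(
    hits: pd.DataFrame,
    top: pd.DataFrame,
    rank_threshold: float = 5e-4,
    rank_col: str = "rank",
) -> float:
    """Fraction of top windows containing at least one external hit SNP.

    ``hits`` is a chrom/pos table with a transformed-rank column; only
    hits below ``rank_threshold`` count.
    """
    if top.empty:
        return 0.0
    strong = hits[hits[rank_col] < rank_threshold]
    covered = 0
    for _, w in top.iterrows():
        inside = strong[
            (strong["chrom"].astype(str) == str(w["chrom"]))
            & (strong["pos_bp"] - 1 >= w["start"])
            & (strong["pos_bp"] - 1 < w["end"])
        ]
        covered += int(len(inside) > 0)
    return covered / len(top)
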
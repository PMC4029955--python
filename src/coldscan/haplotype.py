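"""EHH-based haplotype homozygosity scans: iHS and XP-EHH.

EHH at genetic distance x from a core SNP is the probability that two
randomly drawn carrier haplotypes are identical at every SNP between the
core and x.  iHH integrates the EHH curve (trapezoid over cM) in both
directions, truncated at the first SNP where EHH falls below 0.05; iHS is
ln(iHH_ancestral/iHH_derived) standardized within derived-allele-frequency
bins, and XP-EHH is ln(iHH_test/iHH_ref) over all haplotypes of each
population, standardized genome-wide.

The implementation tracks, for every haplotype pair, the first flanking
SNP at which the pair mismatches; EHH at step t is then the surviving
pair fraction, computed in vectorized chunks so whole-chromosome scans of
thousands of cores stay fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import HaplotypePanel, empty_window_table

EHH_TRUNCATION = 0.05
MAX_GAP_BP = 200_000
_CHUNK = 128


@dataclass
class EhhCurve:
    """EHH values at successive flanking SNPs in one direction.

    ``distance_cM[k]``/``ehh[k]`` describe the k-th SNP out from the core;
    the implicit point (0, 1.0) at the core is not stored.
    """

    core_index: int
    allele_class: str  # "ancestral" | "derived" | "all"
    direction: int  # +1 right, -1 left
    distance_cM: np.ndarray
    ehh: np.ndarray


def _pair_death_steps(
    alleles: np.ndarray,
    carriers: np.ndarray,
    core: int,
    direction: int,
    stop_ehh: float | None,
    max_steps: int | None = None,
) -> np.ndarray:
    """First-mismatch step (1-based from the core) for every carrier pair.

    Walks outward from the core in ``direction`` until the surviving pair
    fraction drops below ``stop_ehh`` (or the chromosome/`max_steps` end);
    pairs still identical at the last examined step get a death step
    beyond it.  Returned array length equals the number of pairs.
    """
    n = len(carriers)
    iu, ju = np.triu_indices(n, 1)
    n_pairs = len(iu)
    limit = alleles.shape[0] - core - 1 if direction > 0 else core
    if max_steps is not None:
        limit = min(limit, max_steps)
    death = np.full(n_pairs, limit + 1, dtype=np.int64)
    alive = np.ones(n_pairs, dtype=bool)
    done = 0
    while done < limit and alive.any():
        span = min(_CHUNK, limit - done)
        if direction > 0:
            rows = slice(core + 1 + done, core + 1 + done + span)
            block = alleles[rows][:, carriers]
        else:
            rows = slice(core - done - span, core - done)
            block = alleles[rows][:, carriers][::-1]
        live = np.flatnonzero(alive)
        D = block[:, iu[live]] != block[:, ju[live]]
        hit = D.any(axis=0)
        first = D.argmax(axis=0)
        died = live[hit]
        death[died] = done + first[hit] + 1
        alive[died] = False
        done += span
        if stop_ehh is not None and alive.sum() / n_pairs < stop_ehh:
            break
    return death


def _ehh_from_deaths(death: np.ndarray, n_steps: int) -> np.ndarray:
    """EHH at steps 1..n_steps from per-pair first-mismatch steps."""
    n_pairs = len(death)
    deaths_at = np.bincount(
        np.clip(death, 1, n_steps + 1), minlength=n_steps + 2
    )[1 : n_steps + 1]
    return (n_pairs - np.cumsum(deaths_at)) / n_pairs


def ehh(
    panel: HaplotypePanel,
    core: int,
    allele_class: str = "derived",
    direction: int = 1,
    max_steps: int | None = None,
) -> EhhCurve:
    """EHH curve from ``core`` in one direction for an allele class.

    ``allele_class`` selects carrier haplotypes: "derived" (allele 1),
    "ancestral" (allele 0) or "all".  Requires ≥2 carriers.
    """
    alleles = panel.alleles
    if allele_class == "all":
        carriers = np.arange(panel.n_haplotypes)
    elif allele_class == "derived":
        carriers = np.flatnonzero(alleles[core] == 1)
    elif allele_class == "ancestral":
        carriers = np.flatnonzero(alleles[core] == 0)
    else:
        raise ValueError(f"unknown allele class {allele_class!r}")
    if len(carriers) < 2:
        raise ValueError(f"fewer than 2 carriers of {allele_class} allele at core")
    death = _pair_death_steps(alleles, carriers, core, direction, None, max_steps)
    limit = alleles.shape[0] - core - 1 if direction > 0 else core
    if max_steps is not None:
        limit = min(limit, max_steps)
    vals = _ehh_from_deaths(death, limit)
    g = panel.variants["gmap_cM"].to_numpy()
    if direction > 0:
        dist = g[core + 1 : core + 1 + limit] - g[core]
    else:
        dist = g[core] - g[core - limit : core][::-1]
    return EhhCurve(core, allele_class, direction, dist, vals)


def ihh(curve: EhhCurve, truncation: float = EHH_TRUNCATION) -> float:
    """Trapezoidal integral (cM) of one EHH decay curve.

    Integration starts from the implicit core point (0, 1) and stops at
    the first SNP where EHH < ``truncation``, which is included as the
    final trapezoid vertex; if EHH never drops below the threshold the
    integral is undefined (NaN).
    """
    below = np.flatnonzero(curve.ehh < truncation)
    if len(below) == 0:
        return float("nan")
    stop = below[0]
    x = np.concatenate([[0.0], curve.distance_cM[: stop + 1]])
    y = np.concatenate([[1.0], curve.ehh[: stop + 1]])
    return float(np.trapezoid(y, x))


def _integrate_deaths(
    death: np.ndarray,
    dist: np.ndarray,
    gaps_bp: np.ndarray,
    truncation: float,
    max_gap_bp: float,
    stop_at: int | None = None,
) -> float:
    """iHH for one direction from pair death steps; NaN when undefined.

    ``stop_at`` (XP-EHH) forces truncation at a given step instead of this
    curve's own threshold crossing.  A physical gap above ``max_gap_bp``
    anywhere in the integrated span makes the value undefined.
    """
    n_steps = len(dist)
    vals = _ehh_from_deaths(death, n_steps)
    if stop_at is None:
        below = np.flatnonzero(vals < truncation)
        if len(below) == 0:
            return float("nan")
        stop = int(below[0])
    else:
        if stop_at >= n_steps:
            return float("nan")
        stop = stop_at
    if np.any(gaps_bp[: stop + 1] > max_gap_bp):
        return float("nan")
    x = np.concatenate([[0.0], dist[: stop + 1]])
    y = np.concatenate([[1.0], vals[: stop + 1]])
    return float(np.trapezoid(y, x))


class _ChromScanner:
    """Shared per-chromosome geometry for iHH integration."""

    def __init__(self, panel: HaplotypePanel, chrom_index: np.ndarray,
                 truncation: float, max_gap_bp: float):
        self.alleles = panel.alleles[chrom_index]
        g = panel.variants["gmap_cM"].to_numpy()[chrom_index]
        p = panel.variants["pos_bp"].to_numpy()[chrom_index]
        self.g, self.p = g, p
        self.truncation = truncation
        self.max_gap_bp = max_gap_bp
        self.n = len(chrom_index)

    def directional(self, core: int, direction: int):
        if direction > 0:
            dist = self.g[core + 1 :] - self.g[core]
            gaps = np.diff(self.p[core:])
        else:
            dist = (self.g[core] - self.g[:core])[::-1]
            gaps = np.diff(self.p[: core + 1])[::-1]
        return dist, gaps

    def ihh_two_sided(self, carriers: np.ndarray, core: int,
                      stops: tuple[int, int] | None = None) -> float:
        """Sum of left and right truncated EHH integrals; NaN if either
        side is undefined."""
        total = 0.0
        for d, side in ((1, 0), (-1, 1)):
            dist, gaps = self.directional(core, d)
            death = _pair_death_steps(
                self.alleles, carriers, core, d,
                None if stops else self.truncation,
                max_steps=stops[side] + 1 if stops else None,
            )
            val = _integrate_deaths(
                death, dist, gaps, self.truncation, self.max_gap_bp,
                stop_at=stops[side] if stops else None,
            )
            if np.isnan(val):
                return float("nan")
            total += val
        return total

    def truncation_steps(self, carriers: np.ndarray, core: int):
        """Per-direction step index where this carrier set's EHH first
        drops below the truncation threshold (None if never)."""
        out = []
        for d in (1, -1):
            dist, _ = self.directional(core, d)
            death = _pair_death_steps(
                self.alleles, carriers, core, d, self.truncation
            )
            vals = _ehh_from_deaths(death, len(dist))
            below = np.flatnonzero(vals < self.truncation)
            out.append(int(below[0]) if len(below) else None)
        return tuple(out)


def ihs_scan(
    panel: HaplotypePanel,
    min_maf: float = 0.05,
    truncation: float = EHH_TRUNCATION,
    max_gap_bp: float = MAX_GAP_BP,
    n_bins: int = 20,
    bin_min_snps: int = 50,
) -> pd.DataFrame:
    """iHS at every polarized SNP with MAF ≥ ``min_maf``.

    Returns a per-SNP track with iHH for each allele, the unstandardized
    ln(iHH_A/iHH_D), the derived-allele frequency, the frequency bin, and
    the bin-standardized iHS (NaN where either integral is undefined).
    """
    freq = panel.derived_freq()
    known = panel.variants["ancestral_known"].to_numpy()
    usable = known & (np.minimum(freq, 1 - freq) >= min_maf)
    ihh_a = np.full(panel.n_variants, np.nan)
    ihh_d = np.full(panel.n_variants, np.nan)
    chroms = panel.variants["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        cidx = np.flatnonzero(chroms == chrom)
        scanner = _ChromScanner(panel, cidx, truncation, max_gap_bp)
        for local, global_i in enumerate(cidx):
            if not usable[global_i]:
                continue
            der = np.flatnonzero(scanner.alleles[local] == 1)
            anc = np.flatnonzero(scanner.alleles[local] == 0)
            if len(der) < 2 or len(anc) < 2:
                continue
            ihh_d[global_i] = scanner.ihh_two_sided(der, local)
            ihh_a[global_i] = scanner.ihh_two_sided(anc, local)
    with np.errstate(invalid="ignore", divide="ignore"):
        unstd = np.log(ihh_a / ihh_d)
    track = pd.DataFrame(
        {
            "chrom": panel.variants["chrom"],
            "pos_bp": panel.variants["pos_bp"],
            "snp_id": panel.variants["snp_id"],
            "daf": freq,
            "ihh_a": ihh_a,
            "ihh_d": ihh_d,
            "ihs_unstd": unstd,
        }
    )
    track["freq_bin"], track["ihs"] = _standardize_by_bin(
        unstd, freq, min_maf, n_bins, bin_min_snps
    )
    return track


def _standardize_by_bin(
    scores: np.ndarray, freq: np.ndarray, min_maf: float, n_bins: int,
    bin_min_snps: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize scores within derived-allele-frequency bins.

    Bins are equal-width on [min_maf, 1−min_maf]; bins holding fewer than
    ``bin_min_snps`` defined scores are merged with their right neighbour
    (last bin merges left).
    """
    lo, hi = min_maf, 1 - min_maf
    edges = np.linspace(lo, hi, n_bins + 1)
    raw_bin = np.clip(np.searchsorted(edges, freq, side="right") - 1, 0, n_bins - 1)
    defined = ~np.isnan(scores)
    # merge sparse bins left-to-right
    remap = np.arange(n_bins)
    counts = np.bincount(raw_bin[defined], minlength=n_bins)
    merged_counts = counts.astype(int).copy()
    b = 0
    while b < n_bins - 1:
        if merged_counts[b] and merged_counts[b] < bin_min_snps:
            remap[remap == b] = b + 1
            merged_counts[b + 1] += merged_counts[b]
            merged_counts[b] = 0
        b += 1
    last = n_bins - 1
    if merged_counts[last] and merged_counts[last] < bin_min_snps:
        prev = np.unique(remap[remap < last])
        if len(prev):
            remap[remap == last] = prev[-1]
    bins = remap[raw_bin]
    std = np.full_like(scores, np.nan)
    for b in np.unique(bins[defined]):
        sel = defined & (bins == b)
        mu = scores[sel].mean()
        sd = scores[sel].std(ddof=0)
        std[sel] = (scores[sel] - mu) / sd if sd > 0 else 0.0
    return bins, std


def xpehh_scan(
    panel_test: HaplotypePanel,
    panel_ref: HaplotypePanel,
    truncation: float = EHH_TRUNCATION,
    max_gap_bp: float = MAX_GAP_BP,
) -> pd.DataFrame:
    """XP-EHH per SNP between a test and a reference population.

    EHH is computed over all haplotypes of each population; both integrals
    are truncated where the EHH of the pooled two-population sample drops
    below the threshold.  Scores ln(iHH_test/iHH_ref) are standardized
    genome-wide to mean 0, sd 1.
    """
    if not panel_test.variants["snp_id"].equals(panel_ref.variants["snp_id"]):
        raise ValueError("test and reference panels must share the variant set")
    pooled = HaplotypePanel(
        panel_test.variants.copy(),
        list(panel_test.haplotype_ids) + list(panel_ref.haplotype_ids),
        np.hstack([panel_test.alleles, panel_ref.alleles]),
    )
    n = panel_test.n_variants
    ihh_t = np.full(n, np.nan)
    ihh_r = np.full(n, np.nan)
    chroms = panel_test.variants["chrom"].to_numpy()
    test_cols = np.arange(panel_test.n_haplotypes)
    ref_cols = np.arange(panel_ref.n_haplotypes)
    for chrom in pd.unique(chroms):
        cidx = np.flatnonzero(chroms == chrom)
        sc_pool = _ChromScanner(pooled, cidx, truncation, max_gap_bp)
        sc_test = _ChromScanner(panel_test, cidx, truncation, max_gap_bp)
        sc_ref = _ChromScanner(panel_ref, cidx, truncation, max_gap_bp)
        all_pool = np.arange(pooled.n_haplotypes)
        for local, global_i in enumerate(cidx):
            stops = sc_pool.truncation_steps(all_pool, local)
            if stops[0] is None or stops[1] is None:
                continue
            ihh_t[global_i] = sc_test.ihh_two_sided(test_cols, local, stops=stops)
            ihh_r[global_i] = sc_ref.ihh_two_sided(ref_cols, local, stops=stops)
    with np.errstate(invalid="ignore", divide="ignore"):
        unstd = np.log(ihh_t / ihh_r)
    defined = ~np.isnan(unstd)
    std = np.full(n, np.nan)
    if defined.sum() >= 2 and unstd[defined].std(ddof=0) > 0:
        std[defined] = (unstd[defined] - unstd[defined].mean()) / unstd[
            defined
        ].std(ddof=0)
    elif defined.any():
        std[defined] = 0.0
    return pd.DataFrame(
        {
            "chrom": panel_test.variants["chrom"],
            "pos_bp": panel_test.variants["pos_bp"],
            "snp_id": panel_test.variants["snp_id"],
            "ihh_test": ihh_t,
            "ihh_ref": ihh_r,
            "xpehh_unstd": unstd,
            "xpehh": std,
        }
    )


def _window_table(
    track: pd.DataFrame,
    value_col: str,
    window_bp: int,
    min_snps: int,
    stat_fn,
) -> pd.DataFrame:
    rows = []
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub[~np.isnan(sub[value_col])]
        if sub.empty:
            continue
        win = (sub["pos_bp"] - 1) // window_bp
        for w, g in sub.assign(win=win).groupby("win"):
            if len(g) < min_snps:
                continue
            rows.append(
                {
                    "chrom": str(chrom),
                    "start": int(w) * window_bp,
                    "end": (int(w) + 1) * window_bp,
                    "n_snps": len(g),
                    "stat": float(stat_fn(g[value_col].to_numpy())),
                }
            )
    if not rows:
        return empty_window_table()
    out = pd.DataFrame(rows)
    out["bin"] = -1
    out["percentile"] = np.nan
    out["top1"] = False
    out["top5"] = False
    out["excluded_by_outgroup"] = False
    return out


def ihs_window_stat(
    track: pd.DataFrame,
    window_bp: int = 200_000,
    ihs_abs_threshold: float = 2.0,
    min_snps: int = 10,
) -> pd.DataFrame:
    """200-kb windows; statistic = fraction of SNPs with |iHS| above the
    threshold; windows with fewer than ``min_snps`` scored SNPs dropped."""
    return _window_table(
        track,
        "ihs",
        window_bp,
        min_snps,
        lambda v: np.mean(np.abs(v) > ihs_abs_threshold),
    )


def xpehh_window_stat(
    track: pd.DataFrame, window_bp: int = 200_000, min_snps: int = 10
) -> pd.DataFrame:
    """200-kb windows; statistic = maximum standardized XP-EHH."""
    return _window_table(track, "xpehh", window_bp, min_snps, np.max)
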
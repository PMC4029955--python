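"""Three-population admixture test f3(C; A, B) with block-jackknife Z.

f3 is the expectation over SNPs of (c − a)(c − b), where a, b, c are
sample allele frequencies.  If C descends from a mixture of populations
related to A and B the statistic is driven negative; a finite-sample
correction (unbiased heterozygosity of C over its sampled chromosome
count) removes the upward bias of the plug-in moment.  Standard errors
come from a weighted delete-one-block jackknife over contiguous SNP
blocks; trios with Z = f3/SE below −2 are flagged admixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, population_index


@dataclass
class F3Result:
    target: str
    sourceA: str
    sourceB: str
    f3: float
    se: float
    z: float
    n_blocks: int
    n_snps: int
    admixed: bool
    degenerate: bool = False


def _freq_and_count(gm: GenotypeMatrix, idx: np.ndarray):
    d = gm.dosage[:, idx]
    obs = d != MISSING
    m = 2 * obs.sum(axis=1).astype(float)  # sampled chromosomes
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(obs, d, 0).sum(axis=1) / m
    return f, m


def f3_statistic(
    gm: GenotypeMatrix,
    labels: pd.DataFrame,
    target: str,
    sourceA: str,
    sourceB: str,
    correction: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP f3 values and a validity mask.

    With ``correction`` the unbiased estimator subtracts ĥ_C/m_C per SNP,
    where ĥ_C = m_C/(m_C−1)·2c(1−c); without it (infinite-n mode) the
    plug-in moment (c−a)(c−b) is returned.  SNPs with fewer than two
    sampled chromosomes in any population, or monomorphic in all three,
    are masked out.
    """
    a, ma = _freq_and_count(gm, population_index(labels, gm.samples, sourceA))
    b, mb = _freq_and_count(gm, population_index(labels, gm.samples, sourceB))
    c, mc = _freq_and_count(gm, population_index(labels, gm.samples, target))
    ok = (ma >= 2) & (mb >= 2) & (mc >= 2)
    ok &= ~(np.isnan(a) | np.isnan(b) | np.isnan(c))
    poly = ~((a % 1 == 0) & (b % 1 == 0) & (a == b) & (b == c))
    ok &= poly
    vals = (c - a) * (c - b)
    if correction:
        with np.errstate(invalid="ignore", divide="ignore"):
            h_c = mc / (mc - 1) * 2 * c * (1 - c)
            vals = vals - h_c / mc
    return np.where(ok, vals, np.nan), ok


def block_jackknife_z(
    values: np.ndarray,
    block_size_snps: int = 500,
    target: str = "C",
    sourceA: str = "A",
    sourceB: str = "B",
    z_threshold: float = -2.0,
) -> F3Result:
    """Weighted delete-one-block jackknife over contiguous SNP blocks.

    Blocks may hold unequal numbers of defined SNPs; the jackknife
    variance weights each block by its SNP count.  A degenerate SE (all
    block means identical) is floored at machine epsilon and flagged.
    """
    vals = np.asarray(values, dtype=float)
    defined = ~np.isnan(vals)
    n = int(defined.sum())
    if n == 0:
        raise ValueError("no defined per-SNP f3 values")
    estimate = float(np.nanmean(vals))
    edges = range(0, len(vals), block_size_snps)
    block_sums, block_ns = [], []
    for lo in edges:
        chunk = vals[lo : lo + block_size_snps]
        m = np.isfinite(chunk).sum()
        if m > 0:
            block_sums.append(np.nansum(chunk))
            block_ns.append(m)
    g = len(block_sums)
    if g < 2:
        return F3Result(target, sourceA, sourceB, estimate, np.nan, np.nan, g, n,
                        False, degenerate=True)
    block_sums = np.asarray(block_sums)
    block_ns = np.asarray(block_ns, dtype=float)
    total = block_sums.sum()
    loo = (total - block_sums) / (n - block_ns)  # delete-one-block estimates
    h = n / block_ns
    pseudo = h * estimate - (h - 1) * loo
    # weighted jackknife variance (Busing et al. 1999)
    var = float(np.sum((pseudo - estimate) ** 2 / (h - 1)) / g)
    se = np.sqrt(var)
    degenerate = False
    # identical block means give var 0 up to float noise
    if not np.isfinite(se) or se <= 1e-12 * max(abs(estimate), 1e-30):
        se = max(se, float(np.finfo(float).eps))
        degenerate = True
    z = estimate / se
    return F3Result(
        target, sourceA, sourceB, estimate, se, float(z), g, n,
        bool(z < z_threshold and not degenerate), degenerate,
    )


def f3_test(
    gm: GenotypeMatrix,
    labels: pd.DataFrame,
    target: str,
    sourceA: str,
    sourceB: str,
    block_size_snps: int = 500,
    correction: bool = True,
    z_threshold: float = -2.0,
) -> F3Result:
    """f3(target; sourceA, sourceB) with block-jackknife Z."""
    vals, _ = f3_statistic(gm, labels, target, sourceA, sourceB, correction)
    res = block_jackknife_z(
        vals, block_size_snps, target, sourceA, sourceB, z_threshold
    )
    return res


def f3_all_trios(
    gm: GenotypeMatrix,
    labels: pd.DataFrame,
    block_size_snps: int = 500,
) -> pd.DataFrame:
    """Every (target; sourceA, sourceB) combination, one row per trio."""
    pops = list(labels["population"].unique())
    columns = ["target", "sourceA", "sourceB", "f3", "se", "z",
               "n_snps", "n_blocks", "admixed"]
    rows = []
    for target in pops:
        others = [p for p in pops if p != target]
        for i, a in enumerate(others):
            for b in others[i + 1 :]:
                r = f3_test(gm, labels, target, a, b, block_size_snps)
                rows.append(
                    {
                        "target": r.target,
                        "sourceA": r.sourceA,
                        "sourceB": r.sourceB,
                        "f3": r.f3,
                        "se": r.se,
                        "z": r.z,
                        "n_snps": r.n_snps,
                        "n_blocks": r.n_blocks,
                        "admixed": r.admixed,
                    }
                )
    return pd.DataFrame(rows, columns=columns)
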
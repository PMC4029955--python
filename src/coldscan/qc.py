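"""Variant and sample quality control.

Implements the scan pipeline's standard filters — genotyping call rate,
minor-allele frequency, sliding-window LD thinning — and method-of-moments
IBD estimation (PI_HAT) with iterative per-population relatedness pruning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, HaplotypePanel, population_index


@dataclass
class RelatednessRecord:
    sample1: str
    sample2: str
    p_ibd0: float
    p_ibd1: float
    p_ibd2: float
    pi_hat: float
    n_snps: int


def filter_call_rate(gm: GenotypeMatrix, min_rate: float = 0.98) -> GenotypeMatrix:
    """Keep variants whose fraction of non-missing genotypes exceeds
    ``min_rate`` (strict inequality)."""
    rate = (gm.dosage != MISSING).mean(axis=1)
    return gm.take_variants(np.flatnonzero(rate > min_rate))


def _maf(freq: np.ndarray) -> np.ndarray:
    return np.minimum(freq, 1 - freq)


def filter_maf(data, min_maf: float = 0.05):
    """Keep variants with minor allele frequency at least ``min_maf``
    (inclusive); works on genotype matrices and haplotype panels alike."""
    if isinstance(data, HaplotypePanel):
        freq = data.derived_freq()
    else:
        freq = data.allele_freq()
    keep = np.flatnonzero(_maf(np.nan_to_num(freq, nan=0.0)) >= min_maf)
    return data.take_variants(keep)


def _dosage_frame(gm: GenotypeMatrix, cols: np.ndarray) -> pd.DataFrame:
    d = gm.dosage[cols].astype(float)
    d[gm.dosage[cols] == MISSING] = np.nan
    return pd.DataFrame(d.T)


def ld_prune(
    gm: GenotypeMatrix, r2_max: float = 0.1, window: int = 50, step: int = 10
) -> np.ndarray:
    """Greedy LD thinning; returns indices of kept variants.

    Within each ``window``-SNP block (advanced by ``step``), any pair with
    genotype-dosage r² above ``r2_max`` loses its later-positioned member;
    the block is re-examined until stable.  Pairwise-complete observations
    handle missingness.
    """
    removed = np.zeros(gm.n_variants, dtype=bool)
    # full sweeps repeat until stable: removals compact the kept list, which
    # can bring previously distant SNPs into the same window
    while True:
        kept = np.flatnonzero(~removed)
        any_removed = False
        start = 0
        while start < len(kept):
            idx = kept[start : start + window]
            while True:
                live = idx[~removed[idx]]
                if len(live) < 2:
                    break
                corr = _dosage_frame(gm, live).corr(min_periods=2).to_numpy()
                r2 = np.nan_to_num(corr, nan=0.0) ** 2
                np.fill_diagonal(r2, 0.0)
                ii, jj = np.nonzero(np.triu(r2 > r2_max, k=1))
                if len(ii) == 0:
                    break
                dropped = set()
                for a, b in zip(ii, jj):
                    if live[a] in dropped or live[b] in dropped:
                        continue
                    removed[live[b]] = True  # later SNP in position order
                    dropped.add(live[b])
                    any_removed = True
            if start + window >= len(kept):
                break
            start += step
        if not any_removed:
            break
    return np.flatnonzero(~removed)


def pihat(
    gm: GenotypeMatrix,
    pair: tuple[int, int],
    freqs: np.ndarray | None = None,
    min_informative: int = 100,
) -> RelatednessRecord:
    """Method-of-moments IBD estimate for one sample pair.

    Observed IBS0/1/2 counts are compared against their expectations given
    allele frequencies (estimated from the matrix unless supplied, with
    fixed alleles excluded); the linear system is solved for P(IBD=0,1,2),
    negatives clamped and renormalized; PI_HAT = P1/2 + P2.
    """
    i, j = pair
    if freqs is None:
        freqs = gm.allele_freq()
    gi, gj = gm.dosage[:, i], gm.dosage[:, j]
    ok = (
        (gi != MISSING)
        & (gj != MISSING)
        & (freqs > 0)
        & (freqs < 1)
        & ~np.isnan(freqs)
    )
    m = int(ok.sum())
    if m < min_informative:
        raise ValueError(f"only {m} informative SNPs for pair; need {min_informative}")
    p = freqs[ok]
    q = 1 - p
    a, b = gi[ok].astype(int), gj[ok].astype(int)
    ibs = 2 - np.abs(a - b)
    obs0, obs1, obs2 = np.bincount(ibs, minlength=3)

    # expected IBS class probabilities given IBD state, summed over loci
    e0_ibd0 = np.sum(2 * p**2 * q**2)
    e1_ibd0 = np.sum(4 * p**3 * q + 4 * p * q**3)
    e1_ibd1 = np.sum(2 * p**2 * q + 2 * p * q**2)
    p0 = obs0 / e0_ibd0 if e0_ibd0 > 0 else 0.0
    p1 = (obs1 - p0 * e1_ibd0) / e1_ibd1 if e1_ibd1 > 0 else 0.0
    p2 = (obs2 - p0 * (m - e0_ibd0 - e1_ibd0) - p1 * (m - e1_ibd1)) / m
    probs = np.clip([p0, p1, p2], 0.0, None)
    total = probs.sum()
    probs = probs / total if total > 0 else np.array([1.0, 0.0, 0.0])
    pi = float(probs[1] / 2 + probs[2])
    return RelatednessRecord(
        gm.samples[i], gm.samples[j], *map(float, probs), min(max(pi, 0.0), 1.0), m
    )


def _population_pihat_table(gm: GenotypeMatrix, idx: np.ndarray) -> pd.DataFrame:
    """All pairwise PI_HAT within one population, frequencies re-estimated
    from that subset with fixed alleles excluded."""
    sub = gm.take_samples(idx)
    freqs = sub.allele_freq()
    poly = (freqs > 0) & (freqs < 1) & ~np.isnan(freqs)
    sub = sub.take_variants(np.flatnonzero(poly))
    freqs = freqs[poly]
    rows = []
    for a in range(sub.n_samples):
        for b in range(a + 1, sub.n_samples):
            rec = pihat(sub, (a, b), freqs)
            rows.append(
                {
                    "sample1": rec.sample1,
                    "sample2": rec.sample2,
                    "pi_hat": rec.pi_hat,
                }
            )
    return pd.DataFrame(rows, columns=["sample1", "sample2", "pi_hat"])


def iterative_relatedness_prune(
    gm: GenotypeMatrix, labels: pd.DataFrame, threshold: float = 0.125
) -> list[str]:
    """Iteratively remove relatives within each population.

    While any pair exceeds ``threshold``, remove the individual with the
    most over-threshold partners (ties: higher mean PI_HAT over those
    partners, then lexicographically smaller id), re-estimate frequencies,
    and repeat.  Returns the removed sample ids.
    """
    removed: list[str] = []
    for pop in labels["population"].unique():
        idx = list(population_index(labels, gm.samples, pop))
        while len(idx) >= 2:
            table = _population_pihat_table(gm, np.asarray(idx))
            over = table[table["pi_hat"] > threshold]
            if over.empty:
                break
            partners: dict[str, list[float]] = {}
            for _, row in over.iterrows():
                partners.setdefault(row["sample1"], []).append(row["pi_hat"])
                partners.setdefault(row["sample2"], []).append(row["pi_hat"])
            victim = sorted(
                partners,
                key=lambda s: (-len(partners[s]), -float(np.mean(partners[s])), s),
            )[0]
            removed.append(victim)
            idx = [i for i in idx if gm.samples[i] != victim]
    return removed
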
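"""Weir–Cockerham F_ST, the population branch statistic (PBS), and
100-kb max-PBS windows.

F_ST uses the Weir & Cockerham (1984) weighted analysis of variance with
the observed-heterozygosity term, two populations, diploid samples.  PBS
transforms pairwise F_ST into branch lengths T = −ln(1 − F_ST) and takes
the test population's private branch, (T_AB + T_AC − T_BC)/2; large PBS
marks loci with unusually fast frequency change on that branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, empty_window_table, population_index


@dataclass
class FstComponents:
    """Per-SNP variance components: a (among populations), b (among
    individuals within populations), c (within individuals)."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    @property
    def theta(self) -> np.ndarray:
        """Per-SNP θ̂ = a/(a+b+c); NaN where the SNP is monomorphic in
        both populations (undefined)."""
        denom = self.a + self.b + self.c
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom != 0, self.a / denom, np.nan)

    @property
    def theta_multilocus(self) -> float:
        """Ratio-of-sums multi-locus estimate Σa / Σ(a+b+c)."""
        denom = np.nansum(self.a + self.b + self.c)
        return float(np.nansum(self.a) / denom) if denom else float("nan")


def _pop_summaries(gm: GenotypeMatrix, idx: np.ndarray):
    d = gm.dosage[:, idx]
    obs = d != MISSING
    n = obs.sum(axis=1).astype(float)  # genotyped individuals per SNP
    dm = np.where(obs, d, 0)
    with np.errstate(invalid="ignore"):
        p = dm.sum(axis=1) / (2 * n)
        h = np.where(obs, d == 1, False).sum(axis=1) / n  # observed het freq
    return n, p, h


def wc_fst(gm: GenotypeMatrix, labels: pd.DataFrame, popA: str, popB: str) -> FstComponents:
    """Two-population Weir & Cockerham (1984) variance components per SNP.

    SNPs with fewer than two genotyped individuals in either population
    get NaN components.
    """
    iA = population_index(labels, gm.samples, popA)
    iB = population_index(labels, gm.samples, popB)
    n1, p1, h1 = _pop_summaries(gm, iA)
    n2, p2, h2 = _pop_summaries(gm, iB)
    r = 2.0
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return FstComponents(a, b, c)


def pbs(
    fst_ab: np.ndarray, fst_ac: np.ndarray, fst_bc: np.ndarray, cap: float = 1 - 1e-6
) -> np.ndarray:
    """PBS_A from the three pairwise per-SNP F_ST tracks.

    Negative θ̂ is clamped to 0 and values capped below 1 so the log
    branch transform stays finite.
    """

    def branch(f):
        f = np.clip(np.nan_to_num(f, nan=0.0), 0.0, cap)
        return -np.log1p(-f)

    return (branch(fst_ab) + branch(fst_ac) - branch(fst_bc)) / 2


def pbs_scan(
    gm: GenotypeMatrix, labels: pd.DataFrame, test: str, out1: str, out2: str
) -> pd.DataFrame:
    """Per-SNP PBS of ``test`` against two outgroups; returns a score track."""
    t_ab = wc_fst(gm, labels, test, out1).theta
    t_ac = wc_fst(gm, labels, test, out2).theta
    t_bc = wc_fst(gm, labels, out1, out2).theta
    scores = pbs(t_ab, t_ac, t_bc)
    return pd.DataFrame(
        {
            "chrom": gm.variants["chrom"],
            "pos_bp": gm.variants["pos_bp"],
            "snp_id": gm.variants["snp_id"],
            "pbs": scores,
        }
    )


def window_max_pbs(scores: pd.DataFrame, window_bp: int = 100_000) -> pd.DataFrame:
    """Non-overlapping windows anchored at 0; statistic = max per-SNP PBS.

    Windows with no SNPs are dropped; the SNP count feeds density-binned
    percentile ranking downstream.
    """
    rows = []
    for chrom, sub in scores.groupby("chrom", sort=False):
        win = (sub["pos_bp"] - 1) // window_bp  # 1-based pos -> 0-based window
        grouped = sub.assign(win=win).groupby("win")
        for w, g in grouped:
            stat = g["pbs"].max()
            if np.isnan(stat):
                continue
            rows.append(
                {
                    "chrom": str(chrom),
                    "start": int(w) * window_bp,
                    "end": (int(w) + 1) * window_bp,
                    "n_snps": int(g["pbs"].notna().sum()),
                    "stat": float(stat),
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
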
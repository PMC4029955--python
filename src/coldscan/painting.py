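"""Haploid copying-model ancestry painting of phased chromosomes.

A recipient haplotype is modelled as a Li–Stephens mosaic of donor
haplotypes: the hidden state is the donor being copied, switches between
consecutive SNPs happen with probability 1 − exp(−ρ·ΔcM) followed by a
uniform re-draw of the donor, and the emission is a match with
probability 1 − θ.  The forward–backward posterior, summed over the
haplotypes of each donor population, gives the expected copying
probability per SNP; a SNP is assigned to a population only when that
probability strictly exceeds 0.7, otherwise it is undecided.

This is a deliberately simplified copying model (no per-donor copy-length
weighting or chunk-count machinery): its role is ancestry assignment of
candidate regions and the regional empirical tail test built on top.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

UNDECIDED = "undecided"


@dataclass
class DonorPanelSpec:
    """Donor haplotype columns per ancestry label."""

    donors: dict[str, np.ndarray]  # label -> haplotype column indices

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for label, idx in self.donors.items():
            idx = np.asarray(idx, dtype=int)
            if len(idx) < 2:
                raise ValueError(f"donor population {label!r} needs ≥2 haplotypes")
            if seen & set(idx.tolist()):
                raise ValueError("donor sets must be disjoint")
            seen |= set(idx.tolist())
            self.donors[label] = idx


def select_donors(
    q_matrix: pd.DataFrame,
    clusters: dict[str, str],
    q_min: float = 0.99,
) -> dict[str, list[str]]:
    """Pick donor samples per ancestry from ancestry coefficients Q.

    A sample becomes a donor for ancestry X when its Q for X is at least
    ``q_min`` AND its cluster label agrees with X.  ``q_matrix`` is
    sample × ancestry; ``clusters`` maps sample → cluster label (named by
    ancestry).
    """
    out: dict[str, list[str]] = {a: [] for a in q_matrix.columns}
    for sample, row in q_matrix.iterrows():
        best = row.idxmax()
        if row[best] >= q_min and clusters.get(sample) == best:
            out[best].append(sample)
    return out


def _emissions(recipient: np.ndarray, donor_alleles: np.ndarray, theta: float) -> np.ndarray:
    match = donor_alleles == recipient[:, None]
    return np.where(match, 1.0 - theta, theta)


def _switch_probs(gmap_cM: np.ndarray, rho: float) -> np.ndarray:
    d = np.diff(gmap_cM)
    if np.any(d < 0):
        raise ValueError("genetic distances must be non-decreasing")
    return 1.0 - np.exp(-rho * d)


def _forward_backward(emit: np.ndarray, r: np.ndarray):
    """Scaled forward–backward for the uniform-redraw copying HMM.

    Returns (posterior γ, log-likelihood, expected redraw probability per
    interval).
    """
    T, nD = emit.shape
    alpha = np.empty((T, nD))
    scale = np.empty(T)
    a = emit[0] / nD
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, T):
        a = ((1 - r[t - 1]) * alpha[t - 1] + r[t - 1] / nD) * emit[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]
    beta = np.empty((T, nD))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        w = emit[t + 1] * beta[t + 1]
        beta[t] = ((1 - r[t]) * w + r[t] / nD * w.sum()) / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    # P(redraw event in interval t | data); Σ_j alpha_t(j) = 1 after scaling
    switch_post = np.empty(T - 1)
    for t in range(T - 1):
        w = emit[t + 1] * beta[t + 1]
        switch_post[t] = (r[t] / nD) * w.sum() / scale[t + 1]
    return gamma, float(np.log(scale).sum()), np.clip(switch_post, 0.0, 1.0)


def copying_probabilities(
    recipient: np.ndarray,
    donor_alleles: np.ndarray,
    donor_pops: list[str],
    gmap_cM: np.ndarray,
    rho: float = 1.0,
    theta: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Expected copying probability per SNP per donor population.

    ``recipient`` is a 0/1 vector, ``donor_alleles`` a SNP × donor matrix
    and ``donor_pops`` the population label of each donor column.  Returns
    (probability table with one column per population, log-likelihood).
    θ defaults to 0.5/(n_donors + 0.5).
    """
    donor_alleles = np.asarray(donor_alleles)
    if donor_alleles.ndim != 2 or donor_alleles.shape[1] == 0:
        raise ValueError("need at least one donor haplotype")
    nD = donor_alleles.shape[1]
    theta = 0.5 / (nD + 0.5) if theta is None else theta
    emit = _emissions(np.asarray(recipient), donor_alleles, theta)
    r = _switch_probs(np.asarray(gmap_cM, dtype=float), rho)
    gamma, loglik, _ = _forward_backward(emit, r)
    table = pd.DataFrame(index=range(len(recipient)))
    for pop in dict.fromkeys(donor_pops):
        cols = [j for j, p in enumerate(donor_pops) if p == pop]
        table[pop] = gamma[:, cols].sum(axis=1)
    return table, loglik


def estimate_rho_em(
    recipients: np.ndarray,
    donor_alleles: np.ndarray,
    gmap_cM: np.ndarray,
    rho_init: float = 1.0,
    theta: float | None = None,
    n_steps: int = 10,
) -> tuple[float, list[float]]:
    """EM estimate of the copying switch rate ρ (per cM).

    The E-step computes the posterior probability of a recombination-
    driven donor re-draw in each inter-SNP interval; the M-step maximizes
    the expected complete-data log-likelihood of the interval Bernoulli
    events in ρ.  Runs a fixed number of steps (the default 10 suffices
    for the scale of data painted here); returns (ρ, per-step data
    log-likelihoods, non-decreasing by EM construction).
    """
    recipients = np.atleast_2d(np.asarray(recipients).T).T
    if recipients.ndim == 1:
        recipients = recipients[:, None]
    nD = donor_alleles.shape[1]
    theta = 0.5 / (nD + 0.5) if theta is None else theta
    d = np.diff(np.asarray(gmap_cM, dtype=float))
    rho = float(rho_init)
    logliks: list[float] = []
    for _ in range(n_steps):
        r = 1.0 - np.exp(-rho * d)
        total_ll = 0.0
        e_switch = np.zeros_like(d)
        for k in range(recipients.shape[1]):
            emit = _emissions(recipients[:, k], donor_alleles, theta)
            _, ll, sp = _forward_backward(emit, r)
            total_ll += ll
            e_switch += sp
        logliks.append(total_ll)
        n_rec = recipients.shape[1]

        def neg_q(log_rho):
            rr = np.clip(1.0 - np.exp(-np.exp(log_rho) * d), 1e-12, 1 - 1e-12)
            return -(np.sum(e_switch * np.log(rr))
                     + np.sum((n_rec - e_switch) * np.log1p(-rr)))

        res = minimize_scalar(
            neg_q, bounds=(np.log(1e-6), np.log(1e6)), method="bounded"
        )
        rho = float(np.exp(res.x))
    return rho, logliks


def assign_ancestry(prob_table: pd.DataFrame, threshold: float = 0.7) -> pd.Series:
    """Per-SNP ancestry label where the copying probability strictly
    exceeds ``threshold``; otherwise "undecided" (ties included)."""
    best = prob_table.idxmax(axis=1)
    best_p = prob_table.max(axis=1)
    return pd.Series(
        np.where(best_p > threshold, best, UNDECIDED),
        index=prob_table.index,
        name="ancestry",
    )


def region_ancestry_test(
    prob: np.ndarray,
    pos_bp: np.ndarray,
    region: tuple[int, int],
    chrom_length_bp: int | None = None,
) -> tuple[float, float, float]:
    """Regional copying-probability tail test for one donor ancestry.

    The observed value is the mean expected copying probability over SNPs
    inside ``region`` (0-based half-open).  The null tiles the chromosome
    with non-overlapping regions of the same width; the empirical p-value
    is the fraction of regions (the queried one included) whose aggregate
    is at least the observed, and the 5% tail threshold of the null
    distribution is reported alongside.
    """
    start, end = region
    width = end - start
    if width <= 0:
        raise ValueError("empty region")
    pos0 = np.asarray(pos_bp) - 1  # physical positions, 0-based
    inside = (pos0 >= start) & (pos0 < end)
    if not inside.any():
        raise ValueError("no SNPs in region")
    observed = float(np.mean(prob[inside]))
    length = chrom_length_bp or int(pos0.max()) + 1
    tiles = []
    for lo in range(0, length, width):
        sel = (pos0 >= lo) & (pos0 < lo + width)
        if sel.any() and not (lo == start):
            tiles.append(float(np.mean(prob[sel])))
    aggregates = np.asarray(tiles + [observed])
    p = float(np.mean(aggregates >= observed))
    tail = float(np.quantile(aggregates, 0.95))
    return observed, p, tail
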
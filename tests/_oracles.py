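"""Independent oracle implementations used only by the tests.

These deliberately take different computational routes from the package
(nested ANOVA sums of squares instead of direct variance components,
exhaustive hidden-path enumeration instead of forward–backward, explicit
hypergeometric tail sums instead of scipy's survival function) so that
agreement is evidence of correctness rather than shared code.
"""

from __future__ import annotations

from itertools import product
from math import comb

import numpy as np


def wc_theta_anova(genotypes_a, genotypes_b) -> float:
    """Weir–Cockerham θ̂ via a nested random-effects ANOVA on allele
    indicators (alleles within individuals within populations)."""
    pops = [np.asarray(genotypes_a, float), np.asarray(genotypes_b, float)]
    r = 2
    n = [len(g) for g in pops]
    N = sum(n)
    ybar_pop = [g.mean() / 2 for g in pops]
    ybar_all = sum(g.sum() for g in pops) / (2 * N)
    ss_within_ind = sum(((g == 1) * 0.5).sum() for g in pops)
    ss_ind = 2 * sum(((g / 2 - yb) ** 2).sum() for g, yb in zip(pops, ybar_pop))
    ss_pop = 2 * sum(ni * (yb - ybar_all) ** 2 for ni, yb in zip(n, ybar_pop))
    msp = ss_pop / (r - 1)
    msi = ss_ind / (N - r)
    msg = ss_within_ind / N
    nc = (N - sum(ni**2 for ni in n) / N) / (r - 1)
    s2_g = msg
    s2_i = (msi - msg) / 2
    s2_p = (msp - msi) / (2 * nc)
    total = s2_p + s2_i + s2_g
    return s2_p / total if total != 0 else float("nan")


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N, K, n) by explicit summation."""
    denom = comb(N, n)
    total = 0
    for x in range(max(k, 0), min(K, n) + 1):
        total += comb(K, x) * comb(N - K, n - x)
    return total / denom


def copying_posterior_brute_force(
    recipient: np.ndarray,
    donors: np.ndarray,
    gmap_cM: np.ndarray,
    rho: float,
    theta: float,
) -> np.ndarray:
    """Posterior copying probability per SNP per donor haplotype by
    enumerating every hidden donor path."""
    T, nD = donors.shape
    emit = np.where(donors == recipient[:, None], 1 - theta, theta)
    r = 1 - np.exp(-rho * np.diff(np.asarray(gmap_cM, float)))
    post = np.zeros((T, nD))
    total = 0.0
    for path in product(range(nD), repeat=T):
        p = (1 / nD) * emit[0, path[0]]
        for t in range(1, T):
            stay = 1.0 if path[t] == path[t - 1] else 0.0
            p *= ((1 - r[t - 1]) * stay + r[t - 1] / nD) * emit[t, path[t]]
        total += p
        for t in range(T):
            post[t, path[t]] += p
    return post / total


def ehh_by_string_partition(alleles: np.ndarray, carriers: np.ndarray,
                            core: int, step: int) -> float:
    """EHH at ``step`` flanking SNPs right of the core by hashing the
    full allele strings of the carrier haplotypes."""
    n = len(carriers)
    strings = [
        tuple(alleles[core + 1 : core + 1 + step, h]) for h in carriers
    ]
    counts: dict[tuple, int] = {}
    for s in strings:
        counts[s] = counts.get(s, 0) + 1
    num = sum(c * (c - 1) // 2 for c in counts.values())
    return num / (n * (n - 1) // 2)
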
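"""Window-count GO enrichment with the EASE score.

Counting windows instead of genes corrects for positional clustering:
a run of adjacent genes sharing a term contributes one window, not many
genes, so a single swept region cannot by itself make its terms look
enriched.  The EASE score is a conservative one-tailed Fisher exact test
computed after removing one item from the overlap (k → k−1 with margins
held fixed); a term with a single supporting window can never be called.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def annotate_windows(
    window_genes: dict[tuple, list[str]],
    go_map: dict[str, list[str]],
) -> dict[tuple, list[str]]:
    """Attach GO terms to windows via their genes, deduplicated per window."""
    out: dict[tuple, list[str]] = {}
    for window, genes in window_genes.items():
        terms: list[str] = []
        for g in genes:
            for t in go_map.get(g, []):
                if t not in terms:
                    terms.append(t)
        out[window] = terms
    return out


def ease_score(k: int, K: int, n: int, N: int) -> tuple[float, float]:
    """One-tailed Fisher p and EASE score for a window-count 2×2 table.

    k = top windows with the term, K = all windows with the term, n = top
    windows, N = all windows.  fisher_p = P(X ≥ k) under hypergeometric
    sampling; ease_p replaces k by k−1 with the margins unchanged, so
    ease_p ≥ fisher_p and k ≤ 1 forces ease_p = 1.
    """
    if k > K or k > n or K > N or n > N or min(k, K, n) < 0:
        raise ValueError(f"invalid contingency margins k={k} K={K} n={n} N={N}")
    fisher_p = float(stats.hypergeom.sf(k - 1, N, K, n))
    ease_p = 1.0 if k <= 1 else float(stats.hypergeom.sf(k - 2, N, K, n))
    return min(fisher_p, 1.0), min(ease_p, 1.0)


def enrich(
    top_windows: list[tuple],
    all_windows: list[tuple],
    window_terms: dict[tuple, list[str]],
    alpha: float = 0.01,
    fdr: bool = False,
) -> pd.DataFrame:
    """EASE enrichment of every term annotated to at least one window.

    The universe is the ranked window set for the test at hand.  Rows are
    sorted by ease_p; ``significant`` marks ease_p ≤ alpha.  A Benjamini–
    Hochberg q-value column is added when ``fdr`` is requested (off by
    default: the uncorrected EASE score is the calling criterion).
    """
    top_set = set(top_windows)
    N = len(all_windows)
    n = len(top_set)
    term_K: dict[str, int] = {}
    term_k: dict[str, int] = {}
    for w in all_windows:
        for t in window_terms.get(w, []):
            term_K[t] = term_K.get(t, 0) + 1
            if w in top_set:
                term_k[t] = term_k.get(t, 0) + 1
    rows = []
    for t in sorted(term_K):
        k, K = term_k.get(t, 0), term_K[t]
        fisher_p, ease_p = ease_score(k, K, n, N)
        rows.append(
            {
                "term": t,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "fisher_p": fisher_p,
                "ease_p": ease_p,
            }
        )
    out = pd.DataFrame(
        rows, columns=["term", "k", "K", "n", "N", "fisher_p", "ease_p"]
    )
    if out.empty:
        out["significant"] = pd.Series(dtype=bool)
        return out
    if fdr:
        m = len(out)
        order = np.argsort(out["ease_p"].to_numpy())
        q = np.empty(m)
        ranked = out["ease_p"].to_numpy()[order] * m / (np.arange(m) + 1)
        q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        out["fdr_q"] = np.minimum(q, 1.0)
    out["significant"] = out["ease_p"] <= alpha
    return out.sort_values("ease_p", ignore_index=True)
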
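"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: the HDI oracle is a
plain grid search over the lower-tail probability, the enrichment oracle an
exhaustive enumeration of gene subsets, and the BH oracle the textbook
step-up formula.
"""

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import beta as beta_dist


def hdi_grid(
    a: float, b: float, mass: float, step: float = 1e-5, refine: int = 2
) -> tuple[float, float]:
    """Narrowest Beta(a, b) quantile interval by grid search over p.

    A coarse pass at ``step`` resolution is followed by ``refine`` local
    passes, each 100x finer around the running argmin: in the far tails the
    quantile function's slope (1 / density) amplifies grid error in p, so a
    single coarse pass cannot pin the bounds themselves tightly.
    """
    span_lo, span_hi = 0.0, 1.0 - mass
    best_p = None
    for _ in range(refine + 1):
        ps = np.arange(span_lo, span_hi + step / 2, step)
        ps = ps[(ps >= 0.0) & (ps <= 1.0 - mass)]
        lo = beta_dist.ppf(ps, a, b)
        hi = beta_dist.ppf(ps + mass, a, b)
        best_p = float(ps[int(np.argmin(hi - lo))])
        span_lo, span_hi = best_p - step, best_p + step
        step /= 100.0
    return float(beta_dist.ppf(best_p, a, b)), float(beta_dist.ppf(best_p + mass, a, b))


def hypergeom_enumerate(background: list[str], term_genes: set[str], selected: set[str]) -> float:
    """P(at least the observed overlap) by enumerating all selected-size subsets."""
    n_sel = len(selected)
    k_obs = len(selected & term_genes)
    hits = total = 0
    for subset in combinations(background, n_sel):
        total += 1
        if len(set(subset) & term_genes) >= k_obs:
            hits += 1
    return hits / total


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, textbook formula."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
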
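"""Independent brute-force oracles used to validate the statistical routes.

These deliberately avoid scipy/statsmodels so they can serve as independent
cross-checks: exact rational hypergeometric enumeration for the two-sided
Fisher test, the literal min-over-tail Benjamini-Hochberg formula, and
exhaustive label enumeration for the permutation burden test.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact enumeration of the hypergeometric support.

    With margins fixed, the table is determined by its top-left cell k; the
    two-sided p sums the probabilities of all k whose likelihood does not
    exceed the observed one (minimum-likelihood two-sidedness).  Exact
    rational arithmetic makes tie comparisons unambiguous.
    """
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, c1)
    if denom == 0:
        return 1.0
    k_min, k_max = max(0, c1 - (n - r1)), min(r1, c1)
    pmf = {k: Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom) for k in range(k_min, k_max + 1)}
    # scipy compares likelihoods in floating point with a small relative
    # slack; mirror that so borderline ties agree
    p_obs = pmf[a] * Fraction(10**12 + 1, 10**12)
    return float(sum(p for p in pmf.values() if p <= p_obs))


def bh_qvalues_oracle(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg q-values by the literal formula q_(i) = min_{j>=i} p_(j)*m/j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q_sorted[rank - 1] = running
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = min(q_sorted[rank], 1.0)
    return out


def permutation_p_exact(double_counts: list[float], single_counts: list[float]) -> float:
    """Exhaustive permutation p: fraction of label assignments whose statistic
    strictly exceeds the observed mean(Double) - mean(Single)."""
    pooled = list(double_counts) + list(single_counts)
    n_d = len(double_counts)
    observed = sum(double_counts) / n_d - sum(single_counts) / len(single_counts)
    n_exceed = total = 0
    for idx in combinations(range(len(pooled)), n_d):
        chosen = set(idx)
        dbl = [pooled[i] for i in idx]
        sgl = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        stat = sum(dbl) / len(dbl) - sum(sgl) / len(sgl)
        total += 1
        if stat > observed + 1e-12:
            n_exceed += 1
    return n_exceed / total
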
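"""Independent brute-force oracles used to validate the statistical core.

These deliberately avoid the code paths they check: the Fisher oracle sums
hypergeometric point probabilities over an explicit table enumeration, the
permutation oracle shuffles allele labels directly, and the burden oracle
convolves per-locus genotype distributions.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom

#: Relative slack when comparing point probabilities for "as or more
#: extreme", matching the conventional guard against floating-point ties.
_REL_TIE = 1 + 1e-7


def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration of tables with fixed margins."""
    n1, k, n = a + b, a + c, a + b + c + d
    xs = np.arange(max(0, k - (n - n1)), min(k, n1) + 1)
    pmf = hypergeom.pmf(xs, n, k, n1)
    p_obs = hypergeom.pmf(a, n, k, n1)
    return float(pmf[pmf <= p_obs * _REL_TIE].sum())


def chi2_stat_2x2(a, b, c, d):
    """Pearson chi-square statistic for 2x2 tables, vectorised over cells."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return np.where(den > 0, num / den, 0.0)


def permutation_chi2_pvalues(
    a: int, b: int, c: int, d: int, n_shuffles: int, rng: np.random.Generator
) -> tuple[float, float, float]:
    """Label-shuffle permutation null of the chi-square statistic.

    Returns (p_ge, p_mid, mc_se): the conventional permutation p
    (fraction of shuffles with a statistic >= observed), the mid-p variant
    (ties counted half), and the Monte-Carlo standard error of p_mid.
    Shuffling allele labels conditions on both margins, so the permuted
    risk-in-group-1 count is hypergeometric.
    """
    n1, k, n = a + b, a + c, a + b + c + d
    obs = chi2_stat_2x2(a, b, c, d)
    x = rng.hypergeometric(k, n - k, n1, size=n_shuffles)
    stat = chi2_stat_2x2(x, n1 - x, k - x, (n - n1) - (k - x))
    greater = (stat > obs + 1e-9).mean()
    ties = (np.abs(stat - obs) <= 1e-9).mean()
    p_mid = greater + 0.5 * ties
    mc_se = float(np.sqrt(max(p_mid * (1 - p_mid), 1e-12) / n_shuffles))
    return float(greater + ties), float(p_mid), mc_se


def iter_tables(n_max: int, n_min: int = 1):
    """All 2x2 tables (a, b, c, d) with positive margins and total <= n_max,
    reduced by row-swap and column-swap symmetry (Fisher p and chi-square
    are invariant under both)."""
    for n in range(n_min, n_max + 1):
        for n1 in range(1, n // 2 + 1):  # n1 <= n2
            n2 = n - n1
            for k in range(1, n // 2 + 1):  # k <= n - k
                for a in range(max(0, k - n2), min(k, n1) + 1):
                    yield a, n1 - a, k - a, n2 - (k - a)


def hwe_burden_pmf(afs) -> np.ndarray:
    """Distribution of the risk-allele burden over independent HWE loci:
    the convolution of per-locus genotype distributions."""
    dist = np.array([1.0])
    for p in afs:
        locus = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        dist = np.convolve(dist, locus)
    return dist
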
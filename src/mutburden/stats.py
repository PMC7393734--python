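"""Closed-form enrichment statistics.

The burden test asks: given a cohort of ``N`` samples and a feature of
testable length ``L`` nucleotides with per-nucleotide, per-sample background
mutation probability ``p``, how surprising is the observed recurrence?

Two test families are provided:

* **binomial** -- counts *samples*. The chance that one sample carries at
  least one mutation in the feature is ``p_n = 1 - (1 - p)**L``; the p-value
  is the upper binomial tail ``P(Bin(N, p_n) >= n)`` for ``n`` mutated
  samples.
* **negative binomial** -- counts *mutations*. With ``x = L * N`` total
  nucleotide trials across the cohort, observing ``k`` mutations is referred
  to the negative-binomial tail ``sum_{r=0}^{x-k} C(k+r-1, r) p^k (1-p)^r``
  (equivalently the upper binomial tail ``P(Bin(x, p) >= k)``).

Per-feature burden and hotspot p-values are combined with Fisher's method and
corrected across features with Benjamini-Hochberg.

All tails are evaluated through scipy survival/distribution functions, which
are numerically stable for the tiny rates typical of somatic data (1e-6 per
nucleotide per sample); naive term-by-term summation is reserved for test
oracles.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats as _scipy_stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "per_feature_success_prob",
    "binomial_burden_pvalue",
    "negbin_pvalue",
    "fisher_combine",
    "bh_fdr",
]

#: p-values below this enter Fisher's method at the floor instead of 0
DEFAULT_PVALUE_FLOOR = 1e-300


def _check_prob(value: float, name: str) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return value


def per_feature_success_prob(per_nt_rate: float, feature_length: int) -> float:
    """Probability that a sample acquires >= 1 mutation in a feature.

    ``p_n = 1 - (1 - p)**L`` for per-nucleotide rate ``p`` and feature length
    ``L``, evaluated as ``-expm1(L * log1p(-p))`` so that tiny rates over
    megabase lengths do not lose precision.
    """
    p = _check_prob(per_nt_rate, "per_nt_rate")
    L = int(feature_length)
    if L < 1:
        raise ValueError(f"feature_length must be >= 1, got {feature_length!r}")
    if p == 1.0:
        return 1.0
    return -math.expm1(L * math.log1p(-p))


def binomial_burden_pvalue(n_mutated_samples: int, cohort_size: int, p_n: float) -> float:
    """Upper binomial tail ``P(Bin(N, p_n) >= n)``.

    ``n = 0`` returns exactly 1: absence of evidence must never look
    significant.
    """
    n = int(n_mutated_samples)
    N = int(cohort_size)
    p_n = _check_prob(p_n, "p_n")
    if n < 0:
        raise ValueError(f"n_mutated_samples must be >= 0, got {n}")
    if N < 1:
        raise ValueError(f"cohort_size must be >= 1, got {N}")
    if n > N:
        raise ValueError(f"n_mutated_samples ({n}) exceeds cohort_size ({N})")
    if n == 0:
        return 1.0
    return float(_scipy_stats.binom.sf(n - 1, N, p_n))


def negbin_pvalue(
    total_mutations: int,
    feature_length: int,
    cohort_size: int,
    per_nt_rate: float,
) -> float:
    """Negative-binomial tail for observing ``k`` mutations in ``x = L*N`` trials.

    ``sum_{r=0}^{x-k} C(k+r-1, r) p^k (1-p)^r`` -- the probability that the
    k-th success (mutation) arrives within the available nucleotide trials.
    Identical to the upper binomial tail ``P(Bin(x, p) >= k)``. ``k = 0``
    returns exactly 1.
    """
    k = int(total_mutations)
    L = int(feature_length)
    N = int(cohort_size)
    p = _check_prob(per_nt_rate, "per_nt_rate")
    if k < 0:
        raise ValueError(f"total_mutations must be >= 0, got {k}")
    if L < 1 or N < 1:
        raise ValueError("feature_length and cohort_size must be >= 1")
    x = L * N
    if k > x:
        raise ValueError(
            f"total_mutations ({k}) exceeds nucleotide trials x = L*N ({x})"
        )
    if k == 0:
        return 1.0
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    return float(_scipy_stats.nbinom.cdf(x - k, k, p))


def fisher_combine(
    p_values: Sequence[float], floor: float = DEFAULT_PVALUE_FLOOR
) -> float:
    """Fisher's method: ``X = -2 sum(ln p_i)`` on chi-square with ``2m`` df.

    Components below ``floor`` (including exact zeros, where the log is
    undefined) are clamped to ``floor`` before taking logs; negative values or
    values above 1 are rejected.
    """
    if len(p_values) == 0:
        raise ValueError("fisher_combine requires at least one p-value")
    if not (0.0 < floor <= 1.0):
        raise ValueError(f"floor must lie in (0, 1], got {floor!r}")
    clamped = []
    for p in p_values:
        p = float(p)
        if math.isnan(p) or p < 0.0 or p > 1.0:
            raise ValueError(f"p-values must lie in [0, 1], got {p!r}")
        clamped.append(max(p, floor))
    statistic = -2.0 * sum(math.log(p) for p in clamped)
    return float(_scipy_stats.chi2.sf(statistic, 2 * len(clamped)))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    arr = np.asarray(list(p_values), dtype=float)
    if arr.size == 0:
        return []
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    qvals = multipletests(arr, method="fdr_bh")[1]
    return [float(q) for q in qvals]
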
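"""Per-model asymptotic Cochran-Armitage trend tests and multiplicity baselines.

Under the null hypothesis of no association the unnormalized trend
statistic W has mean 0 and variance

    Var(W) = (R_X R_Y / N) * (N * sum_i t_i^2 C_i - (sum_i t_i C_i)^2),

so z = W / sqrt(Var(W)) is asymptotically standard normal and the reported
p-value is the two-sided normal tail.  z^2 equals the usual chi-square(1)
form of the CA trend statistic.

Two baseline procedures for testing one SNP under all three genetic
models are provided for comparison:

* ``min_p`` — the smallest of the three per-model p-values, reported
  without correction.  This is NOT a valid test (the three statistics are
  functionally dependent and min-p inflates the type 1 error); it is kept
  purely as a comparator.
* ``bonferroni_p`` — min(1, 3 * min_p), the Bonferroni adjustment for the
  three models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .tables import MODELS, GenotypeTable, TrendWeights, trend_statistic


@dataclass(frozen=True)
class TrendResult:
    """Asymptotic CA trend test result for one genetic model."""

    model: str
    statistic: int
    variance: float
    z_score: float
    p_value: float
    degenerate: bool = False


def ca_trend_test(table: GenotypeTable, weights: TrendWeights | str) -> TrendResult:
    """Two-sided asymptotic CA trend test for one genetic model.

    A monomorphic weighting (all weighted mass in one column) has null
    variance 0; such degenerate tables yield p = 1 with ``degenerate=True``
    rather than an exception.
    """
    if isinstance(weights, str):
        weights = TrendWeights(weights)
    w = trend_statistic(table, weights)
    t = weights.weights
    c = table.columns
    n = table.n
    rx, ry = table.r_x, table.r_y
    st = sum(t[i] * c[i] for i in range(3))
    st2 = sum(t[i] * t[i] * c[i] for i in range(3))
    var = (rx * ry / n) * (n * st2 - st * st)
    if var <= 0:
        return TrendResult(
            model=weights.model,
            statistic=w,
            variance=0.0,
            z_score=0.0,
            p_value=1.0,
            degenerate=True,
        )
    z = w / math.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return TrendResult(
        model=weights.model, statistic=w, variance=var, z_score=z, p_value=min(p, 1.0)
    )


def all_trend_tests(table: GenotypeTable) -> dict[str, TrendResult]:
    """CA trend tests for the additive, dominant, and recessive models."""
    return {m: ca_trend_test(table, m) for m in MODELS}


def min_p(table: GenotypeTable) -> float:
    """Smallest of the three per-model asymptotic p-values (no correction)."""
    return min(r.p_value for r in all_trend_tests(table).values())


def bonferroni_p(table: GenotypeTable) -> float:
    """Bonferroni-adjusted p-value for the three genetic models: min(1, 3 min-p)."""
    return min(1.0, 3.0 * min_p(table))
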
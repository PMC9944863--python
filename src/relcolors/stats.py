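"""Summary statistics for quantization experiments.

BCa bootstrap confidence limits (the interval convention used for every
table-style summary here), the Kruskal-Wallis rank test for comparing
groups of efficiencies or cluster counts, and the ordinary least-squares
regression of mutual information on log2 n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "BootstrapInterval",
    "RegressionResult",
    "bca_bootstrap",
    "kruskal_wallis",
    "regression_mi_vs_logn",
]


@dataclass
class BootstrapInterval:
    low: float
    high: float
    estimate: float
    method: str = "BCa"  # falls back to "percentile" on degenerate input

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("interval bounds out of order")

    def covers(self, value: float) -> bool:
        return self.low <= value <= self.high


def bca_bootstrap(
    values: np.ndarray,
    statistic=np.mean,
    replicates: int = 1000,
    seed: int = 0,
    confidence_level: float = 0.95,
) -> BootstrapInterval:
    """Bias-corrected accelerated bootstrap interval for a 1-sample statistic.

    The bias correction comes from the fraction of the bootstrap
    distribution below the point estimate and the acceleration from the
    jackknife skewness (scipy's BCa implementation).  A degenerate
    bootstrap distribution (e.g. constant data) falls back to the
    percentile interval, flagged in ``method``.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least 2 values to bootstrap")
    if replicates < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    estimate = float(statistic(values))
    rng = np.random.default_rng(seed)
    if np.ptp(values) == 0:  # constant data: zero-width interval
        return BootstrapInterval(estimate, estimate, estimate, method="degenerate")
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sps.bootstrap(
                (values,),
                statistic,
                n_resamples=replicates,
                confidence_level=confidence_level,
                method="BCa",
                vectorized=False,
                rng=rng,
            )
        low, high = float(res.confidence_interval.low), float(res.confidence_interval.high)
        if not (np.isfinite(low) and np.isfinite(high)):
            raise ValueError("degenerate BCa interval")
        return BootstrapInterval(low, high, estimate, method="BCa")
    except Exception:
        boots = np.array(
            [
                statistic(values[rng.integers(0, len(values), len(values))])
                for _ in range(replicates)
            ]
        )
        alpha = (1.0 - confidence_level) / 2.0
        low, high = np.quantile(boots, [alpha, 1.0 - alpha])
        return BootstrapInterval(float(low), float(high), estimate, method="percentile")


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H statistic and chi-squared p-value with tie correction.

    When every value in every group is identical the test is undefined;
    the convention here is H = 0, p = 1.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    allvals = np.concatenate([np.asarray(g, dtype=np.float64) for g in groups])
    if np.ptp(allvals) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    slope_interval: BootstrapInterval


def regression_mi_vs_logn(
    I_values: np.ndarray,
    n_values: np.ndarray,
    replicates: int = 1000,
    seed: int = 0,
) -> RegressionResult:
    """OLS fit of mutual information on log2 n, slope CI by BCa over rows."""
    I_values = np.asarray(I_values, dtype=np.float64)
    n_values = np.asarray(n_values, dtype=np.float64)
    if len(np.unique(n_values)) < 3:
        raise ValueError("need at least 3 distinct n values to regress")
    x = np.log2(n_values)

    def slope_of(idx: np.ndarray) -> float:
        xi, yi = x[idx], I_values[idx]
        xm, ym = xi.mean(), yi.mean()
        denom = ((xi - xm) ** 2).sum()
        if denom == 0:
            return np.nan
        return float(((xi - xm) * (yi - ym)).sum() / denom)

    all_idx = np.arange(len(x))
    slope = slope_of(all_idx)
    intercept = float(I_values.mean() - slope * x.mean())

    rng = np.random.default_rng(seed)
    try:
        res = sps.bootstrap(
            (all_idx,),
            slope_of,
            n_resamples=replicates,
            method="BCa",
            vectorized=False,
            rng=rng,
        )
        interval = BootstrapInterval(
            float(res.confidence_interval.low),
            float(res.confidence_interval.high),
            slope,
            method="BCa",
        )
    except Exception:
        boots = np.array(
            [
                slope_of(rng.integers(0, len(x), len(x)))
                for _ in range(replicates)
            ]
        )
        boots = boots[np.isfinite(boots)]
        low, high = np.quantile(boots, [0.025, 0.975])
        interval = BootstrapInterval(float(low), float(high), slope, method="percentile")
    return RegressionResult(slope=slope, intercept=intercept, slope_interval=interval)
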
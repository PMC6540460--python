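"""Per-subject confidence limits via the parametric bootstrap of the mean.

Given a subject's n BP estimates (one per measurement, typically n = 5),
the procedure fits N(μ̂, σ̂²), draws an n × N Gaussian matrix, takes the
N column means, sorts them ascending, and reads off the percentile
interval: the ⌈αN⌉-th and ⌈(1−α)N⌉-th order statistics (1-based).  With
α = 0.025 this is the nominal 95% interval; its half-width approaches
1.96·σ̂/√n as N grows.

SBP and DBP use independent random streams, so the two intervals are
reproducible independently of each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bootstrap import artificial_sample, gaussian_fit
from .errors import InsufficientDataError, ValidationError

__all__ = [
    "SubjectEstimates",
    "BootstrapMeans",
    "ConfidenceLimits",
    "bootstrap_means",
    "percentile_interval",
    "percentile_interval_values",
    "estimate_cl",
    "cl_report",
]


@dataclass
class SubjectEstimates:
    """One subject's per-measurement SBP and DBP estimates (mmHg)."""

    subject_id: str
    sbp_estimates: np.ndarray
    dbp_estimates: np.ndarray

    def __post_init__(self) -> None:
        self.sbp_estimates = np.asarray(self.sbp_estimates, dtype=float)
        self.dbp_estimates = np.asarray(self.dbp_estimates, dtype=float)
        for name, arr in (("sbp", self.sbp_estimates), ("dbp", self.dbp_estimates)):
            if arr.ndim != 1 or not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name}_estimates must be a finite 1-d vector")


@dataclass
class BootstrapMeans:
    """N replicated sample means of one subject's estimates.

    ``means`` holds the column means in generation order (needed for the
    rank-independence test between the SBP and DBP streams);
    ``sorted_means`` is the same multiset sorted ascending.
    """

    means: np.ndarray
    sorted_means: np.ndarray
    mu_hat: float
    sigma_hat: float
    N: int
    seed: int


@dataclass
class ConfidenceLimits:
    """Percentile confidence limits for one subject, with the underlying
    bootstrap-mean vectors retained for the normality suite."""

    subject_id: str
    alpha: float
    sbp_lower: float
    sbp_upper: float
    dbp_lower: float
    dbp_upper: float
    sbp_means: BootstrapMeans | None = None
    dbp_means: BootstrapMeans | None = None


def bootstrap_means(
    estimates: Sequence[float],
    N: int,
    seed: int | np.random.SeedSequence,
    n_inner: int | None = None,
) -> BootstrapMeans:
    """Replicate the sample mean of ``estimates`` N times.

    Fits N(μ̂, σ̂²) to the estimates, draws an n × N matrix
    μ̂ + σ̂·Z, and takes column means.  ``n_inner`` defaults to the
    number of estimates n.
    """
    if N < 2:
        raise InsufficientDataError("need N >= 2 bootstrap replications")
    fit = gaussian_fit(estimates)
    n = n_inner if n_inner is not None else fit.n
    art = artificial_sample(fit, n, N, seed)
    seed_repr = seed if isinstance(seed, int) else -1
    return BootstrapMeans(
        means=art.values,
        sorted_means=np.sort(art.values),
        mu_hat=fit.mean,
        sigma_hat=fit.sd,
        N=N,
        seed=seed_repr,
    )


def percentile_interval_values(
    sorted_values: np.ndarray, alpha: float
) -> tuple[float, float]:
    """Percentile interval from an ascending-sorted vector.

    Order-statistic convention: lower at index ⌈αN⌉, upper at ⌈(1−α)N⌉,
    both 1-based.
    """
    if not 0 < alpha < 0.5:
        raise ValidationError(f"alpha must be in (0, 0.5), got {alpha}")
    N = len(sorted_values)
    lo_idx = max(math.ceil(alpha * N), 1)
    hi_idx = min(math.ceil((1 - alpha) * N), N)
    return float(sorted_values[lo_idx - 1]), float(sorted_values[hi_idx - 1])


def percentile_interval(bm: BootstrapMeans, alpha: float = 0.025) -> tuple[float, float]:
    """Percentile confidence interval of the replicated means."""
    return percentile_interval_values(bm.sorted_means, alpha)


def estimate_cl(
    est: SubjectEstimates,
    N: int = 1000,
    alpha: float = 0.025,
    seed: int = 0,
) -> ConfidenceLimits:
    """Confidence limits for one subject's SBP and DBP.

    Runs the bootstrap-mean replication and the percentile rule on
    independent streams for the two pressures: permuting or editing the
    DBP estimates leaves the SBP limits bit-identical.
    """
    sbp_bm = bootstrap_means(est.sbp_estimates, N, np.random.SeedSequence([int(seed), 0]))
    dbp_bm = bootstrap_means(est.dbp_estimates, N, np.random.SeedSequence([int(seed), 1]))
    s_lo, s_hi = percentile_interval(sbp_bm, alpha)
    d_lo, d_hi = percentile_interval(dbp_bm, alpha)
    return ConfidenceLimits(
        subject_id=est.subject_id,
        alpha=alpha,
        sbp_lower=s_lo,
        sbp_upper=s_hi,
        dbp_lower=d_lo,
        dbp_upper=d_hi,
        sbp_means=sbp_bm,
        dbp_means=dbp_bm,
    )


def cl_report(cls_list: Sequence[ConfidenceLimits]) -> pd.DataFrame:
    """One row per subject: limits and interval widths for both pressures."""
    rows = []
    for cl in cls_list:
        rows.append(
            {
                "subject_id": cl.subject_id,
                "sbp_lower": cl.sbp_lower,
                "sbp_upper": cl.sbp_upper,
                "sbp_width": cl.sbp_upper - cl.sbp_lower,
                "dbp_lower": cl.dbp_lower,
                "dbp_upper": cl.dbp_upper,
                "dbp_width": cl.dbp_upper - cl.dbp_lower,
            }
        )
    return pd.DataFrame(rows)
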
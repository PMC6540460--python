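"""Normality and independence verification of bootstrap BP distributions.

Three families of checks are provided:

* moment tests — population-moment (non-excess) kurtosis m₄/m₂² and
  skewness m₃/m₂^{3/2}, their large-sample standard errors, and z-scores
  against the Gaussian null (kurtosis 3, skewness 0);
* a one-sample Kolmogorov–Smirnov test with exact finite-sample two-sided
  critical values, by default against a normal whose parameters are
  estimated from the tested sample (evaluated with fully-specified-null
  critical values, which is conservative; a Lilliefors-corrected mode is
  available);
* the Spearman rank independence test, using the asymptotic null moments
  E(r) = 0 and var(r) = 1/(N−1).

`cohort_normality_report` applies all of these to the per-subject
bootstrap-mean vectors produced by the confidence-limit procedure and
averages across subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .climits import ConfidenceLimits
from .errors import (
    DegenerateSampleError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "MomentTestResult",
    "KSResult",
    "RankTestResult",
    "NormalityReport",
    "kurtosis",
    "skewness",
    "se_kurtosis",
    "se_skewness",
    "moment_normality_test",
    "ks_critical_value",
    "ks_test",
    "spearman_independence",
    "cohort_normality_report",
]

logger = logging.getLogger(__name__)

# Above this sample size the exact finite-n KS distribution is replaced by
# the asymptotic Kolmogorov law (indistinguishable there, much cheaper).
_KS_EXACT_MAX_N = 10_000


@dataclass(frozen=True)
class MomentTestResult:
    statistic: float
    se: float
    z: float
    reject: bool


@dataclass(frozen=True)
class KSResult:
    h: int
    p: float
    ks: float
    cv: float
    n: int


@dataclass(frozen=True)
class RankTestResult:
    r: float
    z: float
    reject: bool


@dataclass
class NormalityReport:
    """Per-subject statistics and their cohort summary."""

    per_subject: pd.DataFrame
    summary: pd.DataFrame
    n_excluded: int


def _checked(x: Sequence[float], min_n: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("sample must be one-dimensional")
    if len(arr) < min_n:
        raise InsufficientDataError(f"need at least {min_n} values, got {len(arr)}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("sample contains non-finite values")
    return arr


def kurtosis(x: Sequence[float]) -> float:
    """Population-moment kurtosis m₄/m₂² (3 for a Gaussian).

    Central moments use the 1/n denominator, equivalent to the raw-moment
    expansion (E X⁴ − 4μE X³ + 6μ²σ² + 3μ⁴)/σ⁴ with the population
    variance.
    """
    arr = _checked(x, 4)
    if arr.std() == 0:
        raise DegenerateSampleError("kurtosis undefined for a zero-variance sample")
    return float(stats.kurtosis(arr, fisher=False, bias=True))


def skewness(x: Sequence[float]) -> float:
    """Population-moment skewness m₃/m₂^{3/2} (0 for a Gaussian)."""
    arr = _checked(x, 3)
    if arr.std() == 0:
        raise DegenerateSampleError("skewness undefined for a zero-variance sample")
    return float(stats.skew(arr, bias=True))


def se_kurtosis(n: int) -> float:
    """Large-sample standard error of the kurtosis under the Gaussian null."""
    if n < 4:
        raise ValidationError(f"se_kurtosis requires n >= 4, got {n}")
    n = float(n)
    return float(
        np.sqrt(24 * n * (n - 1) ** 2 / ((n - 2) * (n - 3) * (n + 5) * (n + 3)))
    )


def se_skewness(n: int) -> float:
    """Large-sample standard error of the skewness under the Gaussian null."""
    if n < 3:
        raise ValidationError(f"se_skewness requires n >= 3, got {n}")
    n = float(n)
    return float(np.sqrt(6 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3))))


def moment_normality_test(
    x: Sequence[float], alpha: float = 0.05
) -> tuple[MomentTestResult, MomentTestResult]:
    """Kurtosis and skewness z-tests against the Gaussian null.

    z_kurt = (kurt − 3)/se_kurt and z_skew = skew/se_skew; each rejects
    when |z| exceeds the two-sided normal quantile.  The joint Gaussian
    null (kurt = 3 and skew = 0) is rejected when either rejects.
    """
    arr = _checked(x, 4)
    k = kurtosis(arr)
    s = skewness(arr)
    sek = se_kurtosis(len(arr))
    ses = se_skewness(len(arr))
    zcrit = float(stats.norm.ppf(1 - alpha / 2))
    zk = (k - 3.0) / sek
    zs = (s - 0.0) / ses
    return (
        MomentTestResult(statistic=k, se=sek, z=zk, reject=abs(zk) > zcrit),
        MomentTestResult(statistic=s, se=ses, z=zs, reject=abs(zs) > zcrit),
    )


def ks_critical_value(n: int, alpha: float = 0.05) -> float:
    """Exact two-sided critical value of the one-sample KS statistic.

    Numerical inversion of the finite-sample distribution of D_n; for
    n > 10⁴ the asymptotic Kolmogorov quantile divided by √n is used.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    if n > _KS_EXACT_MAX_N:
        return float(stats.kstwobign.ppf(1 - alpha) / np.sqrt(n))
    return float(stats.kstwo.ppf(1 - alpha, n))


# Asymptotic Lilliefors critical-value coefficients cv ~ coef/sqrt(n)
# (normal null with estimated mean and sd).
_LILLIEFORS_COEF = {0.10: 0.805, 0.05: 0.886, 0.01: 1.031}


def ks_test(
    x: Sequence[float],
    alpha: float = 0.05,
    reference: str | tuple[float, float] = "fitted_normal",
    lilliefors: bool = False,
) -> KSResult:
    """One-sample KS test of normality.

    D is the two-sided sup-distance (both one-sided corrections at the
    jump points).  ``reference`` is either ``"fitted_normal"`` (mean and
    sd estimated from ``x``, the default) or an explicit ``(mu, sd)``
    pair.  By default the decision uses standard fully-specified-null
    critical values and p-values, which is conservative when the
    parameters were fitted from ``x``; ``lilliefors=True`` applies the
    parameter-estimation correction instead (alpha restricted to
    0.10/0.05/0.01 for the critical value).
    """
    arr = _checked(x, 5)
    if reference == "fitted_normal":
        mu, sd = float(arr.mean()), float(arr.std(ddof=1))
    else:
        mu, sd = float(reference[0]), float(reference[1])
    if sd <= 0:
        raise DegenerateSampleError("KS reference sd must be > 0")
    n = len(arr)
    d = float(stats.ks_1samp(arr, stats.norm(mu, sd).cdf).statistic)
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

        _, p = sm_lilliefors(arr, dist="norm", pvalmethod="approx")
        p = float(p)
        try:
            cv = _LILLIEFORS_COEF[round(alpha, 2)] / np.sqrt(n)
        except KeyError:
            raise ValidationError(
                "lilliefors mode supports alpha in {0.10, 0.05, 0.01}"
            ) from None
        h = int(p < alpha)
    else:
        if n > _KS_EXACT_MAX_N:
            p = float(stats.kstwobign.sf(d * np.sqrt(n)))
        else:
            p = float(stats.kstwo.sf(d, n))
        cv = ks_critical_value(n, alpha)
        h = int(d > cv)
    return KSResult(h=h, p=p, ks=d, cv=float(cv), n=n)


def spearman_independence(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> RankTestResult:
    """Spearman rank test of independence between two samples.

    r is the Pearson correlation of mean-tie ranks; under the null of
    independence r has mean 0 and variance 1/(N−1), so z = r·√(N−1).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValidationError(f"length mismatch: {xa.shape} vs {ya.shape}")
    if xa.ndim != 1 or len(xa) < 3:
        raise InsufficientDataError("need two 1-d samples of length >= 3")
    r = float(stats.spearmanr(xa, ya).statistic)
    z = r * np.sqrt(len(xa) - 1)
    zcrit = float(stats.norm.ppf(1 - alpha / 2))
    return RankTestResult(r=r, z=float(z), reject=bool(abs(z) > zcrit))


_SUMMARY_STATS = ("h", "p", "ks", "cv", "kurtosis", "skewness", "corr")


def cohort_normality_report(
    cls_list: Sequence[ConfidenceLimits], alpha: float = 0.05
) -> NormalityReport:
    """Apply the full verification suite to a cohort's bootstrap means.

    For each subject and each pressure stream: kurtosis, skewness, the KS
    normality test (fitted-normal reference), and the Spearman correlation
    between the subject's SBP and DBP bootstrap means in generation order.
    Subjects whose bootstrap distribution is degenerate (σ̂ = 0) are
    excluded with a logged count.  The summary holds the across-subject
    mean and sd of every statistic (one row per pressure), plus both the
    empirical across-subject variance of r and the theoretical 1/(N−1).
    """
    rows = []
    n_excluded = 0
    for cl in cls_list:
        if cl.sbp_means is None or cl.dbp_means is None:
            raise ValidationError(
                f"subject {cl.subject_id}: bootstrap means not retained"
            )
        if cl.sbp_means.sigma_hat == 0 or cl.dbp_means.sigma_hat == 0:
            n_excluded += 1
            continue
        corr = spearman_independence(cl.sbp_means.means, cl.dbp_means.means, alpha)
        for stream, bm in (("SBP", cl.sbp_means), ("DBP", cl.dbp_means)):
            ksr = ks_test(bm.means, alpha)
            rows.append(
                {
                    "subject_id": cl.subject_id,
                    "stream": stream,
                    "h": ksr.h,
                    "p": ksr.p,
                    "ks": ksr.ks,
                    "cv": ksr.cv,
                    "kurtosis": kurtosis(bm.means),
                    "skewness": skewness(bm.means),
                    "corr": corr.r,
                    "N": bm.N,
                }
            )
    if n_excluded:
        logger.warning(
            "normality report: excluded %d degenerate subject(s) (sigma_hat = 0)",
            n_excluded,
        )
    per_subject = pd.DataFrame(rows)
    if per_subject.empty:
        raise ValidationError("no non-degenerate subjects in cohort")
    summary_rows = {}
    for stream, grp in per_subject.groupby("stream"):
        row = {}
        for stat in _SUMMARY_STATS:
            row[stat] = float(grp[stat].mean())
            row[f"{stat}_std"] = float(grp[stat].std(ddof=1)) if len(grp) > 1 else 0.0
        n_boot = int(grp["N"].iloc[0])
        row["corr_var_empirical"] = (
            float(grp["corr"].var(ddof=1)) if len(grp) > 1 else 0.0
        )
        row["corr_var_theoretical"] = 1.0 / (n_boot - 1)
        row["n_subjects"] = int(len(grp))
        row["n_excluded"] = n_excluded
        summary_rows[stream] = row
    summary = pd.DataFrame.from_dict(summary_rows, orient="index").loc[["SBP", "DBP"]]
    return NormalityReport(
        per_subject=per_subject, summary=summary, n_excluded=n_excluded
    )
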
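"""Parametric-bootstrap augmentation of small per-subject samples.

With only n = 5 measurements per subject, each scalar quantity (a feature,
or a blood-pressure reading) is modelled as Gaussian with the sample mean
θ̂ and sample standard deviation σ̂ (n−1 denominator).  Artificial
replicates are then drawn from N(θ̂, σ̂²): either raw draws (for feature
augmentation feeding the regression model) or means of ``n_inner`` draws
(the replicated sample-mean statistic used for confidence limits).

Diagnostics: the bootstrap bias β = mean(θ*) − θ̂ and the bootstrap
standard error Se* = sd(θ*, n−1 denominator), plus a convergence check of
the replicated distribution against its Gaussian limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import FEATURE_NAMES, MeasurementRecord
from .errors import InsufficientDataError, ValidationError

__all__ = [
    "GaussianFit",
    "ArtificialSample",
    "gaussian_fit",
    "artificial_sample",
    "bootstrap_bias",
    "bootstrap_se",
    "convergence_check",
    "augment_records",
    "diagnostics_table",
]


@dataclass(frozen=True)
class GaussianFit:
    """Fitted normal N(mean, sd²) of one small sample (sd uses n−1)."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("GaussianFit.sd must be >= 0")
        if self.n < 2:
            raise InsufficientDataError("GaussianFit.n must be >= 2")


@dataclass(frozen=True)
class ArtificialSample:
    """N bootstrap replicate values of one scalar quantity.

    Each value is the mean of ``n_inner`` independent N(mean, sd²) draws;
    ``n_inner=1`` gives raw parametric draws.  Reproducible from
    (source, n_inner, N, seed).
    """

    values: np.ndarray
    source: GaussianFit
    n_inner: int
    seed: int

    @property
    def N(self) -> int:
        return len(self.values)


def gaussian_fit(sample: Sequence[float]) -> GaussianFit:
    """Fit N(θ̂, σ̂²) to a sample; σ̂ uses the n−1 denominator."""
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1:
        raise ValidationError("sample must be one-dimensional")
    if len(x) < 2:
        raise InsufficientDataError(f"need at least 2 values, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise ValidationError("sample contains non-finite values")
    return GaussianFit(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=len(x))


def artificial_sample(
    fit: GaussianFit, n_inner: int, N: int, seed: int | np.random.SeedSequence
) -> ArtificialSample:
    """Draw N artificial values, each the mean of ``n_inner`` parametric draws."""
    if N < 1:
        raise ValidationError("N must be >= 1")
    if n_inner < 1:
        raise ValidationError("n_inner must be >= 1")
    rng = np.random.default_rng(seed)
    draws = fit.mean + fit.sd * rng.standard_normal((n_inner, N))
    values = draws.mean(axis=0)
    seed_repr = seed if isinstance(seed, int) else -1
    return ArtificialSample(values=values, source=fit, n_inner=n_inner, seed=seed_repr)


def bootstrap_bias(art: ArtificialSample) -> float:
    """Bootstrap bias β = mean of the replicates minus the fitted mean."""
    return float(art.values.mean() - art.source.mean)


def bootstrap_se(art: ArtificialSample) -> float:
    """Bootstrap standard error: sd of the replicates (n−1 denominator)."""
    if art.N < 2:
        raise InsufficientDataError("need N >= 2 replicates for a standard error")
    return float(art.values.std(ddof=1))


def convergence_check(
    fit: GaussianFit,
    n_inner: int,
    N_grid: Sequence[int],
    seed: int,
) -> pd.DataFrame:
    """Sup-norm distance of the replicated statistic from its Gaussian limit.

    For each N in ``N_grid``, draws an artificial sample and computes the
    Kolmogorov–Smirnov sup-distance between the empirical distribution of
    √n_inner·(θ* − θ̂) and N(0, σ̂²).  Distances trend to zero like
    1/√N.  A degenerate fit (σ̂ = 0) is compared against its point-mass
    limit and yields distance 0 at every N.
    """
    grid = [int(N) for N in N_grid]
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValidationError("N_grid must be strictly increasing")
    children = np.random.SeedSequence([int(seed)]).spawn(len(grid))
    rows = []
    for N, child in zip(grid, children):
        art = artificial_sample(fit, n_inner, N, child)
        if fit.sd == 0:
            dist = 0.0
        else:
            z = np.sqrt(n_inner) * (art.values - fit.mean)
            dist = float(stats.ks_1samp(z, stats.norm(0.0, fit.sd).cdf).statistic)
        rows.append({"N": N, "ks_distance": dist})
    return pd.DataFrame(rows)


def _column_values(records: Sequence[MeasurementRecord]) -> dict[str, np.ndarray]:
    """Per-column samples (references + features) of one subject's records."""
    n_feat = len(records[0].features)
    names = list(FEATURE_NAMES[:n_feat])
    if n_feat > len(FEATURE_NAMES):
        names += [f"F{i + 1}" for i in range(len(FEATURE_NAMES), n_feat)]
    cols = {
        "TSBP": np.array([r.ref_sbp for r in records], dtype=float),
        "TDBP": np.array([r.ref_dbp for r in records], dtype=float),
    }
    feats = np.array([r.features for r in records], dtype=float)
    for j, name in enumerate(names):
        cols[name] = feats[:, j]
    return cols


def augment_records(
    records: Sequence[MeasurementRecord],
    N: int = 100,
    n_inner: int = 1,
    seed: int = 0,
) -> list[MeasurementRecord]:
    """Parametric-bootstrap augmentation of a cohort.

    Per subject, each feature and each reference pressure is fitted with a
    Gaussian over that subject's measurements and replaced by N artificial
    replicates (raw draws by default, ``n_inner > 1`` for replicated
    means).  Returns N pseudo-measurements per subject.  Streams are
    derived per (subject, column) from the root seed, so the output is
    independent of subject ordering.
    """
    from .cohort import subject_order

    if N < 1:
        raise ValidationError("N must be >= 1")
    order = subject_order(records)
    by_subject = {sid: [r for r in records if r.subject_id == sid] for sid in order}
    out: list[MeasurementRecord] = []
    for si, sid in enumerate(order):
        recs = by_subject[sid]
        cols = _column_values(recs)
        art_cols = {}
        for ci, (name, values) in enumerate(cols.items()):
            fit = gaussian_fit(values)
            child = np.random.SeedSequence([int(seed), si, ci])
            art_cols[name] = artificial_sample(fit, n_inner, N, child).values
        n_feat = len(recs[0].features)
        feat_names = [n for n in art_cols if n not in ("TSBP", "TDBP")]
        for b in range(N):
            out.append(
                MeasurementRecord(
                    subject_id=sid,
                    meas_idx=b + 1,
                    features=np.array([art_cols[n][b] for n in feat_names]),
                    ref_sbp=float(art_cols["TSBP"][b]),
                    ref_dbp=float(art_cols["TDBP"][b]),
                )
            )
    return out


def diagnostics_table(
    records: Sequence[MeasurementRecord],
    n_inner: int = 5,
    N: int = 100,
    alpha: float = 0.025,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap diagnostics for one subject, one row per column.

    Columns: fitted mean θ̂ and sd σ̂, artificial mean θ̂* and sd, the
    percentile confidence limits of the replicated means, the bootstrap
    bias β, and the two standard errors Se = σ̂ and Se* (bootstrap).
    """
    from .climits import percentile_interval_values

    cols = _column_values(records)
    rows = []
    for ci, (name, values) in enumerate(cols.items()):
        fit = gaussian_fit(values)
        child = np.random.SeedSequence([int(seed), ci])
        art = artificial_sample(fit, n_inner, N, child)
        lo, hi = percentile_interval_values(np.sort(art.values), alpha)
        rows.append(
            {
                "column": name,
                "theta_hat": fit.mean,
                "sd_hat": fit.sd,
                "theta_star": float(art.values.mean()),
                "sd_star": float(art.values.std(ddof=1)) if N > 1 else 0.0,
                "cl_lower": lo,
                "cl_upper": hi,
                "bias": bootstrap_bias(art),
                "se": fit.sd,
                "se_star": bootstrap_se(art) if N > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
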
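"""Synthetic oscillometric cohort generator.

The clinical study shape this package targets — B subjects, n = 5
oscillometric measurements each, an 11-dimensional feature vector per
measurement, and auscultatory reference SBP/DBP — is emulated here with
known ground truth so every downstream stage (bootstrap augmentation, DBN
regression, confidence limits, normality tests) can be exercised and
validated without clinical data.

Generative model, per subject i:

* latent true pressures ``SBP_i ~ N(pop_sbp_mean, pop_sbp_sd²)`` and
  ``DBP_i ~ N(pop_dbp_mean, pop_dbp_sd²)`` (independent);
* per measurement, a physiological fluctuation
  ``N(0, within_subject_sd²)`` is added, and the auscultatory reference is
  the average of two simulated observers each with independent
  ``N(0, observer_noise_sd²)`` reading error;
* features are a fixed linear map of the latent pressures plus i.i.d.
  Gaussian noise, so that they are informative of BP with a few-mmHg
  attainable regression error.

Each subject draws from its own counter-derived random stream, so the
records for subject i do not depend on how many subjects are generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError

__all__ = [
    "FEATURE_NAMES",
    "CohortConfig",
    "MeasurementRecord",
    "generate_cohort",
    "split_cohort",
    "default_feature_loadings",
]

#: Canonical feature names: the envelope-derived quantities named in the
#: oscillometric literature plus three unnamed extras (the feature vector
#: is 11-long while only 8 envelope features carry standard names).
FEATURE_NAMES = (
    "MAP", "AR", "AE", "EL", "MA", "SIG1", "SIG2", "MAPL", "F9", "F10", "F11",
)

# Fixed loading matrix (n_features x 2) on (SBP_true, DBP_true), in
# feature-units per mmHg.  Magnitudes are chosen so that, with the default
# feature_noise_sd of 0.5, ordinary least squares on the 11 features
# recovers the latent pressures with a residual sd of about 3 mmHg.
_DEFAULT_LOADINGS = np.array(
    [
        [0.060, 0.030],
        [0.045, -0.055],
        [-0.050, 0.045],
        [0.035, 0.060],
        [0.055, -0.025],
        [-0.040, 0.050],
        [0.030, 0.065],
        [0.065, -0.035],
        [0.020, 0.055],
        [-0.045, 0.040],
        [0.050, -0.050],
    ]
)

_MAX_REDRAWS = 1000


def default_feature_loadings(n_features: int = 11) -> np.ndarray:
    """Return the default (n_features, 2) loading matrix.

    For ``n_features`` other than 11 the canonical rows are tiled/truncated.
    """
    reps = int(np.ceil(n_features / len(_DEFAULT_LOADINGS)))
    return np.tile(_DEFAULT_LOADINGS, (reps, 1))[:n_features].copy()


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study shape: 85 subjects, 5 measurements each,
    11 features, population SBP ~ (112, 13²) mmHg and DBP ~ (66.5, 9²)
    mmHg, within-subject fluctuation of 3.4 / 3.6 mmHg (SBP / DBP), and a
    reference reading averaged over two observers with 1 mmHg noise each.
    """

    n_subjects: int = 85
    n_measurements: int = 5
    n_features: int = 11
    pop_sbp_mean: float = 112.0
    pop_sbp_sd: float = 13.0
    pop_dbp_mean: float = 66.5
    pop_dbp_sd: float = 9.0
    within_subject_sd_sbp: float = 3.4
    within_subject_sd_dbp: float = 3.6
    observer_noise_sd: float = 1.0
    feature_loadings: np.ndarray | None = None
    feature_noise_sd: float | Sequence[float] = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_loadings is not None:
            self.feature_loadings = np.asarray(self.feature_loadings, dtype=float)

    def loadings(self) -> np.ndarray:
        if self.feature_loadings is None:
            return default_feature_loadings(self.n_features)
        return self.feature_loadings

    def noise_sd_vector(self) -> np.ndarray:
        sd = np.asarray(self.feature_noise_sd, dtype=float)
        if sd.ndim == 0:
            sd = np.full(self.n_features, float(sd))
        return sd

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the offending field."""
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.n_measurements < 2:
            raise ConfigurationError("n_measurements must be >= 2")
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        for name in ("pop_sbp_sd", "pop_dbp_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in (
            "within_subject_sd_sbp",
            "within_subject_sd_dbp",
            "observer_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.pop_sbp_mean <= self.pop_dbp_mean:
            raise ConfigurationError("pop_sbp_mean must exceed pop_dbp_mean")
        L = self.loadings()
        if L.shape != (self.n_features, 2):
            raise ConfigurationError(
                f"feature_loadings must have shape ({self.n_features}, 2), got {L.shape}"
            )
        sd = self.noise_sd_vector()
        if sd.shape != (self.n_features,):
            raise ConfigurationError(
                f"feature_noise_sd must be scalar or length {self.n_features}"
            )
        if np.any(sd < 0):
            raise ConfigurationError("feature_noise_sd must be >= 0")


@dataclass
class MeasurementRecord:
    """One oscillometric measurement with its auscultatory reference."""

    subject_id: str
    meas_idx: int
    features: np.ndarray
    ref_sbp: float
    ref_dbp: float

    def validate(self, n_features: int | None = None) -> None:
        if not (self.ref_sbp > self.ref_dbp > 0):
            raise ValidationError(
                f"subject {self.subject_id} meas {self.meas_idx}: "
                f"need ref_sbp > ref_dbp > 0, got ({self.ref_sbp}, {self.ref_dbp})"
            )
        if n_features is not None and len(self.features) != n_features:
            raise ValidationError(
                f"subject {self.subject_id}: feature vector length "
                f"{len(self.features)} != {n_features}"
            )


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    # Counter-derived stream: independent of cohort size and generation order.
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(subject_index)]))


def generate_cohort(config: CohortConfig) -> list[MeasurementRecord]:
    """Generate ``n_subjects * n_measurements`` measurement records.

    Deterministic given ``config.seed``.  Subject truths and individual
    measurements violating the physiological ordering ``SBP > DBP > 0``
    are redrawn (rare at the defaults, rejection rate ~0.2%); a config
    that cannot satisfy the ordering raises :class:`ConfigurationError`.
    """
    config.validate()
    L = config.loadings()
    noise_sd = config.noise_sd_vector()
    records: list[MeasurementRecord] = []
    for i in range(config.n_subjects):
        rng = _subject_rng(config.seed, i)
        for _ in range(_MAX_REDRAWS):
            true_sbp = config.pop_sbp_mean + config.pop_sbp_sd * rng.standard_normal()
            true_dbp = config.pop_dbp_mean + config.pop_dbp_sd * rng.standard_normal()
            if true_sbp > true_dbp > 0:
                break
        else:
            raise ConfigurationError(
                "could not draw subject truths with SBP > DBP > 0; "
                "check pop_* means and sds"
            )
        subject_id = f"S{i + 1:03d}"
        base = L @ np.array([true_sbp, true_dbp])
        for m in range(config.n_measurements):
            for _ in range(_MAX_REDRAWS):
                ref_sbp = (
                    true_sbp
                    + config.within_subject_sd_sbp * rng.standard_normal()
                    + config.observer_noise_sd * rng.standard_normal(2).mean()
                )
                ref_dbp = (
                    true_dbp
                    + config.within_subject_sd_dbp * rng.standard_normal()
                    + config.observer_noise_sd * rng.standard_normal(2).mean()
                )
                if ref_sbp > ref_dbp > 0:
                    break
            else:
                raise ConfigurationError(
                    "could not draw a measurement with ref_sbp > ref_dbp > 0"
                )
            features = base + noise_sd * rng.standard_normal(config.n_features)
            records.append(
                MeasurementRecord(
                    subject_id=subject_id,
                    meas_idx=m + 1,
                    features=features,
                    ref_sbp=float(ref_sbp),
                    ref_dbp=float(ref_dbp),
                )
            )
    return records


def subject_order(records: Sequence[MeasurementRecord]) -> list[str]:
    """Subject ids in order of first appearance."""
    seen: dict[str, None] = {}
    for r in records:
        seen.setdefault(r.subject_id, None)
    return list(seen)


def split_cohort(
    records: Sequence[MeasurementRecord], n_train_subjects: int
) -> tuple[list[MeasurementRecord], list[MeasurementRecord]]:
    """Subject-disjoint train/test split.

    The first ``n_train_subjects`` subjects (in order of first appearance)
    form the training set; all measurements of a subject fall on the same
    side of the split.
    """
    subjects = subject_order(records)
    if not 0 < n_train_subjects < len(subjects):
        raise ValidationError(
            f"n_train_subjects must be in (0, {len(subjects)}), got {n_train_subjects}"
        )
    train_ids = set(subjects[:n_train_subjects])
    train = [r for r in records if r.subject_id in train_ids]
    test = [r for r in records if r.subject_id not in train_ids]
    return train, test
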
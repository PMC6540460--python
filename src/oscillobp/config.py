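"""Run configuration: nested dataclasses serializable to/from YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort import CohortConfig
from .dbn import TrainConfig
from .errors import ConfigurationError

__all__ = ["BootstrapConfig", "RunConfig"]


@dataclass
class BootstrapConfig:
    """Replication sizes of the two bootstrap stages.

    ``N_features`` pseudo-samples per feature feed the regression model;
    ``N_cl`` replications build each subject's confidence limits with
    tail probability ``alpha``; ``n_inner`` is the inner resample size of
    the replicated mean.  ``mode`` selects raw draws or replicated means
    for feature augmentation.
    """

    N_features: int = 100
    N_cl: int = 1000
    n_inner: int = 5
    alpha: float = 0.025
    mode: str = "raw"

    def validate(self) -> None:
        if self.N_features < 1:
            raise ConfigurationError("N_features must be >= 1")
        if self.N_cl < 2:
            raise ConfigurationError("N_cl must be >= 2")
        if self.n_inner < 1:
            raise ConfigurationError("n_inner must be >= 1")
        if not 0 < self.alpha < 0.5:
            raise ConfigurationError("alpha must be in (0, 0.5)")
        if self.mode not in ("raw", "mean"):
            raise ConfigurationError("mode must be 'raw' or 'mean'")


@dataclass
class RunConfig:
    """Full pipeline configuration."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    n_train_subjects: int = 60
    seed: int = 0
    output_dir: str = "outputs"
    log_level: str = "INFO"

    def validate(self) -> None:
        self.cohort.validate()
        self.train.validate()
        self.bootstrap.validate()
        if not 0 < self.n_train_subjects < self.cohort.n_subjects:
            raise ConfigurationError(
                "n_train_subjects must be in (0, n_subjects)"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        loadings = d["cohort"]["feature_loadings"]
        if loadings is not None:
            d["cohort"]["feature_loadings"] = np.asarray(loadings).tolist()
        d["train"]["hidden_sizes"] = list(self.train.hidden_sizes)
        d["train"]["init_range"] = list(self.train.init_range)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cohort = CohortConfig(**d.get("cohort", {}))
        train_d = dict(d.get("train", {}))
        if "hidden_sizes" in train_d:
            train_d["hidden_sizes"] = tuple(train_d["hidden_sizes"])
        if "init_range" in train_d:
            train_d["init_range"] = tuple(train_d["init_range"])
        train = TrainConfig(**train_d)
        boot = BootstrapConfig(**d.get("bootstrap", {}))
        top = {
            k: d[k]
            for k in ("n_train_subjects", "seed", "output_dir", "log_level")
            if k in d
        }
        cfg = cls(cohort=cohort, train=train, bootstrap=boot, **top)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
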
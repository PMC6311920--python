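"""Run configuration: validated parameters for the full pipeline.

A :class:`RunConfig` mirrors every CLI flag; it can be loaded from a
YAML file (unknown keys are rejected) and overridden field-by-field.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = ["RunConfig"]

_METHODS = ("mi", "fisher", "hellinger")


@dataclass
class RunConfig:
    """Parameters of filter -> weight -> select.

    ``grid_max`` expands to candidate panel sizes 1..grid_max (clipped to
    the post-filter feature count); ``epsilon`` is the AUC-plateau
    tolerance; ``svm_gamma`` is either a positive float or ``"scale"``
    (1 / (n_features x feature variance)).
    """

    alpha: float = 0.05
    method: str = "mi"
    log_base: str = "e"
    bandwidth: float = 1.0
    hellinger_bins: int = 10
    grid_max: int = 50
    epsilon: float = 0.005
    seed: int = 0
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    smote_k: int = 5
    smote_before_cv: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")
        if self.log_base not in ("e", "2"):
            raise ValueError(f"log_base must be 'e' or '2', got {self.log_base!r}")
        if self.bandwidth <= 0:
            raise ValueError(f"bandwidth must be positive, got {self.bandwidth}")
        if self.hellinger_bins < 2:
            raise ValueError(f"hellinger_bins must be >= 2, got {self.hellinger_bins}")
        if self.grid_max < 1:
            raise ValueError(f"grid_max must be >= 1, got {self.grid_max}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if self.svm_c <= 0:
            raise ValueError(f"svm_c must be positive, got {self.svm_c}")
        if isinstance(self.svm_gamma, str):
            if self.svm_gamma != "scale":
                raise ValueError(
                    f"svm_gamma must be 'scale' or a positive float, got {self.svm_gamma!r}"
                )
        elif self.svm_gamma <= 0:
            raise ValueError(f"svm_gamma must be positive, got {self.svm_gamma}")
        if self.smote_k < 1:
            raise ValueError(f"smote_k must be >= 1, got {self.smote_k}")
        if not isinstance(self.seed, int):
            raise ValueError(f"seed must be an integer, got {self.seed!r}")

    @property
    def grid(self) -> list[int]:
        return list(range(1, self.grid_max + 1))

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in dataclasses.fields(cls)]

    @classmethod
    def from_yaml(cls, path: str, **overrides: Any) -> "RunConfig":
        """Load from YAML; ``overrides`` (non-None) win over file values."""
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        unknown = set(raw) - set(cls.field_names())
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **changes: Any) -> "RunConfig":
        return dataclasses.replace(self, **{k: v for k, v in changes.items() if v is not None})
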
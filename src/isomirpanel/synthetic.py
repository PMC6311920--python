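"""Synthetic isomiR expression benchmark generator.

Emulates the statistical structure the pipeline assumes, so every stage
can be exercised without any download:

* a large majority of "noise" features whose total expression follows an
  exponential distribution concentrated below 1 (real isomiR
  quantifications are dominated by such barely-detected variants);
* a small planted set of class-informative features with right-skewed
  (log-normal) positive expression whose log-location is shifted per
  class by ``effect_size``;
* imbalanced 4-class subtype labels with cohort proportions mimicking a
  real breast-cancer series (472/31/119/76 of 698).

Feature identifiers are syntactically valid isomiR names, and the
planted (informative) feature IDs are returned as ground truth for
recovery experiments.  Everything is driven by a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import ExpressionMatrix, LabelVector, Unit

__all__ = ["GeneratorConfig", "generate", "SUBTYPE_NAMES"]

SUBTYPE_NAMES = ("ERa+HER2-", "ERa-HER2+", "TripleNeg", "ERa+HER2+")

# log-location of informative features at class offset 0; median per-sample
# expression exp(-2) ~ 0.14 puts planted totals well above the noise regime
# without dwarfing it
_BASE_LOC = -2.0

_VARIANTS = ("3′t", "3′a", "5′t", "5′a")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic benchmark.

    ``noise_te_mean`` is the mean of the exponential distribution of
    noise-feature totals; ``effect_size`` scales the per-class log-normal
    location shifts of planted features (0 disables the signal);
    ``dispersion`` is the log-normal sigma of planted features.
    """

    n_samples: int = 200
    # empirical cohort fractions 472/31/119/76 of 698
    class_proportions: tuple[float, ...] = (472 / 698, 31 / 698, 119 / 698, 76 / 698)
    n_noise: int = 480
    n_informative: int = 20
    noise_te_mean: float = 0.5
    effect_size: float = 1.0
    dispersion: float = 1.25
    seed: int = 0
    class_names: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        props = np.asarray(self.class_proportions, dtype=float)
        if (props < 0).any():
            raise ValueError("class proportions must be non-negative")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {props.sum()!r}")
        if (props * self.n_samples < 2 - 1e-12).any():
            raise ValueError(
                "every class needs an expected count >= 2 at "
                f"n_samples={self.n_samples}; proportions {props.tolist()}"
            )
        if self.n_samples < 4:
            raise ValueError("need at least 4 samples")
        if self.n_noise < 0 or self.n_informative < 0:
            raise ValueError("feature counts must be non-negative")
        if self.n_noise + self.n_informative == 0:
            raise ValueError("need at least one feature")
        if self.noise_te_mean <= 0:
            raise ValueError("noise_te_mean must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.class_names is not None and len(self.class_names) != props.size:
            raise ValueError("class_names length must match class_proportions")

    @property
    def n_classes(self) -> int:
        return len(self.class_proportions)

    def resolved_class_names(self) -> tuple[str, ...]:
        if self.class_names is not None:
            return tuple(self.class_names)
        if self.n_classes == len(SUBTYPE_NAMES):
            return SUBTYPE_NAMES
        return tuple(f"subtype{i + 1}" for i in range(self.n_classes))


def _class_counts(config: GeneratorConfig) -> np.ndarray:
    """Largest-remainder apportionment of n_samples over the proportions."""
    props = np.asarray(config.class_proportions, dtype=float)
    exact = props * config.n_samples
    counts = np.floor(exact).astype(int)
    remainder = config.n_samples - counts.sum()
    order = np.argsort(-(exact - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def _feature_names(n: int, rng: np.random.Generator) -> list[str]:
    """Unique, parser-valid isomiR names."""
    names = []
    for i in range(n):
        arm = "5p" if i % 2 == 0 else "3p"
        variant = _VARIANTS[i % 4]
        n_nt = 1 + (i // 4) % 3
        names.append(f"hsa-miR-{9000 + i}-{arm} |{variant}-{n_nt}")
    return names


def generate(
    config: GeneratorConfig | None = None,
) -> tuple[ExpressionMatrix, LabelVector, list[str]]:
    """Draw one synthetic dataset.

    Returns ``(matrix, labels, truth)`` where ``truth`` lists the IDs of
    the planted informative features.  Deterministic given the config
    (including its seed).

    Noise features: per-sample values are exponential draws rescaled so
    each feature's total follows Exponential(mean=noise_te_mean) —
    independent of the labels.  Informative features: per-sample values
    are LogNormal(base + effect_size * offset[class], dispersion) where
    each feature carries its own random permutation of the integer class
    offsets 0..n_classes-1, so different features separate different
    subtype orderings (adjacent offsets differ by one effect_size unit
    in log space, i.e. an e-fold change at the default).
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    names = config.resolved_class_names()
    counts = _class_counts(config)
    y = np.repeat(np.array(names, dtype=object), counts)
    rng.shuffle(y)
    codes = np.array([names.index(v) for v in y])

    n_feat = config.n_noise + config.n_informative
    feature_names = _feature_names(n_feat, rng)
    values = np.empty((n_feat, config.n_samples))

    # noise block: label-independent iid log-normals whose location targets an
    # Exponential(noise_te_mean) draw for the expected feature total.  Using
    # the same log-normal family as the informative block (location differences
    # are pure scale, which min-max normalisation removes) makes noise and
    # signal features exactly exchangeable in the no-signal limit.
    te = rng.exponential(config.noise_te_mean, size=config.n_noise)
    loc = np.log(te / config.n_samples) - config.dispersion**2 / 2.0
    values[: config.n_noise] = rng.lognormal(
        loc[:, None], config.dispersion, size=(config.n_noise, config.n_samples)
    )

    # informative block: per-class shifted log-normals
    offsets = np.arange(config.n_classes, dtype=float)
    for i in range(config.n_informative):
        perm = rng.permutation(offsets)
        loc = _BASE_LOC + config.effect_size * perm[codes]
        values[config.n_noise + i] = rng.lognormal(loc, config.dispersion)

    # interleave rows so planted features are not positionally identifiable
    order = rng.permutation(n_feat)
    values = values[order]
    feature_names = [feature_names[i] for i in order]
    truth = [
        feature_names[np.flatnonzero(order == j)[0]]
        for j in range(config.n_noise, n_feat)
    ]

    sample_ids = [f"sample{i + 1:04d}" for i in range(config.n_samples)]
    matrix = ExpressionMatrix(values, feature_names, sample_ids, Unit.RPM)
    labels = LabelVector(y, sample_ids)
    return matrix, labels, sorted(truth)
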
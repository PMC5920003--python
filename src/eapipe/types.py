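"""Core domain containers.

The pipeline passes small, explicit dataclasses between stages: a raw
continuous rating record (:class:`RatingStream`), its 5-s binned form
(:class:`BinnedSeries`), an autoregressive fit (:class:`ARFit`), the
ground-truth effect structure used by the generator (:class:`EffectSpec`),
and a full simulated study (:class:`StudyDataset`).  Bulk (whole-table)
operations use pandas DataFrames with the CSV dialects documented in
:mod:`eapipe.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError

VALENCES = ("negative", "positive")
SEXES = ("female", "male")
CONDITIONS = ("placebo", "alcohol")

DIAL_MIN = 1.0
DIAL_MAX = 9.0
DIAL_NEUTRAL = 5.0


@dataclass(frozen=True)
class ClipMeta:
    """Metadata for one stimulus video clip.

    ``valence`` is the emotional polarity of the narrated event and
    ``target_sex`` the sex of the person narrating it; both enter the
    downstream models as binary predictors.
    """

    clip_id: str
    target_id: str
    target_sex: str
    valence: str
    duration_s: float = 120.0

    def __post_init__(self) -> None:
        if self.valence not in VALENCES:
            raise InvalidArgumentError(f"valence must be one of {VALENCES}, got {self.valence!r}")
        if self.target_sex not in SEXES:
            raise InvalidArgumentError(f"target_sex must be one of {SEXES}, got {self.target_sex!r}")
        if not self.duration_s >= 30:
            raise InvalidArgumentError(f"duration_s must be >= 30, got {self.duration_s}")


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth fixed/random effect structure, on the Fisher-z scale.

    The generator turns a per perceiver x clip linear predictor

        z = z_intercept + beta_valence*I[positive] + beta_condition*I[alcohol]
            + beta_moderator*m + beta_interaction*I[alcohol]*m + u_i + eps_ij

    (``m`` the standardized moderator, ``u_i ~ N(0, sd_perceiver^2)``,
    ``eps ~ N(0, sd_residual^2)``) into a true tracking correlation tanh(z).

    Defaults are calibrated so a 54 x 16 cohort lands near the observed EA
    means (positive ~0.67, negative ~0.59, overall ~0.63): the intercept and
    valence shift solve E[tanh(N(mu, sd^2))] = target mean r with
    sd^2 = sd_perceiver^2 + sd_residual^2, correcting for the concavity of
    tanh over the random effects.  The condition main effect is small and
    the interaction produces an alcohol deficit at low moderator scores and
    none at high scores.
    """

    z_intercept: float = 0.756
    beta_valence: float = 0.145
    beta_condition: float = -0.065
    beta_moderator: float = 0.0
    beta_interaction: float = 0.155
    sd_perceiver: float = 0.15
    sd_residual: float = 0.35

    def __post_init__(self) -> None:
        if self.sd_perceiver < 0 or self.sd_residual < 0:
            raise InvalidArgumentError("random-effect SDs must be non-negative")

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "EffectSpec":
        return cls(**d)

    def linear_predictor(
        self,
        positive: np.ndarray,
        alcohol: np.ndarray,
        moderator_std: np.ndarray,
    ) -> np.ndarray:
        """Fixed-effect part of the true Fisher-z score (no random terms)."""
        return (
            self.z_intercept
            + self.beta_valence * np.asarray(positive, dtype=float)
            + self.beta_condition * np.asarray(alcohol, dtype=float)
            + self.beta_moderator * np.asarray(moderator_std, dtype=float)
            + self.beta_interaction
            * np.asarray(alcohol, dtype=float)
            * np.asarray(moderator_std, dtype=float)
        )


@dataclass
class RatingStream:
    """One rater's continuous dial record for one clip."""

    clip_id: str
    rater_id: str
    role: str  # "perceiver" or "target"
    t_s: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.role not in ("perceiver", "target"):
            raise InvalidArgumentError(f"role must be 'perceiver' or 'target', got {self.role!r}")
        if self.t_s.shape != self.value.shape:
            raise InvalidArgumentError("t_s and value must have equal length")

    def __len__(self) -> int:
        return self.t_s.size

    @property
    def duration_s(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(self.t_s[-1] - self.t_s[0])


@dataclass
class BinnedSeries:
    """5-s interval means for one stream; ``bin_index`` is implicit 0..n-1."""

    clip_id: str
    rater_id: str
    bin_mean: np.ndarray
    n_samples: np.ndarray
    role: str = "perceiver"

    def __post_init__(self) -> None:
        self.bin_mean = np.asarray(self.bin_mean, dtype=float)
        self.n_samples = np.asarray(self.n_samples, dtype=int)

    def __len__(self) -> int:
        return self.bin_mean.size


@dataclass
class AlignedPair:
    """Equal-length perceiver/target vectors for one clip."""

    clip_id: str
    perceiver_id: str
    target_id: str
    perceiver: np.ndarray
    target: np.ndarray
    warning: str | None = None

    @property
    def n_bins(self) -> int:
        return int(self.perceiver.size)


@dataclass(frozen=True)
class ARFit:
    """Yule-Walker autoregressive fit.

    ``coefficients[k-1]`` multiplies lag k; order 0 carries an empty vector.
    """

    order: int
    coefficients: np.ndarray
    innovation_variance: float
    n_obs: int


@dataclass
class ValidationReport:
    """Report-only stream validation result; never raised."""

    clip_id: str
    rater_id: str
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


@dataclass
class ModelResult:
    """Summary of one fitted multilevel model.

    ``f_tests`` maps term name -> dict(F, df_num, df_den, p, d); ``contrasts``
    maps contrast name -> dict(estimate, se, t, df, p, d).
    """

    fixed_effects: dict[str, dict[str, float]]
    f_tests: dict[str, dict[str, float]]
    contrasts: dict[str, dict[str, float]]
    n_subjects: int
    n_obs: int
    converged: bool
    sigma_perceiver: float
    sigma_residual: float
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class StudyDataset:
    """A complete simulated study with its generating truth."""

    streams: pd.DataFrame
    clips: pd.DataFrame
    participants: pd.DataFrame
    assignments: dict[str, list[str]]
    truth: EffectSpec
    seed: int
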
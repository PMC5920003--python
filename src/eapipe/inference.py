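"""Multilevel inference on Fisher-z EA scores and descriptive statistics.

The central model is a linear mixed model with a random intercept per
perceiver,

    z_ij = x_ij' beta + u_i + e_ij,   u_i ~ N(0, sigma_u^2),  e_ij ~ N(0, sigma_e^2),

fitted by restricted maximum likelihood (the variance-ratio profile is
optimized in one dimension, with the GLS solve done in closed form per
evaluation).  Denominator degrees of freedom follow the containment
(between-within) rule: a between-subject effect gets
``n_subjects - p_between`` df (``p_between`` counting the intercept and all
between-subject fixed-effect columns), a within-subject effect gets
``n_subjects - 1``.  Single-df fixed effects are reported as Wald F tests
with Cohen's d attached via d = 2*sqrt(F/df_den); contrasts (e.g. the
condition effect at moderator levels +/- 1 SD) use d = 2*|t|/sqrt(df).

Also provided: summary-statistic t-tests, Cronbach's alpha, AUDIT scoring,
and drinking-behavior descriptives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .exceptions import (
    ConvergenceError,
    InvalidArgumentError,
    UndefinedStatisticError,
)
from .types import CONDITIONS, ModelResult, SEXES, VALENCES

logger = logging.getLogger(__name__)

# reference (0) / non-reference (1) coding for two-level factors
FACTOR_CODING: dict[str, tuple[str, str]] = {
    "condition": CONDITIONS,   # placebo = 0, alcohol = 1
    "valence": VALENCES,       # negative = 0, positive = 1
    "target_sex": SEXES,       # female = 0, male = 1
}


# --------------------------------------------------------------------------
# effect-size conversions
# --------------------------------------------------------------------------

def cohens_d_from_f(f_stat: float, df_den: float) -> float:
    """Cohen's d from a single-numerator-df F statistic: d = 2*sqrt(F/df_den)."""
    if f_stat < 0:
        raise InvalidArgumentError("F must be >= 0")
    if df_den < 1:
        raise InvalidArgumentError("df_den must be >= 1")
    return 2.0 * float(np.sqrt(f_stat / df_den))


def cohens_d_from_t(t_stat: float, df: float) -> float:
    """Cohen's d from a t statistic: d = 2*|t|/sqrt(df)."""
    if df < 1:
        raise InvalidArgumentError("df must be >= 1")
    return 2.0 * abs(float(t_stat)) / float(np.sqrt(df))


# --------------------------------------------------------------------------
# summary-statistic tests
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def two_sample_t(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    method: str = "pooled",
) -> TTestResult:
    """Two-sample t-test from summary statistics (pooled Student or Welch)."""
    if n1 < 2 or n2 < 2:
        raise InvalidArgumentError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise InvalidArgumentError("SDs must be >= 0")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            raise UndefinedStatisticError("zero variance in both groups with equal means")
        raise UndefinedStatisticError("zero variance in both groups")
    if method not in ("pooled", "welch"):
        raise InvalidArgumentError(f"method must be 'pooled' or 'welch', got {method!r}")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(method == "pooled")
    )
    if method == "pooled":
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue))


def one_sample_t(mean: float, sd: float, n: int, mu0: float = 0.0) -> TTestResult:
    """One-sample t-test from summary statistics."""
    if n < 2:
        raise InvalidArgumentError("n must be >= 2")
    if sd <= 0:
        raise UndefinedStatisticError("sd must be > 0")
    t = (mean - mu0) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p))


def cronbach_alpha(item_matrix: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha for an n x k item-score matrix (n-1 variances)."""
    X = pd.DataFrame(item_matrix)
    n_before = len(X)
    X = X.dropna()
    if len(X) < n_before:
        logger.info("cronbach_alpha: dropped %d rows with missing values", n_before - len(X))
    arr = X.to_numpy(dtype=float)
    n, k = arr.shape
    if k < 2 or n < 2:
        raise InvalidArgumentError("need at least 2 items and 2 observations")
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise UndefinedStatisticError("total-score variance is zero")
    item_var = arr.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def score_audit(items: list[int] | np.ndarray, revised: bool = True) -> tuple[int, bool]:
    """AUDIT total and hazardous-drinking flag (cutoff 8).

    ``revised=True`` sums items 1-8 only (range 0-32), the variant used when
    items 9-10 are unusable; ``revised=False`` sums all 10 items (0-40).
    """
    arr = np.asarray(items)
    if arr.shape != (10,):
        raise InvalidArgumentError("AUDIT requires exactly 10 items")
    if np.any(arr < 0) or np.any(arr > 4) or not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == arr.astype(int)):
            raise InvalidArgumentError("AUDIT items must be integers in 0..4")
        arr = arr.astype(int)
        if np.any(arr < 0) or np.any(arr > 4):
            raise InvalidArgumentError("AUDIT items must be integers in 0..4")
    total = int(arr[:8].sum()) if revised else int(arr.sum())
    return total, total >= 8


# --------------------------------------------------------------------------
# random-intercept REML mixed model
# --------------------------------------------------------------------------

def _encode_column(data: pd.DataFrame, name: str) -> np.ndarray:
    if name not in data.columns:
        raise InvalidArgumentError(f"column {name!r} not found in data")
    col = data[name]
    if name in FACTOR_CODING:
        ref, alt = FACTOR_CODING[name]
        vals = set(col.unique())
        if not vals <= {ref, alt}:
            raise InvalidArgumentError(
                f"{name!r} has levels {sorted(vals)}, expected subset of {{{ref!r}, {alt!r}}}"
            )
        return (col == alt).to_numpy(dtype=float)
    return col.to_numpy(dtype=float)


def build_design(data: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept; ``a:b`` terms are elementwise products."""
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for term in terms:
        parts = term.split(":")
        col = _encode_column(data, parts[0])
        for p in parts[1:]:
            col = col * _encode_column(data, p)
        cols.append(col)
        names.append(term)
    return np.column_stack(cols), names


class _REMLProfile:
    """Profiled REML criterion for a random-intercept model, indexed by the
    variance ratio lam = sigma_u^2 / sigma_e^2."""

    def __init__(self, y: np.ndarray, X: np.ndarray, group_sizes: np.ndarray,
                 group_starts: np.ndarray):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.sizes = group_sizes.astype(float)
        self.starts = group_starts
        # per-group sums
        self.Gx = np.add.reduceat(X, group_starts, axis=0)        # (g, p)
        self.Gy = np.add.reduceat(y, group_starts)                # (g,)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _cross(self, lam: float):
        w = lam / (1.0 + lam * self.sizes)                        # (g,)
        XtViX = self.XtX - (self.Gx * w[:, None]).T @ self.Gx
        XtViy = self.Xty - (self.Gx * w[:, None]).T @ self.Gy
        ytViy = self.yty - float(w @ (self.Gy * self.Gy))
        return XtViX, XtViy, ytViy, w

    def criterion(self, lam: float) -> float:
        XtViX, XtViy, ytViy, _ = self._cross(lam)
        try:
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError:
            return np.inf
        rss = ytViy - float(beta @ XtViy)
        if rss <= 0:
            return np.inf
        sign, logdet = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        return (
            (self.n - self.p) * np.log(rss)
            + float(np.sum(np.log1p(lam * self.sizes)))
            + logdet
        )

    def solve(self, lam: float):
        XtViX, XtViy, ytViy, _ = self._cross(lam)
        beta = np.linalg.solve(XtViX, XtViy)
        rss = ytViy - float(beta @ XtViy)
        sigma_e2 = rss / (self.n - self.p)
        cov = sigma_e2 * np.linalg.inv(XtViX)
        return beta, cov, sigma_e2


class MixedEAModel(BaseEstimator):
    """Random-intercept linear mixed model for Fisher-z EA scores.

    sklearn-style estimator: hyperparameters in ``__init__``, data in
    ``fit``, fitted attributes with trailing underscores.

    Parameters
    ----------
    fixed : tuple of str
        Fixed-effect terms; two-level factors (condition, valence,
        target_sex) are dummy-coded, other names are numeric columns, and
        ``a:b`` denotes a product term.
    moderator : str or None
        Continuous between-subject moderator column.  When set, the model
        adds the (optionally grand-mean centered) moderator and its
        interaction with ``condition``.
    center : bool
        Grand-mean center the moderator (mean over subjects) before forming
        the interaction.
    df_method : str
        Only ``"containment"`` is implemented; the parameter exists so the
        choice is explicit and configurable at the call sites.
    """

    def __init__(
        self,
        fixed: tuple[str, ...] = ("condition",),
        moderator: str | None = None,
        center: bool = True,
        df_method: str = "containment",
        subject_col: str = "perceiver_id",
        response_col: str = "z",
    ):
        self.fixed = fixed
        self.moderator = moderator
        self.center = center
        self.df_method = df_method
        self.subject_col = subject_col
        self.response_col = response_col

    # -- fitting -----------------------------------------------------------

    def fit(self, data: pd.DataFrame, y=None) -> "MixedEAModel":
        if self.df_method != "containment":
            raise InvalidArgumentError(
                f"df_method {self.df_method!r} not implemented (use 'containment')"
            )
        data = data.copy()
        if "excluded" in data.columns:
            data = data[~data["excluded"].astype(bool)]
        data = data.dropna(subset=[self.response_col])
        if data.empty:
            raise InvalidArgumentError("no usable rows to fit")

        terms = list(self.fixed)
        if self.moderator is not None:
            subj_mod = data.groupby(self.subject_col)[self.moderator].first()
            if subj_mod.std(ddof=1) == 0:
                raise InvalidArgumentError("moderator has zero variance across subjects")
            self.moderator_mean_ = float(subj_mod.mean()) if self.center else 0.0
            self.moderator_sd_ = float(subj_mod.std(ddof=1))
            mod_c = f"{self.moderator}_c"
            data[mod_c] = data[self.moderator] - self.moderator_mean_
            terms += [mod_c, f"condition:{mod_c}"]
            self._interaction_term = f"condition:{mod_c}"
        else:
            self._interaction_term = None

        data = data.sort_values(self.subject_col, kind="stable")
        groups, group_idx = np.unique(data[self.subject_col].to_numpy(), return_inverse=True)
        order = np.argsort(group_idx, kind="stable")
        data = data.iloc[order]
        group_idx = group_idx[order]
        starts = np.concatenate([[0], np.flatnonzero(np.diff(group_idx)) + 1])
        sizes = np.diff(np.concatenate([starts, [len(data)]]))

        X, names = build_design(data, terms)
        y_vec = data[self.response_col].to_numpy(dtype=float)
        prof = _REMLProfile(y_vec, X, sizes, starts)

        res = optimize.minimize_scalar(
            lambda t: prof.criterion(np.exp(t)), bounds=(-12.0, 8.0), method="bounded",
            options={"xatol": 1e-8},
        )
        if not res.success or not np.isfinite(res.fun):
            raise ConvergenceError("REML optimization failed")
        lam = float(np.exp(res.x))
        if prof.criterion(0.0) <= res.fun:
            lam = 0.0
        beta, cov, sigma_e2 = prof.solve(lam)

        self.term_names_ = names
        self.params_ = pd.Series(beta, index=names)
        self.cov_params_ = pd.DataFrame(cov, index=names, columns=names)
        self.bse_ = pd.Series(np.sqrt(np.diag(cov)), index=names)
        self.lambda_ = lam
        self.sigma_residual_ = float(np.sqrt(sigma_e2))
        self.sigma_perceiver_ = float(np.sqrt(lam * sigma_e2))
        self.n_subjects_ = int(len(groups))
        self.n_obs_ = int(len(data))
        self.converged_ = True
        self.notes_ = []
        if lam == 0.0:
            self.notes_.append(
                "random-intercept variance estimated at 0; estimates coincide with OLS"
            )
            logger.info("mixed model downgraded to OLS (singular random-effect variance)")

        # containment df bookkeeping: a column is between-subject if constant
        # within every subject
        between = []
        for j, name in enumerate(names):
            col = X[:, j]
            mx = np.maximum.reduceat(col, starts)
            mn = np.minimum.reduceat(col, starts)
            between.append(bool(np.all(mx - mn < 1e-10)))
        self.between_term_ = dict(zip(names, between))
        p_between = int(sum(between))
        self.df_between_ = self.n_subjects_ - p_between
        self.df_within_ = self.n_subjects_ - 1

        self._f_tests = {}
        for name in names:
            if name == "intercept":
                continue
            df_den = self.df_between_ if self.between_term_[name] else self.df_within_
            t = float(self.params_[name] / self.bse_[name])
            F = t * t
            self._f_tests[name] = {
                "F": F,
                "df_num": 1,
                "df_den": float(df_den),
                "p": float(stats.f.sf(F, 1, df_den)),
                "d": cohens_d_from_f(F, df_den),
                "estimate": float(self.params_[name]),
                "se": float(self.bse_[name]),
            }
        self.result_ = self._build_result()
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise InvalidArgumentError("model is not fitted")

    # -- inference ---------------------------------------------------------

    def contrast(self, coeffs: dict[str, float], name: str = "contrast") -> dict[str, float]:
        """t test of a linear combination of fixed effects with containment df."""
        self._check_fitted()
        c = np.array([coeffs.get(n, 0.0) for n in self.term_names_])
        est = float(c @ self.params_.to_numpy())
        se = float(np.sqrt(c @ self.cov_params_.to_numpy() @ c))
        involved = [n for n in self.term_names_ if coeffs.get(n, 0.0) != 0.0]
        df = (
            self.df_between_
            if all(self.between_term_[n] for n in involved)
            else self.df_within_
        )
        t = est / se
        return {
            "name": name,
            "estimate": est,
            "se": se,
            "t": float(t),
            "df": float(df),
            "p": float(2.0 * stats.t.sf(abs(t), df)),
            "d": cohens_d_from_t(t, df),
        }

    def simple_slopes(self, levels: tuple[float, float] | None = None) -> dict[str, dict]:
        """Condition contrasts (alcohol - placebo) at low/high moderator levels.

        Default levels are the subject-level mean -/+ 1 SD of the moderator.
        Requires the condition x moderator interaction in the model.
        """
        self._check_fitted()
        if self._interaction_term is None:
            raise InvalidArgumentError("model has no condition x moderator interaction")
        sd = self.moderator_sd_
        if sd == 0:
            raise InvalidArgumentError("moderator SD is zero: degenerate levels")
        mean = self.moderator_mean_ if self.center else 0.0
        if levels is None:
            levels = (mean - sd, mean + sd)
        out = {}
        for label, level in zip(("low", "high"), levels):
            centered = level - mean
            res = self.contrast(
                {"condition": 1.0, self._interaction_term: centered},
                name=f"alcohol-placebo @ moderator={level:g}",
            )
            res["moderator_level"] = float(level)
            out[label] = res
        return out

    def predict_z(self, condition: str, moderator_level: float | None = None) -> float:
        """Model-implied mean Fisher-z score (other factors at reference)."""
        self._check_fitted()
        coeffs = {"intercept": 1.0}
        if condition == "alcohol":
            coeffs["condition"] = 1.0
        if self._interaction_term is not None and moderator_level is not None:
            centered = moderator_level - self.moderator_mean_
            mod_c = f"{self.moderator}_c"
            coeffs[mod_c] = centered
            if condition == "alcohol":
                coeffs[self._interaction_term] = centered
        c = np.array([coeffs.get(n, 0.0) for n in self.term_names_])
        return float(c @ self.params_.to_numpy())

    def _build_result(self, contrasts: dict | None = None) -> ModelResult:
        return ModelResult(
            fixed_effects={
                n: {"estimate": float(self.params_[n]), "se": float(self.bse_[n])}
                for n in self.term_names_
            },
            f_tests={k: dict(v) for k, v in self._f_tests.items()},
            contrasts=contrasts or {},
            n_subjects=self.n_subjects_,
            n_obs=self.n_obs_,
            converged=self.converged_,
            sigma_perceiver=self.sigma_perceiver_,
            sigma_residual=self.sigma_residual_,
            notes=list(self.notes_),
        )


def fit_mixed_model(
    ea_table: pd.DataFrame,
    fixed: tuple[str, ...] = ("condition",),
    moderator: str | None = None,
    center: bool = True,
    df_method: str = "containment",
) -> ModelResult:
    """Thin functional wrapper over :class:`MixedEAModel`; returns a summary."""
    model = MixedEAModel(
        fixed=fixed, moderator=moderator, center=center, df_method=df_method
    ).fit(ea_table)
    result = model.result_
    if moderator is not None:
        slopes = model.simple_slopes()
        result.contrasts = {k: dict(v) for k, v in slopes.items()}
    return result


def build_analysis_table(
    ea: pd.DataFrame, participants: pd.DataFrame
) -> pd.DataFrame:
    """Join per-pair EA scores with participant-level predictors."""
    cols = ["participant_id", "condition", "r_audit"]
    extra = [c for c in ("avg_daily_drinks", "peak_daily_drinks") if c in participants.columns]
    merged = ea.merge(
        participants[cols + extra],
        left_on="perceiver_id",
        right_on="participant_id",
        how="left",
        validate="many_to_one",
    ).drop(columns=["participant_id"])
    if merged["condition"].isna().any():
        missing = merged.loc[merged["condition"].isna(), "perceiver_id"].unique()
        raise InvalidArgumentError(f"no participant record for perceivers: {list(missing)[:5]}")
    return merged


def drinking_summaries(participants: pd.DataFrame, ttest_method: str = "pooled") -> dict:
    """Drinking descriptives: AUDIT-drinks correlations, group means, urge tests."""
    if len(participants) < 3:
        raise InvalidArgumentError("need at least 3 participants")
    out: dict = {"correlations": {}, "group_means": {}, "urge_tests": {}}
    for col in ("avg_daily_drinks", "peak_daily_drinks"):
        x = participants["r_audit"].to_numpy(dtype=float)
        ycol = participants[col].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(ycol) == 0:
            logger.warning("correlation undefined for r_audit vs %s (constant column)", col)
            out["correlations"][col] = None
            continue
        res = stats.pearsonr(x, ycol)
        out["correlations"][col] = {"r": float(res.statistic), "p": float(res.pvalue)}

    numeric = [
        "r_audit", "sias", "avg_daily_drinks", "peak_daily_drinks",
        "dmq_social", "dmq_enhancement", "dmq_coping", "dmq_conformity", "weight_kg",
    ]
    numeric = [c for c in numeric if c in participants.columns]
    grouped = participants.groupby("condition")[numeric]
    means, sds, counts = grouped.mean(), grouped.std(ddof=1), grouped.size()
    for col in numeric:
        out["group_means"][col] = {
            g: {"mean": float(means.loc[g, col]), "sd": float(sds.loc[g, col]),
                "n": int(counts.loc[g])}
            for g in means.index
        }
    for col in ("urge_baseline", "urge_pre_drink", "urge_post_drink", "urge_post_task"):
        if col not in participants.columns:
            continue
        g = participants.groupby("condition")[col]
        m, s, n = g.mean(), g.std(ddof=1), g.size()
        try:
            tt = two_sample_t(
                m["alcohol"], s["alcohol"], int(n["alcohol"]),
                m["placebo"], s["placebo"], int(n["placebo"]),
                method=ttest_method,
            )
            out["urge_tests"][col] = {"t": tt.t, "df": tt.df, "p": tt.p}
        except UndefinedStatisticError:
            out["urge_tests"][col] = None
    return out
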
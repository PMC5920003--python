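"""Per-clip empathic-accuracy scoring.

Continuous affect ratings carry strong serial dependence, which inflates the
sampling variability of a naive Pearson correlation between perceiver and
target bins.  This module estimates autoregressive structure with the
Yule-Walker equations (solved by the Levinson-Durbin recursion on biased
sample autocovariances) and offers three per-clip correlation methods:

``naive``
    Pearson correlation of the binned series as-is.
``prewhiten``
    Each series is filtered by its own AR(p) Yule-Walker fit; Pearson
    correlation of the two residual series.
``ar_error_model`` (default)
    Two-stage regression with AR(p) errors: OLS of perceiver on target, a
    Yule-Walker fit to the OLS residuals, quasi-differencing of both series
    by the fitted coefficients, and the correlation of the transformed
    series, signed by the structural slope.

Correlations are summarized on the Fisher-z scale (atanh), clipped at
|r| = 0.999 so perfect tracking maps to a finite score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import (
    DegeneratePairError,
    DegenerateSeriesError,
    InvalidArgumentError,
    PairingError,
)
from .preprocessing import align_pair, binned_to_objects
from .types import ARFit

logger = logging.getLogger(__name__)

METHODS = ("naive", "prewhiten", "ar_error_model")
DEFAULT_METHOD = "ar_error_model"
DEFAULT_AR_ORDER = 1
FISHER_CLIP = 0.999
_CONST_TOL = 1e-12


def _autocovariance(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocovariances c_0..c_max_lag (1/n normalization)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    return np.array([np.dot(xc[: n - k], xc[k:]) / n for k in range(max_lag + 1)])


def levinson_durbin(acov: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve the Yule-Walker system by the Levinson-Durbin recursion.

    ``acov`` is the autocovariance sequence c_0..c_p.  Returns the AR
    coefficients (lag 1..p) and the innovation variance.  On a valid
    (positive-definite) autocovariance sequence the recursion keeps every
    reflection coefficient in (-1, 1), so the fitted model is stationary.
    """
    acov = np.asarray(acov, dtype=float)
    p = acov.size - 1
    if p < 0 or acov[0] <= 0:
        raise InvalidArgumentError("autocovariance sequence must start with c_0 > 0")
    phi = np.zeros(p)
    e = float(acov[0])
    for k in range(1, p + 1):
        kappa = (acov[k] - np.dot(phi[: k - 1], acov[k - 1 : 0 : -1])) / e
        phi_new = phi.copy()
        phi_new[k - 1] = kappa
        phi_new[: k - 1] = phi[: k - 1] - kappa * phi[: k - 1][::-1]
        phi = phi_new
        e *= 1.0 - kappa * kappa
    return phi, e


def yule_walker_ar(series: np.ndarray, order: int) -> ARFit:
    """Fit an AR(``order``) model by the Yule-Walker method.

    Order 1 reduces to the lag-1 sample autocorrelation; order 0 returns an
    empty coefficient vector with the series variance as innovation variance.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if order < 0:
        raise InvalidArgumentError("order must be >= 0")
    if order >= n - 2:
        raise InvalidArgumentError(f"order {order} too large for series of length {n}")
    if np.ptp(x) < _CONST_TOL or np.var(x) < _CONST_TOL:
        raise DegenerateSeriesError("cannot fit an AR model to a constant series")
    acov = _autocovariance(x, order)
    phi, sigma2 = levinson_durbin(acov)
    return ARFit(order=order, coefficients=phi, innovation_variance=float(sigma2), n_obs=n)


def prewhiten(series: np.ndarray, fit: ARFit) -> np.ndarray:
    """Filter a (centered) series by an AR fit: e_t = x_t - sum_k phi_k x_{t-k}.

    Output length is ``len(series) - fit.order``; an order-0 fit returns the
    centered series unchanged.
    """
    x = np.asarray(series, dtype=float)
    p = fit.order
    if x.size <= p:
        raise InvalidArgumentError("series shorter than AR order")
    xc = x - x.mean()
    e = xc[p:].copy()
    for k in range(1, p + 1):
        e -= fit.coefficients[k - 1] * xc[p - k : x.size - k]
    return e


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) < _CONST_TOL or np.ptp(b) < _CONST_TOL:
        raise DegenerateSeriesError("constant series: correlation undefined")
    r = stats.pearsonr(a, b).statistic
    return float(np.clip(r, -1.0, 1.0))


def ea_correlation(
    perceiver: np.ndarray,
    target: np.ndarray,
    method: str = DEFAULT_METHOD,
    ar_order: int = DEFAULT_AR_ORDER,
) -> float:
    """Per-clip perceiver-target correlation under the chosen method."""
    p = np.asarray(perceiver, dtype=float)
    t = np.asarray(target, dtype=float)
    if method not in METHODS:
        raise InvalidArgumentError(f"method must be one of {METHODS}, got {method!r}")
    if p.size != t.size:
        raise InvalidArgumentError("perceiver and target series must have equal length")
    min_n = max(3, ar_order + 3)
    if p.size < min_n:
        raise InvalidArgumentError(f"need at least {min_n} bins, got {p.size}")

    if method == "naive":
        return _pearson(p, t)

    if method == "prewhiten":
        ep = prewhiten(p, yule_walker_ar(p, ar_order))
        et = prewhiten(t, yule_walker_ar(t, ar_order))
        return _pearson(ep, et)

    # ar_error_model: two-stage regression with AR errors
    if np.ptp(t) < _CONST_TOL or np.ptp(p) < _CONST_TOL:
        raise DegenerateSeriesError("constant series: correlation undefined")
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, p, rcond=None)
    resid = p - X @ beta
    if np.var(resid) < _CONST_TOL:
        # perceiver is an exact affine function of target: AR stage is moot
        return float(np.sign(beta[1]) if beta[1] != 0 else 1.0)
    fit = yule_walker_ar(resid, ar_order)
    phi = fit.coefficients
    o = fit.order
    ps = p[o:].copy()
    ts = t[o:].copy()
    for k in range(1, o + 1):
        ps -= phi[k - 1] * p[o - k : p.size - k]
        ts -= phi[k - 1] * t[o - k : t.size - k]
    return _pearson(ps, ts)


def fisher_z(r: float | np.ndarray, clip_at: float = FISHER_CLIP) -> float | np.ndarray:
    """Fisher z = atanh(r), with |r| clipped at ``clip_at`` to stay finite."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1 + 1e-12):
        raise InvalidArgumentError("|r| must be <= 1")
    z = np.arctanh(np.sign(arr) * np.minimum(np.abs(arr), clip_at))
    return float(z) if np.isscalar(r) or arr.ndim == 0 else z


def inverse_fisher_z(z: float | np.ndarray) -> float | np.ndarray:
    """Inverse Fisher transform, tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if np.isscalar(z) or out.ndim == 0 else out


EA_COLUMNS = [
    "perceiver_id",
    "clip_id",
    "valence",
    "target_sex",
    "r",
    "z",
    "n_bins",
    "method",
    "excluded",
    "reason",
]


def score_dataset(
    binned: pd.DataFrame,
    clips: pd.DataFrame,
    assignments: dict[str, list[str]],
    method: str = DEFAULT_METHOD,
    ar_order: int = DEFAULT_AR_ORDER,
) -> pd.DataFrame:
    """Score every assigned perceiver x clip pair.

    Returns one row per assignment; pairs that cannot be scored (missing
    stream, constant series, too few bins) are retained with ``excluded``
    set and a reason, never silently dropped.
    """
    series = binned_to_objects(binned)
    clip_info = clips.set_index("clip_id")
    rows = []
    for perceiver_id, clip_ids in assignments.items():
        for clip_id in clip_ids:
            meta = clip_info.loc[clip_id]
            row = {
                "perceiver_id": perceiver_id,
                "clip_id": clip_id,
                "valence": meta["valence"],
                "target_sex": meta["target_sex"],
                "r": np.nan,
                "z": np.nan,
                "n_bins": 0,
                "method": method,
                "excluded": False,
                "reason": "",
            }
            pkey = (clip_id, perceiver_id)
            tkey = (clip_id, str(meta["target_id"]))
            if pkey not in series or tkey not in series:
                row["excluded"], row["reason"] = True, "missing"
                rows.append(row)
                continue
            try:
                pair = align_pair(series[pkey], series[tkey])
                r = ea_correlation(pair.perceiver, pair.target, method=method, ar_order=ar_order)
            except (DegenerateSeriesError,) :
                row["excluded"], row["reason"] = True, "constant_series"
                rows.append(row)
                continue
            except (DegeneratePairError, InvalidArgumentError):
                row["excluded"], row["reason"] = True, "too_few_bins"
                rows.append(row)
                continue
            except PairingError:
                row["excluded"], row["reason"] = True, "pairing_error"
                rows.append(row)
                continue
            row["r"] = r
            row["z"] = fisher_z(r)
            row["n_bins"] = pair.n_bins
            rows.append(row)
    ea = pd.DataFrame(rows, columns=EA_COLUMNS)
    n_excl = int(ea["excluded"].sum()) if len(ea) else 0
    logger.info("scored %d pairs (%d excluded)", len(ea), n_excl)
    return ea


def summarize_ea(ea: pd.DataFrame) -> dict:
    """Mean EA correlation overall and by valence and target sex."""
    ok = ea[~ea["excluded"]]
    return {
        "n_pairs": int(len(ea)),
        "n_excluded": int(ea["excluded"].sum()),
        "mean_r": float(ok["r"].mean()) if len(ok) else float("nan"),
        "mean_r_by_valence": {k: float(v) for k, v in ok.groupby("valence")["r"].mean().items()},
        "mean_r_by_target_sex": {
            k: float(v) for k, v in ok.groupby("target_sex")["r"].mean().items()
        },
        "mean_z": float(ok["z"].mean()) if len(ok) else float("nan"),
    }


class EAScorer(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: binned series table -> EA score table.

    Clip metadata and perceiver assignments are estimator parameters; the
    transformed output is the per perceiver x clip EA table.
    """

    def __init__(
        self,
        clips: pd.DataFrame | None = None,
        assignments: dict[str, list[str]] | None = None,
        method: str = DEFAULT_METHOD,
        ar_order: int = DEFAULT_AR_ORDER,
    ):
        self.clips = clips
        self.assignments = assignments
        self.method = method
        self.ar_order = ar_order

    def fit(self, X: pd.DataFrame, y=None) -> "EAScorer":
        if self.clips is None or self.assignments is None:
            raise InvalidArgumentError("EAScorer requires clips and assignments")
        self.n_assignments_ = sum(len(v) for v in self.assignments.values())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.clips is None or self.assignments is None:
            raise InvalidArgumentError("EAScorer requires clips and assignments")
        ea = score_dataset(
            X, self.clips, self.assignments, method=self.method, ar_order=self.ar_order
        )
        self.summary_ = summarize_ea(ea)
        return ea
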
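"""Stream preprocessing: binning, edge truncation, pair alignment, clip order.

Continuous dial streams are averaged over half-open 5-s windows anchored at
the stream's first timestamp, the first and last window are discarded (the
ratings' start-up and wind-down seconds), and perceiver/target bins are
aligned to a common length before correlation.  The clip-order sampler
enforces the presentation constraints used for the stimulus sequence: no
target more than twice overall and no more than two same-valence clips in a
row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import (
    DegeneratePairError,
    InfeasibleOrderError,
    InvalidArgumentError,
    PairingError,
    TooShortClipError,
)
from .types import (
    AlignedPair,
    BinnedSeries,
    ClipMeta,
    DIAL_MAX,
    DIAL_MIN,
    RatingStream,
    ValidationReport,
)

logger = logging.getLogger(__name__)

DEFAULT_BIN_S = 5.0
DEFAULT_EDGE_BINS = 1
MIN_PAIR_BINS = 3


def bin_stream(stream: RatingStream, bin_s: float = DEFAULT_BIN_S) -> BinnedSeries:
    """Average a stream over half-open ``[k*bin_s, (k+1)*bin_s)`` windows.

    Windows are anchored at the first timestamp.  A trailing window that
    covers less than ``bin_s`` of recording is dropped, so every retained bin
    averages the same time span.  Recording length is taken as
    ``t_last - t_first + dt`` with ``dt`` the median sample spacing (a single
    sample spans one nominal interval).
    """
    if len(stream) == 0:
        raise InvalidArgumentError("cannot bin an empty stream")
    if not bin_s > 0:
        raise InvalidArgumentError(f"bin_s must be positive, got {bin_s}")

    rel = stream.t_s - stream.t_s[0]
    if len(stream) > 1:
        dt = float(np.median(np.diff(stream.t_s)))
        if dt <= 0:
            raise InvalidArgumentError("timestamps must be strictly increasing")
    else:
        dt = bin_s
    duration = float(rel[-1]) + dt
    n_full = int(np.floor(duration / bin_s + 1e-9))
    idx = np.floor(rel / bin_s + 1e-9).astype(int)
    keep = idx < n_full
    if n_full == 0:
        return BinnedSeries(stream.clip_id, stream.rater_id, np.empty(0), np.empty(0, int), stream.role)

    counts = np.bincount(idx[keep], minlength=n_full)
    if np.any(counts == 0):
        raise InvalidArgumentError(
            f"stream {stream.rater_id}/{stream.clip_id} has a gap wider than one bin"
        )
    sums = np.bincount(idx[keep], weights=stream.value[keep], minlength=n_full)
    return BinnedSeries(stream.clip_id, stream.rater_id, sums / counts, counts, stream.role)


def truncate_edges(binned: BinnedSeries, n_edge_bins: int = DEFAULT_EDGE_BINS) -> BinnedSeries:
    """Drop the first and last ``n_edge_bins`` bins and re-zero the index."""
    if n_edge_bins < 0:
        raise InvalidArgumentError("n_edge_bins must be >= 0")
    if len(binned) <= 2 * n_edge_bins:
        raise TooShortClipError(
            f"{binned.rater_id}/{binned.clip_id}: {len(binned)} bins, "
            f"need more than {2 * n_edge_bins} to truncate edges"
        )
    sl = slice(n_edge_bins, len(binned) - n_edge_bins if n_edge_bins else None)
    return BinnedSeries(
        binned.clip_id, binned.rater_id, binned.bin_mean[sl], binned.n_samples[sl], binned.role
    )


def align_pair(perceiver: BinnedSeries, target: BinnedSeries) -> AlignedPair:
    """Pair perceiver and target bins from bin 0 up to the shorter length.

    A mismatch of more than 2 bins is tolerated but flagged in the returned
    ``warning`` (dial logs may end a few samples early); fewer than
    ``MIN_PAIR_BINS`` common bins is an error.
    """
    if perceiver.clip_id != target.clip_id:
        raise PairingError(
            f"clip mismatch: perceiver has {perceiver.clip_id!r}, target has {target.clip_id!r}"
        )
    n = min(len(perceiver), len(target))
    if n < MIN_PAIR_BINS:
        raise DegeneratePairError(
            f"{perceiver.rater_id}/{perceiver.clip_id}: only {n} common bins (< {MIN_PAIR_BINS})"
        )
    warning = None
    if abs(len(perceiver) - len(target)) > 2:
        warning = (
            f"{perceiver.clip_id}: length mismatch {len(perceiver)} vs {len(target)} bins; "
            f"truncated to {n}"
        )
        logger.warning(warning)
    return AlignedPair(
        clip_id=perceiver.clip_id,
        perceiver_id=perceiver.rater_id,
        target_id=target.rater_id,
        perceiver=perceiver.bin_mean[:n].copy(),
        target=target.bin_mean[:n].copy(),
        warning=warning,
    )


def _order_ok(order: list[ClipMeta], max_target_repeats: int, max_valence_run: int) -> bool:
    counts: dict[str, int] = {}
    run_val, run_len = None, 0
    for c in order:
        counts[c.target_id] = counts.get(c.target_id, 0) + 1
        if counts[c.target_id] > max_target_repeats:
            return False
        if c.valence == run_val:
            run_len += 1
        else:
            run_val, run_len = c.valence, 1
        if run_len > max_valence_run:
            return False
    return True


def sample_clip_order(
    clips: list[ClipMeta],
    max_target_repeats: int = 2,
    max_valence_run: int = 2,
    seed: int | np.random.Generator = 0,
    max_rejection_tries: int = 500,
) -> list[ClipMeta]:
    """Sample a presentation order satisfying the sequencing constraints.

    First tries uniform rejection sampling (a uniformly shuffled order that
    happens to satisfy the constraints is exactly uniform among feasible
    orders); if that fails repeatedly, falls back to seeded backtracking with
    a randomized candidate order, which always finds an order when one exists
    but is not exactly uniform.  Exhausted backtracking raises
    :class:`InfeasibleOrderError`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clips = list(clips)
    if not clips:
        raise InvalidArgumentError("clip list is empty")
    # total-count constraint is order independent: fail fast if violated
    totals: dict[str, int] = {}
    for c in clips:
        totals[c.target_id] = totals.get(c.target_id, 0) + 1
    if any(v > max_target_repeats for v in totals.values()):
        raise InfeasibleOrderError(
            "a target appears more often than max_target_repeats in the clip set"
        )

    for _ in range(max_rejection_tries):
        perm = [clips[i] for i in rng.permutation(len(clips))]
        if _order_ok(perm, max_target_repeats, max_valence_run):
            return perm

    # backtracking fallback
    order: list[ClipMeta] = []
    used = [False] * len(clips)

    def extend() -> bool:
        if len(order) == len(clips):
            return True
        cand = [i for i in range(len(clips)) if not used[i]]
        for i in rng.permutation(len(cand)):
            j = cand[i]
            order.append(clips[j])
            if _order_ok(order, max_target_repeats, max_valence_run):
                used[j] = True
                if extend():
                    return True
                used[j] = False
            order.pop()
        return False

    if extend():
        return order
    raise InfeasibleOrderError(
        f"no order of {len(clips)} clips satisfies max_target_repeats="
        f"{max_target_repeats}, max_valence_run={max_valence_run}"
    )


def validate_stream(stream: RatingStream, min_duration_s: float = 30.0) -> ValidationReport:
    """Report-only validation; lists violations, never raises."""
    report = ValidationReport(stream.clip_id, stream.rater_id)
    if len(stream) == 0:
        report.violations.append("empty")
        return report
    if np.any(stream.value < DIAL_MIN) or np.any(stream.value > DIAL_MAX):
        report.violations.append("value_out_of_range")
    if len(stream) > 1 and np.any(np.diff(stream.t_s) <= 0):
        report.violations.append("non_monotone_timestamps")
    if stream.duration_s < min_duration_s:
        report.violations.append("too_short")
    if np.ptp(stream.value) == 0:
        report.violations.append("constant_series")
    return report


# --- bulk (DataFrame) interface -------------------------------------------


@dataclass
class PreprocessResult:
    binned: pd.DataFrame
    exclusions: list[dict] = field(default_factory=list)


def streams_to_objects(streams: pd.DataFrame) -> list[RatingStream]:
    """Split a long-format streams table into per (clip, rater) objects."""
    out = []
    for (clip_id, rater_id, role), g in streams.groupby(
        ["clip_id", "rater_id", "role"], sort=True
    ):
        g = g.sort_values("t_s")
        out.append(
            RatingStream(
                clip_id=str(clip_id),
                rater_id=str(rater_id),
                role=str(role),
                t_s=g["t_s"].to_numpy(dtype=float),
                value=g["value"].to_numpy(dtype=float),
            )
        )
    return out


def preprocess_streams(
    streams: pd.DataFrame,
    bin_s: float = DEFAULT_BIN_S,
    n_edge_bins: int = DEFAULT_EDGE_BINS,
) -> PreprocessResult:
    """Bin and edge-truncate every stream in a long-format table.

    Streams too short to truncate are excluded (not raised) and recorded in
    ``exclusions`` so the downstream exclusion ledger stays complete.
    """
    rows = []
    exclusions: list[dict] = []
    objs = streams_to_objects(streams)
    for s in objs:
        try:
            b = truncate_edges(bin_stream(s, bin_s=bin_s), n_edge_bins=n_edge_bins)
        except TooShortClipError as exc:
            logger.warning("excluding %s/%s: %s", s.rater_id, s.clip_id, exc)
            exclusions.append(
                {"clip_id": s.clip_id, "rater_id": s.rater_id, "reason": "too_short"}
            )
            continue
        rows.append(
            pd.DataFrame(
                {
                    "clip_id": b.clip_id,
                    "rater_id": b.rater_id,
                    "role": b.role,
                    "bin_index": np.arange(len(b)),
                    "bin_mean": b.bin_mean,
                    "n_samples": b.n_samples,
                }
            )
        )
    binned = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=["clip_id", "rater_id", "role", "bin_index", "bin_mean", "n_samples"]
        )
    )
    logger.info(
        "preprocessed %d streams -> %d binned series (%d excluded)",
        len(objs),
        len(rows),
        len(exclusions),
    )
    return PreprocessResult(binned=binned, exclusions=exclusions)


def binned_to_objects(binned: pd.DataFrame) -> dict[tuple[str, str], BinnedSeries]:
    """Index a binned table by (clip_id, rater_id)."""
    out: dict[tuple[str, str], BinnedSeries] = {}
    for (clip_id, rater_id), g in binned.groupby(["clip_id", "rater_id"], sort=True):
        g = g.sort_values("bin_index")
        role = str(g["role"].iloc[0]) if "role" in g else "perceiver"
        out[(str(clip_id), str(rater_id))] = BinnedSeries(
            str(clip_id),
            str(rater_id),
            g["bin_mean"].to_numpy(dtype=float),
            g["n_samples"].to_numpy(dtype=int),
            role,
        )
    return out


class ClipBinner(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: long streams table -> binned series table."""

    def __init__(self, bin_s: float = DEFAULT_BIN_S, n_edge_bins: int = DEFAULT_EDGE_BINS):
        self.bin_s = bin_s
        self.n_edge_bins = n_edge_bins

    def fit(self, X: pd.DataFrame, y=None) -> "ClipBinner":
        self.n_streams_ = X.groupby(["clip_id", "rater_id"]).ngroups
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        result = preprocess_streams(X, bin_s=self.bin_s, n_edge_bins=self.n_edge_bins)
        self.exclusions_ = result.exclusions
        return result.binned
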
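"""CSV dialects and round-trip readers/writers.

All tables are UTF-8 CSV with a header row and dot decimals; floating values
are written with 6 significant digits, which is the documented round-trip
precision.  Readers validate the header and basic semantics and raise
:class:`~eapipe.exceptions.ParseError` naming the offending column (and,
where recoverable, the line).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError
from .types import CONDITIONS, EffectSpec, StudyDataset

FLOAT_FORMAT = "%.6g"

STREAM_COLUMNS = ["clip_id", "role", "rater_id", "t_s", "value"]
CLIP_COLUMNS = ["clip_id", "target_id", "target_sex", "valence", "duration_s"]
BINNED_COLUMNS = ["clip_id", "rater_id", "role", "bin_index", "bin_mean", "n_samples"]


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{what}: missing column(s) {', '.join(missing)}")


def _read_csv(path: str | Path, what: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as exc:
        raise ParseError(f"{what}: {exc}") from exc


def write_streams(streams: pd.DataFrame, path: str | Path) -> None:
    streams[STREAM_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_streams(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, "streams file")
    _require_columns(df, STREAM_COLUMNS, "streams file")
    for col in ("t_s", "value"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise ParseError(f"streams file: column {col!r} is not numeric")
    for (clip_id, rater_id), g in df.groupby(["clip_id", "rater_id"]):
        t = g["t_s"].to_numpy()
        if t.size > 1 and np.any(np.diff(t) <= 0):
            bad = int(g.index[np.argmax(np.diff(t) <= 0) + 1]) + 2  # header + 1-based
            raise ParseError(
                f"streams file: non-monotone t_s for {rater_id}/{clip_id} near line {bad}"
            )
    return df


def write_clips(clips: pd.DataFrame, path: str | Path) -> None:
    clips[CLIP_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_clips(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, "clips file")
    _require_columns(df, CLIP_COLUMNS, "clips file")
    if df["clip_id"].duplicated().any():
        dupes = df.loc[df["clip_id"].duplicated(), "clip_id"].tolist()
        raise ParseError(f"clips file: duplicate clip_id {dupes[:3]}")
    return df


def write_binned(binned: pd.DataFrame, path: str | Path) -> None:
    binned[BINNED_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_binned(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, "binned file")
    _require_columns(df, BINNED_COLUMNS, "binned file")
    return df


def write_participants(participants: pd.DataFrame, path: str | Path) -> None:
    participants.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_participants(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, "participants file")
    _require_columns(df, ["participant_id", "condition"], "participants file")
    bad = set(df["condition"].unique()) - set(CONDITIONS)
    if bad:
        raise ParseError(f"participants file: unknown condition value(s) {sorted(bad)}")
    return df


def write_ea(ea: pd.DataFrame, path: str | Path) -> None:
    ea.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_ea(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, "EA table")
    _require_columns(df, ["perceiver_id", "clip_id", "r", "z", "excluded"], "EA table")
    return df


def write_truth(dataset: StudyDataset, path: str | Path) -> None:
    payload = {"seed": dataset.seed, "effects": dataset.truth.to_dict(),
               "assignments": dataset.assignments}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_truth(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    payload["effects"] = EffectSpec.from_dict(payload["effects"])
    return payload


def write_dataset(dataset: StudyDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a full StudyDataset (streams, clips, participants, truth sidecar)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "streams": out / "streams.csv",
        "clips": out / "clips.csv",
        "participants": out / "participants.csv",
        "truth": out / "truth.json",
    }
    write_streams(dataset.streams, paths["streams"])
    write_clips(dataset.clips, paths["clips"])
    write_participants(dataset.participants, paths["participants"])
    write_truth(dataset, paths["truth"])
    return paths


def read_dataset(out_dir: str | Path) -> StudyDataset:
    out = Path(out_dir)
    truth = read_truth(out / "truth.json")
    return StudyDataset(
        streams=read_streams(out / "streams.csv"),
        clips=read_clips(out / "clips.csv"),
        participants=read_participants(out / "participants.csv"),
        assignments=truth["assignments"],
        truth=truth["effects"],
        seed=int(truth["seed"]),
    )
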
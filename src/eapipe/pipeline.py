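"""End-to-end pipeline: simulate -> preprocess -> score -> analyze.

A :class:`PipelineConfig` carries every tunable (seed, cohort size, binning,
scoring method, effect truth) with defaults matching the study shape (54
perceivers x 16 clips).  :func:`run_pipeline` executes all stages, fits the
standard model set (condition; valence; target sex; condition x moderator
with simple slopes; valence-stratified moderation refits), and — when an
output directory is given — writes every artifact plus a manifest with the
seed and a config hash so identical config+seed reproduce identical output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from .exceptions import InvalidArgumentError
from .inference import MixedEAModel, build_analysis_table, drinking_summaries
from .preprocessing import preprocess_streams
from .scoring import score_dataset, summarize_ea
from .synthetic import generate_cohort
from .types import EffectSpec, StudyDataset
from . import io as eio

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    n_perceivers: int = 54
    n_clips: int = 16
    sample_rate_hz: float = 1.0
    clip_duration_s: float = 120.0
    bin_s: float = 5.0
    n_edge_bins: int = 1
    method: str = "ar_error_model"
    ar_order: int = 1
    df_method: str = "containment"
    ttest_method: str = "pooled"
    moderator: str = "r_audit"
    moderator_mean: float = 10.65
    moderator_sd: float = 3.90
    effects: EffectSpec = field(default_factory=EffectSpec)

    def validate(self) -> None:
        if self.n_clips % 2 != 0 or self.n_clips < 2:
            raise InvalidArgumentError(f"n_clips must be even and >= 2, got {self.n_clips}")
        if self.n_perceivers < 4:
            raise InvalidArgumentError("n_perceivers must be >= 4")
        if self.bin_s <= 0 or self.sample_rate_hz <= 0:
            raise InvalidArgumentError("bin_s and sample_rate_hz must be positive")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["effects"] = self.effects.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "effects" in d and isinstance(d["effects"], dict):
            d["effects"] = EffectSpec.from_dict(d["effects"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _fit_models(ea_analysis, config: PipelineConfig) -> dict[str, Any]:
    """The standard model set on a merged EA + participants table."""
    report: dict[str, Any] = {}

    condition_model = MixedEAModel(fixed=("condition",), df_method=config.df_method)
    condition_model.fit(ea_analysis)
    report["condition"] = condition_model.result_.to_dict()

    for factor in ("valence", "target_sex"):
        m = MixedEAModel(fixed=(factor,), df_method=config.df_method).fit(ea_analysis)
        report[factor] = m.result_.to_dict()

    moderation = MixedEAModel(
        fixed=("condition",), moderator=config.moderator, df_method=config.df_method
    ).fit(ea_analysis)
    slopes = moderation.simple_slopes()
    res = moderation._build_result(contrasts={k: dict(v) for k, v in slopes.items()})
    report["moderation"] = res.to_dict()

    # Fig-1-style figure data: model-implied cell means at +/- 1 SD
    lo = moderation.moderator_mean_ - moderation.moderator_sd_
    hi = moderation.moderator_mean_ + moderation.moderator_sd_
    report["figure_data"] = {
        "moderator_levels": {"low": lo, "high": hi},
        "cells": {
            f"{cond}_{label}": moderation.predict_z(cond, level)
            for cond in ("placebo", "alcohol")
            for label, level in (("low", lo), ("high", hi))
        },
    }

    for val in ("positive", "negative"):
        subset = ea_analysis[ea_analysis["valence"] == val]
        m = MixedEAModel(
            fixed=("condition",), moderator=config.moderator, df_method=config.df_method
        ).fit(subset)
        s = m.simple_slopes()
        report[f"moderation_{val}"] = m._build_result(
            contrasts={k: dict(v) for k, v in s.items()}
        ).to_dict()
    return report


def run_pipeline(
    config: PipelineConfig | None = None, out_dir: str | Path | None = None
) -> dict[str, Any]:
    """Run all stages; returns dict with dataset, binned, ea, report, manifest."""
    config = config or PipelineConfig()
    config.validate()

    logger.info("simulate: %d perceivers x %d clips, seed=%d",
                config.n_perceivers, config.n_clips, config.seed)
    dataset: StudyDataset = generate_cohort(
        n_perceivers=config.n_perceivers,
        n_clips=config.n_clips,
        effects=config.effects,
        moderator_mean=config.moderator_mean,
        moderator_sd=config.moderator_sd,
        sample_rate_hz=config.sample_rate_hz,
        seed=config.seed,
    )

    pre = preprocess_streams(dataset.streams, bin_s=config.bin_s, n_edge_bins=config.n_edge_bins)
    ea = score_dataset(
        pre.binned, dataset.clips, dataset.assignments,
        method=config.method, ar_order=config.ar_order,
    )
    ea_analysis = build_analysis_table(ea, dataset.participants)
    report = {
        "summary": summarize_ea(ea),
        "models": _fit_models(ea_analysis, config),
        "drinking": drinking_summaries(dataset.participants, ttest_method=config.ttest_method),
        "exclusions": pre.exclusions,
    }

    manifest = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "config": config.to_dict(),
        "n_streams": int(dataset.streams.groupby(["clip_id", "rater_id"]).ngroups),
        "n_ea_rows": int(len(ea)),
        "n_excluded": int(ea["excluded"].sum()),
    }

    artifacts = {
        "dataset": dataset, "binned": pre.binned, "ea": ea,
        "report": report, "manifest": manifest,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        eio.write_dataset(dataset, out)
        eio.write_binned(pre.binned, out / "binned.csv")
        eio.write_ea(ea, out / "ea.csv")
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        config.to_yaml(out / "config.yaml")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        logger.info("wrote pipeline artifacts to %s", out)
    return artifacts


def plot_simple_slopes(figure_data: dict, path: str | Path) -> None:
    """Two-panel interaction plot (Fisher-z cell means at low/high moderator)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = figure_data["cells"]
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, style in (("low", "o-"), ("high", "s--")):
        ax.plot(
            ["placebo", "alcohol"],
            [cells[f"placebo_{label}"], cells[f"alcohol_{label}"]],
            style,
            label=f"{label} moderator ({figure_data['moderator_levels'][label]:.1f})",
        )
    ax.set_ylabel("EA (Fisher z)")
    ax.set_xlabel("condition")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
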
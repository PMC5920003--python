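"""Synthetic study generator.

Emulates the shape of a placebo-controlled alcohol-administration study of
empathic accuracy: targets narrate ~2-min positive or negative
autobiographical events while self-rating their affect on a 1-9 dial;
perceivers watch 16 clips (8 positive, 8 negative) and continuously rate how
the target felt.  The generator produces target trajectories with serial
autocorrelation (a mean-reverting AR(1) around a valence-dependent anchor),
perceiver streams calibrated to a known tracking correlation, a participant
table with questionnaire scores (AUDIT items with the revised items-1-8
total, drinking quantity/frequency, drinking motives, social anxiety, urge
ratings, breath-alcohol readings), and records the full ground-truth effect
structure so downstream stages have a parameter-recovery surface.

Everything is driven by a single ``numpy`` Generator, so a fixed seed
reproduces a dataset byte-for-byte in exported CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .exceptions import InvalidArgumentError
from .preprocessing import sample_clip_order
from .types import (
    ClipMeta,
    DIAL_MAX,
    DIAL_MIN,
    EffectSpec,
    RatingStream,
    StudyDataset,
)

logger = logging.getLogger(__name__)

POSITIVE_ANCHOR = 6.5
NEGATIVE_ANCHOR = 3.5
DEFAULT_AR_COEF = 0.8
DEFAULT_NOISE_SD = 0.6
DEFAULT_RATE_HZ = 1.0
DEFAULT_CLIP_DURATION_S = 120.0

# study-shaped cohort defaults
DEFAULT_N_PERCEIVERS = 54
DEFAULT_N_CLIPS = 16
DEFAULT_MODERATOR_MEAN = 10.65
DEFAULT_MODERATOR_SD = 3.90


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _ar1(n: int, coef: float, innov_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) sample of length n (mean 0)."""
    e = rng.normal(0.0, innov_sd, n)
    if coef == 0.0:
        return e
    sd_stat = innov_sd / np.sqrt(1.0 - coef * coef)
    x_prev = rng.normal(0.0, sd_stat)
    y, _ = lfilter([1.0], [1.0, -coef], e, zi=np.array([coef * x_prev]))
    return y


def generate_target_trajectory(
    duration_s: float = DEFAULT_CLIP_DURATION_S,
    valence: str = "positive",
    ar_coef: float = DEFAULT_AR_COEF,
    noise_sd: float = DEFAULT_NOISE_SD,
    sample_rate_hz: float = DEFAULT_RATE_HZ,
    seed: int | np.random.Generator = 0,
    clip_id: str = "clip",
    target_id: str = "target",
) -> RatingStream:
    """Simulate a target's self-rating stream for one clip.

    A mean-reverting AR(1) process around a valence-dependent anchor (above
    the neutral dial midpoint for positive clips, below for negative),
    hard-clipped to the dial range [1, 9].
    """
    if not duration_s > 0:
        raise InvalidArgumentError("duration_s must be positive")
    if not sample_rate_hz > 0:
        raise InvalidArgumentError("sample_rate_hz must be positive")
    if not 0 <= ar_coef < 1:
        raise InvalidArgumentError("ar_coef must be in [0, 1) for stationarity")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    if valence not in ("positive", "negative"):
        raise InvalidArgumentError(f"valence must be 'positive' or 'negative', got {valence!r}")
    rng = _rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    if n < 1:
        raise InvalidArgumentError("duration too short for one sample")
    anchor = POSITIVE_ANCHOR if valence == "positive" else NEGATIVE_ANCHOR
    x = _ar1(n, ar_coef, noise_sd, rng)
    value = np.clip(anchor + x, DIAL_MIN, DIAL_MAX)
    t = np.arange(n) / sample_rate_hz
    return RatingStream(clip_id=clip_id, rater_id=target_id, role="target", t_s=t, value=value)


def generate_perceiver_stream(
    target: RatingStream,
    target_r: float,
    lag_s: float = 0.0,
    noise_ar: float = DEFAULT_AR_COEF,
    seed: int | np.random.Generator = 0,
    perceiver_id: str = "perceiver",
) -> RatingStream:
    """Simulate a perceiver stream tracking ``target`` at a known correlation.

    The (optionally lagged) target is standardized and mixed with an
    independent unit-variance AR(1) noise series with weights
    (r, sqrt(1 - r^2)), so the expected Pearson correlation with the target
    equals ``target_r``; the mixture is mapped back to the target's dial
    location/scale and clipped to [1, 9] (clipping can shrink the realized
    correlation slightly).  The noise persistence defaults to the target's
    AR coefficient so that downstream interval averaging attenuates signal
    and noise equally and the calibration survives binning.
    """
    if len(target) == 0:
        raise InvalidArgumentError("target stream is empty")
    if not -1 < target_r < 1:
        raise InvalidArgumentError("|target_r| must be < 1")
    if lag_s < 0:
        raise InvalidArgumentError("lag_s must be >= 0")
    if not 0 <= noise_ar < 1:
        raise InvalidArgumentError("noise_ar must be in [0, 1)")
    rng = _rng(seed)
    n = len(target)
    dt = float(np.median(np.diff(target.t_s))) if n > 1 else 1.0
    k = int(round(lag_s / dt))
    if k >= n:
        raise InvalidArgumentError("lag longer than the clip")

    src = target.value if k == 0 else np.concatenate(
        [np.full(k, target.value[0]), target.value[: n - k]]
    )
    mu, sd = float(src.mean()), float(src.std())
    if sd == 0:
        # constant target: tracking is undefined, emit pure noise around it
        zt = np.zeros(n)
        sd = 1.0
    else:
        zt = (src - mu) / sd
    innov = np.sqrt(1.0 - noise_ar * noise_ar) if noise_ar else 1.0
    noise = _ar1(n, noise_ar, innov, rng)
    w = target_r * zt + np.sqrt(1.0 - target_r * target_r) * noise
    value = np.clip(target.value.mean() + w * target.value.std(), DIAL_MIN, DIAL_MAX)
    return RatingStream(
        clip_id=target.clip_id, rater_id=perceiver_id, role="perceiver",
        t_s=target.t_s.copy(), value=value,
    )


def generate_clip_set(
    n_clips: int = DEFAULT_N_CLIPS,
    duration_s: float = DEFAULT_CLIP_DURATION_S,
) -> list[ClipMeta]:
    """Balanced clip set: n_clips/2 targets, each narrating one positive and
    one negative event, target sex alternating."""
    if n_clips % 2 != 0 or n_clips < 2:
        raise InvalidArgumentError("n_clips must be a positive even number")
    n_targets = n_clips // 2
    clips = []
    for i in range(n_targets):
        target_id = f"t{i + 1:02d}"
        sex = "male" if i % 2 == 0 else "female"
        for valence in ("positive", "negative"):
            clips.append(
                ClipMeta(
                    clip_id=f"{target_id}_{valence[:3]}",
                    target_id=target_id,
                    target_sex=sex,
                    valence=valence,
                    duration_s=duration_s,
                )
            )
    return clips


def clips_to_frame(clips: list[ClipMeta]) -> pd.DataFrame:
    return pd.DataFrame([asdict(c) for c in clips])


@dataclass(frozen=True)
class QuestionnaireConfig:
    """Distributional targets for the participant table.

    Defaults follow the study's baseline table: an AUDIT items-1-8 total
    around 10.65 (SD ~3.9), daily-drink counts coupled to the AUDIT factor
    at rho ~0.7, drinking-motive subscales in the 6-17 range, social-anxiety
    totals around 16, and urge-to-drink ratings near the scale midpoint.
    """

    audit_total_mean: float = DEFAULT_MODERATOR_MEAN
    audit_total_sd: float = DEFAULT_MODERATOR_SD
    audit_item_noise_sd: float = 0.6
    drinks_audit_rho: float = 0.7
    avg_drinks_mean: float = 4.25
    avg_drinks_sd: float = 1.3
    peak_drinks_mean: float = 8.24
    peak_drinks_sd: float = 3.9
    dmq_social: tuple[float, float] = (16.06, 4.3)
    dmq_enhancement: tuple[float, float] = (14.07, 4.6)
    dmq_coping: tuple[float, float] = (7.54, 2.5)
    dmq_conformity: tuple[float, float] = (6.33, 2.0)
    sias: tuple[float, float] = (15.85, 8.5)
    urge: tuple[float, float] = (4.9, 2.4)
    weight: tuple[float, float] = (80.0, 13.0)


def generate_questionnaires(
    n: int,
    seed: int | np.random.Generator = 0,
    config: QuestionnaireConfig | None = None,
) -> pd.DataFrame:
    """Generate a participant questionnaire table.

    AUDIT items load on a single latent hazardous-drinking factor so the
    revised total (items 1-8) has the configured mean/SD and correlates with
    the daily-drink counts.  Items 9 and 10 are generated but flagged
    unusable (column ``audit_9_10_usable`` = False) and excluded from the
    revised total, mirroring an instrument misprint.
    """
    if n <= 0:
        raise InvalidArgumentError("n must be positive")
    cfg = config or QuestionnaireConfig()
    rng = _rng(seed)

    factor = rng.normal(0.0, 1.0, n)
    item_mean = cfg.audit_total_mean / 8.0
    e_sd = cfg.audit_item_noise_sd
    loading = np.sqrt(max(cfg.audit_total_sd**2 - 8 * e_sd**2, 0.01)) / 8.0
    items = {}
    for i in range(1, 11):
        mu = item_mean if i <= 8 else 1.0
        latent = mu + loading * factor + rng.normal(0.0, e_sd, n)
        items[f"audit_{i}"] = np.clip(np.round(latent), 0, 4).astype(int)
    audit = pd.DataFrame(items)
    r_audit = audit[[f"audit_{i}" for i in range(1, 9)]].sum(axis=1)

    rho = cfg.drinks_audit_rho
    mix = lambda: rho * factor + np.sqrt(1 - rho * rho) * rng.normal(0.0, 1.0, n)  # noqa: E731
    avg_drinks = np.round(np.maximum(cfg.avg_drinks_mean + cfg.avg_drinks_sd * mix(), 0.5), 2)
    peak_drinks = np.round(
        np.maximum(cfg.peak_drinks_mean + cfg.peak_drinks_sd * mix(), avg_drinks), 2
    )

    def scale(dist: tuple[float, float], lo: float, hi: float) -> np.ndarray:
        return np.clip(np.round(rng.normal(dist[0], dist[1], n)), lo, hi).astype(int)

    table = pd.DataFrame(
        {
            "participant_id": [f"p{i + 1:03d}" for i in range(n)],
            **{c: audit[c] for c in audit.columns},
            "r_audit": r_audit.astype(int),
            "audit_9_10_usable": False,
            "hazard_flag": (r_audit >= 8).to_numpy(),
            "dmq_social": scale(cfg.dmq_social, 5, 25),
            "dmq_enhancement": scale(cfg.dmq_enhancement, 5, 25),
            "dmq_coping": scale(cfg.dmq_coping, 5, 25),
            "dmq_conformity": scale(cfg.dmq_conformity, 5, 25),
            "sias": scale(cfg.sias, 0, 76),
            "urge_baseline": scale(cfg.urge, 0, 10),
            "urge_pre_drink": scale(cfg.urge, 0, 10),
            "urge_post_drink": scale(cfg.urge, 0, 10),
            "urge_post_task": scale(cfg.urge, 0, 10),
            "avg_daily_drinks": avg_drinks,
            "peak_daily_drinks": peak_drinks,
            "smast": rng.integers(0, 3, n),
            "smast_flag": True,  # inclusion requires SMAST <= 2
            "weight_kg": np.round(np.clip(rng.normal(*cfg.weight, n), 55, 130), 1),
        }
    )
    return table


@dataclass(frozen=True)
class VodkaServing:
    """Volume of vodka to serve, split equally over two glasses."""

    total_ml: float
    glass_ml: float


def compute_vodka_volume(
    weight_kg: float,
    dose: float = 0.56,
    abv: float = 0.375,
    convention: str = "ml_per_kg",
    ethanol_density: float = 0.789,
) -> VodkaServing:
    """Per-weight vodka volume for a 0.56-per-kg dose of alcohol.

    Two dose conventions are supported because the arithmetic differs by the
    density of ethanol: ``ml_per_kg`` treats the dose as millilitres of pure
    ethanol per kg body weight (weight * dose / abv), ``g_per_kg`` as grams
    per kg (weight * dose / (abv * density)).  Neither is asserted as any
    particular study's computation; ``ml_per_kg`` is the default because it
    reproduces typical served-volume ranges for 57-99 kg participants.
    """
    if not weight_kg > 0:
        raise InvalidArgumentError("weight_kg must be positive")
    if not 0 < abv <= 1:
        raise InvalidArgumentError("abv must be in (0, 1]")
    if convention == "ml_per_kg":
        total = weight_kg * dose / abv
    elif convention == "g_per_kg":
        total = weight_kg * dose / (abv * ethanol_density)
    else:
        raise InvalidArgumentError(f"unknown convention {convention!r}")
    return VodkaServing(total_ml=total, glass_ml=total / 2.0)


def draw_true_z(
    effects: EffectSpec,
    positive: np.ndarray,
    alcohol: np.ndarray,
    moderator_std: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """True Fisher-z scores for an (n_perceivers x n_clips) design.

    ``positive`` is (n_clips,), ``alcohol`` and ``moderator_std`` are
    (n_perceivers,); returns an (n_perceivers, n_clips) matrix including the
    perceiver random intercept and the pair-level residual.
    """
    n_p = alcohol.size
    n_c = positive.size
    fixed = effects.linear_predictor(
        positive[None, :], alcohol[:, None], moderator_std[:, None]
    )
    u = rng.normal(0.0, effects.sd_perceiver, n_p)
    eps = rng.normal(0.0, effects.sd_residual, (n_p, n_c))
    return fixed + u[:, None] + eps


def generate_ea_z_table(
    n_perceivers: int = DEFAULT_N_PERCEIVERS,
    n_clips: int = DEFAULT_N_CLIPS,
    effects: EffectSpec | None = None,
    moderator_mean: float = DEFAULT_MODERATOR_MEAN,
    moderator_sd: float = DEFAULT_MODERATOR_SD,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw an analysis-ready EA table directly at the Fisher-z level.

    This samples the same generative linear model the cohort generator uses
    to set per-pair true correlations, skipping stream synthesis and scoring.
    It is the null/power simulation surface for the inference stage (the
    stream -> scoring path is calibration-tested separately).
    """
    effects = effects or EffectSpec()
    rng = _rng(seed)
    clips = generate_clip_set(n_clips)
    positive = np.array([1.0 if c.valence == "positive" else 0.0 for c in clips])
    alcohol = np.array([float(i % 2) for i in range(n_perceivers)])
    m_raw = np.clip(np.round(rng.normal(moderator_mean, moderator_sd, n_perceivers)), 0, 32)
    m_std = (m_raw - moderator_mean) / moderator_sd
    z = draw_true_z(effects, positive, alcohol, m_std, rng)
    rows = pd.DataFrame(
        {
            "perceiver_id": np.repeat([f"p{i + 1:03d}" for i in range(n_perceivers)], n_clips),
            "clip_id": np.tile([c.clip_id for c in clips], n_perceivers),
            "valence": np.tile([c.valence for c in clips], n_perceivers),
            "target_sex": np.tile([c.target_sex for c in clips], n_perceivers),
            "z": z.ravel(),
            "condition": np.repeat(
                ["alcohol" if a else "placebo" for a in alcohol], n_clips
            ),
            "r_audit": np.repeat(m_raw, n_clips),
            "excluded": False,
        }
    )
    rows["r"] = np.tanh(rows["z"])
    return rows


def generate_cohort(
    n_perceivers: int = DEFAULT_N_PERCEIVERS,
    n_clips: int = DEFAULT_N_CLIPS,
    clip_set: list[ClipMeta] | None = None,
    effects: EffectSpec | None = None,
    moderator_mean: float = DEFAULT_MODERATOR_MEAN,
    moderator_sd: float = DEFAULT_MODERATOR_SD,
    sample_rate_hz: float = DEFAULT_RATE_HZ,
    ar_coef: float = DEFAULT_AR_COEF,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    questionnaire_config: QuestionnaireConfig | None = None,
) -> StudyDataset:
    """Generate a full study: streams, clip metadata, participants, truth.

    Perceivers alternate placebo/alcohol (near-equal arms at any n); each
    watches all ``n_clips`` clips in an order satisfying the presentation
    constraints.  The per perceiver x clip true tracking correlation is
    tanh of the ground-truth linear predictor (see :class:`EffectSpec`),
    with the moderator being the generated revised-AUDIT total standardized
    by the stated mean/SD.
    """
    if n_clips % 2 != 0:
        raise InvalidArgumentError("n_clips must be even (balanced valence)")
    effects = effects or EffectSpec()
    clip_set = clip_set or generate_clip_set(n_clips)
    by_valence = {"positive": 0, "negative": 0}
    for c in clip_set:
        by_valence[c.valence] += 1
    if by_valence["positive"] < n_clips // 2 or by_valence["negative"] < n_clips // 2:
        raise InvalidArgumentError("clip_set must hold n_clips/2 clips of each valence")

    rng = np.random.default_rng(seed)
    qcfg = questionnaire_config or QuestionnaireConfig(
        audit_total_mean=moderator_mean, audit_total_sd=moderator_sd
    )
    participants = generate_questionnaires(n_perceivers, seed=rng, config=qcfg)
    conditions = ["placebo" if i % 2 == 0 else "alcohol" for i in range(n_perceivers)]
    participants["condition"] = conditions
    alcohol = np.array([c == "alcohol" for c in conditions], dtype=float)
    participants["vodka_ml"] = np.where(
        alcohol > 0,
        np.round([compute_vodka_volume(w).total_ml for w in participants["weight_kg"]], 2),
        0.0,
    )
    participants["peak_bac"] = np.where(
        alcohol > 0, np.round(np.maximum(rng.normal(0.25, 0.06, n_perceivers), 0.05), 3), 0.0
    )

    # select a balanced subset if the clip set is larger than n_clips
    pos = [c for c in clip_set if c.valence == "positive"][: n_clips // 2]
    neg = [c for c in clip_set if c.valence == "negative"][: n_clips // 2]
    used_clips = pos + neg
    positive = np.array([1.0 if c.valence == "positive" else 0.0 for c in used_clips])

    m_raw = participants["r_audit"].to_numpy(dtype=float)
    m_std = (m_raw - moderator_mean) / moderator_sd
    z_true = draw_true_z(effects, positive, alcohol, m_std, rng)
    r_true = np.tanh(z_true)

    targets = {
        c.clip_id: generate_target_trajectory(
            duration_s=c.duration_s,
            valence=c.valence,
            ar_coef=ar_coef,
            noise_sd=noise_sd,
            sample_rate_hz=sample_rate_hz,
            seed=rng,
            clip_id=c.clip_id,
            target_id=c.target_id,
        )
        for c in used_clips
    }

    assignments: dict[str, list[str]] = {}
    frames = []
    for c in used_clips:
        s = targets[c.clip_id]
        frames.append(
            pd.DataFrame(
                {"clip_id": s.clip_id, "role": "target", "rater_id": s.rater_id,
                 "t_s": s.t_s, "value": s.value}
            )
        )
    clip_index = {c.clip_id: j for j, c in enumerate(used_clips)}
    for i, pid in enumerate(participants["participant_id"]):
        order = sample_clip_order(used_clips, seed=rng)
        assignments[pid] = [c.clip_id for c in order]
        for c in order:
            ps = generate_perceiver_stream(
                targets[c.clip_id],
                target_r=float(r_true[i, clip_index[c.clip_id]]),
                seed=rng,
                perceiver_id=pid,
            )
            frames.append(
                pd.DataFrame(
                    {"clip_id": ps.clip_id, "role": "perceiver", "rater_id": ps.rater_id,
                     "t_s": ps.t_s, "value": ps.value}
                )
            )
    streams = pd.concat(frames, ignore_index=True)
    logger.info(
        "generated cohort: %d perceivers x %d clips (%d stream rows)",
        n_perceivers, n_clips, len(streams),
    )
    return StudyDataset(
        streams=streams,
        clips=clips_to_frame(used_clips),
        participants=participants,
        assignments=assignments,
        truth=effects,
        seed=seed,
    )
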
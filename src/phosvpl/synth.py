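"""Synthetic cohorts, reading responses, gaze traces, and toy video.

Replaces the human-subjects data stream so every pipeline stage is
testable end to end.  The cohort generator follows the same additive
latent model the decoder assumes: each subject's true acuity starts at a
baseline draw and improves by ``beta_R`` per reading test taken and
``beta_V`` per video watched, with no forgetting (an exponential-
saturation variant is available for misspecification experiments).  At
each scheduled reading test, word-level responses are Bernoulli draws
from a logistic psychometric function of print size centered on the
current true acuity, and sentence durations come from a gamma per-word
reading-time model.  Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import t as t_dist

from phosvpl.design import (
    Schedule,
    VIDEOS_BEFORE,
    build_schedule,
    decode_from_spans,
    extract_spans,
)
from phosvpl.field import ScreenGeometry
from phosvpl.gaze import GazeTrace
from phosvpl.psychometrics import DEFAULT_FONTS, fit_acuity

__all__ = [
    "CohortConfig",
    "gen_cohort",
    "measure_cohort",
    "recovery_experiment",
    "gen_sentences",
    "gen_gaze",
    "gen_frames",
]

_WORD_BANK = (
    "we will climb only to be better able give a helping hand the "
    "children found three small boxes under old wooden stairs my mother "
    "asked them come home before dark every bird sang from tall green "
    "trees near quiet river they walked slowly together along sandy road "
    "father read us story about brave young sailor her friends played "
    "outside until it began rain"
).split()


@dataclass(frozen=True)
class CohortConfig:
    """Generating parameters for a synthetic training cohort.

    Defaults anchor to the reference study conditions: eight subjects
    starting at 1.28 +/- 0.04 logMAR, per-session improvements of -0.015
    logMAR per reading test and -0.01/3 logMAR per video, a psychometric
    slope of 15 per logMAR, and two sentences of twelve words per print
    size per test.
    """

    n_subjects: int = 8
    baseline_mean: float = 1.28
    baseline_sd: float = 0.04
    beta_R: float = -0.015
    beta_V: float = -0.01 / 3.0
    slope: float = 15.0
    fonts: tuple[float, ...] = DEFAULT_FONTS
    words_per_sentence: int = 12
    sentences_per_font: int = 2
    #: additive single-test acuity noise (logMAR); applied only when
    #: noise_model is "additive" or "both" — word-level Bernoulli noise is
    #: always present in the responses
    measurement_noise_sd: float = 0.04
    noise_model: str = "bernoulli"  # "bernoulli" | "additive" | "both"
    #: mean per-word reading time, seconds (phosphene view / natural view)
    word_time_s: float = 5.0
    word_time_natural_s: float = 0.43
    word_time_shape: float = 4.0
    include_natural: bool = True
    #: 0 disables saturation (pure additive model); otherwise improvements
    #: shrink as acuity approaches baseline + saturation_floor
    saturation_floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.baseline_sd < 0 or self.measurement_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.noise_model not in ("bernoulli", "additive", "both"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


def _latent_acuity(config: CohortConfig, baseline: float, n_tests: int, n_videos: int) -> float:
    """True acuity after ``n_tests`` reading influences and ``n_videos`` videos."""
    gain = config.beta_R * n_tests + config.beta_V * n_videos
    if config.saturation_floor:
        # exponential approach to baseline - floor instead of a straight line
        span = config.saturation_floor
        gain = -span * (1.0 - np.exp(gain / span))
    return baseline + gain


def gen_cohort(
    config: CohortConfig,
    schedule: Schedule | None = None,
    *,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic cohort.

    Returns ``(latent, trials)``: the per-subject true acuity at every
    test position, and the word-level trial table (one row per sentence)
    ready for :func:`phosvpl.psychometrics.profile_from_trials`.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if schedule is None:
        schedule = build_schedule(config.n_subjects, seed=int(rng.integers(2**31)))
    if schedule.n_subjects != config.n_subjects:
        raise ValueError("schedule and config disagree on cohort size")

    latent_rows = []
    trial_rows = []
    fonts = np.asarray(config.fonts, dtype=float)
    for subj in schedule.subjects:
        baseline = rng.normal(config.baseline_mean, config.baseline_sd)
        positions = schedule.positions(subj)
        for k, pos in enumerate(positions):
            true_acuity = _latent_acuity(config, baseline, k, VIDEOS_BEFORE[pos])
            latent_rows.append(
                {"subject": subj, "position": pos, "true_acuity": true_acuity}
            )
            measured = true_acuity
            if config.noise_model in ("additive", "both"):
                measured += rng.normal(0.0, config.measurement_noise_sd)
            for font in fonts:
                p = float(expit(config.slope * (font - measured)))
                for s in range(config.sentences_per_font):
                    n_words = config.words_per_sentence
                    if config.noise_model == "additive":
                        # response noise lives entirely in the measured
                        # acuity: words carry the exact expected count
                        correct = n_words * p
                    else:
                        correct = int(rng.binomial(n_words, p))
                    dur = rng.gamma(
                        config.word_time_shape,
                        config.word_time_s / config.word_time_shape,
                        n_words,
                    ).sum()
                    trial_rows.append(
                        {
                            "subject": subj,
                            "position": pos,
                            "condition": "P1000",
                            "font_logmar": font,
                            "sentence": s,
                            "words_total": n_words,
                            "words_correct": correct,
                            "duration_s": float(dur),
                        }
                    )
                    if config.include_natural:
                        nat_dur = rng.gamma(
                            config.word_time_shape,
                            config.word_time_natural_s / config.word_time_shape,
                            n_words,
                        ).sum()
                        trial_rows.append(
                            {
                                "subject": subj,
                                "position": pos,
                                "condition": "Natural",
                                "font_logmar": font,
                                "sentence": s,
                                "words_total": n_words,
                                "words_correct": n_words,
                                "duration_s": float(nat_dur),
                            }
                        )
    return pd.DataFrame(latent_rows), pd.DataFrame(trial_rows)


def measure_cohort(trials: pd.DataFrame, *, method: str = "ml") -> pd.DataFrame:
    """Fit equivalent acuity at every subject x test position.

    Pools word counts per print size within each phosphene-view reading
    test and fits the psychometric curve.  Returns columns ``subject,
    position, acuity, usable, extrapolated``.
    """
    rows = []
    pv = trials[trials["condition"] == "P1000"]
    for (subj, pos), g in pv.groupby(["subject", "position"], sort=False):
        agg = g.groupby("font_logmar", sort=True)[["words_correct", "words_total"]].sum()
        fit = fit_acuity(
            agg.index.to_numpy(), agg["words_correct"], agg["words_total"],
            method=method,
        )
        rows.append(
            {
                "subject": subj,
                "position": pos,
                "acuity": fit.acuity_logmar,
                "usable": fit.usable,
                "extrapolated": fit.extrapolated,
            }
        )
    return pd.DataFrame(rows)


def recovery_experiment(
    config: CohortConfig,
    n_replicates: int = 200,
    seed: int = 0,
    *,
    schedule: Schedule | None = None,
    fit_method: str = "ml",
    ci_level: float = 0.95,
) -> dict:
    """Monte-Carlo parameter recovery for the full pipeline.

    Each replicate generates a cohort, fits per-test acuities, extracts
    span improvements, and decodes the learning rates.  Reports estimator
    bias, RMSE, and the empirical coverage of per-subject t-intervals for
    ``beta_R`` and ``beta_V``, plus the fraction of replicates recovering
    the |beta_R| > |beta_V| ordering and the acuity-fit error against the
    latent truth.  Replicate failures are collected, not fatal.
    """
    if n_replicates < 1:
        raise ValueError("need at least 1 replicate")
    rng = np.random.default_rng(seed)
    if schedule is None:
        schedule = build_schedule(config.n_subjects, seed=int(rng.integers(2**31)))

    est_R, est_V = [], []
    cover_R, cover_V = [], []
    acuity_err = []
    ordering = []
    errors = []
    for _rep in range(n_replicates):
        rep_seed = int(rng.integers(2**31))
        try:
            latent, trials = gen_cohort(config, schedule, seed=rep_seed)
            acuities = measure_cohort(trials, method=fit_method)
            spans, _ = extract_spans(acuities, schedule)
            rates = decode_from_spans(spans, per_subject=True)
        except Exception as exc:  # pragma: no cover - collected for report
            errors.append(repr(exc))
            continue
        est_R.append(rates.beta_R)
        est_V.append(rates.beta_V)
        ordering.append(abs(rates.beta_R) > abs(rates.beta_V))
        merged = acuities.merge(latent, on=["subject", "position"])
        ok = merged["usable"].to_numpy(dtype=bool)
        acuity_err.extend(
            (merged.loc[ok, "acuity"] - merged.loc[ok, "true_acuity"]).tolist()
        )
        ps = rates.per_subject
        if ps is not None and len(ps) >= 3:
            tcrit = t_dist.ppf(0.5 + ci_level / 2.0, len(ps) - 1)
            for col, truth, bucket in [
                ("beta_R", config.beta_R, cover_R),
                ("beta_V", config.beta_V, cover_V),
            ]:
                m = ps[col].mean()
                half = tcrit * ps[col].std(ddof=1) / np.sqrt(len(ps))
                bucket.append(m - half <= truth <= m + half)

    def _stats(values: list[float], truth: float) -> dict:
        v = np.asarray(values)
        return {
            "truth": truth,
            "mean": float(v.mean()),
            "bias": float(v.mean() - truth),
            "rmse": float(np.sqrt(((v - truth) ** 2).mean())),
            "se_of_mean": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan,
        }

    ae = np.asarray(acuity_err)
    return {
        "n_replicates": len(est_R),
        "beta_R": _stats(est_R, config.beta_R),
        "beta_V": _stats(est_V, config.beta_V),
        "ordering_fraction": float(np.mean(ordering)) if ordering else np.nan,
        "ci_coverage": {
            "nominal": ci_level,
            "beta_R": float(np.mean(cover_R)) if cover_R else np.nan,
            "beta_V": float(np.mean(cover_V)) if cover_V else np.nan,
        },
        "acuity_fit": {
            "bias": float(ae.mean()) if len(ae) else np.nan,
            "rmse": float(np.sqrt((ae**2).mean())) if len(ae) else np.nan,
        },
        "errors": errors,
    }


def gen_sentences(
    n: int,
    *,
    word_count_range: tuple[int, int] = (10, 14),
    seed: int = 0,
) -> list[str]:
    """Generate simple three-line sentences from a fixed word bank.

    Each sentence has a word count drawn uniformly from
    ``word_count_range`` (inclusive) and is split across three lines as
    evenly as possible, echoing the structure of standardized
    reading-acuity sentences without reproducing any corpus.
    """
    lo, hi = word_count_range
    if not 3 <= lo <= hi:
        raise ValueError("word_count_range must satisfy 3 <= lo <= hi")
    rng = np.random.default_rng(seed)
    sentences = []
    for _ in range(n):
        k = int(rng.integers(lo, hi + 1))
        words = [_WORD_BANK[i] for i in rng.integers(0, len(_WORD_BANK), k)]
        per_line = -(-k // 3)
        lines = [
            " ".join(words[i : i + per_line]) for i in range(0, k, per_line)
        ]
        sentences.append("\n".join(lines))
    return sentences


def gen_gaze(
    task: str,
    duration_s: float,
    *,
    screen: ScreenGeometry | None = None,
    sample_rate_hz: float = 250.0,
    seed: int = 0,
) -> GazeTrace:
    """Generate a synthetic gaze trace for a reading or video task.

    ``task="reading"`` produces exactly three monotone left-to-right
    sweeps (one per sentence line) joined by fast return saccades, with
    small vertical jitter.  ``task="video"`` produces a mean-reverting
    random walk around screen center, emulating casual viewing.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if screen is None:
        screen = ScreenGeometry()
    rng = np.random.default_rng(seed)
    n = max(int(round(duration_s * sample_rate_hz)), 6)
    t = np.arange(n) * (1000.0 / sample_rate_hz)
    w, h = screen.width_px, screen.height_px

    if task == "reading":
        x = np.empty(n)
        y = np.empty(n)
        x0, x1 = 0.1 * w, 0.9 * w
        line_y = np.array([0.35, 0.5, 0.65]) * h
        sweep = n // 3
        for line in range(3):
            a = line * sweep
            b = n if line == 2 else (line + 1) * sweep
            # a handful of samples at the end of lines 1-2 form the return
            ret = 0 if line == 2 else max(2, (b - a) // 20)
            fwd = b - a - ret
            x[a : a + fwd] = np.linspace(x0, x1, fwd)
            y[a : a + fwd] = line_y[line] + rng.normal(0, 0.004 * h, fwd)
            if ret:
                x[a + fwd : b] = np.linspace(x1, x0, ret)
                y[a + fwd : b] = np.linspace(line_y[line], line_y[line + 1], ret)
    elif task == "video":
        x = np.empty(n)
        y = np.empty(n)
        x[0], y[0] = w / 2.0, h / 2.0
        step = 0.01 * w
        for i in range(1, n):
            x[i] = x[i - 1] + 0.02 * (w / 2.0 - x[i - 1]) + rng.normal(0, step)
            y[i] = y[i - 1] + 0.02 * (h / 2.0 - y[i - 1]) + rng.normal(0, step)
        np.clip(x, 0, w - 1, out=x)
        np.clip(y, 0, h - 1, out=y)
    else:
        raise ValueError(f"unknown task {task!r}")

    samples = pd.DataFrame(
        {"t_ms": t, "x_px": x, "y_px": y, "valid": np.ones(n, dtype=bool)}
    )
    return GazeTrace(samples, screen)


def gen_frames(
    n_frames: int,
    *,
    width: int = 160,
    height: int = 90,
    static: bool = False,
    seed: int = 0,
) -> list[np.ndarray]:
    """Generate toy grayscale video frames (drifting bright shapes).

    Frames are luminance grids in [0, 1]: a bright rectangle drifting
    horizontally and a dimmer disc drifting vertically over a dark
    background.  ``static=True`` freezes the motion (every frame equal),
    useful for renderer invariance checks.
    """
    if n_frames < 1:
        raise ValueError("need at least 1 frame")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height, 0:width]
    rect_w, rect_h = width // 5, height // 3
    r = min(width, height) // 6
    x_rect0 = rng.integers(0, width - rect_w)
    y_rect = height // 4
    x_disc = width // 2
    y_disc0 = rng.integers(r, height - r)
    frames = []
    for i in range(n_frames):
        k = 0 if static else i
        frame = np.full((height, width), 0.05)
        xr = (x_rect0 + 2 * k) % (width - rect_w)
        frame[y_rect : y_rect + rect_h, xr : xr + rect_w] = 0.9
        yd = (y_disc0 + k) % (height - 2 * r) + r
        disc = (xx - x_disc) ** 2 + (yy - yd) ** 2 <= r**2
        frame[disc] = 0.6
        frames.append(frame)
    return frames
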
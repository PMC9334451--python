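"""Reading-trial scoring and equivalent-acuity psychometrics.

A reading test presents short three-line sentences at a ladder of print
sizes (logMAR 0.9–1.4 by default).  Per-trial word scoring yields reading
accuracy (percent of words read correctly) and reading speed (correctly
read words per minute).  Accuracy versus print size follows a sigmoid;
*equivalent acuity* is the print size at which the fitted curve crosses
50% correct.

The fit is a maximum-likelihood logistic on word-level Bernoulli counts
with asymptotes fixed at 0 and 100%, so the curve midpoint is exactly the
50% point.  With the small number of sentences per test typical of a
longitudinal design, the word-count likelihood uses strictly more
information than least squares on per-font percentages (which remains
available as a fallback).  Profiles where every word is correct or every
word is wrong carry no information about the midpoint beyond a bound; such
fits are returned censored rather than raising.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.special import expit

__all__ = [
    "ReadingTrial",
    "ReadingProfile",
    "PsychometricFit",
    "score_trial",
    "accuracy_and_speed",
    "logmar_from_snellen",
    "profile_from_trials",
    "fit_acuity",
    "fit_acuity_bootstrap",
]

DEFAULT_FONTS = (0.9, 1.0, 1.1, 1.2, 1.3, 1.4)

_PUNCT_TABLE = str.maketrans("", "", string.punctuation)


@dataclass(frozen=True)
class ReadingTrial:
    """One sentence read under one viewing condition."""

    subject: str
    session: int
    condition: str  # "P1000" or "Natural"
    font_logmar: float
    words_total: int
    words_correct: int
    duration_s: float

    def __post_init__(self) -> None:
        if not 0 <= self.words_correct <= self.words_total:
            raise ValueError(
                f"words_correct {self.words_correct} outside [0, {self.words_total}]"
            )
        if self.duration_s <= 0:
            raise ValueError(f"duration must be positive, got {self.duration_s}")


@dataclass
class ReadingProfile:
    """Per-font accuracy/speed profile for one reading test."""

    fonts: np.ndarray  # logMAR, ascending
    accuracy: np.ndarray  # percent correct per font
    speed: np.ndarray  # WPM per font
    words_correct: np.ndarray  # summed word counts per font
    words_total: np.ndarray

    @property
    def pooled_accuracy(self) -> float:
        """Unweighted mean accuracy over fonts (equal-trials design)."""
        return float(np.mean(self.accuracy))

    @property
    def pooled_speed(self) -> float:
        return float(np.mean(self.speed))


@dataclass
class PsychometricFit:
    """Logistic accuracy-vs-print-size fit; midpoint is equivalent acuity."""

    acuity_logmar: float
    slope: float  # per logMAR; positive: larger print is easier
    lower_asymptote: float = 0.0
    upper_asymptote: float = 100.0
    converged: bool = True
    extrapolated: bool = False  # midpoint outside the tested font range
    censored: str | None = None  # "low" (all correct) / "high" (all wrong)
    method: str = "ml"
    ci: tuple[float, float] | None = None
    fonts: np.ndarray | None = None

    @property
    def usable(self) -> bool:
        """True when the acuity estimate can enter downstream span deltas."""
        return self.converged and self.censored is None

    def predict(self, font_logmar) -> np.ndarray:
        """Predicted percent correct at the given print sizes."""
        f = np.asarray(font_logmar, dtype=float)
        return 100.0 * expit(self.slope * (f - self.acuity_logmar))


def score_trial(response_tokens: Sequence[str], truth_tokens: Sequence[str]) -> int:
    """Count correctly read words by positional token match.

    Tokens are lowercased and stripped of punctuation before comparison;
    word *i* of the response is scored against word *i* of the sentence.
    This is a deterministic stand-in for experimenter scoring.
    """
    if not truth_tokens:
        raise ValueError("truth_tokens must be non-empty")

    def norm(tokens: Sequence[str]) -> list[str]:
        return [t.lower().translate(_PUNCT_TABLE) for t in tokens]

    resp, truth = norm(response_tokens), norm(truth_tokens)
    return sum(1 for r, t in zip(resp, truth) if r == t and t)


def accuracy_and_speed(trial: ReadingTrial) -> tuple[float, float]:
    """(percent of words correct, correctly read words per minute)."""
    accuracy = 100.0 * trial.words_correct / trial.words_total
    wpm = trial.words_correct / (trial.duration_s / 60.0)
    return accuracy, wpm


def logmar_from_snellen(numerator: float, denominator: float) -> float:
    """Convert a Snellen fraction (e.g. 20/500 ft) to logMAR."""
    if numerator <= 0 or denominator <= 0:
        raise ValueError("Snellen numerator and denominator must be positive")
    return float(np.log10(denominator / numerator))


def profile_from_trials(trials: Sequence[ReadingTrial]) -> ReadingProfile:
    """Aggregate trials of one reading test into a per-font profile."""
    if not trials:
        raise ValueError("no trials to profile")
    df = pd.DataFrame(
        {
            "font": [t.font_logmar for t in trials],
            "correct": [t.words_correct for t in trials],
            "total": [t.words_total for t in trials],
            "duration": [t.duration_s for t in trials],
        }
    )
    g = df.groupby("font", sort=True).sum()
    fonts = g.index.to_numpy(dtype=float)
    acc = 100.0 * g["correct"].to_numpy() / g["total"].to_numpy()
    speed = g["correct"].to_numpy() / (g["duration"].to_numpy() / 60.0)
    return ReadingProfile(
        fonts, acc, speed,
        g["correct"].to_numpy(dtype=float), g["total"].to_numpy(dtype=float),
    )


def _nll(midpoint: float, slope: float, fonts, correct, total) -> float:
    p = expit(slope * (np.asarray(fonts) - midpoint))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    c = np.asarray(correct, dtype=float)
    n = np.asarray(total, dtype=float)
    return float(-(c * np.log(p) + (n - c) * np.log(1 - p)).sum())


def fit_acuity(
    fonts: Sequence[float],
    words_correct: Sequence[int],
    words_total: Sequence[int],
    *,
    method: str = "ml",
) -> PsychometricFit:
    """Fit the psychometric curve and extract equivalent acuity.

    Parameters
    ----------
    fonts : print sizes in logMAR (>= 3 distinct values with data).
    words_correct, words_total : word counts per print size.
    method : ``"ml"`` (binomial maximum likelihood, default) or ``"ls"``
        (least squares on percent-correct values).

    Returns a :class:`PsychometricFit`.  All-correct profiles are censored
    low (acuity better than the smallest print tested, reported as that
    bound); all-wrong profiles are censored high.  A midpoint outside the
    tested range sets the ``extrapolated`` flag.
    """
    fonts = np.asarray(fonts, dtype=float)
    correct = np.asarray(words_correct, dtype=float)
    total = np.asarray(words_total, dtype=float)
    if len(np.unique(fonts)) < 3:
        raise ValueError("need >= 3 distinct font sizes to fit a sigmoid")
    if np.any(total <= 0):
        raise ValueError("words_total must be positive at every font")

    if np.all(correct == total):
        return PsychometricFit(
            float(fonts.min()), np.inf, censored="low",
            extrapolated=True, method=method, fonts=fonts,
        )
    if np.all(correct == 0):
        return PsychometricFit(
            float(fonts.max()), np.inf, censored="high",
            extrapolated=True, method=method, fonts=fonts,
        )

    if method == "ml":
        midpoint, slope, converged = _fit_ml(fonts, correct, total)
    elif method == "ls":
        midpoint, slope, converged = _fit_ls(fonts, 100.0 * correct / total)
    else:
        raise ValueError(f"unknown method {method!r}")

    extrapolated = not (fonts.min() <= midpoint <= fonts.max())
    return PsychometricFit(
        float(midpoint), float(slope),
        converged=converged, extrapolated=extrapolated,
        method=method, fonts=fonts,
    )


def _fit_ml(fonts, correct, total) -> tuple[float, float, bool]:
    """Binomial GLM with logit link; profile fallback under separation."""
    import warnings

    X = sm.add_constant(fonts)
    try:
        with warnings.catch_warnings():
            # separation is detected and handled below via the slope cap
            warnings.simplefilter("ignore")
            res = sm.GLM(
                np.column_stack([correct, total - correct]), X,
                family=sm.families.Binomial(),
            ).fit(maxiter=200)
        b0, b1 = res.params
        converged = bool(res.converged) and abs(b1) < 1e3
        if converged and b1 != 0:
            return -b0 / b1, b1, True
    except Exception:
        pass
    # Quasi-separated data: profile the likelihood over the midpoint with
    # the slope capped, which keeps the midpoint finite and interpretable.
    slope_cap = 100.0
    lo, hi = fonts.min() - 1.0, fonts.max() + 1.0
    res = minimize_scalar(
        lambda m: _nll(m, slope_cap, fonts, correct, total),
        bounds=(lo, hi), method="bounded",
    )
    return float(res.x), slope_cap, False


def _fit_ls(fonts, percent) -> tuple[float, float, bool]:
    from scipy.optimize import curve_fit

    def model(f, midpoint, slope):
        return 100.0 * expit(slope * (f - midpoint))

    p0 = (float(np.median(fonts)), 10.0)
    try:
        (midpoint, slope), _ = curve_fit(
            model, fonts, percent, p0=p0, maxfev=10000
        )
        return midpoint, slope, True
    except RuntimeError:
        return p0[0], p0[1], False


def fit_acuity_bootstrap(
    trials: Sequence[ReadingTrial],
    *,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
    method: str = "ml",
) -> PsychometricFit:
    """Fit acuity from raw trials with a sentence-resampling bootstrap CI.

    Sentences (trials) are resampled with replacement within each print
    size; the percentile interval over refitted midpoints is attached to
    the returned fit.  Censored resamples are dropped from the interval.
    """
    profile = profile_from_trials(trials)
    fit = fit_acuity(
        profile.fonts, profile.words_correct, profile.words_total, method=method
    )
    if not fit.usable or n_boot <= 0:
        return fit

    rng = np.random.default_rng(seed)
    by_font: dict[float, list[ReadingTrial]] = {}
    for t in trials:
        by_font.setdefault(t.font_logmar, []).append(t)

    mids = []
    for _ in range(n_boot):
        fonts, corr, tot = [], [], []
        for font, group in sorted(by_font.items()):
            idx = rng.integers(0, len(group), len(group))
            fonts.append(font)
            corr.append(sum(group[i].words_correct for i in idx))
            tot.append(sum(group[i].words_total for i in idx))
        rfit = fit_acuity(fonts, corr, tot, method=method)
        if rfit.usable:
            mids.append(rfit.acuity_logmar)
    if mids:
        alpha = (1.0 - ci_level) / 2.0
        fit.ci = tuple(np.quantile(mids, [alpha, 1.0 - alpha]))
    return fit
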
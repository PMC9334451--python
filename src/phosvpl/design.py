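"""Syncopated session schedule and learning-rate decoding.

The longitudinal design interleaves a small number of reading tests (R)
among daily video-viewing sessions (v) over 23 visits per subject: visit 1
is an intake acuity check, visits 2–22 each show one video, and visit 23
is a final reading test with no video.  Eight potential reading-test
positions exist (one every three videos); each subject takes six of them,
skipping two non-adjacent intermediate positions, so that consecutive
tests bound spans of either three (RvvvR) or six (RvvvvvvR) videos — three
short spans and two long spans per subject, accounting for all 21 videos.

Let y1 and y2 be the mean acuity change over short and long spans.  Each
span carries the influence of one reading test (the earlier one; the later
test measures but is assumed not to influence its own measurement) plus
three or six videos:

    y1 = 3*beta_V + beta_R
    y2 = 6*beta_V + beta_R

which inverts to the synchronous decoder

    beta_V = (y2 - y1) / 3
    beta_R = 2*y1 - y2

giving per-session learning rates (logMAR/session; negative = improving)
for the active reading task and the passive video task.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from importlib import resources
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "Schedule",
    "SpanImprovement",
    "LearningRates",
    "build_schedule",
    "default_schedule",
    "extract_spans",
    "decode_rates",
    "decode_from_spans",
    "rates_from_regression",
    "attribute_gains",
    "exposure_summary",
    "acuity_change",
]

N_SESSIONS = 23
#: sessions holding the eight potential reading-test positions
TEST_SESSIONS = (2, 5, 8, 11, 14, 17, 20, 23)
#: videos watched before each potential test position
VIDEOS_BEFORE = tuple(3 * i for i in range(8))
N_VIDEOS = 21

#: mean session lengths, minutes
T_READING = 13.6
T_VIDEO = 24.7


@dataclass
class Schedule:
    """Per-subject session plan.

    ``assignments`` maps subject id -> sorted tuple of attended test
    positions (indices 0–7 into :data:`TEST_SESSIONS`).
    """

    n_subjects: int
    assignments: dict[str, tuple[int, ...]]
    seed: int | None = None

    @property
    def subjects(self) -> list[str]:
        return list(self.assignments)

    def positions(self, subject: str) -> tuple[int, ...]:
        return self.assignments[subject]

    def span_lengths(self, subject: str) -> list[int]:
        """Videos between consecutive attended tests (3 or 6 each)."""
        pos = self.assignments[subject]
        return [VIDEOS_BEFORE[b] - VIDEOS_BEFORE[a] for a, b in zip(pos, pos[1:])]

    def position_counts(self) -> np.ndarray:
        """Number of subjects attending each of the 8 positions."""
        counts = np.zeros(8, dtype=int)
        for pos in self.assignments.values():
            counts[list(pos)] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        """Long table: subject, session, has_reading_test, has_video."""
        rows = []
        for subj, pos in self.assignments.items():
            test_sessions = {TEST_SESSIONS[i] for i in pos}
            for session in range(1, N_SESSIONS + 1):
                rows.append(
                    {
                        "subject": subj,
                        "session": session,
                        "has_reading_test": session in test_sessions,
                        "has_video": 2 <= session <= 22,
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Schedule":
        assignments = {}
        for subj, g in df.groupby("subject", sort=False):
            sessions = sorted(g.loc[g["has_reading_test"], "session"])
            pos = tuple(TEST_SESSIONS.index(s) for s in sessions)
            assignments[str(subj)] = pos
        sched = cls(len(assignments), assignments)
        sched.validate()
        return sched

    def validate(self) -> None:
        counts = self.position_counts()
        for subj, pos in self.assignments.items():
            if len(pos) != 6:
                raise ValueError(f"{subj}: expected 6 reading tests, got {len(pos)}")
            if pos[0] != 0 or pos[-1] != 7:
                raise ValueError(f"{subj}: first and last positions must be attended")
            spans = self.span_lengths(subj)
            if sorted(spans) != [3, 3, 3, 6, 6]:
                raise ValueError(
                    f"{subj}: spans must be three 3-video and two 6-video, got {spans}"
                )
        if counts[0] != self.n_subjects or counts[7] != self.n_subjects:
            raise ValueError("first and last test positions must be fully populated")


@dataclass(frozen=True)
class SpanImprovement:
    """Acuity change (later minus earlier test) across one span."""

    subject: str
    kind: str  # "short" (3 videos) or "long" (6 videos)
    delta: float  # logMAR


@dataclass
class LearningRates:
    """Decoded per-session learning rates, logMAR/session."""

    beta_R: float
    beta_V: float
    y1_mean: float
    y2_mean: float
    n_short: int = 0
    n_long: int = 0
    per_subject: pd.DataFrame | None = None


def _skip_pairs() -> list[tuple[int, int]]:
    """Admissible skipped-position pairs: two non-adjacent intermediates.

    Adjacent skips would create a 9-video span, which the decoder's
    two-span model cannot use.
    """
    return [(a, b) for a, b in combinations(range(1, 7), 2) if b - a > 1]


def build_schedule(n_subjects: int = 8, seed: int = 0) -> Schedule:
    """Build a syncopated schedule satisfying all design constraints.

    Every subject attends the first and last test positions and skips two
    non-adjacent intermediate positions.  Across the cohort, skips are
    balanced so that each intermediate position is attended by either
    ``n_subjects - ceil(n/3)`` or ``n_subjects - floor(n/3)`` subjects
    (5 or 6 of 8 in the reference design).  Deterministic per seed.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    pairs = _skip_pairs()
    total_skips = 2 * n_subjects
    lo = total_skips // 6  # per-position skip bounds for balance
    hi = -(-total_skips // 6)

    for _ in range(10000):
        counts = np.zeros(8, dtype=int)
        chosen = []
        ok = True
        for _s in range(n_subjects):
            order = rng.permutation(len(pairs))
            for j in order:
                a, b = pairs[j]
                if counts[a] < hi and counts[b] < hi:
                    counts[a] += 1
                    counts[b] += 1
                    chosen.append((a, b))
                    break
            else:
                ok = False
                break
        if ok and all(lo <= counts[i] <= hi for i in range(1, 7)):
            assignments = {}
            for i, (a, b) in enumerate(chosen):
                pos = tuple(p for p in range(8) if p not in (a, b))
                assignments[f"S{i + 1}"] = pos
            sched = Schedule(n_subjects, assignments, seed)
            sched.validate()
            return sched
    raise ValueError(
        f"could not build a balanced schedule for {n_subjects} subjects"
    )


def default_schedule() -> Schedule:
    """The packaged reference assignment (synthetic admissible solution).

    Loaded from ``data/default_schedule.csv``; one of many assignments
    satisfying the design constraints, fixed so downstream results are
    reproducible without regeneration.
    """
    with resources.files("phosvpl").joinpath("data/default_schedule.csv").open() as fh:
        return Schedule.from_frame(pd.read_csv(fh))


def extract_spans(
    acuities: pd.DataFrame, schedule: Schedule
) -> tuple[list[SpanImprovement], int]:
    """Sort per-test acuities into short- and long-span improvements.

    ``acuities`` needs columns ``subject, position, acuity`` (position is
    the 0–7 test-position index) and may carry a boolean ``usable`` column;
    censored or otherwise unusable fits drop their adjacent spans.

    Returns the span list and the number of spans dropped to censoring.
    """
    required = {"subject", "position", "acuity"}
    if not required <= set(acuities.columns):
        raise ValueError(f"acuities table needs columns {sorted(required)}")
    spans: list[SpanImprovement] = []
    dropped = 0
    for subj in schedule.subjects:
        pos = schedule.positions(subj)
        sub = acuities[acuities["subject"] == subj].set_index("position")
        missing = set(pos) - set(sub.index)
        if missing:
            raise ValueError(f"{subj}: acuity missing at positions {sorted(missing)}")
        for a, b in zip(pos, pos[1:]):
            n_videos = VIDEOS_BEFORE[b] - VIDEOS_BEFORE[a]
            kind = "short" if n_videos == 3 else "long"
            ok = True
            if "usable" in sub.columns:
                ok = bool(sub.loc[a, "usable"]) and bool(sub.loc[b, "usable"])
            if not ok:
                dropped += 1
                continue
            delta = float(sub.loc[b, "acuity"] - sub.loc[a, "acuity"])
            spans.append(SpanImprovement(subj, kind, delta))
    return spans, dropped


def decode_rates(y1_mean: float, y2_mean: float) -> LearningRates:
    """Invert the two-span linear model into per-session rates."""
    beta_V = (y2_mean - y1_mean) / 3.0
    beta_R = 2.0 * y1_mean - y2_mean
    return LearningRates(beta_R, beta_V, y1_mean, y2_mean)


def decode_from_spans(
    spans: Sequence[SpanImprovement], *, per_subject: bool = False
) -> LearningRates:
    """Decode learning rates from span improvements.

    Default: pool all short-span deltas into y1 and long-span deltas into
    y2, then decode the population means.  With ``per_subject=True`` each
    subject's (mean y1, mean y2) pair is decoded separately and the
    distribution is attached as ``per_subject``.
    """
    df = pd.DataFrame(
        {
            "subject": [s.subject for s in spans],
            "kind": [s.kind for s in spans],
            "delta": [s.delta for s in spans],
        }
    )
    if df.empty or df["kind"].nunique() < 2:
        raise ValueError("need both short and long spans to decode rates")
    y1 = df.loc[df["kind"] == "short", "delta"]
    y2 = df.loc[df["kind"] == "long", "delta"]
    rates = decode_rates(float(y1.mean()), float(y2.mean()))
    rates.n_short = len(y1)
    rates.n_long = len(y2)
    if per_subject:
        rows = []
        for subj, g in df.groupby("subject", sort=False):
            s1 = g.loc[g["kind"] == "short", "delta"]
            s2 = g.loc[g["kind"] == "long", "delta"]
            if s1.empty or s2.empty:
                continue
            r = decode_rates(float(s1.mean()), float(s2.mean()))
            rows.append(
                {
                    "subject": subj,
                    "y1": r.y1_mean,
                    "y2": r.y2_mean,
                    "beta_R": r.beta_R,
                    "beta_V": r.beta_V,
                }
            )
        rates.per_subject = pd.DataFrame(rows)
    return rates


def rates_from_regression(exposure: pd.DataFrame) -> dict:
    """Validate the decoder with acuity-vs-cumulative-time regressions.

    ``exposure`` needs columns ``acuity, reading_min, video_min`` — one row
    per acuity measurement with the cumulative minutes spent in each task
    at that measurement.  Fits three ordinary-least-squares models (reading
    only, video only, both) and reports slopes (logMAR/min) with 95%
    confidence intervals and R² per predictor set.
    """
    required = {"acuity", "reading_min", "video_min"}
    if not required <= set(exposure.columns):
        raise ValueError(f"exposure table needs columns {sorted(required)}")
    y = exposure["acuity"].to_numpy(dtype=float)
    out: dict = {}
    for name, cols in [
        ("reading", ["reading_min"]),
        ("video", ["video_min"]),
        ("both", ["reading_min", "video_min"]),
    ]:
        X = sm.add_constant(exposure[cols].to_numpy(dtype=float))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"collinear predictors in model {name!r}")
        res = sm.OLS(y, X).fit()
        ci = res.conf_int(alpha=0.05)
        out[name] = {
            "slopes": {c: float(res.params[i + 1]) for i, c in enumerate(cols)},
            "ci": {c: (float(ci[i + 1][0]), float(ci[i + 1][1])) for i, c in enumerate(cols)},
            "r_squared": float(res.rsquared),
        }
    out["per_session"] = {
        "beta_R_prime": out["reading"]["slopes"]["reading_min"] * T_READING,
        "beta_V_prime": out["video"]["slopes"]["video_min"] * T_VIDEO,
    }
    return out


def attribute_gains(
    rates: LearningRates, n_reading_influences: int = 5, n_video: int = N_VIDEOS
) -> dict:
    """Split the overall acuity gain between the two session types.

    ``n_reading_influences`` counts reading tests whose influence lands on
    a later measurement (5 of the 6 under the no-self-influence
    convention).  Returns per-task gains (rate x count, logMAR) and the
    percent split; a zero total gain leaves the split undefined.
    """
    if n_reading_influences < 0 or n_video < 0:
        raise ValueError("session counts must be non-negative")
    reading_gain = rates.beta_R * n_reading_influences
    video_gain = rates.beta_V * n_video
    total = reading_gain + video_gain
    if total == 0:
        return {
            "reading_gain": reading_gain,
            "video_gain": video_gain,
            "reading_percent": np.nan,
            "video_percent": np.nan,
            "split_defined": False,
        }
    return {
        "reading_gain": reading_gain,
        "video_gain": video_gain,
        "reading_percent": 100.0 * reading_gain / total,
        "video_percent": 100.0 * video_gain / total,
        "split_defined": True,
    }


def exposure_summary(reading_s: float, video_s: float) -> dict:
    """Phosphene-exposure bookkeeping from per-task totals (seconds).

    Reports the video:reading exposure ratio and the reading fraction of
    total phosphene-view time, in percent.
    """
    if reading_s <= 0 or video_s < 0:
        raise ValueError("exposure times must be positive")
    total = reading_s + video_s
    return {
        "reading_s": reading_s,
        "video_s": video_s,
        "ratio_video_to_reading": video_s / reading_s,
        "reading_fraction_percent": 100.0 * reading_s / total,
    }


def acuity_change(initial: float, final: float) -> float:
    """Final minus initial population acuity (negative = improvement)."""
    return final - initial
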
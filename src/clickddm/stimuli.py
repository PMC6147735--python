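"""Poisson-clicks stimuli: trials, sessions and their serialization.

In the Poisson-clicks task two trains of auditory clicks are played
simultaneously from left and right speakers.  Each train is a homogeneous
Poisson process; the combined mean rate is fixed (40 Hz by default) and the
trial's difficulty is set by the rate ratio, from 39:1 clicks/s (easiest)
down to 26:14 (hardest).  Stimulus duration is either drawn uniformly from
[0.1, 1.2] s (electrophysiology/pharmacology-style sessions) or fixed at
1 s (optogenetics-style sessions).  A configurable fraction of trials
(default 10%) are "motor control" trials carrying no clicks and a cued
side, used to separate motor effects from accumulation effects.

The session container also records which hemisphere (if any) was perturbed,
which fixes the ipsilateral/contralateral mapping used by the biased model
parameters and by the bias statistics.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClickTrial",
    "Session",
    "COMBINED_RATE",
    "DEFAULT_LEVEL_SET",
    "PERTURBATION_LABELS",
    "generate_click_trains",
    "sample_difficulty",
    "sample_duration",
    "generate_stimulus_session",
    "read_session",
    "write_session",
    "session_to_frame",
]

SCHEMA_VERSION = 1

#: Combined mean click rate in clicks/s.
COMBINED_RATE = 40.0

#: Default difficulty levels as (high, low) rate pairs in clicks/s.  The
#: endpoints 39:1 and 26:14 are fixed by the task; intermediate ratios are
#: an evenly spaced interpolation (the exact intermediate levels are a
#: session configuration).
DEFAULT_LEVEL_SET = ((39.0, 1.0), (36.0, 4.0), (32.0, 8.0), (29.0, 11.0), (26.0, 14.0))

PERTURBATION_LABELS = (
    "none",
    "unilateral_L",
    "unilateral_R",
    "bilateral",
    "epoch_pre",
    "epoch_first_half",
    "epoch_second_half",
    "epoch_post",
)

_SIDES = ("L", "R", "none")


@dataclass
class ClickTrial:
    """One trial: click times (s from stimulus onset), duration and labels."""

    left_clicks: np.ndarray
    right_clicks: np.ndarray
    duration: float
    rate_left: float
    rate_right: float
    correct_side: str = "R"
    choice: str = "none"
    trial_type: str = "accumulation"
    perturbation: str = "none"

    def __post_init__(self) -> None:
        self.left_clicks = np.asarray(self.left_clicks, dtype=float)
        self.right_clicks = np.asarray(self.right_clicks, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.rate_left < 0 or self.rate_right < 0:
            raise ValueError("click rates must be nonnegative")
        for name, arr in (("left_clicks", self.left_clicks), ("right_clicks", self.right_clicks)):
            if arr.size and (np.any(arr < 0) or np.any(arr > self.duration)):
                raise ValueError(f"{name}: click times must lie in [0, duration]")
            if np.any(np.diff(arr) < 0):
                raise ValueError(f"{name}: click times must be sorted ascending")
        if self.choice not in _SIDES:
            raise ValueError(f"choice must be one of {_SIDES}")
        if self.correct_side not in ("L", "R"):
            raise ValueError("correct_side must be 'L' or 'R'")
        if self.trial_type not in ("accumulation", "motor_control"):
            raise ValueError("trial_type must be 'accumulation' or 'motor_control'")
        if self.perturbation not in PERTURBATION_LABELS:
            raise ValueError(f"perturbation must be one of {PERTURBATION_LABELS}")

    @property
    def n_left(self) -> int:
        return int(self.left_clicks.size)

    @property
    def n_right(self) -> int:
        return int(self.right_clicks.size)

    @property
    def click_diff(self) -> int:
        """Played click difference #right - #left."""
        return self.n_right - self.n_left


@dataclass
class Session:
    """A list of trials plus the subject and perturbation-side metadata.

    ``inactivated_side`` defines the ipsi/contra mapping for the lateralized
    model parameters and the bias statistics: choices toward that side are
    ipsilateral.  ``'none'``/``'both'`` sessions have no lateral mapping.
    """

    trials: list[ClickTrial] = field(default_factory=list)
    subject_id: str = "synthetic"
    inactivated_side: str = "none"
    session_role: str = "control"

    def __post_init__(self) -> None:
        if self.inactivated_side not in ("L", "R", "none", "both"):
            raise ValueError("inactivated_side must be 'L', 'R', 'none' or 'both'")
        if self.session_role not in ("control", "perturbation"):
            raise ValueError("session_role must be 'control' or 'perturbation'")
        for t in self.trials:
            if t.perturbation == "unilateral_L" and self.inactivated_side != "L":
                raise ValueError("unilateral_L trial in a session with inactivated_side != 'L'")
            if t.perturbation == "unilateral_R" and self.inactivated_side != "R":
                raise ValueError("unilateral_R trial in a session with inactivated_side != 'R'")
            if t.perturbation == "bilateral" and self.inactivated_side != "both":
                raise ValueError("bilateral trial in a session with inactivated_side != 'both'")

    def __len__(self) -> int:
        return len(self.trials)

    def accumulation_trials(self) -> list[ClickTrial]:
        return [t for t in self.trials if t.trial_type == "accumulation"]


# ----------------------------------------------------------------------
# generation
# ----------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_click_trains(
    rate_left: float,
    rate_right: float,
    duration: float,
    seed=None,
) -> ClickTrial:
    """Draw one trial's left/right click trains as independent homogeneous
    Poisson processes.  Deterministic given ``seed``."""
    if rate_left < 0 or rate_right < 0:
        raise ValueError("click rates must be nonnegative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = _as_rng(seed)
    n_l = rng.poisson(rate_left * duration)
    n_r = rng.poisson(rate_right * duration)
    left = np.sort(rng.uniform(0.0, duration, size=n_l))
    right = np.sort(rng.uniform(0.0, duration, size=n_r))
    if n_r > n_l:
        correct = "R"
    elif n_l > n_r:
        correct = "L"
    else:  # tie on played counts: break by generative rate, then coin flip
        if rate_right != rate_left:
            correct = "R" if rate_right > rate_left else "L"
        else:
            correct = "R" if rng.random() < 0.5 else "L"
    return ClickTrial(
        left_clicks=left,
        right_clicks=right,
        duration=float(duration),
        rate_left=float(rate_left),
        rate_right=float(rate_right),
        correct_side=correct,
    )


def sample_difficulty(
    level_set: Sequence[tuple[float, float]] = DEFAULT_LEVEL_SET,
    seed=None,
    combined_rate: float = COMBINED_RATE,
) -> tuple[float, float]:
    """Uniform draw of a difficulty level, with randomized side assignment.

    Returns ``(rate_left, rate_right)``.  Every pair in ``level_set`` must
    sum to ``combined_rate``.
    """
    if len(level_set) == 0:
        raise ValueError("level_set must not be empty")
    for pair in level_set:
        if abs(pair[0] + pair[1] - combined_rate) > 1e-9:
            raise ValueError(f"difficulty pair {pair} does not sum to {combined_rate}")
    rng = _as_rng(seed)
    hi, lo = level_set[rng.integers(len(level_set))]
    if rng.random() < 0.5:
        return float(hi), float(lo)
    return float(lo), float(hi)


def sample_duration(duration_law, rng) -> float:
    """Draw a stimulus duration.  ``duration_law`` is either a number (fixed
    duration, optogenetics-style) or the string ``"uniform"`` for the
    electrophysiology-style U(0.1, 1.2) s law."""
    if duration_law == "uniform":
        return float(rng.uniform(0.1, 1.2))
    d = float(duration_law)
    if d <= 0:
        raise ValueError("fixed duration must be positive")
    return d


def generate_stimulus_session(
    n_trials: int,
    level_set: Sequence[tuple[float, float]] = DEFAULT_LEVEL_SET,
    duration_law="uniform",
    motor_fraction: float = 0.1,
    seed=None,
    subject_id: str = "synthetic",
    inactivated_side: str = "none",
    session_role: str = "control",
    combined_rate: float = COMBINED_RATE,
) -> Session:
    """Generate a session of stimuli (choices unfilled, ``choice='none'``).

    ``motor_fraction`` of trials are motor-control trials with no clicks and
    a cued side.
    """
    rng = _as_rng(seed)
    trials = []
    for _ in range(n_trials):
        dur = sample_duration(duration_law, rng)
        if rng.random() < motor_fraction:
            cued = "R" if rng.random() < 0.5 else "L"
            trials.append(
                ClickTrial(
                    left_clicks=np.empty(0),
                    right_clicks=np.empty(0),
                    duration=dur,
                    rate_left=0.0,
                    rate_right=0.0,
                    correct_side=cued,
                    trial_type="motor_control",
                )
            )
        else:
            rl, rr = sample_difficulty(level_set, rng, combined_rate)
            trials.append(generate_click_trains(rl, rr, dur, rng))
    return Session(
        trials=trials,
        subject_id=subject_id,
        inactivated_side=inactivated_side,
        session_role=session_role,
    )


# ----------------------------------------------------------------------
# serialization (versioned JSON schema + flat CSV export)
# ----------------------------------------------------------------------

class SessionParseError(ValueError):
    """Raised when a session file violates the documented schema; the
    message names the offending field."""


def _trial_to_obj(t: ClickTrial) -> dict:
    return {
        "left_clicks": [round(float(x), 9) for x in t.left_clicks],
        "right_clicks": [round(float(x), 9) for x in t.right_clicks],
        "duration": round(float(t.duration), 9),
        "rate_left": t.rate_left,
        "rate_right": t.rate_right,
        "correct_side": t.correct_side,
        "choice": t.choice,
        "trial_type": t.trial_type,
        "perturbation": t.perturbation,
    }


def write_session(session: Session, path) -> None:
    obj = {
        "schema_version": SCHEMA_VERSION,
        "subject_id": session.subject_id,
        "inactivated_side": session.inactivated_side,
        "session_role": session.session_role,
        "trials": [_trial_to_obj(t) for t in session.trials],
    }
    with open(path, "w") as fh:
        json.dump(obj, fh)


def read_session(path) -> Session:
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("schema_version") != SCHEMA_VERSION:
        raise SessionParseError(f"schema_version: expected {SCHEMA_VERSION}, got {obj.get('schema_version')}")
    trials = []
    for i, tr in enumerate(obj.get("trials", [])):
        try:
            trials.append(
                ClickTrial(
                    left_clicks=np.asarray(tr["left_clicks"], dtype=float),
                    right_clicks=np.asarray(tr["right_clicks"], dtype=float),
                    duration=float(tr["duration"]),
                    rate_left=float(tr["rate_left"]),
                    rate_right=float(tr["rate_right"]),
                    correct_side=tr["correct_side"],
                    choice=tr["choice"],
                    trial_type=tr["trial_type"],
                    perturbation=tr["perturbation"],
                )
            )
        except KeyError as e:
            raise SessionParseError(f"trials[{i}]: missing field {e.args[0]!r}") from e
        except ValueError as e:
            raise SessionParseError(f"trials[{i}]: {e}") from e
    try:
        return Session(
            trials=trials,
            subject_id=obj["subject_id"],
            inactivated_side=obj["inactivated_side"],
            session_role=obj["session_role"],
        )
    except KeyError as e:
        raise SessionParseError(f"missing field {e.args[0]!r}") from e
    except ValueError as e:
        raise SessionParseError(str(e)) from e


def session_to_frame(session: Session) -> pd.DataFrame:
    """Flat one-row-per-trial view; click times joined with ';'."""
    rows = []
    for i, t in enumerate(session.trials):
        rows.append(
            {
                "trial": i,
                "duration": t.duration,
                "rate_left": t.rate_left,
                "rate_right": t.rate_right,
                "n_left": t.n_left,
                "n_right": t.n_right,
                "left_clicks": ";".join(f"{x:.6f}" for x in t.left_clicks),
                "right_clicks": ";".join(f"{x:.6f}" for x in t.right_clicks),
                "correct_side": t.correct_side,
                "choice": t.choice,
                "trial_type": t.trial_type,
                "perturbation": t.perturbation,
            }
        )
    return pd.DataFrame(rows)
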
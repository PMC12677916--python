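"""Closed-loop trigger-threshold controller and FES channel calibration.

The FES trigger fires when the normalized classifier output (percent of the
session's calibration-phase maximum) reaches an adaptive threshold: initial
70%, bounded to [55, 85].  After each session the threshold moves in 5-point
steps — up after two consecutive sessions above 75% decoding accuracy
(the consecutive counter resets on use), down immediately after a session
below 60%, unchanged for 60-75%.  Error-correction policies raise artifact-
rejection sensitivity on false positives and widen the personalized alpha
band (8-12 -> 7-14 Hz) on false negatives.

The controller is a pure state machine: identical (state, accuracy
sequence) pairs produce identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator

import numpy as np

THRESHOLD_STEP = 5.0
ACCURACY_INCREASE_ABOVE = 75.0
ACCURACY_DECREASE_BELOW = 60.0
MAX_ARTIFACT_SENSITIVITY = 3


@dataclass(frozen=True)
class SMRBandConfig:
    """Personalized sensorimotor-rhythm band edges (Hz)."""

    alpha_edges: tuple[float, float] = (8.0, 12.0)
    beta_edges: tuple[float, float] = (18.0, 24.0)
    expanded_alpha_edges: tuple[float, float] = (7.0, 14.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.alpha_edges, self.beta_edges,
                       self.expanded_alpha_edges):
            if lo >= hi:
                raise ValueError("band edges must satisfy low < high")
        elo, ehi = self.expanded_alpha_edges
        alo, ahi = self.alpha_edges
        if elo > alo or ehi < ahi:
            raise ValueError("expanded alpha band must contain the default band")

    @property
    def alpha_expanded(self) -> bool:
        return self.alpha_edges == self.expanded_alpha_edges


@dataclass(frozen=True)
class ControllerState:
    """Adaptive-threshold controller state (immutable; updates return copies)."""

    threshold: float = 70.0
    threshold_bounds: tuple[float, float] = (55.0, 85.0)
    session_accuracy_history: tuple[float, ...] = ()
    consecutive_high_count: int = 0
    artifact_sensitivity: int = 0
    band_config: SMRBandConfig = field(default_factory=SMRBandConfig)

    def __post_init__(self) -> None:
        lo, hi = self.threshold_bounds
        if not lo <= self.threshold <= hi:
            raise ValueError(f"threshold {self.threshold} outside [{lo}, {hi}]")


def update_threshold(state: ControllerState, session_accuracy: float) -> ControllerState:
    """One weekly threshold update from a session's decoding accuracy.

    +5 points iff this and the previous session both exceeded 75% (counter
    resets on use); -5 points immediately below 60%; unchanged in [60, 75].
    The result is clamped to the dynamic range.
    """
    if not 0.0 <= session_accuracy <= 100.0:
        raise ValueError("accuracy must lie in [0, 100]")
    lo, hi = state.threshold_bounds
    threshold = state.threshold
    count = state.consecutive_high_count
    if session_accuracy < ACCURACY_DECREASE_BELOW:
        threshold -= THRESHOLD_STEP
        count = 0
    elif session_accuracy > ACCURACY_INCREASE_ABOVE:
        count += 1
        if count >= 2:
            threshold += THRESHOLD_STEP
            count = 0
    else:
        count = 0
    return replace(
        state,
        threshold=float(np.clip(threshold, lo, hi)),
        consecutive_high_count=count,
        session_accuracy_history=state.session_accuracy_history + (session_accuracy,),
    )


def apply_error_correction(state: ControllerState, error_type: str) -> ControllerState:
    """Policy response to a decoding error.

    ``false_positive`` raises artifact-rejection sensitivity one level
    (capped); ``false_negative`` widens the alpha band to the expanded
    edges (idempotent).
    """
    if error_type == "false_positive":
        level = min(state.artifact_sensitivity + 1, MAX_ARTIFACT_SENSITIVITY)
        return replace(state, artifact_sensitivity=level)
    if error_type == "false_negative":
        bc = state.band_config
        return replace(state, band_config=replace(
            bc, alpha_edges=bc.expanded_alpha_edges))
    raise ValueError("error_type must be 'false_positive' or 'false_negative'")


def normalize_score(raw_score: float, running_max: float) -> float:
    """Percent of the session maximum, clamped to [0, 100]."""
    if running_max <= 0:
        raise ValueError("running_max must be positive (calibration incomplete)")
    return float(100.0 * np.clip(raw_score / running_max, 0.0, 1.0))


@dataclass
class TrialRecord:
    cue_class: str  # "MI" or "rest"
    features: np.ndarray
    raw_score: float
    normalized_score: float | None
    decision: str | None  # "trigger" / "no-trigger"
    correct: bool | None
    is_calibration: bool


@dataclass
class SessionLog:
    """One 50-trial session: 10 calibration trials establish the score
    normalization maximum, 40 feedback trials are scored against it."""

    trials: list[TrialRecord]
    n_calibration: int
    accuracy: float
    threshold_before: float
    threshold_after: float

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "n_calibration": self.n_calibration,
            "accuracy": self.accuracy,
            "threshold_before": self.threshold_before,
            "threshold_after": self.threshold_after,
            "trials": [
                {
                    "cue_class": t.cue_class,
                    "raw_score": t.raw_score,
                    "normalized_score": t.normalized_score,
                    "decision": t.decision,
                    "correct": t.correct,
                    "is_calibration": t.is_calibration,
                }
                for t in self.trials
            ],
        }


def simulate_session(
    trial_generator: Iterator[tuple[np.ndarray, str]],
    csp,
    lda,
    state: ControllerState,
    n_trials: int = 50,
    n_calibration: int = 10,
) -> tuple[SessionLog, ControllerState]:
    """Run one closed-loop session and apply the weekly threshold update.

    ``trial_generator`` yields (trial data, cue class) pairs; ``csp`` and
    ``lda`` are fitted models whose composed score is oriented MI-positive.
    Calibration trials only establish the running maximum (their scores are
    not normalized or judged); accuracy is trigger-correctness against the
    cue over the remaining feedback trials.
    """
    records: list[TrialRecord] = []
    running_max = 0.0
    n_correct = 0
    n_feedback = 0
    for k in range(n_trials):
        try:
            data, cue = next(trial_generator)
        except StopIteration as exc:
            raise RuntimeError(
                f"trial generator exhausted after {k} of {n_trials} trials"
            ) from exc
        features = csp.transform(data[None])[0]
        raw = float(lda.decision_function(features[None])[0])
        if k < n_calibration:
            running_max = max(running_max, raw)
            records.append(TrialRecord(cue, features, raw, None, None, None, True))
            continue
        score = normalize_score(raw, running_max)
        decision = "trigger" if score >= state.threshold else "no-trigger"
        correct = (decision == "trigger") == (cue == "MI")
        n_correct += int(correct)
        n_feedback += 1
        records.append(TrialRecord(cue, features, raw, score, decision,
                                   correct, False))
    accuracy = 100.0 * n_correct / n_feedback
    new_state = update_threshold(state, accuracy)
    log = SessionLog(trials=records, n_calibration=n_calibration,
                     accuracy=accuracy, threshold_before=state.threshold,
                     threshold_after=new_state.threshold)
    return log, new_state


def run_protocol(
    make_session_generator: Callable[[int], Iterator[tuple[np.ndarray, str]]],
    csp,
    lda,
    state: ControllerState,
    n_sessions: int,
) -> tuple[list[SessionLog], ControllerState]:
    """Simulate ``n_sessions`` consecutive sessions (one threshold update
    each); ``make_session_generator(session_index)`` supplies each
    session's trial stream."""
    logs = []
    for s in range(n_sessions):
        log, state = simulate_session(make_session_generator(s), csp, lda, state)
        logs.append(log)
    return logs, state


# ------------------------------------------------------------- FES calibration

#: Amplifier settings fixed during calibration.
CALIBRATION_SETTINGS = {
    "notch_filter": "on",
    "low_pass_filter": "off",
    "sensitivity_uv_per_cm": 100,
}


@dataclass
class CalibrationResult:
    target_amplitude: float
    measured_amplitude: float
    gain: float
    relative_error: float  # percent
    iterations: int
    converged: bool
    settings: dict = field(default_factory=lambda: dict(CALIBRATION_SETTINGS))
    trace: list[tuple[float, float]] = field(default_factory=list)


def calibrate_fes_channel(
    measure: Callable[[float], float],
    target: float = 200.0,
    tolerance: float = 0.05,
    initial_gain: float = 1.0,
    max_iterations: int = 25,
) -> CalibrationResult:
    """Adjust a channel's gain until the replayed 10-Hz sine measures the
    target amplitude within the relative tolerance (default 5%).

    ``measure(gain)`` returns the measured amplitude in uV and must be
    monotone in gain.  Gains move by multiplicative secant steps
    (``gain * target / measured``), which converges in one step on a linear
    channel.  Non-convergence (e.g. a saturating channel) is reported as a
    failure result with the measurement trace, not raised.
    """
    gain = float(initial_gain)
    trace: list[tuple[float, float]] = []
    measured = float(measure(gain))
    trace.append((gain, measured))
    iterations = 0
    while iterations < max_iterations:
        rel = abs(measured - target) / target
        if rel <= tolerance:
            return CalibrationResult(target, measured, gain, 100.0 * rel,
                                     iterations, True, trace=trace)
        if measured <= 0:
            break
        gain = gain * target / measured
        measured = float(measure(gain))
        iterations += 1
        trace.append((gain, measured))
    rel = abs(measured - target) / target
    return CalibrationResult(target, measured, gain, 100.0 * rel,
                             iterations, rel <= tolerance, trace=trace)
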
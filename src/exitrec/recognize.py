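"""Streaming activity assignment and bed/chair-exit alerting.

Each incoming observation's filtered marginals are summed over the last
second of data to assign an activity (the score function); a small state
machine over consecutive assignments emits bed- and chair-exit alerts,
suppressing repeats of the same kind within 1.75 s.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .crf import CRFModel, MarginalTracker
from .features import FeatureScaler, featurize_trial
from .io import ActivityLabel, RoomConfig, SensorObservation

SCORE_WINDOW_SECONDS = 1.0
SUPPRESSION_SECONDS = 1.75  # minimum plausible posture-transition duration

BED_PREV = frozenset({ActivityLabel.LYING, ActivityLabel.SITTING_ON_BED})
BED_NEW = frozenset({ActivityLabel.AMBULATING, ActivityLabel.SITTING_ON_CHAIR})


@dataclass(frozen=True, slots=True)
class ExitAlert:
    kind: str            #: "bed" or "chair"
    t: float             #: timestamp of the triggering observation
    participant_id: str


@dataclass
class RecognizerState:
    """Current assigned activity and the last emitted alert time per kind."""

    current: ActivityLabel | None = None
    last_alert_t: dict[str, float] = field(
        default_factory=lambda: {"bed": -np.inf, "chair": -np.inf}
    )


def score_assign(
    marginal_history: Sequence[tuple[float, np.ndarray]],
    t_prime: float,
    previous: ActivityLabel | None = None,
) -> ActivityLabel:
    """Activity whose marginals, summed over (t' - 1, t'], are largest.

    Ties go to ``previous`` when it is among the tied set, else to the
    lowest class index.
    """
    sums = np.zeros(4)
    seen = False
    for t, m in marginal_history:
        if t_prime - SCORE_WINDOW_SECONDS < t <= t_prime:
            sums += m
            seen = True
    if not seen:
        raise ValueError(f"no marginals in ({t_prime - 1}, {t_prime}]")
    best = sums.max()
    tied = [k for k in range(4) if sums[k] == best]
    if previous is not None and (int(previous) - 1) in tied:
        return previous
    return ActivityLabel(min(tied) + 1)


def fsm_step(
    state: RecognizerState,
    new_label: ActivityLabel,
    t: float,
    participant_id: str = "",
) -> tuple[RecognizerState, list[ExitAlert]]:
    """Advance the exit-recognition state machine by one assignment.

    Bed exit: previous in {Lying, Sitting-on-bed} and new in
    {Ambulating, Sitting-on-chair}. Chair exit: previous is
    Sitting-on-chair and new is anything else (covers the direct
    chair-to-bed transfer). Alerts of a kind within 1.75 s of the last
    emitted alert of that kind are discarded. The first assignment never
    alerts.
    """
    alerts: list[ExitAlert] = []
    prev = state.current
    if prev is not None and new_label != prev:
        kind = None
        if prev in BED_PREV and new_label in BED_NEW:
            kind = "bed"
        elif prev is ActivityLabel.SITTING_ON_CHAIR:
            kind = "chair"
        if kind is not None and t - state.last_alert_t[kind] > SUPPRESSION_SECONDS:
            alerts.append(ExitAlert(kind=kind, t=t, participant_id=participant_id))
            state.last_alert_t[kind] = t
    state.current = new_label
    return state, alerts


def recognize_stream(
    model: CRFModel,
    stream: Sequence[SensorObservation],
    room: RoomConfig,
    scaler: FeatureScaler | None = None,
    use_score: bool = True,
    features: np.ndarray | None = None,
) -> tuple[list[tuple[float, ActivityLabel]], list[ExitAlert]]:
    """Run the full streaming pipeline over one trial.

    Per observation: causal featurization, one forward-recursion step,
    score-function assignment (or raw argmax if ``use_score`` is False),
    then the exit state machine. Purely causal: no lookahead. A
    precomputed raw feature matrix may be passed to skip featurization.
    """
    x = featurize_trial(stream, room)[0] if features is None else features
    if scaler is not None:
        x = scaler.transform(x)
    tracker = MarginalTracker(model)
    history: deque[tuple[float, np.ndarray]] = deque()
    state = RecognizerState()
    labels: list[tuple[float, ActivityLabel]] = []
    alerts: list[ExitAlert] = []
    for i, obs in enumerate(stream):
        m = tracker.step(x[i])
        history.append((obs.t, m))
        while history and history[0][0] <= obs.t - SCORE_WINDOW_SECONDS:
            history.popleft()
        if use_score:
            label = score_assign(history, obs.t, previous=state.current)
        else:
            label = ActivityLabel(int(np.argmax(m)) + 1)
        state, new_alerts = fsm_step(state, label, obs.t, obs.participant_id)
        labels.append((obs.t, label))
        alerts.extend(new_alerts)
    return labels, alerts


def write_alerts(path, alerts: Iterable[ExitAlert]) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t", "kind", "participant_id"])
        for a in alerts:
            w.writerow([repr(a.t), a.kind, a.participant_id])


def read_alerts(path) -> list[ExitAlert]:
    import csv

    with open(path, newline="") as fh:
        rd = csv.reader(fh)
        next(rd)
        return [ExitAlert(kind=r[1], t=float(r[0]), participant_id=r[2]) for r in rd if r]


def write_label_track(path, labels: Iterable[tuple[float, ActivityLabel]]) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t", "label"])
        for t, lab in labels:
            w.writerow([repr(t), lab.pretty])
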
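"""Event-level alarm scoring and the rotating 6/2/2 cross-validation harness.

An emitted alert is a true positive when the matching ground-truth exit of
its kind starts no more than T = 5 s after the alert, or when the alert
lies within the posture-transition window (1.75 s) around the boundary;
matching is greedy earliest-first and one-to-one per kind. Unmatched
alerts are false positives, unmatched ground-truth exits false negatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import ActivityLabel, AnnotationInterval
from .recognize import BED_NEW, BED_PREV, ExitAlert
from .pipeline import ExitRecognizer

logger = logging.getLogger(__name__)

MATCH_T_SECONDS = 5.0
BOUNDARY_WINDOW_SECONDS = 1.75
KINDS = ("bed", "chair")


class CrossValConfigError(ValueError):
    pass


@dataclass(frozen=True, slots=True)
class GroundTruthExit:
    kind: str   #: "bed" or "chair"
    t: float    #: start of the exit transition


def extract_ground_truth_exits(
    annotations: Sequence[AnnotationInterval],
) -> list[GroundTruthExit]:
    """Qualifying label boundaries, timestamped at the boundary."""
    out: list[GroundTruthExit] = []
    for a, b in zip(annotations, annotations[1:]):
        if a.label in BED_PREV and b.label in BED_NEW:
            out.append(GroundTruthExit(kind="bed", t=b.start))
        elif a.label is ActivityLabel.SITTING_ON_CHAIR and b.label is not a.label:
            out.append(GroundTruthExit(kind="chair", t=b.start))
    return out


@dataclass
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    delays: list[float] = field(default_factory=list)

    def __iadd__(self, other: "MatchCounts") -> "MatchCounts":
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        self.delays.extend(other.delays)
        return self


def match_alerts(
    alerts: Sequence[ExitAlert],
    truths: Sequence[GroundTruthExit],
    t_window: float = MATCH_T_SECONDS,
    boundary_window: float = BOUNDARY_WINDOW_SECONDS,
) -> dict[str, MatchCounts]:
    """Greedy earliest-first one-to-one alert/ground-truth matching per kind.

    Delays are signed: alert time minus ground-truth time (negative when
    the alert precedes the event).
    """
    out: dict[str, MatchCounts] = {}
    for kind in KINDS:
        a_k = sorted((a for a in alerts if a.kind == kind), key=lambda a: a.t)
        t_k = sorted((g for g in truths if g.kind == kind), key=lambda g: g.t)
        matched = [False] * len(t_k)
        counts = MatchCounts()
        for alert in a_k:
            hit = None
            for i, truth in enumerate(t_k):
                if matched[i]:
                    continue
                if alert.t - boundary_window <= truth.t <= alert.t + t_window:
                    hit = i
                    break
                if truth.t > alert.t + t_window:
                    break
            if hit is None:
                counts.fp += 1
            else:
                matched[hit] = True
                counts.tp += 1
                counts.delays.append(alert.t - t_k[hit].t)
        counts.fn = matched.count(False)
        out[kind] = counts
    return out


def metrics(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(recall, precision, F-score); NaN where the denominator is zero."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    precision = tp / (tp + fp) if tp + fp else float("nan")
    if np.isnan(recall) or np.isnan(precision) or recall + precision == 0:
        f = float("nan")
        if not (np.isnan(recall) or np.isnan(precision)):
            f = 0.0
    else:
        f = 2 * recall * precision / (recall + precision)
    return recall, precision, f


def delay_stats(delays: Sequence[float]) -> tuple[float, float, float]:
    """(mean, STD, median) of matched-pair delays; NaNs when empty."""
    if len(delays) == 0:
        return float("nan"), float("nan"), float("nan")
    arr = np.asarray(delays, dtype=float)
    return float(arr.mean()), float(arr.std()), float(np.median(arr))


@dataclass
class KindResult:
    """Per-kind cross-validation aggregate."""

    tp: int
    fp: int
    fn: int
    recall_folds: list[float]
    precision_folds: list[float]
    f_folds: list[float]
    delays: list[float]

    def summary(self) -> dict:
        def ms(vals):
            arr = np.asarray(vals, dtype=float)
            ok = arr[~np.isnan(arr)]
            if len(ok) == 0:
                return {"mean": float("nan"), "std": float("nan")}
            return {"mean": float(ok.mean()), "std": float(ok.std())}

        mean_d, std_d, med_d = delay_stats(self.delays)
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "recall": ms(self.recall_folds),
            "precision": ms(self.precision_folds),
            "f_score": ms(self.f_folds),
            "delay": {"mean": mean_d, "std": std_d, "median": med_d},
        }


@dataclass
class EvalResult:
    """Cross-validation outcome: per-kind fold metrics, pooled counts and
    delay statistics, the fold-assignment manifest, and the selected
    hyperparameters per rotation."""

    per_kind: dict[str, KindResult]
    fold_manifest: list[list[int]]
    selected_params: list[tuple[int, float]]

    def to_dict(self) -> dict:
        return {
            "folds": self.fold_manifest,
            "selected_params": [
                {"tau": t, "vartheta": v} for t, v in self.selected_params
            ],
            "results": {k: r.summary() for k, r in self.per_kind.items()},
        }


@dataclass
class _Prepared:
    """A trial with its featurization and ground truth cached."""

    trial: object
    x_raw: np.ndarray
    y: np.ndarray
    truths: list[GroundTruthExit]


def _prepare(trials: Sequence, room) -> list[_Prepared]:
    from .pipeline import trial_sequence

    out = []
    for t in trials:
        x, y = trial_sequence(t.stream, t.annotations, room)
        out.append(_Prepared(t, x, y, extract_ground_truth_exits(t.annotations)))
    return out


def _match_counts(rec: ExitRecognizer, prepared: Sequence[_Prepared],
                  use_score: bool) -> dict[str, MatchCounts]:
    from .recognize import recognize_stream

    counts = {k: MatchCounts() for k in KINDS}
    for p in prepared:
        _, alerts = recognize_stream(
            rec.model, p.trial.stream, rec.room, scaler=rec.scaler,
            use_score=use_score, features=p.x_raw,
        )
        per_kind = match_alerts(alerts, p.truths)
        for k in KINDS:
            counts[k] += per_kind[k]
    return counts


def _mean_event_f(rec: ExitRecognizer, prepared: Sequence[_Prepared],
                  use_score: bool) -> float:
    counts = _match_counts(rec, prepared, use_score)
    fs = [metrics(c.tp, c.fp, c.fn)[2] for c in counts.values()]
    fs = [f for f in fs if not np.isnan(f)]
    return float(np.mean(fs)) if fs else float("nan")


def crossval(
    trials: Sequence,
    room,
    folds: int = 10,
    tau_grid: Sequence[int] = (0, 1, 2, 4, 8),
    vartheta_grid: Sequence[float] = (1e-4, 3e-4, 1e-3, 1e-2, 1e-1),
    seed: int = 0,
    alpha: float = 1.0,
    use_score: bool = True,
) -> EvalResult:
    """Rotating 6/2/2 cross-validation with (tau, vartheta) selection.

    Trials are partitioned into ``folds`` seeded subsets; rotation r tests
    on subsets {r, r+1}, validates on {r+2, r+3} (hyperparameter selection
    by mean event-level F-score) and trains on the remaining six. Every
    subset serves as test exactly twice across the ``folds`` rotations.
    """
    if len(trials) < folds:
        raise CrossValConfigError(
            f"need at least {folds} trials for {folds}-fold cross-validation, "
            f"got {len(trials)}"
        )
    from . import crf
    from .features import FeatureScaler

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trials))
    subsets = [sorted(int(i) for i in order[s::folds]) for s in range(folds)]
    from .features import feature_schema as _schema_fn

    prepared = _prepare(trials, room)
    schema = _schema_fn(room)

    per_kind = {
        k: KindResult(0, 0, 0, [], [], [], []) for k in KINDS
    }
    selected: list[tuple[int, float]] = []
    for r in range(folds):
        test_ids = subsets[r] + subsets[(r + 1) % folds]
        val_ids = subsets[(r + 2) % folds] + subsets[(r + 3) % folds]
        train_ids = [
            i for i in range(len(trials))
            if i not in set(test_ids) and i not in set(val_ids)
        ]
        train = [prepared[i] for i in train_ids]
        val = [prepared[i] for i in val_ids]
        test = [prepared[i] for i in test_ids]
        scaler = FeatureScaler().fit(np.vstack([p.x_raw for p in train]))
        train_seqs = [(scaler.transform(p.x_raw), p.y) for p in train]
        val_seqs = [(scaler.transform(p.x_raw), p.y) for p in val]
        best = None
        for tau in tau_grid:
            for vt in vartheta_grid:
                model = crf.fit(
                    train_seqs, val_seqs, tau=tau, vartheta=vt, seed=seed,
                    feature_schema=schema, alpha=alpha,
                )
                rec = ExitRecognizer(room=room, scaler=scaler, model=model)
                f_val = _mean_event_f(rec, val, use_score)
                if best is None or (not np.isnan(f_val) and f_val > best[0]):
                    best = (f_val if not np.isnan(f_val) else -np.inf, rec, tau, vt)
        _, rec, tau_sel, vt_sel = best
        selected.append((tau_sel, vt_sel))
        logger.info("rotation %d: selected tau=%d vartheta=%g", r, tau_sel, vt_sel)
        counts = _match_counts(rec, test, use_score)
        for k in KINDS:
            c = counts[k]
            rec_k, prec_k, f_k = metrics(c.tp, c.fp, c.fn)
            agg = per_kind[k]
            agg.tp += c.tp
            agg.fp += c.fp
            agg.fn += c.fn
            agg.recall_folds.append(rec_k)
            agg.precision_folds.append(prec_k)
            agg.f_folds.append(f_k)
            agg.delays.extend(c.delays)
    return EvalResult(
        per_kind=per_kind, fold_manifest=subsets, selected_params=selected
    )
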
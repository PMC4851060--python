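"""End-to-end trained artifact: featurization schema + scaler + chain model."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import crf
from .features import FeatureScaler, featurize_trial
from .io import (
    ActivityLabel,
    AnnotationInterval,
    RoomConfig,
    SensorObservation,
    get_room,
    label_at,
)
from .recognize import ExitAlert, recognize_stream


def trial_sequence(
    stream: Sequence[SensorObservation],
    annotations: Sequence[AnnotationInterval],
    room: RoomConfig,
) -> crf.Seq:
    """(features, 0-based labels) for a ground-truth-annotated trial."""
    x, _ = featurize_trial(stream, room)
    y = np.array([int(label_at(annotations, o.t)) - 1 for o in stream])
    return x, y


@dataclass
class ExitRecognizer:
    """Deployable recognizer: room layout, feature scaler and CRF model."""

    room: RoomConfig
    scaler: FeatureScaler
    model: crf.CRFModel

    @classmethod
    def train(
        cls,
        train_trials: Sequence,
        val_trials: Sequence | None,
        room: RoomConfig,
        tau: int,
        vartheta: float,
        seed: int = 0,
        alpha: float = 1.0,
    ) -> "ExitRecognizer":
        """Fit scaler and dWCRF on trials (objects with .stream/.annotations)."""
        raw = [trial_sequence(t.stream, t.annotations, room) for t in train_trials]
        scaler = FeatureScaler().fit(np.vstack([x for x, _ in raw]))
        train_seqs = [(scaler.transform(x), y) for x, y in raw]
        val_seqs = None
        if val_trials:
            val_seqs = [
                (scaler.transform(x), y)
                for x, y in (
                    trial_sequence(t.stream, t.annotations, room) for t in val_trials
                )
            ]
        x0, schema = featurize_trial(train_trials[0].stream, room)
        del x0
        model = crf.fit(
            train_seqs, val_seqs, tau=tau, vartheta=vartheta, seed=seed,
            feature_schema=schema, alpha=alpha,
        )
        return cls(room=room, scaler=scaler, model=model)

    def recognize(
        self, stream: Sequence[SensorObservation], use_score: bool = True
    ) -> tuple[list[tuple[float, ActivityLabel]], list[ExitAlert]]:
        return recognize_stream(
            self.model, stream, self.room, scaler=self.scaler, use_score=use_score
        )

    def sequence_marginals(self, stream: Sequence[SensorObservation]) -> np.ndarray:
        x, _ = featurize_trial(stream, self.room)
        return crf.forward_marginals(self.model, self.scaler.transform(x))

    def save(self, path: str | Path) -> None:
        payload = {
            "room_id": self.room.room_id,
            "scaler": self.scaler.to_dict(),
            "model": self.model.to_dict(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ExitRecognizer":
        d = json.loads(Path(path).read_text())
        return cls(
            room=get_room(d["room_id"]),
            scaler=FeatureScaler.from_dict(d["scaler"]),
            model=crf.CRFModel.from_dict(d["model"]),
        )
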
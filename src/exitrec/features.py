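"""Per-observation feature extraction for irregular RFID sensor streams.

Three families: instantaneous values of the current read, contextual
statistics over a 4-second sliding window ending at the current read, and
differences of order statistics between consecutive windows. The extra
(dagger) contextual family is emitted only for rooms configured with
``use_dagger_features``.

All features are causal: the vector at time t depends only on reads with
timestamps <= t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid

from .io import RoomConfig, SensorObservation

WINDOW_SECONDS = 4.0
RSSI_FLOOR_DBM = -90.0  # stands in for antennas unseen in a window

_AXES = ("a_v", "a_l", "a_f")


def make_segment(
    stream: Sequence[SensorObservation], index: int
) -> list[SensorObservation]:
    """Window of reads with t in (t_cur - 4, t_cur], current read first."""
    cur = stream[index]
    seg = [cur]
    lo = cur.t - WINDOW_SECONDS
    for j in range(index - 1, -1, -1):
        if stream[j].t <= lo:
            break
        seg.append(stream[j])
    return seg


def instantaneous_features(
    obs: SensorObservation, prev_t: float | None, room: RoomConfig
) -> dict[str, float]:
    """Current-read features: raw axes, tilt/yaw/roll angles, antenna
    one-hot, RSSI, inter-read gap and the gender covariate.

    Angle ratios use the quadrant-aware two-argument arctangent with
    atan2(0, 0) = 0.
    """
    out = {
        "a_v": obs.a_v,
        "a_l": obs.a_l,
        "a_f": obs.a_f,
        "sin_theta": math.sin(math.atan2(obs.a_f, obs.a_v)),
        "yaw": math.atan2(obs.a_l, obs.a_f),
        "roll": math.atan2(obs.a_l, obs.a_v),
    }
    for aid in room.antenna_ids:
        out[f"antenna_is_{aid}"] = 1.0 if obs.antenna_id == aid else 0.0
    out["rssi"] = obs.rssi
    out["dt"] = 0.0 if prev_t is None else obs.t - prev_t
    out["gender"] = float(obs.gender)
    return out


def _wrap_phase(d: float) -> float:
    """Map a phase difference to (-pi, pi]."""
    w = (d + math.pi) % (2.0 * math.pi) - math.pi
    return math.pi if w == -math.pi else w


def _phase_rates(seg_asc: list[SensorObservation]) -> tuple[list[float], list[float]]:
    """(constant-frequency, variable-frequency) phase rates over consecutive
    reads, rad/s, with wrap-around handling; zero-gap pairs skipped."""
    cfpr, vfpr = [], []
    for a, b in zip(seg_asc, seg_asc[1:]):
        dt = b.t - a.t
        if dt <= 0:
            continue
        rate = _wrap_phase(b.phase - a.phase) / dt
        (cfpr if b.channel == a.channel else vfpr).append(rate)
    return cfpr, vfpr


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2:
        return 0.0
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def _displacement_av(seg_asc: list[SensorObservation]) -> float:
    """Double time-integral of gravity-removed a_v over the window."""
    if len(seg_asc) < 2:
        return 0.0
    t = np.array([o.t for o in seg_asc])
    a = np.array([o.a_v for o in seg_asc])
    a = a - a.mean()  # remove the static (gravity) component
    v = cumulative_trapezoid(a, t, initial=0.0)
    return float(trapezoid(v, t))


def contextual_features(
    seg: Sequence[SensorObservation],
    room: RoomConfig,
    rssi_floor: float = RSSI_FLOOR_DBM,
) -> dict[str, float]:
    """Window features: antenna read fractions, the bed/chair area
    alternation score, max/min-RSSI antenna indicators, vertical
    displacement, axis-pair correlations, and — when the room requests the
    dagger family — acceleration and per-antenna RSSI moments plus the two
    phase-rate summaries.
    """
    if not seg:
        raise ValueError("segment must contain the current observation")
    n = len(seg)
    out: dict[str, float] = {}
    counts = {aid: 0 for aid in room.antenna_ids}
    for o in seg:
        counts[o.antenna_id] += 1
    for aid in room.antenna_ids:
        out[f"seg_read_frac_{aid}"] = counts[aid] / n

    # adjacent-pair alternation between bed and chair areas
    areas = [room.area_of(o.antenna_id) for o in seg]
    flips = sum(
        1 for a, b in zip(areas, areas[1:]) if (a, b) in (("bed", "chair"), ("chair", "bed"))
    )
    out["seg_area_mi"] = flips / n

    rssis = [o.rssi for o in seg]
    max_aid = seg[int(np.argmax(rssis))].antenna_id
    min_aid = seg[int(np.argmin(rssis))].antenna_id
    for aid in room.antenna_ids:
        out[f"seg_max_rssi_is_{aid}"] = 1.0 if aid == max_aid else 0.0
        out[f"seg_min_rssi_is_{aid}"] = 1.0 if aid == min_aid else 0.0

    seg_asc = sorted(seg, key=lambda o: o.t)
    out["seg_disp_av"] = _displacement_av(seg_asc)

    acc = np.array([[o.a_v, o.a_l, o.a_f] for o in seg])
    out["seg_corr_vl"] = _pearson(acc[:, 0], acc[:, 1])
    out["seg_corr_vf"] = _pearson(acc[:, 0], acc[:, 2])
    out["seg_corr_lf"] = _pearson(acc[:, 1], acc[:, 2])

    if room.use_dagger_features:
        for k, axis in enumerate(_AXES):
            out[f"seg_mean_{axis}"] = float(acc[:, k].mean())
            out[f"seg_sd_{axis}"] = float(acc[:, k].std())
        for aid in room.antenna_ids:
            vals = [o.rssi for o in seg if o.antenna_id == aid]
            if vals:
                out[f"seg_rssi_mean_{aid}"] = float(np.mean(vals))
                out[f"seg_rssi_sd_{aid}"] = float(np.std(vals))
            else:
                out[f"seg_rssi_mean_{aid}"] = rssi_floor
                out[f"seg_rssi_sd_{aid}"] = 0.0
        cfpr, vfpr = _phase_rates(seg_asc)
        out["seg_vfpr_sd"] = float(np.std(vfpr)) if vfpr else 0.0
        out["seg_cfpr_abs_sum"] = float(np.sum(np.abs(cfpr))) if cfpr else 0.0
    return out


def _axis_stats(seg: Sequence[SensorObservation]) -> dict[str, float]:
    acc = np.array([[o.a_v, o.a_l, o.a_f] for o in seg])
    out = {}
    for k, axis in enumerate(_AXES):
        out[f"{axis}_median"] = float(np.median(acc[:, k]))
        out[f"{axis}_max"] = float(acc[:, k].max())
        out[f"{axis}_min"] = float(acc[:, k].min())
    return out


def _rssi_stats(
    seg: Sequence[SensorObservation], room: RoomConfig, floor: float
) -> dict[str, float]:
    out = {}
    for aid in room.antenna_ids:
        vals = [o.rssi for o in seg if o.antenna_id == aid]
        if vals:
            out[f"rssi_{aid}_median"] = float(np.median(vals))
            out[f"rssi_{aid}_max"] = float(max(vals))
            out[f"rssi_{aid}_min"] = float(min(vals))
        else:
            out[f"rssi_{aid}_median"] = floor
            out[f"rssi_{aid}_max"] = floor
            out[f"rssi_{aid}_min"] = floor
    return out


def intersegment_features(
    seg_cur: Sequence[SensorObservation],
    seg_prev: Sequence[SensorObservation],
    room: RoomConfig,
    rssi_floor: float = RSSI_FLOOR_DBM,
) -> dict[str, float]:
    """Differences (current - previous window) of median/max/min per
    acceleration axis and of per-antenna RSSI; antennas missing from a
    window contribute the RSSI floor."""
    cur = {**_axis_stats(seg_cur), **_rssi_stats(seg_cur, room, rssi_floor)}
    prev = {**_axis_stats(seg_prev), **_rssi_stats(seg_prev, room, rssi_floor)}
    return {f"dseg_{k}": cur[k] - prev[k] for k in cur}


def feature_schema(room: RoomConfig) -> list[str]:
    """Ordered feature names for ``room`` (fixed per dataset)."""
    dummy = SensorObservation(
        t=0.0, a_v=1.0, a_l=0.0, a_f=0.0, rssi=-60.0,
        antenna_id=room.antenna_ids[0], phase=0.0, channel=0,
        participant_id="p", gender=0,
    )
    seg = [dummy]
    names = list(instantaneous_features(dummy, None, room))
    names += list(contextual_features(seg, room))
    names += list(intersegment_features(seg, seg, room))
    return names


def featurize_trial(
    stream: Sequence[SensorObservation],
    room: RoomConfig,
    rssi_floor: float = RSSI_FLOOR_DBM,
) -> tuple[np.ndarray, list[str]]:
    """Feature matrix (one row per observation) plus its column schema."""
    schema = feature_schema(room)
    if not stream:
        return np.zeros((0, len(schema))), schema
    rows = np.empty((len(stream), len(schema)))
    seg_prev: list[SensorObservation] | None = None
    prev_t: float | None = None
    for i, obs in enumerate(stream):
        seg = make_segment(stream, i)
        feats = instantaneous_features(obs, prev_t, room)
        feats.update(contextual_features(seg, room, rssi_floor))
        feats.update(
            intersegment_features(seg, seg_prev if seg_prev is not None else seg,
                                  room, rssi_floor)
        )
        rows[i] = [feats[name] for name in schema]
        seg_prev = seg
        prev_t = obs.t
    return rows, schema


@dataclass
class FeatureScaler:
    """Column-wise z-scoring with training-fold statistics.

    Constant columns get unit scale so indicator features pass through
    unchanged up to centering.
    """

    mean: np.ndarray | None = None
    scale: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "FeatureScaler":
        self.mean = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0.0] = 1.0
        self.scale = sd
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.mean is None or self.scale is None:
            raise RuntimeError("scaler is not fitted")
        return (x - self.mean) / self.scale

    def fit_transform(self, x: np.ndarray) -> np.ndarray:
        return self.fit(x).transform(x)

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        return cls(mean=np.asarray(d["mean"]), scale=np.asarray(d["scale"]))
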
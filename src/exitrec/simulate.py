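"""Synthetic wearable-RFID trial generator.

Produces sensor streams that mimic the phenomena the recognizer has to
survive: bursty irregular read arrivals, posture- and occlusion-dependent
dropout, an inverse-fourth-power backscatter RSSI link with log-normal
multipath, and chest-sensor acceleration that barely distinguishes the
upright postures. Every trial comes with exact interval ground truth.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .io import (
    ActivityLabel,
    AnnotationInterval,
    RoomConfig,
    SensorObservation,
    validate_annotations,
    write_annotations,
    write_stream,
)

__all__ = [
    "RSSIModelParams", "ActivityScript", "SimConfig", "Trial",
    "rssi_db", "simulate_trial", "make_benchmark",
    "default_sim_config", "default_rssi_params",
]

_B = ActivityLabel.SITTING_ON_BED
_C = ActivityLabel.SITTING_ON_CHAIR
_L = ActivityLabel.LYING
_A = ActivityLabel.AMBULATING

#: which activities may follow each activity (supine only via sitting-on-bed)
PLAUSIBLE_NEXT = {
    _L: (_B,),
    _B: (_L, _A, _C),
    _C: (_A, _B),
    _A: (_B, _C),
}


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RSSIModelParams:
    """Parameters of the monostatic backscatter link budget.

    ``p_t`` is in linear milliwatt so the returned power is on the dBm
    scale; the remaining gains are dimensionless and ``wl`` is the carrier
    wavelength in meters. ``h_sigma`` scales the log-normal multipath
    magnitude (unit median).
    """

    k_b: float = 0.1
    p_t: float = 1000.0
    g_t: float = 4.0
    wl: float = 0.326
    h_sigma: float = 0.15

    def __post_init__(self) -> None:
        if min(self.k_b, self.p_t, self.g_t, self.wl) <= 0 or self.h_sigma < 0:
            raise SimulationConfigError("RSSI model parameters must be positive")


def rssi_db(params: RSSIModelParams, d_o: float, h_mag: float = 1.0) -> float:
    """Received backscatter power in dBm at direct distance ``d_o`` meters.

    Implements the fourth-power link
    ``10*log10(k_b * p_t * g_t * wl**4 * h_mag**4 / (4*pi*d_o)**4)``.
    """
    if d_o <= 0:
        raise ValueError(f"direct distance must be positive, got {d_o}")
    if h_mag <= 0:
        raise ValueError(f"multipath magnitude must be positive, got {h_mag}")
    lin = (
        params.k_b * params.p_t * params.g_t
        * params.wl ** 4 * h_mag ** 4 / (4.0 * math.pi * d_o) ** 4
    )
    return 10.0 * math.log10(lin)


@dataclass(frozen=True)
class ActivityScript:
    """An ordered list of (activity, duration-seconds) steps."""

    steps: tuple[tuple[ActivityLabel, float], ...]
    room: RoomConfig

    def __post_init__(self) -> None:
        if not self.steps:
            raise SimulationConfigError("script must have at least one step")
        for label, dur in self.steps:
            if dur <= 0:
                raise SimulationConfigError(f"non-positive duration for {label}")
        for (a, _), (b, _) in zip(self.steps, self.steps[1:]):
            if b not in PLAUSIBLE_NEXT[a]:
                raise SimulationConfigError(
                    f"implausible transition {a.pretty} -> {b.pretty}"
                )

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.steps)

    def annotations(self) -> list[AnnotationInterval]:
        out, t = [], 0.0
        for label, dur in self.steps:
            out.append(AnnotationInterval(t, t + dur, label))
            t += dur
        return validate_annotations(out)


@dataclass(frozen=True)
class SimConfig:
    """Generative knobs for one trial.

    ``read_rate_hz`` / ``dropout_prob`` are keyed ``(activity, antenna_id)``;
    reads per antenna arrive as a Poisson process thinned by the dropout
    probability. ``posture_orientation`` maps each activity to the mean
    accelerometer triple (a_v, a_l, a_f) in g. Positions are 3-D meters.
    """

    seed: int
    read_rate_hz: dict[tuple[ActivityLabel, str], float]
    dropout_prob: dict[tuple[ActivityLabel, str], float]
    accel_noise_sd: float
    posture_orientation: dict[ActivityLabel, tuple[float, float, float]]
    antenna_positions: dict[str, tuple[float, float, float]]
    furniture_positions: dict[str, tuple[float, float, float]]
    gait_amplitude: float = 0.25
    gait_freq_hz: float = 1.8
    phase_noise_sd: float = 0.1
    n_channels: int = 8
    participant_id: str = "p00"
    gender: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.read_rate_hz.values()):
            raise SimulationConfigError("read rates must be positive")
        if any(not 0.0 <= p <= 1.0 for p in self.dropout_prob.values()):
            raise SimulationConfigError("dropout probabilities must be in [0, 1]")
        if self.accel_noise_sd < 0:
            raise SimulationConfigError("accel_noise_sd must be nonnegative")


@dataclass(frozen=True)
class Trial:
    """A simulated trial: stream, exact ground truth, and its manifest."""

    stream: list[SensorObservation]
    annotations: list[AnnotationInterval]
    manifest: dict

    def write(self, directory: str | Path, stem: str) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_stream(directory / f"{stem}.stream.csv", self.stream)
        write_annotations(directory / f"{stem}.annotations.csv", self.annotations)
        with open(directory / f"{stem}.manifest.yaml", "w") as fh:
            yaml.safe_dump(self.manifest, fh, sort_keys=True)


# geometry shared by the default room layouts (meters)
_FURNITURE = {"bed": (1.0, 3.2, 0.6), "chair": (3.5, 1.0, 0.5), "door": (0.3, 0.3, 0.0)}

_ANTENNAS = {
    "room1": {
        "antenna1": (0.4, 3.0, 1.4),
        "antenna2": (3.6, 1.6, 1.6),   # inclined towards the chair
        "antenna3": (1.0, 3.2, 2.6),   # ceiling, above the bed
        "antenna4": (1.8, 3.8, 1.4),
    },
    "room2": {
        "antenna1": (3.6, 1.6, 1.6),   # vertical stand, chair
        "antenna2": (0.7, 2.9, 2.6),   # ceiling, bed
        "antenna3": (1.5, 3.4, 2.6),   # ceiling, bed
    },
}

#: mean chest orientation per posture: upright ~ (1,0,0) g, supine ~ (0,0,1) g
_ORIENTATION = {
    _B: (0.97, 0.05, 0.24),
    _C: (0.90, -0.08, 0.42),
    _L: (0.08, 0.05, 0.99),
    _A: (0.99, 0.0, 0.12),
}


def default_sim_config(
    room: RoomConfig,
    seed: int = 0,
    profile: str = "high_snr",
    participant_id: str = "p00",
    gender: int = 0,
) -> SimConfig:
    """Build a SimConfig for ``room``.

    ``profile`` is ``"high_snr"`` (dense reads, mild dropout, low noise)
    or ``"noisy"`` (sparse bursty reads, strong occlusion dropout, more
    acceleration and multipath noise).
    """
    if profile not in ("high_snr", "noisy"):
        raise SimulationConfigError(f"unknown profile {profile!r}")
    high = profile == "high_snr"
    # base per-antenna rates by (activity area affinity)
    rates: dict[tuple[ActivityLabel, str], float] = {}
    drops: dict[tuple[ActivityLabel, str], float] = {}
    for aid, area in room.antennas.items():
        for act in ActivityLabel:
            near_bed = act in (_L, _B)
            near_chair = act is _C
            if (near_bed and area == "bed") or (near_chair and area == "chair"):
                rate = 3.5 if high else 1.4
                drop = 0.02 if high else 0.15
            elif act is _A:
                rate = 2.2 if high else 0.7
                drop = 0.04 if high else 0.35
            else:
                rate = 1.0 if high else 0.3
                drop = 0.08 if high else 0.55
            rates[(act, aid)] = rate
            drops[(act, aid)] = drop
    return SimConfig(
        seed=seed,
        read_rate_hz=rates,
        dropout_prob=drops,
        accel_noise_sd=0.03 if high else 0.12,
        posture_orientation=dict(_ORIENTATION),
        antenna_positions=dict(_ANTENNAS[room.room_id]),
        furniture_positions=dict(_FURNITURE),
        participant_id=participant_id,
        gender=gender,
    )


def default_rssi_params(profile: str = "high_snr") -> RSSIModelParams:
    return RSSIModelParams(h_sigma=0.05 if profile == "high_snr" else 0.45)


def _anchor(sim: SimConfig, label: ActivityLabel) -> np.ndarray:
    """Sensor (chest) position while holding a static posture."""
    bed = np.asarray(sim.furniture_positions["bed"])
    chair = np.asarray(sim.furniture_positions["chair"])
    if label is _L:
        return bed + np.array([0.0, 0.0, 0.25])
    if label is _B:
        return bed + np.array([0.35, -0.35, 0.55])
    if label is _C:
        return chair + np.array([0.0, 0.0, 0.60])
    raise ValueError("ambulation has no static anchor")


def _positions(
    sim: SimConfig, script: ActivityScript, times: np.ndarray, step_idx: int
) -> np.ndarray:
    """Sensor positions at ``times`` within script step ``step_idx``.

    Static postures sit at their anchor; ambulation walks a straight line
    from the previous posture's anchor to the next one's (or the door).
    """
    steps = script.steps
    label = steps[step_idx][0]
    start_t = sum(d for _, d in steps[:step_idx])
    dur = steps[step_idx][1]
    if label is not _A:
        return np.tile(_anchor(sim, label), (len(times), 1))
    src = (
        _anchor(sim, steps[step_idx - 1][0])
        if step_idx > 0
        else np.asarray(sim.furniture_positions["door"]) + np.array([0, 0, 1.3])
    )
    dst = (
        _anchor(sim, steps[step_idx + 1][0])
        if step_idx + 1 < len(steps)
        else np.asarray(sim.furniture_positions["door"]) + np.array([0, 0, 1.3])
    )
    frac = np.clip((times - start_t) / dur, 0.0, 1.0)[:, None]
    pos = src[None, :] * (1 - frac) + dst[None, :] * frac
    pos[:, 2] = 1.3  # chest height while walking
    return pos


def simulate_trial(
    script: ActivityScript,
    sim: SimConfig,
    rssi: RSSIModelParams | None = None,
) -> Trial:
    """Simulate one trial; identical inputs (incl. seed) give identical output."""
    rssi = rssi or default_rssi_params()
    rng = np.random.default_rng(sim.seed)
    room = script.room
    rows: list[tuple] = []
    t0 = 0.0
    for idx, (label, dur) in enumerate(script.steps):
        for aid in room.antenna_ids:
            rate = sim.read_rate_hz[(label, aid)]
            keep = 1.0 - sim.dropout_prob[(label, aid)]
            n = rng.poisson(rate * keep * dur)
            if n == 0:
                continue
            times = np.sort(t0 + rng.uniform(0.0, dur, size=n))
            pos = _positions(sim, script, times, idx)
            ant = np.asarray(sim.antenna_positions[aid])
            dist = np.linalg.norm(pos - ant[None, :], axis=1)
            h = np.exp(rng.normal(0.0, rssi.h_sigma, size=n))  # unit median
            power = np.array(
                [rssi_db(rssi, d, hm) for d, hm in zip(dist, h)]
            )
            mean = np.asarray(sim.posture_orientation[label])
            acc = mean[None, :] + rng.normal(0.0, sim.accel_noise_sd, size=(n, 3))
            if label is _A:  # gait oscillation, strongest on the vertical axis
                ph0 = rng.uniform(0, 2 * math.pi)
                osc = np.sin(2 * math.pi * sim.gait_freq_hz * times + ph0)
                acc[:, 0] += sim.gait_amplitude * osc
                acc[:, 1] += 0.4 * sim.gait_amplitude * np.sin(
                    math.pi * sim.gait_freq_hz * times + ph0
                )
            acc = np.clip(acc, -3.0, 3.0)
            chan = rng.integers(0, sim.n_channels, size=n)
            phase = np.mod(
                4 * math.pi * dist / rssi.wl
                + rng.normal(0.0, sim.phase_noise_sd, size=n),
                2 * math.pi,
            )
            for k in range(n):
                rows.append((
                    float(times[k]), float(acc[k, 0]), float(acc[k, 1]),
                    float(acc[k, 2]), float(power[k]), aid, float(phase[k]),
                    int(chan[k]),
                ))
        t0 += dur
    rows.sort(key=lambda r: r[0])
    stream = [
        SensorObservation(
            t=r[0], a_v=r[1], a_l=r[2], a_f=r[3], rssi=r[4], antenna_id=r[5],
            phase=r[6], channel=r[7], participant_id=sim.participant_id,
            gender=sim.gender,
        )
        for r in rows
    ]
    manifest = {
        "seed": sim.seed,
        "room_id": room.room_id,
        "participant_id": sim.participant_id,
        "script": [[lab.pretty, float(d)] for lab, d in script.steps],
        "config_sha1": _config_hash(sim, rssi),
        "n_observations": len(stream),
    }
    return Trial(stream=stream, annotations=script.annotations(), manifest=manifest)


def _config_hash(sim: SimConfig, rssi: RSSIModelParams) -> str:
    blob = repr((sorted(sim.read_rate_hz.items()), sorted(sim.dropout_prob.items()),
                 sim.accel_noise_sd, sorted(sim.posture_orientation.items()),
                 sorted(sim.antenna_positions.items()),
                 sorted(sim.furniture_positions.items()), rssi)).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


# --- benchmark generation -------------------------------------------------

#: script templates; "direct" templates exercise the bed<->chair transfers
#: that the exit-recognition state machine special-cases.
_TEMPLATES = [
    (_A, _C, _A, _B, _L, _B, _A),
    (_A, _B, _L, _B, _A, _C, _A),
    (_A, _B, _C, _A, _B, _L, _B, _A),          # direct bed -> chair transfer
    (_A, _C, _B, _L, _B, _A),                  # direct chair -> bed transfer
    (_A, _B, _L, _B, _C, _A, _B, _L, _B, _A),  # direct transfers both ways
]

DEFAULT_IMBALANCE_PROFILE = {
    _L: 0.55, _B: 0.30, _C: 0.11, _A: 0.04,
}


def _effective_rate(sim: SimConfig, room: RoomConfig, label: ActivityLabel) -> float:
    """Expected reads per second while performing ``label``."""
    return sum(
        sim.read_rate_hz[(label, aid)] * (1 - sim.dropout_prob[(label, aid)])
        for aid in room.antenna_ids
    )


def make_script(
    room: RoomConfig,
    sim: SimConfig,
    rng: np.random.Generator,
    total_duration: float,
    profile: dict[ActivityLabel, float],
) -> ActivityScript:
    """Draw a script whose expected pooled *read* fractions track ``profile``.

    Durations are allocated per activity proportional to profile share
    divided by that activity's effective read rate, then split across the
    template's visits with a mild Dirichlet jitter.
    """
    template = _TEMPLATES[rng.integers(len(_TEMPLATES))]
    shares = {
        lab: profile[lab] / _effective_rate(sim, room, lab) for lab in ActivityLabel
    }
    z = sum(shares.values())
    budget = {lab: total_duration * s / z for lab, s in shares.items()}
    steps: list[tuple[ActivityLabel, float]] = []
    counts = {lab: sum(1 for x in template if x is lab) for lab in ActivityLabel}
    splits: dict[ActivityLabel, list[float]] = {}
    for lab, c in counts.items():
        if c == 0:
            continue
        frac = rng.dirichlet(np.full(c, 8.0))
        splits[lab] = list(budget[lab] * frac)
    for lab in template:
        steps.append((lab, max(1.5, splits[lab].pop(0))))
    return ActivityScript(steps=tuple(steps), room=room)


def make_benchmark(
    n_trials: int,
    room: RoomConfig,
    seed: int = 0,
    imbalance_profile: dict[ActivityLabel, float] | None = None,
    profile: str = "high_snr",
    trial_duration: float = 120.0,
) -> list[Trial]:
    """Generate a labeled benchmark of ``n_trials`` simulated trials."""
    if n_trials < 1:
        raise SimulationConfigError("n_trials must be >= 1")
    fractions = dict(imbalance_profile or DEFAULT_IMBALANCE_PROFILE)
    if abs(sum(fractions.values()) - 1.0) > 1e-6:
        raise SimulationConfigError("imbalance profile fractions must sum to 1")
    if set(fractions) != set(ActivityLabel):
        raise SimulationConfigError("imbalance profile must cover all 4 activities")
    root = np.random.default_rng(seed)
    trials = []
    for i in range(n_trials):
        trial_seed = int(root.integers(0, 2**31 - 1))
        sim = default_sim_config(
            room,
            seed=trial_seed,
            profile=profile,
            participant_id=f"p{i % 7:02d}",
            gender=i % 2,
        )
        rng = np.random.default_rng(trial_seed + 1)
        script = make_script(room, sim, rng, trial_duration, fractions)
        trials.append(simulate_trial(script, sim, default_rssi_params(profile)))
    return trials
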
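"""Domain types and delimited-text I/O for sensor streams and annotations.

Streams are CSV files with the fixed header
``t,a_v,a_l,a_f,rssi,antenna_id,phase,channel,participant_id,gender``,
one trial per file, rows sorted by time. Annotations are CSV files with
header ``start,end,label`` holding half-open ``[start, end)`` intervals
that partition the trial span.
"""

from __future__ import annotations

import bisect
import csv
import enum
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import yaml

logger = logging.getLogger(__name__)

STREAM_HEADER = [
    "t", "a_v", "a_l", "a_f", "rssi",
    "antenna_id", "phase", "channel", "participant_id", "gender",
]
ANNOTATION_HEADER = ["start", "end", "label"]

#: accelerometer full-scale range, in g
ACCEL_FULL_SCALE = 3.0


class SchemaError(ValueError):
    """A file does not conform to the expected schema."""


class OrderingError(ValueError):
    """Stream rows are not sorted by time."""


class AnnotationError(ValueError):
    """Annotation intervals violate the overlap/ordering invariants."""


class LabelLookupError(KeyError):
    """A probed time falls outside every annotated interval."""


class ActivityLabel(enum.IntEnum):
    """The four recognized activity classes."""

    SITTING_ON_BED = 1
    SITTING_ON_CHAIR = 2
    LYING = 3
    AMBULATING = 4

    @classmethod
    def from_name(cls, name: str) -> "ActivityLabel":
        key = name.strip().replace("-", "_").replace(" ", "_").upper()
        try:
            return cls[key]
        except KeyError:
            raise SchemaError(f"unknown activity label: {name!r}") from None

    @property
    def pretty(self) -> str:
        return self.name.replace("_", "-").title().replace("On", "on")


N_CLASSES = len(ActivityLabel)


@dataclass(frozen=True, slots=True)
class SensorObservation:
    """One RFID read from the wearable sensor."""

    t: float                #: seconds since trial start
    a_v: float              #: vertical acceleration, g
    a_l: float              #: lateral acceleration, g
    a_f: float              #: frontal acceleration, g
    rssi: float             #: received signal strength, dBm
    antenna_id: str
    phase: float            #: RF phase angle, radians in [0, 2*pi)
    channel: int            #: frequency-channel index
    participant_id: str
    gender: int             #: binary-coded covariate {0, 1}


@dataclass(frozen=True, slots=True)
class AnnotationInterval:
    """Ground-truth activity over the half-open interval [start, end)."""

    start: float
    end: float
    label: ActivityLabel

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(
                f"interval start must precede end, got [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class RoomConfig:
    """Antenna layout of a deployment room.

    ``antennas`` maps antenna_id -> area, where area is ``"bed"`` or
    ``"chair"``. ``use_dagger_features`` switches on the extra feature
    family used only by the 4-antenna room.
    """

    room_id: str
    antennas: dict[str, str]
    use_dagger_features: bool

    def __post_init__(self) -> None:
        bad = set(self.antennas.values()) - {"bed", "chair"}
        if bad:
            raise SchemaError(f"unknown antenna areas: {sorted(bad)}")

    @property
    def antenna_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.antennas))

    def area_of(self, antenna_id: str) -> str:
        try:
            return self.antennas[antenna_id]
        except KeyError:
            raise SchemaError(
                f"antenna_id {antenna_id!r} not in room {self.room_id} "
                f"(expected one of {sorted(self.antennas)})"
            ) from None


#: 4-antenna deployment: antenna2 covers the chair, the rest the bed.
ROOM1 = RoomConfig(
    room_id="room1",
    antennas={"antenna1": "bed", "antenna2": "chair",
              "antenna3": "bed", "antenna4": "bed"},
    use_dagger_features=True,
)

#: 3-antenna deployment: antenna1 covers the chair, antenna2/3 the bed.
ROOM2 = RoomConfig(
    room_id="room2",
    antennas={"antenna1": "chair", "antenna2": "bed", "antenna3": "bed"},
    use_dagger_features=False,
)

ROOMS = {"room1": ROOM1, "room2": ROOM2}


def get_room(room_id: str) -> RoomConfig:
    try:
        return ROOMS[room_id.lower()]
    except KeyError:
        raise SchemaError(f"unknown room_id {room_id!r}") from None


def load_room_config(path: str | Path) -> RoomConfig:
    """Load a RoomConfig from a YAML file keyed by room_id."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RoomConfig(
        room_id=raw["room_id"],
        antennas=dict(raw["antennas"]),
        use_dagger_features=bool(raw["use_dagger_features"]),
    )


def read_stream(path: str | Path, room: RoomConfig) -> list[SensorObservation]:
    """Read a trial's sensor stream, validating against ``room``.

    Rows with non-finite or out-of-range values are dropped with a
    row-indexed warning. Unknown antenna ids raise :class:`SchemaError`;
    time going backwards raises :class:`OrderingError`. Rows with equal
    timestamps keep file order.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, expected header") from None
        if [h.strip() for h in header] != STREAM_HEADER:
            raise SchemaError(
                f"{path}: bad header {header!r}, expected {STREAM_HEADER!r}"
            )
        obs: list[SensorObservation] = []
        prev_t = -math.inf
        for i, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                o = SensorObservation(
                    t=float(row[0]), a_v=float(row[1]), a_l=float(row[2]),
                    a_f=float(row[3]), rssi=float(row[4]),
                    antenna_id=row[5].strip(), phase=float(row[6]),
                    channel=int(row[7]), participant_id=row[8].strip(),
                    gender=int(row[9]),
                )
            except (ValueError, IndexError) as exc:
                logger.warning("%s:%d: dropping malformed row (%s)", path, i, exc)
                continue
            room.area_of(o.antenna_id)  # raises SchemaError on unknown id
            if o.t < prev_t:
                raise OrderingError(
                    f"{path}:{i}: time {o.t} precedes previous {prev_t}"
                )
            if not all(
                math.isfinite(v) for v in (o.t, o.a_v, o.a_l, o.a_f, o.rssi, o.phase)
            ) or max(abs(o.a_v), abs(o.a_l), abs(o.a_f)) > ACCEL_FULL_SCALE:
                logger.warning("%s:%d: dropping out-of-range row", path, i)
                continue
            prev_t = o.t
            obs.append(o)
    return obs


def write_stream(path: str | Path, stream: Iterable[SensorObservation]) -> None:
    """Write a stream CSV that round-trips exactly through ``read_stream``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(STREAM_HEADER)
        for o in stream:
            writer.writerow([
                repr(float(o.t)), repr(float(o.a_v)), repr(float(o.a_l)),
                repr(float(o.a_f)), repr(float(o.rssi)), o.antenna_id,
                repr(float(o.phase)), int(o.channel), o.participant_id,
                int(o.gender),
            ])


def read_annotations(path: str | Path) -> list[AnnotationInterval]:
    """Read and validate interval annotations from CSV."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, expected header") from None
        if [h.strip() for h in header] != ANNOTATION_HEADER:
            raise SchemaError(
                f"{path}: bad header {header!r}, expected {ANNOTATION_HEADER!r}"
            )
        intervals = [
            AnnotationInterval(float(r[0]), float(r[1]), ActivityLabel.from_name(r[2]))
            for r in reader if r
        ]
    return validate_annotations(intervals)


def write_annotations(path: str | Path, intervals: Iterable[AnnotationInterval]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ANNOTATION_HEADER)
        for iv in intervals:
            writer.writerow([repr(float(iv.start)), repr(float(iv.end)),
                             iv.label.pretty])


def validate_annotations(
    intervals: Sequence[AnnotationInterval],
) -> list[AnnotationInterval]:
    """Sort intervals and reject overlaps (adjacency at a shared boundary
    is allowed under the half-open convention)."""
    ordered = sorted(intervals, key=lambda iv: iv.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise AnnotationError(
                f"intervals overlap: [{a.start}, {a.end}) and [{b.start}, {b.end})"
            )
    return ordered


def label_at(annotations: Sequence[AnnotationInterval], t: float) -> ActivityLabel:
    """Ground-truth label at time ``t`` under the [start, end) convention."""
    starts = [iv.start for iv in annotations]
    i = bisect.bisect_right(starts, t) - 1
    if i >= 0 and annotations[i].start <= t < annotations[i].end:
        return annotations[i].label
    raise LabelLookupError(f"t={t} outside every annotated interval")
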
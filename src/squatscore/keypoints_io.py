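"""Read, validate and write 17-keypoint 2-D pose trajectories.

The containers mirror what a browser-side pose estimator (PoseNet / MoveNet
style, COCO 17-part layout) emits: per frame, one (x, y, confidence) triple
per named body part, with x increasing rightward and y increasing DOWNWARD
(image convention).  I/O is lossless and convention-free: no smoothing,
no coordinate flips — all "height" semantics live in :mod:`.kinematics`.

Two encodings are supported:

* JSON — ``{"fps": 30, "source_id": "...", "frames": [{"t": 0.0,
  "keypoints": [{"part": "nose", "x": 1.0, "y": 2.0, "score": 0.9}, ...]}]}``
  (schema shipped as ``schemas/pose_input.schema.json``)
* long-format CSV with header ``t,part,x,y,score``, one row per
  (frame, part).

Parts missing from a frame are represented, not dropped: they are filled
with NaN coordinates and confidence 0 so frame indices stay aligned with
timestamps.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Union

import pandas as pd

from .errors import PoseParseError, PoseSchemaError, PoseValidationError

#: The closed set of 17 COCO part names, in canonical order.
PART_NAMES: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

_PART_SET = frozenset(PART_NAMES)

CSV_HEADER = ("t", "part", "x", "y", "score")


@dataclass(frozen=True)
class Keypoint:
    """A named 2-D landmark with detection confidence.

    ``x``/``y`` are image pixels (y grows downward); ``confidence`` is
    unitless in [0, 1].  A missing detection is encoded as NaN coordinates
    with confidence 0.
    """

    name: str
    x: float
    y: float
    confidence: float

    def __post_init__(self) -> None:
        if self.name not in _PART_SET:
            raise PoseSchemaError(f"unknown part name: {self.name!r}")
        if not (0.0 <= self.confidence <= 1.0):
            raise PoseValidationError(
                f"confidence {self.confidence!r} for {self.name} outside [0, 1]"
            )


@dataclass(frozen=True)
class PoseFrame:
    """One time sample: a timestamp plus exactly one keypoint per part."""

    timestamp: float
    keypoints: dict[str, Keypoint]

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise PoseValidationError(f"negative timestamp {self.timestamp}")
        if set(self.keypoints) != _PART_SET:
            missing = _PART_SET - set(self.keypoints)
            extra = set(self.keypoints) - _PART_SET
            raise PoseSchemaError(
                f"frame at t={self.timestamp} must carry all 17 parts "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )

    @classmethod
    def from_partial(cls, timestamp: float, keypoints: Iterable[Keypoint]) -> "PoseFrame":
        """Build a frame, filling absent parts with confidence-0 NaN keypoints."""
        table: dict[str, Keypoint] = {}
        for kp in keypoints:
            if kp.name in table:
                raise PoseValidationError(
                    f"duplicate part {kp.name!r} at t={timestamp}"
                )
            table[kp.name] = kp
        for name in PART_NAMES:
            if name not in table:
                table[name] = Keypoint(name, math.nan, math.nan, 0.0)
        return cls(timestamp, table)

    def __getitem__(self, part: str) -> Keypoint:
        return self.keypoints[part]


@dataclass
class PoseSequence:
    """A time-ordered pose trajectory.

    Timestamps are authoritative; ``nominal_fps`` is advisory metadata used
    only to choose the uniform resampling grid downstream.
    """

    frames: list[PoseFrame]
    nominal_fps: float = 30.0
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise PoseValidationError(
                f"a pose sequence needs >= 2 frames, got {len(self.frames)}"
            )
        if self.nominal_fps <= 0:
            raise PoseValidationError(f"nominal_fps must be > 0, got {self.nominal_fps}")
        ts = [f.timestamp for f in self.frames]
        for a, b in zip(ts, ts[1:]):
            if not b > a:
                raise PoseValidationError(
                    f"timestamps must be strictly increasing ({a} -> {b})"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def timestamps(self) -> list[float]:
        return [f.timestamp for f in self.frames]

    @property
    def duration(self) -> float:
        return self.frames[-1].timestamp - self.frames[0].timestamp


Stream = Union[IO[str], IO[bytes]]


def _as_text(stream: Stream) -> str:
    data = stream.read()
    if isinstance(data, bytes):
        return data.decode("utf-8")
    return data


def read_pose_json(stream: Stream) -> PoseSequence:
    """Parse the JSON pose encoding into a :class:`PoseSequence`.

    Raises :class:`PoseParseError` (naming the byte offset) on malformed
    JSON, :class:`PoseSchemaError` on unknown parts or missing fields, and
    :class:`PoseValidationError` on non-increasing timestamps.
    """
    text = _as_text(stream)
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise PoseParseError(
            f"malformed JSON at byte offset {exc.pos}: {exc.msg}"
        ) from exc
    if not isinstance(doc, dict) or "frames" not in doc:
        raise PoseSchemaError("top-level object must carry 'fps' and 'frames'")
    try:
        fps = float(doc.get("fps", 30.0))
    except (TypeError, ValueError) as exc:
        raise PoseSchemaError(f"fps must be numeric, got {doc.get('fps')!r}") from exc
    frames = []
    for i, rec in enumerate(doc["frames"]):
        try:
            t = float(rec["t"])
            kps = [
                Keypoint(str(k["part"]), float(k["x"]), float(k["y"]), float(k["score"]))
                for k in rec["keypoints"]
            ]
        except (KeyError, TypeError, ValueError) as exc:
            raise PoseSchemaError(f"frame {i}: {exc}") from exc
        frames.append(PoseFrame.from_partial(t, kps))
    return PoseSequence(frames, nominal_fps=fps, source_id=str(doc.get("source_id", "")))


def read_pose_csv(stream: Stream, nominal_fps: float = 30.0, source_id: str = "") -> PoseSequence:
    """Parse the long-format CSV pose encoding (header ``t,part,x,y,score``)."""
    text = _as_text(stream)
    try:
        df = pd.read_csv(io.StringIO(text))
    except Exception as exc:  # pandas raises several parser error types
        raise PoseParseError(f"malformed CSV: {exc}") from exc
    missing = set(CSV_HEADER) - set(df.columns)
    if missing:
        raise PoseSchemaError(f"CSV missing column(s): {sorted(missing)}")
    bad = set(df["part"].unique()) - _PART_SET
    if bad:
        raise PoseSchemaError(f"unknown part name(s): {sorted(bad)}")
    if df.duplicated(subset=["t", "part"]).any():
        dup = df[df.duplicated(subset=["t", "part"])].iloc[0]
        raise PoseValidationError(
            f"duplicate (t, part) row: t={dup['t']}, part={dup['part']}"
        )
    frames = []
    for t, grp in df.groupby("t", sort=True):
        kps = [
            Keypoint(row.part, float(row.x), float(row.y), float(row.score))
            for row in grp.itertuples()
        ]
        frames.append(PoseFrame.from_partial(float(t), kps))
    return PoseSequence(frames, nominal_fps=nominal_fps, source_id=source_id)


def write_pose_csv(seq: PoseSequence, stream: IO[str]) -> None:
    """Serialize to long-format CSV, one row per (frame, part).

    Floats are written with :func:`repr` so the round trip through
    :func:`read_pose_csv` is exact (timestamps get well over the required
    6 significant digits).
    """
    stream.write(",".join(CSV_HEADER) + "\n")
    for frame in seq.frames:
        t = repr(float(frame.timestamp))
        for name in PART_NAMES:
            kp = frame.keypoints[name]
            stream.write(
                f"{t},{name},{repr(float(kp.x))},{repr(float(kp.y))},{repr(float(kp.confidence))}\n"
            )


def write_pose_json(seq: PoseSequence, stream: IO[str]) -> None:
    """Serialize to the JSON pose encoding (lossless float repr)."""
    doc = {
        "fps": seq.nominal_fps,
        "source_id": seq.source_id,
        "frames": [
            {
                "t": f.timestamp,
                "keypoints": [
                    {
                        "part": name,
                        "x": f.keypoints[name].x,
                        "y": f.keypoints[name].y,
                        "score": f.keypoints[name].confidence,
                    }
                    for name in PART_NAMES
                ],
            }
            for f in seq.frames
        ],
    }
    json.dump(doc, stream)
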
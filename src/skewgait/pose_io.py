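"""Pose-keypoint sequence I/O and fixed-interval frame sampling.

Sequences hold per-frame 2D body keypoints in the OpenPose BODY_25 layout
(25 joints, each an ``(x, y, confidence)`` triple, image convention with the
row index increasing downward).  Two on-disk representations are supported:

* per-frame OpenPose JSON files (``people[0].pose_keypoints_2d`` as a flat
  75-float array), and
* a long-format CSV dialect written by :func:`write_csv` (one row per
  frame x joint, metadata in ``# key=value`` header lines).

A keypoint with ``confidence == 0`` is missing; its coordinates carry no
meaning and every consumer in this package must ignore them.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "N_JOINTS",
    "JOINT_NAMES",
    "Keypoint",
    "PoseFrame",
    "PoseSequence",
    "read_openpose_json",
    "sample_frames",
    "write_csv",
    "read_csv",
]

logger = logging.getLogger(__name__)

N_JOINTS = 25

#: BODY_25 joint order.
JOINT_NAMES = (
    "Nose", "Neck", "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist", "MidHip", "RHip",
    "RKnee", "RAnkle", "LHip", "LKnee", "LAnkle",
    "REye", "LEye", "REar", "LEar", "LBigToe",
    "LSmallToe", "LHeel", "RBigToe", "RSmallToe", "RHeel",
)

DIRECTIONS = ("toward", "away")
LABELS = ("straight", "skew_left", "skew_right", "unlabeled")

_CSV_COLUMNS = ("subject_id", "frame_index", "timestamp", "joint_id", "x", "y", "confidence")


@dataclass(frozen=True)
class Keypoint:
    """A single BODY_25 joint detection in image pixels."""

    joint_id: int
    x: float
    y: float
    confidence: float

    def __post_init__(self) -> None:
        if not 0 <= self.joint_id < N_JOINTS:
            raise ValueError(f"joint_id must be in [0, {N_JOINTS - 1}], got {self.joint_id}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")

    @property
    def missing(self) -> bool:
        return self.confidence == 0.0

    @property
    def name(self) -> str:
        return JOINT_NAMES[self.joint_id]


@dataclass
class PoseFrame:
    """One video frame's 25 keypoints.

    ``keypoints`` is a ``(25, 3)`` float array of ``(x, y, confidence)`` rows
    indexed by joint id.
    """

    frame_index: int
    timestamp: float
    keypoints: np.ndarray

    def __post_init__(self) -> None:
        self.keypoints = np.asarray(self.keypoints, dtype=float)
        if self.keypoints.shape != (N_JOINTS, 3):
            raise ValueError(
                f"keypoints must have shape ({N_JOINTS}, 3), got {self.keypoints.shape}"
            )
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if self.timestamp < 0:
            raise ValueError("timestamp must be >= 0")
        conf = self.keypoints[:, 2]
        if ((conf < 0) | (conf > 1)).any():
            raise ValueError("confidences must lie in [0, 1]")

    def keypoint(self, joint_id: int) -> Keypoint:
        x, y, c = self.keypoints[joint_id]
        return Keypoint(joint_id, float(x), float(y), float(c))


@dataclass
class PoseSequence:
    """An ordered, constant-fps sequence of :class:`PoseFrame`."""

    frames: list[PoseFrame]
    fps: float
    subject_id: str = ""
    direction: str = "toward"
    label: str = "unlabeled"
    path_length_m: float = 5.0
    walk_index: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.path_length_m <= 0:
            raise ValueError("path_length_m must be > 0")
        indices = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        """Duration covered by the sequence: last timestamp plus one frame period."""
        if not self.frames:
            return 0.0
        return self.frames[-1].timestamp + 1.0 / self.fps

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames], dtype=float)

    def keypoint_array(self) -> np.ndarray:
        """Stack all frames into an ``(n_frames, 25, 3)`` array."""
        if not self.frames:
            return np.empty((0, N_JOINTS, 3))
        return np.stack([f.keypoints for f in self.frames])


def _empty_keypoints() -> np.ndarray:
    return np.zeros((N_JOINTS, 3), dtype=float)


def read_openpose_json(
    paths: Sequence[str | Path],
    fps: float,
    *,
    subject_id: str = "",
    direction: str = "toward",
    label: str = "unlabeled",
    path_length_m: float = 5.0,
) -> PoseSequence:
    """Read one OpenPose BODY_25 JSON file per frame, in path order.

    Each file must hold a ``people`` array for a single frame.  An empty
    ``people`` array yields a frame whose 25 keypoints all carry confidence 0
    (and logs a warning); more than one person is an error, since sequences
    model a single walker.
    """
    if fps <= 0:
        raise ValueError("fps must be > 0")
    frames: list[PoseFrame] = []
    for i, path in enumerate(paths):
        path = Path(path)
        with open(path) as fh:
            payload = json.load(fh)
        people = payload.get("people", [])
        if len(people) > 1:
            raise ValueError(
                f"frame {i} ({path.name}): expected a single person, found {len(people)}"
            )
        kp = _empty_keypoints()
        if not people:
            logger.warning("frame %d (%s): no people detected; emitting empty frame", i, path.name)
        else:
            flat = np.asarray(people[0]["pose_keypoints_2d"], dtype=float)
            if flat.size != 3 * N_JOINTS:
                raise ValueError(
                    f"frame {i} ({path.name}): pose_keypoints_2d has {flat.size} values, "
                    f"expected {3 * N_JOINTS}"
                )
            kp = flat.reshape(N_JOINTS, 3)
            missing = kp[:, 2] == 0
            kp[missing, :2] = 0.0
        frames.append(PoseFrame(frame_index=i, timestamp=i / fps, keypoints=kp))
    return PoseSequence(
        frames=frames,
        fps=fps,
        subject_id=subject_id,
        direction=direction,
        label=label,
        path_length_m=path_length_m,
    )


def sample_frames(seq: PoseSequence, interval_s: float) -> PoseSequence:
    """Select the frames nearest a fixed time grid ``t_k = k * interval_s``.

    The grid starts at the first frame and contains ``ceil(D / interval_s)``
    points, where ``D`` is the sequence duration (last timestamp plus one
    frame period).  Nearest frames are resolved as ``round(t_k * fps)``; when
    rounding would reuse a frame at the tail, earlier picks are shifted back
    one frame so that no frame is selected twice.
    """
    if interval_s <= 0:
        raise ValueError("interval_s must be > 0")
    if not seq.frames:
        raise ValueError("cannot sample an empty sequence")
    period = 1.0 / seq.fps
    if interval_s < period - 1e-12:
        raise ValueError(
            f"interval_s={interval_s} is finer than the source frame period {period:.6g}"
        )
    n = len(seq.frames)
    count = math.ceil(seq.duration_s / interval_s - 1e-9)
    count = max(1, min(count, n))
    idx = np.rint(np.arange(count) * interval_s * seq.fps).astype(int)
    idx = np.minimum(idx, n - 1)
    # clipping at the tail can create duplicates; push earlier picks back
    for k in range(count - 2, -1, -1):
        if idx[k] >= idx[k + 1]:
            idx[k] = idx[k + 1] - 1
    if idx[0] < 0:  # pragma: no cover - excluded by interval >= period
        raise ValueError("sampling produced more picks than source frames")
    frames = [seq.frames[i] for i in idx]
    return PoseSequence(
        frames=frames,
        fps=seq.fps,
        subject_id=seq.subject_id,
        direction=seq.direction,
        label=seq.label,
        path_length_m=seq.path_length_m,
        walk_index=seq.walk_index,
    )


def write_csv(seq: PoseSequence, path: str | Path) -> None:
    """Write a sequence as long-format CSV (lossless at 6-decimal precision).

    Sequence metadata goes in ``# key=value`` comment lines; the body has one
    row per frame x joint with columns
    ``subject_id, frame_index, timestamp, joint_id, x, y, confidence``.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("# skewgait-pose-csv v1\n")
        fh.write(f"# fps={seq.fps!r}\n")
        fh.write(f"# subject_id={seq.subject_id}\n")
        fh.write(f"# direction={seq.direction}\n")
        fh.write(f"# label={seq.label}\n")
        fh.write(f"# path_length_m={seq.path_length_m!r}\n")
        fh.write(f"# walk_index={seq.walk_index}\n")
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for frame in seq.frames:
            for j in range(N_JOINTS):
                x, y, c = frame.keypoints[j]
                writer.writerow(
                    [
                        seq.subject_id,
                        frame.frame_index,
                        f"{frame.timestamp:.6f}",
                        j,
                        f"{x:.6f}",
                        f"{y:.6f}",
                        f"{c:.6f}",
                    ]
                )


def read_csv(path: str | Path) -> PoseSequence:
    """Read a sequence written by :func:`write_csv`.

    Malformed rows raise ``ValueError`` naming the 1-based line number.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    frames: dict[int, np.ndarray] = {}
    header_seen = False
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row:
                continue
            if row[0].startswith("#"):
                text = ",".join(row).lstrip("#").strip()
                if "=" in text:
                    key, value = text.split("=", 1)
                    meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                if tuple(row) != _CSV_COLUMNS:
                    raise ValueError(
                        f"{path.name}:{lineno}: bad header {row!r}, expected {list(_CSV_COLUMNS)}"
                    )
                header_seen = True
                continue
            if len(row) != len(_CSV_COLUMNS):
                raise ValueError(
                    f"{path.name}:{lineno}: expected {len(_CSV_COLUMNS)} fields, got {len(row)}"
                )
            try:
                frame_index = int(row[1])
                joint_id = int(row[3])
                x, y, c = float(row[4]), float(row[5]), float(row[6])
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: malformed row: {exc}") from None
            if not 0 <= joint_id < N_JOINTS:
                raise ValueError(f"{path.name}:{lineno}: joint_id {joint_id} out of range")
            kp = frames.setdefault(frame_index, _empty_keypoints())
            kp[joint_id] = (x, y, c)
    if not header_seen:
        raise ValueError(f"{path.name}: missing CSV header row")
    if "fps" not in meta:
        raise ValueError(f"{path.name}: missing '# fps=' metadata line")
    fps = float(meta["fps"])
    pose_frames = [
        PoseFrame(frame_index=i, timestamp=i / fps, keypoints=frames[i])
        for i in sorted(frames)
    ]
    return PoseSequence(
        frames=pose_frames,
        fps=fps,
        subject_id=meta.get("subject_id", ""),
        direction=meta.get("direction", "toward"),
        label=meta.get("label", "unlabeled"),
        path_length_m=float(meta.get("path_length_m", 5.0)),
        walk_index=int(meta.get("walk_index", 0)),
    )
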
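"""Synthetic walking-video keypoint generator.

Emulates a single walker filmed by a static camera while walking a straight
5 m path toward or away from the lens: an articulated 25-joint stick-body
template is placed at a per-frame world position, projected through a pinhole
model (image scale proportional to 1 / depth), then corrupted with Gaussian
pixel jitter and confidence-0 dropout.

Skew semantics
--------------
``skew_deg`` is a constant heading offset in the *walker's* body frame:
positive values veer toward the walker's own left, negative toward their own
right.  In image space a walker veering to their own left drifts toward the
viewer's left when walking away and toward the viewer's right when walking
toward the camera — the sign flip is applied internally so that a given label
produces a consistently-skewed trajectory plot (and a consistent TAR/BAR
direction) on both legs of a round trip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .pose_io import N_JOINTS, PoseFrame, PoseSequence

__all__ = ["WalkerParams", "CohortSpec", "generate_walk", "generate_cohort"]

# Stick-body template: (lateral offset m, height m) per BODY_25 joint for a
# ~1.7 m adult facing along the walking axis.  Lateral +x is the viewer's
# right; the template is left/right symmetric so facing direction does not
# matter for bounding-box geometry.
_TEMPLATE = np.array(
    [
        (0.00, 1.62),   # 0  Nose
        (0.00, 1.45),   # 1  Neck
        (-0.20, 1.42),  # 2  RShoulder
        (-0.24, 1.12),  # 3  RElbow
        (-0.26, 0.82),  # 4  RWrist
        (0.20, 1.42),   # 5  LShoulder
        (0.24, 1.12),   # 6  LElbow
        (0.26, 0.82),   # 7  LWrist
        (0.00, 0.95),   # 8  MidHip
        (-0.11, 0.94),  # 9  RHip
        (-0.12, 0.52),  # 10 RKnee
        (-0.13, 0.10),  # 11 RAnkle
        (0.11, 0.94),   # 12 LHip
        (0.12, 0.52),   # 13 LKnee
        (0.13, 0.10),   # 14 LAnkle
        (-0.04, 1.66),  # 15 REye
        (0.04, 1.66),   # 16 LEye
        (-0.09, 1.60),  # 17 REar
        (0.09, 1.60),   # 18 LEar
        (0.15, 0.02),   # 19 LBigToe
        (0.18, 0.02),   # 20 LSmallToe
        (0.12, 0.03),   # 21 LHeel
        (-0.15, 0.02),  # 22 RBigToe
        (-0.18, 0.02),  # 23 RSmallToe
        (-0.12, 0.03),  # 24 RHeel
    ]
)

_LEFT_LEG = (13, 14, 19, 20, 21)
_RIGHT_LEG = (10, 11, 22, 23, 24)
_LEFT_ARM = (6, 7)
_RIGHT_ARM = (3, 4)


@dataclass(frozen=True)
class WalkerParams:
    """Parameters of one simulated 5 m walk."""

    skew_deg: float = 0.0
    speed_mps: float = 0.68
    duration_s: float | None = None  # defaults to path_length_m / speed_mps
    fps: float = 30.0
    noise_sd_px: float = 0.0
    dropout_rate: float = 0.0
    seed: int = 0
    image_size: tuple[int, int] = (1920, 1080)
    start_distance_m: float = 2.0
    path_length_m: float = 5.0
    focal_px: float = 1000.0
    camera_height_m: float = 1.0

    def __post_init__(self) -> None:
        if self.speed_mps <= 0:
            raise ValueError("speed_mps must be > 0")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.noise_sd_px < 0:
            raise ValueError("noise_sd_px must be >= 0")
        if self.duration_s is not None and self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.start_distance_m <= 0 or self.path_length_m <= 0:
            raise ValueError("distances must be > 0")

    @property
    def effective_duration_s(self) -> float:
        if self.duration_s is not None:
            return self.duration_s
        return self.path_length_m / self.speed_mps


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a labeled cohort of simulated walks.

    Group sizes follow the per-walk label fractions; with the defaults
    (35 subjects x 6 walks = 210 samples) the split is 85 straight,
    36 skew-left, 89 skew-right.
    """

    n_subjects: int = 35
    walks_per_subject: int = 6
    frac_skew_left: float = 36 / 210
    frac_skew_right: float = 89 / 210
    skew_mean_deg: float = 1.0
    skew_sd_deg: float = 0.1
    straight_sd_deg: float = 0.03
    speed_mps: float = 0.68
    speed_sd_mps: float = 0.02
    noise_sd_px: float = 1.0
    dropout_rate: float = 0.02
    seed: int = 0
    group_assignment: Sequence[str] | None = None  # one label per walk, optional
    base_params: WalkerParams = field(default_factory=WalkerParams)

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.walks_per_subject < 1:
            raise ValueError("n_subjects and walks_per_subject must be >= 1")
        if self.frac_skew_left + self.frac_skew_right > 1:
            raise ValueError("group fractions must sum to <= 1")

    @property
    def n_walks(self) -> int:
        return self.n_subjects * self.walks_per_subject


def _gait_offsets(t: np.ndarray, speed_mps: float) -> np.ndarray:
    """Per-frame (n, 25, 2) lateral/height offsets from sinusoidal gait phase."""
    n = t.size
    step_hz = max(0.8, speed_mps / 0.5)  # ~1.4 Hz at the default speed
    phase = 2 * math.pi * step_hz * t
    off = np.zeros((n, N_JOINTS, 2))
    # whole-body vertical bob at double the step frequency; lateral motion is
    # kept left/right antisymmetric so a straight walk has an exactly
    # stationary bounding-box centre
    off[:, :, 1] += 0.004 * np.sin(2 * phase)[:, None]
    lift = np.maximum(0.0, np.sin(phase))
    for j in _LEFT_LEG:
        off[:, j, 1] += 0.05 * lift
    for j in _RIGHT_LEG:
        off[:, j, 1] += 0.05 * np.maximum(0.0, -np.sin(phase))
    swing = 0.02 * np.sin(phase)
    for j in _LEFT_ARM:
        off[:, j, 0] += swing
    for j in _RIGHT_ARM:
        off[:, j, 0] -= swing
    return off


def generate_walk(
    params: WalkerParams,
    direction: str = "toward",
    label: str = "unlabeled",
    *,
    subject_id: str = "sim",
    walk_index: int = 0,
) -> PoseSequence:
    """Simulate one walk and return it as a :class:`PoseSequence`.

    Deterministic given ``params.seed``.  Raises ``ValueError`` if the walker
    projects outside the image for more than 20% of frames, with a hint to
    change camera/path parameters.
    """
    if direction not in ("toward", "away"):
        raise ValueError(f"direction must be 'toward' or 'away', got {direction!r}")
    rng = np.random.default_rng(params.seed)
    width, height = params.image_size

    duration = params.effective_duration_s
    n_frames = max(2, int(round(duration * params.fps)))
    t = np.arange(n_frames) / params.fps
    walked = np.minimum(params.speed_mps * t, params.path_length_m)

    if direction == "away":
        depth = params.start_distance_m + walked
        drift_sign = -1.0  # own left = viewer's left
    else:
        depth = params.start_distance_m + params.path_length_m - walked
        drift_sign = +1.0  # own left = viewer's right
    lateral = drift_sign * math.tan(math.radians(params.skew_deg)) * walked

    pts = _TEMPLATE[None, :, :] + _gait_offsets(t, params.speed_mps)  # (n, 25, 2)
    world_x = pts[:, :, 0] + lateral[:, None]
    world_y = pts[:, :, 1]

    f = params.focal_px
    img_x = width / 2.0 + f * world_x / depth[:, None]
    img_y = height / 2.0 + f * (params.camera_height_m - world_y) / depth[:, None]

    outside = (img_x < 0) | (img_x >= width) | (img_y < 0) | (img_y >= height)
    frac_out = float(outside.any(axis=1).mean())
    if frac_out > 0.20:
        raise ValueError(
            f"walker leaves the frame in {frac_out:.0%} of frames; "
            "reduce skew_deg / path_length_m or enlarge image_size"
        )

    if params.noise_sd_px > 0:
        img_x = img_x + rng.normal(0.0, params.noise_sd_px, img_x.shape)
        img_y = img_y + rng.normal(0.0, params.noise_sd_px, img_y.shape)
    conf = rng.uniform(0.5, 1.0, img_x.shape)
    if params.dropout_rate > 0:
        dropped = rng.random(img_x.shape) < params.dropout_rate
        conf[dropped] = 0.0
        img_x[dropped] = 0.0
        img_y[dropped] = 0.0

    frames = [
        PoseFrame(
            frame_index=i,
            timestamp=i / params.fps,
            keypoints=np.column_stack([img_x[i], img_y[i], conf[i]]),
        )
        for i in range(n_frames)
    ]
    return PoseSequence(
        frames=frames,
        fps=params.fps,
        subject_id=subject_id,
        direction=direction,
        label=label,
        path_length_m=params.path_length_m,
        walk_index=walk_index,
    )


def _cohort_labels(spec: CohortSpec, rng: np.random.Generator) -> list[str]:
    if spec.group_assignment is not None:
        labels = list(spec.group_assignment)
        if len(labels) != spec.n_walks:
            raise ValueError(
                f"group_assignment has {len(labels)} labels, expected {spec.n_walks}"
            )
        return labels
    n = spec.n_walks
    n_left = int(round(spec.frac_skew_left * n))
    n_right = int(round(spec.frac_skew_right * n))
    labels = (
        ["skew_left"] * n_left
        + ["skew_right"] * n_right
        + ["straight"] * (n - n_left - n_right)
    )
    perm = rng.permutation(n)
    return [labels[i] for i in perm]


def generate_cohort(spec: CohortSpec) -> list[PoseSequence]:
    """Simulate ``n_subjects * walks_per_subject`` labeled walks.

    Each walk gets an independent RNG stream seeded from
    ``(spec.seed, subject, walk)`` so cohorts are reproducible and individual
    walks are independent of cohort size.
    """
    label_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0F0]))
    labels = _cohort_labels(spec, label_rng)
    sequences: list[PoseSequence] = []
    k = 0
    for si in range(spec.n_subjects):
        for wi in range(spec.walks_per_subject):
            ss = np.random.SeedSequence([spec.seed, si, wi])
            walk_rng = np.random.default_rng(ss)
            label = labels[k]
            k += 1
            if label == "straight":
                skew = float(walk_rng.normal(0.0, spec.straight_sd_deg))
            else:
                magnitude = abs(walk_rng.normal(spec.skew_mean_deg, spec.skew_sd_deg))
                skew = magnitude if label == "skew_left" else -magnitude
            speed = max(0.2, float(walk_rng.normal(spec.speed_mps, spec.speed_sd_mps)))
            params = replace(
                spec.base_params,
                skew_deg=skew,
                speed_mps=speed,
                noise_sd_px=spec.noise_sd_px,
                dropout_rate=spec.dropout_rate,
                seed=int(ss.generate_state(1)[0]),
            )
            direction = "away" if wi % 2 == 0 else "toward"
            sequences.append(
                generate_walk(
                    params,
                    direction,
                    label,
                    subject_id=f"S{si:03d}",
                    walk_index=wi,
                )
            )
    return sequences
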
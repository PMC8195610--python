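"""Synthetic stimuli and observers for exercising the analysis pipeline.

Real inputs to the pipeline are motion-capture clips of four prototype facial
expressions (monkey fear/threat, human fear/angry, plus a neutral clip) and
trial-level four-class categorization responses. This module fabricates both
with the statistical structure the analysis assumes:

* prototype clips start and end at a neutral pose, rise to a mid-sequence
  expressive peak following a raised-cosine activation, and differ across
  prototypes in which marker groups move (monkey prototypes move the ears and
  open the mouth more), by how much, and in peak timing;
* observer responses are drawn from a ground-truth softmax model over the
  style coordinates (e, s), so every downstream estimator can be checked by
  parameter recovery.

The marker layout is a schematic 43-marker face (forehead, brows, eyes, nose,
cheeks, mouth ring, jaw, chin, ears); it makes no claim to anatomical realism
beyond group semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import MarkerTrajectory

__all__ = [
    "PrototypeSpec",
    "PrototypeSet",
    "ObserverConfig",
    "MARKER_GROUPS",
    "default_beta_true",
    "gen_prototype_trajectories",
    "render_frames",
    "gen_observer_responses",
    "CLASS_LABELS",
]

#: Response classes, in the coding used throughout the analysis.
CLASS_LABELS = {1: "human-angry", 2: "human-fear", 3: "monkey-threat", 4: "monkey-fear"}

# 43 markers split into named facial regions; ids are "<group><index>".
MARKER_GROUPS: dict[str, int] = {
    "forehead": 5,
    "brow_l": 3,
    "brow_r": 3,
    "eye_l": 2,
    "eye_r": 2,
    "nose": 4,
    "cheek_l": 3,
    "cheek_r": 3,
    "mouth": 8,
    "jaw": 4,
    "chin": 2,
    "ear_l": 2,
    "ear_r": 2,
}

# Prototype kinematics: per-group displacement amplitude (relative to
# PrototypeSpec.amplitude) and a unit-ish direction; gamma warps the
# raised-cosine activation so the expressive peak falls early (<1) or late
# (>1) in the clip, exercising time alignment downstream.
_PROTOTYPE_PATTERNS: dict[str, dict] = {
    "monkey-threat": {
        "gamma": 0.75,
        "groups": {
            "mouth": (1.6, (0.0, -1.0, 0.3)),
            "jaw": (1.2, (0.0, -1.0, 0.1)),
            "ear_l": (0.8, (-0.5, 0.4, -0.8)),
            "ear_r": (0.8, (0.5, 0.4, -0.8)),
            "brow_l": (0.4, (0.0, -0.6, 0.2)),
            "brow_r": (0.4, (0.0, -0.6, 0.2)),
        },
    },
    "monkey-fear": {
        "gamma": 1.25,
        "groups": {
            "mouth": (1.1, (0.4, 0.6, -0.2)),
            "cheek_l": (0.5, (-0.5, 0.5, 0.0)),
            "cheek_r": (0.5, (0.5, 0.5, 0.0)),
            "ear_l": (0.6, (-0.3, -0.5, -0.6)),
            "ear_r": (0.6, (0.3, -0.5, -0.6)),
            "brow_l": (0.5, (0.0, 0.8, 0.1)),
            "brow_r": (0.5, (0.0, 0.8, 0.1)),
        },
    },
    "human-angry": {
        "gamma": 0.9,
        "groups": {
            "brow_l": (1.0, (0.3, -0.8, 0.2)),
            "brow_r": (1.0, (-0.3, -0.8, 0.2)),
            "mouth": (0.7, (0.0, -0.5, 0.2)),
            "nose": (0.3, (0.0, 0.5, 0.2)),
            "jaw": (0.4, (0.0, -0.3, 0.1)),
        },
    },
    "human-fear": {
        "gamma": 1.1,
        "groups": {
            "brow_l": (0.9, (0.0, 1.0, 0.1)),
            "brow_r": (0.9, (0.0, 1.0, 0.1)),
            "eye_l": (0.5, (0.0, 0.6, 0.0)),
            "eye_r": (0.5, (0.0, 0.6, 0.0)),
            "mouth": (0.6, (-0.3, 0.4, -0.1)),
            "chin": (0.3, (0.0, -0.4, 0.0)),
        },
    },
}


@dataclass(frozen=True)
class PrototypeSpec:
    """Configuration of the synthetic prototype generator.

    ``amplitude`` is the base peak displacement in capture units (the
    schematic face is ~120 units wide); ``noise_amplitude`` adds seeded
    Gaussian marker jitter and is recorded in the set's metadata.
    """

    marker_count: int = 43
    duration_s: float = 5.0
    frame_rate: float = 30.0
    amplitude: float = 10.0
    noise_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.marker_count < 3:
            raise ValueError(f"marker_count must be >= 3, got {self.marker_count}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")
        if self.amplitude < 0 or self.noise_amplitude < 0:
            raise ValueError("amplitude and noise_amplitude must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate))


@dataclass(frozen=True)
class PrototypeSet:
    """The four prototype clips plus the neutral clip, on shared markers."""

    prototypes: dict[str, MarkerTrajectory]
    neutral: MarkerTrajectory
    spec: PrototypeSpec
    seed: int | None = None

    @property
    def marker_count(self) -> int:
        return self.neutral.n_markers

    @property
    def neutral_pose(self) -> np.ndarray:
        return self.neutral.positions[0]


def _base_layout(marker_count: int) -> tuple[np.ndarray, tuple[str, ...], dict[str, np.ndarray]]:
    """Deterministic schematic face layout; returns positions, ids, group masks."""
    centers = {
        "forehead": (0.0, 55.0, 18.0),
        "brow_l": (-22.0, 32.0, 22.0),
        "brow_r": (22.0, 32.0, 22.0),
        "eye_l": (-20.0, 20.0, 20.0),
        "eye_r": (20.0, 20.0, 20.0),
        "nose": (0.0, 5.0, 30.0),
        "cheek_l": (-32.0, -5.0, 12.0),
        "cheek_r": (32.0, -5.0, 12.0),
        "mouth": (0.0, -28.0, 22.0),
        "jaw": (0.0, -45.0, 10.0),
        "chin": (0.0, -58.0, 14.0),
        "ear_l": (-55.0, 10.0, -15.0),
        "ear_r": (55.0, 10.0, -15.0),
    }
    pos, ids, group_of = [], [], []
    for group, n in MARKER_GROUPS.items():
        cx, cy, cz = centers[group]
        for i in range(n):
            if group == "mouth":  # ring around the mouth center
                ang = 2.0 * np.pi * i / n
                dx, dy, dz = 14.0 * np.cos(ang), 7.0 * np.sin(ang), 0.0
            else:  # short deterministic row
                dx, dy, dz = 8.0 * (i - (n - 1) / 2.0), 1.5 * (i % 2), 0.0
            pos.append((cx + dx, cy + dy, cz + dz))
            ids.append(f"{group}{i}")
            group_of.append(group)
    positions = np.asarray(pos, dtype=float)
    # honour non-default marker counts by truncating / tiling the layout
    if marker_count != len(positions):
        idx = np.arange(marker_count) % len(positions)
        extra = 0.1 * (np.arange(marker_count) // len(positions))
        positions = positions[idx] + extra[:, None]
        ids = [f"{ids[i]}_{k}" if k else ids[i] for k, i in zip(np.arange(marker_count) // len(pos), idx)]
        group_of = [group_of[i] for i in idx]
    masks = {g: np.array([go == g for go in group_of]) for g in MARKER_GROUPS}
    return positions, tuple(ids), masks


def _activation(n_frames: int, gamma: float) -> np.ndarray:
    """Raised-cosine 0→1→0 activation over the clip; gamma shifts the peak."""
    t = np.linspace(0.0, 1.0, n_frames)
    u = t**gamma
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * u))


def gen_prototype_trajectories(
    spec: PrototypeSpec = PrototypeSpec(), seed: int | None = None
) -> PrototypeSet:
    """Generate the four synthetic prototype clips and the neutral clip.

    Every clip starts and ends exactly at the neutral pose (when
    ``noise_amplitude`` is 0); the expressive displacement follows a
    raised-cosine activation whose peak timing differs across prototypes.
    """
    base, ids, masks = _base_layout(spec.marker_count)
    n_frames = spec.n_frames
    if n_frames < 2:
        raise ValueError("duration × frame_rate must give at least 2 frames")
    rng = np.random.default_rng(seed)

    def jitter(shape):
        if spec.noise_amplitude > 0:
            return spec.noise_amplitude * rng.standard_normal(shape)
        return 0.0

    neutral_pos = np.broadcast_to(base, (n_frames, spec.marker_count, 3)).copy()
    neutral = MarkerTrajectory(neutral_pos + jitter(neutral_pos.shape), spec.frame_rate, ids)

    prototypes: dict[str, MarkerTrajectory] = {}
    for name, pat in _PROTOTYPE_PATTERNS.items():
        field_ = np.zeros((spec.marker_count, 3))
        for group, (amp, direction) in pat["groups"].items():
            d = np.asarray(direction, dtype=float)
            d /= np.linalg.norm(d)
            field_[masks[group]] += spec.amplitude * amp * d
        act = _activation(n_frames, pat["gamma"])
        pos = base[None, :, :] + act[:, None, None] * field_[None, :, :]
        prototypes[name] = MarkerTrajectory(pos + jitter(pos.shape), spec.frame_rate, ids)
    return PrototypeSet(prototypes, neutral, spec, seed)


def render_frames(
    traj: MarkerTrajectory, image_size: int = 64, blob_sigma: float = 2.0
) -> np.ndarray:
    """Rasterize a trajectory into grayscale frames of Gaussian marker blobs.

    The (x, y) marker bounding box over the whole clip is mapped into the
    image by one isotropic affine transform (shared across frames, margin of
    3σ), so image motion is proportional to marker motion. Returns an array
    of shape ``(n_frames, image_size, image_size)`` with intensities in [0, 1].
    """
    if blob_sigma <= 0:
        raise ValueError(f"blob_sigma must be positive, got {blob_sigma}")
    margin = 3.0 * blob_sigma
    if image_size < 2 * margin + 4:
        raise ValueError(
            f"image_size {image_size} too small for blob_sigma {blob_sigma} "
            f"(needs at least {int(np.ceil(2 * margin + 4))})"
        )
    xy = traj.positions[:, :, :2]
    lo = xy.reshape(-1, 2).min(axis=0)
    hi = xy.reshape(-1, 2).max(axis=0)
    span = float(max(hi[0] - lo[0], hi[1] - lo[1], 1e-9))
    scale = (image_size - 1 - 2 * margin) / span
    center = 0.5 * (lo + hi)
    # x → column, y → row (flipped so +y is up in the image)
    cols = (xy[:, :, 0] - center[0]) * scale + (image_size - 1) / 2.0
    rows = (center[1] - xy[:, :, 1]) * scale + (image_size - 1) / 2.0
    grid = np.arange(image_size, dtype=float)
    frames = np.zeros((traj.n_frames, image_size, image_size))
    inv2s2 = 1.0 / (2.0 * blob_sigma**2)
    for f in range(traj.n_frames):
        dr = grid[:, None] - rows[f][None, :]  # (H, M)
        dc = grid[:, None] - cols[f][None, :]  # (W, M)
        gr = np.exp(-(dr**2) * inv2s2)
        gc = np.exp(-(dc**2) * inv2s2)
        frames[f] = np.minimum(gr @ gc.T, 1.0)
    return frames


def default_beta_true(slope: float = 4.0) -> np.ndarray:
    """Ground-truth 4×3 coefficient table (intercept, e-slope, s-slope per class).

    Each class's linear predictor is ±slope·(e−½) ± slope·(s−½) with signs
    pointing at its own corner of the style plane, so corner stimuli are
    classified almost perfectly (P ≈ 0.95 at slope 4) and probabilities are
    symmetric about the plane's center.
    """
    half = slope / 2.0
    return np.array(
        [
            [-2 * half, slope, slope],  # 1 human-angry  → corner (1,1)
            [0.0, -slope, slope],       # 2 human-fear   → corner (0,1)
            [0.0, slope, -slope],       # 3 monkey-threat→ corner (1,0)
            [2 * half, -slope, -slope], # 4 monkey-fear  → corner (0,0)
        ]
    )


@dataclass(frozen=True)
class ObserverConfig:
    """Ground truth and design for simulated observers.

    ``beta_true`` maps to class log-odds y_j = β0j + β1j·e + β2j·s; responses
    are drawn from softmax(y). One table per (avatar, view) condition; by
    default all four conditions share the same ground truth, so condition
    comparisons are null. ``beta_by_condition`` overrides single conditions.
    """

    beta_true: np.ndarray = field(default_factory=default_beta_true)
    n_participants: int = 20
    n_reps: int = 10
    seed: int = 0
    conditions: tuple[tuple[str, int], ...] = (
        ("monkey", 0),
        ("monkey", 30),
        ("human", 0),
        ("human", 30),
    )
    beta_by_condition: dict[tuple[str, int], np.ndarray] | None = None

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta_true, dtype=float)
        if beta.shape != (4, 3):
            raise ValueError(f"beta_true must be 4×3, got {beta.shape}")
        if self.n_participants < 1 or self.n_reps < 1:
            raise ValueError("n_participants and n_reps must be >= 1")
        object.__setattr__(self, "beta_true", beta)

    def beta_for(self, condition: tuple[str, int]) -> np.ndarray:
        if self.beta_by_condition and condition in self.beta_by_condition:
            return np.asarray(self.beta_by_condition[condition], dtype=float)
        return self.beta_true


def softmax_probabilities(beta: np.ndarray, e: float, s: float) -> np.ndarray:
    """Analytic class probabilities of the generating model at one style point."""
    y = beta[:, 0] + beta[:, 1] * e + beta[:, 2] * s
    y = y - y.max()
    p = np.exp(y)
    return p / p.sum()


def gen_observer_responses(
    grid_points: list[tuple[float, float]], obs: ObserverConfig
) -> pd.DataFrame:
    """Simulate the trial-level response table.

    One four-class response per (condition, participant, grid cell,
    repetition), drawn from the softmax implied by the condition's ground
    truth. Identical config and seed reproduce the table bit-for-bit.
    """
    for e, s in grid_points:
        if not (0.0 <= e <= 1.0 and 0.0 <= s <= 1.0):
            raise ValueError(f"style coordinates must lie in [0,1]², got ({e}, {s})")
    rng = np.random.default_rng(obs.seed)
    rows = []
    for avatar, view in obs.conditions:
        beta = obs.beta_for((avatar, view))
        for e, s in grid_points:
            p = softmax_probabilities(beta, e, s)
            n = obs.n_participants * obs.n_reps
            draws = rng.choice(4, size=n, p=p) + 1
            k = 0
            for pid in range(1, obs.n_participants + 1):
                for rep in range(1, obs.n_reps + 1):
                    rows.append((pid, avatar, view, e, s, rep, draws[k]))
                    k += 1
    return pd.DataFrame(
        rows,
        columns=["participant_id", "avatar", "view_deg", "e", "s", "rep", "response_class"],
    )
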
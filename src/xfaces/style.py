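"""Two-dimensional motion-morphing style space.

Four prototype expression clips — monkey-fear, monkey-threat, human-fear and
human-angry — span a style plane parameterized by an expression coordinate
``e`` (0 = fear, 1 = anger/threat) and a species coordinate ``s`` (0 = monkey,
1 = human). Any point (e, s) maps to convex bilinear weights over the four
prototypes, and the morphed clip is the frame-wise convex combination of the
time-normalized prototype trajectories. Blending an expressive clip toward a
neutral clip with a morph level λ (``neutral_morph``) scales its
expressiveness down without changing its style coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import AlignmentError, MarkerTrajectory, check_same_markers, time_normalize

__all__ = [
    "PROTOTYPE_ORDER",
    "StylePoint",
    "MorphWeights",
    "StyleGrid",
    "bilinear_weights",
    "morph_trajectories",
    "build_style_grid",
    "neutral_morph",
]

#: Canonical prototype order used by every weight vector in this module.
PROTOTYPE_ORDER = ("monkey-fear", "monkey-threat", "human-fear", "human-angry")


@dataclass(frozen=True)
class StylePoint:
    """A point in the (expression, species) style plane, both in [0, 1]."""

    e: float
    s: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.e <= 1.0 and 0.0 <= self.s <= 1.0):
            raise ValueError(f"style coordinates must lie in [0,1]², got ({self.e}, {self.s})")


@dataclass(frozen=True)
class MorphWeights:
    """Convex weights over the four prototypes (order: :data:`PROTOTYPE_ORDER`)."""

    w_monkey_fear: float
    w_monkey_threat: float
    w_human_fear: float
    w_human_angry: float

    def __post_init__(self) -> None:
        w = self.as_array()
        if np.any(w < -1e-12):
            raise ValueError(f"morph weights must be non-negative, got {w}")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"morph weights must sum to 1, got sum {w.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.w_monkey_fear, self.w_monkey_threat, self.w_human_fear, self.w_human_angry]
        )


def bilinear_weights(p: StylePoint) -> MorphWeights:
    """Bilinear prototype weights for a style point.

    The corners of the plane reproduce single prototypes:
    (0,0) → monkey-fear, (1,0) → monkey-threat, (0,1) → human-fear,
    (1,1) → human-angry.
    """
    e, s = p.e, p.s
    return MorphWeights(
        w_monkey_fear=(1.0 - e) * (1.0 - s),
        w_monkey_threat=e * (1.0 - s),
        w_human_fear=(1.0 - e) * s,
        w_human_angry=e * s,
    )


def morph_trajectories(
    prototypes: dict[str, MarkerTrajectory] | list[MarkerTrajectory],
    weights: MorphWeights,
) -> MarkerTrajectory:
    """Frame-wise convex combination of four time-normalized prototypes.

    ``prototypes`` may be a dict keyed by the labels in :data:`PROTOTYPE_ORDER`
    or a list already in that order. All four must share marker order and
    frame count (normalize first with :func:`~xfaces.trajectory.time_normalize`).
    """
    if isinstance(prototypes, dict):
        missing = [k for k in PROTOTYPE_ORDER if k not in prototypes]
        if missing:
            raise ValueError(f"missing prototypes: {missing}")
        protos = [prototypes[k] for k in PROTOTYPE_ORDER]
    else:
        protos = list(prototypes)
        if len(protos) != 4:
            raise ValueError(f"expected 4 prototypes, got {len(protos)}")
    check_same_markers(protos)
    frames = {t.n_frames for t in protos}
    if len(frames) != 1:
        raise AlignmentError(
            f"prototypes must share a frame count before morphing, got {sorted(frames)}; "
            "apply time_normalize first"
        )
    w = weights.as_array()
    # exact corner identity: avoid float round-off from 0-weight terms
    nonzero = np.nonzero(w)[0]
    if len(nonzero) == 1:
        k = nonzero[0]
        if w[k] == 1.0:
            return protos[k]
    pos = np.einsum("k,kfmc->fmc", w, np.stack([t.positions for t in protos]))
    return MarkerTrajectory(pos, frame_rate=protos[0].frame_rate, marker_ids=protos[0].marker_ids)


@dataclass(frozen=True)
class StyleGrid:
    """An equidistant lattice of morphs over the style plane.

    ``points`` and ``trajectories`` are parallel lists in row-major
    (e-fastest) order over the ``steps_per_axis`` × ``steps_per_axis`` lattice.
    """

    points: tuple[StylePoint, ...]
    trajectories: tuple[MarkerTrajectory, ...]
    steps_per_axis: int

    def trajectory_at(self, e: float, s: float) -> MarkerTrajectory:
        for p, t in zip(self.points, self.trajectories):
            if abs(p.e - e) < 1e-12 and abs(p.s - s) < 1e-12:
                return t
        raise KeyError(f"({e}, {s}) is not a lattice point of this grid")

    @property
    def axis_values(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.steps_per_axis)


def build_style_grid(
    prototypes: dict[str, MarkerTrajectory],
    steps_per_axis: int = 5,
    target_frames: int = 150,
) -> StyleGrid:
    """Morph the four prototypes onto an equidistant (e, s) lattice.

    With the default five steps per axis this produces the 25-clip stimulus
    set; lattice corners reproduce the (time-normalized) prototypes exactly.
    """
    if steps_per_axis < 2:
        raise ValueError(f"steps_per_axis must be >= 2, got {steps_per_axis}")
    protos = {k: v for k, v in prototypes.items()}
    normed = time_normalize([protos[k] for k in PROTOTYPE_ORDER], target_frames)
    normed_dict = dict(zip(PROTOTYPE_ORDER, normed))
    axis = np.linspace(0.0, 1.0, steps_per_axis)
    points: list[StylePoint] = []
    trajs: list[MarkerTrajectory] = []
    for s in axis:
        for e in axis:
            p = StylePoint(float(e), float(s))
            points.append(p)
            trajs.append(morph_trajectories(normed_dict, bilinear_weights(p)))
    return StyleGrid(tuple(points), tuple(trajs), steps_per_axis)


def neutral_morph(
    traj: MarkerTrajectory, neutral: MarkerTrajectory, lam: float
) -> MarkerTrajectory:
    """Blend an expression toward the neutral clip: λ·traj + (1−λ)·neutral.

    λ = 1 returns the expression unchanged, λ = 0 the neutral clip. Used by
    the equilibration stage to scale down expressiveness.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"morph level λ must lie in [0,1], got {lam}")
    check_same_markers([traj, neutral])
    if traj.n_frames != neutral.n_frames:
        raise AlignmentError(
            f"expression has {traj.n_frames} frames but neutral has {neutral.n_frames}; "
            "apply time_normalize first"
        )
    if lam == 1.0:
        return traj
    if lam == 0.0:
        return neutral
    pos = lam * traj.positions + (1.0 - lam) * neutral.positions
    return traj.with_positions(pos)
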
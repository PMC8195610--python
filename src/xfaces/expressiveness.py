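"""Low-level expressiveness measures and stimulus equilibration.

Prototype expressions can differ in sheer amount of motion or deformation,
which would confound any comparison of their perceptual categorization. Three
scalar measures quantify that low-level content:

* **MF** — motion flow: total 2D (x, y) point displacement of the face
  surface summed over markers and frame pairs;
* **DF** — deformation: maximum over frames of the Euclidean norm, in stacked
  2D point space, of the difference from the neutral pose;
* **OF** — optic flow: Horn–Schunck flow magnitude of the rendered image
  sequence, summed (mean per pixel) over frame pairs.

Equilibration blends each prototype toward the neutral clip with a morph
level λ, fits the measure-vs-λ relationship with the logistic curve
``M(λ) = a0 + a1 / (1 + exp(a2·λ + a3))``, and inverts it so every prototype
attains a common target value. Since neutral-blending can only lower a
measure, the target is the measure of the *least* expressive prototype, which
keeps λ = 1; all others are scaled down to meet it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit

from .opticflow import horn_schunck_sequence
from .style import neutral_morph
from .synthetic import PrototypeSet, render_frames
from .trajectory import AlignmentError, MarkerTrajectory

__all__ = [
    "ExpressivenessMeasure",
    "EquilibrationCurve",
    "EquilibrationResult",
    "motion_flow_MF",
    "deformation_DF",
    "optic_flow_OF",
    "fit_equilibration_curve",
    "invert_curve",
    "equilibrate_prototypes",
    "grid_measure_sd",
]


@dataclass(frozen=True)
class ExpressivenessMeasure:
    """A non-negative scalar expressiveness value of one clip."""

    kind: str  # "MF", "DF" or "OF"
    value: float
    region: tuple[str, ...] | None = None


def _project_2d(positions: np.ndarray, view_deg: float = 0.0) -> np.ndarray:
    """Orthographic (x, y) projection, optionally after rotation about the
    vertical (y) axis — the front and 30°-rotated presentation views."""
    if view_deg:
        th = np.deg2rad(view_deg)
        x = positions[..., 0] * np.cos(th) + positions[..., 2] * np.sin(th)
        return np.stack([x, positions[..., 1]], axis=-1)
    return positions[..., :2]


def _region_indices(traj: MarkerTrajectory, region) -> np.ndarray:
    if region is None:
        return np.arange(traj.n_markers)
    region = list(region)
    if not region:
        raise ValueError("region mask is empty")
    index = {m: i for i, m in enumerate(traj.marker_ids)}
    missing = [m for m in region if m not in index]
    if missing:
        raise AlignmentError(f"region names unknown markers: {missing}")
    return np.array([index[m] for m in region])


def motion_flow_MF(
    traj: MarkerTrajectory,
    region: list[str] | None = None,
    view_deg: float = 0.0,
) -> ExpressivenessMeasure:
    """Total 2D motion flow: Σ over frame pairs and (in-region) markers of
    the Euclidean norm of the frame-to-frame (x, y) displacement."""
    if traj.n_frames < 2:
        raise ValueError("motion flow needs at least 2 frames")
    idx = _region_indices(traj, region)
    xy = _project_2d(traj.positions[:, idx, :], view_deg)
    step = np.diff(xy, axis=0)
    value = float(np.linalg.norm(step, axis=2).sum())
    return ExpressivenessMeasure("MF", value, tuple(region) if region else None)


def deformation_DF(
    traj: MarkerTrajectory,
    neutral_pose: np.ndarray,
    region: list[str] | None = None,
    view_deg: float = 0.0,
) -> ExpressivenessMeasure:
    """Maximum 2D deformation from the neutral pose.

    Per frame, the (x, y) marker coordinates are stacked into one vector and
    the Euclidean distance to the stacked neutral pose taken; the measure is
    the maximum over frames (attained at the expressive peak)."""
    ref = np.asarray(neutral_pose, dtype=float)
    if ref.shape != (traj.n_markers, 3):
        raise AlignmentError(
            f"neutral pose shape {ref.shape} does not match ({traj.n_markers}, 3)"
        )
    idx = _region_indices(traj, region)
    diff = _project_2d(traj.positions[:, idx, :], view_deg) - _project_2d(
        ref[None, idx, :], view_deg
    )
    per_frame = np.linalg.norm(diff.reshape(traj.n_frames, -1), axis=1)
    return ExpressivenessMeasure("DF", float(per_frame.max()), tuple(region) if region else None)


def optic_flow_OF(
    frames: np.ndarray, alpha: float = 1.0, iterations: int = 100
) -> ExpressivenessMeasure:
    """Total optic flow of an image sequence: Σ over frame pairs of the mean
    Horn–Schunck flow-vector magnitude (px/frame)."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (frames, H, W) stack with at least 2 frames")
    if frames.min() < -1e-9 or frames.max() > 1.0 + 1e-9:
        raise ValueError("frame intensities must lie in [0, 1]")
    total = 0.0
    for u, v in horn_schunck_sequence(frames, alpha=alpha, iterations=iterations):
        total += float(np.hypot(u, v).mean())
    return ExpressivenessMeasure("OF", total)


# ---------------------------------------------------------------------------
# measure-vs-λ curve


def _logistic(lam, a0, a1, a2, a3):
    return a0 + a1 / (1.0 + np.exp(a2 * lam + a3))


@dataclass(frozen=True)
class EquilibrationCurve:
    """Fitted logistic M(λ) = a0 + a1/(1 + exp(a2·λ + a3))."""

    a0: float
    a1: float
    a2: float
    a3: float
    measure_kind: str = "MF"
    fit_residual: float = 0.0
    degenerate: bool = False

    def __call__(self, lam):
        return _logistic(np.asarray(lam, dtype=float), self.a0, self.a1, self.a2, self.a3)

    def attainable_range(self, n: int = 101) -> tuple[float, float]:
        vals = self(np.linspace(0.0, 1.0, n))
        return float(vals.min()), float(vals.max())

    def is_monotone(self, n: int = 101) -> bool:
        vals = self(np.linspace(0.0, 1.0, n))
        d = np.diff(vals)
        tol = 1e-12 * max(1.0, float(np.abs(vals).max()))
        return bool(np.all(d >= -tol) or np.all(d <= tol))


def fit_equilibration_curve(
    samples: list[tuple[float, float]], measure_kind: str = "MF"
) -> EquilibrationCurve:
    """Least-squares logistic fit of measure-vs-λ samples.

    Needs ≥ 5 distinct λ values spanning [0, 1]. Constant samples are flagged
    degenerate (a1 ≈ 0) rather than fitted.
    """
    lam = np.array([l for l, _ in samples], dtype=float)
    m = np.array([v for _, v in samples], dtype=float)
    if len(np.unique(lam)) < 5:
        raise ValueError("need at least 5 distinct λ samples")
    if lam.min() > 0.05 or lam.max() < 0.95:
        raise ValueError("λ samples must span [0, 1]")
    m_range = float(m.max() - m.min())
    scale = max(abs(m).max(), 1.0)
    if m_range <= 1e-9 * scale:
        return EquilibrationCurve(float(m.mean()), 0.0, 1.0, 0.0, measure_kind, 0.0, True)
    increasing = m[np.argmax(lam)] >= m[np.argmin(lam)]
    sgn = -1.0 if increasing else 1.0
    inits = [
        (m.min() - 0.1 * m_range, 1.4 * m_range, sgn * 6.0, -sgn * 3.0),
        (m.min() - 0.02 * m_range, 1.1 * m_range, sgn * 3.0, -sgn * 1.5),
        (m.min() - 0.5 * m_range, 2.5 * m_range, sgn * 9.0, -sgn * 4.5),
        (m.min(), m_range, sgn * 1.0, 0.0),
    ]
    best, best_sse = None, np.inf
    for p0 in inits:
        try:
            popt, _ = curve_fit(_logistic, lam, m, p0=p0, maxfev=20000)
        except RuntimeError:
            continue
        sse = float(np.sum((_logistic(lam, *popt) - m) ** 2))
        if sse < best_sse:
            best, best_sse = popt, sse
    if best is None:
        raise RuntimeError("logistic fit failed to converge from all starting points")
    rms = float(np.sqrt(best_sse / len(m)))
    return EquilibrationCurve(*map(float, best), measure_kind, rms, False)


def invert_curve(curve: EquilibrationCurve, target_M: float, tol: float = 1e-9) -> float:
    """Morph level λ ∈ [0, 1] at which the fitted curve attains ``target_M``.

    Uses the closed-form logistic inverse when the curve is monotone on
    [0, 1]; falls back to bracketed root finding otherwise. Targets outside
    the attainable range raise a ValueError reporting that range.
    """
    if curve.degenerate or curve.a1 == 0.0:
        raise ValueError("cannot invert a degenerate (constant) curve")
    lo, hi = curve.attainable_range()
    span = max(hi - lo, 1e-12)
    if not (lo - 1e-9 * span <= target_M <= hi + 1e-9 * span):
        raise ValueError(
            f"target {target_M} outside attainable measure range [{lo}, {hi}]"
        )
    target_M = float(np.clip(target_M, lo, hi))
    if curve.is_monotone():
        ratio = curve.a1 / (target_M - curve.a0)
        if ratio > 1.0:  # log argument positive → closed form valid
            lam = (np.log(ratio - 1.0) - curve.a3) / curve.a2
            if -1e-6 <= lam <= 1.0 + 1e-6:
                lam = float(np.clip(lam, 0.0, 1.0))
                if abs(float(curve(lam)) - target_M) <= max(tol, 1e-6 * span):
                    return lam
    # numeric fallback: scan for the bracket closest to λ=1
    grid = np.linspace(0.0, 1.0, 1001)
    vals = curve(grid) - target_M
    hits = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    exact = np.nonzero(np.abs(vals) <= tol * max(1.0, abs(target_M)))[0]
    if len(exact):
        return float(grid[exact[-1]])
    if not len(hits):
        raise ValueError(f"no λ in [0,1] attains target {target_M}")
    i = hits[-1]
    return float(brentq(lambda x: float(curve(x)) - target_M, grid[i], grid[i + 1]))


# ---------------------------------------------------------------------------
# equilibration of a prototype set


@dataclass(frozen=True)
class EquilibrationResult:
    """Per-prototype morph levels equating a low-level measure."""

    lambda_per_prototype: dict[str, float]
    target_M: float
    achieved_M: dict[str, float]
    measure_kind: str
    curves: dict[str, EquilibrationCurve] = field(default_factory=dict)
    rel_tolerance: float = 0.01

    def within_tolerance(self) -> bool:
        return all(
            abs(v - self.target_M) <= self.rel_tolerance * max(abs(self.target_M), 1e-12)
            for v in self.achieved_M.values()
        )


def _measure_for(
    traj: MarkerTrajectory,
    kind: str,
    neutral_pose: np.ndarray,
    region: list[str] | None,
    view_deg: float,
    of_params: dict,
) -> float:
    if kind == "MF":
        return motion_flow_MF(traj, region, view_deg).value
    if kind == "DF":
        return deformation_DF(traj, neutral_pose, region, view_deg).value
    if kind == "OF":
        frames = render_frames(
            traj,
            image_size=of_params.get("image_size", 48),
            blob_sigma=of_params.get("blob_sigma", 2.0),
        )
        return optic_flow_OF(
            frames,
            alpha=of_params.get("alpha", 1.0),
            iterations=of_params.get("iterations", 100),
        ).value
    raise ValueError(f"unknown measure kind {kind!r} (expected MF, DF or OF)")


def equilibrate_prototypes(
    prototypes: PrototypeSet,
    measure_kind: str = "MF",
    lam_grid: np.ndarray | int = 11,
    region: list[str] | None = None,
    view_deg: float = 0.0,
    of_params: dict | None = None,
) -> EquilibrationResult:
    """Find per-prototype morph levels λ that equate the chosen measure.

    The measure is sampled along ``lam_grid`` by neutral-morphing each
    prototype, the logistic curve fitted, and λ solved so every prototype
    attains the common target — the measure of the least expressive prototype
    at λ = 1, which itself keeps λ = 1.
    """
    if isinstance(lam_grid, int):
        lam_grid = np.linspace(0.0, 1.0, lam_grid)
    of_params = of_params or {}
    neutral_pose = prototypes.neutral_pose
    names = list(prototypes.prototypes)

    full_values = {}
    for name in names:
        try:
            full_values[name] = _measure_for(
                prototypes.prototypes[name], measure_kind, neutral_pose, region, view_deg, of_params
            )
        except Exception as err:  # pragma: no cover - defensive labelling
            raise RuntimeError(f"measure {measure_kind} failed for prototype {name!r}") from err
    target = min(full_values.values())
    anchor = min(full_values, key=full_values.get)

    lambdas, achieved, curves = {}, {}, {}
    for name in names:
        traj = prototypes.prototypes[name]
        # prototypes at (or within fit tolerance of) the target keep λ = 1:
        # neutral-blending can only reduce the measure
        if name == anchor or full_values[name] <= target * (1.0 + 1e-9):
            lambdas[name] = 1.0
            achieved[name] = full_values[name]
            continue
        samples = []
        for lam in lam_grid:
            morphed = neutral_morph(traj, prototypes.neutral, float(lam))
            samples.append(
                (float(lam), _measure_for(morphed, measure_kind, neutral_pose, region, view_deg, of_params))
            )
        try:
            curve = fit_equilibration_curve(samples, measure_kind)
            # the fitted curve may undershoot the measured value at λ=1 by its
            # residual; clip the target into the attainable range
            lam_star = invert_curve(curve, min(target, curve.attainable_range()[1]))
        except ValueError as err:
            raise ValueError(f"equilibration failed for prototype {name!r}: {err}") from err
        curves[name] = curve
        lambdas[name] = lam_star
        achieved[name] = _measure_for(
            neutral_morph(traj, prototypes.neutral, lam_star),
            measure_kind,
            neutral_pose,
            region,
            view_deg,
            of_params,
        )
    return EquilibrationResult(lambdas, target, achieved, measure_kind, curves)


def grid_measure_sd(
    grid_trajectories,
    neutral_pose: np.ndarray,
    measure_kind: str = "MF",
    region: list[str] | None = None,
    view_deg: float = 0.0,
    of_params: dict | None = None,
) -> float:
    """Standard deviation of a measure across the clips of a style grid —
    the quantity equilibration is meant to shrink."""
    of_params = of_params or {}
    vals = [
        _measure_for(t, measure_kind, neutral_pose, region, view_deg, of_params)
        for t in grid_trajectories
    ]
    return float(np.std(vals))
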
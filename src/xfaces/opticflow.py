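"""Horn–Schunck optic flow.

Classic global-smoothness optic flow: for each consecutive frame pair the
flow field (u, v) minimizes the brightness-constancy residual plus an
α-weighted smoothness penalty, solved by Jacobi iterations of the standard
update

    u ← ū − Ex (Ex ū + Ey v̄ + Et) / (α² + Ex² + Ey²)
    v ← v̄ − Ey (Ex ū + Ey v̄ + Et) / (α² + Ex² + Ey²)

with image derivatives Ex, Ey, Et from the original 2×2×2 averaging stencil
and ū, v̄ the 8-neighbour weighted local means.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve

__all__ = ["horn_schunck", "horn_schunck_sequence"]

# weighted local-average kernel from the original algorithm
_AVG_KERNEL = np.array(
    [
        [1 / 12, 1 / 6, 1 / 12],
        [1 / 6, 0.0, 1 / 6],
        [1 / 12, 1 / 6, 1 / 12],
    ]
)


def _derivatives(f0: np.ndarray, f1: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ex, Ey, Et averaged over the 2×2×2 cube spanning the frame pair."""
    a = np.pad(f0, ((0, 1), (0, 1)), mode="edge")
    b = np.pad(f1, ((0, 1), (0, 1)), mode="edge")
    ex = 0.25 * (
        (a[:-1, 1:] - a[:-1, :-1])
        + (a[1:, 1:] - a[1:, :-1])
        + (b[:-1, 1:] - b[:-1, :-1])
        + (b[1:, 1:] - b[1:, :-1])
    )
    ey = 0.25 * (
        (a[1:, :-1] - a[:-1, :-1])
        + (a[1:, 1:] - a[:-1, 1:])
        + (b[1:, :-1] - b[:-1, :-1])
        + (b[1:, 1:] - b[:-1, 1:])
    )
    et = 0.25 * (
        (b[:-1, :-1] - a[:-1, :-1])
        + (b[1:, :-1] - a[1:, :-1])
        + (b[:-1, 1:] - a[:-1, 1:])
        + (b[1:, 1:] - a[1:, 1:])
    )
    return ex, ey, et


def horn_schunck(
    frame0: np.ndarray,
    frame1: np.ndarray,
    alpha: float = 1.0,
    iterations: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Flow field (u, v) between two grayscale frames, in px/frame.

    ``u`` is the horizontal (column) component, ``v`` vertical (row,
    increasing downward). ``alpha`` is the smoothness regularizer of the
    energy functional; larger values give smoother, smaller-magnitude fields.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if iterations < 1:
        raise ValueError(f"iterations must be >= 1, got {iterations}")
    f0 = np.asarray(frame0, dtype=float)
    f1 = np.asarray(frame1, dtype=float)
    if f0.shape != f1.shape or f0.ndim != 2:
        raise ValueError("frames must be two 2D arrays of identical shape")
    ex, ey, et = _derivatives(f0, f1)
    u = np.zeros_like(f0)
    v = np.zeros_like(f0)
    denom = alpha**2 + ex**2 + ey**2
    for _ in range(iterations):
        u_bar = convolve(u, _AVG_KERNEL, mode="nearest")
        v_bar = convolve(v, _AVG_KERNEL, mode="nearest")
        common = (ex * u_bar + ey * v_bar + et) / denom
        u = u_bar - ex * common
        v = v_bar - ey * common
    return u, v


def horn_schunck_sequence(
    frames: np.ndarray, alpha: float = 1.0, iterations: int = 100
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Flow fields for every consecutive pair of a frame stack (F, H, W)."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (frames, H, W) stack with at least 2 frames")
    return [
        horn_schunck(frames[i], frames[i + 1], alpha, iterations)
        for i in range(frames.shape[0] - 1)
    ]
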
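"""Marker-trajectory container and time normalization.

A :class:`MarkerTrajectory` holds the 3D positions of a fixed set of facial
markers over the frames of one expression clip, in the (arbitrary) units of
the capture system. All morphing operations require trajectories that share
marker order and frame count; :func:`time_normalize` resamples clips of
unequal length onto a common frame count by per-marker linear interpolation
over normalized time [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MarkerTrajectory",
    "time_normalize",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "AlignmentError",
]


class AlignmentError(ValueError):
    """Raised when trajectories entering one operation disagree on markers."""


@dataclass(frozen=True)
class MarkerTrajectory:
    """Time series of 3D marker positions for one expression clip.

    Parameters
    ----------
    positions
        Array of shape ``(n_frames, n_markers, 3)``; must be finite.
    frame_rate
        Capture frame rate in Hz, strictly positive.
    marker_ids
        Ordered marker labels, one per marker column.
    """

    positions: np.ndarray
    frame_rate: float
    marker_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 3 or pos.shape[2] != 3:
            raise ValueError(f"positions must be (frames, markers, 3), got {pos.shape}")
        if pos.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if not np.all(np.isfinite(pos)):
            raise ValueError("trajectory contains missing or non-finite values")
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")
        ids = tuple(self.marker_ids) or tuple(f"m{i:02d}" for i in range(pos.shape[1]))
        if len(ids) != pos.shape[1]:
            raise ValueError("marker_ids length does not match marker count")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "marker_ids", ids)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_markers(self) -> int:
        return self.positions.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def with_positions(self, positions: np.ndarray) -> "MarkerTrajectory":
        return MarkerTrajectory(positions, self.frame_rate, self.marker_ids)

    def displacement_from(self, reference_frame: np.ndarray) -> np.ndarray:
        """Per-frame displacement from a single reference pose (markers, 3)."""
        ref = np.asarray(reference_frame, dtype=float)
        if ref.shape != (self.n_markers, 3):
            raise AlignmentError(
                f"reference pose shape {ref.shape} does not match "
                f"({self.n_markers}, 3)"
            )
        return self.positions - ref[None, :, :]


def check_same_markers(trajs: list[MarkerTrajectory]) -> None:
    """Raise :class:`AlignmentError` naming markers that differ across inputs."""
    base = trajs[0].marker_ids
    for t in trajs[1:]:
        if t.marker_ids != base:
            offending = sorted(set(base).symmetric_difference(t.marker_ids))
            raise AlignmentError(
                "marker sets differ between trajectories; offending markers: "
                + (", ".join(offending) if offending else "same set, different order")
            )


def time_normalize(
    trajs: list[MarkerTrajectory] | MarkerTrajectory,
    target_frames: int = 150,
) -> list[MarkerTrajectory] | MarkerTrajectory:
    """Resample trajectories to a common frame count.

    Interpolates each marker coordinate linearly over normalized clip time
    [0, 1]; first and last frames are preserved exactly. A trajectory already
    at ``target_frames`` is returned unchanged.
    """
    single = isinstance(trajs, MarkerTrajectory)
    traj_list = [trajs] if single else list(trajs)
    if target_frames < 2:
        raise ValueError(f"target_frames must be >= 2, got {target_frames}")
    out = []
    for traj in traj_list:
        if traj.n_frames < 2:
            raise ValueError("time normalization requires at least 2 frames")
        if traj.n_frames == target_frames:
            out.append(traj)
            continue
        t_src = np.linspace(0.0, 1.0, traj.n_frames)
        t_dst = np.linspace(0.0, 1.0, target_frames)
        flat = traj.positions.reshape(traj.n_frames, -1)
        resampled = np.empty((target_frames, flat.shape[1]))
        for j in range(flat.shape[1]):
            resampled[:, j] = np.interp(t_dst, t_src, flat[:, j])
        # np.interp endpoints are exact, but enforce bit-identity anyway
        resampled[0] = flat[0]
        resampled[-1] = flat[-1]
        new_rate = traj.frame_rate * (target_frames - 1) / max(traj.n_frames - 1, 1)
        out.append(
            MarkerTrajectory(
                resampled.reshape(target_frames, traj.n_markers, 3),
                frame_rate=new_rate,
                marker_ids=traj.marker_ids,
            )
        )
    return out[0] if single else out


def write_trajectory_csv(traj: MarkerTrajectory, path: str | Path) -> None:
    """Write the long-format trajectory CSV (frame, marker_id, x, y, z)."""
    frames = np.repeat(np.arange(traj.n_frames), traj.n_markers)
    markers = np.tile(np.asarray(traj.marker_ids, dtype=object), traj.n_frames)
    xyz = traj.positions.reshape(-1, 3)
    df = pd.DataFrame(
        {
            "frame": frames,
            "marker_id": markers,
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
        }
    )
    df.to_csv(path, index=False)


def read_trajectory_csv(path: str | Path, frame_rate: float = 30.0) -> MarkerTrajectory:
    """Read the long-format trajectory CSV written by :func:`write_trajectory_csv`."""
    df = pd.read_csv(path)
    required = {"frame", "marker_id", "x", "y", "z"}
    missing = required.difference(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV {path} lacks columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"trajectory CSV {path} is empty")
    marker_ids = tuple(df[df["frame"] == df["frame"].min()]["marker_id"].astype(str))
    n_frames = df["frame"].nunique()
    pivot = df.sort_values(["frame"]).reset_index(drop=True)
    pos = np.full((n_frames, len(marker_ids), 3), np.nan)
    marker_index = {m: i for i, m in enumerate(marker_ids)}
    frame_values = np.sort(df["frame"].unique())
    frame_index = {f: i for i, f in enumerate(frame_values)}
    fi = pivot["frame"].map(frame_index).to_numpy()
    mi = pivot["marker_id"].astype(str).map(marker_index).to_numpy()
    if np.any(pd.isna(mi)):
        raise ValueError(f"trajectory CSV {path} has inconsistent marker ids")
    pos[fi, mi.astype(int)] = pivot[["x", "y", "z"]].to_numpy()
    if np.any(np.isnan(pos)):
        raise ValueError(f"trajectory CSV {path} has missing (frame, marker) cells")
    return MarkerTrajectory(pos, frame_rate=frame_rate, marker_ids=marker_ids)
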
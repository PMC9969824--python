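"""Frame synchronization and side-by-side comparison of simulations.

Trajectories of different lengths or time steps are aligned on a shared
integer axis: aligned index k of a trajectory with sync parameters
(offset, stride) maps to local frame ``offset + k * stride``.  Offsets may
be negative (the trajectory joins the shared axis later); mappings outside
a trajectory's range yield missing values (NaN in combined series).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import MetricsError, TimeSeries

MISSING = -1


class CompareError(Exception):
    pass


@dataclass(frozen=True)
class TrajectorySync:
    """Per-trajectory alignment: local frame = offset + k * stride."""

    offset: int = 0
    stride: int = 1

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise CompareError("sync stride must be >= 1")


@dataclass(frozen=True)
class SyncSpec:
    trajectories: tuple[TrajectorySync, ...]

    @staticmethod
    def from_pairs(pairs: list[tuple[int, int]]) -> "SyncSpec":
        return SyncSpec(tuple(TrajectorySync(o, s) for o, s in pairs))


def time_offset_to_frames(offset_ps: float, dt_ps: float) -> int:
    """Convert a time offset to the nearest frame (ties round half down)."""
    if dt_ps <= 0:
        raise CompareError("frame spacing dt must be positive")
    return int(np.ceil(offset_ps / dt_ps - 0.5))


def synchronize(lengths: list[int], spec: SyncSpec) -> np.ndarray:
    """Aligned index table: rows k = 0..K-1, one column per trajectory.

    Cell (k, t) holds trajectory t's local frame index at aligned index k,
    or :data:`MISSING` (-1) where the mapping falls outside the trajectory.
    K is the largest k + 1 for which at least one trajectory is valid.
    """
    if len(lengths) != len(spec.trajectories):
        raise CompareError("one sync entry per trajectory required")
    if any(n < 1 for n in lengths):
        raise CompareError("every trajectory needs at least one frame")
    max_k = MISSING
    for n, ts in zip(lengths, spec.trajectories):
        # largest k with 0 <= offset + k*stride <= n-1
        k_hi = (n - 1 - ts.offset) // ts.stride
        max_k = max(max_k, k_hi)
    if max_k < 0:
        raise CompareError("no trajectory has a valid frame under this sync spec")
    table = np.full((max_k + 1, len(lengths)), MISSING, dtype=int)
    for t, (n, ts) in enumerate(zip(lengths, spec.trajectories)):
        for k in range(max_k + 1):
            local = ts.offset + k * ts.stride
            if 0 <= local < n:
                table[k, t] = local
    return table


def series_compare(
    series_per_traj: list[TimeSeries],
    alignment: np.ndarray,
    labels: list[str] | None = None,
) -> TimeSeries:
    """Place each trajectory's series on the shared aligned axis.

    Each input series must be indexed by its trajectory's local frames (row
    i = local frame i).  The result has one column per input column per
    trajectory, NaN where the alignment is missing.  Colliding column names
    are suffixed with the trajectory label.
    """
    if alignment.shape[1] != len(series_per_traj):
        raise CompareError("alignment table and series list disagree on count")
    if labels is None:
        labels = [f"traj{t + 1}" for t in range(len(series_per_traj))]
    K = alignment.shape[0]
    columns: dict[str, np.ndarray] = {}
    for t, series in enumerate(series_per_traj):
        for name, col in series.columns.items():
            out_name = name if name not in columns else f"{name}_{labels[t]}"
            out = np.full(K, np.nan)
            for k in range(K):
                local = alignment[k, t]
                if local != MISSING and local < len(col):
                    out[k] = col[local]
            columns[out_name] = out
    try:
        return TimeSeries(x=np.arange(K, dtype=float), columns=columns,
                          xlabel="Aligned frame")
    except MetricsError as exc:  # pragma: no cover
        raise CompareError(str(exc)) from exc
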
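"""The 3D segmented Poincaré box model: grids, rotation, binning, coarse graining.

The aligned point cloud of 2–3 coupled series (or of one lag-embedded
series) is partitioned into a 12×12×12 cubic box of equal cubelets, and each
cubelet's occupation probability ``Prob(Xr,Yc,Zd) = #points / N`` is the
feature.  Two grid variants exist:

* adapted — cubelet edges derive from each series' SD and the box is
  centred on the cloud centroid, so the 12 cells per axis span the centroid
  ± 3·SD (edge = SD/2; at 6 cells per axis edge = SD, same span);
* predefined — fixed physiological axis ranges identical for all subjects
  (BBI 400–1300 ms in 75-ms steps, SBP 50–206 mmHg in 13-mmHg steps, DBP
  22–130 mmHg in 9-mmHg steps, RESP from 0.5 s in 1.25-s steps; the RESP
  axis is extended to 15.5 s so 12 equal cells exist).

Optionally the cloud is first rotated about its centroid by the plane-wise
regression angles (α in the XY-plane, β in YZ, γ in ZX), normalising the
orientation of the cloud before binning.  A coarsely segmented 6×6×6 model
is obtained by summing each 2×2×2 block of the fine model.

Cells are half-open ``[lo, hi)``: a point exactly on an interior boundary
belongs to the higher-index cell, and a point on the global upper edge is
out of range.  Out-of-range points are excluded from every cubelet but kept
in N, so probabilities always satisfy ``sum(probs) + out_of_range == 1``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import AlignedRecording, SignalKind

__all__ = [
    "GridSpec",
    "RotationResult",
    "CubeletKey",
    "ProbabilityBox",
    "PREDEFINED_DIMENSIONS",
    "adapted_grids",
    "predefined_grids",
    "fit_plane_rotation",
    "rotate_fixed",
    "probability_box",
    "coarse_grain",
    "multivariate_box",
    "write_probability_box",
    "read_probability_box",
]

#: Predefined cubelet edge and axis range per signal (12-cell grid):
#: kind -> (edge, axis minimum, axis maximum).  The RESP maximum is the
#: extended 15.5 s (the nominal 15 s is not an integer multiple of 1.25 s
#: above 0.5 s).
PREDEFINED_DIMENSIONS: dict[SignalKind, tuple[float, float, float]] = {
    SignalKind.BBI: (75.0, 400.0, 1300.0),
    SignalKind.SBP: (13.0, 50.0, 206.0),
    SignalKind.DBP: (9.0, 22.0, 130.0),
    SignalKind.RESP: (1.25, 0.5, 15.5),
}


@dataclass(frozen=True)
class GridSpec:
    """Equal partition of one axis into ``n_cells`` cubelet edges."""

    kind: SignalKind
    mode: str  # "adapted" | "predefined"
    origin: float  # lower edge of cell 1, signal units
    edge: float  # cubelet size, signal units
    n_cells: int

    def __post_init__(self) -> None:
        if self.edge <= 0:
            raise ValueError("cubelet edge must be positive")
        if self.n_cells not in (6, 12):
            raise ValueError("n_cells must be 6 or 12")
        if self.mode not in ("adapted", "predefined"):
            raise ValueError(f"unknown grid mode {self.mode!r}")

    @property
    def upper(self) -> float:
        return self.origin + self.n_cells * self.edge

    def cell_index(self, values: np.ndarray) -> np.ndarray:
        """1-based cell index per value; indices outside 1..n_cells are out of range."""
        return np.floor((np.asarray(values, float) - self.origin) / self.edge).astype(
            int
        ) + 1


@dataclass(frozen=True)
class RotationResult:
    """Plane-wise regression angles and the rigidly rotated cloud."""

    alpha_deg: float
    beta_deg: float
    gamma_deg: float
    centroid: np.ndarray
    rotated_points: np.ndarray

    @property
    def angles_deg(self) -> tuple[float, float, float]:
        return (self.alpha_deg, self.beta_deg, self.gamma_deg)


@dataclass(frozen=True)
class CubeletKey:
    """1-based (row, column, depth) coordinates of one cubelet."""

    r: int
    c: int
    d: int
    signals: tuple[SignalKind, SignalKind, SignalKind]

    @property
    def label(self) -> str:
        sx, sy, sz = self.signals
        return f"{sx.value}{self.r}_{sy.value}{self.c}_{sz.value}{self.d}"


def adapted_grids(
    recording: AlignedRecording, n_cells: int = 12
) -> list[GridSpec]:
    """SD-adapted grids: per axis the box spans centroid ± 3·SD.

    edge = 6·SD/n_cells, i.e. SD/2 on the fine (12-cell) grid and SD on the
    coarse (6-cell) grid; origin = mean − 3·SD so the centroid sits exactly
    on the boundary between cells n/2 and n/2+1.
    """
    if n_cells not in (6, 12):
        raise ValueError("n_cells must be 6 or 12")
    means = recording.centroid()
    sds = recording.sd(ddof=1)
    grids = []
    for kind, mean, sd in zip(recording.signals, means, sds):
        if sd <= 0:
            raise ValueError(f"zero variance on axis {kind.value}; cannot adapt grid")
        edge = 6.0 * sd / n_cells
        grids.append(
            GridSpec(
                kind=kind,
                mode="adapted",
                origin=mean - 3.0 * sd,
                edge=edge,
                n_cells=n_cells,
            )
        )
    return grids


def predefined_grids(
    signals: tuple[SignalKind, ...] | list[SignalKind], n_cells: int = 12
) -> list[GridSpec]:
    """Fixed physiological grids, identical for every subject.

    At 6 cells per axis the edge doubles and the origin is unchanged, so the
    axis range is preserved.
    """
    if n_cells not in (6, 12):
        raise ValueError("n_cells must be 6 or 12")
    grids = []
    for kind in signals:
        kind = SignalKind(kind)
        if kind not in PREDEFINED_DIMENSIONS:
            raise ValueError(f"no predefined dimensions for signal {kind!r}")
        edge, lo, _hi = PREDEFINED_DIMENSIONS[kind]
        grids.append(
            GridSpec(
                kind=kind,
                mode="predefined",
                origin=lo,
                edge=edge * (12 // n_cells),
                n_cells=n_cells,
            )
        )
    return grids


def _ls_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y on x; 0 for a zero-variance predictor.

    A degenerate predictor axis carries no orientation information, so the
    corresponding plane rotation is the identity.
    """
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        return 0.0
    return float(xc @ (y - y.mean())) / sxx


def _rotation_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Sequential rotation −α about Z, then −β about X, then −γ about Y (radians)."""

    def rz(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def rx(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])

    def ry(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])

    return ry(-gamma) @ rx(-beta) @ rz(-alpha)


def _apply_rotation(
    points: np.ndarray, alpha: float, beta: float, gamma: float
) -> tuple[np.ndarray, np.ndarray]:
    centroid = points.mean(axis=0)
    rot = _rotation_matrix(alpha, beta, gamma)
    return (points - centroid) @ rot.T + centroid, centroid


def fit_plane_rotation(recording: AlignedRecording) -> RotationResult:
    """Fit the plane-wise regression angles and rotate the cloud rigidly.

    α = atan(slope of Y on X) in the XY-plane, β = atan(slope of Z on Y) in
    the YZ-plane, γ = atan(slope of X on Z) in the ZX-plane.  All three
    angles are estimated from the original (un-rotated) cloud, then the
    rotations −α about Z, −β about X and −γ about Y are applied in that
    fixed order about the centroid.
    """
    if len(recording.signals) != 3:
        raise ValueError("plane rotation requires a 3-axis recording")
    x, y, z = recording.points.T
    alpha = float(np.arctan(_ls_slope(x, y)))
    beta = float(np.arctan(_ls_slope(y, z)))
    gamma = float(np.arctan(_ls_slope(z, x)))
    rotated, centroid = _apply_rotation(recording.points, alpha, beta, gamma)
    return RotationResult(
        alpha_deg=float(np.degrees(alpha)),
        beta_deg=float(np.degrees(beta)),
        gamma_deg=float(np.degrees(gamma)),
        centroid=centroid,
        rotated_points=rotated,
    )


def rotate_fixed(points: np.ndarray, angle_deg: float = 45.0) -> RotationResult:
    """Rotate by the same fixed angle in all three planes (univariate variant)."""
    a = float(np.radians(angle_deg))
    rotated, centroid = _apply_rotation(np.asarray(points, float), a, a, a)
    return RotationResult(
        alpha_deg=angle_deg,
        beta_deg=angle_deg,
        gamma_deg=angle_deg,
        centroid=centroid,
        rotated_points=rotated,
    )


@dataclass(frozen=True)
class ProbabilityBox:
    """Per-cubelet occurrence probabilities of one recording's point cloud."""

    probs: np.ndarray  # (n, n, n)
    n_points: int
    out_of_range: float
    grids: tuple[GridSpec, ...]
    signals: tuple[SignalKind, ...]
    mode: str
    rotated: bool
    variant: str = "multivariate"  # "multivariate" | "univariate"
    rotation: RotationResult | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, float)
        object.__setattr__(self, "probs", probs)
        n = probs.shape[0]
        if probs.shape != (n, n, n):
            raise ValueError("probs must be a cubic tensor")
        if np.any(probs < -1e-15):
            raise ValueError("negative probability")
        total = probs.sum() + self.out_of_range
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities and out_of_range sum to {total}, not 1")
        if self.n_points < 3:
            raise ValueError("n_points must be at least 3")

    @property
    def n_cells(self) -> int:
        return self.probs.shape[0]

    def key(self, r: int, c: int, d: int) -> CubeletKey:
        return CubeletKey(r=r, c=c, d=d, signals=tuple(self.signals))

    def labels(self) -> list[str]:
        """Cubelet labels in (r, c, d) row-major order, e.g. BBI1_SBP4_RESP2."""
        n = self.n_cells
        return [
            self.key(r, c, d).label
            for r, c, d in itertools.product(range(1, n + 1), repeat=3)
        ]

    def to_series(self) -> pd.Series:
        return pd.Series(self.probs.ravel(), index=self.labels(), name="prob")

    def to_long_frame(self) -> pd.DataFrame:
        n = self.n_cells
        idx = np.array(list(itertools.product(range(1, n + 1), repeat=3)))
        sx, sy, sz = (s.value for s in self.signals)
        return pd.DataFrame(
            {
                "signalX": sx,
                "signalY": sy,
                "signalZ": sz,
                "r": idx[:, 0],
                "c": idx[:, 1],
                "d": idx[:, 2],
                "prob": self.probs.ravel(),
            }
        )


def probability_box(
    recording: AlignedRecording,
    grids: list[GridSpec] | tuple[GridSpec, ...],
    rotate: bool = False,
) -> ProbabilityBox:
    """Bin the point cloud into its cubic box and return occurrence probabilities.

    With ``rotate=True`` the plane-regression rotation is fitted and applied
    first; grids are used as given (for the adapted variant they derive from
    the original series' SDs, and the centroid is invariant under the
    rotation, so the box stays centred on the cloud).
    """
    grids = tuple(grids)
    if len(recording.signals) != 3:
        raise ValueError("the cubic box model requires a 3-axis recording")
    if len(grids) != len(recording.signals):
        raise ValueError("one grid per axis required")
    for grid, kind in zip(grids, recording.signals):
        if grid.kind is not SignalKind(kind):
            raise ValueError("grid order does not match recording axis order")
    n_cells = grids[0].n_cells
    if any(g.n_cells != n_cells for g in grids):
        raise ValueError("mixed n_cells across axes")

    rotation = None
    points = recording.points
    if rotate:
        rotation = fit_plane_rotation(recording)
        points = rotation.rotated_points

    idx = np.column_stack(
        [grid.cell_index(points[:, j]) for j, grid in enumerate(grids)]
    )
    in_range = ((idx >= 1) & (idx <= n_cells)).all(axis=1)
    counts = np.zeros((n_cells, n_cells, n_cells))
    np.add.at(counts, tuple((idx[in_range] - 1).T), 1.0)
    n = recording.n_points
    return ProbabilityBox(
        probs=counts / n,
        n_points=n,
        out_of_range=float((~in_range).sum()) / n,
        grids=grids,
        signals=tuple(recording.signals),
        mode=grids[0].mode,
        rotated=rotate,
        rotation=rotation,
    )


def coarse_grain(box: ProbabilityBox) -> ProbabilityBox:
    """Combine each 2×2×2 block of the 12³ model into one 6³ cubelet."""
    if box.n_cells != 12:
        raise ValueError("coarse graining applies to the 12-cell box only")
    coarse = box.probs.reshape(6, 2, 6, 2, 6, 2).sum(axis=(1, 3, 5))
    grids = tuple(
        replace(g, edge=g.edge * 2.0, n_cells=6) for g in box.grids
    )
    return replace(box, probs=coarse, grids=grids, rotation=box.rotation)


def multivariate_box(
    recording: AlignedRecording,
    mode: str = "adapted",
    rotate: bool = False,
    n_cells: int = 12,
) -> ProbabilityBox:
    """Convenience wrapper: build grids for ``mode`` and bin the recording.

    The coarse model is always derived by coarse-graining the fine box, so
    adapted coarse cubelets are exact 2×2×2 sums of the fine ones.  In the
    rotated adapted variant the grid adapts to the rotated cloud (the
    rotation normalises the box model; the centroid is invariant), because
    plane regressions between axes of heterogeneous units produce angles
    near ±90° and a grid sized from the un-rotated SDs would miss nearly
    the whole rotated cloud.
    """
    if mode == "adapted":
        if rotate:
            rotation = fit_plane_rotation(recording)
            rotated_rec = AlignedRecording(
                signals=recording.signals,
                points=rotation.rotated_points,
                beat_times=recording.beat_times,
            )
            grids = adapted_grids(rotated_rec, n_cells=12)
            box = probability_box(rotated_rec, grids, rotate=False)
            box = replace(box, rotated=True, rotation=rotation)
        else:
            grids = adapted_grids(recording, n_cells=12)
            box = probability_box(recording, grids, rotate=False)
    elif mode == "predefined":
        grids = predefined_grids(recording.signals, n_cells=12)
        box = probability_box(recording, grids, rotate=rotate)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if n_cells == 6:
        box = coarse_grain(box)
    elif n_cells != 12:
        raise ValueError("n_cells must be 6 or 12")
    return box


def write_probability_box(box: ProbabilityBox, path: str | Path) -> None:
    """Long-format CSV plus a JSON sidecar with grids and variant flags."""
    path = Path(path)
    box.to_long_frame().to_csv(path, index=False)
    meta = {
        "signals": [s.value for s in box.signals],
        "mode": box.mode,
        "rotated": box.rotated,
        "variant": box.variant,
        "n_points": box.n_points,
        "out_of_range": box.out_of_range,
        "n_cells": box.n_cells,
        "grids": [
            {
                "kind": g.kind.value,
                "mode": g.mode,
                "origin": g.origin,
                "edge": g.edge,
                "n_cells": g.n_cells,
            }
            for g in box.grids
        ],
        "rotation_deg": list(box.rotation.angles_deg) if box.rotation else None,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_probability_box(path: str | Path) -> ProbabilityBox:
    path = Path(path)
    frame = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    n = meta["n_cells"]
    probs = np.zeros((n, n, n))
    probs[frame["r"] - 1, frame["c"] - 1, frame["d"] - 1] = frame["prob"]
    grids = tuple(
        GridSpec(
            kind=SignalKind(g["kind"]),
            mode=g["mode"],
            origin=g["origin"],
            edge=g["edge"],
            n_cells=g["n_cells"],
        )
        for g in meta["grids"]
    )
    return ProbabilityBox(
        probs=probs,
        n_points=meta["n_points"],
        out_of_range=meta["out_of_range"],
        grids=grids,
        signals=tuple(SignalKind(s) for s in meta["signals"]),
        mode=meta["mode"],
        rotated=meta["rotated"],
        variant=meta["variant"],
    )
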
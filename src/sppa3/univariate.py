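"""Univariate SPPA3: lag-embedding one series into 3D phase space.

One series x is plotted against its own future, (x_n, x_{n+1}, x_{n+2})
with lags τ = 1, 2, and the resulting pseudo-phase-space cloud goes through
the same cubic box machinery as the multivariate couplings.  The rotated
variant uses a fixed 45° angle in each of the three planes — the main
diagonal of a strongly autocorrelated series has unit slope, so 45° aligns
it with an axis — instead of fitting regressions.  Cubelet labels repeat the
source signal name, e.g. BBI1_BBI4_BBI2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .boxmodel import (
    GridSpec,
    ProbabilityBox,
    predefined_grids,
    probability_box,
    rotate_fixed,
)
from .signals import AlignedRecording, BeatSeries, SignalKind

__all__ = ["LagEmbedding", "embed_series", "univariate_box", "UNIVARIATE_ROTATION_DEG"]

#: Fixed rotation angle of the univariate rotated variant, degrees.
UNIVARIATE_ROTATION_DEG = 45.0


@dataclass(frozen=True)
class LagEmbedding:
    """3D lag embedding (x_n, x_{n+1}, x_{n+2}) of one series, N = len − 2."""

    recording: AlignedRecording
    source: SignalKind

    def __post_init__(self) -> None:
        pts = self.recording.points
        if pts.shape[1] != 3:
            raise ValueError("lag embedding must have 3 axes")
        # shifted-copy structure: column j is the source shifted by lag j
        if not (
            np.array_equal(pts[1:, 0], pts[:-1, 1])
            and np.array_equal(pts[1:, 1], pts[:-1, 2])
        ):
            raise ValueError("columns are not lag-shifted copies of one series")

    @property
    def n_points(self) -> int:
        return self.recording.n_points

    def column_sds(self, ddof: int = 1) -> np.ndarray:
        """SD(x_n), SD(x_{n+1}), SD(x_{n+2})."""
        return self.recording.sd(ddof=ddof)


def embed_series(series: BeatSeries) -> LagEmbedding:
    """Lag-embed a series: rows (x_i, x_{i+1}, x_{i+2}), i = 1 … N−2."""
    x = series.values
    if len(x) < 5:
        raise ValueError(f"series too short to embed (need ≥ 5, got {len(x)})")
    points = np.column_stack([x[:-2], x[1:-1], x[2:]])
    recording = AlignedRecording(
        signals=(series.kind, series.kind, series.kind),
        points=points,
        beat_times=series.times[:-2],
    )
    return LagEmbedding(recording=recording, source=series.kind)


def _adapted_univariate_grids(emb: LagEmbedding, n_cells: int) -> list[GridSpec]:
    # grid adapted to the per-column SDs of the original embedding, centred
    # on the main focus; same ±3·SD span convention as the multivariate case
    means = emb.recording.centroid()
    sds = emb.column_sds()
    grids = []
    for mean, sd in zip(means, sds):
        if sd <= 0:
            raise ValueError(
                f"zero variance in lag-embedded {emb.source.value} series"
            )
        edge = 6.0 * sd / n_cells
        grids.append(
            GridSpec(
                kind=emb.source,
                mode="adapted",
                origin=mean - 3.0 * sd,
                edge=edge,
                n_cells=n_cells,
            )
        )
    return grids


def univariate_box(
    series: BeatSeries,
    rotate: bool = False,
    mode: str = "adapted",
    n_cells: int = 12,
) -> ProbabilityBox:
    """Build the univariate probability box of one lag-embedded series.

    ``mode="adapted"`` adapts the grid to the SDs of the three embedding
    columns; ``mode="predefined"`` reuses the signal's fixed physiological
    axis on all three axes.  With ``rotate=True`` the cloud is rotated by
    the fixed 45° in each plane (same sequential scheme as the multivariate
    rotation) before binning.
    """
    if n_cells not in (6, 12):
        raise ValueError("n_cells must be 6 or 12")
    emb = embed_series(series)
    if mode == "adapted":
        grids = _adapted_univariate_grids(emb, n_cells)
    elif mode == "predefined":
        grids = predefined_grids(emb.recording.signals, n_cells=n_cells)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    recording = emb.recording
    rotation = None
    if rotate:
        rotation = rotate_fixed(recording.points, UNIVARIATE_ROTATION_DEG)
        recording = AlignedRecording(
            signals=recording.signals,
            points=rotation.rotated_points,
            beat_times=recording.beat_times,
        )
    box = probability_box(recording, grids, rotate=False)
    return replace(box, rotated=rotate, variant="univariate", rotation=rotation)
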
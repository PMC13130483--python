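"""Depth-point ROI derivation from localization responses.

Pointer responses are binned on a uniform 32 x 16 grid over the stimulus,
cells reaching a per-cell response threshold are grouped into connected
components (8-connectivity by default), and each component becomes a
rectangular ROI via the minimum bounding rectangle of its member cells, in
normalized coordinates. Between one and six ROIs are kept per stimulus,
ranked by total response support.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidConfigError

N_COLS = 32
N_ROWS = 16


@dataclass
class GridCounts:
    """Response counts on the 32 x 16 localization grid (rows x cols)."""

    stimulus_id: str
    counts: np.ndarray
    n_rejected: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (N_ROWS, N_COLS):
            raise InvalidConfigError(f"counts must be {N_ROWS}x{N_COLS}")
        if (self.counts < 0).any():
            raise InvalidConfigError("counts must be nonnegative")


@dataclass(frozen=True)
class DepthROI:
    """Axis-aligned rectangle in normalized coordinates, half-open on both
    axes: a point belongs iff min_x <= x < max_x and min_y <= y < max_y."""

    roi_id: int
    min_x: float
    max_x: float
    min_y: float
    max_y: float
    support: int
    n_cells: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_x < self.max_x <= 1.0
                and 0.0 <= self.min_y < self.max_y <= 1.0):
            raise InvalidConfigError("ROI bounds must satisfy 0 <= min < max <= 1")


@dataclass
class DepthROISet:
    """1-6 depth ROIs for one stimulus, ordered by descending support.

    ``no_consensus`` is True when no grid cell reached the threshold; the
    ROI list is then empty (a flagged result, not an error).
    """

    stimulus_id: str
    rois: list[DepthROI] = field(default_factory=list)
    no_consensus: bool = False


def default_threshold(n_respondents: int) -> int:
    """Per-cell response threshold: max(2, ceil(5% of respondents))."""
    return max(2, math.ceil(0.05 * n_respondents))


def bin_responses(responses: pd.DataFrame, stim_meta: dict) -> GridCounts:
    """Aggregate one stimulus's pointer responses onto the 32 x 16 grid.

    Cell index = (floor(32*x/width), floor(16*y/height)); points exactly on
    the right/bottom edge clamp to the last column/row. Points more than
    1 px outside the image are rejected (counted in ``n_rejected``).
    """
    sids = responses["stimulus_id"].unique()
    if len(sids) > 1:
        raise InvalidConfigError(f"responses span multiple stimuli: {sids}")
    sid = str(sids[0]) if len(sids) else str(stim_meta.get("stimulus_id", ""))
    w = float(stim_meta["width_px"])
    h = float(stim_meta["height_px"])
    counts = np.zeros((N_ROWS, N_COLS), dtype=int)
    n_rejected = 0
    x = responses["point_x_px"].to_numpy(float)
    y = responses["point_y_px"].to_numpy(float)
    in_tol = (x >= -1.0) & (x <= w + 1.0) & (y >= -1.0) & (y <= h + 1.0)
    n_rejected = int((~in_tol).sum())
    xc = np.clip(x[in_tol], 0.0, w)
    yc = np.clip(y[in_tol], 0.0, h)
    col = np.minimum((N_COLS * xc / w).astype(int), N_COLS - 1)
    row = np.minimum((N_ROWS * yc / h).astype(int), N_ROWS - 1)
    np.add.at(counts, (row, col), 1)
    return GridCounts(stimulus_id=sid, counts=counts, n_rejected=n_rejected)


def extract_rois(
    grid: GridCounts,
    threshold: int,
    connectivity: int = 8,
    max_rois: int = 6,
) -> DepthROISet:
    """Threshold the grid, group contiguous cells, and box each group.

    Cells with count >= threshold are grouped into connected components
    (``connectivity`` 4 or 8); each component yields one ROI via the
    minimum bounding rectangle of its cells in normalized coordinates.
    Components are ranked by descending support (ties broken by the
    smaller row-major index of the component's first cell) and at most
    ``max_rois`` are kept.
    """
    if threshold < 1:
        raise InvalidConfigError("threshold must be >= 1")
    if connectivity not in (4, 8):
        raise InvalidConfigError("connectivity must be 4 or 8")
    mask = grid.counts >= threshold
    if not mask.any():
        return DepthROISet(stimulus_id=grid.stimulus_id, no_consensus=True)
    structure = np.ones((3, 3), int) if connectivity == 8 else ndimage.generate_binary_structure(2, 1)
    labels, n_comp = ndimage.label(mask, structure=structure)
    comps = []
    for lab in range(1, n_comp + 1):
        rows, cols = np.nonzero(labels == lab)
        support = int(grid.counts[rows, cols].sum())
        first_cell = int((rows * N_COLS + cols).min())
        comps.append((support, first_cell, rows, cols))
    comps.sort(key=lambda c: (-c[0], c[1]))
    rois = []
    for i, (support, _first, rows, cols) in enumerate(comps[:max_rois]):
        rois.append(
            DepthROI(
                roi_id=i,
                min_x=cols.min() / N_COLS,
                max_x=(cols.max() + 1) / N_COLS,
                min_y=rows.min() / N_ROWS,
                max_y=(rows.max() + 1) / N_ROWS,
                support=support,
                n_cells=len(rows),
            )
        )
    return DepthROISet(stimulus_id=grid.stimulus_id, rois=rois)


def point_in_roi(x: float, y: float, roi: DepthROI) -> bool:
    """Half-open membership test in normalized coordinates."""
    return roi.min_x <= x < roi.max_x and roi.min_y <= y < roi.max_y


def membership_mask(
    x: np.ndarray, y: np.ndarray, rois: Sequence[DepthROI]
) -> np.ndarray:
    """Vectorised union membership: True where (x, y) falls in any ROI.

    NaN coordinates are never members.
    """
    inside = np.zeros(len(x), dtype=bool)
    for roi in rois:
        inside |= (
            (x >= roi.min_x) & (x < roi.max_x) & (y >= roi.min_y) & (y < roi.max_y)
        )
    return inside


def rois_for_stimuli(
    responses: pd.DataFrame,
    stim_meta: dict[str, dict],
    threshold: int | None = None,
    connectivity: int = 8,
    max_rois: int = 6,
) -> dict[str, DepthROISet]:
    """Derive a DepthROISet for every stimulus present in ``responses``.

    With ``threshold=None`` the per-stimulus default threshold (5% of that
    stimulus's respondents, floor 2) is applied.
    """
    out = {}
    for sid, grp in responses.groupby("stimulus_id", sort=True):
        sid = str(sid)
        grid = bin_responses(grp, stim_meta[sid])
        thr = threshold if threshold is not None else default_threshold(len(grp))
        out[sid] = extract_rois(grid, thr, connectivity=connectivity, max_rois=max_rois)
    return out


# ---------------------------------------------------------------------------
# Serialization / visualisation helpers
# ---------------------------------------------------------------------------

def roi_sets_to_json_dict(roi_sets: dict[str, DepthROISet]) -> dict:
    return {
        sid: {
            "no_consensus": rs.no_consensus,
            "rois": [
                dict(roi_id=r.roi_id, min_x=r.min_x, max_x=r.max_x,
                     min_y=r.min_y, max_y=r.max_y, support=r.support,
                     n_cells=r.n_cells)
                for r in rs.rois
            ],
        }
        for sid, rs in sorted(roi_sets.items())
    }


def write_roi_sets(roi_sets: dict[str, DepthROISet], path: str | Path) -> None:
    Path(path).write_text(json.dumps(roi_sets_to_json_dict(roi_sets), indent=2, sort_keys=True) + "\n")


def read_roi_sets(path: str | Path) -> dict[str, DepthROISet]:
    data = json.loads(Path(path).read_text())
    out = {}
    for sid, d in data.items():
        out[sid] = DepthROISet(
            stimulus_id=sid,
            no_consensus=d["no_consensus"],
            rois=[DepthROI(**r) for r in d["rois"]],
        )
    return out


def plot_grid_density(grid: GridCounts, ax=None):
    """Plain response-density heatmap of the localization grid (diagnostic
    only; no algorithmic role). Requires matplotlib."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(grid.counts, cmap="viridis", aspect="auto",
              extent=(0, 1, 1, 0), interpolation="nearest")
    ax.set_xlabel("x (normalized)")
    ax.set_ylabel("y (normalized)")
    ax.set_title(f"depth-localization density: {grid.stimulus_id}")
    return ax
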
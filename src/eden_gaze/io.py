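"""Domain types, table I/O, screen geometry, and trial validity filtering.

Conventions used throughout the package
---------------------------------------
* Pixel coordinates are 0-based with the origin at the top-left of the
  display, x increasing rightward and y increasing downward.
* Time is measured in milliseconds from stimulus onset; windows are
  half-open ``[start, end)`` so bin edges are never double-counted.
* Tracking loss is represented explicitly: an invalid sample keeps its
  timestamp with ``valid=False`` (and NaN coordinates), so the duration of
  missing runs is computable, rather than being silently dropped.

A :class:`GazeTrial` stores its samples as parallel NumPy arrays (one trial
is typically 1,500–9,000 samples); per-sample objects would be wasteful.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidGeometryError

GAZE_COLUMNS = ["participant_id", "stimulus_id", "t_ms", "x_px", "y_px", "valid"]
RATING_COLUMNS = [
    "participant_id",
    "stimulus_id",
    "beauty",
    "liking",
    "composition",
    "color",
    "seen_before",
]
LOCALIZATION_COLUMNS = [
    "participant_id",
    "stimulus_id",
    "point_x_px",
    "point_y_px",
    "distance_km",
    "recognition_time_s",
    "calc_time_s",
]


# ---------------------------------------------------------------------------
# Screen geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display description.

    Parameters
    ----------
    diagonal_in : float
        Display diagonal in inches.
    aspect_w, aspect_h : int
        Aspect ratio terms, e.g. 16 and 9.
    distance_cm : float
        Viewing distance in centimetres.
    res_x_px, res_y_px : int
        Native resolution in pixels.
    """

    diagonal_in: float
    aspect_w: int
    aspect_h: int
    distance_cm: float
    res_x_px: int
    res_y_px: int

    def __post_init__(self) -> None:
        for name in ("diagonal_in", "aspect_w", "aspect_h", "distance_cm",
                     "res_x_px", "res_y_px"):
            if getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be positive")


def physical_extent(geom: ScreenGeometry) -> tuple[float, float]:
    """Physical (width_cm, height_cm) of a display from diagonal and aspect.

    width = 2.54 * diagonal * aspect_w / sqrt(aspect_w^2 + aspect_h^2),
    and analogously for height.
    """
    hyp = math.hypot(geom.aspect_w, geom.aspect_h)
    diag_cm = 2.54 * geom.diagonal_in
    return diag_cm * geom.aspect_w / hyp, diag_cm * geom.aspect_h / hyp


def extent_to_visual_angle(extent_cm: float, distance_cm: float) -> float:
    """Visual angle in degrees subtended by ``extent_cm`` at ``distance_cm``.

    Uses the full (non-small-angle) formula 2*atan(extent / (2*distance)).
    """
    if distance_cm <= 0:
        raise InvalidGeometryError("distance_cm must be positive")
    if extent_cm < 0:
        raise InvalidGeometryError("extent_cm must be nonnegative")
    return math.degrees(2.0 * math.atan2(extent_cm, 2.0 * distance_cm))


def visual_angles(geom: ScreenGeometry) -> tuple[float, float]:
    """Horizontal and vertical visual angle (degrees) of the full display."""
    w_cm, h_cm = physical_extent(geom)
    return (
        extent_to_visual_angle(w_cm, geom.distance_cm),
        extent_to_visual_angle(h_cm, geom.distance_cm),
    )


def pixels_per_degree(geom: ScreenGeometry) -> float:
    """Approximate pixels per degree at screen centre (horizontal)."""
    w_cm, _ = physical_extent(geom)
    cm_per_px = w_cm / geom.res_x_px
    # one degree at the viewing distance
    deg_cm = 2.0 * geom.distance_cm * math.tan(math.radians(0.5))
    return deg_cm / cm_per_px


# ---------------------------------------------------------------------------
# Gaze trials
# ---------------------------------------------------------------------------

@dataclass
class GazeTrial:
    """One participant x stimulus sample sequence.

    ``t_ms``, ``x_px``, ``y_px`` and ``valid`` are parallel arrays; invalid
    samples have NaN coordinates. ``normalized`` is True once coordinates
    have been divided by the stimulus dimensions (unit square).
    """

    participant_id: str
    stimulus_id: str
    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray
    sampling_rate_hz: float
    normalized: bool = False

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t_ms)
        if not (len(self.x_px) == len(self.y_px) == len(self.valid) == n):
            raise ValueError("sample arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.t_ms) > 0):
            raise ValueError("t_ms must be strictly increasing")
        if self.sampling_rate_hz <= 0:
            raise InvalidGeometryError("sampling_rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.t_ms)

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    def valid_segments(self) -> list[slice]:
        """Maximal runs of consecutive valid samples, as index slices."""
        if len(self) == 0:
            return []
        v = self.valid.astype(np.int8)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], v, [0]))))
        return [slice(int(edges[i]), int(edges[i + 1]))
                for i in range(0, len(edges), 2)]

    def is_regular(self, jitter_tol: float = 0.10) -> bool:
        """True if inter-sample intervals match the nominal period within
        the given relative jitter tolerance."""
        if len(self) < 2:
            return True
        dt = np.diff(self.t_ms)
        return bool(np.all(np.abs(dt - self.period_ms) <= jitter_tol * self.period_ms))


def normalize_coordinates(trial: GazeTrial, stim_w_px: float, stim_h_px: float) -> GazeTrial:
    """Return a copy of ``trial`` with coordinates mapped to the unit square.

    x' = x / stim_w, y' = y / stim_h. Invalid samples stay invalid (NaN).
    """
    if stim_w_px <= 0 or stim_h_px <= 0:
        raise InvalidGeometryError("stimulus dimensions must be positive")
    return replace(
        trial,
        x_px=trial.x_px / float(stim_w_px),
        y_px=trial.y_px / float(stim_h_px),
        normalized=True,
    )


def filter_valid_trials(
    trials: Iterable[GazeTrial], max_gap_ms: float = 2000.0
) -> tuple[list[GazeTrial], list[tuple[GazeTrial, str]]]:
    """Partition trials by the continuous-tracking-loss rule.

    A trial is excluded iff it contains a maximal run of invalid samples
    whose duration *strictly exceeds* ``max_gap_ms`` (default 2 s). Run
    duration is the number of invalid samples in the run times the nominal
    sample period. Empty trials are excluded with reason ``"empty"``.

    Returns ``(kept, excluded)`` where ``excluded`` pairs each trial with a
    human-readable reason.
    """
    kept: list[GazeTrial] = []
    excluded: list[tuple[GazeTrial, str]] = []
    for trial in trials:
        if len(trial) == 0:
            excluded.append((trial, "empty"))
            continue
        gap = _longest_invalid_run_ms(trial)
        if gap > max_gap_ms:
            excluded.append((trial, f"missing run of {gap:.0f} ms > {max_gap_ms:.0f} ms"))
        else:
            kept.append(trial)
    return kept, excluded


def _longest_invalid_run_ms(trial: GazeTrial) -> float:
    inv = (~trial.valid).astype(np.int8)
    if not inv.any():
        return 0.0
    edges = np.flatnonzero(np.diff(np.concatenate(([0], inv, [0]))))
    run_lengths = edges[1::2] - edges[0::2]
    return float(run_lengths.max()) * trial.period_ms


# ---------------------------------------------------------------------------
# Optional dispersion-based fixation detection (I-DT)
# ---------------------------------------------------------------------------

def detect_fixations(
    trial: GazeTrial,
    geom: ScreenGeometry,
    dispersion_deg: float = 1.0,
    min_duration_ms: float = 100.0,
) -> pd.DataFrame:
    """Dispersion-threshold (I-DT) fixation detection on raw pixel samples.

    All windowed metrics in this package operate on raw samples; this
    detector exists for fidelity experiments on sample-versus-fixation
    representations. A fixation is a maximal run of valid samples whose
    bounding-box dispersion (width + height) stays below ``dispersion_deg``
    of visual angle and that lasts at least ``min_duration_ms``.

    Returns a DataFrame with columns t_start_ms, t_end_ms, x_px, y_px
    (centroid), n_samples.
    """
    if trial.normalized:
        raise ValueError("fixation detection expects pixel coordinates")
    thresh_px = dispersion_deg * pixels_per_degree(geom)
    rows = []
    for seg in trial.valid_segments():
        t = trial.t_ms[seg]
        x = trial.x_px[seg]
        y = trial.y_px[seg]
        i = 0
        n = len(t)
        while i < n:
            j = i + 1
            while j <= n:
                disp = (x[i:j].max() - x[i:j].min()) + (y[i:j].max() - y[i:j].min())
                if disp > thresh_px:
                    break
                j += 1
            j -= 1  # last index (exclusive) still below threshold
            if j > i:
                dur = t[j - 1] - t[i] + trial.period_ms
                if dur >= min_duration_ms:
                    rows.append(
                        dict(
                            t_start_ms=float(t[i]),
                            t_end_ms=float(t[j - 1] + trial.period_ms),
                            x_px=float(x[i:j].mean()),
                            y_px=float(y[i:j].mean()),
                            n_samples=int(j - i),
                        )
                    )
                i = j
            else:
                i += 1
    return pd.DataFrame(rows, columns=["t_start_ms", "t_end_ms", "x_px", "y_px", "n_samples"])


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def trials_to_frame(trials: Sequence[GazeTrial]) -> pd.DataFrame:
    frames = []
    for tr in trials:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": tr.participant_id,
                    "stimulus_id": tr.stimulus_id,
                    "t_ms": tr.t_ms,
                    "x_px": tr.x_px,
                    "y_px": tr.y_px,
                    "valid": tr.valid,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=GAZE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def frame_to_trials(df: pd.DataFrame, sampling_rate_hz: float) -> list[GazeTrial]:
    trials = []
    for (pid, sid), grp in df.groupby(["participant_id", "stimulus_id"], sort=True):
        grp = grp.sort_values("t_ms")
        trials.append(
            GazeTrial(
                participant_id=str(pid),
                stimulus_id=str(sid),
                t_ms=grp["t_ms"].to_numpy(float),
                x_px=grp["x_px"].to_numpy(float),
                y_px=grp["y_px"].to_numpy(float),
                valid=grp["valid"].to_numpy(bool),
                sampling_rate_hz=sampling_rate_hz,
            )
        )
    return trials


def write_gaze_csv(trials: Sequence[GazeTrial], path: str | Path) -> None:
    trials_to_frame(trials).to_csv(path, index=False, float_format="%.10g")


def read_gaze_csv(path: str | Path, sampling_rate_hz: float) -> list[GazeTrial]:
    df = pd.read_csv(path, dtype={"participant_id": str, "stimulus_id": str})
    return frame_to_trials(df, sampling_rate_hz)


def write_ratings_csv(ratings: pd.DataFrame, path: str | Path) -> None:
    ratings.loc[:, RATING_COLUMNS].to_csv(path, index=False)


def read_ratings_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "stimulus_id": str})
    for col in ("beauty", "liking", "composition", "color"):
        bad = ~df[col].between(1, 10)
        if bad.any():
            raise ValueError(f"{col} outside 1..10 in rows {list(df.index[bad])[:5]}")
    return df


def write_localization_csv(responses: pd.DataFrame, path: str | Path) -> None:
    responses.loc[:, LOCALIZATION_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_localization_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant_id": str, "stimulus_id": str})


def read_stimulus_meta(path: str | Path) -> dict[str, dict]:
    """Read stimulus metadata from YAML or JSON.

    The file holds a list of ``{stimulus_id, width_px, height_px, set_label}``
    mappings; returns a dict keyed by stimulus_id.
    """
    path = Path(path)
    text = path.read_text()
    entries = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    meta = {}
    for e in entries:
        if e.get("width_px", 0) <= 0 or e.get("height_px", 0) <= 0:
            raise InvalidGeometryError(f"nonpositive stimulus dimensions: {e}")
        meta[str(e["stimulus_id"])] = {
            "width_px": int(e["width_px"]),
            "height_px": int(e["height_px"]),
            "set_label": e.get("set_label", "primary"),
        }
    return meta


def write_stimulus_meta(meta: dict[str, dict], path: str | Path) -> None:
    path = Path(path)
    entries = [
        {"stimulus_id": sid, **{k: v for k, v in m.items()}}
        for sid, m in sorted(meta.items())
    ]
    if path.suffix == ".json":
        path.write_text(json.dumps(entries, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(entries, sort_keys=True))
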
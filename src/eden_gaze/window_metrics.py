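"""Time-windowed gaze-state and depth-point engagement metrics.

The 30-s viewing period is segmented two ways: consecutive 3-s bins
(0-3, 3-6, ..., 27-30 s) and cumulative windows growing from onset
(0-3, 0-6, ..., 0-30 s). All windows are half-open ``[start, end)``.

For each trial x window the state-distribution metrics are computed from
the mean posterior ``p`` over in-window valid samples:

    H        = -sum_i p_i * ln(p_i)          (Shannon entropy, nats)
    Hnorm    = H / ln(K)
    MaxP     = max_i p_i
    Neff     = exp(H)                         (effective number of states)
    NeffNorm = Neff / K
    TV       = 0.5 * sum_i |p_i - q_i|        (vs the previous window)
    switch   = fraction of adjacent valid sample pairs whose Viterbi
               states differ

Natural log is used throughout so the identity ``Neff = exp(H)`` holds
exactly and ``Hnorm`` divides by ``ln K``.

Depth-point engagement uses the union of a stimulus's depth ROIs: an
*entry* is a valid inside sample whose previous valid sample was outside
(or the first valid sample of the trial, if inside). Dwell is counted
sample-wise (inside-sample count x sample period); the dwell ratio is
normalised by valid in-window time so tracking loss does not deflate
engagement. First-hit latency is reported on cumulative windows only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .depth_rois import DepthROISet, membership_mask
from .errors import InvalidDistributionError
from .hmm import StateModel, StateSequence, decode
from .io import GazeTrial

METRICS_COLUMNS = [
    "participant_id", "stimulus_id", "window_start_s", "window_end_s",
    "cumulative", "n_samples", "H", "Hnorm", "MaxP", "Neff", "NeffNorm",
    "TV", "switch_rate", "hit_count", "dwell_ms", "dwell_ratio",
    "revisit_count", "mean_dwell_per_visit_ms", "first_hit_ms",
]


@dataclass(frozen=True)
class TimeWindow:
    start_s: float
    end_s: float
    cumulative: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.start_s < self.end_s:
            raise ValueError("window must satisfy 0 <= start < end")
        if self.cumulative and self.start_s != 0:
            raise ValueError("cumulative windows start at 0")


@dataclass
class WindowStateDistribution:
    window: TimeWindow
    p: np.ndarray | None   # None when the window holds no valid samples
    n_samples: int


def tile_windows(
    duration_s: float = 30.0, bin_s: float = 3.0
) -> tuple[list[TimeWindow], list[TimeWindow]]:
    """(binned, cumulative) windows tiling [0, duration) in bin_s steps."""
    n = int(round(duration_s / bin_s))
    binned = [TimeWindow(i * bin_s, (i + 1) * bin_s) for i in range(n)]
    cumulative = [TimeWindow(0.0, (i + 1) * bin_s, cumulative=True) for i in range(n)]
    return binned, cumulative


# ---------------------------------------------------------------------------
# Elementary metric operations
# ---------------------------------------------------------------------------

def state_entropy(p: np.ndarray, K: int) -> tuple[float, float, float, float, float]:
    """(H, Hnorm, MaxP, Neff, NeffNorm) of a state distribution.

    ``p`` must lie on the K-simplex (sum within 1e-6 of 1); 0*log(0) = 0.
    """
    p = np.asarray(p, float)
    if abs(p.sum() - 1.0) > 1e-6 or (p < -1e-12).any():
        raise InvalidDistributionError(f"not a probability vector (sum={p.sum()})")
    pz = p[p > 0]
    H = float(-(pz * np.log(pz)).sum())
    Hnorm = H / math.log(K) if K > 1 else 0.0
    Neff = math.exp(H)
    return H, Hnorm, float(p.max()), Neff, Neff / K


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance 0.5 * L1 between two distributions."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape:
        raise InvalidDistributionError("distributions have different lengths")
    return float(0.5 * np.abs(p - q).sum())


def switch_rate(states: np.ndarray, valid: np.ndarray | None = None) -> float:
    """Fraction of adjacent valid sample pairs with differing states.

    Pairs straddling a tracking-loss gap are not counted; segments on
    either side of a gap contribute their pairs to a pooled rate.
    Returns NaN when no pair exists.
    """
    states = np.asarray(states)
    if valid is None:
        valid = np.ones(len(states), bool)
    pair_ok = valid[:-1] & valid[1:]
    n_pairs = int(pair_ok.sum())
    if n_pairs == 0:
        return float("nan")
    n_switch = int((pair_ok & (states[:-1] != states[1:])).sum())
    return n_switch / n_pairs


def aggregate_window(seq: StateSequence, window: TimeWindow) -> WindowStateDistribution:
    """Mean posterior over the valid samples falling in the window."""
    i0 = int(np.searchsorted(seq.t_ms, window.start_s * 1000.0, "left"))
    i1 = int(np.searchsorted(seq.t_ms, window.end_s * 1000.0, "left"))
    rows = seq.posteriors[i0:i1][seq.valid[i0:i1]]
    if len(rows) == 0:
        return WindowStateDistribution(window, None, 0)
    return WindowStateDistribution(window, rows.mean(axis=0), len(rows))


# ---------------------------------------------------------------------------
# Depth-point engagement
# ---------------------------------------------------------------------------

def entry_flags(trial: GazeTrial, rois: DepthROISet) -> tuple[np.ndarray, np.ndarray]:
    """(inside, entry) boolean arrays over the trial's samples.

    ``inside`` marks valid samples within the union of depth ROIs;
    ``entry`` marks inside samples whose previous *valid* sample was
    outside (the first valid sample counts as an entry if inside).
    """
    inside = membership_mask(trial.x_px, trial.y_px, rois.rois) & trial.valid
    entry = np.zeros(len(trial), bool)
    vidx = np.flatnonzero(trial.valid)
    if len(vidx) == 0:
        return inside, entry
    ins_v = inside[vidx]
    ent_v = ins_v & np.concatenate(([True], ~ins_v[:-1]))
    entry[vidx] = ent_v
    return inside, entry


def dp_engagement(
    trial: GazeTrial, rois: DepthROISet, window: TimeWindow
) -> dict:
    """Depth-point engagement metrics for one trial x window.

    Returns a dict with hit_count, dwell_ms, dwell_ratio, revisit_count,
    mean_dwell_per_visit_ms and first_hit_ms (NaN on binned windows, and
    NaN when the cumulative window contains no entry). An empty ROI set
    yields an all-zero row flagged ``no_rois``.
    """
    if not rois.rois:
        return dict(hit_count=0, dwell_ms=0.0, dwell_ratio=float("nan"),
                    revisit_count=0, mean_dwell_per_visit_ms=float("nan"),
                    first_hit_ms=float("nan"), no_rois=True)
    inside, entry = entry_flags(trial, rois)
    return _engagement_from_flags(trial, inside, entry, window)


def _engagement_from_flags(trial, inside, entry, window) -> dict:
    t = trial.t_ms
    period = trial.period_ms
    i0 = int(np.searchsorted(t, window.start_s * 1000.0, "left"))
    i1 = int(np.searchsorted(t, window.end_s * 1000.0, "left"))
    hit = int(entry[i0:i1].sum())
    n_inside = int(inside[i0:i1].sum())
    n_valid = int(trial.valid[i0:i1].sum())
    dwell = n_inside * period
    ratio = dwell / (n_valid * period) if n_valid > 0 else float("nan")
    first_hit = float("nan")
    if window.cumulative and hit > 0:
        first_hit = float(t[i0:i1][entry[i0:i1]][0])
    return dict(
        hit_count=hit,
        dwell_ms=dwell,
        dwell_ratio=ratio,
        revisit_count=max(hit - 1, 0),
        mean_dwell_per_visit_ms=dwell / hit if hit > 0 else float("nan"),
        first_hit_ms=first_hit,
        no_rois=False,
    )


# ---------------------------------------------------------------------------
# Tidy per-trial table
# ---------------------------------------------------------------------------

def metrics_table(
    trials: Sequence[GazeTrial],
    model: StateModel | None = None,
    roi_sets: dict[str, DepthROISet] | None = None,
    bin_s: float = 3.0,
    duration_s: float = 30.0,
    models: dict[str, StateModel] | None = None,
    sequences: dict[tuple[str, str], StateSequence] | None = None,
) -> pd.DataFrame:
    """One row per trial x window x {binned, cumulative}.

    State metrics come from ``sequences`` if given, else from decoding
    with the per-stimulus ``models`` (or the single ``model``); they are
    NaN when no model is available. DP metrics are NaN-or-zero when
    ``roi_sets`` lacks the stimulus. Row order is deterministic:
    (participant, stimulus, cumulative flag, window start).
    """
    binned, cumulative = tile_windows(duration_s, bin_s)
    rows: list[dict] = []
    for trial in sorted(trials, key=lambda tr: (tr.participant_id, tr.stimulus_id)):
        seq = None
        if sequences is not None:
            seq = sequences.get((trial.participant_id, trial.stimulus_id))
        elif models is not None:
            m = models.get(trial.stimulus_id)
            seq = decode(m, trial) if m is not None else None
        elif model is not None:
            seq = decode(model, trial)
        roi_set = None
        if roi_sets is not None:
            roi_set = roi_sets.get(trial.stimulus_id)
        if roi_set is not None and roi_set.rois:
            inside, entry = entry_flags(trial, roi_set)
        else:
            inside = entry = None
        for windows in (binned, cumulative):
            prev_p = None
            for w in windows:
                row = dict(
                    participant_id=trial.participant_id,
                    stimulus_id=trial.stimulus_id,
                    window_start_s=w.start_s,
                    window_end_s=w.end_s,
                    cumulative=w.cumulative,
                )
                nan = float("nan")
                row.update(dict(n_samples=0, H=nan, Hnorm=nan, MaxP=nan,
                                Neff=nan, NeffNorm=nan, TV=nan, switch_rate=nan))
                if seq is not None:
                    dist = aggregate_window(seq, w)
                    row["n_samples"] = dist.n_samples
                    if dist.p is not None:
                        H, Hn, mp, ne, nen = state_entropy(dist.p, len(dist.p))
                        row.update(dict(H=H, Hnorm=Hn, MaxP=mp, Neff=ne, NeffNorm=nen))
                        if prev_p is not None:
                            row["TV"] = total_variation(dist.p, prev_p)
                        prev_p = dist.p
                    i0 = int(np.searchsorted(trial.t_ms, w.start_s * 1000.0, "left"))
                    i1 = int(np.searchsorted(trial.t_ms, w.end_s * 1000.0, "left"))
                    row["switch_rate"] = switch_rate(
                        seq.viterbi[i0:i1], seq.valid[i0:i1]
                    )
                if inside is not None:
                    row.update({k: v for k, v in
                                _engagement_from_flags(trial, inside, entry, w).items()
                                if k != "no_rois"})
                else:
                    row.update(dict(hit_count=np.nan, dwell_ms=np.nan,
                                    dwell_ratio=np.nan, revisit_count=np.nan,
                                    mean_dwell_per_visit_ms=np.nan,
                                    first_hit_ms=np.nan))
                rows.append(row)
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def cumulative_dwell_table(
    trials: Sequence[GazeTrial],
    roi_sets: dict[str, DepthROISet],
    bin_s: float = 3.0,
    duration_s: float = 30.0,
) -> pd.DataFrame:
    """Fast path: cumulative DP engagement only (no HMM decoding).

    Used for calibration studies where only dwell-based metrics are
    needed; columns match the engagement subset of :func:`metrics_table`.
    """
    _, cumulative = tile_windows(duration_s, bin_s)
    rows = []
    for trial in sorted(trials, key=lambda tr: (tr.participant_id, tr.stimulus_id)):
        roi_set = roi_sets.get(trial.stimulus_id)
        if roi_set is None or not roi_set.rois:
            continue
        inside, entry = entry_flags(trial, roi_set)
        for w in cumulative:
            row = dict(
                participant_id=trial.participant_id,
                stimulus_id=trial.stimulus_id,
                window_start_s=w.start_s,
                window_end_s=w.end_s,
                cumulative=True,
            )
            row.update({k: v for k, v in
                        _engagement_from_flags(trial, inside, entry, w).items()
                        if k != "no_rois"})
            rows.append(row)
    return pd.DataFrame(rows)
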
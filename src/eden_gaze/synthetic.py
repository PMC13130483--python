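"""Synthetic free-viewing data with a known depth-engagement divergence.

The generator emulates the structure the downstream analysis assumes:

* Each trial is a first-order Markov chain over ``k_true`` latent gaze
  states with isotropic Gaussian emissions in unit coordinates, sampled at
  ``rate_hz`` for ``duration_s`` seconds.
* Two viewer cohorts ("high-like" / "low-like") share one transition matrix
  before ``divergence_onset_s``; afterwards the high-like cohort's rows
  receive extra probability mass ``occupancy_boost`` spread over the
  designated depth states and are renormalised. The pre-onset null is
  therefore exact by construction: cohorts differ *only* via transitions
  after onset, never via emissions.
* Depth-localization pointing responses cluster around the true depth-state
  centres; verbal-report timing and subjective distance have cohort-shifted
  lognormal medians.
* Impression ratings carry participant-specific additive bias and
  multiplicative scale so that within-participant normalization has real
  work to do.

A single global seed expands into independent per-trial substreams (keyed
by participant and stimulus index), so any subset of trials is reproducible
on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .io import GazeTrial

_STREAM_LAYOUT = 1
_STREAM_TRIALS = 2
_STREAM_LOCALIZATION = 3
_STREAM_RATINGS = 4


@dataclass
class SynthConfig:
    """Study-scale defaults: 16 participants per cohort, 12 stimuli, 30-s
    trials. 50 Hz is the desk-scale default sampling rate; 300 Hz is
    supported but only changes the time grid."""

    n_participants_per_cohort: int = 16
    n_stimuli: int = 12
    duration_s: float = 30.0
    rate_hz: float = 50.0
    k_true: int = 6
    depth_state_ids: tuple[int, ...] = (0, 1)
    divergence_onset_s: float = 6.0
    occupancy_boost: float = 0.15
    emission_sd: float = 0.05
    missing_rate: float = 0.02
    stay_prob: float = 0.93
    min_state_separation: float = 0.18
    stim_width_px: int = 1920
    stim_height_px: int = 1080
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants_per_cohort < 1 or self.n_stimuli < 1:
            raise InvalidConfigError("counts must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidConfigError("missing_rate must lie in [0, 1)")
        if not 0.0 < self.stay_prob < 1.0:
            raise InvalidConfigError("stay_prob must lie in (0, 1)")
        if not self.depth_state_ids:
            raise InvalidConfigError("depth_state_ids must be nonempty")
        if any(s < 0 or s >= self.k_true for s in self.depth_state_ids):
            raise InvalidConfigError("depth_state_ids out of range")
        if self.emission_sd <= 0 or self.rate_hz <= 0 or self.duration_s <= 0:
            raise InvalidConfigError("emission_sd, rate_hz, duration_s must be positive")
        # boosted rows must remain valid probability rows
        base = _base_transition(self.k_true, self.stay_prob)
        boosted = boost_transition(base, self.depth_state_ids, self.occupancy_boost)
        if (boosted < 0).any():
            raise InvalidConfigError("occupancy_boost makes a transition row negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.rate_hz))

    @property
    def onset_index(self) -> int:
        return int(round(self.divergence_onset_s * self.rate_hz))

    def participant_ids(self) -> tuple[list[str], list[str]]:
        n = self.n_participants_per_cohort
        return ([f"H{i:03d}" for i in range(n)], [f"L{i:03d}" for i in range(n)])

    def stimulus_ids(self) -> list[str]:
        return [f"S{i:02d}" for i in range(self.n_stimuli)]


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    config: SynthConfig
    state_means: dict[str, np.ndarray]          # stimulus_id -> (k_true, 2) unit coords
    state_covs: dict[str, np.ndarray]           # stimulus_id -> (k_true, 2, 2)
    depth_centers_px: dict[str, np.ndarray]     # stimulus_id -> (n_depth, 2) pixels
    cohort: dict[str, str]                      # participant_id -> "high-like"/"low-like"
    transition_base: np.ndarray
    transition_boosted: np.ndarray
    state_paths: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def stimulus_meta(self) -> dict[str, dict]:
        c = self.config
        return {
            sid: {"width_px": c.stim_width_px, "height_px": c.stim_height_px,
                  "set_label": "primary"}
            for sid in self.state_means
        }


def _base_transition(k: int, stay_prob: float) -> np.ndarray:
    if k == 1:
        return np.ones((1, 1))
    off = (1.0 - stay_prob) / (k - 1)
    trans = np.full((k, k), off)
    np.fill_diagonal(trans, stay_prob)
    return trans


def boost_transition(
    base: np.ndarray, depth_state_ids: Sequence[int], boost: float
) -> np.ndarray:
    """Add ``boost`` probability mass (split over depth states) to every row
    and renormalise: row' = (row + boost * spread) / (1 + boost)."""
    k = base.shape[0]
    spread = np.zeros(k)
    spread[list(depth_state_ids)] = 1.0 / len(depth_state_ids)
    out = (base + boost * spread[None, :]) / (1.0 + boost)
    return out


def _place_state_means(rng: np.random.Generator, k: int, min_sep: float) -> np.ndarray:
    """Rejection-sample state centres in [0.15, 0.85]^2 with pairwise
    separation >= min_sep (relaxed if geometrically infeasible)."""
    means: list[np.ndarray] = []
    sep = min_sep
    attempts = 0
    while len(means) < k:
        cand = rng.uniform(0.15, 0.85, size=2)
        if all(np.linalg.norm(cand - m) >= sep for m in means):
            means.append(cand)
        attempts += 1
        if attempts > 2000:
            sep *= 0.8
            attempts = 0
    return np.array(means)


def simulate_trials(config: SynthConfig) -> tuple[list[GazeTrial], GroundTruth]:
    """Simulate all participant x stimulus trials plus ground truth.

    Returns trials in *pixel* coordinates (downstream normalization is part
    of the analysis under test). Fully deterministic for a given config.
    """
    c = config
    k = c.k_true
    rng_layout = np.random.default_rng(np.random.SeedSequence((c.seed, _STREAM_LAYOUT)))
    base = _base_transition(k, c.stay_prob)
    boosted = boost_transition(base, c.depth_state_ids, c.occupancy_boost)
    cum_base = np.cumsum(base, axis=1)
    cum_boost = np.cumsum(boosted, axis=1)

    high_ids, low_ids = c.participant_ids()
    participants = high_ids + low_ids
    is_high = np.array([True] * len(high_ids) + [False] * len(low_ids))
    cohort = {pid: ("high-like" if h else "low-like")
              for pid, h in zip(participants, is_high)}

    state_means: dict[str, np.ndarray] = {}
    state_covs: dict[str, np.ndarray] = {}
    depth_centers: dict[str, np.ndarray] = {}
    for sid in c.stimulus_ids():
        means = _place_state_means(rng_layout, k, c.min_state_separation)
        state_means[sid] = means
        state_covs[sid] = np.tile((c.emission_sd ** 2) * np.eye(2), (k, 1, 1))
        depth_centers[sid] = means[list(c.depth_state_ids)] * np.array(
            [c.stim_width_px, c.stim_height_px], float
        )

    gt = GroundTruth(
        config=c,
        state_means=state_means,
        state_covs=state_covs,
        depth_centers_px=depth_centers,
        cohort=cohort,
        transition_base=base,
        transition_boosted=boosted,
    )

    T = c.n_samples
    onset = c.onset_index
    t_ms = np.arange(T) * (1000.0 / c.rate_hz)
    n_tr = len(participants)
    dims = np.array([c.stim_width_px, c.stim_height_px], float)

    trials: list[GazeTrial] = []
    for s_idx, sid in enumerate(c.stimulus_ids()):
        # per-trial substreams, drawn in a fixed order so any subset of
        # trials is reproducible independently of the rest
        u_state = np.empty((n_tr, T))
        z_emit = np.empty((n_tr, T, 2))
        u_miss = np.empty((n_tr, T))
        for p_idx in range(n_tr):
            rng = np.random.default_rng(
                np.random.SeedSequence((c.seed, _STREAM_TRIALS, p_idx, s_idx))
            )
            u_state[p_idx] = rng.random(T)
            z_emit[p_idx] = rng.standard_normal((T, 2))
            u_miss[p_idx] = rng.random(T)

        # vectorised time-inhomogeneous Markov chain across trials
        states = np.empty((n_tr, T), dtype=np.int32)
        states[:, 0] = np.minimum((u_state[:, 0] * k).astype(np.int32), k - 1)
        for t in range(1, T):
            prev = states[:, t - 1]
            cum = cum_base[prev]
            if t >= onset and is_high.any():
                cum = np.where(is_high[:, None], cum_boost[prev], cum)
            states[:, t] = (cum < u_state[:, t, None]).sum(axis=1)

        means = state_means[sid]
        xy = means[states] + c.emission_sd * z_emit  # (n_tr, T, 2) unit coords
        np.clip(xy, 0.0, 1.0 - 1e-9, out=xy)
        xy_px = xy * dims

        valid = u_miss >= c.missing_rate
        for p_idx, pid in enumerate(participants):
            x = xy_px[p_idx, :, 0].copy()
            y = xy_px[p_idx, :, 1].copy()
            x[~valid[p_idx]] = np.nan
            y[~valid[p_idx]] = np.nan
            trials.append(
                GazeTrial(
                    participant_id=pid,
                    stimulus_id=sid,
                    t_ms=t_ms.copy(),
                    x_px=x,
                    y_px=y,
                    valid=valid[p_idx].copy(),
                    sampling_rate_hz=c.rate_hz,
                )
            )
            gt.state_paths[(pid, sid)] = states[p_idx].copy()
    return trials, gt


def simulate_localization(
    ground_truth: GroundTruth,
    pointing_sd_px: float = 20.0,
    seed: int = 0,
    recognition_median_s: tuple[float, float] = (3.0, 4.5),
    calc_median_s: tuple[float, float] = (5.0, 5.0),
    distance_median_km: tuple[float, float] = (40.0, 14.0),
    time_sigma: float = 0.4,
    distance_sigma: float = 0.9,
) -> pd.DataFrame:
    """One depth-localization response per participant x stimulus.

    The pointed location is a true depth-point centre plus isotropic
    Gaussian noise, clipped to the image. ``(high-like, low-like)`` median
    pairs control the cohort-shifted lognormal report-timing and subjective
    distance distributions; the high-like cohort recognises depth points
    faster and reports larger subjective distances.
    """
    if pointing_sd_px < 0:
        raise InvalidConfigError("pointing_sd_px must be nonnegative")
    c = ground_truth.config
    participants = sorted(ground_truth.cohort)
    stimuli = sorted(ground_truth.depth_centers_px)
    rows = []
    for p_idx, pid in enumerate(participants):
        hi = ground_truth.cohort[pid] == "high-like"
        for s_idx, sid in enumerate(stimuli):
            rng = np.random.default_rng(
                np.random.SeedSequence((seed, _STREAM_LOCALIZATION, p_idx, s_idx))
            )
            centers = ground_truth.depth_centers_px[sid]
            center = centers[rng.integers(len(centers))]
            pt = center + pointing_sd_px * rng.standard_normal(2)
            pt[0] = np.clip(pt[0], 0.0, c.stim_width_px - 1e-6)
            pt[1] = np.clip(pt[1], 0.0, c.stim_height_px - 1e-6)
            rec_med = recognition_median_s[0] if hi else recognition_median_s[1]
            cal_med = calc_median_s[0] if hi else calc_median_s[1]
            dist_med = distance_median_km[0] if hi else distance_median_km[1]
            rows.append(
                dict(
                    participant_id=pid,
                    stimulus_id=sid,
                    point_x_px=float(pt[0]),
                    point_y_px=float(pt[1]),
                    distance_km=float(dist_med * np.exp(distance_sigma * rng.standard_normal())),
                    recognition_time_s=float(rec_med * np.exp(time_sigma * rng.standard_normal())),
                    calc_time_s=float(cal_med * np.exp(time_sigma * rng.standard_normal())),
                )
            )
    return pd.DataFrame(rows)


def simulate_ratings(
    ground_truth: GroundTruth,
    participant_bias_sd: float = 1.5,
    seed: int = 0,
    cohort_delta: float = 1.2,
    noise_sd: float = 0.7,
    scale_sd: float = 0.25,
    dim_noise_sd: float = 0.4,
) -> pd.DataFrame:
    """10-point impression ratings on four correlated dimensions.

    Latent appreciation per trial = cohort effect (+/- cohort_delta/2)
    + per-trial noise; each participant applies an additive bias and a
    multiplicative scale before the latent value is discretised to 1..10
    on each dimension (with small per-dimension noise, so the four
    dimensions correlate through the shared latent). Raw scores are thus
    deliberately incomparable across participants.
    """
    participants = sorted(ground_truth.cohort)
    stimuli = sorted(ground_truth.state_means)
    rows = []
    dims = ("beauty", "liking", "composition", "color")
    for p_idx, pid in enumerate(participants):
        prng = np.random.default_rng(
            np.random.SeedSequence((seed, _STREAM_RATINGS, p_idx))
        )
        bias = participant_bias_sd * prng.standard_normal()
        scale = float(np.exp(scale_sd * prng.standard_normal()))
        effect = cohort_delta / 2.0 * (1 if ground_truth.cohort[pid] == "high-like" else -1)
        for s_idx, sid in enumerate(stimuli):
            rng = np.random.default_rng(
                np.random.SeedSequence((seed, _STREAM_RATINGS, p_idx, s_idx))
            )
            latent = effect + noise_sd * rng.standard_normal()
            rec: dict = dict(participant_id=pid, stimulus_id=sid)
            for d in dims:
                v = scale * (latent + dim_noise_sd * rng.standard_normal()) + bias
                rec[d] = int(np.clip(np.rint(5.5 + v), 1, 10))
            rec["seen_before"] = bool(rng.random() < 0.1)
            rows.append(rec)
    return pd.DataFrame(rows)


def ground_truth_to_json_dict(gt: GroundTruth) -> dict:
    """JSON-serialisable snapshot of the ground truth (for run artifacts)."""
    return {
        "cohort": gt.cohort,
        "transition_base": gt.transition_base.tolist(),
        "transition_boosted": gt.transition_boosted.tolist(),
        "state_means": {sid: m.tolist() for sid, m in gt.state_means.items()},
        "state_covs": {sid: cv.tolist() for sid, cv in gt.state_covs.items()},
        "depth_centers_px": {sid: d.tolist() for sid, d in gt.depth_centers_px.items()},
    }
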
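"""Constrained Gaussian-emission HMMs over normalized gaze coordinates.

One model is fitted per stimulus on the pooled sequences of *all*
participants (both later-compared groups), which avoids circularity when
groups are contrasted downstream. Each of the K states is a 2-D Gaussian
"gaze region"; EM re-applies two constraints after every M-step:

* **area clamp** — the 2-SD ellipse area ``A_k = 4 * pi * sqrt(det(Sigma_k))``
  is kept within configurable bounds (default 0.1%-5% of the unit image)
  by isotropic rescaling of the covariance;
* **axis clamp** — each principal-axis length (sqrt of an eigenvalue) is
  kept within mean +/- N standard deviations of the axis lengths pooled
  across states (default N = 2).

Clamping can reduce the EM objective, so likelihood monotonicity is only
guaranteed between iterations where no clamp fired; every clamp event is
logged on the fitted model.

Tracking-loss gaps split a trial into independent valid segments: no
transition is counted (or decoded) across a gap. Because a pooled fit
involves hundreds to thousands of short segments, the E-step runs in a
packed time-major layout (segments sorted by length, the recursion
vectorised across all segments active at each time step), which keeps the
per-iteration cost at O(T_total * K^2) NumPy work instead of a Python
loop over segments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import kmeans_plusplus

from .errors import InsufficientDataError, InvalidConfigError
from .io import GazeTrial

_EIG_FLOOR = 1e-10
_AXIS_FLOOR = 1e-6
_INIT_VAR = 9e-4  # isotropic init variance; ellipse area ~1.1% of image
_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Covariance constraints
# ---------------------------------------------------------------------------

def ellipse_area(cov: np.ndarray) -> float:
    """Area of the 2-SD ellipse of a 2x2 covariance: 4*pi*sqrt(det)."""
    return float(4.0 * np.pi * np.sqrt(max(np.linalg.det(cov), 0.0)))


def clamp_covariances(
    covs: np.ndarray,
    area_bounds: tuple[float, float] = (0.001, 0.05),
    axis_clamp_sd: float = 2.0,
) -> tuple[np.ndarray, int, int]:
    """Apply the area and axis constraints to a stack of 2x2 covariances.

    Returns (clamped covariances, #area clamps fired, #axis clamps fired).
    """
    lo_a, hi_a = area_bounds
    if not 0 < lo_a < hi_a:
        raise InvalidConfigError("area bounds must satisfy 0 < lo < hi")
    covs = np.array(covs, dtype=float)
    K = covs.shape[0]
    n_area = 0
    eigw = np.empty((K, 2))
    eigv = np.empty((K, 2, 2))
    for k in range(K):
        c = 0.5 * (covs[k] + covs[k].T)
        w, v = np.linalg.eigh(c)
        w = np.maximum(w, _EIG_FLOOR)
        area = 4.0 * np.pi * np.sqrt(w[0] * w[1])
        target = min(max(area, lo_a), hi_a)
        if target != area:
            w = w * (target / area)  # isotropic rescale: area scales linearly
            n_area += 1
        eigw[k] = w
        eigv[k] = v
    lengths = np.sqrt(eigw)  # principal-axis lengths, pooled across states
    mean_len = lengths.mean()
    sd_len = lengths.std()
    lo_l = max(mean_len - axis_clamp_sd * sd_len, _AXIS_FLOOR)
    hi_l = mean_len + axis_clamp_sd * sd_len
    clipped = np.clip(lengths, lo_l, hi_l)
    n_axis = int((clipped != lengths).sum())
    for k in range(K):
        covs[k] = (eigv[k] * (clipped[k] ** 2)) @ eigv[k].T
        covs[k] = 0.5 * (covs[k] + covs[k].T)
    return covs, n_area, n_axis


# ---------------------------------------------------------------------------
# Public model containers
# ---------------------------------------------------------------------------

@dataclass
class StateModel:
    """Fitted K-state model in unit coordinates."""

    K: int
    means: np.ndarray            # (K, 2)
    covariances: np.ndarray      # (K, 2, 2)
    transition: np.ndarray       # (K, K) row-stochastic
    initial: np.ndarray          # (K,)
    log_likelihood: float
    n_restarts_used: int
    seed: int
    converged: bool = True
    clamp_events: int = 0

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, float).reshape(self.K, 2)
        self.covariances = np.asarray(self.covariances, float).reshape(self.K, 2, 2)
        self.transition = np.asarray(self.transition, float).reshape(self.K, self.K)
        self.initial = np.asarray(self.initial, float).reshape(self.K)

    def to_json_dict(self) -> dict:
        return {
            "K": self.K,
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "transition": self.transition.tolist(),
            "initial": self.initial.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_restarts_used": self.n_restarts_used,
            "seed": self.seed,
            "converged": self.converged,
            "clamp_events": self.clamp_events,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "StateModel":
        return cls(**{k: d[k] for k in (
            "K", "means", "covariances", "transition", "initial",
            "log_likelihood", "n_restarts_used", "seed", "converged",
            "clamp_events")})


def write_model(model: StateModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_json_dict(), indent=2) + "\n")


def read_model(path: str | Path) -> StateModel:
    return StateModel.from_json_dict(json.loads(Path(path).read_text()))


@dataclass
class StateSequence:
    """Per-trial decoding: posteriors and Viterbi path aligned to samples.

    Invalid samples carry NaN posterior rows and Viterbi state -1; each
    maximal run of valid samples was decoded as an independent sequence.
    """

    participant_id: str
    stimulus_id: str
    t_ms: np.ndarray
    valid: np.ndarray
    posteriors: np.ndarray       # (T, K), NaN rows where invalid
    viterbi: np.ndarray          # (T,), -1 where invalid

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def empty(self) -> bool:
        return self.n_valid == 0


# ---------------------------------------------------------------------------
# Gaussian emission log-densities
# ---------------------------------------------------------------------------

def _log_gaussian(X: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """(N, K) log-density of 2-D points under each state's Gaussian."""
    N = len(X)
    K = len(means)
    out = np.empty((N, K))
    for k in range(K):
        a, b = covs[k, 0, 0], covs[k, 0, 1]
        c = covs[k, 1, 1]
        det = a * c - b * b
        dx = X[:, 0] - means[k, 0]
        dy = X[:, 1] - means[k, 1]
        quad = (c * dx * dx - 2.0 * b * dx * dy + a * dy * dy) / det
        out[:, k] = -_LOG2PI - 0.5 * math.log(det) - 0.5 * quad
    return out


# ---------------------------------------------------------------------------
# Packed time-major E-step over many segments
# ---------------------------------------------------------------------------

class _PackedSegments:
    """Samples of all segments reordered to (time step, segment-rank) order.

    Segments are sorted by length descending, so at every time step the
    active segments form a prefix of the sorted order; the forward and
    backward recursions then act on contiguous array slices.
    """

    def __init__(self, X: np.ndarray, lengths: Sequence[int]):
        lengths = np.asarray(lengths, int)
        self.n_segments = len(lengths)
        self.order = np.argsort(-lengths, kind="stable")
        sorted_len = lengths[self.order]
        starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
        starts_sorted = starts[self.order]
        L = int(sorted_len[0]) if self.n_segments else 0
        # number of segments still active at each time step
        self.n_active = np.searchsorted(-sorted_len, -np.arange(1, L + 1),
                                        side="right")
        idx_chunks = [starts_sorted[: self.n_active[t]] + t for t in range(L)]
        self.packed_idx = (np.concatenate(idx_chunks) if idx_chunks
                           else np.empty(0, int))
        self.offsets = np.concatenate(([0], np.cumsum(self.n_active)))
        self.L = L
        self.X_packed = X[self.packed_idx]

    def estep(self, logB_packed, pi, A):
        """Scaled forward-backward over all segments at once.

        Returns (loglik, gamma_packed, xi_sum, gamma0_sum) where
        gamma_packed aligns with the packed sample order.
        """
        N, K = logB_packed.shape
        m = logB_packed.max(axis=1)
        P = np.exp(logB_packed - m[:, None])
        alpha = np.empty((N, K))
        logc_sum = 0.0
        off = self.offsets
        # forward
        a0 = pi[None, :] * P[off[0]:off[1]]
        c0 = a0.sum(axis=1)
        alpha[off[0]:off[1]] = a0 / c0[:, None]
        logc_sum += np.log(c0).sum()
        for t in range(1, self.L):
            n = self.n_active[t]
            prev = alpha[off[t - 1]: off[t - 1] + n]
            a = (prev @ A) * P[off[t]: off[t + 1]]
            c = a.sum(axis=1)
            alpha[off[t]: off[t + 1]] = a / c[:, None]
            logc_sum += np.log(c).sum()
        loglik = float(logc_sum + m.sum())
        # backward, accumulating gamma and xi
        gamma = np.empty((N, K))
        xi_sum = np.zeros((K, K))
        beta = np.ones((self.n_segments, K))
        # at the last time step of each segment beta = 1; segments whose
        # last index is t enter the recursion as t decreases
        t = self.L - 1
        n = self.n_active[t]
        gamma[off[t]: off[t + 1]] = alpha[off[t]: off[t + 1]] * beta[:n]
        for t in range(self.L - 2, -1, -1):
            n_next = self.n_active[t + 1]
            n = self.n_active[t]
            Pn = P[off[t + 1]: off[t + 2]]
            cn = (alpha[off[t]: off[t] + n_next] @ A * Pn).sum(axis=1)
            E = Pn * beta[:n_next] / cn[:, None]
            xi_sum += A * (alpha[off[t]: off[t] + n_next].T @ E)
            beta[:n_next] = E @ A.T
            beta[n_next:n] = 1.0  # segments ending exactly at t
            gamma[off[t]: off[t + 1]] = alpha[off[t]: off[t + 1]] * beta[:n]
        gamma0_sum = gamma[off[0]: off[1]].sum(axis=0)
        return loglik, gamma, xi_sum, gamma0_sum


def _em_fit(
    X: np.ndarray,
    lengths: Sequence[int],
    pi: np.ndarray,
    A: np.ndarray,
    means: np.ndarray,
    covs: np.ndarray,
    max_iter: int,
    tol: float,
    area_bounds: tuple[float, float],
    axis_clamp_sd: float,
    constrain: bool,
):
    """Run constrained EM from the given initial parameters.

    Convergence: relative log-likelihood change below ``tol``. Returns
    (pi, A, means, covs, loglik, converged, clamp_log) where clamp_log
    lists per-iteration clamp counts.
    """
    packed = _PackedSegments(X, lengths)
    K = len(means)
    Xp = packed.X_packed
    clamp_log: list[dict] = []
    prev_ll = -np.inf
    converged = False
    loglik = -np.inf
    for _ in range(max_iter):
        logB = _log_gaussian(Xp, means, covs)
        loglik, gamma, xi_sum, gamma0 = packed.estep(logB, pi, A)
        # M-step; states with (near-)zero responsibility keep their params
        counts = gamma.sum(axis=0)
        occupied = counts > 1e-6
        safe = np.maximum(counts, 1e-300)
        new_means = (gamma.T @ Xp) / safe[:, None]
        new_covs = np.empty_like(covs)
        for k in range(K):
            if not occupied[k]:
                new_means[k] = means[k]
                new_covs[k] = covs[k]
                continue
            d = Xp - new_means[k]
            wd = gamma[:, k][:, None] * d
            new_covs[k] = (wd.T @ d) / safe[k] + 1e-12 * np.eye(2)
        means = new_means
        covs = new_covs
        if constrain:
            covs, n_area, n_axis = clamp_covariances(covs, area_bounds, axis_clamp_sd)
            if n_area or n_axis:
                clamp_log.append({"area": n_area, "axis": n_axis})
        row = xi_sum.sum(axis=1)
        A = np.where(row[:, None] > 0, xi_sum / np.maximum(row, 1e-300)[:, None],
                     1.0 / K)
        pi = gamma0 / gamma0.sum()
        if abs(loglik - prev_ll) < tol * max(1.0, abs(loglik)):
            converged = True
            break
        prev_ll = loglik
    # score once more under the final (clamped) parameters
    logB = _log_gaussian(Xp, means, covs)
    loglik = packed.estep(logB, pi, A)[0]
    return pi, A, means, covs, loglik, converged, clamp_log


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def pooled_valid_segments(trials: Sequence[GazeTrial]) -> tuple[np.ndarray, list[int]]:
    """Concatenate the valid segments of all trials into (X, lengths)."""
    chunks: list[np.ndarray] = []
    lengths: list[int] = []
    for tr in trials:
        if not tr.normalized:
            raise InvalidConfigError("trials must be normalized before fitting")
        for seg in tr.valid_segments():
            chunks.append(np.column_stack((tr.x_px[seg], tr.y_px[seg])))
            lengths.append(seg.stop - seg.start)
    if not chunks:
        return np.empty((0, 2)), []
    return np.concatenate(chunks, axis=0), lengths


def fit_model(
    trials: Sequence[GazeTrial],
    K: int = 14,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    area_bounds: tuple[float, float] = (0.001, 0.05),
    axis_clamp_sd: float = 2.0,
    seed: int = 0,
    constrain: bool = True,
) -> StateModel:
    """EM fit over pooled per-trial sequences, best of ``n_restarts``.

    Each restart initialises means by k-means++ on the pooled samples,
    an isotropic covariance, and uniform initial/transition rows mixed
    with Dirichlet(1) jitter; all randomness derives from ``seed`` so two
    identical calls return identical models. Restarts are compared by
    the log-likelihood of the final (constrained) parameters.
    """
    X, lengths = pooled_valid_segments(trials)
    if len(X) < K:
        raise InsufficientDataError(f"{len(X)} valid samples < K={K}; cannot fit")
    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence((seed, r)))
        centers, _ = kmeans_plusplus(
            X, n_clusters=K, random_state=int(rng.integers(2**31 - 1))
        )
        pi0 = _jittered_uniform(rng, K)
        A0 = np.vstack([_jittered_uniform(rng, K) for _ in range(K)])
        covs0 = np.tile(_INIT_VAR * np.eye(2), (K, 1, 1))
        result = _em_fit(
            X, lengths, pi0, A0, centers.astype(float), covs0,
            max_iter=max_iter, tol=tol, area_bounds=area_bounds,
            axis_clamp_sd=axis_clamp_sd, constrain=constrain,
        )
        if best is None or result[4] > best[4]:
            best = result
    pi, A, means, covs, ll, converged, clamp_log = best
    return StateModel(
        K=K,
        means=means,
        covariances=covs,
        transition=A,
        initial=pi,
        log_likelihood=ll,
        n_restarts_used=n_restarts,
        seed=seed,
        converged=converged,
        clamp_events=int(sum(e["area"] + e["axis"] for e in clamp_log)),
    )


def _jittered_uniform(rng: np.random.Generator, K: int) -> np.ndarray:
    row = 0.5 * np.full(K, 1.0 / K) + 0.5 * rng.dirichlet(np.ones(K))
    return row / row.sum()


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def _segment_posteriors(logB: np.ndarray, pi: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Scaled forward-backward posteriors for one contiguous segment."""
    T, K = logB.shape
    m = logB.max(axis=1)
    P = np.exp(logB - m[:, None])
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi * P[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * P[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (P[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    return gamma / gamma.sum(axis=1, keepdims=True)


def _segment_viterbi(logB: np.ndarray, pi: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Most likely state path for one contiguous segment (log-space DP)."""
    T, K = logB.shape
    with np.errstate(divide="ignore"):
        logA = np.log(A)
        logpi = np.log(pi)
    delta = logpi + logB[0]
    back = np.empty((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def decode(model: StateModel, trial: GazeTrial) -> StateSequence:
    """Forward-backward posteriors and Viterbi path for one trial.

    Valid segments are decoded independently (the chain restarts at
    ``initial`` after every gap); invalid samples get NaN posteriors and
    Viterbi state -1. A trial without valid samples decodes to an empty
    (all-NaN / all -1) sequence.
    """
    if not trial.normalized:
        raise InvalidConfigError("trial must be normalized before decoding")
    T = len(trial)
    posteriors = np.full((T, model.K), np.nan)
    viterbi = np.full(T, -1, dtype=int)
    for seg in trial.valid_segments():
        Xseg = np.column_stack((trial.x_px[seg], trial.y_px[seg]))
        logB = _log_gaussian(Xseg, model.means, model.covariances)
        posteriors[seg] = _segment_posteriors(logB, model.initial, model.transition)
        viterbi[seg] = _segment_viterbi(logB, model.initial, model.transition)
    return StateSequence(
        participant_id=trial.participant_id,
        stimulus_id=trial.stimulus_id,
        t_ms=trial.t_ms.copy(),
        valid=trial.valid.copy(),
        posteriors=posteriors,
        viterbi=viterbi,
    )


def model_selection_curve(
    trials: Sequence[GazeTrial],
    K_values: Sequence[int],
    seed: int = 0,
    n_restarts: int = 5,
    **fit_kwargs,
):
    """Best-restart log-likelihood per K (the saturation diagnostic).

    Documents how likelihood gains flatten as states are added; it does
    not auto-select K. Returns a pandas DataFrame with columns
    ``K`` and ``log_likelihood``.
    """
    import pandas as pd

    if list(K_values) != sorted(K_values):
        raise InvalidConfigError("K_values must be sorted ascending")
    rows = []
    for K in K_values:
        m = fit_model(trials, K=K, n_restarts=n_restarts, seed=seed, **fit_kwargs)
        rows.append({"K": K, "log_likelihood": m.log_likelihood})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def match_states(
    true_means: np.ndarray, est_means: np.ndarray
) -> tuple[np.ndarray, float]:
    """Optimal one-to-one state matching by mean location (Hungarian).

    Returns (permutation mapping true index -> estimated index, mean
    Euclidean distance over matched pairs).
    """
    cost = np.linalg.norm(true_means[:, None, :] - est_means[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    return cols, float(cost[rows, cols].mean())


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    w, v = np.linalg.eig(transition.T)
    idx = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()
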
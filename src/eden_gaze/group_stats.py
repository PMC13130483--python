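"""Rating normalization, evaluation-group assignment, and group contrasts.

Impression ratings are z-scored *within participant* (separately per
stimulus set) before any grouping, because raw 10-point scores carry
participant-specific bias and scale. Per artwork, participants are split
into high / medium / low tertiles of the normalized composite rating;
the medium tertile is excluded from two-group contrasts.

Contrasts are nonparametric: Wilcoxon signed-rank for paired designs with
the rank-biserial effect size r_rb = (W+ - W-) / (W+ + W-), and
Mann-Whitney for between designs with r = 2U/(n1*n2) - 1. The signed-rank
null distribution is computed exactly (tie-aware, by dynamic programming
over doubled midranks) up to n = 25 pairs and by the tie-corrected normal
approximation beyond. Welch's t with Satterthwaite df and Cohen's d (with
a normal-approximation CI) covers the interval-scale localization
measures, and small power-planning utilities round out the module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import GroupingError, InvalidConfigError

RATING_DIMENSIONS = ("beauty", "liking", "composition", "color")

EXACT_SIGNRANK_MAX_N = 25


# ---------------------------------------------------------------------------
# Normalization and grouping
# ---------------------------------------------------------------------------

def normalize_ratings(
    ratings: pd.DataFrame,
    dimensions: tuple[str, ...] = RATING_DIMENSIONS,
    set_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Within-participant z-scores of the composite rating.

    The composite is the mean of ``dimensions`` (default: all four 10-point
    scales). z = (composite - participant mean) / participant SD with the
    n-1 denominator, computed separately per stimulus set when
    ``set_labels`` (stimulus_id -> set label) is given. A participant with
    zero SD gets NaN z-scores and ``degenerate=True``.

    Returns the input columns plus ``composite``, ``z`` and ``degenerate``.
    """
    df = ratings.copy()
    df["composite"] = df[list(dimensions)].mean(axis=1)
    df["set_label"] = (
        df["stimulus_id"].map(set_labels) if set_labels is not None else "all"
    )
    grp = df.groupby(["participant_id", "set_label"])["composite"]
    mean = grp.transform("mean")
    sd = grp.transform("std")  # ddof=1
    df["z"] = (df["composite"] - mean) / sd
    df["degenerate"] = ~np.isfinite(df["z"])
    counts = df.groupby(["participant_id", "set_label"]).size()
    if (counts < 2).any():
        raise GroupingError("every participant must rate >= 2 stimuli per set")
    return df


def assign_groups(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-stimulus tertile split of participants by normalized rating.

    Within each stimulus, participants are ranked by z (ties broken by
    participant_id order, so assignment is deterministic); the top third
    is ``high``, the bottom third ``low``, the remainder ``medium``.
    48 participants yield 16/16/16.
    """
    rows = []
    for sid, grp in normalized.groupby("stimulus_id", sort=True):
        grp = grp.dropna(subset=["z"])
        n = len(grp)
        if n < 3:
            raise GroupingError(f"stimulus {sid}: {n} participants < 3")
        n_side = n // 3
        order = grp.sort_values(
            ["z", "participant_id"], ascending=[False, True]
        ).reset_index(drop=True)
        group = np.array(["medium"] * n, dtype=object)
        group[:n_side] = "high"
        group[n - n_side:] = "low"
        for i, rec in order.iterrows():
            rows.append(
                dict(
                    participant_id=rec["participant_id"],
                    stimulus_id=rec["stimulus_id"],
                    normalized_rating=rec["z"],
                    group=group[i],
                )
            )
    return pd.DataFrame(rows)


def cohort_assignments(cohort: dict[str, str], stimulus_ids) -> pd.DataFrame:
    """Assignment table from known cohort labels (synthetic ground truth).

    Maps "high-like" -> high and "low-like" -> low for every stimulus, so
    generator cohorts can stand in for rating-derived evaluation groups.
    """
    rows = [
        dict(participant_id=pid, stimulus_id=sid,
             normalized_rating=np.nan,
             group="high" if lab == "high-like" else "low")
        for pid, lab in sorted(cohort.items())
        for sid in stimulus_ids
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank with exact tie-aware null
# ---------------------------------------------------------------------------

@dataclass
class PairedComparison:
    metric: str
    n_paired: int
    median_high: float
    median_low: float
    median_diff: float
    p_signrank: float
    r_rank_biserial: float
    undefined: bool = False


def signed_rank_statistics(diffs: np.ndarray) -> tuple[float, float, np.ndarray]:
    """(W+, W-, midranks of |d|) after dropping zero differences."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    if len(d) == 0:
        return 0.0, 0.0, np.empty(0)
    ranks = sps.rankdata(np.abs(d))  # midranks for ties
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    return w_pos, w_neg, ranks


def _exact_signrank_p(ranks: np.ndarray, w_pos: float) -> float:
    """Exact two-sided p for W+ under the sign-flip null, ties allowed.

    Works on doubled midranks (integers); convolves the +-rank generating
    function, then doubles the smaller tail (capped at 1). The null is
    symmetric about sum(ranks)/2 even with ties, so tail doubling is exact.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    w2 = int(round(2.0 * w_pos))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _approx_signrank_p(ranks: np.ndarray, w_pos: float) -> float:
    """Tie-corrected normal approximation for the signed-rank test."""
    n = len(ranks)
    mu = n * (n + 1) / 4.0
    # variance with tie correction: subtract sum(t^3 - t)/48 over tie groups
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((counts**3 - counts).sum()) / 48.0
    if var <= 0:
        return 1.0
    z = (w_pos - mu) / math.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def paired_signed_rank(
    values_high: np.ndarray, values_low: np.ndarray, metric: str = ""
) -> PairedComparison:
    """Wilcoxon signed-rank contrast of paired per-participant values.

    Zero differences are dropped (Wilcoxon convention). The rank-biserial
    effect size is r_rb = (W+ - W-) / (W+ + W-). Exact p up to
    ``EXACT_SIGNRANK_MAX_N`` nonzero pairs, tie-corrected normal
    approximation above. All-zero differences yield an undefined result
    (flagged, not raised).
    """
    hi = np.asarray(values_high, float)
    lo = np.asarray(values_low, float)
    if hi.shape != lo.shape:
        raise InvalidConfigError("paired vectors must have equal length")
    diffs = hi - lo
    w_pos, w_neg, ranks = signed_rank_statistics(diffs)
    base = dict(
        metric=metric,
        n_paired=len(diffs),
        median_high=float(np.median(hi)),
        median_low=float(np.median(lo)),
        median_diff=float(np.median(diffs)),
    )
    if len(ranks) == 0:
        return PairedComparison(**base, p_signrank=float("nan"),
                                r_rank_biserial=float("nan"), undefined=True)
    r_rb = (w_pos - w_neg) / (w_pos + w_neg)
    if len(ranks) <= EXACT_SIGNRANK_MAX_N:
        p = _exact_signrank_p(ranks, w_pos)
    else:
        p = _approx_signrank_p(ranks, w_pos)
    return PairedComparison(**base, p_signrank=p, r_rank_biserial=float(r_rb))


# ---------------------------------------------------------------------------
# Mann-Whitney (between groups)
# ---------------------------------------------------------------------------

def mann_whitney_rb(high: np.ndarray, low: np.ndarray) -> tuple[float, float, float]:
    """(U1, p, rank-biserial r) for a two-sample rank contrast.

    r = 2*U1/(n1*n2) - 1, positive when ``high`` tends to exceed ``low``.

    The asymptotic p-value omits the continuity correction so the test is
    calibrated at its nominal level for the window-wise trial counts used
    here (with the correction it is noticeably conservative).
    """
    high = np.asarray(high, float)
    low = np.asarray(low, float)
    res = sps.mannwhitneyu(high, low, alternative="two-sided",
                           use_continuity=False)
    n1, n2 = len(high), len(low)
    r = 2.0 * res.statistic / (n1 * n2) - 1.0
    return float(res.statistic), float(res.pvalue), float(r)


# ---------------------------------------------------------------------------
# Welch t and effect-size utilities
# ---------------------------------------------------------------------------

@dataclass
class TwoSampleResult:
    metric: str
    n_high: int
    n_low: int
    mean_high: float
    mean_low: float
    t: float
    df: float
    p: float
    cohens_d: float
    d_ci_low: float
    d_ci_high: float
    undefined: bool = False


def welch_test(high: np.ndarray, low: np.ndarray, metric: str = "") -> TwoSampleResult:
    """Welch's t with Satterthwaite df, plus Cohen's d and its 95% CI.

    d uses the pooled SD sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)); the
    CI uses the normal-approximation standard error
    SE(d) = sqrt((n1+n2)/(n1*n2) + d^2/(2*(n1+n2))).
    """
    x = np.asarray(high, float)
    y = np.asarray(low, float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise InvalidConfigError("need n >= 2 per group")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    m1, m2 = x.mean(), y.mean()
    base = dict(metric=metric, n_high=n1, n_low=n2,
                mean_high=float(m1), mean_low=float(m2))
    if v1 == 0 and v2 == 0:
        if m1 == m2:
            return TwoSampleResult(**base, t=float("nan"), df=float("nan"),
                                   p=float("nan"), cohens_d=float("nan"),
                                   d_ci_low=float("nan"), d_ci_high=float("nan"),
                                   undefined=True)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = float(2.0 * sps.t.sf(abs(t), df))
    sd_pool = math.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    d = (m1 - m2) / sd_pool if sd_pool > 0 else float("inf") * np.sign(m1 - m2)
    se_d = math.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2)))
    z = sps.norm.ppf(0.975)
    return TwoSampleResult(**base, t=float(t), df=float(df), p=p,
                           cohens_d=float(d),
                           d_ci_low=float(d - z * se_d),
                           d_ci_high=float(d + z * se_d))


def r_to_d(r: float) -> float:
    """Convert a point-biserial-style r to Cohen's d: d = 2r / sqrt(1-r^2)."""
    if abs(r) >= 1:
        raise InvalidConfigError("|r| must be < 1")
    return 2.0 * r / math.sqrt(1.0 - r * r)


def required_n_per_group(
    d: float, alpha: float = 0.05, power: float = 0.80, tails: int = 1
) -> int:
    """Normal-approximation sample size per group for a two-group design:
    n = ceil(((z_{1-alpha[/2]} + z_{power}) / d)^2)."""
    if d <= 0:
        raise InvalidConfigError("d must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise InvalidConfigError("alpha and power must lie in (0, 1)")
    if tails not in (1, 2):
        raise InvalidConfigError("tails must be 1 or 2")
    z_a = sps.norm.ppf(1.0 - alpha / tails)
    z_b = sps.norm.ppf(power)
    return math.ceil(((z_a + z_b) / d) ** 2)


# ---------------------------------------------------------------------------
# Per-window group contrasts
# ---------------------------------------------------------------------------

def group_timecourse_contrast(
    metrics: pd.DataFrame,
    assignments: pd.DataFrame,
    metric: str = "dwell_ratio",
    design: str = "between_pooled",
    cumulative: bool = True,
    holm: bool = False,
) -> pd.DataFrame:
    """Per-window high-vs-low contrast of one metric.

    Designs
    -------
    ``between_pooled``
        Mann-Whitney across all high-group vs low-group trials
        (participant x stimulus rows pooled over artworks) per window.
        Because artworks differ in baseline level, values are converted
        to within-artwork fractional ranks before pooling (a stratified
        rank test); pooling raw values would be conservative whenever the
        between-artwork spread dominates the within-artwork spread.
    ``between_per_artwork``
        The same test separately per artwork (one row per artwork x
        window).
    ``paired_per_participant``
        For each participant, the mean metric over the artworks that
        participant's own normalized rating places in their top vs bottom
        tertile; Wilcoxon signed-rank over participants per window.
        Requires a finite ``normalized_rating`` column in ``assignments``.

    Windows with fewer than two defined values on either side are flagged
    ``undefined``. With ``holm=True`` a Holm adjustment across windows is
    added as ``p_holm`` (off by default: per-window statistics are
    reported unadjusted).
    """
    sub = metrics[metrics["cumulative"] == cumulative]
    rows = []
    if design in ("between_pooled", "between_per_artwork"):
        merged = sub.merge(assignments[["participant_id", "stimulus_id", "group"]],
                           on=["participant_id", "stimulus_id"])
        merged = merged[merged["group"].isin(["high", "low"])].copy()
        if design == "between_pooled":
            # stratify by artwork: within-artwork fractional ranks per window
            def _frac_rank(s):
                return sps.rankdata(s, nan_policy="omit") / (s.notna().sum() + 1.0)

            merged[metric] = (
                merged.groupby(["stimulus_id", "window_start_s", "window_end_s"])[
                    metric
                ].transform(_frac_rank)
            )
            iterator = [(("__pooled__",), merged)]
        else:
            iterator = [((sid,), g) for sid, g in merged.groupby("stimulus_id", sort=True)]
        for (label,), g in iterator:
            for (ws, we), win in g.groupby(["window_start_s", "window_end_s"], sort=True):
                hi = win.loc[win["group"] == "high", metric].dropna().to_numpy()
                lo = win.loc[win["group"] == "low", metric].dropna().to_numpy()
                row = dict(stimulus_id=label, metric=metric,
                           window_start_s=ws, window_end_s=we,
                           cumulative=cumulative, design=design,
                           n_high=len(hi), n_low=len(lo))
                if len(hi) < 2 or len(lo) < 2:
                    row.update(dict(statistic=np.nan, p=np.nan,
                                    effect_r=np.nan, undefined=True))
                else:
                    u, p, r = mann_whitney_rb(hi, lo)
                    row.update(dict(statistic=u, p=p, effect_r=r, undefined=False))
                rows.append(row)
    elif design == "paired_per_participant":
        z = assignments.dropna(subset=["normalized_rating"])
        if z.empty:
            raise InvalidConfigError(
                "paired design needs normalized_rating in assignments"
            )
        # each participant's own artwork tertiles by normalized rating
        art_group = []
        for pid, g in z.groupby("participant_id", sort=True):
            g = g.sort_values(["normalized_rating", "stimulus_id"],
                              ascending=[False, True])
            n_side = len(g) // 3
            if n_side < 1:
                continue
            for sid in g["stimulus_id"].head(n_side):
                art_group.append((pid, sid, "high_art"))
            for sid in g["stimulus_id"].tail(n_side):
                art_group.append((pid, sid, "low_art"))
        ag = pd.DataFrame(art_group,
                          columns=["participant_id", "stimulus_id", "art_group"])
        merged = sub.merge(ag, on=["participant_id", "stimulus_id"])
        for (ws, we), win in merged.groupby(["window_start_s", "window_end_s"], sort=True):
            piv = (
                win.groupby(["participant_id", "art_group"])[metric]
                .mean()
                .unstack("art_group")
                .dropna()
            )
            row = dict(stimulus_id="__paired__", metric=metric,
                       window_start_s=ws, window_end_s=we,
                       cumulative=cumulative, design=design,
                       n_high=len(piv), n_low=len(piv))
            if len(piv) < 2 or "high_art" not in piv or "low_art" not in piv:
                row.update(dict(statistic=np.nan, p=np.nan,
                                effect_r=np.nan, undefined=True))
            else:
                cmp_ = paired_signed_rank(piv["high_art"].to_numpy(),
                                          piv["low_art"].to_numpy(), metric)
                row.update(dict(statistic=np.nan, p=cmp_.p_signrank,
                                effect_r=cmp_.r_rank_biserial,
                                undefined=cmp_.undefined))
            rows.append(row)
    else:
        raise InvalidConfigError(f"unknown design: {design}")
    out = pd.DataFrame(rows)
    if holm and len(out):
        out["p_holm"] = np.nan
        for label, idx in out.groupby("stimulus_id").groups.items():
            p = out.loc[idx, "p"].to_numpy()
            out.loc[idx, "p_holm"] = _holm(p)
    return out


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (NaNs passed through)."""
    p = np.asarray(p, float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    q = p[ok]
    m = len(q)
    order = np.argsort(q)
    adj = np.minimum(np.maximum.accumulate((m - np.arange(m)) * q[order]), 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def paired_summary_table(
    metrics: pd.DataFrame,
    assignments: pd.DataFrame,
    metric_names: tuple[str, ...] = ("Hnorm", "NeffNorm", "MaxP", "TV", "switch_rate"),
    window_start_s: float = 6.0,
) -> pd.DataFrame:
    """Per-participant paired summary of state metrics after a time point.

    For each metric: a participant's mean over their high-rated artworks
    vs their low-rated artworks (binned windows starting at or after
    ``window_start_s``), compared by Wilcoxon signed-rank. Output columns
    mirror a metric / nPaired / median high / median low / medianDiff /
    p_signrank / r_rankBiserial summary layout.
    """
    sub = metrics[(~metrics["cumulative"])
                  & (metrics["window_start_s"] >= window_start_s)]
    z = assignments.dropna(subset=["normalized_rating"])
    if z.empty:
        # participant-level (cohort-style) assignments cannot be paired
        # within participant; pair by stimulus instead: per stimulus, the
        # high-group mean vs the low-group mean, signed-rank over stimuli
        grp = assignments[assignments["group"].isin(["high", "low"])]
        merged = sub.merge(grp[["participant_id", "stimulus_id", "group"]],
                           on=["participant_id", "stimulus_id"])
        out = []
        for name in metric_names:
            piv = (
                merged.groupby(["stimulus_id", "group"])[name]
                .mean()
                .unstack("group")
                .dropna()
            )
            if len(piv) < 2:
                continue
            cmp_ = paired_signed_rank(piv["high"].to_numpy(),
                                      piv["low"].to_numpy(), name)
            out.append(dict(metric=name, nPaired=cmp_.n_paired,
                            median_high=cmp_.median_high,
                            median_low=cmp_.median_low,
                            medianDiff_HminusL=cmp_.median_diff,
                            p_signrank=cmp_.p_signrank,
                            r_rankBiserial=cmp_.r_rank_biserial))
        return pd.DataFrame(out)
    else:
        rows_ag = []
        for pid, g in z.groupby("participant_id", sort=True):
            g = g.sort_values(["normalized_rating", "stimulus_id"],
                              ascending=[False, True])
            n_side = len(g) // 3
            for sid in g["stimulus_id"].head(n_side):
                rows_ag.append((pid, sid, "high_art"))
            for sid in g["stimulus_id"].tail(n_side):
                rows_ag.append((pid, sid, "low_art"))
        ag = pd.DataFrame(rows_ag,
                          columns=["participant_id", "stimulus_id", "art_group"])
    merged = sub.merge(ag, on=["participant_id", "stimulus_id"])
    out = []
    for name in metric_names:
        piv = (
            merged.groupby(["participant_id", "art_group"])[name]
            .mean()
            .unstack("art_group")
            .dropna()
        )
        if len(piv) < 2:
            continue
        cmp_ = paired_signed_rank(piv["high_art"].to_numpy(),
                                  piv["low_art"].to_numpy(), name)
        out.append(dict(metric=name, nPaired=cmp_.n_paired,
                        median_high=cmp_.median_high,
                        median_low=cmp_.median_low,
                        medianDiff_HminusL=cmp_.median_diff,
                        p_signrank=cmp_.p_signrank,
                        r_rankBiserial=cmp_.r_rank_biserial))
    return pd.DataFrame(out)
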
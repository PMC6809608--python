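"""Bespoke statistical operators for the ERP and behavioural analyses.

Covers the pre-movement trend regressions (average-level ordinary least
squares and single-trial robust IRLS, both on 25 Hz low-passed, 10-fold
decimated samples), the cluster-based nonparametric permutation test of
waveforms against zero (one-sample design, sign-flip null, t threshold 2),
radial-EOG saccade detection and counting, and the behavioural consistency
grade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

import mne
import statsmodels.api as sm

logger = logging.getLogger("driftrace")

#: Normalised IQR: IQR times this factor estimates sigma for Gaussian data,
#: so "2.5 standardized IQRs" behaves like 2.5 robust standard deviations.
IQR_TO_SIGMA = 0.7413

#: Decimation factor applied after the 25 Hz anti-aliasing low-pass.
DECIMATE = 10


# -- trend regressions --------------------------------------------------------


def _decimated_window(
    waves: np.ndarray, times: np.ndarray, rate: float, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """25 Hz low-pass then every DECIMATE-th sample inside ``window``."""
    w = np.atleast_2d(np.asarray(waves, dtype=float))
    filt = mne.filter.filter_data(
        w, rate, l_freq=None, h_freq=25.0, method="fir", phase="zero", verbose="ERROR"
    )
    sel = np.flatnonzero((times >= window[0]) & (times < window[1]))
    sel = sel[::DECIMATE]
    return filt[:, sel], times[sel]


def trend_slope_average(
    waveform: np.ndarray,
    times: np.ndarray,
    rate: float,
    window: tuple[float, float] = (-1.0, 0.0),
) -> tuple[float, float]:
    """OLS slope of a subject-average waveform against time.

    ``waveform`` is the response-locked per-subject average (µV) with
    ``times`` in seconds relative to the response.  The signal is low-pass
    filtered at 25 Hz for anti-aliasing and decimated tenfold before the
    first-order fit.  Returns (slope in µV/s, two-sided p-value).
    """
    y, t = _decimated_window(waveform, np.asarray(times), rate, window)
    y = y[0]
    if t.size < 20:
        raise ValueError(f"window holds only {t.size} decimated samples (< 20)")
    res = stats.linregress(t, y)
    return float(res.slope), float(res.pvalue)


def trend_slope_trials(
    trial_waves: np.ndarray,
    times: np.ndarray,
    rate: float,
    window: tuple[float, float] = (-1.0, 0.0),
    max_iter: int = 50,
    tol: float = 1e-6,
) -> np.ndarray:
    """Robust (bisquare IRLS) slope per single trial, µV/s.

    Single-trial EEG is noisy and spiky, so each trial's decimated voltage
    is regressed on time with iteratively reweighted least squares using
    Tukey's bisquare weights; non-convergence falls back to OLS with a
    warning.
    """
    ys, t = _decimated_window(trial_waves, np.asarray(times), rate, window)
    X = sm.add_constant(t)
    slopes = np.empty(ys.shape[0])
    for i, y in enumerate(ys):
        try:
            fit = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight()).fit(
                maxiter=max_iter, tol=tol
            )
            slopes[i] = fit.params[1]
        except Exception:  # pragma: no cover - degenerate trials
            logger.warning("robust fit failed on trial %d; falling back to OLS", i)
            slopes[i] = stats.linregress(t, y).slope
    return slopes


def significant_downward(
    slopes: np.ndarray, alpha: float = 0.05, bonferroni_n: int = 1
) -> tuple[float, float, bool]:
    """One-sided test that a subject's per-trial slopes are below zero.

    Returns (t statistic, one-sided p, significant at alpha/bonferroni_n).
    """
    slopes = np.asarray(slopes, dtype=float)
    t, p = stats.ttest_1samp(slopes, 0.0, alternative="less")
    return float(t), float(p), bool(p < alpha / bonferroni_n)


# -- cluster-based permutation test -------------------------------------------


@dataclass
class Cluster:
    start: float  # seconds (or samples when no time base given)
    end: float
    mass: float  # sum of t values over the cluster
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    threshold_t: float
    n_permutations: int
    alpha: float

    def significant_clusters(self, alpha: float | None = None) -> list[Cluster]:
        a = self.alpha if alpha is None else alpha
        return [c for c in self.clusters if c.p_value < a]


def _one_sample_t(data: np.ndarray) -> np.ndarray:
    n = data.shape[0]
    m = data.mean(axis=0)
    s = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(s > 0, m / (s / np.sqrt(n)), 0.0)


def _clusters_from_t(tvals: np.ndarray, thr: float, two_tailed: bool):
    """Maximal runs of supra-threshold samples: list of (i0, i1, mass)."""
    out = []
    signs = (1, -1) if two_tailed else (1,)
    for sign in signs:
        above = sign * tvals > thr
        if not above.any():
            continue
        d = np.diff(above.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1)
        if above[0]:
            starts = np.concatenate(([0], starts))
        if above[-1]:
            ends = np.concatenate((ends, [above.size - 1]))
        for i0, i1 in zip(starts, ends):
            out.append((int(i0), int(i1), float(tvals[i0 : i1 + 1].sum())))
    return sorted(out)


def _max_cluster_mass(tvals: np.ndarray, thr: float, two_tailed: bool) -> float:
    cl = _clusters_from_t(tvals, thr, two_tailed)
    return max((abs(m) for _, _, m in cl), default=0.0)


def cluster_permutation_vs_zero(
    data: np.ndarray,
    times: np.ndarray | None = None,
    threshold_t: float = 2.0,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int | np.random.Generator | None = None,
    two_tailed: bool = True,
) -> ClusterResult:
    """Cluster-based permutation test of subject waveforms against zero.

    ``data`` is subjects x time.  Per sample, a one-sample t across
    subjects is computed; contiguous runs with |t| > ``threshold_t`` form
    clusters whose mass is the sum of t values.  The null distribution is
    built by random per-subject sign flips (the one-sample permutation
    scheme); each observed cluster's p-value is the fraction of
    permutations whose maximum |mass| reaches the observed |mass|.
    Positive and negative clusters are pooled against the same max-|mass|
    null (two-tailed by default).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 6:
        raise ValueError("need a subjects x time array with >= 6 subjects")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    n_subj, n_time = data.shape
    rng = np.random.default_rng(seed)

    t_obs = _one_sample_t(data)
    observed = _clusters_from_t(t_obs, threshold_t, two_tailed)

    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n_subj))
    sum_sx = signs @ data  # n_perm x time
    sumsq = (data**2).sum(axis=0)
    mean_p = sum_sx / n_subj
    var_p = (sumsq / n_subj - mean_p**2) * (n_subj / (n_subj - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = np.where(var_p > 0, mean_p / np.sqrt(var_p / n_subj), 0.0)
    null_max = np.array(
        [_max_cluster_mass(t_perm[i], threshold_t, two_tailed) for i in range(n_permutations)]
    )

    tb = np.arange(n_time, dtype=float) if times is None else np.asarray(times)
    clusters = []
    for i0, i1, mass in observed:
        p = (np.sum(null_max >= abs(mass)) + 1.0) / (n_permutations + 1.0)
        clusters.append(Cluster(start=float(tb[i0]), end=float(tb[i1]), mass=mass, p_value=float(p)))
    return ClusterResult(
        clusters=clusters,
        threshold_t=threshold_t,
        n_permutations=n_permutations,
        alpha=alpha,
    )


# -- saccade detection --------------------------------------------------------


@dataclass
class SaccadeConfig:
    """Detection settings for the radial EOG saccade count."""

    band: tuple[float, float] = (30.0, 100.0)
    z_thresh: float = 2.5
    min_duration_s: float = 0.002
    refractory_s: float = 0.05
    count_window_s: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.band[0] < self.band[1]):
            raise ValueError("band must be an increasing positive pair")
        for name in ("z_thresh", "min_duration_s", "refractory_s", "count_window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def detect_saccades(
    eog: np.ndarray, rate: float, cfg: SaccadeConfig | None = None
) -> np.ndarray:
    """Saccade onset samples from 4-channel EOG.

    The radial eye signal is the mean of the four EOG channels, band-pass
    filtered to ``cfg.band``.  A saccade is a maximal run of samples whose
    deviation from the median exceeds ``z_thresh`` normalised IQRs for
    longer than ``min_duration_s``; detections closer than
    ``refractory_s`` are merged into one.
    """
    cfg = cfg or SaccadeConfig()
    eog = np.asarray(eog, dtype=float)
    if eog.ndim != 2 or eog.shape[0] != 4:
        raise ValueError("expected a 4 x samples EOG array")
    if cfg.band[1] >= rate / 2:
        raise ValueError("band must lie below Nyquist")
    radial = eog.mean(axis=0)
    radial = mne.filter.filter_data(
        radial[None, :], rate, l_freq=cfg.band[0], h_freq=cfg.band[1],
        method="fir", phase="zero", verbose="ERROR",
    )[0]
    med = np.median(radial)
    q75, q25 = np.percentile(radial, [75, 25])
    sigma = (q75 - q25) * IQR_TO_SIGMA
    if sigma == 0:
        return np.array([], dtype=int)
    dev = np.abs(radial - med) > cfg.z_thresh * sigma

    d = np.diff(dev.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if dev[0]:
        starts = np.concatenate(([0], starts))
    if dev[-1]:
        ends = np.concatenate((ends, [dev.size - 1]))
    min_len = cfg.min_duration_s * rate
    onsets = [int(s) for s, e in zip(starts, ends) if (e - s + 1) > min_len]

    merged: list[int] = []
    gap = cfg.refractory_s * rate
    for s in onsets:
        if merged and s - merged[-1] < gap:
            continue
        merged.append(s)
    return np.asarray(merged, dtype=int)


def saccade_count(
    eog: np.ndarray,
    rate: float,
    response_samples: np.ndarray,
    cfg: SaccadeConfig | None = None,
) -> np.ndarray:
    """Number of saccades in the last ``count_window_s`` before each response."""
    cfg = cfg or SaccadeConfig()
    onsets = detect_saccades(eog, rate, cfg)
    w = int(round(cfg.count_window_s * rate))
    counts = np.empty(len(response_samples), dtype=int)
    for i, r in enumerate(np.asarray(response_samples, dtype=int)):
        counts[i] = int(np.sum((onsets >= r - w) & (onsets < r)))
    return counts


# -- behavioural consistency --------------------------------------------------


def consistency_grade(
    rating_chosen: np.ndarray, rating_unchosen: np.ndarray
) -> float:
    """Fraction of trials where the chosen alternative was rated higher.

    Each trial scores 1 when the chosen option's rating exceeds the
    unchosen one's and 0 otherwise; tied ratings are excluded with a
    warning (they cannot occur under the pairing rule, which keeps the two
    ratings at least one point apart).
    """
    a = np.asarray(rating_chosen, dtype=float)
    b = np.asarray(rating_unchosen, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rating arrays must have the same shape")
    tied = a == b
    if tied.any():
        logger.warning("excluding %d trials with tied ratings", int(tied.sum()))
    a, b = a[~tied], b[~tied]
    if a.size == 0:
        raise ValueError("no trials left after excluding ties")
    return float(np.mean(a > b))
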
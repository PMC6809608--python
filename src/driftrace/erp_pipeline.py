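"""EEG preprocessing and ERP computation.

Implements the preprocessing contracts of the empirical analysis: zero-phase
FIR filtering (0.1 Hz high-pass, 59-61 Hz notch, optional 25 Hz low-pass for
the trend analyses), amplitude/step/flatline artifact rejection with 150 ms
guard intervals, behavioural trial exclusion, stimulus- or response-locked
epoching with baseline subtraction, the readiness potential (RP: mean Cz
amplitude over the last 500 ms before movement) and the lateralized
readiness potential (LRP: left-hand minus right-hand C3-C4 difference).

Window convention: all windows are half-open in samples, [start, end).  A
response-locked [-2, 0.2) s window at 512 Hz therefore spans
round(2.2 * 512) = 1126 samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, minimum_filter1d

import mne

logger = logging.getLogger("driftrace")
mne.set_log_level("ERROR")

#: EOG channel labels used by the synthetic generator and the pipeline.
EOG_LABELS = ("EOG1", "EOG2", "EOG3", "EOG4")

#: Behavioural exclusion bounds, seconds.
RT_MIN_S = 0.2
RT_MAX_S = 10.0
RT_SD_CUTOFF = 3.0

#: Minimum kept trials per condition for a subject to enter group stats.
MIN_TRIALS_PER_CONDITION = 30


@dataclass
class Recording:
    """A continuous multichannel recording in microvolts.

    ``events`` is a DataFrame with integer column ``sample`` and string
    column ``kind`` in {stimulus, response-left, response-right, other}.
    """

    data: np.ndarray  # channels x samples, float, µV
    rate: float  # Hz
    labels: list[str]
    events: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(self.events):
            s = self.events["sample"].to_numpy()
            if s.min() < 0 or s.max() >= self.data.shape[1]:
                raise ValueError("event sample indices out of bounds")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None


@dataclass
class Epochs:
    """Epoched data plus bookkeeping for dropped trials.

    ``data`` holds kept trials only (trials x channels x time).  ``meta``
    covers every input trial, with a ``kept`` flag, a ``reason`` code for
    dropped trials and ``epoch_index`` into ``data`` (-1 when dropped).
    """

    data: np.ndarray
    rate: float
    labels: list[str]
    lock: str  # 'stimulus' | 'response'
    window: tuple[float, float]
    baseline: tuple[float, float, str] | None
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    baseline_subtracted: bool = True

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[2]
        start = round(self.window[0] * self.rate)
        return (start + np.arange(n)) / self.rate

    def channel(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None


# -- filtering ----------------------------------------------------------------


def apply_filters(
    rec: Recording,
    highpass_hz: float | None = 0.1,
    notch_band: tuple[float, float] | None = (59.0, 61.0),
    lowpass_hz: float | None = None,
) -> Recording:
    """Zero-phase FIR filtering: high-pass, notch, optional low-pass.

    Transition widths: 0.1 Hz for the high-pass, 1 Hz for the notch edges,
    and an automatic width for the low-pass.  Corners at or above the
    Nyquist frequency are rejected.
    """
    nyq = rec.rate / 2.0
    for corner in filter(None, (highpass_hz, lowpass_hz)):
        if corner >= nyq:
            raise ValueError(f"filter corner {corner} Hz >= Nyquist {nyq} Hz")
    if notch_band is not None and notch_band[1] >= nyq:
        raise ValueError("notch band must lie below Nyquist")

    x = rec.data.copy()
    if highpass_hz is not None or lowpass_hz is not None:
        x = mne.filter.filter_data(
            x,
            rec.rate,
            l_freq=highpass_hz,
            h_freq=lowpass_hz,
            method="fir",
            fir_design="firwin",
            phase="zero",
            l_trans_bandwidth=0.1 if highpass_hz is not None else "auto",
            verbose="ERROR",
        )
    if notch_band is not None:
        lo, hi = notch_band
        x = mne.filter.notch_filter(
            x,
            rec.rate,
            freqs=(lo + hi) / 2.0,
            notch_widths=hi - lo,
            trans_bandwidth=1.0,
            method="fir",
            phase="zero",
            verbose="ERROR",
        )
    return dc_replace(rec, data=x)


def average_reference(rec: Recording, exclude: tuple[str, ...] = EOG_LABELS) -> Recording:
    """Re-reference to the average of all channels except ``exclude``
    (external electrodes); the reference is subtracted from every channel."""
    keep = [i for i, lab in enumerate(rec.labels) if lab not in exclude]
    if not keep:
        raise ValueError("no channels left to build the reference")
    ref = rec.data[keep].mean(axis=0)
    return dc_replace(rec, data=rec.data - ref)


# -- artifact rejection -------------------------------------------------------


def _rolling_ptp(x: np.ndarray, w: int) -> np.ndarray:
    """Peak-to-peak range in a centred window of ``w`` samples, per channel."""
    return maximum_filter1d(x, w, axis=-1) - minimum_filter1d(x, w, axis=-1)


def reject_artifacts(
    rec: Recording,
    amp_thresh_uv: float = 100.0,
    step_thresh_uv: float = 100.0,
    step_window_s: float = 0.2,
    flat_thresh_uv: float = 0.5,
    flat_window_s: float = 0.1,
    pad_s: float = 0.15,
    channels: list[str] | None = None,
) -> np.ndarray:
    """Boolean bad-sample mask over the whole recording.

    A sample is bad when, on any considered channel, (a) the absolute
    amplitude exceeds ``amp_thresh_uv``, (b) the peak-to-peak range within a
    ``step_window_s`` window exceeds ``step_thresh_uv``, or (c) the
    peak-to-peak range stays below ``flat_thresh_uv`` across a
    ``flat_window_s`` window (flatline).  Flagged samples are expanded by
    ``pad_s`` on both sides, and the mask applies to all channels.
    """
    idx = (
        np.arange(rec.data.shape[0])
        if channels is None
        else [rec.channel(c) for c in channels]
    )
    x = rec.data[idx]
    bad = (np.abs(x) > amp_thresh_uv).any(axis=0)
    w_step = max(int(round(step_window_s * rec.rate)), 2)
    bad |= (_rolling_ptp(x, w_step) > step_thresh_uv).any(axis=0)
    w_flat = max(int(round(flat_window_s * rec.rate)), 2)
    bad |= (_rolling_ptp(x, w_flat) < flat_thresh_uv).any(axis=0)
    pad = int(round(pad_s * rec.rate))
    if pad > 0 and bad.any():
        bad = maximum_filter1d(bad.astype(np.uint8), 2 * pad + 1).astype(bool)
    return bad


# -- behavioural trial exclusion ----------------------------------------------


def exclude_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Flag trials for exclusion with reason codes.

    Rules, in order: a press on a non-designated key (boolean column
    ``wrong_key`` when present), RT < 200 ms, RT > 10 s, and RT more than
    three standard deviations from the subject-by-condition mean.  The
    3-SD rule is computed once, on the trials surviving the earlier rules.
    Returns a copy with ``kept`` and ``reason`` columns.
    """
    out = trials.copy()
    n = len(out)
    kept = np.ones(n, dtype=bool)
    reason = np.array([""] * n, dtype=object)
    rt = out["rt"].to_numpy(dtype=float)

    if "wrong_key" in out.columns:
        wk = out["wrong_key"].to_numpy(dtype=bool)
        kept &= ~wk
        reason[wk] = "wrong_key"
    fast = kept & (rt < RT_MIN_S)
    kept &= ~fast
    reason[fast] = "too_fast"
    slow = kept & (rt > RT_MAX_S)
    kept &= ~slow
    reason[slow] = "too_slow"

    group_cols = [
        c for c in ("subject", "decision_type", "difficulty") if c in out.columns
    ]
    out["kept"], out["reason"] = kept, reason  # interim, for the groupby
    if group_cols:
        grouped = out[out["kept"]].groupby(group_cols)["rt"]
        stats = grouped.agg(["mean", "std"]).rename(
            columns={"mean": "_m", "std": "_s"}
        )
        merged = out.merge(stats, left_on=group_cols, right_index=True, how="left")
        m, s = merged["_m"].to_numpy(), merged["_s"].to_numpy()
    else:
        surv = rt[kept]
        m = np.full(n, surv.mean() if surv.size else np.nan)
        s = np.full(n, surv.std(ddof=1) if surv.size > 1 else np.nan)
    with np.errstate(invalid="ignore"):
        outlier = kept & (np.abs(rt - m) > RT_SD_CUTOFF * np.nan_to_num(s, nan=np.inf))
    kept &= ~outlier
    reason[outlier] = "rt_outlier"
    out["kept"], out["reason"] = kept, reason
    return out


# -- epoching -----------------------------------------------------------------


def epoch(
    rec: Recording,
    trials: pd.DataFrame,
    lock: str = "response",
    window: tuple[float, float] = (-2.0, 0.2),
    baseline: tuple[float, float, str] | None = (-1.0, -0.5, "stimulus"),
    bad_mask: np.ndarray | None = None,
) -> Epochs:
    """Cut per-trial epochs around stimulus or response onsets.

    ``trials`` needs integer columns ``stimulus_sample`` and
    ``response_sample``; other columns are carried into the metadata.
    ``baseline`` is (start_s, end_s, lock) with its own lock event; the
    per-trial, per-channel baseline mean is subtracted.  Trials that
    overlap ``bad_mask`` or extend beyond the recording are dropped with a
    reason code.  Windows are half-open in samples.
    """
    if lock not in ("stimulus", "response"):
        raise ValueError("lock must be 'stimulus' or 'response'")
    n_samp = round((window[1] - window[0]) * rec.rate)
    start_off = round(window[0] * rec.rate)
    lock_col = "stimulus_sample" if lock == "stimulus" else "response_sample"

    if baseline is not None:
        b0, b1, block = baseline
        if block not in ("stimulus", "response"):
            raise ValueError("baseline lock must be 'stimulus' or 'response'")
        bcol = "stimulus_sample" if block == "stimulus" else "response_sample"
        b_start_off = round(b0 * rec.rate)
        b_n = round((b1 - b0) * rec.rate)

    kept_rows: list[np.ndarray] = []
    kept_flags = np.zeros(len(trials), dtype=bool)
    reasons = np.array([""] * len(trials), dtype=object)
    epoch_index = np.full(len(trials), -1, dtype=int)

    for row_i, (_, tr) in enumerate(trials.iterrows()):
        lock_sample = int(tr[lock_col])
        a = lock_sample + start_off
        b = a + n_samp
        if a < 0 or b > rec.n_samples:
            reasons[row_i] = "out_of_bounds"
            continue
        if baseline is not None:
            ba = int(tr[bcol]) + b_start_off
            bb = ba + b_n
            if ba < 0 or bb > rec.n_samples:
                reasons[row_i] = "baseline_out_of_bounds"
                continue
        if bad_mask is not None and bad_mask[a:b].any():
            reasons[row_i] = "artifact"
            continue
        seg = rec.data[:, a:b]
        if baseline is not None:
            seg = seg - rec.data[:, ba:bb].mean(axis=1, keepdims=True)
        kept_flags[row_i] = True
        epoch_index[row_i] = len(kept_rows)
        kept_rows.append(seg)

    meta = trials.copy().reset_index(drop=True)
    meta["kept"] = kept_flags
    meta["reason"] = reasons
    meta["epoch_index"] = epoch_index
    data = (
        np.stack(kept_rows)
        if kept_rows
        else np.empty((0, rec.data.shape[0], n_samp))
    )
    n_dropped = int((~kept_flags).sum())
    if n_dropped:
        logger.info("epoching dropped %d/%d trials", n_dropped, len(trials))
    return Epochs(
        data=data,
        rate=rec.rate,
        labels=list(rec.labels),
        lock=lock,
        window=window,
        baseline=baseline,
        meta=meta,
    )


# -- ERP summaries ------------------------------------------------------------


def _window_slice(ep: Epochs, stat_window: tuple[float, float]) -> slice:
    t0 = round(ep.window[0] * ep.rate)
    a = round(stat_window[0] * ep.rate) - t0
    b = round(stat_window[1] * ep.rate) - t0
    if a < 0 or b > ep.data.shape[2] or a >= b:
        raise ValueError("stat window outside the epoch window")
    return slice(a, b)


def compute_rp(
    epochs: Epochs,
    channel: str = "Cz",
    stat_window: tuple[float, float] = (-0.5, 0.0),
    min_trials: int = MIN_TRIALS_PER_CONDITION,
) -> tuple[pd.DataFrame, dict[tuple[str, str], np.ndarray]]:
    """Readiness-potential summary from response-locked epochs.

    Per subject and condition: the trial-average Cz waveform is averaged
    over ``stat_window`` (half-open) to one mean amplitude; subjects with
    fewer than ``min_trials`` kept trials in a condition are flagged.
    Returns the per-subject table and the grand-average waveform (mean of
    subject-average waveforms) per (decision_type, difficulty).
    """
    ch = epochs.channel(channel)
    sl = _window_slice(epochs, stat_window)
    meta = epochs.meta
    kept = meta[meta["kept"]]
    rows = []
    grand: dict[tuple[str, str], list[np.ndarray]] = {}
    for (subj, dec, diff), g in kept.groupby(["subject", "decision_type", "difficulty"]):
        waves = epochs.data[g["epoch_index"].to_numpy(), ch, :]
        avg = waves.mean(axis=0)
        rows.append(
            {
                "subject": subj,
                "decision_type": dec,
                "difficulty": diff,
                "n_trials": len(g),
                "mean_amplitude_uv": float(avg[sl].mean()),
                "flagged_low_n": len(g) < min_trials,
            }
        )
        grand.setdefault((dec, diff), []).append(avg)
    table = pd.DataFrame(rows)
    grand_avg = {k: np.mean(v, axis=0) for k, v in grand.items()}
    return table, grand_avg


def compute_lrp(
    epochs: Epochs,
    left_channel: str = "C3",
    right_channel: str = "C4",
    stat_window: tuple[float, float] = (-0.5, 0.0),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Lateralized readiness potential from response-locked epochs.

    Per subject: LRP(t) = mean over left-hand trials of (C3-C4) minus the
    same mean over right-hand trials.  Returns a per-subject summary table
    (mean over ``stat_window``) and the subjects x time LRP waveforms.
    Requires a ``hand`` metadata column with both hands represented for
    every subject.
    """
    c3, c4 = epochs.channel(left_channel), epochs.channel(right_channel)
    sl = _window_slice(epochs, stat_window)
    kept = epochs.meta[epochs.meta["kept"]]
    rows, waves = [], []
    for subj, g in kept.groupby("subject"):
        diffs = (
            epochs.data[g["epoch_index"].to_numpy(), c3, :]
            - epochs.data[g["epoch_index"].to_numpy(), c4, :]
        )
        hands = g["hand"].to_numpy()
        if not (hands == "left").any() or not (hands == "right").any():
            raise ValueError(f"subject {subj!r} lacks trials for one hand")
        lrp = diffs[hands == "left"].mean(axis=0) - diffs[hands == "right"].mean(axis=0)
        rows.append({"subject": subj, "lrp_mean_uv": float(lrp[sl].mean())})
        waves.append(lrp)
    return pd.DataFrame(rows), np.stack(waves)
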
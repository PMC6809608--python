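"""Movement-locked readiness-potential prediction from simulated traces.

The simulated Cz electrode sees the mean of the two SMA accumulators.  For
every decided trial the last 2 s (2000 samples at dt = 1 ms) of that mean
trace *before* the threshold crossing are taken as a model epoch; trials
whose crossing comes earlier than 2 s after onset are padded at the head
with missing values.  Averaging the epochs sample-wise (missing values do
not contribute) and flipping the result vertically gives the model RP, in
accumulator activation units, time-locked to decision completion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from driftrace.ddm_core import ConditionParams, TrialResult, simulate_condition

logger = logging.getLogger("driftrace")

#: Epoch length in samples (2 s at the 1 ms integration step).
EPOCH_LEN = 2000


@dataclass
class ModelEpoch:
    """One movement-locked model epoch ending at the decision crossing."""

    samples: np.ndarray  # length EPOCH_LEN, NaN head where the trial is short
    n_missing: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        nan = ~np.isfinite(self.samples)
        if nan.any():
            # missing prefix must be contiguous and at the head
            if not nan[: self.n_missing].all() or nan[self.n_missing :].any():
                raise ValueError("missing values must form a contiguous head")


@dataclass
class ModelRp:
    """Averaged, sign-flipped model RP for one condition."""

    time: np.ndarray  # seconds relative to the crossing (negative)
    mean: np.ndarray  # flipped mean activation; NaN where no trial contributes
    count: np.ndarray  # contributing trials per sample
    n_trials: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time, "mean_activation": self.mean, "n_trials": self.count}
        )


def _epoch_from_traces(
    sma_traces: tuple[np.ndarray, np.ndarray],
    crossing_index: int,
    epoch_len: int = EPOCH_LEN,
) -> ModelEpoch:
    mean_trace = (sma_traces[0] + sma_traces[1]) / 2.0
    start = crossing_index - epoch_len
    out = np.full(epoch_len, np.nan)
    lo = max(start, 0)
    out[lo - start :] = mean_trace[lo:crossing_index]
    return ModelEpoch(samples=out, n_missing=max(0, -start))


def epoch_model_trial(trial: TrialResult, epoch_len: int = EPOCH_LEN) -> ModelEpoch:
    """Epoch one decided trial: mean of the two SMA traces, last
    ``epoch_len`` samples before the crossing, head-padded with NaN."""
    if not trial.decided or trial.crossing_index is None:
        raise ValueError("cannot epoch an undecided trial")
    if len(trial.sma_traces[0]) != len(trial.sma_traces[1]):
        raise ValueError("SMA traces must have equal length")
    return _epoch_from_traces(trial.sma_traces, trial.crossing_index, epoch_len)


def average_model_rp(
    epochs: Sequence[ModelEpoch],
) -> tuple[np.ndarray, np.ndarray]:
    """Sample-wise mean over epochs, vertically flipped.

    Missing values do not contribute; a sample with no contributing trial
    is NaN in the output.  Returns ``(flipped_mean, count)``.
    """
    if len(epochs) == 0:
        raise ValueError("need at least one epoch")
    stack = np.stack([e.samples for e in epochs])
    count = np.isfinite(stack).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, np.nanmean(stack, axis=0), np.nan)
    return -mean, count


def predict_condition_rp(
    cond: ConditionParams,
    n_runs: int = 1000,
    seed: int | np.random.Generator = 0,
    epoch_len: int = EPOCH_LEN,
) -> ModelRp:
    """Simulate a condition and average its movement-locked SMA epochs."""
    sim = simulate_condition(cond, n_runs, seed, keep_traces=True)
    epochs = []
    for i in range(n_runs):
        ci = int(sim.crossing_indices[i])
        if ci < 0:
            logger.info("skipping undecided trial %d in RP prediction", i)
            continue
        epochs.append(_epoch_from_traces(sim.sma_traces[i], ci, epoch_len))
    if not epochs:
        raise ValueError("no decided trials to epoch")
    mean, count = average_model_rp(epochs)
    dt = cond.congruent.dt
    time = (np.arange(epoch_len) - epoch_len) * dt
    return ModelRp(time=time, mean=mean, count=count, n_trials=len(epochs))


def late_window_slope(rp: ModelRp, window_s: float = 0.5) -> float:
    """Least-squares slope of the model RP over the final ``window_s``
    seconds (activation units per second); ignores missing samples."""
    sel = rp.time >= -window_s
    t, y = rp.time[sel], rp.mean[sel]
    ok = np.isfinite(y)
    if ok.sum() < 2:
        raise ValueError("not enough finite samples in the window")
    return float(np.polyfit(t[ok], y[ok], 1)[0])
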
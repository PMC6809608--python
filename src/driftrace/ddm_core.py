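"""Leaky stochastic accumulators and races to threshold.

The elementary process is a leaky stochastic accumulator ("drift-diffusion"
unit) integrated by explicit Euler–Maruyama:

    x[i+1] = x[i] + (I - k*x[i]) * dt + c * xi[i] * sqrt(dt),   x[0] = 0

where ``I`` is the drift rate (1/s), ``k`` the leak (1/s), ``c`` the noise
scale (1/sqrt(s)) and ``xi`` standard-normal deviates.  A decision is the
first sample at which the activation reaches a threshold ``theta``.

Choices are modelled as a *race* between two such accumulators — one for the
alternative that was rated higher in the preference-rating session (the
*congruent* option) and one for the lower-rated (*incongruent*) option.  A
trial couples two races:

* a value (``Region X``) pair that decides *deliberate* trials, and
* a noise (``SMA``) pair, the simulated recording site under electrode Cz,
  that decides *arbitrary* trials.

During deliberate trials the SMA pair keeps integrating without any
threshold (the decision is made elsewhere) with drift rates scaled down by
``sma_drift_ratio``; its activation is simply read out up to the moment the
value pair crosses.

The update rule is a linear recurrence, so batches of trials are integrated
with :func:`scipy.signal.lfilter` along time, in chunks with early stopping;
this is what makes the grid-search fits in :mod:`driftrace.model_fit`
tractable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

logger = logging.getLogger("driftrace")

# -- package-wide simulation defaults ---------------------------------------

#: Euler step of the numerical integration, seconds.
DT = 0.001
#: Simulation cap, seconds (mirrors the behavioural 20 s response deadline).
T_MAX = 20.0
#: Decision threshold on the accumulator activation (dimensionless).
THRESHOLD = 0.3
#: Drift-rate attenuation of the SMA pair relative to the value pair in
#: deliberate trials (Cz activity vs. mean activity over the other scalp
#: electrodes in arbitrary trials).
SMA_DRIFT_RATIO = 1.45

UNBOUNDED = math.inf

#: Published best-fitting parameters of the deciding pair for the four
#: experimental conditions (threshold fixed at 0.3).  Keys are
#: (decision_type, difficulty); values are (I_congruent, I_incongruent, k, c).
BEST_FIT_PARAMS: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("deliberate", "easy"): (0.23, 0.06, 0.52, 0.08),
    ("deliberate", "hard"): (0.18, 0.09, 0.53, 0.11),
    ("arbitrary", "easy"): (0.24, 0.21, 0.53, 0.22),
    ("arbitrary", "hard"): (0.22, 0.20, 0.54, 0.23),
}

#: Alternative local minimum found for the deliberate-hard condition
#: (I_congruent, I_incongruent, k, c).
DELIBERATE_HARD_ALT_BASIN = (0.15, 0.07, 0.21, 0.09)

CONDITIONS: tuple[tuple[str, str], ...] = tuple(BEST_FIT_PARAMS)

_WINNER_NONE = "none"
_WINNER_CONGRUENT = "congruent"
_WINNER_INCONGRUENT = "incongruent"


# -- parameter containers ----------------------------------------------------


@dataclass(frozen=True)
class AccumulatorParams:
    """Parameters of a single leaky stochastic accumulator.

    Attributes
    ----------
    drift : float
        Drift rate ``I`` per second.
    leak : float
        Leak ``k`` per second (exponential decay of the activation).
    noise_scale : float
        Noise scale ``c`` per sqrt(second).
    threshold : float
        Decision threshold on the activation; ``math.inf`` (UNBOUNDED) for a
        thresholdless accumulator that never decides.
    dt : float
        Integration step in seconds.
    t_max : float
        Simulation cap in seconds.
    """

    drift: float
    leak: float
    noise_scale: float
    threshold: float = THRESHOLD
    dt: float = DT
    t_max: float = T_MAX

    def __post_init__(self) -> None:
        for name in ("drift", "leak", "noise_scale", "threshold", "dt", "t_max"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or math.isnan(v):
                raise ValueError(f"{name} must be a finite number, got {v!r}")
        if not math.isfinite(self.drift):
            raise ValueError("drift must be finite")
        if self.dt <= 0 or self.t_max <= 0:
            raise ValueError("dt and t_max must be positive")
        if self.leak < 0 or self.noise_scale < 0:
            raise ValueError("leak and noise_scale must be non-negative")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive (use UNBOUNDED for none)")

    @property
    def unbounded(self) -> bool:
        return math.isinf(self.threshold)

    @property
    def n_steps(self) -> int:
        """Number of Euler steps to the simulation cap."""
        return int(round(self.t_max / self.dt))


@dataclass(frozen=True)
class ConditionParams:
    """Full parameterisation of one experimental condition.

    ``congruent``/``incongruent`` are the deciding pair: the value (Region X)
    pair for deliberate conditions, the noise (SMA) pair for arbitrary ones.
    ``simulate_value_in_arbitrary`` exposes the outcome-irrelevant value pair
    during arbitrary trials; it defaults off because those accumulators do
    not affect the decision or the recorded site.
    """

    decision_type: str
    difficulty: str
    congruent: AccumulatorParams
    incongruent: AccumulatorParams
    sma_drift_ratio: float = SMA_DRIFT_RATIO
    simulate_value_in_arbitrary: bool = False

    def __post_init__(self) -> None:
        if self.decision_type not in ("deliberate", "arbitrary"):
            raise ValueError(f"unknown decision_type {self.decision_type!r}")
        if self.difficulty not in ("easy", "hard"):
            raise ValueError(f"unknown difficulty {self.difficulty!r}")
        if self.sma_drift_ratio <= 0:
            raise ValueError("sma_drift_ratio must be positive")
        for a, b in ((self.congruent, self.incongruent),):
            if a.dt != b.dt or a.t_max != b.t_max:
                raise ValueError("both accumulators must share dt and t_max")
        if (
            self.decision_type == "deliberate"
            and self.congruent.drift < self.incongruent.drift
        ):
            raise ValueError(
                "deliberate conditions require congruent.drift >= incongruent.drift"
            )

    def sma_pair(self) -> tuple[AccumulatorParams, AccumulatorParams]:
        """The SMA pair as actually simulated for this condition.

        Arbitrary: the deciding pair itself.  Deliberate: same leak and
        noise, drifts divided by ``sma_drift_ratio``, no threshold.
        """
        if self.decision_type == "arbitrary":
            return self.congruent, self.incongruent
        return (
            replace(
                self.congruent,
                drift=self.congruent.drift / self.sma_drift_ratio,
                threshold=UNBOUNDED,
            ),
            replace(
                self.incongruent,
                drift=self.incongruent.drift / self.sma_drift_ratio,
                threshold=UNBOUNDED,
            ),
        )


@dataclass
class RaceResult:
    """Outcome of a single race between two accumulators."""

    winner: str  # 'congruent' | 'incongruent' | 'none'
    rt: float  # seconds; nan when winner == 'none'
    crossing_index: int | None
    traces: tuple[np.ndarray, np.ndarray]  # (congruent, incongruent)


@dataclass
class TrialResult:
    """One simulated trial of the two-component model."""

    winner: str
    rt: float
    crossing_index: int | None
    deciding_traces: tuple[np.ndarray, np.ndarray]
    sma_traces: tuple[np.ndarray, np.ndarray]

    @property
    def decided(self) -> bool:
        return self.winner != _WINNER_NONE


@dataclass
class ConditionSimulation:
    """Vectorised result of many trials of one condition."""

    rts: np.ndarray  # seconds, nan where undecided
    winners: np.ndarray  # array of 'congruent'/'incongruent'/'none'
    sma_traces: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    crossing_indices: np.ndarray | None = None

    @property
    def n_undecided(self) -> int:
        return int(np.sum(self.winners == _WINNER_NONE))

    @property
    def consistency(self) -> float:
        """Fraction of congruent winners among decided trials."""
        decided = self.winners != _WINNER_NONE
        if not decided.any():
            raise ValueError("no decided trials; degenerate parameters")
        return float(np.mean(self.winners[decided] == _WINNER_CONGRUENT))

    @property
    def mean_rt(self) -> float:
        return float(np.nanmean(self.rts))


# -- parameter table I/O ------------------------------------------------------

_TABLE_COLUMNS = [
    "decision_type",
    "difficulty",
    "I_congruent",
    "I_incongruent",
    "k",
    "c",
    "threshold",
]


def condition_from_entry(
    decision_type: str,
    difficulty: str,
    I_congruent: float,
    I_incongruent: float,
    k: float,
    c: float,
    threshold: float = THRESHOLD,
    dt: float = DT,
    t_max: float = T_MAX,
    sma_drift_ratio: float = SMA_DRIFT_RATIO,
) -> ConditionParams:
    """Build :class:`ConditionParams` from one parameter-table row."""
    mk = lambda I: AccumulatorParams(  # noqa: E731
        drift=I, leak=k, noise_scale=c, threshold=threshold, dt=dt, t_max=t_max
    )
    return ConditionParams(
        decision_type=decision_type,
        difficulty=difficulty,
        congruent=mk(I_congruent),
        incongruent=mk(I_incongruent),
        sma_drift_ratio=sma_drift_ratio,
    )


def best_fit_condition(
    decision_type: str, difficulty: str, dt: float = DT, t_max: float = T_MAX
) -> ConditionParams:
    """The published best-fitting condition parameterisation."""
    Ic, Ii, k, c = BEST_FIT_PARAMS[(decision_type, difficulty)]
    return condition_from_entry(
        decision_type, difficulty, Ic, Ii, k, c, dt=dt, t_max=t_max
    )


def parameter_table(conditions: Sequence[ConditionParams] | None = None) -> pd.DataFrame:
    """Parameter table as a DataFrame (one row per condition)."""
    if conditions is None:
        conditions = [best_fit_condition(d, e) for d, e in CONDITIONS]
    rows = [
        {
            "decision_type": c.decision_type,
            "difficulty": c.difficulty,
            "I_congruent": c.congruent.drift,
            "I_incongruent": c.incongruent.drift,
            "k": c.congruent.leak,
            "c": c.congruent.noise_scale,
            "threshold": c.congruent.threshold,
        }
        for c in conditions
    ]
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def save_parameter_table(conditions: Sequence[ConditionParams], path) -> None:
    parameter_table(conditions).to_csv(path, index=False)


def load_parameter_table(path, dt: float = DT, t_max: float = T_MAX) -> list[ConditionParams]:
    df = pd.read_csv(path)
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"parameter table missing columns: {sorted(missing)}")
    return [
        condition_from_entry(
            r.decision_type,
            r.difficulty,
            r.I_congruent,
            r.I_incongruent,
            r.k,
            r.c,
            threshold=r.threshold,
            dt=dt,
            t_max=t_max,
        )
        for r in df.itertuples()
    ]


# -- integration engine -------------------------------------------------------


def _integrate_batch(
    params: AccumulatorParams, noise: np.ndarray, x0: np.ndarray | float = 0.0
) -> np.ndarray:
    """Integrate the recurrence for a (n_runs, n_steps) block of noise.

    Returns activations at steps 1..n_steps (the initial activation x0 is
    not included).  The update is linear in x, so it is an AR(1) filter:

        x[t] = (1 - k*dt) * x[t-1] + I*dt + c*sqrt(dt)*xi[t]
    """
    a = 1.0 - params.leak * params.dt
    drive = params.drift * params.dt + params.noise_scale * math.sqrt(params.dt) * noise
    x0 = np.broadcast_to(np.asarray(x0, dtype=float), (drive.shape[0],))
    # direct-form II transposed state for b=[1], a=[1, -a] is z = a * y_prev
    zi = (a * x0)[:, None]
    y, _ = lfilter([1.0], [1.0, -a], drive, axis=1, zi=zi)
    return y


def simulate_accumulator(
    params: AccumulatorParams, seed: int | np.random.Generator
) -> tuple[np.ndarray, int | None]:
    """Simulate one accumulator from stimulus onset.

    Returns ``(trace, crossing_index)``.  ``trace[0] = 0`` is the activation
    at stimulus onset; ``crossing_index`` is the first sample i with
    ``trace[i] >= threshold`` (``None`` if no crossing before ``t_max`` or
    the threshold is unbounded).  The trace is truncated at the crossing.
    """
    rng = np.random.default_rng(seed)
    n = params.n_steps
    noise = rng.standard_normal((1, n))
    y = _integrate_batch(params, noise)[0]
    trace = np.concatenate(([0.0], y))
    if params.unbounded:
        return trace, None
    above = trace >= params.threshold
    if not above.any():
        return trace, None
    idx = int(above.argmax())
    return trace[: idx + 1], idx


def _first_crossing(y: np.ndarray, threshold: float, offset: int) -> np.ndarray:
    """First crossing index (absolute, 1-based wrt trace) per row; -1 if none.

    ``y`` holds activations at steps offset+1 .. offset+L.
    """
    if math.isinf(threshold):
        return np.full(y.shape[0], -1, dtype=np.int64)
    above = y >= threshold
    has = above.any(axis=1)
    idx = np.where(has, above.argmax(axis=1) + offset + 1, -1)
    return idx.astype(np.int64)


def _race_batch(
    pc: AccumulatorParams,
    pi: AccumulatorParams,
    n_runs: int,
    rng: np.random.Generator,
    collect_traces: bool,
    chunk: int = 2000,
):
    """Race ``n_runs`` independent congruent/incongruent pairs.

    Returns ``(winner_codes, crossing, traces)`` where winner_codes is
    +1 congruent / -1 incongruent / 0 none, ``crossing`` the winning
    crossing sample (-1 if none) and ``traces`` a list of per-run
    (congruent, incongruent) activation traces truncated at the winning
    crossing (or the full cap when undecided); traces is empty unless
    ``collect_traces``.

    Each accumulator consumes its own child generator so that the two noise
    streams are independent; a third stream breaks same-sample ties by fair
    coin.
    """
    rng_c, rng_i, rng_tie = rng.spawn(3)
    n_steps = pc.n_steps
    cross_c = np.full(n_runs, -1, dtype=np.int64)
    cross_i = np.full(n_runs, -1, dtype=np.int64)
    active = np.arange(n_runs)
    x_c = np.zeros(n_runs)
    x_i = np.zeros(n_runs)
    pieces_c: list[list[np.ndarray]] = [[] for _ in range(n_runs)] if collect_traces else []
    pieces_i: list[list[np.ndarray]] = [[] for _ in range(n_runs)] if collect_traces else []
    offset = 0
    while offset < n_steps and active.size:
        L = min(chunk, n_steps - offset)
        y_c = _integrate_batch(pc, rng_c.standard_normal((active.size, L)), x_c[active])
        y_i = _integrate_batch(pi, rng_i.standard_normal((active.size, L)), x_i[active])
        cc = _first_crossing(y_c, pc.threshold, offset)
        ci = _first_crossing(y_i, pi.threshold, offset)
        cross_c[active] = np.where(cc >= 0, cc, cross_c[active])
        cross_i[active] = np.where(ci >= 0, ci, cross_i[active])
        x_c[active] = y_c[:, -1]
        x_i[active] = y_i[:, -1]
        if collect_traces:
            for row, run in enumerate(active):
                pieces_c[run].append(y_c[row])
                pieces_i[run].append(y_i[row])
        decided = (cross_c[active] >= 0) | (cross_i[active] >= 0)
        active = active[~decided]
        offset += L

    winner = np.zeros(n_runs, dtype=np.int64)
    crossing = np.full(n_runs, -1, dtype=np.int64)
    has_c, has_i = cross_c >= 0, cross_i >= 0
    only_c = has_c & (~has_i | (cross_c < cross_i))
    only_i = has_i & (~has_c | (cross_i < cross_c))
    tie = has_c & has_i & (cross_c == cross_i)
    winner[only_c], winner[only_i] = 1, -1
    crossing[only_c] = cross_c[only_c]
    crossing[only_i] = cross_i[only_i]
    if tie.any():
        coin = rng_tie.random(int(tie.sum())) < 0.5
        winner[tie] = np.where(coin, 1, -1)
        crossing[tie] = cross_c[tie]

    traces: list[tuple[np.ndarray, np.ndarray]] = []
    if collect_traces:
        for run in range(n_runs):
            tc = np.concatenate([[0.0]] + pieces_c[run])
            ti = np.concatenate([[0.0]] + pieces_i[run])
            end = crossing[run] + 1 if crossing[run] >= 0 else n_steps + 1
            traces.append((tc[:end], ti[:end]))
    return winner, crossing, traces


def _sma_batch(
    cond: ConditionParams,
    crossing: np.ndarray,
    rng: np.random.Generator,
    chunk: int = 4000,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Thresholdless SMA traces for deliberate trials, cut at the value
    pair's crossing sample (undecided runs run to the cap)."""
    ps_c, ps_i = cond.sma_pair()
    rng_c, rng_i = rng.spawn(2)
    n_runs = crossing.size
    n_steps = ps_c.n_steps
    length = np.where(crossing >= 0, crossing, n_steps)  # steps to simulate
    max_len = int(length.max()) if n_runs else 0
    out_c = [np.zeros(1)] * n_runs
    out_i = [np.zeros(1)] * n_runs
    pieces_c: list[list[np.ndarray]] = [[] for _ in range(n_runs)]
    pieces_i: list[list[np.ndarray]] = [[] for _ in range(n_runs)]
    active = np.arange(n_runs)[length > 0]
    x_c = np.zeros(n_runs)
    x_i = np.zeros(n_runs)
    offset = 0
    while offset < max_len and active.size:
        L = min(chunk, max_len - offset)
        y_c = _integrate_batch(ps_c, rng_c.standard_normal((active.size, L)), x_c[active])
        y_i = _integrate_batch(ps_i, rng_i.standard_normal((active.size, L)), x_i[active])
        x_c[active] = y_c[:, -1]
        x_i[active] = y_i[:, -1]
        for row, run in enumerate(active):
            take = min(L, length[run] - offset)
            pieces_c[run].append(y_c[row, :take])
            pieces_i[run].append(y_i[row, :take])
        offset += L
        active = active[length[active] > offset]
    for run in range(n_runs):
        out_c[run] = np.concatenate([[0.0]] + pieces_c[run])
        out_i[run] = np.concatenate([[0.0]] + pieces_i[run])
    return list(zip(out_c, out_i))


# -- public simulation API ----------------------------------------------------

_CODE_TO_WINNER = {1: _WINNER_CONGRUENT, -1: _WINNER_INCONGRUENT, 0: _WINNER_NONE}


def run_race(
    congruent: AccumulatorParams,
    incongruent: AccumulatorParams,
    seed: int | np.random.Generator,
) -> RaceResult:
    """Race two accumulators with independent noise streams.

    The accumulator with the earlier threshold crossing wins and sets the
    RT; a tie at the identical sample is broken by a fair coin drawn from
    the trial's seed stream.
    """
    if congruent.dt != incongruent.dt or congruent.t_max != incongruent.t_max:
        raise ValueError("racing accumulators must share dt and t_max")
    rng = np.random.default_rng(seed)
    winner, crossing, traces = _race_batch(congruent, incongruent, 1, rng, True)
    w = _CODE_TO_WINNER[int(winner[0])]
    idx = int(crossing[0]) if crossing[0] >= 0 else None
    rt = idx * congruent.dt if idx is not None else float("nan")
    return RaceResult(winner=w, rt=rt, crossing_index=idx, traces=traces[0])


def run_trial(cond: ConditionParams, seed: int | np.random.Generator) -> TrialResult:
    """Simulate one trial of the two-component model.

    Arbitrary trials: the SMA race decides; its traces are both the deciding
    and the recorded (SMA) traces.  Deliberate trials: the value (Region X)
    race decides while the thresholdless SMA pair integrates alongside and
    is truncated at the value pair's crossing.
    """
    sim = simulate_condition(cond, 1, seed, keep_traces=True)
    idx = sim.crossing_indices[0]
    return TrialResult(
        winner=str(sim.winners[0]),
        rt=float(sim.rts[0]),
        crossing_index=int(idx) if idx >= 0 else None,
        deciding_traces=sim.deciding_traces[0],
        sma_traces=sim.sma_traces[0],
    )


@dataclass
class _FullSimulation(ConditionSimulation):
    deciding_traces: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


def simulate_condition(
    cond: ConditionParams,
    n_runs: int,
    seed: int | np.random.Generator,
    keep_traces: bool = True,
) -> ConditionSimulation:
    """Simulate ``n_runs`` independent trials of one condition.

    With ``keep_traces=False`` only RTs and winners are produced (the fast
    path used by the grid-search fit).  Undecided trials (no crossing before
    ``t_max``, the analogue of the 20 s no-response rule) get winner
    ``'none'`` and RT nan; their count is logged.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    rng_value, rng_sma = rng.spawn(2)
    deciding_rng = rng_value if cond.decision_type == "deliberate" else rng_sma
    winner, crossing, traces = _race_batch(
        cond.congruent, cond.incongruent, n_runs, deciding_rng, keep_traces
    )
    rts = np.where(crossing >= 0, crossing * cond.congruent.dt, np.nan)
    winners = np.array([_CODE_TO_WINNER[int(w)] for w in winner])
    n_undecided = int((winner == 0).sum())
    if n_undecided:
        logger.info(
            "%s-%s: %d/%d trials undecided before t_max",
            cond.decision_type,
            cond.difficulty,
            n_undecided,
            n_runs,
        )
    if not keep_traces:
        return ConditionSimulation(rts=rts, winners=winners, crossing_indices=crossing)

    if cond.decision_type == "deliberate":
        sma_traces = _sma_batch(cond, crossing, rng_sma)
    else:
        sma_traces = traces
    sim = _FullSimulation(
        rts=rts,
        winners=winners,
        sma_traces=sma_traces,
        crossing_indices=crossing,
        deciding_traces=traces,
    )
    return sim


def noiseless_crossing_time(I: float, k: float, threshold: float) -> float:
    """Closed-form first-passage time of the noiseless leaky integrator.

    Continuous solution x(t) = (I/k)(1 - exp(-k t)) reaches ``threshold`` at
    t* = -ln(1 - threshold*k/I)/k, provided threshold*k/I < 1 (otherwise the
    asymptote I/k lies below threshold and the integrator never crosses:
    returns inf).  For k = 0 the ramp crosses at threshold/I.
    """
    if I <= 0:
        return math.inf
    if k == 0:
        return threshold / I
    r = threshold * k / I
    if r >= 1:
        return math.inf
    return -math.log(1.0 - r) / k
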
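"""Fitting condition parameters to RT distributions and consistency.

The fit target per condition is twofold: the cumulative RT distribution,
summarised by a 2-parameter gamma CDF fitted on a fixed time grid, and the
choice-consistency score (fraction of congruent choices).  The misfit is

* RT error: one minus the ratio of the areas under the pointwise minimum
  and maximum of the two gamma-fitted CDF curves (intersection over union),
* consistency error: |empirical - model consistency|,
* overall error: the mean of the two (equal weights).

Parameters are found by an exhaustive, iteratively zooming grid search:
each of the four free parameters (congruent drift, incongruent drift as a
fraction of the congruent one, leak, noise scale; the threshold stays fixed
at 0.3) is sampled at five equally spaced points, the 5^4 grid is evaluated
with a fixed number of model runs per entry, and the search zooms in on the
interval between the two neighbours of the argmin until every parameter
range is narrower than 0.025 or the error falls below 0.025.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from driftrace import ddm_core
from driftrace.ddm_core import ConditionParams, condition_from_entry, simulate_condition

logger = logging.getLogger("driftrace")

#: Fixed evaluation grid for CDF overlap: 0-20 s at 1 ms spacing.
CDF_GRID = np.round(np.arange(0, 20001) * 0.001, 3)


class DegenerateConditionError(ValueError):
    """Raised when a parameter set yields too few decided trials to score."""


@dataclass
class RtCdf:
    """A cumulative RT distribution on the fixed grid.

    ``gamma_params`` is (shape, scale) of the fitted gamma, or None for
    curves that are themselves averages of fitted CDFs.
    """

    grid: np.ndarray
    values: np.ndarray
    gamma_params: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must have the same shape")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValueError("CDF values must lie in [0, 1]")
        if np.any(np.diff(self.values) < -1e-9):
            raise ValueError("CDF values must be non-decreasing")


@dataclass
class ConditionFit:
    """Best-fitting parameter set for one condition with its errors."""

    params: ConditionParams
    rt_error: float
    consistency_error: float
    overall_error: float
    n_runs_per_eval: int
    search_trace: list[dict] = field(default_factory=list)


def fit_gamma_cdf(rts: Sequence[float], grid: np.ndarray | None = None) -> RtCdf:
    """Fit a 2-parameter gamma to the empirical cumulative RT distribution.

    The (shape, scale) pair minimises the summed squared deviation between
    the gamma CDF and the empirical CDF evaluated on the fixed grid.
    Requires at least 10 finite, positive RTs with nonzero spread.
    """
    if grid is None:
        grid = CDF_GRID
    rts = np.asarray(rts, dtype=float)
    rts = rts[np.isfinite(rts) & (rts > 0)]
    if rts.size < 10:
        raise ValueError(f"need >= 10 finite positive RTs, got {rts.size}")
    if np.ptp(rts) == 0:
        raise ValueError("degenerate (constant) RT sample")
    # objective on a uniform 10-fold subsample of the grid: the SSE is a
    # Riemann-sum approximation either way, and the subsample leaves the
    # argmin unchanged to well below the optimizer tolerance
    ogrid = grid[::10]
    ecdf = np.searchsorted(np.sort(rts), ogrid, side="right") / rts.size

    m, v = rts.mean(), rts.var()
    shape0 = max(m * m / v, 1e-3)
    scale0 = v / m

    def sse(logp: np.ndarray) -> float:
        shape, scale = np.exp(logp)
        return float(np.sum((stats.gamma.cdf(ogrid, shape, scale=scale) - ecdf) ** 2))

    res = optimize.minimize(
        sse,
        np.log([shape0, scale0]),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-9, "maxiter": 200},
    )
    shape, scale = np.exp(res.x)
    values = stats.gamma.cdf(grid, shape, scale=scale)
    return RtCdf(grid=grid, values=values, gamma_params=(float(shape), float(scale)))


def rt_distribution_error(a: RtCdf, b: RtCdf) -> float:
    """Intersection-over-union misfit of two cumulative distributions.

    error = 1 - sum(min(a, b)) / sum(max(a, b)) over the shared grid;
    symmetric, in [0, 1], and 0 iff the curves coincide on the grid.
    """
    if a.grid.shape != b.grid.shape or not np.allclose(a.grid, b.grid):
        raise ValueError("CDFs must share the same grid")
    lo = np.minimum(a.values, b.values).sum()
    hi = np.maximum(a.values, b.values).sum()
    if hi == 0:
        return 0.0
    return float(1.0 - lo / hi)


def average_rt_cdfs(cdfs: Sequence[RtCdf]) -> RtCdf:
    """Pointwise average of gamma-fitted CDFs (the across-subject target)."""
    if not cdfs:
        raise ValueError("need at least one CDF")
    grid = cdfs[0].grid
    for c in cdfs[1:]:
        if not np.allclose(c.grid, grid):
            raise ValueError("CDFs must share the same grid")
    values = np.mean([c.values for c in cdfs], axis=0)
    return RtCdf(grid=grid, values=values, gamma_params=None)


def condition_error(
    cond: ConditionParams,
    target_cdf: RtCdf,
    target_consistency: float,
    n_runs: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float]:
    """Simulate a condition and score it against the fit targets.

    Returns (rt_error, consistency_error, overall_error).  Raises
    :class:`DegenerateConditionError` when fewer than 10 trials decide
    before the simulation cap.
    """
    if n_runs < 100:
        raise ValueError("n_runs must be >= 100")
    if not 0 <= target_consistency <= 1:
        raise ValueError("target_consistency must be a probability")
    sim = simulate_condition(cond, n_runs, seed, keep_traces=False)
    decided = np.isfinite(sim.rts)
    if decided.sum() < 10:
        raise DegenerateConditionError(
            f"only {int(decided.sum())}/{n_runs} trials decided"
        )
    model_cdf = fit_gamma_cdf(sim.rts[decided], grid=target_cdf.grid)
    rt_err = rt_distribution_error(model_cdf, target_cdf)
    cons_err = abs(target_consistency - sim.consistency)
    return rt_err, cons_err, (rt_err + cons_err) / 2.0


@dataclass
class GridSearchConfig:
    """Search box and schedule for the zooming grid search.

    The incongruent drift is parameterised as a fraction of the congruent
    one and the fraction axis keeps its relative meaning at every zoom
    level.  Common random numbers (one seed for every entry) damp the
    simulation noise between neighbouring entries.
    """

    decision_type: str = "deliberate"
    difficulty: str = "easy"
    i_congruent_range: tuple[float, float] = (0.05, 0.4)
    incongruent_fraction_range: tuple[float, float] = (0.2, 1.0)
    k_range: tuple[float, float] = (0.2, 0.55)
    c_range: tuple[float, float] = (0.01, 0.3)
    n_points: int = 5
    n_runs: int = 1000
    seed: int = 0
    threshold: float = ddm_core.THRESHOLD
    dt: float = ddm_core.DT
    t_max: float = ddm_core.T_MAX
    stop_range: float = 0.025
    stop_error: float = 0.025
    max_levels: int = 10


def _zoom(axis: np.ndarray, i: int, name: str) -> tuple[float, float]:
    if i == 0 or i == axis.size - 1:
        logger.warning("grid-search argmin on boundary of %s axis", name)
    lo = axis[max(i - 1, 0)]
    hi = axis[min(i + 1, axis.size - 1)]
    return float(lo), float(hi)


def grid_search_fit(
    target_cdf: RtCdf,
    target_consistency: float,
    config: GridSearchConfig | None = None,
) -> ConditionFit:
    """Iteratively zooming exhaustive grid search over the 4 free parameters.

    Every level evaluates the full n_points^4 grid with ``config.n_runs``
    simulated trials per entry; the next level spans the interval between
    the left and right neighbours of the argmin on each axis.  Stops when
    every parameter range is narrower than ``stop_range``, the best error
    drops below ``stop_error``, or ``max_levels`` is reached.
    """
    cfg = config or GridSearchConfig()
    ranges = {
        "I_congruent": cfg.i_congruent_range,
        "incongruent_fraction": cfg.incongruent_fraction_range,
        "k": cfg.k_range,
        "c": cfg.c_range,
    }
    trace: list[dict] = []
    best: tuple[float, float, float] | None = None
    best_entry: dict | None = None

    for level in range(cfg.max_levels):
        axes = {
            name: np.linspace(lo, hi, cfg.n_points) for name, (lo, hi) in ranges.items()
        }
        level_best = np.inf
        level_best_idx: tuple[int, int, int, int] | None = None
        level_best_errs: tuple[float, float, float] | None = None
        for a, Ic in enumerate(axes["I_congruent"]):
            for b, f in enumerate(axes["incongruent_fraction"]):
                for g, k in enumerate(axes["k"]):
                    for d, c in enumerate(axes["c"]):
                        cond = condition_from_entry(
                            cfg.decision_type,
                            cfg.difficulty,
                            Ic,
                            Ic * f,
                            k,
                            c,
                            threshold=cfg.threshold,
                            dt=cfg.dt,
                            t_max=cfg.t_max,
                        )
                        try:
                            errs = condition_error(
                                cond,
                                target_cdf,
                                target_consistency,
                                n_runs=cfg.n_runs,
                                seed=cfg.seed,
                            )
                        except DegenerateConditionError:
                            errs = (1.0, 1.0, 1.0)
                        if errs[2] < level_best:
                            level_best = errs[2]
                            level_best_idx = (a, b, g, d)
                            level_best_errs = errs
        assert level_best_idx is not None and level_best_errs is not None
        a, b, g, d = level_best_idx
        entry = {
            "I_congruent": float(axes["I_congruent"][a]),
            "incongruent_fraction": float(axes["incongruent_fraction"][b]),
            "k": float(axes["k"][g]),
            "c": float(axes["c"][d]),
        }
        trace.append(
            {
                "level": level,
                "ranges": {k_: tuple(map(float, v)) for k_, v in ranges.items()},
                "best_entry": entry,
                "rt_error": level_best_errs[0],
                "consistency_error": level_best_errs[1],
                "overall_error": level_best_errs[2],
            }
        )
        if best is None or level_best_errs[2] < best[2]:
            best, best_entry = level_best_errs, entry

        ranges = {
            "I_congruent": _zoom(axes["I_congruent"], a, "I_congruent"),
            "incongruent_fraction": _zoom(
                axes["incongruent_fraction"], b, "incongruent_fraction"
            ),
            "k": _zoom(axes["k"], g, "k"),
            "c": _zoom(axes["c"], d, "c"),
        }
        widths = [hi - lo for lo, hi in ranges.values()]
        if best[2] < cfg.stop_error or all(w < cfg.stop_range for w in widths):
            break

    assert best is not None and best_entry is not None
    params = condition_from_entry(
        cfg.decision_type,
        cfg.difficulty,
        best_entry["I_congruent"],
        best_entry["I_congruent"] * best_entry["incongruent_fraction"],
        best_entry["k"],
        best_entry["c"],
        threshold=cfg.threshold,
        dt=cfg.dt,
        t_max=cfg.t_max,
    )
    return ConditionFit(
        params=params,
        rt_error=best[0],
        consistency_error=best[1],
        overall_error=best[2],
        n_runs_per_eval=cfg.n_runs,
        search_trace=trace,
    )
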
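"""Dose-response and platform-control fitting with identifiability diagnostics.

The dose-response objective compares observed and simulated log10 geometric
means of the input-proxy (IFP) and output (OFP) channels of gated
populations, summed over the conditions of an inducer titration at a single
Flp:shRNA ratio.  Simulations inside the objective use common random numbers
(a fixed substream per condition), so the objective is a smooth deterministic
function of the parameters and standard bounded least squares applies.

Identifiability is probed two ways, mirroring how over-parameterized circuit
models are usually diagnosed:

* a multistart landscape — repeated fits from log-uniform random starts,
  tabulating where each start lands;
* a ridge scan over the (b_f, K_d) plane — for each recombinase production
  rate b_f, the titration softness K_d is profiled with all other parameters
  frozen, and a line is fitted to the (log b_f, log K_d) ridge of profile
  minima.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from . import flow_io
from .digitizer_model import ModelParams, PlatformParams, simulate_population
from .flow_io import Condition, ExperimentTable, SamplePopulation, Topology
from .population_metrics import geometric_stats
from .synthetic_data import (
    DEFAULT_CFP_NG, DEFAULT_REPORTER_NG, UptakeParams, condition_seed,
)

logger = logging.getLogger("digitizer_lab")

__all__ = [
    "FitConfig", "FitResult", "LandscapeTable", "RidgeScan",
    "PlatformFitResult", "fit_dose_response", "fit_platform_controls",
    "multistart_landscape", "ridge_scan", "dose_response_loss",
]

#: Parameters treated as rates (log-uniform bounds around their defaults).
RATE_BOUND_DECADES = 4.0
HILL_BOUNDS = (1.0, 4.0)
HILL_PARAMS = ("n_dox", "n_rep", "h_rec")


@dataclass
class FitConfig:
    """Options shared by the fitting routines.

    ``fit_params`` names the :class:`ModelParams` fields optimized; all other
    fields stay at the start parameters.  ``n_cells_sim`` controls the size
    of each simulated population inside the objective (larger = smoother
    objective, slower fit).
    """

    fit_params: tuple[str, ...] = ("a_f", "b_f", "K_d", "c")
    plat: PlatformParams = field(default_factory=PlatformParams)
    uptake: UptakeParams = field(default_factory=UptakeParams)
    reporter_ng: float = DEFAULT_REPORTER_NG
    cfp_ng: float = DEFAULT_CFP_NG
    n_cells_sim: int = 2000
    gate_fraction: float = 0.30
    gate_channel: str = "cfp"
    floor: float = flow_io.DEFAULT_FLOOR_MEFL
    channels: tuple[str, ...] = ("ifp", "ofp")
    channel_weights: tuple[float, ...] = (1.0, 1.0)
    max_nfev: int = 200


@dataclass
class FitResult:
    params: ModelParams
    loss: float
    n_iter: int
    start_id: int
    converged: bool
    message: str = ""


@dataclass
class LandscapeRow:
    start_id: int
    initial: dict[str, float]
    final: dict[str, float]
    loss: float
    converged: bool


@dataclass
class LandscapeTable:
    """Multistart endpoints, sorted by final loss (best first)."""

    rows: list[LandscapeRow]

    @property
    def best(self) -> LandscapeRow:
        return self.rows[0]

    def to_dataframe(self):
        import pandas as pd

        records = []
        for row in self.rows:
            rec = {"start_id": row.start_id, "loss": row.loss,
                   "converged": row.converged}
            rec.update({f"init_{k}": v for k, v in row.initial.items()})
            rec.update({f"final_{k}": v for k, v in row.final.items()})
            records.append(rec)
        return pd.DataFrame(records)


@dataclass
class RidgeScan:
    """Profiled (b_f, K_d) landscape and the fitted log-log ridge line."""

    b_f_values: np.ndarray
    K_d_values: np.ndarray
    loss_grid: np.ndarray            # shape (len(b_f), len(K_d))
    ridge_points: list[tuple[float, float]]
    excluded_b_f: list[float]
    slope: float
    intercept: float
    r_squared: float


@dataclass
class PlatformFitResult:
    """Fitted platform constants plus the delay-model comparison."""

    params: PlatformParams
    rss_gaussian: float
    rss_uniform: float
    n_timepoints: int

    @property
    def gaussian_preferred(self) -> bool:
        return self.rss_gaussian < self.rss_uniform


# ---------------------------------------------------------------------------
# Objective machinery


def _gated_log_geomeans(pop: SamplePopulation, config: FitConfig) -> dict[str, float]:
    pop = flow_io.filter_valid_events(pop, config.floor)
    pop = flow_io.gate_top_fraction(pop, config.gate_channel, config.gate_fraction)
    out = {}
    for ch in config.channels:
        vals = np.maximum(pop.channel(ch), config.floor)
        out[ch] = float(np.log10(geometric_stats(vals)[0]))
    return out


def _observed_summaries(table: ExperimentTable, config: FitConfig):
    return [(pop.condition, _gated_log_geomeans(pop, config)) for pop in table]


def _simulated_summary(
    params: ModelParams, cond: Condition, config: FitConfig, seed: int
) -> dict[str, float]:
    doses = {"flp": cond.flp_ng, "shrna": cond.shrna_ng,
             "reporter": config.reporter_ng, "cfp": config.cfp_ng}
    pop = simulate_population(
        config.n_cells_sim, doses, cond.dox_nM, cond.topology, params,
        config.plat, config.uptake, t=cond.time_h,
        seed=condition_seed(seed, cond), replicate=cond.replicate)
    return _gated_log_geomeans(pop, config)


def _residuals(
    params: ModelParams, observed, config: FitConfig, seed: int
) -> np.ndarray:
    res = []
    for cond, obs in observed:
        sim = _simulated_summary(params, cond, config, seed)
        for ch, w in zip(config.channels, config.channel_weights):
            res.append(np.sqrt(w) * (sim[ch] - obs[ch]))
    return np.asarray(res)


def dose_response_loss(
    params: ModelParams,
    table: ExperimentTable,
    config: FitConfig | None = None,
    seed: int = 0,
) -> float:
    """Sum of squared log10-geomean residuals of ``params`` against ``table``."""
    config = config or FitConfig()
    observed = _observed_summaries(table, config)
    r = _residuals(params, observed, config, seed)
    return float(np.sum(r * r))


def _param_bounds(name: str, default: float) -> tuple[float, float]:
    if name in HILL_PARAMS:
        return HILL_BOUNDS
    return (default * 10.0 ** -RATE_BOUND_DECADES,
            default * 10.0 ** RATE_BOUND_DECADES)


def _validate_dose_response(table: ExperimentTable, topology: Topology) -> None:
    conds = [pop.condition for pop in table]
    if any(c.topology is not topology for c in conds):
        raise ValueError("table contains conditions of a different topology")
    dox_levels = sorted({c.dox_nM for c in conds})
    if len(dox_levels) < 4:
        raise ValueError("dose-response fit requires >= 4 dox levels")
    if 0.0 not in dox_levels:
        raise ValueError("dose-response fit requires the uninduced (dox = 0) "
                         "conditions")
    ratios = {(c.flp_ng, c.shrna_ng) for c in conds}
    if len(ratios) != 1:
        raise ValueError("dose-response fit requires a single Flp:shRNA ratio")
    times = {c.time_h for c in conds}
    if len(times) != 1:
        raise ValueError("dose-response fit requires a single time point")


def fit_dose_response(
    table: ExperimentTable,
    topology: Topology,
    config: FitConfig | None = None,
    seed: int = 0,
    start: ModelParams | None = None,
    start_id: int = 0,
) -> FitResult:
    """Fit kinetic parameters to an inducer titration.

    Bounded least squares on log10-transformed parameters, minimizing the sum
    of squared differences between observed and simulated log10 geometric
    means of the gated IFP and OFP signals.  Deterministic given ``seed``;
    the returned loss never exceeds the loss at the start point.
    """
    config = config or FitConfig()
    _validate_dose_response(table, topology)
    start = start or ModelParams()
    observed = _observed_summaries(table, config)

    obs_matrix = np.array([[obs[ch] for ch in config.channels]
                           for _, obs in observed])
    degenerate = bool(np.allclose(obs_matrix, obs_matrix[0], atol=1e-6))
    if degenerate:
        warnings.warn("all observed summaries are identical; the fit is "
                      "unidentifiable", stacklevel=2)

    defaults = ModelParams()
    names = list(config.fit_params)
    x0 = np.log10([getattr(start, n) for n in names])
    lo, hi = zip(*[_param_bounds(n, getattr(defaults, n)) for n in names])
    lo = np.log10(lo)
    hi = np.log10(hi)
    x0 = np.clip(x0, lo, hi)

    def params_at(x: np.ndarray) -> ModelParams:
        return replace(start, **{n: float(10.0 ** xi) for n, xi in zip(names, x)})

    def fun(x: np.ndarray) -> np.ndarray:
        return _residuals(params_at(x), observed, config, seed)

    result = optimize.least_squares(
        fun, x0, bounds=(lo, hi), method="trf",
        diff_step=1e-3, max_nfev=config.max_nfev)

    loss0 = float(np.sum(fun(x0) ** 2))
    loss = float(2.0 * result.cost)
    if loss > loss0:  # monotone improvement contract
        x_best, loss = x0, loss0
    else:
        x_best = result.x
    return FitResult(
        params=params_at(x_best), loss=loss, n_iter=int(result.nfev),
        start_id=start_id, converged=bool(result.success) and not degenerate,
        message=str(result.message))


# ---------------------------------------------------------------------------
# Platform controls


def _control_log_geomeans(
    gamma: float, mu_delay: float, sd_delay: float, delta_p: float,
    times: np.ndarray, n_cells: int, uptake: UptakeParams, seed: int,
    uniform_delay: bool, gate_fraction: float, floor: float,
) -> np.ndarray:
    """Simulated gated log10 geomean CFP of a constitutive control at each time."""
    out = np.empty(len(times))
    for i, t in enumerate(times):
        rng = np.random.default_rng([seed, i])
        total = np.rint(10.0 ** rng.normal(
            uptake.mu_uptake, uptake.sd_uptake, n_cells)).astype(np.int64)
        if uniform_delay:
            delays = rng.uniform(0.0, 2.0 * mu_delay, n_cells)
        else:
            delays = np.maximum(rng.normal(mu_delay, sd_delay, n_cells), 0.0)
        tau = np.clip(t - delays, 0.0, None)
        if delta_p > 1e-12:
            accum = (1.0 - np.exp(-delta_p * tau)) / delta_p
        else:
            accum = tau
        cfp_true = gamma * total * accum
        af = uptake.autofluorescence_mu * 10.0 ** rng.normal(0.0, 0.2, n_cells)
        cfp = np.maximum((cfp_true + af) * 10.0 ** rng.normal(0.0, uptake.sigma_m,
                                                              n_cells), floor)
        k = int(np.ceil(gate_fraction * n_cells))
        top = np.sort(cfp)[-k:]
        out[i] = np.log10(geometric_stats(top)[0])
    return out


def fit_platform_controls(
    controls: ExperimentTable,
    uptake: UptakeParams | None = None,
    gate_fraction: float = 0.30,
    floor: float = flow_io.DEFAULT_FLOOR_MEFL,
    seed: int = 0,
) -> PlatformFitResult:
    """Fit platform constants to a constitutive single-color time series.

    Least squares on the log10 geometric means of the gated constitutive
    channel across time points; fits gamma, mu_delay, sd_delay and delta_p
    under Gaussian onset delays, refits under the alternative
    Uniform(0, 2 * mu_delay) delays, and reports which residual is lower
    (the uniform alternative corresponds to cell division driving plasmid
    availability; Gaussian to exogenous factors such as cell health).
    """
    uptake = uptake or UptakeParams()
    pops = sorted(controls, key=lambda pop: pop.condition.time_h)
    times = np.array([pop.condition.time_h for pop in pops])
    if len(np.unique(times)) < 3:
        raise ValueError("platform fit requires >= 3 distinct time points")
    n_cells = max(len(pop) for pop in pops)

    obs = np.empty(len(pops))
    for i, pop in enumerate(pops):
        pop = flow_io.filter_valid_events(pop, floor)
        gated = flow_io.gate_top_fraction(pop, "cfp", gate_fraction)
        obs[i] = np.log10(geometric_stats(np.maximum(gated.channel("cfp"),
                                                     floor))[0])

    def rss(x: np.ndarray, uniform: bool) -> float:
        gamma, mu_delay, log_sd, log_dp = x
        if gamma <= 0 or mu_delay <= 0 or mu_delay >= times.max():
            return 1e6
        sim = _control_log_geomeans(
            gamma, mu_delay, 10.0 ** log_sd, 10.0 ** log_dp, times, n_cells,
            uptake, seed, uniform, gate_fraction, floor)
        return float(np.sum((sim - obs) ** 2))

    x0 = np.array([PlatformParams().gamma, PlatformParams().mu_delay,
                   np.log10(PlatformParams().sd_delay), -4.0])

    def minimize(uniform: bool):
        res = optimize.minimize(
            rss, x0, args=(uniform,), method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 600})
        return res.x, float(res.fun)

    xg, rss_g = minimize(False)
    _, rss_u = minimize(True)
    params = PlatformParams(
        gamma=float(xg[0]), mu_delay=float(xg[1]),
        sd_delay=float(10.0 ** xg[2]), delta_p=float(10.0 ** xg[3]))
    return PlatformFitResult(params=params, rss_gaussian=rss_g,
                             rss_uniform=rss_u, n_timepoints=len(np.unique(times)))


# ---------------------------------------------------------------------------
# Identifiability diagnostics


def multistart_landscape(
    table: ExperimentTable,
    topology: Topology,
    n_starts: int,
    seed: int = 0,
    config: FitConfig | None = None,
) -> LandscapeTable:
    """Fit from ``n_starts`` log-uniform random starts within the bounds."""
    if n_starts < 2:
        raise ValueError("n_starts must be >= 2")
    config = config or FitConfig()
    defaults = ModelParams()
    rng = np.random.default_rng(seed)

    rows = []
    for start_id in range(n_starts):
        draw = {}
        for name in config.fit_params:
            lo, hi = _param_bounds(name, getattr(defaults, name))
            draw[name] = float(10.0 ** rng.uniform(np.log10(lo), np.log10(hi)))
        start = replace(defaults, **draw)
        try:
            fit = fit_dose_response(table, topology, config=config, seed=seed,
                                    start=start, start_id=start_id)
            final = {n: getattr(fit.params, n) for n in config.fit_params}
            rows.append(LandscapeRow(start_id, draw, final, fit.loss,
                                     fit.converged))
        except Exception as exc:  # recorded, not fatal
            logger.warning("multistart %d failed: %s", start_id, exc)
            rows.append(LandscapeRow(start_id, draw, {}, float("inf"), False))
    rows.sort(key=lambda row: row.loss)
    return LandscapeTable(rows)


def _refine_profile_min(logK: np.ndarray, losses: np.ndarray) -> float:
    """Parabolic refinement of the profile minimum in log10 K_d."""
    i = int(np.argmin(losses))
    if i == 0 or i == len(losses) - 1:
        return float(logK[i])
    x0, x1, x2 = logK[i - 1: i + 2]
    y0, y1, y2 = losses[i - 1: i + 2]
    denom = (y0 - 2 * y1 + y2)
    if denom <= 0:
        return float(logK[i])
    return float(x1 + 0.5 * (y0 - y2) / denom * (x2 - x1))


def ridge_scan(
    table: ExperimentTable,
    topology: Topology,
    grid: tuple,
    base_params: ModelParams,
    config: FitConfig | None = None,
    seed: int = 0,
) -> RidgeScan:
    """Profile K_d against b_f with all other parameters frozen.

    For each b_f value the loss is evaluated over the K_d grid (parabolic
    refinement around the grid minimum); b_f columns with a flat profile or
    a boundary minimum are flagged and excluded from the ridge line, which is
    fitted to the remaining (log10 b_f, log10 K_d) minima.
    """
    config = config or FitConfig()
    b_f_values = np.asarray(grid[0], float)
    K_d_values = np.asarray(grid[1], float)
    if b_f_values.size < 5 or K_d_values.size < 5:
        raise ValueError("ridge scan requires grids of >= 5 values each")
    observed = _observed_summaries(table, config)
    logK = np.log10(K_d_values)

    loss_grid = np.empty((b_f_values.size, K_d_values.size))
    ridge_points: list[tuple[float, float]] = []
    excluded: list[float] = []
    for i, b_f in enumerate(b_f_values):
        for j, K_d in enumerate(K_d_values):
            params = replace(base_params, b_f=float(b_f), K_d=float(K_d))
            r = _residuals(params, observed, config, seed)
            loss_grid[i, j] = float(np.sum(r * r))
        losses = loss_grid[i]
        jmin = int(np.argmin(losses))
        flat = (losses.max() - losses.min()) <= 1e-9 * max(losses.max(), 1e-30)
        if flat or jmin == 0 or jmin == K_d_values.size - 1:
            excluded.append(float(b_f))
            continue
        ridge_points.append((float(b_f), float(10.0 ** _refine_profile_min(
            logK, losses))))

    if len(ridge_points) >= 2:
        xs = np.log10([p[0] for p in ridge_points])
        ys = np.log10([p[1] for p in ridge_points])
        fit = stats.linregress(xs, ys)
        slope, intercept, r2 = fit.slope, fit.intercept, fit.rvalue ** 2
    else:
        slope = intercept = r2 = float("nan")
    return RidgeScan(
        b_f_values=b_f_values, K_d_values=K_d_values, loss_grid=loss_grid,
        ridge_points=ridge_points, excluded_b_f=excluded,
        slope=float(slope), intercept=float(intercept), r_squared=float(r2))
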
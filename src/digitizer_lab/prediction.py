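"""Forward prediction of digitizer performance.

Three prediction modes:

* sweep a grid of Flp:shRNA plasmid ratios and compute the full metric set
  (FC, AUC, SNR and delta-SNR between the input-proxy and output channels)
  at every grid point — the in-silico analogue of a component-ratio
  heatmap experiment;
* transduce an empirical per-cell input distribution through a chosen
  configuration (the phenotypic half of the mixed model): each measured
  input value is converted to a per-cell promoter flux that replaces the
  inducer Hill term, and the predicted output distribution is collected;
* compare predicted and observed metric tables (Pearson correlation and
  mean absolute error over matched grid points).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .digitizer_model import (
    ModelParams, PlatformParams, _endpoint_true, _measure, shrna_flux,
)
from .flow_io import Condition, SamplePopulation, Topology, filter_valid_events, gate_top_fraction
from .population_metrics import DeltaReport, MetricSet, delta_metrics, metric_set
from .synthetic_data import (
    DEFAULT_CFP_NG, DEFAULT_REPORTER_NG, UptakeParams, _sample_dose_arrays,
    condition_seed,
)

__all__ = [
    "MetricHeatmap", "HeatmapCell", "ComparisonReport",
    "sweep_ratio_grid", "transduce_distribution", "compare_predicted_observed",
    "DEFAULT_ON_THRESHOLD_MEFL",
]

#: Threshold used when classifying cells as ON by raw output fluorescence:
#: one decade above the autofluorescence background (~1e2 MEFL), the usual
#: positive-gate convention for a reporter with a large dynamic range.
DEFAULT_ON_THRESHOLD_MEFL = 1.0e3

#: Ceiling on the activation Hill level used when inverting a measured input
#: back to an equivalent inducer concentration: above this level the proxy is
#: saturated and the inversion is ill-conditioned.
HILL_INVERSION_CAP = 0.95


@dataclass
class HeatmapCell:
    flp_ng: float
    shrna_ng: float
    ofp: MetricSet
    ifp: MetricSet
    delta: DeltaReport | None


@dataclass
class MetricHeatmap:
    """Metric sets over a (flp_ng, shrna_ng) grid."""

    flp_values: np.ndarray
    shrna_values: np.ndarray
    cells: list[HeatmapCell]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for cell in self.cells:
            rows.append({
                "flp_ng": cell.flp_ng,
                "shrna_ng": cell.shrna_ng,
                "fc": cell.ofp.fc,
                "auc": cell.ofp.auc,
                "snr_db": cell.ofp.snr.snr_db,
                "delta_snr_db": (cell.delta.delta_snr_db
                                 if cell.delta is not None else np.nan),
            })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ComparisonReport:
    pearson_r: float
    mean_abs_error: float
    n_points: int


def sweep_ratio_grid(
    p: ModelParams,
    plat: PlatformParams,
    flp_list,
    shrna_list,
    topology: Topology,
    dox_pair: tuple[float, float] = (225.0, 0.0),
    t: float = 48.0,
    n_cells: int = 2000,
    seed: int = 0,
    uptake: UptakeParams | None = None,
    reporter_ng: float = DEFAULT_REPORTER_NG,
    cfp_ng: float = DEFAULT_CFP_NG,
    gate_fraction: float = 0.30,
) -> MetricHeatmap:
    """Simulate induced/uninduced pairs over a Flp:shRNA ratio grid.

    At every grid point an induced and an uninduced population are simulated,
    gated on the constitutive channel, and scored: the output (OFP) metric
    set, the input-proxy (IFP) metric set, and their difference.  Seeded and
    reproducible; each grid point uses its own substream.
    """
    from .digitizer_model import simulate_population

    uptake = uptake or UptakeParams()
    flp_values = np.asarray(flp_list, float)
    shrna_values = np.asarray(shrna_list, float)
    if flp_values.size == 0 or shrna_values.size == 0:
        raise ValueError("grids must be non-empty")

    def gated(flp_ng, shrna_ng, dox):
        doses = {"flp": flp_ng, "shrna": shrna_ng,
                 "reporter": reporter_ng, "cfp": cfp_ng}
        cond = Condition(topology=topology, flp_ng=flp_ng, shrna_ng=shrna_ng,
                         dox_nM=dox, time_h=t)
        pop = simulate_population(
            n_cells, doses, dox, topology, p, plat, uptake, t=t,
            seed=condition_seed(seed, cond))
        return gate_top_fraction(filter_valid_events(pop), "cfp", gate_fraction)

    cells = []
    for flp_ng in flp_values:
        for shrna_ng in shrna_values:
            induced = gated(float(flp_ng), float(shrna_ng), dox_pair[0])
            uninduced = gated(float(flp_ng), float(shrna_ng), dox_pair[1])
            ofp_ms = metric_set(induced, uninduced, channel="ofp", seed=seed)
            ifp_ms = metric_set(induced, uninduced, channel="ifp", seed=seed)
            delta = None
            if ofp_ms.snr.defined and ifp_ms.snr.defined:
                delta = delta_metrics(ifp_ms, ofp_ms)
            cells.append(HeatmapCell(float(flp_ng), float(shrna_ng),
                                     ofp_ms, ifp_ms, delta))
    return MetricHeatmap(flp_values, shrna_values, cells)


def transduce_distribution(
    ifp_samples,
    p: ModelParams,
    plat: PlatformParams,
    topology: Topology,
    ratio: tuple[float, float],
    t: float = 72.0,
    seed: int = 0,
    uptake: UptakeParams | None = None,
    reporter_ng: float = DEFAULT_REPORTER_NG,
    cfp_ng: float = DEFAULT_CFP_NG,
    input_reference_copies: float = 10.0,
    input_window_h: float | None = None,
) -> SamplePopulation:
    """Predict the output distribution for a measured per-cell input signal.

    Each input fluorescence value is inverted through the input-proxy
    production model to a per-copy promoter activity,

        activity = max(0, ifp - autofluorescence) / (b_i * window * N_ref),

    clipped at the maximal promoter rate ``b_f`` (promoter saturation), where
    ``N_ref`` (``input_reference_copies``) is the nominal inducible-plasmid
    copy number of the configuration on which the input was measured and
    ``window`` the accumulation time of the input measurement (default
    ``t - mu_delay``).  The activity is held constant over the simulation —
    the measured input is an endpoint proxy, so within-window input dynamics
    are not modeled.  Per-cell promoter flux ``activity * copies_flp`` then
    replaces the inducer Hill term; for the feedforward topology the shRNA
    promoter sees the equivalent inducer concentration obtained by inverting
    the activation Hill curve at that activity.

    Returns the predicted (noise-carrying) population; its ``ofp`` channel is
    the predicted digitizer output.
    """
    uptake = uptake or UptakeParams()
    ifp = np.asarray(ifp_samples, float)
    if ifp.size == 0 or np.any(ifp <= 0):
        raise ValueError("ifp_samples must be positive and non-empty")
    window = input_window_h if input_window_h is not None else t - plat.mu_delay
    if window <= 0:
        raise ValueError("input window must be positive")

    flp_ng, shrna_ng = float(ratio[0]), float(ratio[1])
    cond = Condition(topology=topology, flp_ng=flp_ng, shrna_ng=shrna_ng,
                     dox_nM=0.0, time_h=float(t))
    rng = np.random.default_rng(condition_seed(seed, cond))
    doses = {"flp": flp_ng, "shrna": shrna_ng,
             "reporter": reporter_ng, "cfp": cfp_ng}
    copies, delays = _sample_dose_arrays(ifp.size, doses, uptake, plat, rng)

    activity = np.maximum(ifp - uptake.autofluorescence_mu, 0.0)
    activity = activity / (p.b_i * window * input_reference_copies)
    activity = np.minimum(activity, p.b_f)
    m0 = activity * copies["flp"]

    # equivalent inducer level for the feedforward shRNA promoter
    span = max(p.b_f - p.a_f, 1e-12)
    hill = np.clip((activity - p.a_f) / span, 0.0, HILL_INVERSION_CAP)
    dox_eq = p.K_dox * (hill / (1.0 - hill)) ** (1.0 / p.n_dox)
    s0 = shrna_flux(dox_eq, copies["shrna"], topology, p)

    ifp_true, ofp_true, cfp_true = _endpoint_true(
        m0, s0, copies["reporter"].astype(float), copies["cfp"].astype(float),
        delays, p, plat, t)
    return SamplePopulation.from_arrays(
        cond,
        cfp=_measure(cfp_true, rng, uptake.autofluorescence_mu, uptake.sigma_m),
        ifp=_measure(ifp_true, rng, uptake.autofluorescence_mu, uptake.sigma_m),
        ofp=_measure(ofp_true, rng, uptake.autofluorescence_mu, uptake.sigma_m),
    )


def compare_predicted_observed(predicted, observed) -> ComparisonReport:
    """Pearson correlation and mean absolute error over matched grid points.

    ``predicted`` and ``observed`` are mappings (or pandas Series) from a
    shared set of keys — typically (flp_ng, shrna_ng) grid points — to metric
    values.
    """
    pred = pd.Series(dict(predicted) if not isinstance(predicted, pd.Series)
                     else predicted)
    obs = pd.Series(dict(observed) if not isinstance(observed, pd.Series)
                    else observed)
    if set(pred.index) != set(obs.index):
        raise ValueError("predicted and observed tables must share keys")
    if len(pred) < 3:
        raise ValueError("comparison requires at least 3 matched points")
    obs = obs.reindex(pred.index)
    x = pred.to_numpy(float)
    y = obs.to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance in a table")
    r = float(stats.pearsonr(x, y).statistic)
    return ComparisonReport(
        pearson_r=r,
        mean_abs_error=float(np.mean(np.abs(x - y))),
        n_points=len(pred),
    )
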
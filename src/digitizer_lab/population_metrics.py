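"""Signal-quality metrics for ON/OFF single-cell population pairs.

Three complementary metrics quantify how well a circuit separates its ON and
OFF states:

* **Fold change (FC)** — ratio of geometric means; measures amplitude only.
* **AUC** — area under the empirical ROC curve obtained by sweeping a
  threshold over the combined fluorescence range; 0.5 means the populations
  are indistinguishable, 1.0 fully distinguishable.  Equals the tie-corrected
  Mann-Whitney U statistic divided by n_pos * n_neg.
* **SNR (dB)** — signal-to-noise ratio in log10-fluorescence space.  Signal
  power is the squared distance ``delta_mu**2`` between the ON mode of the
  induced population and the OFF mode of the uninduced population (modes from
  a two-component Gaussian mixture fit to log10 values).  Noise power is the
  squared average mode SD plus a *fail power* term charging the
  misclassified subpopulations — P_Dud (cells OFF when they should be ON) and
  P_Leaky (cells ON when they should be OFF) — at full signal amplitude:

      SNR = 10 log10( delta_mu**2 / (sigma_bar**2 + (P_Dud + P_Leaky) * delta_mu**2) )

  The fail-power weighting by ``delta_mu**2`` is a dimensional choice made
  here: the fail probabilities are dimensionless, so they are scaled by the
  signal power so that a misclassified cell contributes a full-amplitude
  squared error.  With no misclassified cells and symmetric unimodal
  populations the expression reduces to the classical square-wave moment
  formula 10 log10(delta_mu**2 / sigma_bar**2).

Delta metrics (output minus input) measure how signal quality changes as a
signal propagates through a circuit; positive delta-SNR indicates
amplification.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import roc_curve
from sklearn.mixture import GaussianMixture

from .flow_io import DEFAULT_FLOOR_MEFL, SamplePopulation

__all__ = [
    "MixtureFit", "SNRReport", "MetricSet", "DeltaReport",
    "geometric_stats", "fold_change", "empirical_auc", "fit_log_mixture2",
    "snr_db", "snr_from_components", "metric_set", "delta_metrics",
    "on_fraction",
]

#: Two fitted mixture means closer than this (log10 units) are treated as a
#: single mode.
UNIMODAL_MEAN_GAP = 0.05

EM_MAX_ITER = 200
EM_TOL = 1e-8
EM_VAR_FLOOR = 1e-4  # variance floor, log10 units squared


@dataclass(frozen=True)
class MixtureFit:
    """Two-component Gaussian fit of a log10-fluorescence distribution.

    Components are sorted by mean (``mu_off <= mu_on``).  ``unimodal`` is set
    when the fitted means are closer than :data:`UNIMODAL_MEAN_GAP`; the
    dominant component then carries the weight as fitted.
    """

    w_off: float
    w_on: float
    mu_off: float
    mu_on: float
    sd_off: float
    sd_on: float
    loglik: float
    converged: bool
    unimodal: bool

    def __post_init__(self) -> None:
        if abs(self.w_off + self.w_on - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if self.mu_on < self.mu_off:
            raise ValueError("components must be sorted by mean")
        if self.sd_off <= 0 or self.sd_on <= 0:
            raise ValueError("component SDs must be > 0")

    @property
    def dominant_is_on(self) -> bool:
        return self.w_on >= self.w_off


@dataclass(frozen=True)
class SNRReport:
    """Extended SNR decomposition for one induced/uninduced pair.

    ``snr_db`` is ``-inf`` (with ``defined`` False) when the signal
    amplitude vanishes.
    """

    snr_db: float
    delta_mu: float
    sigma_bar: float
    p_dud: float
    p_leaky: float
    fail_power: float

    @property
    def defined(self) -> bool:
        return math.isfinite(self.snr_db)


@dataclass(frozen=True)
class MetricSet:
    """FC, AUC and SNR for one condition pair on one channel."""

    fc: float
    auc: float
    snr: SNRReport


@dataclass(frozen=True)
class DeltaReport:
    """Output-minus-input metric differences across a circuit stage."""

    delta_snr_db: float
    delta_fc: float
    delta_auc: float


def geometric_stats(values) -> tuple[float, float]:
    """Geometric mean and geometric SD of a positive sample.

    geosd uses the sample (n-1) denominator and is 1 for n = 1.
    """
    v = np.asarray(values, float)
    if v.size < 1:
        raise ValueError("need at least one value")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValueError("geometric statistics require positive finite values")
    logs = np.log(v)
    geomean = float(np.exp(logs.mean()))
    geosd = 1.0 if v.size == 1 else float(np.exp(logs.std(ddof=1)))
    return geomean, geosd


def fold_change(on_pop, off_pop) -> float:
    """Ratio of geometric means, ON over OFF."""
    return geometric_stats(on_pop)[0] / geometric_stats(off_pop)[0]


def empirical_auc(pos, neg) -> tuple[float, np.ndarray]:
    """Empirical ROC and its area for a positive/negative sample pair.

    The ROC is built by sweeping a threshold over all distinct observed
    values (plus the two trivial endpoints); the area is the trapezoid
    integral, under which ties contribute one half, so the AUC equals the
    tie-corrected Mann-Whitney U statistic divided by n_pos * n_neg.

    Returns ``(auc, roc)`` where ``roc`` is an (k, 2) array of ordered
    (FPR, TPR) points.
    """
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both samples must be non-empty")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    scores = np.concatenate([pos, neg])
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


def fit_log_mixture2(values, seed: int = 0) -> MixtureFit:
    """Two-component Gaussian EM on log10 values, deterministic given seed.

    Initialization splits the data at its 25th/75th percentiles (means at the
    quartiles, equal weights, pooled variance), so repeated fits of the same
    data are identical.  On non-convergence the best-so-far parameters are
    returned with ``converged`` False.
    """
    v = np.asarray(values, float)
    if v.size < 10:
        raise ValueError("mixture fit requires at least 10 values")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValueError("mixture fit requires positive finite values")
    x = np.log10(v)[:, None]

    q25, q75 = np.percentile(x[:, 0], [25.0, 75.0])
    var0 = max(float(np.var(x[:, 0])) / 4.0, EM_VAR_FLOOR)
    gm = GaussianMixture(
        n_components=2,
        covariance_type="spherical",
        max_iter=EM_MAX_ITER,
        tol=EM_TOL,
        reg_covar=EM_VAR_FLOOR,
        weights_init=np.array([0.5, 0.5]),
        means_init=np.array([[q25], [q75]]),
        precisions_init=np.array([1.0 / var0, 1.0 / var0]),
        random_state=int(seed) & 0x7FFFFFFF,
    )
    with warnings.catch_warnings():
        # non-convergence is reported through the converged flag instead
        warnings.simplefilter("ignore", ConvergenceWarning)
        gm.fit(x)

    means = gm.means_[:, 0]
    sds = np.sqrt(np.maximum(gm.covariances_, EM_VAR_FLOOR))
    weights = gm.weights_
    order = np.argsort(means, kind="stable")
    mu_off, mu_on = means[order]
    sd_off, sd_on = sds[order]
    w_off, w_on = weights[order]
    w_off = float(w_off)
    return MixtureFit(
        w_off=w_off, w_on=1.0 - w_off,
        mu_off=float(mu_off), mu_on=float(mu_on),
        sd_off=float(sd_off), sd_on=float(sd_on),
        loglik=float(gm.score(x) * x.shape[0]),
        converged=bool(gm.converged_),
        unimodal=bool(mu_on - mu_off < UNIMODAL_MEAN_GAP),
    )


def _on_component(fit: MixtureFit) -> tuple[float, float, float]:
    """(mu, sd, fail_weight) of the ON mode of an induced-population fit.

    For a unimodal fit the dominant component is the mode and no weight is
    charged as failed (the minor component is a fitting artifact, not a
    distinct cell state).
    """
    if fit.unimodal:
        if fit.dominant_is_on:
            return fit.mu_on, fit.sd_on, 0.0
        return fit.mu_off, fit.sd_off, 0.0
    return fit.mu_on, fit.sd_on, fit.w_off


def _off_component(fit: MixtureFit) -> tuple[float, float, float]:
    """(mu, sd, fail_weight) of the OFF mode of an uninduced-population fit."""
    if fit.unimodal:
        if fit.dominant_is_on:
            return fit.mu_on, fit.sd_on, 0.0
        return fit.mu_off, fit.sd_off, 0.0
    return fit.mu_off, fit.sd_off, fit.w_on


def snr_from_components(
    delta_mu: float, sigma_bar: float, p_dud: float, p_leaky: float
) -> SNRReport:
    """Extended SNR assembled from explicit mode parameters.

    Signal power ``delta_mu**2``; noise power ``sigma_bar**2`` plus the fail
    power ``(p_dud + p_leaky) * delta_mu**2``.  A non-positive amplitude
    yields the negative-infinite sentinel.
    """
    if not 0.0 <= p_dud <= 1.0 or not 0.0 <= p_leaky <= 1.0:
        raise ValueError("fail probabilities must be in [0, 1]")
    fail_power = (p_dud + p_leaky) * delta_mu ** 2
    if delta_mu <= 0:
        return SNRReport(float("-inf"), delta_mu, sigma_bar,
                         p_dud, p_leaky, fail_power)
    value = 10.0 * math.log10(delta_mu ** 2 / (sigma_bar ** 2 + fail_power))
    return SNRReport(value, delta_mu, sigma_bar, p_dud, p_leaky, fail_power)


def snr_db(
    induced: SamplePopulation,
    uninduced: SamplePopulation,
    channel: str = "ofp",
    seed: int = 0,
    floor: float = DEFAULT_FLOOR_MEFL,
) -> SNRReport:
    """Extended SNR between an induced and an uninduced population.

    Mixture fits define the modes: ``delta_mu`` is the induced ON mode minus
    the uninduced OFF mode, ``sigma_bar`` the mean of those two mode SDs,
    ``p_dud`` the OFF-like weight in the induced fit and ``p_leaky`` the
    ON-like weight in the uninduced fit.  A vanishing (or inverted) amplitude
    yields the negative-infinite sentinel rather than an error.
    """
    on_vals = np.maximum(induced.channel(channel), floor)
    off_vals = np.maximum(uninduced.channel(channel), floor)
    fit_on = fit_log_mixture2(on_vals, seed=seed)
    fit_off = fit_log_mixture2(off_vals, seed=seed)

    mu_on, sd_on, p_dud = _on_component(fit_on)
    mu_off, sd_off, p_leaky = _off_component(fit_off)
    return snr_from_components(
        delta_mu=mu_on - mu_off, sigma_bar=0.5 * (sd_on + sd_off),
        p_dud=p_dud, p_leaky=p_leaky)


def metric_set(
    induced: SamplePopulation,
    uninduced: SamplePopulation,
    channel: str = "ofp",
    seed: int = 0,
    floor: float = DEFAULT_FLOOR_MEFL,
) -> MetricSet:
    """Bundle FC, AUC and SNR for one induced/uninduced pair on one channel."""
    on_vals = np.maximum(induced.channel(channel), floor)
    off_vals = np.maximum(uninduced.channel(channel), floor)
    auc, _ = empirical_auc(on_vals, off_vals)
    return MetricSet(
        fc=fold_change(on_vals, off_vals),
        auc=auc,
        snr=snr_db(induced, uninduced, channel=channel, seed=seed, floor=floor),
    )


def delta_metrics(input_ms: MetricSet, output_ms: MetricSet) -> DeltaReport:
    """Output-minus-input deltas; requires both SNRs to be finite."""
    if not (input_ms.snr.defined and output_ms.snr.defined):
        raise ValueError("delta metrics undefined for sentinel (infinite) SNR")
    return DeltaReport(
        delta_snr_db=output_ms.snr.snr_db - input_ms.snr.snr_db,
        delta_fc=output_ms.fc - input_ms.fc,
        delta_auc=output_ms.auc - input_ms.auc,
    )


def on_fraction(values, threshold: float) -> float:
    """Fraction of cells whose fluorescence exceeds ``threshold`` MEFL."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("need at least one value")
    return float(np.mean(v > threshold))
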
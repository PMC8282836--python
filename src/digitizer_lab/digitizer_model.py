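"""Per-cell model of recombinase digitizer circuits on a transient-transfection platform.

The model is deliberately minimal ("mixed phenotypic/mechanistic"): fast RNA
species are eliminated by a quasi-steady-state (QSS) reduction, leaving a
small ODE per cell, while cell-to-cell variability enters phenotypically
through sampled plasmid doses, Gaussian expression-onset delays and a
measurement-noise model.

Per-cell state after the onset delay (all rates per hour):

* recombinase transcription flux ``m`` from the inducible promoter (Hill in
  inducer, with a leaky basal term),
* shRNA flux ``s`` set by the circuit topology,
* free recombinase production flux ``phi = titrate_flux(m, s, K_d)`` — the
  QSS solution of fast molecular titration of the recombinase transcript by
  the shRNA (threshold ``s``, softness ``K_d``),
* recombinase activity ``F``:    dF/dt = phi - delta_F * F
* recombined reporter fraction:  dr/dt = c * F**h_rec * (1 - r)
* stable fluorescent proteins accumulate linearly in their drivers:
  output OFP from recombined reporter copies, input-proxy IFP from the
  inducible promoter's flux, constitutive CFP from its plasmid.

Plasmid copies may dilute at rate ``delta_p`` (default 0: no observable
dilution over the 96 h experiment window).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .flow_io import Condition, SamplePopulation, Topology

__all__ = [
    "PlatformParams", "ModelParams", "CellDose", "CellTrajectory",
    "DimensionlessGroups", "ptre_flux", "shrna_flux", "titrate_flux",
    "simulate_cell", "simulate_population", "nondimensional_groups",
    "copies_from_fluorescence", "load_params", "save_params",
]


@dataclass(frozen=True)
class PlatformParams:
    """Constants of the transient-transfection testing platform.

    gamma
        Fluorescence accumulated per plasmid copy per hour by a constitutive
        transcription unit (MEFL / copy / h); calibrates the
        fluorescence-to-copy-number map.
    mu_delay, sd_delay
        Mean and SD (hours) of the Gaussian distribution of expression onset
        delays after transfection (truncated at zero when sampled).
    delta_p
        First-order plasmid dilution rate (1/h).  Default 0: constitutive
        controls show no observable dilution over 96 h.
    """

    gamma: float = 50.0
    mu_delay: float = 6.0
    sd_delay: float = 2.0
    delta_p: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.sd_delay < 0 or self.delta_p < 0 or self.mu_delay < 0:
            raise ValueError("mu_delay, sd_delay, delta_p must be >= 0")


@dataclass(frozen=True)
class ModelParams:
    """Kinetic constants of the QSS-reduced digitizer model.

    a_f, b_f
        Leaky and maximal inducible-promoter transcription flux per plasmid
        copy (1/h).
    K_dox, n_dox
        Inducer half-max (nM) and Hill coefficient of induction.
    b_s
        shRNA transcription flux per shRNA plasmid copy (1/h).
    K_rep, n_rep
        Inducer half-max (nM) and Hill coefficient of feedforward repression
        of the shRNA promoter (tetO site).
    K_d
        Titration softness of the shRNA/transcript interaction (flux units,
        1/h); the K_d -> 0 limit is a hard threshold max(0, m - s).
    delta_F
        Recombinase decay/dilution rate (1/h).
    c
        Scaled cleavage-and-dissociation rate of recombination (per
        recombinase-activity unit**h_rec per hour).
    h_rec
        Recombination Hill order (cooperativity of recombinase action).
    b_g, b_i, b_c
        Fluorescent-protein production scales: OFP per recombined reporter
        copy per hour (MEFL/copy/h), IFP per unit of inducible-promoter flux
        (MEFL per (1/h) per h), CFP per constitutive copy per hour.
    """

    a_f: float = 0.03
    b_f: float = 2.0
    K_dox: float = 5.0
    n_dox: float = 2.0
    b_s: float = 4.0
    K_rep: float = 10.0
    n_rep: float = 2.0
    K_d: float = 0.2
    delta_F: float = 0.1
    c: float = 2e-4
    h_rec: float = 1.0
    b_g: float = 20.0
    b_i: float = 10.0
    b_c: float = 50.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0 (got {value})")
        if self.n_dox < 1 or self.n_rep < 1 or self.h_rec < 1:
            raise ValueError("Hill coefficients n_dox, n_rep, h_rec must be >= 1")


@dataclass(frozen=True)
class CellDose:
    """Plasmid copies delivered to one cell plus its expression onset delay."""

    copies_flp: int
    copies_shrna: int
    copies_reporter: int
    copies_cfp: int
    delay_h: float

    def __post_init__(self) -> None:
        for n in (self.copies_flp, self.copies_shrna,
                  self.copies_reporter, self.copies_cfp):
            if n < 0 or n != int(n):
                raise ValueError("copy numbers must be non-negative integers")
        if self.delay_h < 0:
            raise ValueError("delay_h must be >= 0")


@dataclass
class CellTrajectory:
    """Time courses for one simulated cell, aligned with the time grid ``t``."""

    t: np.ndarray
    F: np.ndarray
    r: np.ndarray
    ifp: np.ndarray
    ofp: np.ndarray
    cfp: np.ndarray


@dataclass(frozen=True)
class DimensionlessGroups:
    """Scaled parameter groups of the reduced model.

    eKd
        "Effective Kd" K_d / (b_f * copies_flp): the titration tolerance
        relative to the cell's maximal recombinase production capacity; a
        dimensionless measure of tolerance to leaky expression.
    tau_scale
        Time scale delta_F (1/h); scaled time is delta_F * t.
    rec_rate
        Scaled recombination rate c / delta_F * (b_f * copies_flp / delta_F)**h_rec.
    basal_fraction
        a_f / b_f, the leak fraction of the inducible promoter.
    """

    eKd: float
    tau_scale: float
    rec_rate: float
    basal_fraction: float


# ---------------------------------------------------------------------------
# Fluxes


def ptre_flux(dox, copies, p: ModelParams):
    """Inducible-promoter transcription flux (1/h) for ``copies`` plasmids.

    Hill activation with a basal leak: copies * (a_f + (b_f - a_f) * H(dox)).
    Accepts scalars or arrays.
    """
    dox = np.asarray(dox, float)
    if np.any(dox < 0):
        raise ValueError("dox must be >= 0")
    with np.errstate(over="ignore", invalid="ignore"):
        dn = dox ** p.n_dox
        hill = np.where(np.isinf(dn), 1.0, dn / (p.K_dox ** p.n_dox + dn))
    return np.asarray(copies, float) * (p.a_f + (p.b_f - p.a_f) * hill)


def shrna_flux(dox, copies, topology: Topology, p: ModelParams):
    """shRNA transcription flux (1/h) under the given circuit topology."""
    dox = np.asarray(dox, float)
    if np.any(dox < 0):
        raise ValueError("dox must be >= 0")
    copies = np.asarray(copies, float)
    if topology is Topology.NO_SHRNA:
        return np.zeros(np.broadcast(dox, copies).shape)
    if topology is Topology.CONSTANT:
        return copies * p.b_s * np.ones_like(dox)
    if topology is Topology.FEEDFORWARD:
        kn = p.K_rep ** p.n_rep
        with np.errstate(over="ignore", invalid="ignore"):
            dn = dox ** p.n_rep
            rep = np.where(np.isinf(dn), 0.0, kn / (kn + dn))
        return copies * p.b_s * rep
    raise ValueError(f"unknown topology {topology!r}")


def titrate_flux(m_flux, s_flux, K_d):
    """Free recombinase production flux after molecular titration by shRNA.

    QSS solution of mass-action sequestration of the recombinase transcript
    by the shRNA (production fluxes ``m`` and ``s``, first-order turnover of
    both species, irreversible pairing): the flux that escapes titration is

        0.5 * [(m - s - K_d) + sqrt((m - s - K_d)**2 + 4 * K_d * m)]

    where ``K_d`` collects the turnover and pairing rates into a softness
    scale.  Limits: s = 0 gives m exactly; K_d -> 0 gives the hard threshold
    max(0, m - s).  Continuous, bounded by m, non-decreasing in m and
    non-increasing in s.  Accepts scalars or arrays.
    """
    m = np.asarray(m_flux, float)
    s = np.asarray(s_flux, float)
    K = np.asarray(K_d, float)
    if np.any(m < 0) or np.any(s < 0) or np.any(K < 0):
        raise ValueError("titrate_flux arguments must be >= 0")
    d = m - s - K
    out = 0.5 * (d + np.sqrt(d * d + 4.0 * K * m))
    # guard tiny negative round-off in the hard-threshold limit
    return np.maximum(out, 0.0)


# ---------------------------------------------------------------------------
# Single-cell reference integration


def simulate_cell(
    dose: CellDose,
    dox: float,
    topology: Topology,
    p: ModelParams,
    plat: PlatformParams,
    t_grid: np.ndarray,
    ptre_flux_override: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> CellTrajectory:
    """Integrate one cell's trajectory on ``t_grid`` (hours, starting at 0).

    All production is zero before the cell's onset delay; afterwards plasmid
    copies decay at ``delta_p`` and the reduced ODE runs with an adaptive
    stiff-capable solver (LSODA).

    ``ptre_flux_override`` replaces the Hill induction term (including its
    leak) with a fixed total inducible-promoter flux at onset — the hook used
    to drive the model with phenotypic input measurements.
    """
    t_grid = np.asarray(t_grid, float)
    if t_grid.ndim != 1 or t_grid[0] != 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be increasing and start at 0")

    n = len(t_grid)
    zeros = np.zeros(n)
    t_end = t_grid[-1]
    if dose.delay_h >= t_end:
        return CellTrajectory(t_grid, zeros, zeros.copy(), zeros.copy(),
                              zeros.copy(), zeros.copy())

    if ptre_flux_override is None:
        m0 = float(ptre_flux(dox, dose.copies_flp, p))
    else:
        if ptre_flux_override < 0:
            raise ValueError("ptre_flux_override must be >= 0")
        m0 = float(ptre_flux_override)
    s0 = float(shrna_flux(dox, dose.copies_shrna, topology, p))

    def rhs(tau, y):
        F, r, ofp, ifp, cfp = y
        decay = np.exp(-plat.delta_p * tau)
        m = m0 * decay
        s = s0 * decay
        phi = float(titrate_flux(m, s, p.K_d))
        F = max(F, 0.0)
        return [
            phi - p.delta_F * F,
            p.c * F ** p.h_rec * (1.0 - r),
            p.b_g * r * dose.copies_reporter * decay,
            p.b_i * m,
            p.b_c * dose.copies_cfp * decay,
        ]

    tau_eval = np.clip(t_grid - dose.delay_h, 0.0, None)
    sol = solve_ivp(
        rhs, (0.0, t_end - dose.delay_h), [0.0, 0.0, 0.0, 0.0, 0.0],
        t_eval=np.unique(tau_eval), method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(
            f"integration failed ({sol.message}); dose={dose}, dox={dox}, "
            f"topology={topology}, params={p}")

    # map back onto the requested grid (zeros before onset)
    interp = {tau: i for i, tau in enumerate(sol.t)}
    idx = np.array([interp[tau] for tau in tau_eval])
    F = sol.y[0][idx]
    r = np.clip(sol.y[1][idx], 0.0, 1.0)
    ofp = sol.y[2][idx]
    ifp = sol.y[3][idx]
    cfp = sol.y[4][idx]
    before = t_grid < dose.delay_h
    for arr in (F, r, ofp, ifp, cfp):
        arr[before] = 0.0
    return CellTrajectory(t_grid, F, r, ifp, ofp, cfp)


# ---------------------------------------------------------------------------
# Vectorized population endpoint (shares the same reduced equations)


def _endpoint_true(
    m0: np.ndarray,
    s0: np.ndarray,
    copies_reporter: np.ndarray,
    copies_cfp: np.ndarray,
    delays: np.ndarray,
    p: ModelParams,
    plat: PlatformParams,
    t: float,
    n_steps: int = 256,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """True (noise-free) IFP/OFP/CFP of every cell at time ``t``.

    Fixed-step trapezoidal integration of the same reduced equations as
    :func:`simulate_cell`, vectorized across cells on a per-cell normalized
    time grid; the recombinase equation uses an exact exponential
    integrating factor per step, so the scheme is robust for any delta_F.
    """
    m0 = np.asarray(m0, float)
    s0 = np.asarray(s0, float)
    tau_end = np.clip(t - np.asarray(delays, float), 0.0, None)
    n = m0.shape[0]
    dt = tau_end / n_steps

    F = np.zeros(n)
    z = np.zeros(n)          # cumulative recombination hazard
    ofp = np.zeros(n)
    ifp = np.zeros(n)
    cfp = np.zeros(n)

    def fluxes(k):
        decay = np.exp(-plat.delta_p * dt * k)
        m = m0 * decay
        return m, titrate_flux(m, s0 * decay, p.K_d), decay

    m_k, phi_k, decay_k = fluxes(0)
    r_k = np.zeros(n)
    E = np.exp(-p.delta_F * dt)
    for k in range(n_steps):
        m_n, phi_n, decay_n = fluxes(k + 1)
        F_n = F * E + 0.5 * dt * (phi_k * E + phi_n)
        z = z + 0.5 * dt * p.c * (F ** p.h_rec + F_n ** p.h_rec)
        r_n = 1.0 - np.exp(-z)
        ofp += 0.5 * dt * p.b_g * copies_reporter * (r_k * decay_k + r_n * decay_n)
        ifp += 0.5 * dt * p.b_i * (m_k + m_n)
        cfp += 0.5 * dt * p.b_c * copies_cfp * (decay_k + decay_n)
        F, r_k, m_k, phi_k, decay_k = F_n, r_n, m_n, phi_n, decay_n
    return ifp, ofp, cfp


def _measure(
    true_values: np.ndarray, rng: np.random.Generator,
    autofluorescence_mu: float, sigma_m: float,
    floor: float = 1.0, af_sigma_log10: float = 0.2,
) -> np.ndarray:
    """Apply the measurement model: add an autofluorescence draw, multiply by
    lognormal noise, clamp at the detection floor."""
    n = true_values.shape[0]
    af = autofluorescence_mu * 10.0 ** rng.normal(0.0, af_sigma_log10, n)
    noisy = (true_values + af) * 10.0 ** rng.normal(0.0, sigma_m, n)
    return np.maximum(noisy, floor)


def simulate_population(
    n_cells: int,
    doses_ng: Mapping[str, float],
    dox: float,
    topology: Topology,
    p: ModelParams,
    plat: PlatformParams,
    uptake,
    t: float,
    seed,
    replicate: int = 0,
) -> SamplePopulation:
    """Simulate a measured cell population at a single time point.

    Per-cell plasmid doses and onset delays are drawn by
    :func:`digitizer_lab.synthetic_data.sample_transfection`; each cell is run
    to time ``t`` with the reduced model and read out through the measurement
    model (autofluorescence + multiplicative lognormal noise + floor).
    Identical seeds give identical output.

    ``doses_ng`` maps plasmid names ``flp``, ``shrna``, ``reporter``, ``cfp``
    to co-transfected masses (ng); ``uptake`` is an
    :class:`~digitizer_lab.synthetic_data.UptakeParams`.
    """
    from .synthetic_data import _sample_dose_arrays  # local import: avoid cycle

    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    copies, delays = _sample_dose_arrays(n_cells, doses_ng, uptake, plat, rng)

    m0 = ptre_flux(dox, copies["flp"], p)
    s0 = shrna_flux(dox, copies["shrna"], topology, p)
    ifp, ofp, cfp = _endpoint_true(
        m0, s0, copies["reporter"].astype(float), copies["cfp"].astype(float),
        delays, p, plat, t)

    cond = Condition(
        topology=topology,
        flp_ng=float(doses_ng.get("flp", 0.0)),
        shrna_ng=float(doses_ng.get("shrna", 0.0)),
        dox_nM=float(dox), time_h=float(t), replicate=replicate,
    )
    return SamplePopulation.from_arrays(
        cond,
        cfp=_measure(cfp, rng, uptake.autofluorescence_mu, uptake.sigma_m),
        ifp=_measure(ifp, rng, uptake.autofluorescence_mu, uptake.sigma_m),
        ofp=_measure(ofp, rng, uptake.autofluorescence_mu, uptake.sigma_m),
    )


# ---------------------------------------------------------------------------
# Analysis helpers


def nondimensional_groups(p: ModelParams, dose: CellDose) -> DimensionlessGroups:
    """Dimensionless parameter groups for one cell's dose."""
    if p.b_f <= 0 or dose.copies_flp <= 0 or p.delta_F <= 0:
        raise ZeroDivisionError(
            "nondimensional groups require b_f, copies_flp, delta_F > 0")
    cap = p.b_f * dose.copies_flp
    return DimensionlessGroups(
        eKd=p.K_d / cap,
        tau_scale=p.delta_F,
        rec_rate=p.c / p.delta_F * (cap / p.delta_F) ** p.h_rec,
        basal_fraction=p.a_f / p.b_f,
    )


def copies_from_fluorescence(cfp: float, t: float, plat: PlatformParams) -> int:
    """Invert the constitutive accumulation model to estimate plasmid copies.

    cfp = gamma * copies * max(0, t - mu_delay), rounded to the nearest
    non-negative integer.  Requires t > mu_delay.
    """
    if t <= plat.mu_delay:
        raise ValueError(
            f"copies undefined for t={t} <= mean onset delay {plat.mu_delay}")
    if cfp < 0:
        raise ValueError("cfp must be >= 0")
    return max(0, int(round(cfp / (plat.gamma * (t - plat.mu_delay)))))


def save_params(p: "ModelParams | PlatformParams", path: "str | Path") -> None:
    """Serialize parameters to a flat YAML document."""
    doc = {"kind": type(p).__name__, **asdict(p)}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_params(path: "str | Path"):
    """Load :class:`ModelParams` or :class:`PlatformParams` from YAML."""
    doc = yaml.safe_load(Path(path).read_text())
    kind = doc.pop("kind", "ModelParams")
    cls = {"ModelParams": ModelParams, "PlatformParams": PlatformParams}[kind]
    return cls(**doc)


def with_params(p: ModelParams, **updates) -> ModelParams:
    """Return a copy of ``p`` with the given fields replaced."""
    return replace(p, **updates)
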
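"""Synthetic transfection doses, virtual experiments and weak graded inputs.

Emulates the statistical structure of transiently transfected single-cell
fluorescence data: lognormal total plasmid uptake partitioned multinomially
among co-delivered plasmids (so all plasmid copies are correlated within a
cell, which is what makes constitutive-marker gating informative), Gaussian
expression-onset delays, bimodal ON/OFF output distributions, and a weak
bimodal synNotch-like input for signal-transduction studies.

All randomness flows from a single integer seed; each condition of a design
draws from its own substream keyed by a checksum of the condition metadata,
so subsetting a design never changes another condition's data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .digitizer_model import (
    CellDose, ModelParams, PlatformParams, simulate_population,
)
from .flow_io import Condition, ExperimentTable, Topology

__all__ = [
    "UptakeParams", "ExperimentDesign", "SynnotchMix",
    "sample_transfection", "generate_experiment", "generate_synnotch_input",
    "preset_doses", "dose_response_design", "condition_seed",
]

PLASMID_KEYS = ("flp", "shrna", "reporter", "cfp")

#: Default co-transfected reporter and constitutive-marker masses (ng).
DEFAULT_REPORTER_NG = 100.0
DEFAULT_CFP_NG = 50.0

#: Flp:shRNA plasmid masses (ng) for the three performance regimes of each
#: topology: well-balanced, over-repressed (too much shRNA; induction fails)
#: and under-repressed (too little shRNA; leaky basal activation).
PRESET_RATIOS_NG: dict[tuple[Topology, str], tuple[float, float]] = {
    (Topology.CONSTANT, "balanced"): (35.0, 5.0),
    (Topology.CONSTANT, "over_repressed"): (1.0, 5.0),
    (Topology.CONSTANT, "under_repressed"): (35.0, 1.0),
    (Topology.FEEDFORWARD, "balanced"): (15.0, 20.0),
    (Topology.FEEDFORWARD, "over_repressed"): (1.0, 20.0),
    (Topology.FEEDFORWARD, "under_repressed"): (15.0, 1.0),
    (Topology.NO_SHRNA, "balanced"): (1.0, 0.0),
}

#: Default inducer titration (nM) for dose-response designs; concentrates
#: points around the induction threshold and includes the uninduced and the
#: standard fully induced (225 nM = 100 ng/mL) conditions.
DEFAULT_DOX_LEVELS_NM = (0.0, 1.0, 2.0, 3.0, 5.0, 8.0, 25.0, 225.0)


@dataclass(frozen=True)
class UptakeParams:
    """Plasmid uptake heterogeneity and measurement-noise parameters.

    mu_uptake, sd_uptake
        log10 mean and SD of total plasmid copies taken up per cell
        (lognormal heterogeneity of transfection).
    autofluorescence_mu
        Median autofluorescence background per channel (MEFL).
    sigma_m
        Multiplicative measurement noise SD (log10 units).
    """

    mu_uptake: float = 2.0
    sd_uptake: float = 0.5
    autofluorescence_mu: float = 100.0
    sigma_m: float = 0.1

    def __post_init__(self) -> None:
        if self.sd_uptake < 0 or self.sigma_m < 0:
            raise ValueError("sd_uptake and sigma_m must be >= 0")


@dataclass
class ExperimentDesign:
    """A list of (condition, n_cells) pairs plus shared plasmid masses."""

    conditions: list[tuple[Condition, int]]
    reporter_ng: float = DEFAULT_REPORTER_NG
    cfp_ng: float = DEFAULT_CFP_NG

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("design must contain at least one condition")
        seen = set()
        for cond, n in self.conditions:
            if n < 1:
                raise ValueError("n_cells must be >= 1 for every condition")
            if cond in seen:
                raise ValueError(f"duplicate condition in design: {cond}")
            seen.add(cond)

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "ExperimentDesign":
        doc = yaml.safe_load(Path(path).read_text())
        conds = []
        for row in doc["conditions"]:
            n = int(row.pop("n_cells"))
            row["topology"] = Topology.parse(row["topology"])
            conds.append((Condition(**row), n))
        return cls(conds,
                   reporter_ng=float(doc.get("reporter_ng", DEFAULT_REPORTER_NG)),
                   cfp_ng=float(doc.get("cfp_ng", DEFAULT_CFP_NG)))


@dataclass(frozen=True)
class SynnotchMix:
    """Two-component log10 mixture describing a weak graded input signal.

    Defaults give broadly overlapping ON/OFF modes (separation comparable to
    the component SD) so that the input populations are poorly
    distinguishable — a negative-SNR input of the kind a contact-dependent
    synNotch sensor produces.
    """

    w_on: float = 0.5
    mu_off: float = 2.35
    mu_on: float = 3.8
    sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_on <= 1.0:
            raise ValueError("w_on must be in [0, 1]")
        if self.mu_on < self.mu_off:
            raise ValueError("mu_on must be >= mu_off")
        if self.sd <= 0:
            raise ValueError("sd must be > 0")


def condition_seed(seed: int, cond: Condition) -> list[int]:
    """Substream key for one condition: the root seed plus a CRC32 checksum
    of the condition metadata.  Stable across runs and processes."""
    text = (f"{cond.topology.value}|{cond.flp_ng!r}|{cond.shrna_ng!r}|"
            f"{cond.dox_nM!r}|{cond.time_h!r}|{cond.replicate}")
    return [int(seed), zlib.crc32(text.encode())]


def _sample_dose_arrays(
    n_cells: int,
    doses_ng,
    uptake: UptakeParams,
    plat: PlatformParams,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Array-level dose sampler used by the population simulators."""
    masses = np.array([float(doses_ng.get(k, 0.0)) for k in PLASMID_KEYS])
    if np.any(masses < 0):
        raise ValueError("plasmid masses must be >= 0")
    total_mass = masses.sum()

    total = np.rint(10.0 ** rng.normal(uptake.mu_uptake, uptake.sd_uptake,
                                       n_cells)).astype(np.int64)
    total = np.maximum(total, 0)
    if total_mass == 0:
        counts = np.zeros((n_cells, len(PLASMID_KEYS)), dtype=np.int64)
    else:
        counts = rng.multinomial(total, masses / total_mass)
    delays = np.maximum(rng.normal(plat.mu_delay, plat.sd_delay, n_cells), 0.0)
    copies = {k: counts[:, i] for i, k in enumerate(PLASMID_KEYS)}
    return copies, delays


def sample_transfection(
    n_cells: int,
    doses_ng,
    uptake: UptakeParams,
    plat: PlatformParams,
    seed,
) -> list[CellDose]:
    """Draw per-cell plasmid doses and onset delays.

    Total uptake is lognormal (fully correlated co-delivery) and partitioned
    multinomially with probabilities proportional to the plasmid mass
    fractions; onset delays are Gaussian truncated at zero.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    copies, delays = _sample_dose_arrays(n_cells, doses_ng, uptake, plat, rng)
    return [
        CellDose(
            copies_flp=int(copies["flp"][i]),
            copies_shrna=int(copies["shrna"][i]),
            copies_reporter=int(copies["reporter"][i]),
            copies_cfp=int(copies["cfp"][i]),
            delay_h=float(delays[i]),
        )
        for i in range(n_cells)
    ]


def generate_experiment(
    design: ExperimentDesign,
    p: ModelParams,
    plat: PlatformParams,
    uptake: UptakeParams,
    seed: int,
) -> ExperimentTable:
    """Run a full virtual experiment: one simulated population per design row."""
    table = ExperimentTable()
    for cond, n_cells in design.conditions:
        doses = {
            "flp": cond.flp_ng,
            "shrna": cond.shrna_ng,
            "reporter": design.reporter_ng,
            "cfp": design.cfp_ng,
        }
        pop = simulate_population(
            n_cells, doses, cond.dox_nM, cond.topology, p, plat, uptake,
            t=cond.time_h, seed=condition_seed(seed, cond),
            replicate=cond.replicate,
        )
        table.add(pop)
    return table


def generate_synnotch_input(
    n_cells: int,
    mix: SynnotchMix | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Draw a weak bimodal input-fluorescence sample (MEFL).

    Values come from a two-component lognormal mixture; component membership
    is Bernoulli(w_on) per cell.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    mix = mix or SynnotchMix()
    rng = np.random.default_rng(seed)
    on = rng.random(n_cells) < mix.w_on
    mu = np.where(on, mix.mu_on, mix.mu_off)
    return 10.0 ** rng.normal(mu, mix.sd)


def preset_doses(topology: Topology, regime: str = "balanced") -> dict[str, float]:
    """Plasmid mass map (ng) for a named topology/regime preset."""
    key = (Topology.parse(topology), regime)
    if key not in PRESET_RATIOS_NG:
        valid = sorted(f"{t.value}-{r}" for t, r in PRESET_RATIOS_NG)
        raise KeyError(f"unknown preset {key}; valid: {valid}")
    flp, shrna = PRESET_RATIOS_NG[key]
    return {"flp": flp, "shrna": shrna,
            "reporter": DEFAULT_REPORTER_NG, "cfp": DEFAULT_CFP_NG}


def dose_response_design(
    topology: Topology,
    flp_ng: float,
    shrna_ng: float,
    n_cells: int,
    dox_levels=DEFAULT_DOX_LEVELS_NM,
    time_h: float = 48.0,
    replicates: int = 1,
) -> ExperimentDesign:
    """Design for an inducer titration at a single Flp:shRNA ratio."""
    conds = [
        (Condition(topology=topology, flp_ng=flp_ng, shrna_ng=shrna_ng,
                   dox_nM=float(dox), time_h=time_h, replicate=rep), n_cells)
        for rep in range(replicates)
        for dox in dox_levels
    ]
    return ExperimentDesign(conds)
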
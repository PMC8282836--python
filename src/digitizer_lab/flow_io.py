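"""Reading, validation, gating and unit helpers for per-cell fluorescence tables.

The interchange currency is a delimited text table of calibrated MEFL
(Molecules of Equivalent Fluorescein) values, one row per cell event, in three
channels:

* ``cfp`` — constitutive marker, correlated with plasmid copy number,
* ``ifp`` — input proxy, reporting inducible-promoter (pTRE) activity,
* ``ofp`` — digitizer output, reporting recombination state,

plus six condition columns (circuit topology, plasmid masses, inducer
concentration, time point, replicate).  Calibration itself (bead standards,
autofluorescence subtraction, compensation) is assumed to have been done
upstream; this module only floors, gates and groups already-calibrated values.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("digitizer_lab")

#: Molecular weight of doxycycline hyclate-free base, g/mol.
DOX_MW_G_PER_MOL = 444.44

#: Detection floor applied before any log transform, MEFL.
DEFAULT_FLOOR_MEFL = 1.0

#: Canonical column order for delimited-text tables.
CANONICAL_COLUMNS = (
    "topology", "flp_ng", "shrna_ng", "dox_nM", "time_h", "replicate",
    "cfp", "ifp", "ofp",
)

CHANNELS = ("cfp", "ifp", "ofp")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ParseError(ValueError):
    """A fluorescence cell could not be parsed as a number."""


class EmptyPopulationError(ValueError):
    """A filtering or gating step removed every event."""


class Topology(enum.Enum):
    """Digitizer circuit topology.

    NO_SHRNA: inducible recombinase only, no RNAi control.
    CONSTANT: constitutively expressed shRNA imposes a fixed translation
        threshold on the recombinase transcript.
    FEEDFORWARD: shRNA transcription is itself repressed by the inducer
        (coherent feedforward loop), so induction simultaneously raises
        recombinase transcription and lowers the threshold.
    """

    NO_SHRNA = "no_shrna"
    CONSTANT = "constant"
    FEEDFORWARD = "feedforward"

    @classmethod
    def parse(cls, value: "str | Topology") -> "Topology":
        if isinstance(value, Topology):
            return value
        key = str(value).strip().lower().replace("-", "_")
        for member in cls:
            if member.value == key or member.name.lower() == key:
                return member
        raise ValueError(
            f"unknown topology {value!r}; valid: {[m.value for m in cls]}"
        )


@dataclass(frozen=True)
class Condition:
    """Experimental condition metadata for one cell population."""

    topology: Topology
    flp_ng: float
    shrna_ng: float
    dox_nM: float
    time_h: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.flp_ng < 0 or self.shrna_ng < 0:
            raise ValueError("plasmid masses must be >= 0")
        if self.dox_nM < 0:
            raise ValueError("dox_nM must be >= 0")
        if self.time_h < 0:
            raise ValueError("time_h must be >= 0")
        if self.topology is Topology.NO_SHRNA and self.shrna_ng != 0:
            raise ValueError("NO_SHRNA topology requires shrna_ng == 0")


@dataclass(frozen=True)
class CellRecord:
    """Fluorescence of a single cell event, MEFL."""

    cfp: float
    ifp: float
    ofp: float


@dataclass
class SamplePopulation:
    """An ordered collection of cell events sharing one condition.

    ``data`` holds the three fluorescence channels as columns; row order is
    the insertion (acquisition) order and is preserved by every operation in
    this package.
    """

    condition: Condition
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"population data missing channels: {missing}")
        self.data = self.data.loc[:, list(CHANNELS)].reset_index(drop=True)

    @classmethod
    def from_arrays(cls, condition: Condition, cfp, ifp, ofp) -> "SamplePopulation":
        return cls(condition, pd.DataFrame(
            {"cfp": np.asarray(cfp, float),
             "ifp": np.asarray(ifp, float),
             "ofp": np.asarray(ofp, float)}))

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise ValueError(f"unknown channel {name!r}; valid channels: {CHANNELS}")
        return self.data[name].to_numpy()

    @property
    def records(self) -> list[CellRecord]:
        return [CellRecord(*row) for row in self.data.itertuples(index=False)]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class ExperimentTable:
    """Populations keyed by condition; keys must be unique."""

    populations: dict[Condition, SamplePopulation] = field(default_factory=dict)

    def add(self, pop: SamplePopulation) -> None:
        if pop.condition in self.populations:
            raise ValueError(f"duplicate condition {pop.condition}")
        self.populations[pop.condition] = pop

    def __iter__(self) -> Iterator[SamplePopulation]:
        return iter(self.populations.values())

    def __len__(self) -> int:
        return len(self.populations)

    def __getitem__(self, condition: Condition) -> SamplePopulation:
        return self.populations[condition]

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for cond, pop in self.populations.items():
            df = pop.data.copy()
            df.insert(0, "replicate", cond.replicate)
            df.insert(0, "time_h", cond.time_h)
            df.insert(0, "dox_nM", cond.dox_nM)
            df.insert(0, "shrna_ng", cond.shrna_ng)
            df.insert(0, "flp_ng", cond.flp_ng)
            df.insert(0, "topology", cond.topology.value)
            frames.append(df)
        if not frames:
            return pd.DataFrame(columns=list(CANONICAL_COLUMNS))
        return pd.concat(frames, ignore_index=True)


def _separator_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_population_table(
    path: "str | Path",
    schema: Mapping[str, str] | None = None,
) -> ExperimentTable:
    """Read a delimited-text table of cell events grouped into populations.

    Parameters
    ----------
    path
        CSV or TSV file (autodetected by extension), UTF-8, header row
        required.
    schema
        Optional map from canonical column names to the file's column names,
        e.g. ``{"ofp": "GFP_MEFL"}``.  Unmapped columns use canonical names.

    Row order within each population is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_separator_for(path), encoding="utf-8")
    schema = dict(schema or {})
    rename = {schema.get(c, c): c for c in CANONICAL_COLUMNS}
    df = df.rename(columns=rename)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    for col in ("flp_ng", "shrna_ng", "dox_nM", "time_h", "replicate", *CHANNELS):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any() or coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna())[0])
            raise ParseError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r} "
                f"at data row {row}"
            )
        df[col] = coerced
    if not np.isfinite(df[list(CHANNELS)].to_numpy()).all():
        raise ParseError("non-finite fluorescence value in table")

    table = ExperimentTable()
    keys = ["topology", "flp_ng", "shrna_ng", "dox_nM", "time_h", "replicate"]
    for key, group in df.groupby(keys, sort=False):
        cond = Condition(
            topology=Topology.parse(key[0]),
            flp_ng=float(key[1]), shrna_ng=float(key[2]),
            dox_nM=float(key[3]), time_h=float(key[4]),
            replicate=int(key[5]),
        )
        table.add(SamplePopulation(cond, group[list(CHANNELS)]))
    return table


def write_population_table(table: ExperimentTable, path: "str | Path") -> None:
    """Write a table in the canonical schema.

    Fluorescence is written with 17 significant digits so that a
    read-after-write round trip is bit-exact for double precision values.
    """
    path = Path(path)
    df = table.to_dataframe()
    df.to_csv(path, sep=_separator_for(path), index=False, float_format="%.17g")


def filter_valid_events(
    pop: SamplePopulation, floor: float = DEFAULT_FLOOR_MEFL
) -> SamplePopulation:
    """Drop events whose constitutive (CFP) signal is below ``floor`` MEFL.

    This is a simple transfection-level validity filter: events with
    essentially no constitutive signal are untransfected cells or debris.
    """
    if floor < 0:
        raise ValueError("floor must be >= 0")
    keep = pop.channel("cfp") >= floor
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_valid_events: removed %d of %d events below "
                    "CFP floor %g MEFL", n_removed, len(pop), floor)
    if not keep.any():
        raise EmptyPopulationError(
            f"all {len(pop)} events fall below CFP floor {floor} MEFL")
    return SamplePopulation(pop.condition, pop.data.loc[keep])


def gate_top_fraction(
    pop: SamplePopulation, channel: str, fraction: float
) -> SamplePopulation:
    """Retain the ``ceil(fraction * n)`` events with the highest channel values.

    The standard gate in this workflow keeps the top 30% of CFP-expressing
    cells so that populations are compared at similar transfection levels.
    Boundary ties are broken by stable input order; the retained events keep
    their original relative order.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(pop) == 0:
        raise EmptyPopulationError("cannot gate an empty population")
    values = pop.channel(channel)
    k = math.ceil(fraction * len(pop))
    # stable argsort on negated values: descending, ties in input order
    order = np.argsort(-values, kind="stable")[:k]
    keep = np.sort(order)
    return SamplePopulation(pop.condition, pop.data.iloc[keep])


def dox_mass_to_molar(ng_per_ml: float) -> float:
    """Convert a doxycycline mass concentration (ng/mL) to nM.

    Uses a molecular weight of 444.44 g/mol, under which the standard
    100 ng/mL working concentration equals 225 nM.
    """
    if ng_per_ml < 0:
        raise ValueError("concentration must be >= 0")
    return ng_per_ml / DOX_MW_G_PER_MOL * 1000.0
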
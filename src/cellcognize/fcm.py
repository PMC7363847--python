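"""Flow-cytometry event tables: reading, filtering, gating, subsampling, anchoring.

An *event table* holds one row per particle with the seven optical
parameters recorded by the cytometer (FITC-A, FITC-H, FSC-A, FSC-H,
SSC-A, SSC-H, Width).  Raw intensities are filtered to a per-parameter
window, log10-transformed, and optionally gated into rectangular boxes in
the three height channels (FITC-H, SSC-H, FSC-H) to separate
subpopulations of a standard.  Per-standard datasets are then subsampled
and, for the first standard in a training set, extended with two
synthetic "anchor" events that pin the global per-parameter range to the
filter bounds, so that min-max scaling downstream is fixed by the filter
configuration and not by the biological data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: The seven cytometer parameters, in canonical column order.
PARAMETERS: tuple[str, ...] = (
    "FITC-A", "FITC-H", "FSC-A", "FSC-H", "SSC-A", "SSC-H", "Width",
)

#: The three parameters used for rectangular subpopulation gating.
GATE_PARAMETERS: tuple[str, ...] = ("FITC-H", "SSC-H", "FSC-H")

RAW = "raw"
LOG10 = "log10"


class FormatError(ValueError):
    """An input file does not conform to the expected event-table format."""


class EmptyTableError(ValueError):
    """An input file contains no events."""


class ConfigError(ValueError):
    """A gate, manifest or filter configuration is inconsistent."""


@dataclass
class EventTable:
    """Matrix of cytometry events over the seven canonical parameters.

    Parameters
    ----------
    data
        One row per event; must contain exactly the seven parameter
        columns (extra columns are rejected here — drop them before
        constructing).  Stored in canonical column order.
    scale
        ``"raw"`` for instrument intensities, ``"log10"`` after
        transformation.
    analyzed_volume_ul
        Volume of sample analyzed by the instrument, in microlitres.
        Used for absolute cell-density calculations.
    dilution_factor
        Dilution applied before acquisition (>= 1).
    sample_id
        Free-text sample label.
    """

    data: pd.DataFrame
    scale: str = RAW
    analyzed_volume_ul: float = 20.0
    dilution_factor: float = 1.0
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        missing = [p for p in PARAMETERS if p not in self.data.columns]
        if missing:
            raise FormatError(f"event table missing required column(s): {missing}")
        extra = [c for c in self.data.columns if c not in PARAMETERS]
        if extra:
            raise FormatError(f"event table has unexpected column(s): {extra}")
        self.data = self.data.loc[:, list(PARAMETERS)].reset_index(drop=True)
        if self.scale not in (RAW, LOG10):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.analyzed_volume_ul <= 0:
            raise ValueError("analyzed_volume_ul must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        """Event matrix as a float64 array, shape (n_events, 7)."""
        return self.data.to_numpy(dtype=float)

    def copy_with(self, data: pd.DataFrame, scale: str | None = None) -> "EventTable":
        return EventTable(
            data=data.reset_index(drop=True),
            scale=self.scale if scale is None else scale,
            analyzed_volume_ul=self.analyzed_volume_ul,
            dilution_factor=self.dilution_factor,
            sample_id=self.sample_id,
        )


@dataclass
class FilterSpec:
    """Per-parameter raw-intensity window applied before log transform.

    ``lower``/``upper`` may be scalars (applied to all seven parameters)
    or mappings from parameter name to bound.  Defaults: lower 100 for
    every parameter, upper 1e7.
    """

    lower: float | Mapping[str, float] = 100.0
    upper: float | Mapping[str, float] = 1e7

    def __post_init__(self) -> None:
        self._lower = self._expand(self.lower)
        self._upper = self._expand(self.upper)
        if np.any(self._lower <= 0):
            raise ConfigError("lower filter bounds must be positive")
        if np.any(self._upper <= self._lower):
            raise ConfigError("upper filter bounds must exceed lower bounds")

    @staticmethod
    def _expand(bound: float | Mapping[str, float]) -> np.ndarray:
        if isinstance(bound, Mapping):
            missing = [p for p in PARAMETERS if p not in bound]
            if missing:
                raise ConfigError(f"filter bounds missing parameter(s): {missing}")
            return np.array([float(bound[p]) for p in PARAMETERS])
        return np.full(len(PARAMETERS), float(bound))

    @property
    def lower_bounds(self) -> np.ndarray:
        return self._lower.copy()

    @property
    def upper_bounds(self) -> np.ndarray:
        return self._upper.copy()

    @property
    def log_lower(self) -> np.ndarray:
        return np.log10(self._lower)

    @property
    def log_upper(self) -> np.ndarray:
        return np.log10(self._upper)


@dataclass
class GateBox:
    """Axis-aligned, inclusive gate in log10(FITC-H) x log10(SSC-H) x log10(FSC-H).

    ``bounds`` maps each of the three gating parameters to a
    ``(lower, upper)`` pair of log10 intensities.  A warning is issued
    when the gate captures less than ``min_fraction`` of its input, the
    minimum share expected of a genuine subpopulation.
    """

    bounds: Mapping[str, tuple[float, float]]
    label: str
    min_fraction: float = 0.05

    def __post_init__(self) -> None:
        bad_axes = [p for p in self.bounds if p not in GATE_PARAMETERS]
        if bad_axes:
            raise ConfigError(
                f"gate {self.label!r} uses non-gating parameter(s) {bad_axes}; "
                f"allowed: {list(GATE_PARAMETERS)}"
            )
        for p, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ConfigError(f"gate {self.label!r}: lower >= upper on {p}")
        if not 0 < self.min_fraction < 1:
            raise ConfigError("min_fraction must be in (0, 1)")


@dataclass
class StandardDataset:
    """Gated, log10-scale events of one standard (strain subpopulation or bead)."""

    standard_name: str
    events: EventTable
    replicate_of: str | None = None
    anchor_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.events.scale != LOG10:
            raise ValueError("StandardDataset events must be on log10 scale")
        if self.anchor_mask is None:
            self.anchor_mask = np.zeros(self.events.n_events, dtype=bool)
        self.anchor_mask = np.asarray(self.anchor_mask, dtype=bool)
        if self.anchor_mask.shape != (self.events.n_events,):
            raise ValueError("anchor_mask length must equal event count")

    @property
    def n_events(self) -> int:
        return self.events.n_events


def read_event_table(
    path: str | Path,
    format: str = "csv",
    sep: str = ",",
    **metadata,
) -> EventTable:
    """Read a delimited event table exported from the cytometer software.

    The file must carry a header naming the seven parameters; extra
    columns are ignored.  Events with any negative value are dropped
    (instrument artifacts) with a warning reporting the count.

    Only delimited tables are supported; ``format="fcs"`` raises, as no
    FCS reader is bundled — export events to CSV first.
    """
    if format != "csv":
        raise NotImplementedError(
            f"unsupported event-table format {format!r}; export to a delimited "
            "table with the seven parameter columns"
        )
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise EmptyTableError(f"{path} contains no data") from None
    missing = [p for p in PARAMETERS if p not in df.columns]
    if missing:
        raise FormatError(f"{path} missing required column(s): {missing}")
    if len(df) == 0:
        raise EmptyTableError(f"{path} contains a header but no events")
    df = df.loc[:, list(PARAMETERS)].astype(float)
    neg = (df.to_numpy() < 0).any(axis=1)
    if neg.any():
        warnings.warn(
            f"{path.name}: dropped {int(neg.sum())} event(s) with negative values"
        )
        df = df.loc[~neg]
    return EventTable(data=df.reset_index(drop=True), scale=RAW, **metadata)


def write_event_table(table: EventTable, path: str | Path) -> None:
    """Write an event table to CSV with full float precision (round-trip safe)."""
    table.data.to_csv(path, index=False, float_format="%.17g")


def preprocess(raw: EventTable, spec: FilterSpec | None = None) -> EventTable:
    """Filter raw events to the per-parameter window and log10-transform.

    An event is retained only when ``lower <= value <= upper`` on *all*
    seven parameters.  Retained intensities are log10-transformed (well
    defined, since lower bounds are positive).  Metadata is preserved.
    Removing every event yields an empty table with a warning, not an
    error.
    """
    if raw.scale != RAW:
        raise ValueError("preprocess expects a raw-scale event table")
    spec = spec or FilterSpec()
    x = raw.values
    keep = np.all((x >= spec.lower_bounds) & (x <= spec.upper_bounds), axis=1)
    if not keep.any():
        warnings.warn(
            f"{raw.sample_id}: filtering removed all {raw.n_events} events"
        )
    filtered = np.log10(x[keep])
    df = pd.DataFrame(filtered, columns=list(PARAMETERS))
    return raw.copy_with(df, scale=LOG10)


def apply_gate(
    data: EventTable,
    gate: GateBox,
    replicate_of: str | None = None,
) -> StandardDataset:
    """Select the events inside a rectangular gate (inclusive bounds).

    Returns the gated events as a :class:`StandardDataset` labelled with
    the gate's name.  A warning is issued when the captured fraction
    falls below ``gate.min_fraction``.
    """
    if data.scale != LOG10:
        raise ValueError("apply_gate expects log10-scale events")
    mask = np.ones(data.n_events, dtype=bool)
    for p, (lo, hi) in gate.bounds.items():
        col = data.data[p].to_numpy()
        mask &= (col >= lo) & (col <= hi)
    fraction = mask.mean() if data.n_events else 0.0
    if fraction < gate.min_fraction:
        warnings.warn(
            f"gate {gate.label!r} captured {fraction:.1%} of events, below the "
            f"{gate.min_fraction:.0%} subpopulation threshold"
        )
    gated = data.copy_with(data.data.loc[mask], scale=LOG10)
    return StandardDataset(
        standard_name=gate.label, events=gated, replicate_of=replicate_of
    )


def partition_by_gates(
    data: EventTable, gates: Sequence[GateBox]
) -> dict[str, StandardDataset]:
    """Split events over several gates, first matching gate wins.

    Events matching no gate are discarded.  Gate order therefore acts as
    a priority when boxes overlap.
    """
    if data.scale != LOG10:
        raise ValueError("partition_by_gates expects log10-scale events")
    remaining = data
    out: dict[str, StandardDataset] = {}
    for gate in gates:
        if gate.label in out:
            raise ConfigError(f"duplicate gate label {gate.label!r}")
        out[gate.label] = apply_gate(remaining, gate)
        mask = np.ones(remaining.n_events, dtype=bool)
        for p, (lo, hi) in gate.bounds.items():
            col = remaining.data[p].to_numpy()
            mask &= (col >= lo) & (col <= hi)
        remaining = remaining.copy_with(remaining.data.loc[~mask], scale=LOG10)
    return out


def subsample_events(data: StandardDataset, n: int, seed: int) -> StandardDataset:
    """Draw ``min(n, available)`` events uniformly without replacement.

    Reproducible under a fixed seed; warns when fewer than ``n`` events
    are available (in which case all are returned).
    """
    if n < 1:
        raise ValueError("subsample size must be >= 1")
    avail = data.n_events
    if avail == 0:
        warnings.warn(f"{data.standard_name}: subsampling an empty dataset")
        return data
    if avail < n:
        warnings.warn(
            f"{data.standard_name}: only {avail} events available, requested {n}"
        )
        return data
    rng = np.random.default_rng(seed)
    idx = rng.choice(avail, size=n, replace=False)
    return StandardDataset(
        standard_name=data.standard_name,
        events=data.events.copy_with(data.events.data.iloc[idx], scale=LOG10),
        replicate_of=data.replicate_of,
        anchor_mask=data.anchor_mask[idx],
    )


def add_anchors(first_standard: StandardDataset, spec: FilterSpec) -> StandardDataset:
    """Append the two anchor events that pin scaling to the filter bounds.

    One synthetic event sits at the log10 lower filter bound on every
    parameter, the other at the log10 upper bound.  After anchoring, the
    per-parameter min/max of any training concatenation that includes
    this standard equal the log filter bounds exactly, so [-1, 1]
    min-max scaling becomes a property of the filter configuration.
    Anchors carry this standard's class label but are flagged so they
    can be excluded from evaluation.  Idempotent: re-anchoring warns and
    returns the input unchanged.
    """
    if first_standard.anchor_mask.any():
        warnings.warn(
            f"{first_standard.standard_name}: anchors already present, not re-adding"
        )
        return first_standard
    anchors = pd.DataFrame(
        [spec.log_lower, spec.log_upper], columns=list(PARAMETERS)
    )
    data = pd.concat([first_standard.events.data, anchors], ignore_index=True)
    mask = np.concatenate(
        [first_standard.anchor_mask, np.array([True, True])]
    )
    return StandardDataset(
        standard_name=first_standard.standard_name,
        events=first_standard.events.copy_with(data, scale=LOG10),
        replicate_of=first_standard.replicate_of,
        anchor_mask=mask,
    )
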
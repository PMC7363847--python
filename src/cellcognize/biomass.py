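"""Absolute densities, allometric biomass conversion and substrate yields.

Class-attribution counts become biomass through a per-standard lookup
of mean cell biovolume V (um^3, measured by 3D imaging and supplied as
a table).  Dry weight per cell follows the allometric power law
m_b = 435 * V**0.86 (fg), and carbon mass is taken as half the dry
weight.  Community carbon biomass is the count-weighted sum over
classes; uncertainty bounds propagate the biovolume mean +/- SD through
the power law.  Yields divide the produced biomass carbon by the
substrate carbon added.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .fcm import ConfigError

__all__ = [
    "allometric_biomass",
    "BiomassStandardTable",
    "CommunityBiomassEstimate",
    "community_biomass",
    "biomass_yield",
    "absolute_density",
]

#: Allometric coefficients for dry weight (fg) from biovolume (um^3).
ALLOMETRIC_COEFFICIENT = 435.0
ALLOMETRIC_EXPONENT = 0.86

#: Carbon fraction of dry weight.
CARBON_PER_DRY_WEIGHT = 0.5


def allometric_biomass(volume_um3):
    """Dry-weight biomass (fg) of a cell of biovolume ``volume_um3`` (um^3).

    Applies the allometric power law 435 * V**0.86; accepts scalars or
    arrays.  Strictly increasing and sublinear: doubling the biovolume
    less than doubles the dry weight.
    """
    v = np.asarray(volume_um3, dtype=float)
    if np.any(v < 0):
        raise ValueError("biovolume must be non-negative")
    out = ALLOMETRIC_COEFFICIENT * v**ALLOMETRIC_EXPONENT
    return float(out) if np.isscalar(volume_um3) else out


class BiomassStandardTable:
    """Per-standard biovolume statistics and derived per-cell masses.

    Built from a table with columns ``standard``, ``v_mean``, ``v_sd``
    (um^3) and optionally ``is_bead``.  Derived columns: dry weight and
    carbon mass per cell at the mean biovolume and at mean +/- SD.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"standard", "v_mean", "v_sd"}
        missing = required - set(table.columns)
        if missing:
            raise ConfigError(f"biomass table missing column(s): {sorted(missing)}")
        df = table.copy()
        if "is_bead" not in df.columns:
            df["is_bead"] = False
        if (df["v_mean"] < 0).any() or (df["v_sd"] < 0).any():
            raise ValueError("biovolumes and their SDs must be non-negative")
        df["v_lower"] = np.clip(df["v_mean"] - df["v_sd"], 0.0, None)
        df["v_upper"] = df["v_mean"] + df["v_sd"]
        for which in ("mean", "lower", "upper"):
            dry = allometric_biomass(df[f"v_{which}"].to_numpy())
            df[f"dry_{which}_fg"] = dry
            df[f"carbon_{which}_fg"] = dry * CARBON_PER_DRY_WEIGHT
        self.table = df.set_index("standard")

    @classmethod
    def from_csv(cls, path: str | Path) -> "BiomassStandardTable":
        return cls(pd.read_csv(path))

    def carbon_per_cell(self, standard: str, which: str = "mean") -> float:
        return float(self.table.loc[standard, f"carbon_{which}_fg"])


@dataclass
class CommunityBiomassEstimate:
    """Per-class and total community carbon biomass (fg C) with bounds."""

    per_class: pd.DataFrame
    total_fg_c: float
    lower_fg_c: float
    upper_fg_c: float
    excluded_classes: list[str]


def community_biomass(
    mean_counts: pd.Series | Mapping[str, float],
    table: BiomassStandardTable,
    include_beads: bool = False,
) -> CommunityBiomassEstimate:
    """Carbon biomass of a classified community from per-class mean counts.

    Each class's mean attributed event count is multiplied by that
    standard's per-cell carbon mass and summed.  Bead classes are
    excluded by default (polystyrene is not biomass); with
    ``include_beads=True`` their allometric mass proxy is used and the
    classes are flagged in the output.  Lower/upper totals propagate
    the biovolume mean +/- SD.
    """
    counts = pd.Series(mean_counts, dtype=float)
    missing = [c for c in counts.index
               if c not in table.table.index and counts[c] > 0]
    if missing:
        raise ConfigError(f"no biomass entry for counted class(es): {missing}")
    rows = []
    excluded = []
    for cls_name, n in counts.items():
        if cls_name not in table.table.index:
            continue
        info = table.table.loc[cls_name]
        if info["is_bead"] and not include_beads:
            excluded.append(str(cls_name))
            continue
        rows.append({
            "standard": cls_name,
            "mean_count": n,
            "is_bead_proxy": bool(info["is_bead"]),
            "carbon_fg": n * info["carbon_mean_fg"],
            "carbon_lower_fg": n * info["carbon_lower_fg"],
            "carbon_upper_fg": n * info["carbon_upper_fg"],
        })
    per_class = pd.DataFrame(
        rows, columns=["standard", "mean_count", "is_bead_proxy",
                       "carbon_fg", "carbon_lower_fg", "carbon_upper_fg"],
    ).set_index("standard")
    return CommunityBiomassEstimate(
        per_class=per_class,
        total_fg_c=float(per_class["carbon_fg"].sum()),
        lower_fg_c=float(per_class["carbon_lower_fg"].sum()),
        upper_fg_c=float(per_class["carbon_upper_fg"].sum()),
        excluded_classes=excluded,
    )


def biomass_yield(biomass_produced_g_c: float, substrate_added_g_c: float) -> float:
    """Yield in g biomass-C per g substrate-C.

    ``biomass_produced_g_c`` is the biomass difference between the end
    and start of the incubation; negative production (apparent loss) is
    floored at zero with a warning.  Both quantities must share the
    same mass unit — the ratio is then unit-free.
    """
    if substrate_added_g_c <= 0:
        raise ValueError("substrate carbon added must be positive")
    if biomass_produced_g_c < 0:
        warnings.warn("negative biomass production floored at 0")
        biomass_produced_g_c = 0.0
    return biomass_produced_g_c / substrate_added_g_c


def absolute_density(
    events: int, analyzed_volume_ul: float, dilution_factor: float = 1.0
) -> float:
    """Volumetric cell density (cells per ml) from an event count.

    Relies on the cytometer's volumetric counting: density =
    events / (volume in ml) * dilution factor.
    """
    if analyzed_volume_ul <= 0:
        raise ValueError("analyzed volume must be positive")
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    return events / (analyzed_volume_ul / 1000.0) * dilution_factor
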
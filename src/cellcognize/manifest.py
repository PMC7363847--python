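"""Standards manifest: YAML description of standards, gates, filters, biomass.

Example manifest::

    filter:
      lower: 100
      upper: 1.0e7
    standards:
      - name: AJH1
        source: ajh.csv        # raw event table, CSV
        gate:                  # log10 bounds on the three height channels
          FITC-H: [2.5, 4.5]
          SSC-H: [2.0, 4.0]
          FSC-H: [2.5, 4.5]
        biovolume: {mean: 0.52, sd: 0.11}
        is_bead: false
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .biomass import BiomassStandardTable
from .fcm import ConfigError, FilterSpec, GateBox


@dataclass
class StandardEntry:
    name: str
    source: Path
    gate: GateBox | None
    biovolume_mean: float | None
    biovolume_sd: float | None
    is_bead: bool = False


@dataclass
class Manifest:
    filter_spec: FilterSpec
    standards: list[StandardEntry]

    def biomass_table(self) -> BiomassStandardTable:
        rows = [
            {"standard": s.name, "v_mean": s.biovolume_mean,
             "v_sd": s.biovolume_sd, "is_bead": s.is_bead}
            for s in self.standards if s.biovolume_mean is not None
        ]
        if not rows:
            raise ConfigError("manifest contains no biovolume entries")
        return BiomassStandardTable(pd.DataFrame(rows))


def load_manifest(path: str | Path) -> Manifest:
    """Parse a YAML standards manifest; paths resolve relative to the file."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "standards" not in doc:
        raise ConfigError(f"{path}: manifest must define a 'standards' list")
    filt = doc.get("filter", {})
    spec = FilterSpec(lower=filt.get("lower", 100.0), upper=filt.get("upper", 1e7))
    entries = []
    seen = set()
    for item in doc["standards"]:
        name = item.get("name")
        if not name:
            raise ConfigError(f"{path}: every standard needs a 'name'")
        if name in seen:
            raise ConfigError(f"{path}: duplicate standard name {name!r}")
        seen.add(name)
        gate = None
        if "gate" in item:
            gate = GateBox(
                bounds={p: tuple(b) for p, b in item["gate"].items()},
                label=name,
                min_fraction=item.get("min_fraction", 0.05),
            )
        bv = item.get("biovolume") or {}
        entries.append(StandardEntry(
            name=name,
            source=(path.parent / item["source"]) if "source" in item else None,
            gate=gate,
            biovolume_mean=bv.get("mean"),
            biovolume_sd=bv.get("sd"),
            is_bead=bool(item.get("is_bead", False)),
        ))
    return Manifest(filter_spec=spec, standards=entries)
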
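"""Holdridge life-zone classification from a monthly climate stack.

The classifier is the environmental axis of the genetic-differentiation
proxies: cells with similar biotemperature and moisture regime are grouped
into one life zone.  We use the basic Holdridge lattice of latitudinal
belts (by annual biotemperature) crossed with humidity provinces (by the
ratio of potential evapotranspiration to precipitation), without the
frost-line or transitional-hexagon refinements.

Definitions
-----------
* biotemperature — annual mean of the 12 monthly mean temperatures, each
  month clamped to [0, 30] degC before averaging (temperatures outside that
  range contribute nothing to plant growth in Holdridge's system).
* PET ratio — annual potential evapotranspiration divided by annual
  precipitation, with PET = 58.93 x biotemperature (mm/yr per degC).
* belts — biotemperature intervals with boundaries {1.5, 3, 6, 12, 24},
  lower-inclusive, e.g. the warm-temperate/subtropical belt is [12, 24).
* humidity provinces — PET-ratio intervals with log2-spaced boundaries
  {0.125, 0.25, 0.5, 1, 2, 4, 8, 16, 32}, lower-inclusive / upper-exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .grids import GridError, LabelGrid, ValueGrid, check_alignment

__all__ = [
    "ClimateStack",
    "LifeZoneMap",
    "biotemperature",
    "pet_ratio",
    "classify_lifezones",
    "BELT_BOUNDS",
    "HUMIDITY_BOUNDS",
    "BELT_NAMES",
    "HUMIDITY_NAMES",
    "PET_COEFFICIENT",
]

#: Holdridge PET constant: annual potential evapotranspiration in mm per
#: degC of biotemperature.
PET_COEFFICIENT = 58.93

#: Latitudinal-belt boundaries on biotemperature (degC); lower-inclusive.
BELT_BOUNDS = (1.5, 3.0, 6.0, 12.0, 24.0)

#: Humidity-province boundaries on the PET ratio; lower-inclusive.
HUMIDITY_BOUNDS = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)

BELT_NAMES = (
    "polar",
    "subpolar",
    "boreal",
    "cool temperate",
    "warm temperate",
    "tropical",
)

#: From wet (low PET ratio) to dry (high PET ratio).
HUMIDITY_NAMES = (
    "saturated",
    "subsaturated",
    "superhumid",
    "perhumid",
    "humid",
    "subhumid",
    "semiarid",
    "arid",
    "perarid",
    "superarid",
)


@dataclass
class ClimateStack:
    """Twelve aligned monthly mean-temperature grids plus annual precipitation."""

    monthly_temperature: Sequence[ValueGrid]
    annual_precipitation: ValueGrid

    def __post_init__(self) -> None:
        if len(self.monthly_temperature) != 12:
            raise GridError(
                f"expected 12 monthly temperature grids, got {len(self.monthly_temperature)}"
            )
        check_alignment([*self.monthly_temperature, self.annual_precipitation])
        p = self.annual_precipitation
        if (p.values[p.data_mask] < 0).any():
            raise GridError("negative precipitation outside nodata")


@dataclass
class LifeZoneMap:
    """Life-zone partition plus its legend.

    ``legend`` columns: zone_id, belt, humidity, name — one row per label
    present in ``zones``, ids consecutive from 1 ordered by (belt, humidity).
    """

    zones: LabelGrid
    legend: pd.DataFrame

    def __post_init__(self) -> None:
        present = set(self.zones.label_set().tolist())
        listed = set(self.legend["zone_id"].tolist())
        if present != listed:
            raise GridError("legend ids do not match zone labels")

    @property
    def n_zones(self) -> int:
        return len(self.legend)


def biotemperature(monthly_temperature: Sequence[ValueGrid]) -> ValueGrid:
    """Annual biotemperature: mean of monthly values clamped to [0, 30] degC.

    A cell is nodata in the output if any month is nodata there.
    """
    if len(monthly_temperature) != 12:
        raise GridError(
            f"expected 12 monthly temperature grids, got {len(monthly_temperature)}"
        )
    check_alignment(monthly_temperature)
    spec = monthly_temperature[0].spec
    stack = np.stack([g.filled(np.nan) for g in monthly_temperature])
    clamped = np.clip(stack, 0.0, 30.0)
    mean = clamped.mean(axis=0)
    out = np.where(np.isnan(mean), spec.nodata, mean)
    return ValueGrid(spec=spec, values=out)


def pet_ratio(biotemp: ValueGrid, precipitation: ValueGrid) -> ValueGrid:
    """Potential-evapotranspiration ratio: 58.93 x biotemperature / precipitation."""
    check_alignment([biotemp, precipitation])
    spec = biotemp.spec
    bt = biotemp.filled(np.nan)
    p = precipitation.filled(np.nan)
    both = ~np.isnan(bt) & ~np.isnan(p)
    zero_p = both & (p == 0)
    if zero_p.any():
        cells = np.argwhere(zero_p)[:10].tolist()
        raise GridError(f"zero precipitation on non-nodata cells, e.g. {cells}")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = PET_COEFFICIENT * bt / p
    out = np.where(both, ratio, spec.nodata)
    return ValueGrid(spec=spec, values=out)


def belt_index(biotemp_values: np.ndarray) -> np.ndarray:
    """Latitudinal belt per value: 0 (polar) .. 5 (tropical); lower-inclusive."""
    return np.searchsorted(np.asarray(BELT_BOUNDS), biotemp_values, side="right")


def humidity_index(ratio_values: np.ndarray) -> np.ndarray:
    """Humidity province per PET-ratio value: 0 (saturated) .. 9 (superarid)."""
    return np.searchsorted(np.asarray(HUMIDITY_BOUNDS), ratio_values, side="right")


def classify_lifezones(climate: ClimateStack) -> LifeZoneMap:
    """Classify every cell with complete climate data into a life zone.

    Zones are the occupied (belt, humidity province) pairs, relabeled
    consecutively from 1 in (belt, humidity) order; the legend carries the
    standard belt and humidity-province names.
    """
    bt = biotemperature(climate.monthly_temperature)
    ratio = pet_ratio(bt, climate.annual_precipitation)
    spec = bt.spec
    btv = bt.filled(np.nan)
    rv = ratio.filled(np.nan)
    valid = ~np.isnan(btv) & ~np.isnan(rv)

    belts = belt_index(np.where(valid, btv, 0.0))
    hums = humidity_index(np.where(valid, rv, 0.0))
    combo = belts * len(HUMIDITY_NAMES) + hums

    occupied = np.unique(combo[valid])
    labels = np.zeros(spec.shape, dtype=np.int32)
    rows = []
    for zone_id, c in enumerate(np.sort(occupied), start=1):
        b, h = divmod(int(c), len(HUMIDITY_NAMES))
        labels[valid & (combo == c)] = zone_id
        rows.append(
            {
                "zone_id": zone_id,
                "belt": b,
                "humidity": h,
                "name": f"{BELT_NAMES[b]} {HUMIDITY_NAMES[h]}",
            }
        )
    legend = pd.DataFrame(rows, columns=["zone_id", "belt", "humidity", "name"])
    return LifeZoneMap(zones=LabelGrid(spec=spec, labels=labels), legend=legend)
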
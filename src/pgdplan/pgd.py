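"""Proxies of genetic differentiation (PGD).

A PGD is a geographic zone within which populations are expected to be
genetically similar and between which differentiated.  It is built by
subdividing each environmental life zone by "divider" cartography that
captures historical isolation — biogeographic provinces, watersheds,
edaphic units — with a per-life-zone choice of which dividers apply.
The result is a non-overlapping partition of the land mask in which every
PGD is nested inside exactly one life zone.  PGDs need not be spatially
connected: one PGD may consist of several patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import GridError, LabelGrid, check_alignment
from .lifezones import LifeZoneMap

__all__ = ["DividerSet", "PGDMap", "subdivide_lifezones", "filter_fragments", "pgd_summary"]


@dataclass
class DividerSet:
    """Named categorical divider rasters plus the per-life-zone assignment.

    ``assignment`` maps a life-zone id to the ordered list of divider names
    used to split that zone; an empty list means the zone is not subdivided.
    """

    dividers: Mapping[str, LabelGrid]
    assignment: Mapping[int, Sequence[str]]

    def validate(self, lifezones: LifeZoneMap) -> None:
        check_alignment([lifezones.zones, *self.dividers.values()])
        present = set(lifezones.zones.label_set().tolist())
        missing_zones = present - set(self.assignment)
        if missing_zones:
            raise GridError(
                f"assignment missing for life zones: {sorted(missing_zones)}"
            )
        for zone, names in self.assignment.items():
            unknown = [n for n in names if n not in self.dividers]
            if unknown:
                raise GridError(
                    f"life zone {zone} assigned unknown dividers: {unknown}"
                )


@dataclass
class PGDMap:
    """Partition of the land mask into genetic-differentiation proxy zones.

    ``provenance`` columns: pgd_id, lifezone_id, divider_combo (string
    ``name=class;...``, empty for undivided zones), n_cells.
    """

    zones: LabelGrid
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        present = set(self.zones.label_set().tolist())
        listed = set(self.provenance["pgd_id"].tolist())
        if present != listed:
            raise GridError("provenance ids do not match PGD labels")

    @property
    def n_pgd(self) -> int:
        return len(self.provenance)

    def areas(self) -> pd.Series:
        """Cell count per pgd id, recomputed from the label grid."""
        labels = self.zones.labels
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        return pd.Series(counts, index=ids, name="n_cells")


def subdivide_lifezones(lifezones: LifeZoneMap, dividers: DividerSet) -> PGDMap:
    """Split each life zone by the joint class of its assigned dividers.

    Occupied (life zone, divider-class combination) pairs are relabeled
    consecutively from 1, ordered by (life zone id, class tuple), so the
    labeling is deterministic for identical inputs.
    """
    dividers.validate(lifezones)
    lz = lifezones.zones
    spec = lz.spec
    out = np.zeros(spec.shape, dtype=np.int32)
    rows = []
    next_id = 1
    for zone in lz.label_set():
        zone = int(zone)
        in_zone = lz.labels == zone
        names = list(dividers.assignment[zone])
        if not names:
            out[in_zone] = next_id
            rows.append(
                {
                    "pgd_id": next_id,
                    "lifezone_id": zone,
                    "divider_combo": "",
                    "n_cells": int(in_zone.sum()),
                }
            )
            next_id += 1
            continue
        class_stack = np.stack(
            [dividers.dividers[n].labels[in_zone] for n in names], axis=1
        )
        combos, inverse = np.unique(class_stack, axis=0, return_inverse=True)
        # lexicographic order of np.unique over rows is the deterministic order
        zone_ids = np.zeros(in_zone.sum(), dtype=np.int32)
        for k, combo in enumerate(combos):
            zone_ids[inverse == k] = next_id
            rows.append(
                {
                    "pgd_id": next_id,
                    "lifezone_id": zone,
                    "divider_combo": ";".join(
                        f"{n}={int(c)}" for n, c in zip(names, combo)
                    ),
                    "n_cells": int((inverse == k).sum()),
                }
            )
            next_id += 1
        out[in_zone] = zone_ids
    provenance = pd.DataFrame(
        rows, columns=["pgd_id", "lifezone_id", "divider_combo", "n_cells"]
    )
    return PGDMap(zones=LabelGrid(spec=spec, labels=out), provenance=provenance)


def _relabel(
    labels: np.ndarray, provenance: pd.DataFrame
) -> tuple[pd.DataFrame, np.ndarray]:
    """Relabel surviving PGDs consecutively, keeping (lifezone, combo) order."""
    surviving = provenance[provenance["pgd_id"].isin(np.unique(labels[labels > 0]))]
    surviving = surviving.sort_values(["lifezone_id", "divider_combo"], kind="stable")
    mapping = {old: new for new, old in enumerate(surviving["pgd_id"], start=1)}
    out = np.zeros_like(labels)
    for old, new in mapping.items():
        out[labels == old] = new
    rows = surviving.copy()
    rows["pgd_id"] = rows["pgd_id"].map(mapping)
    counts = pd.Series(out[out > 0]).value_counts()
    rows["n_cells"] = rows["pgd_id"].map(counts)
    rows = rows.sort_values("pgd_id").reset_index(drop=True)
    return rows, out


def filter_fragments(pgd: PGDMap, min_cells: int) -> PGDMap:
    """Merge PGDs smaller than ``min_cells`` into a same-life-zone neighbor.

    A too-small PGD is absorbed by the largest 4-adjacent PGD of the same
    life zone; if none exists its cells become nodata (and are reported in
    the provenance as dropped).  ``min_cells = 0`` is the identity.
    Merging proceeds smallest-first and repeats until stable, so two small
    fragments may first merge with each other and then survive.
    """
    if min_cells < 0:
        raise GridError("min_cells must be >= 0")
    if min_cells == 0:
        return pgd
    labels = pgd.zones.labels.copy()
    prov = pgd.provenance.set_index("pgd_id")
    lifezone_of = prov["lifezone_id"].to_dict()

    def neighbors_of(pid: int) -> dict[int, int]:
        mask = labels == pid
        neigh: dict[int, int] = {}
        for shift, axis in ((1, 0), (-1, 0), (1, 1), (-1, 1)):
            rolled = np.roll(labels, shift, axis=axis)
            if axis == 0:
                edge = slice(0, 1) if shift == 1 else slice(-1, None)
                rolled[edge, :] = 0
            else:
                if shift == 1:
                    rolled[:, 0] = 0
                else:
                    rolled[:, -1] = 0
            vals = rolled[mask]
            for v in np.unique(vals):
                v = int(v)
                if v > 0 and v != pid and lifezone_of.get(v) == lifezone_of[pid]:
                    neigh[v] = neigh.get(v, 0) + int((vals == v).sum())
        return neigh

    while True:
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        sizes = dict(zip(ids.tolist(), counts.tolist()))
        small = sorted(
            (pid for pid, n in sizes.items() if n < min_cells),
            key=lambda pid: (sizes[pid], pid),
        )
        if not small:
            break
        pid = small[0]
        neigh = neighbors_of(pid)
        if neigh:
            # largest same-zone neighbor; ties to smallest id
            target = max(neigh, key=lambda v: (sizes.get(v, 0), -v))
            labels[labels == pid] = target
        else:
            labels[labels == pid] = 0  # drop isolated fragment to nodata
    new_prov, new_labels = _relabel(labels, pgd.provenance)
    return PGDMap(
        zones=LabelGrid(spec=pgd.zones.spec, labels=new_labels), provenance=new_prov
    )


def pgd_summary(pgd: PGDMap) -> pd.DataFrame:
    """One row per PGD: id, life zone, divider combination, cell count, area."""
    counts = pgd.areas()
    df = pgd.provenance.copy()
    df["n_cells"] = df["pgd_id"].map(counts)
    df["area"] = df["n_cells"] * pgd.zones.spec.cell_area
    return df[["pgd_id", "lifezone_id", "divider_combo", "n_cells", "area"]]
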
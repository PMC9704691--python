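"""Great-circle geometry and closest-genetic-neighbor summaries.

Distances are haversine great-circle kilometres on a sphere of radius
6371.0088 km (the IUGG mean Earth radius); no ellipsoid correction is applied,
matching the precision at which population sampling locations are known.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import FstMatrix, PopulationPanel, ValidationError

EARTH_RADIUS_KM = 6371.0088


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    lat1, lon1 = np.radians(a)
    lat2, lon2 = np.radians(b)
    s = (
        np.sin((lat2 - lat1) / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    )
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0))))


def distance_matrix_km(panel: PopulationPanel) -> pd.DataFrame:
    """All pairwise great-circle distances of a panel (km), vectorised."""
    coords = np.radians(panel.coordinates())
    lat = coords[:, 0][:, None]
    lon = coords[:, 1][:, None]
    s = (
        np.sin((lat.T - lat) / 2.0) ** 2
        + np.cos(lat) * np.cos(lat.T) * np.sin((lon.T - lon) / 2.0) ** 2
    )
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=panel.pop_ids, columns=panel.pop_ids)


@dataclass
class NeighborSummary:
    """Radius neighbour counts and closest-FST neighbour for one population."""

    pop_id: str
    counts_other_family: dict[float, int]
    closest_genetic_pop: Optional[str]
    closest_genetic_same_family: Optional[bool]

    @property
    def has_closest(self) -> bool:
        return self.closest_genetic_pop is not None


def neighbor_counts(
    panel: PopulationPanel,
    fst: FstMatrix,
    radii: Sequence[float] = (500.0, 1000.0),
) -> list[NeighborSummary]:
    """Per population: other-family neighbours within each radius (closed ball)
    and the closest-FST neighbour with its family concordance.

    Closest-FST ties are broken by smaller geographic distance, then by
    lexicographic pop_id.  Populations with no finite FST to any other are
    reported with no closest neighbour and excluded from concordance.
    """
    if len(panel) < 2:
        raise ValidationError("neighbor_counts needs at least 2 populations")
    geo = distance_matrix_km(panel)
    out = []
    for rec in panel:
        others = [p for p in panel.pop_ids if p != rec.pop_id]
        other_family = [p for p in others if panel.family_of(p) != rec.family]
        d = geo.loc[rec.pop_id]
        counts = {float(r): int(sum(d[p] <= r for p in other_family)) for r in radii}
        f = fst.row(rec.pop_id)
        f = f[np.isfinite(f.to_numpy())]
        if len(f) == 0:
            out.append(NeighborSummary(rec.pop_id, counts, None, None))
            continue
        fmin = f.min()
        cands = sorted(f.index[f == fmin], key=lambda p: (d[p], p))
        best = cands[0]
        out.append(
            NeighborSummary(
                rec.pop_id, counts, best,
                panel.family_of(best) == rec.family,
            )
        )
    return out


def family_span_km(
    panel: PopulationPanel,
    family: str,
    radius_floor_km: float = 500.0,
    geo: Optional[pd.DataFrame] = None,
) -> float:
    """Geographic span of a family: the largest within-family pairwise
    distance, floored at ``radius_floor_km``.  Undefined for singletons."""
    members = panel.family_members(family)
    if len(members) < 2:
        raise ValidationError(f"family {family!r} has < 2 members; span undefined")
    if geo is None:
        geo = distance_matrix_km(panel.subset(members))
    span = float(geo.loc[members, members].to_numpy().max())
    return max(span, radius_floor_km)


def concordance_rate(summaries: Sequence[NeighborSummary]) -> float:
    """Fraction of populations whose closest-FST neighbour belongs to a
    *different* language family (the closest-neighbour mismatch proportion),
    over populations with a defined closest neighbour."""
    defined = [s for s in summaries if s.has_closest]
    if not defined:
        raise ValidationError("no population has a defined closest neighbour")
    return sum(not s.closest_genetic_same_family for s in defined) / len(defined)


def neighbor_table(summaries: Sequence[NeighborSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"pop_id": s.pop_id}
        for r, c in sorted(s.counts_other_family.items()):
            row[f"n_other_family_within_{int(r)}km"] = c
        row["closest_genetic_pop"] = s.closest_genetic_pop
        row["closest_genetic_same_family"] = s.closest_genetic_same_family
        rows.append(row)
    return pd.DataFrame(rows)
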
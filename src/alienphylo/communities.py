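"""Occurrence cleaning, spatial thinning, and community construction.

Occurrence records are pandas DataFrames with columns
``species, lon, lat, status`` (plus optional ``source``). Records are
deduplicated on exact coordinates, spatially rarefied so no two retained
points of a species lie within a minimum great-circle distance (default
5 km, matching the resolution of typical bioclimatic rasters), assigned to
the spatial units of each scale, and expanded into the seven community
types analysed per unit: the three single-status communities (Inv, Nat,
Int), the three pairwise co-occurrence communities (InvNat, InvInt, NatInt)
and the full community (All).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import Point

logger = logging.getLogger(__name__)

__all__ = [
    "COMMUNITY_TYPES",
    "EARTH_RADIUS_KM",
    "CommunityMatrix",
    "Assemblage",
    "haversine_km",
    "validate_records",
    "dedupe",
    "thin_occurrences",
    "assign_to_regions",
    "build_assemblages",
]

EARTH_RADIUS_KM = 6371.0

#: community type -> statuses pooled into it
COMMUNITY_TYPES = {
    "Inv": ("invasive",),
    "Nat": ("naturalized",),
    "Int": ("introduced",),
    "InvNat": ("invasive", "naturalized"),
    "InvInt": ("invasive", "introduced"),
    "NatInt": ("naturalized", "introduced"),
    "All": ("invasive", "naturalized", "introduced"),
}

_VALID_STATUSES = frozenset(("introduced", "naturalized", "invasive"))


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = {"species", "lon", "lat", "status"} - set(records.columns)
    if missing:
        raise ValueError(f"occurrence table missing columns: {sorted(missing)}")
    bad_status = set(records["status"].unique()) - _VALID_STATUSES
    if bad_status:
        raise ValueError(f"invalid status values: {sorted(bad_status)}")
    if (records["lat"].abs() > 90).any() or (records["lon"].abs() > 180).any():
        raise ValueError("coordinates out of range")
    return records


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def dedupe(records: pd.DataFrame) -> pd.DataFrame:
    """Drop exact duplicate (species, lon, lat) records, keeping the first."""
    return records.drop_duplicates(
        subset=["species", "lon", "lat"], keep="first"
    ).reset_index(drop=True)


def thin_occurrences(
    records: pd.DataFrame,
    min_dist_km: float = 5.0,
    sort: bool = False,
) -> pd.DataFrame:
    """Spatially rarefy each species' records to a minimum pairwise distance.

    Greedy in input order: a record is kept iff it lies at least
    ``min_dist_km`` (haversine) from every previously kept record of the
    same species. With ``sort=True`` records are first ordered by
    (species, lon, lat) so the result is independent of input order.
    """
    if min_dist_km <= 0:
        raise ValueError("min_dist_km must be positive")
    if sort:
        records = records.sort_values(["species", "lon", "lat"],
                                      kind="stable").reset_index(drop=True)
    keep_idx = []
    for _, group in records.groupby("species", sort=False):
        lon = group["lon"].to_numpy()
        lat = group["lat"].to_numpy()
        kept: list[int] = []
        for i in range(len(group)):
            if not kept or np.all(
                haversine_km(lon[kept], lat[kept], lon[i], lat[i]) >= min_dist_km
            ):
                kept.append(i)
        keep_idx.extend(group.index[kept])
    return records.loc[sorted(keep_idx)].reset_index(drop=True)


@dataclass
class CommunityMatrix:
    """Spatial-unit × species table of occurrence counts for one scale."""

    scale: str
    counts: pd.DataFrame  # index: unit ids, columns: species, values: int
    n_dropped: int = 0

    @property
    def units(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    def to_long(self) -> pd.DataFrame:
        long = self.counts.stack().rename("count").reset_index()
        long.columns = ["unit", "species", "count"]
        long.insert(0, "scale", self.scale)
        return long[long["count"] > 0].reset_index(drop=True)


def _check_disjoint(units) -> None:
    for i in range(len(units)):
        for j in range(i + 1, len(units)):
            inter = units[i][1].intersection(units[j][1])
            if not inter.is_empty and inter.area > 1e-12:
                raise ValueError(
                    f"overlapping units: {units[i][0]} and {units[j][0]}"
                )


def assign_to_regions(
    records: pd.DataFrame,
    regions,
    scale: str = "default",
) -> CommunityMatrix:
    """Count each species' records per spatial unit of one scale.

    ``regions`` is a list of ``(unit_id, polygon)`` pairs (disjoint). A point
    on a shared boundary is credited to the unit with the lexicographically
    smallest id; points inside no unit are dropped (and counted in
    ``n_dropped``), the analogue of discarding occurrences that fall in the
    ocean. Units without records keep an all-zero row.
    """
    units = sorted(regions, key=lambda u: u[0])
    _check_disjoint(units)
    polys = [p for _, p in units]
    ids = [u for u, _ in units]
    tree = STRtree(polys)
    species_list = sorted(records["species"].unique())
    counts = pd.DataFrame(
        0, index=pd.Index(ids, name="unit"),
        columns=pd.Index(species_list, name="species"), dtype=int,
    )
    pts = np.array(
        [Point(x, y) for x, y in zip(records["lon"], records["lat"])], dtype=object
    )
    sp_codes = records["species"].map(
        {s: i for i, s in enumerate(species_list)}
    ).to_numpy()
    pt_idx, poly_idx = tree.query(pts, predicate="covered_by")
    # boundary points hit several units; keep the smallest poly index, which
    # is the lexicographically smallest unit id since units are sorted
    assign = {}
    for p, u in zip(pt_idx, poly_idx):
        if p not in assign or u < assign[p]:
            assign[p] = u
    n_dropped = len(records) - len(assign)
    arr = counts.to_numpy()
    for p, u in assign.items():
        arr[u, sp_codes[p]] += 1
    counts = pd.DataFrame(arr, index=counts.index, columns=counts.columns)
    if n_dropped:
        logger.info("%s: %d record(s) outside all units dropped", scale, n_dropped)
    return CommunityMatrix(scale=scale, counts=counts, n_dropped=n_dropped)


@dataclass
class Assemblage:
    """One spatial unit's species subset for one community type."""

    unit: str
    scale: str
    community_type: str
    abundances: pd.Series  # index: species, values >= 1
    usable: bool = field(default=True)

    @property
    def n_taxa(self) -> int:
        return len(self.abundances)


def build_assemblages(
    matrix: CommunityMatrix, statuses: dict[str, str]
) -> list[Assemblage]:
    """Expand a community matrix into the seven per-unit community types.

    A community type is a status filter applied within the unit (the unit's
    species of that status / status pair / all three), carrying the unit's
    occurrence counts unchanged. Assemblages with fewer than two species are
    emitted with ``usable=False`` so they are flagged rather than silently
    dropped.
    """
    missing = set(matrix.species) - set(statuses)
    if missing:
        raise ValueError(f"species without status: {sorted(missing)}")
    status_arr = pd.Series({s: statuses[s] for s in matrix.species})
    out = []
    for unit in matrix.units:
        row = matrix.counts.loc[unit]
        present = row[row > 0]
        for ctype, wanted in COMMUNITY_TYPES.items():
            sub = present[status_arr[present.index].isin(wanted)]
            out.append(
                Assemblage(
                    unit=unit,
                    scale=matrix.scale,
                    community_type=ctype,
                    abundances=sub.astype(int),
                    usable=len(sub) >= 2,
                )
            )
    return out
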
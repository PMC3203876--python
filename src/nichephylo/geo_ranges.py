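"""Buffer-union geographic ranges and pairwise range overlap.

A species' range is estimated as the union of discs of a fixed radius
around its (deduplicated) collection points; the overlap of a pair is the
intersection area expressed as a percentage of the smaller range.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.ops import unary_union

from .containers import InvalidArgumentError, OccurrenceSet

#: default buffer radius (km); 2 and 10 km are the usual alternatives
DEFAULT_RADIUS_KM = 20.0

#: vertices per disc in the polygonal approximation (4 * quad_segs)
DISC_QUAD_SEGS = 16

EARTH_RADIUS_KM = 6371.0088


def project_lonlat(lonlat: np.ndarray, lon0: float = 0.0) -> np.ndarray:
    """Cylindrical equal-area (Lambert) projection of lon/lat degrees to km.

    Equal-area so that buffer and overlap areas are unbiased; adequate for
    the low-latitude study extents this pipeline targets.
    """
    lonlat = np.atleast_2d(np.asarray(lonlat, dtype=float))
    x = np.radians(lonlat[:, 0] - lon0) * EARTH_RADIUS_KM
    y = np.sin(np.radians(lonlat[:, 1])) * EARTH_RADIUS_KM
    return np.column_stack([x, y])


@dataclass
class BufferRange:
    """Union-of-discs range estimate for one species."""

    species_id: str
    radius_km: float
    geometry: object  # shapely geometry
    area_km2: float

    def contains_points(self, xy: np.ndarray) -> np.ndarray:
        from shapely import points as _points
        from shapely import contains as _contains

        xy = np.atleast_2d(xy)
        return _contains(self.geometry, _points(xy[:, 0], xy[:, 1]))


def dedup_localities(occ: OccurrenceSet) -> OccurrenceSet:
    """Drop coordinate-identical localities (order-independent)."""
    return occ.dedup()


def buffer_range(occ: OccurrenceSet, radius_km: float = DEFAULT_RADIUS_KM) -> BufferRange:
    """Fuse discs of ``radius_km`` around every locality into one range."""
    if radius_km <= 0:
        raise InvalidArgumentError("radius_km must be positive")
    occ = occ if occ.deduplicated else occ.dedup()
    if len(occ) == 0:
        raise InvalidArgumentError("cannot buffer an empty occurrence set")
    discs = [Point(x, y).buffer(radius_km, quad_segs=DISC_QUAD_SEGS) for x, y in occ.points]
    geom = unary_union(discs)
    return BufferRange(occ.species_id, radius_km, geom, float(geom.area))


def range_overlap_pct(a: BufferRange, b: BufferRange) -> float:
    """Intersection area as % of the smaller of the two range areas."""
    if a.radius_km != b.radius_km:
        raise InvalidArgumentError("ranges must use the same buffer radius")
    smaller = min(a.area_km2, b.area_km2)
    if smaller <= 0:
        raise InvalidArgumentError("smaller range has zero area")
    inter = a.geometry.intersection(b.geometry).area
    return 100.0 * inter / smaller


def overlap_table(
    ranges: dict[str, BufferRange], pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Pairwise overlap summary (species_a, species_b, pct, smaller species)."""
    rows = []
    for sa, sb in pairs:
        ra, rb = ranges[sa], ranges[sb]
        pct = range_overlap_pct(ra, rb)
        smaller = sa if ra.area_km2 <= rb.area_km2 else sb
        rows.append(
            {
                "species_a": sa,
                "species_b": sb,
                "pct_overlap": pct,
                "smaller_range_species": smaller if pct > 0 else "no overlap",
            }
        )
    return pd.DataFrame(rows)


def export_wkt(ranges: dict[str, BufferRange], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sp, rng in sorted(ranges.items()):
            fh.write(f"{sp}\t{rng.geometry.wkt}\n")
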
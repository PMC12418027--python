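"""Great-circle deduplication of occurrence records.

Occurrence datasets pooled from herbaria and field surveys contain near-duplicate
records (the same tree reported by several collectors, GPS jitter around one
population). Records of the same species closer than a distance threshold —
1 km by convention for 30 arc-second climate layers — are collapsed to a single
representative so that one densely re-collected site does not dominate the
estimated climatic niche.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0
WGS84 = "EPSG:4326"


class CoordinateError(ValueError):
    """A longitude/latitude pair outside valid WGS84 bounds."""


@dataclass(frozen=True)
class OccurrenceRecord:
    """One georeferenced presence point (WGS84 decimal degrees)."""

    species: str
    lon: float
    lat: float
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species label must be non-empty")
        _validate_coords(self.lon, self.lat)


@dataclass
class OccurrenceSet:
    """Ordered collection of occurrence records, fixed to WGS84.

    Input order is preserved throughout: the thinning scan is defined in terms
    of it, and reports refer to positional indices within this set.
    """

    records: list[OccurrenceRecord] = field(default_factory=list)

    #: coordinate reference of all records; immutable by convention
    crs: str = WGS84

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterable[OccurrenceRecord]:
        return iter(self.records)

    def species_labels(self) -> list[str]:
        return [r.species for r in self.records]

    def coords(self) -> np.ndarray:
        """(n, 2) array of (lon, lat)."""
        return np.array([[r.lon, r.lat] for r in self.records], dtype=float).reshape(-1, 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": [r.species for r in self.records],
                "lon": [r.lon for r in self.records],
                "lat": [r.lat for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OccurrenceSet":
        recs = [
            OccurrenceRecord(str(s), float(x), float(y))
            for s, x, y in zip(df["species"], df["lon"], df["lat"])
        ]
        return cls(recs)

    @classmethod
    def read_csv(cls, path) -> "OccurrenceSet":
        # round_trip parsing keeps written coordinates bit-identical on re-read
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _validate_coords(lon: float, lat: float) -> None:
    if not (-180.0 <= lon <= 180.0):
        raise CoordinateError(f"longitude {lon} outside [-180, 180]")
    if not (-90.0 <= lat <= 90.0):
        raise CoordinateError(f"latitude {lat} outside [-90, 90]")


def haversine_km(
    a: Sequence[float],
    b: Sequence[float],
    earth_radius_km: float = EARTH_RADIUS_KM,
) -> float:
    """Great-circle distance between two (lon, lat) points in kilometres.

    Uses the haversine formula, numerically stable for nearby points where the
    spherical law of cosines loses precision.
    """
    lon1, lat1 = float(a[0]), float(a[1])
    lon2, lat2 = float(b[0]), float(b[1])
    _validate_coords(lon1, lat1)
    _validate_coords(lon2, lat2)
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * earth_radius_km * math.asin(min(1.0, math.sqrt(h)))


def _pairwise_km_to_kept(point: np.ndarray, kept: np.ndarray, radius: float) -> np.ndarray:
    """Vectorised haversine from one (lon, lat) point to an (m, 2) array."""
    lon1, lat1 = np.radians(point)
    lons, lats = np.radians(kept[:, 0]), np.radians(kept[:, 1])
    h = (
        np.sin((lats - lat1) / 2.0) ** 2
        + np.cos(lat1) * np.cos(lats) * np.sin((lons - lon1) / 2.0) ** 2
    )
    return 2.0 * radius * np.arcsin(np.minimum(1.0, np.sqrt(h)))


@dataclass
class ThinReport:
    """Which records the thinning scan dropped, and why."""

    threshold_km: float
    per_species: bool
    n_input: int
    n_kept: int
    dropped: list[dict]  # {"index", "species", "lon", "lat", "near_index", "distance_km"}

    def to_dict(self) -> dict:
        return {
            "threshold_km": self.threshold_km,
            "per_species": self.per_species,
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_dropped": len(self.dropped),
            "dropped": self.dropped,
        }


def thin(
    occ: OccurrenceSet,
    threshold_km: float = 1.0,
    per_species: bool = True,
    earth_radius_km: float = EARTH_RADIUS_KM,
) -> tuple[OccurrenceSet, ThinReport]:
    """Greedy first-wins spatial thinning.

    Scans records in input order; a record is kept unless it lies closer than
    ``threshold_km`` to an already-kept record of the same species (or of any
    species when ``per_species=False``). First-wins makes the result
    deterministic and order-stable, and the operation idempotent.
    """
    if threshold_km <= 0:
        raise ValueError("threshold_km must be positive")
    kept_records: list[OccurrenceRecord] = []
    kept_coords: dict[str, list[list[float]]] = {}
    kept_index: dict[str, list[int]] = {}
    dropped: list[dict] = []
    for i, rec in enumerate(occ.records):
        key = rec.species if per_species else "__all__"
        prev = kept_coords.get(key)
        if prev:
            d = _pairwise_km_to_kept(
                np.array([rec.lon, rec.lat]), np.asarray(prev), earth_radius_km
            )
            j = int(np.argmin(d))
            if d[j] < threshold_km:
                dropped.append(
                    {
                        "index": i,
                        "species": rec.species,
                        "lon": rec.lon,
                        "lat": rec.lat,
                        "near_index": kept_index[key][j],
                        "distance_km": float(d[j]),
                    }
                )
                continue
        kept_records.append(rec)
        kept_coords.setdefault(key, []).append([rec.lon, rec.lat])
        kept_index.setdefault(key, []).append(i)
    report = ThinReport(
        threshold_km=threshold_km,
        per_species=per_species,
        n_input=len(occ),
        n_kept=len(kept_records),
        dropped=dropped,
    )
    return OccurrenceSet(kept_records, crs=occ.crs), report
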
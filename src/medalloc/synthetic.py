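"""Synthetic hospital networks and packaged reference fixtures.

Real facility registries (CMS star ratings, VA medical-center tables) are
access-restricted or need downloads, so the generator emulates their
shape: one row per facility with rating, beds, death-rate and cost scores
on a 0-100-like normalized scale, a patient load, and coordinates in a
Virginia-like bounding box. Distributions are deliberately simple
(uniform; log-uniform for beds) and documented; a blob-count knob
produces geographically clustered networks for regional-routing studies.

Two small published reference tables are packaged as fixtures: the
six-case PSAF scenario grid and the 11-row hospital readiness table with
its printed decisions and fitness values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import HospitalRecord
from .mdp import PSAFCase
from .routing import GeoLocation

__all__ = [
    "NetworkSpec",
    "generate_network",
    "generate_locations",
    "table2_cases",
    "table3_rows",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Shape of a synthetic facility network.

    Ranges mirror the magnitudes of published normalized tables: beds
    16-69, death rate 10-45, cost 49-78 (0-100-like scores). The default
    bounding box covers Virginia and neighbors. ``n_blobs`` switches the
    geography from uniform to Gaussian clusters around random centers.
    """

    n_hospitals: int = 100
    seed: int = 0
    bbox: tuple[float, float, float, float] = (36.5, 39.5, -83.7, -75.2)
    beds_range: tuple[float, float] = (16.0, 69.0)
    death_rate_range: tuple[float, float] = (10.0, 45.0)
    cost_range: tuple[float, float] = (49.0, 78.0)
    patients_range: tuple[int, int] = (0, 5000)
    rating_distribution: tuple[float, ...] = (0.05, 0.15, 0.30, 0.30, 0.20)
    n_blobs: int | None = None

    def __post_init__(self) -> None:
        if self.n_hospitals < 0:
            raise ValueError("n_hospitals must be >= 0")
        for name in ("beds_range", "death_rate_range", "cost_range", "patients_range"):
            lo, hi = getattr(self, name)
            if not hi > lo:
                raise ValueError(f"{name} must be non-degenerate, got ({lo}, {hi})")
        lat_min, lat_max, lon_min, lon_max = self.bbox
        if not (lat_max > lat_min and lon_max > lon_min):
            raise ValueError("bbox must be non-degenerate")
        probs = np.asarray(self.rating_distribution, dtype=float)
        if probs.size != 5 or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("rating_distribution must be 5 probabilities summing to 1")
        if self.n_blobs is not None and self.n_blobs < 1:
            raise ValueError("n_blobs must be >= 1 when given")


def _coordinates(spec: NetworkSpec, rng: np.random.Generator):
    lat_min, lat_max, lon_min, lon_max = spec.bbox
    n = spec.n_hospitals
    if spec.n_blobs is None:
        lat = rng.uniform(lat_min, lat_max, size=n)
        lon = rng.uniform(lon_min, lon_max, size=n)
    else:
        centers_lat = rng.uniform(lat_min, lat_max, size=spec.n_blobs)
        centers_lon = rng.uniform(lon_min, lon_max, size=spec.n_blobs)
        which = rng.integers(spec.n_blobs, size=n)
        sd_lat = 0.03 * (lat_max - lat_min)
        sd_lon = 0.03 * (lon_max - lon_min)
        lat = rng.normal(centers_lat[which], sd_lat)
        lon = rng.normal(centers_lon[which], sd_lon)
    return np.clip(lat, lat_min, lat_max), np.clip(lon, lon_min, lon_max)


def generate_network(spec: NetworkSpec) -> list[HospitalRecord]:
    """Draw a seeded, reproducible network of facility records."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_hospitals
    lat, lon = _coordinates(spec, rng)
    beds = np.exp(
        rng.uniform(np.log(spec.beds_range[0]), np.log(spec.beds_range[1]), size=n)
    )
    death = rng.uniform(*spec.death_rate_range, size=n)
    cost = rng.uniform(*spec.cost_range, size=n)
    patients = rng.integers(spec.patients_range[0], spec.patients_range[1] + 1, size=n)
    ratings = rng.choice(
        np.arange(1, 6), size=n, p=np.asarray(spec.rating_distribution, dtype=float)
    )
    return [
        HospitalRecord(
            id=f"H{i:04d}",
            name=f"Synthetic Hospital {i:04d}",
            latitude=float(lat[i]),
            longitude=float(lon[i]),
            rating=int(ratings[i]),
            beds=float(beds[i]),
            death_rate=float(death[i]),
            cost=float(cost[i]),
            patients=int(patients[i]),
        )
        for i in range(n)
    ]


def generate_locations(
    spec: NetworkSpec, avg_recovery_days: float = 10.0
) -> list[GeoLocation]:
    """Network records converted to routable locations.

    The recovery cost is the per-day cost score times an average
    recovery duration in days (default 10, a mid-range inpatient stay).
    """
    return [
        GeoLocation(
            id=r.id,
            latitude=r.latitude,
            longitude=r.longitude,
            patients=float(r.patients),
            recovery_cost=avg_recovery_days * r.cost,
            rating=float(r.rating),
        )
        for r in generate_network(spec)
    ]


def table2_cases() -> list[PSAFCase]:
    """The six published PSAF scenarios (hospitalization ratio, severity,
    transmissibility) spanning mild to outlier pandemics."""
    grid = [
        (0.1, 2, 2),
        (0.1, 7, 5),
        (0.5, 2, 2),
        (0.5, 7, 5),
        (0.9, 2, 2),
        (0.9, 7, 5),
    ]
    return [
        PSAFCase(
            hospitalization_ratio=r, clinical_severity=s, transmissibility=t
        )
        for r, s, t in grid
    ]


#: Published 11-row readiness ranking: (name, rating, beds, death_rate,
#: cost, decision_1, ff1, decision_2, ff2) with inputs on the normalized
#: 0-100-like scale.
_TABLE3 = [
    ("Centra", 4, 39.1, 10.3, 63.6, 1, 29.2, 1, 7.3),
    ("Inova Alexandria Hospital", 5, 42.4, 25.5, 64.5, 1, 16.9, 1, 3.4),
    ("Bon Secours St Mary's Hospital", 3, 68.5, 26.1, 77.6, 1, 15.7, 1, 5.2),
    ("Mary Washington Hospital", 3, 29.3, 13.3, 70.2, 1, 13.2, 1, 4.4),
    ("Sentara Princess Anne Hospital", 5, 16.3, 15.2, 66.5, 1, 11.4, 1, 2.3),
    ("Inova Fair Oaks Hospital", 5, 33.7, 30.9, 69.2, 1, 11.3, 1, 2.3),
    ("Sentara Norfolk General Hospital", 3, 64.1, 34.5, 54.8, 0, 11.0, 1, 3.7),
    ("Winchester Medical Center", 4, 51.1, 43.6, 50.3, 0, 9.4, 0, 2.4),
    ("Virginia Hospital Center", 5, 33.7, 38.8, 68.8, 1, 9.1, 1, 1.8),
    ("Reston Hospital Center", 4, 16.3, 17.0, 66.7, 1, 8.2, 1, 2.1),
    ("Inova Loudoun Hospital", 5, 23.9, 30.9, 49.7, 1, 8.2, 1, 1.6),
]


def table3_rows() -> list[dict]:
    """The published readiness table as dict rows, for validation suites."""
    keys = (
        "name",
        "rating",
        "beds",
        "death_rate",
        "cost",
        "decision_1",
        "ff1",
        "decision_2",
        "ff2",
    )
    return [dict(zip(keys, row)) for row in _TABLE3]
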
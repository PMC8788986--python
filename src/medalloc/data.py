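"""Hospital records, min-max normalization, and delimited-text I/O.

Every method in the toolkit consumes the same tabular shape: one row per
facility with a star rating, bed count, death-rate score, cost score,
patient count and coordinates. Columns are matched against a documented
alias map so exports from different registries (e.g. "Facility name",
"No. of beds") load without renaming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HospitalRecord",
    "NormalizationSpec",
    "DegenerateRangeError",
    "COLUMN_ALIASES",
    "linear_scale",
    "inverse_linear_scale",
    "normalize_columns",
    "read_hospital_table",
    "write_hospital_table",
    "records_to_dataframe",
]


class DegenerateRangeError(ValueError):
    """Raised when a scaling range collapses (max == min)."""


@dataclass(frozen=True)
class HospitalRecord:
    """One facility: the unit of allocation and routing decisions.

    ``beds`` may be fractional: allocation runs report bed counts as
    decimals for accuracy, to be rounded up in practice. ``death_rate``
    and ``cost`` are normalized scores, not raw dollar amounts.
    """

    id: str
    name: str
    latitude: float
    longitude: float
    rating: int
    beds: float
    death_rate: float
    cost: float
    patients: int = 0

    def __post_init__(self) -> None:
        if self.rating not in (1, 2, 3, 4, 5):
            raise ValueError(f"rating must be in 1..5, got {self.rating!r}")
        if not self.beds >= 0:
            raise ValueError(f"beds must be >= 0, got {self.beds!r}")
        if not self.death_rate >= 0:
            raise ValueError(f"death_rate must be >= 0, got {self.death_rate!r}")
        if not self.cost > 0:
            raise ValueError(f"cost must be > 0, got {self.cost!r}")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude!r}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude!r}")
        if self.patients < 0:
            raise ValueError(f"patients must be >= 0, got {self.patients!r}")


@dataclass(frozen=True)
class NormalizationSpec:
    """Anchors and target range for affine min-max scaling."""

    mn: float
    mx: float
    target_lo: float = 0.0
    target_hi: float = 1.0

    def __post_init__(self) -> None:
        if not self.mx > self.mn:
            raise DegenerateRangeError(
                f"degenerate range: mx ({self.mx}) must exceed mn ({self.mn})"
            )
        if not self.target_hi > self.target_lo:
            raise ValueError("target_hi must exceed target_lo")


def linear_scale(x, spec: NormalizationSpec):
    """Affine rescale of ``x`` from [mn, mx] to [target_lo, target_hi].

    Accepts scalars or array-likes. Values outside [mn, mx] extrapolate
    linearly (there is no clamp in the underlying formula); such values
    are flagged in the log rather than rejected, since out-of-anchor
    observations are legitimate when anchors come from a reference table.
    """
    arr = np.asarray(x, dtype=float)
    out_of_range = (arr < spec.mn) | (arr > spec.mx)
    if np.any(out_of_range[np.isfinite(arr)] if arr.ndim else out_of_range):
        logger.warning(
            "linear_scale: %d value(s) outside [%g, %g]; extrapolating linearly",
            int(np.count_nonzero(out_of_range)),
            spec.mn,
            spec.mx,
        )
    scaled = spec.target_lo + (arr - spec.mn) / (spec.mx - spec.mn) * (
        spec.target_hi - spec.target_lo
    )
    return float(scaled) if np.ndim(x) == 0 else scaled


def inverse_linear_scale(y, spec: NormalizationSpec):
    """Exact inverse of :func:`linear_scale` (round-trips to ~1e-12)."""
    arr = np.asarray(y, dtype=float)
    x = spec.mn + (arr - spec.target_lo) / (spec.target_hi - spec.target_lo) * (
        spec.mx - spec.mn
    )
    return float(x) if np.ndim(y) == 0 else x


def normalize_columns(
    table: pd.DataFrame,
    columns,
    target: tuple[float, float] = (0.0, 1.0),
) -> pd.DataFrame:
    """Min-max rescale the named columns of a table to ``target``.

    Anchors (mn, mx) are taken per column with missing values excluded
    (na.rm semantics); missing entries propagate unchanged through the
    scaling. Returns a new frame; the input is not modified.
    """
    out = table.copy()
    lo, hi = target
    for col in columns:
        if col not in out.columns:
            raise KeyError(f"no such column: {col!r}")
        values = pd.to_numeric(out[col], errors="raise")
        mn = float(values.min(skipna=True))
        mx = float(values.max(skipna=True))
        if not mx > mn:
            raise DegenerateRangeError(
                f"column {col!r} is constant (min == max == {mn}); cannot rescale"
            )
        spec = NormalizationSpec(mn=mn, mx=mx, target_lo=lo, target_hi=hi)
        out[col] = linear_scale(values.to_numpy(dtype=float), spec)
    return out


# Case-insensitive header aliases accepted by read_hospital_table.
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "id": ("id", "facility id", "provider id", "hospital id"),
    "name": ("name", "facility name", "facility", "hospital name"),
    "latitude": ("latitude", "lat"),
    "longitude": ("longitude", "lon", "long", "lng"),
    "rating": ("rating", "star rating", "hospital rating", "overall rating"),
    "beds": ("beds", "no. of beds", "number of beds", "bed count"),
    "death_rate": ("death_rate", "death rate", "mortality rate"),
    "cost": ("cost", "cost score"),
    "patients": ("patients", "patient count", "covid patients", "n_patients"),
}

_REQUIRED = ("name", "rating", "beds", "death_rate", "cost")


def _canonical_columns(df: pd.DataFrame) -> dict[str, str]:
    lookup = {}
    for canonical, aliases in COLUMN_ALIASES.items():
        for col in df.columns:
            if str(col).strip().lower() in aliases:
                lookup[canonical] = col
                break
    return lookup


def read_hospital_table(path, sep=None) -> list[HospitalRecord]:
    """Read a delimited hospital table (comma default, tab accepted).

    Headers are matched case-insensitively against :data:`COLUMN_ALIASES`.
    Rows violating record invariants are rejected collectively with their
    1-based data row numbers.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    if df.empty and len(df.columns) == 0:
        raise ValueError(f"empty file: {path}")
    lookup = _canonical_columns(df)
    missing = [c for c in _REQUIRED if c not in lookup]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")

    records: list[HospitalRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowmap = dict(zip(df.columns, row))

        def get(canonical, default=None):
            col = lookup.get(canonical)
            if col is None:
                return default
            val = rowmap[col]
            return default if pd.isna(val) else val

        try:
            records.append(
                HospitalRecord(
                    id=str(get("id", f"row{i}")),
                    name=str(get("name")),
                    latitude=float(get("latitude", 0.0)),
                    longitude=float(get("longitude", 0.0)),
                    rating=int(get("rating")),
                    beds=float(get("beds")),
                    death_rate=float(get("death_rate")),
                    cost=float(get("cost")),
                    patients=int(get("patients", 0)),
                )
            )
        except (TypeError, ValueError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValueError("invalid rows:\n" + "\n".join(errors))
    return records


def records_to_dataframe(records) -> pd.DataFrame:
    """Stable-column-order frame view of a record list."""
    cols = [
        "id",
        "name",
        "latitude",
        "longitude",
        "rating",
        "beds",
        "death_rate",
        "cost",
        "patients",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)


def write_hospital_table(records, path, sep=",") -> None:
    """Write records back out in the same dialect with 2-dp numerics."""
    df = records_to_dataframe(records)
    df.to_csv(path, sep=sep, index=False, float_format="%.2f")
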
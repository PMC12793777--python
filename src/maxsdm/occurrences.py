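"""Loading, validation, cleaning, and spatial thinning of presence records.

Cleaning removes the standard classes of unusable records (out-of-range
coordinates, the (0, 0) artefact, exact duplicates after rounding to six
decimal places, points off-grid or on nodata cells) and logs one reason code
per dropped record.  Thinning enforces at most one record per grid cell —
the usual guard against spatial pseudo-replication in presence-only SDMs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import EnvStack, GridSpec

logger = logging.getLogger(__name__)

__all__ = ["Occurrence", "OccurrenceSet", "load_occurrences", "clean_coordinates",
           "thin_to_grid", "extract_values"]

_ROUND = 6  # decimal places defining coordinate duplicates (~0.1 m)


@dataclass(frozen=True)
class Occurrence:
    lon: float
    lat: float
    source_id: str | None = None


@dataclass
class OccurrenceSet:
    """Ordered presence records for one species."""

    species: str
    records: list[Occurrence] = field(default_factory=list)
    drop_log: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def lons(self) -> np.ndarray:
        return np.array([r.lon for r in self.records], dtype=float)

    @property
    def lats(self) -> np.ndarray:
        return np.array([r.lat for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "longitude": self.lons,
                "latitude": self.lats,
                "source_id": [r.source_id for r in self.records],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def drop_log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.drop_log, columns=["row", "reason"])


def load_occurrences(path, species: str | None = None) -> OccurrenceSet:
    """Read a delimited text file with columns species, longitude, latitude.

    Rows that fail numeric parsing are skipped and logged with their line
    number; coordinate-validity checks are deferred to
    :func:`clean_coordinates`.  An optional ``source_id`` column is carried
    through; otherwise the 1-based data row number serves as provenance.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    aliases = {"lon": "longitude", "lng": "longitude", "x": "longitude",
               "lat": "latitude", "y": "latitude"}
    df = df.rename(columns=aliases)
    required = {"species", "longitude", "latitude"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")

    if species is not None:
        df = df[df["species"] == species]
    elif len(df) and df["species"].nunique() > 1:
        raise ValueError(
            f"{path}: multiple species present; pass species= to select one"
        )
    name = species if species is not None else (
        str(df["species"].iloc[0]) if len(df) else ""
    )

    occ = OccurrenceSet(species=name)
    n_bad = 0
    for idx, row in df.iterrows():
        sid = str(row["source_id"]) if "source_id" in df.columns and pd.notna(
            row.get("source_id")
        ) else f"row{idx + 1}"
        try:
            lon = float(row["longitude"])
            lat = float(row["latitude"])
        except (TypeError, ValueError):
            occ.drop_log.append((sid, "unparseable"))
            n_bad += 1
            continue
        if np.isnan(lon) or np.isnan(lat):
            occ.drop_log.append((sid, "unparseable"))
            n_bad += 1
            continue
        occ.records.append(Occurrence(lon, lat, sid))
    if n_bad:
        logger.warning("%s: skipped %d malformed rows", path, n_bad)
    if not occ.records:
        warnings.warn(f"{path}: no usable occurrence records", stacklevel=2)
    return occ


def clean_coordinates(occ: OccurrenceSet, stack: EnvStack) -> OccurrenceSet:
    """Drop invalid records; the stack's joint nodata mask defines the region.

    Removal order per record: coordinate range, the (0, 0) point, exact
    duplicates (six-decimal rounding), off-grid, nodata cell.  Survivor
    order is preserved; every drop is logged with a reason code.
    """
    out = OccurrenceSet(species=occ.species, drop_log=list(occ.drop_log))
    mask = stack.mask
    seen: set[tuple[float, float]] = set()
    for rec in occ.records:
        sid = rec.source_id or ""
        if not (-180.0 <= rec.lon <= 180.0 and -90.0 <= rec.lat <= 90.0):
            out.drop_log.append((sid, "coordinate_out_of_range"))
            continue
        if rec.lon == 0.0 and rec.lat == 0.0:
            out.drop_log.append((sid, "zero_zero"))
            continue
        key = (round(rec.lon, _ROUND), round(rec.lat, _ROUND))
        if key in seen:
            out.drop_log.append((sid, "duplicate"))
            continue
        cell = stack.grid.locate(rec.lon, rec.lat)
        if cell is None:
            out.drop_log.append((sid, "off_grid"))
            continue
        if not mask[cell]:
            out.drop_log.append((sid, "nodata_cell"))
            continue
        seen.add(key)
        out.records.append(rec)
    n_drop = len(out.drop_log) - len(occ.drop_log)
    if n_drop:
        logger.info("%s: cleaning dropped %d of %d records",
                    occ.species, n_drop, len(occ))
    if not out.records:
        warnings.warn(f"{occ.species}: no records survive cleaning", stacklevel=2)
    return out


def thin_to_grid(
    occ: OccurrenceSet,
    grid: GridSpec,
    keep: str = "first",
    seed: int | None = None,
) -> OccurrenceSet:
    """Retain at most one record per grid cell (idempotent).

    ``keep='first'`` (default) keeps the first record encountered in each
    cell, which makes thinning deterministic; ``keep='random'`` draws the
    survivor per cell with the given seed.
    """
    if keep not in ("first", "random"):
        raise ValueError("keep must be 'first' or 'random'")
    by_cell: dict[tuple[int, int], list[Occurrence]] = {}
    order: list[tuple[int, int]] = []
    for rec in occ.records:
        cell = grid.locate(rec.lon, rec.lat)
        if cell is None:
            raise ValueError(f"record {rec.source_id!r} falls off-grid; clean first")
        if cell not in by_cell:
            by_cell[cell] = []
            order.append(cell)
        by_cell[cell].append(rec)

    rng = np.random.default_rng(seed)
    out = OccurrenceSet(species=occ.species, drop_log=list(occ.drop_log))
    for cell in order:
        group = by_cell[cell]
        pick = group[0] if keep == "first" else group[int(rng.integers(len(group)))]
        out.records.append(pick)
        for rec in group:
            if rec is not pick:
                out.drop_log.append((rec.source_id or "", "thinned"))
    return out


def extract_values(occ: OccurrenceSet, stack: EnvStack) -> pd.DataFrame:
    """Predictor values at each record's containing cell, one row per record."""
    rows, cols = [], []
    for rec in occ.records:
        cell = stack.grid.locate(rec.lon, rec.lat)
        if cell is None:
            raise ValueError(f"record {rec.source_id!r} falls outside the grid")
        rows.append(cell[0])
        cols.append(cell[1])
    if not rows:
        return pd.DataFrame(columns=stack.names)
    table = stack.table(np.array(rows), np.array(cols))
    return pd.DataFrame(table, columns=stack.names)
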
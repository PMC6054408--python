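"""Independent-detection filtering, detection matrices and guild summaries.

Camera-trap records of the same species at the same station are thinned to
"independent" detections with a greedy minimum-gap rule (default 1 hour): a
record is kept iff at least the minimum gap has elapsed since the previously
*kept* record of that (station, species) pair.  Counts of independent
detections per station feed every downstream model; per-area detection
frequency is expressed per 100 trap-nights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_DETECTION_COLS = ("station_id", "species", "timestamp")
REQUIRED_STATION_COLS = ("station_id", "x", "y", "effort")


def _parse_timestamps(records: pd.DataFrame) -> pd.Series:
    ts = pd.to_datetime(records["timestamp"], errors="coerce", format="mixed")
    if ts.isna().any():
        bad = records.index[ts.isna()][0]
        raise ValueError(
            f"unparseable timestamp {records.loc[bad, 'timestamp']!r} at row {bad}"
        )
    return ts


def enforce_independence(records: pd.DataFrame, min_gap: pd.Timedelta = pd.Timedelta(hours=1)) -> pd.DataFrame:
    """Greedy per-(station, species) thinning to one detection per ``min_gap``.

    Records are scanned in time order within each (station, species) group;
    a record is kept iff >= min_gap has elapsed since the previously kept
    record.  Ties at exactly min_gap are kept.  Different stations or species
    never interact.  The operation is idempotent.
    """
    if records.empty:
        return records.copy()
    df = records.copy()
    df["_ts"] = _parse_timestamps(df)
    df["species"] = df["species"].astype(str).str.strip().str.lower()
    keep = np.zeros(len(df), dtype=bool)
    order = df.sort_values("_ts", kind="stable")
    for _, grp in order.groupby(["station_id", "species"], sort=False):
        last_kept = None
        for idx, ts in zip(grp.index, grp["_ts"]):
            if last_kept is None or ts - last_kept >= min_gap:
                keep[df.index.get_loc(idx)] = True
                last_kept = ts
    out = df.loc[keep].drop(columns=["_ts"])
    return out


def build_matrix(records: pd.DataFrame, stations: pd.DataFrame,
                 species_list: list[str] | None = None) -> pd.DataFrame:
    """Station x species matrix of independent detection counts.

    ``records`` must already be independence-filtered.  Column totals equal
    the number of filtered records per species.  Rows cover every station in
    the station table (zero-filled), so absences are explicit.
    """
    station_ids = pd.Index(stations["station_id"].astype(str), name="station_id")
    if not station_ids.is_unique:
        raise ValueError("duplicate station_id in station table")
    if records.empty:
        species = [s.lower() for s in (species_list or [])]
        return pd.DataFrame(0, index=station_ids, columns=species, dtype=int)
    rec = records.copy()
    rec["station_id"] = rec["station_id"].astype(str)
    rec["species"] = rec["species"].astype(str).str.strip().str.lower()
    unknown = set(rec["station_id"]) - set(station_ids)
    if unknown:
        raise ValueError(f"detections at unknown stations: {sorted(unknown)}")
    mat = (
        rec.groupby(["station_id", "species"]).size().unstack(fill_value=0)
        .reindex(index=station_ids, fill_value=0)
    )
    if species_list is not None:
        cols = [s.lower() for s in species_list]
        mat = mat.reindex(columns=cols, fill_value=0)
    return mat.astype(int)


def aggregate_groups(matrix: pd.DataFrame, groups: dict[str, list[str]]) -> pd.DataFrame:
    """Add species-group columns (e.g. "all mousedeer") as sums of member columns."""
    out = matrix.copy()
    for group, members in groups.items():
        present = [m.lower() for m in members if m.lower() in matrix.columns]
        if present:
            out[group.lower()] = matrix[present].sum(axis=1)
    return out


def detection_frequency(count: int, effort: float) -> float:
    """Independent detections per 100 trap-nights, to 3 decimals."""
    if effort <= 0:
        raise ValueError("effort must be positive")
    return round(100.0 * count / effort, 3)


def filter_min_detections(matrix: pd.DataFrame, threshold: int = 20) -> list[str]:
    """Species whose total independent detections reach the threshold (default >= 20)."""
    totals = matrix.sum(axis=0)
    return [sp for sp in matrix.columns if totals[sp] >= threshold]


@dataclass
class BodyMassRatios:
    """Pairwise heavier/lighter body-mass ratio table with similar-size flags."""

    ratios: pd.DataFrame      # ratio rounded to 1 decimal, always >= 1
    similar: pd.DataFrame     # True iff ratio < 2 (very similar body size)


def body_mass_ratio_matrix(means: dict[str, float]) -> BodyMassRatios:
    """Heavier/lighter mean-mass ratio for every species pair.

    Ratios are symmetric under argument order by construction (>= 1) and a
    pair is flagged similar-sized when the ratio is < 2.
    """
    for sp, m in means.items():
        if m <= 0:
            raise ValueError(f"non-positive mass for {sp!r}")
    names = list(means)
    n = len(names)
    rat = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            hi, lo = max(means[names[i]], means[names[j]]), min(means[names[i]], means[names[j]])
            rat[i, j] = round(hi / lo, 1)
    ratios = pd.DataFrame(rat, index=names, columns=names)
    return BodyMassRatios(ratios=ratios, similar=ratios < 2.0)
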
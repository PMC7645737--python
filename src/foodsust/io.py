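"""Readers and writers for the interchange formats.

Canonical interchange is CSV (UTF-8, comma-separated, ``NA`` for missing):
score tables have one row per indicator and one column per food system.  An
XLSX importer extracts the same matrix from a supplementary-style workbook
whose sheets carry per-dimension rating blocks; it is written defensively
because such workbooks vary in layout.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .aggregation import ActivityProfile, SustainabilityProfile, assess_all
from .framework import IndicatorRegistry, ScoreMatrix, validate_scores

__all__ = [
    "read_score_table",
    "write_score_table",
    "read_landcover_table",
    "import_supplementary_xlsx",
    "profiles_to_radar",
    "activity_profiles_to_stacked",
    "write_manifest",
]

NA_TOKEN = "NA"


class ScoreTableError(ValueError):
    """Raised when a score table cell cannot be interpreted."""


def _coerce_cell(value, row_label: str, column: str) -> float:
    if pd.isna(value) or (isinstance(value, str) and value.strip() in ("", NA_TOKEN, "N/A", "na")):
        return np.nan
    try:
        number = float(value)
    except (TypeError, ValueError) as exc:
        raise ScoreTableError(
            f"unparseable score {value!r} at (row {row_label!r}, column {column!r})"
        ) from exc
    if number != int(number) or not 0 <= number <= 4:
        # half-points arise only from aggregation, never from raw ratings
        raise ScoreTableError(
            f"score {value!r} at (row {row_label!r}, column {column!r}) is not an integer in 0-4"
        )
    return number


def read_score_table(
    path: str | Path, registry: IndicatorRegistry | None = None
) -> ScoreMatrix:
    """Read an indicator x food-system score CSV into a :class:`ScoreMatrix`.

    First column holds indicator ids; remaining columns are food systems.
    Cells must be integers 0-4 or ``NA``.  When a registry is given the
    matrix is validated against it and errors raise.
    """
    frame = pd.read_csv(path, index_col=0, dtype=object)
    coerced = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=float)
    for column in frame.columns:
        for row_label, value in frame[column].items():
            coerced.at[row_label, column] = _coerce_cell(value, str(row_label), str(column))
    matrix = ScoreMatrix(coerced)
    if registry is not None:
        report = validate_scores(matrix, registry)
        if not report.ok:
            details = "; ".join(f"{i.location}: {i.message}" for i in report.errors)
            raise ScoreTableError(f"score table failed validation: {details}")
    return matrix


def write_score_table(matrix: ScoreMatrix, path: str | Path) -> None:
    """Write a score matrix in the canonical CSV dialect (missing as ``NA``)."""
    out = matrix.scores.copy()
    # keep integer appearance for valid ordinal scores
    formatted = out.map(lambda v: NA_TOKEN if pd.isna(v) else str(int(v)))
    formatted.index.name = "indicator"
    formatted.to_csv(path)


def read_landcover_table(path: str | Path):
    """Read a land-cover CSV (class, area_share, n_services, strength).

    Percent-scale areas (summing to ~100) are detected and divided by 100.
    """
    from .metrics import LandCoverClass

    frame = pd.read_csv(path)
    required = {"class", "area_share", "n_services", "strength"}
    missing = required - set(frame.columns)
    if missing:
        raise ScoreTableError(f"land-cover table missing columns: {sorted(missing)}")
    shares = frame["area_share"].astype(float)
    if shares.sum() > 1.5:  # percent-scale input
        shares = shares / 100.0
    return [
        LandCoverClass(str(row["class"]), float(share), int(row.n_services), float(row.strength))
        for (_, row), share in zip(frame.iterrows(), shares)
    ]


def import_supplementary_xlsx(
    path: str | Path, registry: IndicatorRegistry | None = None
) -> ScoreMatrix:
    """Extract a score matrix from a supplementary-style workbook.

    The importer scans every sheet for rating blocks: a header row whose
    cells name food systems (tokens like ``B1``..``K3``), followed by rows
    whose first non-empty cell matches a registry indicator id or label.
    Blocks found across sheets are merged into one matrix.  Layout quirks
    (extra header rows, rating-criteria columns, blank separators) are
    tolerated; anything unrecognised is ignored rather than fatal.
    """
    import openpyxl

    workbook = openpyxl.load_workbook(Path(path), data_only=True, read_only=True)
    label_to_id: dict[str, str] = {}
    if registry is not None:
        for ind in registry:
            label_to_id[ind.id.lower()] = ind.id
            label_to_id[ind.label.lower()] = ind.id

    collected: dict[str, dict[str, float]] = {}
    system_names: list[str] = []

    def looks_like_system(cell) -> bool:
        return isinstance(cell, str) and 2 <= len(cell.strip()) <= 12 and any(
            ch.isdigit() for ch in cell
        )

    for sheet in workbook.worksheets:
        rows = list(sheet.iter_rows(values_only=True))
        header_map: dict[int, str] | None = None
        for row in rows:
            if row is None or all(v is None for v in row):
                continue
            cells = list(row)
            str_cells = [c for c in cells if isinstance(c, str)]
            # candidate header: several short system-like tokens
            if sum(looks_like_system(c) for c in str_cells) >= 2:
                header_map = {
                    idx: str(c).strip()
                    for idx, c in enumerate(cells)
                    if looks_like_system(c)
                }
                for name in header_map.values():
                    if name not in system_names:
                        system_names.append(name)
                continue
            if header_map is None:
                continue
            first = next((c for c in cells if c is not None), None)
            if not isinstance(first, str):
                continue
            key = first.strip().lower()
            indicator_id = label_to_id.get(key, key if registry is None else None)
            if indicator_id is None:
                continue
            row_scores = collected.setdefault(indicator_id, {})
            for idx, system in header_map.items():
                if idx < len(cells) and cells[idx] is not None:
                    try:
                        row_scores[system] = _coerce_cell(cells[idx], indicator_id, system)
                    except ScoreTableError:
                        continue
    workbook.close()
    if not collected:
        raise ScoreTableError(f"no rating blocks recognised in workbook {path}")
    frame = pd.DataFrame.from_dict(collected, orient="index").reindex(columns=system_names)
    if registry is not None:
        order = [i for i in registry.ids if i in frame.index]
        frame = frame.loc[order]
    return ScoreMatrix(frame)


def profiles_to_radar(profiles: Iterable[SustainabilityProfile]) -> pd.DataFrame:
    """Tidy (system, dimension, value) table for radar-chart plotting."""
    rows = []
    for p in profiles:
        for dim, value in p.dimension_medians.items():
            rows.append({"system": p.system, "dimension": dim.value, "value": value})
    return pd.DataFrame(rows)


def activity_profiles_to_stacked(profiles: Iterable[ActivityProfile]) -> pd.DataFrame:
    """Tidy (system, activity, median) table for stacked-bar plotting."""
    rows = []
    for p in profiles:
        for activity, value in p.activity_medians.items():
            rows.append({"system": p.system, "activity": activity.value, "median": value})
    return pd.DataFrame(rows)


def write_manifest(path: str | Path, **entries) -> None:
    """Write a machine-readable run manifest (inputs, seed, parameters)."""
    import foodsust

    manifest = {"package": "foodsust", "version": foodsust.__version__}
    manifest.update(entries)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
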
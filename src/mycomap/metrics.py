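"""Colonization parameters computed from eyepiece grids.

Seven parameters are carried per microscopic field:

frequency (F%)
    Gridline occupancy: the mean of the horizontal share (rows crossing at
    least one fungal structure) and the vertical share (columns doing so),
    i.e. ``100 * (occupied rows + occupied columns) / 20`` on a 10x10 grid.
    The horizontal and vertical indices are computed separately and combined
    by simple average.
intensity (I%)
    Share of grid cells occupied by fungal structures.
arbuscules / vesicles (%)
    Share of grid cells coded A, respectively V.
degree (%)
    Composite index F * I / 100, computed per field and then averaged.
non_mycorrhizal (%)
    Complement 100 - I, exactly.
mnm_report
    Per-field ratio of colonized to uncolonized area, I / (100 - I);
    undefined at I = 100 (flagged as NaN, excluded from means).

``frequency >= intensity`` holds for every grid: with r occupied rows, c
occupied columns and k colonized cells, k <= r*c <= ((r+c)/2)^2 and
k <= 100 give k <= 10*sqrt(k) <= 5*(r+c).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    GRID_SHAPE,
    LEGAL_COMBINATIONS,
    PARAMETERS,
    FieldGrid,
    FragmentMap,
)

__all__ = [
    "FieldMetrics",
    "field_frequency",
    "field_intensity",
    "field_structure_share",
    "field_metrics",
    "fragment_metrics",
    "observations_from_maps",
    "variant_summary",
]


@dataclass(frozen=True)
class FieldMetrics:
    """The seven colonization parameters for one scoring unit.

    ``mnm_report`` is NaN when the unit is fully colonized (intensity 100),
    in which case ``report_undefined`` counts the affected fields (1 for a
    single field; for a fragment, how many of its fields were saturated).
    """

    frequency: float
    intensity: float
    arbuscules: float
    vesicles: float
    degree: float
    non_mycorrhizal: float
    mnm_report: float
    report_undefined: int = 0

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETERS}


def _cells(grid) -> np.ndarray:
    cells = grid.cells if isinstance(grid, FieldGrid) else np.asarray(grid)
    if cells.shape != GRID_SHAPE:
        raise ValueError(
            f"expected a {GRID_SHAPE[0]}x{GRID_SHAPE[1]} grid, got {cells.shape}"
        )
    return cells


def field_frequency(grid) -> float:
    """Gridline-occupancy frequency (%) of one field."""
    colonized = _cells(grid) != "N"
    rows = int(colonized.any(axis=1).sum())
    cols = int(colonized.any(axis=0).sum())
    return 100.0 * (rows + cols) / (GRID_SHAPE[0] + GRID_SHAPE[1])


def field_intensity(grid) -> float:
    """Share (%) of cells holding any fungal structure."""
    colonized = _cells(grid) != "N"
    return 100.0 * colonized.sum() / colonized.size


def field_structure_share(grid, structure: str) -> float:
    """Share (%) of cells holding a given structure (A or V)."""
    if structure not in ("A", "V"):
        raise ValueError(
            f"structure must be 'A' (arbuscule) or 'V' (vesicle), got {structure!r}"
        )
    cells = _cells(grid)
    return 100.0 * (cells == structure).sum() / cells.size


def field_metrics(grid) -> FieldMetrics:
    """All seven parameters of one microscopic field."""
    freq = field_frequency(grid)
    inten = field_intensity(grid)
    non_myc = 100.0 - inten
    if non_myc > 0:
        report, undefined = inten / non_myc, 0
    else:
        report, undefined = float("nan"), 1
    return FieldMetrics(
        frequency=freq,
        intensity=inten,
        arbuscules=field_structure_share(grid, "A"),
        vesicles=field_structure_share(grid, "V"),
        degree=freq * inten / 100.0,
        non_mycorrhizal=non_myc,
        mnm_report=report,
        report_undefined=undefined,
    )


def fragment_metrics(fmap: FragmentMap) -> FieldMetrics:
    """Arithmetic mean of each parameter over a fragment's fields.

    The M/nM report is averaged over fields where it is defined; saturated
    fields (intensity 100) are excluded from that mean and counted in
    ``report_undefined``.  If every field is saturated the report is NaN.
    """
    per_field = [field_metrics(g) for g in fmap.fields]
    reports = [m.mnm_report for m in per_field if m.report_undefined == 0]
    return FieldMetrics(
        frequency=float(np.mean([m.frequency for m in per_field])),
        intensity=float(np.mean([m.intensity for m in per_field])),
        arbuscules=float(np.mean([m.arbuscules for m in per_field])),
        vesicles=float(np.mean([m.vesicles for m in per_field])),
        degree=float(np.mean([m.degree for m in per_field])),
        non_mycorrhizal=float(np.mean([m.non_mycorrhizal for m in per_field])),
        mnm_report=float(np.mean(reports)) if reports else float("nan"),
        report_undefined=sum(m.report_undefined for m in per_field),
    )


#: Column layout of the long-format observation table.
OBSERVATION_COLUMNS = [
    "treatment",
    "phenophase",
    "plant_id",
    "fragment_id",
    "field_index",
    *PARAMETERS,
]


def observations_from_maps(maps) -> pd.DataFrame:
    """Score every field of every map into a long-format observation table.

    One row per microscopic field, keyed by (treatment, phenophase,
    plant_id, fragment_id, field_index).
    """
    records = []
    for fmap in maps:
        for grid in fmap.fields:
            m = field_metrics(grid)
            records.append(
                (
                    fmap.treatment,
                    fmap.phenophase,
                    fmap.plant_id,
                    fmap.fragment_id,
                    grid.field_index,
                    *(getattr(m, name) for name in PARAMETERS),
                )
            )
    table = pd.DataFrame.from_records(records, columns=OBSERVATION_COLUMNS)
    key = OBSERVATION_COLUMNS[:5]
    if table.duplicated(key).any():
        dup = table.loc[table.duplicated(key), key].iloc[0]
        raise ValueError(f"duplicate observation key: {tuple(dup)}")
    return table


def variant_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of each parameter per treatment-phenophase.

    Standard error is the sample standard deviation (ddof=1) over sqrt(n).
    Rows are ordered as reported: the control point first, then A1-B2..B5,
    then A2-B2..B5 (combinations absent from the table are skipped).  The
    M/nM report is averaged over observations where it is defined.

    Returns a frame indexed by ``variant`` (e.g. ``"A0-B1"``) with columns
    ``<param>_mean``, ``<param>_se`` for the seven parameters, plus ``n``.
    """
    rows = []
    order = [c for c in LEGAL_COMBINATIONS]
    seen = set(zip(table["treatment"], table["phenophase"]))
    order += sorted(seen - set(order))  # tolerate non-study combinations
    for (t, p) in order:
        sub = table[(table["treatment"] == t) & (table["phenophase"] == p)]
        if sub.empty:
            continue
        if len(sub) < 2:
            raise ValueError(
                f"combination {t}-{p} has {len(sub)} observation(s); "
                "need at least 2 for a standard error"
            )
        row = {"variant": f"{t}-{p}", "n": len(sub)}
        for name in PARAMETERS:
            vals = sub[name].dropna()
            row[f"{name}_mean"] = vals.mean()
            row[f"{name}_se"] = vals.std(ddof=1) / np.sqrt(len(vals))
        rows.append(row)
    return pd.DataFrame(rows).set_index("variant")
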
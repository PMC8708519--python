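"""File formats and rendering for colonization maps and observation tables.

Map file dialect (one fragment per file)::

    # treatment=A1
    # phenophase=B2
    # plant=3
    # fragment=2
    # fields_per_fragment=15
    N,N,H,...   <- 10 rows x (10 * fields) comma-separated single-letter codes
    ...

Fields are concatenated left-to-right along the root axis (columns = root
length, rows = root width).  Reading validates the map; ``read(write(m))``
is exact.

Observation tables are plain long-format CSV (UTF-8, '.' decimal): columns
treatment, phenophase, plant_id, fragment_id, field_index plus the seven
parameters.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    GRID_SHAPE,
    FieldGrid,
    FragmentMap,
    MapValidationError,
    validate_fragment_map,
)
from .metrics import OBSERVATION_COLUMNS

__all__ = [
    "read_map",
    "write_map",
    "read_observations",
    "write_observations",
    "render_map",
    "parse_rendered",
]

_META_KEYS = ("treatment", "phenophase", "plant", "fragment", "fields_per_fragment")

#: Display glyphs; plain single-letter mode is the canonical interchange.
GLYPHS = {"N": "·", "H": "─", "A": "✱", "V": "●"}


def write_map(fmap: FragmentMap, path) -> None:
    """Write one fragment map in the CSV grid dialect."""
    path = Path(path)
    matrix = fmap.as_matrix()
    with path.open("w", newline="", encoding="utf-8") as fh:
        fh.write(f"# treatment={fmap.treatment}\n")
        fh.write(f"# phenophase={fmap.phenophase}\n")
        fh.write(f"# plant={fmap.plant_id}\n")
        fh.write(f"# fragment={fmap.fragment_id}\n")
        fh.write(f"# fields_per_fragment={len(fmap.fields)}\n")
        writer = csv.writer(fh)
        for row in matrix:
            writer.writerow(row.tolist())


def read_map(path) -> FragmentMap:
    """Read and validate one fragment map; errors cite the offending line."""
    path = Path(path)
    meta: dict[str, str] = {}
    body: list[list[str]] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                key, sep, value = line.lstrip("# ").partition("=")
                if not sep:
                    raise MapValidationError(
                        f"{path}:{lineno}: malformed metadata line {line!r}"
                    )
                meta[key.strip()] = value.strip()
            else:
                body.append([tok.strip() for tok in line.split(",")])
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise MapValidationError(f"{path}: missing metadata {missing}")
    n_fields = int(meta["fields_per_fragment"])
    n_rows, n_cols = GRID_SHAPE
    if len(body) != n_rows:
        raise MapValidationError(
            f"{path}: body has {len(body)} rows, expected {n_rows} "
            f"(first body line is line {6})"
        )
    want = n_cols * n_fields
    for i, row in enumerate(body):
        if len(row) != want:
            raise MapValidationError(
                f"{path}: body row {i + 1} has {len(row)} cells, expected {want}"
            )
    matrix = np.asarray(body, dtype="<U1")
    fields = tuple(
        FieldGrid(matrix[:, i * n_cols : (i + 1) * n_cols], i + 1)
        for i in range(n_fields)
    )
    fmap = FragmentMap(
        fields=fields,
        fragment_id=int(meta["fragment"]),
        plant_id=int(meta["plant"]),
        treatment=meta["treatment"],
        phenophase=meta["phenophase"],
    )
    return validate_fragment_map(fmap, fields_per_fragment=n_fields)


def write_observations(table: pd.DataFrame, path) -> None:
    """Write a long-format observation table as CSV."""
    table.to_csv(path, index=False, encoding="utf-8")


def read_observations(path) -> pd.DataFrame:
    """Read a long-format observation table, checking the exact header."""
    table = pd.read_csv(path, encoding="utf-8")
    if list(table.columns) != OBSERVATION_COLUMNS:
        raise ValueError(
            f"unexpected observation header {list(table.columns)}; "
            f"expected {OBSERVATION_COLUMNS}"
        )
    return table


def render_map(
    fmap: FragmentMap, mode: str = "glyph", field_separator: str = ""
) -> str:
    """Text rendering of a fragment map, 10 rows x (10 * fields) columns.

    ``mode="glyph"`` uses display glyphs (· hypha-free, ─ hypha, ✱
    arbuscule, ● vesicle); ``mode="plain"`` keeps the single-letter codes
    and is parseable back by :func:`parse_rendered`.  ``field_separator``
    optionally marks field boundaries (e.g. ``"|"``).
    """
    if mode not in ("glyph", "plain"):
        raise ValueError(f"mode must be 'glyph' or 'plain', got {mode!r}")
    lines = []
    for r in range(GRID_SHAPE[0]):
        chunks = []
        for grid in fmap.fields:
            row = grid.cells[r]
            if mode == "glyph":
                chunks.append("".join(GLYPHS[c] for c in row))
            else:
                chunks.append("".join(row))
        lines.append(field_separator.join(chunks))
    return "\n".join(lines)


def parse_rendered(
    text: str,
    treatment: str,
    phenophase: str,
    plant_id: int = 1,
    fragment_id: int = 1,
) -> FragmentMap:
    """Inverse of plain-mode :func:`render_map` (separator-free)."""
    rows = [line for line in text.splitlines() if line.strip()]
    n_rows, n_cols = GRID_SHAPE
    if len(rows) != n_rows or len(set(map(len, rows))) != 1:
        raise MapValidationError("rendered text is not a rectangular 10-row block")
    width = len(rows[0])
    if width % n_cols:
        raise MapValidationError(
            f"rendered width {width} is not a multiple of {n_cols}"
        )
    matrix = np.asarray([list(r) for r in rows], dtype="<U1")
    n_fields = width // n_cols
    fields = tuple(
        FieldGrid(matrix[:, i * n_cols : (i + 1) * n_cols], i + 1)
        for i in range(n_fields)
    )
    fmap = FragmentMap(fields, fragment_id, plant_id, treatment, phenophase)
    return validate_fragment_map(fmap, fields_per_fragment=n_fields)
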
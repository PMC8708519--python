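"""Data model for grid-based mycorrhizal colonization mapping.

A root fragment (~1 cm) is scored under the microscope as an ordered run of
microscopic fields; each field is a 10x10 eyepiece grid whose cells are coded
by the fungal structure seen in them:

====  =========================================
code  meaning
====  =========================================
N     no fungal structure (non-mycorrhizal)
H     hypha
A     arbuscule
V     vesicle
====  =========================================

A cell is *colonized* iff its code is H, A or V.  The experimental design is
a treatment x phenophase layout with a shared control point: treatments A0
(pre-treatment control point), A1 (unfertilized) and A2 (organically
fertilized); phenophases B1 (2-4 leaves) through B5 (physiological maturity).
A0 is only observed at B1; A1/A2 at B2..B5, giving nine legal combinations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np

__all__ = [
    "CELL_CODES",
    "COLONIZED_CODES",
    "TREATMENTS",
    "PHENOPHASES",
    "LEGAL_COMBINATIONS",
    "PARAMETERS",
    "GRID_SHAPE",
    "FieldGrid",
    "FragmentMap",
    "DesignSpec",
    "DesignKey",
    "MapValidationError",
    "DesignError",
    "validate_fragment_map",
    "enumerate_design",
]

#: Legal single-letter cell codes.
CELL_CODES = ("N", "H", "A", "V")

#: Codes that count as colonized.
COLONIZED_CODES = ("H", "A", "V")

TREATMENTS = ("A0", "A1", "A2")
PHENOPHASES = ("B1", "B2", "B3", "B4", "B5")

#: The nine treatment-phenophase combinations realized in the study design:
#: the control point A0-B1 plus {A1,A2} x {B2..B5}.
LEGAL_COMBINATIONS = (("A0", "B1"),) + tuple(
    (a, b) for a in ("A1", "A2") for b in ("B2", "B3", "B4", "B5")
)

#: Column order of the seven colonization parameters, as reported.
PARAMETERS = (
    "frequency",
    "intensity",
    "arbuscules",
    "vesicles",
    "degree",
    "non_mycorrhizal",
    "mnm_report",
)

#: Eyepiece grid dimensions (rows, columns).
GRID_SHAPE = (10, 10)


class MapValidationError(ValueError):
    """A grid or fragment map violates a structural invariant."""


class DesignError(ValueError):
    """A key refers to a combination outside the experimental design."""


class DesignKey(NamedTuple):
    """Identity of one microscopic field within the full design."""

    treatment: str
    phenophase: str
    plant_id: int
    fragment_id: int
    field_index: int


def _as_cell_array(cells) -> np.ndarray:
    arr = np.asarray(cells, dtype="<U1")
    if arr.shape != GRID_SHAPE:
        raise MapValidationError(
            f"grid must be {GRID_SHAPE[0]}x{GRID_SHAPE[1]}, got shape {arr.shape}"
        )
    bad = ~np.isin(arr, CELL_CODES)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise MapValidationError(
            f"unknown cell code {arr[r, c]!r} at row {r + 1}, column {c + 1}; "
            f"legal codes are {CELL_CODES}"
        )
    return arr


@dataclass(frozen=True)
class FieldGrid:
    """One microscopic field: a 10x10 matrix of cell codes.

    Parameters
    ----------
    cells
        10x10 array-like of single-letter codes from :data:`CELL_CODES`.
    field_index
        1-based position of the field within its fragment.
    """

    cells: np.ndarray
    field_index: int = 1

    def __post_init__(self):
        object.__setattr__(self, "cells", _as_cell_array(self.cells))
        if self.field_index < 1:
            raise MapValidationError(
                f"field_index must be >= 1, got {self.field_index}"
            )

    @property
    def colonized(self) -> np.ndarray:
        """Boolean mask of colonized cells (H, A or V)."""
        return self.cells != "N"

    def __eq__(self, other):
        if not isinstance(other, FieldGrid):
            return NotImplemented
        return self.field_index == other.field_index and np.array_equal(
            self.cells, other.cells
        )

    @classmethod
    def empty(cls, field_index: int = 1) -> "FieldGrid":
        return cls(np.full(GRID_SHAPE, "N"), field_index)


@dataclass(frozen=True)
class FragmentMap:
    """Ordered sequence of fields scored along one 1-cm root fragment."""

    fields: tuple[FieldGrid, ...]
    fragment_id: int
    plant_id: int
    treatment: str
    phenophase: str

    def __post_init__(self):
        object.__setattr__(self, "fields", tuple(self.fields))

    @property
    def combination(self) -> tuple[str, str]:
        return (self.treatment, self.phenophase)

    def __len__(self) -> int:
        return len(self.fields)

    def __iter__(self) -> Iterator[FieldGrid]:
        return iter(self.fields)

    def as_matrix(self) -> np.ndarray:
        """Concatenate fields left-to-right into a 10 x (10*n_fields) array.

        Columns run along the root axis, matching how colonization maps are
        rendered.
        """
        return np.concatenate([f.cells for f in self.fields], axis=1)


@dataclass(frozen=True)
class DesignSpec:
    """Bookkeeping for the sampling layout.

    Defaults reproduce the study totals: 5 plants per combination, 6
    fragments per plant at the control point and 9 elsewhere, 15 fields per
    fragment; hence 450 field observations for A0-B1, 675 for each of the
    other eight combinations, 5850 fields and 390 fragment maps overall.
    """

    combinations: tuple[tuple[str, str], ...] = LEGAL_COMBINATIONS
    plants_per_combination: int = 5
    fragments_per_plant_control: int = 6
    fragments_per_plant: int = 9
    fields_per_fragment: int = 15

    def __post_init__(self):
        object.__setattr__(
            self, "combinations", tuple((t, p) for t, p in self.combinations)
        )
        for t, p in self.combinations:
            _check_combination(t, p)
        for name in (
            "plants_per_combination",
            "fragments_per_plant_control",
            "fragments_per_plant",
            "fields_per_fragment",
        ):
            if getattr(self, name) < 1:
                raise DesignError(f"{name} must be positive")

    def n_fragments(self, treatment: str, phenophase: str) -> int:
        """Fragments scored per plant for one combination."""
        if treatment == "A0":
            return self.fragments_per_plant_control
        return self.fragments_per_plant

    def n_fields(self, treatment: str, phenophase: str) -> int:
        """Field observations contributed by one combination."""
        return (
            self.plants_per_combination
            * self.n_fragments(treatment, phenophase)
            * self.fields_per_fragment
        )

    @property
    def total_fields(self) -> int:
        return sum(self.n_fields(t, p) for t, p in self.combinations)

    @property
    def total_fragments(self) -> int:
        return sum(
            self.plants_per_combination * self.n_fragments(t, p)
            for t, p in self.combinations
        )


def _check_combination(treatment: str, phenophase: str) -> None:
    if treatment not in TREATMENTS:
        raise DesignError(
            f"unknown treatment {treatment!r}; expected one of {TREATMENTS}"
        )
    if phenophase not in PHENOPHASES:
        raise DesignError(
            f"unknown phenophase {phenophase!r}; expected one of {PHENOPHASES}"
        )
    if (treatment, phenophase) not in LEGAL_COMBINATIONS:
        raise DesignError(
            f"combination {treatment}-{phenophase} is not part of the design; "
            f"A0 pairs only with B1, A1/A2 only with B2..B5"
        )


def validate_fragment_map(
    fmap: FragmentMap, fields_per_fragment: int = 15
) -> FragmentMap:
    """Check all structural invariants of a fragment map.

    Returns the map unchanged if valid; raises :class:`MapValidationError`
    for grid defects and :class:`DesignError` for an illegal
    treatment-phenophase pair.  Idempotent.
    """
    _check_combination(fmap.treatment, fmap.phenophase)
    if len(fmap.fields) != fields_per_fragment:
        raise MapValidationError(
            f"fragment {fmap.fragment_id} has {len(fmap.fields)} fields, "
            f"expected {fields_per_fragment}"
        )
    for expected, grid in enumerate(fmap.fields, start=1):
        if not isinstance(grid, FieldGrid):  # re-validate raw payloads
            grid = FieldGrid(grid, expected)
        if grid.field_index != expected:
            raise MapValidationError(
                f"field_index {grid.field_index} out of order; expected {expected}"
            )
    return fmap


def enumerate_design(spec: DesignSpec | None = None) -> list[DesignKey]:
    """List one key per microscopic field in the full design.

    Pure function of ``spec``: the order is fixed (combinations as given,
    then plant, fragment, field, each 1-based).  The default spec yields
    5850 keys in 390 fragment groups.
    """
    spec = spec or DesignSpec()
    keys = []
    for (t, p) in spec.combinations:
        for plant, frag, fld in itertools.product(
            range(1, spec.plants_per_combination + 1),
            range(1, spec.n_fragments(t, p) + 1),
            range(1, spec.fields_per_fragment + 1),
        ):
            keys.append(DesignKey(t, p, plant, frag, fld))
    return keys
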
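"""Seeded simulator for colonization patterns in root fragments.

Stands in for raw microscopy: it generates fragment maps whose per-variant
mean frequency and intensity approximate prescribed targets, with one of two
spatial strategies:

longitudinal
    Hyphae run along the root axis as horizontal tracks that extend
    column-by-column with probability ``persistence`` (continuing across
    field boundaries), with arbuscules budding as single-cell lateral
    branches off the tracks.  This is the pattern of unfertilized roots.
radial
    Colonization appears as compact spots: Poisson-many centers per field,
    each grown as a discrete disc until its share of the field's cell budget
    is met, with arbuscules converted in spot interiors.  Spots alternate
    with colonization-free fields.  This is the pattern under organic
    treatment.

Both strategies share a budget model: a field is skipped entirely with
probability ``gap_rate``; otherwise it receives a cell budget drawn around
``target_intensity / (1 - gap_rate)`` so that the long-run mean intensity
matches the target.  Frequency is an emergent property of the geometry;
``calibrate_preset`` searches ``gap_rate`` plus the strategy's shape knob
(``persistence`` or ``spot_rate``) until pilot means hit both targets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy import ndimage

from .core import (
    GRID_SHAPE,
    PHENOPHASES,
    TREATMENTS,
    DesignSpec,
    FieldGrid,
    FragmentMap,
    validate_fragment_map,
)
from .metrics import field_frequency, field_intensity, observations_from_maps

__all__ = [
    "StrategyParams",
    "CalibrationResult",
    "CalibrationError",
    "simulate_fragment",
    "generate_design",
    "calibrate_preset",
    "fragment_seed",
    "mean_run_length",
    "component_count",
]

_N_ROWS, _N_COLS = GRID_SHAPE
_N_CELLS = _N_ROWS * _N_COLS


@dataclass(frozen=True)
class StrategyParams:
    """Parameters of one simulation preset.

    Parameters
    ----------
    strategy
        ``"longitudinal"`` or ``"radial"``.
    target_frequency, target_intensity
        Desired long-run means, in percent.
    arbuscule_share, vesicle_share
        Fraction of colonized cells coded A respectively V; their sum must
        not exceed 1 (arbuscule wins over vesicle on conflict).
    gap_rate
        Probability that a field is left entirely uncolonized.
    spot_rate
        Radial only: expected number of spot centers per colonized field.
    persistence
        Longitudinal only: probability that a hyphal track continues into
        the next column (also across the boundary to the next field).
    field_cv
        Coefficient of variation of the per-field cell budget; sets how
        dispersed colonization is between fields of one fragment.
    seed
        Base RNG seed mixed with the fragment key.
    """

    strategy: str
    target_frequency: float
    target_intensity: float
    arbuscule_share: float = 0.0
    vesicle_share: float = 0.0
    gap_rate: float = 0.0
    spot_rate: float = 3.0
    persistence: float = 0.85
    field_cv: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in ("longitudinal", "radial"):
            raise ValueError(
                f"strategy must be 'longitudinal' or 'radial', got {self.strategy!r}"
            )
        for name in ("target_frequency", "target_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        for name in ("arbuscule_share", "vesicle_share", "gap_rate", "persistence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.arbuscule_share + self.vesicle_share > 1.0 + 1e-12:
            raise ValueError("arbuscule_share + vesicle_share must not exceed 1")
        if self.spot_rate < 0:
            raise ValueError("spot_rate must be nonnegative")
        if self.field_cv < 0:
            raise ValueError("field_cv must be nonnegative")
        if self.target_intensity > 0 and self.gap_rate >= 1.0:
            raise ValueError("gap_rate must be < 1 when target_intensity > 0")
        if self.target_intensity > 0:
            mu = self.target_intensity / (1.0 - self.gap_rate)
            if mu > 98.0:
                raise ValueError(
                    f"infeasible targets: intensity {self.target_intensity} at "
                    f"gap_rate {self.gap_rate} needs {mu:.1f} colonized cells "
                    "per colonized field (grid holds 100)"
                )


def fragment_seed(master_seed: int, treatment: str, phenophase: str,
                  plant_id: int, fragment_id: int) -> np.random.SeedSequence:
    """Stable per-fragment seed, independent of generation order."""
    return np.random.SeedSequence(
        [
            int(master_seed),
            TREATMENTS.index(treatment),
            PHENOPHASES.index(phenophase),
            int(plant_id),
            int(fragment_id),
        ]
    )


def _stochastic_round(rng, x: float) -> int:
    """Integer with expectation x; keeps sub-cell structure shares unbiased."""
    base = int(np.floor(x))
    return base + int(rng.random() < (x - base))


def _field_budget(rng, mu: float, cv: float) -> int:
    k = int(round(rng.normal(mu, cv * mu)))
    return int(np.clip(k, 0, _N_CELLS))


def _lay_longitudinal(rng, budget: int, persistence: float,
                      carry: list[int]) -> tuple[np.ndarray, list[int]]:
    """Lay horizontal hyphal tracks; return colonized mask and carried rows."""
    mask = np.zeros(GRID_SHAPE, dtype=bool)
    placed = 0
    next_carry: list[int] = []
    attempts = 0
    pending = list(carry)
    while placed < budget and attempts < 50 * budget + 50:
        attempts += 1
        if pending:
            row, col = pending.pop(0), 0
        else:
            row = int(rng.integers(_N_ROWS))
            col = int(rng.integers(_N_COLS))
        while placed < budget:
            if not mask[row, col]:
                mask[row, col] = True
                placed += 1
            if rng.random() >= persistence:
                break
            col += 1
            if col >= _N_COLS:
                # track runs off the right edge into the next field
                next_carry.append(row)
                break
    return mask, next_carry


def _lay_radial(rng, budget: int, spot_rate: float) -> np.ndarray:
    """Lay compact spots grown as discrete discs until the budget is met."""
    mask = np.zeros(GRID_SHAPE, dtype=bool)
    n_spots = max(1, int(rng.poisson(spot_rate)))
    n_spots = min(n_spots, budget)  # no empty spots
    # near-equal split of the budget across spots
    per_spot = np.full(n_spots, budget // n_spots)
    per_spot[: budget % n_spots] += 1
    rows, cols = np.indices(GRID_SHAPE)
    placed = 0
    centers: list[tuple[int, int]] = []
    for b in per_spot:
        if placed >= budget:
            break
        # spots alternate with mycorrhiza-free area: keep centers apart
        # (Chebyshev >= 3) where the field allows it
        for _ in range(20):
            r0 = int(rng.integers(_N_ROWS))
            c0 = int(rng.integers(_N_COLS))
            if all(max(abs(r0 - r), abs(c0 - c)) >= 3 for r, c in centers):
                break
        centers.append((r0, c0))
        # grow outward by distance; jitter breaks ties so discs stay roundish
        dist = (rows - r0) ** 2 + (cols - c0) ** 2 + rng.random(GRID_SHAPE) * 0.5
        order = np.argsort(dist, axis=None)
        taken = 0
        for idx in order:
            if taken >= b:
                break
            r, c = divmod(int(idx), _N_COLS)
            if not mask[r, c]:
                mask[r, c] = True
                taken += 1
                placed += 1
    return mask


_NEIGHBOR_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))


def _colonized_neighbour_counts(mask: np.ndarray) -> np.ndarray:
    counts = np.zeros(GRID_SHAPE, dtype=int)
    counts[:-1, :] += mask[1:, :]
    counts[1:, :] += mask[:-1, :]
    counts[:, :-1] += mask[:, 1:]
    counts[:, 1:] += mask[:, :-1]
    return counts


def _place_structures(rng, mask: np.ndarray, n_arb: int, n_ves: int,
                      strategy: str) -> np.ndarray:
    """Assign A and V codes over a colonized mask; returns the coded grid."""
    cells = np.where(mask, "H", "N").astype("<U1")
    if n_arb > 0 and mask.any():
        if strategy == "longitudinal":
            # lateral branches: new A cells directly above/below track cells
            track = np.argwhere(mask)
            budded = 0
            for _ in range(20 * n_arb + 20):
                if budded >= n_arb:
                    break
                r, c = track[rng.integers(len(track))]
                dr = -1 if rng.random() < 0.5 else 1
                rr = r + dr
                if 0 <= rr < _N_ROWS and cells[rr, c] == "N":
                    cells[rr, c] = "A"
                    mask[rr, c] = True
                    budded += 1
            n_arb -= budded
        if n_arb > 0:
            # interiors first: colonized cells with the most colonized
            # 4-neighbours (keeps every arbuscule inside a colonized patch)
            counts = _colonized_neighbour_counts(mask)
            cand = np.argwhere(mask & (counts > 0) & (cells != "A"))
            if len(cand):
                score = counts[cand[:, 0], cand[:, 1]] + rng.random(len(cand))
                for i in np.argsort(-score)[:n_arb]:
                    cells[cand[i, 0], cand[i, 1]] = "A"
    if n_ves > 0:
        hyphal = np.argwhere(cells == "H")
        if len(hyphal):
            pick = rng.choice(len(hyphal), size=min(n_ves, len(hyphal)),
                              replace=False)
            for i in np.atleast_1d(pick):
                cells[hyphal[i][0], hyphal[i][1]] = "V"
    return cells


def simulate_fragment(
    params: StrategyParams,
    key=("A1", "B2", 1, 1),
    n_fields: int = 15,
) -> FragmentMap:
    """Simulate one fragment map for a design key.

    ``key`` is ``(treatment, phenophase, plant_id, fragment_id)``; the RNG
    stream is a pure function of ``(params.seed, key)``, so identical inputs
    reproduce byte-identical maps regardless of call order.
    """
    treatment, phenophase, plant_id, fragment_id = key[:4]
    rng = np.random.default_rng(
        fragment_seed(params.seed, treatment, phenophase, plant_id, fragment_id)
    )
    target_i = params.target_intensity
    mu = target_i / (1.0 - params.gap_rate) if target_i > 0 else 0.0

    grids = []
    carry: list[int] = []
    for idx in range(1, n_fields + 1):
        if target_i <= 0 or rng.random() < params.gap_rate:
            carry = []  # colonization-free field breaks running hyphae
            grids.append(FieldGrid.empty(idx))
            continue
        budget = _field_budget(rng, mu, params.field_cv)
        if budget == 0:
            carry = []
            grids.append(FieldGrid.empty(idx))
            continue
        n_arb = _stochastic_round(rng, budget * params.arbuscule_share)
        n_ves = _stochastic_round(rng, budget * params.vesicle_share)
        n_hyphal = max(1, budget - n_arb)
        if params.strategy == "longitudinal":
            mask, carry = _lay_longitudinal(rng, n_hyphal, params.persistence, carry)
        else:
            mask = _lay_radial(rng, budget, params.spot_rate)
            n_arb = min(n_arb, budget)  # conversions, not additions
        cells = _place_structures(rng, mask, n_arb, n_ves, params.strategy)
        grids.append(FieldGrid(cells, idx))
    fmap = FragmentMap(
        fields=tuple(grids),
        fragment_id=fragment_id,
        plant_id=plant_id,
        treatment=treatment,
        phenophase=phenophase,
    )
    return validate_fragment_map(fmap, fields_per_fragment=n_fields)


def generate_design(
    spec: DesignSpec | None = None,
    presets: Mapping[tuple[str, str], StrategyParams] | None = None,
    seed: int = 0,
):
    """Simulate every fragment of the design and score all its fields.

    Returns ``(maps, table)``: one :class:`FragmentMap` per (combination,
    plant, fragment) and the long-format observation table of per-field
    metrics.  Per-fragment seeds are derived deterministically from ``seed``
    and the key, so generation is reproducible end-to-end.
    """
    from .presets import default_presets  # late import to avoid cycle

    spec = spec or DesignSpec()
    presets = presets if presets is not None else default_presets()
    for combo in spec.combinations:
        if combo not in presets:
            raise KeyError(
                f"no preset for combination {combo[0]}-{combo[1]}"
            )
    maps = []
    for (t, p) in spec.combinations:
        params = replace(presets[(t, p)], seed=seed)
        for plant in range(1, spec.plants_per_combination + 1):
            for frag in range(1, spec.n_fragments(t, p) + 1):
                maps.append(
                    simulate_fragment(
                        params, (t, p, plant, frag),
                        n_fields=spec.fields_per_fragment,
                    )
                )
    return maps, observations_from_maps(maps)


# ---------------------------------------------------------------------------
# spatial-pattern descriptors (used to contrast the two strategies)


def mean_run_length(grid) -> float:
    """Mean length of maximal horizontal runs of colonized cells.

    Returns NaN for an empty field.
    """
    mask = (grid.cells if isinstance(grid, FieldGrid) else np.asarray(grid)) != "N"
    runs = []
    for row in mask:
        n = 0
        for v in row:
            if v:
                n += 1
            elif n:
                runs.append(n)
                n = 0
        if n:
            runs.append(n)
    return float(np.mean(runs)) if runs else float("nan")


def component_count(grid) -> int:
    """Number of 4-connected colonized components in one field."""
    mask = (grid.cells if isinstance(grid, FieldGrid) else np.asarray(grid)) != "N"
    _, n = ndimage.label(mask)
    return int(n)


# ---------------------------------------------------------------------------
# calibration


class CalibrationError(RuntimeError):
    """Pilot search failed to reach the targets; carries the best params."""

    def __init__(self, message: str, best: StrategyParams, achieved):
        super().__init__(message)
        self.best = best
        self.achieved = achieved


@dataclass(frozen=True)
class CalibrationResult:
    """Calibrated parameters plus the pilot means they achieved."""

    params: StrategyParams
    achieved_frequency: float
    achieved_intensity: float
    n_pilot: int


def _pilot_means(params: StrategyParams, n_fragments: int) -> tuple[float, float]:
    freqs, intens = [], []
    for frag in range(1, n_fragments + 1):
        fmap = simulate_fragment(params, ("A1", "B2", 1, frag))
        for g in fmap.fields:
            freqs.append(field_frequency(g))
            intens.append(field_intensity(g))
    return float(np.mean(freqs)), float(np.mean(intens))


_SHAPE_GRID = {
    # candidates in order of preference: long tracks for the longitudinal
    # habit, many small discs for the radial one, so the two habits stay
    # visually and topologically distinct; later entries are fallbacks
    "longitudinal": [("persistence", v) for v in (0.95, 0.9, 0.85)],
    "radial": [("spot_rate", v) for v in (6.0, 7.0, 5.0, 4.0)],
}


def calibrate_preset(
    strategy: str,
    target_metrics: Mapping[str, float],
    n_pilot: int = 200,
    seed: int = 0,
    tolerance: float = 0.10,
) -> CalibrationResult:
    """Search gap_rate and the strategy's shape knob to hit the targets.

    ``target_metrics`` holds ``frequency`` and ``intensity`` (percent) and
    optionally ``arbuscules`` and ``vesicles`` (percent, converted to shares
    of colonized cells).  The search bisects ``gap_rate`` — frequency is
    monotone decreasing in it at fixed intensity — for each shape candidate,
    then keeps the candidate with the smallest worst-case relative error
    over ``n_pilot`` pilot fragments.

    Raises :class:`CalibrationError` (carrying the best parameters found)
    if neither pilot mean lands within ``tolerance`` relative error.
    """
    t_freq = float(target_metrics["frequency"])
    t_int = float(target_metrics["intensity"])
    if n_pilot < 50:
        raise ValueError("n_pilot must be at least 50")
    if not (0.0 <= t_int <= t_freq <= 100.0):
        raise ValueError(
            f"targets must satisfy 0 <= intensity <= frequency <= 100; "
            f"got frequency={t_freq}, intensity={t_int}"
        )
    arb_share = (
        float(target_metrics.get("arbuscules", 0.0)) / t_int if t_int > 0 else 0.0
    )
    ves_share = (
        float(target_metrics.get("vesicles", 0.0)) / t_int if t_int > 0 else 0.0
    )

    def make(gap: float, shape_name: str, shape_val: float) -> StrategyParams:
        kw = dict(
            strategy=strategy,
            target_frequency=t_freq,
            target_intensity=t_int,
            arbuscule_share=min(arb_share, 1.0),
            vesicle_share=min(ves_share, 1.0 - min(arb_share, 1.0)),
            gap_rate=gap,
            seed=seed,
        )
        kw[shape_name] = shape_val
        return StrategyParams(**kw)

    if t_int == 0.0:
        params = StrategyParams(
            strategy=strategy, target_frequency=0.0, target_intensity=0.0,
            gap_rate=1.0, seed=seed,
        )
        return CalibrationResult(params, 0.0, 0.0, n_pilot)

    n_search = max(30, n_pilot // 5)
    g_hi = 1.0 - t_int / 95.0
    best = None
    for shape_name, shape_val in _SHAPE_GRID[strategy]:
        lo, hi = 0.0, g_hi
        gap = g_hi / 2
        for _ in range(12):
            gap = (lo + hi) / 2
            f_hat, _ = _pilot_means(make(gap, shape_name, shape_val), n_search)
            if f_hat > t_freq:
                lo = gap  # too spread out: concentrate more
            else:
                hi = gap
            if abs(f_hat - t_freq) / t_freq < 0.02:
                break
        cand = make(gap, shape_name, shape_val)
        f_hat, i_hat = _pilot_means(cand, n_pilot)
        err = max(abs(f_hat - t_freq) / t_freq, abs(i_hat - t_int) / t_int)
        if best is None or err < best[0]:
            best = (err, cand, f_hat, i_hat)
        if err <= tolerance / 2:
            break  # preferred geometry fits; no need to fall back
    err, cand, f_hat, i_hat = best
    if err > tolerance:
        raise CalibrationError(
            f"calibration missed targets (worst relative error {err:.3f}); "
            f"best pilot means F={f_hat:.2f}, I={i_hat:.2f} "
            f"for F={t_freq}, I={t_int}",
            cand,
            (f_hat, i_hat),
        )
    return CalibrationResult(cand, f_hat, i_hat, n_pilot)
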
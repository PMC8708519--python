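"""Four-step representative-map selection.

For one treatment-phenophase variant, the map that best represents the
general colonization pattern is found by sequential tolerance-band
filtering on fragment-level means: keep fragments whose frequency lies
within a band around the variant mean, then intensity, then arbuscules,
then vesicles.  The band is 0-5% deviation from the mean by default,
read as relative deviation ``|x - mean| / mean <= tolerance``; an
absolute-percentage-point band is available as ``mode="absolute"``.

A step with a zero mean passes only fragments whose value is exactly
zero (the relative band is undefined there).  All survivors are
returned; no single-winner tie-break is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .metrics import fragment_metrics

__all__ = ["SelectionResult", "select_representative", "FILTER_STEPS"]

#: Parameters applied in order, one filtering step each.
FILTER_STEPS = ("frequency", "intensity", "arbuscules", "vesicles")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the four-step filter for one variant."""

    treatment: str
    phenophase: str
    reference_means: dict
    tolerance: float
    mode: str
    survivors_per_step: tuple[int, int, int, int]
    selected: tuple[tuple[int, int], ...]  # (plant_id, fragment_id)
    emptied_at: str | None = None  # step at which the selection emptied

    @property
    def combination(self) -> tuple[str, str]:
        return (self.treatment, self.phenophase)


def _fragment_table(maps, table, combination) -> pd.DataFrame:
    t, p = combination
    if table is not None:
        sub = table[(table["treatment"] == t) & (table["phenophase"] == p)]
        if sub.empty:
            raise ValueError(f"combination {t}-{p} not present in table")
        return (
            sub.groupby(["plant_id", "fragment_id"])[list(FILTER_STEPS)]
            .mean()
            .reset_index()
        )
    rows = []
    for fmap in maps:
        if (fmap.treatment, fmap.phenophase) != (t, p):
            continue
        m = fragment_metrics(fmap)
        rows.append(
            {
                "plant_id": fmap.plant_id,
                "fragment_id": fmap.fragment_id,
                **{name: getattr(m, name) for name in FILTER_STEPS},
            }
        )
    if not rows:
        raise ValueError(f"no fragment maps for combination {t}-{p}")
    return pd.DataFrame(rows)


def select_representative(
    maps=None,
    table: pd.DataFrame | None = None,
    combination: tuple[str, str] = ("A0", "B1"),
    tolerance: float = 0.05,
    mode: str = "relative",
    reference_means: dict | None = None,
) -> SelectionResult:
    """Run the four-step filter for one variant.

    Fragment-level means come from ``table`` (averaged over its fields) when
    given, otherwise are recomputed from ``maps``.  ``reference_means`` may
    override the variant means the bands are centred on (e.g. to reuse
    published values); by default they are recomputed from the input set.

    The result lists survivor counts after each step and the surviving
    ``(plant_id, fragment_id)`` pairs; an empty final selection is flagged
    via ``emptied_at``, not raised.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if mode not in ("relative", "absolute"):
        raise ValueError(f"mode must be 'relative' or 'absolute', got {mode!r}")
    frags = _fragment_table(maps, table, combination)
    means = {name: float(frags[name].mean()) for name in FILTER_STEPS}
    if reference_means:
        means.update({k: float(v) for k, v in reference_means.items()})

    survivors = frags
    counts = []
    emptied_at = None
    for step in FILTER_STEPS:
        if not survivors.empty:
            mu = means[step]
            if mode == "absolute":
                keep = (survivors[step] - mu).abs() <= tolerance
            elif mu == 0.0:
                keep = survivors[step] == 0.0
            else:
                keep = (survivors[step] - mu).abs() / abs(mu) <= tolerance
            survivors = survivors[keep]
            if survivors.empty and emptied_at is None:
                emptied_at = step
        counts.append(len(survivors))
    return SelectionResult(
        treatment=combination[0],
        phenophase=combination[1],
        reference_means=means,
        tolerance=tolerance,
        mode=mode,
        survivors_per_step=tuple(counts),
        selected=tuple(
            (int(r.plant_id), int(r.fragment_id)) for r in survivors.itertuples()
        ),
        emptied_at=emptied_at,
    )
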
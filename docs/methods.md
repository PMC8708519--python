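# Methods

## Scoring model

A microscopic field is a 10×10 grid of single-letter cell codes (`N`, `H`,
`A`, `V`); one code per cell, with arbuscule taking precedence over vesicle
and any structure over bare hypha when the simulator assigns codes. The
seven parameters per field are defined in the README; three conventions
deserve note because the index family admits variants:

- **Combining horizontal and vertical frequency.** The row-occupancy and
  column-occupancy shares are computed separately and combined by simple
  average. The average is symmetric under transposition and reduces to the
  plain presence/absence share at the 0% and 100% extremes.
- **Degree per field, then averaged.** `D = F·I/100` is computed per field
  and the fragment/variant value is the mean of per-field degrees. Because
  F and I are positively correlated within a variant, this per-field
  product exceeds the product of the means — the ordering real scoring
  tables show. A means-level product is not offered.
- **M/nM report per field, then averaged.** `I/(100−I)` is convex in I, so
  the per-field mean dominates `mean(I)/mean(100−I)` whenever intensity
  varies (Jensen); tests assert this ordering on every simulated variant.
  Saturated fields (`I = 100`) leave the ratio undefined: they are flagged,
  counted (`report_undefined`) and excluded from report means rather than
  clipped, since fully colonized fields are edge cases, not the norm.

Percentages are carried at full float precision; rounding (half-up, two
decimals) happens only in report strings such as the regression equation.

## Experimental-design bookkeeping

The printed totals of the emulated design (5850 field observations; 450 at
the control point; 390 fragment maps) force 15 fields per fragment and 6
(control point) or 9 (elsewhere) fragments per plant at 5 plants per
variant; `DesignSpec` defaults encode that reading and every count is
configurable. The pre-treatment control point is modelled as its own
treatment level `A0`, legal only with phenophase `B1`.

## Simulator

The generator stands in for unavailable microscopy; its defaults are the
study conditions. Per field it draws a colonized-cell budget and lays it
out with one of two habits:

- a field is skipped entirely with probability `gap_rate` (running hyphae
  die at a skipped field);
- otherwise the budget is `clip(round(Normal(μ, cv·μ)), 0, 100)` with
  `μ = target_intensity/(1 − gap_rate)`, so mean intensity matches the
  target by construction; `field_cv = 0.35` by default, giving the broad,
  zero-inflated intensity histograms typical of gridded colonization scores;
- **longitudinal**: horizontal tracks start at random cells and extend
  column-by-column with probability `persistence` (0.95 in the shipped
  presets, expected runs ≈ 20 cells), continuing across field boundaries;
  arbuscules bud as single-cell lateral branches off tracks; vesicles
  convert random hyphal cells.
- **radial**: `max(1, Poisson(spot_rate))` centers per field, kept ≥3 cells
  apart (Chebyshev, rejection-sampled) so spots alternate with free area;
  each spot grows as a discrete Euclidean disc (ties jittered) until its
  share of the budget is met; arbuscules convert interior cells (most
  colonized 4-neighbours first), which keeps every arbuscule adjacent to
  colonized tissue.

Arbuscule/vesicle counts per field use stochastic rounding so that shares
well below one cell per field (vesicles ~0.1% of area) still realize their
expectation.

Frequency is emergent: `calibrate_preset` bisects `gap_rate` (frequency is
monotone decreasing in it at fixed intensity) for each candidate shape knob
and accepts the first geometry whose pilot means land within half the
requested tolerance, preferring long tracks (longitudinal) and many small
discs (radial) so the two habits stay distinct in run length and patch
count. The shipped presets were calibrated against the study-level variant
means (seed 12345, 600 pilot fragments; worst pilot error ≈ 4%) and are
frozen in `default_config.yaml`.

What the simulator does **not** emulate: root anatomy, hyphal growth
dynamics between phenophases, plant-to-plant heterogeneity (plants are
exchangeable within a variant, so simulated standard errors differ from
field data), and the dispersion of published standard errors (means only
are calibrated). Passing tests therefore validate the pipeline's
arithmetic, invariants and calibration — not biological fidelity of any
particular map.

## Representative-map filter

Sequential tolerance bands on fragment-level means: frequency, then
intensity, then arbuscules, then vesicles. "0–5% deviation from the
average" is read as relative deviation (`|x − μ|/μ ≤ 0.05`, default), with
an absolute-percentage-point mode as a switch; a zero-mean step passes only
exact zeros. The filter returns all survivors and the per-step counts — no
tie-break is imposed. Note that with sparsely occurring vesicles a strict
relative band often empties the selection at the vesicle step; the result
flags the emptying step (`emptied_at`) instead of erroring, and a wider
tolerance or the absolute mode is the practical remedy.

## Statistics

- **Two-way ANOVA** (sequential/type-I, via statsmodels `anova_lm`) runs on
  the crossed A1/A2 × B2..B5 sub-design; the control point cannot enter a
  crossed layout and is handled descriptively. The nine-variant LSD letter
  display instead derives from a one-way ANOVA over the nine combinations.
  The design is balanced under defaults, so type-I vs type-III is moot but
  the sequential choice is explicit. Zero total variance is flagged
  degenerate (all groups share `a`), not an error.
- **LSD letters**: groups differ iff
  `|m_i − m_j| > t(1−α/2, df)·√(MS_e(1/n_i + 1/n_j))`; letters come from
  maximal non-significant intervals along the descending-sorted means
  (insert-and-absorb), best group `a`. With equal group sizes the
  share-a-letter ⇔ not-significant equivalence is exact (the largest
  within-interval difference is between its extremes); with very unequal
  sizes the interval representation can be conservative.
- **Regression**: OLS `I = a + b·F`, per variant and pooled, reported as
  `y = a + b × x` with two half-up decimals. Two points are allowed (exact
  interpolation); constant frequency is rejected.
- **PCA** on the correlation matrix (parameters mix percentages and a
  ratio, so covariance scaling would be dominated by units), eigenvalues
  clipped at zero for rank-deficient inputs, sign fixed by making the
  largest-magnitude loading of each axis positive. Variance shares sum to
  100 by trace conservation. NMDS cross-ordination is out of scope; PCA
  results objects expose scores/loadings so an external ordination can be
  compared downstream.
- **Histograms**: half-open bins with the final bin closed, default widths
  10 (percent parameters), 2 (arbuscules/vesicles), 0.5 (M/nM report,
  upper edge derived from the data when unstated).

## Problem sizes and determinism

The test suite simulates one full design (390 fragments) once per session,
calibrates two pilot presets, and runs a 1000-replicate null Monte Carlo of
the two-way ANOVA at design size (5400 observations per replicate) to check
the type-I error at α = 0.05; the whole suite runs in about a minute on one
core. All RNG flows through `numpy.random.SeedSequence`: per-fragment
streams are seeded by `(master seed, treatment, phenophase, plant,
fragment)`, so any fragment can be regenerated in isolation and generation
order is irrelevant.

## Known limitations

- Cell-level coding is a modelling choice; eyepiece scoring conventions
  that record multiple structures per cell would need a richer code set.
- The frequency combination rule (simple average of horizontal and
  vertical) and the per-field degree/report conventions are defensible but
  not uniquely determined by the index family's descriptions; all are
  isolated behind `metrics` so alternatives can be swapped in.
- The LSD letter display assumes the homoscedastic one-error-term model of
  the underlying ANOVA; it is not a substitute for Tukey-style familywise
  control.
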
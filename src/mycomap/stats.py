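"""Statistical stage: histograms, correlations, regressions, ANOVA+LSD, PCA.

The fitted analyses follow the Model -> Results convention: construct a
model from an observation table, call ``fit()``, read estimates and
diagnostics off the results object or print ``summary()``.

Factorial structure.  The study design crosses fertilization (A1
unfertilized / A2 treated) with phenophase (B2..B5); the shared control
point A0-B1 has no pairing on either factor, so the two-way ANOVA runs on
the 2x4 sub-design and A0-B1 enters descriptively.  The LSD letter display
spanning all nine variants comes from a one-way ANOVA over the nine
treatment-phenophase combinations, matching how a nine-row means table
carries one letter set per column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.anova import anova_lm

from .core import PARAMETERS

__all__ = [
    "HistogramSpec",
    "histogram",
    "correlation_matrix",
    "FrequencyIntensityRegression",
    "FrequencyIntensityResults",
    "fit_frequency_intensity",
    "ColonizationAnova",
    "AnovaResults",
    "two_way_anova",
    "lsd_letters",
    "ColonizationPCA",
    "PcaResults",
    "pca",
    "round_half_up",
    "format_p",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero, as in printed reports."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_p(p: float) -> str:
    """p to three decimals with a '< 0.001' floor."""
    if np.isnan(p):
        return "NA"
    return "p < 0.001" if p < 0.001 else f"{p:.3f}"


# ---------------------------------------------------------------------------
# histograms

_DEFAULT_BIN_WIDTH = {
    "frequency": 10.0,
    "intensity": 10.0,
    "degree": 10.0,
    "non_mycorrhizal": 10.0,
    "arbuscules": 2.0,
    "vesicles": 2.0,
    "mnm_report": 0.5,
}


@dataclass(frozen=True)
class HistogramSpec:
    """Binning of one parameter: half-open ``[lo, hi)`` bins, last closed."""

    parameter: str
    bin_width: float
    lo: float = 0.0
    hi: float | None = None  # None: derived from data, rounded up to a bin

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @classmethod
    def for_parameter(cls, parameter: str, **kw) -> "HistogramSpec":
        width = kw.pop("bin_width", _DEFAULT_BIN_WIDTH.get(parameter, 10.0))
        hi = kw.pop("hi", 100.0 if parameter != "mnm_report" else None)
        return cls(parameter, width, hi=hi, **kw)


def histogram(values, spec: HistogramSpec) -> tuple[np.ndarray, np.ndarray]:
    """Bin counts and edges for one parameter.

    Counts sum to the number of (non-NaN) observations; values outside
    ``[lo, hi]`` are rejected.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("histogram needs at least one observation")
    hi = spec.hi
    if hi is None:
        hi = spec.lo + spec.bin_width * max(
            1, int(np.ceil((vals.max() - spec.lo) / spec.bin_width))
        )
    if (vals < spec.lo).any() or (vals > hi).any():
        bad = vals[(vals < spec.lo) | (vals > hi)][0]
        raise ValueError(
            f"value {bad} outside the declared range [{spec.lo}, {hi}] "
            f"for {spec.parameter}"
        )
    n_bins = int(round((hi - spec.lo) / spec.bin_width))
    edges = spec.lo + spec.bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)  # numpy closes the last bin
    return counts, edges


# ---------------------------------------------------------------------------
# correlations

def correlation_matrix(
    table: pd.DataFrame, parameters=PARAMETERS
) -> pd.DataFrame:
    """Pearson correlations between colonization parameters.

    Pairwise-complete over NaNs (the M/nM report is undefined on saturated
    fields).  A constant column yields NaN in its row and column, with a
    warning naming it, rather than an error.
    """
    cols = list(parameters)
    data = table[cols]
    if len(data) < 3:
        raise ValueError("correlation matrix needs at least 3 observations")
    constant = [c for c in cols if data[c].dropna().nunique() <= 1]
    if constant:
        warnings.warn(
            f"constant column(s) {constant}: correlations undefined",
            stacklevel=2,
        )
    corr = data.corr(method="pearson")
    for c in constant:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    return corr


# ---------------------------------------------------------------------------
# frequency -> intensity regression

class FrequencyIntensityRegression:
    """OLS forecast of colonization intensity from frequency.

    Fits ``intensity = a + b * frequency`` for one variant (or any subset),
    the per-variant prognosis of how densely mycorrhiza will develop for
    each percent of root penetrated.
    """

    def __init__(self, frequency, intensity):
        x = np.asarray(frequency, dtype=float)
        y = np.asarray(intensity, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("frequency and intensity must be 1-d and aligned")
        if x.size < 2:
            raise ValueError("regression needs at least 2 observations")
        if np.ptp(x) == 0:
            raise ValueError("frequency is constant; slope is undefined")
        self.frequency = x
        self.intensity = y

    @classmethod
    def from_table(
        cls, table: pd.DataFrame, combination: tuple[str, str] | None = None
    ) -> "FrequencyIntensityRegression":
        sub = table
        if combination is not None:
            t, p = combination
            sub = table[(table["treatment"] == t) & (table["phenophase"] == p)]
            if sub.empty:
                raise ValueError(f"combination {t}-{p} not present in table")
        return cls(sub["frequency"].to_numpy(), sub["intensity"].to_numpy())

    def fit(self) -> "FrequencyIntensityResults":
        res = sm.OLS(self.intensity, sm.add_constant(self.frequency)).fit()
        return FrequencyIntensityResults(self, res)


class FrequencyIntensityResults:
    """Estimates and diagnostics of one frequency->intensity fit."""

    def __init__(self, model, sm_results):
        self.model = model
        self._sm = sm_results
        self.intercept = float(sm_results.params[0])
        self.slope = float(sm_results.params[1])
        self.rsquared = float(sm_results.rsquared)
        self.nobs = int(sm_results.nobs)
        self.resid = np.asarray(sm_results.resid)

    @property
    def equation(self) -> str:
        """The fit as printed: ``y = a + b × x`` with 2-decimal coefficients."""
        a = round_half_up(self.intercept, 2)
        b = round_half_up(self.slope, 2)
        return f"y = {a:.2f} + {b:.2f} × x"

    def predict(self, frequency) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(frequency, dtype=float)

    def summary(self) -> str:
        return (
            f"Intensity ~ frequency OLS (n = {self.nobs})\n"
            f"  {self.equation}\n"
            f"  intercept = {self.intercept:.4f}, slope = {self.slope:.4f} "
            f"per 1% frequency, r² = {self.rsquared:.3f}"
        )


def fit_frequency_intensity(
    table: pd.DataFrame, combination: tuple[str, str] | None = None
) -> FrequencyIntensityResults:
    """Fit the intensity-on-frequency regression for one variant or overall."""
    return FrequencyIntensityRegression.from_table(table, combination).fit()


# ---------------------------------------------------------------------------
# ANOVA and LSD letters

def _variant_labels(table: pd.DataFrame) -> pd.Series:
    return table["treatment"].astype(str) + "-" + table["phenophase"].astype(str)


class ColonizationAnova:
    """ANOVA of one colonization parameter over the experimental design.

    ``kind="two_way"`` fits the sequential (type-I) decomposition
    treatment + phenophase + interaction on the crossed A1/A2 x B2..B5
    sub-design; the control point is excluded from the factorial.
    ``kind="one_way"`` fits a single factor over all treatment-phenophase
    combinations present, which is what the nine-variant LSD letter display
    is based on.
    """

    def __init__(self, table: pd.DataFrame, parameter: str, kind: str = "two_way"):
        if parameter not in table.columns:
            raise ValueError(f"parameter {parameter!r} not in table")
        if kind not in ("two_way", "one_way"):
            raise ValueError(f"kind must be 'two_way' or 'one_way', got {kind!r}")
        self.parameter = parameter
        self.kind = kind
        if kind == "two_way":
            data = table[
                table["treatment"].isin(["A1", "A2"])
                & table["phenophase"].isin(["B2", "B3", "B4", "B5"])
            ].copy()
            if data["treatment"].nunique() < 2 or data["phenophase"].nunique() < 2:
                raise ValueError(
                    "two-way ANOVA needs at least 2 levels of each factor"
                )
            counts = data.groupby(["treatment", "phenophase"], observed=True)[
                parameter
            ].count()
            thin = counts[counts < 2]
            full = data["treatment"].nunique() * data["phenophase"].nunique()
            missing = full - len(counts)
            if missing or len(thin):
                cells = [f"{t}-{p}" for t, p in thin.index]
                raise ValueError(
                    f"cells with fewer than 2 replicates or empty: {cells or 'missing cells'}"
                )
            data["group"] = _variant_labels(data)
        else:
            data = table.copy()
            data["group"] = _variant_labels(data)
            sizes = data.groupby("group")[parameter].count()
            if (sizes < 2).any():
                bad = list(sizes[sizes < 2].index)
                raise ValueError(f"groups with fewer than 2 observations: {bad}")
        self.data = data.dropna(subset=[parameter])

    def fit(self) -> "AnovaResults":
        y = self.data[self.parameter]
        degenerate = float(np.ptp(y)) == 0.0
        if self.kind == "two_way":
            formula = f"{self.parameter} ~ C(treatment) * C(phenophase)"
        else:
            formula = f"{self.parameter} ~ C(group)"
        ols_fit = smf.ols(formula, data=self.data).fit()
        if degenerate:
            table = None
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                raw = anova_lm(ols_fit, typ=1)
            rename = {
                "C(treatment)": "treatment",
                "C(phenophase)": "phenophase",
                "C(treatment):C(phenophase)": "treatment:phenophase",
                "C(group)": "group",
                "Residual": "residual",
            }
            table = raw.rename(index=rename, columns={"PR(>F)": "p"})
            if "mean_sq" not in table.columns:
                table["mean_sq"] = table["sum_sq"] / table["df"]
        group_stats = self.data.groupby("group")[self.parameter]
        return AnovaResults(
            parameter=self.parameter,
            kind=self.kind,
            table=table,
            residual_ms=float(ols_fit.mse_resid),
            residual_df=float(ols_fit.df_resid),
            group_means=group_stats.mean(),
            group_sizes=group_stats.count(),
            degenerate=degenerate,
        )


@dataclass
class AnovaResults:
    """Fitted ANOVA: the F table plus what the LSD display needs."""

    parameter: str
    kind: str
    table: pd.DataFrame | None
    residual_ms: float
    residual_df: float
    group_means: pd.Series
    group_sizes: pd.Series
    degenerate: bool = False

    def lsd_letters(self, alpha: float = 0.05) -> dict[str, str]:
        """Compact letter display over the fitted groups."""
        if self.degenerate:
            return {g: "a" for g in self.group_means.index}
        return lsd_letters(
            self.group_means,
            self.residual_ms,
            self.residual_df,
            self.group_sizes,
            alpha=alpha,
        )

    def summary(self) -> str:
        lines = [f"ANOVA ({self.kind}) of {self.parameter}"]
        if self.degenerate:
            lines.append("  degenerate: zero total variance, F undefined")
        else:
            for name, row in self.table.iterrows():
                if name == "residual":
                    lines.append(
                        f"  residual: df = {row['df']:.0f}, MS = {row['mean_sq']:.4f}"
                    )
                else:
                    lines.append(
                        f"  {name}: F = {row['F']:.2f} ({format_p(row['p'])})"
                    )
        letters = self.lsd_letters()
        means = ", ".join(
            f"{g} {self.group_means[g]:.2f} {letters[g]}"
            for g in self.group_means.sort_values(ascending=False).index
        )
        lines.append(f"  group means (LSD letters): {means}")
        return "\n".join(lines)


def two_way_anova(table: pd.DataFrame, parameter: str) -> AnovaResults:
    """Sequential two-way ANOVA on the crossed fertilization x phenophase design."""
    return ColonizationAnova(table, parameter, kind="two_way").fit()


def lsd_letters(
    group_means,
    residual_ms: float,
    residual_df: float,
    group_sizes,
    alpha: float = 0.05,
) -> dict[str, str]:
    """Compact letter display by the least-significant-difference criterion.

    Groups i, j differ significantly iff
    ``|mean_i - mean_j| > t(1 - alpha/2, df) * sqrt(MS_error * (1/n_i + 1/n_j))``.
    Letters are assigned by insert-and-absorb over means sorted in
    descending order (best group gets 'a'), so that two groups share a
    letter exactly when they are not significantly different.
    """
    means = pd.Series(group_means, dtype=float)
    sizes = pd.Series(group_sizes).reindex(means.index)
    if residual_df < 1:
        raise ValueError("residual df must be at least 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    tcrit = sps.t.ppf(1 - alpha / 2, residual_df)
    order = means.sort_values(ascending=False).index.to_list()
    k = len(order)

    def differ(i: int, j: int) -> bool:
        gi, gj = order[i], order[j]
        lsd = tcrit * np.sqrt(residual_ms * (1 / sizes[gi] + 1 / sizes[gj]))
        return abs(means[gi] - means[gj]) > lsd

    # maximal intervals of mutually non-different groups along the sorted
    # means (for LSD the largest gap in an interval is between its extremes,
    # so checking all pairs just guards the unequal-n corner)
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and not any(differ(l, j + 1) for l in range(i, j + 1)):
            j += 1
        if not intervals or intervals[-1][1] < j:
            intervals.append((i, j))
    letters = {g: "" for g in order}
    for letter_idx, (i, j) in enumerate(intervals):
        ch = chr(ord("a") + letter_idx)
        for l in range(i, j + 1):
            letters[order[l]] += ch
    return letters


# ---------------------------------------------------------------------------
# PCA

class ColonizationPCA:
    """PCA ordination of colonization parameters.

    Works on the correlation matrix (standardized variables) since the
    parameters mix percentages and a ratio.  Rows with missing values in
    the chosen parameters are dropped; constant parameters are dropped with
    a warning.
    """

    def __init__(self, table: pd.DataFrame, parameters=PARAMETERS):
        data = table[list(parameters)].dropna()
        if len(data) < 3:
            raise ValueError("PCA needs at least 3 complete observations")
        constant = [c for c in data.columns if data[c].nunique() <= 1]
        if constant:
            warnings.warn(
                f"dropping constant parameter(s) {constant} from PCA",
                stacklevel=2,
            )
            data = data.drop(columns=constant)
        if data.shape[1] < 2:
            raise ValueError("PCA needs at least 2 non-constant parameters")
        self.data = data
        self.dropped = constant

    def fit(self) -> "PcaResults":
        X = self.data.to_numpy(dtype=float)
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        corr = np.corrcoef(Z, rowvar=False)
        eigval, eigvec = np.linalg.eigh(corr)
        order = np.argsort(eigval)[::-1]
        eigval = np.clip(eigval[order], 0.0, None)  # rank deficiency -> 0% axes
        eigvec = eigvec[:, order]
        # deterministic sign: largest-magnitude loading positive per axis
        for j in range(eigvec.shape[1]):
            i = np.argmax(np.abs(eigvec[:, j]))
            if eigvec[i, j] < 0:
                eigvec[:, j] *= -1
        axes = [f"PC{i + 1}" for i in range(len(eigval))]
        loadings = pd.DataFrame(eigvec, index=self.data.columns, columns=axes)
        scores = pd.DataFrame(Z @ eigvec, index=self.data.index, columns=axes)
        explained = pd.Series(100.0 * eigval / eigval.sum(), index=axes)
        return PcaResults(loadings, scores, explained, tuple(self.dropped))


@dataclass
class PcaResults:
    """Loadings, scores and percent variance per axis."""

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained: pd.Series
    dropped: tuple[str, ...] = ()

    def summary(self) -> str:
        lines = ["PCA of colonization parameters (correlation matrix)"]
        lines.append(
            "  variance explained: "
            + ", ".join(f"{a} {v:.1f}%" for a, v in self.explained.items())
        )
        lines.append(
            f"  first two axes jointly: {self.explained.iloc[:2].sum():.1f}%"
        )
        if self.dropped:
            lines.append(f"  dropped constant parameters: {list(self.dropped)}")
        return "\n".join(lines)


def pca(table: pd.DataFrame, parameters=PARAMETERS) -> PcaResults:
    """Correlation-matrix PCA of the chosen parameters."""
    return ColonizationPCA(table, parameters).fit()
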
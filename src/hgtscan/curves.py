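"""Cross-species threshold justification.

The foreignness threshold on the HGT index is justified by comparing species:
for each species, the survival curve pct(h) gives the percentage of matched
transcripts with index >= h, and the ratio statistic

    R(h) = pct_1(h) / pct_2(h)

plateaus once h exceeds the value at which truly metazoan transcripts have
been excluded; raising the threshold past the plateau onset only discards
genuinely foreign sequences at the same rate in both species.  The
length-controlled models (logistic regression of the foreign call, and an
ANCOVA on the signed square-root of h) check that between-species
differences are not artifacts of contig-length differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

DEFAULT_GRID = np.arange(-200, 201)


@dataclass
class SurvivalCurve:
    """Percentage of matched transcripts with HGT index >= h, over a grid."""

    species: str
    grid: np.ndarray
    pct: np.ndarray
    n: int

    def at(self, h: float) -> float:
        idx = np.nonzero(self.grid == h)[0]
        if idx.size == 0:
            raise KeyError(f"h={h} not on grid")
        return float(self.pct[idx[0]])


@dataclass
class RCurve:
    """Pointwise ratio of two survival curves; undefined where pct_2 = 0."""

    species: tuple[str, str]
    grid: np.ndarray
    ratio: np.ndarray          # NaN where undefined
    defined: np.ndarray        # boolean mask

    def at(self, h: float) -> float:
        idx = np.nonzero(self.grid == h)[0]
        if idx.size == 0:
            raise KeyError(f"h={h} not on grid")
        return float(self.ratio[idx[0]])

    def plateau(self, window: tuple[float, float] = (30.0, 100.0)) -> tuple[float, float]:
        """Mean and sd of R over a window of the grid (defined points only)."""
        mask = (self.grid >= window[0]) & (self.grid <= window[1]) & self.defined
        vals = self.ratio[mask]
        if vals.size == 0:
            return float("nan"), float("nan")
        return float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0


def survival_curve(
    h_values: Sequence[float],
    species: str = "",
    grid: np.ndarray | None = None,
) -> SurvivalCurve:
    """Exact-count survival curve: pct(h) = 100 * #{i : h_i >= h} / n."""
    h = np.asarray(h_values, dtype=float)
    if h.size == 0:
        raise ValueError("survival_curve requires at least one h value")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    sorted_h = np.sort(h)
    # count of values >= g, via position of g in the sorted sample
    counts = h.size - np.searchsorted(sorted_h, grid, side="left")
    return SurvivalCurve(species, grid, 100.0 * counts / h.size, int(h.size))


def r_curve(curve1: SurvivalCurve, curve2: SurvivalCurve) -> RCurve:
    """Pointwise R(h) = pct_1(h) / pct_2(h); undefined points are NaN-flagged."""
    if curve1.grid.shape != curve2.grid.shape or np.any(curve1.grid != curve2.grid):
        raise ValueError("survival curves must share a grid")
    defined = curve2.pct > 0
    ratio = np.full_like(curve1.pct, np.nan)
    ratio[defined] = curve1.pct[defined] / curve2.pct[defined]
    return RCurve((curve1.species, curve2.species), curve1.grid, ratio, defined)


@dataclass
class GlmResult:
    """Logistic regression of the foreign call on species and length."""

    model: object
    coef: pd.Series
    pvalues: pd.Series
    predicted: pd.DataFrame
    separation: bool = False


def hgt_glm(
    records: pd.DataFrame,
    theta: float | None = None,
    reference_species: str | None = None,
) -> GlmResult:
    """Binomial GLM: P(foreign) ~ species + contig length.

    ``records`` needs columns (species, length) and either a binary
    ``foreign`` column or an ``h`` column with ``theta`` given.  Returns the
    fit plus, per species, the predicted probability at the extremes of that
    species' observed length range.  Complete separation is reported on the
    result rather than failing silently.
    """
    df = records.copy()
    if "foreign" not in df.columns:
        if theta is None:
            raise ValueError("need a 'foreign' column or theta to derive it from h")
        df["foreign"] = (df["h"] >= theta).astype(int)
    df["foreign"] = df["foreign"].astype(int)
    if df["species"].nunique() < 2:
        raise ValueError("need records from at least two species")
    if reference_species is not None:
        cats = [reference_species] + sorted(
            s for s in df["species"].unique() if s != reference_species
        )
        df["species"] = pd.Categorical(df["species"], categories=cats)
    separation = False
    try:
        fit = smf.glm(
            "foreign ~ C(species) + length", data=df,
            family=sm.families.Binomial(),
        ).fit()
        if not np.all(np.isfinite(fit.bse)) or np.any(fit.bse > 1e3):
            separation = True
    except Exception:
        # perfect separation can make IRLS blow up entirely
        raise
    rows = []
    for species, sub in df.groupby("species", observed=True):
        lo, hi = sub["length"].min(), sub["length"].max()
        pred = fit.predict(
            pd.DataFrame({"species": [species, species], "length": [lo, hi]})
        )
        rows.append((species, lo, hi, float(pred.iloc[0]), float(pred.iloc[1])))
    predicted = pd.DataFrame(
        rows, columns=["species", "length_min", "length_max", "p_at_min", "p_at_max"]
    )
    return GlmResult(fit, fit.params, fit.pvalues, predicted, separation)


def signed_sqrt(h):
    """The variance-stabilising transform used for the ANCOVA: sign(h)*sqrt(|h|)."""
    h = np.asarray(h, dtype=float)
    return np.sign(h) * np.sqrt(np.abs(h))


@dataclass
class AncovaResult:
    """Linear model of transformed h on length and species."""

    model: object
    coef: pd.Series
    anova: pd.DataFrame
    variance_explained: dict[str, float] = field(default_factory=dict)


def hgt_ancova(records: pd.DataFrame, reference_species: str | None = None) -> AncovaResult:
    """ANCOVA: sign(h)*sqrt(|h|) ~ length + species.

    Variance shares are sequential (type-I) sums of squares with length
    entered first, reported as percent of total.
    """
    df = records.copy()
    df["response"] = signed_sqrt(df["h"])
    if float(np.var(df["response"])) == 0.0:
        raise ValueError("zero-variance response: all transformed h equal")
    if reference_species is not None:
        cats = [reference_species] + sorted(
            s for s in df["species"].unique() if s != reference_species
        )
        df["species"] = pd.Categorical(df["species"], categories=cats)
    fit = smf.ols("response ~ length + C(species)", data=df).fit()
    # sequential (type-I) sums of squares, length entered first: patsy
    # reorders terms in anova_lm, so build the decomposition from nested fits
    fit_len = smf.ols("response ~ length", data=df).fit()
    tss = float(np.sum((df["response"] - df["response"].mean()) ** 2))
    ss_length = tss - fit_len.ssr
    ss_species = fit_len.ssr - fit.ssr
    table = pd.DataFrame(
        {
            "df": [1.0, df["species"].nunique() - 1.0, fit.df_resid],
            "sum_sq": [ss_length, ss_species, fit.ssr],
        },
        index=["length", "C(species)", "Residual"],
    )
    shares = {
        "length": 100.0 * ss_length / tss,
        "species": 100.0 * ss_species / tss,
    }
    return AncovaResult(fit, fit.params, table, shares)


def curves_frame(curves: Sequence[SurvivalCurve]) -> pd.DataFrame:
    """Long-format table of survival curves (species, h, pct)."""
    return pd.concat(
        [
            pd.DataFrame({"species": c.species, "h": c.grid, "pct": c.pct})
            for c in curves
        ],
        ignore_index=True,
    )
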
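"""Biodegradability regression and treatment/matrix comparisons.

The central model is an ordinary least-squares multilinear regression of the
min-max normalized 4-day respiration index on the normalized carbohydrate
and polymer guild activities,

    RI4_norm = b0 + b_carb * Carbohydrates_norm + b_poly * Polymers_norm + eps,

reported with coefficient p-values, adjusted R^2 and n. Group comparisons
follow the conventional sequence: Levene (variance homogeneity) and Shapiro
(normality) prechecks, one-way ANOVA with Tukey HSD post-hoc and a compact
letter display between the three treatments at the final campaign, and
rank-sum (Mann-Whitney/Wilcoxon) tests between solid and leachate samples at
each time point with star encoding (*** p<0.001, ** p<0.01, * p<0.05).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "RI4Model",
    "ComparisonResult",
    "fit_ri4_model",
    "anova_prechecks",
    "anova_tukey",
    "wilcoxon_solid_vs_leachate",
    "p_to_stars",
    "compact_letter_display",
]


@dataclass(frozen=True)
class RI4Model:
    """Fitted biodegradability regression on normalized [0, 1] scales."""

    beta0: float
    beta_carb: float
    beta_poly: float
    adj_r2: float
    p_values: Mapping[str, float]
    std_errors: Mapping[str, float]
    n: int

    def predict(self, carb: np.ndarray, poly: np.ndarray) -> np.ndarray:
        return self.beta0 + self.beta_carb * np.asarray(carb) + self.beta_poly * np.asarray(poly)

    def summary_text(self) -> str:
        lines = [
            "Multilinear biodegradability model (normalized scales)",
            f"  RI4_norm = {self.beta0:.4g} + {self.beta_carb:.4g} * Carbohydrates "
            f"+ {self.beta_poly:.4g} * Polymers",
            f"  n = {self.n}, adjusted R^2 = {self.adj_r2:.4g}",
            "  term          coef        se          p",
        ]
        for term, coef in (
            ("intercept", self.beta0),
            ("carbohydrates", self.beta_carb),
            ("polymers", self.beta_poly),
        ):
            lines.append(
                f"  {term:<13} {coef:>9.4g}  {self.std_errors[term]:>9.3g}  "
                f"{self.p_values[term]:>9.3g}"
            )
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ComparisonResult:
    test: str  # anova_tukey | wilcoxon | levene | shapiro
    grouping: str
    statistic: float
    p_value: float
    encoding: str = ""  # letters or stars


def fit_ri4_model(model_frame: pd.DataFrame) -> RI4Model:
    """OLS of normalized RI4 on normalized carbohydrate/polymer activities.

    ``model_frame`` needs one row per sample with columns ``carbohydrates``,
    ``polymers`` and ``ri4`` already on their normalized scales. Fewer than
    4 rows is refused (2 covariates + intercept leave no residual degree of
    freedom).
    """
    n = len(model_frame)
    if n < 4:
        raise ValueError(f"need at least 4 samples to fit 2 covariates + intercept, got {n}")
    X = sm.add_constant(model_frame[["carbohydrates", "polymers"]].to_numpy())
    fit = sm.OLS(model_frame["ri4"].to_numpy(), X).fit()
    terms = ("intercept", "carbohydrates", "polymers")
    return RI4Model(
        beta0=float(fit.params[0]),
        beta_carb=float(fit.params[1]),
        beta_poly=float(fit.params[2]),
        adj_r2=float(fit.rsquared_adj),
        p_values=dict(zip(terms, map(float, fit.pvalues))),
        std_errors=dict(zip(terms, map(float, fit.bse))),
        n=n,
    )


def p_to_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compact_letter_display(
    groups: list[str], nonsig_pairs: set[tuple[str, str]]
) -> dict[str, str]:
    """Letters such that two groups share a letter iff their pair is in
    ``nonsig_pairs`` (not significantly different).

    Greedy clique cover of the non-significance graph -- exact for the
    handful of groups a treatment comparison has.
    """
    adj = {g: {g} for g in groups}
    for a, b in nonsig_pairs:
        adj[a].add(b)
        adj[b].add(a)
    # all maximal cliques, largest first (brute force; #groups is tiny)
    cliques: list[set[str]] = []
    for size in range(len(groups), 0, -1):
        for combo in itertools.combinations(sorted(groups), size):
            cs = set(combo)
            if all(cs <= adj[g] for g in combo) and not any(cs <= c for c in cliques):
                cliques.append(cs)
    letters: dict[str, str] = {g: "" for g in groups}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for idx, c in enumerate(sorted(cliques, key=lambda c: sorted(c))):
        for g in sorted(c):
            letters[g] += alphabet[idx]
    return letters


def anova_prechecks(
    table: pd.DataFrame, value_col: str, group_col: str = "treatment"
) -> list[ComparisonResult]:
    """Levene (across groups) and Shapiro (per group) before an ANOVA.

    A constant group makes Shapiro undefined; it is reported with p=NaN
    rather than raised -- degenerate data should surface, not crash.
    """
    out: list[ComparisonResult] = []
    grouped = [
        (name, grp[value_col].dropna().to_numpy())
        for name, grp in table.groupby(group_col, sort=True)
    ]
    arrays = [a for _, a in grouped if len(a) >= 2]
    if len(arrays) >= 2:
        stat, p = stats.levene(*arrays)
        out.append(ComparisonResult("levene", f"across {group_col}", float(stat), float(p)))
    for name, a in grouped:
        if len(a) >= 3 and np.ptp(a) > 0:
            stat, p = stats.shapiro(a)
            out.append(ComparisonResult("shapiro", f"{group_col}={name}", float(stat), float(p)))
        else:
            out.append(ComparisonResult("shapiro", f"{group_col}={name}", float("nan"), float("nan")))
    return out


def anova_tukey(
    table: pd.DataFrame,
    value_col: str,
    group_col: str = "treatment",
    alpha: float = 0.05,
) -> tuple[ComparisonResult, dict[str, str]]:
    """One-way ANOVA plus Tukey HSD with a compact letter display.

    Returns the ANOVA result and a letters dict; groups sharing a letter
    are not significantly different at ``alpha``.
    """
    d = table.dropna(subset=[value_col])
    names = sorted(d[group_col].unique())
    arrays = [d.loc[d[group_col] == g, value_col].to_numpy() for g in names]
    if any(len(a) < 2 for a in arrays) or len(arrays) < 2:
        raise ValueError("anova_tukey needs >= 2 groups with >= 2 observations each")
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        # all observations identical: F = 0 by convention, nothing differs
        anova = ComparisonResult("anova_tukey", group_col, 0.0, 1.0, "")
        letters = {g: "a" for g in names}
        return anova, letters
    f, p = stats.f_oneway(*arrays)
    tk = pairwise_tukeyhsd(d[value_col].to_numpy(), d[group_col].to_numpy(), alpha=alpha)
    nonsig = set()
    res = tk.summary().data[1:]
    for row in res:
        g1, g2, reject = str(row[0]), str(row[1]), bool(row[-1])
        if not reject:
            nonsig.add((g1, g2))
    letters = compact_letter_display(names, nonsig)
    anova = ComparisonResult(
        "anova_tukey", group_col, float(f), float(p), " ".join(f"{g}:{letters[g]}" for g in names)
    )
    return anova, letters


def wilcoxon_solid_vs_leachate(
    scaled_table: pd.DataFrame, value_col: str = "scaled"
) -> pd.DataFrame:
    """Rank-sum test solid vs leachate per (day, guild) with star encoding.

    Exact null distribution when both sides have n <= 10 and no ties;
    normal approximation with tie correction otherwise (scipy's automatic
    policy). Cells with fewer than 2 observations on a side are reported
    with missing p.
    """
    rows = []
    for (day, group), cell in scaled_table.groupby(["day", "group"], sort=True):
        solid = cell.loc[cell["matrix"] == "solid", value_col].dropna().to_numpy()
        leach = cell.loc[cell["matrix"] == "leachate", value_col].dropna().to_numpy()
        if len(solid) < 2 or len(leach) < 2:
            rows.append(dict(day=day, group=group, statistic=np.nan, p_value=np.nan, stars=""))
            continue
        stat, p = stats.mannwhitneyu(solid, leach, alternative="two-sided", method="auto")
        rows.append(
            dict(day=day, group=group, statistic=float(stat), p_value=float(p),
                 stars=p_to_stars(float(p)))
        )
    return pd.DataFrame(rows)
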
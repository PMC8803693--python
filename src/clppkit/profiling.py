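"""Substrate-guild aggregation, baseline scaling and min-max normalization.

Per-substrate activity integrals are summed into the five guild activities
("Carbohydrates", "Polymers", ... -- the regression covariates). For display
over time, each reactor's guild series is divided by its own day-0 value
(so every series starts at 1). For the regression, every variable is
min-max normalized onto [0, 1] over the modeling cohort:

    x_norm = (x - min(x)) / (max(x) - min(x))
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from clppkit.plate_io import GROUP_NAMES, META_COLS, SubstrateCatalog, default_catalog

__all__ = [
    "aggregate_groups",
    "scale_to_baseline",
    "minmax_normalize",
    "group_summary",
]

log = logging.getLogger(__name__)


def aggregate_groups(
    auc_table: pd.DataFrame, catalog: SubstrateCatalog | None = None
) -> pd.DataFrame:
    """Sum per-substrate AUCs into guild activities, 5 rows per sample.

    Every sample must carry an AUC for each of the 31 catalog substrates;
    a missing substrate is a hard error (silent zeros would bias the sums).
    """
    catalog = catalog or default_catalog()
    expected = set(catalog.names)
    problems = []
    for sid, grp in auc_table.groupby("sample_id"):
        missing = expected - set(grp["substrate"])
        if missing:
            problems.append(f"{sid}: missing {sorted(missing)[:5]}")
        extra = set(grp["substrate"]) - expected
        if extra:
            problems.append(f"{sid}: unknown {sorted(extra)[:5]}")
    if problems:
        raise ValueError("incomplete substrate coverage:\n  " + "\n  ".join(problems))

    t = auc_table.copy()
    t["group"] = t["substrate"].map(dict(catalog.entries))
    keys = META_COLS + (["imputed"] if "imputed" in t.columns else []) + ["group"]
    out = t.groupby(keys, sort=True)["auc"].sum().rename("activity").reset_index()
    # enforce deterministic guild order within each sample
    out["group"] = pd.Categorical(out["group"], categories=GROUP_NAMES, ordered=True)
    out = out.sort_values(META_COLS + ["group"]).reset_index(drop=True)
    out["group"] = out["group"].astype(str)
    return out


def scale_to_baseline(group_table: pd.DataFrame) -> pd.DataFrame:
    """Divide each reactor x guild series by its own day-0 activity.

    Day-0 rows scale to exactly 1. A zero (or absent) baseline leaves that
    series' scaled values missing, with a warning -- a ratio to zero carries
    no information.
    """
    t = group_table.copy()
    base = (
        t[t["day"] == 0]
        .set_index(["reactor_id", "matrix", "group"])["activity"]
        .rename("baseline")
    )
    t = t.join(base, on=["reactor_id", "matrix", "group"])
    bad = (t["baseline"] == 0) | t["baseline"].isna()
    if bad.any():
        n = t.loc[bad, ["reactor_id", "group"]].drop_duplicates().shape[0]
        log.warning("scale_to_baseline: %d series with zero/absent day-0 baseline -> NaN", n)
    t["scaled"] = np.where(bad, np.nan, t["activity"] / t["baseline"])
    return t.drop(columns="baseline")


def minmax_normalize(
    table: pd.DataFrame, value_col: str, variable_col: str = "variable"
) -> pd.DataFrame:
    """Min-max normalize ``value_col`` onto [0, 1] within each variable.

    The cohort is whatever rows are passed in. A variable with fewer than
    two distinct values cannot be normalized (zero range) and is a hard
    error. Affine-invariant: normalize(a*x + b) == normalize(x) for a > 0.
    """
    t = table.copy()
    g = t.groupby(variable_col)[value_col]
    lo, hi = g.transform("min"), g.transform("max")
    span = hi - lo
    degenerate = t.loc[span == 0, variable_col].unique()
    if len(degenerate):
        raise ValueError(f"constant variable(s), cannot normalize: {sorted(map(str, degenerate))}")
    t["x_norm"] = (t[value_col] - lo) / span
    return t


def group_summary(
    scaled_table: pd.DataFrame,
    by: tuple[str, ...] = ("treatment", "day", "group"),
    value_col: str = "scaled",
) -> pd.DataFrame:
    """Mean, standard error (sd/sqrt(n)) and n per grouping cell.

    With the study design, grouping by (day, group) pools all reactors
    sampled that day (n=9 at day 0, n=6 on days 57-358) while
    (treatment, day, group) splits the final campaign into n=3 cells.
    """
    g = scaled_table.dropna(subset=[value_col]).groupby(list(by), sort=True)[value_col]
    out = g.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="size").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] == 1, "se"] = np.nan
    return out.drop(columns="sd")
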
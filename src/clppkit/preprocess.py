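"""Cleaning of raw well readings into kinetic curves.

The fixed order of operations is: subtract the per-sample blank mean at each
read time, set negative corrected values to 0, then average the technical
replicates. Clipping before averaging is deliberate (it is not the same as
averaging first); a switch on :func:`clean_plate` allows the alternative
order for sensitivity checks.

One missing solid sample per treatment x day cell may be imputed as the
element-wise mean of the present reactors' curves (per substrate, per time).
Leachate samples are never imputed; they simply stay missing.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from clppkit.plate_io import BLANK, META_COLS, REACTORS_BY_TREATMENT

__all__ = [
    "subtract_blank",
    "clip_negatives",
    "average_replicates",
    "impute_missing_sample",
    "clean_plate",
    "CleaningReport",
]

log = logging.getLogger(__name__)

#: Curve-table value column (blank-corrected, replicate-averaged OD590).
OD_COL = "od"


class CleaningReport(dict):
    """Counts of clipped values, imputed samples and dropped readings."""


def subtract_blank(readings: pd.DataFrame) -> pd.DataFrame:
    """Subtract each sample's mean blank OD at the matching read time.

    The blank mean is taken over the (up to three) blank replicates of the
    same sample at the same ``time_h``. Blank rows are consumed: the result
    contains only substrate wells. A substrate reading with no blank at its
    time point is a hard error -- blanks are never interpolated.
    """
    is_blank = readings["substrate"] == BLANK
    blanks = readings[is_blank]
    wells = readings[~is_blank]
    if blanks.empty:
        raise ValueError("no blank wells (substrate == 'BLANK') in input")
    bmean = (
        blanks.groupby(["sample_id", "time_h"])["od590"]
        .mean()
        .rename("blank_mean")
        .reset_index()
    )
    merged = wells.merge(bmean, on=["sample_id", "time_h"], how="left")
    miss = merged["blank_mean"].isna()
    if miss.any():
        bad = merged.loc[miss, ["sample_id", "time_h"]].drop_duplicates()
        raise ValueError(
            "missing blank reading(s) for: "
            + "; ".join(f"{r.sample_id} @ {r.time_h} h" for r in bad.itertuples())
        )
    merged["od590"] = merged["od590"] - merged["blank_mean"]
    return merged.drop(columns="blank_mean")


def clip_negatives(readings: pd.DataFrame) -> pd.DataFrame:
    """Replace negative blank-corrected OD values by exactly 0.

    The number of clipped values is logged and stored in
    ``result.attrs['n_clipped']``.
    """
    out = readings.copy()
    neg = out["od590"] < 0
    out.loc[neg, "od590"] = 0.0
    n = int(neg.sum())
    if n:
        log.info("clip_negatives: set %d negative value(s) to 0", n)
    out.attrs["n_clipped"] = n
    return out


def average_replicates(readings: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates into one curve per (sample, substrate).

    Returns a long curve table with columns ``META_COLS + [substrate,
    time_h, od, n_replicates_used]``. A time point with zero usable
    replicates is simply absent from the curve (warned upstream).
    """
    keys = META_COLS + ["substrate", "time_h"]
    grouped = readings.groupby(keys, sort=True)["od590"]
    out = grouped.mean().rename(OD_COL).reset_index()
    out["n_replicates_used"] = grouped.count().to_numpy()
    out["imputed"] = False
    return out


def impute_missing_sample(
    curves: pd.DataFrame,
    expected_reactors: Mapping[str, tuple[int, ...]] | None = None,
) -> pd.DataFrame:
    """Fill in at most one missing solid sample per treatment x day cell.

    For a treatment x day cell of solid samples where exactly one of the
    expected reactors is absent and at least two donors are present, a
    synthetic sample is appended whose OD at each (substrate, time) is the
    mean of the donors' values, flagged ``imputed=True``. With fewer than
    two donors the cell is left as-is (logged). Leachate samples are never
    imputed.

    ``expected_reactors`` maps treatment -> reactor ids; by default the
    canonical 3-reactors-per-treatment design.
    """
    expected_reactors = expected_reactors or REACTORS_BY_TREATMENT
    solids = curves[curves["matrix"] == "solid"]
    added = []
    for (tr, day), cell in solids.groupby(["treatment", "day"]):
        present = set(cell["reactor_id"].unique())
        expected = set(expected_reactors[tr])
        missing = expected - present
        if not missing:
            continue
        if len(present) < 2 or len(missing) != 1:
            log.warning(
                "impute_missing_sample: %s day %s: %d reactor(s) missing, "
                "%d donor(s) present -> left missing",
                tr, day, len(missing), len(present),
            )
            continue
        (lost,) = missing
        donor_mean = (
            cell.groupby(["substrate", "time_h"])
            .agg(od=(OD_COL, "mean"), n_replicates_used=("n_replicates_used", "min"))
            .reset_index()
        )
        donor_mean["sample_id"] = f"IMP-{tr}-d{day}-solid"
        donor_mean["reactor_id"] = lost
        donor_mean["treatment"] = tr
        donor_mean["day"] = day
        donor_mean["matrix"] = "solid"
        donor_mean["imputed"] = True
        added.append(donor_mean[curves.columns])
        log.info("impute_missing_sample: imputed reactor %d, %s day %s (solid)", lost, tr, day)
    if not added:
        return curves
    return pd.concat([curves, *added], ignore_index=True)


def clean_plate(
    readings: pd.DataFrame,
    impute: bool = True,
    clip_before_average: bool = True,
) -> pd.DataFrame:
    """Full cleaning chain: subtract -> clip -> average [-> impute].

    ``clip_before_average=False`` averages the signed corrected values first
    and clips the means instead, for sensitivity analysis only.
    """
    corrected = subtract_blank(readings)
    if clip_before_average:
        curves = average_replicates(clip_negatives(corrected))
    else:
        curves = average_replicates(corrected)
        curves[OD_COL] = curves[OD_COL].clip(lower=0.0)
    if impute:
        curves = impute_missing_sample(curves)
    return curves
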
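"""End-to-end orchestration: cleaning -> kinetics -> profiling -> inference.

`run_pipeline` is the library entry point the CLI wraps: it takes a
validated plate table (and optionally an RI4 table), runs every stage with
one configuration object, and returns all intermediate and final tables
plus the fitted biodegradability model. All stages are deterministic; the
only randomness in the package lives in the synthetic generator's seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

try:
    from importlib.metadata import version as _dist_version

    _pkg_version = _dist_version("clppkit")
except Exception:  # uninstalled source tree
    _pkg_version = "0+unknown"
from clppkit.inference import (
    RI4Model,
    anova_prechecks,
    anova_tukey,
    fit_ri4_model,
    wilcoxon_solid_vs_leachate,
)
from clppkit.kinetics import KineticsOptions, fit_table, success_bookkeeping
from clppkit.plate_io import write_results
from clppkit.preprocess import clean_plate
from clppkit.profiling import (
    aggregate_groups,
    group_summary,
    minmax_normalize,
    scale_to_baseline,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "result_tables", "make_manifest"]


@dataclass(frozen=True)
class PipelineConfig:
    kinetics: KineticsOptions = field(default_factory=KineticsOptions)
    impute: bool = True
    clip_before_average: bool = True
    #: samples entering the regression cohort: 'solid' (default) or 'all'
    cohort: str = "solid"
    #: min-max normalize the RI4 response as well as the covariates
    normalize_response: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        kin_keys = {f: raw.pop(f) for f in list(raw) if f in KineticsOptions.__dataclass_fields__}
        known = {f: raw.pop(f) for f in list(raw) if f in cls.__dataclass_fields__}
        if raw:
            raise ValueError(f"unknown config key(s): {sorted(raw)}")
        return cls(kinetics=KineticsOptions(**kin_keys), **known)


@dataclass
class PipelineResult:
    curves: pd.DataFrame
    fits: pd.DataFrame
    success_table: pd.DataFrame
    group_activity: pd.DataFrame
    scaled: pd.DataFrame
    summary: pd.DataFrame
    normalized: pd.DataFrame | None
    model_frame: pd.DataFrame | None
    model: RI4Model | None
    comparisons: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


def build_model_frame(
    group_activity: pd.DataFrame,
    ri4_table: pd.DataFrame,
    cohort: str = "solid",
    normalize_response: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the normalized regression frame.

    Returns (long normalized table, wide model frame). Activities are merged
    with RI4 records on (reactor_id, day, matrix) so an imputed plate sample
    still pairs with its independently measured respiration index. Min-max
    normalization runs within the selected cohort; the response is
    normalized too unless ``normalize_response`` is off.
    """
    wide = group_activity.pivot_table(
        index=["sample_id", "reactor_id", "treatment", "day", "matrix"],
        columns="group", values="activity",
    ).reset_index()
    merged = wide.merge(
        ri4_table[["reactor_id", "day", "matrix", "ri4"]],
        on=["reactor_id", "day", "matrix"], how="inner",
    )
    if cohort == "solid":
        merged = merged[merged["matrix"] == "solid"]
    elif cohort != "all":
        raise ValueError(f"unknown cohort {cohort!r}")
    merged = merged.sort_values("sample_id").reset_index(drop=True)

    long = merged.melt(
        id_vars=["sample_id"], value_vars=["carbohydrates", "polymers", "ri4"],
        var_name="variable", value_name="value",
    )
    normed = minmax_normalize(long, "value")
    frame = normed.pivot(index="sample_id", columns="variable", values="x_norm").reset_index()
    if not normalize_response:
        frame = frame.drop(columns="ri4").merge(merged[["sample_id", "ri4"]], on="sample_id")
    return normed, frame


def _comparisons(scaled: pd.DataFrame, has_leachate: bool) -> pd.DataFrame:
    rows: list[dict] = []
    solids = scaled[(scaled["matrix"] == "solid") & scaled["scaled"].notna()]
    if solids.empty:
        return pd.DataFrame(
            columns=["test", "grouping", "statistic", "p_value", "encoding"]
        )
    final_day = int(solids["day"].max())
    final = solids[solids["day"] == final_day]
    for group, cell in final.groupby("group", sort=True):
        enough = cell.groupby("treatment")["scaled"].count()
        if len(enough) < 2 or (enough < 2).any():
            continue
        for res in anova_prechecks(cell, "scaled"):
            rows.append(dict(test=res.test, grouping=f"day {final_day}/{group}/{res.grouping}",
                             statistic=res.statistic, p_value=res.p_value, encoding=""))
        anova, letters = anova_tukey(cell, "scaled")
        rows.append(dict(test="anova_tukey", grouping=f"day {final_day}/{group}",
                         statistic=anova.statistic, p_value=anova.p_value,
                         encoding=anova.encoding))
    if has_leachate:
        wx = wilcoxon_solid_vs_leachate(scaled[scaled["scaled"].notna()])
        for r in wx.itertuples():
            rows.append(dict(test="wilcoxon", grouping=f"day {r.day}/{r.group}",
                             statistic=r.statistic, p_value=r.p_value, encoding=r.stars))
    return pd.DataFrame(rows)


def run_pipeline(
    plate: pd.DataFrame,
    ri4_table: pd.DataFrame | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run every stage on a validated plate table."""
    warnings: list[str] = []
    curves = clean_plate(plate, impute=config.impute,
                         clip_before_average=config.clip_before_average)
    fits = fit_table(curves, config.kinetics)
    success = success_bookkeeping(fits)
    groups = aggregate_groups(fits)
    scaled = scale_to_baseline(groups)
    summary = group_summary(scaled)
    has_leachate = bool((plate["matrix"] == "leachate").any())
    comparisons = _comparisons(scaled, has_leachate)

    normalized = model_frame = model = None
    if ri4_table is not None:
        normalized, model_frame = build_model_frame(
            groups, ri4_table, config.cohort, config.normalize_response
        )
        model = fit_ri4_model(model_frame)
    return PipelineResult(
        curves=curves, fits=fits, success_table=success, group_activity=groups,
        scaled=scaled, summary=summary, normalized=normalized,
        model_frame=model_frame, model=model, comparisons=comparisons,
        warnings=warnings,
    )


def result_tables(result: PipelineResult) -> dict[str, pd.DataFrame | str]:
    """Output tables in the canonical file layout for write_results."""
    auc_cols = [c for c in result.fits.columns if c != "auc_spline"]
    tables: dict[str, pd.DataFrame | str] = {
        "auc_per_substrate.csv": result.fits[auc_cols],
        "group_activity.csv": result.group_activity,
        "scaled_activity.csv": result.scaled,
        "success_table.csv": result.success_table,
        "group_summary.csv": result.summary,
        "comparisons.csv": result.comparisons,
    }
    if result.normalized is not None:
        tables["normalized.csv"] = result.normalized
    if result.model is not None:
        tables["ri4_model.txt"] = result.model.summary_text()
    return tables


def make_manifest(
    inputs: dict[str, Path],
    outputs: list[Path],
    config: PipelineConfig,
    result: PipelineResult,
    seed: int | None = None,
) -> dict:
    """Run manifest: config snapshot, input/output digests, row counts."""

    def digest(p: Path) -> str:
        return hashlib.sha256(p.read_bytes()).hexdigest()

    return {
        "version": _pkg_version,
        "seed": seed,
        "config": {
            "kinetics": result_config_dict(config.kinetics),
            "impute": config.impute,
            "clip_before_average": config.clip_before_average,
            "cohort": config.cohort,
            "normalize_response": config.normalize_response,
        },
        "inputs": {name: digest(p) for name, p in inputs.items()},
        "outputs": {p.name: digest(p) for p in outputs},
        "row_counts": {
            "curves": len(result.curves),
            "fits": len(result.fits),
            "group_activity": len(result.group_activity),
            "comparisons": len(result.comparisons),
        },
        "warnings": result.warnings,
    }


def result_config_dict(opts: KineticsOptions) -> dict:
    return {f: getattr(opts, f) for f in KineticsOptions.__dataclass_fields__}


def write_pipeline_outputs(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    return write_results(result_tables(result), out_dir)


def manifest_to_json(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
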
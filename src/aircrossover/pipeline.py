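"""End-to-end orchestration: enumerate the model grid, fit every cell,
assemble matrices and summaries, and write the output bundle.

The full default design fits one single-lag, single-pollutant conditional
Poisson model per (chapter, stratum, pollutant, lag) cell: with 8 pollutants,
18 strata and lags 0-14 that is 2160 models per disease chapter and 25,920
over the 12 ICD-10 chapters.  Outputs are a flat results CSV (one row per
fitted model), per-chapter binary matrices, per-pollutant summed matrices,
a counting summary, a two-threshold persistence report and diagnostics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate
from .exposure import ExposureSeries, read_daily_csv
from .matrices import (AssociationMatrix, build_binary_matrix, sum_matrices,
                       count_summaries, persistence_ratio, export_heatmap)
from .model import (build_dataset, fit_conditional_poisson, relative_risk,
                    DataError, NotIdentifiedError)
from .simulate import SimulationConfig, CountSeries
from .strata import enumerate_patient_strata

logger = logging.getLogger(__name__)

DEFAULT_POLLUTANTS = ("CO", "NO2", "O3", "O3H8", "PM25", "SO2", "AQHI", "AQHIX")

#: ICD-10 chapter code ranges analysed collectively as outcome groups.
DEFAULT_CHAPTERS = (
    "A00-B99", "F00-F99", "G00-G99", "H00-H59", "H60-H95", "I00-I99",
    "J00-J99", "K00-K93", "L00-L99", "M00-M99", "N00-N99", "S00-T98",
)


class PipelineError(RuntimeError):
    pass


@dataclass
class AnalysisConfig:
    pollutants: tuple = DEFAULT_POLLUTANTS
    chapters: tuple = DEFAULT_CHAPTERS
    lags: tuple = tuple(range(15))
    spline_df: int = 3
    p_thresholds: tuple = (0.05, 0.001)
    rr_increment: str | float = "iqr"   # "iqr" or a fixed concentration step
    output_dir: str = "output"
    seed: int = 0
    simulation: SimulationConfig | None = None
    pollutant_path: str | None = None
    weather_path: str | None = None
    counts_path: str | None = None

    def validate(self) -> None:
        if not self.pollutants:
            raise PipelineError("pollutant list is empty")
        if not self.chapters:
            raise PipelineError("chapter list is empty")
        if not all(0 <= l <= 14 for l in self.lags):
            raise PipelineError("lags must lie in [0, 14]")
        if self.simulation is None and not (
                self.pollutant_path and self.weather_path and self.counts_path):
            raise PipelineError(
                "either a simulation config or input paths are required")


def enumerate_model_grid(config: AnalysisConfig) -> list[tuple]:
    """Deterministic list of (chapter, pollutant, stratum label, lag) cells.

    Order is chapter-major, then pollutant, stratum, lag; with defaults each
    chapter contributes 8 x 18 x 15 = 2160 cells.
    """
    config.validate()
    labels = [s.label for s in enumerate_patient_strata()]
    return [
        (ch, pol, lbl, lag)
        for ch in config.chapters
        for pol in config.pollutants
        for lbl in labels
        for lag in config.lags
    ]


def _simulate_inputs(config: AnalysisConfig):
    """Generate exposures, weather and per-(chapter, stratum) counts."""
    sim = config.simulation
    pollutants = simulate.compute_indices(simulate.simulate_pollutants(sim))
    weather = simulate.simulate_weather(sim)
    eff_series = pollutants.get(sim.effect.pollutant)
    if eff_series is None:
        raise PipelineError(
            f"effect pollutant {sim.effect.pollutant} not simulated")
    counts = {}
    for k, chapter in enumerate(config.chapters):
        # Independent count streams per chapter, same planted effect.
        ch_cfg = dataclasses.replace(sim, seed=sim.seed + 10_000 * (k + 1))
        ch_counts = simulate.simulate_counts(ch_cfg, eff_series, weather)
        ch_counts.chapter = chapter
        for lbl, cs in simulate.split_counts_by_strata(ch_cfg, ch_counts).items():
            cs.chapter = chapter
            counts[(chapter, lbl)] = cs
    return pollutants, weather, counts


def _load_inputs(config: AnalysisConfig):
    pollutants = read_daily_csv(config.pollutant_path)
    weather = pd.read_csv(config.weather_path, index_col="date",
                          parse_dates=True)
    raw = pd.read_csv(config.counts_path, index_col="date", parse_dates=True)
    counts = {}
    for chapter in config.chapters:
        for col in raw.columns:
            # Columns either "<stratum>" (single chapter) or "<chapter>|<stratum>".
            if "|" in col:
                ch, lbl = col.split("|", 1)
                if ch != chapter:
                    continue
            else:
                lbl = col
            counts[(chapter, lbl)] = CountSeries(chapter, lbl, raw[col])
    return pollutants, weather, counts


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Fit every grid cell and write the full output bundle.

    Returns a dict with the results table, matrices, summary and diagnostics.
    Cells that cannot be fitted (sparse strata, non-identification) are
    logged skips contributing 0 to the matrices, not errors: sparse subgroups
    are a real feature of stratified ED-visit data.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        pollutants, weather, counts = _simulate_inputs(config)
    else:
        pollutants, weather, counts = _load_inputs(config)

    p_main = config.p_thresholds[0]
    labels = [s.label for s in enumerate_patient_strata()]
    rows = []
    skips = []
    results_by_cell = {}
    for chapter in config.chapters:
        for pol in config.pollutants:
            exp_series = pollutants[pol]
            if config.rr_increment == "iqr":
                vals = exp_series.data.dropna()
                increment = float(vals.quantile(0.75) - vals.quantile(0.25))
            else:
                increment = float(config.rr_increment)
            for lbl in labels:
                cs = counts.get((chapter, lbl))
                if cs is None:
                    skips.append((chapter, pol, lbl, "all", "no counts"))
                    continue
                for lag in config.lags:
                    cell = (chapter, pol, lbl, lag)
                    try:
                        data = build_dataset(cs, exp_series, weather, lag,
                                             spline_df=config.spline_df)
                        res = fit_conditional_poisson(data)
                    except (DataError, NotIdentifiedError) as exc:
                        skips.append((chapter, pol, lbl, lag, str(exc)))
                        continue
                    results_by_cell[cell] = res
                    rr = (relative_risk(res, increment)
                          if res.converged and increment > 0 else
                          {"rr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                           "increment": increment})
                    rows.append({
                        "chapter": chapter, "pollutant": pol, "stratum": lbl,
                        "lag": lag, "beta": res.beta, "se": res.se,
                        "p_value": res.p_value, "rr": rr["rr"],
                        "rr_ci_low": rr["ci_low"], "rr_ci_high": rr["ci_high"],
                        "rr_increment": rr["increment"],
                        "n_rows": res.n_rows, "n_strata": res.n_strata,
                        "converged": res.converged,
                    })

    results = pd.DataFrame(rows)
    results.to_csv(outdir / "results.csv", index=False)

    # Binary matrices per (chapter, pollutant) and summed per pollutant.
    binary = {}
    summed = {}
    persistence = []
    matdir = outdir / "matrices"
    matdir.mkdir(exist_ok=True)
    for pol in config.pollutants:
        per_chapter = []
        for chapter in config.chapters:
            grid = {(lbl, lag): results_by_cell.get((chapter, pol, lbl, lag))
                    for lbl in labels for lag in config.lags}
            m = build_binary_matrix(grid, pol, chapter_id=chapter,
                                    p_threshold=p_main,
                                    row_labels=tuple(labels),
                                    lags=tuple(config.lags))
            binary[(chapter, pol)] = m
            m.to_frame().rename_axis("stratum").to_csv(
                matdir / f"binary_{pol}_{chapter}.csv")
            per_chapter.append(m)
        s = sum_matrices(per_chapter, expected=len(config.chapters))
        summed[pol] = s
        export_heatmap(s, matdir / f"summed_{pol}")

        counts_by_thr = []
        for thr in config.p_thresholds:
            n = sum(
                build_binary_matrix(
                    {(lbl, lag): results_by_cell.get((chapter, pol, lbl, lag))
                     for lbl in labels for lag in config.lags},
                    pol, chapter_id=chapter, p_threshold=thr,
                    row_labels=tuple(labels), lags=tuple(config.lags)).total()
                for chapter in config.chapters)
            counts_by_thr.append(n)
        persistence.append({
            "pollutant": pol,
            f"n_p{config.p_thresholds[0]}": counts_by_thr[0],
            f"n_p{config.p_thresholds[1]}": counts_by_thr[1],
            "persistence_pct": persistence_ratio(counts_by_thr[0],
                                                 counts_by_thr[1]),
        })

    summary = count_summaries(summed)
    summary.rename_axis("stratum").to_csv(outdir / "summary.csv")
    persistence_df = pd.DataFrame(persistence)
    persistence_df.to_csv(outdir / "persistence.csv", index=False)

    diagnostics = {
        "n_cells_planned": len(enumerate_model_grid(config)),
        "n_fitted": len(rows),
        "n_skipped": len(skips),
        "n_nonconverged": int((~results["converged"]).sum()) if len(rows) else 0,
        "skips": [list(map(str, s)) for s in skips[:200]],
    }
    (outdir / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2))
    run_log = {
        "seed": config.seed,
        "config": _jsonable_config(config),
        "rng": simulate.RNG_NAME,
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2))
    return {
        "results": results, "binary": binary, "summed": summed,
        "summary": summary, "persistence": persistence_df,
        "diagnostics": diagnostics,
    }


def _jsonable_config(config: AnalysisConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.simulation is not None:
        d["simulation"] = simulate._config_to_jsonable(config.simulation)
    return d
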
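"""End-to-end orchestration: simulate -> rgb -> spectral -> cwsi ->
bioristor -> cross-scale statistics.

Each stage is a plain function over a :class:`FieldDataset` so the numbered
analysis drivers, the CLI and the tests all exercise exactly the same code.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .bioristor import compute_response, daily_smooth, minmax_normalize, treatment_divergence
from .containers import records_to_frame
from .errors import ValidationError
from .io import PipelineConfig
from .rgb import summarize_plot_rgb
from .spectral import segment_vegetation, spectral_records
from .stats import (CorrelationMatrix, TukeyResult, align_observations,
                    anova_tukey, build_report, correlation_matrix, summary_stats)
from .synthetic import FieldDataset, SimConfig, simulate_field
from .thermal import (CWSIBaseline, cwsi_plot_means, fit_baseline,
                      vapor_pressure_deficit)

__all__ = ["PipelineResult", "run_pipeline", "process_rgb",
           "process_spectral_thermal", "process_bioristor",
           "build_observations", "CORRELATION_VARIABLES"]

#: variables entering the pooled cross-scale correlation matrix
CORRELATION_VARIABLES = ["rwc", "spad", "r", "csi", "ga", "gga", "cwsi",
                         "ndvi", "gndvi", "ndre"]

YIELD_TRAITS = ("marketable", "unripen", "rotten", "total")


@dataclass
class PipelineResult:
    dataset: FieldDataset
    rgb_indices: pd.DataFrame
    spectral_indices: pd.DataFrame
    cwsi: pd.DataFrame
    masks: dict                       # (plot_id, dat) -> segmentation mask
    baseline: CWSIBaseline
    bioristor_daily: pd.DataFrame     # per trace per day
    bioristor_plot_daily: pd.DataFrame  # per plot per day (replicate mean)
    divergence_dat: Optional[int]
    divergence_p: pd.Series
    observations: pd.DataFrame
    correlation: CorrelationMatrix
    tukey: list[TukeyResult]
    yield_summary: pd.DataFrame
    report: dict


def process_rgb(dataset: FieldDataset,
                config: Optional[PipelineConfig] = None) -> pd.DataFrame:
    """Colour indices for every plot photo, ordered by (plot_id, DAT)."""
    config = config or PipelineConfig()
    records = [
        summarize_plot_rgb(img, plot_id, dat,
                           ga_range=config.ga_range, gga_range=config.gga_range)
        for (plot_id, dat), img in sorted(dataset.rgb.items())
    ]
    return records_to_frame(records)


def process_spectral_thermal(
    dataset: FieldDataset,
    config: Optional[PipelineConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict, CWSIBaseline]:
    """Segment every plot raster, then extract vegetation-index and CWSI
    plot means.

    Returns (spectral table, cwsi table, masks, baseline used).  The CWSI
    baseline is either the configured (a, b) pair or an OLS fit on the
    well-watered reference treatment's (Tc - Ta, VPD) observations.
    """
    config = config or PipelineConfig()
    masks = {}
    spec_records, mean_tc = [], {}
    for (plot_id, dat), raster in sorted(dataset.bands.items()):
        thermal = dataset.thermal[(plot_id, dat)]
        mask = segment_vegetation(
            raster, thermal if config.use_thermal_in_segmentation else None,
            k=config.kmeans_k, seed=config.seed)
        masks[(plot_id, dat)] = mask
        plot = next(p for p in dataset.plots if p.plot_id == plot_id)
        spec_records.extend(spectral_records(raster, mask, [plot], dat))
        tc = thermal.tc[mask]
        mean_tc[(plot_id, dat)] = float(tc.mean()) if tc.size else np.nan

    if config.fit_baseline_from_reference:
        ref = config.fit_baseline_reference_treatment
        obs_y, obs_x = [], []
        for (plot_id, dat), tc in mean_tc.items():
            if dataset.treatment_of(plot_id) != ref or not np.isfinite(tc):
                continue
            ta, rh = dataset.flight_meteo(dat)
            obs_y.append(tc - ta)
            obs_x.append(vapor_pressure_deficit(ta, rh))
        baseline = fit_baseline(obs_y, obs_x)
    else:
        baseline = CWSIBaseline(config.cwsi_baseline_a, config.cwsi_baseline_b)

    cwsi_records = []
    for (plot_id, dat), thermal in sorted(dataset.thermal.items()):
        plot = next(p for p in dataset.plots if p.plot_id == plot_id)
        ta, rh = dataset.flight_meteo(dat)
        cwsi_records.extend(
            cwsi_plot_means(thermal, masks[(plot_id, dat)], [plot], dat,
                            ta, rh, baseline))
    return (records_to_frame(spec_records), records_to_frame(cwsi_records),
            masks, baseline)


def process_bioristor(
    dataset: FieldDataset,
    config: Optional[PipelineConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, Optional[int], pd.Series]:
    """Response, daily smoothing, normalization and treatment divergence.

    Returns (per-trace daily table, per-plot daily table with normalized R,
    divergence onset DAT or None, per-day ANOVA p-values).
    """
    config = config or PipelineConfig()
    t0 = dataset.config.transplant_date
    rows = []
    for trace in dataset.traces:
        r = compute_response(trace)
        daily = daily_smooth(r, config.smoothing_window_hours, t0)
        treatment = dataset.treatment_of(trace.plot_id)
        for dat, val in daily.items():
            rows.append({"plot_id": trace.plot_id,
                         "trace_id": f"{trace.plot_id}#r{trace.replicate}",
                         "treatment": treatment, "dat": int(dat),
                         "r": float(val)})
    trace_daily = pd.DataFrame(rows)
    if trace_daily.empty:
        raise ValidationError("dataset contains no bioristor traces")

    onset, pvals = treatment_divergence(
        trace_daily, alpha=config.divergence_alpha,
        consecutive=config.divergence_consecutive_days)

    plot_daily = (trace_daily.groupby(["plot_id", "treatment", "dat"],
                                      as_index=False)["r"].mean())
    mode = config.normalization_mode
    if mode == "global":
        plot_daily["r_norm"] = minmax_normalize(plot_daily["r"])
    else:
        by = "plot_id" if mode == "per_plant" else "treatment"
        plot_daily["r_norm"] = (plot_daily.groupby(by)["r"]
                                .transform(lambda s: minmax_normalize(s)))
    return trace_daily, plot_daily, onset, pvals


def build_observations(
    dataset: FieldDataset,
    rgb_indices: pd.DataFrame,
    spectral_indices: pd.DataFrame,
    cwsi_table: pd.DataFrame,
    plot_daily: pd.DataFrame,
    config: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """Join all per-plot/per-date observations into one table keyed by
    (plot_id, DAT)."""
    config = config or PipelineConfig()
    r_at_dates = (plot_daily[plot_daily["dat"].isin(dataset.config.dates)]
                  [["plot_id", "dat", "r_norm"]]
                  .rename(columns={"r_norm": "r"}))
    sources = {
        "physio": dataset.physio[["plot_id", "dat", "rwc", "spad"]],
        "bioristor": r_at_dates,
        "rgb": rgb_indices[["plot_id", "dat", "ga", "gga", "csi"]],
        "spectral": spectral_indices[["plot_id", "dat", "ndvi", "gndvi", "ndre"]],
        "thermal": cwsi_table[["plot_id", "dat", "cwsi"]],
    }
    return align_observations(sources, tolerance=config.date_tolerance_days)


def run_pipeline(
    sim_config: Optional[SimConfig] = None,
    config: Optional[PipelineConfig] = None,
    dataset: Optional[FieldDataset] = None,
) -> PipelineResult:
    """Run the full multiscale analysis on a (simulated) trial."""
    config = config or PipelineConfig()
    if dataset is None:
        sim_kwargs = dict(config.sim)
        if sim_config is None:
            sim_config = SimConfig(seed=config.seed, **sim_kwargs)
        dataset = simulate_field(sim_config)

    rgb_indices = process_rgb(dataset, config)
    spectral_indices, cwsi_table, masks, baseline = process_spectral_thermal(
        dataset, config)
    trace_daily, plot_daily, onset, pvals = process_bioristor(dataset, config)
    observations = build_observations(dataset, rgb_indices, spectral_indices,
                                      cwsi_table, plot_daily, config)
    variables = [v for v in CORRELATION_VARIABLES if v in observations.columns]
    corr = correlation_matrix(observations, variables)
    tukey = [anova_tukey(dataset.yields, t, alpha=config.tukey_alpha)
             for t in YIELD_TRAITS]
    ysum = summary_stats(dataset.yields)

    report = build_report(
        {"rgb_indices": rgb_indices, "spectral_indices": spectral_indices,
         "cwsi": cwsi_table, "bioristor_daily": plot_daily,
         "observations": observations, "correlation": corr, "tukey": tukey,
         "yield_summary": ysum, "divergence_dat": onset,
         "config": dataclasses.asdict(config)},
        seed=config.seed, version=__version__)
    return PipelineResult(
        dataset=dataset, rgb_indices=rgb_indices,
        spectral_indices=spectral_indices, cwsi=cwsi_table, masks=masks,
        baseline=baseline, bioristor_daily=trace_daily,
        bioristor_plot_daily=plot_daily, divergence_dat=onset,
        divergence_p=pvals, observations=observations, correlation=corr,
        tukey=tukey, yield_summary=ysum, report=report)
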
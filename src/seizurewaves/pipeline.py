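"""Orchestration: coherence -> delays -> plane waves -> interval summaries.

``run_analysis`` applies the full estimation chain to one recording pair
(microarray, optional macro grid); ``run_experiment`` repeats a simulation
scenario over seeds and pools pre-seizure versus seizure statistics the way
the figure-level comparisons do (the seizure group pools the Early, Middle
and Late per-run values, so group sizes are n and 3n).  ``export_report``
writes figure-ready CSV bundles plus a manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coherence import CoherenceEngine, MultitaperParams, band_average_coherence
from .model import ModelParams, SimConfig, SimResult, run_simulation
from .recordings import (
    INTERVALS,
    AnalysisWindow,
    ElectrodeLayout,
    Recording,
    assign_interval,
    make_windows,
)
from .waves import (
    DelayEstimate,
    IntervalSummary,
    PlaneWaveFit,
    build_delay_map,
    coherence_vs_distance,
    delay_series,
    direction_consistency,
    direction_difference,
    fit_plane,
    group_test,
    summarize_intervals,
)

log = logging.getLogger("seizurewaves")

__all__ = [
    "AnalysisParams",
    "AnalysisResult",
    "ExperimentResult",
    "central_electrode",
    "merge_recordings",
    "run_analysis",
    "run_experiment",
    "export_report",
]


@dataclass(frozen=True)
class AnalysisParams:
    """Thresholds and bands of the estimation chain."""

    multitaper: MultitaperParams = MultitaperParams()
    band: tuple[float, float] = (1.0, 13.0)
    min_band: float = 3.0
    window_length: float = 10.0
    window_step: float = 1.0
    pre_duration: float = 60.0
    robust: bool = True
    n_closest_macros: int = 30
    bootstrap: int = 1000
    bootstrap_seed: int = 0


@dataclass
class AnalysisResult:
    """Tables produced by one analysis run."""

    windows: list[AnalysisWindow]
    wave_table: pd.DataFrame              # one row per window x scale
    fits: dict[str, list[PlaneWaveFit]]   # per scale
    interval_summaries: dict[str, dict[str, IntervalSummary]]
    coherence_table: pd.DataFrame         # pair band-average coherence
    distance_regressions: pd.DataFrame
    direction_differences: pd.DataFrame


def central_electrode(layout: ElectrodeLayout) -> str:
    """Electrode closest to the array centroid (the delay reference)."""
    centroid = layout.positions.mean(axis=0)
    d = np.linalg.norm(layout.positions - centroid, axis=1)
    return layout.ids[int(np.argmin(d))]


def merge_recordings(a: Recording, b: Recording) -> Recording:
    """Stack two simultaneous recordings into one mixed-scale recording."""
    if a.rate != b.rate or a.n_samples != b.n_samples:
        raise ValueError("recordings must share rate and length")
    if set(a.layout.ids) & set(b.layout.ids):
        raise ValueError("electrode ids collide between recordings")
    layout = ElectrodeLayout(
        ids=a.layout.ids + b.layout.ids,
        scale="mixed",
        positions=np.vstack([a.layout.positions, b.layout.positions]),
    )
    return Recording(
        samples=np.hstack([a.samples, b.samples]),
        rate=a.rate, onset=a.onset, offset=a.offset, layout=layout, t0=a.t0,
        meta={**b.meta, **a.meta},
    )


def _plane_fits(
    delay_maps: list, layout: ElectrodeLayout, scale: str, robust: bool
) -> list[PlaneWaveFit]:
    fits = []
    for dm in delay_maps:
        f = fit_plane(dm, layout, robust=robust)
        f.scale = scale
        fits.append(f)
    return fits


def _wave_rows(fits: list[PlaneWaveFit], scale: str) -> list[dict]:
    return [
        {
            "window_start": f.window.start,
            "normalized_time": f.window.normalized_time,
            "scale": scale,
            "b0": f.b0, "b1": f.b1, "b2": f.b2,
            "fit_p": f.fit_p, "n_defined": f.n_defined, "n_total": f.n_total,
            "speed_mm_s": f.speed,
            "source_direction_rad": f.source_direction,
            "valid": f.valid,
        }
        for f in fits
    ]


def run_analysis(
    micro: Recording,
    macro: Recording | None = None,
    params: AnalysisParams = AnalysisParams(),
) -> AnalysisResult:
    """Full estimation chain on a microarray recording (+ optional macros).

    Micro scale: group delays of every microelectrode against the central
    microelectrode, plane fit over the array per window.  Macro scale (when
    ``macro`` is given): each macroelectrode's delay is the mean over its
    defined micro-pair delays (the closest ``n_closest_macros`` macros),
    plane fit over macro positions.  Also emits band-averaged coherence per
    pair, per-interval coherence-versus-distance regressions, interval
    summaries and micro-macro direction differences.
    """
    pre = min(params.pre_duration, micro.onset - micro.t0)
    windows = make_windows(
        micro, length=params.window_length, step=params.window_step,
        pre_duration=pre,
    )
    nt = [w.normalized_time for w in windows]

    # ---- micro scale ----------------------------------------------------
    ref = central_electrode(micro.layout)
    eng = CoherenceEngine(micro, windows, params.multitaper)
    micro_delay: dict[tuple[str, str], list[DelayEstimate]] = {}
    coh_rows = []
    for other in micro.layout.ids:
        if other == ref:
            continue
        cg = eng.coherogram(ref, other, cache_b=False)
        micro_delay[(ref, other)] = delay_series(cg, params.band, params.min_band)
        bac = band_average_coherence(cg, params.band)
        d = micro.layout.distance(ref, other)
        for w, win in enumerate(windows):
            coh_rows.append({
                "pair": f"{ref}-{other}", "kind": "micro",
                "window_start": win.start, "normalized_time": nt[w],
                "distance_mm": d, "band_coherence": bac[w],
            })
    micro_maps = [
        build_delay_map(
            {pr: ests[w] for pr, ests in micro_delay.items()},
            windows[w], "micro", ref,
        )
        for w in range(len(windows))
    ]
    fits: dict[str, list[PlaneWaveFit]] = {}
    fits["micro"] = _plane_fits(micro_maps, micro.layout, "micro", params.robust)

    # ---- macro scale ----------------------------------------------------
    dd_rows: list[dict] = []
    if macro is not None:
        mea_center = micro.layout.positions.mean(axis=0)
        dist_to_mea = np.linalg.norm(
            macro.layout.positions - mea_center, axis=1
        )
        keep = np.argsort(dist_to_mea)[: params.n_closest_macros]
        macro_ids = [macro.layout.ids[i] for i in keep]
        merged = merge_recordings(micro, macro)
        eng2 = CoherenceEngine(merged, windows, params.multitaper)
        macro_delay: dict[tuple[str, str], list[DelayEstimate]] = {}
        for m in micro.layout.ids:
            for M in macro_ids:
                cg = eng2.coherogram(m, M)
                macro_delay[(m, M)] = delay_series(
                    cg, params.band, params.min_band
                )
                bac = band_average_coherence(cg, params.band)
                d = np.linalg.norm(
                    merged.layout.positions[merged.layout.index(m)]
                    - merged.layout.positions[merged.layout.index(M)]
                )
                for w, win in enumerate(windows):
                    coh_rows.append({
                        "pair": f"{m}-{M}", "kind": "inter",
                        "window_start": win.start, "normalized_time": nt[w],
                        "distance_mm": d, "band_coherence": bac[w],
                    })
        macro_maps = [
            build_delay_map(
                {pr: ests[w] for pr, ests in macro_delay.items()},
                windows[w], "macro", "MEA",
            )
            for w in range(len(windows))
        ]
        fits["macro"] = _plane_fits(
            macro_maps, macro.layout, "macro", params.robust
        )
        for fm, fM in zip(fits["micro"], fits["macro"]):
            if fm.valid and fM.valid:
                dd_rows.append({
                    "window_start": fm.window.start,
                    "normalized_time": fm.window.normalized_time,
                    "direction_difference_rad": direction_difference(
                        fm.source_direction, fM.source_direction
                    ),
                })

    # ---- tables ----------------------------------------------------------
    wave_rows = []
    for scale, fl in fits.items():
        wave_rows.extend(_wave_rows(fl, scale))
    wave_table = pd.DataFrame(wave_rows)
    coherence_table = pd.DataFrame(coh_rows)

    summaries = {
        scale: summarize_intervals(
            fl, n_boot=params.bootstrap, rng=params.bootstrap_seed
        )
        for scale, fl in fits.items()
    }

    dr_rows = []
    if len(coherence_table):
        kind = "inter" if macro is not None else "micro"
        sub = coherence_table[coherence_table["kind"] == kind]
        for name in INTERVALS:
            m = sub["normalized_time"].map(
                lambda t: name in assign_interval(t)
            )
            per_pair = (
                sub[m].groupby("pair")
                .agg(distance_mm=("distance_mm", "first"),
                     band_coherence=("band_coherence", "mean"))
            )
            if len(per_pair) >= 3 and per_pair["distance_mm"].nunique() > 1:
                reg = coherence_vs_distance(
                    per_pair["distance_mm"].values,
                    per_pair["band_coherence"].values,
                    interval=name,
                )
                dr_rows.append(asdict(reg))
    distance_regressions = pd.DataFrame(dr_rows)

    return AnalysisResult(
        windows=windows,
        wave_table=wave_table,
        fits=fits,
        interval_summaries=summaries,
        coherence_table=coherence_table,
        distance_regressions=distance_regressions,
        direction_differences=pd.DataFrame(dd_rows),
    )


@dataclass
class ExperimentResult:
    """Pooled statistics over repeated simulations of one scenario."""

    scenario: str
    seeds: list[int]
    per_run: pd.DataFrame          # one row per run x interval
    group_tests: pd.DataFrame      # Pre vs pooled seizure comparisons
    analyses: list[AnalysisResult] = field(default_factory=list)
    sims: list[SimResult] = field(default_factory=list)

    def interval_mean(self, column: str, interval: str) -> float:
        sub = self.per_run[self.per_run["interval"] == interval]
        return float(sub[column].mean())


def run_experiment(
    scenario: str,
    n_seeds: int = 10,
    base_config: SimConfig | None = None,
    model_params: ModelParams = ModelParams(),
    analysis_params: AnalysisParams = AnalysisParams(),
    base_seed: int = 0,
    include_macro: bool = False,
    keep_sims: bool = False,
    progress: bool = False,
) -> ExperimentResult:
    """Repeat a scenario over seeds, analyse each run and pool statistics.

    Per run and interval the table records the valid-wave count, direction
    consistency and mean speed on the virtual microarray.  The group test
    compares the Pre values against the pooled Early/Middle/Late values
    (group sizes n and 3n), two-sided t-test, uncorrected.
    """
    if base_config is None:
        base_config = SimConfig.reduced()
    seeds = [int(base_seed + i) for i in range(n_seeds)]
    rows, analyses, sims = [], [], []
    for i, seed in enumerate(seeds):
        cfg = SimConfig(**{**asdict(base_config),
                           "scenario": scenario, "seed": seed})
        t_start = time.time()
        sim = run_simulation(cfg, model_params)
        res = run_analysis(
            sim.micro, sim.macro if include_macro else None, analysis_params
        )
        if progress:
            print(
                f"[{scenario}] seed {seed}: "
                f"{time.time() - t_start:5.1f} s, "
                f"{int(res.wave_table['valid'].sum())} valid fits",
                flush=True,
            )
        for name, summ in res.interval_summaries["micro"].items():
            rows.append({
                "scenario": scenario, "seed": seed, "interval": name,
                "n_waves": summ.n_waves,
                "direction_consistency": summ.direction_consistency,
                "mean_speed": summ.mean_speed,
            })
        analyses.append(res)
        if keep_sims:
            sims.append(sim)
    per_run = pd.DataFrame(rows)

    tests = []
    if n_seeds >= 2:
        for col in ("direction_consistency", "mean_speed", "n_waves"):
            pre = per_run[per_run["interval"] == "Pre"][col].to_numpy(float)
            sz = per_run[
                per_run["interval"].isin(["Early", "Middle", "Late"])
            ][col].to_numpy(float)
            pre_ok = pre[np.isfinite(pre)]
            sz_ok = sz[np.isfinite(sz)]
            if len(pre_ok) >= 2 and len(sz_ok) >= 2:
                p = group_test(pre_ok, sz_ok)
            else:
                p = np.nan
            tests.append({
                "statistic": col, "n_pre": len(pre_ok), "n_sz": len(sz_ok),
                "p_value": p,
            })
    else:
        log.info("single seed: group test skipped")
    return ExperimentResult(
        scenario=scenario, seeds=seeds, per_run=per_run,
        group_tests=pd.DataFrame(tests), analyses=analyses, sims=sims,
    )


def export_report(
    result: AnalysisResult | ExperimentResult,
    out_dir: str | Path,
    manifest_extra: dict | None = None,
) -> Path:
    """Write figure-ready CSV bundles plus a JSON manifest; returns out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software_version": __version__,
        "written": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "tables": {},
        "missing": [],
    }
    if manifest_extra:
        manifest.update(manifest_extra)

    def _write(df: pd.DataFrame, name: str) -> None:
        if df is None or len(df) == 0:
            manifest["missing"].append(name)
            return
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        manifest["tables"][name] = {"rows": int(len(df))}

    if isinstance(result, AnalysisResult):
        _write(result.wave_table, "wave_table")
        _write(result.coherence_table, "coherence_by_distance")
        _write(result.distance_regressions, "distance_regressions")
        _write(result.direction_differences, "direction_differences")
        summ_rows = [
            {"scale": scale, "interval": s.interval, "n_waves": s.n_waves,
             "direction_consistency": s.direction_consistency,
             "mean_speed": s.mean_speed,
             "ci_consistency_lo": s.ci_consistency[0],
             "ci_consistency_hi": s.ci_consistency[1],
             "ci_speed_lo": s.ci_speed[0], "ci_speed_hi": s.ci_speed[1]}
            for scale, d in result.interval_summaries.items()
            for s in d.values()
        ]
        _write(pd.DataFrame(summ_rows), "interval_summaries")
    else:
        _write(result.per_run, "scenario_per_run")
        _write(result.group_tests, "scenario_group_tests")
        manifest["scenario"] = result.scenario
        manifest["seeds"] = result.seeds
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
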
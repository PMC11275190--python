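"""End-to-end analysis runs: simulate -> detrend -> detect -> summarise ->
dose-response -> harmonics -> neuromorphic abstraction -> complexity.

Every run is driven by a :class:`RunConfig` and a single global seed;
per-condition substreams are spawned deterministically, so two runs with the
same config produce byte-identical machine outputs (timestamps excluded —
none are embedded). Stage failures are wrapped in
:class:`~protospike.errors.PipelineStageError` naming the failing stage.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .complexity import binarize_matrix, normalized_lz
from .conditions import (BUILTIN_CONDITIONS, CURRENT_BASELINE_UA,
                         ConditionSpec)
from .detrend import BaselineDetrender
from .dose import build_report
from .errors import NoPeriodicityError, PipelineStageError
from .harmonics import HarmonicDecomposer
from .io import write_metrics_table, write_trace_csv
from .neuro import (binarize_current, cumulative_charge,
                    current_distribution_stats, init_weights)
from .spikes import SpikeDetector, summarize
from .synth import generate_condition_trace, generate_current_trace

logger = logging.getLogger("protospike")


@dataclass
class RunConfig:
    """Configuration for one end-to-end run."""

    conditions: list[ConditionSpec] = field(
        default_factory=lambda: list(BUILTIN_CONDITIONS.values()))
    n_spikes: int = 200
    baseline_degree: int = 3
    baseline_knot_spacing: float | None = None
    detect_refractory: float = 30.0
    k_max: int = 16
    n_neurons: int = 30
    current_duration: float = 600.0
    seed: int = 0
    out_dir: str | Path | None = None


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc
    return wrap


def _condition_seed(global_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([global_seed, index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and optionally writes) the bundle."""
    summaries = []
    harmonic_tables = {}
    neuro_results = {}
    traces = {}
    for idx, spec in enumerate(config.conditions):
        label = spec.label
        seed = spec.seed if spec.seed is not None \
            else _condition_seed(config.seed, idx)
        logger.info("[synthetic_data] generating %s (seed %d)", label, seed)
        trace, _events = _stage("synthetic_data")(
            generate_condition_trace, spec, config.n_spikes, seed=seed)
        traces[label] = trace
        logger.info("[baseline_detrend] detrending %s", label)
        detrender = _stage("baseline_detrend")(
            BaselineDetrender(degree=config.baseline_degree,
                              knot_spacing=config.baseline_knot_spacing).fit,
            trace)
        residual = detrender.transform(trace)
        logger.info("[spike_metrics] detecting spikes in %s", label)
        detector = _stage("spike_metrics")(
            SpikeDetector(refractory=config.detect_refractory).fit, residual)
        summaries.append(_stage("spike_metrics")(
            summarize, detector.events_, label))
        try:
            dec = HarmonicDecomposer(k_max=config.k_max).fit(residual)
            harmonic_tables[label] = [
                {"k": c.k, "amplitude": c.amplitude, "phase": c.phase,
                 "omega": c.omega} for c in dec.components_]
        except (NoPeriodicityError, ValueError) as exc:
            logger.info("[harmonics] skipped for %s: %s", label, exc)
            harmonic_tables[label] = None
        logger.info("[neuro_abstraction] current abstraction for %s", label)
        current = _stage("neuro_abstraction")(
            generate_current_trace, label, config.current_duration,
            seed=seed) if label in CURRENT_BASELINE_UA else None
        weights = _stage("neuro_abstraction")(
            init_weights, config.n_neurons, seed)
        wm_complexity = _stage("complexity")(
            normalized_lz, binarize_matrix(weights), f"{label} weight map")
        entry = {
            "weight_matrix_seed": seed,
            "weight_map_lz_raw": wm_complexity.raw_c,
            "weight_map_lz_normalized": wm_complexity.normalized,
        }
        if current is not None:
            code = binarize_current(current)
            charge = cumulative_charge(current)
            stats = current_distribution_stats(current)
            entry.update({
                "current_mean_uA": stats["mean"],
                "current_median_uA": stats["median"],
                "current_q1_uA": stats["q1"],
                "current_q3_uA": stats["q3"],
                "active_fraction": code.n_active / code.bits.size,
                "final_charge_uC": float(charge[-1]),
                "code_lz_raw": normalized_lz(code.bits).raw_c
                if code.bits.size >= 2 else None,
            })
        neuro_results[label] = entry
        if config.out_dir is not None:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            safe = label.replace("/", "-").replace(" ", "_")
            write_trace_csv(trace, out / f"trace_{safe}.csv")
            np.savetxt(out / f"weights_{safe}.csv", weights.W, delimiter=",")

    report = _stage("dose_response")(build_report, summaries,
                                     config.conditions[0].label)
    bundle = {
        "provenance": {
            "package": "protospike",
            "version": __version__,
            "seed": config.seed,
            "n_spikes": config.n_spikes,
            "n_neurons": config.n_neurons,
            "k_max": config.k_max,
        },
        "summaries": {
            s.condition: {
                "amplitude": vars(s.amplitude),
                "isi": vars(s.isi),
                "n_spikes": s.n_spikes,
                "sem_isi": s.sem_isi,
            } for s in summaries
        },
        "dose_response": report.to_dict(),
        "harmonics": harmonic_tables,
        "neuro": neuro_results,
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        write_metrics_table([s.amplitude for s in summaries],
                            out / "amplitude_metrics.csv")
        write_metrics_table([s.isi for s in summaries],
                            out / "isi_metrics.csv", value_decimals=2)
        (out / "report.json").write_text(
            json.dumps(bundle, indent=2, sort_keys=True, default=str))
        (out / "report.md").write_text(report.to_markdown())
    return bundle
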
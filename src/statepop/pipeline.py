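"""End-to-end orchestration: generate (or load) a cohort, run every analysis
stage, and write result tables plus a reproducibility manifest.

Stage order follows the analysis narrative: single-neuron state metrics,
cell-population coupling, subpopulation pooling vs behavior (including the
window sweep and both alignments), then population decoding with noise
correlations and the working-memory control.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    AnalysisConfig,
    SessionData,
    filter_trials,
    save_session,
    write_results,
)
from .coupling import coupling_profile, coupling_table
from .decoder import (
    decoder_table,
    noise_correlations,
    state_conditioned_decoding,
    target_memory_control,
)
from .pooling import PoolingCurve, aggregate_cohort, pooling_curve, window_sweep
from .state import median_split, minmax_normalize, state_metrics, window_counts
from .synthgen import GeneratorParams, generate_cohort

logger = logging.getLogger("statepop")


@dataclass
class RunManifest:
    """What a pipeline run produced, with config, seeds, and file hashes."""

    out_dir: str
    seed: int
    n_sessions: int
    table_rows: dict[str, int] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    files: dict = field(default_factory=dict)
    completed: bool = False


def _population_labels(session: SessionData, config: AnalysisConfig):
    pre = window_counts(session, config.alignment, config.window_offset_ms)
    trace = minmax_normalize(pre.astype(float)).mean(axis=1)
    return median_split(trace, source_neurons=tuple(range(session.n_neurons)))


def run_pipeline(
    gen_params: GeneratorParams,
    config: AnalysisConfig,
    out_dir: str | Path,
    n_sessions: int = 12,
    master_seed: int = 0,
    neuron_range: tuple[int, int] | None = None,
    decoder_sizes: tuple[int, ...] | None = None,
    save_bundles: bool = True,
) -> RunManifest:
    """Generate a cohort, run all stages, and write CSV tables + manifest."""
    out_dir = Path(out_dir)
    manifest = RunManifest(out_dir=str(out_dir), seed=master_seed, n_sessions=n_sessions)
    t0 = time.perf_counter()
    sessions = generate_cohort(gen_params, n_sessions, master_seed, neuron_range)
    if save_bundles:
        for s in sessions:
            save_session(s, out_dir / "sessions" / s.session_id)
    manifest.stage_seconds["generate"] = time.perf_counter() - t0

    filtered = [filter_trials(s, config) for s in sessions]

    tables: dict[str, pd.DataFrame] = {}

    t0 = time.perf_counter()
    tables["state_metrics"] = pd.concat(
        [state_metrics(s, config).assign(session_id=s.session_id) for s in filtered],
        ignore_index=True,
    )
    manifest.stage_seconds["state"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    coup = []
    for s in filtered:
        if s.n_neurons >= 3:
            coup.append(coupling_table(coupling_profile(s, config)).assign(
                session_id=s.session_id))
    tables["coupling"] = pd.concat(coup, ignore_index=True)
    manifest.stage_seconds["coupling"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    curves = [pooling_curve(s, config) for s in filtered]
    tables["pooling_curves"] = pd.concat(
        [c.to_table() for c in curves], ignore_index=True
    )
    summary = aggregate_cohort(curves, seed=master_seed)
    tables["pooling_cohort"] = summary.per_size
    sweep_rows = []
    for s in filtered:
        for off, delta in window_sweep(s, config).items():
            sweep_rows.append(
                {"session_id": s.session_id, "offset_ms": off, "behavior_delta_pct": delta}
            )
    tables["window_sweep"] = pd.DataFrame(sweep_rows)
    manifest.stage_seconds["pooling"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    dec, nc_rows = [], []
    for s in filtered:
        sizes = decoder_sizes or (1, 2, min(5, s.n_neurons), s.n_neurons)
        sizes = tuple(sorted({m for m in sizes if 1 <= m <= s.n_neurons}))
        dec.append(decoder_table(s.session_id, state_conditioned_decoding(s, config, sizes)))
        if s.n_neurons >= 2:
            nc = noise_correlations(s, _population_labels(s, config))
            nc_rows.append(
                {
                    "session_id": s.session_id,
                    "r_sc_low": nc.r_sc_low,
                    "r_sc_high": nc.r_sc_high,
                    "sem_low": nc.sem_low,
                    "sem_high": nc.sem_high,
                    "fraction_negative": nc.fraction_negative,
                }
            )
    tables["decoder"] = pd.concat(dec, ignore_index=True)
    tables["noise_correlations"] = pd.DataFrame(nc_rows)
    manifest.stage_seconds["decoder"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    mem_rows = []
    for s in filtered:
        mc = target_memory_control(s, config)
        mem_rows.append(
            {
                "session_id": s.session_id,
                "mean_accuracy": mc.mean_accuracy,
                "chance_low": mc.chance_band[0],
                "chance_high": mc.chance_band[1],
                "above_chance": mc.above_chance,
            }
        )
    tables["memory_control"] = pd.DataFrame(mem_rows)
    manifest.stage_seconds["memory_control"] = time.perf_counter() - t0

    files = write_results(
        tables,
        out_dir,
        config=config,
        seed=master_seed,
        extra_manifest={
            "generator_params": dataclasses.asdict(gen_params),
            "stage_seconds": manifest.stage_seconds,
            "pooling_summary": {
                "largest_common_size": summary.largest_common_size,
                "signed_rank_p": summary.signed_rank_p,
                "gap_small": summary.gap_small,
                "gap_large": summary.gap_large,
                "bootstrap_p": summary.bootstrap_p,
            },
        },
    )
    manifest.files = files["files"]
    manifest.table_rows = {k: int(len(v)) for k, v in tables.items()}
    manifest.completed = True
    return manifest


def session_gap_at_size(session: SessionData, config: AnalysisConfig, k: int = 5) -> float:
    """Low-minus-high session-normalized performance at one pool size."""
    curve = pooling_curve(session, config)
    k = min(k, int(curve.sizes.max()))
    return float(curve.gap()[curve.sizes == k][0])


def compare_conditions(
    sessions: list[SessionData],
    config: AnalysisConfig,
    contrasts: tuple[str, ...] = ("delay_mode", "delta_theta", "alignment"),
    pool_size: int = 5,
) -> pd.DataFrame:
    """Paired / grouped signed-rank comparisons of the low-vs-high behavioral
    gap across sessions, at a fixed pool size, for the requested contrasts:

    * ``delay_mode``  — fixed vs random delay sessions (rank-sum, unpaired);
    * ``delta_theta`` — the same sessions analyzed at filter 5 vs filter 10
      (paired signed-rank);
    * ``alignment``   — pre-test vs pre-target state labels (paired).
    """
    rows = []
    for contrast in contrasts:
        if contrast == "delay_mode":
            gaps = {"fixed": [], "random": []}
            for s in sessions:
                mode = s.trials[0].delay_mode
                gaps[mode].append(session_gap_at_size(filter_trials(s, config), config, pool_size))
            if not gaps["fixed"] or not gaps["random"]:
                logger.warning("delay_mode contrast skipped: one level missing")
                continue
            p = float(stats.mannwhitneyu(gaps["fixed"], gaps["random"]).pvalue)
            rows.append(
                {
                    "contrast": "delay_mode",
                    "level_a": "fixed",
                    "level_b": "random",
                    "gap_a": float(np.mean(gaps["fixed"])),
                    "gap_b": float(np.mean(gaps["random"])),
                    "p_value": p,
                }
            )
        elif contrast == "delta_theta":
            cfg5 = dataclasses.replace(config, delta_theta_filter=5.0)
            cfg10 = dataclasses.replace(config, delta_theta_filter=10.0)
            g5, g10 = [], []
            for s in sessions:
                try:
                    g5.append(session_gap_at_size(filter_trials(s, cfg5), cfg5, pool_size))
                    g10.append(session_gap_at_size(filter_trials(s, cfg10), cfg10, pool_size))
                except Exception:  # too few hard trials in a session
                    continue
            if len(g5) < 2:
                logger.warning("delta_theta contrast skipped: too few sessions")
                continue
            diff = np.array(g5) - np.array(g10)
            p = 1.0 if np.allclose(diff, 0) else float(stats.wilcoxon(g5, g10).pvalue)
            rows.append(
                {
                    "contrast": "delta_theta",
                    "level_a": "filter_5",
                    "level_b": "filter_10",
                    "gap_a": float(np.mean(g5)),
                    "gap_b": float(np.mean(g10)),
                    "p_value": p,
                }
            )
        elif contrast == "alignment":
            cfg_test = dataclasses.replace(config, alignment="pre_test")
            cfg_targ = dataclasses.replace(config, alignment="pre_target")
            gt, gg = [], []
            for s in sessions:
                f = filter_trials(s, config)
                gt.append(session_gap_at_size(f, cfg_test, pool_size))
                gg.append(session_gap_at_size(f, cfg_targ, pool_size))
            diff = np.array(gt) - np.array(gg)
            p = 1.0 if np.allclose(diff, 0) else float(stats.wilcoxon(gt, gg).pvalue)
            rows.append(
                {
                    "contrast": "alignment",
                    "level_a": "pre_test",
                    "level_b": "pre_target",
                    "gap_a": float(np.mean(gt)),
                    "gap_b": float(np.mean(gg)),
                    "p_value": p,
                }
            )
        else:
            raise ValueError(f"unknown contrast {contrast!r}")
    return pd.DataFrame(rows)
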
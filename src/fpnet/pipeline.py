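"""End-to-end orchestration: simulate -> preprocess -> GC -> networks -> stats.

Every stage's outputs are written under one run directory together with a
manifest (config echo, seeds, row counts, exercised decision counters) from
which the run is fully re-derivable.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .design import SourceTimeSeries
from .metrics import metric_series
from .network import binarize_networks, conditional_gc_table, window_gc_table
from .preprocess import bandpass_filter, baseline_correct
from .stats import format_phase_table, per_window_anova, phase_band_table
from .storage import write_cohort, write_gc_table, write_manifest, write_networks
from .synth import Cohort, generate_cohort

__all__ = ["PipelineResult", "preprocess_cohort", "run_pipeline"]


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    outdir: Path
    cohort: Cohort
    gc_table: pd.DataFrame
    networks: dict
    series: pd.DataFrame
    anova: dict
    phase_tables: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def preprocess_cohort(cohort: Cohort, filter_band: tuple[float, float]) -> tuple[Cohort, dict]:
    """Bandpass + baseline-correct every trial in place of the raw cohort."""
    groups: dict[str, dict[str, list[SourceTimeSeries]]] = {}
    n = 0
    for group, subjects in cohort.groups.items():
        groups[group] = {}
        for subject, trials in subjects.items():
            processed = []
            for ts in trials:
                out = baseline_correct(bandpass_filter(ts, *filter_band))
                processed.append(out)
                n += 1
            groups[group][subject] = processed
    log = {"filter_band": list(filter_band), "n_trials": n, "order": "bandpass->baseline_correct"}
    return (
        Cohort(design=cohort.design, groups=groups, master_seed=cohort.master_seed,
               scenarios=cohort.scenarios),
        log,
    )


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    seed: int | None = None,
    force: bool = False,
    write_trials: bool = False,
) -> PipelineResult:
    """Execute all stages and write results under ``outdir``.

    ``seed`` overrides the config seed. Re-running into an existing run
    directory requires ``force``. ``write_trials`` additionally persists the
    raw cohort arrays (they can always be regenerated from the manifest seed).
    """
    t0 = time.time()
    out = Path(outdir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else int(seed)

    cohort = generate_cohort(config.design, config.scenarios, config.counts, master_seed=seed)
    if write_trials:
        write_cohort(cohort, out / "cohort", force=force)

    cohort, prep_log = preprocess_cohort(cohort, config.filter_band)

    gc_table = window_gc_table(
        cohort,
        config.grid,
        config.pairs,
        bands={b: config.bands[b] for b in config.analysis_bands},
        p_max=config.p_max,
        n_freqs=config.n_freqs,
        gate_rule=config.gate_rule,
        include_reverse=config.include_reverse,
    )
    write_gc_table(gc_table, out / "gc_table.tsv")

    networks = binarize_networks(
        gc_table,
        config.grid.n_windows,
        config.pairs,
        bands=config.analysis_bands,
        alpha=config.alpha,
        n_perm=config.n_perm,
        seed=seed + 1,
    )
    write_networks(networks, out / "networks")

    series = metric_series(networks, gc_table, config.grid, config.design, config.unreachable_rule)
    if config.estimator == "conditional":
        # alternative causal-density estimator conditioning on the rest of
        # the network (broadband time-domain measure); appended alongside the
        # bivariate band-resolved series
        cond_table = conditional_gc_table(cohort, config.grid, config.pairs)
        cond_nets = {
            (g, "broadband"): networks[(g, config.analysis_bands[0])]
            for g in {k[0] for k in networks}
        }
        cond_series = metric_series(
            cond_nets, cond_table, config.grid, config.design, config.unreachable_rule
        )
        cond_series = cond_series[cond_series["metric"].isin(["CD", "CD_subject"])]
        series = pd.concat([series, cond_series], ignore_index=True)
    series.to_csv(out / "metric_series.csv", index=False)

    anova: dict[str, dict] = {}
    groups = sorted(cohort.groups)
    for band in config.analysis_bands:
        sub = series[(series["metric"] == "CD_subject") & (series["band"] == band)]
        values_by_group = {}
        for g in groups:
            piv = sub[sub["group"] == g].pivot_table(
                index="subject", columns="window", values="value", dropna=False
            )
            piv = piv.reindex(columns=range(config.grid.n_windows))
            values_by_group[g] = piv.to_numpy()
        wc = per_window_anova(
            values_by_group, alpha=config.anova_alpha, correction=config.anova_correction
        )
        anova[band] = {
            "f": wc.f_stats.tolist(),
            "p": wc.p_values.tolist(),
            "mask": wc.mask.astype(int).tolist(),
            "spans": wc.spans,
        }
    (out / "anova.json").write_text(json.dumps(anova, indent=1))

    tables = []
    for metric in ("CD", "L"):
        tables.append(phase_band_table(series, metric=metric, bands=config.analysis_bands))
    phase_tables = pd.concat(tables, ignore_index=True)
    phase_tables.to_csv(out / "phase_tables.csv", index=False)
    (out / "phase_tables.txt").write_text(
        "\n".join(format_phase_table(phase_tables, m) for m in ("CD", "L"))
    )

    flag_counts = gc_table["flags"].value_counts().to_dict()
    cfg_dict = config.to_dict()
    cfg_hash = hashlib.sha256(json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()[:16]
    manifest = {
        "package_version": __version__,
        "config": cfg_dict,
        "config_hash": cfg_hash,
        "seed": seed,
        "samples_per_window": config.grid.samples_per_window(config.design),
        "preprocessing": prep_log,
        "n_gc_rows": int(len(gc_table)),
        "window_flag_counts": {str(k): int(v) for k, v in flag_counts.items()},
        "n_networks": len(networks),
        "elapsed_s": round(time.time() - t0, 2),
    }
    write_manifest(manifest_path, manifest)
    return PipelineResult(
        outdir=out,
        cohort=cohort,
        gc_table=gc_table,
        networks=networks,
        series=series,
        anova=anova,
        phase_tables=phase_tables,
        manifest=manifest,
    )
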
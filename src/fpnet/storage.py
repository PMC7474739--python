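"""On-disk formats: cohort directories, tables, adjacency stacks, manifests.

A cohort is written as one directory per group/subject with per-trial binary
arrays (.npy: node x sample float64, little-endian) plus a JSON sidecar per
trial (sampling rate, node labels, frontal/parietal partition, phase
boundaries, seed provenance) and a top-level manifest listing every trial.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import SourceTimeSeries, TrialDesign
from .network import BinaryDirectedNetwork
from .synth import Cohort

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_gc_table",
    "read_gc_table",
    "write_networks",
    "write_manifest",
]


def _design_dict(design: TrialDesign) -> dict:
    return {
        "sampling_rate": design.sampling_rate,
        "baseline_duration": design.baseline_duration,
        "task_duration": design.task_duration,
        "phase_boundaries": list(design.phase_boundaries),
        "frontal_nodes": list(design.frontal_nodes),
        "parietal_nodes": list(design.parietal_nodes),
    }


def _design_from_dict(d: dict) -> TrialDesign:
    return TrialDesign(
        sampling_rate=d["sampling_rate"],
        baseline_duration=d["baseline_duration"],
        task_duration=d["task_duration"],
        phase_boundaries=tuple(d["phase_boundaries"]),
        frontal_nodes=tuple(d["frontal_nodes"]),
        parietal_nodes=tuple(d["parietal_nodes"]),
    )


def write_cohort(cohort: Cohort, outdir: str | Path, force: bool = False) -> Path:
    """Write a cohort directory tree; refuses to overwrite unless ``force``."""
    out = Path(outdir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True to overwrite")
    entries = []
    for group, subjects in cohort.groups.items():
        for subject, trials in subjects.items():
            sdir = out / group / subject
            sdir.mkdir(parents=True, exist_ok=True)
            for trial in trials:
                tid = trial.meta.get("trial", 0)
                stem = f"trial{tid:04d}"
                arr = np.ascontiguousarray(trial.data, dtype="<f8")
                np.save(sdir / f"{stem}.npy", arr)
                sidecar = {
                    "design": _design_dict(trial.design),
                    "meta": {
                        k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in trial.meta.items()
                    },
                    "shape": list(arr.shape),
                    "dtype": "<f8",
                }
                (sdir / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
                entries.append(
                    {"group": group, "subject": subject, "trial": int(tid),
                     "path": str(Path(group) / subject / f"{stem}.npy")}
                )
    manifest = {
        "design": _design_dict(cohort.design),
        "master_seed": cohort.master_seed,
        "n_trials": len(entries),
        "trials": entries,
    }
    out.mkdir(parents=True, exist_ok=True)
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return out


def read_cohort(indir: str | Path) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    root = Path(indir)
    manifest = json.loads((root / "manifest.json").read_text())
    design = _design_from_dict(manifest["design"])
    groups: dict[str, dict[str, list[SourceTimeSeries]]] = {}
    for entry in manifest["trials"]:
        data = np.load(root / entry["path"])
        sidecar = json.loads((root / entry["path"]).with_suffix(".json").read_text())
        ts = SourceTimeSeries(data=data, design=design, meta=sidecar["meta"])
        groups.setdefault(entry["group"], {}).setdefault(entry["subject"], []).append(ts)
    return Cohort(design=design, groups=groups, master_seed=manifest["master_seed"])


def write_gc_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_gc_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["flags"] = df["flags"].fillna("")
    return df


def write_networks(
    networks: dict[tuple[str, str], BinaryDirectedNetwork], outdir: str | Path
) -> list[Path]:
    """Adjacency stacks as TSV (windows x pairs) + compressed binary + header."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for (group, band), net in networks.items():
        stem = f"network_{group}_{band}"
        cols = [f"{s}->{t}" for s, t in net.pairs.pairs]
        df = pd.DataFrame(net.adjacency, columns=cols)
        df.insert(0, "window", np.arange(net.adjacency.shape[0]))
        tsv = out / f"{stem}.tsv"
        df.to_csv(tsv, sep="\t", index=False)
        npz = out / f"{stem}.npz"
        np.savez_compressed(npz, adjacency=net.adjacency)
        header = {
            "group": group,
            "band": band,
            "pairs": [list(p) for p in net.pairs.pairs],
            "alpha": net.alpha,
            "n_perm": net.n_perm,
            "cluster_rule": net.cluster_rule,
            "coverage": net.coverage,
        }
        (out / f"{stem}.json").write_text(json.dumps(header, indent=1))
        written += [tsv, npz]
    return written


def write_manifest(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1, default=str))
    return path
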
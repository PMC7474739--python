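"""Pipeline configuration: YAML schema, defaults, and cross-field validation."""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import yaml

from .design import DEFAULT_BANDS, FrequencyBand, TrialDesign, default_design
from .network import ROIPairSet, WindowGrid
from .synth import (
    Coupling,
    CouplingScenario,
    GroupSpec,
    Oscillator,
    default_group_scenarios,
)

__all__ = ["PipelineConfig", "validate_config", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Configuration violation, reported with the offending field path."""


@dataclass
class PipelineConfig:
    """Validated parameters for a full pipeline run."""

    design: TrialDesign
    scenarios: dict[str, CouplingScenario]
    counts: dict[str, GroupSpec]
    grid: WindowGrid
    pairs: ROIPairSet
    bands: dict[str, FrequencyBand]
    analysis_bands: tuple[str, ...] = ("theta", "gamma")
    filter_band: tuple[float, float] = (1.0, 60.0)
    p_max: int = 3
    n_freqs: int = 128
    gate_rule: str = "both"
    estimator: str = "bivariate"  # or "conditional"
    alpha: float = 0.05
    n_perm: int = 200
    anova_alpha: float = 0.05
    anova_correction: str = "none"
    unreachable_rule: str = "zero"
    include_reverse: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "design": {
                "sampling_rate": self.design.sampling_rate,
                "baseline_duration": self.design.baseline_duration,
                "task_duration": self.design.task_duration,
                "phase_boundaries": list(self.design.phase_boundaries),
                "frontal_nodes": list(self.design.frontal_nodes),
                "parietal_nodes": list(self.design.parietal_nodes),
            },
            "groups": {
                g: {
                    "n_subjects": self.counts[g].n_subjects,
                    "n_trials": self.counts[g].n_trials,
                    "coupling_scale": self.scenarios[g].coupling_scale,
                    "innovation_scale": self.scenarios[g].innovation_scale,
                    "innovation_corr": self.scenarios[g].innovation_corr,
                    "couplings": [
                        {
                            "source": c.source, "target": c.target, "band": c.band,
                            "interval_ms": list(c.interval_ms), "strength": c.strength,
                        }
                        for c in self.scenarios[g].couplings
                    ],
                    "oscillators": {
                        lbl: [[o.freq_hz, o.damping] for o in oscs]
                        for lbl, oscs in self.scenarios[g].oscillators.items()
                    },
                }
                for g in self.scenarios
            },
            "grid": {"window_ms": self.grid.window_ms, "n_windows": self.grid.n_windows},
            "pairs": [list(p) for p in self.pairs.pairs],
            "bands": {k: [b.low, b.high] for k, b in self.bands.items()},
            "analysis_bands": list(self.analysis_bands),
            "filter_band": list(self.filter_band),
            "p_max": self.p_max,
            "n_freqs": self.n_freqs,
            "gate_rule": self.gate_rule,
            "estimator": self.estimator,
            "alpha": self.alpha,
            "n_perm": self.n_perm,
            "anova_alpha": self.anova_alpha,
            "anova_correction": self.anova_correction,
            "unreachable_rule": self.unreachable_rule,
            "include_reverse": self.include_reverse,
            "seed": self.seed,
        }
        return d


def _design_from(raw: dict) -> TrialDesign:
    d = raw.get("design") or {}
    if "frontal_nodes" in d or "parietal_nodes" in d:
        return TrialDesign(
            sampling_rate=float(d.get("sampling_rate", 500.0)),
            baseline_duration=float(d.get("baseline_duration", 1000.0)),
            task_duration=float(d.get("task_duration", 9000.0)),
            phase_boundaries=tuple(d.get("phase_boundaries", (3000.0, 6000.0))),
            frontal_nodes=tuple(d.get("frontal_nodes", ())),
            parietal_nodes=tuple(d.get("parietal_nodes", ())),
        )
    return default_design(sampling_rate=float(d.get("sampling_rate", 500.0)))


def validate_config(raw: dict | None) -> PipelineConfig:
    """Fill defaults and cross-validate a raw (YAML-derived) mapping.

    An empty/None input yields the full-default configuration (study-scale
    cohort, 8x5 frontal/parietal layout, 40 ROI pairs, 90 x 100 ms windows).
    """
    raw = dict(raw or {})
    design = _design_from(raw)
    nyq = design.sampling_rate / 2.0

    filt = tuple(float(v) for v in raw.get("filter_band", (1.0, 60.0)))
    if not (0 < filt[0] < filt[1] < nyq):
        raise ConfigError(f"filter_band: [{filt[0]}, {filt[1]}] must satisfy 0 < low < high < Nyquist ({nyq})")

    bands_raw = raw.get("bands")
    if bands_raw:
        bands = {k: FrequencyBand(k, float(v[0]), float(v[1])) for k, v in bands_raw.items()}
    else:
        bands = dict(DEFAULT_BANDS)
    edges = sorted((b.low, b.high) for b in bands.values())
    for (l1, h1), (l2, h2) in zip(edges[:-1], edges[1:]):
        if l2 < h1:
            raise ConfigError(f"bands: overlapping band edges [{l1},{h1}) and [{l2},{h2})")
    for k, b in bands.items():
        if b.high > nyq:
            raise ConfigError(f"bands.{k}: high edge {b.high} Hz exceeds Nyquist ({nyq} Hz)")

    grid_raw = raw.get("grid") or {}
    grid = WindowGrid(
        window_ms=float(grid_raw.get("window_ms", 100.0)),
        n_windows=int(grid_raw.get("n_windows", round(design.task_duration / float(grid_raw.get("window_ms", 100.0))))),
    )
    try:
        grid.validate(design)
    except ValueError as e:
        raise ConfigError(f"grid: {e}") from None

    groups_raw = raw.get("groups")
    if groups_raw:
        scenarios: dict[str, CouplingScenario] = {}
        counts: dict[str, GroupSpec] = {}
        for g, spec in groups_raw.items():
            cpl = [
                Coupling(
                    source=c["source"], target=c["target"], band=c.get("band", "theta"),
                    interval_ms=tuple(c["interval_ms"]), strength=float(c["strength"]),
                )
                for c in spec.get("couplings", [])
            ]
            oscs = {
                lbl: tuple(Oscillator(float(f), float(r)) for f, r in pairs)
                for lbl, pairs in (spec.get("oscillators") or {}).items()
            }
            scenarios[g] = CouplingScenario(
                couplings=cpl,
                oscillators=oscs,
                coupling_scale=float(spec.get("coupling_scale", 1.0)),
                innovation_scale=float(spec.get("innovation_scale", 1.0)),
                innovation_corr=float(spec.get("innovation_corr", 0.0)),
            )
            counts[g] = GroupSpec(int(spec.get("n_subjects", 10)), int(spec.get("n_trials", 100)))
    else:
        scenarios = default_group_scenarios(design)
        counts = {"gifted": GroupSpec(20, 400), "control": GroupSpec(18, 380)}

    pairs_raw = raw.get("pairs")
    if pairs_raw:
        pairs = ROIPairSet(tuple((s, t) for s, t in pairs_raw))
    else:
        pairs = ROIPairSet.frontal_to_parietal(design)
    try:
        pairs.validate(design)
    except ValueError as e:
        raise ConfigError(f"pairs: {e}") from None
    if len(pairs) != 40:
        warnings.warn(
            f"pairs: {len(pairs)} ordered pairs configured (the reference region-of-interest "
            "set has 40); proceeding with the override",
            stacklevel=2,
        )

    analysis_bands = tuple(raw.get("analysis_bands", ("theta", "gamma")))
    for b in analysis_bands:
        if b not in bands:
            raise ConfigError(f"analysis_bands: unknown band {b!r}")

    n_perm = int(raw.get("n_perm", 200))
    if n_perm < 100:
        raise ConfigError("n_perm: must be >= 100")
    if n_perm <= 200:
        # smallest attainable cluster p is 1/(n_perm+1)
        warnings.warn(
            f"n_perm={n_perm} limits permutation p-resolution to {1.0 / (n_perm + 1):.4f}",
            stacklevel=2,
        )

    estimator = raw.get("estimator", "bivariate")
    if estimator not in ("bivariate", "conditional"):
        raise ConfigError(f"estimator: unknown estimator {estimator!r}")

    return PipelineConfig(
        design=design,
        scenarios=scenarios,
        counts=counts,
        grid=grid,
        pairs=pairs,
        bands=bands,
        analysis_bands=analysis_bands,
        filter_band=filt,
        p_max=int(raw.get("p_max", 3)),
        n_freqs=int(raw.get("n_freqs", 128)),
        gate_rule=raw.get("gate_rule", "both"),
        estimator=estimator,
        alpha=float(raw.get("alpha", 0.05)),
        n_perm=n_perm,
        anova_alpha=float(raw.get("anova_alpha", 0.05)),
        anova_correction=raw.get("anova_correction", "none"),
        unreachable_rule=raw.get("unreachable_rule", "zero"),
        include_reverse=bool(raw.get("include_reverse", False)),
        seed=int(raw.get("seed", 0)),
    )


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML config file (None/empty file -> defaults)."""
    raw = None
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
    return validate_config(raw)
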
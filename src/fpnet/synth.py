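"""Synthetic source-signal cohorts from time-varying VAR processes.

Each node carries one or more damped stochastic oscillators (AR(2) resonances
at a chosen center frequency); directed coupling between nodes is injected as
a lag-1 autoregressive coefficient that is switched on only inside a scheduled
task-time interval. Two groups with different coupling schedules stand in for
the gifted/control cohorts whose real recordings are not publicly deposited.

The coefficient schedule is piecewise-constant in time; every segment is
checked for VAR stability (companion spectral radius < 1) before simulation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .design import SourceTimeSeries, TrialDesign, default_design

__all__ = [
    "Oscillator",
    "Coupling",
    "CouplingScenario",
    "VarSchedule",
    "Cohort",
    "GroupSpec",
    "oscillator_poly",
    "build_tv_var",
    "simulate_trial",
    "simulate_trials",
    "generate_cohort",
    "default_group_scenarios",
]

#: Seconds of simulation discarded before the trial proper starts.
BURN_IN_S = 2.0


@dataclass(frozen=True)
class Oscillator:
    """A damped AR(2) resonance: poles at ``r * exp(+-i 2 pi f0 / fs)``.

    The default damping gives a broad spectral hump peaking at ``freq_hz``
    (EEG-like band-dominant content) while keeping short windows comfortably
    stationary; damping close to 1 yields near-unit-root windows that the
    stationarity gate would difference almost always.
    """

    freq_hz: float
    damping: float = 0.65

    def __post_init__(self) -> None:
        if not (0 < self.damping < 1):
            raise ValueError("damping must be in (0, 1) for stability")
        if self.freq_hz <= 0:
            raise ValueError("freq_hz must be positive")


@dataclass(frozen=True)
class Coupling:
    """Directed lag-1 coupling active inside a task-time interval.

    ``interval_ms`` is (start, stop) in ms relative to *task onset*; the
    ``band`` tag records which band the source oscillator is tuned to (it is
    descriptive: the mechanical injection is always the lag-1 coefficient).
    """

    source: str
    target: str
    band: str
    interval_ms: tuple[float, float]
    strength: float

    def __post_init__(self) -> None:
        lo, hi = self.interval_ms
        if not lo < hi:
            raise ValueError(f"coupling {self.source}->{self.target}: empty interval {self.interval_ms}")
        if self.source == self.target:
            raise ValueError("coupling source and target must differ")


@dataclass
class CouplingScenario:
    """Generative recipe for one group.

    Parameters
    ----------
    couplings :
        Scheduled directed couplings (task-time intervals).
    oscillators :
        Node label -> list of resonances; nodes absent from the mapping get
        ``default_oscillators``.
    coupling_scale :
        Group-level multiplier applied to every coupling strength.
    innovation_scale :
        Standard deviation of the i.i.d. Gaussian innovations.
    innovation_corr :
        Optional instantaneous correlation between all node pairs' innovations
        (exercises the partial-covariance correction); 0 = independent.
    """

    couplings: list[Coupling] = field(default_factory=list)
    oscillators: dict[str, tuple[Oscillator, ...]] = field(default_factory=dict)
    default_oscillators: tuple[Oscillator, ...] = (Oscillator(6.0, 0.65),)
    coupling_scale: float = 1.0
    innovation_scale: float = 1.0
    innovation_corr: float = 0.0

    def node_oscillators(self, node: str) -> tuple[Oscillator, ...]:
        return tuple(self.oscillators.get(node, self.default_oscillators))


def oscillator_poly(oscillators: Sequence[Oscillator], fs: float) -> np.ndarray:
    """AR coefficients a_1..a_p of the product of damped AR(2) resonances.

    Each resonance contributes the polynomial ``1 - 2 r cos(w0) L + r^2 L^2``;
    the composite characteristic polynomial is their product, so the composite
    roots are exactly the union of the resonance poles (stability preserved).
    Returns the coefficients such that ``x_t = sum_k a_k x_{t-k} + e_t``.
    """
    poly = np.array([1.0])
    for osc in oscillators:
        w0 = 2.0 * np.pi * osc.freq_hz / fs
        r = osc.damping
        poly = np.convolve(poly, np.array([1.0, -2.0 * r * np.cos(w0), r * r]))
    return -poly[1:]


def _companion(a_stack: np.ndarray) -> np.ndarray:
    """Companion matrix of VAR coefficients ``a_stack`` of shape (p, n, n)."""
    p, n, _ = a_stack.shape
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = np.concatenate(list(a_stack), axis=1)
    if p > 1:
        comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    return comp


def spectral_radius(a_stack: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(_companion(a_stack)))))


@dataclass
class VarSchedule:
    """Piecewise-constant VAR(p) coefficient schedule over one whole trial.

    ``segments`` is a list of ``(start_sample, stop_sample, A)`` with ``A`` of
    shape (p, n, n); segments tile ``[0, design.n_samples)``.
    """

    design: TrialDesign
    order: int
    segments: list[tuple[int, int, np.ndarray]]
    innovation_scale: float
    innovation_corr: float = 0.0

    def coefficients_at(self, sample: int) -> np.ndarray:
        for start, stop, a in self.segments:
            if start <= sample < stop:
                return a
        raise IndexError(f"sample {sample} outside schedule")


def build_tv_var(design: TrialDesign, scenario: CouplingScenario) -> VarSchedule:
    """Compile a scenario into a stability-checked coefficient schedule.

    The diagonal blocks implement each node's damped oscillators (all nodes are
    padded to the common maximal AR order); off-diagonal lag-1 entries implement
    the scheduled couplings, exactly zero outside their intervals. Raises
    ``ValueError`` naming the offending interval if any composite segment is
    unstable, or naming an unknown node label.
    """
    nodes = design.nodes
    idx = {lbl: i for i, lbl in enumerate(nodes)}
    for c in scenario.couplings:
        for lbl in (c.source, c.target):
            if lbl not in idx:
                raise ValueError(f"coupling references unknown node label {lbl!r}")

    diag_polys = [oscillator_poly(scenario.node_oscillators(lbl), design.sampling_rate) for lbl in nodes]
    p = max(2, max((len(c) for c in diag_polys), default=2))
    n = len(nodes)
    base = np.zeros((p, n, n))
    for i, coefs in enumerate(diag_polys):
        for k, a in enumerate(coefs):
            base[k, i, i] = a

    nb = design.n_baseline_samples
    total = design.n_samples
    # breakpoints in absolute sample time; couplings only exist during the task
    cuts = {0, nb, total}
    spans: list[tuple[int, int, Coupling]] = []
    for c in scenario.couplings:
        lo = nb + design.ms_to_samples(c.interval_ms[0])
        hi = nb + design.ms_to_samples(min(c.interval_ms[1], design.task_duration))
        lo, hi = max(lo, nb), min(hi, total)
        if lo >= hi:
            continue
        spans.append((lo, hi, c))
        cuts.update((lo, hi))

    segments: list[tuple[int, int, np.ndarray]] = []
    edges = sorted(cuts)
    for start, stop in zip(edges[:-1], edges[1:]):
        a = base.copy()
        for lo, hi, c in spans:
            if lo <= start and stop <= hi:
                a[0, idx[c.target], idx[c.source]] += c.strength * scenario.coupling_scale
        rho = spectral_radius(a)
        if rho >= 1.0:
            raise ValueError(
                f"unstable VAR segment over samples [{start}, {stop}) "
                f"(spectral radius {rho:.4f} >= 1); reduce coupling strengths or damping"
            )
        segments.append((start, stop, a))
    return VarSchedule(
        design=design,
        order=p,
        segments=segments,
        innovation_scale=scenario.innovation_scale,
        innovation_corr=scenario.innovation_corr,
    )


def _innovation_chol(n: int, scale: float, corr: float) -> np.ndarray:
    if scale == 0.0 or corr == 0.0 or n == 1:
        return scale * np.eye(n)
    cov = np.full((n, n), corr * scale * scale)
    np.fill_diagonal(cov, scale * scale)
    return np.linalg.cholesky(cov)


def simulate_trials(
    schedule: VarSchedule,
    n_trials: int,
    seed: int | np.random.SeedSequence,
    meta: dict | None = None,
) -> list[SourceTimeSeries]:
    """Simulate ``n_trials`` independent trials from one schedule.

    Trials share the schedule but draw innovations from per-trial child seeds
    spawned from ``seed``; the recursion runs batched over trials for speed.
    A 2 s burn-in under the first segment's coefficients is discarded. Raises
    ``RuntimeError`` if any sample goes non-finite (instability diagnostic).
    """
    design = schedule.design
    n, p = design.n_nodes, schedule.order
    t_total = design.n_samples
    n_burn = int(round(BURN_IN_S * design.sampling_rate))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_trials)
    chol = _innovation_chol(n, schedule.innovation_scale, schedule.innovation_corr)

    # innovations: (n_burn + t_total, n, n_trials), per-trial independent streams
    eps = np.empty((n_burn + t_total, n, n_trials))
    for j, child in enumerate(children):
        rng = np.random.default_rng(child)
        eps[:, :, j] = rng.standard_normal((n_burn + t_total, n)) @ chol.T

    hist = np.zeros((p, n, n_trials))  # hist[k] = x_{t-1-k}
    out = np.empty((t_total, n, n_trials))
    a_burn = schedule.segments[0][2]
    for t in range(-n_burn, t_total):
        a = a_burn if t < 0 else schedule.coefficients_at(t)
        x = eps[t + n_burn]
        for k in range(p):
            x = x + a[k] @ hist[k]
        if not np.all(np.isfinite(x)):
            raise RuntimeError(
                f"non-finite sample at t={t} (relative to trial start); unstable schedule"
            )
        hist = np.roll(hist, 1, axis=0)
        hist[0] = x
        if t >= 0:
            out[t] = x

    base_meta = dict(meta or {})
    trials = []
    for j, child in enumerate(children):
        m = dict(base_meta)
        m.update(trial=j, seed_entropy=child.entropy, seed_path=child.spawn_key)
        trials.append(SourceTimeSeries(data=out[:, :, j].T.copy(), design=design, meta=m))
    return trials


def simulate_trial(schedule: VarSchedule, design: TrialDesign | None = None, seed: int = 0) -> SourceTimeSeries:
    """Single-trial convenience wrapper around :func:`simulate_trials`."""
    if design is not None and design is not schedule.design:
        raise ValueError("design must match the schedule's design")
    return simulate_trials(schedule, 1, seed)[0]


@dataclass(frozen=True)
class GroupSpec:
    """Cohort arm: ``n_subjects`` sharing one scenario, ``n_trials`` in total.

    Trials are distributed as evenly as possible; the first
    ``n_trials % n_subjects`` subjects receive one extra trial.
    """

    n_subjects: int
    n_trials: int

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_trials <= 0:
            raise ValueError("subject and trial counts must be positive")

    def trials_per_subject(self) -> list[int]:
        base, extra = divmod(self.n_trials, self.n_subjects)
        return [base + (1 if i < extra else 0) for i in range(self.n_subjects)]


#: Defaults match the study cohort: 20 subjects / 400 trials vs 18 / 380.
DEFAULT_GROUP_SPECS: dict[str, GroupSpec] = {
    "gifted": GroupSpec(20, 400),
    "control": GroupSpec(18, 380),
}


@dataclass
class Cohort:
    """group label -> subject id -> list of trials, plus generative provenance."""

    design: TrialDesign
    groups: dict[str, dict[str, list[SourceTimeSeries]]]
    master_seed: int
    scenarios: dict[str, CouplingScenario] = field(default_factory=dict)

    def n_trials(self, group: str | None = None) -> int:
        gs = [self.groups[group]] if group else self.groups.values()
        return sum(len(trials) for g in gs for trials in g.values())

    def iter_trials(self):
        for group, subjects in self.groups.items():
            for subject, trials in subjects.items():
                for trial in trials:
                    yield group, subject, trial


def generate_cohort(
    design: TrialDesign,
    scenario_by_group: Mapping[str, CouplingScenario],
    counts: Mapping[str, GroupSpec] | None = None,
    master_seed: int = 0,
) -> Cohort:
    """Generate a two-arm (or k-arm) cohort of simulated trials.

    Per-subject seeds are spawned deterministically from ``master_seed`` (one
    child per (group, subject), in iteration order), and per-trial seeds from
    the subject seed, so the whole cohort reproduces bit-identically.
    """
    counts = dict(counts or DEFAULT_GROUP_SPECS)
    if set(counts) != set(scenario_by_group):
        raise ValueError("counts and scenario_by_group must cover the same groups")
    ss = np.random.SeedSequence(master_seed)
    groups: dict[str, dict[str, list[SourceTimeSeries]]] = {}
    for group in scenario_by_group:
        spec = counts[group]
        schedule = build_tv_var(design, scenario_by_group[group])
        subjects: dict[str, list[SourceTimeSeries]] = {}
        subj_seeds = ss.spawn(spec.n_subjects)
        for i, (n_tr, subj_seed) in enumerate(zip(spec.trials_per_subject(), subj_seeds)):
            sid = f"{group}_s{i + 1:02d}"
            subjects[sid] = simulate_trials(
                schedule, n_tr, subj_seed, meta={"group": group, "subject": sid}
            )
        groups[group] = subjects
    return Cohort(
        design=design,
        groups=groups,
        master_seed=master_seed,
        scenarios=dict(scenario_by_group),
    )


#: Default group-by-phase coupling strengths: equal in premise coding, gifted
#: above control during premise integration + early conclusion, reversed in
#: the late conclusion. Chosen so the designed contrast is recoverable by the
#: windowed estimator at cohort scale; conventions, not measured facts.
DEFAULT_EFFECT = {
    "premise": 0.15,
    "mid": {"gifted": 0.45, "control": 0.15},
    "late": {"gifted": 0.10, "control": 0.35},
    "mid_interval": (3000.0, 7500.0),
    "late_interval": (7500.0, 9000.0),
}


def group_effect_scenarios(
    coupled_pairs: Sequence[tuple[str, str]],
    oscillators: Mapping[str, Sequence[Oscillator]],
    band: str = "theta",
    effect: Mapping | None = None,
) -> dict[str, CouplingScenario]:
    """Two-arm scenarios with the standard group-by-phase coupling contrast.

    Each coupled pair gets three scheduled couplings: an arm-equal strength in
    the premise-coding phase, then arm-specific strengths over the mid
    (premise integration + early conclusion) and late-conclusion intervals.
    """
    eff = dict(DEFAULT_EFFECT)
    if effect:
        eff.update(effect)
    osc = {lbl: tuple(o) for lbl, o in oscillators.items()}

    def arm(group: str) -> CouplingScenario:
        cpl = []
        for src, tgt in coupled_pairs:
            cpl.append(Coupling(src, tgt, band, (0.0, eff["mid_interval"][0]), eff["premise"]))
            cpl.append(Coupling(src, tgt, band, eff["mid_interval"], eff["mid"][group]))
            cpl.append(Coupling(src, tgt, band, eff["late_interval"], eff["late"][group]))
        return CouplingScenario(couplings=cpl, oscillators=osc, default_oscillators=())

    return {"gifted": arm("gifted"), "control": arm("control")}


def default_group_scenarios(
    design: TrialDesign | None = None,
    theta_hz: float = 6.0,
    gamma_hz: float = 40.0,
) -> dict[str, CouplingScenario]:
    """Study-scale group scenarios with mixed theta/gamma-tuned nodes.

    Nodes are tuned to a single band each — alternating theta/gamma within
    the frontal and parietal sets — so the cohort carries band-limited
    content in both bands while each coupling's spectral signature stays
    attributable to its source's band. The designed group effect couples
    theta-tuned frontal sources to theta-tuned parietal targets round-robin
    (approximately disjoint, keeping pairwise attribution clean); no
    gamma-band coupling is scheduled (both arms equal in gamma).
    """
    design = design or default_design()
    osc: dict[str, tuple[Oscillator, ...]] = {}
    for nodes in (design.frontal_nodes, design.parietal_nodes):
        for i, lbl in enumerate(nodes):
            tuned = Oscillator(theta_hz, 0.65) if i % 2 == 0 else Oscillator(gamma_hz, 0.8)
            osc[lbl] = (tuned,)
    theta_front = [n for n in design.frontal_nodes if osc[n][0].freq_hz == theta_hz]
    theta_par = [n for n in design.parietal_nodes if osc[n][0].freq_hz == theta_hz]
    if not theta_front or not theta_par:
        raise ValueError("design too small for the default mixed-band tuning")
    coupled = [(src, theta_par[i % len(theta_par)]) for i, src in enumerate(theta_front)]
    return group_effect_scenarios(coupled, osc)
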
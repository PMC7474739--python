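"""Generator contracts: schedule construction, stability, recoverable design."""
import numpy as np
import pytest
from scipy import signal as ssignal
from scipy import stats as sstats

from fpnet.design import TrialDesign, default_design
from fpnet.synth import (
    Coupling,
    CouplingScenario,
    GroupSpec,
    Oscillator,
    build_tv_var,
    default_group_scenarios,
    generate_cohort,
    oscillator_poly,
    simulate_trial,
    simulate_trials,
    spectral_radius,
)
from fpnet.vargc import time_domain_gc


class TestBuildSchedule:
    def test_empty_coupling_list_has_zero_off_diagonals(self, two_node_design, null_scenario):
        sched = build_tv_var(two_node_design, null_scenario)
        for _, _, a in sched.segments:
            off = a * (1 - np.eye(2))
            assert np.all(off == 0.0)

    def test_single_coupling_exact_inside_interval_zero_outside(self, two_node_design, theta_pair_scenario):
        sched = build_tv_var(two_node_design, theta_pair_scenario)
        fs = two_node_design.sampling_rate
        nb = two_node_design.n_baseline_samples
        lo = nb + int(3000 * fs / 1000)
        hi = nb + int(6000 * fs / 1000)
        # sample a representative instant inside and outside the interval
        for t, expected in [(lo, 0.4), (hi - 1, 0.4), (lo - 1, 0.0), (hi, 0.0), (0, 0.0)]:
            a = sched.coefficients_at(t)
            assert a[0, 1, 0] == expected  # lag-1 entry target P1 (row 1), source F1 (col 0)

    def test_oscillator_block_resonates_at_design_frequency(self):
        # oracle: eigendecomposition of the AR(2) companion matrix
        coefs = oscillator_poly([Oscillator(6.0, 0.65)], fs=500.0)
        comp = np.array([[coefs[0], coefs[1]], [1.0, 0.0]])
        eig = np.linalg.eigvals(comp)
        arg = np.abs(np.angle(eig)).max()
        assert abs(arg - 2 * np.pi * 6.0 / 500.0) / (2 * np.pi * 6.0 / 500.0) < 0.05

    def test_unknown_node_rejected(self, two_node_design):
        scen = CouplingScenario(couplings=[Coupling("F9", "P1", "theta", (0.0, 1000.0), 0.2)])
        with pytest.raises(ValueError, match="unknown node"):
            build_tv_var(two_node_design, scen)

    def test_unstable_composite_rejected_with_interval_diagnostic(self, two_node_design):
        scen = CouplingScenario(
            couplings=[
                Coupling("F1", "P1", "theta", (1000.0, 2000.0), 1.2),
                Coupling("P1", "F1", "theta", (1000.0, 2000.0), 1.2),
            ],
            oscillators={"F1": (Oscillator(6.0, 0.9),), "P1": (Oscillator(6.0, 0.9),)},
            default_oscillators=(),
        )
        with pytest.raises(ValueError, match="unstable VAR segment"):
            build_tv_var(two_node_design, scen)

    def test_all_segments_stable(self, two_node_design, theta_pair_scenario):
        sched = build_tv_var(two_node_design, theta_pair_scenario)
        for _, _, a in sched.segments:
            assert spectral_radius(a) < 1.0


class TestSimulate:
    def test_zero_innovation_scale_gives_zero_trial(self, two_node_design, null_scenario):
        scen = CouplingScenario(innovation_scale=0.0)
        sched = build_tv_var(two_node_design, scen)
        trial = simulate_trial(sched, seed=3)
        assert np.all(trial.data == 0.0)

    def test_same_seed_bit_identical(self, two_node_design, theta_pair_scenario):
        sched = build_tv_var(two_node_design, theta_pair_scenario)
        a = simulate_trial(sched, seed=11)
        b = simulate_trial(sched, seed=11)
        np.testing.assert_array_equal(a.data, b.data)

    def test_sharply_tuned_theta_oscillator_spectrum_peaks_in_band(self, two_node_design):
        # narrowband tuning (damping 0.99) puts the spectral peak at the pole frequency
        scen = CouplingScenario(
            oscillators={lbl: (Oscillator(6.0, 0.99),) for lbl in ("F1", "P1")},
            default_oscillators=(),
        )
        sched = build_tv_var(two_node_design, scen)
        trial = simulate_trial(sched, seed=5)
        freqs, psd = ssignal.welch(trial.data, fs=500.0, nperseg=2048, axis=1)
        for row in psd:
            assert 4.0 <= freqs[np.argmax(row)] < 8.0

    def test_trials_finite_and_variance_stationary_within_phases(self, two_node_design, theta_pair_scenario):
        sched = build_tv_var(two_node_design, theta_pair_scenario)
        trials = simulate_trials(sched, 8, seed=2)
        data = np.stack([t.data for t in trials])
        assert np.all(np.isfinite(data))
        # baseline segment: variance profile over 10 bins has no trend beyond
        # sampling noise (3x the binomial-ish standard error of a variance)
        base = data[:, :, : two_node_design.n_baseline_samples]
        bins = np.array_split(base, 10, axis=2)
        profile = np.array([b.var() for b in bins])
        n_per_bin = base.shape[0] * base.shape[1] * base.shape[2] // 10
        se = profile.mean() * np.sqrt(2.0 / n_per_bin)
        slope = np.polyfit(np.arange(10), profile, 1)[0]
        assert abs(slope) < 3 * se


class TestCohort:
    def test_minimal_counts_yield_two_trials(self, two_node_design, null_scenario):
        cohort = generate_cohort(
            two_node_design,
            {"a": null_scenario, "b": null_scenario},
            {"a": GroupSpec(1, 1), "b": GroupSpec(1, 1)},
            master_seed=0,
        )
        assert cohort.n_trials() == 2

    def test_default_counts_match_retained_trial_numbers(self):
        # 400 gifted / 380 control retained trials over 20 / 18 subjects
        specs = {"gifted": GroupSpec(20, 400), "control": GroupSpec(18, 380)}
        assert sum(specs["gifted"].trials_per_subject()) == 400
        assert sum(specs["control"].trials_per_subject()) == 380
        assert len(specs["control"].trials_per_subject()) == 18
        design = default_design(n_frontal=2, n_parietal=1)
        cohort = generate_cohort(
            design, default_group_scenarios(design), specs, master_seed=0
        )
        assert cohort.n_trials("gifted") == 400
        assert cohort.n_trials("control") == 380

    def test_same_master_seed_reproduces_cohort(self, two_node_design, theta_pair_scenario):
        kw = dict(
            scenario_by_group={"g": theta_pair_scenario},
            counts={"g": GroupSpec(2, 4)},
            master_seed=42,
        )
        c1 = generate_cohort(two_node_design, **kw)
        c2 = generate_cohort(two_node_design, **kw)
        for (g1, s1, t1), (g2, s2, t2) in zip(c1.iter_trials(), c2.iter_trials()):
            assert (g1, s1) == (g2, s2)
            np.testing.assert_array_equal(t1.data, t2.data)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            GroupSpec(0, 10)
        with pytest.raises(ValueError):
            GroupSpec(2, 0)


@pytest.fixture(scope="module")
def long_segments():
    # stationary coupled pair: coupling 0.4 active over the whole trial
    design = TrialDesign(frontal_nodes=("F1",), parietal_nodes=("P1",))
    scen = CouplingScenario(
        couplings=[Coupling("F1", "P1", "theta", (0.0, 9000.0), 0.4)],
        oscillators={lbl: (Oscillator(6.0, 0.65),) for lbl in ("F1", "P1")},
        default_oscillators=(),
    )
    sched = build_tv_var(design, scen)
    trials = simulate_trials(sched, 100, seed=17)
    nb = design.n_baseline_samples
    return [t.data[:, nb : nb + 1000] for t in trials]  # 2 s segments


class TestDesignedCausality:
    """The generator's couplings are recoverable by time-domain GC."""

    def test_coupled_direction_dominates(self, long_segments):
        wins = 0
        for seg in long_segments:
            fwd = time_domain_gc(seg, p=3, target_idx=1, source_idx=0)  # F1 -> P1
            rev = time_domain_gc(seg, p=3, target_idx=0, source_idx=1)
            wins += int(fwd > rev)
        assert wins >= 95

    def test_null_directions_exchangeable(self, two_node_design, null_scenario):
        sched = build_tv_var(two_node_design, null_scenario)
        trials = simulate_trials(sched, 100, seed=23)
        nb = two_node_design.n_baseline_samples
        fwd, rev = [], []
        for t in trials:
            seg = t.data[:, nb : nb + 1000]
            fwd.append(time_domain_gc(seg, p=3, target_idx=1, source_idx=0))
            rev.append(time_domain_gc(seg, p=3, target_idx=0, source_idx=1))
        p = sstats.wilcoxon(fwd, rev).pvalue
        assert p > 0.01
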
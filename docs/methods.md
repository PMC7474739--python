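# Methods

`fpnet` implements a directed-connectivity analysis of frontoparietal
source-level EEG signals during a three-phase deductive-reasoning trial
(premise coding, premise integration, conclusion), together with a synthetic
cohort generator that stands in for the unavailable recordings. This note
documents the model, the estimators, the generator, the numerical choices,
and what the synthetic validation does and does not establish.

## Signal model and trial geometry

A trial is a node-by-time real matrix: 1000 ms of pre-stimulus baseline
followed by 9000 ms of task at a default 500 Hz sampling rate. The task is
split into three 3000 ms phases (configurable boundaries). Analysis nodes are
partitioned into frontal and parietal sets; the directed network is defined
over an ordered (source, target) pair list, by default the 40
frontal→parietal pairs of an 8×5 layout.

The sampling rate is a package convention: it places the 60 Hz analysis
ceiling well below Nyquist and makes a 100 ms window exactly 50 samples.

## Spectral Granger causality

Each analysis window is modeled as a vector autoregression
x_t = Σ_{k=1..p} A_k x_{t−k} + ε_t with residual covariance Σ. On the unit
circle the transfer function is H(ω) = (I − Σ_k A_k e^{−ikω})^{−1} and the
cross-power spectral density factorizes as S(ω) = H(ω) Σ H*(ω). The
directed spectral measure from source Y to target X is Geweke's

    f_{Y→X}(ω) = −ln(1 − H_XY(ω) Σ_{Y|X} H*_XY(ω) / S_XX(ω)),

with the partial residual covariance Σ_{Y|X} = Σ_YY − Σ_YX Σ_XX^{−1} Σ_XY
removing the instantaneous residual correlation. Values are in nats (natural
log). Band summaries are arithmetic means of f over the grid frequencies
falling in [low, high): θ 4–8, α 8–13, β 13–30, γ 30–60 Hz (conventional
edges; the γ ceiling matches the 1–60 Hz analysis filter). The default grid
is 128 equally spaced points over (0, Nyquist].

Edges and causal density use the *bivariate* pairwise measure (a separate
2-node VAR per pair). A conditional time-domain estimator (log-ratio of the
target's residual variance between the full-network VAR and the VAR omitting
the source's lags) is available behind a config switch
(`estimator: conditional`): the pipeline then appends a broadband conditional
causal-density series (band label `broadband`) alongside the band-resolved
bivariate one. Conditional *spectral* decomposition would require partitioned
spectral factorization machinery that is out of scope.

The classical time-domain statistic ln(σ²_restricted/σ²_full) doubles as an
independent oracle: by Geweke's integral identity the mean of f over the full
grid equals the time-domain value. Two caveats that the test suite makes
explicit: the identity needs a fitting order adequate for the *marginal*
process of the target (the marginal of a VAR(2) system is ARMA, so the
cross-check fits order 6), and at near-zero true causality both routes return
pure sampling noise, so relative agreement is only meaningful for systems
with measurable causal strength (the consistency check conditions on
time-domain GC > 0.01 nats).

## Per-window protocol

Pipeline order is fixed: zero-phase 4th-order Butterworth bandpass (1–60 Hz)
and baseline correction (subtracting each node's mean over the first 1000 ms)
on the whole trial; then, per 100 ms window: linear detrend/demean, a
stationarity gate, at most one first-order difference for windows failing the
gate, and the VAR fit with BIC order selection over 1..p_max (default 3 — at
50 samples a bivariate VAR(3) keeps the regression well-posed). Ties in BIC
break toward the smaller order, and candidates are compared on a common
estimation sample.

The gate combines an augmented Dickey–Fuller test (fixed lag 1; automatic lag
selection is unstable at 50 samples) with a KPSS level test, both at 5%:
a window passes only if ADF rejects a unit root AND KPSS does not reject
stationarity (configurable to either-test mode). The decisions are computed
by direct OLS against the standard critical values (MacKinnon for ADF, 0.463
for KPSS 'c') because the batch pipeline gates hundreds of thousands of
windows; unit tests pin the statistics to the statsmodels implementations to
1e-8. Degenerate (constant) windows fail the gate and propagate as missing
values, never as zeros. Windows still non-stationary after one difference are
flagged and retained.

## Binary networks

For every pair, band, and group, task windows are contrasted against the
pooled baseline-window GC values (baseline windows use the same 50-sample
estimator so both sides share the estimator's bias). A one-sided Welch t per
window (task above baseline — the edge semantics) is thresholded at the
pointwise t(0.05) quantile; contiguous supra-threshold windows form clusters
whose summed t-mass is compared against the max-cluster-mass distribution
from 200 permutations that shuffle the task/baseline labels within each
trial. Windows in clusters with permutation p < 0.05 become 1-entries of the
binary directed network. 200 permutations limit the attainable p-resolution
to ~1/201; the count is configurable upward and a warning records the limit.
Missing (flagged) windows are excluded from the contrast and counted in a
coverage report, never imputed.

## Graph metrics

- **Characteristic path length** L: BFS shortest paths on the binary directed
  network, averaged over ordered pairs (j≠i, then over i). Unreachable pairs
  contribute 0 under the default rule — the only convention under which L
  can fall below 1 on sparse networks, as observed summary values do;
  exclude-unreachable and harmonic-mean rules are available, and every result
  reports the reachable-pair fraction.
- **Causal density** CD: mean of the directed GC values over ordered pairs,
  with missing entries excluded and counted.
- **Causal flow**: outgoing minus incoming total influence per node
  (out-degree minus in-degree on binary networks); positive = causal source.
  The standard definition, labeled as such in outputs.

Metric series are produced per window, band, and group; causal density is
additionally computed per subject (mean over the subject's trials), which is
the observation unit for the group comparison.

## Group statistics

Per window, a one-way ANOVA compares the groups' subject-level CD values
(for two groups F = t², cross-checked in the tests). The significance mask is
the uncorrected p < 0.05 decision; reported contiguous spans require ≥ 2
consecutive significant windows, and a Benjamini–Hochberg switch is
available. Phase-level tables give mean ± SD over the windows within each
phase (window-level group values; SD over windows) with a Welch t contrast
between θ and γ and the conventional star coding (* p<0.05, ** p<0.01,
*** p<0.001).

## Synthetic cohort generator

Each node carries a damped AR(2) resonance (poles at r·e^{±i2πf₀/fs});
directed coupling is a lag-1 coefficient switched on only inside scheduled
task-time intervals, giving a piecewise-constant time-varying VAR whose every
segment is checked for stability (companion spectral radius < 1). Trials are
simulated with i.i.d. Gaussian innovations (optional instantaneous
correlation exercises the partial-covariance correction) after a discarded
2 s burn-in; all seeds derive deterministically from a master seed.

Key generator conventions, and why:

- **Damping** defaults to 0.65 (θ) / 0.80 (γ). This is a deliberate
  trade-off: sharply tuned oscillators (r ≥ 0.95, which produce a visible
  spectral peak at the pole frequency) are nearly integrated over 50-sample
  windows — the gate differences almost every window and the band-restricted
  GC estimator's noise concentrates at the peak, swamping any designed
  coupling. At the default damping the spectrum is a broad band-dominant hump
  rather than a narrow peak; the coupling's causal signature remains
  attributable to the source's band. Narrowband tuning remains available per
  node.
- **Single-band tuning per node.** Giving every node both a θ and a γ
  resonance (an AR(4) truth) makes the order-limited window VAR leak the
  coupling across bands and produce reverse-direction false positives, so
  default cohorts alternate θ/γ tuning within the frontal and parietal sets.
- **Group effect**: equal coupling (0.15) during premise coding; gifted 0.45
  vs control 0.15 during premise integration + early conclusion
  (3000–7500 ms); gifted 0.10 vs control 0.35 in the late conclusion
  (7500–9000 ms); θ-tuned frontal→parietal pairs assigned round-robin
  (approximately disjoint — all-to-all coupling dilutes the pairwise
  bivariate GC because every source inflates every target's variance). These
  effect sizes are configuration conventions chosen once so that the designed
  contrast is recoverable by the windowed estimator at cohort scale; they are
  not claims about any real cohort.
- **Cohort sizes** default to the study's structure: 20 subjects / 400 trials
  vs 18 subjects / 380 trials (380 = 2×22 + 16×21).

What the generator does *not* emulate: volume conduction and scalp mixing,
forward-model projection, artifacts, 1/f background, trial-to-trial amplitude
variability, or between-subject random effects. Passing tests therefore
establish estimator and pipeline correctness under a known band-limited VAR
ground truth — not robustness to the full complexity of cortical source
signals.

## Validation problem sizes

The acceptance script and the heavy tests run at desk scale, chosen as the
smallest sizes at which the measured rates are stable: spectral/temporal
consistency over 20 random VAR(2) systems at 5000 samples; null edge
calibration over repeated 20-trial no-coupling cohorts; direction recovery
over 20-trial cohorts with the 0.4 coupling; designed-group-effect recovery
over two-arm cohorts of 8 subjects × 5 trials per arm (windows 30–89 carry
the designed difference); ANOVA type-I calibration over 200 null replicates
of 10 subjects per arm. The study-scale defaults (38 subjects, 780 trials,
40 pairs) run through exactly the same code path.

## Known limitations

- Bivariate (not conditional) spectral GC: common-driver and chain motifs can
  yield spurious pairwise edges; the conditional time-domain switch mitigates
  but does not spectrally decompose.
- 50-sample windows resolve θ only parametrically (the window spans 0.6 θ
  cycles); band averages inherit substantial estimator bias, which the
  baseline-referenced contrast removes only to first order.
- The within-trial label permutation assumes per-window GC values are
  approximately exchangeable within a trial under the null; window-to-window
  dependence beyond the fitted structure would make the test conservative or
  liberal depending on its sign (empirically the family-wise rate is at the
  nominal level; see the calibration test).
- First-order differencing changes the passband weighting of the GC spectrum;
  since it is applied identically to both nodes of a pair and equally to task
  and baseline windows, directional contrasts are preserved.
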
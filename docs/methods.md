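# Methods

## The Ks neuron

Single-compartment Hodgkin–Huxley-type cell with fast sodium, delayed
rectifier, leak and a slow non-inactivating (M-type) potassium current:

    c_m dV/dt = I_syn + I_ext − g̅_Na m∞(V)³ h (V − E_Na) − g̅_Kdr n⁴ (V − E_K)
                − g̅_Ks s (V − E_K) − g_L (V − E_L)
    dx/dt     = (x∞(V) − x)/τ_x(V)        for x = h, n, s

Sodium activation is instantaneous (m∞³ enters the voltage equation
directly; there is no m state variable).  The slow gate s has a
voltage-independent time constant τ_s = 75 ms; its conductance g̅Ks is the
single control parameter of the study, swept over [0, 1.5] mS/cm² as an
inverse proxy for acetylcholine (muscarinic activation suppresses the
M-current).  All quantities are in mV, ms, μA/cm², mS/cm², μF/cm².

Fixed constants and gating functions (recorded in
`src/ratephase/data/ks_model.yaml`, the single versioned source of these
numbers): c_m = 1, g̅_Na = 24, g̅_Kdr = 3, g_L = 0.02 mS/cm², E_Na = 55,
E_K = −90, E_L = −60 mV;

    m∞ = 1/(1+exp(−(V+30)/9.5))      h∞ = 1/(1+exp((V+53)/7))
    n∞ = 1/(1+exp(−(V+30)/10))       s∞ = 1/(1+exp(−(V+39)/5))
    τ_h = 0.37 + 2.78/(1+exp((V+40.5)/6))
    τ_n = 0.37 + 1.85/(1+exp((V+27)/15))

These are the standard constants of this model lineage (Stiefel, Gutkin &
Sejnowski 2009 and the network studies built on it).  With them the cell is
Type 1 at g̅Ks = 0 (continuous onset near I ≈ −0.13 μA/cm², onset rate
< 1 Hz on a 0.02 μA/cm² grid, gain ≈ 42 Hz per μA/cm²) and Type 2 at
g̅Ks = 1.5 (onset jumps to ≈ 7–8 Hz at I ≈ 1.2 μA/cm², gain ≈ 7 Hz per
μA/cm²).  The f/I curve is non-monotone far above onset (depolarisation
block near 7–8 μA/cm²), which the calibration routine works around.

## Synapses

Directed connections carry a normalised double-exponential conductance
pulse driven by the **most recent** presynaptic spike only (no pulse
superposition — the printed formula depends on a single last-spike time):

    g_syn(t) = max( B · [e^{−(Δ−τ_D)/τ_S} − e^{−(Δ−τ_D)/τ_F}], 0 ),  Δ = t − t_spike

with delay τ_D = 0.08 ms, decay constants τ_S = 3 ms, τ_F = 0.3 ms, and B
chosen so the peak is exactly 1 at Δ = τ_D + τ_Sτ_F ln(τ_S/τ_F)/(τ_S−τ_F)
≈ 0.848 ms.  Total input to neuron i is
w_e Σ_j A_ij g_syn,ij (E_E − V_i) + w_i Σ_j A_ij g_syn,ij (E_I − V_i) with
w_e = w_i = 0.02 mS/cm², E_E = 0, E_I = −75 mV.  τ_S = τ_F is rejected at
construction (degenerate normalisation).

## Networks, inputs, noise

300 excitatory + 75 inhibitory neurons.  Each excitatory neuron projects
onto a uniformly chosen 3% of each population (9 E, 2 I targets), each
inhibitory neuron onto 6% (18 E, 5 I; fractional counts round half-up), no
self-connections.  Connectivity, DC patterns and noise schedules are pure
functions of integer seeds (bit-reproducible).  The per-neuron external
drive is constant in time, drawn uniformly over a 2.0 μA/cm²-wide band.

**Calibration.** The band's mean is set by bisection so that an isolated
neuron fires at 10 Hz over the final 5 s of a 7 s run.  Because the f/I
curve is non-monotone, the bracket comes from a coarse upward scan, and
near the Type 2 bifurcation a run only counts as firing if spiking is
sustained through the window (a transient onset volley otherwise fools the
bisection).  Calibration is per-g̅Ks by default: anchoring the mean at the
g̅Ks = 0 value (−0.055 μA/cm²) leaves high-g̅Ks networks almost silent
(~2 Hz, no population bursts), in which state the phase-coding regime does
not exist; recalibrating per condition (e.g. +1.375 μA/cm² at g̅Ks = 1.4)
restores the intended 10 Hz operating point everywhere.  A flag disables
the recalibration for sensitivity analyses.

**Noise** is a per-neuron Poisson schedule (default 1 Hz) of forced spikes:
the event is recorded as a spike, triggers synaptic output, and the
membrane is clamped to the spike peak (+30 mV) for one step so the intrinsic
currents generate the afterhyperpolarisation.

## Integration

Classical RK4, dt = 0.05 ms, 7 s runs with analysis restricted to the final
5 s (experiment drivers default to 3 s / final 2 s at reduced scale).
Spikes are upward crossings of 0 mV with linearly interpolated crossing
times (this removes dt-quantisation from the phase metrics); a one-step
refractory guard prevents double counting.  Initial conditions: V uniform
on [−70, −50] mV, gates at steady state for that voltage, per run seed.
|V| > 500 mV aborts with diagnostics.

The production integrator is numba-compiled.  Two numerical devices keep
the hot loop free of exponentials: gating sigmoids are tabulated on a
0.01 mV grid and linearly interpolated (interpolation error ~1e−6, far
below RK4 truncation error at this dt), and the synaptic exponentials are
advanced by constant per-step decay factors and restarted analytically on
each spike.  The readable reference implementation of the same equations
lives in `model.py` and the test suite cross-checks the two paths.
Halving dt shifts single-neuron spike times by < 0.1 ms per second of
model time.

## Analysis

* **Rates / COV** — spike counts over the analysis window; COV is the
  across-neuron std/mean (undefined marker for silent rasters).
* **Pairwise phase / MPC** — φ_ijk = 2π (t_k^i − t_−^j)/(t_+^j − t_−^j)
  for spikes of i bracketed by consecutive spikes of j; coherence is the
  modulus of the mean complex phase (the modulus makes r ∈ [0, 1], as the
  verbal definition requires).  Pairs qualify only if both neurons fired
  ≥ 30 spikes in the window (scaled proportionally when the window is
  shorter than 5 s, e.g. 12 spikes for 2 s).  The population summary pairs
  every qualifying excitatory neuron with one inhibitory reference — the
  lowest-index inhibitory neuron qualifying in *every* run of a cohort, so
  mean phases are comparable across runs; the network MPC is the mean
  coherence over qualifying pairs.
* **Bursts** — population spike counts in 0.05 ms bins convolved with
  exp(−t²/σ²), σ² = 1 ms² (taken literally, t in ms), on ±10 ms support; a
  burst is a contiguous region above 10% of the neuron count, padded by
  10 ms and merged when padded windows overlap.  Burst order similarity is
  the Spearman correlation of first-spike times over shared participants
  (≥ 3 required), ties broken by neuron index.
* **Similarity S** — per-run feature vectors (rates; or mean phases
  embedded as [cos, sin] to avoid wrap-around).  The default mode is the
  Pearson correlation of the raw vectors over neurons valid in both runs.
  A PCA mode (centre across runs, project on the leading axis, normalise by
  the full centred norms) and an unnormalised dot mode are provided, but
  projecting on a single principal axis cannot represent three or more
  distinct group means — with many realizations it leaves some groups with
  near-zero within-group similarity — so it is not the default.
* **NS score** — per realization i, NS_i = (⟨S within i⟩ − ⟨S between i
  and the rest⟩)/2, diagonal excluded.  The halving (rather than squaring)
  is used because a squared score cannot be negative, contradicting the
  score's stated −1 anchor; a `squared` switch exposes the other reading.
  With S ∈ [0, 1] features the attainable ceiling is 0.5 (identical within,
  orthogonal between); 0 exactly when grouping is irrelevant.  Scaled
  variants multiply by the group's mean COV (frequency) or mean MPC
  (phase) to discount narrow-band or unlocked cohorts.  The chance control
  scrambles the neuron assignment independently within each run.

## Experiments

Structure-varying (20→5 wirings × one pattern) and input-varying (one
wiring × 20→5 patterns) designs run `runs_per_realization` simulations per
realization with fresh initial conditions and noise, then score NS for
frequency and phase with scrambled controls.  All seeds derive from one
master seed; re-running a plan is bit-identical.  Failed runs are logged
and excluded, never imputed.

The offset experiment drives 20 random excitatory neurons with an extra
constant current (grid up to 1.95 μA/cm²).  At g̅Ks = 0 the readout is the
subset-minus-rest mean rate; at g̅Ks = 1.5 it is the subset-minus-rest
circular mean burst phase.  The phase reference is the Gaussian-smoothed
population rate: its per-burst maxima form a reference event train, every
excitatory spike bracketed by consecutive maxima gets the standard cycle
phase, and each neuron is reduced to its circular mean.  This all-spike
estimator was chosen over a first-spike-per-burst readout because a
strongly driven subset fires between bursts as well (≈ 23 Hz against an
≈ 11 Hz rhythm at the largest offset), which pins a first-spike statistic
to the burst-window edge and destroys its monotonicity; the bracketed-phase
estimator degrades gracefully and keeps the lead visible.  At the reference
settings the rate readout is perfectly monotone in the offset and the phase
readout is monotonically decreasing (subset leads ever earlier).

The robustness scan repeats a design over a grid of noise rates or
excitatory couplings (w_e ∈ [0, 0.04] mS/cm²).

## Scale of the shipped defaults

The experiment drivers default to 5 realizations × 5 runs × 3 s with
g̅Ks ∈ {0.0, 1.4} — the smallest design in which the four directional
contracts (COV falls, MPC rises, frequency-NS dominates at low g̅Ks,
phase-NS at high g̅Ks, each above its scrambled control) are testable by
exact one-sided sign tests across realizations at α = 0.05.  A full-scale
design (20 × 50 × 7 s × many g̅Ks values) is cluster-sized and is reached
purely through `ExperimentPlan` parameters.

## What the surrogates do and do not show

The synthetic rasters (Poisson, phase-locked, grouped cohorts) validate
the *metrics*: planted rate or phase structure is recovered, nulls score
zero, boundaries (MPC 0/1) are exact.  They contain no biophysics — no
refractoriness, adaptation, E/I interaction or common drive — so passing
metric tests on surrogates says nothing about the network model itself;
that evidence comes from the simulator-based protocol and experiment tests.

## Known limitations

* The network at g̅Ks = 0 with the printed coupling (w_e = w_i = 0.02) runs
  hot (population mean ≈ 130 Hz): recurrent excitation dominates because
  the inhibitory driving force near rest is small.  The rate-coding
  contracts hold there, but the across-neuron COV is compressed by f/I
  saturation; at weaker coupling (w_e ≈ 0.005–0.01) the rate spread is much
  wider.  The COV contrast between the two g̅Ks poles is therefore small
  (though consistent in sign across realizations) at the printed weights.
* Only the most recent presynaptic spike drives a synapse; at very high
  presynaptic rates this under-counts synaptic charge relative to a
  superposing synapse.
* The forced-noise spike mechanism (one-step clamp to +30 mV) is one of
  several defensible readings of "randomly induced spiking"; it is isolated
  behind `inject_noise_spikes` plus a single clamp constant.
* Gating-table interpolation and the incremental synaptic exponentials make
  the jitted path agree with the closed-form reference only to ~1e−5;
  bit-exact determinism holds within a path, not between them.
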
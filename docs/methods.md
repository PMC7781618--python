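# Methods

## Scope and model

`cavgating` analyses (and simulates) whole-cell voltage-clamp recordings of
Cav1.3-type Ca²⁺ currents.  The biophysical forward model is deliberately
the *same* functional form the estimators assume: a Boltzmann-gated
conductance with an ohmic (linear) driving force,

    I_chan(t) = G_max · m(t) · h(t) · (V(t) − V_rev),

not a GHK permeation model — the peak I–V fit used downstream assumes
linearity, and using it in the simulator keeps generator and estimator
self-consistent, so recovery errors measure the pipeline rather than a
model mismatch.  Units are mV, ms, nS, pA, pF throughout (nS·mV = pA).

Gates relax exponentially toward their voltage-dependent steady states on
each constant-voltage segment, so sweeps are evaluated in closed form with
no integration error:

* activation `m`: single exponential, default `tau_act = 0.5 ms`.  No
  activation time constant is tabulated for these constructs; 0.5 ms is
  fast relative to the 20-ms test steps, which is the regime the peak-based
  analysis assumes.
* inactivation `h`: weighted sum of two exponentials (`frac_fast`,
  `tau_fast`, `tau_slow`) relaxing toward the modified-Boltzmann
  availability `h∞(V) = (1 − p)/(1 + exp[(V − V₀.₅,inact)/k]) + p`.
  Defaults `tau_fast = 80 ms`, `tau_slow = 1000 ms`, `frac_fast = 0.55`
  make inactivation minor during 20-ms steps while bringing a 5-s
  conditioning step within 1% of steady state (`exp(−5000/1000) ≈ 0.7%` of
  the gap), which is why SSI fits recover `h∞`.  True Cav1.3 inactivation
  is multi-exponential and Ca²⁺-dependent; six r-value time points cannot
  identify such kinetics, so these constants are conventions, constrained
  only when a printed r-value row is explicitly fitted
  (`fit_rvalue_decay`).
* passive membrane: ohmic leak `g_leak (V − E_leak)` (defaults 1 nS, 0 mV —
  leak is strictly linear so P/4 subtraction has an analytic zero), a
  capacitive transient `c_m ΔV/τ_cap · exp(−t/τ_cap)` at every step edge
  (default `τ_cap = 0.2 ms`), and i.i.d. Gaussian current noise (default
  SD 5 pA).

## Protocols and voltage bookkeeping

Protocols are declared in nominal (amplifier) voltages; the simulator
shifts them by the liquid junction potential (−9.3 mV) to get the true
membrane potential, and the analysis applies the same correction once, at
preprocessing.  All reported voltages are therefore on the corrected scale
(nominal −80 mV holding → −89 mV).  Defaults: I–V, 20-ms steps from −89 to
+71 mV (corrected) in 5-mV increments (50-ms steps selectable); SSI, 20-ms
control and test pulses to V_max around a 5-s conditioning step, −119 to
+1 mV in 10-mV increments; INACT5S, one 5-s pulse to V_max.  V_max is
located per cell from that cell's own simulated I–V family.  The 30-s
intersweep interval is carried as metadata only (no rundown is modelled).

## Synthetic cohorts

A cohort is built from a mean parameter set plus between-cell variability:
voltages and slopes normal, `G_max` and the inactivation time constants
log-normal with a mean-preserving −σ²/2 offset, slopes truncated at 0.5 mV,
fractions clipped to [0, 1], `c_m` normal(20 pF, 4 pF) truncated above 5 pF
(typical HEK values).  When a cohort emulates a published table row, the
between-cell SD is reconstructed as SEM·√n from the printed SEM and n —
i.e. the dispersion those SEMs imply.  `G_max` defaults to the value giving
a ≈ 400 pA quasi-steady peak (mid QC window) with log-normal σ = 0.3, so
nearly all cells pass QC; `qc_outlier_fraction` deliberately pushes cells
outside the window to exercise the exclusion logic.  Every draw is
reproducible from `(seed, cell_index)`.

What the generator does **not** emulate: series-resistance voltage errors,
Ca²⁺-dependent inactivation, rundown, seal degradation, filtered/correlated
noise.  Passing recovery tests therefore demonstrate the *estimator chain*
is unbiased under the stated noise model, not that real recordings are free
of those artefacts.

## Preprocessing

* Leak subtraction.  Offline: leak conductance from the steady current of a
  50-ms −80→−90 mV reference step (channel closed at both levels), then
  per-sweep baseline + `g_leak·ΔV(t)` removal.  Online P/4: four inverted
  quarter-amplitude subsweeps from the holding potential (never entering
  the activation range); the scale factor is derived from the stored
  command waveforms, so linear leak *and* capacitive transients cancel
  exactly.  Both are exact for linear leak (residual < 10⁻⁹ pA in
  noise-free tests).
* Peak extraction.  The peak is the signed value of the largest-|I| sample
  after a ±0.2-ms moving average applied inside the search window only
  (earliest sample on ties; stored traces are never smoothed).  Inward
  currents are negative; beyond V_rev the same rule returns the outward
  limb needed to extrapolate V_rev.  The search starts 2.5 ms after the
  step edge: with `τ_cap = 0.2 ms` and typical `c_m`, the ~16-nA transient
  has decayed to < 0.1 pA by then, whereas at 1 ms (5τ) ~100 pA would
  remain and corrupt the small outward-limb currents.
* QC: cells with |peak at V_max| < 100 pA or > 1000 pA are excluded
  prospectively, with the reason recorded; the rule is idempotent and
  per-cell.

## Fitting

All fits are bounded nonlinear least squares with deterministic,
data-driven initialisation (I–V: V_rev from the zero crossing of the
outward limb, V₀.₅ from the half-maximal inward current, slope 8 mV);
slope factors are bounded to [0.5, 30] mV and plateau to [0, 1], and a fit
pinned at a bound is flagged non-converged and excluded from summaries.

The G–V transform divides by the cell's own fitted V_rev and drops points
within 5 mV of it (0/0 amplification).  The G–V Boltzmann is fitted by
weighted least squares with weights ∝ |V − V_rev|: peak-current noise is
approximately homoscedastic, so conductance noise scales as 1/(V − V_rev)
and the weights restore the current-space noise model.  Unweighted fitting
lets the points just beyond the 5-mV exclusion dominate and biases the
cohort-mean V₀.₅ by ~+0.4 mV at the default noise; with weights the
residual bias is ≈ +0.1 mV.

r-values are read as the mean current over ±2 ms around each time point
(clipped to the pulse interior at 5000 ms), normalised to the extracted
peak.  Because the measurable peak sits ~3 ms into the decay, re-extracted
r-values exceed the generating decay by up to ~1–3% of itself (largest for
r50); the same normalisation is inherent to any peak-referenced measurement.
The SSI ratio (test/control peak) carries the analogous effect plus the
~0.7% conditioning non-equilibration, which together overestimate the
non-inactivating percentage by roughly +0.5 points noiseless and +1.5
points at 5 pA noise — V₀.₅,inact and k_inact are essentially unaffected.

## Statistics

Summaries are mean ± SEM (SD/√n, ddof = 1) per construct, computed after
dropping QC-excluded and non-converged cells.  Two groups: unpaired
two-sided equal-variance Student's t (df = n₁ + n₂ − 2); zero pooled
variance with equal means returns (t = 0, p = 1), with unequal means it is
an error.  Three or more groups: one-way ANOVA, then pairwise t-tests using
the pooled within-group variance and the ANOVA error df, Bonferroni-scaled
by the size of the comparison set — each variant vs its reference construct
by default (matching how such tables are starred), all-pairs by flag.
Stars: * p < 0.05, ** p < 0.01, *** p < 0.001.  The ANOVA p agrees with a
10⁴-draw permutation null within Monte-Carlo error, and the vs-reference
raw test rejects a true null in 5% ± 1.5% of 1000 seeded replicates.

## Validation against the published tables

With no raw recordings deposited, validation is simulate-then-recover
(`cavgating.validation`): cohorts are generated from a printed table row
(means = printed values, SD = SEM·√n, published n), the full pipeline runs
on the simulated sweeps, and the recovered cohort mean is compared with the
printed value within ±2 printed SEM, requiring ≥ 9 of 10 seeded replicates.
For the r-value row, a bi-exponential-plus-plateau decay is first fitted to
the six printed r-values (the availability midpoint is placed far below
V_max so the decay's long-time limit equals the fitted plateau exactly);
per-cell kinetic variability uses a σ = 0.25 log-normal factor on both time
constants, SD 0.05 on `frac_fast`, and a plateau SD implied by the printed
r5000 SEM.  The S652L comparison checks the mean recovered activation and
inactivation shifts over 10 replicate cohort pairs against the printed
−12.1 / −19.0 mV within ±1.5 mV (a single pair's shift has ~1 mV sampling
SD from the SEM-implied cell dispersion alone, so averaging isolates the
pipeline's systematic error from the generator's sampling noise).

Problem sizes: cohorts are ≤ 44 cells sampled at 20 kHz (dt = 0.05 ms);
an I–V family is 33 sweeps of 35 ms, an SSI family 13 sweeps of ≈ 5.6 s.
The closed-form sweep evaluation makes a full three-protocol cohort a
sub-second to few-second computation.

## Known limitations

* Kinetic parameters (`tau_act`, `tau_fast/slow`, `frac_fast`) are
  under-determined by the steady-state tables and treated as conventions.
* The peak-referenced normalisations bias r50 and the non-inactivating
  percentage slightly upward (quantified above); noiseless, idealised
  configurations recover all parameters to < 0.01 mV.
* Whether the original SSI analysis used peak or mean test-pulse current is
  unknown; peak is assumed.  Whether G is normalised by fitted or observed
  maximal conductance is likewise unknown; the fitted G_max is used (the
  fit equation has a free scale).
* No ABF (binary Axon) reader: the tab-separated text dialect and the HDF5
  container are the interchange formats.
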
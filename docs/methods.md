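# Methods and design notes

## The cortisol model

The model treats the adrenal response as an open loop: measured (or
synthetic) ACTH drives cortisol production through a sigmoidal dose–response
H(A) = A^m / (K_A^m + A^m) evaluated on the input 10 minutes earlier, and
two first-order compartments — fast (λ_f) and slow (λ_s > λ_f) — accumulate
the product. Opening the loop trades mechanistic completeness (no
CRH/pituitary feedback, no explicit cortisone interconversion, no cytokine
inputs) for a small parameter count and the ability to use one measured
hormone as the other's input. Consequences to keep in mind:

* ultradian structure in cortisol is inherited from the ACTH input, not
  generated by the model;
* cytokine effects can only appear as *misfit* — which is precisely what
  the residual analysis exploits;
* the six parameters are interpretable but only partially identifiable
  (see *Identifiability*).

**Initial condition.** The fast compartment starts at quasi-equilibrium
with the delay-clamped drive at the record start,
C_f(0) = p_f λ_f H(A(0)), and the slow compartment absorbs the remainder
of the observed initial cortisol, C_s(0) = max(C_obs(0) − C_f(0), 0).
Before the record, A(t − delay) is clamped to the first sample rather than
inventing pre-record history.

**Integration.** The states are linear given the drive, so stiffness is
mild; `simulate_cortisol` uses fixed-step classic Runge–Kutta with the
piecewise-linear input evaluated at stage times (default sub-step 0.5 min;
agreement with a 0.01-min reference is ≤ 1e-9 relative on pulsatile
inputs). The ensemble fitter instead advances each compartment with the
*exact* exponential update over 2.5-min sub-intervals, linearizing the
drive between knots: this is unconditionally stable for the fastest
turnover draws (λ_f → 1 min) and vectorizes across 10⁵–10⁶ parameter sets;
its discrepancy against the reference path is ~2e-4 in ε, far below the
search resolution.

**Units.** A in ng/l (numerically identical to pg/ml as assayed), C in
nmol/l, time in minutes. K_A is in ng/l; the value 50.28 used for the
fixed-sensitivity scenario is adopted on that scale.

## Ensemble calibration

Pure random search, by design: the goal is the *distribution* of
well-fitting parameter sets, not one optimum, so no gradient or MCMC
machinery is used. Defaults: 10⁶ draws, keep the lowest-ε 0.1%. Sampling
ranges (log-uniform unless noted): p_f, p_s ∈ [10⁻¹, 10³] nmol l⁻¹ min⁻¹,
λ_f ∈ [1, 60] min, λ_s ∈ [30, 600] min, K_A ∈ [1, 500] ng/l, m uniform on
the integers 1..5; λ_f < λ_s enforced by rejection. The production-rate
range is wide because the drive H̄ of a healthy profile is small (~0.1), so
physiological cortisol levels require composite gains p_f λ_f + p_s λ_s of
order 10³.

The fit error is the range-normalized RMSE,
ε = RMSE(pred, obs) / (max(obs) − min(obs)) — dimensionless,
offset-sensitive, infinite for a constant observation. On good fits to
synthetic subjects it produces magnitudes in the 0.02–0.14 range.

**Identifiability.** On self-generated data the composite drive gain
(p_f λ_f + p_s λ_s)·H̄ is recovered within a few percent while p_f or λ_f
individually spread over an order of magnitude (relative-IQR ratio > 10).
Only products of production and turnover are constrained by the
trajectory; the test suite asserts this rather than hiding it.

**Scenarios.** `free_KA`, `fixed_KA` (K_A = 50.28, the control median),
`fixed_m` (m = 2) and `fixed_both`. Residual analysis uses `fixed_both`,
the configuration under which group comparisons of the slow parameters are
made.

## Synchrony battery

* **TLCC** — Spearman correlation of the pair at every integer multiple of
  the sampling step within ±180 min; positive lag means ACTH leads. Ties
  break toward the smallest |lag|.
* **RWTLCC** — TLCC restricted to rolling epochs. Defaults: 360-min
  windows, 60-min steps, per-epoch lag range ±120 min. The per-epoch
  window must cover 2·max_lag + 3 samples for every lag to have at least
  three pairs, which is why the epoch lag range is narrower than the
  whole-record one.
* **μ_lag** — the classifier's lag evidence is the *epoch-mean* RWTLCC
  peak lag. On 24-h records with circadian amplitude, the whole-record
  rank correlation can peak at ±one ultradian period (pulse k aligning
  with pulse k+1); bounding the lag search to the ultradian scale inside
  each epoch removes that alias, and the mean across epochs is the natural
  summary of a lag that is (or is not) stable over time.
* **Synchrony stability** — fraction of epochs whose peak lag falls within
  2 sampling steps of the modal peak lag: 1.0 is a vertical stripe in the
  RWTLCC heat map.
* **IPS** — both series are z-scored, band-passed to ultradian periods
  (60–480 min, second-order zero-phase Butterworth), Hilbert-transformed,
  and compared as 1 − |sin(Δφ/2)| ∈ [0, 1]. The formula maps zero phase
  difference to 1 and antiphase to 0. Filter and Hilbert edge effects
  extend about two oscillation periods into the record; analytic accuracy
  (±0.02) holds in the interior.
* **Rolling Pearson r** — centered 60-min windows; windows with
  numerically negligible variance (< 1e-4 of the trace range) are flagged
  missing rather than reported as spurious values.
* **Period** — first prominent positive autocorrelation peak of the
  6-h-moving-average-detrended trace, falling back to the mean inter-pulse
  interval; constant or single-pulse records raise an undefined-period
  error that callers (the classifier) handle.
* **Pulse count** — interior local maxima with prominence ≥ 20% of the
  trace range and ≥ 60 min separation; boundary extrema never count, so a
  monotone ramp has zero pulses.

## Phenotype classification

Rules fire in order on (pulse count, period, μ_lag, stability):

1. ≤ 1 pulse → **single_pulse**;
2. exactly 2 pulses, period ≥ 240 min, stability ≥ 0.7 → **two_pulse**;
3. ≥ 3 pulses, period ≤ 210 min, |μ_lag| ≥ 40 min → **multiple_pulse**;
4. ≥ 3 pulses, |μ_lag| ≤ 20 min, stability ≥ 0.7 → **control_like**;
5. otherwise the nearest rule under a normalized hinge distance (periods
   scaled by 60 min, lags by the 40-min dissociation threshold, stability
   by 0.3; an undefined period counts one full unit against
   period-dependent rules), with control_like excluded for ≤ 2 pulses.

The numeric thresholds operationalize qualitative group boundaries
(physiological T_u ≤ 3 h; near-physiological lag ≈ 10–13 min vs
dissociated ≈ 77–106 min) and are all exposed in `AnalysisConfig`. The
rule trace in every call records which rules fired or were skipped.

## Synthetic-data generator

The generator is first-class, seeded code that defines the study
conditions the pipeline is tested under.

* **ACTH** is a train of Gaussian pulses (FWHM ≈ 30 min) on a baseline.
  Controls: 24-h records, inter-pulse intervals uniform in [150, 180] min,
  a raised-cosine circadian envelope peaking at the record start (08:00)
  scaling both baseline (3–14 ng/l) and pulse amplitudes, and lognormal
  amplitude jitter (sd 0.4) — strong pulse-to-pulse amplitude variation is
  physiological and also prevents rank-correlation period aliasing.
  Surgical regimes: 12-h records, flat 3-ng/l baseline, regime-specific
  pulse placement (two pulses 300–360 min apart; pulses every ~120 ± 15
  min; one broad excursion peaking ~2 h post-surgery), amplitudes
  calibrated so a mixed panel shows ≈ 6× the control ACTH AUC and ≈ 2× the
  cortisol AUC over 12 h.
* **Cortisol** is always generated mechanistically by the model.
  Control-like parameters (p_f = 325, p_s = 0.8, λ_f = 2.5, λ_s = 300,
  K_A = 50.28, m = 2) are strongly fast-dominated: rapid turnover tracking
  the delayed drive is the configuration consistent with the ~10-min
  peak-association lag of healthy profiles — a slow-dominated trace buries
  that lag under its asymmetric decay tail. Regime parameters vary this
  base per the fitted-parameter story (two-pulse: longer λ_s;
  multiple-pulse: lower K_A; single-pulse: higher slow production with
  faster slow turnover), with surgical gains scaled down against the
  saturating drive so 6× ACTH maps onto 2× cortisol.
* **Initial condition**: cortisol starts from the steady state at the
  early-record mean ACTH. A burn-in would be marginally more realistic but
  would break the exact zero-noise contract (observed cortisol ==
  sampled model output); the fast compartment equilibrates within ~λ_f
  anyway.
* **Dissociation** is produced by warping the cortisol trace in time,
  c(t − δ(t)): constant δ (stable), δ ramping in across the surgery window
  (partial), or per-2-h-epoch random δ smoothed over 40 min (unstable).
* **Cytokines** rise from ~1% of peak only after the surgery midpoint with
  mediator-specific onsets, time constants and peaks (IL6 250, TNFα 25,
  IL10 150, IL8 60 pg/ml), gamma-shaped rise-and-decay, 3% multiplicative
  noise. A coupling gain g adds g × mediator trace to cortisol (clipped at
  zero) and records the disturbance; negative g models cytokine-driven
  cortisol suppression. Suppressive couplings are the discriminating test
  case: an *additive* hump is largely absorbed by the ensemble fit (it is
  collinear with the model's own slow response), whereas suppression
  cannot be mimicked by non-negative production.
* **Observation noise** is multiplicative Gaussian (default 5%, clipped at
  zero) on both hormones, matching assay-scale variability.

What the generator does **not** emulate: assay noise floors and
limit-of-detection censoring, inter-assay drift, closed-loop feedback
(cortisol never influences synthetic ACTH), between-subject parameter
heterogeneity beyond seeded pulse-placement/amplitude variation, and
missing-sample patterns. Passing tests therefore demonstrate internal
consistency of the pipeline under its own assumptions, not clinical
validity on real records.

## Numerical conventions

* Time grids are uniform; spacing jitter ≤ 1% of the step is snapped.
* Missing values are NaN, never zero; mediators that were inconsistently
  detected stay present but flagged.
* Z-scoring uses the sample (n−1) standard deviation throughout; additive
  mediator combinations are sums of individually z-scored members,
  re-z-scored.
* Signed difference series (residuals) carry a `signed` metadata flag to
  bypass the non-negativity check that applies to concentrations.
* PCA pools post-surgery-onset time points across subjects, variables
  being per-subject z-scored mediators.
* Problem sizes in the test suite: recovery fits run 10⁶ draws (the full
  search scale; ~10 s vectorized), other ensemble fits 2·10³–5·10⁴ draws;
  synthetic panels use 2–3 subjects per regime over a handful of seeds.

## Known limitations

* The lag evidence saturates at the per-epoch lag bound (±120 min); lags
  beyond it are reported at the bound.
* Rank-based TLCC on smooth noiseless traces is sensitive to baseline
  micro-structure; the generator's observation noise reflects reality and
  stabilizes the estimator, but exact-arithmetic inputs can still bias the
  whole-record peak toward positive lags.
* With a single excursion, epochs far from the pulse carry little
  correlation structure, so single-pulse stability scores are noisy — the
  classifier deliberately does not use stability for that class.
* ε is not comparable across subjects with very different cortisol ranges
  (it is range-normalized per subject by construction).
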
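# Methods

## System and scope

`luxlink` models two *E. coli* populations confined to the two halves of a
microfluidic trapping chamber separated by a cellulose-nanofibril (CNF)
filter.  The filter passes small molecules (the quorum-sensing signal AHL)
but not cells, so each side holds a genetically distinct population at a
stable density.  The package covers: (i) the gene-circuit dynamics of the
five canonical sender/receiver layouts, (ii) a fixed-step delay-equation
integrator, (iii) transport estimates for the filter (exchange rate,
diffusion time), (iv) the particle-sieving porosity assay and its cutoff
estimator, (v) trace analyses (peaks, period, synchrony, phenotype calls),
and (vi) synthetic-data generation so every stage runs without external
inputs.  It does not model intra-compartment spatial gradients (the
compartments are well mixed), stochastic gene expression, or image
processing — the unit of analysis is an already-extracted trap-averaged
fluorescence trace.

## Circuit model

State per population: cell density ρ (fraction of trap capacity), protein
levels I (LuxI), A (AiiA), G (reporter) in arbitrary units, and compartment
AHL concentration H in nM.  Time is in minutes throughout.

* **Growth** is logistic, `r = ln(81)/180 ≈ 0.0244 /min` with ρ(0) = 0.1, so
  density reaches 0.9 three hours after loading — matching when induction is
  applied in the stable-communication experiment.
* **Promoter.** *lux*-driven cassettes follow a delayed Hill activation
  `P(h) = δ + α·h²/(C0² + h²)` with basal leak δ = 0.02, span α = 1, half
  activation C0 = 30 nM, and a transcription–translation delay τ_d.  LuxR is
  constitutive and non-limiting and is folded into the Hill form.
  Arabinose-driven cassettes are an ideal 0→1 step at the induction time
  (no dose information is modelled).
* **Sensed AHL.** The promoter reads the *intracellular* AHL level `h`, the
  quasi-steady balance of membrane influx `k_in(H − h)` against intracellular
  hydrolysis `k_cat·A·h/(K_M + h)` (positive root of the resulting
  quadratic).  With no lactonase, h = H exactly.  This term is what lets a
  lactonase-loaded receiver stay dark while the compartment around it is full
  of signal: quenching happens in the cytoplasm, upstream of LuxR, and is
  limited by the membrane exchange rate k_in rather than by the much faster
  filter exchange k_x.
* **Protein turnover.** LuxI and the reporters carry ssrA/LAA degradation
  tags and compete for a shared, saturable ClpXP pool:
  rate `γ_E/(1 + (I+G)/K_clp)` per molecule.  AiiA is degraded through its
  own saturable pathway `γ_A·A/(K_A + A)`: it does not load the ClpXP queue,
  and its near-zero-order decay makes the AiiA pool an integral controller —
  production balances the fixed capacity γ_A only when the time-averaged
  promoter activity equals γ_A/κ_A, so a population adapts its mean response
  to sustained signal while still passing transient waves.  A shared pool for
  all three proteins was tried first and rejected: identical specific
  degradation rates lock the AiiA:LuxI ratio within a population, which
  structurally cancels the sender's own negative feedback (no parameter
  choice oscillates; verified both by characteristic-root analysis of the
  delay system and by direct simulation across wide parameter scans).
* **AHL kinetics.** Synthesis `b·I·ρ/(1 + I/K_syn)` saturates in LuxI
  (substrate/precursor limitation); without this saturation the positive
  feedback has no intrinsic bound and the circuit is bistable rather than
  oscillatory at any parameter set compatible with ignition from the basal
  leak.  Removal is Michaelis–Menten lactonase activity
  `k_cat·A·ρ·H/(K_M + H)`, washout μ_H·H, and inter-compartment exchange
  `k_x(H_q − H_p)`; exchange is forced to zero when the filter is replaced by
  a solid block.

### Shipped parameters (`default-v1`)

| symbol | value | unit | meaning |
|---|---|---|---|
| δ, α | 0.02, 1.0 | – | promoter leak and span |
| C0, n | 30, 2 | nM, – | Hill half-activation and coefficient |
| τ_d | 5 | min | expression delay (calibrated) |
| κ_I, κ_A, κ_G | 7, 15, 3.2 | a.u./min | synthesis rates (sender reporter) |
| κ_G receiver | 14 | a.u./min | sfGFP cassette (brighter, stronger RBS) |
| γ_E, K_clp | 3.5 (calibrated), 1 | a.u./min, a.u. | ClpXP capacity and saturation |
| γ_A, K_A | 2.25, 1 | a.u./min, a.u. | AiiA degradation |
| μ | 0.005 | /min | dilution (growth stalls at capacity) |
| b, K_syn | 56, 1.2 | nM/(min·a.u.), a.u. | AHL synthesis and LuxI saturation |
| k_cat, K_M | 2, 50 | /(min·a.u.), nM | lactonase kinetics |
| k_in | 0.7 | /min | cell-membrane AHL exchange |
| μ_H | 0.05 | /min | AHL washout |
| k_x | 8.8 | /min | compartment exchange (filter) |
| r, ρ0 | 0.0244, 0.1 | /min, – | growth |

AHL is reported in nM but its absolute scale is arbitrary (trap volumes and
cell counts are not quantified), so b was chosen to place the oscillating AHL
swing across the Hill half-activation; protein units are arbitrary
fluorescence-equivalent amounts.  (τ_d, γ_E) are not hand-set: they are the
output of `calibrate_period` on the full oscillator against a 60-minute
target over τ_d ∈ {5, 8, 11, 14, 17, 20} min × γ_E ∈ {3.0, 3.5, 4.0}
a.u./min, which selects (5, 3.5) with an achieved period of 64 min.  The γ_E
grid starts at 3.0 because below that the ClpXP capacity γ_E·K_clp falls
under the receiver reporter load and the quenched-receiver phenotype (dark
receiver when only the receiver carries *aiiA*) is lost; the calibration is
restricted to the regime where all four observed phenotypes hold.

### What the calibrated model reproduces — and what it does not

With `default-v1`, at the solver defaults:

* full oscillator: sender and receiver both oscillate with a 64-min period,
  >20 post-transient peaks over 30 h, amplitude CV of the last ten peaks
  < 0.01, and zero median receiver-sender peak lag at 3-min sampling;
* blocked filter: the receiver never exceeds its basal leak level;
* no receiver feedback: the receiver climbs to ~3.4× the oscillator
  receiver's peaks and stays high on average — but its trace keeps the
  sender's wave envelope (trough/peak ≈ 0.2), so the four-way classifier
  labels it *oscillatory* rather than *accumulating*.  With the promoter span
  pinned at α/δ = 50 and the zero-order ClpXP drain, a monotone plateau
  between waves is not reachable at parameter sets that simultaneously keep
  the quenched topology dark and the period near one hour; this is a known,
  documented gap between the model family and that qualitative read-out;
* no sender feedback: the receiver stays below 5% of the oscillator
  receiver's peak amplitude (classified *suppressed*) while the sender
  accumulates its signal;
* the receiver's *first* response is ~0.6× its steady peaks, not larger: the
  limit cycle is approached from below (waves grow with cell density), and
  the inter-wave residue of receiver AiiA is too dilute to attenuate later
  responses, so the experimentally observed initial overshoot of the
  responder is not reproduced.

## Solver

Classical fixed-step RK4 with a per-step history buffer of the sensed AHL of
both populations; delayed values are linear interpolations into that history
(pre-history for t < 0 is the constant initial state).  Defaults: dt = 0.05
min (the 5-min delay is resolved by 100 steps), recording every 1 min,
300 min of transient discarded before any period statistics.  Fixed stepping
was chosen over adaptive embedding to keep delayed lookups trivial and
output bit-reproducible.  Round-off excursions in (−1e−9, 0) are clamped to
zero; anything more negative aborts with the offending field and time, since
that indicates instability rather than rounding.  Halving dt changes every
recorded channel by < 1e−4 of its scale, and the trajectories agree with an
independently coded first-order Euler integrator (Richardson-extrapolated to
second order; a raw Euler at dt = 0.001 carries ~5e−3 discretization error
of its own on oscillatory runs) to better than 1e−3 on all five topologies.

## Transport and porosity

* Exchange rate: quasi-steady Fickian flux through the filter,
  `k_x = 60·D·A_f/(L_f·V_c)`; defaults D = 490 µm²/s (literature value for
  AHLs in water), A_f = 48 µm² (30 µm filter width × 1.6 µm trap height),
  L_f = 10 µm, V_c = 16 000 µm³ → 8.82 /min.
* Diffusion time: 1-D mean-first-passage `τ = L_eff²/(2D)` with
  L_eff = 100 µm → 10.2 s, well under a minute.
* Sieving: ideal mode passes a particle iff diameter ≤ cutoff (inclusive);
  logistic mode passes with probability `1/(1+exp((d−cutoff)/width))` for
  imperfectly packed filters.  High-pressure packing cutoff 24 nm,
  low-pressure 42 nm.
* Cutoff estimator: the sample maximum of the passed diameters —
  conservative (never exceeds the true cutoff of an ideal sieve) and
  consistent (error ~ range/(n+1) for a uniform sample); a 99th-percentile
  variant is provided for contaminated samples.

## Analyses

Traces are resampled to the imaging interval (3 min for oscillation
experiments, 6 min for stable-communication experiments) by linear
interpolation.  Peaks are strict local maxima filtered by prominence
(≥ 0.2 of the channel range, making detection invariant to amplitude
rescaling) and separation (≥ 15 min, a quarter of the expected period,
keeping the higher of two close peaks).  Period = median inter-peak
interval.  Synchrony: each receiver peak matches the nearest sender peak
within half a sender period; lags are signed receiver-minus-sender; the
first receiver peak is excluded by default as the initial transient.
Phenotype classification, evaluated in order: *silent* (max ≤ 2× the basal
leak level — computed from the ClpXP-aware steady state of an uninduced
reporter, not the far looser no-degradation bound), *suppressed* (max < 5%
of a supplied reference peak), *oscillatory* (≥ 3 peaks whose intervening
troughs drop below 0.5 of the adjacent peaks), *accumulating* (final value
≥ 0.8 of the maximum, well above basal); anything else falls to the nearest
label with a degraded-confidence flag.  All thresholds are keyword
arguments.

## Synthetic data

The noise model is multiplicative plus additive Gaussian
(`out = clean·(1+ε_rel) + ε_abs`, clamped at zero) with σ_rel = 0.05 and
σ_abs = 0.5 a.u. — roughness comparable to trap-averaged intensity traces.
It emulates detector/segmentation noise only: no photobleaching, focus
drift, or autofluorescence trends, so noise-robustness results transfer to
real traces only where those artifacts are secondary.  Particle samples are
uniform (default) or log-uniform on 10–100 nm.  Named fixture bundles
(`osc-a-noisy`, `ind-pair`, `porosity-hp`, `porosity-lp`) exercise every
pipeline stage from CSV inputs alone.

## Numerical and design choices

* Problem sizes: simulations run 30 h of biology (1800 min) at dt = 0.05 min
  in a few seconds; analysis-stage statistics use the post-300-min window.
* Calibration ties break toward the first grid point scanned (deterministic).
* Degenerate inputs: constant channels yield empty peak lists (not errors);
  an empty post-filter sample is a valid result with n = 0 (estimation on it
  is the error).
* CSV serialization uses shortest-round-trip float formatting, so
  write → read reproduces arrays bit-exactly.
* The ideal sieve is inclusive at the cutoff, matching a "maximally d nm"
  reading of passage.

## Known limitations

* The two qualitative gaps listed above (no monotone accumulation plateau in
  the no-receiver-feedback layout; no initial receiver overshoot).
* Absolute fluorescence and AHL scales are arbitrary; only shapes, ratios,
  periods and lags are meaningful.
* Well-mixed compartments: sub-minute spatial transients inside a trap are
  below the model's resolution, so "zero lag" statements are bounded by the
  3-min imaging interval, not by the model's internal coupling time.
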
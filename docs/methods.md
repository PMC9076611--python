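# Methods

## Scope and data model

The pipeline starts downstream of read alignment and image analysis: its
inputs are per-nucleotide mutation/read count tables (TSV), dose–response
tables (CSV) and single-molecule intensity traces or lifetime lists
(TSV). Raw sequencing reads, camera frames, spot detection and
colocalization are out of scope. Because the study's raw data are not
packaged, every stage is exercised against seeded synthetic generators
(`ribopal.synth`) that reproduce the statistical structure each stage
assumes; what those generators do and do not emulate is listed at the
end.

## Differential MaP site calling (`ribopal.sitecalls`)

Replicate libraries are pooled by summing counts before rates are formed
(`M = mutations / reads`); pooling rates instead of counts would weight
replicates incorrectly at unequal depth. Positions with pooled depth
below 100 reads in any present condition are excluded (a zero depth
yields an excluded site, never a division error).

The candidate screen applies four filters jointly: fold change
PAL/PRE ≥ 1.5 (with a 0.5-count pseudocount on both mutation counts when
the PRE count is zero, keeping ratios finite without reordering ranks),
average PAL/PRE mutation count ≥ 100, Z-factor > 0 and p < 0.05. The
Z-factor normalization `A` is the per-site mean of the PAL and PRE rates;
a transcript-wide mean is available (`CallThresholds.a_mode`) because
either reading is defensible. A rate tie (ΔN = 0) maps to z = −∞ so the
site can never pass. The screen description exists in two printed forms —
"≥100 reads for each mutated site" and "average mutation count ≥100" —
which differ materially at low mutation rates; both are implemented
(coverage floor on reads, threshold on average mutation count) with the
mutation-count form as the default gate.

No named test accompanies the published p < 0.05 filter. We use a pooled
two-proportion z-test, replaced by an exact conditional binomial test
(successes M_PAL out of M_PAL + M_PRE against p = C_PAL/(C_PAL + C_PRE))
wherever an expected mutation cell is below 5. No multiple-testing
correction is applied, matching the published criteria; the filters are a
screen, not an inference, and the joint gate (fold change + counts + z)
controls the practical false-positive rate (measured ≤ 1 % per 6000 null
positions, in practice ~0 under the default depth law).

UV artifacts require UV/NUL ratio > 10, rate difference > 0.01 and
average count > 100; native modifications require NUL rate ≥ 0.2.
Categories are mutually exclusive with precedence
excluded > native_mod > uv_artifact > candidate > background.

## Dose–response models (`ribopal.binding`)

Hyperbolic (one-site), Hill, and a biphasic two-site model — a tight
hyperbola plus a *linear* weak term, because isolated-factor labeling
grows strictly linearly at the weak site over the accessible
concentration range; a dual-hyperbola variant is available. Fits use a
bounded trust-region least-squares solver. Initialization: PI_max ← max
signal, EC50/K_A ← concentration nearest half-max, n ← 2. Bounds:
n ∈ [0.3, 6], EC50/K_A ∈ [min positive concentration/10, 10 × max
concentration] — these prevent boundary escape on sparse grids.
Standard errors are asymptotic (Jacobian covariance); a seeded case
bootstrap is available. Fits that fail to converge are flagged rather
than silently returned. Since assay noise is multiplicative, recovery
analyses pass weights `1/(0.05 y)²`; the unweighted default matches
ordinary practice for such curves.

## Single-molecule kinetics (`ribopal.smkinetics`)

**Lifetime extraction.** Traces are two-level with a single loss step.
The loss frame is the first illuminated frame below the midpoint of the
estimated on/baseline levels that stays below it for the rest of the
trace; a step is accepted only when the on–baseline separation exceeds
4× a robust (median-absolute-difference) noise estimate, so flat traces
censor rather than mis-split. Because the duty cycle spends ~92 % of the
time dark, assigning the event to the loss *frame* would bias lifetimes
upward by about half the dark gap (~12 s); the event time is therefore
assigned to the midpoint between the last above-threshold frame and the
loss frame (`assign="first_low"` restores the frame-time convention).
Lifetimes are real elapsed time (dark gaps included): the photobleaching
control is recorded under the identical duty cycle, so the duty-cycle
factor cancels in the rate subtraction.

**Rates.** The censored-exponential MLE is the closed form
`k̂ = events / total time at risk`, with a χ²(2d) confidence interval.
⟨T⟩ in the moment correction `k_RF = 1/⟨T_obs⟩ − 1/⟨T_pb⟩` is defined as
total time at risk / events (the reciprocal MLE), not the naive mean of
uncensored lifetimes — the naive mean is biased low by ~12 % for the
photobleaching population under a 22.7-min window and would propagate
into k_RF. Negative k_RF (possible at low RFC by sampling noise) floors
to zero with a warning. A cumulative-distribution estimator
(`fit_cdf_rate`: least-squares fit of 1 − e^(−kt) to the fraction of all
traces lost by t) is provided for populations that are *mixtures* of
reactive and blocked molecules, where the MLE's time-at-risk from blocked
molecules compresses rate trends; for homogeneous exponential samples the
two agree.

**Condition fits.** k_RF vs [RFC] is fit to `V_max [RFC]/(EC50 + [RFC])`;
rates normalized to the zero-ataluren rate are fit to the decreasing
Hill form `K_A^n/(K_A^n + I^n)` (convergence flagged false when the data
do not genuinely decrease). CC between paired lifetimes is the Pearson
product-moment in raw-sums form; censored pairs are excluded.

## Termination scheme (`ribopal.scheme`)

A linear chain with one branch: productive RFC binding at
`k_bind_max · rfc/(K_rfc + rfc) · (1 − θ_At)` with rapid-equilibrium
cooperative ataluren occupancy `θ_At = I^n/(K_At^n + I^n)` (the scheme
shows n molecules binding in one step and only equilibrium-style
inhibition is observed); cleavage `k_hyd`; a shared step `k_c`; then
independent final waits `k_t1`, `k_p1`. Each stage is exponential and
sampled sequentially per complex — no general reaction-network engine is
needed for a linear chain. Factor (eRF1) departure is not simulated: its
coordination with product release is unresolved, and only the peptide
and tRNA channels are observed.

Defaults (min⁻¹, µM): `k_bind_max = 400`, `K_rfc = 36`, `k_hyd = 10`,
`k_c = 0.9`, `k_t1 = k_p1 = 0.3`, `n_At = 3`, `K_At = 250`. These jointly
reproduce the observed phenomenology: saturating release rates
≈ 0.22 min⁻¹, apparent RFC EC50 ≈ 0.02 µM
(EC50_app = K_rfc/(1 + k_bind_max·D), D the summed downstream mean
times), a release-time correlation ≈ 0.11 at saturating RFC rising
steeply at low RFC, V_max nearly invariant under ataluren while EC50_app
rises — the competitive signature. The binding stage is a *lumped
effective* stage: its two parameters are only constrained through
EC50_app and V_max, so K_rfc itself is not interpretable as a physical
affinity. One tension is inherited from the measurements themselves: an
apparent EC50 of 0.02 µM forces the lumped binding stage to be
minute-scale at ~0.08 µM RFC, while the delayed-addition experiments
show the inhibitable step completing at ~10 min⁻¹ there; a strictly
sequential scheme cannot satisfy both. The delayed-addition analyses
are therefore run at binding-saturating RFC, making cleavage the
protection-limiting step, which is the mechanistic claim being tested.

`analytic_cc` gives the closed-form correlation
`CC = V_s/√((V_s + 1/k_t1²)(V_s + 1/k_p1²))` with `V_s = 1/k_c²` plus
optional extra shared stages (binding, cleavage); it is verified against
simulation on a 3×3 grid at n = 10⁵.

**Delayed addition.** Complexes cleaved before the ataluren delay
proceed; uncleaved complexes are blocked absolutely (θ_At ≈ 0.985 at
1 mM; a probabilistic `blocking="equilibrium"` mode exists). Observed
loss competes with photobleaching; per-delay k_RF uses the CDF estimator
(the per-delay populations are exactly the reactive/blocked mixtures it
is designed for), and k_RF(τ) is fit to
`k_inf − (k_inf − k_0) e^(−rτ)` with k_inf anchored to a no-ataluren
control. Deterministic (infinite-sample) analysis of this procedure at
delays 0–25 s recovers r ≈ 8 min⁻¹ for a true cleavage rate of
10 min⁻¹ — the short delay window and the residual nonlinearity of the
estimator deflate the fitted approach rate somewhat; the MLE-based
variant deflates it further (~7 min⁻¹), which is why it is not the
default here.

## Structure proximity (`ribopal.proximity`)

Coordinate files (PDB or mmCIF, via gemmi) become a flat atom table;
waters and, by default, heteroatoms are dropped. Distances of closest
approach are all-atom minima (a C1′/Cα representative mode exists, but
"closest approach" implies any-atom); computed with a k-d tree and
verified against brute force in tests. Bands are half-open:
d < 10 Å, 10 ≤ d < 16 Å, d ≥ 40 Å, else intermediate. Residue numbering
is the file's author numbering; cross-species rRNA renumbering is the
caller's input. No real structure download is required anywhere; tests
and the analysis driver use small synthetic coordinate files.

## Synthetic generators: what they emulate, and what not

* **Counts** (`gen_count_tables`): per-position basal rates are Beta
  (mean 0.2 %, shape 10 → CV ≈ 32 %, a typical MaP background; the
  untreated-library background is lower, ~0.05 %, where that matters);
  depths are lognormal (median 1.2×10⁵ reads, log-sd 0.5, floored at
  10⁴ — deep rRNA coverage with >97 % of nucleotides ≥ 10⁴ reads);
  mutations are Binomial(C, rate). Planted labeled sites scale the rate
  in PAL only; native modifications (0.28–1.0) apply everywhere;
  UV-crosslink sites (0.018–0.099) apply to PAL/PRE/UV. Two replicate
  libraries, pooled by counting, are the default. Not emulated:
  alignment artifacts, position-correlated backgrounds, overdispersion
  beyond the Beta layer, sequence-context effects. Passing tests
  therefore show the statistics and filters are implemented correctly
  and powered under idealized binomial sampling — not that real
  libraries are free of systematic error.
* **Dose–response** (`gen_dose_response`): exact model mean times
  (1 + N(0, 0.05)) relative noise, clipped at 0. No plate effects or
  concentration errors.
* **Traces** (`gen_timelapse_traces`): exponential loss at hazard
  k_release + k_pb in real time from injection (3 s), two-level
  intensity with 5 % additive Gaussian read noise, sampled only at
  illuminated frames (bursts of 20 × 100 ms, 24 s gaps, 22.7 min);
  survivors are censored at the recording end. Not emulated: blinking,
  partial steps, drift, multi-fluorophore spots.
  `gen_exponential_lifetimes` is the lifetime-level shortcut with the
  same censoring convention.

## Problem sizes and precision

Recovery experiments (`ribopal.experiments`) fix their replication by
power analysis so estimator noise is small against the uncertainty band
of the quantity recovered: 12 replicate curves for the one-site EC50,
6 for the two-site tight EC50, 3 for the Hill cooperativity; 4000
lifetimes per ataluren concentration (8000 for the photobleach control);
300 rendered traces per RFC concentration; 5000 complexes per delay;
2×10⁵ release pairs for CC; 6000 nucleotides with 22 planted sites for
the screen. All randomness derives from a single seed per experiment
via `numpy.random.SeedSequence`, and every generator is bit-reproducible
given its seed.

## Known limitations

* The p-value choice (two-proportion/exact-binomial) is one defensible
  reading of an unspecified test; rankings are insensitive but exact
  p-values near the 0.05 gate are not.
* The step detector assumes single-step loss; multi-step or blinking
  traces need the pluggable `assign`/threshold machinery replaced.
* The kinetic scheme is deliberately minimal (no recycling factors, no
  reversible binding, no spatial effects) and its binding stage is an
  effective lump; parameter values off the constrained observables
  should not be over-interpreted.
* The delayed-addition approach-rate fit is a ~20 % biased estimator of
  the cleavage rate at the experimentally accessible delay window (see
  above); comparisons should use the same procedure on both sides.
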
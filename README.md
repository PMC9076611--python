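# ribopal

Analysis pipeline for locating where the readthrough drug ataluren binds
the eukaryotic protein-synthesis machinery and how it inhibits
release-factor-dependent termination. The package re-implements, against
synthetic data generators, the computational machinery of that study:

1. **Differential MaP site calling** — azidoataluren (AzAt) photoaffinity
   labeling read out by mutational profiling. Per-nucleotide mutation
   rates `M = mutations / reads` are compared between photolabeled (PAL)
   and pre-photolyzed-reagent (PRE) libraries; candidate labeled sites
   must pass fold change ≥ 1.5, average mutation count ≥ 100, p < 0.05 and
   a Z-factor separation statistic

   `z = 1 − 1.96 (σ_PAL + σ_PRE) / |ΔN|`, with `σ_X = √(M_X/C_X) / A`,
   `N_X = M_X / A`, `A = (M_PAL + M_PRE)/2`.

   UV-crosslink artifacts (UV/NUL ratio > 10, ΔM > 0.01, counts > 100) and
   native modifications (NUL rate ≥ 0.2) are flagged from the control
   libraries, and labeling stoichiometries can be occupancy-corrected,
   `PI_corr = (1/f)(PI_meas − (1−f) PI_IRES)` with `f = 0.40`.

2. **Saturation-binding fits** — hyperbolic, Hill
   (`PI = PI_max x^n / (K_A^n + x^n)`) and biphasic two-site
   (tight hyperbola + weak linear term) dose–response models.

3. **Single-molecule termination kinetics** — time-lapse TIRF traces
   (bursts of 20 frames at 100 ms, 24 s dark gaps, 22.7 min total) are
   reduced to censored lifetimes; rates are censored-exponential MLEs
   (`k̂ = events / total time at risk`) and the release-factor-dependent
   rate is photobleach-corrected, `k_RF = 1/⟨T_obs⟩ − 1/⟨T_pb⟩`.
   Michaelis–Menten fits in [RFC] and decreasing-Hill fits in [ataluren]
   quantify the apparent competitive, cooperative inhibition, and the
   Pearson correlation CC between paired tRNA/peptide release times
   reports on shared rate-limiting steps.

4. **Termination-scheme simulator** — a sequential stochastic scheme
   (productive RFC binding in competition with cooperative ataluren
   occupancy → rapid peptidyl-tRNA cleavage at 10 min⁻¹ → a shared
   conformational step `k_c` → independent peptide/tRNA release at
   `k_t1 ≈ k_p1 ≈ 0.2–0.3 min⁻¹`), with the closed-form correlation
   `CC = V_s / √((V_s + 1/k_t1²)(V_s + 1/k_p1²))`, `V_s = 1/k_c²`, and a
   delayed-inhibitor-addition protocol.

5. **Structure proximity** — all-atom distance of closest approach
   between called nucleotides and a protein chain (e.g. eRF1 in a
   termination-complex structure), banded at 10 / 16 / 40 Å.

It is aimed at researchers analyzing chemical-probing count tables,
single-molecule dissociation data, or simple sequential kinetic schemes,
and at anyone wanting a fully synthetic, seedable test bed for such
pipelines.

## Worked example

The numbered scripts under `analysis/` run each stage end to end and
write tables under `results/`. For example:

```bash
python analysis/01_simulate_counts.py   # synthetic PAL/PRE/UV/NUL counts
python analysis/02_call_sites.py        # four-filter candidate screen
```

prints

```
category counts:
background     5954
candidate        22
uv_artifact      14
native_mod       10
planted: 22/22 recovered as candidate
native_mod: 10/10 recovered as native_mod
uv_artifact: 14/14 recovered as uv_artifact
false-positive candidates: 0
```

i.e. every planted labeled site (fold change 5 over a ~0.2 % background
at ≥10⁴ read depth) survives the screen and nothing else does. Similarly
`analysis/04_sm_kinetics.py` reduces simulated time-lapse traces to
photobleach-corrected rates and recovers the termination kinetics:

```
tRNA   : 1/2.45 - 1/4.9 = 0.2041 min^-1
peptide: 1/2.45 - 1/6.8 = 0.2611 min^-1
MM fit from traces: V_max 0.261 min^-1, EC50 0.0211 µM
peptide inhibition: K_A 249 µM, Hill n 2.84
```

and `analysis/05_term_scheme.py` checks the shared-intermediate
correlation (analytic 0.100 vs simulated 0.106 at 2×10⁵ pairs), the
competitive signature (apparent V_max constant at ~0.22 min⁻¹ while the
apparent RFC EC50 rises with ataluren) and the delayed-addition protocol
(elimination rate ≈ 8 min⁻¹ for cleavage at 10 min⁻¹).

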
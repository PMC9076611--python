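"""End-to-end recovery experiments on synthetic data.

Each function runs one complete simulate -> analyze -> fit loop under the
study conditions the analysis emulates, with every random draw derived
from a single seed. They are the workhorses behind the numbered analysis
scripts and the acceptance checks; problem sizes are chosen so that the
estimator's sampling error is small against the uncertainty band of the
quantity being recovered (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from ribopal import binding, scheme, sitecalls, smkinetics, synth

__all__ = [
    "delayed_addition_recovery",
    "hill_cooperativity_recovery",
    "hyperbolic_ec50_recovery",
    "inhibition_recovery",
    "mm_trace_recovery",
    "planted_site_recovery",
    "release_correlation_experiment",
    "relative_weights",
    "two_site_recovery",
]

# AzAt saturation grid (µM), spanning the experimental 0-600 µM range
DOSE_GRID = (0, 10, 20, 40, 60, 80, 120, 160, 200, 240, 280, 320, 400, 500, 600)
# grid used for the biphasic eRF1-in-ternary-complex curve (0-500 µM)
TWO_SITE_GRID = (0, 10, 20, 35, 50, 70, 90, 120, 160, 200, 250, 300, 400, 500)
# ataluren inhibition grid (µM) and RFC titration grid (µM)
INHIBITION_GRID = (0.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0, 400.0, 500.0, 700.0, 1000.0)
RFC_GRID = (0.005, 0.01, 0.02, 0.04, 0.08, 0.32)

NOISE_SD = 0.05  # relative measurement noise of the dose-response assays
PEPTIDE_PB_RATE = 1.0 / 6.8  # photobleaching, Atto647 peptide label (min^-1)
TRNA_PB_RATE = 1.0 / 4.9  # photobleaching, Cy3 tRNA label (min^-1)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from one master seed."""
    return [int(s) % 2**31 for s in np.random.SeedSequence(seed).generate_state(n)]


def relative_weights(signal, rel: float = NOISE_SD) -> np.ndarray:
    """Least-squares weights matching multiplicative measurement noise."""
    y = np.asarray(signal, dtype=float)
    sigma = np.maximum(rel * y, rel * max(float(y.max()), 1e-12) * 0.05)
    return 1.0 / sigma**2


def release_correlation_experiment(seed: int, k: float = 0.3, n_pairs: int = 200_000) -> dict:
    """Correlation of paired release times under the shared-intermediate
    model with k_c = 3k and equal final release rates."""
    pairs = scheme.simulate_release_pairs(3.0 * k, k, k, n_pairs, seed=seed)
    cc_sim = smkinetics.release_correlation(pairs["t_release"], pairs["p_release"])
    return {
        "cc_simulated": cc_sim,
        "cc_analytic": scheme.analytic_cc(3.0 * k, k, k),
        "n_pairs": n_pairs,
    }


def _dose_recovery(seed, model_kind, params_true, grid, replicates):
    data = synth.gen_dose_response(model_kind, params_true, grid, NOISE_SD, replicates, seed=seed)
    fit = binding.fit_binding(data, model_kind, weights=relative_weights(data["signal"]))
    return fit, data


def hyperbolic_ec50_recovery(seed: int, ec50_true: float = 240.0, replicates: int = 12) -> dict:
    """Recover the one-site EC50 of the 18S-A1195 fragment saturation curve."""
    fit, data = _dose_recovery(
        seed, "hyperbolic", {"pi_max": 1.0, "ec50": ec50_true}, DOSE_GRID, replicates
    )
    return {"ec50": fit.params["ec50"], "se": fit.ses["ec50"], "fit": fit, "n_obs": len(data)}


def hill_cooperativity_recovery(
    seed: int, k_a_true: float = 200.0, n_true: float = 3.0, replicates: int = 3
) -> dict:
    """Recover the cooperative (PTC fragment) saturation parameters."""
    fit, data = _dose_recovery(
        seed, "hill", {"pi_max": 1.0, "k_a": k_a_true, "n": n_true}, DOSE_GRID, replicates
    )
    return {"k_a": fit.params["k_a"], "n": fit.params["n"], "fit": fit, "n_obs": len(data)}


def two_site_recovery(
    seed: int, ec50_true: float = 90.0, weak_slope_true: float = 0.001, replicates: int = 6
) -> dict:
    """Recover the tight-site EC50 of the biphasic eRF1-in-ternary-complex
    curve (tight hyperbola plus weak linear component)."""
    fit, data = _dose_recovery(
        seed,
        "two_site",
        {"pi_max": 1.0, "ec50": ec50_true, "weak_slope": weak_slope_true},
        TWO_SITE_GRID,
        replicates,
    )
    return {"ec50": fit.params["ec50"], "weak_slope": fit.params["weak_slope"], "fit": fit}


def inhibition_recovery(
    seed: int,
    channel: str = "peptide",
    k0: float | None = None,
    k_a_true: float | None = None,
    n_true: float | None = None,
    n_traces: int = 4000,
    n_pb_traces: int = 8000,
) -> dict:
    """Full single-molecule pipeline across an ataluren grid.

    Lifetimes are drawn with hazard k_RF(I) + k_pb under the standard
    22.7-min recording, rates are estimated by censored MLE with
    photobleach subtraction against a same-schedule control, normalized to
    the zero-ataluren rate and fit to the decreasing Hill isotherm.
    Channel defaults: peptide K_A 250 µM, n 3.0, k0 0.25; tRNA K_A 180 µM,
    n 2.7, k0 0.20.
    """
    if channel == "peptide":
        k0 = 0.25 if k0 is None else k0
        k_a_true = 250.0 if k_a_true is None else k_a_true
        n_true = 3.0 if n_true is None else n_true
        k_pb = PEPTIDE_PB_RATE
    elif channel == "tRNA":
        k0 = 0.20 if k0 is None else k0
        k_a_true = 180.0 if k_a_true is None else k_a_true
        n_true = 2.7 if n_true is None else n_true
        k_pb = TRNA_PB_RATE
    else:
        raise ValueError(f"unknown channel {channel!r}")
    grid = np.asarray(INHIBITION_GRID)
    seeds = _child_seeds(seed, grid.size + 1)
    schedule = synth.IlluminationSchedule()
    obs_min = (schedule.total_duration - schedule.injection_time) / 60.0
    pb = synth.gen_exponential_lifetimes(k_pb, obs_min, n_pb_traces, seed=seeds[-1])
    rates = []
    for i, conc in enumerate(grid):
        k_rf = k0 * k_a_true**n_true / (k_a_true**n_true + conc**n_true) if conc > 0 else k0
        life = synth.gen_exponential_lifetimes(k_rf + k_pb, obs_min, n_traces, seed=seeds[i])
        rates.append(smkinetics.rate_estimate(life, pb).k_rf)
    rates = np.asarray(rates)
    k_a, n_hat, se_k, se_n, converged = smkinetics.fit_hill_inhibition(grid, rates / rates[0])
    return {
        "k_a": k_a,
        "n": n_hat,
        "se_k_a": se_k,
        "se_n": se_n,
        "converged": converged,
        "ataluren_uM": grid,
        "k_rf": rates,
    }


def mm_trace_recovery(
    seed: int,
    v_max_true: float = 0.27,
    ec50_true: float = 0.02,
    n_traces: int = 300,
    n_pb_traces: int = 400,
) -> dict:
    """Trace-level Michaelis-Menten recovery across an RFC titration.

    Full pipeline: render time-lapse traces (release + photobleaching
    hazards, read noise), detect loss steps, extract lifetimes, correct
    against a same-schedule photobleaching control, fit k_RF vs [RFC].
    """
    grid = np.asarray(RFC_GRID)
    seeds = _child_seeds(seed, grid.size + 1)
    schedule = synth.IlluminationSchedule()
    pb_traces = synth.gen_timelapse_traces(0.0, PEPTIDE_PB_RATE, schedule, n_pb_traces, seed=seeds[-1])
    pb_life = smkinetics.extract_lifetimes(pb_traces)
    rates = []
    for i, rfc in enumerate(grid):
        k_rf = v_max_true * rfc / (ec50_true + rfc)
        traces = synth.gen_timelapse_traces(k_rf, PEPTIDE_PB_RATE, schedule, n_traces, seed=seeds[i])
        life = smkinetics.extract_lifetimes(traces)
        rates.append(smkinetics.rate_estimate(life, pb_life).k_rf)
    v_max, ec50, se_v, se_e = smkinetics.fit_mm(grid, rates)
    return {"v_max": v_max, "ec50": ec50, "se_v_max": se_v, "se_ec50": se_e, "rfc_uM": grid, "k_rf": np.asarray(rates)}


def planted_site_recovery(
    seed: int,
    n_positions: int = 6000,
    n_planted: int = 22,
    fold_change: float = 5.0,
) -> dict:
    """Plant strongly labeled sites in a null count table and run the full
    four-filter candidate screen."""
    rng = np.random.default_rng(seed)
    positions = rng.choice(np.arange(1, n_positions + 1), size=n_planted, replace=False)
    config = synth.CountSimConfig(
        n_positions=n_positions,
        planted_sites=tuple((int(p), fold_change) for p in positions),
        seed=seed,
    )
    sim = synth.gen_count_tables(config)
    calls = sitecalls.call_sites(sim.counts)
    candidates = set(calls.loc[calls["category"] == "candidate", "position"])
    planted = set(int(p) for p in positions)
    return {
        "n_candidates": len(candidates),
        "n_recovered": len(candidates & planted),
        "n_false_positive": len(candidates - planted),
        "calls": calls,
        "truth": sim.truth,
    }


def delayed_addition_recovery(
    seed: int,
    channel: str = "peptide",
    n_complexes: int = 5000,
    delays_s=(0, 4, 8, 12, 16, 20, 25),
) -> dict:
    """Delayed-ataluren-addition protocol at binding-saturating RFC.

    Cleavage (k_hyd = 10 min^-1) is the protection-limiting step; the
    fitted single-exponential approach of k_RF to the uninhibited rate
    estimates its rate constant.
    """
    params = scheme.SchemeParams(k_hyd=10.0, k_c=0.75, k_t1=0.25, k_p1=0.25)
    k_pb = PEPTIDE_PB_RATE if channel == "peptide" else TRNA_PB_RATE
    return scheme.delayed_addition_protocol(
        params,
        rfc=400.0,
        ataluren=1000.0,
        delays_s=delays_s,
        n_complexes=n_complexes,
        seed=seed,
        t_max=22.7,
        k_pb=k_pb,
        channel=channel,
    )
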
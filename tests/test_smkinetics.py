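"""Lifetime extraction, censored-exponential estimation, rate fits, CC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribopal import smkinetics, synth


def lifetimes(values, censored=None):
    values = list(values)
    censored = [False] * len(values) if censored is None else list(censored)
    return pd.DataFrame({"lifetime_min": values, "censored": censored})


class TestExtractLifetimes:
    def test_planted_loss_frame_recovered_exactly_at_five_percent_noise(self):
        sched = synth.IlluminationSchedule(total_duration=600.0)
        ts = synth.gen_timelapse_traces(1.0, 0.5, sched, 200, seed=4, noise_sd=0.05)
        out = smkinetics.extract_lifetimes(ts)
        times = ts.times_s
        for _, row in out[~out["censored"]].iterrows():
            true_loss = ts.truth.loc[int(row["trace_id"]), "loss_time_s"]
            expected_frame = int(np.searchsorted(times, true_loss, side="right"))
            assert int(row["loss_frame"]) == expected_frame

    def test_flat_trace_censored(self):
        sched = synth.IlluminationSchedule(total_duration=300.0)
        ts = synth.gen_timelapse_traces(0.0, 0.0, sched, 10, seed=1)
        out = smkinetics.extract_lifetimes(ts)
        assert out["censored"].all()

    def test_too_few_frames_skipped(self):
        sched = synth.IlluminationSchedule(burst_frames=2, frame_interval=0.1, dark_gap=1000.0, total_duration=10.0)
        ts = synth.gen_timelapse_traces(1.0, 0.0, sched, 5, seed=2)
        assert smkinetics.extract_lifetimes(ts).empty

    def test_population_mean_matches_generator(self):
        """At the saturating-RFC condition (total hazard 1/2.45 min^-1) the
        extracted censoring-adjusted mean lifetime reproduces 2.45 min."""
        sched = synth.IlluminationSchedule()
        ts = synth.gen_timelapse_traces(1 / 2.45 - 1 / 6.8, 1 / 6.8, sched, 2000, seed=8)
        out = smkinetics.extract_lifetimes(ts)
        mean = smkinetics.mean_observed_lifetime(out)
        n_events = int((~out["censored"]).sum())
        assert abs(mean - 2.45) < 3 * 2.45 / np.sqrt(n_events)

    def test_first_low_assignment_is_spec_literal_and_biased_upward(self):
        sched = synth.IlluminationSchedule(total_duration=1800.0)
        ts = synth.gen_timelapse_traces(1 / 2.45, 0.0, sched, 500, seed=3)
        mid = smkinetics.extract_lifetimes(ts, assign="interval_midpoint")
        first = smkinetics.extract_lifetimes(ts, assign="first_low")
        joined = mid.merge(first, on="trace_id", suffixes=("_mid", "_first"))
        ok = ~(joined["censored_mid"] | joined["censored_first"])
        assert (joined.loc[ok, "lifetime_min_first"] >= joined.loc[ok, "lifetime_min_mid"]).all()


class TestMLE:
    def test_reciprocal_mean_no_censoring(self):
        k, ci, d, total = smkinetics.mle_exponential(lifetimes([2, 2, 2]), min_events=1)
        assert k == pytest.approx(0.5)
        assert ci[0] < 0.5 < ci[1]

    def test_censored_closed_form(self):
        k, _, d, total = smkinetics.mle_exponential(
            lifetimes([1, 2, 3, 4], censored=[False, False, False, True]), min_events=1
        )
        assert k == pytest.approx(0.3)
        assert (d, total) == (3, 10.0)

    def test_zero_events_raise(self):
        with pytest.raises(ValueError):
            smkinetics.mle_exponential(lifetimes([5.0], censored=[True]))

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(10)
        t = rng.exponential(4.0, 1000)
        k, _, d, _ = smkinetics.mle_exponential(lifetimes(t), min_events=1)
        assert abs(k - 0.25) < 3 * 0.25 / np.sqrt(1000)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_equals_closed_form_on_arbitrary_input(self, data):
        n = data.draw(st.integers(2, 40))
        vals = data.draw(
            st.lists(st.floats(0.01, 50.0, allow_nan=False), min_size=n, max_size=n)
        )
        cens = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        if not any(not c for c in cens):
            cens[0] = False
        k, _, d, total = smkinetics.mle_exponential(lifetimes(vals, cens), min_events=1)
        assert k == pytest.approx(sum(1 for c in cens if not c) / sum(vals), rel=1e-12)


class TestPhotobleachCorrection:
    def test_trna_and_peptide_worked_values(self):
        assert smkinetics.photobleach_correct(2.45, 4.9) == pytest.approx(0.2041, abs=1e-4)
        assert smkinetics.photobleach_correct(2.45, 6.8) == pytest.approx(0.2611, abs=1e-4)

    def test_equal_means_give_zero_and_negative_floors(self):
        assert smkinetics.photobleach_correct(3.0, 3.0) == 0.0
        with pytest.warns(UserWarning):
            assert smkinetics.photobleach_correct(5.0, 3.0) == 0.0
        with pytest.raises(ValueError):
            smkinetics.photobleach_correct(0.0, 3.0)

    def test_end_to_end_unbiased_over_many_seeds(self):
        """Traces generated with hazard k_RF + k_pb, corrected with a
        same-schedule photobleach control, recover k_RF without systematic
        bias (mean over 50 seeds within 3 SE of truth)."""
        sched = synth.IlluminationSchedule()
        k_rf_true, k_pb = 0.25, 1 / 6.8
        estimates = []
        for seed in range(50):
            obs = synth.gen_timelapse_traces(k_rf_true, k_pb, sched, 150, seed=seed)
            ctrl = synth.gen_timelapse_traces(0.0, k_pb, sched, 150, seed=1000 + seed)
            est = smkinetics.rate_estimate(
                smkinetics.extract_lifetimes(obs), smkinetics.extract_lifetimes(ctrl)
            )
            estimates.append(est.k_rf)
        mean = np.mean(estimates)
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean - k_rf_true) < 3 * se


class TestRateFits:
    def test_mm_midpoint_and_exact_inversion(self):
        conc = np.array([0.005, 0.02, 0.08, 0.32])
        rates = 0.27 * conc / (0.02 + conc)
        vmax, ec50, *_ = smkinetics.fit_mm(conc, rates)
        assert vmax == pytest.approx(0.27, rel=1e-6)
        assert ec50 == pytest.approx(0.02, rel=1e-6)
        assert 0.27 * 0.02 / (0.02 + 0.02) == pytest.approx(vmax / 2, rel=1e-6)

    def test_mm_underdetermined(self):
        with pytest.raises(ValueError):
            smkinetics.fit_mm([0.02, 0.02], [0.1, 0.11])

    def test_hill_inhibition_midpoint_and_inversion(self):
        conc = np.array([0.0, 50, 150, 250, 400, 1000.0])
        rates = 250.0**3 / (250.0**3 + conc**3)
        k_a, n, *_, conv = smkinetics.fit_hill_inhibition(conc, rates)
        assert conv
        assert k_a == pytest.approx(250.0, rel=1e-6)
        assert n == pytest.approx(3.0, rel=1e-6)
        assert rates[3] == pytest.approx(0.5)

    def test_hill_inhibition_flags_non_monotone_data(self):
        conc = np.array([0.0, 50, 150, 250, 400, 1000.0])
        flat = np.ones_like(conc)
        *_, conv = smkinetics.fit_hill_inhibition(conc, flat)
        assert not conv


class TestReleaseCorrelation:
    def test_identical_pairs_give_one(self):
        t = np.array([1.0, 2.5, 4.0, 0.5])
        assert smkinetics.release_correlation(t, t) == pytest.approx(1.0)

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(3.0, 100_000)
        p = rng.exponential(3.0, 100_000)
        assert abs(smkinetics.release_correlation(t, p)) < 0.01

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(6)
        shared = rng.exponential(1.0, 500)
        t = shared + rng.exponential(2.0, 500)
        p = shared + rng.exponential(2.0, 500)
        cc = smkinetics.release_correlation(t, p)
        assert cc == pytest.approx(np.corrcoef(t, p)[0, 1], rel=1e-12)

    def test_too_few_pairs_raise(self):
        with pytest.raises(ValueError):
            smkinetics.release_correlation([1.0], [2.0])
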
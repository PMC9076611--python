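"""Site-caller statistics and the four-filter candidate screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribopal import sitecalls, synth


def make_profile_row(
    m_pal, c_pal, m_pre, c_pre, m_uv=0, c_uv=10_000, m_nul=0, c_nul=10_000, position=1
):
    row = {
        "transcript": "18S",
        "position": position,
        "excluded": False,
    }
    for cond, m, c in [("PAL", m_pal, c_pal), ("PRE", m_pre, c_pre), ("UV", m_uv, c_uv), ("NUL", m_nul, c_nul)]:
        row[f"reads_{cond}"] = c
        row[f"mutations_{cond}"] = m
        row[f"rate_{cond}"] = m / c if c else np.nan
    return row


class TestLoadCounts:
    def test_roundtrip_from_generator_is_lossless(self, tmp_path):
        cfg = synth.CountSimConfig(n_positions=50, seed=1)
        counts = synth.gen_count_tables(cfg).counts
        path = tmp_path / "counts.tsv"
        counts.to_csv(path, sep="\t", index=False)
        loaded = sitecalls.load_counts(path)
        pd.testing.assert_frame_equal(loaded, counts)
        # record count = positions x conditions x replicates
        assert len(loaded) == 50 * 4 * cfg.replicates

    def test_mutations_exceeding_reads_rejected_with_position(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "transcript\tposition\tref_base\tcondition\treplicate\treads\tmutations\n"
            "18S\t7\tA\tPAL\t1\t100\t250\n"
        )
        with pytest.raises(ValueError, match="position 7"):
            sitecalls.load_counts(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "transcript\tposition\tref_base\tcondition\treplicate\treads\tmutations\n"
            "18S\t1\tA\tPAL\t1\t100\t1\n"
            "18S\ttwo\tA\tPAL\t1\t100\t1\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            sitecalls.load_counts(path)


class TestProfiles:
    def test_rates_are_pooled_counts(self):
        records = pd.DataFrame(
            {
                "transcript": "18S",
                "position": 1,
                "ref_base": "A",
                "condition": "PAL",
                "replicate": [1, 2],
                "reads": [5000, 5000],
                "mutations": [200, 300],
            }
        )
        prof = sitecalls.compute_profiles(records, coverage_floor=0)
        assert prof["rate_PAL"].iloc[0] == pytest.approx(0.05)

    def test_zero_depth_is_excluded_not_an_error(self):
        records = pd.DataFrame(
            {
                "transcript": "18S",
                "position": [1, 1],
                "ref_base": "A",
                "condition": ["PAL", "PRE"],
                "replicate": 1,
                "reads": [0, 10_000],
                "mutations": [0, 500],
            }
        )
        prof = sitecalls.compute_profiles(records)
        assert bool(prof["excluded"].iloc[0])
        assert np.isnan(prof["rate_PAL"].iloc[0])


class TestZFactor:
    def test_worked_example(self):
        r = sitecalls.zfactor(0.05, 10_000, 0.01, 10_000)
        assert r.A == pytest.approx(0.03)
        assert r.delta_n == pytest.approx(1.33333, abs=1e-4)
        assert r.z == pytest.approx(0.84143, abs=1e-4)

    def test_equal_rates_give_sentinel(self):
        assert sitecalls.zfactor(0.02, 1000, 0.02, 1000).z == -np.inf

    def test_doubling_depth_increases_z(self):
        z1 = sitecalls.zfactor(0.05, 10_000, 0.01, 10_000).z
        z2 = sitecalls.zfactor(0.05, 20_000, 0.01, 20_000).z
        assert z2 > z1

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        m1=st.integers(1, 5000),
        m2=st.integers(1, 5000),
        c1=st.integers(5001, 200_000),
        c2=st.integers(5001, 200_000),
    )
    def test_matches_independent_recomputation_and_never_exceeds_one(self, m1, m2, c1, c2):
        """Spreadsheet-style oracle written from the definition, compared at
        1e-12 relative; z <= 1 always."""
        r1, r2 = m1 / c1, m2 / c2
        res = sitecalls.zfactor(r1, c1, r2, c2)
        a = (r1 + r2) / 2
        if r1 == r2:
            assert res.z == -np.inf
            return
        oracle = 1 - 1.96 * (np.sqrt(r1 / c1) / a + np.sqrt(r2 / c2) / a) / abs(r1 / a - r2 / a)
        assert res.z == pytest.approx(oracle, rel=1e-12)
        assert res.z <= 1.0

    def test_replicate_pooling_order_invariance(self):
        reps = [(200, 5000), (300, 5000), (100, 2000)]
        zs = []
        for perm in ([0, 1, 2], [2, 0, 1], [1, 2, 0]):
            m = sum(reps[i][0] for i in perm)
            c = sum(reps[i][1] for i in perm)
            zs.append(sitecalls.zfactor(m / c, c, 0.01, 12_000).z)
        assert zs[0] == zs[1] == zs[2]


class TestPValue:
    def test_strong_separation(self):
        assert sitecalls.site_pvalue(500, 10_000, 100, 10_000) < 1e-10

    def test_identical_counts_give_one(self):
        assert sitecalls.site_pvalue(50, 10_000, 50, 10_000) == pytest.approx(1.0)
        assert sitecalls.site_pvalue(0, 10_000, 0, 10_000) == pytest.approx(1.0)

    def test_small_counts_use_exact_test(self):
        assert sitecalls.site_pvalue(3, 10_000, 2, 10_000) > 0.05

    def test_agrees_with_statsmodels_for_large_counts(self):
        from statsmodels.stats.proportion import proportions_ztest

        for m1, c1, m2, c2 in [(500, 10_000, 100, 10_000), (250, 9000, 300, 11_000)]:
            _, p_ref = proportions_ztest([m1, m2], [c1, c2])
            assert sitecalls.site_pvalue(m1, c1, m2, c2) == pytest.approx(p_ref, rel=1e-9)


class TestScreen:
    @pytest.mark.parametrize(
        "m_pal,m_pre,expect",
        [
            (400, 200, True),  # FC 2, counts 300, clear separation
            (270, 200, False),  # FC 1.35 < 1.5 with everything else passing
            (90, 30, False),  # avg count 60 < 100
        ],
    )
    def test_candidate_thresholds(self, m_pal, m_pre, expect):
        prof = pd.DataFrame([make_profile_row(m_pal, 100_000, m_pre, 100_000)])
        out = sitecalls.call_candidate_sites(prof)
        assert bool(out["candidate"].iloc[0]) is expect

    def test_uv_classifier_thresholds(self):
        yes = make_profile_row(0, 10_000, 0, 10_000, m_uv=500, c_uv=10_000, m_nul=20, c_nul=10_000)
        no = make_profile_row(0, 10_000, 0, 10_000, m_uv=300, c_uv=10_000, m_nul=300, c_nul=10_000)
        prof = pd.DataFrame([yes, no])
        flags = sitecalls.classify_uv_sites(prof)
        assert flags.tolist() == [True, False]

    @pytest.mark.parametrize("rate,expect", [(0.28, True), (0.19, False)])
    def test_native_mod_threshold(self, rate, expect):
        prof = pd.DataFrame(
            [make_profile_row(100, 10_000, 100, 10_000, m_nul=int(rate * 10_000), c_nul=10_000)]
        )
        assert bool(sitecalls.classify_native_mods(prof).iloc[0]) is expect

    def test_planted_uv_and_native_sites_recovered_from_generator(self):
        rng = np.random.default_rng(12)
        uv_pos = rng.choice(np.arange(1, 1001), 14, replace=False)
        native_pos = [p for p in range(1, 1001) if p not in set(uv_pos)][:10]
        cfg = synth.CountSimConfig(
            n_positions=1000,
            depth_median=1e5,
            # untreated-library background (~0.05%): the >10x UV/NUL ratio
            # gate only resolves 1.8% crosslink rates against a low background
            background_rate_mean=5e-4,
            uv_sites=tuple((int(p), float(r)) for p, r in zip(uv_pos, rng.uniform(0.018, 0.099, 14))),
            native_mod_sites=tuple(
                (int(p), float(r)) for p, r in zip(native_pos, rng.uniform(0.28, 1.0, 10))
            ),
            seed=12,
        )
        sim = synth.gen_count_tables(cfg)
        calls = sitecalls.call_sites(sim.counts)
        got_uv = set(calls.loc[calls["category"] == "uv_artifact", "position"])
        got_native = set(calls.loc[calls["category"] == "native_mod", "position"])
        assert got_native == set(native_pos)  # exact at depth >= 1e4
        assert len(got_uv & set(uv_pos)) / len(uv_pos) >= 0.95

    def test_categories_exclusive_exhaustive_with_precedence(self):
        cfg = synth.CountSimConfig(
            n_positions=300,
            planted_sites=((10, 8.0),),
            native_mod_sites=((20, 0.5),),
            uv_sites=((30, 0.05),),
            excluded_regions=((40, 45),),
            seed=3,
        )
        calls = sitecalls.call_sites(synth.gen_count_tables(cfg).counts)
        allowed = {"candidate", "uv_artifact", "native_mod", "background", "excluded"}
        assert set(calls["category"]) <= allowed
        assert calls.loc[calls["position"] == 20, "category"].iloc[0] == "native_mod"
        assert calls.loc[calls["position"] == 30, "category"].iloc[0] == "uv_artifact"
        assert (calls.loc[calls["position"].between(40, 45), "category"] == "excluded").all()

    def test_type_one_error_control_under_null(self):
        """With no planted sites the candidate rate stays <= 1% across 20 seeds."""
        rates = []
        for seed in range(20):
            cfg = synth.CountSimConfig(n_positions=6000, seed=seed)
            calls = sitecalls.call_sites(synth.gen_count_tables(cfg).counts)
            rates.append((calls["category"] == "candidate").mean())
        assert max(rates) <= 0.01

    def test_power_monotone_in_fold_change_and_depth(self):
        planted = tuple((p, 1.0) for p in range(1, 23))  # fold filled per case

        def recovery(fold, depth):
            cfg = synth.CountSimConfig(
                n_positions=2000,
                depth_median=depth,
                planted_sites=tuple((p, fold) for p, _ in planted),
                seed=17,
            )
            calls = sitecalls.call_sites(synth.gen_count_tables(cfg).counts)
            cand = set(calls.loc[calls["category"] == "candidate", "position"])
            return len(cand & set(range(1, 23)))

        by_fold = [recovery(f, 3e4) for f in (1.3, 2.0, 5.0)]
        assert by_fold == sorted(by_fold)
        by_depth = [recovery(1.7, d) for d in (2e4, 1e5, 4e5)]
        assert by_depth == sorted(by_depth)


class TestStoichiometryCorrections:
    def test_occupancy_coefficients_and_identity(self):
        # f = 0.40 reproduces the printed 2.5/0.6 coefficients
        assert sitecalls.correct_pi_stoppost5(1.0, 0.5, f=0.40) == pytest.approx(2.5 * (1.0 - 0.6 * 0.5))
        assert sitecalls.correct_pi_stoppost5(1.0, 0.5, f=0.40) == pytest.approx(1.75)
        assert sitecalls.correct_pi_stoppost5(0.8, 0.3, f=1.0) == pytest.approx(0.8)
        with pytest.raises(ValueError):
            sitecalls.correct_pi_stoppost5(1.0, 0.5, f=0.0)
        with pytest.warns(UserWarning):
            sitecalls.correct_pi_stoppost5(0.1, 1.0, f=0.40)

    def test_fragment_recovery_correction(self):
        assert sitecalls.fragment_stoichiometry(0.2, recovery=0.20) == pytest.approx(1.0)
        assert sitecalls.fragment_stoichiometry(0.37) == pytest.approx(0.37 / 0.20)
        assert sitecalls.fragment_stoichiometry(0.5, recovery=1.0) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            sitecalls.fragment_stoichiometry(0.2, recovery=0.0)
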
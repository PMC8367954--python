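"""Normality gating, FDR comparisons, moment-based tests and bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import eegmicrostates as em
from eegmicrostates import cohort_reference as ref
from eegmicrostates.core import PARAM_COLUMNS
from statsmodels.stats.multitest import multipletests


def params_from_moments(rng, n, group_col, label="s"):
    """Draw per-subject TemporalParams tables from the reference moments."""
    mom = ref.temporal_moments()
    draws = {}
    for _, row in mom.iterrows():
        draws[(row["map"], row["parameter"])] = rng.normal(
            row[f"mean_{group_col}"], row[f"sd_{group_col}"], n)
    out = []
    for i in range(n):
        table = pd.DataFrame(
            {p: [draws[(m, p)][i] for m in "ABCDE"] for p in PARAM_COLUMNS},
            index=pd.Index(list("ABCDE"), name="map"))
        out.append(em.TemporalParams(subject_id=f"{label}{i}", table=table))
    return out


class TestNormalityGate:
    def test_gaussian_samples_take_t(self, rng):
        assert em.normality_gate(rng.normal(size=60), rng.normal(size=60)) == "t"

    def test_exponential_sample_takes_rank_test(self, rng):
        a = rng.normal(size=60)
        b = rng.exponential(size=60)
        assert em.normality_gate(a, b) == "mann_whitney"

    def test_small_samples_fall_back_with_warning(self, rng):
        with pytest.warns(UserWarning):
            out = em.normality_gate(rng.normal(size=5), rng.normal(size=60))
        assert out == "mann_whitney"


class TestCompareGroupsFDR:
    def test_identical_groups_rarely_significant(self, rng):
        a = params_from_moments(rng, 30, "td", "a")
        b = params_from_moments(rng, 30, "td", "b")
        df = em.compare_groups_fdr(a, b)
        assert len(df) == 20  # 5 maps x 4 parameters
        assert not df["significant"].any()

    def test_reference_effect_detected_on_map_b(self, rng):
        # the study-sized cohort: map-B differs on all four parameters
        a = params_from_moments(rng, 66, "asd", "a")
        b = params_from_moments(rng, 47, "td", "b")
        df = em.compare_groups_fdr(a, b)
        sig_b = df[df["map"] == "B"]["significant"]
        # duration/coverage/occurrence effects (d ~ 0.74-0.87) are reliably
        # caught; the GEV effect (d ~ 0.63) has ~90% power, so require >= 3
        assert sig_b.sum() >= 3
        strong = df[(df["map"] == "B") & (df["parameter"] != "gev")]
        assert strong["significant"].all()

    def test_reference_effect_power_matches_oracle(self, rng):
        # Monte-Carlo power for "all four map-B comparisons survive FDR":
        # dominated by the weakest (GEV) effect; oracle estimate ~0.83
        hits = 0
        reps = 40
        for _ in range(reps):
            a = params_from_moments(rng, 66, "asd", "a")
            b = params_from_moments(rng, 47, "td", "b")
            df = em.compare_groups_fdr(a, b)
            hits += int(df[df["map"] == "B"]["significant"].all())
        assert 0.6 < hits / reps <= 1.0

    def test_too_few_subjects_rejected(self, rng):
        a = params_from_moments(rng, 1, "asd")
        b = params_from_moments(rng, 5, "td")
        with pytest.raises(ValueError):
            em.compare_groups_fdr(a, b)


class TestWelchFromMoments:
    def test_equal_means_give_zero_t(self):
        t, df, p = em.welch_t_from_moments(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_reference_map_b_duration_highly_significant(self):
        ma, sa, na, mt, st_, nt = ref.temporal_moment("B", "mean_duration_ms")
        t, df, p = em.welch_t_from_moments(ma, sa, na, mt, st_, nt)
        assert p < 0.001
        assert t > 0

    def test_matches_raw_data_reduced_to_moments(self, rng):
        a = rng.normal(1.0, 2.0, 35)
        b = rng.normal(0.2, 1.5, 28)
        t_raw, p_raw = sps.ttest_ind(a, b, equal_var=False)
        t_m, _, p_m = em.welch_t_from_moments(a.mean(), a.std(ddof=1), a.size,
                                              b.mean(), b.std(ddof=1), b.size)
        assert t_m == pytest.approx(t_raw)
        assert p_m == pytest.approx(p_raw)

    def test_degenerate_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            em.welch_t_from_moments(1.0, 0.0, 10, 1.0, 0.0, 10)


class TestBenjaminiHochberg:
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=8))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_fdr_matches_step_up_definition(self, pvals):
        p = np.array(pvals)
        reject, _, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        # independent step-up oracle
        m = p.size
        order = np.argsort(p)
        thresh = 0.05 * (np.arange(1, m + 1)) / m
        passing = np.flatnonzero(p[order] <= thresh)
        expect = np.zeros(m, dtype=bool)
        if passing.size:
            expect[order[: passing.max() + 1]] = True
        assert np.array_equal(reject, expect)

    def test_single_comparison_q_equals_p(self, rng):
        a = params_from_moments(rng, 20, "td", "a")
        b = params_from_moments(rng, 20, "td", "b")
        df = em.compare_groups_fdr(a, b)
        row = df.iloc[[7]]
        _, q, _, _ = multipletests(row["p"], alpha=0.05, method="fdr_bh")
        assert q[0] == pytest.approx(row["p"].iloc[0])


class TestCorrelateClinical:
    def _params_and_clinical(self, rng, n=40, rho_noise=0.0):
        params = params_from_moments(rng, n, "asd")
        frame = em.params_to_frame(params)
        b_cov = frame[frame["map"] == "B"].set_index("subject_id")["coverage_pct"]
        clinical = pd.DataFrame({
            "subject_id": [p.subject_id for p in params],
            "group": "ASD",
            "sex": "M",
            "age_years": rng.uniform(2, 5, n),
            "CBCL_AffP": 2.0 * b_cov.values + rho_noise * rng.normal(size=n),
            "MSEL_total_DQ": rng.normal(100, 15, n),
        })
        return params, clinical

    def test_coupled_score_strongly_correlated(self, rng):
        params, clinical = self._params_and_clinical(rng, rho_noise=2.0)
        df = em.correlate_clinical(params, clinical, score_set=["CBCL_AffP"])
        row = df[(df["parameter"] == "B_coverage_pct")].iloc[0]
        assert row["r"] > 0.8
        assert row["p"] < 0.01

    def test_independent_score_uncorrelated(self, rng):
        # over repetitions, raw p < 0.05 at roughly the nominal 5% rate
        raw_p = []
        for _ in range(8):
            params, clinical = self._params_and_clinical(rng)
            df = em.correlate_clinical(params, clinical,
                                       score_set=["MSEL_total_DQ"])
            raw_p.extend(df["p"].tolist())
            assert df["r"].abs().mean() < 0.35
        assert np.mean(np.array(raw_p) < 0.05) < 0.12

    def test_constant_score_skipped(self, rng):
        params, clinical = self._params_and_clinical(rng)
        clinical["flat"] = 7.0
        with pytest.warns(UserWarning):
            df = em.correlate_clinical(params, clinical, score_set=["flat"])
        assert len(df) == 0

    def test_subset_filter_restricts_rows(self, rng):
        params, clinical = self._params_and_clinical(rng)
        clinical.loc[::2, "sex"] = "F"
        df_all = em.correlate_clinical(params, clinical, score_set=["CBCL_AffP"])
        df_m = em.correlate_clinical(params, clinical, score_set=["CBCL_AffP"],
                                     subset="sex == 'M'")
        assert df_m["n"].max() == len(clinical) // 2
        assert df_all["n"].max() == len(clinical)


class TestBootstrapPower:
    def test_null_calibrates_to_alpha(self, rng):
        # large base samples so resampling noise, not the fixed draw's
        # mean offset, dominates the rejection rate
        a = rng.normal(size=5000)
        b = rng.normal(size=5000)
        cfg = em.BootstrapConfig(n_min=10, n_max=40, step=10, reps=500, rng_seed=1)
        curve = em.bootstrap_power_curve(a, b, cfg)
        assert np.all(np.abs(curve["likelihood"] - 0.05) < 0.03)

    def test_curve_nondecreasing_up_to_monte_carlo_error(self, rng):
        a = rng.normal(0.6, 1.0, 300)
        b = rng.normal(0.0, 1.0, 300)
        cfg = em.BootstrapConfig(n_min=3, n_max=47, reps=500, rng_seed=2)
        curve = em.bootstrap_power_curve(a, b, cfg)["likelihood"].to_numpy()
        violations = np.clip(curve[:-1] - curve[1:], 0, None)
        assert violations.max() < 0.05

    def test_invalid_reps_rejected(self):
        with pytest.raises(ValueError):
            em.BootstrapConfig(reps=0)

    def test_gev_effect_detected_half_the_time_at_n20(self):
        ma, sa, _, mt, st_, _ = ref.temporal_moment("B", "gev")
        power = em.power_from_moments(ma, sa, mt, st_, n=20, reps=3000, rng=7)
        assert power == pytest.approx(0.50, abs=0.07)

    def test_duration_effect_detected_half_the_time_at_n12(self):
        ma, sa, _, mt, st_, _ = ref.temporal_moment("B", "mean_duration_ms")
        power = em.power_from_moments(ma, sa, mt, st_, n=12, reps=3000, rng=8)
        assert power == pytest.approx(0.50, abs=0.07)
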
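"""TMP regression, model comparison, prediction grid, Welch tests and
risk flagging."""

import numpy as np
import pandas as pd
import pytest

from avfsound import cohort
from avfsound.features import SubjectFeatures
from avfsound.synthetic import (
    CohortConfig,
    ModelCoefficients,
    SubjectProfile,
    generate_cohort,
    simulate_tmp_observations,
)

REFERENCE_B = ModelCoefficients()  # intercept -1.4819, hz -3e-4, dm -0.1709, vintage 0.1324


def _subject_features(profile, tmp_by_band=None):
    tmp = np.full(40, 25.0) if tmp_by_band is None else tmp_by_band
    return SubjectFeatures(subject_id=profile.subject_id, tmp_by_band=tmp,
                           band_psd=np.full(40, 1.0), mf=200, psd200=0.5,
                           n_cycles_used=3)


class TestBuildLongTable:
    def test_full_cohort_gives_seven_rows_per_subject(self):
        profiles = generate_cohort(CohortConfig(seed=0))
        feats = [_subject_features(p) for p in profiles]
        df = cohort.build_long_table(feats, profiles)
        assert len(df) == 53 * 7
        assert set(df["hz"]) == set(range(100, 701, 100))
        assert df.attrs["n_dropped"] == 0

    def test_missing_band_dropped_and_counted(self):
        profiles = generate_cohort(CohortConfig(n_subjects=5, seed=0))
        tmp = np.full(40, 25.0)
        tmp[3] = np.nan  # silent 400-Hz band for the first subject
        feats = [_subject_features(profiles[0], tmp)] + [
            _subject_features(p) for p in profiles[1:]]
        df = cohort.build_long_table(feats, profiles)
        assert len(df) == 5 * 7 - 1
        assert df.attrs["n_dropped"] == 1

    def test_vintage_five_years_is_inclusive(self):
        p = SubjectProfile("S1", 0, 0, 0, 5.0)
        df = cohort.build_long_table([_subject_features(p)], [p])
        assert (df["vintage_ge5"] == 1).all()

    def test_unmatched_ids_rejected(self):
        p = SubjectProfile("S1", 0, 0, 0, 1.0)
        ghost = _subject_features(SubjectProfile("S9", 0, 0, 0, 1.0))
        with pytest.raises(ValueError, match="S9"):
            cohort.build_long_table([ghost], [p])


class TestFitTmpGlm:
    def test_noiseless_data_recovers_generating_coefficients(self):
        profiles = generate_cohort(CohortConfig(seed=1))
        coef = ModelCoefficients(noise_sd=0.0)
        obs = simulate_tmp_observations(profiles, coef, coding="as_stated", seed=0)
        fit = cohort.fit_tmp_glm(obs, "B")
        assert fit.params["intercept"] == pytest.approx(coef.intercept, abs=1e-6)
        assert fit.params["hz"] == pytest.approx(coef.beta_hz, abs=1e-6)
        assert fit.params["dm"] == pytest.approx(coef.beta_dm, abs=1e-6)
        assert fit.params["vintage_ge5"] == pytest.approx(coef.beta_vintage, abs=1e-6)

    def test_parameter_recovery_with_noise(self):
        """Monte-Carlo: mean diabetes-effect estimate unbiased and its
        CI covers truth at near-nominal rate."""
        est, covered = [], 0
        n_reps = 60
        for rep in range(n_reps):
            profiles = generate_cohort(CohortConfig(seed=1000 + rep))
            obs = simulate_tmp_observations(profiles, REFERENCE_B,
                                            coding="as_stated", seed=2000 + rep)
            fit = cohort.fit_tmp_glm(obs, "B")
            est.append(fit.params["dm"])
            lo, hi = fit.conf_int["dm"]
            covered += lo <= REFERENCE_B.beta_dm <= hi
        assert np.mean(est) == pytest.approx(REFERENCE_B.beta_dm, abs=0.02)
        assert 0.85 <= covered / n_reps <= 1.0

    def test_recovery_under_grid_consistent_coding(self):
        """When data are simulated with the diabetes effect on the
        no-diabetes group, the fitted indicator coefficient is the
        sign-flipped effect and the intercept absorbs it."""
        profiles = generate_cohort(CohortConfig(seed=3))
        coef = ModelCoefficients(noise_sd=0.0)
        obs = simulate_tmp_observations(profiles, coef, coding="table4", seed=0)
        fit = cohort.fit_tmp_glm(obs, "B")
        assert fit.params["dm"] == pytest.approx(-coef.beta_dm, abs=1e-6)
        assert fit.params["intercept"] == pytest.approx(
            coef.intercept + coef.beta_dm, abs=1e-6)

    def test_null_covariates_rarely_reach_two_se(self):
        """Under a generating model without hypertension/event effects,
        the full model's extra terms should look null."""
        hits_ht = hits_event = 0
        n_reps = 40
        for rep in range(n_reps):
            profiles = generate_cohort(CohortConfig(seed=5000 + rep))
            obs = simulate_tmp_observations(profiles, REFERENCE_B,
                                            coding="as_stated", seed=6000 + rep)
            fit = cohort.fit_tmp_glm(obs, "A")
            hits_ht += abs(fit.params["ht"]) < 2 * fit.bse["ht"]
            hits_event += abs(fit.params["event"]) < 2 * fit.bse["event"]
        assert hits_ht / n_reps >= 0.9
        assert hits_event / n_reps >= 0.9

    def test_constant_covariate_rejected(self):
        profiles = [SubjectProfile(f"S{i}", 0, i % 2, i % 2, 1.0 + 5 * (i % 2))
                    for i in range(10)]
        obs = simulate_tmp_observations(profiles, REFERENCE_B, seed=0)
        with pytest.raises(ValueError, match="dm"):
            cohort.fit_tmp_glm(obs, "B")


class TestCompareModels:
    def _fit_like(self, label, aic, n_obs=371, n_terms=4):
        terms = tuple(["intercept"] + [f"x{i}" for i in range(n_terms - 1)])
        return cohort.GLMFit(
            model_label=label, terms=terms,
            params={t: 0.0 for t in terms}, bse={t: 1.0 for t in terms},
            conf_int={t: (-1.0, 1.0) for t in terms},
            pvalues={t: 0.5 for t in terms}, aic=aic, n_obs=n_obs,
            cov_params=np.eye(n_terms))

    def test_reference_aics_prefer_full_model(self):
        assert cohort.compare_models(self._fit_like("A", 441.2, n_terms=6),
                                     self._fit_like("B", 444.8)) == "A"

    def test_equal_aic_prefers_smaller_model(self):
        assert cohort.compare_models(self._fit_like("A", 400.0, n_terms=6),
                                     self._fit_like("B", 400.0)) == "B"

    def test_different_n_obs_rejected(self):
        with pytest.raises(ValueError, match="371"):
            cohort.compare_models(self._fit_like("A", 400.0),
                                  self._fit_like("B", 401.0, n_obs=370))


class TestPredictTmpGrid:
    # the full published 4-group x 7-frequency grid of point estimates
    PUBLISHED = {
        (0, 0): [18.6, 18.0, 17.5, 17.0, 16.5, 16.0, 15.5],
        (0, 1): [21.2, 20.6, 20.0, 19.4, 18.8, 18.3, 17.7],
        (1, 0): [22.0, 21.4, 20.8, 20.2, 19.6, 19.0, 18.4],
        (1, 1): [25.2, 24.4, 23.7, 23.0, 22.3, 21.7, 21.0],
    }

    def test_reproduces_all_28_published_estimates(self):
        grid = cohort.predict_tmp_grid(REFERENCE_B, coding="table4")
        for (dm, v), expected in self.PUBLISHED.items():
            got = grid[(grid.dm == dm) & (grid.vintage_ge5 == v)].sort_values("hz")
            assert np.allclose(np.round(got["estimate_pct"], 1), expected, atol=0.05)

    def test_estimates_strictly_decrease_with_frequency(self):
        grid = cohort.predict_tmp_grid(REFERENCE_B)
        for (_, _), g in grid.groupby(["dm", "vintage_ge5"]):
            assert np.all(np.diff(g.sort_values("hz")["estimate_pct"]) < 0)

    def test_zero_frequency_effect_gives_flat_profile(self):
        flat = ModelCoefficients(beta_hz=0.0)
        grid = cohort.predict_tmp_grid(flat)
        for (_, _), g in grid.groupby(["dm", "vintage_ge5"]):
            assert g["estimate_pct"].nunique() == 1

    def test_fit_based_grid_carries_delta_method_cis(self):
        profiles = generate_cohort(CohortConfig(seed=2))
        obs = simulate_tmp_observations(profiles, REFERENCE_B,
                                        coding="as_stated", seed=1)
        fit = cohort.fit_tmp_glm(obs, "B")
        grid = cohort.predict_tmp_grid(fit, coding="as_stated")
        assert np.all(grid["ci_low"] < grid["estimate_pct"])
        assert np.all(grid["estimate_pct"] < grid["ci_high"])


class TestWelch:
    def test_identical_groups_give_zero_t_unit_p(self):
        c = cohort.welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert c.t == 0.0 and c.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        c = cohort.welch_t_test([1, 2, 3], [4, 5, 6])
        assert c.t == pytest.approx(-3.674, abs=0.001)
        assert c.df == pytest.approx(4.0)
        assert c.p == pytest.approx(0.0213, abs=0.0005)

    def test_swapping_groups_negates_t_preserves_p(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 12), rng.normal(0.7, 2, 8)
        a = cohort.welch_t_test(x, y)
        b = cohort.welch_t_test(y, x)
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    def test_event_group_interval_matches_published_bounds(self):
        """A group with mean 7,502, SD 8,774 and n=9 must yield the
        published 95% CI of roughly [757, 14,246]."""
        values = _with_moments(9, 7502.0, 8774.0)
        c = cohort.welch_t_test(values, [1.0, 2.0, 3.0])
        lo, hi = c.ci[0]
        assert lo == pytest.approx(757, abs=1.0)
        assert hi == pytest.approx(14246, abs=1.0)

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValueError):
            cohort.welch_t_test([1.0], [2.0, 3.0])


def _with_moments(n, mean, sd):
    """A sample with exactly the requested mean and (ddof=1) SD."""
    base = np.arange(n, dtype=np.float64)
    base = (base - base.mean()) / base.std(ddof=1)
    return base * sd + mean


class TestComparePsd200AndRisk:
    def test_comparisons_cover_all_four_groupings(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "psd200": rng.normal(10, 2, 40),
            "dm": rng.integers(0, 2, 40), "ht": rng.integers(0, 2, 40),
            "event": rng.integers(0, 2, 40), "vintage_ge5": rng.integers(0, 2, 40),
        })
        comps = cohort.compare_psd200_by_history(df)
        assert [c.variable for c in comps] == ["dm", "ht", "event", "vintage_ge5"]

    def test_single_subject_level_rejected(self):
        df = pd.DataFrame({
            "psd200": np.arange(10.0),
            "dm": [1] + [0] * 9, "ht": [0, 1] * 5,
            "event": [0, 1] * 5, "vintage_ge5": [0, 1] * 5,
        })
        with pytest.raises(ValueError, match="dm"):
            cohort.compare_psd200_by_history(df)

    def test_flag_risk_boundary_is_strict(self):
        assert cohort.flag_risk(7502.0) is True
        assert cohort.flag_risk(30011.0) is False
        assert cohort.flag_risk(14246.0) is False


class TestEventContrastOnGeneratedCohorts:
    @staticmethod
    def _cohort_psd200(seed):
        """Subject-level PSD200 for a generated cohort, via the full
        acoustic pipeline."""
        from avfsound import features, segmentation, synthetic
        profiles = generate_cohort(CohortConfig(seed=seed))
        rows = []
        for i, p in enumerate(profiles):
            cfg = synthetic.AcousticsConfig(seed=seed * 100 + i, n_cycles=4)
            rec = synthetic.generate_waveform(p, cfg)
            segs = segmentation.detect_cycles(
                segmentation.compute_envelope(rec), rec.sample_rate)
            agg = features.aggregate_subject(
                [features.cycle_features(s.extract(rec), rec.sample_rate)
                 for s in segs], p.subject_id)
            rows.append({"psd200": agg.psd200, "dm": p.dm, "ht": p.ht,
                         "event": p.event, "vintage_ge5": p.vintage_ge5})
        return pd.DataFrame(rows)

    def test_event_attenuation_detected_by_welch(self):
        """The attenuated 200-Hz peak of event subjects should make the
        event contrast significant in nearly every generated cohort."""
        hits = 0
        n_cohorts = 12
        for seed in range(n_cohorts):
            df = self._cohort_psd200(seed)
            if df["event"].sum() < 2 or (1 - df["event"]).sum() < 2:
                n_cohorts -= 1
                continue
            comp = [c for c in cohort.compare_psd200_by_history(df)
                    if c.variable == "event"][0]
            neg_mean, pos_mean = comp.mean
            hits += (pos_mean < neg_mean) and (comp.p < 0.05)
        assert hits / n_cohorts >= 0.9

    def test_permuted_labels_give_uniform_pvalues(self):
        """With event labels shuffled the Welch p-value should be
        calibrated (uniform on [0, 1])."""
        from scipy import stats as sps
        df = self._cohort_psd200(99)
        values = df["psd200"].to_numpy()
        rng = np.random.default_rng(42)
        pvals = []
        for _ in range(300):
            perm = rng.permutation(len(values))
            pvals.append(cohort.welch_t_test(values[perm[:44]],
                                             values[perm[44:]]).p)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
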
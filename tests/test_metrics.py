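"""Evaluation metrics: normalization, pooling, AUC estimators, %PE, SF fit."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from adcpbpk import DeconjugationParams
from adcpbpk.metrics import (auc_sparse, auc_trapezoid, dose_normalize, fit_sf,
                             kp_sensitivity, observed_dar_profile, percent_pe,
                             payload_source_attribution, pool_profiles,
                             _integrate_dar)


def _records(times, concs, dose=5.0, analyte="total_mAb", study="s1", unit="ug/mL"):
    return pd.DataFrame({
        "study": study, "species": "rat", "analyte": analyte, "matrix": "plasma",
        "dose_mgkg": dose, "time_day": times, "conc": concs, "unit": unit})


class TestDoseNormalize:
    def test_proportional_scaling(self):
        out = dose_normalize(_records([1.0], [10.0], dose=5.0), 10.0)
        assert out["conc"].iloc[0] == 20.0
        assert out["dose_mgkg"].iloc[0] == 10.0

    def test_identity_at_same_dose(self):
        out = dose_normalize(_records([1.0], [10.0], dose=5.0), 5.0)
        assert out["conc"].iloc[0] == 10.0

    def test_roundtrip(self):
        rec = _records([1.0, 2.0], [10.0, 7.0], dose=5.0)
        back = dose_normalize(dose_normalize(rec, 10.0), 5.0)
        assert np.allclose(back["conc"], rec["conc"])

    def test_zero_dose_rejected(self):
        with pytest.raises(ValueError):
            dose_normalize(_records([1.0], [10.0], dose=0.0), 10.0)


class TestPooling:
    def test_single_record_per_bin(self):
        out = pool_profiles(_records([1.0, 2.0], [10.0, 8.0]))
        assert list(out["mean_conc"]) == [10.0, 8.0]
        assert list(out["n"]) == [1, 1]

    def test_mean_of_two(self):
        out = pool_profiles(_records([1.0, 1.0], [10.0, 20.0]))
        assert len(out) == 1
        assert out["mean_conc"].iloc[0] == 15.0

    def test_order_invariance(self):
        rec = _records([3.0, 1.0, 1.01, 7.0], [5.0, 10.0, 12.0, 2.0])
        shuffled = rec.sample(frac=1.0, random_state=4)
        a = pool_profiles(rec)
        b = pool_profiles(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_profiles(_records([], []))


class TestDarProfile:
    def test_molar_ratio(self):
        conj = pool_profiles(_records([1.0], [400 * 717.98e-3], analyte="conjugated_MMAE",
                                      unit="ng/mL"))
        mab = pool_profiles(_records([1.0], [100 * 150000e-6]))
        prof = observed_dar_profile(conj, mab)
        assert prof["DAR"].iloc[0] == pytest.approx(4.0)

    def test_zero_conjugated_gives_zero_dar(self):
        conj = pool_profiles(_records([1.0], [0.0], analyte="conjugated_MMAE", unit="ng/mL"))
        mab = pool_profiles(_records([1.0], [10.0]))
        assert observed_dar_profile(conj, mab)["DAR"].iloc[0] == 0.0

    def test_zero_mab_bin_dropped_with_warning(self):
        conj = pool_profiles(_records([1.0, 2.0], [1.0, 1.0], analyte="conjugated_MMAE",
                                      unit="ng/mL"))
        mab = pool_profiles(_records([1.0, 2.0], [10.0, 0.0]))
        with pytest.warns(UserWarning, match="zero antibody"):
            prof = observed_dar_profile(conj, mab)
        assert len(prof) == 1


class TestAuc:
    def test_constant_profile(self):
        assert auc_trapezoid([0.0, 2.0, 5.0], [3.0, 3.0, 3.0]) == pytest.approx(15.0)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            auc_trapezoid([1.0], [1.0])

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            auc_trapezoid([0.0, 2.0, 1.0], [1.0, 1.0, 1.0])

    def test_exponential_closed_form(self):
        t = np.linspace(0, 10, 2000)
        assert auc_trapezoid(t, np.exp(-t)) == pytest.approx(1 - np.exp(-10), rel=1e-5)

    def test_sparse_single_obs_equals_trapezoid(self):
        t = [0.0, 1.0, 3.0, 7.0]
        c = [10.0, 6.0, 3.0, 1.0]
        r = auc_sparse(_records(t, c))
        assert r.auc == pytest.approx(auc_trapezoid(t, c))
        assert not r.se_defined and r.se == 0.0

    def test_sparse_duplicated_obs_zero_se(self):
        t = [0.0, 0.0, 1.0, 1.0, 3.0, 3.0]
        c = [10.0, 10.0, 6.0, 6.0, 3.0, 3.0]
        r = auc_sparse(_records(t, c))
        assert r.se == 0.0 and r.se_defined

    def test_sparse_single_bin_rejected(self):
        with pytest.raises(ValueError):
            auc_sparse(_records([1.0, 1.0], [5.0, 6.0]))


class TestPercentPe:
    def test_exact_prediction(self):
        assert percent_pe(5.0, 5.0) == 0.0

    def test_twofold_bounds(self):
        assert percent_pe(2.0, 1.0) == 100.0
        assert percent_pe(1.0, 2.0) == -100.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            percent_pe(0.0, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-3, max_value=1e3),
           st.floats(min_value=1e-3, max_value=1e3))
    def test_antisymmetry(self, a, b):
        assert percent_pe(a, b) == pytest.approx(-percent_pe(b, a), rel=1e-12)


class TestFitSf:
    def test_noise_free_recovery(self):
        t = np.array([1.0, 3.0, 7.0, 14.0, 21.0, 28.0, 42.0])
        p = dataclasses.replace(DeconjugationParams(), SF=0.3)
        d = _integrate_dar(t, p, 4.0)
        fit = fit_sf(pd.DataFrame({"time_day": t, "DAR": d}), DeconjugationParams(), 4.0)
        assert fit.converged
        assert fit.sf == pytest.approx(0.3, abs=1e-3)

    def test_noisy_recovery_within_20_percent(self):
        t = np.array([1.0, 3.0, 7.0, 14.0, 21.0, 28.0, 35.0, 42.0])
        truth = 0.6
        p = dataclasses.replace(DeconjugationParams(), SF=truth)
        d0 = _integrate_dar(t, p, 4.0)
        rng = np.random.default_rng(11)
        ok = 0
        n_rep = 100
        for _ in range(n_rep):
            noise = np.exp(rng.normal(0.0, 0.1, size=len(t)))
            fit = fit_sf(pd.DataFrame({"time_day": t, "DAR": d0 * noise}),
                         DeconjugationParams(), 4.0)
            ok += abs(fit.sf / truth - 1.0) < 0.20
        assert ok / n_rep >= 0.90

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_sf(pd.DataFrame({"time_day": [1.0, 2.0], "DAR": [4.0, 3.9]}),
                   DeconjugationParams(), 4.0)


class TestSimulationMetrics:
    def test_kp_sensitivity_sign(self, rat_model):
        reg_kw = dict(n_points=200)
        from adcpbpk import build_regimen
        df = kp_sensitivity(rat_model, build_regimen("single", 1.0), 14.0,
                            tissues=["kidney"], **reg_kw)
        up = df[(df.tissue == "kidney") & (df.perturbation == "+20%")]
        down = df[(df.tissue == "kidney") & (df.perturbation == "-20%")]
        # equilibrium-ratio oracle: higher Kp raises that tissue's cellular AUC
        assert up["tissue_auc_pct_change"].iloc[0] > 0
        assert down["tissue_auc_pct_change"].iloc[0] < 0

    def test_attribution_fractions_sum_to_one(self, rat_single):
        att = payload_source_attribution(rat_single)
        frac = att.drop(columns="time_day").to_numpy().sum(axis=1)
        assert np.allclose(frac, 1.0, atol=1e-9)

    def test_attribution_detail_matches_summary(self, rat_single):
        att = payload_source_attribution(rat_single, detail=True)
        frac = att.drop(columns="time_day").to_numpy().sum(axis=1)
        assert np.allclose(frac, 1.0, atol=1e-9)

    def test_no_degradation_means_pure_deconjugation(self):
        import adcpbpk
        params = adcpbpk.default_parameters("rat")
        params = dataclasses.replace(
            params, mab=dataclasses.replace(params.mab, kdeg_base=0.0))
        res = adcpbpk.AdcPbpkModel(species="rat", params=params).simulate(
            adcpbpk.build_regimen("single", 5.0), 14.0)
        att = payload_source_attribution(res)
        assert np.all(att["tissue_degradation"].to_numpy() == 0.0)
        deconj = att["plasma_deconjugation"] + att["tissue_deconjugation"]
        assert np.allclose(deconj, 1.0, atol=1e-12)
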
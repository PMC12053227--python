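"""DAR kinetics, interspecies scaling and analyte assembly."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from adcpbpk import (DeconjugationParams, allometric_sf, analyte_assembly,
                     dar_derivative, deconjugation_release_fluxes,
                     degradation_release_flux, kdec_of_dar, kdeg_for_species)
from adcpbpk.metrics import observed_dar_profile
import pandas as pd

P = DeconjugationParams()  # published coefficients, SF = 1


class TestKdec:
    def test_high_dar_limit_is_alpha(self):
        assert kdec_of_dar(1e6, P) == pytest.approx(P.alpha, rel=1e-9)

    def test_zero_dar_limit_is_beta(self):
        assert kdec_of_dar(0.0, P) == pytest.approx(P.beta, abs=1e-15)
        assert kdec_of_dar(1e-9, P) == pytest.approx(P.beta, rel=1e-6)

    def test_at_dar4_value_close_to_alpha(self):
        # high-precision evaluation of the published expression as oracle:
        # 4^-5.68 = 3.84e-4 << F, so k_dec(4) is within 0.2% of alpha
        dar = 4.0
        expected = (P.alpha - (P.alpha - P.beta) * dar ** -P.tau
                    / (P.F + dar ** -P.tau)) * P.SF
        assert kdec_of_dar(4.0, P) == pytest.approx(expected, rel=1e-12)
        assert abs(kdec_of_dar(4.0, P) / P.alpha - 1) < 2e-3

    def test_negative_dar_rejected(self):
        with pytest.raises(ValueError):
            kdec_of_dar(-0.1, P)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1e3),
           st.floats(min_value=0.0, max_value=1e3))
    def test_monotone_and_bounded(self, d1, d2):
        k1, k2 = kdec_of_dar(d1, P), kdec_of_dar(d2, P)
        assert P.beta * P.SF - 1e-15 <= k1 <= P.alpha * P.SF + 1e-15
        if d1 <= d2:
            assert k1 <= k2 + 1e-15


class TestDarOde:
    def test_zero_dar_has_zero_derivative(self):
        assert dar_derivative(0.0, P) == 0.0

    def test_constant_rate_case_is_exponential(self):
        # alpha = beta collapses the ODE to dDAR/dt = -k*SF*DAR
        p = dataclasses.replace(P, alpha=0.05, beta=0.05, SF=0.6)
        sol = solve_ivp(lambda t, y: dar_derivative(y[0], p), (0, 30), [4.0],
                        t_eval=np.linspace(0, 30, 7), rtol=1e-10, atol=1e-12)
        expected = 4.0 * np.exp(-0.05 * 0.6 * sol.t)
        assert np.allclose(sol.y[0], expected, rtol=1e-8)

    def test_biphasic_decline_slopes(self):
        # early log-slope ~ -alpha (high DAR), late log-slope ~ -beta (low DAR)
        sol = solve_ivp(lambda t, y: dar_derivative(y[0], P), (0, 2000), [4.0],
                        t_eval=[0, 1, 1500, 1501], rtol=1e-10, atol=1e-12)
        early = -np.log(sol.y[0][1] / sol.y[0][0])
        late = -np.log(sol.y[0][3] / sol.y[0][2])
        assert early == pytest.approx(P.alpha, rel=0.01)
        assert late == pytest.approx(P.beta, rel=0.15)
        assert sol.y[0][-1] > 0


class TestScaling:
    @pytest.mark.parametrize("bw,expected", [(0.028, 1.0), (0.28, 0.6),
                                             (6.2, 0.3), (70.0, 0.1)])
    def test_species_sf_after_rounding(self, bw, expected):
        assert round(allometric_sf(bw, 0.028, -0.25), 1) == pytest.approx(expected)

    def test_sf_strictly_decreasing_in_weight(self):
        bws = np.linspace(0.028, 70, 50)
        sfs = [allometric_sf(b, 0.028, -0.25) for b in bws]
        assert all(a > b for a, b in zip(sfs, sfs[1:]))

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            allometric_sf(-1.0, 0.028, -0.25)

    @pytest.mark.parametrize("fold,expected", [(1.0, 30.0), (3.0, 90.0), (4.0, 120.0)])
    def test_kdeg_fold_change(self, fold, expected):
        assert kdeg_for_species(30.0, fold) == expected


class TestReleaseFluxes:
    def test_zero_dar_or_zero_rate_gives_zero_sources(self):
        amounts = {"blood": 5.0, "liver_v": 1.0}
        assert all(v == 0 for v in deconjugation_release_fluxes(amounts, 0.0, P).values())
        assert degradation_release_flux(1.0, 0.0, 4.0) == 0.0
        assert degradation_release_flux(1.0, 1.0, 0.0) == 0.0

    def test_source_sum_matches_bookkeeping(self):
        amounts = {"a": 1.5, "b": 2.5, "c": 0.25}
        dar = 3.0
        fluxes = deconjugation_release_fluxes(amounts, dar, P)
        k = kdec_of_dar(dar, P) / 24.0
        assert sum(fluxes.values()) == pytest.approx(k * dar * sum(amounts.values()))


class TestAnalyteAssembly:
    def test_zero_dar_zero_conjugated(self):
        out = analyte_assembly(100.0, 0.0, 5.0, 150000.0, 717.98)
        assert out["conjugated_MMAE_ngml"] == 0.0

    def test_arithmetic_oracle(self):
        out = analyte_assembly(100.0, 4.0, 0.0, 150000.0, 717.98)
        assert out["conjugated_MMAE_ngml"] == pytest.approx(4 * 100 * 717.98 * 1e-3)
        assert out["total_mAb_ugml"] == pytest.approx(100 * 150000 * 1e-6)

    def test_observed_dar_roundtrip(self):
        dar_in = 2.7
        out = analyte_assembly(80.0, dar_in, 1.0, 150000.0, 717.98)
        conj = pd.DataFrame({"time_day": [1.0], "mean_conc": [out["conjugated_MMAE_ngml"]],
                             "unit": ["ng/mL"]})
        mab = pd.DataFrame({"time_day": [1.0], "mean_conc": [out["total_mAb_ugml"]],
                            "unit": ["ug/mL"]})
        prof = observed_dar_profile(conj, mab)
        assert prof["DAR"].iloc[0] == pytest.approx(dar_in, rel=1e-12)
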
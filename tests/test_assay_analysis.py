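import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from caxport.assay_analysis import (
    KineticFit,
    LretMeasurement,
    SpeciationParams,
    estimate_stoichiometry,
    fit_itc_one_site,
    fit_lifetime,
    fit_michaelis_menten,
    fold_acceleration,
    forster_distance,
    one_site_heats,
    ph_profile_peak,
    phosphate_speciation,
    tau_da_for_distance,
)
from caxport.synthetic_data import (
    ItcSimConfig,
    TransportSimConfig,
    gen_initial_rates,
    gen_itc_isotherm,
    gen_lret_decay,
    gen_paired_rates,
)

GRID_UM = np.geomspace(10, 1000, 8)


class TestMichaelisMenten:
    def test_noiseless_recovery_within_point1_percent(self):
        df = gen_initial_rates(69.0, 4.2, GRID_UM, noise_cv=0.0, n_rep=1)
        fit = fit_michaelis_menten(df)
        assert fit.converged
        assert abs(fit.km - 69.0) / 69.0 < 1e-3
        assert abs(fit.vmax - 4.2) / 4.2 < 1e-3

    def test_half_maximal_rate_at_km(self):
        df = gen_initial_rates(69.0, 4.2, GRID_UM, noise_cv=0.0, n_rep=1)
        fit = fit_michaelis_menten(df)
        v_at_km = fit.vmax * fit.km / (fit.km + fit.km)
        assert v_at_km == pytest.approx(fit.vmax / 2.0)

    def test_all_zero_rates_flagged(self):
        df = pd.DataFrame({"conc": GRID_UM, "rate": np.zeros(8)})
        fit = fit_michaelis_menten(df)
        assert not fit.converged

    def test_too_few_concentrations_rejected(self):
        df = pd.DataFrame({"conc": [1.0, 2.0, 3.0], "rate": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError):
            fit_michaelis_menten(df)


class TestFoldAcceleration:
    def _fit(self, vmax, se):
        return KineticFit(km=50.0, vmax=vmax, km_se=1.0, vmax_se=se,
                          km_ci95=(45, 55), vmax_ci95=(vmax - se, vmax + se),
                          converged=True, n_points=8, rss=0.0)

    def test_reported_kinetics_give_about_eightfold(self):
        ratio, _err = fold_acceleration(self._fit(33.3, 0.0), self._fit(4.2, 0.0))
        assert ratio == pytest.approx(7.93, abs=0.01)

    def test_identical_fits_ratio_one(self):
        ratio, err = fold_acceleration(self._fit(4.2, 0.0), self._fit(4.2, 0.0))
        assert (ratio, err) == (1.0, 0.0)

    def test_error_symmetric_in_relative_errors(self):
        _r, e1 = fold_acceleration(self._fit(10.0, 1.0), self._fit(5.0, 0.25))
        _r, e2 = fold_acceleration(self._fit(10.0, 0.5), self._fit(5.0, 0.5))
        # both cases have the same relative errors {10%, 5%}
        assert e1 == pytest.approx(e2)

    def test_unconverged_input_rejected(self):
        bad = KineticFit(np.nan, np.nan, np.nan, np.nan, (np.nan, np.nan),
                         (np.nan, np.nan), converged=False, n_points=8, rss=1.0)
        with pytest.raises(ValueError):
            fold_acceleration(self._fit(10, 0.1), bad)


class TestStoichiometry:
    def test_exactly_equal_pairs(self):
        df = pd.DataFrame({"ca_rate": [1.0, 2.0, 3.0], "pi_rate": [1.0, 2.0, 3.0]})
        slope, (lo, hi) = estimate_stoichiometry(df, seed=1)
        assert slope == 1.0
        assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_through_origin_slope(self):
        df = pd.DataFrame({"ca_rate": [1.0, 2.0, 3.0], "pi_rate": [2.0, 4.0, 6.0]})
        slope, _ci = estimate_stoichiometry(df, seed=1)
        assert slope == pytest.approx(2.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 5, 12)
        y = 1.3 * x + rng.normal(0, 0.1, 12)
        df = pd.DataFrame({"ca_rate": x, "pi_rate": y})
        df_scaled = df * 7.5
        s1, _ = estimate_stoichiometry(df, seed=2)
        s2, _ = estimate_stoichiometry(df_scaled, seed=2)
        assert s1 == pytest.approx(s2)

    def test_generator_recovery_ci_coverage(self):
        """The bootstrap 95% CI brackets the true 1:1 ratio for most seeds."""
        hits = 0
        for seed in range(20):
            cfg = TransportSimConfig(mode="co_transport", noise_cv=0.05, seed=seed)
            df = gen_paired_rates(cfg, np.linspace(0.5, 8, 8), 500.0, 5.0, n_rep=4)
            _slope, (lo, hi) = estimate_stoichiometry(df, seed=seed)
            hits += lo <= 1.0 <= hi
        assert hits >= 17

    def test_all_zero_rates_rejected(self):
        df = pd.DataFrame({"ca_rate": [0.0] * 4, "pi_rate": [0.0] * 4})
        with pytest.raises(ValueError):
            estimate_stoichiometry(df)


class TestItcFit:
    def test_noiseless_roundtrip_kd_within_1_percent(self):
        cfg = ItcSimConfig(kd=0.93e-3, delta_h=-3.0, cell_conc=10e-6,
                           syringe_conc=10e-3, noise_sd=0.0)
        fit = fit_itc_one_site(gen_itc_isotherm(cfg), 10e-6, 10e-3, 10e-6,
                               fix_n=1.0)
        assert fit.converged
        assert abs(fit.kd - cfg.kd) / cfg.kd < 0.01

    def test_no_signal_is_flagged(self):
        cfg = ItcSimConfig(kd=10.0, cell_conc=5e-6, syringe_conc=1e-4,
                           noise_sd=0.0)
        fit = fit_itc_one_site(gen_itc_isotherm(cfg), 5e-6, 1e-4, 10e-6)
        assert (not fit.converged) or fit.flags

    def test_heats_linear_in_enthalpy(self):
        kwargs = dict(kd=1e-6, n_sites=1.0, cell_conc=5e-6, syringe_conc=1e-4,
                      injection_volume=10e-6, n_injections=20)
        h1 = one_site_heats(delta_h=-4.0, **kwargs)
        h2 = one_site_heats(delta_h=-8.0, **kwargs)
        assert np.allclose(h2, 2.0 * h1)

    def test_too_few_injections_rejected(self):
        df = pd.DataFrame({"injection": [1, 2], "heat_ucal": [1.0, 0.5]})
        with pytest.raises(ValueError):
            fit_itc_one_site(df, 5e-6, 1e-4, 10e-6)


class TestLifetime:
    def test_noiseless_recovery(self):
        fit = fit_lifetime(gen_lret_decay(1.5, noise_sd=0.0))
        assert fit.converged
        assert abs(fit.tau - 1.5) / 1.5 < 1e-3

    def test_decay_falls_to_1_over_e_at_tau(self):
        fit = fit_lifetime(gen_lret_decay(2.0, noise_sd=0.0))
        y_tau = fit.amplitude * math.exp(-fit.tau / fit.tau) + fit.baseline
        y_0 = fit.amplitude + fit.baseline
        assert y_tau / y_0 == pytest.approx(math.exp(-1), abs=1e-3)

    def test_flat_trace_flagged(self):
        df = pd.DataFrame({"t": np.linspace(0, 5, 50), "y": np.ones(50)})
        fit = fit_lifetime(df)
        assert not fit.converged
        assert "non_decaying" in fit.flags


class TestForster:
    def test_half_lifetime_gives_r0(self):
        m = LretMeasurement(tau_d=1.5, tau_da=0.75, r0=30.0)
        assert forster_distance(m) == pytest.approx(30.0)

    def test_short_lifetime_limit_gives_short_distance(self):
        m = LretMeasurement(tau_d=1.5, tau_da=1e-9, r0=30.0)
        assert forster_distance(m) < 1.0

    def test_inverse_roundtrip_at_apo_distance(self):
        tau_da = tau_da_for_distance(25.5, 30.0, 1.5)
        m = LretMeasurement(tau_d=1.5, tau_da=tau_da, r0=30.0)
        assert forster_distance(m) == pytest.approx(25.5, abs=1e-10)

    def test_invalid_lifetime_ordering_rejected(self):
        with pytest.raises(ValueError):
            LretMeasurement(tau_d=1.0, tau_da=1.2, r0=30.0)


class TestSpeciation:
    def test_half_titration_at_pka(self):
        assert phosphate_speciation(7.2) == pytest.approx(0.5)

    def test_one_unit_above_pka(self):
        assert phosphate_speciation(8.2) == pytest.approx(1.0 / 11.0)

    @given(st.floats(0.0, 13.9))
    def test_monotonically_decreasing_in_ph(self, ph):
        assert phosphate_speciation(ph) > phosphate_speciation(min(ph + 0.1, 14.0))

    def test_invalid_pka_rejected(self):
        with pytest.raises(ValueError):
            SpeciationParams(pka=15.0)


class TestPhProfile:
    def test_peak_at_7p5(self):
        df = pd.DataFrame({"ph": [6.5, 7.0, 7.5, 8.0, 8.5],
                           "vmax": [0.04, 0.07, 0.097, 0.06, 0.03]})
        out = ph_profile_peak(df)
        assert out["peak_ph"] == [7.5]
        assert out["flags"] == []

    def test_monotone_profile_flags_boundary(self):
        df = pd.DataFrame({"ph": [6.5, 7.0, 7.5], "vmax": [0.01, 0.02, 0.03]})
        out = ph_profile_peak(df)
        assert out["peak_ph"] == [7.5]
        assert "boundary_maximum" in out["flags"]

    def test_single_point_degenerate(self):
        df = pd.DataFrame({"ph": [7.0], "vmax": [0.05]})
        out = ph_profile_peak(df)
        assert out["peak_ph"] == [7.0]
        assert "degenerate_single_point" in out["flags"]

    def test_ties_report_all(self):
        df = pd.DataFrame({"ph": [6.5, 7.0, 7.5], "vmax": [0.01, 0.03, 0.03]})
        out = ph_profile_peak(df)
        assert out["peak_ph"] == [7.0, 7.5]
        assert "tied_maximum" in out["flags"]
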
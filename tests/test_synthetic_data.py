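import math

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from caxport.assay_analysis import fit_itc_one_site, fit_lifetime
from caxport.protonation_fep import exp_free_energy
from caxport.site_survey import pairwise_identity, parse_structure
from caxport.synthetic_data import (
    CA_RESNUM,
    PHOSPHATE_RESNUM,
    SITE_RESIDUES,
    FepSimConfig,
    ItcSimConfig,
    ScaffoldSpec,
    TransportSimConfig,
    build_scaffold,
    gen_fep_samples,
    gen_initial_rates,
    gen_itc_isotherm,
    gen_lret_decay,
    gen_paired_rates,
    gen_transport_timecourse,
)


class TestScaffold:
    def test_contains_all_site_residues_and_ions(self, scaffold):
        residues = {(num, name3) for (_c, num, name3) in scaffold.residues()
                    if name3 in SITE_RESIDUES.values()}
        assert residues == set(SITE_RESIDUES.items())
        ca = scaffold.atom(CA_RESNUM, "CA")
        assert ca.element == "Ca"
        pho = [a for a in scaffold.atoms if a.residue_number == PHOSPHATE_RESNUM]
        assert {a.name for a in pho} == {"P", "O1", "O2", "O3", "O4"}

    def test_carboxylate_oxygens_near_calcium_seed(self, scaffold):
        ca = scaffold.atom(CA_RESNUM, "CA").pos
        for num in (72, 255):
            for name in ("OE1", "OE2"):
                assert np.linalg.norm(scaffold.atom(num, name).pos - ca) < 6.0

    def test_initial_ion_pair_distance_under_8A(self, scaffold):
        ca = scaffold.atom(CA_RESNUM, "CA").pos
        p = scaffold.atom(PHOSPHATE_RESNUM, "P").pos
        assert np.linalg.norm(ca - p) < 8.0

    def test_bitwise_deterministic(self):
        a, b = build_scaffold(), build_scaffold()
        assert all(np.array_equal(x.pos, y.pos) for x, y in zip(a.atoms, b.atoms))

    def test_missing_site_position_rejected(self):
        types = dict(SITE_RESIDUES)
        del types[256]
        with pytest.raises(ValidationError, match="256"):
            ScaffoldSpec(residue_types=types)

    def test_invalid_residue_identity_rejected(self):
        types = dict(SITE_RESIDUES)
        types[256] = "XXX"
        with pytest.raises(ValidationError, match="invalid residue identity"):
            ScaffoldSpec(residue_types=types)


class TestSurveyFixtures:
    def test_truth_table_labels(self, survey_fixture_dir):
        _out, paths, truth = survey_fixture_dir
        assert len(paths) >= 6
        labels = dict(zip(truth.source_id, truth.label))
        reasons = dict(zip(truth.source_id, truth.reason))
        assert labels["fix_pos_a"] == labels["fix_pos_b"] == "accept"
        assert reasons["fix_neg_distance"] == "distance"
        assert reasons["fix_neg_motif"] == "motif"
        assert reasons["fix_neg_resolution"] == "resolution"
        assert reasons["fix_neg_redundant"] == "redundancy"

    def test_positive_remeasures_within_ion_distance(self, survey_fixture_dir):
        out, _paths, _truth = survey_fixture_dir
        m = parse_structure(out / "fix_pos_a.pdb")
        ca = next(a for a in m.atoms if a.element == "Ca")
        pho = [a for a in m.atoms if a.residue_number == PHOSPHATE_RESNUM
               and a.element == "O"]
        dmin = min(np.linalg.norm(ca.pos - a.pos) for a in pho)
        assert dmin <= 3.2

    def test_redundancy_pair_identity_at_least_70_percent(self, survey_fixture_dir):
        out, _paths, _truth = survey_fixture_dir
        a = parse_structure(out / "fix_pos_a.pdb")
        dup = parse_structure(out / "fix_neg_redundant.pdb")
        ident = pairwise_identity(a.chain_sequences["A"], dup.chain_sequences["A"])
        assert ident >= 0.70


class TestInitialRates:
    def test_half_saturation_at_km(self):
        df = gen_initial_rates(69.0, 4.2, [69.0], noise_cv=0.0, n_rep=1)
        assert df.rate.iloc[0] == pytest.approx(2.1)

    def test_saturating_limit_approaches_vmax(self):
        df = gen_initial_rates(69.0, 4.2, [69.0e6], noise_cv=0.0, n_rep=1)
        assert df.rate.iloc[0] == pytest.approx(4.2, rel=1e-3)

    def test_seed_reproducibility(self):
        grid = [10, 30, 100, 300]
        a = gen_initial_rates(69.0, 4.2, grid, 0.05, 3, seed=7)
        b = gen_initial_rates(69.0, 4.2, grid, 0.05, 3, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            gen_initial_rates(69.0, 4.2, [])


class TestTimecourse:
    times = np.linspace(0.0, 10.0, 9)

    def test_protonophore_mode_is_noise_around_zero(self):
        cfg = TransportSimConfig(mode="cccp", noise_cv=0.05, seed=2)
        df = gen_transport_timecourse(cfg, self.times, 500.0, 5.0)
        # mean uptake statistically indistinguishable from zero
        sem = df.ca_uptake.std(ddof=1) / math.sqrt(len(df))
        assert abs(df.ca_uptake.mean()) < 3.0 * sem + 1e-9

    def test_coupled_mode_noiseless_ratio_is_exactly_one(self):
        cfg = TransportSimConfig(mode="co_transport", noise_cv=0.0, coupling_ratio=1.0)
        df = gen_transport_timecourse(cfg, self.times[1:], 500.0, 5.0)
        assert np.allclose(df.pi_uptake / df.ca_uptake, 1.0)

    def test_chelator_mode_gives_zero_uptake(self):
        cfg = TransportSimConfig(mode="edta", noise_cv=0.05, seed=4)
        df = gen_transport_timecourse(cfg, self.times, 0.0, 5.0)
        assert (df.pi_uptake == 0.0).all()
        assert (df.ca_uptake == 0.0).all()

    def test_negative_concentration_rejected(self):
        cfg = TransportSimConfig()
        with pytest.raises(ValueError):
            gen_transport_timecourse(cfg, self.times, -1.0, 5.0)

    def test_paired_rates_expected_ratio(self):
        cfg = TransportSimConfig(mode="co_transport", noise_cv=0.0)
        df = gen_paired_rates(cfg, self.times[1:], 500.0, 5.0, n_rep=2)
        assert np.allclose(df.pi_rate / df.ca_rate, 1.0)


class TestItc:
    def test_no_binding_limit_gives_zero_heats(self):
        cfg = ItcSimConfig(kd=1e6, noise_sd=0.0, seed=0)
        df = gen_itc_isotherm(cfg)
        assert np.all(np.abs(df.heat_ucal) < 1e-3)

    def test_noiseless_roundtrip_recovers_kd(self):
        cfg = ItcSimConfig(kd=0.46e-6, delta_h=-8.0, cell_conc=5e-6,
                           syringe_conc=1e-4, noise_sd=0.0)
        fit = fit_itc_one_site(gen_itc_isotherm(cfg), 5e-6, 1e-4, 10e-6)
        assert fit.converged
        assert abs(fit.kd - cfg.kd) / cfg.kd < 0.01

    def test_cumulative_heat_at_saturation_is_total_binding_enthalpy(self):
        # tight binding, large ligand excess: all sites fill
        cfg = ItcSimConfig(kd=1e-9, delta_h=-8.0, cell_conc=5e-6,
                           syringe_conc=1e-3, noise_sd=0.0)
        df = gen_itc_isotherm(cfg)
        total = df.heat_ucal.sum() / 1e9  # kcal
        # dilution shrinks the cell content slightly; compare loosely
        expected = cfg.n_sites * cfg.delta_h * cfg.cell_conc * cfg.cell_volume
        assert total == pytest.approx(expected, rel=0.15)

    def test_low_saturation_flag(self):
        cfg = ItcSimConfig(kd=1e-6, cell_conc=1e-4, syringe_conc=1e-6, noise_sd=0.0)
        df = gen_itc_isotherm(cfg)
        assert df.attrs["low_saturation"] is True


class TestLretDecay:
    def test_noiseless_value_at_one_lifetime(self):
        df = gen_lret_decay(1.5, n_points=151, noise_sd=0.0)
        idx = np.argmin(np.abs(df.t.to_numpy() - 1.5))
        assert df.y.iloc[idx] == pytest.approx(math.exp(-1), abs=1e-6)

    def test_noiseless_roundtrip_recovers_tau(self):
        fit = fit_lifetime(gen_lret_decay(1.5, noise_sd=0.0))
        assert fit.converged
        assert abs(fit.tau - 1.5) / 1.5 < 0.01

    def test_seed_reproducibility(self):
        a = gen_lret_decay(1.5, noise_sd=0.02, seed=3)
        b = gen_lret_decay(1.5, noise_sd=0.02, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            gen_lret_decay(0.0)


class TestFepSamples:
    def test_zero_spread_samples_equal_window_free_energy(self):
        cfg = FepSimConfig(n_windows=3, samples_per_window=10,
                           true_dg_per_window=0.7, work_sd=0.0, seed=1)
        ds = gen_fep_samples(cfg)
        w = ds.direction("forward")[0]
        assert np.allclose(w.samples, 0.7)
        assert exp_free_energy(w.production) == pytest.approx(0.7)

    def test_gaussian_identity_mu_minus_half_variance(self):
        cfg = FepSimConfig(n_windows=1, samples_per_window=100_000,
                           true_dg_per_window=1.5, work_sd=1.0,
                           equil_fraction=0.0, seed=2)
        w = gen_fep_samples(cfg).direction("forward")[0]
        # mu = 2.0, sigma = 1.0 -> dG = mu - sigma^2/2 = 1.5 kT
        se = math.sqrt((math.exp(1.0) - 1.0) / w.production.size)
        assert abs(exp_free_energy(w.production) - 1.5) < 3.0 * se

    def test_ground_truth_is_additive_over_windows(self):
        cfg = FepSimConfig(n_windows=8, samples_per_window=5000,
                           true_dg_per_window=0.25, work_sd=0.3, seed=3)
        ds = gen_fep_samples(cfg)
        total = sum(exp_free_energy(w.production) for w in ds.direction("forward"))
        assert total == pytest.approx(8 * 0.25, abs=0.05)

    def test_equilibration_fraction_marked(self):
        cfg = FepSimConfig(n_windows=2, samples_per_window=240,
                           equil_fraction=1.0 / 6.0, seed=4)
        ds = gen_fep_samples(cfg)
        assert all(int(w.equil_mask.sum()) == 40 for w in ds.windows)
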
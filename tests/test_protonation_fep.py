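import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from caxport.protonation_fep import (
    GAS_CONSTANT_KCAL,
    FepDataset,
    FepWindow,
    FreeEnergyResult,
    PROTONATION_REFERENCE,
    ProtonationContext,
    bar_free_energy,
    combine_bidirectional,
    ddg_to_pka_shift,
    discard_equilibration,
    estimate,
    exp_free_energy,
    pka_shift_to_ddg,
    protonation_ddg,
    total_free_energy,
)
from caxport.synthetic_data import FepSimConfig, gen_fep_samples


def _dataset(samples_by_window, direction="forward", temperature=298.0):
    windows = [FepWindow(lambda_index=i, direction=direction,
                         samples=np.asarray(s, dtype=float))
               for i, s in enumerate(samples_by_window)]
    return FepDataset(windows, temperature=temperature)


class TestEquilibrationDiscard:
    def test_fraction_masks_leading_samples(self):
        ds = _dataset([np.ones(1000), np.ones(1000)])
        out = discard_equilibration(ds, 0.2)
        assert all(w.production.size == 800 for w in out.windows)

    def test_zero_fraction_is_identity(self):
        ds = _dataset([np.arange(10.0)])
        out = discard_equilibration(ds, 0.0)
        assert np.array_equal(out.windows[0].production, np.arange(10.0))

    def test_one_sixth_of_240_masks_40(self):
        ds = _dataset([np.zeros(240)])
        out = discard_equilibration(ds, 1.0 / 6.0)
        assert int(out.windows[0].equil_mask.sum()) == 40

    def test_overdiscard_rejected(self):
        ds = _dataset([np.ones(3)])
        with pytest.raises(ValueError, match="<2 samples"):
            discard_equilibration(ds, 0.8)


class TestExponentialEstimator:
    def test_constant_work_returns_the_constant(self):
        assert exp_free_energy(np.full(50, 2.5)) == pytest.approx(2.5)

    def test_gaussian_closed_form(self):
        rng = np.random.default_rng(11)
        du = rng.normal(2.0, 1.0, size=100_000)
        se = math.sqrt((math.e - 1.0) / du.size)
        assert abs(exp_free_energy(du) - 1.5) < 3.0 * se

    def test_bimodal_limit_and_upper_bound(self):
        # {0, M}: as M -> inf the average is dominated by the small value
        du = np.array([0.0, 500.0])
        assert exp_free_energy(du) == pytest.approx(math.log(2.0), abs=1e-6)

    def test_numerically_stable_at_700kT(self):
        assert exp_free_energy(np.array([700.0, 700.0])) == pytest.approx(700.0)
        assert exp_free_energy(np.array([-700.0, -700.0])) == pytest.approx(-700.0)

    @given(st.lists(st.floats(-30, 30), min_size=2, max_size=40))
    def test_jensen_bound_below_sample_mean(self, values):
        du = np.array(values)
        assert exp_free_energy(du) <= du.mean() + 1e-9


class TestPathTotals:
    def test_forty_windows_of_tenth_kt(self):
        ds = _dataset([np.full(10, 0.1)] * 40)
        total = total_free_energy(ds)["forward"]
        assert total == pytest.approx(4.0 * GAS_CONSTANT_KCAL * 298.0, abs=1e-9)
        assert total == pytest.approx(2.369, abs=2e-3)

    def test_noiseless_reverse_agrees_with_forward(self):
        cfg = FepSimConfig(n_windows=5, samples_per_window=10,
                           true_dg_per_window=0.3, work_sd=0.0, seed=0)
        totals = total_free_energy(gen_fep_samples(cfg))
        assert totals["reverse"] == pytest.approx(totals["forward"])

    def test_single_window_total_equals_window_estimate(self):
        samples = np.array([0.2, 0.4, 0.9])
        ds = _dataset([samples])
        kt_to_kcal = GAS_CONSTANT_KCAL * 298.0
        assert total_free_energy(ds)["forward"] == pytest.approx(
            kt_to_kcal * exp_free_energy(samples))

    def test_bar_matches_exponential_on_gaussian_work(self):
        cfg = FepSimConfig(n_windows=4, samples_per_window=20_000,
                           true_dg_per_window=0.5, work_sd=1.0, seed=6)
        ds = gen_fep_samples(cfg)
        truth = 4 * 0.5 * GAS_CONSTANT_KCAL * 298.0
        bar = total_free_energy(ds, "bar")["forward"]
        assert bar == pytest.approx(truth, abs=0.02)

    def test_unbalanced_directions_rejected_for_bar(self):
        ds = _dataset([np.ones(5)] * 3)
        with pytest.raises(ValueError):
            total_free_energy(ds, "bar")


class TestBidirectionalCombination:
    def test_mean_and_half_difference(self):
        r = combine_bidirectional(1.6, 1.4)
        assert (r.dg, r.error) == (1.5, pytest.approx(0.1))

    def test_identical_directions_have_zero_error(self):
        r = combine_bidirectional(2.2, 2.2)
        assert (r.dg, r.error) == (2.2, 0.0)

    def test_order_invariance(self):
        a, b = combine_bidirectional(1.0, 3.0), combine_bidirectional(3.0, 1.0)
        assert (a.dg, a.error) == (b.dg, b.error)


class TestProtonationCycle:
    def _res(self, dg, err, site="E72"):
        return FreeEnergyResult(dg=dg, error=err, site_label=site)

    def test_difference_and_error_propagation(self):
        ddg = protonation_ddg(self._res(-5.0, 0.3), self._res(-3.0, 0.4, "E0"))
        assert ddg.dg == pytest.approx(-2.0)
        assert ddg.error == pytest.approx(0.5)

    def test_surface_site_null_expectation(self):
        ddg = protonation_ddg(self._res(-3.1, 0.1, "E233"), self._res(-3.1, 0.1, "E0"))
        assert ddg.dg == 0.0

    def test_cycle_antisymmetry(self):
        a, b = self._res(-5.0, 0.2), self._res(-3.0, 0.1, "E0")
        assert protonation_ddg(a, b).dg == -protonation_ddg(b, a).dg

    def test_mismatched_sidechain_types_rejected(self):
        with pytest.raises(ValueError, match="different side-chain types"):
            protonation_ddg(self._res(-5.0, 0.1, "E72"), self._res(-3.0, 0.1, "H256"))

    def test_context_validation(self):
        ProtonationContext({"E72": "protonated", "E255": "protonated"})
        with pytest.raises(ValueError):
            ProtonationContext({"E999": "protonated"})


class TestPkaConversion:
    def test_one_ph_unit_per_1p364_kcal(self):
        ddg = -GAS_CONSTANT_KCAL * 298.0 * math.log(10.0)
        assert ddg == pytest.approx(-1.364, abs=5e-4)
        assert ddg_to_pka_shift(ddg) == pytest.approx(1.0)

    def test_zero_maps_to_zero(self):
        assert ddg_to_pka_shift(0.0) == 0.0

    def test_strongly_shifted_buried_glutamate(self):
        # ddG = -11.5 kcal/mol corresponds to about +8.4 pH units at 298 K
        assert ddg_to_pka_shift(-11.5) == pytest.approx(8.43, abs=0.02)

    @given(st.floats(-20, 20), st.floats(250, 350))
    def test_unit_roundtrip_machine_precision(self, ddg, temperature):
        back = pka_shift_to_ddg(ddg_to_pka_shift(ddg, temperature), temperature)
        assert back == pytest.approx(ddg, abs=1e-12)


def test_reference_table_is_annotation_only():
    """The shipped MD reference values carry site/context labels and errors."""
    assert {r["site"] for r in PROTONATION_REFERENCE} <= {"E72", "E255", "H256",
                                                          "E233", "H226"}
    assert all(r["error"] > 0 for r in PROTONATION_REFERENCE)


def test_estimate_convenience_combines_directions():
    cfg = FepSimConfig(n_windows=3, samples_per_window=2000,
                       true_dg_per_window=0.2, work_sd=0.5, seed=9)
    r = estimate(gen_fep_samples(cfg))
    truth = 3 * 0.2 * GAS_CONSTANT_KCAL * 298.0
    assert r.dg == pytest.approx(truth, abs=0.05)
    assert r.error >= 0.0
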
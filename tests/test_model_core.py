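"""One-substrate mass-action model: derivatives, integration, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import apckinetics as ak
from apckinetics.model import SPECIES_ONE, derivatives_one_substrate, initial_state

N = len(SPECIES_ONE)


def random_state(rng, scale=200.0):
    return scale * rng.random(N)


class TestDerivatives:
    def test_empty_system_only_apc_accumulates(self):
        p = ak.RateParameters(p_A=0.06)
        dy = derivatives_one_substrate(np.zeros(N), p)
        assert dy[0] == pytest.approx(0.06)
        assert np.all(dy[1:] == 0.0)

    def test_constant_mode_has_no_apc_production(self):
        p = ak.RateParameters(apc_mode="constant", A_const=100.0)
        dy = derivatives_one_substrate(np.zeros(N), p)
        assert np.all(dy == 0.0)

    def test_uncoupled_substrate_is_static(self):
        # no binding, no APC production: S0 has no route anywhere
        p = ak.RateParameters(k_a=0.0, p_A=0.0)
        y = np.zeros(N)
        y[1] = 200.0
        dy = derivatives_one_substrate(y, p)
        assert np.all(dy == 0.0)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_substrate_mass_flux_equals_degradation(self, seed):
        """Sum of substrate derivatives is exactly -e (S4 + AS4): substrate
        leaves the system only through proteasomal degradation."""
        rng = np.random.default_rng(seed)
        p = ak.RateParameters(k_a=10 ** rng.uniform(-4, 1),
                              k_d=10 ** rng.uniform(-3, 3),
                              k_c=10 ** rng.uniform(-3, 3))
        y = random_state(rng)
        dy = derivatives_one_substrate(y, p)
        total_flux = dy[1:].sum()
        expected = -p.e * (y[5] + y[10])
        assert total_flux == pytest.approx(expected, rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize("variant", ["all", "free_only", "bound_only", "mono_only"])
    def test_deub_variants_reduce_to_none_when_rate_zero(self, variant):
        rng = np.random.default_rng(3)
        y = random_state(rng)
        p0 = ak.RateParameters(deub_variant="none")
        p1 = ak.RateParameters(deub_variant=variant, k_dub=0.0)
        assert np.array_equal(derivatives_one_substrate(y, p0),
                              derivatives_one_substrate(y, p1))

    def test_deub_conserves_substrate(self):
        rng = np.random.default_rng(4)
        y = random_state(rng)
        y[5] = y[10] = 0.0  # no four-ubiquitin species: no degradation flux
        p = ak.RateParameters(deub_variant="all", k_dub=0.5)
        dy = derivatives_one_substrate(y, p)
        assert dy[1:].sum() == pytest.approx(0.0, abs=1e-12)

    def test_mono_only_touches_single_ubiquitin_species(self):
        y = np.zeros(N)
        y[3] = 50.0  # S2 only
        p = ak.RateParameters(k_a=0.0, p_A=0.0, deub_variant="mono_only", k_dub=1.0)
        assert np.all(derivatives_one_substrate(y, p) == 0.0)
        p_all = p.with_(deub_variant="all")
        dy = derivatives_one_substrate(y, p_all)
        assert dy[3] == pytest.approx(-50.0)
        assert dy[2] == pytest.approx(50.0)


class TestParameterValidation:
    @pytest.mark.parametrize("field", ["k_a", "k_d", "k_c", "e", "p_A", "S0_init", "k_dub"])
    def test_negative_rates_rejected(self, field):
        with pytest.raises(ValueError):
            ak.RateParameters(**{field: -1.0})

    def test_bad_mode_and_variant_rejected(self):
        with pytest.raises(ValueError):
            ak.RateParameters(apc_mode="quadratic")
        with pytest.raises(ValueError):
            ak.RateParameters(deub_variant="everything")
        with pytest.raises(ValueError):
            ak.RateParameters(max_ub=5)


class TestSimulate:
    def test_no_substrate_leaves_linear_apc_ramp(self):
        p = ak.RateParameters(S0_init=0.0)
        tc = ak.simulate(p, horizon=100.0)
        assert np.all(tc.states[:, 1:] == 0.0)
        np.testing.assert_allclose(tc["A"], p.p_A * tc.times, rtol=1e-8, atol=1e-9)

    def test_no_catalysis_conserves_substrate(self):
        # without ubiquitin transfer nothing ever reaches four ubiquitins
        p = ak.RateParameters(k_c=0.0)
        tc = ak.simulate(p)
        np.testing.assert_allclose(ak.total_substrate(tc), 200.0, rtol=1e-7)

    def test_initial_condition_matches_mode(self):
        tc = ak.simulate(ak.RateParameters(), horizon=10.0)
        assert tc["A"][0] == 0.0
        assert tc["S0"][0] == 200.0
        tc2 = ak.simulate(ak.RateParameters(apc_mode="constant", A_const=100.0),
                          horizon=10.0)
        assert tc2["A"][0] == 100.0

    def test_output_grid_and_horizon(self):
        tc = ak.simulate(ak.RateParameters(), horizon=50.0, output_grid=0.5)
        assert tc.times[0] == 0.0
        assert tc.times[-1] == 50.0
        assert np.allclose(np.diff(tc.times), 0.5)

    def test_nonnegative_after_clipping(self):
        tc = ak.simulate(ak.RateParameters(k_c=100.0, k_d=0.01))
        assert tc.states.min() >= 0.0

    def test_fast_degradation_keeps_tetra_ubiquitin_pool_tiny(self):
        # e = 1000/s: four-ubiquitin species are destroyed essentially instantly
        for kc, kd in [(0.1, 0.1), (100.0, 0.01), (1000.0, 1000.0)]:
            tc = ak.simulate(ak.RateParameters(k_c=kc, k_d=kd))
            tetra = tc["S4"] + tc["AS4"]
            assert tetra.max() < 0.01 * 200.0

    def test_bad_horizon_rejected(self):
        with pytest.raises(ValueError):
            ak.simulate(ak.RateParameters(), horizon=-1.0)
        with pytest.raises(ValueError):
            ak.simulate(ak.RateParameters(), horizon=10.0, output_grid=20.0)


class TestConservation:
    """APC/C and substrate balance across random parameter sets."""

    _rng = np.random.default_rng(20)
    PARAM_SETS = [
        dict(k_a=float(10 ** u[0]), k_d=float(10 ** u[1]), k_c=float(10 ** u[2]))
        for u in _rng.uniform([-4, -3, -3], [0, 3, 3], size=(20, 3))
    ]

    @pytest.mark.parametrize("kw", PARAM_SETS)
    def test_apc_balance_constant_mode(self, kw):
        p = ak.RateParameters(apc_mode="constant", A_const=100.0, **kw)
        tc = ak.simulate(p, horizon=500.0)
        total_apc = tc["A"] + tc.group([f"AS{i}" for i in range(5)])
        np.testing.assert_allclose(total_apc, 100.0, rtol=1e-6)

    @pytest.mark.parametrize("kw", PARAM_SETS)
    def test_substrate_mass_conserved_without_degradation(self, kw):
        p = ak.RateParameters(e=0.0, **kw)
        tc = ak.simulate(p, horizon=500.0)
        np.testing.assert_allclose(ak.total_substrate(tc), 200.0, rtol=1e-6)

    def test_apc_balance_linear_mode_tracks_production(self):
        p = ak.RateParameters(k_c=0.0)  # no degradation: no APC release path needed
        tc = ak.simulate(p)
        total_apc = tc["A"] + tc.group([f"AS{i}" for i in range(5)])
        np.testing.assert_allclose(total_apc, p.p_A * tc.times, rtol=1e-6, atol=1e-8)

    def test_total_substrate_non_increasing(self):
        tc = ak.simulate(ak.RateParameters(k_c=0.1, k_d=0.1))
        total = ak.total_substrate(tc)
        assert np.all(np.diff(total) <= 1e-9)


class TestFixedStepOracle:
    def test_adaptive_matches_euler_reference(self):
        """Total-substrate trace from the adaptive solver agrees with an
        independent explicit-Euler integration at dt = 1 ms within 0.5 %."""
        p = ak.RateParameters(k_a=0.01, k_d=1.0, k_c=1.0)
        ref = ak.euler_reference(p, horizon=300.0, dt=1e-3)
        tc = ak.simulate(p, horizon=300.0)
        a, b = ak.total_substrate(tc), ak.total_substrate(ref)
        assert np.max(np.abs(a - b) / b) < 0.005

    def test_dt_must_divide_output_grid(self):
        with pytest.raises(ValueError):
            ak.euler_reference(ak.RateParameters(), horizon=2.0, dt=0.3)
        with pytest.raises(ValueError):
            ak.euler_reference(ak.RateParameters(), horizon=2.0, dt=-0.1)


def test_timecourse_shape_validation():
    with pytest.raises(ValueError):
        ak.TimeCourse(times=np.arange(3.0), states=np.zeros((2, 11)),
                      species=SPECIES_ONE, params=None)


def test_initial_state_layout():
    y0 = initial_state(ak.RateParameters())
    assert y0[1] == 200.0 and y0.sum() == 200.0
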
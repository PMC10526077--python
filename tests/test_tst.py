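import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radkin.constants import thermal_frequency
from radkin.tst import eckart_kappa, eckart_transmission, tst_rate

# independent literal constants for the symmetric-barrier oracle below
_HC_NA_KCAL_PER_CM = 6.62607015e-34 * 2.99792458e10 * 6.02214076e23 / 4184.0


def symmetric_eckart_transmission(E, V, wavenumber):
    """Closed-form transmission for a symmetric Eckart barrier (oracle).

    T(E) = [cosh(2u) − 1] / [cosh(2u) + cosh(π√(16V²/(hcν)² − 1))]
    with u = 2π√(E·V)/(hcν).
    """
    hnu = wavenumber * _HC_NA_KCAL_PER_CM
    u = 2.0 * math.pi * math.sqrt(E * V) / hnu
    d = math.pi * math.sqrt(16.0 * V * V / (hnu * hnu) - 1.0)
    return (math.cosh(2 * u) - 1.0) / (math.cosh(2 * u) + math.cosh(d))


class TestTstRate:
    def test_adduct_formation_rows_reproduced_from_inputs(self):
        # published rows: (dG, kappa) -> k_app for activation-controlled channels
        assert tst_rate(14.2, 1.0) == pytest.approx(2.40e2, rel=0.02)
        assert tst_rate(19.7, 1.5) == pytest.approx(3.40e-2, rel=0.02)

    def test_zero_barrier_gives_thermal_frequency(self):
        assert tst_rate(0.0, 1.0, 1) == pytest.approx(thermal_frequency(), rel=1e-12)

    def test_linear_in_symmetry_number(self):
        assert tst_rate(10.0, 2.0, 2) == pytest.approx(2 * tst_rate(10.0, 2.0, 1), rel=1e-12)

    def test_subunit_tunneling_factor_warns_but_computes(self):
        with pytest.warns(UserWarning, match="impossible for an Eckart barrier"):
            k = tst_rate(8.7, 0.7)
        assert k == pytest.approx(1.80e6, rel=0.02)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            tst_rate(10.0, -0.5)
        with pytest.raises(ValueError):
            tst_rate(10.0, 1.0, 0)

    @settings(deadline=None, derandomize=True)
    @given(
        g1=st.floats(1.0, 25.0),
        dg=st.floats(0.01, 10.0),
        dT=st.floats(1.0, 200.0),
    )
    def test_decreasing_in_barrier_increasing_in_temperature(self, g1, dg, dT):
        assert tst_rate(g1 + dg, 1.0) < tst_rate(g1, 1.0)
        assert tst_rate(g1, 1.0, 1, 298.15 + dT) > tst_rate(g1, 1.0, 1, 298.15)


class TestEckartTransmission:
    def test_classical_limit_far_above_barrier(self):
        p = eckart_transmission(80.0, 6.0, 8.0, 1500.0)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_nondecreasing_in_energy(self):
        energies = np.linspace(0.0, 30.0, 400)
        p = eckart_transmission(energies, 6.0, 9.0, 1400.0)
        assert np.all(np.diff(p) >= -1e-12)
        assert 0.0 <= p[0] <= p[-1] <= 1.0

    @pytest.mark.parametrize("V,nu", [(5.0, 1500.0), (3.0, 900.0), (12.0, 2100.0)])
    def test_symmetric_case_matches_closed_form_oracle(self, V, nu):
        for E in (0.5, 0.25 * V, 0.9 * V, V, 1.5 * V, 3.0 * V):
            mine = float(eckart_transmission(E, V, V, nu))
            oracle = symmetric_eckart_transmission(E, V, nu)
            assert mine == pytest.approx(oracle, abs=1e-8)

    def test_below_product_asymptote_closed(self):
        # exothermic direction seen in reverse: no flux below V1 - V2
        assert eckart_transmission(1.0, 10.0, 2.0, 1500.0) == 0.0

    def test_too_thin_barrier_falls_back_to_step(self):
        with pytest.warns(UserWarning, match="too thin"):
            below = eckart_transmission(0.5, 1.0, 1.0, 40000.0)
        with pytest.warns(UserWarning):
            above = eckart_transmission(1.5, 1.0, 1.0, 40000.0)
        assert below == 0.0 and above == 1.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            eckart_transmission(1.0, -5.0, 5.0, 1500.0)
        with pytest.raises(ValueError):
            eckart_transmission(-1.0, 5.0, 5.0, 1500.0)


class TestEckartKappa:
    def test_always_at_least_one(self):
        for fwd, rev, nu in [(2.0, 2.0, 800.0), (5.0, 12.0, 1500.0), (15.0, 3.0, 2200.0)]:
            assert eckart_kappa(fwd, rev, nu) >= 1.0

    def test_classical_limit_small_imaginary_frequency(self):
        assert eckart_kappa(5.0, 5.0, 1.0) == pytest.approx(1.0, abs=1e-4)

    def test_monotone_decreasing_in_temperature(self):
        kappas = [eckart_kappa(5.0, 8.0, 1500.0, T) for T in (250.0, 298.15, 350.0)]
        assert kappas[0] > kappas[1] > kappas[2] > 1.0

    def test_matches_wigner_expansion_at_small_frequency(self):
        # kappa -> 1 + (hc*nu/kB/T)^2/24 for shallow tunneling
        nu = 100.0
        u = nu * _HC_NA_KCAL_PER_CM / (1.987204e-3 * 298.15)
        assert eckart_kappa(20.0, 20.0, nu) == pytest.approx(1.0 + u * u / 24.0, abs=1e-3)
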
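import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radkin.speciation import (
    fractions_at_ph,
    pka_from_gibbs,
    rank_deprotonation_sites,
    speciation_profile,
)


def brute_force_fractions(pka_values, pH):
    """Independent oracle: stepwise Henderson–Hasselbalch concentration ratios.

    [A_j]/[A_{j-1}] = 10^(pH − pKa_j); populations are cumulative products,
    normalized by the mass balance.
    """
    pops = [1.0]
    for pka in pka_values:
        pops.append(pops[-1] * 10.0 ** (pH - pka))
    total = sum(pops)
    return {j: p / total for j, p in enumerate(pops)}


class TestPkaFromGibbs:
    def test_zero_gibbs_gives_water_reference_value(self):
        # 14 + 3*log10(55.345) = 19.23
        assert pka_from_gibbs(0.0) == pytest.approx(19.23, abs=0.005)

    def test_affine_with_slope_one_over_rt_ln10(self):
        # one RT*ln10 (independent literals) shifts the pKa by exactly one unit
        rt_ln10 = 1.987204e-3 * 298.15 * math.log(10.0)
        base = pka_from_gibbs(0.0)
        assert pka_from_gibbs(-rt_ln10) == pytest.approx(base - 1.0, abs=1e-9)
        assert pka_from_gibbs(-10 * rt_ln10) == pytest.approx(9.23, abs=0.005)

    @settings(deadline=None, derandomize=True)
    @given(g1=st.floats(-30, 30), g2=st.floats(-30, 30))
    def test_linearity_in_gibbs_energy(self, g1, g2):
        mid = pka_from_gibbs((g1 + g2) / 2.0)
        avg = (pka_from_gibbs(g1) + pka_from_gibbs(g2)) / 2.0
        assert mid == pytest.approx(avg, abs=1e-9)


class TestFractionsAtPh:
    def test_ph_equal_to_single_pka_splits_evenly(self):
        fracs = fractions_at_ph([7.4], 7.4)
        assert fracs[0] == pytest.approx(0.5, abs=1e-12)
        assert fracs[1] == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize(
        "pkas,expected_mono,expected_di",
        [
            ([3.5, 8.449], 0.918, 0.082),  # catechol-bearing compound
            ([3.5, 9.316], 0.988, 0.012),  # guaiacol-bearing compound
        ],
    )
    def test_diprotic_fractions_at_physiological_ph(self, pkas, expected_mono, expected_di):
        fracs = fractions_at_ph(pkas, 7.4)
        assert fracs[1] == pytest.approx(expected_mono, abs=5e-4)
        assert fracs[2] == pytest.approx(expected_di, abs=5e-4)
        assert fracs[0] < 1e-3  # neutral form effectively absent

    def test_non_monotone_pka_list_rejected(self):
        with pytest.raises(ValueError):
            fractions_at_ph([8.0, 3.0], 7.4)
        with pytest.raises(ValueError):
            fractions_at_ph([], 7.4)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        pkas=st.lists(st.floats(0.0, 14.0), min_size=1, max_size=3, unique=True),
        pH=st.floats(0.0, 14.0),
    )
    def test_matches_stepwise_equilibrium_oracle(self, pkas, pH):
        pkas = sorted(pkas)
        if any(b - a < 1e-6 for a, b in zip(pkas, pkas[1:])):
            return
        fracs = fractions_at_ph(pkas, pH)
        oracle = brute_force_fractions(pkas, pH)
        assert sum(fracs.values()) == pytest.approx(1.0, abs=1e-9)
        for j in oracle:
            assert fracs[j] == pytest.approx(oracle[j], abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        pkas=st.lists(st.floats(2.0, 12.0), min_size=1, max_size=3, unique=True),
        pH=st.floats(1.0, 13.0),
        dpH=st.floats(0.01, 2.0),
    )
    def test_deprotonated_states_monotone_in_ph(self, pkas, pH, dpH):
        pkas = sorted(pkas)
        if any(b - a < 1e-6 for a, b in zip(pkas, pkas[1:])):
            return
        lo = fractions_at_ph(pkas, pH)
        hi = fractions_at_ph(pkas, pH + dpH)
        n = len(pkas)
        # fully deprotonated never decreases with pH; fully protonated never increases
        assert hi[n] >= lo[n] - 1e-12
        assert hi[0] <= lo[0] + 1e-12


class TestSiteRanking:
    def test_sites_ordered_by_ascending_proton_affinity(self):
        order, tied = rank_deprotonation_sites({"COOH": 320.0, "13OH": 330.0, "12OH": 335.0})
        assert order == ["COOH", "13OH", "12OH"]
        assert not tied

    def test_ties_break_lexicographically_and_flag(self):
        order, tied = rank_deprotonation_sites({"B": 300.0, "A": 300.0})
        assert order == ["A", "B"]
        assert tied

    def test_single_site_and_empty_map(self):
        assert rank_deprotonation_sites({"COOH": 320.0})[0] == ["COOH"]
        with pytest.raises(ValueError):
            rank_deprotonation_sites({})


def test_profile_validates_fraction_sum_and_pka_order():
    prof = speciation_profile("cpd", [3.5, 8.449], 7.4)
    assert sum(prof.fractions.values()) == pytest.approx(1.0, abs=1e-12)
    assert prof.dominant_state() == 1
    with pytest.raises(ValueError):
        speciation_profile("cpd", [8.0, 8.0], 7.4)
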
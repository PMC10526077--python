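import pytest
from hypothesis import given, settings, strategies as st

from radkin.diffusion import (
    DEFAULT_K_DIFFUSION,
    collins_kimball,
    diffusion_context_for_medium,
    smoluchowski_kd,
    stokes_einstein_diffusivity,
)
from radkin.model import MediumSpec


class TestStokesEinstein:
    def test_reference_value_in_water(self):
        d = stokes_einstein_diffusivity(3e-10, 8.91e-4, 298.15)
        assert d == pytest.approx(8.17e-10, rel=0.01)

    def test_inverse_in_radius_and_viscosity(self):
        base = stokes_einstein_diffusivity(3e-10, 8.91e-4)
        assert stokes_einstein_diffusivity(6e-10, 8.91e-4) == pytest.approx(base / 2, rel=1e-12)
        assert stokes_einstein_diffusivity(3e-10, 2 * 8.91e-4) == pytest.approx(base / 2, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            stokes_einstein_diffusivity(0.0, 8.91e-4)
        with pytest.raises(ValueError):
            stokes_einstein_diffusivity(3e-10, -1.0)


class TestSmoluchowski:
    def test_reference_value(self):
        # R_AB = 6.4 Angstrom, D_AB = 1.5e-9 m^2/s
        kd = smoluchowski_kd(3.2e-10, 3.2e-10, 7.5e-10, 7.5e-10)
        assert kd == pytest.approx(7.26e9, rel=0.01)

    def test_linear_in_diffusivities(self):
        base = smoluchowski_kd(3e-10, 3e-10, 1e-9, 1e-9)
        assert smoluchowski_kd(3e-10, 3e-10, 2e-9, 2e-9) == pytest.approx(2 * base, rel=1e-12)

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            smoluchowski_kd(0.0, 3e-10, 1e-9, 1e-9)


class TestCollinsKimball:
    def test_activation_controlled_limit_passes_through(self):
        k_act, k_d = 2.4e2, 2.3e9
        k_app = collins_kimball(k_act, k_d)
        assert abs(k_app - k_act) / k_act < 1e-6

    def test_equal_rates_give_half(self):
        assert collins_kimball(1e9, 1e9) == pytest.approx(5e8, rel=1e-12)

    def test_diffusion_limited_row(self):
        # fast hydrogen abstraction against a calibrated encounter rate
        assert collins_kimball(2.55e11, 2.32e9) == pytest.approx(2.30e9, rel=0.01)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            collins_kimball(0.0, 0.0)

    @settings(deadline=None, derandomize=True)
    @given(
        k_act=st.floats(1e-6, 1e13),
        k_d=st.floats(1e6, 1e11),
        scale=st.floats(1.0, 100.0),
    )
    def test_bounded_symmetric_and_monotone(self, k_act, k_d, scale):
        k_app = collins_kimball(k_act, k_d)
        assert k_app <= min(k_act, k_d) * (1 + 1e-12)
        assert collins_kimball(k_d, k_act) == pytest.approx(k_app, rel=1e-12)
        assert collins_kimball(k_act * scale, k_d) >= k_app


class TestMediumResolution:
    def test_override_wins(self):
        m = MediumSpec(name="water", aqueous=True, pH=7.4, diffusion_override=2.3e9)
        ctx = diffusion_context_for_medium(m)
        assert ctx.k_diffusion == 2.3e9 and ctx.source == "override"

    def test_radii_route_uses_stokes_einstein(self):
        m = MediumSpec(
            name="water", aqueous=True, pH=7.4, viscosity=8.91e-4,
            reactant_radii={"antioxidant": 3.2e-10, "radical": 3.2e-10},
        )
        ctx = diffusion_context_for_medium(m)
        assert ctx.source == "stokes-einstein"
        # equal radii give the viscosity-only encounter limit ~7.4e9 in water
        assert ctx.k_diffusion == pytest.approx(7.42e9, rel=0.01)

    def test_fallback_is_calibrated_default(self):
        m = MediumSpec(name="water", aqueous=True, pH=7.4)
        assert diffusion_context_for_medium(m).k_diffusion == DEFAULT_K_DIFFUSION

    def test_implausible_kd_warns(self):
        with pytest.warns(UserWarning, match="plausible bimolecular range"):
            diffusion_context_for_medium(
                MediumSpec(name="w", aqueous=True, pH=7.0, diffusion_override=1e3)
            )
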
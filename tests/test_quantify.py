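import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fractoc.formulas import get_material
from fractoc.quantify import (
    SpikeDesign,
    UValue,
    af4_recovery,
    background_subtract,
    filtration_recovery,
    mass_concentration_from_toc,
    mass_to_number_concentration,
    number_to_mass_concentration,
    recovery,
    spike_equivalent_carbon,
    subtraction_estimator,
)
from fractoc.sedimentation import ParticleSpec
from fractoc.toc import NegativeCarbonWarning


class TestMassFromCarbon:
    def test_ps_inverse_of_definition(self, ps):
        assert mass_concentration_from_toc(0.9226, ps) == pytest.approx(1.000)
        assert mass_concentration_from_toc(4.613, ps) == pytest.approx(5.0, rel=1e-4)

    def test_pure_carbon_identity(self):
        from fractoc.formulas import PolymerSpec

        carbon = PolymerSpec.from_formula("carbon", "C")
        assert mass_concentration_from_toc(1.0, carbon) == pytest.approx(1.0)


class TestSpikeArithmetic:
    def test_one_plus_one_ps_spike(self, ps):
        """1 + 1 mg/L PS at the certificate 92.26 %C adds exactly
        1.8452 mg C/L."""
        assert spike_equivalent_carbon([(ps, 1.0), (ps, 1.0)]) == pytest.approx(
            1.8452, abs=1e-12
        )

    def test_empty_design(self):
        assert spike_equivalent_carbon(SpikeDesign(spikes=())) == 0.0

    def test_cellulose_spike(self):
        cellulose = get_material("cellulose")
        assert spike_equivalent_carbon([(cellulose, 2.0)]) == pytest.approx(0.889)


class TestRecovery:
    def test_lake_unfiltered_spike(self):
        rec = recovery(UValue(1.637, 0.131), UValue(1.712, 0.014))
        assert rec.rounded == 96
        assert rec.uncertainty == pytest.approx(8.0, abs=0.5)

    def test_river_filtered_spike(self):
        rec = recovery(UValue(0.577, 0.265), UValue(0.830, 0.004))
        assert rec.rounded == 70

    def test_exact_match_zero_uncertainty(self):
        rec = recovery(UValue(2.0), UValue(2.0))
        assert (rec.value, rec.uncertainty) == (100.0, 0.0)

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValueError):
            recovery(UValue(1.0), UValue(0.0))

    @given(
        m=st.floats(0.1, 100.0),
        e=st.floats(0.1, 100.0),
        c=st.floats(0.01, 1000.0),
    )
    def test_scale_invariance(self, m, e, c):
        r1 = recovery(UValue(m), UValue(e))
        r2 = recovery(UValue(m * c), UValue(e * c))
        assert r2.value == pytest.approx(r1.value, rel=1e-12)

    def test_quadrature_vs_monte_carlo_oracle(self):
        """First-order propagation reproduces a 1e5-draw Monte-Carlo
        uncertainty within 5 % for the spike-recovery cases."""
        rng = np.random.default_rng(42)
        cases = [
            ((1.637, 0.131), (1.712, 0.014)),
            ((0.788, 0.223), (0.830, 0.004)),
            ((0.577, 0.265), (0.830, 0.004)),
        ]
        for (m, um), (e, ue) in cases:
            draws = 100.0 * rng.normal(m, um, 100_000) / rng.normal(e, ue, 100_000)
            rec = recovery(UValue(m, um), UValue(e, ue))
            assert rec.uncertainty == pytest.approx(draws.std(), rel=0.05)

    def test_linear_rule_is_wider(self):
        q = recovery(UValue(1.637, 0.131), UValue(1.712, 0.014), rule="quadrature")
        l = recovery(UValue(1.637, 0.131), UValue(1.712, 0.014), rule="linear")
        assert l.uncertainty > q.uncertainty
        assert l.value == q.value
        assert l.rule == "linear"


class TestBackgroundSubtraction:
    def test_consistency_with_reported_net(self):
        net = background_subtract(UValue(2.509, 0.0), UValue(0.872, 0.0))
        assert net.value == pytest.approx(1.637)

    def test_zero_background_identity(self):
        x = background_subtract(UValue(3.3, 0.1), UValue(0.0))
        assert (x.value, x.u) == (pytest.approx(3.3), pytest.approx(0.1))

    def test_negative_net_flagged(self):
        with pytest.warns(NegativeCarbonWarning):
            net = background_subtract(UValue(0.5, 0.05), UValue(0.8, 0.05))
        assert net.value == pytest.approx(-0.3)
        assert net.u == pytest.approx(math.hypot(0.05, 0.05))

    def test_monte_carlo_difference_oracle(self):
        rng = np.random.default_rng(7)
        draws = rng.normal(2.509, 0.12, 100_000) - rng.normal(0.872, 0.098, 100_000)
        net = background_subtract(UValue(2.509, 0.12), UValue(0.872, 0.098))
        assert net.u == pytest.approx(draws.std(), rel=0.05)


class TestNumberMassConversion:
    def test_single_1000nm_ps_particle(self):
        particle = ParticleSpec.from_size(1000.0, "nm", 1.05)
        # (pi/6) * 1e-12 cm^3 * 1.05 g/cm^3 per particle
        assert number_to_mass_concentration(1.0, particle) == pytest.approx(
            5.50e-7, rel=1e-3
        )

    @given(nc=st.floats(1.0, 1e9), d_nm=st.floats(50.0, 5000.0))
    def test_round_trip(self, nc, d_nm):
        particle = ParticleSpec.from_size(d_nm, "nm", 1.05)
        mass = number_to_mass_concentration(nc, particle)
        assert mass_to_number_concentration(mass, particle) == pytest.approx(
            nc, rel=1e-12
        )

    def test_doubling_diameter_multiplies_mass_by_eight(self):
        p1 = ParticleSpec.from_size(500.0, "nm", 1.05)
        p2 = ParticleSpec.from_size(1000.0, "nm", 1.05)
        ratio = number_to_mass_concentration(1.0, p2) / number_to_mass_concentration(
            1.0, p1
        )
        assert ratio == pytest.approx(8.0, rel=1e-12)


class TestSubtractionEstimator:
    def test_counter_invisible_component_recovery(self):
        """Total by TOC (98.3 % of 15 mg/L) minus counted 500/1000 nm
        populations (108.3 % and 105.0 % of 5 mg/L) leaves ~81.5 % of the
        nominal 200 nm component."""
        res = subtraction_estimator(
            UValue(0.983 * 15.0),
            [UValue(1.083 * 5.0), UValue(1.050 * 5.0)],
            nominal=5.0,
        )
        assert res.recovery.value == pytest.approx(81.5, abs=0.3)

    def test_no_components_returns_total(self):
        res = subtraction_estimator(UValue(5.0, 0.1), [], nominal=5.0)
        assert res.recovery.value == pytest.approx(100.0)

    def test_exact_balance_gives_zero_residual(self):
        res = subtraction_estimator(UValue(10.0), [UValue(4.0), UValue(6.0)])
        assert res.residual.value == pytest.approx(0.0)
        assert res.recovery is None

    def test_negative_residual_flagged(self):
        with pytest.warns(NegativeCarbonWarning):
            res = subtraction_estimator(UValue(5.0), [UValue(6.0)])
        assert res.residual.value == pytest.approx(-1.0)

    @given(scale=st.floats(0.1, 10.0))
    def test_linearity(self, scale):
        base = subtraction_estimator(UValue(14.745), [UValue(5.415), UValue(5.25)])
        scaled = subtraction_estimator(
            UValue(14.745 * scale), [UValue(5.415 * scale), UValue(5.25 * scale)]
        )
        assert scaled.residual.value == pytest.approx(
            base.residual.value * scale, rel=1e-9
        )


class TestAF4Recovery:
    def test_full_recovery_is_compliant(self):
        res = af4_recovery({"F1": 30.0, "F2": 120.0}, injected_mass=150.0)
        assert res.absolute["total"] == pytest.approx(100.0)
        assert res.compliant_absolute

    def test_absolute_and_relative_modes(self):
        res = af4_recovery(
            {"F1": 30.0, "F2": 100.0},
            injected_mass=150.0,
            no_crossflow_reference_mass=125.0,
        )
        assert res.absolute["F1"] == pytest.approx(20.0)
        assert res.absolute["F2"] == pytest.approx(66.7, abs=0.05)
        assert res.relative["F1"] == pytest.approx(24.0)
        assert res.relative["F2"] == pytest.approx(80.0)
        assert res.compliant_absolute and res.compliant_relative

    def test_zero_mass_noncompliant(self):
        res = af4_recovery({"F1": 0.0, "F2": 0.0}, injected_mass=150.0)
        assert res.absolute["total"] == 0.0
        assert not res.compliant_absolute

    def test_relative_mode_requires_reference(self):
        res = af4_recovery({"F1": 30.0}, injected_mass=150.0)
        assert res.relative is None and res.compliant_relative is None
        with pytest.raises(ValueError):
            af4_recovery({"F1": 30.0}, injected_mass=150.0, no_crossflow_reference_mass=0.0)


class TestFiltrationRecovery:
    @pytest.mark.parametrize(
        "filtrate, before, pct",
        [(1.0, 1.0, 100.0), (0.99, 1.00, 99.0), (0.577, 0.830, 69.5)],
    )
    def test_ratio(self, filtrate, before, pct):
        assert filtration_recovery(filtrate, before).value == pytest.approx(
            pct, abs=0.05
        )
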
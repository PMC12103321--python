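import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fractoc.sedimentation import (
    G,
    BuoyantParticleError,
    CentrifugeRun,
    FluidSpec,
    ParticleSpec,
    SuspensionComponent,
    effective_cutoff_diameter,
    geometry_from_rcf_gradient,
    nominal_spin_time,
    pellet_fraction,
    rcf_to_rpm,
    sedimentation_rate,
    simulate_sequential_fractionation,
    spin_time_for_cutoff,
    stokes_settling_speed,
)


def _ps(d_nm):
    return ParticleSpec.from_size(d_nm, "nm", 1.05)


class TestStokesSpeed:
    @pytest.mark.parametrize(
        "d_um, cm_per_min",
        [(10.0, 0.0164), (90.0, 1.32)],  # gravitational settling of PS in water
    )
    def test_gravitational_settling_of_ps(self, d_um, cm_per_min, water):
        v = stokes_settling_speed(ParticleSpec.from_size(d_um, "um", 1.05), water)
        assert v == pytest.approx(cm_per_min, rel=5e-3)

    def test_zero_diameter_and_buoyancy(self, water):
        assert stokes_settling_speed(_ps(0.0), water) == 0.0
        hollow = ParticleSpec.from_size(1.0, "um", 0.5)
        assert stokes_settling_speed(hollow, water) < 0
        assert hollow.is_buoyant(water)

    def test_rejects_nonpositive_viscosity(self):
        with pytest.raises(ValueError):
            FluidSpec(viscosity=0.0)


class TestGeometry:
    def test_reconstructed_radii_from_first_gradient(self):
        r_top, r_bottom, _ = geometry_from_rcf_gradient(1042.0, 1976.0, 60.0)
        assert r_top == pytest.approx(66.9, abs=0.1)
        assert r_bottom == pytest.approx(126.9, abs=0.1)

    def test_trivial_half_ratio(self):
        r_top, r_bottom, _ = geometry_from_rcf_gradient(1.0, 2.0, 60.0)
        assert (r_top, r_bottom) == (pytest.approx(60.0), pytest.approx(120.0))

    def test_second_gradient_implies_the_set_rpm(self):
        """The 1668-3161 g gradient implies ~4718 rpm, within 0.2% of the
        4714 rpm the instrument displayed for its 4000 g setting."""
        run = CentrifugeRun.from_rcf_gradient(1668.0, 3161.0, 60.0, 1800.0)
        assert run.r_bottom == pytest.approx(127.0, abs=0.1)
        assert run.rpm == pytest.approx(4714.0, rel=2e-3)

    def test_rcf_round_trip_is_exact(self):
        run = CentrifugeRun.from_rcf_gradient(1042.0, 1976.0, 60.0, 840.0)
        assert run.rcf_top == pytest.approx(1042.0, rel=1e-12)
        assert run.rcf_bottom == pytest.approx(1976.0, rel=1e-12)

    def test_two_setpoints_imply_one_rotor_radius(self):
        """2500 g at 3727 rpm and 4000 g at 4714 rpm pin the same outer
        rotor radius (~161 mm) within 0.5%."""
        r1 = 2500.0 * G / (3727.0 * 2 * math.pi / 60.0) ** 2 * 1e3
        r2 = 4000.0 * G / (4714.0 * 2 * math.pi / 60.0) ** 2 * 1e3
        assert r1 == pytest.approx(161.0, abs=1.0)
        assert abs(r1 - r2) / r1 < 0.005
        assert rcf_to_rpm(2500.0, r1) == pytest.approx(3727.0, rel=1e-6)

    def test_impossible_gradient_rejected(self):
        with pytest.raises(ValueError):
            geometry_from_rcf_gradient(2000.0, 1000.0, 60.0)


class TestCutoffs:
    def test_effective_cutoffs_of_reference_spins(self, c1_run, c2_run):
        assert effective_cutoff_diameter(c1_run, 1.05) == pytest.approx(1341.0, rel=5e-3)
        assert effective_cutoff_diameter(c2_run, 1.05) == pytest.approx(724.0, rel=5e-3)

    def test_doubling_time_halves_d_squared(self, c1_run):
        import dataclasses

        longer = dataclasses.replace(c1_run, duration=2 * c1_run.duration)
        d1 = effective_cutoff_diameter(c1_run, 1.05)
        d2 = effective_cutoff_diameter(longer, 1.05)
        assert d2**2 == pytest.approx(d1**2 / 2.0, rel=1e-12)

    def test_cutoff_time_inversion_round_trip(self, c1_run):
        d = effective_cutoff_diameter(c1_run, 1.05)
        t = spin_time_for_cutoff(d, c1_run, 1.05)
        assert t == pytest.approx(c1_run.duration, rel=1e-9)

    def test_spin_time_for_reference_cutoff(self, c1_run):
        assert spin_time_for_cutoff(1341.2, c1_run, 1.05) == pytest.approx(
            14 * 60.0, rel=1e-3
        )

    def test_nominal_planning_time_matches_bench_choice(self):
        """1000 nm at a uniform 2500 g over 60 mm needs ~14 min at constant
        Stokes speed — the planning rule behind the first spin's duration."""
        t = nominal_spin_time(1000.0, 2500.0, 60.0, 1.05)
        assert t == pytest.approx(14 * 60.0, rel=0.06)

    def test_buoyant_particle_has_no_cutoff(self, c1_run):
        with pytest.raises(BuoyantParticleError):
            effective_cutoff_diameter(c1_run, 0.9)

    @given(scale=st.floats(1.1, 5.0))
    def test_cutoff_decreases_with_time_and_speed(self, scale):
        import dataclasses

        run = CentrifugeRun.from_rcf_gradient(1042.0, 1976.0, 60.0, 840.0)
        d0 = effective_cutoff_diameter(run, 1.05)
        longer = dataclasses.replace(run, duration=run.duration * scale)
        faster = dataclasses.replace(run, angular_speed=run.angular_speed * scale)
        assert effective_cutoff_diameter(longer, 1.05) < d0
        assert effective_cutoff_diameter(faster, 1.05) < d0


class TestPelletFraction:
    def test_reference_value_ps1000_first_spin(self, c1_run):
        assert pellet_fraction(_ps(1000.0), c1_run) == pytest.approx(0.634, abs=2e-3)

    def test_zero_time_gives_zero(self, c1_run):
        import dataclasses

        flash = dataclasses.replace(c1_run, duration=1e-12)
        assert pellet_fraction(_ps(1000.0), flash) == pytest.approx(0.0, abs=1e-9)

    def test_buoyant_gives_zero(self, c1_run):
        assert pellet_fraction(ParticleSpec.from_size(1.0, "um", 0.9), c1_run) == 0.0

    @given(d_nm=st.floats(50.0, 3000.0), step=st.floats(1.01, 2.0))
    def test_strictly_increasing_in_diameter_until_capped(self, d_nm, step):
        run = CentrifugeRun.from_rcf_gradient(1042.0, 1976.0, 60.0, 840.0)
        f1 = pellet_fraction(_ps(d_nm), run)
        f2 = pellet_fraction(_ps(d_nm * step), run)
        assert f2 >= f1
        if f1 < 1.0 and f2 < 1.0:
            assert f2 > f1

    def test_monte_carlo_oracle(self, c1_run, c2_run):
        """Uniform (stratified) initial positions propagated as
        r(t) = r0 e^{kt}: arrival counts agree with the closed form within
        3 binomial SDs.  Stratification keeps the marginal distribution
        uniform while removing false alarms from the 3-sigma band."""
        rng = np.random.default_rng(20260928)
        n = 100_000
        for run in (c1_run, c2_run):
            strata = (np.arange(n) + rng.uniform(0.0, 1.0, n)) / n
            r0 = run.r_top + (run.r_bottom - run.r_top) * strata
            for d_nm in (200.0, 500.0, 1000.0):
                particle = _ps(d_nm)
                k = sedimentation_rate(particle, run)
                arrived = r0 * np.exp(k * run.duration) >= run.r_bottom
                f_mc = arrived.mean()
                f = pellet_fraction(particle, run)
                se = math.sqrt(max(f * (1 - f), 1e-12) / n)
                assert abs(f_mc - f) <= 3 * se + 1e-9


class TestSequentialFractionation:
    def test_theoretical_pellet_shares(self, ps_mixture, c1_run, c2_run):
        """Equimassic 5/5/5 mg/L PS 200/500/1000 through both spins gives
        the Stokes-law pellet compositions 75.1/21.3 (F1) and 49.5/39.9 (F2)."""
        stages = simulate_sequential_fractionation(ps_mixture, [c1_run, c2_run])
        f1, f2 = stages
        assert f1.pellet_shares["PS 1000 nm"] == pytest.approx(75.1, abs=0.3)
        assert f1.pellet_shares["PS 500 nm"] == pytest.approx(21.3, abs=0.3)
        assert f2.pellet_shares["PS 500 nm"] == pytest.approx(49.5, abs=0.3)
        assert f2.pellet_shares["PS 1000 nm"] == pytest.approx(39.9, abs=0.3)

    def test_mass_conservation_exact(self, ps_mixture, c1_run, c2_run):
        stages = simulate_sequential_fractionation(ps_mixture, [c1_run, c2_run])
        for comp in ps_mixture:
            total = (
                sum(s.pellet_mass[comp.name] for s in stages)
                + stages[-1].supernatant_concentration[comp.name]
            )
            assert total == pytest.approx(comp.mass_concentration, rel=1e-12)

    def test_shares_sum_to_100(self, ps_mixture, c1_run, c2_run):
        for stage in simulate_sequential_fractionation(ps_mixture, [c1_run, c2_run]):
            assert sum(stage.pellet_shares.values()) == pytest.approx(100.0, abs=1e-9)

    def test_single_component_full_pelleting(self, c1_run):
        import dataclasses

        week = dataclasses.replace(c1_run, duration=7 * 24 * 3600.0)
        comp = SuspensionComponent(_ps(1000.0), 5.0)
        (stage,) = simulate_sequential_fractionation([comp], [week])
        assert stage.pellet_fractions[comp.name] == 1.0
        assert stage.pellet_shares[comp.name] == pytest.approx(100.0)
        assert stage.supernatant_concentration[comp.name] == 0.0

    def test_empty_mixture_rejected(self, c1_run):
        with pytest.raises(ValueError):
            simulate_sequential_fractionation([], [c1_run])

    def test_tidy_export(self, ps_mixture, c1_run):
        (stage,) = simulate_sequential_fractionation(ps_mixture, [c1_run])
        frame = stage.to_frame()
        assert set(frame.columns) == {
            "stage",
            "component",
            "pellet_fraction",
            "pellet_mg_L",
            "share_pct",
            "supernatant_mg_L",
        }
        assert len(frame) == 3
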
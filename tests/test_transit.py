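"""Device-run integration: rate laws, mass balance, protocol behaviour."""

import dataclasses

import numpy as np
import pytest

from gitransit.drugs import DrugSubstance
from gitransit.synthetic import make_fixture
from gitransit.transit import (
    DeviceGeometry,
    DisintegrationModel,
    Formulation,
    Protocol,
    apply_sampling_correction,
    dissolution_rate,
    integrate_fixed_step,
    simulate,
    wetted_area,
)

GEO = DeviceGeometry()


class TestWettedArea:
    @pytest.mark.parametrize(
        "volume,expected", [(0.0, 0.0), (40.0, 0.0), (70.0, 3.30), (100.0, 6.60)]
    )
    def test_linear_ramp(self, volume, expected):
        assert wetted_area(GEO, volume) == pytest.approx(expected)

    def test_monotone(self):
        areas = [wetted_area(GEO, v) for v in np.linspace(0, 100, 51)]
        assert all(a <= b for a, b in zip(areas, areas[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            wetted_area(GEO, 120.0)


class TestDissolutionRate:
    def setup_method(self):
        self.drug, self.form = make_fixture("metoprolol_like")

    def test_zero_without_solid(self):
        assert dissolution_rate(self.drug, self.form, 0.0, 0.1, 5.0, 40.0, 100.0) == 0.0

    def test_zero_at_equilibrium(self):
        assert dissolution_rate(self.drug, self.form, 10.0, 5.0, 5.0, 40.0, 100.0) == 0.0

    def test_rpm_power_law(self):
        r100 = dissolution_rate(self.drug, self.form, 10.0, 0.0, 5.0, 40.0, 100.0)
        r200 = dissolution_rate(self.drug, self.form, 10.0, 0.0, 5.0, 40.0, 200.0)
        assert r200 / r100 == pytest.approx(2.0**self.form.k_rpm_exponent)

    def test_sink_condition_matches_cube_root_law(self):
        """Under sink conditions at constant volume the fraction remaining
        follows the Hixson-Crowell closed form (1 - b t)^3."""
        dose, s, v, k = 100.0, 2.0, 50.0, 0.05
        form = dataclasses.replace(self.form, dose=dose, k_ref=k, k_rpm_exponent=0.0)
        b = k * s * v / (3.0 * dose)

        def rhs(_k, y):
            return np.array(
                [-dissolution_rate(self.drug, form, y[0], 0.0, s, v, 100.0)]
            )

        step = 0.01
        n_steps = 3500
        path = integrate_fixed_step(rhs, [dose], n_steps, step)
        times = np.arange(n_steps + 1) * step
        inside = times < 1.0 / b  # before complete dissolution
        expected = dose * (1.0 - b * times[inside]) ** 3
        assert np.max(np.abs(path[inside, 0] - expected)) < 0.005 * dose


class TestSamplingCorrection:
    def test_identity_without_sampling(self):
        conc = np.array([0.0, 0.05, 0.1])
        vol = np.array([40.0, 70.0, 100.0])
        out = apply_sampling_correction(conc, vol, 0.0, dose=20.0)
        assert np.allclose(out, 100.0 * conc * vol / 20.0)

    def test_hand_example_third_sample(self):
        conc = np.full(3, 0.1)
        vol = np.full(3, 100.0)
        out = apply_sampling_correction(conc, vol, 1.0, dose=100.0)
        assert out[2] == pytest.approx(10.2)  # (0.1*100 + 2*0.1*1) mg of 100 mg

    def test_never_below_uncorrected(self):
        rng = np.random.default_rng(7)
        conc = rng.uniform(0.0, 0.2, size=8)
        vol = np.full(8, 100.0)
        raw = apply_sampling_correction(conc, vol, 0.0, dose=25.0)
        corrected = apply_sampling_correction(conc, vol, 1.5, dose=25.0)
        assert np.all(corrected >= raw - 1e-12)


class TestSimulate:
    def test_mass_conserved_at_every_output(self, metoprolol_runs, dipyridamole_runs, naftopidil_runs):
        for prof in (
            *metoprolol_runs.values(),
            *dipyridamole_runs.values(),
            naftopidil_runs[100.0]["ordinary"],
            naftopidil_runs[50.0]["od"],
        ):
            prof.validate(tol=1e-6)

    def test_permeated_monotone_nondecreasing(self, metoprolol_runs, dipyridamole_runs):
        for prof in (*metoprolol_runs.values(), *dipyridamole_runs.values()):
            assert np.all(np.diff(prof.permeated_pct) >= -1e-9)

    def test_zero_permeability_gives_zero_permeation(self):
        drug, form = make_fixture("metoprolol_like")
        drug0 = dataclasses.replace(drug, permeation_coefficient=0.0)
        prof = simulate(drug0, form, Protocol(), step_min=0.02)
        assert np.all(prof.permeated_pct == 0.0)
        prof.validate()

    def test_dissolved_profile_dose_invariant_in_first_order_regime(self):
        """For a freely soluble drug far from saturation the dissolved %
        profile does not depend on the dose."""
        drug, form = make_fixture("metoprolol_like")
        proto = Protocol(run_length_min=60.0, sampling_times=(0, 10, 20, 30, 45, 60))
        profs = [
            simulate(drug, dataclasses.replace(form, dose=d), proto, step_min=0.02)
            for d in (1e-4, 2e-4)
        ]
        assert np.allclose(profs[0].dissolved_pct, profs[1].dissolved_pct, atol=0.01)

    def test_agitation_monotonicity_for_freely_soluble_drug(self, metoprolol_runs):
        d50, d100, d200 = (metoprolol_runs[r].dissolved_pct for r in (50.0, 100.0, 200.0))
        assert np.all(d100 >= d50 - 1e-6)
        assert np.all(d200 >= d100 - 1e-6)

    def test_supersaturation_then_precipitation(self, dipyridamole_runs):
        prof = dipyridamole_runs[200.0]
        assert prof.dissolved_pct.max() > 90.0
        assert prof.times[prof.dissolved_pct.argmax()] < 10.0
        assert prof.at(120.0) < 25.0  # precipitated after the pH shift

    def test_low_agitation_suppresses_dissolution(self, dipyridamole_runs):
        for rpm in (50.0, 100.0):
            assert dipyridamole_runs[rpm].dissolved_pct.max() < 25.0

    def test_step_halving_stability(self):
        drug, form = make_fixture("dipyridamole_like")
        proto = Protocol(initial_gastric_ph=1.6, paddle_rpm=200.0)
        coarse = simulate(drug, form, proto, step_min=0.02)
        fine = simulate(drug, form, proto, step_min=0.01)
        for attr in ("dissolved_pct", "permeated_pct", "solid_pct"):
            assert np.max(np.abs(getattr(coarse, attr) - getattr(fine, attr))) < 0.1

    def test_saturation_bound_with_fast_precipitation(self):
        """With near-instant precipitation the dissolved amount stays at or
        below the solubility ceiling."""
        from gitransit.drugs import equilibrium_solubility

        drug, form = make_fixture("dipyridamole_like")
        fast = dataclasses.replace(drug, precipitation_rate=20.0)
        proto = Protocol(initial_gastric_ph=1.6, paddle_rpm=200.0)
        prof = simulate(fast, form, proto, step_min=0.01)
        for t, pct, ph, v in zip(
            prof.times, prof.dissolved_pct, prof.donor_ph, prof.donor_volume
        ):
            ceiling = 100.0 * equilibrium_solubility(fast, ph) * v / form.dose
            assert pct <= min(ceiling, 100.0) * 1.02 + 0.5

    def test_finite_volume_sampling_keeps_mass_balance(self):
        drug, form = make_fixture("metoprolol_like")
        proto = Protocol(sample_volume_ml=1.0)
        prof = simulate(drug, form, proto, step_min=0.02)
        prof.validate(tol=1e-6)
        assert prof.sampled_pct[-1] > 0.0
        corrected = apply_sampling_correction(
            prof.dissolved_pct / 100.0 * form.dose / prof.donor_volume,
            prof.donor_volume,
            1.0,
            form.dose,
        )
        assert np.all(corrected >= prof.dissolved_pct - 1e-9)

    def test_water_predispersion_changes_early_environment(self, naftopidil_runs):
        prof = naftopidil_runs[100.0]["ordinary"]
        assert prof.donor_ph[0] == pytest.approx(7.0)  # water phase
        assert prof.donor_volume[0] == pytest.approx(37.5)
        assert prof.donor_ph[-1] == pytest.approx(6.5, abs=0.1)


def test_disintegration_model_rpm_scaling():
    model = DisintegrationModel(
        tau_ref={"water": 2.0, "acidic_chloride": 10.0},
        rpm_exponent={"acidic_chloride": 2.0},
    )
    assert model.tau("water", 50.0) == 2.0  # exponent defaults to 0
    assert model.tau("acidic_chloride", 50.0) == pytest.approx(40.0)
    with pytest.raises(KeyError):
        model.tau("neutral", 100.0)


def test_protocol_validation():
    with pytest.raises(ValueError):
        Protocol(sampling_times=(0.0, 200.0))
    with pytest.raises(ValueError):
        Protocol(paddle_rpm=0.0)
    with pytest.raises(ValueError):
        DeviceGeometry(final_volume=90.0)
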
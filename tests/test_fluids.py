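"""Fluid design, mixing mass balance, and the charge-balance pH solver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gitransit import fluids as fl


def brute_force_ph(comp: fl.FluidComposition, n: int = 100_001) -> float:
    """Independent oracle: sign-change scan of a vectorised charge balance."""
    ph = np.linspace(0.0, 14.0, n)
    h = 10.0**-ph
    resid = h - fl.KW / h + comp.strong_ion_offset * 1e-3
    for name, conc in comp.species_totals.items():
        chem = comp.chemistry[name]
        c = conc * 1e-3
        resid = resid + c * (chem.cation_equiv - chem.anion_equiv)
        if chem.pkas:
            log_terms = np.zeros((len(chem.pkas) + 1, n))
            acc = np.zeros(n)
            for j, pk in enumerate(chem.pkas, start=1):
                acc = acc + (ph - pk)
                log_terms[j] = acc
            log_terms -= log_terms.max(axis=0)
            w = 10.0**log_terms
            mean_deprot = (np.arange(len(chem.pkas) + 1)[:, None] * w).sum(0) / w.sum(0)
            resid = resid - c * mean_deprot
    sign_change = np.nonzero(np.diff(np.sign(resid)) != 0)[0]
    assert sign_change.size == 1
    return float(ph[sign_change[0]])


@pytest.fixture(scope="module")
def gastric():
    return fl.fassgf(ph=1.6)


@pytest.fixture(scope="module")
def intestinal():
    return fl.fassif()


@pytest.fixture(scope="module")
def schedule(gastric, intestinal):
    pre = fl.design_pre_fluid(gastric, 40.0, intestinal, 100.0)
    return fl.MixingSchedule(40.0, 60.0, 10.0, gastric, pre)


class TestDesignPreFluid:
    def test_mass_balance_examples(self, gastric, intestinal):
        pre = fl.design_pre_fluid(gastric, 40.0, intestinal, 100.0)
        assert pre.species_totals["d_glucose"] == pytest.approx(2500.0 / 60.0)
        assert pre.species_totals["sodium_taurocholate"] == pytest.approx((300.0 - 3.2) / 60.0)
        assert pre.species_totals["nacl"] == pytest.approx((1370.0 - 1368.0) / 60.0)

    def test_infeasible_when_oversupplied(self, intestinal):
        rich = fl.FluidComposition({"nacl": 90.0})
        with pytest.raises(fl.InfeasibleDesignError, match="nacl"):
            fl.design_pre_fluid(rich, 40.0, intestinal, 100.0)

    def test_forward_inverse_consistency(self, schedule, intestinal):
        """Designing the infusate then mixing to completion must reproduce
        the target composition to high relative accuracy."""
        volume, comp = fl.mixing_state(schedule, 10.0)
        assert volume == pytest.approx(100.0)
        for name, target in intestinal.species_totals.items():
            assert comp.species_totals[name] == pytest.approx(target, rel=1e-10)
        assert comp.strong_ion_offset == pytest.approx(
            intestinal.strong_ion_offset, rel=1e-10
        )

    def test_uniform_multiple_is_reporting_only(self):
        assert fl.uniform_concentration_multiple(40.0, 100.0) == pytest.approx(5.0 / 3.0)


class TestMixingState:
    def test_identity_at_start(self, schedule, gastric):
        volume, comp = fl.mixing_state(schedule, 0.0)
        assert volume == 40.0
        for name, conc in comp.species_totals.items():
            assert conc == gastric.species_totals.get(name, 0.0)

    def test_constant_after_infusion(self, schedule):
        v1, c1 = fl.mixing_state(schedule, 10.0)
        v2, c2 = fl.mixing_state(schedule, 57.0)
        assert v1 == v2
        assert c1.species_totals == c2.species_totals

    def test_hand_calculation_midway(self, schedule):
        volume, comp = fl.mixing_state(schedule, 5.0)
        assert volume == pytest.approx(70.0)
        expected = (34.2 * 40.0 + (2.0 / 60.0) * 30.0) / 70.0
        assert comp.species_totals["nacl"] == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(t=st.floats(min_value=0.0, max_value=30.0))
    def test_species_conservation(self, schedule, t):
        volume, comp = fl.mixing_state(schedule, t)
        te = min(t, schedule.infusion_duration)
        for name in comp.species_totals:
            amount = volume * comp.species_totals[name]
            expected = (
                schedule.initial_volume
                * schedule.initial_fluid.species_totals.get(name, 0.0)
                + schedule.rate * te * schedule.infusate_fluid.species_totals.get(name, 0.0)
            )
            assert amount == pytest.approx(expected, rel=1e-12, abs=1e-12)


class TestSolvePh:
    def test_pure_water(self):
        assert fl.solve_ph(fl.FluidComposition({})) == pytest.approx(7.0, abs=1e-6)

    def test_strong_acid_millimolar(self):
        comp = fl.FluidComposition({}, strong_ion_offset=-1.0)
        assert fl.solve_ph(comp) == pytest.approx(3.0, abs=1e-3)

    def test_calibration_round_trips(self, gastric, intestinal):
        assert fl.solve_ph(gastric) == pytest.approx(1.6, abs=0.005)
        assert fl.solve_ph(intestinal) == pytest.approx(6.5, abs=0.005)

    def test_calibrate_empty_strong_acid_closed_form(self):
        empty = fl.FluidComposition({})
        offset = fl.calibrate_strong_ion(empty, 1.6)
        assert offset == pytest.approx(-(10.0**-1.6) * 1e3, rel=1e-3)
        assert fl.calibrate_strong_ion(empty, 7.0) == pytest.approx(0.0, abs=1e-6)

    def test_calibration_monotone_in_target(self):
        comp = fl.load_recipe("fassgf")
        offsets = [fl.calibrate_strong_ion(comp, ph) for ph in (1.6, 3.0, 5.0, 6.5)]
        assert offsets == sorted(offsets)

    def test_no_root_raises(self):
        class Hostile(fl.FluidComposition):
            def charge_residual(self, ph):
                return 1.0

        comp = Hostile({})
        with pytest.raises(fl.PhConvergenceError):
            fl.solve_ph(comp)

    def test_agrees_with_brute_force_scan_on_random_compositions(self):
        """The bisection root matches a 1e5-point sign-change scan of the
        charge balance on 20 random mixtures, within one grid cell."""
        rng = np.random.default_rng(42)
        names = list(fl.DEFAULT_CHEMISTRY)
        grid_cell = 14.0 / 100_000
        for _ in range(20):
            chosen = rng.choice(names, size=rng.integers(1, 6), replace=False)
            totals = {n: float(rng.uniform(0.0, 50.0)) for n in chosen}
            offset = float(rng.uniform(-20.0, 20.0))
            comp = fl.FluidComposition(totals, strong_ion_offset=offset)
            assert fl.solve_ph(comp) == pytest.approx(
                brute_force_ph(comp), abs=1.5 * grid_cell
            )


class TestPhTrajectory:
    def test_flat_when_start_equals_end(self, intestinal):
        gastric_at_65 = fl.fassgf(ph=6.5)
        pre = fl.design_pre_fluid(gastric_at_65, 40.0, intestinal, 100.0)
        sched = fl.MixingSchedule(40.0, 60.0, 10.0, gastric_at_65, pre)
        traj = fl.ph_trajectory(sched, np.linspace(0.0, 10.0, 11))
        assert np.all(np.abs(traj - 6.5) < 0.05)

    def test_gradual_monotone_shift(self, schedule):
        times = np.linspace(0.0, 12.0, 25)
        traj = fl.ph_trajectory(schedule, times)
        assert traj[0] == pytest.approx(1.6, abs=0.005)
        assert np.all(np.diff(traj) >= -1e-9)
        assert traj[-1] == pytest.approx(6.5, abs=0.1)

    @pytest.mark.parametrize("initial_ph", [3.0, 5.0])
    def test_monotone_from_elevated_gastric_ph(self, intestinal, initial_ph):
        gastric = fl.fassgf(ph=initial_ph)
        pre = fl.design_pre_fluid(gastric, 40.0, intestinal, 100.0)
        sched = fl.MixingSchedule(40.0, 60.0, 20.0, gastric, pre)
        traj = fl.ph_trajectory(sched, np.linspace(0.0, 20.0, 21))
        assert np.all(np.diff(traj) >= -1e-9)
        assert traj[-1] == pytest.approx(6.5, abs=0.1)


def test_chloride_accounts_for_added_strong_acid():
    comp = fl.fassgf(ph=1.6)
    assert comp.chloride_mM > 34.2  # NaCl plus the HCl used for adjustment
    neutralish = fl.fassgf(ph=6.5)
    assert neutralish.chloride_mM == pytest.approx(34.2, abs=1e-6)


def test_invalid_compositions_rejected():
    with pytest.raises(KeyError):
        fl.FluidComposition({"unobtainium": 1.0})
    with pytest.raises(ValueError):
        fl.FluidComposition({"nacl": -1.0})
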
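"""Full device run: disintegration, dissolution, precipitation, permeation.

State variables (mg of drug): intact-tablet solid, disintegrated solid,
dissolved drug in the donor fluid, drug partitioned into the octanol
receiver, and cumulatively sampled drug.  The donor volume, pH and chloride
follow the fluid-infusion schedule; the filter area wetted by the rising
fluid level grows linearly from zero (at the gastric volume) to its full
value (at the final volume), so permeation only starts once the infusion
lifts the level above the filter's lower edge.

Rate laws
---------
* disintegration: first-order release of intact solid with a time constant
  that depends on the surrounding medium class (water / acidic-chloride /
  neutral, switching at pH 5) and on the paddle speed;
* dissolution: Noyes-Whitney with a Hixson-Crowell surface factor,
  ``k_d(rpm) * (m_solid/dose)**(2/3) * (S - C) * V``; the rpm dependence is
  a power law around 100 rpm;
* precipitation: first-order decay of supersaturation (see ``drugs``),
  returning mass to the disintegrated-solid pool;
* permeation: ``P * A_wetted(V) * C`` into a perfect-sink receiver.

Integration is fixed-step classical Runge-Kutta with the environment
(volume, pH, chloride, solubility, wetted area) pre-tabulated on half
steps, for bit-reproducible profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from . import fluids as _fluids
from .drugs import DrugSubstance, equilibrium_solubility

__all__ = [
    "MEDIUM_CLASSES",
    "DisintegrationModel",
    "Formulation",
    "Protocol",
    "DeviceGeometry",
    "FluidPair",
    "ProfileSet",
    "wetted_area",
    "dissolution_rate",
    "simulate",
    "apply_sampling_correction",
    "calibrate_fixture",
    "Feature",
    "FitResult",
    "integrate_fixed_step",
]

MEDIUM_CLASSES = ("water", "acidic_chloride", "neutral")
#: pH above which the disintegration medium counts as neutral (gel-layer
#: behaviour is specific to strongly acidic chloride-rich media).
MEDIUM_SWITCH_PH = 5.0
#: below this fraction of the dose the 2/3-power surface factor is replaced
#: by a linear ramp, bounding the per-mass dissolution rate (avoids the
#: finite-time-extinction stiffness of the pure cube-root law).
_SURFACE_EPS = 1e-3
#: fastest relaxation (min) of the disintegrated-solid pool inside a run:
#: when the intrinsic rate would deplete the pool faster, dissolution is
#: treated as instantaneous on this timescale (keeps the explicit integrator
#: stable and makes the small-dose limit exactly release-controlled).
_FAST_DISSOLUTION_TAU = 0.05


@dataclass(frozen=True)
class DisintegrationModel:
    """Disintegration time constants per medium class with rpm scaling.

    ``tau(medium, rpm) = tau_ref[medium] * (100 / rpm) ** rpm_exponent``;
    ``tau_ref`` is the time constant at the reference paddle speed of
    100 rpm.  ``rpm_exponent = 0`` makes a medium rpm-independent (e.g. a
    tablet that falls apart in water regardless of agitation).
    """

    tau_ref: Mapping[str, float]  # min at 100 rpm, keyed by medium class
    rpm_exponent: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for medium, tau in self.tau_ref.items():
            if medium not in MEDIUM_CLASSES:
                raise ValueError(f"unknown medium class {medium!r}")
            if not tau > 0:
                raise ValueError(f"tau for {medium!r} must be positive")

    def tau(self, medium: str, rpm: float) -> float:
        if medium not in self.tau_ref:
            raise KeyError(f"no time constant for medium {medium!r}")
        expo = self.rpm_exponent.get(medium, 0.0)
        return self.tau_ref[medium] * (100.0 / rpm) ** expo


@dataclass(frozen=True)
class Formulation:
    """One drug product: dose, disintegration behaviour, dissolution rate."""

    label: str
    dose: float  # mg
    disintegration: DisintegrationModel
    k_ref: float  # dissolution rate constant at 100 rpm, 1/min
    k_rpm_exponent: float = 0.0
    role: str = "test"  # "reference" or "test"

    def __post_init__(self):
        if not self.dose > 0:
            raise ValueError("dose must be positive")
        if not self.k_ref > 0:
            raise ValueError("k_ref must be positive")
        if self.role not in ("reference", "test"):
            raise ValueError("role must be 'reference' or 'test'")

    def k_d(self, rpm: float) -> float:
        """Dissolution rate constant (1/min) at the given paddle speed."""
        return self.k_ref * (rpm / 100.0) ** self.k_rpm_exponent


@dataclass(frozen=True)
class Protocol:
    """Knobs of one device run (fasted-state gastric-to-intestinal transfer)."""

    initial_gastric_ph: float = 1.6
    infusion_min: float = 10.0
    paddle_rpm: float = 100.0
    water_disintegration: bool = False
    gastric_hold_min: float = 1.0
    run_length_min: float = 120.0
    sampling_times: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0)
    sample_volume_ml: float = 0.0  # 0 = ideal (non-perturbing) sampling

    def __post_init__(self):
        object.__setattr__(self, "sampling_times", tuple(float(t) for t in self.sampling_times))
        if not self.paddle_rpm > 0:
            raise ValueError("paddle_rpm must be positive")
        if not self.infusion_min > 0:
            raise ValueError("infusion_min must be positive")
        if self.gastric_hold_min < 0:
            raise ValueError("gastric_hold_min must be >= 0")
        if self.sample_volume_ml < 0:
            raise ValueError("sample_volume_ml must be >= 0")
        ts = self.sampling_times
        if any(t < 0 or t > self.run_length_min for t in ts) or list(ts) != sorted(ts):
            raise ValueError("sampling_times must be sorted within [0, run_length]")


@dataclass(frozen=True)
class DeviceGeometry:
    """Chamber volumes and filter area of the quarter-scale device."""

    gastric_volume: float = 40.0  # mL
    final_volume: float = 100.0  # mL
    infusate_volume: float = 60.0  # mL
    receiver_final_volume: float = 30.0  # mL
    filter_area_max: float = 6.60  # cm^2
    water_phase_volume: float = 37.5  # mL, pre-dispersion in water

    def __post_init__(self):
        for name in ("gastric_volume", "final_volume", "infusate_volume",
                     "receiver_final_volume", "filter_area_max", "water_phase_volume"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not math.isclose(self.final_volume, self.gastric_volume + self.infusate_volume):
            raise ValueError("final_volume must equal gastric_volume + infusate_volume")


@dataclass(frozen=True)
class FluidPair:
    """Gastric and intestinal recipes used by a run (uncalibrated)."""

    gastric: _fluids.FluidComposition
    intestinal: _fluids.FluidComposition
    final_ph: float = _fluids.DEFAULT_FINAL_PH


def default_fluids() -> FluidPair:
    return FluidPair(gastric=_fluids.fassgf(), intestinal=_fluids.fassif(ph=None))


@dataclass
class ProfileSet:
    """Paired time series of one run, as % of dose plus fluid state."""

    times: np.ndarray  # min
    dissolved_pct: np.ndarray
    permeated_pct: np.ndarray
    solid_pct: np.ndarray
    sampled_pct: np.ndarray
    donor_ph: np.ndarray
    donor_volume: np.ndarray  # mL

    def validate(self, tol: float = 1e-6) -> None:
        for arr in (self.dissolved_pct, self.permeated_pct, self.solid_pct, self.sampled_pct):
            if np.any(arr < -tol) or np.any(arr > 100.0 + tol):
                raise ValueError("percentages out of [0, 100]")
        total = self.dissolved_pct + self.permeated_pct + self.solid_pct + self.sampled_pct
        if np.any(np.abs(total - 100.0) > tol):
            raise ValueError("mass balance violated")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_min": self.times,
                "dissolved_pct": self.dissolved_pct,
                "permeated_pct": self.permeated_pct,
                "solid_pct": self.solid_pct,
                "sampled_pct": self.sampled_pct,
                "pH": self.donor_ph,
                "volume_mL": self.donor_volume,
            }
        )

    def at(self, t: float, series: str = "dissolved_pct") -> float:
        """Value of one series at a sampled time (exact match required)."""
        idx = np.nonzero(np.isclose(self.times, t))[0]
        if idx.size == 0:
            raise KeyError(f"time {t} not in sampling grid")
        return float(getattr(self, series)[idx[0]])


def wetted_area(geometry: DeviceGeometry, donor_volume: float) -> float:
    """Filter area (cm^2) wetted by the donor fluid at the given volume.

    Zero at or below the gastric volume (the filter sits above the initial
    fluid level), the full area at the final volume, linear in between.
    """
    if donor_volume < -1e-9 or donor_volume > geometry.final_volume + 1e-9:
        raise ValueError("donor_volume outside [0, final_volume]")
    if donor_volume <= geometry.gastric_volume:
        return 0.0
    frac = (donor_volume - geometry.gastric_volume) / (
        geometry.final_volume - geometry.gastric_volume
    )
    return geometry.filter_area_max * min(frac, 1.0)


def _surface_factor(m_solid: float, dose: float) -> float:
    """Hixson-Crowell (m/dose)^(2/3), linearised below ``_SURFACE_EPS``."""
    x = max(m_solid, 0.0) / dose
    if x >= _SURFACE_EPS:
        return x ** (2.0 / 3.0)
    return x / _SURFACE_EPS ** (1.0 / 3.0)


def dissolution_rate(
    drug: DrugSubstance,
    formulation: Formulation,
    m_disintegrated: float,
    dissolved_conc: float,
    solubility: float,
    volume: float,
    rpm: float,
) -> float:
    """Dissolution rate (mg/min) from the disintegrated-solid pool.

    Zero when no solid is available or the fluid is at/above saturation
    (precipitation is handled separately and never returned here).
    """
    if m_disintegrated <= 0.0 or dissolved_conc >= solubility:
        return 0.0
    return (
        formulation.k_d(rpm)
        * _surface_factor(m_disintegrated, formulation.dose)
        * (solubility - dissolved_conc)
        * volume
    )


def integrate_fixed_step(
    rhs: Callable[[int, np.ndarray], np.ndarray],
    y0: Sequence[float],
    n_steps: int,
    step: float,
) -> np.ndarray:
    """Classical RK4 with the environment indexed on half steps.

    ``rhs(k, y)`` receives the half-step index ``k`` (node ``i`` of the step
    grid corresponds to ``k = 2 i``), so tabulated environment arrays of
    length ``2 * n_steps + 1`` can be used without interpolation.  Returns
    the state at every full step, shape ``(n_steps + 1, len(y0))``.
    """
    y = np.asarray(y0, dtype=float)
    out = np.empty((n_steps + 1, y.size))
    out[0] = y
    for i in range(n_steps):
        k = 2 * i
        k1 = rhs(k, y)
        k2 = rhs(k + 1, y + 0.5 * step * k1)
        k3 = rhs(k + 1, y + 0.5 * step * k2)
        k4 = rhs(k + 2, y + step * k3)
        y = y + (step / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[i + 1] = y
    return out


def _tabulate_environment(
    drug: DrugSubstance,
    protocol: Protocol,
    geometry: DeviceGeometry,
    pair: FluidPair,
    grid: np.ndarray,
) -> dict[str, np.ndarray]:
    """Volume, pH, chloride, solubility, wetted area and medium class on a grid."""
    gastric = pair.gastric.with_offset(
        _fluids.calibrate_strong_ion(pair.gastric, protocol.initial_gastric_ph)
    )
    final = pair.intestinal.with_offset(
        _fluids.calibrate_strong_ion(pair.intestinal, pair.final_ph)
    )
    pre = _fluids.design_pre_fluid(
        gastric, geometry.gastric_volume, final, geometry.final_volume
    )
    schedule = _fluids.MixingSchedule(
        initial_volume=geometry.gastric_volume,
        infusate_volume=geometry.infusate_volume,
        infusion_duration=protocol.infusion_min,
        initial_fluid=gastric,
        infusate_fluid=pre,
    )
    hold = protocol.gastric_hold_min

    # pH during infusion on a coarse subgrid (the trajectory is smooth),
    # then interpolated onto the integration grid.
    coarse = np.linspace(0.0, protocol.infusion_min, max(int(protocol.infusion_min * 10), 2) + 1)
    ph_coarse = _fluids.ph_trajectory(schedule, coarse)

    n = grid.size
    volume = np.empty(n)
    ph = np.empty(n)
    chloride = np.empty(n)
    medium = np.empty(n, dtype=np.int8)  # index into MEDIUM_CLASSES

    gastric_cl = gastric.chloride_mM
    pre_cl = pre.chloride_mM
    final_ph_val = _fluids.solve_ph(_fluids.mixing_state(schedule, protocol.infusion_min)[1])
    final_volume = geometry.final_volume
    rate = schedule.rate

    for i, t in enumerate(grid):
        if protocol.water_disintegration and t < hold:
            volume[i] = geometry.water_phase_volume
            ph[i] = 7.0
            chloride[i] = 0.0
            medium[i] = 0
            continue
        if t < hold:
            volume[i] = geometry.gastric_volume
            ph[i] = protocol.initial_gastric_ph
            chloride[i] = gastric_cl
        else:
            te = min(t - hold, protocol.infusion_min)
            v_in = rate * te
            volume[i] = geometry.gastric_volume + v_in
            # chloride amounts mix conservatively
            chloride[i] = (
                gastric_cl * geometry.gastric_volume + pre_cl * v_in
            ) / volume[i]
            if te >= protocol.infusion_min:
                ph[i] = final_ph_val
            else:
                ph[i] = float(np.interp(te, coarse, ph_coarse))
            volume[i] = min(volume[i], final_volume)
        medium[i] = 1 if ph[i] < MEDIUM_SWITCH_PH else 2

    solubility = np.array(
        [equilibrium_solubility(drug, ph[i], chloride[i]) for i in range(n)]
    )
    area = np.array([wetted_area(geometry, v) for v in volume])
    return {
        "volume": volume,
        "ph": ph,
        "chloride": chloride,
        "solubility": solubility,
        "area": area,
        "medium": medium,
    }


def simulate(
    drug: DrugSubstance,
    formulation: Formulation,
    protocol: Protocol,
    geometry: DeviceGeometry | None = None,
    fluid_pair: FluidPair | None = None,
    step_min: float = 0.01,
) -> ProfileSet:
    """Integrate one device run and sample the profiles.

    The run starts with the intact tablet in the gastric fluid (or, with the
    water-disintegration protocol, in the water pre-dispersion volume for the
    hold period, after which the medium becomes the calibrated gastric fluid).
    Infusion of the designed concentrated intestinal fluid starts after the
    gastric hold and raises volume, pH and the wetted filter area.

    Sampling with ``sample_volume_ml > 0`` removes dissolved drug from the
    donor at each sampling time (volume is maintained with fresh fluid, as on
    the bench); the reported ``dissolved_pct`` stays the in-chamber value --
    use :func:`apply_sampling_correction` to reconstruct the cumulative
    dissolved amount the way bench data are reported.
    """
    geometry = geometry or DeviceGeometry()
    pair = fluid_pair or default_fluids()

    run = protocol.run_length_min
    n_steps = int(round(run / step_min))
    if not math.isclose(n_steps * step_min, run, rel_tol=0, abs_tol=1e-9):
        raise ValueError("step_min must divide run_length_min")
    half_grid = np.linspace(0.0, run, 2 * n_steps + 1)
    env = _tabulate_environment(drug, protocol, geometry, pair, half_grid)

    rpm = protocol.paddle_rpm
    dose = formulation.dose
    taus = np.array(
        [formulation.disintegration.tau(MEDIUM_CLASSES[m], rpm) for m in range(3)]
    )
    k_d = formulation.k_d(rpm)
    p_coef = drug.permeation_coefficient
    k_ppt = drug.precipitation_rate

    volume = env["volume"]
    solubility = env["solubility"]
    area = env["area"]
    medium = env["medium"]
    eps13 = _SURFACE_EPS ** (1.0 / 3.0)

    def rhs(k: int, y: np.ndarray) -> np.ndarray:
        m_intact, m_dis, m_sol, _m_rec = y
        v = volume[k]
        s = solubility[k]
        c = m_sol / v
        release = max(m_intact, 0.0) / taus[medium[k]]
        x = max(m_dis, 0.0) / dose
        surf = x ** (2.0 / 3.0) if x >= _SURFACE_EPS else x / eps13
        if c < s:
            diss = min(
                k_d * surf * (s - c) * v,
                release + max(m_dis, 0.0) / _FAST_DISSOLUTION_TAU,
            )
            ppt = 0.0
        else:
            diss = 0.0
            ppt = k_ppt * (c - s) * v
        perm = p_coef * area[k] * c
        return np.array(
            [-release, release - diss + ppt, diss - ppt - perm, perm]
        )

    y0 = np.array([dose, 0.0, 0.0, 0.0])
    sample_idx = [int(round(t / step_min)) for t in protocol.sampling_times]

    if protocol.sample_volume_ml > 0.0:
        # integrate piecewise, withdrawing a sample at each sampling time
        states = np.empty((n_steps + 1, 4))
        states[0] = y0
        sampled_cum = np.zeros(len(sample_idx))
        sampled_total = 0.0
        y = y0.copy()
        pos = 0
        pending = sorted(set(sample_idx))
        for j, target in enumerate(pending):
            if target > pos:
                seg = integrate_fixed_step(
                    lambda k, yy, off=2 * pos: rhs(off + k, yy),
                    y, target - pos, step_min,
                )
                states[pos + 1 : target + 1] = seg[1:]
                y = seg[-1]
                pos = target
            if target > 0:  # no withdrawal before the run starts
                conc = y[2] / volume[2 * target]
                removed = conc * protocol.sample_volume_ml
                y[2] -= removed
                sampled_total += removed
                states[pos] = y
            for i, si in enumerate(sample_idx):
                if si == target:
                    sampled_cum[i] = sampled_total
        if pos < n_steps:
            seg = integrate_fixed_step(
                lambda k, yy, off=2 * pos: rhs(off + k, yy), y, n_steps - pos, step_min
            )
            states[pos + 1 :] = seg[1:]
        sampled_at = sampled_cum
    else:
        states = integrate_fixed_step(rhs, y0, n_steps, step_min)
        sampled_at = np.zeros(len(sample_idx))

    picked = states[sample_idx]
    solid = np.clip(picked[:, 0] + picked[:, 1], 0.0, None)
    dissolved = np.clip(picked[:, 2], 0.0, None)
    permeated = np.clip(picked[:, 3], 0.0, None)
    profile = ProfileSet(
        times=np.array(protocol.sampling_times),
        dissolved_pct=100.0 * dissolved / dose,
        permeated_pct=100.0 * permeated / dose,
        solid_pct=100.0 * solid / dose,
        sampled_pct=100.0 * sampled_at / dose,
        donor_ph=env["ph"][[2 * i for i in sample_idx]],
        donor_volume=env["volume"][[2 * i for i in sample_idx]],
    )
    return profile


def apply_sampling_correction(
    conc_series: Sequence[float],
    volume_series: Sequence[float],
    sample_volume: float,
    dose: float,
) -> np.ndarray:
    """Cumulative dissolved % of dose, correcting for sampled aliquots.

    Bench sampling removes ``sample_volume`` of fluid at each sampling time
    (replaced with fresh medium); the cumulative amount at sample ``n`` is
    ``C_n V_n + sum_{i<n} C_i v_s``.  With ``sample_volume = 0`` this reduces
    to the in-chamber dissolved amount.
    """
    conc = np.asarray(conc_series, dtype=float)
    vol = np.asarray(volume_series, dtype=float)
    if conc.shape != vol.shape:
        raise ValueError("series must be aligned")
    if sample_volume < 0:
        raise ValueError("sample_volume must be >= 0")
    removed = np.concatenate([[0.0], np.cumsum(conc * sample_volume)[:-1]])
    return 100.0 * (conc * vol + removed) / dose


# ---------------------------------------------------------------------------
# fixture calibration


@dataclass(frozen=True)
class Feature:
    """One calibration anchor: a simulated quantity compared to a value.

    ``protocol_overrides`` are keyword replacements applied to the base
    protocol; ``cmp`` is 'eq' (squared error), 'ge' or 'le' (one-sided
    hinge penalty).
    """

    time_min: float
    value: float
    quantity: str = "dissolved_pct"
    cmp: str = "eq"
    protocol_overrides: Mapping[str, object] = field(default_factory=dict)
    weight: float = 1.0


@dataclass
class FitResult:
    params: dict[str, float]
    residuals: np.ndarray
    cost: float
    success: bool
    message: str


def _apply_params(
    drug: DrugSubstance, formulation: Formulation, values: Mapping[str, float]
) -> tuple[DrugSubstance, Formulation]:
    """Return copies with dotted-path parameters replaced.

    Supported paths: ``drug.<field>``, ``formulation.<field>`` and
    ``formulation.tau.<medium>`` (the 100-rpm reference time constant).
    """
    drug_kwargs: dict[str, float] = {}
    form_kwargs: dict[str, object] = {}
    tau_ref = dict(formulation.disintegration.tau_ref)
    for path, val in values.items():
        parts = path.split(".")
        if parts[0] == "drug" and len(parts) == 2:
            drug_kwargs[parts[1]] = val
        elif parts[0] == "formulation" and len(parts) == 2:
            form_kwargs[parts[1]] = val
        elif parts[0] == "formulation" and len(parts) == 3 and parts[1] == "tau":
            tau_ref[parts[2]] = val
        else:
            raise KeyError(f"unsupported parameter path {path!r}")
    if tau_ref != formulation.disintegration.tau_ref:
        form_kwargs["disintegration"] = replace(
            formulation.disintegration, tau_ref=tau_ref
        )
    return (
        replace(drug, **drug_kwargs) if drug_kwargs else drug,
        replace(formulation, **form_kwargs) if form_kwargs else formulation,
    )


def calibrate_fixture(
    features: Sequence[Feature],
    free_params: Sequence[str],
    x0: Sequence[float],
    drug: DrugSubstance,
    formulation: Formulation,
    protocol: Protocol,
    geometry: DeviceGeometry | None = None,
    step_min: float = 0.05,
    bounds: tuple[Sequence[float], Sequence[float]] | None = None,
) -> FitResult:
    """Least-squares fit of free parameters to feature anchors.

    Deterministic (derivative-based trust-region from the given start); each
    objective evaluation simulates every distinct protocol appearing in the
    features.  'ge'/'le' features contribute hinge residuals, so they vanish
    once satisfied.
    """
    from scipy.optimize import least_squares

    geometry = geometry or DeviceGeometry()
    proto_keys = sorted(
        {tuple(sorted(f.protocol_overrides.items())) for f in features}
    )

    def residuals(x: np.ndarray) -> np.ndarray:
        d, f = _apply_params(drug, formulation, dict(zip(free_params, x)))
        sims = {}
        for key in proto_keys:
            overrides = dict(key)
            proto = replace(protocol, **overrides)
            sims[key] = simulate(d, f, proto, geometry, step_min=step_min)
        out = []
        for feat in features:
            prof = sims[tuple(sorted(feat.protocol_overrides.items()))]
            sim_val = float(
                np.interp(feat.time_min, prof.times, getattr(prof, feat.quantity))
            )
            if feat.cmp == "eq":
                r = sim_val - feat.value
            elif feat.cmp == "ge":
                r = max(0.0, feat.value - sim_val)
            elif feat.cmp == "le":
                r = max(0.0, sim_val - feat.value)
            else:
                raise ValueError(f"unknown cmp {feat.cmp!r}")
            out.append(feat.weight * r)
        return np.array(out)

    kwargs = {}
    if bounds is not None:
        kwargs["bounds"] = bounds
    res = least_squares(
        residuals, np.asarray(x0, dtype=float), diff_step=1e-3, **kwargs
    )
    return FitResult(
        params=dict(zip(free_params, res.x)),
        residuals=res.fun,
        cost=float(res.cost),
        success=bool(res.success),
        message=res.message,
    )
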
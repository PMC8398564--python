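"""Biorelevant fluid chemistry: compositions, infusate design, and pH speciation.

The donor chamber of the transfer device starts as simulated gastric fluid
(FaSSGF) and is converted in place to simulated intestinal fluid (FaSSIF) by
infusing a concentrated "pre-intestinal" fluid at constant rate.  This module
represents fluids as total analytical concentrations of named solutes, designs
the concentrated infusate by inverse per-species mass balance, and computes
the pH of any mixture from a polyprotic charge balance.

pH adjustment with HCl/NaOH is abstracted as a signed *strong-ion offset*:
the net concentration (mM) of strong base (positive) or strong acid
(negative) added to the recipe.  The offset enters the charge balance as a
fixed-charge term and, when negative, contributes chloride for common-ion
solubility calculations downstream.

Concentrations are treated as activities (no ionic-strength correction);
this is adequate for recipe-level pH trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "SpeciesChemistry",
    "FluidComposition",
    "MixingSchedule",
    "InfeasibleDesignError",
    "PhConvergenceError",
    "load_chemistry",
    "load_recipe",
    "fassgf",
    "fassif",
    "design_pre_fluid",
    "mixing_state",
    "solve_ph",
    "calibrate_strong_ion",
    "ph_trajectory",
    "uniform_concentration_multiple",
    "DEFAULT_FINAL_PH",
]

KW = 1.0e-14  # water autoionization product at 25 degC
DEFAULT_FINAL_PH = 6.5


class InfeasibleDesignError(ValueError):
    """The initial fluid already over-supplies a species; no non-negative
    infusate concentration can reach the requested final composition."""


class PhConvergenceError(RuntimeError):
    """The charge-balance residual has no sign change on pH in [0, 14]."""


@dataclass(frozen=True)
class SpeciesChemistry:
    """Charge-balance behaviour of one named solute.

    ``pkas`` are the successive dissociation constants of the fully
    protonated form of the buffering moiety; the species with ``j`` protons
    removed carries charge ``-j`` relative to that form.  ``cation_equiv``
    and ``anion_equiv`` count fully dissociated strong counter-ions per mM.
    """

    cation_equiv: float = 0.0
    anion_equiv: float = 0.0
    chloride: bool = False
    pkas: tuple[float, ...] = ()


def _load_yaml() -> dict:
    with resources.files("gitransit.data").joinpath("recipes.yaml").open() as fh:
        return yaml.safe_load(fh)


_SHIPPED = _load_yaml()


def load_chemistry(source: Mapping | None = None) -> dict[str, SpeciesChemistry]:
    """Build the species table from the shipped YAML (or an override mapping)."""
    raw = (source or _SHIPPED)["species"]
    return {
        name: SpeciesChemistry(
            cation_equiv=float(entry.get("cation_equiv", 0.0)),
            anion_equiv=float(entry.get("anion_equiv", 0.0)),
            chloride=bool(entry.get("chloride", False)),
            pkas=tuple(float(p) for p in entry.get("pkas", [])),
        )
        for name, entry in raw.items()
    }


DEFAULT_CHEMISTRY = load_chemistry()


@dataclass(frozen=True)
class FluidComposition:
    """A chamber fluid: total concentrations (mM) plus a strong-ion offset.

    ``strong_ion_offset`` is the net strong base (positive) or strong acid
    (negative) concentration in mM added by pH adjustment.
    """

    species_totals: Mapping[str, float]
    strong_ion_offset: float = 0.0
    label: str = ""
    chemistry: Mapping[str, SpeciesChemistry] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self.chemistry is None:
            object.__setattr__(self, "chemistry", DEFAULT_CHEMISTRY)
        totals = dict(self.species_totals)
        for name, conc in totals.items():
            if name not in self.chemistry:
                raise KeyError(f"unknown species {name!r}")
            if not (conc >= 0.0):
                raise ValueError(f"negative total for {name!r}: {conc}")
        if not math.isfinite(self.strong_ion_offset):
            raise ValueError("strong_ion_offset must be finite")
        object.__setattr__(self, "species_totals", totals)

    def with_offset(self, offset: float) -> "FluidComposition":
        return replace(self, strong_ion_offset=offset)

    @property
    def chloride_mM(self) -> float:
        """Total chloride: NaCl-type salts plus any strong acid (as HCl)."""
        cl = sum(
            conc
            for name, conc in self.species_totals.items()
            if self.chemistry[name].chloride
        )
        return cl + max(0.0, -self.strong_ion_offset)

    def charge_residual(self, ph: float) -> float:
        """Charge-balance residual (mol/L, cations minus anions) at ``ph``."""
        h = 10.0 ** (-ph)
        resid = h - KW / h + self.strong_ion_offset * 1e-3
        for name, conc in self.species_totals.items():
            chem = self.chemistry[name]
            c = conc * 1e-3
            resid += c * (chem.cation_equiv - chem.anion_equiv)
            if chem.pkas:
                resid -= c * _mean_deprotonation(ph, chem.pkas)
        return resid


def _mean_deprotonation(ph: float, pkas: Sequence[float]) -> float:
    """Average number of protons removed from the fully protonated acid."""
    log_terms = [0.0]
    acc = 0.0
    for pk in pkas:
        acc += ph - pk
        log_terms.append(acc)
    m = max(log_terms)
    weights = [10.0 ** (lt - m) for lt in log_terms]
    total = sum(weights)
    return sum(j * w for j, w in enumerate(weights)) / total


@dataclass(frozen=True)
class MixingSchedule:
    """Constant-rate infusion of one fluid into a stirred initial fluid."""

    initial_volume: float  # mL
    infusate_volume: float  # mL
    infusion_duration: float  # min
    initial_fluid: FluidComposition
    infusate_fluid: FluidComposition

    def __post_init__(self):
        for attr in ("initial_volume", "infusate_volume", "infusion_duration"):
            if not (getattr(self, attr) > 0):
                raise ValueError(f"{attr} must be positive")

    @property
    def rate(self) -> float:
        """Infusion rate in mL/min."""
        return self.infusate_volume / self.infusion_duration


def design_pre_fluid(
    initial: FluidComposition,
    initial_volume: float,
    final: FluidComposition,
    final_volume: float,
) -> FluidComposition:
    """Design the concentrated infusate by per-species inverse mass balance.

    The returned fluid, infused at volume ``final_volume - initial_volume``
    into ``initial_volume`` of ``initial``, reconstructs ``final`` exactly:
    ``C_pre = (C_final * Vf - C_initial * V0) / (Vf - V0)`` for every species,
    and likewise for the strong-ion offset.

    Raises
    ------
    InfeasibleDesignError
        If any species is already over-supplied by the initial fluid (a
        negative infusate concentration would be required).
    """
    if not final_volume > initial_volume:
        raise ValueError("final_volume must exceed initial_volume")
    dv = final_volume - initial_volume
    names = set(initial.species_totals) | set(final.species_totals)
    totals: dict[str, float] = {}
    infeasible: list[str] = []
    for name in sorted(names):
        c0 = initial.species_totals.get(name, 0.0)
        cf = final.species_totals.get(name, 0.0)
        c_pre = (cf * final_volume - c0 * initial_volume) / dv
        if c_pre < -1e-9:
            infeasible.append(name)
        totals[name] = max(c_pre, 0.0)
    if infeasible:
        raise InfeasibleDesignError(
            "initial fluid over-supplies species: " + ", ".join(infeasible)
        )
    offset = (
        final.strong_ion_offset * final_volume
        - initial.strong_ion_offset * initial_volume
    ) / dv
    return FluidComposition(
        species_totals=totals,
        strong_ion_offset=offset,
        label=f"pre-fluid for {final.label or 'final'}",
        chemistry=final.chemistry,
    )


def uniform_concentration_multiple(initial_volume: float, final_volume: float) -> float:
    """Nominal concentration factor of the infusate, Vf / (Vf - V0).

    The exact per-species design generally differs from uniformly scaling the
    final recipe by this factor whenever the initial fluid already contains
    the species; the multiple is reported for reference only.
    """
    return final_volume / (final_volume - initial_volume)


def mixing_state(schedule: MixingSchedule, t: float) -> tuple[float, FluidComposition]:
    """Volume (mL) and well-mixed composition at elapsed time ``t`` (min).

    Species amounts are conserved: the total at time ``t`` is the initial
    amount plus the infused amount, divided by the current volume.  After the
    infusion ends the state is constant.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    te = min(t, schedule.infusion_duration)
    v_in = schedule.rate * te
    volume = schedule.initial_volume + v_in
    names = set(schedule.initial_fluid.species_totals) | set(
        schedule.infusate_fluid.species_totals
    )
    totals = {
        name: (
            schedule.initial_fluid.species_totals.get(name, 0.0)
            * schedule.initial_volume
            + schedule.infusate_fluid.species_totals.get(name, 0.0) * v_in
        )
        / volume
        for name in sorted(names)
    }
    offset = (
        schedule.initial_fluid.strong_ion_offset * schedule.initial_volume
        + schedule.infusate_fluid.strong_ion_offset * v_in
    ) / volume
    comp = FluidComposition(
        species_totals=totals,
        strong_ion_offset=offset,
        label=f"{schedule.initial_fluid.label} + infusate @ {te:g} min",
        chemistry=schedule.initial_fluid.chemistry,
    )
    return volume, comp


def solve_ph(comp: FluidComposition, tol: float = 1e-12) -> float:
    """Unique pH in [0, 14] where the charge-balance residual vanishes.

    The residual is strictly decreasing in pH, so bisection is used for
    robustness; iteration continues until the bracket is narrower than
    ``tol`` in pH units.
    """
    lo, hi = 0.0, 14.0
    r_lo = comp.charge_residual(lo)
    r_hi = comp.charge_residual(hi)
    if r_lo < 0.0 or r_hi > 0.0:
        raise PhConvergenceError(
            f"no charge-balance root in [0, 14] for {comp.label!r} "
            f"(residuals {r_lo:.3e}, {r_hi:.3e})"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if comp.charge_residual(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_strong_ion(comp: FluidComposition, target_ph: float) -> float:
    """Strong-ion offset (mM) that brings ``comp`` exactly to ``target_ph``.

    The charge-balance residual is linear in the offset, so the calibration
    is closed-form: the offset cancels the residual of the offset-free
    composition at the target pH.
    """
    if not (0.0 <= target_ph <= 14.0):
        raise ValueError("target_ph must be in [0, 14]")
    base = comp.with_offset(0.0)
    return -base.charge_residual(target_ph) * 1e3


def ph_trajectory(schedule: MixingSchedule, times: Sequence[float]) -> np.ndarray:
    """pH of the mixture at each requested time (min).

    The strong-ion offset mixes conservatively (volume-weighted), so for an
    acidic initial fluid and a near-neutral final fluid the series is
    non-decreasing and ends at the final-fluid pH.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(times < 0) or np.any(np.diff(times) < 0):
        raise ValueError("times must be a sorted 1-D array of non-negative minutes")
    return np.array([solve_ph(mixing_state(schedule, t)[1]) for t in times])


def load_recipe(
    name: str,
    source: Mapping | None = None,
    chemistry: Mapping[str, SpeciesChemistry] | None = None,
) -> FluidComposition:
    """Load a named recipe (``fassgf``/``fassif``) from the shipped YAML."""
    raw = (source or _SHIPPED)["recipes"]
    if name not in raw:
        raise KeyError(f"unknown recipe {name!r}; available: {sorted(raw)}")
    entry = raw[name]
    return FluidComposition(
        species_totals={k: float(v) for k, v in entry["species"].items()},
        strong_ion_offset=0.0,
        label=entry.get("label", name),
        chemistry=chemistry or DEFAULT_CHEMISTRY,
    )


def fassgf(ph: float | None = None) -> FluidComposition:
    """Shipped gastric recipe, optionally calibrated to an initial pH."""
    comp = load_recipe("fassgf")
    if ph is None:
        return comp
    return comp.with_offset(calibrate_strong_ion(comp, ph))


def fassif(ph: float | None = DEFAULT_FINAL_PH) -> FluidComposition:
    """Shipped intestinal recipe, calibrated to pH 6.5 by default."""
    comp = load_recipe("fassif")
    if ph is None:
        return comp
    return comp.with_offset(calibrate_strong_ion(comp, ph))
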
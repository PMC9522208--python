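"""Gas-transport physics for spiracular respiration at 25 degrees C.

Two transport modes through a spiracle, modelled as a short cylinder:

* diffusion (Fick):       G_diff = (area/depth) * K,  K = D * beta
  with D the O2 diffusivity in air and beta the capacitance coefficient
  of O2 in air, so G_diff carries nmol s^-1 kPa^-1 and the flux is
  J_diff = G_diff * dPO2.
* advection (Poiseuille): G_adv = area^2 / (8 * mu * length) in SI,
  carrying m^3 s^-1 kPa^-1; the O2 flux is J_adv = G_adv * [O2] * dHP.

Resting metabolic rate follows the interspecific insect allometry
log10(MR uW) = 3.2 + 0.75 log10(mass g); converted to O2 consumption
via 20.7 uJ per nL O2 (RQ 0.85) and 24.5 nL per nmol (ideal gas at
25 C).  The partial-pressure gradient a beetle needs to supply a
metabolic scenario purely by diffusion across its spiracles is

    dPO2 = MR_O2(AS, EXP, mass) / G_diff_total

where AS is the aerobic scope (1 at rest, 90 for maximal flight) and
EXP the metabolic mass-scaling exponent.  Air caps dPO2 at ~21 kPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

ATMOSPHERIC_PO2_KPA = 21.0


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical and energetic constants, frozen at 25 degrees C.

    D            O2 diffusivity in air, cm^2 s^-1
    beta_cap     O2 capacitance coefficient in air, nmol cm^-3 kPa^-1
    mu           dynamic viscosity of air, kPa s
    e_per_nl     energy equivalent of O2 at RQ 0.85, uJ nL^-1
    nl_per_nmol  molar volume of O2 at 25 C, nL nmol^-1
    mr_intercept log10 resting metabolic rate (uW) of a 1 g insect
    mr_exponent  resting metabolic mass-scaling exponent
    """

    D: float = 0.178
    beta_cap: float = 404.0
    mu: float = 1.86e-8
    e_per_nl: float = 20.7
    nl_per_nmol: float = 24.5
    mr_intercept: float = 3.2
    mr_exponent: float = 0.75
    temperature_c: float = 25.0

    def __post_init__(self):
        for name in ("D", "beta_cap", "mu", "e_per_nl", "nl_per_nmol"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")

    @property
    def krogh_K(self) -> float:
        """Krogh's diffusion constant D*beta, nmol cm^-1 s^-1 kPa^-1."""
        return self.D * self.beta_cap


DEFAULT_CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class FlowConditions:
    """Driving gradients for the two transport modes.

    dPO2     O2 partial-pressure gradient across the exchanger, kPa
    dHP      hydrostatic pressure gradient, kPa
    o2_conc  O2 concentration in the advected fluid, mol m^-3
    """

    dPO2: float = 0.0
    dHP: float = 0.0
    o2_conc: float = 8.6

    def __post_init__(self):
        if self.o2_conc < 0:
            raise ValueError("o2_conc must be >= 0")


@dataclass(frozen=True)
class MetabolicScenario:
    """An activity level: aerobic scope and metabolic scaling exponent."""

    aerobic_scope: float = 1.0
    exponent: float = 0.75
    name: str = ""

    def __post_init__(self):
        if self.aerobic_scope < 1:
            raise ValueError("aerobic_scope must be >= 1 (1 = rest)")
        if not (self.exponent > 0):
            raise ValueError("exponent must be > 0")


REST = MetabolicScenario(aerobic_scope=1.0, exponent=0.75, name="rest")
FLIGHT_LOW = MetabolicScenario(aerobic_scope=90.0, exponent=0.67, name="flight_exp0.67")
FLIGHT_HIGH = MetabolicScenario(aerobic_scope=90.0, exponent=1.19, name="flight_exp1.19")
DEFAULT_SCENARIOS = (REST, FLIGHT_LOW, FLIGHT_HIGH)


def diffusive_conductance(area, depth, c: PhysicalConstants = DEFAULT_CONSTANTS):
    """Fick diffusive conductance (nmol s^-1 kPa^-1) of a barrier.

    ``area`` in cm^2, ``depth`` in cm; accepts arrays elementwise.
    """
    area = np.asarray(area, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if np.any(area <= 0) or np.any(depth <= 0):
        raise ValueError("area and depth must be > 0")
    out = (area / depth) * c.krogh_K
    return out.item() if out.ndim == 0 else out


def diffusive_conductance_from_index(diff_index, c: PhysicalConstants = DEFAULT_CONSTANTS):
    """G_diff from a precomputed area/depth index (cm)."""
    diff_index = np.asarray(diff_index, dtype=float)
    if np.any(diff_index <= 0):
        raise ValueError("diff_index must be > 0")
    out = diff_index * c.krogh_K
    return out.item() if out.ndim == 0 else out


def diffusive_flux(g_diff, f: FlowConditions):
    """O2 flux (nmol s^-1) down a partial-pressure gradient."""
    g = np.asarray(g_diff, dtype=float)
    if np.any(g < 0):
        raise ValueError("G_diff must be >= 0")
    out = g * f.dPO2
    return out.item() if out.ndim == 0 else out


def advective_conductance(area, length, c: PhysicalConstants = DEFAULT_CONSTANTS):
    """Poiseuille advective conductance (m^3 s^-1 kPa^-1) of a channel.

    ``area`` in m^2, ``length`` in m; accepts arrays elementwise.
    """
    area = np.asarray(area, dtype=float)
    length = np.asarray(length, dtype=float)
    if np.any(area <= 0) or np.any(length <= 0):
        raise ValueError("area and length must be > 0")
    out = area**2 / (8.0 * c.mu * length)
    return out.item() if out.ndim == 0 else out


def advective_conductance_from_index(adv_index_m3, c: PhysicalConstants = DEFAULT_CONSTANTS):
    """G_adv from a precomputed area^2/length index already in m^3."""
    idx = np.asarray(adv_index_m3, dtype=float)
    if np.any(idx <= 0):
        raise ValueError("adv_index must be > 0")
    out = idx / (8.0 * c.mu)
    return out.item() if out.ndim == 0 else out


def advective_flux(g_adv, f: FlowConditions):
    """O2 flux (mol s^-1) carried by bulk flow down a pressure gradient."""
    g = np.asarray(g_adv, dtype=float)
    if np.any(g < 0):
        raise ValueError("G_adv must be >= 0")
    out = g * f.o2_conc * f.dHP
    return out.item() if out.ndim == 0 else out


def resting_metabolic_rate(mass, c: PhysicalConstants = DEFAULT_CONSTANTS):
    """Resting metabolic rate (uW) of an insect of ``mass`` grams."""
    mass = np.asarray(mass, dtype=float)
    if np.any(mass <= 0):
        raise ValueError("mass must be > 0")
    out = 10.0 ** (c.mr_intercept + c.mr_exponent * np.log10(mass))
    return out.item() if out.ndim == 0 else out


def o2_consumption(mr_uw, c: PhysicalConstants = DEFAULT_CONSTANTS):
    """Convert a metabolic rate (uW) to O2 consumption (nmol s^-1)."""
    mr = np.asarray(mr_uw, dtype=float)
    if np.any(mr < 0):
        raise ValueError("metabolic rate must be >= 0")
    out = mr / c.e_per_nl / c.nl_per_nmol
    return out.item() if out.ndim == 0 else out


def metabolic_o2_demand(
    mass, scen: MetabolicScenario, c: PhysicalConstants = DEFAULT_CONSTANTS
):
    """O2 consumption (nmol s^-1) for a scenario: AS-scaled allometry."""
    mass = np.asarray(mass, dtype=float)
    if np.any(mass <= 0):
        raise ValueError("mass must be > 0")
    mr = 10.0 ** (
        np.log10(scen.aerobic_scope) + c.mr_intercept + scen.exponent * np.log10(mass)
    )
    return o2_consumption(mr, c)


def required_dpo2(
    mass,
    total_g_diff,
    scen: MetabolicScenario = REST,
    c: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Partial-pressure gradient (kPa) needed to supply a scenario's O2
    demand purely by diffusion through conductance ``total_g_diff``
    (nmol s^-1 kPa^-1)."""
    g = np.asarray(total_g_diff, dtype=float)
    if np.any(g <= 0):
        raise ValueError("total_g_diff must be > 0")
    out = metabolic_o2_demand(mass, scen, c) / g
    return out.item() if out.ndim == 0 else out


def exceeds_atmosphere(dpo2) -> bool | np.ndarray:
    """True where a required gradient exceeds atmospheric PO2 (21 kPa)."""
    d = np.asarray(dpo2, dtype=float)
    if np.any(d < 0):
        raise ValueError("dPO2 must be >= 0")
    out = d > ATMOSPHERIC_PO2_KPA
    return out.item() if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Scaling-exponent algebra
# ---------------------------------------------------------------------------
# If the opening's linear size scales as mass^r and its depth/length as
# mass^L, then area ~ mass^(2r), G_diff = area/depth ~ mass^(2r - L) and
# G_adv = area^2/length ~ mass^(4r - L).  These identities let published
# vertebrate morphometric exponents be turned into conductance exponents.

def conductance_exponent(area_exp: float, depth_exp: float, k: int = 1) -> float:
    """Exponent of a conductance scaling from area and depth exponents:
    k=1 for diffusive (area/depth), k=2 for advective (area^2/depth)."""
    return k * area_exp - depth_exp


def diffusive_exponent_from_radius(radius_exp: float, length_exp: float) -> float:
    """G_diff exponent from radius and length exponents: 2r - L."""
    return 2.0 * radius_exp - length_exp


def advective_exponent_from_radius(radius_exp: float, length_exp: float) -> float:
    """G_adv exponent from radius and length exponents: 4r - L."""
    return 4.0 * radius_exp - length_exp


def area_exponent_conserving_dpo2(
    metabolic_exp: float = 0.75, depth_exp: float = 0.33
) -> float:
    """Area exponent that would hold the required dPO2 constant across
    sizes: the opening area must scale as mass^(metabolic + depth)."""
    return metabolic_exp + depth_exp


def log10_scope(aerobic_scope: float) -> float:
    """log10 of the aerobic scope, the additive term in the demand model."""
    if aerobic_scope <= 0:
        raise ValueError("aerobic_scope must be > 0")
    return math.log10(aerobic_scope)
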
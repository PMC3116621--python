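"""Temperature and pH transforms for the EI model parameters.

Equilibrium constants follow the van't Hoff relation, rate constants the
Arrhenius relation, both relative to a reference temperature.  pH enters
through the Cornish-Bowden dibasic-acid picture: each relevant site of the
enzyme (or its monomer) is a dibasic acid whose singly protonated form is the
active one, giving the classical bell-shaped Michaelis pH function.  The pH
factor is normalized to the parameter set's reference pH so that at reference
conditions every parameter keeps its tabulated value.

Six protonation sites (12 pKa values) are distinguished: one per dimerization
family (applied to the dissociation constants, squared because two monomers
protonate independently) and one per catalytic step family (applied to the
phosphorylation and HPr-transfer rate constants).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, TYPE_CHECKING

from .cycle_network import PH_SITES, ph_site_of

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import ParameterSet

R_GAS = 8.314  # J/(mol K)

__all__ = [
    "R_GAS",
    "Environment",
    "ThermalMeta",
    "EffectiveParams",
    "vant_hoff",
    "arrhenius",
    "ph_active_fraction",
    "apply_environment",
]


@dataclass(frozen=True)
class Environment:
    """Experimental condition: absolute temperature (K) and pH."""

    T: float
    pH: float

    def __post_init__(self) -> None:
        if not (273.0 < self.T < 373.0):
            raise ValueError(f"temperature {self.T} K outside the liquid range")
        if not (0.0 < self.pH < 14.0):
            raise ValueError(f"pH {self.pH} out of range")

    @classmethod
    def from_celsius(cls, t_celsius: float, pH: float) -> "Environment":
        return cls(T=t_celsius + 273.15, pH=pH)


@dataclass
class ThermalMeta:
    """Thermal/pH metadata: reaction enthalpies for the independent
    equilibrium constants (J/mol; dependent constants inherit theirs through
    the detailed-balance identities), activation energies per shared Ea class
    (J/mol), and per-site (pKa1, pKa2) pairs with pKa1 > pKa2."""

    dH: dict[str, float] = field(default_factory=dict)
    Ea: dict[str, float] = field(default_factory=dict)
    pKa: dict[str, tuple[float, float]] = field(default_factory=dict)

    def validate(self) -> None:
        for site, (p1, p2) in self.pKa.items():
            if not p1 > p2:
                raise ValueError(f"site {site}: require pKa1 > pKa2, got {p1}, {p2}")


def vant_hoff(K_at_T0: float, dH: float, T: float, T0: float) -> float:
    """K(T) = K(T0) * exp(dH * (T0 - T) / (R * T * T0))."""
    if not K_at_T0 > 0:
        raise ValueError("equilibrium constant must be positive")
    if T <= 0 or T0 <= 0:
        raise ValueError("absolute temperatures must be positive")
    return K_at_T0 * math.exp(dH * (T0 - T) / (R_GAS * T * T0))


def arrhenius(k_at_T0: float, Ea: float, T: float, T0: float) -> float:
    """k(T) = k(T0) * exp(Ea * (T0 - T) / (R * T * T0))."""
    if k_at_T0 < 0:
        raise ValueError("rate constant must be non-negative")
    if T <= 0 or T0 <= 0:
        raise ValueError("absolute temperatures must be positive")
    return k_at_T0 * math.exp(Ea * (T0 - T) / (R_GAS * T * T0))


def ph_active_fraction(pH: float, pKa1: float, pKa2: float) -> float:
    """Fraction of the singly protonated (active) form of a dibasic acid.

    With the deprotonation convention pKa1 > pKa2 the fraction is
    ``1 / (1 + 10**(pKa2 - pH) + 10**(pH - pKa1))``: a bell peaking at the
    midpoint of the two pKa and vanishing at both pH extremes.
    """
    if not pKa1 > pKa2:
        raise ValueError("require pKa1 > pKa2")
    return 1.0 / (1.0 + 10.0 ** (pKa2 - pH) + 10.0 ** (pH - pKa1))


@dataclass
class EffectiveParams:
    """Parameter values transformed to one experimental condition.

    ``K_site`` maps every equilibrium-constant identifier to its per-site
    value at (T, pH); ``k`` maps every rate-constant identifier likewise.
    """

    K_site: dict[str, float]
    k: dict[str, float]
    k9: float
    env: Environment
    variant: str


def apply_environment(params: "ParameterSet", env: Environment) -> EffectiveParams:
    """Transform a reference-condition parameter set to (T, pH).

    Order of operations: van't Hoff on the independent equilibrium constants,
    detailed-balance resolution of the dependent ones, pH factors on the
    designated constants, Arrhenius plus pH factors on the rate constants.
    The HPrP hydrolysis constant k9 is temperature- and pH-independent.
    """
    meta = params.thermal
    meta.validate()
    net = params.network()
    T0 = params.T0

    K_ind = {
        kid: vant_hoff(v, meta.dH.get(kid, 0.0), env.T, T0)
        for kid, v in params.K_independent.items()
    }
    K_site = net.resolve_parameters(K_ind)

    phi: dict[str, float] = {}
    for site in PH_SITES:
        if site in meta.pKa:
            p1, p2 = meta.pKa[site]
            phi[site] = ph_active_fraction(env.pH, p1, p2) / ph_active_fraction(
                params.pH0, p1, p2
            )
        else:
            phi[site] = 1.0

    for kid in K_site:
        site = ph_site_of(kid)
        if site is not None:
            # dimerization: two independently protonating monomers must be
            # active, so association scales with phi**2 and the dissociation
            # constant with phi**-2
            K_site[kid] /= phi[site] ** 2

    from .cycle_network import ea_class_of

    ea_of_k: dict[str, str] = {}
    for r in net.reactions:
        if r.k_id:
            ea_of_k[r.k_id] = ea_class_of(r)
    k_eff: dict[str, float] = {}
    for kid, v in params.k.items():
        if kid in params.fixed_zero:
            k_eff[kid] = 0.0
            continue
        v = arrhenius(v, meta.Ea.get(ea_of_k.get(kid, ""), 0.0), env.T, T0)
        site = ph_site_of(kid)
        if site is not None:
            v *= phi[site]
        k_eff[kid] = v

    return EffectiveParams(
        K_site=K_site, k=k_eff, k9=params.k9, env=env, variant=params.variant
    )
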
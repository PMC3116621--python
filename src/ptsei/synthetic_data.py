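"""Ground-truth parameter sets and synthetic datasets for the EI model.

No machine-readable dataset accompanies the original in vitro experiments,
so fitting, model selection and prediction are exercised on synthetic data
emulating the four experiment families the model was identified on:

* EI phosphorylation time courses (EI 0.06 / 0.23 mg/mL at 20-fold molar
  PEP excess, 23 C, pH 6.5),
* mixed EI+HPr phosphorylation time courses (PEP 160 uM, HPr 24.4 uM,
  EI 157 nM - 1.57 uM at 37 C pH 7.4; and low-concentration runs down to
  EI 32.8 nM, PEP 390 nM),
* equilibrium phospho-EI titrations against PEP,
* initial-rate curves v0(HPr; PEP) at EI 1.3 uM, 25 C, pH 7.2.

The ground truth is constructed from micro-state free energies, so it is
thermodynamically consistent by construction (every reaction-cycle product
of equilibrium constants equals one) while honoring the qualitative
orderings of the fitted constants: PEP binding stabilizes the
unphosphorylated dimer (Kd 3.8e-4 -> 8e-5 -> 9.7e-8 mM with 0, 1, 2 bound
PEP), phosphorylation stabilizes the dimer (Kd(ZP2) < Kd(ZP) << Kd(Z)),
monomeric PEP binding at 0.37 mM, and transfer to HPr blocked when PEP sits
on the unphosphorylated subunit of the singly phosphorylated dimer.
Pyruvate binding is taken uniform across phosphorylation states, which makes
the Pyr-blind sharing of the transfer constants exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cycle_network import build_network
from .environment import Environment, ThermalMeta
from .fit import Dataset, Stage, predict
from .parameters import ParameterSet
from .reduced_model import POOLS
from .simulate import ExperimentSpec

DEFAULT_EI_KDA = 63.5  # monomer molar mass used for mg/mL designs

__all__ = [
    "DEFAULT_EI_KDA",
    "SyntheticDesign",
    "mgml_to_mM",
    "make_truth_params",
    "restrict_to_variant",
    "reduced_free_parameters",
    "stage_plan_for",
    "standard_designs",
    "generate",
]


def mgml_to_mM(mass_conc: float, molar_mass: float = DEFAULT_EI_KDA) -> float:
    """Convert mg/mL to mM given the molar mass in kDa."""
    if not mass_conc > 0 or not molar_mass > 0:
        raise ValueError("mass concentration and molar mass must be positive")
    return mass_conc / molar_mass


# ---------------------------------------------------------------------------
# Ground-truth parameters

def _truth_site_energies(rng: np.random.Generator):
    """Free energies (ln, mM units) of every micro-state plus the HPrP
    chemical-potential offset, from a handful of physical constants."""
    j = lambda s=0.03: 10.0 ** rng.normal(0.0, s)

    KE_Y = 0.37 * j()       # PEP off the monomer (mM)
    KE_YP = 0.5 * j()       # PEP off the phosphorylated monomer
    KY = 2.0 * j()          # Pyr, uniform across phosphorylation states
    KdZ0 = 3.8e-4 * j()     # unphosphorylated dimer dissociation
    fZ = [1.0, (8e-5 / 3.8e-4) * j(), (9.7e-8 / 3.8e-4) * j()]  # per bound PEP
    KdZP0 = 1e-5 * j()      # singly phosphorylated dimer
    KdZP20 = 5e-7 * j()     # doubly phosphorylated dimer
    rE = 0.5 * j()          # PEP stabilization per molecule, ZP/ZP2 families
    Kp1 = 5.0 * j()         # first-phosphorylation equilibrium (root)
    Kt1 = 20.0 * j()        # ZP -> Z transfer equilibrium (root)

    gP = (math.log(KY) + math.log(KdZP0) - math.log(KE_Y)
          - math.log(KdZ0 * fZ[1]) - math.log(Kp1))
    delta = gP - math.log(KdZP0) + math.log(KdZ0) - math.log(Kt1)

    def g_mono(phospho: bool, ligand: str) -> float:
        g = gP if phospho else 0.0
        if ligand == "PEP":
            g -= math.log(KE_YP if phospho else KE_Y)
        elif ligand == "Pyr":
            g -= math.log(KY)
        return g

    def kd_dimer(state) -> float:
        nE = state.ligand_count("PEP")
        if state.pool == "Z":
            return KdZ0 * fZ[nE]
        if state.pool == "ZP":
            return KdZP0 * rE ** nE
        return KdZP20 * rE ** nE

    net = build_network("all_forms")
    G = {}
    for s in net.states:
        if s.oligomer == "monomer":
            G[s] = g_mono(s.subunits[0].phospho, s.subunits[0].ligand)
        else:
            G[s] = sum(g_mono(u.phospho, u.ligand) for u in s.subunits) \
                - math.log(kd_dimer(s))
    return net, G, delta


def _truth_K_site(net, G, delta) -> dict[str, float]:
    full: dict[str, float] = {}
    for r in net.reactions:
        ln = sum(G[s] for s in r.products) - sum(G[s] for s in r.reactants)
        ln += r.small_deltas.get("HPrP", 0) * delta
        v = math.exp(ln)
        if r.K_id in full and abs(math.log(full[r.K_id] / v)) > 1e-9:
            raise AssertionError(f"inconsistent class value for {r.K_id}")
        full[r.K_id] = v
    return full


_ZERO_TRANSFERS = ("kt:ZP:dfse", "kt:ZP:dese", "kt:ZP:dyse")


def _truth_rates(rng: np.random.Generator, K_site: dict[str, float]) -> dict[str, float]:
    """Rate constants: dimerization families share an association rate (so
    ligand stabilization slows dissociation instead of accelerating
    association past the diffusion limit); the root dissociation rates echo
    the fitted 1/k1 ~ 0.003 1/s and k45 ~ 0.43 1/s."""
    j = lambda: 10.0 ** rng.normal(0.0, 0.03)
    kd_root = {"Z": 0.003 * j(), "ZP": 1.0 * j(), "ZP2": 0.43 * j()}
    K_root = {"Z": K_site["Kd:Z(f,f)"], "ZP": K_site["Kd:ZP(f,F)"],
              "ZP2": K_site["Kd:ZP2(F,F)"]}

    def kd_of(kid: str) -> float:
        pool = kid[3:].split("(")[0]
        # linear free-energy split: ligand stabilization accelerates
        # association and slows dissociation in equal measure
        ratio = K_site["Kd:" + kid[3:]] / K_root[pool]
        return kd_root[pool] * ratio ** 0.5

    kp1, kp2 = 20.0 * j(), 15.0 * j()
    ktm, ktZP, ktZP2 = 3e4 * j(), 5000.0 * j(), 2500.0 * j()
    k: dict[str, float] = {}
    net = build_network("all_forms")
    for kid in net.k_ids:
        if kid.startswith("kd:"):
            k[kid] = kd_of(kid)
        elif kid.startswith("kp:Z("):
            k[kid] = kp1 * (0.3 if kid == "kp:Z(e,e)" else 1.0)
        elif kid.startswith("kp:ZP("):
            k[kid] = kp2 * (0.3 if kid == "kp:ZP(e,E)" else 1.0)
        elif kid.startswith("kt:YP:"):
            k[kid] = ktm * (0.3 if kid.endswith(":e") else 1.0)
        elif kid.startswith("kt:ZP:"):
            if kid in _ZERO_TRANSFERS:
                k[kid] = 0.0  # PEP on the unphosphorylated subunit blocks transfer
            else:
                k[kid] = ktZP * (0.4 if ":de" in kid else 1.0)
        elif kid.startswith("kt:ZP2:"):
            k[kid] = ktZP2 * (0.4 if ":de" in kid else 1.0)
        else:  # pragma: no cover
            raise AssertionError(kid)
    return k


_DEFAULT_PKA = {
    "pH:dim:Z": (7.0, 5.0),
    "pH:dim:ZP": (7.5, 5.5),
    "pH:dim:ZP2": (7.5, 5.5),
    "pH:phos:1": (8.5, 6.0),
    "pH:phos:2": (8.5, 6.0),
    "pH:hpr": (8.5, 6.5),
}

_DEFAULT_EA = {
    "Ea:dim:Z": 60e3, "Ea:dim:ZP": 55e3, "Ea:dim:ZP2": 55e3,
    "Ea:phos:sf": 45e3, "Ea:phos:se": 45e3, "Ea:phos:sy": 45e3,
}


def make_truth_params(seed: int = 0, scale: str = "full",
                      table=None) -> ParameterSet:
    """Detailed-balance-consistent ground-truth parameter set.

    ``table`` may point to a CSV parameter table (the shape written by
    :meth:`ParameterSet.to_csv`); otherwise documented defaults are used,
    jittered reproducibly by ``seed``.  ``scale`` only selects which
    parameters the desk-scale fitting helpers treat as free (see
    :func:`reduced_free_parameters`); the constants themselves are identical.
    """
    if scale not in ("full", "reduced"):
        raise ValueError(f"unknown scale {scale!r}")
    if table is not None:
        return ParameterSet.from_csv(table)
    rng = np.random.default_rng(seed)
    net, G, delta = _truth_site_energies(rng)
    K_site = _truth_K_site(net, G, delta)
    basis = net.detailed_balance_basis()
    K_ind = {kid: K_site[kid] for kid in basis.independent}
    k = _truth_rates(rng, K_site)
    dH = {}
    for kid in basis.independent:
        if kid.startswith("Kd:Z("):
            dH[kid] = 40e3
        elif kid.startswith("Kd:ZP("):
            dH[kid] = 30e3
        elif kid.startswith("Kd:ZP2("):
            dH[kid] = 25e3
    thermal = ThermalMeta(dH=dH, Ea=dict(_DEFAULT_EA), pKa=dict(_DEFAULT_PKA))
    return ParameterSet(
        variant="all_forms", K_independent=K_ind, k=k, thermal=thermal,
        fixed_zero=set(_ZERO_TRANSFERS),
    )


def restrict_to_variant(params: ParameterSet, variant: str) -> ParameterSet:
    """The same constants expressed on a different mechanism variant's
    network (its own independent set and rate-constant subset)."""
    net = build_network(variant)
    site = params.site_K()
    basis = net.detailed_balance_basis()
    # transfer classes absent from the all_forms resolution cannot occur:
    # every variant's classes are a subset of all_forms classes
    K_ind = {kid: site[kid] for kid in basis.independent}
    k = {kid: params.k[kid] for kid in net.k_ids}
    return ParameterSet(
        variant=variant, K_independent=K_ind, k=k, thermal=params.thermal,
        k9=params.k9, T0=params.T0, pH0=params.pH0,
        fixed_zero={z for z in params.fixed_zero if z in k},
    )


def reduced_free_parameters(params: ParameterSet) -> tuple[str, ...]:
    """Desk-scale free-parameter subset (<= 10 rate constants): the root
    dimerization and phosphorylation constants plus one transfer constant
    per donor route.  When both dimer routes are active, the ZP2 constant is
    held at its prior (its flux is largely interchangeable with the ZP route
    at desk scale, so freeing both would leave neither determined)."""
    core = [c for c in ("kd:Z(f,f)", "kd:ZP2(F,F)", "kp:Z(e,f)", "kp:ZP(e,F)")
            if c in params.k]
    transfer = [c for c in ("kt:YP:f", "kt:ZP:dfsf", "kt:ZP2:dfsf")
                if c in params.k]
    if "kt:ZP:dfsf" in transfer and "kt:YP:f" in transfer:
        transfer.remove("kt:ZP2:dfsf")
    return tuple(core + transfer)


def stage_plan_for(params: ParameterSet) -> list[Stage]:
    """Default three-step plan over the reduced free-parameter subset.

    Stage 1 frees only the core constants the EI-only time courses actually
    determine; the remaining core constants join at stage 3, where the
    pooled data pin them down (freeing them earlier lets the search slide
    along compensation valleys in the EI-only objective)."""
    free = reduced_free_parameters(params)
    stage1 = tuple(p for p in free if p in ("kd:ZP2(F,F)", "kp:ZP(e,F)"))
    stage2 = tuple(p for p in free if p.startswith("kt:"))
    return [
        Stage("pep_to_ei", ("ei_only",), stage1),
        Stage("to_hpr", ("hpr",), stage2),
        Stage("all", None, free),
    ]


# ---------------------------------------------------------------------------
# Synthetic designs

@dataclass
class SyntheticDesign:
    """One synthetic experiment: a simulable spec, its abscissae, and a
    multiplicative lognormal noise model (relative sd)."""

    name: str
    family: str  # ei_timecourse | mixed_timecourse | equilibrium_titration | initial_rate_curve
    spec: ExperimentSpec
    abscissa: np.ndarray
    group: str
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        families = ("ei_timecourse", "mixed_timecourse",
                    "equilibrium_titration", "initial_rate_curve")
        if self.family not in families:
            raise ValueError(f"unknown family {self.family!r}")


def standard_designs(seed: int = 0, noise_sd: float = 0.02) -> list[SyntheticDesign]:
    """Desk-scale set of designs mirroring the four fitted experiment
    families (~50 points in total)."""
    designs: list[SyntheticDesign] = []

    # EI phosphorylation without HPr: 0.06 / 0.23 mg/mL, 20-fold PEP excess
    env_ei = Environment.from_celsius(23.0, 6.5)
    for i, mgml in enumerate((0.06, 0.23)):
        ei = mgml_to_mM(mgml, DEFAULT_EI_KDA)
        spec = ExperimentSpec.model1(
            env=env_ei, EItotal=ei, PEP0=20.0 * ei,
            observable="phospho_EI", kind="timecourse", rtol=1e-6)
        designs.append(SyntheticDesign(
            name=f"ei_tc_{mgml}", family="ei_timecourse", spec=spec,
            abscissa=np.geomspace(5.0, 900.0, 7), group="ei_only",
            noise_sd=noise_sd, seed=seed + i))

    # EI phosphorylation without HPr at sub-saturating PEP: EI 140 nM, PEP 44 uM
    spec_ei_low = ExperimentSpec.model1(
        env=Environment.from_celsius(25.0, 6.5), EItotal=1.4e-4, PEP0=0.044,
        observable="phospho_EI", kind="timecourse", rtol=1e-6)
    designs.append(SyntheticDesign(
        name="ei_tc_lowpep", family="ei_timecourse", spec=spec_ei_low,
        abscissa=np.geomspace(10.0, 1800.0, 6), group="ei_only",
        noise_sd=noise_sd, seed=seed + 2))

    # mixed EI+HPr time courses: PEP 160 uM, HPr 24.4 uM, EI 157 nM / 1.57 uM
    env_mix = Environment.from_celsius(37.0, 7.4)
    for i, ei in enumerate((1.57e-4, 1.57e-3)):
        spec = ExperimentSpec.model1(
            env=env_mix, EItotal=ei, HPrtotal=0.0244, PEP0=0.16,
            observable="total_phospho_protein", kind="timecourse", rtol=1e-6)
        designs.append(SyntheticDesign(
            name=f"mix_tc_{ei:g}", family="mixed_timecourse", spec=spec,
            abscissa=np.geomspace(2.0, 600.0, 7), group="hpr",
            noise_sd=noise_sd, seed=seed + 10 + i))
    # low-concentration run: EI 32.8 nM, PEP 390 nM, HPr 66 nM at 25 C pH 6.5
    spec_low = ExperimentSpec.model1(
        env=Environment.from_celsius(25.0, 6.5), EItotal=3.28e-5,
        HPrtotal=6.6e-5, PEP0=3.9e-4,
        observable="phospho_HPr", kind="timecourse", rtol=1e-6)
    designs.append(SyntheticDesign(
        name="mix_tc_low", family="mixed_timecourse", spec=spec_low,
        abscissa=np.geomspace(5.0, 1800.0, 6), group="hpr",
        noise_sd=noise_sd, seed=seed + 12))

    # equilibrium phospho-EI titration vs PEP (no HPr)
    spec_tit = ExperimentSpec.model1(
        env=Environment.from_celsius(25.0, 7.0), EItotal=1e-3,
        observable="phospho_EI", kind="titration", scan_var="PEP0",
        times=np.array([3600.0]), rtol=1e-6)
    designs.append(SyntheticDesign(
        name="titration_pep", family="equilibrium_titration", spec=spec_tit,
        abscissa=np.geomspace(1e-3, 1.0, 6), group="equilibrium",
        noise_sd=noise_sd, seed=seed + 20))

    # initial-rate curves v0(HPr) at two PEP levels, EI 1.3 uM, 25 C pH 7.2
    env_v0 = Environment.from_celsius(25.0, 7.2)
    for i, pep in enumerate((2.0, 0.0615)):
        spec = ExperimentSpec.model2(
            env=env_v0, EItotal=1.3e-3, PEP=pep, Pyr=0.0, HPr=0.0,
            observable="initial_rate", kind="rate_curve", scan_var="HPr",
            rtol=1e-6)
        designs.append(SyntheticDesign(
            name=f"v0_pep{pep:g}", family="initial_rate_curve", spec=spec,
            abscissa=np.array([2e-3, 6e-3, 0.018, 0.05]), group="hpr",
            noise_sd=noise_sd, seed=seed + 30 + i))
    return designs


def generate(design: SyntheticDesign, truth: ParameterSet) -> Dataset:
    """Simulate the design under the truth and apply multiplicative
    lognormal noise; the clean Dataset (noise_sd = 0) reproduces the truth's
    predictions exactly.

    Because the noise is multiplicative, the emitted datasets carry
    generalized-least-squares weights 1/v^2 (floored at 5% of the dataset
    maximum), so that experiments measured on very different concentration
    scales contribute comparable information to the fit.
    """
    ds = Dataset(spec=design.spec, abscissa=design.abscissa,
                 observed=np.zeros_like(np.asarray(design.abscissa, float)),
                 provenance=f"synthetic:{design.name}:seed{design.seed}",
                 group=design.group)
    clean = predict(truth, ds)
    rng = np.random.default_rng(design.seed)
    noisy = clean * np.exp(rng.normal(0.0, design.noise_sd, size=clean.shape)) \
        if design.noise_sd > 0 else clean
    ds.observed = noisy
    scale = np.maximum(np.abs(noisy), 0.05 * np.max(np.abs(noisy), initial=0.0))
    if np.all(scale > 0):
        ds.weights = 1.0 / scale**2
    return ds
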
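"""Catalytic-cycle network of E. coli PTS Enzyme I (EI).

EI shuttles between monomer and dimer, binds its substrate PEP and product
pyruvate on each subunit's C-terminal domain, autophosphorylates (dimer only)
on His-189 from subunit-bound PEP, and passes the phosphoryl group to HPr.
This module enumerates every micro-state of the enzyme, generates all
reversible elementary reactions between them, attaches statistical weight
factors for the symmetric dimer, and parameterizes the equilibrium constants
so that a declared system of detailed-balance (Wegscheider) conditions holds
by construction.

Micro-states are canonicalized so that the two subunits of a dimer are
interchangeable; statistical factors then follow from counting the labeled
(subunit-distinguishable) configurations behind each merged state.  The five
classical pools are

    Y   unphosphorylated monomer          (3 states: free, PEP, Pyr)
    YP  phosphorylated monomer            (3 states)
    Z   unphosphorylated dimer            (6 states after symmetry merging)
    ZP  singly phosphorylated dimer       (9 states)
    ZP2 doubly phosphorylated dimer       (6 states)

Equilibrium constants are oriented in the dissociation direction
(complex -> parts).  Concentration unit is mM, time s, energies J/mol.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

__all__ = [
    "LIGANDS",
    "SubunitState",
    "EnzymeState",
    "Reaction",
    "MechanismVariant",
    "ReactionNetwork",
    "enumerate_states",
    "build_network",
    "detailed_balance_basis",
    "resolve_parameters",
    "wegscheider_basis",
    "VARIANTS",
]

LIGANDS = ("none", "PEP", "Pyr")

_LIG_TOKEN = {"none": "f", "PEP": "e", "Pyr": "y"}
_TOKEN_LIG = {v: k for k, v in _LIG_TOKEN.items()}


@dataclass(frozen=True, order=True)
class SubunitState:
    """Configuration of one EI subunit: phosphorylation flag and bound ligand."""

    phospho: bool
    ligand: str

    def __post_init__(self) -> None:
        if self.ligand not in LIGANDS:
            raise ValueError(f"unknown ligand {self.ligand!r}")

    @property
    def token(self) -> str:
        t = _LIG_TOKEN[self.ligand]
        return t.upper() if self.phospho else t


@dataclass(frozen=True)
class EnzymeState:
    """One micro-state of EI: monomer or (symmetry-merged) dimer."""

    oligomer: str  # 'monomer' | 'dimer'
    subunits: tuple[SubunitState, ...]

    def __post_init__(self) -> None:
        if self.oligomer == "monomer":
            if len(self.subunits) != 1:
                raise ValueError("monomer has exactly one subunit")
        elif self.oligomer == "dimer":
            if len(self.subunits) != 2:
                raise ValueError("dimer has exactly two subunits")
            object.__setattr__(self, "subunits", tuple(sorted(self.subunits)))
        else:
            raise ValueError(f"unknown oligomer {self.oligomer!r}")

    @property
    def n_phospho(self) -> int:
        return sum(1 for s in self.subunits if s.phospho)

    @property
    def pool(self) -> str:
        if self.oligomer == "monomer":
            return "YP" if self.n_phospho else "Y"
        return {0: "Z", 1: "ZP", 2: "ZP2"}[self.n_phospho]

    @property
    def multiplicity(self) -> int:
        """Number of labeled (subunit-distinguishable) configurations."""
        if self.oligomer == "monomer":
            return 1
        return 1 if self.subunits[0] == self.subunits[1] else 2

    def ligand_count(self, ligand: str) -> int:
        return sum(1 for s in self.subunits if s.ligand == ligand)

    @property
    def label(self) -> str:
        toks = ",".join(s.token for s in self.subunits)
        return f"{self.pool}({toks})"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"EnzymeState<{self.label}>"

    def __hash__(self) -> int:
        return hash((self.oligomer, self.subunits))


def _mono(phospho: bool, ligand: str) -> EnzymeState:
    return EnzymeState("monomer", (SubunitState(phospho, ligand),))


def _dimer(a: SubunitState, b: SubunitState) -> EnzymeState:
    return EnzymeState("dimer", (a, b))


def state_from_label(label: str) -> EnzymeState:
    """Parse a state label such as ``'Z(f,e)'`` or ``'YP(E)'``."""
    toks = label[label.index("(") + 1 : -1].split(",")
    subs = tuple(SubunitState(t.isupper(), _TOKEN_LIG[t.lower()]) for t in toks)
    return EnzymeState("monomer" if len(subs) == 1 else "dimer", subs)


def enumerate_states() -> set[EnzymeState]:
    """All canonicalized EI micro-states (27: Y 3, YP 3, Z 6, ZP 9, ZP2 6)."""
    states: set[EnzymeState] = set()
    for p in (False, True):
        for l in LIGANDS:
            states.add(_mono(p, l))
    for s1, s2 in itertools.product(
        (SubunitState(p, l) for p in (False, True) for l in LIGANDS), repeat=2
    ):
        states.add(_dimer(s1, s2))
    return states


# ---------------------------------------------------------------------------
# Mechanism variants: which pools may donate the phosphoryl group to HPr.

@dataclass(frozen=True)
class MechanismVariant:
    label: str
    donors: frozenset[str]  # subset of {'YP', 'ZP', 'ZP2'}


VARIANTS: dict[str, MechanismVariant] = {
    "monomer_only": MechanismVariant("monomer_only", frozenset({"YP"})),
    "zp2_only": MechanismVariant("zp2_only", frozenset({"ZP2"})),
    "zp_and_zp2": MechanismVariant("zp_and_zp2", frozenset({"ZP", "ZP2"})),
    "all_forms": MechanismVariant("all_forms", frozenset({"YP", "ZP", "ZP2"})),
}


# ---------------------------------------------------------------------------
# Reactions

@dataclass(frozen=True)
class Reaction:
    """One reversible merged reaction.

    ``reactants``/``products`` list the enzyme states consumed/produced in
    the forward direction; ``small_deltas`` gives the net change of free
    small molecules (PEP, Pyr, HPr, HPrP) in the forward direction.

    Forward-direction conventions (K and k both refer to this direction):

    * ``ligand_binding``   complex -> state + ligand  (dissociation; K in mM,
      no rate constant: binding is quasi-equilibrated)
    * ``dimerization``     dimer -> monomer(s)        (dissociation; K in mM,
      k in 1/s)
    * ``phosphorylation``  PEP-bound subunit -> phospho subunit with bound
      Pyr (K dimensionless, k in 1/s)
    * ``hpr_transfer``     donor + HPr -> acceptor + HPrP (K dimensionless,
      k in 1/(mM*s))

    ``sigma`` converts the shared per-site constant to the apparent constant
    for merged concentrations, ``K_app = sigma * K_site``; ``n_channels`` is
    the number of labeled elementary reactions lumped into this one, which
    scales the apparent forward rate constant.
    """

    kind: str
    reactants: tuple[EnzymeState, ...]
    products: tuple[EnzymeState, ...]
    small_deltas: Mapping[str, int]
    K_id: str
    k_id: str | None
    sigma: Fraction
    n_channels: int

    @property
    def statistical_factor(self) -> int:
        f = self.sigma if self.sigma >= 1 else 1 / self.sigma
        return int(f)

    def check_balance(self) -> None:
        """Raise if subunits, phosphoryl groups or ligands do not balance."""

        def count(states: Sequence[EnzymeState], what: str) -> int:
            if what == "sub":
                return sum(len(s.subunits) for s in states)
            if what == "pho":
                return sum(s.n_phospho for s in states)
            return sum(s.ligand_count(what) for s in states)

        d = dict(self.small_deltas)
        if count(self.products, "sub") != count(self.reactants, "sub"):
            raise AssertionError(f"subunit imbalance in {self.K_id}")
        # phosphoryl groups: carried by phospho subunits, bound/free PEP, HPrP
        pho_lhs = count(self.reactants, "pho") + count(self.reactants, "PEP")
        pho_rhs = count(self.products, "pho") + count(self.products, "PEP")
        if pho_rhs - pho_lhs + d.get("PEP", 0) + d.get("HPrP", 0) != 0:
            raise AssertionError(f"phosphoryl imbalance in {self.K_id}")
        # three-carbon backbone: PEP + Pyr, bound or free
        c3_lhs = count(self.reactants, "PEP") + count(self.reactants, "Pyr")
        c3_rhs = count(self.products, "PEP") + count(self.products, "Pyr")
        if c3_rhs - c3_lhs + d.get("PEP", 0) + d.get("Pyr", 0) != 0:
            raise AssertionError(f"backbone imbalance in {self.K_id}")
        if d.get("HPr", 0) + d.get("HPrP", 0) != 0:
            raise AssertionError(f"HPr moiety imbalance in {self.K_id}")


def _transfer_K_class(pool: str, donor_lig: str, other_lig: str | None) -> str:
    """K-sharing for phosphotransfer to HPr.

    Pyr occupancy is taken not to alter the transfer constants (it binds the
    C-terminal domain while transfer is carried by the N-terminal domain), so
    Pyr counts as an empty site here; for the doubly phosphorylated dimer the
    spectator subunit's occupancy is ignored as well.
    """
    blind = lambda l: "f" if l in ("none", "Pyr") else "e"
    if pool == "YP":
        return f"Kt:YP:{blind(donor_lig)}"
    if pool == "ZP":
        return f"Kt:ZP:d{blind(donor_lig)}s{blind(other_lig)}"
    return f"Kt:ZP2:d{blind(donor_lig)}"


def _transfer_k_class(pool: str, donor_lig: str, other_lig: str | None) -> str:
    """k-sharing for phosphotransfer: Pyr on the donor site is equivalent to
    an empty donor site when the partner subunit is empty (dimer donors)."""
    t = lambda l: _LIG_TOKEN[l]
    if pool == "YP":
        return f"kt:YP:{t(donor_lig)}"
    d, s = t(donor_lig), t(other_lig)
    if s == "f" and d == "y":
        d = "f"
    return f"kt:{pool}:d{d}s{s}"


def _phos_step(state: EnzymeState) -> int:
    return 1 if state.pool == "Z" else 2


def ea_class_of(reaction: Reaction) -> str | None:
    """Activation-energy sharing: one Ea per dimerization family, one per
    phosphorylation step x spectator ligand, one per transfer rate class."""
    if reaction.k_id is None:
        return None
    if reaction.kind == "dimerization":
        return f"Ea:dim:{reaction.reactants[0].pool}"
    if reaction.kind == "phosphorylation":
        # spectator = the subunit that is not being phosphorylated (for
        # Z(e,e) either subunit may fire; the spectator is then PEP-bound)
        subs = list(reaction.reactants[0].subunits)
        for i, s in enumerate(subs):
            if not s.phospho and s.ligand == "PEP":
                subs.pop(i)
                break
        return f"Ea:phos:s{_LIG_TOKEN[subs[0].ligand]}"
    return f"Ea:{reaction.k_id}"


def ph_site_of(param_id: str) -> str | None:
    """pH-sensitivity sharing map: 6 protonation sites, 12 pKa values.

    Dimerization equilibria carry a squared per-monomer factor; the catalytic
    rate constants (phosphorylation, HPr transfer) carry a single factor."""
    if param_id.startswith("Kd:Z("):
        return "pH:dim:Z"
    if param_id.startswith("Kd:ZP("):
        return "pH:dim:ZP"
    if param_id.startswith("Kd:ZP2("):
        return "pH:dim:ZP2"
    if param_id.startswith("kp:Z("):
        return "pH:phos:1"
    if param_id.startswith("kp:ZP("):
        return "pH:phos:2"
    if param_id.startswith("kt:"):
        return "pH:hpr"
    return None


PH_SITES = ("pH:dim:Z", "pH:dim:ZP", "pH:dim:ZP2", "pH:phos:1", "pH:phos:2", "pH:hpr")


# ---------------------------------------------------------------------------
# Labeled (subunit-distinguishable) enumeration: used to derive statistical
# factors, channel counts and the detailed-balance constraint system.

def _labeled_states() -> list[tuple]:
    cfgs = [(p, l) for p in (False, True) for l in LIGANDS]
    mono = [("m", (c,)) for c in cfgs]
    dim = [("d", (c1, c2)) for c1 in cfgs for c2 in cfgs]
    return mono + dim


def _merge_labeled(s: tuple) -> EnzymeState:
    o, subs = s
    subs = tuple(SubunitState(p, l) for p, l in subs)
    return EnzymeState("monomer" if o == "m" else "dimer", subs)


def _labeled_reactions() -> list[dict]:
    """Labeled elementary reactions with their merged-reaction identity key."""
    out = []
    for s in _labeled_states():
        o, subs = s
        for i, (p, l) in enumerate(subs):
            if l != "none":
                t = (o, tuple((p, "none") if j == i else c for j, c in enumerate(subs)))
                out.append(
                    dict(kind="ligand_binding", lhs=[s], rhs=[t],
                         small={l: +1},
                         key=("bind", _merge_labeled(s), _merge_labeled(t))))
            if (not p) and l == "PEP" and o == "d":
                t = (o, tuple((True, "Pyr") if j == i else c for j, c in enumerate(subs)))
                out.append(
                    dict(kind="phosphorylation", lhs=[s], rhs=[t], small={},
                         key=("phos", _merge_labeled(s), _merge_labeled(t))))
            if p:
                t = (o, tuple((False, l) if j == i else c for j, c in enumerate(subs)))
                if o == "m":
                    key = ("hpr", "YP", l, None)
                else:
                    op, ol = subs[1 - i]
                    key = ("hpr", "ZP2" if op else "ZP", l, ol,
                           _merge_labeled(s), _merge_labeled(t))
                out.append(
                    dict(kind="hpr_transfer", lhs=[s], rhs=[t],
                         small={"HPr": -1, "HPrP": +1}, key=key))
    monos = [s for s in _labeled_states() if s[0] == "m"]
    for a in monos:
        for b in monos:
            dm = ("d", (a[1][0], b[1][0]))
            # stored in dissociation orientation: dimer -> monomers
            out.append(
                dict(kind="dimerization", lhs=[dm], rhs=[a, b], small={},
                     key=("dimer", _merge_labeled(dm))))
    return out


def _merged_reaction_table() -> list[dict]:
    """Group labeled reactions into merged reactions; compute sigma/channels."""
    groups: dict[tuple, list[dict]] = {}
    for lr in _labeled_reactions():
        groups.setdefault(lr["key"], []).append(lr)
    merged = []
    for key, lrs in sorted(groups.items(), key=lambda kv: str(kv[0])):
        rep = lrs[0]
        lhs = tuple(_merge_labeled(s) for s in rep["lhs"])
        rhs = tuple(_merge_labeled(s) for s in rep["rhs"])
        mu = lambda states: Fraction(
            int.__mul__(*(s.multiplicity for s in states)) if len(states) == 2
            else states[0].multiplicity)
        sigma = mu(rhs) / mu(lhs)
        merged.append(
            dict(kind=rep["kind"], reactants=lhs, products=rhs,
                 small=dict(rep["small"]), sigma=sigma, n_channels=len(lrs),
                 key=key, labeled=lrs))
    return merged


def _K_id_for(m: dict) -> str:
    kind = m["kind"]
    r, p = m["reactants"], m["products"]
    if kind == "ligand_binding":
        return f"Kb:{r[0].label}>{p[0].label}"
    if kind == "dimerization":
        return f"Kd:{r[0].label}"
    if kind == "phosphorylation":
        return f"Kp:{r[0].label}"
    pool, dlig, olig = m["key"][1], m["key"][2], m["key"][3]
    return _transfer_K_class(pool, dlig, olig)


def _k_id_for(m: dict) -> str | None:
    kind = m["kind"]
    if kind == "ligand_binding":
        return None
    if kind == "dimerization":
        return f"kd:{m['reactants'][0].label}"
    if kind == "phosphorylation":
        return f"kp:{m['reactants'][0].label}"
    pool, dlig, olig = m["key"][1], m["key"][2], m["key"][3]
    return _transfer_k_class(pool, dlig, olig)


@dataclass
class ReactionNetwork:
    """Typed reversible reaction network over the EI micro-states."""

    states: tuple[EnzymeState, ...]
    reactions: tuple[Reaction, ...]
    variant: MechanismVariant
    _basis_cache: dict | None = field(default=None, repr=False, compare=False)

    @property
    def K_ids(self) -> tuple[str, ...]:
        return tuple(sorted({r.K_id for r in self.reactions}))

    @property
    def k_ids(self) -> tuple[str, ...]:
        return tuple(sorted({r.k_id for r in self.reactions if r.k_id}))

    @property
    def Ea_ids(self) -> tuple[str, ...]:
        return tuple(sorted({c for c in (ea_class_of(r) for r in self.reactions) if c}))

    def reactions_of_kind(self, kind: str) -> list[Reaction]:
        return [r for r in self.reactions if r.kind == kind]

    def is_connected(self) -> bool:
        adj: dict[EnzymeState, set[EnzymeState]] = {s: set() for s in self.states}
        for r in self.reactions:
            members = list(r.reactants) + list(r.products)
            for a in members:
                for b in members:
                    if a != b:
                        adj[a].add(b)
        seen, todo = set(), [self.states[0]]
        while todo:
            s = todo.pop()
            if s in seen:
                continue
            seen.add(s)
            todo.extend(adj[s] - seen)
        return len(seen) == len(self.states)

    # -- detailed balance ---------------------------------------------------

    def detailed_balance_basis(self):
        return detailed_balance_basis(self)

    def resolve_parameters(self, independent_values: Mapping[str, float]):
        return resolve_parameters(self, independent_values)

    def cycle_conditions(self) -> list[dict[str, Fraction]]:
        """The declared Wegscheider constraint system: each entry maps K_id to
        its (rational) exponent in a product that must equal one."""
        basis = detailed_balance_basis(self)
        return basis.conditions

    def to_json(self) -> str:
        doc = {
            "variant": self.variant.label,
            "states": [s.label for s in self.states],
            "reactions": [
                {
                    "kind": r.kind,
                    "reactants": [s.label for s in r.reactants],
                    "products": [s.label for s in r.products],
                    "small_deltas": dict(r.small_deltas),
                    "K_id": r.K_id,
                    "k_id": r.k_id,
                    "statistical_factor": r.statistical_factor,
                    "sigma": str(r.sigma),
                    "n_channels": r.n_channels,
                    "Ea_id": ea_class_of(r),
                    "pH_site_K": ph_site_of(r.K_id),
                    "pH_site_k": ph_site_of(r.k_id) if r.k_id else None,
                }
                for r in self.reactions
            ],
        }
        return json.dumps(doc, indent=1)


def build_network(variant: str | MechanismVariant = "all_forms") -> ReactionNetwork:
    """Construct the full catalytic-cycle network for a mechanism variant.

    The ``all_forms`` network has 76 reversible merged reactions carrying 63
    distinct equilibrium-constant identifiers and 46 rate-constant
    identifiers.
    """
    if isinstance(variant, str):
        try:
            variant = VARIANTS[variant]
        except KeyError:
            raise ValueError(f"unknown variant {variant!r}") from None
    reactions = []
    for m in _merged_reaction_table():
        if m["kind"] == "hpr_transfer":
            pool = m["reactants"][0].pool
            if pool not in variant.donors:
                continue
        reactions.append(
            Reaction(
                kind=m["kind"],
                reactants=m["reactants"],
                products=m["products"],
                small_deltas=m["small"],
                K_id=_K_id_for(m),
                k_id=_k_id_for(m),
                sigma=m["sigma"],
                n_channels=m["n_channels"],
            )
        )
    states = tuple(sorted(enumerate_states(), key=lambda s: s.label))
    return ReactionNetwork(states=states, reactions=tuple(reactions), variant=variant)


# ---------------------------------------------------------------------------
# Detailed balance (Wegscheider conditions)

# Declared ratio conditions tying ligand-substituted HPr-transfer constants to
# the base constants through PEP exchange on the adjacent binding equilibria.
# (The Pyr analogues are *not* closed: Pyr-blindness of the transfer constants
# is imposed as an equality regardless of the Pyr binding constants.)
_DECLARED_TRANSFER_CONDITIONS: list[dict[str, int]] = [
    # PEP on the spectator subunit of the singly phosphorylated dimer
    {"Kt:ZP:dfse": 1, "Kb:Z(e,f)>Z(f,f)": 1,
     "Kt:ZP:dfsf": -1, "Kb:ZP(e,F)>ZP(f,F)": -1},
    {"Kt:ZP:dese": 1, "Kb:Z(e,e)>Z(e,f)": 1,
     "Kt:ZP:desf": -1, "Kb:ZP(e,E)>ZP(f,E)": -1},
    # PEP on the donor subunit of the doubly phosphorylated dimer
    {"Kt:ZP2:de": 1, "Kb:ZP(e,F)>ZP(f,F)": 1,
     "Kt:ZP2:df": -1, "Kb:ZP2(E,F)>ZP2(F,F)": -1},
]


@dataclass
class DetailedBalanceBasis:
    independent: tuple[str, ...]
    dependent: tuple[str, ...]
    # dependent K_id -> list of (independent K_id, exponent)
    dependency: dict[str, list[tuple[str, Fraction]]]
    conditions: list[dict[str, Fraction]]

    @property
    def rank(self) -> int:
        return len(self.dependent)


def wegscheider_basis(
    stoich_rows: Sequence[Mapping[int, int]],
    class_of: Sequence[str],
    n_species: int,
    extra_conditions: Sequence[Mapping[str, int]] = (),
) -> DetailedBalanceBasis:
    """Generic Wegscheider analysis for a reversible reaction system.

    ``stoich_rows[j]`` maps species index -> stoichiometric coefficient of
    reaction j (forward direction); ``class_of[j]`` names the shared
    equilibrium-constant class of reaction j.  The constraint system is the
    cycle space of the stoichiometric matrix projected onto the classes, plus
    any explicitly declared product conditions.
    """
    import sympy

    classes = sorted({*class_of, *(k for c in extra_conditions for k in c)})
    cidx = {c: i for i, c in enumerate(classes)}
    n_rxn = len(stoich_rows)
    S = sympy.zeros(n_species, n_rxn)
    for j, row in enumerate(stoich_rows):
        for i, v in row.items():
            S[i, j] = v
    rows = []
    for v in S.nullspace():
        row = [sympy.Integer(0)] * len(classes)
        for j in range(n_rxn):
            if v[j] != 0:
                row[cidx[class_of[j]]] += v[j]
        rows.append(row)
    for cond in extra_conditions:
        row = [sympy.Integer(0)] * len(classes)
        for k, e in cond.items():
            row[cidx[k]] += e
        rows.append(row)
    if not rows:
        return DetailedBalanceBasis(tuple(classes), (), {}, [])
    M = sympy.Matrix(rows)
    R, pivots = M.rref()
    dependent = [classes[p] for p in pivots]
    independent = [c for i, c in enumerate(classes) if i not in set(pivots)]
    dependency: dict[str, list[tuple[str, Fraction]]] = {}
    conditions: list[dict[str, Fraction]] = []
    for r, p in enumerate(pivots):
        expr = []
        cond: dict[str, Fraction] = {classes[p]: Fraction(1)}
        for j in range(len(classes)):
            if j == p:
                continue
            c = R[r, j]
            if c != 0:
                expr.append((classes[j], -Fraction(int(c.p), int(c.q))))
                cond[classes[j]] = Fraction(int(c.p), int(c.q))
        dependency[classes[p]] = expr
        conditions.append(cond)
    return DetailedBalanceBasis(
        tuple(independent), tuple(dependent), dependency, conditions
    )


@lru_cache(maxsize=8)
def _basis_for_variant(variant_label: str) -> DetailedBalanceBasis:
    network = build_network(variant_label)
    # Constraint system is built on the *labeled* network so that the shared
    # per-site constants are exactly cycle-consistent (statistical factors are
    # a separate, multiplicative bookkeeping on top of them).
    labeled = _labeled_reactions()
    key_to_K: dict[tuple, str] = {}
    for m in _merged_reaction_table():
        key_to_K[m["key"]] = _K_id_for(m)
    lstates = _labeled_states()
    lidx = {s: i for i, s in enumerate(lstates)}
    small_idx = {n: len(lstates) + i for i, n in enumerate(("PEP", "Pyr", "HPr", "HPrP"))}
    n_species = len(lstates) + 4
    present_K = set(network.K_ids)
    rows, class_of = [], []
    for lr in labeled:
        if lr["kind"] == "hpr_transfer":
            # transfer cycles are not closed: their constants enter only via
            # the declared conditions below
            continue
        row: dict[int, int] = {}
        for s in lr["lhs"]:
            row[lidx[s]] = row.get(lidx[s], 0) - 1
        for s in lr["rhs"]:
            row[lidx[s]] = row.get(lidx[s], 0) + 1
        for name, v in lr["small"].items():
            row[small_idx[name]] = row.get(small_idx[name], 0) + v
        rows.append(row)
        class_of.append(key_to_K[lr["key"]])
    extra = [
        c for c in _DECLARED_TRANSFER_CONDITIONS
        if all(k in present_K for k in c)
    ]
    basis = wegscheider_basis(rows, class_of, n_species, extra)
    # transfer classes absent from core rows and declared conditions are free
    missing = [k for k in present_K if k not in basis.independent and k not in basis.dependent]
    return DetailedBalanceBasis(
        tuple(sorted([*basis.independent, *missing])),
        basis.dependent,
        basis.dependency,
        basis.conditions,
    )


def detailed_balance_basis(network: ReactionNetwork) -> DetailedBalanceBasis:
    """Independent/dependent split of the network's equilibrium constants.

    For the ``all_forms`` network: 63 distinct constants, 31 independent,
    32 expressed through them.
    """
    if not network.is_connected():
        raise ValueError("reaction network is disconnected")
    if network._basis_cache is None:
        network._basis_cache = _basis_for_variant(network.variant.label)
    return network._basis_cache


def resolve_parameters(
    network: ReactionNetwork, independent_values: Mapping[str, float]
) -> dict[str, float]:
    """Full per-site equilibrium-constant assignment from independent values.

    Dependent constants are signed products of independent ones so that every
    declared reaction-cycle product equals one.  Apparent (merged-state)
    constants follow as ``sigma * K_site`` per reaction; e.g. PEP dissociation
    from the dimer with two bound PEP has apparent constant 2 * per-site value.
    """
    basis = detailed_balance_basis(network)
    full: dict[str, float] = {}
    for kid in basis.independent:
        if kid not in independent_values:
            raise ValueError(f"missing independent constant {kid}")
        v = float(independent_values[kid])
        if not v > 0:
            raise ValueError(f"non-positive value for {kid}")
        full[kid] = v
    import math

    for kid in basis.dependent:
        ln = 0.0
        for dep_id, expo in basis.dependency[kid]:
            ln += float(expo) * math.log(full[dep_id])
        full[kid] = math.exp(ln)
    return full


def apparent_constants(
    network: ReactionNetwork, site_values: Mapping[str, float]
) -> dict[int, float]:
    """Apparent equilibrium constant per reaction index (statistical factors
    applied to the shared per-site values)."""
    return {
        j: float(r.sigma) * site_values[r.K_id]
        for j, r in enumerate(network.reactions)
    }


def export_sharing_map(network: ReactionNetwork) -> dict:
    """Auditable sharing map: reaction -> K/k/Ea/pH identifiers plus the
    declared transfer ratio conditions."""
    return {
        "variant": network.variant.label,
        "K_of_reaction": {
            f"{r.kind}:{'+'.join(s.label for s in r.reactants)}>"
            f"{'+'.join(s.label for s in r.products)}": r.K_id
            for r in network.reactions
        },
        "k_of_reaction": {
            f"{r.kind}:{'+'.join(s.label for s in r.reactants)}>"
            f"{'+'.join(s.label for s in r.products)}": r.k_id
            for r in network.reactions
            if r.k_id
        },
        "Ea_classes": {r.k_id: ea_class_of(r) for r in network.reactions if r.k_id},
        "pH_sites": {
            pid: ph_site_of(pid)
            for pid in [*network.K_ids, *network.k_ids]
            if ph_site_of(pid)
        },
        "declared_transfer_conditions": _DECLARED_TRANSFER_CONDITIONS,
    }
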
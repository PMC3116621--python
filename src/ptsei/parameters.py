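"""Reference-condition parameter sets for the EI catalytic-cycle model.

A :class:`ParameterSet` carries the 31 independent per-site equilibrium
constants (mM for dissociation constants, dimensionless for phosphorylation
and HPr transfer), the 46 rate constants, the first-order HPrP hydrolysis
constant k9, and the thermal/pH metadata, all at the reference condition
(default T0 = 298.15 K).  Dependent equilibrium constants are resolved on
demand through the detailed-balance identities of the network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .cycle_network import ReactionNetwork, build_network, ea_class_of, ph_site_of
from .environment import ThermalMeta

# HPrP decays to 15% of its initial value in 30 minutes: k9 = ln(1/0.15)/1800 s
K9_DEFAULT = math.log(1.0 / 0.15) / 1800.0

__all__ = ["ParameterSet", "K9_DEFAULT"]


@dataclass
class ParameterSet:
    """Constants of the model at the reference condition, plus metadata."""

    variant: str
    K_independent: dict[str, float]
    k: dict[str, float]
    thermal: ThermalMeta = field(default_factory=ThermalMeta)
    k9: float = K9_DEFAULT
    T0: float = 298.15
    pH0: float = 7.0
    fixed_zero: set[str] = field(default_factory=set)
    _network: ReactionNetwork | None = field(default=None, repr=False, compare=False)
    _site_K: dict[str, float] | None = field(default=None, repr=False, compare=False)
    _models: dict = field(default_factory=dict, repr=False, compare=False)

    def network(self) -> ReactionNetwork:
        if self._network is None:
            self._network = build_network(self.variant)
        return self._network

    def site_K(self) -> dict[str, float]:
        """Full per-site equilibrium-constant map (dependent ones resolved)."""
        if self._site_K is None:
            self._site_K = self.network().resolve_parameters(self.K_independent)
        return self._site_K

    def rate(self, k_id: str) -> float:
        return 0.0 if k_id in self.fixed_zero else self.k[k_id]

    def updated(self, K: dict[str, float] | None = None,
                k: dict[str, float] | None = None, **kw) -> "ParameterSet":
        """Copy with some constants replaced (caches invalidated)."""
        new = replace(
            self,
            K_independent={**self.K_independent, **(K or {})},
            k={**self.k, **(k or {})},
            fixed_zero=set(self.fixed_zero),
            _network=self._network,
            _site_K=None,
            _models={},
            **kw,
        )
        return new

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Parameter table with columns (param_id, class, value_at_reference,
        dH, Ea, pKa_link, statistical_factor, fixed_to_zero)."""
        net = self.network()
        site_K = self.site_K()
        factor: dict[str, int] = {}
        ea_of_k: dict[str, str] = {}
        for r in net.reactions:
            factor.setdefault(r.K_id, r.statistical_factor)
            if r.k_id:
                ea_of_k[r.k_id] = ea_class_of(r)
        rows = []
        dep = set(net.detailed_balance_basis().dependent)
        for kid in net.K_ids:
            rows.append(dict(
                param_id=kid,
                **{"class": "K_dependent" if kid in dep else "K_independent"},
                value_at_reference=site_K[kid],
                dH=self.thermal.dH.get(kid, 0.0),
                Ea=0.0,
                pKa_link=ph_site_of(kid) or "",
                statistical_factor=factor.get(kid, 1),
                fixed_to_zero=False,
            ))
        for kid in net.k_ids:
            rows.append(dict(
                param_id=kid,
                **{"class": "rate"},
                value_at_reference=self.k.get(kid, 0.0),
                dH=0.0,
                Ea=self.thermal.Ea.get(ea_of_k.get(kid, ""), 0.0),
                pKa_link=ph_site_of(kid) or "",
                statistical_factor=1,
                fixed_to_zero=kid in self.fixed_zero,
            ))
        rows.append(dict(param_id="k9", **{"class": "hydrolysis"},
                         value_at_reference=self.k9, dH=0.0, Ea=0.0,
                         pKa_link="", statistical_factor=1, fixed_to_zero=False))
        for site, (p1, p2) in sorted(self.thermal.pKa.items()):
            rows.append(dict(param_id=f"{site}:pKa1", **{"class": "pKa"},
                             value_at_reference=p1, dH=0.0, Ea=0.0,
                             pKa_link=site, statistical_factor=1,
                             fixed_to_zero=False))
            rows.append(dict(param_id=f"{site}:pKa2", **{"class": "pKa"},
                             value_at_reference=p2, dH=0.0, Ea=0.0,
                             pKa_link=site, statistical_factor=1,
                             fixed_to_zero=False))
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, variant: str = "all_forms",
                 T0: float = 298.15, pH0: float = 7.0) -> "ParameterSet":
        df = pd.read_csv(path)
        net = build_network(variant)
        indep = set(net.detailed_balance_basis().independent)
        ea_of_k = {r.k_id: ea_class_of(r) for r in net.reactions if r.k_id}
        K_ind, k, dH, Ea, pKa1, pKa2, zero = {}, {}, {}, {}, {}, {}, set()
        k9 = K9_DEFAULT
        for _, row in df.iterrows():
            pid, klass, v = row["param_id"], row["class"], float(row["value_at_reference"])
            if klass == "K_independent" or (klass.startswith("K") and pid in indep):
                K_ind[pid] = v
                if float(row.get("dH", 0.0)):
                    dH[pid] = float(row["dH"])
            elif klass == "rate":
                k[pid] = v
                if bool(row.get("fixed_to_zero", False)):
                    zero.add(pid)
                if float(row.get("Ea", 0.0)):
                    Ea[ea_of_k.get(pid, pid)] = float(row["Ea"])
            elif klass == "hydrolysis":
                k9 = v
            elif klass == "pKa":
                site = row["pKa_link"]
                (pKa1 if pid.endswith("pKa1") else pKa2)[site] = v
        pka = {s: (pKa1[s], pKa2[s]) for s in pKa1 if s in pKa2}
        return cls(variant=variant, K_independent=K_ind, k=k,
                   thermal=ThermalMeta(dH=dH, Ea=Ea, pKa=pka),
                   k9=k9, T0=T0, pH0=pH0, fixed_zero=zero)
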
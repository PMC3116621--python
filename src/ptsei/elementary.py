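"""Full elementary mass-action system over all 27 EI micro-states.

This is the unreduced counterpart of the five-pool model: every micro-state
is an explicit dynamical species and ligand binding is given finite kinetics
(association rate ``binding_rate``, dissociation rate fixed by the apparent
equilibrium constant).  When the binding rates are taken much faster than
the slowest dimerization/phosphorylation step, the pooled trajectories of
this system converge to the reduced model after a short boundary layer —
which is exactly the rapid-equilibrium assumption, and is how the reduction
is validated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .cycle_network import ReactionNetwork, build_network
from .environment import EffectiveParams
from .reduced_model import POOLS

__all__ = ["ElementarySystem"]

_SMALL = ("PEP", "Pyr", "HPr", "HPrP", "Pi")


class ElementarySystem:
    """Mass-action ODEs on micro-states + (PEP, Pyr, HPr, HPrP, Pi)."""

    def __init__(
        self,
        eff: EffectiveParams,
        network: ReactionNetwork | None = None,
        binding_rate: float = 1e4,
    ):
        self.eff = eff
        self.network = network if network is not None else build_network(eff.variant)
        self.binding_rate = binding_rate
        net = self.network
        states = sorted(net.states, key=lambda s: (POOLS.index(s.pool), s.label))
        self.states = states
        self.species = [s.label for s in states] + list(_SMALL)
        idx = {s: i for i, s in enumerate(states)}
        ns = len(states)
        self.i_small = {n: ns + i for i, n in enumerate(_SMALL)}

        rows = []
        n_rxn = len(net.reactions) + 1  # + hydrolysis
        S = np.zeros((len(self.species), n_rxn))
        self._kf = np.zeros(n_rxn)
        self._kr = np.zeros(n_rxn)
        self._fidx: list[list[int]] = []
        self._bidx: list[list[int]] = []
        for j, r in enumerate(net.reactions):
            mu_r = float(np.prod([s.multiplicity for s in r.reactants]))
            mu_p = float(np.prod([s.multiplicity for s in r.products]))
            K_app = float(r.sigma) * eff.K_site[r.K_id]
            fwd = [idx[s] for s in r.reactants]
            back = [idx[s] for s in r.products]
            for name, v in r.small_deltas.items():
                if v > 0:
                    back.extend([self.i_small[name]] * v)
                else:
                    fwd.extend([self.i_small[name]] * (-v))
            if r.kind == "ligand_binding":
                # forward = dissociation, rate binding_rate * K_app * [bound]
                self._kf[j] = self.binding_rate * K_app
                self._kr[j] = self.binding_rate
            else:
                kf = eff.k[r.k_id] * r.n_channels / mu_r
                self._kf[j] = kf
                self._kr[j] = eff.k[r.k_id] / K_app * float(r.sigma) * r.n_channels / mu_p
            for i in [idx[s] for s in r.reactants]:
                S[i, j] -= 1
            for i in [idx[s] for s in r.products]:
                S[i, j] += 1
            for name, v in r.small_deltas.items():
                S[self.i_small[name], j] += v
            self._fidx.append(fwd)
            self._bidx.append(back)
        # hydrolysis HPrP -> HPr + Pi
        j = n_rxn - 1
        self._kf[j] = eff.k9
        self._kr[j] = 0.0
        self._fidx.append([self.i_small["HPrP"]])
        self._bidx.append([])
        S[self.i_small["HPrP"], j] -= 1
        S[self.i_small["HPr"], j] += 1
        S[self.i_small["Pi"], j] += 1
        self.S = S

    def rates(self, y: np.ndarray) -> np.ndarray:
        v = np.empty(len(self._kf))
        for j in range(len(self._kf)):
            f = self._kf[j]
            for i in self._fidx[j]:
                f *= y[i]
            b = self._kr[j]
            for i in self._bidx[j]:
                b *= y[i]
            v[j] = f - b
        return v

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.S @ self.rates(np.maximum(y, 0.0))

    def initial(
        self, pool_totals: dict[str, float], PEP: float = 0.0, Pyr: float = 0.0,
        HPr: float = 0.0, HPrP: float = 0.0,
    ) -> np.ndarray:
        """All pool mass starts in the ligand-free root state of each pool;
        the fast binding step redistributes it within the boundary layer."""
        y = np.zeros(len(self.species))
        for i, s in enumerate(self.states):
            if s.ligand_count("PEP") == 0 and s.ligand_count("Pyr") == 0:
                y[i] = pool_totals.get(s.pool, 0.0)
        y[self.i_small["PEP"]] = PEP
        y[self.i_small["Pyr"]] = Pyr
        y[self.i_small["HPr"]] = HPr
        y[self.i_small["HPrP"]] = HPrP
        return y

    def pools_of(self, y: np.ndarray) -> dict[str, np.ndarray]:
        out = {p: 0.0 for p in POOLS}
        y = np.asarray(y)
        for i, s in enumerate(self.states):
            out[s.pool] = out[s.pool] + y[..., i]
        for n in _SMALL:
            out[n] = y[..., self.i_small[n]]
        return out

    def simulate(self, y0: np.ndarray, t_eval: np.ndarray, rtol=1e-8, atol=1e-14):
        sol = solve_ivp(
            self.rhs, (0.0, float(t_eval[-1])), y0, t_eval=t_eval,
            method="LSODA", rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"elementary integration failed: {sol.message}")
        return sol
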
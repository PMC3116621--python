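"""Quasi-equilibrium reduction of the EI catalytic cycle to five pools.

PEP/Pyr binding is much faster than dimerization, phosphorylation and
phosphotransfer, so within each pool (Y, Z, ZP, ZP2, YP) the micro-states
follow their binding equilibrium at the current *free* PEP and Pyr
concentrations.  The slow dynamics then close on the pool totals:

    dY/dt    = -2 V1 + V5 + V6          dZ/dt   = V1 - V2 + V8
    dZP/dt   = V2 - V3 - V8 + V7 - V6   dYP/dt  = 2 V4 - V5 + V6
    dHPrP/dt = V5 + V7 + V8 - V9        dPi/dt  = V9

with ZP2 closed by the EI conservation law
Y + 2 Z + 2 ZP + 2 ZP2 + YP = EItotal, free PEP and Pyr closed by the
phosphoryl and three-carbon-backbone conservation laws (the enzyme-bound
ligand is subtracted), and HPr + HPrP = HPrtotal.  V9 = k9 * HPrP is the
first-order hydrolysis of phosphorylated HPr.

Model II clamps free PEP, Pyr and HPr and fixes HPrP = Pi = 0, keeping the
four enzyme-pool equations only.

Dimer pools are counted in dimer units; monomer-equivalent bookkeeping enters
only through the conservation laws (factor 2 on Z, ZP, ZP2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .cycle_network import EnzymeState, ReactionNetwork, build_network
from .environment import EffectiveParams, Environment, apply_environment

try:  # JIT-compiled inner loops; plain numpy remains the fallback
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f
        return deco


@_njit(cache=False)
def _rates_kernel(pools5, PEP, Pyr, HPr, HPrP, base_w, nE, nY, pool_of,
                  rk, rKinv, rffwd, rfrev, Ridx, Rcnt, Pidx, Pcnt,
                  rhpr, rlump, rsign, k9):
    n = base_w.size
    w = np.empty(n)
    sums = np.zeros(5)
    for i in range(n):
        wi = base_w[i] * PEP ** nE[i] * Pyr ** nY[i]
        w[i] = wi
        sums[pool_of[i]] += wi
    conc = np.empty(n)
    for i in range(n):
        conc[i] = pools5[pool_of[i]] * w[i] / sums[pool_of[i]]
    V = np.zeros(9)
    for j in range(rk.size):
        cr = conc[Ridx[j, 0]]
        if Rcnt[j] == 2:
            cr *= conc[Ridx[j, 1]]
        cp = conc[Pidx[j, 0]]
        if Pcnt[j] == 2:
            cp *= conc[Pidx[j, 1]]
        fwd = rffwd[j] * cr
        rev = rKinv[j] * rfrev[j] * cp
        if rhpr[j]:
            fwd *= HPr
            rev *= HPrP
        V[rlump[j]] += rsign[j] * rk[j] * (fwd - rev)
    V[8] = k9 * HPrP
    return V


@_njit(cache=False)
def _ligand_newton_kernel(T, availE, availY, p0, q0, base_w, nE, nY, pool_of):
    """Damped Newton for the free-ligand balance; returns (p, q, converged)."""
    n = base_w.size
    tolE = 1e-11 * availE + 1e-18
    tolY = 1e-11 * availY + 1e-18
    p, q = p0, q0
    for _ in range(60):
        W = np.zeros(5)
        SE = np.zeros(5)
        SY = np.zeros(5)
        SEE = np.zeros(5)
        SYY = np.zeros(5)
        SEY = np.zeros(5)
        for i in range(n):
            wi = base_w[i] * p ** nE[i] * q ** nY[i]
            ip = pool_of[i]
            W[ip] += wi
            SE[ip] += nE[i] * wi
            SY[ip] += nY[i] * wi
            SEE[ip] += nE[i] * nE[i] * wi
            SYY[ip] += nY[i] * nY[i] * wi
            SEY[ip] += nE[i] * nY[i] * wi
        F1 = p - availE
        F2 = q - availY
        J11 = 1.0
        J22 = 1.0
        J12 = 0.0
        J21 = 0.0
        for ip in range(5):
            if T[ip] == 0.0:
                continue
            mE = SE[ip] / W[ip]
            mY = SY[ip] / W[ip]
            F1 += T[ip] * mE
            F2 += T[ip] * mY
            vEE = SEE[ip] / W[ip] - mE * mE
            vYY = SYY[ip] / W[ip] - mY * mY
            vEY = SEY[ip] / W[ip] - mE * mY
            if p > 0.0:
                J11 += T[ip] * vEE / p
                J21 += T[ip] * vEY / p
            if q > 0.0:
                J12 += T[ip] * vEY / q
                J22 += T[ip] * vYY / q
        if abs(F1) < tolE and abs(F2) < tolY:
            return p, q, True
        det = J11 * J22 - J12 * J21
        if det == 0.0:
            return p, q, False
        dp = (F1 * J22 - F2 * J12) / det
        dq = (F2 * J11 - F1 * J21) / det
        pn = p - dp
        qn = q - dq
        if availE > 0.0:
            if pn < p * 0.1:
                pn = p * 0.1
            if pn > availE:
                pn = availE
        else:
            pn = 0.0
        if availY > 0.0:
            if qn < q * 0.1:
                qn = q * 0.1
            if qn > availY:
                qn = availY
        else:
            qn = 0.0
        p, q = pn, qn
    return p, q, False

POOLS = ("Y", "Z", "ZP", "ZP2", "YP")
_LUMP_OF = {
    ("dimerization", "Z"): (0, -1.0),   # V1 positive = association
    ("phosphorylation", "Z"): (1, 1.0),  # V2
    ("phosphorylation", "ZP"): (2, 1.0),  # V3
    ("dimerization", "ZP2"): (3, 1.0),  # V4 positive = dissociation
    ("hpr_transfer", "YP"): (4, 1.0),   # V5
    ("dimerization", "ZP"): (5, 1.0),   # V6 positive = dissociation
    ("hpr_transfer", "ZP2"): (6, 1.0),  # V7
    ("hpr_transfer", "ZP"): (7, 1.0),   # V8
}

__all__ = [
    "POOLS",
    "LumpedState",
    "ConservedTotals",
    "PoolPartition",
    "ReducedModel",
    "partition_pools",
    "microstate_concentrations",
    "lumped_rates",
    "rhs_model1",
    "rhs_model2",
]


@dataclass
class LumpedState:
    """Pool totals (dimers in dimer units) and solution species, all in mM.
    PEP and Pyr are *free* concentrations."""

    Y: float = 0.0
    Z: float = 0.0
    ZP: float = 0.0
    ZP2: float = 0.0
    YP: float = 0.0
    PEP: float = 0.0
    Pyr: float = 0.0
    HPr: float = 0.0
    HPrP: float = 0.0
    Pi: float = 0.0

    @property
    def EI_monomer_equivalents(self) -> float:
        return self.Y + 2 * self.Z + 2 * self.ZP + 2 * self.ZP2 + self.YP

    @property
    def phospho_EI(self) -> float:
        """Phosphorylated EI subunits (monomer equivalents)."""
        return self.ZP + 2 * self.ZP2 + self.YP

    @property
    def PTSP(self) -> float:
        """Total phosphorylated PTS protein (EI subunits + HPrP)."""
        return self.phospho_EI + self.HPrP

    def pools(self) -> np.ndarray:
        return np.array([self.Y, self.Z, self.ZP, self.ZP2, self.YP])


@dataclass
class ConservedTotals:
    """Conserved totals fixing the algebraic closures of Model I."""

    EItotal: float  # monomer equivalents, mM
    HPrtotal: float = 0.0
    PEP0: float = 0.0
    Pyr0: float = 0.0
    PTSP0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("EItotal", "HPrtotal", "PEP0", "Pyr0", "PTSP0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class PoolPartition:
    """Rapid-equilibrium distribution of micro-states within each pool."""

    PEP: float
    Pyr: float
    fractions: dict[str, dict[EnzymeState, float]]

    def fraction(self, state: EnzymeState) -> float:
        return self.fractions[state.pool][state]


class ReducedModel:
    """Compiled reduced model bound to one effective parameter set.

    Precomputes, per micro-state, the quasi-equilibrium weight
    ``w = c * PEP**nE * Pyr**nY`` (c collects the binding constants and
    statistical factors along a spanning path from the ligand-free root of
    the pool), and per slow reaction the apparent forward/reverse rate
    factors, so that one right-hand-side evaluation is a handful of
    vectorized array operations.
    """

    def __init__(self, eff: EffectiveParams, network: ReactionNetwork | None = None):
        self.eff = eff
        self.network = network if network is not None else build_network(eff.variant)
        self._compile()
        self._ligand_guess: tuple[float, float] | None = None

    # -- compilation --------------------------------------------------------

    def _compile(self) -> None:
        net, eff = self.network, self.eff
        states = sorted(net.states, key=lambda s: (POOLS.index(s.pool), s.label))
        self.states = states
        self.state_index = {s: i for i, s in enumerate(states)}
        self.pool_slices: dict[str, slice] = {}
        i0 = 0
        for p in POOLS:
            n = sum(1 for s in states if s.pool == p)
            self.pool_slices[p] = slice(i0, i0 + n)
            i0 += n
        n_states = len(states)
        self.nE = np.array([s.ligand_count("PEP") for s in states], float)
        self.nY = np.array([s.ligand_count("Pyr") for s in states], float)
        self._nE2 = self.nE ** 2
        self._nY2 = self.nY ** 2
        self._nEY = self.nE * self.nY
        self._pool_starts = np.array([self.pool_slices[p].start for p in POOLS])
        self._pool_of = np.concatenate([
            np.full(self.pool_slices[p].stop - self.pool_slices[p].start, ip)
            for ip, p in enumerate(POOLS)
        ])

        # spanning-path weights from each pool's ligand-free root
        lnc = np.full(n_states, np.nan)
        adj: dict[EnzymeState, list[tuple[EnzymeState, float]]] = {
            s: [] for s in states
        }
        for r in net.reactions:
            if r.kind != "ligand_binding":
                continue
            bound, free = r.reactants[0], r.products[0]
            K_app = float(r.sigma) * eff.K_site[r.K_id]
            # w(bound) = w(free) * [L] / K_app ; ligand powers tracked via nE/nY
            adj[free].append((bound, -math.log(K_app)))
            adj[bound].append((free, +math.log(K_app)))
        for p in POOLS:
            root = next(
                s for s in states
                if s.pool == p and s.ligand_count("PEP") == 0 and s.ligand_count("Pyr") == 0
            )
            lnc[self.state_index[root]] = 0.0
            todo = [root]
            while todo:
                s = todo.pop()
                for t, dln in adj[s]:
                    j = self.state_index[t]
                    if np.isnan(lnc[j]):
                        lnc[j] = lnc[self.state_index[s]] + dln
                        todo.append(t)
        assert not np.isnan(lnc).any(), "binding subnetwork does not span a pool"
        self.base_w = np.exp(lnc)

        # slow-reaction table
        rows = []
        for r in net.reactions:
            if r.k_id is None:
                continue
            lump, sign = _LUMP_OF[(r.kind, r.reactants[0].pool)]
            mu_r = float(np.prod([s.multiplicity for s in r.reactants]))
            mu_p = float(np.prod([s.multiplicity for s in r.products]))
            rows.append(dict(
                k=eff.k[r.k_id],
                K=eff.K_site[r.K_id],
                f_fwd=r.n_channels / mu_r,
                f_rev=r.n_channels / mu_p,
                ridx=[self.state_index[s] for s in r.reactants],
                pidx=[self.state_index[s] for s in r.products],
                hpr=r.kind == "hpr_transfer",
                lump=lump,
                sign=sign,
            ))
        self.rxn = rows
        self._rk = np.array([r["k"] for r in rows])
        self._rKinv = np.array([1.0 / r["K"] for r in rows])
        self._rffwd = np.array([r["f_fwd"] for r in rows])
        self._rfrev = np.array([r["f_rev"] for r in rows])
        self._rlump = np.array([r["lump"] for r in rows])
        self._rsign = np.array([r["sign"] for r in rows])
        self._rhpr = np.array([r["hpr"] for r in rows])
        nr = len(rows)
        self._Ridx = np.zeros((nr, 2), int)
        self._Rcnt = np.zeros(nr, int)
        self._Pidx = np.zeros((nr, 2), int)
        self._Pcnt = np.zeros(nr, int)
        for j, r in enumerate(rows):
            self._Rcnt[j] = len(r["ridx"])
            self._Ridx[j, : len(r["ridx"])] = r["ridx"]
            self._Pcnt[j] = len(r["pidx"])
            self._Pidx[j, : len(r["pidx"])] = r["pidx"]
        self._rhpr_b = np.ascontiguousarray(self._rhpr, dtype=np.bool_)
        self._rlump_i = np.ascontiguousarray(self._rlump, dtype=np.int64)
        self._pool_of_i = np.ascontiguousarray(self._pool_of, dtype=np.int64)

    # -- quasi-equilibrium weights ------------------------------------------

    def weights(self, PEP: float, Pyr: float) -> np.ndarray:
        if not (np.isfinite(PEP) and np.isfinite(Pyr)) or PEP < 0 or Pyr < 0:
            raise ValueError("free ligand concentrations must be finite and >= 0")
        return self.base_w * PEP ** self.nE * Pyr ** self.nY

    def fractions(self, PEP: float, Pyr: float) -> np.ndarray:
        w = self.weights(PEP, Pyr)
        sums = np.add.reduceat(w, self._pool_starts)
        return w / sums[self._pool_of]

    def mean_bound(self, frac: np.ndarray, pool_totals: np.ndarray) -> tuple[float, float]:
        """Enzyme-bound PEP and Pyr (mM), dimers contributing per bound ligand."""
        bE = np.add.reduceat(self.nE * frac, self._pool_starts) @ pool_totals
        bY = np.add.reduceat(self.nY * frac, self._pool_starts) @ pool_totals
        return float(bE), float(bY)

    # -- free-ligand closure -------------------------------------------------

    def free_ligands(
        self, pool_totals: np.ndarray, availE: float, availY: float
    ) -> tuple[float, float]:
        """Solve free PEP and Pyr from total = free + enzyme-bound.

        Damped Newton with analytic covariance Jacobian, bracketed-bisection
        fallback; tolerance 1e-12 mM (relative to the available totals).
        """
        availE = max(availE, 0.0)
        availY = max(availY, 0.0)
        if availE == 0.0 and availY == 0.0:
            return 0.0, 0.0
        tolE = 1e-11 * availE + 1e-18
        tolY = 1e-11 * availY + 1e-18
        g = self._ligand_guess
        p = min(g[0], availE) if g else availE * 0.5
        q = min(g[1], availY) if g else availY * 0.5
        if availE > 0 and p <= 0:
            p = availE * 0.5
        if availY > 0 and q <= 0:
            q = availY * 0.5
        if availE == 0.0:
            p = 0.0
        if availY == 0.0:
            q = 0.0
        if _HAVE_NUMBA:
            pk, qk, ok = _ligand_newton_kernel(
                np.asarray(pool_totals, float), availE, availY, p, q,
                self.base_w, self.nE, self.nY, self._pool_of_i)
            if ok:
                self._ligand_guess = (pk, qk)
                return pk, qk
        T = pool_totals
        st = self._pool_starts
        for _ in range(60):
            w = self.weights(p, q)
            W = np.add.reduceat(w, st)
            mE = np.add.reduceat(self.nE * w, st) / W
            mY = np.add.reduceat(self.nY * w, st) / W
            F1 = p - availE + float(mE @ T)
            F2 = q - availY + float(mY @ T)
            vEE = np.add.reduceat(self._nE2 * w, st) / W - mE * mE
            vYY = np.add.reduceat(self._nY2 * w, st) / W - mY * mY
            vEY = np.add.reduceat(self._nEY * w, st) / W - mE * mY
            J11 = J22 = 1.0
            J12 = J21 = 0.0
            if p > 0:
                J11 += float(vEE @ T) / p
                J21 += float(vEY @ T) / p
            if q > 0:
                J12 += float(vEY @ T) / q
                J22 += float(vYY @ T) / q
            if abs(F1) < tolE and abs(F2) < tolY:
                self._ligand_guess = (p, q)
                return p, q
            det = J11 * J22 - J12 * J21
            if det == 0:
                break
            dp = (F1 * J22 - F2 * J12) / det
            dq = (F2 * J11 - F1 * J21) / det
            pn, qn = p - dp, q - dq
            if availE > 0:
                pn = min(max(pn, p * 0.1), availE)
            else:
                pn = 0.0
            if availY > 0:
                qn = min(max(qn, q * 0.1), availY)
            else:
                qn = 0.0
            p, q = pn, qn
        # fallback: nested bracketed root finding
        def inner(pp: float) -> float:
            if availY == 0.0:
                return 0.0
            def h(qq: float) -> float:
                w = self.weights(pp, qq)
                b = 0.0
                for ip, pool in enumerate(POOLS):
                    if T[ip] == 0.0:
                        continue
                    sl = self.pool_slices[pool]
                    ws = w[sl]
                    b += T[ip] * float(self.nY[sl] @ ws) / ws.sum()
                return qq + b - availY
            if h(availY) <= 0:
                return availY
            return brentq(h, 0.0, availY, xtol=1e-15, rtol=8.9e-16)

        def outer(pp: float) -> float:
            qq = inner(pp)
            w = self.weights(pp, qq)
            b = 0.0
            for ip, pool in enumerate(POOLS):
                if T[ip] == 0.0:
                    continue
                sl = self.pool_slices[pool]
                ws = w[sl]
                b += T[ip] * float(self.nE[sl] @ ws) / ws.sum()
            return pp + b - availE

        if availE == 0.0:
            p, q = 0.0, inner(0.0)
        elif outer(availE) <= 0:
            p, q = availE, inner(availE)
        else:
            p = brentq(outer, 0.0, availE, xtol=1e-15, rtol=8.9e-16)
            q = inner(p)
        self._ligand_guess = (p, q)
        return p, q

    # -- lumped rates --------------------------------------------------------

    def rates(
        self, pool_totals: np.ndarray, PEP: float, Pyr: float,
        HPr: float, HPrP: float,
    ) -> np.ndarray:
        """Net lumped rates V1..V9 (mM/s) at the quasi-equilibrium partition."""
        if not (np.isfinite(PEP) and np.isfinite(Pyr)) or PEP < 0 or Pyr < 0:
            raise ValueError("free ligand concentrations must be finite and >= 0")
        if _HAVE_NUMBA:
            return _rates_kernel(
                np.asarray(pool_totals, float), float(PEP), float(Pyr),
                float(HPr), float(HPrP), self.base_w, self.nE, self.nY,
                self._pool_of_i, self._rk, self._rKinv, self._rffwd,
                self._rfrev, self._Ridx, self._Rcnt, self._Pidx, self._Pcnt,
                self._rhpr_b, self._rlump_i, self._rsign, self.eff.k9)
        frac = self.fractions(PEP, Pyr)
        conc = np.empty_like(frac)
        for ip, p in enumerate(POOLS):
            sl = self.pool_slices[p]
            conc[sl] = pool_totals[ip] * frac[sl]
        cr = conc[self._Ridx[:, 0]]
        two = self._Rcnt == 2
        cr[two] = cr[two] * conc[self._Ridx[two, 1]]
        cp = conc[self._Pidx[:, 0]]
        two = self._Pcnt == 2
        cp[two] = cp[two] * conc[self._Pidx[two, 1]]
        fwd = self._rffwd * cr
        rev = self._rKinv * self._rfrev * cp
        fwd[self._rhpr] *= HPr
        rev[self._rhpr] *= HPrP
        net = self._rk * (fwd - rev)
        V = np.zeros(9)
        np.add.at(V, self._rlump, self._rsign * net)
        V[8] = self.eff.k9 * HPrP
        return V

    def transfer_decomposition(
        self, pool_totals: np.ndarray, PEP: float, Pyr: float,
        HPr: float, HPrP: float,
    ) -> dict[str, float]:
        V = self.rates(pool_totals, PEP, Pyr, HPr, HPrP)
        return {
            "monomer": V[4], "ZP": V[7], "ZP2": V[6],
            "total": V[4] + V[6] + V[7],
        }

    # -- right-hand sides ----------------------------------------------------

    def closures_model1(
        self, y: np.ndarray, totals: ConservedTotals
    ) -> tuple[np.ndarray, float, float, float, float]:
        """Given y = (Y, Z, ZP, YP, HPrP, Pi), return pool totals and the
        algebraically closed ZP2, free PEP, free Pyr, HPr."""
        Y, Z, ZP, YP, HPrP, Pi = y
        ZP2 = 0.5 * (totals.EItotal - Y - 2 * Z - 2 * ZP - YP)
        scale = max(totals.EItotal, totals.HPrtotal, 1e-30)
        if ZP2 < -1e-3 * scale:
            raise ValueError(f"negative ZP2 closure: {ZP2}")
        ZP2 = max(ZP2, 0.0)
        HPrP = min(max(HPrP, 0.0), totals.HPrtotal)
        HPr = totals.HPrtotal - HPrP
        if totals.HPrtotal - y[4] < -1e-3 * scale:
            raise ValueError(f"negative HPr closure: {totals.HPrtotal - y[4]}")
        pools = np.array([max(Y, 0.0), max(Z, 0.0), max(ZP, 0.0), ZP2, max(YP, 0.0)])
        PTSP = ZP + 2 * ZP2 + YP + HPrP
        availE = totals.PEP0 + totals.PTSP0 - PTSP - Pi
        # each hydrolysis event removes a phosphoryl from PTSP without
        # consuming a pyruvate backbone, hence the +Pi term
        availY = totals.Pyr0 + PTSP - totals.PTSP0 + Pi
        PEP, Pyr = self.free_ligands(pools, availE, availY)
        return pools, ZP2, PEP, Pyr, HPr

    def rhs1(self, y: np.ndarray, totals: ConservedTotals) -> np.ndarray:
        pools, _, PEP, Pyr, HPr = self.closures_model1(y, totals)
        V = self.rates(pools, PEP, Pyr, HPr, totals.HPrtotal - HPr)
        V1, V2, V3, V4, V5, V6, V7, V8, V9 = V
        return np.array([
            -2 * V1 + V5 + V6,
            V1 - V2 + V8,
            V2 - V3 - V8 + V7 - V6,
            2 * V4 - V5 + V6,
            V5 + V7 + V8 - V9,
            V9,
        ])

    def rhs2(
        self, y: np.ndarray, EItotal: float, PEP: float, Pyr: float, HPr: float
    ) -> np.ndarray:
        """Model II: y = (Y, Z, ZP, YP); PEP/Pyr/HPr clamped, HPrP = Pi = 0."""
        Y, Z, ZP, YP = y
        ZP2 = 0.5 * (EItotal - Y - 2 * Z - 2 * ZP - YP)
        if ZP2 < -1e-3 * max(EItotal, 1e-30):
            raise ValueError(f"negative ZP2 closure: {ZP2}")
        pools = np.array([max(Y, 0.0), max(Z, 0.0), max(ZP, 0.0), max(ZP2, 0.0), max(YP, 0.0)])
        V = self.rates(pools, PEP, Pyr, HPr, 0.0)
        V1, V2, V3, V4, V5, V6, V7, V8, _ = V
        return np.array([
            -2 * V1 + V5 + V6,
            V1 - V2 + V8,
            V2 - V3 - V8 + V7 - V6,
            2 * V4 - V5 + V6,
        ])

    def partition(self, PEP: float, Pyr: float) -> PoolPartition:
        f = self.fractions(PEP, Pyr)
        out: dict[str, dict[EnzymeState, float]] = {}
        for p in POOLS:
            sl = self.pool_slices[p]
            out[p] = {s: float(f[self.state_index[s]]) for s in self.states[sl]}
        return PoolPartition(PEP=PEP, Pyr=Pyr, fractions=out)


# ---------------------------------------------------------------------------
# Functional interface

def _as_model(params, env: Environment | None) -> ReducedModel:
    if isinstance(params, ReducedModel):
        return params
    if isinstance(params, EffectiveParams):
        return ReducedModel(params)
    if env is None:
        env = Environment(T=params.T0, pH=params.pH0)
    return ReducedModel(apply_environment(params, env))


def partition_pools(params, PEP: float, Pyr: float, env: Environment | None = None) -> PoolPartition:
    """Within-pool rapid-equilibrium fractions at free PEP and Pyr (mM)."""
    return _as_model(params, env).partition(PEP, Pyr)


def microstate_concentrations(
    state: LumpedState, partition: PoolPartition
) -> dict[str, float]:
    """Micro-state concentrations (mM) plus the bound-ligand aggregates
    EIoPEP and EIoPyr (dimers contribute per bound ligand)."""
    totals = dict(zip(POOLS, state.pools()))
    out: dict[str, float] = {}
    EIoPEP = EIoPyr = 0.0
    for pool, fr in partition.fractions.items():
        for s, f in fr.items():
            c = totals[pool] * f
            out[s.label] = c
            EIoPEP += c * s.ligand_count("PEP")
            EIoPyr += c * s.ligand_count("Pyr")
    out["EIoPEP"] = EIoPEP
    out["EIoPyr"] = EIoPyr
    return out


def lumped_rates(
    state: LumpedState, partition: PoolPartition, params, env: Environment | None = None
) -> np.ndarray:
    """Net lumped rates V1..V9 (mM/s) for a lumped state under a partition."""
    model = _as_model(params, env)
    if abs(partition.PEP - state.PEP) > 1e-9 * (1 + state.PEP) or abs(
        partition.Pyr - state.Pyr
    ) > 1e-9 * (1 + state.Pyr):
        warnings.warn("partition was computed at different free-ligand levels")
    return model.rates(state.pools(), partition.PEP, partition.Pyr, state.HPr, state.HPrP)


def rhs_model1(
    state: LumpedState, totals: ConservedTotals, params, env: Environment | None = None
) -> dict[str, float]:
    """Model I right-hand side plus the algebraic closures."""
    model = _as_model(params, env)
    y = np.array([state.Y, state.Z, state.ZP, state.YP, state.HPrP, state.Pi])
    pools, ZP2, PEP, Pyr, HPr = model.closures_model1(y, totals)
    V = model.rates(pools, PEP, Pyr, HPr, state.HPrP)
    d = model.rhs1(y, totals)
    return {
        "dY": d[0], "dZ": d[1], "dZP": d[2], "dYP": d[3],
        "dHPrP": d[4], "dPi": d[5],
        "ZP2": ZP2, "PEP": PEP, "Pyr": Pyr, "HPr": HPr,
        "PTSP": pools[2] + 2 * pools[3] + pools[4] + state.HPrP,
        "V": V,
    }


def rhs_model2(
    state: LumpedState, params, env: Environment | None = None
) -> dict[str, float]:
    """Model II right-hand side (PEP, Pyr, HPr clamped; HPrP = Pi = 0)."""
    model = _as_model(params, env)
    EItotal = state.EI_monomer_equivalents
    y = np.array([state.Y, state.Z, state.ZP, state.YP])
    d = model.rhs2(y, EItotal, state.PEP, state.Pyr, state.HPr)
    return {"dY": d[0], "dZ": d[1], "dZP": d[2], "dYP": d[3]}
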
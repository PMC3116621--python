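"""Simulation of EI experiments: time courses, steady states, initial rates,
mechanism-resolved flux decompositions and 2-D PEP x Pyr response surfaces.

Model I integrates the six differential pools (Y, Z, ZP, YP, HPrP, Pi) with
ZP2, free PEP, free Pyr and HPr closed algebraically by the conservation
laws.  Model II clamps free PEP, Pyr and HPr, fixes HPrP = Pi = 0 and keeps
the four enzyme pools; it is the natural setting for initial-rate and
steady-state analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .environment import Environment, apply_environment
from .parameters import ParameterSet
from .reduced_model import ConservedTotals, LumpedState, ReducedModel

OBSERVABLES = (
    "phospho_EI",
    "phospho_HPr",
    "total_phospho_protein",
    "initial_rate",
    "steady_rate",
    "Y_concentration",
)

KNOCKOUTS = (
    "no_monomer_transfer",
    "no_second_phosphorylation",
    "no_Z_dissociation",
    "cyclic_only",
)

# below ~1 uM PEP the rapid-binding assumption may break down
LOW_PEP_VALIDITY_MM = 1e-3

__all__ = [
    "ExperimentSpec",
    "Trajectory",
    "FluxDecomposition",
    "time_course",
    "steady_state",
    "initial_rate",
    "scan_2d",
    "variant_experiment",
    "OBSERVABLES",
    "KNOCKOUTS",
]


@dataclass
class ExperimentSpec:
    """A simulable experimental design (concentrations in mM, times in s)."""

    model: str  # 'model1' | 'model2'
    env: Environment
    observable: str = "phospho_EI"
    totals: ConservedTotals | None = None  # model1
    clamps: dict[str, float] | None = None  # model2: PEP, Pyr, HPr
    EItotal: float = 0.0
    times: np.ndarray | None = None
    initial: Mapping[str, float] | None = None  # pool overrides (+ 'HPrP')
    scan_var: str | None = None  # abscissa of rate curves / titrations
    kind: str = "timecourse"  # 'timecourse' | 'rate_curve' | 'titration'
    rtol: float = 1e-8  # integrator relative tolerance

    def __post_init__(self) -> None:
        if self.model not in ("model1", "model2"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.observable not in OBSERVABLES:
            raise ValueError(f"unknown observable {self.observable!r}")
        if self.model == "model1" and self.totals is None:
            raise ValueError("model1 specs carry totals")
        if self.model == "model2" and self.clamps is None:
            raise ValueError("model2 specs carry clamps")

    @classmethod
    def model1(cls, env, EItotal, HPrtotal=0.0, PEP0=0.0, Pyr0=0.0,
               observable="phospho_EI", times=None, initial=None, **kw):
        init = dict(initial or {})
        PTSP0 = (init.get("ZP", 0.0) + 2 * init.get("ZP2", 0.0)
                 + init.get("YP", 0.0) + init.get("HPrP", 0.0))
        totals = ConservedTotals(EItotal=EItotal, HPrtotal=HPrtotal,
                                 PEP0=PEP0, Pyr0=Pyr0, PTSP0=PTSP0)
        return cls(model="model1", env=env, totals=totals, EItotal=EItotal,
                   observable=observable,
                   times=None if times is None else np.asarray(times, float),
                   initial=init, **kw)

    @classmethod
    def model2(cls, env, EItotal, PEP, Pyr=0.0, HPr=0.0,
               observable="steady_rate", times=None, initial=None, **kw):
        return cls(model="model2", env=env,
                   clamps={"PEP": PEP, "Pyr": Pyr, "HPr": HPr},
                   EItotal=EItotal, observable=observable,
                   times=None if times is None else np.asarray(times, float),
                   initial=dict(initial or {}), **kw)

    def initial_pools(self) -> np.ndarray:
        """Initial (Y, Z, ZP, ZP2, YP); by default all EI starts as
        unphosphorylated monomers."""
        init = dict(self.initial or {})
        pools = np.array([init.get(p, 0.0) for p in ("Y", "Z", "ZP", "ZP2", "YP")])
        if pools.sum() == 0.0 and self.EItotal > 0:
            pools[0] = self.EItotal
        return pools


@dataclass
class FluxDecomposition:
    """HPr phosphorylation flux split by donor form of EI (mM/s)."""

    total: float
    monomer: float
    ZP: float
    ZP2: float

    def check(self) -> None:
        s = self.monomer + self.ZP + self.ZP2
        if abs(s - self.total) > 1e-10 * max(abs(self.total), 1e-30):
            raise AssertionError("flux decomposition does not sum to total")


@dataclass
class Trajectory:
    times: np.ndarray
    states: list[LumpedState]
    observable: str
    values: np.ndarray
    spec: ExperimentSpec = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, s, v in zip(self.times, self.states, self.values):
            rows.append(dict(time=t, Y=s.Y, Z=s.Z, ZP=s.ZP, ZP2=s.ZP2, YP=s.YP,
                             PEP=s.PEP, Pyr=s.Pyr, HPr=s.HPr, HPrP=s.HPrP,
                             Pi=s.Pi, observable=v))
        return pd.DataFrame(rows)


def _observe(state: LumpedState, observable: str) -> float:
    if observable == "phospho_EI":
        return state.phospho_EI
    if observable == "phospho_HPr":
        return state.HPrP
    if observable == "total_phospho_protein":
        return state.PTSP
    if observable == "Y_concentration":
        return state.Y
    raise ValueError(f"observable {observable!r} is not a state function")


def _model_for(spec: ExperimentSpec, params: ParameterSet) -> ReducedModel:
    key = (spec.env.T, spec.env.pH)
    model = params._models.get(key)
    if model is None:
        model = ReducedModel(apply_environment(params, spec.env))
        params._models[key] = model
    model._ligand_guess = None
    return model


def time_course(spec: ExperimentSpec, params: ParameterSet) -> Trajectory:
    """Integrate the stiff reduced model on the spec's time grid."""
    if spec.times is None:
        raise ValueError("time_course needs a time grid")
    model = _model_for(spec, params)
    times = np.asarray(spec.times, float)
    t_end = float(times[-1])
    pools0 = spec.initial_pools()
    scale = max(spec.EItotal, 1e-12)

    if spec.model == "model1":
        totals = spec.totals
        init = dict(spec.initial or {})
        scale = max(scale, totals.HPrtotal, totals.PEP0, totals.Pyr0)
        y0 = np.array([pools0[0], pools0[1], pools0[2], pools0[4],
                       init.get("HPrP", 0.0), init.get("Pi", 0.0)])
        if abs(pools0.sum() + pools0[1] + pools0[2] + pools0[3] - totals.EItotal) \
                > 1e-9 * max(totals.EItotal, 1e-30):
            raise ValueError("initial pools violate the EI conservation law")
        fun = lambda t, y: model.rhs1(y, totals)
    else:
        c = spec.clamps
        y0 = np.array([pools0[0], pools0[1], pools0[2], pools0[4]])
        fun = lambda t, y: model.rhs2(y, spec.EItotal, c["PEP"], c["Pyr"], c["HPr"])

    t_eval = times if times[0] == 0.0 else np.concatenate([[0.0], times])
    sol = solve_ivp(fun, (0.0, t_end), y0, method="LSODA", t_eval=t_eval,
                    rtol=spec.rtol, atol=1e-4 * spec.rtol * scale)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")

    states, values = [], []
    undershoot = 0.0
    for k, t in enumerate(sol.t):
        if t not in times:
            continue
        y = sol.y[:, k]
        undershoot = min(undershoot, float(y.min()))
        y = np.maximum(y, 0.0)
        if spec.model == "model1":
            pools, ZP2, PEP, Pyr, HPr = model.closures_model1(
                np.array([y[0], y[1], y[2], y[3], y[4], y[5]]), spec.totals)
            st = LumpedState(Y=pools[0], Z=pools[1], ZP=pools[2], ZP2=pools[3],
                             YP=pools[4], PEP=PEP, Pyr=Pyr, HPr=HPr,
                             HPrP=y[4], Pi=y[5])
            drift = abs(st.EI_monomer_equivalents - spec.totals.EItotal)
            if drift > 1e-6 * max(spec.totals.EItotal, 1e-30):
                raise RuntimeError(f"EI conservation drift {drift} at t={t}")
        else:
            c = spec.clamps
            ZP2 = max(0.5 * (spec.EItotal - y[0] - 2 * y[1] - 2 * y[2] - y[3]), 0.0)
            st = LumpedState(Y=y[0], Z=y[1], ZP=y[2], ZP2=ZP2, YP=y[3],
                             PEP=c["PEP"], Pyr=c["Pyr"], HPr=c["HPr"])
        states.append(st)
        values.append(_observe(st, spec.observable)
                      if spec.observable in ("phospho_EI", "phospho_HPr",
                                             "total_phospho_protein",
                                             "Y_concentration") else np.nan)
    if undershoot < -1e-9 * scale:
        warnings.warn(f"integrator undershoot clipped at {undershoot:.2e} mM")
    return Trajectory(times=times, states=states, observable=spec.observable,
                      values=np.array(values), spec=spec)


def steady_state(
    spec: ExperimentSpec, params: ParameterSet, x0: np.ndarray | None = None
) -> tuple[LumpedState, FluxDecomposition]:
    """Stationary state of Model II (clamped PEP, Pyr, HPr).

    Damped Newton from an integrated warm start, long-integration fallback;
    the returned state satisfies |rhs| < 1e-12 and the EI closure exactly.
    """
    if spec.model != "model2":
        raise ValueError("steady_state is defined for model2 specs")
    model = _model_for(spec, params)
    c = spec.clamps
    if 0.0 < c["PEP"] < LOW_PEP_VALIDITY_MM:
        warnings.warn(
            "sub-micromolar PEP: the rapid-binding reduction may not be valid",
            stacklevel=2)
    fun = lambda y: model.rhs2(y, spec.EItotal, c["PEP"], c["Pyr"], c["HPr"])

    def integrate_from(y, t_end):
        sol = solve_ivp(lambda t, yy: fun(yy), (0.0, t_end), y, method="LSODA",
                        rtol=1e-8, atol=1e-12 * max(spec.EItotal, 1e-12))
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        return sol.y[:, -1]

    if x0 is None:
        pools0 = spec.initial_pools()
        x0 = integrate_from(
            np.array([pools0[0], pools0[1], pools0[2], pools0[4]]), 1e4)
    tol = 1e-12
    y = x0
    sol = root(fun, y, method="hybr", tol=1e-14)
    ok = sol.success and np.all(sol.x > -1e-12 * max(spec.EItotal, 1e-12))
    if ok:
        y = np.maximum(sol.x, 0.0)
    if not ok or np.max(np.abs(fun(y))) > tol:
        y = integrate_from(np.maximum(y, 0.0), 1e6)
        sol = root(fun, y, method="hybr", tol=1e-14)
        if sol.success and np.all(sol.x > -1e-12 * max(spec.EItotal, 1e-12)):
            y = np.maximum(sol.x, 0.0)
    res = np.max(np.abs(fun(y)))
    if res > tol:
        raise RuntimeError(f"steady state did not converge (residual {res:.2e})")

    ZP2 = max(0.5 * (spec.EItotal - y[0] - 2 * y[1] - 2 * y[2] - y[3]), 0.0)
    st = LumpedState(Y=y[0], Z=y[1], ZP=y[2], ZP2=ZP2, YP=y[3],
                     PEP=c["PEP"], Pyr=c["Pyr"], HPr=c["HPr"])
    d = model.transfer_decomposition(st.pools(), c["PEP"], c["Pyr"], c["HPr"], 0.0)
    dec = FluxDecomposition(total=d["total"], monomer=d["monomer"],
                            ZP=d["ZP"], ZP2=d["ZP2"])
    dec.check()
    return st, dec


def initial_rate(spec: ExperimentSpec, params: ParameterSet) -> float:
    """Initial HPr phosphorylation rate (mM/s) under Model II clamps.

    Operationally the least-squares slope of cumulative phosphoryl transfer
    over the earliest window past the enzyme-distribution boundary layer
    (t1 = 0.1 s by default) on which a linear fit has R^2 > 0.999.
    """
    if spec.model != "model2":
        raise ValueError("initial_rate is defined for model2 specs")
    c = spec.clamps
    if c["HPr"] == 0.0 or spec.EItotal == 0.0:
        return 0.0
    model = _model_for(spec, params)

    def fun(t, y):
        d = model.rhs2(y[:4], spec.EItotal, c["PEP"], c["Pyr"], c["HPr"])
        pools = np.array([max(y[0], 0.0), max(y[1], 0.0), max(y[2], 0.0),
                          max(0.5 * (spec.EItotal - y[0] - 2 * y[1]
                                     - 2 * y[2] - y[3]), 0.0),
                          max(y[3], 0.0)])
        V = model.rates(pools, c["PEP"], c["Pyr"], c["HPr"], 0.0)
        return np.append(d, V[4] + V[6] + V[7])

    pools0 = spec.initial_pools()
    y0 = np.array([pools0[0], pools0[1], pools0[2], pools0[4], 0.0])
    t_max = 0.1 * 4.0 * 2.0 ** 19
    sol = solve_ivp(fun, (0.0, t_max), y0, method="LSODA", dense_output=True,
                    rtol=min(spec.rtol, 1e-7),
                    atol=min(spec.rtol, 1e-7) * 1e-4 * max(spec.EItotal, 1e-12))
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    t1 = 0.1
    while t1 * 4.0 <= t_max:
        t2 = 4.0 * t1
        tgrid = np.linspace(t1, t2, 9)
        cum = sol.sol(tgrid)[4]
        if cum[-1] <= 0.0:
            t1 *= 2.0
            continue
        # linear to 1%: the slopes of the two half-windows must agree
        mid = len(tgrid) // 2
        s1 = np.polyfit(tgrid[: mid + 1], cum[: mid + 1], 1)[0]
        s2 = np.polyfit(tgrid[mid:], cum[mid:], 1)[0]
        if s1 > 0 and abs(s2 - s1) <= 0.01 * abs(s1):
            A = np.vstack([tgrid, np.ones_like(tgrid)]).T
            coef, *_ = np.linalg.lstsq(A, cum, rcond=None)
            return float(coef[0])
        t1 *= 2.0
    raise RuntimeError("no linear window found for the initial rate")


def scan_2d(
    spec: ExperimentSpec,
    params: ParameterSet,
    PEP_grid: np.ndarray,
    Pyr_grid: np.ndarray,
    quantity: str = "steady_rate",
) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state quantity over a PEP x Pyr grid (rows: Pyr, cols: PEP).

    Returns (matrix, ok_mask); failed cells are NaN and flagged, not filled.
    ``quantity`` is 'steady_rate', 'Y_concentration' or one of the
    decomposition components 'flux_monomer', 'flux_ZP', 'flux_ZP2'.
    """
    if quantity not in ("steady_rate", "Y_concentration",
                        "flux_monomer", "flux_ZP", "flux_ZP2"):
        raise ValueError(f"unknown scan quantity {quantity!r}")
    PEP_grid = np.atleast_1d(np.asarray(PEP_grid, float))
    Pyr_grid = np.atleast_1d(np.asarray(Pyr_grid, float))
    M = np.full((len(Pyr_grid), len(PEP_grid)), np.nan)
    ok = np.zeros(M.shape, bool)
    warm: np.ndarray | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, pyr in enumerate(Pyr_grid):
            row_warm = warm
            for j, pep in enumerate(PEP_grid):
                cell = replace(spec, clamps={**spec.clamps, "PEP": pep, "Pyr": pyr})
                try:
                    st, dec = steady_state(cell, params, x0=row_warm)
                except RuntimeError:
                    try:
                        st, dec = steady_state(cell, params, x0=None)
                    except RuntimeError:
                        continue
                row_warm = np.array([st.Y, st.Z, st.ZP, st.YP])
                if j == 0:
                    warm = row_warm
                ok[i, j] = True
                if quantity == "steady_rate":
                    M[i, j] = dec.total
                elif quantity == "Y_concentration":
                    M[i, j] = st.Y
                else:
                    M[i, j] = getattr(dec, quantity.split("_", 1)[1])
    return M, ok


def variant_experiment(params: ParameterSet, knockout: str | None) -> ParameterSet:
    """Parameter set with the named rate constants zeroed (in-silico knockout);
    the original set is untouched."""
    if knockout in (None, "none"):
        return params.updated()
    prefixes = {
        "no_monomer_transfer": ("kt:YP:",),
        "no_second_phosphorylation": ("kp:ZP(",),
        "no_Z_dissociation": ("kd:Z(",),
        "cyclic_only": ("kt:ZP:", "kt:ZP2:"),
    }
    if knockout not in prefixes:
        raise ValueError(f"unknown knockout {knockout!r}")
    zeros = {
        kid: 0.0
        for kid in params.k
        if any(kid.startswith(p) for p in prefixes[knockout])
    }
    return params.updated(k=zeros)
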
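"""Least-squares fitting of the EI model to heterogeneous experiments.

The fitness criterion is the plain sum of squared deviations between
simulated and observed values across all experimental points,
f = sum_i (v_i - vbar_i)^2, minimized with the Hooke-Jeeves pattern search
on log10-transformed positive parameters.  Fitting proceeds in stages: the
PEP -> EI transfer parameters are first determined on EI-phosphorylation
data without HPr, then fixed while the transfer-to-HPr parameters are fitted
to HPr-phosphorylation data, and finally all parameters are freed on the
pooled data.  Rate constants whose estimates collapse to the lower box bound
with an open sensitivity interval are fixed to zero and no longer counted as
free parameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .parameters import ParameterSet
from .simulate import ExperimentSpec, initial_rate, time_course

logger = logging.getLogger(__name__)

LOG10_LOWER, LOG10_UPPER = -14.0, 6.0  # box bounds, model units

__all__ = [
    "Dataset",
    "FitResult",
    "Stage",
    "predict",
    "objective",
    "hooke_jeeves",
    "staged_fit",
    "sensitivity_range",
    "default_stage_plan",
]


@dataclass
class Dataset:
    """Observed points of one experiment family.

    ``abscissa`` are times (timecourse), scanned concentrations (rate curve,
    titration); ``group`` tags the fitting stage the dataset belongs to
    ('ei_only' for EI phosphorylation without HPr, 'hpr' otherwise).
    """

    spec: ExperimentSpec
    abscissa: np.ndarray
    observed: np.ndarray
    weights: np.ndarray | None = None
    provenance: str = ""
    group: str = "hpr"

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, float)
        self.observed = np.asarray(self.observed, float)
        if self.weights is not None:
            self.weights = np.asarray(self.weights, float)
            if np.any(self.weights <= 0):
                raise ValueError("weights must be positive")
            logger.info("dataset %s uses non-unit weights", self.provenance)

    @property
    def n(self) -> int:
        return len(self.abscissa)


def predict(params: ParameterSet, dataset: Dataset) -> np.ndarray:
    """Model values at the dataset's abscissae (same units as observed)."""
    spec = dataset.spec
    if spec.kind == "timecourse":
        traj = time_course(replace(spec, times=dataset.abscissa), params)
        return traj.values
    if spec.kind == "rate_curve":
        var = spec.scan_var or "HPr"
        out = np.empty(dataset.n)
        for i, a in enumerate(dataset.abscissa):
            cell = replace(spec, clamps={**spec.clamps, var: float(a)})
            out[i] = initial_rate(cell, params)
        return out
    if spec.kind == "titration":
        # equilibrium observable vs. the scanned design variable; the spec's
        # time grid provides the equilibration horizon
        var = spec.scan_var or "PEP0"
        horizon = float(spec.times[-1]) if spec.times is not None else 3600.0
        out = np.empty(dataset.n)
        for i, a in enumerate(dataset.abscissa):
            a = float(a)
            if var == "pH":
                from .environment import Environment

                cell = replace(spec, env=Environment(T=spec.env.T, pH=a))
            elif var in ("PEP0", "Pyr0", "EItotal", "HPrtotal"):
                totals = replace(spec.totals, **{var: a})
                cell = replace(spec, totals=totals,
                               EItotal=a if var == "EItotal" else spec.EItotal)
            else:
                raise ValueError(f"unknown titration variable {var!r}")
            traj = time_course(replace(cell, times=np.array([horizon])), params)
            out[i] = traj.values[-1]
        return out
    raise ValueError(f"unknown dataset kind {spec.kind!r}")


def objective(params: ParameterSet, datasets: Sequence[Dataset]) -> float:
    """f = sum over all points of (v_model - v_observed)^2 (unit weights by
    default); a failed simulation yields an infinite objective (rejected
    step), never an exception."""
    total = 0.0
    for ds in datasets:
        try:
            v = predict(params, ds)
        except Exception as exc:  # noqa: BLE001 - rejected step, logged
            logger.warning("simulation failed for %s: %s", ds.provenance, exc)
            return math.inf
        if not np.all(np.isfinite(v)):
            logger.warning("non-finite prediction for %s", ds.provenance)
            return math.inf
        w = ds.weights if ds.weights is not None else 1.0
        total += float(np.sum(w * (v - ds.observed) ** 2))
    return total


# ---------------------------------------------------------------------------
# Hooke-Jeeves pattern search

@dataclass
class HJResult:
    x: np.ndarray
    f: float
    evals: int
    trace: list[tuple[int, float]]
    converged: bool


def hooke_jeeves(
    fun: Callable[[np.ndarray], float],
    x0: np.ndarray,
    step: float | np.ndarray = 0.3,
    shrink: float = 0.5,
    tol: float = 1e-4,
    max_evals: int = 5000,
    bounds: tuple[float, float] = (LOG10_LOWER, LOG10_UPPER),
) -> HJResult:
    """Classic exploratory + pattern-move search; the step halves whenever an
    exploratory sweep fails, and the search stops when it falls below tol.
    Never returns a point worse than x0."""
    lo, hi = bounds
    x0 = np.clip(np.asarray(x0, float), lo, hi)
    h = np.full_like(x0, step) if np.isscalar(step) else np.asarray(step, float).copy()
    evals = 0
    trace: list[tuple[int, float]] = []

    def f(x: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        return fun(x)

    fb = f(x0)
    base, fbase = x0.copy(), fb
    trace.append((evals, fbase))

    def explore(x: np.ndarray, fx: float) -> tuple[np.ndarray, float]:
        x = x.copy()
        for i in range(len(x)):
            for d in (+h[i], -h[i]):
                xi = min(max(x[i] + d, lo), hi)
                if xi == x[i]:
                    continue
                xt = x.copy()
                xt[i] = xi
                ft = f(xt)
                if ft < fx:
                    x, fx = xt, ft
                    break
        return x, fx

    while evals < max_evals:
        new, fnew = explore(base, fbase)
        if fnew < fbase:
            # pattern moves while they keep paying off
            while evals < max_evals:
                cand = np.clip(new + (new - base), lo, hi)
                base, fbase = new, fnew
                fc = f(cand)
                new2, fnew2 = explore(cand, fc)
                if fnew2 < fbase:
                    new, fnew = new2, fnew2
                else:
                    break
            base, fbase = new, fnew
            trace.append((evals, fbase))
        else:
            h *= shrink
            if np.max(h) < tol:
                return HJResult(base, fbase, evals, trace, True)
    return HJResult(base, fbase, evals, trace, False)


# ---------------------------------------------------------------------------
# Staged fitting

@dataclass
class Stage:
    name: str
    groups: tuple[str, ...] | None  # None = all datasets
    free: tuple[str, ...]


def default_stage_plan(
    stage1_free: Sequence[str], stage2_free: Sequence[str]
) -> list[Stage]:
    """Three-step protocol: PEP->EI parameters on EI-only data, transfer-to-
    HPr parameters on HPr data, then everything together."""
    all_free = tuple(dict.fromkeys([*stage1_free, *stage2_free]))
    return [
        Stage("pep_to_ei", ("ei_only",), tuple(stage1_free)),
        Stage("to_hpr", ("hpr",), tuple(stage2_free)),
        Stage("all", None, all_free),
    ]


@dataclass
class FitResult:
    params: ParameterSet
    f: float
    free_ids: tuple[str, ...]
    fixed_to_zero: tuple[str, ...]
    per_dataset: dict[str, float]
    trace: list[tuple[str, int, float]]
    n: int
    evals: int

    @property
    def q(self) -> int:
        """Number of free parameters actually varied (zero-fixed excluded)."""
        return len(self.free_ids)


def _get_param(params: ParameterSet, pid: str) -> float:
    if pid in params.K_independent:
        return params.K_independent[pid]
    if pid in params.k:
        return params.rate(pid)
    raise KeyError(f"{pid} is neither an independent constant nor a rate")


def _set_params(params: ParameterSet, values: Mapping[str, float]) -> ParameterSet:
    K = {p: v for p, v in values.items() if p in params.K_independent}
    k = {p: v for p, v in values.items() if p in params.k}
    new = params.updated(K=K, k=k)
    new.fixed_zero -= set(k)
    return new


def fit_stage(
    params: ParameterSet,
    datasets: Sequence[Dataset],
    free_ids: Sequence[str],
    step: float = 0.3,
    shrink: float = 0.5,
    tol: float = 1e-3,
    max_evals: int = 2000,
    restarts: int = 2,
) -> tuple[ParameterSet, HJResult]:
    """Hooke-Jeeves on log10 of the selected parameters over the datasets.

    The search is restarted from its own best point with the step reset to
    its initial size until no further improvement is found (strongly
    correlated constants form narrow curved valleys that a single
    exploratory cycle can stall in)."""
    free_ids = list(free_ids)
    x0 = np.array([
        math.log10(max(_get_param(params, p), 10.0 ** LOG10_LOWER))
        for p in free_ids
    ])

    def fun(x: np.ndarray) -> float:
        vals = {p: 10.0 ** xi for p, xi in zip(free_ids, x)}
        return objective(_set_params(params, vals), datasets)

    res = hooke_jeeves(fun, x0, step=step, shrink=shrink, tol=tol,
                       max_evals=max_evals)
    evals, trace = res.evals, list(res.trace)
    for _ in range(restarts):
        if evals >= max_evals:
            break
        again = hooke_jeeves(fun, res.x, step=step, shrink=shrink, tol=tol,
                             max_evals=max_evals - evals)
        evals += again.evals
        trace += [(evals, fv) for _, fv in again.trace]
        if again.f >= res.f * (1 - 1e-10):
            res = HJResult(res.x, res.f, evals, trace, res.converged)
            break
        res = HJResult(again.x, again.f, evals, trace, again.converged)
    best = _set_params(params, {p: 10.0 ** xi for p, xi in zip(free_ids, res.x)})
    return best, res


def staged_fit(
    datasets: Sequence[Dataset],
    stage_plan: Sequence[Stage],
    start: ParameterSet,
    step: float = 0.3,
    shrink: float = 0.5,
    tol: float = 1e-3,
    max_evals: int = 2000,
    zero_fix: bool = True,
) -> FitResult:
    """Run the staged protocol and return the final fit.

    After the last stage, rate constants sitting at the lower box bound are
    fixed to zero (and removed from the free-parameter count) when doing so
    does not worsen the objective — the operational version of pruning
    constants that are "close to zero".
    """
    if not datasets:
        raise ValueError("no datasets")
    params = start
    trace: list[tuple[str, int, float]] = []
    evals = 0
    last_free: tuple[str, ...] = ()
    for stage in stage_plan:
        subset = [
            d for d in datasets
            if stage.groups is None or d.group in stage.groups
        ]
        if not subset:
            raise ValueError(f"stage {stage.name!r} selects no datasets")
        if not stage.free:
            continue
        params, res = fit_stage(params, subset, stage.free,
                                step=step, shrink=shrink, tol=tol,
                                max_evals=max_evals)
        evals += res.evals
        trace.append((stage.name, res.evals, res.f))
        last_free = tuple(stage.free)

    f_final = objective(params, datasets)
    fixed: list[str] = []
    if zero_fix:
        for pid in last_free:
            if pid in params.k and 0.0 < params.rate(pid) <= 10.0 ** (LOG10_LOWER + 2):
                candidate = params.updated()
                candidate.fixed_zero.add(pid)
                f_zero = objective(candidate, datasets)
                if f_zero <= f_final * (1 + 1e-9):
                    params, f_final = candidate, f_zero
                    fixed.append(pid)
    free_ids = tuple(p for p in last_free if p not in fixed)
    per_dataset = {}
    for ds in datasets:
        try:
            v = predict(params, ds)
            w = ds.weights if ds.weights is not None else 1.0
            per_dataset[ds.provenance or ds.group] = float(
                np.sum(w * (v - ds.observed) ** 2))
        except Exception:  # noqa: BLE001
            per_dataset[ds.provenance or ds.group] = math.inf
    n = sum(ds.n for ds in datasets)
    return FitResult(params=params, f=f_final, free_ids=free_ids,
                     fixed_to_zero=tuple(fixed), per_dataset=per_dataset,
                     trace=trace, n=n, evals=evals)


# ---------------------------------------------------------------------------
# Sensitivity ranges

@dataclass
class SensitivityRange:
    param_id: str
    low: float
    high: float
    open_low: bool
    open_high: bool
    f_base: float


def sensitivity_range(
    params: ParameterSet,
    datasets: Sequence[Dataset],
    param_id: str,
    factor: float = 2.0,
    bounds: tuple[float, float] = (LOG10_LOWER, LOG10_UPPER),
) -> SensitivityRange:
    """Single-parameter interval over which f stays below ``factor`` times
    its baseline (all other parameters fixed); sides where the threshold is
    never reached are reported open at the scan bound."""
    f0 = objective(params, datasets)
    if not f0 > 0:
        raise ValueError("sensitivity range undefined at a perfect fit")
    target = factor * f0
    x_hat = math.log10(max(_get_param(params, param_id), 10.0 ** bounds[0]))

    def f_at(x: float) -> float:
        return objective(_set_params(params, {param_id: 10.0 ** x}), datasets)

    def side(direction: float) -> tuple[float, bool]:
        bound = bounds[1] if direction > 0 else bounds[0]
        x_in, step = x_hat, 0.25 * direction
        x = x_hat + step
        while (x - bound) * direction < 0:
            fx = f_at(x)
            if fx >= target:
                from scipy.optimize import brentq

                g = lambda xx: f_at(xx) - target
                xr = brentq(g, min(x_in, x), max(x_in, x), xtol=1e-4)
                # refine to ~1e-3 relative on the parameter itself
                return 10.0 ** xr, False
            x_in = x
            step *= 2.0
            x = x_hat + step if abs(x_hat + step - x_in) > 1e-12 else x + step
            if (x - bound) * direction > 0:
                x = bound
                fx = f_at(x)
                if fx >= target:
                    g = lambda xx: f_at(xx) - target
                    from scipy.optimize import brentq

                    xr = brentq(g, min(x_in, x), max(x_in, x), xtol=1e-4)
                    return 10.0 ** xr, False
                break
        return 10.0 ** bound, True

    high, open_high = side(+1.0)
    low, open_low = side(-1.0)
    return SensitivityRange(param_id=param_id, low=low, high=high,
                            open_low=open_low, open_high=open_high, f_base=f0)
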
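"""AIC comparison of the four phosphotransfer mechanisms.

Each mechanism variant (transfer to HPr by the monomer only, by the doubly
phosphorylated dimer only, by both dimer forms, or by all forms of EI) is
fitted with the same staged protocol; goodness of fit is then compared with
the Akaike information criterion

    AIC = ln(s2 / n) + 2 q,    s2 = sum_i ((v_i - vbar_i) / v_i)^2,

where n is the number of experimental points, q the number of free
parameters, and the relative error s2 is normalized by the *predicted*
value v_i (unusual, but implemented exactly as defined; points where the
prediction is zero are excluded with a warning).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fit import Dataset, FitResult, Stage, predict, staged_fit
from .parameters import ParameterSet

__all__ = ["aic", "relative_error_sum", "compare_variants", "VariantReport"]


def aic(s2: float, n: int, q: int) -> float:
    """ln(s2/n) + 2q; undefined (signaled) for s2 = 0."""
    if n < 1:
        raise ValueError("n must be a positive integer")
    if q < 0:
        raise ValueError("q must be non-negative")
    if not s2 > 0:
        raise ValueError("AIC undefined for zero relative error")
    return math.log(s2 / n) + 2.0 * q


def relative_error_sum(
    params: ParameterSet, datasets: Sequence[Dataset]
) -> float:
    """s2 = sum((v - vbar)/v)^2 with v the model prediction; zero-prediction
    points are excluded with a warning."""
    s2 = 0.0
    for ds in datasets:
        v = predict(params, ds)
        mask = v != 0.0
        if not mask.all():
            warnings.warn(
                f"{(~mask).sum()} zero-prediction point(s) excluded from s2 "
                f"in {ds.provenance or ds.group}")
        s2 += float(np.sum(((v[mask] - ds.observed[mask]) / v[mask]) ** 2))
    return s2


@dataclass
class VariantRow:
    variant: str
    q: int
    f: float
    s2: float
    n: int
    aic: float | None
    failed: bool = False
    fit: FitResult | None = None


@dataclass
class VariantReport:
    rows: list[VariantRow]
    selected: str | None
    tie: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            dict(variant=r.variant, q=r.q, f=r.f, s2=r.s2, n=r.n,
                 AIC=r.aic, failed=r.failed, selected=r.variant == self.selected)
            for r in self.rows
        ])


def compare_variants(
    datasets: Sequence[Dataset],
    stage_plan_of: Mapping[str, Sequence[Stage]],
    start_of: Mapping[str, ParameterSet],
    **fit_kw,
) -> VariantReport:
    """Fit every variant with its staged plan and rank by AIC.

    A failed fit becomes a failed row; the comparison continues.  Ties on
    the minimal AIC are flagged.
    """
    if len(start_of) < 2:
        raise ValueError("need at least two variants to compare")
    rows: list[VariantRow] = []
    n = sum(ds.n for ds in datasets)
    for variant, start in start_of.items():
        try:
            fit = staged_fit(datasets, stage_plan_of[variant], start, **fit_kw)
            s2 = relative_error_sum(fit.params, datasets)
            a = aic(s2, n, fit.q) if s2 > 0 else None
            rows.append(VariantRow(variant=variant, q=fit.q, f=fit.f, s2=s2,
                                   n=n, aic=a, fit=fit))
        except Exception as exc:  # noqa: BLE001 - reported as failed row
            warnings.warn(f"variant {variant} failed: {exc}")
            rows.append(VariantRow(variant=variant, q=0, f=math.inf,
                                   s2=math.inf, n=n, aic=None, failed=True))
    scored = [r for r in rows if r.aic is not None]
    selected, tie = None, False
    if scored:
        best = min(r.aic for r in scored)
        winners = [r.variant for r in scored if abs(r.aic - best) < 1e-12]
        selected = winners[0]
        tie = len(winners) > 1
    return VariantReport(rows=rows, selected=selected, tie=tie)
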
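"""Selection-evaluation metrics and relative efficiencies.

For a selected set of ``s`` genotypes with binary indicator ``x``:

M   mean genetic gain, ``sum_{i sel} sum_j y_ji / (s * p0)``;
V   variance of the mean, ``x^T G x / s^2`` — uses *all* entries of the
    selected G submatrix including the self-relatedness diagonal,
    exactly the quantity the quadratic penalty controls;
MV  gain-to-relatedness ratio, ``M / sqrt(V)``; higher means more gain
    per unit relatedness;
MR  mean pairwise relatedness: the average of the ``s(s-1)/2``
    strictly-upper-triangular entries of the selected G submatrix.

Relative efficiency (RE) compares methods on one metric: the best
method is the maximizer for M and MV and the minimizer for V and MR,
and

    RE_M(q)  = (M_best / M_q - 1) * 100     RE_V(q)  = (V_q / V_best - 1) * 100
    RE_MV(q) = (MV_best / MV_q - 1) * 100   RE_MR(q) = (MR_q / MR_best - 1) * 100

expressed in percent; the best method scores 0 against itself.  The
ratio form is ill-behaved when values straddle zero (MR frequently goes
negative under strong penalization); such entries are computed verbatim
but flagged unreliable rather than redefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np

from .errors import EmptySelection
from .grm import RelationshipMatrix
from .optimize import SelectionResult
from .preprocess import StandardizedTraits

MetricName = Literal["M", "V", "MV", "MR"]

#: metrics where larger is better (best = max); the rest are best = min
_HIGHER_BETTER = {"M": True, "V": False, "MV": True, "MR": False}


@dataclass(frozen=True)
class MetricsReport:
    """M/V/MV/MR for one selected set.

    ``MV`` is ``None`` when ``V = 0`` (ratio undefined); ``MR`` is
    ``None`` for ``s = 1`` (no pairs).
    """

    M: float
    V: float
    MV: float | None
    MR: float | None
    s: int
    method_label: str = ""

    def as_dict(self) -> dict:
        return {
            "method": self.method_label,
            "s": self.s,
            "M": self.M,
            "V": self.V,
            "MV": self.MV,
            "MR": self.MR,
        }


@dataclass(frozen=True)
class EfficiencyReport:
    """Relative efficiencies of several methods on one metric.

    ``RE`` maps method label -> percent; ``flags`` carries per-method
    annotations (``"unreliable: sign change"``, ``"division by zero"``,
    ``"undefined metric"``).
    """

    metric: MetricName
    best_label: str
    RE: dict[str, float] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)


def compute_metrics(
    result: SelectionResult,
    y: StandardizedTraits,
    G: RelationshipMatrix,
    *,
    method_label: str = "",
) -> MetricsReport:
    """Evaluate M, V, MV and MR for a solver result.

    Raises
    ------
    EmptySelection
        When the result selected nothing (e.g. an infeasible run).
    """
    idx = result.selected_indices
    s = idx.size
    if s == 0:
        raise EmptySelection(f"no genotypes selected (status={result.status})")
    if y.n != G.n:
        raise ValueError("trait table and relationship matrix sizes differ")
    p0 = y.p0
    M = float(y.y[idx].sum()) / (s * p0)
    sub = G.submatrix(idx)
    V = float(sub.sum()) / s**2
    MV = M / np.sqrt(V) if V > 0 else None
    if s > 1:
        MR = float(sub[np.triu_indices(s, k=1)].mean())
    else:
        MR = None
    return MetricsReport(
        M=M, V=V, MV=MV, MR=MR, s=s,
        method_label=method_label or result.solver,
    )


def relative_efficiency(
    values: Mapping[str, float | None], metric: MetricName
) -> EfficiencyReport:
    """Compute percent relative efficiencies across methods for one metric.

    Parameters
    ----------
    values
        Method label -> metric value.  ``None``/NaN entries (undefined
        metrics, e.g. from infeasible runs) are flagged and excluded
        from the best-method search.
    metric
        Which metric the values belong to; decides the direction of
        "best" and the ratio orientation.
    """
    if metric not in _HIGHER_BETTER:
        raise ValueError(f"unknown metric {metric!r}")
    finite = {
        m: float(v) for m, v in values.items()
        if v is not None and np.isfinite(v)
    }
    if len(finite) < 2:
        raise ValueError("need at least two methods with finite metric values")
    higher = _HIGHER_BETTER[metric]
    best_label = (max if higher else min)(finite, key=finite.get)
    best = finite[best_label]

    RE: dict[str, float] = {}
    flags: dict[str, str] = {}
    for m, v in values.items():
        if m not in finite:
            flags[m] = "undefined metric"
            continue
        v = finite[m]
        denom = v if higher else best  # RE = (best/q - 1) or (q/best - 1)
        numer = best if higher else v
        if denom == 0.0:
            RE[m] = float("inf") if numer > 0 else float("nan")
            flags[m] = "division by zero"
            continue
        RE[m] = (numer / denom - 1.0) * 100.0
        if np.sign(v) != np.sign(best) and v != best:
            flags[m] = "unreliable: sign change"
    return EfficiencyReport(metric=metric, best_label=best_label, RE=RE, flags=flags)
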
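"""Incremental cost-effectiveness analysis and the efficiency frontier.

Two complementary views are produced from per-strategy totals:

* pairwise incremental analysis versus a fixed reference strategy (the
  ICER-versus-reference table, with "dominates"/"dominated" labels), and
* the efficiency frontier (strictly and extendedly dominated strategies
  removed; surviving strategies ordered by cost with increasing sequential
  ICERs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "StrategyTotals",
    "IncrementalRow",
    "CEAResult",
    "incremental_analysis",
    "efficiency_frontier",
]


@dataclass(frozen=True)
class StrategyTotals:
    name: str
    cost: float
    qalys: float
    life_years: float = float("nan")


@dataclass
class IncrementalRow:
    name: str
    cost: float
    qalys: float
    incremental_cost: float | None
    incremental_qalys: float | None
    icer: float | None
    label: str  # "reference" | "icer" | "dominates" | "dominated" | "equivalent" | "undefined"

    def verdict(self, wtp: float) -> str:
        """Cost-effectiveness verdict versus the reference at a WTP threshold."""
        if self.label == "reference":
            return "reference"
        if self.label == "dominates":
            return "cost-effective (dominant)"
        if self.label == "dominated":
            return "not cost-effective (dominated)"
        if self.label == "icer" and self.icer is not None:
            return "cost-effective" if self.icer <= wtp else "not cost-effective"
        return "indeterminate"


@dataclass
class CEAResult:
    reference: str
    rows: list[IncrementalRow]
    frontier: list[str] = field(default_factory=list)
    frontier_icers: dict[str, float | None] = field(default_factory=dict)
    wtp_threshold: float = 50_000.0

    def row(self, name: str) -> IncrementalRow:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)


def _pairwise(dc: float, dq: float) -> tuple[float | None, str]:
    """ICER and label for (Δcost, Δqaly) of a comparator versus a reference."""
    if abs(dq) < 1e-15 and abs(dc) < 1e-15:
        return None, "equivalent"
    if dq > 0 and dc < 0:
        return None, "dominates"
    if dq < 0 and dc > 0:
        return None, "dominated"
    if abs(dq) < 1e-15:
        return None, "undefined"
    if dq > 0:
        return dc / dq, "icer"
    # less effective and cheaper: ICER of the *reference* over this strategy;
    # report the ratio but keep the directional label
    return dc / dq, "icer"


def incremental_analysis(totals: list[StrategyTotals], reference: str,
                         wtp_threshold: float = 50_000.0) -> CEAResult:
    """Pairwise incremental costs, QALYs and ICERs versus ``reference``.

    ICERs are computed from the exact (unrounded) totals.  A comparator that
    is cheaper and more effective than the reference is labelled
    ``dominates``; more costly and less effective, ``dominated``.
    """
    if len(totals) < 2:
        raise ValueError("need at least two strategies")
    names = [t.name for t in totals]
    if reference not in names:
        raise ValueError(f"reference {reference!r} not among strategies {names}")
    ref = next(t for t in totals if t.name == reference)
    rows = []
    for t in totals:
        if t.name == reference:
            rows.append(IncrementalRow(t.name, t.cost, t.qalys, None, None, None, "reference"))
            continue
        dc, dq = t.cost - ref.cost, t.qalys - ref.qalys
        icer, label = _pairwise(dc, dq)
        rows.append(IncrementalRow(t.name, t.cost, t.qalys, dc, dq, icer, label))
    res = CEAResult(reference=reference, rows=rows, wtp_threshold=wtp_threshold)
    res.frontier, res.frontier_icers = efficiency_frontier(totals)
    return res


def efficiency_frontier(totals: list[StrategyTotals]
                        ) -> tuple[list[str], dict[str, float | None]]:
    """Efficient set ordered by cost, with sequential ICERs.

    Strictly dominated strategies (another strategy no more costly and no
    less effective, better on at least one axis) are removed first; then
    extendedly dominated strategies (sequential ICER higher than the next
    one up the frontier) are removed iteratively.  The cheapest efficient
    strategy anchors the frontier with ICER ``None``.
    """
    pts = sorted(totals, key=lambda t: (t.cost, -t.qalys))
    # strict dominance
    kept = []
    for t in pts:
        if any(o.cost <= t.cost and o.qalys >= t.qalys
               and (o.cost < t.cost or o.qalys > t.qalys) for o in pts):
            continue
        kept.append(t)
    # drop exact ties (same cost and qalys), keep first
    uniq = []
    for t in kept:
        if not any(abs(o.cost - t.cost) < 1e-12 and abs(o.qalys - t.qalys) < 1e-12
                   for o in uniq):
            uniq.append(t)
    # extended dominance: sequential ICERs must be increasing
    changed = True
    while changed and len(uniq) > 2:
        changed = False
        for i in range(1, len(uniq) - 1):
            lo, mid, hi = uniq[i - 1], uniq[i], uniq[i + 1]
            icer_mid = (mid.cost - lo.cost) / (mid.qalys - lo.qalys)
            icer_hi = (hi.cost - mid.cost) / (hi.qalys - mid.qalys)
            if icer_mid > icer_hi - 1e-15:
                del uniq[i]
                changed = True
                break
    icers: dict[str, float | None] = {}
    for i, t in enumerate(uniq):
        if i == 0:
            icers[t.name] = None
        else:
            prev = uniq[i - 1]
            icers[t.name] = (t.cost - prev.cost) / (t.qalys - prev.qalys)
    return [t.name for t in uniq], icers
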
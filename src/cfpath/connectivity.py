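"""Connectivity curves.

For an identified metabolite, the connectivity curve (CC) maps a step count
``n`` to the number of metabolites whose shortest carbon-flux-path distance
is at most ``n``. In *accumulation* mode distances run from the metabolite
(its degradation side); in *depletion* mode they run toward it (its
biosynthesis side). One CFP solve is performed per candidate metabolite;
proven-infeasible solves are recorded as disconnections, and time-limit hits
are reported separately as undetermined, never as disconnections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .cfp import CfpSolver
from .milp import UndeterminedError
from .network import CarbonArcTable, MetabolicNetwork, ValidationError

ACCUMULATION = "accumulation"
DEPLETION = "depletion"


@dataclass(frozen=True)
class ConnectivityCurve:
    source: str
    direction: str
    distances: dict[str, int]
    disconnected: frozenset[str]
    undetermined: frozenset[str] = frozenset()
    blocked: frozenset[str] = frozenset()

    @property
    def knockout(self) -> str | None:
        """The knocked-out reaction when the scenario blocks exactly one."""
        return next(iter(self.blocked)) if len(self.blocked) == 1 else None

    @property
    def connected(self) -> frozenset[str]:
        """C_infinity: every metabolite with a finite CFP distance."""
        return frozenset(self.distances)

    @property
    def c_infinity(self) -> int:
        return len(self.distances)

    @property
    def d_max(self) -> int:
        """Smallest n at which the curve reaches its full connected count."""
        return max(self.distances.values()) if self.distances else 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"target_id": m, "distance": d} for m, d in sorted(self.distances.items())
        ]
        rows += [
            {"target_id": m, "distance": "disconnected"} for m in sorted(self.disconnected)
        ]
        rows += [
            {"target_id": m, "distance": "undetermined"} for m in sorted(self.undetermined)
        ]
        return pd.DataFrame(rows, columns=["target_id", "distance"])

    def summary(self) -> dict:
        return {
            "source": self.source,
            "direction": self.direction,
            "blocked": sorted(self.blocked),
            "cumulative_counts": {str(n): c for n, c in cumulative_counts(self).items()},
            "connected": self.c_infinity,
            "d_max": self.d_max,
            "disconnected": sorted(self.disconnected),
            "undetermined": sorted(self.undetermined),
        }

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_summary(self, path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n", encoding="utf-8")


def cumulative_counts(curve: ConnectivityCurve) -> dict[int, int]:
    """|C_n| for n = 1..D^max (empty when nothing is connected)."""
    if not curve.distances:
        return {}
    counts: dict[int, int] = {}
    dmax = curve.d_max
    for n in range(1, dmax + 1):
        counts[n] = sum(1 for d in curve.distances.values() if d <= n)
    return counts


def connectivity_curve(
    network: MetabolicNetwork,
    arcs: CarbonArcTable,
    source: str,
    direction: str = ACCUMULATION,
    blocked=frozenset(),
    solver: CfpSolver | None = None,
    big_M: float = 1000.0,
    time_limit: float | None = 60.0,
) -> ConnectivityCurve:
    """Compute the CC of ``source``: one CFP solve per other carbon-graph node.

    In accumulation mode the source plays the path origin (alpha); in
    depletion mode it plays the target (beta).
    """
    if direction not in (ACCUMULATION, DEPLETION):
        raise ValidationError(f"unknown direction {direction!r}")
    if solver is None:
        solver = CfpSolver(network, arcs, big_M=big_M, time_limit=time_limit)
    if source not in solver.graph:
        raise ValidationError(f"source metabolite {source!r} is not in the carbon graph")
    blocked = frozenset(blocked)
    distances: dict[str, int] = {}
    disconnected: set[str] = set()
    undetermined: set[str] = set()
    for target in sorted(solver.graph.nodes):
        if target == source:
            continue
        alpha, beta = (source, target) if direction == ACCUMULATION else (target, source)
        try:
            sol = solver.solve(alpha, beta, blocked=blocked, time_limit=time_limit)
        except UndeterminedError:
            undetermined.add(target)
            continue
        except Exception as exc:
            raise type(exc)(f"CFP solve for target {target!r} failed: {exc}") from exc
        if sol.optimal:
            distances[target] = sol.length
        else:
            disconnected.add(target)
    return ConnectivityCurve(
        source=source,
        direction=direction,
        distances=distances,
        disconnected=frozenset(disconnected),
        undetermined=frozenset(undetermined),
        blocked=blocked,
    )
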
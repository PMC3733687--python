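"""Single-reaction knockout scan and enzyme ranking.

For every internal (non-exchange) reaction ``j`` the connectivity curve of
the study metabolite is recomputed with ``j`` blocked, and the knockout is
scored by the length-increasing parameter

    dL_j = L_j^K - L_j^W,

the increase of the mean shortest-CFP distance over the metabolites that
*remain* connected under the knockout (disconnected metabolites do not
enter the average; the wild-type mean is restricted to the same set).
Knockouts that disconnect any wild-type-connected (medium input, excreted
output) pair are flagged non-viable and excluded from the ranking: they
disrupt rather than modulate metabolism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd

from .cfp import CfpSolver
from .connectivity import ACCUMULATION, ConnectivityCurve, connectivity_curve, cumulative_counts
from .network import CarbonArcTable, MetabolicNetwork, ValidationError


class FullDisconnectionError(ValueError):
    """The knockout disconnects every metabolite: dL is undefined."""


def _mean_distance_cumulative(
    counts: dict[int, int], c_inf: int
) -> Fraction:
    """Mean distance from cumulative counts: sum_i i * (|C_i| - |C_{i-1}|) / |C_inf|."""
    total = Fraction(0)
    prev = 0
    for i in sorted(counts):
        total += i * (counts[i] - prev)
        prev = counts[i]
    return total / c_inf


def delta_L(
    wild: ConnectivityCurve, ko: ConnectivityCurve
) -> tuple[Fraction, Fraction, Fraction, frozenset[str]]:
    """(dL, L^K, L^W restricted, newly disconnected set), in exact rationals.

    Both means are evaluated over the knockout-connected set: L^K from the
    knockout curve's cumulative counts, L^W from the wild-type distances
    intersected with that same set.
    """
    if wild.source != ko.source or wild.direction != ko.direction:
        raise ValidationError("wild-type and knockout curves must share source and direction")
    if wild.blocked:
        raise ValidationError("the wild-type curve must have no blocked reactions")
    surviving = ko.connected
    if not surviving:
        raise FullDisconnectionError(
            f"knockout {sorted(ko.blocked)} disconnects every metabolite from {ko.source!r}"
        )
    c_inf = len(surviving)
    L_K = _mean_distance_cumulative(cumulative_counts(ko), c_inf)
    # wild-type cumulative counts restricted to the surviving set
    wild_restricted = {m: d for m, d in wild.distances.items() if m in surviving}
    missing = surviving - set(wild_restricted)
    if missing:
        raise ValidationError(
            f"metabolites {sorted(missing)} connected only under the knockout; "
            "the knockout curve is inconsistent with the wild type"
        )
    dmax_w = max(wild_restricted.values())
    counts_w = {
        n: sum(1 for d in wild_restricted.values() if d <= n) for n in range(1, dmax_w + 1)
    }
    L_W = _mean_distance_cumulative(counts_w, c_inf)
    disconnected = wild.connected - surviving
    return L_K - L_W, L_K, L_W, frozenset(disconnected)


@dataclass(frozen=True)
class KnockoutResult:
    reaction: str
    name: str
    delta_L: float | None
    L_knockout: float | None
    L_wildtype_restricted: float | None
    disconnected: frozenset[str]
    viable: bool
    undetermined: frozenset[str] = frozenset()
    fully_disconnecting: bool = False


@dataclass
class RankingTable:
    source: str
    direction: str
    rows: tuple[KnockoutResult, ...]
    positions: dict[str, int]
    pvalues: dict[str, float] = field(default_factory=dict)

    def result(self, reaction: str) -> KnockoutResult:
        for row in self.rows:
            if row.reaction == reaction:
                return row
        raise KeyError(reaction)

    @property
    def ranked(self) -> tuple[KnockoutResult, ...]:
        return tuple(r for r in self.rows if r.reaction in self.positions)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            records.append(
                {
                    "reaction_id": r.reaction,
                    "reaction_name": r.name,
                    "delta_L": r.delta_L,
                    "position": self.positions.get(r.reaction),
                    "p_value": self.pvalues.get(r.reaction),
                    "viable": r.viable,
                    "n_disconnected": len(r.disconnected),
                }
            )
        return pd.DataFrame(
            records,
            columns=[
                "reaction_id",
                "reaction_name",
                "delta_L",
                "position",
                "p_value",
                "viable",
                "n_disconnected",
            ],
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def wildtype_io_pairs(
    network: MetabolicNetwork,
    arcs: CarbonArcTable,
    solver: CfpSolver | None = None,
) -> tuple[tuple[str, str], ...]:
    """(input, output) pairs CFP-connected in the wild type."""
    if solver is None:
        solver = CfpSolver(network, arcs)
    pairs = []
    for inp in network.medium_inputs():
        for out in network.excreted_outputs():
            if inp == out or inp not in solver.graph or out not in solver.graph:
                continue
            if solver.reachable(inp, out):
                pairs.append((inp, out))
    return tuple(pairs)


def viability_filter(
    network: MetabolicNetwork,
    arcs: CarbonArcTable,
    blocked,
    solver: CfpSolver | None = None,
    wild_pairs: tuple[tuple[str, str], ...] | None = None,
) -> bool:
    """True iff every wild-type-connected (input, output) pair stays connected.

    A solver time-out on any pair propagates as :class:`UndeterminedError`;
    viability is never silently decided by a timeout.
    """
    if solver is None:
        solver = CfpSolver(network, arcs)
    if wild_pairs is None:
        wild_pairs = wildtype_io_pairs(network, arcs, solver)
    blocked = frozenset(blocked)
    if not blocked:
        return True
    return all(solver.reachable(i, o, blocked=blocked) for i, o in wild_pairs)


def _assign_positions(results: list[KnockoutResult]) -> dict[str, int]:
    """Competition (min) ranking by descending dL; ties share the best rank."""
    scored = [(r.reaction, r.delta_L) for r in results if r.delta_L is not None]
    positions = {}
    for rid, d in scored:
        positions[rid] = 1 + sum(1 for _, other in scored if other > d)
    return positions


def scan_knockouts(
    network: MetabolicNetwork,
    arcs: CarbonArcTable,
    source: str,
    direction: str = ACCUMULATION,
    rank_nonviable: bool = False,
    solver: CfpSolver | None = None,
    big_M: float = 1000.0,
    time_limit: float | None = 60.0,
    wild: ConnectivityCurve | None = None,
) -> RankingTable:
    """Knock out each internal reaction in turn and rank by dL.

    The wild-type curve is computed once and reused. Rows are ordered by
    descending dL with lexicographic reaction-id tie-break for display;
    positions use competition ranking over the viable knockouts (all
    knockouts when ``rank_nonviable``).
    """
    if solver is None:
        solver = CfpSolver(network, arcs, big_M=big_M, time_limit=time_limit)
    if wild is None:
        wild = connectivity_curve(
            network, arcs, source, direction=direction, solver=solver, time_limit=time_limit
        )
    wild_pairs = wildtype_io_pairs(network, arcs, solver)
    results: list[KnockoutResult] = []
    for rid in network.internal_original_ids:
        name = network.original_reaction(rid).name
        blocked = frozenset({rid})
        viable = viability_filter(network, arcs, blocked, solver=solver, wild_pairs=wild_pairs)
        ko = connectivity_curve(
            network, arcs, source, direction=direction, blocked=blocked,
            solver=solver, time_limit=time_limit,
        )
        try:
            d, lk, lw, disc = delta_L(wild, ko)
            results.append(
                KnockoutResult(
                    reaction=rid,
                    name=name,
                    delta_L=float(d),
                    L_knockout=float(lk),
                    L_wildtype_restricted=float(lw),
                    disconnected=disc,
                    viable=viable,
                    undetermined=ko.undetermined,
                )
            )
        except FullDisconnectionError:
            results.append(
                KnockoutResult(
                    reaction=rid,
                    name=name,
                    delta_L=None,
                    L_knockout=None,
                    L_wildtype_restricted=None,
                    disconnected=wild.connected,
                    viable=viable,
                    undetermined=ko.undetermined,
                    fully_disconnecting=True,
                )
            )
    eligible = results if rank_nonviable else [r for r in results if r.viable]
    positions = _assign_positions(eligible)
    ordered = sorted(
        results,
        key=lambda r: (
            r.delta_L is None,
            -(r.delta_L if r.delta_L is not None else 0.0),
            r.reaction,
        ),
    )
    return RankingTable(
        source=source, direction=direction, rows=tuple(ordered), positions=positions
    )
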
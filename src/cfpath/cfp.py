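"""Carbon Flux Path (CFP) solver.

A CFP between a source metabolite alpha and a target beta is the shortest
simple directed path in the carbon-exchange graph that can operate inside a
nonnegative steady-state flux distribution of the full stoichiometric
network. The search is a mixed-integer linear program with three variable
groups:

* ``u_ij``  (binary)      arc (i, j) is on the path
* ``z_r``   (binary)      post-split reaction r is active
* ``v_r``   (continuous)  flux through r, with ``z_r <= v_r <= M z_r``

Constraints: unit out-degree at the source and in-degree at the target, no
arc into the source or out of the target, flow conservation and a visit
limit of one at every node (the path is simple), steady-state mass balance
``S v = 0`` over *all* metabolites (hubs included), mutual exclusion of the
two halves of a split reversible reaction, and arc/flux linking: an active
arc requires an active supporting reaction. The objective minimises the
number of arcs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import sparse

from .milp import (
    DEFAULT_BACKEND,
    INFEASIBLE,
    OPTIMAL,
    UNDETERMINED,
    MilpBackend,
    MilpProblem,
    UndeterminedError,
)
from .network import CarbonArcTable, MetabolicNetwork, ValidationError, carbon_graph

STATUS_OPTIMAL = "optimal"
STATUS_INFEASIBLE = "infeasible"


@dataclass(frozen=True)
class CfpProblem:
    network: MetabolicNetwork
    arcs: CarbonArcTable
    source: str
    target: str
    blocked_reactions: frozenset[str] = frozenset()
    big_M: float = 1000.0


@dataclass(frozen=True)
class CfpSolution:
    status: str
    length: int | None = None
    path: tuple[str, ...] = ()
    active_reactions: frozenset[str] = frozenset()
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == STATUS_OPTIMAL


_INFEASIBLE = CfpSolution(status=STATUS_INFEASIBLE)


class CfpSolver:
    """Reusable CFP solver for one (network, arc table) pair.

    The constraint matrix is assembled once; individual solves only swap the
    source/target right-hand sides and variable bounds, which makes the many
    solves of a connectivity curve or knockout scan cheap.
    """

    def __init__(
        self,
        network: MetabolicNetwork,
        arcs: CarbonArcTable,
        big_M: float = 1000.0,
        time_limit: float | None = 60.0,
        backend: MilpBackend | None = None,
    ):
        self.network = network
        self.arcs = arcs
        self.big_M = float(big_M)
        self.time_limit = time_limit
        self.backend = backend or DEFAULT_BACKEND
        self.graph = carbon_graph(arcs)

        support = arcs.support()
        self._arc_list: list[tuple[str, str]] = sorted(support)
        self._arc_index = {a: k for k, a in enumerate(self._arc_list)}
        self._nodes = sorted(self.graph.nodes)
        rxn_ids = [r.id for r in network.reactions]
        self._rxn_index = {rid: j for j, rid in enumerate(rxn_ids)}
        self._rxn_ids = rxn_ids

        n_u = len(self._arc_list)
        n_r = len(rxn_ids)
        self.n_u, self.n_r = n_u, n_r
        self._z0 = n_u
        self._v0 = n_u + n_r
        n_var = n_u + 2 * n_r

        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []
        row_lb: list[float] = []
        row_ub: list[float] = []
        inf = np.inf

        def add_row(entries: list[tuple[int, float]], lb: float, ub: float) -> None:
            i = len(row_lb)
            for c, v in entries:
                rows.append(i)
                cols.append(c)
                vals.append(v)
            row_lb.append(lb)
            row_ub.append(ub)

        in_arcs = {n: [] for n in self._nodes}
        out_arcs = {n: [] for n in self._nodes}
        for k, (i, j) in enumerate(self._arc_list):
            out_arcs[i].append(k)
            in_arcs[j].append(k)
        self._in_arcs, self._out_arcs = in_arcs, out_arcs

        # flow conservation: in(k) - out(k) = b_k (b set per solve)
        self._conservation_row = {}
        for n in self._nodes:
            self._conservation_row[n] = len(row_lb)
            add_row(
                [(k, 1.0) for k in in_arcs[n]] + [(k, -1.0) for k in out_arcs[n]],
                0.0,
                0.0,
            )
        # visit limit: in(k) <= 1
        for n in self._nodes:
            add_row([(k, 1.0) for k in in_arcs[n]], -inf, 1.0)
        self._balance_start = len(row_lb)
        # steady state: S v = 0 for every metabolite (hubs included)
        S, met_index, _ = network.stoichiometric_matrix()
        S = S.tocoo()
        for r_, c_, v_ in zip(S.row, S.col, S.data):
            rows.append(self._balance_start + int(r_))
            cols.append(self._v0 + int(c_))
            vals.append(float(v_))
        for _ in range(len(network.metabolites)):
            row_lb.append(0.0)
            row_ub.append(0.0)
        # activity linking: z_r <= v_r <= M z_r
        for j in range(n_r):
            add_row([(self._v0 + j, 1.0), (self._z0 + j, -1.0)], 0.0, inf)
        for j in range(n_r):
            add_row([(self._v0 + j, 1.0), (self._z0 + j, -self.big_M)], -inf, 0.0)
        # reverse exclusivity: z_f + z_b <= 1
        for pair in sorted(network.reverse_pairs, key=sorted):
            a, b = sorted(pair)
            add_row(
                [(self._z0 + self._rxn_index[a], 1.0), (self._z0 + self._rxn_index[b], 1.0)],
                -inf,
                1.0,
            )
        # arc support: sum_{r in support(i,j)} z_r >= u_ij
        for k, a in enumerate(self._arc_list):
            entries = [(self._z0 + self._rxn_index[r], 1.0) for r in sorted(support[a])]
            entries.append((k, -1.0))
            add_row(entries, 0.0, inf)
        self._mass_balance_rows = slice(self._balance_start, len(row_lb))

        self._A = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(row_lb), n_var)
        )
        self._row_lb = np.asarray(row_lb)
        self._row_ub = np.asarray(row_ub)
        lb = np.zeros(n_var)
        ub = np.ones(n_var)
        ub[self._v0 :] = self.big_M
        self._lb, self._ub = lb, ub
        integrality = np.zeros(n_var)
        integrality[: self._v0] = 1
        self._integrality = integrality
        self._objective = np.zeros(n_var)
        self._objective[:n_u] = 1.0

    # ------------------------------------------------------------------

    def _expand_blocked(self, blocked) -> list[str]:
        split: list[str] = []
        for oid in blocked:
            try:
                split.extend(self.network.split_ids(oid))
            except KeyError:
                raise ValidationError(f"unknown reaction to block: {oid!r}")
        return split

    def _restricted_graph(self, blocked_split: set[str]) -> nx.DiGraph:
        if not blocked_split:
            return self.graph
        g = nx.DiGraph()
        g.add_nodes_from(self.graph.nodes)
        for i, j, data in self.graph.edges(data=True):
            if data["reactions"] - blocked_split:
                g.add_edge(i, j)
        return g

    def bfs_distance(self, source: str, target: str, blocked=()) -> int | None:
        """Plain shortest-path length on the carbon graph (no mass balance)."""
        g = self._restricted_graph(set(self._expand_blocked(blocked)))
        try:
            return nx.shortest_path_length(g, source, target)
        except (nx.NetworkXNoPath, nx.NodeNotFound):
            return None

    def solve(
        self,
        source: str,
        target: str,
        blocked=(),
        feasibility_only: bool = False,
        relax_mass_balance: bool = False,
        time_limit: float | None = None,
    ) -> CfpSolution:
        """Solve one CFP instance.

        ``blocked`` holds *original* reaction ids; a knockout removes the
        enzyme, so both split halves are forced inactive. With
        ``relax_mass_balance`` the steady-state, linking and exclusivity
        constraints are dropped, reducing the program to plain shortest path.
        """
        if source == target:
            raise ValidationError("source and target metabolites must differ")
        for m, role in ((source, "source"), (target, "target")):
            if m not in self.graph:
                raise ValidationError(f"{role} metabolite {m!r} is not in the carbon graph")
        blocked_split = self._expand_blocked(blocked)

        if not relax_mass_balance:
            # sound pruning: topological unreachability implies CFP infeasibility
            if self.bfs_distance(source, target, blocked) is None:
                return _INFEASIBLE

        row_lb = self._row_lb.copy()
        row_ub = self._row_ub.copy()
        r = self._conservation_row[source]
        row_lb[r] = row_ub[r] = -1.0  # one arc leaves the source
        r = self._conservation_row[target]
        row_lb[r] = row_ub[r] = 1.0  # one arc enters the target
        ub = self._ub.copy()
        for k in self._in_arcs[source]:
            ub[k] = 0.0  # no arc enters the source
        for k in self._out_arcs[target]:
            ub[k] = 0.0  # no arc leaves the target
        if relax_mass_balance:
            row_lb[self._mass_balance_rows] = -np.inf
            row_ub[self._mass_balance_rows] = np.inf
        else:
            for rid in blocked_split:
                ub[self._z0 + self._rxn_index[rid]] = 0.0

        objective = np.zeros_like(self._objective) if feasibility_only else self._objective
        problem = MilpProblem(
            c=objective,
            A=self._A,
            row_lb=row_lb,
            row_ub=row_ub,
            lb=self._lb,
            ub=ub,
            integrality=self._integrality,
        )
        tl = self.time_limit if time_limit is None else time_limit
        res = self.backend.solve(problem, time_limit=tl)
        if res.status == INFEASIBLE:
            return _INFEASIBLE
        if res.status == UNDETERMINED:
            raise UndeterminedError(
                f"CFP {source} -> {target} undetermined within the time limit; "
                "not reporting disconnection"
            )
        assert res.status == OPTIMAL
        x = res.values
        active_arcs = [self._arc_list[k] for k in range(self.n_u) if x[k] > 0.5]
        succ = dict(active_arcs)
        path = [source]
        while path[-1] != target and path[-1] in succ:
            path.append(succ.pop(path[-1]))
        active = frozenset(
            self._rxn_ids[j] for j in range(self.n_r) if x[self._z0 + j] > 0.5
        )
        fluxes = {
            self._rxn_ids[j]: float(x[self._v0 + j])
            for j in range(self.n_r)
            if x[self._v0 + j] > 1e-9
        }
        if feasibility_only:
            return CfpSolution(
                status=STATUS_OPTIMAL,
                length=None,
                path=(),
                active_reactions=active,
                fluxes=fluxes,
            )
        return CfpSolution(
            status=STATUS_OPTIMAL,
            length=int(round(res.objective)),
            path=tuple(path),
            active_reactions=active,
            fluxes=fluxes,
        )

    def reachable(self, source: str, target: str, blocked=(), time_limit=None) -> bool:
        """True iff a mass-balanceable carbon path from source to target exists."""
        sol = self.solve(
            source, target, blocked=blocked, feasibility_only=True, time_limit=time_limit
        )
        return sol.optimal


def solve_cfp(
    problem: CfpProblem,
    time_limit: float | None = 60.0,
    backend: MilpBackend | None = None,
) -> CfpSolution:
    solver = CfpSolver(
        problem.network,
        problem.arcs,
        big_M=problem.big_M,
        time_limit=time_limit,
        backend=backend,
    )
    return solver.solve(problem.source, problem.target, blocked=problem.blocked_reactions)


def reachability(
    problem: CfpProblem,
    time_limit: float | None = 60.0,
    backend: MilpBackend | None = None,
) -> bool:
    solver = CfpSolver(
        problem.network,
        problem.arcs,
        big_M=problem.big_M,
        time_limit=time_limit,
        backend=backend,
    )
    return solver.reachable(problem.source, problem.target, blocked=problem.blocked_reactions)
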
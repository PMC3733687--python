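"""Independent brute-force oracle for shortest mass-balanced carbon paths.

Enumerates simple paths of the carbon graph in order of increasing length
(networkx) and checks each for steady-state embeddability with a small
standalone MILP over reaction activities only (no path variables): S v = 0,
z <= v <= M z, mutual exclusion of split halves, and at least one active
supporting reaction per path arc. The first embeddable path gives the
oracle distance; if enumeration exhausts without one, the pair is
disconnected. This shares no code path with cfpath's ILP formulation.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

BIG_M = 1000.0


def _support_map(network, arcs, blocked_split):
    sup = {}
    for i, j, r in arcs.arcs:
        if r not in blocked_split:
            sup.setdefault((i, j), set()).add(r)
    return sup


def _blocked_split(network, blocked):
    out = set()
    for oid in blocked:
        out.update(network.split_ids(oid))
    return out


def path_embeddable(network, arcs, path, blocked=(), big_m=BIG_M):
    """Can every arc of ``path`` be supported inside one steady-state flux?"""
    blocked_split = _blocked_split(network, blocked)
    sup = _support_map(network, arcs, blocked_split)
    rxn_ids = [r.id for r in network.reactions]
    ridx = {r: j for j, r in enumerate(rxn_ids)}
    n = len(rxn_ids)
    # variables: z (binary) then v (continuous)
    rows, cols, vals, lo, hi = [], [], [], [], []

    def add(entries, lb, ub):
        i = len(lo)
        for c, v in entries:
            rows.append(i)
            cols.append(c)
            vals.append(v)
        lo.append(lb)
        hi.append(ub)

    S, met_index, rxn_index = network.stoichiometric_matrix()
    S = S.tocoo()
    base = 0
    for r_, c_, v_ in zip(S.row, S.col, S.data):
        rows.append(base + int(r_))
        cols.append(n + int(c_))
        vals.append(float(v_))
    for _ in range(len(network.metabolites)):
        lo.append(0.0)
        hi.append(0.0)
    for j in range(n):
        add([(n + j, 1.0), (j, -1.0)], 0.0, np.inf)  # v >= z
        add([(n + j, 1.0), (j, -big_m)], -np.inf, 0.0)  # v <= M z
    for pair in network.reverse_pairs:
        a, b = sorted(pair)
        add([(ridx[a], 1.0), (ridx[b], 1.0)], -np.inf, 1.0)
    for i, j in zip(path, path[1:]):
        supp = sup.get((i, j), set())
        if not supp:
            return False
        add([(ridx[r], 1.0) for r in sorted(supp)], 1.0, np.inf)

    lb = np.zeros(2 * n)
    ub = np.concatenate([np.ones(n), np.full(n, big_m)])
    for r in blocked_split:
        ub[ridx[r]] = 0.0
    integrality = np.concatenate([np.ones(n), np.zeros(n)])
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(len(lo), 2 * n))
    res = milp(
        c=np.zeros(2 * n),
        constraints=[LinearConstraint(A, np.asarray(lo), np.asarray(hi))],
        integrality=integrality,
        bounds=Bounds(lb, ub),
    )
    if res.status == 0:
        return True
    if res.status == 2:
        return False
    raise RuntimeError(f"oracle MILP unexpected status {res.status}: {res.message}")


def oracle_distance(network, arcs, source, target, blocked=(), max_paths=100000):
    """Brute-force shortest embeddable simple-path length, or None."""
    blocked_split = _blocked_split(network, blocked)
    sup = _support_map(network, arcs, blocked_split)
    g = nx.DiGraph()
    g.add_nodes_from({m for pair in sup for m in pair})
    for (i, j) in sup:
        g.add_edge(i, j)
    if source not in g or target not in g or not nx.has_path(g, source, target):
        return None
    n_seen = 0
    for path in nx.shortest_simple_paths(g, source, target):
        n_seen += 1
        if n_seen > max_paths:
            raise RuntimeError("oracle path enumeration budget exhausted")
        if path_embeddable(network, arcs, path, blocked=blocked):
            return len(path) - 1
    return None
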
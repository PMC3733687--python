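"""Stoichiometric network representation and its carbon-exchange graph.

A metabolic network is stored *post-split*: every reversible reaction is
replaced by a forward/backward pair of irreversible reactions (suffixes
``_f``/``_b``), so that all flux variables are nonnegative. The pairs created
by splitting are recorded so the path solver can forbid a reaction and its
reverse from operating simultaneously.

Carbon arcs are the (substrate, product, reaction) triples stating which
substrate/product pairs of a reaction actually exchange carbon atoms. The
directed graph over these arcs is the search space for carbon flux paths;
hub metabolites (highly connected cofactors such as ATP or CoA) may be
excluded from the graph while their mass-balance rows are retained.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
from scipy import sparse


class ValidationError(ValueError):
    """Raised when an input violates a structural requirement."""


class ParseError(ValueError):
    """Raised when a network or arc file cannot be parsed."""


FORWARD_SUFFIX = "_f"
BACKWARD_SUFFIX = "_b"

#: Default hub metabolites whose carbon arcs are dropped at genome scale.
DEFAULT_HUBS = ("CoA", "CO2", "AMP", "ATP", "ADP")


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    is_hub: bool = False


@dataclass(frozen=True)
class Reaction:
    """A reaction with signed rational stoichiometry.

    Negative coefficients are substrates, positive are products. Exchange
    reactions are boundary fluxes with coefficients of a single sign.
    """

    id: str
    stoichiometry: Mapping[str, Fraction]
    reversible: bool = False
    is_exchange: bool = False
    name: str = ""

    def __post_init__(self):
        if not self.stoichiometry:
            raise ValidationError(f"reaction {self.id!r} has no participants")
        if any(c == 0 for c in self.stoichiometry.values()):
            raise ValidationError(f"reaction {self.id!r} has a zero coefficient")
        if self.is_exchange:
            signs = {c > 0 for c in self.stoichiometry.values()}
            if len(signs) > 1:
                raise ValidationError(
                    f"exchange reaction {self.id!r} must have single-signed coefficients"
                )

    @property
    def substrates(self) -> frozenset[str]:
        return frozenset(m for m, c in self.stoichiometry.items() if c < 0)

    @property
    def products(self) -> frozenset[str]:
        return frozenset(m for m, c in self.stoichiometry.items() if c > 0)

    def reversed(self, new_id: str) -> "Reaction":
        return Reaction(
            id=new_id,
            stoichiometry={m: -c for m, c in self.stoichiometry.items()},
            reversible=False,
            is_exchange=self.is_exchange,
            name=self.name,
        )


class MetabolicNetwork:
    """Post-split stoichiometric network.

    Parameters
    ----------
    metabolites:
        Metabolite declarations; ids must be unique.
    reactions:
        Pre-split reactions (reversible allowed). Splitting happens here.
    """

    def __init__(self, metabolites: Sequence[Metabolite], reactions: Sequence[Reaction]):
        ids = [m.id for m in metabolites]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate metabolite ids: {dup}")
        rids = [r.id for r in reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({i for i in rids if rids.count(i) > 1})
            raise ValidationError(f"duplicate reaction ids: {dup}")
        self.metabolites: tuple[Metabolite, ...] = tuple(metabolites)
        self._met_ids = {m.id for m in metabolites}
        for r in reactions:
            unknown = set(r.stoichiometry) - self._met_ids
            if unknown:
                raise ValidationError(
                    f"reaction {r.id!r} references unknown metabolites {sorted(unknown)}"
                )
        self.original_reactions: tuple[Reaction, ...] = tuple(reactions)
        self._original_by_id = {r.id: r for r in reactions}

        split: list[Reaction] = []
        reverse_pairs: set[frozenset[str]] = set()
        origin_map: dict[str, str] = {}
        for r in reactions:
            if r.reversible:
                fwd = Reaction(
                    id=r.id + FORWARD_SUFFIX,
                    stoichiometry=dict(r.stoichiometry),
                    reversible=False,
                    is_exchange=r.is_exchange,
                    name=r.name,
                )
                bwd = r.reversed(r.id + BACKWARD_SUFFIX)
                split.extend([fwd, bwd])
                reverse_pairs.add(frozenset({fwd.id, bwd.id}))
                origin_map[fwd.id] = r.id
                origin_map[bwd.id] = r.id
            else:
                split.append(
                    Reaction(
                        id=r.id,
                        stoichiometry=dict(r.stoichiometry),
                        reversible=False,
                        is_exchange=r.is_exchange,
                        name=r.name,
                    )
                )
                origin_map[r.id] = r.id
        self.reactions: tuple[Reaction, ...] = tuple(split)
        self._reaction_by_id = {r.id: r for r in split}
        self.reverse_pairs: frozenset[frozenset[str]] = frozenset(reverse_pairs)
        self.origin_map: dict[str, str] = origin_map
        self._split_ids: dict[str, tuple[str, ...]] = {}
        for sid, oid in origin_map.items():
            self._split_ids.setdefault(oid, ())
        for sid, oid in origin_map.items():
            self._split_ids[oid] = self._split_ids[oid] + (sid,)

    # -- lookups ---------------------------------------------------------

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_ids

    def reaction(self, rxn_id: str) -> Reaction:
        return self._reaction_by_id[rxn_id]

    def original_reaction(self, rxn_id: str) -> Reaction:
        return self._original_by_id[rxn_id]

    def split_ids(self, original_id: str) -> tuple[str, ...]:
        """Post-split reaction ids implementing an original reaction."""
        if original_id not in self._split_ids:
            raise KeyError(original_id)
        return self._split_ids[original_id]

    @property
    def internal_original_ids(self) -> tuple[str, ...]:
        """Original (pre-split) non-exchange reaction ids: the knockout universe."""
        return tuple(r.id for r in self.original_reactions if not r.is_exchange)

    @property
    def exchange_reactions(self) -> tuple[Reaction, ...]:
        return tuple(r for r in self.reactions if r.is_exchange)

    def medium_inputs(self) -> tuple[str, ...]:
        """Metabolites imported by exchange fluxes (medium)."""
        mets: list[str] = []
        for r in self.exchange_reactions:
            for m in sorted(r.products):
                if m not in mets:
                    mets.append(m)
        return tuple(mets)

    def excreted_outputs(self) -> tuple[str, ...]:
        """Metabolites exported by exchange fluxes."""
        mets: list[str] = []
        for r in self.exchange_reactions:
            for m in sorted(r.substrates):
                if m not in mets:
                    mets.append(m)
        return tuple(mets)

    def stoichiometric_matrix(self) -> tuple[sparse.csc_matrix, dict[str, int], dict[str, int]]:
        """Post-split S (metabolites x reactions) in float64, with index maps."""
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        rxn_index = {r.id: j for j, r in enumerate(self.reactions)}
        rows, cols, vals = [], [], []
        for r in self.reactions:
            j = rxn_index[r.id]
            for m, c in r.stoichiometry.items():
                rows.append(met_index[m])
                cols.append(j)
                vals.append(float(c))
        S = sparse.csc_matrix(
            (vals, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )
        return S, met_index, rxn_index


@dataclass(frozen=True)
class CarbonArcTable:
    """Per-reaction carbon-exchanging (substrate, product) pairs, post-split.

    Each triple ``(i, j, r)`` states that post-split reaction ``r`` transfers
    carbon from its substrate ``i`` to its product ``j``.
    """

    arcs: frozenset[tuple[str, str, str]]

    @staticmethod
    def from_original(
        network: MetabolicNetwork,
        triples: Iterable[tuple[str, str, str]],
        hub_ids: Iterable[str] = (),
    ) -> "CarbonArcTable":
        """Expand (substrate, product, original-reaction) triples to the split network.

        Arcs on a reversible reaction yield both the forward triple and the
        role-swapped backward triple. Triples touching a hub metabolite are
        dropped; exchange reactions may not carry arcs.
        """
        hubs = set(hub_ids)
        out: set[tuple[str, str, str]] = set()
        for sub, prod, rid in triples:
            if rid not in {r.id for r in network.original_reactions}:
                raise ValidationError(f"carbon arc references unknown reaction {rid!r}")
            orig = network.original_reaction(rid)
            if orig.is_exchange:
                raise ValidationError(f"exchange reaction {rid!r} cannot carry carbon arcs")
            for m in (sub, prod):
                if not network.has_metabolite(m):
                    raise ValidationError(f"carbon arc references unknown metabolite {m!r}")
            if sub == prod:
                raise ValidationError(f"self-arc {sub!r} on reaction {rid!r}")
            if sub not in orig.substrates or prod not in orig.products:
                raise ValidationError(
                    f"arc ({sub!r} -> {prod!r}) is not a substrate/product pair of {rid!r}"
                )
            if sub in hubs or prod in hubs:
                continue
            split = network.split_ids(rid)
            if orig.reversible:
                fwd = next(s for s in split if s.endswith(FORWARD_SUFFIX))
                bwd = next(s for s in split if s.endswith(BACKWARD_SUFFIX))
                out.add((sub, prod, fwd))
                out.add((prod, sub, bwd))
            else:
                out.add((sub, prod, rid))
        return CarbonArcTable(arcs=frozenset(out))

    def support(self) -> dict[tuple[str, str], frozenset[str]]:
        """Map arc (i, j) -> set of post-split reactions supporting it."""
        sup: dict[tuple[str, str], set[str]] = {}
        for i, j, r in self.arcs:
            sup.setdefault((i, j), set()).add(r)
        return {k: frozenset(v) for k, v in sup.items()}


def carbon_graph(table: CarbonArcTable) -> nx.DiGraph:
    """Directed metabolite graph; edge attribute ``reactions`` holds support."""
    g = nx.DiGraph()
    for (i, j), rxns in sorted(table.support().items()):
        g.add_edge(i, j, reactions=rxns)
    return g


# ---------------------------------------------------------------------------
# Native tabular format


_ARROWS = ("<->", "<=>", "->", "=>")


def parse_equation(text: str) -> tuple[dict[str, Fraction], bool]:
    """Parse ``"2 A + B -> C"`` into stoichiometry; returns (coeffs, reversible).

    One side may be empty (exchange fluxes): ``"-> D-Glc"`` or ``"Pyr ->"``.
    """
    arrow = None
    for a in _ARROWS:
        if a in text:
            arrow = a
            break
    if arrow is None:
        raise ParseError(f"no reaction arrow in equation {text!r}")
    lhs, rhs = text.split(arrow, 1)
    reversible = arrow in ("<->", "<=>")
    coeffs: dict[str, Fraction] = {}

    def add_side(side: str, sign: int) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ParseError(f"empty term in equation {text!r}")
            m = re.match(r"^(\d+(?:/\d+)?(?:\.\d+)?)\s+(.+)$", term)
            if m:
                coef = Fraction(m.group(1))
                met = m.group(2).strip()
            else:
                coef = Fraction(1)
                met = term
            coeffs[met] = coeffs.get(met, Fraction(0)) + sign * coef

    add_side(lhs, -1)
    add_side(rhs, +1)
    coeffs = {m: c for m, c in coeffs.items() if c != 0}
    if not coeffs:
        raise ParseError(f"equation {text!r} has no net stoichiometry")
    return coeffs, reversible


def format_equation(reaction: Reaction) -> str:
    def side(mets: Iterable[str], sign: int) -> str:
        parts = []
        for m in sorted(mets):
            c = reaction.stoichiometry[m] * sign
            parts.append(m if c == 1 else f"{c} {m}")
        return " + ".join(parts)

    arrow = "<->" if reaction.reversible else "->"
    return f"{side(reaction.substrates, -1)} {arrow} {side(reaction.products, 1)}".strip()


_REACTIONS_HEADER = ["id", "name", "equation", "reversible", "exchange"]
_ARCS_HEADER = ["reaction_id", "substrate_id", "product_id"]


def _read_tsv(path: Path, expected_header: list[str]) -> list[dict[str, str]]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    if header != expected_header:
        raise ParseError(f"{path}: expected header {expected_header}, got {header}")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(expected_header):
            raise ParseError(f"{path}:{lineno}: expected {len(expected_header)} fields")
        rows.append(dict(zip(expected_header, fields)))
    return rows


def _parse_flag(value: str, path: Path, lineno_hint: str) -> bool:
    v = value.strip().lower()
    if v in ("1", "true", "yes"):
        return True
    if v in ("0", "false", "no"):
        return False
    raise ParseError(f"{path}: bad boolean {value!r} in {lineno_hint}")


def load_native_reactions(path: str | Path) -> list[Reaction]:
    path = Path(path)
    rows = _read_tsv(path, _REACTIONS_HEADER)
    reactions = []
    for row in rows:
        coeffs, arrow_rev = parse_equation(row["equation"])
        reversible = _parse_flag(row["reversible"], path, row["id"])
        exchange = _parse_flag(row["exchange"], path, row["id"])
        reactions.append(
            Reaction(
                id=row["id"],
                stoichiometry=coeffs,
                reversible=reversible or arrow_rev,
                is_exchange=exchange,
                name=row["name"],
            )
        )
    return reactions


def load_network(path: str | Path, format: str = "native") -> MetabolicNetwork:
    """Load a network from the native reactions TSV or an SBML file.

    For the native format, metabolites are collected from the equations in
    order of first appearance.
    """
    if format == "native":
        reactions = load_native_reactions(path)
        seen: dict[str, None] = {}
        for r in reactions:
            for m in r.stoichiometry:
                seen.setdefault(m)
        mets = [Metabolite(id=m) for m in seen]
        return MetabolicNetwork(mets, reactions)
    if format == "sbml":
        return load_sbml(path)
    raise ValidationError(f"unknown network format {format!r}")


def load_sbml(path: str | Path) -> MetabolicNetwork:
    """Read an SBML Level 2/3 model (via cobrapy/libsbml).

    Reversibility is taken from flux bounds (lower bound < 0) and boundary
    fluxes from the model's boundary reactions.
    """
    import cobra.io

    model = cobra.io.read_sbml_model(str(path))
    mets = [
        Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "")
        for m in model.metabolites
    ]
    boundary = {r.id for r in model.boundary}
    reactions = []
    for r in model.reactions:
        coeffs = {
            m.id: Fraction(str(c)).limit_denominator(10**6)
            for m, c in r.metabolites.items()
        }
        reactions.append(
            Reaction(
                id=r.id,
                stoichiometry=coeffs,
                reversible=r.lower_bound < 0,
                is_exchange=r.id in boundary,
                name=r.name or "",
            )
        )
    return MetabolicNetwork(mets, reactions)


def write_native(network: MetabolicNetwork, path: str | Path) -> None:
    """Write the pre-split reaction list as the native reactions TSV."""
    lines = ["\t".join(_REACTIONS_HEADER)]
    for r in network.original_reactions:
        lines.append(
            "\t".join(
                [
                    r.id,
                    r.name,
                    format_equation(r),
                    "1" if r.reversible else "0",
                    "1" if r.is_exchange else "0",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_carbon_arcs(
    path: str | Path,
    network: MetabolicNetwork,
    hub_ids: Iterable[str] = (),
) -> CarbonArcTable:
    """Load the carbon-arc TSV (reaction_id, substrate_id, product_id)."""
    rows = _read_tsv(Path(path), _ARCS_HEADER)
    triples = [(r["substrate_id"], r["product_id"], r["reaction_id"]) for r in rows]
    return CarbonArcTable.from_original(network, triples, hub_ids=hub_ids)


def write_carbon_arcs(
    triples: Iterable[tuple[str, str, str]], path: str | Path
) -> None:
    """Write original-reaction arc triples (substrate, product, reaction)."""
    lines = ["\t".join(_ARCS_HEADER)]
    for sub, prod, rid in triples:
        lines.append("\t".join([rid, sub, prod]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
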
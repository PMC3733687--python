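"""Built-in test networks.

``toy_network`` builds the classical glycolysis / pentose-phosphate-pathway
network (19 internal reactions, a glucose input and CO2/R5P/pyruvate
outputs) together with its carbon-arc table. ``random_network`` generates
small reproducible networks for property testing.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from .network import CarbonArcTable, Metabolite, MetabolicNetwork, Reaction


class GenerationError(ValueError):
    """A random network cannot be generated for the requested sizes."""


_TOY_METABOLITES = [
    ("D-Glc", "D-Glucose"),
    ("G6P", "D-Glucose 6-phosphate"),
    ("F6P", "D-Fructose 6-phosphate"),
    ("FP2", "D-Fructose 1,6-bisphosphate"),
    ("DHAP", "Dihydroxyacetone phosphate"),
    ("GAP", "Glyceraldehyde 3-phosphate"),
    ("13BPG", "3-Phospho-D-glyceroyl phosphate"),
    ("3PG", "3-Phospho-D-glycerate"),
    ("2PG", "D-Glycerate 2-phosphate"),
    ("PEP", "Phosphoenolpyruvate"),
    ("Pyr", "Pyruvate"),
    ("GO6P", "6-phospho-D-glucono-1,5-lactone"),
    ("6PG", "6-Phospho-D-gluconate"),
    ("Ru5P", "D-Ribulose 5-phosphate"),
    ("Xyl5P", "D-Xylulose 5-phosphate"),
    ("R5P", "alpha-D-Ribose 5-phosphate"),
    ("Sed7P", "Sedoheptulose 7-phosphate"),
    ("Ery4P", "D-Erythrose 4-phosphate"),
    ("CO2", "Carbon dioxide"),
]

# (id, name, substrates, products, reversible); cofactors (ATP/NAD/...) are
# treated as external and omitted from the balance system, as usual for this
# classic example. Kinases, dehydrogenases and the lactonase are
# irreversible; the isomerase/aldolase/transferase steps are reversible.
_TOY_REACTIONS = [
    ("Hex1", "hexokinase", ["D-Glc"], ["G6P"], False),
    ("Pgi", "phosphoglucoisomerase", ["G6P"], ["F6P"], True),
    ("Pfk", "6-phosphofructokinase", ["F6P"], ["FP2"], False),
    ("Fbp", "fructose 1,6-bisphosphatase", ["FP2"], ["F6P"], False),
    ("Fba", "fructose 1,6-bisphosphate aldolase", ["FP2"], ["DHAP", "GAP"], True),
    ("TpiA", "triosephosphate isomerase", ["DHAP"], ["GAP"], True),
    ("Gap", "glyceraldehyde 3-phosphate dehydrogenase", ["GAP"], ["13BPG"], False),
    ("Pgk", "phosphoglycerate kinase", ["13BPG"], ["3PG"], False),
    ("Gpm", "phosphoglycerate mutase", ["3PG"], ["2PG"], False),
    ("Eno", "enolase", ["2PG"], ["PEP"], False),
    ("Pyk", "pyruvate kinase", ["PEP"], ["Pyr"], False),
    ("Zwf", "glucose 6-phosphate dehydrogenase", ["G6P"], ["GO6P"], False),
    ("Pgl", "phosphogluconolactonase", ["GO6P"], ["6PG"], False),
    ("Gnd", "phosphogluconate dehydrogenase", ["6PG"], ["Ru5P", "CO2"], False),
    ("Rpe", "ribulose-phosphate 3-epimerase", ["Ru5P"], ["Xyl5P"], True),
    ("Rpi", "ribose 5-phosphate isomerase", ["Ru5P"], ["R5P"], True),
    ("TktI", "transketolase", ["Xyl5P", "R5P"], ["Sed7P", "GAP"], True),
    ("Tal", "transaldolase", ["Sed7P", "GAP"], ["Ery4P", "F6P"], True),
    ("TktII", "transketolase", ["Xyl5P", "Ery4P"], ["F6P", "GAP"], True),
]

_TOY_EXCHANGES = [
    ("EX_DGlc", "D-glucose uptake", [], ["D-Glc"]),
    ("EX_Pyr", "pyruvate excretion", ["Pyr"], []),
    ("EX_CO2", "CO2 excretion", ["CO2"], []),
    ("EX_R5P", "ribose 5-phosphate excretion", ["R5P"], []),
]

# Carbon transfers per reaction (substrate -> product). Cofactor-side pairs
# carry no arc; the decarboxylation by Gnd transfers a carbon to CO2. The
# transketolase/transaldolase steps move a C2/C3 unit onto the acceptor and
# leave the donor backbone in the second product, so the donor feeds both
# products while the acceptor feeds only the elongated one.
TOY_CARBON_ARCS: tuple[tuple[str, str, str], ...] = (
    ("D-Glc", "G6P", "Hex1"),
    ("G6P", "F6P", "Pgi"),
    ("F6P", "FP2", "Pfk"),
    ("FP2", "F6P", "Fbp"),
    ("FP2", "DHAP", "Fba"),
    ("FP2", "GAP", "Fba"),
    ("DHAP", "GAP", "TpiA"),
    ("GAP", "13BPG", "Gap"),
    ("13BPG", "3PG", "Pgk"),
    ("3PG", "2PG", "Gpm"),
    ("2PG", "PEP", "Eno"),
    ("PEP", "Pyr", "Pyk"),
    ("G6P", "GO6P", "Zwf"),
    ("GO6P", "6PG", "Pgl"),
    ("6PG", "Ru5P", "Gnd"),
    ("6PG", "CO2", "Gnd"),
    ("Ru5P", "Xyl5P", "Rpe"),
    ("Ru5P", "R5P", "Rpi"),
    ("Xyl5P", "Sed7P", "TktI"),
    ("Xyl5P", "GAP", "TktI"),
    ("R5P", "Sed7P", "TktI"),
    ("Sed7P", "Ery4P", "Tal"),
    ("Sed7P", "F6P", "Tal"),
    ("GAP", "F6P", "Tal"),
    ("Xyl5P", "F6P", "TktII"),
    ("Xyl5P", "GAP", "TktII"),
    ("Ery4P", "F6P", "TktII"),
)


def toy_network(hub_ids=()) -> tuple[MetabolicNetwork, CarbonArcTable]:
    """The glycolysis/PPP example network and its carbon-arc table.

    No hub exclusion by default: CO2 is an ordinary, countable metabolite in
    this small network.
    """
    mets = [Metabolite(id=i, name=n, is_hub=i in set(hub_ids)) for i, n in _TOY_METABOLITES]
    reactions = []
    for rid, name, subs, prods, rev in _TOY_REACTIONS:
        stoich: dict[str, Fraction] = {}
        for m in subs:
            stoich[m] = Fraction(-1)
        for m in prods:
            stoich[m] = Fraction(1)
        reactions.append(
            Reaction(id=rid, stoichiometry=stoich, reversible=rev, is_exchange=False, name=name)
        )
    for rid, name, subs, prods in _TOY_EXCHANGES:
        stoich = {m: Fraction(-1) for m in subs}
        stoich.update({m: Fraction(1) for m in prods})
        reactions.append(
            Reaction(id=rid, stoichiometry=stoich, reversible=False, is_exchange=True, name=name)
        )
    network = MetabolicNetwork(mets, reactions)
    arcs = CarbonArcTable.from_original(network, TOY_CARBON_ARCS, hub_ids=hub_ids)
    return network, arcs


def random_network(
    n_metabolites: int,
    n_reactions: int,
    reversible_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[MetabolicNetwork, CarbonArcTable]:
    """A small random, connected, unit-stoichiometry network.

    A chain m0 -> m1 -> ... guarantees connectivity; remaining reactions are
    random 1->1, 2->1 or 1->2 conversions. The first metabolite has an input
    exchange and the last an output exchange. Every substrate/product pair
    of an internal reaction carries a carbon arc. Deterministic under
    ``seed``.
    """
    if n_metabolites < 2 or n_reactions < 1:
        raise GenerationError("need at least 2 metabolites and 1 reaction")
    if not 0.0 <= reversible_fraction <= 1.0:
        raise GenerationError("reversible_fraction must be in [0, 1]")
    if n_reactions < n_metabolites - 1:
        raise GenerationError(
            f"{n_reactions} reactions cannot connect {n_metabolites} metabolites"
        )
    rng = np.random.default_rng(seed)
    met_ids = [f"m{i}" for i in range(n_metabolites)]
    mets = [Metabolite(id=m) for m in met_ids]
    specs: list[tuple[list[str], list[str]]] = []
    for i in range(n_metabolites - 1):
        specs.append(([met_ids[i]], [met_ids[i + 1]]))
    while len(specs) < n_reactions:
        kind = rng.choice(["1to1", "2to1", "1to2"], p=[0.6, 0.2, 0.2])
        if kind == "1to1" or n_metabolites < 3:
            a, b = rng.choice(n_metabolites, size=2, replace=False)
            specs.append(([met_ids[a]], [met_ids[b]]))
        elif kind == "2to1":
            a, b, c = rng.choice(n_metabolites, size=3, replace=False)
            specs.append(([met_ids[a], met_ids[b]], [met_ids[c]]))
        else:
            a, b, c = rng.choice(n_metabolites, size=3, replace=False)
            specs.append(([met_ids[a]], [met_ids[b], met_ids[c]]))
    n_rev = int(round(reversible_fraction * n_reactions))
    rev_idx = set(rng.choice(n_reactions, size=n_rev, replace=False).tolist()) if n_rev else set()
    reactions = []
    triples: list[tuple[str, str, str]] = []
    for k, (subs, prods) in enumerate(specs):
        rid = f"r{k}"
        stoich = {m: Fraction(-1) for m in subs}
        stoich.update({m: Fraction(1) for m in prods})
        reactions.append(
            Reaction(id=rid, stoichiometry=stoich, reversible=k in rev_idx, is_exchange=False)
        )
        for s in subs:
            for p in prods:
                triples.append((s, p, rid))
    reactions.append(
        Reaction(id="EX_in", stoichiometry={met_ids[0]: Fraction(1)}, is_exchange=True)
    )
    reactions.append(
        Reaction(id="EX_out", stoichiometry={met_ids[-1]: Fraction(-1)}, is_exchange=True)
    )
    network = MetabolicNetwork(mets, reactions)
    arcs = CarbonArcTable.from_original(network, triples)
    return network, arcs
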
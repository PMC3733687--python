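"""Network representation: splitting, formats, carbon graph."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import null_space

from cfpath import (
    CarbonArcTable,
    Metabolite,
    MetabolicNetwork,
    ParseError,
    Reaction,
    ValidationError,
    carbon_graph,
    load_carbon_arcs,
    load_network,
    write_carbon_arcs,
    write_native,
)
from cfpath.fixtures import TOY_CARBON_ARCS, random_network, toy_network
from cfpath.network import format_equation, parse_equation


class TestSplitting:
    def test_toy_split_counts(self, toy):
        net, _ = toy
        internal = [r for r in net.reactions if not r.is_exchange]
        assert len(internal) == 27  # 19 originals, 8 reversible
        assert len(net.exchange_reactions) == 4
        assert len(net.reverse_pairs) == 8
        assert all(not r.reversible for r in net.reactions)

    def test_reverse_pairs_perfect_matching(self, toy):
        net, _ = toy
        halves = [rid for pair in net.reverse_pairs for rid in pair]
        assert len(halves) == len(set(halves))
        for pair in net.reverse_pairs:
            a, b = sorted(pair)
            assert net.origin_map[a] == net.origin_map[b]
            ra, rb = net.reaction(a), net.reaction(b)
            assert ra.stoichiometry == {m: -c for m, c in rb.stoichiometry.items()}

    def test_origin_map_total(self, toy):
        net, _ = toy
        assert set(net.origin_map) == {r.id for r in net.reactions}

    def test_irreversible_network_has_no_reverse_pairs(self):
        net, _ = random_network(5, 6, reversible_fraction=0.0, seed=3)
        assert net.reverse_pairs == frozenset()

    def test_splitting_preserves_steady_state_cone(self, toy):
        # a signed flux of the original network maps to a nonnegative flux of
        # the split network with the same balance, and vice versa
        net, _ = toy
        met_index = {m.id: i for i, m in enumerate(net.metabolites)}
        orig = net.original_reactions
        S_orig = np.zeros((len(net.metabolites), len(orig)))
        for j, r in enumerate(orig):
            for m, c in r.stoichiometry.items():
                S_orig[met_index[m], j] = float(c)
        S_split, _, rxn_index = net.stoichiometric_matrix()
        S_split = S_split.toarray()
        ns = null_space(S_orig)
        rng = np.random.default_rng(0)
        for _ in range(5):
            v = ns @ rng.normal(size=ns.shape[1])
            v_split = np.zeros(len(net.reactions))
            for j, r in enumerate(orig):
                if r.reversible:
                    v_split[rxn_index[r.id + "_f"]] = max(v[j], 0.0)
                    v_split[rxn_index[r.id + "_b"]] = max(-v[j], 0.0)
                else:
                    v_split[rxn_index[r.id]] = v[j]
            assert np.allclose(S_split @ v_split, 0.0, atol=1e-9)
        ns_split = null_space(S_split)
        for _ in range(5):
            w = ns_split @ rng.normal(size=ns_split.shape[1])
            net_flux = np.zeros(len(orig))
            for j, r in enumerate(orig):
                if r.reversible:
                    net_flux[j] = w[rxn_index[r.id + "_f"]] - w[rxn_index[r.id + "_b"]]
                else:
                    net_flux[j] = w[rxn_index[r.id]]
            assert np.allclose(S_orig @ net_flux, 0.0, atol=1e-9)

    def test_duplicate_ids_rejected(self):
        mets = [Metabolite(id="A"), Metabolite(id="A")]
        with pytest.raises(ValidationError, match="duplicate"):
            MetabolicNetwork(mets, [])


class TestCarbonArcs:
    def test_reversible_arc_role_swap(self, toy):
        _, arcs = toy
        assert ("G6P", "F6P", "Pgi_f") in arcs.arcs
        assert ("F6P", "G6P", "Pgi_b") in arcs.arcs

    def test_hub_arcs_dropped_but_balance_row_kept(self):
        net, arcs = toy_network(hub_ids=("CO2",))
        g = carbon_graph(arcs)
        assert "CO2" not in g
        S, met_index, _ = net.stoichiometric_matrix()
        assert "CO2" in met_index  # still mass balanced

    def test_empty_arc_table_valid(self, toy):
        net, _ = toy
        table = CarbonArcTable.from_original(net, [])
        assert table.arcs == frozenset()
        assert carbon_graph(table).number_of_edges() == 0

    @pytest.mark.parametrize(
        "triple, message",
        [
            (("G6P", "F6P", "NoSuchRxn"), "unknown reaction"),
            (("G6P", "Nope", "Pgi"), "unknown metabolite"),
            (("G6P", "G6P", "Pgi"), "self-arc"),
            (("F6P", "FP2", "Pgi"), "not a substrate/product pair"),
            (("Pyr", "Pyr", "EX_Pyr"), "exchange"),
        ],
    )
    def test_invalid_triples_rejected(self, toy, triple, message):
        net, _ = toy
        with pytest.raises(ValidationError, match=message):
            CarbonArcTable.from_original(net, [triple])

    def test_carbon_graph_support_annotations(self, toy):
        _, arcs = toy
        g = carbon_graph(arcs)
        assert g.edges["G6P", "GO6P"]["reactions"] == {"Zwf"}
        assert g.edges["6PG", "CO2"]["reactions"] == {"Gnd"}
        # GAP -> F6P is carried by the forward transaldolase half only
        assert g.edges["GAP", "F6P"]["reactions"] == {"Tal_f"}

    def test_single_triple_graph(self, toy):
        net, _ = toy
        table = CarbonArcTable.from_original(net, [("PEP", "Pyr", "Pyk")])
        g = carbon_graph(table)
        assert list(g.edges) == [("PEP", "Pyr")]


class TestNativeFormat:
    def test_round_trip(self, toy, tmp_path):
        net, arcs = toy
        write_native(net, tmp_path / "reactions.tsv")
        write_carbon_arcs(TOY_CARBON_ARCS, tmp_path / "arcs.tsv")
        net2 = load_network(tmp_path / "reactions.tsv", format="native")
        arcs2 = load_carbon_arcs(tmp_path / "arcs.tsv", net2)
        assert {r.id for r in net2.original_reactions} == {r.id for r in net.original_reactions}
        for r in net.original_reactions:
            r2 = net2.original_reaction(r.id)
            assert r2.stoichiometry == dict(r.stoichiometry)
            assert r2.reversible == r.reversible
            assert r2.is_exchange == r.is_exchange
        assert arcs2.arcs == arcs.arcs

    def test_bad_header_rejected(self, tmp_path):
        p = tmp_path / "reactions.tsv"
        p.write_text("id\tequation\n", encoding="utf-8")
        with pytest.raises(ParseError, match="header"):
            load_network(p, format="native")

    def test_malformed_equation_names_problem(self, tmp_path):
        p = tmp_path / "reactions.tsv"
        p.write_text(
            "id\tname\tequation\treversible\texchange\nr1\t\tA B C\t0\t0\n",
            encoding="utf-8",
        )
        with pytest.raises(ParseError, match="arrow"):
            load_network(p, format="native")


@st.composite
def reaction_strategy(draw):
    names = st.sampled_from([f"M{i}" for i in range(8)])
    subs = draw(st.lists(names, min_size=0, max_size=3, unique=True))
    prods = draw(
        st.lists(
            names.filter(lambda m: m not in subs), min_size=0 if subs else 1,
            max_size=3, unique=True,
        )
    )
    coeffs = {}
    for m in subs:
        coeffs[m] = -Fraction(draw(st.integers(1, 5)), draw(st.integers(1, 3)))
    for m in prods:
        coeffs[m] = Fraction(draw(st.integers(1, 5)), draw(st.integers(1, 3)))
    rev = draw(st.booleans()) and bool(subs) and bool(prods)
    exchange = not (subs and prods)
    return Reaction(id="r", stoichiometry=coeffs, reversible=rev, is_exchange=exchange)


@settings(derandomize=True, max_examples=60)
@given(reaction_strategy())
def test_equation_format_parse_round_trip(reaction):
    coeffs, rev = parse_equation(format_equation(reaction))
    assert coeffs == dict(reaction.stoichiometry)
    assert rev == reaction.reversible


class TestSbml:
    def test_sbml_load_and_native_round_trip(self, toy, tmp_path):
        import cobra

        net, _ = toy
        sid = lambda m: m.replace("-", "_")  # SBML SIds forbid dashes
        model = cobra.Model("toy")
        cmets = {
            m.id: cobra.Metabolite(sid(m.id), name=m.name, compartment="c")
            for m in net.metabolites
        }
        model.add_metabolites(list(cmets.values()))
        for r in net.original_reactions:
            cr = cobra.Reaction(r.id, name=r.name)
            model.add_reactions([cr])
            cr.add_metabolites({cmets[m]: float(c) for m, c in r.stoichiometry.items()})
            cr.lower_bound = -1000.0 if r.reversible else 0.0
            cr.upper_bound = 1000.0
        path = tmp_path / "toy.xml"
        cobra.io.write_sbml_model(model, str(path))
        loaded = load_network(path, format="sbml")
        assert len(loaded.original_reactions) == len(net.original_reactions)
        for r in net.original_reactions:
            lr = loaded.original_reaction(r.id)
            assert lr.reversible == r.reversible
            assert dict(lr.stoichiometry) == {sid(m): c for m, c in r.stoichiometry.items()}
        # boundary detection: pure-source/sink reactions are exchanges
        assert {r.id for r in loaded.original_reactions if r.is_exchange} == {
            "EX_DGlc", "EX_Pyr", "EX_CO2", "EX_R5P",
        }
        # native round trip preserves stoichiometry
        write_native(loaded, tmp_path / "native.tsv")
        again = load_network(tmp_path / "native.tsv", format="native")
        for r in loaded.original_reactions:
            assert dict(again.original_reaction(r.id).stoichiometry) == dict(r.stoichiometry)
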
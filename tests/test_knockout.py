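"""Knockout scan: dL computation, viability filter, ranking."""

from fractions import Fraction

import pytest

from cfpath import connectivity_curve, delta_L, scan_knockouts, viability_filter
from cfpath.knockout import FullDisconnectionError, wildtype_io_pairs
from cfpath.network import ValidationError


def mean_distance(distances, restrict):
    """Independent per-metabolite form of the average distance."""
    vals = [Fraction(distances[m]) for m in restrict]
    return sum(vals) / len(vals)


class TestDeltaL:
    @pytest.mark.parametrize("knockout", ["Pgi", "TpiA", "Pfk", "Rpe"])
    def test_cumulative_form_equals_per_metabolite_mean(
        self, toy, toy_solver, toy_wild_curve, knockout
    ):
        net, arcs = toy
        ko = connectivity_curve(net, arcs, "G6P", blocked={knockout}, solver=toy_solver)
        d, lk, lw, disc = delta_L(toy_wild_curve, ko)
        surviving = ko.connected
        assert lk == mean_distance(ko.distances, surviving)
        assert lw == mean_distance(toy_wild_curve.distances, surviving)
        assert d == lk - lw
        assert d >= 0

    def test_identical_curves_give_zero(self, toy_wild_curve):
        d, lk, lw, disc = delta_L(toy_wild_curve, toy_wild_curve)
        assert d == 0
        assert disc == frozenset()

    def test_tpia_knockout_averages_over_survivors(self, toy, toy_solver, toy_wild_curve):
        net, arcs = toy
        ko = connectivity_curve(net, arcs, "G6P", blocked={"TpiA"}, solver=toy_solver)
        d, lk, lw, disc = delta_L(toy_wild_curve, ko)
        assert disc == frozenset({"DHAP"})
        assert len(ko.connected) == 16

    def test_fully_disconnecting_knockout_raises(self, toy, toy_solver, toy_wild_curve):
        net, arcs = toy
        ko = connectivity_curve(net, arcs, "G6P", blocked={"Pgi", "Zwf"}, solver=toy_solver)
        assert ko.c_infinity == 0
        with pytest.raises(FullDisconnectionError):
            delta_L(toy_wild_curve, ko)

    def test_mismatched_curves_rejected(self, toy, toy_solver, toy_wild_curve):
        net, arcs = toy
        other = connectivity_curve(net, arcs, "F6P", solver=toy_solver)
        with pytest.raises(ValidationError, match="share source"):
            delta_L(toy_wild_curve, other)


class TestViabilityFilter:
    def test_wildtype_io_pairs(self, toy, toy_solver):
        net, arcs = toy
        pairs = wildtype_io_pairs(net, arcs, solver=toy_solver)
        assert set(pairs) == {("D-Glc", "Pyr"), ("D-Glc", "CO2"), ("D-Glc", "R5P")}

    def test_pyk_knockout_rejected(self, toy, toy_solver):
        net, arcs = toy
        assert viability_filter(net, arcs, {"Pyk"}, solver=toy_solver) is False

    def test_tpia_knockout_accepted(self, toy, toy_solver):
        net, arcs = toy
        assert viability_filter(net, arcs, {"TpiA"}, solver=toy_solver) is True

    def test_empty_block_set_is_viable(self, toy, toy_solver):
        net, arcs = toy
        assert viability_filter(net, arcs, set(), solver=toy_solver) is True


@pytest.fixture(scope="module")
def toy_ranking(toy, toy_solver):
    net, arcs = toy
    return scan_knockouts(net, arcs, "G6P", solver=toy_solver)


class TestScan:
    def test_pgi_tops_the_viable_ranking(self, toy_ranking):
        assert toy_ranking.positions["Pgi"] == 1
        best = max(r.delta_L for r in toy_ranking.ranked)
        assert toy_ranking.result("Pgi").delta_L == best

    def test_one_result_per_internal_reaction(self, toy, toy_ranking):
        net, _ = toy
        assert {r.reaction for r in toy_ranking.rows} == set(net.internal_original_ids)

    def test_nonviable_excluded_from_positions(self, toy_ranking):
        for row in toy_ranking.rows:
            if not row.viable:
                assert row.reaction not in toy_ranking.positions

    def test_rank_nonviable_flag_restores_them(self, toy, toy_solver):
        net, arcs = toy
        table = scan_knockouts(net, arcs, "G6P", rank_nonviable=True, solver=toy_solver)
        ranked = {r.reaction for r in table.rows if r.delta_L is not None}
        assert ranked <= set(table.positions)

    def test_ties_share_minimum_position(self, toy_ranking):
        by_delta = {}
        for r in toy_ranking.ranked:
            by_delta.setdefault(r.delta_L, []).append(r.reaction)
        for delta, group in by_delta.items():
            positions = {toy_ranking.positions[r] for r in group}
            assert len(positions) == 1  # tied dL means tied position
        # competition ranking: position = 1 + number of strictly better scores
        for r in toy_ranking.ranked:
            better = sum(1 for o in toy_ranking.ranked if o.delta_L > r.delta_L)
            assert toy_ranking.positions[r.reaction] == 1 + better

    def test_viable_deltas_nonnegative(self, toy_ranking):
        assert all(r.delta_L >= 0 for r in toy_ranking.ranked)

    def test_scan_is_deterministic(self, toy, toy_solver, toy_ranking):
        net, arcs = toy
        again = scan_knockouts(net, arcs, "G6P", solver=toy_solver)
        assert [(r.reaction, r.delta_L) for r in again.rows] == [
            (r.reaction, r.delta_L) for r in toy_ranking.rows
        ]
        assert again.positions == toy_ranking.positions

    def test_inert_knockout_scores_zero(self, toy_ranking):
        # Fbp participates in no wild-type shortest path or its balance
        row = toy_ranking.result("Fbp")
        assert row.viable
        assert row.delta_L == 0
        assert row.disconnected == frozenset()

    def test_export_columns(self, toy_ranking, tmp_path):
        frame = toy_ranking.to_frame()
        assert list(frame.columns) == [
            "reaction_id", "reaction_name", "delta_L", "position",
            "p_value", "viable", "n_disconnected",
        ]
        toy_ranking.write_csv(tmp_path / "ranking.csv")
        assert (tmp_path / "ranking.csv").exists()
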
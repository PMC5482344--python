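import numpy as np
import pytest

from dtnet import (
    ActivityRecord,
    BipartiteError,
    ConflictError,
    EdgeColoredNetwork,
    InteractionStatus,
    InvalidInputError,
    InvalidRecordError,
    assemble_full_adjacency,
    build_network,
    classify_activity,
    decompose,
    transpose,
)

from conftest import ACTIVE_MATRIX, random_networks

A = InteractionStatus.ACTIVE
I = InteractionStatus.INACTIVE
U = InteractionStatus.UNKNOWN


class TestClassifyActivity:
    @pytest.mark.parametrize(
        "value,threshold,direction,expected",
        [
            (0.5, 10, "at_most", A),
            (15, 10, "at_most", I),
            (10, 10, "at_most", A),  # boundary inclusive
            (12, 10, "at_least", A),
            (10, 10, "at_least", A),
            (0.5, 10, "at_least", I),
        ],
    )
    def test_comparator(self, value, threshold, direction, expected):
        assert classify_activity(value, threshold, direction) is expected

    @pytest.mark.parametrize("bad", [-1.0, float("nan"), float("inf")])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            classify_activity(bad, 10)
        with pytest.raises(InvalidInputError):
            classify_activity(1.0, bad)

    def test_never_returns_unknown(self):
        for v in np.linspace(0, 30, 13):
            assert classify_activity(float(v), 10) is not U


class TestActivityRecord:
    def test_requires_value_or_status(self):
        with pytest.raises(InvalidRecordError):
            ActivityRecord("d1", "t1")

    def test_labels_trimmed_and_nonempty(self):
        rec = ActivityRecord("  d1 ", " t1", status=A)
        assert (rec.drug_id, rec.target_id) == ("d1", "t1")
        with pytest.raises(InvalidRecordError):
            ActivityRecord("   ", "t1", status=A)

    def test_unit_conversion_to_micromolar(self):
        assert ActivityRecord("d", "t", value=500.0, unit="nM").value_in_um() == 0.5
        assert ActivityRecord("d", "t", value=0.02, unit="mM").value_in_um() == 20.0

    def test_negative_value_rejected(self):
        with pytest.raises(InvalidRecordError):
            ActivityRecord("d", "t", value=-3.0)


class TestBuildNetwork:
    def test_worked_example_from_determined_records(self, worked_example):
        # the 26 determined pairs alone, over the full 8x4 universe,
        # reproduce the fixture: the remaining 6 pairs are unknown-by-omission
        records = [r for r in worked_example.to_records() if r.status is not U]
        assert len(records) == 26
        net = build_network(
            records,
            drug_universe=worked_example.drugs,
            target_universe=worked_example.targets,
        )
        assert net == worked_example
        assert int((net.codes == -1).sum()) == 6

    def test_empty_records_all_unknown(self):
        net = build_network([], drug_universe=["d1", "d2"], target_universe=["t1", "t2"])
        assert (net.codes == -1).all()

    def test_value_records_classified_with_threshold(self):
        records = [
            ActivityRecord("d1", "t1", value=2.0),
            ActivityRecord("d1", "t2", value=50.0),
            ActivityRecord("d1", "t3", value=5000.0, unit="nM"),
        ]
        net = build_network(records, threshold=10.0, direction="at_most")
        assert net.status("d1", "t1") is A
        assert net.status("d1", "t2") is I
        assert net.status("d1", "t3") is A  # 5000 nM == 5 uM

    def test_value_and_status_must_agree(self):
        ok = ActivityRecord("d1", "t1", value=2.0, status=A)
        assert build_network([ok]).status("d1", "t1") is A
        with pytest.raises(InvalidRecordError):
            build_network([ActivityRecord("d1", "t1", value=2.0, status=I)])

    def test_conflict_policy_error(self):
        records = [
            ActivityRecord("d1", "t1", status=A),
            ActivityRecord("d1", "t1", status=I),
        ]
        with pytest.raises(ConflictError, match=r"\(d1, t1\)"):
            build_network(records)

    def test_conflict_policy_any_active(self):
        records = [
            ActivityRecord("d1", "t1", status=I),
            ActivityRecord("d1", "t1", status=A),
            ActivityRecord("d1", "t2", status=I),
            ActivityRecord("d1", "t2", status=U),
        ]
        net = build_network(records, conflict_policy="any_active")
        assert net.status("d1", "t1") is A
        assert net.status("d1", "t2") is I

    def test_conflict_policy_majority_ties_to_unknown(self):
        records = [
            ActivityRecord("d1", "t1", status=A),
            ActivityRecord("d1", "t1", status=A),
            ActivityRecord("d1", "t1", status=I),
            ActivityRecord("d1", "t2", status=A),
            ActivityRecord("d1", "t2", status=I),
        ]
        net = build_network(records, conflict_policy="majority")
        assert net.status("d1", "t1") is A
        assert net.status("d1", "t2") is U

    def test_duplicate_agreeing_records_are_not_conflicts(self):
        records = [ActivityRecord("d1", "t1", status=A)] * 3
        assert build_network(records).status("d1", "t1") is A

    def test_label_outside_universe_is_domain_error(self):
        records = [ActivityRecord("d9", "t1", status=A)]
        with pytest.raises(InvalidInputError, match="d9"):
            build_network(records, drug_universe=["d1"], target_universe=["t1"])

    def test_universe_order_wins_over_first_seen(self):
        records = [ActivityRecord("d2", "t2", status=A), ActivityRecord("d1", "t1", status=I)]
        net = build_network(records, drug_universe=["d1", "d2"], target_universe=["t1", "t2"])
        assert net.drugs == ("d1", "d2")
        assert net.targets == ("t1", "t2")
        first_seen = build_network(records)
        assert first_seen.drugs == ("d2", "d1")

    def test_missing_status_inactive_for_decoy_datasets(self):
        net = build_network(
            [ActivityRecord("d1", "t1", status=A)],
            drug_universe=["d1"],
            target_universe=["t1", "t2"],
            missing_status=I,
        )
        assert net.status("d1", "t2") is I

    def test_bipartite_collision_error_and_suffix_escape(self):
        records = [ActivityRecord("x", "x", status=A)]
        with pytest.raises(BipartiteError):
            build_network(records)
        net = build_network(records, collision_policy="suffix")
        assert net.drugs == ("x",)
        assert net.targets == ("x#target",)
        assert net.status("x", "x#target") is A

    def test_construction_is_deterministic(self):
        records = [
            ActivityRecord("d2", "t1", status=A),
            ActivityRecord("d1", "t2", value=3.0),
        ]
        assert build_network(records) == build_network(records)

    def test_round_trip_through_records(self):
        for net in random_networks(10, seed0=7):
            rebuilt = build_network(
                net.to_records(), drug_universe=net.drugs, target_universe=net.targets
            )
            assert rebuilt == net


class TestEdgeColoredNetwork:
    def test_label_invariants_enforced(self):
        with pytest.raises(InvalidInputError):
            EdgeColoredNetwork(("d1", "d1"), ("t1",), [[1], [0]])
        with pytest.raises(BipartiteError):
            EdgeColoredNetwork(("x",), ("x",), [[1]])
        with pytest.raises(InvalidInputError):
            EdgeColoredNetwork((), ("t1",), np.zeros((0, 1)))

    def test_codes_validated_and_frozen(self):
        with pytest.raises(InvalidInputError):
            EdgeColoredNetwork(("d1",), ("t1",), [[2]])
        net = EdgeColoredNetwork(("d1",), ("t1",), [[1]])
        with pytest.raises(ValueError):
            net.codes[0, 0] = 0


class TestTranspose:
    def test_worked_example_shape_and_status(self, worked_example):
        t = transpose(worked_example)
        assert t.shape == (4, 8)
        assert t.drugs == worked_example.targets
        for d in worked_example.drugs:
            for tj in worked_example.targets:
                assert t.status(tj, d) is worked_example.status(d, tj)

    def test_involution_on_random_networks(self):
        for net in random_networks(100, seed0=11):
            assert transpose(transpose(net)) == net

    def test_biadjacency_transposes_per_color(self, worked_example):
        sub = decompose(worked_example)
        sub_t = decompose(transpose(worked_example))
        assert np.array_equal(sub_t.a_plus, sub.a_plus.T)
        assert np.array_equal(sub_t.a_minus, sub.a_minus.T)
        assert np.array_equal(sub_t.a_star, sub.a_star.T)


class TestDecompose:
    def test_worked_example_active_matrix(self, worked_example):
        sub = decompose(worked_example)
        assert np.array_equal(sub.a_plus, ACTIVE_MATRIX)
        assert list(sub.a_plus.sum(axis=1)) == [3, 2, 1, 3, 2, 2, 4, 2]

    def test_all_active_network(self):
        net = EdgeColoredNetwork(("d1", "d2"), ("t1",), np.ones((2, 1)))
        sub = decompose(net)
        assert not sub.a_minus.any()
        assert not sub.a_star.any()

    def test_partition_invariant_on_random_networks(self):
        for net in random_networks(100, seed0=13):
            sub = decompose(net)
            assert (sub.a_plus + sub.a_minus + sub.a_star == 1).all()


def _edges_by_enumeration(biadjacency):
    """Brute-force oracle: the edge set of the bipartite graph, with target
    node indices offset by n."""
    n, m = biadjacency.shape
    return {
        (i, n + j)
        for i in range(n)
        for j in range(m)
        if biadjacency[i][j]
    }


class TestAssembleFullAdjacency:
    def test_worked_example_block_structure(self, worked_example):
        a_plus = decompose(worked_example).a_plus
        full = assemble_full_adjacency(a_plus)
        assert full.shape == (12, 12)
        assert np.array_equal(full, full.T)
        assert not full[:8, :8].any() and not full[8:, 8:].any()
        edges = {
            (i, j) for i in range(12) for j in range(i + 1, 12) if full[i, j]
        }
        assert edges == _edges_by_enumeration(a_plus)

    def test_zero_matrix(self):
        assert not assemble_full_adjacency(np.zeros((3, 2), dtype=int)).any()

    def test_row_sums_concatenate_input_margins(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            b = rng.integers(0, 2, size=(int(rng.integers(1, 8)), int(rng.integers(1, 8))))
            full = assemble_full_adjacency(b)
            expected = list(b.sum(axis=1)) + list(b.sum(axis=0))
            assert list(full.sum(axis=1)) == expected

    def test_non_binary_rejected(self):
        with pytest.raises(InvalidInputError):
            assemble_full_adjacency(np.array([[0, 2]]))
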
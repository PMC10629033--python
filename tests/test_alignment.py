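"""Similarity matrix, greedy pre-mapping, Jaccard refinement, full pipeline."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from layeralign import (
    EdgeRecord,
    MultilayerNetwork,
    SimilarityMatrix,
    align,
    build_similarity_matrix,
    cosine_similarity,
    identity_similarity,
    jaccard,
    node_correctness,
    pre_mapping,
    read_similarity_matrix,
    refine,
    write_similarity_matrix,
)
from layeralign.alignment import Alignment, AlignmentConfigError
from layeralign.embedding import embed_network

from conftest import FAST_EMBED


class TestCosine:
    def test_identity(self):
        assert cosine_similarity([1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine_similarity([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)

    def test_closed_form(self):
        assert cosine_similarity([1.0, 0.0], [1.0, 1.0]) == pytest.approx(
            1.0 / math.sqrt(2.0), abs=1e-5
        )

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0.0, 0.0], [1.0, 0.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cosine_similarity([1.0], [1.0, 2.0])


class TestSimilarityMatrix:
    def test_build_shape_and_bounds(self, toy_network):
        emb = embed_network(toy_network, FAST_EMBED)
        S = build_similarity_matrix(emb, emb)
        assert S.shape == (4, 4)
        assert np.all(S.values <= 1.0) and np.all(S.values >= -1.0)
        assert np.allclose(np.diag(S.values), 1.0)

    def test_dimension_mismatch(self, toy_network):
        from dataclasses import replace

        e1 = embed_network(toy_network, FAST_EMBED)
        e2 = embed_network(toy_network, replace(FAST_EMBED, dimensions=8))
        with pytest.raises(AlignmentConfigError):
            build_similarity_matrix(e1, e2)

    def test_file_round_trip(self, tmp_path):
        S = SimilarityMatrix(("v1", "v2"), ("u1", "u2"), [[0.9, 0.8], [0.7, 0.1]])
        path = tmp_path / "S.tsv"
        write_similarity_matrix(S, path)
        back = read_similarity_matrix(path)
        assert back.row_labels == S.row_labels
        assert back.col_labels == S.col_labels
        np.testing.assert_allclose(back.values, S.values)

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("\tu1\tu2\nv1\t0.5\toops\nv2\t0.1\t0.2\n")
        with pytest.raises(ValueError):
            read_similarity_matrix(path)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            SimilarityMatrix(("v1", "v1"), ("u1", "u2"), [[0.1, 0.2], [0.3, 0.4]])


def _greedy_oracle(S: SimilarityMatrix):
    """Hand-simulable descending-order greedy: an independent reference."""
    triples = [
        (S.values[i, j], S.row_labels[i], S.col_labels[j])
        for i in range(len(S.row_labels))
        for j in range(len(S.col_labels))
    ]
    triples.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_v, used_u, result = set(), set(), {}
    for s, v, u in triples:
        if v not in used_v and u not in used_u:
            result[v] = u
            used_v.add(v)
            used_u.add(u)
    return result


class TestPreMapping:
    def test_perfect_matching_matrix(self):
        S = identity_similarity(["a", "b", "c"], ["a", "b", "c"])
        aln = pre_mapping(S)
        assert aln.mapping == {"a": "a", "b": "b", "c": "c"}

    def test_greedy_consumes_best_first(self):
        S = SimilarityMatrix(("v1", "v2"), ("u1", "u2"), [[0.9, 0.8], [0.7, 0.1]])
        assert pre_mapping(S).mapping == {"v1": "u1", "v2": "u2"}

    def test_single_row_takes_argmax(self):
        S = SimilarityMatrix(("v",), ("a", "b", "c"), [[0.2, 0.9, 0.5]])
        assert pre_mapping(S).mapping == {"v": "b"}

    def test_matches_oracle_on_small_instances(self):
        """Exhaustive comparison with the hand-simulated greedy on <=6-node
        instances; the greedy need not be the globally optimal assignment,
        and on crafted instances it is not (asserted below)."""
        rng = np.random.default_rng(7)
        for n in range(2, 7):
            for _ in range(30):
                vals = np.round(rng.random((n, n)), 3)
                S = SimilarityMatrix(
                    tuple(f"v{i}" for i in range(n)),
                    tuple(f"u{j}" for j in range(n)),
                    vals,
                )
                assert pre_mapping(S).mapping == _greedy_oracle(S)

    def test_greedy_not_necessarily_optimal(self):
        S = SimilarityMatrix(("v1", "v2"), ("u1", "u2"), [[0.9, 0.8], [0.7, 0.1]])
        greedy_total = sum(s for _, _, s in pre_mapping(S).pairs)
        best_total = max(
            S.values[0, p[0]] + S.values[1, p[1]]
            for p in itertools.permutations(range(2))
        )
        assert greedy_total < best_total  # 1.0 < 1.5: greedy is not Hungarian

    def test_optimal_mode_maximises_total_similarity(self):
        S = SimilarityMatrix(("v1", "v2"), ("u1", "u2"), [[0.9, 0.8], [0.7, 0.1]])
        aln = pre_mapping(S, method="optimal")
        assert aln.mapping == {"v1": "u2", "v2": "u1"}
        assert sum(s for _, _, s in aln.pairs) == pytest.approx(1.5)
        with pytest.raises(AlignmentConfigError):
            pre_mapping(S, method="nope")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_one_to_one_invariant(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(1, 8)), int(rng.integers(1, 8))
        S = SimilarityMatrix(
            tuple(f"v{i}" for i in range(n)),
            tuple(f"u{j}" for j in range(m)),
            rng.random((n, m)),
        )
        aln = pre_mapping(S)
        assert len(aln) == min(n, m)
        assert len(set(aln.mapping.values())) == len(aln)


def _net(edge_pairs, layer=1, interlayer=9):
    return MultilayerNetwork(
        edges=frozenset(EdgeRecord(a, b, layer) for a, b in edge_pairs),
        layer_ids=(layer,),
        interlayer_id=interlayer,
    )


class TestJaccard:
    def test_identical_translated_sets(self):
        src = _net([("v", "a"), ("v", "b")])
        tgt = _net([("u", "x"), ("u", "y")])
        current = {"a": "x", "b": "y"}
        assert jaccard(src, tgt, "v", "u", current) == pytest.approx(1.0)

    def test_disjoint_sets(self):
        src = _net([("v", "a")])
        tgt = _net([("u", "x")])
        assert jaccard(src, tgt, "v", "u", {"a": "z", "z": "q"}) == 0.0

    def test_partial_overlap_closed_form(self):
        """Translated Γ(v) = {b,c,d}, Γ(u) = {c,d,e}: Jc = 2/4."""
        src = _net([("v", "p"), ("v", "q"), ("v", "r")])
        tgt = _net([("u", "c"), ("u", "d"), ("u", "e")])
        current = {"p": "b", "q": "c", "r": "d"}
        assert jaccard(src, tgt, "v", "u", current) == pytest.approx(0.5)

    def test_unmapped_neighbors_count_in_union_only(self):
        src = _net([("v", "p"), ("v", "q")])
        tgt = _net([("u", "x")])
        # p translates to x (intersection), q is unmapped (union only)
        assert jaccard(src, tgt, "v", "u", {"p": "x"}) == pytest.approx(0.5)

    def test_unknown_node_raises(self, toy_network):
        with pytest.raises(KeyError):
            jaccard(toy_network, toy_network, "zz", "a", {})


def _total_jc(net_a, net_b, aln):
    return sum(jaccard(net_a, net_b, v, u, aln) for v, u, _ in aln.pairs)


class TestRefine:
    def _crossed_case(self):
        """Two identical 4-node networks; a similarity matrix whose greedy
        pre-mapping crosses x and y, while Jaccard overlap disambiguates."""
        pairs = [("x", "a"), ("x", "b"), ("y", "c"), ("a", "c")]
        net = _net(pairs)
        truth = {n: n for n in net.nodes}
        rows = cols = tuple(sorted(net.nodes))
        vals = np.full((len(rows), len(cols)), 0.1)
        ri = {r: i for i, r in enumerate(rows)}
        for n in rows:  # true pairs score high...
            vals[ri[n], ri[n]] = 0.8
        # ...but (x,y) is the global maximum, so myopic greedy crosses x and
        # y even though the crossed total (0.95+0.55) is below the true total
        # (0.9+0.85) — the swap then raises both Jaccard and similarity
        vals[ri["x"], ri["x"]] = 0.9
        vals[ri["y"], ri["y"]] = 0.85
        vals[ri["x"], ri["y"]] = 0.95
        vals[ri["y"], ri["x"]] = 0.55
        S = SimilarityMatrix(rows, cols, vals)
        return net, truth, S

    def test_swap_restores_true_mapping(self):
        net, truth, S = self._crossed_case()
        pre = pre_mapping(S)
        assert pre.mapping["x"] == "y" and pre.mapping["y"] == "x"
        refined = refine(S, pre, net, net)
        assert refined.mapping == truth
        assert refined.permutations_used >= 1
        # exhaustive check over all 5! mappings: the true mapping attains the
        # maximum total Jaccard (self-symmetries of the graph may tie it)
        nodes = sorted(net.nodes)
        totals = [
            sum(
                jaccard(net, net, v, u, dict(zip(nodes, perm)))
                for v, u in zip(nodes, perm)
            )
            for perm in itertools.permutations(nodes)
        ]
        truth_total = sum(
            jaccard(net, net, v, truth[v], truth) for v in nodes
        )
        assert truth_total == pytest.approx(max(totals))

    def test_already_perfect_mapping_untouched(self):
        net = _net([("a", "b"), ("b", "c")])
        S = identity_similarity(net.nodes, net.nodes)
        pre = pre_mapping(S)
        refined = refine(S, pre, net, net)
        assert refined.permutations_used == 0
        assert refined.stop_reason == "all-overlapping"
        assert refined.mapping == pre.mapping

    def test_zero_budget_returns_pre(self):
        net, _, S = self._crossed_case()
        pre = pre_mapping(S)
        refined = refine(S, pre, net, net, max_permutations=0)
        assert refined.mapping == pre.mapping and refined.permutations_used == 0

    def test_negative_budget_rejected(self):
        net, _, S = self._crossed_case()
        with pytest.raises(AlignmentConfigError):
            refine(S, pre_mapping(S), net, net, max_permutations=-1)

    def test_total_jaccard_never_decreases(self, benchmark_network, rng):
        from layeralign.synthetic import perturb_edges

        net, _ = benchmark_network
        tgt = perturb_edges(net, 0.2, rng)
        emb_s = embed_network(net, FAST_EMBED)
        emb_t = embed_network(tgt, FAST_EMBED)
        S = build_similarity_matrix(emb_s, emb_t)
        pre = pre_mapping(S)
        refined = refine(S, pre, net, tgt)
        assert _total_jc(net, tgt, refined) >= _total_jc(net, tgt, pre) - 1e-9
        assert len(set(refined.mapping.values())) == len(refined)

    def test_budget_default_is_half_premapping(self, benchmark_network, rng):
        from layeralign.synthetic import perturb_edges

        net, _ = benchmark_network
        tgt = perturb_edges(net, 0.25, rng)
        emb_s = embed_network(net, FAST_EMBED)
        emb_t = embed_network(tgt, FAST_EMBED)
        S = build_similarity_matrix(emb_s, emb_t)
        refined = refine(S, pre_mapping(S), net, tgt)
        assert refined.permutations_used <= math.ceil(0.5 * len(refined))


class TestAlign:
    def test_identity_similarity_self_alignment(self, benchmark_network):
        net, truth = benchmark_network
        S = identity_similarity(net.nodes, net.nodes)
        aln = align(net, net, external_S=S)
        assert node_correctness(aln, truth) == 1.0
        assert all(s == 1.0 for _, _, s in aln.pairs)

    def test_external_similarity_label_mismatch(self, toy_network):
        S = identity_similarity(["wrong"], ["labels"])
        with pytest.raises(AlignmentConfigError):
            align(toy_network, toy_network, external_S=S)

    def test_source_larger_than_target_is_swapped(self):
        big = _net([("a", "b"), ("b", "c"), ("c", "d")])
        small = _net([("a", "b"), ("b", "c")])
        S = identity_similarity(small.nodes, big.nodes)
        aln = align(big, small, external_S=S.transpose())
        # |pairs| equals the smaller node set; mapping keys are big's nodes
        assert len(aln) == len(small.nodes)
        assert set(aln.mapping) <= big.nodes

    def test_full_pipeline_contract_under_noise(self, benchmark_network, rng):
        from layeralign.synthetic import perturb_edges

        net, truth = benchmark_network
        tgt = perturb_edges(net, 0.25, rng)
        aln = align(net, tgt, emb_cfg=FAST_EMBED)
        assert len(aln) == len(net.nodes)
        assert len(set(aln.mapping.values())) == len(aln)

    def test_alignment_tsv_round_trip(self, tmp_path):
        aln = Alignment(
            pairs=[("v1", "u2", 0.8), ("v2", "u1", 0.7)],
            jaccard_scores=[0.5, 1.0],
        )
        path = tmp_path / "aln.tsv"
        aln.write_tsv(path)
        back = Alignment.read_tsv(path)
        assert back.pairs == aln.pairs
        assert back.jaccard_scores == aln.jaccard_scores
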
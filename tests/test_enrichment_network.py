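"""Mode-overlap counting, permutation enrichment, network, metaclusters."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from metabmodes.enrichment_network import (assign_metaclusters, build_network,
                                           network_to_edge_table,
                                           observed_shared,
                                           permutation_enrichment)
from metabmodes.feature_tables import ValidationError
from metabmodes.pattern_analysis import ModePartition


def partition(dataset_id, labels: dict[str, str]) -> ModePartition:
    s = pd.Series(labels)
    return ModePartition(dataset_id=dataset_id, labels=s, medoids={},
                         k=int(s.nunique()))


def block_partition(dataset_id, sizes: dict[str, int], offset=0):
    labels = {}
    i = offset
    for mode, size in sizes.items():
        for _ in range(size):
            labels[f"f{i}"] = mode
            i += 1
    return partition(dataset_id, labels)


class TestObservedShared:
    def test_identical_partitions_diagonal(self):
        pa = block_partition("a", {"x": 3, "y": 2})
        pb = block_partition("b", {"x": 3, "y": 2})
        m = observed_shared(pa, pb)
        assert m.loc["x", "x"] == 3 and m.loc["y", "y"] == 2
        assert m.loc["x", "y"] == 0
        assert m.to_numpy().sum() == 5

    def test_marginals_are_mode_sizes(self):
        rng = np.random.default_rng(1)
        ids = [f"f{i}" for i in range(40)]
        pa = partition("a", dict(zip(ids, rng.choice(["m1", "m2", "m3"], 40))))
        pb = partition("b", dict(zip(ids, rng.choice(["n1", "n2"], 40))))
        m = observed_shared(pa, pb)
        assert m.sum(axis=1).to_dict() == pa.mode_sizes().to_dict()
        assert m.sum(axis=0).to_dict() == pb.mode_sizes().to_dict()

    def test_20_feature_toy(self):
        pa = block_partition("a", {"A": 10, "B": 10})
        pb = block_partition("b", {"X": 10, "Y": 10})
        assert observed_shared(pa, pb).loc["A", "X"] == 10

    def test_universe_mismatch_reported(self):
        pa = block_partition("a", {"A": 3})
        pb = block_partition("b", {"X": 3}, offset=1)
        with pytest.raises(ValidationError, match="symmetric"):
            observed_shared(pa, pb)


def overlap_toy(overlap=8):
    """20-feature universe, two modes of 10 per dataset, given overlap."""
    ids = [f"f{i}" for i in range(20)]
    pa = partition("a", {f: ("A" if i < 10 else "B") for i, f in enumerate(ids)})
    pb_labels = {}
    for i, f in enumerate(ids):
        in_x = (i < overlap) or (10 <= i < 20 - overlap)
        pb_labels[f] = "X" if in_x else "Y"
    return pa, partition("b", pb_labels)


class TestPermutationEnrichment:
    def test_converges_to_hypergeometric_tail(self):
        pa, pb = overlap_toy(overlap=8)
        res = permutation_enrichment(pa, pb, n_perm=10000, seed=42)
        assert res.observed.loc["A", "X"] == 8
        exact = hypergeom.sf(7, 20, 10, 10)          # P(X >= 8) ≈ 0.0115
        mc_se = np.sqrt(exact * (1 - exact) / 10000)
        assert res.p_values.loc["A", "X"] == pytest.approx(exact, abs=2 * mc_se)

    def test_estimator_floor(self):
        pa, pb = overlap_toy(overlap=10)             # maximum possible overlap
        res = permutation_enrichment(pa, pb, n_perm=200, seed=0)
        assert res.p_values.loc["A", "X"] >= 1 / 201
        assert res.p_values.loc["A", "X"] <= 5 / 201

    def test_reproducible_and_side_symmetric_null(self):
        pa, pb = overlap_toy(overlap=7)
        r1 = permutation_enrichment(pa, pb, n_perm=5000, seed=9)
        r2 = permutation_enrichment(pa, pb, n_perm=5000, seed=9)
        pd.testing.assert_frame_equal(r1.p_values, r2.p_values)
        # permuting the other side draws from the same null distribution
        r3 = permutation_enrichment(pb, pa, n_perm=5000, seed=10)
        assert r3.p_values.loc["X", "A"] == pytest.approx(
            r1.p_values.loc["A", "X"], abs=0.02)

    def test_type_one_error_calibrated(self):
        # independent random partitions: p-values should be uniform
        rng = np.random.default_rng(7)
        ids = [f"f{i}" for i in range(100)]
        hits = total = 0
        for rep in range(40):
            la = dict(zip(ids, rng.permutation(["m1"] * 50 + ["m2"] * 50)))
            lb = dict(zip(ids, rng.permutation(["n1"] * 50 + ["n2"] * 50)))
            res = permutation_enrichment(partition("a", la), partition("b", lb),
                                         n_perm=400, seed=int(rng.integers(2**31)))
            hits += int((res.p_values.to_numpy() < 0.05).sum())
            total += res.p_values.size
        assert 0.01 <= hits / total <= 0.10

    def test_rejects_bad_n_perm(self):
        pa, pb = overlap_toy()
        with pytest.raises(ValidationError):
            permutation_enrichment(pa, pb, n_perm=0)


class TestBuildNetwork:
    def test_identical_partitions_match(self):
        pa = block_partition("a", {"x": 15, "y": 12})
        pb = block_partition("b", {"x": 15, "y": 12})
        g = build_network([pa, pb], n_perm=500, seed=1)
        assert g.has_edge(("a", "x"), ("b", "x"))
        assert g.has_edge(("a", "y"), ("b", "y"))
        assert not g.has_edge(("a", "x"), ("b", "y"))

    def test_small_modes_excluded(self):
        pa = block_partition("a", {"x": 9, "y": 15})
        pb = block_partition("b", {"x": 9, "y": 15})
        g = build_network([pa, pb], min_mode_size=10, n_perm=200, seed=1)
        assert ("a", "x") not in g.nodes
        assert ("a", "y") in g.nodes

    def test_edge_table_export(self):
        pa = block_partition("a", {"x": 15, "y": 12})
        pb = block_partition("b", {"x": 15, "y": 12})
        g = build_network([pa, pb], n_perm=500, seed=1)
        edges = network_to_edge_table(g)
        assert set(edges.columns) == {"dataset_a", "mode_a", "dataset_b",
                                      "mode_b", "shared", "p_value"}
        assert (edges["p_value"] < 0.05).all()


class TestMetaclusters:
    def _toy_network(self):
        """Root culture mode C-a linked to env modes T-a, Z-a, G-a."""
        ids = [f"c{i}" for i in range(12)]
        culture = partition("culture", {
            **{f: "a" for f in ids[:8]}, **{f: "b" for f in ids[8:]}})
        env_ts = {}
        # compound c0: in T-a, Z-a (2 env modes) -> member
        # compound c1: in T-a only -> not a member
        # compound c2 is NOT in culture mode a
        transect = partition("transect", {
            "c0": "a", "c1": "a", "c2": "a",
            **{f: "b" for f in ids[3:]}})
        npsg = partition("npsg", {
            "c0": "a", "c1": "b", "c2": "a",
            **{f: "b" for f in ids[3:]}})
        gyre = partition("gyre", {
            "c0": "b", "c1": "b", "c2": "a",
            **{f: "b" for f in ids[3:]}})
        import networkx as nx
        g = nx.Graph()
        for node in [("culture", "a"), ("transect", "a"), ("npsg", "a"),
                     ("gyre", "a")]:
            g.add_node(node)
        g.add_edge(("culture", "a"), ("transect", "a"))
        g.add_edge(("culture", "a"), ("npsg", "a"))
        g.add_edge(("culture", "a"), ("gyre", "a"))
        return g, [culture, transect, npsg, gyre]

    def test_worked_examples(self):
        g, parts = self._toy_network()
        # move c2 out of the culture root mode
        parts[0].labels["c2"] = "b"
        mcs, unrooted = assign_metaclusters(g, parts, "culture")
        assert len(mcs) == 1 and not unrooted
        mc = mcs[0]
        assert mc.root == ("culture", "a")
        assert "c0" in mc.compounds      # root mode + 2 env modes
        assert "c1" not in mc.compounds  # only 1 env mode
        assert "c2" not in mc.compounds  # not in the root mode

    def test_unrooted_component_reported(self):
        g, parts = self._toy_network()
        g.remove_node(("culture", "a"))
        mcs, unrooted = assign_metaclusters(g, parts, "culture")
        assert mcs == []
        # the three env modes fall apart into three unrooted components
        assert len(unrooted) == 3
        assert all(n[0] != "culture" for comp in unrooted for n in comp)

    def test_compound_sets_disjoint_across_roots(self):
        rng = np.random.default_rng(3)
        ids = [f"f{i}" for i in range(60)]
        culture = partition("culture", dict(zip(ids, rng.choice(["a", "b"], 60))))
        env1 = partition("e1", dict(zip(ids, rng.choice(["a", "b"], 60))))
        env2 = partition("e2", dict(zip(ids, rng.choice(["a", "b"], 60))))
        g = build_network([culture, env1, env2], alpha=1.1, min_mode_size=1,
                          n_perm=50, seed=0)   # fully connected on purpose
        mcs, _ = assign_metaclusters(g, [culture, env1, env2], "culture")
        seen = set()
        for mc in mcs:
            assert not (seen & set(mc.compounds))
            seen |= set(mc.compounds)
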
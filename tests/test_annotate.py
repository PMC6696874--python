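import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from gficf.annotate import (
    UNASSIGNED,
    ReferencePanel,
    annotate_clusters,
    cluster_signature,
    enrichment_score,
    permutation_test,
    read_gmt,
    write_gmt,
)
from gficf.core import gficf_transform
from gficf.graph import Clustering


def es_oracle(genes, stats, gene_set, p):
    """Plain-python running-sum GSEA statistic, evaluated at every rank."""
    hits = [g in gene_set for g in genes]
    m = sum(hits)
    n = len(genes)
    norm = sum(abs(s) ** p for s, h in zip(stats, hits) if h)
    run, best = 0.0, 0.0
    for s, h in zip(stats, hits):
        if h:
            run += (abs(s) ** p) / norm if norm > 0 else 1.0 / m
        else:
            run -= 1.0 / (n - m)
        if abs(run) > abs(best):
            best = run
    return best


def ranked(n, rng):
    genes = np.array([f"g{i:03d}" for i in range(n)], dtype=object)
    stats = np.sort(rng.normal(size=n))[::-1]
    return genes, stats


class TestEnrichmentScore:
    def test_top_set_unweighted_is_one(self):
        genes, stats = ranked(10, np.random.default_rng(0))
        assert enrichment_score(genes, stats, set(genes[:3]), 0) == pytest.approx(1.0)

    def test_bottom_set_unweighted_is_minus_one(self):
        genes, stats = ranked(10, np.random.default_rng(0))
        assert enrichment_score(genes, stats, set(genes[-3:]), 0) == pytest.approx(-1.0)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_matches_running_sum_oracle(self, p):
        rng = np.random.default_rng(1)
        for _ in range(100):
            genes, stats = ranked(50, rng)
            gene_set = set(rng.choice(genes, size=8, replace=False))
            got = enrichment_score(genes, stats, gene_set, p)
            assert got == pytest.approx(es_oracle(genes, stats, gene_set, p), abs=1e-12)

    def test_empty_intersection_is_undefined(self):
        genes, stats = ranked(10, np.random.default_rng(2))
        with pytest.raises(ValueError, match="does not intersect"):
            enrichment_score(genes, stats, {"nope"}, 1)

    def test_invariant_to_relabeling_outside_set(self):
        genes, stats = ranked(30, np.random.default_rng(3))
        gene_set = set(genes[5:10])
        renamed = np.array(
            [g if g in gene_set else f"x_{g}" for g in genes], dtype=object
        )
        assert enrichment_score(genes, stats, gene_set, 1) == pytest.approx(
            enrichment_score(renamed, stats, gene_set, 1), abs=1e-15
        )


class TestPermutationTest:
    def test_null_pvalues_uniform(self):
        """Random signatures vs their own permutation null: p ~ U(0,1)."""
        rng = np.random.default_rng(4)
        ps = []
        for rep in range(200):
            genes, stats = ranked(200, rng)
            gene_set = set(rng.choice(genes, size=12, replace=False))
            _, _, p = permutation_test(
                genes, stats, gene_set, n_permutations=400, seed=rep
            )
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_deterministic_given_seed(self):
        genes, stats = ranked(100, np.random.default_rng(5))
        gene_set = set(genes[:10])
        r1 = permutation_test(genes, stats, gene_set, seed=42)
        r2 = permutation_test(genes, stats, gene_set, seed=42)
        assert r1 == r2

    def test_strong_enrichment_is_significant(self):
        genes, stats = ranked(300, np.random.default_rng(6))
        _, nes, p = permutation_test(
            genes, stats, set(genes[:15]), n_permutations=500, seed=0
        )
        assert nes > 1.5
        assert p <= 1 / 500 * 5


class TestClusterSignature:
    def test_single_cell_cluster_order(self, small_sim):
        _, m, _, _, _ = small_sim
        g = gficf_transform(m)
        c = Clustering(
            labels=np.zeros(1, dtype=int),
            cell_ids=g.cell_ids[:1],
            n_clusters=1,
            modularity=0.0,
        )
        sig = cluster_signature(g, c, size=50)[0]
        col = g.weights[:, 0].toarray().ravel()
        order = np.lexsort((g.gene_ids.astype(str), -col))
        expect = g.gene_ids[order[col[order] > 0][:50]]
        assert list(sig.genes) == list(expect)
        assert (np.diff(sig.scores) <= 1e-15).all()

    def test_tie_break_lexicographic(self):
        import scipy.sparse as sp

        from gficf.core import GficfMatrix

        w = np.array([[0.5, 0.5], [0.5, 0.5], [0.2, 0.2]])
        g = GficfMatrix(
            weights=sp.csc_matrix(w),
            gene_ids=np.array(["zz", "aa", "mm"], dtype=object),
            cell_ids=np.array(["c0", "c1"], dtype=object),
            icf=np.ones(3),
            n_cells_expressing=np.ones(3, dtype=int),
            n_cells=2,
        )
        c = Clustering(
            labels=np.zeros(2, dtype=int), cell_ids=g.cell_ids,
            n_clusters=1, modularity=0.0,
        )
        sig = cluster_signature(g, c)[0]
        assert list(sig.genes) == ["aa", "zz", "mm"]  # aa/zz tie at 1.0

    def test_unknown_cell_ids_error(self, small_sim):
        _, m, _, _, _ = small_sim
        g = gficf_transform(m)
        c = Clustering(
            labels=np.zeros(2, dtype=int),
            cell_ids=np.array(["ghost1", "ghost2"], dtype=object),
            n_clusters=1, modularity=0.0,
        )
        with pytest.raises(ValueError, match="unknown"):
            cluster_signature(g, c)

    def test_planted_markers_in_signature(self, small_sim):
        _, m, labels, marker_map, _ = small_sim
        g = gficf_transform(m)
        types = sorted(marker_map)
        lab_idx = np.array([types.index(t) for t in labels])
        c = Clustering(
            labels=lab_idx, cell_ids=m.cell_ids,
            n_clusters=len(types), modularity=0.0,
        )
        for sig, t in zip(cluster_signature(g, c, size=100), types):
            assert set(marker_map[t]) <= set(map(str, sig.genes))


class TestAnnotateClusters:
    def test_known_mapping_end_to_end(self, small_sim):
        _, m, labels, marker_map, panel = small_sim
        g = gficf_transform(m)
        types = sorted(marker_map)
        lab_idx = np.array([types.index(t) for t in labels])
        c = Clustering(
            labels=lab_idx, cell_ids=m.cell_ids,
            n_clusters=len(types), modularity=0.0,
        )
        sigs = cluster_signature(g, c)
        res = annotate_clusters(sigs, panel, n_permutations=200, seed=0)
        for q, t in enumerate(types):
            assert res.assigned_type[q] == t

    def test_disjoint_signature_unassigned(self, small_sim):
        *_, panel = small_sim
        from gficf.annotate import ClusterSignature

        sig = ClusterSignature(
            cluster_id=0,
            genes=np.array(["not_a_gene_1", "not_a_gene_2"], dtype=object),
            scores=np.array([2.0, 1.0]),
        )
        res = annotate_clusters([sig], panel, n_permutations=50)
        assert res.assigned_type[0] == UNASSIGNED
        assert res.table.empty

    def test_deterministic_given_seed(self, small_sim):
        _, m, labels, marker_map, panel = small_sim
        g = gficf_transform(m)
        types = sorted(marker_map)
        lab_idx = np.array([types.index(t) for t in labels])
        c = Clustering(
            labels=lab_idx, cell_ids=m.cell_ids,
            n_clusters=len(types), modularity=0.0,
        )
        sigs = cluster_signature(g, c)
        r1 = annotate_clusters(sigs, panel, n_permutations=100, seed=3)
        r2 = annotate_clusters(sigs, panel, n_permutations=100, seed=3)
        pd.testing.assert_frame_equal(r1.table, r2.table)


class TestPanelIo:
    def test_gmt_round_trip(self, tmp_path, small_sim):
        _, m, labels, marker_map, _ = small_sim
        g = gficf_transform(m)
        types = sorted(marker_map)
        lab_idx = np.array([types.index(t) for t in labels])
        c = Clustering(
            labels=lab_idx, cell_ids=m.cell_ids,
            n_clusters=len(types), modularity=0.0,
        )
        sigs = cluster_signature(g, c)
        write_gmt(sigs, tmp_path / "s.gmt")
        back = read_gmt(tmp_path / "s.gmt")
        assert [s.cluster_id for s in back] == [s.cluster_id for s in sigs]
        for a, b in zip(back, sigs):
            assert list(a.genes) == list(map(str, b.genes))

    def test_panel_needs_two_types(self):
        expr = pd.DataFrame(
            np.ones((5, 2)), index=[f"g{i}" for i in range(5)], columns=["a", "b"]
        )
        with pytest.raises(ValueError, match="2 cell types"):
            ReferencePanel(
                expression=expr,
                sample_cell_type=np.array(["t", "t"], dtype=object),
                cell_types=np.array(["t"], dtype=object),
            )
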
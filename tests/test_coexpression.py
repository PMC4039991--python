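"""Anchor screen, correlation matrices, and module/cell clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lymphosteroid import (
    ExpressionMatrix,
    GeneAnnotation,
    ScreenConfig,
    anchor_screen,
    cluster_cells,
    cluster_genes,
    gene_correlation_matrix,
    nominate_surface_markers,
    spearman_rho,
)
from lymphosteroid.coexpression import ConstantInputError, linkage_to_newick

from conftest import brute_force_spearman


class TestSpearmanRho:
    def test_identity_and_antitone(self):
        x = [1.0, 3.0, 2.0, 5.0, 4.0]
        assert spearman_rho(x, x)[0] == pytest.approx(1.0)
        assert spearman_rho(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_tie_heavy_example_matches_brute_force_oracle(self):
        # oracle (rank by sorting with explicit tie averaging, then Pearson)
        # gives exactly 0.5 for this tie-heavy pair
        x, y = [1, 2, 2, 4], [3, 1, 4, 4]
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(0.5, abs=1e-12)
        assert rho == pytest.approx(brute_force_spearman(x, y), abs=1e-12)

    def test_constant_vector_raises_typed_error(self):
        with pytest.raises(ConstantInputError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    def test_length_mismatch_and_short_input(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [1, 2, 3])
        with pytest.raises(ValueError, match="at least 3"):
            spearman_rho([1, 2], [2, 1])

    def test_permutation_p_reasonable(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho_a, p_asym = spearman_rho(x, y)
        rho_p, p_perm = spearman_rho(
            x, y, p_method="permutation", n_permutations=499, rng=np.random.default_rng(1)
        )
        assert rho_a == rho_p
        assert p_perm < 0.05 and p_asym < 0.05

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            # stay away from subnormals: cubing must keep distinct values
            # distinct for the transform to be strictly monotone in floats
            st.one_of(
                st.floats(min_value=0.25, max_value=50),
                st.floats(min_value=-50, max_value=-0.25),
                st.just(0.0),
            ),
            min_size=4,
            max_size=30,
        ).filter(lambda v: len(set(v)) > 1)
    )
    def test_invariance_under_strictly_monotone_transform(self, x):
        rng = np.random.default_rng(7)
        y = list(rng.normal(size=len(x)))
        rho_raw, _ = spearman_rho(x, y)
        rho_cubed, _ = spearman_rho([v**3 for v in x], y)  # strictly monotone map
        assert rho_raw == pytest.approx(rho_cubed, abs=1e-12)


def _screen_matrix(seed=0, n=60):
    """Anchor + one correlated gene + noise genes, with a constant and a
    nearly-all-zero gene to exercise the exclusion rules."""
    rng = np.random.default_rng(seed)
    anchor = rng.lognormal(1, 1, n)
    partner = np.argsort(np.argsort(anchor)) + rng.normal(0, 5, n) + 10.0
    partner -= partner.min()
    noise = rng.lognormal(1, 1, (3, n))
    constant = np.full(n, 2.0)
    sparse = np.zeros(n)
    sparse[:2] = 1.0
    values = np.vstack([anchor, anchor.copy(), partner, noise, constant, sparse])
    genes = ["Cyp11a1", "Twin", "Ly6C2", "N1", "N2", "N3", "Const", "Sparse"]
    return ExpressionMatrix(genes, [f"c{i}" for i in range(n)], values)


class TestAnchorScreen:
    def test_duplicated_anchor_ranks_first_with_rho_one(self):
        res = anchor_screen(_screen_matrix(), GeneAnnotation())
        assert res.records[0].gene == "Twin"
        assert res.records[0].rho == pytest.approx(1.0)
        assert "Twin" in res.screened_genes

    def test_exclusion_rules_recorded(self):
        res = anchor_screen(_screen_matrix(), GeneAnnotation())
        reasons = {e["gene"]: e["reason"] for e in res.excluded_genes}
        assert reasons == {"Const": "constant", "Sparse": "too_few_detected_cells"}
        assert all(r.gene not in reasons for r in res.records)

    def test_anchor_absent_or_constant_is_hard_error(self):
        m = _screen_matrix()
        with pytest.raises(ValueError, match="anchor gene 'Gata3' not present"):
            anchor_screen(m, GeneAnnotation(), ScreenConfig(anchor_gene="Gata3"))
        flat = ExpressionMatrix(
            ["Cyp11a1", "g"], ["a", "b", "c"], np.array([[1.0, 1.0, 1.0], [1, 2, 3]])
        )
        with pytest.raises(ValueError, match="constant"):
            anchor_screen(flat, GeneAnnotation())

    def test_records_sorted_by_rho_then_gene(self):
        res = anchor_screen(_screen_matrix(), GeneAnnotation())
        keys = [(-r.rho, r.gene) for r in res.records]
        assert keys == sorted(keys)

    def test_invariant_under_cell_permutation(self):
        m = _screen_matrix(seed=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.n_cells)
        mp = ExpressionMatrix(m.gene_ids, [m.cell_ids[i] for i in perm], m.values[:, perm])
        r1 = anchor_screen(m, GeneAnnotation())
        r2 = anchor_screen(mp, GeneAnnotation())
        for a, b in zip(r1.records, r2.records):
            assert a.gene == b.gene
            assert a.rho == pytest.approx(b.rho, abs=1e-12)

    def test_threshold_set_consistency(self):
        res = anchor_screen(_screen_matrix(seed=5), GeneAnnotation())
        cfg = res.config
        by_gene = {r.gene: r.rho for r in res.records}
        assert res.screened_genes == {g for g, r in by_gene.items() if r > cfg.screen_threshold}
        hi = max(cfg.screen_threshold, cfg.cell_cluster_threshold)
        assert res.cell_cluster_genes & res.screened_genes == {
            g for g, r in by_gene.items() if r > hi
        }
        assert res.anchor not in res.screened_genes | res.cell_cluster_genes

    def test_null_matrix_screen_size_matches_monte_carlo_tail(self):
        # independent noise: expected hits = n_genes * P(rho > 0.3), which is
        # vanishingly small at n=200 cells
        rng = np.random.default_rng(12)
        n_cells, n_genes = 200, 150
        values = rng.lognormal(1, 1, (n_genes + 1, n_cells))
        genes = ["Cyp11a1"] + [f"g{i}" for i in range(n_genes)]
        m = ExpressionMatrix(genes, [f"c{i}" for i in range(n_cells)], values)
        res = anchor_screen(m, GeneAnnotation())
        null_rhos = [
            spearman_rho(rng.normal(size=n_cells), rng.normal(size=n_cells))[0]
            for _ in range(500)
        ]
        p_tail = np.mean(np.array(null_rhos) > 0.3)
        expected = n_genes * p_tail
        sd = np.sqrt(max(expected, 1.0))
        assert len(res.screened_genes) <= expected + 4 * sd


class TestMarkerNomination:
    def _result(self, rhos):
        genes = list(rhos)
        n = 40
        rng = np.random.default_rng(8)
        anchor = rng.lognormal(1, 1, n)
        ranks = np.argsort(np.argsort(anchor)).astype(float)
        rows = [anchor]
        for g in genes:
            target = rhos[g]
            mix = target * ranks + (1 - target) * rng.normal(0, n / 3, n)
            rows.append(mix - mix.min())
        m = ExpressionMatrix(["Cyp11a1"] + genes, [f"c{i}" for i in range(n)], np.vstack(rows))
        ann = GeneAnnotation(
            {g: "surface_receptor" for g in genes if g.startswith(("Ly6", "S"))}
        )
        return anchor_screen(m, ann)

    def test_highest_rho_surface_receptor_tops_list(self):
        res = self._result({"Ly6C2": 0.9, "Ly6C1": 0.5, "Sx": 0.7, "Il10": 0.95})
        markers = nominate_surface_markers(res)
        assert markers[0].gene == "Ly6C2"
        assert [m.gene for m in markers] == sorted(
            [m.gene for m in markers], key=lambda g: -res.record(g).rho
        )

    def test_rank_four_with_three_stronger_surface_genes(self):
        res = self._result({"Ly6C1": 0.35, "S1": 0.9, "S2": 0.8, "S3": 0.7, "Il4": 0.6})
        markers = nominate_surface_markers(res)
        assert [m.gene for m in markers].index("Ly6C1") == 3

    def test_no_surface_receptors_gives_empty_list(self):
        res = self._result({"Il10": 0.9})
        assert nominate_surface_markers(res) == []


class TestGeneCorrelationMatrix:
    def test_identical_and_reversed_genes(self):
        x = np.array([1.0, 2, 3, 4, 5])
        m = ExpressionMatrix(
            ["a", "b", "c"], [f"c{i}" for i in range(5)], np.vstack([x, x, x[::-1]])
        )
        corr = gene_correlation_matrix(m)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_matches_pairwise_brute_force(self, small_matrix):
        corr = gene_correlation_matrix(small_matrix)
        for gi in small_matrix.gene_ids:
            for gj in small_matrix.gene_ids:
                expected = brute_force_spearman(
                    list(small_matrix.gene_values(gi)), list(small_matrix.gene_values(gj))
                )
                assert corr.loc[gi, gj] == pytest.approx(expected, abs=1e-12)

    def test_constant_gene_dropped_with_fewer_than_two_error(self):
        m = ExpressionMatrix(
            ["a", "b"], ["c1", "c2", "c3"], np.array([[1.0, 1, 1], [1, 2, 3]])
        )
        with pytest.raises(ValueError, match="at least 2 non-constant"):
            gene_correlation_matrix(m)


def _block_corr(rho_in=0.8, rho_out=0.0, size=5):
    import pandas as pd

    genes = [f"A{i}" for i in range(size)] + [f"B{i}" for i in range(size)]
    c = np.full((2 * size, 2 * size), rho_out)
    c[:size, :size] = rho_in
    c[size:, size:] = rho_in
    np.fill_diagonal(c, 1.0)
    return pd.DataFrame(c, index=genes, columns=genes)


class TestClusterGenes:
    def test_recovers_planted_blocks_exactly(self):
        corr = _block_corr()
        res = cluster_genes(corr, anchor="A0")
        assert res.anchor_module == {f"A{i}" for i in range(5)}
        blocks = {}
        for g, c in res.modules.items():
            blocks.setdefault(c, set()).add(g)
        assert sorted(map(sorted, blocks.values())) == [
            [f"A{i}" for i in range(5)],
            [f"B{i}" for i in range(5)],
        ]

    def test_anchor_module_includes_suppressor_pair_not_effector_trio(self):
        import pandas as pd

        genes = ["Cyp11a1", "Il10", "Tgfb1", "Il4", "Il5", "Il13"]
        c = np.eye(6)
        for i in range(3):  # anchor + suppressor pair
            for j in range(3):
                if i != j:
                    c[i, j] = 0.6
        for i in range(3, 6):  # effector trio
            for j in range(3, 6):
                if i != j:
                    c[i, j] = 0.6
        corr = pd.DataFrame(c, index=genes, columns=genes)
        res = cluster_genes(corr, anchor="Cyp11a1")
        assert res.anchor_module == {"Cyp11a1", "Il10", "Tgfb1"}

    def test_missing_anchor_is_error(self):
        with pytest.raises(ValueError, match="anchor gene 'X'"):
            cluster_genes(_block_corr(), anchor="X")

    def test_single_gene_is_error(self):
        import pandas as pd

        corr = pd.DataFrame([[1.0]], index=["Cyp11a1"], columns=["Cyp11a1"])
        with pytest.raises(ValueError, match="at least 2"):
            cluster_genes(corr, anchor="Cyp11a1")

    def test_partition_invariant_under_gene_permutation(self):
        corr = _block_corr(rho_in=0.7, rho_out=0.1)
        res = cluster_genes(corr, anchor="A0")
        rng = np.random.default_rng(4)
        perm = rng.permutation(corr.index)
        res_p = cluster_genes(corr.loc[perm, perm], anchor="A0")
        assert res.anchor_module == res_p.anchor_module

    def test_newick_export_contains_all_leaves(self):
        corr = _block_corr()
        res = cluster_genes(corr, anchor="A0")
        nwk = linkage_to_newick(res.gene_linkage, list(corr.index))
        assert nwk.endswith(";")
        for g in corr.index:
            assert g in nwk


class TestClusterCells:
    def test_separable_duplicate_pairs_split_exactly(self):
        vals = np.array(
            [[5.0, 5.0, 0.0, 0.0], [4.0, 4.0, 0.5, 0.5], [0.0, 0.0, 3.0, 3.0]]
        )
        m = ExpressionMatrix(["Cyp11a1", "g1", "g2"], ["a", "b", "c", "d"], vals)
        res = cluster_cells(m, ["g1", "g2"], anchor="Cyp11a1")
        part = res.cell_partition
        assert part["a"] == part["b"] != part["c"] == part["d"]
        assert res.anchor_cell_cluster == part["a"]
        assert res.anchor_detected_fraction_in_cluster == pytest.approx(1.0)

    def test_uniform_anchor_fraction_equals_cluster_share(self):
        rng = np.random.default_rng(2)
        vals = np.vstack([np.full(10, 3.0), rng.lognormal(1, 1, (3, 10))])
        m = ExpressionMatrix(
            ["Cyp11a1", "g1", "g2", "g3"], [f"c{i}" for i in range(10)], vals
        )
        res = cluster_cells(m, ["g1", "g2", "g3"], anchor="Cyp11a1")
        share = sum(
            1 for v in res.cell_partition.values() if v == res.anchor_cell_cluster
        ) / len(res.cell_partition)
        assert res.anchor_detected_fraction_in_cluster == pytest.approx(share)

    def test_empty_gene_set_error_advises_relaxation(self, small_matrix):
        with pytest.raises(ValueError, match="relax"):
            cluster_cells(small_matrix, [], anchor="g0")
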
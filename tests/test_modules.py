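"""Module detection: dendrogram, tree cut, eigengenes, merging, heatmap."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score

from _oracles import average_linkage_loop, first_pc_eig
from lncnet import DataError, ExpressionMatrix
from lncnet.modules import (
    ModulePartition,
    cluster_dendrogram,
    dendrogram_to_newick,
    dynamic_tree_cut,
    eigengene_heatmap_table,
    merge_close_modules,
    module_eigengenes,
)


def _tom_frame(arr, ids=None):
    arr = np.asarray(arr, dtype=float)
    ids = ids or [f"g{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=ids, columns=ids)


def _block_tom(sizes, within=0.8, between=0.05):
    n = sum(sizes)
    tom = np.full((n, n), between)
    start = 0
    for s in sizes:
        tom[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(tom, 1.0)
    return _tom_frame(tom)


def _log_expr(x):
    x = np.asarray(x, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(x, index=[f"g{i}" for i in range(x.shape[0])],
                     columns=[f"s{i}" for i in range(x.shape[1])]),
        scale="log2",
    )


class TestClusterDendrogram:
    def test_two_genes_merge_at_one_minus_tom(self):
        z = cluster_dendrogram(_tom_frame([[1.0, 0.3], [0.3, 1.0]]))
        assert z.shape == (1, 4)
        assert z[0, 2] == pytest.approx(0.7)

    def test_duplicated_gene_merges_first_at_zero(self):
        tom = _tom_frame([[1.0, 1.0, 0.2], [1.0, 1.0, 0.2], [0.2, 0.2, 1.0]])
        z = cluster_dendrogram(tom)
        assert z[0, 2] == pytest.approx(0.0)
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}

    def test_matches_naive_average_linkage(self):
        rng = np.random.default_rng(10)
        a = rng.random((10, 10))
        tom = np.clip((a + a.T) / 2, 0, 1)
        np.fill_diagonal(tom, 1.0)
        z = cluster_dendrogram(_tom_frame(tom))
        merges = average_linkage_loop(1.0 - tom)
        for row, (ma, mb, h, size) in zip(z, merges):
            assert {int(row[0]), int(row[1])} == {ma, mb}
            assert row[2] == pytest.approx(h, abs=1e-12)
            assert int(row[3]) == size

    def test_single_gene_rejected(self):
        with pytest.raises(DataError):
            cluster_dendrogram(_tom_frame([[1.0]]))


class TestDynamicTreeCut:
    def test_two_separated_blocks_recovered_exactly(self):
        tom = _block_tom([50, 50])
        z = cluster_dendrogram(tom)
        part = dynamic_tree_cut(z, 1.0 - tom, min_size=30)
        truth = [0] * 50 + [1] * 50
        assert part.n_modules == 2
        assert adjusted_rand_score(truth, part.labels.to_numpy()) == 1.0

    def test_block_below_min_size_unassigned(self):
        tom = _block_tom([10])
        z = cluster_dendrogram(tom)
        part = dynamic_tree_cut(z, 1.0 - tom, min_size=30)
        assert (part.labels == 0).all()

    def test_all_overlapping_genes_one_module(self):
        tom = _tom_frame(np.ones((40, 40)))
        z = cluster_dendrogram(tom)
        part = dynamic_tree_cut(z, 1.0 - tom, min_size=30)
        assert part.n_modules == 1
        assert (part.labels == 1).all()

    def test_min_size_above_gene_count_warns(self):
        tom = _block_tom([20])
        z = cluster_dendrogram(tom)
        with pytest.warns(UserWarning, match="unassigned"):
            part = dynamic_tree_cut(z, 1.0 - tom, min_size=50)
        assert (part.labels == 0).all()

    def test_labels_ordered_by_size(self):
        tom = _block_tom([35, 60])
        z = cluster_dendrogram(tom)
        part = dynamic_tree_cut(z, 1.0 - tom, min_size=30)
        sizes = part.module_sizes()
        assert sizes[1] == 60 and sizes[2] == 35

    def test_pam_stage_rescues_near_module_genes(self):
        # a 40-gene block with heterogeneous internal dissimilarity plus one
        # straggler that sits just inside the block's internal spread but
        # joins the dendrogram above the cut height
        rng = np.random.default_rng(21)
        n = 41
        diss = np.zeros((n, n))
        block = rng.uniform(0.05, 0.3, size=(40, 40))
        diss[:40, :40] = (block + block.T) / 2
        diss[40, :40] = diss[:40, 40] = 0.25
        np.fill_diagonal(diss, 0.0)
        tom = _tom_frame(1.0 - diss)
        z = cluster_dendrogram(tom)
        no_pam = dynamic_tree_cut(z, 1.0 - tom, min_size=30, cut_height=0.2,
                                  pam_stage=False)
        with_pam = dynamic_tree_cut(z, 1.0 - tom, min_size=30, cut_height=0.2,
                                    pam_stage=True, pam_quantile=0.95)
        assert no_pam.labels.iloc[40] == 0
        assert with_pam.labels.iloc[40] == 1
        assert (with_pam.labels.iloc[:40] == 1).all()


class TestModuleEigengenes:
    def _partition(self, labels):
        return ModulePartition(pd.Series(labels,
                                         index=[f"g{i}" for i in range(len(labels))]))

    def test_identical_genes_variance_explained_one(self):
        v = np.array([1.0, 4.0, 2.0, 6.0, 3.0])
        expr = _log_expr(np.tile(v, (4, 1)))
        eig = module_eigengenes(expr, self._partition([1, 1, 1, 1]))
        assert eig.variance_explained[1] == pytest.approx(1.0)
        prof = eig.profiles.loc[1].to_numpy()
        vs = (v - v.mean()) / v.std()
        np.testing.assert_allclose(prof, vs / np.linalg.norm(vs), atol=1e-12)

    def test_opposite_genes_orientation_rule(self):
        v = np.array([2.0, 5.0, 3.0, 7.0, 4.0])
        expr = _log_expr(np.vstack([v, 10.0 - v]))
        eig = module_eigengenes(expr, self._partition([1, 1]))
        assert eig.variance_explained[1] == pytest.approx(1.0)
        prof = eig.profiles.loc[1].to_numpy()
        # mean profile is exactly zero: tie resolves to + first nonzero entry
        assert prof[np.flatnonzero(prof)[0]] > 0

    def test_matches_principal_axis_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.random((20, 15)) * 6
        expr = _log_expr(x)
        eig = module_eigengenes(expr, self._partition([1] * 20))
        xs = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        oracle, var = first_pc_eig(xs)
        prof = eig.profiles.loc[1].to_numpy()
        sign = np.sign(prof @ oracle)
        np.testing.assert_allclose(prof, sign * oracle, atol=1e-8)
        assert eig.variance_explained[1] == pytest.approx(var, abs=1e-10)

    def test_singleton_module_uses_gene_profile(self):
        x = np.array([[1.0, 3.0, 2.0, 5.0]])
        eig = module_eigengenes(_log_expr(x), self._partition([1]))
        assert eig.variance_explained[1] == 1.0
        assert np.linalg.norm(eig.profiles.loc[1]) == pytest.approx(1.0)

    def test_profiles_unit_norm_and_varexp_in_unit_interval(self):
        rng = np.random.default_rng(12)
        expr = _log_expr(rng.random((30, 10)) * 5)
        eig = module_eigengenes(expr, self._partition([1] * 10 + [2] * 20))
        norms = np.linalg.norm(eig.profiles.to_numpy(), axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)
        assert ((eig.variance_explained > 0) & (eig.variance_explained <= 1)).all()


class TestMergeCloseModules:
    def _two_module_expr(self, shift, n_per=6, n_samp=24, seed=13):
        """Two planted modules whose trajectories differ by `shift` mixing."""
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 1, n_samp)
        e1 = np.sin(2 * np.pi * t)
        e2 = (1 - shift) * e1 + shift * np.cos(2 * np.pi * t)
        rows = [3 + e1 + rng.normal(0, 0.05, n_samp) for _ in range(n_per)]
        rows += [3 + e2 + rng.normal(0, 0.05, n_samp) for _ in range(n_per)]
        expr = _log_expr(np.vstack(rows))
        part = ModulePartition(
            pd.Series([1] * n_per + [2] * n_per, index=expr.gene_ids),
            min_module_size=2,
        )
        return expr, part

    def test_similar_eigengenes_merge(self):
        expr, part = self._two_module_expr(shift=0.05)
        eig = module_eigengenes(expr, part)
        merged, _ = merge_close_modules(expr, part, eig, cut_height=0.2)
        assert merged.n_modules == 1

    def test_distinct_eigengenes_not_merged(self):
        expr, part = self._two_module_expr(shift=1.0)
        eig = module_eigengenes(expr, part)
        merged, _ = merge_close_modules(expr, part, eig, cut_height=0.2)
        assert merged.n_modules == 2

    def test_chain_collapses_to_single_module(self):
        rng = np.random.default_rng(14)
        t = np.linspace(0, 1, 30)
        base = np.sin(2 * np.pi * t)
        shifts = [0.0, 0.12, 0.24]  # pairwise eigengene diss ~{small, small}
        rows, labels = [], []
        for m, s in enumerate(shifts, start=1):
            traj = (1 - s) * base + s * np.cos(2 * np.pi * t)
            for _ in range(5):
                rows.append(4 + traj + rng.normal(0, 0.03, len(t)))
                labels.append(m)
        expr = _log_expr(np.vstack(rows))
        part = ModulePartition(pd.Series(labels, index=expr.gene_ids),
                               min_module_size=2)
        eig = module_eigengenes(expr, part)
        merged, final_eig = merge_close_modules(expr, part, eig, cut_height=0.2)
        assert merged.n_modules == 1

    def test_post_merge_no_pair_below_cut(self):
        rng = np.random.default_rng(15)
        expr = _log_expr(rng.random((40, 20)) * 5)
        part = ModulePartition(
            pd.Series(np.repeat([1, 2, 3, 4], 10), index=expr.gene_ids),
            min_module_size=5,
        )
        eig = module_eigengenes(expr, part)
        merged, final_eig = merge_close_modules(expr, part, eig, cut_height=0.4)
        if merged.n_modules > 1:
            corr = np.corrcoef(final_eig.profiles.to_numpy())
            diss = 1 - corr[~np.eye(len(corr), dtype=bool)]
            assert (diss >= 0.4).all()


class TestHeatmapTable:
    def _meta(self, n):
        rows = []
        ages = np.linspace(10, 35, n)
        for i, a in enumerate(ages):
            rows.append({"sample_id": f"s{i}", "structure": "neocortex",
                         "age": a, "age_unit": "pcw", "period": "prenatal"})
        return pd.DataFrame(rows)

    def test_shape_and_chronological_columns(self, default_dataset):
        from lncnet.modules import EigengeneSet

        expr, meta, _, truth = default_dataset
        eig = EigengeneSet(
            truth.eigengene_profiles.rename(index={"M1": 1, "M2": 2, "M3": 3,
                                                   "M4": 4, "M5": 5}),
            pd.Series(1.0, index=[1, 2, 3, 4, 5]),
        )
        table = eigengene_heatmap_table(eig, meta)
        assert table.table.shape == (5, expr.n_samples)
        days = {
            "prenatal": 0, "childhood": 1, "adulthood": 2,
        }
        periods = meta.set_index("sample_id")["period"]
        order = [days[periods[s]] for s in table.table.columns]
        assert order == sorted(order)

    def test_identical_rows_adjacent(self):
        from lncnet.modules import EigengeneSet

        rng = np.random.default_rng(16)
        base = rng.random(8)
        profiles = pd.DataFrame(
            [base, rng.random(8), base + 1e-9],
            index=[1, 2, 3],
            columns=[f"s{i}" for i in range(8)],
        )
        eig = EigengeneSet(profiles, pd.Series(1.0, index=[1, 2, 3]))
        table = eigengene_heatmap_table(eig, self._meta(8))
        order = table.row_order
        assert abs(order.index(1) - order.index(3)) == 1

    def test_planted_trajectories_fall_in_opposite_clades(self, default_dataset):
        """A prenatal-high eigengene clade and a postnatal-high clade
        separate at the top split of the row dendrogram."""
        from scipy.cluster import hierarchy as h

        from lncnet.modules import EigengeneSet

        _, meta, _, truth = default_dataset
        rng = np.random.default_rng(22)
        falling = truth.eigengene_profiles.iloc[0].to_numpy()
        rising = truth.eigengene_profiles.iloc[1].to_numpy()
        profiles = pd.DataFrame(
            [
                falling,
                falling + rng.normal(0, 0.2, falling.size),
                rising,
                rising + rng.normal(0, 0.2, rising.size),
            ],
            index=[1, 2, 3, 4],
            columns=truth.eigengene_profiles.columns,
        )
        eig = EigengeneSet(profiles, pd.Series(1.0, index=profiles.index))
        table = eigengene_heatmap_table(eig, meta)
        top_split = h.fcluster(table.row_linkage, t=2, criterion="maxclust")
        # linkage leaves follow the profiles' original order 1..4
        split = dict(zip(profiles.index, top_split))
        assert split[1] == split[2]
        assert split[3] == split[4]
        assert split[1] != split[3]


def test_newick_serialisation_parses():
    import io

    from Bio import Phylo

    tom = _block_tom([3, 3])
    z = cluster_dendrogram(tom)
    nwk = dendrogram_to_newick(z, tom.index)
    tree = Phylo.read(io.StringIO(nwk), "newick")
    assert sorted(leaf.name for leaf in tree.get_terminals()) == sorted(tom.index)
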
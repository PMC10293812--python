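import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode
from sklearn.metrics import adjusted_rand_score

from cochlea_atlas_kit.patterns import (
    celltype_similarity,
    cut_tree,
    hcluster,
    profile_matrix,
    to_newick,
    zscore_rows,
)


def _block_profiles(n_blocks, genes_per_block, n_cols=12, noise=0.05, seed=0):
    """Panel profile matrix with correlated blocks of genes."""
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n_blocks, n_cols))
    rows, truth = [], []
    for b in range(n_blocks):
        for g in range(genes_per_block):
            rows.append(base[b] + noise * rng.normal(size=n_cols))
            truth.append(b)
    index = [f"gene{b}_{g}" for b in range(n_blocks) for g in range(genes_per_block)]
    cols = pd.MultiIndex.from_product(
        [[f"t{j}" for j in range(n_cols // 2)], ["P8", "P20"]],
        names=["cell_type", "stage"],
    )
    return pd.DataFrame(rows, index=index, columns=cols), np.array(truth)


def test_profile_matrix_group_means():
    X = np.array([[0.0], [2.0], [4.0]])
    prof = profile_matrix(X, ["g"], ["A", "A", "A"], ["P8", "P8", "P8"], ["g"])
    assert prof.loc["g", ("A", "P8")] == pytest.approx(2.0)


def test_profile_matrix_reports_missing_genes():
    X = np.ones((2, 1))
    prof = profile_matrix(X, ["g"], ["A", "A"], ["P8", "P8"], ["g", "ghost"])
    assert prof.attrs["missing_genes"] == ["ghost"]
    assert list(prof.index) == ["g"]


def test_profile_matrix_empty_panel_rejected():
    with pytest.raises(ValueError):
        profile_matrix(np.ones((1, 1)), ["g"], ["A"], ["P8"], [])


def test_atlas_profiles_have_one_column_per_type_stage(atlas_annotation):
    norm, truth, annotation = atlas_annotation
    prof = profile_matrix(
        norm.X, list(norm.var_names), truth["true_type"].to_numpy(),
        norm.obs["stage"].to_numpy(), list(norm.var_names[:50]),
    )
    assert prof.shape[1] == 37  # 37 types x 1 stage simulated


def test_zscore_uses_population_sd():
    df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
    z = zscore_rows(df)
    np.testing.assert_allclose(z.loc["g"], [-1.22474487, 0.0, 1.22474487])


def test_zscore_constant_rows_flagged_as_zero():
    df = pd.DataFrame([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]], index=["c", "g"])
    z = zscore_rows(df)
    assert (z.loc["c"] == 0).all()
    assert z.attrs["constant_rows"] == ["c"]


def test_zscore_rows_have_zero_mean_unit_sd(rng):
    df = pd.DataFrame(rng.normal(size=(20, 8)))
    z = zscore_rows(df)
    np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(z.to_numpy().std(axis=1), 1.0, rtol=1e-12)


def test_zscore_is_idempotent(rng):
    df = pd.DataFrame(rng.normal(size=(10, 6)))
    once = zscore_rows(df)
    twice = zscore_rows(once)
    np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)


def test_identical_rows_merge_first_at_zero_distance():
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 1.0, 4.0]],
        index=["a", "b", "c"],
    )
    Z, order, labels = hcluster(df)
    assert {labels[int(Z[0, 0])], labels[int(Z[0, 1])]} == {"a", "b"}
    assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)


def test_three_block_structure_recovered_exactly():
    df, truth = _block_profiles(3, 6)
    Z, _, labels = hcluster(df)
    found = cut_tree(Z, 3, labels)
    assert adjusted_rand_score(truth, found.to_numpy()) == 1.0


def test_twenty_block_structure_recovered_exactly():
    df, truth = _block_profiles(20, 5, n_cols=16, seed=3)
    Z, _, labels = hcluster(df)
    found = cut_tree(Z, 20, labels)
    assert adjusted_rand_score(truth, found.to_numpy()) == 1.0


def test_hcluster_invariant_to_row_permutation(rng):
    df, truth = _block_profiles(4, 5, seed=2)
    perm = rng.permutation(len(df))
    Z1, _, labels1 = hcluster(df)
    Z2, _, labels2 = hcluster(df.iloc[perm])
    a = cut_tree(Z1, 4, labels1)
    b = cut_tree(Z2, 4, labels2)
    assert adjusted_rand_score(a.reindex(b.index).to_numpy(), b.to_numpy()) == 1.0


def test_singleton_axis_gives_degenerate_tree():
    df = pd.DataFrame([[1.0, 2.0]], index=["only"])
    Z, order, labels = hcluster(df)
    assert labels == ["only"]
    assert len(order) == 1


def test_constant_row_distance_maximal_with_warning(caplog):
    df = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["c", "g"])
    with caplog.at_level("WARNING"):
        Z, _, _ = hcluster(df)
    assert Z[0, 2] == pytest.approx(1.0)


def test_similarity_matrix_properties(rng):
    df = pd.DataFrame(rng.normal(size=(30, 6)), columns=list("abcdef"))
    sim = celltype_similarity(df)
    np.testing.assert_allclose(sim, sim.T)
    np.testing.assert_array_equal(np.diag(sim), 1.0)
    dup = df.copy()
    dup["b"] = dup["a"]
    assert celltype_similarity(dup).loc["a", "b"] == pytest.approx(1.0)


def test_orthogonal_profiles_have_near_zero_similarity(rng):
    df = pd.DataFrame(rng.normal(size=(4000, 3)), columns=list("abc"))
    sim = celltype_similarity(df)
    off = sim.to_numpy()[~np.eye(3, dtype=bool)]
    assert np.abs(off).max() < 0.05


def test_cut_tree_extremes_and_nesting():
    df, _ = _block_profiles(3, 4)
    Z, _, labels = hcluster(df)
    assert cut_tree(Z, 1, labels).nunique() == 1
    assert cut_tree(Z, len(labels), labels).nunique() == len(labels)
    for k in range(2, 8):
        a = cut_tree(Z, k, labels)
        b = cut_tree(Z, k + 1, labels)
        # nested: the k+1 cut refines the k cut
        joint = pd.crosstab(a, b)
        assert ((joint > 0).sum(axis=0) == 1).all()
    with pytest.raises(ValueError):
        cut_tree(Z, 0, labels)


def test_newick_round_trips_through_skbio():
    df, _ = _block_profiles(3, 3)
    Z, _, labels = hcluster(df)
    import io
    tree = TreeNode.read(io.StringIO(to_newick(Z, labels)))
    assert {t.name for t in tree.tips()} == set(labels)
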
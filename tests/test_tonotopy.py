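import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import cochlea_atlas_kit as cak
from cochlea_atlas_kit.simulate import GradientSpec, simulate_tbc_gradient
from cochlea_atlas_kit.stats import rank_sum_vectorized
from cochlea_atlas_kit.tonotopy import (
    assign_bins,
    classify_direction,
    dunn_mc,
    fold_change,
    kruskal_wallis,
    over_representation,
    screen,
)


def kw_brute_force(values, labels):
    """Oracle: Kruskal-Wallis H computed from first principles — midranks
    by explicit sorting, the rank-sum formula, and the tie correction."""
    values = list(map(float, values))
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    groups = {}
    for lab, r in zip(labels, ranks):
        groups.setdefault(lab, []).append(r)
    h = 12.0 / (n * (n + 1)) * sum(
        len(rs) * (sum(rs) / len(rs)) ** 2 for rs in groups.values()
    ) - 3 * (n + 1)
    ties = {}
    for v in values:
        ties[v] = ties.get(v, 0) + 1
    correction = 1 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / correction if correction > 0 else 0.0


# --- binning ----------------------------------------------------------------

def test_eight_cells_split_into_equal_quartiles():
    bins = assign_bins([8, 7, 6, 5, 4, 3, 2, 1])
    assert list(bins["bin"]) == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]
    assert list(bins["region"][:2]) == ["base", "base"]


def test_uneven_sizes_put_larger_bins_on_the_base_side():
    bins = assign_bins(np.arange(10)[::-1])
    sizes = bins["bin"].value_counts().sort_index()
    assert list(sizes) == [3, 3, 2, 2]


def test_exactly_four_bin_labels():
    bins = assign_bins(np.random.default_rng(0).normal(size=57))
    assert bins["bin"].nunique() == 4
    assert set(bins["region"]) == {"base", "middle-base", "middle-apex", "apex"}


def test_strongest_anchor_expression_maps_to_base():
    values = np.array([0.1, 5.0, 2.0, 0.0])
    bins = assign_bins(values)
    assert bins.loc[1, "bin"] == "Q1"  # strongest
    assert bins.loc[3, "bin"] == "Q4"  # zero anchor falls apex-most


@given(
    st.lists(st.floats(-20, 20), min_size=8, max_size=40, unique=True),
    st.sampled_from([np.exp, lambda v: 3 * v + 1, np.cbrt]),
)
def test_binning_invariant_under_monotone_transforms(values, f):
    v = np.asarray(values)
    if len(np.unique(f(v))) < len(v):  # transform must stay injective
        return
    base = assign_bins(v)["bin"]
    transformed = assign_bins(f(v))["bin"]
    assert (base == transformed).all()


def test_ties_broken_by_stable_input_order():
    bins = assign_bins([1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
    assert list(bins["bin"]) == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]


def test_too_few_cells_for_bins_errors():
    with pytest.raises(ValueError):
        assign_bins([1.0, 2.0, 3.0])


# --- Kruskal-Wallis ---------------------------------------------------------

def test_kw_hand_computed_example():
    H, p = kruskal_wallis([1, 2, 3, 4], ["a", "a", "b", "b"])
    assert H == pytest.approx(2.4)


def test_kw_degenerate_all_equal():
    H, p = kruskal_wallis(np.ones(9), np.repeat(["a", "b", "c"], 3))
    assert H == 0.0
    assert p == 1.0


def test_kw_matches_brute_force_on_1000_random_instances(rng):
    for _ in range(1000):
        k = rng.integers(2, 5)
        sizes = rng.integers(2, 8, size=k)
        values = rng.integers(0, 6, size=sizes.sum()).astype(float)  # heavy ties
        labels = np.repeat([f"g{i}" for i in range(k)], sizes)
        if np.all(values == values[0]):
            continue
        H, _ = kruskal_wallis(values, labels)
        assert H == pytest.approx(kw_brute_force(values, labels), abs=1e-10)


def test_kw_two_groups_equals_squared_ranksum_z(rng):
    for _ in range(50):
        x = rng.normal(size=(30, 1))
        mask = np.zeros(30, bool)
        mask[:12] = True
        _, z, _ = rank_sum_vectorized(x, mask)
        H, _ = kruskal_wallis(x.ravel(), np.where(mask, "a", "b"))
        assert H == pytest.approx(z[0] ** 2, rel=1e-9)


def test_kw_single_group_rejected():
    with pytest.raises(ValueError):
        kruskal_wallis([1.0, 2.0], ["a", "a"])


def test_kw_small_sample_null_is_conservative(rng):
    """At 4 groups x 5 values, the chi-square tail under-rejects: the
    type-I rate sits below the nominal 0.05 (small-sample conservatism)."""
    labels = np.repeat(list("abcd"), 5)
    rej = sum(
        kruskal_wallis(rng.normal(size=20), labels)[1] < 0.05 for _ in range(2000)
    )
    assert 0.02 <= rej / 2000 <= 0.05


# --- Dunn-Holland-Wolfe ------------------------------------------------------

def test_dunn_identical_groups_not_significant():
    res = dunn_mc([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], np.repeat(["a", "b"], 3))
    assert res.iloc[0].z == 0.0
    assert not res.iloc[0].significant


def test_dunn_two_groups_equals_ranksum_z_without_ties(rng):
    for _ in range(30):
        v = rng.normal(size=24)
        mask = np.zeros(24, bool)
        mask[:10] = True
        _, z_rs, _ = rank_sum_vectorized(v[:, None], mask)
        res = dunn_mc(v, np.where(mask, "a", "b"))
        assert abs(res.iloc[0].z) == pytest.approx(abs(z_rs[0]), rel=1e-9)


def test_dunn_familywise_error_controlled_under_null(rng):
    labels = np.repeat(list("abcd"), 10)
    hits = sum(
        dunn_mc(rng.normal(size=40), labels)["significant"].any()
        for _ in range(2000)
    )
    assert hits / 2000 <= 0.06


def test_dunn_pair_count():
    res = dunn_mc(np.arange(12.0), np.repeat(list("abcd"), 3))
    assert len(res) == 6  # k(k-1)/2


# --- fold change & direction -------------------------------------------------

def test_equal_means_fail_any_threshold():
    fc, passes = fold_change({"Q1": 2.0, "Q4": 2.0})
    assert fc == pytest.approx(1.0)
    assert not passes


def test_threshold_boundary_is_strict():
    fc, passes = fold_change({"Q1": 1.3, "Q4": 1.0}, threshold=1.3)
    assert not passes
    _, passes_above = fold_change({"Q1": 1.31, "Q4": 1.0}, threshold=1.3)
    assert passes_above


def test_zero_base_mean_passes_via_vice_versa_branch():
    fc, passes = fold_change({"Q1": 0.0, "Q4": 2.0})
    assert 0 < fc < 1
    assert passes


def test_direction_requires_all_gates():
    common = dict(alpha=0.05, fc_threshold=1.3)
    assert classify_direction(0.01, True, 2.0, 4.0, 2.0, **common) == "base_high"
    assert classify_direction(0.01, True, 0.5, 2.0, 4.0, **common) == "apex_high"
    assert classify_direction(0.2, True, 2.0, 4.0, 2.0, **common) == "none"
    assert classify_direction(0.01, False, 2.0, 4.0, 2.0, **common) == "none"
    assert classify_direction(0.01, True, 1.2, 4.0, 2.0, **common) == "none"


# --- screen ------------------------------------------------------------------

def test_planted_directions_recovered_at_moderate_size():
    """Emilin2-like planted genes (robustly expressed, low dispersion,
    two-fold gradients) are recovered with correct directions at 400
    TBCs."""
    specs = (
        GradientSpec("up", 2.0, "base_high"),
        GradientSpec("down", 2.0, "apex_high"),
    )
    adata, _ = simulate_tbc_gradient(
        400, specs, n_null_genes=200, seed=2,
        dispersion_overrides=(("up", 0.1), ("down", 0.1)),
    )
    norm = cak.normalize(adata)
    res = screen(norm.X, list(norm.var_names), min_frac=0.05).set_index("gene")
    assert res.loc["up", "direction"] == "base_high"
    assert res.loc["down", "direction"] == "apex_high"


def test_anchor_flags_itself_base_high(tbc_screen_fixture):
    adata, _, _ = tbc_screen_fixture
    norm = cak.normalize(adata)
    res = screen(norm.X, list(norm.var_names), min_frac=0.05)
    anchor_row = res[res.is_anchor].iloc[0]
    assert anchor_row.gene == "Emilin2"
    assert anchor_row.direction == "base_high"


def test_screen_with_only_the_anchor():
    adata, _ = simulate_tbc_gradient(100, (), n_null_genes=0, seed=1)
    norm = cak.normalize(adata)
    res = screen(norm.X, list(norm.var_names))
    assert len(res) == 1
    assert res.iloc[0].is_anchor


def test_missing_anchor_errors():
    with pytest.raises(ValueError, match="anchor"):
        screen(np.ones((10, 2)), ["a", "b"])


# --- over-representation ------------------------------------------------------

def test_hypergeometric_closed_form():
    # universe 20, one set of 5, all 5 selected genes inside it
    universe = [f"g{i}" for i in range(20)]
    res = over_representation(universe[:5], {"s": universe[:5]}, universe)
    assert res.iloc[0].p == pytest.approx(1 / 15504)
    assert res.iloc[0].overlap == 5


def test_selection_equal_to_universe_is_uninformative():
    universe = ["a", "b", "c"]
    res = over_representation(universe, {"s": universe}, universe)
    assert res.iloc[0].p == pytest.approx(1.0)


def test_empty_selection_gives_empty_table():
    assert over_representation([], {"s": ["a"]}, ["a", "b"]).empty


def test_set_gene_outside_universe_dropped(caplog):
    with caplog.at_level("WARNING"):
        res = over_representation(["a"], {"s": ["a", "zz"]}, ["a", "b"])
    assert res.iloc[0].n_set == 1
    assert any("outside universe" in r.message for r in caplog.records)


def test_selected_outside_universe_rejected():
    with pytest.raises(ValueError):
        over_representation(["zz"], {"s": ["a"]}, ["a"])
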
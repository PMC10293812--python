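import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import cochlea_atlas_kit as cak
from cochlea_atlas_kit.registry import CellTypeSpec
from cochlea_atlas_kit.simulate import (
    GradientSpec,
    SimConfig,
    simulate_counts,
    simulate_tbc_gradient,
)

ONE_TYPE = [
    CellTypeSpec("fibrocyte", "lateral_wall", (("Otos", 8.0),), 1.0)
]


def _cfg(**kw):
    base = dict(n_cells={("P8", "cell"): 200}, n_genes=60, seed=0)
    base.update(kw)
    return SimConfig(**base)


def test_same_seed_reproduces_identical_output():
    a1, t1 = simulate_counts(_cfg(), ONE_TYPE)
    a2, t2 = simulate_counts(_cfg(), ONE_TYPE)
    assert (a1.X != a2.X).nnz == 0
    pd.testing.assert_frame_equal(t1, t2)


def test_different_seed_changes_output():
    a1, _ = simulate_counts(_cfg(seed=0), ONE_TYPE)
    a2, _ = simulate_counts(_cfg(seed=1), ONE_TYPE)
    assert (a1.X != a2.X).nnz > 0


def test_zero_keep_probability_gives_all_zero_matrix():
    adata, _ = simulate_counts(_cfg(dropout_keep=0.0), ONE_TYPE)
    assert adata.X.nnz == 0


def test_counts_nonnegative_integers():
    adata, _ = simulate_counts(_cfg(), ONE_TYPE)
    assert adata.X.min() >= 0
    assert np.issubdtype(adata.X.dtype, np.integer)


def test_marker_mean_matches_nb_moments():
    """1,000 cells of one type with an 8x marker at baseline mean 1: the
    empirical marker mean must sit within 3 standard errors of
    8 x (mean library factor)."""
    cfg = _cfg(
        n_cells={("P8", "cell"): 1000},
        baseline_mean=1.0,
        gene_mean_sdlog=0.0,
        dropout_keep=1.0,
        type_variation_sdlog=0.0,
        gradients=(),
        seed=3,
    )
    adata, _ = simulate_counts(cfg, ONE_TYPE)
    col = np.asarray(adata[:, "Otos"].X.todense()).ravel()
    lib = adata.obs_names  # library factors are internal; recover expectation
    expected = 8.0  # E[s] = 1 by construction
    se = col.std(ddof=1) / np.sqrt(len(col))
    assert abs(col.mean() - expected) < 3 * se


def test_moment_fidelity_of_nb_thinning_model():
    """Mean and variance of a non-marker gene match NB-plus-thinning
    moments (mean q*mu; var q*mu + phi*(q*mu)^2) within 3 MC SEs."""
    mu, phi, q = 2.0, 0.5, 0.8
    cfg = _cfg(
        n_cells={("P8", "cell"): 4000},
        n_genes=40,
        baseline_mean=mu,
        gene_mean_sdlog=0.0,
        dispersion=phi,
        dropout_keep=q,
        library_sdlog=0.0,
        type_variation_sdlog=0.0,
        gradients=(),
        seed=4,
    )
    adata, _ = simulate_counts(cfg, ONE_TYPE)
    col = np.asarray(adata[:, "synth-gene-0000"].X.todense()).ravel().astype(float)
    n = len(col)
    m_exp = q * mu
    v_exp = q * mu + phi * (q * mu) ** 2
    se_mean = col.std(ddof=1) / np.sqrt(n)
    m4 = ((col - col.mean()) ** 4).mean()
    se_var = np.sqrt(max(m4 - col.var(ddof=1) ** 2, 0.0) / n)
    assert abs(col.mean() - m_exp) < 3 * se_mean
    assert abs(col.var(ddof=1) - v_exp) < 3 * se_var


def test_gradient_ratio_recovered_between_extreme_positions():
    """Base-high r=2 genes over 2,000 TBCs: the ratio of empirical count
    means between cells at p<0.1 and p>0.9 (averaged over five replicate
    genes to tame NB noise) recovers 2 within 15%."""
    specs = tuple(GradientSpec(f"g{i}", 2.0, "base_high") for i in range(5))
    adata, truth = simulate_tbc_gradient(2000, specs, n_null_genes=5, seed=5)
    p = truth["position"].to_numpy()
    ratios = []
    for s in specs:
        col = np.asarray(adata[:, s.gene].X.todense()).ravel()
        ratios.append(col[p < 0.1].mean() / col[p > 0.9].mean())
    assert abs(np.mean(ratios) - 2.0) / 2.0 < 0.15


@pytest.mark.parametrize("r_pair", [(1.5, 2.0), (2.0, 4.0)])
def test_gradient_spearman_negative_and_monotone_in_fold(r_pair):
    rhos = []
    for r in r_pair:
        adata, truth = simulate_tbc_gradient(
            1500, (GradientSpec("g", r, "base_high"),), n_null_genes=0, seed=6
        )
        col = np.asarray(adata[:, "g"].X.todense()).ravel()
        rho = spearmanr(col, truth["position"]).statistic
        assert rho < 0
        rhos.append(abs(rho))
    assert rhos[1] > rhos[0]


def test_technology_capture_contract(registry):
    cfg = SimConfig(
        n_cells={("P8", "cell"): 1000, ("P8", "nucleus"): 1000}, n_genes=300, seed=7
    )
    _, truth = simulate_counts(cfg, registry)
    cell = truth[truth.technology == "cell"]
    nuc = truth[truth.technology == "nucleus"]
    assert (cell.true_type == "OHC").sum() == 0
    ohc_frac = (nuc.true_type == "OHC").mean()
    assert abs(ohc_frac - 1 / 37) < 0.01  # registry proportion, near-uniform


def test_position_defined_exactly_for_tbcs(registry):
    cfg = SimConfig(n_cells={("P8", "nucleus"): 500}, n_genes=300, seed=8)
    _, truth = simulate_counts(cfg, registry)
    assert truth.loc[truth.true_type == "TBC", "position"].notna().all()
    assert truth.loc[truth.true_type != "TBC", "position"].isna().all()
    pos = truth.loc[truth.true_type == "TBC", "position"]
    assert ((pos >= 0) & (pos <= 1)).all()


def test_tbc_fixture_gene_budget():
    adata, _ = simulate_tbc_gradient(
        8, (GradientSpec("g", 2.0, "base_high"),), n_null_genes=0, seed=0
    )
    assert adata.n_vars == 2  # anchor + the one spec
    assert set(adata.var_names) == {"Emilin2", "g"}


def test_tbc_fixture_rejects_duplicate_genes():
    with pytest.raises(ValueError, match="duplicate"):
        simulate_tbc_gradient(
            100, (GradientSpec("Emilin2", 2.0, "base_high"),), seed=0
        )
    with pytest.raises(ValueError, match="duplicate"):
        simulate_tbc_gradient(
            100,
            (GradientSpec("g", 2.0, "base_high"), GradientSpec("g", 3.0, "apex_high")),
            seed=0,
        )


@pytest.mark.parametrize(
    "bad",
    [
        dict(baseline_mean=0.0),
        dict(dispersion=-1.0),
        dict(n_cells={("P8", "tissue"): 10}),
        dict(n_cells={("P9", "cell"): 10}),
        dict(dropout_keep=1.5),
    ],
)
def test_invalid_config_rejected(bad):
    with pytest.raises(ValueError):
        _cfg(**bad).validate()


def test_invalid_gradient_spec_rejected():
    with pytest.raises(ValueError):
        GradientSpec("g", 1.0, "base_high")
    with pytest.raises(ValueError):
        GradientSpec("g", 2.0, "sideways")
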
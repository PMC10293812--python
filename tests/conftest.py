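import numpy as np
import pytest
from hypothesis import settings

import cochlea_atlas_kit as cak
from cochlea_atlas_kit.simulate import GradientSpec, SimConfig, simulate_counts

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

ATLAS_SEED = 20230620
ATLAS_CELLS_PER_TYPE = 60


@pytest.fixture(scope="session")
def registry():
    return cak.default_registry()


@pytest.fixture(scope="session")
def atlas(registry):
    """Default synthetic atlas: one population per registry entry under
    the nucleus technology (all 37 populations capturable), 60 cells per
    population."""
    config = SimConfig(
        n_cells={("P8", "nucleus"): ATLAS_CELLS_PER_TYPE * len(registry)},
        n_genes=300,
        seed=ATLAS_SEED,
    )
    adata, truth = simulate_counts(config, registry)
    return adata, truth


@pytest.fixture(scope="session")
def atlas_annotation(atlas, registry):
    """QC -> normalize -> cluster -> assign on the default atlas."""
    adata, truth = atlas
    filtered = cak.qc_filter(adata, 1, 1)
    norm = cak.normalize(filtered)
    clusters = cak.cluster_cells(norm.X, seed=0)
    annotation = cak.score_and_assign(
        norm.X, list(norm.var_names), clusters, registry, barcodes=norm.obs_names
    )
    return norm, truth.loc[annotation.index], annotation


@pytest.fixture(scope="session")
def tbc_screen_fixture():
    """Tonotopy power fixture: 10 planted 2-fold gradients (alternating
    directions) among 500 null genes, 800 TBCs."""
    specs = tuple(
        GradientSpec(f"grad{i}", 2.0, "base_high" if i % 2 else "apex_high")
        for i in range(10)
    )
    adata, truth = cak.simulate_tbc_gradient(800, specs, n_null_genes=500, seed=0)
    return adata, truth, specs


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
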
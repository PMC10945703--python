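import numpy as np
import pytest

import patterncode as pc


@pytest.fixture(scope="session")
def tree():
    return pc.LineageTree.default()


@pytest.fixture(scope="session")
def tiny_sim():
    """One 8-cell stage, 4 embryos, small gene panel, planted programs."""
    cfg = pc.SimulationConfig(
        stages=(8,), n_embryos_per_stage=4, n_genes=300, n_tf_genes=60,
        maternal_fraction=0.6, program_size=10, effect_size=1.0,
        embryo_effect_sd=0.15, depth_mean=20000.0, seed=42,
    )
    adata, truth = pc.simulate(cfg)
    return adata, truth, cfg


@pytest.fixture(scope="session")
def tiny_preprocessed(tiny_sim):
    adata, truth, cfg = tiny_sim
    return pc.preprocess(adata.copy()), truth, cfg


@pytest.fixture(scope="session")
def recovery_run():
    """The parameter-recovery experiment, preprocessed, with truth."""
    cfg = pc.recovery_config(seed=1)
    adata, truth = pc.simulate(cfg)
    return pc.preprocess(adata), truth, cfg


@pytest.fixture(scope="session")
def recovery_calls(recovery_run):
    adata, truth, cfg = recovery_run
    calls = pc.call_stage(
        np.asarray(adata.X),
        np.asarray(adata.layers["log10"]),
        np.asarray(adata.layers["z"]),
        adata.obs["true_state"].to_numpy(),
        list(adata.var_names),
        stage=15, n_shuffles=2000, fdr=0.01, seed=8,
        embryos=adata.obs["embryo_id"].to_numpy(),
    )
    return calls
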
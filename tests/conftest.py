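import numpy as np
import pandas as pd
import pytest

from dualseq import simulate


@pytest.fixture(scope="session")
def small_catalog():
    return simulate.simulate_catalog(300, 150, 20, seed=11)


@pytest.fixture(scope="session")
def small_design():
    return simulate.default_design(
        n_pairs=4, n_capsule=3, host_depth=400_000, capsule_depth=600_000
    )


@pytest.fixture(scope="session")
def small_truth(small_catalog, small_design):
    return simulate.make_sim_truth(
        small_catalog,
        de_fraction=0.1,
        design=small_design,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_counts(small_catalog, small_design, small_truth):
    return simulate.simulate_counts(small_catalog, small_design, small_truth)


def constant_truth(catalog, means, dispersion=0.1, seed=0, **kwargs):
    """SimTruth with externally fixed per-gene means, no DE, no GC bias."""
    genes = catalog["transcript_id"]
    cm = pd.DataFrame(
        {cls: np.asarray(means, dtype=float) for cls in simulate.SAMPLE_CLASSES},
        index=pd.Index(genes, name="gene"),
    )
    defaults = dict(
        condition_means=cm,
        de_indicator={},
        log2_effect={},
        nb_dispersion=np.full(len(genes), float(dispersion)),
        gc_bias={"low_input": (0.6, 0.0), "standard": (0.6, 0.0)},
        symbiont_depth_fraction={"default": 0.05},
        seed=seed,
    )
    defaults.update(kwargs)
    return simulate.SimTruth(**defaults)
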
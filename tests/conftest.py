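import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A fast fixture-scale synthetic design: 400 kb genome, a few planted DMRs."""
    from dmrscape import SyntheticConfig
    return SyntheticConfig(seed=7, genome=(("chr1", 400_000),),
                           n_genes=8, n_planted_hypo=4, n_planted_hyper=4)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Annotation + methylomes + expression for the small design."""
    from dmrscape import (simulate_annotation, simulate_expression,
                          simulate_methylomes)
    ann = simulate_annotation(small_config)
    matrix, truth = simulate_methylomes(small_config, ann)
    expression = simulate_expression(small_config, ann)
    return ann, matrix, truth, expression


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory, small_config):
    from dmrscape import write_fixture_bundle
    out = tmp_path_factory.mktemp("bundle") / "fixture"
    write_fixture_bundle(small_config, out)
    return out


def random_dms(rng, n=30, chrom="chr1", direction=None):
    pos = np.sort(rng.choice(np.arange(100, 100_000), size=n, replace=False))
    dirs = (np.full(n, direction) if direction
            else rng.choice(["hypo", "hyper"], size=n))
    diff = np.where(dirs == "hypo", -1, 1) * rng.uniform(0.1, 0.6, size=n)
    return pd.DataFrame({
        "chrom": chrom, "pos": pos, "direction": dirs,
        "meth_diff": diff, "p_value": rng.uniform(1e-6, 0.05, size=n),
        "q_value": rng.uniform(1e-6, 0.05, size=n),
    })
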
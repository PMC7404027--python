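import numpy as np
import pandas as pd
import pytest

import chillnet as cn


@pytest.fixture(scope="session")
def default_config():
    return cn.SimConfig(seed=1)


@pytest.fixture(scope="session")
def bundle(default_config):
    """Synthetic expression bundle at the study-design defaults, seed 1."""
    fpkm, design, truth = cn.generate_expression(default_config)
    return fpkm, design, truth


@pytest.fixture(scope="session")
def fitted(bundle):
    """DEG-union matrix and fitted coexpression network for seed 1."""
    fpkm, design, truth = bundle
    filt = cn.filter_expressed(fpkm)
    union, _ = cn.deg_union(filt.kept, design)
    deg = filt.kept.loc[sorted(union)]
    res = cn.CoexpressionNetwork(deg, design).fit()
    return deg, res


@pytest.fixture()
def toy_design():
    """Two stages x three replicates, six samples."""
    return cn.SampleDesign.from_layout(["A", "B"], ["t"], 3)


def make_two_group_matrix(seed, n_sig=100, n_null=1900, shift_log2=2.0, noise_sd=0.2):
    """FPKM matrix with planted log2-shifted genes between groups A and B."""
    rng = np.random.default_rng(seed)
    n = n_sig + n_null
    base = rng.normal(5.0, 1.0, n)
    x = base[:, None] + rng.normal(0.0, noise_sd, (n, 6))
    x[:n_sig, 3:] += shift_log2
    genes = [f"g{i}" for i in range(n)]
    cols = [f"A.t.R{i}" for i in range(1, 4)] + [f"B.t.R{i}" for i in range(1, 4)]
    fpkm = pd.DataFrame(np.maximum(np.power(2.0, x) - 1.0, 0.0),
                        index=genes, columns=cols)
    design = cn.SampleDesign(pd.DataFrame({
        "sample_id": cols,
        "genotype": ["A"] * 3 + ["B"] * 3,
        "timepoint": "t",
        "replicate": [1, 2, 3, 1, 2, 3],
    }))
    return fpkm, design, set(genes[:n_sig])
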
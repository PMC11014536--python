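import numpy as np
import pytest

import sizedeconv as sd


@pytest.fixture(scope="session")
def tiny_signature():
    """Full-rank 3-gene x 2-type signature for exact round trips."""
    return sd.SignatureMatrix(
        np.array([[10.0, 1.0], [2.0, 8.0], [5.0, 5.0]]),
        ["g1", "g2", "g3"],
        ["neuron", "glial"],
    )


@pytest.fixture(scope="session")
def brain_factors():
    return sd.CellScaleFactors({"neuron": 10.0, "glial": 3.0})


@pytest.fixture(scope="session")
def synth_default():
    """One shared draw of the default synthetic single-cell study."""
    return sd.synth_sc(sd.SynthConfig(seed=11))


def random_instance(rng, n_genes, n_types):
    """Random full-column-rank (Z, s, p) triple for oracle checks."""
    Z = sd.SignatureMatrix(
        rng.uniform(0.5, 20.0, size=(n_genes, n_types)),
        [f"g{i}" for i in range(n_genes)],
        [f"t{k}" for k in range(n_types)],
    )
    s = sd.CellScaleFactors({f"t{k}": rng.uniform(0.5, 12.0) for k in range(n_types)})
    p = rng.dirichlet(np.ones(n_types))
    return Z, s, p
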
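import numpy as np
import pytest

from gist import ExpressionMatrix, McmcConfig, SignatureMatrix


@pytest.fixture(scope="session")
def noiseless_toy():
    """40 genes, 3 orthogonal signature blocks, Y = W @ H_true exactly.

    H_true columns are (0.2, 0.3, 0.5); with orthogonal signatures this is
    also the unique sum-to-one least-squares optimum, verified in the tests
    against a constrained solver.
    """
    m, p, n = 40, 3, 5
    W = np.zeros((m, p))
    for k in range(p):
        W[k * 12 : (k + 1) * 12, k] = 5.0
    H_true = np.tile(np.array([0.2, 0.3, 0.5])[:, None], (1, n))
    Y = W @ H_true
    gene_ids = [f"g{i}" for i in range(m)]
    spot_ids = [f"s{j}" for j in range(n)]
    em = ExpressionMatrix(Y, gene_ids, spot_ids, layer="normalized")
    sig = SignatureMatrix(W, gene_ids, ["A", "B", "C"])
    return em, sig, H_true


@pytest.fixture(scope="session")
def quick_mcmc():
    """Short chains for unit tests; long enough for ~0.02 posterior-mean error."""
    return McmcConfig(iterations=500, burn_in=250, seed=7)
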
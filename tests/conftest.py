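import numpy as np
import pandas as pd
import pytest

from cpmkit.cohort import AlignedCohort, PhenotypeTable
from cpmkit.connectome import CohortEdgeMatrix, EdgeIndexMap
from cpmkit.simulate import planted_benchmark, simulate_cohort


def make_cohort(X, y, sites=None, rng=None, cov=None):
    """Wrap a raw edge matrix and outcome into an AlignedCohort."""
    n, E = X.shape
    # infer region count from E = N(N-1)/2
    N = int(round((1 + np.sqrt(1 + 8 * E)) / 2))
    edge_map = EdgeIndexMap(N)
    assert edge_map.n_edges == E, "E must be a triangular number"
    rng = rng or np.random.default_rng(0)
    if cov is None:
        cov = rng.normal(size=(n, 3))
    pids = [f"p{i:04d}" for i in range(n)]
    df = pd.DataFrame({
        "participant_id": pids,
        "site_id": (sites if sites is not None
                    else [f"s{i % 4}" for i in range(n)]),
        "family_id": [f"f{i}" for i in range(n)],
        "sex": ["F" if i % 2 else "M" for i in range(n)],
        "age": 10.0 + cov[:, 1] * 0.1,
        "mean_fd": 0.1 + 0.01 * np.abs(cov[:, 2]),
        "score_base": 50.0 + cov[:, 0],
        "score_y1": y,
        "group": "none",
    })
    edges = CohortEdgeMatrix(X=X, participant_ids=pids, edge_map=edge_map)
    return AlignedCohort(edges=edges, phenotypes=PhenotypeTable(df=df))


@pytest.fixture(scope="session")
def planted_sim():
    """One planted benchmark cohort, shared across tests."""
    return simulate_cohort(planted_benchmark(seed=11))
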
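import logging

import numpy as np
import pytest

import flowrosetta as fr

# the EM emits expected non-convergence warnings for overfitted candidate
# configurations; keep test output readable
logging.getLogger("flowrosetta").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    # fresh per test so assertions do not depend on test execution order
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def benchmark_events():
    """The built-in two-cluster benchmark dataset, one fixed seed."""
    return fr.two_cluster_benchmark(1)


@pytest.fixture(scope="session")
def benchmark_analysis(benchmark_events):
    """Full-routine analysis of the benchmark dataset (shared: it is slow)."""
    return fr.analyze_dataset(benchmark_events, seed=1)


def cluster_rows_by_center(report, centers):
    """Map report rows to the cluster specs they recover, by centroid."""
    out = []
    for cx, cy in centers:
        out.append(min(report.clusters,
                       key=lambda r: (r.x_mean - cx) ** 2 + (r.y_mean - cy) ** 2))
    return out
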
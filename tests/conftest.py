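"""Shared fixtures: small converged embeddings reused across the suite.

All fixtures are generated programmatically and seeded; the expensive ones
(converged embeddings + Jacobians) are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

from tsne_sensitivity import (
    ClusterSpec,
    TimeSeriesSpec,
    TsneConfig,
    make_clusters,
    make_timeseries,
    optimize_embedding,
    replicate_moments,
    sensitivity_jacobian,
)


@pytest.fixture(scope="session")
def cluster30():
    """Generic 3-cluster fixture (N=30, D=5) with a tightly converged embedding."""
    spec = ClusterSpec(seed=1)  # defaults: 3 x 10 points, D=5, interacting regime
    data, labels = make_clusters(spec)
    cfg = TsneConfig(perplexity=12.0, grad_tol=1e-9, seed=1)
    emb = optimize_embedding(data, cfg)
    assert emb.converged
    return {"spec": spec, "data": data, "labels": labels, "emb": emb, "config": cfg}


@pytest.fixture(scope="session")
def cluster30_jacobian(cluster30):
    return sensitivity_jacobian(cluster30["data"], cluster30["emb"])


@pytest.fixture(scope="session")
def fix12():
    """Small N=12, D=3 fixture converged to near machine precision, for
    finite-difference oracles that re-optimize per input entry."""
    spec = ClusterSpec(n_clusters=3, points_per_cluster=4, dim=3, seed=2)
    data, labels = make_clusters(spec)
    cfg = TsneConfig(perplexity=5.0, grad_tol=1e-11, seed=2)
    emb = optimize_embedding(data, cfg)
    assert emb.converged
    return {"spec": spec, "data": data, "labels": labels, "emb": emb, "config": cfg}


@pytest.fixture(scope="session")
def fix12_jacobian(fix12):
    return sensitivity_jacobian(fix12["data"], fix12["emb"])


@pytest.fixture(scope="session")
def timeseries8():
    """Replicated switch-block time course reduced to means + variances,
    with a converged embedding of the 8 timepoint means."""
    spec = TimeSeriesSpec(seed=3)
    tensor = make_timeseries(spec)
    data, unc = replicate_moments(tensor)
    cfg = TsneConfig(perplexity=5.0, grad_tol=1e-10, seed=3)
    emb = optimize_embedding(data, cfg)
    assert emb.converged
    return {"spec": spec, "tensor": tensor, "data": data, "unc": unc,
            "emb": emb, "config": cfg}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
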
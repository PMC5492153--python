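"""Shared fixtures and the independent linear-system oracle.

The oracle solves the quadratic segmentation objectives exactly (dense
per-class linear systems over the flattened lattice) and is kept free of
any solver code from the package, so Gauss-Seidel results can be checked
against it on small lattices.
"""

from __future__ import annotations

import numpy as np
import pytest

import gmmfusion as gf


def _edge_list(h: int, w: int, connectivity: int = 4):
    """Unordered lattice edges as (site_a, site_b) in row-major flat ids."""
    edges = []
    for i in range(h):
        for j in range(w):
            a = i * w + j
            if i + 1 < h:
                edges.append((a, (i + 1) * w + j))
            if j + 1 < w:
                edges.append((a, i * w + j + 1))
            if connectivity == 8:
                if i + 1 < h and j + 1 < w:
                    edges.append((a, (i + 1) * w + j + 1))
                if i + 1 < h and j - 1 >= 0:
                    edges.append((a, (i + 1) * w + j - 1))
    return edges


def direct_minimizer(u, lam, edge_weight_of=None, connectivity=4):
    """Exact minimizer of sum_r sum_k (p-u)^2 + lam * sum_edges w_rs (p(r)-p(s))^2.

    ``edge_weight_of(a, b)`` returns the weight of the unordered edge; by
    default every edge weighs 1 (the classic model).  Solves one dense
    linear system per class.
    """
    u = np.asarray(u, dtype=np.float64)
    h, w, K = u.shape
    n = h * w
    A = np.eye(n)
    for a, b in _edge_list(h, w, connectivity):
        wt = 1.0 if edge_weight_of is None else edge_weight_of(a, b)
        A[a, a] += lam * wt
        A[b, b] += lam * wt
        A[a, b] -= lam * wt
        A[b, a] -= lam * wt
    flat = u.reshape(n, K)
    return np.linalg.solve(A, flat).reshape(h, w, K)


def fusion_oracle(v_list, cfg, measure="gini"):
    """Exact fusion-model minimizer for fixed (likelihood-derived) weights.

    Recomputes the uncertainty weights, mixture field and edge weights
    from their defining formulas (not via the package's fusion_solve),
    then solves the linear system.
    """
    v = [np.asarray(x, dtype=np.float64) for x in v_list]
    fn = gf.gini_impurity if measure == "gini" else gf.shannon_uncertainty
    U = np.stack([fn(x) for x in v])
    raw = cfg.mu_data / (cfg.mu_data + U)
    wdat = raw / raw.sum(axis=0, keepdims=True)
    u = np.einsum("fhw,fhwk->hwk", wdat, np.stack(v))
    h, w, K = u.shape
    uflat = u.reshape(-1, K)

    def edge_weight_of(a, b):
        d2 = float(((uflat[a] - uflat[b]) ** 2).sum())
        return cfg.mu_edge / (cfg.mu_edge + d2)

    return direct_minimizer(u, cfg.lambda_reg, edge_weight_of, cfg.connectivity)


@pytest.fixture(scope="session")
def oracle():
    return direct_minimizer


@pytest.fixture(scope="session")
def fusion_oracle_fn():
    return fusion_oracle


def random_simplex_field(rng, h, w, K):
    x = rng.gamma(1.0, 1.0, size=(h, w, K))
    return x / x.sum(axis=-1, keepdims=True)


@pytest.fixture(scope="session")
def benchmark_scene():
    """Frozen benchmark scene (seed 0): ground truth, stack, scribbles."""
    return gf.generate_scene(gf.benchmark_default())


@pytest.fixture(scope="session")
def benchmark_likelihoods(benchmark_scene):
    """Likelihood fields per source under the benchmark protocol config."""
    gt, stack, scribbles = benchmark_scene
    cfg = gf.benchmark_config(scribbles)
    hists = gf.fit_histograms(stack, scribbles, cfg)
    return gf.evaluate_likelihood(hists, stack), cfg


@pytest.fixture
def small_scene():
    """A 24 x 24, K=3 scene small enough for per-test segmentation."""
    spec = gf.ScenarioSpec(
        shape=(24, 24),
        K=3,
        region_model="voronoi",
        n_regions=6,
        sources=(
            gf.SourceSpec(dims=2, class_means=((0.0, 0.0), (3.0, 0.0), (0.0, 3.0)), class_cov=1.0),
            gf.SourceSpec(dims=2, class_means=((0.0, 0.0), (1.0, 0.0), (0.0, 1.0)), class_cov=1.0),
        ),
        scribble_fraction=0.2,
        seed=7,
    )
    return gf.generate_scene(spec)
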
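import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import faunadiv as fd
from faunadiv.trait_space import build_trait_space

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

TOY_NEWICK = "((A:1,B:1):2,(C:3,D:1):1);"


@pytest.fixture(scope="session")
def toy_tree():
    """The 4-tip reference tree used across the phylogeny tests."""
    return fd.parse_newick(TOY_NEWICK).trees[0]


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic study system shared across pipeline tests."""
    config = fd.SimulationConfig(seed=11, n_species=60, n_trees=10, n_regions=8)
    return fd.simulate_dataset(config)


@pytest.fixture(scope="session")
def small_evaluator(small_dataset):
    space = build_trait_space(small_dataset.species, k=5)
    return fd.MetricEvaluator(small_dataset.ensemble, space)


@pytest.fixture(scope="session")
def continental():
    """The deterministic whole-continent dataset (few trees for speed)."""
    return fd.continental_fixture(n_trees=5)


# ---------------------------------------------------------------------------
# Independent oracles (kept free of the implementation paths they check).
# ---------------------------------------------------------------------------


def brute_force_pd(tree, tips):
    """Faith's PD as the union of edges on all pairwise tip-to-tip paths."""
    tips = list(tips)
    if len(tips) <= 1:
        return 0.0
    idx = {lab: i for i, lab in enumerate(tree.tip_labels)}

    def path_to_root(tip_label):
        nodes = []
        node = idx[tip_label]
        while node != -1:
            nodes.append(node)
            node = int(tree.parent[node])
        return nodes

    edges = set()
    for i, a in enumerate(tips):
        for b in tips[i + 1 :]:
            pa, pb = path_to_root(a), path_to_root(b)
            sa, sb = set(pa), set(pb)
            # Path a->b: edges above nodes strictly below the meeting point.
            for node in pa:
                if node in sb:
                    break
                edges.add(node)
            for node in pb:
                if node in sa:
                    break
                edges.add(node)
    return float(sum(tree.edge_lengths[e] for e in edges))


def monte_carlo_hull_volume(points, n_samples=1_000_000, seed=0):
    """Rejection-sampling estimate of a convex hull's volume."""
    from scipy.spatial import ConvexHull

    points = np.asarray(points, dtype=float)
    hull = ConvexHull(points)
    lo, hi = points.min(axis=0), points.max(axis=0)
    box_volume = float(np.prod(hi - lo))
    rng = np.random.default_rng(seed)
    samples = rng.uniform(lo, hi, size=(n_samples, points.shape[1]))
    inside = in_hull(hull, samples)
    return box_volume * inside.mean()


def in_hull(hull, samples, tol=1e-9, chunk=20_000):
    normals, offsets = hull.equations[:, :-1], hull.equations[:, -1]
    out = np.empty(len(samples), dtype=bool)
    for start in range(0, len(samples), chunk):  # bound memory for many facets
        block = samples[start : start + chunk]
        out[start : start + chunk] = np.all(block @ normals.T + offsets <= tol, axis=1)
    return out


def monte_carlo_overlap_fraction(points_a, points_b, n_samples=1_000_000, seed=0):
    """MC estimate of the fraction of hull(A)'s volume inside hull(B)."""
    from scipy.spatial import ConvexHull

    points_a = np.asarray(points_a, dtype=float)
    hull_a, hull_b = ConvexHull(points_a), ConvexHull(points_b)
    lo, hi = points_a.min(axis=0), points_a.max(axis=0)
    rng = np.random.default_rng(seed)
    samples = rng.uniform(lo, hi, size=(n_samples, points_a.shape[1]))
    in_a = in_hull(hull_a, samples)
    if not in_a.any():
        return 0.0
    return float(in_hull(hull_b, samples[in_a]).mean())
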
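import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import morphoevo as me

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cranium():
    return me.get_template("cranium19")


@pytest.fixture(scope="session")
def mandible():
    return me.get_template("mandible10")


@pytest.fixture(scope="session")
def small_tree():
    """Fixed 8-tip ultrametric tree used by oracle tests."""
    return me.parse_newick(
        "(((t1:1,t2:1):1.5,(t3:0.5,t4:0.5):2):2.5,((t5:2,t6:2):1,(t7:1.5,t8:1.5):1.5):2);"
    )


def random_configs(template, n, noise=0.01, seed=0, with_nuisance=True):
    """Template + small shape noise, optionally disguised by similarity
    transforms: a quick stand-in for digitised specimens."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        pts = template.points + rng.normal(0, noise, template.points.shape)
        if with_nuisance:
            th = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            pts = pts @ R.T * rng.uniform(0.5, 2.0) + rng.uniform(-5, 5, 2)
        out.append(me.LandmarkConfiguration(f"s{i}", pts).with_roles(template))
    return out


@pytest.fixture
def config_factory():
    return random_configs


def opa_distance(a, b, n_grid=3600):
    """Brute-force full Procrustes distance between two configurations:
    centre, scale to unit size, then grid + golden-section search over the
    rotation angle."""
    def unitize(p):
        c = p - p.mean(0)
        return c / np.sqrt((c**2).sum())

    A, B = unitize(np.asarray(a, float)), unitize(np.asarray(b, float))

    def dist(theta):
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        return np.sqrt(((A @ R.T - B) ** 2).sum())

    grid = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    vals = [dist(t) for t in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[i] - 2 * np.pi / n_grid, grid[i] + 2 * np.pi / n_grid
    gr = (np.sqrt(5) - 1) / 2
    for _ in range(200):
        m1, m2 = hi - gr * (hi - lo), lo + gr * (hi - lo)
        if dist(m1) < dist(m2):
            hi = m2
        else:
            lo = m1
    return dist(0.5 * (lo + hi))
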
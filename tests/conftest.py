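import numpy as np
import pytest

from morphomodes import BoundaryTrace, generate_templates, sample_population


def star_polygon(rng, n_vertices=80, irregularity=0.25):
    """A random simple (star-convex) polygon for geometry tests."""
    theta = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    # keep angles distinct
    theta += np.linspace(0, 1e-6, n_vertices)
    r = 1.0 + rng.uniform(-irregularity, irregularity, n_vertices)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


@pytest.fixture
def rng():
    return np.random.default_rng(20250901)


@pytest.fixture(scope="session")
def template_population():
    """A 5-template population with moderate shape noise and its truth."""
    templates = generate_templates(5, irregularity=0.3, seed=11)
    boundaries, truth = sample_population(
        templates, np.full(5, 0.2), 600, shape_noise=0.05, seed=12)
    return templates, boundaries, truth


@pytest.fixture
def unit_square():
    return BoundaryTrace(vertices=np.array(
        [[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


@pytest.fixture
def circle_trace():
    theta = 2 * np.pi * np.arange(400) / 400
    return BoundaryTrace(vertices=np.column_stack(
        [np.cos(theta), np.sin(theta)]))
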
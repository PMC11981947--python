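import numpy as np
import pytest

from liketolike.morphology import SkeletonArbor
from liketolike.synthetic_world import WorldConfig, generate_pair_table


def straight_arbor(kind, start, direction, n_vertices, spacing=1.0, neuron_id=0):
    """Straight polyline arbor along a unit direction."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    verts = np.asarray(start, float) + spacing * np.arange(n_vertices)[:, None] * direction
    edges = np.column_stack([np.arange(n_vertices - 1), np.arange(1, n_vertices)])
    return SkeletonArbor(neuron_id=neuron_id, compartment=kind, vertices=verts, edges=edges)


def random_arbor(kind, rng, n_vertices=80, scale=20.0, neuron_id=0):
    """Random tree: each vertex attaches to a uniformly chosen earlier vertex."""
    verts = [rng.uniform(-scale, scale, 3)]
    edges = []
    for k in range(1, n_vertices):
        parent = int(rng.integers(0, k))
        step = rng.normal(0, 1.5, 3)
        if np.linalg.norm(step) < 1e-3:
            step = np.array([1.0, 0, 0])
        verts.append(verts[parent] + step)
        edges.append((parent, k))
    return SkeletonArbor(
        neuron_id=neuron_id, compartment=kind,
        vertices=np.array(verts), edges=np.array(edges, int),
    )


@pytest.fixture(scope="session")
def small_pair_world():
    """A modest statistical world with known like-to-like slopes."""
    cfg = WorldConfig(
        n_neurons=200, n_presyn_full=25, n_presyn_partial=5, seed=42,
        feature_dim=48, beta_axonal=0.4, beta_synaptic=0.5,
    )
    return generate_pair_table(cfg)
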
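"""Skeleton discretization, proximity geometry, L_d and cohort assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from liketolike.morphology import (
    SkeletonArbor,
    assign_synapses,
    build_cohorts,
    compute_pair_geometry,
    discretize_skeleton,
    somatic_distance,
)

from conftest import random_arbor, straight_arbor


def brute_force_proximity(axon, dendrite, radius=5.0):
    """O(n^2) oracle: all vertex pairs at distance <= radius and the L_d sum."""
    D = cdist(axon.vertices, dendrite.vertices)
    pairs = np.argwhere(D <= radius)
    prox_d = np.unique(pairs[:, 1]) if len(pairs) else np.zeros(0, int)
    touched = [
        k for k, (a, b) in enumerate(dendrite.edges) if a in prox_d or b in prox_d
    ]
    L_d = float(dendrite.edge_lengths[touched].sum())
    return {tuple(p) for p in pairs}, L_d


class TestDiscretize:
    def test_short_edge_unchanged(self):
        arb = straight_arbor("axon", [0, 0, 0], [1, 0, 0], 2, spacing=0.8)
        out = discretize_skeleton(arb)
        assert out.n_vertices == 2
        assert np.allclose(out.edge_lengths, [0.8])

    def test_long_edge_split_equally(self):
        arb = straight_arbor("axon", [0, 0, 0], [1, 0, 0], 2, spacing=2.5)
        out = discretize_skeleton(arb)
        assert len(out.edges) == 3
        assert np.allclose(out.edge_lengths, 2.5 / 3)
        assert np.isclose(out.total_cable, 2.5)

    def test_cable_conserved_on_random_trees(self):
        rng = np.random.default_rng(0)
        for k in range(5):
            arb = random_arbor("dendrite", rng, n_vertices=60)
            out = discretize_skeleton(arb)
            assert np.isclose(out.total_cable, arb.total_cable, rtol=0, atol=1e-9)
            assert out.edge_lengths.max() <= 1.0 + 1e-12

    def test_zero_length_edge_rejected(self):
        arb = SkeletonArbor(
            0, "axon", np.zeros((2, 3)), np.array([[0, 1]])
        )
        with pytest.raises(ValueError, match="zero-length"):
            discretize_skeleton(arb)


class TestPairGeometry:
    def test_distant_arbors_zero(self):
        ax = straight_arbor("axon", [0, 0, 0], [1, 0, 0], 10)
        de = straight_arbor("dendrite", [0, 100, 0], [1, 0, 0], 10)
        prox = compute_pair_geometry(ax, de)
        assert prox.L_d == 0.0 and prox.is_empty

    def test_parallel_lines_co_travel(self):
        # axon x in [0, 20] at y=0; dendrite x in [5, 15] at y=3: every
        # dendritic vertex is proximal, 10 edges of 1 um -> L_d = 10
        ax = straight_arbor("axon", [0, 0, 0], [1, 0, 0], 21)
        de = straight_arbor("dendrite", [5, 3, 0], [1, 0, 0], 11)
        prox = compute_pair_geometry(ax, de)
        assert np.isclose(prox.L_d, 10.0)
        assert len(prox.proximal_dendrite_vertices) == 11
        _, oracle_ld = brute_force_proximity(ax, de)
        assert np.isclose(prox.L_d, oracle_ld)

    @pytest.mark.parametrize("y,expected", [(4.9, 10.0), (5.1, 0.0)])
    def test_radius_boundary_inclusive(self, y, expected):
        ax = straight_arbor("axon", [0, 0, 0], [1, 0, 0], 21)
        de = straight_arbor("dendrite", [5, y, 0], [1, 0, 0], 11)
        prox = compute_pair_geometry(ax, de)
        assert np.isclose(prox.L_d, expected)
        _, oracle_ld = brute_force_proximity(ax, de)
        assert np.isclose(prox.L_d, oracle_ld)

    def test_matches_brute_force_on_random_arbors(self):
        rng = np.random.default_rng(7)
        for k in range(25):
            ax = discretize_skeleton(random_arbor("axon", rng, n_vertices=120, scale=8))
            de = discretize_skeleton(random_arbor("dendrite", rng, n_vertices=120, scale=8))
            prox = compute_pair_geometry(ax, de)
            pairs, oracle_ld = brute_force_proximity(ax, de)
            assert {tuple(p) for p in prox.proximal_vertex_pairs} == pairs
            assert np.isclose(prox.L_d, oracle_ld)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        ax = discretize_skeleton(random_arbor("axon", rng, n_vertices=100, scale=8))
        de = discretize_skeleton(random_arbor("dendrite", rng, n_vertices=100, scale=8))
        base = compute_pair_geometry(ax, de).L_d
        # random rotation + translation applied to both arbors
        from scipy.spatial.transform import Rotation

        R = Rotation.random(rng=123).as_matrix()
        t = np.array([50.0, -20.0, 7.0])
        ax2 = SkeletonArbor(0, "axon", ax.vertices @ R.T + t, ax.edges)
        de2 = SkeletonArbor(1, "dendrite", de.vertices @ R.T + t, de.edges)
        assert np.isclose(compute_pair_geometry(ax2, de2).L_d, base, atol=1e-8)

    def test_finer_discretization_stable(self):
        rng = np.random.default_rng(11)
        ax = discretize_skeleton(random_arbor("axon", rng, n_vertices=80, scale=6))
        de = random_arbor("dendrite", rng, n_vertices=80, scale=6)
        coarse = compute_pair_geometry(ax, discretize_skeleton(de, 1.0)).L_d
        fine = compute_pair_geometry(ax, discretize_skeleton(de, 0.25)).L_d
        # refinement can only move L_d by a bounded amount
        assert abs(coarse - fine) < 0.15 * max(coarse, 1.0) + 2.0


class TestAssignSynapses:
    @staticmethod
    def _setup():
        ax = straight_arbor("axon", [0, 0, 0], [1, 0, 0], 21)
        de = straight_arbor("dendrite", [5, 3, 0], [1, 0, 0], 11)
        prox = compute_pair_geometry(ax, de)
        return ax, de, prox

    def test_synapse_at_proximal_vertex_assigned(self):
        _, de, prox = self._setup()
        syn = pd.DataFrame(
            [{"synapse_id": 0, "pre_id": 0, "post_id": 0, "x": 5.0, "y": 3.0, "z": 0.0}]
        )
        out = assign_synapses(syn, prox, de)
        assert bool(out["adp_assigned"].iloc[0])

    @pytest.mark.parametrize("dz,expected", [(2.9, True), (3.1, False)])
    def test_three_um_boundary(self, dz, expected):
        _, de, prox = self._setup()
        syn = pd.DataFrame(
            [{"synapse_id": 0, "pre_id": 0, "post_id": 0, "x": 10.0, "y": 3.0, "z": dz}]
        )
        out = assign_synapses(syn, prox, de)
        assert bool(out["adp_assigned"].iloc[0]) is expected

    def test_empty_proximity_no_assignment(self):
        ax = straight_arbor("axon", [0, 0, 0], [1, 0, 0], 5)
        de = straight_arbor("dendrite", [0, 50, 0], [1, 0, 0], 5)
        prox = compute_pair_geometry(ax, de)
        syn = pd.DataFrame(
            [{"synapse_id": 0, "pre_id": 0, "post_id": 0, "x": 0.0, "y": 0.0, "z": 0.0}]
        )
        out = assign_synapses(syn, prox, de)
        assert not out["adp_assigned"].any()

    def test_pair_mismatch_flagged_not_dropped(self):
        _, de, prox = self._setup()
        syn = pd.DataFrame(
            [{"synapse_id": 0, "pre_id": 9, "post_id": 9, "x": 5.0, "y": 3.0, "z": 0.0}]
        )
        out = assign_synapses(syn, prox, de)
        assert len(out) == 1
        assert bool(out["pair_mismatch"].iloc[0])
        assert not bool(out["adp_assigned"].iloc[0])


class TestCohorts:
    @staticmethod
    def _units():
        return pd.DataFrame(
            {
                "id": [0, 1, 2, 3, 4],
                "area": ["V1", "V1", "V1", "V1", "HVA"],
                "layer": ["L2/3"] * 5,
                "cc_max": [0.9] * 5,
                "cc_abs": [0.9] * 5,
            }
        )

    def test_toy_cohort_assignment(self):
        # presyn 0; candidates: 1 connected, 2 ADP (L_d>0, no syn),
        # 3 same area L_d=0, 4 other area L_d=0
        units = self._units()
        pairs = pd.DataFrame(
            {
                "pre_id": [0, 0],
                "post_id": [1, 2],
                "L_d": [30.0, 20.0],
                "n_syn": [1, 0],
            }
        )
        out = build_cohorts(units, pairs, [0]).set_index("post_id")["cohort"]
        assert out[1] == "connected"
        assert out[2] == "adp_control"
        assert out[3] == "same_region_control"
        assert out[4] == "excluded"

    def test_adp_priority_over_same_region(self):
        # candidate in the target's region AND with L_d > 0 goes to ADP only
        units = self._units()
        pairs = pd.DataFrame(
            {"pre_id": [0, 0], "post_id": [1, 2], "L_d": [10.0, 5.0], "n_syn": [1, 0]}
        )
        out = build_cohorts(units, pairs, [0]).set_index("post_id")["cohort"]
        assert out[2] == "adp_control"

    def test_reliability_gate_excludes(self):
        units = self._units()
        units.loc[units["id"] == 3, "cc_max"] = 0.3  # fails CC_max > 0.4
        pairs = pd.DataFrame(
            {"pre_id": [0], "post_id": [1], "L_d": [10.0], "n_syn": [1]}
        )
        out = build_cohorts(units, pairs, [0]).set_index("post_id")["cohort"]
        assert out[3] == "excluded"

    def test_missing_presyn_raises(self):
        with pytest.raises(KeyError):
            build_cohorts(self._units(), pd.DataFrame(
                {"pre_id": [], "post_id": [], "L_d": [], "n_syn": []}
            ), [99])


class TestSomaticDistance:
    def test_values_and_symmetry(self):
        assert somatic_distance([1, 2, 3], [1, 2, 3]) == 0.0
        assert somatic_distance([0, 0, 0], [3, 4, 0]) == 5.0
        a, b = [1.5, -2, 7], [0, 4, 1]
        assert somatic_distance(a, b) == somatic_distance(b, a)
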
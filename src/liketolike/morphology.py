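"""Skeleton geometry: discretization, axon-dendrite proximities and cohorts.

The anatomical backbone of the analysis. An axon-dendrite proximity (ADP) is
any place where the axonal skeleton of one neuron passes within ``PROXIMITY_RADIUS``
(5 um) of the dendritic skeleton of another. The co-travel distance ``L_d`` is
the total length of dendritic cable participating in such proximities; it
quantifies the anatomical *opportunity* to synapse, independent of whether a
synapse actually formed (a Peters'-rule control). Synapses are attributed to an
ADP when they fall within ``SYNAPSE_RADIUS`` (3 um) of a proximal vertex.

All coordinates are micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

PROXIMITY_RADIUS = 5.0  # um, axon-dendrite proximity criterion
SYNAPSE_RADIUS = 3.0  # um, synapse-to-proximity assignment
MAX_EDGE = 1.0  # um, skeleton discretization upper bound

#: reliability gates applied to every functional unit entering cohorts
CC_MAX_THRESHOLD = 0.4
CC_ABS_THRESHOLD = 0.2


@dataclass
class SkeletonArbor:
    """Polyline tree of one compartment (axon or dendrite) of one neuron.

    Vertices are 3D points in um; edges are index pairs forming a forest.
    """

    neuron_id: int
    compartment: str  # "axon" | "dendrite"
    vertices: np.ndarray  # (n, 3) float
    edges: np.ndarray  # (m, 2) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if self.compartment not in ("axon", "dendrite"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.edges.size and self.edges.max() >= len(self.vertices):
            raise ValueError("edge references missing vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def edge_lengths(self) -> np.ndarray:
        if not len(self.edges):
            return np.zeros(0)
        a, b = self.edges[:, 0], self.edges[:, 1]
        return np.linalg.norm(self.vertices[a] - self.vertices[b], axis=1)

    @property
    def total_cable(self) -> float:
        return float(self.edge_lengths.sum())

    def validate_forest(self) -> None:
        """Raise if the edge set contains a cycle."""
        n = self.n_vertices
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in self.edges:
            ra, rb = find(int(a)), find(int(b))
            if ra == rb:
                raise ValueError("skeleton edges contain a cycle")
            parent[ra] = rb


@dataclass
class ProximitySet:
    """All proximal vertex pairs between one axon and one dendrite.

    ``L_d`` is the sum of lengths of the dendritic edges incident to at least
    one proximal dendritic vertex, each edge counted once.
    """

    pre_id: int
    post_id: int
    proximal_vertex_pairs: np.ndarray  # (k, 2) int: (axon vertex, dendrite vertex)
    touched_dendrite_edges: np.ndarray  # sorted unique edge indices into dendrite
    L_d: float
    proximal_dendrite_vertices: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    axon_vertices: np.ndarray | None = None  # coordinates of proximal axon vertices

    @property
    def is_empty(self) -> bool:
        return len(self.proximal_vertex_pairs) == 0


def discretize_skeleton(arbor: SkeletonArbor, max_edge: float = MAX_EDGE) -> SkeletonArbor:
    """Subdivide every edge into equal sub-edges no longer than ``max_edge``.

    Geometry is preserved exactly: new vertices lie on the original segments
    and total cable length is conserved to machine precision.
    """
    lengths = arbor.edge_lengths
    if np.any(lengths <= 0):
        raise ValueError("skeleton contains zero-length edges")
    if not len(arbor.edges) or lengths.max() <= max_edge:
        return replace(arbor, vertices=arbor.vertices.copy(), edges=arbor.edges.copy())

    new_vertices = [arbor.vertices]
    new_edges = []
    next_idx = arbor.n_vertices
    for (a, b), length in zip(arbor.edges, lengths):
        n_sub = int(np.ceil(length / max_edge))
        if n_sub == 1:
            new_edges.append((a, b))
            continue
        # interior points at fractions 1/n .. (n-1)/n along the segment
        t = np.arange(1, n_sub)[:, None] / n_sub
        pts = arbor.vertices[a] * (1 - t) + arbor.vertices[b] * t
        new_vertices.append(pts)
        idx = [a] + list(range(next_idx, next_idx + n_sub - 1)) + [b]
        next_idx += n_sub - 1
        new_edges.extend(zip(idx[:-1], idx[1:]))
    return replace(
        arbor,
        vertices=np.concatenate(new_vertices, axis=0),
        edges=np.array(new_edges, dtype=int),
    )


def compute_pair_geometry(
    axon: SkeletonArbor,
    dendrite: SkeletonArbor,
    radius: float = PROXIMITY_RADIUS,
) -> ProximitySet:
    """Find all axon-dendrite vertex pairs within ``radius`` and derive ``L_d``.

    The proximal set is defined set-theoretically (every vertex pair at
    Euclidean distance <= radius, boundary inclusive) and found with a KD-tree.
    Touched dendritic edges are those incident to any proximal dendritic
    vertex; their lengths sum to ``L_d``.
    """
    if axon.compartment != "axon" or dendrite.compartment != "dendrite":
        raise ValueError("expected (axon, dendrite) arbors")
    if axon.n_vertices == 0 or dendrite.n_vertices == 0:
        return ProximitySet(axon.neuron_id, dendrite.neuron_id,
                            np.zeros((0, 2), int), np.zeros(0, int), 0.0)

    tree_a = cKDTree(axon.vertices)
    tree_d = cKDTree(dendrite.vertices)
    neighbours = tree_a.query_ball_tree(tree_d, r=radius)
    pairs = [(ia, id_) for ia, ids in enumerate(neighbours) for id_ in ids]
    if not pairs:
        return ProximitySet(axon.neuron_id, dendrite.neuron_id,
                            np.zeros((0, 2), int), np.zeros(0, int), 0.0)
    pairs = np.array(pairs, dtype=int)
    prox_d = np.unique(pairs[:, 1])
    touched = np.flatnonzero(
        np.isin(dendrite.edges[:, 0], prox_d) | np.isin(dendrite.edges[:, 1], prox_d)
    )
    L_d = float(dendrite.edge_lengths[touched].sum())
    prox_a = np.unique(pairs[:, 0])
    return ProximitySet(
        pre_id=axon.neuron_id,
        post_id=dendrite.neuron_id,
        proximal_vertex_pairs=pairs,
        touched_dendrite_edges=touched,
        L_d=L_d,
        proximal_dendrite_vertices=prox_d,
        axon_vertices=axon.vertices[prox_a],
    )


def proximity_vertex_positions(proximity: ProximitySet, dendrite: SkeletonArbor) -> np.ndarray:
    """Coordinates of every vertex in the proximity (axon and dendrite side)."""
    parts = []
    if proximity.axon_vertices is not None and len(proximity.axon_vertices):
        parts.append(proximity.axon_vertices)
    if len(proximity.proximal_dendrite_vertices):
        parts.append(dendrite.vertices[proximity.proximal_dendrite_vertices])
    if not parts:
        return np.zeros((0, 3))
    return np.concatenate(parts, axis=0)


def assign_synapses(
    synapses: pd.DataFrame,
    proximity: ProximitySet,
    dendrite: SkeletonArbor,
    radius: float = SYNAPSE_RADIUS,
) -> pd.DataFrame:
    """Flag each synapse of the proximity's (pre, post) pair as ADP-assigned.

    A synapse is assigned iff its position lies within ``radius`` (inclusive)
    of any vertex in the proximity. Synapses of other pairs are flagged
    ``pair_mismatch`` rather than silently dropped.
    """
    out = synapses.copy()
    out["adp_assigned"] = False
    out["pair_mismatch"] = (out["pre_id"] != proximity.pre_id) | (
        out["post_id"] != proximity.post_id
    )
    own = ~out["pair_mismatch"]
    verts = proximity_vertex_positions(proximity, dendrite)
    if not len(verts) or not own.any():
        return out
    pos = out.loc[own, ["x", "y", "z"]].to_numpy(float)
    dmin, _ = cKDTree(verts).query(pos, k=1)
    out.loc[own, "adp_assigned"] = dmin <= radius
    return out


def somatic_distance(soma_a, soma_b) -> float:
    """Euclidean distance between two soma centroids (um)."""
    return float(np.linalg.norm(np.asarray(soma_a, float) - np.asarray(soma_b, float)))


def _passes_reliability(row) -> bool:
    return bool(row["cc_max"] > CC_MAX_THRESHOLD and row["cc_abs"] > CC_ABS_THRESHOLD)


def projection_label(pre_area: str, post_area: str) -> str:
    return f"{pre_area}->{post_area}"


def build_cohorts(
    units: pd.DataFrame,
    pairs: pd.DataFrame,
    presyn_ids,
    match_layer: bool = False,
) -> pd.DataFrame:
    """Assign every (presyn, candidate) pair to exactly one control cohort.

    Cohorts, in priority order:

    - ``connected``: at least one synapse (N_syn >= 1).
    - ``adp_control``: no synapse but non-zero co-travel distance L_d — the
      axon passed close to the candidate's dendrites yet did not synapse.
    - ``same_region_control``: no synapse, L_d = 0, candidate located in the
      same cortical area as (one of) the presyn's actual postsynaptic targets
      (optionally also the same layer, for layer-resolved analyses).
    - ``excluded``: everything else, including units failing the reliability
      gates (CC_max > 0.4 and CC_abs > 0.2).

    A candidate qualifying for both controls goes to ``adp_control`` only.

    ``units`` must carry columns id, area, layer, cc_max, cc_abs;
    ``pairs`` must carry pre_id, post_id, L_d, n_syn.
    """
    units = units.set_index("id", drop=False)
    for pid in presyn_ids:
        if pid not in units.index:
            raise KeyError(f"presynaptic unit {pid} absent from unit table")

    pair_idx = pairs.set_index(["pre_id", "post_id"])
    records = []
    for pre in presyn_ids:
        pre_area = units.at[pre, "area"]
        # regions hosting this presyn's synaptic targets define where
        # same-region controls may be recruited
        connected_posts = pairs.loc[
            (pairs["pre_id"] == pre) & (pairs["n_syn"] >= 1), "post_id"
        ]
        target_regions = set()
        for post in connected_posts:
            if post in units.index:
                key = (units.at[post, "area"], units.at[post, "layer"])
                target_regions.add(key if match_layer else key[0])
        for post, post_row in units.iterrows():
            if post == pre:
                continue
            try:
                prow = pair_idx.loc[(pre, post)]
                L_d = float(prow["L_d"])
                n_syn = int(prow["n_syn"])
            except KeyError:
                L_d, n_syn = 0.0, 0
            reliable = _passes_reliability(post_row)
            key = (post_row["area"], post_row["layer"])
            same_region = (key if match_layer else key[0]) in target_regions
            if not reliable:
                cohort = "excluded"
            elif n_syn >= 1:
                cohort = "connected"
            elif L_d > 0:
                cohort = "adp_control"
            elif same_region:
                cohort = "same_region_control"
            else:
                cohort = "excluded"
            records.append(
                {
                    "pre_id": pre,
                    "post_id": post,
                    "projection": projection_label(pre_area, post_row["area"]),
                    "cohort": cohort,
                    "L_d": L_d,
                    "n_syn": n_syn,
                }
            )
    return pd.DataFrame.from_records(records)
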
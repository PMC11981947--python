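"""Synthetic cortical volumes with configurable ground-truth wiring rules.

Emulates the statistical structure of a functional-connectomics volume: two
visual areas separated by a boundary plane, three cortical layers, neurons
with axonal/dendritic arbors, smooth retinotopy with configurable scatter, a
locally biased orientation map, and connectivity that is like-to-like at two
scales — the axonal scale (log mean co-travel distance L_d increases with
functional similarity at slope ``beta_axonal``) and the synaptic scale (log
synapse rate per mm of L_d increases at slope ``beta_synaptic``). An optional
higher-order "assembly" factor makes presynaptic neurons prefer postsynaptic
targets from one functional cluster, producing postsynaptic cohorts more
similar to each other than any pairwise rule predicts.

Two generation paths are provided:

- :func:`generate_world` builds a full geometric world (branching-walk
  arbors, KD-tree proximities, synapses placed on proximity vertices) for
  geometry-facing analyses;
- :func:`generate_pair_table` draws the same pair-level law (compound
  Poisson-gamma L_d, Poisson N_syn) directly, for statistical analyses at
  sample sizes where per-vertex geometry is irrelevant.

Every generator is deterministic given ``config.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from liketolike.glmm import sample_compound_poisson_gamma
from liketolike.morphology import (
    SkeletonArbor,
    compute_pair_geometry,
    discretize_skeleton,
)

MIN_SOMA_SPACING = 10.0  # um, documented minimum inter-soma distance

#: fraction of feature-vector energy carried by the orientation-tuned
#: components (fixes how strongly feature cosine tracks orientation match)
TUNING_STRENGTH = 0.7

#: assemblies used by the higher-order term: preferred-orientation clusters
N_ASSEMBLIES = 4


@dataclass
class WorldConfig:
    """Ground-truth parameters of a synthetic volume.

    Counts and scales default to a desk-sized volume; the statistical
    structure (not the absolute size) mirrors a millimetre-scale cortical
    recording with ~150 proofread presynaptic neurons and thousands of
    co-registered postsynaptic candidates.
    """

    n_neurons: int = 150
    volume_extent: tuple = (400.0, 400.0, 400.0)  # um; z is cortical depth
    area_boundary: float = 200.0  # x position of the V1/HVA border, um
    layer_depth_ranges: dict = field(
        default_factory=lambda: {"L2/3": (0.0, 150.0), "L4": (150.0, 250.0), "L5": (250.0, 400.0)}
    )
    n_presyn_full: int = 10
    n_presyn_partial: int = 5
    feature_dim: int = 512
    rf_scatter: float = 3.0  # degrees of visual angle
    orientation_map_bias: float = 0.5  # 0 = salt-and-pepper, 1 = smooth map
    beta_axonal: float = 0.5  # d log E[L_d] / d similarity
    beta_synaptic: float = 0.5  # d log synapse rate / d similarity
    baseline_synapse_rate: float = 1.0  # synapses per mm of L_d at similarity 0
    higher_order_strength: float = 0.0  # log-rate boost within the presyn's assembly
    noise_sd: float = 0.5  # response noise, response units
    n_trials: int = 10
    seed: int = 0
    # morphology of generated arbors
    axon_cable_target: float = 2000.0  # um
    dendrite_cable_target: float = 800.0  # um
    dendrite_radius: float = 300.0  # um, hard bound on dendritic extent
    branch_prob: float = 0.06  # per 2-um step
    # pair-level generator scale parameters
    mean_ld_um: float = 120.0  # E[L_d] at similarity 0 among proximal pairs
    ld_gamma_shape: float = 1.5  # shape of per-proximity gamma stretches
    ld_mean_contacts: float = 2.0  # Poisson mean number of proximity stretches

    def validate(self) -> None:
        for name in ("n_neurons", "n_presyn_full", "n_presyn_partial", "feature_dim", "n_trials"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.baseline_synapse_rate <= 0:
            raise ValueError("baseline_synapse_rate must be positive")
        if self.higher_order_strength < 0:
            raise ValueError("higher_order_strength must be >= 0")
        if not 0.0 <= self.orientation_map_bias <= 1.0:
            raise ValueError("orientation_map_bias must lie in [0, 1]")
        spans = sorted(self.layer_depth_ranges.values())
        for (a0, a1), (b0, b1) in zip(spans[:-1], spans[1:]):
            if a1 > b0:
                raise ValueError("layer depth ranges overlap")
        if self.n_presyn_full + self.n_presyn_partial > self.n_neurons:
            raise ValueError("more presynaptic neurons than neurons")
        # crude packing feasibility at the documented minimum spacing
        vol = float(np.prod(self.volume_extent))
        if self.n_neurons * (MIN_SOMA_SPACING ** 3) > vol:
            raise ValueError(
                f"volume cannot host {self.n_neurons} somas at "
                f"{MIN_SOMA_SPACING} um minimum spacing"
            )


@dataclass
class ResponseMatrix:
    """Binned model responses plus a repeated-stimulus block."""

    unit_ids: np.ndarray
    values: np.ndarray  # (units, bins)
    bin_width_ms: float
    repeat_block: np.ndarray | None = None  # (n_repeats, units, bins)
    repeat_signal: np.ndarray | None = None  # noiseless drive for the repeats


@dataclass
class SyntheticWorld:
    units: pd.DataFrame
    axons: dict
    dendrites: dict
    tuning: pd.DataFrame
    feature_weights: np.ndarray  # (n_neurons, feature_dim), unit rows
    direction_responses: np.ndarray  # (n_neurons, 16)
    proximities: dict
    pairs: pd.DataFrame
    synapses: pd.DataFrame
    responses: ResponseMatrix | None
    ground_truth: WorldConfig


# ---------------------------------------------------------------------------
# soma placement and tuning latents
# ---------------------------------------------------------------------------

def _place_somas(config: WorldConfig, rng: np.random.Generator) -> np.ndarray:
    ext = np.asarray(config.volume_extent, float)
    placed = []
    tries = 0
    max_tries = 200 * config.n_neurons
    while len(placed) < config.n_neurons:
        if tries > max_tries:
            raise ValueError(
                "volume cannot host requested somas at minimum spacing "
                f"{MIN_SOMA_SPACING} um"
            )
        p = rng.uniform(0, ext)
        tries += 1
        if placed:
            d = np.linalg.norm(np.array(placed) - p, axis=1).min()
            if d < MIN_SOMA_SPACING:
                continue
        placed.append(p)
    return np.array(placed)


def _layer_of(depth: float, ranges: dict) -> str:
    for name, (lo, hi) in ranges.items():
        if lo <= depth < hi:
            return name
    # depth at the very bottom of the volume belongs to the deepest layer
    return max(ranges, key=lambda k: ranges[k][1])


def _orientation_map(somas: np.ndarray, config: WorldConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Preferred orientations in [0, 180) with tunable spatial smoothness.

    In double-angle space each unit's orientation vector is a convex mixture
    of a smooth sinusoidal map over cortical position and an iid random
    vector; ``orientation_map_bias`` is the mixture weight of the map.
    """
    ext = np.asarray(config.volume_extent, float)
    phase = 2 * np.pi * (somas[:, 0] / ext[0] + somas[:, 1] / ext[1])
    map_vec = np.column_stack([np.cos(phase), np.sin(phase)])
    rnd = rng.normal(size=(len(somas), 2))
    rnd /= np.linalg.norm(rnd, axis=1, keepdims=True)
    b = config.orientation_map_bias
    mix = b * map_vec + (1 - b) * rnd
    double_angle = np.arctan2(mix[:, 1], mix[:, 0])
    return np.degrees(double_angle % (2 * np.pi)) / 2.0


def _feature_vectors(pref_ori_deg: np.ndarray, feature_dim: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Unit-norm feature-weight vectors whose cosine tracks orientation match."""
    n = len(pref_ori_deg)
    theta2 = np.radians(2 * pref_ori_deg)
    tuned = np.column_stack([np.cos(theta2), np.sin(theta2)])
    rest = rng.normal(size=(n, feature_dim - 2))
    rest /= np.linalg.norm(rest, axis=1, keepdims=True)
    w = np.concatenate(
        [np.sqrt(TUNING_STRENGTH) * tuned, np.sqrt(1 - TUNING_STRENGTH) * rest], axis=1
    )
    return w / np.linalg.norm(w, axis=1, keepdims=True)


def _readout_locations(somas: np.ndarray, config: WorldConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Retinotopy: isotropic linear map of tangential soma position to the
    monitor, in normalized [-1, 1] coordinates, jittered by ``rf_scatter``
    degrees (converted at ~60 degrees of visual field per monitor width)."""
    ext = np.asarray(config.volume_extent, float)
    scale = 2.0 / max(ext[0], ext[1])  # same factor on both axes: isotropic
    loc = (somas[:, :2] - ext[:2] / 2) * scale * 0.5
    jitter_norm = config.rf_scatter / 60.0
    loc = loc + rng.normal(0, jitter_norm, size=loc.shape)
    return loc


def _direction_tuning_curves(pref_ori_deg: np.ndarray, rng: np.random.Generator,
                             n_directions: int = 16) -> np.ndarray:
    from liketolike.functional_similarity import von_mises_mixture

    theta = np.radians(np.arange(n_directions) * 360.0 / n_directions)
    n = len(pref_ori_deg)
    pref_dir = np.radians(pref_ori_deg + 180.0 * rng.integers(0, 2, n))
    kappa = rng.gamma(4.0, 0.5, n)
    alpha = rng.uniform(0.8, 1.2, n)
    beta = alpha * rng.uniform(0.3, 0.7, n)
    gamma = rng.uniform(0.05, 0.15, n)
    return np.stack(
        [von_mises_mixture(theta, m, k, a, b, g)
         for m, k, a, b, g in zip(pref_dir, kappa, alpha, beta, gamma)]
    )


def make_units(config: WorldConfig, rng: np.random.Generator):
    """Unit table + tuning latents shared by both generation paths."""
    somas = _place_somas(config, rng)
    n = config.n_neurons
    area = np.where(somas[:, 0] < config.area_boundary, "V1", "HVA")
    layer = [_layer_of(z, config.layer_depth_ranges) for z in somas[:, 2]]
    n_pre = config.n_presyn_full + config.n_presyn_partial
    proofread = np.array(["none"] * n, dtype=object)
    pre_ids = rng.choice(n, size=n_pre, replace=False)
    proofread[pre_ids[: config.n_presyn_full]] = "full"
    proofread[pre_ids[config.n_presyn_full:]] = "partial"

    pref_ori = _orientation_map(somas, config, rng)
    W = _feature_vectors(pref_ori, config.feature_dim, rng)
    locs = _readout_locations(somas, config, rng)
    direction_responses = _direction_tuning_curves(pref_ori, rng)
    assembly = np.floor(pref_ori / (180.0 / N_ASSEMBLIES)).astype(int) % N_ASSEMBLIES
    # target assembly: the functional cluster a presyn's higher-order factor
    # favours; assigned to every unit, consumed only for presynaptic ones
    target_assembly = rng.integers(0, N_ASSEMBLIES, n)

    units = pd.DataFrame(
        {
            "id": np.arange(n),
            "x": somas[:, 0],
            "y": somas[:, 1],
            "z": somas[:, 2],
            "area": area,
            "layer": layer,
            "proofread": proofread,
            "pref_orientation": pref_ori,
            "readout_x": locs[:, 0],
            "readout_y": locs[:, 1],
            "assembly": assembly,
            "target_assembly": target_assembly,
        }
    )
    return units, W, direction_responses


# ---------------------------------------------------------------------------
# arbors
# ---------------------------------------------------------------------------

def generate_arbor(
    soma,
    kind: str,
    extent_params: dict,
    rng: np.random.Generator,
    neuron_id: int = 0,
) -> SkeletonArbor:
    """Branching random walk rooted at the soma.

    ``extent_params`` keys: ``total_cable`` (um, walk stops when reached —
    the realized cable equals the target up to one step), ``step`` (um,
    default 2), ``branch_prob`` (per step), ``radius_limit`` (um or None;
    steps leaving the radius are reflected back toward the soma),
    ``persistence`` (0..1 directional inertia).
    """
    soma = np.asarray(soma, float)
    total = float(extent_params["total_cable"])
    step = float(extent_params.get("step", 2.0))
    branch_p = float(extent_params.get("branch_prob", 0.05))
    radius = extent_params.get("radius_limit")
    persistence = float(extent_params.get("persistence", 0.8))

    vertices = [soma]
    edges = []
    # active growth cones: (vertex index, direction)
    d0 = rng.normal(size=3)
    d0 /= np.linalg.norm(d0)
    cones = [(0, d0)]
    cable = 0.0
    while cable < total and cones:
        new_cones = []
        for idx, direction in cones:
            if cable >= total:
                new_cones.append((idx, direction))
                continue
            wobble = rng.normal(size=3)
            wobble /= np.linalg.norm(wobble)
            d = persistence * direction + (1 - persistence) * wobble
            d /= np.linalg.norm(d)
            nxt = vertices[idx] + d * step
            if radius is not None and np.linalg.norm(nxt - soma) > radius:
                back = soma - vertices[idx]
                nb = np.linalg.norm(back)
                d = back / nb if nb > 0 else -d
                nxt = vertices[idx] + d * step
            vertices.append(nxt)
            j = len(vertices) - 1
            edges.append((idx, j))
            cable += step
            new_cones.append((j, d))
            if branch_p > 0 and rng.random() < branch_p and cable < total:
                bd = rng.normal(size=3)
                bd /= np.linalg.norm(bd)
                new_cones.append((idx, bd))
        cones = new_cones
    return SkeletonArbor(
        neuron_id=neuron_id,
        compartment=kind,
        vertices=np.array(vertices),
        edges=np.array(edges, int) if edges else np.zeros((0, 2), int),
    )


# ---------------------------------------------------------------------------
# similarity + synapse law shared by both paths
# ---------------------------------------------------------------------------

def pairwise_similarity(W: np.ndarray, i_idx, j_idx) -> np.ndarray:
    """Cosine similarity of feature latents for index arrays (rows are unit-norm)."""
    return np.einsum("ij,ij->i", W[i_idx], W[j_idx])


def synapse_rate(
    L_d_um: np.ndarray,
    similarity: np.ndarray,
    config: WorldConfig,
    same_assembly: np.ndarray | None = None,
) -> np.ndarray:
    """Poisson mean synapse count for pairs:

    N_syn ~ Pois(L_d[mm] * baseline_rate * exp(beta_synaptic * Sim + h * A)),

    with A = 1 when the postsynaptic unit belongs to the presynaptic unit's
    *target assembly* — a functional cluster assigned to each presynaptic
    neuron independently of its own tuning. Because the boost concentrates a
    presyn's targets inside one mutually-similar cluster without being a
    function of pre-post similarity, no pairwise rule can reproduce it: the
    signature of higher-order structure. Absent when
    ``higher_order_strength`` = 0.
    """
    log_rate = np.log(config.baseline_synapse_rate) + config.beta_synaptic * similarity
    if same_assembly is not None and config.higher_order_strength > 0:
        log_rate = log_rate + config.higher_order_strength * same_assembly
    return (np.asarray(L_d_um, float) / 1000.0) * np.exp(log_rate)


def sample_synapses(
    world: SyntheticWorld,
    config: WorldConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw synapses for every pair with a computed proximity.

    Counts follow :func:`synapse_rate`; each synapse sits at the midpoint of
    a randomly chosen proximal axon-dendrite vertex pair (so it lies within
    3 um of both skeletons), with sub-um jitter; cleft volumes are log-normal
    with a mild similarity-dependent mean shift. Pairs with L_d = 0 receive
    no synapses.
    """
    config = config or world.ground_truth
    rng = rng or np.random.default_rng(config.seed + 1)
    units = world.units.set_index("id")
    rows = []
    syn_id = 0
    for (pre, post), prox in world.proximities.items():
        if prox.L_d <= 0:
            continue
        sim = float(world.feature_weights[pre] @ world.feature_weights[post])
        same_asm = float(units.at[post, "assembly"] == units.at[pre, "target_assembly"])
        lam = synapse_rate(np.array([prox.L_d]), np.array([sim]), config,
                           np.array([same_asm]))[0]
        n_syn = rng.poisson(lam)
        if n_syn == 0:
            continue
        dend = world.dendrites[post]
        axon = world.axons[pre]
        pick = rng.integers(0, len(prox.proximal_vertex_pairs), n_syn)
        pa = axon.vertices[prox.proximal_vertex_pairs[pick, 0]]
        pd_ = dend.vertices[prox.proximal_vertex_pairs[pick, 1]]
        pos = 0.5 * (pa + pd_) + rng.normal(0, 0.15, size=(n_syn, 3))
        cleft = rng.lognormal(np.log(5000.0) + 0.3 * sim, 0.5, n_syn)
        for k in range(n_syn):
            rows.append(
                {
                    "synapse_id": syn_id,
                    "pre_id": pre,
                    "post_id": post,
                    "x": pos[k, 0],
                    "y": pos[k, 1],
                    "z": pos[k, 2],
                    "cleft_volume": cleft[k],
                }
            )
            syn_id += 1
    cols = ["synapse_id", "pre_id", "post_id", "x", "y", "z", "cleft_volume"]
    return pd.DataFrame(rows, columns=cols)


def simulate_responses(
    feature_weights: np.ndarray,
    n_time_bins: int = 300,
    n_repeat_trials: int = 10,
    noise_sd: float = 0.5,
    seed: int = 0,
    n_repeat_bins: int = 60,
    unit_ids=None,
) -> ResponseMatrix:
    """Shared stimulus drive through each unit's feature weights, plus noise.

    The stimulus is a white latent feature time course; unit signal is a
    softplus of its projection (non-negative), so signal correlation grows
    with feature-cosine by construction. A repeated-stimulus block (same
    signal, fresh noise per repeat) supports CC_max estimation.
    """
    rng = np.random.default_rng(seed)
    W = np.asarray(feature_weights, float)
    n_units, fdim = W.shape
    drive = rng.normal(size=(fdim, n_time_bins))
    signal = np.logaddexp(0.0, 3.0 * (W @ drive))  # softplus, gain 3
    values = signal + rng.normal(0, noise_sd, size=signal.shape) if noise_sd > 0 else signal.copy()

    rep_drive = rng.normal(size=(fdim, n_repeat_bins))
    rep_signal = np.logaddexp(0.0, 3.0 * (W @ rep_drive))
    reps = np.stack(
        [
            rep_signal + (rng.normal(0, noise_sd, rep_signal.shape) if noise_sd > 0 else 0.0)
            for _ in range(n_repeat_trials)
        ]
    )
    if unit_ids is None:
        unit_ids = np.arange(n_units)
    return ResponseMatrix(
        unit_ids=np.asarray(unit_ids), values=values, bin_width_ms=500.0,
        repeat_block=reps, repeat_signal=rep_signal,
    )


# ---------------------------------------------------------------------------
# full geometric world
# ---------------------------------------------------------------------------

def generate_world(config: WorldConfig, with_responses: bool = True) -> SyntheticWorld:
    """Build a complete geometric synthetic volume.

    Arbors are grown for every neuron (axons only matter for presynaptic
    neurons but are generated for all, with fully proofread axons grown to
    the full cable target and partially proofread ones to half). Proximities
    and L_d are computed for every (presynaptic, other) pair with the 5-um
    criterion after 1-um discretization, and synapses are drawn from the
    configured pair-level law.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    units, W, dir_resp = make_units(config, rng)

    axons, dendrites = {}, {}
    for _, row in units.iterrows():
        uid = int(row["id"])
        soma = row[["x", "y", "z"]].to_numpy(float)
        cable = config.axon_cable_target
        if row["proofread"] == "partial":
            cable *= 0.5
        elif row["proofread"] == "none":
            cable *= 0.25  # unproofread axons are heavily truncated
        axons[uid] = discretize_skeleton(
            generate_arbor(
                soma, "axon",
                {"total_cable": cable, "branch_prob": config.branch_prob,
                 "persistence": 0.9},
                rng, neuron_id=uid,
            )
        )
        dendrites[uid] = discretize_skeleton(
            generate_arbor(
                soma, "dendrite",
                {"total_cable": config.dendrite_cable_target,
                 "branch_prob": config.branch_prob * 2,
                 "radius_limit": config.dendrite_radius, "persistence": 0.7},
                rng, neuron_id=uid,
            )
        )

    presyn_ids = units.loc[units["proofread"] != "none", "id"].to_numpy()
    proximities = {}
    for pre in presyn_ids:
        for post in units["id"]:
            if post == pre:
                continue
            prox = compute_pair_geometry(axons[pre], dendrites[post])
            if prox.L_d > 0:
                proximities[(int(pre), int(post))] = prox

    world = SyntheticWorld(
        units=units, axons=axons, dendrites=dendrites,
        tuning=units[["id", "pref_orientation", "readout_x", "readout_y", "assembly"]].copy(),
        feature_weights=W, direction_responses=dir_resp,
        proximities=proximities, pairs=pd.DataFrame(), synapses=pd.DataFrame(),
        responses=None, ground_truth=dataclasses.replace(config),
    )
    world.synapses = sample_synapses(world, config, np.random.default_rng(config.seed + 1))
    world.pairs = _pair_table_from_world(world, presyn_ids)
    if with_responses:
        world.responses = simulate_responses(
            W, noise_sd=config.noise_sd, n_repeat_trials=config.n_trials,
            seed=config.seed + 2, unit_ids=units["id"].to_numpy(),
        )
    return world


def _pair_table_from_world(world: SyntheticWorld, presyn_ids) -> pd.DataFrame:
    units = world.units.set_index("id")
    syn_counts = (
        world.synapses.groupby(["pre_id", "post_id"]).size()
        if len(world.synapses) else pd.Series(dtype=int)
    )
    rows = []
    for pre in presyn_ids:
        for post in world.units["id"]:
            if post == pre:
                continue
            prox = world.proximities.get((int(pre), int(post)))
            L_d = prox.L_d if prox is not None else 0.0
            n_syn = int(syn_counts.get((pre, post), 0))
            sim = float(world.feature_weights[pre] @ world.feature_weights[post])
            rows.append(
                {
                    "pre_id": int(pre),
                    "post_id": int(post),
                    "projection": f"{units.at[pre, 'area']}->{units.at[post, 'area']}",
                    "proofread": units.at[pre, "proofread"],
                    "L_d": L_d,
                    "n_syn": n_syn,
                    "feature_similarity": sim,
                    "somatic_distance": float(
                        np.linalg.norm(
                            units.loc[pre, ["x", "y", "z"]].to_numpy(float)
                            - units.loc[post, ["x", "y", "z"]].to_numpy(float)
                        )
                    ),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pair-level statistical world
# ---------------------------------------------------------------------------

def generate_pair_table(
    config: WorldConfig,
    rng: np.random.Generator | None = None,
    presyn_sd: float = 0.3,
) -> dict:
    """Draw the pair-level generative law directly, skipping geometry.

    For every (presynaptic, other) pair:

    - L_d is compound Poisson-gamma: N contacts ~ Pois(ld_mean_contacts),
      each contributing a Gamma stretch, with log mean scaled by
      ``beta_axonal * similarity`` plus a presynaptic random intercept;
    - N_syn | L_d ~ Pois(L_d[mm] * baseline * exp(beta_synaptic * Sim
      + higher_order_strength * same-assembly)).

    Returns a dict with ``pairs`` (DataFrame), ``units``, ``feature_weights``,
    ``signal_correlations`` proxy matrix inputs and the config.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    units, W, dir_resp = make_units(config, rng)
    n = config.n_neurons
    presyn_ids = units.loc[units["proofread"] != "none", "id"].to_numpy()
    post_ids = units["id"].to_numpy()

    pre_intercept = {p: rng.normal(0, presyn_sd) for p in presyn_ids}
    target_assembly = units.set_index("id")["target_assembly"]

    pre_col, post_col = [], []
    for pre in presyn_ids:
        for post in post_ids:
            if post != pre:
                pre_col.append(pre)
                post_col.append(post)
    pre_col = np.array(pre_col)
    post_col = np.array(post_col)
    sim = pairwise_similarity(W, pre_col, post_col)

    # axonal scale: CPG L_d with log-mean like-to-like
    u_pre = np.array([pre_intercept[p] for p in pre_col])
    gamma_mean0 = config.mean_ld_um / config.ld_mean_contacts
    lam_contacts = config.ld_mean_contacts * np.exp(
        config.beta_axonal * sim + u_pre
    )
    L_d = sample_compound_poisson_gamma(
        lam_contacts, gamma_mean0, config.ld_gamma_shape, rng
    )

    asm = units.set_index("id")["assembly"]
    tgt = target_assembly.loc[pre_col].to_numpy()
    same_asm = (asm.loc[post_col].to_numpy() == tgt).astype(float)
    lam_syn = synapse_rate(L_d, sim, config, same_asm) * np.exp(u_pre)
    n_syn = rng.poisson(lam_syn)

    area = units.set_index("id")["area"]
    pr = units.set_index("id")["proofread"]
    soma = units.set_index("id")[["x", "y", "z"]]
    d_soma = np.linalg.norm(
        soma.loc[pre_col].to_numpy(float) - soma.loc[post_col].to_numpy(float), axis=1
    )
    pairs = pd.DataFrame(
        {
            "pre_id": pre_col,
            "post_id": post_col,
            "projection": [f"{area.loc[a]}->{area.loc[b]}" for a, b in zip(pre_col, post_col)],
            "proofread": pr.loc[pre_col].to_numpy(),
            "L_d": L_d,
            "n_syn": n_syn,
            "feature_similarity": sim,
            "same_assembly": same_asm,
            "somatic_distance": d_soma,
        }
    )
    return {
        "pairs": pairs,
        "units": units,
        "feature_weights": W,
        "direction_responses": dir_resp,
        "config": config,
    }
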
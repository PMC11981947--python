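"""Standard-format I/O and the end-to-end pipeline.

SWC reader/writer for skeletons (7-column, type field 2 = axon,
3 = dendrite), CSV tables for units/synapses/pairs, a YAML key-value config,
and :func:`run_pipeline`, which runs the stages in dependency order on a
synthetic world and writes every result table plus a JSON run manifest
(config hash, seeds, thresholds, row counts at each filter).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from liketolike import morphology
from liketolike.morphology import SkeletonArbor
from liketolike.synthetic_world import WorldConfig

logger = logging.getLogger("liketolike")

SWC_TYPE_CODES = {"soma": 1, "axon": 2, "dendrite": 3}
SWC_TYPE_NAMES = {2: "axon", 3: "dendrite"}


@dataclass
class PipelineConfig:
    """Thresholds default to the analysis' canonical values; the config is
    echoed verbatim into the output directory of every run."""

    world: WorldConfig = field(default_factory=WorldConfig)
    proximity_radius_um: float = morphology.PROXIMITY_RADIUS
    synapse_radius_um: float = morphology.SYNAPSE_RADIUS
    discretization_um: float = morphology.MAX_EDGE
    cc_max_threshold: float = 0.4
    cc_abs_threshold: float = 0.2
    gosi_threshold: float = 0.25
    seed: int = 0
    run_cohorts: bool = True
    run_glmm: bool = True
    run_binned: bool = True
    run_common_input: bool = True
    run_rnn: bool = False  # heavy; off by default in the smoke pipeline
    n_boot: int = 200
    output_dir: str = "results"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["world"]["layer_depth_ranges"] = {
            k: list(v) for k, v in d["world"]["layer_depth_ranges"].items()
        }
        d["world"]["volume_extent"] = list(d["world"]["volume_extent"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        wd = dict(d.pop("world", {}))
        if "layer_depth_ranges" in wd:
            wd["layer_depth_ranges"] = {
                k: tuple(v) for k, v in wd["layer_depth_ranges"].items()
            }
        if "volume_extent" in wd:
            wd["volume_extent"] = tuple(wd["volume_extent"])
        return cls(world=WorldConfig(**wd), **d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

def read_swc(path) -> SkeletonArbor:
    """Parse a standard 7-column SWC file into a skeleton.

    The type column selects the compartment (2 = axon, 3 = dendrite; the
    first non-soma code present wins and must be unique within the file).
    Malformed lines and cyclic parent references raise with the line number.
    """
    ids, types, xyz, parents = [], [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                ids.append(int(parts[0]))
                types.append(int(parts[1]))
                xyz.append([float(parts[2]), float(parts[3]), float(parts[4])])
                parents.append(int(parts[6]))
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from None
    id_to_idx = {i: k for k, i in enumerate(ids)}
    edges = []
    for k, par in enumerate(parents):
        if par == -1:
            continue
        if par not in id_to_idx:
            raise ValueError(f"{path}: parent {par} of node {ids[k]} missing")
        edges.append((id_to_idx[par], k))
    comp_codes = {t for t in types if t in SWC_TYPE_NAMES}
    compartment = SWC_TYPE_NAMES[comp_codes.pop()] if comp_codes else "dendrite"
    arbor = SkeletonArbor(
        neuron_id=0,
        compartment=compartment,
        vertices=np.array(xyz),
        edges=np.array(edges, int) if edges else np.zeros((0, 2), int),
    )
    arbor.validate_forest()
    return arbor


def write_swc(arbor: SkeletonArbor, path) -> None:
    """Write a skeleton as SWC; vertex order and edge structure round-trip."""
    code = SWC_TYPE_CODES[arbor.compartment]
    parent = np.full(arbor.n_vertices, -1, int)
    for a, b in arbor.edges:
        parent[b] = a
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for k in range(arbor.n_vertices):
            x, y, z = arbor.vertices[k]
            par = parent[k] + 1 if parent[k] >= 0 else -1
            fh.write(f"{k + 1} {code} {x:.6f} {y:.6f} {z:.6f} 1.0 {par}\n")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the synthetic-mode pipeline end to end.

    Stages: world generation, reliability scoring, cohort assignment, mixed
    models, binned effect curves, common-input test. Each stage's outputs
    are written as CSV/JSON under ``config.output_dir``; the manifest
    records seeds, thresholds, stage timings and row counts at every filter.
    Stage failures preserve partial outputs and mark the failure point.
    """
    from liketolike import common_input, functional_similarity as fs, likelike_stats
    from liketolike.synthetic_world import generate_pair_table

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    h = config.config_hash
    manifest = {
        "config_hash": h,
        "seed": config.seed,
        "thresholds": {
            "proximity_um": config.proximity_radius_um,
            "synapse_um": config.synapse_radius_um,
            "discretization_um": config.discretization_um,
            "cc_max": config.cc_max_threshold,
            "cc_abs": config.cc_abs_threshold,
            "gosi": config.gosi_threshold,
        },
        "stages": [],
        "filter_counts": {},
        "status": "running",
    }

    def stage(name):
        manifest["stages"].append({"name": name, "t": time.strftime("%H:%M:%S")})
        logger.info("stage: %s", name)

    try:
        stage("simulate")
        world_cfg = config.world
        world_cfg.seed = config.seed
        sim = generate_pair_table(world_cfg)
        units, pairs, W = sim["units"], sim["pairs"], sim["feature_weights"]
        from liketolike.synthetic_world import simulate_responses

        responses = simulate_responses(
            W, noise_sd=world_cfg.noise_sd, n_repeat_trials=world_cfg.n_trials,
            seed=config.seed + 2,
        )

        stage("reliability")
        reps = responses.repeat_block  # (R, units, bins)
        cc_max_vals = np.array([fs.cc_max(reps[:, u, :]) for u in range(reps.shape[1])])
        # model-vs-data correlation on the repeat block (signal vs trial mean)
        units = units.copy()
        units["cc_max"] = cc_max_vals
        units["cc_abs"] = np.array(
            [
                fs.cc_abs(responses.repeat_signal[u], reps[:, u, :].mean(axis=0))
                for u in range(reps.shape[1])
            ]
        )
        passed = units[
            (units["cc_max"] > config.cc_max_threshold)
            & (units["cc_abs"] > config.cc_abs_threshold)
        ]
        manifest["filter_counts"]["units_total"] = int(len(units))
        manifest["filter_counts"]["units_passing_reliability"] = int(len(passed))
        _write_csv(units, out / "units.csv", h)

        keep = set(passed["id"])
        pairs = pairs[pairs["pre_id"].isin(keep) & pairs["post_id"].isin(keep)].copy()
        manifest["filter_counts"]["pairs_after_reliability"] = int(len(pairs))

        if config.run_cohorts:
            stage("cohorts")
            pairs["cohort"] = np.where(
                pairs["n_syn"] >= 1, "connected",
                np.where(pairs["L_d"] > 0, "adp_control", "same_region_control"),
            )
            tests = likelike_stats.cohort_mean_test(pairs, "feature_similarity")
            _write_csv(tests, out / "cohort_tests.csv", h)
            manifest["filter_counts"]["connected_pairs"] = int((pairs["n_syn"] >= 1).sum())

        if config.run_binned:
            stage("binned")
            eff = likelike_stats.centered_binned_effect(
                pairs, "feature_similarity", mode="density",
                n_boot=config.n_boot, seed=config.seed,
            )
            _write_csv(eff.table, out / "binned_density.csv", h)

        if config.run_glmm:
            stage("glmm")
            from liketolike.likelike_stats import GlmmSpec, fit_likelike_glmm

            fit = fit_likelike_glmm(pairs, GlmmSpec(response="N_syn"))
            coefs = likelike_stats.extract_likelike_coefficients(fit)
            _write_csv(coefs, out / "likelike_coefficients.csv", h)
            (out / "glmm_report.json").write_text(
                json.dumps(
                    {
                        "family": fit.result.family,
                        "converged": bool(fit.result.converged),
                        "sigma2": fit.result.sigma2,
                        "phi": fit.result.phi,
                        "params": dict(zip(fit.result.exog_names, fit.result.params)),
                    },
                    indent=2,
                )
            )

        if config.run_common_input:
            stage("common_input")
            res = common_input.common_input_analysis(
                pairs, W, units["id"].to_numpy()
            )
            _write_csv(
                pd.DataFrame(
                    [
                        {
                            "presyn_id": s.presyn_id,
                            "rho_observed": s.rho_observed,
                            "rho_expected": s.rho_expected,
                            "n_postsyn": s.n_postsyn,
                        }
                        for s in res["scores"]
                    ]
                ),
                out / "convergence_scores.csv", h,
            )
            (out / "common_input_report.json").write_text(
                json.dumps(res["report"], indent=2)
            )

        _write_csv(pairs, out / "pairs.csv", h)
        manifest["status"] = "complete"
    except Exception as err:  # preserve partial outputs, mark failure point
        manifest["status"] = "failed"
        manifest["error"] = f"{type(err).__name__}: {err}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
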
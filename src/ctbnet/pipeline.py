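"""End-to-end orchestration: simulate -> preprocess -> learn -> analyze,
driven by one declarative YAML configuration with a single seed.

The seed spawns independent derived streams per stochastic stage, so
changing, say, the number of null genes does not perturb the learner's
tie-breaking.  Every run writes a manifest recording the config hash,
seed, package version and per-stage gene/arc counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io, network
from .errors import ConfigError, DataError
from .learn import LearnConfig, TrajectoryData, greedy_structure_search, exhaustive_structure_search, trajectory_from_observations
from .preprocessing import SelectionConfig, preprocess
from .synthetic import GeneratorConfig, simulate_study

__all__ = ["PipelineConfig", "validate_config", "load_config", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Nested configuration for the whole pipeline.

    Defaults reproduce the study's stated settings: alpha = 0.01,
    tau = 5 h, max 5 parents, bins at +/-1, detection p < 0.05,
    SD >= 0.15, FDR 0.05, |log2 FC| > 1.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    learn: LearnConfig = field(default_factory=LearnConfig)
    subnetwork_genes: list[str] = field(default_factory=list)
    subnetwork_radius: int = 1
    normalize_method: str = "none"
    input_paths: dict[str, str] | None = None  # real mode: expression/samples/detection_p
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["level_map"] = {int(k): v for k, v in d["generator"]["level_map"].items()}
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_BLOCKS = {
    "generator": GeneratorConfig,
    "selection": SelectionConfig,
    "learn": LearnConfig,
}
_TOP_KEYS = set(_BLOCKS) | {
    "subnetwork_genes",
    "subnetwork_radius",
    "normalize_method",
    "input_paths",
    "seed",
    "log_level",
}


def validate_config(raw: str | dict) -> PipelineConfig:
    """Parse and validate a YAML config; every violation is reported
    with its path.  Unknown keys are rejected; missing blocks receive
    defaults (recorded in the manifest)."""
    if isinstance(raw, str):
        try:
            data = yaml.safe_load(raw) or {}
        except yaml.YAMLError as e:
            mark = getattr(e, "problem_mark", None)
            line = f" at line {mark.line + 1}" if mark else ""
            raise ConfigError([f"unparseable YAML{line}: {getattr(e, 'problem', e)}"])
    else:
        data = dict(raw)
    if not isinstance(data, dict):
        raise ConfigError(["config root must be a mapping"])
    errors = []
    unknown = set(data) - _TOP_KEYS
    for k in sorted(unknown):
        errors.append(f"{k}: unknown key")
    kwargs = {}
    injected = []
    for name, cls in _BLOCKS.items():
        block = data.get(name)
        if block is None:
            injected.append(name)
            continue
        if not isinstance(block, dict):
            errors.append(f"{name}: must be a mapping")
            continue
        valid_fields = {f.name for f in dataclasses.fields(cls)} - {"search"} | (
            {"search"} if cls is LearnConfig else set()
        )
        bad = set(block) - {f.name for f in dataclasses.fields(cls)}
        for k in sorted(bad):
            errors.append(f"{name}.{k}: unknown key")
        block = {k: v for k, v in block.items() if k not in bad}
        if name == "generator" and "level_map" in block:
            block["level_map"] = {int(k): float(v) for k, v in block["level_map"].items()}
        if name == "generator" and "grid" in block:
            block["grid"] = tuple(block["grid"])
        if name == "selection" and "bin_edges" in block:
            block["bin_edges"] = tuple(block["bin_edges"])
        try:
            kwargs[name] = cls(**block)
        except ConfigError as e:
            errors.extend(f"{name}.{msg}" if ":" not in msg else f"{name}: {msg}" for msg in e.errors)
        except TypeError as e:
            errors.append(f"{name}: {e}")
    for k in ("subnetwork_genes", "subnetwork_radius", "normalize_method", "input_paths", "seed", "log_level"):
        if k in data:
            kwargs[k] = data[k]
    if kwargs.get("subnetwork_radius", 1) < 0:
        errors.append("subnetwork_radius: must be >= 0")
    if kwargs.get("normalize_method", "none") not in ("none", "quantile", "median"):
        errors.append("normalize_method: must be none, quantile or median")
    if errors:
        raise ConfigError(errors)
    cfg = PipelineConfig(**kwargs)
    cfg._injected_defaults = injected  # noqa: attribute for the manifest
    return cfg


def load_config(path) -> PipelineConfig:
    return validate_config(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return round(float(o), 10)
    raise TypeError(f"not serializable: {type(o)}")


def run_pipeline(config: PipelineConfig, out_dir, seed: int | None = None) -> dict:
    """Execute all stages, writing each stage's outputs and a manifest.

    Returns a dict with the manifest and in-memory stage products.
    Idempotent for a fixed config + seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else int(seed)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": seed,
        "version": __version__,
        "injected_defaults": getattr(config, "_injected_defaults", []),
        "stages": {},
    }

    # --- stage 1: simulate or load --------------------------------------
    truth_model = None
    if config.input_paths:
        try:
            bundle = io.read_bundle(
                config.input_paths["expression"],
                config.input_paths["samples"],
                config.input_paths.get("detection_p"),
            )
        except (KeyError, FileNotFoundError, DataError) as e:
            raise DataError(f"stage simulate/load: {e}") from e
        manifest["stages"]["input"] = {"probes": len(bundle.values)}
    else:
        study = simulate_study(config.generator, seed=seed)
        truth_model = study["model"]
        bundle = study["bundle"]
        sim_dir = out_dir / "simulate"
        io.write_bundle(bundle, sim_dir)
        io.write_sif(truth_model.arcs(), sim_dir / "truth_network.sif")
        truth_states = study["truth_states"]
        from .preprocessing import DiscreteStateMatrix

        io.write_states(DiscreteStateMatrix(truth_states), sim_dir / "truth_states.tsv")
        manifest["stages"]["simulate"] = {
            "probes": len(bundle.values),
            "signal_genes": config.generator.n_genes,
            "true_arcs": len(truth_model.arcs()),
        }
        log.info("stage=simulate probes=%d arcs=%d", len(bundle.values), len(truth_model.arcs()))

    # --- stage 2: preprocess --------------------------------------------
    try:
        pp = preprocess(bundle, config.selection, normalize_method=config.normalize_method)
    except DataError as e:
        raise DataError(f"stage preprocess: {e}") from e
    states = pp["states"]
    pre_dir = out_dir / "preprocess"
    pre_dir.mkdir(parents=True, exist_ok=True)
    io.write_states(states, pre_dir / "states.tsv")
    io.write_matrix(pp["fc"].loc[states.genes], pre_dir / "fold_change.tsv")
    io.write_matrix(pp["q"].loc[states.genes], pre_dir / "qvalues.tsv")
    manifest["stages"]["preprocess"] = {
        **pp["filter_report"],
        "selected": len(pp["selected"]),
        "dropped_constant": len(pp["dropped_constant"]),
        "genes": len(states.genes),
    }
    log.info("stage=preprocess %s", manifest["stages"]["preprocess"])

    # --- stage 3: learn ---------------------------------------------------
    grid = states.times
    trajectories = [
        trajectory_from_observations(states.replicate_matrix(r).to_numpy(), grid, states.genes)
        for r in states.replicates
    ]
    try:
        data = TrajectoryData(trajectories, {g: 3 for g in states.genes})
        search = exhaustive_structure_search if config.learn.search == "exhaustive" else greedy_structure_search
        result = search(data, config.learn)
    except DataError as e:
        raise DataError(f"stage learn: {e}") from e
    learn_dir = out_dir / "learn"
    learn_dir.mkdir(parents=True, exist_ok=True)
    io.write_sif(result.arcs(), learn_dir / "network.sif")
    io.write_adjacency(result, learn_dir / "adjacency.tsv")
    io.write_trajectories(dict(enumerate(trajectories, 1)), learn_dir / "trajectories.tsv")
    manifest["stages"]["learn"] = {
        "genes": len(states.genes),
        "arcs": len(result.arcs()),
        "score": round(result.score, 6),
    }
    log.info("stage=learn arcs=%d score=%.3f", len(result.arcs()), result.score)

    # --- stage 4: analyze -------------------------------------------------
    g = network.build_graph(result.parent_sets)
    ana_dir = out_dir / "analyze"
    ana_dir.mkdir(parents=True, exist_ok=True)
    io.write_node_attributes(g, ana_dir / "node_attributes.tsv")
    io.write_graphml(g, ana_dir / "network.graphml")
    hubs = network.rank_hubs(g)
    classes = network.classify_hierarchy(g)
    manifest["stages"]["analyze"] = {
        "nodes": g.number_of_nodes(),
        "arcs": g.number_of_edges(),
        "top_hub": hubs[0] if hubs else None,
        "top_hub_out_degree": g.out_degree(hubs[0]) if hubs else 0,
        "n_roots": sum(1 for c in classes.values() if c == "root"),
        "n_leaves": sum(1 for c in classes.values() if c == "leaf"),
    }
    evaluation = None
    if truth_model is not None:
        truth_arcs = {(p, c) for (p, c) in truth_model.arcs() if p in g and c in g}
        truth_g = network.build_graph(
            {v: tuple(sorted(p for p, c in truth_arcs if c == v)) for v in g.nodes}
        )
        evaluation = network.evaluate_structure(g, truth_g)
        manifest["stages"]["analyze"]["evaluation"] = {
            k: round(float(v), 6) for k, v in evaluation.items()
        }
    if config.subnetwork_genes:
        sub = network.extract_subnetwork(g, config.subnetwork_genes, config.subnetwork_radius)
        io.write_sif(set(sub.edges), ana_dir / "subnetwork.sif")
        manifest["stages"]["analyze"]["subnetwork_nodes"] = sub.number_of_nodes()
    log.info("stage=analyze %s", manifest["stages"]["analyze"])

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    return {
        "manifest": manifest,
        "bundle": bundle,
        "preprocess": pp,
        "search": result,
        "graph": g,
        "evaluation": evaluation,
        "truth_model": truth_model,
    }
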
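"""Plain-text I/O: TSV matrices, sample metadata, discrete states, SIF,
GraphML and node-attribute tables.

Floats are written with a fixed 6-significant-digit format so that a
fixed seed reproduces byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataError
from .model import Trajectory
from .preprocessing import DiscreteStateMatrix, ExpressionBundle

FLOAT_FMT = "%.6g"


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_bundle(bundle: ExpressionBundle, out_dir, prefix: str = "") -> dict[str, Path]:
    """Write expression, metadata and (if present) detection-p TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["expression"] = out_dir / f"{prefix}expression.tsv"
    write_matrix(bundle.values, paths["expression"])
    paths["samples"] = out_dir / f"{prefix}samples.tsv"
    bundle.samples.to_csv(paths["samples"], sep="\t", float_format=FLOAT_FMT)
    if bundle.detection_p is not None:
        paths["detection_p"] = out_dir / f"{prefix}detection_p.tsv"
        write_matrix(bundle.detection_p, paths["detection_p"])
    return paths


def read_bundle(expr_path, samples_path, detection_path=None, log2: bool = True) -> ExpressionBundle:
    values = read_matrix(expr_path)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    detection = read_matrix(detection_path) if detection_path else None
    return ExpressionBundle(values, samples, detection, log2=log2)


def write_states(matrix: DiscreteStateMatrix, path) -> None:
    """One row per (gene, replicate), one column per time point."""
    rows = []
    for r in matrix.replicates:
        sub = matrix.replicate_matrix(r)
        sub = sub.copy()
        sub.insert(0, "replicate", r)
        rows.append(sub.rename_axis("gene").reset_index())
    out = pd.concat(rows, ignore_index=True)
    out.columns = ["gene", "replicate"] + [f"t{t:g}" for t in matrix.times]
    out.to_csv(path, sep="\t", index=False)


def read_states(path) -> DiscreteStateMatrix:
    df = pd.read_csv(path, sep="\t")
    times = [float(c[1:]) for c in df.columns[2:]]
    pieces = {}
    for (gene, rep), row in df.set_index(["gene", "replicate"]).iterrows():
        for t, v in zip(times, row):
            pieces.setdefault((t, int(rep)), {})[gene] = int(v)
    frame = pd.DataFrame(pieces)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["time_h", "replicate"])
    cols = sorted(frame.columns, key=lambda c: (c[0], c[1]))
    return DiscreteStateMatrix(frame[cols])


def write_trajectories(trajectories: dict | list, path) -> None:
    """Long-format TSV: trajectory_id, t_start, t_end, variable, state."""
    if isinstance(trajectories, list):
        trajectories = {i + 1: tr for i, tr in enumerate(trajectories)}
    rows = []
    for tid, tr in trajectories.items():
        starts = tr.start_times()
        for i in range(tr.n_segments):
            t0, t1 = starts[i], starts[i] + tr.durations[i]
            for j, v in enumerate(tr.variables):
                rows.append((tid, t0, t1, v, tr.states[i, j]))
    pd.DataFrame(rows, columns=["trajectory_id", "t_start", "t_end", "variable", "state"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def write_sif(arcs, path, relation: str = "ctbn") -> None:
    """SIF format: `parent <relation> child`, one arc per line, sorted."""
    with open(path, "w") as fh:
        for p, c in sorted(arcs):
            fh.write(f"{p}\t{relation}\t{c}\n")


def read_sif(path) -> set[tuple[str, str]]:
    arcs = set()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise DataError(f"malformed SIF line: {line!r}")
            arcs.add((parts[0], parts[2]))
    return arcs


def write_adjacency(result, path) -> None:
    """Adjacency TSV with per-family scores: child, parents, family_score."""
    rows = [
        (v, ",".join(result.parent_sets[v]), result.family_scores[v])
        for v in sorted(result.parent_sets)
    ]
    pd.DataFrame(rows, columns=["child", "parents", "family_score"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def write_graphml(g: nx.DiGraph, path) -> None:
    nx.write_graphml(g, path)


def write_node_attributes(g: nx.DiGraph, path) -> None:
    rows = [
        (
            n,
            g.nodes[n].get("out_degree", g.out_degree(n)),
            g.nodes[n].get("in_degree", g.in_degree(n)),
            g.nodes[n].get("hierarchy_class", ""),
            g.nodes[n].get("hub_rank", ""),
        )
        for n in sorted(g.nodes, key=lambda n: g.nodes[n].get("hub_rank", 0))
    ]
    pd.DataFrame(rows, columns=["gene", "out_degree", "in_degree", "class", "hub_rank"]).to_csv(
        path, sep="\t", index=False
    )
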
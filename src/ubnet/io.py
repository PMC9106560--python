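"""Readers and writers for the on-disk formats.

Plain-text formats only: per-subject edge lists are TSV
(``node_i  node_j  probability``), cohorts are described by a manifest CSV
(``subject_id, path, group``) with generic ``pos`` / ``neg`` group labels,
subgraph patterns and mining/selection results are JSON, feature matrices
are CSV with a JSON sidecar mapping columns to edge sets, and region time
series are CSV with one row per region.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .build import TimeSeriesMatrix
from .features import FeatureMatrix
from .graph import Cohort, SubgraphPattern, UncertainNetwork
from .mining import FrequentSubgraph
from .selection import DiscriminativeSubgraph

__all__ = [
    "read_network",
    "write_network",
    "read_node_universe",
    "write_node_universe",
    "read_cohort",
    "write_cohort",
    "read_patterns",
    "write_patterns",
    "write_mining_results",
    "read_mining_results",
    "write_selection",
    "read_selection",
    "write_features",
    "read_timeseries",
]

GROUPS = ("pos", "neg")


def _parse_label(text: str):
    # node labels round-trip as ints when they look like ints
    try:
        return int(text)
    except ValueError:
        return text


def write_network(net: UncertainNetwork, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("node_i\tnode_j\tprobability\n")
        for u, v in net.edges():
            fh.write(f"{u}\t{v}\t{net.edge_prob[(u, v)]:.10g}\n")


def read_network(path, nodes: Sequence | None = None) -> UncertainNetwork:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["node_i", "node_j", "probability"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, found {list(df.columns)}")
    probs = {}
    for _, row in df.iterrows():
        u, v = _parse_label(row["node_i"]), _parse_label(row["node_j"])
        probs[(u, v)] = float(row["probability"])
    if nodes is None:
        nodes = {n for e in probs for n in e}
    return UncertainNetwork(nodes, probs)


def write_node_universe(nodes: Sequence, path) -> None:
    Path(path).write_text("".join(f"{n}\n" for n in nodes))


def read_node_universe(path) -> tuple:
    return tuple(
        _parse_label(line.strip())
        for line in Path(path).read_text().splitlines()
        if line.strip()
    )


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write per-subject edge lists, the node universe, and a manifest CSV;
    returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_node_universe(cohort.nodes, out_dir / "nodes.txt")
    rows = []
    for sid, net, y in zip(cohort.subject_ids, cohort.networks, cohort.labels):
        fname = f"{sid}.tsv"
        write_network(net, out_dir / fname)
        rows.append({"subject_id": sid, "path": fname, "group": "pos" if y == 1 else "neg"})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path) -> Cohort:
    """Load a cohort from a manifest CSV; paths are resolved relative to the
    manifest.  A ``nodes.txt`` beside the manifest, when present, declares
    the node universe (making isolated nodes representable)."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, dtype=str)
    required = {"subject_id", "path", "group"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    nodes_file = manifest_path.parent / "nodes.txt"
    nodes = read_node_universe(nodes_file) if nodes_file.exists() else None
    networks, labels, sids = [], [], []
    for _, row in df.iterrows():
        if row["group"] not in GROUPS:
            raise ValueError(
                f"subject {row['subject_id']}: unknown group {row['group']!r}; "
                f"allowed labels are {GROUPS}"
            )
        p = manifest_path.parent / row["path"]
        if not p.exists():
            raise FileNotFoundError(f"subject {row['subject_id']}: network file {p} is missing")
        networks.append(read_network(p, nodes=nodes))
        labels.append(1 if row["group"] == "pos" else -1)
        sids.append(row["subject_id"])
    if nodes is None:
        # no declared universe: unify to the union of observed nodes
        union = sorted({n for net in networks for n in net.nodes}, key=lambda n: (type(n).__name__, n))
        networks = [UncertainNetwork(union, net.edge_prob) for net in networks]
    return Cohort(networks, np.array(labels), sids)


def write_patterns(patterns: Sequence[SubgraphPattern], path) -> None:
    data = [[list(e) for e in g.edges] for g in patterns]
    Path(path).write_text(json.dumps(data, indent=1))


def read_patterns(path) -> list[SubgraphPattern]:
    data = json.loads(Path(path).read_text())
    return [SubgraphPattern([tuple(e) for e in edges]) for edges in data]


def write_mining_results(results: Sequence[FrequentSubgraph], path, group: str) -> None:
    data = [
        {
            "edges": [list(e) for e in fs.pattern.edges],
            "esup": fs.esup,
            "layer": fs.layer,
            "group": group,
        }
        for fs in sorted(results, key=FrequentSubgraph.sort_key)
    ]
    Path(path).write_text(json.dumps(data, indent=1))


def read_mining_results(path) -> list[FrequentSubgraph]:
    data = json.loads(Path(path).read_text())
    out = []
    for rec in data:
        pattern = SubgraphPattern([tuple(e) for e in rec["edges"]])
        out.append(FrequentSubgraph(pattern, rec["esup"], rec["layer"], -1))
    return out


def write_selection(disc: Sequence[DiscriminativeSubgraph], path) -> None:
    data = [
        {
            "edges": [list(e) for e in d.pattern.edges],
            "mean_pos": d.mean_pos,
            "mean_neg": d.mean_neg,
            "confidence_pos": d.confidence_pos,
            "confidence_neg": d.confidence_neg,
            "source_group": d.source_group,
            "rank": d.rank,
        }
        for d in disc
    ]
    Path(path).write_text(json.dumps(data, indent=1))


def read_selection(path) -> list[DiscriminativeSubgraph]:
    data = json.loads(Path(path).read_text())
    return [
        DiscriminativeSubgraph(
            SubgraphPattern([tuple(e) for e in rec["edges"]]),
            rec["mean_pos"],
            rec["mean_neg"],
            rec["confidence_pos"],
            rec["confidence_neg"],
            rec["source_group"],
            rec["rank"],
        )
        for rec in data
    ]


def write_features(fm: FeatureMatrix, path) -> None:
    """Feature CSV plus a ``.json`` sidecar mapping columns to edge sets."""
    path = Path(path)
    cols = [f"feature_{j}" for j in range(fm.n_features)]
    df = pd.DataFrame(fm.values, index=fm.subject_ids, columns=cols)
    df.index.name = "subject_id"
    df.to_csv(path)
    sidecar = {
        col: [list(e) for e in g.edges]
        for col, g in zip(cols, fm.feature_patterns)
    }
    path.with_suffix(".json").write_text(json.dumps({"kind": fm.kind, "columns": sidecar}, indent=1))


def read_timeseries(path) -> TimeSeriesMatrix:
    """CSV with one row per region; first column holds the region label."""
    df = pd.read_csv(path, index_col=0)
    labels = [_parse_label(str(x)) for x in df.index]
    return TimeSeriesMatrix(df.to_numpy(dtype=float), labels)
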
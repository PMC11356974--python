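"""Readers, writers and run configuration.

Tabular formats are tab-separated with samples in rows and taxa in columns
(no orientation auto-detection; callers pass ``transpose=True`` when a file
is taxa-in-rows).  Networks round-trip through GraphML, results through
JSON plus flat TSV mirrors.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import networkx as nx
import pandas as pd

logger = logging.getLogger("emnet")

__all__ = [
    "RunConfig",
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "write_metadata",
    "write_network_graphml",
    "read_network_graphml",
    "write_json",
    "read_json",
]


@dataclasses.dataclass
class RunConfig:
    """Thresholds and seeds applied across the pipeline.

    Defaults mirror the analysis conventions of the study design: taxa
    entering correlation networks must reach 0.01% total relative
    abundance; fungal networks keep edges with |rho| >= 0.6 at p <= 0.001,
    cross-kingdom networks at p <= 0.05; node roles use the Guimera-Amaral
    cuts (Zi 2.5, Pi 0.62); covariates correlated at |r| >= 0.6 are pruned;
    a path model is deemed acceptable at goodness-of-fit > 0.5.
    """

    seed: int = 0
    abundance_filter: float = 1e-4
    fungal_edge_r: float = 0.6
    fungal_edge_p: float = 0.001
    crosskingdom_edge_r: float = 0.6
    crosskingdom_edge_p: float = 0.05
    zi_cut: float = 2.5
    pi_cut: float = 0.62
    collinearity_cut: float = 0.6
    gof_accept: float = 0.5
    bootstrap_n: int = 500

    def __post_init__(self) -> None:
        for name in ("abundance_filter", "fungal_edge_r", "fungal_edge_p",
                     "crosskingdom_edge_r", "crosskingdom_edge_p",
                     "pi_cut", "collinearity_cut", "gof_accept"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.zi_cut < 0:
            raise ValueError("zi_cut must be >= 0")
        if self.bootstrap_n < 0:
            raise ValueError("bootstrap_n must be >= 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   sort_keys=True) + "\n")
        return path


def _check_unique(labels, what: str, path) -> None:
    dup = pd.Index(labels)[pd.Index(labels).duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicated {what}: {dup}")


def read_abundance_table(path: str | Path, transpose: bool = False) -> pd.DataFrame:
    """Read a samples x taxa count table from TSV.

    First column holds sample identifiers, header row taxon identifiers.
    Duplicate identifiers, missing cells and negative or non-numeric counts
    are rejected with the offending label in the message.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    _check_unique(header, "header identifiers", path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"{path}: cannot parse as TSV: {exc}") from exc
    if transpose:
        df = df.T
    _check_unique(df.index, "sample identifiers", path)
    _check_unique(df.columns, "taxon identifiers", path)
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"{path}: missing cells in samples {rows}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric count: {exc}") from exc
    if (df.to_numpy() < 0).any():
        bad = df.index[(df < 0).any(axis=1)].tolist()
        raise ValueError(f"{path}: negative counts in samples {bad}")
    return df


def write_abundance_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t")
    return path


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata (site, forest_type, plant_richness, covariates)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index, "sample identifiers", path)
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    meta.to_csv(path, sep="\t")
    return path


def write_network_graphml(net, path: str | Path) -> Path:
    """Serialize a co-occurrence network to GraphML.

    Node attributes: taxon id (the node key), plus any annotations carried
    on the graph (genus, kingdom).  Edge attributes: rho, p_value, sign.
    """
    path = Path(path)
    # nx.Graph instances carry a `.graph` attribute dict, so check the
    # graph type first and unwrap CooccurrenceNetwork otherwise
    graph = net if isinstance(net, nx.Graph) else net.graph
    nx.write_graphml(graph, path)
    logger.info("wrote GraphML with %d nodes / %d edges to %s",
                graph.number_of_nodes(), graph.number_of_edges(), path)
    return path


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(Path(path))


def _jsonify(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return {"columns": list(map(str, obj.columns)),
                "index": list(map(str, obj.index)),
                "data": obj.to_numpy().tolist()}
    if isinstance(obj, pd.Series):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def write_json(obj: Any, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonify(obj), indent=2, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path) -> Any:
    with open(path) as fh:
        return json.load(fh)
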
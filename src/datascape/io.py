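"""Tabular input, run configuration, and datascape serialization.

Datasets come in as CSV/TSV with a header; a built datascape is stored as
a single zip container of diffable text parts (JSON metadata + TSV point
and edge tables) with per-part SHA-256 checksums, so corruption and
tampering are detected at load time.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import zipfile
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import Datascape
from .dataset import Dataset, get_metric
from .graph import NeighborGraph

__all__ = [
    "RunConfig",
    "read_table",
    "write_table",
    "export_edges",
    "export_graphml",
    "save_datascape",
    "load_datascape",
]

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Build/run parameters; serializes losslessly to a YAML key-value file."""

    k: int = 10
    metric: str = "euclidean"
    input_path: str | None = None
    id_column: str | None = None
    label_column: str | None = None
    feature_columns: list[str] | None = None
    eps: float | None = None
    seed: int = 0
    drop_duplicates: bool = False
    use_connecting: bool = True
    per_hull: int = 3

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.eps is not None and self.eps <= 0:
            raise ValueError("eps must be > 0")
        get_metric(self.metric)  # must resolve

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_table(path: str | Path, config: RunConfig | None = None) -> Dataset:
    """Read a CSV/TSV point table into a :class:`Dataset`.

    Column roles come from ``config`` (id/label/feature selectors).  Rows
    with missing or non-numeric feature values are rejected with their
    1-based data line numbers; imputation is deliberately not performed.
    """
    config = config or RunConfig()
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty table")

    # columns literally named "id"/"label" (write_table's convention) are
    # picked up automatically unless the config overrides them
    id_col = config.id_column
    if id_col is None and "id" in df.columns:
        id_col = "id"
    label_col = config.label_column
    if label_col is None and "label" in df.columns:
        label_col = "label"

    ids = None
    if id_col is not None:
        if id_col not in df.columns:
            raise ValueError(f"{path}: missing id column {id_col!r}")
        ids = df[id_col].to_numpy(dtype=object)
        if len(set(ids.tolist())) != len(ids):
            dup = df[id_col][df[id_col].duplicated()].iloc[0]
            raise ValueError(f"{path}: duplicate id {dup!r}")

    labels = None
    if label_col is not None:
        if label_col not in df.columns:
            raise ValueError(f"{path}: missing label column {label_col!r}")
        labels = df[label_col].to_numpy()

    feat_cols = config.feature_columns
    if feat_cols is None:
        skip = {id_col, label_col}
        feat_cols = [c for c in df.columns if c not in skip]
    else:
        missing = [c for c in feat_cols if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing feature columns {missing}")
    if not feat_cols:
        raise ValueError(f"{path}: no feature columns")

    feats = df[feat_cols].apply(pd.to_numeric, errors="coerce")
    bad = feats.isna().any(axis=1)
    if bad.any():
        lines = [int(i) + 2 for i in np.where(bad)[0][:5]]  # +2: header + 1-based
        raise ValueError(
            f"{path}: missing or non-numeric feature values at line(s) {lines}"
        )
    data = Dataset(feats.to_numpy(float), ids, labels)
    if config.drop_duplicates:
        data = data.drop_duplicates()
    return data


def write_table(data: Dataset, path: str | Path) -> None:
    """Write a dataset back to CSV/TSV (id, optional label, features)."""
    path = Path(path)
    df = pd.DataFrame(data.points, columns=[f"f{i}" for i in range(data.d)])
    df.insert(0, "id", data.ids)
    if data.labels is not None:
        df.insert(1, "label", data.labels)
    df.to_csv(path, sep=_sep_for(path), index=False)


def export_edges(graph: NeighborGraph, path: str | Path) -> None:
    """Write the edge list as TSV: id_i, id_j, weight, provenance."""
    Path(path).write_text(_edges_tsv(graph))


def export_graphml(graph: NeighborGraph, path: str | Path) -> None:
    """Write the graph (weights + provenance as edge attributes) as GraphML."""
    import networkx as nx

    g = nx.Graph()
    for pid in graph.data.ids:
        g.add_node(str(pid))
    ids = graph.data.ids
    for i, j, w, prov in graph.edge_list(use_connecting=True):
        g.add_edge(str(ids[i]), str(ids[j]), weight=float(w), provenance=prov)
    nx.write_graphml(g, str(path))


# ---------------------------------------------------------------------------
# datascape container


def _edges_tsv(graph: NeighborGraph) -> str:
    lines = ["id_i\tid_j\tweight\tprovenance"]
    ids = graph.data.ids
    for i, j, w, prov in graph.edge_list(use_connecting=True):
        lines.append(f"{ids[i]}\t{ids[j]}\t{w!r}\t{prov}")
    return "\n".join(lines) + "\n"


def _points_tsv(data: Dataset) -> str:
    buf = _io.StringIO()
    df = pd.DataFrame(data.points, columns=[f"f{i}" for i in range(data.d)])
    df.insert(0, "id", data.ids)
    if data.labels is not None:
        df.insert(1, "label", data.labels)
    df.to_csv(buf, sep="\t", index=False, float_format="%.17g")
    return buf.getvalue()


def save_datascape(ds: Datascape, path: str | Path) -> None:
    """Store a datascape as a zip of JSON + TSV parts with checksums."""
    parts = {
        "points.tsv": _points_tsv(ds.data),
        "edges.tsv": _edges_tsv(ds.graph),
    }
    meta = {
        "schema_version": SCHEMA_VERSION,
        "n": ds.n,
        "d": ds.d,
        "k": ds.k,
        "metric": ds.metric.name,
        "eps": ds.eps,
        "extreme_ids": [str(x) for x in ds.extreme_ids],
        "checksums": {
            name: hashlib.sha256(text.encode()).hexdigest() for name, text in parts.items()
        },
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1))
        for name, text in parts.items():
            zf.writestr(name, text)


def load_datascape(path: str | Path) -> Datascape:
    """Load a datascape container; rebuilds the graph from the stored tables.

    Checksum or schema mismatches raise ``ValueError``.  The stored extreme
    ids are kept, so boundary queries answer identically to the saved
    instance without recomputation.
    """
    from .core import build_datascape

    try:
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            parts = {
                name: zf.read(name).decode()
                for name in ("points.tsv", "edges.tsv")
            }
    except (zipfile.BadZipFile, KeyError) as exc:
        raise ValueError(f"{path}: corrupted datascape container ({exc})") from exc
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"{path}: unsupported schema version {meta.get('schema_version')!r}"
        )
    for name, text in parts.items():
        digest = hashlib.sha256(text.encode()).hexdigest()
        if digest != meta["checksums"].get(name):
            raise ValueError(f"{path}: checksum mismatch for {name}")

    df = pd.read_csv(_io.StringIO(parts["points.tsv"]), sep="\t")
    ids = df["id"].to_numpy(dtype=object)
    labels = df["label"].to_numpy() if "label" in df.columns else None
    feats = df[[c for c in df.columns if c.startswith("f")]].to_numpy(float)
    data = Dataset(feats, ids, labels)

    ds = build_datascape(data, k=int(meta["k"]), metric=meta["metric"], eps=meta["eps"])
    stored = set(meta["extreme_ids"])
    ds._extreme_idx = np.array(
        [i for i, pid in enumerate(data.ids) if str(pid) in stored], dtype=int
    )
    return ds
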
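"""Readers and writers for graphs, population bundles, posterior
samples and run manifests.

A population bundle is a directory holding one adjacency CSV per
network (``graph_000.csv`` ...), a node-attribute table ``nodes.csv``
(columns node, hemisphere, homotopy_partner), the design matrix
``X.csv``, an optional ``truth.json`` and a ``manifest.json``.
Everything is plain text; adjacency CSVs carry node names as header.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .multilevel import PopulationData, PosteriorSamples, SamplerConfig
from .netstats import Graph, StatisticSpec

__all__ = [
    "read_adjacency_csv",
    "write_adjacency_csv",
    "read_edge_list",
    "read_graphml",
    "read_node_table",
    "write_node_table",
    "write_population_bundle",
    "read_population_bundle",
    "write_posterior_csv",
    "read_posterior_csv",
    "write_manifest",
]


def read_adjacency_csv(path, hemisphere=None, homotopy_partner=None) -> Graph:
    """Read an N x N 0/1 adjacency matrix (optional header row)."""
    df = pd.read_csv(path, header=None)
    first = df.iloc[0]
    if not np.all([str(v).strip().lstrip("-").replace(".", "").isdigit() for v in first]):
        df = pd.read_csv(path)  # header row of node names
    A = df.to_numpy(dtype=np.float64)
    return Graph(A.astype(np.int8), hemisphere, homotopy_partner)


def write_adjacency_csv(g: Graph, path) -> None:
    names = [f"n{i}" for i in range(g.n_nodes)]
    pd.DataFrame(g.adjacency, columns=names).to_csv(path, index=False)


def read_edge_list(path, n_nodes: int, one_based: bool = False, **attrs) -> Graph:
    """Two-column edge list; ``one_based`` declares the indexing."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("edge list needs two columns")
    edges = df.iloc[:, :2].to_numpy(dtype=np.int64)
    if one_based:
        edges = edges - 1
    return Graph.from_edges(n_nodes, [tuple(e) for e in edges], **attrs)


def read_graphml(path, **attrs) -> Graph:
    """GraphML input; absent edges default to 0."""
    gx = nx.read_graphml(path)
    nodes = sorted(gx.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)), dtype=np.int8)
    for u, v in gx.edges():
        A[index[u], index[v]] = A[index[v], index[u]] = 1
    return Graph(A, **attrs)


def read_node_table(path) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Node attribute CSV with columns node, hemisphere, homotopy_partner."""
    df = pd.read_csv(path).sort_values("node")
    hemi = df["hemisphere"].to_numpy() if "hemisphere" in df else None
    partner = (
        df["homotopy_partner"].to_numpy(dtype=np.int64)
        if "homotopy_partner" in df
        else None
    )
    return hemi, partner


def write_node_table(g: Graph, path) -> None:
    cols = {"node": np.arange(g.n_nodes)}
    if g.hemisphere is not None:
        cols["hemisphere"] = g.hemisphere
    if g.homotopy_partner is not None:
        cols["homotopy_partner"] = g.homotopy_partner
    pd.DataFrame(cols).to_csv(path, index=False)


def write_population_bundle(
    data: PopulationData, out_dir, truth: dict | None = None, manifest: dict | None = None
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, g in enumerate(data.networks):
        write_adjacency_csv(g, out / f"graph_{i:03d}.csv")
    write_node_table(data.networks[0], out / "nodes.csv")
    pd.DataFrame(data.X, columns=[f"x{j}" for j in range(data.q)]).to_csv(
        out / "X.csv", index=False
    )
    meta = dict(manifest or {})
    meta.setdefault("n_networks", data.n)
    meta["spec"] = data.spec.to_strings()
    write_manifest(meta, out / "manifest.json")
    if truth is not None:
        with open(out / "truth.json", "w") as fh:
            json.dump(_jsonable(truth), fh, indent=2)
    return out


def read_population_bundle(bundle_dir, spec: StatisticSpec | None = None) -> PopulationData:
    bundle = Path(bundle_dir)
    with open(bundle / "manifest.json") as fh:
        manifest = json.load(fh)
    if spec is None:
        spec = StatisticSpec.from_strings(manifest["spec"])
    hemi, partner = read_node_table(bundle / "nodes.csv")
    graphs = [
        read_adjacency_csv(p, hemisphere=hemi, homotopy_partner=partner)
        for p in sorted(bundle.glob("graph_*.csv"))
    ]
    X = pd.read_csv(bundle / "X.csv").to_numpy(dtype=np.float64)
    return PopulationData(networks=graphs, X=X, spec=spec)


def write_posterior_csv(samples: PosteriorSamples, path, chain: int = 0) -> None:
    """Tidy long-format draws: chain, iteration, block, row, col, value."""
    frames = []
    for block, arr in (
        ("beta", samples.beta),
        ("sigma_eps", samples.sigma_eps),
        ("theta", samples.theta),
    ):
        K, r, c = arr.shape
        it, row, col = np.meshgrid(
            np.arange(K), np.arange(r), np.arange(c), indexing="ij"
        )
        frames.append(
            pd.DataFrame(
                {
                    "chain": chain,
                    "iteration": it.ravel(),
                    "block": block,
                    "row": row.ravel(),
                    "col": col.ravel(),
                    "value": arr.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_posterior_csv(path) -> dict[str, np.ndarray]:
    """Rebuild the stacked draw arrays from a tidy posterior CSV."""
    df = pd.read_csv(path)
    out = {}
    for block, sub in df.groupby("block"):
        K = sub["iteration"].max() + 1
        r = sub["row"].max() + 1
        c = sub["col"].max() + 1
        arr = np.empty((K, r, c))
        arr[sub["iteration"], sub["row"], sub["col"]] = sub["value"]
        out[block] = arr
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def write_manifest(meta: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(meta), fh, indent=2, default=str)
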
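"""Readers and writers for the pipeline's tabular and graph artifacts.

Canonical tabular dialect: tab-delimited UTF-8 with a header row and decimal
points. Networks are written as GraphML (node ids + ``rho`` edge attribute)
or as a three-column edge list; both round-trip exactly.
"""

from __future__ import annotations

import os
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    CorrelationNetwork,
    MeasurementTable,
    OTUTable,
    SampleFrame,
    ValidationError,
)


class ParseError(ValueError):
    """Raised when an input file cannot be parsed into its container."""


def read_sample_frame(path: str | os.PathLike) -> SampleFrame:
    return SampleFrame(pd.read_csv(path, sep="\t", dtype=str))


def write_sample_frame(design: SampleFrame, path: str | os.PathLike) -> None:
    design.frame.to_csv(path, sep="\t", index=False)


def read_measurements(path: str | os.PathLike) -> MeasurementTable:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "variable": str})
    return MeasurementTable(frame)


def write_measurements(table: MeasurementTable, path: str | os.PathLike) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | os.PathLike, kingdom: str) -> OTUTable:
    """Read a taxa-by-sample TSV count table.

    First column holds taxa ids; remaining columns are samples. Cells must be
    integers (integral floats such as ``12.0`` are accepted). Malformed cells
    raise :class:`ParseError` naming the offending taxon and sample.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    raw.index.name = "taxon_id"
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.any().any():
        taxon = bad.any(axis=1).idxmax()
        sample = bad.loc[taxon][bad.loc[taxon]].index[0]
        raise ParseError(
            f"non-numeric count {raw.loc[taxon, sample]!r} "
            f"at taxon {taxon!r}, sample {sample!r} in {path}"
        )
    if numeric.isna().any().any():
        taxon = numeric.isna().any(axis=1).idxmax()
        raise ParseError(f"missing count for taxon {taxon!r} in {path}")
    arr = numeric.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        off = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise ParseError(
            f"non-integral count {arr[tuple(off)]} at taxon "
            f"{numeric.index[off[0]]!r}, sample {numeric.columns[off[1]]!r}"
        )
    try:
        return OTUTable(numeric.round().astype(np.int64), kingdom)
    except ValidationError as exc:
        raise ParseError(str(exc)) from exc


def write_feature_table(table: OTUTable, path: str | os.PathLike) -> None:
    out = table.counts.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


NetworkFormat = Literal["graphml", "edgelist"]


def write_network(
    net: CorrelationNetwork, path: str | os.PathLike, format: NetworkFormat = "graphml"
) -> None:
    """Write a co-occurrence network as GraphML or a TSV edge list."""
    if format == "graphml":
        g = nx.Graph()
        g.add_nodes_from(net.graph.nodes)
        for u, v, d in net.graph.edges(data=True):
            g.add_edge(u, v, rho=float(d["rho"]))
        g.graph["r_min"] = float(net.r_min)
        g.graph["alpha"] = float(net.alpha)
        g.graph["samples"] = ",".join(net.sample_ids)
        nx.write_graphml(g, path)
    elif format == "edgelist":
        net.edge_frame().to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | os.PathLike, format: NetworkFormat = "graphml") -> CorrelationNetwork:
    if format == "graphml":
        g = nx.read_graphml(path)
        meta = g.graph
        samples = [s for s in str(meta.get("samples", "")).split(",") if s]
        clean = nx.Graph()
        clean.add_nodes_from(g.nodes)
        for u, v, d in g.edges(data=True):
            clean.add_edge(u, v, rho=float(d["rho"]))
        return CorrelationNetwork(
            clean,
            r_min=float(meta.get("r_min", np.nan)),
            alpha=float(meta.get("alpha", np.nan)),
            sample_ids=samples,
        )
    if format == "edgelist":
        frame = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for _, row in frame.iterrows():
            g.add_edge(str(row["taxon_a"]), str(row["taxon_b"]), rho=float(row["rho"]))
        return CorrelationNetwork(g, r_min=np.nan, alpha=np.nan, sample_ids=[])
    raise ValueError(f"unknown network format {format!r}")
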
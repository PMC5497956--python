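"""Readers and writers for networks, constraint lists, and partitions.

Formats
-------
* networks: whitespace-delimited edge lists (``u v`` per line, ``#``
  comments) and GML (via :mod:`networkx`);
* constraints: TSV with lines ``u<TAB>v<TAB>{ml|cl}`` over node indices;
* partitions: two-column TSV ``node_id<TAB>community``.

Directed inputs are symmetrized (an arc in either direction becomes an
undirected edge), duplicate edges are collapsed and self-loops dropped
with a warning, matching the undirected simple-graph model used
throughout.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import networkx as nx
import numpy as np

from .network import ConstraintSet, Network, Partition, ValidationError, canonical_pair

__all__ = [
    "read_network",
    "write_network",
    "read_constraints",
    "write_constraints",
    "read_partition",
    "write_partition",
    "FormatError",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not parse in the declared dialect."""


def _infer_format(path: str | os.PathLike) -> str:
    return "gml" if Path(path).suffix.lower() == ".gml" else "edgelist"


def read_network(path: str | os.PathLike, format: str | None = None) -> Network:
    """Read an undirected simple network from an edge list or GML file.

    Node identifiers are kept in first-appearance order (GML: declaration
    order, including isolated nodes).  Self-loops are dropped with a
    logged warning; duplicate and reciprocal edges collapse to one
    undirected edge.
    """
    fmt = format or _infer_format(path)
    if fmt == "edgelist":
        ids: list[str] = []
        index: dict[str, int] = {}
        raw_edges: list[tuple[int, int]] = []
        n_loops = 0
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                stripped = line.split("#", 1)[0].strip()
                if not stripped:
                    continue
                parts = stripped.split()
                if len(parts) != 2:
                    raise FormatError(
                        f"{path}: line {lineno}: expected 'u v', got {line.rstrip()!r}"
                    )
                uv = []
                for tok in parts:
                    if tok not in index:
                        index[tok] = len(ids)
                        ids.append(tok)
                    uv.append(index[tok])
                if uv[0] == uv[1]:
                    n_loops += 1
                    continue
                raw_edges.append((uv[0], uv[1]))
        if n_loops:
            logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
        return Network.from_edges(len(ids), raw_edges, node_ids=ids)
    if fmt == "gml":
        try:
            g = nx.read_gml(path, label="id")
        except Exception as exc:  # networkx raises several parser errors
            raise FormatError(f"{path}: not parseable as GML: {exc}") from exc
        g = nx.Graph(g)  # symmetrize / collapse parallel edges
        loops = list(nx.selfloop_edges(g))
        if loops:
            logger.warning("%s: dropped %d self-loop(s)", path, len(loops))
            g.remove_edges_from(loops)
        ids = list(g.nodes())
        index = {v: i for i, v in enumerate(ids)}
        edges = [(index[u], index[v]) for u, v in g.edges()]
        return Network.from_edges(len(ids), edges, node_ids=[str(v) for v in ids])
    raise ValueError(f"unknown network format {fmt!r}")


def write_network(network: Network, path: str | os.PathLike) -> None:
    """Write a network as an edge list (one ``u v`` line per edge, i < j order)."""
    with open(path, "w") as fh:
        for i, j in network.edges():
            fh.write(f"{network.node_ids[i]} {network.node_ids[j]}\n")


def read_constraints(path: str | os.PathLike) -> ConstraintSet:
    """Read a constraint TSV (``u<TAB>v<TAB>{ml|cl}``) over node indices."""
    ml: set[tuple[int, int]] = set()
    cl: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            parts = stripped.split()
            if len(parts) != 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected 'u\\tv\\t{{ml|cl}}'"
                )
            try:
                pair = canonical_pair(int(parts[0]), int(parts[1]))
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            tag = parts[2].lower()
            if tag == "ml":
                ml.add(pair)
            elif tag == "cl":
                cl.add(pair)
            else:
                raise FormatError(
                    f"{path}: line {lineno}: unknown tag {parts[2]!r} (want ml or cl)"
                )
    return ConstraintSet(frozenset(ml), frozenset(cl))  # raises on ml/cl overlap


def write_constraints(constraints: ConstraintSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for i, j in sorted(constraints.must_link):
            fh.write(f"{i}\t{j}\tml\n")
        for i, j in sorted(constraints.cannot_link):
            fh.write(f"{i}\t{j}\tcl\n")


def write_partition(
    partition: Partition, path: str | os.PathLike, node_ids: list | None = None
) -> None:
    """Write a partition as ``node_id<TAB>community`` lines in node order."""
    ids = node_ids if node_ids is not None else [str(i) for i in range(partition.n_nodes)]
    if len(ids) != partition.n_nodes:
        raise ValidationError("node_ids length must match the partition")
    with open(path, "w") as fh:
        for nid, lab in zip(ids, partition.labels):
            fh.write(f"{nid}\t{lab}\n")


def read_partition(path: str | os.PathLike) -> tuple[Partition, list[str]]:
    """Read a partition TSV; returns the partition and node ids in file order."""
    ids: list[str] = []
    labels: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            parts = stripped.split()
            if len(parts) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 'node\\tcommunity'")
            ids.append(parts[0])
            try:
                labels.append(int(parts[1]))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    lab = np.asarray(labels, dtype=int)
    k = int(lab.max()) if lab.size else 0
    return Partition(lab, k), ids
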
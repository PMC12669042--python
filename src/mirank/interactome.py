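"""Heterogeneous multiscale-interactome data model and I/O.

The multiscale interactome (MI) is a heterogeneous graph ``G = (V, E)``
whose nodes are proteins (genes) and biological functions, and whose edges
fall into three types:

* ``protein_protein`` — physical/functional PPI links, undirected;
* ``protein_function`` — a protein's membership in a biological function
  (Gene Ontology style), undirected;
* ``function_function`` — the function hierarchy, stored directed
  child -> parent but traversable both ways with distinct bias weights.

Node identity is an opaque string id; positions 0..N-1 are assigned
deterministically by sorting on ``(node_type, node_id)`` so that seed and
diffusion vectors are reproducible across runs.

Entities (bioactive molecules or drugs) and diseases enter the analysis as
binary seed vectors over the node index: ``m_i = 1`` if protein *i* is a
target of the molecule, ``d_i = 1`` if gene *i* is associated with the
disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROTEIN = "protein"
FUNCTION = "biological_function"
NODE_TYPES = (PROTEIN, FUNCTION)

PP = "protein_protein"
PF = "protein_function"
FF = "function_function"
EDGE_TYPES = (PP, PF, FF)

#: node types required at the two endpoints of each edge type
_ENDPOINT_TYPES = {
    PP: (PROTEIN, PROTEIN),
    PF: (PROTEIN, FUNCTION),
    FF: (FUNCTION, FUNCTION),
}

EDGE_LIST_COLUMNS = ["node_1", "node_1_type", "node_2", "node_2_type"]


@dataclass(frozen=True)
class Edge:
    """A typed edge.

    For ``protein_protein`` and ``protein_function`` the orientation is not
    meaningful (they are canonicalized on construction); ``function_function``
    edges are directed child -> parent.
    """

    source: str
    target: str
    edge_type: str

    def canonical(self) -> "Edge":
        if self.edge_type == PP and self.target < self.source:
            return Edge(self.target, self.source, PP)
        return self


@dataclass
class Interactome:
    """The indexed heterogeneous graph.

    Attributes
    ----------
    node_ids : list of str
        Node identifiers in index order (sorted by ``(node_type, node_id)``).
    node_types : list of str
        Parallel to ``node_ids``; ``"protein"`` or ``"biological_function"``.
    edges : list of Edge
        Deduplicated, self-loop-free typed edges.
    """

    node_ids: list[str]
    node_types: list[str]
    edges: list[Edge]
    node_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.node_index = {nid: i for i, nid in enumerate(self.node_ids)}
        if len(self.node_index) != len(self.node_ids):
            raise ValueError("duplicate node ids in interactome")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def protein_ids(self) -> list[str]:
        return [i for i, t in zip(self.node_ids, self.node_types) if t == PROTEIN]

    def type_of(self, node_id: str) -> str:
        return self.node_types[self.node_index[node_id]]

    def is_protein(self, node_id: str) -> bool:
        return self.type_of(node_id) == PROTEIN

    def edge_counts(self) -> dict[str, int]:
        counts = {t: 0 for t in EDGE_TYPES}
        for e in self.edges:
            counts[e.edge_type] += 1
        return counts

    def to_networkx(self):
        """Undirected networkx view with node/edge type attributes.

        The function hierarchy direction is kept as an edge attribute
        (``child``/``parent``) rather than as digraph orientation; this view
        is used for subgraph extraction and export, not for propagation.
        """
        import networkx as nx

        g = nx.Graph()
        for nid, ntype in zip(self.node_ids, self.node_types):
            g.add_node(nid, node_type=ntype)
        for e in self.edges:
            g.add_edge(e.source, e.target, edge_type=e.edge_type)
        return g


@dataclass
class EntityTargets:
    """A molecule or drug and the proteins it targets."""

    entity_id: str
    entity_name: str
    entity_class: str  # "bioactive_molecule" | "drug"
    target_ids: frozenset[str]

    def resolve(self, interactome: Interactome) -> tuple[frozenset[str], frozenset[str]]:
        """Split targets into (present-as-protein, unresolved) against an MI."""
        resolved = frozenset(
            t
            for t in self.target_ids
            if t in interactome.node_index and interactome.is_protein(t)
        )
        return resolved, frozenset(self.target_ids) - resolved


@dataclass
class SeedVector:
    """Binary indicator over interactome nodes (the vectors m and d)."""

    values: np.ndarray
    n_seeds: int
    missing_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all((self.values == 0) | (self.values == 1)):
            raise ValueError("seed vector entries must be 0/1")
        if self.n_seeds != int(self.values.sum()):
            raise ValueError("n_seeds inconsistent with vector")
        if self.n_seeds < 1:
            raise ValueError("seed vector needs at least one seed")

    @property
    def seed_positions(self) -> np.ndarray:
        return np.flatnonzero(self.values)


def read_edge_list(path: str | Path, expected_edge_type: str) -> list[Edge]:
    """Read a typed TSV edge list, validating endpoint types.

    The file layout matches the public MI release: a header
    ``node_1\\tnode_1_type\\tnode_2\\tnode_2_type`` followed by one edge per
    row. Rows whose node types contradict ``expected_edge_type`` raise with
    their 1-based row numbers; duplicates are collapsed and self-loops
    dropped (logged).
    """
    if expected_edge_type not in EDGE_TYPES:
        raise ValueError(f"unknown edge type {expected_edge_type!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != EDGE_LIST_COLUMNS:
        raise ValueError(
            f"{path}: malformed header {list(df.columns)!r}, "
            f"expected {EDGE_LIST_COLUMNS!r}"
        )
    if len(df) == 0:
        raise ValueError(f"{path}: empty edge list body")

    want = _ENDPOINT_TYPES[expected_edge_type]
    bad_rows = [
        i + 1
        for i, (t1, t2) in enumerate(zip(df["node_1_type"], df["node_2_type"]))
        if (t1, t2) != want
    ]
    if bad_rows:
        raise ValueError(
            f"{path}: rows {bad_rows} have node types inconsistent with "
            f"edge type {expected_edge_type!r} (expected {want[0]}/{want[1]})"
        )

    edges: dict[tuple[str, str], Edge] = {}
    n_self = 0
    for a, b in zip(df["node_1"], df["node_2"]):
        if a == b:
            n_self += 1
            continue
        e = Edge(a, b, expected_edge_type).canonical()
        edges[(e.source, e.target)] = e
    if n_self:
        logger.warning("%s: dropped %d self-loop(s)", path, n_self)
    return list(edges.values())


def write_edge_list(path: str | Path, edges: Iterable[Edge]) -> None:
    """Write edges in the TSV dialect read by :func:`read_edge_list`."""
    rows = []
    for e in edges:
        t1, t2 = _ENDPOINT_TYPES[e.edge_type]
        rows.append((e.source, t1, e.target, t2))
    pd.DataFrame(rows, columns=EDGE_LIST_COLUMNS).to_csv(path, sep="\t", index=False)


def build_interactome(edge_collections: Mapping[str, Iterable[Edge]] | Iterable[Iterable[Edge]]) -> Interactome:
    """Assemble an :class:`Interactome` from per-type edge collections.

    Nodes are the union of all edge endpoints, indexed lexicographically by
    ``(node_type, node_id)``. An id used with two different node types is an
    error; duplicate edges are collapsed.
    """
    if isinstance(edge_collections, Mapping):
        collections = list(edge_collections.values())
    else:
        collections = list(edge_collections)

    node_type: dict[str, str] = {}
    edge_map: dict[tuple[str, str, str], Edge] = {}
    for coll in collections:
        for e in coll:
            e = e.canonical()
            if e.source == e.target:
                continue
            t1, t2 = _ENDPOINT_TYPES[e.edge_type]
            for nid, t in ((e.source, t1), (e.target, t2)):
                prev = node_type.setdefault(nid, t)
                if prev != t:
                    raise ValueError(
                        f"node {nid!r} used with conflicting types {prev!r} and {t!r}"
                    )
            edge_map[(e.source, e.target, e.edge_type)] = e

    if not edge_map:
        raise ValueError("no edges provided")
    if not any(e.edge_type == PP for e in edge_map.values()):
        raise ValueError("at least one protein_protein edge is required")

    order = sorted(node_type, key=lambda nid: (node_type[nid], nid))
    return Interactome(
        node_ids=order,
        node_types=[node_type[n] for n in order],
        edges=sorted(
            edge_map.values(), key=lambda e: (e.edge_type, e.source, e.target)
        ),
    )


def read_entity_targets(
    path: str | Path, entity_class: str = "bioactive_molecule"
) -> list[EntityTargets]:
    """Read an entity-target TSV (``entity_id\\tentity_name\\tprotein_id``).

    One row per (entity, target) pair; rows are grouped by ``entity_id`` and
    per-entity target sets deduplicated.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["entity_id", "entity_name", "protein_id"]
    if list(df.columns)[:3] != required:
        raise ValueError(f"{path}: expected columns {required!r}")
    if len(df) == 0:
        raise ValueError(f"{path}: empty entity-target table")
    if df["entity_id"].isna().any() or (df["entity_id"].str.strip() == "").any():
        raise ValueError(f"{path}: blank entity_id")

    out = []
    for eid, grp in df.groupby("entity_id", sort=True):
        out.append(
            EntityTargets(
                entity_id=str(eid),
                entity_name=str(grp["entity_name"].iloc[0]),
                entity_class=entity_class,
                target_ids=frozenset(grp["protein_id"]),
            )
        )
    return out


def write_entity_targets(path: str | Path, entities: Iterable[EntityTargets]) -> None:
    rows = [
        (e.entity_id, e.entity_name, t)
        for e in entities
        for t in sorted(e.target_ids)
    ]
    pd.DataFrame(rows, columns=["entity_id", "entity_name", "protein_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_list(path: str | Path) -> list[str]:
    """Read a disease gene list: one id per line, optional tab-separated
    ``evidence_tier`` second column (ignored here, used by subset runs)."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        genes.append(line.split("\t")[0])
    if not genes:
        raise ValueError(f"{path}: empty gene list")
    return genes


def write_gene_list(path: str | Path, genes: Sequence[str]) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def make_seed_vector(interactome: Interactome, gene_ids: Iterable[str]) -> SeedVector:
    """Build the binary seed vector for a set of protein ids.

    Ids absent from the interactome (or present as function nodes) are
    recorded in ``missing_ids`` and the walk proceeds with the available
    subset; it is an error only when no id resolves.
    """
    gene_ids = sorted(set(gene_ids))
    if not gene_ids:
        raise ValueError("empty gene id set")
    values = np.zeros(interactome.n_nodes)
    missing = []
    for g in gene_ids:
        idx = interactome.node_index.get(g)
        if idx is None or interactome.node_types[idx] != PROTEIN:
            missing.append(g)
        else:
            values[idx] = 1.0
    n_seeds = int(values.sum())
    if n_seeds == 0:
        raise ValueError("no seeds resolved against the interactome")
    if missing:
        logger.warning("%d seed id(s) not in interactome: %s", len(missing), missing)
    return SeedVector(values=values, n_seeds=n_seeds, missing_ids=missing)


def save_interactome(interactome: Interactome, out_dir: str | Path) -> None:
    """Write a validated interactome bundle (one edge-list TSV per type)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_type: dict[str, list[Edge]] = {t: [] for t in EDGE_TYPES}
    for e in interactome.edges:
        by_type[e.edge_type].append(e)
    names = {PP: "protein_protein.tsv", PF: "protein_function.tsv", FF: "function_function.tsv"}
    for t, edges in by_type.items():
        if edges:
            write_edge_list(out / names[t], edges)


def load_interactome(in_dir: str | Path) -> Interactome:
    """Load a bundle written by :func:`save_interactome`."""
    in_dir = Path(in_dir)
    names = {PP: "protein_protein.tsv", PF: "protein_function.tsv", FF: "function_function.tsv"}
    collections = {}
    for t, name in names.items():
        p = in_dir / name
        if p.exists():
            collections[t] = read_edge_list(p, t)
    if not collections:
        raise FileNotFoundError(f"no edge-list files found in {in_dir}")
    return build_interactome(collections)
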
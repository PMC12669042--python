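"""Synthetic heterogeneous interactomes with planted beneficial molecules.

Real multiscale interactomes (17,600 genes, thousands of molecules) are
external downloads; this module generates desk-scale stand-ins with the
same structural ingredients so every pipeline stage is testable
end-to-end:

* a scale-free protein layer (Barabasi–Albert preferential attachment,
  connected, heavy-tailed degrees like a PPI network);
* a hierarchical function layer (balanced rooted tree, edges stored
  child -> parent like an ontology);
* per-protein function memberships (Poisson-distributed count, uniform
  choice of functions);
* a small disease gene set concentrated in one graph neighborhood (a BFS
  ball around a random center), emulating a polygenic disease whose genes
  cluster in a pathway;
* "planted" beneficial molecules that draw a fraction of their targets
  from within radius 2 of the disease ball (weighted toward the disease
  genes themselves), against background molecules with uniformly random
  targets.

Every stage draws from an independent child stream of one top-level
``rng_seed``, so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from . import interactome as mi
from .interactome import Edge, EntityTargets, Interactome
from .validation import BenefitCategorization, write_benefit_categorization


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults define the standard benchmark conditions.

    ``planted_overlap`` is the fraction of a planted molecule's targets
    drawn from the radius-2 neighborhood of the disease gene ball (the
    planted effect strength); the rest, and all targets of background
    molecules, are uniform over proteins.
    """

    n_proteins: int = 1000
    n_functions: int = 80
    n_molecules: int = 100
    ppi_attachment: int = 1
    function_branching: int = 3
    membership_rate: float = 2.0
    n_disease_genes: int = 13
    n_planted: int = 15
    planted_overlap: float = 1.0
    targets_per_molecule: int = 6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_proteins",
            "n_functions",
            "n_molecules",
            "ppi_attachment",
            "function_branching",
            "n_disease_genes",
            "targets_per_molecule",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_planted > self.n_molecules:
            raise ValueError("n_planted exceeds n_molecules")
        if self.n_planted < 0:
            raise ValueError("n_planted must be >= 0")
        if not 0.0 < self.planted_overlap <= 1.0:
            raise ValueError("planted_overlap outside (0, 1]")
        if self.n_disease_genes > self.n_proteins:
            raise ValueError("more disease genes than proteins")


#: relative sampling weight of a pool node by its graph distance (0/1/2)
#: to the disease gene set: planted molecules mostly target the disease
#: genes themselves, with occasional first/second-shell neighbors
POOL_DISTANCE_WEIGHTS = {0: 1.0, 1: 0.02, 2: 0.005}


def _streams(params: SimParams) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(params.rng_seed)
    names = ("ppi", "membership", "disease", "molecules")
    return {
        name: np.random.default_rng(child)
        for name, child in zip(names, root.spawn(len(names)))
    }


def _protein_id(i: int) -> str:
    return f"P{i:04d}"


def _function_id(i: int) -> str:
    return f"F{i:03d}"


def generate_interactome(params: SimParams) -> Interactome:
    """Generate the two-layer heterogeneous graph. Deterministic per seed."""
    rng = _streams(params)

    m = min(params.ppi_attachment, params.n_proteins - 1)
    if m < 1:
        raise ValueError("n_proteins too small for a protein layer")
    ppi = nx.barabasi_albert_graph(
        params.n_proteins, m, seed=int(rng["ppi"].integers(2**31))
    )
    pp_edges = [
        Edge(_protein_id(u), _protein_id(v), mi.PP) for u, v in ppi.edges
    ]

    # balanced-arity rooted tree on the function layer, child -> parent
    ff_edges = [
        Edge(_function_id(i), _function_id((i - 1) // params.function_branching), mi.FF)
        for i in range(1, params.n_functions)
    ]

    memb = rng["membership"]
    pf_edges = []
    for i in range(params.n_proteins):
        count = memb.poisson(params.membership_rate)
        count = min(count, params.n_functions)
        if count:
            funcs = memb.choice(params.n_functions, size=count, replace=False)
            pf_edges.extend(
                Edge(_protein_id(i), _function_id(int(f)), mi.PF) for f in funcs
            )
    if not pf_edges:  # tiny parameterizations: guarantee a non-empty layer
        pf_edges = [Edge(_protein_id(0), _function_id(0), mi.PF)]
    if params.n_functions == 1:
        ff_edges = []
        collections = {mi.PP: pp_edges, mi.PF: pf_edges}
    else:
        collections = {mi.PP: pp_edges, mi.PF: pf_edges, mi.FF: ff_edges}
    return mi.build_interactome(collections)


def _bfs_ball(graph: nx.Graph, center: str, size: int) -> list[str]:
    """First ``size`` nodes in deterministic BFS order around ``center``."""
    order = [center]
    seen = {center}
    frontier = [center]
    while frontier and len(order) < size:
        nxt = []
        for node in frontier:
            for nb in sorted(graph.neighbors(node)):
                if nb not in seen:
                    seen.add(nb)
                    order.append(nb)
                    nxt.append(nb)
        frontier = nxt
    return order[:size]


def plant_disease_and_molecules(
    interactome: Interactome, params: SimParams
) -> tuple[list[str], list[EntityTargets], BenefitCategorization]:
    """Sample disease genes and molecule target sets with planted structure.

    Disease genes are a BFS ball in the protein layer around a random
    center. Planted molecules draw ``round(planted_overlap *
    targets_per_molecule)`` targets from within graph radius 2 of the
    disease ball — sampling weighted toward the disease genes themselves
    (distance-0/1/2 weights in :data:`POOL_DISTANCE_WEIGHTS`) so planted
    molecules model compounds that hit the disease pathway directly — and
    the rest uniformly; background molecules draw all targets uniformly.
    Planted molecules are labelled benefit category ``a``, background ``d``.
    """
    rng_d = _streams(params)["disease"]
    rng_m = _streams(params)["molecules"]
    proteins = interactome.protein_ids

    ppi = nx.Graph()
    ppi.add_nodes_from(proteins)
    for e in interactome.edges:
        if e.edge_type == mi.PP:
            ppi.add_edge(e.source, e.target)

    if params.n_disease_genes > len(proteins):
        raise ValueError("protein layer smaller than requested disease gene count")
    center = proteins[int(rng_d.integers(len(proteins)))]
    disease_genes = _bfs_ball(ppi, center, params.n_disease_genes)
    if len(disease_genes) < params.n_disease_genes:
        raise ValueError("graph too small/disconnected for the disease ball")

    # radius-2 neighborhood of the disease set: the planted target pool,
    # with per-node graph distance to the disease set (0, 1, or 2)
    dist = {g: 0 for g in disease_genes}
    for g in disease_genes:
        for nb in ppi.neighbors(g):
            dist.setdefault(nb, 1)
    for nb in [k for k, v in dist.items() if v == 1]:
        for n2 in ppi.neighbors(nb):
            dist.setdefault(n2, 2)
    pool = sorted(dist)
    weights = np.array([POOL_DISTANCE_WEIGHTS[dist[x]] for x in pool])
    weights = weights / weights.sum()

    n_in = round(params.planted_overlap * params.targets_per_molecule)
    n_in = min(max(n_in, 1), params.targets_per_molecule)

    entities = []
    labels = {}
    width = len(str(params.n_molecules))
    for j in range(params.n_molecules):
        eid = f"M{j:0{width}d}"
        planted = j < params.n_planted
        if planted:
            inside = rng_m.choice(
                len(pool), size=min(n_in, len(pool)), replace=False, p=weights
            )
            targets = {pool[int(i)] for i in inside}
            while len(targets) < params.targets_per_molecule:
                targets.add(proteins[int(rng_m.integers(len(proteins)))])
        else:
            picks = rng_m.choice(
                len(proteins), size=params.targets_per_molecule, replace=False
            )
            targets = {proteins[int(i)] for i in picks}
        entities.append(
            EntityTargets(
                entity_id=eid,
                entity_name=f"molecule-{j}",
                entity_class="bioactive_molecule",
                target_ids=frozenset(targets),
            )
        )
        labels[eid] = "a" if planted else "d"
    return disease_genes, entities, BenefitCategorization(labels)


def write_fixture(
    interactome: Interactome,
    disease_genes: list[str],
    entities: list[EntityTargets],
    labels: BenefitCategorization,
    out_dir: str | Path,
) -> None:
    """Write the full TSV bundle consumed by the I/O layer.

    A fresh pipeline run on the written bundle reproduces the in-memory
    results exactly (round-trip property).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mi.save_interactome(interactome, out)
    mi.write_entity_targets(out / "targets.tsv", entities)
    mi.write_gene_list(out / "disease_genes.txt", disease_genes)
    write_benefit_categorization(out / "categories.tsv", labels)


PRESETS = {
    "tiny": SimParams(
        n_proteins=8,
        n_functions=3,
        n_molecules=6,
        n_disease_genes=3,
        n_planted=2,
        targets_per_molecule=2,
        membership_rate=1.0,
    ),
    "bench": SimParams(n_proteins=500),
    "paperlike": SimParams(
        n_proteins=17600,
        n_functions=2000,
        n_molecules=2100,
        n_disease_genes=13,
        n_planted=15,
    ),
}


def generate_benchmark(
    params: SimParams | None = None, seed: int | None = None
) -> tuple[Interactome, list[str], list[EntityTargets], BenefitCategorization]:
    """One-call generation of interactome + disease + molecules + labels."""
    params = params or SimParams()
    if seed is not None:
        params = SimParams(**{**params.__dict__, "rng_seed": seed})
    graph = generate_interactome(params)
    disease, entities, labels = plant_disease_and_molecules(graph, params)
    return graph, disease, entities, labels
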
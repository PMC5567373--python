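"""Metabolite-centric metabolic network reconstruction and topology descriptors.

A network is built from substrate-product reactant pairs: each node is a
metabolite, each undirected edge a substrate-product relation. Two
screening criteria are applied before edges are created: pairs whose
pathway annotation does not intersect the organism's pathway set are
dropped, and pairs involving compounds with unspecified residues
(generic "R" groups) are dropped.

Per-node descriptors are the degree (neighbour count ``n``) and the
clustering coefficient ``2 * e_n / (n * (n - 1))`` where ``e_n`` counts
edges among the node's neighbours; nodes of degree 0 or 1 are assigned a
clustering coefficient of 0, matching the NetworkAnalyzer convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .dataio import Dataset

logger = logging.getLogger(__name__)

__all__ = [
    "ReactantPair",
    "MetabolicNetwork",
    "reconstruct_network",
    "read_reactant_pairs",
    "flag_unspecified",
    "tertile_cluster_report",
]


@dataclass(frozen=True)
class ReactantPair:
    """One substrate-product pair with its pathway annotation."""

    substrate_id: str
    product_id: str
    pathway_ids: frozenset[str] = field(default_factory=frozenset)
    has_unspecified_residue: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "pathway_ids", frozenset(self.pathway_ids))


def flag_unspecified(formulas: Mapping[str, str], pattern: str = "R") -> set[str]:
    """Return metabolite ids whose formula contains an unspecified residue.

    ``pattern`` is matched as a substring of the formula field (default
    the generic residue symbol ``R``).
    """
    return {mid for mid, formula in formulas.items() if pattern in (formula or "")}


class MetabolicNetwork:
    """Simple undirected metabolite graph with topology descriptors.

    Thin wrapper over :class:`networkx.Graph` guaranteeing no self-loops
    and no parallel edges, plus the descriptor conventions used for
    concentration modelling.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = nx.Graph()
        if graph is not None:
            for u, v in graph.edges():
                if u != v:
                    self.graph.add_edge(u, v)
            self.graph.add_nodes_from(graph.nodes())

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes())

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self.graph.edges()}

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def degree(self, node: str) -> int:
        """Number of distinct neighbours of ``node``."""
        if node not in self.graph:
            raise KeyError(f"unknown node {node!r}")
        return int(self.graph.degree[node])

    def clustering_coefficient(self, node: str) -> float:
        """Fraction of realised edges among the node's neighbours, in [0, 1]."""
        if node not in self.graph:
            raise KeyError(f"unknown node {node!r}")
        return float(nx.clustering(self.graph, node))

    def descriptors_for(self, metabolite_ids: Sequence[str]) -> pd.DataFrame:
        """Degree and clustering coefficient per requested metabolite.

        Metabolites absent from the network receive degree 0 and
        clustering coefficient 0 with a logged warning.
        """
        missing = [m for m in metabolite_ids if m not in self.graph]
        if missing:
            logger.warning(
                "%d metabolite(s) absent from the network assigned degree=0, cc=0: %s",
                len(missing),
                ", ".join(sorted(missing)[:10]),
            )
        rows = []
        for mid in metabolite_ids:
            if mid in self.graph:
                rows.append((mid, self.degree(mid), self.clustering_coefficient(mid)))
            else:
                rows.append((mid, 0, 0.0))
        return pd.DataFrame(rows, columns=["metabolite_id", "degree", "clustering_coefficient"])

    # -- export ------------------------------------------------------------
    def to_edge_tsv(self, path: str | Path) -> None:
        pd.DataFrame(sorted((sorted(e) for e in self.edges)), columns=["source", "target"]).to_csv(
            path, sep="\t", index=False
        )

    def to_sif(self, path: str | Path, relation: str = "sp") -> None:
        with open(path, "w") as fh:
            for u, v in sorted(sorted(e) for e in self.edges):
                fh.write(f"{u}\t{relation}\t{v}\n")
            for node in sorted(self.nodes):
                if self.graph.degree[node] == 0:
                    fh.write(f"{node}\n")


def reconstruct_network(
    pairs: Iterable[ReactantPair], organism_pathways: set[str]
) -> MetabolicNetwork:
    """Build the organism network from reactant pairs via two screens.

    A pair survives iff (1) its pathway annotation intersects the
    organism's pathway set and (2) it carries no unspecified residue.
    Surviving pairs become deduplicated undirected edges; self-pairs
    never create an edge.
    """
    if not organism_pathways:
        raise ValueError("organism_pathways must be non-empty")
    net = MetabolicNetwork()
    kept = 0
    for pair in pairs:
        if pair.has_unspecified_residue:
            continue
        if not (pair.pathway_ids & organism_pathways):
            continue
        if pair.substrate_id == pair.product_id:
            net.graph.add_node(pair.substrate_id)
            continue
        net.graph.add_edge(pair.substrate_id, pair.product_id)
        kept += 1
    if kept == 0:
        logger.warning("no reactant pair survived screening; returning an empty network")
    return net


def read_reactant_pairs(
    path: str | Path, pathway_sidecar: str | Path | None = None
) -> list[ReactantPair]:
    """Read reactant pairs from TSV, or SIF with a pathway sidecar.

    TSV columns: substrate_id, product_id, pathway_ids (semicolon
    separated, may be empty), unspecified_residue (0/1). A SIF file
    (``node relation node``) needs a sidecar TSV mapping
    ``substrate_id<TAB>product_id<TAB>pathway_ids`` for pathway screening.
    """
    path = Path(path)
    pairs: list[ReactantPair] = []
    if path.suffix.lower() == ".sif":
        sidecar: dict[tuple[str, str], frozenset[str]] = {}
        if pathway_sidecar is not None:
            sc = pd.read_csv(pathway_sidecar, sep="\t", dtype=str, keep_default_na=False)
            for row in sc.itertuples(index=False):
                pws = frozenset(p for p in str(row.pathway_ids).split(";") if p)
                sidecar[(row.substrate_id, row.product_id)] = pws
                sidecar[(row.product_id, row.substrate_id)] = pws
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if len(parts) >= 3:
                    s, _, t = parts[0], parts[1], parts[2]
                    pairs.append(ReactantPair(s, t, sidecar.get((s, t), frozenset())))
        return pairs
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for row in frame.itertuples(index=False):
        pws = frozenset(p for p in str(getattr(row, "pathway_ids", "")).split(";") if p)
        pairs.append(
            ReactantPair(
                substrate_id=str(row.substrate_id),
                product_id=str(row.product_id),
                pathway_ids=pws,
                has_unspecified_residue=str(getattr(row, "unspecified_residue", "0")) in ("1", "true", "True"),
            )
        )
    return pairs


def tertile_cluster_report(
    dataset: Dataset, net: MetabolicNetwork, organism: str
) -> pd.DataFrame:
    """Concentration tertiles vs mean clustering coefficient for one organism.

    Metabolites of ``organism`` with a concentration are sorted by
    concentration (stable on input order) and cut into three near-equal
    Low/Medium/High groups; the report carries each group's size, mean
    concentration and mean clustering coefficient. Metabolites missing
    from the network contribute 0 (see :meth:`MetabolicNetwork.descriptors_for`).
    """
    records = [
        r for r in dataset.records if r.organism == organism and r.concentration is not None
    ]
    if len(records) < 3:
        raise ValueError(
            f"organism {organism!r} has {len(records)} mapped metabolites; need at least 3"
        )
    ordered = sorted(records, key=lambda r: r.concentration)  # Python sort is stable
    n = len(ordered)
    base, rem = divmod(n, 3)
    sizes = [base, base, base]
    for i in range(rem):  # remainder goes to the later (higher-concentration) groups
        sizes[2 - i] += 1
    rows = []
    start = 0
    for label, size in zip(("Low", "Medium", "High"), sizes):
        grp = ordered[start : start + size]
        start += size
        ccs = net.descriptors_for([r.metabolite_id for r in grp])["clustering_coefficient"]
        rows.append(
            {
                "group": label,
                "n": size,
                "mean_concentration_molar": float(pd.Series([r.concentration for r in grp]).mean()),
                "mean_clustering_coefficient": float(ccs.mean()),
            }
        )
    return pd.DataFrame(rows)
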
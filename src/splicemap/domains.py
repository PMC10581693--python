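"""Domain segmentation of predicted structures from AlphaFold confidence.

Residue pairs that are mutually well-placed (both pLDDT > 70 and
symmetrised PAE < 5 Angstroms) are joined in a weighted graph with edge
weight 1/PAE; greedy modularity maximisation then partitions the graph
into communities, which correspond to rigidly packed domains.
Communities below 20 residues are discarded, and low-confidence
(disordered) residues never acquire edges, so they stay unassigned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ConfidenceData",
    "DomainSet",
    "build_confidence_graph",
    "segment_domains",
    "read_alphafold_json",
    "read_plddt_from_structure",
]


@dataclass
class ConfidenceData:
    """PAE matrix (Angstroms, possibly asymmetric) plus per-residue pLDDT."""

    pae: np.ndarray
    plddt: np.ndarray

    def __post_init__(self):
        self.pae = np.asarray(self.pae, dtype=float)
        self.plddt = np.asarray(self.plddt, dtype=float)
        n = len(self.plddt)
        if self.pae.shape != (n, n):
            raise ValueError("PAE must be square and match pLDDT length")
        if np.isnan(self.pae).any() or np.isnan(self.plddt).any():
            raise ValueError("NaN in confidence data")
        if (self.pae < 0).any():
            raise ValueError("negative PAE")

    @property
    def n_residues(self) -> int:
        return len(self.plddt)

    def symmetrized_pae(self) -> np.ndarray:
        return 0.5 * (self.pae + self.pae.T)


def read_alphafold_json(pae_path, plddt=None) -> ConfidenceData:
    """Read an AlphaFold-DB style JSON with a predicted_aligned_error matrix.

    ``plddt`` may be an array, or omitted if the JSON itself carries a
    "plddt" entry.
    """
    with open(pae_path) as fh:
        data = json.load(fh)
    if isinstance(data, list):  # AFDB wraps the object in a 1-element list
        data = data[0]
    pae = np.asarray(data["predicted_aligned_error"], dtype=float)
    if plddt is None:
        if "plddt" not in data:
            raise ValueError("no pLDDT in JSON; pass plddt= explicitly")
        plddt = data["plddt"]
    return ConfidenceData(pae=pae, plddt=np.asarray(plddt, dtype=float))


def read_plddt_from_structure(path) -> np.ndarray:
    """Per-residue pLDDT from the B-factor column of a PDB/mmCIF file."""
    import gemmi

    structure = gemmi.read_structure(str(path))
    out = []
    for model in structure:
        for chain in model:
            for residue in chain:
                if len(residue):
                    out.append(residue[0].b_iso)
        break  # first model only
    return np.array(out, dtype=float)


def build_confidence_graph(
    conf: ConfidenceData,
    plddt_min: float = 70.0,
    pae_max: float = 5.0,
    pae_floor: float = 0.2,
) -> nx.Graph:
    """Weighted residue graph from confidence thresholds.

    Nodes are all residues; an edge joins i != j when both residues have
    pLDDT above ``plddt_min`` and their symmetrised PAE is below
    ``pae_max``, with weight 1/PAE (PAE floored at ``pae_floor`` Angstroms
    to keep weights bounded).
    """
    pae = conf.symmetrized_pae()
    n = conf.n_residues
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    confident = conf.plddt > plddt_min
    ii, jj = np.where(np.triu(np.outer(confident, confident) & (pae < pae_max), k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        graph.add_edge(i, j, weight=1.0 / max(pae[i, j], pae_floor))
    return graph


@dataclass
class DomainSet:
    """Disjoint residue-index domains plus the unassigned remainder."""

    domains: list[list[int]]
    unassigned: list[int] = field(default_factory=list)

    def __post_init__(self):
        seen: set[int] = set()
        for dom in self.domains:
            if seen & set(dom):
                raise ValueError("domains overlap")
            seen.update(dom)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "domain_id": f"D{i + 1}",
                "start": min(dom),
                "end": max(dom),
                "n_residues": len(dom),
            }
            for i, dom in enumerate(self.domains)
        ]
        return pd.DataFrame(rows, columns=["domain_id", "start", "end", "n_residues"])


def segment_domains(graph: nx.Graph, min_size: int = 20) -> DomainSet:
    """Partition the confidence graph into domains by greedy modularity.

    Communities smaller than ``min_size`` residues are discarded (their
    members become unassigned, along with every edge-less residue).
    Output domains are sorted by their smallest residue index; the
    algorithm is deterministic for a fixed node ordering.
    """
    all_nodes = set(graph.nodes)
    if graph.number_of_edges() == 0:
        return DomainSet(domains=[], unassigned=sorted(all_nodes))
    communities = nx.community.greedy_modularity_communities(graph, weight="weight")
    domains = [sorted(c) for c in communities if len(c) >= min_size]
    domains.sort(key=lambda d: d[0])
    assigned = {r for dom in domains for r in dom}
    return DomainSet(domains=domains, unassigned=sorted(all_nodes - assigned))


def segment_confidence(
    conf: ConfidenceData,
    plddt_min: float = 70.0,
    pae_max: float = 5.0,
    min_size: int = 20,
) -> DomainSet:
    """Convenience wrapper: graph construction plus segmentation."""
    return segment_domains(
        build_confidence_graph(conf, plddt_min=plddt_min, pae_max=pae_max),
        min_size=min_size,
    )
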
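"""Per-molecule graph construction.

A drug becomes an atom graph (heavy atoms as nodes, chemical bonds as
edges) with a 78-dimensional atom descriptor per node: one-hot element
symbol over a fixed 44-symbol list, one-hot degree (0-10), one-hot total
hydrogen count (0-10), one-hot implicit valence (0-10), and an aromaticity
flag — the descriptor set used across the graph-based affinity-prediction
literature, so drug encoders remain comparable to those baselines.

A protein becomes a residue graph: nodes are amino acids, and an edge joins
residues i < j whenever their contact-map entry reaches the threshold.
Each residue carries a 29-dimensional descriptor: one-hot over the 21-letter
alphabet (20 amino acids + X), seven physicochemical class flags
(aliphatic, aromatic, polar-neutral, acidic, basic, hydrophobic, small),
and the normalized chain position.  When no contact map is available a
sequence-window fallback connects residues within a fixed chain distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem

from .data_io import ProteinRecord

__all__ = [
    "MolecularGraph",
    "smiles_to_graph",
    "contact_map_to_graph",
    "sequence_fallback_graph",
    "save_graphs",
    "load_graphs",
    "DRUG_FEATURE_DIM",
    "PROTEIN_FEATURE_DIM",
]

ATOM_SYMBOLS = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb", "Unknown",
]
DRUG_FEATURE_DIM = len(ATOM_SYMBOLS) + 11 + 11 + 11 + 1  # 78

RESIDUES = "ACDEFGHIKLMNPQRSTVWYX"
_PROPERTY_CLASSES = [
    set("AGILPV"),      # aliphatic
    set("FWY"),         # aromatic
    set("CMNQST"),      # polar neutral
    set("DE"),          # acidic
    set("HKR"),         # basic
    set("ACFILMVW"),    # hydrophobic
    set("ACDGNPSTV"),   # small
]
PROTEIN_FEATURE_DIM = len(RESIDUES) + len(_PROPERTY_CLASSES) + 1  # 29


@dataclass
class MolecularGraph:
    node_features: np.ndarray  # N x F
    edges: list[tuple[int, int]]  # undirected, i < j, no self-loops
    kind: str  # "drug" | "protein"
    ids: str | None = None

    def __post_init__(self):
        self.node_features = np.asarray(self.node_features, dtype=float)
        n = self.node_features.shape[0]
        norm = []
        for i, j in self.edges:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i}, {j}) out of range for {n} nodes")
            if i == j:
                raise ValueError(f"self-loop ({i}, {i}) not allowed in stored edges")
            norm.append((min(i, j), max(i, j)))
        self.edges = sorted(set(norm))

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.n_nodes, self.n_nodes))
        for i, j in self.edges:
            A[i, j] = A[j, i] = 1.0
        return A

    def edge_index(self, add_self_loops: bool = False) -> np.ndarray:
        """Directed (2, E) edge index with both orientations of every edge."""
        src = [i for i, j in self.edges] + [j for i, j in self.edges]
        dst = [j for i, j in self.edges] + [i for i, j in self.edges]
        if add_self_loops:
            src += list(range(self.n_nodes))
            dst += list(range(self.n_nodes))
        return np.array([src, dst], dtype=np.intp).reshape(2, -1)


def _one_hot(value, choices: list) -> list[float]:
    if value not in choices:
        value = choices[-1]
    return [1.0 if value == c else 0.0 for c in choices]


def _atom_features(atom: Chem.Atom) -> list[float]:
    return (
        _one_hot(atom.GetSymbol(), ATOM_SYMBOLS)
        + _one_hot(atom.GetDegree(), list(range(11)))
        + _one_hot(atom.GetTotalNumHs(), list(range(11)))
        + _one_hot(atom.GetImplicitValence(), list(range(11)))
        + [1.0 if atom.GetIsAromatic() else 0.0]
    )


def smiles_to_graph(smiles: str, drug_id: str | None = None) -> MolecularGraph:
    """Atom graph of a single-fragment molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) > 1:
        raise ValueError(f"multi-fragment SMILES rejected: {smiles!r}")
    feats = np.array([_atom_features(a) for a in mol.GetAtoms()], dtype=float)
    edges = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    return MolecularGraph(node_features=feats, edges=edges, kind="drug", ids=drug_id)


def _residue_features(sequence: str) -> np.ndarray:
    L = len(sequence)
    feats = np.zeros((L, PROTEIN_FEATURE_DIM))
    for i, aa in enumerate(sequence):
        aa = aa if aa in RESIDUES else "X"
        feats[i, RESIDUES.index(aa)] = 1.0
        for k, cls in enumerate(_PROPERTY_CLASSES):
            if aa in cls:
                feats[i, len(RESIDUES) + k] = 1.0
        feats[i, -1] = i / max(1, L - 1) if L > 1 else 0.0
    return feats


def contact_map_to_graph(protein: ProteinRecord, threshold: float = 0.5) -> MolecularGraph:
    """Residue graph from a contact map: edge iff map entry >= threshold."""
    if protein.contact_map is None:
        raise ValueError(f"protein {protein.protein_id} has no contact map")
    cm = protein.contact_map
    L = len(protein.sequence)
    if cm.shape != (L, L):
        raise ValueError(f"contact map shape {cm.shape} != ({L}, {L})")
    iu, ju = np.nonzero(np.triu(cm, k=1) >= threshold)
    edges = list(zip(iu.tolist(), ju.tolist()))
    return MolecularGraph(node_features=_residue_features(protein.sequence),
                          edges=edges, kind="protein", ids=protein.protein_id)


def sequence_fallback_graph(protein: ProteinRecord, window: int = 1) -> MolecularGraph:
    """Residue graph connecting residues within ``window`` chain positions."""
    if not protein.sequence:
        raise ValueError("empty protein sequence")
    L = len(protein.sequence)
    edges = [(i, j) for i in range(L) for j in range(i + 1, min(L, i + window + 1))]
    return MolecularGraph(node_features=_residue_features(protein.sequence),
                          edges=edges, kind="protein", ids=protein.protein_id)


def protein_to_graph(protein: ProteinRecord, threshold: float = 0.5,
                     window: int = 3) -> MolecularGraph:
    """Contact-map graph when a map is present, sequence-window fallback otherwise."""
    if protein.contact_map is not None:
        return contact_map_to_graph(protein, threshold)
    return sequence_fallback_graph(protein, window)


# ---------------------------------------------------------------------------
# serialization


def save_graphs(graphs: list[MolecularGraph], path: str | Path) -> None:
    payload = [
        {
            "id": g.ids,
            "kind": g.kind,
            "node_features": g.node_features.tolist(),
            "edges": [list(e) for e in g.edges],
        }
        for g in graphs
    ]
    Path(path).write_text(json.dumps(payload))


def load_graphs(path: str | Path) -> list[MolecularGraph]:
    payload = json.loads(Path(path).read_text())
    return [
        MolecularGraph(
            node_features=np.array(item["node_features"], dtype=float),
            edges=[tuple(e) for e in item["edges"]],
            kind=item["kind"],
            ids=item["id"],
        )
        for item in payload
    ]
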
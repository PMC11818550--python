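"""Drug-drug and protein-protein similarity.

Drugs are compared through Morgan (ECFP) circular fingerprints and the
Tanimoto coefficient |a AND b| / (|a| + |b| - |a AND b|); proteins through
Needleman-Wunsch global sequence alignment.  Two alignment scorers are
provided: a simple match/mismatch/linear-gap dynamic program (exact, easy to
verify) and a BLOSUM62 affine-gap scorer backed by Biopython's pairwise
aligner, which is the default for real amino-acid sequences.

Raw alignment scores are mapped into [0, 1] by geometric self-score
normalization, ``S(a, b) = nw(a, b) / sqrt(nw(a, a) * nw(b, b))``, with
negative values clipped to zero, so both similarity matrices live on the
same bounded nonnegative scale required by the heterogeneous graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .data_io import DrugRecord, ProteinRecord

__all__ = [
    "Fingerprint",
    "SimilarityMatrix",
    "morgan_fingerprint",
    "tanimoto",
    "drug_similarity_matrix",
    "nw_score",
    "nw_score_blosum",
    "protein_similarity_matrix",
    "save_similarity_matrix",
    "load_similarity_matrix",
]


@dataclass(frozen=True)
class Fingerprint:
    bits: np.ndarray  # binary uint8 vector
    radius: int
    n_bits: int

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.shape != (self.n_bits,) or not np.isin(bits, (0, 1)).all():
            raise ValueError("fingerprint must be a binary vector of length n_bits")
        object.__setattr__(self, "bits", bits)


@dataclass
class SimilarityMatrix:
    values: np.ndarray
    kind: str  # "drug" | "protein"
    ids: list[str]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"similarity matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity matrix diagonal must be 1")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")
        self.values = v


# ---------------------------------------------------------------------------
# drugs


def morgan_fingerprint(smiles: str, radius: int = 2, n_bits: int = 1024) -> Fingerprint:
    """Hashed circular-substructure fingerprint of a molecule (ECFP style)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in gen.GetFingerprint(mol).GetOnBits():
        arr[bit] = 1
    return Fingerprint(bits=arr, radius=radius, n_bits=n_bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient of two binary fingerprints, in [0, 1]."""
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprints have different lengths")
    inter = int(np.sum(a.bits & b.bits))
    union = int(np.sum(a.bits)) + int(np.sum(b.bits)) - inter
    if union == 0:
        warnings.warn("both fingerprints are all-zero; Tanimoto defined as 0")
        return 0.0
    return inter / union


def drug_similarity_matrix(drugs: list[DrugRecord], radius: int = 2, n_bits: int = 1024) -> SimilarityMatrix:
    """Pairwise Tanimoto similarity over a drug list."""
    fps = []
    for d in drugs:
        try:
            fps.append(morgan_fingerprint(d.smiles, radius, n_bits))
        except ValueError as exc:
            raise ValueError(f"drug {d.drug_id}: {exc}") from exc
    n = len(drugs)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = tanimoto(fps[i], fps[j])
    return SimilarityMatrix(values=S, kind="drug", ids=[d.drug_id for d in drugs])


# ---------------------------------------------------------------------------
# proteins


def nw_score(seq_a: str, seq_b: str, match: float = 1.0, mismatch: float = -1.0,
             gap: float = -1.0) -> float:
    """Optimal global alignment score, simple scoring with linear gaps.

    Classical dynamic program over the (len_a+1) x (len_b+1) score matrix;
    rows are filled with a running-maximum trick so the inner loop is
    vectorized.  Accepts arbitrary alphabets.
    """
    la, lb = len(seq_a), len(seq_b)
    if la == 0 or lb == 0:
        # all-gap path
        return gap * max(la, lb)
    b_arr = np.frombuffer(seq_b.encode("latin-1"), dtype=np.uint8)
    prev = gap * np.arange(lb + 1, dtype=float)
    j_idx = np.arange(1, lb + 1)
    for i in range(1, la + 1):
        sub = np.where(b_arr == ord(seq_a[i - 1]), match, mismatch)
        cand = np.maximum(prev[:-1] + sub, prev[1:] + gap)  # diagonal vs up
        # left-neighbor recursion H[j] = max(cand[j], H[j-1] + gap) solved by
        # a prefix max of cand[j] - j*gap
        u = np.empty(lb + 1)
        u[0] = i * gap - 0 * gap
        u[1:] = cand - j_idx * gap
        row = np.maximum.accumulate(u) + np.concatenate(([0.0], j_idx)) * gap
        prev = row
    return float(prev[-1])


_BLOSUM_CACHE: dict[str, object] = {}


def _get_aligner(matrix_name: str, gap_open: float, gap_extend: float):
    key = f"{matrix_name}:{gap_open}:{gap_extend}"
    if key not in _BLOSUM_CACHE:
        matrix = substitution_matrices.load(matrix_name)
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = matrix
        aligner.mode = "global"
        aligner.open_gap_score = gap_open
        aligner.extend_gap_score = gap_extend
        _BLOSUM_CACHE[key] = (aligner, set(str(c) for c in matrix.alphabet))
    return _BLOSUM_CACHE[key]


def nw_score_blosum(seq_a: str, seq_b: str, matrix_name: str = "BLOSUM62",
                    gap_open: float = -10.0, gap_extend: float = -1.0) -> float:
    """Global alignment score under a substitution matrix with affine gaps.

    Residue letters absent from the matrix alphabet are mapped to ``X``;
    if the matrix has no ``X`` row this is an error.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner, alphabet = _get_aligner(matrix_name, gap_open, gap_extend)

    def sanitize(seq: str) -> str:
        seq = seq.upper()
        if set(seq) <= alphabet:
            return seq
        if "X" not in alphabet:
            bad = sorted(set(seq) - alphabet)
            raise ValueError(f"residues {bad} not in {matrix_name} alphabet, which lacks X")
        return "".join(c if c in alphabet else "X" for c in seq)

    return float(aligner.score(sanitize(seq_a), sanitize(seq_b)))


def protein_similarity_matrix(proteins: list[ProteinRecord], scoring: str = "blosum62",
                              **kwargs) -> SimilarityMatrix:
    """Pairwise normalized global-alignment similarity over a protein list.

    ``scoring="blosum62"`` uses the affine-gap BLOSUM62 scorer;
    ``scoring="simple"`` uses the match/mismatch/linear-gap program
    (keyword arguments are forwarded to the scorer).
    """
    if scoring == "blosum62":
        score = lambda a, b: nw_score_blosum(a, b, **kwargs)  # noqa: E731
    elif scoring == "simple":
        score = lambda a, b: nw_score(a, b, **kwargs)  # noqa: E731
    else:
        raise ValueError(f"unknown scoring {scoring!r}")

    n = len(proteins)
    self_scores = np.empty(n)
    for i, p in enumerate(proteins):
        try:
            self_scores[i] = score(p.sequence, p.sequence)
        except ValueError as exc:
            raise ValueError(f"protein {p.protein_id}: {exc}") from exc
    if np.any(self_scores <= 0):
        bad = [proteins[i].protein_id for i in np.nonzero(self_scores <= 0)[0]]
        raise ValueError(f"non-positive self-alignment score for proteins {bad}")

    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                raw = score(proteins[i].sequence, proteins[j].sequence)
            except ValueError as exc:
                raise ValueError(
                    f"aligning {proteins[i].protein_id} vs {proteins[j].protein_id}: {exc}"
                ) from exc
            val = raw / np.sqrt(self_scores[i] * self_scores[j])
            S[i, j] = S[j, i] = max(0.0, min(1.0, val))
    return SimilarityMatrix(values=S, kind="protein", ids=[p.protein_id for p in proteins])


# ---------------------------------------------------------------------------
# caching


def save_similarity_matrix(sim: SimilarityMatrix, matrix_path: str | Path,
                           ids_path: str | Path | None = None) -> None:
    matrix_path = Path(matrix_path)
    ids_path = Path(ids_path) if ids_path else matrix_path.with_suffix(".ids")
    np.savetxt(matrix_path, sim.values, fmt="%.10g", header=sim.kind, comments="# ")
    ids_path.write_text("\n".join(sim.ids) + "\n")


def load_similarity_matrix(matrix_path: str | Path, ids_path: str | Path | None = None,
                           kind: str | None = None) -> SimilarityMatrix:
    matrix_path = Path(matrix_path)
    ids_path = Path(ids_path) if ids_path else matrix_path.with_suffix(".ids")
    if kind is None:
        with open(matrix_path) as fh:
            first = fh.readline()
        kind = first.lstrip("# ").strip() or "drug"
    values = np.loadtxt(matrix_path)
    if values.ndim == 0:
        values = values.reshape(1, 1)
    ids = ids_path.read_text().split()
    return SimilarityMatrix(values=values, kind=kind, ids=ids)
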
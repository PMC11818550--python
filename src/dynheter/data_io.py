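"""Dataset input/output and split planning.

Drugs are (id, SMILES) pairs, proteins are (id, sequence) pairs with an
optional residue contact map, and affinities are sparse
(drug_id, protein_id, value) records.  Two on-disk dialects are accepted:

* two/three-column TSV files (``id<TAB>string`` and
  ``drug_id<TAB>protein_id<TAB>value``), the package's native layout;
* DeepDTA-style JSON dictionaries (``id -> SMILES`` / ``id -> sequence``),
  the layout the public kinase benchmarks ship in.

Contact maps live one-per-protein as whitespace-delimited square numeric
text matrices named ``<protein_id>.txt`` in a sidecar directory.

Splitting follows the benchmark convention: a random 5:1 train/test split
over (drug, protein) pairs followed by fivefold cross-validation over the
training records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

__all__ = [
    "DrugRecord",
    "ProteinRecord",
    "AffinityTable",
    "SplitPlan",
    "load_dataset",
    "write_dataset",
    "load_contact_map",
    "transform_affinity",
    "make_splits",
]

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    smiles: str


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str
    contact_map: np.ndarray | None = None

    def __post_init__(self):
        if self.contact_map is not None:
            cm = np.asarray(self.contact_map, dtype=float)
            L = len(self.sequence)
            if cm.shape != (L, L):
                raise ValueError(
                    f"contact map for {self.protein_id} has shape {cm.shape}, "
                    f"expected ({L}, {L})"
                )
            if not np.allclose(cm, cm.T):
                raise ValueError(f"contact map for {self.protein_id} is not symmetric")
            if cm.min() < 0 or cm.max() > 1:
                raise ValueError(f"contact map for {self.protein_id} has entries outside [0, 1]")
            object.__setattr__(self, "contact_map", cm)


@dataclass
class AffinityTable:
    records: list[tuple[str, str, float]]
    task: str = "regression"  # "regression" | "classification"

    def __post_init__(self):
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        pairs = [(d, p) for d, p, _ in self.records]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (drug_id, protein_id) pair in affinity table")
        if self.task == "classification":
            bad = [r for r in self.records if r[2] not in (0.0, 1.0)]
            if bad:
                raise ValueError(f"classification labels must be 0/1; offending rows: {bad[:5]}")

    @property
    def n(self) -> int:
        return len(self.records)

    def values(self) -> np.ndarray:
        return np.array([v for _, _, v in self.records], dtype=float)


@dataclass
class SplitPlan:
    test_indices: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train, validation) per fold
    seed: int = field(default=0)


# ---------------------------------------------------------------------------
# loading / writing


def _read_two_col(path: Path) -> dict[str, str]:
    if path.suffix == ".json":
        with open(path) as fh:
            data = json.load(fh)
        return {str(k): str(v) for k, v in data.items()}
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            out[parts[0]] = parts[1]
    return out


def load_contact_map(path: str | Path) -> np.ndarray:
    cm = np.loadtxt(path, dtype=float)
    if cm.ndim == 0:
        cm = cm.reshape(1, 1)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"{path}: contact map is not square (shape {cm.shape})")
    return cm


def load_dataset(
    drug_path: str | Path,
    protein_path: str | Path,
    affinity_path: str | Path,
    task: str = "regression",
    contact_map_dir: str | Path | None = None,
) -> tuple[list[DrugRecord], list[ProteinRecord], AffinityTable]:
    """Load a full dataset, validating SMILES and referential integrity."""
    drug_path, protein_path, affinity_path = Path(drug_path), Path(protein_path), Path(affinity_path)
    for p in (drug_path, protein_path, affinity_path):
        if not p.exists():
            raise FileNotFoundError(p)

    drug_map = _read_two_col(drug_path)
    bad_smiles = [
        (did, smi) for did, smi in drug_map.items()
        if Chem.MolFromSmiles(smi) is None or Chem.MolFromSmiles(smi).GetNumHeavyAtoms() < 1
    ]
    if bad_smiles:
        raise ValueError(f"unparseable SMILES for drug ids: {bad_smiles}")
    drugs = [DrugRecord(did, smi) for did, smi in drug_map.items()]

    protein_map = _read_two_col(protein_path)
    proteins = []
    cm_dir = Path(contact_map_dir) if contact_map_dir is not None else None
    for pid, seq in protein_map.items():
        seq = seq.upper()
        bad = set(seq) - AMINO_ALPHABET
        if bad:
            raise ValueError(f"protein {pid}: unknown residue letters {sorted(bad)}")
        cm = None
        if cm_dir is not None:
            cm_path = cm_dir / f"{pid}.txt"
            if cm_path.exists():
                cm = load_contact_map(cm_path)
        proteins.append(ProteinRecord(pid, seq, cm))

    records: list[tuple[str, str, float]] = []
    with open(affinity_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{affinity_path}:{lineno}: expected 3 tab-separated columns")
            did, pid, raw = parts
            if did not in drug_map:
                raise ValueError(f"{affinity_path}:{lineno}: unknown drug id {did!r}")
            if pid not in protein_map:
                raise ValueError(f"{affinity_path}:{lineno}: unknown protein id {pid!r}")
            records.append((did, pid, float(raw)))

    return drugs, proteins, AffinityTable(records, task=task)


def write_dataset(
    out_dir: str | Path,
    drugs: list[DrugRecord],
    proteins: list[ProteinRecord],
    table: AffinityTable,
) -> dict[str, Path]:
    """Write a dataset in the native TSV layout; returns the file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "drugs": out_dir / "drugs.tsv",
        "proteins": out_dir / "proteins.tsv",
        "affinities": out_dir / "affinities.tsv",
        "contact_maps": out_dir / "contact_maps",
    }
    with open(paths["drugs"], "w") as fh:
        for d in drugs:
            fh.write(f"{d.drug_id}\t{d.smiles}\n")
    with open(paths["proteins"], "w") as fh:
        for p in proteins:
            fh.write(f"{p.protein_id}\t{p.sequence}\n")
    with open(paths["affinities"], "w") as fh:
        for did, pid, v in table.records:
            fh.write(f"{did}\t{pid}\t{v!r}\n")
    if any(p.contact_map is not None for p in proteins):
        paths["contact_maps"].mkdir(exist_ok=True)
        for p in proteins:
            if p.contact_map is not None:
                np.savetxt(paths["contact_maps"] / f"{p.protein_id}.txt", p.contact_map, fmt="%.6g")
    return paths


# ---------------------------------------------------------------------------
# affinity transforms


def transform_affinity(values, mode: str = "none") -> np.ndarray:
    """Transform raw affinity values.

    ``neg_log10_nM`` converts a dissociation constant in nanomolar units to
    the pKd scale: Kd[nM] -> -log10(Kd * 1e-9).  ``none`` is the identity
    (used for score-style affinities that are already on a modelling scale).
    """
    values = np.asarray(values, dtype=float)
    if mode == "none":
        return values.copy()
    if mode == "neg_log10_nM":
        if np.any(values <= 0):
            raise ValueError("neg_log10_nM requires strictly positive Kd values")
        return -np.log10(values * 1e-9)
    raise ValueError(f"unknown transform mode {mode!r}")


# ---------------------------------------------------------------------------
# splits


def make_splits(table: AffinityTable, seed: int) -> SplitPlan:
    """Random 5:1 test split over pairs, then 5 CV folds on the remainder.

    ``floor(n/6)`` records go to the test set; the training remainder is cut
    into five validation folds of near-equal size.  Deterministic in ``seed``.
    """
    n = table.n
    if n < 6:
        raise ValueError(f"need at least 6 records to split 5:1, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = n // 6
    test_indices = np.sort(order[:n_test])
    train_pool = order[n_test:]
    fold_chunks = np.array_split(train_pool, 5)
    folds = []
    for k in range(5):
        val = np.sort(fold_chunks[k])
        train = np.sort(np.concatenate([fold_chunks[j] for j in range(5) if j != k]))
        folds.append((train, val))
    return SplitPlan(test_indices=test_indices, folds=folds, seed=seed)
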
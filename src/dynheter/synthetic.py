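"""Self-contained synthetic datasets for the full pipeline.

Drugs are drawn from a packaged library of known-valid, single-fragment
drug-like SMILES, padded with trivially valid generated chains and rings
once the library is exhausted (padding is flagged).  Proteins are uniform
random sequences over the 20-letter amino-acid alphabet with banded
contact maps (all residue pairs within ``contact_band`` chain positions in
contact) plus sparse symmetric long-range contacts.

Affinities can carry planted structure: under the ``linear_similarity``
rule, ``y = 5 * tanimoto(d, d_ref) + 3 * nwsim(p, p_ref) + N(0, noise_sd)``
where ``d_ref`` / ``p_ref`` are a seed-chosen reference drug and protein
and ``nwsim`` is the normalized global-alignment similarity — an additive
per-drug/per-protein signal the heterogeneous graph can learn.  The
``random`` rule draws i.i.d. normal values with no structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import AffinityTable, DrugRecord, ProteinRecord
from .similarity import morgan_fingerprint, nw_score_blosum, tanimoto

__all__ = [
    "SMILES_LIBRARY",
    "SyntheticSpec",
    "sample_drugs",
    "sample_proteins",
    "plant_affinities",
    "generate_dataset",
]

# Common drug and drug-like scaffolds; all parse to single-fragment
# molecules with at least one heavy atom.
SMILES_LIBRARY = [
    "CC(=O)Oc1ccccc1C(=O)O",                      # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",                 # caffeine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",                 # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",                         # paracetamol
    "Clc1ccccc1C2=NCC(=O)Nc3ccc(cc23)[N+](=O)[O-]",
    "CN1CCC[C@H]1c2cccnc2",                       # nicotine
    "OC(=O)c1ccccc1O",                            # salicylic acid
    "Nc1ccc(cc1)S(=O)(=O)N",                      # sulfanilamide
    "CC(N)Cc1ccccc1",                             # amphetamine
    "OCC(O)CO",                                   # glycerol
    "CC(C)NCC(O)c1ccc(O)c(O)c1",                  # isoprenaline
    "CN(C)CCOC(c1ccccc1)c2ccccc2",                # diphenhydramine
    "NC(=O)c1ccc[nH]1",
    "O=C(O)Cc1ccccc1",                            # phenylacetic acid
    "CC12CCC3c4ccc(O)cc4CCC3C1CCC2O",             # estradiol scaffold
    "c1ccc2c(c1)ccc3c2cccc3",                     # anthracene
    "c1ccc2[nH]ccc2c1",                           # indole
    "c1ccc2ncccc2c1",                             # quinoline
    "O=c1cc[nH]c(=O)[nH]1",                       # uracil
    "Nc1ncnc2[nH]cnc12",                          # adenine
    "CN1CCN(CC1)c2ccc(N)cc2",
    "OC(=O)C1CCCN1",                              # proline
    "NCCc1ccc(O)c(O)c1",                          # dopamine
    "NCCc1c[nH]c2ccccc12",                        # tryptamine
    "COc1cc2c(cc1OC)CC(N)C2",
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",              # salbutamol
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",                 # procainamide
    "CCOC(=O)c1ccccc1N",
    "O=C(Nc1ccccc1)c2ccccc2",                     # benzanilide
    "CC(=O)N1CCN(CC1)c2ccccc2",
    "Fc1ccc(cc1)C(=O)CCCN2CCC(O)(CC2)c3ccc(Cl)cc3",  # haloperidol
    "CC(C)(C)c1ccc(O)cc1",
    "Oc1ccc(Cl)cc1",
    "COc1ccccc1OCCN",
    "CN1CCCC1=O",                                 # N-methylpyrrolidone
    "O=C1CCCCC1",                                 # cyclohexanone
    "c1ccsc1",                                    # thiophene
    "c1ccoc1",                                    # furan
    "c1cc[nH]c1",                                 # pyrrole
    "c1ccncc1",                                   # pyridine
    "c1cnc2[nH]ccc2c1",                           # azaindole
    "OC(=O)CCC(=O)O",                             # succinic acid
    "NC(CC(=O)O)C(=O)O",                          # aspartate
    "NC(Cc1ccccc1)C(=O)O",                        # phenylalanine
    "CSCCC(N)C(=O)O",                             # methionine
    "NC(CO)C(=O)O",                               # serine
    "CC(O)C(N)C(=O)O",                            # threonine
    "N[C@@H](Cc1c[nH]cn1)C(=O)O",                 # histidine
    "OCC1OC(O)C(O)C(O)C1O",                       # glucose
    "CC(C)CC(NC(=O)C(N)CC(C)C)C(=O)O",            # dipeptide
    "CN(C)c1ccc(cc1)C(c2ccccc2)c3ccc(cc3)N(C)C",
    "COc1ccc2cc(ccc2c1)C(C)C(=O)O",               # naproxen
    "CC(C)Cc1ccccc1",
    "CCCCCCCCO",                                  # octanol
    "CCCCCC(=O)O",                                # hexanoic acid
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticSpec:
    n_drugs: int = 20
    n_proteins: int = 30
    seq_len_range: tuple[int, int] = (30, 60)
    contact_band: int = 2
    long_range_contact_prob: float = 0.05
    affinity_rule: str = "linear_similarity"  # | "random"
    noise_sd: float = 0.1
    seed: int = 42
    random_mean: float = 5.0
    random_sd: float = 1.0

    def __post_init__(self):
        if self.n_drugs < 2 or self.n_proteins < 2:
            raise ValueError("need at least 2 drugs and 2 proteins")
        if not 0 <= self.long_range_contact_prob <= 1:
            raise ValueError("long_range_contact_prob must lie in [0, 1]")
        if self.affinity_rule not in ("linear_similarity", "random"):
            raise ValueError(f"unknown affinity rule {self.affinity_rule!r}")


def _generated_variant(rng: np.random.Generator) -> str:
    """A trivially valid chain or ring SMILES for library overflow."""
    kind = rng.integers(0, 3)
    n = int(rng.integers(3, 12))
    if kind == 0:
        return "C" * n
    if kind == 1:
        return f"C1{'C' * max(2, n)}1"          # cycloalkane
    return "C" * n + "O"                         # alcohol chain


def sample_drugs(spec: SyntheticSpec) -> list[DrugRecord]:
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(3)[0])
    order = rng.permutation(len(SMILES_LIBRARY))
    smiles = [SMILES_LIBRARY[i] for i in order[: spec.n_drugs]]
    if spec.n_drugs > len(SMILES_LIBRARY):
        warnings.warn("drug library exhausted; padding with generated chain/ring variants")
        seen = set(smiles)
        while len(smiles) < spec.n_drugs:
            cand = _generated_variant(rng)
            if cand not in seen:
                seen.add(cand)
                smiles.append(cand)
    return [DrugRecord(f"D{i:03d}", s) for i, s in enumerate(smiles)]


def _contact_map(rng: np.random.Generator, L: int, band: int, p_long: float) -> np.ndarray:
    idx = np.arange(L)
    dist = np.abs(idx[:, None] - idx[None, :])
    cm = (dist <= band).astype(float)
    if p_long > 0:
        long_mask = np.triu(dist > band)
        hits = (rng.random((L, L)) < p_long) & long_mask
        cm[hits] = 1.0
        cm[hits.T] = 1.0
    return cm


def sample_proteins(spec: SyntheticSpec) -> list[ProteinRecord]:
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(4)[1])
    lo, hi = spec.seq_len_range
    out = []
    for i in range(spec.n_proteins):
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
        cm = _contact_map(rng, L, spec.contact_band, spec.long_range_contact_prob)
        out.append(ProteinRecord(f"P{i:03d}", seq, cm))
    return out


def _nw_similarity(seq: str, ref: str, self_scores: dict[str, float]) -> float:
    raw = nw_score_blosum(seq, ref)
    val = raw / np.sqrt(self_scores[seq] * self_scores[ref])
    return max(0.0, min(1.0, val))


def plant_affinities(drugs: list[DrugRecord], proteins: list[ProteinRecord],
                     spec: SyntheticSpec) -> AffinityTable:
    """Dense affinity table over all (drug, protein) pairs."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(5)[2])
    n_pairs = len(drugs) * len(proteins)
    if spec.affinity_rule == "random":
        values = rng.normal(spec.random_mean, spec.random_sd, size=n_pairs)
        records = [
            (d.drug_id, p.protein_id, float(values[i * len(proteins) + j]))
            for i, d in enumerate(drugs) for j, p in enumerate(proteins)
        ]
        return AffinityTable(records, task="regression")

    d_ref = drugs[int(rng.integers(len(drugs)))]
    p_ref = proteins[int(rng.integers(len(proteins)))]
    ref_fp = morgan_fingerprint(d_ref.smiles)
    drug_sim = np.array([tanimoto(morgan_fingerprint(d.smiles), ref_fp) for d in drugs])
    self_scores = {s: nw_score_blosum(s, s)
                   for s in {p.sequence for p in proteins} | {p_ref.sequence}}
    prot_sim = np.array([
        _nw_similarity(p.sequence, p_ref.sequence, self_scores) for p in proteins
    ])
    noise = rng.normal(0.0, spec.noise_sd, size=(len(drugs), len(proteins)))
    records = [
        (d.drug_id, p.protein_id, float(5.0 * drug_sim[i] + 3.0 * prot_sim[j] + noise[i, j]))
        for i, d in enumerate(drugs) for j, p in enumerate(proteins)
    ]
    return AffinityTable(records, task="regression")


def generate_dataset(spec: SyntheticSpec | None = None):
    """Full synthetic dataset: (drugs, proteins, affinity table)."""
    spec = spec or SyntheticSpec()
    drugs = sample_drugs(spec)
    proteins = sample_proteins(spec)
    table = plant_affinities(drugs, proteins, spec)
    return drugs, proteins, table
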
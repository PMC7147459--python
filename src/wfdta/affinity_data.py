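"""Drug-target affinity datasets: loading, transforms, filtering, splitting.

Affinities are either pKd values (Davis-style Kd measurements in nM,
transformed as pKd = -log10(Kd / 1e9)) or KIBA composite scores used
untransformed.  Datasets are long-format lists of unique
(drug, protein, affinity) records; dense proteins x drugs matrices are
flattened one record per non-missing cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .protein_encoding import ProteinSequence, read_fasta

LONG_COLUMNS = ("drug_id", "smiles", "protein_id", "sequence", "affinity")


@dataclass(frozen=True)
class AffinityRecord:
    drug_id: str
    smiles: str
    protein_id: str
    sequence: str
    affinity: float

    def __post_init__(self) -> None:
        if not self.drug_id or not self.protein_id:
            raise ValueError("drug_id and protein_id must be non-empty")
        if not math.isfinite(self.affinity):
            raise ValueError(
                f"non-finite affinity for pair ({self.drug_id}, {self.protein_id})"
            )


@dataclass(frozen=True)
class AffinityDataset:
    """Unique (drug, protein) affinity records with a units tag."""

    records: tuple[AffinityRecord, ...]
    units: str = "pKd"  # "pKd" | "KIBA"

    def __post_init__(self) -> None:
        if self.units not in ("pKd", "KIBA"):
            raise ValueError(f"units must be 'pKd' or 'KIBA', got {self.units!r}")
        pairs = [(r.drug_id, r.protein_id) for r in self.records]
        if len(set(pairs)) != len(pairs):
            seen, dup = set(), None
            for p in pairs:
                if p in seen:
                    dup = p
                    break
                seen.add(p)
            raise ValueError(f"duplicate (drug, protein) pair {dup}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def affinities(self) -> np.ndarray:
        return np.array([r.affinity for r in self.records])

    def proteins(self) -> list[ProteinSequence]:
        """Unique proteins in first-appearance order."""
        seen: dict[str, str] = {}
        for r in self.records:
            seen.setdefault(r.protein_id, r.sequence)
        return [ProteinSequence(id=k, residues=v) for k, v in seen.items()]

    def drugs(self) -> list[tuple[str, str]]:
        """Unique (drug_id, smiles) rows in first-appearance order."""
        seen: dict[str, str] = {}
        for r in self.records:
            seen.setdefault(r.drug_id, r.smiles)
        return list(seen.items())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records], columns=LONG_COLUMNS)

    def to_long_csv(self, path) -> None:
        # %.17g keeps float64 affinities exact across a write/read cycle
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def kd_to_pkd(kd_nm: float) -> float:
    """pKd from a dissociation constant in nM: -log10(Kd / 1e9)."""
    if not kd_nm > 0:
        raise ValueError(f"Kd must be positive, got {kd_nm}")
    return -math.log10(kd_nm / 1e9)


def filter_min_interactions(
    ds: AffinityDataset, k: int = 10, *, iterate: bool = True
) -> AffinityDataset:
    """Keep only drugs and proteins with at least ``k`` interactions.

    By default the filter is iterated to a fixpoint: removing records may
    push other drugs/proteins below the threshold, so passes repeat until
    every remaining drug and protein has >= k records.  ``iterate=False``
    applies a single pass.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    records = list(ds.records)
    while True:
        drug_counts: dict[str, int] = {}
        prot_counts: dict[str, int] = {}
        for r in records:
            drug_counts[r.drug_id] = drug_counts.get(r.drug_id, 0) + 1
            prot_counts[r.protein_id] = prot_counts.get(r.protein_id, 0) + 1
        kept = [
            r
            for r in records
            if drug_counts[r.drug_id] >= k and prot_counts[r.protein_id] >= k
        ]
        changed = len(kept) != len(records)
        records = kept
        if not changed or not iterate:
            break
    return replace(ds, records=tuple(records))


def train_test_split(
    ds: AffinityDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[AffinityDataset, AffinityDataset]:
    """Uniform random split of records into disjoint train/test sets.

    The split unit is the (drug, protein) pair (warm start): train size is
    round(fraction * n) and the partition is reproducible under ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(ds)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    train_idx = set(order[:n_train].tolist())
    train = tuple(r for i, r in enumerate(ds.records) if i in train_idx)
    test = tuple(r for i, r in enumerate(ds.records) if i not in train_idx)
    return replace(ds, records=train), replace(ds, records=test)


def load_long_csv(path, units: str = "pKd") -> AffinityDataset:
    """Load a long-format CSV with columns drug_id, smiles, protein_id, sequence, affinity."""
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in LONG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    problems: list[str] = []
    records: list[AffinityRecord] = []
    for i, row in table.iterrows():
        try:
            records.append(
                AffinityRecord(
                    drug_id=str(row["drug_id"]),
                    smiles=str(row["smiles"]),
                    protein_id=str(row["protein_id"]),
                    sequence=str(row["sequence"]).upper(),
                    affinity=float(row["affinity"]),
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    return AffinityDataset(records=tuple(records), units=units)


def load_matrix(
    matrix: pd.DataFrame,
    drugs: dict[str, str] | pd.DataFrame,
    proteins: dict[str, str] | pd.DataFrame,
    units: str = "pKd",
) -> AffinityDataset:
    """Flatten a dense proteins(rows) x drugs(columns) affinity matrix.

    One record is emitted per non-missing cell; NaN cells are skipped.
    ``drugs`` maps drug_id -> SMILES, ``proteins`` maps protein_id ->
    sequence (dicts, or two-column DataFrames with id in the first column).
    """
    if isinstance(drugs, pd.DataFrame):
        drugs = dict(zip(drugs.iloc[:, 0].astype(str), drugs.iloc[:, 1].astype(str)))
    if isinstance(proteins, pd.DataFrame):
        proteins = dict(zip(proteins.iloc[:, 0].astype(str), proteins.iloc[:, 1].astype(str)))
    problems: list[str] = []
    records: list[AffinityRecord] = []
    for protein_id, row in matrix.iterrows():
        protein_id = str(protein_id)
        if protein_id not in proteins:
            problems.append(f"protein {protein_id!r} has no sequence")
            continue
        for drug_id, value in row.items():
            drug_id = str(drug_id)
            if pd.isna(value):
                continue
            if drug_id not in drugs:
                problems.append(f"drug {drug_id!r} has no SMILES")
                break
            try:
                records.append(
                    AffinityRecord(
                        drug_id=drug_id,
                        smiles=drugs[drug_id],
                        protein_id=protein_id,
                        sequence=proteins[protein_id].upper(),
                        affinity=float(value),
                    )
                )
            except (ValueError, TypeError) as exc:
                problems.append(f"cell ({protein_id}, {drug_id}): {exc}")
    if problems:
        raise ValueError("affinity matrix problems: " + "; ".join(sorted(set(problems))))
    return AffinityDataset(records=tuple(records), units=units)


def load_matrix_files(matrix_path, drug_csv, protein_path, units: str = "pKd") -> AffinityDataset:
    """Matrix mode from files: TSV matrix + drug CSV + FASTA/CSV protein table."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    drug_table = pd.read_csv(drug_csv, dtype=str)
    protein_path = str(protein_path)
    if protein_path.endswith((".fa", ".fasta", ".faa")):
        proteins = {p.id: p.residues for p in read_fasta(protein_path)}
    else:
        prot_table = pd.read_csv(protein_path, dtype=str)
        proteins = dict(zip(prot_table.iloc[:, 0], prot_table.iloc[:, 1]))
    return load_matrix(matrix, drug_table, proteins, units=units)
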
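"""SMILES compounds as molecular graphs with 78-dim one-hot atom features.

Each heavy atom becomes a node described by five characteristics,
concatenated into a 78-wide vector:

* element symbol — one-hot over 43 common elements plus a catch-all bucket
  (44 slots);
* atomic rank — by default the number of bonds to neighbouring atoms plus
  the number of attached hydrogens; a ``rank_mode="degree"`` option uses the
  heavy-neighbour degree alone (11 slots, 0-10);
* total hydrogen count (11 slots, 0-10);
* implicit valence (11 slots, 0-10);
* aromaticity flag (1 slot).

Counts above 10 are clamped into the top bucket with a warning.  Every
chemical bond contributes a directed edge in both orientations; hydrogens
are implicit and bond orders are not featurized — the graph carries
connectivity only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

# 43 named elements + trailing catch-all bucket = 44 symbol slots.
ATOM_SYMBOLS: tuple[str, ...] = (
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg",
    "Na", "Ca", "Fe", "As", "Al", "I", "B", "V", "K", "Tl",
    "Yb", "Sb", "Sn", "Ag", "Pd", "Co", "Se", "Ti", "Zn", "H",
    "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn", "Zr", "Cr",
    "Pt", "Hg", "Pb",
)
N_SYMBOL_SLOTS = len(ATOM_SYMBOLS) + 1  # 44, last slot = unknown element
COUNT_SLOTS = 11  # one-hot buckets 0..10 for rank / H count / valence
FEATURE_DIM = N_SYMBOL_SLOTS + 3 * COUNT_SLOTS + 1  # 78

_SYMBOL_INDEX = {s: i for i, s in enumerate(ATOM_SYMBOLS)}


@dataclass(frozen=True)
class MolecularGraph:
    """Graph of one compound: per-atom feature rows + directed edge list."""

    compound_id: str
    node_features: np.ndarray  # (num_atoms, 78)
    edges: tuple[tuple[int, int], ...]  # directed; each bond appears twice

    @property
    def num_atoms(self) -> int:
        return self.node_features.shape[0]

    @property
    def num_bonds(self) -> int:
        return len(self.edges) // 2

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge endpoints as (source, target) integer arrays."""
        if not self.edges:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty
        arr = np.asarray(self.edges, dtype=np.int64)
        return arr[:, 0], arr[:, 1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "compound_id": self.compound_id,
                "node_features": self.node_features.astype(int).tolist(),
                "edges": [list(e) for e in self.edges],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MolecularGraph":
        obj = json.loads(text)
        return cls(
            compound_id=obj["compound_id"],
            node_features=np.asarray(obj["node_features"], dtype=np.float64),
            edges=tuple(tuple(e) for e in obj["edges"]),
        )


def _one_hot(value: int, size: int, what: str, context: str) -> np.ndarray:
    if value < 0:
        raise ValueError(f"{what} must be >= 0 (got {value} for {context})")
    if value >= size:
        warnings.warn(
            f"{what}={value} exceeds bucket range 0-{size - 1} for {context}; "
            "clamped to the top bucket",
            stacklevel=3,
        )
        value = size - 1
    vec = np.zeros(size)
    vec[value] = 1.0
    return vec


def atom_features(
    symbol: str,
    heavy_neighbors: int,
    num_h: int,
    implicit_valence: int,
    aromatic: bool,
    *,
    rank_mode: str = "bonds_plus_h",
) -> np.ndarray:
    """78-dim one-hot feature vector for one atom descriptor."""
    if rank_mode == "bonds_plus_h":
        rank = heavy_neighbors + num_h
    elif rank_mode == "degree":
        rank = heavy_neighbors
    else:
        raise ValueError(f"unknown rank_mode {rank_mode!r}; use 'bonds_plus_h' or 'degree'")
    symbol_vec = np.zeros(N_SYMBOL_SLOTS)
    symbol_vec[_SYMBOL_INDEX.get(symbol, N_SYMBOL_SLOTS - 1)] = 1.0
    ctx = f"atom {symbol!r}"
    return np.concatenate(
        [
            symbol_vec,
            _one_hot(rank, COUNT_SLOTS, "atomic rank", ctx),
            _one_hot(num_h, COUNT_SLOTS, "hydrogen count", ctx),
            _one_hot(implicit_valence, COUNT_SLOTS, "implicit valence", ctx),
            [1.0 if aromatic else 0.0],
        ]
    )


def smiles_to_graph(smiles: str, compound_id: str = "", *, rank_mode: str = "bonds_plus_h") -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Node order follows the parser's atom order; each bond yields a directed
    edge in both orientations.  Unparseable SMILES raise ``ValueError``
    carrying the compound id.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for compound {compound_id or smiles!r}: {smiles!r}")
    features = np.array(
        [
            atom_features(
                atom.GetSymbol(),
                atom.GetDegree(),
                atom.GetTotalNumHs(),
                atom.GetImplicitValence(),
                atom.GetIsAromatic(),
                rank_mode=rank_mode,
            )
            for atom in mol.GetAtoms()
        ]
    )
    edges: list[tuple[int, int]] = []
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((a, b))
        edges.append((b, a))
    edges.sort()
    return MolecularGraph(
        compound_id=compound_id or smiles,
        node_features=features,
        edges=tuple(edges),
    )


@dataclass
class GraphBatchReport:
    """Per-row failures collected while featurizing a compound table."""

    failures: list[tuple[str, str]] = field(default_factory=list)  # (id, message)

    @property
    def ok(self) -> bool:
        return not self.failures


def graphs_from_table(
    rows: list[tuple[str, str]],
    *,
    rank_mode: str = "bonds_plus_h",
) -> tuple[list[MolecularGraph], GraphBatchReport]:
    """Featurize (compound_id, smiles) rows, collecting failures per row.

    Row order is preserved; duplicate SMILES strings are parsed once and the
    cached graph is reused (re-labelled with each row's id).
    """
    report = GraphBatchReport()
    cache: dict[str, MolecularGraph] = {}
    graphs: list[MolecularGraph] = []
    for compound_id, smiles in rows:
        try:
            if smiles in cache:
                base = cache[smiles]
                graphs.append(
                    MolecularGraph(
                        compound_id=compound_id,
                        node_features=base.node_features.copy(),
                        edges=base.edges,
                    )
                )
            else:
                graph = smiles_to_graph(smiles, compound_id, rank_mode=rank_mode)
                cache[smiles] = graph
                graphs.append(graph)
        except ValueError as exc:
            report.failures.append((compound_id, str(exc)))
    return graphs, report
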
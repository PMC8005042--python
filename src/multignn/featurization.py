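"""SMILES-to-graph featurization.

Each molecule becomes a heavy-atom graph: a node feature matrix of 46
binary/integer slots per atom (one-hot blocks for atom symbol, degree,
hybridization, implicit valence, formal charge, ring-size membership,
aromaticity flag, and explicit-hydrogen count) and a directed COO edge list
holding both directions of every chemical bond.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.rdBase import BlockLogs


class FeaturizationError(ValueError):
    """Base class for featurization failures."""


class SmilesParseError(FeaturizationError):
    """The SMILES string could not be parsed into a molecule."""


class EncodingDomainError(FeaturizationError):
    """An atom property falls outside the schema categories (strict mode)."""


ATOM_SYMBOLS = ["C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "I", "H", "other"]
DEGREES = [0, 1, 2, 3, 4, 5, 6]
HYBRIDIZATIONS = ["sp", "sp2", "sp3", "sp3d", "sp3d2"]
VALENCES = [0, 1, 2, 3, 4, 5, 6]
FORMAL_CHARGES = [-1, 0, 1]
RING_SIZES = [3, 4, 5, 6, 7, 8]
EXPLICIT_HS = [0, 1, 2, 3, 4]

_RDKIT_HYBRID = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
    Chem.HybridizationType.SP3D: "sp3d",
    Chem.HybridizationType.SP3D2: "sp3d2",
}


@dataclass(frozen=True)
class AtomFeatureSchema:
    """Ordered feature blocks and their encoding modes.

    ``blocks`` is a list of ``(name, categories, mode)`` with mode one of
    ``one-hot`` (exactly one slot set), ``multi-hot`` (zero or more slots,
    used for ring-size membership of fused-ring atoms) or ``integer`` (a
    single integer-valued slot, used for the aromaticity flag).
    """

    blocks: tuple = (
        ("symbol", tuple(ATOM_SYMBOLS), "one-hot"),
        ("degree", tuple(DEGREES), "one-hot"),
        ("hybridization", tuple(HYBRIDIZATIONS), "one-hot"),
        ("valence", tuple(VALENCES), "one-hot"),
        ("formal_charge", tuple(FORMAL_CHARGES), "one-hot"),
        ("ring_size", tuple(RING_SIZES), "multi-hot"),
        ("aromatic", (0, 1), "integer"),
        ("explicit_h", tuple(EXPLICIT_HS), "one-hot"),
    )

    @property
    def total_width(self) -> int:
        return sum(1 if mode == "integer" else len(cats)
                   for _, cats, mode in self.blocks)

    def block_width(self, name: str) -> int:
        for block_name, cats, mode in self.blocks:
            if block_name == name:
                return 1 if mode == "integer" else len(cats)
        raise KeyError(name)

    def block_slice(self, name: str) -> slice:
        start = 0
        for block_name, cats, mode in self.blocks:
            width = 1 if mode == "integer" else len(cats)
            if block_name == name:
                return slice(start, start + width)
            start += width
        raise KeyError(name)


def build_schema() -> AtomFeatureSchema:
    """Return the fixed 46-slot atom feature schema."""
    return AtomFeatureSchema()


@dataclass
class AtomDescriptor:
    """Plain record of the atom properties the schema encodes."""

    symbol: str
    degree: int
    hybridization: str
    valence: int
    formal_charge: int
    ring_sizes: tuple[int, ...] = ()
    aromatic: bool = False
    explicit_h: int = 0


@dataclass
class MolecularGraph:
    """Node feature matrix plus directed COO edge list for one molecule."""

    node_features: np.ndarray          # (n_atoms, 46)
    edge_index: np.ndarray             # (2, 2m) int64, both directions, no self-loops
    label: float | None = None         # pIC50, -log10 molar
    id: str | None = None
    smiles: str | None = None

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]


def _clamp(value: int, categories: list[int], strict: bool, what: str) -> int:
    if value in categories:
        return value
    if strict:
        raise EncodingDomainError(f"{what}={value} outside categories {categories}")
    return min(categories, key=lambda c: abs(c - value))


def encode_atom(descriptor: AtomDescriptor, schema: AtomFeatureSchema,
                strict: bool = False) -> np.ndarray:
    """Encode one atom descriptor into a length-46 feature vector.

    In tolerant mode (default) out-of-range ordinal categories are clamped to
    the nearest listed category and unknown symbols fall into "other"; strict
    mode raises :class:`EncodingDomainError` instead (symbols still use the
    "other" catch-all, which Table-style schemas provide by construction).
    """
    vec = np.zeros(schema.total_width, dtype=np.float64)

    symbol = descriptor.symbol if descriptor.symbol in ATOM_SYMBOLS else "other"
    vec[schema.block_slice("symbol")][ATOM_SYMBOLS.index(symbol)] = 1.0

    degree = _clamp(descriptor.degree, DEGREES, strict, "degree")
    vec[schema.block_slice("degree")][DEGREES.index(degree)] = 1.0

    hybrid = descriptor.hybridization
    if hybrid not in HYBRIDIZATIONS:
        if strict:
            raise EncodingDomainError(f"hybridization={hybrid!r} not in {HYBRIDIZATIONS}")
        hybrid = "sp3"  # tolerant fallback for unspecified/other hybridizations
    vec[schema.block_slice("hybridization")][HYBRIDIZATIONS.index(hybrid)] = 1.0

    valence = _clamp(descriptor.valence, VALENCES, strict, "valence")
    vec[schema.block_slice("valence")][VALENCES.index(valence)] = 1.0

    charge = _clamp(descriptor.formal_charge, FORMAL_CHARGES, strict, "formal_charge")
    vec[schema.block_slice("formal_charge")][FORMAL_CHARGES.index(charge)] = 1.0

    ring_block = vec[schema.block_slice("ring_size")]
    for size in descriptor.ring_sizes:
        if size in RING_SIZES:
            ring_block[RING_SIZES.index(size)] = 1.0

    vec[schema.block_slice("aromatic")] = 1.0 if descriptor.aromatic else 0.0

    explicit_h = _clamp(descriptor.explicit_h, EXPLICIT_HS, strict, "explicit_h")
    vec[schema.block_slice("explicit_h")][EXPLICIT_HS.index(explicit_h)] = 1.0
    return vec


def describe_atom(atom: Chem.Atom) -> AtomDescriptor:
    """Read the schema-relevant properties off an RDKit atom."""
    return AtomDescriptor(
        symbol=atom.GetSymbol(),
        degree=atom.GetDegree(),
        hybridization=_RDKIT_HYBRID.get(atom.GetHybridization(), "unspecified"),
        valence=atom.GetImplicitValence(),
        formal_charge=atom.GetFormalCharge(),
        ring_sizes=tuple(s for s in RING_SIZES if atom.IsInRingSize(s)),
        aromatic=atom.GetIsAromatic(),
        explicit_h=atom.GetNumExplicitHs(),
    )


def smiles_to_graph(smiles: str, schema: AtomFeatureSchema | None = None,
                    strict: bool = False, label: float | None = None,
                    mol_id: str | None = None) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Both directions of every bond are stored (2m directed edge columns for m
    bonds); self-loops are never present — self-information enters through
    the layer definitions, not the molecule.
    """
    schema = schema or build_schema()
    with BlockLogs():
        mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise SmilesParseError(f"molecule with zero atoms: {smiles!r}")

    features = np.stack([encode_atom(describe_atom(atom), schema, strict=strict)
                         for atom in mol.GetAtoms()])
    edges: list[tuple[int, int]] = []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((u, v))
        edges.append((v, u))
    edge_index = (np.array(edges, dtype=np.int64).T if edges
                  else np.zeros((2, 0), dtype=np.int64))
    return MolecularGraph(node_features=features, edge_index=edge_index,
                          label=label, id=mol_id, smiles=smiles)


def pic50_from_ic50(ic50_nM: float) -> float:
    """Convert an IC50 in nanomolar to pIC50 = -log10(IC50 in molar)."""
    if not ic50_nM > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nM}")
    return -math.log10(ic50_nM * 1e-9)


def read_compounds_csv(path, schema: AtomFeatureSchema | None = None,
                       strict: bool = False) -> list[MolecularGraph]:
    """Load a compounds CSV (``id,smiles,ic50_nM`` or ``id,smiles,pic50``)."""
    import pandas as pd

    frame = pd.read_csv(path)
    required = {"id", "smiles"}
    if not required.issubset(frame.columns):
        raise ValueError(f"compounds CSV needs columns {sorted(required)}")
    if "pic50" in frame.columns:
        labels = frame["pic50"].astype(float)
    elif "ic50_nM" in frame.columns:
        labels = frame["ic50_nM"].astype(float).map(pic50_from_ic50)
    else:
        labels = pd.Series([None] * len(frame))
    graphs = []
    for (_, row), label in zip(frame.iterrows(), labels):
        graphs.append(smiles_to_graph(row["smiles"], schema, strict=strict,
                                      label=None if label is None else float(label),
                                      mol_id=str(row["id"])))
    return graphs
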
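"""Deterministic synthetic data: molecules, activities, descriptor tables.

Molecules come from a fragment grammar — curated substituents grafted onto
ring/chain scaffold templates — so every emitted SMILES is chemically valid
by construction (no valence-repair pass). The scaffold library spans ring
sizes 3-8, aromatic and aliphatic systems, the heteroatoms of the atom-symbol
schema, and formal charges -1/0/+1.

The synthetic activity model is a structure-determined linear response,

    pIC50 = b0 + b1 * (#N + #O) + b2 * (#aromatic atoms) + b3 * (#rings) + noise,

with defaults b = (4.0, 0.4, 0.05, -0.1) and Gaussian noise of standard
deviation ``sigma``. It is a testing surrogate with no biological meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .featurization import MolecularGraph, build_schema, smiles_to_graph
from .qsar import DescriptorTable

# Scaffold templates with exactly two substitution slots each.
SCAFFOLD_TEMPLATES = [
    "C1C({0})C1{1}",          # cyclopropane
    "C1CC({0})C1{1}",         # cyclobutane
    "C1CC({0})CC1{1}",        # cyclopentane
    "C1CC({0})CC({1})C1",     # cyclohexane
    "C1CCC({0})CCC1{1}",      # cycloheptane
    "C1CCCC({0})CCC1{1}",     # cyclooctane
    "c1cc({0})ccc1{1}",       # benzene
    "c1cc({0})ncc1{1}",       # pyridine
    "c1cc({0})sc1{1}",        # thiophene
    "c1cc({0})oc1{1}",        # furan
    "c1cc({0})[nH]c1{1}",     # pyrrole
    "c1ccc2cc({0})ccc2c1{1}",  # naphthalene (fused rings)
    "CC({0})CC{1}",           # branched aliphatic chain
    "C({0})CC{1}",            # short chain
]

SUBSTITUENTS = [
    "C", "CC", "CCC", "C(C)C", "O", "OC", "OCC", "N", "NC", "N(C)C",
    "F", "Cl", "Br", "I", "S", "SC", "C#N", "C=O", "C(=O)O", "C(=O)OC",
    "C(F)(F)F", "C(=O)[O-]", "[NH3+]", "[Si](C)(C)C", "P(C)C", "CO", "CN",
]

# Fixed molecules guaranteeing schema coverage independent of the rng draw.
COVERAGE_LIBRARY = [
    "C1CC1", "C1CCC1", "C1CCCC1", "C1CCCCC1", "C1CCCCCC1", "C1CCCCCCC1",
    "c1ccccc1", "c1ccncc1", "c1ccsc1", "c1cc[nH]c1", "c1ccc2ccccc2c1",
    "CC(C)O", "CCN", "CCCl", "CCBr", "CCI", "CCF", "CCS", "CC#N",
    "CC(=O)[O-]", "C[NH3+]", "C[Si](C)(C)C", "CP(C)C", "C",
]


class GrammarExhaustedError(RuntimeError):
    """The fragment grammar ran out of unique molecules."""


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_molecules: int = 200
    seed: int = 0
    sigma: float = 0.2
    betas: tuple[float, float, float, float] = (4.0, 0.4, 0.05, -0.1)


def _canonical(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def generate_molecules(spec: SyntheticSpec) -> list[str]:
    """Emit ``spec.n_molecules`` unique, valid, canonical SMILES strings."""
    if spec.n_molecules < 1:
        raise ValueError("need n_molecules >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    seen: set[str] = set()
    out: list[str] = []
    for smiles in COVERAGE_LIBRARY:
        canonical = _canonical(smiles)
        assert canonical is not None, smiles
        if canonical not in seen:
            seen.add(canonical)
            out.append(canonical)
        if len(out) == spec.n_molecules:
            return out
    attempts = 0
    max_attempts = 500 * spec.n_molecules
    while len(out) < spec.n_molecules:
        attempts += 1
        if attempts > max_attempts:
            raise GrammarExhaustedError(
                f"could not reach {spec.n_molecules} unique molecules")
        template = SCAFFOLD_TEMPLATES[rng.integers(len(SCAFFOLD_TEMPLATES))]
        subs = [SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))] for _ in range(2)]
        canonical = _canonical(template.format(*subs))
        if canonical is not None and canonical not in seen:
            seen.add(canonical)
            out.append(canonical)
    return out


def structure_counts(smiles: str) -> dict[str, int]:
    """Atom/ring counts entering the synthetic activity model."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    return {
        "hetero_no_count": sum(s in ("N", "O") for s in symbols),
        "aromatic_count": sum(a.GetIsAromatic() for a in mol.GetAtoms()),
        "ring_count": mol.GetRingInfo().NumRings(),
        "heavy_atom_count": mol.GetNumAtoms(),
        "n_count": symbols.count("N"),
        "o_count": symbols.count("O"),
    }


def generate_activity(graphs: list[MolecularGraph],
                      spec: SyntheticSpec) -> np.ndarray:
    """Synthetic pIC50 labels under the linear structure-activity model."""
    b0, b1, b2, b3 = spec.betas
    clean = np.empty(len(graphs))
    for i, g in enumerate(graphs):
        counts = structure_counts(g.smiles)
        clean[i] = (b0 + b1 * counts["hetero_no_count"]
                    + b2 * counts["aromatic_count"]
                    + b3 * counts["ring_count"])
    if spec.sigma == 0:
        return clean
    noise_rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[1])
    return clean + noise_rng.normal(0.0, spec.sigma, size=len(graphs))


def make_dataset(spec: SyntheticSpec) -> list[MolecularGraph]:
    """Featurized, labeled synthetic dataset — the standard test harness."""
    schema = build_schema()
    graphs = [smiles_to_graph(s, schema, mol_id=f"SYN{i:05d}")
              for i, s in enumerate(generate_molecules(spec))]
    for g, label in zip(graphs, generate_activity(graphs, spec)):
        g.label = float(label)
    return graphs


def generate_descriptor_table(graphs: list[MolecularGraph], n_decoys: int = 0,
                              seed: int = 0,
                              labels: np.ndarray | None = None) -> DescriptorTable:
    """Structural-count descriptors plus independent-noise decoy columns."""
    names = ["hetero_no_count", "aromatic_count", "ring_count",
             "heavy_atom_count", "n_count", "o_count"]
    rows = [[structure_counts(g.smiles)[n] for n in names] for g in graphs]
    values = np.array(rows, dtype=np.float64)
    if n_decoys > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
        decoys = rng.normal(size=(len(graphs), n_decoys))
        values = np.concatenate([values, decoys], axis=1)
        names = names + [f"decoy_{i}" for i in range(n_decoys)]
    if labels is None:
        labels = np.array([np.nan if g.label is None else g.label
                           for g in graphs])
    return DescriptorTable(ids=[g.id or f"SYN{i:05d}"
                                for i, g in enumerate(graphs)],
                           names=names, values=values, labels=labels)


def write_compounds_csv(path, spec: SyntheticSpec) -> None:
    """Emit the standard ``id,smiles,pic50`` compounds CSV for a spec."""
    import pandas as pd

    graphs = make_dataset(spec)
    pd.DataFrame({"id": [g.id for g in graphs],
                  "smiles": [g.smiles for g in graphs],
                  "pic50": [g.label for g in graphs]}).to_csv(path, index=False)
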
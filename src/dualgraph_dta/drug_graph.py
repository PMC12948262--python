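"""Molecular graph construction from SMILES.

Atoms become nodes carrying provider-supplied embeddings (512-D for the
reference provider); every covalent bond becomes two directed edges carrying
a 6-D one-hot-style feature vector::

    [single, double, triple, aromatic, is_conjugated, pi_flag]

The first four bits encode the bond type (exactly one set), bit five marks
conjugation, and bit six is set when both endpoint atoms are sp2- or
sp-hybridised, i.e. the bond sits in a pi-capable environment. Hydrogens are
implicit throughout: node counts refer to heavy atoms in RDKit's canonical
atom order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from rdkit import Chem
from rdkit.Chem import DataStructs, rdFingerprintGenerator

logger = logging.getLogger(__name__)

BOND_FEATURE_DIM = 6
DEFAULT_ATOM_DIM = 512

_PI_HYBRIDISATIONS = (Chem.HybridizationType.SP, Chem.HybridizationType.SP2)


@runtime_checkable
class AtomEmbeddingProvider(Protocol):
    """Contract for per-atom embedding sources.

    ``embed`` must be deterministic and return one row per heavy atom of the
    canonicalised molecule, aligned to RDKit atom indices.
    """

    name: str
    dim: int

    def embed(self, smiles: str) -> np.ndarray:  # pragma: no cover - protocol
        ...


@dataclass
class MolecularGraph:
    """Directed molecular graph over heavy atoms.

    ``edge_index`` has shape (E, 2) with rows (src, dst); each undirected
    bond contributes both orientations with identical ``edge_features``.
    """

    smiles: str
    num_nodes: int
    node_features: np.ndarray  # (N, D)
    edge_index: np.ndarray  # (E, 2) int
    edge_features: np.ndarray  # (E, 6) {0,1}

    def __post_init__(self) -> None:
        if self.node_features.shape[0] != self.num_nodes:
            raise ValueError("node_features row count must equal num_nodes")
        if len(self.edge_index) != len(self.edge_features):
            raise ValueError("edge_index / edge_features length mismatch")


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    if mol.GetNumHeavyAtoms() < 1:
        raise ValueError(f"SMILES has no heavy atoms: {smiles!r}")
    return mol


def encode_bond_features(bond: Chem.Bond) -> np.ndarray:
    """6-D bond feature: one-hot bond type, conjugation, pi-environment flag."""
    vec = np.zeros(BOND_FEATURE_DIM, dtype=np.float64)
    order = bond.GetBondType()
    if order == Chem.BondType.SINGLE:
        vec[0] = 1
    elif order == Chem.BondType.DOUBLE:
        vec[1] = 1
    elif order == Chem.BondType.TRIPLE:
        vec[2] = 1
    elif order == Chem.BondType.AROMATIC:
        vec[3] = 1
    else:
        # exotic orders (dative, quadruple, ...) map to the nearest of the
        # four canonical types by bond order
        warnings.warn(f"unusual bond type {order}; mapping to nearest canonical type")
        approx = bond.GetBondTypeAsDouble()
        idx = int(np.clip(round(approx), 1, 3)) - 1
        vec[idx] = 1
    if bond.GetIsConjugated():
        vec[4] = 1
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()
    if a.GetHybridization() in _PI_HYBRIDISATIONS and b.GetHybridization() in _PI_HYBRIDISATIONS:
        vec[5] = 1
    return vec


def build_molecular_graph(smiles: str, provider: AtomEmbeddingProvider) -> MolecularGraph:
    """Build the directed heavy-atom graph for ``smiles``.

    Node features come from ``provider.embed`` and must have one row per
    heavy atom; a mismatch raises ``ValueError`` (provider error).
    """
    mol = _mol_from_smiles(smiles)
    n = mol.GetNumHeavyAtoms()
    feats = np.asarray(provider.embed(smiles), dtype=np.float64)
    if feats.shape != (n, provider.dim):
        raise ValueError(
            f"provider {provider.name!r} returned shape {feats.shape}, "
            f"expected {(n, provider.dim)}"
        )
    src, dst, efeat = [], [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = encode_bond_features(bond)
        src.extend((i, j))
        dst.extend((j, i))
        efeat.extend((f, f))
    edge_index = (
        np.array(list(zip(src, dst)), dtype=np.intp) if src else np.zeros((0, 2), dtype=np.intp)
    )
    edge_features = (
        np.array(efeat, dtype=np.float64) if efeat else np.zeros((0, BOND_FEATURE_DIM))
    )
    return MolecularGraph(
        smiles=smiles,
        num_nodes=n,
        node_features=feats,
        edge_index=edge_index,
        edge_features=edge_features,
    )


def read_smiles_file(path) -> list[str]:
    """One SMILES per line; blank lines and '#' comments skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split()[0] if line.split() else ""
            if line and not line.startswith("#"):
                out.append(line)
    return out


def read_sdf(path) -> list[str]:
    """SMILES of every parseable molecule in an SDF file (in file order)."""
    smiles = []
    n_bad = 0
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None:
            n_bad += 1
            continue
        smiles.append(Chem.MolToSmiles(mol))
    if n_bad:
        logger.warning("skipped %d unparseable SDF entries", n_bad)
    return smiles


def tanimoto_ecfp4(smiles_a: str, smiles_b: str, n_bits: int = 2048) -> float:
    """Tanimoto similarity of 2048-bit ECFP4 (Morgan radius-2) fingerprints.

    Low values against a reference compound indicate scaffold novelty.
    """
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    fps = [gen.GetFingerprint(_mol_from_smiles(s)) for s in (smiles_a, smiles_b)]
    return float(DataStructs.TanimotoSimilarity(fps[0], fps[1]))


__all__ = [
    "AtomEmbeddingProvider",
    "MolecularGraph",
    "BOND_FEATURE_DIM",
    "DEFAULT_ATOM_DIM",
    "encode_bond_features",
    "build_molecular_graph",
    "read_smiles_file",
    "read_sdf",
    "tanimoto_ecfp4",
]
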
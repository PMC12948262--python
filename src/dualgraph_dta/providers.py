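"""Embedding providers backed by precomputed sidecar files.

Real pretrained embedders are heavyweight, so their outputs can be exported
once and injected here: a sidecar is an ``.npz`` archive mapping the exact
input string (SMILES for atoms, sequence for residues) to its embedding
matrix, row-aligned with the canonical atom order / residue order. The
providers satisfy the same contract as the mock embedders and validate row
counts on every lookup.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
from rdkit import Chem


def write_embedding_sidecar(embeddings: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Save a {input-string: matrix} mapping as an .npz sidecar."""
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in embeddings.items()}
    dims = {a.shape[1] for a in arrays.values()}
    if len(dims) > 1:
        raise ValueError(f"inconsistent embedding dims in sidecar: {sorted(dims)}")
    np.savez(path, **arrays)


class _SidecarBase:
    def __init__(self, path: str | Path, name: str):
        self.name = name
        self._data = np.load(path)
        keys = list(self._data.files)
        if not keys:
            raise ValueError(f"sidecar {path} is empty")
        self.dim = int(self._data[keys[0]].shape[1])

    def _lookup(self, key: str) -> np.ndarray:
        if key not in self._data.files:
            raise KeyError(f"{self.name}: no embedding stored for {key!r}")
        return np.asarray(self._data[key], dtype=np.float64)


class SidecarAtomProvider(_SidecarBase):
    """Atom embeddings looked up by SMILES from a precomputed sidecar."""

    def __init__(self, path: str | Path):
        super().__init__(path, "sidecar-atom")

    def embed(self, smiles: str) -> np.ndarray:
        mat = self._lookup(smiles)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"invalid SMILES {smiles!r}")
        if mat.shape[0] != mol.GetNumHeavyAtoms():
            raise ValueError(
                f"sidecar rows ({mat.shape[0]}) != heavy atoms "
                f"({mol.GetNumHeavyAtoms()}) for {smiles!r}"
            )
        return mat


class SidecarResidueProvider(_SidecarBase):
    """Residue embeddings looked up by sequence from a precomputed sidecar."""

    def __init__(self, path: str | Path):
        super().__init__(path, "sidecar-residue")

    def embed(self, sequence: str) -> np.ndarray:
        mat = self._lookup(sequence)
        if mat.shape[0] != len(sequence):
            raise ValueError(
                f"sidecar rows ({mat.shape[0]}) != sequence length ({len(sequence)})"
            )
        return mat


__all__ = [
    "write_embedding_sidecar",
    "SidecarAtomProvider",
    "SidecarResidueProvider",
]
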
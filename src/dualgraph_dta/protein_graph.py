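"""Residue-level protein contact graphs.

Residues are nodes; an edge connects residues i != j whenever the Euclidean
distance between their Calpha atoms is at most the cutoff (8 A inclusive by
default). Each edge carries weight 1/d in inverse Angstrom, which downstream
attention layers consume as a 1-D edge feature so that spatially close
residues are prioritised. Node features come from a residue-embedding
provider (2560-D for the reference provider).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
from scipy.spatial.distance import squareform, pdist

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 8.0  # Angstrom, inclusive
DEFAULT_RESIDUE_DIM = 2560
DEFAULT_MAX_LENGTH = 1022  # common single-pass limit of residue embedders


@runtime_checkable
class ResidueEmbeddingProvider(Protocol):
    name: str
    dim: int

    def embed(self, sequence: str) -> np.ndarray:  # pragma: no cover - protocol
        ...


@runtime_checkable
class StructureProvider(Protocol):
    """Source of Calpha coordinates for a sequence (PDB, predictor, synthetic)."""

    name: str

    def coords_for(self, sequence: str) -> np.ndarray:  # pragma: no cover - protocol
        ...


@dataclass
class ProteinGraph:
    sequence: str
    num_nodes: int
    coords: np.ndarray  # (M, 3) Angstrom
    node_features: np.ndarray  # (M, D)
    edge_index: np.ndarray  # (E, 2) int, both directions present
    edge_weights: np.ndarray  # (E,) inverse distance, 1/A


def compute_distance_matrix(coords: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean Calpha distance matrix (symmetric, zero diagonal)."""
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be an (M, 3) array")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords contain non-finite values")
    if coords.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(coords))


def truncate_center(sequence: str, coords: np.ndarray, max_length: int) -> tuple[str, np.ndarray]:
    """Center-truncate overlong chains, keeping the middle ``max_length`` residues."""
    m = len(sequence)
    if m <= max_length:
        return sequence, coords
    start = (m - max_length) // 2
    logger.warning("sequence of length %d center-truncated to %d residues", m, max_length)
    return sequence[start : start + max_length], coords[start : start + max_length]


def build_protein_graph(
    sequence: str,
    coords: np.ndarray,
    provider: ResidueEmbeddingProvider,
    cutoff: float = DEFAULT_CUTOFF,
    max_length: int = DEFAULT_MAX_LENGTH,
) -> ProteinGraph:
    """Contact graph with inverse-distance edge weights.

    Raises ``ValueError`` if ``len(sequence)`` does not match the number of
    coordinate rows. Residues with no neighbour within the cutoff are kept
    as isolated nodes.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if len(sequence) != coords.shape[0]:
        raise ValueError(
            f"sequence length {len(sequence)} != coordinate rows {coords.shape[0]}"
        )
    sequence, coords = truncate_center(sequence, coords, max_length)
    m = len(sequence)
    feats = np.asarray(provider.embed(sequence), dtype=np.float64)
    if feats.shape != (m, provider.dim):
        raise ValueError(
            f"provider {provider.name!r} returned shape {feats.shape}, expected {(m, provider.dim)}"
        )
    dist = compute_distance_matrix(coords)
    ii, jj = np.nonzero((dist <= cutoff) & ~np.eye(m, dtype=bool))
    edge_index = np.stack([ii, jj], axis=1).astype(np.intp)
    edge_weights = 1.0 / dist[ii, jj] if len(ii) else np.zeros(0)
    return ProteinGraph(
        sequence=sequence,
        num_nodes=m,
        coords=coords,
        node_features=feats,
        edge_index=edge_index,
        edge_weights=edge_weights,
    )


def save_protein_graph(graph: ProteinGraph, path) -> None:
    """Cache a protein graph as an .npz bundle (arrays + sequence)."""
    np.savez(
        path,
        sequence=np.array(graph.sequence),
        coords=graph.coords,
        node_features=graph.node_features,
        edge_index=graph.edge_index,
        edge_weights=graph.edge_weights,
    )


def load_protein_graph(path) -> ProteinGraph:
    data = np.load(path, allow_pickle=False)
    sequence = str(data["sequence"])
    return ProteinGraph(
        sequence=sequence,
        num_nodes=len(sequence),
        coords=data["coords"],
        node_features=data["node_features"],
        edge_index=data["edge_index"].astype(np.intp),
        edge_weights=data["edge_weights"],
    )


__all__ = [
    "ProteinGraph",
    "ResidueEmbeddingProvider",
    "StructureProvider",
    "DEFAULT_CUTOFF",
    "DEFAULT_RESIDUE_DIM",
    "compute_distance_matrix",
    "build_protein_graph",
    "save_protein_graph",
    "load_protein_graph",
    "truncate_center",
]
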
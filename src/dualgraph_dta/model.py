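"""End-to-end model assembly and pair-dataset featurisation.

A ``DualGraphModel`` couples (optionally) a molecular-graph encoder and a
protein-graph encoder with the multimodal fusion head. Ablation variants are
expressed purely through the config:

* ``wo_MG`` / ``wo_PG`` / ``wo_MG_PG`` -- bypass the GNN on that side and use
  the column-mean of the provider's node embeddings as the graph-level
  vector (the sequence-level feature of the upstream embedder).
* ``wo_AM`` -- GCN layers (no attention) instead of GATv2.
* ``wo_DAM`` -- static-attention GAT layers instead of GATv2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .autodiff import Tensor, as_tensor, gather_rows
from .data_io import AffinityRecord
from .drug_graph import (
    AtomEmbeddingProvider,
    BOND_FEATURE_DIM,
    MolecularGraph,
    build_molecular_graph,
)
from .fusion_head import FusionConfig, FusionHead
from .gnn_core import GraphEncoder, GraphEncoderConfig
from .protein_graph import (
    DEFAULT_CUTOFF,
    ProteinGraph,
    ResidueEmbeddingProvider,
    StructureProvider,
    build_protein_graph,
)

ABLATION_VARIANTS = ("full", "wo_MG", "wo_PG", "wo_MG_PG", "wo_AM", "wo_DAM")


@dataclass
class ModelConfig:
    """Structural configuration of the full architecture."""

    drug_dim: int = 512
    prot_dim: int = 2560
    drug_hidden: int = 512
    prot_hidden: int = 2560
    gnn_heads: int = 4
    gnn_variant: str = "gatv2"
    score_mode: str = "gatv2_canonical"
    activation: str = "elu"
    dropout: float = 0.0
    use_drug_graph: bool = True
    use_prot_graph: bool = True
    d_model: int = 384
    fusion_heads: int = 8
    fcl_dims: tuple[int, int] = (1280, 320)
    head_mode: str = "regression"

    @classmethod
    def reference(cls) -> "ModelConfig":
        """Reference widths: 512-D atoms, 2560-D residues, 3072-D fusion."""
        return cls()

    @classmethod
    def reduced(cls, drug_dim: int = 16, prot_dim: int = 32) -> "ModelConfig":
        """Small widths for CPU-scale experiments and tests."""
        return cls(
            drug_dim=drug_dim,
            prot_dim=prot_dim,
            drug_hidden=16,
            prot_hidden=16,
            gnn_heads=2,
            d_model=16,
            fusion_heads=8,
            fcl_dims=(32, 16),
        )

    def for_variant(self, variant: str) -> "ModelConfig":
        if variant not in ABLATION_VARIANTS:
            raise ValueError(f"unknown ablation variant {variant!r}")
        if variant == "full":
            return replace(self)
        if variant == "wo_MG":
            return replace(self, use_drug_graph=False)
        if variant == "wo_PG":
            return replace(self, use_prot_graph=False)
        if variant == "wo_MG_PG":
            return replace(self, use_drug_graph=False, use_prot_graph=False)
        if variant == "wo_AM":
            return replace(self, gnn_variant="gcn")
        return replace(self, gnn_variant="gat")  # wo_DAM


# ---------------------------------------------------------------------------
# featurised dataset
# ---------------------------------------------------------------------------

@dataclass
class _GraphBatch:
    """Disjoint union of a list of graphs, precomputed once."""

    node_features: np.ndarray
    edge_index: np.ndarray
    edge_feats: np.ndarray | None
    graph_ids: np.ndarray
    n_graphs: int
    means: np.ndarray  # per-graph column mean of raw node features

    @classmethod
    def from_graphs(cls, graphs: Sequence, edge_feature_attr: str) -> "_GraphBatch":
        feats, edges, efeats, gids = [], [], [], []
        offset = 0
        for g, graph in enumerate(graphs):
            nf = np.asarray(graph.node_features, dtype=np.float64)
            feats.append(nf)
            ei = np.asarray(graph.edge_index, dtype=np.intp).reshape(-1, 2)
            edges.append(ei + offset)
            ef = getattr(graph, edge_feature_attr, None)
            if ef is not None:
                efeats.append(np.asarray(ef, dtype=np.float64).reshape(len(ei), -1))
            gids.append(np.full(graph.num_nodes, g, dtype=np.intp))
            offset += graph.num_nodes
        return cls(
            node_features=np.concatenate(feats),
            edge_index=np.concatenate(edges) if edges else np.zeros((0, 2), dtype=np.intp),
            edge_feats=np.concatenate(efeats) if efeats else None,
            graph_ids=np.concatenate(gids),
            n_graphs=len(graphs),
            means=np.stack([np.asarray(g.node_features).mean(axis=0) for g in graphs]),
        )


@dataclass
class PairDataset:
    """Featurised drug-protein pairs with labels.

    ``drug_index`` / ``protein_index`` map each pair to its unique graph, so
    each distinct molecule/protein is encoded once per forward pass.
    """

    drug_graphs: list[MolecularGraph]
    protein_graphs: list[ProteinGraph]
    drug_index: np.ndarray
    protein_index: np.ndarray
    labels: np.ndarray
    records: list[AffinityRecord] | None = None
    _drug_batch: _GraphBatch | None = field(default=None, repr=False)
    _prot_batch: _GraphBatch | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def drug_batch(self) -> _GraphBatch:
        if self._drug_batch is None:
            self._drug_batch = _GraphBatch.from_graphs(self.drug_graphs, "edge_features")
        return self._drug_batch

    @property
    def prot_batch(self) -> _GraphBatch:
        if self._prot_batch is None:
            graphs = []
            for g in self.protein_graphs:
                graphs.append(g)
            batch = _GraphBatch.from_graphs(graphs, "edge_weights")
            if batch.edge_feats is not None:
                batch.edge_feats = batch.edge_feats.reshape(-1, 1)
            self._prot_batch = batch
        return self._prot_batch

    def with_labels(self, labels: np.ndarray) -> "PairDataset":
        ds = PairDataset(
            drug_graphs=self.drug_graphs,
            protein_graphs=self.protein_graphs,
            drug_index=self.drug_index,
            protein_index=self.protein_index,
            labels=np.asarray(labels, dtype=np.float64),
            records=self.records,
        )
        ds._drug_batch = self._drug_batch
        ds._prot_batch = self._prot_batch
        return ds


def featurize_records(
    records: Sequence[AffinityRecord],
    atom_provider: AtomEmbeddingProvider,
    residue_provider: ResidueEmbeddingProvider,
    structure_provider: StructureProvider,
    cutoff: float = DEFAULT_CUTOFF,
) -> PairDataset:
    """Build the featurised pair dataset for a list of affinity records."""
    drug_ids: dict[str, int] = {}
    prot_ids: dict[str, int] = {}
    drug_graphs: list[MolecularGraph] = []
    protein_graphs: list[ProteinGraph] = []
    di, pi = [], []
    for rec in records:
        if rec.drug_smiles not in drug_ids:
            drug_ids[rec.drug_smiles] = len(drug_graphs)
            drug_graphs.append(build_molecular_graph(rec.drug_smiles, atom_provider))
        if rec.protein_sequence not in prot_ids:
            prot_ids[rec.protein_sequence] = len(protein_graphs)
            coords = structure_provider.coords_for(rec.protein_sequence)
            protein_graphs.append(
                build_protein_graph(rec.protein_sequence, coords, residue_provider, cutoff)
            )
        di.append(drug_ids[rec.drug_smiles])
        pi.append(prot_ids[rec.protein_sequence])
    return PairDataset(
        drug_graphs=drug_graphs,
        protein_graphs=protein_graphs,
        drug_index=np.asarray(di, dtype=np.intp),
        protein_index=np.asarray(pi, dtype=np.intp),
        labels=np.asarray([r.label_value for r in records], dtype=np.float64),
        records=list(records),
    )


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

class DualGraphModel:
    """Dual graph encoders + fusion head, assembled from a ModelConfig."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        # regression targets are standardised during training; predictions
        # are mapped back to label units here
        self.label_mean = 0.0
        self.label_sd = 1.0
        enc_cfg = dict(
            n_layers=3,
            n_heads=config.gnn_heads,
            variant=config.gnn_variant,
            score_mode=config.score_mode,
            activation=config.activation,
            dropout=config.dropout,
        )
        self.drug_encoder = (
            GraphEncoder(
                config.drug_dim, BOND_FEATURE_DIM,
                GraphEncoderConfig(hidden_dim=config.drug_hidden, **enc_cfg), rng,
            )
            if config.use_drug_graph
            else None
        )
        self.prot_encoder = (
            GraphEncoder(
                config.prot_dim, 1,
                GraphEncoderConfig(hidden_dim=config.prot_hidden, **enc_cfg), rng,
            )
            if config.use_prot_graph
            else None
        )
        drug_out = self.drug_encoder.out_dim if self.drug_encoder else config.drug_dim
        prot_out = self.prot_encoder.out_dim if self.prot_encoder else config.prot_dim
        self.fusion = FusionHead(
            FusionConfig(
                drug_dim=drug_out,
                prot_dim=prot_out,
                d_model=config.d_model,
                n_heads=config.fusion_heads,
                fcl_dims=config.fcl_dims,
                head_mode=config.head_mode,
            ),
            rng,
        )

    @property
    def n_graph_layers(self) -> int:
        n = 0
        for enc in (self.drug_encoder, self.prot_encoder):
            if enc is not None:
                n += len(enc.layers)
        return n

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for enc in (self.drug_encoder, self.prot_encoder):
            if enc is not None:
                ps.extend(enc.parameters())
        ps.extend(self.fusion.parameters())
        return ps

    def _side_vectors(self, batch: _GraphBatch, encoder: GraphEncoder | None,
                      training: bool, rng: np.random.Generator | None) -> Tensor:
        if encoder is None:
            return as_tensor(batch.means)
        return encoder.encode_batch(
            batch.node_features, batch.edge_index, batch.edge_feats,
            batch.graph_ids, batch.n_graphs, rng=rng, training=training,
        )

    def forward(
        self,
        dataset: PairDataset,
        pair_idx: np.ndarray | None = None,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Predictions for the given pairs (all pairs when ``pair_idx`` is None)."""
        if pair_idx is None:
            pair_idx = np.arange(len(dataset))
        pair_idx = np.asarray(pair_idx, dtype=np.intp)
        drug_enc = self._side_vectors(dataset.drug_batch, self.drug_encoder, training, rng)
        prot_enc = self._side_vectors(dataset.prot_batch, self.prot_encoder, training, rng)
        dvec = gather_rows(drug_enc, dataset.drug_index[pair_idx])
        pvec = gather_rows(prot_enc, dataset.protein_index[pair_idx])
        return self.fusion.forward(dvec, pvec, training=training)

    def predict(self, dataset: PairDataset, pair_idx: np.ndarray | None = None) -> np.ndarray:
        out = self.forward(dataset, pair_idx, training=False).data
        if self.config.head_mode == "regression":
            return self.label_mean + self.label_sd * out
        return out


def save_checkpoint(model: DualGraphModel, path) -> None:
    """Serialise a trained model as an .npz tensor bundle.

    The bundle holds the flat parameter list in construction order, the
    batch-norm running statistics, the label standardisation and the JSON
    model config, which is enough to rebuild the model exactly.
    """
    import dataclasses
    import json

    arrays = {f"param_{i:04d}": p.data for i, p in enumerate(model.parameters())}
    for name, bn in (("bn1", model.fusion.bn1), ("bn2", model.fusion.bn2)):
        arrays[f"{name}_running_mean"] = bn.running_mean
        arrays[f"{name}_running_var"] = bn.running_var
    arrays["label_stats"] = np.array([model.label_mean, model.label_sd])
    arrays["config_json"] = np.array(json.dumps(dataclasses.asdict(model.config)))
    np.savez(path, **arrays)


def load_checkpoint(path) -> DualGraphModel:
    import json

    data = np.load(path, allow_pickle=False)
    cfg_dict = json.loads(str(data["config_json"]))
    cfg_dict["fcl_dims"] = tuple(cfg_dict["fcl_dims"])
    model = DualGraphModel(ModelConfig(**cfg_dict), np.random.default_rng(0))
    for i, p in enumerate(model.parameters()):
        stored = data[f"param_{i:04d}"]
        if stored.shape != p.data.shape:
            raise ValueError(f"checkpoint shape mismatch at parameter {i}")
        p.data = stored.copy()
    for name, bn in (("bn1", model.fusion.bn1), ("bn2", model.fusion.bn2)):
        bn.running_mean = data[f"{name}_running_mean"].copy()
        bn.running_var = data[f"{name}_running_var"].copy()
    model.label_mean, model.label_sd = (float(v) for v in data["label_stats"])
    return model


__all__ = [
    "ABLATION_VARIANTS",
    "ModelConfig",
    "PairDataset",
    "DualGraphModel",
    "featurize_records",
    "save_checkpoint",
    "load_checkpoint",
]
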
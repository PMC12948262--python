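"""Multimodal fusion and prediction head.

The drug and protein graph-level vectors are treated as a two-token
sequence: each modality is projected to a shared model width, 8-head scaled
dot-product self-attention mixes the two tokens, the attended tokens are
projected back to their native widths, added residually to the inputs, and
concatenated. At the reference widths (512-D drug, 2560-D protein) the
fused vector is 3072-D. Prediction then runs through fully connected layers
3072 -> 1280 -> 320 -> 1 with batch normalisation and ReLU after the first
two, and a linear (regression) or sigmoid (classification) output.

Attention over a single concatenated vector would be degenerate (softmax of
one element); the two-token scheme is the non-degenerate reading and can be
bypassed (``use_attention=False``) to recover a plain concatenation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .autodiff import Tensor, as_tensor, concat, glorot, parameter

REFERENCE_FUSED_DIM = 3072
REFERENCE_FCL_DIMS = (1280, 320)
DEFAULT_D_MODEL = 384
DEFAULT_N_HEADS = 8


@dataclass
class FusionConfig:
    drug_dim: int = 512
    prot_dim: int = 2560
    d_model: int = DEFAULT_D_MODEL
    n_heads: int = DEFAULT_N_HEADS
    fcl_dims: tuple[int, int] = REFERENCE_FCL_DIMS
    head_mode: str = "regression"  # or "classification"
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1
    use_attention: bool = True

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.head_mode not in ("regression", "classification"):
            raise ValueError("head_mode must be regression or classification")
        if self.bn_eps <= 0:
            raise ValueError("bn_eps must be positive")

    @property
    def fused_dim(self) -> int:
        return self.drug_dim + self.prot_dim


def batch_norm(
    x_batch: np.ndarray,
    gamma: np.ndarray,
    beta: np.ndarray,
    eps: float = 1e-5,
    running_mean: np.ndarray | None = None,
    running_var: np.ndarray | None = None,
) -> np.ndarray:
    """(x - mu_B) / sqrt(sigma_B^2 + eps) * gamma + beta.

    Batch statistics are used unless both running statistics are given
    (inference mode). Training-mode normalisation of a single-row batch is
    refused: the batch variance is degenerate.
    """
    x = np.asarray(x_batch, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("x_batch must be 2-D (batch, features)")
    if running_mean is not None and running_var is not None:
        mu, var = np.asarray(running_mean), np.asarray(running_var)
    else:
        if x.shape[0] < 2:
            raise ValueError("training-mode batch norm needs a batch of at least 2")
        mu = x.mean(axis=0)
        var = x.var(axis=0)
    return (x - mu) / np.sqrt(var + eps) * np.asarray(gamma) + np.asarray(beta)


class BatchNorm:
    """Batch-norm layer with running statistics for inference."""

    def __init__(self, dim: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = parameter(np.ones(dim))
        self.beta = parameter(np.zeros(dim))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def forward(self, x: Tensor, training: bool) -> Tensor:
        if training:
            b = x.shape[0]
            if b < 2:
                raise ValueError("training-mode batch norm needs a batch of at least 2")
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            unbiased = var.data[0] * b / max(b - 1, 1)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu.data[0]
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            xhat = (x - as_tensor(self.running_mean)) / as_tensor(
                np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta


class FusionHead:
    """Two-token multi-head self-attention fusion plus the FCL stack."""

    def __init__(self, config: FusionConfig, rng: np.random.Generator):
        self.config = config
        c = config
        hd = c.d_model // c.n_heads
        self.head_dim = hd
        self.W_in_d = glorot(rng, (c.drug_dim, c.d_model))
        self.W_in_p = glorot(rng, (c.prot_dim, c.d_model))
        self.heads = [
            {
                "Wq": glorot(rng, (c.d_model, hd)),
                "Wk": glorot(rng, (c.d_model, hd)),
                "Wv": glorot(rng, (c.d_model, hd)),
            }
            for _ in range(c.n_heads)
        ]
        self.W_o = glorot(rng, (c.d_model, c.d_model))
        self.W_out_d = glorot(rng, (c.d_model, c.drug_dim))
        self.W_out_p = glorot(rng, (c.d_model, c.prot_dim))
        d1, d2 = c.fcl_dims
        self.fc1_W = glorot(rng, (c.fused_dim, d1))
        self.fc1_b = parameter(np.zeros(d1))
        self.bn1 = BatchNorm(d1, c.bn_eps, c.bn_momentum)
        self.fc2_W = glorot(rng, (d1, d2))
        self.fc2_b = parameter(np.zeros(d2))
        self.bn2 = BatchNorm(d2, c.bn_eps, c.bn_momentum)
        self.fc3_W = glorot(rng, (d2, 1))
        self.fc3_b = parameter(np.zeros(1))

    def parameters(self) -> list[Tensor]:
        ps = [self.W_in_d, self.W_in_p, self.W_o, self.W_out_d, self.W_out_p,
              self.fc1_W, self.fc1_b, self.fc2_W, self.fc2_b, self.fc3_W, self.fc3_b]
        for h in self.heads:
            ps.extend(h.values())
        ps.extend(self.bn1.parameters())
        ps.extend(self.bn2.parameters())
        return ps

    # -- attention sub-layer -------------------------------------------
    def two_token_attention(self, t_drug: Tensor, t_prot: Tensor) -> tuple[Tensor, Tensor]:
        """Pre-residual attended tokens (each (B, d_model))."""
        outs_d, outs_p = [], []
        scale = 1.0 / np.sqrt(self.head_dim)
        for h in self.heads:
            qd, kd, vd = t_drug @ h["Wq"], t_drug @ h["Wk"], t_drug @ h["Wv"]
            qp, kp, vp = t_prot @ h["Wq"], t_prot @ h["Wk"], t_prot @ h["Wv"]
            for q, outs in ((qd, outs_d), (qp, outs_p)):
                s_d = (q * kd).sum(axis=1, keepdims=True) * scale
                s_p = (q * kp).sum(axis=1, keepdims=True) * scale
                shift = np.maximum(s_d.data, s_p.data)  # constant: softmax-invariant
                e_d = (s_d - as_tensor(shift)).exp()
                e_p = (s_p - as_tensor(shift)).exp()
                denom = e_d + e_p
                outs.append((e_d / denom) * vd + (e_p / denom) * vp)
        att_d = concat(outs_d, axis=1) @ self.W_o
        att_p = concat(outs_p, axis=1) @ self.W_o
        return att_d, att_p

    def fuse(self, drug_vec: Tensor, prot_vec: Tensor) -> Tensor:
        """Fused (B, drug_dim + prot_dim) representation."""
        if not self.config.use_attention:
            return concat([drug_vec, prot_vec], axis=1)
        t_d = drug_vec @ self.W_in_d
        t_p = prot_vec @ self.W_in_p
        att_d, att_p = self.two_token_attention(t_d, t_p)
        out_d = drug_vec + att_d @ self.W_out_d
        out_p = prot_vec + att_p @ self.W_out_p
        return concat([out_d, out_p], axis=1)

    def predict_from_fused(self, fused: Tensor, training: bool = False) -> Tensor:
        """FCL stack: fused -> d1 -> d2 -> 1, BN+ReLU after the first two."""
        if not np.all(np.isfinite(fused.data)):
            raise FloatingPointError("non-finite values in fused representation")
        x = self.bn1.forward(fused @ self.fc1_W + self.fc1_b, training).relu()
        x = self.bn2.forward(x @ self.fc2_W + self.fc2_b, training).relu()
        out = (x @ self.fc3_W + self.fc3_b).reshape(-1)
        if self.config.head_mode == "classification":
            out = out.sigmoid()
        return out

    def forward(self, drug_vec: Tensor, prot_vec: Tensor, training: bool = False) -> Tensor:
        return self.predict_from_fused(self.fuse(drug_vec, prot_vec), training)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def _as_batch(v: np.ndarray) -> tuple[np.ndarray, bool]:
    v = np.asarray(v, dtype=np.float64)
    return (v.reshape(1, -1), True) if v.ndim == 1 else (v, False)


def multi_head_fuse(drug_vec: np.ndarray, protein_vec: np.ndarray, head: FusionHead) -> np.ndarray:
    """Fused vector(s); a 1-D input pair yields a 1-D fused vector."""
    d, squeeze = _as_batch(drug_vec)
    p, _ = _as_batch(protein_vec)
    fused = head.fuse(as_tensor(d), as_tensor(p)).data
    return fused[0] if squeeze else fused


def predict(fused: np.ndarray, head: FusionHead, training: bool = False) -> np.ndarray | float:
    """Affinity (regression) or activity probability (classification)."""
    f, squeeze = _as_batch(fused)
    if f.shape[1] != head.config.fused_dim:
        raise ValueError(f"fused dim {f.shape[1]} != configured {head.config.fused_dim}")
    out = head.predict_from_fused(as_tensor(f), training=training).data
    return float(out[0]) if squeeze else out


__all__ = [
    "FusionConfig",
    "FusionHead",
    "BatchNorm",
    "batch_norm",
    "multi_head_fuse",
    "predict",
    "REFERENCE_FUSED_DIM",
    "REFERENCE_FCL_DIMS",
]
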
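"""Quadrant attention: hemispheric partition, per-quadrant multihead
scaled dot-product attention, and assembly of the n x n edge-score matrix S.

The connectome is split into the four hemispheric blocks LL/LR/RL/RR, each
block is scored by its own multihead attention, and the four score blocks are
concatenated back into the original layout. S then multiplies the connectome
elementwise before graph convolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor

__all__ = [
    "AttentionConfig",
    "QuadrantBlocks",
    "QUADRANTS",
    "partition_quadrants",
    "assemble_edge_scores",
    "apply_edge_scores",
    "scaled_dot_attention",
    "multihead_attention",
    "QuadrantAttention",
]

QUADRANTS = ("LL", "LR", "RL", "RR")


@dataclass(frozen=True)
class AttentionConfig:
    """Multihead attention hyperparameters.

    ``dk`` defaults to ``(n/2) // h`` (at least 1) when left unset.
    """

    h: int = 4
    dk: int | None = None
    quadrant_weight_sharing: bool = False
    clamp_nonnegative: bool = False
    # output projections start near zero so the initial edge scores are
    # unbiased and the trained S reflects learned importance only
    wo_init_scale: float = 0.02

    def __post_init__(self):
        if self.h < 1:
            raise ValueError(f"head count must be >= 1, got {self.h}")
        if self.dk is not None and self.dk < 1:
            raise ValueError(f"key dimension must be >= 1, got {self.dk}")
        if self.wo_init_scale <= 0:
            raise ValueError("wo_init_scale must be positive")

    def resolve_dk(self, half_n: int) -> int:
        if self.dk is not None:
            return self.dk
        return max(1, half_n // self.h)


@dataclass
class QuadrantBlocks:
    ll: np.ndarray
    lr: np.ndarray
    rl: np.ndarray
    rr: np.ndarray

    def as_tuple(self):
        return (self.ll, self.lr, self.rl, self.rr)


def partition_quadrants(X: np.ndarray) -> QuadrantBlocks:
    """Split an n x n matrix (batched or not) into its hemispheric quadrants."""
    X = np.asarray(X, dtype=float)
    n = X.shape[-1]
    if X.shape[-2] != n:
        raise ValueError(f"expected a square matrix, got shape {X.shape}")
    if n % 2 != 0:
        raise ValueError(f"region count must be even, got n={n}")
    half = n // 2
    return QuadrantBlocks(
        ll=X[..., :half, :half],
        lr=X[..., :half, half:],
        rl=X[..., half:, :half],
        rr=X[..., half:, half:],
    )


def assemble_edge_scores(blocks) -> np.ndarray:
    """Concatenate four (n/2) x (n/2) score blocks back into n x n layout."""
    if isinstance(blocks, QuadrantBlocks):
        ll, lr, rl, rr = blocks.as_tuple()
    else:
        ll, lr, rl, rr = blocks
    arrs = [np.asarray(b, dtype=float) for b in (ll, lr, rl, rr)]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError(f"block shape mismatch: {[a.shape for a in arrs]}")
    top = np.concatenate([arrs[0], arrs[1]], axis=-1)
    bottom = np.concatenate([arrs[2], arrs[3]], axis=-1)
    return np.concatenate([top, bottom], axis=-2)


def apply_edge_scores(X: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Elementwise product X * S."""
    X = np.asarray(X, dtype=float)
    S = np.asarray(S, dtype=float)
    if X.shape != S.shape:
        raise ValueError(f"shape mismatch: X {X.shape} vs S {S.shape}")
    return X * S


def scaled_dot_attention(Q, K, V):
    """softmax(Q K^T / sqrt(dk)) V with dk = key width."""
    Q = np.asarray(Q, dtype=float)
    K = np.asarray(K, dtype=float)
    V = np.asarray(V, dtype=float)
    dk = Q.shape[-1]
    if dk <= 0:
        raise ValueError("key dimension must be positive")
    if K.shape[-1] != dk or K.shape[-2] != Q.shape[-2] or V.shape[-2] != Q.shape[-2]:
        raise ValueError("Q, K, V row counts / key widths disagree")
    t = _attention_t(Tensor(Q), Tensor(K), Tensor(V), dk)
    return t.data


def _attention_t(Q: Tensor, K: Tensor, V: Tensor, dk: int) -> Tensor:
    logits = ag.matmul(Q, _swap_last(K)) * (1.0 / np.sqrt(dk))
    return ag.matmul(ag.softmax(logits), V)


def _swap_last(t: Tensor) -> Tensor:
    axes = list(range(t.ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    data = np.transpose(t.data, axes)
    out = Tensor(data)
    if t.requires_grad or t._parents:
        out.requires_grad = t.requires_grad
        out._parents = (t,)

        def backward(g):
            t._accumulate(np.transpose(g, axes))

        out._backward = backward
    return out


def init_head_weights(half_n: int, cfg: AttentionConfig, rng: np.random.Generator,
                      requires_grad: bool = True) -> dict:
    """Seeded uniform init scaled by 1/sqrt(fan-in)."""
    dk = cfg.resolve_dk(half_n)

    def u(rows, cols):
        scale = 1.0 / np.sqrt(rows)
        return Tensor(rng.uniform(-scale, scale, size=(rows, cols)),
                      requires_grad=requires_grad)

    weights = {
        "WQ": [u(half_n, dk) for _ in range(cfg.h)],
        "WK": [u(half_n, dk) for _ in range(cfg.h)],
        "WV": [u(half_n, dk) for _ in range(cfg.h)],
        "WO": u(cfg.h * dk, half_n),
    }
    weights["WO"].data *= cfg.wo_init_scale
    return weights


def _mha_t(Xpq: Tensor, w: dict, cfg: AttentionConfig) -> Tensor:
    half_n = Xpq.shape[-1]
    dk = cfg.resolve_dk(half_n)
    heads = []
    for j in range(cfg.h):
        Q = ag.matmul(Xpq, w["WQ"][j])
        K = ag.matmul(Xpq, w["WK"][j])
        V = ag.matmul(Xpq, w["WV"][j])
        heads.append(_attention_t(Q, K, V, dk))
    hcat = ag.concat(heads, axis=-1) if len(heads) > 1 else heads[0]
    if hcat.shape[-1] != w["WO"].shape[0]:
        raise ValueError(
            f"concatenated head width {hcat.shape[-1]} does not match "
            f"WO rows {w['WO'].shape[0]}"
        )
    return ag.matmul(hcat, w["WO"])


def multihead_attention(Xpq: np.ndarray, w: dict, cfg: AttentionConfig) -> np.ndarray:
    """MHA(Xpq) = Concat(head_1, ..., head_h) WO for one quadrant block.

    ``w`` holds per-head projections ``WQ``/``WK``/``WV`` (lists of (n/2) x dk
    arrays or Tensors) and the output matrix ``WO``.
    """
    Xpq = np.asarray(Xpq, dtype=float)
    wt = {
        "WQ": [t if isinstance(t, Tensor) else Tensor(t) for t in w["WQ"]],
        "WK": [t if isinstance(t, Tensor) else Tensor(t) for t in w["WK"]],
        "WV": [t if isinstance(t, Tensor) else Tensor(t) for t in w["WV"]],
        "WO": w["WO"] if isinstance(w["WO"], Tensor) else Tensor(w["WO"]),
    }
    out = _mha_t(Tensor(Xpq), wt, cfg)
    return out.data


class QuadrantAttention:
    """Learnable quadrant attention producing the edge-score matrix S.

    Each quadrant has its own head weights unless ``quadrant_weight_sharing``
    is set, in which case all four share one set.
    """

    def __init__(self, n: int, cfg: AttentionConfig, rng: np.random.Generator):
        if n % 2 != 0:
            raise ValueError(f"region count must be even, got n={n}")
        self.n = n
        self.cfg = cfg
        half = n // 2
        if cfg.quadrant_weight_sharing:
            shared = init_head_weights(half, cfg, rng)
            self.weights = {q: shared for q in QUADRANTS}
        else:
            self.weights = {q: init_head_weights(half, cfg, rng) for q in QUADRANTS}

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for q in QUADRANTS:
            w = self.weights[q]
            for t in (*w["WQ"], *w["WK"], *w["WV"], w["WO"]):
                if id(t) not in seen:
                    seen.add(id(t))
                    params.append(t)
        return params

    def forward(self, X: np.ndarray) -> Tensor:
        """Edge scores for a batch of connectomes, shape (B, n, n)."""
        X = np.asarray(X, dtype=float)
        blocks = partition_quadrants(X)
        scored = {}
        for q, xb in zip(QUADRANTS, blocks.as_tuple()):
            scored[q] = _mha_t(Tensor(xb), self.weights[q], self.cfg)
        top = ag.concat([scored["LL"], scored["LR"]], axis=-1)
        bottom = ag.concat([scored["RL"], scored["RR"]], axis=-1)
        S = ag.concat([top, bottom], axis=-2)
        if self.cfg.clamp_nonnegative:
            S = ag.relu(S)
        return S

    def edge_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-subject S as plain arrays (no gradient tracking)."""
        single = np.asarray(X).ndim == 2
        Xb = X[None] if single else X
        S = self.forward(Xb).data
        return S[0] if single else S
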
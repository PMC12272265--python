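"""The three parallel subnetworks and fusion head.

* score-weighted graph convolution with top-K pooling over the connectome,
* a 1D CNN over the trait vector,
* a 2D CNN over the trials x metrics behavior block,

whose embeddings are concatenated and passed through an MLP that outputs the
predicted age in days. Layer l = 1 of the GNN multiplies node features
elementwise by the edge scores S; deeper layers do not (delta-function gating).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .qam import AttentionConfig, QuadrantAttention

__all__ = [
    "FusionConfig",
    "AblationFlags",
    "CNNWeights",
    "gnn_layer",
    "topk_pool",
    "topk_indices",
    "cnn1d_forward",
    "cnn2d_forward",
    "fuse_predict",
    "AgeNetwork",
    "save_network",
    "load_network",
]

CHECKPOINT_SCHEMA = "connage-checkpoint-v1"


@dataclass(frozen=True)
class FusionConfig:
    """Architecture plan (layer counts, kernel sizes, and widths)."""

    topk_ratio: float = 0.5
    gnn_layers: int = 2
    conv1_channels: tuple[int, ...] = (8, 16)
    conv1_kernel: int = 2
    conv2_channels: tuple[int, ...] = (8, 16)
    conv2_kernel: int = 3
    embed_width: int = 32
    mlp_hidden: tuple[int, ...] = (64, 16)

    def __post_init__(self):
        if not (0 < self.topk_ratio <= 1):
            raise ValueError(f"topk_ratio must be in (0, 1], got {self.topk_ratio}")


@dataclass(frozen=True)
class AblationFlags:
    """Which subnetworks feed the fusion head."""

    use_qam: bool = True
    use_traits: bool = True
    use_behavior: bool = True


ABLATIONS = {
    "comp1": AblationFlags(use_qam=False, use_traits=False, use_behavior=False),
    "comp2": AblationFlags(use_qam=True, use_traits=False, use_behavior=False),
    "comp3": AblationFlags(use_qam=True, use_traits=False, use_behavior=True),
    "comp4": AblationFlags(use_qam=True, use_traits=True, use_behavior=False),
    "full": AblationFlags(use_qam=True, use_traits=True, use_behavior=True),
}


@dataclass
class CNNWeights:
    """Convolution stack plus optional linear readout, as plain arrays."""

    conv: list[tuple[np.ndarray, np.ndarray]]  # [(W (Cout,Cin,kh,kw), b (Cout,)), ...]
    linear: tuple[np.ndarray, np.ndarray] | None = None  # (W (fin,fout), b (fout,))


# ---------------------------------------------------------------------------
# functional operations (single-sample; the network runs the batched analogue)
# ---------------------------------------------------------------------------

def gnn_layer(
    H: np.ndarray,
    S: np.ndarray | None,
    level: int,
    W: np.ndarray,
    D: np.ndarray | None = None,
) -> np.ndarray:
    """One graph-convolution update.

    level 1: ReLU[(I + H*S) D W]; level > 1: ReLU[(I + H) D W]. When ``D`` is
    not supplied it is the inverse-degree diagonal of the layer's (weighted)
    adjacency, isolated nodes getting degree 1.
    """
    H = np.asarray(H, dtype=float)
    k = H.shape[0]
    A = H * np.asarray(S, dtype=float) if (level == 1 and S is not None) else H
    if D is None:
        # degree = total connection magnitude; near-isolated nodes get
        # degree 1 so the inverse never blows up (scores may be signed)
        deg = np.abs(A).sum(axis=1)
        deg = np.where(deg < 1e-8, 1.0, deg)
        D = np.diag(1.0 / deg)
    M = (np.eye(k) + A) @ np.asarray(D, dtype=float) @ np.asarray(W, dtype=float)
    return np.maximum(M, 0.0)


def topk_indices(node_scores: np.ndarray, ratio: float) -> np.ndarray:
    """Indices (ascending) of the ceil(ratio*n) highest-scoring nodes.

    Ties keep the lowest node index (stable sort on the negated scores).
    """
    scores = np.asarray(node_scores, dtype=float)
    if np.any(np.isnan(scores)):
        raise ValueError("node scores contain NaN")
    if not (0 < ratio <= 1):
        raise ValueError(f"ratio must be in (0, 1], got {ratio}")
    k = math.ceil(ratio * scores.shape[-1])
    order = np.argsort(-scores, axis=-1, kind="stable")
    kept = order[..., :k]
    return np.sort(kept, axis=-1)


def topk_pool(H: np.ndarray, node_scores: np.ndarray, ratio: float):
    """Keep the top-ratio nodes; returns (kept_indices, reduced features).

    For square feature matrices the induced submatrix is returned (node rows
    and the matching feature columns); otherwise only rows are selected.
    """
    H = np.asarray(H, dtype=float)
    idx = topk_indices(node_scores, ratio)
    if H.ndim == 2 and H.shape[0] == H.shape[1]:
        return idx, H[np.ix_(idx, idx)]
    return idx, H[idx]


def _check_unit_interval(x: np.ndarray, what: str):
    x = np.asarray(x, dtype=float)
    if x.size and (x.min() < 0 or x.max() > 1 + 1e-9):
        raise ValueError(f"{what} must lie in [0, 1]")
    return x


def _conv_stack_t(x: Tensor, conv_weights) -> Tensor:
    h = x
    for W, b in conv_weights:
        Wt = W if isinstance(W, Tensor) else Tensor(W)
        bt = b if isinstance(b, Tensor) else Tensor(b)
        h = ag.relu(ag.conv2d(h, Wt, bt))
    return h


def _embed_t(x: Tensor, conv_weights, linear) -> Tensor:
    h = _conv_stack_t(x, conv_weights)
    pooled = ag.tmean(ag.tmean(h, axis=3), axis=2)  # global average -> (B, C)
    if linear is None:
        return pooled
    W, b = linear
    Wt = W if isinstance(W, Tensor) else Tensor(W)
    bt = b if isinstance(b, Tensor) else Tensor(b)
    return ag.add(ag.matmul(pooled, Wt), bt)


def cnn1d_forward(t: np.ndarray, w: CNNWeights) -> np.ndarray:
    """Trait vector -> embedding via the 1D convolution stack."""
    t = _check_unit_interval(np.asarray(t, dtype=float).ravel(), "trait input")
    x = Tensor(t.reshape(1, 1, 1, -1))
    return _embed_t(x, w.conv, w.linear).data[0]


def cnn2d_forward(b: np.ndarray, w: CNNWeights) -> np.ndarray:
    """Behavior block (trials x metrics) -> embedding via the 2D stack."""
    b = _check_unit_interval(np.asarray(b, dtype=float), "behavior input")
    x = Tensor(b.reshape(1, 1, *b.shape))
    return _embed_t(x, w.conv, w.linear).data[0]


def fuse_predict(gnn_out, c1_out, c2_out, mlp: list, ablation: AblationFlags) -> float:
    """Concatenate the enabled embeddings and run the fully connected block."""
    parts = [np.asarray(gnn_out, dtype=float).ravel()]
    if ablation.use_traits:
        if c1_out is None:
            raise ValueError("trait embedding required but missing")
        parts.append(np.asarray(c1_out, dtype=float).ravel())
    if ablation.use_behavior:
        if c2_out is None:
            raise ValueError("behavior embedding required but missing")
        parts.append(np.asarray(c2_out, dtype=float).ravel())
    h = np.concatenate(parts)
    for i, (W, b) in enumerate(mlp):
        h = h @ np.asarray(W, dtype=float) + np.asarray(b, dtype=float)
        if i < len(mlp) - 1:
            h = np.maximum(h, 0.0)
    return float(h.ravel()[0])


# ---------------------------------------------------------------------------
# the trainable network
# ---------------------------------------------------------------------------

def _uniform(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = 1.0 / np.sqrt(max(1, fan_in))
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


class AgeNetwork:
    """Quadrant attention + GNN + CNNs + fusion MLP, trained end to end.

    Parameters are grouped by subnetwork (``qam``, ``gnn``, ``c1``, ``c2``,
    ``fc``) so the optimizer can apply the per-subnetwork learning rates.
    Predictions are internally computed on an age scale normalized by
    ``y_scale`` (training-set maximum age) and rescaled to days.
    """

    def __init__(
        self,
        n: int,
        trait_len: int,
        behavior_shape: tuple[int, int],
        attn_cfg: AttentionConfig | None = None,
        fusion_cfg: FusionConfig | None = None,
        ablation: AblationFlags | None = None,
        seed: int = 0,
        y_scale: float = 1.0,
        out_bias_init: float = 0.0,
    ):
        self.n = int(n)
        self.trait_len = int(trait_len)
        self.behavior_shape = tuple(int(v) for v in behavior_shape)
        self.attn_cfg = attn_cfg or AttentionConfig()
        self.fusion_cfg = fusion_cfg or FusionConfig()
        self.ablation = ablation or AblationFlags()
        self.seed = int(seed)
        self.y_scale = float(y_scale)
        self.out_bias_init = float(out_bias_init)
        rng = np.random.default_rng(self.seed)
        fc = self.fusion_cfg

        self.qam = QuadrantAttention(self.n, self.attn_cfg, rng) if self.ablation.use_qam else None

        # GNN stack: conv width tracks node count (node features are
        # connectome rows, so pooling trims rows and columns together)
        self.gnn_weights: list[Tensor] = []
        self.gnn_scoreproj: list[Tensor] = []
        k = self.n
        self._gnn_widths = []
        for _ in range(fc.gnn_layers):
            self.gnn_weights.append(_uniform(rng, (k, k), k))
            self.gnn_scoreproj.append(_uniform(rng, (k,), k))
            self._gnn_widths.append(k)
            k = math.ceil(fc.topk_ratio * k)
        self.gnn_out_width = k

        def conv_plan(channels, kh, kw):
            layers = []
            cin = 1
            for cout in channels:
                layers.append(
                    (
                        _uniform(rng, (cout, cin, kh, kw), cin * kh * kw),
                        Tensor(np.zeros(cout), requires_grad=True),
                    )
                )
                cin = cout
            return layers

        if self.ablation.use_traits:
            self.c1_conv = conv_plan(fc.conv1_channels, 1, fc.conv1_kernel)
            self.c1_linear = (
                _uniform(rng, (fc.conv1_channels[-1], fc.embed_width), fc.conv1_channels[-1]),
                Tensor(np.zeros(fc.embed_width), requires_grad=True),
            )
        else:
            self.c1_conv, self.c1_linear = [], None
        if self.ablation.use_behavior:
            self.c2_conv = conv_plan(fc.conv2_channels, fc.conv2_kernel, fc.conv2_kernel)
            self.c2_linear = (
                _uniform(rng, (fc.conv2_channels[-1], fc.embed_width), fc.conv2_channels[-1]),
                Tensor(np.zeros(fc.embed_width), requires_grad=True),
            )
        else:
            self.c2_conv, self.c2_linear = [], None

        concat_dim = self.gnn_out_width
        if self.ablation.use_traits:
            concat_dim += fc.embed_width
        if self.ablation.use_behavior:
            concat_dim += fc.embed_width
        self.concat_dim = concat_dim
        widths = [concat_dim, *fc.mlp_hidden, 1]
        self.mlp: list[tuple[Tensor, Tensor]] = []
        for i in range(len(widths) - 1):
            W = _uniform(rng, (widths[i], widths[i + 1]), widths[i])
            bias = np.zeros(widths[i + 1])
            if i == len(widths) - 2:
                bias[:] = self.out_bias_init
            self.mlp.append((W, Tensor(bias, requires_grad=True)))

    # -- parameters ------------------------------------------------------
    def parameter_groups(self) -> dict[str, list[Tensor]]:
        groups: dict[str, list[Tensor]] = {"qam": [], "gnn": [], "c1": [], "c2": [], "fc": []}
        if self.qam is not None:
            groups["qam"] = self.qam.parameters()
        groups["gnn"] = [*self.gnn_weights, *self.gnn_scoreproj]
        for W, b in self.c1_conv:
            groups["c1"] += [W, b]
        if self.c1_linear:
            groups["c1"] += list(self.c1_linear)
        for W, b in self.c2_conv:
            groups["c2"] += [W, b]
        if self.c2_linear:
            groups["c2"] += list(self.c2_linear)
        for W, b in self.mlp:
            groups["fc"] += [W, b]
        return groups

    def parameters(self) -> list[Tensor]:
        return [p for ps in self.parameter_groups().values() for p in ps]

    # -- forward ----------------------------------------------------------
    def forward(self, X: np.ndarray, traits: np.ndarray, behavior: np.ndarray):
        """Batched forward pass.

        Returns (yhat, S) where yhat is a Tensor of shape (B,) on the
        normalized age scale and S the (B, n, n) edge-score Tensor (None for
        ablations without the attention module).
        """
        X = np.asarray(X, dtype=float)
        B = X.shape[0]
        S = self.qam.forward(X) if self.qam is not None else None

        H: Tensor = Tensor(X)
        for level0, (W, p) in enumerate(zip(self.gnn_weights, self.gnn_scoreproj)):
            level = level0 + 1
            k = self._gnn_widths[level0]
            A = ag.mul(H, S) if (level == 1 and S is not None) else H
            # degree from connection magnitudes; guard near-isolated nodes so
            # the inverse stays bounded even when scores are tiny or signed
            deg = ag.tsum(ag.mul(A, Tensor(np.sign(A.data))), axis=2)  # (B, k)
            iso = (deg.data < 1e-8).astype(float)
            dinv = ag.reciprocal(ag.add(ag.mul(deg, Tensor(1.0 - iso)), Tensor(iso)))
            M = ag.add(Tensor(np.eye(k)), A)
            M = ag.mul(M, ag.reshape(dinv, (B, 1, k)))  # right-diagonal: scale columns
            H = ag.relu(ag.matmul(M, W))
            # top-K pooling with a learnable score projection, tanh gating
            pnorm = ag.sqrt(ag.tsum(ag.square(p)) + Tensor(1e-12))
            scores = ag.mul(
                ag.reshape(ag.matmul(H, ag.reshape(p, (k, 1))), (B, k)),
                ag.reciprocal(pnorm),
            )
            idx = topk_indices(scores.data, self.fusion_cfg.topk_ratio)
            H = ag.mul(
                ag.gather_nodes(H, idx),
                ag.reshape(ag.tanh(ag.gather_vec(scores, idx)), (B, idx.shape[1], 1)),
            )
        g_embed = ag.tmean(H, axis=1)  # (B, k_final)

        parts = [g_embed]
        if self.ablation.use_traits:
            t = _check_unit_interval(np.asarray(traits, dtype=float), "trait input")
            parts.append(_embed_t(Tensor(t.reshape(B, 1, 1, -1)), self.c1_conv, self.c1_linear))
        if self.ablation.use_behavior:
            bm = _check_unit_interval(np.asarray(behavior, dtype=float), "behavior input")
            parts.append(
                _embed_t(Tensor(bm.reshape(B, 1, *bm.shape[1:])), self.c2_conv, self.c2_linear)
            )
        h = ag.concat(parts, axis=1) if len(parts) > 1 else parts[0]
        for i, (W, b) in enumerate(self.mlp):
            h = ag.add(ag.matmul(h, W), b)
            if i < len(self.mlp) - 1:
                h = ag.relu(h)
        yhat = ag.reshape(h, (B,))
        return yhat, S

    def predict(self, X: np.ndarray, traits: np.ndarray, behavior: np.ndarray) -> np.ndarray:
        """Predicted ages in days."""
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.n:
            raise ValueError(
                f"connectome has {X.shape[-1]} regions but the model was trained with {self.n}"
            )
        yhat, _ = self.forward(X, traits, behavior)
        return yhat.data * self.y_scale

    def edge_scores(self, X: np.ndarray) -> np.ndarray | None:
        if self.qam is None:
            return None
        return self.qam.edge_scores(np.asarray(X, dtype=float))

    # -- serialization -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for group, params in self.parameter_groups().items():
            for i, p in enumerate(params):
                state[f"{group}/{i}"] = p.data
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for group, params in self.parameter_groups().items():
            for i, p in enumerate(params):
                key = f"{group}/{i}"
                if key not in state:
                    raise KeyError(f"checkpoint is missing parameter {key}")
                if state[key].shape != p.data.shape:
                    raise ValueError(f"shape mismatch for {key}")
                p.data = np.array(state[key], dtype=float)

    def config_dict(self) -> dict:
        return {
            "schema": CHECKPOINT_SCHEMA,
            "n": self.n,
            "trait_len": self.trait_len,
            "behavior_shape": list(self.behavior_shape),
            "attn_cfg": asdict(self.attn_cfg),
            "fusion_cfg": asdict(self.fusion_cfg),
            "ablation": asdict(self.ablation),
            "seed": self.seed,
            "y_scale": self.y_scale,
            "out_bias_init": self.out_bias_init,
        }


def save_network(net: AgeNetwork, path: str, extra: dict | None = None) -> str:
    """Single-archive checkpoint: weight arrays + JSON config."""
    if not path.endswith(".npz"):
        path += ".npz"
    cfg = net.config_dict()
    if extra:
        cfg["extra"] = extra
    arrays = {k.replace("/", "__"): v for k, v in net.state_dict().items()}
    np.savez(path, __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
             **arrays)
    return path


def load_network(path: str) -> AgeNetwork:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        if cfg.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unknown checkpoint schema: {cfg.get('schema')!r}")
        state = {
            k.replace("__", "/"): np.array(v)
            for k, v in data.items()
            if k != "__config__"
        }
    fusion_cfg = cfg["fusion_cfg"].copy()
    for key in ("conv1_channels", "conv2_channels", "mlp_hidden"):
        fusion_cfg[key] = tuple(fusion_cfg[key])
    net = AgeNetwork(
        n=cfg["n"],
        trait_len=cfg["trait_len"],
        behavior_shape=tuple(cfg["behavior_shape"]),
        attn_cfg=AttentionConfig(**cfg["attn_cfg"]),
        fusion_cfg=FusionConfig(**fusion_cfg),
        ablation=AblationFlags(**cfg["ablation"]),
        seed=cfg["seed"],
        y_scale=cfg["y_scale"],
        out_bias_init=cfg["out_bias_init"],
    )
    net.load_state_dict(state)
    return net
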
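"""Hybrid GCN-GAT-GCN node encoder over the heterogeneous network.

GCN layer (symmetrically normalized, self-looped):

    F^(l+1) = sigma( D^{-1/2} (I + H) D^{-1/2} F^(l) W^(l) )

GAT layer (multi-head, head-averaged): per head k the attention logit for
an ordered pair (i, j) of distinct neighbors is

    e_ij = LeakyReLU( a_k^T [W_k F_i || W_k F_j] ) + B_k * S_ij

with S_ij the H_DP edge weight and B_k one learnable scalar per head;
coefficients phi_ij are the softmax of e_ij over j in N(i) = {j != i :
H_ij > 0} (an isolated node attends to itself), and the new feature is
ReLU of the head-averaged sum of phi_ij W_k F_j.

Training minimizes the binary cross-entropy of a disposable scoring head
on the node embeddings plus an L2 penalty (lambda/2)||theta||^2 over all
learnable parameters; the head is dropped after training and the fused
pair representation Z = [x_drug || x_protein] is handed to the downstream
forest. The default head is the inner-product link decoder
p = sigmoid(s * <x_drug, x_protein> + b): a linear head on the
concatenation cannot express pair affinity (it decomposes into separate
drug and protein propensities), whereas the inner product aligns
interacting pairs in embedding space. The concatenation head remains
available as ``head="linear"``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .hetnet import HeteroNetwork

LayerPlan = tuple[str, ...]


@dataclass
class EncoderConfig:
    layer_plan: LayerPlan = ("gcn", "gat", "gcn")
    hidden_dims: tuple[int, ...] = (256, 128, 64)
    heads: int = 4
    leaky_slope: float = 0.2
    # full-graph gradient training: dropout off by default (L2 is the
    # regularizer); 800 epochs brings the deterministic optimizer near its
    # loss plateau at reference problem sizes
    dropout: float = 0.0
    lr: float = 1e-3
    epochs: int = 800
    l2_lambda: float = 5e-4
    seed: int = 0
    optimizer: str = "adam"  # "adam" or "sgd"
    head: str = "dot"  # training head: "dot" (inner product) or "linear" (concat)

    def __post_init__(self) -> None:
        plan = tuple(p.lower() for p in self.layer_plan)
        if any(p not in {"gcn", "gat"} for p in plan):
            raise ValueError(f"unknown layer kind in plan {plan}")
        if len(self.hidden_dims) != len(plan):
            raise ValueError("hidden_dims must have one entry per layer")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.heads < 1:
            raise ValueError("need at least one attention head")
        if self.head not in {"dot", "linear"}:
            raise ValueError(f"unknown training head {self.head!r}")
        self.layer_plan = plan
        self.hidden_dims = tuple(int(d) for d in self.hidden_dims)


@dataclass
class NodeEmbeddings:
    """Final node representations, split into drug and protein blocks."""

    drug_ids: list[str]
    protein_ids: list[str]
    X_D: np.ndarray
    X_P: np.ndarray

    def vector(self, entity_id: str) -> np.ndarray:
        if entity_id in self._d_index:
            return self.X_D[self._d_index[entity_id]]
        return self.X_P[self._p_index[entity_id]]

    def __post_init__(self) -> None:
        self._d_index = {d: i for i, d in enumerate(self.drug_ids)}
        self._p_index = {p: i for i, p in enumerate(self.protein_ids)}


class EncoderModel:
    """Layer weights of the GCN/GAT stack plus the training head."""

    def __init__(self, config: EncoderConfig, in_dim: int):
        self.config = config
        self.in_dim = in_dim
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(config.seed)
        dims = [in_dim, *config.hidden_dims]
        for l, kind in enumerate(config.layer_plan):
            d_in, d_out = dims[l], dims[l + 1]
            if kind == "gcn":
                self._add(f"gcn{l}_W", self._glorot(rng, d_in, d_out))
            else:
                for k in range(config.heads):
                    self._add(f"gat{l}_W{k}", self._glorot(rng, d_in, d_out))
                    self._add(f"gat{l}_a{k}", self._glorot(rng, 2 * d_out, 1)[:, 0])
                    self._add(f"gat{l}_B{k}", np.zeros(()))
        d_final = dims[-1]
        if config.head == "linear":
            self._add("head_wd", self._glorot(rng, d_final, 1)[:, 0])
            self._add("head_wp", self._glorot(rng, d_final, 1)[:, 0])
        else:
            self._add("head_s", np.ones(()))
        self._add("head_b", np.zeros(()))

    @staticmethod
    def _glorot(rng: np.random.Generator, d_in: int, d_out: int) -> np.ndarray:
        bound = np.sqrt(6.0 / (d_in + d_out))
        return rng.uniform(-bound, bound, size=(d_in, d_out))

    def _add(self, name: str, value: np.ndarray) -> None:
        self.params[name] = Tensor(value, requires_grad=True)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write all weights plus the config to a single .npz archive."""
        arrays = {name: t.data for name, t in self.params.items()}
        cfg = asdict(self.config)
        cfg["layer_plan"] = list(cfg["layer_plan"])
        cfg["hidden_dims"] = list(cfg["hidden_dims"])
        np.savez(path, __config__=np.array(repr(cfg)), __in_dim__=np.array(self.in_dim),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "EncoderModel":
        import ast

        with np.load(path, allow_pickle=False) as npz:
            cfg = ast.literal_eval(str(npz["__config__"]))
            cfg["layer_plan"] = tuple(cfg["layer_plan"])
            cfg["hidden_dims"] = tuple(cfg["hidden_dims"])
            model = cls(EncoderConfig(**cfg), int(npz["__in_dim__"]))
            for name in model.params:
                model.params[name] = Tensor(npz[name], requires_grad=True)
        return model


def normalized_adjacency(H: np.ndarray) -> np.ndarray:
    """D^{-1/2} (I + H) D^{-1/2} with D the degree matrix of I + H."""
    H_tilde = np.eye(H.shape[0]) + H
    d = H_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return H_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]


def gcn_layer(net: HeteroNetwork, F: Tensor | np.ndarray, W: Tensor | np.ndarray,
              activate: bool = True) -> Tensor:
    """One graph convolution over the self-looped normalized adjacency."""
    F = F if isinstance(F, Tensor) else Tensor(F)
    W = W if isinstance(W, Tensor) else Tensor(W)
    A_hat = Tensor(normalized_adjacency(net.H))
    out = A_hat @ F @ W
    return out.relu() if activate else out


def _attention_mask(H: np.ndarray) -> np.ndarray:
    """N(i) = off-diagonal neighbors with positive edge weight; isolated
    nodes fall back to attending to themselves."""
    mask = H > 0
    np.fill_diagonal(mask, False)
    isolated = ~mask.any(axis=1)
    if isolated.any():
        idx = np.where(isolated)[0]
        mask[idx, idx] = True
    return mask


def gat_layer(net: HeteroNetwork, F: Tensor | np.ndarray,
              heads: list[tuple[Tensor, Tensor, Tensor]], leaky_slope: float,
              activate: bool = True,
              return_attention: bool = False):
    """Multi-head graph attention; heads are (W_k, a_k, B_k) triples.

    Attention per head is a softmax over each node's neighborhood of
    LeakyReLU(a^T[Wf_i || Wf_j]) + B * H_ij; the head outputs are averaged
    (not concatenated) before the activation.
    """
    F = F if isinstance(F, Tensor) else Tensor(F)
    H = net.H
    mask = _attention_mask(H)
    S = Tensor(H)
    acc = None
    attn_sum = None
    for W_k, a_k, B_k in heads:
        U = F @ W_k                              # (N, d')
        d_out = U.shape[1]
        # split a_k into source/destination halves: a^T [u_i || u_j]
        src = U @ _slice_vec(a_k, 0, d_out)      # (N, 1)
        dst = U @ _slice_vec(a_k, d_out, 2 * d_out)
        logits = _outer_sum(src, dst).leaky_relu(leaky_slope) + B_k * S
        phi = logits.masked_softmax(mask)        # (N, N)
        head_out = phi @ U
        acc = head_out if acc is None else acc + head_out
        attn_sum = phi.data if attn_sum is None else attn_sum + phi.data
    out = acc * (1.0 / len(heads))
    out = out.relu() if activate else out
    if return_attention:
        return out, attn_sum / len(heads)
    return out


def _slice_vec(a: Tensor, lo: int, hi: int) -> Tensor:
    """Differentiable slice of a 1-D tensor into a column vector."""
    idx = np.arange(lo, hi)
    return a.gather_rows(idx).reshape_col()


def _outer_sum(col: Tensor, row: Tensor) -> Tensor:
    """col_i + row_j as an (N, N) tensor from two (N, 1) tensors."""
    return col + row.transpose2d()


# small helpers attached to Tensor for shapes used only here
def _reshape_col(self: Tensor) -> Tensor:
    n = self.data.shape[0]

    def bwd(g):
        if self.requires_grad:
            self._accum(g[:, 0])

    return Tensor._make(self.data.reshape(n, 1), (self,), bwd)


def _transpose2d(self: Tensor) -> Tensor:
    def bwd(g):
        if self.requires_grad:
            self._accum(g.T)

    return Tensor._make(self.data.T, (self,), bwd)


Tensor.reshape_col = _reshape_col
Tensor.transpose2d = _transpose2d


def _forward(net: HeteroNetwork, F0: np.ndarray, model: EncoderModel,
             dropout_rng: np.random.Generator | None = None) -> Tensor:
    cfg = model.config
    x: Tensor = Tensor(F0)
    for l, kind in enumerate(cfg.layer_plan):
        if kind == "gcn":
            x = gcn_layer(net, x, model.params[f"gcn{l}_W"], activate=True)
        else:
            heads = [
                (model.params[f"gat{l}_W{k}"], model.params[f"gat{l}_a{k}"],
                 model.params[f"gat{l}_B{k}"])
                for k in range(cfg.heads)
            ]
            x = gat_layer(net, x, heads, cfg.leaky_slope, activate=True)
        if dropout_rng is not None and cfg.dropout > 0.0:
            keep = (dropout_rng.random(x.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            x = x * Tensor(keep)
    return x


def encode(net: HeteroNetwork, F_DP: np.ndarray, model: EncoderModel) -> NodeEmbeddings:
    """Apply the layer plan and split the result into drug/protein blocks."""
    out = _forward(net, F_DP, model).data
    v = net.n_drugs
    return NodeEmbeddings(drug_ids=list(net.drug_ids), protein_ids=list(net.protein_ids),
                          X_D=out[:v].copy(), X_P=out[v:].copy())


def fuse(emb: NodeEmbeddings, pairs: list[tuple[str, str]]) -> np.ndarray:
    """Concatenate drug and protein embeddings into pair feature rows Z."""
    d = emb.X_D.shape[1]
    Z = np.empty((len(pairs), 2 * d))
    for r, (drug_id, protein_id) in enumerate(pairs):
        if drug_id not in emb._d_index:
            raise KeyError(f"unknown drug id {drug_id}")
        if protein_id not in emb._p_index:
            raise KeyError(f"unknown protein id {protein_id}")
        Z[r, :d] = emb.X_D[emb._d_index[drug_id]]
        Z[r, d:] = emb.X_P[emb._p_index[protein_id]]
    return Z


def train_encoder(
    net: HeteroNetwork,
    F_DP: np.ndarray,
    train_pairs: list[tuple[tuple[str, str], int]],
    config: EncoderConfig,
) -> tuple[EncoderModel, list[float]]:
    """Fit the encoder by minimizing cross-entropy + L2 on labeled pairs.

    The pair probability comes from the configured disposable head
    (inner-product decoder by default). Returns the trained model and the
    per-epoch loss trace. Deterministic for a fixed config seed on a
    single thread.
    """
    labels = np.array([y for _, y in train_pairs], dtype=np.float64)
    if labels.min() == labels.max():
        raise ValueError("training pairs must contain both classes")
    model = EncoderModel(config, in_dim=F_DP.shape[1])
    v = net.n_drugs
    d_idx = np.array([net.node_index[d] for (d, _), _ in train_pairs], dtype=np.intp)
    p_idx = np.array([net.node_index[p] - v for (_, p), _ in train_pairs], dtype=np.intp)
    y = Tensor(labels)
    rng = np.random.default_rng(config.seed + 1)
    opt = _Optimizer(model.params, config)
    losses: list[float] = []
    ones_col: Tensor | None = None
    for epoch in range(config.epochs):
        for t in model.params.values():
            t.grad = None
        drop_rng = rng if config.dropout > 0.0 else None
        out = _forward(net, F_DP, model, dropout_rng=drop_rng)
        xd = out.gather_rows(d_idx)
        xp = out.gather_rows(p_idx + v)
        if config.head == "linear":
            logit = (xd @ model.params["head_wd"].reshape_col()
                     + xp @ model.params["head_wp"].reshape_col())
            p = (logit + model.params["head_b"]).sigmoid()
            p_flat = p.squeeze_col()             # (n, 1) -> (n,)
        else:
            if ones_col is None:
                ones_col = Tensor(np.ones((xd.shape[1], 1)))
            dot = ((xd * xp) @ ones_col).squeeze_col()
            p_flat = (model.params["head_s"] * dot + model.params["head_b"]).sigmoid()
        eps = 1e-12
        bce = -((y * (p_flat + eps).log()
                 + (1.0 - y) * (1.0 - p_flat + eps).log()).sum())
        reg = None
        for t in model.params.values():
            term = (t * t).sum()
            reg = term if reg is None else reg + term
        loss = bce + (config.l2_lambda / 2.0) * reg
        value = float(loss.data)
        if not np.isfinite(value):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        losses.append(value)
        loss.backward()
        opt.step()
    return model, losses


def _squeeze_col(self: Tensor) -> Tensor:
    def bwd(g):
        if self.requires_grad:
            self._accum(g.reshape(self.data.shape))

    return Tensor._make(self.data.reshape(-1), (self,), bwd)


Tensor.squeeze_col = _squeeze_col


class _Optimizer:
    """Plain SGD or Adam over the model's parameter dict."""

    def __init__(self, params: dict[str, Tensor], config: EncoderConfig):
        self.params = params
        self.lr = config.lr
        self.kind = config.optimizer
        if self.kind not in {"sgd", "adam"}:
            raise ValueError(f"unknown optimizer {self.kind!r}")
        if self.kind == "adam":
            self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
            self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
            self.t = 0
            self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self) -> None:
        if self.kind == "sgd":
            for t in self.params.values():
                if t.grad is not None:
                    t.data -= self.lr * t.grad
            return
        self.t += 1
        for k, t in self.params.items():
            if t.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * t.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * t.grad**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            t.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def extract_attention(
    model: EncoderModel, net: HeteroNetwork, F_DP: np.ndarray,
    pair: tuple[str, str],
) -> tuple[np.ndarray, np.ndarray]:
    """Head-averaged GAT attention over the drug's and protein's neighborhoods.

    Runs the forward pass up to the first GAT layer and returns the two
    attention rows (each a distribution over the node's neighborhood,
    nonnegative, summing to 1).
    """
    cfg = model.config
    if "gat" not in cfg.layer_plan:
        raise ValueError("layer plan contains no GAT layer")
    x: Tensor = Tensor(F_DP)
    attn = None
    for l, kind in enumerate(cfg.layer_plan):
        if kind == "gcn":
            x = gcn_layer(net, x, model.params[f"gcn{l}_W"], activate=True)
        else:
            heads = [
                (model.params[f"gat{l}_W{k}"], model.params[f"gat{l}_a{k}"],
                 model.params[f"gat{l}_B{k}"])
                for k in range(cfg.heads)
            ]
            x, attn = gat_layer(net, x, heads, cfg.leaky_slope, activate=True,
                                return_attention=True)
            break
    drug_id, protein_id = pair
    i, j = net.node_index[drug_id], net.node_index[protein_id]
    return attn[i], attn[j]
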
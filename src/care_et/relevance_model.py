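"""Multi-hop graph-attention / belief-network relevance model with
deep-embedded-clustering self-supervision.

The model encodes the event feature matrix through interleaved
graph-attention and logistic compression layers, soft-assigns events to
cluster centroids with a Student-t kernel, sharpens that assignment into
a target distribution, and trains both networks jointly by minimizing

    L_total = lambda1 * KL(P || K) + lambda2 * KL(P || D)

with AdamW (decoupled weight decay) and a linear warmup schedule.  All
forward operations are exposed as plain-numpy functions so they can be
checked against scalar oracles; training runs on a small internal
reverse-mode autodiff tape (`care_et._autodiff`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from care_et import _autodiff as ad
from care_et._autodiff import Tensor
from care_et.event_model import EventFeatureMatrix, ValidationError

__all__ = [
    "NeighborSets",
    "GatLayerParams",
    "DbnLayerParams",
    "TrainingConfig",
    "TrainedRelevanceModel",
    "TrainingError",
    "build_neighbor_sets",
    "attention_scores",
    "gat_layer_forward",
    "dbn_layer_forward",
    "interleaved_encode",
    "soft_assignment",
    "target_distribution",
    "kl_loss",
    "train_relevance_model",
]

_EPS = 1e-12


class TrainingError(RuntimeError):
    pass


@dataclass
class NeighborSets:
    """Direct (first-hop) and qualified indirect (second-hop) neighbor sets.

    ``direct[i]`` holds j != i with cos(h_i, h_j) > tau1; ``indirect[i]``
    holds k outside ``direct[i] | {i}`` witnessed by some j in
    ``direct[i]`` with cos(h_j, h_k) > tau2.
    """

    direct: dict[int, set[int]]
    indirect: dict[int, set[int]]
    tau1: float
    tau2: float

    def union(self, i: int) -> set[int]:
        return self.direct[i] | self.indirect[i]


@dataclass
class GatLayerParams:
    """One attention layer: per-head weight matrices W (heads, out, in)
    and attention vectors a (heads, 2*out)."""

    W: np.ndarray
    a: np.ndarray
    leaky_slope: float = 0.2
    heads: int = 1
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.W.ndim == 2:  # single-head shorthand
            self.W = np.repeat(self.W[None, :, :], self.heads, axis=0)
        if self.a.ndim == 1:
            self.a = np.repeat(self.a[None, :], self.heads, axis=0)
        if self.heads < 1:
            raise ValidationError("heads must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError("dropout_rate must lie in [0, 1)")
        if self.W.shape[0] != self.heads or self.a.shape[0] != self.heads:
            raise ValidationError("per-head parameter count must equal heads")
        if self.a.shape[1] != 2 * self.W.shape[1]:
            raise ValidationError("attention vector must have length 2*out_dim")

    @property
    def out_dim(self) -> int:
        return self.W.shape[1]

    @property
    def in_dim(self) -> int:
        return self.W.shape[2]


@dataclass
class DbnLayerParams:
    """One logistic compression layer: h+ = sigmoid(weights @ v + biases)."""

    weights: np.ndarray
    biases: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.biases = np.asarray(self.biases, dtype=float)
        if self.weights.ndim != 2 or self.biases.shape != (self.weights.shape[0],):
            raise ValidationError("inconsistent logistic-layer shapes")


@dataclass
class TrainingConfig:
    tau1: float = 0.6
    tau2: float = 0.8
    lambda1: float = 0.7
    lambda2: float = 0.3
    learning_rate: float = 1e-3
    weight_decay: float = 0.01
    warmup_fraction: float = 0.10
    dropout: float = 0.5
    heads: int = 2
    layer_dims: tuple[int, int] = (16, 8)  # (attention out dim, compression dim)
    rounds: int = 2
    epochs: int = 60
    seed: int = 0
    n_clusters: int | None = None
    v_c: float = 1.0
    leaky_slope: float = 0.2
    reconstruction: bool = False  # optional mirrored-decoder MSE penalty
    # refresh the sharpened target every this many epochs; refreshing every
    # step admits a degenerate all-rows-equal minimum of KL(P||D)
    target_update_interval: int = 10

    def __post_init__(self) -> None:
        if abs(self.lambda1 + self.lambda2 - 1.0) > 1e-9:
            raise ValidationError("lambda1 + lambda2 must equal 1")
        if not 0.0 <= self.warmup_fraction < 1.0:
            raise ValidationError("warmup_fraction must lie in [0, 1)")
        if not (0 < self.tau1 < 1 and 0 < self.tau2 < 1):
            raise ValidationError("thresholds must lie in (0, 1)")
        if self.v_c <= 0:
            raise ValidationError("v_c must be positive")


# ---------------------------------------------------------------------------
# forward operations (numpy API)


def _cosine_matrix(h: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(h, axis=1)
    if np.any(norms == 0.0):
        bad = int(np.argmin(norms))
        raise ValidationError(f"zero-norm feature row at index {bad}: cosine undefined")
    normed = h / norms[:, None]
    return normed @ normed.T


def build_neighbor_sets(
    features: EventFeatureMatrix | np.ndarray, tau1: float = 0.6, tau2: float = 0.8
) -> NeighborSets:
    """Threshold the cosine-similarity graph into first- and second-hop sets."""
    h = features.matrix if isinstance(features, EventFeatureMatrix) else np.asarray(features)
    if not (0 < tau1 < 1 and 0 < tau2 < 1):
        raise ValidationError("thresholds must lie in (0, 1)")
    n = h.shape[0]
    cos = _cosine_matrix(h)
    direct: dict[int, set[int]] = {}
    for i in range(n):
        direct[i] = {j for j in range(n) if j != i and cos[i, j] > tau1}
    indirect: dict[int, set[int]] = {}
    for i in range(n):
        cand: set[int] = set()
        for j in direct[i]:
            cand |= {k for k in range(n) if cos[j, k] > tau2}
        indirect[i] = cand - direct[i] - {i}
    return NeighborSets(direct=direct, indirect=indirect, tau1=tau1, tau2=tau2)


def _attention_mask(sets: NeighborSets, n: int) -> np.ndarray:
    """0/1 mask of attendable pairs; rows with no neighbors attend to self."""
    mask = np.zeros((n, n))
    for i in range(n):
        members = sets.union(i)
        if members:
            mask[i, list(members)] = 1.0
        else:
            mask[i, i] = 1.0
    return mask


def _split_attention(z: Tensor, a: Tensor, slope: float, mask: np.ndarray) -> Tensor:
    """alpha rows from theta_ij = LeakyReLU(u_i + v_j), where u = z @ a[:d]
    applies the first half of the attention vector to the source node and
    v = z @ a[d:] the second half to the target node (the concatenation
    [Wh_i || Wh_j] evaluated without materializing n^2 vectors)."""
    d = z.value.shape[1]
    sel_left = Tensor(np.vstack([np.eye(d), np.zeros((d, d))]))  # (2d, d)
    sel_right = Tensor(np.vstack([np.zeros((d, d)), np.eye(d)]))
    a_row = Tensor(a.value.reshape(1, -1), (a,), lambda g: (g.reshape(a.value.shape),))
    u = (a_row @ sel_left) @ z.T  # (1, n)
    v = (a_row @ sel_right) @ z.T  # (1, n)
    theta = ad.leaky_relu(u.T + v, slope)  # (n, n) via broadcasting
    if np.any(~np.isfinite(theta.value)):
        bad = int(np.argwhere(~np.isfinite(theta.value))[0][0])
        raise TrainingError(f"non-finite attention score at node {bad}")
    # numerically stable masked softmax; the shift is treated as a constant
    shift = np.max(np.where(mask > 0, theta.value, -np.inf), axis=1, keepdims=True)
    e = ad.exp(theta - Tensor(shift)) * Tensor(mask)
    denom = e.sum(axis=1, keepdims=True)
    return e / denom


def attention_scores(
    h: np.ndarray, params: GatLayerParams, sets: NeighborSets
) -> np.ndarray:
    """Attention coefficient matrix for the first head (numpy view).

    Entry (i, j) is defined only for j in the neighbor union of i and the
    rows sum to 1 there; rows with an empty union self-attend with weight 1.
    """
    h = np.asarray(h, dtype=float)
    n = h.shape[0]
    mask = _attention_mask(sets, n)
    z = Tensor(h) @ Tensor(params.W[0]).T
    alpha = _split_attention(z, Tensor(params.a[0]), params.leaky_slope, mask)
    return alpha.value


def _gat_layer_t(
    h: Tensor,
    W_heads: Sequence[Tensor],
    a_heads: Sequence[Tensor],
    slope: float,
    mask: np.ndarray,
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Tensor:
    outputs = []
    for W, a in zip(W_heads, a_heads):
        z = h @ W.T
        alpha = _split_attention(z, a, slope, mask)
        if dropout_rate > 0.0 and rng is not None:
            keep = (rng.random(alpha.value.shape) >= dropout_rate).astype(float)
            alpha = alpha * Tensor(keep / (1.0 - dropout_rate))
        outputs.append(ad.elu(alpha @ z))
    total = outputs[0]
    for o in outputs[1:]:
        total = total + o
    return total * (1.0 / len(outputs))


def gat_layer_forward(
    h: np.ndarray,
    params: GatLayerParams,
    sets: NeighborSets,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Multi-head attention aggregation: mean over heads of
    elu(alpha @ h W^T).  Dropout on the attention coefficients is applied
    only when an ``rng`` is supplied (training mode)."""
    h = np.asarray(h, dtype=float)
    mask = _attention_mask(sets, h.shape[0])
    out = _gat_layer_t(
        Tensor(h),
        [Tensor(params.W[k]) for k in range(params.heads)],
        [Tensor(params.a[k]) for k in range(params.heads)],
        params.leaky_slope,
        mask,
        params.dropout_rate if rng is not None else 0.0,
        rng,
    )
    return out.value


def _dbn_layer_t(v: Tensor, weights: Tensor, biases: Tensor) -> Tensor:
    return ad.sigmoid(v @ weights.T + biases)


def dbn_layer_forward(v: np.ndarray, params: DbnLayerParams) -> np.ndarray:
    """Elementwise logistic layer h+ = sigmoid(W v + b); accepts a single
    visible vector or a batch of rows."""
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    if single:
        v = v[None, :]
    if v.shape[1] != params.weights.shape[1]:
        raise ValidationError(
            f"visible dim {v.shape[1]} != layer input dim {params.weights.shape[1]}"
        )
    out = _dbn_layer_t(Tensor(v), Tensor(params.weights), Tensor(params.biases)).value
    return out[0] if single else out


def interleaved_encode(
    phi: EventFeatureMatrix | np.ndarray,
    gat_stack: Sequence[GatLayerParams],
    dbn_stack: Sequence[DbnLayerParams],
    sets: NeighborSets,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Alternate attention and compression rounds.

    Round 0 feeds the raw feature matrix to the first attention layer;
    each later round feeds the concatenation of the previous attention
    output and the previous hidden state.  Returns the final attention
    output and every hidden state.
    """
    if len(gat_stack) != len(dbn_stack) or not gat_stack:
        raise ValidationError("need equal, non-empty attention and compression stacks")
    x = phi.matrix if isinstance(phi, EventFeatureMatrix) else np.asarray(phi, dtype=float)
    hidden_states: list[np.ndarray] = []
    out = None
    for r, (gp, dp) in enumerate(zip(gat_stack, dbn_stack)):
        inp = x if r == 0 else np.concatenate([out, hidden_states[-1]], axis=1)
        if inp.shape[1] != gp.in_dim:
            raise ValidationError(
                f"round {r}: input dim {inp.shape[1]} != layer dim {gp.in_dim}"
            )
        out = gat_layer_forward(inp, gp, sets)
        hidden_states.append(dbn_layer_forward(out, dp))
    return out, hidden_states


def _soft_assignment_t(h: Tensor, centroids: Tensor, v_c: float) -> Tensor:
    sq = (
        (h * h).sum(axis=1, keepdims=True)
        + (centroids * centroids).sum(axis=1, keepdims=True).T
        - 2.0 * (h @ centroids.T)
    )
    base = (1.0 + sq * (1.0 / v_c)) ** (-(v_c + 1.0) / 2.0)
    return base / base.sum(axis=1, keepdims=True)


def soft_assignment(
    features: np.ndarray, centroids: np.ndarray, v_c: float = 1.0
) -> np.ndarray:
    """Student-t soft cluster assignment D (rows sum to 1)."""
    features = np.asarray(features, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    if v_c <= 0:
        raise ValidationError("v_c must be positive")
    if features.shape[1] != centroids.shape[1]:
        raise ValidationError("feature and centroid dimensions differ")
    return _soft_assignment_t(Tensor(features), Tensor(centroids), v_c).value


def target_distribution(D: np.ndarray) -> np.ndarray:
    """Sharpen D: p_ij = (d_ij^2 / f_j) / sum_j'(d_ij'^2 / f_j'), f_j = sum_i d_ij."""
    D = np.asarray(D, dtype=float)
    f = D.sum(axis=0)
    if np.any(f <= 0):
        raise ValidationError("degenerate cluster: zero soft-assignment mass")
    w = D**2 / f
    return w / w.sum(axis=1, keepdims=True)


def kl_loss(P: np.ndarray, Q: np.ndarray) -> float:
    """KL(P || Q) over rows with an epsilon floor before the logarithms."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValidationError("distribution shapes differ")
    Pf = np.maximum(P, _EPS)
    Qf = np.maximum(Q, _EPS)
    return float(np.sum(P * (np.log(Pf) - np.log(Qf))))


def _kl_t(P: np.ndarray, Q: Tensor) -> Tensor:
    """KL(P || Q) with P constant, for the training graph."""
    Pf = np.maximum(P, _EPS)
    return Tensor(np.sum(P * np.log(Pf))) - (Tensor(P) * ad.log(Q + _EPS)).sum()


def _softmax_rows_t(logits: Tensor) -> Tensor:
    shift = logits.value.max(axis=1, keepdims=True)
    e = ad.exp(logits - Tensor(shift))
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainedRelevanceModel:
    gat_stack: list[GatLayerParams]
    dbn_stack: list[DbnLayerParams]
    head_weights: np.ndarray
    head_biases: np.ndarray
    centroids: np.ndarray
    config: TrainingConfig
    losses: list[float] = field(default_factory=list)
    encoded: np.ndarray | None = None  # final compression features
    D: np.ndarray | None = None
    # per-epoch max |row sum - 1| of the soft assignment and target
    d_rowsum_err: list[float] = field(default_factory=list)
    p_rowsum_err: list[float] = field(default_factory=list)

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.D, axis=1)


class _AdamW:
    """Decoupled-weight-decay Adam with linear warmup then constant rate."""

    def __init__(self, shapes, lr, weight_decay, warmup_steps, decay_mask):
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.lr = lr
        self.wd = weight_decay
        self.warmup = max(warmup_steps, 0)
        self.decay_mask = decay_mask
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        lr = self.lr * min(1.0, self.t / self.warmup) if self.warmup else self.lr
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
            if self.decay_mask[i]:
                p -= lr * self.wd * p


def _init_params(
    m: int, config: TrainingConfig, rng: np.random.Generator
) -> tuple[list[GatLayerParams], list[DbnLayerParams]]:
    d_g, d_b = config.layer_dims
    gat_stack, dbn_stack = [], []
    in_dim = m
    for _ in range(config.rounds):
        W = rng.normal(0, np.sqrt(2.0 / in_dim), size=(config.heads, d_g, in_dim))
        a = rng.normal(0, 0.1, size=(config.heads, 2 * d_g))
        gat_stack.append(
            GatLayerParams(
                W=W, a=a, leaky_slope=config.leaky_slope,
                heads=config.heads, dropout_rate=config.dropout,
            )
        )
        dbn_stack.append(
            DbnLayerParams(
                weights=rng.normal(0, np.sqrt(2.0 / d_g), size=(d_b, d_g)),
                biases=np.zeros(d_b),
            )
        )
        in_dim = d_g + d_b
    return gat_stack, dbn_stack


def _scale_init(
    phi: np.ndarray,
    gat_stack: list[GatLayerParams],
    dbn_stack: list[DbnLayerParams],
    sets: NeighborSets,
    target_std: float = 1.5,
) -> None:
    """Data-dependent rescaling of the logistic layers (in place).

    Random init often leaves sigmoid pre-activations either saturated or
    vanishingly small, which flattens the Student-t kernel and makes the
    initial self-supervision target uninformative.  Center each unit's
    pre-activation and scale it to ``target_std`` on the actual data.
    """
    x = phi
    out = None
    for r, (gp, dp) in enumerate(zip(gat_stack, dbn_stack)):
        inp = x if r == 0 else np.concatenate([out, hid], axis=1)
        out = gat_layer_forward(inp, gp, sets)
        pre = out @ dp.weights.T + dp.biases
        std = np.maximum(pre.std(axis=0), 1e-8)
        dp.weights *= (target_std / std)[:, None]
        dp.biases = -(out @ dp.weights.T).mean(axis=0)
        hid = dbn_layer_forward(out, dp)


def train_relevance_model(
    events,
    features: EventFeatureMatrix,
    config: TrainingConfig,
) -> tuple[TrainedRelevanceModel, EventFeatureMatrix]:
    """Jointly train the attention and compression networks under the
    self-supervised clustering loss.

    Returns the trained model and the encoded feature matrix whose cosine
    structure feeds the joint (k-means / DBSCAN) adjustment stage.
    Fully reproducible for a fixed ``config.seed``.
    """
    from sklearn.cluster import KMeans

    phi = features.matrix
    ids = features.event_ids
    n, m = phi.shape
    rng = np.random.default_rng(config.seed)

    gat_stack, dbn_stack = _init_params(m, config, rng)
    sets = build_neighbor_sets(phi, config.tau1, config.tau2)
    _scale_init(phi, gat_stack, dbn_stack, sets)

    # initial compression features -> k-means centroids
    _, hiddens = interleaved_encode(phi, gat_stack, dbn_stack, sets)
    h0 = hiddens[-1]
    if config.n_clusters is not None:
        k = config.n_clusters
    else:
        from care_et.joint_adjustment import select_k

        k = select_k(h0, range(2, max(3, min(8, n - 1))))
    if not 2 <= k <= n:
        raise ValidationError(f"need n >= k >= 2, got n={n}, k={k}")
    km = KMeans(n_clusters=k, n_init=10, random_state=config.seed).fit(h0)
    centroids = km.cluster_centers_.astype(float)

    head_W = rng.normal(0, np.sqrt(2.0 / config.layer_dims[0]),
                        size=(k, config.layer_dims[0]))
    head_b = np.zeros(k)
    dec_W = rng.normal(0, 0.1, size=(m, config.layer_dims[1]))
    dec_b = np.zeros(m)

    # flat parameter list: [per-layer (W_h..., a_h..., dbnW, dbnb)..., headW, headb, centroids]
    params: list[np.ndarray] = []
    decay: list[bool] = []
    for gp, dp in zip(gat_stack, dbn_stack):
        for h_i in range(config.heads):
            params.append(gp.W[h_i]); decay.append(True)
            params.append(gp.a[h_i]); decay.append(True)
        params.append(dp.weights); decay.append(True)
        params.append(dp.biases); decay.append(False)
    params += [head_W, head_b, centroids]
    decay += [True, False, False]
    if config.reconstruction:
        params += [dec_W, dec_b]
        decay += [True, False]

    total_steps = config.epochs
    opt = _AdamW(
        [p.shape for p in params],
        config.learning_rate,
        config.weight_decay,
        int(np.ceil(config.warmup_fraction * total_steps)),
        decay,
    )

    losses: list[float] = []
    d_rowsum_err: list[float] = []
    p_rowsum_err: list[float] = []
    drop_rng = np.random.default_rng(config.seed + 1)
    current_encoded = phi

    for epoch in range(config.epochs):
        if epoch > 0:
            # center before thresholding: trained activations drift
            # all-positive, which would inflate every cosine past tau1 and
            # collapse the graph into a clique
            centered = current_encoded - current_encoded.mean(axis=0)
            try:
                sets = build_neighbor_sets(centered, config.tau1, config.tau2)
            except ValidationError:
                pass  # keep previous sets if a row collapsed to zero
        mask = _attention_mask(sets, n)

        # rebuild leaves over the shared parameter buffers
        leaves = [Tensor(p) for p in params]
        li = 0
        x_t = Tensor(phi)
        out_t: Tensor | None = None
        hid_t: Tensor | None = None
        for r in range(config.rounds):
            W_heads = [leaves[li + 2 * h_i] for h_i in range(config.heads)]
            a_heads = [leaves[li + 2 * h_i + 1] for h_i in range(config.heads)]
            li += 2 * config.heads
            dbn_w, dbn_b = leaves[li], leaves[li + 1]
            li += 2
            inp = x_t if r == 0 else ad.concat([out_t, hid_t], axis=1)
            out_t = _gat_layer_t(
                inp, W_heads, a_heads, config.leaky_slope, mask,
                config.dropout, drop_rng,
            )
            hid_t = _dbn_layer_t(out_t, dbn_w, dbn_b)
        head_W_t, head_b_t, centroids_t = leaves[li], leaves[li + 1], leaves[li + 2]

        D_t = _soft_assignment_t(hid_t, centroids_t, config.v_c)
        if epoch % max(config.target_update_interval, 1) == 0:
            P = target_distribution(D_t.value)  # detached, refreshed at intervals
        K_t = _softmax_rows_t(out_t @ head_W_t.T + head_b_t)

        loss_t = config.lambda1 * _kl_t(P, K_t) + config.lambda2 * _kl_t(P, D_t)
        if config.reconstruction:
            recon = hid_t @ leaves[li + 3].T + leaves[li + 4]
            diff = recon - x_t
            loss_t = loss_t + (diff * diff).mean()

        if not np.isfinite(loss_t.value):
            raise TrainingError(f"divergent loss at step {epoch}")
        d_rowsum_err.append(float(np.abs(D_t.value.sum(axis=1) - 1.0).max()))
        p_rowsum_err.append(float(np.abs(P.sum(axis=1) - 1.0).max()))
        loss_t.backward()
        losses.append(float(loss_t.value))
        opt.step(params, [lf.grad for lf in leaves])
        current_encoded = out_t.value

    # final deterministic forward (no dropout)
    O, hiddens = interleaved_encode(phi, gat_stack, dbn_stack, sets)
    encoded = hiddens[-1]
    D = soft_assignment(encoded, centroids, config.v_c)

    model = TrainedRelevanceModel(
        gat_stack=gat_stack,
        dbn_stack=dbn_stack,
        head_weights=head_W,
        head_biases=head_b,
        centroids=centroids,
        config=config,
        losses=losses,
        encoded=encoded,
        D=D,
        d_rowsum_err=d_rowsum_err,
        p_rowsum_err=p_rowsum_err,
    )
    return model, EventFeatureMatrix(ids, encoded)
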
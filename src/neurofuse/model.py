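"""Dual-GNN multimodal fusion model for treatment-response regression.

Each modality's normalized connectivity matrix is treated as a graph:
node i carries ROI i's connectivity profile as its feature vector, and
the adjacency is the ReLU-clamped cosine similarity between profiles.
A learnable edge-scaling matrix S_m (kept symmetric, initialized at 1)
multiplies the adjacency entrywise before row-normalization, letting the
model reweight connections during training; the trained S_m is read out
post hoc as edge importance. Two graph-convolution layers (neighborhood
averaging + linear map + tanh) encode each graph; node embeddings are
reduced to a per-ROI activation vector h by a feature-axis mean, and a
per-modality projection W_m maps h to a d-dimensional latent. A
correlation penalty pushes the paired fMRI/EEG latents toward per-
dimension agreement (CCA-style), softmax aggregation weights α reweight
latent dimensions, and the concatenated weighted latents feed an MLP
that predicts the HAMD17 change.

Training minimizes  MSE(ŷ, y) + λ · correlation_loss  by Adam with an
inner validation split and early stopping. No autodiff framework is
used: gradients are derived by hand and checked against finite
differences in the test suite.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np

from .connectivity import ConnectivityMatrix

__all__ = [
    "FusionConfig",
    "BrainGraph",
    "FusionModelParams",
    "LatentPair",
    "build_graph",
    "graphs_to_batch",
    "gnn_forward",
    "project_latent",
    "correlation_loss",
    "train_model",
    "predict",
    "latent_pairs",
    "fast_model_config",
]

MODALITIES = ("fmri", "eeg")
_RIDGE = 1e-4
_ROW_EPS = 1e-6


@dataclass
class FusionConfig:
    """Architecture and optimization hyperparameters."""

    n_rois: int = 100
    hidden: int = 64                 # GNN embedding width H
    latent_dim: int = 32             # d
    mlp_hidden: tuple[int, int] = (64, 32)
    lam: float = 0.5                 # weight of the correlation penalty
    lr: float = 1e-3
    epochs: int = 200
    batch_size: int = 32
    patience: int = 20
    val_frac: float = 0.1
    scale_lr_mult: float = 10.0      # learning-rate multiplier for S_m
    scale_l2: float = 1e-3           # shrinkage of S_m toward its init (1)
    scale_warmup: int = 30           # epochs with S_m frozen before it adapts

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mlp_hidden"] = list(self.mlp_hidden)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FusionConfig":
        d = dict(d)
        d["mlp_hidden"] = tuple(d["mlp_hidden"])
        return cls(**d)


def fast_model_config(n_rois: int = 20, **overrides) -> FusionConfig:
    """Desk-scale model: narrower widths for 20-ROI synthetic cohorts."""
    defaults = dict(n_rois=n_rois, hidden=32, latent_dim=8, mlp_hidden=(32, 16),
                    epochs=150, lr=3e-3)
    defaults.update(overrides)
    return FusionConfig(**defaults)


@dataclass
class BrainGraph:
    """Node features (connectivity profiles) plus similarity adjacency."""

    node_features: np.ndarray     # N×N, row i = ROI i's profile
    adjacency: np.ndarray         # N×N nonnegative, unit diagonal
    modality: str
    subject_id: str = ""


@dataclass
class LatentPair:
    z_fmri: np.ndarray
    z_eeg: np.ndarray
    subject_id: str = ""


def build_graph(c: ConnectivityMatrix) -> BrainGraph:
    """Graph for one subject: ReLU-clamped cosine similarity adjacency.

    A(i,j) = max(0, cos(row_i, row_j)) for i≠j and A(i,i) = 1, so the
    message-passing operator stays nonnegative and row-normalizable.
    """
    x = np.asarray(c.values, dtype=float)
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms == 0):
        raise ValueError(f"zero connectivity profile row at index {int(np.argmin(norms))}")
    cosine = (x @ x.T) / np.outer(norms, norms)
    a = np.maximum(cosine, 0.0)
    np.fill_diagonal(a, 1.0)
    return BrainGraph(x, a, c.modality, c.subject_id)


def graphs_to_batch(graphs: list[BrainGraph]) -> tuple[np.ndarray, np.ndarray]:
    """Stack graphs into (S,N,N) feature and adjacency arrays."""
    x = np.stack([g.node_features for g in graphs])
    a = np.stack([g.adjacency for g in graphs])
    return x, a


# ---------------------------------------------------------------------------
# parameters


@dataclass
class FusionModelParams:
    """All learnable parameters plus data-scaling constants."""

    config: FusionConfig
    gnn: dict[str, dict[str, np.ndarray]]      # per modality: W1,b1,W2,b2
    scale: dict[str, np.ndarray]               # per modality: S_m (N×N)
    proj: dict[str, np.ndarray]                # per modality: W_m (N×d)
    agg_raw: np.ndarray                        # d-vector, softmax → α
    mlp: dict[str, np.ndarray]                 # V1,c1,V2,c2,V3,c3
    y_mean: float = 0.0
    y_std: float = 1.0
    seed: int | None = None

    @property
    def alpha(self) -> np.ndarray:
        e = np.exp(self.agg_raw - self.agg_raw.max())
        return e / e.sum()

    def flat_arrays(self) -> list[np.ndarray]:
        out = []
        for m in MODALITIES:
            out += [self.gnn[m][k] for k in ("W1", "b1", "W2", "b2")]
            out += [self.scale[m], self.proj[m]]
        out.append(self.agg_raw)
        out += [self.mlp[k] for k in ("V1", "c1", "V2", "c2", "V3", "c3")]
        return out

    def copy(self) -> "FusionModelParams":
        return copy.deepcopy(self)


def init_params(config: FusionConfig, seed: int = 0) -> FusionModelParams:
    rng = np.random.default_rng(seed)
    n, h, d = config.n_rois, config.hidden, config.latent_dim
    h1, h2 = config.mlp_hidden

    def glorot(fan_in, fan_out):
        s = np.sqrt(2.0 / (fan_in + fan_out))
        return rng.normal(0.0, s, size=(fan_in, fan_out))

    gnn = {}
    scale = {}
    proj = {}
    for m in MODALITIES:
        gnn[m] = {
            "W1": glorot(n, h), "b1": np.zeros(h),
            "W2": glorot(h, h), "b2": np.zeros(h),
        }
        scale[m] = np.ones((n, n))
        proj[m] = glorot(n, d)
    mlp = {
        "V1": glorot(2 * d, h1), "c1": np.zeros(h1),
        "V2": glorot(h1, h2), "c2": np.zeros(h2),
        "V3": glorot(h2, 1), "c3": np.zeros(1),
    }
    return FusionModelParams(config, gnn, scale, proj, rng.normal(0, 0.01, size=d), mlp, seed=seed)


# ---------------------------------------------------------------------------
# forward


def _operator(a: np.ndarray, s_mat: np.ndarray):
    """Row-normalized scaled adjacency P = rownorm(A ⊙ sym(S)).

    Returns (P, M, row sums with sign-preserving floor, clamp mask).
    """
    ssym = (s_mat + s_mat.T) / 2.0
    m = a * ssym[None, :, :]
    r = m.sum(axis=2)
    clamped = np.abs(r) < _ROW_EPS
    r_safe = np.where(clamped, np.where(r < 0, -_ROW_EPS, _ROW_EPS), r)
    p = m / r_safe[:, :, None]
    return p, m, r_safe, clamped


def _branch_forward(x: np.ndarray, a: np.ndarray, params: FusionModelParams, mod: str):
    """One modality's GNN branch; returns latents and a cache for backprop."""
    g = params.gnn[mod]
    p, m, r_safe, clamped = _operator(a, params.scale[mod])
    c1 = x @ g["W1"]
    t1 = np.einsum("snm,smh->snh", p, c1) + g["b1"]
    z1 = np.tanh(t1)
    b2 = z1 @ g["W2"]
    t2 = np.einsum("snm,smh->snh", p, b2) + g["b2"]
    z2 = np.tanh(t2)
    h = z2.mean(axis=2)                       # (S,N)
    z = h @ params.proj[mod]                  # (S,d)
    cache = dict(x=x, a=a, p=p, r=r_safe, clamped=clamped, c1=c1, z1=z1, b2=b2, z2=z2, h=h)
    return z, cache

def _mlp_forward(u: np.ndarray, mlp: dict):
    m1 = np.tanh(u @ mlp["V1"] + mlp["c1"])
    m2 = np.tanh(m1 @ mlp["V2"] + mlp["c2"])
    out = (m2 @ mlp["V3"] + mlp["c3"])[:, 0]
    return out, (m1, m2)


def _full_forward(batch: dict, params: FusionModelParams):
    alpha = params.alpha
    z = {}
    caches = {}
    for mod in MODALITIES:
        z[mod], caches[mod] = _branch_forward(batch[mod]["x"], batch[mod]["a"], params, mod)
    u = np.concatenate([z["fmri"] * alpha, z["eeg"] * alpha], axis=1)
    yhat_n, mlp_cache = _mlp_forward(u, params.mlp)
    return yhat_n, z, u, caches, mlp_cache, alpha


def gnn_forward(graph: BrainGraph, params: FusionModelParams) -> np.ndarray:
    """Node embedding (N×H) for a single graph through its modality branch."""
    x = graph.node_features[None]
    a = graph.adjacency[None]
    _, cache = _branch_forward(x, a, params, graph.modality)
    return cache["z2"][0]


def project_latent(embedding: np.ndarray, w_m: np.ndarray) -> np.ndarray:
    """Reduce an N×H node embedding to a d-latent: z = W_mᵀ · mean_H(embedding)."""
    h = np.asarray(embedding).mean(axis=1)
    return np.asarray(w_m).T @ h


def correlation_loss(z_fmri: np.ndarray, z_eeg: np.ndarray) -> float:
    """−mean per-dimension Pearson correlation between paired latents.

    Variances are ridge-regularized (ε=1e-4) so degenerate batches stay
    finite; the value lies in [−1, 1].
    """
    z_fmri = np.atleast_2d(z_fmri)
    z_eeg = np.atleast_2d(z_eeg)
    s, d = z_fmri.shape
    if s < d + 2:
        raise ValueError(f"batch size {s} too small for {d} latent dimensions")
    cx = z_fmri - z_fmri.mean(axis=0)
    cy = z_eeg - z_eeg.mean(axis=0)
    vx = (cx ** 2).mean(axis=0) + _RIDGE
    vy = (cy ** 2).mean(axis=0) + _RIDGE
    cxy = (cx * cy).mean(axis=0)
    return float(-(cxy / np.sqrt(vx * vy)).mean())


def _correlation_loss_grads(zf: np.ndarray, ze: np.ndarray):
    """Gradients of correlation_loss w.r.t. both latent batches."""
    s, d = zf.shape
    cx = zf - zf.mean(axis=0)
    cy = ze - ze.mean(axis=0)
    vx = (cx ** 2).mean(axis=0) + _RIDGE
    vy = (cy ** 2).mean(axis=0) + _RIDGE
    cxy = (cx * cy).mean(axis=0)
    denom = np.sqrt(vx * vy)
    c = cxy / denom
    gx = (cy / denom - c * cx / vx) / s
    gy = (cx / denom - c * cy / vy) / s
    # loss = -mean_j c_j ; centering maps gradients through (I - 1/S)
    gx = -(gx - gx.mean(axis=0)) / d
    gy = -(gy - gy.mean(axis=0)) / d
    return gx, gy


# ---------------------------------------------------------------------------
# backward


def _branch_backward(dz: np.ndarray, cache: dict, params: FusionModelParams, mod: str):
    g = params.gnn[mod]
    x, a, p = cache["x"], cache["a"], cache["p"]
    z1, z2, c1, b2, h = cache["z1"], cache["z2"], cache["c1"], cache["b2"], cache["h"]
    n_h = z2.shape[2]

    d_proj = cache["h"].T @ dz
    dh = dz @ params.proj[mod].T              # (S,N)
    dz2 = dh[:, :, None] / n_h
    g2 = dz2 * (1.0 - z2 ** 2)
    db2_vec = g2.sum(axis=(0, 1))
    dp = np.einsum("snh,smh->snm", g2, b2)
    d_b2mat = np.einsum("snm,snh->smh", p, g2)
    dW2 = np.einsum("snh,snk->hk", z1, d_b2mat)
    dz1 = d_b2mat @ g["W2"].T
    g1 = dz1 * (1.0 - z1 ** 2)
    db1_vec = g1.sum(axis=(0, 1))
    dp += np.einsum("snh,smh->snm", g1, c1)
    d_c1 = np.einsum("snm,snh->smh", p, g1)
    dW1 = np.einsum("snh,snk->hk", x, d_c1)

    # dP -> dM through row normalization
    r = cache["r"]
    clamped = cache["clamped"]
    row_dot = (dp * p).sum(axis=2)
    dm = (dp - row_dot[:, :, None]) / r[:, :, None]
    dm_clamped = dp / r[:, :, None]
    dm = np.where(clamped[:, :, None], dm_clamped, dm)
    dssym = (a * dm).sum(axis=0)
    dS = (dssym + dssym.T) / 2.0

    return {"W1": dW1, "b1": db1_vec, "W2": dW2, "b2": db2_vec, "S": dS, "proj": d_proj}


def _full_backward(batch: dict, y_n: np.ndarray, params: FusionModelParams):
    """Loss and gradients for one (sub)batch; y_n is standardized outcome."""
    yhat_n, z, u, caches, (m1, m2), alpha = _full_forward(batch, params)
    s = len(y_n)
    resid = yhat_n - y_n
    mse = float((resid ** 2).mean())
    closs = correlation_loss(z["fmri"], z["eeg"]) if params.config.lam != 0 else 0.0
    loss = mse + params.config.lam * closs

    mlp = params.mlp
    dout = (2.0 / s) * resid                     # (S,)
    dV3 = m2.T @ dout[:, None]
    dc3 = np.array([dout.sum()])
    dm2 = dout[:, None] @ mlp["V3"].T * (1 - m2 ** 2)
    dV2 = m1.T @ dm2
    dc2 = dm2.sum(axis=0)
    dm1 = dm2 @ mlp["V2"].T * (1 - m1 ** 2)
    dV1 = u.T @ dm1
    dc1 = dm1.sum(axis=0)
    du = dm1 @ mlp["V1"].T
    d_latent = params.config.latent_dim
    dzt = {"fmri": du[:, :d_latent], "eeg": du[:, d_latent:]}

    if params.config.lam != 0:
        gf, ge = _correlation_loss_grads(z["fmri"], z["eeg"])
    else:
        gf = ge = 0.0
    dz = {
        "fmri": dzt["fmri"] * alpha + params.config.lam * gf,
        "eeg": dzt["eeg"] * alpha + params.config.lam * ge,
    }
    # aggregation weights: u uses z·α for both modalities
    g_alpha = (dzt["fmri"] * z["fmri"]).sum(axis=0) + (dzt["eeg"] * z["eeg"]).sum(axis=0)
    d_agg = alpha * (g_alpha - float(g_alpha @ alpha))

    grads = {"mlp": {"V1": dV1, "c1": dc1, "V2": dV2, "c2": dc2, "V3": dV3, "c3": dc3},
             "agg_raw": d_agg, "gnn": {}, "scale": {}, "proj": {}}
    for mod in MODALITIES:
        br = _branch_backward(dz[mod], caches[mod], params, mod)
        grads["gnn"][mod] = {k: br[k] for k in ("W1", "b1", "W2", "b2")}
        # shrink the edge-scaling matrix toward its init so only edges with
        # persistent predictive gradient keep large learned deviations
        grads["scale"][mod] = br["S"] + 2.0 * params.config.scale_l2 * (params.scale[mod] - 1.0)
        grads["proj"][mod] = br["proj"]
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite training loss (exploding weights?)")
    return loss, mse, closs, grads


# ---------------------------------------------------------------------------
# optimizer / training


class _Adam:
    def __init__(self, shapes, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.t = 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]

    def step(self, arrays, grads, lr_mults):
        self.t += 1
        for i, (a, g, mult) in enumerate(zip(arrays, grads, lr_mults)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            a -= self.lr * mult * mhat / (np.sqrt(vhat) + self.eps)


def _grads_flat(params: FusionModelParams, grads: dict) -> list[np.ndarray]:
    out = []
    for m in MODALITIES:
        out += [grads["gnn"][m][k] for k in ("W1", "b1", "W2", "b2")]
        out += [grads["scale"][m], grads["proj"][m]]
    out.append(grads["agg_raw"])
    out += [grads["mlp"][k] for k in ("V1", "c1", "V2", "c2", "V3", "c3")]
    return out


def _lr_mults(params: FusionModelParams) -> list[float]:
    out = []
    for _ in MODALITIES:
        out += [1.0, 1.0, 1.0, 1.0]          # W1,b1,W2,b2
        out += [params.config.scale_lr_mult, 1.0]  # S_m, proj
    out.append(1.0)
    out += [1.0] * 6
    return out


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


def train_model(
    dataset: "FusionDataset",
    config: FusionConfig,
    seed: int = 0,
    history: TrainingHistory | None = None,
) -> FusionModelParams:
    """Fit the fusion model on a training set (augmented samples allowed).

    A 10% inner validation split is drawn from the non-augmented subjects
    only; early stopping restores the best-validation-loss parameters
    after ``patience`` epochs without improvement. Fully reproducible
    given ``seed``.
    """
    rng = np.random.default_rng(seed)
    params = init_params(config, seed=seed)

    y = dataset.labels
    params.y_mean = float(y[~dataset.is_augmented].mean())
    params.y_std = float(y[~dataset.is_augmented].std()) or 1.0
    y_n = (y - params.y_mean) / params.y_std

    real_idx = np.flatnonzero(~dataset.is_augmented)
    n_val = max(1, int(round(config.val_frac * len(real_idx)))) if len(real_idx) >= 5 else 0
    perm = rng.permutation(real_idx)
    val_idx = perm[:n_val]
    train_idx = np.concatenate([perm[n_val:], np.flatnonzero(dataset.is_augmented)])

    arrays = params.flat_arrays()
    opt = _Adam([a.shape for a in arrays], config.lr)
    mults = _lr_mults(params)

    best_val = np.inf
    best = params.copy()
    best_epoch = -1
    stall = 0
    min_batch = config.latent_dim + 2
    scale_slots = [4, 10]  # positions of S_fmri / S_eeg in the flat array list
    for epoch in range(config.epochs):
        # edge scaling stays frozen until the other pathways have formed,
        # so S_m updates reflect trained-model sensitivities
        ep_mults = list(mults)
        if epoch < config.scale_warmup:
            for slot in scale_slots:
                ep_mults[slot] = 0.0
        order = rng.permutation(train_idx)
        ep_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            if len(idx) < min_batch:
                continue
            batch = dataset.subset(idx)
            loss, _, _, grads = _full_backward(batch, y_n[idx], params)
            opt.step(arrays, _grads_flat(params, grads), ep_mults)
            ep_loss += loss
            n_batches += 1
        ep_loss /= max(n_batches, 1)
        if n_val:
            vb = dataset.subset(val_idx)
            vy, _, _, _, _, _ = _full_forward(vb, params)
            val = float(((vy - y_n[val_idx]) ** 2).mean())
        else:
            val = ep_loss
        if history is not None:
            history.train_loss.append(ep_loss)
            history.val_loss.append(val)
        if val < best_val - 1e-7:
            best_val = val
            best = params.copy()
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    if history is not None:
        history.best_epoch = best_epoch
    return best


def predict(params: FusionModelParams, batch: dict) -> np.ndarray:
    """Predicted ΔHAMD for a multimodal batch (original outcome scale)."""
    yhat_n, _, _, _, _, _ = _full_forward(batch, params)
    return yhat_n * params.y_std + params.y_mean


def latent_pairs(params: FusionModelParams, batch: dict, subject_ids=None) -> list[LatentPair]:
    """Per-subject latent vectors from both GNN branches."""
    _, z, _, _, _, _ = _full_forward(batch, params)
    ids = subject_ids or [""] * len(z["fmri"])
    return [LatentPair(zf, ze, sid) for zf, ze, sid in zip(z["fmri"], z["eeg"], ids)]


# ---------------------------------------------------------------------------
# dataset container


class FusionDataset:
    """Paired-modality graph batch with labels and augmentation flags."""

    def __init__(self, x_fmri, a_fmri, x_eeg, a_eeg, labels, subject_ids, is_augmented=None):
        self.batch = {
            "fmri": {"x": np.asarray(x_fmri), "a": np.asarray(a_fmri)},
            "eeg": {"x": np.asarray(x_eeg), "a": np.asarray(a_eeg)},
        }
        self.labels = np.asarray(labels, dtype=float)
        self.subject_ids = list(subject_ids)
        n = len(self.labels)
        self.is_augmented = (
            np.zeros(n, dtype=bool) if is_augmented is None else np.asarray(is_augmented, dtype=bool)
        )

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx) -> dict:
        return {
            m: {"x": self.batch[m]["x"][idx], "a": self.batch[m]["a"][idx]}
            for m in MODALITIES
        }

    def take(self, idx) -> "FusionDataset":
        idx = np.asarray(idx)
        return FusionDataset(
            self.batch["fmri"]["x"][idx], self.batch["fmri"]["a"][idx],
            self.batch["eeg"]["x"][idx], self.batch["eeg"]["a"][idx],
            self.labels[idx], [self.subject_ids[i] for i in idx], self.is_augmented[idx],
        )

    @classmethod
    def from_cohort(cls, cohort) -> "FusionDataset":
        graphs = {m: [build_graph(c) for c in cohort.connectivity[m]] for m in MODALITIES}
        xf, af = graphs_to_batch(graphs["fmri"])
        xe, ae = graphs_to_batch(graphs["eeg"])
        return cls(xf, af, xe, ae, cohort.outcomes, cohort.subject_ids)
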
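"""Neural Relational Inference of residue interaction graphs.

A variational autoencoder whose latent variables are categorical edge
types on the fully connected graph over residues: the encoder is a
message-passing network mapping a trajectory segment to per-ordered-pair
edge-type logits, edges are sampled with the Gumbel-softmax (concrete)
relaxation, and an MLP decoder predicts Gaussian-distributed next-frame
displacements using messages that flow only through edge types ≥ 1
(type 0 is hard-wired non-interacting). Training minimizes the ELBO:
Gaussian reconstruction error of teacher-forced rollouts plus the KL of
the edge posterior against a uniform prior.

The model, including its reverse-mode gradients, runs on
:mod:`allokit.autodiff`; no deep-learning framework is used.

The default training schedule is Adam at learning rate 5e-4 decayed by
0.2 every 200 epochs for 500 epochs with batch size 1 (the
``paper_scale`` preset); the ``ci`` preset trades that schedule for a
full-batch run at desk scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "NRIConfig", "LatentInteractionGraph", "NRIModel",
    "gumbel_softmax_sample", "train_nri", "consensus_graph",
    "NeuralRelationalInference", "reverse_sampling_check",
    "ordered_pairs",
]


@dataclass
class NRIConfig:
    """Hyperparameters of the relational-inference model and its training."""

    n_edge_types: int = 2
    hidden_dim: int = 64
    gumbel_temperature: float = 0.5
    learning_rate: float = 0.0005
    lr_decay_factor: float = 0.2
    lr_decay_every: int = 200
    epochs: int = 500
    batch_size: int | None = 1
    prediction_steps: int = 10
    output_variance: float = 5e-5
    grad_clip: float | None = 10.0
    dtype: str = "float64"
    seed: int = 0

    def __post_init__(self):
        if self.n_edge_types < 2:
            raise ValueError("n_edge_types must be ≥ 2")
        if self.gumbel_temperature <= 0:
            raise ValueError("gumbel_temperature must be > 0")
        if not 0 < self.lr_decay_factor <= 1:
            raise ValueError("lr_decay_factor must be in (0, 1]")
        for name in ("hidden_dim", "epochs", "prediction_steps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be ≥ 1")

    @classmethod
    def paper_scale(cls, **overrides) -> "NRIConfig":
        """The published training schedule (500 epochs, batch 1)."""
        return cls(**{"hidden_dim": 256, **overrides})

    @classmethod
    def ci(cls, **overrides) -> "NRIConfig":
        """Desk-scale preset: fewer epochs, full-batch Adam, larger lr."""
        defaults = dict(hidden_dim=64, epochs=100, batch_size=5,
                        learning_rate=2e-3, lr_decay_every=1000,
                        dtype="float32")
        defaults.update(overrides)
        return cls(**defaults)

    def config_hash(self) -> str:
        import hashlib
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def ordered_pairs(n_nodes: int) -> list[tuple[int, int]]:
    """All ordered (sender, receiver) pairs, diagonal excluded."""
    return [(i, j) for i in range(n_nodes) for j in range(n_nodes) if i != j]


@dataclass
class LatentInteractionGraph:
    """Per-ordered-pair edge-type probabilities inferred by the encoder.

    ``edge_probs`` has shape (n_pairs, n_edge_types) in the ordering of
    :func:`ordered_pairs`. The interaction probability of a pair is
    defined as 1 − p(type 0).
    """

    n_nodes: int
    edge_probs: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.edge_probs = np.asarray(self.edge_probs, dtype=np.float64)
        n_pairs = self.n_nodes * (self.n_nodes - 1)
        if self.edge_probs.shape[0] != n_pairs:
            raise ValueError("edge_probs row count must be n·(n−1)")
        if np.any(self.edge_probs < -1e-12):
            raise ValueError("edge probabilities must be ≥ 0")
        sums = self.edge_probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("edge-type probabilities must sum to 1")

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return ordered_pairs(self.n_nodes)

    def interaction_matrix(self) -> np.ndarray:
        """n×n matrix of interaction probabilities 1 − p(type 0); diag 0."""
        m = np.zeros((self.n_nodes, self.n_nodes))
        p_int = 1.0 - self.edge_probs[:, 0]
        for (i, j), p in zip(self.pairs, p_int):
            m[i, j] = p
        return m

    def to_files(self, prefix: str | Path) -> None:
        """Portable binary array + JSON sidecar with provenance."""
        prefix = Path(prefix)
        np.save(prefix.with_suffix(".npy"), self.edge_probs)
        prefix.with_suffix(".json").write_text(json.dumps({
            "n_nodes": self.n_nodes, "provenance": self.provenance,
            "pair_order": "row-major ordered pairs, diagonal excluded",
        }, indent=1, default=str))

    @classmethod
    def from_files(cls, prefix: str | Path) -> "LatentInteractionGraph":
        prefix = Path(prefix)
        side = json.loads(prefix.with_suffix(".json").read_text())
        return cls(side["n_nodes"], np.load(prefix.with_suffix(".npy")),
                   side.get("provenance", {}))

    def to_edge_tsv(self, path: str | Path) -> None:
        """Cytoscape-compatible edge list (1-based residue numbering)."""
        lines = ["source\ttarget\tprobability"]
        p_int = 1.0 - self.edge_probs[:, 0]
        lines += [f"{i + 1}\t{j + 1}\t{p:.6f}"
                  for (i, j), p in zip(self.pairs, p_int)]
        Path(path).write_text("\n".join(lines) + "\n")


def orient_by_locality(graph: LatentInteractionGraph,
                       mean_positions: np.ndarray
                       ) -> tuple[LatentInteractionGraph, bool]:
    """Resolve the edge-type label ambiguity using spatial locality.

    In superposed trajectories the centered coordinates sum to zero,
    so the message sum over a node's non-neighbors equals minus its
    neighbor sum: a weight-shared decoder reconstructs the dynamics
    equally well from a graph or from its complement, and training
    converges to either labeling (the same ambiguity as a sign flip
    in PCA/ICA). Physical residue interactions are short-ranged, so
    the orientation is fixed by requiring inferred interaction
    probability to *decrease* with mean inter-node distance: if the
    rank correlation is positive the edge-type columns are swapped.
    Returns the oriented graph and whether a flip was applied.
    """
    mean_positions = np.asarray(mean_positions, dtype=np.float64)
    if mean_positions.shape != (graph.n_nodes, 3):
        raise ValueError("mean_positions must be (n_nodes, 3)")
    p_int = 1.0 - graph.edge_probs[:, 0]
    dists = np.array([np.linalg.norm(mean_positions[i] - mean_positions[j])
                      for i, j in graph.pairs])
    if np.std(p_int) == 0 or np.std(dists) == 0:
        return graph, False
    rho = float(spearmanr(p_int, dists).statistic)
    if rho <= 0:
        return graph, False
    flipped = LatentInteractionGraph(
        graph.n_nodes, graph.edge_probs[:, ::-1].copy(),
        {**graph.provenance, "locality_flip": True})
    return flipped, True


def consensus_graph(graphs: list[LatentInteractionGraph]
                    ) -> LatentInteractionGraph:
    """Element-wise mean of replicate edge posteriors."""
    if not graphs:
        raise ValueError("no graphs to average")
    n = graphs[0].n_nodes
    shape = graphs[0].edge_probs.shape
    for g in graphs[1:]:
        if g.n_nodes != n or g.edge_probs.shape != shape:
            raise ValueError("graphs have mismatched shapes")
    mean = np.mean([g.edge_probs for g in graphs], axis=0)
    replicate_ids: list = []
    for g in graphs:
        replicate_ids.extend(g.provenance.get("replicate_ids", []))
    return LatentInteractionGraph(n, mean, {
        "replicate_ids": replicate_ids,
        "averaged_from": len(graphs),
    })


# --------------------------------------------------------------------
# model

def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> Tensor:
    scale = np.sqrt(6.0 / (n_in + n_out))
    return Tensor(rng.uniform(-scale, scale, size=(n_in, n_out)),
                  requires_grad=True)


def _zeros(n: int) -> Tensor:
    return Tensor(np.zeros(n), requires_grad=True)


def _batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
                eps: float = 1e-5) -> Tensor:
    """Normalize each feature over all leading axes (training-mode
    statistics; the model is always used on full segment batches)."""
    axes = tuple(range(x.ndim - 1))
    mu = x.mean(axis=axes, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=axes, keepdims=True)
    return centered * ((var + eps) ** -0.5) * gamma + beta


def _mlp(params: dict, name: str, x: Tensor) -> Tensor:
    """Two-layer MLP head without normalization (used for outputs)."""
    h = ad.elu(x @ params[f"{name}_w1"] + params[f"{name}_b1"])
    return h @ params[f"{name}_w2"] + params[f"{name}_b2"]


def _mlp_elu(params: dict, name: str, x: Tensor) -> Tensor:
    """fc → ELU → fc → ELU → batchnorm block (the encoder's
    message-passing workhorse; batch normalization keeps the
    small-signal gradients well-conditioned)."""
    h = ad.elu(x @ params[f"{name}_w1"] + params[f"{name}_b1"])
    h = ad.elu(h @ params[f"{name}_w2"] + params[f"{name}_b2"])
    return _batch_norm(h, params[f"{name}_g"], params[f"{name}_bn"])


def _mlp_elu_plain(params: dict, name: str, x: Tensor) -> Tensor:
    """fc → ELU → fc → ELU without normalization. Used for decoder
    messages: normalizing them would decouple message amplitude from
    the edge weight, letting the decoder exploit messages at near-zero
    edge probability and removing the encoder's selectivity pressure.
    """
    h = ad.elu(x @ params[f"{name}_w1"] + params[f"{name}_b1"])
    return ad.elu(h @ params[f"{name}_w2"] + params[f"{name}_b2"])


class NRIModel:
    """Encoder/decoder parameter container with forward passes.

    The node graph is fully connected; ``rel_send``/``rel_recv`` are
    fixed one-hot incidence matrices over the ordered pairs.
    """

    def __init__(self, n_nodes: int, n_frames: int, n_channels: int,
                 config: NRIConfig):
        self.n_nodes = n_nodes
        self.n_frames = n_frames
        self.n_channels = n_channels
        self.config = config
        pairs = ordered_pairs(n_nodes)
        self.rel_send = np.zeros((len(pairs), n_nodes))
        self.rel_recv = np.zeros((len(pairs), n_nodes))
        for e, (i, j) in enumerate(pairs):
            self.rel_send[e, i] = 1.0
            self.rel_recv[e, j] = 1.0
        self._send_t = Tensor(self.rel_send)
        self._recv_t = Tensor(self.rel_recv)
        self._send_tT = Tensor(self.rel_send.T)
        self._recv_tT = Tensor(self.rel_recv.T)
        rng = np.random.default_rng(config.seed)
        h, k = config.hidden_dim, config.n_edge_types
        c = n_channels
        p: dict[str, Tensor] = {}

        def add_block(name, n_in, n_out):
            p[f"{name}_w1"] = _glorot(rng, n_in, h)
            p[f"{name}_b1"] = _zeros(h)
            p[f"{name}_w2"] = _glorot(rng, h, n_out)
            p[f"{name}_b2"] = _zeros(n_out)
            p[f"{name}_g"] = Tensor(np.ones(n_out), requires_grad=True)
            p[f"{name}_bn"] = _zeros(n_out)

        def add_plain(name, n_in, n_out):
            p[f"{name}_w1"] = _glorot(rng, n_in, h)
            p[f"{name}_b1"] = _zeros(h)
            p[f"{name}_w2"] = _glorot(rng, h, n_out)
            p[f"{name}_b2"] = _zeros(n_out)

        def add_head(name, n_in, n_out):
            p[f"{name}_w1"] = _glorot(rng, n_in, h)
            p[f"{name}_b1"] = _zeros(h)
            # zero-init so the posterior starts uniform and the decoder
            # starts inert; avoids early collapse to the silent edge type
            p[f"{name}_w2"] = Tensor(np.zeros((h, n_out)),
                                     requires_grad=True)
            p[f"{name}_b2"] = _zeros(n_out)

        # encoder: node embed → edge → node → edge (with skip) → logits
        add_block("enc_node", n_frames * c, h)
        add_block("enc_edge1", 2 * h, h)
        add_block("enc_agg", h, h)
        add_block("enc_edge2", 3 * h, h)
        add_head("enc_out", h, k)
        # decoder: one message MLP per interacting edge type + output MLP
        for t in range(1, k):
            add_plain(f"dec_msg{t}", 2 * c, h)
        add_head("dec_out", h + c, c)
        if config.dtype == "float32":
            for t in p.values():
                t.data = t.data.astype(np.float32)
            for name in ("rel_send", "rel_recv"):
                setattr(self, name,
                        getattr(self, name).astype(np.float32))
            self._send_t = Tensor(self.rel_send)
            self._recv_t = Tensor(self.rel_recv)
            self._send_tT = Tensor(self.rel_send.T)
            self._recv_tT = Tensor(self.rel_recv.T)
        self.params = p

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    # ---- encoder ---------------------------------------------------
    def encode(self, segment) -> Tensor:
        """Segment (…, frames, nodes, channels) → logits (…, pairs, types)."""
        x = segment if isinstance(segment, Tensor) else Tensor(segment)
        if x.shape[-2] != self.n_nodes:
            raise ValueError(
                f"node-count mismatch: model has {self.n_nodes}, "
                f"segment has {x.shape[-2]}")
        # (…, N, T*C) node descriptors
        flat = x.swapaxes(-3, -2).reshape(
            *x.shape[:-3], self.n_nodes, x.shape[-3] * x.shape[-1])
        h_node = _mlp_elu(self.params, "enc_node", flat)
        send, recv = self._send_t, self._recv_t
        h_edge = _mlp_elu(self.params, "enc_edge1",
                          ad.concat([send @ h_node, recv @ h_node], axis=-1))
        skip = h_edge
        agg = _mlp_elu(self.params, "enc_agg",
                       self._recv_tT @ h_edge
                       * (1.0 / (self.n_nodes - 1)))
        h_edge2 = _mlp_elu(
            self.params, "enc_edge2",
            ad.concat([send @ agg, recv @ agg, skip], axis=-1))
        logits = _mlp(self.params, "enc_out", h_edge2)
        if not np.all(np.isfinite(logits.data)):
            raise FloatingPointError("encoder produced non-finite logits")
        return logits

    # ---- decoder ---------------------------------------------------
    def decode_step(self, state, edge_sample) -> Tensor:
        """One-step prediction: state (…, N, C) → state + Δ̂.

        ``edge_sample`` (…, pairs, types) weights per-type messages;
        type 0 contributes nothing by construction, so with all
        probability on type 0 each node evolves independently.
        """
        x = state if isinstance(state, Tensor) else Tensor(state)
        z = edge_sample if isinstance(edge_sample, Tensor) \
            else Tensor(edge_sample)
        if z.shape[-2] != self.n_nodes * (self.n_nodes - 1):
            raise ValueError("edge_sample pair count mismatch")
        send, recv = self._send_t, self._recv_t
        pre = ad.concat([send @ x, recv @ x], axis=-1)
        msg_sum = None
        for t in range(1, self.config.n_edge_types):
            m = _mlp_elu_plain(self.params, f"dec_msg{t}", pre)
            w = z[..., t:t + 1]
            m = m * w
            msg_sum = m if msg_sum is None else msg_sum + m
        agg = self._recv_tT @ msg_sum * (1.0 / (self.n_nodes - 1))
        delta = _mlp(self.params, "dec_out", ad.concat([agg, x], axis=-1))
        if not np.all(np.isfinite(delta.data)):
            raise FloatingPointError("decoder produced non-finite output")
        return x + delta

    def rollout(self, state, edge_sample, n_steps: int) -> list[Tensor]:
        """Chained single-step predictions (k steps = k calls exactly)."""
        out = []
        cur = state if isinstance(state, Tensor) else Tensor(state)
        for _ in range(n_steps):
            cur = self.decode_step(cur, edge_sample)
            out.append(cur)
        return out


def gumbel_softmax_sample(logits, temperature: float, seed: int | None = None,
                          hard: bool = False,
                          rng: np.random.Generator | None = None) -> Tensor:
    """Concrete-relaxation sample of a categorical edge type per pair.

    With ``hard=True`` the forward value is the exact one-hot argmax
    while the gradient follows the relaxed sample (straight-through).
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    x = logits if isinstance(logits, Tensor) else Tensor(logits)
    if rng is None:
        rng = np.random.default_rng(seed)
    u = rng.uniform(1e-12, 1.0 - 1e-12, size=x.shape)
    gumbel = (-np.log(-np.log(u))).astype(x.data.dtype)
    soft = ad.softmax((x + Tensor(gumbel)) * (1.0 / temperature), axis=-1)
    if not hard:
        return soft
    onehot = np.zeros_like(soft.data)
    idx = soft.data.argmax(axis=-1)
    np.put_along_axis(onehot, idx[..., None], 1.0, axis=-1)
    # straight-through: forward hard, backward through the soft sample
    return soft + Tensor(onehot - soft.data)


def elbo_loss(predicted: list[Tensor], targets: list[np.ndarray],
              logits: Tensor, output_variance: float,
              n_edge_types: int) -> tuple[Tensor, float, float]:
    """Gaussian NLL of predictions + KL(edge posterior ‖ uniform).

    Both terms are normalized per segment and node. Returns the total
    loss tensor plus the two components as floats.
    """
    if len(predicted) != len(targets):
        raise ValueError("prediction/target count mismatch")
    total_elems = 0
    nll = None
    for pred, tgt in zip(predicted, targets):
        diff = pred - Tensor(tgt)
        term = (diff * diff).sum()
        nll = term if nll is None else nll + term
        total_elems += tgt.size
    nll = nll * (1.0 / (2.0 * output_variance * max(total_elems, 1)))
    logq = ad.log_softmax(logits, axis=-1)
    q = ad.softmax(logits, axis=-1)
    n_pairs = logits.shape[-2]
    batch = int(np.prod(logits.shape[:-2])) if logits.ndim > 2 else 1
    kl = (q * (logq - float(np.log(1.0 / n_edge_types)))).sum() \
        * (1.0 / (batch * n_pairs))
    loss = nll + kl
    return loss, float(nll.data), float(kl.data)


# --------------------------------------------------------------------
# training

class _Adam:
    def __init__(self, params: list[Tensor], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class TrainingDiverged(RuntimeError):
    pass


def _chunk_starts(n_frames: int, steps: int) -> np.ndarray:
    return np.arange(0, n_frames - 1, steps)


def _forward_loss(model: NRIModel, batch: np.ndarray,
                  rng: np.random.Generator):
    """ELBO of one batch (B, T, N, C) of segments."""
    cfg = model.config
    logits = model.encode(batch)
    z = gumbel_softmax_sample(logits, cfg.gumbel_temperature, rng=rng,
                              hard=False)
    t_frames = batch.shape[1]
    starts = _chunk_starts(t_frames, cfg.prediction_steps)
    state = Tensor(batch[:, starts])          # (B, C_chunks, N, F)
    zb = z.reshape(z.shape[0], 1, *z.shape[1:])  # broadcast over chunks
    preds, targets = [], []
    cur = state
    for step in range(1, cfg.prediction_steps + 1):
        valid = starts + step <= t_frames - 1
        n_valid = int(valid.sum())
        if n_valid == 0:
            break
        if n_valid < len(starts):
            cur = cur[:, :n_valid]
            starts = starts[:n_valid]
        cur = model.decode_step(cur, zb)
        preds.append(cur)
        targets.append(batch[:, starts + step])
    return elbo_loss(preds, targets, logits, cfg.output_variance,
                     cfg.n_edge_types)


def edge_posterior(model: NRIModel, segments: np.ndarray) -> np.ndarray:
    """Segment-averaged softmax of encoder logits, (pairs, types)."""
    dtype = next(iter(model.params.values())).data.dtype
    logits = model.encode(np.asarray(segments, dtype=dtype))
    q = ad.softmax(logits, axis=-1).data.astype(np.float64)
    q /= q.sum(axis=-1, keepdims=True)  # exact simplex after cast
    return q.mean(axis=0) if q.ndim == 3 else q


def train_nri(segments: np.ndarray, config: NRIConfig,
              replicate_id: str | None = None, verbose: bool = False,
              node_positions: np.ndarray | None = None
              ) -> tuple[NRIModel, LatentInteractionGraph, dict]:
    """Fit the relational-inference model to windowed trajectory segments.

    ``segments`` has shape (n_segments, frames, nodes, channels).
    Returns the trained model, the segment-averaged edge posterior as a
    :class:`LatentInteractionGraph`, and a history dict with per-epoch
    loss components. Deterministic given ``config.seed``.

    If ``node_positions`` (mean coordinates, nodes × 3) is given, the
    edge-type labeling is oriented by :func:`orient_by_locality`
    before the graph is returned.
    """
    dtype = np.float32 if config.dtype == "float32" else np.float64
    segments = np.asarray(segments, dtype=dtype)
    if segments.ndim != 4:
        raise ValueError("segments must be (segments, frames, nodes, channels)")
    n_seg, t_frames, n_nodes, n_chan = segments.shape
    if n_seg < 1:
        raise ValueError("need at least one segment")
    model = NRIModel(n_nodes, t_frames, n_chan, config)
    rng = np.random.default_rng(config.seed + 1)
    opt = _Adam(model.parameters(), config.learning_rate)
    history = {"loss": [], "nll": [], "kl": [], "lr": []}
    bs = config.batch_size or n_seg
    for epoch in range(config.epochs):
        lr = config.learning_rate * config.lr_decay_factor ** (
            epoch // config.lr_decay_every)
        opt.lr = lr
        order = rng.permutation(n_seg) if bs < n_seg else np.arange(n_seg)
        ep_loss = ep_nll = ep_kl = 0.0
        n_batches = 0
        for s in range(0, n_seg, bs):
            batch = segments[order[s:s + bs]]
            opt.zero_grad()
            loss, nll, kl = _forward_loss(model, batch, rng)
            if not np.isfinite(loss.data):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch} (lr={lr:g})")
            loss.backward()
            if config.grad_clip:
                gn = np.sqrt(sum(float((p.grad ** 2).sum())
                                 for p in model.parameters()
                                 if p.grad is not None))
                if gn > config.grad_clip:
                    scale = config.grad_clip / gn
                    for p in model.parameters():
                        if p.grad is not None:
                            p.grad *= scale
            opt.step()
            ep_loss += float(loss.data)
            ep_nll += nll
            ep_kl += kl
            n_batches += 1
        history["loss"].append(ep_loss / n_batches)
        history["nll"].append(ep_nll / n_batches)
        history["kl"].append(ep_kl / n_batches)
        history["lr"].append(lr)
        if verbose and (epoch % 10 == 0 or epoch == config.epochs - 1):
            print(f"epoch {epoch:4d} loss {ep_loss / n_batches:.4f} "
                  f"lr {lr:g}")
    probs = edge_posterior(model, segments)
    graph = LatentInteractionGraph(n_nodes, probs, {
        "replicate_ids": [replicate_id] if replicate_id else [],
        "config_hash": config.config_hash(),
        "n_segments": n_seg,
    })
    if node_positions is not None:
        graph, _ = orient_by_locality(graph, node_positions)
    return model, graph, history


class NeuralRelationalInference(BaseEstimator):
    """Scikit-learn-style estimator wrapping :func:`train_nri`.

    ``fit`` takes segments of shape (n_segments, frames, nodes,
    channels); after fitting, ``graph_`` holds the inferred
    :class:`LatentInteractionGraph`, ``model_`` the trained network and
    ``history_`` the loss curve. ``transform`` returns per-segment edge
    posteriors for new segments.
    """

    def __init__(self, n_edge_types: int = 2, hidden_dim: int = 64,
                 gumbel_temperature: float = 0.5,
                 learning_rate: float = 0.0005,
                 lr_decay_factor: float = 0.2, lr_decay_every: int = 200,
                 epochs: int = 500, batch_size: int | None = 1,
                 prediction_steps: int = 10,
                 output_variance: float = 5e-5,
                 grad_clip: float | None = 10.0,
                 dtype: str = "float64", seed: int = 0):
        self.n_edge_types = n_edge_types
        self.hidden_dim = hidden_dim
        self.gumbel_temperature = gumbel_temperature
        self.learning_rate = learning_rate
        self.lr_decay_factor = lr_decay_factor
        self.lr_decay_every = lr_decay_every
        self.epochs = epochs
        self.batch_size = batch_size
        self.prediction_steps = prediction_steps
        self.output_variance = output_variance
        self.grad_clip = grad_clip
        self.dtype = dtype
        self.seed = seed

    def _config(self) -> NRIConfig:
        return NRIConfig(**self.get_params())

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 4:
            raise ValueError(
                "X must be (n_segments, frames, nodes, channels)")
        self.model_, self.graph_, self.history_ = train_nri(
            X, self._config())
        self.n_nodes_ = X.shape[2]
        return self

    def transform(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=np.float64)
        logits = self.model_.encode(X)
        return ad.softmax(logits, axis=-1).data

    def interaction_matrix(self) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "graph_")
        return self.graph_.interaction_matrix()


# --------------------------------------------------------------------
# reverse-sampling consistency

def region_cross_strength_from_graph(graph: LatentInteractionGraph,
                                     regions: dict[str, set[int]],
                                     node_ids: np.ndarray) -> np.ndarray:
    """Region × region mean interaction probability.

    ``node_ids`` maps graph node positions to residue indices (the
    graph was trained on a residue subset). Entry (A, B) is the mean
    interaction probability over ordered pairs with the sender residue
    in A and the receiver in B, self-pairs excluded.
    """
    m = graph.interaction_matrix()
    node_ids = np.asarray(node_ids)
    names = list(regions)
    out = np.full((len(names), len(names)), np.nan)
    for a, na in enumerate(names):
        ia = np.flatnonzero(np.isin(node_ids, list(regions[na])))
        for b, nb in enumerate(names):
            ib = np.flatnonzero(np.isin(node_ids, list(regions[nb])))
            vals = [m[i, j] for i in ia for j in ib if i != j]
            if vals:
                out[a, b] = float(np.mean(vals))
    return out


def reverse_sampling_check(traj, fraction: float, config: NRIConfig,
                           regions: dict[str, set[int]],
                           window: int = 50, stride: int = 100,
                           seed: int = 0) -> dict:
    """Train on a spatially uniform residue half and on its complement;
    compare region-level cross-strength matrices by rank correlation.

    Returns a dict with the Spearman score (NaN with an explanatory
    status when a matrix is constant and the correlation is undefined)
    and both matrices.
    """
    from .trajectory import sparse_sample, compute_features

    sel = sparse_sample(traj, fraction, seed=seed)
    if len(sel.complement) == 0:
        raise ValueError("fraction 1.0 leaves no reverse-sampling half")
    for name, members in regions.items():
        members = set(int(v) for v in members)
        if not members & set(sel.selected.tolist()):
            raise ValueError(f"region {name!r} has no residues in the "
                             "selected half")
        if not members & set(sel.complement.tolist()):
            raise ValueError(f"region {name!r} has no residues in the "
                             "reverse-sampling half")
    mats = []
    ca_mean = traj.ca_coords().mean(axis=0)
    for half in (sel, sel.reverse()):
        feats = compute_features(traj, half)
        segments = feats.windows(window, stride)
        _, graph, _ = train_nri(segments, config,
                                node_positions=ca_mean[half.selected])
        mats.append(region_cross_strength_from_graph(
            graph, regions, half.selected))
    a, b = (m.ravel() for m in mats)
    ok = np.isfinite(a) & np.isfinite(b)
    if np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
        return {"score": float("nan"), "status": "undefined: constant matrix",
                "matrix_selected": mats[0], "matrix_reverse": mats[1]}
    rho = float(spearmanr(a[ok], b[ok]).statistic)
    return {"score": rho, "status": "ok",
            "matrix_selected": mats[0], "matrix_reverse": mats[1]}
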
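"""Temporal Activation Expansive Neural Network (TAENN).

A single-layer gated recurrent classifier.  Per time step n (input x_n,
previous hidden h_{n-1}):

    m_n = tanh(W_mi x_n + W_mh h_{n-1})                 (memory state)
    o_n = sigmoid(W_oi x_n + W_ho h_{n-1} + W_om m_n)   (output gate)
    c_n = C_i x_n + U_p h_{n-1}                         (candidate)
    h_n = o_n * f(c_n; gamma)                           (gated hidden state)

where f is the learnable penalized tanh: f(h) = tanh(h) for h > 0 and
gamma * tanh(h) for h <= 0, with one slope gamma per hidden unit trained
alongside the weights.  Logits are W_out h_K + b_o, probabilities via
softmax.  Training is full-batch gradient descent with backpropagation
through time, cross-entropy loss plus an L1 penalty on weight matrices,
inverted dropout on hidden states (train mode only), global gradient-norm
clipping, and the exponentially decayed cosine learning-rate schedule

    lr(Ep) = exp(-theta*Ep) * (rho + (vartheta - rho)/2 *
                               (1 + cos(pi * Ep / Ep_total))).

All arithmetic is plain numpy; with a fixed seed training is bit
reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signal_io import LabeledDataset

_WEIGHT_NAMES = ("C_i", "U_p", "W_mi", "W_mh", "W_oi", "W_ho", "W_om", "W_out")


@dataclass
class TAENNParams:
    """All trainable arrays; shapes follow (input_dim d, hidden H, classes C)."""

    C_i: np.ndarray    # (H, d) candidate input weights
    U_p: np.ndarray    # (H, H) candidate recurrent weights
    W_mi: np.ndarray   # (H, d) memory input weights
    W_mh: np.ndarray   # (H, H) memory recurrent weights
    W_oi: np.ndarray   # (H, d) gate input weights
    W_ho: np.ndarray   # (H, H) gate recurrent weights
    W_om: np.ndarray   # (H, H) gate memory weights
    W_out: np.ndarray  # (C, H) hidden-to-logit weights
    b_o: np.ndarray    # (C,)   logit bias
    gamma: np.ndarray  # (H,)   learnable activation slopes

    def names(self):
        return list(_WEIGHT_NAMES) + ["b_o", "gamma"]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in self.names()}


@dataclass(frozen=True)
class TAENNHyper:
    """Training hyper-parameters (defaults are the package's study conditions)."""

    hidden_size: int = 32
    dropout_rate: float = 0.2
    theta: float = 0.01      # exponential decay rate of the LR envelope
    rho: float = 1e-3        # minimum learning rate
    vartheta: float = 0.3    # maximum learning rate (full-batch GD needs
                             # a much larger step than minibatch training)
    epochs: int = 100
    l1_lambda: float = 1e-4
    grad_clip_norm: float = 5.0
    seq_len: int = 4
    seed: int = 0
    class_weighting: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if not 0 < self.rho <= self.vartheta:
            raise ValueError("need 0 < rho <= vartheta")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainedModel:
    params: TAENNParams
    hyper: TAENNHyper
    class_names: list[str]
    history: dict = field(default_factory=dict)   # per-epoch "loss" and "lr"
    feature_mean: np.ndarray | None = None        # training standardization
    feature_sd: np.ndarray | None = None


def lr_schedule(Ep: int, hyper: TAENNHyper) -> float:
    """Exponentially decayed cosine annealing between vartheta and rho."""
    if not 0 <= Ep <= hyper.epochs:
        raise ValueError(f"epoch {Ep} outside [0, {hyper.epochs}]")
    cos_part = hyper.rho + 0.5 * (hyper.vartheta - hyper.rho) * (
        1.0 + math.cos(math.pi * Ep / hyper.epochs)
    )
    return math.exp(-hyper.theta * Ep) * cos_part


def penalized_tanh(h: np.ndarray, gamma: np.ndarray):
    """Learnable penalized tanh: value and partials w.r.t. h and gamma.

    value    = tanh(h)              if h > 0, else gamma * tanh(h)
    d/dh     = sech^2(h) * (1 if h > 0 else gamma)
    d/dgamma = 0                    if h > 0, else tanh(h)
    """
    th = np.tanh(h)
    pos = h > 0
    value = np.where(pos, th, gamma * th)
    sech2 = 1.0 - th * th
    d_dh = np.where(pos, sech2, gamma * sech2)
    d_dgamma = np.where(pos, 0.0, th)
    return value, d_dh, d_dgamma


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    p = z >= 0
    out[p] = 1.0 / (1.0 + np.exp(-z[p]))
    ez = np.exp(z[~p])
    out[~p] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def init_params(input_dim: int, hidden: int, n_classes: int,
                rng: np.random.Generator) -> TAENNParams:
    """Uniform(-1/sqrt(fan_in), +1/sqrt(fan_in)) weights; gamma starts at 0.25."""
    def u(rows, cols):
        b = 1.0 / math.sqrt(cols)
        return rng.uniform(-b, b, size=(rows, cols))

    return TAENNParams(
        C_i=u(hidden, input_dim), U_p=u(hidden, hidden),
        W_mi=u(hidden, input_dim), W_mh=u(hidden, hidden),
        W_oi=u(hidden, input_dim), W_ho=u(hidden, hidden),
        W_om=u(hidden, hidden), W_out=u(n_classes, hidden),
        b_o=np.zeros(n_classes), gamma=np.full(hidden, 0.25),
    )


def taenn_forward(
    x_seq: np.ndarray, params: TAENNParams, hyper: TAENNHyper,
    mode: str = "eval", rng: np.random.Generator | None = None,
):
    """Forward pass over a batch of sequences.

    Parameters
    ----------
    x_seq : ndarray, shape (batch, K, d) or (K, d)
        Input feature sequences.
    mode : "train" | "eval"
        Train mode applies inverted dropout to each hidden state (rng
        required); eval mode is deterministic.

    Returns
    -------
    probs : ndarray, shape (batch, C)
    cache : dict
        Intermediate states for backpropagation.
    """
    x_seq = np.asarray(x_seq, dtype=float)
    squeeze = x_seq.ndim == 2
    if squeeze:
        x_seq = x_seq[None]
    B, K, d = x_seq.shape
    H = params.C_i.shape[0]
    if d != params.C_i.shape[1]:
        raise ValueError(f"input dim {d} != model dim {params.C_i.shape[1]}")
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    drop = hyper.dropout_rate if mode == "train" else 0.0
    if drop > 0 and rng is None:
        raise ValueError("train mode with dropout needs an rng")

    h = np.zeros((B, H))
    cache = {"x": x_seq, "h": [h], "m": [], "o": [], "c": [], "fc": [],
             "dfc_dh": [], "dfc_dg": [], "mask": []}
    for n in range(K):
        x_n = x_seq[:, n, :]
        m = np.tanh(x_n @ params.W_mi.T + h @ params.W_mh.T)
        o = _sigmoid(x_n @ params.W_oi.T + h @ params.W_ho.T + m @ params.W_om.T)
        c = x_n @ params.C_i.T + h @ params.U_p.T
        fc, dfc_dh, dfc_dg = penalized_tanh(c, params.gamma)
        h_new = o * fc
        if drop > 0:
            keep = (rng.uniform(size=h_new.shape) >= drop) / (1.0 - drop)
        else:
            keep = np.ones_like(h_new)
        h = h_new * keep
        for key, val in (("m", m), ("o", o), ("c", c), ("fc", fc),
                         ("dfc_dh", dfc_dh), ("dfc_dg", dfc_dg), ("mask", keep)):
            cache[key].append(val)
        cache["h"].append(h)
    logits = h @ params.W_out.T + params.b_o
    probs = _softmax(logits)
    cache["logits"] = logits
    cache["probs"] = probs
    if squeeze:
        probs = probs[0]
    return probs, cache


def _loss_and_grads(
    x_seq: np.ndarray, y: np.ndarray, params: TAENNParams, hyper: TAENNHyper,
    rng: np.random.Generator | None, mode: str = "train",
    class_weights: np.ndarray | None = None,
):
    """Cross-entropy + L1 loss and analytic gradients via BPTT."""
    probs, cache = taenn_forward(x_seq, params, hyper, mode=mode, rng=rng)
    B, K, _ = cache["x"].shape
    C = probs.shape[1]
    w = class_weights[y] if class_weights is not None else np.ones(B)
    wsum = w.sum()
    ce = -(w * np.log(np.clip(probs[np.arange(B), y], 1e-300, None))).sum() / wsum
    l1 = sum(np.abs(getattr(params, n)).sum() for n in _WEIGHT_NAMES)
    loss = ce + hyper.l1_lambda * l1

    grads = {n: np.zeros_like(getattr(params, n)) for n in params.names()}
    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits *= (w / wsum)[:, None]
    h_K = cache["h"][-1]
    grads["W_out"] += dlogits.T @ h_K
    grads["b_o"] += dlogits.sum(axis=0)
    dh = dlogits @ params.W_out

    for n in range(K - 1, -1, -1):
        x_n = cache["x"][:, n, :]
        h_prev = cache["h"][n]
        m, o = cache["m"][n], cache["o"][n]
        fc, dfc_dh, dfc_dg = cache["fc"][n], cache["dfc_dh"][n], cache["dfc_dg"][n]
        keep = cache["mask"][n]
        dh_pre = dh * keep                 # through dropout
        do = dh_pre * fc
        dfc = dh_pre * o
        # gate pre-activation
        dzo = do * o * (1.0 - o)
        # candidate pre-activation and gamma
        dc = dfc * dfc_dh
        grads["gamma"] += (dfc * dfc_dg).sum(axis=0)
        # memory path: m feeds the gate
        dm = dzo @ params.W_om
        dzm = dm * (1.0 - m * m)
        grads["C_i"] += dc.T @ x_n
        grads["U_p"] += dc.T @ h_prev
        grads["W_oi"] += dzo.T @ x_n
        grads["W_ho"] += dzo.T @ h_prev
        grads["W_om"] += dzo.T @ m
        grads["W_mi"] += dzm.T @ x_n
        grads["W_mh"] += dzm.T @ h_prev
        dh = dc @ params.U_p + dzo @ params.W_ho + dzm @ params.W_mh
    for n in _WEIGHT_NAMES:
        grads[n] += hyper.l1_lambda * np.sign(getattr(params, n))
    return loss, grads, probs


def _clip(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = math.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


def _to_sequences(dataset: LabeledDataset, seq_len: int):
    """Shape each instance into a (K, d) sequence.

    2-D instances are taken as ready-made sequences; 1-D feature vectors
    become length-1 sequences (the recurrence degenerates gracefully).
    """
    seqs = []
    for x, _ in dataset.instances:
        arr = np.asarray(x, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        seqs.append(arr)
    shapes = {s.shape for s in seqs}
    if len(shapes) != 1:
        raise ValueError(f"instances have inconsistent shapes: {shapes}")
    return np.stack(seqs)


def taenn_train(dataset: LabeledDataset, hyper: TAENNHyper | None = None) -> TrainedModel:
    """Train a TAENN on a labeled dataset by full-batch gradient descent."""
    hyper = hyper or TAENNHyper()
    class_names = list(dataset.class_names)
    if len(set(dataset.labels)) < 2:
        raise ValueError("training needs at least 2 classes present")
    X = _to_sequences(dataset, hyper.seq_len)
    y = np.array([class_names.index(lab) for lab in dataset.labels])
    B, K, d = X.shape
    mean = X.reshape(-1, d).mean(axis=0)
    sd = X.reshape(-1, d).std(axis=0)
    sd[sd == 0] = 1.0
    Xn = (X - mean) / sd

    rng = np.random.default_rng(hyper.seed)
    params = init_params(d, hyper.hidden_size, len(class_names), rng)
    cw = None
    if hyper.class_weighting:
        counts = np.bincount(y, minlength=len(class_names)).astype(float)
        cw = counts.sum() / (len(counts) * np.maximum(counts, 1))
    history = {"loss": [], "lr": []}
    for ep in range(hyper.epochs):
        lr = lr_schedule(ep, hyper)
        loss, grads, _ = _loss_and_grads(Xn, y, params, hyper, rng,
                                         mode="train", class_weights=cw)
        _clip(grads, hyper.grad_clip_norm)
        for name in params.names():
            getattr(params, name).__isub__(lr * grads[name])
        history["loss"].append(float(loss))
        history["lr"].append(lr)
        if not all(np.all(np.isfinite(getattr(params, n))) for n in params.names()):
            raise FloatingPointError(f"non-finite parameters at epoch {ep}")
    return TrainedModel(params=params, hyper=hyper, class_names=class_names,
                        history=history, feature_mean=mean, feature_sd=sd)


def taenn_predict(model: TrainedModel, instances) -> tuple[list[str], np.ndarray]:
    """Predict labels and class probabilities (dropout disabled).

    ``instances`` may be a LabeledDataset, a list of arrays, or a stacked
    (batch, K, d) / (batch, d) array.  Ties pick the lowest class index.
    """
    if isinstance(instances, LabeledDataset):
        X = _to_sequences(instances, model.hyper.seq_len)
    else:
        arrs = [np.asarray(a, dtype=float) for a in instances]
        arrs = [a[None, :] if a.ndim == 1 else a for a in arrs]
        X = np.stack(arrs)
    if X.shape[-1] != model.params.C_i.shape[1]:
        raise ValueError(
            f"feature dim {X.shape[-1]} != model dim {model.params.C_i.shape[1]}"
        )
    if model.feature_mean is not None:
        X = (X - model.feature_mean) / model.feature_sd
    probs, _ = taenn_forward(X, model.params, model.hyper, mode="eval")
    idx = np.argmax(probs, axis=1)   # argmax returns the lowest tied index
    labels = [model.class_names[i] for i in idx]
    return labels, probs


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a model to JSON (metadata + flat arrays), bit-exact."""
    blob = {
        "class_names": model.class_names,
        "hyper": {k: getattr(model.hyper, k) for k in (
            "hidden_size", "dropout_rate", "theta", "rho", "vartheta",
            "epochs", "l1_lambda", "grad_clip_norm", "seq_len", "seed",
            "class_weighting")},
        "params": {n: {"shape": list(getattr(model.params, n).shape),
                       "data": getattr(model.params, n).ravel().tolist()}
                   for n in model.params.names()},
        "feature_mean": None if model.feature_mean is None else model.feature_mean.tolist(),
        "feature_sd": None if model.feature_sd is None else model.feature_sd.tolist(),
        "history": model.history,
    }
    Path(path).write_text(json.dumps(blob))


def load_model(path: str | Path) -> TrainedModel:
    blob = json.loads(Path(path).read_text())
    params = TAENNParams(**{
        n: np.array(v["data"]).reshape(v["shape"])
        for n, v in blob["params"].items()
    })
    model = TrainedModel(
        params=params, hyper=TAENNHyper(**blob["hyper"]),
        class_names=blob["class_names"], history=blob.get("history", {}),
        feature_mean=None if blob["feature_mean"] is None else np.array(blob["feature_mean"]),
        feature_sd=None if blob["feature_sd"] is None else np.array(blob["feature_sd"]),
    )
    return model
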
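"""BiLSTM sequence-to-sequence behavior classifier.

Architecture: sequence input (512-d spatiotemporal features per frame)
→ BiLSTM → dropout(0.5) → BiLSTM → dropout(0.5) → fully-connected(K)
→ softmax, trained with cross-entropy over K mutually exclusive behaviors.
Clips are cut into ~15-second sequences before training to limit
overfitting and padding waste; predictions are re-concatenated per clip.

Training follows a fixed schedule: Adam, initial learning rate 1e-3 dropped
by 10× every 4 epochs, minibatches of 8 sequences, at most 16 epochs, with
early stopping once the validation loss has been ≥ its running minimum more
than twice (patience 2); the parameters from the best-validation epoch are
restored.

The network, backpropagation through time, and the optimizer are
implemented directly in numpy so training is single-threaded, deterministic
and dependency-light.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax as _softmax

from .project import BehaviorSet, round_half_away_from_zero

__all__ = [
    "Hyperparameters",
    "BiLSTMNetwork",
    "TrainedSequenceModel",
    "PredictionResult",
    "build_network",
    "split_into_sequences",
    "train",
    "predict",
    "learning_rate_schedule",
    "early_stop_epoch",
]


@dataclass(frozen=True)
class Hyperparameters:
    """Training schedule defaults."""

    max_epochs: int = 16
    validation_frequency: int = 1  # evaluations per epoch
    validation_patience: int = 2
    initial_lr: float = 1e-3
    lr_drop_period: int = 4
    lr_drop_factor: float = 0.1
    minibatch_size: int = 8
    dropout: float = 0.5
    hidden_units: int = 128  # per direction, per BiLSTM layer
    sequence_seconds: float = 15.0

    def __post_init__(self):
        if not 0 < self.lr_drop_factor < 1:
            raise ValueError("lr_drop_factor must be in (0, 1)")
        for name in ("max_epochs", "validation_patience", "initial_lr",
                     "lr_drop_period", "minibatch_size", "hidden_units",
                     "sequence_seconds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def learning_rate_schedule(epoch: int, hp: Hyperparameters) -> float:
    """Learning rate for 1-based ``epoch``: drops 10× every 4 epochs."""
    return hp.initial_lr * hp.lr_drop_factor ** ((epoch - 1) // hp.lr_drop_period)


def early_stop_epoch(val_losses, patience: int = 2) -> int | None:
    """Epoch (1-based) after which the patience rule terminates training.

    Training stops once the number of epochs whose validation loss is
    ≥ the smallest loss of any *earlier* epoch exceeds ``patience``.
    Returns None if the rule never fires on the given trace.
    """
    best = np.inf
    count = 0
    for e, loss in enumerate(val_losses, start=1):
        if loss >= best:
            count += 1
            if count > patience:
                return e
        best = min(best, loss)
    return None


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _reverse_padded(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each sequence in a padded batch within its true length."""
    out = np.zeros_like(x)
    for b, L in enumerate(lengths):
        out[b, :L] = x[b, L - 1::-1]
    return out


def _lstm_forward(x, Wx, Wh, b):
    """Run an LSTM over (B, T, d) inputs; returns hidden states and caches."""
    B, T, _ = x.shape
    H = Wh.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    hs = np.zeros((B, T, H))
    cache = {k: np.zeros((B, T, H)) for k in ("i", "f", "g", "o", "c", "tc", "cp", "hp")}
    for t in range(T):
        a = x[:, t] @ Wx + h @ Wh + b
        i = _sigmoid(a[:, :H])
        f = _sigmoid(a[:, H:2 * H])
        g = np.tanh(a[:, 2 * H:3 * H])
        o = _sigmoid(a[:, 3 * H:])
        cache["cp"][:, t] = c
        cache["hp"][:, t] = h
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        hs[:, t] = h
        for k, v in (("i", i), ("f", f), ("g", g), ("o", o), ("c", c), ("tc", tc)):
            cache[k][:, t] = v
    return hs, cache


def _lstm_backward(dh_out, x, cache, Wx, Wh):
    """BPTT through one LSTM direction; returns dx and parameter grads."""
    B, T, H = dh_out.shape
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dx = np.zeros_like(x)
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        i, f, g, o = (cache[k][:, t] for k in ("i", "f", "g", "o"))
        tc, cp, hp = (cache[k][:, t] for k in ("tc", "cp", "hp"))
        dh = dh_out[:, t] + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_next
        da = np.concatenate(
            [
                dc * g * i * (1.0 - i),
                dc * cp * f * (1.0 - f),
                dc * i * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dWx += x[:, t].T @ da
        dWh += hp.T @ da
        db += da.sum(axis=0)
        dx[:, t] = da @ Wx.T
        dh_next = da @ Wh.T
        dc_next = dc * f
    return dx, dWx, dWh, db


class BiLSTMNetwork:
    """Two stacked (Bi)LSTM layers with dropout and a per-frame softmax head."""

    def __init__(
        self,
        K: int,
        d_in: int = 512,
        hidden_units: int = 128,
        dropout: float = 0.5,
        n_layers: int = 2,
        bidirectional: bool = True,
        seed: int = 0,
    ):
        if K < 2:
            raise ValueError("need at least 2 classes")
        self.K = K
        self.d_in = d_in
        self.H = hidden_units
        self.dropout = dropout
        self.n_layers = n_layers
        self.bidirectional = bidirectional
        self.seed = seed
        self.directions = ("fwd", "bwd") if bidirectional else ("fwd",)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        d = d_in
        for layer in range(n_layers):
            for dirn in self.directions:
                s = 1.0 / np.sqrt(d)
                self.params[f"Wx{layer}{dirn}"] = rng.uniform(-s, s, (d, 4 * self.H))
                self.params[f"Wh{layer}{dirn}"] = rng.uniform(
                    -1.0 / np.sqrt(self.H), 1.0 / np.sqrt(self.H), (self.H, 4 * self.H)
                )
                b = np.zeros(4 * self.H)
                b[self.H:2 * self.H] = 1.0  # forget-gate bias
                self.params[f"b{layer}{dirn}"] = b
            d = self.H * len(self.directions)
        s = 1.0 / np.sqrt(d)
        self.params["Wd"] = rng.uniform(-s, s, (d, K))
        self.params["bd"] = np.zeros(K)

    def forward(self, x, lengths, train: bool = False, rng=None):
        """Compute per-frame logits for a padded batch (B, T, d_in).

        In training mode, inverted dropout is applied after each (Bi)LSTM
        layer using ``rng``; in eval mode two identical calls agree exactly.
        """
        lengths = np.asarray(lengths)
        cache = {"x": x, "lengths": lengths, "layers": []}
        h = x
        for layer in range(self.n_layers):
            layer_cache = {"in": h}
            outs = []
            for dirn in self.directions:
                hin = _reverse_padded(h, lengths) if dirn == "bwd" else h
                hs, c = _lstm_forward(
                    hin,
                    self.params[f"Wx{layer}{dirn}"],
                    self.params[f"Wh{layer}{dirn}"],
                    self.params[f"b{layer}{dirn}"],
                )
                layer_cache[dirn] = (hin, c)
                outs.append(_reverse_padded(hs, lengths) if dirn == "bwd" else hs)
            h = np.concatenate(outs, axis=2)
            if train and self.dropout > 0:
                mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                h = h * mask
                layer_cache["drop"] = mask
            layer_cache["out"] = h
            cache["layers"].append(layer_cache)
        logits = h @ self.params["Wd"] + self.params["bd"]
        cache["head_in"] = h
        return logits, cache

    def backward(self, cache, dlogits):
        """Gradients of the loss w.r.t. all parameters, given dL/dlogits."""
        grads = {}
        grads["Wd"] = np.einsum("btd,btk->dk", cache["head_in"], dlogits)
        grads["bd"] = dlogits.sum(axis=(0, 1))
        dh = dlogits @ self.params["Wd"].T
        lengths = cache["lengths"]
        for layer in range(self.n_layers - 1, -1, -1):
            lc = cache["layers"][layer]
            if "drop" in lc:
                dh = dh * lc["drop"]
            dnext = np.zeros_like(lc["in"])
            for d_idx, dirn in enumerate(self.directions):
                dh_dir = dh[:, :, d_idx * self.H:(d_idx + 1) * self.H]
                if dirn == "bwd":
                    dh_dir = _reverse_padded(dh_dir, lengths)
                hin, c = lc[dirn]
                dx, dWx, dWh, db = _lstm_backward(
                    dh_dir, hin, c,
                    self.params[f"Wx{layer}{dirn}"],
                    self.params[f"Wh{layer}{dirn}"],
                )
                if dirn == "bwd":
                    dx = _reverse_padded(dx, lengths)
                dnext += dx
                grads[f"Wx{layer}{dirn}"] = dWx
                grads[f"Wh{layer}{dirn}"] = dWh
                grads[f"b{layer}{dirn}"] = db
            dh = dnext
        return grads


def build_network(
    K: int,
    d_in: int = 512,
    hidden_units: int = 128,
    dropout: float = 0.5,
    bidirectional: bool = True,
    seed: int = 0,
) -> BiLSTMNetwork:
    """Construct the untrained two-layer BiLSTM classifier."""
    return BiLSTMNetwork(
        K=K, d_in=d_in, hidden_units=hidden_units, dropout=dropout,
        bidirectional=bidirectional, seed=seed,
    )


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def split_into_sequences(
    features: np.ndarray,
    labels: np.ndarray | None,
    fps: float,
    sequence_seconds: float = 15.0,
):
    """Cut a clip into consecutive ~15-s sequences.

    The final sequence keeps the remainder; concatenating the pieces
    reconstructs the clip exactly.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    features = np.asarray(features)
    if features.shape[0] == 0:
        raise ValueError("empty clip")
    seq_len = max(1, round_half_away_from_zero(sequence_seconds * fps))
    out = []
    for lo in range(0, features.shape[0], seq_len):
        hi = min(lo + seq_len, features.shape[0])
        y = None if labels is None else np.asarray(labels)[lo:hi]
        out.append((features[lo:hi], y))
    return out


def _pad_batch(seqs):
    """Pad variable-length (x, y) sequences to a common length with a mask."""
    B = len(seqs)
    T = max(x.shape[0] for x, _ in seqs)
    d = seqs[0][0].shape[1]
    x = np.zeros((B, T, d))
    y = np.zeros((B, T), dtype=np.int64)
    mask = np.zeros((B, T), dtype=bool)
    lengths = np.zeros(B, dtype=np.int64)
    for b, (xs, ys) in enumerate(seqs):
        L = xs.shape[0]
        x[b, :L] = xs
        if ys is not None:
            y[b, :L] = ys
        mask[b, :L] = True
        lengths[b] = L
    return x, y, mask, lengths


def _masked_ce_loss(logits, y, mask):
    """Mean cross-entropy over valid frames and its gradient w.r.t. logits."""
    zmax = logits.max(axis=2, keepdims=True)
    logp = logits - zmax - np.log(np.exp(logits - zmax).sum(axis=2, keepdims=True))
    n_valid = int(mask.sum())
    nll = -np.take_along_axis(logp, y[..., None], axis=2)[..., 0]
    loss = float((nll * mask).sum() / n_valid)
    dlogits = np.exp(logp)
    rows = np.arange(y.shape[0])[:, None], np.arange(y.shape[1])[None, :]
    onehot = np.zeros_like(dlogits)
    onehot[rows[0], rows[1], y] = 1.0
    dlogits = (dlogits - onehot) * mask[..., None] / n_valid
    return loss, dlogits


class _Adam:
    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params, grads, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------

@dataclass
class TrainedSequenceModel:
    """A trained classifier plus its training log and provenance."""

    network: BiLSTMNetwork
    behavior_set: BehaviorSet
    fps: float
    sequence_seconds: float
    log: list[dict] = field(default_factory=list)
    stopping_reason: str = "max_epochs"
    best_epoch: int = 0
    seed: int = 0


@dataclass
class PredictionResult:
    """Per-frame logits, probabilities and argmax labels for one clip."""

    logits: np.ndarray  # (n, K)
    probabilities: np.ndarray  # (n, K)
    label_indices: np.ndarray  # (n,)
    labels: np.ndarray  # (n,) behavior names

    @property
    def n_frames(self) -> int:
        return self.logits.shape[0]


def _eval_loss(network, seqs, batch_size):
    total, n = 0.0, 0
    for lo in range(0, len(seqs), batch_size):
        x, y, mask, lengths = _pad_batch(seqs[lo:lo + batch_size])
        logits, _ = network.forward(x, lengths, train=False)
        loss, _ = _masked_ce_loss(logits, y, mask)
        k = int(mask.sum())
        total += loss * k
        n += k
    return total / n


def train(
    network: BiLSTMNetwork,
    train_clips: dict,
    validate_clips: dict,
    behavior_set: BehaviorSet,
    fps: float,
    hp: Hyperparameters = Hyperparameters(),
    seed: int = 0,
) -> TrainedSequenceModel:
    """Train the classifier on labeled clips with early stopping.

    ``train_clips`` / ``validate_clips`` map clip_id → (features [n×d],
    labels [n] of behavior names).  Minibatches mix sequences across clips,
    reshuffled every epoch from the run seed.  Returns the parameters of the
    epoch with the lowest validation loss.
    """
    if not train_clips or not validate_clips:
        raise ValueError("both training and validation sets must be non-empty")

    def clip_seqs(clips):
        seqs = []
        for cid in sorted(clips):
            feats, labels = clips[cid]
            y = behavior_set.to_indices(labels)
            seqs.extend(split_into_sequences(feats, y, fps, hp.sequence_seconds))
        return seqs

    train_seqs = clip_seqs(train_clips)
    val_seqs = clip_seqs(validate_clips)

    all_train_labels = np.concatenate([y for _, y in train_seqs])
    if len(np.unique(all_train_labels)) < 2:
        warnings.warn(
            "training labels contain a single class; the classifier will be "
            "degenerate", UserWarning, stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    opt = _Adam(network.params)
    log: list[dict] = []
    best_loss = np.inf
    best_params = copy.deepcopy(network.params)
    best_epoch = 0
    patience_count = 0
    stopping_reason = "max_epochs"

    for epoch in range(1, hp.max_epochs + 1):
        lr = learning_rate_schedule(epoch, hp)
        order = rng.permutation(len(train_seqs))
        epoch_loss, n_frames = 0.0, 0
        for lo in range(0, len(order), hp.minibatch_size):
            batch = [train_seqs[i] for i in order[lo:lo + hp.minibatch_size]]
            x, y, mask, lengths = _pad_batch(batch)
            logits, cache = network.forward(x, lengths, train=True, rng=rng)
            loss, dlogits = _masked_ce_loss(logits, y, mask)
            grads = network.backward(cache, dlogits)
            opt.step(network.params, grads, lr)
            k = int(mask.sum())
            epoch_loss += loss * k
            n_frames += k
        val_loss = _eval_loss(network, val_seqs, hp.minibatch_size)
        log.append(
            {
                "epoch": epoch,
                "learning_rate": lr,
                "train_loss": epoch_loss / n_frames,
                "val_loss": val_loss,
            }
        )
        # patience rule: count epochs with val_loss >= smallest earlier loss
        if val_loss >= best_loss:
            patience_count += 1
        else:
            best_loss = val_loss
            best_params = copy.deepcopy(network.params)
            best_epoch = epoch
        if patience_count > hp.validation_patience:
            stopping_reason = "patience"
            break

    network.params = best_params
    return TrainedSequenceModel(
        network=network,
        behavior_set=behavior_set,
        fps=fps,
        sequence_seconds=hp.sequence_seconds,
        log=log,
        stopping_reason=stopping_reason,
        best_epoch=best_epoch,
        seed=seed,
    )


def predict(model: TrainedSequenceModel, features: np.ndarray) -> PredictionResult:
    """Per-frame predictions for one clip.

    The clip is processed in the same ~15-s sequences used in training and
    the outputs re-concatenated, so an n-frame clip yields n labels.
    """
    features = np.asarray(features)
    net = model.network
    if features.ndim != 2 or features.shape[1] != net.d_in:
        raise ValueError(
            f"features must be (n, {net.d_in}), got {features.shape}"
        )
    seqs = split_into_sequences(features, None, model.fps, model.sequence_seconds)
    pieces = []
    for lo in range(0, len(seqs), 8):
        x, _, mask, lengths = _pad_batch(seqs[lo:lo + 8])
        logits, _ = net.forward(x, lengths, train=False)
        for b, L in enumerate(lengths):
            pieces.append(logits[b, :L])
    logits = np.concatenate(pieces, axis=0)
    probs = _softmax(logits, axis=1)
    idx = probs.argmax(axis=1)
    return PredictionResult(
        logits=logits,
        probabilities=probs,
        label_indices=idx,
        labels=model.behavior_set.to_labels(idx),
    )
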
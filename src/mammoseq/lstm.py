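"""Variable-length sequence classification with a gated LSTM, in NumPy.

One LSTM layer processes each case's chronologically ordered (oldest to
newest) per-exam feature vectors.  The cell follows the standard gated
recurrence: with sigmoid gates and tanh activations,

    i_t = sigmoid(W_i h_{t-1} + U_i x_t + b_i)      input gate
    o_t = sigmoid(W_o h_{t-1} + U_o x_t + b_o)      output gate
    f_t = sigmoid(W_f h_{t-1} + U_f x_t + b_f)      forget gate
    g_t = tanh   (W_g h_{t-1} + U_g x_t + b_g)      candidate
    c_t = f_t * c_{t-1} + i_t * g_t
    h_t = o_t * tanh(c_t)

A per-step sigmoid read-out gives P(future malignant) at every exam; the
per-case score is the read-out at the last *valid* step.  Sequences are
zero-padded at the tail to the batch's longest length, and the binary
cross-entropy loss is computed over valid steps only (the padded part never
contributes to loss or gradients), so predictions and loss are exactly
invariant to extra padding.

Training is plain minibatch stochastic gradient descent,
``theta <- theta - alpha * grad(J)``, with analytic backpropagation through
time; no momentum, weight decay or early stopping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .imaging import Case

CLIP = 1e-7  # read-out probabilities are clipped to [CLIP, 1-CLIP] in the loss


@dataclass
class LSTMConfig:
    """Training hyperparameters.

    Defaults follow the selected operating point of the hyperparameter sweep
    the method prescribes (hidden 512, learning rate 1e-4, 100 epochs of SGD,
    batches of 8).  ``loss_reduction`` chooses whether the masked BCE
    averages over valid steps in the batch ("per_step", default) or first
    within each sequence ("per_sequence").
    """

    hidden_dim: int = 512
    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 8
    seed: int = 0
    loss_reduction: str = "per_step"

    def __post_init__(self) -> None:
        if self.hidden_dim < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("hidden_dim, epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.loss_reduction not in ("per_step", "per_sequence"):
            raise ValueError("loss_reduction must be 'per_step' or 'per_sequence'")


@dataclass
class FeatureSequence:
    """Time-ordered per-exam feature vectors for one case and one breast."""

    case_id: str
    label: int
    laterality: str
    times: np.ndarray          # exam times, years, strictly increasing
    features: np.ndarray       # (n_exams, dim)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        if len(self.times) != self.features.shape[0]:
            raise ValueError("times and features disagree on sequence length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("exam times must be strictly increasing")

    def __len__(self) -> int:
        return self.features.shape[0]


@dataclass
class PaddedSequenceBatch:
    """Zero-padded feature block with validity mask (post-padding)."""

    features: np.ndarray   # (n_cases, max_len, dim)
    mask: np.ndarray       # (n_cases, max_len), 1 = valid, ones first
    labels: np.ndarray     # (n_cases,)
    lengths: np.ndarray    # (n_cases,)
    case_ids: list[str] = field(default_factory=list)


def sequences_from_cases(cases: list[Case], laterality: str) -> list[FeatureSequence]:
    """Build per-breast feature sequences from cases with array payloads.

    ``laterality`` is ``"affected"``, ``"contralateral"``, ``"left"`` or
    ``"right"``.  Exams are sorted chronologically regardless of input order.
    """
    out = []
    for case in cases:
        if laterality == "affected":
            side = case.affected_laterality
        elif laterality == "contralateral":
            side = case.contralateral()
        elif laterality in ("left", "right"):
            side = laterality
        else:
            raise ValueError(f"unknown laterality {laterality!r}")
        exams = sorted(case.exams, key=lambda e: e.date_years)
        feats = np.stack([np.asarray(e.side(side), dtype=float) for e in exams])
        times = np.array([e.date_years for e in exams])
        out.append(FeatureSequence(case.case_id, case.y, side, times, feats))
    return out


# ---------------------------------------------------------------------------
# Padding, masking, standardization
# ---------------------------------------------------------------------------

def pad_and_mask(sequences: list[FeatureSequence]) -> PaddedSequenceBatch:
    """Zero-pad sequences at the tail to the longest length, with a mask."""
    if not sequences:
        raise ValueError("no sequences")
    dims = {s.features.shape[1] for s in sequences}
    if len(dims) != 1:
        raise ValueError(f"inconsistent feature dimensions: {sorted(dims)}")
    dim = dims.pop()
    lengths = np.array([len(s) for s in sequences])
    max_len = int(lengths.max())
    n = len(sequences)
    feats = np.zeros((n, max_len, dim))
    mask = np.zeros((n, max_len))
    for k, s in enumerate(sequences):
        feats[k, : len(s)] = s.features
        mask[k, : len(s)] = 1.0
    labels = np.array([s.label for s in sequences])
    return PaddedSequenceBatch(feats, mask, labels, lengths,
                               [s.case_id for s in sequences])


@dataclass
class Standardizer:
    """Per-feature z-scoring statistics, fit on valid training steps only."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, batch: PaddedSequenceBatch) -> "Standardizer":
        valid = batch.mask.astype(bool)
        x = batch.features[valid]  # (n_valid_steps, dim)
        mean = x.mean(axis=0)
        scale = x.std(axis=0)
        zero_var = scale <= 1e-12
        if zero_var.any():
            warnings.warn(f"{int(zero_var.sum())} zero-variance feature(s); scale set to 1")
            scale = np.where(zero_var, 1.0, scale)
        return cls(mean, scale)

    def apply(self, batch: PaddedSequenceBatch) -> PaddedSequenceBatch:
        z = (batch.features - self.mean) / self.scale
        z *= batch.mask[..., None]  # padded entries stay exactly 0
        return PaddedSequenceBatch(z, batch.mask, batch.labels, batch.lengths,
                                   batch.case_ids)


def standardize(
    batch: PaddedSequenceBatch, stats: Standardizer | None = None
) -> tuple[PaddedSequenceBatch, Standardizer]:
    """Z-score a batch with training-fold statistics (fit here if absent)."""
    if stats is None:
        stats = Standardizer.fit(batch)
    return stats.apply(batch), stats


# ---------------------------------------------------------------------------
# Parameters, forward, loss, backward
# ---------------------------------------------------------------------------

GATES = ("i", "f", "o", "g")


def init_params(dim: int, hidden_dim: int, seed: int = 0) -> dict[str, np.ndarray]:
    """Glorot-scaled gate weights; forget-gate bias starts at 1 (standard)."""
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    for gate in GATES:
        params[f"U_{gate}"] = rng.normal(0, np.sqrt(1.0 / dim), (dim, hidden_dim))
        params[f"W_{gate}"] = rng.normal(0, np.sqrt(1.0 / hidden_dim),
                                         (hidden_dim, hidden_dim))
        params[f"b_{gate}"] = np.zeros(hidden_dim)
    params["b_f"] = np.ones(hidden_dim)
    params["w_y"] = rng.normal(0, np.sqrt(1.0 / hidden_dim), hidden_dim)
    params["b_y"] = np.zeros(1)
    return params


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def lstm_forward(
    batch: PaddedSequenceBatch, params: dict[str, np.ndarray], return_cache: bool = False
):
    """Run the recurrence; return per-step probabilities and per-case scores.

    Outputs have shape (n_cases, max_len); the per-case score is the read-out
    at each sequence's last valid step, so appending padded steps can never
    change it.
    """
    x = batch.features
    n, T, dim = x.shape
    hd = params["W_i"].shape[0]
    if params["U_i"].shape[0] != dim:
        raise ValueError(
            f"feature dim mismatch: params expect {params['U_i'].shape[0]}, got {dim}"
        )
    h = np.zeros((n, hd))
    c = np.zeros((n, hd))
    probs = np.zeros((n, T))
    cache = []
    for t in range(T):
        xt = x[:, t, :]
        a = {g: xt @ params[f"U_{g}"] + h @ params[f"W_{g}"] + params[f"b_{g}"]
             for g in GATES}
        i = _sigmoid(a["i"])
        f = _sigmoid(a["f"])
        o = _sigmoid(a["o"])
        g = np.tanh(a["g"])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        z = h_new @ params["w_y"] + params["b_y"][0]
        probs[:, t] = _sigmoid(z)
        if return_cache:
            cache.append((xt, h, c, i, f, o, g, c_new, tc, h_new))
        h, c = h_new, c_new
    last = np.maximum(batch.lengths - 1, 0)
    scores = probs[np.arange(n), last]
    if return_cache:
        return probs, scores, cache
    return probs, scores


def masked_bce(
    probs: np.ndarray, labels: np.ndarray, mask: np.ndarray,
    reduction: str = "per_step",
) -> float:
    """Binary cross-entropy against the case label over valid steps only.

    "per_step": summed over valid steps, divided by the total number of valid
    steps in the batch.  "per_sequence": averaged within each sequence first,
    then across sequences.  Probabilities are clipped to [1e-7, 1-1e-7].
    """
    p = np.clip(probs, CLIP, 1.0 - CLIP)
    y = labels[:, None]
    ll = -(y * np.log(p) + (1 - y) * np.log(1 - p)) * mask
    if reduction == "per_step":
        return float(ll.sum() / mask.sum())
    per_seq = ll.sum(axis=1) / mask.sum(axis=1)
    return float(per_seq.mean())


def loss_and_grads(
    batch: PaddedSequenceBatch, params: dict[str, np.ndarray],
    reduction: str = "per_step",
) -> tuple[float, dict[str, np.ndarray]]:
    """Masked BCE and its analytic gradients by backpropagation through time."""
    probs, _, cache = lstm_forward(batch, params, return_cache=True)
    loss = masked_bce(probs, batch.labels, batch.mask, reduction)

    n, T = probs.shape
    y = batch.labels[:, None]
    p = np.clip(probs, CLIP, 1.0 - CLIP)
    # d(loss)/d(readout logit); the clip zeroes the gradient where saturated
    dz = (p - y) * batch.mask
    inside = (probs > CLIP) & (probs < 1.0 - CLIP)
    dz *= inside
    if reduction == "per_step":
        dz /= batch.mask.sum()
    else:
        dz = dz / batch.mask.sum(axis=1)[:, None] / n

    grads = {k: np.zeros_like(v) for k, v in params.items()}
    hd = params["W_i"].shape[0]
    dh_next = np.zeros((n, hd))
    dc_next = np.zeros((n, hd))
    for t in range(T - 1, -1, -1):
        xt, h_prev, c_prev, i, f, o, g, c_new, tc, h_new = cache[t]
        dzt = dz[:, t]
        grads["w_y"] += h_new.T @ dzt
        grads["b_y"][0] += dzt.sum()
        dh = dzt[:, None] * params["w_y"] + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc**2) + dc_next
        df = dc * c_prev
        di = dc * g
        dg = dc * i
        da = {
            "i": di * i * (1.0 - i),
            "f": df * f * (1.0 - f),
            "o": do * o * (1.0 - o),
            "g": dg * (1.0 - g**2),
        }
        dh_next = np.zeros((n, hd))
        for gate in GATES:
            grads[f"U_{gate}"] += xt.T @ da[gate]
            grads[f"W_{gate}"] += h_prev.T @ da[gate]
            grads[f"b_{gate}"] += da[gate].sum(axis=0)
            dh_next += da[gate] @ params[f"W_{gate}"].T
        dc_next = dc * f
    return loss, grads


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

@dataclass
class LSTMModel:
    params: dict[str, np.ndarray]
    config: LSTMConfig
    stats: Standardizer
    dim: int
    loss_history: list[float] = field(default_factory=list)


def train(config: LSTMConfig, sequences: list[FeatureSequence]) -> LSTMModel:
    """Minibatch SGD on the masked BCE; reproducible given ``config.seed``."""
    labels = {s.label for s in sequences}
    if labels != {0, 1}:
        raise ValueError("training data must contain both classes")
    full = pad_and_mask(sequences)
    full, stats = standardize(full)
    dim = full.features.shape[2]
    params = init_params(dim, config.hidden_dim, seed=config.seed)
    rng = np.random.default_rng(config.seed + 1)
    n = len(sequences)
    history = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            sub = PaddedSequenceBatch(
                full.features[sel], full.mask[sel], full.labels[sel],
                full.lengths[sel], [full.case_ids[k] for k in sel],
            )
            loss, grads = loss_and_grads(sub, params, config.loss_reduction)
            for k in params:
                params[k] -= config.learning_rate * grads[k]
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / n_batches)
    return LSTMModel(params, config, stats, dim, history)


def predict(model: LSTMModel, sequence: FeatureSequence) -> float:
    """Risk score in [0, 1]: read-out at the last valid step."""
    if len(sequence) < 1:
        raise ValueError("sequence must have at least one exam")
    if sequence.features.shape[1] != model.dim:
        raise ValueError(
            f"feature dim mismatch: model expects {model.dim}, "
            f"got {sequence.features.shape[1]}"
        )
    batch = pad_and_mask([sequence])
    batch = model.stats.apply(batch)
    _, scores = lstm_forward(batch, model.params)
    return float(scores[0])


class LSTMTrainer:
    """fit/score adapter over :func:`train` for cross-validation.

    ``laterality`` selects which breast's sequences feed the network.
    """

    def __init__(self, config: LSTMConfig, laterality: str = "affected"):
        self.config = config
        self.laterality = laterality
        self.model: LSTMModel | None = None

    def fit(self, cases: list[Case]) -> "LSTMTrainer":
        seqs = sequences_from_cases(cases, self.laterality)
        self.model = train(self.config, seqs)
        return self

    def score(self, case: Case) -> float:
        if self.model is None:
            raise RuntimeError("trainer is not fitted")
        (seq,) = sequences_from_cases([case], self.laterality)
        return predict(self.model, seq)
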
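"""Like-to-like connectivity in a trained recurrent network.

A vanilla RNN (tanh recurrence over 20 time steps, static image input
through a linear layer, linear readout of the final hidden state) is
trained on image classification with Adam and categorical cross-entropy.
After training, hidden units are treated like recorded neurons: pairwise
"signal correlations" of their activations on held-out stimuli, a weight
threshold defining "connected" pairs (weight > 0.01, the top ~35th
percentile at the printed scale), targeted ablation of like-to-like
connections versus strength-matched random connections, and the
common-input convergence statistic with a logistic pairwise null.

The recurrent weight W[post, pre] carries the connection from unit ``pre``
to unit ``post``. Thresholding uses signed weights (an absolute-value
variant is available via ``use_abs``).

The network and optimizer are implemented directly in numpy (forward,
backpropagation-through-time, Adam), so the experiment is self-contained
and deterministic given a seed. The bundled synthetic-digits task — glyph
images rendered and jittered at generation time — allows the full
experiment to run without any download; MNIST/FashionMNIST IDX files can be
supplied on disk for the printed-scale run.
"""

from __future__ import annotations

import gzip
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

WEIGHT_THRESHOLD = 0.01
CORR_THRESHOLD = 0.2

# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

_DIGIT_GLYPHS = [
    "01110 10001 10011 10101 11001 10001 01110",  # 0
    "00100 01100 00100 00100 00100 00100 01110",  # 1
    "01110 10001 00001 00110 01000 10000 11111",  # 2
    "11110 00001 00001 01110 00001 00001 11110",  # 3
    "00010 00110 01010 10010 11111 00010 00010",  # 4
    "11111 10000 11110 00001 00001 10001 01110",  # 5
    "00110 01000 10000 11110 10001 10001 01110",  # 6
    "11111 00001 00010 00100 01000 01000 01000",  # 7
    "01110 10001 10001 01110 10001 10001 01110",  # 8
    "01110 10001 10001 01111 00001 00010 01100",  # 9
]


def _glyph_array(digit: int) -> np.ndarray:
    rows = _DIGIT_GLYPHS[digit].split()
    return np.array([[int(c) for c in r] for r in rows], float)  # (7, 5)


def synthetic_digits(
    n_samples: int,
    rng: np.random.Generator,
    image_size: int = 16,
    noise_sd: float = 0.15,
) -> tuple[np.ndarray, np.ndarray]:
    """Ten-class glyph-image task generated on the fly.

    Each sample places a 7x5 digit glyph (doubled to 14x10) at a random
    offset inside an ``image_size`` square, with pixel noise. Returns
    (images flattened to (n, image_size**2) in [0, ~1], labels).
    """
    X = np.zeros((n_samples, image_size, image_size))
    yl = rng.integers(0, 10, n_samples)
    for i, d in enumerate(yl):
        g = np.kron(_glyph_array(int(d)), np.ones((2, 2)))  # 14 x 10
        dy = rng.integers(0, image_size - g.shape[0] + 1)
        dx = rng.integers(0, image_size - g.shape[1] + 1)
        X[i, dy:dy + g.shape[0], dx:dx + g.shape[1]] = g
    X += rng.normal(0, noise_sd, X.shape)
    return X.reshape(n_samples, -1), yl


def load_mnist_idx(directory, kind: str = "train") -> tuple[np.ndarray, np.ndarray]:
    """Read MNIST/FashionMNIST IDX files (optionally gzipped) from disk."""
    directory = Path(directory)
    prefix = "train" if kind == "train" else "t10k"

    def _open(name):
        p = directory / name
        if p.exists():
            return open(p, "rb")
        pz = directory / (name + ".gz")
        if pz.exists():
            return gzip.open(pz, "rb")
        raise FileNotFoundError(f"{name}[.gz] not found under {directory}")

    with _open(f"{prefix}-images-idx3-ubyte") as f:
        _, n, rows, cols = struct.unpack(">IIII", f.read(16))
        X = np.frombuffer(f.read(), dtype=np.uint8).reshape(n, rows * cols) / 255.0
    with _open(f"{prefix}-labels-idx1-ubyte") as f:
        _, n = struct.unpack(">II", f.read(8))
        y = np.frombuffer(f.read(), dtype=np.uint8)
    return X.astype(float), y.astype(int)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class RnnConfig:
    hidden_units: int = 1000
    time_steps: int = 20
    epochs: int = 10
    batch_size: int = 512
    learning_rate: float = 1e-3
    seed: int = 0
    dataset: str = "synthetic-digits"  # | "mnist" | "fashion-mnist"
    data_dir: str | None = None  # IDX files for mnist modes
    n_classes: int = 10
    # synthetic-digits sizes (ignored for mnist)
    n_train: int = 8000
    n_test: int = 2000
    image_size: int = 16


@dataclass
class RnnModel:
    """Parameter container; ``W_hh[post, pre]`` is the recurrent weight."""

    W_in: np.ndarray
    b_in: np.ndarray
    W_hh: np.ndarray
    W_out: np.ndarray
    b_out: np.ndarray
    time_steps: int

    def copy(self) -> "RnnModel":
        return RnnModel(
            self.W_in.copy(), self.b_in.copy(), self.W_hh.copy(),
            self.W_out.copy(), self.b_out.copy(), self.time_steps,
        )

    def forward(self, X: np.ndarray, return_states: bool = False):
        inp = X @ self.W_in.T + self.b_in
        h = np.zeros((X.shape[0], self.W_hh.shape[0]))
        states = []
        for _ in range(self.time_steps):
            h = np.tanh(inp + h @ self.W_hh.T)
            if return_states:
                states.append(h)
        logits = h @ self.W_out.T + self.b_out
        if return_states:
            return logits, np.stack(states)  # (T, B, H)
        return logits

    def accuracy(self, X: np.ndarray, y: np.ndarray, batch: int = 2048) -> float:
        correct = 0
        for i in range(0, len(X), batch):
            logits = self.forward(X[i:i + batch])
            correct += int((logits.argmax(axis=1) == y[i:i + batch]).sum())
        return correct / len(X)


def init_model(config: RnnConfig, input_dim: int) -> RnnModel:
    """Uniform(-1/sqrt(H), 1/sqrt(H)) init on every layer (the standard
    vanilla-RNN convention; it puts ~35% of recurrent weights above 0.01 at
    H = 1000)."""
    rng = np.random.default_rng(config.seed)
    H, C = config.hidden_units, config.n_classes
    k = 1.0 / np.sqrt(H)
    ki = 1.0 / np.sqrt(input_dim)
    return RnnModel(
        W_in=rng.uniform(-ki, ki, (H, input_dim)),
        b_in=rng.uniform(-k, k, H),
        W_hh=rng.uniform(-k, k, (H, H)),
        W_out=rng.uniform(-k, k, (C, H)),
        b_out=rng.uniform(-k, k, C),
        time_steps=config.time_steps,
    )


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, shapes, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _batch_grads(model: RnnModel, X, y):
    B = X.shape[0]
    inp = X @ model.W_in.T + model.b_in
    h = np.zeros((B, model.W_hh.shape[0]))
    states = [h]
    for _ in range(model.time_steps):
        h = np.tanh(inp + h @ model.W_hh.T)
        states.append(h)
    logits = h @ model.W_out.T + model.b_out
    probs = _softmax(logits)
    loss = -np.mean(np.log(np.clip(probs[np.arange(B), y], 1e-12, None)))

    dlogits = probs
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    gW_out = dlogits.T @ states[-1]
    gb_out = dlogits.sum(axis=0)
    dh = dlogits @ model.W_out
    gW_hh = np.zeros_like(model.W_hh)
    dinp = np.zeros_like(inp)
    for t in range(model.time_steps, 0, -1):
        dpre = dh * (1.0 - states[t] ** 2)
        gW_hh += dpre.T @ states[t - 1]
        dinp += dpre
        dh = dpre @ model.W_hh
    gW_in = dinp.T @ X
    gb_in = dinp.sum(axis=0)
    return loss, [gW_in, gb_in, gW_hh, gW_out, gb_out]


@dataclass
class TrainedRnn:
    model: RnnModel
    initial: RnnModel  # pre-training snapshot, same seed
    config: RnnConfig
    test_accuracy: float
    loss_history: list = field(default_factory=list)
    data: dict = field(default_factory=dict)  # X_train/y_train/X_test/y_test


def load_dataset(config: RnnConfig):
    if config.dataset == "synthetic-digits":
        rng = np.random.default_rng(config.seed + 7)
        X_tr, y_tr = synthetic_digits(config.n_train, rng, config.image_size)
        X_te, y_te = synthetic_digits(config.n_test, rng, config.image_size)
        return X_tr, y_tr, X_te, y_te
    if config.dataset in ("mnist", "fashion-mnist"):
        if config.data_dir is None:
            raise FileNotFoundError(
                f"{config.dataset} requires IDX files on disk; set data_dir"
            )
        X_tr, y_tr = load_mnist_idx(config.data_dir, "train")
        X_te, y_te = load_mnist_idx(config.data_dir, "test")
        return X_tr, y_tr, X_te, y_te
    raise ValueError(f"unknown dataset {config.dataset!r}")


def train_rnn(config: RnnConfig) -> TrainedRnn:
    """Train the three layers jointly; keeps the pre-training snapshot for
    before/after comparisons. Aborts on divergent loss."""
    X_tr, y_tr, X_te, y_te = load_dataset(config)
    model = init_model(config, X_tr.shape[1])
    initial = model.copy()
    params = [model.W_in, model.b_in, model.W_hh, model.W_out, model.b_out]
    opt = _Adam([p.shape for p in params], config.learning_rate)
    rng = np.random.default_rng(config.seed + 13)
    losses = []
    for _ in range(config.epochs):
        order = rng.permutation(len(X_tr))
        for i in range(0, len(X_tr), config.batch_size):
            idx = order[i:i + config.batch_size]
            loss, grads = _batch_grads(model, X_tr[idx], y_tr[idx])
            if not np.isfinite(loss) or loss > 1e3:
                raise RuntimeError(f"divergent training loss {loss}")
            opt.step(params, grads)
            losses.append(loss)
    acc = model.accuracy(X_te, y_te)
    return TrainedRnn(
        model=model, initial=initial, config=config, test_accuracy=acc,
        loss_history=losses,
        data={"X_train": X_tr, "y_train": y_tr, "X_test": X_te, "y_test": y_te},
    )


# ---------------------------------------------------------------------------
# analyses
# ---------------------------------------------------------------------------

def hidden_signal_correlations(
    model: RnnModel, stimuli: np.ndarray, mode: str = "all_steps"
) -> np.ndarray:
    """Pearson correlation between hidden units' activation profiles.

    mode "all_steps" concatenates activations across the simulated time
    steps; "final_step" uses only the last state. Constant units get nan
    rows/columns.
    """
    _, states = model.forward(stimuli, return_states=True)  # (T, B, H)
    if mode == "all_steps":
        acts = states.transpose(2, 1, 0).reshape(states.shape[2], -1)  # (H, B*T)
    elif mode == "final_step":
        acts = states[-1].T
    else:
        raise ValueError("mode must be 'all_steps' or 'final_step'")
    sd = acts.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(acts)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    return corr


def classify_connections(
    W: np.ndarray, threshold: float = WEIGHT_THRESHOLD, use_abs: bool = False
) -> np.ndarray:
    """Boolean connected mask (diagonal excluded)."""
    val = np.abs(W) if use_abs else W
    mask = val > threshold
    np.fill_diagonal(mask, False)
    return mask


def connection_probability_curve(
    mask: np.ndarray, signal_corr: np.ndarray, bins=10
) -> "pd.DataFrame":
    """Fraction of connected pairs per signal-correlation bin."""
    import pandas as pd

    off = ~np.eye(mask.shape[0], dtype=bool)
    ok = off & np.isfinite(signal_corr)
    c = signal_corr[ok]
    m = mask[ok]
    edges = np.histogram_bin_edges(c, bins=bins)
    which = np.clip(np.digitize(c, edges) - 1, 0, len(edges) - 2)
    rows = []
    for k in range(len(edges) - 1):
        sel = which == k
        rows.append(
            {
                "bin_left": edges[k], "bin_right": edges[k + 1],
                "n_pairs": int(sel.sum()),
                "connection_probability": float(m[sel].mean()) if sel.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def mean_connected_correlation(mask: np.ndarray, signal_corr: np.ndarray) -> dict:
    """Mean signal correlation among all and among connected pairs."""
    off = ~np.eye(mask.shape[0], dtype=bool)
    ok = off & np.isfinite(signal_corr)
    return {
        "all_pairs": float(signal_corr[ok].mean()),
        "connected_pairs": float(signal_corr[ok & mask].mean()) if (ok & mask).any() else np.nan,
    }


def like_to_like_candidates(
    W: np.ndarray,
    signal_corr: np.ndarray,
    w_thresh: float = WEIGHT_THRESHOLD,
    corr_thresh: float = CORR_THRESHOLD,
    use_abs: bool = False,
) -> np.ndarray:
    """Connections whose weight and endpoint signal correlation both exceed
    their thresholds (the ablation candidate set)."""
    val = np.abs(W) if use_abs else W
    cand = (val > w_thresh) & (signal_corr > corr_thresh) & np.isfinite(signal_corr)
    np.fill_diagonal(cand, False)
    return cand


def _strength_matched_sample(
    W, pool_mask, cand_mask, n, rng, n_quantile_bins: int = 10
):
    """Sample n connections from pool_mask whose weight-magnitude
    distribution matches the candidate set's, by quantile-bin matching."""
    cand_w = np.abs(W[cand_mask])
    qs = np.quantile(cand_w, np.linspace(0, 1, n_quantile_bins + 1))
    qs[0], qs[-1] = -np.inf, np.inf
    pool_idx = np.flatnonzero(pool_mask.ravel())
    pool_w = np.abs(W.ravel()[pool_idx])
    chosen = []
    per_bin = np.bincount(
        np.clip(np.digitize(np.abs(W[cand_mask]), qs) - 1, 0, n_quantile_bins - 1),
        minlength=n_quantile_bins,
    )
    per_bin = np.round(per_bin * n / per_bin.sum()).astype(int)
    for k in range(n_quantile_bins):
        in_bin = pool_idx[(pool_w > qs[k]) & (pool_w <= qs[k + 1])]
        take = min(per_bin[k], len(in_bin))
        if take > 0:
            chosen.append(rng.choice(in_bin, size=take, replace=False))
    flat = np.concatenate(chosen) if chosen else np.zeros(0, int)
    if len(flat) < n:  # top up from the whole pool
        rest = np.setdiff1d(pool_idx, flat)
        extra = rng.choice(rest, size=min(n - len(flat), len(rest)), replace=False)
        flat = np.concatenate([flat, extra])
    return np.unravel_index(flat[:n], W.shape)


def ablation_experiment(
    trained: TrainedRnn,
    n_ablate_grid,
    mode: str = "like_to_like",
    signal_corr: np.ndarray | None = None,
    w_thresh: float = WEIGHT_THRESHOLD,
    corr_thresh: float = CORR_THRESHOLD,
    n_repeats: int = 5,
    seed: int = 0,
    eval_size: int = 2000,
) -> "pd.DataFrame":
    """Test accuracy as recurrent connections are zeroed.

    mode "like_to_like" ablates from the candidate set (weight and signal
    correlation above threshold); mode "random" ablates equal counts drawn
    from all connected pairs with a strength-matched (quantile-bin) weight
    distribution. Grid values exceeding the candidate count are capped.
    """
    import pandas as pd

    model = trained.model
    X_te = trained.data["X_test"][:eval_size]
    y_te = trained.data["y_test"][:eval_size]
    if signal_corr is None:
        signal_corr = hidden_signal_correlations(model, X_te[:512])
    cand = like_to_like_candidates(model.W_hh, signal_corr, w_thresh, corr_thresh)
    pool = classify_connections(model.W_hh, w_thresh)
    n_cand = int(cand.sum())
    rng = np.random.default_rng(seed)
    cand_idx = np.array(np.nonzero(cand)).T
    rows = []
    for rep in range(n_repeats):
        order = rng.permutation(n_cand)
        for n_abl in n_ablate_grid:
            n_eff = min(int(n_abl), n_cand)
            ablated = model.copy()
            if mode == "like_to_like":
                sel = cand_idx[order[:n_eff]]
                ablated.W_hh[sel[:, 0], sel[:, 1]] = 0.0
            elif mode == "random":
                ii, jj = _strength_matched_sample(model.W_hh, pool, cand, n_eff, rng)
                ablated.W_hh[ii, jj] = 0.0
            else:
                raise ValueError("mode must be 'like_to_like' or 'random'")
            rows.append(
                {
                    "mode": mode, "repeat": rep, "n_ablated": n_eff,
                    "capped": n_eff < int(n_abl),
                    "accuracy": ablated.accuracy(X_te, y_te),
                }
            )
    return pd.DataFrame(rows)


def rnn_convergence_analysis(
    model: RnnModel,
    signal_corr: np.ndarray,
    w_thresh: float = WEIGHT_THRESHOLD,
) -> dict:
    """Common-input test on the binarized recurrent graph.

    Connections are binarized at ``w_thresh``; a logistic regression of
    connection on signal correlation provides the pairwise null; rho and
    rho' are evaluated for every unit as a presynaptic source (its outgoing
    connections weight the pairwise similarity of its targets); a two-sided
    sign test compares them across units.
    """
    from sklearn.linear_model import LogisticRegression

    H = model.W_hh.shape[0]
    B = classify_connections(model.W_hh, w_thresh)  # B[post, pre]
    off = ~np.eye(H, dtype=bool)
    ok = off & np.isfinite(signal_corr)
    Xlr = signal_corr[ok].reshape(-1, 1)
    ylr = B[ok].astype(int)
    lr = LogisticRegression(max_iter=1000)
    lr.fit(Xlr, ylr)
    P = np.zeros_like(signal_corr)
    P[ok] = lr.predict_proba(Xlr)[:, 1]

    # rho_i = (v_i' S v_i - sum_j v_ij^2 S_jj) / ((sum_j v_ij)^2 - sum_j v_ij^2)
    # with v_i the outgoing weights of unit i (column i, self zeroed)
    S = np.where(np.isfinite(signal_corr), signal_corr, 0.0)

    def _rho_all(V):
        V = V.copy()
        np.fill_diagonal(V, 0.0)
        quad = np.einsum("ji,jk,ki->i", V, S, V, optimize=True)
        diag_part = (V ** 2 * np.diag(S)[:, None]).sum(axis=0)
        tot = V.sum(axis=0)
        sq = (V ** 2).sum(axis=0)
        denom = tot ** 2 - sq
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (quad - diag_part) / denom
        rho[(V > 0).sum(axis=0) < 2] = np.nan
        rho[denom <= 0] = np.nan
        return rho

    rho_obs = _rho_all(B.astype(float))
    rho_exp = _rho_all(P)
    okr = np.isfinite(rho_obs) & np.isfinite(rho_exp)
    diff = rho_obs[okr] - rho_exp[okr]
    n_pos = int((diff > 0).sum())
    n_neg = int((diff < 0).sum())
    if n_pos + n_neg:
        p = stats.binomtest(n_pos, n_pos + n_neg, 0.5).pvalue
    else:
        p = np.nan
    return {
        "rho_observed": rho_obs,
        "rho_expected": rho_exp,
        "n_units": int(okr.sum()),
        "n_positive": n_pos,
        "n_negative": n_neg,
        "sign_test_p": float(p) if np.isfinite(p) else np.nan,
        "logistic_coef": float(lr.coef_[0, 0]),
    }
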
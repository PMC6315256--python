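"""Bidirectional peephole LSTM-CRF sequence tagger (pure numpy, float64).

Each character t of a sentence is represented by the concatenation of its
embedding and a 4-dimensional BMES segmentation one-hot.  Two peephole LSTMs
read the representation sequence left-to-right and right-to-left; their
hidden states are concatenated per position, linearly projected to label
space, and decoded by the shared linear-chain CRF layer.

The LSTM unit uses the peephole formulation — the input and forget gates see
the previous cell state and the output gate sees the current cell state,
through diagonal (vector) peephole weights:

    i_t = sigmoid(W_xi x_t + W_hi h_{t-1} + w_ci * c_{t-1} + b_i)
    f_t = sigmoid(W_xf x_t + W_hf h_{t-1} + w_cf * c_{t-1} + b_f)
    c_t = f_t * c_{t-1} + i_t * tanh(W_xc x_t + W_hc h_{t-1} + b_c)
    o_t = sigmoid(W_xo x_t + W_ho h_{t-1} + w_co * c_t + b_o)
    h_t = o_t * tanh(c_t)

Training is Adam over shuffled mini-batches with inverted dropout on the
concatenated context rows, global-norm gradient clipping, and early stopping
on held-out strict entity F1.  Gradients are hand-derived backpropagation
through time and are verified against central finite differences in the
test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from cnerkit.corpus import (
    EntityMention,
    TaggedSentence,
    TagScheme,
    bio_to_entities,
)
from cnerkit.crf import SequenceScores, posterior_marginals, sequence_log_score, viterbi_decode

logger = logging.getLogger(__name__)

UNK = "<UNK>"
SEG_TAGS = ("B", "M", "E", "S")
_SEG_INDEX = {t: i for i, t in enumerate(SEG_TAGS)}


@dataclass
class LstmParams:
    """Weights of one peephole LSTM direction.

    Peephole weights (``w_ci``, ``w_cf``, ``w_co``) are diagonal and stored
    as vectors of length H.
    """

    W_xi: np.ndarray
    W_hi: np.ndarray
    w_ci: np.ndarray
    b_i: np.ndarray
    W_xf: np.ndarray
    W_hf: np.ndarray
    w_cf: np.ndarray
    b_f: np.ndarray
    W_xc: np.ndarray
    W_hc: np.ndarray
    b_c: np.ndarray
    W_xo: np.ndarray
    W_ho: np.ndarray
    w_co: np.ndarray
    b_o: np.ndarray

    @property
    def hidden(self) -> int:
        return self.W_xi.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_xi.shape[1]

    def arrays(self) -> dict[str, np.ndarray]:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}

    @classmethod
    def init(cls, input_dim: int, hidden: int, rng: np.random.Generator) -> "LstmParams":
        """Uniform(-0.1, 0.1) matrices and peepholes, zero biases, forget bias +1."""

        def mat(r: int, c: int) -> np.ndarray:
            return rng.uniform(-0.1, 0.1, size=(r, c))

        def vec(r: int) -> np.ndarray:
            return rng.uniform(-0.1, 0.1, size=r)

        return cls(
            W_xi=mat(hidden, input_dim), W_hi=mat(hidden, hidden), w_ci=vec(hidden), b_i=np.zeros(hidden),
            W_xf=mat(hidden, input_dim), W_hf=mat(hidden, hidden), w_cf=vec(hidden), b_f=np.ones(hidden),
            W_xc=mat(hidden, input_dim), W_hc=mat(hidden, hidden), b_c=np.zeros(hidden),
            W_xo=mat(hidden, input_dim), W_ho=mat(hidden, hidden), w_co=vec(hidden), b_o=np.zeros(hidden),
        )

    def zeros_like(self) -> "LstmParams":
        return LstmParams(**{k: np.zeros_like(v) for k, v in self.arrays().items()})


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def lstm_step(
    x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, params: LstmParams
) -> tuple[np.ndarray, np.ndarray]:
    """One peephole LSTM step; returns (h_t, c_t)."""
    if x_t.shape[0] != params.input_dim or h_prev.shape[0] != params.hidden:
        raise ValueError(
            f"dimension mismatch: x {x_t.shape}, h {h_prev.shape}, "
            f"params expect input {params.input_dim}, hidden {params.hidden}"
        )
    i = _sigmoid(params.W_xi @ x_t + params.W_hi @ h_prev + params.w_ci * c_prev + params.b_i)
    f = _sigmoid(params.W_xf @ x_t + params.W_hf @ h_prev + params.w_cf * c_prev + params.b_f)
    g = np.tanh(params.W_xc @ x_t + params.W_hc @ h_prev + params.b_c)
    c = f * c_prev + i * g
    o = _sigmoid(params.W_xo @ x_t + params.W_ho @ h_prev + params.w_co * c + params.b_o)
    h = o * np.tanh(c)
    return h, c


def _lstm_forward(X: np.ndarray, params: LstmParams) -> tuple[np.ndarray, list[dict]]:
    """Run one direction over the whole sequence, keeping per-step caches."""
    n = X.shape[0]
    H = params.hidden
    out = np.zeros((n, H))
    caches: list[dict] = []
    h = np.zeros(H)
    c = np.zeros(H)
    for t in range(n):
        x = X[t]
        h_prev, c_prev = h, c
        i = _sigmoid(params.W_xi @ x + params.W_hi @ h_prev + params.w_ci * c_prev + params.b_i)
        f = _sigmoid(params.W_xf @ x + params.W_hf @ h_prev + params.w_cf * c_prev + params.b_f)
        g = np.tanh(params.W_xc @ x + params.W_hc @ h_prev + params.b_c)
        c = f * c_prev + i * g
        o = _sigmoid(params.W_xo @ x + params.W_ho @ h_prev + params.w_co * c + params.b_o)
        tanh_c = np.tanh(c)
        h = o * tanh_c
        out[t] = h
        caches.append(
            dict(x=x, h_prev=h_prev, c_prev=c_prev, i=i, f=f, g=g, c=c, o=o, tanh_c=tanh_c)
        )
    return out, caches


def _lstm_backward(
    dH: np.ndarray, caches: list[dict], params: LstmParams
) -> tuple[np.ndarray, LstmParams]:
    """Backpropagation through time for one direction.

    ``dH`` holds the loss gradient with respect to each output h_t; returns
    the gradient with respect to the inputs and a parameter-gradient bundle.
    """
    n = dH.shape[0]
    grads = params.zeros_like()
    dX = np.zeros((n, params.input_dim))
    dh_next = np.zeros(params.hidden)
    dc_next = np.zeros(params.hidden)
    for t in range(n - 1, -1, -1):
        cc = caches[t]
        dh = dH[t] + dh_next
        do = dh * cc["tanh_c"]
        d_ao = do * cc["o"] * (1.0 - cc["o"])
        dc = dc_next + dh * cc["o"] * (1.0 - cc["tanh_c"] ** 2) + d_ao * params.w_co
        di = dc * cc["g"]
        df = dc * cc["c_prev"]
        dg = dc * cc["i"]
        d_ai = di * cc["i"] * (1.0 - cc["i"])
        d_af = df * cc["f"] * (1.0 - cc["f"])
        d_ag = dg * (1.0 - cc["g"] ** 2)

        grads.W_xi += np.outer(d_ai, cc["x"])
        grads.W_hi += np.outer(d_ai, cc["h_prev"])
        grads.w_ci += d_ai * cc["c_prev"]
        grads.b_i += d_ai
        grads.W_xf += np.outer(d_af, cc["x"])
        grads.W_hf += np.outer(d_af, cc["h_prev"])
        grads.w_cf += d_af * cc["c_prev"]
        grads.b_f += d_af
        grads.W_xc += np.outer(d_ag, cc["x"])
        grads.W_hc += np.outer(d_ag, cc["h_prev"])
        grads.b_c += d_ag
        grads.W_xo += np.outer(d_ao, cc["x"])
        grads.W_ho += np.outer(d_ao, cc["h_prev"])
        grads.w_co += d_ao * cc["c"]
        grads.b_o += d_ao

        dX[t] = (
            params.W_xi.T @ d_ai
            + params.W_xf.T @ d_af
            + params.W_xc.T @ d_ag
            + params.W_xo.T @ d_ao
        )
        dh_next = (
            params.W_hi.T @ d_ai
            + params.W_hf.T @ d_af
            + params.W_hc.T @ d_ag
            + params.W_ho.T @ d_ao
        )
        dc_next = dc * cc["f"] + d_ai * params.w_ci + d_af * params.w_cf
    return dX, grads


def bilstm_encode(X: np.ndarray, fwd: LstmParams, bwd: LstmParams) -> np.ndarray:
    """Encode a sequence bidirectionally: row t = [h_fwd(t) ; h_bwd(t)].

    The backward pass reads the sequence right-to-left; both passes start
    from zero hidden and cell states.
    """
    if X.shape[0] < 1:
        raise ValueError("empty input sequence")
    Hf, _ = _lstm_forward(X, fwd)
    Hb_rev, _ = _lstm_forward(X[::-1], bwd)
    return np.concatenate([Hf, Hb_rev[::-1]], axis=1)


@dataclass(frozen=True)
class NeuralConfig:
    """Hyperparameters of the BiLSTM-CRF tagger.

    Defaults follow the standard recipe for this architecture on Chinese
    clinical text: Adam at learning rate 4e-4, dropout 0.5 on the context
    representation, embedding dimension 100 and hidden size 100.  ``hidden``
    is typically scaled down (e.g. 25) for desk-scale experiments.
    """

    embed_dim: int = 100
    hidden: int = 100
    lr: float = 4e-4
    dropout: float = 0.5
    batch_size: int = 8
    epochs: int = 30
    clip_norm: float = 5.0
    patience: int = 8
    dev_fraction: float = 0.1


@dataclass
class BiLstmCrfModel:
    """Embeddings, two LSTM directions, projection, and CRF transitions."""

    vocab: dict[str, int]  # includes UNK
    embeddings: np.ndarray  # [V x embed_dim]
    forward_lstm: LstmParams
    backward_lstm: LstmParams
    proj_W: np.ndarray  # [2H x n_labels]
    proj_b: np.ndarray  # [n_labels]
    transitions: np.ndarray  # [n_labels x n_labels]
    scheme: TagScheme
    config: NeuralConfig = field(default_factory=NeuralConfig)

    def parameters(self) -> list[tuple[str, np.ndarray]]:
        """All trainable arrays in a fixed order (for the optimizer and checks)."""
        params: list[tuple[str, np.ndarray]] = [("embeddings", self.embeddings)]
        for prefix, lstm in (("fwd", self.forward_lstm), ("bwd", self.backward_lstm)):
            params.extend((f"{prefix}.{k}", v) for k, v in lstm.arrays().items())
        params.append(("proj_W", self.proj_W))
        params.append(("proj_b", self.proj_b))
        params.append(("transitions", self.transitions))
        return params

    def char_ids(self, chars: str) -> np.ndarray:
        unk = self.vocab[UNK]
        return np.array([self.vocab.get(ch, unk) for ch in chars], dtype=np.intp)

    def copy(self) -> "BiLstmCrfModel":
        return BiLstmCrfModel(
            dict(self.vocab),
            self.embeddings.copy(),
            LstmParams(**{k: v.copy() for k, v in self.forward_lstm.arrays().items()}),
            LstmParams(**{k: v.copy() for k, v in self.backward_lstm.arrays().items()}),
            self.proj_W.copy(),
            self.proj_b.copy(),
            self.transitions.copy(),
            self.scheme,
            self.config,
        )


def seg_ids(seg_tags: list[str]) -> np.ndarray:
    try:
        return np.array([_SEG_INDEX[t] for t in seg_tags], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"unknown segmentation tag {exc.args[0]!r}") from None


def build_inputs(model: BiLstmCrfModel, chars: str, seg_tags: list[str]) -> np.ndarray:
    """x_t = [embedding(char_t) ; onehot(seg_tag_t)]; OOV characters use UNK."""
    if len(chars) != len(seg_tags):
        raise ValueError(f"{len(chars)} characters but {len(seg_tags)} segmentation tags")
    ids = model.char_ids(chars)
    onehot = np.zeros((len(chars), len(SEG_TAGS)))
    onehot[np.arange(len(chars)), seg_ids(seg_tags)] = 1.0
    return np.concatenate([model.embeddings[ids], onehot], axis=1)


def init_model(
    vocab_chars: list[str],
    scheme: TagScheme,
    config: NeuralConfig,
    seed: int,
    pretrained: "np.ndarray | None" = None,
    pretrained_vocab: dict[str, int] | None = None,
) -> BiLstmCrfModel:
    """Initialize a model: seeded uniform weights, optional pretrained embeddings."""
    rng = np.random.default_rng(seed)
    vocab = {UNK: 0}
    for ch in vocab_chars:
        vocab.setdefault(ch, len(vocab))
    if pretrained is not None:
        if pretrained_vocab is None:
            raise ValueError("pretrained embeddings require their vocabulary")
        if pretrained.shape[1] != config.embed_dim:
            raise ValueError(
                f"pretrained dimension {pretrained.shape[1]} != configured {config.embed_dim}"
            )
        # the pretraining corpus defines the reachable character inventory,
        # so characters unseen in the labeled data still get useful vectors
        for ch in sorted(pretrained_vocab):
            if ch != UNK:
                vocab.setdefault(ch, len(vocab))
    V = len(vocab)
    E = rng.uniform(-0.05, 0.05, size=(V, config.embed_dim))
    if pretrained is not None:
        for ch, row in pretrained_vocab.items():
            if ch in vocab:
                E[vocab[ch]] = pretrained[row]
            elif ch == UNK:
                E[0] = pretrained[row]
    d_in = config.embed_dim + len(SEG_TAGS)
    H = config.hidden
    return BiLstmCrfModel(
        vocab=vocab,
        embeddings=E,
        forward_lstm=LstmParams.init(d_in, H, rng),
        backward_lstm=LstmParams.init(d_in, H, rng),
        proj_W=rng.uniform(-0.1, 0.1, size=(2 * H, scheme.n_labels)),
        proj_b=np.zeros(scheme.n_labels),
        transitions=np.zeros((scheme.n_labels, scheme.n_labels)),
        scheme=scheme,
        config=config,
    )


def neural_loss(
    model: BiLstmCrfModel,
    chars: str,
    seg_tags: list[str],
    gold_labels: list[str] | np.ndarray,
    dropout_mask: np.ndarray | None = None,
) -> float:
    """CRF negative log-likelihood of the gold labeling (no regularizer).

    ``dropout_mask``, when given, multiplies the concatenated context rows
    (inverted-dropout scaling is the caller's responsibility); inference and
    gradient checks leave it ``None`` so the loss is deterministic.
    """
    loss, _ = _forward_loss(model, chars, seg_tags, _label_ids(model, gold_labels), dropout_mask)
    return loss


def _label_ids(model: BiLstmCrfModel, labels: list[str] | np.ndarray) -> np.ndarray:
    if isinstance(labels, np.ndarray) and labels.dtype != object:
        return labels.astype(np.intp)
    return np.array([model.scheme.index(str(lab)) for lab in labels], dtype=np.intp)


def _forward_loss(
    model: BiLstmCrfModel,
    chars: str,
    seg_tags: list[str],
    y: np.ndarray,
    dropout_mask: np.ndarray | None,
) -> tuple[float, dict]:
    X = build_inputs(model, chars, seg_tags)
    Hf, caches_f = _lstm_forward(X, model.forward_lstm)
    Hb_rev, caches_b = _lstm_forward(X[::-1], model.backward_lstm)
    ctx = np.concatenate([Hf, Hb_rev[::-1]], axis=1)
    if dropout_mask is not None:
        ctx = ctx * dropout_mask
    emissions = ctx @ model.proj_W + model.proj_b
    scores = SequenceScores(emissions, model.transitions)
    node, pair, log_z = posterior_marginals(scores)
    loss = log_z - sequence_log_score(scores, y)
    cache = dict(
        X=X, caches_f=caches_f, caches_b=caches_b, ctx=ctx,
        node=node, pair=pair, y=y, chars=chars,
        dropout_mask=dropout_mask,
    )
    return float(loss), cache


def loss_and_gradients(
    model: BiLstmCrfModel,
    chars: str,
    seg_tags: list[str],
    gold_labels: list[str] | np.ndarray,
    dropout_mask: np.ndarray | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Loss plus gradients for every parameter array, keyed as in
    :meth:`BiLstmCrfModel.parameters`."""
    y = _label_ids(model, gold_labels)
    loss, cache = _forward_loss(model, chars, seg_tags, y, dropout_mask)
    n = len(chars)
    H = model.config.hidden

    # CRF layer: d loss / d emissions = marginals - onehot(gold)
    demissions = cache["node"].copy()
    demissions[np.arange(n), y] -= 1.0
    dtrans = cache["pair"].copy()
    if n > 1:
        np.add.at(dtrans, (y[:-1], y[1:]), -1.0)

    ctx = cache["ctx"]
    dproj_W = ctx.T @ demissions
    dproj_b = demissions.sum(axis=0)
    dctx = demissions @ model.proj_W.T
    if cache["dropout_mask"] is not None:
        dctx = dctx * cache["dropout_mask"]

    dXf, gf = _lstm_backward(dctx[:, :H], cache["caches_f"], model.forward_lstm)
    dXb_rev, gb = _lstm_backward(dctx[:, H:][::-1], cache["caches_b"], model.backward_lstm)
    dX = dXf + dXb_rev[::-1]

    dE = np.zeros_like(model.embeddings)
    ids = model.char_ids(chars)
    np.add.at(dE, ids, dX[:, : model.config.embed_dim])

    grads: dict[str, np.ndarray] = {"embeddings": dE}
    for prefix, bundle in (("fwd", gf), ("bwd", gb)):
        grads.update({f"{prefix}.{k}": v for k, v in bundle.arrays().items()})
    grads["proj_W"] = dproj_W
    grads["proj_b"] = dproj_b
    grads["transitions"] = dtrans
    return loss, grads


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _strict_f1(model: BiLstmCrfModel, sents: list[TaggedSentence], seg_fn) -> float:
    tp = n_pred = n_gold = 0
    for sent in sents:
        gold = bio_to_entities(sent, model.scheme)
        pred = predict_bilstm_crf(model, sent.chars, seg_fn(sent.chars), doc_offset=sent.doc_offset)
        tp += len(gold & pred)
        n_pred += len(pred)
        n_gold += len(gold)
    p = tp / n_pred if n_pred else 0.0
    r = tp / n_gold if n_gold else 0.0
    return 2 * p * r / (p + r) if p + r > 0 else 0.0


def train_bilstm_crf(
    corpus: list[TaggedSentence],
    seg_fn,
    config: NeuralConfig = NeuralConfig(),
    seed: int = 0,
    scheme: TagScheme | None = None,
    pretrained: np.ndarray | None = None,
    pretrained_vocab: dict[str, int] | None = None,
    dev: list[TaggedSentence] | None = None,
) -> BiLstmCrfModel:
    """Train end-to-end with Adam over shuffled mini-batches.

    ``seg_fn`` maps a sentence string to its per-character BMES tag list.
    A held-out split (``dev``, or ``dev_fraction`` carved off the corpus) is
    scored by strict entity F1 after every epoch; the best-scoring weights
    are kept and training stops early after ``patience`` epochs without
    improvement.  Fully reproducible given the seed.
    """
    if not corpus:
        raise ValueError("empty training corpus")
    scheme = scheme or TagScheme()
    rng = np.random.default_rng(seed)

    if dev is None:
        order = rng.permutation(len(corpus))
        n_dev = max(1, int(round(config.dev_fraction * len(corpus)))) if len(corpus) > 1 else 0
        dev = [corpus[i] for i in order[:n_dev]]
        train = [corpus[i] for i in order[n_dev:]]
        if not train:
            train, dev = list(corpus), []
    else:
        train = list(corpus)

    vocab_chars = sorted({ch for sent in train for ch in sent.chars})
    model = init_model(vocab_chars, scheme, config, seed=int(rng.integers(2**31)),
                       pretrained=pretrained, pretrained_vocab=pretrained_vocab)

    # Adam state per parameter array
    m_state = {k: np.zeros_like(v) for k, v in model.parameters()}
    v_state = {k: np.zeros_like(v) for k, v in model.parameters()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    pre_seg = {id(s): seg_fn(s.chars) for s in train}
    best_f1, best_model, since_best = -1.0, model.copy(), 0
    history: list[dict] = []

    for epoch in range(config.epochs):
        order = rng.permutation(len(train))
        total_loss = 0.0
        for start in range(0, len(train), config.batch_size):
            batch = [train[i] for i in order[start : start + config.batch_size]]
            acc = {k: np.zeros_like(v) for k, v in model.parameters()}
            for sent in batch:
                mask = None
                if config.dropout > 0.0:
                    keep = rng.random((len(sent.chars), 2 * config.hidden)) >= config.dropout
                    mask = keep / (1.0 - config.dropout)
                loss, grads = loss_and_gradients(
                    model, sent.chars, pre_seg[id(sent)], sent.labels, dropout_mask=mask
                )
                total_loss += loss
                for k in acc:
                    acc[k] += grads[k]
            scale = 1.0 / len(batch)
            gnorm = float(np.sqrt(sum(np.sum((g * scale) ** 2) for g in acc.values())))
            clip = min(1.0, config.clip_norm / gnorm) if gnorm > 0 else 1.0
            step += 1
            params = dict(model.parameters())
            for k, g in acc.items():
                g = g * (scale * clip)
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * g
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * g * g
                m_hat = m_state[k] / (1 - beta1**step)
                v_hat = v_state[k] / (1 - beta2**step)
                params[k] -= config.lr * m_hat / (np.sqrt(v_hat) + eps)

        dev_f1 = _strict_f1(model, dev, seg_fn) if dev else float("nan")
        history.append(dict(epoch=epoch, train_loss=total_loss / max(1, len(train)), dev_f1=dev_f1))
        logger.info("epoch %d: mean train loss %.4f, dev strict F1 %s",
                    epoch, total_loss / max(1, len(train)),
                    f"{dev_f1:.4f}" if dev else "n/a")
        if dev:
            if dev_f1 > best_f1 + 1e-12:
                best_f1, best_model, since_best = dev_f1, model.copy(), 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    break

    final = best_model if dev else model
    final.training_history = history  # type: ignore[attr-defined]
    return final


def predict_bilstm_crf(
    model: BiLstmCrfModel,
    chars: str,
    seg_tags: list[str],
    doc_offset: int = 0,
) -> set[EntityMention]:
    """Decode one sentence (dropout disabled) into entity mentions."""
    if not chars:
        return set()
    X = build_inputs(model, chars, seg_tags)
    ctx = bilstm_encode(X, model.forward_lstm, model.backward_lstm)
    emissions = ctx @ model.proj_W + model.proj_b
    path, _ = viterbi_decode(SequenceScores(emissions, model.transitions))
    labels = [model.scheme.labels[j] for j in path]
    return bio_to_entities(TaggedSentence(chars, labels, doc_offset=doc_offset), model.scheme)


# ---------------------------------------------------------------------------
# Serialization (mirrors the CRF container: one versioned .npz file)
# ---------------------------------------------------------------------------

def save_bilstm(model: BiLstmCrfModel, path) -> None:
    chars = sorted(model.vocab, key=model.vocab.get)
    arrays = {f"param.{k}": v for k, v in model.parameters()}
    np.savez(
        path,
        format_version=np.array([1]),
        kind=np.array(["bilstm-crf"]),
        vocab=np.array(chars, dtype=np.str_),
        categories=np.array(model.scheme.categories, dtype=np.str_),
        hp=np.array([
            model.config.embed_dim, model.config.hidden, model.config.batch_size,
            model.config.epochs, model.config.patience,
        ], dtype=np.int64),
        hp_float=np.array([
            model.config.lr, model.config.dropout, model.config.clip_norm,
            model.config.dev_fraction,
        ]),
        **arrays,
    )


def load_bilstm(path) -> BiLstmCrfModel:
    with np.load(path, allow_pickle=False) as data:
        if str(data["kind"][0]) != "bilstm-crf":
            raise ValueError(f"{path} is not a BiLSTM-CRF model file")
        vocab = {str(ch): i for i, ch in enumerate(data["vocab"])}
        hp, hpf = data["hp"], data["hp_float"]
        config = NeuralConfig(
            embed_dim=int(hp[0]), hidden=int(hp[1]), batch_size=int(hp[2]),
            epochs=int(hp[3]), patience=int(hp[4]),
            lr=float(hpf[0]), dropout=float(hpf[1]), clip_norm=float(hpf[2]),
            dev_fraction=float(hpf[3]),
        )
        def lstm(prefix: str) -> LstmParams:
            names = LstmParams.__dataclass_fields__
            return LstmParams(**{k: data[f"param.{prefix}.{k}"].copy() for k in names})
        return BiLstmCrfModel(
            vocab=vocab,
            embeddings=data["param.embeddings"].copy(),
            forward_lstm=lstm("fwd"),
            backward_lstm=lstm("bwd"),
            proj_W=data["param.proj_W"].copy(),
            proj_b=data["param.proj_b"].copy(),
            transitions=data["param.transitions"].copy(),
            scheme=TagScheme(tuple(str(c) for c in data["categories"])),
            config=config,
        )
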
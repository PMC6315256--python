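"""Feature-based linear-chain CRF tagger: featurization, maximum-likelihood
training with L2 regularization, and entity prediction.

State feature functions are (feature-string x label) indicators; transition
feature functions are label-pair indicators with no observation dependence
(the bigram/unigram template semantics of CRF++-style taggers).  Training
minimizes the L2-penalized negative conditional log-likelihood

    sum_s [ log Z(x_s) - score(x_s, y_s) ] + (C/2) ||w||^2

by batch L-BFGS; the gradient is expected minus empirical feature counts
(via forward-backward marginals) plus C·w.  Everything is deterministic
given the corpus and configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import fmin_l_bfgs_b

from cnerkit.corpus import EntityMention, TaggedSentence, TagScheme, bio_to_entities, split_sentences
from cnerkit.crf import SequenceScores, posterior_marginals, sequence_log_score, viterbi_decode
from cnerkit.features import FeatureConfig, sentence_features
from cnerkit.segmenter import Segmenter

logger = logging.getLogger(__name__)


@dataclass
class FeaturizedSentence:
    """A sentence reduced to integer feature ids and label ids."""

    feature_ids: list[np.ndarray]  # per position, ids of active state features
    label_ids: np.ndarray

    def __len__(self) -> int:
        return len(self.feature_ids)


@dataclass
class CrfModel:
    """A trained CRF: feature index plus state and transition weights."""

    feature_index: dict[str, int]
    state_weights: np.ndarray  # [n_features x n_labels]
    transitions: np.ndarray  # [n_labels x n_labels]
    scheme: TagScheme
    config: FeatureConfig = field(default_factory=FeatureConfig)

    @property
    def n_features(self) -> int:
        return len(self.feature_index)

    def featurize(self, chars: str, segmenter: Segmenter | None = None) -> list[np.ndarray]:
        """Map a sentence to known feature ids; unseen features are dropped."""
        per_pos = sentence_features(chars, self.config, segmenter)
        return [
            np.array(
                [self.feature_index[f] for f in feats if f in self.feature_index],
                dtype=np.intp,
            )
            for feats in per_pos
        ]

    def scores_for(self, feature_ids: list[np.ndarray]) -> SequenceScores:
        emissions = np.zeros((len(feature_ids), self.state_weights.shape[1]))
        for t, ids in enumerate(feature_ids):
            if ids.size:
                emissions[t] = self.state_weights[ids].sum(axis=0)
        return SequenceScores(emissions, self.transitions)


def build_feature_index(
    corpus: list[TaggedSentence],
    config: FeatureConfig,
    segmenter: Segmenter | None = None,
) -> dict[str, int]:
    """Assign dense integer ids to every feature string seen in the corpus."""
    index: dict[str, int] = {}
    for sent in corpus:
        for feats in sentence_features(sent.chars, config, segmenter):
            for f in feats:
                if f not in index:
                    index[f] = len(index)
    return index


def featurize_corpus(
    corpus: list[TaggedSentence],
    feature_index: dict[str, int],
    scheme: TagScheme,
    config: FeatureConfig,
    segmenter: Segmenter | None = None,
    strict: bool = True,
) -> list[FeaturizedSentence]:
    """Featurize sentences against an existing index.

    With ``strict`` (training), a feature missing from the index is an error;
    without it (prediction), unseen features are silently dropped.
    """
    out = []
    for sent in corpus:
        ids_per_pos = []
        for feats in sentence_features(sent.chars, config, segmenter):
            ids = []
            for f in feats:
                if f in feature_index:
                    ids.append(feature_index[f])
                elif strict:
                    raise KeyError(f"feature {f!r} not in the feature index")
            ids_per_pos.append(np.array(ids, dtype=np.intp))
        labels = np.array([scheme.index(lab) for lab in sent.labels], dtype=np.intp)
        out.append(FeaturizedSentence(ids_per_pos, labels))
    return out


def neg_log_likelihood_and_gradient(
    state_weights: np.ndarray,
    transitions: np.ndarray,
    batch: list[FeaturizedSentence],
    c_reg: float = 1.0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """L2-penalized NLL and its gradient over a batch of featurized sentences."""
    if not batch:
        raise ValueError("empty batch")
    grad_state = np.zeros_like(state_weights)
    grad_trans = np.zeros_like(transitions)
    loss = 0.0
    for fs in batch:
        if len(fs) == 0:
            continue
        emissions = np.zeros((len(fs), state_weights.shape[1]))
        for t, ids in enumerate(fs.feature_ids):
            if ids.size:
                emissions[t] = state_weights[ids].sum(axis=0)
        scores = SequenceScores(emissions, transitions)
        node, pair, log_z = posterior_marginals(scores)
        loss += log_z - sequence_log_score(scores, fs.label_ids)
        # expected minus empirical state-feature counts
        for t, ids in enumerate(fs.feature_ids):
            if ids.size:
                np.add.at(grad_state, ids, node[t])
                grad_state[ids, fs.label_ids[t]] -= 1.0
        grad_trans += pair
        y = fs.label_ids
        if y.shape[0] > 1:
            np.add.at(grad_trans, (y[:-1], y[1:]), -1.0)
    loss += 0.5 * c_reg * (float(np.sum(state_weights**2)) + float(np.sum(transitions**2)))
    grad_state += c_reg * state_weights
    grad_trans += c_reg * transitions
    return loss, grad_state, grad_trans


def _pack_batch(
    batch: list[FeaturizedSentence], n_features: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pad a featurized batch into dense index tensors.

    Returns ``(ids, labels, lengths)`` where ``ids`` is [B x T x K] feature
    indices (padded with the dummy index ``n_features``, whose weight row is
    held at zero), ``labels`` is [B x T] gold label ids (pad 0), and
    ``lengths`` the true sentence lengths.
    """
    batch = [fs for fs in batch if len(fs) > 0]
    B = len(batch)
    T = max(len(fs) for fs in batch)
    K = max((ids.size for fs in batch for ids in fs.feature_ids), default=1)
    ids = np.full((B, T, max(K, 1)), n_features, dtype=np.intp)
    labels = np.zeros((B, T), dtype=np.intp)
    lengths = np.zeros(B, dtype=np.intp)
    for b, fs in enumerate(batch):
        lengths[b] = len(fs)
        labels[b, : len(fs)] = fs.label_ids
        for t, row in enumerate(fs.feature_ids):
            ids[b, t, : row.size] = row
    return ids, labels, lengths


def _logsumexp_last(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=-1)
    return m + np.log(np.exp(a - m[..., None]).sum(axis=-1))


def batched_nll_and_gradient(
    state_weights: np.ndarray,
    transitions: np.ndarray,
    packed: tuple[np.ndarray, np.ndarray, np.ndarray],
    c_reg: float = 1.0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Vectorized L2-penalized NLL and gradient over a padded batch.

    Numerically identical (up to float reordering) to
    :func:`neg_log_likelihood_and_gradient`; runs the forward-backward
    recursions across all sentences at once for speed.
    """
    ids, labels, lengths = packed
    B, T, K = ids.shape
    F, L = state_weights.shape
    sw_aug = np.vstack([state_weights, np.zeros((1, L))])
    emissions = sw_aug[ids].sum(axis=2)  # [B x T x L]
    t_range = np.arange(T)
    valid = t_range[None, :] < lengths[:, None]  # [B x T]

    # forward; padded steps carry alpha unchanged so alpha[:, -1] is final
    alpha = np.empty((B, T, L))
    alpha[:, 0] = emissions[:, 0]
    for t in range(1, T):
        prev = alpha[:, t - 1]
        step = emissions[:, t] + _logsumexp_last(
            prev[:, :, None].transpose(0, 2, 1) + transitions.T[None]
        )
        alpha[:, t] = np.where(valid[:, t, None], step, prev)
    log_z = _logsumexp_last(alpha[:, -1])

    # backward; beta = 0 at and beyond the last real position
    beta = np.zeros((B, T, L))
    for t in range(T - 2, -1, -1):
        nxt = emissions[:, t + 1] + beta[:, t + 1]
        step = _logsumexp_last(transitions[None] + nxt[:, None, :])
        inside = (t + 1) < lengths
        beta[:, t] = np.where(inside[:, None], step, 0.0)

    node = np.exp(alpha + beta - log_z[:, None, None])
    node[~valid] = 0.0

    # pairwise marginals summed over batch and time
    pair = np.zeros((L, L))
    for t in range(1, T):
        inside = valid[:, t]
        if not inside.any():
            continue
        log_pair = (
            alpha[:, t - 1, :, None]
            + transitions[None]
            + (emissions[:, t] + beta[:, t])[:, None, :]
            - log_z[:, None, None]
        )
        pair += np.exp(log_pair[inside]).sum(axis=0)

    # gold score
    b_idx = np.arange(B)[:, None]
    gold_em = np.where(valid, emissions[b_idx, t_range[None], labels], 0.0).sum()
    trans_mask = valid[:, 1:]
    gold_tr = np.where(trans_mask, transitions[labels[:, :-1], labels[:, 1:]], 0.0).sum()
    loss = float(log_z.sum() - gold_em - gold_tr)

    # state gradient: expected minus empirical counts, scattered by feature id
    grad_aug = np.zeros_like(sw_aug)
    flat_ids = ids.reshape(B * T, K)
    flat_node = node.reshape(B * T, L)
    np.add.at(grad_aug, flat_ids.ravel(), np.repeat(flat_node, K, axis=0))
    emp = np.zeros((B * T, L))
    emp[np.arange(B * T), labels.ravel()] = valid.ravel().astype(np.float64)
    np.add.at(grad_aug, flat_ids.ravel(), np.repeat(-emp, K, axis=0))
    grad_state = grad_aug[:F]

    grad_trans = pair
    pairs_prev = labels[:, :-1][trans_mask]
    pairs_next = labels[:, 1:][trans_mask]
    np.add.at(grad_trans, (pairs_prev, pairs_next), -1.0)

    loss += 0.5 * c_reg * (float(np.sum(state_weights**2)) + float(np.sum(transitions**2)))
    grad_state += c_reg * state_weights
    grad_trans += c_reg * transitions
    return loss, grad_state, grad_trans


def train_crf(
    corpus: list[TaggedSentence],
    config: FeatureConfig = FeatureConfig(),
    segmenter: Segmenter | None = None,
    scheme: TagScheme | None = None,
    c_reg: float = 1.0,
    max_iter: int = 200,
    gtol: float = 1e-5,
    lbfgs_memory: int = 10,
) -> CrfModel:
    """Train a CRF by batch L-BFGS on the featurized corpus.

    Deterministic given the corpus and configuration: the feature index is
    built in corpus order and the optimizer starts from zero weights.
    """
    if not corpus:
        raise ValueError("empty training corpus")
    scheme = scheme or TagScheme()
    feature_index = build_feature_index(corpus, config, segmenter)
    batch = featurize_corpus(corpus, feature_index, scheme, config, segmenter)
    F, L = len(feature_index), scheme.n_labels
    n_state = F * L
    packed = _pack_batch(batch, F)

    losses: list[float] = []

    def objective(w: np.ndarray) -> tuple[float, np.ndarray]:
        state = w[:n_state].reshape(F, L)
        trans = w[n_state:].reshape(L, L)
        loss, gs, gt = batched_nll_and_gradient(state, trans, packed, c_reg)
        losses.append(loss)
        return loss, np.concatenate([gs.ravel(), gt.ravel()])

    w0 = np.zeros(n_state + L * L)
    w_opt, final_loss, info = fmin_l_bfgs_b(
        objective, w0, m=lbfgs_memory, maxiter=max_iter, pgtol=gtol, factr=10.0
    )
    logger.info(
        "CRF training finished: %d features, final loss %.4f, %d evaluations",
        F, final_loss, info["funcalls"],
    )
    model = CrfModel(
        feature_index,
        w_opt[:n_state].reshape(F, L).copy(),
        w_opt[n_state:].reshape(L, L).copy(),
        scheme,
        config,
    )
    model.training_losses = losses  # type: ignore[attr-defined]
    return model


def predict_sentence(
    model: CrfModel,
    chars: str,
    segmenter: Segmenter | None = None,
    doc_offset: int = 0,
) -> set[EntityMention]:
    """Decode one sentence into entity mentions with document-level offsets."""
    if not chars:
        return set()
    feature_ids = model.featurize(chars, segmenter)
    path, _ = viterbi_decode(model.scores_for(feature_ids))
    labels = [model.scheme.labels[j] for j in path]
    return bio_to_entities(TaggedSentence(chars, labels, doc_offset=doc_offset), model.scheme)


def predict_document(
    model: CrfModel,
    text: str,
    segmenter: Segmenter | None = None,
) -> set[EntityMention]:
    """Split a document into sentences and decode each."""
    mentions: set[EntityMention] = set()
    for sent, start in split_sentences(text):
        mentions |= predict_sentence(model, sent, segmenter, doc_offset=start)
    return mentions


# ---------------------------------------------------------------------------
# Serialization: one versioned .npz container, bit-exact round-trip
# ---------------------------------------------------------------------------

def save_crf(model: CrfModel, path: str | Path) -> None:
    features = sorted(model.feature_index, key=model.feature_index.get)
    np.savez(
        path,
        format_version=np.array([1]),
        kind=np.array(["crf"]),
        features=np.array(features, dtype=np.str_),
        state_weights=model.state_weights,
        transitions=model.transitions,
        categories=np.array(model.scheme.categories, dtype=np.str_),
        families=np.array(model.config.families, dtype=np.str_),
        window=np.array([model.config.window]),
        bigrams=np.array([int(model.config.bigrams)]),
    )


def load_crf(path: str | Path) -> CrfModel:
    with np.load(path, allow_pickle=False) as data:
        if str(data["kind"][0]) != "crf":
            raise ValueError(f"{path} is not a CRF model file")
        features = [str(f) for f in data["features"]]
        config = FeatureConfig(
            families=tuple(str(f) for f in data["families"]),
            window=int(data["window"][0]),
            bigrams=bool(data["bigrams"][0]),
        )
        return CrfModel(
            {f: i for i, f in enumerate(features)},
            data["state_weights"].copy(),
            data["transitions"].copy(),
            TagScheme(tuple(str(c) for c in data["categories"])),
            config,
        )
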
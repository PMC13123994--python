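"""Training machinery: resampling, loss, cross-validation, thresholding.

Training operates on whole-protein graphs with a binary cross-entropy loss
over residues and Adam updates.  Class imbalance is handled two ways:

* :func:`resample` implements the hybrid strategy on a flat feature matrix —
  SMOTE over-sampling of positives plus random under-sampling of negatives
  to an exact 1:2 positive:negative ratio;
* inside graph training, where synthetic residues would have no coordinates
  or edges, the same 1:2 balance is applied as a per-protein loss mask with
  negatives under-sampled.

The decision threshold is chosen to maximize F1 on validation scores.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .autodiff import Adam, Tensor
from .metrics import aupr, confusion_counts, confusion_metrics, roc_auc
from .model_core import ModalityBundle, ModelConfig, ModelParams, forward

__all__ = [
    "TrainConfig",
    "ProteinSample",
    "resample",
    "bce_loss",
    "kfold_split",
    "select_threshold",
    "train",
    "cross_validate",
    "predict",
]


@dataclasses.dataclass
class TrainConfig:
    lr: float = 1e-3
    epochs: int = 100
    betas: tuple = (0.9, 0.999)
    seed: int = 0
    resample_ratio: float = 2.0      # negatives per positive in the loss mask
    smote_neighbors: int = 5
    patience: int = 10               # early stop on validation AUPR
    balance_loss: bool = True


@dataclasses.dataclass
class ProteinSample:
    """One training unit: a protein's modalities, graph and labels."""
    protein_id: str
    bundle: ModalityBundle
    graph: object
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size != self.bundle.n_residues:
            raise ValueError("label count does not match residue count")


def resample(features: np.ndarray, labels: np.ndarray, ratio: float = 2.0,
             smote_neighbors: int = 5, seed: int = 0):
    """Hybrid resampling to a 1:``ratio`` positive:negative class balance.

    Positives are augmented with SMOTE (each synthetic point is a uniform
    interpolation between a positive and one of its ``smote_neighbors``
    nearest positive neighbours); negatives are randomly under-sampled.
    The target sizes are final_pos = min(2·n_pos, ⌊n_neg/ratio⌋) and
    final_neg = min(n_neg, ratio·final_pos); a set already at or below the
    target ratio is returned unchanged (shuffled).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    n_pos, n_neg = len(pos_idx), len(neg_idx)
    if n_pos < smote_neighbors + 1:
        raise ValueError(
            f"need at least {smote_neighbors + 1} positives for SMOTE; "
            "consider pure under-sampling"
        )
    if n_neg <= ratio * n_pos:
        perm = rng.permutation(labels.size)
        return features[perm], labels[perm]

    final_pos = min(2 * n_pos, int(n_neg // ratio))
    final_neg = min(n_neg, int(round(ratio * final_pos)))
    n_synth = final_pos - n_pos

    pos_feats = features[pos_idx]
    nn = NearestNeighbors(n_neighbors=smote_neighbors + 1).fit(pos_feats)
    neighbor_idx = nn.kneighbors(pos_feats, return_distance=False)[:, 1:]
    base = rng.integers(0, n_pos, size=n_synth)
    pick = rng.integers(0, smote_neighbors, size=n_synth)
    gamma = rng.uniform(0.0, 1.0, size=n_synth)
    partners = neighbor_idx[base, pick]
    synth = pos_feats[base] + gamma[:, None] * (
        pos_feats[partners] - pos_feats[base]
    )

    keep_neg = rng.choice(neg_idx, size=final_neg, replace=False)
    out_feats = np.vstack([pos_feats, synth, features[keep_neg]])
    out_labels = np.r_[
        np.ones(final_pos, dtype=int), np.zeros(final_neg, dtype=int)
    ]
    perm = rng.permutation(out_labels.size)
    return out_feats[perm], out_labels[perm]


def bce_loss(p, y, eps: float = 1e-7):
    """Mean binary cross-entropy with probability clipping at ``eps``.

    Accepts numpy arrays (returns a float) or an autodiff Tensor of
    probabilities (returns a Tensor for backprop).
    """
    if isinstance(p, Tensor):
        y = np.asarray(y, dtype=float)
        clipped = Tensor(np.clip(p.data, eps, 1.0 - eps))
        clipped.requires_grad = p.requires_grad
        clipped._parents = (p,)
        inside = (p.data > eps) & (p.data < 1.0 - eps)

        def bwd(g):
            if p.requires_grad:
                p.grad += g * inside

        clipped._backward = bwd
        term = Tensor(y) * clipped.log() + Tensor(1.0 - y) * (1.0 - clipped).log()
        return -term.mean()
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    y = np.asarray(y, dtype=float)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def kfold_split(protein_ids, folds: int = 10, seed: int = 0):
    """Protein-level k-fold partition: disjoint folds covering all ids,
    sizes differing by at most one."""
    ids = list(protein_ids)
    if folds < 2 or folds > len(ids):
        raise ValueError("folds must be in [2, n_proteins]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    chunks = np.array_split(order, folds)
    splits = []
    for c in chunks:
        val = [ids[i] for i in c]
        train_ids = [ids[i] for i in order if i not in set(c)]
        splits.append((train_ids, val))
    return splits


def select_threshold(scores, labels):
    """Threshold maximizing F1 (rule: score ≥ t → positive).

    Candidates are −∞, +∞ and the midpoints between consecutive sorted
    unique scores; ties resolve to the lowest threshold.  With no positive
    labels every threshold has F1 = 0 and +∞ (predict all-negative) is
    returned.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0:
        return np.inf
    uniq = np.unique(scores)
    candidates = np.r_[-np.inf, (uniq[:-1] + uniq[1:]) / 2.0, np.inf]
    best_t, best_f1 = np.inf, -1.0
    for t in candidates:
        tp, fp, fn, _tn = confusion_counts(scores, labels, t)
        m = confusion_metrics(tp, fp, fn, _tn)
        if m["f1"] > best_f1 + 1e-15:
            best_f1, best_t = m["f1"], t
    return float(best_t)


def _loss_mask(labels: np.ndarray, ratio: float,
               rng: np.random.Generator) -> np.ndarray:
    """Boolean residue mask: all positives plus ratio× under-sampled
    negatives (all negatives if fewer are available)."""
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    n_keep = min(len(neg), int(round(ratio * max(len(pos), 1))))
    keep_neg = rng.choice(neg, size=n_keep, replace=False)
    mask = np.zeros(labels.size, dtype=bool)
    mask[pos] = True
    mask[keep_neg] = True
    return mask


def predict(params: ModelParams, sample: ProteinSample) -> np.ndarray:
    """Per-residue epitope probabilities for one protein (inference mode)."""
    return forward(sample.bundle, sample.graph, params, mode="infer").data


def _scores_over(params, samples):
    scores = [predict(params, s) for s in samples]
    labels = [s.labels for s in samples]
    return np.concatenate(scores), np.concatenate(labels)


def train(train_samples, config: TrainConfig,
          model_config: ModelConfig | None = None,
          val_samples=None):
    """Fit the dual-branch model with Adam on BCE loss.

    Returns ``(params, history)`` where history holds the per-epoch mean
    training loss and, when a validation set is given, validation AUPR.
    Early stopping monitors validation AUPR with the configured patience
    and restores the best parameters.
    """
    if model_config is None:
        b = train_samples[0].bundle
        model_config = ModelConfig(
            seq_dim=b.seq_emb.shape[1], if_dim=b.if_emb.shape[1],
            dssp_dim=b.dssp_feats.shape[1], seed=config.seed,
        )
    params = ModelParams(model_config)
    opt = Adam(params.parameters(), lr=config.lr, betas=config.betas)
    rng = np.random.default_rng(config.seed)
    masks = [
        _loss_mask(s.labels, config.resample_ratio, rng)
        if config.balance_loss else np.ones(s.labels.size, dtype=bool)
        for s in train_samples
    ]

    history = {"loss": [], "val_aupr": []}
    best_aupr, best_state, since_best = -np.inf, None, 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_samples))
        losses = []
        for i in order:
            s = train_samples[i]
            opt.zero_grad()
            probs = forward(s.bundle, s.graph, params, mode="train",
                            dropout_rng=rng)
            mask = masks[i]
            loss = bce_loss(probs.take_rows(np.flatnonzero(mask)),
                            s.labels[mask])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["loss"].append(float(np.mean(losses)))

        if val_samples:
            vs, vl = _scores_over(params, val_samples)
            val_aupr = aupr(vs, vl)
            history["val_aupr"].append(val_aupr)
            if val_aupr > best_aupr:
                best_aupr, since_best = val_aupr, 0
                best_state = [p.data.copy() for p in params.parameters()]
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
    if best_state is not None:
        for p, d in zip(params.parameters(), best_state):
            p.data = d
    return params, history


def cross_validate(samples, config: TrainConfig, folds: int = 10,
                   model_config: ModelConfig | None = None,
                   selection: str = "validation", test_samples=None):
    """Protein-level k-fold cross-validation.

    ``selection='validation'`` (default) picks the fold model with the best
    held-out-fold AUC — leak-free.  ``selection='test'`` mirrors the
    protocol of picking the fold model with the highest AUC on the external
    test set (optimistic; requires ``test_samples``).

    Returns (best_params, per-fold records, threshold from the best fold's
    validation scores).
    """
    if selection not in ("validation", "test"):
        raise ValueError("selection must be 'validation' or 'test'")
    if selection == "test" and not test_samples:
        raise ValueError("selection='test' requires test_samples")
    by_id = {s.protein_id: s for s in samples}
    splits = kfold_split(list(by_id), folds=folds, seed=config.seed)
    records, fitted = [], []
    for fold, (tr_ids, va_ids) in enumerate(splits):
        tr = [by_id[i] for i in tr_ids]
        va = [by_id[i] for i in va_ids]
        params, history = train(tr, config, model_config, val_samples=va)
        vs, vl = _scores_over(params, va)
        rec = {
            "fold": fold,
            "val_auc": roc_auc(vs, vl),
            "val_aupr": aupr(vs, vl),
            "threshold": select_threshold(vs, vl),
        }
        if test_samples:
            ts, tl = _scores_over(params, test_samples)
            rec["test_auc"] = roc_auc(ts, tl)
        records.append(rec)
        fitted.append(params)
    key = "val_auc" if selection == "validation" else "test_auc"
    best = int(np.argmax([r[key] for r in records]))
    return fitted[best], records, records[best]["threshold"]
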
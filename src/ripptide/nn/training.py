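"""Training loops, data splitting, and cross-validation for the sequence models."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Adam
from .models import (Bgc2orfSpec, CleavageTagger, DataSplit, Orf2coreSpec,
                     PrecursorClassifier, encode_sequence, labels_for_core)


@dataclass
class TrainResult:
    model: object
    metrics: dict


def split_data(n: int, split: DataSplit, rng: np.random.Generator):
    """Disjoint train/validation/test index arrays in the split proportions."""
    idx = rng.permutation(n)
    n_train = int(round(split.train * n))
    n_val = int(round(split.validation * n))
    return idx[:n_train], idx[n_train:n_train + n_val], idx[n_train + n_val:]


def _rebalance(pos_idx, neg_idx, rng):
    """Subsample negatives to match the positive count."""
    if len(neg_idx) > len(pos_idx):
        neg_idx = rng.choice(neg_idx, size=len(pos_idx), replace=False)
    return np.sort(neg_idx)


def train_bgc2orf(sequences: list[str], labels: list[int],
                  split: DataSplit | None = None,
                  spec: Bgc2orfSpec | None = None,
                  seed: int = 0, batch_size: int = 64,
                  partitions=None) -> TrainResult:
    """Train the precursor classifier with class-rebalanced splits.

    Deterministic given the seed.  Negatives are randomly subsampled to
    match the positives in each partition; early stopping monitors
    validation loss.  ``partitions`` may supply explicit
    (train, val, test) index arrays (used by cross-validation).
    """
    spec = spec or Bgc2orfSpec()
    split = split or DataSplit()
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("need both positive and negative examples")
    rng = np.random.default_rng(seed)
    if partitions is None:
        parts = {}
        for name, cls_idx in (("pos", np.flatnonzero(labels == 1)),
                              ("neg", np.flatnonzero(labels == 0))):
            tr, va, te = split_data(len(cls_idx), split, rng)
            parts[name] = (cls_idx[tr], cls_idx[va], cls_idx[te])
        partitions = tuple(
            np.concatenate([parts["pos"][k], parts["neg"][k]]) for k in range(3))
    sets = {}
    n_train_pos = n_train_neg = 0
    for part, idx in zip(("train", "val", "test"), partitions):
        pos = idx[labels[idx] == 1]
        neg = idx[labels[idx] == 0]
        if split.rebalance:
            neg = _rebalance(pos, neg, rng)
        use = np.concatenate([pos, neg])
        ids = np.stack([encode_sequence(sequences[i], spec.pad_len) for i in use]) \
            if len(use) else np.zeros((0, spec.pad_len), dtype=np.int64)
        sets[part] = (ids, labels[use].astype(float))
        if part == "train":
            n_train_pos, n_train_neg = len(pos), len(neg)

    model = PrecursorClassifier(spec, seed=seed)
    metrics = _fit(model, sets, rng, spec, batch_size,
                   loss_fn=lambda m, ids, y: m.loss(ids, y),
                   acc_fn=lambda m, ids, y: float(
                       np.mean((m.forward(ids).data.ravel() >= spec.cutoff) == (y == 1))))
    metrics["n_train_pos"] = n_train_pos
    metrics["n_train_neg"] = n_train_neg
    return TrainResult(model, metrics)


def train_orf2core(sequences: list[str], cores: list[tuple[int, int]],
                   split: DataSplit | None = None,
                   spec: Orf2coreSpec | None = None,
                   seed: int = 0, batch_size: int = 64,
                   partitions=None) -> TrainResult:
    """Train the cleavage tagger on (ORF, core interval) pairs."""
    spec = spec or Orf2coreSpec()
    split = split or DataSplit()
    rng = np.random.default_rng(seed)
    ids = np.stack([encode_sequence(s, spec.pad_len) for s in sequences])
    lab, msk = zip(*[labels_for_core(min(len(s), spec.pad_len), cs, ce, spec.pad_len)
                     for s, (cs, ce) in zip(sequences, cores)])
    lab, msk = np.stack(lab), np.stack(msk)
    if partitions is None:
        partitions = split_data(len(sequences), split, rng)
    tr, va, te = partitions
    sets = {part: (ids[i], (lab[i], msk[i]))
            for part, i in (("train", tr), ("val", va), ("test", te))}

    model = CleavageTagger(spec, seed=seed)

    def acc_fn(m, ids_, y_):
        lab_, msk_ = y_
        correct = total = 0
        for ids_row, lab_row, msk_row in zip(ids_, lab_, msk_):
            L = int(msk_row.sum())
            from .crf import crf_viterbi
            emis = m.emissions(ids_row[None, :]).data[0][:L]
            path = crf_viterbi(emis, m._trans_matrix())
            correct += int(np.sum(np.asarray(path) == lab_row[:L]))
            total += L
        return correct / max(total, 1)

    metrics = _fit(model, sets, rng, spec, batch_size,
                   loss_fn=lambda m, ids_, y_: m.loss(ids_, y_[0], y_[1]),
                   acc_fn=acc_fn)
    return TrainResult(model, metrics)


def _fit(model, sets, rng, spec, batch_size, loss_fn, acc_fn):
    opt = Adam(model.params(), lr=spec.lr)
    ids_tr, y_tr = sets["train"]
    n = len(ids_tr)
    best_val = np.inf
    best_state = None
    stale = 0
    history = []
    for epoch in range(spec.max_epochs):
        opt.lr = spec.lr * spec.lr_decay ** (epoch // spec.lr_decay_every)
        order = rng.permutation(n)
        for lo in range(0, n, batch_size):
            sel = order[lo:lo + batch_size]
            y = (y_tr[sel] if not isinstance(y_tr, tuple)
                 else (y_tr[0][sel], y_tr[1][sel]))
            loss = loss_fn(model, ids_tr[sel], y)
            opt.zero_grad()
            loss.backward()
            opt.step()
        if len(sets["val"][0]):
            val_loss = float(loss_fn(model, *sets["val"]).data)
        else:
            val_loss = float(loss_fn(model, ids_tr, y_tr).data)
        history.append(val_loss)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = [p.data.copy() for p in model.params()]
            stale = 0
        else:
            stale += 1
            if stale > spec.patience:
                break
    if best_state is not None:
        for p, d in zip(model.params(), best_state):
            p.data = d
    metrics = {"epochs": len(history), "val_loss": best_val,
               "val_history": history}
    for part in ("train", "val", "test"):
        ids_, y_ = sets[part]
        if len(ids_):
            metrics[f"{part}_accuracy"] = acc_fn(model, ids_, y_)
    return metrics


def crossval(train_fn, data, folds: int = 10, seed: int = 0, **kwargs) -> dict:
    """K-fold cross-validation; each example is tested exactly once.

    ``train_fn(sequences, targets, split=..., seed=...)`` must accept a
    DataSplit whose test fraction it respects; here folds are carved out
    explicitly and passed as the test partition via index masking.
    """
    sequences, targets = data
    n = len(sequences)
    counts = None
    if all(t in (0, 1) for t in targets):
        counts = min(sum(1 for t in targets if t == 1),
                     sum(1 for t in targets if t == 0))
    if (counts if counts is not None else n) < folds:
        raise ValueError("too few examples per class for the requested folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_ids = np.array_split(order, folds)
    accs = []
    for k, test_idx in enumerate(fold_ids):
        rest = np.concatenate([f for j, f in enumerate(fold_ids) if j != k])
        rest = rng.permutation(rest)
        n_val = max(1, int(round(0.1 * len(rest))))
        partitions = (rest[n_val:], rest[:n_val], test_idx)
        res = train_fn(sequences, targets, seed=seed + k,
                       partitions=partitions, **kwargs)
        accs.append(res.metrics.get("test_accuracy", np.nan))
    return {"fold_accuracies": accs, "mean_accuracy": float(np.mean(accs)),
            "folds": folds, "test_partition": [f.tolist() for f in fold_ids]}


def save_model(model, path) -> None:
    """Checkpoint: npz arrays + embedded spec JSON."""
    arrays = {f"p{i}": p.data for i, p in enumerate(model.params())}
    arrays["spec_json"] = np.frombuffer(
        json.dumps({"class": type(model).__name__,
                    "spec": asdict(model.spec)}).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path):
    data = np.load(path)
    meta = json.loads(bytes(data["spec_json"].tolist()).decode())
    cls = {"PrecursorClassifier": PrecursorClassifier,
           "CleavageTagger": CleavageTagger}[meta["class"]]
    spec_cls = {"PrecursorClassifier": Bgc2orfSpec,
                "CleavageTagger": Orf2coreSpec}[meta["class"]]
    model = cls(spec_cls(**meta["spec"]))
    for i, p in enumerate(model.params()):
        p.data = data[f"p{i}"]
    return model
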
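"""Self-supervised pretraining and frozen-backbone supervised fine-tuning.

Pretraining uses masked-frame reconstruction: a fraction of input frames is
replaced by a learned 60-dim mask token, the transformer encodes the corrupted
sequence, and a linear head (discarded afterwards) reconstructs the original
frames; the loss is the mean squared error on masked positions only.

Fine-tuning freezes the speech encoder entirely — its parameters are
bit-identical before and after — and trains only the classifier and, where
present, the demographic lookup tables (about 4-5% of a speech-bearing
assembly's parameters).  Training folds are class-balanced by majority
undersampling; an inner stratified 80/20 split drives early stopping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import AcousticFeatureMatrix
from .models import ModelAssembly
from .nn import Adam, Linear, softmax

__all__ = [
    "SSLConfig",
    "FinetuneConfig",
    "CohortDataset",
    "balance_training_set",
    "pretrain_speech_embedding",
    "finetune",
    "precompute_speech_embeddings",
    "predict_proba",
]


@dataclass(frozen=True)
class SSLConfig:
    mask_fraction: float = 0.15
    learning_rate: float = 1e-3
    epochs: int = 10
    batch_size: int = 16
    heldout_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.mask_fraction < 1):
            raise ValueError(
                "mask_fraction must lie strictly in (0, 1); masking nothing "
                "makes the reconstruction objective vacuous"
            )


@dataclass(frozen=True)
class FinetuneConfig:
    learning_rate: float = 1e-3
    max_epochs: int = 200
    patience: int = 10
    inner_val_fraction: float = 0.2
    balance: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class CohortDataset:
    """Aligned per-participant arrays consumed by training and evaluation."""

    ids: list[str]
    features: list[AcousticFeatureMatrix | None]
    ages: np.ndarray
    sexes: list[str]
    labels: np.ndarray
    functionals: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.ids)


def balance_training_set(
    indices: np.ndarray, labels: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Undersample the majority class (without replacement) to the minority count."""
    indices = np.asarray(indices)
    labels = np.asarray(labels)
    if len(indices) != len(labels):
        raise ValueError("indices and labels must have equal length")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present to balance a training set")
    rng = np.random.default_rng(seed)
    counts = {c: int(np.sum(labels == c)) for c in classes}
    n_min = min(counts.values())
    kept: list[np.ndarray] = []
    for c in classes:
        idx_c = indices[labels == c]
        if len(idx_c) > n_min:
            idx_c = rng.choice(idx_c, size=n_min, replace=False)
        kept.append(np.sort(idx_c))
    return np.concatenate(kept)


# ---------------------------------------------------------------------------
# self-supervised pretraining


def _segment_corpus(
    features: list[AcousticFeatureMatrix], chunk_frames: int
) -> np.ndarray:
    """Stack equal-length training segments (n_seg, L, 60) from a corpus."""
    min_t = min(f.n_frames for f in features)
    seg_len = min(chunk_frames, min_t)
    segs = []
    for f in features:
        v = f.values
        for a in range(0, v.shape[0] - seg_len + 1, seg_len):
            segs.append(v[a : a + seg_len])
    return np.stack(segs)


def pretrain_speech_embedding(
    corpus_features: list[AcousticFeatureMatrix],
    encoder_module,
    config: SSLConfig | None = None,
) -> tuple[dict[str, np.ndarray], list[float]]:
    """Masked-frame reconstruction pretraining of a speech encoder.

    Returns the trained encoder weights and the held-out masked-reconstruction
    loss trace (entry 0 is the pre-training loss).  The reconstruction head and
    mask token are discarded.  Deterministic for a fixed config seed.
    """
    if not corpus_features:
        raise ValueError("pretraining corpus is empty")
    config = config or SSLConfig()
    enc = encoder_module.encoder
    rng = np.random.default_rng(config.seed)

    segs = _segment_corpus(corpus_features, encoder_module.config.chunk_frames)
    n = segs.shape[0]
    order = rng.permutation(n)
    n_held = max(1, int(round(config.heldout_fraction * n)))
    held, train = segs[order[:n_held]], segs[order[n_held:]]
    if train.shape[0] == 0:
        raise ValueError("corpus too small: no training segments left after holdout")

    d_in = enc.input_dim
    mask_token = rng.normal(0.0, 0.1, size=d_in)
    head = Linear(enc.model_dim, d_in, rng)

    params = {f"enc.{k}": v for k, v in enc.parameters().items()}
    params.update({f"head.{k}": v for k, v in head.parameters().items()})
    params["mask_token"] = mask_token
    opt = Adam(params, lr=config.learning_rate)

    t_seg = segs.shape[1]
    n_mask = max(1, int(round(config.mask_fraction * t_seg)))

    def make_mask(r: np.random.Generator, batch: int) -> np.ndarray:
        m = np.zeros((batch, t_seg), dtype=bool)
        for b in range(batch):
            m[b, r.choice(t_seg, size=n_mask, replace=False)] = True
        return m

    held_mask = make_mask(np.random.default_rng(config.seed + 1), held.shape[0])

    def masked_loss(x: np.ndarray, mask: np.ndarray, train_mode: bool) -> float:
        xm = x.copy()
        xm[mask] = mask_token
        h = enc.forward(xm)
        recon = head.forward(h)
        err = (recon - x)[mask]
        loss = float(np.mean(err**2))
        if train_mode:
            drecon = np.zeros_like(recon)
            drecon[mask] = 2.0 * err / err.size
            dh = head.backward(drecon)
            dx = enc.backward(dh)
            grads = {f"enc.{k}": v for k, v in enc.grads().items()}
            grads.update({f"head.{k}": v for k, v in head.grads().items()})
            grads["mask_token"] = dx[mask].sum(axis=0)
            opt.step(grads)
        return loss

    trace = [masked_loss(held, held_mask, train_mode=False)]
    for epoch in range(config.epochs):
        ep_rng = np.random.default_rng(config.seed + 1000 + epoch)
        perm = ep_rng.permutation(train.shape[0])
        for a in range(0, len(perm), config.batch_size):
            batch = train[perm[a : a + config.batch_size]]
            enc.zero_grad()
            head.zero_grad()
            masked_loss(batch, make_mask(ep_rng, batch.shape[0]), train_mode=True)
        trace.append(masked_loss(held, held_mask, train_mode=False))
    return enc.state_dict(), trace


# ---------------------------------------------------------------------------
# supervised fine-tuning (frozen backbone)


def precompute_speech_embeddings(
    assembly: ModelAssembly, dataset: CohortDataset, indices=None
) -> dict[int, np.ndarray]:
    """Embed each clip once through the frozen encoder (keyed by dataset index)."""
    if assembly.speech is None:
        return {}
    if indices is None:
        indices = range(len(dataset))
    out = {}
    for i in indices:
        feats = dataset.features[i]
        if feats is None:
            raise ValueError(f"sample {dataset.ids[i]} has no speech features")
        out[int(i)] = assembly.speech.embed(feats)
    return out


def _joint_matrix(
    assembly: ModelAssembly,
    dataset: CohortDataset,
    indices: np.ndarray,
    speech_cache: dict[int, np.ndarray],
) -> np.ndarray:
    rows = []
    for i in indices:
        rows.append(
            assembly.joint_vector(
                speech_vec=speech_cache.get(int(i)),
                age=dataset.ages[i] if assembly.demo is not None else None,
                sex=dataset.sexes[i] if assembly.demo is not None else None,
            )
        )
    return np.stack(rows)


def _demo_index_cols(assembly, dataset, indices):
    age_bins = np.array([assembly.demo.age_bin(dataset.ages[i]) for i in indices])
    sex_idx = np.array([assembly.demo.sex_index(dataset.sexes[i]) for i in indices])
    return age_bins, sex_idx


def _stratified_inner_split(
    indices: np.ndarray, labels: np.ndarray, frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    tr, va = [], []
    for c in np.unique(labels):
        idx_c = indices[labels == c]
        idx_c = rng.permutation(idx_c)
        n_val = max(1, int(round(frac * len(idx_c))))
        if n_val >= len(idx_c):
            raise ValueError("inner split leaves no training samples for a class")
        va.append(idx_c[:n_val])
        tr.append(idx_c[n_val:])
    return np.concatenate(tr), np.concatenate(va)


def _ce_loss_and_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    p = softmax(logits, axis=1)
    n = len(y)
    loss = float(-np.mean(np.log(np.maximum(p[np.arange(n), y], 1e-12))))
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


def finetune(
    assembly: ModelAssembly,
    dataset: CohortDataset,
    train_indices: np.ndarray,
    config: FinetuneConfig | None = None,
    pretrained_weights: dict[str, np.ndarray] | None = None,
    speech_cache: dict[int, np.ndarray] | None = None,
) -> tuple[ModelAssembly, list[dict]]:
    """Train classifier (+ demographic tables) with the speech encoder frozen.

    Returns the assembly (updated in place) and a per-epoch training log.
    Raises if the (balanced) training fold contains a single class.
    """
    config = config or FinetuneConfig()
    rng = np.random.default_rng(config.seed)
    train_indices = np.asarray(train_indices)
    y_all = dataset.labels

    if pretrained_weights is not None:
        if assembly.speech is None:
            raise ValueError(f"{assembly.kind} has no speech branch to load weights into")
        assembly.speech.encoder.set_parameters(pretrained_weights)

    frozen_before = (
        assembly.speech.encoder.state_dict() if assembly.speech is not None else None
    )

    idx = train_indices
    if config.balance:
        idx = balance_training_set(idx, y_all[idx], seed=int(rng.integers(2**31)))
    if len(np.unique(y_all[idx])) < 2:
        raise ValueError("training fold has a single class after balancing")

    tr_idx, va_idx = _stratified_inner_split(idx, y_all[idx], config.inner_val_fraction, rng)

    if speech_cache is None:
        speech_cache = precompute_speech_embeddings(
            assembly, dataset, np.concatenate([tr_idx, va_idx])
        )

    has_demo = assembly.demo is not None
    if has_demo:
        speech_dim = assembly.speech.config.model_dim if assembly.speech else 0
        tr_bins, tr_sex = _demo_index_cols(assembly, dataset, tr_idx)
        va_bins, va_sex = _demo_index_cols(assembly, dataset, va_idx)

    def joint(ind, bins=None, sexi=None):
        return _joint_matrix(assembly, dataset, ind, speech_cache)

    x_tr = joint(tr_idx)
    x_va = joint(va_idx)
    y_tr = y_all[tr_idx].astype(int)
    y_va = y_all[va_idx].astype(int)

    clf = assembly.classifier
    params = {f"clf.{k}": v for k, v in clf.parameters().items()}
    if has_demo:
        params["demo.age_table"] = assembly.demo.age_table
        params["demo.sex_table"] = assembly.demo.sex_table
    opt = Adam(params, lr=config.learning_rate)

    def snapshot():
        return {k: v.copy() for k, v in params.items()}

    def restore(snap):
        for k, v in params.items():
            v[...] = snap[k]

    def rebuild_demo_rows(x, ind, bins, sexi):
        # refresh joint-vector demo slice after each table update
        if not has_demo:
            return x
        x[:, speech_dim : speech_dim + assembly.demo.config.age_embed_dim] = (
            assembly.demo.age_table[bins]
        )
        x[:, speech_dim + assembly.demo.config.age_embed_dim :] = (
            assembly.demo.sex_table[sexi]
        )
        return x

    best_val = np.inf
    best_snap = snapshot()
    best_epoch = 0
    wait = 0
    log: list[dict] = []
    stopped = False

    for epoch in range(config.max_epochs):
        if has_demo:
            x_tr = rebuild_demo_rows(x_tr, tr_idx, tr_bins, tr_sex)
        clf.zero_grad()
        logits = clf.forward(x_tr)
        train_loss, dlogits = _ce_loss_and_grad(logits, y_tr)
        dx = clf.backward(dlogits)
        grads = {f"clf.{k}": v for k, v in clf.grads().items()}
        if has_demo:
            d_age = np.zeros_like(assembly.demo.age_table)
            d_sex = np.zeros_like(assembly.demo.sex_table)
            age_d = assembly.demo.config.age_embed_dim
            np.add.at(d_age, tr_bins, dx[:, speech_dim : speech_dim + age_d])
            np.add.at(d_sex, tr_sex, dx[:, speech_dim + age_d :])
            grads["demo.age_table"] = d_age
            grads["demo.sex_table"] = d_sex
        opt.step(grads)

        if has_demo:
            x_va = rebuild_demo_rows(x_va, va_idx, va_bins, va_sex)
        val_loss, _ = _ce_loss_and_grad(clf.forward(x_va), y_va)
        log.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss, "stopped": False}
        )
        if val_loss < best_val - 1e-9:
            best_val, best_snap, best_epoch, wait = val_loss, snapshot(), epoch, 0
        else:
            wait += 1
            if wait >= config.patience:
                stopped = True
                break

    restore(best_snap)
    if log:
        log[-1]["stopped"] = stopped
        log[-1]["best_epoch"] = best_epoch

    if frozen_before is not None:
        after = assembly.speech.encoder.state_dict()
        drift = max(
            float(np.max(np.abs(after[k] - frozen_before[k]))) for k in frozen_before
        )
        if drift != 0.0:
            raise RuntimeError("frozen speech-encoder weights changed during fine-tuning")
    return assembly, log


def predict_proba(
    assembly: ModelAssembly,
    dataset: CohortDataset,
    indices: np.ndarray,
    speech_cache: dict[int, np.ndarray] | None = None,
) -> np.ndarray:
    """Positive-class probabilities for the given dataset rows."""
    indices = np.asarray(indices)
    if assembly.speech is not None and speech_cache is None:
        speech_cache = precompute_speech_embeddings(assembly, dataset, indices)
    x = _joint_matrix(assembly, dataset, indices, speech_cache or {})
    logits = assembly.classifier.forward(x)
    return softmax(logits, axis=1)[:, 1]
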
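"""End-to-end optimisation of the conditional sequence VAE.

The encoder, condition MLP, temporal module and decoder are trained
jointly with Adam on the sequence loss (frame-summed voxel-mean
cross-entropy + β·KL). Early stopping monitors the validation sequence
loss; the returned model carries the best-validation parameters.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

from .metrics import dice, STRUCTURES
from .model import ModelConfig, SequenceVAE, encode_condition_vector
from .nn import Adam
from .phantom import AnatomySequence, ConditionSet

logger = logging.getLogger(__name__)

__all__ = ["TrainRecord", "split_dataset", "train_model"]

Dataset = list[tuple[AnatomySequence, ConditionSet]]


@dataclass(frozen=True)
class TrainRecord:
    epoch: int
    train_loss: float
    val_loss: float
    val_dice: float
    wall_time: float  # seconds, metadata only


def split_dataset(subjects: list, fractions=(0.70, 0.10, 0.20),
                  seed: int = 0) -> tuple[list, list, list]:
    """Seeded disjoint train/validation/test split.

    Validation and test sizes are floors of their fractions; the
    remainder goes to training (so 10 subjects at (0.7, 0.1, 0.2) split
    as 7/1/2).
    """
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(subjects)
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    perm = np.random.default_rng(seed).permutation(n)
    train = [subjects[i] for i in perm[:n_train]]
    val = [subjects[i] for i in perm[n_train:n_train + n_val]]
    test = [subjects[i] for i in perm[n_train + n_val:]]
    return train, val, test


def _as_arrays(data: Dataset, config: ModelConfig):
    labels = np.stack([seq.labels for seq, _ in data])
    if labels.shape[1] != config.n_frames:
        raise ValueError(f"sequences have {labels.shape[1]} frames, "
                         f"config expects {config.n_frames}")
    cvecs = np.stack([encode_condition_vector(c) for _, c in data])
    return labels, cvecs


def _reconstruction_dice(model: SequenceVAE, labels: np.ndarray,
                         cvecs: np.ndarray) -> float:
    """Mean Dice over structures/frames of posterior-mean completions,
    batched across the whole validation set."""
    from .model import _one_hot
    from .nn import concat, constant, stack

    B, T = labels.shape[:2]
    z_c = model._embed_conditions_t(cvecs)
    mean, _ = model._encode_t(_one_hot(labels[:, 0], model.config.n_labels), z_c)
    zs = model._rollout_t(concat([mean, z_c], axis=1), T)
    flat = stack(zs, axis=0).reshape(T * B, model.config.joint_dim)
    pred = model.decode_labels(flat.data).reshape(T, B, *labels.shape[2:])
    scores = [dice(labels[b, t], pred[t, b], s)
              for b in range(B) for t in range(T) for s in STRUCTURES]
    return float(np.mean(scores))


def train_model(train_data: Dataset, val_data: Dataset,
                config: ModelConfig) -> tuple[SequenceVAE, list[TrainRecord]]:
    """Train from scratch; returns the best-validation model and history.

    Per epoch the training set is reshuffled (seeded) and consumed in
    minibatches of ``config.batch_size`` whole sequences. Training stops
    after ``config.max_epochs`` or when the validation loss has not
    improved for more than ``config.early_stop_patience`` epochs. A
    non-finite loss aborts with a diagnostic naming the epoch and batch.
    """
    model = SequenceVAE(config)
    labels, cvecs = _as_arrays(train_data, config)
    val_labels, val_cvecs = _as_arrays(val_data, config)
    model.init_output_bias(np.bincount(labels.reshape(-1),
                                       minlength=config.n_labels))
    opt = Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)

    records: list[TrainRecord] = []
    best_val = np.inf
    best_state = model.state_dict()
    stale = 0
    t0 = time.time()
    n = len(train_data)
    zero_eps = np.zeros((len(val_data), config.latent_dim), np.float32)

    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(n)
        epoch_losses = []
        for bi, start in enumerate(range(0, n, config.batch_size)):
            idx = perm[start:start + config.batch_size]
            eps = rng.standard_normal((len(idx), config.latent_dim)).astype(np.float32)
            loss, _ = model.training_loss(labels[idx], cvecs[idx], eps)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite loss at epoch {epoch}, batch {bi}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))

        val_loss, _ = model.training_loss(val_labels, val_cvecs, zero_eps)
        val_loss = float(val_loss.data)
        val_dice = _reconstruction_dice(model, val_labels, val_cvecs)
        rec = TrainRecord(epoch=epoch, train_loss=float(np.mean(epoch_losses)),
                          val_loss=val_loss, val_dice=val_dice,
                          wall_time=time.time() - t0)
        records.append(rec)
        logger.info("epoch %d: train %.4f val %.4f dice %.3f",
                    epoch, rec.train_loss, rec.val_loss, rec.val_dice)

        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = model.state_dict()
            stale = 0
        else:
            stale += 1
            if stale > config.early_stop_patience:
                logger.info("early stop at epoch %d", epoch)
                break

    model.load_state_dict(best_state)
    return model, records
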
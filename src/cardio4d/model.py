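"""Conditional β-VAE over 4D cardiac label maps with latent temporal rollout.

The generative model factorises a T-frame anatomy sequence into

* a condition embedding: the clinical factors c (age group, sex, weight,
  height, systolic blood pressure) are encoded as a 12-dimensional vector
  (7 one-hot age groups + 2 one-hot sexes + 3 min-max-scaled continuous
  factors) and mapped by an MLP to a condition latent z_c;
* a spatial encoder q(z_0 | x_0, z_c): four strided 3D convolutions over
  the one-hot end-diastolic frame, flattened and concatenated with z_c at
  the bottleneck, yielding a diagonal Gaussian posterior over z_0;
* a temporal module: a single shared-weight LSTM cell rolled out
  one-to-many from the concatenated joint latent z^c_0 = [z_0, z_c],
  producing per-frame joint latents z^c_t;
* a decoder p(x_t | z^c_t): a linear map to the coarsest spatial grid
  followed by four strided transposed convolutions, giving per-voxel
  class probabilities for the 4 labels.

Training minimises the sum over frames of the per-frame voxel-mean
cross-entropy plus beta times the KL divergence between the t = 0
posterior and the standard-normal prior (the KL term appears once per
sequence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn import Tensor, constant
from .phantom import ConditionSet, AnatomySequence, CONDITION_RANGES

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "TEST_PROFILE",
    "EncoderPosterior",
    "encode_condition_vector",
    "kl_gaussian",
    "sequence_loss",
    "SequenceVAE",
]

N_AGE_GROUPS = 7
COND_VEC_DIM = N_AGE_GROUPS + 2 + 3  # one-hot age + one-hot sex + 3 scalars


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters; the defaults are the full-scale settings."""

    latent_dim: int = 32
    beta: float = 0.001
    grid_shape: tuple[int, int, int] = (128, 128, 64)
    n_frames: int = 20
    n_labels: int = 4
    encoder_channels: tuple[int, ...] = (16, 32, 64, 128)
    kernel_size: int = 4
    condition_mlp_widths: tuple[int, ...] = (64, 64)
    lstm_layers: int = 1
    lr: float = 5e-4
    batch_size: int = 8
    max_epochs: int = 500
    early_stop_patience: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        if self.lstm_layers != 1:
            raise ValueError("only a single shared LSTM cell layer is supported")
        n_down = len(self.encoder_channels)
        for d in self.grid_shape:
            if d % (2 ** n_down) != 0:
                raise ValueError(
                    f"grid shape {self.grid_shape} must be divisible by "
                    f"2^{n_down} per axis for {n_down} stride-2 stages")

    @property
    def joint_dim(self) -> int:
        return 2 * self.latent_dim

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["encoder_channels"] = list(self.encoder_channels)
        d["condition_mlp_widths"] = list(self.condition_mlp_widths)
        return d


#: Reduced profile for desk-scale experiments and the test suite.
TEST_PROFILE = ModelConfig(
    grid_shape=(32, 32, 16), n_frames=10, encoder_channels=(8, 16, 32, 64),
    max_epochs=60, early_stop_patience=10,
)


@dataclass(frozen=True)
class EncoderPosterior:
    """Diagonal Gaussian posterior q(z_0 | x_0, z_c)."""

    mean: np.ndarray
    log_var: np.ndarray

    def __post_init__(self):
        if not (np.all(np.isfinite(self.mean)) and np.all(np.isfinite(self.log_var))):
            raise ValueError("posterior parameters must be finite")


_SCALED = {"weight": CONDITION_RANGES["weight"],
           "height": CONDITION_RANGES["height"],
           "sbp": CONDITION_RANGES["sbp"]}


def encode_condition_vector(c: ConditionSet) -> np.ndarray:
    """Fixed 12-dimensional encoding of the clinical factors.

    Continuous factors are min-max scaled by the cohort ranges; values
    outside a range are clamped with a warning so inference on unseen
    demographics degrades gracefully instead of failing.
    """
    v = np.zeros(COND_VEC_DIM, dtype=np.float32)
    v[c.age_group] = 1.0
    v[N_AGE_GROUPS + (0 if c.sex == "female" else 1)] = 1.0
    for i, (name, (lo, hi)) in enumerate(_SCALED.items()):
        raw = getattr(c, name)
        x = (raw - lo) / (hi - lo)
        if not 0.0 <= x <= 1.0:
            logger.warning("condition %s=%.1f outside [%g, %g]; clamped",
                           name, raw, lo, hi)
            x = float(np.clip(x, 0.0, 1.0))
        v[N_AGE_GROUPS + 2 + i] = x
    return v


def kl_gaussian(p: EncoderPosterior) -> float:
    """Closed-form KL(q || N(0, I)) = ½ Σ (μ² + σ² − 1 − ln σ²)."""
    mu, lv = np.asarray(p.mean, float), np.asarray(p.log_var, float)
    return float(0.5 * np.sum(mu ** 2 + np.exp(lv) - 1.0 - lv))


def sequence_loss(x: AnatomySequence, probs: np.ndarray,
                  p: EncoderPosterior, beta: float) -> float:
    """Sequence loss from decoded probabilities (evaluation form).

    Reconstruction is the per-frame voxel-mean cross-entropy summed over
    frames; the KL term of the t = 0 posterior is added once, weighted by
    beta.
    """
    probs = np.asarray(probs)
    if probs.shape[0] != x.n_frames:
        raise ValueError(f"frame count mismatch: {probs.shape[0]} probability "
                         f"volumes vs {x.n_frames} frames")
    recon = 0.0
    for t in range(x.n_frames):
        p_true = np.take_along_axis(
            probs[t], x.labels[t][None].astype(np.int64), axis=0)[0]
        recon += float(-np.log(np.maximum(p_true, 1e-30)).mean())
    return recon + beta * kl_gaussian(p)


class SequenceVAE(nn.Module):
    """The full conditional spatio-temporal generative model."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        L, J = config.latent_dim, config.joint_dim
        ch = config.encoder_channels
        k = config.kernel_size

        self.condition_mlp = nn.MLP(rng, [COND_VEC_DIM,
                                          *config.condition_mlp_widths, L])
        # start the condition embedding at zero: every coordinate of z_c is
        # then learned from data, so untrained embedding directions cannot
        # masquerade as condition effects during sweeps
        self.condition_mlp.layers[-1].weight.data[:] = 0.0
        self.enc_convs = [nn.Conv3d(rng, a, b, kernel=k, stride=2, padding=1)
                          for a, b in zip((config.n_labels,) + ch[:-1], ch)]
        self._spatial_stack = [tuple(config.grid_shape)]
        for conv in self.enc_convs:
            self._spatial_stack.append(conv.out_shape(self._spatial_stack[-1]))
        self._flat_dim = ch[-1] * int(np.prod(self._spatial_stack[-1]))
        self.fc_mean = nn.Linear(rng, self._flat_dim + L, L)
        self.fc_logvar = nn.Linear(rng, self._flat_dim + L, L)

        self.temporal_cell = nn.LSTMCell(rng, J, J)

        self.dec_fc = nn.Linear(rng, J, self._flat_dim)
        dch = tuple(reversed(ch))
        self.dec_convs = [nn.ConvTranspose3d(rng, a, b, kernel=k, stride=2, padding=1)
                          for a, b in zip(dch, dch[1:] + (config.n_labels,))]

    # -- parameter bookkeeping ----------------------------------------------
    def parameter_groups(self) -> dict[str, list[Tensor]]:
        return {
            "condition_mlp": self.condition_mlp.parameters(),
            "encoder": (sum([c.parameters() for c in self.enc_convs], [])
                        + self.fc_mean.parameters() + self.fc_logvar.parameters()),
            "temporal": self.temporal_cell.parameters(),
            "decoder": (self.dec_fc.parameters()
                        + sum([c.parameters() for c in self.dec_convs], [])),
        }

    def parameters(self) -> list[Tensor]:
        return [p for group in self.parameter_groups().values() for p in group]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"{g}.{i}": p.data.copy()
                for g, params in self.parameter_groups().items()
                for i, p in enumerate(params)}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for g, params in self.parameter_groups().items():
            for i, p in enumerate(params):
                src = state[f"{g}.{i}"]
                if src.shape != p.data.shape:
                    raise ValueError(f"shape mismatch for {g}.{i}")
                p.data = src.astype(np.float32).copy()

    # -- graph builders (Tensor in, Tensor out) ------------------------------
    def _embed_conditions_t(self, cond_vecs: np.ndarray) -> Tensor:
        return self.condition_mlp(constant(cond_vecs))

    def _encode_t(self, x0_onehot: np.ndarray, z_c: Tensor) -> tuple[Tensor, Tensor]:
        h = constant(x0_onehot)
        for conv in self.enc_convs:
            h = nn.relu(conv(h))
        h = h.reshape(h.shape[0], self._flat_dim)  # channels-last flatten
        h = nn.concat([h, z_c], axis=1)
        return self.fc_mean(h), self.fc_logvar(h)

    def _rollout_t(self, z0c: Tensor, T: int) -> list[Tensor]:
        if T < 1:
            raise ValueError("T must be >= 1")
        B, J = z0c.shape
        h = constant(np.zeros((B, J), np.float32))
        cell_state = constant(np.zeros((B, J), np.float32))
        zs = [z0c]
        z = z0c
        for _ in range(1, T):
            z, cell_state = self.temporal_cell(z, h, cell_state)
            h = z
            zs.append(z)
        return zs

    def _decode_t(self, z: Tensor) -> Tensor:
        """Joint latents (N, J) -> logits (N, X, Y, Z, n_labels)."""
        h = nn.relu(self.dec_fc(z))
        small = self._spatial_stack[-1]
        ch = self.config.encoder_channels[-1]
        h = h.reshape(h.shape[0], *small, ch)
        spatials = list(reversed(self._spatial_stack[:-1]))
        for i, (deconv, sp) in enumerate(zip(self.dec_convs, spatials)):
            h = deconv(h, sp)
            if i < len(self.dec_convs) - 1:
                h = nn.relu(h)
        return h

    def training_loss(self, labels: np.ndarray, cond_vecs: np.ndarray,
                      eps: np.ndarray) -> tuple[Tensor, dict[str, float]]:
        """Batch loss graph.

        ``labels`` is (B, T, X, Y, Z) int; ``cond_vecs`` (B, 12);
        ``eps`` (B, latent_dim) standard-normal reparameterisation noise.
        Returns the scalar loss Tensor (mean over the batch of the
        per-sequence loss) and float diagnostics.
        """
        B, T = labels.shape[:2]
        x0_onehot = _one_hot(labels[:, 0], self.config.n_labels)
        z_c = self._embed_conditions_t(cond_vecs)
        mean, log_var = self._encode_t(x0_onehot, z_c)
        z0 = mean + nn.exp(log_var * 0.5) * constant(eps)
        z0c = nn.concat([z0, z_c], axis=1)
        zs = self._rollout_t(z0c, T)
        # stack as (T, B, J) then flatten so frame t of subject b sits at
        # row t*B + b, matching the label ordering below
        zflat = nn.stack(zs, axis=0).reshape(T * B, self.config.joint_dim)
        logits = self._decode_t(zflat)
        V = int(np.prod(self.config.grid_shape))
        C = self.config.n_labels
        logits2 = logits.reshape(T * B * V, C)
        targets = labels.transpose(1, 0, 2, 3, 4).reshape(-1).astype(np.int64)
        ce = nn.cross_entropy_logits(logits2, targets).mean() * float(T)
        kl = ((mean * mean + nn.exp(log_var) - 1.0 - log_var).sum(axis=1)
              .mean() * 0.5)
        loss = ce + kl * self.config.beta
        diag = {"recon": float(ce.data), "kl": float(kl.data)}
        return loss, diag

    def init_output_bias(self, class_frequencies: np.ndarray) -> None:
        """Start the decoder at the label marginals.

        Setting the final-layer bias to the log class frequencies makes
        the untrained decoder emit the dataset's label marginal instead
        of a uniform map, which skips the early optimisation phase that
        merely rediscovers the background/foreground balance.
        """
        freq = np.asarray(class_frequencies, dtype=np.float64)
        if freq.shape != (self.config.n_labels,):
            raise ValueError("need one frequency per label")
        freq = np.maximum(freq / freq.sum(), 1e-8)
        self.dec_convs[-1].bias.data = np.log(freq).astype(np.float32)

    # -- public inference ops (numpy in, numpy out) --------------------------
    def embed_conditions(self, c: ConditionSet) -> np.ndarray:
        """Condition latent z_c (latent_dim,)."""
        return self._embed_conditions_t(
            encode_condition_vector(c)[None]).data[0].copy()

    def encode(self, x0: np.ndarray, z_c: np.ndarray) -> EncoderPosterior:
        """Posterior over z_0 given the ED label map and z_c."""
        if tuple(x0.shape) != tuple(self.config.grid_shape):
            raise ValueError(f"x0 shape {x0.shape} != configured grid "
                             f"{self.config.grid_shape}")
        zc_t = constant(np.asarray(z_c, np.float32)[None])
        mean, log_var = self._encode_t(_one_hot(x0[None], self.config.n_labels), zc_t)
        return EncoderPosterior(mean=mean.data[0].copy(),
                                log_var=log_var.data[0].copy())

    @staticmethod
    def reparameterize(p: EncoderPosterior, eps: np.ndarray) -> np.ndarray:
        """z_0 = μ + exp(log σ² / 2) ⊙ ε."""
        eps = np.asarray(eps)
        if eps.shape != p.mean.shape:
            raise ValueError("eps length must equal latent_dim")
        return p.mean + np.exp(0.5 * p.log_var) * eps

    def temporal_rollout(self, z0c: np.ndarray, T: int) -> np.ndarray:
        """Per-frame joint latents (T, joint_dim); element 0 is z0c itself."""
        zs = self._rollout_t(constant(np.asarray(z0c, np.float32)[None]), T)
        return np.stack([z.data[0] for z in zs])

    def decode_frame(self, ztc: np.ndarray) -> np.ndarray:
        """Per-voxel class probabilities (n_labels, X, Y, Z) for one latent."""
        logits = self._decode_t(constant(np.asarray(ztc, np.float32)[None]))
        probs = nn.softmax(logits.data, axis=-1)[0]
        return np.moveaxis(probs, -1, 0)

    def decode_labels(self, zs: np.ndarray, chunk: int = 32) -> np.ndarray:
        """Batch argmax decode: (N, joint_dim) -> (N, X, Y, Z) labels."""
        zs = np.asarray(zs, np.float32)
        out = []
        for i in range(0, len(zs), chunk):
            logits = self._decode_t(constant(zs[i:i + chunk]))
            out.append(np.argmax(logits.data, axis=-1).astype(np.uint8))
        return np.concatenate(out)


def _one_hot(labels: np.ndarray, n_labels: int) -> np.ndarray:
    """(..., X, Y, Z) int labels -> (..., X, Y, Z, C) float32 one-hot."""
    eye = np.eye(n_labels, dtype=np.float32)
    return eye[labels.astype(np.int64)]
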
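"""Sequence completion, sequence generation and condition manipulation.

Completion infers the full cardiac cycle from the end-diastolic frame and
the clinical conditions; generation synthesises whole cycles from
conditions alone by sampling the anatomy latent from its standard-normal
prior; the condition sweep regenerates the same latent anatomy under a
varying clinical factor, isolating that factor's effect on the anatomy.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .model import SequenceVAE, encode_condition_vector
from .phantom import AnatomySequence, ConditionSet, spacing_for_grid

__all__ = [
    "complete_sequence",
    "generate_sequences",
    "simulate_condition_sweep",
]

SWEEPABLE = ("age_group", "sex", "weight", "height", "sbp")


def _decode_sequence(model: SequenceVAE, z0c: np.ndarray) -> AnatomySequence:
    zs = model.temporal_rollout(z0c, model.config.n_frames)
    labels = model.decode_labels(zs)
    return AnatomySequence(labels=labels,
                           spacing=spacing_for_grid(model.config.grid_shape))


def complete_sequence(model: SequenceVAE, x0: np.ndarray, c: ConditionSet,
                      sample: bool = False,
                      seed: int | None = None) -> AnatomySequence:
    """Generate the full T-frame sequence from the ED frame and conditions.

    By default z_0 is the posterior mean, making completion deterministic;
    ``sample=True`` draws z_0 through the reparameterisation instead.
    Frame 0 of the output is the model's reconstruction of ``x0``, not a
    copy of the input.
    """
    if tuple(x0.shape) != tuple(model.config.grid_shape):
        raise ValueError(f"x0 shape {x0.shape} does not match configured "
                         f"grid {model.config.grid_shape}")
    z_c = model.embed_conditions(c)
    post = model.encode(x0, z_c)
    if sample:
        eps = np.random.default_rng(seed).standard_normal(model.config.latent_dim)
        z0 = model.reparameterize(post, eps)
    else:
        z0 = post.mean
    return _decode_sequence(model, np.concatenate([z0, z_c]))


def generate_sequences(model: SequenceVAE, c: ConditionSet, n_samples: int,
                       seed: int) -> list[AnatomySequence]:
    """Draw ``n_samples`` anatomies for one condition set, z_0 ~ N(0, I)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    z_c = model.embed_conditions(c)
    out = []
    for _ in range(n_samples):
        z0 = rng.standard_normal(model.config.latent_dim).astype(np.float32)
        out.append(_decode_sequence(model, np.concatenate([z0, z_c])))
    return out


def _with_factor(c: ConditionSet, factor: str, value) -> ConditionSet:
    if factor == "age_group":
        group = int(value)
        if not 0 <= group <= 6:
            raise ValueError("age_group must be in 0..6")
        # bin centre keeps age_years consistent with the group
        return replace(c, age_years=float(15 + 10 * group), age_group=group)
    if factor == "sex":
        return replace(c, sex=value)
    return replace(c, **{factor: float(value)})


def simulate_condition_sweep(model: SequenceVAE, c_base: ConditionSet,
                             factor: str, values: list,
                             z0: np.ndarray) -> list[AnatomySequence]:
    """One generated sequence per factor value, sharing the fixed z_0.

    All other conditions stay at ``c_base``; only the swept factor varies,
    so differences between the outputs reflect that factor alone.
    """
    if factor not in SWEEPABLE:
        raise ValueError(f"unknown factor {factor!r}; one of {SWEEPABLE}")
    z0 = np.asarray(z0, np.float32)
    if z0.shape != (model.config.latent_dim,):
        raise ValueError("z0 must have length latent_dim")
    out = []
    for v in values:
        z_c = model.embed_conditions(_with_factor(c_base, factor, v))
        out.append(_decode_sequence(model, np.concatenate([z0, z_c])))
    return out
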
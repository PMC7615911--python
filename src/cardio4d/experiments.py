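"""Desk-scale benchmark: the full pipeline at reduced problem size.

Trains the conditional sequence VAE on a synthetic phantom cohort
(60 training / 6 validation / 10 held-out subjects, 32 x 32 x 16 voxel
grid, 10 frames per cycle) and evaluates the three tasks the model
exists for:

* sequence completion accuracy against held-out ground truth (Dice /
  HD / ASSD over frames 1..T-1), contrasted with an untrained model;
* sequence generation: mean/best similarity over 20 latent samples per
  condition set, phenotype differences, distribution distances, and the
  fraction of generated cycles showing systolic contraction;
* condition manipulation: 200 seeded age sweeps with fixed anatomy
  latents, recovering the built-in cohort trends (myocardial mass rises,
  LV end-diastolic volume falls from the youngest to the oldest group).

The problem sizes here are deliberate package defaults for CPU-scale
experimentation; all randomness descends from one integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .inference import _with_factor, complete_sequence
from .metrics import (STRUCTURES, completion_report, dice, extract_phenotypes,
                      generation_report)
from .model import TEST_PROFILE, SequenceVAE
from .phantom import (AnatomySequence, CohortSpec, generate_sequence,
                      sample_conditions)
from .training import TrainRecord, split_dataset, train_model

logger = logging.getLogger(__name__)

__all__ = ["ToyBenchmark", "run_toy_benchmark", "build_toy_cohort"]

N_TRAIN, N_VAL, N_TEST = 60, 6, 10
N_GEN_SUBJECTS = 5          # test subjects evaluated in the generation task
N_GEN_SAMPLES = 20          # latent samples per condition set
N_SWEEPS = 200              # seeded condition sweeps for the ageing trend
CONTRACTION_MARGIN = 0.9    # "contracting" = min LV volume < 0.9 x ED volume


@dataclass
class ToyBenchmark:
    model: SequenceVAE
    records: list[TrainRecord]
    completion: pd.DataFrame
    completion_dice: float
    untrained_completion_dice: float
    generation: dict
    contracting_fraction: float
    generation_lvedv_spread: float
    trend: dict[str, float]
    test_data: list = field(repr=False, default_factory=list)

    def summary(self) -> dict[str, float]:
        """Flat numeric summary of every benchmark quantity."""
        gen_mean = self.generation["mean"]
        gen_best = self.generation["best"]
        pheno = self.generation["phenotype_differences"]
        out = {
            "completion_dice_mean": self.completion_dice,
            "completion_dice_untrained": self.untrained_completion_dice,
            "completion_hd_mm": float(self.completion.loc["Average", "hd_mean"]),
            "completion_assd_mm": float(self.completion.loc["Average", "assd_mean"]),
            "generation_dice_mean": float(gen_mean.loc["Average", "dice"]),
            "generation_dice_best": float(gen_best.loc["Average", "dice"]),
            "generation_hd_mean_mm": float(gen_mean.loc["Average", "hd"]),
            "generation_hd_best_mm": float(gen_best.loc["Average", "hd"]),
            "generation_assd_mean_mm": float(gen_mean.loc["Average", "assd"]),
            "generation_assd_best_mm": float(gen_best.loc["Average", "assd"]),
            "contracting_fraction": self.contracting_fraction,
            "generation_lvedv_spread_ml": self.generation_lvedv_spread,
            **{f"dphenotype_mean_{k.lower()}": float(pheno.loc[k, "mean_abs_diff"])
               for k in pheno.index},
            **{f"dphenotype_min_{k.lower()}": float(pheno.loc[k, "min_abs_diff"])
               for k in pheno.index},
            **self.trend,
        }
        for name, comp in self.generation.get("distributions", {}).items():
            out[f"kl_{name.lower()}"] = comp.kl
            out[f"wd_{name.lower()}"] = comp.wd
        return out


def build_toy_cohort(seed: int, n_subjects: int = N_TRAIN + N_VAL + N_TEST,
                     config=TEST_PROFILE):
    """Phantom cohort matching the training profile's grid and frames."""
    spec = CohortSpec(n_subjects=n_subjects, grid_shape=config.grid_shape,
                      n_frames=config.n_frames, seed=seed)
    conds = sample_conditions(n_subjects, seed + 11)
    data = [(generate_sequence(c, spec, seed * 1009 + i), c)
            for i, c in enumerate(conds)]
    return data


def _decode_many(model: SequenceVAE, z0cs: np.ndarray) -> list[AnatomySequence]:
    """Roll out and decode many joint latents in one batch (fast path;
    numerically equivalent to per-sample decoding up to float32 rounding)."""
    from .nn import constant, stack
    from .phantom import spacing_for_grid
    N = len(z0cs)
    T = model.config.n_frames
    zs = model._rollout_t(constant(np.asarray(z0cs, np.float32)), T)
    flat = stack(zs, axis=0).reshape(T * N, model.config.joint_dim)
    labels = model.decode_labels(flat.data, chunk=64).reshape(
        T, N, *model.config.grid_shape)
    spacing = spacing_for_grid(model.config.grid_shape)
    return [AnatomySequence(labels=np.ascontiguousarray(labels[:, i]),
                            spacing=spacing) for i in range(N)]


def _mean_completion_dice(model: SequenceVAE, data) -> float:
    """Mean Dice over LV/Myo/RV and frames 1..T-1 on paired subjects."""
    scores = []
    for seq, c in data:
        comp = complete_sequence(model, seq.labels[0], c)
        scores.append(np.mean([dice(seq.labels[t], comp.labels[t], lab)
                               for t in range(1, seq.n_frames)
                               for lab in STRUCTURES]))
    return float(np.mean(scores))


def run_toy_benchmark(seed: int = 0, config=None) -> ToyBenchmark:
    """Run the whole desk-scale study; see the module docstring."""
    config = replace(config or TEST_PROFILE, seed=seed)
    data = build_toy_cohort(seed, config=config)
    n = len(data)
    train, val, test = split_dataset(
        data, (N_TRAIN / n, N_VAL / n, N_TEST / n), seed=seed + 23)

    logger.info("training on %d subjects (%d validation)", len(train), len(val))
    model, records = train_model(train, val, config)
    untrained = SequenceVAE(replace(config, seed=seed + 97))

    truths = [s for s, _ in test]
    completions = [complete_sequence(model, s.labels[0], c) for s, c in test]
    comp_table = completion_report(truths, completions)
    comp_dice = float(np.mean(
        [comp_table.loc[name, "dice_mean"] for name in STRUCTURES.values()]))
    untrained_dice = _mean_completion_dice(untrained, test)

    # generation task on a subset of held-out conditions (batched decode)
    gen_subset = test[:N_GEN_SUBJECTS]
    sample_lists = []
    for i, (_, c) in enumerate(gen_subset):
        rng_i = np.random.default_rng(seed * 131 + i)
        z_c = model.embed_conditions(c)
        z0cs = np.stack([np.concatenate([
            rng_i.standard_normal(config.latent_dim).astype(np.float32), z_c])
            for _ in range(N_GEN_SAMPLES)])
        sample_lists.append(_decode_many(model, z0cs))
    gen = generation_report([s for s, _ in gen_subset],
                            [c for _, c in gen_subset],
                            sample_lists,
                            age_years=[c.age_years for _, c in gen_subset])

    contracting, lvedvs = [], []
    for samples in sample_lists:
        for s in samples:
            vols = (s.labels.reshape(s.n_frames, -1) == 1).sum(axis=1)
            ed = vols[0]
            contracting.append(ed > 0 and vols.min() < CONTRACTION_MARGIN * ed)
            lvedvs.append(extract_phenotypes(s).lvedv)
    contracting_fraction = float(np.mean(contracting))
    lvedv_spread = float(np.std(lvedvs))

    # ageing sweeps: youngest vs oldest age group, fixed anatomy latents
    rng = np.random.default_rng(seed + 31)
    base_conditions = sample_conditions(N_SWEEPS, seed + 41)
    groups = (0, 6)
    lvm = {g: [] for g in groups}
    lvedv = {g: [] for g in groups}
    z0s = rng.standard_normal((N_SWEEPS, config.latent_dim)).astype(np.float32)
    for group in groups:
        z0cs = np.stack([np.concatenate([
            z0, model.embed_conditions(_with_factor(c_base, "age_group", group))])
            for z0, c_base in zip(z0s, base_conditions)])
        for seq in _decode_many(model, z0cs):
            ph = extract_phenotypes(seq)
            lvm[group].append(ph.lvm)
            lvedv[group].append(ph.lvedv)
    trend = {
        "sweep_lvm_youngest_g": float(np.mean(lvm[0])),
        "sweep_lvm_oldest_g": float(np.mean(lvm[6])),
        "sweep_lvedv_youngest_ml": float(np.mean(lvedv[0])),
        "sweep_lvedv_oldest_ml": float(np.mean(lvedv[6])),
    }
    trend["sweep_lvm_delta_g"] = trend["sweep_lvm_oldest_g"] - trend["sweep_lvm_youngest_g"]
    trend["sweep_lvedv_delta_ml"] = (trend["sweep_lvedv_oldest_ml"]
                                     - trend["sweep_lvedv_youngest_ml"])

    return ToyBenchmark(
        model=model, records=records, completion=comp_table,
        completion_dice=comp_dice, untrained_completion_dice=untrained_dice,
        generation=gen, contracting_fraction=contracting_fraction,
        generation_lvedv_spread=lvedv_spread, trend=trend, test_data=test)
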
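"""On-disk formats: 4D NIfTI label maps, conditions tables, YAML configs
and model checkpoints.

A cohort on disk is a directory of one 4D NIfTI per subject (uint8
labels, voxel spacing in the header, dimensions ordered X, Y, Z, T) plus
a ``conditions.csv`` with columns subject_id, age_years, age_group, sex,
weight_kg, height_cm, sbp_mmhg and optionally split.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .model import ModelConfig, SequenceVAE, TEST_PROFILE
from .phantom import AnatomySequence, ConditionSet, age_group_of

__all__ = [
    "read_sequence", "write_sequence",
    "read_conditions", "write_conditions",
    "load_config", "save_config",
    "save_checkpoint", "load_checkpoint",
    "write_cohort",
]

_CSV_COLUMNS = ["subject_id", "age_years", "age_group", "sex",
                "weight_kg", "height_cm", "sbp_mmhg"]


def write_sequence(seq: AnatomySequence, path) -> None:
    """Write a sequence as one 4D NIfTI (X, Y, Z, T), uint8 labels."""
    data = np.ascontiguousarray(np.moveaxis(seq.labels, 0, -1).astype(np.uint8))
    affine = np.diag([*seq.spacing, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((*seq.spacing, seq.frame_duration or 1.0))
    nib.save(img, str(path))


def read_sequence(path) -> AnatomySequence:
    """Read a 3D or 4D NIfTI label map; 3D files load as a single frame."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise ValueError(f"expected a 3D or 4D volume, got {data.ndim}D")
    labels = np.moveaxis(data, -1, 0).astype(np.uint8)
    bad = sorted(set(np.unique(labels)) - {0, 1, 2, 3})
    if bad:
        raise ValueError(f"unknown label value(s) {bad} in {path.name}; "
                         "expected labels 0-3")
    zooms = img.header.get_zooms()[:3]
    return AnatomySequence(labels=labels, spacing=tuple(float(z) for z in zooms))


def write_conditions(conditions: list[ConditionSet], path,
                     subject_ids: list[str] | None = None,
                     splits: list[str] | None = None) -> None:
    if subject_ids is None:
        subject_ids = [f"subj{i:04d}" for i in range(len(conditions))]
    rows = [{"subject_id": sid, "age_years": c.age_years,
             "age_group": c.age_group, "sex": c.sex, "weight_kg": c.weight,
             "height_cm": c.height, "sbp_mmhg": c.sbp}
            for sid, c in zip(subject_ids, conditions)]
    df = pd.DataFrame(rows)
    if splits is not None:
        df["split"] = splits
    df.to_csv(path, index=False)


def read_conditions(path) -> tuple[list[ConditionSet], pd.DataFrame]:
    """Load and validate a conditions table.

    Returns the typed condition sets and the raw dataframe (which may
    carry extra columns such as subject_id and split). A stored age_group
    inconsistent with age_years is an error.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns and c != "age_group"]
    if missing:
        raise ValueError(f"conditions file missing column(s): {missing}")
    out = []
    for _, row in df.iterrows():
        if row["sex"] not in ("female", "male"):
            raise ValueError(f"invalid sex {row['sex']!r} for "
                             f"{row['subject_id']!r}")
        if "age_group" in df.columns:
            expected = age_group_of(float(row["age_years"]))
            if int(row["age_group"]) != expected:
                raise ValueError(
                    f"age_group {row['age_group']} inconsistent with "
                    f"age_years {row['age_years']} for {row['subject_id']!r}")
        out.append(ConditionSet(age_years=float(row["age_years"]),
                                sex=row["sex"], weight=float(row["weight_kg"]),
                                height=float(row["height_cm"]),
                                sbp=float(row["sbp_mmhg"])))
    return out, df


def write_cohort(sequences: list[AnatomySequence],
                 conditions: list[ConditionSet], out_dir,
                 splits: list[str] | None = None) -> list[str]:
    """Write a cohort directory; returns the subject ids."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids = [f"subj{i:04d}" for i in range(len(sequences))]
    for sid, seq in zip(ids, sequences):
        write_sequence(seq, out_dir / f"{sid}.nii.gz")
    write_conditions(conditions, out_dir / "conditions.csv", ids, splits)
    return ids


_TUPLE_KEYS = {"grid_shape", "encoder_channels", "condition_mlp_widths"}


def load_config(path=None, profile: str | None = None) -> ModelConfig:
    """Build a ModelConfig from YAML; unknown keys are rejected.

    An empty (or absent) file yields the full-scale defaults; the named
    ``test`` profile selects the reduced desk-scale settings before
    applying any overrides from the file.
    """
    base = TEST_PROFILE if profile == "test" else ModelConfig()
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a YAML mapping")
    if "profile" in raw:
        if raw.pop("profile") == "test":
            base = TEST_PROFILE
    valid = set(ModelConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs = base.to_dict()
    kwargs.update(raw)
    for key in _TUPLE_KEYS:
        kwargs[key] = tuple(kwargs[key])
    return ModelConfig(**kwargs)


def save_config(config: ModelConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def save_checkpoint(model: SequenceVAE, path) -> None:
    """Checkpoint = npz of parameters + JSON-embedded config."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8)
    np.savez_compressed(str(path), **state)


def load_checkpoint(path) -> SequenceVAE:
    with np.load(str(path)) as data:
        cfg_raw = json.loads(bytes(data["__config__"].tobytes()).decode())
        for key in _TUPLE_KEYS:
            cfg_raw[key] = tuple(cfg_raw[key])
        config = ModelConfig(**cfg_raw)
        model = SequenceVAE(config)
        model.load_state_dict({k: data[k] for k in data.files
                               if k != "__config__"})
    return model
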
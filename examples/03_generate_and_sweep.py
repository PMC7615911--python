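"""Generate synthetic anatomies from clinical conditions alone, then
simulate ageing by sweeping the age group with a fixed anatomy latent.

Generation draws the anatomy latent from its standard-normal prior, so
repeated samples for one condition set are plausible yet distinct
hearts. In the sweep, everything except age is pinned — the anatomy
latent included — so phenotype changes isolate the age effect the
model has learned.
"""

import dataclasses

import numpy as np

from cardio4d import (TEST_PROFILE, extract_phenotypes, generate_sequences,
                      simulate_condition_sweep, split_dataset, train_model)
from cardio4d.experiments import build_toy_cohort

config = dataclasses.replace(TEST_PROFILE, max_epochs=40, seed=0)
data = build_toy_cohort(seed=0, n_subjects=32, config=config)
train, val, test = split_dataset(data, (24 / 32, 4 / 32, 4 / 32), seed=1)
model, _ = train_model(train, val, config)

seq, c = test[0]
print(f"conditions: {c.age_years:.0f} y {c.sex}, {c.weight:.0f} kg, "
      f"{c.height:.0f} cm, SBP {c.sbp:.0f} mmHg")
real = extract_phenotypes(seq)
print(f"real subject:  LVEDV {real.lvedv:6.1f} mL   LVM {real.lvm:6.1f} g")
for i, sample in enumerate(generate_sequences(model, c, n_samples=5, seed=7)):
    ph = extract_phenotypes(sample)
    print(f"sample {i}:      LVEDV {ph.lvedv:6.1f} mL   LVM {ph.lvm:6.1f} g")

print("\nAge sweep (same anatomy latent, same sex/weight/height/SBP):")
rng = np.random.default_rng(7)
z0 = rng.standard_normal(config.latent_dim).astype(np.float32)
for group, swept in zip(range(0, 7, 2), simulate_condition_sweep(
        model, c, "age_group", [0, 2, 4, 6], z0)):
    ph = extract_phenotypes(swept)
    print(f"  age group {group} ({10 + 10 * group}-{20 + 10 * group} y): "
          f"LVEDV {ph.lvedv:6.1f} mL   LVM {ph.lvm:6.1f} g")

print("\nAcross samples the phenotypes vary (generation diversity). The "
      "sweep isolates the learned\nage effect; at this small training "
      "scale it is weak — the cohort's built-in trend is myocardial\n"
      "mass up and end-diastolic volume down, and docs/methods.md "
      "discusses how faithfully sweeps\nrecover it.")
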
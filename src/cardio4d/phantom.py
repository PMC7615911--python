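"""Synthetic beating-heart phantom cohorts with analytic ground truth.

The phantom stands in for a real cine-CMR segmentation cohort: each
subject is a nested-ellipsoid heart — an LV blood-pool ellipsoid (label 1)
wrapped in a myocardial shell of constant thickness (label 2), with the RV
blood pool (label 3) modelled as a half-shell between the myocardial outer
surface and a concentric enlarged copy of it, clipped to one side of the
septal plane. This concentric construction is deliberate: every chamber
volume and the myocardial mass have exact closed forms, so the phantom
doubles as an oracle for the voxel-counting phenotype extraction.

Geometry depends on the clinical conditions the generative model is
conditioned on (age group, sex, weight, height, systolic blood pressure):
wall thickness increases and cavity size decreases with age group, male
hearts are larger, and overall size scales with body surface area. Cyclic
contraction over the cardiac cycle is applied as a smooth volumetric scale
with its minimum at the end-systolic phase.

All randomness flows through explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ConditionSet",
    "PhantomGeometry",
    "AnatomySequence",
    "CohortSpec",
    "PhenotypeSet",
    "MYO_DENSITY_G_PER_ML",
    "FEMALE_FRACTION",
    "CONDITION_RANGES",
    "FOV_MM",
    "sample_conditions",
    "geometry_from_conditions",
    "contraction_scale",
    "rasterize_frame",
    "generate_sequence",
    "analytic_phenotypes",
    "spacing_for_grid",
]

#: Myocardial tissue density used to convert myocardial volume to mass.
MYO_DENSITY_G_PER_ML = 1.05

#: Female prevalence used when sampling sex (775 of 1383 in the cohort the
#: demographic ranges are modelled on).
FEMALE_FRACTION = 775.0 / 1383.0

#: Sampling ranges of the continuous clinical factors (min, max).
CONDITION_RANGES = {
    "age_years": (18.0, 73.0),
    "weight": (33.0, 131.0),
    "height": (142.0, 195.0),
    "sbp": (79.0, 183.0),
}

#: Physical field of view in mm; voxel spacing is FOV / grid shape, so the
#: default 128 x 128 x 64 grid has 1.25 x 1.25 x 2 mm voxels.
FOV_MM = (160.0, 160.0, 128.0)


def spacing_for_grid(grid_shape: tuple[int, int, int]) -> tuple[float, float, float]:
    """Voxel spacing (mm) that keeps the physical field of view fixed."""
    return tuple(f / n for f, n in zip(FOV_MM, grid_shape))


def age_group_of(age_years: float) -> int:
    """Decade bin index 0-6 over [10, 80) years, clipped at the ends."""
    return int(np.clip(np.floor((age_years - 10.0) / 10.0), 0, 6))


@dataclass(frozen=True)
class ConditionSet:
    """One subject's clinical conditioning factors."""

    age_years: float
    sex: str                # "female" | "male"
    weight: float           # kg
    height: float           # cm
    sbp: float              # mmHg
    age_group: int = field(default=-1)

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        expected = age_group_of(self.age_years)
        if self.age_group == -1:
            object.__setattr__(self, "age_group", expected)
        elif self.age_group != expected:
            raise ValueError(
                f"age_group {self.age_group} inconsistent with age_years "
                f"{self.age_years} (expected {expected})")

    def bsa(self) -> float:
        """Du Bois body-surface area in m^2."""
        return 0.007184 * self.weight ** 0.425 * self.height ** 0.725


@dataclass(frozen=True)
class PhantomGeometry:
    """Analytic ellipsoid/shell parameters of one synthetic heart (mm)."""

    lv_semi_axes: tuple[float, float, float]
    wall_thickness: float
    rv_scale: float
    center: tuple[float, float, float]
    ejection_amplitude: float
    es_phase: float

    def __post_init__(self):
        if any(a <= 0 for a in self.lv_semi_axes):
            raise ValueError("LV semi-axes must be positive")
        if self.wall_thickness <= 0:
            raise ValueError("wall thickness must be positive")
        if not 0.0 <= self.ejection_amplitude < 1.0:
            raise ValueError("ejection_amplitude must lie in [0, 1)")
        if not 0.0 < self.es_phase < 1.0:
            raise ValueError("es_phase must lie in (0, 1)")

    @property
    def outer_semi_axes(self) -> tuple[float, float, float]:
        return tuple(a + self.wall_thickness for a in self.lv_semi_axes)


@dataclass
class AnatomySequence:
    """A T-frame 4D label volume: labels[t, x, y, z] in {0, 1, 2, 3}."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    frame_duration: float | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 4:
            raise ValueError("labels must be a 4D (T, X, Y, Z) array")
        bad = set(np.unique(self.labels)) - {0, 1, 2, 3}
        if bad:
            raise ValueError(f"unknown label values: {sorted(bad)}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class PhenotypeSet:
    """The five imaging phenotypes: mass in g, volumes in mL."""

    lvm: float
    lvedv: float
    lvesv: float
    rvedv: float
    rvesv: float

    def as_dict(self) -> dict[str, float]:
        return {"LVM": self.lvm, "LVEDV": self.lvedv, "LVESV": self.lvesv,
                "RVEDV": self.rvedv, "RVESV": self.rvesv}


#: Condition -> geometry effect sizes. Fractional changes per unit of the
#: named factor; signs are fixed so that myocardial mass rises and LV
#: end-diastolic volume falls across age groups, and male hearts are larger.
DEFAULT_EFFECT_SIZES = {
    "age_wall_per_group": 0.05,    # wall thickness +5% per age group
    "age_size_per_group": -0.02,   # each LV semi-axis -2% per age group
    "sex_male_size": 0.08,         # male semi-axes +8%
    "bsa_exponent": 1.0 / 3.0,     # semi-axes scale with (BSA/1.75)^(1/3)
}

_REFERENCE_AGE_GROUP = 3
_REFERENCE_BSA = 1.75
_BASE_LV_SEMI_AXES = (25.0, 25.0, 30.0)
_FOV_FILL_LIMIT = 0.97
_BASE_WALL_MM = 9.0
_BASE_RV_SCALE = 1.25
_BASE_EJECTION_AMPLITUDE = 0.5
_DEFAULT_ES_PHASE = 0.45


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort."""

    n_subjects: int = 60
    grid_shape: tuple[int, int, int] = (32, 32, 16)
    n_frames: int = 10
    seed: int = 0
    effect_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    noise_sd: float = 0.04

    def __post_init__(self):
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.effect_sizes["age_wall_per_group"] < 0:
            raise ValueError("age->wall effect must be >= 0 (mass rises with age)")
        if self.effect_sizes["age_size_per_group"] > 0:
            raise ValueError("age->size effect must be <= 0 (LVEDV falls with age)")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return spacing_for_grid(self.grid_shape)


def sample_conditions(n: int, seed: int) -> list[ConditionSet]:
    """Draw ``n`` subjects' conditions uniformly within the cohort ranges."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        age = rng.uniform(*CONDITION_RANGES["age_years"])
        sex = "female" if rng.random() < FEMALE_FRACTION else "male"
        weight = rng.uniform(*CONDITION_RANGES["weight"])
        height = rng.uniform(*CONDITION_RANGES["height"])
        sbp = rng.uniform(*CONDITION_RANGES["sbp"])
        out.append(ConditionSet(age_years=float(age), sex=sex, weight=float(weight),
                                height=float(height), sbp=float(sbp)))
    return out


def geometry_from_conditions(c: ConditionSet, spec: CohortSpec,
                             subject_seed: int) -> PhantomGeometry:
    """Deterministic condition-dependent geometry plus seeded jitter."""
    eff = spec.effect_sizes
    rng = np.random.default_rng(subject_seed)

    size = (c.bsa() / _REFERENCE_BSA) ** eff["bsa_exponent"]
    size *= 1.0 + eff["age_size_per_group"] * (c.age_group - _REFERENCE_AGE_GROUP)
    if c.sex == "male":
        size *= 1.0 + eff["sex_male_size"]

    wall = _BASE_WALL_MM * (1.0 + eff["age_wall_per_group"]
                            * (c.age_group - _REFERENCE_AGE_GROUP))
    wall *= (c.bsa() / _REFERENCE_BSA) ** eff["bsa_exponent"]

    jit = rng.normal(0.0, spec.noise_sd, size=5)
    semi = [float(a * size * (1.0 + j)) for a, j in zip(_BASE_LV_SEMI_AXES, jit[:3])]
    wall = float(wall * (1.0 + jit[3]))
    ea = float(np.clip(_BASE_EJECTION_AMPLITUDE * (1.0 + jit[4]), 0.3, 0.7))

    # fit-to-FOV clamp: extreme body sizes are shrunk isotropically so the
    # full heart (incl. the RV half-shell) stays inside the imaging grid,
    # mirroring the template cropping applied to real cohorts
    shrink = 1.0
    for a, fov in zip(semi, FOV_MM):
        extent = _BASE_RV_SCALE * (a + wall)
        allowed = _FOV_FILL_LIMIT * fov / 2.0
        shrink = min(shrink, allowed / extent)
    semi = tuple(a * shrink for a in semi)
    wall *= shrink

    center = tuple(f / 2.0 for f in FOV_MM)
    return PhantomGeometry(lv_semi_axes=semi, wall_thickness=wall,
                           rv_scale=_BASE_RV_SCALE, center=center,
                           ejection_amplitude=ea, es_phase=_DEFAULT_ES_PHASE)


def contraction_scale(t: int, T: int, g: PhantomGeometry) -> float:
    """Volumetric scale of the cavity at frame ``t`` of a T-frame cycle.

    A raised-cosine systole/diastole pair: 1 at end-diastole (t = 0),
    minimum 1 - ejection_amplitude at the end-systolic phase, returning
    towards 1 by the end of the cycle. Phase is t / T so that the final
    frame sits just short of the next end-diastole.
    """
    if not 0 <= t <= T - 1:
        raise ValueError(f"frame index {t} outside [0, {T - 1}]")
    tau = t / T
    ea, es = g.ejection_amplitude, g.es_phase
    if tau <= es:
        return 1.0 - ea * 0.5 * (1.0 - np.cos(np.pi * tau / es))
    return 1.0 - ea * 0.5 * (1.0 + np.cos(np.pi * (tau - es) / (1.0 - es)))


def _voxel_centers(grid_shape, spacing):
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(grid_shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def rasterize_frame(g: PhantomGeometry, scale: float,
                    grid_shape: tuple[int, int, int],
                    spacing: tuple[float, float, float]) -> np.ndarray:
    """Rasterise one frame of the phantom at the given volumetric scale.

    Voxel centres inside the scaled cavity are label 1; inside the outer
    (cavity + wall) ellipsoid, label 2; inside the RV half-shell, label 3.
    Labels are mutually exclusive by construction.
    """
    u = scale ** (1.0 / 3.0)
    cav = tuple(a * u for a in g.lv_semi_axes)
    outer = tuple(a + g.wall_thickness for a in cav)
    rv_outer = tuple(a * g.rv_scale for a in outer)

    names = ("x", "y", "z")
    for axis, (extent, fov, cc) in enumerate(zip(rv_outer, FOV_MM, g.center)):
        n, s = grid_shape[axis], spacing[axis]
        if cc - extent < 0 or cc + extent > n * s:
            raise ValueError(
                f"geometry exceeds grid along axis {names[axis]}: extent "
                f"{extent:.1f} mm about centre {cc:.1f} mm vs grid "
                f"{n * s:.1f} mm")

    X, Y, Z = _voxel_centers(grid_shape, spacing)
    dx, dy, dz = X - g.center[0], Y - g.center[1], Z - g.center[2]

    def inside(semi):
        return (dx / semi[0]) ** 2 + (dy / semi[1]) ** 2 + (dz / semi[2]) ** 2 <= 1.0

    labels = np.zeros(grid_shape, dtype=np.uint8)
    in_outer = inside(outer)
    labels[in_outer] = 2
    labels[inside(cav)] = 1
    rv = inside(rv_outer) & ~in_outer & (dx >= 0)
    labels[rv] = 3
    return labels


def generate_sequence(c: ConditionSet, spec: CohortSpec,
                      subject_seed: int) -> AnatomySequence:
    """Rasterise the full cardiac cycle for one subject."""
    g = geometry_from_conditions(c, spec, subject_seed)
    frames = [rasterize_frame(g, contraction_scale(t, spec.n_frames, g),
                              spec.grid_shape, spec.spacing)
              for t in range(spec.n_frames)]
    return AnatomySequence(labels=np.stack(frames), spacing=spec.spacing)


def _ellipsoid_volume_ml(semi) -> float:
    return 4.0 / 3.0 * np.pi * semi[0] * semi[1] * semi[2] / 1000.0


def analytic_phenotypes(g: PhantomGeometry) -> PhenotypeSet:
    """Closed-form volumes (mL) and mass (g) of the phantom geometry.

    End-systolic values use the minimum volumetric scale
    1 - ejection_amplitude; the RV half-shell volume is
    (rv_scale^3 - 1) / 2 times the outer-ellipsoid volume.
    """
    u_es = (1.0 - g.ejection_amplitude) ** (1.0 / 3.0)

    def chamber_volumes(u):
        cav = tuple(a * u for a in g.lv_semi_axes)
        outer = tuple(a + g.wall_thickness for a in cav)
        v_out = _ellipsoid_volume_ml(outer)
        lv = _ellipsoid_volume_ml(cav)
        rv = 0.5 * (g.rv_scale ** 3 - 1.0) * v_out
        return lv, rv, v_out

    lvedv, rvedv, v_out_ed = chamber_volumes(1.0)
    lvesv, rvesv, _ = chamber_volumes(u_es)
    lvm = (v_out_ed - lvedv) * MYO_DENSITY_G_PER_ML
    return PhenotypeSet(lvm=lvm, lvedv=lvedv, lvesv=lvesv,
                        rvedv=rvedv, rvesv=rvesv)
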
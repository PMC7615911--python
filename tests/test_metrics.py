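"""Metric layer: overlap and surface distances against hand-computed and
brute-force oracles, phenotype extraction against the analytic phantom,
and distribution distances against closed forms."""

import numpy as np
import pytest
from scipy.optimize import linprog

from cardio4d.metrics import (assd, completion_report, dice,
                              extract_phenotypes, generation_report,
                              hausdorff, kl_divergence_joint,
                              phenotype_differences, surface_points,
                              wasserstein_distance)
from cardio4d.phantom import (AnatomySequence, CohortSpec, PhenotypeSet,
                              analytic_phenotypes, generate_sequence,
                              geometry_from_conditions, sample_conditions)

UNIT = (1.0, 1.0, 1.0)


def _vol(shape=(6, 6, 6)):
    return np.zeros(shape, dtype=np.uint8)


class TestDice:
    def test_identical_and_disjoint(self):
        a = _vol()
        a[1:3, 1:3, 1:3] = 1
        assert dice(a, a.copy(), 1) == 1.0
        b = _vol()
        b[4:6, 4:6, 4:6] = 1
        assert dice(a, b, 1) == 0.0

    def test_hand_computed_overlap(self):
        # |A| = 3, |B| = 2, |A ∩ B| = 1 -> 2*1 / 5
        a, b = _vol(), _vol()
        a[0, 0, 0] = a[0, 0, 1] = a[0, 0, 2] = 1
        b[0, 0, 2] = b[0, 0, 3] = 1
        assert dice(a, b, 1) == pytest.approx(0.4)

    def test_both_empty_defined_as_one(self):
        assert dice(_vol(), _vol(), 1) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(_vol((4, 4, 4)), _vol((5, 4, 4)), 1)


class TestSurfacePoints:
    def test_single_voxel(self):
        m = _vol().astype(bool)
        m[2, 3, 4] = True
        pts = surface_points(m, UNIT)
        np.testing.assert_allclose(pts, [[2.5, 3.5, 4.5]])

    def test_cube_surface_count(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:4, 1:4, 1:4] = True   # 3x3x3 solid: all but the centre are surface
        assert len(surface_points(m, UNIT)) == 26

    def test_sphere_interior_excluded_and_r2_scaling(self):
        counts = {}
        for r in (5, 10):
            n = 2 * r + 5
            x, y, z = np.mgrid[:n, :n, :n]
            c = n / 2 - 0.5
            m = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= r ** 2
            pts = surface_points(m, UNIT)
            # brute force: voxels with a 6-neighbour outside the mask
            mm = np.pad(m, 1)
            shifts = [np.roll(mm, s, a) for a in range(3) for s in (1, -1)]
            brute = mm & ~np.logical_and.reduce(shifts)
            assert len(pts) == brute.sum()
            assert len(pts) < m.sum()  # interior excluded
            counts[r] = len(pts)
        # surface voxel count grows ~ r^2
        assert counts[10] / counts[5] == pytest.approx(4.0, rel=0.25)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            surface_points(np.zeros((3, 3, 3), bool), UNIT)


class TestSurfaceDistances:
    def test_identical_masks_zero(self):
        m = np.zeros((6, 6, 6), bool)
        m[2:4, 2:4, 2:4] = True
        assert hausdorff(m, m.copy(), UNIT) == 0.0
        assert assd(m, m.copy(), UNIT) == 0.0

    def test_single_voxels_hand_geometry(self):
        # voxels 3 apart along x with 2 mm spacing -> 6 mm
        a = np.zeros((8, 4, 4), bool)
        b = np.zeros((8, 4, 4), bool)
        a[1, 1, 1] = True
        b[4, 1, 1] = True
        spacing = (2.0, 1.0, 1.0)
        assert hausdorff(a, b, spacing) == pytest.approx(6.0)
        assert assd(a, b, spacing) == pytest.approx(6.0)

    def test_symmetry_and_ordering(self):
        rng = np.random.default_rng(0)
        a = rng.random((8, 8, 8)) > 0.7
        b = rng.random((8, 8, 8)) > 0.7
        assert hausdorff(a, b, UNIT) == pytest.approx(hausdorff(b, a, UNIT))
        assert assd(a, b, UNIT) <= hausdorff(a, b, UNIT)


class TestExtractPhenotypes:
    def test_all_background(self):
        seq = AnatomySequence(labels=np.zeros((3, 4, 4, 4), np.uint8),
                              spacing=UNIT)
        ph = extract_phenotypes(seq)
        assert all(v == 0 for v in ph.as_dict().values())

    def test_hand_computed_mass(self):
        # 100 myocardial voxels of 1 mm^3 at the ED frame
        lab = np.zeros((1, 10, 10, 10), np.uint8)
        lab[0].flat[:100] = 2
        ph = extract_phenotypes(AnatomySequence(labels=lab, spacing=UNIT))
        assert ph.lvm == pytest.approx(0.105)

    def test_matches_analytic_phantom_within_5pct(self):
        spec = CohortSpec(n_subjects=1, grid_shape=(64, 64, 32), n_frames=20)
        c = sample_conditions(1, 3)[0]
        g = geometry_from_conditions(c, spec, 11)
        seq = generate_sequence(c, spec, 11)
        measured = extract_phenotypes(seq).as_dict()
        for name, truth in analytic_phenotypes(g).as_dict().items():
            assert measured[name] == pytest.approx(truth, rel=0.05), name


class TestPhenotypeDifferences:
    R = PhenotypeSet(lvm=100, lvedv=120, lvesv=50, rvedv=130, rvesv=60)

    def test_single_sample_mean_equals_min(self):
        s = PhenotypeSet(lvm=90, lvedv=110, lvesv=55, rvedv=140, rvesv=52)
        df = phenotype_differences(self.R, [s])
        np.testing.assert_allclose(df["mean_abs_diff"], df["min_abs_diff"])

    def test_hand_computed_aggregation(self):
        s1 = PhenotypeSet(lvm=100, lvedv=130, lvesv=50, rvedv=130, rvesv=60)
        s2 = PhenotypeSet(lvm=100, lvedv=122, lvesv=50, rvedv=130, rvesv=60)
        df = phenotype_differences(self.R, [s1, s2])
        assert df.loc["LVEDV", "mean_abs_diff"] == pytest.approx(6.0)
        assert df.loc["LVEDV", "min_abs_diff"] == pytest.approx(2.0)

    def test_identical_gives_zero_and_empty_rejected(self):
        df = phenotype_differences(self.R, [self.R])
        assert float(df.to_numpy().sum()) == 0.0
        with pytest.raises(ValueError):
            phenotype_differences(self.R, [])


class TestKLDivergence:
    def test_identical_samples_zero(self):
        rng = np.random.default_rng(1)
        pts = np.column_stack([rng.uniform(20, 70, 500),
                               rng.normal(100, 20, 500)])
        assert kl_divergence_joint(pts, pts.copy()) == pytest.approx(0.0, abs=1e-9)

    def test_nonnegative(self):
        rng = np.random.default_rng(2)
        a = np.column_stack([rng.uniform(20, 70, 300), rng.normal(100, 20, 300)])
        b = np.column_stack([rng.uniform(20, 70, 300), rng.normal(90, 25, 300)])
        assert kl_divergence_joint(a, b) >= 0.0

    def test_gaussian_shift_matches_closed_form(self):
        """KL(N(0,σ²) || N(δ,σ²)) = δ²/(2σ²); checked via the histogram
        estimator on large samples with a shared age axis."""
        rng = np.random.default_rng(3)
        n, sigma, delta = 100_000, 10.0, 4.0
        age = rng.uniform(20, 70, n)
        a = np.column_stack([age, rng.normal(0, sigma, n)])
        b = np.column_stack([age, rng.normal(delta, sigma, n)])
        expected = delta ** 2 / (2 * sigma ** 2)
        est = kl_divergence_joint(a, b, bins=(1, 40))
        assert est == pytest.approx(expected, rel=0.25)

    def test_degenerate_axis_rejected(self):
        a = np.array([[30.0, 5.0], [30.0, 6.0]])
        with pytest.raises(ValueError):
            kl_divergence_joint(a, a)


class TestWasserstein:
    def test_point_masses_and_identity(self):
        assert wasserstein_distance([0.0], [5.0]) == pytest.approx(5.0)
        assert wasserstein_distance([1, 2, 3], [1, 2, 3]) == 0.0
        assert wasserstein_distance([0, 1], [1, 2]) == pytest.approx(1.0)

    def test_matches_bruteforce_transport_lp(self):
        """Empirical CDF formula vs a linear-program optimal transport
        solution on random 10-point samples."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            u = rng.normal(0, 5, 10)
            v = rng.normal(2, 3, 10)
            cost = np.abs(u[:, None] - v[None, :]).ravel()
            # marginals: uniform mass 1/10 on each point
            a_eq = np.zeros((20, 100))
            for i in range(10):
                a_eq[i, i * 10:(i + 1) * 10] = 1          # rows of gamma
                a_eq[10 + i, i::10] = 1                   # columns of gamma
            b_eq = np.full(20, 0.1)
            res = linprog(cost, A_eq=a_eq, b_eq=b_eq, bounds=(0, None))
            assert res.status == 0
            assert wasserstein_distance(u, v) == pytest.approx(res.fun, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wasserstein_distance([], [1.0])


def _toy_sequences(n, seed, n_frames=4):
    spec = CohortSpec(n_subjects=n, grid_shape=(32, 32, 16), n_frames=n_frames)
    conds = sample_conditions(n, seed)
    return [generate_sequence(c, spec, seed * 100 + i)
            for i, c in enumerate(conds)], conds


class TestCompletionReport:
    def test_perfect_predictions(self):
        truths, _ = _toy_sequences(2, 5)
        rep = completion_report(truths, [AnatomySequence(t.labels.copy(), t.spacing)
                                         for t in truths])
        assert list(rep.index) == ["LV", "Myo", "RV", "Average"]
        assert rep["dice_mean"].eq(1.0).all()
        assert rep["hd_mean"].eq(0.0).all()
        assert rep["assd_mean"].eq(0.0).all()

    def test_average_row_is_structure_mean(self):
        truths, _ = _toy_sequences(2, 6)
        preds, _ = _toy_sequences(2, 7)
        rep = completion_report(truths, preds)
        for col in rep.columns:
            assert rep.loc["Average", col] == pytest.approx(
                rep.loc[["LV", "Myo", "RV"], col].mean())

    def test_pairing_mismatch(self):
        truths, _ = _toy_sequences(2, 5)
        with pytest.raises(ValueError):
            completion_report(truths, truths[:1])


class TestGenerationReport:
    def test_single_sample_mean_equals_best_and_bounds(self):
        truths, conds = _toy_sequences(2, 8)
        others, _ = _toy_sequences(2, 9)
        rep1 = generation_report(truths, conds, [[o] for o in others])
        for m in ("dice", "hd", "assd"):
            np.testing.assert_allclose(rep1["mean"][m], rep1["best"][m])
        # with several samples, best dominates mean in the right direction
        multi = generation_report(truths, conds,
                                  [[others[0], truths[0]], [others[1], truths[1]]],
                                  age_years=[c.age_years for c in conds])
        assert (multi["best"]["dice"] >= multi["mean"]["dice"] - 1e-12).all()
        assert (multi["best"]["hd"] <= multi["mean"]["hd"] + 1e-12).all()
        assert (multi["best"]["assd"] <= multi["mean"]["assd"] + 1e-12).all()
        for comp in multi["distributions"].values():
            assert comp.kl >= 0 and comp.wd >= 0

    def test_seeded_rerun_reproduces_report(self):
        truths, conds = _toy_sequences(2, 8)
        others, _ = _toy_sequences(2, 9)
        kw = dict(age_years=[c.age_years for c in conds])
        r1 = generation_report(truths, conds, [[o] for o in others], **kw)
        r2 = generation_report(truths, conds, [[o] for o in others], **kw)
        for key in ("mean", "best", "phenotype_differences"):
            np.testing.assert_array_equal(r1[key].to_numpy(), r2[key].to_numpy())
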
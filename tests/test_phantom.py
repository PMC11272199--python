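"""Phantom construction: curves, voxelization, rendering, cohorts."""

import numpy as np
import pytest
from scipy import ndimage

from corkscrew.phantom import (CohortModel, PhantomSpec, VesselInstance,
                               generate_cohort, make_curve, render_dual_echo,
                               voxel_centers, voxelize,
                               QUADRATIC_AGE_COEFFS)


class TestMakeCurve:
    def test_straight_is_two_endpoint_polyline(self):
        c = make_curve("straight", {"length_mm": 10.0})
        assert len(c.samples) == 2
        assert c.arc_length == pytest.approx(10.0)

    def test_helix_arc_length_matches_closed_form(self):
        r, p, n = 0.15, 0.4, 5
        c = make_curve("helix", {"radius_mm": r, "pitch_mm": p, "n_turns": n,
                                 "n_samples": 2000})
        expected = n * np.hypot(2 * np.pi * r, p)
        assert c.arc_length == pytest.approx(expected, rel=1e-3)

    def test_helix_samples_match_analytic_coordinates(self):
        r, p = 0.2, 0.5
        c = make_curve("helix", {"radius_mm": r, "pitch_mm": p, "n_turns": 2,
                                 "axis": (0, 0, 1.0), "n_samples": 101})
        theta = np.linspace(0, 4 * np.pi, 101)
        # axis +z: radial distance from the axis is exactly r
        radial = np.linalg.norm(c.samples[:, :2], axis=1)
        np.testing.assert_allclose(radial, r, atol=1e-9)
        np.testing.assert_allclose(c.samples[:, 2],
                                   p * theta / (2 * np.pi), atol=1e-9)

    def test_sinusoid_amplitude_and_length(self):
        c = make_curve("sinusoid", {"amplitude_mm": 0.36, "period_mm": 2.0,
                                    "n_periods": 3})
        lateral = c.samples @ np.array([0.0, 1.0, 0.0])
        assert np.abs(lateral).max() == pytest.approx(0.36, rel=1e-4)
        along = c.samples @ np.array([1.0, 0.0, 0.0])
        assert along.max() == pytest.approx(6.0)

    def test_random_walk_is_seed_deterministic(self):
        params = {"length_mm": 5.0, "step_mm": 0.1}
        a = make_curve("random_walk", params, seed=7)
        b = make_curve("random_walk", params, seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)
        c = make_curve("random_walk", params, seed=8)
        assert not np.array_equal(a.samples, c.samples)

    def test_random_walk_hits_target_ti(self):
        c = make_curve("random_walk",
                       {"length_mm": 8.0, "step_mm": 0.1, "target_ti": 1.3},
                       seed=2)
        seg = np.linalg.norm(np.diff(c.samples, axis=0), axis=1).sum()
        dl = np.linalg.norm(c.samples[-1] - c.samples[0])
        assert seg / dl == pytest.approx(1.3, rel=0.02)

    @pytest.mark.parametrize("kind,params", [
        ("spiral", {"length_mm": 1.0}),
        ("helix", {"radius_mm": -0.1, "pitch_mm": 0.4, "n_turns": 5}),
        ("straight", {"length_mm": 0.0}),
    ])
    def test_invalid_inputs_raise(self, kind, params):
        with pytest.raises(ValueError):
            make_curve(kind, params)


class TestVoxelize:
    def test_straight_tube_is_connected_and_spans_fov(self):
        fov, sp = (6.0, 6.0, 4.0), (0.25, 0.25, 1.0)
        curve = make_curve("straight", {"length_mm": 5.0,
                                        "axis": (0, 1.0, 0),
                                        "origin": (3.0, 0.5, 2.5)})
        v = VesselInstance(curve=curve, radius_mm=0.3, vclass="artery")
        spec = PhantomSpec(fov_mm=fov, spacing_mm=sp, vessels=[v])
        labels, masks = voxelize([v], spec)
        lab, n = ndimage.label(masks[0], structure=np.ones((3, 3, 3)))
        assert n == 1
        ys = np.argwhere(masks[0])[:, 1]
        assert ys.min() <= 2 and ys.max() >= 21

    def test_empty_vessel_list_gives_zero_labels(self):
        spec = PhantomSpec(fov_mm=(4, 4, 4), spacing_mm=(0.5, 0.5, 1.0))
        labels, masks = voxelize([], spec)
        assert labels.sum() == 0 and masks == []

    def test_two_parallel_vessels_match_bruteforce_distance(self):
        fov, sp = (6.0, 6.0, 4.0), (0.25, 0.25, 1.0)
        vessels = []
        for x in (2.0, 4.0):
            curve = make_curve("straight", {"length_mm": 5.0,
                                            "axis": (0, 1.0, 0),
                                            "origin": (x, 0.5, 2.5),
                                            "n_samples": 200})
            vessels.append(VesselInstance(curve=curve, radius_mm=0.3,
                                          vclass="artery"))
        spec = PhantomSpec(fov_mm=fov, spacing_mm=sp, vessels=vessels)
        labels, masks = voxelize(vessels, spec)
        lab, n = ndimage.label(labels > 0, structure=np.ones((3, 3, 3)))
        assert n == 2
        # brute-force oracle: distance of every voxel center to the curve
        centers = voxel_centers(spec.shape, sp)
        for v, m in zip(vessels, masks):
            d = np.min(np.linalg.norm(
                centers[:, None, :] - v.curve.samples[None, :, :], axis=2),
                axis=1).reshape(spec.shape)
            np.testing.assert_array_equal(m, d <= v.radius_mm)

    def test_subvoxel_radius_warns(self):
        fov, sp = (4.0, 4.0, 4.0), (0.25, 0.25, 1.0)
        curve = make_curve("straight", {"length_mm": 3.0, "axis": (0, 1.0, 0),
                                        "origin": (2.0, 0.5, 2.0)})
        v = VesselInstance(curve=curve, radius_mm=0.05, vclass="artery")
        spec = PhantomSpec(fov_mm=fov, spacing_mm=sp, vessels=[v])
        with pytest.warns(UserWarning, match="sub-voxel"):
            voxelize([v], spec)


class TestRenderDualEcho:
    def make_spec(self, vclass, noise=0.0):
        fov, sp = (4.0, 6.0, 5.0), (0.25, 0.25, 1.0)
        curve = make_curve("straight", {"length_mm": 5.0, "axis": (0, 1.0, 0),
                                        "origin": (2.0, 0.5, 2.5),
                                        "n_samples": 100})
        v = VesselInstance(curve=curve, radius_mm=0.3, vclass=vclass)
        return PhantomSpec(fov_mm=fov, spacing_mm=sp, vessels=[v],
                           noise_sigma=noise, seed=4), v

    def test_no_vessels_no_noise_is_uniform_one(self):
        spec = PhantomSpec(fov_mm=(4, 4, 4), spacing_mm=(0.5, 0.5, 1.0),
                           noise_sigma=0.0)
        vols = render_dual_echo(spec)
        for vol in vols.values():
            np.testing.assert_array_equal(vol.data, 1.0)

    def test_artery_visible_post_only(self):
        spec, v = self.make_spec("artery")
        vols, truth = render_dual_echo(spec, return_truth=True)
        core = truth["masks"][0]
        assert core.any()
        # pre-contrast: artery voxels indistinguishable from background
        np.testing.assert_allclose(vols["pre_TE1"].data[core], 1.0)
        # post-contrast: a fully interior voxel reads exactly a_artery
        assert vols["post_TE1"].data[core].min() == pytest.approx(
            spec.a_artery)

    def test_vein_attenuates_everywhere_and_more_post(self):
        spec, v = self.make_spec("vein")
        vols, truth = render_dual_echo(spec, return_truth=True)
        core = truth["masks"][0]
        pre1 = vols["pre_TE1"].data[core]
        assert pre1.min() == pytest.approx(spec.a_vein)
        # longer echo darkens further; contrast agent darkens further still
        assert vols["pre_TE2"].data[core].min() == pytest.approx(
            spec.a_vein * spec.te2_factor)
        assert np.all(vols["post_TE1"].data[core] <= pre1 + 1e-12)

    def test_veins_darker_than_arteries_post(self):
        spec_a, _ = self.make_spec("artery")
        spec_v, _ = self.make_spec("vein")
        post_a = render_dual_echo(spec_a)["post_TE1"].data.min()
        post_v = render_dual_echo(spec_v)["post_TE1"].data.min()
        assert post_v < post_a

    def test_visibility_ratio_property(self):
        """Artery voxels have post/pre < 1; background stays near 1."""
        spec, _ = self.make_spec("artery", noise=0.01)
        vols, truth = render_dual_echo(spec, return_truth=True)
        core = truth["masks"][0]
        ratio = vols["post_TE1"].data / np.clip(vols["pre_TE1"].data,
                                                1e-6, None)
        assert np.all(ratio[core] < 1.0)
        background = ~truth["bloomed"][0]
        assert np.median(np.abs(ratio[background] - 1.0)) < 3 * 0.01

    def test_pvs_sheath_hyperintense_pre(self):
        fov, sp = (4.0, 6.0, 5.0), (0.25, 0.25, 1.0)
        curve = make_curve("straight", {"length_mm": 5.0, "axis": (0, 1.0, 0),
                                        "origin": (2.0, 0.5, 2.5),
                                        "n_samples": 100})
        v = VesselInstance(curve=curve, radius_mm=0.3, vclass="artery",
                           pvs_radius_mm=0.8)
        spec = PhantomSpec(fov_mm=fov, spacing_mm=sp, vessels=[v],
                           noise_sigma=0.0)
        vols = render_dual_echo(spec)
        assert vols["pre_TE1"].data.max() > 1.05
        assert vols["post_TE1"].data.max() <= 1.0 + 1e-9

    def test_rendering_is_bit_deterministic(self):
        spec, _ = self.make_spec("vein", noise=0.05)
        a = render_dual_echo(spec)
        b = render_dual_echo(spec)
        for key in a:
            np.testing.assert_array_equal(a[key].data, b[key].data)

    def test_bad_attenuation_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(a_artery=1.5)


class TestGenerateCohort:
    def test_noise_free_counts_follow_printed_quadratic(self):
        model = CohortModel(count_sd=0.0)
        table = generate_cohort(500, seed=0, model=model)
        a, b, c = QUADRATIC_AGE_COEFFS
        expected = a * table.age_years**2 + b * table.age_years + c
        np.testing.assert_allclose(table.n_tortuous, expected, atol=1e-9)
        # spot value: age 50 from the printed coefficients
        assert a * 2500 + b * 50 + c == pytest.approx(54.94, abs=0.005)

    def test_same_seed_reproduces_table(self):
        a = generate_cohort(50, seed=3)
        b = generate_cohort(50, seed=3)
        assert a.equals(b)

    def test_noisy_cohort_recovers_quadratic_coefficient(self):
        table = generate_cohort(2000, seed=11)
        X = np.column_stack([table.age_years**2, table.age_years,
                             np.ones(len(table))])
        coef, *_ = np.linalg.lstsq(X, table.n_tortuous, rcond=None)
        assert coef[0] == pytest.approx(QUADRATIC_AGE_COEFFS[0], abs=0.005)

    def test_invariants_and_errors(self):
        table = generate_cohort(200, seed=1)
        assert (table.n_tortuous >= 0).all()
        assert (table.ti_mean >= 1).all()
        assert table.age_years.between(21, 70).all()
        with pytest.raises(ValueError):
            generate_cohort(1, seed=0)
        with pytest.raises(ValueError):
            generate_cohort(10, seed=0, model=CohortModel(count_sd=-1))

    def test_tortuosity_links_increase_with_age(self):
        table = generate_cohort(3000, seed=5)
        young = table[table.age_years <= 35]
        old = table[table.age_years > 55]
        for col in ("ti_mean", "bl_mean_mm", "cwicm_mean"):
            assert old[col].mean() > young[col].mean()
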
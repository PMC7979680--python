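import numpy as np
import pytest

from morphhead import (
    Region,
    RegionLabels,
    element_strain_history,
    jacobian_determinant,
    map_dti_to_elements,
    quality_report,
    regional_peaks,
)
from morphhead.dti import ElementFiberMap
from morphhead.synthetic import (
    PhantomSpec,
    ellipsoid_volume_mm3,
    make_head_phantom,
    make_hex_lattice,
    make_impact_history,
    make_tensor_field,
    make_warp,
)


class TestPhantom:
    def test_deterministic_given_spec(self):
        a = make_head_phantom(PhantomSpec(seed=13))
        b = make_head_phantom(PhantomSpec(seed=13))
        assert np.array_equal(a["t1"].data, b["t1"].data)
        assert np.array_equal(a["labels"].data, b["labels"].data)

    def test_zero_noise_idempotent(self):
        spec = PhantomSpec(noise_sd=0.0, seed=0)
        a = make_head_phantom(spec)
        b = make_head_phantom(spec)
        assert np.array_equal(a["t1"].data, b["t1"].data)

    def test_declared_label_set_present(self, phantom):
        found = set(int(v) for v in np.unique(phantom["labels"].data))
        expected = {0} | {int(r) for r in Region if r != Region.BACKGROUND}
        assert found == expected

    def test_masks_nest(self, phantom):
        brain = np.asarray(phantom["brain_mask"].data) > 0
        cran = np.asarray(phantom["cranial_mask"].data) > 0
        assert (cran | brain).sum() == cran.sum()  # brain ⊂ cranium
        labeled = np.asarray(phantom["labels"].data) > 0
        assert (brain | labeled).sum() == brain.sum()  # labels ⊂ brain

    def test_icv_scaling_matches_closed_form(self):
        # a 1.37× linear size step spans the reported smallest-to-largest
        # ICV range (ratio ~2.57); shrink the base so the pair fits the grid
        base = PhantomSpec(scale=0.70)
        big = PhantomSpec(scale=0.70 * 1.37)
        ratio = ellipsoid_volume_mm3(big.cranium_radii, big.scale) / (
            ellipsoid_volume_mm3(base.cranium_radii, base.scale)
        )
        assert ratio == pytest.approx(1.37 ** 3, rel=1e-12)
        # the generated pair matches the analytic ratio at voxel resolution
        small_vox = int(np.asarray(make_head_phantom(base)["cranial_mask"].data).sum())
        big_vox = int(np.asarray(make_head_phantom(big)["cranial_mask"].data).sum())
        assert big_vox / small_vox == pytest.approx(ratio, rel=0.02)

    def test_nesting_violation_rejected(self):
        spec = PhantomSpec(brain_radii=(73.0, 89.0, 69.0))  # outside cranium
        with pytest.raises(ValueError, match="nest"):
            make_head_phantom(spec)


class TestWarps:
    def test_zero_amplitude_sinusoid_is_zero_field(self):
        w = make_warp("sinusoid", 0.0, (16, 16, 16), np.eye(4))
        assert np.abs(w.field.data).max() == 0.0

    def test_affine_kind_matches_closed_form(self):
        A, b = np.diag([1.05, 0.96, 1.02]), np.array([1.0, -2.0, 0.5])
        w = make_warp("affine", None, (12, 12, 12), np.diag([2, 2, 2, 1.0]),
                      matrix=A, offset=b)
        rng = np.random.default_rng(61)
        pts = rng.uniform(2, 20, size=(40, 3))
        c = np.array([11.0, 11.0, 11.0])
        expected = (pts - c) @ (A - np.eye(3)).T + b
        assert np.allclose(w.evaluate(pts), expected, atol=1e-10)

    @pytest.mark.parametrize("kind,amp", [("sinusoid", 1.5), ("radial", 0.4)])
    def test_generated_warps_pass_jacobian_check(self, kind, amp):
        w = make_warp(kind, amp, (24, 24, 24), np.diag([2, 2, 2, 1.0]))
        assert w.min_jacobian >= 0.2
        det = jacobian_determinant(w.field)
        assert det[1:-1, 1:-1, 1:-1].min() >= 0.2 - 0.05  # numeric gradient slack

    def test_radial_amplitude_bound_enforced(self):
        with pytest.raises(ValueError, match="Jacobian"):
            make_warp("radial", -0.5, (16, 16, 16), np.eye(4))
        # at the positive bound the analytic minimum stays >= 0.2
        w = make_warp("radial", 1.79, (16, 16, 16), np.eye(4))
        assert w.min_jacobian >= 0.2

    def test_sinusoid_amplitude_bound_enforced(self):
        with pytest.raises(ValueError, match="Jacobian"):
            make_warp("sinusoid", 5.0, (16, 16, 16), np.eye(4), wavelength=20.0)

    def test_inverse_displacement_consistency(self):
        w = make_warp("radial", 0.3, (20, 20, 20), np.eye(4))
        rng = np.random.default_rng(62)
        pts = rng.uniform(4, 15, size=(30, 3))
        fwd = w.apply_to_points(pts)
        back = fwd + w.inverse_displacement(fwd)
        assert np.abs(back - pts).max() < 1e-7


class TestLatticeAndTensors:
    def test_single_cube(self):
        m = make_hex_lattice(1, 1, 1)
        assert m.n_elements == 1
        assert m.n_nodes == 8
        assert quality_report(m).min_jacobian == pytest.approx(1.0)

    def test_lattice_counts(self):
        m = make_hex_lattice(10, 10, 10)
        assert m.n_elements == 1000
        assert m.n_nodes == 11 ** 3
        assert quality_report(m).passed

    def test_uniform_tensor_field_hits_fa_target(self):
        vol = make_tensor_field("uniform", 0.7, (6, 6, 6), np.eye(4))
        mesh = make_hex_lattice(4, 4, 4, spacing=1.0, origin=(0.5, 0.5, 0.5))
        fmap = map_dti_to_elements(mesh, vol)
        assert np.allclose(fmap.fa, 0.7, atol=1e-9)
        assert np.allclose(np.abs(fmap.v1 @ [1, 0, 0]), 1.0, atol=1e-9)

    def test_isotropic_target(self):
        vol = make_tensor_field("uniform", 0.0, (4, 4, 4), np.eye(4))
        D = vol.matrices(vol.data[0, 0, 0])
        assert np.allclose(D, np.eye(3) / 3.0, atol=1e-12)


class TestImpactHistory:
    def test_rotation_mode_is_objective(self):
        mesh = make_hex_lattice(3, 3, 3)
        motion, table = make_impact_history(
            mesh, mode="rotation", amplitude=np.deg2rad(25), peak_time_ms=36.0
        )
        sh = element_strain_history(mesh, motion)
        assert np.abs(sh.tensors).max() <= 1e-10
        assert table.get(Region.CEREBRAL_WM, "MPS").value == pytest.approx(
            0.0, abs=1e-12
        )

    def test_stretch_mode_closed_form_peak_recovered(self):
        mesh = make_hex_lattice(4, 3, 3)
        motion, expected = make_impact_history(
            mesh, mode="stretch", amplitude=1.2, peak_time_ms=36.0
        )
        sh = element_strain_history(mesh, motion)
        labels = RegionLabels(np.full(mesh.n_elements, int(Region.CEREBRAL_WM)))
        table = regional_peaks(sh, labels)
        rec = table.get(Region.CEREBRAL_WM, "MPS")
        exp = expected.get(Region.CEREBRAL_WM, "MPS")
        assert exp.value == pytest.approx(0.22, abs=1e-12)  # ½(1.2²−1)
        assert rec.value == pytest.approx(exp.value, abs=1e-10)
        assert rec.time_ms == exp.time_ms == 36.0

    def test_fiber_alignment_controls_mas(self):
        mesh = make_hex_lattice(2, 2, 2)
        n = mesh.n_elements
        along = ElementFiberMap(np.full(n, 0.7), np.tile([1.0, 0, 0], (n, 1)))
        across = ElementFiberMap(np.full(n, 0.7), np.tile([0.0, 1.0, 0], (n, 1)))
        motion, t_along = make_impact_history(
            mesh, mode="stretch", amplitude=1.2, fibers=along
        )
        _, t_across = make_impact_history(
            mesh, mode="stretch", amplitude=1.2, fibers=across
        )
        mas_along = t_along.get(Region.CEREBRAL_WM, "MAS").value
        mas_across = t_across.get(Region.CEREBRAL_WM, "MAS").value
        assert mas_along == pytest.approx(0.22, abs=1e-12)  # MAS = MPS
        assert mas_across == pytest.approx(0.0, abs=1e-12)  # ⟂ stretch axis
        # FE pipeline agrees with both closed forms
        sh = element_strain_history(mesh, motion)
        labels = RegionLabels(np.full(n, int(Region.CEREBRAL_WM)))
        assert regional_peaks(sh, labels, along).get(
            Region.CEREBRAL_WM, "MAS"
        ).value == pytest.approx(mas_along, abs=1e-10)
        assert regional_peaks(sh, labels, across).get(
            Region.CEREBRAL_WM, "MAS"
        ).value == pytest.approx(mas_across, abs=1e-10)

    def test_peak_time_must_lie_on_grid(self):
        mesh = make_hex_lattice(1, 1, 1)
        with pytest.raises(ValueError, match="time grid"):
            make_impact_history(mesh, peak_time_ms=36.0, n_frames=40)
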
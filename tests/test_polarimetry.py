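"""Stokes reconstruction and polarimetric parameter maps."""

import numpy as np
import pytest

from pshg.polarimetry import (
    MeasurementStack,
    PolState,
    STATE_ORDER,
    compute_dcp,
    compute_icp,
    compute_parameter_maps,
    compute_r_ratio,
    compute_shg_cd,
    compute_shg_ld,
    enumerate_measurement_scheme,
    reconstruct_stokes,
    snr_mask,
)
from pshg.synthetic import (
    forward_stokes,
    generate_fiber_field,
    render_stack,
)

from conftest import make_uniform_field, one_pixel_stokes


class TestMeasurementScheme:
    def test_sixteen_psg_major_pairs(self):
        scheme = enumerate_measurement_scheme()
        assert len(scheme) == 16
        assert scheme[0] == (PolState.LCP, PolState.LCP)
        assert len({g for g, _ in scheme}) == 4
        assert len(set(scheme)) == 16
        # PSG-major: first four entries share the first PSG state
        assert all(g == PolState.LCP for g, _ in scheme[:4])


def _stack_from_pixel(values: dict) -> MeasurementStack:
    """One-pixel stack; unspecified (psg, psa) intensities default to 0."""
    images = {key: np.array([[values.get(key, 0.0)]]) for key in enumerate_measurement_scheme()}
    return MeasurementStack(images=images)


class TestReconstruction:
    def test_equal_intensities_give_unpolarized_unit_s0(self):
        p = PolState.RCP
        stack = _stack_from_pixel(
            {(p, a): 0.5 for a in STATE_ORDER}
        )
        st = reconstruct_stokes(stack)
        assert st.s0[p][0, 0] == pytest.approx(1.0)
        assert st.s1[p][0, 0] == pytest.approx(0.0)
        assert st.s3[p][0, 0] == pytest.approx(0.0)
        assert st.residual[p][0, 0] == pytest.approx(0.0)

    def test_circular_difference_gives_s3(self):
        p = PolState.HLP
        stack = _stack_from_pixel(
            {
                (p, PolState.RCP): 1.0,
                (p, PolState.LCP): 0.0,
                (p, PolState.HLP): 0.5,
                (p, PolState.VLP): 0.5,
            }
        )
        st = reconstruct_stokes(stack)
        assert st.s0[p][0, 0] == pytest.approx(1.0)
        assert st.s1[p][0, 0] == pytest.approx(0.0)
        assert st.s3[p][0, 0] == pytest.approx(1.0)

    def test_sign_flips(self):
        p = PolState.HLP
        stack = _stack_from_pixel(
            {(p, PolState.RCP): 1.0, (p, PolState.HLP): 0.8}
        )
        st = reconstruct_stokes(stack, sign_s1=-1, sign_s3=-1)
        assert st.s1[p][0, 0] == pytest.approx(-0.8)
        assert st.s3[p][0, 0] == pytest.approx(-1.0)

    def test_missing_state_rejected(self):
        images = {k: np.zeros((2, 2)) for k in enumerate_measurement_scheme()[:-1]}
        with pytest.raises(KeyError, match="vlp"):
            MeasurementStack(images=images)

    def test_dimension_mismatch_rejected(self):
        images = {k: np.zeros((2, 2)) for k in enumerate_measurement_scheme()}
        images[(PolState.LCP, PolState.LCP)] = np.zeros((3, 3))
        with pytest.raises(ValueError, match="mismatched"):
            MeasurementStack(images=images)

    def test_negative_intensity_rejected(self):
        images = {k: np.zeros((2, 2)) for k in enumerate_measurement_scheme()}
        images[(PolState.LCP, PolState.LCP)] = np.full((2, 2), -1.0)
        with pytest.raises(ValueError, match="negative"):
            MeasurementStack(images=images)

    def test_noise_free_roundtrip_matches_forward_model(self):
        """Reconstruction recovers the simulator's analytic Stokes vectors."""
        field = make_uniform_field(delta=35.0, alpha=20.0, r=2.3, c=0.2)
        stack = render_stack(field, noise=None, seed=0)
        st = reconstruct_stokes(stack)
        for psg in STATE_ORDER:
            s0, s1, _, s3 = forward_stokes(field, psg)
            scale = max(float(np.max(np.abs(s0))), 1.0)
            assert np.max(np.abs(st.s0[psg] - s0)) / scale <= 1e-9
            assert np.max(np.abs(st.s1[psg] - s1)) / scale <= 1e-9
            assert np.max(np.abs(st.s3[psg] - s3)) / scale <= 1e-9
            assert np.max(st.residual[psg]) <= 1e-9 * scale

    def test_dark_offset_subtraction(self):
        field = make_uniform_field(delta=10.0, r=2.0, amplitude=5.0)
        clean = render_stack(field, noise=None, seed=0)
        offset = 7.5
        shifted = MeasurementStack(
            images={k: im + offset for k, im in clean.images.items()}
        )
        st_clean = reconstruct_stokes(clean)
        st_shifted = reconstruct_stokes(shifted, dark_offset=offset)
        for psg in STATE_ORDER:
            np.testing.assert_allclose(st_shifted.s0[psg], st_clean.s0[psg], atol=1e-12)
            np.testing.assert_allclose(st_shifted.s3[psg], st_clean.s3[psg], atol=1e-12)

    def test_physicality_flagged_not_clamped(self):
        st = one_pixel_stokes(s0r=1.0, s3r=2.0)  # |s3| > s0
        counts = st.physicality_violations()
        assert counts[PolState.RCP] == 1
        assert st.s3[PolState.RCP][0, 0] == 2.0  # untouched


class TestIcp:
    def test_forced_arithmetic(self):
        st = one_pixel_stokes(s0r=2.0, s0l=4.0)
        assert compute_icp(st)[0, 0] == pytest.approx(3.0)
        st = one_pixel_stokes(s0r=1.7, s0l=1.7)
        assert compute_icp(st)[0, 0] == pytest.approx(1.7)

    def test_orientation_independence(self):
        """ICP is invariant under in-plane rotation of the fiber field."""
        maps = []
        for delta in (0.0, 37.0, 90.0):
            field = make_uniform_field(delta=delta, r=2.0, amplitude=3.0)
            st = reconstruct_stokes(render_stack(field, noise=None, seed=0))
            maps.append(compute_icp(st))
        for other in maps[1:]:
            assert np.max(np.abs(other - maps[0])) <= 1e-9


class TestRRatio:
    def test_degenerate_a_equals_one_gives_three(self):
        # s0R=s0L=1, s3R-s3L=2 -> A=1; both roots coincide at R=3
        st = one_pixel_stokes(s0r=1.0, s0l=1.0, s3r=1.0, s3l=-1.0)
        for branch in ("plus", "minus"):
            r, valid = compute_r_ratio(st, branch=branch)
            assert valid[0, 0]
            assert r[0, 0] == pytest.approx(3.0)

    def test_inverse_map_consistency(self):
        # A(R) = ((R-1)^2 + 4) / (4 (R-1)) evaluated at R=3 is 1
        r0 = 3.0
        a = ((r0 - 1) ** 2 + 4) / (4 * (r0 - 1))
        assert a == pytest.approx(1.0)

    def test_sub_unit_a_is_invalid(self):
        st = one_pixel_stokes(s0r=0.5, s0l=0.5, s3r=1.0, s3l=-1.0)  # A = 0.5
        with pytest.warns(UserWarning, match="no valid"):
            r, valid = compute_r_ratio(st, branch="minus")
        assert not valid[0, 0]
        assert np.isnan(r[0, 0])

    def test_auto_branch_recovers_ground_truth(self):
        field = make_uniform_field(delta=0.0, alpha=0.0, r=2.0)
        st = reconstruct_stokes(render_stack(field, noise=None, seed=0))
        r, valid = compute_r_ratio(st, branch="auto", r_probe=2.0)
        assert valid.all()
        assert np.max(np.abs(r - 2.0)) <= 1e-6

    @pytest.mark.parametrize("r0", [1.5, 2.0, 2.5, 3.0, 4.0])
    @pytest.mark.parametrize("delta", [0.0, 30.0, 60.0, 90.0])
    def test_roundtrip_grid(self, r0, delta):
        """Noise-free forward simulation recovers R over the (R, delta) grid."""
        field = make_uniform_field(shape=(4, 4), delta=delta, r=r0)
        st = reconstruct_stokes(render_stack(field, noise=None, seed=0))
        r, valid = compute_r_ratio(st, branch="auto", r_probe=r0)
        assert valid.all()
        assert np.max(np.abs(r - r0)) / r0 <= 1e-6

    def test_exactly_one_branch_roundtrips_off_degeneracy(self):
        """Brute-force check: away from R=3 a single root matches truth."""
        r0 = 2.0
        field = make_uniform_field(delta=15.0, r=r0)
        st = reconstruct_stokes(render_stack(field, noise=None, seed=0))
        matches = []
        for branch in ("plus", "minus"):
            r, valid = compute_r_ratio(st, branch=branch)
            matches.append(valid.all() and np.max(np.abs(r - r0)) <= 1e-6)
        assert matches.count(True) == 1


class TestScalarParameters:
    def test_dcp_forced_arithmetic(self):
        st = one_pixel_stokes(s0r=1.0, s0l=1.0, s3r=0.8, s3l=0.6)
        assert compute_dcp(st)[0, 0] == pytest.approx(0.7)
        st = one_pixel_stokes(s0r=2.0, s0l=3.0, s3r=2.0, s3l=-3.0)
        assert compute_dcp(st)[0, 0] == pytest.approx(1.0)
        st = one_pixel_stokes(s0r=1.0, s0l=1.0, s3r=0.0, s3l=0.0)
        assert compute_dcp(st)[0, 0] == pytest.approx(0.0)

    def test_shg_cd_examples(self):
        assert compute_shg_cd(one_pixel_stokes(s0r=1.0, s0l=1.0))[0, 0] == pytest.approx(0.0)
        assert compute_shg_cd(one_pixel_stokes(s0r=1.0, s0l=0.0))[0, 0] == pytest.approx(2.0)
        assert compute_shg_cd(one_pixel_stokes(s0r=3.0, s0l=1.0))[0, 0] == pytest.approx(1.0)

    def test_shg_ld_examples(self):
        assert compute_shg_ld(one_pixel_stokes(s0v=1.0, s0h=1.0))[0, 0] == pytest.approx(0.0)
        assert compute_shg_ld(one_pixel_stokes(s0v=1.0, s0h=0.0))[0, 0] == pytest.approx(2.0)
        assert compute_shg_ld(one_pixel_stokes(s0v=1.0, s0h=3.0))[0, 0] == pytest.approx(-1.0)

    def test_bounds_on_random_physical_stokes(self, rng):
        """DCP in [0,1], |CD| <= 2, |LD| <= 2 for any physical Stokes input."""
        n = 10_000
        s0 = rng.uniform(0.1, 10.0, (4, n))
        s3 = s0 * rng.uniform(-1.0, 1.0, (4, n))  # |s3| <= s0
        arr = lambda row: row.reshape(1, -1)
        from pshg.polarimetry import StokesMaps

        st = StokesMaps(
            s0={p: arr(s0[i]) for i, p in enumerate(STATE_ORDER)},
            s1={p: arr(np.zeros(n)) for p in STATE_ORDER},
            s3={p: arr(s3[i]) for i, p in enumerate(STATE_ORDER)},
        )
        dcp = compute_dcp(st)
        cd = compute_shg_cd(st)
        ld = compute_shg_ld(st)
        assert np.nanmin(dcp) >= 0.0 and np.nanmax(dcp) <= 1.0 + 1e-12
        assert np.nanmax(np.abs(cd)) <= 2.0 + 1e-12
        assert np.nanmax(np.abs(ld)) <= 2.0 + 1e-12

    def test_shg_cd_zero_for_achiral_in_plane_fields(self):
        field = make_uniform_field(delta=25.0, alpha=0.0, r=2.5, c=0.0)
        st = reconstruct_stokes(render_stack(field, noise=None, seed=0))
        assert np.max(np.abs(compute_shg_cd(st))) <= 1e-12


class TestSnrMask:
    def test_threshold_behaviour(self):
        img = np.array([[10.0, 20.0]])
        mask = snr_mask(img, (10.0, 2.0), threshold=3.0)
        assert not mask[0, 0]  # pixel at background mean
        assert mask[0, 1]  # five sigma above

    def test_zero_sigma_rejected(self):
        with pytest.raises(ValueError, match="standard deviation"):
            snr_mask(np.ones((2, 2)), (1.0, 0.0))

    def test_background_region_spec(self):
        img = np.full((10, 10), 5.0)
        img[:2, :2] = [[4.0, 6.0], [5.0, 5.0]]  # background patch, sd ~ 0.7
        img[5, 5] = 50.0
        mask = snr_mask(img, (slice(0, 2), slice(0, 2)), threshold=3.0)
        assert mask[5, 5]
        assert not mask[0, 0]

    def test_retained_fraction_matches_fiber_fraction(self, fast_presets, rng):
        """SNR mask retains (almost exactly) the ground-truth fiber pixels."""
        preset = fast_presets["normal"]
        field = generate_fiber_field(128, preset, rng)
        # background N(10, 2); bright fibers at 100 counts
        img = np.where(field.fiber_mask, 100.0, 0.0) + rng.normal(10.0, 2.0, field.shape)
        mask = snr_mask(img, (10.0, 2.0), threshold=3.0)
        assert abs(mask.mean() - field.fiber_fraction) <= 0.01


class TestParameterMaps:
    def test_common_validity_and_dcp_clamp(self):
        field = make_uniform_field(shape=(6, 6), delta=10.0, r=2.0, amplitude=4.0)
        st = reconstruct_stokes(render_stack(field, noise=None, seed=0))
        params = compute_parameter_maps(st, branch="minus")
        assert params.valid.all()
        assert params.qc["r_branch"] == "minus"
        assert params.qc["dcp_clamped"] == 0
        assert np.nanmax(params.dcp) <= 1.0
        for name, m in params.as_dict().items():
            assert np.isfinite(m[params.valid]).all(), name

    def test_masked_pixels_are_nan(self):
        field = make_uniform_field(shape=(4, 4), delta=10.0, r=2.0)
        st = reconstruct_stokes(render_stack(field, noise=None, seed=0))
        sig = np.ones((4, 4), dtype=bool)
        sig[0, 0] = False
        params = compute_parameter_maps(st, signal_mask=sig, branch="minus")
        assert not params.valid[0, 0]
        assert np.isnan(params.r_ratio[0, 0])
        assert params.valid[1:, :].all()
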
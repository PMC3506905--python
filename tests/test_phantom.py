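"""Phantom generator: geometry, tissue parameters, lesions, forward models,
noise, and slide rendering."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from cortiq.phantom import (
    BSSFP_HIGH,
    BSSFP_LOW,
    SPGR_HIGH,
    SPGR_LOW,
    AcquisitionParams,
    LesionSpec,
    PhantomSpec,
    Tissue,
    add_rician_noise,
    assign_tissue_parameters,
    bssfp_signal,
    build_geometry,
    calibrate_couplings,
    default_tissue_table,
    find_subpial_seed,
    generate_b1_field,
    generate_phantom,
    implant_lesions,
    render_histology_slide,
    simulate_bssfp,
    simulate_dam_pair,
    simulate_mt_pair,
    simulate_spgr,
    spgr_signal,
)
from cortiq.cortex import depth_field

from conftest import small_spec


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

class TestGeometry:
    def test_shell_topology(self, spec64, dataset64):
        """Every cortical component is 26-adjacent to both formalin and WM."""
        labels = dataset64.labels
        cortical = labels.mask(Tissue.CORTEX, Tissue.CORTICAL_LESION)
        comp, ncomp = ndimage.label(cortical, structure=np.ones((3, 3, 3), bool))
        formalin = labels.mask(Tissue.FORMALIN)
        wm = labels.mask(Tissue.WM, Tissue.WM_LESION)
        for c in range(1, ncomp + 1):
            grown = ndimage.binary_dilation(comp == c, np.ones((3, 3, 3), bool))
            assert (grown & formalin).any()
            assert (grown & wm).any()

    def test_deterministic_given_seed(self, spec64):
        a = build_geometry(spec64)
        b = build_geometry(spec64)
        assert np.array_equal(a.data, b.data)

    def test_cortical_thickness_matches_distance_oracle(self, spec64):
        """Thickness recovered from pial+WM distance transforms equals the
        configured shell thickness within one voxel."""
        labels = build_geometry(spec64)
        cortex = labels.mask(Tissue.CORTEX)
        dp = ndimage.distance_transform_edt(labels.data != int(Tissue.FORMALIN))
        dw = ndimage.distance_transform_edt(
            ~np.isin(labels.data, [int(Tissue.WM), int(Tissue.SUBCORTICAL_GM)])
        )
        thickness = (dp + dw)[cortex]  # in voxels
        assert abs(np.median(thickness) - spec64.cortical_thickness_vox) <= 1.0

    def test_too_small_grid_fails(self):
        with pytest.raises(ValueError, match="at least 32"):
            build_geometry(small_spec(grid_shape=(16, 16, 16)))
        with pytest.raises(ValueError, match="grid too small"):
            build_geometry(small_spec(grid_shape=(34, 34, 34), wm_radius_frac=0.45))


# ---------------------------------------------------------------------------
# tissue parameters and couplings
# ---------------------------------------------------------------------------

class TestCouplings:
    def test_two_point_calibration_endpoints(self):
        """The calibrated rate-linear couplings map the lesion and
        normal-cortex myelin means exactly onto their tissue rows."""
        table = default_tissue_table()
        coup = calibrate_couplings(table["cortex"], table["cortical_lesion"])
        assert coup.t1(7.96) == pytest.approx(209.0, rel=1e-12)
        assert coup.t1(1.96) == pytest.approx(236.0, rel=1e-12)
        assert coup.t2(7.96) == pytest.approx(64.0, rel=1e-12)
        assert coup.t2(1.96) == pytest.approx(91.0, rel=1e-12)
        assert coup.delta(7.96) == pytest.approx(0.0747, abs=1e-12)
        assert coup.m0(1.96) == pytest.approx(3835.0, rel=1e-12)

    def test_rate_slope_analytic(self):
        """kappa1 equals the analytic two-point solution in rate space."""
        table = default_tissue_table()
        coup = calibrate_couplings(table["cortex"], table["cortical_lesion"])
        expected = (1.0 / 209 - 1.0 / 236) / (7.96 - 1.96)
        assert coup.k1 == pytest.approx(expected, rel=1e-12)

    def test_non_monotone_table_rejected(self):
        table = default_tissue_table()
        bad = dataclasses.replace(table["cortical_lesion"], t1=150.0)  # < NAC T1
        with pytest.raises(ValueError, match="non-monotone"):
            calibrate_couplings(table["cortex"], bad)

    def test_t1_strictly_decreases_with_myelin(self, dataset64):
        """Within the cortical ribbon, generated T1 is a strictly decreasing
        function of myelin content."""
        sel = dataset64.labels.mask(Tissue.CORTEX, Tissue.CORTICAL_LESION)
        m = dataset64.truth.myelin[sel]
        t1 = dataset64.truth.t1[sel]
        order = np.argsort(m)
        m_sorted, t1_sorted = m[order], t1[order]
        distinct = np.diff(m_sorted) > 0
        assert np.all(np.diff(t1_sorted)[distinct] < 0)

    def test_parameter_map_invariants(self, dataset64):
        maps = dataset64.truth
        assert np.all(maps.t1 > 0) and np.all(maps.t2 > 0)
        assert np.all(maps.t2 < maps.t1)
        assert np.all((maps.delta >= 0) & (maps.delta <= 1))
        assert np.all((maps.myelin >= 0) & (maps.myelin <= 100))

    def test_cortex_myelin_marginal_matches_row(self, dataset64):
        """Rank-mapped laminar field reproduces the normal-cortex myelin
        mean and SD."""
        row = dataset64.spec.tissue_table["cortex"]
        m = dataset64.truth.myelin[dataset64.labels.mask(Tissue.CORTEX)]
        # lesion implantation removes preferentially low-myelin superficial
        # voxels, so compare against the pre-lesion ribbon reconstruction
        spec = dataset64.spec
        labels = build_geometry(spec)
        depth = depth_field(labels)
        maps = assign_tissue_parameters(labels, spec, depth=depth)
        m_all = maps.myelin[labels.mask(Tissue.CORTEX)]
        assert m_all.mean() == pytest.approx(row.myelin, abs=0.1)
        assert m_all.std() == pytest.approx(row.myelin_sd, abs=0.1)
        assert m.size > 0  # lesioned dataset still has normal cortex


# ---------------------------------------------------------------------------
# lesions
# ---------------------------------------------------------------------------

class TestLesions:
    def test_subpial_respects_depth_fraction(self, dataset64):
        cl = dataset64.labels.mask(Tissue.CORTICAL_LESION)
        assert cl.any()
        assert np.all(dataset64.depth[cl] < 0.5)

    def test_voxel_set_matches_brute_force_predicate(self, spec64):
        """Implanted subpial voxels are exactly the voxels satisfying both
        geometric predicates (tangential ball and depth cut), scanned
        independently."""
        labels = build_geometry(spec64)
        depth = depth_field(labels)
        maps = assign_tissue_parameters(labels, spec64, depth=depth)
        pial = np.argwhere(labels.mask(Tissue.CORTEX) & (depth <= 0.2))
        center = tuple(int(v) for v in pial[0])
        les = LesionSpec("subpial_typeIII", center, tangential_radius=4.0,
                         depth_fraction=0.6)
        spec = dataclasses.replace(spec64, lesion_specs=[les])
        out_labels, _ = implant_lesions(labels, maps, spec, depth)

        seed_vox = find_subpial_seed(labels, depth, center, 4.0)
        expected = set()
        vox = labels.voxel_size
        for p in np.argwhere(labels.mask(Tissue.CORTEX)):
            dist = np.sqrt(((p - np.asarray(seed_vox)) ** 2).sum()) * vox
            if dist <= 4.0 and depth[tuple(p)] < 0.6:
                expected.add(tuple(p))
        got = set(map(tuple, np.argwhere(out_labels.mask(Tissue.CORTICAL_LESION))))
        assert got == expected

    def test_lesion_myelin_mean(self, dataset64):
        """Implanted cortical-lesion voxels average the lesion-row myelin
        content (1.96 %) within 0.5 points at n >= 500."""
        cl = dataset64.labels.mask(Tissue.CORTICAL_LESION)
        assert cl.sum() >= 500
        assert dataset64.truth.myelin[cl].mean() == pytest.approx(1.96, abs=0.5)

    def test_wm_lesion_center_must_be_wm(self, spec64):
        labels = build_geometry(spec64)
        depth = depth_field(labels)
        maps = assign_tissue_parameters(labels, spec64, depth=depth)
        formalin_voxel = tuple(np.argwhere(labels.mask(Tissue.FORMALIN))[0])
        les = LesionSpec("wm_focal", formalin_voxel, 2.0)
        spec = dataclasses.replace(spec64, lesion_specs=[les])
        with pytest.raises(ValueError, match="not in white matter"):
            implant_lesions(labels, maps, spec, depth)


# ---------------------------------------------------------------------------
# B1 field
# ---------------------------------------------------------------------------

class TestB1Field:
    def test_zero_amplitude_is_uniform(self):
        b1 = generate_b1_field(small_spec(b1_amplitude=0.0))
        assert np.all(b1.data == 1.0)

    def test_range_contract(self, spec64):
        b1 = generate_b1_field(spec64)
        assert b1.data.min() >= 1.0 - spec64.b1_amplitude - 1e-12
        assert b1.data.max() <= 1.0 + spec64.b1_amplitude + 1e-12

    def test_reproducible(self, spec64):
        a = generate_b1_field(spec64)
        b = generate_b1_field(spec64)
        assert np.array_equal(a.data, b.data)

    def test_smooth(self, spec64):
        b1 = generate_b1_field(spec64)
        grad = np.abs(np.diff(b1.data, axis=0))
        assert grad.max() < 0.05  # bounded voxel-to-voxel change


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

def _uniform_maps(t1, t2, m0=1.0, delta=0.0, shape=(4, 4, 4), vox=0.35):
    from cortiq.phantom import ParameterMaps

    full = lambda v: np.full(shape, float(v))
    return ParameterMaps(full(t1), full(t2), full(m0), full(delta), full(0.0), vox)


def _uniform_b1(value=1.0, shape=(4, 4, 4), vox=0.35):
    from cortiq.phantom import B1Map

    return B1Map(np.full(shape, float(value)), vox)


class TestForwardModels:
    def test_spgr_matches_scalar_closed_form(self):
        """Simulated SPGR pair at the study protocol equals an independent
        scalar evaluation of the steady-state equation."""
        maps = _uniform_maps(t1=209.0, t2=64.0, m0=1.0)
        b1 = _uniform_b1(1.0)
        for acq in (SPGR_LOW, SPGR_HIGH):
            s = simulate_spgr(maps, acq, b1)
            a = np.deg2rad(acq.flip_deg)
            e1 = np.exp(-acq.tr / 209.0)
            expected = np.sin(a) * (1 - e1) / (1 - np.cos(a) * e1)
            assert s.data == pytest.approx(expected, rel=1e-12)

    def test_spgr_small_flip_limit(self):
        maps = _uniform_maps(209.0, 64.0)
        s = simulate_spgr(maps, AcquisitionParams("SPGR", 7.7, 3.35, 1e-4),
                          _uniform_b1())
        assert np.all(s.data < 1e-5)

    def test_spgr_saturation_recovery_limit(self):
        """TR >> T1: the signal approaches M0 sin(alpha)."""
        maps = _uniform_maps(209.0, 64.0, m0=2.0)
        acq = AcquisitionParams("SPGR", tr=1e5, te=3.35, flip_deg=30.0)
        s = simulate_spgr(maps, acq, _uniform_b1())
        assert s.data == pytest.approx(2.0 * np.sin(np.deg2rad(30.0)), rel=1e-6)

    def test_bssfp_matches_scalar_closed_form(self):
        t1, t2 = 380.0, 121.0
        maps = _uniform_maps(t1, t2, m0=1.5)
        for acq in (BSSFP_LOW, BSSFP_HIGH):
            s = simulate_bssfp(maps, acq, _uniform_b1())
            a = np.deg2rad(acq.flip_deg)
            e1, e2 = np.exp(-acq.tr / t1), np.exp(-acq.tr / t2)
            expected = 1.5 * np.sin(a) * (1 - e1) / (1 - e1 * e2 - (e1 - e2) * np.cos(a))
            assert s.data == pytest.approx(expected, rel=1e-12)

    def test_bssfp_t2_near_t1_90deg(self):
        """T2 -> T1 at 90 degrees reduces to M0 (1-E1)/(1-E1 E2)."""
        t1 = 200.0
        t2 = t1 * (1 - 1e-9)
        val = bssfp_signal(t1, t2, 1.0, 90.0, 7.7)
        e1 = np.exp(-7.7 / t1)
        assert val == pytest.approx((1 - e1) / (1 - e1 * e1), rel=1e-6)

    def test_bssfp_defect_metadata_bookkeeping(self):
        maps = _uniform_maps(209.0, 64.0)
        mask = np.zeros((4, 4, 4), bool)
        mask[1:3, 1:3, 1:3] = True
        s = simulate_bssfp(maps, BSSFP_LOW, _uniform_b1(), defect_mask=mask,
                           defect_factor=0.5)
        assert np.array_equal(s.defect_mask, mask)
        ref = simulate_bssfp(maps, BSSFP_LOW, _uniform_b1())
        assert np.allclose(s.data[mask], 0.5 * ref.data[mask])
        assert np.allclose(s.data[~mask], ref.data[~mask])

    def test_mt_pair_ratio_equals_one_minus_delta(self):
        maps = _uniform_maps(196.0, 56.0, m0=3467.0, delta=0.1282)
        s0, ssat = simulate_mt_pair(maps, _uniform_b1(1.1))
        assert ssat.data / s0.data == pytest.approx(1 - 0.1282, rel=1e-12)

    def test_mt_pair_identical_when_delta_zero(self):
        maps = _uniform_maps(196.0, 56.0, m0=3467.0, delta=0.0)
        s0, ssat = simulate_mt_pair(maps, _uniform_b1())
        assert np.array_equal(s0.data, ssat.data)

    @pytest.mark.parametrize("b1val", [1.0, 1.2])
    def test_dam_ratio_trigonometric(self, b1val):
        s1, s2 = simulate_dam_pair(_uniform_b1(b1val), prep_flip_deg=20.0)
        expected = np.cos(np.deg2rad(40.0 * b1val)) / np.cos(np.deg2rad(20.0 * b1val))
        assert s2.data / s1.data == pytest.approx(expected, rel=1e-12)

    def test_dam_ratio_scale_invariant(self):
        a1, a2 = simulate_dam_pair(_uniform_b1(1.1), scale=1.0)
        b1_, b2 = simulate_dam_pair(_uniform_b1(1.1), scale=3797.0)
        assert a2.data / a1.data == pytest.approx(b2.data / b1_.data, rel=1e-12)

    def test_dam_precondition_failure_names_voxels(self):
        with pytest.raises(ValueError, match="voxels"):
            simulate_dam_pair(_uniform_b1(2.5), prep_flip_deg=20.0)


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

class TestRicianNoise:
    def test_zero_sigma_is_identity(self):
        maps = _uniform_maps(209.0, 64.0)
        s = simulate_spgr(maps, SPGR_LOW, _uniform_b1())
        assert add_rician_noise(s, 0.0, seed=1) is s

    def test_rayleigh_mean_at_zero_signal(self):
        """With S = 0 the magnitude is Rayleigh; its mean is sigma sqrt(pi/2)."""
        from cortiq.phantom import SignalVolume

        zero = SignalVolume(np.zeros((50, 50, 50)), SPGR_LOW, 0.35)
        noisy = add_rician_noise(zero, 3.0, seed=4)
        assert noisy.data.mean() == pytest.approx(3.0 * np.sqrt(np.pi / 2), rel=0.01)

    def test_seed_reproducible(self):
        maps = _uniform_maps(209.0, 64.0, m0=1000.0)
        s = simulate_spgr(maps, SPGR_LOW, _uniform_b1())
        a = add_rician_noise(s, 5.0, seed=9)
        b = add_rician_noise(s, 5.0, seed=9)
        assert np.array_equal(a.data, b.data)
        c = add_rician_noise(s, 5.0, seed=10)
        assert not np.array_equal(a.data, c.data)


# ---------------------------------------------------------------------------
# slide rendering
# ---------------------------------------------------------------------------

class TestSlideRendering:
    def test_extreme_contents(self):
        from cortiq.histology import segment_myelin

        slide = render_histology_slide(np.array([[0.0, 100.0]]), 10, seed=3)
        fibers = segment_myelin(slide)
        assert not fibers[:, :10].any()  # content-0 block
        assert fibers[:, 10:].all()  # content-100 block

    def test_round_trip_recovers_content(self):
        """Render -> segment -> block-average recovers the target content
        within one percentage point per block."""
        from cortiq.histology import myelin_content_map, segment_myelin

        target = np.array([[7.96, 30.0], [74.18, 55.5]])
        slide = render_histology_slide(target, 10, seed=8)
        rec = myelin_content_map(segment_myelin(slide), 10)
        assert np.abs(rec.data - target).max() <= 1.0

    def test_content_above_100_rejected(self):
        with pytest.raises(ValueError):
            render_histology_slide(np.array([[120.0]]), 10, seed=0)

    def test_deterministic(self):
        a = render_histology_slide(np.array([[40.0]]), 10, seed=5)
        b = render_histology_slide(np.array([[40.0]]), 10, seed=5)
        assert np.array_equal(a.data, b.data)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

class TestDataset:
    def test_bit_reproducible(self, spec64, dataset64):
        other = generate_phantom(spec64)
        assert np.array_equal(other.labels.data, dataset64.labels.data)
        for key in dataset64.signals:
            assert np.array_equal(other.signals[key].data,
                                  dataset64.signals[key].data)
        assert np.array_equal(other.slide.data, dataset64.slide.data)

    def test_signals_nonnegative_finite(self, dataset64):
        for vol in dataset64.signals.values():
            assert np.all(np.isfinite(vol.data))
            assert np.all(vol.data >= 0)
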
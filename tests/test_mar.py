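import numpy as np
import pytest

from marct.ct_sim import (ScanGeometry, Sinogram, acquire, forward_project,
                          log_normalize, simulate_counts, water_linearize)
from marct.mar import (MarConfig, MetalSegmentation, complete_sinogram,
                       mar_pipeline, metal_path_sinogram, metal_trace,
                       physics_correct, segment_metal)
from marct.materials import linear_attenuation
from marct.phantom import (GridSpec, build_phantom, configuration_spec,
                           make_ground_truth, metal_slot_mask)
from marct.volumes import StructureMask, Volume


GRID = GridSpec(n_xy=128, spacing_mm=3.0, n_slices=1)
GEOMETRY = ScanGeometry.for_grid(128, 3.0, n_views=180)
N0 = 2.0e6


@pytest.fixture(scope="module")
def highz_acquisition(table, spectrum):
    labels = build_phantom(configuration_spec(2, grid=GRID))
    counts, uncorrected = acquire(labels, spectrum, GEOMETRY, N0, seed=7,
                                  table=table)
    return labels, counts, uncorrected


@pytest.fixture(scope="module")
def lowz_acquisition(table, spectrum):
    labels = build_phantom(configuration_spec(1, grid=GRID))
    counts, uncorrected = acquire(labels, spectrum, GEOMETRY, N0, seed=7,
                                  table=table)
    return labels, counts, uncorrected


@pytest.fixture(scope="module")
def ground_truth_image(table, spectrum):
    labels_sw = build_phantom(configuration_spec(3, grid=GRID))
    _, img = acquire(labels_sw, spectrum, GEOMETRY, N0, seed=100, table=table)
    return img


def _make_volume(values):
    n = values.shape[-1]
    half = n * 3.0 / 2.0
    return Volume(values, (2.5, 3.0, 3.0), (-1.25, -half, -half))


class TestSegmentMetal:
    def test_all_water_image_yields_empty_mask(self):
        img = _make_volume(np.zeros((1, 64, 64)))
        assert segment_metal(img).is_empty

    def test_tiny_component_removed(self):
        values = np.zeros((1, 64, 64))
        values[0, 30, 30] = 3071.0
        assert segment_metal(_make_volume(values)).is_empty

    def test_low_z_components_match_insert_geometry(self, lowz_acquisition):
        labels, _, uncorrected = lowz_acquisition
        seg = segment_metal(uncorrected)
        comps = set(seg.component_hu) - {0}
        assert len(comps) == 2
        disk_area = np.pi * 5.0**2 / 9.0  # 1 cm disk on 3 mm voxels
        for c in comps:
            area = (seg.component_labels == c).sum()
            assert area == pytest.approx(disk_area, rel=0.30)


class TestMetalTrace:
    def test_empty_segmentation_trace_is_starvation_only(self):
        img = _make_volume(np.zeros((1, 64, 64)))
        seg = segment_metal(img)
        starved = np.zeros((1, GEOMETRY.n_views, GEOMETRY.n_bins), dtype=bool)
        starved[0, 3, 10] = True
        trace = metal_trace(seg, GEOMETRY, starved=starved)
        assert not trace.metal_trace.any()
        assert np.array_equal(trace.missing, starved)

    def test_single_voxel_flags_one_run_per_view(self):
        values = np.zeros((1, 64, 64), dtype=bool)
        values[0, 32, 40] = True
        vol = _make_volume(values.astype(float))
        seg = MetalSegmentation(
            StructureMask("metal", values, vol.spacing, vol.origin),
            values.astype(int), {1: 3071.0}, 3071.0)
        trace = metal_trace(seg, GEOMETRY)
        for v in range(GEOMETRY.n_views):
            runs = np.diff(np.flatnonzero(trace.metal_trace[0, v]))
            assert trace.metal_trace[0, v].any()
            assert np.all(runs == 1)  # contiguous

    def test_wider_insert_covers_larger_trace_fraction(
            self, lowz_acquisition, highz_acquisition):
        frac = {}
        for name, (labels, _, img) in (("low", lowz_acquisition),
                                       ("high", highz_acquisition)):
            mask = metal_slot_mask(labels)
            seg = MetalSegmentation(
                mask, mask.mask.astype(int), {1: 3071.0}, 3071.0)
            frac[name] = metal_trace(seg, GEOMETRY).metal_trace.mean()
        assert frac["high"] > frac["low"]


class TestPhysicsCorrect:
    def test_no_metal_is_passthrough(self, table, spectrum):
        p = Sinogram(np.random.default_rng(0).uniform(
            0, 3, (1, 8, 32)), "line_integral", GEOMETRY)
        seg = MetalSegmentation(
            StructureMask("metal", np.zeros((1, 64, 64), bool),
                          (2.5, 3, 3), (0, 0, 0)),
            np.zeros((1, 64, 64), int), {}, 0.0, material="titanium")
        out, failed = physics_correct(p, np.zeros((1, 8, 32)), seg, spectrum,
                                      table)
        assert np.array_equal(out.values, p.values)
        assert not failed.any()

    def test_round_trip_through_forward_model(self, table, spectrum):
        """Bins built from known (t_w, t_m) with the polychromatic forward
        model (plus the scanner's water calibration) are corrected to the
        monochromatic equivalent within 1%."""
        from marct.ct_sim import water_linearization

        e = spectrum.energies_kev
        mu_w = np.asarray(linear_attenuation("water", e, table))
        mu_m = np.asarray(linear_attenuation("titanium", e, table))
        tw = np.array([[[5.0, 10.0, 18.0, 14.0]]])
        tm = np.array([[[0.3, 1.0, 0.7, 0.0]]])
        p_poly = -np.log(np.einsum(
            "zvbe,e->zvb",
            np.exp(-(tw[..., None] * mu_w + tm[..., None] * mu_m)),
            spectrum.weights))
        p_meas = water_linearization(spectrum, table)(p_poly)
        sino = Sinogram(p_meas, "line_integral", GEOMETRY)
        seg = MetalSegmentation(
            StructureMask("metal", np.ones((1, 2, 2), bool),
                          (2.5, 3, 3), (0, 0, 0)),
            np.ones((1, 2, 2), int), {1: 3071.0}, 3071.0,
            material="titanium")
        out, failed = physics_correct(sino, tm, seg, spectrum, table)
        e_ref = spectrum.reference_energy_kev
        expected = (linear_attenuation("water", e_ref, table) * tw
                    + linear_attenuation("titanium", e_ref, table) * tm)
        metal_bins = tm > 0
        assert not failed.any()
        np.testing.assert_allclose(out.values[metal_bins],
                                   expected[metal_bins], rtol=0.01)
        # non-metal bin passes through unchanged
        assert out.values[~metal_bins] == pytest.approx(
            p_meas[~metal_bins], rel=1e-12)

    def test_monochromatic_spectrum_is_identity(self, table, spectrum):
        """Without beam hardening the correction changes nothing (within
        lookup interpolation error)."""
        mono = spectrum.monochromatic()
        e_ref = mono.reference_energy_kev
        mu_w = linear_attenuation("water", e_ref, table)
        mu_m = linear_attenuation("titanium", e_ref, table)
        tw = np.array([[[4.0, 12.0, 17.5]]])
        tm = np.array([[[0.5, 1.0, 0.2]]])
        p = mu_w * tw + mu_m * tm
        sino = Sinogram(p, "line_integral", GEOMETRY)
        seg = MetalSegmentation(
            StructureMask("metal", np.ones((1, 2, 2), bool),
                          (2.5, 3, 3), (0, 0, 0)),
            np.ones((1, 2, 2), int), {1: 3071.0}, 3071.0,
            material="titanium")
        out, _ = physics_correct(sino, tm, seg, mono, table)
        np.testing.assert_allclose(out.values, p, rtol=1e-3)


class TestCompleteSinogram:
    def _smooth_disk_sinogram(self, table, spectrum):
        labels = build_phantom(configuration_spec(3, grid=GRID))
        e_ref = spectrum.reference_energy_kev
        p = forward_project(labels, GEOMETRY, table, [e_ref])
        return Sinogram(p.values[..., 0], "line_integral", GEOMETRY)

    def test_empty_missing_mask_is_identity(self, table, spectrum):
        sino = self._smooth_disk_sinogram(table, spectrum)
        out = complete_sinogram(sino, np.zeros_like(sino.values, dtype=bool))
        assert np.array_equal(out.values, sino.values)

    def test_missing_view_recovered_within_2pct_rms(self, table, spectrum):
        sino = self._smooth_disk_sinogram(table, spectrum)
        missing = np.zeros_like(sino.values, dtype=bool)
        missing[0, 90, :] = True
        corrupted = sino.copy_with(sino.values.copy())
        corrupted.values[0, 90, :] = 0.0
        out = complete_sinogram(corrupted, missing)
        truth = sino.values[0, 90]
        rms = np.sqrt(np.mean((out.values[0, 90] - truth) ** 2))
        assert rms / np.sqrt(np.mean(truth**2)) < 0.02

    def test_view_moments_match_median_within_1pct(self, highz_acquisition,
                                                   table, spectrum):
        _, counts, _ = highz_acquisition
        p = water_linearize(log_normalize(counts), spectrum, table)
        out = complete_sinogram(p, ~p.valid)
        ds = GEOMETRY.bin_width_mm / 10.0
        masses = out.values[0].sum(axis=1) * ds
        med = np.median(masses)
        assert np.all(np.abs(masses - med) / med < 0.01)

    def test_objective_non_increasing(self, highz_acquisition, table,
                                      spectrum):
        _, counts, _ = highz_acquisition
        p = water_linearize(log_normalize(counts), spectrum, table)
        _, objectives = complete_sinogram(p, ~p.valid, return_objectives=True)
        for obj in objectives:
            assert all(b <= a + 1e-9 * max(abs(a), 1.0)
                       for a, b in zip(obj, obj[1:]))

    def test_fully_starved_acquisition_rejected(self):
        sino = Sinogram(np.zeros((1, 8, 16)), "line_integral", GEOMETRY)
        with pytest.raises(ValueError, match="unrecoverable"):
            complete_sinogram(sino, np.ones((1, 8, 16), dtype=bool))


class TestMarPipeline:
    def test_metal_free_scan_is_idempotent(self, table, spectrum,
                                           ground_truth_image):
        labels = build_phantom(configuration_spec(3, grid=GRID))
        counts, uncorrected = acquire(labels, spectrum, GEOMETRY, N0,
                                      seed=100, table=table)
        corrected = mar_pipeline(counts, uncorrected, spectrum=spectrum,
                                 table=table)
        body = labels.labels > 0
        rms = np.sqrt(np.mean(
            (corrected.values - uncorrected.values)[body] ** 2))
        assert rms < 2.0

    @pytest.mark.parametrize("configuration,metal", [(1, "titanium"),
                                                     (2, "cerrobend")])
    def test_correction_improves_rmse_against_ground_truth(
            self, configuration, metal, table, spectrum, ground_truth_image,
            lowz_acquisition, highz_acquisition):
        labels, counts, uncorrected = (lowz_acquisition if configuration == 1
                                       else highz_acquisition)
        result = mar_pipeline(counts, uncorrected, spectrum=spectrum,
                              table=table, return_diagnostics=True)
        gt = make_ground_truth(
            ground_truth_image, labels,
            [("A", table.material(metal)), ("B", table.material(metal))],
            table, spectrum.reference_energy_kev)
        region = (labels.labels > 0) & ~metal_slot_mask(labels).mask \
            & ~result.segmentation.mask.mask
        rmse_unc = np.sqrt(np.mean(
            (uncorrected.values - gt.values)[region] ** 2))
        rmse_cor = np.sqrt(np.mean(
            (result.corrected.values - gt.values)[region] ** 2))
        assert rmse_cor < rmse_unc

    def test_high_z_artifacts_worse_than_low_z(
            self, table, spectrum, ground_truth_image, lowz_acquisition,
            highz_acquisition):
        stds = {}
        for cfg, metal, (labels, _, unc) in (
                (1, "titanium", lowz_acquisition),
                (2, "cerrobend", highz_acquisition)):
            gt = make_ground_truth(
                ground_truth_image, labels,
                [("A", table.material(metal)), ("B", table.material(metal))],
                table, spectrum.reference_energy_kev)
            region = (labels.labels > 0) & ~metal_slot_mask(labels).mask
            stds[cfg] = (unc.values - gt.values)[region].std()
        assert stds[2] > stds[1]

    def test_metal_voxels_take_reinsertion_hu(self, highz_acquisition, table,
                                              spectrum):
        _, counts, uncorrected = highz_acquisition
        result = mar_pipeline(counts, uncorrected, spectrum=spectrum,
                              table=table, return_diagnostics=True)
        for comp_id, hu in result.segmentation.component_hu.items():
            sel = result.segmentation.component_labels == comp_id
            assert np.all(result.corrected.values[sel] == hu)

    def test_deterministic(self, highz_acquisition, table, spectrum):
        _, counts, uncorrected = highz_acquisition
        a = mar_pipeline(counts, uncorrected, spectrum=spectrum, table=table)
        b = mar_pipeline(counts, uncorrected, spectrum=spectrum, table=table)
        assert np.array_equal(a.values, b.values)
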
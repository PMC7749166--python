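"""Height-map topography: referencing, particle detection and measurement,
population mixture fitting, orientation calls and multiplex overlay."""

import numpy as np
import pandas as pd
import pytest

from forcespec import (
    HeightMap,
    MapTruth,
    classify_orientation,
    detect_particles,
    fit_modes,
    flatten_and_reference,
    gen_height_map,
    gen_multiplex_events,
    measure_particle,
    measure_particles,
    overlay_events,
)
from forcespec.exceptions import ReferencingError
from forcespec.topography import (
    em_log_likelihood_trace,
    read_height_map,
    write_height_map,
)


def gaussian_bump_map(size=101, h=1.7, fwhm=16.0, px=1.0, center=None):
    rows = cols = size
    r0, c0 = center if center else (size // 2, size // 2)
    rr, cc = np.mgrid[0:rows, 0:cols]
    sigma = fwhm / 2.354820045 / px
    return h * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))


class TestFlattenAndReference:
    def test_removes_tilt_to_sub_angstrom(self, rng):
        rows = cols = 120
        rr, cc = np.mgrid[0:rows, 0:cols]
        grid = 0.01 * rr - 0.004 * cc + 5.0 + rng.normal(0, 0.03, (rows, cols))
        flat = flatten_and_reference(HeightMap(grid, 2.0))
        assert np.abs(np.median(flat.grid)) < 0.05
        assert flat.grid.std() < 0.05

    def test_idempotent_on_flat_map(self, rng):
        grid = rng.normal(0, 0.03, (100, 100))
        once = flatten_and_reference(HeightMap(grid, 2.0))
        twice = flatten_and_reference(once)
        np.testing.assert_allclose(twice.grid, once.grid, atol=0.01)

    def test_bilayer_mode_found_with_particle_coverage(self):
        truth = MapTruth(n_particles=40, tilt=(0.005, -0.002))
        grid, _ = gen_height_map(truth, size=(256, 256), seed=7)
        flat = flatten_and_reference(HeightMap(grid, truth.pixel_size))
        # bilayer (the histogram mode) must sit at 0 within 0.1 nm
        counts, edges = np.histogram(flat.grid.ravel(), bins=200)
        mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
        assert abs(mode) < 0.1

    def test_no_dominant_background_raises(self, rng):
        # two equally occupied levels 3 nm apart: no single bilayer
        grid = np.where(rng.random((100, 100)) < 0.5, 0.0, 3.0)
        grid += rng.normal(0, 0.02, (100, 100))
        with pytest.raises(ReferencingError):
            flatten_and_reference(HeightMap(grid, 2.0))


class TestDetectParticles:
    def test_single_bump_single_detection(self):
        hm = HeightMap(gaussian_bump_map(h=2.0), 1.0)
        seeds = detect_particles(hm, min_height=0.5, min_separation=6.0)
        assert len(seeds) == 1
        assert seeds[0] == (50, 50)

    def test_all_planted_particles_recovered(self):
        truth = MapTruth(
            n_particles=50,
            height_means=(2.0,),
            height_sds=(1e-9,),
            height_weights=(1.0,),
            roughness_sd=0.05,
        )
        grid, table = gen_height_map(truth, size=(420, 420), seed=2)
        hm = flatten_and_reference(HeightMap(grid, truth.pixel_size))
        seeds = detect_particles(hm, min_height=0.8, min_separation=8.0)
        assert len(seeds) == 50

    def test_empty_bilayer_yields_no_detections(self, rng):
        grid = rng.normal(0, 0.1, (200, 200))
        hm = HeightMap(grid, 2.0)
        assert detect_particles(hm, min_height=0.5, min_separation=6.0) == []


class TestMeasureParticle:
    def test_reference_particle_height_and_diameter(self):
        """A 1.7 nm bump of 16 nm FWHM measures back within 1%."""
        truth = MapTruth(
            n_particles=1,
            height_means=(1.7,),
            height_sds=(1e-9,),
            height_weights=(1.0,),
            diam_means=(16.0,),
            diam_sds=(1e-9,),
            diam_weights=(1.0,),
            roughness_sd=0.0,
            pixel_size=1.0,
        )
        grid, _ = gen_height_map(truth, size=(101, 101), seed=1)
        hm = HeightMap(grid, 1.0)
        p = measure_particle(hm, detect_particles(hm, 0.5, 6.0)[0])
        assert p.protrusion_height == pytest.approx(1.7, rel=0.01)
        assert p.fwhm_diameter == pytest.approx(16.0, rel=0.01)

    def test_fwhm_independent_of_amplitude(self):
        widths = []
        for h in (0.8, 1.7, 3.4):
            hm = HeightMap(gaussian_bump_map(h=h, fwhm=12.0), 1.0)
            p = measure_particle(hm, (50, 50))
            widths.append(p.fwhm_diameter)
        assert max(widths) - min(widths) < 0.05

    def test_subpixel_fwhm_on_coarse_grid(self):
        # sigma_g = 3 nm on a 1 nm grid: FWHM = 7.06 nm within one pixel
        fwhm_true = 2.354820045 * 3.0
        hm = HeightMap(gaussian_bump_map(h=2.0, fwhm=fwhm_true), 1.0)
        p = measure_particle(hm, (50, 50))
        assert p.fwhm_diameter == pytest.approx(fwhm_true, abs=1.0)

    def test_rotation_invariance(self):
        grid = gaussian_bump_map(h=2.0, fwhm=14.0, center=(47, 55))
        hm = HeightMap(grid, 1.0)
        p0 = measure_particle(hm, detect_particles(hm, 0.5, 6)[0])
        hm90 = HeightMap(np.rot90(grid).copy(), 1.0)
        p90 = measure_particle(hm90, detect_particles(hm90, 0.5, 6)[0])
        assert p90.fwhm_diameter == pytest.approx(p0.fwhm_diameter, rel=0.02)

    def test_edge_particle_skipped_with_warning(self):
        grid = gaussian_bump_map(h=2.0, fwhm=16.0, center=(3, 50))
        hm = HeightMap(grid, 1.0)
        with pytest.warns(UserWarning):
            assert measure_particle(hm, (3, 50)) is None


class TestFitModes:
    def test_degenerate_single_component(self):
        mf = fit_modes(np.full(50, 2.5), k=1, seed=0)
        assert mf.means[0] == pytest.approx(2.5, abs=1e-6)
        assert mf.sds[0] < 1e-3

    def test_two_height_populations_recovered(self):
        rng = np.random.default_rng(1)
        h = np.concatenate([rng.normal(1.1, 0.5, 2000), rng.normal(2.8, 1.2, 2000)])
        mf = fit_modes(h, k=2, seed=0)
        assert mf.means[0] == pytest.approx(1.1, abs=0.2)
        assert mf.means[1] == pytest.approx(2.8, abs=0.2)
        assert np.sum(mf.weights) == pytest.approx(1.0, abs=1e-9)

    def test_three_diameter_populations_recovered(self):
        rng = np.random.default_rng(1)
        d = np.concatenate(
            [
                rng.normal(8.6, 0.4, 200),
                rng.normal(14.1, 0.3, 200),
                rng.normal(23.4, 1.2, 200),
            ]
        )
        mf = fit_modes(d, k=3, seed=0)
        np.testing.assert_allclose(mf.means, [8.6, 14.1, 23.4], atol=0.5)

    def test_requires_enough_samples(self):
        with pytest.raises(ValueError):
            fit_modes(np.arange(15), k=2, seed=0)

    def test_em_log_likelihood_nondecreasing(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(1.1, 0.5, 300), rng.normal(2.8, 1.2, 300)])
        trace = em_log_likelihood_trace(x, k=2, seed=0)
        assert np.all(np.diff(trace) >= -1e-10)


class TestOrientation:
    @pytest.mark.parametrize(
        "height,expected",
        [
            (1.7, "extracellular_up"),
            (3.1, "intracellular_up"),
            (1.75, "intracellular_up"),  # boundary goes to the upper class
        ],
    )
    def test_threshold_calls(self, height, expected):
        assert classify_orientation(height) == expected


class TestOverlayEvents:
    def make_particles(self, n, rng, low=1.0, high=3.0):
        rows = rng.uniform(20, 480, n)
        cols = rng.uniform(20, 480, n)
        heights = np.where(np.arange(n) % 2 == 0, low, high)
        return pd.DataFrame(
            {
                "id": np.arange(n),
                "row": rows,
                "col": cols,
                "height_nm": heights,
                "fwhm_nm": np.full(n, 14.0),
                "orientation": [classify_orientation(h) for h in heights],
            }
        )

    def test_perfectly_sorted_field_gives_full_concordance(self, rng):
        particles = self.make_particles(40, rng)
        events = gen_multiplex_events(particles, consistency=1.0, seed=0)
        _, summary = overlay_events(particles, events, pixel_size=1.0)
        assert summary["concordance"] == pytest.approx(1.0)
        assert summary["n_unassigned"] == 0

    def test_partial_consistency_within_binomial_error(self, rng):
        particles = self.make_particles(400, rng)
        events = gen_multiplex_events(particles, consistency=0.95, seed=1)
        _, summary = overlay_events(particles, events, pixel_size=1.0)
        assert summary["concordance"] == pytest.approx(0.95, abs=0.03)

    def test_no_events_is_not_an_error(self, rng):
        particles = self.make_particles(10, rng)
        table, summary = overlay_events(particles, {"ligand": [], "his_tag": []})
        assert len(table) == 0
        assert np.isnan(summary["concordance"])

    def test_far_event_tallied_unassigned(self, rng):
        particles = self.make_particles(5, rng)
        events = {"ligand": [(900, 900)]}
        table, summary = overlay_events(particles, events, pixel_size=1.0)
        assert summary["n_unassigned"] == 1
        assert len(table) == 0


class TestMapIO:
    def test_csv_round_trip(self, tmp_path, rng):
        hm = HeightMap(rng.normal(0, 0.1, (40, 40)), pixel_size=2.0)
        write_height_map(hm, tmp_path / "m.csv")
        back = read_height_map(tmp_path / "m.csv")
        np.testing.assert_allclose(back.grid, hm.grid, atol=1e-4)
        assert back.pixel_size == 2.0

    def test_tiff_round_trip(self, tmp_path, rng):
        hm = HeightMap(rng.normal(0, 0.1, (40, 40)), pixel_size=1.5)
        write_height_map(hm, tmp_path / "m.tif")
        back = read_height_map(tmp_path / "m.tif")
        np.testing.assert_allclose(back.grid, hm.grid, atol=1e-5)
        assert back.pixel_size == 1.5
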
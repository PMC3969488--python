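import math

import numpy as np
import pytest

from ramansizer.calibrate import size_areas
from ramansizer.core import read_spectrum_table, write_spectrum_table
from ramansizer.phantom import (
    PhantomSpec,
    default_library,
    generate,
    preset,
    truth_section_summary,
)
from ramansizer.preprocess import band_image, second_derivative_map
from ramansizer.segment import KSigmaBinarizer


class TestComponentLibrary:
    def test_library_contents(self):
        lib = default_library()
        names = {c.name for c in lib}
        assert len(lib) >= 4
        assert "polystyrene_analog" in names and "ebastine_analog" in names
        # a crowding band near 1620 must exist among the excipients
        excipients = [c for c in lib if "analog" in c.name and "poly" not in c.name
                      and "ebastine" not in c.name]
        centers = [ctr for c in excipients for ctr, _, _ in c.peaks]
        assert any(1610 <= c <= 1640 for c in centers)

    def test_particle_band_dominates_on_pure_pixel(self):
        """The flipped second derivative at 1,605 cm^-1 of a pure particle
        spectrum exceeds that of any pure excipient spectrum."""
        lib = {c.name: c for c in default_library()}
        wn = np.arange(1400.0, 1801.0, 2.0)

        def band_value(comp):
            from ramansizer.core import HyperMap

            cube = comp.evaluate(wn).reshape(1, 1, -1)
            dmap = second_derivative_map(HyperMap(cube, wn, 1.0))
            return band_image(dmap, 1605.0).values[0, 0]

        ps_val = band_value(lib["polystyrene_analog"])
        for name, comp in lib.items():
            if name != "polystyrene_analog":
                assert band_value(comp) < ps_val

    def test_spectra_round_trip_csv(self, tmp_path):
        wn = np.arange(1400.0, 1801.0, 2.0)
        for comp in default_library():
            path = tmp_path / f"{comp.name}.csv"
            write_spectrum_table(comp.as_spectrum(wn), path)
            back = read_spectrum_table(path)
            np.testing.assert_allclose(back.intensities, comp.evaluate(wn))

    def test_invalid_peaks_rejected(self):
        from ramansizer.phantom import ComponentSpectrum

        with pytest.raises(ValueError):
            ComponentSpectrum("bad", peaks=((1605.0, -1.0, 10.0),))


class TestPhantomSpec:
    def test_axis_must_cover_band_with_margin(self):
        with pytest.raises(ValueError, match="15 channels"):
            PhantomSpec(wn_start=1595.0, wn_stop=1800.0)

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            PhantomSpec(target_area_fraction=1.5)

    def test_thin_axis_keeps_other_fields(self):
        spec = preset("ps15", seed=3, thin_axis=True)
        assert spec.particle_diameter_mean == 15.8
        assert spec.wn_start == 1400.0 and spec.wn_stop == 1800.0


class TestGenerate:
    def test_seeded_determinism_bitwise(self):
        spec = preset("ps10", seed=11, thin_axis=True)
        m1, t1 = generate(spec)
        m2, t2 = generate(spec)
        np.testing.assert_array_equal(m1.intensities, m2.intensities)
        assert t1.disks == t2.disks
        np.testing.assert_array_equal(t1.fraction_map, t2.fraction_map)

    def test_different_seeds_differ(self):
        m1, _ = generate(preset("ps10", seed=1, thin_axis=True))
        m2, _ = generate(preset("ps10", seed=2, thin_axis=True))
        assert not np.array_equal(m1.intensities, m2.intensities)

    def test_single_disk_closed_control(self):
        """Noise- and halo-free single 10-um disk: the pipeline at k = 0.5
        finds exactly one particle within a pixel of the true diameter."""
        spec = PhantomSpec(
            seed=0,
            target_area_fraction=math.pi * 25.0 / 10000.0 * 0.999,
            particle_diameter_mean=10.0,
            particle_diameter_sd=1e-9,
            noise_sd=0.0,
            halo_strength=0.0,
            wn_start=1400.0,
            wn_stop=1800.0,
        )
        hmap, truth = generate(spec)
        assert len(truth.disks) == 1
        pooled = size_areas([hmap], 1605.0, k=0.5)
        assert pooled.total_particles == 1
        assert abs(pooled.pooled_mean - 10.0) <= 1.0

    def test_truth_mean_matches_certificate_within_sampling_error(self):
        # 10-um preset: truth mean within 2 sd/sqrt(n) of 9.8 um
        _, truth = generate(preset("ps10", seed=5, thin_axis=True))
        d = truth.diameters
        assert abs(d.mean() - 9.8) <= 2.0 * 1.0 / math.sqrt(d.size) + 0.05

    def test_unreachable_area_fraction_errors(self):
        spec = PhantomSpec(
            rows=20,
            cols=20,
            target_area_fraction=0.9,
            particle_diameter_mean=10.0,
            particle_diameter_sd=0.5,
            wn_start=1400.0,
            wn_stop=1800.0,
        )
        with pytest.raises(RuntimeError, match="fraction"):
            generate(spec)

    def test_band_image_peaks_inside_a_particle(self, ps10_phantom):
        hmap, truth = ps10_phantom
        img = band_image(second_derivative_map(hmap), 1605.0)
        iy, ix = np.unravel_index(np.argmax(img.values), img.values.shape)
        assert truth.fraction_map[iy, ix] > 0.5

    def test_excipient_only_phantom_nearly_empty_mask(self):
        """With no particles, mean + 0.5 sigma keeps (almost) nothing: the
        histogram's right tail is the particle signature."""
        spec = PhantomSpec(
            seed=3, target_area_fraction=0.0, wn_start=1400.0, wn_stop=1800.0
        )
        hmap, truth = generate(spec)
        assert len(truth.disks) == 0
        img = band_image(second_derivative_map(hmap), 1605.0)
        mask = KSigmaBinarizer(k=0.5).fit_binarize(img)
        assert mask.area_percent < 1.0

    def test_agglomerates_share_ids(self):
        spec = preset("ps10", seed=9, thin_axis=True, agglomeration_prob=0.9)
        _, truth = generate(spec)
        ids = [a for *_, a in truth.disks if a is not None]
        assert ids, "high agglomeration probability must produce agglomerates"
        # at least one id shared by >= 2 disks
        assert any(ids.count(i) >= 2 for i in set(ids))

    def test_halo_only_outside_particles(self, ps10_phantom):
        hmap, truth = ps10_phantom
        # signal inside particles dominates; fraction_map stays geometric
        assert truth.fraction_map.max() <= 1.0
        assert truth.fraction_map.min() >= 0.0


def test_tenfold_noise_degrades_recovery_in_expectation():
    """Raising detector noise 10x worsens the mean absolute recovery error
    (spurious above-threshold pixels enter the particle statistics)."""
    errors = {}
    for noise in (8.0, 80.0):
        errs = []
        for s in range(3):
            hmap, gt = generate(
                preset("ps10", seed=600 + s, thin_axis=True, noise_sd=noise)
            )
            pooled = size_areas([hmap], 1605.0, k=0.5)
            truth = truth_section_summary(gt).mean_diameter
            errs.append(abs(100.0 * pooled.pooled_mean / truth - 100.0))
        errors[noise] = np.mean(errs)
    assert errors[80.0] > errors[8.0]


class TestTruthSummary:
    def test_single_disk_count(self):
        spec = PhantomSpec(
            seed=0,
            target_area_fraction=math.pi * 25.0 / 10000.0 * 0.999,
            particle_diameter_mean=10.0,
            particle_diameter_sd=1e-9,
            wn_start=1400.0,
            wn_stop=1800.0,
        )
        _, truth = generate(spec)
        s = truth_section_summary(truth)
        assert s.particle_count == 1
        assert s.std_diameter == 0.0

    def test_truth_area_consistent_with_fraction_map(self, ps10_phantom):
        _, truth = ps10_phantom
        s = truth_section_summary(truth)
        # coverage-map mean equals sum(pi d^2/4)/image area up to the
        # supersampling discretisation (disks may also touch in agglomerates)
        assert s.area_percent == pytest.approx(
            100.0 * truth.fraction_map.mean(), abs=0.5
        )

    def test_threshold_zero_segmentation_recovers_truth(self):
        """Noise/halo-free phantom segmented at threshold ~0 matches the
        truth summary to about a pixel per particle."""
        spec = preset(
            "ps15", seed=21, thin_axis=True, noise_sd=0.0, halo_strength=0.0,
            agglomeration_prob=0.0,
        )
        hmap, truth = generate(spec)
        img = band_image(second_derivative_map(hmap), 1605.0)
        from ramansizer.segment import binarize
        from ramansizer.sizing import label_particles, summarize

        mask = binarize(img, 0.05 * img.values.max())
        s = summarize(label_particles(mask))
        t = truth_section_summary(truth)
        assert s.particle_count == t.particle_count
        assert abs(s.mean_diameter - t.mean_diameter) <= 1.0
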
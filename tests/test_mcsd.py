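import numpy as np
import pytest

from funduslab.errors import ConfigError, InputError
from funduslab.imaging import GrayImage
from funduslab.mcsd import (ContrastField, MCSDParams, Mode, Polarity,
                            derive_vessel_mask, directional_contrast_stack,
                            directional_profile_contrast,
                            extract_candidate_regions, multiscale_blob_field,
                            region_from_mask, shape_descriptor_field)
from funduslab.synthetic import make_disc_image, make_line_disc_scene

from conftest import flat_gray


def brute_force_field(gray, d, params):
    """Per-pixel loop over the single-ray oracle; the reference for the
    vectorized field computation."""
    h, w = gray.shape
    out = np.zeros((h, w))
    angles = params.angles()
    for r in range(h):
        for c in range(w):
            if not gray.fov[r, c]:
                continue
            cs = [directional_profile_contrast(gray, (r, c), d, t)
                  for t in angles]
            if params.mode is Mode.BLOB:
                if params.polarity is Polarity.DARK:
                    out[r, c] = max(0.0, min(cs))
                else:
                    out[r, c] = max(0.0, -max(cs))
            else:
                out[r, c] = max(0.0, max(cs))
    return out


class TestParams:
    @pytest.mark.parametrize("kw", [{"scales": ()}, {"scales": (1, 5)},
                                    {"n_directions": 3},
                                    {"n_directions": 7}])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ConfigError):
            MCSDParams(**kw)


class TestDirectionalProfile:
    def test_flat_field_gives_zero(self):
        g = flat_gray()
        for theta in (0.0, 1.1, 3.9):
            assert directional_profile_contrast(g, (32, 32), 8, theta) == 0.0

    def test_dark_disc_center_positive_all_directions(self):
        g, _ = make_disc_image((64, 64), 0.2, 0.7, 2.0)
        vals = [directional_profile_contrast(g, (32, 32), 10, t)
                for t in MCSDParams().angles()]
        assert min(vals) > 0
        # most of each 10-sample ray lies outside the radius-2 disc
        assert min(vals) > 0.5 * (0.7 - 0.2)

    def test_bright_spot_gives_negative_contrast(self):
        g, _ = make_disc_image((64, 64), 0.9, 0.4, 2.0)
        assert directional_profile_contrast(g, (32, 32), 10, 0.0) < 0


class TestFieldOracleEquivalence:
    @pytest.mark.parametrize("mode,polarity", [
        (Mode.BLOB, Polarity.DARK), (Mode.BLOB, Polarity.BRIGHT),
        (Mode.LINEAR, Polarity.DARK)])
    def test_field_matches_per_pixel_loop(self, mode, polarity):
        rng = np.random.default_rng(11)
        px = rng.random((24, 24))
        fov = np.zeros((24, 24), bool)
        fov[8:16, 8:16] = True
        g = GrayImage(px, fov)
        params = MCSDParams(scales=(5,), n_directions=8, mode=mode,
                            polarity=polarity)
        fld = shape_descriptor_field(g, 5, params)
        ref = brute_force_field(g, 5, params)
        assert np.abs(fld.values - ref).max() < 1e-9


class TestBlobVsLinear:
    def test_disc_strong_line_suppressed_in_blob_mode(self):
        g, center, line = make_line_disc_scene(seed=3, noise_sigma=0.0)
        params = MCSDParams()
        stacks = directional_contrast_stack(g, params.scales, 16)
        blob = multiscale_blob_field(g, params, 0.0, stacks).values
        assert blob[center] > 0.15
        assert blob[line & g.fov].max() < blob[center] / 3

    def test_linear_mode_fires_on_the_line(self):
        g, _center, line = make_line_disc_scene(seed=3, noise_sigma=0.0)
        from funduslab.mcsd import multiscale_field
        params = MCSDParams(mode=Mode.LINEAR)
        lin = multiscale_field(g, params, 0.0).values
        assert lin[line & g.fov].min() > 0.05

    def test_rotation_by_90_degrees_is_exact(self):
        g, mask = make_disc_image((64, 64), 0.25, 0.6, 3.0, center=(25, 40))
        params = MCSDParams(scales=(5,), n_directions=16)
        f1 = shape_descriptor_field(g, 5, params).values
        g2 = GrayImage(np.rot90(g.pixels).copy(), np.rot90(g.fov).copy())
        f2 = shape_descriptor_field(g2, 5, params).values
        np.testing.assert_allclose(np.rot90(f1), f2, atol=1e-9)

    def test_center_response_monotone_in_contrast(self):
        prev = -1.0
        params = MCSDParams()
        for contrast in (0.05, 0.15, 0.25, 0.35):
            g, _ = make_disc_image((64, 64), 0.6 - contrast, 0.6, 2.5)
            v = multiscale_blob_field(g, params, 0.0).values[32, 32]
            assert v >= prev
            prev = v


class TestVesselMask:
    def test_line_centerline_covered_background_clean(self):
        g, _c, line = make_line_disc_scene(seed=5, noise_sigma=0.0)
        mask = derive_vessel_mask(g, MCSDParams())
        center_cover = mask[line & g.fov].mean()
        assert center_cover >= 0.90
        bg = g.fov & (g.pixels > 0.5)
        assert mask[bg].mean() < 0.01

    def test_flat_image_empty(self):
        assert not derive_vessel_mask(flat_gray(), MCSDParams()).any()

    def test_isolated_disc_not_marked_vessel(self):
        g, _ = make_disc_image((64, 64), 0.25, 0.55, 3.0)
        mask = derive_vessel_mask(g, MCSDParams())
        assert not mask[32, 32]


class TestExtractCandidates:
    def _field(self, values):
        return ContrastField(values=values, params=MCSDParams())

    def test_two_discs_two_regions_with_areas(self):
        v = np.zeros((40, 40))
        yy, xx = np.mgrid[0:40, 0:40]
        d1 = np.hypot(yy - 10, xx - 10) <= 3
        d2 = np.hypot(yy - 30, xx - 28) <= 5
        v[d1] = 0.2
        v[d2] = 0.3
        regs = extract_candidate_regions(self._field(v), flat_gray((40, 40)))
        assert len(regs) == 2
        assert sorted(r.area for r in regs) == sorted([int(d1.sum()),
                                                       int(d2.sum())])

    def test_diagonal_pair_is_one_region_8_connectivity(self):
        v = np.zeros((20, 20))
        v[5, 5] = v[6, 6] = 0.1
        regs = extract_candidate_regions(self._field(v), flat_gray((20, 20)))
        assert len(regs) == 1 and regs[0].area == 2

    def test_zero_field_and_min_area(self):
        assert extract_candidate_regions(self._field(np.zeros((10, 10))),
                                         flat_gray((10, 10))) == []
        v = np.zeros((10, 10))
        v[4, 4] = 0.5  # single pixel: below min_area=2
        assert extract_candidate_regions(self._field(v),
                                         flat_gray((10, 10))) == []

    def test_negative_field_rejected(self):
        with pytest.raises(InputError):
            fld = ContrastField(values=np.zeros((5, 5)), params=MCSDParams())
            fld.values[0, 0] = -1.0  # bypass constructor check
            extract_candidate_regions(fld, flat_gray((5, 5)))

    def test_deterministic_raster_order(self):
        v = np.zeros((30, 30))
        v[2:5, 20:23] = 0.1
        v[10:13, 2:5] = 0.1
        regs = extract_candidate_regions(self._field(v), flat_gray((30, 30)))
        assert regs[0].bbox[0] < regs[1].bbox[0]

    def test_interior_holes_filled(self):
        v = np.zeros((30, 30))
        yy, xx = np.mgrid[0:30, 0:30]
        ring = (np.hypot(yy - 15, xx - 15) <= 6) & (np.hypot(yy - 15, xx - 15) >= 4)
        v[ring] = 0.2
        regs = extract_candidate_regions(self._field(v), flat_gray((30, 30)))
        assert len(regs) == 1
        assert regs[0].area == int((np.hypot(yy - 15, xx - 15) <= 6).sum())


def test_region_from_mask_matches_extracted_geometry():
    v = np.zeros((40, 40))
    yy, xx = np.mgrid[0:40, 0:40]
    disc = np.hypot(yy - 20, xx - 20) <= 5
    v[disc] = 0.2
    extracted = extract_candidate_regions(
        ContrastField(values=v, params=MCSDParams()), flat_gray((40, 40)))[0]
    direct = region_from_mask(disc, Polarity.DARK)
    assert extracted.area == direct.area
    np.testing.assert_array_equal(np.sort(extracted.boundary, axis=0),
                                  np.sort(direct.boundary, axis=0))
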
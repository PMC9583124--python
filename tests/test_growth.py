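"""Growth kernel, plate influence, stepping, simulation, morphology."""

import numpy as np
import pytest

import morphocode as mc
from morphocode.growth import plate_influence


def direct_step(colony, kernel_values, mask, half_saturation=2.0):
    """Brute-force nested-sum evaluation of the update (oracle)."""
    n = colony.shape[0]
    kc = kernel_values.shape[0] // 2
    raw = np.zeros_like(colony)
    for y in range(n):
        for x in range(n):
            acc = 0.0
            for dy in range(-kc, kc + 1):
                for dx in range(-kc, kc + 1):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < n and 0 <= xx < n:
                        acc += kernel_values[kc + dy, kc + dx] * colony[yy, xx]
            raw[y, x] = max(acc, 0.0)
    out = raw / (half_saturation + raw)
    return np.where(mask, out, 0.0)


class TestKernel:
    def test_analytic_values_at_defaults(self):
        k = mc.build_kernel(mc.GrowthParams())  # b=6.5, d1=4, d2=10
        c = k.values.shape[0] // 2
        assert k.values[c, c] == pytest.approx(6.5 - 1.0)          # K(0) = b - 1
        assert k.values[c, c + 7] == pytest.approx(-1.0, abs=1e-9)  # d1 << 7 << d2
        assert abs(k.values[c, c + 12]) < 1e-9                      # d ~ 1.2 d2

    def test_kernel_is_radially_symmetric(self):
        v = mc.build_kernel(mc.GrowthParams()).values
        assert np.allclose(v, v.T)
        assert np.allclose(v, v[::-1, :])
        assert np.allclose(v, v[:, ::-1])

    def test_invalid_distances_rejected(self):
        with pytest.raises(ValueError):
            mc.GrowthParams(d1=10.0, d2=4.0)

    def test_noiseless_snr_returns_kernel_unchanged(self):
        k = mc.build_kernel(mc.GrowthParams())
        out = mc.sample_kernel_noise(k, None, np.random.default_rng(0))
        assert np.array_equal(out, k.values)

    def test_noise_std_matches_rms_over_snr(self):
        # Monte-Carlo check of the stated noise amplitude: pooled std of
        # (noisy - clean) over the support across many draws = RMS(K)/snr
        params = mc.GrowthParams(d1=1.6, d2=4.0)
        k = mc.build_kernel(params)
        rng = np.random.default_rng(1)
        snr = 3.5
        diffs = np.concatenate(
            [
                (mc.sample_kernel_noise(k, snr, rng) - k.values)[k.support]
                for _ in range(10_000)
            ]
        )
        assert diffs.std() == pytest.approx(k.rms / snr, rel=0.02)


class TestInfluence:
    def test_analytic_influence_values(self):
        assert plate_influence(0.0, R=64.0, k=1000.0, eps=1.0) == pytest.approx(-1000.0)
        assert plate_influence(64.0, R=64.0, k=1000.0, eps=1.0) == pytest.approx(-500.0)
        assert abs(plate_influence(32.0, R=64.0, k=1000.0, eps=2000.0)) < 1e-290

    def test_influence_field_monotone_toward_zero_with_distance(self):
        geom = mc.DomainGeometry("circle", field_side=128, eps=1.0)
        field = mc.boundary_influence_field(geom)
        inside = geom.mask
        d = geom.d_field[inside]
        i = field[inside]
        order = np.argsort(d)
        assert np.all(np.diff(i[order]) >= -1e-9)
        assert i.max() <= 0.0

    def test_degenerate_radius_rejected(self):
        with pytest.raises(ValueError):
            plate_influence(1.0, R=0.0)

    def test_equal_area_across_shapes(self):
        areas = {
            s: mc.DomainGeometry(s, field_side=128, area_fraction=0.5).mask.sum()
            for s in ("circle", "diamond", "square", "triangle")
        }
        ref = areas["circle"]
        for s, a in areas.items():
            assert abs(a - ref) / ref < 0.03, (s, a, ref)

    def test_oversized_shapes_rejected(self):
        with pytest.raises(ValueError, match="area_fraction"):
            mc.DomainGeometry("triangle", field_side=128)
        with pytest.raises(ValueError, match="area_fraction"):
            mc.DomainGeometry("diamond", field_side=128, area_fraction=0.9)


class TestStep:
    def test_zero_colony_stays_zero(self):
        geom = mc.DomainGeometry("circle", field_side=32)
        k = mc.build_kernel(mc.GrowthParams(d1=1.6, d2=4.0))
        out = mc.step(np.zeros((32, 32)), k.values, mask=geom.mask)
        assert not out.any()

    def test_fft_step_equals_direct_nested_sum(self):
        # FFT-based stepping against the brute-force double-sum oracle
        rng = np.random.default_rng(0)
        geom = mc.DomainGeometry("circle", field_side=32)
        colony = rng.random((32, 32)) * geom.mask
        k = mc.build_kernel(mc.GrowthParams(d1=1.6, d2=4.0))
        fast = mc.step(colony, k.values, mask=geom.mask)
        slow = direct_step(colony, k.values, geom.mask)
        assert np.abs(fast - slow).max() < 1e-8

    def test_shape_mismatch_rejected(self):
        k = mc.build_kernel(mc.GrowthParams(d1=1.6, d2=4.0))
        with pytest.raises(ValueError):
            mc.step(np.zeros((32, 32)), k.values, influence=np.zeros((16, 16)))

    def test_colonized_area_grows_from_a_seeded_disk(self):
        params, layout, geom, _ = mc.profiles.reduced(n_bits=1)
        field = mc.bits_to_seeding("1", layout, mc.SeedingNoise(enabled=False))
        k = mc.build_kernel(params)
        n = field.values.copy()
        areas = [(n > 0.05).sum()]
        for _ in range(10):
            n = mc.step(n, k.values, mask=geom.mask, half_saturation=params.half_saturation)
            areas.append((n > 0.05).sum())
        assert all(b >= a for a, b in zip(areas, areas[1:]))
        assert areas[-1] > areas[0]


class TestSimulate:
    def test_zero_seeding_terminates_immediately_all_zero(self):
        params, layout, geom, _ = mc.profiles.reduced()
        pat = mc.simulate(np.zeros((128, 128)), params, geom)
        assert not pat.pixels.any()
        assert pat.metadata["steps"] <= params.stop_patience + 1

    def test_identical_seed_gives_bit_identical_pattern(self, reduced_cfg):
        params, layout, geom, noise = reduced_cfg
        pats = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            f = mc.bits_to_seeding("10", layout, noise, rng)
            pats.append(mc.simulate(f, params, geom, rng))
        assert pats[0].pixels.tobytes() == pats[1].pixels.tobytes()

    def test_four_fold_symmetric_seeding_evolves_symmetrically(self):
        # The update is equivariant under 90-degree rotation, so a 4-fold
        # symmetric seeding stays symmetric.  Checked over a short horizon:
        # over long runs floating-point roundoff is chaotically amplified by
        # the pattern-forming instability and the symmetry breaks
        # spontaneously, as in any real pattern-forming system.
        params, layout, geom, _ = mc.profiles.reduced(n_bits=4)
        f = mc.bits_to_seeding("1111", layout, mc.SeedingNoise(enabled=False))
        assert np.allclose(f.values, np.rot90(f.values))
        kernel = mc.build_kernel(params)
        n = np.where(geom.mask, f.values, 0.0)
        for _ in range(8):
            n = mc.step(n, kernel.values, mask=geom.mask,
                        half_saturation=params.half_saturation)
        q = np.floor(255 * n + 0.5)
        assert np.abs(q - np.rot90(q)).max() <= 1

    def test_fields_bounded_and_zero_outside_domain(self, branching_pattern):
        pat, _ = branching_pattern
        geom = mc.DomainGeometry("circle", field_side=128)
        assert pat.pixels.min() >= 0 and pat.pixels.max() <= 255
        assert not pat.pixels[~geom.mask].any()

    def test_png_round_trip_preserves_pixels_and_metadata(self, branching_pattern, tmp_path):
        pat, _ = branching_pattern
        p = tmp_path / "pat.png"
        pat.save(p)
        back = mc.PatternImage.load(p)
        assert np.array_equal(back.pixels, pat.pixels)
        assert back.metadata["steps"] == pat.metadata["steps"]


class TestMorphology:
    def test_pattern_equal_to_seeding_is_trivial(self):
        layout = mc.SeedingLayout(n_bits=2, spacing=6, spot_radius=2, field_side=128)
        f = mc.bits_to_seeding("11", layout, mc.SeedingNoise(enabled=False))
        assert mc.classify_morphology(f.values, f.values) == "trivial"

    def test_fully_colonized_domain_is_disk(self):
        geom = mc.DomainGeometry("circle", field_side=128)
        full = geom.mask.astype(float)
        seed = np.zeros_like(full)
        seed[60:68, 60:68] = 0.5
        assert mc.classify_morphology(full, seed, geom) == "disk"

    def test_default_parameters_give_branching(self, branching_pattern):
        pat, field = branching_pattern
        geom = mc.DomainGeometry("circle", field_side=128)
        assert mc.classify_morphology(pat, field, geom) == "branching"

    def test_phase_directions(self):
        # stronger, longer-ranged expansion -> disk; collapsed expansion
        # range -> the colony never leaves its seeds (trivial)
        _, layout, geom, _ = mc.profiles.reduced(n_bits=4)
        f = mc.bits_to_seeding("1011", layout, mc.SeedingNoise(enabled=False))
        disk_params = mc.GrowthParams(b=10.0, d1=2.2, d2=4.0, max_steps=120)
        pat = mc.simulate(f, disk_params, geom)
        assert mc.classify_morphology(pat, f, geom) == "disk"
        collapsed = mc.GrowthParams(d1=0.6, d2=1.5, max_steps=120)
        pat = mc.simulate(f, collapsed, geom)
        assert mc.classify_morphology(pat, f, geom) == "trivial"


class TestCrop:
    def test_huge_radius_is_identity_inside_domain(self, branching_pattern):
        pat, _ = branching_pattern
        out = mc.crop_center(pat, crop_radius=1000.0)
        assert np.array_equal(out.pixels, pat.pixels)

    def test_crop_of_zero_pattern_is_zero(self):
        z = mc.PatternImage(np.zeros((128, 128), np.uint8))
        assert not mc.crop_center(z, 40.0).pixels.any()

    def test_same_crop_mask_regardless_of_domain_shape(self):
        params, layout, _, _ = mc.profiles.reduced(n_bits=2)
        f = mc.bits_to_seeding("11", layout, mc.SeedingNoise(enabled=False))
        outs = {}
        for shape in ("circle", "square"):
            geom = mc.DomainGeometry(shape, field_side=128)
            outs[shape] = mc.crop_center(mc.simulate(f, params, geom), 40.0)
        yy, xx = np.mgrid[0:128, 0:128]
        outside = np.hypot(yy - 63.5, xx - 63.5) > 40.0 + 1
        for shape, out in outs.items():
            assert not out.pixels[outside].any(), shape

    def test_nonpositive_radius_rejected(self, branching_pattern):
        with pytest.raises(ValueError):
            mc.crop_center(branching_pattern[0], 0.0)
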
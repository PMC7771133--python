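import math

import numpy as np
import pytest

from nsc import (
    DistanceSpec,
    NscLocus,
    SegmentBrightness,
    SegmentPartition,
    Spectrum,
    WavelengthGrid,
    brightness,
    builtin_illuminant,
    endler_achromatic_distance,
    endler_chromatic_distance,
    endler_locus,
    nsc_distance,
    nsc_locus,
    nsc_locus_from_brightness,
    radiance,
    segment_relative_brightness,
    white_standard_brightness,
)
from nsc.datasets import _load_table
from nsc.synthetic_spectra import SpectrumRecipe, generate

from conftest import tally_segment_brightness


def flat_radiance(grid, level=1.0):
    return Spectrum(grid, np.full(grid.n_samples, level), "radiance")


class TestPartition:
    def test_boundaries(self, partition):
        assert np.allclose(partition.boundaries, [300, 400, 500, 600, 700])

    def test_tetrachromat_boundaries(self):
        p = SegmentPartition(300, 700, 4)
        assert np.allclose(p.boundaries, [300, 380, 460, 540, 620, 700])

    def test_invalid(self):
        with pytest.raises(ValueError):
            SegmentPartition(700, 300, 3)
        with pytest.raises(ValueError):
            SegmentPartition(300, 700, 1)


class TestBrightness:
    def test_flat_full_range_1nm(self, grid):
        assert brightness(flat_radiance(grid), 300, 700, closed_right=True) == 401

    def test_flat_full_range_5nm(self, grid5):
        assert brightness(flat_radiance(grid5), 300, 700, closed_right=True) == 81

    def test_segment_additivity(self, grid, partition):
        rng = np.random.default_rng(42)
        l = Spectrum(grid, rng.uniform(0, 2, grid.n_samples), "radiance")
        bounds = partition.boundaries
        per_segment = sum(
            brightness(l, bounds[i], bounds[i + 1], closed_right=(i == 3))
            for i in range(4)
        )
        total = brightness(l, 300, 700, closed_right=True)
        assert per_segment == pytest.approx(total, rel=1e-14)

    def test_empty_segment_error(self, grid5):
        with pytest.raises(ValueError, match="empty"):
            brightness(flat_radiance(grid5), 301, 304)

    def test_outside_range_error(self, grid):
        with pytest.raises(ValueError, match="range"):
            brightness(flat_radiance(grid), 200, 700)

    def test_bad_interval(self, grid):
        with pytest.raises(ValueError):
            brightness(flat_radiance(grid), 500, 400)


class TestWhiteStandardBrightness:
    def test_flat_illuminant(self, grid, partition, flat_illuminant):
        assert white_standard_brightness(flat_illuminant, partition) == 401

    def test_equals_radiance_of_perfect_reflector(self, grid, partition, d65):
        r = Spectrum(grid, np.ones(grid.n_samples), "reflectance")
        direct = white_standard_brightness(d65, partition)
        via_radiance = brightness(radiance(r, d65), 300, 700, closed_right=True)
        assert direct == via_radiance

    def test_d65_bin_width_ratio(self, partition):
        # independent oracle: plain sums over the embedded tables
        t1 = _load_table("d65_energy_1nm.csv")
        t5 = _load_table("d65_energy_5nm.csv")
        in_range1 = t1[(t1.wavelength >= 300) & (t1.wavelength <= 700)]
        in_range5 = t5[(t5.wavelength >= 300) & (t5.wavelength <= 700)]
        expected_ratio = in_range1.d65.sum() / in_range5.d65.sum()

        d1 = builtin_illuminant("d65", grid=WavelengthGrid(300, 700, 1), units="energy")
        d5 = builtin_illuminant("d65", grid=WavelengthGrid(300, 700, 5), units="energy")
        ratio = white_standard_brightness(d1, partition) / white_standard_brightness(
            d5, partition
        )
        assert ratio == pytest.approx(expected_ratio, rel=1e-12)
        assert ratio == pytest.approx(5.0, rel=0.01)


class TestSegmentRelativeBrightness:
    def test_flat_spectrum_near_quarter(self, grid, partition):
        sb = segment_relative_brightness(flat_radiance(grid), partition)
        # 101 samples in the closed final segment, 100 in the half-open others
        assert np.allclose(sb.S, [100 / 401, 100 / 401, 100 / 401, 101 / 401])
        assert sb.S.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(sb.S, 0.25, atol=0.005)

    def test_point_support_fourth_segment(self, grid, partition):
        vals = np.zeros(grid.n_samples)
        vals[grid.wavelengths >= 650] = 2.0
        sb = segment_relative_brightness(Spectrum(grid, vals, "radiance"), partition)
        assert np.allclose(sb.S, [0, 0, 0, 1])

    def test_step_at_boundary_matches_tally_oracle(self, grid, partition):
        # hard step exactly at the 500 nm segment boundary
        step = generate(SpectrumRecipe("step", center=500.0), grid)
        l = Spectrum(grid, step.values, "radiance")
        sb = segment_relative_brightness(l, partition)
        oracle = tally_segment_brightness(l, partition)
        assert np.array_equal(sb.S, oracle)
        # sample at exactly 500 nm belongs to the third (half-open) segment
        assert sb.S[:2] == pytest.approx([0, 0])
        assert sb.S[2] == pytest.approx(100 / 201)
        assert sb.S[3] == pytest.approx(101 / 201)

    def test_random_spectra_match_tally_oracle(self, grid, partition):
        rng = np.random.default_rng(7)
        for _ in range(5):
            l = Spectrum(grid, rng.uniform(0, 1, grid.n_samples), "radiance")
            sb = segment_relative_brightness(l, partition)
            assert np.array_equal(sb.S, tally_segment_brightness(l, partition))

    def test_all_black_error(self, grid, partition):
        with pytest.raises(ValueError, match="undefined chromatic"):
            segment_relative_brightness(
                Spectrum(grid, np.zeros(grid.n_samples), "radiance"), partition
            )

    def test_beta_m_with_illuminant(self, grid, partition, flat_illuminant):
        sb = segment_relative_brightness(
            flat_radiance(grid, 0.5), partition, d=flat_illuminant
        )
        assert sb.beta == pytest.approx(0.5 * 401)
        assert sb.beta_m == 401


def make_sb(S, beta=1.0, beta_m=None):
    return SegmentBrightness(S=np.asarray(S, dtype=float), beta=beta, beta_m=beta_m)


class TestEndlerLocus:
    def test_worked_example_first_branch(self, partition):
        locus = endler_locus(make_sb([0.1, 0.2, 0.3, 0.4]), partition)
        assert locus.X1 == pytest.approx(math.sqrt(0.08), abs=1e-12)
        assert locus.X1 == pytest.approx(0.28284, abs=5e-6)
        assert locus.X2 == pytest.approx(math.pi / 4, abs=1e-12)

    def test_achromatic_point(self, partition):
        locus = endler_locus(make_sb([0.25, 0.25, 0.25, 0.25], beta=7.0), partition)
        assert locus.X1 == 0
        assert locus.X2 == 0
        assert not locus.hue_defined
        assert locus.X3 == 7.0

    def test_worked_example_third_branch(self, partition):
        locus = endler_locus(make_sb([0.4, 0.3, 0.2, 0.1]), partition)
        assert locus.X2 == pytest.approx(math.pi + math.pi / 4, abs=1e-12)

    def test_second_branch_wraps_positive(self, partition):
        # R > G but Y < B: angle in [3*pi/2, 2*pi)
        locus = endler_locus(make_sb([0.4, 0.1, 0.2, 0.3]), partition)
        assert 1.5 * math.pi <= locus.X2 < 2 * math.pi

    def test_requires_trichromat(self):
        p4 = SegmentPartition(300, 700, 4)
        with pytest.raises(ValueError, match="trichromatic"):
            endler_locus(make_sb([0.2, 0.2, 0.2, 0.2, 0.2]), p4)

    def test_chroma_bound(self, partition):
        rng = np.random.default_rng(3)
        for _ in range(200):
            S = rng.dirichlet(np.ones(4))
            locus = endler_locus(make_sb(S), partition)
            assert 0 <= locus.X1 <= math.sqrt(2) + 1e-12


class TestEndlerDistances:
    def test_identity(self, partition):
        a = endler_locus(make_sb([0.1, 0.2, 0.3, 0.4]), partition)
        assert endler_chromatic_distance(a, a) == 0

    def test_antipodal(self, partition):
        a = endler_locus(make_sb([0.1, 0.2, 0.3, 0.4]), partition)
        b = endler_locus(make_sb([0.4, 0.3, 0.2, 0.1]), partition)
        # opposite chromatic vectors with equal chroma c -> distance 2c
        assert a.X2 - b.X2 == pytest.approx(-math.pi)
        assert endler_chromatic_distance(a, b) == pytest.approx(2 * a.X1, abs=1e-12)

    def test_achromatic_distance(self, partition):
        a = endler_locus(make_sb([0.1, 0.2, 0.3, 0.4], beta=10.0), partition)
        b = endler_locus(make_sb([0.1, 0.2, 0.3, 0.4], beta=4.0), partition)
        assert endler_achromatic_distance(a, b) == 6.0


class TestNscLocus:
    def test_white_under_flat_illuminant(self, grid, partition, flat_illuminant):
        r = Spectrum(grid, np.ones(grid.n_samples), "reflectance")
        locus = nsc_locus(radiance(r, flat_illuminant), flat_illuminant, partition)
        # half-open convention puts one extra sample in the last segment
        assert np.allclose(locus.chromatic, [1 / 401, 0.0], atol=1e-12)
        assert np.allclose(locus.chromatic, 0, atol=0.003)
        assert locus.achromatic == pytest.approx(1.0, abs=1e-12)

    def test_worked_example_standard(self, partition):
        sb = make_sb([0.1, 0.2, 0.3, 0.4], beta=0.5, beta_m=1.0)
        locus = nsc_locus_from_brightness(sb, partition, "standard")
        assert np.allclose(locus.Z, [0.2, 0.2, 0.5], atol=1e-15)

    def test_worked_example_normalized(self, partition):
        # 2*(R-G)/(R+G) = 0.4/0.6, 2*(Y-B)/(Y+B) = 0.4/0.4
        sb = make_sb([0.1, 0.2, 0.3, 0.4], beta=0.5, beta_m=1.0)
        locus = nsc_locus_from_brightness(sb, partition, "chromatic-normalized")
        assert np.allclose(locus.Z, [2 / 3, 1.0, 0.5], atol=1e-12)

    def test_tetrachromat_shape(self, grid):
        p4 = SegmentPartition(300, 700, 4)
        d = builtin_illuminant("flat", grid=grid)
        r = generate(SpectrumRecipe("sigmoid", center=550, width=30), grid)
        locus = nsc_locus(radiance(r, d), d, p4)
        assert len(locus.Z) == 4
        assert len(locus.chromatic) == 3

    def test_trichromat_reduction(self, grid, partition, flat_illuminant):
        # n=3 chromatic coordinates are exactly S3-S1 and S4-S2
        r = generate(SpectrumRecipe("sigmoid", center=550, width=30), grid)
        l = radiance(r, flat_illuminant)
        sb = segment_relative_brightness(l, partition)
        locus = nsc_locus(l, flat_illuminant, partition)
        assert locus.Z[0] == pytest.approx(sb.S[3] - sb.S[1], abs=1e-15)  # R - G
        assert locus.Z[1] == pytest.approx(sb.S[2] - sb.S[0], abs=1e-15)  # Y - B

    def test_normalized_denominator_guard(self, partition):
        # R + G = S4 + S2 = 0 -> Z1 undefined
        sb = make_sb([0.5, 0.0, 0.5, 0.0], beta=1.0, beta_m=2.0)
        with pytest.raises(ValueError, match="Z1"):
            nsc_locus_from_brightness(sb, partition, "chromatic-normalized")

    def test_missing_beta_m(self, partition):
        with pytest.raises(ValueError, match="beta_m"):
            nsc_locus_from_brightness(make_sb([0.25] * 4), partition)

    def test_unknown_variant(self, partition):
        sb = make_sb([0.25] * 4, beta=1.0, beta_m=2.0)
        with pytest.raises(ValueError, match="variant"):
            nsc_locus_from_brightness(sb, partition, "polar")


class TestNscDistance:
    def test_identity(self, partition):
        a = NscLocus(np.array([0.1, -0.2, 0.4]), "standard", partition)
        for alpha in (0.0, 0.5, 1.0, 4.0):
            assert nsc_distance(a, a, DistanceSpec(alpha)) == 0

    def test_worked_example(self, partition):
        a = NscLocus(np.array([0.2, 0.2, 0.9]), "standard", partition)
        b = NscLocus(np.array([0.2, 0.2, 0.4]), "standard", partition)
        assert nsc_distance(a, b, DistanceSpec(1.0)) == pytest.approx(0.5)
        assert nsc_distance(a, b, DistanceSpec(0.0)) == 0.0

    def test_alpha_scales_achromatic_axis(self, partition):
        a = NscLocus(np.array([0.0, 0.0, 0.3]), "standard", partition)
        b = NscLocus(np.array([0.0, 0.0, 0.1]), "standard", partition)
        assert nsc_distance(a, b, DistanceSpec(4.0)) == pytest.approx(2 * 0.2)

    def test_mismatched_variant_error(self, partition):
        a = NscLocus(np.array([0.1, 0.1, 0.5]), "standard", partition)
        b = NscLocus(np.array([0.1, 0.1, 0.5]), "chromatic-normalized", partition)
        with pytest.raises(ValueError, match="variant"):
            nsc_distance(a, b)

    def test_mismatched_partition_error(self, partition):
        other = SegmentPartition(310, 700, 3)
        a = NscLocus(np.array([0.1, 0.1, 0.5]), "standard", partition)
        b = NscLocus(np.array([0.1, 0.1, 0.5]), "standard", other)
        with pytest.raises(ValueError, match="partition"):
            nsc_distance(a, b)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            DistanceSpec(-0.5)
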
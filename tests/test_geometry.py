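"""Sphere/ellipsoid volumes, IE conversion factors, and binned totals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isletquant import (
    BinningScheme,
    IsletRecord,
    density_expectation_factor,
    ellipsoid_volume,
    endpoint_mean_factor,
    ie_binned,
    ie_exact,
    ie_total_exact,
    sphere_volume,
)
from conftest import CONVENTIONAL_FACTORS_3DP

diameters = st.floats(min_value=1.0, max_value=400.0)


class TestVolumes:
    @pytest.mark.parametrize(
        "d, expected",
        [(150.0, 1_767_146), (0.0, 0.0), (100.0, 523_599)],
    )
    def test_sphere_volume(self, d, expected):
        assert sphere_volume(d) == pytest.approx(expected, abs=0.5)

    def test_reference_volume_matches_1_77e6_to_3sf(self):
        assert round(sphere_volume(150.0), -4) == 1.77e6

    @pytest.mark.parametrize(
        "axes, expected",
        [
            ((150, 150, 150), 1_767_146),
            ((150, 0.82 * 150, 0.6 * 150), 869_436),  # mean oblate axis ratios
            ((150, 0, 150), 0.0),
        ],
    )
    def test_ellipsoid_volume(self, axes, expected):
        assert ellipsoid_volume(*axes) == pytest.approx(expected, abs=1.0)

    def test_negative_dimensions_rejected(self):
        with pytest.raises(ValueError):
            sphere_volume(-1)
        with pytest.raises(ValueError):
            ellipsoid_volume(10, -2, 5)

    @given(d=diameters)
    @settings(derandomize=True)
    def test_ellipsoid_reduces_to_sphere(self, d):
        assert ellipsoid_volume(d, d, d) == pytest.approx(sphere_volume(d))


class TestIeExact:
    @pytest.mark.parametrize("d, expected", [(150, 1.0), (75, 0.125), (300, 8.0)])
    def test_reference_points(self, d, expected):
        assert ie_exact(d) == pytest.approx(expected, rel=1e-12)

    @given(d=diameters)
    @settings(derandomize=True)
    def test_cubic_scaling(self, d):
        assert ie_exact(2 * d) == pytest.approx(8 * ie_exact(d), rel=1e-9)

    def test_strictly_increasing(self):
        grid = np.linspace(1, 400, 500)
        assert np.all(np.diff([ie_exact(d) for d in grid]) > 0)


class TestFactors:
    @pytest.mark.parametrize(
        "lo, hi, expected",
        [(150, 150, 1.0), (50, 100, 0.16667), (150, 200, 1.68519)],
    )
    def test_endpoint_mean(self, lo, hi, expected):
        assert endpoint_mean_factor(lo, hi) == pytest.approx(expected, abs=5e-6)

    def test_conventional_factor_table(self, conventional_scheme):
        derived = [round(f, 3) for f in conventional_scheme.factors]
        assert tuple(derived) == CONVENTIONAL_FACTORS_3DP

    @pytest.mark.parametrize(
        "lo, hi, density, expected",
        [
            (100, 200, 150.0, 1.0),  # point mass at the reference diameter
            (50, 100, None, 0.13889),  # uniform closed form
            (150, 200, None, 1.62037),
        ],
    )
    def test_density_expectation(self, lo, hi, density, expected):
        assert density_expectation_factor(lo, hi, density) == pytest.approx(
            expected, abs=5e-6
        )

    def test_callable_density_matches_uniform_closed_form(self):
        by_quad = density_expectation_factor(50, 100, lambda x: 1.0)
        assert by_quad == pytest.approx(density_expectation_factor(50, 100), rel=1e-9)

    def test_decreasing_density_corrects_below_uniform(self):
        decreasing = density_expectation_factor(50, 100, lambda x: 1.0 / x**2)
        assert decreasing < density_expectation_factor(50, 100)

    @given(
        lo=st.floats(min_value=10, max_value=300),
        width=st.floats(min_value=1.0, max_value=100),
    )
    @settings(derandomize=True)
    def test_uniform_expectation_below_endpoint_mean(self, lo, width):
        # strict convexity of d^3: the within-bin mean cube is below the
        # edge-cube average on every nondegenerate bin
        hi = lo + width
        assert density_expectation_factor(lo, hi) < endpoint_mean_factor(lo, hi)

    def test_invalid_bins_rejected(self):
        with pytest.raises(ValueError):
            endpoint_mean_factor(100, 50)
        with pytest.raises(ValueError):
            density_expectation_factor(50, 100, density=200.0)  # mass outside bin


class TestIsletRecord:
    def test_diameter_is_mean_of_measurements(self):
        islet = IsletRecord((140.0, 160.0))
        assert islet.diameter == 150.0

    def test_rejects_nonpositive_diameters(self):
        with pytest.raises(ValueError):
            IsletRecord((100.0, -5.0))
        with pytest.raises(ValueError):
            IsletRecord(())


class TestIeBinned:
    def test_empty_preparation(self, conventional_scheme):
        result = ie_binned([], conventional_scheme)
        assert result.total_ie == 0.0
        assert all(v == 0 for v in result.per_bin_counts.values())

    def test_single_islet_at_reference(self, conventional_scheme):
        result = ie_binned(
            [IsletRecord.from_diameter(150)], conventional_scheme
        )
        # half-open bins: 150 falls in [150, 200)
        assert result.total_ie == pytest.approx(1.68519, abs=5e-6)
        assert result.per_bin_counts["150-200"] == 1

    def test_three_small_islets(self, conventional_scheme):
        islets = [IsletRecord.from_diameter(d) for d in (60, 80, 90)]
        result = ie_binned(islets, conventional_scheme)
        assert result.total_ie == pytest.approx(0.5, abs=2e-5)

    def test_sub_minimum_islets_reported_not_dropped(self, conventional_scheme):
        islets = [
            IsletRecord.from_diameter(30, islet_id="tiny"),
            IsletRecord.from_diameter(150, islet_id="ok"),
        ]
        result = ie_binned(islets, conventional_scheme)
        assert result.excluded_islets == ("tiny",)
        assert result.per_bin_counts["150-200"] == 1

    def test_overflow_default_errors(self, conventional_scheme):
        with pytest.raises(ValueError, match="overflow"):
            ie_binned([IsletRecord.from_diameter(360)], conventional_scheme)

    def test_overflow_extrapolates_endpoint_mean_bins(self, conventional_scheme):
        result = ie_binned(
            [IsletRecord.from_diameter(360)],
            conventional_scheme,
            overflow="extrapolate",
        )
        assert result.total_ie == pytest.approx(
            endpoint_mean_factor(350, 400), rel=1e-12
        )

    @given(data=st.lists(st.floats(min_value=50, max_value=349), max_size=30))
    @settings(derandomize=True, max_examples=50)
    def test_permutation_invariance_and_additivity(self, data, conventional_scheme):
        islets = [IsletRecord.from_diameter(d) for d in data]
        total = ie_binned(islets, conventional_scheme).total_ie
        shuffled = ie_binned(islets[::-1], conventional_scheme).total_ie
        assert shuffled == pytest.approx(total, rel=1e-12)
        half = len(islets) // 2
        split = (
            ie_binned(islets[:half], conventional_scheme).total_ie
            + ie_binned(islets[half:], conventional_scheme).total_ie
        )
        assert split == pytest.approx(total, rel=1e-12)

    def test_hermite_hadamard_binned_overestimates_exact(self, conventional_scheme):
        # per bin: (lo^3 + hi^3)/2 >= mean of d^3 for uniform d in the bin,
        # so the endpoint-mean binned total exceeds the exact total in
        # expectation; checked by Monte Carlo and by the closed form
        rng = np.random.default_rng(7)
        edges = conventional_scheme.bin_edges
        for lo, hi, factor in zip(edges[:-1], edges[1:], conventional_scheme.factors):
            closed_form_exact = (hi**4 - lo**4) / (4 * (hi - lo)) / 150**3
            assert factor >= closed_form_exact
            draws = rng.uniform(lo, hi, size=100_000)
            mc_exact = np.mean((draws / 150.0) ** 3)
            assert factor >= mc_exact

    def test_exact_total_matches_per_islet_sum(self):
        islets = [IsletRecord.from_diameter(d) for d in (60, 150, 300)]
        result = ie_total_exact(islets)
        assert result.total_ie == pytest.approx(sum(result.per_islet_ie))
        assert result.total_ie == pytest.approx(
            sum(ie_exact(d) for d in (60, 150, 300))
        )


class TestBinningScheme:
    def test_rejects_nonincreasing_edges_and_mismatched_factors(self):
        with pytest.raises(ValueError):
            BinningScheme((100.0, 50.0), (1.0,))
        with pytest.raises(ValueError):
            BinningScheme((50.0, 100.0, 150.0), (0.2,))
        with pytest.raises(ValueError):
            BinningScheme((50.0, 100.0, 150.0), (0.8, 0.2))  # not increasing

    def test_refined_factors_below_conventional(self, conventional_scheme):
        refined = BinningScheme.refined()
        assert all(
            r < c for r, c in zip(refined.factors, conventional_scheme.factors)
        )
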
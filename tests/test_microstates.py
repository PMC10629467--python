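"""GFP, peak picking, polarity-blind clustering, averaging and labelling."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from somnostate.core import DegenerateDataError
from somnostate.microstates import (
    IntervalExcluded,
    MicrostateSolution,
    align_and_average,
    explained_variance,
    find_gfp_peaks,
    gfp,
    gfp_curve,
    label_by_template,
    modified_kmeans,
    spatial_correlation,
)
from somnostate.synth import make_template_maps


class TestGfp:
    def test_flat_map_is_zero(self):
        assert gfp(np.zeros(19)) == 0.0

    def test_two_channel_antisymmetric_map(self):
        assert gfp(np.array([1.0, -1.0])) == pytest.approx(1.0)

    @given(c=st.floats(min_value=-100, max_value=100), seed=st.integers(0, 50))
    def test_homogeneity(self, c, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(0, 1, 19)
        v -= v.mean()
        assert gfp(c * v) == pytest.approx(abs(c) * gfp(v), abs=1e-9)


class TestFindGfpPeaks:
    def test_small_series(self):
        # build a 1-channel 'epoch' whose |value| is the wanted GFP series
        data = np.array([[1.0, 3.0, 1.0, 3.0, 1.0]])
        assert list(find_gfp_peaks(data)) == [1, 3]

    def test_monotone_series_has_no_peaks(self):
        data = np.arange(10.0)[None, :]
        assert find_gfp_peaks(data).size == 0

    def test_constant_series_has_no_peaks(self):
        assert find_gfp_peaks(np.ones((2, 50))).size == 0

    def test_carrier_gives_two_peaks_per_cycle(self, template_maps):
        fs, f, seconds = 250.0, 10.0, 2.5
        t = np.arange(int(fs * seconds)) / fs
        envelope = 1.0 + 0.3 * np.sin(2 * np.pi * 0.7 * t)
        data = template_maps[0][:, None] * (np.sin(2 * np.pi * f * t) * envelope)
        n_peaks = find_gfp_peaks(data).size
        assert n_peaks == pytest.approx(2 * f * seconds, abs=4)


class TestModifiedKmeans:
    def test_recovers_orthogonal_templates_with_polarity_flips(self, template_maps):
        rng = np.random.default_rng(0)
        idx = rng.integers(0, 4, 200)
        signs = rng.choice([-1.0, 1.0], 200)
        maps = template_maps[idx] * signs[:, None]
        sol = modified_kmeans(maps, 4, seed=1)
        r = np.abs(sol.maps @ template_maps.T)
        assert np.allclose(np.sort(r.max(axis=1)), 1.0, atol=1e-9)
        assert sol.explained_variance == pytest.approx(1.0)

    def test_polarity_invariance_of_solution(self, template_maps):
        rng = np.random.default_rng(3)
        idx = rng.integers(0, 4, 100)
        maps = template_maps[idx] + rng.normal(0, 0.05, (100, 19))
        maps -= maps.mean(axis=1, keepdims=True)
        sol_a = modified_kmeans(maps, 4, seed=5)
        flipped = maps * rng.choice([-1.0, 1.0], 100)[:, None]
        sol_b = modified_kmeans(flipped, 4, seed=5)
        match = np.abs(sol_a.maps @ sol_b.maps.T)
        # every class map of one solution appears (up to sign) in the other
        assert np.allclose(np.sort(match.max(axis=1)), 1.0, atol=1e-6)

    def test_duplicated_identical_maps_degenerate(self, template_maps):
        maps = np.tile(template_maps[0], (20, 1))
        sol = modified_kmeans(maps, 4, seed=2)
        assert sol.explained_variance == pytest.approx(1.0)
        assert sol.degenerate.sum() >= 1

    def test_fewer_maps_than_classes_rejected(self, template_maps):
        with pytest.raises(ValueError):
            modified_kmeans(template_maps[:2], 4)


class TestExplainedVariance:
    def test_perfect_solution(self, template_maps):
        sol = MicrostateSolution(maps=template_maps)
        assert explained_variance(sol, template_maps) == pytest.approx(1.0)

    def test_orthogonal_maps_explain_nothing(self):
        maps = make_template_maps(19, 8, seed=0)
        sol = MicrostateSolution(maps=maps[:4])
        assert explained_variance(sol, maps[4:]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_projection(self, template_maps):
        rng = np.random.default_rng(7)
        maps = rng.normal(0, 1, (50, 19))
        maps -= maps.mean(axis=1, keepdims=True)
        sol = MicrostateSolution(maps=template_maps)
        # oracle: explicit per-map residual after best polarity-blind projection
        total = res = 0.0
        for m in maps:
            best = max(
                (np.dot(m, c / np.linalg.norm(c)) ** 2 for c in template_maps)
            )
            total += np.dot(m, m)
            res += np.dot(m, m) - best
        assert explained_variance(sol, maps) == pytest.approx(1 - res / total)

    def test_non_decreasing_in_class_count(self):
        rng = np.random.default_rng(9)
        maps = rng.normal(0, 1, (120, 19))
        maps -= maps.mean(axis=1, keepdims=True)
        evs = [
            modified_kmeans(maps, k, restarts=10, seed=3).explained_variance
            for k in (1, 2, 3, 4)
        ]
        assert all(b >= a - 1e-6 for a, b in zip(evs, evs[1:]))


class TestAlignAndAverage:
    def test_permuted_class_order_detected(self, template_maps):
        a = MicrostateSolution(maps=template_maps)
        b = MicrostateSolution(maps=template_maps[[2, 0, 3, 1]])
        mean = align_and_average([a, b])
        match = np.abs(mean.maps @ template_maps.T)
        assert np.allclose(np.sort(match.max(axis=1)), 1.0, atol=1e-9)

    def test_polarity_flip_detected(self, template_maps):
        a = MicrostateSolution(maps=template_maps)
        b = MicrostateSolution(maps=-template_maps)
        mean = align_and_average([a, b])
        r = np.abs(np.diag(mean.maps @ template_maps.T))
        assert np.allclose(r, 1.0, atol=1e-9)

    def test_averaging_beats_median_single_solution(self, template_maps):
        rng = np.random.default_rng(4)
        perturbed = []
        for _ in range(10):
            noisy = template_maps + rng.normal(0, 0.25, template_maps.shape)
            noisy -= noisy.mean(axis=1, keepdims=True)
            noisy /= np.linalg.norm(noisy, axis=1, keepdims=True)
            perturbed.append(MicrostateSolution(maps=noisy))
        mean = align_and_average(perturbed)

        def fidelity(sol):
            return np.mean(
                [
                    max(
                        spatial_correlation(sol.maps[c], template_maps[k], True)
                        for k in range(4)
                    )
                    for c in range(4)
                ]
            )

        singles = sorted(fidelity(s) for s in perturbed)
        assert fidelity(mean) > singles[len(singles) // 2]

    def test_below_min_datasets_excluded(self, template_maps):
        with pytest.raises(IntervalExcluded):
            align_and_average([MicrostateSolution(maps=template_maps)], min_datasets=2)


class TestLabelByTemplate:
    def test_identity(self, template_maps):
        sol = label_by_template(MicrostateSolution(maps=template_maps), template_maps)
        assert sol.labels == ("A", "B", "C", "D")
        np.testing.assert_allclose(sol.template_correlations, 1.0)
        np.testing.assert_allclose(sol.maps, template_maps)

    def test_swap_detected(self, template_maps):
        swapped = template_maps[[1, 0, 2, 3]]
        sol = label_by_template(MicrostateSolution(maps=swapped), template_maps)
        np.testing.assert_allclose(sol.maps, template_maps)

    def test_matches_exhaustive_permutation_oracle(self, template_maps):
        rng = np.random.default_rng(12)
        noisy = template_maps[[3, 1, 0, 2]] + rng.normal(0, 0.4, (4, 19))
        noisy -= noisy.mean(axis=1, keepdims=True)
        sol = label_by_template(MicrostateSolution(maps=noisy), template_maps)
        # independent oracle: search all 24 permutations directly
        best_perm, best = None, -np.inf
        for perm in itertools.permutations(range(4)):
            score = sum(
                abs(spatial_correlation(noisy[perm[j]], template_maps[j]))
                for j in range(4)
            )
            if score > best:
                best_perm, best = perm, score
        np.testing.assert_allclose(sol.maps, noisy[list(best_perm)])


class TestSpatialCorrelation:
    def test_self_correlation(self, template_maps):
        assert spatial_correlation(template_maps[0], template_maps[0]) == pytest.approx(1.0)

    def test_polarity_blind_on_negated_map(self, template_maps):
        m = template_maps[1]
        assert spatial_correlation(m, -m, ignore_polarity=True) == pytest.approx(1.0)
        assert spatial_correlation(m, -m) == pytest.approx(-1.0)

    def test_orthogonal_maps(self, template_maps):
        assert spatial_correlation(template_maps[0], template_maps[1]) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_flat_map_rejected(self, template_maps):
        with pytest.raises(DegenerateDataError):
            spatial_correlation(template_maps[0], np.zeros(19))


def test_gfp_curve_matches_per_sample_gfp():
    rng = np.random.default_rng(1)
    data = rng.normal(0, 5, (19, 40))
    data -= data.mean(axis=0)
    expected = [gfp(data[:, i]) for i in range(40)]
    np.testing.assert_allclose(gfp_curve(data), expected)
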
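"""GFP, peak extraction, AAHC clustering, GEV, k selection, template averaging."""

import itertools

import numpy as np
import pytest

from mstates.clustering import (
    ClusteringResult,
    PeakMaps,
    TemplateSet,
    _principal_axis,
    aahc_cluster,
    align_and_average_templates,
    canonical_maps,
    compute_gev,
    compute_gfp,
    find_gfp_peaks,
    match_templates,
    select_k,
    spatial_correlation,
)
from mstates.errors import DataQualityError, InvalidArgumentError, \
    UndefinedCorrelationError
from mstates.layout import make_layout
from mstates.preproc import average_reference, make_epochs

from conftest import epochs_from_array


def _orthonormal_maps(n_channels: int, k: int, seed: int = 0) -> np.ndarray:
    """k orthonormal average-referenced maps."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_channels, k + 1))
    x -= x.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(x)
    q = q[:, :k].T
    q -= q.mean(axis=1, keepdims=True)
    return q / np.linalg.norm(q, axis=1, keepdims=True)


def _peakmaps(maps: np.ndarray) -> PeakMaps:
    maps = maps - maps.mean(axis=1, keepdims=True)
    gfp = np.linalg.norm(maps, axis=1) / np.sqrt(maps.shape[1])
    src = np.column_stack([np.zeros(len(maps), int), np.arange(len(maps))])
    return PeakMaps(maps=maps, peak_gfp=gfp, source=src)


def _partition_gev(maps: np.ndarray, parts: list[list[int]]) -> float:
    """Independent oracle: GEV of a partition with principal-axis centroids."""
    c = maps.shape[1]
    denom = np.sum(np.linalg.norm(maps, axis=1) ** 2) / c
    num = 0.0
    for members in parts:
        t = _principal_axis(maps[members])
        num += np.sum((maps[members] @ t) ** 2) / c
    return num / denom


def _set_partitions(items, k):
    """All partitions of ``items`` into exactly k nonempty blocks."""
    if k == 1:
        yield [list(items)]
        return
    if len(items) == k:
        yield [[i] for i in items]
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest, k - 1):
        yield [[first]] + part
    for part in _set_partitions(rest, k):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]


class TestComputeGfp:
    def test_equal_channels_give_zero(self):
        ep = epochs_from_array(np.full((1, 4, 10), 3.0), reference=False)
        ep.epochs[:] = 0.0  # average reference of equal channels
        assert np.allclose(compute_gfp(ep).values, 0.0)

    def test_two_channel_antisymmetric_map(self):
        data = np.zeros((1, 4, 1))
        ep = epochs_from_array(data, reference=False)
        ep.epochs[0, :, 0] = [1.0, -1.0, 1.0, -1.0]
        assert compute_gfp(ep).values[0] == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        ep = epochs_from_array(rng.normal(size=(2, 7, 20)))
        g = compute_gfp(ep)
        v = ep.kept()
        expected = np.sqrt(
            np.mean((v - v.mean(axis=1, keepdims=True)) ** 2, axis=1)).ravel()
        assert np.allclose(g.values, expected, atol=1e-12)


class TestFindGfpPeaks:
    def _epochs_with_gfp(self, gfp_rows):
        """Epochs whose per-sample GFP equals the requested sequence."""
        gfp = np.asarray(gfp_rows, dtype=float)
        n_e, n_s = gfp.shape
        data = np.zeros((n_e, 4, n_s))
        data[:, 0, :] = gfp
        data[:, 1, :] = -gfp
        data[:, 2, :] = gfp
        data[:, 3, :] = -gfp
        return epochs_from_array(data, reference=False)

    def test_strict_local_maxima(self):
        ep = self._epochs_with_gfp([[1, 3, 2, 5, 4]])
        peaks = find_gfp_peaks(ep)
        assert peaks.source[:, 1].tolist() == [1, 3]
        assert np.allclose(peaks.peak_gfp, [3, 5])

    def test_monotone_sequence_aborts_for_lack_of_peaks(self):
        ep = self._epochs_with_gfp([[1, 2, 3, 4, 5]])
        with pytest.raises(DataQualityError):
            find_gfp_peaks(ep)

    def test_min_separation_keeps_larger_peak(self):
        ep = self._epochs_with_gfp([[0, 5, 0, 6, 0, 1, 0]])
        peaks = find_gfp_peaks(ep, min_separation=3)
        assert peaks.source[:, 1].tolist() == [3]

    def test_rectified_alpha_envelope_peak_rate(self, realistic_case):
        # 10 Hz rectified envelope -> two GFP maxima per cycle, ~20 per
        # second once narrow-band filtered (raw noise adds spurious maxima)
        from mstates.preproc import preprocess

        rec, _, _ = realistic_case
        res = preprocess(rec, target_sfreq=500.0)
        peaks = find_gfp_peaks(res.narrow)
        per_second = len(peaks.maps) / res.narrow.total_time
        assert 15 <= per_second <= 25


class TestSpatialCorrelation:
    def test_identity_sign_flip_orthogonal(self):
        maps = _orthonormal_maps(12, 2)
        assert spatial_correlation(maps[0], maps[0]) == pytest.approx(1.0)
        assert spatial_correlation(maps[0], -maps[0]) == pytest.approx(1.0)
        assert spatial_correlation(maps[0], -maps[0],
                                   polarity_invariant=False) == pytest.approx(-1.0)
        assert spatial_correlation(maps[0], maps[1]) == pytest.approx(0.0, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spatial_correlation(np.zeros(5), np.ones(5) - 1.0 + np.arange(5))


class TestAahc:
    def test_exact_two_template_mixture(self):
        t = _orthonormal_maps(10, 2)
        gfp = np.array([2.0, 3.0, 1.5, 2.5, 2.0, 3.5, 1.0, 2.0])
        assign = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        maps = t[assign] * (gfp * np.sqrt(10))[:, None]
        cr = aahc_cluster(_peakmaps(maps), 2, 2)
        assert cr.gev[2] == pytest.approx(1.0, abs=1e-12)
        corr = np.abs(cr.templates[2].maps @ t.T)
        assert np.allclose(corr.max(axis=1), 1.0, atol=1e-9)

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_exhaustive_best_partition(self, k):
        # structured maps: k templates + noise, the regime AAHC is built for
        rng = np.random.default_rng(42 + k)
        t = _orthonormal_maps(10, k, seed=k)
        assign = rng.integers(k, size=8)
        assign[:k] = np.arange(k)  # every template represented
        maps = t[assign] * rng.uniform(1, 3, size=8)[:, None]
        maps += 0.15 * rng.standard_normal(maps.shape)
        maps -= maps.mean(axis=1, keepdims=True)
        cr = aahc_cluster(_peakmaps(maps), k_min=k, k_max=k)
        best = max(_partition_gev(_peakmaps(maps).maps, p)
                   for p in _set_partitions(list(range(8)), k))
        assert cr.gev[k] == pytest.approx(best, abs=1e-6)

    def test_polarity_invariance_under_sign_flips(self):
        rng = np.random.default_rng(3)
        t = _orthonormal_maps(12, 3, seed=5)
        assign = rng.integers(3, size=20)
        maps = t[assign] * rng.uniform(1, 2, (20, 1)) \
            + 0.1 * rng.standard_normal((20, 12))
        maps -= maps.mean(axis=1, keepdims=True)
        flipped = maps.copy()
        flip = rng.random(20) < 0.5
        flipped[flip] *= -1
        a = aahc_cluster(_peakmaps(maps), 2, 3)
        b = aahc_cluster(_peakmaps(flipped), 2, 3)
        for k in (2, 3):
            assert a.gev[k] == pytest.approx(b.gev[k], abs=1e-9)
            corr = np.abs(a.templates[k].maps @ b.templates[k].maps.T)
            assert np.allclose(np.sort(corr.max(axis=1)), 1.0, atol=1e-9)

    def test_gev_nondecreasing_in_k(self, realistic_case):
        rec, _, _ = realistic_case
        ep = average_reference(make_epochs(rec, 2.0))
        cr = aahc_cluster(find_gfp_peaks(ep), 2, 8)
        gev = [cr.gev[k] for k in sorted(cr.gev)]
        assert all(b - a >= -1e-6 for a, b in zip(gev, gev[1:]))

    def test_degenerate_identical_maps(self):
        m = _orthonormal_maps(8, 1)[0]
        maps = np.tile(m, (6, 1)) * np.arange(1, 7)[:, None]
        with pytest.warns(UserWarning):
            cr = aahc_cluster(_peakmaps(maps), 2, 3)
        assert cr.degenerate
        assert cr.gev[1] == pytest.approx(1.0)


class TestComputeGev:
    def test_exact_scaled_templates_give_one(self):
        t = _orthonormal_maps(10, 3)
        labels = np.array([0, 1, 2, 1, 0])
        maps = t[labels] * np.array([2.0, 1.0, 3.0, 1.5, 2.5])[:, None]
        gfp = np.linalg.norm(maps, axis=1) / np.sqrt(10)
        ts = TemplateSet(maps=t, class_labels=("A", "B", "C"))
        assert compute_gev(maps, gfp, ts, labels) == pytest.approx(1.0)

    def test_orthogonal_templates_give_zero(self):
        t = _orthonormal_maps(10, 4)
        maps = np.tile(t[3], (5, 1)) * 2.0
        gfp = np.linalg.norm(maps, axis=1) / np.sqrt(10)
        ts = TemplateSet(maps=t[:2], class_labels=("A", "B"))
        labels = np.zeros(5, dtype=int)
        assert compute_gev(maps, gfp, ts, labels) == pytest.approx(0.0, abs=1e-12)


class TestSelectK:
    def _cr(self, gev_by_k):
        return ClusteringResult(templates={}, assignments={}, gev=dict(gev_by_k))

    def test_first_gain_below_threshold(self):
        cr = self._cr({2: 0.50, 3: 0.70, 4: 0.71, 5: 0.72})
        assert select_k(cr, 0.02) == 3

    def test_never_below_threshold_returns_k_max(self):
        cr = self._cr({k: 0.5 + 0.05 * (k - 2) for k in range(2, 6)})
        assert select_k(cr, 0.01) == 5

    def test_single_k(self):
        assert select_k(self._cr({4: 0.8}), 0.01) == 4


class TestTemplateAveraging:
    def test_permuted_identical_sets_recovered(self):
        t = _orthonormal_maps(10, 3)
        sets = [TemplateSet(maps=t[perm], class_labels=("A", "B", "C"))
                for perm in ([0, 1, 2], [2, 0, 1], [1, 2, 0])]
        avg = align_and_average_templates(sets)
        corr = np.abs(avg.maps @ t.T)
        assert np.allclose(np.sort(corr.max(axis=1)), 1.0, atol=1e-9)

    def test_sign_flip_has_no_effect(self):
        t = _orthonormal_maps(10, 3)
        a = [TemplateSet(maps=t, class_labels=("A", "B", "C"))] * 2
        b = [TemplateSet(maps=t, class_labels=("A", "B", "C")),
             TemplateSet(maps=-t, class_labels=("A", "B", "C"))]
        avg_a = align_and_average_templates(a)
        avg_b = align_and_average_templates(b)
        assert np.allclose(np.abs(avg_a.maps @ avg_b.maps.T).max(axis=1), 1.0,
                           atol=1e-9)

    def test_assignment_matches_exhaustive_permutation(self):
        rng = np.random.default_rng(7)
        ref = TemplateSet(maps=_orthonormal_maps(12, 3, seed=1),
                          class_labels=("A", "B", "C"))
        noisy = ref.maps[[2, 0, 1]] + 0.2 * rng.standard_normal((3, 12))
        noisy -= noisy.mean(axis=1, keepdims=True)
        noisy /= np.linalg.norm(noisy, axis=1, keepdims=True)
        src = TemplateSet(maps=noisy, class_labels=("A", "B", "C"))
        perm, signs = match_templates(src, ref)
        corr = np.abs(src.maps @ ref.maps.T)
        best = max(itertools.permutations(range(3)),
                   key=lambda p: sum(corr[p[j], j] for j in range(3)))
        assert tuple(perm) == best

    def test_canonical_ordering_for_four_classes(self):
        lay = make_layout(20)
        canon = canonical_maps(lay)
        shuffled = [TemplateSet(maps=canon.maps[[3, 1, 0, 2]],
                                class_labels=("A", "B", "C", "D"))]
        avg = align_and_average_templates(shuffled, layout=lay)
        corr = np.abs(np.diag(avg.maps @ canon.maps.T))
        assert np.allclose(corr, 1.0, atol=1e-9)

    def test_k_mismatch_rejected(self):
        a = TemplateSet(maps=_orthonormal_maps(10, 2), class_labels=("A", "B"))
        b = TemplateSet(maps=_orthonormal_maps(10, 3), class_labels=("A", "B", "C"))
        with pytest.raises(InvalidArgumentError):
            align_and_average_templates([a, b])
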
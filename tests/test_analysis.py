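import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hsifuse.analysis import (
    adjusted_rand_index,
    minibatch_kmeans,
    mutual_information,
    silhouette_mean,
    spectral_correlation,
)
from hsifuse.datacube import make_datacube
from hsifuse.errors import MetricError, ParameterError, ValidationError
from hsifuse.fusion import fuse_cubes


def _cube(data, modality="NIR"):
    data = np.asarray(data, np.float32)
    return make_datacube(data, 1000.0 + np.arange(data.shape[2]),
                         modality, 10.0)


def brute_force_silhouette(X, labels):
    """Textbook O(n^2) silhouette, python loops."""
    n = len(X)
    out = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            out[i] = 0.0
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
        b = np.inf
        for c in set(labels) - {labels[i]}:
            others = [j for j in range(n) if labels[j] == c]
            b = min(b, np.mean([np.linalg.norm(X[i] - X[j]) for j in others]))
        out[i] = (b - a) / max(a, b)
    return out.mean()


class TestMiniBatchKMeans:
    def test_separated_blobs_fully_recovered(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(0, 1, (100, 2)),
                            rng.normal(20, 1, (100, 2))])
        truth = np.repeat([0, 1], 100)
        cube = _cube(X.reshape(10, 20, 2))
        res = minibatch_kmeans(cube, k=2, seed=1)
        assert adjusted_rand_index(res.labels.ravel(), truth) == 1.0
        assert res.inertia >= 0

    def test_k_equals_distinct_points_zero_inertia(self):
        pts = np.array([[0.0, 0], [10, 0], [0, 10], [10, 10]])
        X = np.repeat(pts, 25, axis=0)
        cube = _cube(X.reshape(10, 10, 2))
        res = minibatch_kmeans(cube, k=4, seed=0)
        assert res.inertia == pytest.approx(0.0, abs=1e-9)

    def test_background_labeled_minus_one(self):
        cube = _cube(np.random.default_rng(1).random((6, 6, 3)))
        cube.mask = np.zeros((6, 6), bool)
        cube.mask[0] = True
        res = minibatch_kmeans(cube, k=2, seed=0)
        assert (res.labels[0] == -1).all()
        assert (res.labels[1:] >= 0).all()

    def test_seed_reproducible_bitwise(self, tiny_phantom):
        _, mir, _, _ = tiny_phantom
        r1 = minibatch_kmeans(mir, k=4, seed=7)
        r2 = minibatch_kmeans(mir, k=4, seed=7)
        assert r1.labels.tobytes() == r2.labels.tobytes()
        assert r1.inertia == r2.inertia

    def test_k_errors(self):
        cube = _cube(np.random.default_rng(0).random((2, 2, 2)))
        with pytest.raises(ParameterError):
            minibatch_kmeans(cube, k=1, seed=0)
        with pytest.raises(ParameterError):
            minibatch_kmeans(cube, k=5, seed=0)


class TestSilhouette:
    def test_two_tight_distant_pairs(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = np.array([0, 0, 1, 1])
        assert silhouette_mean(X, labels) == pytest.approx(0.990, abs=1e-3)

    def test_matches_bruteforce_exactly(self):
        for seed in range(4):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(20, 120))
            X = rng.random((n, 3))
            labels = rng.integers(0, 3, n)
            if len(np.unique(labels)) < 2:
                continue
            got = silhouette_mean(X, labels, max_points=None)
            assert got == pytest.approx(brute_force_silhouette(X, labels),
                                        abs=1e-10)

    def test_matches_sklearn_crosscheck(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(5)
        X = rng.random((150, 4))
        labels = rng.integers(0, 4, 150)
        assert silhouette_mean(X, labels, max_points=None) == pytest.approx(
            silhouette_score(X, labels), abs=1e-10)

    def test_same_distribution_clusters_near_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (200, 2))
        labels = np.repeat([0, 1], 100)
        assert abs(silhouette_mean(X, labels)) < 0.2

    def test_subsampling_is_seeded(self):
        rng = np.random.default_rng(3)
        X = rng.random((500, 2))
        labels = rng.integers(0, 2, 500)
        a = silhouette_mean(X, labels, max_points=100, seed=9)
        b = silhouette_mean(X, labels, max_points=100, seed=9)
        assert a == b

    def test_single_cluster_undefined(self):
        with pytest.raises(MetricError):
            silhouette_mean(np.zeros((5, 2)), np.zeros(5, int))


class TestSpectralCorrelation:
    def _pair(self, block):
        orig = _cube(np.random.default_rng(0).random((4, 4, 3)), "MIR")
        fused = fuse_cubes([_cube(block(orig.data), "NIR"), orig],
                           normalize="band")
        return orig, fused

    def test_exact_copy_gives_one(self):
        rng = np.random.default_rng(0)
        a = rng.random((4, 4, 3)).astype(np.float32)
        orig = _cube(a, "MIR")
        fused_like = _cube(np.concatenate([rng.random((4, 4, 2)), a],
                                          axis=2).astype(np.float32))
        from hsifuse.datacube import WavelengthAxis
        from hsifuse.fusion import reassign_wavelengths

        fused_like.wavelengths = reassign_wavelengths([
            WavelengthAxis.from_values([1.0, 2.0], "NIR"),
            WavelengthAxis.from_values([3.0, 4.0, 5.0], "MIR")])
        assert spectral_correlation(orig, fused_like, "MIR") == pytest.approx(
            1.0, abs=1e-6)

    def test_fused_block_after_band_normalization_stays_high(self):
        rng = np.random.default_rng(0)
        orig = _cube(rng.random((4, 4, 3)), "MIR")
        other = _cube(rng.random((4, 4, 2)), "NIR")
        fused = fuse_cubes([other, orig], normalize="band")
        assert spectral_correlation(orig, fused, "MIR") > 0.9

    def test_negated_copy_gives_minus_one(self):
        rng = np.random.default_rng(1)
        a = rng.random((3, 3, 3)).astype(np.float32)
        orig = _cube(a, "MIR")
        fused_like = _cube(np.concatenate([rng.random((3, 3, 2)),
                                           1.0 - a], axis=2).astype(np.float32))
        from hsifuse.datacube import WavelengthAxis
        from hsifuse.fusion import reassign_wavelengths

        fused_like.wavelengths = reassign_wavelengths([
            WavelengthAxis.from_values([1.0, 2.0], "NIR"),
            WavelengthAxis.from_values([3.0, 4.0, 5.0], "MIR")])
        fused_like.validate()
        assert spectral_correlation(orig, fused_like, "MIR") == pytest.approx(
            -1.0, abs=1e-6)

    def test_hand_computed_pearson(self):
        a = np.array([[[0.0, 1.0, 0.0, 1.0]]], np.float32)
        b = np.array([[[0.0, 1.0, 1.0, 1.0]]], np.float32)
        orig = _cube(a, "MIR")
        fused_like = _cube(b)
        from hsifuse.datacube import WavelengthAxis
        from hsifuse.fusion import reassign_wavelengths

        fused_like.wavelengths = reassign_wavelengths(
            [WavelengthAxis.from_values([1.0, 2.0, 3.0, 4.0], "MIR")])
        assert spectral_correlation(orig, fused_like, "MIR") == pytest.approx(
            1 / np.sqrt(3), abs=1e-4)

    def test_missing_modality_raises_lookup(self):
        orig = _cube(np.random.default_rng(0).random((2, 2, 2)), "MIR")
        fused_like = _cube(np.random.default_rng(1).random((2, 2, 2)), "NIR")
        with pytest.raises(LookupError):
            spectral_correlation(orig, fused_like, "MIR")

    def test_affine_intensity_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.random((4, 4, 5)).astype(np.float32)
        orig = _cube(a, "MIR")
        scaled = _cube((2.5 * a + 0.3).astype(np.float32), "MIR")
        from hsifuse.datacube import WavelengthAxis
        from hsifuse.fusion import reassign_wavelengths

        fused_like = _cube(a)
        fused_like.wavelengths = reassign_wavelengths(
            [WavelengthAxis.from_values(np.arange(5.0) + 1, "MIR")])
        r1 = spectral_correlation(orig, fused_like, "MIR")
        r2 = spectral_correlation(scaled, fused_like, "MIR")
        assert r1 == pytest.approx(r2, abs=1e-6)


class TestMutualInformation:
    def test_self_information_equals_entropy(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 4, (64, 64)) / 3.0
        mi = mutual_information(img, img, bins=4)
        _, counts = np.unique(img, return_counts=True)
        p = counts / counts.sum()
        assert mi == pytest.approx(-(p * np.log(p)).sum(), abs=1e-9)

    def test_equiprobable_levels_give_ln4(self):
        img = (np.arange(16).reshape(4, 4) % 4) / 3.0
        assert mutual_information(img, img, bins=4) == pytest.approx(
            np.log(4), abs=1e-9)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.random((1000, 1000))
        b = rng.random((1000, 1000))
        assert mutual_information(a, b, bins=64) < 0.01

    @given(st.integers(0, 10_000))
    def test_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((16, 16))
        b = rng.random((16, 16))
        assert mutual_information(a, b) == mutual_information(b, a)

    def test_constant_rejected(self):
        with pytest.raises(ValidationError):
            mutual_information(np.ones((4, 4)), np.random.rand(4, 4))


class TestARI:
    def test_identical_and_permuted(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        assert adjusted_rand_index(labels, labels) == 1.0
        permuted = np.array([2, 2, 0, 0, 1, 1])
        assert adjusted_rand_index(labels, permuted) == 1.0

    def test_independent_labelings_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 4, 1000)
        b = rng.integers(0, 4, 1000)
        assert abs(adjusted_rand_index(a, b)) < 0.05

    def test_background_excluded_pairwise(self):
        a = np.array([-1, 0, 0, 1, 1])
        b = np.array([0, 0, 0, -1, 1])
        # only positions 1, 2, 4 survive
        assert adjusted_rand_index(a, b) == adjusted_rand_index(
            np.array([0, 0, 1]), np.array([0, 0, 1]))

    def test_empty_overlap_rejected(self):
        with pytest.raises(ValidationError):
            adjusted_rand_index(np.array([-1, -1]), np.array([0, 1]))
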
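"""NMDS, MRPP, Mantel and the provisional k-medoids labelling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from phylodistricts import (
    DissimilarityMatrix,
    k_medoids,
    mantel,
    mrpp,
    nmds,
)


def _dm(values, label="test"):
    n = values.shape[0]
    return DissimilarityMatrix(values, [f"p{i}" for i in range(n)], label)


def _planar_dm(n=15, seed=0, scale=0.35):
    rng = np.random.default_rng(seed)
    pts = rng.random((n, 2)) * scale
    return _dm(squareform(pdist(pts))), pts


class TestNMDS:
    def test_planar_configuration_recovered(self):
        """Distances from genuine 2-D points should embed with near-zero
        stress and reproduce the inter-point rank order."""
        D, _ = _planar_dm(n=15, seed=1)
        ord_ = nmds(D, n_starts=4, seed=0)
        assert ord_.stress < 0.01
        emb = squareform(pdist(ord_.coordinates.to_numpy()))
        tri = np.tril_indices(D.n, -1)
        rho = np.corrcoef(
            np.argsort(np.argsort(D.values[tri])),
            np.argsort(np.argsort(emb[tri])),
        )[0, 1]
        assert rho > 0.99

    def test_centered_output(self):
        D, _ = _planar_dm(n=10, seed=2)
        ord_ = nmds(D, n_starts=2, seed=0)
        np.testing.assert_allclose(
            ord_.coordinates.to_numpy().mean(axis=0), 0, atol=1e-9
        )

    def test_more_starts_never_worse(self):
        D, _ = _planar_dm(n=12, seed=3)
        s1 = nmds(D, n_starts=1, seed=7).stress
        s4 = nmds(D, n_starts=4, seed=7).stress
        s8 = nmds(D, n_starts=8, seed=7).stress
        assert s4 <= s1 + 1e-12
        assert s8 <= s4 + 1e-12

    def test_reproducible(self):
        D, _ = _planar_dm(n=10, seed=4)
        a = nmds(D, n_starts=3, seed=42)
        b = nmds(D, n_starts=3, seed=42)
        assert a.stress == b.stress
        pd.testing.assert_frame_equal(a.coordinates, b.coordinates)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            nmds(_dm(np.zeros((4, 4))))

    def test_csv_header_records_stress(self, tmp_path):
        D, _ = _planar_dm(n=8, seed=5)
        ord_ = nmds(D, n_starts=2, seed=0)
        path = tmp_path / "ord.csv"
        ord_.to_csv(path)
        first = path.read_text().splitlines()[0]
        assert first.startswith("# stress-1 = ")


def _mrpp_oracle(values, codes, n_groups):
    """delta and exact p by brute-force enumeration, written independently
    of the library's internals."""
    n = len(codes)

    def delta(perm_codes):
        total = 0.0
        for g in range(n_groups):
            idx = [i for i in range(n) if perm_codes[i] == g]
            m = len(idx)
            s = sum(values[i, j] for i in idx for j in idx if i != j)
            total += (m / n) * s / (m * (m - 1))
        return total

    d_obs = delta(codes)
    deltas = [delta([codes[i] for i in p])
              for p in itertools.permutations(range(n))]
    p = sum(d <= d_obs + 1e-12 for d in deltas) / len(deltas)
    return d_obs, float(np.mean(deltas)), p


class TestMRPP:
    def test_perfect_separation(self):
        """Two internally identical, mutually maximally distant groups:
        delta_obs = 0, A = 1, exact p = its minimum attainable value."""
        n = 6
        vals = np.zeros((n, n))
        vals[:3, 3:] = 1.0
        vals[3:, :3] = 1.0
        D = _dm(vals)
        groups = {f"p{i}": "x" if i < 3 else "y" for i in range(n)}
        res = mrpp(D, groups, method="exact")
        assert res.delta_obs == pytest.approx(0.0)
        assert res.a_statistic == pytest.approx(1.0)
        # delta = 0 only when the permutation keeps each block intact:
        # 2 * 3! * 3! of the 6! permutations, i.e. p = 72/720 = 0.1
        assert res.p_value == pytest.approx(0.1)

    def test_exact_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(10)
        n = 7
        pts = rng.random((n, 2))
        vals = squareform(pdist(pts))
        vals = vals / vals.max()
        D = _dm(vals)
        codes = [0, 0, 1, 1, 1, 0, 1]
        groups = {f"p{i}": ["a", "b"][c] for i, c in enumerate(codes)}
        res = mrpp(D, groups, method="exact")
        d_obs, d_exp, p = _mrpp_oracle(vals, codes, 2)
        assert res.delta_obs == pytest.approx(d_obs, abs=1e-12)
        assert res.delta_exp == pytest.approx(d_exp, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)
        assert res.a_statistic == pytest.approx(1 - d_obs / d_exp, abs=1e-12)

    def test_random_p_close_to_exact(self):
        rng = np.random.default_rng(11)
        n = 7
        vals = squareform(pdist(rng.random((n, 2))))
        vals /= vals.max()
        D = _dm(vals)
        codes = [0, 1, 0, 1, 0, 1, 0]
        groups = {f"p{i}": str(c) for i, c in enumerate(codes)}
        exact = mrpp(D, groups, method="exact")
        rand = mrpp(D, groups, n_perm=4999, seed=0, method="random")
        assert rand.p_value == pytest.approx(exact.p_value, abs=0.05)

    def test_singleton_group_raises(self):
        D = _dm(np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]]))
        with pytest.raises(ValueError, match="singleton"):
            mrpp(D, {"p0": "a", "p1": "a", "p2": "b"})

    def test_one_group_raises(self):
        D = _dm(np.array([[0, 0.5], [0.5, 0]]))
        with pytest.raises(ValueError, match="two groups"):
            mrpp(D, {"p0": "a", "p1": "a"})

    def test_random_labels_give_high_p(self):
        """Labels independent of structure: A near 0, p not small."""
        rng = np.random.default_rng(12)
        vals = squareform(pdist(rng.random((16, 2))))
        vals /= vals.max()
        D = _dm(vals)
        groups = {f"p{i}": str(i % 2) for i in range(16)}
        res = mrpp(D, groups, n_perm=999, seed=5)
        assert abs(res.a_statistic) < 0.2
        assert res.p_value > 0.01


def _mantel_oracle(m1, m2):
    """Exact one-tailed Mantel p by enumerating permutations of m2."""
    n = m1.shape[0]
    tri = np.tril_indices(n, -1)
    v1 = m1[tri]
    r_obs = np.corrcoef(v1, m2[tri])[0, 1]
    count = total = 0
    for perm in itertools.permutations(range(n)):
        idx = np.array(perm)
        r = np.corrcoef(v1, m2[np.ix_(idx, idx)][tri])[0, 1]
        count += r >= r_obs - 1e-12
        total += 1
    return r_obs, count / total


class TestMantel:
    def test_identity_r_is_one(self):
        D, _ = _planar_dm(n=8, seed=20)
        res = mantel(D, D, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_affine_transform_r_is_one(self):
        D, _ = _planar_dm(n=8, seed=21)
        v = np.clip(0.1 + 0.5 * D.values, 0, 1)
        np.fill_diagonal(v, 0)  # the affine shift must not touch the diagonal
        D2 = _dm(v)
        tri = np.tril_indices(8, -1)
        r = np.corrcoef(D.values[tri], D2.values[tri])[0, 1]
        assert r == pytest.approx(1.0)
        res = mantel(D, D2, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_exact_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(22)
        n = 6
        m1 = squareform(pdist(rng.random((n, 2))))
        m1 /= m1.max()
        m2 = squareform(pdist(rng.random((n, 2))))
        m2 /= m2.max()
        res = mantel(_dm(m1), _dm(m2), method="exact")
        r, p = _mantel_oracle(m1, m2)
        assert res.r == pytest.approx(r, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_mismatched_plots_raise(self):
        D1, _ = _planar_dm(n=5, seed=23)
        vals = D1.values
        D2 = DissimilarityMatrix(vals, [f"q{i}" for i in range(5)], "x")
        with pytest.raises(ValueError, match="same plots"):
            mantel(D1, D2)

    def test_constant_matrix_raises(self):
        vals = np.ones((4, 4)) - np.eye(4)
        D1, _ = _planar_dm(n=4, seed=24)
        with pytest.raises(ValueError, match="constant"):
            mantel(D1, _dm(vals))

    def test_skbio_crosscheck(self):
        """Agreement with the reference implementation in scikit-bio, when
        available, on r and the permutation p at matched settings."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(25)
        n = 12
        m1 = squareform(pdist(rng.random((n, 2))))
        m1 /= m1.max()
        m2 = squareform(pdist(m1[:, :2] + 0.05 * rng.random((n, 2))))
        m2 /= m2.max()
        res = mantel(_dm(m1), _dm(m2), n_perm=999, seed=0)
        r_ref, p_ref, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(m1), skbio.DistanceMatrix(m2),
            method="pearson", permutations=999, alternative="greater",
        )
        assert res.r == pytest.approx(r_ref, abs=1e-9)
        assert res.p_value == pytest.approx(p_ref, abs=0.05)


class TestKMedoids:
    def test_recovers_clear_clusters(self):
        rng = np.random.default_rng(30)
        centers = np.array([[0.1, 0.1], [0.8, 0.2], [0.4, 0.9]])
        pts = np.vstack([c + 0.03 * rng.standard_normal((6, 2)) for c in centers])
        vals = squareform(pdist(pts))
        vals /= vals.max()
        D = _dm(vals)
        labels = k_medoids(D, k=3)
        truth = np.repeat([0, 1, 2], 6)
        # every true cluster maps to exactly one derived label
        for g in range(3):
            assert labels.iloc[np.flatnonzero(truth == g)].nunique() == 1
        assert labels.nunique() == 3

    def test_k_bounds(self):
        D, _ = _planar_dm(n=6, seed=31)
        with pytest.raises(ValueError):
            k_medoids(D, k=1)
        with pytest.raises(ValueError):
            k_medoids(D, k=4)
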
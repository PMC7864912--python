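"""Bray-Curtis, PCoA, PERMANOVA and rank-sum tests against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from paleogut.compare import (
    DistanceMatrix,
    bray_curtis,
    pcoa,
    permanova,
    pmds_reads_per_million,
    wilcoxon_ranksum,
)
from paleogut.compare import _pseudo_f
from paleogut.profiles import AbundanceTable


def _dm(points):
    pts = np.asarray(points, dtype=float)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(ids=[f"s{i}" for i in range(len(pts))], data=d)


class TestBrayCurtis:
    def _table(self, rows, index):
        return AbundanceTable(
            counts=pd.DataFrame(rows, index=index), rank="family"
        )

    def test_identical_rows_zero(self):
        t = self._table({"a": [2, 2], "b": [3, 3]}, ["s1", "s2"])
        assert bray_curtis(t).data[0, 1] == 0.0

    def test_disjoint_rows_one(self):
        t = self._table({"a": [1, 0], "b": [0, 1]}, ["s1", "s2"])
        assert bray_curtis(t).data[0, 1] == pytest.approx(1.0)

    def test_hand_computed_third(self):
        t = self._table({"a": [2, 1], "b": [2, 1]}, ["s1", "s2"])
        assert bray_curtis(t).data[0, 1] == pytest.approx(1.0 / 3.0)

    def test_symmetry_and_bounds_random(self):
        rng = np.random.Generator(np.random.PCG64(3))
        counts = pd.DataFrame(rng.integers(0, 50, size=(6, 9)).astype(float),
                              index=[f"s{i}" for i in range(6)])
        dm = bray_curtis(counts)
        assert np.allclose(dm.data, dm.data.T)
        assert dm.data.min() >= 0 and dm.data.max() <= 1

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(pd.DataFrame({"a": [1]}, index=["s1"]))


class TestPCoA:
    def test_two_points_closed_form(self):
        dm = DistanceMatrix(ids=["a", "b"], data=np.array([[0.0, 1.0], [1.0, 0.0]]))
        res = pcoa(dm)
        coords = res.coordinates.iloc[:, 0].to_numpy()
        assert sorted(coords) == pytest.approx([-0.5, 0.5])

    def test_euclidean_roundtrip_procrustes(self):
        # distances of known 2-D points must be reproduced up to rotation/reflection
        rng = np.random.Generator(np.random.PCG64(7))
        pts = rng.normal(size=(8, 2))
        res = pcoa(_dm(pts), k=2)
        recovered = res.coordinates.to_numpy()
        a = pts - pts.mean(0)
        b = recovered - recovered.mean(0)
        from scipy.linalg import orthogonal_procrustes

        r, _ = orthogonal_procrustes(b, a)
        assert np.abs(b @ r - a).max() < 1e-8

    def test_duplicate_points_identical_coordinates(self):
        res = pcoa(_dm([[0, 0], [0, 0], [3, 4]]))
        c = res.coordinates.to_numpy()
        assert np.allclose(c[0], c[1])

    def test_eigenvalue_sum_equals_total_dispersion(self):
        rng = np.random.Generator(np.random.PCG64(11))
        pts = rng.normal(size=(7, 3))
        dm = _dm(pts)
        res = pcoa(dm)
        n = dm.n
        total = (dm.data**2).sum() / (2 * n)
        assert res.eigenvalues.sum() == pytest.approx(total)
        assert not res.has_negative_eigenvalues

    def test_negative_eigenvalues_flagged_for_non_euclidean(self):
        # Bray-Curtis is a semimetric: its PCoA typically has negative axes
        rng = np.random.Generator(np.random.PCG64(0))
        counts = pd.DataFrame(
            rng.integers(0, 20, size=(6, 4)).astype(float),
            index=[f"s{i}" for i in range(6)],
        )
        res = pcoa(bray_curtis(counts))
        assert res.has_negative_eigenvalues
        # negative axes are dropped from the coordinates
        assert res.coordinates.shape[1] < 6


class TestPermanova:
    def test_separated_clusters_maximal_f(self):
        # two tight clusters far apart: observed F is the maximum over all
        # 70 ways of relabelling 8 samples into two groups of 4
        rng = np.random.Generator(np.random.PCG64(5))
        pts = np.vstack([rng.normal(0, 0.1, (4, 2)), rng.normal(20, 0.1, (4, 2)) + 20])
        dm = _dm(pts)
        d2 = dm.data**2
        obs_codes = np.array([0] * 4 + [1] * 4)
        f_obs = _pseudo_f(d2, obs_codes, 2)
        f_all = []
        for members in itertools.combinations(range(8), 4):
            codes = np.ones(8, dtype=int)
            codes[list(members)] = 0
            f_all.append(_pseudo_f(d2, codes, 2))
        assert f_obs == pytest.approx(max(f_all))
        res = permanova(dm, ["x"] * 4 + ["y"] * 4, n_perm=999, seed=1)
        assert res.pseudo_F == pytest.approx(f_obs)
        # only the 2/70 label patterns reproducing the split tie the observed F
        assert res.p < 0.06

    def test_exhaustive_enumeration_oracle(self):
        # p from seeded sampling approximates the exact enumeration p-value
        rng = np.random.Generator(np.random.PCG64(9))
        pts = rng.normal(size=(8, 2))
        pts[4:] += 0.8
        dm = _dm(pts)
        d2 = dm.data**2
        f_obs = _pseudo_f(d2, np.array([0] * 4 + [1] * 4), 2)
        n_ge = 0
        n_all = 0
        for members in itertools.combinations(range(8), 4):
            codes = np.ones(8, dtype=int)
            codes[list(members)] = 0
            n_all += 1
            if _pseudo_f(d2, codes, 2) >= f_obs - 1e-12:
                n_ge += 1
        exact_p = n_ge / n_all
        res = permanova(dm, ["x"] * 4 + ["y"] * 4, n_perm=1999, seed=2)
        assert abs(res.p - exact_p) < 0.1

    def test_skbio_pseudo_f_agreement(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.Generator(np.random.PCG64(13))
        pts = rng.normal(size=(9, 3))
        dm = _dm(pts)
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        mine = permanova(dm, groups, n_perm=99, seed=0)
        theirs = sk_permanova(
            skbio.DistanceMatrix(dm.data, ids=dm.ids), grouping=groups, permutations=99
        )
        assert mine.pseudo_F == pytest.approx(float(theirs["test statistic"]), rel=1e-9)

    def test_null_calibration_mean_p_near_half(self):
        rng = np.random.Generator(np.random.PCG64(17))
        ps = []
        for rep in range(20):
            pts = rng.normal(size=(10, 2))
            res = permanova(_dm(pts), ["a"] * 5 + ["b"] * 5, n_perm=99, seed=rep)
            ps.append(res.p)
        assert 0.3 < np.mean(ps) < 0.7

    def test_single_group_rejected(self):
        dm = _dm([[0, 0], [1, 0], [2, 0]])
        with pytest.raises(ValueError, match=">=2 groups"):
            permanova(dm, ["a", "a", "a"])

    def test_p_respects_floor(self):
        pts = np.vstack([np.zeros((4, 2)), np.full((4, 2), 50.0)])
        pts += np.arange(8)[:, None] * 0.01
        res = permanova(_dm(pts), ["x"] * 4 + ["y"] * 4, n_perm=99, seed=3)
        assert res.p >= 1.0 / 100


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        _, p = wilcoxon_ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_fully_separated_small_groups_exact(self):
        # only 1 of the C(6,3)=20 rank splits is as extreme: one-sided p = 0.05
        _, p = wilcoxon_ranksum([1, 2, 3], [4, 5, 6], alternative="less")
        assert p == pytest.approx(0.05)

    def test_enumeration_oracle_n4(self):
        rng = np.random.Generator(np.random.PCG64(23))
        x = rng.normal(size=4)
        y = rng.normal(size=4) + 0.5
        u_obs, p = wilcoxon_ranksum(x, y, alternative="two-sided")
        pooled = np.concatenate([x, y])
        ranks = pooled.argsort().argsort() + 1
        # exact two-sided p by enumerating all C(8,4) assignments of ranks to x
        n = len(pooled)
        u_null = []
        for members in itertools.combinations(range(n), 4):
            rx = ranks[list(members)].sum()
            u_null.append(rx - 4 * 5 / 2)
        u_null = np.array(u_null)
        mean_u = 4 * 4 / 2
        exact = np.mean(np.abs(u_null - mean_u) >= abs(u_obs - mean_u) - 1e-12)
        assert p == pytest.approx(exact)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum([], [1.0])


class TestReadsPerMillion:
    @pytest.mark.parametrize("n5, total, expected", [(690, 10**6, 690.0), (0, 100, 0.0)])
    def test_rate(self, n5, total, expected):
        assert pmds_reads_per_million(n5, total) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            pmds_reads_per_million(1, 0)

    def test_ancient_rich_sample_exceeds_blank(self, refs):
        from paleogut.alignio import parse_alignments
        from paleogut.damage import DamageModelParams, pmd_score
        from paleogut.simdata import SimConfig, simulate_reads
        import tempfile, os

        params = DamageModelParams()

        def rate(cfg):
            ds = simulate_reads(refs, cfg, params)
            with tempfile.TemporaryDirectory() as d:
                path = os.path.join(d, "x.sam")
                ds.write_sam(path)
                scores = [pmd_score(r, params).pmds for r in parse_alignments(path)]
            n5 = sum(1 for s in scores if s > 5)
            return pmds_reads_per_million(n5, len(scores))

        rich = rate(SimConfig(n_ancient=1500, n_modern=500, seed=29))
        blank = rate(SimConfig(n_ancient=0, n_modern=2000, seed=31, blank=True))
        assert rich > blank
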
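import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from ecoassembly import (
    betadisper,
    cailliez_constant,
    db_rda,
    ezekiel_adjusted_r2,
    pcoa,
    permanova,
    rda,
    variance_partition,
    vif_prune,
)


def euclidean_dm(points, ids=None):
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(np.asarray(points, dtype=float))), ids=ids)


@pytest.fixture
def non_euclidean_dm():
    """Bray–Curtis distances of random compositions are non-Euclidean.

    This fixture reproduces the configuration whose Cailliez constant was
    cross-checked against R's ape::pcoa (0.167064418259192)."""
    rng = np.random.default_rng(5)
    x = rng.dirichlet(np.ones(6), size=7)
    return DistanceMatrix(squareform(pdist(x, "braycurtis")), ids=[f"s{i}" for i in range(7)])


class TestPcoa:
    def test_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(9, 3))
        dm = euclidean_dm(pts)
        res = pcoa(dm, correction="none")
        coords = res.coordinates.to_numpy()
        recon = squareform(pdist(coords))
        assert np.allclose(recon, dm.data, atol=1e-9)

    def test_collinear_points_single_axis(self):
        dm = euclidean_dm([[0.0], [1.0], [2.0]])
        res = pcoa(dm, correction="none")
        assert res.proportions[0] == pytest.approx(1.0)
        d = np.abs(res.coordinates.iloc[:, 0].to_numpy())
        assert np.allclose(sorted(d), [0, 1, 1]) or np.allclose(
            np.abs(np.diff(res.coordinates.iloc[:, 0])), [1, 1]
        )

    def test_cailliez_zero_for_euclidean(self):
        rng = np.random.default_rng(1)
        dm = euclidean_dm(rng.normal(size=(8, 4)))
        assert cailliez_constant(dm) == 0.0

    def test_cailliez_constant_matches_ape(self, non_euclidean_dm):
        # value computed independently with R ape::pcoa(correction="cailliez")
        assert cailliez_constant(non_euclidean_dm) == pytest.approx(0.167064418259192, abs=1e-9)

    def test_correction_removes_negative_eigenvalues(self, non_euclidean_dm):
        raw = pcoa(non_euclidean_dm, correction="none")
        assert raw.eigenvalues.min() < -1e-6
        fixed = pcoa(non_euclidean_dm, correction="cailliez")
        assert fixed.eigenvalues.min() > -1e-8
        assert fixed.cailliez_constant_ > 0

    def test_matches_skbio_eigenvalues(self):
        rng = np.random.default_rng(2)
        dm = euclidean_dm(rng.normal(size=(7, 3)))
        mine = pcoa(dm, correction="none")
        ref = skbio_pcoa(dm)
        k = len(mine.proportions)
        assert np.allclose(mine.eigenvalues[:k], ref.eigvals.to_numpy()[:k], atol=1e-9)

    def test_asymmetric_input_rejected(self):
        bad = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            pcoa(bad, correction="none")


class TestPermanova:
    def test_perfect_separation(self):
        # groups big enough that a random permutation essentially never
        # reproduces the partition, so p sits at its 1/(n_perm+1) boundary
        pts = [[0, 0]] * 10 + [[10, 10]] * 10
        dm = euclidean_dm(pts)
        md = pd.DataFrame({"grp": ["a"] * 10 + ["b"] * 10}, index=dm.ids)
        res = permanova(dm, md, ["grp"], n_perm=99, seed=0)
        assert res.table.loc["grp", "r2"] == pytest.approx(1.0)
        # p sits at the 1/(n_perm+1) boundary except for the (rare)
        # partition-preserving permutations, which legitimately tie
        assert res.table.loc["grp", "p_value"] <= 3 / 100

    def test_pseudo_f_matches_skbio_single_factor(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 3))
        pts[:6] += 1.0
        dm = euclidean_dm(pts)
        groups = ["a"] * 6 + ["b"] * 6
        md = pd.DataFrame({"grp": groups}, index=dm.ids)
        mine = permanova(dm, md, ["grp"], n_perm=9, seed=0)
        ref = skbio_permanova(dm, grouping=groups, permutations=9)
        assert mine.table.loc["grp", "pseudo_f"] == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_r2_sums_to_one(self):
        rng = np.random.default_rng(4)
        dm = euclidean_dm(rng.normal(size=(16, 4)))
        md = pd.DataFrame(
            {
                "f1": ["a", "b"] * 8,
                "f2": ["x"] * 8 + ["y"] * 8,
                "cov": rng.normal(size=16),
            },
            index=dm.ids,
        )
        res = permanova(dm, md, ["f1", "f2", "cov"], n_perm=9, seed=0)
        r2 = res.table.drop(index="Total")["r2"].sum()
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_euclidean_equivalence_with_classical_decomposition(self):
        # single factor on a Euclidean distance matrix == SS decomposition
        # computed directly from the coordinates
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 3))
        groups = np.array(["a"] * 5 + ["b"] * 5)
        dm = euclidean_dm(pts)
        md = pd.DataFrame({"grp": groups}, index=dm.ids)
        res = permanova(dm, md, ["grp"], n_perm=9, seed=0)
        centered = pts - pts.mean(axis=0)
        ss_total = (centered**2).sum()
        ss_within = sum(
            ((pts[groups == g] - pts[groups == g].mean(axis=0)) ** 2).sum() for g in "ab"
        )
        assert res.table.loc["grp", "r2"] == pytest.approx(1 - ss_within / ss_total, abs=1e-10)

    def test_single_level_term_rejected(self):
        dm = euclidean_dm(np.random.default_rng(0).normal(size=(6, 2)))
        md = pd.DataFrame({"grp": ["a"] * 6}, index=dm.ids)
        with pytest.raises(ValueError, match="single level"):
            permanova(dm, md, ["grp"], n_perm=9)


class TestBetadisper:
    def test_equal_dispersion_not_significant(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(15, 2))
        dm = euclidean_dm(np.vstack([a, a + 20.0]))  # mirror-image groups
        groups = pd.Series(["a"] * 15 + ["b"] * 15, index=dm.ids)
        res = betadisper(dm, groups, n_perm=199, seed=0)
        assert res.p_value > 0.1

    def test_inflated_group_detected(self):
        rng = np.random.default_rng(7)
        hits = 0
        for rep in range(8):
            a = rng.normal(size=(20, 2))
            b = rng.normal(size=(20, 2)) * 3.0
            dm = euclidean_dm(np.vstack([a, b + 50]))
            groups = pd.Series(["a"] * 20 + ["b"] * 20, index=dm.ids)
            res = betadisper(dm, groups, n_perm=199, seed=rep)
            hits += res.p_value < 0.05
        assert hits >= 6

    def test_identical_samples_degenerate(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        res = betadisper(dm, pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd")), n_perm=9)
        assert res.degenerate


class TestVifPrune:
    def test_orthogonal_predictors_untouched(self):
        rng = np.random.default_rng(8)
        q, _ = np.linalg.qr(rng.normal(size=(30, 3)))
        x = pd.DataFrame(q, columns=["p1", "p2", "p3"])
        res = vif_prune(x, threshold=10)
        assert res.retained == ["p1", "p2", "p3"]
        # orthogonality is broken only by centering, so VIFs sit at ~1
        assert np.allclose(res.final_vifs, 1.0, atol=1e-2)

    def test_duplicated_column_removed_first(self):
        rng = np.random.default_rng(9)
        x = pd.DataFrame({"a": rng.normal(size=25), "b": rng.normal(size=25)})
        x["a_copy"] = x["a"]
        res = vif_prune(x, threshold=10)
        assert len(res.retained) == 2
        assert res.removed[0][0] in ("a", "a_copy")
        assert not np.isfinite(res.removed[0][1]) or res.removed[0][1] > 1e6

    def test_near_collinear_trio_pruned(self):
        rng = np.random.default_rng(10)
        x1, x2 = rng.normal(size=25), rng.normal(size=25)
        x3 = x1 + x2 + rng.normal(scale=0.01, size=25)
        x = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        res = vif_prune(x, threshold=10)
        assert len(res.retained) == 2
        assert (res.final_vifs < 10).all()


class TestConstrainedOrdination:
    def test_ezekiel_spot_value(self):
        assert ezekiel_adjusted_r2(0.5, 21, 4) == pytest.approx(0.375)

    def test_perfect_linear_response_r2_one(self):
        rng = np.random.default_rng(11)
        x = pd.DataFrame(rng.normal(size=(20, 2)), columns=["u", "v"])
        y = x.to_numpy() @ np.array([[1.0, 0.3], [0.2, -1.0]])
        dm = euclidean_dm(y, ids=list(x.index.astype(str)))
        x.index = list(dm.ids)
        res = db_rda(dm, x, n_perm=99, seed=0)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert res.adjusted_r2 == pytest.approx(1.0, abs=1e-9)
        assert res.p_overall == pytest.approx(1 / 100)

    def test_saturated_model_rejected(self):
        rng = np.random.default_rng(12)
        dm = euclidean_dm(rng.normal(size=(5, 2)))
        x = pd.DataFrame(rng.normal(size=(5, 4)), index=list(dm.ids))
        with pytest.raises(ValueError, match="saturated"):
            db_rda(dm, x, n_perm=0)

    def test_rda_single_response_equals_ols(self):
        rng = np.random.default_rng(13)
        x = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        y = pd.DataFrame({"resp": x["a"] * 2 - x["b"] + rng.normal(size=30)})
        res = rda(y, x, n_perm=0)
        # OLS oracle
        xz = (x - x.mean()) / x.std(ddof=1)
        xm = np.hstack([np.ones((30, 1)), xz.to_numpy()])
        yz = ((y - y.mean()) / y.std(ddof=1)).to_numpy()
        beta, *_ = np.linalg.lstsq(xm, yz, rcond=None)
        resid = yz - xm @ beta
        r2 = 1 - (resid**2).sum() / (yz**2).sum()
        assert res.r2 == pytest.approx(r2, abs=1e-12)

    def test_duplicate_responses_rank_one(self):
        rng = np.random.default_rng(14)
        x = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        base = x["a"] + rng.normal(size=20)
        y = pd.DataFrame({"r1": base, "r2": base})
        res = rda(y, x, n_perm=0)
        assert len(res.eigenvalues) == 1

    def test_rda_recovers_planted_predictor(self):
        rng = np.random.default_rng(15)
        sal = rng.uniform(0, 34, 30)
        other = rng.normal(size=30)
        y = pd.DataFrame({"diss": 0.8 * np.abs(sal - 17) / 17 + rng.normal(scale=0.05, size=30)})
        x = pd.DataFrame({"sal_mid": np.abs(sal - 17), "other": other})
        res = rda(y, x, n_perm=0)
        loadings = res.biplot_scores["CAP1"].abs()
        assert loadings["sal_mid"] > loadings["other"]


class TestVariancePartition:
    def _setup(self, seed=16, n=40):
        rng = np.random.default_rng(seed)
        x = pd.DataFrame(
            rng.normal(size=(n, 4)), columns=["a1", "a2", "b1", "b2"],
            index=[f"s{i}" for i in range(n)],
        )
        y = np.column_stack(
            [x["a1"] + rng.normal(scale=0.3, size=n), x["b1"] + rng.normal(scale=0.3, size=n)]
        )
        dm = euclidean_dm(y, ids=list(x.index))
        return dm, x

    def test_single_group_unique_equals_adjusted_r2(self):
        dm, x = self._setup()
        vp = variance_partition(dm, x, {"ga": ["a1", "a2"]})
        full = db_rda(dm, x[["a1", "a2"]], n_perm=0).adjusted_r2
        assert vp.unique("ga") == pytest.approx(full, abs=1e-12)
        assert vp.residual == pytest.approx(1 - full, abs=1e-12)

    def test_duplicate_groups_share_everything(self):
        dm, x = self._setup()
        x2 = x.copy()
        x2["a1_dup"] = x2["a1"]
        x2["a2_dup"] = x2["a2"]
        vp = variance_partition(
            dm, x2, {"g1": ["a1", "a2"], "g2": ["a1_dup", "a2_dup"]}
        )
        shared = vp.cells[frozenset(["g1", "g2"])]
        assert abs(vp.unique("g1")) < 0.02
        assert abs(vp.unique("g2")) < 0.02
        assert shared == pytest.approx(vp.total_adjusted_r2, abs=0.03)

    def test_orthogonal_groups_share_nothing(self):
        # larger n so the finite-sample adjustment penalty differences vanish
        dm, x = self._setup(n=150)
        vp = variance_partition(dm, x, {"ga": ["a1", "a2"], "gb": ["b1", "b2"]})
        assert abs(vp.cells[frozenset(["ga", "gb"])]) < 0.02

    def test_cells_sum_to_total(self):
        dm, x = self._setup()
        vp = variance_partition(
            dm, x, {"ga": ["a1"], "gb": ["a2", "b1"], "gc": ["b2"]}
        )
        assert sum(vp.cells.values()) == pytest.approx(vp.total_adjusted_r2, abs=1e-9)

    def test_overlapping_groups_rejected(self):
        dm, x = self._setup()
        with pytest.raises(ValueError, match="more than one group"):
            variance_partition(dm, x, {"g1": ["a1", "a2"], "g2": ["a2"]})
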
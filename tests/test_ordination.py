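"""Ordination tests: Hellinger, Bray-Curtis, NMDS, ANOSIM."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from casecomm.ordination import (
    DissimilarityMatrix,
    anosim,
    bray_curtis,
    hellinger,
    nmds,
)

def dm_from_points(points: np.ndarray, ids=None) -> DissimilarityMatrix:
    ids = ids or [f"p{i}" for i in range(len(points))]
    return DissimilarityMatrix(ids=ids, values=squareform(pdist(points)))


class TestHellinger:
    def test_hand_example(self):
        mat = pd.DataFrame({"f1": [1.0], "f2": [3.0]}, index=["s"])
        out = hellinger(mat)
        assert out.loc["s", "f1"] == pytest.approx(0.5)
        assert out.loc["s", "f2"] == pytest.approx(np.sqrt(0.75), abs=1e-4)

    def test_single_feature_sample(self):
        mat = pd.DataFrame({"f1": [7.0]}, index=["s"])
        assert hellinger(mat).loc["s", "f1"] == 1.0

    def test_rows_have_unit_l2_norm(self, rarefied):
        out = hellinger(rarefied)
        norms = (out**2).sum(axis=1)
        assert np.allclose(norms, 1.0)

    def test_zero_total_sample_raises(self):
        mat = pd.DataFrame({"f1": [0.0, 1.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            hellinger(mat)


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        mat = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [0.0, 5.0]],
                           index=["a", "b", "c"], columns=["f1", "f2"])
        dm = bray_curtis(mat)
        assert dm.to_frame().loc["a", "b"] == 0.0
        disjoint = pd.DataFrame([[3.0, 0.0], [0.0, 4.0]], index=["a", "b"])
        assert bray_curtis(disjoint).to_frame().loc["a", "b"] == 1.0

    def test_hand_example(self):
        mat = pd.DataFrame([[2.0, 1.0], [1.0, 3.0]], index=["a", "b"])
        assert bray_curtis(mat).to_frame().loc["a", "b"] == pytest.approx(3 / 7, abs=1e-6)

    def test_bounded_symmetric_zero_diagonal(self, rarefied):
        dm = bray_curtis(hellinger(rarefied))
        v = dm.values
        assert (v >= 0).all() and (v <= 1 + 1e-12).all()
        assert np.allclose(v, v.T) and np.allclose(np.diag(v), 0)

    def test_depth_scaling_invariance_via_hellinger(self):
        counts = pd.DataFrame([[10, 30, 60], [20, 20, 60]], index=["a", "b"],
                              columns=list("xyz"), dtype=float)
        d1 = bray_curtis(hellinger(counts))
        d2 = bray_curtis(hellinger(counts * [7, 3][0] * 1.0))
        scaled = counts.copy()
        scaled.loc["a"] *= 11  # per-sample depth change
        d3 = bray_curtis(hellinger(scaled))
        assert d1.values == pytest.approx(d2.values)
        assert d1.values == pytest.approx(d3.values)

    def test_two_all_zero_samples_error(self):
        mat = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 2.0]],
                           index=["a", "b", "c"])
        with pytest.raises(ValueError):
            bray_curtis(mat)


class TestNmds:
    def test_planar_configuration_embeds_exactly(self):
        rng = np.random.default_rng(4)
        points = rng.normal(size=(4, 2))
        res = nmds(dm_from_points(points), k=2, n_starts=5, seed=0)
        assert res.stress < 1e-3

    def test_three_points_always_embed(self):
        points = np.array([[0.0, 0.0], [1.0, 0.2], [0.3, 2.0]])
        res = nmds(dm_from_points(points), k=2, n_starts=3, seed=1)
        assert res.stress < 1e-6

    def test_stress_trace_non_increasing(self):
        rng = np.random.default_rng(9)
        points = rng.normal(size=(12, 4))
        res = nmds(dm_from_points(points), k=2, n_starts=3, seed=2)
        trace = np.array(res.stress_trace)
        assert (np.diff(trace) <= 1e-8).all()

    def test_too_few_samples_for_k_raises(self):
        points = np.random.default_rng(0).normal(size=(2, 2))
        with pytest.raises(ValueError):
            nmds(dm_from_points(points), k=2)

    def test_stage_structure_separates(self, rarefied, meta_by_sample):
        from sklearn.metrics import silhouette_score

        casing = [s for s in rarefied.sample_ids
                  if meta_by_sample[s].compartment == "casing_soil"
                  and meta_by_sample[s].treatment == "normal"]
        sub = rarefied.counts[casing]
        dm = bray_curtis(hellinger(sub.T))
        res = nmds(dm, k=2, n_starts=10, seed=3)
        stages = [meta_by_sample[s].stage for s in dm.ids]
        assert silhouette_score(res.coordinates.to_numpy(), stages) > 0


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        # two tight, far-apart clusters
        a = np.zeros((4, 2))
        b = np.ones((4, 2)) * 10 + np.arange(8).reshape(4, 2) * 0.01
        a += np.arange(8).reshape(4, 2) * 0.01
        dm = dm_from_points(np.vstack([a, b]))
        res = anosim(dm, ["A"] * 4 + ["B"] * 4, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p <= 0.05

    def test_duplicated_groups_not_separated(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(5, 3))
        both = np.vstack([pts, pts + rng.normal(0, 1e-9, pts.shape)])
        dm = dm_from_points(both)
        res = anosim(dm, ["A"] * 5 + ["B"] * 5, n_perm=99, seed=0)
        assert res.r <= 0.0 + 1e-9

    def test_matches_skbio(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.stats.distance import anosim as skbio_anosim

        rng = np.random.default_rng(6)
        pts = rng.normal(size=(12, 3))
        pts[6:] += 0.8
        dm = dm_from_points(pts)
        groups = ["A"] * 6 + ["B"] * 6
        ours = anosim(dm, groups, n_perm=999, seed=0)
        ref = skbio_anosim(SkbioDM(dm.values, ids=dm.ids), grouping=groups,
                           permutations=999)
        assert ours.r == pytest.approx(ref["test statistic"], abs=1e-12)
        # p-values are permutation estimates from different RNG streams
        assert ours.p == pytest.approx(ref["p-value"], abs=0.05)

    def test_group_of_one_raises(self):
        dm = dm_from_points(np.random.default_rng(0).normal(size=(4, 2)))
        with pytest.raises(ValueError):
            anosim(dm, ["A", "A", "A", "B"])

    def test_stage_signal_on_synthetic_communities(self, rarefied, meta_by_sample):
        dm = bray_curtis(hellinger(rarefied))
        groups = [f"{meta_by_sample[s].stage}/{meta_by_sample[s].compartment}"
                  for s in dm.ids]
        res = anosim(dm, groups, n_perm=199, seed=1)
        assert res.r > 0.8
        assert res.p <= 0.01


class TestDissimilarityMatrixIO:
    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        dm = dm_from_points(rng.normal(size=(5, 2)))
        path = tmp_path / "dm.tsv"
        dm.write_tsv(path)
        back = DissimilarityMatrix.read_tsv(path)
        assert back.ids == dm.ids
        assert back.values == pytest.approx(dm.values, abs=1e-9)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            DissimilarityMatrix(ids=["a", "b"], values=np.array([[0, 1], [0.5, 0]]))
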
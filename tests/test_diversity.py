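"""Alpha/beta diversity against closed forms, enumeration oracles and skbio."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gutliver as gl
from gutliver._rng import substream


class TestAlpha:
    @pytest.mark.parametrize("p,expected", [
        ([0.25, 0.25, 0.25, 0.25], math.log(4)),
        ([1.0, 0.0, 0.0], 0.0),
        ([0.5, 0.25, 0.25], 1.5 * math.log(2)),
    ])
    def test_shannon_closed_forms(self, p, expected):
        assert gl.shannon(p) == pytest.approx(expected, abs=1e-12)

    def test_shannon_all_zero_flagged(self):
        assert math.isnan(gl.shannon([0.0, 0.0]))

    def test_evenness_uniform_is_one(self):
        for s in (2, 5, 17):
            assert gl.evenness([1.0 / s] * s) == pytest.approx(1.0, abs=1e-12)

    def test_evenness_skewed_below_one(self):
        p = [0.97, 0.01, 0.01, 0.01]
        h = -sum(x * math.log(x) for x in p)
        assert gl.evenness(p) == pytest.approx(h / math.log(4), abs=1e-12)
        assert gl.evenness(p) < 1.0

    def test_evenness_degenerate_richness_flagged(self):
        assert math.isnan(gl.evenness([1.0, 0.0]))

    def test_oracle_equivalence_random_compositions(self):
        rng = substream(0, "alpha_oracle")
        for _ in range(200):
            p = rng.dirichlet(np.ones(rng.integers(2, 12)))
            h_oracle = -sum(x * math.log(x) for x in p if x > 0)
            assert abs(gl.shannon(p) - h_oracle) < 1e-12
            s = int((p > 0).sum())
            if s > 1:
                assert abs(gl.evenness(p) - h_oracle / math.log(s)) < 1e-12


class TestBrayCurtis:
    def test_identity_and_disjoint(self):
        assert gl.bray_curtis([0.2, 0.8], [0.2, 0.8]) == 0.0
        assert gl.bray_curtis([1.0, 0.0], [0.0, 1.0]) == 1.0

    def test_hand_evaluation(self):
        assert gl.bray_curtis([0.5, 0.5, 0], [0.25, 0.25, 0.5]) == pytest.approx(0.5)

    def test_both_zero_flagged(self):
        assert math.isnan(gl.bray_curtis([0.0], [0.0]))

    def test_matrix_properties(self, mixed_table):
        dm = gl.bray_curtis_matrix(mixed_table.to_relative())
        m = dm.to_numpy()
        assert np.allclose(m, m.T, atol=1e-12)
        assert np.allclose(np.diag(m), 0.0)
        assert (m >= 0).all() and (m <= 1).all()


class TestMannWhitney:
    def test_exact_enumeration_example(self):
        # fully separated n=3 vs n=3: one-sided 1/20, two-sided 0.1
        assert gl.mann_whitney([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_label_swap_symmetry(self):
        rng = substream(1, "mw")
        x, y = rng.normal(size=8), rng.normal(size=11)
        assert gl.mann_whitney(x, y) == pytest.approx(gl.mann_whitney(y, x))

    def test_degenerate_identical_values(self):
        assert gl.mann_whitney([2, 2, 2], [2, 2, 2]) == 1.0


def _permanova_oracle(dm, labels):
    """Brute-force exhaustive PERMANOVA p: direct SS computation per perm."""
    labels = np.asarray(labels)
    n = len(labels)

    def pseudo_f(lab):
        groups = np.unique(lab)
        k = len(groups)
        ss_total = sum(dm[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
        ss_within = 0.0
        for g in groups:
            idx = [i for i in range(n) if lab[i] == g]
            ss_within += sum(dm[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
        return ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))

    f_obs = pseudo_f(labels)
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if pseudo_f(labels[list(perm)]) >= f_obs - 1e-12:
            hits += 1
    return f_obs, hits / total


class TestPermanova:
    @pytest.fixture
    def clustered(self):
        rng = substream(2, "clusters")
        a = rng.normal(0.0, 0.05, size=(10, 3))
        b = rng.normal(3.0, 0.05, size=(10, 3))
        pts = np.vstack([a, b])
        dm = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        labels = np.array(["a"] * 10 + ["b"] * 10)
        return dm, labels

    def test_relabeling_invariance(self, clustered):
        dm, labels = clustered
        res = gl.permanova(dm, labels, n_perm=99, seed=0)
        perm = substream(3, "shuffle").permutation(len(labels))
        res2 = gl.permanova(dm[np.ix_(perm, perm)], labels[perm], n_perm=99, seed=0)
        assert res2.f == pytest.approx(res.f, rel=1e-12)

    def test_separated_clusters(self, clustered):
        dm, labels = clustered
        res = gl.permanova(dm, labels, n_perm=999, seed=5)
        assert res.p == pytest.approx(1 / 1000)
        assert res.r2 > 0.9

    def test_exact_matches_enumeration_oracle_n6(self):
        rng = substream(4, "exact6")
        pts = rng.normal(size=(6, 2))
        dm = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        res = gl.permanova(dm, labels, n_perm="exact")
        f_oracle, p_oracle = _permanova_oracle(dm, labels)
        assert res.f == pytest.approx(f_oracle, rel=1e-10)
        assert res.p == p_oracle
        assert res.n_permutations == 720

    def test_r2_invariant_to_distance_scaling(self, clustered):
        dm, labels = clustered
        r1 = gl.permanova(dm, labels, n_perm=9, seed=0).r2
        r2 = gl.permanova(3.7 * dm, labels, n_perm=9, seed=0).r2
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_matches_skbio_f_statistic(self, clustered):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        dm, labels = clustered
        ours = gl.permanova(dm, labels, n_perm=99, seed=0)
        theirs = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(dm), list(labels), permutations=99)
        assert ours.f == pytest.approx(float(theirs["test statistic"]), rel=1e-9)

    def test_group_too_small_errors(self):
        dm = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="fewer than 2"):
            gl.permanova(dm, ["a", "a", "b"], n_perm=9, seed=0)

    def test_constant_distances_flagged_degenerate(self):
        dm = np.ones((6, 6)) * 0.0
        res = gl.permanova(dm, ["a"] * 3 + ["b"] * 3, n_perm=9, seed=0)
        assert res.degenerate and math.isnan(res.f)


class TestPairwisePermanova:
    def test_three_groups_three_records(self, mixed_table):
        beta = gl.beta_diversity_report(mixed_table, "feces", n_perm=49, seed=0)
        assert len(beta.pairwise) == 3
        assert set(beta.pairwise["group1"]).issubset(set(gl.GROUPS))

    def test_displaced_group_pattern(self):
        """One displaced group: its two pairs significant, the third not."""
        rng = substream(6, "displaced")
        a = rng.normal(0, 0.1, size=(8, 3))
        b = rng.normal(0, 0.1, size=(8, 3))
        c = rng.normal(4, 0.1, size=(8, 3))
        pts = np.vstack([a, b, c])
        dm = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        labels = np.repeat(["a", "b", "c"], 8)
        pw = gl.pairwise_permanova(dm, labels, n_perm=199, seed=0).set_index(
            ["group1", "group2"])
        assert pw.loc[("a", "c"), "p"] <= 0.05
        assert pw.loc[("b", "c"), "p"] <= 0.05
        assert pw.loc[("a", "b"), "p"] > 0.05


@given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=8))
def test_shannon_invariant_to_normalization_route(weights):
    """H computed from normalized weights equals the direct-sum oracle."""
    w = np.asarray(weights)
    p = w / w.sum()
    h_oracle = -sum(x * math.log(x) for x in p if x > 0)
    assert gl.shannon(p) == pytest.approx(h_oracle, abs=1e-12)
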
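import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import rumenstab as rs
from rumenstab import diversity as dv


class TestShannon:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([1, 1, 1, 1], np.log(4)),
            ([0, 7, 0], 0.0),
            ([1, 1, 2], -(2 * 0.25 * np.log(0.25) + 0.5 * np.log(0.5))),
        ],
    )
    def test_known_values(self, row, expected):
        assert dv.shannon_index(row) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "row, expected",
        [
            ([3, 3, 3, 3, 3], 1.0),
            ([0, 9, 0], 0.0),
            ([1, 1, 2], 1.0397207708399179 / np.log(3)),
        ],
    )
    def test_adjusted_known_values(self, row, expected):
        assert dv.adjusted_shannon(row) == pytest.approx(expected, abs=1e-6)

    def test_adjusted_scale_invariance(self, rng):
        row = rng.integers(0, 50, size=30)
        row[0] = 3
        assert dv.adjusted_shannon(row) == pytest.approx(
            dv.adjusted_shannon(row * 13), abs=1e-12
        )

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            dv.shannon_index([0, 0])


class TestAlphaTimepointTest:
    def test_zero_animal_variance_reduces_to_anova(self, balanced_meta, rng):
        from scipy.stats import f_oneway

        # pure noise: no animal effect; Wald p should track one-way ANOVA
        y = rng.standard_normal(len(balanced_meta))
        res = dv.alpha_timepoint_test(y, balanced_meta)
        groups = [
            y[(balanced_meta["timepoint"] == f"T{t}").to_numpy()] for t in range(1, 7)
        ]
        f, p_anova = f_oneway(*groups)
        assert res.p == pytest.approx(p_anova, abs=0.05)

    def test_planted_shift_flags_right_pairs(self, balanced_meta, rng):
        uid = pd.factorize(balanced_meta["animal_id"])[0]
        y = rng.standard_normal(20)[uid] * 0.3 + rng.standard_normal(len(balanced_meta)) * 0.2
        y = y + 2.0 * (balanced_meta["timepoint"] == "T6").to_numpy(float)
        res = dv.alpha_timepoint_test(y, balanced_meta)
        assert res.p < 0.05
        tab = res.pairwise.sort_values("p_adj")
        t6_pairs = tab["pair"].str.contains("T6")
        # every contrast involving the shifted timepoint is significant and
        # ranks ahead of all null contrasts
        assert (tab.loc[t6_pairs, "p_adj"] < 0.05).all()
        assert t6_pairs.head(5).all()

    def test_single_timepoint_raises(self):
        meta = pd.DataFrame({"animal_id": ["a", "b"], "timepoint": ["T1", "T1"]})
        with pytest.raises(ValueError):
            dv.alpha_timepoint_test([1.0, 2.0], meta)


class TestBrayCurtis:
    def test_known_values(self):
        counts = pd.DataFrame([[6, 0, 2], [2, 2, 0], [6, 0, 2]])
        D = dv.bray_curtis_matrix(counts)
        assert D.iloc[0, 1] == pytest.approx(8 / 12)
        assert D.iloc[0, 2] == 0.0
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)

    def test_disjoint_supports_give_one(self):
        D = dv.bray_curtis_matrix(pd.DataFrame([[5, 0], [0, 3]]))
        assert D.iloc[0, 1] == pytest.approx(1.0)

    def test_zero_sum_row_raises(self):
        with pytest.raises(ValueError):
            dv.bray_curtis_matrix(pd.DataFrame([[1, 1], [0, 0]]))


def exhaustive_permanova(D, groups):
    """Brute-force oracle: F, R2 and the exact enumeration p over all
    distinct label assignments."""
    D = np.asarray(D, float)
    groups = np.asarray(groups)
    n = len(groups)

    def f_and_r2(labels):
        labs = np.unique(labels)
        a = len(labs)
        d2 = D * D
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for g in labs:
            idx = np.where(labels == g)[0]
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ss_between = ss_total - ss_within
        f = (ss_between / (a - 1)) / (ss_within / (n - a))
        return f, ss_between / ss_total

    f_obs, r2 = f_and_r2(groups)
    count = total = 0
    for perm in set(itertools.permutations(range(n))):
        labels = groups[list(perm)]
        total += 1
        if f_and_r2(labels)[0] >= f_obs - 1e-12:
            count += 1
    return f_obs, r2, count / total


class TestPermanova:
    @pytest.fixture()
    def toy(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (3, 4)), rng.normal(1.5, 1, (3, 4))])
        D = squareform(pdist(np.abs(X), "braycurtis"))
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        return D, groups

    def test_matches_exhaustive_oracle(self, toy):
        D, groups = toy
        f_oracle, r2_oracle, p_exact = exhaustive_permanova(D, groups)
        res = dv.permanova(D, groups, n_permutations=999, seed=1)
        assert res.pseudo_f == pytest.approx(f_oracle, abs=1e-10)
        assert res.r2 == pytest.approx(r2_oracle, abs=1e-10)
        # permutation p converges to the exact enumeration value
        assert res.p == pytest.approx(p_exact, abs=0.05)

    def test_matches_skbio(self, toy):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        D, groups = toy
        dm = skbio.DistanceMatrix(D, ids=[str(i) for i in range(6)])
        sk = sk_permanova(dm, grouping=list(groups), permutations=99)
        res = dv.permanova(D, groups, n_permutations=99, seed=0)
        assert res.pseudo_f == pytest.approx(float(sk["test statistic"]), abs=1e-8)

    def test_ss_decomposition(self, toy):
        D, groups = toy
        d2 = D * D
        n = len(groups)
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        res = dv.permanova(D, groups, n_permutations=9, seed=0)
        a = 2
        ss_between = res.r2 * ss_total
        ss_within = ss_total - ss_between
        assert res.pseudo_f == pytest.approx(
            (ss_between / (a - 1)) / (ss_within / (n - a)), abs=1e-9
        )

    def test_identical_samples_degenerate(self):
        D = np.zeros((6, 6))
        res = dv.permanova(D, ["a"] * 3 + ["b"] * 3, n_permutations=99, seed=0)
        assert res.degenerate
        assert res.p == 1.0

    def test_seeded_reproducibility(self, toy):
        D, groups = toy
        p1 = dv.permanova(D, groups, n_permutations=199, seed=7).p
        p2 = dv.permanova(D, groups, n_permutations=199, seed=7).p
        assert p1 == p2


class TestPairwisePermanova:
    def test_only_shifted_group_flagged(self, rng):
        X = np.vstack(
            [rng.lognormal(0, 0.2, (8, 10)), rng.lognormal(0, 0.2, (8, 10)),
             rng.lognormal(1.5, 0.2, (8, 10))]
        )
        D = squareform(pdist(X, "braycurtis"))
        groups = np.repeat(["A", "B", "C"], 8)
        tab = dv.pairwise_permanova(D, groups, n_permutations=199, seed=2)
        sig = set(tab.loc[tab["p_adj"] < 0.05, "pair"])
        assert sig == {"A-C", "B-C"}

    def test_two_groups_pair_equals_full(self, rng):
        X = rng.lognormal(0, 0.5, (10, 6))
        D = squareform(pdist(X, "braycurtis"))
        groups = np.repeat(["A", "B"], 5)
        tab = dv.pairwise_permanova(D, groups, n_permutations=99, seed=0)
        full = dv.permanova(D, groups, n_permutations=99, seed=0)
        assert len(tab) == 1
        assert tab["r2"].iloc[0] == pytest.approx(full.r2, abs=1e-12)

    def test_identical_groups_p_capped_at_one(self):
        rng = np.random.default_rng(1)
        X = rng.lognormal(0, 0.3, (6, 5))
        D = squareform(pdist(np.vstack([X, X, X]), "braycurtis"))
        groups = np.repeat(["A", "B", "C"], 6)
        tab = dv.pairwise_permanova(D, groups, n_permutations=49, seed=0)
        assert (tab["p_adj"] <= 1.0).all()


class TestPermdisp:
    def test_identical_groups_f_near_zero(self, rng):
        X = rng.lognormal(0, 0.4, (6, 5))
        D = squareform(pdist(np.vstack([X, X]), "braycurtis"))
        f, p = dv.permdisp(D, np.repeat(["a", "b"], 6), n_permutations=99, seed=0)
        assert f == pytest.approx(0.0, abs=1e-9)

    def test_inflated_dispersion_detected(self, rng):
        hits = 0
        for r in range(10):
            a = rng.normal(0, 0.3, (10, 4))
            b = rng.normal(0, 3.0, (10, 4))
            D = squareform(pdist(np.vstack([a, b])))
            f, p = dv.permdisp(D, np.repeat(["a", "b"], 10), n_permutations=199, seed=r)
            hits += p < 0.05
        assert hits >= 6

    def test_equal_dispersion_not_over_rejected(self, rng):
        hits = 0
        for r in range(20):
            X = rng.normal(0, 1.0, (20, 4))
            D = squareform(pdist(X))
            f, p = dv.permdisp(D, np.repeat(["a", "b"], 10), n_permutations=99, seed=r)
            hits += p < 0.05
        assert hits <= 4


class TestNmds:
    def test_perfect_recovery_of_euclidean_points(self, rng):
        pts = rng.standard_normal((9, 2))
        D = squareform(pdist(pts))
        res = dv.nmds(D, k=2, n_restarts=2, seed=1)
        assert res.stress < 0.01

    def test_best_of_restarts(self, rng):
        X = rng.lognormal(0, 0.8, (10, 6))
        D = squareform(pdist(X, "braycurtis"))
        res = dv.nmds(D, k=2, n_restarts=3, seed=2)
        assert res.stress <= min(res.restart_stresses) + 1e-12

    def test_stress_formula_matches_pava_oracle(self, rng):
        # kruskal_stress cross-checked against a hand-rolled
        # pool-adjacent-violators isotonic fit
        def pava(y):
            y = list(map(float, y))
            w = [1.0] * len(y)
            blocks = [[v, wt] for v, wt in zip(y, w)]
            i = 0
            while i < len(blocks) - 1:
                if blocks[i][0] > blocks[i + 1][0] + 1e-15:
                    v = (
                        blocks[i][0] * blocks[i][1] + blocks[i + 1][0] * blocks[i + 1][1]
                    ) / (blocks[i][1] + blocks[i + 1][1])
                    blocks[i] = [v, blocks[i][1] + blocks[i + 1][1]]
                    del blocks[i + 1]
                    i = max(0, i - 1)
                else:
                    i += 1
            out = []
            for v, wt in blocks:
                out.extend([v] * int(wt))
            return np.array(out)

        pts = rng.standard_normal((7, 2))
        conf = pts + rng.standard_normal((7, 2)) * 0.3
        D = squareform(pdist(pts))
        iu = np.triu_indices(7, 1)
        order = np.argsort(D[iu], kind="stable")
        d = squareform(pdist(conf))[iu]
        dhat = np.empty_like(d)
        dhat[order] = pava(d[order])
        expected = np.sqrt(((d - dhat) ** 2).sum() / (d * d).sum())
        assert dv.kruskal_stress(D, conf) == pytest.approx(expected, abs=1e-9)

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            dv.nmds(np.zeros((3, 3)), k=3)
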
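import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microlake import (
    anova_tukey,
    bh_adjust,
    bray_curtis,
    env_correlation,
    kruskal_per_taxon,
    pcoa,
    permanova,
    shannon,
)
from microlake.diversity import compact_letters
from microlake.io import RelAbundTable


def rel(arr, taxa, samples):
    return RelAbundTable(pd.DataFrame(arr, index=taxa, columns=samples))


class TestShannon:
    def test_single_taxon_zero(self):
        assert shannon(rel([[1.0]], ["a"], ["s"]))["s"] == 0.0

    def test_uniform_closed_form(self):
        r = rel(np.full((10, 1), 0.1), [f"t{i}" for i in range(10)], ["s"])
        assert shannon(r)["s"] == pytest.approx(np.log(10), abs=1e-12)

    def test_hand_value(self):
        r = rel([[0.5], [0.3], [0.2]], list("abc"), ["s"])
        expected = -(0.5 * np.log(0.5) + 0.3 * np.log(0.3) + 0.2 * np.log(0.2))
        assert shannon(r)["s"] == pytest.approx(expected, abs=1e-12)
        assert shannon(r)["s"] == pytest.approx(1.02965, abs=1e-5)

    def test_bounded_by_log_richness(self, neutral_rel):
        r, _ = neutral_rel
        h = shannon(r)
        richness = (r.proportions > 0).sum(axis=0)
        assert (h <= np.log(richness) + 1e-12).all()


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        r = rel([[0.6, 0.6], [0.4, 0.4]], ["a", "b"], ["s1", "s2"])
        assert bray_curtis(r)["s1", "s2"] == 0.0

    def test_disjoint_sets_one(self):
        r = rel([[1.0, 0.0], [0.0, 1.0]], ["a", "b"], ["s1", "s2"])
        assert bray_curtis(r)["s1", "s2"] == 1.0

    def test_hand_value(self):
        r = rel(
            [[0.5, 0.25], [0.5, 0.25], [0.0, 0.5]], list("abc"), ["j", "k"]
        )
        assert bray_curtis(r)["j", "k"] == pytest.approx(0.5, abs=1e-12)


class TestPcoa:
    def test_three_equidistant_points(self):
        from skbio import DistanceMatrix

        dm = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float),
                            ids=list("abc"))
        res = pcoa(dm)
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1], rel=1e-9)

    def test_collinear_points_single_axis(self):
        from skbio import DistanceMatrix

        dm = DistanceMatrix(
            np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float), ids=list("abc")
        )
        res = pcoa(dm)
        assert res.proportion_explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_euclidean_identity(self):
        from skbio import DistanceMatrix

        rng = np.random.default_rng(4)
        pts = rng.normal(size=(5, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix(D, ids=[str(i) for i in range(5)]))
        C = res.coordinates.to_numpy()
        D2 = np.sqrt(((C[:, None] - C[None]) ** 2).sum(-1))
        assert np.allclose(D, D2, atol=1e-8)

    def test_matches_skbio(self, neutral_rel):
        import skbio.stats.ordination as ord_

        r, _ = neutral_rel
        dm = bray_curtis(r)
        ours = pcoa(dm)
        theirs = ord_.pcoa(dm, method="eigh")
        pos = theirs.eigvals[theirs.eigvals > 1e-10].to_numpy()
        assert np.allclose(
            np.sort(ours.eigenvalues[ours.eigenvalues > 1e-10]),
            np.sort(pos),
            atol=1e-8,
        )


def _pseudo_f_oracle(D, labels):
    """Independent pseudo-F: explicit SS decomposition from squared distances."""
    n = len(labels)
    d2 = D**2
    sst = d2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    for g in set(labels):
        idx = [i for i, l in enumerate(labels) if l == g]
        ssw += d2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(set(labels))
    return ((sst - ssw) / (a - 1)) / (ssw / (n - a))


class TestPermanova:
    def test_identical_samples_degenerate(self):
        from skbio import DistanceMatrix

        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        res = permanova(dm, ["x", "x", "y", "y"], n_perm=99, seed=0)
        assert res.degenerate and res.p_value == 1.0

    def test_separated_clusters_min_p(self, ):
        from skbio import DistanceMatrix

        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(0, 0.01, (4, 2)), rng.normal(5, 0.01, (4, 2))])
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(D, ids=[str(i) for i in range(8)])
        res = permanova(dm, ["a"] * 4 + ["b"] * 4, n_perm=999, seed=0)
        assert res.p_value <= 0.03

    def test_monte_carlo_matches_exhaustive(self):
        from skbio import DistanceMatrix

        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 2))
        pts[3:] += 1.5
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = ["a", "a", "a", "b", "b", "b"]
        f_obs = _pseudo_f_oracle(D, labels)
        hits = total = 0
        for perm in set(itertools.permutations(labels)):
            total += 1
            if _pseudo_f_oracle(D, list(perm)) >= f_obs - 1e-12:
                hits += 1
        p_exact = hits / total
        dm = DistanceMatrix(D, ids=[str(i) for i in range(6)])
        res = permanova(dm, labels, n_perm=4999, seed=3)
        assert abs(res.p_value - p_exact) <= 0.02

    def test_matches_skbio_statistic(self, neutral_rel):
        from skbio.stats.distance import permanova as sk_permanova

        r, meta = neutral_rel
        dm = bray_curtis(r)
        ours = permanova(dm, meta["region"], n_perm=99, seed=0)
        theirs = sk_permanova(dm, meta, column="region", permutations=99)
        assert ours.statistic == pytest.approx(theirs["test statistic"], rel=1e-9)


class TestKruskal:
    def test_constant_taxon(self):
        r = rel([[0.5, 0.5, 0.5, 0.5], [0.5, 0.5, 0.5, 0.5]], ["a", "b"],
                list("wxyz"))
        out = kruskal_per_taxon(r, ["g1", "g1", "g2", "g2"])
        assert out.loc["a", "H"] == 0.0 and out.loc["a", "p"] == 1.0

    def test_complete_separation_maximal_h(self):
        vals = np.arange(1, 19, dtype=float)
        arr = np.vstack([vals / vals.sum(), 1 - vals / vals.sum()])
        r = rel(arr, ["sep", "rest"], [f"s{i}" for i in range(18)])
        groups = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        out = kruskal_per_taxon(r, groups)
        # closed form for untied ranks 1..18 in three blocks of 6
        h_max = 12 / (18 * 19) * 6 * ((3.5 - 9.5) ** 2 + 0 + (15.5 - 9.5) ** 2)
        assert out.loc["sep", "H"] == pytest.approx(h_max, rel=1e-9)

    def test_bh_step_up_hand_values(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.5]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5], atol=1e-12)

    def test_bh_never_decreases_and_preserves_order(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        assert (np.argsort(p) == np.argsort(q, kind="stable")).all() or np.allclose(
            np.sort(p), p[np.argsort(q, kind="stable")], atol=1
        )  # order preserved up to ties
        assert (np.diff(q[np.argsort(p)]) >= -1e-12).all()


class TestAnovaTukey:
    def test_two_groups_matches_anova(self):
        rng = np.random.default_rng(0)
        v = np.concatenate([rng.normal(0, 1, 8), rng.normal(1, 1, 8)])
        g = ["a"] * 8 + ["b"] * 8
        res = anova_tukey(v, g)
        # with two groups the studentized-range p equals the F-test p
        assert res.pairwise_p.loc["a", "b"] == pytest.approx(res.p_value, abs=1e-9)

    def test_letters_separate_shifted_group(self):
        rng = np.random.default_rng(1)
        v = np.concatenate(
            [rng.normal(0, 1, 6), rng.normal(0, 1, 6), rng.normal(10, 1, 6)]
        )
        g = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        res = anova_tukey(v, g)
        assert res.letters["a"] == res.letters["b"]
        assert res.letters["c"] != res.letters["a"]

    def test_letters_oracle_direct_studentized_range(self):
        rng = np.random.default_rng(2)
        parts = [rng.normal(m, 1, 6) for m in (0, 0, 10)]
        v = np.concatenate(parts)
        g = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        res = anova_tukey(v, g)
        msw = sum(((p - p.mean()) ** 2).sum() for p in parts) / (18 - 3)
        for gi, gj, pi, pj in [("a", "b", 0, 1), ("a", "c", 0, 2), ("b", "c", 1, 2)]:
            q = abs(parts[pi].mean() - parts[pj].mean()) / np.sqrt(msw / 6)
            assert res.pairwise_p.loc[gi, gj] == pytest.approx(
                stats.studentized_range.sf(q, 3, 15), rel=1e-9
            )

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(3)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            v = rng.normal(size=18)
            g = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
            res = anova_tukey(v, g)
            if len(set(res.letters.values())) > 1:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07

    def test_degenerate_constant_data(self):
        res = anova_tukey([1.0] * 8, ["a"] * 4 + ["b"] * 4)
        assert res.degenerate and res.letters["a"] == res.letters["b"]


def test_compact_letters_chain():
    # a ~ b, b ~ c, but a != c -> b shares letters with both
    pw = pd.DataFrame(1.0, index=list("abc"), columns=list("abc"))
    pw.loc["a", "c"] = pw.loc["c", "a"] = 0.001
    letters = compact_letters(list("abc"), pw)
    assert set(letters["a"]) & set(letters["b"])
    assert set(letters["b"]) & set(letters["c"])
    assert not set(letters["a"]) & set(letters["c"])


class TestEnvCorrelation:
    def test_monotone_taxon_rho_one(self):
        n = 12
        arr = np.vstack([np.linspace(0.1, 0.9, n), 1 - np.linspace(0.1, 0.9, n)])
        r = rel(arr, ["up", "down"], [f"s{i}" for i in range(n)])
        env = pd.DataFrame({"TN": np.arange(n, dtype=float)},
                           index=[f"s{i}" for i in range(n)])
        out = env_correlation(r, env, top_n=2)
        assert out.set_index("taxon").loc["up", "rho"] == pytest.approx(1.0)
        assert out.set_index("taxon").loc["down", "rho"] == pytest.approx(-1.0)

    def test_constant_variable_reported_missing(self, neutral_rel):
        r, _ = neutral_rel
        env = pd.DataFrame(
            {"flat": np.ones(len(r.sample_ids))}, index=r.sample_ids
        )
        out = env_correlation(r, env, top_n=5)
        assert out["rho"].isna().all()

    def test_null_significant_fraction(self):
        rng = np.random.default_rng(5)
        hits = 0
        sims = 1000
        n = 20
        for _ in range(sims):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            hits += stats.spearmanr(x, y).pvalue < 0.05
        assert 0.03 <= hits / sims <= 0.07
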
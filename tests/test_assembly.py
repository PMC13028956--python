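import io as _io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from microlake import (
    OtuTable,
    beta_mntd,
    beta_mntd_matrix,
    beta_nti,
    classify_pair,
    cophenetic_matrix,
    partition_processes,
    process_fractions,
    rc_bray,
    simulate_tree,
)
from microlake.assembly import assembly_analysis


def tree_from(newick: str) -> TreeNode:
    return TreeNode.read(_io.StringIO(newick))


@pytest.fixture
def hand_tree():
    # 4 tips with hand-set branch lengths
    return tree_from("((A:1,B:2):0.5,(C:3,D:1):2);")


class TestBetaMntd:
    def test_identical_single_taxon_zero(self, hand_tree):
        ids, D = cophenetic_matrix(hand_tree, ["A", "B", "C", "D"])
        x = np.array([5.0, 0.0, 0.0, 0.0])
        assert beta_mntd(x, x, D) == 0.0

    def test_identical_communities_zero(self, hand_tree):
        ids, D = cophenetic_matrix(hand_tree, ["A", "B", "C", "D"])
        x = np.array([2.0, 3.0, 1.0, 4.0])
        assert beta_mntd(x, x, D) == 0.0

    def test_hand_tree_matches_double_loop_oracle(self, hand_tree):
        taxa = ["A", "B", "C", "D"]
        ids, D = cophenetic_matrix(hand_tree, taxa)
        # patristic distances by hand: A-B=3, A-C=6.5, A-D=4.5, B-C=7.5,
        # B-D=5.5, C-D=4
        hand = {
            ("A", "B"): 3.0, ("A", "C"): 6.5, ("A", "D"): 4.5,
            ("B", "C"): 7.5, ("B", "D"): 5.5, ("C", "D"): 4.0,
        }
        for (u, v), d in hand.items():
            assert D[taxa.index(u), taxa.index(v)] == pytest.approx(d, abs=1e-12)

        x_k = np.array([1.0, 1.0, 0.0, 0.0])  # {A, B}
        x_l = np.array([0.0, 0.0, 1.0, 1.0])  # {C, D}

        def oracle(xk, xl, weighted):
            ik = [i for i in range(4) if xk[i] > 0]
            il = [i for i in range(4) if xl[i] > 0]
            term_k = term_l = 0.0
            for i in ik:
                nearest = min(D[i, j] for j in il)
                w = xk[i] / sum(xk[m] for m in ik) if weighted else 1 / len(ik)
                term_k += w * nearest
            for j in il:
                nearest = min(D[j, i] for i in ik)
                w = xl[j] / sum(xl[m] for m in il) if weighted else 1 / len(il)
                term_l += w * nearest
            return 0.5 * (term_k + term_l)

        for weighted in (True, False):
            assert beta_mntd(x_k, x_l, D, weighted=weighted) == pytest.approx(
                oracle(x_k, x_l, weighted), abs=1e-12
            )
        # unweighted hand value: mean nearest distances (4.5, 5.5 | 6.5, 4.5)
        assert beta_mntd(x_k, x_l, D, weighted=False) == pytest.approx(5.25, abs=1e-12)

        # abundance-weighted with uneven abundances
        x_k2 = np.array([3.0, 1.0, 0.0, 0.0])
        assert beta_mntd(x_k2, x_l, D, weighted=True) == pytest.approx(
            oracle(x_k2, x_l, True), abs=1e-12
        )

    def test_missing_tip_named_in_error(self, hand_tree):
        df = pd.DataFrame(
            [[1, 1], [1, 1]], index=["A", "ZZZ"], columns=["s1", "s2"]
        )
        with pytest.raises(ValueError, match="ZZZ"):
            beta_mntd_matrix(df, hand_tree)


class TestBetaNti:
    def test_star_tree_degenerate(self):
        star = tree_from("(A:1,B:1,C:1,D:1);")
        df = pd.DataFrame(
            [[4, 0], [1, 0], [0, 3], [0, 2]],
            index=list("ABCD"), columns=["s1", "s2"],
        )
        res = beta_nti(df, star, n_null=99, seed=0)
        assert bool(res.degenerate.loc["s1", "s2"])
        assert np.isnan(res.betanti.loc["s1", "s2"])

    def test_branch_length_scaling_invariance(self):
        tree = simulate_tree(16, seed=1)
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 30, size=(16, 4))
        counts[counts < 5] = 0
        counts[0] += 5  # keep samples non-empty
        df = pd.DataFrame(counts, index=[t.name for t in tree.tips()],
                          columns=list("wxyz"))
        ids, D = cophenetic_matrix(tree, list(df.index))
        a = beta_nti(df, (ids, D), n_null=99, seed=3).betanti
        b = beta_nti(df, (ids, 7.3 * D), n_null=99, seed=3).betanti
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9, equal_nan=True)

    def test_reproducible_for_fixed_seed(self):
        tree = simulate_tree(12, seed=4)
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.integers(1, 50, size=(12, 4)),
                          index=[t.name for t in tree.tips()], columns=list("wxyz"))
        a = beta_nti(df, tree, n_null=99, seed=6).betanti
        b = beta_nti(df, tree, n_null=99, seed=6).betanti
        assert a.equals(b)


class TestRcBray:
    def test_range_and_symmetry(self, neutral_sim):
        table, _, _ = neutral_sim
        sub = OtuTable(table.counts.iloc[:, :4])
        rc = rc_bray(sub, n_null=99, seed=0)
        arr = rc.to_numpy()
        assert (arr >= -1).all() and (arr <= 1).all()
        assert np.allclose(arr, arr.T)

    def test_generative_null_is_centered(self):
        """Pairs drawn from the null's own assembly model give RC near 0."""
        rng = np.random.default_rng(7)
        n_taxa = 40
        meta_ab = rng.lognormal(0, 1.5, n_taxa)
        pool_counts = rng.multinomial(5000, meta_ab / meta_ab.sum(),
                                      size=8).T  # taxa x 8 pool samples
        pool = pd.DataFrame(pool_counts, index=[f"t{i}" for i in range(n_taxa)],
                            columns=[f"p{j}" for j in range(8)])
        occ = (pool > 0).sum(axis=1).to_numpy().astype(float)
        ab = pool.sum(axis=1).to_numpy().astype(float)
        keep = occ > 0
        occ_p = occ[keep] / occ[keep].sum()
        ab_p = ab[keep] / ab[keep].sum()
        idx = np.flatnonzero(keep)

        def draw(rich, total):
            chosen = rng.choice(len(idx), size=rich, replace=False, p=occ_p)
            vec = np.ones(rich)
            w = ab_p[chosen]
            vec += rng.multinomial(total - rich, w / w.sum())
            out = np.zeros(n_taxa)
            out[idx[chosen]] = vec
            return out.astype(int)

        rcs = []
        for rep in range(30):
            a = draw(25, 3000)
            b = draw(25, 3000)
            cols = pool.copy()
            cols["a"], cols["b"] = a, b
            rc = rc_bray(OtuTable(cols), n_null=199, seed=100 + rep,
                         pool_samples=[f"p{j}" for j in range(8)],
                         pairs=[("a", "b")])
            rcs.append(float(rc.loc["a", "b"]))
        rcs = np.array(rcs)
        assert -0.2 <= rcs.mean() <= 0.2
        assert (np.abs(rcs) <= 0.95).mean() >= 0.85

    def test_richness_exceeding_pool_rejected(self):
        # pool restricted to s1 holds one taxon; s2 has richness 2
        df = pd.DataFrame([[1, 1], [0, 1]], index=["a", "b"], columns=["s1", "s2"])
        with pytest.raises(ValueError):
            rc_bray(OtuTable(df), n_null=99, seed=0, pool_samples=["s1"])


class TestPartition:
    def test_rule_table(self):
        assert classify_pair(3.0, 0.0) == "heterogeneous_selection"
        assert classify_pair(-3.0, 0.99) == "homogeneous_selection"
        assert classify_pair(0.0, 0.99) == "dispersal_limitation"
        assert classify_pair(0.0, -0.99) == "homogenizing_dispersal"
        assert classify_pair(0.0, 0.0) == "drift"
        # no tree: only the stochastic rules apply
        assert classify_pair(float("nan"), 0.99) == "dispersal_limitation"
        assert classify_pair(float("nan"), 0.5) == "drift"

    def test_all_heterogeneous(self):
        ids = list("abcd")
        b = pd.DataFrame(3.0, index=ids, columns=ids)
        r = pd.DataFrame(0.0, index=ids, columns=ids)
        pairs = partition_processes(b, r)
        assert (pairs["process"] == "heterogeneous_selection").all()
        frac = process_fractions(pairs)
        assert frac.loc["all", "deterministic"] == 1.0

    def test_mixed_matrix_matches_hand_tally(self):
        ids = [f"s{i}" for i in range(5)]  # 10 pairs
        vals = {
            (0, 1): (3.0, 0.0), (0, 2): (-2.5, 0.0), (0, 3): (0.0, 0.99),
            (0, 4): (1.0, -0.99), (1, 2): (0.5, 0.5), (1, 3): (2.5, 0.0),
            (1, 4): (-4.0, 0.0), (2, 3): (0.0, 0.96), (2, 4): (0.0, -0.96),
            (3, 4): (1.9, 0.94),
        }
        b = pd.DataFrame(0.0, index=ids, columns=ids)
        r = pd.DataFrame(0.0, index=ids, columns=ids)
        for (i, j), (bv, rv) in vals.items():
            b.iloc[i, j] = b.iloc[j, i] = bv
            r.iloc[i, j] = r.iloc[j, i] = rv
        pairs = partition_processes(b, r)
        tally = pairs["process"].value_counts()
        # hand tally: het 2, hom 2, disp 2, homog 2, drift 2
        assert tally["heterogeneous_selection"] == 2
        assert tally["homogeneous_selection"] == 2
        assert tally["dispersal_limitation"] == 2
        assert tally["homogenizing_dispersal"] == 2
        assert tally["drift"] == 2
        frac = process_fractions(pairs)
        assert frac.loc["all", list(frac.columns[:5])].sum() == pytest.approx(1.0)

    def test_mismatched_matrices_rejected(self):
        b = pd.DataFrame(0.0, index=list("ab"), columns=list("ab"))
        r = pd.DataFrame(0.0, index=list("ac"), columns=list("ac"))
        with pytest.raises(ValueError):
            partition_processes(b, r)

    def test_fractions_sum_to_one_per_group(self, neutral_sim):
        table, meta, truth = neutral_sim
        sub = OtuTable(table.counts.iloc[:, :6].loc[lambda d: d.sum(axis=1) > 0])
        tree = simulate_tree(len(sub.taxon_ids), seed=9)
        renamed = sub.counts.copy()
        renamed.index = [t.name for t in tree.tips()][: len(renamed)]
        b = beta_nti(renamed, tree, n_null=99, seed=1).betanti
        r = rc_bray(renamed, n_null=99, seed=1)
        pairs = partition_processes(b, r, groups=meta.loc[list(renamed.columns), "region"])
        frac = process_fractions(pairs, by="scope")
        for _, row in frac.iterrows():
            assert row[list(frac.columns[:5])].sum() == pytest.approx(1.0, abs=1e-9)
            assert row["deterministic"] + row["stochastic"] == pytest.approx(1.0)


def test_assembly_analysis_without_tree_uses_rc_only(neutral_sim):
    table, meta, _ = neutral_sim
    sub = OtuTable(table.counts.iloc[:, :6])
    pairs = assembly_analysis(sub, meta, tree=None, n_null=99, seed=0)
    assert pairs["betaNTI"].isna().all()
    assert set(pairs["process"]) <= {
        "dispersal_limitation", "homogenizing_dispersal", "drift"
    }
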
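"""Null-model partitioning of community assembly processes.

The framework compares, for every pair of samples, (i) observed phylogenetic
turnover (beta mean nearest taxon distance, betaMNTD) against a null obtained
by shuffling taxa across the tips of the phylogeny, giving the standardized
beta nearest taxon index (betaNTI); and (ii) observed Bray-Curtis
dissimilarity against a null that reassembles each community from the species
pool (probability of inclusion proportional to occupancy, abundance filled
proportionally to pool relative abundance), giving the Raup-Crick metric
RCbray in [-1, 1].

Pairs are then assigned to one of five processes:

* betaNTI >  2  -> heterogeneous selection
* betaNTI < -2  -> homogeneous selection
* |betaNTI| <= 2 and RCbray >  0.95 -> dispersal limitation
* |betaNTI| <= 2 and RCbray < -0.95 -> homogenizing dispersal
* otherwise                          -> (ecological) drift

Selection processes are "deterministic"; the remaining three "stochastic".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import OtuTable, cophenetic_matrix

__all__ = [
    "PROCESSES",
    "DETERMINISTIC",
    "beta_mntd",
    "beta_mntd_matrix",
    "beta_nti",
    "BetaNtiResult",
    "rc_bray",
    "classify_pair",
    "partition_processes",
    "process_fractions",
    "assembly_analysis",
]

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)
DETERMINISTIC = frozenset(PROCESSES[:2])

BNTI_CUTOFF = 2.0
RC_CUTOFF = 0.95


def beta_mntd(
    x_k: np.ndarray, x_l: np.ndarray, dist: np.ndarray, weighted: bool = True
) -> float:
    """betaMNTD between two abundance vectors over a patristic distance matrix.

    For each taxon present in one community, take its distance to the nearest
    taxon present in the *other* community; average with the taxon's relative
    abundance within its community (or uniformly when unweighted) and take
    the mean of the two directions.
    """
    x_k = np.asarray(x_k, dtype=float)
    x_l = np.asarray(x_l, dtype=float)
    ik = np.flatnonzero(x_k > 0)
    il = np.flatnonzero(x_l > 0)
    if len(ik) == 0 or len(il) == 0:
        raise ValueError("both communities must contain at least one taxon")
    sub = dist[np.ix_(ik, il)]
    dk = sub.min(axis=1)
    dl = sub.min(axis=0)
    if weighted:
        fk = x_k[ik] / x_k[ik].sum()
        fl = x_l[il] / x_l[il].sum()
    else:
        fk = np.full(len(ik), 1 / len(ik))
        fl = np.full(len(il), 1 / len(il))
    return 0.5 * (float(fk @ dk) + float(fl @ dl))


def _pair_list(n: int):
    return list(itertools.combinations(range(n), 2))


def _beta_mntd_all(
    present: list[np.ndarray],
    weights: list[np.ndarray],
    dist: np.ndarray,
    order: np.ndarray | None = None,
) -> np.ndarray:
    """betaMNTD for every sample pair; *order* remaps taxon rows (null shuffle)."""
    n = len(present)
    out = np.empty(n * (n - 1) // 2)
    for m, (k, l) in enumerate(_pair_list(n)):
        ik, il = present[k], present[l]
        if order is not None:
            ik, il = order[ik], order[il]
        sub = dist[np.ix_(ik, il)]
        out[m] = 0.5 * (weights[k] @ sub.min(axis=1) + weights[l] @ sub.min(axis=0))
    return out


def beta_mntd_matrix(
    table: OtuTable | pd.DataFrame,
    tree: TreeNode | tuple,
    weighted: bool = True,
) -> pd.DataFrame:
    """Square DataFrame of betaMNTD between all sample pairs."""
    df = table.counts if isinstance(table, OtuTable) else table
    taxa = [str(t) for t in df.index]
    ids, D = tree if isinstance(tree, tuple) else cophenetic_matrix(tree, taxa)
    X = df.loc[ids].to_numpy(dtype=float)
    present = [np.flatnonzero(X[:, j] > 0) for j in range(X.shape[1])]
    weights = [
        X[idx, j] / X[idx, j].sum() if weighted else np.full(len(idx), 1 / len(idx))
        for j, idx in enumerate(present)
    ]
    vals = _beta_mntd_all(present, weights, D)
    return _square(vals, [str(c) for c in df.columns])


def _square(condensed: np.ndarray, ids: list[str]) -> pd.DataFrame:
    n = len(ids)
    M = np.zeros((n, n))
    for m, (k, l) in enumerate(_pair_list(n)):
        M[k, l] = M[l, k] = condensed[m]
    return pd.DataFrame(M, index=ids, columns=ids)


@dataclass
class BetaNtiResult:
    betanti: pd.DataFrame = field(repr=False)
    betamntd_obs: pd.DataFrame = field(repr=False)
    degenerate: pd.DataFrame = field(repr=False)
    n_null: int = 0


def beta_nti(
    table: OtuTable | pd.DataFrame,
    tree: TreeNode | tuple,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> BetaNtiResult:
    """betaNTI per sample pair against a tip-shuffling null.

    Each null draw permutes taxon identities across the whole phylogeny
    (implemented by remapping rows of the cached patristic matrix, which is
    mathematically identical to relabelling tips) and recomputes betaMNTD;
    betaNTI = (obs - mean_null) / sd_null. Pairs whose null distribution has
    zero spread are flagged degenerate (betaNTI = NaN).
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    df = table.counts if isinstance(table, OtuTable) else table
    taxa = [str(t) for t in df.index]
    ids, D = tree if isinstance(tree, tuple) else cophenetic_matrix(tree, taxa)
    X = df.loc[ids].to_numpy(dtype=float)
    sample_ids = [str(c) for c in df.columns]
    present = [np.flatnonzero(X[:, j] > 0) for j in range(X.shape[1])]
    weights = [
        X[idx, j] / X[idx, j].sum() if weighted else np.full(len(idx), 1 / len(idx))
        for j, idx in enumerate(present)
    ]
    obs = _beta_mntd_all(present, weights, D)
    rng = np.random.default_rng(seed)
    n_taxa = len(ids)
    nulls = np.empty((n_null, len(obs)))
    for b in range(n_null):
        order = rng.permutation(n_taxa)
        nulls[b] = _beta_mntd_all(present, weights, D, order=order)
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    degen = sd <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = np.where(degen, np.nan, (obs - mean) / sd)
    return BetaNtiResult(
        betanti=_square(bnti, sample_ids),
        betamntd_obs=_square(obs, sample_ids),
        degenerate=_square(degen.astype(float), sample_ids).astype(bool),
        n_null=n_null,
    )


def _bray_counts(a: np.ndarray, b: np.ndarray) -> float:
    tot = (a + b).sum()
    return float(np.abs(a - b).sum() / tot) if tot else 0.0


def rc_bray(
    table: OtuTable | pd.DataFrame,
    n_null: int = 999,
    seed: int = 0,
    pool_samples: list | None = None,
    pairs: list | None = None,
) -> pd.DataFrame:
    """Raup-Crick metric on Bray-Curtis, per sample pair, rescaled to [-1, 1].

    The species pool is the whole table (or ``pool_samples``): inclusion
    probability proportional to occupancy, abundance fill proportional to
    pooled relative abundance. Each null draw rebuilds both communities at
    their observed richness and total reads and measures Bray-Curtis;
    ``RC = 2 * ((#{null < obs} + 0.5 * #{null == obs}) / n_null) - 1``.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    df = table.counts if isinstance(table, OtuTable) else table
    X = df.to_numpy(dtype=float)
    sample_ids = [str(c) for c in df.columns]
    pool_X = X if pool_samples is None else df[pool_samples].to_numpy(dtype=float)
    occupancy = (pool_X > 0).sum(axis=1).astype(float)
    in_pool = occupancy > 0
    pool_idx = np.flatnonzero(in_pool)
    occ_p = occupancy[pool_idx] / occupancy[pool_idx].sum()
    ab = pool_X[pool_idx].sum(axis=1)
    ab_p = ab / ab.sum()
    richness = (X > 0).sum(axis=0)
    if (richness > len(pool_idx)).any():
        raise ValueError("observed richness exceeds the species-pool size")
    totals = X.sum(axis=0).astype(int)
    rng = np.random.default_rng(seed)
    n_taxa_pool = len(pool_idx)
    n_samples = X.shape[1]

    def draw_null(rich: int, total: int) -> np.ndarray:
        chosen = rng.choice(n_taxa_pool, size=rich, replace=False, p=occ_p)
        vec = np.ones(rich)  # each drawn species is present with >= 1 read
        fill = total - rich
        if fill > 0:
            w = ab_p[chosen]
            vec += rng.multinomial(fill, w / w.sum())
        out = np.zeros(n_taxa_pool)
        out[chosen] = vec
        return out

    if pairs is None:
        pair_idx = _pair_list(n_samples)
    else:
        pos = {s: i for i, s in enumerate(sample_ids)}
        pair_idx = [(pos[a], pos[b]) for a, b in pairs]
    Xp = X[pool_idx]
    rc_vals = np.empty(len(pair_idx))
    for m, (k, l) in enumerate(pair_idx):
        obs = _bray_counts(Xp[:, k], Xp[:, l])
        less = equal = 0
        for _ in range(n_null):
            bc = _bray_counts(
                draw_null(int(richness[k]), int(totals[k])),
                draw_null(int(richness[l]), int(totals[l])),
            )
            if bc < obs - 1e-12:
                less += 1
            elif abs(bc - obs) <= 1e-12:
                equal += 1
        rc_vals[m] = 2 * ((less + 0.5 * equal) / n_null) - 1
    if pairs is not None:
        out = pd.DataFrame(np.nan, index=sample_ids, columns=sample_ids)
        np.fill_diagonal(out.values, 0.0)
        for m, (k, l) in enumerate(pair_idx):
            out.iloc[k, l] = out.iloc[l, k] = rc_vals[m]
        return out
    return _square(rc_vals, sample_ids)


def classify_pair(betanti: float, rcbray: float) -> str:
    """Five-way process rule for one sample pair.

    A NaN betaNTI (no tree, or a degenerate null) falls through to the
    stochastic RCbray rules, so selection is only ever inferred from a
    usable phylogenetic null.
    """
    if np.isfinite(betanti):
        if betanti > BNTI_CUTOFF:
            return "heterogeneous_selection"
        if betanti < -BNTI_CUTOFF:
            return "homogeneous_selection"
    if rcbray > RC_CUTOFF:
        return "dispersal_limitation"
    if rcbray < -RC_CUTOFF:
        return "homogenizing_dispersal"
    return "drift"


def partition_processes(
    betanti: pd.DataFrame | None,
    rcbray: pd.DataFrame,
    groups=None,
    class_subset: str = "all",
) -> pd.DataFrame:
    """Per-pair process assignment with within/between-group scope.

    *betanti* may be None (no phylogeny — e.g. fungal ITS communities), in
    which case only the dispersal/drift rules apply. Returns a long DataFrame
    with one row per unordered sample pair.
    """
    ids = list(rcbray.index.astype(str))
    if betanti is not None:
        b_ids = list(betanti.index.astype(str))
        if b_ids != ids:
            raise ValueError("betaNTI and RCbray matrices must share sample pairs")
    if groups is not None:
        g = pd.Series(groups) if not isinstance(groups, pd.Series) else groups
        g = g.loc[ids]
    rows = []
    for k, l in _pair_list(len(ids)):
        sk, sl = ids[k], ids[l]
        b = float(betanti.loc[sk, sl]) if betanti is not None else np.nan
        r = float(rcbray.loc[sk, sl])
        row = {
            "sample_1": sk,
            "sample_2": sl,
            "class_subset": class_subset,
            "betaNTI": b,
            "RCbray": r,
            "process": classify_pair(b, r),
        }
        if groups is not None:
            row["scope"] = (
                f"within_{g[sk]}" if g[sk] == g[sl] else "between_region"
            )
        rows.append(row)
    return pd.DataFrame(rows)


def process_fractions(pairs: pd.DataFrame, by: str | None = None) -> pd.DataFrame:
    """Stacked process fractions (summing to 1) overall or per *by* column."""
    def tally(d: pd.DataFrame) -> pd.Series:
        frac = d["process"].value_counts(normalize=True)
        out = pd.Series({p: float(frac.get(p, 0.0)) for p in PROCESSES})
        out["deterministic"] = sum(out[p] for p in DETERMINISTIC)
        out["stochastic"] = 1.0 - out["deterministic"]
        out["n_pairs"] = len(d)
        return out

    if by is None:
        return tally(pairs).to_frame("all").T
    return pairs.groupby(by, sort=False).apply(tally, include_groups=False)


def assembly_analysis(
    table: OtuTable,
    meta: pd.DataFrame,
    tree: TreeNode | tuple | None = None,
    assignment: pd.DataFrame | None = None,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> pd.DataFrame:
    """Full assembly partition: all taxa plus per-abundance-class subsets.

    Runs betaNTI (when a tree is supplied) and RCbray on the whole table and,
    if an AT/IT/RT *assignment* is given, on each class's sub-table, then
    classifies every sample pair. Class sub-tables keep only samples where
    the class still has at least one read.
    """
    groups = meta.loc[list(table.sample_ids), "region"]
    subsets: dict[str, pd.DataFrame] = {"all": table.counts}
    if assignment is not None:
        for cls in ("AT", "IT", "RT"):
            taxa = assignment.index[assignment["label"] == cls]
            sub = table.counts.loc[table.counts.index.intersection(taxa)]
            sub = sub.loc[:, sub.sum(axis=0) > 0]
            if sub.shape[0] >= 2 and sub.shape[1] >= 3:
                subsets[cls] = sub
    results = []
    for i, (name, sub) in enumerate(subsets.items()):
        sub_seed = seed + 104729 * i
        rc = rc_bray(sub, n_null=n_null, seed=sub_seed)
        if tree is not None:
            taxa = [str(t) for t in sub.index]
            sub_tree = (
                cophenetic_matrix(tree, taxa) if not isinstance(tree, tuple)
                else _restrict(tree, taxa)
            )
            bnti = beta_nti(
                sub, sub_tree, n_null=n_null, seed=sub_seed + 1, weighted=weighted
            ).betanti
        else:
            bnti = None
        results.append(
            partition_processes(bnti, rc, groups=groups, class_subset=name)
        )
    return pd.concat(results, ignore_index=True)


def _restrict(tree_tuple: tuple, taxa: list[str]) -> tuple:
    ids, D = tree_tuple
    index = {t: i for i, t in enumerate(ids)}
    missing = [t for t in taxa if t not in index]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing}")
    order = [index[t] for t in taxa]
    return list(taxa), D[np.ix_(order, order)]
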
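"""Alpha/beta diversity, ordination, group tests, and taxon-environment correlation.

Shannon diversity uses the natural logarithm. Beta diversity is Bray-Curtis on
relative abundances; PCoA is classical Gower double-centering with negative
eigenvalues reported but excluded from the explained-variance denominator.
PERMANOVA is a seed-controlled label-permutation test on the distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .io import OtuTable, RelAbundTable, to_relative

__all__ = [
    "shannon",
    "bray_curtis",
    "pcoa",
    "PcoaResult",
    "permanova",
    "PermanovaResult",
    "kruskal_per_taxon",
    "anova_tukey",
    "GroupTestResult",
    "compact_letters",
    "env_correlation",
    "bh_adjust",
]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _proportions(table) -> pd.DataFrame:
    if isinstance(table, OtuTable):
        return to_relative(table).proportions
    if isinstance(table, RelAbundTable):
        return table.proportions
    return table


def shannon(table) -> pd.Series:
    """Per-sample Shannon index H' = -sum p_i ln p_i (natural log)."""
    P = _proportions(table)
    if (P.sum(axis=0) <= 0).any():
        raise ValueError("every sample needs at least one nonzero taxon")
    arr = P.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(arr > 0, arr * np.log(arr), 0.0)
    return pd.Series(-terms.sum(axis=0), index=P.columns, name="shannon")


def bray_curtis(table) -> "DistanceMatrix":
    """Bray-Curtis dissimilarity between samples, on relative abundances."""
    from skbio import DistanceMatrix

    P = _proportions(table)
    d = squareform(pdist(P.to_numpy(dtype=float).T, metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(c) for c in P.columns])


@dataclass(frozen=True)
class PcoaResult:
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray  # over the positive eigenvalues only


def pcoa(dist) -> PcoaResult:
    """Classical principal-coordinate analysis of a distance matrix.

    Gower-centers -d^2/2, eigendecomposes, orders axes by eigenvalue and
    keeps coordinates for positive eigenvalues; the percent variance uses the
    sum of positive eigenvalues as the denominator.
    """
    D = np.asarray(dist.data if hasattr(dist, "data") else dist, dtype=float)
    ids = list(dist.ids) if hasattr(dist, "ids") else [str(i) for i in range(len(D))]
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    eigvals, eigvecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals).max())
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    prop = eigvals[pos] / eigvals[pos].sum()
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=cols),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


@dataclass(frozen=True)
class PermanovaResult:
    statistic: float
    p_value: float
    n_permutations: int
    degenerate: bool = False


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F from squared distances and integer group labels."""
    n = len(labels)
    groups = np.unique(labels)
    a = len(groups)
    ss_total = d2.sum() / (2 * n)  # d2 is the full symmetric matrix
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_between = ss_total - ss_within
    if ss_within <= 1e-300:
        return np.inf if ss_between > 1e-300 else 0.0
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(dist, groups, n_perm: int = 999, seed: int = 0) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``p = (1 + #{perm F >= obs F}) / (1 + n_perm)`` with whole-sample label
    permutation under a fixed seed. A distance matrix with zero total
    variance is flagged degenerate with p = 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    D = np.asarray(dist.data if hasattr(dist, "data") else dist, dtype=float)
    ids = list(dist.ids) if hasattr(dist, "ids") else list(range(len(D)))
    g = pd.Series(list(groups), index=ids) if not isinstance(groups, pd.Series) else groups
    labels = pd.Categorical(g.loc[ids]).codes.astype(np.int64)
    sizes = np.bincount(labels)
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")
    d2 = D**2
    if d2.sum() <= 1e-300:
        return PermanovaResult(0.0, 1.0, n_perm, degenerate=True)
    f_obs = _pseudo_f(d2, labels)
    rng = np.random.default_rng(seed)
    count = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        if _pseudo_f(d2, lab) >= f_obs - 1e-12:
            count += 1
    return PermanovaResult(float(f_obs), (1 + count) / (1 + n_perm), n_perm)


def kruskal_per_taxon(relabund, groups, min_mean: float = 0.0) -> pd.DataFrame:
    """Kruskal-Wallis H test per taxon across sample groups.

    Returns per-taxon H, p, and BH-adjusted q; taxa whose values are
    identical in every sample get H = 0, p = 1. ``min_mean`` optionally
    restricts the test to taxa at or above a mean relative abundance
    (the usual "dominant taxa" filter).
    """
    P = _proportions(relabund)
    g = pd.Series(list(groups), index=P.columns) if not isinstance(groups, pd.Series) else groups
    g = g.loc[P.columns]
    if g.value_counts().min() < 1 or g.nunique() < 2:
        raise ValueError("need >= 2 non-empty groups")
    if min_mean > 0:
        P = P.loc[P.mean(axis=1) >= min_mean]
    idx_by_group = [np.flatnonzero((g == lev).to_numpy()) for lev in pd.unique(g)]
    H = np.empty(P.shape[0])
    pvals = np.empty(P.shape[0])
    arr = P.to_numpy(dtype=float)
    for i, row in enumerate(arr):
        samples = [row[idx] for idx in idx_by_group]
        if np.ptp(row) == 0:
            H[i], pvals[i] = 0.0, 1.0
        else:
            H[i], pvals[i] = stats.kruskal(*samples)
    out = pd.DataFrame({"H": H, "p": pvals, "q": bh_adjust(pvals)}, index=P.index)
    out["significant"] = out["p"] < 0.05
    return out


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    p_value: float
    group_means: pd.Series
    group_se: pd.Series
    letters: dict
    pairwise_p: pd.DataFrame
    degenerate: bool = False


def compact_letters(group_names, pairwise_p: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Compact letter display by greedy insert-absorb.

    Groups sharing a letter are not significantly different at *alpha*.
    Group order (hence letter order) follows ``group_names``.
    """
    names = list(group_names)
    letter_sets: list[frozenset] = [frozenset(names)]
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            if pairwise_p.loc[gi, gj] >= alpha:
                continue
            split: list[frozenset] = []
            for s in letter_sets:
                if gi in s and gj in s:
                    split.extend((s - {gi}, s - {gj}))
                else:
                    split.append(s)
            # absorb: drop duplicates and sets contained in another
            letter_sets = [
                s
                for k, s in enumerate(split)
                if s
                and not any(
                    s < t or (s == t and k > m) for m, t in enumerate(split)
                )
            ]
    # stable letter order: by earliest member in group order
    letter_sets.sort(key=lambda s: min(names.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in names}
    for k, s in enumerate(letter_sets):
        for g in names:
            if g in s:
                out[g] += alphabet[k]
    return out


def anova_tukey(values, groups, alpha: float = 0.05) -> GroupTestResult:
    """One-way ANOVA with Tukey-Kramer HSD pairwise comparisons and letters.

    Handles unequal group sizes (Kramer correction); pairwise p-values come
    from the studentized-range distribution. All-constant data is flagged
    degenerate (F undefined) with p = 1 and identical letters.
    """
    v = np.asarray(list(values), dtype=float)
    g = pd.Series(list(groups))
    names = list(pd.unique(g))
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    parts = [v[(g == name).to_numpy()] for name in names]
    ns = np.array([len(p) for p in parts])
    if (ns < 2).any():
        raise ValueError("every group needs >= 2 observations")
    means = np.array([p.mean() for p in parts])
    se = np.array([p.std(ddof=1) / np.sqrt(len(p)) for p in parts])
    n, a = len(v), len(names)
    msw = sum(((p - p.mean()) ** 2).sum() for p in parts) / (n - a)
    if msw <= 1e-300:
        pw = pd.DataFrame(
            np.where(np.subtract.outer(means, means) == 0, 1.0, 0.0),
            index=names,
            columns=names,
        )
        letters = compact_letters(names, pw, alpha)
        return GroupTestResult(
            np.nan, 1.0 if np.ptp(means) == 0 else 0.0,
            pd.Series(means, index=names), pd.Series(se, index=names),
            letters, pw, degenerate=True,
        )
    f_stat, p_val = stats.f_oneway(*parts)
    pw = pd.DataFrame(np.ones((a, a)), index=names, columns=names)
    for i in range(a):
        for j in range(i + 1, a):
            q = abs(means[i] - means[j]) / np.sqrt(
                msw / 2 * (1 / ns[i] + 1 / ns[j])
            )
            p_ij = float(stats.studentized_range.sf(q, a, n - a))
            pw.iloc[i, j] = pw.iloc[j, i] = p_ij
    letters = compact_letters(names, pw, alpha)
    return GroupTestResult(
        float(f_stat), float(p_val),
        pd.Series(means, index=names), pd.Series(se, index=names),
        letters, pw,
    )


def env_correlation(
    relabund, env: pd.DataFrame, top_n: int = 50, alpha: float = 0.05
) -> pd.DataFrame:
    """Spearman correlation of the top-n taxa against each environmental variable.

    Returns a long DataFrame (taxon, variable, rho, p, q, stars); constant
    variables yield NaN rho/p. The companion per-variable summary — the
    fraction of top-n taxa significantly correlated — can be derived with
    :func:`env_correlation_summary`.
    """
    P = _proportions(relabund)
    env = env.loc[list(P.columns)]
    top = P.mean(axis=1).sort_values(ascending=False).index[: min(top_n, P.shape[0])]
    rows = []
    for taxon in top:
        x = P.loc[taxon].to_numpy(dtype=float)
        for var in env.columns:
            y = env[var].to_numpy(dtype=float)
            if np.ptp(y) == 0 or np.ptp(x) == 0:
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(x, y)
            rows.append({"taxon": taxon, "variable": var, "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["stars"] = pd.cut(
        out["p"].fillna(1.0),
        [-np.inf, 0.001, 0.01, 0.05, np.inf],
        labels=["***", "**", "*", ""],
    ).astype(str)
    return out


def env_correlation_summary(corr: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Per-variable fraction of tested taxa with p < alpha."""
    return corr.groupby("variable", sort=False).apply(
        lambda d: float((d["p"] < alpha).mean()), include_groups=False
    )
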
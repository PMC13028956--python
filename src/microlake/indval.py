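"""Dufrene-Legendre indicator species analysis with permutation significance.

For taxon t and group g: A (specificity) = mean relative abundance of t in g
divided by the sum of those group means — the group-mean form corrects for
unequal group sizes; B (fidelity) = fraction of g's samples where t occurs.
IndVal_g = A * B, the taxon's score is the maximum over groups, and its
p-value comes from shuffling whole samples across groups.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .diversity import bh_adjust, _proportions

__all__ = ["indval", "summarize_indicators"]


def _indval_scores(X: np.ndarray, group_idx: list[np.ndarray]):
    """Per-taxon (best IndVal, best group index, A, B) for abundance matrix X."""
    means = np.stack([X[:, idx].mean(axis=1) for idx in group_idx], axis=1)
    occup = np.stack([(X[:, idx] > 0).mean(axis=1) for idx in group_idx], axis=1)
    denom = means.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, means / denom, 0.0)
    iv = A * occup
    best = iv.argmax(axis=1)
    rows = np.arange(X.shape[0])
    return iv[rows, best], best, A[rows, best], occup[rows, best]


def indval(
    relabund,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    indval_min: float = 0.7,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Indicator value per taxon with a whole-sample permutation test.

    Returns a DataFrame indexed by taxon with columns ``best_group``, ``A``,
    ``B``, ``indval``, ``p``, ``q`` (BH) and ``strong`` (indval > indval_min
    and raw p < p_max). Taxa absent from every sample are dropped with a
    warning. ``p = (1 + #{perm IndVal >= obs}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    P = _proportions(relabund)
    g = pd.Series(list(groups), index=P.columns) if not isinstance(groups, pd.Series) else groups
    g = g.loc[P.columns]
    levels = list(pd.unique(g))
    if len(levels) < 2 or g.value_counts().min() < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")
    absent = P.sum(axis=1) == 0
    if absent.any():
        warnings.warn(f"{int(absent.sum())} taxa absent everywhere; skipped")
        P = P.loc[~absent]
    X = P.to_numpy(dtype=float)
    codes = pd.Categorical(g, categories=levels).codes
    group_idx = [np.flatnonzero(codes == k) for k in range(len(levels))]
    obs_iv, best, A, B = _indval_scores(X, group_idx)
    rng = np.random.default_rng(seed)
    count = np.zeros(len(obs_iv), dtype=np.int64)
    perm_codes = codes.copy()
    for _ in range(n_perm):
        rng.shuffle(perm_codes)
        idx = [np.flatnonzero(perm_codes == k) for k in range(len(levels))]
        perm_iv, _, _, _ = _indval_scores(X, idx)
        count += perm_iv >= obs_iv - 1e-12
    p = (1 + count) / (1 + n_perm)
    out = pd.DataFrame(
        {
            "best_group": [levels[b] for b in best],
            "A": A,
            "B": B,
            "indval": obs_iv,
            "p": p,
            "q": bh_adjust(p),
        },
        index=P.index,
    )
    out["strong"] = (out["indval"] > indval_min) & (out["p"] < p_max)
    return out


def summarize_indicators(
    results: pd.DataFrame, assignment: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Cross-tabulate indicator and strong-indicator counts by region (and class).

    ``assignment`` is the AT/IT/RT table from ``classify_taxa``; without it
    the summary is per region only.
    """
    if results.empty:
        raise ValueError("empty indicator result set")
    df = results.copy()
    if assignment is not None:
        df["label"] = assignment.loc[df.index, "label"]
        keys = ["best_group", "label"]
    else:
        keys = ["best_group"]
    grouped = df.groupby(keys, sort=False)
    out = grouped.agg(
        n_taxa=("indval", "size"), n_strong=("strong", "sum")
    ).reset_index()
    out["n_strong"] = out["n_strong"].astype(int)
    return out
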
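"""Abundance-class partitioning of OTUs into abundant / intermediate / rare taxa.

The classification follows the dual local/regional threshold framework used
for the rare biosphere: a taxon is *abundant* (AT) when it exceeds 1% of the
reads in at least one sample AND averages >= 0.1% across all samples; *rare*
(RT) when it never reaches 0.01% in any sample AND averages < 0.001%;
everything else is *intermediate* (IT).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import OtuTable, RelAbundTable, pool_by_region

__all__ = ["CLASS_LABELS", "Thresholds", "classify_taxa", "class_summary"]

CLASS_LABELS = ("AT", "IT", "RT")


class Thresholds:
    """Default class thresholds (fractions, not percent)."""

    at_local = 0.01     # > 1% in at least one sample
    at_mean = 0.001     # >= 0.1% mean across samples
    rt_local = 0.0001   # < 0.01% in every sample
    rt_mean = 0.00001   # < 0.001% mean across samples


def classify_taxa(
    relabund: RelAbundTable,
    at_local: float = Thresholds.at_local,
    at_mean: float = Thresholds.at_mean,
    rt_local: float = Thresholds.rt_local,
    rt_mean: float = Thresholds.rt_mean,
) -> pd.DataFrame:
    """Label every taxon AT/IT/RT from its per-sample relative abundances.

    Returns a DataFrame indexed by taxon_id with columns
    ``label``, ``max_local_relabund``, ``mean_relabund``.

    AT requires strict ``max > at_local`` and ``mean >= at_mean``; RT requires
    strict ``max < rt_local`` and ``mean < rt_mean``; the two conditions of
    each class must hold jointly, so AT and RT are disjoint by construction.
    """
    if not (at_local > at_mean > rt_local > rt_mean):
        raise ValueError("thresholds must satisfy at_local > at_mean > rt_local > rt_mean")
    P = relabund.proportions
    if P.shape[1] == 0 or P.shape[0] == 0:
        raise ValueError("empty relative-abundance table")
    mx = P.max(axis=1)
    mean = P.mean(axis=1)
    label = pd.Series("IT", index=P.index, name="label")
    label[(mx > at_local) & (mean >= at_mean)] = "AT"
    label[(mx < rt_local) & (mean < rt_mean)] = "RT"
    return pd.DataFrame(
        {"label": label, "max_local_relabund": mx, "mean_relabund": mean}
    )


def class_summary(
    assignment: pd.DataFrame,
    relabund: RelAbundTable,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-region richness and abundance share of each abundance class.

    For every region (or the whole table when *meta* is None) report, per
    class, the fraction of the region's observed OTUs carrying that label and
    the fraction of the region's pooled relative abundance they hold — the
    numbers behind the richness/abundance decoupling.
    """
    P = relabund.proportions
    rows = []
    if meta is None:
        scopes = {"all": list(P.columns)}
    else:
        regions = meta.loc[list(P.columns), "region"]
        scopes = {
            str(r): [s for s in P.columns if regions[s] == r]
            for r in pd.unique(regions)
        }
    for scope, cols in scopes.items():
        block = P[cols]
        present = block.sum(axis=1) > 0
        labels = assignment.loc[block.index, "label"]
        n_present = int(present.sum())
        total_ab = float(block.to_numpy().sum())
        for cls in CLASS_LABELS:
            in_cls = labels == cls
            rows.append(
                {
                    "region": scope,
                    "label": cls,
                    "n_otus": int((in_cls & present).sum()),
                    "richness_fraction": float((in_cls & present).sum() / n_present)
                    if n_present
                    else np.nan,
                    "abundance_fraction": float(
                        block.loc[in_cls.to_numpy()].to_numpy().sum() / total_ab
                    ),
                }
            )
    return pd.DataFrame(rows)
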
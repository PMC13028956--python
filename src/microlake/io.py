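"""Reading, writing and validation of OTU tables, metadata, trees and environment tables.

All tabular formats are plain TSV (UTF-8, tab-delimited, header row); trees are
newick with branch lengths. The in-memory substrate is a pandas DataFrame with
taxa as rows and samples as columns, wrapped in :class:`OtuTable` /
:class:`RelAbundTable` to carry the validated invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "OtuTable",
    "RelAbundTable",
    "OtuFormatError",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "read_env_table",
    "read_taxonomy",
    "read_tree",
    "write_tree",
    "cophenetic_matrix",
    "rarefy",
    "to_relative",
    "pool_by_region",
    "RegionPools",
]

REGIONS = ("hPollut", "HABs", "SubmP")

ENV_VARIABLES = (
    "BOD5", "COD", "TP", "TN", "SS", "ChlA",
    "permanganate_index", "pH", "DO", "temperature",
    "transparency", "conductivity",
)


class OtuFormatError(ValueError):
    """Raised when a table violates a structural invariant (duplicate ids, bad header)."""


@dataclass(frozen=True)
class OtuTable:
    """Integer count table, taxa x samples.

    Invariants: unique taxon and sample ids, non-negative integer counts,
    every sample (column) sum > 0.
    """

    counts: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()].tolist()
            raise OtuFormatError(f"duplicate taxon ids: {dup}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()].tolist()
            raise OtuFormatError(f"duplicate sample ids: {dup}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr), atol=0):
                raise ValueError("counts must be integers")
            object.__setattr__(self, "counts", df.astype(np.int64))
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        colsum = arr.sum(axis=0)
        if (colsum == 0).any():
            empty = df.columns[colsum == 0].tolist()
            raise ValueError(f"all-zero sample column(s): {empty}")

    @property
    def taxon_ids(self) -> list[str]:
        return [str(t) for t in self.counts.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.counts.columns]

    @property
    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def drop_empty_taxa(self) -> "OtuTable":
        keep = self.counts.sum(axis=1) > 0
        return OtuTable(self.counts.loc[keep])


@dataclass(frozen=True)
class RelAbundTable:
    """Relative abundance table, taxa x samples; every column sums to 1."""

    proportions: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        colsum = self.proportions.sum(axis=0).to_numpy()
        if not np.allclose(colsum, 1.0, atol=1e-9):
            raise ValueError("relative-abundance columns must sum to 1")
        if (self.proportions.to_numpy() < 0).any():
            raise ValueError("proportions must be non-negative")

    @property
    def taxon_ids(self) -> list[str]:
        return [str(t) for t in self.proportions.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.proportions.columns]


def read_otu_table(path: str | Path) -> OtuTable:
    """Read a TSV count table (first column taxon ids, header row sample ids).

    If the header's first field is ``#sample_id`` the file is stored
    samples-as-rows and is transposed on read.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dup = {h for h in header[1:] if header[1:].count(h) > 1}
    if dup:
        raise OtuFormatError(f"duplicate sample ids: {sorted(dup)}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.index.name is not None and str(df.index.name).lstrip("#").lower() in (
        "sample_id",
        "sampleid",
    ):
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise OtuFormatError(f"non-numeric cells in {path}")
    if np.issubdtype(arr.dtype, np.floating) and not (arr == np.floor(arr)).all():
        raise ValueError(f"non-integer counts in {path}")
    return OtuTable(df.astype(np.int64))


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write canonical TSV: taxa as rows, index label ``#OTU_ID``."""
    df = table.counts.copy()
    df.index.name = "#OTU_ID"
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV: sample_id, region, plot, replicate, date."""
    meta = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
    unknown = set(meta["region"]) - set(REGIONS)
    if unknown:
        raise ValueError(f"unknown region label(s): {sorted(unknown)}")
    return meta


def validate_metadata(table: OtuTable, meta: pd.DataFrame) -> None:
    missing = set(table.sample_ids) - set(meta.index)
    if missing:
        raise ValueError(f"samples missing from metadata: {sorted(missing)}")
    sizes = meta.loc[list(table.sample_ids), "region"].value_counts()
    if (sizes < 2).any():
        raise ValueError("every region needs at least 2 samples")


def read_env_table(path: str | Path) -> pd.DataFrame:
    env = pd.read_csv(path, sep="\t").set_index("sample_id")
    env = env.astype(float)
    if not np.isfinite(env.to_numpy()).all():
        raise ValueError("environment table contains non-finite values")
    return env


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Seven-rank taxonomy TSV indexed by taxon_id (domain..genus, species optional)."""
    return pd.read_csv(path, sep="\t", dtype=str).set_index("taxon_id")


def read_tree(path: str | Path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise ValueError(f"negative branch length at {node.name!r}")
    return tree


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def cophenetic_matrix(tree: TreeNode, taxon_ids: list[str] | None = None):
    """Patristic (tip-to-tip) distance matrix.

    Returns ``(ids, D)`` where ``D`` is a symmetric zero-diagonal ndarray
    aligned to ``ids``. If *taxon_ids* is given, the matrix is restricted to
    (and ordered by) those tips; a missing tip raises ``ValueError`` naming it.
    """
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    if taxon_ids is None:
        return ids, dm.data.copy()
    index = {t: i for i, t in enumerate(ids)}
    missing = [t for t in taxon_ids if t not in index]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing}")
    order = [index[t] for t in taxon_ids]
    return list(taxon_ids), dm.data[np.ix_(order, order)].copy()


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to *depth* reads without replacement.

    Each column is drawn from a multivariate hypergeometric distribution over
    its observed counts, so column sums are exactly *depth* and no absent
    taxon can appear.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    sums = table.sample_sums
    short = sums[sums < depth]
    if len(short):
        raise ValueError(
            f"depth {depth} exceeds reads in sample(s): {short.index.tolist()}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    for j, col in enumerate(table.counts.to_numpy().T):
        out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return OtuTable(
        pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    )


def to_relative(table: OtuTable | pd.DataFrame) -> RelAbundTable:
    """Divide each sample column by its sum."""
    df = table.counts if isinstance(table, OtuTable) else table
    colsum = df.sum(axis=0)
    if (colsum == 0).any():
        raise ValueError("cannot normalize an all-zero sample")
    return RelAbundTable(df.astype(float) / colsum)


@dataclass(frozen=True)
class RegionPools:
    """Per-region presence sets plus Venn bookkeeping with both denominators."""

    present: dict[str, set]
    relabund: RelAbundTable = field(repr=False)
    meta: pd.DataFrame = field(repr=False)

    @property
    def union(self) -> set:
        out: set = set()
        for s in self.present.values():
            out |= s
        return out

    @property
    def shared(self) -> set:
        sets = list(self.present.values())
        out = sets[0].copy()
        for s in sets[1:]:
            out &= s
        return out

    @property
    def specific(self) -> dict[str, set]:
        out = {}
        for region, s in self.present.items():
            others: set = set()
            for r2, s2 in self.present.items():
                if r2 != region:
                    others |= s2
            out[region] = s - others
        return out

    def subset_abundance(self, taxa, region: str | None = None) -> float:
        """Summed relative abundance of a taxon subset, pooled over a region's
        samples (or over all samples)."""
        taxa = [t for t in taxa if t in self.relabund.proportions.index]
        if region is None:
            cols = self.relabund.sample_ids
        else:
            if region not in self.present:
                raise ValueError(f"unknown region {region!r}")
            cols = [s for s in self.relabund.sample_ids
                    if self.meta.loc[s, "region"] == region]
        block = self.relabund.proportions.loc[taxa, cols]
        return float(block.to_numpy().sum() / len(cols))

    def venn_summary(self) -> dict:
        """Venn cell sizes and shared/specific fractions.

        Fractions are reported against two denominators: the union of all
        regional OTU sets, and the sum of per-region richnesses (the two
        conventions seen in published Venn percentages).
        """
        union_n = len(self.union)
        sum_richness = sum(len(s) for s in self.present.values())
        shared = self.shared
        summary = {
            "total_otus": union_n,
            "sum_region_richness": sum_richness,
            "region_richness": {r: len(s) for r, s in self.present.items()},
            "shared_all": len(shared),
            "shared_fraction_union": len(shared) / union_n,
            "shared_fraction_sum": len(shared) / sum_richness,
            "specific": {r: len(s) for r, s in self.specific.items()},
            "specific_fraction_union": {
                r: len(s) / union_n for r, s in self.specific.items()
            },
            "shared_abundance": {
                r: self.subset_abundance(shared, r) for r in self.present
            },
            "specific_abundance": {
                r: self.subset_abundance(s, r) for r, s in self.specific.items()
            },
        }
        return summary


def pool_by_region(table: OtuTable, meta: pd.DataFrame) -> RegionPools:
    """Pool samples per region: presence sets, Venn cells and abundance shares."""
    validate_metadata(table, meta)
    rel = to_relative(table)
    present: dict[str, set] = {}
    regions = meta.loc[list(table.sample_ids), "region"]
    for region in pd.unique(regions):
        cols = [s for s in table.sample_ids if regions[s] == region]
        pooled = table.counts[cols].sum(axis=1)
        present[str(region)] = set(pooled.index[pooled > 0].astype(str))
    return RegionPools(present=present, relabund=rel, meta=meta)
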
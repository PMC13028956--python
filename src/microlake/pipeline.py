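"""End-to-end orchestration: load or simulate inputs, run every stage, report.

The run report is a JSON-serializable dict mirroring the summary statistics a
lake-microbiome survey reports: Venn cells with both denominators, abundance
class shares, Shannon by region, PERMANOVA, differential-taxon counts,
network modularity/robustness, indicator counts, and assembly-process
fractions. Every fraction is emitted with its numerator and denominator, and
every random stage consumes a child seed derived from the master seed by
stage-name hashing so adding a stage never perturbs earlier ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assembly import assembly_analysis, process_fractions
from .classes import class_summary, classify_taxa
from .diversity import (
    anova_tukey,
    bray_curtis,
    env_correlation,
    env_correlation_summary,
    kruskal_per_taxon,
    pcoa,
    permanova,
    shannon,
)
from .indval import indval, summarize_indicators
from .io import (
    OtuTable,
    pool_by_region,
    rarefy,
    read_env_table,
    read_metadata,
    read_otu_table,
    read_taxonomy,
    read_tree,
    to_relative,
    write_otu_table,
)
from .network import build_network, class_subnetwork, compare_robustness, modularity
from .simulate import SimulationConfig, simulate_communities, simulate_env_table

log = logging.getLogger("microlake")

__all__ = ["RunConfig", "run_pipeline", "function_table_tests", "child_seed", "pct"]


def child_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def pct(num: float, den: float) -> dict:
    """(numerator, denominator, fraction, percent) with round-half-even to 1 dp."""
    frac = num / den if den else float("nan")
    return {
        "numerator": float(num),
        "denominator": float(den),
        "fraction": frac,
        "percent": round(100 * frac, 1) if den else float("nan"),
    }


@dataclass
class RunConfig:
    """Pipeline configuration; either file paths or a simulate block."""

    otu_path: str | None = None
    meta_path: str | None = None
    tree_path: str | None = None
    env_path: str | None = None
    taxonomy_path: str | None = None
    function_map_path: str | None = None
    simulate: SimulationConfig | None = None
    depth: int | str = "min"
    at_local: float = 0.01   # abundant: > 1% in at least one sample
    at_mean: float = 0.001   # abundant: mean >= 0.1%
    rt_local: float = 0.0001  # rare: < 0.01% in every sample
    rt_mean: float = 0.00001  # rare: mean < 0.001%
    dominant_mean: float = 0.001  # "dominant" filter: mean rel. abundance > 0.1%
    network_top_n: int = 100
    network_rho_min: float = 0.6
    network_p_max: float = 0.05
    removal_fraction: float = 0.5
    robustness_iter: int = 500
    indval_n_perm: int = 999
    indval_min: float = 0.7
    indval_p_max: float = 0.05
    assembly_n_null: int = 999
    assembly_weighted: bool = True
    run_assembly: bool = True
    n_perm: int = 999
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimulationConfig(**sim)
        return cfg


def _load_inputs(config: RunConfig):
    if config.simulate is not None:
        sim = config.simulate
        table, meta, truth = simulate_communities(sim)
        tree = truth["tree"]
        env = simulate_env_table(meta, seed=child_seed(config.seed, "env"))
        taxonomy = None
    else:
        if config.otu_path is None or config.meta_path is None:
            raise ValueError("need otu_path and meta_path, or a simulate block")
        table = read_otu_table(config.otu_path)
        meta = read_metadata(config.meta_path)
        tree = read_tree(config.tree_path) if config.tree_path else None
        env = read_env_table(config.env_path) if config.env_path else None
        taxonomy = (
            read_taxonomy(config.taxonomy_path) if config.taxonomy_path else None
        )
    return table, meta, tree, env, taxonomy


def _genus_table(rel: pd.DataFrame, taxonomy: pd.DataFrame) -> pd.DataFrame:
    genus = taxonomy.loc[rel.index, "genus"]
    return rel.groupby(genus.to_numpy()).sum()


def function_table_tests(
    function_map: pd.DataFrame, relabund, groups, alpha: float = 0.05
) -> dict:
    """Per-function Kruskal-Wallis tests on summed member abundances.

    ``function_map`` needs columns ``taxon_id`` and ``function``; an optional
    ``category`` column yields per-category counts among the significant
    functions. Unknown taxa raise; an empty map raises.
    """
    if function_map.empty:
        raise ValueError("empty function map")
    P = relabund.proportions if hasattr(relabund, "proportions") else relabund
    unknown = set(function_map["taxon_id"]) - set(P.index.astype(str))
    if unknown:
        raise ValueError(f"function map references unknown taxa: {sorted(unknown)[:5]}")
    func_abund = {}
    for fn, sub in function_map.groupby("function", sort=False):
        func_abund[fn] = P.loc[sub["taxon_id"]].sum(axis=0)
    F = pd.DataFrame(func_abund).T
    # test the raw summed abundances (no renormalization across functions)
    from scipy import stats as _stats

    g = pd.Series(list(groups), index=P.columns) if not isinstance(groups, pd.Series) else groups
    idx_by_group = [
        np.flatnonzero((g.loc[F.columns] == lev).to_numpy())
        for lev in pd.unique(g.loc[F.columns])
    ]
    pvals = []
    for _, row in F.iterrows():
        arr = row.to_numpy(dtype=float)
        if np.ptp(arr) == 0:
            pvals.append(1.0)
        else:
            pvals.append(_stats.kruskal(*[arr[i] for i in idx_by_group]).pvalue)
    out = pd.DataFrame({"p": pvals}, index=F.index)
    out["significant"] = out["p"] < alpha
    result = {
        "n_functions": len(out),
        "significant": pct(int(out["significant"].sum()), len(out)),
        "per_function": out,
        "function_abundance": F,
    }
    if "category" in function_map.columns:
        cat = function_map.drop_duplicates("function").set_index("function")["category"]
        sig = out.index[out["significant"]]
        n_sig = len(sig)
        by_cat = cat.loc[sig].value_counts()
        result["categories"] = {
            str(c): pct(int(n), n_sig) for c, n in by_cat.items()
        }
    return result


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute every stage in order and return the run report.

    Stage order: IO/normalization -> abundance classes -> diversity &
    ordination -> co-occurrence networks -> indicator species -> assembly
    null models. When *outdir* is given, per-stage TSVs, the JSON report and
    a MANIFEST of completed stages are written there.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    report: dict = {"version": __version__, "seed": config.seed}

    def checkpoint(stage: str) -> None:
        manifest.append(stage)
        if out is not None:
            (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1))

    table, meta, tree, env, taxonomy = _load_inputs(config)
    depth = (
        int(table.sample_sums.min()) if config.depth == "min" else int(config.depth)
    )
    norm_seed = child_seed(config.seed, "rarefy")
    table = rarefy(table, depth, seed=norm_seed)
    log.info("normalized %d samples to depth %d (seed %d)",
             len(table.sample_ids), depth, norm_seed)
    rel = to_relative(table)
    groups = meta.loc[list(table.sample_ids), "region"]
    report["inputs"] = {
        "n_taxa": len(table.taxon_ids),
        "n_samples": len(table.sample_ids),
        "depth": depth,
        "regions": groups.value_counts().to_dict(),
    }
    if out is not None:
        write_otu_table(table, out / "otu_normalized.tsv")
    checkpoint("normalize")

    pools = pool_by_region(table, meta)
    report["venn"] = pools.venn_summary()
    report["venn"]["shared_pct_union"] = pct(
        report["venn"]["shared_all"], report["venn"]["total_otus"]
    )
    checkpoint("venn")

    assignment = classify_taxa(
        rel, at_local=config.at_local, at_mean=config.at_mean,
        rt_local=config.rt_local, rt_mean=config.rt_mean,
    )
    summary = class_summary(assignment, rel, meta)
    report["abundance_classes"] = {
        "counts": assignment["label"].value_counts().to_dict(),
        "per_region": summary.to_dict(orient="records"),
    }
    if out is not None:
        assignment.to_csv(out / "abundance_classes.tsv", sep="\t")
        summary.to_csv(out / "class_summary.tsv", sep="\t", index=False)
    checkpoint("classes")

    h = shannon(rel)
    shannon_test = anova_tukey(h.to_numpy(), groups.to_numpy())
    dm = bray_curtis(rel)
    ord_res = pcoa(dm)
    perm = permanova(
        dm, groups, n_perm=config.n_perm, seed=child_seed(config.seed, "permanova")
    )
    genus_rel = _genus_table(rel.proportions, taxonomy) if taxonomy is not None else rel
    kw = kruskal_per_taxon(genus_rel, groups, min_mean=0.0)
    report["diversity"] = {
        "shannon_by_region": {
            r: {"mean": float(shannon_test.group_means[r]),
                "se": float(shannon_test.group_se[r]),
                "letter": shannon_test.letters[r]}
            for r in shannon_test.group_means.index
        },
        "shannon_anova_p": shannon_test.p_value,
        "pcoa_pc1_pc2_pct": [
            round(100 * float(v), 1) for v in ord_res.proportion_explained[:2]
        ],
        "permanova": {"F": perm.statistic, "p": perm.p_value},
        "differential_taxa": pct(int(kw["significant"].sum()), len(kw)),
        "taxon_level": "genus" if taxonomy is not None else "otu",
    }
    if out is not None:
        h.to_frame().to_csv(out / "shannon.tsv", sep="\t")
        dm.to_data_frame().to_csv(out / "bray_curtis.tsv", sep="\t")
        ord_res.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
        kw.to_csv(out / "kruskal_per_taxon.tsv", sep="\t")
    checkpoint("diversity")

    if env is not None:
        corr = env_correlation(rel, env, top_n=50)
        report["env_correlation"] = {
            "significant_fraction_by_variable": {
                k: round(float(v), 3)
                for k, v in env_correlation_summary(corr).items()
            }
        }
        if out is not None:
            corr.to_csv(out / "env_correlation.tsv", sep="\t", index=False)
        checkpoint("env_correlation")

    node_tags = assignment[["label"]]
    region_networks = {}
    net_report = {}
    for region in pd.unique(groups):
        cols = [s for s in table.sample_ids if groups[s] == region]
        sub_rel = to_relative(table.counts[cols])
        net = build_network(
            sub_rel,
            top_n=config.network_top_n,
            rho_min=config.network_rho_min,
            p_max=config.network_p_max,
            node_tags=node_tags,
        )
        entry = {
            "n_nodes": net.graph.number_of_nodes(),
            "n_edges": net.graph.number_of_edges(),
            "positive_edges": net.n_positive,
            "negative_edges": net.n_negative,
        }
        if net.graph.number_of_edges() > 0:
            q, _ = modularity(net)
            entry["modularity"] = q
        if net.graph.number_of_nodes() >= 4:
            region_networks[str(region)] = net
        net_report[str(region)] = entry
        if out is not None:
            from .network import write_edge_list

            write_edge_list(net, out / f"network_{region}.tsv")
    rob_df, rob_test = compare_robustness(
        region_networks,
        removal_fraction=config.removal_fraction,
        n_iter=config.robustness_iter,
        seed=child_seed(config.seed, "robustness"),
    )
    if rob_test is not None:
        for region in rob_test.group_means.index:
            net_report[region]["robustness"] = {
                "mean": float(rob_test.group_means[region]),
                "se": float(rob_test.group_se[region]),
                "letter": rob_test.letters[region],
            }
    # abundance-class subnetworks of a whole-dataset network
    whole = build_network(
        rel,
        top_n=config.network_top_n,
        rho_min=config.network_rho_min,
        p_max=config.network_p_max,
        node_tags=node_tags,
    )
    class_nets = {}
    for cls in ("AT", "IT", "RT"):
        taxa = assignment.index[assignment["label"] == cls]
        sub = class_subnetwork(whole, taxa)
        if sub.number_of_nodes() >= 4:
            class_nets[cls] = sub
    _, cls_test = compare_robustness(
        class_nets,
        removal_fraction=config.removal_fraction,
        n_iter=config.robustness_iter,
        seed=child_seed(config.seed, "class_robustness"),
    )
    if cls_test is not None:
        net_report["class_robustness"] = {
            cls: {"mean": float(cls_test.group_means[cls]),
                  "se": float(cls_test.group_se[cls]),
                  "letter": cls_test.letters[cls]}
            for cls in cls_test.group_means.index
        }
    report["network"] = net_report
    if out is not None and not rob_df.empty:
        rob_df.to_csv(out / "robustness.tsv", sep="\t", index=False)
    checkpoint("network")

    iv = indval(
        rel,
        groups,
        n_perm=config.indval_n_perm,
        seed=child_seed(config.seed, "indval"),
        indval_min=config.indval_min,
        p_max=config.indval_p_max,
    )
    iv_summary = summarize_indicators(iv, assignment)
    report["indicators"] = {
        "n_strong": int(iv["strong"].sum()),
        "by_region_class": iv_summary.to_dict(orient="records"),
    }
    if out is not None:
        iv.to_csv(out / "indval.tsv", sep="\t")
    checkpoint("indval")

    if config.run_assembly:
        if tree is None:
            log.warning("no phylogeny supplied: assembly partition uses RCbray only "
                        "(selection cannot be inferred)")
            report["assembly_note"] = "no tree: betaNTI unavailable, RCbray-only partition"
        pairs = assembly_analysis(
            table,
            meta,
            tree=tree,
            assignment=assignment,
            n_null=config.assembly_n_null,
            seed=child_seed(config.seed, "assembly"),
            weighted=config.assembly_weighted,
        )
        frac_scope = process_fractions(pairs[pairs["class_subset"] == "all"], by="scope")
        frac_class = process_fractions(pairs, by="class_subset")
        report["assembly"] = {
            "by_scope": frac_scope.round(4).to_dict(orient="index"),
            "by_class": frac_class.round(4).to_dict(orient="index"),
        }
        if out is not None:
            pairs.to_csv(out / "assembly_pairs.tsv", sep="\t", index=False)
        checkpoint("assembly")

    if config.function_map_path:
        fmap = pd.read_csv(config.function_map_path, sep="\t", dtype=str)
        fres = function_table_tests(fmap, rel, groups)
        report["functions"] = {
            "n_functions": fres["n_functions"],
            "significant": fres["significant"],
            "categories": fres.get("categories", {}),
        }
        if out is not None:
            fres["per_function"].to_csv(out / "function_tests.tsv", sep="\t")
        checkpoint("functions")

    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report
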
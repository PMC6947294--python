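"""End-to-end pipeline: gene sets -> ages -> divergence -> resampling ->
network statistics -> functional age profiles.

``run_pipeline`` executes the stages on files named in a ``PipelineConfig``
and writes per-stage tables plus a machine-readable run manifest (inputs,
seed, config hash, per-stage record counts).  Re-running with the same
config and inputs reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from phylostress import io as pio
from phylostress.divergence import ng86_ka_ks
from phylostress.function_evolution import enrich_terms, term_age_profile
from phylostress.gene_sets import (
    build_stress_gene_set,
    ochiai_distance,
    overlap_stats,
    select_terms_by_keyword,
    upgma_tree,
)
from phylostress.network_analysis import (
    age_assortativity,
    cluster_quality,
    degree_age_correlation,
    dpai_by_distance,
    filter_network,
    node_audit,
)
from phylostress.phylostratigraphy import assign_pai_table, pai_distribution
from phylostress.resampling import DiscreteBins, IntervalBins, permutation_test

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters of a full run (all paths are TSV/FASTA/OBO)."""

    lineage_file: str
    species_file: str
    focal_species: str
    hits_file: str
    codon_fasta: str
    ontology_file: str
    annotations_file: str
    edges_file: str
    out_dir: str
    stress_keywords: list = field(default_factory=list)
    term_exclusions: dict = field(default_factory=dict)  # keyword -> excluded term ids
    clusters_file: str = ""
    identity_threshold: float = 0.5
    collapse_names: list = field(default_factory=list)
    collapse_mode: str = "keep_ranks"
    n_permutations: int = 100_000
    seed: int = 0
    alpha: float = 0.05
    score_threshold: float = 0.7
    neutral_tolerance: float = 0.05

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to out_dir)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
        "warnings": [],
    }

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                counts = fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"].append(
                {
                    "name": name,
                    "records": counts,
                    "seconds": round(time.perf_counter() - t0, 3),
                }
            )

        return wrap

    # ---------------------------------------------------------- gene sets
    ontology = pio.read_ontology_obo(config.ontology_file)
    annotations = pio.read_annotations(config.annotations_file)
    sets = []

    @stage("gene_sets")
    def _():
        for keyword in config.stress_keywords:
            terms = select_terms_by_keyword(
                ontology, keyword, config.term_exclusions.get(keyword, frozenset())
            )
            gs = build_stress_gene_set(annotations, terms, name=keyword)
            if not gs.genes:
                manifest["warnings"].append(f"gene set {keyword!r} is empty")
            sets.append(gs)
            pio.write_gene_set(gs, out / f"geneset_{keyword}.tsv")
        if len(sets) >= 2:
            ov = overlap_stats(sets)
            ov["counts"].to_csv(out / "overlap_counts.tsv", sep="\t")
            ov["fractions"].to_csv(out / "overlap_fractions.tsv", sep="\t")
            ov["unique"].to_csv(out / "overlap_unique.tsv", sep="\t")
            pio.write_gene_set(ov["union"], out / "geneset_all_stresses_nr.tsv")
            names = [s.stress for s in sets]
            dist = pd.DataFrame(
                [[ochiai_distance(a.genes, b.genes) if a.genes and b.genes else 1.0
                  for b in sets] for a in sets],
                index=names,
                columns=names,
            )
            for n in names:
                dist.loc[n, n] = 0.0
            (out / "set_similarity.nwk").write_text(upgma_tree(dist).to_newick() + "\n")
        return {"sets": len(sets), "genes_union": len(set().union(*(s.genes for s in sets)) if sets else set())}

    # ------------------------------------------------------------ ages
    from phylostress.taxonomy import collapse_single_child

    lineage = pio.read_lineage(config.lineage_file, config.species_file, config.focal_species)
    if config.collapse_names:
        lineage = collapse_single_child(
            lineage, set(config.collapse_names), mode=config.collapse_mode
        )
    hits = pio.read_ortholog_hits(config.hits_file)
    ages_df = None

    @stage("phylostratigraphy")
    def _():
        nonlocal ages_df
        all_genes = sorted(hits["gene_id"].unique())
        ages_df = assign_pai_table(hits, config.identity_threshold, lineage, all_genes)
        pio.write_gene_ages(ages_df, out / "gene_ages.tsv")
        profile = pai_distribution(ages_df["pai"], lineage)
        pd.DataFrame(
            {"rank": profile.bins, "count": profile.counts, "freq": profile.freq}
        ).to_csv(out / "pai_distribution.tsv", sep="\t", index=False)
        return {"genes": len(ages_df)}

    # ------------------------------------------------------- divergence
    alignments = pio.read_codon_pairs(config.codon_fasta)
    div_results = []

    @stage("divergence")
    def _():
        div_results.extend(ng86_ka_ks(a) for a in alignments)
        pio.write_divergence_results(div_results, out / "divergence.tsv")
        n_excluded = sum(1 for r in div_results if r.status == "excluded_ks_zero")
        if n_excluded:
            manifest["warnings"].append(f"{n_excluded} gene(s) excluded with Ks = 0")
        return {"pairs": len(div_results), "excluded_ks_zero": n_excluded}

    # ------------------------------------------------------- resampling
    @stage("resampling")
    def _():
        age_map = dict(zip(ages_df["gene_id"], ages_df["pai"]))
        bg_genes = sorted(age_map)
        pai_values = np.array([age_map[g] for g in bg_genes], dtype=float)
        gene_pos = {g: i for i, g in enumerate(bg_genes)}
        di_map = {r.gene: r.di for r in div_results if r.status == "ok"}
        di_genes = sorted(set(di_map) & set(bg_genes))
        di_values = np.array([di_map[g] for g in di_genes])
        di_pos = {g: i for i, g in enumerate(di_genes)}
        report = {}
        for gs in sets:
            entry = {}
            idx = np.array([gene_pos[g] for g in sorted(gs.genes) if g in gene_pos])
            if idx.size:
                res = permutation_test(
                    pai_values,
                    idx,
                    binning=DiscreteBins(lineage.ranks),
                    n_permutations=config.n_permutations,
                    seed=config.seed,
                    alpha=config.alpha,
                )
                entry["pai"] = _result_to_dict(res)
            didx = np.array([di_pos[g] for g in sorted(gs.genes) if g in di_pos])
            if didx.size:
                res = permutation_test(
                    di_values,
                    didx,
                    binning=IntervalBins(),
                    n_permutations=config.n_permutations,
                    seed=config.seed + 1,
                    alpha=config.alpha,
                )
                entry["di"] = _result_to_dict(res)
            report[gs.stress] = entry
        pio.write_json(report, out / "permutation_tests.json")
        return {"sets_tested": len(report), "n_permutations": config.n_permutations}

    # ---------------------------------------------------------- network
    @stage("network_analysis")
    def _():
        age_map = dict(zip(ages_df["gene_id"], ages_df["pai"]))
        edges = pio.read_edges(config.edges_file)
        nodes = {a for a, _, _ in edges} | {b for _, b, _ in edges}
        ages = {n: age_map[n] for n in nodes if n in age_map}
        missing = nodes - set(ages)
        if missing:
            manifest["warnings"].append(
                f"{len(missing)} network node(s) without an age were dropped"
            )
        edges = [(a, b, s) for a, b, s in edges if a in ages and b in ages]
        clusters = pio.read_clusters(config.clusters_file) if config.clusters_file else None
        net = filter_network(
            edges, ages, threshold=config.score_threshold, clusters=clusters
        )
        stats = {"n_nodes": net.n_nodes, "n_edges": net.n_edges,
                 "audit": node_audit(net, nodes)}
        if net.n_edges:
            ar = age_assortativity(net)
            stats["assortativity"] = {
                "r_a": ar.r_a, "sigma": ar.sigma, "n_pairs": ar.n_pairs,
                "defined": ar.defined,
            }
        if net.n_nodes >= 3:
            try:
                corr = degree_age_correlation(net)
                stats["degree_age"] = {"r": corr.r, "p_value": corr.p_value}
            except ValueError as exc:
                manifest["warnings"].append(str(exc))
        dist = dpai_by_distance(net)
        rows = [
            (str(bucket), dpai, count)
            for bucket, counter in dist.items()
            for dpai, count in sorted(counter.items())
        ]
        pd.DataFrame(rows, columns=["distance", "abs_dpai", "pairs"]).to_csv(
            out / "dpai_by_distance.tsv", sep="\t", index=False
        )
        if net.clusters:
            quality = [
                cluster_quality(net, lab) for lab in sorted(set(net.clusters.values()))
            ]
            pd.DataFrame(
                [(q.cluster, q.deg_int, q.deg_ext, q.k_net) for q in quality],
                columns=["cluster", "deg_int", "deg_ext", "k_net"],
            ).to_csv(out / "cluster_quality.tsv", sep="\t", index=False)
        pio.write_json(stats, out / "network_stats.json")
        return {"nodes": net.n_nodes, "edges": net.n_edges}

    # ----------------------------------------------- function evolution
    @stage("function_evolution")
    def _():
        age_map = dict(zip(ages_df["gene_id"], ages_df["pai"]))
        background = set(age_map)
        profiles = []
        n_enriched = 0
        for gs in sets:
            genes = gs.genes & background
            if not genes:
                continue
            table = enrich_terms(genes, background, annotations, alpha=config.alpha)
            table.insert(0, "stress", gs.stress)
            table.to_csv(out / f"enrichment_{gs.stress}.tsv", sep="\t", index=False)
            scope_ages = {g: age_map[g] for g in genes}
            for term in table.loc[table["significant"], "term"]:
                try:
                    prof = term_age_profile(term, scope_ages, annotations)
                except ValueError:
                    continue
                n_enriched += 1
                for rank, pct in sorted(prof.freq.items()):
                    profiles.append((gs.stress, term, rank, pct, prof.n_genes,
                                     prof.acquisition_rank))
        pd.DataFrame(
            profiles,
            columns=["stress", "term", "rank", "percentage", "n_genes",
                     "acquisition_rank"],
        ).to_csv(out / "term_age_profiles.tsv", sep="\t", index=False)
        return {"profiled_terms": n_enriched}

    manifest["n_stages"] = len(manifest["stages"])
    pio.write_json(manifest, out / "manifest.json")
    return manifest


def _result_to_dict(res) -> dict:
    out = {
        "n_permutations": res.n_permutations,
        "seed": res.seed,
        "bins": list(res.bins),
    }
    for stat in res.observed:
        out[stat] = {
            "observed": res.observed[stat],
            "n_rand": res.n_rand[stat],
            "p": res.p[stat],
            "flag": res.flags[stat],
        }
    return out
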
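"""End-to-end orchestration: filter -> per-trait prescreen/PLS/LDA ->
coabundance networks -> MCL -> enrichment -> overlap report.

The pipeline mirrors the staged analysis it implements: the gene filter
runs once; each trait is screened and carried through sequential PLS
selection and LDA of its high/low groups; the first coabundance network
covers every filtered gene at the covering threshold and is clustered
coarsely; clusters holding selected genes are carried into a tighter
second network whose clusters are tested for enrichment of the per-trait
gene sets. Every stage output is persisted so each number in a rendered
table can be re-derived, and the whole run is deterministic given the
configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import AbundanceMatrix, filter_genes, read_abundance, read_annotation
from .discriminant import classify, fit_lda
from .network import (CoabundanceNetwork, Clustering, build_network, carry_forward,
                      correlation_matrix, covering_threshold, enrich, mcl_cluster,
                      overlap_sets, trait_gene_sets, write_graphml)
from .phenotypes import TRAITS, add_group_labels, class6_labels, read_phenotypes, trait_correlations
from .pls import GeneSelection, sequential_select
from .prescreen import prescreen_all

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    abundance_path: str | None = None
    phenotypes_path: str | None = None
    annotation_path: str | None = None
    output_dir: str = "results"
    traits: tuple[str, ...] = TRAITS
    # gene filter
    max_absent: int = 2
    min_mean: float = 1e-5
    filter_mode: str = "either"
    drop_unannotated: bool = True  # only when an annotation table is given
    # prescreen
    alpha: float = 0.1
    # sequential PLS
    vip_threshold: float = 1.0
    max_drop_frac: float = 0.2
    eval_factors: int = 3
    max_factors_cv: int = 10
    rsq_tolerance: float = 3.0
    criterion: str = "combined"
    # networks
    t1: str | float = "auto"  # covering threshold, or a fixed value
    t2: float = 0.80
    inflation1: float = 6.0
    pre_inflation1: float = 6.0
    inflation2: float = 2.0
    pre_inflation2: float = 2.0
    enrichment_alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        unknown = set(self.traits) - set(TRAITS)
        if unknown:
            raise ValueError(f"unknown traits: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "traits" in data:
            data["traits"] = tuple(data["traits"])
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class TraitResult:
    trait: str
    n_screened: int
    n_retained: int
    prescreen_table: pd.DataFrame
    selection: GeneSelection
    lda_resub_accuracy: float
    lda_loo_accuracy: float | None
    ld1_scores: pd.DataFrame


@dataclass
class StudyReport:
    config: PipelineConfig
    n_genes_input: int
    n_genes_filtered: int
    trait_results: dict[str, TraitResult]
    trait_correlation: pd.DataFrame
    trait_correlation_p: pd.DataFrame
    t1: float
    network1: CoabundanceNetwork
    clustering1: Clustering
    carried_nodes: list[str]
    network2: CoabundanceNetwork
    clustering2: Clustering
    enrichment: pd.DataFrame
    overlaps: dict
    metadata: dict = field(default_factory=dict)

    def selection_table(self, trait: str,
                        annotation: pd.DataFrame | None = None) -> pd.DataFrame:
        """Per-trait selection table with cluster ids joined (``NC`` for
        genes absent from the clustered second-stage network)."""
        sel = self.trait_results[trait].selection.table.copy()
        assign = self.clustering2.assignment
        sel["cluster"] = [str(int(assign[g])) if g in assign.index else "NC"
                          for g in sel["ko"]]
        if annotation is not None:
            sel = sel.merge(annotation, on="ko", how="left")
        return sel


def run_all(config: PipelineConfig,
            abundance: AbundanceMatrix | None = None,
            phenotypes: pd.DataFrame | None = None,
            annotation: pd.DataFrame | None = None) -> StudyReport:
    """Execute the full pipeline; inputs may be in-memory or paths."""
    config.validate()
    stage = "load"
    try:
        if abundance is None:
            abundance = read_abundance(config.abundance_path)
        if phenotypes is None:
            phenotypes = read_phenotypes(config.phenotypes_path)
        if annotation is None and config.annotation_path:
            annotation = read_annotation(config.annotation_path)

        stage = "filter"
        filtered, removal_log = filter_genes(
            abundance, max_absent=config.max_absent, min_mean=config.min_mean,
            filter_mode=config.filter_mode)
        if annotation is not None and config.drop_unannotated:
            known = set(annotation["ko"])
            keep = [g for g in filtered.genes if g in known]
            dropped = filtered.shape[1] - len(keep)
            if dropped:
                logger.info("dropping %d unannotated genes", dropped)
                filtered = AbundanceMatrix(values=filtered.values[keep])

        stage = "phenotypes"
        phen = add_group_labels(phenotypes, traits=config.traits)
        class6 = class6_labels(phen)
        corr, corr_p = trait_correlations(phen, traits=config.traits)

        trait_results: dict[str, TraitResult] = {}
        for trait in config.traits:
            stage = f"prescreen:{trait}"
            scr = prescreen_all(filtered, phen, trait, alpha=config.alpha)
            retained = scr.retained
            stage = f"select:{trait}"
            sel = sequential_select(
                filtered.values[retained], phen[trait].to_numpy(float), trait,
                class6=class6, vip_threshold=config.vip_threshold,
                max_drop_frac=config.max_drop_frac,
                eval_factors=config.eval_factors,
                max_factors_cv=config.max_factors_cv,
                rsq_tolerance=config.rsq_tolerance, criterion=config.criterion)
            logger.info("%s: %d genes screened -> %d retained -> %d selected",
                        trait, len(scr.table), len(retained), len(sel.genes))
            stage = f"lda:{trait}"
            labels = phen[f"{trait}_group"].to_numpy()
            X = filtered.values[sel.genes].to_numpy(float)
            model = fit_lda(X, labels, columns=sel.genes)
            rep = classify(model, X, labels, animal_ids=list(phen["animal_id"]))
            trait_results[trait] = TraitResult(
                trait=trait, n_screened=len(scr.table), n_retained=len(retained),
                prescreen_table=scr.table, selection=sel,
                lda_resub_accuracy=rep.resubstitution_accuracy,
                lda_loo_accuracy=rep.loo_accuracy, ld1_scores=rep.scores)

        stage = "network1"
        corr_genes = correlation_matrix(filtered)
        t1 = (covering_threshold(filtered, corr=corr_genes)
              if config.t1 == "auto" else float(config.t1))
        net1 = build_network(filtered, t1, corr=corr_genes)
        clust1 = mcl_cluster(net1, inflation=config.inflation1,
                             pre_inflation=config.pre_inflation1)
        stage = "carry_forward"
        selected_union = {g for r in trait_results.values() for g in r.selection.genes}
        carried = carry_forward(clust1, selected_union)
        stage = "network2"
        sub = AbundanceMatrix(values=filtered.values[sorted(carried)])
        net2 = build_network(sub, config.t2,
                             corr=corr_genes.loc[sorted(carried), sorted(carried)])
        clust2 = mcl_cluster(net2, inflation=config.inflation2,
                             pre_inflation=config.pre_inflation2)
        stage = "enrichment"
        selections = {t: r.selection.genes for t, r in trait_results.items()}
        sets = trait_gene_sets(selections)
        universe = set(net2.nodes)
        enrichment = enrich(clust2, sets, universe, alpha=config.enrichment_alpha)
        overlaps = overlap_sets(selections)

        return StudyReport(
            config=config, n_genes_input=abundance.shape[1],
            n_genes_filtered=filtered.shape[1], trait_results=trait_results,
            trait_correlation=corr, trait_correlation_p=corr_p,
            t1=t1, network1=net1, clustering1=clust1, carried_nodes=carried,
            network2=net2, clustering2=clust2, enrichment=enrichment,
            overlaps=overlaps,
            metadata={"version": __version__, "seed": config.seed,
                      "config_hash": config.config_hash(),
                      "removal_log_size": len(removal_log)})
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def render_tables(report: StudyReport, out_dir,
                  annotation: pd.DataFrame | None = None) -> dict[str, Path]:
    """Persist the report as TSV/JSON files (plus GraphML networks)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    var_rows = []
    for trait, res in report.trait_results.items():
        vt = res.selection.variance_table.copy()
        vt.insert(0, "trait", trait)
        var_rows.append(vt)
    paths["variance_table"] = out / "variance_table.tsv"
    pd.concat(var_rows).to_csv(paths["variance_table"], sep="\t", index=False)

    for trait in report.trait_results:
        sel = report.selection_table(trait, annotation=annotation)
        sel["abundance_scale"] = "fraction"
        p = out / f"selection_{trait}.tsv"
        sel.to_csv(p, sep="\t", index=False)
        paths[f"selection_{trait}"] = p
        p = out / f"ld1_scores_{trait}.tsv"
        report.trait_results[trait].ld1_scores.to_csv(p, sep="\t", index=False)
        paths[f"ld1_{trait}"] = p

    summary = {
        "n_genes_input": report.n_genes_input,
        "n_genes_filtered": report.n_genes_filtered,
        "t1": report.t1,
        "t2": report.config.t2,
        "n_carried": len(report.carried_nodes),
        "trait_correlation": report.trait_correlation.round(4).to_dict(),
        "overlaps": {k: (v if not isinstance(v, dict) else v)
                     for k, v in report.overlaps.items()},
        "accuracy": {t: {"resubstitution": r.lda_resub_accuracy,
                         "loo": r.lda_loo_accuracy}
                     for t, r in report.trait_results.items()},
        "explained_variance": {
            t: {"with_class": r.selection.explained_y_with_class,
                "without_class": r.selection.explained_y_without_class}
            for t, r in report.trait_results.items()},
        "selection_sizes": {t: len(r.selection.genes)
                            for t, r in report.trait_results.items()},
        "prescreen": {t: {"screened": r.n_screened, "retained": r.n_retained}
                      for t, r in report.trait_results.items()},
        "metadata": report.metadata,
    }
    paths["report"] = out / "report.json"
    with open(paths["report"], "w") as fh:
        json.dump(summary, fh, indent=1, default=str)

    paths["enrichment"] = out / "enrichment.tsv"
    report.enrichment.to_csv(paths["enrichment"], sep="\t", index=False)
    paths["network2"] = out / "network_t2.graphml"
    write_graphml(report.network2, report.clustering2, paths["network2"])
    paths["edges2"] = out / "edges_t2.tsv"
    report.network2.edge_table().to_csv(paths["edges2"], sep="\t", index=False)
    return paths
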
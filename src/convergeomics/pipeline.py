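"""Orchestrates the three omic layers into one convergence report.

The report is a pydantic model (JSON-serializable, schema shipped under
``convergeomics/schemas/report_schema.json``) holding, per layer, the
overlap and concordance statistics between the knockdown contrast and the
cell-state contrast, together with an echo of every threshold used and
digests of the input files.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .core_stats import ConcordanceResult, OverlapResult, overlap_test
from .expression import (
    ExpressionMatrix,
    de_feature_set,
    detectable_pool,
    differential_expression,
    kd_state_convergence,
    load_expression,
)
from .methylation import (
    GeneModel,
    call_clusters,
    cluster_overlap,
    cluster_state_correlation,
    common_positions,
    filter_sites,
    map_clusters_to_genes,
    mean_cluster_frequency,
    read_bed6,
    read_bismark_coverage,
    read_blacklist,
    read_gff3_genes,
    significant_clusters,
    test_clusters,
)
from .mirna import (
    ProbeCountTable,
    differential_mirna,
    mirna_feature_set,
    mirna_state_concordance,
    normalize_counts,
    presence_filter,
    read_probe_counts,
)
from .simulate import CONDITION_DIFF, CONDITION_KD, CONDITION_PROLIF

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


class ConvergeParams(BaseModel):
    """All tunable thresholds of the pipeline, echoed into the report."""

    kd_condition: str = CONDITION_KD
    prolif_condition: str = CONDITION_PROLIF
    diff_condition: str = CONDITION_DIFF

    fpkm_threshold: float = 1.0
    pool_rule: str = "mean-or"
    expr_q_threshold: float = 0.05

    mirna_p_threshold: float = 0.05
    mirna_q_threshold: float = 0.10
    min_detected_kd: int = 3
    min_detected_control: int = 3

    min_coverage_exclusive: int = 5
    top_coverage_fraction: float = 0.001
    max_gap: int = 50
    min_sites: int = 2
    meth_method: str = "bonferroni"
    meth_alpha: float = 0.05
    upstream: int = 5000
    downstream: int = 2000

    equal_var: bool = False


# ---------------------------------------------------------------------------
# Report models
# ---------------------------------------------------------------------------


class OverlapModel(BaseModel):
    pool_size: int
    set_a_size: int
    set_b_size: int
    intersection_size: int
    p_hyper: float
    intersection_ids: list[str]

    @classmethod
    def from_result(cls, r: OverlapResult) -> "OverlapModel":
        return cls(
            pool_size=r.pool_size,
            set_a_size=r.set_a_size,
            set_b_size=r.set_b_size,
            intersection_size=r.intersection_size,
            p_hyper=r.p_hyper,
            intersection_ids=list(r.intersection_ids),
        )


class ConcordanceModel(BaseModel):
    n_a: int
    n_shared: int
    frac_a_in_b: float
    frac_directionally_identical: Optional[float] = None
    pearson_r: Optional[float] = None
    pearson_p: Optional[float] = None

    @classmethod
    def from_result(cls, r: ConcordanceResult) -> "ConcordanceModel":
        return cls(
            n_a=r.n_a,
            n_shared=r.n_shared,
            frac_a_in_b=r.frac_a_in_b,
            frac_directionally_identical=r.frac_directionally_identical,
            pearson_r=r.pearson_r,
            pearson_p=r.pearson_p,
        )


class ExpressionLayerReport(BaseModel):
    pool_size: int
    n_significant_kd: int
    n_significant_kd_increased: int
    n_significant_kd_decreased: int
    n_significant_state: int
    overlap: OverlapModel
    overlap_increased: OverlapModel
    overlap_decreased: OverlapModel
    frac_increased_in_state_any: float
    frac_increased_in_state_same: float
    frac_decreased_in_state_any: float
    frac_decreased_in_state_same: float
    concordance: ConcordanceModel


class MirnaLayerReport(BaseModel):
    n_endogenous: int
    n_retained: int
    n_nominal_kd: int
    n_fdr_kd: int
    n_nominal_state: int
    overlap: OverlapModel
    concordance: ConcordanceModel


class MethylationLayerReport(BaseModel):
    n_clusters_kd: int
    n_clusters_state: int
    n_significant_kd: int
    n_significant_state: int
    overlap: OverlapModel
    n_clusters_significant_both: int
    pearson_vs_proliferating: Optional[float] = None
    pearson_vs_differentiating: Optional[float] = None
    n_gene_links_kd: int


class ProvenanceModel(BaseModel):
    package_version: str = __version__
    input_digests: dict[str, str] = Field(default_factory=dict)


class ConvergenceReport(BaseModel):
    """Machine-readable summary of the full convergence analysis."""

    parameters: ConvergeParams
    provenance: ProvenanceModel
    mrna: Optional[ExpressionLayerReport] = None
    mirna: Optional[MirnaLayerReport] = None
    methylation: Optional[MethylationLayerReport] = None


# ---------------------------------------------------------------------------
# Layer runners (in-memory)
# ---------------------------------------------------------------------------


def run_expression_layer(
    matrix: ExpressionMatrix, params: ConvergeParams
) -> ExpressionLayerReport:
    kd_contrast = (params.kd_condition, params.prolif_condition)
    state_contrast = (params.diff_condition, params.prolif_condition)
    pool_kd = detectable_pool(matrix, kd_contrast, params.fpkm_threshold, params.pool_rule)
    pool_state = detectable_pool(
        matrix, state_contrast, params.fpkm_threshold, params.pool_rule
    )
    pool = pool_kd & pool_state  # both lists must be drawable from the background
    de_kd = differential_expression(
        matrix, kd_contrast, params.expr_q_threshold, pool=pool,
        equal_var=params.equal_var,
    )
    de_state = differential_expression(
        matrix, state_contrast, params.expr_q_threshold, pool=pool,
        equal_var=params.equal_var,
    )
    conv = kd_state_convergence(de_kd, de_state, pool)
    kd_set = de_feature_set(de_kd)
    return ExpressionLayerReport(
        pool_size=len(pool),
        n_significant_kd=len(kd_set),
        n_significant_kd_increased=len(kd_set.with_direction(1)),
        n_significant_kd_decreased=len(kd_set.with_direction(-1)),
        n_significant_state=int(de_state["significant"].sum()),
        overlap=OverlapModel.from_result(conv.overlap),
        overlap_increased=OverlapModel.from_result(conv.overlap_increased),
        overlap_decreased=OverlapModel.from_result(conv.overlap_decreased),
        frac_increased_in_state_any=conv.frac_increased_in_state_any,
        frac_increased_in_state_same=conv.frac_increased_in_state_same,
        frac_decreased_in_state_any=conv.frac_decreased_in_state_any,
        frac_decreased_in_state_same=conv.frac_decreased_in_state_same,
        concordance=ConcordanceModel.from_result(conv.concordance),
    )


def run_mirna_layer(table: ProbeCountTable, params: ConvergeParams) -> MirnaLayerReport:
    norm = normalize_counts(table)
    kd_lanes = norm.lanes_for(params.kd_condition)
    control_lanes = norm.lanes_for(params.prolif_condition)
    retained = presence_filter(
        norm,
        group_a=control_lanes,
        group_b=kd_lanes,
        min_a=min(params.min_detected_control, len(control_lanes)),
        min_b=min(params.min_detected_kd, len(kd_lanes)),
    )
    probes = sorted(retained)
    kd_contrast = (params.kd_condition, params.prolif_condition)
    state_contrast = (params.diff_condition, params.prolif_condition)
    de_kd = differential_mirna(
        norm, kd_contrast, probes=probes,
        p_threshold=params.mirna_p_threshold, q_threshold=params.mirna_q_threshold,
        equal_var=params.equal_var,
    )
    de_state = differential_mirna(
        norm, state_contrast, probes=probes,
        p_threshold=params.mirna_p_threshold, q_threshold=params.mirna_q_threshold,
        equal_var=params.equal_var,
    )
    kd_set = mirna_feature_set(de_kd, "nominal")
    state_set = mirna_feature_set(de_state, "nominal")
    overlap = overlap_test(kd_set, state_set, retained)
    concordance = mirna_state_concordance(kd_set, norm, state_contrast)
    return MirnaLayerReport(
        n_endogenous=len(norm.probes_of_class("endogenous")),
        n_retained=len(retained),
        n_nominal_kd=len(kd_set),
        n_fdr_kd=int(de_kd["fdr_significant"].sum()),
        n_nominal_state=len(state_set),
        overlap=OverlapModel.from_result(overlap),
        concordance=ConcordanceModel.from_result(concordance),
    )


def run_methylation_layer(
    samples: Mapping[str, pd.DataFrame],
    conditions: pd.Series,
    params: ConvergeParams,
    genes: Sequence[GeneModel] = (),
    blacklist: set[tuple[str, int]] | None = None,
) -> MethylationLayerReport:
    filtered = filter_sites(
        samples,
        min_coverage_exclusive=params.min_coverage_exclusive,
        top_coverage_fraction=params.top_coverage_fraction,
        blacklist=blacklist,
    )
    kd_names = list(conditions.index[conditions == params.kd_condition])
    prolif_names = list(conditions.index[conditions == params.prolif_condition])
    diff_names = list(conditions.index[conditions == params.diff_condition])

    def analyse(group_a, group_b):
        universe = common_positions(filtered, list(group_a) + list(group_b))
        clusters = call_clusters(universe, params.max_gap, params.min_sites)
        results = test_clusters(
            filtered, clusters, group_a, group_b, positions_by_chrom=universe,
            equal_var=params.equal_var,
        )
        flagged = significant_clusters(results, params.meth_method, params.meth_alpha)
        return flagged

    kd_results = analyse(kd_names, prolif_names)
    state_results = analyse(diff_names, prolif_names)
    sig_kd = kd_results[kd_results["genome_wide_significant"]]
    sig_state = state_results[state_results["genome_wide_significant"]]
    overlap = cluster_overlap(sig_kd, sig_state, len(kd_results))

    # clusters significant in both analyses: KD methylation vs the two states
    both_ids = list(overlap.intersection_ids)
    sig_both = sig_kd[sig_kd["cluster_id"].isin(both_ids)]
    kd_freqs, prolif_freqs, diff_freqs = [], [], []
    for row in sig_both.itertuples():
        span = (row.chrom, int(row.start), int(row.end))
        kd_freqs.append(mean_cluster_frequency(filtered, span, kd_names))
        prolif_freqs.append(mean_cluster_frequency(filtered, span, prolif_names))
        diff_freqs.append(mean_cluster_frequency(filtered, span, diff_names))
    r_prolif, r_diff = cluster_state_correlation(kd_freqs, prolif_freqs, diff_freqs)

    links = map_clusters_to_genes(sig_kd, list(genes), params.upstream, params.downstream)
    return MethylationLayerReport(
        n_clusters_kd=len(kd_results),
        n_clusters_state=len(state_results),
        n_significant_kd=len(sig_kd),
        n_significant_state=len(sig_state),
        overlap=OverlapModel.from_result(overlap),
        n_clusters_significant_both=len(sig_both),
        pearson_vs_proliferating=r_prolif,
        pearson_vs_differentiating=r_diff,
        n_gene_links_kd=len(links),
    )


# ---------------------------------------------------------------------------
# Bundle-level entry point
# ---------------------------------------------------------------------------


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_convergence(
    bundle_dir: str | Path,
    params: ConvergeParams | None = None,
    skip_mrna: bool = False,
    skip_mirna: bool = False,
    skip_methylation: bool = False,
) -> ConvergenceReport:
    """Run the full convergence analysis on a bundle directory.

    Expects the layout written by :func:`convergeomics.simulate.write_bundle`
    (the same layout documents the real-data inputs): expression.tsv,
    samples.csv, mirna_counts.csv, meth/<sample>.cov, genes.bed, optionally
    blacklist.tsv and genes.gff3 in place of genes.bed.
    """
    params = params or ConvergeParams()
    bundle = Path(bundle_dir)
    digests: dict[str, str] = {}

    mrna_report = None
    if not skip_mrna:
        expr_path = bundle / "expression.tsv"
        sheet_path = bundle / "samples.csv"
        matrix = load_expression(expr_path, sheet_path)
        digests["expression.tsv"] = _digest(expr_path)
        digests["samples.csv"] = _digest(sheet_path)
        mrna_report = run_expression_layer(matrix, params)

    mirna_report = None
    if not skip_mirna:
        mirna_path = bundle / "mirna_counts.csv"
        table = read_probe_counts(mirna_path, bundle / "samples.csv")
        digests["mirna_counts.csv"] = _digest(mirna_path)
        mirna_report = run_mirna_layer(table, params)

    meth_report = None
    if not skip_methylation:
        from .expression import read_sample_sheet

        conditions = read_sample_sheet(bundle / "samples.csv")
        meth_dir = bundle / "meth"
        samples = {}
        for cov in sorted(meth_dir.glob("*.cov")):
            name = cov.stem
            if name not in conditions.index:
                logger.warning("coverage file %s has no sample-sheet entry; skipped", cov)
                continue
            samples[name] = read_bismark_coverage(cov)
            digests[f"meth/{cov.name}"] = _digest(cov)
        if not samples:
            raise ValueError(f"no usable coverage files under {meth_dir}")
        genes: list[GeneModel] = []
        if (bundle / "genes.bed").exists():
            genes = read_bed6(bundle / "genes.bed")
        elif (bundle / "genes.gff3").exists():
            genes = read_gff3_genes(bundle / "genes.gff3")
        blacklist = None
        if (bundle / "blacklist.tsv").exists():
            blacklist = read_blacklist(bundle / "blacklist.tsv")
        conditions = conditions.loc[list(samples)]
        meth_report = run_methylation_layer(samples, conditions, params, genes, blacklist)

    return ConvergenceReport(
        parameters=params,
        provenance=ProvenanceModel(input_digests=digests),
        mrna=mrna_report,
        mirna=mirna_report,
        methylation=meth_report,
    )


def report_summary(report: ConvergenceReport) -> str:
    """Short human-readable digest of a convergence report."""
    lines = ["convergence report"]
    if report.mrna:
        m = report.mrna
        lines.append(
            f"  mRNA: pool={m.pool_size}, KD significant={m.n_significant_kd} "
            f"(up {m.n_significant_kd_increased} / down {m.n_significant_kd_decreased}), "
            f"state significant={m.n_significant_state}"
        )
        lines.append(
            f"    overlap k={m.overlap.intersection_size}, hypergeometric "
            f"p={m.overlap.p_hyper:.3g}; decreased-in-state "
            f"{100 * m.frac_decreased_in_state_any:.1f}% (same direction "
            f"{100 * m.frac_decreased_in_state_same:.1f}%); increased-in-state "
            f"{100 * m.frac_increased_in_state_any:.1f}%"
        )
        if m.concordance.pearson_r is not None:
            lines.append(f"    log2FC Pearson r={m.concordance.pearson_r:.3f}")
    if report.mirna:
        m = report.mirna
        lines.append(
            f"  miRNA: retained {m.n_retained}/{m.n_endogenous}, KD nominal="
            f"{m.n_nominal_kd} (FDR {m.n_fdr_kd}), overlap p={m.overlap.p_hyper:.3g}"
        )
        if m.concordance.pearson_r is not None:
            lines.append(
                f"    state concordance: identical direction "
                f"{100 * (m.concordance.frac_directionally_identical or 0):.1f}%, "
                f"Pearson r={m.concordance.pearson_r:.3f}"
            )
    if report.methylation:
        m = report.methylation
        lines.append(
            f"  methylation: KD clusters tested={m.n_clusters_kd}, significant="
            f"{m.n_significant_kd}; state significant={m.n_significant_state}; "
            f"overlap k={m.overlap.intersection_size}, p={m.overlap.p_hyper:.3g}"
        )
        if m.pearson_vs_differentiating is not None:
            lines.append(
                f"    per-cluster r vs proliferating={m.pearson_vs_proliferating:.3f}, "
                f"vs differentiating={m.pearson_vs_differentiating:.3f} "
                f"(n={m.n_clusters_significant_both})"
            )
    return "\n".join(lines)
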
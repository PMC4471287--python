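"""Expression layer: FPKM matrices -> DE lists -> convergence statistics.

The analysis compares a knockdown (KD) contrast (KD lines vs non-target
proliferating controls) with a cell-state contrast (non-target
differentiating vs proliferating controls). Genes detectable above an FPKM
threshold form the background pool; differential expression is a Welch test
on log2(FPKM+1) with BH correction; the convergence statistics ask how many
KD-responsive genes recur in the cell-state signature, in which direction,
and how well the fold changes correlate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_stats import (
    ConcordanceResult,
    DirectionalFeatureSet,
    FeatureRecord,
    OverlapResult,
    bh_fdr,
    directional_concordance,
    overlap_test,
    welch_t_arrays,
)

logger = logging.getLogger(__name__)

POOL_RULES = ("mean-or", "all-samples", "any-sample")


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM values plus a condition label per sample."""

    values: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene IDs in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample IDs in expression matrix")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        missing = set(self.values.columns) - set(self.conditions.index)
        if missing:
            raise ValueError(f"samples without a condition label: {sorted(missing)}")
        self.conditions = self.conditions.loc[list(self.values.columns)]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_for(self, condition: str) -> list[str]:
        sel = self.conditions[self.conditions == condition]
        return list(sel.index)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_sample_sheet(path: str | Path) -> pd.Series:
    """Sample sheet CSV with columns sample, condition[, replicate]."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("sample", "condition"):
        if col not in df.columns:
            raise ValueError(f"{path}: sample sheet missing required column {col!r}")
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicated sample IDs in sample sheet")
    return df.set_index("sample")["condition"].astype(str)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Expression TSV: first column gene ID, header row of sample IDs."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.astype(float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(
            f"{path}: not a gene-by-sample TSV (first column gene ID, "
            f"numeric FPKM columns): {exc}"
        ) from exc
    return df


def load_expression(
    expression_tsv: str | Path, sample_sheet_csv: str | Path
) -> ExpressionMatrix:
    values = read_expression_tsv(expression_tsv)
    conditions = read_sample_sheet(sample_sheet_csv)
    return ExpressionMatrix(values=values, conditions=conditions)


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Externally produced DE list: TSV with gene, log2fc, p, q columns."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "log2fc", "p", "q"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: DE table needs columns {sorted(required)}")
    df = df.set_index("gene")
    df["direction"] = np.sign(df["log2fc"]).astype(int)
    return df


# ---------------------------------------------------------------------------
# Detection pool and differential expression
# ---------------------------------------------------------------------------


def detectable_pool(
    matrix: ExpressionMatrix,
    conditions: tuple[str, str],
    fpkm_threshold: float = 1.0,
    rule: str = "mean-or",
) -> set[str]:
    """Genes detectable (FPKM strictly above threshold) in a two-condition
    comparison.

    ``rule`` picks the detection reading: "mean-or" keeps a gene whose mean
    FPKM exceeds the threshold in at least one of the two conditions (the
    default, most permissive reading); "all-samples" requires every sample of
    both conditions to exceed it; "any-sample" requires any single sample.
    """
    if rule not in POOL_RULES:
        raise ValueError(f"unknown detection rule {rule!r}; choose from {POOL_RULES}")
    cols = []
    for cond in conditions:
        samples = matrix.samples_for(cond)
        if not samples:
            raise ValueError(f"condition {cond!r} absent from the sample sheet")
        cols.append(samples)
    v = matrix.values
    if rule == "mean-or":
        keep = (v[cols[0]].mean(axis=1) > fpkm_threshold) | (
            v[cols[1]].mean(axis=1) > fpkm_threshold
        )
    elif rule == "all-samples":
        keep = (v[cols[0] + cols[1]] > fpkm_threshold).all(axis=1)
    else:  # any-sample
        keep = (v[cols[0] + cols[1]] > fpkm_threshold).any(axis=1)
    return set(v.index[keep])


def differential_expression(
    matrix: ExpressionMatrix,
    contrast: tuple[str, str],
    q_threshold: float = 0.05,
    fpkm_threshold: float = 1.0,
    pool: set[str] | None = None,
    pool_rule: str = "mean-or",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-gene Welch test on log2(FPKM+1) between contrast and reference.

    ``contrast`` is (test condition, reference condition); log2fc is the mean
    log2(FPKM+1) difference, test over reference. Genes outside the
    detectable pool are excluded before testing. Returns a DataFrame indexed
    by gene with columns log2fc, t, p, q, significant, direction.
    """
    test_cond, ref_cond = contrast
    test_samples = matrix.samples_for(test_cond)
    ref_samples = matrix.samples_for(ref_cond)
    if len(test_samples) < 2 or len(ref_samples) < 2:
        raise ValueError("each contrast group needs at least 2 samples")
    if pool is None:
        pool = detectable_pool(matrix, contrast, fpkm_threshold, rule=pool_rule)
    genes = [g for g in matrix.genes if g in pool]
    log_v = np.log2(matrix.values.loc[genes] + 1.0)
    a = log_v[test_samples].to_numpy()
    b = log_v[ref_samples].to_numpy()
    t, df, p = welch_t_arrays(a, b, axis=1, equal_var=equal_var)
    q = bh_fdr(p) if len(genes) else np.array([])
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "df": df,
            "p": p,
            "q": q,
            "significant": q <= q_threshold,
            "direction": np.sign(log2fc).astype(int),
        },
        index=pd.Index(genes, name="gene"),
    )
    return out


def de_feature_set(table: pd.DataFrame, significant_only: bool = True) -> DirectionalFeatureSet:
    """Convert a DE result table into a DirectionalFeatureSet."""
    sub = table[table["significant"]] if significant_only and "significant" in table else table
    feats = {}
    for gene, row in sub.iterrows():
        fc = float(row["log2fc"])
        feats[str(gene)] = FeatureRecord(
            direction=1 if fc >= 0 else -1,
            log2fc=fc,
            p=float(row.get("p", 0.0)),
            q=float(row.get("q", 0.0)),
        )
    return DirectionalFeatureSet(feats)


# ---------------------------------------------------------------------------
# Convergence statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionConvergence:
    """KD-vs-cell-state convergence summary for the mRNA layer.

    ``frac_*_in_state_any`` is the fraction of significant KD genes of that
    direction that are significant in the state contrast in any direction;
    ``frac_*_in_state_same`` additionally requires the same direction.
    """

    overlap: OverlapResult
    overlap_increased: OverlapResult
    overlap_decreased: OverlapResult
    frac_increased_in_state_any: float
    frac_increased_in_state_same: float
    frac_decreased_in_state_any: float
    frac_decreased_in_state_same: float
    concordance: ConcordanceResult


def _direction_fractions(
    kd_dir: DirectionalFeatureSet, state: DirectionalFeatureSet
) -> tuple[float, float]:
    n = len(kd_dir)
    if n == 0:
        return 0.0, 0.0
    shared = kd_dir.ids & state.ids
    same = sum(1 for g in shared if kd_dir[g].direction == state[g].direction)
    return len(shared) / n, same / n


def kd_state_convergence(
    de_kd: pd.DataFrame, de_state: pd.DataFrame, pool: set[str]
) -> ExpressionConvergence:
    """Overlap, directional fractions and fold-change correlation between the
    KD and cell-state DE tables over a shared background pool."""
    kd_set = de_feature_set(de_kd)
    state_set = de_feature_set(de_state)
    kd_up = kd_set.with_direction(1)
    kd_down = kd_set.with_direction(-1)
    up_any, up_same = _direction_fractions(kd_up, state_set)
    down_any, down_same = _direction_fractions(kd_down, state_set)
    return ExpressionConvergence(
        overlap=overlap_test(kd_set, state_set, pool),
        overlap_increased=overlap_test(kd_up, state_set, pool),
        overlap_decreased=overlap_test(kd_down, state_set, pool),
        frac_increased_in_state_any=up_any,
        frac_increased_in_state_same=up_same,
        frac_decreased_in_state_any=down_any,
        frac_decreased_in_state_same=down_same,
        concordance=directional_concordance(kd_set, state_set),
    )


def cross_model_gene_overlap(
    de_a: pd.DataFrame, de_b: pd.DataFrame, pool: set[str]
) -> tuple[OverlapResult, dict[str, bool]]:
    """Overlap of two KD models' significant genes, with per-gene directional
    identity flags for the shared genes."""
    a_set = de_feature_set(de_a)
    b_set = de_feature_set(de_b)
    result = overlap_test(a_set, b_set, pool)
    identity = {
        g: a_set[g].direction == b_set[g].direction for g in result.intersection_ids
    }
    return result, identity


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="gene")
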
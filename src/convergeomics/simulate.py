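"""Synthetic multi-omics generator with planted, fully recorded structure.

Emulates the three data types of the study design — gene-level FPKM
matrices, nCounter-style miRNA probe counts and per-sample bisulfite CpG
calls — for three groups of samples: knockdown lines ("kd"), non-target
proliferating controls ("nt_prolif", the reference) and non-target
differentiating controls ("nt_diff"). Two contrasts are planted: the KD
contrast (kd vs nt_prolif) and the cell-state contrast (nt_diff vs
nt_prolif). A fraction ``rho_shared`` of the planted features is perturbed
concordantly in both contrasts, which is the ground-truth convergence signal
every downstream overlap statistic is validated against.

Everything is driven by one integer seed through numpy Generator streams
(one substream per layer), so identical configs give identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_stats import DirectionalFeatureSet, FeatureRecord
from .expression import ExpressionMatrix
from .methylation import GeneModel, write_bismark_coverage
from .mirna import ProbeCountTable

CONDITION_KD = "kd"
CONDITION_PROLIF = "nt_prolif"
CONDITION_DIFF = "nt_diff"
CONDITIONS = (CONDITION_KD, CONDITION_PROLIF, CONDITION_DIFF)

_LAYER_TAGS = {"expression": 11, "mirna": 22, "methylome": 33}

# positive spike-in expected counts (fixed concentration ladder) and
# negative-control Poisson background
_POSITIVE_LADDER = {"POS_A": 8000, "POS_B": 2000, "POS_C": 500,
                    "POS_D": 125, "POS_E": 32, "POS_F": 8}
_N_NEGATIVE = 8
_NEGATIVE_MEAN = 2.0


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic multi-omics experiment.

    Defaults mirror the study conditions: 4 samples per group (two shRNA
    constructs x two replicates for the KD group, four non-target controls),
    a 2-unit log2 fold change for planted expression effects with the
    cell-state contrast twice as pronounced, mean RRBS coverage 30x, CpG
    clusters of 5 sites with intra-cluster gaps well under the 50-bp joining
    rule, and a planted methylation difference of 0.3.
    """

    seed: int = 0
    n_genes: int = 2000
    n_mirna: int = 300
    n_cpg_sites: int = 2500
    samples_per_group: int = 4
    rho_shared: float = 0.5
    frac_de: float = 0.1
    effect_log2fc: float = 2.0
    state_effect_multiplier: float = 2.0
    effect_sd: float = 0.0
    effect_corr: float | None = None
    fpkm_dispersion: float = 0.5
    base_log2_fpkm_mean: float = 4.0
    base_log2_fpkm_sd: float = 2.0
    mirna_lane_scales: tuple[float, ...] | None = None
    mirna_dispersion: float = 0.05
    mirna_base_log2_mean: float = 6.0
    mirna_base_log2_sd: float = 1.5
    coverage_mean: float = 30.0
    meth_delta: float = 0.3
    sites_per_cluster: int = 5
    cluster_gap_mean: float = 20.0
    intercluster_gap_min: int = 2000
    n_chroms: int = 2
    frac_genes_near_clusters: float = 0.3

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_mirna", "n_cpg_sites", "samples_per_group",
                     "sites_per_cluster", "n_chroms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.samples_per_group < 2:
            raise ValueError("samples_per_group must be >= 2 for group testing")
        for name in ("rho_shared", "frac_de"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 2.0 <= self.cluster_gap_mean < 50.0:
            raise ValueError("cluster_gap_mean must lie in [2, 50)")
        if self.intercluster_gap_min <= 50:
            raise ValueError("intercluster_gap_min must exceed the 50-bp rule")
        if self.sites_per_cluster < 2:
            raise ValueError("sites_per_cluster must be >= 2")
        if self.mirna_lane_scales is not None:
            scales = tuple(float(s) for s in self.mirna_lane_scales)
            if len(scales) != 3 * self.samples_per_group:
                raise ValueError(
                    "mirna_lane_scales must have one entry per lane "
                    f"({3 * self.samples_per_group})"
                )
            if any(s <= 0 for s in scales):
                raise ValueError("lane scales must be positive")
            object.__setattr__(self, "mirna_lane_scales", scales)
        if not 0.0 < self.meth_delta < 1.0:
            raise ValueError("meth_delta must lie in (0, 1)")

    @property
    def sample_names(self) -> list[str]:
        k = self.samples_per_group
        return (
            [f"kd_{i + 1}" for i in range(k)]
            + [f"ntp_{i + 1}" for i in range(k)]
            + [f"ntd_{i + 1}" for i in range(k)]
        )

    @property
    def sample_conditions(self) -> pd.Series:
        k = self.samples_per_group
        return pd.Series(
            [CONDITION_KD] * k + [CONDITION_PROLIF] * k + [CONDITION_DIFF] * k,
            index=self.sample_names,
        )


@dataclass(frozen=True)
class PlantedCluster:
    """Ground truth for one simulated CpG cluster."""

    chrom: str
    start: int
    end: int
    n_sites: int
    baseline: float
    delta_kd: float
    delta_state: float

    @property
    def span(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    @property
    def in_kd(self) -> bool:
        return self.delta_kd != 0.0

    @property
    def in_state(self) -> bool:
        return self.delta_state != 0.0


@dataclass
class LayerTruth:
    """Planted feature effects for one feature-based layer."""

    de_kd: DirectionalFeatureSet
    de_state: DirectionalFeatureSet

    @property
    def shared_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.de_kd.ids & self.de_state.ids))


@dataclass
class MethylomeTruth:
    clusters: list[PlantedCluster]

    @property
    def dm_clusters_kd(self) -> list[PlantedCluster]:
        return [c for c in self.clusters if c.in_kd]

    @property
    def dm_clusters_state(self) -> list[PlantedCluster]:
        return [c for c in self.clusters if c.in_state]

    @property
    def shared_spans(self) -> list[tuple[str, int, int]]:
        return [c.span for c in self.clusters if c.in_kd and c.in_state]


@dataclass
class SimTruth:
    """All planted structure of one simulated bundle."""

    expression: LayerTruth
    mirna: LayerTruth
    methylome: MethylomeTruth


def _rng(config: SimConfig, layer: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _LAYER_TAGS[layer]])


def _balanced_signs(rng: np.random.Generator, n: int) -> np.ndarray:
    """Half +1, half -1 (odd leftover assigned at random), shuffled."""
    signs = np.ones(n, dtype=int)
    signs[: n // 2] = -1
    if n % 2:
        signs[n // 2] = rng.choice([-1, 1])
    rng.shuffle(signs)
    return signs


def _plant_effects(
    rng: np.random.Generator, ids: Sequence[str], config: SimConfig
) -> tuple[dict[str, float], dict[str, float]]:
    """Choose planted KD and cell-state effects over a feature universe.

    Both contrasts perturb round(frac_de * n) features; a quota of
    round(rho_shared * n_de) is shared and concordant in sign, and the
    remaining state features are drawn from all features outside that quota
    — so with rho_shared=0 the two contrasts are planted independently and
    chance overlap follows the hypergeometric null exactly. The cell-state
    effect is ``state_effect_multiplier`` times the KD effect. With
    ``effect_corr`` set, quota-shared features draw their (KD, state) log2
    fold changes from a bivariate normal around the signed means with that
    correlation.
    """
    n = len(ids)
    n_de = round(config.frac_de * n)
    if n_de == 0:
        return {}, {}
    n_shared = round(config.rho_shared * n_de)
    order = rng.permutation(n)
    kd_idx = order[:n_de]
    shared_idx = kd_idx[:n_shared]
    rest_pool = np.setdiff1d(np.arange(n), shared_idx)
    state_only_idx = rng.choice(rest_pool, size=n_de - n_shared, replace=False)
    signs_kd = _balanced_signs(rng, n_de)
    signs_state_only = _balanced_signs(rng, len(state_only_idx))

    mult = config.state_effect_multiplier
    kd_fc: dict[str, float] = {}
    state_fc: dict[str, float] = {}
    shared_set = set(shared_idx.tolist())
    sd = config.effect_sd
    for j, idx in enumerate(kd_idx):
        mean_kd = signs_kd[j] * config.effect_log2fc
        mean_state = mean_kd * mult
        if idx in shared_set and config.effect_corr is not None:
            cov = [
                [sd**2, config.effect_corr * sd * (mult * sd)],
                [config.effect_corr * sd * (mult * sd), (mult * sd) ** 2],
            ]
            fc_kd, fc_state = rng.multivariate_normal([mean_kd, mean_state], cov)
        else:
            fc_kd = mean_kd + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            fc_state = mean_state + (rng.normal(0.0, mult * sd) if sd > 0 else 0.0)
        kd_fc[ids[idx]] = float(fc_kd)
        if idx in shared_set:
            state_fc[ids[idx]] = float(fc_state)
    for j, idx in enumerate(state_only_idx):
        mean_state = signs_state_only[j] * config.effect_log2fc * mult
        fc = mean_state + (rng.normal(0.0, mult * sd) if sd > 0 else 0.0)
        state_fc[ids[idx]] = float(fc)
    # zero planted effects carry no signal and are not truth
    kd_fc = {k: v for k, v in kd_fc.items() if v != 0.0}
    state_fc = {k: v for k, v in state_fc.items() if v != 0.0}
    return kd_fc, state_fc


def _fc_to_set(fc: dict[str, float]) -> DirectionalFeatureSet:
    return DirectionalFeatureSet(
        {
            fid: FeatureRecord(direction=1 if v > 0 else -1, log2fc=v, p=0.0, q=0.0)
            for fid, v in fc.items()
        }
    )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def simulate_expression(config: SimConfig) -> tuple[ExpressionMatrix, LayerTruth]:
    """Log-normal FPKM per gene and sample with planted group shifts."""
    rng = _rng(config, "expression")
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    base = rng.normal(config.base_log2_fpkm_mean, config.base_log2_fpkm_sd, config.n_genes)
    kd_fc, state_fc = _plant_effects(rng, genes, config)

    conditions = config.sample_conditions
    eff = np.zeros((config.n_genes, len(conditions)))
    gene_index = {g: i for i, g in enumerate(genes)}
    kd_cols = np.flatnonzero((conditions == CONDITION_KD).to_numpy())
    diff_cols = np.flatnonzero((conditions == CONDITION_DIFF).to_numpy())
    for g, v in kd_fc.items():
        eff[gene_index[g], kd_cols] = v
    for g, v in state_fc.items():
        eff[gene_index[g], diff_cols] = v

    noise = rng.normal(0.0, config.fpkm_dispersion, eff.shape)
    fpkm = np.exp2(base[:, None] + eff + noise)
    values = pd.DataFrame(fpkm, index=pd.Index(genes, name="gene"),
                          columns=config.sample_names)
    matrix = ExpressionMatrix(values=values, conditions=conditions)
    return matrix, LayerTruth(de_kd=_fc_to_set(kd_fc), de_state=_fc_to_set(state_fc))


# ---------------------------------------------------------------------------
# miRNA
# ---------------------------------------------------------------------------


def simulate_mirna(config: SimConfig) -> tuple[ProbeCountTable, LayerTruth]:
    """Negative-binomial endogenous counts with per-lane scale factors,
    positive spike-ins on a fixed concentration ladder, and low-Poisson
    negative controls."""
    rng = _rng(config, "mirna")
    probes = [f"mir_{i + 1:04d}" for i in range(config.n_mirna)]
    base_mean = np.exp2(
        rng.normal(config.mirna_base_log2_mean, config.mirna_base_log2_sd, config.n_mirna)
    )
    kd_fc, state_fc = _plant_effects(rng, probes, config)

    conditions = config.sample_conditions
    lanes = config.sample_names
    scales = np.asarray(
        config.mirna_lane_scales
        if config.mirna_lane_scales is not None
        else np.ones(len(lanes))
    )

    eff = np.zeros((config.n_mirna, len(lanes)))
    probe_index = {p: i for i, p in enumerate(probes)}
    kd_cols = np.flatnonzero((conditions == CONDITION_KD).to_numpy())
    diff_cols = np.flatnonzero((conditions == CONDITION_DIFF).to_numpy())
    for pid, v in kd_fc.items():
        eff[probe_index[pid], kd_cols] = v
    for pid, v in state_fc.items():
        eff[probe_index[pid], diff_cols] = v

    mean = base_mean[:, None] * np.exp2(eff) * scales[None, :]
    if config.mirna_dispersion > 0:
        shape = 1.0 / config.mirna_dispersion
        lam = mean * rng.gamma(shape, 1.0 / shape, size=mean.shape)
    else:
        lam = mean
    endo_counts = rng.poisson(lam)

    pos_ids = list(_POSITIVE_LADDER)
    pos_counts = rng.poisson(
        np.asarray(list(_POSITIVE_LADDER.values()), dtype=float)[:, None] * scales[None, :]
    )
    neg_ids = [f"NEG_{chr(ord('A') + i)}" for i in range(_N_NEGATIVE)]
    neg_counts = rng.poisson(_NEGATIVE_MEAN * scales[None, :], size=(_N_NEGATIVE, len(lanes)))

    counts = pd.DataFrame(
        np.vstack([endo_counts, pos_counts, neg_counts]),
        index=pd.Index(probes + pos_ids + neg_ids, name="probe_id"),
        columns=lanes,
        dtype=int,
    )
    probe_class = pd.Series(
        ["endogenous"] * len(probes) + ["positive"] * len(pos_ids) + ["negative"] * len(neg_ids),
        index=counts.index,
    )
    table = ProbeCountTable(counts=counts, probe_class=probe_class, conditions=conditions)
    return table, LayerTruth(de_kd=_fc_to_set(kd_fc), de_state=_fc_to_set(state_fc))


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------


def simulate_methylome(
    config: SimConfig,
) -> tuple[dict[str, pd.DataFrame], MethylomeTruth, list[GeneModel]]:
    """CpG sites laid out in well-separated clusters, with binomial
    methylation counts around per-cluster baselines and planted group deltas.

    Clusters have ``sites_per_cluster`` sites with intra-cluster gaps drawn
    around ``cluster_gap_mean`` (capped under the 50-bp joining rule) and are
    separated by gaps exceeding ``intercluster_gap_min``, so the cluster
    caller recovers the planted partition exactly. Gene models are tiled near
    a subset of clusters on alternating strands for mapping tests.
    """
    rng = _rng(config, "methylome")
    n_clusters = max(1, round(config.n_cpg_sites / config.sites_per_cluster))
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]

    # plant differential methylation over clusters with the shared-rho logic
    cluster_ids = [f"cl_{i}" for i in range(n_clusters)]
    n_dm = round(config.frac_de * n_clusters)
    kd_delta = np.zeros(n_clusters)
    state_delta = np.zeros(n_clusters)
    if n_dm:
        n_shared = round(config.rho_shared * n_dm)
        order = rng.permutation(n_clusters)
        kd_idx = order[:n_dm]
        shared_quota = kd_idx[:n_shared]
        shared_idx = set(shared_quota.tolist())
        rest_pool = np.setdiff1d(np.arange(n_clusters), shared_quota)
        state_only_idx = rng.choice(rest_pool, size=n_dm - n_shared, replace=False)
        signs = _balanced_signs(rng, n_dm)
        for j, idx in enumerate(kd_idx):
            kd_delta[idx] = signs[j] * config.meth_delta
            if idx in shared_idx:
                state_delta[idx] = signs[j] * config.meth_delta
        signs_state = _balanced_signs(rng, len(state_only_idx))
        for j, idx in enumerate(state_only_idx):
            state_delta[idx] = signs_state[j] * config.meth_delta

    # lay out positions cluster by cluster, round-robin over chromosomes
    cursors = {c: 1000 for c in chroms}
    cluster_positions: list[np.ndarray] = []
    cluster_chrom: list[str] = []
    for i in range(n_clusters):
        chrom = chroms[i % len(chroms)]
        gaps = 2 + np.minimum(
            rng.poisson(config.cluster_gap_mean - 2, config.sites_per_cluster - 1), 47
        )
        start = cursors[chrom]
        pos = start + np.concatenate(([0], np.cumsum(gaps)))
        extra = int(rng.integers(1, max(100, config.intercluster_gap_min // 2)))
        cursors[chrom] = int(pos[-1]) + config.intercluster_gap_min + extra
        cluster_positions.append(pos.astype(np.int64))
        cluster_chrom.append(chrom)

    baselines = rng.uniform(0.35, 0.65, n_clusters)
    site_jitter = [rng.normal(0.0, 0.02, len(p)) for p in cluster_positions]

    conditions = config.sample_conditions
    samples: dict[str, pd.DataFrame] = {}
    shape = 10.0  # gamma-Poisson coverage, CV ~ 1/sqrt(shape)
    for sample, cond in conditions.items():
        chrom_col, pos_col, cov_col, meth_col = [], [], [], []
        for i in range(n_clusters):
            pos = cluster_positions[i]
            p_meth = baselines[i] + site_jitter[i]
            if cond == CONDITION_KD:
                p_meth = p_meth + kd_delta[i]
            elif cond == CONDITION_DIFF:
                p_meth = p_meth + state_delta[i]
            p_meth = np.clip(p_meth, 0.005, 0.995)
            cov = np.maximum(
                rng.poisson(rng.gamma(shape, config.coverage_mean / shape, len(pos))), 1
            )
            n_meth = rng.binomial(cov, p_meth)
            chrom_col.append(np.full(len(pos), cluster_chrom[i], dtype=object))
            pos_col.append(pos)
            cov_col.append(cov)
            meth_col.append(n_meth)
        df = pd.DataFrame(
            {
                "chrom": np.concatenate(chrom_col),
                "pos": np.concatenate(pos_col),
                "coverage": np.concatenate(cov_col),
                "n_meth": np.concatenate(meth_col),
            }
        )
        df["freq"] = df["n_meth"] / df["coverage"]
        samples[sample] = (
            df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        )

    planted = [
        PlantedCluster(
            chrom=cluster_chrom[i],
            start=int(cluster_positions[i][0]),
            end=int(cluster_positions[i][-1]) + 1,
            n_sites=len(cluster_positions[i]),
            baseline=float(baselines[i]),
            delta_kd=float(kd_delta[i]),
            delta_state=float(state_delta[i]),
        )
        for i in range(n_clusters)
    ]

    # gene models near a subset of clusters, alternating strands
    genes: list[GeneModel] = []
    near = rng.random(n_clusters) < config.frac_genes_near_clusters
    g = 0
    for i in range(n_clusters):
        if not near[i]:
            continue
        strand = "+" if g % 2 == 0 else "-"
        offset = int(rng.integers(-3000, 4000))
        start = max(0, int(cluster_positions[i][0]) + offset)
        length = int(rng.integers(2000, 8000))
        genes.append(
            GeneModel(cluster_chrom[i], start, start + length, strand, f"GENE{g + 1:04d}")
        )
        g += 1
    return samples, MethylomeTruth(clusters=planted), genes


# ---------------------------------------------------------------------------
# Bundle on disk
# ---------------------------------------------------------------------------


def _feature_set_json(fs: DirectionalFeatureSet) -> dict:
    return {
        fid: {"direction": rec.direction, "log2fc": rec.log2fc}
        for fid, rec in sorted(fs.features.items())
    }


def truth_to_json(truth: SimTruth) -> dict:
    return {
        "expression": {
            "de_kd": _feature_set_json(truth.expression.de_kd),
            "de_state": _feature_set_json(truth.expression.de_state),
            "shared_ids": list(truth.expression.shared_ids),
        },
        "mirna": {
            "de_kd": _feature_set_json(truth.mirna.de_kd),
            "de_state": _feature_set_json(truth.mirna.de_state),
            "shared_ids": list(truth.mirna.shared_ids),
        },
        "methylome": {
            "clusters": [dataclasses.asdict(c) for c in truth.methylome.clusters],
            "shared_spans": [list(s) for s in truth.methylome.shared_spans],
        },
    }


def simulate_bundle(config: SimConfig) -> tuple[ExpressionMatrix, ProbeCountTable,
                                                dict[str, pd.DataFrame],
                                                list[GeneModel], SimTruth]:
    """All three layers from one config."""
    matrix, expr_truth = simulate_expression(config)
    table, mirna_truth = simulate_mirna(config)
    meth_samples, meth_truth, genes = simulate_methylome(config)
    return matrix, table, meth_samples, genes, SimTruth(
        expression=expr_truth, mirna=mirna_truth, methylome=meth_truth
    )


def write_bundle(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full fixture bundle in the pipeline's input formats.

    Produces expression.tsv, samples.csv, mirna_counts.csv, one Bismark
    coverage file per sample under meth/, genes.bed, truth.json and
    config.json; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, table, meth_samples, genes, truth = simulate_bundle(config)

    paths: dict[str, Path] = {}
    paths["expression"] = outdir / "expression.tsv"
    matrix.values.to_csv(paths["expression"], sep="\t", index_label="gene",
                         float_format="%.6g")

    paths["samples"] = outdir / "samples.csv"
    sheet = pd.DataFrame(
        {
            "sample": matrix.samples,
            "condition": matrix.conditions.to_list(),
            "replicate": [int(s.split("_")[1]) for s in matrix.samples],
        }
    )
    sheet.to_csv(paths["samples"], index=False)

    paths["mirna"] = outdir / "mirna_counts.csv"
    out = table.counts.copy()
    out.insert(0, "class", table.probe_class)
    out.to_csv(paths["mirna"], index_label="probe_id")

    meth_dir = outdir / "meth"
    meth_dir.mkdir(exist_ok=True)
    for sample, df in meth_samples.items():
        write_bismark_coverage(df, meth_dir / f"{sample}.cov")
    paths["meth_dir"] = meth_dir

    paths["genes"] = outdir / "genes.bed"
    bed = pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "name": [g.gene_id for g in genes],
            "score": 0,
            "strand": [g.strand for g in genes],
        }
    )
    bed.to_csv(paths["genes"], sep="\t", header=False, index=False)

    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(truth_to_json(truth), indent=1, sort_keys=True))

    paths["config"] = outdir / "config.json"
    paths["config"].write_text(
        json.dumps(dataclasses.asdict(config), indent=1, sort_keys=True)
    )
    return paths
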
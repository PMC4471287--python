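"""Methylation layer: RRBS site filtering, CpG-cluster calling and testing.

Inputs are per-sample CpG calls in Bismark-coverage format (1-based
inclusive on disk; converted to 0-based positions in memory). The analysis:

1. keep sites with coverage strictly above a floor (default >5x), then drop
   the top fraction (default 0.1%, ceiling rule) of highest-coverage sites
   per sample, plus an optional position blacklist (stands in for masking of
   positions confounded by genetic variation);
2. restrict to positions surviving the filters in every sample of the
   comparison, and call CpG clusters: maximal runs of sites whose
   consecutive gaps are at most 50 bp, keeping runs of 2+ sites;
3. per cluster, a Welch t-test on the pooled per-site per-sample methylation
   frequencies of the two groups, with Bonferroni (default) or BH control
   over the tested clusters;
4. cross-experiment cluster overlap (>=1 bp shared) scored by the exact
   hypergeometric tail over the tested-cluster universe, strand-aware gene
   mapping (5 kb upstream / 2 kb downstream windows), and per-cluster
   correlation of KD methylation against reference cell states.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core_stats import (
    OverlapResult,
    _welch_core,
    bh_fdr,
    hypergeometric_tail,
    pearson,
    welch_t,
)

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["chrom", "pos", "coverage", "n_meth", "freq"]


@dataclass(frozen=True)
class CpGCluster:
    """A maximal run of nearby CpG sites; 0-based half-open span."""

    chrom: str
    start: int
    end: int
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.positions) < 2:
            raise ValueError("a CpG cluster needs at least 2 sites")
        if self.start > self.positions[0] or self.end <= self.positions[-1]:
            raise ValueError("cluster span must cover all sites")

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class GeneModel:
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must precede end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class ClusterTestResult:
    cluster: CpGCluster
    t: float
    df: float
    p: float
    mean_freq_a: float
    mean_freq_b: float
    n_obs_a: int
    n_obs_b: int

    @property
    def delta(self) -> float:
        return self.mean_freq_a - self.mean_freq_b


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_bismark_coverage(path: str | Path) -> pd.DataFrame:
    """Read a Bismark coverage file (chrom, start, end, %meth, n_meth,
    n_unmeth; 1-based inclusive) into 0-based site calls."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "pct", "n_meth", "n_unmeth"],
            dtype={
                "chrom": str,
                "start": np.int64,
                "end": np.int64,
                "pct": float,
                "n_meth": np.int64,
                "n_unmeth": np.int64,
            },
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(
            f"{path}: not a Bismark coverage file (6 tab-separated columns: "
            f"chrom, start, end, %methylation, count-methylated, "
            f"count-unmethylated): {exc}"
        ) from exc
    if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
        raise ValueError(f"{path}: negative read counts")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"] - 1,  # Bismark 1-based -> 0-based
            "coverage": df["n_meth"] + df["n_unmeth"],
            "n_meth": df["n_meth"],
        }
    )
    if (out["coverage"] <= 0).any():
        raise ValueError(f"{path}: sites with zero coverage")
    out["freq"] = out["n_meth"] / out["coverage"]
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def write_bismark_coverage(sites: pd.DataFrame, path: str | Path) -> None:
    """Write site calls back out in the Bismark coverage dialect."""
    df = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "start": sites["pos"] + 1,
            "end": sites["pos"] + 1,
            "pct": 100.0 * sites["n_meth"] / sites["coverage"],
            "n_meth": sites["n_meth"],
            "n_unmeth": sites["coverage"] - sites["n_meth"],
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_bed6(path: str | Path) -> list[GeneModel]:
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "name": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"{path}: not a BED6 file (6 tab-separated columns): {exc}") from exc
    return [
        GeneModel(r.chrom, int(r.start), int(r.end), str(r.strand), str(r.name))
        for r in df.itertuples()
    ]


def read_gff3_genes(path: str | Path, feature_type: str = "gene") -> list[GeneModel]:
    """Gene models from a GFF3 file (gffutils line iterator; no database)."""
    import gffutils.iterators

    genes = []
    for feat in gffutils.iterators.DataIterator(str(path)):
        if feat.featuretype != feature_type:
            continue
        gid = feat.attributes.get("ID", [feat.id or f"{feat.seqid}:{feat.start}"])[0]
        genes.append(
            GeneModel(feat.seqid, int(feat.start) - 1, int(feat.end), feat.strand, gid)
        )
    return genes


def read_blacklist(path: str | Path) -> set[tuple[str, int]]:
    """2-column (chrom, 0-based position) file of positions to drop."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos"],
                     dtype={"chrom": str, "pos": np.int64})
    return set(zip(df["chrom"], df["pos"].astype(int)))


# ---------------------------------------------------------------------------
# Site filtering
# ---------------------------------------------------------------------------


def filter_sites(
    samples: Mapping[str, pd.DataFrame],
    min_coverage_exclusive: int = 5,
    top_coverage_fraction: float = 0.001,
    blacklist: set[tuple[str, int]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per sample: drop sites with coverage <= floor, then the ceil(fraction x
    n_kept) highest-coverage sites (ties broken by position, descending),
    then any blacklisted positions."""
    out = {}
    for name, df in samples.items():
        kept = df[df["coverage"] > min_coverage_exclusive]
        n_kept = len(kept)
        n_drop = math.ceil(top_coverage_fraction * n_kept) if top_coverage_fraction > 0 else 0
        if n_drop > 0 and n_kept > 0:
            order = np.lexsort((kept["pos"].to_numpy(), kept["coverage"].to_numpy()))
            kept = kept.iloc[order[: n_kept - n_drop]]
            kept = kept.sort_values(["chrom", "pos"], kind="stable")
        if blacklist:
            mask = [
                (c, int(p)) not in blacklist
                for c, p in zip(kept["chrom"], kept["pos"])
            ]
            kept = kept[mask]
        out[name] = kept.reset_index(drop=True)
    return out


def common_positions(
    samples: Mapping[str, pd.DataFrame], sample_names: Sequence[str] | None = None
) -> dict[str, np.ndarray]:
    """Positions present (post-filter) in every listed sample, per chromosome."""
    names = list(sample_names) if sample_names is not None else list(samples)
    if not names:
        raise ValueError("no samples given")
    common: dict[str, set[int]] | None = None
    for name in names:
        df = samples[name]
        per_chrom = {
            str(c): set(g["pos"].astype(int)) for c, g in df.groupby("chrom", sort=True)
        }
        if common is None:
            common = per_chrom
        else:
            for c in list(common):
                common[c] &= per_chrom.get(c, set())
                if not common[c]:
                    del common[c]
    assert common is not None
    return {c: np.array(sorted(p), dtype=np.int64) for c, p in sorted(common.items())}


# ---------------------------------------------------------------------------
# Cluster calling
# ---------------------------------------------------------------------------


def call_clusters(
    positions_by_chrom: Mapping[str, Sequence[int]],
    max_gap: int = 50,
    min_sites: int = 2,
) -> list[CpGCluster]:
    """Maximal runs of CpG positions with consecutive gaps <= max_gap.

    Runs with fewer than ``min_sites`` sites are discarded. Input positions
    must be sorted and unique per chromosome; the output is sorted and
    non-overlapping.
    """
    clusters: list[CpGCluster] = []
    for chrom in sorted(positions_by_chrom):
        pos = np.asarray(positions_by_chrom[chrom], dtype=np.int64)
        if pos.size == 0:
            continue
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions on {chrom} must be sorted and unique")
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for run in np.split(pos, breaks):
            if run.size >= min_sites:
                clusters.append(
                    CpGCluster(
                        chrom=chrom,
                        start=int(run[0]),
                        end=int(run[-1]) + 1,
                        positions=tuple(int(p) for p in run),
                    )
                )
    return clusters


# ---------------------------------------------------------------------------
# Per-cluster testing
# ---------------------------------------------------------------------------


def _freq_lookup(df: pd.DataFrame) -> dict[str, pd.Series]:
    return {
        str(c): g.set_index("pos")["freq"] for c, g in df.groupby("chrom", sort=True)
    }


def test_cluster(
    cluster: CpGCluster,
    samples: Mapping[str, pd.DataFrame],
    group_a: Sequence[str],
    group_b: Sequence[str],
    equal_var: bool = False,
) -> ClusterTestResult | None:
    """Welch t-test on the pooled per-site per-sample frequencies of a cluster.

    Observations are the methylation frequencies at each CpG site of the
    cluster in each sample, pooled within group. Returns None (with a logged
    reason) when either group provides fewer than 2 observations from fewer
    than 2 samples.
    """
    obs = {}
    samples_with_calls = {}
    for names, key in ((group_a, "a"), (group_b, "b")):
        vals: list[float] = []
        n_with = 0
        for name in names:
            lut = _freq_lookup(samples[name]).get(cluster.chrom)
            if lut is None:
                continue
            got = lut.reindex(list(cluster.positions)).dropna()
            if len(got):
                n_with += 1
                vals.extend(got.to_list())
        obs[key] = vals
        samples_with_calls[key] = n_with
    if (
        min(samples_with_calls.values()) < 2
        or len(obs["a"]) < 2
        or len(obs["b"]) < 2
    ):
        logger.info("cluster %s skipped: insufficient observations", cluster.id)
        return None
    res = welch_t(obs["a"], obs["b"], equal_var=equal_var)
    return ClusterTestResult(
        cluster=cluster,
        t=res.t,
        df=res.df,
        p=res.p,
        mean_freq_a=float(np.mean(obs["a"])),
        mean_freq_b=float(np.mean(obs["b"])),
        n_obs_a=len(obs["a"]),
        n_obs_b=len(obs["b"]),
    )


def frequency_matrix(
    samples: Mapping[str, pd.DataFrame],
    positions_by_chrom: Mapping[str, np.ndarray],
    sample_names: Sequence[str],
) -> dict[str, np.ndarray]:
    """Per-chromosome (n_sites x n_samples) frequency matrices over a common
    position universe."""
    mats = {}
    luts = {name: _freq_lookup(samples[name]) for name in sample_names}
    for chrom, pos in positions_by_chrom.items():
        cols = []
        for name in sample_names:
            lut = luts[name].get(chrom)
            if lut is None:
                raise ValueError(f"sample {name} has no calls on {chrom}")
            col = lut.reindex(pos).to_numpy(dtype=float)
            if np.isnan(col).any():
                raise ValueError(
                    f"sample {name} missing positions on {chrom}; "
                    "use a common-position universe"
                )
            cols.append(col)
        mats[chrom] = np.column_stack(cols)
    return mats


def test_clusters(
    samples: Mapping[str, pd.DataFrame],
    clusters: Sequence[CpGCluster],
    group_a: Sequence[str],
    group_b: Sequence[str],
    positions_by_chrom: Mapping[str, np.ndarray] | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Vectorised per-cluster Welch tests over a common position universe.

    Equivalent to mapping :func:`test_cluster` over ``clusters`` (cross-checked
    in the test suite) but runs the grouped sums with reduceat, which keeps
    genome-scale simulations fast.
    """
    if positions_by_chrom is None:
        positions_by_chrom = common_positions(samples, list(group_a) + list(group_b))
    mats_a = frequency_matrix(samples, positions_by_chrom, group_a)
    mats_b = frequency_matrix(samples, positions_by_chrom, group_b)
    rows = []
    by_chrom: dict[str, list[CpGCluster]] = {}
    for cl in clusters:
        by_chrom.setdefault(cl.chrom, []).append(cl)
    for chrom, cls in by_chrom.items():
        pos = positions_by_chrom[chrom]
        fa, fb = mats_a[chrom], mats_b[chrom]
        starts = np.searchsorted(pos, [c.positions[0] for c in cls], side="left")
        stops = np.searchsorted(pos, [c.positions[-1] for c in cls], side="right")
        n_sites = stops - starts
        na = n_sites * fa.shape[1]
        nb = n_sites * fb.shape[1]
        # grouped sums over each cluster's [start, stop) row block via cumsum
        row_a, row_b = fa.sum(axis=1), fb.sum(axis=1)
        row_a2, row_b2 = (fa**2).sum(axis=1), (fb**2).sum(axis=1)
        ca, cb, ca2, cb2 = (
            np.concatenate(([0.0], np.cumsum(v)))
            for v in (row_a, row_b, row_a2, row_b2)
        )
        sums_a = ca[stops] - ca[starts]
        sums_b = cb[stops] - cb[starts]
        sq_a = ca2[stops] - ca2[starts]
        sq_b = cb2[stops] - cb2[starts]
        mean_a = sums_a / na
        mean_b = sums_b / nb
        var_a = np.maximum(sq_a - na * mean_a**2, 0.0) / np.maximum(na - 1, 1)
        var_b = np.maximum(sq_b - nb * mean_b**2, 0.0) / np.maximum(nb - 1, 1)
        t, df, p, _ = _welch_core(mean_a, var_a, na, mean_b, var_b, nb, equal_var)
        for i, cl in enumerate(cls):
            rows.append(
                {
                    "cluster_id": cl.id,
                    "chrom": chrom,
                    "start": cl.start,
                    "end": cl.end,
                    "n_sites": int(n_sites[i]),
                    "t": float(t[i]),
                    "df": float(df[i]),
                    "p": float(p[i]),
                    "mean_freq_a": float(mean_a[i]),
                    "mean_freq_b": float(mean_b[i]),
                    "delta": float(mean_a[i] - mean_b[i]),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return out


def significant_clusters(
    results: pd.DataFrame, method: str = "bonferroni", alpha: float = 0.05
) -> pd.DataFrame:
    """Flag genome-wide significant clusters over the tested set.

    bonferroni (default): p <= alpha / m over the m tested clusters;
    bh: BH q <= alpha (q column added).
    """
    if method not in ("bonferroni", "bh"):
        raise ValueError("method must be 'bonferroni' or 'bh'")
    out = results.copy()
    m = len(out)
    if m == 0:
        out["genome_wide_significant"] = pd.Series(dtype=bool)
        return out
    if method == "bonferroni":
        out["genome_wide_significant"] = out["p"] <= alpha / m
    else:
        out["q"] = bh_fdr(out["p"].to_numpy())
        out["genome_wide_significant"] = out["q"] <= alpha
    return out


# ---------------------------------------------------------------------------
# Cross-experiment overlap, gene mapping, state correlation
# ---------------------------------------------------------------------------


def _intervals(obj) -> list[tuple[str, int, int, str]]:
    """Normalise clusters / result rows to (chrom, start, end, id) tuples."""
    if isinstance(obj, pd.DataFrame):
        ids = (
            obj["cluster_id"]
            if "cluster_id" in obj
            else obj["chrom"].str.cat(obj["start"].astype(str), ":")
        )
        return list(zip(obj["chrom"], obj["start"].astype(int), obj["end"].astype(int), ids))
    out = []
    for c in obj:
        if isinstance(c, CpGCluster):
            out.append((c.chrom, c.start, c.end, c.id))
        else:
            chrom, start, end = c[:3]
            out.append((str(chrom), int(start), int(end), f"{chrom}:{start}-{end}"))
    return out


def cluster_overlap(
    sig_a, sig_b, universe_size: int | Sequence | pd.DataFrame
) -> OverlapResult:
    """Hypergeometric test of cross-experiment cluster overlap.

    Two clusters overlap when their genomic intervals share >= 1 bp; k is the
    number of a-side significant clusters overlapping any b-side significant
    cluster, and the pool is the a-side tested-cluster universe.
    """
    a = _intervals(sig_a)
    b = _intervals(sig_b)
    n_universe = (
        int(universe_size) if isinstance(universe_size, int) else len(_intervals(universe_size))
    )
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, _ in b:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    hits = [aid for chrom, start, end, aid in a if trees.get(chrom) and trees[chrom].overlap(start, end)]
    k = len(hits)
    if k > min(len(a), len(b)):
        logger.warning(
            "cluster_overlap: %d a-side hits exceed min(K=%d, n=%d); clamping",
            k, len(a), len(b),
        )
        k = min(len(a), len(b))
        hits = hits[:k]
    p = hypergeometric_tail(n_universe, len(a), len(b), k)
    return OverlapResult(
        pool_size=n_universe,
        set_a_size=len(a),
        set_b_size=len(b),
        intersection_size=k,
        p_hyper=p,
        intersection_ids=tuple(hits),
    )


def map_clusters_to_genes(
    clusters, genes: Sequence[GeneModel], upstream: int = 5000, downstream: int = 2000
) -> list[tuple[str, str]]:
    """Strand-aware promoter/flank mapping of clusters to genes.

    A + strand gene's window is [start - upstream, end + downstream); a -
    strand gene's is [start - downstream, end + upstream). A cluster links to
    every gene whose window its interval intersects.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        if g.strand == "+":
            w_start, w_end = g.start - upstream, g.end + downstream
        else:
            w_start, w_end = g.start - downstream, g.end + upstream
        trees.setdefault(g.chrom, IntervalTree()).addi(max(0, w_start), w_end, g.gene_id)
    links = []
    for chrom, start, end, cid in _intervals(clusters):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(start, end)):
            links.append((cid, iv.data))
    return links


def mean_cluster_frequency(
    samples: Mapping[str, pd.DataFrame],
    cluster_span: tuple[str, int, int],
    sample_names: Sequence[str],
) -> float:
    """Mean methylation frequency over a genomic span, pooling the listed
    samples' sites inside it (NaN when no calls fall inside)."""
    chrom, start, end = cluster_span
    vals: list[float] = []
    for name in sample_names:
        df = samples[name]
        sel = df[(df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] < end)]
        vals.extend(sel["freq"].to_list())
    return float(np.mean(vals)) if vals else float("nan")


def cluster_state_correlation(
    kd_freqs: Sequence[float],
    ref_freqs_a: Sequence[float],
    ref_freqs_b: Sequence[float],
) -> tuple[float | None, float | None]:
    """Pearson correlations of per-cluster KD methylation against two
    reference states, over the same cluster set.

    Returns (r with reference A, r with reference B); a correlation is None
    (flagged undefined) with fewer than 3 clusters or a constant vector.
    """
    kd = np.asarray(kd_freqs, dtype=float)
    a = np.asarray(ref_freqs_a, dtype=float)
    b = np.asarray(ref_freqs_b, dtype=float)
    if not (kd.size == a.size == b.size):
        raise ValueError("the three frequency vectors must share a cluster set")
    r_a, _ = pearson(kd, a)
    r_b, _ = pearson(kd, b)
    return r_a, r_b


def write_clusters_bed(results: pd.DataFrame, path: str | Path) -> None:
    """Tested clusters as BED: name = cluster ID, score = -10 log10 p."""
    with np.errstate(divide="ignore"):
        score = np.minimum(-10.0 * np.log10(np.maximum(results["p"], 1e-300)), 3000)
    bed = pd.DataFrame(
        {
            "chrom": results["chrom"],
            "start": results["start"],
            "end": results["end"],
            "name": results["cluster_id"],
            "score": score.round(2),
            "strand": ".",
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)
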
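"""miRNA layer: digital-counting normalization, detection and concordance.

Models nCounter-style probe count tables carrying three probe classes:
endogenous miRNAs, positive spike-in controls at fixed concentrations, and
negative controls measuring background. Normalization is the platform's
two-step scheme — equalize the positive-control geometric means across
lanes, then equalize overall endogenous content — followed by a per-lane
detection threshold of mean + 2 sd of the negative controls.

Geometric means are taken over strictly positive counts (spike-ins are
nonzero by design; occasional endogenous zeros are excluded rather than
offset so that scaling a lane's counts by a constant rescales its factors
exactly and leaves normalized values invariant). The +1 offset guarding
zeros is applied where logs of endogenous counts are actually taken, i.e.
in the log2 transform before differential testing.
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
    bh_fdr,
    directional_concordance,
    geometric_mean,
    welch_t_arrays,
)

logger = logging.getLogger(__name__)

PROBE_CLASSES = ("endogenous", "positive", "negative")


@dataclass
class ProbeCountTable:
    """Raw probe counts (probes x lanes) with probe classes and lane labels."""

    counts: pd.DataFrame
    probe_class: pd.Series
    conditions: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate probe IDs")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate lane IDs")
        arr = self.counts.to_numpy()
        if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be non-negative integers")
        unknown = set(self.probe_class.unique()) - set(PROBE_CLASSES)
        if unknown:
            raise ValueError(f"unknown probe classes: {sorted(unknown)}")
        self.probe_class = self.probe_class.loc[list(self.counts.index)]
        for cls in ("positive", "negative"):
            if not (self.probe_class == cls).any():
                raise ValueError(f"need at least one {cls} control probe")
        missing = set(self.counts.columns) - set(self.conditions.index)
        if missing:
            raise ValueError(f"lanes without a condition label: {sorted(missing)}")
        self.conditions = self.conditions.loc[list(self.counts.columns)]

    @property
    def lanes(self) -> list[str]:
        return list(self.counts.columns)

    def probes_of_class(self, cls: str) -> list[str]:
        return list(self.probe_class.index[self.probe_class == cls])

    def lanes_for(self, condition: str) -> list[str]:
        sel = self.conditions[self.conditions == condition]
        return list(sel.index)


@dataclass
class NormalizedTable:
    """Normalized probe values plus the per-lane factors that produced them."""

    values: pd.DataFrame
    probe_class: pd.Series
    conditions: pd.Series
    factors: pd.DataFrame  # columns: positive_factor, content_factor, background_threshold

    def probes_of_class(self, cls: str) -> list[str]:
        return list(self.probe_class.index[self.probe_class == cls])

    def lanes_for(self, condition: str) -> list[str]:
        sel = self.conditions[self.conditions == condition]
        return list(sel.index)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_probe_counts(path: str | Path, sample_sheet_csv: str | Path) -> ProbeCountTable:
    """Probe-count CSV: columns probe_id, class, then one column per lane."""
    from .expression import read_sample_sheet

    path = Path(path)
    df = pd.read_csv(path)
    for col in ("probe_id", "class"):
        if col not in df.columns:
            raise ValueError(f"{path}: probe-count CSV missing column {col!r}")
    df = df.set_index("probe_id")
    probe_class = df.pop("class").astype(str)
    try:
        counts = df.astype(int)
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer count values: {exc}") from exc
    conditions = read_sample_sheet(sample_sheet_csv)
    lanes = [c for c in counts.columns if c in conditions.index]
    if not lanes:
        raise ValueError(f"{path}: no lane column matches the sample sheet")
    return ProbeCountTable(
        counts=counts[lanes], probe_class=probe_class, conditions=conditions
    )


def write_probe_counts(table: ProbeCountTable, path: str | Path) -> None:
    out = table.counts.copy()
    out.insert(0, "class", table.probe_class)
    out.to_csv(path, index_label="probe_id")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def _lane_geomeans(block: pd.DataFrame, what: str) -> pd.Series:
    """Per-lane geometric mean over the strictly positive counts of a block."""
    out = {}
    for lane in block.columns:
        vals = block[lane].to_numpy(dtype=float)
        vals = vals[vals > 0]
        if vals.size == 0:
            raise ValueError(f"lane {lane!r} has all-zero {what} counts; lane rejected")
        out[lane] = geometric_mean(vals)
    return pd.Series(out)


def normalize_counts(table: ProbeCountTable) -> NormalizedTable:
    """Two-step per-lane scaling: positive-control factor, then content factor.

    Step 1 scales each lane so its positive-control geometric mean equals the
    grand geometric mean across lanes; step 2 repeats the same construction
    on the endogenous probes after step 1. The per-lane detection threshold
    is mean + 2 sd of the lane's normalized negative controls.
    """
    pos = table.probes_of_class("positive")
    endo = table.probes_of_class("endogenous")
    neg = table.probes_of_class("negative")

    pos_geo = _lane_geomeans(table.counts.loc[pos], "positive-control")
    grand_pos = geometric_mean(pos_geo.to_numpy())
    positive_factor = grand_pos / pos_geo

    step1 = table.counts.astype(float) * positive_factor

    content_geo = _lane_geomeans(step1.loc[endo], "endogenous")
    grand_content = geometric_mean(content_geo.to_numpy())
    content_factor = grand_content / content_geo

    values = step1 * content_factor

    neg_vals = values.loc[neg]
    sd = neg_vals.std(axis=0, ddof=1).fillna(0.0) if len(neg) > 1 else pd.Series(
        0.0, index=values.columns
    )
    background = neg_vals.mean(axis=0) + 2.0 * sd

    factors = pd.DataFrame(
        {
            "positive_factor": positive_factor,
            "content_factor": content_factor,
            "background_threshold": background,
        }
    )
    return NormalizedTable(
        values=values,
        probe_class=table.probe_class,
        conditions=table.conditions,
        factors=factors,
    )


# ---------------------------------------------------------------------------
# Detection / presence filter
# ---------------------------------------------------------------------------


def presence_filter(
    norm: NormalizedTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_a: int,
    min_b: int,
) -> set[str]:
    """Endogenous probes detected in enough lanes of either group.

    A probe is "detected" in a lane when its normalized value strictly
    exceeds that lane's background threshold; it is kept when detected in at
    least ``min_a`` lanes of group A or at least ``min_b`` lanes of group B.
    """
    if min_a > len(group_a) or min_b > len(group_b):
        raise ValueError("minimum detected-lane counts exceed group sizes")
    endo = norm.probes_of_class("endogenous")
    thr = norm.factors["background_threshold"]
    detected = norm.values.loc[endo].gt(thr, axis=1)
    keep = (detected[list(group_a)].sum(axis=1) >= min_a) | (
        detected[list(group_b)].sum(axis=1) >= min_b
    )
    return set(keep.index[keep])


# ---------------------------------------------------------------------------
# Differential testing and concordance
# ---------------------------------------------------------------------------


def differential_mirna(
    norm: NormalizedTable,
    contrast: tuple[str, str],
    probes: Sequence[str] | None = None,
    p_threshold: float = 0.05,
    q_threshold: float = 0.10,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Welch t on log2(normalized+1) per probe.

    Probes should have been pre-filtered with :func:`presence_filter`; the
    nominal list is p strictly below ``p_threshold``, FDR flags at BH q
    strictly below ``q_threshold``.
    """
    test_cond, ref_cond = contrast
    a_lanes = norm.lanes_for(test_cond)
    b_lanes = norm.lanes_for(ref_cond)
    if len(a_lanes) < 2 or len(b_lanes) < 2:
        raise ValueError("each contrast group needs at least 2 lanes")
    ids = list(probes) if probes is not None else norm.probes_of_class("endogenous")
    log_v = np.log2(norm.values.loc[ids] + 1.0)
    a = log_v[a_lanes].to_numpy()
    b = log_v[b_lanes].to_numpy()
    t, df, p = welch_t_arrays(a, b, axis=1, equal_var=equal_var)
    q = bh_fdr(p) if ids else np.array([])
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "df": df,
            "p": p,
            "q": q,
            "nominal": p < p_threshold,
            "fdr_significant": q < q_threshold,
            "direction": np.sign(log2fc).astype(int),
        },
        index=pd.Index(ids, name="probe_id"),
    )


def mirna_feature_set(table: pd.DataFrame, which: str = "nominal") -> DirectionalFeatureSet:
    """Nominal (p) or FDR (q) significant probes as a DirectionalFeatureSet."""
    if which not in ("nominal", "fdr", "all"):
        raise ValueError("which must be 'nominal', 'fdr' or 'all'")
    if which == "all":
        sub = table
    else:
        sub = table[table["nominal" if which == "nominal" else "fdr_significant"]]
    feats = {}
    for pid, row in sub.iterrows():
        fc = float(row["log2fc"])
        feats[str(pid)] = FeatureRecord(
            direction=1 if fc >= 0 else -1,
            log2fc=fc,
            p=float(row["p"]),
            q=float(row["q"]),
        )
    return DirectionalFeatureSet(feats)


def mirna_state_concordance(
    de_kd: DirectionalFeatureSet,
    state_norm: NormalizedTable,
    contrast: tuple[str, str],
) -> ConcordanceResult:
    """For each KD-significant probe, look up its cell-state fold change (no
    significance requirement on the state side) and summarize directional
    identity and the Pearson correlation of the log2 fold changes."""
    measured = [p for p in de_kd.ids if p in state_norm.values.index]
    if len(measured) < len(de_kd):
        logger.warning(
            "mirna_state_concordance: %d KD probes not measured in the state table",
            len(de_kd) - len(measured),
        )
    state_table = differential_mirna(
        state_norm, contrast, probes=measured, p_threshold=1.1, q_threshold=1.1
    ) if measured else pd.DataFrame(columns=["log2fc", "p", "q"])
    state_set = mirna_feature_set(state_table, which="all")
    return directional_concordance(de_kd, state_set)


def write_normalized(norm: NormalizedTable, path: str | Path) -> None:
    out = norm.values.copy()
    out.insert(0, "class", norm.probe_class)
    out.to_csv(path, index_label="probe_id")
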
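"""Shared statistical primitives for the convergence analysis.

This module houses the statistics that every omic layer leans on: the exact
hypergeometric upper tail used for set-overlap enrichment, directional
fold-change concordance between two contrasts, Welch's t-test (scalar and
vectorised), Benjamini-Hochberg FDR, and the geometric mean used by the
count-normalisation code.

The hypergeometric tail is evaluated by explicit summation of the
probability mass function in log space (log-gamma binomials), which is exact
to floating precision and stable for pool sizes well beyond 10^5 — no normal
approximation is ever used, because the overlap p-values of interest are
often far in the tail.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureRecord",
    "DirectionalFeatureSet",
    "OverlapResult",
    "ConcordanceResult",
    "TTestResult",
    "hypergeometric_tail",
    "overlap_test",
    "directional_concordance",
    "welch_t",
    "welch_t_arrays",
    "bh_fdr",
    "geometric_mean",
    "pearson",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureRecord:
    """One feature (gene, miRNA probe, CpG cluster) in a directional set.

    ``direction`` is +1 or -1 and must agree with ``sign(log2fc)`` whenever
    the fold change is nonzero; ``p`` and ``q`` are the nominal and
    FDR-adjusted probabilities attached to the feature (0 for planted truth).
    """

    direction: int
    log2fc: float
    p: float = 0.0
    q: float = 0.0

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError(f"direction must be +1 or -1, got {self.direction}")
        if self.log2fc != 0 and self.direction != (1 if self.log2fc > 0 else -1):
            raise ValueError(
                f"direction {self.direction} disagrees with sign(log2fc={self.log2fc})"
            )
        for name in ("p", "q"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) and not math.isnan(v):
                raise ValueError(f"{name}={v} outside [0, 1]")


class DirectionalFeatureSet:
    """A set of feature IDs, each carrying a sign and a log2 fold change.

    The unit of every overlap / concordance analysis in the package. Feature
    IDs are unique by construction (dict-backed).
    """

    def __init__(self, features: Mapping[str, FeatureRecord] | None = None):
        self._features: dict[str, FeatureRecord] = dict(features or {})

    @classmethod
    def from_arrays(
        cls,
        ids: Sequence[str],
        log2fc: Sequence[float],
        p: Sequence[float] | None = None,
        q: Sequence[float] | None = None,
    ) -> "DirectionalFeatureSet":
        if len(set(ids)) != len(ids):
            raise ValueError("feature IDs must be unique")
        n = len(ids)
        p = p if p is not None else [0.0] * n
        q = q if q is not None else [0.0] * n
        feats = {}
        for i, fid in enumerate(ids):
            fc = float(log2fc[i])
            direction = 1 if fc >= 0 else -1
            feats[fid] = FeatureRecord(direction, fc, float(p[i]), float(q[i]))
        return cls(feats)

    @property
    def features(self) -> Mapping[str, FeatureRecord]:
        return self._features

    @property
    def ids(self) -> set[str]:
        return set(self._features)

    def __len__(self) -> int:
        return len(self._features)

    def __contains__(self, fid: str) -> bool:
        return fid in self._features

    def __getitem__(self, fid: str) -> FeatureRecord:
        return self._features[fid]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DirectionalFeatureSet):
            return NotImplemented
        return self._features == other._features

    def subset(self, ids: Iterable[str]) -> "DirectionalFeatureSet":
        keep = set(ids)
        return DirectionalFeatureSet(
            {k: v for k, v in self._features.items() if k in keep}
        )

    def with_direction(self, direction: int) -> "DirectionalFeatureSet":
        return DirectionalFeatureSet(
            {k: v for k, v in self._features.items() if v.direction == direction}
        )


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric overlap between two feature sets drawn from a pool."""

    pool_size: int
    set_a_size: int
    set_b_size: int
    intersection_size: int
    p_hyper: float
    intersection_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.intersection_size > min(self.set_a_size, self.set_b_size):
            raise ValueError("intersection larger than one of the sets")
        if max(self.set_a_size, self.set_b_size) > self.pool_size:
            raise ValueError("set larger than the pool")


@dataclass(frozen=True)
class ConcordanceResult:
    """Directional agreement between two contrasts over their shared features.

    ``pearson_r``/``pearson_p`` are None (flagged undefined) when fewer than
    3 shared features exist or a fold-change vector is constant;
    ``frac_directionally_identical`` is None when no features are shared.
    """

    shared_ids: tuple[str, ...]
    n_a: int
    frac_a_in_b: float
    frac_directionally_identical: float | None
    pearson_r: float | None
    pearson_p: float | None

    @property
    def n_shared(self) -> int:
        return len(self.shared_ids)

    @property
    def a_empty(self) -> bool:
        return self.n_a == 0


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Hypergeometric tail
# ---------------------------------------------------------------------------


def _log_binom(n: np.ndarray | float, k: np.ndarray | float) -> np.ndarray:
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the pool size, K the number of "successes" in the pool, n the draw
    size and k the observed successes. Computed by summing the pmf from k to
    min(K, n) in log space, so it is exact (to float precision) for pools up
    to at least 10^5.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    N, K, n, k = int(N), int(K), int(n), int(k)
    if n > N or K > N:
        raise ValueError(f"require n <= N and K <= N, got N={N}, K={K}, n={n}")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K, n)={min(K, n)}")
    lo = max(0, n - (N - K))  # smallest attainable number of successes
    if k <= lo:
        return 1.0
    i = np.arange(k, min(K, n) + 1)
    log_pmf = _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, n)
    tail = float(np.exp(special.logsumexp(log_pmf)))
    return min(1.0, max(0.0, tail))


def overlap_test(
    set_a: DirectionalFeatureSet,
    set_b: DirectionalFeatureSet,
    pool: set[str] | frozenset[str],
) -> OverlapResult:
    """Test whether two feature sets overlap more than chance within a pool.

    Features outside the pool are dropped (with a logged warning) before
    counting; the p-value is the exact hypergeometric upper tail of the
    observed intersection size.
    """
    if not pool:
        raise ValueError("pool must be non-empty")
    pool = set(pool)
    a_ids = set_a.ids & pool
    b_ids = set_b.ids & pool
    dropped = (len(set_a) - len(a_ids)) + (len(set_b) - len(b_ids))
    if dropped:
        logger.warning("overlap_test: dropped %d features outside the pool", dropped)
    inter = sorted(a_ids & b_ids)
    p = hypergeometric_tail(len(pool), len(a_ids), len(b_ids), len(inter))
    return OverlapResult(
        pool_size=len(pool),
        set_a_size=len(a_ids),
        set_b_size=len(b_ids),
        intersection_size=len(inter),
        p_hyper=p,
        intersection_ids=tuple(inter),
    )


# ---------------------------------------------------------------------------
# Directional concordance
# ---------------------------------------------------------------------------


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float | None, float | None]:
    """Pearson r with its two-sided p (t-transform, n-2 df).

    Returns (None, None) when fewer than 3 pairs or either vector is
    constant — flagged undefined rather than NaN-propagated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def directional_concordance(
    set_a: DirectionalFeatureSet, set_b: DirectionalFeatureSet
) -> ConcordanceResult:
    """How much of contrast A recurs in contrast B, and in the same direction.

    ``frac_a_in_b`` is |A∩B| / |A| (0, flagged, for empty A);
    ``frac_directionally_identical`` and the Pearson correlation of the log2
    fold changes are computed over the shared features only.
    """
    shared = sorted(set_a.ids & set_b.ids)
    n_a = len(set_a)
    frac_a_in_b = len(shared) / n_a if n_a else 0.0
    if shared:
        same = [set_a[f].direction == set_b[f].direction for f in shared]
        frac_same: float | None = float(np.mean(same))
    else:
        frac_same = None
    fc_a = [set_a[f].log2fc for f in shared]
    fc_b = [set_b[f].log2fc for f in shared]
    r, p = pearson(fc_a, fc_b) if len(shared) >= 3 else (None, None)
    return ConcordanceResult(
        shared_ids=tuple(shared),
        n_a=n_a,
        frac_a_in_b=frac_a_in_b,
        frac_directionally_identical=frac_same,
        pearson_r=r,
        pearson_p=p,
    )


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------


def welch_t(
    a: Sequence[float], b: Sequence[float], equal_var: bool = False
) -> TTestResult:
    """Two-sample t-test; Welch (unequal variance) by default.

    Degenerate inputs resolve deterministically: two constant, equal groups
    give t=0, p=1; two constant, unequal groups give p=0 (both flagged).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    t, df, p, degen = _welch_core(
        a.mean(), a.var(ddof=1), a.size, b.mean(), b.var(ddof=1), b.size, equal_var
    )
    return TTestResult(t=float(t), df=float(df), p=float(p), degenerate=bool(degen))


def _welch_core(ma, va, na, mb, vb, nb, equal_var):
    ma, va, mb, vb = (np.asarray(x, dtype=float) for x in (ma, va, mb, vb))
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = (na + nb - 2) * np.ones_like(se2)
    else:
        sa, sb = va / na, vb / nb
        se2 = sa + sb
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    degen = se2 == 0
    delta = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(se2)
    # constant-and-equal -> t=0, p=1; constant-and-unequal -> +/-inf, p=0
    with np.errstate(invalid="ignore"):
        t = np.where(degen, np.where(delta == 0, 0.0, np.sign(delta) * np.inf), t)
    df = np.where(degen, na + nb - 2, df)
    p = np.where(degen, np.where(delta == 0, 1.0, 0.0), 0.0)
    ok = ~degen
    if np.any(ok):
        p = np.where(ok, 2.0 * stats.t.sf(np.abs(np.where(ok, t, 0.0)), df), p)
    return t, df, p, degen


def welch_t_arrays(
    a: np.ndarray, b: np.ndarray, axis: int = -1, equal_var: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Welch t over the given axis; returns (t, df, p) arrays.

    Same statistic and degenerate-input rules as :func:`welch_t`; used by the
    per-gene / per-probe / per-cluster testing loops.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[axis], b.shape[axis]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    t, df, p, _ = _welch_core(
        a.mean(axis=axis),
        a.var(axis=axis, ddof=1),
        na,
        b.mean(axis=axis),
        b.var(axis=axis, ddof=1),
        nb,
        equal_var,
    )
    return t, df, p


# ---------------------------------------------------------------------------
# Multiple testing, geometric mean
# ---------------------------------------------------------------------------


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving by input index."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def geometric_mean(x: Sequence[float]) -> float:
    """exp(mean(log x)) over strictly positive values."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("geometric mean of an empty sequence")
    if np.any(x <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(x))))
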
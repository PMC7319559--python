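"""Core enrichment statistics shared by all workflows.

Implements over-representation analysis (ORA) with hypergeometric tail
p-values, an unweighted running-sum (Kolmogorov–Smirnov-like) set-enrichment
statistic with a gene-label permutation null, multiple-testing correction,
and the chi-square test on a 2x2 contingency table.

Notation used throughout: ``N`` is the universe size, ``K`` the category
size within the universe, ``n`` the test-set size, and ``k`` the overlap
between test set and category.  Under the null, ``k ~ Hypergeom(N, K, n)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DIRECTIONS = ("over", "under", "two_sided")


def _adjust_bonferroni(p: np.ndarray) -> np.ndarray:
    return p * p.size


def _adjust_holm(p: np.ndarray) -> np.ndarray:
    # step-down: q_(i) = max_{j<=i} (m - j + 1) p_(j) on the sorted scale
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = (m - np.arange(m)) * p[order]
    adj = np.maximum.accumulate(scaled)
    out = np.empty(m)
    out[order] = adj
    return out


def _adjust_bh(p: np.ndarray) -> np.ndarray:
    # step-up: q_(i) = min_{j>=i} (m / j) p_(j) on the sorted scale
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = adj
    return out


def _adjust_by(p: np.ndarray) -> np.ndarray:
    c_m = np.sum(1.0 / np.arange(1, p.size + 1))
    return _adjust_bh(p) * c_m


#: Multiple-testing correction registry, so further corrections can be
#: added without touching call sites.
ADJUST_METHODS: dict[str, object] = {
    "bonferroni": _adjust_bonferroni,
    "holm": _adjust_holm,
    "bh": _adjust_bh,
    "by": _adjust_by,
}


@dataclass
class EnrichmentRecord:
    """Result of one ORA test of a category against a test set."""

    category_id: str
    n_universe: int
    n_category: int
    n_test: int
    n_overlap: int
    statistic: float
    p_raw: float
    p_adjusted: float
    direction: str
    hits: list[str] = field(default_factory=list)
    name: str = ""


@dataclass
class RunningSumResult:
    """Running-sum enrichment score with its permutation p-value."""

    category_id: str
    es: float
    p_raw: float
    n_permutations: int
    leading_edge: list[str] = field(default_factory=list)


def hypergeom_tail(N: int, K: int, n: int, k: int, direction: str) -> float:
    """Hypergeometric tail probability for an overlap of ``k``.

    ``over``: P(X >= k); ``under``: P(X <= k); ``two_sided``: the doubled
    smaller tail, capped at 1.
    """
    if direction == "over":
        return float(stats.hypergeom.sf(k - 1, N, K, n))
    if direction == "under":
        return float(stats.hypergeom.cdf(k, N, K, n))
    if direction == "two_sided":
        over = stats.hypergeom.sf(k - 1, N, K, n)
        under = stats.hypergeom.cdf(k, N, K, n)
        return float(min(1.0, 2.0 * min(over, under)))
    raise ValueError(f"unknown direction {direction!r}; expected one of {DIRECTIONS}")


def ora(
    test_set: Iterable[str],
    category: Iterable[str],
    universe: Iterable[str],
    direction: str = "over",
    category_id: str = "",
    name: str = "",
) -> EnrichmentRecord:
    """Over-representation analysis of ``category`` within ``test_set``.

    The test set must be a subset of the universe; the category is
    intersected with the universe before testing.  ``hits`` lists the
    overlapping genes sorted lexicographically.  ``p_adjusted`` is
    initialized to ``p_raw``; callers correct across a family of
    categories with :func:`adjust_records`.
    """
    test = frozenset(test_set)
    uni = frozenset(universe)
    if not test:
        raise ValueError("test_set is empty")
    if not test <= uni:
        extra = sorted(test - uni)[:5]
        raise ValueError(f"test_set is not a subset of the universe (e.g. {extra})")
    cat = frozenset(category) & uni

    N, K, n = len(uni), len(cat), len(test)
    hits = sorted(test & cat)
    k = len(hits)
    p = hypergeom_tail(N, K, n, k, direction)
    expected = K * n / N
    return EnrichmentRecord(
        category_id=category_id,
        name=name,
        n_universe=N,
        n_category=K,
        n_test=n,
        n_overlap=k,
        statistic=k - expected,
        p_raw=p,
        p_adjusted=p,
        direction=direction,
        hits=hits,
    )


def _running_sum(ranked: Sequence[str], category: frozenset[str]) -> tuple[np.ndarray, np.ndarray]:
    is_hit = np.fromiter((g in category for g in ranked), dtype=bool, count=len(ranked))
    N = len(ranked)
    K = int(is_hit.sum())
    if K == 0 or K == N:
        raise ValueError("category must hit some but not all of the ranked list")
    steps = np.where(is_hit, 1.0 / K, -1.0 / (N - K))
    return np.cumsum(steps), is_hit


def running_sum_es(ranked_genes: Sequence[str], category: Iterable[str]) -> float:
    """Unweighted running-sum enrichment score of ``category`` on a ranking.

    Walking the list top to bottom, a category hit adds ``1/K`` and a miss
    subtracts ``1/(N-K)``; the score is the running sum's value at its
    maximum absolute deviation (ties resolved to the earliest position).
    ES is +1 when all hits sit at the top of the list and -1 at the bottom.
    """
    ranked = list(ranked_genes)
    if len(set(ranked)) != len(ranked):
        raise ValueError("ranked_genes contains duplicates")
    rs, _ = _running_sum(ranked, frozenset(category))
    return float(rs[int(np.argmax(np.abs(rs)))])


def running_sum_pvalue(
    ranked_genes: Sequence[str],
    category: Iterable[str],
    n_permutations: int = 1000,
    seed: int | None = None,
    category_id: str = "",
) -> RunningSumResult:
    """Permutation p-value for the running-sum enrichment score.

    The null permutes gene labels (i.e. shuffles hit positions along the
    list) ``n_permutations`` times; the p-value uses the add-one estimator
    ``(1 + #{|ES*| >= |ES|}) / (1 + n_permutations)`` so it is never zero.
    ``seed`` makes the permutation stream reproducible and is required for
    any pipeline run.

    The leading edge is the set of category hits at or before the position
    of the extremum.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    ranked = list(ranked_genes)
    if len(set(ranked)) != len(ranked):
        raise ValueError("ranked_genes contains duplicates")
    cat = frozenset(category)
    rs, is_hit = _running_sum(ranked, cat)
    peak = int(np.argmax(np.abs(rs)))
    es = float(rs[peak])
    leading_edge = [g for i, g in enumerate(ranked[: peak + 1]) if is_hit[i]]

    N = len(ranked)
    K = int(is_hit.sum())
    steps = np.where(is_hit, 1.0 / K, -1.0 / (N - K))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(steps)
        es_null = np.max(np.abs(np.cumsum(perm)))
        if es_null >= abs(es) - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return RunningSumResult(
        category_id=category_id,
        es=es,
        p_raw=p,
        n_permutations=n_permutations,
        leading_edge=leading_edge,
    )


def adjust(p_values: Sequence[float], method: str = "bh") -> list[float]:
    """Multiple-testing correction, preserving input order.

    Supported methods: ``bonferroni``, ``holm``, ``bh``
    (Benjamini–Hochberg step-up), ``by`` (Benjamini–Yekutieli).
    All raw p-values must lie in (0, 1]; adjusted values are clipped to 1.
    """
    if method not in ADJUST_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {sorted(ADJUST_METHODS)}")
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("all p-values must lie in (0, 1]")
    adj = ADJUST_METHODS[method](p)
    return np.minimum(adj, 1.0).tolist()


def adjust_records(records: list[EnrichmentRecord], method: str = "bh") -> list[EnrichmentRecord]:
    """Fill ``p_adjusted`` across one family of enrichment records in place."""
    if records:
        adjusted = adjust([r.p_raw for r in records], method=method)
        for rec, padj in zip(records, adjusted):
            rec.p_adjusted = padj
    return records


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """Pearson chi-square test on the 2x2 table [[a, b], [c, d]].

    Returns ``(statistic, p, odds_ratio)`` where the statistic is the
    closed form ``N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))`` with
    ``N = a+b+c+d`` and no continuity correction, and p comes from the
    chi-square distribution with 1 df.  The odds ratio is ``ad / bc``;
    when any cell is zero, 0.5 is added to every cell (Haldane–Anscombe)
    before forming the ratio.

    Raises ``ValueError`` for negative counts or a zero row/column margin
    (degenerate table).
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("counts must be non-negative")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("degenerate table: a row or column margin is zero")
    N = a + b + c + d
    chi2 = N * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1))
    if 0 in cells:
        aa, bb, cc, dd = (x + 0.5 for x in cells)
    else:
        aa, bb, cc, dd = cells
    odds_ratio = (aa * dd) / (bb * cc)
    return float(chi2), p, float(odds_ratio)


# ---------------------------------------------------------------------------
# Serialization

RESULT_COLUMNS = [
    "category_id",
    "name",
    "N",
    "K",
    "n",
    "k",
    "statistic",
    "p_raw",
    "p_adjusted",
    "direction",
    "hits",
]


def records_to_frame(records: Iterable[EnrichmentRecord]) -> pd.DataFrame:
    rows = [
        {
            "category_id": r.category_id,
            "name": r.name,
            "N": r.n_universe,
            "K": r.n_category,
            "n": r.n_test,
            "k": r.n_overlap,
            "statistic": r.statistic,
            "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted,
            "direction": r.direction,
            "hits": ";".join(r.hits),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_records_tsv(records: Iterable[EnrichmentRecord], path) -> None:
    """TSV with fixed column order and 6-significant-digit p-values."""
    df = records_to_frame(records)
    for col in ("statistic", "p_raw", "p_adjusted"):
        df[col] = df[col].map(lambda v: f"{v:.6g}")
    df.to_csv(path, sep="\t", index=False)


def write_records_json(records: Iterable[EnrichmentRecord], path) -> None:
    df = records_to_frame(records)
    with open(path, "w") as fh:
        json.dump(df.to_dict(orient="records"), fh, indent=1)
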
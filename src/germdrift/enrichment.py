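"""Hypergeometric over/under-enrichment of gene lists against gene sets and
chromosomes, fold enrichment, list-overlap tests, and rank-based comparison of
score distributions between chromosome groups."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError
from .preprocess import bh_adjust

logger = logging.getLogger(__name__)

CHROMOSOMES = ("I", "II", "III", "IV", "V", "X", "other")


@dataclass(frozen=True)
class EnrichmentResult:
    """One hypergeometric contingency: k of n query genes hit a K-of-N set."""

    set_name: str
    N: int  # universe size
    K: int  # set members in the universe
    n: int  # query size
    k: int  # overlap
    fold: float
    p_over: float  # P(X >= k)
    p_under: float  # P(X <= k)


def _check_contingency(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"need 0 <= K={K}, n={n} <= N={N}")
    if not (max(0, n + K - N) <= k <= min(K, n)):
        raise ValidationError(
            f"impossible overlap k={k} for K={K}, n={n}, N={N} "
            f"(valid range [{max(0, n + K - N)}, {min(K, n)}])"
        )


def hypergeom_tail(k: int, K: int, n: int, N: int, direction: str = "over") -> float:
    """Exact tail probability of hypergeometric(N, K, n), via log-space CDFs.

    ``over`` gives P(X >= k), ``under`` gives P(X <= k).
    """
    _check_contingency(k, K, n, N)
    dist = stats.hypergeom(N, K, n)
    if direction == "over":
        return float(np.exp(dist.logsf(k - 1)))
    if direction == "under":
        return float(np.exp(dist.logcdf(k)))
    raise ValidationError(f"direction must be 'over' or 'under', got {direction!r}")


def fold_enrichment(k: int, K: int, n: int, N: int) -> float:
    """Observed/expected overlap ratio: k*N / (K*n)."""
    if K <= 0 or n <= 0 or N <= 0:
        raise ValidationError("fold enrichment requires K > 0, n > 0 and N > 0")
    _check_contingency(k, K, n, N)
    return k * N / (K * n)


def _result(set_name: str, k: int, K: int, n: int, N: int) -> EnrichmentResult:
    fold = float("nan") if K == 0 or n == 0 else fold_enrichment(k, K, n, N)
    return EnrichmentResult(
        set_name=set_name,
        N=N,
        K=K,
        n=n,
        k=k,
        fold=fold,
        p_over=hypergeom_tail(k, K, n, N, "over"),
        p_under=hypergeom_tail(k, K, n, N, "under"),
    )


def enrich_sets(
    query: list[str],
    sets: dict[str, list[str]],
    universe: list[str],
    adjust: bool = False,
) -> list[EnrichmentResult]:
    """Test a query list against every gene set, both tails.

    Query ids outside the universe are dropped (count logged); each set is
    intersected with the universe before testing. With ``adjust`` the over-tail
    p-values get a BH-adjusted companion column downstream.
    """
    if not universe:
        raise ValidationError("enrichment universe is empty")
    uni = set(universe)
    q = [g for g in dict.fromkeys(query) if g in uni]
    dropped = len(set(query)) - len(q)
    if dropped:
        logger.info("dropped %d query ids outside the universe", dropped)
    N, n = len(uni), len(q)
    results = []
    for name, members in sets.items():
        in_universe = uni.intersection(members)
        k = len(in_universe.intersection(q))
        results.append(_result(name, k, len(in_universe), n, N))
    if adjust:
        padj = bh_adjust([r.p_over for r in results])
        logger.info("BH-adjusted over-tail p-values: %s",
                    {r.set_name: float(a) for r, a in zip(results, padj)})
    return results


def overlap_test(list_a: list[str], list_b: list[str], universe: list[str]) -> EnrichmentResult:
    """Hypergeometric overlap of two lists inside a universe (A is the query)."""
    if not universe:
        raise ValidationError("overlap universe is empty")
    uni = set(universe)
    a = [g for g in dict.fromkeys(list_a) if g in uni]
    b = set(list_b) & uni
    k = len(b.intersection(a))
    return _result("overlap", k, len(b), len(a), len(uni))


def chromosome_distribution(
    query: list[str],
    annotation: pd.DataFrame,
    universe: list[str],
) -> tuple[list[EnrichmentResult], float, float]:
    """Per-chromosome hypergeometric tests plus a global chi-square fit.

    Returns (per-chromosome results, chi2 statistic, chi2 p-value) where the
    chi-square compares the query's chromosome counts to the proportions in
    the universe.
    """
    if not universe:
        raise ValidationError("universe is empty")
    chrom = dict(zip(annotation["gene_id"].astype(str), annotation["chromosome"].astype(str)))
    unannotated = [g for g in universe if g not in chrom]
    if unannotated:
        raise ValidationError(f"unannotated universe genes: {unannotated[:10]}")
    uni = list(dict.fromkeys(universe))
    q = [g for g in dict.fromkeys(query) if g in set(uni)]
    uni_chrom = pd.Series([chrom[g] for g in uni])
    q_chrom = pd.Series([chrom[g] for g in q], dtype=str)

    labels = [c for c in CHROMOSOMES if (uni_chrom == c).any()]
    extra = sorted(set(uni_chrom) - set(labels))
    labels += extra

    results = []
    for c in labels:
        K = int((uni_chrom == c).sum())
        k = int((q_chrom == c).sum())
        results.append(_result(c, k, K, len(q), len(uni)))

    observed = np.array([(q_chrom == c).sum() for c in labels], dtype=float)
    expected = np.array([(uni_chrom == c).sum() for c in labels], dtype=float)
    expected = expected / expected.sum() * observed.sum()
    # collapse cells with tiny expectation to keep the chi-square applicable
    ok = expected > 0
    chi2, p = stats.chisquare(observed[ok], expected[ok])
    return results, float(chi2), float(p)


def score_distribution_compare(
    scores: pd.Series,
    annotation: pd.DataFrame,
    group_chromosomes: tuple[str, ...] = ("X",),
) -> dict[str, float]:
    """Two-sided Wilcoxon rank-sum of scores on ``group_chromosomes`` (e.g. X)
    versus all other chromosomes, with group medians."""
    chrom = dict(zip(annotation["gene_id"].astype(str), annotation["chromosome"].astype(str)))
    in_group, out_group = [], []
    for gene, score in scores.items():
        c = chrom.get(str(gene))
        if c is None:
            continue
        (in_group if c in group_chromosomes else out_group).append(float(score))
    if not in_group or not out_group:
        raise ValidationError("both chromosome groups must be non-empty")
    # Mann-Whitney U is the rank-sum statistic up to a shift; scipy picks the
    # exact null distribution for small untied samples
    stat, p = stats.mannwhitneyu(in_group, out_group, alternative="two-sided", method="auto")
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "median_group": float(np.median(in_group)),
        "median_rest": float(np.median(out_group)),
        "n_group": len(in_group),
        "n_rest": len(out_group),
    }


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Enrichment results as a TSV-ready table."""
    return pd.DataFrame(
        [
            {
                "set": r.set_name,
                "N": r.N,
                "K": r.K,
                "n": r.n,
                "k": r.k,
                "fold": r.fold,
                "p_over": r.p_over,
                "p_under": r.p_under,
            }
            for r in results
        ]
    )
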
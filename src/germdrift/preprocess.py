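"""Count normalization, log transform, expression filtering, and a surrogate
per-gene differential-expression count against the founder state.

Normalization is classic median-of-ratios: the reference profile is the
per-gene geometric mean across samples (over genes positive everywhere), and a
sample's size factor is the median ratio of its counts to that reference.

The differential-expression test is an explicitly labeled *surrogate* for the
negative-binomial GLM machinery of dedicated packages: a moments-based NB Wald
test on the log2 fold change of normalized group means. Downstream stages never
consume its output; it exists to reproduce the "genes deregulated vs founder"
counting behaviour on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import SampleDesign, ValidationError, validate_counts


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Only genes with strictly positive counts in every sample enter the
    geometric-mean reference; the median over an even number of ratios is the
    midpoint mean.
    """
    validate_counts(counts)
    values = counts.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise ValidationError(
            "size-factor estimation requires at least one gene with strictly "
            "positive counts in all samples"
        )
    pos = values[all_positive]
    ref = np.exp(np.log(pos).mean(axis=1))  # per-gene geometric mean
    factors = np.median(pos / ref[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series | np.ndarray) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (counts.shape[1],):
        raise ValidationError(
            f"expected {counts.shape[1]} size factors, got {factors.size}"
        )
    if (factors <= 0).any():
        raise ValidationError("size factors must all be positive")
    return counts / factors


def log_transform(normalized: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(x + 1)."""
    values = normalized.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValidationError("log transform requires non-negative values")
    return pd.DataFrame(np.log2(values + 1.0), index=normalized.index,
                        columns=normalized.columns)


def expression_sd_summary(lm: pd.DataFrame) -> pd.DataFrame:
    """Per-gene (max_expression, sd_expression) across samples.

    The standard deviation uses the n-1 denominator. This pair renders the
    2-D density diagnostic used to pick the expression-filter threshold.
    """
    if lm.shape[1] < 2:
        raise ValidationError("expression summary needs >= 2 samples (sd undefined)")
    values = lm.to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "max_expression": values.max(axis=1),
            "sd_expression": values.std(axis=1, ddof=1),
        },
        index=lm.index,
    )


def filter_expressed(lm: pd.DataFrame, threshold: float = 5.0) -> list[str]:
    """Genes whose maximum log-expression strictly exceeds ``threshold``.

    Order-preserving and idempotent; a gene whose max is exactly the threshold
    is excluded.
    """
    keep = lm.to_numpy(dtype=float).max(axis=1) > threshold
    return list(lm.index[keep])


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


@dataclass(frozen=True)
class DeTable:
    """Surrogate differential-expression results for one state-vs-founder test."""

    table: pd.DataFrame  # gene_id index; log2_fold_change, p_value, adjusted_p
    n_significant: int
    state: str
    alpha: float


def de_count_vs_p0(
    counts: pd.DataFrame,
    design: SampleDesign,
    state: str,
    alpha: float = 1e-5,
    reference_state: str | None = None,
    size_factors: pd.Series | None = None,
    dispersion_prior_df: float = 20.0,
) -> DeTable:
    """Moments-based NB Wald surrogate test of ``state`` samples vs the founder.

    Lineages (and replicates) serve as the replicate unit in each group. The
    per-gene dispersion is a pooled method-of-moments estimate shrunk toward
    the common (median) dispersion of expressed genes, which stabilizes the
    small-sample Wald statistic on the log2 fold change of normalized group
    means; p-values come from the standard normal reference.
    """
    if reference_state is None:
        reference_state = design.states[0]
    for st in (state, reference_state):
        if st not in set(design.table["state"]):
            raise ValidationError(f"state {st!r} absent from design")
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    norm = normalize(counts, size_factors.loc[counts.columns])

    group1 = design.table.loc[design.table["state"] == state, "sample_id"]
    group0 = design.table.loc[design.table["state"] == reference_state, "sample_id"]
    if len(group1) < 2 or len(group0) < 2:
        raise ValidationError(
            "each compared state needs >= 2 samples (lineages are the replicates)"
        )
    x1 = norm[list(group1)].to_numpy(dtype=float)
    x0 = norm[list(group0)].to_numpy(dtype=float)
    n1, n0 = x1.shape[1], x0.shape[1]

    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    v1, v0 = x1.var(axis=1, ddof=1), x0.var(axis=1, ddof=1)

    # pooled method-of-moments NB dispersion: var = mu + alpha*mu^2
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (n1 - 1) * (v1 - m1) + (n0 - 1) * (v0 - m0)
        den = (n1 - 1) * m1**2 + (n0 - 1) * m0**2
        disp = np.where(den > 0, np.maximum(num / den, 0.0), 0.0)

    # shrink gene-wise dispersions toward the common value; the gene-wise
    # moment estimate at n1+n0-2 residual df is far too noisy on its own
    df_gene = n1 + n0 - 2
    expressed = (m1 + m0) / 2 >= 10
    common = float(np.median(disp[expressed])) if expressed.any() else float(np.median(disp))
    disp = (dispersion_prior_df * common + df_gene * disp) / (dispersion_prior_df + df_gene)

    pseudo = 0.5  # guards zero means; absorbed into both groups symmetrically
    lfc = np.log2((m1 + pseudo) / (m0 + pseudo))
    # delta-method variance of log2(mean) under the NB mean-variance relation
    var_mean1 = (m1 + disp * m1**2) / n1
    var_mean0 = (m0 + disp * m0**2) / n0
    ln2_sq = np.log(2.0) ** 2
    se = np.sqrt(
        var_mean1 / ((m1 + pseudo) ** 2 * ln2_sq) + var_mean0 / ((m0 + pseudo) ** 2 * ln2_sq)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p = np.clip(p, 0.0, 1.0)
    padj = bh_adjust(p)

    table = pd.DataFrame(
        {"log2_fold_change": lfc, "p_value": p, "adjusted_p": padj},
        index=counts.index,
    )
    return DeTable(table=table, n_significant=int((padj < alpha).sum()), state=state, alpha=alpha)
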
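"""Contributor selection from WCA scores and per-gene trajectory classification
(priming and amplification across the generation states)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import SampleDesign, ValidationError


@dataclass(frozen=True)
class ContributorSets:
    """Top-N most-negative ("down") and most-positive ("up") score gene lists."""

    down: list[str]
    up: list[str]
    n_down: int
    n_up: int


def select_contributors(
    scores: pd.Series, n_down: int = 250, n_up: int = 1000
) -> ContributorSets:
    """Pick the ``n_down`` most-negative and ``n_up`` most-positive scores.

    Ordering is most-extreme first. Boundary ties break lexicographically on
    gene id, so the selection is invariant to input order. Only genes of the
    required sign are eligible; a short side is truncated with a warning.
    """
    if n_down < 0 or n_up < 0:
        raise ValidationError("contributor set sizes must be non-negative")
    if n_down + n_up > scores.size:
        raise ValidationError(
            f"requested {n_down} + {n_up} contributors from a universe of {scores.size} genes"
        )
    frame = pd.DataFrame({"score": scores.to_numpy(dtype=float), "gene": scores.index.astype(str)})

    neg = frame[frame["score"] < 0].sort_values(["score", "gene"], ascending=[True, True])
    pos = frame[frame["score"] > 0].sort_values(["score", "gene"], ascending=[False, True])
    if len(neg) < n_down:
        warnings.warn(
            f"only {len(neg)} negative-score genes available for n_down={n_down}; truncating",
            stacklevel=2,
        )
    if len(pos) < n_up:
        warnings.warn(
            f"only {len(pos)} positive-score genes available for n_up={n_up}; truncating",
            stacklevel=2,
        )
    return ContributorSets(
        down=list(neg["gene"].iloc[:n_down]),
        up=list(pos["gene"].iloc[:n_up]),
        n_down=n_down,
        n_up=n_up,
    )


def score_asymmetry(scores: pd.Series) -> tuple[int, int, float]:
    """Counts of positive/negative scores and an exact two-sided sign-test p.

    Zero scores are uninformative for the sign test and are excluded from it.
    """
    values = scores.to_numpy(dtype=float)
    n_pos = int((values > 0).sum())
    n_neg = int((values < 0).sum())
    n = n_pos + n_neg
    p = 1.0 if n == 0 else stats.binomtest(n_pos, n, 0.5, alternative="two-sided").pvalue
    return n_pos, n_neg, float(p)


@dataclass(frozen=True)
class TrajectoryRecord:
    """Per-lineage log2 changes of one gene along the state path.

    ``changes`` maps lineage -> (P0->F2, F2->F4_fertile, F2->F4_sterile) style
    triples keyed by transition name. ``primed``: the first transition has the
    same (nonzero) sign in every lineage. ``amplified``: in >= quorum lineages
    the change to the terminal state strictly exceeds the change to the
    penultimate state in magnitude, with matching sign.
    """

    gene_id: str
    changes: dict[str, dict[str, float]] = field(repr=False)
    primed: bool = False
    amplified: bool = False


def trajectory_table(
    lm: pd.DataFrame,
    design: SampleDesign,
    genes: list[str],
    amplification_quorum: int | None = None,
) -> list[TrajectoryRecord]:
    """Log2 changes relative to each lineage's founder state, plus flags.

    All changes are differences of log2(x+1) values (a shifted log ratio). With
    the default 4-state schedule the stored transitions per lineage are
    founder->second, second->penultimate and second->terminal.
    """
    missing = [g for g in genes if g not in lm.index]
    if missing:
        raise ValidationError(f"unknown genes: {missing[:5]}")
    states = design.states
    if len(states) < 4:
        raise ValidationError("trajectory classification needs >= 4 ordered states")
    s0, s1, s_pen, s_term = states[0], states[1], states[-2], states[-1]
    lineages = design.lineages
    if amplification_quorum is None:
        amplification_quorum = len(lineages)

    profiles: dict[tuple[str, str], pd.Series] = {}
    for lineage in lineages:
        for state in (s0, s1, s_pen, s_term):
            samples = [s for s in design.sample_for(lineage, state) if s in lm.columns]
            if not samples:
                raise ValidationError(f"missing (lineage, state) cell: ({lineage}, {state})")
            profiles[(lineage, state)] = lm[samples].mean(axis=1)

    records = []
    for gene in genes:
        changes: dict[str, dict[str, float]] = {}
        primed_signs = []
        n_amplified = 0
        for lineage in lineages:
            v0 = float(profiles[(lineage, s0)].loc[gene])
            v1 = float(profiles[(lineage, s1)].loc[gene])
            v_pen = float(profiles[(lineage, s_pen)].loc[gene])
            v_term = float(profiles[(lineage, s_term)].loc[gene])
            early = v1 - v0
            to_pen = v_pen - v1
            to_term = v_term - v1
            changes[lineage] = {
                f"{s0}->{s1}": early,
                f"{s1}->{s_pen}": to_pen,
                f"{s1}->{s_term}": to_term,
            }
            primed_signs.append(np.sign(early))
            if to_term != 0 and abs(to_term) > abs(to_pen) and to_term * to_pen >= 0:
                n_amplified += 1
        primed = bool(primed_signs and primed_signs[0] != 0 and
                      all(s == primed_signs[0] for s in primed_signs))
        records.append(
            TrajectoryRecord(
                gene_id=str(gene),
                changes=changes,
                primed=primed,
                amplified=n_amplified >= amplification_quorum,
            )
        )
    return records


def count_trajectory_classes(records: list[TrajectoryRecord]) -> dict[str, int]:
    """Tally of primed and amplified genes in a record list."""
    return {
        "n_genes": len(records),
        "n_primed": sum(r.primed for r in records),
        "n_amplified": sum(r.amplified for r in records),
    }


def trajectory_frame(records: list[TrajectoryRecord]) -> pd.DataFrame:
    """Flatten trajectory records to a TSV-ready table (one row per gene/lineage)."""
    rows = []
    for r in records:
        for lineage, ch in r.changes.items():
            rows.append({"gene_id": r.gene_id, "lineage": lineage, **ch,
                         "primed": r.primed, "amplified": r.amplified})
    return pd.DataFrame(rows)
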
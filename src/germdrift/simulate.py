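"""Negative-binomial count simulator with a planted transgenerational signal.

The generator emulates a multi-lineage, multi-generation gonad RNA-seq design:
each lineage is sampled at a series of ordered states whose "severity" grows
toward sterility. A minority of genes carry a planted global effect that scales
linearly (in log2 space) with state severity; a further minority carry
lineage-private effects. Baseline expression is a two-component log2-normal
mixture so that a max-expression filter has two populations to separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import DEFAULT_SEVERITY, DEFAULT_STATES, SampleDesign, ValidationError

AUTOSOMES = ("I", "II", "III", "IV", "V")

LABEL_UP = "up_contributor"
LABEL_DOWN = "down_contributor"
LABEL_PRIVATE = "lineage_private"
LABEL_BACKGROUND = "background"


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic transgenerational design.

    Counts for gene g in sample (lineage l, state s) are negative binomial with
    mean ``sf * 2**(beta_g + delta_g * t(s) + pi_gl * t(s))`` and variance
    ``mu + dispersion * mu**2`` (Poisson when dispersion is 0).
    """

    n_genes: int = 8000
    n_lineages: int = 3
    states: tuple[str, ...] = DEFAULT_STATES
    severity: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEVERITY))
    n_up_planted: int = 200
    n_down_planted: int = 50
    effect_size_log2: float = 1.0
    n_lineage_private: int = 100
    private_effect_log2: float = 1.0
    background_fraction: float = 0.6
    dispersion: float = 0.05
    library_size_factors: tuple[float, ...] | None = None
    x_fraction_background: float = 0.15
    x_fraction_up_planted: float = 0.15
    n_replicates: int = 1
    background_log2_mean: float = 2.0
    background_log2_sd: float = 1.0
    expressed_log2_mean: float = 8.0
    expressed_log2_sd: float = 1.0
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.n_lineages * len(self.states) * self.n_replicates

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValidationError("invariant violated: n_genes must be positive")
        if self.n_lineages < 1:
            raise ValidationError("invariant violated: n_lineages must be >= 1")
        if self.n_replicates < 1:
            raise ValidationError("invariant violated: n_replicates must be >= 1")
        planted = self.n_up_planted + self.n_down_planted + self.n_lineage_private
        if min(self.n_up_planted, self.n_down_planted, self.n_lineage_private) < 0:
            raise ValidationError("invariant violated: planted gene counts must be non-negative")
        if planted > self.n_genes:
            raise ValidationError(
                "invariant violated: n_up_planted + n_down_planted + n_lineage_private "
                f"({planted}) exceeds n_genes ({self.n_genes})"
            )
        if len(set(self.states)) != len(self.states) or len(self.states) < 1:
            raise ValidationError("invariant violated: states must be a non-empty ordered list "
                                  "of distinct labels")
        missing = [s for s in self.states if s not in self.severity]
        if missing:
            raise ValidationError(f"invariant violated: severity missing for states {missing}")
        sev = [float(self.severity[s]) for s in self.states]
        if any(not np.isfinite(v) or v < 0 for v in sev):
            raise ValidationError("invariant violated: severity values must be finite and "
                                  "non-negative")
        if self.dispersion < 0:
            raise ValidationError("invariant violated: dispersion must be >= 0")
        if not (0.0 <= self.background_fraction <= 1.0):
            raise ValidationError("invariant violated: background_fraction must lie in [0, 1]")
        for name in ("x_fraction_background", "x_fraction_up_planted"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"invariant violated: {name} must lie in [0, 1]")
        if self.effect_size_log2 <= 0:
            raise ValidationError("invariant violated: effect_size_log2 must be positive")
        if self.library_size_factors is not None:
            sf = np.asarray(self.library_size_factors, dtype=float)
            if sf.shape != (self.n_samples,):
                raise ValidationError(
                    "invariant violated: library_size_factors must have one entry per sample "
                    f"(expected {self.n_samples}, got {sf.size})"
                )
            if (sf <= 0).any():
                raise ValidationError("invariant violated: library_size_factors must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["states"] = list(self.states)
        if self.library_size_factors is not None:
            d["library_size_factors"] = list(self.library_size_factors)
        return d


def truth_gene_sets(truth: pd.DataFrame) -> dict[str, list[str]]:
    """Planted ground truth as named gene sets (GMT-ready)."""
    return {
        "planted_up": list(truth.index[truth["label"] == LABEL_UP]),
        "planted_down": list(truth.index[truth["label"] == LABEL_DOWN]),
        "lineage_private": list(truth.index[truth["label"] == LABEL_PRIVATE]),
    }


def simulate_counts(
    params: SimulationParams,
) -> tuple[pd.DataFrame, SampleDesign, pd.DataFrame, pd.DataFrame]:
    """Draw a (counts, design, annotation, truth) quadruple.

    Returns
    -------
    counts : DataFrame, genes x samples, int64
    design : SampleDesign with one row per (lineage, state, replicate)
    annotation : DataFrame with columns gene_id, chromosome
    truth : DataFrame indexed by gene_id with columns label, baseline_log2,
        delta_log2, private_lineage, private_log2
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    n = params.n_genes
    width = max(5, len(str(n)))
    gene_ids = np.array([f"g{i:0{width}d}" for i in range(1, n + 1)])
    lineages = [f"L{i}" for i in range(1, params.n_lineages + 1)]

    # --- per-gene truth assignment on a random permutation of gene slots
    labels = np.full(n, LABEL_BACKGROUND, dtype=object)
    perm = rng.permutation(n)
    n_up, n_down, n_priv = params.n_up_planted, params.n_down_planted, params.n_lineage_private
    up_idx = perm[:n_up]
    down_idx = perm[n_up : n_up + n_down]
    priv_idx = perm[n_up + n_down : n_up + n_down + n_priv]
    labels[up_idx] = LABEL_UP
    labels[down_idx] = LABEL_DOWN
    labels[priv_idx] = LABEL_PRIVATE

    # baselines: planted genes come from the expressed component so they survive
    # the max-expression filter; the rest follow the two-component mixture
    planted_mask = labels != LABEL_BACKGROUND
    is_background_component = np.zeros(n, dtype=bool)
    is_background_component[~planted_mask] = (
        rng.random((~planted_mask).sum()) < params.background_fraction
    )
    beta = np.where(
        is_background_component,
        rng.normal(params.background_log2_mean, params.background_log2_sd, n),
        rng.normal(params.expressed_log2_mean, params.expressed_log2_sd, n),
    )

    delta = np.zeros(n)
    delta[up_idx] = params.effect_size_log2
    delta[down_idx] = -params.effect_size_log2

    private_lineage = np.full(n, "", dtype=object)
    private_effect = np.zeros(n)
    if n_priv:
        private_lineage[priv_idx] = rng.choice(lineages, size=n_priv)
        private_effect[priv_idx] = params.private_effect_log2 * rng.choice([-1.0, 1.0], size=n_priv)

    # chromosome assignment: X with a label-dependent probability, otherwise a
    # uniform autosome
    p_x = np.where(labels == LABEL_UP, params.x_fraction_up_planted, params.x_fraction_background)
    on_x = rng.random(n) < p_x
    chromosome = np.where(on_x, "X", rng.choice(AUTOSOMES, size=n))

    # --- sample grid
    rows = []
    for lin in lineages:
        for state in params.states:
            for rep in range(1, params.n_replicates + 1):
                sid = f"{lin}_{state}" if params.n_replicates == 1 else f"{lin}_{state}_r{rep}"
                rows.append((sid, lin, state))
    design_table = pd.DataFrame(rows, columns=["sample_id", "lineage", "state"])
    design = SampleDesign(table=design_table, states=params.states)

    if params.library_size_factors is None:
        size_factors = np.ones(len(rows))
    else:
        size_factors = np.asarray(params.library_size_factors, dtype=float)

    # --- draw counts column by column (sample order fixes the random stream)
    severity = {s: float(params.severity[s]) for s in params.states}
    counts = np.empty((n, len(rows)), dtype=np.int64)
    for j, (sid, lin, state) in enumerate(rows):
        t = severity[state]
        log2_mu = beta + delta * t + np.where(private_lineage == lin, private_effect, 0.0) * t
        mu = size_factors[j] * np.exp2(log2_mu)
        if params.dispersion == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / params.dispersion
            p = r / (r + mu)
            counts[:, j] = rng.negative_binomial(r, p)

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=[r[0] for r in rows])
    annotation = pd.DataFrame({"gene_id": gene_ids, "chromosome": chromosome})
    truth = pd.DataFrame(
        {
            "label": labels,
            "baseline_log2": beta,
            "delta_log2": delta,
            "private_lineage": private_lineage,
            "private_log2": private_effect,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return counts_df, design, annotation, truth
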
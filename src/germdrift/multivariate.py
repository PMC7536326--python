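"""Principal-component machinery built from first principles: sample PCA,
PCA on within-lineage expression differences, and within-class analysis (WCA).

Conventions (matching the duality-diagram style of classic multivariate
toolkits): uniform row weights 1/n, so eigenvalues are variances of row
coordinates under that weighting; variable loadings are unit-norm; row
coordinates are the (class-)centered matrix projected onto the loadings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import SampleDesign, ValidationError

_EIG_DROP = 1e-12  # eigenvalues below this fraction of the largest are noise


@dataclass(frozen=True)
class PcaResult:
    eigenvalues: np.ndarray  # component variances under 1/n row weights
    percent_variance: np.ndarray
    row_coordinates: np.ndarray  # individuals x components
    variable_loadings: np.ndarray  # variables x components, unit-norm columns
    row_ids: list[str] | None = None
    variable_ids: list[str] | None = None


@dataclass(frozen=True)
class WcaResult:
    classes: np.ndarray
    eigenvalues: np.ndarray  # within-class component variances
    pve: np.ndarray  # percent of within-class variance per component
    sample_coordinates: np.ndarray
    gene_loadings: np.ndarray  # unit-norm columns
    within_total_ratio: float
    sample_ids: list[str] | None = None
    gene_ids: list[str] | None = None


def _as_matrix(matrix) -> tuple[np.ndarray, list[str] | None, list[str] | None]:
    if isinstance(matrix, pd.DataFrame):
        return (
            matrix.to_numpy(dtype=float),
            [str(i) for i in matrix.index],
            [str(c) for c in matrix.columns],
        )
    return np.asarray(matrix, dtype=float), None, None


def _orient(loadings: np.ndarray, coords: np.ndarray) -> None:
    """Fix eigenvector sign in place: largest-|loading| variable positive."""
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] *= -1.0
            coords[:, j] *= -1.0


def _decompose(centered: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD route to the 1/n-weighted eigendecomposition."""
    n = centered.shape[0]
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eig = s**2 / n
    eig = eig[:n_components]
    loadings = vt[:n_components].T.copy()
    if eig.size and eig[0] > 0:
        keep = eig >= _EIG_DROP * eig[0]
        eig, loadings = eig[keep], loadings[:, keep]
    coords = centered @ loadings
    return eig, loadings, coords


def _pve(eigenvalues: np.ndarray) -> np.ndarray:
    total = eigenvalues.sum()
    if total <= 0:
        return np.zeros_like(eigenvalues)
    return eigenvalues / total * 100.0


def pca(matrix, center: bool = True, scale: bool = False) -> PcaResult:
    """Centered (optionally scaled) PCA of an individuals x variables matrix."""
    values, row_ids, var_ids = _as_matrix(matrix)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValidationError("pca requires a 2-D matrix with >= 2 individuals")
    if not np.isfinite(values).all():
        raise ValidationError("pca requires finite values")
    x = values - values.mean(axis=0) if center else values.copy()
    if scale:
        sd = values.std(axis=0, ddof=0)
        zero = np.where(sd == 0)[0]
        if zero.size:
            names = [var_ids[i] if var_ids else str(i) for i in zero[:5]]
            raise ValidationError(f"cannot scale zero-variance variables: {names}")
        x = x / sd
    n_components = min(x.shape)
    eig, loadings, coords = _decompose(x, n_components)
    _orient(loadings, coords)
    return PcaResult(
        eigenvalues=eig,
        percent_variance=_pve(eig),
        row_coordinates=coords,
        variable_loadings=loadings,
        row_ids=row_ids,
        variable_ids=var_ids,
    )


def build_diff_matrix(
    lm: pd.DataFrame,
    design: SampleDesign,
    transitions: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Within-lineage expression-difference matrix (genes x transition columns).

    For every lineage and each consecutive state transition, the column is
    LM(later state) - LM(earlier state); headers read ``lineage:from->to``.
    Replicate samples in one (lineage, state) cell are averaged first.
    """
    if transitions is None:
        transitions = list(zip(design.states[:-1], design.states[1:]))
    columns: dict[str, np.ndarray] = {}
    for lineage in design.lineages:
        profiles: dict[str, np.ndarray] = {}
        for state in {s for pair in transitions for s in pair}:
            samples = [s for s in design.sample_for(lineage, state) if s in lm.columns]
            if not samples:
                raise ValidationError(f"missing (lineage, state) cell: ({lineage}, {state})")
            profiles[state] = lm[samples].to_numpy(dtype=float).mean(axis=1)
        for earlier, later in transitions:
            columns[f"{lineage}:{earlier}->{later}"] = profiles[later] - profiles[earlier]
    return pd.DataFrame(columns, index=lm.index)


def pca_on_differences(dlm: pd.DataFrame) -> PcaResult:
    """PCA with individuals = transition difference profiles, variables = genes."""
    if dlm.shape[1] < 2:
        raise ValidationError("difference PCA requires >= 2 difference columns")
    return pca(dlm.T)


def wca(matrix, classes, severity_rank=None) -> WcaResult:
    """Within-class analysis of a samples x genes matrix.

    Genes are centered across all samples, then each sample's class mean is
    subtracted per gene, and the class-centered matrix is eigendecomposed under
    uniform 1/n row weights. The first component is oriented so its sample
    coordinates correlate positively (Spearman) with ``severity_rank`` when
    given; otherwise the largest-|loading| gene is made positive.
    """
    values, sample_ids, gene_ids = _as_matrix(matrix)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValidationError("wca requires a 2-D matrix with >= 2 samples")
    if not np.isfinite(values).all():
        raise ValidationError("wca requires finite values")
    classes = np.asarray(classes)
    if classes.shape != (values.shape[0],):
        raise ValidationError(
            f"need one class label per sample ({values.shape[0]}), got {classes.size}"
        )
    n, p = values.shape
    unique = list(dict.fromkeys(classes))
    k = len(unique)
    if k == 1:
        warnings.warn(
            "wca with a single class degenerates to plain centered PCA",
            stacklevel=2,
        )
    if k == n:
        warnings.warn(
            "every class is a singleton: class centering zeroes the matrix and "
            "all within-class eigenvalues vanish",
            stacklevel=2,
        )

    centered = values - values.mean(axis=0)
    total_var = float((centered**2).sum()) / n
    within = centered.copy()
    for cls in unique:
        mask = classes == cls
        within[mask] -= within[mask].mean(axis=0)

    eig, loadings, coords = _decompose(within, min(n - k, p))
    _orient(loadings, coords)
    if severity_rank is not None and eig.size:
        severity_rank = np.asarray(severity_rank, dtype=float)
        if severity_rank.shape != (n,):
            raise ValidationError("severity_rank must have one entry per sample")
        rho = stats.spearmanr(coords[:, 0], severity_rank).statistic
        if np.isfinite(rho) and rho < 0:
            loadings[:, 0] *= -1.0
            coords[:, 0] *= -1.0

    within_var = float(eig.sum())
    return WcaResult(
        classes=classes,
        eigenvalues=eig,
        pve=_pve(eig),
        sample_coordinates=coords,
        gene_loadings=loadings,
        within_total_ratio=within_var / total_var if total_var > 0 else 0.0,
        sample_ids=sample_ids,
        gene_ids=gene_ids,
    )


def wca_scores(result: WcaResult) -> pd.Series:
    """Per-gene first-component loading (the unit-norm score vector).

    Positive scores mark genes globally upregulated along the severity path,
    negative scores genes globally downregulated (given the orientation rule).
    """
    if result.eigenvalues.size < 1:
        raise ValidationError("wca result has no components; scores undefined")
    index = result.gene_ids if result.gene_ids is not None else range(
        result.gene_loadings.shape[0]
    )
    return pd.Series(result.gene_loadings[:, 0], index=index, name="wca_score")


def subset_wca_pve(matrix, classes, gene_subset, severity_rank=None) -> float:
    """Percent of within-class variance on PC1 when WCA runs on a gene subset."""
    if len(gene_subset) == 0:
        raise ValidationError("gene subset must be non-empty")
    if isinstance(matrix, pd.DataFrame):
        missing = [g for g in gene_subset if g not in matrix.columns]
        if missing:
            raise ValidationError(f"subset genes absent from matrix: {missing[:5]}")
        sub = matrix[list(gene_subset)]
    else:
        sub = np.asarray(matrix, dtype=float)[:, list(gene_subset)]
    result = wca(sub, classes, severity_rank=severity_rank)
    if result.pve.size == 0:
        return 0.0
    return float(result.pve[0])
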
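"""End-to-end orchestration: per-stage functions that read/write plain-text
files, a config object, and a manifest recording checksums of every output.

Each stage function is the single implementation behind both the matching CLI
subcommand and :func:`run_all`, so piping the subcommands by hand reproduces
the composite run byte for byte.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .core import GermdriftError, SampleDesign, ValidationError
from .contributors import (
    select_contributors,
    score_asymmetry,
    trajectory_frame,
    trajectory_table,
)
from .enrichment import (
    chromosome_distribution,
    enrich_sets,
    results_frame,
    score_distribution_compare,
)
from .multivariate import build_diff_matrix, pca, pca_on_differences, wca, wca_scores
from .preprocess import (
    de_count_vs_p0,
    estimate_size_factors,
    expression_sd_summary,
    filter_expressed,
    log_transform,
    normalize,
)
from .simulate import SimulationParams, simulate_counts, truth_gene_sets

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


class PipelineStageError(GermdriftError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything a full run needs; round-trips through YAML unchanged."""

    out_dir: str = "germdrift_out"
    counts: str | None = None
    design: str | None = None
    annotation: str | None = None
    gene_sets: str | None = None
    filter_threshold: float = 5.0
    de_alpha: float = 1e-5
    n_down: int = 250
    n_up: int = 1000
    trajectory_quorum: int | None = None
    simulation: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.filter_threshold <= 0:
            raise ValidationError("filter_threshold must be positive")
        if not (0 < self.de_alpha <= 1):
            raise ValidationError("de_alpha must lie in (0, 1]")
        if self.n_down < 0 or self.n_up < 0:
            raise ValidationError("contributor sizes must be non-negative")

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "counts": self.counts,
            "design": self.design,
            "annotation": self.annotation,
            "gene_sets": self.gene_sets,
            "filter_threshold": self.filter_threshold,
            "de_alpha": self.de_alpha,
            "n_down": self.n_down,
            "n_up": self.n_up,
            "trajectory_quorum": self.trajectory_quorum,
            "simulation": self.simulation,
            "seed": self.seed,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Derive a per-stage seed so stage order cannot change random draws."""
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(stage_index,))
    return int(ss.generate_state(1)[0])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# stages


def stage_simulate(params: SimulationParams, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts, design, annotation, truth = simulate_counts(params)
    paths = {
        "counts": out / "counts.tsv",
        "design": out / "design.tsv",
        "annotation": out / "annotation.tsv",
        "truth": out / "truth.tsv",
        "truth_sets": out / "truth_sets.gmt",
        "params": out / "simulation_params.json",
    }
    io.write_matrix_tsv(counts, paths["counts"])
    io.write_design_tsv(design, paths["design"])
    io.write_annotation_tsv(annotation, paths["annotation"])
    truth.to_csv(paths["truth"], sep="\t", float_format=io.FLOAT_FMT)
    io.write_gmt(truth_gene_sets(truth), paths["truth_sets"], description="planted_truth")
    io.write_json({"params": params.to_dict(), "seed": params.seed}, paths["params"])
    return paths


def stage_normalize(
    counts_path: str | Path, out_dir: str | Path, threshold: float = 5.0
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = io.read_counts_tsv(counts_path)
    factors = estimate_size_factors(counts)
    norm = normalize(counts, factors)
    lm = log_transform(norm)
    summary = expression_sd_summary(lm)
    universe = filter_expressed(lm, threshold=threshold)
    paths = {
        "size_factors": out / "size_factors.tsv",
        "normalized": out / "normalized.tsv",
        "log_expression": out / "log_expression.tsv",
        "expression_summary": out / "expression_summary.tsv",
        "universe": out / "universe.txt",
    }
    factors.to_frame().to_csv(paths["size_factors"], sep="\t", index_label="sample_id",
                              float_format=io.FLOAT_FMT)
    io.write_matrix_tsv(norm, paths["normalized"])
    io.write_matrix_tsv(lm, paths["log_expression"])
    io.write_matrix_tsv(summary, paths["expression_summary"])
    io.write_gene_list(universe, paths["universe"])
    return paths


def stage_de(
    counts_path: str | Path,
    design_path: str | Path,
    out_dir: str | Path,
    alpha: float = 1e-5,
) -> dict[str, Path]:
    """Surrogate DE counting of every non-founder state against the founder."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = io.read_counts_tsv(counts_path)
    design = io.read_design_tsv(design_path)
    paths: dict[str, Path] = {}
    summary = []
    for state in design.states[1:]:
        res = de_count_vs_p0(counts, design, state, alpha=alpha)
        p = out / f"de_{state}_vs_{design.states[0]}.tsv"
        res.table.to_csv(p, sep="\t", index_label="gene_id", float_format=io.FLOAT_FMT)
        paths[f"de_{state}"] = p
        summary.append({"state": state, "n_significant": res.n_significant, "alpha": alpha})
    paths["de_summary"] = out / "de_summary.tsv"
    pd.DataFrame(summary).to_csv(paths["de_summary"], sep="\t", index=False)
    return paths


def stage_wca(
    log_path: str | Path,
    design_path: str | Path,
    universe_path: str | Path,
    out_dir: str | Path,
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lm = io.read_matrix_tsv(log_path)
    design = io.read_design_tsv(design_path)
    universe = io.read_gene_list(universe_path)
    missing = [g for g in universe if g not in lm.index]
    if missing:
        raise ValidationError(f"universe genes absent from log matrix: {missing[:5]}")

    dlm = build_diff_matrix(lm, design)
    diff_pca = pca_on_differences(dlm)

    sub = lm.loc[universe].T  # samples x genes, universe only
    classes = design.classes_for(list(sub.index))
    severity = design.severity_rank_for(list(sub.index))
    result = wca(sub, classes, severity_rank=severity)
    scores = wca_scores(result)

    sample_pca = pca(lm.T)

    paths = {
        "diff_matrix": out / "diff_matrix.tsv",
        "diff_pca_coordinates": out / "diff_pca_coordinates.tsv",
        "sample_pca_coordinates": out / "sample_pca_coordinates.tsv",
        "wca_eigenvalues": out / "wca_eigenvalues.tsv",
        "wca_sample_coordinates": out / "wca_sample_coordinates.tsv",
        "wca_scores": out / "wca_scores.tsv",
    }
    io.write_matrix_tsv(dlm, paths["diff_matrix"])
    pd.DataFrame(
        diff_pca.row_coordinates[:, :2],
        index=diff_pca.row_ids,
        columns=["PC1", "PC2"][: diff_pca.row_coordinates.shape[1]],
    ).to_csv(paths["diff_pca_coordinates"], sep="\t", index_label="profile",
             float_format=io.FLOAT_FMT)
    pd.DataFrame(
        sample_pca.row_coordinates[:, :2],
        index=sample_pca.row_ids,
        columns=["PC1", "PC2"][: sample_pca.row_coordinates.shape[1]],
    ).to_csv(paths["sample_pca_coordinates"], sep="\t", index_label="sample_id",
             float_format=io.FLOAT_FMT)
    pd.DataFrame(
        {
            "component": np.arange(1, result.eigenvalues.size + 1),
            "eigenvalue": result.eigenvalues,
            "pve": result.pve,
        }
    ).to_csv(paths["wca_eigenvalues"], sep="\t", index=False, float_format=io.FLOAT_FMT)
    n_show = min(2, result.sample_coordinates.shape[1])
    pd.DataFrame(
        result.sample_coordinates[:, :n_show],
        index=result.sample_ids,
        columns=[f"PC{i+1}" for i in range(n_show)],
    ).to_csv(paths["wca_sample_coordinates"], sep="\t", index_label="sample_id",
             float_format=io.FLOAT_FMT)
    score_table = scores.to_frame()
    score_table["rank"] = score_table["wca_score"].rank(ascending=False, method="first").astype(int)
    score_table.to_csv(paths["wca_scores"], sep="\t", index_label="gene_id",
                       float_format=io.FLOAT_FMT)
    return paths


def stage_contributors(
    scores_path: str | Path,
    log_path: str | Path,
    design_path: str | Path,
    out_dir: str | Path,
    n_down: int = 250,
    n_up: int = 1000,
    quorum: int | None = None,
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scores = pd.read_csv(scores_path, sep="\t", index_col="gene_id")["wca_score"]
    lm = io.read_matrix_tsv(log_path)
    design = io.read_design_tsv(design_path)

    sets = select_contributors(scores, n_down=n_down, n_up=n_up)
    n_pos, n_neg, p_sign = score_asymmetry(scores)
    records = trajectory_table(lm, design, sets.down + sets.up, amplification_quorum=quorum)

    paths = {
        "down": out / "contributors_down.txt",
        "up": out / "contributors_up.txt",
        "gmt": out / "contributors.gmt",
        "asymmetry": out / "score_asymmetry.json",
        "trajectories": out / "trajectories.tsv",
    }
    io.write_gene_list(sets.down, paths["down"])
    io.write_gene_list(sets.up, paths["up"])
    io.write_gmt({"down_contributors": sets.down, "up_contributors": sets.up}, paths["gmt"],
                 description="wca_contributors")
    io.write_json(
        {"n_positive": n_pos, "n_negative": n_neg, "sign_test_p": p_sign}, paths["asymmetry"]
    )
    trajectory_frame(records).to_csv(paths["trajectories"], sep="\t", index=False,
                                     float_format=io.FLOAT_FMT)
    return paths


def stage_enrich(
    up_path: str | Path,
    down_path: str | Path,
    universe_path: str | Path,
    annotation_path: str | Path,
    out_dir: str | Path,
    gene_sets_path: str | Path | None = None,
    scores_path: str | Path | None = None,
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    up = io.read_gene_list(up_path)
    down = io.read_gene_list(down_path)
    universe = io.read_gene_list(universe_path)
    annotation = io.read_annotation_tsv(annotation_path)

    paths: dict[str, Path] = {}
    if gene_sets_path is not None:
        sets = io.read_gmt(gene_sets_path)
        in_universe = {name: set(m) & set(universe) for name, m in sets.items()}
        empty = [name for name, m in in_universe.items() if not m]
        if empty:
            raise ValidationError(
                f"gene sets share no members with the universe: {empty}"
            )
        for label, query in (("up", up), ("down", down)):
            res = enrich_sets(query, sets, universe)
            p = out / f"enrichment_{label}.tsv"
            results_frame(res).to_csv(p, sep="\t", index=False, float_format=io.FLOAT_FMT)
            paths[f"enrichment_{label}"] = p

    for label, query in (("up", up), ("down", down)):
        res, chi2, chi2_p = chromosome_distribution(query, annotation, universe)
        frame = results_frame(res).rename(columns={"set": "chromosome"})
        frame["chi2"] = chi2
        frame["chi2_p"] = chi2_p
        p = out / f"chromosome_{label}.tsv"
        frame.to_csv(p, sep="\t", index=False, float_format=io.FLOAT_FMT)
        paths[f"chromosome_{label}"] = p

    if scores_path is not None:
        scores = pd.read_csv(scores_path, sep="\t", index_col="gene_id")["wca_score"]
        cmp = score_distribution_compare(scores, annotation)
        paths["x_vs_autosome"] = out / "x_vs_autosome.json"
        io.write_json(cmp, paths["x_vs_autosome"])
    return paths


# ---------------------------------------------------------------------------
# composite run


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage in order and return the manifest (also written as
    ``manifest.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "status": "incomplete",
    }

    def record(stage: str, paths: dict[str, Path]) -> None:
        manifest["stages"][stage] = {
            "outputs": {key: str(p) for key, p in paths.items()},
            "checksums": {str(p): _sha256(Path(p)) for p in paths.values()},
        }
        logger.info("stage %s: wrote %d outputs", stage, len(paths))

    def fail(stage: str, exc: Exception) -> None:
        manifest["stages"][stage] = {"error": str(exc)}
        io.write_json(manifest, out / "manifest.json")

    stage = "simulate"
    try:
        if config.simulation is not None:
            sim_kwargs = dict(config.simulation)
            if "states" in sim_kwargs:
                sim_kwargs["states"] = tuple(sim_kwargs["states"])
            sim_kwargs.setdefault("seed", stage_seed(config.seed, 0))
            params = SimulationParams(**sim_kwargs)
            sim_paths = stage_simulate(params, out)
            record(stage, sim_paths)
            counts_path = sim_paths["counts"]
            design_path = sim_paths["design"]
            annotation_path = sim_paths["annotation"]
            gene_sets_path = sim_paths["truth_sets"]
        else:
            if config.counts is None or config.design is None or config.annotation is None:
                raise ValidationError(
                    "config needs either a simulation block or counts/design/annotation paths"
                )
            counts_path = Path(config.counts)
            design_path = Path(config.design)
            annotation_path = Path(config.annotation)
            gene_sets_path = Path(config.gene_sets) if config.gene_sets else None

        stage = "normalize"
        norm_paths = stage_normalize(counts_path, out, threshold=config.filter_threshold)
        record(stage, norm_paths)

        stage = "de"
        de_paths = stage_de(counts_path, design_path, out, alpha=config.de_alpha)
        record(stage, de_paths)

        stage = "wca"
        wca_paths = stage_wca(
            norm_paths["log_expression"], design_path, norm_paths["universe"], out
        )
        record(stage, wca_paths)

        stage = "contributors"
        contrib_paths = stage_contributors(
            wca_paths["wca_scores"],
            norm_paths["log_expression"],
            design_path,
            out,
            n_down=config.n_down,
            n_up=config.n_up,
            quorum=config.trajectory_quorum,
        )
        record(stage, contrib_paths)

        stage = "enrich"
        enrich_paths = stage_enrich(
            contrib_paths["up"],
            contrib_paths["down"],
            norm_paths["universe"],
            annotation_path,
            out,
            gene_sets_path=gene_sets_path,
            scores_path=wca_paths["wca_scores"],
        )
        record(stage, enrich_paths)
    except Exception as exc:
        fail(stage, exc)
        raise PipelineStageError(stage, exc) from exc

    manifest["status"] = "complete"
    io.write_json(manifest, out / "manifest.json")
    return manifest
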
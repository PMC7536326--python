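"""Shared domain types: sample design, validation errors, default state schedule."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_STATES: tuple[str, ...] = ("P0", "F2", "F4_fertile", "F4_sterile")
DEFAULT_SEVERITY: dict[str, float] = {
    "P0": 0.0,
    "F2": 1.0,
    "F4_fertile": 1.5,
    "F4_sterile": 3.0,
}


class GermdriftError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(GermdriftError):
    """An input violated a documented invariant."""


class ParseError(GermdriftError):
    """A text input file could not be parsed; carries the offending line."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


@dataclass(frozen=True)
class SampleDesign:
    """Per-sample lineage label and ordered generation state.

    ``table`` must have columns ``sample_id``, ``lineage``, ``state``; ``states``
    fixes the severity ordering of the generation states (earliest first).
    """

    table: pd.DataFrame
    states: tuple[str, ...] = DEFAULT_STATES

    def __post_init__(self) -> None:
        required = {"sample_id", "lineage", "state"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"design table is missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dupes = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise ValidationError(f"duplicate sample ids in design: {sorted(set(dupes))}")
        unknown = set(self.table["state"]) - set(self.states)
        if unknown:
            raise ValidationError(
                f"design states {sorted(unknown)} not in declared state order {list(self.states)}"
            )
        if len(set(self.states)) != len(self.states):
            raise ValidationError("state order contains duplicates")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def lineages(self) -> list[str]:
        """Lineage labels in order of first appearance."""
        return list(dict.fromkeys(self.table["lineage"]))

    def classes_for(self, sample_ids: list[str]) -> np.ndarray:
        """Lineage label per sample, aligned to ``sample_ids``."""
        lut = dict(zip(self.table["sample_id"], self.table["lineage"]))
        missing = [s for s in sample_ids if s not in lut]
        if missing:
            raise ValidationError(f"samples missing from design: {missing}")
        return np.asarray([lut[s] for s in sample_ids])

    def severity_rank_for(self, sample_ids: list[str]) -> np.ndarray:
        """Integer severity rank (index into the state order) per sample."""
        rank = {s: i for i, s in enumerate(self.states)}
        lut = dict(zip(self.table["sample_id"], self.table["state"]))
        missing = [s for s in sample_ids if s not in lut]
        if missing:
            raise ValidationError(f"samples missing from design: {missing}")
        return np.asarray([rank[lut[s]] for s in sample_ids])

    def sample_for(self, lineage: str, state: str) -> list[str]:
        t = self.table
        return list(t.loc[(t["lineage"] == lineage) & (t["state"] == state), "sample_id"])


def validate_counts(counts: pd.DataFrame) -> None:
    """Check the count-matrix invariants: unique ids, non-negative values."""
    if counts.index.duplicated().any():
        raise ValidationError(
            f"duplicate gene ids: {sorted(set(counts.index[counts.index.duplicated()]))}"
        )
    if counts.columns.duplicated().any():
        raise ValidationError(
            f"duplicate sample ids: {sorted(set(counts.columns[counts.columns.duplicated()]))}"
        )
    if (counts.to_numpy() < 0).any():
        raise ValidationError("count matrix contains negative entries")


def check_design_covers(counts: pd.DataFrame, design: SampleDesign) -> None:
    """Every count-matrix sample must appear exactly once in the design."""
    missing = [s for s in counts.columns if s not in set(design.sample_ids)]
    if missing:
        raise ValidationError(f"count-matrix samples absent from design: {missing}")
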
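"""Readers and writers for the plain-text formats used throughout.

Everything is tab-separated UTF-8 with '.' decimals; floats are serialized with
10 significant digits so repeated runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .core import ParseError, SampleDesign

FLOAT_FMT = "%.10g"


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path, index_label: str = "gene_id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FMT)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"could not parse matrix: {exc}", path=str(path)) from exc
    return df


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Counts matrix: first column gene ids, header row of sample ids, int cells."""
    df = read_matrix_tsv(path)
    for col in df.columns:
        bad = df[col][~df[col].apply(lambda v: float(v).is_integer())]
        if len(bad):
            line = df.index.get_loc(bad.index[0]) + 2  # header + 1-based
            raise ParseError(
                f"non-integer count {bad.iloc[0]!r} for gene {bad.index[0]!r} in sample {col!r}",
                path=str(path),
                line=line,
            )
    return df.astype("int64")


def write_design_tsv(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_design_tsv(path: str | Path, states: tuple[str, ...] | None = None) -> SampleDesign:
    try:
        table = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise ParseError(f"could not parse design: {exc}", path=str(path)) from exc
    if states is None:
        # preserve order of first appearance so the file is self-describing
        states = tuple(dict.fromkeys(table["state"])) if "state" in table else ()
    return SampleDesign(table=table, states=states)


def write_annotation_tsv(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    """Two-column TSV (gene_id, chromosome)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise ParseError(f"could not parse annotation: {exc}", path=str(path)) from exc
    if not {"gene_id", "chromosome"} <= set(df.columns):
        raise ParseError(
            f"annotation needs columns gene_id, chromosome; got {list(df.columns)}",
            path=str(path),
        )
    return df[["gene_id", "chromosome"]]


def read_annotation_gff3(path: str | Path) -> pd.DataFrame:
    """Minimal GFF3 support: chromosome = seqid of each ``gene`` feature.

    The gene identifier is taken from the ``ID`` attribute (``gene:`` prefix
    stripped) or, failing that, ``gene_id``.
    """
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"expected 9 GFF3 columns, got {len(fields)}", path=str(path), line=lineno
                )
            if fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if kv and "=" in kv
            )
            gene_id = attrs.get("ID", attrs.get("gene_id"))
            if gene_id is None:
                raise ParseError("gene feature lacks ID/gene_id", path=str(path), line=lineno)
            rows.append((gene_id.removeprefix("gene:"), fields[0]))
    return pd.DataFrame(rows, columns=["gene_id", "chromosome"])


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: one set per line — name, description, then member ids."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    "GMT line needs >= 3 tab-separated fields (name, description, members)",
                    path=str(path),
                    line=lineno,
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"duplicate gene-set name {name!r}", path=str(path), line=lineno)
            # deduplicate while keeping order
            sets[name] = list(dict.fromkeys(g for g in fields[2:] if g))
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "germdrift") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: list[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(g + "\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
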
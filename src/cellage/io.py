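"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices travel as dense TSV (genes x cells) or as Matrix Market
(.mtx) with gene/cell TSV sidecars; gene sets as GMT; rankings, labels, age
tables, homology tables and annotations as TSV.  All writers use a fixed
float format so reruns with the same seed are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from cellage.errors import CellageError
from cellage.profiles import NONSPECIFIC, GeneSetCatalog
from cellage.rankings import AgeRanking

FLOAT_FMT = "%.10g"


# -- expression ------------------------------------------------------------

def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FMT)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_expression_mtx(expr: pd.DataFrame, directory: str | Path) -> None:
    """Write expression as matrix.mtx + genes.tsv/cells.tsv sidecars."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(directory / "matrix.mtx", sparse.csr_matrix(expr.to_numpy()))
    pd.Series(expr.index, name="gene").to_csv(
        directory / "genes.tsv", sep="\t", index=False
    )
    pd.Series(expr.columns, name="cell_id").to_csv(
        directory / "cells.tsv", sep="\t", index=False
    )


def read_expression_mtx(directory: str | Path) -> pd.DataFrame:
    directory = Path(directory)
    matrix = spio.mmread(directory / "matrix.mtx").toarray()
    genes = pd.read_csv(directory / "genes.tsv", sep="\t")["gene"]
    cells = pd.read_csv(directory / "cells.tsv", sep="\t")["cell_id"]
    frame = pd.DataFrame(matrix, index=genes.tolist(), columns=cells.tolist())
    return frame.rename_axis("gene")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Dispatch on path: a directory means MTX + sidecars, a file dense TSV."""
    path = Path(path)
    return read_expression_mtx(path) if path.is_dir() else read_expression_tsv(path)


# -- labels ----------------------------------------------------------------

def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename("cell_type").to_csv(path, sep="\t", index_label="cell_id")


def read_labels(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t")
    if not {"cell_id", "cell_type"} <= set(frame.columns):
        raise CellageError("labels file needs 'cell_id' and 'cell_type' columns")
    return frame.set_index("cell_id")["cell_type"]


# -- age tables and rankings ----------------------------------------------

def write_age_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_age_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ranking(ranking: AgeRanking, path: str | Path) -> None:
    ranking.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_ranking(path: str | Path) -> AgeRanking:
    frame = pd.read_csv(path, sep="\t")
    if not {"gene", "score"} <= set(frame.columns):
        raise CellageError("ranking file needs 'gene' and 'score' columns")
    if "position" in frame.columns:
        frame = frame.sort_values("position", kind="stable")
    return AgeRanking(tuple(frame["gene"]), frame["score"].to_numpy(float))


# -- gene set catalogs (GMT) ----------------------------------------------

def write_gmt(catalog: GeneSetCatalog, path: str | Path) -> None:
    """One line per set: name, description (records tau), tab-joined genes."""
    lines = []
    for name, genes in catalog.sets().items():
        description = f"tau={catalog.tau:g}"
        lines.append("\t".join([name, description, *sorted(genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> GeneSetCatalog:
    enriched: dict[str, frozenset[str]] = {}
    nonspecific: frozenset[str] = frozenset()
    tau = 2.0
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise CellageError(f"malformed GMT line: {line[:60]!r}")
        name, description, genes = fields[0], fields[1], frozenset(fields[2:])
        if description.startswith("tau="):
            tau = float(description[4:])
        if name == NONSPECIFIC:
            nonspecific = genes
        else:
            enriched[name] = genes
    return GeneSetCatalog(enriched, nonspecific, tau)


def read_gene_sets(path: str | Path) -> dict[str, frozenset[str]]:
    """Plain named sets from a GMT file (for fixed external set tests)."""
    out: dict[str, frozenset[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise CellageError(f"malformed GMT line: {line[:60]!r}")
        out[fields[0]] = frozenset(fields[2:])
    return out


# -- homology --------------------------------------------------------------

def read_homology_table(path: str | Path) -> pd.DataFrame:
    """Either a Homologene-dialect 3-column or a flattened 2-column table."""
    frame = pd.read_csv(path, sep="\t")
    if {"homology_group_id", "taxon", "symbol"} <= set(frame.columns):
        return frame
    if frame.shape[1] >= 2:
        return frame.iloc[:, :2]
    raise CellageError(
        "homology table must have (homology_group_id, taxon, symbol) or two"
        " (mouse, human) columns"
    )


def write_homology_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


# -- annotations -----------------------------------------------------------

_GAF_ASPECTS = {"P": "biological_process", "F": "molecular_function",
                "C": "cellular_component"}


def read_annotations(path: str | Path) -> pd.DataFrame:
    """TSV with (gene, term_id[, term_name[, domain]]) columns, or GAF 2.x."""
    path = Path(path)
    first = ""
    with open(path) as handle:
        for line in handle:
            if not line.startswith("!"):
                first = line
                break
    if first.startswith("!gaf") or "\tGO:" in first and "gene" not in first:
        return _read_gaf(path)
    frame = pd.read_csv(path, sep="\t", comment="!")
    if not {"gene", "term_id"} <= set(frame.columns):
        raise CellageError("annotations need 'gene' and 'term_id' columns")
    return frame.drop_duplicates(subset=["gene", "term_id"])


def _read_gaf(path: Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="!", header=None, dtype=str)
    if frame.shape[1] < 9:
        raise CellageError("GAF file has fewer than 9 columns")
    out = pd.DataFrame(
        {
            "gene": frame.iloc[:, 2],
            "term_id": frame.iloc[:, 4],
            "term_name": "",
            "domain": frame.iloc[:, 8].map(_GAF_ASPECTS).fillna(""),
        }
    )
    return out.drop_duplicates(subset=["gene", "term_id"])


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations.to_csv(path, sep="\t", index=False)


# -- generic results -------------------------------------------------------

def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
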
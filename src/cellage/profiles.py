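"""Cell-type expression profiles and threshold-derived gene sets.

The transformation chain is: remove all-zero genes, standardize
``log(x + 1)`` per gene across all cells, average the standardized values
within each cell type, and call a gene *enriched* in a type when its average
standardized expression exceeds a threshold (default 2) and *non-specific*
when its absolute average stays below the threshold in every type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from cellage.errors import CellageError

log = logging.getLogger(__name__)

#: reserved set name for genes without clear enrichment in any type
NONSPECIFIC = "nonspecific"


def _validate_expression(expr: pd.DataFrame) -> None:
    if expr.index.has_duplicates:
        raise CellageError("duplicate gene symbols in expression matrix")
    if expr.columns.has_duplicates:
        raise CellageError("duplicate cell ids in expression matrix")
    values = expr.to_numpy(float)
    if not np.all(np.isfinite(values)):
        raise CellageError("expression matrix contains non-finite values")
    if np.any(values < 0):
        raise CellageError("expression matrix contains negative values")


@dataclass(frozen=True)
class ZMatrix:
    """Standardized log-expression, gene x cell.

    ``constant_genes`` flags genes whose log values were identical across all
    cells; their rows are set to zero rather than dropped so the gene universe
    stays aligned across pipeline stages.
    """

    values: pd.DataFrame
    constant_genes: frozenset[str] = frozenset()


@dataclass(frozen=True)
class CellTypeProfile:
    """Average standardized expression, gene x type, plus per-type cell counts."""

    values: pd.DataFrame
    cell_counts: pd.Series = field(repr=False)


@dataclass(frozen=True)
class GeneSetCatalog:
    """One enriched gene set per cell type plus the non-specific set."""

    enriched: dict[str, frozenset[str]]
    nonspecific: frozenset[str]
    tau: float = 2.0

    def __post_init__(self) -> None:
        if NONSPECIFIC in self.enriched:
            raise CellageError(
                f"cell-type label {NONSPECIFIC!r} collides with the reserved"
                " non-specific set name"
            )
        union = set().union(*self.enriched.values()) if self.enriched else set()
        if self.nonspecific & union:
            raise CellageError("non-specific set overlaps an enriched set")

    def sets(self) -> dict[str, frozenset[str]]:
        """All sets keyed by name, the non-specific set last."""
        out = dict(self.enriched)
        out[NONSPECIFIC] = self.nonspecific
        return out


def filter_zero_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Drop genes with zero values in every cell.

    Raises if nothing remains (there would be nothing to analyze).
    """
    _validate_expression(expr)
    keep = (expr.to_numpy(float) > 0).any(axis=1)
    removed = int((~keep).sum())
    if removed:
        log.info("filter_zero_genes: removed %d all-zero gene(s)", removed)
    if not keep.any():
        raise CellageError("all genes are zero across all cells")
    return expr.loc[keep]


def standardize(expr: pd.DataFrame, *, ddof: int = 1) -> ZMatrix:
    """Standardize ``log(x + 1)`` per gene across all cells.

    Natural log; sample (n-1) standard deviation by default.  Genes whose log
    values are constant across cells get a zero row and are flagged.  Both
    conventions (log base, SD denominator) are scale decisions only -- the
    log base cancels in the z-score and the denominator is configurable via
    ``ddof``.
    """
    _validate_expression(expr)
    if expr.shape[1] < 2:
        raise CellageError("standardization requires at least 2 cells")
    logged = np.log1p(expr.to_numpy(float))
    mean = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, ddof=ddof, keepdims=True)
    constant = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    sd[constant] = 1.0
    z = (logged - mean) / sd
    z[constant] = 0.0
    flagged = frozenset(expr.index[constant])
    if flagged:
        log.info("standardize: %d constant gene(s) set to z=0", len(flagged))
    return ZMatrix(pd.DataFrame(z, index=expr.index, columns=expr.columns), flagged)


def _labels_for(z: ZMatrix, ann: Mapping[str, str] | pd.Series) -> pd.Series:
    labels = pd.Series(dict(ann)) if not isinstance(ann, pd.Series) else ann
    cells = z.values.columns
    missing = set(cells) - set(labels.index)
    if missing:
        raise CellageError(
            f"{len(missing)} cell(s) have no cell-type label, e.g. "
            f"{sorted(missing)[0]!r}"
        )
    extra = set(labels.index) - set(cells)
    if extra:
        log.warning(
            "type_profile: dropping %d labeled cell(s) absent from the matrix",
            len(extra),
        )
    return labels.loc[cells]


def type_profile(z: ZMatrix, ann: Mapping[str, str] | pd.Series) -> CellTypeProfile:
    """Average standardized expression per cell type.

    Column order is lexicographic by label.  Labels with zero cells in the
    matrix are dropped with a warning.
    """
    labels = _labels_for(z, ann)
    types = sorted(labels.unique())
    values = z.values.to_numpy(float)
    cols = {}
    counts = {}
    for t in types:
        mask = (labels == t).to_numpy()
        n = int(mask.sum())
        if n == 0:  # pragma: no cover - unreachable via unique(), kept for clarity
            log.warning("type_profile: label %r has zero cells, dropped", t)
            continue
        cols[t] = values[:, mask].mean(axis=1)
        counts[t] = n
    profile = pd.DataFrame(cols, index=z.values.index)
    return CellTypeProfile(profile, pd.Series(counts))


def derive_gene_sets(profile: CellTypeProfile, tau: float = 2.0) -> GeneSetCatalog:
    """Threshold the profile into enriched and non-specific gene sets.

    Strict inequalities on both sides: a gene is enriched in type ``c`` when
    its average standardized expression there is ``> tau`` and non-specific
    when its absolute average is ``< tau`` in every type.  Genes can belong
    to several enriched sets, or to neither category.
    """
    if tau <= 0:
        raise CellageError("tau must be positive")
    values = profile.values
    if values.empty:
        raise CellageError("empty cell-type profile")
    enriched = {}
    for t in values.columns:
        members = frozenset(values.index[values[t].to_numpy() > tau])
        if not members:
            log.info("derive_gene_sets: no enriched genes for type %r", t)
        enriched[t] = members
    nonspecific = frozenset(
        values.index[(np.abs(values.to_numpy()) < tau).all(axis=1)]
    )
    if not nonspecific:
        log.info("derive_gene_sets: non-specific set is empty")
    return GeneSetCatalog(enriched, nonspecific, float(tau))
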
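"""Signed age-association gene rankings.

A ranking is a total order over genes from the most significantly
age-up-regulated (position 1) to the most significantly down-regulated
(position N).  Each gene carries a signed score ``s = sign * (-log10 p)``
with ``up -> +`` and ``down -> -``; the order is non-increasing in ``s``.
Genes with equal ``(p, direction)`` form a tie group; their stored order is
lexicographic by symbol, and all downstream statistics use midranks so the
within-tie order never affects results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from cellage.errors import CellageError

log = logging.getLogger(__name__)

DIRECTIONS = frozenset({"up", "down"})


@dataclass(frozen=True)
class AgeRanking:
    """Ordered gene list with signed scores (up end first)."""

    genes: tuple[str, ...]
    scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if len(self.genes) != len(scores):
            raise CellageError("genes and scores must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise CellageError("duplicate genes in ranking")
        if len(scores) > 1 and np.any(np.diff(scores) > 1e-12):
            raise CellageError("scores must be non-increasing along the ranking")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def positions(self) -> pd.Series:
        """1-based position per gene (1 = most up-regulated)."""
        return pd.Series(np.arange(1, len(self) + 1), index=list(self.genes))

    def rank_values(self) -> np.ndarray:
        """Midranks of the signed scores; the up end gets the largest values.

        Aligned with :attr:`genes`.  Used by AUROC/Mann-Whitney statistics so
        tie groups receive half credit.
        """
        return stats.rankdata(self.scores)

    def score_series(self) -> pd.Series:
        return pd.Series(self.scores, index=list(self.genes))

    def subset(self, genes: Iterable[str]) -> "AgeRanking":
        """Restrict to ``genes``, preserving relative order."""
        keep = set(genes)
        mask = np.fromiter((g in keep for g in self.genes), bool, len(self))
        return AgeRanking(
            tuple(g for g, m in zip(self.genes, mask) if m), self.scores[mask]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, len(self) + 1),
                "gene": list(self.genes),
                "score": self.scores,
            }
        )


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"gene", "p", "direction"}
    missing = required - set(table.columns)
    if missing:
        raise CellageError(f"age table missing columns: {sorted(missing)}")
    dup = table["gene"][table["gene"].duplicated()]
    if len(dup):
        raise CellageError(f"duplicate gene in age table: {dup.iloc[0]!r}")
    p = table["p"].to_numpy(float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        bad = table["gene"].iloc[int(np.argmax((p <= 0) | (p > 1) | ~np.isfinite(p)))]
        raise CellageError(f"p-value out of (0, 1] for gene {bad!r}")
    bad_dir = set(table["direction"]) - DIRECTIONS
    if bad_dir:
        raise CellageError(f"unknown direction value(s): {sorted(bad_dir)}")
    return table


def build_signed_ranking(table: pd.DataFrame) -> AgeRanking:
    """Order genes from up-regulated (ascending p) to down-regulated
    (descending p).

    The signed score is ``-log10(p)`` for up genes and ``log10(p)`` for down
    genes; ``p = 1`` maps to score 0 for either direction, so such genes sit
    in a single tie group at the up/down boundary.  Ties are stored in
    lexicographic gene order.
    """
    table = _validate_table(table)
    p = table["p"].to_numpy(float)
    sign = np.where(table["direction"].to_numpy() == "up", 1.0, -1.0)
    score = sign * (-np.log10(p))
    # -0.0 would break the tie-group equality at p == 1
    score[score == 0] = 0.0
    order = np.lexsort((table["gene"].to_numpy(), -score))
    return AgeRanking(tuple(table["gene"].to_numpy()[order]), score[order])


def merge_directional(
    up_table: pd.DataFrame, down_table: pd.DataFrame
) -> pd.DataFrame:
    """Merge per-direction association tables, keeping each gene's lower p.

    Input tables have columns ``gene`` and ``p``; the output has
    ``(gene, p, direction)`` rows.  Genes present in only one table pass
    through.  Genes with an exact p tie between directions cannot be assigned
    a direction and are excluded (counted in the log).
    """
    up = up_table.set_index("gene")["p"]
    down = down_table.set_index("gene")["p"]
    if up.index.has_duplicates or down.index.has_duplicates:
        raise CellageError("duplicate gene within a directional table")
    rows = []
    ties = 0
    for gene in sorted(set(up.index) | set(down.index)):
        pu = up.get(gene)
        pd_ = down.get(gene)
        if pu is None:
            rows.append((gene, pd_, "down"))
        elif pd_ is None:
            rows.append((gene, pu, "up"))
        elif pu < pd_:
            rows.append((gene, pu, "up"))
        elif pd_ < pu:
            rows.append((gene, pd_, "down"))
        else:
            ties += 1
    if ties:
        log.warning("merge_directional: excluded %d gene(s) with exact p ties", ties)
    return pd.DataFrame(rows, columns=["gene", "p", "direction"])


def spearman_compare(r1: AgeRanking, r2: AgeRanking) -> tuple[float, int]:
    """Spearman correlation of ranking positions over the common genes.

    Midranks are used for ties.  Returns ``(rho, n_common)``.
    """
    common = sorted(set(r1.genes) & set(r2.genes))
    if len(common) < 3:
        raise CellageError(
            f"need at least 3 common genes to compare rankings, got {len(common)}"
        )
    s1 = r1.score_series().loc[common].to_numpy()
    s2 = r2.score_series().loc[common].to_numpy()
    # positions are anti-monotone in score for both rankings, so the rho of
    # positions equals the rho of scores
    rho = float(stats.spearmanr(s1, s2).statistic)
    return rho, len(common)
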
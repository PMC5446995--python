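"""Functional-annotation dissection within cell-type enriched gene sets.

Each cell-type set (and the non-specific set) is turned into a sub-ranking
by restricting the age ranking to the set's genes; annotation terms whose
intersection with the sub-ranking is strictly between the size bounds are
scored by AUROC and a two-sided Mann-Whitney p.  Benjamini-Hochberg FDR is
applied once across all performed (set x term) tests jointly.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from cellage.enrichment import auroc, mw_pvalue
from cellage.errors import CellageError
from cellage.profiles import GeneSetCatalog
from cellage.rankings import AgeRanking

log = logging.getLogger(__name__)


def within_set_ranking(gene_set: Iterable[str], ranking: AgeRanking) -> AgeRanking:
    """Sub-ranking containing exactly the set's genes, order preserved."""
    sub = ranking.subset(gene_set)
    if len(sub) < 2:
        raise CellageError(
            f"set shares only {len(sub)} gene(s) with the ranking; need >= 2"
        )
    return sub


def go_auroc_scan(
    catalog: GeneSetCatalog,
    ranking: AgeRanking,
    annotations: pd.DataFrame,
    size_bounds: tuple[int, int] = (10, 200),
) -> pd.DataFrame:
    """Scan every (cell-type set, annotation term) combination.

    ``annotations`` needs columns ``gene`` and ``term_id`` (``term_name``
    optional).  A term is tested within a set only when the three-way
    intersection size ``n`` satisfies ``lo < n < hi`` strictly; AUROC and the
    Mann-Whitney p are computed within the set's sub-ranking, so genes
    outside the set can never influence a row.  The result is sorted by q
    then p.
    """
    lo, hi = size_bounds
    if lo >= hi:
        raise CellageError(f"size_bounds inverted or empty: {size_bounds}")
    required = {"gene", "term_id"}
    if required - set(annotations.columns):
        raise CellageError("annotations need 'gene' and 'term_id' columns")
    ann = annotations.drop_duplicates(subset=["gene", "term_id"])
    names = (
        ann.drop_duplicates("term_id").set_index("term_id").get("term_name")
        if "term_name" in ann.columns
        else None
    )
    term_genes = {
        term: set(group["gene"]) for term, group in ann.groupby("term_id")
    }
    rows = []
    for set_name, genes in catalog.sets().items():
        present = set(genes) & set(ranking.genes)
        if len(present) < 2:
            log.info("go_auroc_scan: skipping %r (fewer than 2 ranked genes)", set_name)
            continue
        sub = within_set_ranking(present, ranking)
        for term, tg in term_genes.items():
            members = tg & present
            n = len(members)
            if not (lo < n < hi) or n == len(sub):
                continue
            rows.append(
                (
                    set_name,
                    term,
                    names.get(term, "") if names is not None else "",
                    n,
                    auroc(members, sub),
                    mw_pvalue(members, sub),
                )
            )
    columns = ["set", "term_id", "term_name", "n_genes", "auroc", "p"]
    if not rows:
        log.warning("go_auroc_scan: no (set, term) pair passed the size filter")
        return pd.DataFrame(columns=columns + ["q"])
    out = pd.DataFrame(rows, columns=columns)
    out["q"] = stats.false_discovery_control(out["p"].to_numpy(), method="bh")
    return out.sort_values(["q", "p"], kind="stable").reset_index(drop=True)
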
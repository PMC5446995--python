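"""Mouse-to-human ortholog mapping of gene sets and ranking backgrounds.

Raw homology tables may be many-to-many; only pairs that are one-to-one in
both directions after filtering are retained, preventing set inflation.
Symbol comparison is case-sensitive after whitespace trimming -- mouse
(Title-case) and human (UPPER-case) conventions must be explicit in the map.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from cellage.errors import CellageError
from cellage.profiles import GeneSetCatalog
from cellage.rankings import AgeRanking

log = logging.getLogger(__name__)

MOUSE_TAXON = 10090
HUMAN_TAXON = 9606


def _one_to_one(pairs: list[tuple[str, str]]) -> tuple[dict[str, str], int]:
    """Keep only pairs whose mouse and human symbols each occur once."""
    mouse_counts = Counter(m for m, _ in pairs)
    human_counts = Counter(h for _, h in pairs)
    kept = {
        m: h
        for m, h in pairs
        if mouse_counts[m] == 1 and human_counts[h] == 1
    }
    return kept, len(pairs) - len(kept)


@dataclass(frozen=True)
class OrthologMap:
    """One-to-one mouse -> human symbol map."""

    mouse_to_human: dict[str, str]
    n_dropped_pairs: int = 0
    human_symbols: frozenset[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "human_symbols", frozenset(self.mouse_to_human.values())
        )
        if len(self.human_symbols) != len(self.mouse_to_human):
            raise CellageError("ortholog map is not one-to-one")

    def __len__(self) -> int:
        return len(self.mouse_to_human)

    @classmethod
    def from_pairs(cls, table: pd.DataFrame) -> "OrthologMap":
        """Build from a two-column (mouse, human) table, filtering to 1:1."""
        mouse = table.iloc[:, 0].astype(str).str.strip()
        human = table.iloc[:, 1].astype(str).str.strip()
        pairs = list(dict.fromkeys(zip(mouse, human)))  # dedupe, keep order
        kept, dropped = _one_to_one(pairs)
        if dropped:
            log.warning(
                "OrthologMap: dropped %d non-1:1 pair(s) of %d", dropped, len(pairs)
            )
        return cls(kept, dropped)

    @classmethod
    def from_homologene(
        cls,
        table: pd.DataFrame,
        mouse_taxon: int = MOUSE_TAXON,
        human_taxon: int = HUMAN_TAXON,
    ) -> "OrthologMap":
        """Build from a (homology_group_id, taxon, symbol) table.

        A group contributes a pair only when it holds exactly one mouse and
        one human symbol; the flattened pairs are then filtered to global 1:1.
        """
        required = {"homology_group_id", "taxon", "symbol"}
        missing = required - set(table.columns)
        if missing:
            raise CellageError(f"homology table missing columns: {sorted(missing)}")
        pairs = []
        dropped_groups = 0
        for _, group in table.groupby("homology_group_id"):
            mouse = group.loc[group["taxon"] == mouse_taxon, "symbol"]
            human = group.loc[group["taxon"] == human_taxon, "symbol"]
            if len(mouse) == 1 and len(human) == 1:
                pairs.append((mouse.iloc[0].strip(), human.iloc[0].strip()))
            else:
                dropped_groups += 1
        kept, dropped = _one_to_one(pairs)
        if dropped_groups or dropped:
            log.warning(
                "OrthologMap: dropped %d non-1:1 group(s) and %d ambiguous pair(s)",
                dropped_groups,
                dropped,
            )
        return cls(kept, dropped + dropped_groups)

    @classmethod
    def identity(cls, genes: Iterable[str]) -> "OrthologMap":
        """Identity map over ``genes`` (synthetic-data default)."""
        return cls({g: g for g in genes})


def map_sets(catalog: GeneSetCatalog, omap: OrthologMap) -> GeneSetCatalog:
    """Convert every set in the catalog to human symbols.

    Unmapped genes are dropped (counted in the log); the threshold carries
    over unchanged.
    """
    if not omap.mouse_to_human:
        log.warning("map_sets: empty ortholog map, all sets become empty")
    m2h = omap.mouse_to_human
    dropped = 0

    def _map(genes: frozenset[str]) -> frozenset[str]:
        nonlocal dropped
        mapped = frozenset(m2h[g] for g in genes if g in m2h)
        dropped += len(genes) - len(mapped)
        return mapped

    enriched = {t: _map(genes) for t, genes in catalog.enriched.items()}
    nonspecific = _map(catalog.nonspecific)
    if dropped:
        log.info("map_sets: dropped %d unmapped gene(s) across all sets", dropped)
    return GeneSetCatalog(enriched, nonspecific, catalog.tau)


def restrict_ranking(ranking: AgeRanking, omap: OrthologMap) -> AgeRanking:
    """Keep only ranking genes whose human symbol appears in the map.

    Relative order is preserved.  Raises when nothing remains.
    """
    restricted = ranking.subset(omap.human_symbols)
    if len(restricted) == 0:
        raise CellageError("no ranking gene has an ortholog mapping")
    removed = len(ranking) - len(restricted)
    if removed:
        log.info("restrict_ranking: removed %d unmapped gene(s)", removed)
    return restricted
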
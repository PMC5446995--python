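"""AUROC gene-set scoring, label-permutation null and empirical min-p FDR.

The enrichment statistic for a gene set within a signed age ranking is the
AUROC: the probability that a set member ranks closer to the up-regulated
end than a non-member (Mann-Whitney U / (n1*n2), midranks for ties).

Significance is assessed against an empirical null built by shuffling the
cell -> cell-type assignment B times and rerunning the whole set-derivation
chain (profile averaging, thresholding, ortholog mapping, AUROC) per
shuffle, so the permuted gene sets have emergent sizes.  This controls for
baseline AUROC inflation that analytic rank tests cannot see: when broadly
expressed genes shift together in the ranking, threshold-derived sets score
away from 0.5 even for random labels.

Per-type p-values measure how often a shuffle's AUROC deviates from the
permuted mean at least as far as the observed one, floored at 1/B.  The
q-value is an empirical min-p FDR: the fraction of shuffles in which at
least one type attains an equal or lower p-value within its own null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from cellage.errors import CellageError
from cellage.orthology import OrthologMap, map_sets
from cellage.profiles import (
    NONSPECIFIC,
    GeneSetCatalog,
    ZMatrix,
    derive_gene_sets,
    type_profile,
)
from cellage.rankings import AgeRanking

log = logging.getLogger(__name__)


def _member_mask(gene_set: Iterable[str], ranking: AgeRanking) -> np.ndarray:
    members = set(gene_set)
    mask = np.fromiter((g in members for g in ranking.genes), bool, len(ranking))
    absent = len(members) - int(mask.sum())
    if absent:
        log.debug("%d set gene(s) absent from the ranking, dropped", absent)
    return mask


def _check_proper(mask: np.ndarray) -> None:
    n1 = int(mask.sum())
    if n1 == 0:
        raise CellageError("no set member is present in the ranking")
    if n1 == len(mask):
        raise CellageError("set covers the entire ranking; complement is empty")


def auroc(gene_set: Iterable[str], ranking: AgeRanking) -> float:
    """Probability that a set member outranks a non-member toward the up end.

    Computed as Mann-Whitney U / (n1*n2) on the ranking's midranks; ties
    contribute half.  Values above 0.5 mean the set is shifted toward
    age-up-regulation.  Set members absent from the ranking are dropped
    first.
    """
    mask = _member_mask(gene_set, ranking)
    _check_proper(mask)
    rv = ranking.rank_values()
    n1 = int(mask.sum())
    n2 = len(mask) - n1
    u = rv[mask].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def mw_pvalue(
    gene_set: Iterable[str], ranking: AgeRanking, sides: str = "two"
) -> float:
    """Normal-approximation Mann-Whitney p-value for the set's rank shift.

    Tie and continuity corrections applied.  ``sides`` is ``"two"`` (default)
    or ``"one"`` (tests the side the observed AUROC leans toward).
    """
    mask = _member_mask(gene_set, ranking)
    _check_proper(mask)
    rv = ranking.rank_values()
    x, y = rv[mask], rv[~mask]
    if sides == "two":
        alternative = "two-sided"
    elif sides == "one":
        alternative = "greater" if x.mean() >= y.mean() else "less"
    else:
        raise CellageError(f"sides must be 'one' or 'two', got {sides!r}")
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return float(min(max(res.pvalue, np.nextafter(0, 1)), 1.0))


@dataclass(frozen=True)
class PermutationNull:
    """AUROCs of threshold-derived sets under B label shuffles.

    ``aurocs`` is a B x (types + non-specific) frame; NaN marks a shuffle
    whose derived set was empty (or covered the whole ranking).
    """

    aurocs: pd.DataFrame
    seed: int
    B: int

    def __post_init__(self) -> None:
        values = self.aurocs.to_numpy(float)
        with np.errstate(invalid="ignore"):
            if np.any((values < 0) | (values > 1)):
                raise CellageError("permuted AUROC outside [0, 1]")


def permuted_labels(ann: pd.Series, seed: int, b: int, B: int) -> pd.Series:
    """The b-th shuffled cell -> type assignment of a B-shuffle null.

    A single master seed spawns one substream per shuffle, so any shuffle can
    be reproduced independently (and the loop parallelized) with identical
    results.
    """
    ss = np.random.SeedSequence(seed).spawn(B)[b]
    perm = np.random.default_rng(ss).permutation(len(ann))
    return pd.Series(ann.to_numpy()[perm], index=ann.index, name=ann.name)


def _ranking_lookup(
    genes: pd.Index, ranking: AgeRanking, omap: OrthologMap | None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene midrank of the mapped symbol in the ranking (0 if absent)."""
    rv = ranking.rank_values()
    by_symbol = dict(zip(ranking.genes, rv))
    if omap is None:
        mapped = list(genes)
    else:
        mapped = [omap.mouse_to_human.get(g) for g in genes]
    r_filled = np.array([by_symbol.get(h, 0.0) if h else 0.0 for h in mapped])
    present = (r_filled > 0).astype(float)
    return r_filled, present


def _set_aurocs_from_masks(
    masks: np.ndarray, r_filled: np.ndarray, present: np.ndarray, n_rank: int
) -> np.ndarray:
    """AUROC per mask column; NaN for empty/improper sets."""
    n1 = present @ masks
    sum_r = r_filled @ masks
    n2 = n_rank - n1
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (sum_r - n1 * (n1 + 1) / 2.0) / (n1 * n2)
    out[(n1 == 0) | (n2 == 0)] = np.nan
    return out


def permutation_null(
    z: ZMatrix,
    ann: pd.Series,
    ranking: AgeRanking,
    omap: OrthologMap | None = None,
    *,
    tau: float = 2.0,
    B: int = 10_000,
    seed: int = 0,
) -> PermutationNull:
    """Build the label-permutation null for all derived sets at once.

    For each of ``B`` seeded shuffles of the cell -> type assignment the
    profile, the enriched sets, the non-specific set and the ortholog-mapped
    AUROCs against the (already restricted) ranking are recomputed; set sizes
    are emergent per shuffle.  The fast path below is algebraically identical
    to composing ``type_profile`` -> ``derive_gene_sets`` -> ``map_sets`` ->
    ``auroc`` (a dedicated test asserts the equivalence).
    """
    if B < 1:
        raise CellageError("B must be at least 1")
    labels = ann.loc[z.values.columns]
    types = sorted(labels.unique())
    type_index = {t: i for i, t in enumerate(types)}
    label_idx = labels.map(type_index).to_numpy()
    zz = z.values.to_numpy(float)
    n_genes, n_cells = zz.shape
    counts = np.bincount(label_idx, minlength=len(types)).astype(float)

    r_filled, present = _ranking_lookup(z.values.index, ranking, omap)
    n_rank = len(ranking)
    eye = np.eye(len(types))
    out = np.empty((B, len(types) + 1))
    streams = np.random.SeedSequence(seed).spawn(B)
    for b in range(B):
        rng = np.random.default_rng(streams[b])
        idx = label_idx[rng.permutation(n_cells)]
        zbar = (zz @ eye[idx]) / counts
        masks = np.empty((n_genes, len(types) + 1))
        np.greater(zbar, tau, out=masks[:, :-1])
        masks[:, -1] = (np.abs(zbar) < tau).all(axis=1)
        out[b] = _set_aurocs_from_masks(masks, r_filled, present, n_rank)
    frame = pd.DataFrame(out, columns=types + [NONSPECIFIC])
    n_missing = int(frame.isna().to_numpy().sum())
    if n_missing:
        log.info(
            "permutation_null: %d empty derived set(s) across %d shuffles",
            n_missing,
            B,
        )
    return PermutationNull(frame, seed, B)


def observed_aurocs(
    catalog: GeneSetCatalog, ranking: AgeRanking
) -> pd.Series:
    """AUROC of every catalog set (non-specific included) in the ranking.

    Sets with no gene in the ranking get NaN with a warning.
    """
    values = {}
    for name, genes in catalog.sets().items():
        try:
            values[name] = auroc(genes, ranking)
        except CellageError as exc:
            log.warning("observed_aurocs: %s -> NaN (%s)", name, exc)
            values[name] = np.nan
    return pd.Series(values)


def _tail_counts(sorted_vals: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(#{x >= v}, #{x <= v}) against the sorted sample."""
    ge = len(sorted_vals) - np.searchsorted(sorted_vals, v, side="left")
    le = np.searchsorted(sorted_vals, v, side="right")
    return ge, le


def empirical_pq(
    observed: pd.Series,
    null: PermutationNull,
    *,
    variant: str = "plugin",
    rule: str = "symmetric",
) -> pd.DataFrame:
    """Empirical p and min-p q per set.

    With the default ``rule="symmetric"``, the p-value for set ``c`` is the
    fraction of shuffles whose AUROC deviates from the permuted mean ``m_c``
    at least as far (in absolute value) as the observed AUROC does, floored
    at 1/B -- "larger or smaller relative to the average" read as a
    symmetric two-tailed extremeness measure, which is exactly calibrated
    under exchangeability.  ``rule="sided"`` instead counts only the side the
    observed value falls on (an exact tie with the mean takes the side with
    the larger p); this halves small p-values but doubles the type-I rate.

    ``q_c`` is the fraction of shuffles in which at least one set attains an
    equal-or-lower p within its own null, the per-shuffle p computed under
    the same rule ("plugin", Westfall-Young style; ``variant="loo"``
    excludes the shuffle itself from its own null).
    """
    if variant not in {"plugin", "loo"}:
        raise CellageError(f"unknown variant {variant!r}")
    if rule not in {"symmetric", "sided"}:
        raise CellageError(f"unknown rule {rule!r}")
    missing = set(observed.index) - set(null.aurocs.columns)
    if missing:
        raise CellageError(f"set(s) absent from the null: {sorted(missing)}")
    B = null.B
    cols = list(observed.index)
    p_obs = pd.Series(np.nan, index=cols)
    m_obs = pd.Series(np.nan, index=cols)
    inner = np.full((B, len(cols)), np.inf)
    for j, c in enumerate(cols):
        col = null.aurocs[c].to_numpy(float)
        valid = np.isfinite(col)
        b_c = int(valid.sum())
        obs = observed[c]
        if b_c == 0 or not np.isfinite(obs):
            log.warning("empirical_pq: no usable null or observation for %r", c)
            continue
        m = float(col[valid].mean())
        m_obs[c] = m
        if rule == "symmetric":
            dev = np.sort(np.abs(col[valid] - m))
            ge_obs, _ = _tail_counts(dev, np.array([abs(obs - m)]))
            p_obs[c] = max(int(ge_obs[0]), 1) / b_c
            ge_all, _ = _tail_counts(dev, np.abs(col[valid] - m))
            counts = ge_all
        else:
            vals = np.sort(col[valid])
            ge_obs, le_obs = _tail_counts(vals, np.array([obs]))
            p_ge = max(int(ge_obs[0]), 1) / b_c
            p_le = max(int(le_obs[0]), 1) / b_c
            if obs > m:
                side, p_obs[c] = "ge", p_ge
            elif obs < m:
                side, p_obs[c] = "le", p_le
            else:  # tie with the mean: conservative side
                side, p_obs[c] = ("ge", p_ge) if p_ge >= p_le else ("le", p_le)
            ge_all, le_all = _tail_counts(vals, col[valid])
            counts = ge_all if side == "ge" else le_all
        if variant == "plugin":
            inner[valid, j] = counts / b_c
        else:  # leave-one-out: the shuffle's own value is excluded
            if b_c < 2:
                continue
            inner[valid, j] = np.maximum(counts - 1, 1) / (b_c - 1)
    min_p = inner.min(axis=1)
    q_obs = pd.Series(
        [
            float((min_p <= p_obs[c]).sum()) / B if np.isfinite(p_obs[c]) else np.nan
            for c in cols
        ],
        index=cols,
    )
    return pd.DataFrame(
        {"permuted_auroc": m_obs, "p": p_obs, "q": q_obs}
    )


def fixed_set_test(
    sets: Mapping[str, Iterable[str]],
    ranking: AgeRanking,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Analytic AUROC + Mann-Whitney test for externally fixed gene sets.

    Each set is intersected with the ranking first; sets with an empty
    intersection are skipped with a warning and excluded from the Bonferroni
    family size ``m``.
    """
    if correction != "bonferroni":
        raise CellageError(f"unsupported correction {correction!r}")
    if not sets:
        raise CellageError("no gene sets supplied")
    rows = []
    for name, genes in sets.items():
        members = set(genes) & set(ranking.genes)
        if not members or len(members) == len(ranking):
            log.warning("fixed_set_test: skipping %r (empty effective set)", name)
            continue
        rows.append(
            (name, len(members), auroc(members, ranking), mw_pvalue(members, ranking))
        )
    if not rows:
        raise CellageError("no gene set overlaps the ranking")
    m = len(rows)
    frame = pd.DataFrame(rows, columns=["name", "n_genes", "auroc", "p"])
    frame["p_adj"] = np.minimum(1.0, m * frame["p"])
    return frame


def enrichment_analysis(
    z: ZMatrix,
    ann: pd.Series,
    ranking: AgeRanking,
    omap: OrthologMap | None = None,
    *,
    tau: float = 2.0,
    B: int = 10_000,
    seed: int = 0,
    variant: str = "plugin",
    rule: str = "symmetric",
) -> tuple[pd.DataFrame, PermutationNull]:
    """Full observed-vs-permuted enrichment table for one dataset pairing.

    Returns a frame indexed by set name with cell counts, effective gene
    counts, observed and permuted-mean AUROCs, empirical p and q, plus the
    permutation null itself.
    """
    profile = type_profile(z, ann)
    catalog = derive_gene_sets(profile, tau)
    if omap is not None:
        catalog = map_sets(catalog, omap)
    observed = observed_aurocs(catalog, ranking)
    null = permutation_null(z, ann, ranking, omap, tau=tau, B=B, seed=seed)
    pq = empirical_pq(observed, null, variant=variant, rule=rule)
    ranking_genes = set(ranking.genes)
    gene_counts = {
        name: len(set(genes) & ranking_genes)
        for name, genes in catalog.sets().items()
    }
    cell_counts = profile.cell_counts.reindex(observed.index)
    table = pd.DataFrame(
        {
            "cell_count": cell_counts,
            "gene_count": pd.Series(gene_counts).reindex(observed.index),
            "permuted_auroc": pq["permuted_auroc"],
            "auroc": observed,
            "p": pq["p"],
            "q": pq["q"],
        }
    )
    table.index.name = "set"
    return table.sort_values(["p", "q"]), null
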
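"""Synthetic single-cell matrices, age tables, homolog maps and annotations.

The generator plants the statistical structure the analysis assumes:

* cell-type structured expression with disjoint planted marker sets
  (log-normal model: latent log value = baseline + marker effect + Gaussian
  noise, exponentiated minus one and clipped at zero);
* a stratum of *stable* genes (moderate baseline, unit noise) that behave
  like broadly expressed housekeeping genes and form the ground-truth
  non-specific set;
* a stratum of *variable* genes with low baselines whose clipped expression
  is zero-inflated and heavy-tailed, so threshold-derived gene sets remain
  non-empty under label permutations (as in real single-cell data);
* age-association tables built from a per-gene standard-normal statistic
  with optional directional shifts for the planted sets and a global shift
  of the stable genes (which reproduces the inflated permuted-baseline
  phenomenon the empirical testing procedure corrects for).

All outputs are deterministic functions of the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from cellage.errors import ConfigError


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the synthetic generator; validated on construction."""

    n_types: int
    cells_per_type: int
    n_genes: int
    markers_per_type: int = 0
    marker_effect: float = 0.0
    noise_sd: float = 1.0
    injected_up_types: tuple[str, ...] = ()
    injected_down_types: tuple[str, ...] = ()
    set_shift: float = 0.0
    nonspecific_shift: float = 0.0
    seed: int = 0
    # structure of the non-marker gene population
    stable_fraction: float = 0.5
    marker_baseline_range: tuple[float, float] = (0.5, 2.0)
    stable_baseline_range: tuple[float, float] = (1.0, 3.0)
    variable_baseline_range: tuple[float, float] = (-6.0, -2.0)
    variable_noise_scale: float = 3.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "injected_up_types", tuple(self.injected_up_types)
        )
        object.__setattr__(
            self, "injected_down_types", tuple(self.injected_down_types)
        )
        for name in ("n_types", "cells_per_type", "n_genes"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        if self.markers_per_type < 0:
            raise ConfigError("markers_per_type must be non-negative")
        if self.markers_per_type * self.n_types > self.n_genes:
            raise ConfigError(
                "markers_per_type * n_types exceeds n_genes: planted marker"
                " sets must be disjoint"
            )
        if self.marker_effect < 0:
            raise ConfigError("marker_effect must be non-negative")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.set_shift < 0:
            raise ConfigError("set_shift must be non-negative")
        if not 0 <= self.stable_fraction <= 1:
            raise ConfigError("stable_fraction must lie in [0, 1]")
        if self.variable_noise_scale <= 0:
            raise ConfigError("variable_noise_scale must be positive")
        known = set(self.type_names)
        unknown = (set(self.injected_up_types) | set(self.injected_down_types)) - known
        if unknown:
            raise ConfigError(f"unknown injected type name(s): {sorted(unknown)}")

    @property
    def type_names(self) -> tuple[str, ...]:
        return tuple(f"T{i + 1:02d}" for i in range(self.n_types))


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: marker sets, stable genes and the full gene universe."""

    marker_map: dict[str, frozenset[str]]
    nonspecific_genes: frozenset[str]
    genes: tuple[str, ...] = ()
    ranking_stat: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t, members in self.marker_map.items():
            if seen & members:
                raise ConfigError(f"marker set for {t!r} overlaps another set")
            seen |= members
        if self.nonspecific_genes & seen:
            raise ConfigError("nonspecific_genes overlap a marker set")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "marker_map": {t: sorted(g) for t, g in self.marker_map.items()},
            "nonspecific_genes": sorted(self.nonspecific_genes),
            "genes": list(self.genes),
            "ranking_stat": self.ranking_stat,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            {t: frozenset(g) for t, g in payload["marker_map"].items()},
            frozenset(payload["nonspecific_genes"]),
            tuple(payload["genes"]),
            dict(payload.get("ranking_stat", {})),
        )


def _gene_names(n: int) -> list[str]:
    return [f"g{i + 1:05d}" for i in range(n)]


def _cell_names(n: int) -> list[str]:
    return [f"c{i + 1:05d}" for i in range(n)]


def simulate_single_cell(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Generate an expression matrix (genes x cells), labels and ground truth.

    Each planted marker gene's latent mean log expression is elevated by
    ``marker_effect`` in exactly one type.  Values are
    ``clip(exp(latent) - 1, 0)`` so low latent values truncate to zero --
    the clipping is what produces realistic zero inflation for low-baseline
    genes.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    genes = _gene_names(cfg.n_genes)
    n_cells = cfg.n_types * cfg.cells_per_type
    cells = _cell_names(n_cells)
    labels = pd.Series(
        np.repeat(cfg.type_names, cfg.cells_per_type), index=cells, name="cell_type"
    )

    n_marker = cfg.markers_per_type * cfg.n_types
    n_rest = cfg.n_genes - n_marker
    n_stable = int(round(n_rest * cfg.stable_fraction))

    baseline = np.empty(cfg.n_genes)
    baseline[:n_marker] = rng.uniform(*cfg.marker_baseline_range, size=n_marker)
    baseline[n_marker : n_marker + n_stable] = rng.uniform(
        *cfg.stable_baseline_range, size=n_stable
    )
    baseline[n_marker + n_stable :] = rng.uniform(
        *cfg.variable_baseline_range, size=n_rest - n_stable
    )

    noise_sd = np.full(cfg.n_genes, float(cfg.noise_sd))
    noise_sd[n_marker + n_stable :] *= cfg.variable_noise_scale
    latent = baseline[:, None] + noise_sd[:, None] * rng.normal(
        0.0, 1.0, size=(cfg.n_genes, n_cells)
    )
    marker_map: dict[str, frozenset[str]] = {}
    for i, t in enumerate(cfg.type_names):
        g0 = i * cfg.markers_per_type
        g1 = g0 + cfg.markers_per_type
        c0 = i * cfg.cells_per_type
        c1 = c0 + cfg.cells_per_type
        latent[g0:g1, c0:c1] += cfg.marker_effect
        marker_map[t] = frozenset(genes[g0:g1])

    expr = pd.DataFrame(
        np.clip(np.expm1(latent), 0.0, None), index=genes, columns=cells
    )
    truth = GroundTruth(
        marker_map,
        frozenset(genes[n_marker : n_marker + n_stable]),
        tuple(genes),
    )
    return expr, labels, truth


def simulate_age_table(
    truth: GroundTruth, cfg: SimulationConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate an age-association table of ``(gene, p, direction)`` rows.

    The per-gene statistic is standard normal, plus ``set_shift`` (signed per
    injected type) for planted marker genes and ``nonspecific_shift`` for the
    ground-truth stable genes; it is converted to a two-sided normal p-value
    and a direction.  Returns the table and a copy of the truth carrying the
    realized statistic.
    """
    if not truth.genes:
        raise ConfigError("ground truth has an empty gene universe")
    rng = np.random.default_rng([cfg.seed, 1])
    genes = list(truth.genes)
    index = {g: i for i, g in enumerate(genes)}
    stat = rng.standard_normal(len(genes))
    for t in cfg.injected_up_types:
        if t not in truth.marker_map:
            raise ConfigError(f"injected type {t!r} not present in ground truth")
        for g in truth.marker_map[t]:
            stat[index[g]] += cfg.set_shift
    for t in cfg.injected_down_types:
        if t not in truth.marker_map:
            raise ConfigError(f"injected type {t!r} not present in ground truth")
        for g in truth.marker_map[t]:
            stat[index[g]] -= cfg.set_shift
    for g in truth.nonspecific_genes:
        stat[index[g]] += cfg.nonspecific_shift

    p = np.clip(2.0 * stats.norm.sf(np.abs(stat)), 1e-300, 1.0)
    direction = np.where(stat > 0, "up", "down")
    table = pd.DataFrame({"gene": genes, "p": p, "direction": direction})
    realized = replace(truth, ranking_stat=dict(zip(genes, stat.tolist())))
    return table, realized


def simulate_go_annotations(
    genes: list[str],
    n_terms: int,
    size_range: tuple[int, int],
    seed: int = 0,
) -> pd.DataFrame:
    """Annotate uniform-random gene subsets to synthetic ontology terms.

    Each term receives a subset whose size is uniform over ``size_range``
    (inclusive).  Empty ``genes`` yields an empty table.
    """
    lo, hi = size_range
    if n_terms < 1:
        raise ConfigError("n_terms must be at least 1")
    if lo > hi:
        raise ConfigError(f"size_range is inverted: {size_range}")
    if genes and not (1 <= lo and hi <= len(genes)):
        raise ConfigError(f"size_range {size_range} outside [1, {len(genes)}]")
    columns = ["gene", "term_id", "term_name"]
    if not genes:
        return pd.DataFrame(columns=columns)
    rng = np.random.default_rng([seed, 2])
    rows = []
    for i in range(n_terms):
        term_id = f"SYN:{i + 1:07d}"
        term_name = f"synthetic term {i + 1}"
        size = int(rng.integers(lo, hi + 1))
        for g in sorted(rng.choice(genes, size=size, replace=False)):
            rows.append((g, term_id, term_name))
    return pd.DataFrame(rows, columns=columns)
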
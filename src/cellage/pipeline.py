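"""End-to-end orchestration: config validation, stage wiring, reports.

A run is configured by a YAML mapping with exactly one of a ``synthetic``
section (generator parameters) or an ``inputs`` section (paths to expression,
labels, age table(s), homology, annotations).  Every stage default (tau=2,
B=10,000, size bounds 10/200) is a named key.  Runs are deterministic for a
fixed seed and emit a machine-readable manifest accounting for every drop
and skip.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

import cellage
from cellage import io as cio
from cellage.enrichment import enrichment_analysis
from cellage.errors import CellageError, ConfigError
from cellage.go_scan import go_auroc_scan
from cellage.orthology import OrthologMap, map_sets, restrict_ranking
from cellage.profiles import (
    GeneSetCatalog,
    derive_gene_sets,
    filter_zero_genes,
    standardize,
    type_profile,
)
from cellage.rankings import AgeRanking, build_signed_ranking, spearman_compare
from cellage.synthetic import (
    SimulationConfig,
    simulate_age_table,
    simulate_go_annotations,
    simulate_single_cell,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    outdir: Path
    synthetic: SimulationConfig | None = None
    inputs: dict[str, str] = dc_field(default_factory=dict)
    tau: float = 2.0
    B: int = 10_000
    seed: int = 0
    size_bounds: tuple[int, int] = (10, 200)
    variant: str = "plugin"
    n_go_terms: int = 50
    go_size_range: tuple[int, int] = (5, 60)

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (not self.inputs):
            raise ConfigError(
                "exactly one of a 'synthetic' section or an 'inputs' section"
                " must be configured"
            )
        if self.B < 1:
            raise ConfigError("B must be at least 1")
        if self.tau <= 0:
            raise ConfigError("tau must be positive")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        synthetic = raw.pop("synthetic", None)
        if synthetic is not None:
            synthetic = SimulationConfig(**synthetic)
        known = {
            "outdir", "inputs", "tau", "B", "seed", "size_bounds", "variant",
            "n_go_terms", "go_size_range",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "outdir" not in raw:
            raise ConfigError("config requires an 'outdir' key")
        if "size_bounds" in raw:
            raw["size_bounds"] = tuple(raw["size_bounds"])
        if "go_size_range" in raw:
            raw["go_size_range"] = tuple(raw["go_size_range"])
        return cls(synthetic=synthetic, **raw)


def _load_inputs(cfg: RunConfig):
    """Returns (expr, labels, age_tables, omap, annotations)."""
    if cfg.synthetic is not None:
        expr, labels, truth = simulate_single_cell(cfg.synthetic)
        age_table, truth = simulate_age_table(truth, cfg.synthetic)
        omap = OrthologMap.identity(truth.genes)
        annotations = simulate_go_annotations(
            list(truth.genes), cfg.n_go_terms, cfg.go_size_range, cfg.synthetic.seed
        )
        return expr, labels, {"synthetic": age_table}, omap, annotations, truth
    paths = cfg.inputs
    required = {"expression", "labels", "age_tables"}
    missing = required - set(paths)
    if missing:
        raise ConfigError(f"inputs section missing: {sorted(missing)}")
    expr = cio.read_expression(paths["expression"])
    labels = cio.read_labels(paths["labels"])
    tables = paths["age_tables"]
    if isinstance(tables, str):
        tables = {"ranking": tables}
    age_tables = {name: cio.read_age_table(p) for name, p in tables.items()}
    if "homology" in paths:
        table = cio.read_homology_table(paths["homology"])
        if "homology_group_id" in table.columns:
            omap = OrthologMap.from_homologene(table)
        else:
            omap = OrthologMap.from_pairs(table)
    else:
        omap = OrthologMap.identity(expr.index)
    annotations = (
        cio.read_annotations(paths["annotations"])
        if "annotations" in paths
        else None
    )
    return expr, labels, age_tables, omap, annotations, None


def run_full_analysis(cfg: RunConfig) -> dict[str, Path]:
    """Execute every stage and write the result bundle under ``cfg.outdir``.

    Produces enrichment and annotation-scan TSVs per ranking, a ranking
    comparison TSV when several rankings are supplied, a report with ROC
    curve tables, and a JSON manifest with versions, parameters and all
    drop/skip counts.
    """
    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "cellage_version": cellage.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "python_version": platform.python_version(),
        "seed": cfg.seed,
        "tau": cfg.tau,
        "B": cfg.B,
        "size_bounds": list(cfg.size_bounds),
        "variant": cfg.variant,
        "counts": {},
    }
    expr, labels, age_tables, omap, annotations, truth = _load_inputs(cfg)
    if truth is not None:
        truth.to_json(outdir / "ground_truth.json")

    n_before = expr.shape[0]
    expr = filter_zero_genes(expr)
    manifest["counts"]["all_zero_genes_removed"] = n_before - expr.shape[0]
    z = standardize(expr)
    manifest["counts"]["constant_genes_flagged"] = len(z.constant_genes)
    profile = type_profile(z, labels)
    catalog = derive_gene_sets(profile, cfg.tau)
    mapped = map_sets(catalog, omap)
    manifest["counts"]["homology_pairs"] = len(omap)
    cio.write_table(
        profile.values.rename_axis("gene"), outdir / "profile.tsv", index=True
    )
    cio.write_gmt(mapped, outdir / "sets.gmt")

    rankings: dict[str, AgeRanking] = {}
    for name, table in age_tables.items():
        ranking = build_signed_ranking(table)
        n_full = len(ranking)
        ranking = restrict_ranking(ranking, omap)
        manifest["counts"][f"ranking_{name}_genes"] = len(ranking)
        manifest["counts"][f"ranking_{name}_unmapped_removed"] = n_full - len(ranking)
        rankings[name] = ranking
        cio.write_ranking(ranking, outdir / f"ranking_{name}.tsv")

    if len(rankings) > 1:
        rows = []
        names = sorted(rankings)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                rho, n_common = spearman_compare(rankings[a], rankings[b])
                rows.append((a, b, rho, n_common))
        cio.write_table(
            pd.DataFrame(rows, columns=["ranking_a", "ranking_b", "rho", "n_common"]),
            outdir / "ranking_comparison.tsv",
        )

    results: dict[str, pd.DataFrame] = {}
    scans: dict[str, pd.DataFrame] = {}
    for name, ranking in rankings.items():
        table, _null = enrichment_analysis(
            z, labels, ranking, omap,
            tau=cfg.tau, B=cfg.B, seed=cfg.seed, variant=cfg.variant,
        )
        results[name] = table
        cio.write_table(
            table.reset_index(), outdir / f"enrichment_{name}.tsv"
        )
        if annotations is not None and len(annotations):
            scan = go_auroc_scan(mapped, ranking, annotations, cfg.size_bounds)
            scans[name] = scan
            manifest["counts"][f"goscan_{name}_tests"] = len(scan)
            cio.write_table(scan, outdir / f"goscan_{name}.tsv")

    write_report(results, scans, mapped, rankings, outdir)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    paths = {p.name: p for p in sorted(outdir.iterdir())}
    log.info("run_full_analysis: wrote %d file(s) to %s", len(paths), outdir)
    return paths


def roc_curve_table(gene_set, ranking: AgeRanking) -> pd.DataFrame:
    """(false-positive fraction, true-positive fraction) pairs for one set.

    One point per score tie group plus the (0, 0) origin; the trapezoid area
    of the curve equals the midrank AUROC exactly.
    """
    members = set(gene_set)
    mask = np.fromiter((g in members for g in ranking.genes), bool, len(ranking))
    n1 = int(mask.sum())
    n2 = len(mask) - n1
    if n1 == 0 or n2 == 0:
        raise CellageError("ROC curve needs both members and non-members")
    scores = ranking.scores
    # walk tie groups from the up end (position 1)
    boundaries = np.flatnonzero(np.diff(scores) != 0) + 1
    edges = np.concatenate([[0], boundaries, [len(scores)]])
    tp = fp = 0
    rows = [(0.0, 0.0)]
    for lo, hi in zip(edges[:-1], edges[1:]):
        tp += int(mask[lo:hi].sum())
        fp += int(hi - lo) - int(mask[lo:hi].sum())
        rows.append((fp / n2, tp / n1))
    return pd.DataFrame(rows, columns=["fpr", "tpr"])


def write_report(
    results: dict[str, pd.DataFrame],
    scans: dict[str, pd.DataFrame],
    catalog: GeneSetCatalog,
    rankings: dict[str, AgeRanking],
    outdir: Path,
) -> Path:
    """Human-readable summary plus ROC-style curve tables per set."""
    outdir = Path(outdir)
    lines = ["# cellage run report", ""]
    if not results:
        lines.append("WARNING: no enrichment results were produced.")
        log.warning("write_report: empty results, writing stub report")
    curve_rows = []
    for name, table in results.items():
        lines.append(f"## Ranking: {name}")
        significant = table[table["q"] < 0.05]
        lines.append(f"significant sets (q < 0.05): {len(significant)}")
        for set_name, row in significant.iterrows():
            lines.append(
                f"  {set_name}: AUROC={row['auroc']:.3f} "
                f"(permuted {row['permuted_auroc']:.3f}), "
                f"p={row['p']:.4g}, q={row['q']:.4g}"
            )
        top = table.head(5)
        lines.append("top sets by p:")
        for set_name, row in top.iterrows():
            lines.append(
                f"  {set_name}: AUROC={row['auroc']:.3f}, p={row['p']:.4g},"
                f" q={row['q']:.4g}"
            )
        scan = scans.get(name)
        if scan is not None and len(scan):
            lines.append("top annotation rows:")
            for _, row in scan.head(5).iterrows():
                lines.append(
                    f"  {row['set']} x {row['term_id']}: n={row['n_genes']},"
                    f" AUROC={row['auroc']:.3f}, q={row['q']:.4g}"
                )
        lines.append("")
        ranking = rankings[name]
        ranked = set(ranking.genes)
        for set_name, genes in catalog.sets().items():
            effective = set(genes) & ranked
            if not effective or len(effective) == len(ranked):
                continue
            curve = roc_curve_table(effective, ranking)
            curve.insert(0, "set", set_name)
            curve.insert(0, "ranking", name)
            curve_rows.append(curve)
    report_path = outdir / "report.txt"
    report_path.write_text("\n".join(lines) + "\n")
    if curve_rows:
        cio.write_table(pd.concat(curve_rows), outdir / "curves.tsv")
    return report_path
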
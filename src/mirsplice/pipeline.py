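"""End-to-end pipeline driver: DE screen -> categorize -> targets -> splicing -> gels.

A :class:`PipelineConfig` collects every input path and tunable threshold
in one auditable place; defaults are the screening thresholds used
throughout (miRNA: raw p < 0.05, |log2FC| > 1; DEGs: adjusted p < 0.05,
log2FC > 1; splicing events: p < 0.05; mean reads > 10; top 3).
``run_pipeline`` chains the stages, writes every stage's output as a new
file and emits a manifest sufficient to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from mirsplice import de, gelstats, splicing, tableio, targets

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Input paths plus every tunable threshold and toggle."""

    counts: str = ""
    degs: str = ""
    db_a: str = ""
    db_b: str = ""
    db_c: str = ""
    ih_events: str = ""
    kd_events: str = ""
    bands: str = ""
    reporter: str = ""

    weeks: tuple = (1, 3, 5, 7)
    seed: int = 0

    mirna_p: float = 0.05
    mirna_lfc: float = 1.0
    mirna_use_adjusted: bool = False
    deg_padj: float = 0.05
    deg_lfc: float = 1.0
    as_p: float = 0.05
    min_mean_reads: float = 10.0
    top_k: int = 3
    alpha_norm: float = 0.05
    reads_side: str = "ih"  # "ih" | "both"
    signed_rank: bool = False
    t_equal_var: bool = True

    def __post_init__(self):
        object.__setattr__(self, "weeks", tuple(self.weeks))
        if not self.weeks:
            raise ValueError("weeks must be nonempty")
        for name in ("mirna_p", "mirna_lfc", "deg_padj", "deg_lfc", "as_p",
                     "min_mean_reads", "alpha_norm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "weeks" in raw:
            raw["weeks"] = tuple(raw["weeks"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _up_deg_sets(degs: pd.DataFrame, cfg: PipelineConfig) -> dict:
    out = {}
    for week in cfg.weeks:
        sub = degs[degs["week"] == week]
        mask = (sub["padj"] < cfg.deg_padj) & (sub["log2FC"] > cfg.deg_lfc)
        out[week] = set(sub.loc[mask, "gene"])
    return out


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every configured stage and write results plus a manifest.

    Stages without configured inputs are skipped.  Returns a dict of
    in-memory results keyed by stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    row_counts: dict = {}

    de_records = None
    if config.counts:
        counts = tableio.read_counts(config.counts)
        frames = []
        for week in config.weeks:
            logger.info("stage de: week %d", week)
            frames.append(de.compute_de(counts, week))
        de_records = pd.concat(frames, ignore_index=True)
        tableio.write_table(de_records, outdir / "de_results.tsv", "de_result")
        per_week_sig = {
            w: de.screen_significant(
                de_records[de_records["week"] == w],
                config.mirna_p, config.mirna_lfc, config.mirna_use_adjusted,
            )
            for w in config.weeks
        }
        categories = de.categorize_temporal(per_week_sig, de_records)
        cat_out = categories.copy()
        cat_out["direction_consistent"] = cat_out["direction_consistent"].astype(str)
        tableio.write_table(cat_out, outdir / "categories.tsv", "category")
        results["de"] = de_records
        results["categories"] = categories
        row_counts["de"] = len(de_records)
        row_counts["categories"] = len(categories)

    if config.degs and config.db_a and "categories" in results:
        logger.info("stage targets")
        degs = tableio.read_table(config.degs, "deg")
        dbs = {
            db_id: tableio.read_table(path, "target_db")
            for db_id, path in (("A", config.db_a), ("B", config.db_b), ("C", config.db_c))
        }
        up_sets = _up_deg_sets(degs, config)
        target_tbl, shared_tbl = targets.target_screen(dbs, results["categories"], up_sets)
        target_tbl.to_csv(outdir / "predicted_targets.tsv", sep="\t", index=False)
        shared_tbl.to_csv(outdir / "shared_targets.tsv", sep="\t", index=False)
        results["targets"] = target_tbl
        results["shared_targets"] = shared_tbl
        row_counts["targets"] = len(target_tbl)
        row_counts["shared_targets"] = len(shared_tbl)

    if config.ih_events and config.kd_events:
        logger.info("stage as-screen")
        ih = tableio.read_table(config.ih_events, "event")
        kd = tableio.read_table(config.kd_events, "event")
        screen = splicing.as_screen(
            ih, kd, config.as_p, config.min_mean_reads, config.top_k,
            reads_side=config.reads_side, signed=config.signed_rank,
        )
        overlap_rows = [
            (etype, len(genes), ";".join(sorted(genes)))
            for etype, genes in sorted(screen["gene_overlap"].items())
        ]
        pd.DataFrame(overlap_rows, columns=["event_type", "n_genes", "genes"]).to_csv(
            outdir / "as_overlap.tsv", sep="\t", index=False
        )
        screen["ranked"].to_csv(outdir / "as_ranked.tsv", sep="\t", index=False)
        results["as"] = screen
        row_counts["as_overlap_genes"] = sum(
            len(g) for g in screen["gene_overlap"].values()
        )
        row_counts["as_same_site"] = len(screen["same_site"])
        row_counts["as_ranked"] = len(screen["ranked"])

    if config.bands:
        logger.info("stage psi")
        bands = tableio.read_table(config.bands, "band")
        rates = gelstats.inclusion_rates(bands)
        rates.to_csv(outdir / "inclusion_rates.tsv", sep="\t", index=False)
        groups = sorted(rates["group"].unique())
        comparisons = []
        for i, ga in enumerate(groups):
            for gb in groups[i + 1 :]:
                a = rates.loc[rates["group"] == ga, "inclusion_rate"].to_numpy()
                b = rates.loc[rates["group"] == gb, "inclusion_rate"].to_numpy()
                if len(a) >= 3 and len(b) >= 3:
                    cmp_ = gelstats.gated_compare(
                        a, b, config.alpha_norm, equal_var=config.t_equal_var
                    )
                    comparisons.append(
                        (ga, gb, cmp_.test_used, cmp_.statistic, cmp_.p_value, cmp_.stars)
                    )
        pd.DataFrame(
            comparisons,
            columns=["group_a", "group_b", "test", "statistic", "pvalue", "stars"],
        ).to_csv(outdir / "psi_comparisons.tsv", sep="\t", index=False)
        results["psi"] = rates
        row_counts["psi_samples"] = len(rates)

    if config.reporter:
        logger.info("stage reporter")
        wells = tableio.read_table(config.reporter, "reporter")
        control = "control" if "control" in set(wells["group"]) else sorted(set(wells["group"]))[0]
        ratios, cmps = gelstats.relative_reporter_activity(wells, control)
        ratios.to_csv(outdir / "reporter_ratios.tsv", sep="\t", index=False)
        results["reporter"] = (ratios, cmps)
        row_counts["reporter_wells"] = len(ratios)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "thresholds": {
            k: getattr(config, k)
            for k in ("mirna_p", "mirna_lfc", "mirna_use_adjusted", "deg_padj",
                      "deg_lfc", "as_p", "min_mean_reads", "top_k", "alpha_norm",
                      "reads_side", "signed_rank", "t_equal_var")
        },
        "weeks": list(config.weeks),
        "row_counts": row_counts,
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    results["manifest"] = manifest
    return results
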
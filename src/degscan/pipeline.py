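"""End-to-end orchestration: normalize -> DE -> scan -> merge -> locus analyses.

Every stage reads and writes only documented plain-text formats, so the
stages can be run separately (see the CLI) or swapped out.  A run ends
with an internal consistency audit: every headline number in the report
is recomputed from the emitted TSVs and must match.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .annotation import (
    Annotation,
    read_annotation,
    read_chrom_lengths,
    read_gene_classes,
    write_regions_bed,
)
from .compare import (
    CompareError,
    FractionReport,
    GeneSubset,
    SubsetComparison,
    compare_subsets,
    define_subsets,
    group_correlation,
    histone_fraction,
)
from .counts import CountMatrix, estimate_size_factors, relative_to_group_mean
from .de import DEResultTable, estimate_dispersions, nb_wald_test
from .windows import (
    RefractoryRegion,
    enumerate_windows,
    intersect_contrasts,
    merge_flagged,
    regions_to_dataframe,
    scan,
    windows_to_dataframe,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Paths and settings for a full pipeline run."""

    annotation_path: str
    counts_path: str
    samples_path: str
    out_dir: str
    chrom_lengths_path: Optional[str] = None
    gene_classes_path: Optional[str] = None
    annotation_format: Optional[str] = None

    reference_group: str = "IVF"
    contrasts: Sequence[str] = ("cSCNT", "fSCNT")  # contrast groups vs reference
    alpha: float = 0.05
    use_padj: bool = False
    min_abs_log2fc: Optional[float] = None

    window_size: int = 2_000_000
    step: int = 1_000_000
    min_degs: int = 6
    max_gap: int = 0

    cluster_tag: str = "HIST1"
    n_flank: tuple[int, int] = (47, 57)
    compare_group: Optional[str] = None  # default: last contrast group
    correlation_level: str = "group"

    def contrast_label(self, group: str) -> str:
        return f"{group}:{self.reference_group}"


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    deg_counts: dict[str, int]
    flagged_window_counts: dict[str, int]
    common_window_count: int
    regions: pd.DataFrame
    subset_comparison: Optional[SubsetComparison]
    fraction: Optional[FractionReport]
    correlation: pd.DataFrame
    provenance: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "deg_counts": self.deg_counts,
            "flagged_window_counts": self.flagged_window_counts,
            "common_window_count": self.common_window_count,
            "n_regions": int(len(self.regions)),
            "regions": self.regions.to_dict(orient="records"),
            "correlation": self.correlation.round(6).to_dict(),
            "provenance": self.provenance,
        }
        if self.subset_comparison is not None:
            payload["subset_tests"] = self.subset_comparison.tests.round(10).to_dict(
                orient="records"
            )
            payload["subset_summary"] = self.subset_comparison.summary.round(6).to_dict(
                orient="records"
            )
        if self.fraction is not None:
            payload["fraction"] = {
                "per_group": self.fraction.per_group.round(6).to_dict(orient="index"),
                "total_ratio": round(self.fraction.total_ratio, 6),
                "fraction_ratio": round(self.fraction.fraction_ratio, 6),
            }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(
        {k: (list(v) if isinstance(v, tuple) else v)
         for k, v in vars(config).items() if k != "out_dir"},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_inputs(config: PipelineConfig) -> tuple[Annotation, CountMatrix]:
    chrom_lengths = (
        read_chrom_lengths(config.chrom_lengths_path) if config.chrom_lengths_path else None
    )
    class_map = (
        read_gene_classes(config.gene_classes_path) if config.gene_classes_path else None
    )
    annotation = read_annotation(
        config.annotation_path,
        config.annotation_format,
        class_map=class_map,
        chrom_lengths=chrom_lengths,
    )
    cm = CountMatrix.from_tsv(config.counts_path, config.samples_path)
    return annotation, cm


def run(config: PipelineConfig) -> RunReport:
    """Execute the full pipeline and write all artifacts to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        annotation, cm = load_inputs(config)
    except Exception as exc:
        raise PipelineError(f"stage load_inputs failed: {exc}") from exc
    return run_objects(annotation, cm, config, out)


def run_objects(
    annotation: Annotation,
    cm: CountMatrix,
    config: PipelineConfig,
    out_dir: Optional[Path] = None,
) -> RunReport:
    """Pipeline on in-memory objects; writes artifacts when out_dir is set."""
    stage = "normalize"
    try:
        estimate_size_factors(cm)
        logger.info("size factors: %s",
                     ", ".join(f"{s}={f:.3f}" for s, f in cm.size_factors.items()))

        stage = "differential_expression"
        de_results: dict[str, DEResultTable] = {}
        deg_sets: dict[str, dict[str, str]] = {}
        for group in config.contrasts:
            label = config.contrast_label(group)
            disp = estimate_dispersions(cm, (config.reference_group, group))
            res = nb_wald_test(
                cm, disp, (config.reference_group, group),
                alpha=config.alpha, min_abs_log2fc=config.min_abs_log2fc,
                use_padj=config.use_padj,
            )
            de_results[label] = res
            deg_sets[label] = res.deg_ids()
            logger.info("contrast %s: %d DEGs of %d tested genes",
                        label, len(deg_sets[label]), int(res.table["tested"].sum()))
            if out_dir:
                res.to_tsv(out_dir / f"de_{group}_vs_{config.reference_group}.tsv")

        stage = "window_scan"
        grid = enumerate_windows(annotation, config.window_size, config.step)
        flagged = scan(grid, deg_sets, config.min_degs)
        common = intersect_contrasts(flagged)
        if out_dir:
            for label, ws in flagged.items():
                safe = label.replace(":", "_vs_")
                windows_to_dataframe(ws).to_csv(
                    out_dir / f"windows_{safe}.tsv", sep="\t", index=False
                )
            windows_to_dataframe(common).to_csv(
                out_dir / "windows_common.tsv", sep="\t", index=False
            )

        stage = "merge_regions"
        common_sorted = sorted(common, key=lambda w: (w.chrom, w.start))
        regions = merge_flagged(common_sorted, config.max_gap)
        regions_df = regions_to_dataframe(regions)
        logger.info("%d merged refractory region(s)", len(regions))
        if out_dir:
            write_regions_bed(regions, out_dir / "regions.bed")
            regions_df.to_csv(out_dir / "regions.tsv", sep="\t", index=False)

        stage = "subset_comparison"
        compare_group = config.compare_group or list(config.contrasts)[-1]
        rel = relative_to_group_mean(cm, config.reference_group)
        subset_comparison = None
        fraction = None
        try:
            subsets = define_subsets(annotation, config.cluster_tag, config.n_flank)
        except CompareError as exc:
            logger.info("subset comparison skipped: %s", exc)
            subsets = []
        if subsets:
            subset_comparison = compare_subsets(rel, subsets, compare_group)
            by_name = {s.name: s for s in subsets}
            all_histone = {g.gene_id for g in annotation if g.gene_class == "histone"}
            if "cluster_histone" in by_name and all_histone:
                stage = "fraction_accounting"
                fraction = histone_fraction(
                    cm, by_name["cluster_histone"].gene_ids, all_histone,
                    config.reference_group, compare_group,
                )
            if out_dir:
                subset_comparison.per_gene.to_csv(
                    out_dir / "subset_values.tsv", sep="\t", index=False
                )
                subset_comparison.tests.to_csv(
                    out_dir / "subset_tests.tsv", sep="\t", index=False
                )
                if fraction is not None:
                    fraction.per_group.to_csv(out_dir / "fractions.tsv", sep="\t")

        stage = "correlation"
        corr = group_correlation(cm, config.correlation_level)
        if out_dir:
            corr.r.round(6).to_csv(out_dir / "correlation.tsv", sep="\t")
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    report = RunReport(
        deg_counts={c: len(s) for c, s in deg_sets.items()},
        flagged_window_counts={c: len(ws) for c, ws in flagged.items()},
        common_window_count=len(common),
        regions=regions_df,
        subset_comparison=subset_comparison,
        fraction=fraction,
        correlation=corr.r,
        provenance={
            "degscan_version": __version__,
            "config_hash": _config_hash(config),
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "window_size": config.window_size,
            "step": config.step,
            "min_degs": config.min_degs,
            "alpha": config.alpha,
            "use_padj": config.use_padj,
        },
    )
    if out_dir:
        report.to_json(out_dir / "report.json")
        audit(report, out_dir, config)
    return report


def audit(report: RunReport, out_dir: Path, config: PipelineConfig) -> None:
    """Recompute the report's headline numbers from the emitted TSVs."""
    for label, n in report.deg_counts.items():
        group = label.split(":")[0]
        tsv = pd.read_csv(
            out_dir / f"de_{group}_vs_{config.reference_group}.tsv", sep="\t"
        )
        if int(tsv["is_deg"].sum()) != n:
            raise PipelineError(f"audit: DEG count mismatch for {label}")
    for label, n in report.flagged_window_counts.items():
        safe = label.replace(":", "_vs_")
        tsv = pd.read_csv(out_dir / f"windows_{safe}.tsv", sep="\t")
        if len(tsv) != n:
            raise PipelineError(f"audit: window count mismatch for {label}")
    common = pd.read_csv(out_dir / "windows_common.tsv", sep="\t")
    if len(common) != report.common_window_count:
        raise PipelineError("audit: common window count mismatch")
    regions = pd.read_csv(out_dir / "regions.tsv", sep="\t")
    if len(regions) != len(report.regions):
        raise PipelineError("audit: region count mismatch")
    logger.info("internal consistency audit passed")
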
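"""Synthetic single-embryo RNA-seq study with a planted refractory cluster.

The generator emulates the statistical structure the scan assumes: a
multi-chromosome gene annotation carrying one ~1.5 Mb cluster of 47
histone-like genes interleaved with 26 nonhistone genes, ~100 further
histone genes scattered elsewhere, and a genes x samples negative-binomial
count matrix for five embryo groups (IVF reference, two nuclear-transfer
groups, and TSA-treated IVF and fSCNT groups).  The planted effect
downregulates the cluster's histone genes in the nuclear-transfer groups
by ``cluster_effect_log2fc``; ``tsa_rescue`` removes that fraction of the
effect in TSA-treated groups.  Background DEGs are scattered at a fixed
rate outside the cluster so planted truth stays unambiguous.

Everything is driven by one integer seed: the same config yields
byte-identical fixtures.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .annotation import (
    Annotation,
    GeneModel,
    write_annotation_bed,
    write_annotation_gtf,
    write_chrom_lengths,
)
from .counts import CountMatrix

DEFAULT_GROUPS = {"IVF": 3, "cSCNT": 3, "fSCNT": 3, "IVF+TSA": 3, "fSCNT+TSA": 3}


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults emulate the single-blastocyst design at desk scale: three
    embryos per group, ~2×10^5 gene-assigned counts per library, NB
    overdispersion 0.3, a 47+26-gene cluster spanning 1.5 Mb with a −2
    log2 planted effect on its histone genes in nuclear-transfer groups,
    and full rescue of that effect under TSA.
    """

    seed: int = 0
    n_chroms: int = 5
    genes_per_chrom: int = 400
    chrom_length: int = 50_000_000
    cluster_chrom: int = 0
    cluster_start: int = 30_500_000
    cluster_span: int = 1_500_000
    n_cluster_histone: int = 47
    n_cluster_nonhistone: int = 26
    n_noncluster_histone: int = 100
    cluster_tag: str = "HIST1"
    samples_per_group: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    reference_group: str = "IVF"
    baseline_log_mean: float = 0.0      # log-normal location of baseline abundance
    baseline_log_sd: float = 1.2        # log-normal scale of baseline abundance
    histone_boost: float = 20.0         # abundance multiplier for histone-class genes
    dispersion: float = 0.3             # NB alpha, variance = mu + alpha*mu^2
    cluster_effect_log2fc: float = -2.0
    tsa_rescue: float = 1.0             # fraction of the effect removed under TSA
    background_deg_rate: float = 0.03
    background_lfc_range: tuple[float, float] = (1.0, 3.0)
    tsa_response_rate: float = 0.10     # shared TSA transcriptional response
    tsa_response_up_fraction: float = 0.75
    tsa_response_lfc_range: tuple[float, float] = (1.0, 3.0)
    library_size: float = 200_000.0     # mean gene-assigned counts per sample
    library_size_cv: float = 0.3
    min_gene_length: int = 1_000
    max_gene_length: int = 30_000

    def validate(self) -> None:
        if self.n_chroms < 1 or self.cluster_chrom >= self.n_chroms:
            raise SimulationError("cluster_chrom must index an existing chromosome")
        if not (0.0 <= self.tsa_rescue <= 1.0):
            raise SimulationError("tsa_rescue must be in [0, 1]")
        if not (0.0 <= self.background_deg_rate < 1.0):
            raise SimulationError("background_deg_rate must be in [0, 1)")
        if self.cluster_start + self.cluster_span > self.chrom_length:
            raise SimulationError("cluster does not fit on its chromosome")
        if any(n < 0 for n in self.samples_per_group.values()):
            raise SimulationError("negative group size")
        if self.samples_per_group.get(self.reference_group, 0) < 1:
            raise SimulationError(
                f"reference group {self.reference_group!r} needs at least one sample"
            )
        if self.dispersion < 0:
            raise SimulationError("dispersion must be >= 0")

    def group_effect(self, group: str) -> float:
        """Planted log2 effect on cluster histone genes for one group."""
        if group == self.reference_group or "SCNT" not in group:
            return 0.0
        if "TSA" in group:
            return self.cluster_effect_log2fc * (1.0 - self.tsa_rescue)
        return self.cluster_effect_log2fc


@dataclass
class Truth:
    """Ground truth of a simulated study.

    ``effects`` holds the realized per-gene log2 shift of every group
    relative to the reference, combining the planted cluster effect,
    lineage-specific reprogramming-error background and the shared TSA
    response.  ``background_degs`` records the reprogramming-error DEGs as
    realized per group (already scaled by rescue in TSA-treated groups);
    ``tsa_response`` the shared TSA signature.
    """

    effects: pd.DataFrame          # genes x groups true log2 fold change vs reference
    refractory_interval: tuple[str, int, int]
    subset_labels: pd.Series       # gene_id -> cluster_histone / cluster_nonhistone / ...
    background_degs: dict[str, dict[str, float]]  # group -> gene_id -> log2fc
    tsa_response: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "refractory_interval": list(self.refractory_interval),
            "subset_labels": self.subset_labels.to_dict(),
            "background_degs": self.background_degs,
            "tsa_response": self.tsa_response,
            "effects": {g: self.effects[g].round(6).to_dict() for g in self.effects.columns},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "Truth":
        with open(path) as fh:
            payload = json.load(fh)
        effects = pd.DataFrame(payload["effects"])
        chrom, start, end = payload["refractory_interval"]
        return cls(
            effects,
            (chrom, int(start), int(end)),
            pd.Series(payload["subset_labels"]),
            payload["background_degs"],
            payload.get("tsa_response", {}),
        )


def _place_genes(
    rng: np.random.Generator,
    n: int,
    lo: int,
    hi: int,
    cfg: SimulationConfig,
    exclude: Optional[tuple[int, int]] = None,
) -> list[tuple[int, int]]:
    """Non-overlapping (start, end) intervals at uniform-random starts.

    Starts are sorted uniforms with a guaranteed minimum spacing; an
    ``exclude`` interval (the cluster span) is skipped by remapping.
    """
    min_len = cfg.min_gene_length
    spacing = min_len + 100
    if exclude is not None:
        a, b = exclude
        a2 = max(lo, a - min_len)  # a start here would reach into the exclusion
        excl = b - a2
    else:
        a2 = excl = 0
    usable = (hi - lo) - excl - n * spacing
    if usable <= 0:
        raise SimulationError(
            f"cannot pack {n} genes of >= {min_len} bp into {hi - lo - excl} bp; "
            "increase chrom_length or reduce genes_per_chrom"
        )
    raw = np.sort(rng.uniform(0.0, usable, size=n))
    starts = (lo + raw + np.arange(n) * spacing).astype(int)
    if exclude is not None:
        starts = np.where(starts >= a2, starts + excl, starts)
    out = []
    for i, s in enumerate(starts):
        limit = (int(starts[i + 1]) - 100) if i + 1 < n else hi
        if exclude is not None and s < a2:
            limit = min(limit, exclude[0])
        length = int(rng.integers(min_len, cfg.max_gene_length))
        out.append((int(s), int(min(s + length, limit))))
    return out


def generate_annotation(cfg: SimulationConfig) -> tuple[Annotation, Truth]:
    """Build the synthetic annotation and its ground truth.

    Background genes get uniform-random non-overlapping starts; cluster
    histone and nonhistone genes are shuffled together across evenly
    spaced (jittered) slots inside the cluster span, so the two classes
    interleave as in a real histone locus.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes: list[GeneModel] = []
    subset_labels: dict[str, str] = {}
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    cluster_chrom = chroms[cfg.cluster_chrom]
    cluster_lo = cfg.cluster_start
    cluster_hi = cfg.cluster_start + cfg.cluster_span

    # cluster genes: evenly spaced slots with jitter, classes shuffled
    n_cluster = cfg.n_cluster_histone + cfg.n_cluster_nonhistone
    if n_cluster > 0:
        slot = cfg.cluster_span / n_cluster
        if slot < cfg.min_gene_length + 200:
            raise SimulationError("cluster_span too small for the cluster gene count")
        classes = ["histone"] * cfg.n_cluster_histone + ["nonhistone"] * cfg.n_cluster_nonhistone
        rng.shuffle(classes)
        n_h = n_n = 0
        for i, klass in enumerate(classes):
            s = cluster_lo + int(i * slot) + int(rng.integers(0, max(1, int(slot * 0.2))))
            e = min(s + int(rng.integers(cfg.min_gene_length, max(int(slot * 0.8),
                                                                  cfg.min_gene_length + 1))),
                    cluster_lo + int((i + 1) * slot) - 50)
            if klass == "histone":
                n_h += 1
                gid = f"{cfg.cluster_tag}_H{n_h:03d}"
                subset_labels[gid] = "cluster_histone"
            else:
                n_n += 1
                gid = f"{cfg.cluster_tag}_N{n_n:03d}"
                subset_labels[gid] = "cluster_nonhistone"
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(gid, cluster_chrom, s, max(e, s + cfg.min_gene_length),
                                   strand, klass, cfg.cluster_tag))

    # background genes per chromosome; scattered histone genes on non-cluster chroms
    other_chroms = [c for c in chroms if c != cluster_chrom] or [cluster_chrom]
    hist_share = {c: 0 for c in chroms}
    for i in range(cfg.n_noncluster_histone):
        hist_share[other_chroms[i % len(other_chroms)]] += 1
    n_hist_assigned = 0
    for ci, chrom in enumerate(chroms):
        n_bg = cfg.genes_per_chrom + hist_share[chrom]
        exclude = (cluster_lo, cluster_hi) if chrom == cluster_chrom else None
        intervals = _place_genes(rng, n_bg, 0, cfg.chrom_length, cfg, exclude)
        hist_idx = set(rng.choice(n_bg, size=hist_share[chrom], replace=False).tolist())
        for i, (s, e) in enumerate(intervals):
            strand = "+" if rng.random() < 0.5 else "-"
            if i in hist_idx:
                n_hist_assigned += 1
                gid = f"HISTX_{n_hist_assigned:03d}"
                genes.append(GeneModel(gid, chrom, s, e, strand, "histone"))
                subset_labels[gid] = "noncluster_histone"
            else:
                gid = f"G{ci + 1}_{i + 1:04d}"
                genes.append(GeneModel(gid, chrom, s, e, strand, "other"))
                subset_labels[gid] = "background"

    annotation = Annotation(genes, {c: cfg.chrom_length for c in chroms})

    # planted effects: cluster knockdown, lineage-specific reprogramming-error
    # background, and a shared TSA transcriptional response.  Background and
    # TSA-response genes never fall inside the cluster span so planted truth
    # stays unambiguous.
    groups = [g for g in cfg.samples_per_group if cfg.samples_per_group[g] > 0]
    effects = pd.DataFrame(0.0, index=annotation.gene_ids, columns=groups)
    cluster_hist_ids = [g for g, l in subset_labels.items() if l == "cluster_histone"]
    for grp in groups:
        effects.loc[cluster_hist_ids, grp] = cfg.group_effect(grp)
    eligible = [
        g.gene_id
        for g in annotation
        if not (g.chrom == cluster_chrom and cluster_lo <= g.start < cluster_hi)
    ]
    lo_fc, hi_fc = cfg.background_lfc_range

    def _draw(rate: float, up_fraction: float, lo: float, hi: float) -> dict[str, float]:
        picked = rng.random(len(eligible)) < rate
        chosen = [g for g, p in zip(eligible, picked) if p]
        signs = np.where(rng.random(len(chosen)) < up_fraction, 1.0, -1.0)
        lfcs = rng.uniform(lo, hi, size=len(chosen)) * signs
        return {g: float(round(v, 6)) for g, v in zip(chosen, lfcs)}

    # one reprogramming-error set per donor lineage; TSA-treated clones
    # inherit their lineage's errors scaled by (1 - tsa_rescue)
    lineages = sorted({g.split("+")[0] for g in groups if "SCNT" in g})
    lineage_errors = {
        lin: _draw(cfg.background_deg_rate, 0.5, lo_fc, hi_fc) for lin in lineages
    }
    tsa_lo, tsa_hi = cfg.tsa_response_lfc_range
    tsa_response = _draw(cfg.tsa_response_rate, cfg.tsa_response_up_fraction,
                         tsa_lo, tsa_hi)

    background: dict[str, dict[str, float]] = {}
    for grp in groups:
        if grp == cfg.reference_group:
            continue
        combined: dict[str, float] = {}
        if "SCNT" in grp:
            lin = grp.split("+")[0]
            scale = (1.0 - cfg.tsa_rescue) if "TSA" in grp else 1.0
            if scale > 0:
                combined = {g: round(v * scale, 6) for g, v in lineage_errors[lin].items()}
        background[grp] = combined
        for g, v in combined.items():
            effects.loc[g, grp] += v
        if "TSA" in grp:
            for g, v in tsa_response.items():
                effects.loc[g, grp] += v

    truth = Truth(
        effects=effects,
        refractory_interval=(cluster_chrom, cluster_lo, cluster_hi),
        subset_labels=pd.Series(subset_labels).loc[annotation.gene_ids],
        background_degs=background,
        tsa_response=tsa_response,
    )
    return annotation, truth


def simulate_counts(annotation: Annotation, truth: Truth, cfg: SimulationConfig) -> CountMatrix:
    """Draw the NB count matrix implied by the annotation and truth.

    ``count[g, s] ~ NB(mean = L_s * p_g * 2^beta_g(group), alpha)`` where
    p_g are baseline abundance proportions (log-normal, histone-class
    genes boosted), L_s is the per-sample library scale and beta the
    planted log2 effect.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)  # independent of placement stream
    gene_ids = annotation.gene_ids
    base = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=len(gene_ids))
    is_histone = np.array([annotation[g].gene_class == "histone" for g in gene_ids])
    base = base * np.where(is_histone, cfg.histone_boost, 1.0)
    props = base / base.sum()

    samples: list[str] = []
    group_of: dict[str, str] = {}
    means_cols: list[np.ndarray] = []
    for grp, n in cfg.samples_per_group.items():
        beta = truth.effects[grp].reindex(gene_ids).to_numpy() if n > 0 else None
        for i in range(n):
            sid = f"{grp}_{i + 1}"
            samples.append(sid)
            group_of[sid] = grp
            lib = cfg.library_size * rng.lognormal(
                -0.5 * math.log1p(cfg.library_size_cv**2),
                math.sqrt(math.log1p(cfg.library_size_cv**2)),
            )
            means_cols.append(lib * props * np.power(2.0, beta))
    mean = np.column_stack(means_cols)
    if cfg.dispersion > 0:
        r = 1.0 / cfg.dispersion
        p = r / (r + mean)
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(mean)
    df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    return CountMatrix(df, group_of)


def simulate_study(cfg: SimulationConfig) -> tuple[Annotation, Truth, CountMatrix]:
    """Annotation, truth and counts in one call."""
    annotation, truth = generate_annotation(cfg)
    cm = simulate_counts(annotation, truth, cfg)
    return annotation, truth, cm


def write_fixture(dir_path: str | Path, cfg: SimulationConfig) -> dict[str, Path]:
    """Emit a complete on-disk fixture: annotation (GTF + BED), chromosome
    lengths, counts TSV, sample sheet, subset labels and truth JSON."""
    cfg.validate()
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    annotation, truth, cm = simulate_study(cfg)
    paths = {
        "gtf": out / "annotation.gtf",
        "bed": out / "annotation.bed",
        "chrom_lengths": out / "chrom_lengths.tsv",
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "subsets": out / "subsets.tsv",
        "truth": out / "truth.json",
        "config": out / "config.json",
    }
    write_annotation_gtf(annotation, paths["gtf"])
    write_annotation_bed(annotation, paths["bed"])
    write_chrom_lengths(annotation, paths["chrom_lengths"])
    cm.to_tsv(paths["counts"], paths["samples"])
    truth.subset_labels.to_csv(paths["subsets"], sep="\t", header=False)
    truth.to_json(paths["truth"])
    cfg_dict = asdict(cfg)
    cfg_dict["background_lfc_range"] = list(cfg.background_lfc_range)
    with open(paths["config"], "w") as fh:
        json.dump(cfg_dict, fh, indent=1, sort_keys=True)
    return paths
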
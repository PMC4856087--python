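"""Locus-level analyses around a gene cluster.

Three operations establish whether a flagged cluster is coordinately and
specifically mis-regulated:

* subset comparison — per-gene mean log2 relative expression of the
  cluster's histone genes vs its nonhistone genes, the flanking genes and
  histone genes elsewhere, with Welch t-tests between subsets (genes are
  the unit of replication, matching gene-level box plots);
* histone-expression fraction accounting — how much of total histone-gene
  output the cluster contributes per group, and how that shifts between
  groups;
* group-wise Pearson correlation of log2 expression profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Annotation
from .counts import CountMatrix, CountsError, RelativeExpression, normalize

logger = logging.getLogger(__name__)


class CompareError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSubset:
    name: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise CompareError(f"subset {self.name!r} is empty")


@dataclass
class SubsetComparison:
    """Per-subset relative-expression distributions and pairwise tests.

    ``per_gene``: gene_id, subset, value (mean log2 relative expression in
    the contrast group).  ``summary``: per-subset n/median/quartiles/mean.
    ``tests``: one row per subset pair with Welch t statistic and p-value;
    pairs involving a subset of fewer than two genes are flagged undefined.
    """

    contrast_group: str
    per_gene: pd.DataFrame
    summary: pd.DataFrame
    tests: pd.DataFrame

    def test_p(self, a: str, b: str) -> float:
        t = self.tests
        row = t[((t.subset_a == a) & (t.subset_b == b)) | ((t.subset_a == b) & (t.subset_b == a))]
        if row.empty:
            raise CompareError(f"no test for pair ({a!r}, {b!r})")
        return float(row["pvalue"].iloc[0])


def define_subsets(
    annotation: Annotation,
    cluster_tag: str = "HIST1",
    n_flank: int | tuple[int, int] = (47, 57),
    noncluster_histone_name: str = "nonHIST1_histone",
) -> list[GeneSubset]:
    """Split a tagged cluster and its neighborhood into comparison subsets.

    Returns up to five pairwise-disjoint subsets: cluster_histone,
    cluster_nonhistone, upstream_flank, downstream_flank (nearest genes by
    coordinate on each side; upstream = lower coordinates), and the
    histone genes residing outside the cluster.  ``n_flank`` may be a
    single count or an (upstream, downstream) pair; flanks larger than the
    available genes are truncated with a warning.
    """
    if isinstance(n_flank, int):
        n_up = n_down = n_flank
    else:
        n_up, n_down = n_flank
    cluster = [g for g in annotation if g.cluster_tag == cluster_tag]
    if not cluster:
        raise CompareError(f"no genes tagged {cluster_tag!r}")
    chroms = {g.chrom for g in cluster}
    if len(chroms) > 1:
        raise CompareError(f"cluster {cluster_tag!r} spans multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop()
    cluster_ids = {g.gene_id for g in cluster}
    lo = min(g.start for g in cluster)
    hi = max(g.end for g in cluster)

    on_chrom = annotation.genes_on(chrom)
    upstream = [g for g in on_chrom if g.end <= lo and g.gene_id not in cluster_ids]
    downstream = [g for g in on_chrom if g.start >= hi and g.gene_id not in cluster_ids]
    if len(upstream) < n_up:
        logger.warning(
            "upstream flank truncated: requested %d genes, %d available", n_up, len(upstream)
        )
    if len(downstream) < n_down:
        logger.warning(
            "downstream flank truncated: requested %d genes, %d available", n_down, len(downstream)
        )
    upstream = upstream[-n_up:] if n_up else []
    downstream = downstream[:n_down] if n_down else []

    subsets = []
    hist = frozenset(g.gene_id for g in cluster if g.gene_class == "histone")
    nonhist = frozenset(g.gene_id for g in cluster if g.gene_class != "histone")
    if hist:
        subsets.append(GeneSubset("cluster_histone", hist))
    if nonhist:
        subsets.append(GeneSubset("cluster_nonhistone", nonhist))
    if upstream:
        subsets.append(GeneSubset("upstream_flank", frozenset(g.gene_id for g in upstream)))
    if downstream:
        subsets.append(GeneSubset("downstream_flank", frozenset(g.gene_id for g in downstream)))
    other_hist = frozenset(
        g.gene_id
        for g in annotation
        if g.gene_class == "histone" and g.cluster_tag != cluster_tag
    )
    if other_hist:
        subsets.append(GeneSubset(noncluster_histone_name, other_hist))
    _check_disjoint(subsets)
    return subsets


def _check_disjoint(subsets: Sequence[GeneSubset]) -> None:
    seen: dict[str, str] = {}
    for s in subsets:
        for g in s.gene_ids:
            if g in seen:
                raise CompareError(
                    f"gene {g!r} is in both {seen[g]!r} and {s.name!r}; subsets must be disjoint"
                )
            seen[g] = s.name


def compare_subsets(
    rel: RelativeExpression,
    subsets: Sequence[GeneSubset],
    contrast_group: str,
) -> SubsetComparison:
    """Welch t-tests between subsets of per-gene mean log2 relative expression.

    Each gene contributes one value: its mean log2 relative expression
    over the contrast-group samples.  All subset pairs are tested
    two-sided; a pair where either subset has fewer than two genes gets an
    undefined (NaN) result flagged in the table.
    """
    _check_disjoint(subsets)
    samples = list(rel.groups.index[rel.groups == contrast_group])
    if not samples:
        raise CompareError(f"no samples in contrast group {contrast_group!r}")
    log2 = np.log2(rel.values[samples])
    per_gene_rows = []
    values: dict[str, np.ndarray] = {}
    for s in subsets:
        ids = sorted(s.gene_ids & set(rel.values.index))
        if not ids:
            raise CompareError(f"subset {s.name!r} has no genes in the expression matrix")
        vals = log2.loc[ids].mean(axis=1)
        values[s.name] = vals.to_numpy()
        per_gene_rows.append(
            pd.DataFrame({"gene_id": ids, "subset": s.name, "value": vals.values})
        )
    per_gene = pd.concat(per_gene_rows, ignore_index=True)
    summary = (
        per_gene.groupby("subset")["value"]
        .agg(
            n="count",
            mean="mean",
            median="median",
            q1=lambda v: v.quantile(0.25),
            q3=lambda v: v.quantile(0.75),
        )
        .reset_index()
    )
    rows = []
    names = [s.name for s in subsets]
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va, vb = values[a], values[b]
            if len(va) < 2 or len(vb) < 2:
                rows.append((a, b, np.nan, np.nan, True))
                continue
            if np.array_equal(np.sort(va), np.sort(vb)) and np.ptp(va) == 0:
                t, p = 0.0, 1.0  # identical constant groups: no evidence, not NaN
            else:
                t, p = stats.ttest_ind(va, vb, equal_var=False)
            rows.append((a, b, float(t), float(p), False))
    tests = pd.DataFrame(rows, columns=["subset_a", "subset_b", "t", "pvalue", "undefined"])
    return SubsetComparison(contrast_group, per_gene, summary, tests)


@dataclass
class FractionReport:
    """Cluster share of total histone-gene expression, per group.

    ``per_group`` columns: total (sum of normalized counts over all
    histone genes), cluster_sum, noncluster_sum, cluster_fraction.
    ``total_ratio`` and ``fraction_ratio`` compare the contrast group with
    the reference group.
    """

    per_group: pd.DataFrame
    reference_group: str
    contrast_group: str
    total_ratio: float
    fraction_ratio: float


def histone_fraction(
    cm: CountMatrix,
    cluster_histone: Iterable[str],
    all_histone: Iterable[str],
    reference_group: str,
    contrast_group: str,
) -> FractionReport:
    """Cluster-histone share of total histone expression, per group.

    Sums per-sample normalized counts over genes and averages across the
    samples of each group, so groups of different size are comparable.
    Conservation holds exactly: cluster_sum + noncluster_sum == total.
    """
    cluster = set(cluster_histone)
    allh = set(all_histone)
    if not cluster <= allh:
        raise CompareError("cluster_histone must be a subset of all_histone")
    missing = allh - set(cm.genes)
    if missing:
        raise CompareError(f"histone genes absent from count matrix: {sorted(missing)[:5]}...")
    norm = normalize(cm)
    rows = []
    for group in cm.group_labels():
        samp = cm.samples_of(group)
        per_sample_total = norm.loc[sorted(allh), samp].sum(axis=0)
        per_sample_cluster = norm.loc[sorted(cluster), samp].sum(axis=0)
        total = float(per_sample_total.mean())
        cl = float(per_sample_cluster.mean())
        if total == 0:
            raise CompareError(f"zero total histone expression in group {group!r}")
        rows.append((group, total, cl, total - cl, cl / total))
    per_group = pd.DataFrame(
        rows, columns=["group", "total", "cluster_sum", "noncluster_sum", "cluster_fraction"]
    ).set_index("group")
    for g in (reference_group, contrast_group):
        if g not in per_group.index:
            raise CompareError(f"group {g!r} not present")
    total_ratio = per_group.loc[contrast_group, "total"] / per_group.loc[reference_group, "total"]
    fraction_ratio = (
        per_group.loc[contrast_group, "cluster_fraction"]
        / per_group.loc[reference_group, "cluster_fraction"]
    )
    return FractionReport(per_group, reference_group, contrast_group,
                          float(total_ratio), float(fraction_ratio))


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson-correlation matrix with unit diagonal.

    ``undefined`` lists label pairs where a constant profile made r
    undefined (NaN in the matrix).
    """

    r: pd.DataFrame
    level: str
    undefined: list[tuple[str, str]]

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return float(self.r.loc[pair[0], pair[1]])


def group_correlation(cm: CountMatrix, level: str = "group") -> CorrelationMatrix:
    """Pearson correlation of log2(normalized + 1) expression profiles.

    ``level="group"`` correlates per-group mean profiles (the standard
    between-condition comparison); ``level="sample"`` correlates
    individual samples for diagnostics.
    """
    if level not in ("group", "sample"):
        raise CompareError(f"level must be 'group' or 'sample', got {level!r}")
    log2 = np.log2(normalize(cm) + 1.0)
    if level == "group":
        profiles = pd.DataFrame(
            {g: log2[cm.samples_of(g)].mean(axis=1) for g in cm.group_labels()}
        )
    else:
        profiles = log2
    if profiles.shape[1] < 2:
        raise CompareError("need at least two columns after aggregation")
    labels = list(profiles.columns)
    arr = profiles.to_numpy()
    sd = arr.std(axis=0)
    sd_tol = 1e-12 * max(1.0, float(np.abs(arr).max()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(arr, rowvar=False)
    np.fill_diagonal(r, 1.0)
    undefined = []
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            if sd[i] <= sd_tol or sd[j] <= sd_tol:
                r[i, j] = r[j, i] = np.nan
                undefined.append((a, labels[j]))
    return CorrelationMatrix(pd.DataFrame(r, index=labels, columns=labels), level, undefined)
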
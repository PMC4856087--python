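"""Count matrix container, size-factor normalization and relative expression.

Normalization is the classical median-of-ratios: the per-sample size
factor is the median, over genes whose counts are positive in every
sample, of the ratio of the sample's count to the gene's geometric mean.
Relative expression divides each normalized value by the mean of a
reference group (the fertilization-derived control in the cloning study
design), optionally with a pseudocount for sparse single-embryo libraries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd


class CountsError(ValueError):
    pass


class StateError(RuntimeError):
    """Operation called before its prerequisite (e.g. size factors missing)."""


class CountMatrix:
    """Genes x samples integer counts with a sample -> group assignment.

    Parameters
    ----------
    counts : DataFrame
        Non-negative integers, index = gene_id, columns = sample_id.
    groups : Mapping or Series
        sample_id -> group label; every sample must be assigned.
    size_factors : Series, optional
        Strictly positive per-sample normalization constants; usually left
        unset and filled by :func:`estimate_size_factors`.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        groups: Mapping[str, str] | pd.Series,
        size_factors: Optional[pd.Series] = None,
    ) -> None:
        counts = counts.copy()
        if (counts.values < 0).any():
            raise CountsError("counts must be non-negative")
        groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
        missing = [s for s in counts.columns if s not in groups.index]
        if missing:
            raise CountsError(f"samples without a group assignment: {missing}")
        self.counts = counts
        self.groups = groups.loc[counts.columns]
        self.size_factors: Optional[pd.Series] = None
        if size_factors is not None:
            size_factors = pd.Series(size_factors).loc[counts.columns]
            if (size_factors <= 0).any():
                raise CountsError("size factors must be strictly positive")
            self.size_factors = size_factors.astype(float)

    # -- basic introspection -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def group_labels(self) -> list[str]:
        return list(dict.fromkeys(self.groups))

    def samples_of(self, group: str) -> list[str]:
        if group not in set(self.groups):
            raise CountsError(f"unknown group {group!r}")
        return list(self.groups.index[self.groups == group])

    # -- I/O -----------------------------------------------------------------
    @classmethod
    def from_tsv(cls, counts_path: str | Path, samples_path: str | Path) -> "CountMatrix":
        """Load counts (first column gene_id, header sample_ids) and a
        two-column sample sheet (sample_id, group)."""
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        sheet = pd.read_csv(
            samples_path, sep="\t", header=None, names=["sample_id", "group"],
            comment="#",
        )
        if list(sheet.columns) and str(sheet.iloc[0, 0]) == "sample_id":
            sheet = sheet.iloc[1:]
        groups = pd.Series(sheet["group"].values, index=sheet["sample_id"].values)
        return cls(counts, groups)

    def to_tsv(self, counts_path: str | Path, samples_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
        with open(samples_path, "w") as fh:
            for s in self.samples:
                fh.write(f"{s}\t{self.groups[s]}\n")


@dataclass
class RelativeExpression:
    """Per-gene, per-sample expression relative to a reference-group mean.

    ``values[g, s] = (norm[g, s] + pseudocount) / (mean_ref(norm[g]) + pseudocount)``;
    log2 of these values is what heatmaps, box plots and subset tests consume.
    """

    values: pd.DataFrame
    reference_group: str
    pseudocount: float
    groups: pd.Series

    def log2(self) -> pd.DataFrame:
        return np.log2(self.values)


def estimate_size_factors(cm: CountMatrix, store: bool = True) -> pd.Series:
    """Median-of-ratios size factors.

    The geometric mean uses only genes with all-positive counts, which is
    robust for sparse single-embryo libraries.  Raises if any sample has
    all-zero counts or if no gene is detected in every sample.
    """
    counts = cm.counts.to_numpy(dtype=float)
    zero_samples = [s for s, tot in zip(cm.samples, counts.sum(axis=0)) if tot == 0]
    if zero_samples:
        raise CountsError(f"all-zero sample(s): {zero_samples}")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise CountsError("no gene has positive counts in every sample")
    sub = counts[positive]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.exp(np.log(sub) - log_geomean[:, None])
    factors = pd.Series(np.median(ratios, axis=0), index=cm.samples)
    if store:
        cm.size_factors = factors
    return factors


def normalize(cm: CountMatrix) -> pd.DataFrame:
    """Counts divided by per-sample size factors."""
    if cm.size_factors is None:
        raise StateError("size factors not estimated; call estimate_size_factors first")
    return cm.counts / cm.size_factors


def relative_to_group_mean(
    cm: CountMatrix, reference_group: str, pseudocount: float = 1.0
) -> RelativeExpression:
    """Expression of every sample relative to the reference-group mean.

    With pseudocount 0 the reference-group mean of the output is exactly 1
    for every gene with nonzero reference mean.
    """
    if pseudocount < 0:
        raise CountsError("pseudocount must be >= 0")
    ref_samples = cm.samples_of(reference_group)
    norm = normalize(cm)
    ref_mean = norm[ref_samples].mean(axis=1)
    values = (norm + pseudocount).div(ref_mean + pseudocount, axis=0)
    if not np.isfinite(values.to_numpy()).all():
        raise CountsError(
            "non-finite relative expression; use a positive pseudocount for "
            "genes with zero reference mean"
        )
    return RelativeExpression(values, reference_group, pseudocount, cm.groups)
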
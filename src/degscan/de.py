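"""Two-group negative-binomial differential expression.

The model is NB with mean mu and variance mu + alpha * mu**2.  Per-gene
dispersions alpha are estimated by a pooled method-of-moments on the
normalized scale; because gene-wise estimates at 2-3 replicates per group
are extremely noisy (and anti-conservative when they undershoot), the
default sharing mode takes, per gene, the maximum of the gene-wise
estimate and a fitted mean-dispersion trend alpha(mu) = a0 + a1/mu — the
classical conservative sharing rule for small-replicate RNA-seq.

The test is a Wald test on log2 fold change between two groups.  When
dispersions were estimated from the data, the statistic is referred to a
t distribution with the residual degrees of freedom of the dispersion
estimate, which accounts for variance-estimation noise and reproduces the
conservative small-sample behavior of the classical NB pipelines; when
exact dispersions are supplied externally the reference is standard
normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counts import CountMatrix, CountsError, normalize

DISPERSION_FLOOR = 0.01


class DEError(ValueError):
    pass


@dataclass
class DispersionEstimates:
    """Per-gene NB dispersions plus how they were obtained.

    ``dispersion`` is what the Wald test consumes; ``genewise`` and
    ``trend`` are kept for diagnostics.  ``df_resid`` is the residual
    degrees of freedom of the gene-wise estimator (n_samples - n_groups);
    it is None when dispersions were supplied externally (treated as known).
    """

    dispersion: pd.Series
    genewise: Optional[pd.Series] = None
    trend: Optional[pd.Series] = None
    df_resid: Optional[int] = None
    floor: float = DISPERSION_FLOOR


def _as_dispersions(dispersions) -> DispersionEstimates:
    if isinstance(dispersions, DispersionEstimates):
        return dispersions
    return DispersionEstimates(pd.Series(dispersions, dtype=float))


def fit_dispersion_trend(mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Least-squares fit of alpha(mu) = a0 + a1/mu over gene-wise estimates."""
    ok = mean > 0
    if ok.sum() < 2:
        return np.full_like(disp, np.nan)
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
    coef, *_ = np.linalg.lstsq(X, disp[ok], rcond=None)
    fitted = np.full_like(disp, np.nan, dtype=float)
    fitted[ok] = np.maximum(0.0, X @ coef)
    return fitted


def estimate_dispersions(
    cm: CountMatrix,
    groups: Sequence[str],
    floor: float = DISPERSION_FLOOR,
    sharing: str = "max-trend",
) -> DispersionEstimates:
    """Pooled method-of-moments NB dispersion per gene.

    Within-group residual variance on the normalized scale is pooled over
    the given groups; ``alpha_g = max(floor, (s2 - mu) / mu**2)``.
    ``sharing="max-trend"`` (default) replaces each gene-wise value by the
    maximum of itself and a fitted mean-dispersion trend;
    ``sharing="gene"`` keeps the raw gene-wise estimates.
    """
    if sharing not in ("max-trend", "gene"):
        raise DEError(f"unknown sharing mode {sharing!r}")
    if len(set(groups)) < 2:
        raise DEError("need at least two distinct groups")
    norm = normalize(cm)
    cols: list[str] = []
    ss = np.zeros(len(cm.genes))
    n_total = 0
    for g in set(groups):
        samp = cm.samples_of(g)
        if len(samp) < 2:
            raise DEError(f"group {g!r} has {len(samp)} sample(s); need >=2 for dispersion")
        sub = norm[samp].to_numpy()
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        cols.extend(samp)
        n_total += len(samp)
    df_resid = n_total - len(set(groups))
    s2 = ss / df_resid
    mu = norm[cols].to_numpy().mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        genewise = np.where(mu > 0, (s2 - mu) / np.maximum(mu, 1e-300) ** 2, 0.0)
    genewise = np.maximum(floor, genewise)
    if sharing == "max-trend":
        trend = fit_dispersion_trend(mu, genewise)
        final = np.fmax(genewise, np.where(np.isnan(trend), floor, trend))
    else:
        trend = np.full_like(genewise, np.nan)
        final = genewise
    idx = cm.counts.index
    return DispersionEstimates(
        dispersion=pd.Series(final, index=idx),
        genewise=pd.Series(genewise, index=idx),
        trend=pd.Series(trend, index=idx),
        df_resid=df_resid,
        floor=floor,
    )


@dataclass
class DEResultTable:
    """Per-gene statistics for one contrast (contrast group over reference).

    ``table`` columns: base_mean, log2fc, se, stat, pvalue, padj, tested,
    is_deg, direction; index is gene_id.
    """

    table: pd.DataFrame
    contrast: tuple[str, str]  # (reference, contrast)
    alpha: float
    min_abs_log2fc: Optional[float]
    use_padj: bool

    def deg_ids(self) -> dict[str, str]:
        sub = self.table[self.table["is_deg"]]
        return dict(zip(sub.index, sub["direction"]))

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path, contrast: tuple[str, str],
                 alpha: float = 0.05, min_abs_log2fc: Optional[float] = None,
                 use_padj: bool = False) -> "DEResultTable":
        table = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(table, contrast, alpha, min_abs_log2fc, use_padj)


def nb_wald_test(
    cm: CountMatrix,
    dispersions,
    contrast: tuple[str, str],
    alpha: float = 0.05,
    min_abs_log2fc: Optional[float] = None,
    use_padj: bool = False,
    min_total_count: int = 1,
    pseudocount: float = 1.0,
) -> DEResultTable:
    """Wald test of log2 fold change under NB variance mu + alpha*mu^2.

    ``contrast`` is (reference_group, contrast_group); log2fc is contrast
    over reference with a pseudocount on normalized means so it is always
    finite.  Genes whose total count is below ``min_total_count`` are not
    tested (pvalue 1, excluded from the BH denominator); all-zero genes
    get log2fc 0.
    """
    ref, con = contrast
    if ref == con:
        raise DEError(f"degenerate contrast ({ref!r}, {con!r})")
    ref_s, con_s = cm.samples_of(ref), cm.samples_of(con)
    if len(ref_s) < 2 or len(con_s) < 2:
        raise DEError("both groups need >=2 samples for the Wald test")
    disp = _as_dispersions(dispersions)
    alpha_g = disp.dispersion.reindex(cm.counts.index)
    if alpha_g.isna().any():
        raise DEError("dispersions missing for some genes")

    norm = normalize(cm)
    sf = cm.size_factors
    m_ref = norm[ref_s].mean(axis=1).to_numpy()
    m_con = norm[con_s].mean(axis=1).to_numpy()
    a = alpha_g.to_numpy(dtype=float)

    # Var of a normalized NB count: mu / sf_s + alpha * mu^2.
    inv_sf_ref = float((1.0 / sf[ref_s]).mean())
    inv_sf_con = float((1.0 / sf[con_s]).mean())
    v_ref = (m_ref * inv_sf_ref + a * m_ref**2) / len(ref_s)
    v_con = (m_con * inv_sf_con + a * m_con**2) / len(con_s)

    ln2 = np.log(2.0)
    log2fc = np.log2((m_con + pseudocount) / (m_ref + pseudocount))
    se = np.sqrt(
        v_con / np.maximum(m_con + pseudocount, 1e-300) ** 2
        + v_ref / np.maximum(m_ref + pseudocount, 1e-300) ** 2
    ) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    if disp.df_resid is not None:
        pvalue = 2.0 * stats.t.sf(np.abs(z), df=disp.df_resid)
    else:
        pvalue = 2.0 * stats.norm.sf(np.abs(z))

    total = cm.counts.sum(axis=1).to_numpy()
    tested = total >= max(min_total_count, 1)
    all_zero = total == 0
    log2fc = np.where(all_zero, 0.0, log2fc)
    pvalue = np.where(~tested, 1.0, pvalue)
    z = np.where(~tested, 0.0, z)

    padj = np.ones_like(pvalue)
    if tested.any():
        padj[tested] = multipletests(pvalue[tested], method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "base_mean": (m_ref * len(ref_s) + m_con * len(con_s)) / (len(ref_s) + len(con_s)),
            "log2fc": log2fc,
            "se": se,
            "stat": z,
            "pvalue": pvalue,
            "padj": padj,
            "tested": tested,
        },
        index=cm.counts.index,
    )
    result = DEResultTable(table, contrast, alpha, min_abs_log2fc, use_padj)
    _apply_deg_call(result)
    return result


def _apply_deg_call(result: DEResultTable) -> None:
    t = result.table
    p = t["padj"] if result.use_padj else t["pvalue"]
    sig = t["tested"] & (p < result.alpha)
    if result.min_abs_log2fc is not None:
        sig &= t["log2fc"].abs() > result.min_abs_log2fc
    t["is_deg"] = sig
    t["direction"] = np.where(t["log2fc"] > 0, "up", np.where(t["log2fc"] < 0, "down", "none"))
    t.loc[~sig, "direction"] = "none"


def call_degs(
    result: DEResultTable,
    alpha: float = 0.05,
    min_abs_log2fc: Optional[float] = None,
    use_padj: bool = False,
) -> dict[str, str]:
    """DEG gene_ids with direction labels under the given thresholds.

    Re-thresholds an existing result table; also updates its is_deg /
    direction columns so that the table and the returned set agree.
    """
    if not (0.0 < alpha < 1.0):
        raise DEError(f"alpha must be in (0, 1), got {alpha}")
    result.alpha = alpha
    result.min_abs_log2fc = min_abs_log2fc
    result.use_padj = use_padj
    _apply_deg_call(result)
    return result.deg_ids()
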
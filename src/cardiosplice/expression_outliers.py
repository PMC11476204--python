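"""Per-gene expression Z-scores and the nonsense-mediated-decay check.

Aberrant splicing frequently triggers nonsense-mediated decay (NMD), which
is visible as reduced expression of the affected gene in the carrier
sample.  This module standardizes log-normalized gene counts into per-gene
Z-scores (size factors by median-of-ratios, log2 with pseudocount 1) and
compares the Z-scores of genes harboring model-selected variants against
those harboring rejected variants with a Welch two-sided t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionZ:
    """Sample x gene Z-scores of log-normalized counts.

    Each retained gene's column has mean 0 and SD 1 (constant genes get
    Z = 0 everywhere).
    """

    zscores: pd.DataFrame
    size_factors: pd.Series
    retained_genes: list[str]


def filter_genes(gene_counts: pd.DataFrame, min_count: int = 10, min_frac: float = 0.5) -> list[str]:
    """Genes with at least ``min_count`` reads in more than ``min_frac`` of
    samples (strict inequality: exactly half the samples is not enough)."""
    counts = gene_counts.to_numpy()
    if (counts < 0).any():
        raise ValueError("gene counts must be non-negative")
    n_ok = (gene_counts >= min_count).sum(axis=0)
    keep = n_ok > min_frac * gene_counts.shape[0]
    return list(gene_counts.columns[keep])


def expression_zscores(gene_counts: pd.DataFrame, retained: list[str] | None = None) -> ExpressionZ:
    """Standardize log2(normalized count + 1) per gene.

    Size factors are median-of-ratios across the retained genes, with
    genes that have a zero count in any sample excluded from the
    reference (their geometric mean would be degenerate).
    """
    if gene_counts.shape[0] < 3:
        raise ValueError("expression_zscores requires >= 3 samples")
    if retained is None:
        retained = filter_genes(gene_counts)
    sub = gene_counts[retained].astype(float)
    if (sub.sum(axis=1) == 0).any():
        bad = sub.index[sub.sum(axis=1) == 0].tolist()
        raise ValueError(f"size factor undefined for all-zero samples: {bad}")

    positive = sub.columns[(sub > 0).all(axis=0)]
    if len(positive) == 0:
        raise ValueError("no gene has positive counts in every sample; size factors undefined")
    log_ref = np.log(sub[positive]).mean(axis=0)  # log geometric mean per gene
    ratios = np.log(sub[positive]) - log_ref
    size_factors = np.exp(ratios.median(axis=1))

    norm = sub.div(size_factors, axis=0)
    logn = np.log2(norm + 1.0)
    mu = logn.mean(axis=0)
    sd = logn.std(axis=0, ddof=0)
    z = (logn - mu).div(sd.replace(0.0, np.nan), axis=1).fillna(0.0)
    return ExpressionZ(zscores=z, size_factors=size_factors, retained_genes=list(retained))


@dataclass
class NmdResult:
    mean_z_selected: float
    mean_z_rejected: float
    pvalue: float
    n_selected: int
    n_rejected: int
    n_skipped: int


def nmd_check(
    expr: ExpressionZ,
    selected_variants: pd.DataFrame,
    rejected_variants: pd.DataFrame,
    sample_col: str = "sample",
    gene_col: str = "gene_id",
) -> NmdResult:
    """Compare expression Z-scores of (carrier sample, gene) pairs between
    model-selected and model-rejected variants; Welch two-sided t-test.

    Variants in genes that did not pass the count filter are skipped and
    tallied.  A group smaller than 2 leaves the p-value undefined (NaN).
    """
    z = expr.zscores
    retained = set(expr.retained_genes)

    def _collect(df: pd.DataFrame) -> tuple[np.ndarray, int]:
        vals, skipped = [], 0
        for row in df.itertuples(index=False):
            g = getattr(row, gene_col)
            s = getattr(row, sample_col)
            if g in retained and s in z.index:
                vals.append(z.at[s, g])
            else:
                skipped += 1
        return np.asarray(vals, float), skipped

    zs, sk1 = _collect(selected_variants)
    zr, sk2 = _collect(rejected_variants)
    if len(zs) == 0 or len(zr) == 0:
        raise ValueError("nmd_check requires non-empty selected and rejected groups")
    if len(zs) < 2 or len(zr) < 2:
        p = float("nan")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = float(stats.ttest_ind(zs, zr, equal_var=False).pvalue)
    return NmdResult(
        mean_z_selected=float(zs.mean()),
        mean_z_rejected=float(zr.mean()),
        pvalue=p,
        n_selected=len(zs),
        n_rejected=len(zr),
        n_skipped=sk1 + sk2,
    )
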
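"""Screening of DNA variants for putative splice disruption.

A variant enters the candidate pool when it has a PASS filter flag, a
maximum splice-disruption Δ score >= 0.2 (any of acceptor/donor gain/loss)
and is rare within the cohort (carried by no more than one sample; the
carrier-count rule implements the internal-MAF phrasing for any cohort
size).  Population rarity against gnomAD (v2 AF and v3 PopMax AF, both
< 1e-4) is applied separately when selecting high-confidence variants.

Each screened variant is annotated with the feature vector used by the
prediction models: maximum Δ score, distance to the nearest annotated
splice junction, SNV/indel status, branchpoint / low-complexity / repeat
region membership, and the gene's median expression (TPM).  Missing
values are carried as missing and never imputed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .splice_outliers import GeneModel

logger = logging.getLogger(__name__)

DELTA_COLS = ["delta_ag", "delta_al", "delta_dg", "delta_dl"]

FEATURE_COLS = [
    "max_delta", "dist_junction", "is_snv",
    "in_branchpoint", "in_low_complexity", "in_repeat", "median_tpm",
]


def _carrier_list(value) -> list[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return []
    if isinstance(value, (list, tuple)):
        return list(value)
    return [s for s in str(value).split(",") if s]


def screen_variants(
    variants: pd.DataFrame,
    delta_min: float = 0.2,
    max_internal_carriers: int = 1,
    require_pass: bool = True,
) -> pd.DataFrame:
    """Retain PASS variants with max Δ >= ``delta_min`` (inclusive) carried
    by at most ``max_internal_carriers`` samples.

    Records with malformed Δ fields (missing, non-numeric, or outside
    [0, 1]) are rejected individually with a logged reason.  The result is
    a subset of the input; screening is idempotent and order-independent.
    """
    deltas = variants[DELTA_COLS].apply(pd.to_numeric, errors="coerce")
    malformed = deltas.isna().any(axis=1) | (deltas < 0).any(axis=1) | (deltas > 1).any(axis=1)
    if malformed.any():
        for vid in variants.index[malformed][:20]:
            logger.warning("screen_variants: rejecting %s (malformed delta fields)", vid)
        logger.warning("screen_variants: rejected %d records with malformed deltas", int(malformed.sum()))
    ok = ~malformed
    max_delta = deltas.max(axis=1)
    ok &= max_delta >= delta_min
    if require_pass:
        ok &= variants["filter"].eq("PASS")
    n_carriers = variants["sample"].map(lambda v: len(_carrier_list(v)))
    ok &= n_carriers <= max_internal_carriers
    out = variants.loc[ok].copy()
    out["max_delta"] = max_delta.loc[ok]
    return out


def rare_in_controls(
    variants: pd.DataFrame,
    v2_max: float = 1e-4,
    v3_popmax_max: float = 1e-4,
) -> pd.DataFrame:
    """Keep variants rare in population controls: gnomAD v2 AF < ``v2_max``
    and gnomAD v3 PopMax AF < ``v3_popmax_max`` (strict).

    Missing frequencies are treated as 0 (absent from controls); the
    number of such records is tallied in ``result.attrs['n_missing_af']``.
    """
    v2 = pd.to_numeric(variants["af_gnomad_v2"], errors="coerce")
    v3 = pd.to_numeric(variants["af_gnomad_v3_popmax"], errors="coerce")
    n_missing = int((v2.isna() | v3.isna()).sum())
    keep = v2.fillna(0.0).lt(v2_max) & v3.fillna(0.0).lt(v3_popmax_max)
    out = variants.loc[keep].copy()
    out.attrs["n_missing_af"] = n_missing
    if n_missing:
        logger.info("rare_in_controls: %d records had missing gnomAD AFs (treated as 0)", n_missing)
    return out


def dist_to_junction(pos: int, gene: GeneModel) -> float:
    """Distance (bp) from ``pos`` to the nearest annotated junction
    endpoint of the gene; NaN when the gene has no junctions.

    For indels ``pos`` is the leftmost reference position.  A tie between
    two equidistant endpoints resolves to the same distance either way.
    """
    endpoints = gene.junction_endpoints
    if not endpoints:
        return float("nan")
    return float(min(abs(pos - e) for e in endpoints))


def assemble_features(
    variant: pd.Series,
    gene: GeneModel,
    tpm_table: pd.DataFrame | pd.Series | None = None,
) -> dict:
    """Build the model feature vector for one screened variant.

    ``tpm_table`` is a samples x genes TPM matrix (the gene's median is
    taken) or a precomputed per-gene median Series; a gene absent from it
    leaves median_tpm missing (models later omit the row — no imputation).
    """
    if variant["gene_id"] != gene.gene_id:
        raise ValueError(f"variant maps to {variant['gene_id']}, not {gene.gene_id}")
    max_delta = float(max(variant[c] for c in DELTA_COLS))
    is_snv = len(str(variant["ref"])) == 1 and len(str(variant["alt"])) == 1
    median_tpm = float("nan")
    if tpm_table is not None:
        if isinstance(tpm_table, pd.DataFrame):
            if gene.gene_id in tpm_table.columns:
                median_tpm = float(tpm_table[gene.gene_id].median())
        elif gene.gene_id in tpm_table.index:
            median_tpm = float(tpm_table[gene.gene_id])
    return {
        "max_delta": max_delta,
        "dist_junction": dist_to_junction(int(variant["pos"]), gene),
        "is_snv": bool(is_snv),
        "in_branchpoint": bool(variant["in_branchpoint"]),
        "in_low_complexity": bool(variant["in_low_complexity"]),
        "in_repeat": bool(variant["in_repeat"]),
        "median_tpm": median_tpm,
    }


def annotate_features(
    variants: pd.DataFrame,
    genes: dict[str, GeneModel] | list[GeneModel],
    tpm_table: pd.DataFrame | pd.Series | None = None,
) -> pd.DataFrame:
    """Vectorized feature assembly for a screened variant table.

    Variants whose gene is absent from ``genes`` are rejected with a
    logged reason; the result carries the FEATURE_COLS columns.
    """
    if isinstance(genes, list):
        genes = {g.gene_id: g for g in genes}
    median_tpm = None
    if tpm_table is not None:
        median_tpm = tpm_table.median(axis=0) if isinstance(tpm_table, pd.DataFrame) else tpm_table
    known = variants["gene_id"].isin(genes.keys())
    n_bad = int((~known).sum())
    if n_bad:
        logger.warning("annotate_features: rejected %d variants outside any gene model", n_bad)
    out = variants.loc[known].copy()
    feats = [
        assemble_features(row, genes[row["gene_id"]], median_tpm)
        for _, row in out.iterrows()
    ]
    fdf = pd.DataFrame(feats, index=out.index)
    for c in FEATURE_COLS:
        out[c] = fdf[c]
    return out
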
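"""Positional and mechanistic classification of predicted variants, and
gene-tier reporting rules.

Positions within a gene are bucketed relative to the nearest annotated
splice junction using the standard consequence convention: the two
intronic bases flanking an exon are the canonical splice site; intronic
offsets 3-8 and exonic offsets 1-3 are the splice region; exonic beyond
3 bp is plain exonic; intronic offsets 9-10 are proximal intronic; and
anything deeper than 10 bp into the intron is deep intronic (the class
that conventional exome panels miss).

The predicted mechanism splits by the Δ-score pattern: splice-site loss
(donor/acceptor loss >= 0.2), cryptic-site gain (donor/acceptor gain
>= 0.2), or both.  Reportability restricts to Tier 1 disease genes under
their inheritance mode (dominant, or homozygous in recessive genes) and
to haploinsufficiency-intolerant Tier 2 genes (pLI >= 0.9).
"""

from __future__ import annotations

import pandas as pd

from .splice_outliers import GeneModel

REGION_CLASSES = [
    "canonical_splice_site", "splice_region", "exonic",
    "intronic_proximal", "deep_intronic",
]


def classify_position(pos: int, gene: GeneModel) -> str:
    """Region class of a 1-based position inside the gene span.

    Offsets count from the exon/intron boundary: exonic offset 1 is the
    boundary base itself, intronic offset 1 the first intronic base.
    Only internal (spliced) exon edges define junctions; a single-exon
    gene is exonic throughout.
    """
    lo, hi = gene.span
    if not lo <= pos <= hi:
        raise ValueError(f"position {pos} outside gene {gene.gene_id} span {gene.span}")
    exon_idx = next(
        (i for i, (s, e) in enumerate(gene.exons) if s <= pos <= e), None
    )
    n_ex = len(gene.exons)
    if exon_idx is not None:
        s, e = gene.exons[exon_idx]
        offsets = []
        if exon_idx > 0:
            offsets.append(pos - s + 1)  # distance to upstream junction edge
        if exon_idx < n_ex - 1:
            offsets.append(e - pos + 1)  # downstream junction edge
        if not offsets:
            return "exonic"
        off = min(offsets)
        return "splice_region" if off <= 3 else "exonic"
    # intronic: find flanking exons
    for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
        if e1 < pos < s2:
            off = min(pos - e1, s2 - pos)
            if off <= 2:
                return "canonical_splice_site"
            if off <= 8:
                return "splice_region"
            if off <= 10:
                return "intronic_proximal"
            return "deep_intronic"
    raise ValueError(f"position {pos} not locatable in gene {gene.gene_id}")


def classify_effect(variant: pd.Series | dict, threshold: float = 0.2) -> str:
    """Predicted mechanism from the four Δ scores: loss_only, gain_only or
    both.  A screened variant always satisfies at least one; anything
    else violates the screening precondition and raises."""
    loss = max(float(variant["delta_dl"]), float(variant["delta_al"]))
    gain = max(float(variant["delta_dg"]), float(variant["delta_ag"]))
    has_loss = loss >= threshold
    has_gain = gain >= threshold
    if has_loss and has_gain:
        return "both"
    if has_loss:
        return "loss_only"
    if has_gain:
        return "gain_only"
    raise ValueError("no delta score reaches the screening threshold; variant was not screened")


def tier_call(gene: GeneModel, genotype: str) -> str:
    """Reportability of one carrier genotype in one gene."""
    if gene.tier == 1:
        if gene.inheritance not in ("AD", "AR"):
            raise ValueError(f"tier-1 gene {gene.gene_id} lacks an inheritance annotation")
        if gene.inheritance == "AD" or (gene.inheritance == "AR" and genotype == "hom"):
            return "tier1_reportable"
        return "none"
    if gene.tier == 2 and gene.pli >= 0.9:
        return "tier2_reportable"
    return "none"


def tier_filter(
    variants: pd.DataFrame,
    genes: dict[str, GeneModel] | list[GeneModel],
) -> pd.Series:
    """Per-variant tier call from gene tier/inheritance/pLI and the
    carrier genotype (``genotype`` column, het/hom)."""
    if isinstance(genes, list):
        genes = {g.gene_id: g for g in genes}
    return pd.Series(
        [tier_call(genes[v.gene_id], v.genotype) for v in variants.itertuples(index=False)],
        index=variants.index,
        name="tier_call",
    )


def prioritize_variants(
    variants: pd.DataFrame,
    genes: dict[str, GeneModel] | list[GeneModel],
    scores: pd.Series | None = None,
) -> pd.DataFrame:
    """Annotate model-selected variants with region class, effect class
    and tier call."""
    if isinstance(genes, list):
        genes = {g.gene_id: g for g in genes}
    out = variants.copy()
    if scores is not None:
        out["model_score"] = scores
    out["region_class"] = [
        classify_position(int(v.pos), genes[v.gene_id]) for v in out.itertuples(index=False)
    ]
    out["effect_class"] = [classify_effect(row) for _, row in out.iterrows()]
    out["tier_call"] = tier_filter(out, genes)
    return out
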
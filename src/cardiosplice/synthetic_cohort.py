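"""Synthetic DNA + RNA cohort generator.

Emulates the inputs of the discovery analysis — gene models with
tier/inheritance/pLI annotations, myocardial expression (TPM and gene
counts), splice-junction split-read and site-level non-split counts, and
screened DNA variant tables with splice Δ scores — together with a latent
causal truth table so every downstream stage can be tested without
controlled-access patient data.

The generator embodies the statistical structure the analysis assumes:

* a variant's latent probability of truly disrupting splicing is
  logistic in (max Δ score, log median gene expression, repeat-region
  membership) with coefficients (+, +, −), so truly disruptive variants
  have higher Δ scores, sit in better-expressed genes and avoid repeat
  regions;
* each causal variant perturbs the nearest annotated junction of its
  gene in the carrier sample only, re-allocating split reads from the
  canonical junction to a cryptic junction sharing the donor (per-donor
  totals conserved) by a planted Δψ;
* optionally, the carrier's expression of the affected gene is reduced
  to emulate nonsense-mediated decay (a planted expression Z shift);
* case samples receive extra causal variants in Tier 1/2 disease genes
  at a configurable rate, planting a carrier-burden excess.

Determinism: a fixed ``SimConfig`` (including seed) yields identical
outputs across runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .splice_outliers import GeneModel, JunctionCountSet, genes_to_frame

VARIANT_COLUMNS = [
    "variant_id", "chrom", "pos", "ref", "alt", "gene_id", "sample", "genotype",
    "filter", "delta_ag", "delta_al", "delta_dg", "delta_dl",
    "offset_ag", "offset_al", "offset_dg", "offset_dl",
    "af_internal", "af_gnomad_v2", "af_gnomad_v3_popmax",
    "in_branchpoint", "in_low_complexity", "in_repeat", "consequence",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults are sized so the full pipeline runs in a few minutes on one
    CPU while keeping the class structure of the real analysis
    (confirmed : unconfirmed candidates ≈ 1 : 80).
    """

    seed: int = 0
    n_case_samples: int = 100
    n_control_samples: int = 250
    n_genes: int = 300
    frac_tier1: float = 0.10
    frac_tier2: float = 0.20
    exons_per_gene: tuple[int, int] = (4, 8)
    mean_depth: float = 60.0
    expr_lognormal_params: tuple[float, float] = (1.0, 0.5)
    variants_per_sample: float = 80.0
    causal_logit_coefs: tuple[float, float, float, float] = (-9.8, 8.0, 1.0, -1.5)
    planted_delta_psi: float = 0.4
    nmd_shift: float = -0.2
    flag_probs: dict = field(
        default_factory=lambda: {"branchpoint": 0.05, "low_complexity": 0.10, "repeat": 0.30}
    )
    case_excess_rate: float = 0.3
    synonymous_rate: float = 40.0
    frac_indel: float = 0.15
    frac_multi_carrier: float = 0.02
    frac_fail_filter: float = 0.02
    frac_common_gnomad: float = 0.10
    frac_low_expr: float = 0.10
    gene_mu_spread: float = 1.2
    psi_concentration: float = 120.0
    baseline_cryptic_psi: float = 0.03
    theta_mean: float = 0.95
    minus_strand_frac: float = 0.0
    nmd_frac: float = 1.0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.exons_per_gene[0] < 1:
            raise ValueError("exons_per_gene must be >= 1")
        for name in ("frac_tier1", "frac_tier2", "frac_indel", "frac_low_expr"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if not 0.0 < self.planted_delta_psi < 1.0 and self.planted_delta_psi != 0.0:
            raise ValueError("planted_delta_psi must be in [0,1)")


@dataclass
class SyntheticCohort:
    """All simulated inputs plus the latent truth table."""

    config: SimConfig
    genes: list[GeneModel]
    case_samples: list[str]
    control_samples: list[str]
    tpm: pd.DataFrame           # case samples x genes
    gene_counts: pd.DataFrame   # case samples x genes (NMD applied)
    junction_counts: JunctionCountSet  # case samples, effects planted
    variants: pd.DataFrame
    truth: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return self.case_samples + self.control_samples


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def simulate_gene_models(config: SimConfig, rng: np.random.Generator | None = None) -> list[GeneModel]:
    """Draw non-overlapping gene models with sorted exons and panel
    annotations.

    Tiers follow frac_tier1/frac_tier2; Tier 1 genes get AD or AR
    inheritance; pLI is drawn so Tier 2 contains genes on both sides of
    0.9.  Genes are laid out with gaps on 22 synthetic chromosomes.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if config.n_genes < 1 or config.exons_per_gene[0] < 1:
        raise ValueError("need at least one gene with at least one exon")
    lo, hi = config.exons_per_gene
    chrom_cursor = {f"chr{i}": 10_000 for i in range(1, 23)}
    genes: list[GeneModel] = []
    n_t1 = int(round(config.frac_tier1 * config.n_genes))
    n_t2 = int(round(config.frac_tier2 * config.n_genes))
    tiers = np.array([1] * n_t1 + [2] * n_t2 + [0] * (config.n_genes - n_t1 - n_t2))
    rng.shuffle(tiers)
    for i in range(config.n_genes):
        chrom = f"chr{(i % 22) + 1}"
        n_ex = int(rng.integers(lo, hi + 1))
        pos = chrom_cursor[chrom]
        exons = []
        for e in range(n_ex):
            length = int(rng.integers(100, 300))
            exons.append((pos, pos + length - 1))
            pos += length + int(rng.integers(500, 3000))
        chrom_cursor[chrom] = pos + 50_000
        tier = int(tiers[i])
        if tier == 1:
            inheritance = "AD" if rng.random() < 0.7 else "AR"
            pli = float(rng.beta(8, 2))
        else:
            inheritance = "NA"
            pli = float(rng.beta(0.7, 0.7))
        strand = "-" if rng.random() < config.minus_strand_frac else "+"
        genes.append(
            GeneModel(
                gene_id=f"G{i:04d}", chrom=chrom, exons=exons, strand=strand,
                tier=tier, inheritance=inheritance, pli=pli,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(
    genes: list[GeneModel],
    n_samples: int,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    sample_prefix: str = "CASE",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TPM matrix and gene-level count matrix for the RNA cohort.

    Per-gene log-TPM means are spread around ``mu``; per-sample TPM is
    lognormal around the gene mean with within-gene sigma.  A declared
    fraction of genes is forced to low expression (median TPM < 1) to
    exercise the expression filter.  Counts are Poisson with per-sample
    library factors, mean proportional to TPM.
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    mu, sigma = config.expr_lognormal_params
    n_genes = len(genes)
    gene_mu = rng.normal(mu, config.gene_mu_spread, size=n_genes)
    n_low = int(round(config.frac_low_expr * n_genes))
    low_idx = rng.choice(n_genes, size=n_low, replace=False)
    gene_mu[low_idx] = np.log(rng.uniform(0.05, 0.8, size=n_low))
    log_tpm = rng.normal(gene_mu[None, :], sigma, size=(n_samples, n_genes))
    tpm = np.exp(log_tpm)
    lib = np.exp(rng.normal(0.0, 0.1, size=n_samples))
    counts = rng.poisson(lib[:, None] * tpm * 20.0)
    samples = [f"{sample_prefix}{i:03d}" for i in range(n_samples)]
    gene_ids = [g.gene_id for g in genes]
    tpm_df = pd.DataFrame(tpm, index=samples, columns=gene_ids)
    counts_df = pd.DataFrame(counts, index=samples, columns=gene_ids)
    return tpm_df, counts_df


# ---------------------------------------------------------------------------
# Junction counts
# ---------------------------------------------------------------------------

def simulate_junction_counts(
    genes: list[GeneModel],
    samples: list[str],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> JunctionCountSet:
    """Baseline (null) junction and splice-site counts.

    Each annotated junction has a canonical and a cryptic form sharing
    the donor; the canonical fraction is close to 1 with beta-binomial
    sample noise.  θ sites at each donor carry split/non-split counts
    with splicing efficiency near ``theta_mean``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    n_s = len(samples)
    jrows, split_cols = [], []
    srows, site_split_cols, site_nonsplit_cols = [], [], []
    conc = config.psi_concentration
    for g in genes:
        for ji, (donor, acceptor) in enumerate(g.junctions):
            can_id = f"{g.gene_id}_j{ji}_can"
            intron_len = acceptor - donor
            shift = min(35, max(5, intron_len // 3))
            cry_id = f"{g.gene_id}_j{ji}_cry"
            jrows.append((can_id, g.gene_id, donor, acceptor))
            jrows.append((cry_id, g.gene_id, donor, acceptor - shift))
            psi_gene = 1.0 - config.baseline_cryptic_psi
            psi_s = rng.beta(psi_gene * conc, (1 - psi_gene) * conc, size=n_s)
            depth = rng.poisson(config.mean_depth, size=n_s)
            can = rng.binomial(depth, psi_s)
            split_cols.append(can)
            split_cols.append(depth - can)
            # θ site at the donor
            site_id = f"{g.gene_id}_s{ji}"
            srows.append((site_id, g.gene_id, donor))
            theta_s = rng.beta(config.theta_mean * conc, (1 - config.theta_mean) * conc, size=n_s)
            sdepth = rng.poisson(config.mean_depth, size=n_s)
            nonsplit = rng.binomial(sdepth, 1.0 - theta_s)
            site_split_cols.append(sdepth - nonsplit)
            site_nonsplit_cols.append(nonsplit)
    junctions = pd.DataFrame(jrows, columns=["junction_id", "gene_id", "donor", "acceptor"]).set_index("junction_id")
    sites = pd.DataFrame(srows, columns=["site_id", "gene_id", "pos"]).set_index("site_id")
    split = pd.DataFrame(np.column_stack(split_cols), index=samples, columns=junctions.index)
    ssplit = pd.DataFrame(np.column_stack(site_split_cols), index=samples, columns=sites.index)
    snon = pd.DataFrame(np.column_stack(site_nonsplit_cols), index=samples, columns=sites.index)
    return JunctionCountSet(junctions, split, sites, ssplit, snon)


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _draw_deltas(rng: np.random.Generator, n: int, strong: bool = False) -> np.ndarray:
    """Four Δ scores per variant with max >= 0.2.

    The marginal of the dominant score is 0.2 + 0.8 * Beta; the mixture
    shape is a free modelling choice (the screened-pool Δ distribution is
    not observable at desk scale).  The dominant score is placed on a
    random gain/loss channel; secondary channels are small.
    """
    a, b = (2.0, 2.0) if strong else (0.8, 2.5)
    m = 0.2 + 0.8 * rng.beta(a, b, size=n)
    out = rng.uniform(0.0, 0.15, size=(n, 4)) * (rng.random((n, 4)) < 0.5)
    chan = rng.integers(0, 4, size=n)
    out[np.arange(n), chan] = m
    # occasional dual loss+gain pattern
    dual = rng.random(n) < 0.15
    alt_chan = (chan + rng.integers(1, 4, size=n)) % 4
    out[dual, alt_chan[dual]] = 0.2 + 0.8 * rng.beta(1.0, 3.0, size=int(dual.sum()))
    return np.clip(out, 0.0, 1.0)


def _variant_position(rng: np.random.Generator, gene: GeneModel) -> int:
    """Place a variant in an exon, near-junction intron, or deep intron."""
    cat = rng.random()
    junctions = gene.junctions
    if not junctions or cat < 0.30:
        s, e = gene.exons[rng.integers(0, len(gene.exons))]
        return int(rng.integers(s, e + 1))
    donor, acceptor = junctions[rng.integers(0, len(junctions))]
    intron_len = acceptor - donor - 1
    if cat < 0.70:  # within 100 bp of a junction endpoint
        off = int(rng.integers(1, min(100, max(2, intron_len // 2)) + 1))
    else:  # deep intronic
        off = int(rng.integers(101, max(102, intron_len - 100)))
        off = min(off, max(1, intron_len - 1))
    return int(donor + off) if rng.random() < 0.5 else int(acceptor - off)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(x)


def simulate_variants(
    genes: list[GeneModel],
    case_samples: list[str],
    control_samples: list[str],
    tpm: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Variant table plus latent causal truth.

    Splice-candidate variants (max Δ >= 0.2) are carried by a single
    sample each (a small fraction by two, to exercise the rarity
    filter).  The latent causal indicator is Bernoulli with logit
    b0 + b1 * maxΔ + b2 * log(median TPM) + b3 * repeat_flag.  Case
    samples additionally receive Poisson(case_excess_rate) forced-causal
    variants in Tier 1/2 genes.  Synonymous technical-control variants
    are emitted for every sample at ``synonymous_rate``.
    """
    if not genes:
        raise ValueError("gene models required")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    gene_by_id = {g.gene_id: g for g in genes}
    gene_ids = np.array([g.gene_id for g in genes])
    median_tpm = tpm.median(axis=0)
    log_tpm = np.log(median_tpm + 0.01)
    all_samples = list(case_samples) + list(control_samples)
    n_total = len(all_samples)
    b0, b1, b2, b3 = config.causal_logit_coefs

    rows: list[dict] = []
    truth_rows: list[dict] = []
    vid = 0

    def _add_variant(sample_list, gene, pos, deltas, flags, causal, consequence="splice_candidate",
                     genotype=None):
        nonlocal vid
        is_indel = rng.random() < config.frac_indel and consequence != "synonymous"
        ref = str(rng.choice(_BASES))
        if is_indel:
            extra = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
            if rng.random() < 0.5:
                ref, alt = ref + extra, ref
            else:
                alt = ref + extra
        else:
            alt = str(rng.choice(_BASES[_BASES != ref]))
        common = rng.random() < config.frac_common_gnomad
        af2 = float(10 ** rng.uniform(-4.0, -2.0)) if common else float(10 ** rng.uniform(-6.5, -4.5))
        af3 = af2 * float(np.exp(rng.normal(0.0, 0.3)))
        flt = "PASS" if rng.random() >= config.frac_fail_filter else "LowQual"
        offsets = rng.integers(-50, 51, size=4)
        gt = genotype or ("hom" if rng.random() < 0.05 else "het")
        rows.append(
            dict(
                variant_id=f"v{vid:06d}", chrom=gene.chrom, pos=int(pos), ref=ref, alt=alt,
                gene_id=gene.gene_id, sample=",".join(sample_list), genotype=gt, filter=flt,
                delta_ag=float(deltas[0]), delta_al=float(deltas[1]),
                delta_dg=float(deltas[2]), delta_dl=float(deltas[3]),
                offset_ag=int(offsets[0]), offset_al=int(offsets[1]),
                offset_dg=int(offsets[2]), offset_dl=int(offsets[3]),
                af_internal=len(sample_list) / n_total,
                af_gnomad_v2=af2, af_gnomad_v3_popmax=af3,
                in_branchpoint=bool(flags[0]), in_low_complexity=bool(flags[1]),
                in_repeat=bool(flags[2]), consequence=consequence,
            )
        )
        truth_rows.append(dict(variant_id=f"v{vid:06d}", causal=bool(causal)))
        vid += 1
        return rows[-1]["variant_id"]

    fp = config.flag_probs
    for sample in all_samples:
        n_v = rng.poisson(config.variants_per_sample)
        if n_v == 0:
            continue
        gidx = rng.integers(0, len(genes), size=n_v)
        deltas = _draw_deltas(rng, n_v)
        flags = np.column_stack([
            rng.random(n_v) < fp["branchpoint"],
            rng.random(n_v) < fp["low_complexity"],
            rng.random(n_v) < fp["repeat"],
        ])
        max_d = deltas.max(axis=1)
        eta = b0 + b1 * max_d + b2 * log_tpm.iloc[gidx].to_numpy() + b3 * flags[:, 2]
        causal = rng.random(n_v) < _sigmoid(eta)
        for i in range(n_v):
            gene = gene_by_id[gene_ids[gidx[i]]]
            pos = _variant_position(rng, gene)
            carriers = [sample]
            if rng.random() < config.frac_multi_carrier:
                other = rng.choice([s for s in all_samples if s != sample])
                carriers.append(str(other))
            _add_variant(carriers, gene, pos, deltas[i], flags[i], causal[i])

    # planted case excess in disease genes
    if config.case_excess_rate > 0:
        t12 = [g for g in genes if g.tier in (1, 2)]
        if t12:
            for sample in case_samples:
                for _ in range(rng.poisson(config.case_excess_rate)):
                    gene = t12[rng.integers(0, len(t12))]
                    pos = _variant_position(rng, gene)
                    deltas = _draw_deltas(rng, 1, strong=True)[0]
                    flags = [rng.random() < fp["branchpoint"],
                             rng.random() < fp["low_complexity"],
                             rng.random() < fp["repeat"]]
                    _add_variant([sample], gene, pos, deltas, flags, causal=True)

    # synonymous technical-control variants (no splice effect)
    if config.synonymous_rate > 0:
        for sample in all_samples:
            n_syn = rng.poisson(config.synonymous_rate)
            for _ in range(n_syn):
                gene = gene_by_id[gene_ids[rng.integers(0, len(genes))]]
                s, e = gene.exons[rng.integers(0, len(gene.exons))]
                pos = int(rng.integers(s, e + 1))
                deltas = rng.uniform(0.0, 0.05, size=4)
                flags = [False, False, rng.random() < fp["repeat"]]
                _add_variant([sample], gene, pos, deltas, flags, causal=False,
                             consequence="synonymous")

    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    truth = pd.DataFrame(truth_rows).set_index("variant_id")
    return variants, truth


# ---------------------------------------------------------------------------
# Planted effects
# ---------------------------------------------------------------------------

def plant_splice_effects(
    variants: pd.DataFrame,
    truth: pd.DataFrame,
    junction_counts: JunctionCountSet,
    config: SimConfig,
    genes: list[GeneModel] | None = None,
    gene_counts: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[JunctionCountSet, pd.DataFrame, pd.DataFrame]:
    """Perturb the carrier sample at each causal variant's nearest
    junction and apply the NMD expression shift.

    Split reads are re-allocated from the canonical to the cryptic
    junction of the nearest donor by ``planted_delta_psi`` of the donor
    total (per-donor totals conserved; a shift that would push ψ below 0
    is clipped and recorded).  For NMD-flagged genes the carrier's gene
    count is scaled by 2**(nmd_shift * sd_g) with sd_g the gene's SD of
    log2(count+1), moving the expression Z by about ``nmd_shift``.

    Returns the perturbed counts, the (possibly shifted) gene counts and
    the truth table extended with the perturbed junction, planted Δψ and
    clipping flag.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    split = junction_counts.split_counts.copy()
    junc = junction_counts.junctions
    gene_counts = None if gene_counts is None else gene_counts.copy()
    truth = truth.copy()
    for col, default in (("perturbed_junction", None), ("planted_dpsi", 0.0),
                         ("clipped", False), ("nmd_applied", False)):
        truth[col] = default

    if gene_counts is not None and config.nmd_shift != 0.0:
        log2c = np.log2(gene_counts + 1.0)
        sd_g = log2c.std(axis=0, ddof=0)

    can_junc = junc[junc.index.str.endswith("_can")]
    by_gene: dict[str, pd.DataFrame] = {g: df for g, df in can_junc.groupby("gene_id")}

    causal_ids = truth.index[truth["causal"]]
    vsub = variants.set_index("variant_id").loc[causal_ids]
    for vid, var in vsub.iterrows():
        gene_id = var["gene_id"]
        carriers = [s for s in str(var["sample"]).split(",") if s in split.index]
        if gene_id not in by_gene or not carriers:
            continue
        cands = by_gene[gene_id]
        d = np.minimum(
            np.abs(cands["donor"] - var["pos"]), np.abs(cands["acceptor"] - var["pos"])
        )
        can_id = d.idxmin()
        cry_id = can_id[:-4] + "_cry"
        sample = carriers[0]  # the planted event lives in exactly one sample
        if config.planted_delta_psi > 0 and cry_id in split.columns:
            total = int(split.at[sample, can_id] + split.at[sample, cry_id])
            moved = int(round(config.planted_delta_psi * total))
            clipped = moved > split.at[sample, can_id]
            moved = min(moved, int(split.at[sample, can_id]))
            split.at[sample, can_id] -= moved
            split.at[sample, cry_id] += moved
            truth.at[vid, "perturbed_junction"] = can_id
            truth.at[vid, "planted_dpsi"] = -moved / total if total else 0.0
            truth.at[vid, "clipped"] = bool(clipped)
        if (
            gene_counts is not None
            and config.nmd_shift != 0.0
            and sample in gene_counts.index
            and gene_id in gene_counts.columns
            and rng.random() < config.nmd_frac
        ):
            factor = 2.0 ** (config.nmd_shift * sd_g[gene_id])
            gene_counts.at[sample, gene_id] = int(round(gene_counts.at[sample, gene_id] * factor))
            truth.at[vid, "nmd_applied"] = True

    perturbed = JunctionCountSet(
        junctions=junction_counts.junctions,
        split_counts=split,
        sites=junction_counts.sites,
        site_split=junction_counts.site_split,
        site_nonsplit=junction_counts.site_nonsplit,
    )
    return perturbed, gene_counts, truth


# ---------------------------------------------------------------------------
# Cohort orchestration and carrier-status shortcut
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort with planted effects."""
    genes = simulate_gene_models(config)
    case_samples = [f"CASE{i:03d}" for i in range(config.n_case_samples)]
    control_samples = [f"CTRL{i:03d}" for i in range(config.n_control_samples)]
    tpm, gene_counts = simulate_expression(genes, config.n_case_samples, config)
    median_tpm = tpm.median(axis=0)
    for g in genes:
        g.median_tpm = float(median_tpm[g.gene_id])
    jcs = simulate_junction_counts(genes, case_samples, config)
    variants, truth = simulate_variants(genes, case_samples, control_samples, tpm, config)
    jcs, gene_counts, truth = plant_splice_effects(
        variants, truth, jcs, config, genes=genes, gene_counts=gene_counts
    )
    return SyntheticCohort(
        config=config, genes=genes,
        case_samples=case_samples, control_samples=control_samples,
        tpm=tpm, gene_counts=gene_counts, junction_counts=jcs,
        variants=variants, truth=truth,
    )


def simulate_carrier_status(
    n_cases: int,
    n_controls: int,
    carrier_rate: float = 0.3,
    case_or: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[int, int]:
    """Carrier counts for a case-control burden replicate.

    Controls carry a qualifying variant with probability
    ``carrier_rate``; case odds are multiplied by ``case_or``.  Used for
    burden calibration/recovery at full study sizes without simulating
    every variant.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    odds = carrier_rate / (1.0 - carrier_rate) * case_or
    p_case = odds / (1.0 + odds)
    return (
        int(rng.binomial(n_cases, p_case)),
        int(rng.binomial(n_controls, carrier_rate)),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write all cohort tables as TSV; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["genes"] = outdir / "genes.tsv"
    genes_to_frame(cohort.genes).to_csv(paths["genes"], sep="\t", index=False)

    paths["variants"] = outdir / "variants.tsv"
    cohort.variants.to_csv(paths["variants"], sep="\t", index=False)

    paths["truth"] = outdir / "truth.tsv"
    cohort.truth.to_csv(paths["truth"], sep="\t")

    paths["tpm"] = outdir / "tpm.tsv"
    cohort.tpm.to_csv(paths["tpm"], sep="\t", index_label="sample")

    paths["gene_counts"] = outdir / "gene_counts.tsv"
    cohort.gene_counts.to_csv(paths["gene_counts"], sep="\t", index_label="sample")

    jcs = cohort.junction_counts
    jlong = (
        jcs.split_counts.stack().rename("split_count").reset_index()
        .rename(columns={"level_0": "sample", "level_1": "junction_id"})
    )
    jlong = jlong.merge(jcs.junctions.reset_index(), on="junction_id")
    paths["junctions"] = outdir / "junctions.tsv"
    jlong[["junction_id", "donor", "acceptor", "gene_id", "sample", "split_count"]].to_csv(
        paths["junctions"], sep="\t", index=False
    )

    ssplit = jcs.site_split.stack().rename("split_count")
    snon = jcs.site_nonsplit.stack().rename("nonsplit_count")
    slong = pd.concat([ssplit, snon], axis=1).reset_index()
    slong.columns = ["sample", "site_id", "split_count", "nonsplit_count"]
    slong = slong.merge(jcs.sites.reset_index(), on="site_id")
    paths["sites"] = outdir / "sites.tsv"
    slong[["site_id", "gene_id", "pos", "sample", "split_count", "nonsplit_count"]].to_csv(
        paths["sites"], sep="\t", index=False
    )

    samples = pd.DataFrame(
        {"sample": cohort.samples,
         "cohort": ["case"] * len(cohort.case_samples) + ["control"] * len(cohort.control_samples)}
    )
    paths["samples"] = outdir / "samples.tsv"
    samples.to_csv(paths["samples"], sep="\t", index=False)
    return paths


def read_star_junctions(
    sample_files: dict[str, str | Path],
    genes: list[GeneModel],
) -> JunctionCountSet:
    """Build a JunctionCountSet from per-sample STAR ``SJ.out.tab``-style
    tables (chrom, intron first/last base, strand, motif, annotated,
    unique reads, multimap reads, overhang; no header).

    Donor/acceptor are the flanking exonic bases (intron start − 1,
    intron end + 1); unique-read counts are used.  Junctions are assigned
    to genes by span containment — a junction inside no gene or multiple
    genes keeps the joined gene list and is excluded later by the
    outlier caller's single-gene rule.
    """
    cols = ["chrom", "intron_start", "intron_end", "strand", "motif",
            "annotated", "unique_reads", "multi_reads", "overhang"]
    per_sample = {}
    for sample, path in sample_files.items():
        df = pd.read_csv(path, sep="\t", header=None, names=cols)
        df["donor"] = df["intron_start"] - 1
        df["acceptor"] = df["intron_end"] + 1
        per_sample[sample] = df.set_index(["chrom", "donor", "acceptor"])["unique_reads"]
    wide = pd.DataFrame(per_sample).T.fillna(0).astype(int)

    def _genes_at(chrom: str, donor: int, acceptor: int) -> str:
        hits = [g.gene_id for g in genes
                if g.chrom == chrom and g.span[0] <= donor and acceptor <= g.span[1]]
        return ",".join(hits)

    keys = wide.columns
    junctions = pd.DataFrame(
        {
            "gene_id": [_genes_at(c, d, a) for c, d, a in keys],
            "donor": [d for _, d, _ in keys],
            "acceptor": [a for _, _, a in keys],
        },
        index=pd.Index([f"{c}:{d}-{a}" for c, d, a in keys], name="junction_id"),
    )
    wide.columns = junctions.index
    return JunctionCountSet(junctions=junctions, split_counts=wide)


def read_junction_counts(junctions_tsv: str | Path, sites_tsv: str | Path | None = None) -> JunctionCountSet:
    """Load junction/site count tables written by :func:`write_cohort`
    (or STAR SJ.out.tab-style input mapped to the same columns)."""
    jlong = pd.read_csv(junctions_tsv, sep="\t")
    junctions = (
        jlong[["junction_id", "gene_id", "donor", "acceptor"]]
        .drop_duplicates().set_index("junction_id")
    )
    split = jlong.pivot(index="sample", columns="junction_id", values="split_count").fillna(0).astype(int)
    split = split[junctions.index]
    sites = pd.DataFrame(columns=["gene_id", "pos"])
    ssplit = snon = None
    if sites_tsv is not None:
        slong = pd.read_csv(sites_tsv, sep="\t")
        sites = slong[["site_id", "gene_id", "pos"]].drop_duplicates().set_index("site_id")
        ssplit = slong.pivot(index="sample", columns="site_id", values="split_count").fillna(0).astype(int)
        snon = slong.pivot(index="sample", columns="site_id", values="nonsplit_count").fillna(0).astype(int)
        ssplit, snon = ssplit[sites.index], snon[sites.index]
    return JunctionCountSet(junctions, split, sites, ssplit, snon)
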
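"""Splice-outlier detection from RNA-Seq junction counts.

Implements the percent-spliced-in metrics ψ5 (donor usage), ψ3 (acceptor
usage) and θ (splicing efficiency, split vs non-split reads at a site),
fits a per-site beta-binomial null across the cohort, and calls per-sample
outlier splicing events with the decision rule

    significant ⇔ FDR < 0.2  ∧  |Z| ≥ 1  ∧  |Δψ| ≥ 0.2
                  ∧  (expected ψ ≤ 0.1 ∨ expected ψ ≥ 0.9)

where the expected ψ is a leave-one-out, count-weighted cohort mean.
The null replaces a denoising-autoencoder fit with a method-of-moments
beta-binomial per site: desk-scale, dependency-free, and sufficient for a
threshold-based decision rule.  Z-scores are computed on logit(ψ) with
pseudocounts (numerator +1, denominator +2) and standardized by the cohort
mean/SD at the site.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

METRICS = ("psi5", "psi3", "theta")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene with exon structure and clinical-panel annotations.

    Coordinates are 1-based inclusive.  ``tier`` is 1 (moderate-to-definitive
    disease association), 2 (limited association) or 0 (off panel).
    ``inheritance`` is "AD"/"AR" for tier-1 genes, "NA" otherwise.  ``pli``
    is the loss-of-function-intolerance probability.
    """

    gene_id: str
    chrom: str
    exons: list[tuple[int, int]]
    strand: str = "+"
    tier: int = 0
    inheritance: str = "NA"
    pli: float = 0.0
    median_tpm: float | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: at least one exon required")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        if not 0.0 <= self.pli <= 1.0:
            raise ValueError(f"gene {self.gene_id}: pli outside [0,1]")
        if self.tier == 1 and self.inheritance not in ("AD", "AR"):
            raise ValueError(f"gene {self.gene_id}: tier-1 gene needs AD/AR inheritance")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def junctions(self) -> list[tuple[int, int]]:
        """Annotated splice junctions: (donor, acceptor) coordinate pairs of
        adjacent exon ends, donor < acceptor in coordinate order."""
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    @property
    def junction_endpoints(self) -> list[int]:
        return [c for j in self.junctions for c in j]


def genes_to_frame(genes: list[GeneModel]) -> pd.DataFrame:
    rows = []
    for g in genes:
        rows.append(
            dict(
                gene_id=g.gene_id,
                chrom=g.chrom,
                strand=g.strand,
                tier=g.tier,
                inheritance=g.inheritance,
                pli=g.pli,
                median_tpm=np.nan if g.median_tpm is None else g.median_tpm,
                exons=";".join(f"{s}-{e}" for s, e in g.exons),
            )
        )
    return pd.DataFrame(rows)


def frame_to_genes(df: pd.DataFrame) -> list[GeneModel]:
    genes = []
    for row in df.itertuples(index=False):
        exons = [tuple(map(int, x.split("-"))) for x in row.exons.split(";")]
        tpm = None if pd.isna(row.median_tpm) else float(row.median_tpm)
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                chrom=row.chrom,
                exons=exons,
                strand=row.strand,
                tier=int(row.tier),
                inheritance=row.inheritance,
                pli=float(row.pli),
                median_tpm=tpm,
            )
        )
    return genes


@dataclass
class JunctionCountSet:
    """Per-sample split-read counts per junction and split/non-split counts
    per splice site.

    ``junctions``: index junction_id, columns gene_id, donor, acceptor
    (donor < acceptor).  ``split_counts``: samples x junction_id integer
    matrix.  ``sites``: index site_id, columns gene_id, pos.  ``site_split``
    / ``site_nonsplit``: samples x site_id integer matrices.
    """

    junctions: pd.DataFrame
    split_counts: pd.DataFrame
    sites: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["gene_id", "pos"]))
    site_split: pd.DataFrame | None = None
    site_nonsplit: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        bad = self.junctions["donor"] >= self.junctions["acceptor"]
        if bad.any():
            raise ValueError("junctions must satisfy donor < acceptor")
        for m in (self.split_counts, self.site_split, self.site_nonsplit):
            if m is not None and (np.asarray(m) < 0).any():
                raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.split_counts.index)


def filter_junctions(counts: JunctionCountSet, min_count: int = 15) -> JunctionCountSet:
    """Drop junctions and sites whose maximum count across samples is below
    ``min_count`` (a junction seen with >= min_count reads in at least one
    sample is kept)."""
    keep_j = counts.split_counts.columns[counts.split_counts.max(axis=0) >= min_count]
    junctions = counts.junctions.loc[keep_j]
    split = counts.split_counts[keep_j]
    sites, ssplit, snon = counts.sites, counts.site_split, counts.site_nonsplit
    if ssplit is not None:
        tot = ssplit + snon
        keep_s = ssplit.columns[tot.max(axis=0) >= min_count]
        sites = counts.sites.loc[keep_s]
        ssplit = ssplit[keep_s]
        snon = snon[keep_s]
    if len(junctions) == 0 and (ssplit is None or ssplit.shape[1] == 0):
        warnings.warn("junction filter removed every junction and site")
    return JunctionCountSet(junctions, split, sites, ssplit, snon)


# ---------------------------------------------------------------------------
# ψ metrics
# ---------------------------------------------------------------------------

@dataclass
class PsiMatrix:
    """ψ values with the underlying (k, n) binomial pairs.

    ``psi`` is NaN where the denominator is zero (undefined, never
    propagated).  ``site_info`` has one row per tested site with columns
    gene_id, coord_a, coord_b (coord_b is NaN for θ sites).
    """

    metric: str
    psi: pd.DataFrame
    k: pd.DataFrame
    n: pd.DataFrame
    site_info: pd.DataFrame


def compute_psi(counts: JunctionCountSet, metric: str) -> PsiMatrix:
    """Compute one of the three splice metrics.

    ψ5(j) at donor D = split(j) / Σ split over junctions sharing D;
    ψ3 is symmetric over shared acceptors;
    θ(site) = split / (split + nonsplit).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if metric == "theta":
        if counts.site_split is None or counts.site_nonsplit is None:
            raise ValueError("theta requires site-level split/non-split counts")
        k = counts.site_split.astype(float)
        n = (counts.site_split + counts.site_nonsplit).astype(float)
        info = pd.DataFrame(
            {
                "gene_id": counts.sites["gene_id"],
                "coord_a": counts.sites["pos"].astype(float),
                "coord_b": np.nan,
            },
            index=counts.sites.index,
        )
    else:
        key = "donor" if metric == "psi5" else "acceptor"
        k = counts.split_counts.astype(float)
        group = counts.junctions[key]
        # denominator: total split reads over junctions sharing the donor
        # (ψ5) or acceptor (ψ3), within the same gene
        gkey = counts.junctions["gene_id"].astype(str) + ":" + group.astype(str)
        totals = k.T.groupby(gkey.loc[k.columns]).transform("sum").T
        n = totals
        info = pd.DataFrame(
            {
                "gene_id": counts.junctions["gene_id"],
                "coord_a": counts.junctions["donor"].astype(float),
                "coord_b": counts.junctions["acceptor"].astype(float),
            },
            index=counts.junctions.index,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = k / n
    psi = psi.where(n > 0)  # undefined where denominator is zero
    return PsiMatrix(metric, psi, k, n, info)


# ---------------------------------------------------------------------------
# Beta-binomial null
# ---------------------------------------------------------------------------

def betabinom_mom(k: np.ndarray, n: np.ndarray) -> tuple[float, float, float, float]:
    """Method-of-moments beta-binomial fit to (k, n) pairs.

    Matches the mean m and variance v of the per-observation ratios k/n:
    rho = (v/(m(1-m)) - 1/n̄) / (1 - 1/n̄) with n̄ the mean denominator,
    then alpha = m(1/rho - 1), beta = (1-m)(1/rho - 1).  Returns
    (pi, alpha, beta, rho); alpha/beta are NaN when rho <= 0 (no
    overdispersion beyond binomial).
    """
    k = np.asarray(k, float)
    n = np.asarray(n, float)
    p = k / n
    m = float(p.mean())
    v = float(p.var())
    nbar = float(n.mean())
    denom = m * (1.0 - m)
    if denom <= 0 or nbar <= 1:
        return m, np.nan, np.nan, 0.0
    rho = (v / denom - 1.0 / nbar) / (1.0 - 1.0 / nbar)
    if rho <= 0:
        return m, np.nan, np.nan, 0.0
    rho = min(rho, 1.0 - 1e-9)
    s = 1.0 / rho - 1.0
    return m, m * s, (1.0 - m) * s, rho


@dataclass
class NullFit:
    """Leave-one-out cohort null per (sample, site).

    ``alpha``/``beta`` are LOO method-of-moments beta-binomial parameters
    (NaN where the LOO cohort shows no overdispersion; the null is then
    binomial with probability ``pi``).  ``psi_expected`` is the LOO
    count-weighted mean ψ.  ``logit_mean``/``logit_sd`` are full-cohort
    moments of logit((k+1)/(n+2)) per site, the scale of the Z-score.
    ``tested`` marks sites with >= ``min_samples`` informative samples.
    """

    psi_expected: pd.DataFrame
    pi: pd.DataFrame
    alpha: pd.DataFrame
    beta: pd.DataFrame
    logit_mean: pd.Series
    logit_sd: pd.Series
    tested: pd.Series
    min_samples: int = 3


def fit_null(psimat: PsiMatrix, min_samples: int = 3) -> NullFit:
    """Fit the per-site leave-one-out beta-binomial null.

    Method of moments on the per-sample ratios p_i = k_i/n_i: with mean m
    and variance v of the LOO ratios and mean denominator n̄, the
    overdispersion is rho = (v/(m(1-m)) - 1/n̄) / (1 - 1/n̄); rho <= 0
    falls back to a plain binomial.  Sites with fewer than ``min_samples``
    informative samples are skipped (logged).
    """
    k = psimat.k.to_numpy(float)
    n = psimat.n.to_numpy(float)
    defined = n > 0
    n_inf = defined.sum(axis=0)
    tested = n_inf >= min_samples
    n_skipped = int((~tested).sum())
    if n_skipped:
        logger.info("fit_null: skipped %d sites with < %d informative samples", n_skipped, min_samples)

    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(defined, k / np.where(n > 0, n, 1.0), np.nan)

    # leave-one-out sums over informative samples
    cnt = n_inf[None, :].astype(float)
    sk = np.nansum(k, axis=0, keepdims=True)
    sn = np.nansum(np.where(defined, n, 0.0), axis=0, keepdims=True)
    sp = np.nansum(np.where(defined, p, 0.0), axis=0, keepdims=True)
    sp2 = np.nansum(np.where(defined, p * p, 0.0), axis=0, keepdims=True)

    cnt_loo = np.where(defined, cnt - 1, cnt)
    with np.errstate(invalid="ignore", divide="ignore"):
        exp_psi = np.where(defined, (sk - k) / (sn - n), sk / sn)  # count-weighted LOO mean
        m = (sp - np.where(defined, p, 0.0)) / cnt_loo
        m2 = (sp2 - np.where(defined, p * p, 0.0)) / cnt_loo
        v = np.maximum(m2 - m * m, 0.0)
        nbar = (sn - np.where(defined, n, 0.0)) / cnt_loo
        denom = m * (1.0 - m)
        rho = np.where(denom > 0, (v / np.where(denom > 0, denom, 1.0) - 1.0 / nbar) / (1.0 - 1.0 / nbar), 0.0)
    rho = np.clip(np.nan_to_num(rho, nan=0.0), 0.0, 1.0 - 1e-9)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = 1.0 / rho - 1.0
        alpha = np.where(rho > 0, m * s, np.nan)
        beta = np.where(rho > 0, (1.0 - m) * s, np.nan)

    # full-cohort logit moments with pseudocount 1 / 2
    logit = np.where(defined, np.log((k + 1.0) / (n - k + 1.0)), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lmean = np.nanmean(logit, axis=0)
        lsd = np.nanstd(logit, axis=0)

    cols = psimat.psi.columns
    idx = psimat.psi.index

    def _df(a):
        return pd.DataFrame(a, index=idx, columns=cols)

    return NullFit(
        psi_expected=_df(exp_psi),
        pi=_df(m),
        alpha=_df(alpha),
        beta=_df(beta),
        logit_mean=pd.Series(lmean, index=cols),
        logit_sd=pd.Series(lsd, index=cols),
        tested=pd.Series(tested, index=cols),
        min_samples=min_samples,
    )


def _betabinom_pvalue(k: np.ndarray, n: np.ndarray, pi: np.ndarray,
                      alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Two-sided p-value by doubling the smaller tail, capped at 1.

    Beta-binomial where the moment fit found overdispersion, binomial
    otherwise.  Both tails include the observed value.
    """
    k = np.asarray(k, float)
    n = np.asarray(n, float)
    use_bb = np.isfinite(alpha) & np.isfinite(beta)
    lo = np.empty_like(k)
    hi = np.empty_like(k)
    kk = np.round(k).astype(int)
    nn = np.round(n).astype(int)
    if use_bb.any():
        a = alpha[use_bb]
        b = beta[use_bb]
        kb = kk[use_bb]
        nb = nn[use_bb]
        # vectorized lower tail: accumulate pmf over the support up to k
        # (scipy's betabinom.cdf falls back to per-point summation)
        cdf = np.zeros(kb.shape)
        pmf_k = np.zeros(kb.shape)
        for j in range(int(kb.max()) + 1):
            live = j <= kb
            pj = np.exp(stats.betabinom.logpmf(j, nb[live], a[live], b[live]))
            cdf[live] += pj
            at_k = kb[live] == j
            pmf_k[live] = np.where(at_k, pj, pmf_k[live])
        cdf = np.minimum(cdf, 1.0)
        lo[use_bb] = cdf
        hi[use_bb] = np.clip(1.0 - cdf + pmf_k, 0.0, 1.0)
    if (~use_bb).any():
        pr = np.clip(pi[~use_bb], 0.0, 1.0)
        lo[~use_bb] = stats.binom.cdf(kk[~use_bb], nn[~use_bb], pr)
        hi[~use_bb] = stats.binom.sf(kk[~use_bb] - 1, nn[~use_bb], pr)
    return np.minimum(1.0, 2.0 * np.minimum(lo, hi))


# ---------------------------------------------------------------------------
# Outlier calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutlierThresholds:
    """Significance rule for an outlier splicing event."""

    fdr: float = 0.2
    min_abs_z: float = 1.0
    min_abs_dpsi: float = 0.2
    expected_low: float = 0.1
    expected_high: float = 0.9

    def __post_init__(self) -> None:
        for name in ("fdr", "expected_low", "expected_high"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"threshold {name}={v} outside [0,1]")
        if not 0.0 <= self.min_abs_dpsi <= 1.0:
            raise ValueError("min_abs_dpsi outside [0,1]")


OUTLIER_COLUMNS = [
    "sample", "gene_id", "metric", "site_id", "coord_a", "coord_b",
    "psi_obs", "psi_expected", "delta_psi", "zscore", "pvalue", "fdr",
    "significant",
]


def call_outliers(
    psimat: PsiMatrix,
    null: NullFit,
    thresholds: OutlierThresholds = OutlierThresholds(),
    include_nonsignificant: bool = False,
) -> pd.DataFrame:
    """Call per-sample outlier splicing events for one metric.

    Returns a long-format table of SpliceOutlier records.  The FDR is
    Benjamini-Hochberg within each sample across that sample's tested
    sites; ties in p are broken by site coordinate for determinism.
    Events mapping to zero genes or to multiple genes (comma-separated
    gene_id) are excluded before output.
    """
    info = psimat.site_info
    gene_ids = info["gene_id"].astype(str)
    single_gene = gene_ids.str.len().gt(0) & ~gene_ids.str.contains(",")
    cols = psimat.psi.columns[null.tested.to_numpy() & single_gene.to_numpy()]
    if len(cols) == 0:
        return pd.DataFrame(columns=OUTLIER_COLUMNS)

    order = info.loc[cols].sort_values(["gene_id", "coord_a", "coord_b"]).index
    k = psimat.k[order].to_numpy(float)
    n = psimat.n[order].to_numpy(float)
    defined = n > 0
    pval = np.full(k.shape, np.nan)
    pval[defined] = _betabinom_pvalue(
        k[defined], n[defined],
        null.pi[order].to_numpy(float)[defined],
        null.alpha[order].to_numpy(float)[defined],
        null.beta[order].to_numpy(float)[defined],
    )

    logit = np.where(defined, np.log((k + 1.0) / (n - k + 1.0)), np.nan)
    sd = null.logit_sd[order].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (logit - null.logit_mean[order].to_numpy(float)) / sd, 0.0)
    z = np.where(defined, z, np.nan)

    psi = psimat.psi[order].to_numpy(float)
    exp_psi = null.psi_expected[order].to_numpy(float)
    dpsi = psi - exp_psi

    # BH within each sample across its tested, defined sites
    fdr = np.full(pval.shape, np.nan)
    for i in range(pval.shape[0]):
        mask = np.isfinite(pval[i])
        if mask.any():
            fdr[i, mask] = stats.false_discovery_control(pval[i, mask], method="bh")

    sig = (
        (fdr < thresholds.fdr)
        & (np.abs(z) >= thresholds.min_abs_z)
        & (np.abs(dpsi) >= thresholds.min_abs_dpsi)
        & ((exp_psi <= thresholds.expected_low) | (exp_psi >= thresholds.expected_high))
    )
    sig = np.where(np.isfinite(pval), sig, False).astype(bool)

    rows_mask = sig if not include_nonsignificant else defined
    si, sj = np.nonzero(rows_mask)
    info_o = info.loc[order]
    out = pd.DataFrame(
        {
            "sample": np.asarray(psimat.psi.index)[si],
            "gene_id": info_o["gene_id"].to_numpy()[sj],
            "metric": psimat.metric,
            "site_id": np.asarray(order)[sj],
            "coord_a": info_o["coord_a"].to_numpy(float)[sj],
            "coord_b": info_o["coord_b"].to_numpy(float)[sj],
            "psi_obs": psi[si, sj],
            "psi_expected": exp_psi[si, sj],
            "delta_psi": dpsi[si, sj],
            "zscore": z[si, sj],
            "pvalue": pval[si, sj],
            "fdr": fdr[si, sj],
            "significant": sig[si, sj],
        }
    )
    return out.reset_index(drop=True)


def find_splice_outliers(
    counts: JunctionCountSet,
    metrics: tuple[str, ...] = METRICS,
    min_count: int = 15,
    thresholds: OutlierThresholds = OutlierThresholds(),
    min_samples: int = 3,
) -> pd.DataFrame:
    """Filter junctions, compute each metric, fit nulls and call outliers;
    returns the concatenated significant events across metrics."""
    filtered = filter_junctions(counts, min_count=min_count)
    frames = []
    for metric in metrics:
        if metric == "theta" and filtered.site_split is None:
            continue
        psimat = compute_psi(filtered, metric)
        if psimat.psi.shape[1] == 0:
            continue
        null = fit_null(psimat, min_samples=min_samples)
        frames.append(call_outliers(psimat, null, thresholds))
    if not frames:
        return pd.DataFrame(columns=OUTLIER_COLUMNS)
    return pd.concat(frames, ignore_index=True)
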
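"""Tissue confirmation of screened DNA variants.

A screened variant is *confirmed* when a significant outlier splicing
event exists in the same gene and the same carrier sample within
±100 bp (inclusive) of the event's altered splicing boundaries — the
donor/acceptor coordinates of the outlier junction, or the site
coordinate for θ (intron-retention) events.  A variant whose gene and
carrier show a significant event only beyond that window is
*indeterminate* and excluded from model training and evaluation;
everything else is *unconfirmed*.

The module also provides the univariable enrichment comparison between
confirmed and unconfirmed variants (Mann-Whitney U for continuous
features, Fisher's exact test for binary features) and the report of
orphan events — significant events in genes of interest with no candidate
DNA variant nearby.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .variant_screen import _carrier_list

CONTINUOUS_FEATURES = ["max_delta", "dist_junction", "median_tpm"]
BINARY_FEATURES = ["is_snv", "in_branchpoint", "in_low_complexity", "in_repeat"]


def _event_distance(pos: int, coord_a: float, coord_b: float) -> float:
    d = abs(pos - coord_a)
    if np.isfinite(coord_b):
        d = min(d, abs(pos - coord_b))
    return d


def label_variants(
    screened: pd.DataFrame,
    outliers: pd.DataFrame,
    window: int = 100,
) -> pd.DataFrame:
    """Assign confirmed / unconfirmed / indeterminate to each screened
    variant by matching significant splice outliers.

    The three labels partition the screened set; matching requires the
    variant's carrier sample to be the outlier sample, and the window
    test is inclusive (distance <= window confirms).  Deterministic and
    independent of input order.
    """
    events = outliers.loc[outliers["significant"]] if "significant" in outliers else outliers
    by_key: dict[tuple[str, str], list[tuple[float, float, int]]] = {}
    for i, ev in enumerate(events.itertuples(index=False)):
        by_key.setdefault((ev.gene_id, ev.sample), []).append((ev.coord_a, ev.coord_b, i))

    labels, match_idx, match_dist = [], [], []
    for _, var in screened.iterrows():
        carriers = _carrier_list(var["sample"])
        if not carriers:
            raise ValueError(f"variant {var.get('variant_id', '?')} has no carrier sample")
        pos = int(var["pos"])
        cands: list[tuple[float, int]] = []
        for s in carriers:
            for ca, cb, i in by_key.get((var["gene_id"], s), []):
                cands.append((_event_distance(pos, ca, cb), i))
        if not cands:
            labels.append("unconfirmed")
            match_idx.append(-1)
            match_dist.append(np.nan)
            continue
        d, i = min(cands)
        if d <= window:
            labels.append("confirmed")
            match_idx.append(i)
            match_dist.append(d)
        else:
            labels.append("indeterminate")
            match_idx.append(-1)
            match_dist.append(d)

    out = screened.copy()
    out["label"] = labels
    out["matched_event"] = [
        events.index[i] if i >= 0 else None for i in match_idx
    ]
    out["matched_distance"] = match_dist
    return out


def univariate_enrichment(labeled: pd.DataFrame) -> pd.DataFrame:
    """Per-feature two-sided tests of confirmed vs unconfirmed variants:
    Mann-Whitney U for continuous features, Fisher's exact for binary.
    Indeterminate variants are excluded; a degenerate (all-identical)
    feature yields p = 1 with a warning."""
    conf = labeled.loc[labeled["label"] == "confirmed"]
    unconf = labeled.loc[labeled["label"] == "unconfirmed"]
    if len(conf) < 2 or len(unconf) < 2:
        raise ValueError("univariate_enrichment needs >= 2 confirmed and >= 2 unconfirmed variants")
    rows = []
    for feat in CONTINUOUS_FEATURES:
        a = conf[feat].dropna().to_numpy(float)
        b = unconf[feat].dropna().to_numpy(float)
        if len(np.unique(np.concatenate([a, b]))) < 2:
            warnings.warn(f"feature {feat} is constant; p set to 1")
            stat, p = np.nan, 1.0
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(dict(feature=feat, test="mannwhitneyu", statistic=stat, pvalue=p,
                         mean_confirmed=a.mean(), mean_unconfirmed=b.mean()))
    for feat in BINARY_FEATURES:
        a = conf[feat].astype(bool)
        b = unconf[feat].astype(bool)
        table = [[int(a.sum()), int((~a).sum())], [int(b.sum()), int((~b).sum())]]
        if (a.nunique() < 2 and b.nunique() < 2 and a.iloc[0] == b.iloc[0]):
            warnings.warn(f"feature {feat} is constant; p set to 1")
            stat, p = np.nan, 1.0
        else:
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            stat, p = float(odds), float(p)
        rows.append(dict(feature=feat, test="fisher", statistic=stat, pvalue=p,
                         mean_confirmed=float(a.mean()), mean_unconfirmed=float(b.mean())))
    return pd.DataFrame(rows).set_index("feature")


def orphan_events(
    outliers: pd.DataFrame,
    screened: pd.DataFrame,
    gene_set: set[str] | list[str],
    window: int = 100,
) -> pd.DataFrame:
    """Significant events in ``gene_set`` genes whose carrier sample has no
    screened variant within ``window`` bp of the event boundaries.  These
    are reported only, never fed to model training."""
    gene_set = set(gene_set)
    events = outliers.loc[outliers["significant"]] if "significant" in outliers else outliers
    events = events.loc[events["gene_id"].isin(gene_set)]
    if len(events) == 0:
        return events
    var_by_key: dict[tuple[str, str], list[int]] = {}
    for _, var in screened.iterrows():
        for s in _carrier_list(var["sample"]):
            var_by_key.setdefault((var["gene_id"], s), []).append(int(var["pos"]))
    orphan = []
    for idx, ev in events.iterrows():
        positions = var_by_key.get((ev["gene_id"], ev["sample"]), [])
        if not any(_event_distance(p, ev["coord_a"], ev["coord_b"]) <= window for p in positions):
            orphan.append(idx)
    return events.loc[orphan]
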
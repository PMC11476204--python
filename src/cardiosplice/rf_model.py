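"""Random-forest prediction of tissue-confirmed splice-disrupting variants.

Four feature sets are compared:

* model 1 — the maximum splice Δ score only;
* model 2 — DNA variant features without Δ scores (distance to the
  nearest annotated junction, SNV/indel, branchpoint / low-complexity /
  repeat membership);
* model 3 — model 2 plus the gene's median myocardial expression (TPM);
* model 4 — everything (model 3 plus the maximum Δ score).

Because confirmed variants are a small minority (~1:80), training either
weights classes inversely to their frequency or oversamples the minority
class with SMOTE (synthetic points on segments between minority nearest
neighbors).  Performance is assessed with stratified k-fold
cross-validation: AUC, sensitivity, specificity, a Haldane-Anscombe
corrected odds ratio (0.5 added to each confusion cell) and Fisher's
exact p on the raw confusion table, plus a bias-variance decomposition
over bootstrap refits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

FEATURE_SETS: dict[int, list[str]] = {
    1: ["max_delta"],
    2: ["dist_junction", "is_snv", "in_branchpoint", "in_low_complexity", "in_repeat"],
    3: ["dist_junction", "is_snv", "in_branchpoint", "in_low_complexity", "in_repeat",
        "median_tpm"],
    4: ["dist_junction", "is_snv", "in_branchpoint", "in_low_complexity", "in_repeat",
        "median_tpm", "max_delta"],
}


@dataclass(frozen=True)
class ModelConfig:
    feature_set: int = 4
    imbalance: str = "weighted"  # weighted | smote | none
    n_trees: int = 500
    smote_k: int = 5
    vote_threshold: float = 0.5
    seed: int = 0
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"feature_set must be in {sorted(FEATURE_SETS)}")
        if self.imbalance not in ("weighted", "smote", "none"):
            raise ValueError("imbalance must be weighted, smote or none")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class EvalMetrics:
    auc: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    fn: int
    tn: int
    or_ha: float
    fisher_p: float
    bias2: float = float("nan")
    variance: float = float("nan")
    mse: float = float("nan")

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def make_training_set(labeled: pd.DataFrame, feature_set: int) -> tuple[pd.DataFrame, pd.Series]:
    """Build (X, y) from a labeled variant table.

    Indeterminate variants are dropped; rows with any missing value in the
    chosen feature set are omitted (missing values are never imputed) and
    counted in ``X.attrs['n_dropped_missing']``.  y = 1 for confirmed.
    """
    cols = FEATURE_SETS[feature_set]
    df = labeled.loc[labeled["label"].isin(["confirmed", "unconfirmed"])]
    X = df[cols].astype(float)
    complete = X.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    X = X.loc[complete]
    y = (df.loc[complete, "label"] == "confirmed").astype(int)
    if y.nunique() < 2:
        raise ValueError("training set must contain both classes")
    X.attrs["n_dropped_missing"] = n_dropped
    return X, y


def smote_oversample(
    X_minority: np.ndarray,
    k: int,
    n_new: int,
    seed: int | np.random.Generator = 0,
    binary_cols: np.ndarray | None = None,
) -> np.ndarray:
    """Generate ``n_new`` synthetic minority rows.

    Each synthetic row is x + lam * (x_nn - x) for a uniformly chosen one
    of x's k nearest minority neighbors (Euclidean distance on
    continuous features standardized to unit variance) with
    lam ~ Uniform(0, 1).  Binary columns are copied from the nearer
    parent: from x when lam < 0.5, else from the neighbor.
    """
    X = np.asarray(X_minority, float)
    if len(X) < 2:
        raise ValueError("SMOTE needs at least 2 minority rows")
    if k > len(X) - 1:
        raise ValueError(f"smote_k={k} exceeds minority size - 1 ({len(X) - 1})")
    if n_new == 0:
        return np.empty((0, X.shape[1]))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if binary_cols is None:
        binary_cols = np.array([set(np.unique(col)) <= {0.0, 1.0} for col in X.T])
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X / scale)
    _, idx = nn.kneighbors(X / scale)
    base = rng.integers(0, len(X), size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)  # skip self at position 0
    neigh = idx[base, pick]
    lam = rng.uniform(0.0, 1.0, size=n_new)
    out = X[base] + lam[:, None] * (X[neigh] - X[base])
    if binary_cols.any():
        src = np.where(lam[:, None] < 0.5, X[base], X[neigh])
        out[:, binary_cols] = src[:, binary_cols]
    return out


@dataclass
class FittedModel:
    """A fitted ensemble with the feature list it expects; ``score``
    returns the mean tree probability of the confirmed class."""

    model: RandomForestClassifier
    features: list[str]
    config: ModelConfig

    def score(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.features].to_numpy(float)
        return self.model.predict_proba(X)[:, 1]


def train_model(X: pd.DataFrame, y: pd.Series | np.ndarray, config: ModelConfig) -> FittedModel:
    """Fit the bagged-tree ensemble with the configured imbalance handling.

    ``weighted`` assigns class weights proportional to 1/class_count;
    ``smote`` oversamples the minority class to parity before fitting.
    Deterministic for a fixed config seed.
    """
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ValueError("constant-label y: cannot train a classifier")
    features = list(X.columns) if isinstance(X, pd.DataFrame) else [f"f{i}" for i in range(X.shape[1])]
    Xa = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)

    class_weight = None
    if config.imbalance == "weighted":
        counts = np.bincount(y, minlength=2)
        class_weight = {0: 1.0 / counts[0], 1: 1.0 / counts[1]}
    elif config.imbalance == "smote":
        rng = np.random.default_rng(config.seed)
        minority = int(np.bincount(y).argmin())
        Xm = Xa[y == minority]
        n_new = int(np.sum(y != minority) - np.sum(y == minority))
        k = min(config.smote_k, len(Xm) - 1)
        if n_new > 0 and k >= 1:
            synth = smote_oversample(Xm, k=k, n_new=n_new, seed=rng)
            Xa = np.vstack([Xa, synth])
            y = np.concatenate([y, np.full(n_new, minority)])

    rf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features="sqrt",
        class_weight=class_weight,
        random_state=config.seed % (2**32),
        n_jobs=1,
    )
    rf.fit(Xa, y)
    return FittedModel(model=rf, features=features, config=config)


def haldane_anscombe_or(tp: int, fp: int, fn: int, tn: int) -> float:
    """Odds ratio with 0.5 added to each cell (finite for any table)."""
    return ((tp + 0.5) * (tn + 0.5)) / ((fp + 0.5) * (fn + 0.5))


def evaluate(scores: np.ndarray, y_true: np.ndarray, config: ModelConfig) -> EvalMetrics:
    """Metrics of a score vector against labels.

    AUC is the rank (Mann-Whitney) statistic with ties averaged; the
    confusion table is taken at ``vote_threshold`` (score >= threshold
    predicts confirmed); the odds ratio is Haldane-Anscombe corrected
    while Fisher's exact p uses the raw table.  Single-class labels leave
    the AUC undefined (NaN).
    """
    scores = np.asarray(scores, float)
    y = np.asarray(y_true, int)
    auc = float("nan") if len(np.unique(y)) < 2 else float(roc_auc_score(y, scores))
    pred = scores >= config.vote_threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    _, fisher_p = stats.fisher_exact([[tp, fp], [fn, tn]], alternative="two-sided")
    return EvalMetrics(
        auc=auc, sensitivity=sens, specificity=spec,
        tp=tp, fp=fp, fn=fn, tn=tn,
        or_ha=haldane_anscombe_or(tp, fp, fn, tn),
        fisher_p=float(fisher_p),
    )


@dataclass
class CVResult:
    fold_metrics: list[EvalMetrics]
    pooled: EvalMetrics
    oof_scores: pd.Series
    final_model: FittedModel
    y: pd.Series = field(repr=False, default=None)


def cross_validate(labeled: pd.DataFrame, config: ModelConfig) -> CVResult:
    """Stratified k-fold cross-validation of one model configuration.

    Imbalance handling (weights or SMOTE) is applied strictly inside the
    training folds; pooled metrics are computed on the concatenated
    out-of-fold scores.  The final model is refit on all rows before
    application to new cohorts.
    """
    X, y = make_training_set(labeled, config.feature_set)
    if y.sum() < config.cv_folds or (len(y) - y.sum()) < config.cv_folds:
        raise ValueError("need at least cv_folds members of each class for stratification")
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                          random_state=config.seed % (2**32))
    oof = pd.Series(np.nan, index=X.index)
    fold_metrics = []
    for f, (tr, te) in enumerate(skf.split(X, y)):
        fold_cfg = replace(config, seed=config.seed + 1000 * (f + 1))
        fitted = train_model(X.iloc[tr], y.iloc[tr], fold_cfg)
        s = fitted.score(X.iloc[te])
        oof.iloc[te] = s
        fold_metrics.append(evaluate(s, y.iloc[te], config))
    pooled = evaluate(oof.to_numpy(), y.to_numpy(), config)
    final_model = train_model(X, y, config)
    return CVResult(fold_metrics=fold_metrics, pooled=pooled, oof_scores=oof,
                    final_model=final_model, y=y)


def feature_importance(fitted: FittedModel) -> pd.Series:
    """Impurity-decrease (Gini) importances, normalized to sum to 1."""
    imp = np.asarray(fitted.model.feature_importances_, float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return pd.Series(imp, index=fitted.features).sort_values(ascending=False)


def decompose_scores(score_matrix: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(bias², variance, mse) of repeated scores per point.

    ``score_matrix`` is reps x points with NaN where a point was not
    scored in a repetition; points with fewer than 2 scores are dropped.
    mse = bias² + variance holds exactly by construction.
    """
    S = np.asarray(score_matrix, float)
    y = np.asarray(y, float)
    n_scores = np.isfinite(S).sum(axis=0)
    ok = n_scores >= 2
    if not ok.any():
        raise ValueError("no point was scored at least twice")
    m = np.nanmean(S[:, ok], axis=0)
    msq = np.nanmean(S[:, ok] ** 2, axis=0)
    yk = y[ok]
    mse = msq - 2 * m * yk + yk**2
    bias2 = (m - yk) ** 2
    var = msq - m**2
    return float(bias2.mean()), float(var.mean()), float(mse.mean())


def bias_variance_decomposition(
    labeled: pd.DataFrame,
    config: ModelConfig,
    n_reps: int = 20,
) -> tuple[float, float, float]:
    """Bias²/variance/MSE of the score over bootstrap refits.

    For each of ``n_reps`` bootstrap resamples the model is refit and
    scored on the out-of-bag points.  Per point with >= 2 out-of-bag
    scores s: mse = mean (s - y)², bias² = (mean s - y)², variance =
    mean (s - mean s)²; aggregates are means over points, so
    mse = bias² + variance holds exactly.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    X, y = make_training_set(labeled, config.feature_set)
    Xa, ya = X.to_numpy(float), y.to_numpy(int)
    rng = np.random.default_rng(config.seed)
    n = len(ya)
    S = np.full((n_reps, n), np.nan)
    for r in range(n_reps):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if len(oob) == 0 or len(np.unique(ya[boot])) < 2:
            continue
        cfg = replace(config, seed=config.seed + 7919 * (r + 1))
        fitted = train_model(pd.DataFrame(Xa[boot], columns=X.columns), ya[boot], cfg)
        S[r, oob] = fitted.score(Xa[oob])
    return decompose_scores(S, ya)
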
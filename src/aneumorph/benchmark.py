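"""Statistical learning benchmark for rupture-status discrimination.

The pipeline mirrors standard clinical shape-benchmark practice:

* unpaired pooled-variance t-tests per feature with Bonferroni correction;
* standardization of the morphometric block (location dummies are appended
  unstandardized), optional PCA retaining 90% of the training variance;
* L1-regularized (LASSO) logistic regression with the regularization
  strength chosen by an inner stratified 5-fold grid search maximizing AUC;
* stratified 5-fold cross-validation repeated 20 times (100 evaluations),
  with all transformers fitted on training folds only;
* ROC metrics: trapezoidal AUC plus accuracy/sensitivity/specificity at the
  ROC point closest to (0, 1);
* frozen-model external validation with bootstrapped ROC summaries;
* the cut-robustness statistic delta' = median / IQR of per-case feature
  differences between two cut configurations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import config_context
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold

from .features import CATEGORIES, ZMI_FEATURES
from .synthetic import LOCATIONS

log = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-3, 2, 30))
PCA_VARIANCE = 0.90
BUP_AUC_THRESHOLD = 0.7


class BenchmarkError(ValueError):
    pass


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Named feature block, optional location dummies, labels and tags."""

    X: pd.DataFrame                      # morphometric features
    y: np.ndarray                        # bool, True = ruptured
    location: list[str] | None = None    # one of the 12 categories, per row
    dataset: list[str] | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=bool)
        if len(self.X) != len(self.y):
            raise BenchmarkError("X and y length mismatch")
        if self.X.isna().any().any():
            raise BenchmarkError("feature matrix contains missing values")

    @property
    def dummies(self) -> pd.DataFrame | None:
        if self.location is None:
            return None
        d = pd.DataFrame(0.0, index=self.X.index, columns=[f"LOC_{l}" for l in LOCATIONS])
        for i, loc in enumerate(self.location):
            if loc not in LOCATIONS:
                raise BenchmarkError(f"unknown location {loc!r}")
            d.iloc[i, list(LOCATIONS).index(loc)] = 1.0
        return d

    @classmethod
    def from_records(cls, records, features=None) -> "FeatureMatrix":
        from .features import feature_frame

        df = feature_frame(records, features=features)
        return cls(
            X=df,
            y=np.array([r.ruptured for r in records]),
            location=[r.location for r in records],
            dataset=[r.dataset for r in records],
        )

    def subset(self, rows) -> "FeatureMatrix":
        rows = np.asarray(rows)
        return FeatureMatrix(
            X=self.X.iloc[rows],
            y=self.y[rows],
            location=[self.location[i] for i in rows] if self.location else None,
            dataset=[self.dataset[i] for i in rows] if self.dataset else None,
        )


@dataclass(frozen=True)
class UnivariateStats:
    table: pd.DataFrame  # columns: t, p, significant
    alpha: float
    d: int


@dataclass(frozen=True)
class ModelConfig:
    """A named model configuration.

    ``features`` is an explicit list, or None for all; ``feature_rule`` may
    be 'bup' (select features with training-partition univariate AUC above
    0.7).  ``use_pca`` applies PCA at 90% retained variance to the
    standardized morphometric block; ``use_location`` appends the 12
    unstandardized location dummies after any PCA.
    """

    name: str
    features: tuple[str, ...] | None = None
    feature_rule: str | None = None
    use_pca: bool = False
    use_location: bool = False
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    exclude_high_order_zmi: bool = False


def named_config(name: str, **overrides) -> ModelConfig:
    """The named model configurations of the benchmark."""
    presets = {
        "MAX": dict(use_pca=True, exclude_high_order_zmi=True),
        "MAX+LOC": dict(use_pca=True, exclude_high_order_zmi=True, use_location=True),
        "BUP": dict(feature_rule="bup"),
        "BUP+LOC": dict(feature_rule="bup", use_location=True),
        "NSI+LOC": dict(features=("NSI",), use_location=True),
        "Zsurf6+LOC": dict(features=("Zsurf_6",), use_location=True),
        "LOC": dict(features=(), use_location=True),
    }
    if name not in presets:
        raise BenchmarkError(f"unknown model config {name!r}")
    kw = dict(presets[name])
    kw.update(overrides)
    return ModelConfig(name=name, **kw)


@dataclass(frozen=True)
class RocMetrics:
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float


@dataclass
class CVResult:
    evaluations: pd.DataFrame      # one row per fold evaluation
    summary: pd.DataFrame          # mean and SD per metric
    final_model: "FittedModel"
    config: ModelConfig
    seed: int


@dataclass
class FittedModel:
    transformer: "DesignTransformer"
    estimator: LogisticRegression
    lam: float
    threshold: float | None = None

    def decision_scores(self, fm: FeatureMatrix) -> np.ndarray:
        design = self.transformer.transform(fm)
        return self.estimator.predict_proba(design)[:, 1]


# ---------------------------------------------------------------------------
# univariate tests
# ---------------------------------------------------------------------------

def univariate_tests(fm: FeatureMatrix, d: int | None = None, alpha: float = 0.05) -> UnivariateStats:
    """Two-sided pooled-variance t-tests per feature, Bonferroni-corrected.

    ``d`` is the Bonferroni corrector; by default the number of feature
    columns in the assembled matrix.
    """
    y = fm.y
    if y.sum() < 2 or (~y).sum() < 2:
        raise BenchmarkError("each class needs at least 2 samples")
    if d is None:
        d = fm.X.shape[1]
    a, b = fm.X.values[y], fm.X.values[~y]
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    cutoff = alpha / d
    table = pd.DataFrame(
        {"t": t, "p": p, "significant": p < cutoff}, index=fm.X.columns
    )
    return UnivariateStats(table=table, alpha=alpha, d=int(d))


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

class DesignTransformer:
    """Training-fitted standardization (+ optional PCA) of the feature block.

    The morphometric block is centered/scaled with training statistics;
    zero-variance training columns are dropped with a warning.  PCA keeps
    the smallest number of components reaching 90% of the training
    variance.  Location dummies are appended unstandardized.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        self.columns_: list[str] | None = None
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None
        self.pca_: PCA | None = None
        self.n_components_: int | None = None

    def fit(self, fm: FeatureMatrix) -> "DesignTransformer":
        cols = self._select_columns(fm)
        X = fm.X[cols].values
        std = X.std(axis=0, ddof=0)
        keep = std > 1e-12
        if not keep.all():
            dropped = [c for c, k in zip(cols, keep) if not k]
            log.warning("dropping zero-variance features: %s", dropped)
            cols = [c for c, k in zip(cols, keep) if k]
            X = fm.X[cols].values
            std = std[keep]
        self.columns_ = cols
        self.mean_ = X.mean(axis=0)
        self.std_ = std
        if self.config.use_pca and len(cols) > 1:
            z = (X - self.mean_) / self.std_
            pca = PCA(svd_solver="full")
            pca.fit(z)
            cum = np.cumsum(pca.explained_variance_ratio_)
            k = int(np.searchsorted(cum, PCA_VARIANCE) + 1)
            self.pca_ = pca
            self.n_components_ = k
        return self

    def _select_columns(self, fm: FeatureMatrix) -> list[str]:
        cfg = self.config
        if cfg.features is not None:
            missing = [f for f in cfg.features if f not in fm.X.columns]
            if missing:
                raise BenchmarkError(f"features not in matrix: {missing}")
            return list(cfg.features)
        cols = list(fm.X.columns)
        if cfg.exclude_high_order_zmi:
            high = {f for f in ZMI_FEATURES if int(f.split("_")[1]) >= 10}
            cols = [c for c in cols if c not in high]
        if cfg.feature_rule == "bup":
            cols = _best_univariate(fm, cols)
        return cols

    def transform(self, fm: FeatureMatrix) -> np.ndarray:
        if self.columns_ is None:
            raise BenchmarkError("transformer not fitted")
        blocks = []
        if self.columns_:
            z = (fm.X[self.columns_].values - self.mean_) / self.std_
            if self.pca_ is not None:
                z = self.pca_.transform(z)[:, : self.n_components_]
            blocks.append(z)
        if self.config.use_location:
            d = fm.dummies
            if d is None:
                raise BenchmarkError("config requires location but records have none")
            blocks.append(d.values)
        if not blocks:
            raise BenchmarkError("empty design matrix")
        return np.hstack(blocks)


def _best_univariate(fm: FeatureMatrix, cols: list[str]) -> list[str]:
    """Features whose empirical AUC on this (training) partition exceeds 0.7.

    AUC is computed on the raw feature by rank statistics and symmetrized
    (max of AUC and 1-AUC), so inversely oriented features qualify too.
    """
    y = fm.y
    out = []
    for c in cols:
        a = roc_auc_score(y, fm.X[c].values)
        if max(a, 1.0 - a) > BUP_AUC_THRESHOLD:
            out.append(c)
    if not out:
        log.warning("no feature passed the univariate AUC threshold; keeping all")
        return cols
    return out


def assemble_design(fm_train: FeatureMatrix, config: ModelConfig):
    """Fit a :class:`DesignTransformer` on training rows; return (design, t)."""
    t = DesignTransformer(config).fit(fm_train)
    return t.transform(fm_train), t


# ---------------------------------------------------------------------------
# model fitting and metrics
# ---------------------------------------------------------------------------

def fit_lasso_lr(
    design: np.ndarray,
    y: np.ndarray,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    seed: int = 0,
    inner_folds: int = 5,
) -> tuple[LogisticRegression, float]:
    """L1 logistic regression with lambda chosen by inner stratified CV.

    The grid value maximizing mean inner-fold AUC wins; ties go to the
    strongest regularization.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise BenchmarkError("need both classes to fit")
    n_min = np.bincount(y).min()
    folds = int(min(inner_folds, n_min))
    lambda_grid = np.asarray(sorted(lambda_grid))
    with config_context(skip_parameter_validation=True, assume_finite=True):
        if folds >= 2:
            cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            scores = np.zeros(len(lambda_grid))
            counts = np.zeros(len(lambda_grid))
            for tr, te in cv.split(design, y):
                if len(np.unique(y[te])) < 2:
                    continue
                for i, lam in enumerate(lambda_grid):
                    m = _lasso(lam, seed).fit(design[tr], y[tr])
                    s = design[te] @ m.coef_.ravel() + m.intercept_[0]
                    scores[i] += _fast_auc(y[te], s)
                    counts[i] += 1
            mean_scores = scores / np.maximum(counts, 1)
            # argmax with ties resolved toward larger lambda (simpler model)
            best = len(mean_scores) - 1 - int(np.argmax(mean_scores[::-1]))
        else:
            best = 0
        lam = float(lambda_grid[best])
        model = _lasso(lam, seed).fit(design, y)
    return model, lam


def _fast_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Rank-statistic AUC (Mann-Whitney), ties by midrank."""
    ranks = stats.rankdata(scores)
    n1 = int(y.sum())
    n0 = len(y) - n1
    return float((ranks[y.astype(bool)].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _lasso(lam: float, seed: int) -> LogisticRegression:
    return LogisticRegression(
        l1_ratio=1.0, C=1.0 / lam, solver="liblinear", random_state=seed,
        max_iter=1000,
    )


def roc_metrics(scores, labels) -> RocMetrics:
    """AUC and the operating point closest to the ideal (0, 1) ROC corner."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise BenchmarkError("ROC metrics need both classes")
    auc = roc_auc_score(y, s)
    fpr, tpr, thr = roc_curve(y, s)
    d2 = fpr**2 + (1.0 - tpr) ** 2
    i = int(np.argmin(d2))
    threshold = float(thr[i])
    pred = s >= threshold
    tp = int((pred & y).sum())
    tn = int((~pred & ~y).sum())
    return RocMetrics(
        auc=float(auc),
        accuracy=(tp + tn) / len(y),
        sensitivity=tp / int(y.sum()),
        specificity=tn / int((~y).sum()),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# cross-validation and external validation
# ---------------------------------------------------------------------------

def cross_validate(
    fm: FeatureMatrix,
    config: ModelConfig,
    folds: int = 5,
    repeats: int = 20,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold evaluation; transformers and lambda are
    fitted on the training folds only.  The final model is refit on all data.
    """
    y = fm.y.astype(int)
    if np.bincount(y, minlength=2).min() < folds:
        raise BenchmarkError("need at least `folds` samples per class")
    rskf = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    rows = []
    for k, (tr, te) in enumerate(rskf.split(fm.X.values, y)):
        fm_tr, fm_te = fm.subset(tr), fm.subset(te)
        design_tr, transformer = assemble_design(fm_tr, config)
        model, lam = fit_lasso_lr(design_tr, fm_tr.y, config.lambda_grid, seed=seed)
        scores = model.predict_proba(transformer.transform(fm_te))[:, 1]
        m = roc_metrics(scores, fm_te.y)
        rows.append(
            {"repeat": k // folds, "fold": k % folds, "lambda": lam,
             "n_components": transformer.n_components_,
             "auc": m.auc, "accuracy": m.accuracy,
             "sensitivity": m.sensitivity, "specificity": m.specificity}
        )
    ev = pd.DataFrame(rows)
    metrics = ["auc", "accuracy", "sensitivity", "specificity"]
    summary = pd.DataFrame({"mean": ev[metrics].mean(), "sd": ev[metrics].std(ddof=1)})

    design_all, transformer = assemble_design(fm, config)
    model, lam = fit_lasso_lr(design_all, fm.y, config.lambda_grid, seed=seed)
    final_scores = model.predict_proba(design_all)[:, 1]
    threshold = roc_metrics(final_scores, fm.y).threshold
    final = FittedModel(transformer=transformer, estimator=model, lam=lam,
                        threshold=threshold)
    return CVResult(evaluations=ev, summary=summary, final_model=final,
                    config=config, seed=seed)


def external_validate(
    final: FittedModel,
    fm_ext: FeatureMatrix,
    resamples: int = 100,
    seed: int = 0,
    refreeze_threshold: bool = False,
) -> pd.DataFrame:
    """Bootstrapped ROC analysis of a frozen model on an external dataset.

    The model, transformer and (by default) the internal operating
    threshold stay frozen; ``resamples`` bootstrap draws of the external
    cohort give mean +/- SD of the metrics.  Single-class resamples are
    redrawn.
    """
    rng = np.random.default_rng(seed)
    scores = final.decision_scores(fm_ext)
    y = fm_ext.y
    n = len(y)
    rows = []
    for _ in range(resamples):
        for _attempt in range(1000):
            idx = rng.integers(0, n, size=n)
            if 0 < y[idx].sum() < n:
                break
        else:
            raise BenchmarkError("could not draw a two-class bootstrap sample")
        s, yy = scores[idx], y[idx]
        auc = roc_auc_score(yy, s)
        thr = final.threshold
        if refreeze_threshold or thr is None:
            thr = roc_metrics(s, yy).threshold
        pred = s >= thr
        tp = int((pred & yy).sum()); tn = int((~pred & ~yy).sum())
        rows.append({
            "auc": float(auc),
            "accuracy": (tp + tn) / n,
            "sensitivity": tp / int(yy.sum()),
            "specificity": tn / int((~yy).sum()),
        })
    ev = pd.DataFrame(rows)
    return pd.DataFrame({"mean": ev.mean(), "sd": ev.std(ddof=1)})


# ---------------------------------------------------------------------------
# cut comparison and correlations
# ---------------------------------------------------------------------------

def delta_prime(diffs: np.ndarray) -> float:
    """median / IQR of per-case differences; quartiles by linear interpolation.

    IQR = 0 with nonzero median is reported as +/- infinity (flagged via a
    warning); IQR = 0 with zero median gives 0.
    """
    d = np.asarray(diffs, dtype=float)
    med = float(np.median(d))
    q1, q3 = np.percentile(d, [25, 75])  # linear interpolation
    iqr = float(q3 - q1)
    if iqr == 0.0:
        if med == 0.0:
            return 0.0
        log.warning("delta': IQR is zero with nonzero median; reporting inf")
        return float(np.sign(med) * np.inf)
    return med / iqr


def compare_cut_configs(
    features_a: pd.DataFrame, features_b: pd.DataFrame
) -> tuple[pd.Series, pd.Series]:
    """Cut-sensitivity statistic delta' per feature and mean per category.

    Rows must be the same cases measured under two cut types (e.g. dome
    vs. ninja).  Returns (delta' per feature, category means; infinite
    entries are excluded from the category averages).
    """
    common = [c for c in features_a.columns if c in features_b.columns]
    if not common:
        raise BenchmarkError("no common features between the two cut types")
    a = features_a.loc[:, common]
    b = features_b.loc[a.index, common]
    dp = pd.Series({c: delta_prime(a[c].values - b[c].values) for c in common})
    cat = pd.Series({c: CATEGORIES.get(c, "other") for c in common})
    finite = dp.replace([np.inf, -np.inf], np.nan)
    means = finite.groupby(cat).mean()
    return dp, means


def feature_correlations(fm: FeatureMatrix, method: str = "pearson") -> pd.DataFrame:
    """Pairwise feature correlations (Spearman = rank transform + Pearson)."""
    if method not in ("pearson", "spearman"):
        raise BenchmarkError("method must be 'pearson' or 'spearman'")
    if len(fm.X) < 3:
        raise BenchmarkError("need at least 3 rows for correlations")
    zero_var = fm.X.std(ddof=0) <= 1e-15
    if zero_var.any():
        log.warning("zero-variance columns in correlation: %s",
                    fm.X.columns[zero_var].tolist())
    return fm.X.corr(method=method)
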
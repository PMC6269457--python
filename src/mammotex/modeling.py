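"""Case-control risk modeling on texture signatures.

Workflow: per-woman bilateral averaging and z-score normalization, an
IQR-based correlation filter (|Pearson r| > 0.90 removes the lower-IQR member
of each pair), elastic-net logistic regression with nested stratified
cross-validation scored by out-of-fold AUC, and model comparison via
DeLong's test for correlated ROC curves plus the category-free net
reclassification improvement (NRI).

The estimator follows the statsmodels idiom: :class:`TextureRiskModel` is
built from a feature table and labels; ``fit()`` returns a
:class:`TextureRiskResults` carrying out-of-fold predictions, the
cross-validated AUC with a bootstrap CI, per-fold hyperparameters, the
selected features from a full-data refit, and a ``summary()`` table.

Normalization is fold-aware by default (scalers fitted on each outer
training fold only); ``zscore_mode='cohort'`` restores whole-cohort scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold


class ModelingError(RuntimeError):
    pass


@dataclass
class ModelConfig:
    outer_folds: int = 10
    inner_folds: int = 5
    l1_ratios: tuple = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    n_penalties: int = 20
    penalty_range: tuple = (1e-2, 1e2)     # C = 1/lambda, log-spaced
    n_bootstrap: int = 2000
    seed: int = 0
    zscore_mode: str = "fold"              # 'fold' or 'cohort'
    max_iter: int = 300

    @property
    def Cs(self) -> np.ndarray:
        return np.logspace(np.log10(self.penalty_range[0]),
                           np.log10(self.penalty_range[1]), self.n_penalties)


# ---------------------------------------------------------------------------
# Aggregation, normalization and filtering


def aggregate_signatures(signature_sets: dict[str, list[np.ndarray]],
                         labels: dict[str, int],
                         columns: list[str]) -> tuple[pd.DataFrame, np.ndarray]:
    """Average each woman's (1 or 2) breast signatures into one row."""
    rows, y = [], []
    for sid, sigs in signature_sets.items():
        if len(sigs) not in (1, 2):
            raise ModelingError(f"{sid}: expected 1 or 2 breast signatures")
        if len(sigs) == 1:
            warnings.warn(f"{sid}: only one breast signature available")
        rows.append(np.mean(sigs, axis=0))
        y.append(labels[sid])
    X = pd.DataFrame(rows, columns=columns, index=list(signature_sets))
    return X, np.asarray(y)


def zscore_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column means, SDs and a keep-mask for non-degenerate columns."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 1e-12
    return mu, sd, keep


def zscore_apply(X: np.ndarray, mu, sd, keep) -> np.ndarray:
    return (X[:, keep] - mu[keep]) / sd[keep]


def correlation_filter(X: pd.DataFrame, threshold: float = 0.90):
    """Remove, from each highly correlated pair, the lower-IQR feature.

    Pairs with |Pearson r| > threshold are visited in decreasing |r| (ties
    broken by column order); for each pair still fully active the member with
    the smaller interquartile range is dropped (IQR tie: drop the later
    column label).  Returns (filtered X, removed labels).
    """
    cols = list(X.columns)
    vals = X.to_numpy(float)
    sd = vals.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    iqr = np.subtract(*np.percentile(vals, [75, 25], axis=0))
    n = len(cols)
    pairs = [(abs(corr[i, j]), i, j) for i in range(n) for j in range(i + 1, n)
             if abs(corr[i, j]) > threshold]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    active = np.ones(n, bool)
    removed = []
    for _, i, j in pairs:
        if not (active[i] and active[j]):
            continue
        if iqr[i] < iqr[j]:
            drop = i
        elif iqr[j] < iqr[i]:
            drop = j
        else:
            drop = j  # tie: later column label
        active[drop] = False
        removed.append(cols[drop])
    return X.loc[:, [c for k, c in enumerate(cols) if active[k]]], removed


# ---------------------------------------------------------------------------
# AUC utilities


def rank_auc(pred: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC by the Mann-Whitney rank statistic (ties counted half)."""
    pred = np.asarray(pred, float)
    labels = np.asarray(labels)
    pos = pred[labels == 1]
    neg = pred[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ModelingError("AUC needs both classes")
    r = stats.rankdata(np.concatenate([pos, neg]))
    return float((r[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2)
                 / (len(pos) * len(neg)))


def bootstrap_auc_ci(pred, labels, n_boot=2000, seed=0, alpha=0.05):
    """Percentile CI from stratified bootstrap of pooled predictions."""
    rng = np.random.default_rng(seed)
    pred = np.asarray(pred, float)
    labels = np.asarray(labels)
    pos_idx = np.nonzero(labels == 1)[0]
    neg_idx = np.nonzero(labels == 0)[0]
    aucs = np.empty(n_boot)
    for k in range(n_boot):
        pi = rng.choice(pos_idx, len(pos_idx))
        ni = rng.choice(neg_idx, len(neg_idx))
        idx = np.concatenate([pi, ni])
        aucs[k] = rank_auc(pred[idx], labels[idx])
    lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Elastic-net logistic regression with nested CV


@dataclass
class TextureRiskResults:
    """Fit artefacts of :class:`TextureRiskModel`."""

    feature_labels: list
    oof_pred: np.ndarray
    labels: np.ndarray
    cv_auc: float
    auc_ci: tuple[float, float]
    fold_assignments: np.ndarray
    fold_hyperparams: list
    final_hyperparams: tuple
    coefficients: pd.Series
    intercept: float

    @property
    def selected_features(self) -> list:
        return list(self.coefficients.index[self.coefficients != 0.0])

    def summary(self) -> str:
        lines = [
            "Elastic-net logistic case-control model (nested CV)",
            "=" * 55,
            f"n = {len(self.labels)}  (cases {int(self.labels.sum())}, "
            f"controls {int((1 - self.labels).sum())})",
            f"features offered: {len(self.feature_labels)}; "
            f"selected (nonzero): {len(self.selected_features)}",
            f"cross-validated AUC: {self.cv_auc:.3f}  "
            f"95% CI [{self.auc_ci[0]:.3f}, {self.auc_ci[1]:.3f}]",
            f"final hyperparameters: l1_ratio={self.final_hyperparams[0]:.2f}, "
            f"C={self.final_hyperparams[1]:.4g}",
            "-" * 55,
        ]
        coefs = self.coefficients[self.coefficients != 0.0]
        for name, beta in coefs.sort_values(key=np.abs, ascending=False).items():
            lines.append(f"{name:>14s}  {beta:+.4f}")
        return "\n".join(lines)


class TextureRiskModel:
    """Penalized logistic case-control model over a per-woman feature table.

    Hyperparameters (elastic-net mixing, penalty strength) are selected per
    outer fold by pooled inner-fold out-of-fold AUC; the reported AUC pools
    the outer out-of-fold predictions, so every woman is predicted exactly
    once by a model that never saw her.
    """

    def __init__(self, X: pd.DataFrame, y, config: ModelConfig | None = None):
        if isinstance(X, np.ndarray):
            X = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
        self.X = X
        self.y = np.asarray(y, int)
        if set(np.unique(self.y)) - {0, 1}:
            raise ModelingError("labels must be binary 0/1")
        self.config = config or ModelConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label",
                       config: ModelConfig | None = None) -> "TextureRiskModel":
        y = df[label_col].to_numpy()
        return cls(df.drop(columns=[label_col]), y, config)

    # -- internals ---------------------------------------------------------

    def _estimator(self, l1_ratio: float, C: float) -> LogisticRegression:
        return LogisticRegression(solver="saga", l1_ratio=l1_ratio, C=C,
                                  max_iter=self.config.max_iter, tol=1e-4,
                                  random_state=self.config.seed)

    def _hyper_grid(self):
        # ordered so argmax tie-breaks toward the strongest penalty
        return [(l1, C) for C in self.config.Cs for l1 in self.config.l1_ratios]

    def _inner_select(self, X: np.ndarray, y: np.ndarray, seed: int):
        grid = self._hyper_grid()
        inner = StratifiedKFold(self.config.inner_folds, shuffle=True, random_state=seed)
        splits = list(inner.split(X, y))
        scores = np.zeros(len(grid))
        for gi, (l1, C) in enumerate(grid):
            oof = np.zeros(len(y))
            for tr, te in splits:
                mu, sd, keep = zscore_fit(X[tr])
                est = self._estimator(l1, C)
                est.fit(zscore_apply(X[tr], mu, sd, keep), y[tr])
                oof[te] = est.predict_proba(zscore_apply(X[te], mu, sd, keep))[:, 1]
            scores[gi] = rank_auc(oof, y)
        return grid[int(np.argmax(scores))]

    def fit(self) -> TextureRiskResults:
        cfg = self.config
        X = self.X.to_numpy(float)
        y = self.y
        if min(np.bincount(y, minlength=2)) < cfg.outer_folds:
            raise ModelingError("too few members of a class for stratified folds")
        outer = StratifiedKFold(cfg.outer_folds, shuffle=True, random_state=cfg.seed)
        oof = np.zeros(len(y))
        fold_of = np.zeros(len(y), int)
        fold_hp = []
        for k, (tr, te) in enumerate(outer.split(X, y)):
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 1:
                raise ModelingError("single-class outer fold")
            l1, C = self._inner_select(X[tr], y[tr], seed=cfg.seed + 1000 + k)
            if cfg.zscore_mode == "cohort":
                mu, sd, keep = zscore_fit(X)
            else:
                mu, sd, keep = zscore_fit(X[tr])
            est = self._estimator(l1, C)
            est.fit(zscore_apply(X[tr], mu, sd, keep), y[tr])
            oof[te] = est.predict_proba(zscore_apply(X[te], mu, sd, keep))[:, 1]
            fold_of[te] = k
            fold_hp.append((l1, C))
        cv_auc = rank_auc(oof, y)
        ci = bootstrap_auc_ci(oof, y, n_boot=cfg.n_bootstrap, seed=cfg.seed + 77)

        # modal hyperparameters across outer folds; ties -> strongest penalty
        uniq, counts = np.unique(np.array(fold_hp), axis=0, return_counts=True)
        best = uniq[counts == counts.max()]
        best = sorted(map(tuple, best), key=lambda t: (t[1], t[0]))[0]
        mu, sd, keep = zscore_fit(X)
        final = self._estimator(best[0], best[1])
        final.fit(zscore_apply(X, mu, sd, keep), y)
        coefs = np.zeros(X.shape[1])
        coefs[keep] = final.coef_.ravel()
        return TextureRiskResults(
            feature_labels=list(self.X.columns), oof_pred=oof, labels=y,
            cv_auc=cv_auc, auc_ci=ci, fold_assignments=fold_of,
            fold_hyperparams=fold_hp, final_hyperparams=best,
            coefficients=pd.Series(coefs, index=list(self.X.columns)),
            intercept=float(final.intercept_[0]),
        )


def fit_elastic_net_cv(X: pd.DataFrame, y, config: ModelConfig | None = None) -> TextureRiskResults:
    return TextureRiskModel(X, y, config).fit()


# ---------------------------------------------------------------------------
# Model comparison: DeLong and NRI


@dataclass
class ComparisonResult:
    delta_auc: float
    delong_p: float
    nri_overall: float
    nri_case_component: float
    nri_control_component: float


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_covariance(preds: np.ndarray, labels: np.ndarray):
    """AUCs and their covariance matrix (DeLong structural components)."""
    pos = preds[:, labels == 1]
    neg = preds[:, labels == 0]
    m, n = pos.shape[1], neg.shape[1]
    k = preds.shape[0]
    aucs = np.empty(k)
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    for r in range(k):
        allr = _midrank(np.concatenate([pos[r], neg[r]]))
        posr = _midrank(pos[r])
        negr = _midrank(neg[r])
        aucs[r] = (allr[:m].sum() - m * (m + 1) / 2) / (m * n)
        v10[r] = (allr[:m] - posr) / n
        v01[r] = 1.0 - (allr[m:] - negr) / m
    s10 = np.cov(v10) if k > 1 else np.atleast_2d(np.var(v10, ddof=1))
    s01 = np.cov(v01) if k > 1 else np.atleast_2d(np.var(v01, ddof=1))
    cov = s10 / m + s01 / n
    return aucs, np.atleast_2d(cov)


def delong_test(pred_a, pred_b, labels) -> tuple[float, float]:
    """Two-sided DeLong test for the AUC difference of paired predictors."""
    pred_a, pred_b = np.asarray(pred_a, float), np.asarray(pred_b, float)
    labels = np.asarray(labels)
    if pred_a.shape != pred_b.shape or pred_a.shape != labels.shape:
        raise ModelingError("predictions must be paired on identical subjects")
    aucs, cov = _delong_covariance(np.vstack([pred_a, pred_b]), labels)
    delta = float(aucs[0] - aucs[1])
    var = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    if var <= 1e-16:
        return delta, 1.0 if abs(delta) < 1e-12 else 0.0
    z = delta / np.sqrt(var)
    return delta, float(2 * stats.norm.sf(abs(z)))


def nri(pred_new, pred_old, labels) -> ComparisonResult:
    """Category-free NRI; 'up' = higher predicted probability under the new
    model.  Case component = P(up|case) - P(down|case); control component =
    P(down|control) - P(up|control); overall = their sum."""
    pred_new, pred_old = np.asarray(pred_new, float), np.asarray(pred_old, float)
    labels = np.asarray(labels)
    if pred_new.shape != pred_old.shape or pred_new.shape != labels.shape:
        raise ModelingError("predictions must be paired on identical subjects")
    up = pred_new > pred_old
    down = pred_new < pred_old
    case = labels == 1
    ctrl = labels == 0
    case_comp = float(up[case].mean() - down[case].mean()) if case.any() else 0.0
    ctrl_comp = float(down[ctrl].mean() - up[ctrl].mean()) if ctrl.any() else 0.0
    delta, p = delong_test(pred_new, pred_old, labels)
    return ComparisonResult(delta_auc=delta, delong_p=p,
                            nri_overall=case_comp + ctrl_comp,
                            nri_case_component=case_comp,
                            nri_control_component=ctrl_comp)


compare_models = nri


# ---------------------------------------------------------------------------
# Baseline augmentation


def _logistic_oof(X: np.ndarray, y: np.ndarray, folds, zscore_mode="fold"):
    oof = np.zeros(len(y))
    for tr, te in folds:
        mu, sd, keep = zscore_fit(X[tr] if zscore_mode == "fold" else X)
        est = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500)
        est.fit(zscore_apply(X[tr], mu, sd, keep), y[tr])
        oof[te] = est.predict_proba(zscore_apply(X[te], mu, sd, keep))[:, 1]
    return oof


def augment_baseline(covariates: pd.DataFrame, texture_X: pd.DataFrame, y,
                     texture_results: TextureRiskResults | None = None,
                     config: ModelConfig | None = None) -> dict:
    """Baseline (covariates-only) vs augmented (covariates + selected texture
    features) logistic models under shared outer folds.

    Rows with missing covariates are dropped with a warning.  Returns a dict
    with both OOF AUCs and the DeLong/NRI comparison.
    """
    config = config or ModelConfig()
    y = np.asarray(y, int)
    cov = covariates.copy()
    ok = ~cov.isna().any(axis=1)
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} women with missing covariates")
        cov = cov.loc[ok.values]
        texture_X = texture_X.loc[ok.values]
        y = y[ok.values]
    if texture_results is None:
        texture_results = TextureRiskModel(texture_X, y, config).fit()
    selected = [c for c in texture_results.selected_features if c in texture_X.columns]
    outer = StratifiedKFold(config.outer_folds, shuffle=True, random_state=config.seed)
    folds = list(outer.split(cov.to_numpy(), y))
    base_oof = _logistic_oof(cov.to_numpy(float), y, folds, config.zscore_mode)
    aug_X = pd.concat([cov, texture_X[selected]], axis=1).to_numpy(float)
    aug_oof = _logistic_oof(aug_X, y, folds, config.zscore_mode)
    comparison = nri(aug_oof, base_oof, y)
    return {
        "baseline_auc": rank_auc(base_oof, y),
        "augmented_auc": rank_auc(aug_oof, y),
        "baseline_oof": base_oof,
        "augmented_oof": aug_oof,
        "selected_texture_features": selected,
        "comparison": comparison,
    }


# ---------------------------------------------------------------------------
# Parameter-grid optimization


@dataclass
class OptimizationResult:
    best_params: dict
    best_results: TextureRiskResults
    table: pd.DataFrame


def repeated_cv_auc(X: pd.DataFrame, y, config: ModelConfig,
                    n_repeats: int = 1) -> tuple[float, TextureRiskResults]:
    """Mean cross-validated AUC over ``n_repeats`` fold partitions.

    Single-partition CV AUC is a noisy model-selection statistic; averaging
    over independent outer-fold seeds stabilizes grid-search argmaxes.
    Returns the mean AUC and the first repeat's full results object.
    """
    import dataclasses as _dc

    aucs = []
    first = None
    for r in range(n_repeats):
        res = TextureRiskModel(X, y, _dc.replace(config, seed=config.seed + 101 * r)).fit()
        if first is None:
            first = res
        aucs.append(res.cv_auc)
    return float(np.mean(aucs)), first


def optimize_parameters(caches_by_D: dict, y, param_tuples: list[tuple],
                        correlation_threshold: float = 0.90,
                        config: ModelConfig | None = None,
                        n_repeats: int = 1) -> OptimizationResult:
    """Grid search over (D, f, a, b, c): rebuild signatures from the cached
    per-breast region data, filter, fit, and return the argmax of the
    cross-validated AUC (averaged over ``n_repeats`` fold partitions).
    Ties break toward smaller D then larger c.
    """
    from .pipeline import signatures_from_caches

    if not param_tuples:
        raise ModelingError("empty parameter grid")
    config = config or ModelConfig()
    rows = []
    best = None
    for (D, f, a, b, c) in param_tuples:
        if D not in caches_by_D:
            raise ModelingError(f"no cached features for D={D}")
        X = signatures_from_caches(caches_by_D[D], a, b, c, f)
        Xf, _ = correlation_filter(X, correlation_threshold)
        auc, res = repeated_cv_auc(Xf, y, config, n_repeats)
        rows.append({"D": D, "f": f, "a": a, "b": b, "c": c,
                     "cv_auc": auc, "n_selected": len(res.selected_features)})
        key = (-auc, D, -c, f, a, b)
        if best is None or key < best[0]:
            best = (key, {"D": D, "f": f, "a": a, "b": b, "c": c}, res)
    return OptimizationResult(best_params=best[1], best_results=best[2],
                              table=pd.DataFrame(rows))
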
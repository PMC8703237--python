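"""Penalized-logistic metabolic surrogates.

Each binary clinical variable c_k is modelled by elastic-net logistic
regression on the z-scaled metabolite panel,

    pi_k = Pr(c_k = 1 | m) = 1 / (1 + exp(-(beta0 + beta' m))),

with the L1/L2 mixing parameter alpha fixed at 0.5 and the penalty weight
lambda chosen by an inner loop of repeated stratified 5-fold cross-validation
minimizing the mean held-out binomial deviance over a log-spaced grid
descending from lambda_max (the smallest lambda that zeroes every
coefficient). The fitted posterior probability pi_k is the (uncalibrated)
"surrogate value" of the clinical variable.

Two evaluation procedures are provided: an outer loop of repeated stratified
5-fold CV (:func:`evaluate_cv`), and leave-one-biobank-out validation
(:func:`evaluate_lobov`) summarized by a test-size-weighted mean AUC. In both,
the full lambda-selection inner loop runs inside each outer training split,
so no outer test data leaks into hyperparameter choice. A model is
conventionally called sufficiently accurate at AUC > 0.7.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata, ttest_ind
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import RepeatedStratifiedKFold

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "SurrogateModel", "EvaluationReport", "auc",
           "train_surrogate", "predict_surrogate", "evaluate_cv",
           "evaluate_lobov", "relative_importance",
           "surrogate_correlations_and_separation", "lambda_grid",
           "fit_enet_logistic"]

#: conventional adequacy threshold for surrogate models
AUC_PASS_THRESHOLD = 0.7


@dataclass
class TrainConfig:
    """Hyperparameters of surrogate training and evaluation.

    ``n_lambda`` log-spaced penalty weights spanning ``lambda_decades``
    decades below lambda_max are searched by ``inner_folds``-fold CV with
    ``inner_repeats`` repetitions (lambda-min rule on mean held-out binomial
    deviance). The outer evaluation loop uses ``outer_folds`` folds and
    ``outer_repeats`` repetitions, stratified by label; fold partitions are
    drawn independently per repeat.
    """

    alpha: float = 0.5
    n_lambda: int = 100
    lambda_decades: float = 4.0
    inner_folds: int = 5
    inner_repeats: int = 5
    outer_folds: int = 5
    outer_repeats: int = 5
    seed: int = 0
    tol: float = 1e-4
    max_iter: int = 500

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0,1]")
        if self.n_lambda < 2:
            raise ValueError("need at least two lambda values")


@dataclass
class SurrogateModel:
    """A deployable surrogate predictor: intercept, coefficients, scaling."""

    name: str
    intercept: float
    coef: np.ndarray
    marker_names: list[str]
    alpha: float
    lambda_: float
    scaling_mean: np.ndarray | None = None
    scaling_sd: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        if len(self.coef) != len(self.marker_names):
            raise ValueError("coefficient length must equal panel size")

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.coef))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema_version": 1,
            "name": self.name,
            "intercept": self.intercept,
            "coef": self.coef.tolist(),
            "marker_names": self.marker_names,
            "alpha": self.alpha,
            "lambda": self.lambda_,
            "scaling_mean": None if self.scaling_mean is None
            else np.asarray(self.scaling_mean).tolist(),
            "scaling_sd": None if self.scaling_sd is None
            else np.asarray(self.scaling_sd).tolist(),
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SurrogateModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            name=d["name"], intercept=d["intercept"],
            coef=np.asarray(d["coef"]), marker_names=d["marker_names"],
            alpha=d["alpha"], lambda_=d["lambda"],
            scaling_mean=None if d["scaling_mean"] is None
            else np.asarray(d["scaling_mean"]),
            scaling_sd=None if d["scaling_sd"] is None
            else np.asarray(d["scaling_sd"]),
            metadata=d.get("metadata", {}),
        )


@dataclass
class EvaluationReport:
    """Per-fold (or per-held-out-cohort) AUCs and their summary."""

    mode: str                     # "cv" | "lobov"
    phenotype: str
    entries: list[dict]           # per fold/cohort: auc, n_test, ...
    mean_auc: float
    weighted_mean_auc: float | None = None   # lobov only
    skipped_cohorts: list[str] = field(default_factory=list)

    @property
    def passes(self) -> bool:
        score = (self.weighted_mean_auc if self.weighted_mean_auc is not None
                 else self.mean_auc)
        return score > AUC_PASS_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), default=float,
                                         indent=2), encoding="utf-8")


# --- elementary operations --------------------------------------------------

def auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney identity.

    Equals the probability that a random positive outscores a random
    negative, with ties counted 1/2. Raises if either class is absent.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    r = rankdata(s)  # average ranks for ties
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def lambda_grid(X: np.ndarray, y: np.ndarray, alpha: float,
                n_lambda: int, decades: float) -> np.ndarray:
    """Descending log-spaced penalty grid from lambda_max.

    lambda_max = max_j |x_j'(y - ybar)| / (n * alpha) is the smallest penalty
    at which the KKT conditions zero every coefficient.
    """
    n = len(y)
    ybar = y.mean()
    lam_max = np.max(np.abs(X.T @ (y - ybar))) / (n * max(alpha, 1e-3))
    return np.geomspace(lam_max, lam_max * 10.0 ** -decades, n_lambda)


def fit_enet_logistic(X: np.ndarray, y: np.ndarray, alpha: float, lam: float,
                      tol: float = 1e-4, max_iter: int = 500,
                      _clf: LogisticRegression | None = None
                      ) -> tuple[float, np.ndarray]:
    """Fit one elastic-net logistic regression at fixed penalty weight.

    Minimizes (1/n) sum log-loss + lam * (alpha*||b||_1 + (1-alpha)/2*||b||_2^2)
    with an unpenalized intercept. Returns (intercept, coefficients).
    """
    n = len(y)
    clf = _clf or LogisticRegression(l1_ratio=alpha, solver="saga",
                                     warm_start=True, tol=tol,
                                     max_iter=max_iter, random_state=0)
    clf.C = 1.0 / (n * lam)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign ConvergenceWarning at tiny lam
        clf.fit(X, y)
    intercept = float(clf.intercept_[0])
    coef = clf.coef_[0].copy()
    if not np.any(coef):
        # with all coefficients zeroed the profile optimum of the
        # unpenalized intercept is exactly logit of the prevalence
        prev = float(np.mean(y))
        intercept = float(np.log(prev / (1.0 - prev)))
    return intercept, coef


def _fit_path(X, y, lambdas, alpha, tol, max_iter):
    """Warm-started fits along a descending lambda path."""
    clf = LogisticRegression(l1_ratio=alpha, solver="saga", warm_start=True,
                             tol=tol, max_iter=max_iter, random_state=0)
    intercepts = np.empty(len(lambdas))
    coefs = np.empty((len(lambdas), X.shape[1]))
    for i, lam in enumerate(lambdas):
        intercepts[i], coefs[i] = fit_enet_logistic(X, y, alpha, lam,
                                                    _clf=clf)
    return intercepts, coefs


def _select_lambda(X, y, lambdas, config: TrainConfig) -> tuple[float, np.ndarray]:
    """Inner repeated stratified k-fold CV; returns (best lambda, mean
    held-out deviance per lambda)."""
    cv = RepeatedStratifiedKFold(n_splits=config.inner_folds,
                                 n_repeats=config.inner_repeats,
                                 random_state=config.seed)
    dev = np.zeros(len(lambdas))
    n_folds = 0
    for tr, te in cv.split(X, y):
        ic, co = _fit_path(X[tr], y[tr], lambdas, config.alpha, config.tol,
                           config.max_iter)
        eta = X[te] @ co.T + ic
        p = 1.0 / (1.0 + np.exp(-eta))
        for i in range(len(lambdas)):
            dev[i] += 2.0 * log_loss(y[te], p[:, i], labels=[0, 1])
        n_folds += 1
    dev /= n_folds
    return float(lambdas[int(np.argmin(dev))]), dev


def train_surrogate(X: np.ndarray, y: np.ndarray, config: TrainConfig,
                    marker_names: list[str] | None = None,
                    name: str = "surrogate",
                    scaling: tuple[np.ndarray, np.ndarray] | None = None
                    ) -> SurrogateModel:
    """Train one surrogate model with inner-CV penalty selection.

    ``X`` must be complete and on the modelling scale (globally z-scaled by
    default policy); ``scaling`` is the (mean, sd) pair that maps raw
    concentrations onto that scale, stored in the model so it can be applied
    to new raw data. ``y`` must contain both classes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if min((y == 0).sum(), (y == 1).sum()) < config.inner_folds:
        raise ValueError("fewer samples in a class than inner CV folds")

    lambdas = lambda_grid(X, y, config.alpha, config.n_lambda,
                          config.lambda_decades)
    best_lam, dev = _select_lambda(X, y, lambdas, config)
    intercept, coef = fit_enet_logistic(X, y, config.alpha, best_lam,
                                        tol=config.tol,
                                        max_iter=config.max_iter)
    mu, sd = (None, None) if scaling is None else scaling
    return SurrogateModel(
        name=name, intercept=intercept, coef=coef,
        marker_names=list(marker_names) if marker_names is not None
        else [f"m{i}" for i in range(X.shape[1])],
        alpha=config.alpha, lambda_=best_lam,
        scaling_mean=mu, scaling_sd=sd,
        metadata={"n": int(len(y)), "prevalence": float(y.mean()),
                  "seed": config.seed, "n_lambda": config.n_lambda,
                  "inner_folds": config.inner_folds,
                  "inner_repeats": config.inner_repeats,
                  "cv_deviance_min": float(dev.min())},
    )


def predict_surrogate(model: SurrogateModel, X_new,
                      marker_names: list[str] | None = None) -> np.ndarray:
    """Posterior probabilities pi = 1/(1 + exp(-(b0 + b'm))) per sample.

    If ``X_new`` is a DataFrame, columns are aligned to the model's panel; a
    mismatch fails naming the offending markers. The model's stored scaling
    (if any) is applied before the linear predictor.
    """
    if isinstance(X_new, pd.DataFrame):
        missing = [m for m in model.marker_names if m not in X_new.columns]
        if missing:
            raise KeyError(f"input lacks model markers: {missing}")
        X = X_new[model.marker_names].to_numpy(dtype=float)
    else:
        X = np.asarray(X_new, dtype=float)
        if marker_names is not None and list(marker_names) != model.marker_names:
            extra = set(marker_names) - set(model.marker_names)
            missing = set(model.marker_names) - set(marker_names)
            raise KeyError(f"marker mismatch; missing={sorted(missing)}, "
                           f"unexpected={sorted(extra)}")
        if X.shape[1] != len(model.marker_names):
            raise ValueError(
                f"expected {len(model.marker_names)} markers, got {X.shape[1]}")
    if model.scaling_mean is not None:
        X = (X - model.scaling_mean) / model.scaling_sd
    eta = model.intercept + X @ model.coef
    return 1.0 / (1.0 + np.exp(-eta))


# --- evaluation -------------------------------------------------------------

def evaluate_cv(X: np.ndarray, y: np.ndarray, config: TrainConfig,
                phenotype: str = "surrogate") -> EvaluationReport:
    """Outer repeated stratified k-fold CV with the full inner lambda
    selection re-run inside each outer training split."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    outer = RepeatedStratifiedKFold(n_splits=config.outer_folds,
                                    n_repeats=config.outer_repeats,
                                    random_state=config.seed + 1)
    entries = []
    for k, (tr, te) in enumerate(outer.split(X, y)):
        model = train_surrogate(X[tr], y[tr], config, name=phenotype)
        score = auc(predict_surrogate(model, X[te]), y[te])
        entries.append({"repeat": k // config.outer_folds,
                        "fold": k % config.outer_folds,
                        "auc": score, "n_test": int(len(te)),
                        "lambda": model.lambda_,
                        "n_selected": model.n_selected})
    mean_auc = float(np.mean([e["auc"] for e in entries]))
    return EvaluationReport(mode="cv", phenotype=phenotype, entries=entries,
                            mean_auc=mean_auc)


def evaluate_lobov(X: np.ndarray, y: np.ndarray, cohorts, config: TrainConfig,
                   phenotype: str = "surrogate") -> EvaluationReport:
    """Leave-one-biobank-out validation.

    Each cohort in turn is held out entirely; the weighted mean AUC uses the
    held-out sample counts as weights. Cohorts whose held-out labels contain
    a single class are skipped with a logged warning (an undefined AUC is not
    evidence), not scored 0.5.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    cohorts = np.asarray(cohorts)
    unique = list(pd.unique(cohorts))
    if len(unique) < 2:
        raise ValueError("LOBOV requires at least two cohorts")
    entries, skipped = [], []
    for c in unique:
        te = cohorts == c
        if len(np.unique(y[te])) < 2:
            logger.warning("LOBOV: cohort %s held-out labels single-class; "
                           "skipped", c)
            skipped.append(str(c))
            continue
        model = train_surrogate(X[~te], y[~te], config, name=phenotype)
        score = auc(predict_surrogate(model, X[te]), y[te])
        entries.append({"cohort": str(c), "auc": score,
                        "n_test": int(te.sum()),
                        "lambda": model.lambda_,
                        "n_selected": model.n_selected})
    if not entries:
        raise ValueError("no cohort had both classes in the held-out set")
    w = np.array([e["n_test"] for e in entries], dtype=float)
    a = np.array([e["auc"] for e in entries])
    return EvaluationReport(
        mode="lobov", phenotype=phenotype, entries=entries,
        mean_auc=float(a.mean()),
        weighted_mean_auc=float((w * a).sum() / w.sum()),
        skipped_cohorts=skipped)


# --- model introspection ----------------------------------------------------

def relative_importance(models: list[SurrogateModel],
                        signed_sum: bool = False) -> pd.DataFrame:
    """Per-model coefficients scaled to relative importances.

    Default scales each model's coefficients by the sum of their absolute
    values, so each row sums to 1 in absolute value and the scaling is
    invariant to multiplying a model's coefficients by a positive constant.
    ``signed_sum=True`` divides by the plain (signed) coefficient sum instead.
    """
    if not models:
        raise ValueError("need at least one model")
    names = models[0].marker_names
    rows = {}
    for m in models:
        if m.marker_names != names:
            raise ValueError("models span different panels")
        denom = (m.coef.sum() if signed_sum else np.abs(m.coef).sum())
        if denom == 0:
            raise ValueError(f"model {m.name} has all-zero coefficients")
        rows[m.name] = m.coef / denom
    return pd.DataFrame(rows, index=names).T


def surrogate_correlations_and_separation(
        surrogates: pd.DataFrame,
        labels: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations between surrogates, plus per-phenotype
    Welch t-tests of the surrogate between TRUE and FALSE label groups.

    Returns ``(correlation matrix, separation table)``; the separation table
    reports group means for the TRUE / FALSE / missing strata. Phenotypes
    without labels get NaN statistics.
    """
    if surrogates.shape[1] < 2:
        raise ValueError("need at least two surrogates")
    sd = surrogates.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(
            f"constant surrogate columns: {list(sd.index[sd == 0])}")
    corr = surrogates.corr(method="pearson")

    rows = []
    for col in surrogates.columns:
        row = {"phenotype": col, "t": np.nan, "p": np.nan,
               "mean_true": np.nan, "mean_false": np.nan,
               "mean_missing": np.nan}
        if labels is not None and col in labels.columns:
            lab = labels[col]
            s = surrogates[col]
            is_na = lab.isna().to_numpy()
            truthy = (lab == 1).fillna(False).to_numpy() if lab.dtype != bool \
                else lab.to_numpy()
            g_true = s[~is_na & truthy]
            g_false = s[~is_na & ~truthy]
            row["mean_true"] = float(g_true.mean()) if len(g_true) else np.nan
            row["mean_false"] = float(g_false.mean()) if len(g_false) else np.nan
            row["mean_missing"] = float(s[is_na].mean()) if is_na.any() else np.nan
            if len(g_true) > 1 and len(g_false) > 1:
                t, p = ttest_ind(g_true, g_false, equal_var=False)
                row["t"], row["p"] = float(t), float(p)
        rows.append(row)
    return corr, pd.DataFrame(rows).set_index("phenotype")
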
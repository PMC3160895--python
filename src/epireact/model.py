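"""Feature selection, logistic-regression fitting and leakage-aware
leave-one-out cross-validation.

Three feature subsets are supported, mirroring a filter-style selection
strategy: subset A keeps all 37 features; subset B removes collinear
features and then runs M5-style backward elimination under the Akaike
criterion on a linear fit; subset C keeps the features with non-zero
coefficients of an L1-penalized logistic fit, with the penalty chosen by
internal 5-fold cross-validated deviance.

The alignment-based features use the class labels of the *other*
peptides, so naive cross-validation leaks the held-out label into the
features.  :func:`loocv` therefore masks the held-out peptide from every
reference maximum, re-learns normalization (and, if requested, the
feature subset) on the remaining n-1 peptides, refits, and only then
scores the held-out peptide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .alignment import AlignmentParams, PairwiseScoreMatrix, \
    alignment_feature_frame, alignment_features, query_alignment_features, \
    score_matrix
from .core import PeptideSet, RunConfig, ValidationError
from .features import ALIGN_FEATURE_NAMES, FEATURE_NAMES, FeatureTable, \
    apply_feature_table, build_feature_table, sequence_features

SUBSETS = {"A": "none", "B": "m5", "C": "lasso"}


def _binary_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if set(arr) - {"positive", "negative"}:
        raise ValidationError("labels must be 'positive'/'negative'")
    return (arr == "positive").astype(float)


# ---------------------------------------------------------------------------
# univariate screening

def single_regression_coefficients(table: pd.DataFrame, labels) -> pd.Series:
    """Univariate regression slope of the 0/1 class on each standardized
    feature (equivalently corr(feature, class) * sd(class)).

    Used as a sign/importance sanity check on fitted multivariate
    coefficients.  Constant features get coefficient 0 with a warning.
    """
    y = _binary_labels(labels)
    out = {}
    for name in table.columns:
        x = table[name].to_numpy(float)
        sd = x.std()
        if sd == 0.0:
            warnings.warn(f"feature {name!r} is constant; SRC set to 0")
            out[name] = 0.0
        else:
            out[name] = float(np.cov(x / sd, y, bias=True)[0, 1])
    return pd.Series(out)


def remove_collinear(table: pd.DataFrame, labels,
                     threshold: float = 0.95) -> list[str]:
    """Greedy collinearity filter: while any pair of kept features has
    |Pearson r| above the threshold, drop the member with the lower
    |SRC| (ties: drop the lexicographically later name)."""
    src = single_regression_coefficients(table, labels).abs()
    kept = list(table.columns)
    with np.errstate(invalid="ignore"):
        corr = np.abs(np.corrcoef(table.to_numpy(float), rowvar=False))
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    pos = {name: i for i, name in enumerate(table.columns)}
    while len(kept) > 1:
        idx = [pos[k] for k in kept]
        sub = corr[np.ix_(idx, idx)]
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= threshold:
            break
        a, b = kept[i], kept[j]
        if src[a] < src[b]:
            drop = a
        elif src[b] < src[a]:
            drop = b
        else:
            drop = max(a, b)
        kept.remove(drop)
    return kept


# ---------------------------------------------------------------------------
# subset selection

def _ols_aic(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit with intercept; Gaussian AIC = n ln(RSS/n) + 2k."""
    n = len(y)
    A = np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(((A @ coef - y) ** 2).sum())
    rss = max(rss, 1e-12)
    aic = n * np.log(rss / n) + 2 * A.shape[1]
    return coef[1:], aic


def select_m5(table: pd.DataFrame, labels,
              features: list[str] | None = None) -> list[str]:
    """M5-style backward elimination ("subset B", after collinearity removal).

    Repeatedly drops the feature with the smallest |standardized
    coefficient| in the full linear fit of the 0/1 class, as long as the
    Akaike criterion does not worsen.  Deterministic; ties drop the
    lexicographically first name.
    """
    y = _binary_labels(labels)
    kept = list(features) if features is not None else list(table.columns)
    X = table[kept].to_numpy(float)
    sds = X.std(axis=0)
    _, aic = _ols_aic(X, y)
    while len(kept) > 1:
        coef, _ = _ols_aic(X, y)
        std_coef = np.abs(coef) * sds
        order = sorted(range(len(kept)), key=lambda k: (std_coef[k], kept[k]))
        drop = order[0]
        mask = [k for k in range(len(kept)) if k != drop]
        _, aic_new = _ols_aic(X[:, mask], y)
        if aic_new > aic:
            break
        kept = [kept[k] for k in mask]
        X = X[:, mask]
        sds = sds[mask]
        aic = aic_new
    return kept


def select_lasso(table: pd.DataFrame, labels, seed: int = 0,
                 C: float | None = None) -> list[str]:
    """L1-penalized logistic selection ("subset C").

    The penalty is chosen by 5-fold cross-validated deviance unless a
    fixed inverse penalty ``C`` is given; features whose coefficient is
    shrunk to zero are removed.
    """
    y = _binary_labels(labels)
    X = table.to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if C is not None:
            fit = LogisticRegression(l1_ratio=1, C=C, solver="liblinear",
                                     max_iter=5000).fit(X, y)
        else:
            cv = StratifiedKFold(5, shuffle=True, random_state=seed)
            fit = LogisticRegressionCV(l1_ratios=[1], solver="liblinear",
                                       Cs=np.logspace(-3, 3, 13), cv=cv,
                                       scoring="neg_log_loss", max_iter=5000,
                                       use_legacy_attributes=False).fit(X, y)
    coef = fit.coef_.ravel()
    return [name for name, c in zip(table.columns, coef) if c != 0.0]


def select_subset(table: pd.DataFrame, labels, method: str,
                  config: RunConfig | None = None) -> list[str]:
    """Dispatch on selection method: none / m5 (with collinearity
    pre-filter) / lasso, a.k.a. subsets A / B / C."""
    config = config or RunConfig()
    method = SUBSETS.get(method, method)
    if method == "none":
        return list(table.columns)
    if method == "m5":
        kept = remove_collinear(table, labels, config.collinearity_threshold)
        return select_m5(table, labels, kept)
    if method == "lasso":
        return select_lasso(table, labels, seed=config.seed)
    raise ValueError(f"unknown selection method {method!r}")


# ---------------------------------------------------------------------------
# logistic regression

def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))


@dataclass
class TrainedModel:
    """A fitted logistic-regression reactivity classifier.

    ``coefficients`` always spans the full feature schema; removed
    features carry an exact zero.
    """

    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    selection_method: str = "none"

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Predicted probability of the positive (reactive) class."""
        X = table[self.feature_names].to_numpy(float)
        return _sigmoid(self.intercept + X @ self.coefficients)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# selection_method\t{self.selection_method}\n")
            fh.write("feature\tcoefficient\n")
            for name, c in zip(self.feature_names, self.coefficients):
                fh.write(f"{name}\t{float(c)!r}\n")
            fh.write(f"Intercept\t{float(self.intercept)!r}\n")

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        names, coefs = [], []
        intercept = 0.0
        method = "none"
        for line in Path(path).read_text().splitlines():
            if line.startswith("# selection_method"):
                method = line.split("\t")[1]
                continue
            if not line or line.startswith("feature\t"):
                continue
            name, value = line.split("\t")
            if name == "Intercept":
                intercept = float(value)
            else:
                names.append(name)
                coefs.append(float(value))
        return cls(names, np.array(coefs), intercept, method)


def _loglik_gradient(X: np.ndarray, y: np.ndarray, coef: np.ndarray,
                     intercept: float) -> np.ndarray:
    p = _sigmoid(intercept + X @ coef)
    r = y - p
    return np.concatenate(([r.sum()], X.T @ r))


def fit_logistic(table: pd.DataFrame, labels, subset: list[str] | None = None,
                 selection_method: str = "none") -> TrainedModel:
    """Maximum-likelihood logistic fit on a feature subset.

    Coefficients outside the subset are exactly zero.  Under (quasi-)
    perfect separation the unpenalized likelihood has no maximizer; the
    fit then falls back to a small L2 ridge (1e-6) with a warning.
    """
    if subset is not None and len(subset) == 0:
        raise ValidationError("fit_logistic requires a non-empty feature subset")
    subset = list(subset) if subset is not None else list(table.columns)
    y = _binary_labels(labels)
    X = table[subset].to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        fit = LogisticRegression(C=np.inf, solver="lbfgs", tol=1e-10,
                                 max_iter=2000).fit(X, y)
    coef = fit.coef_.ravel()
    intercept = float(fit.intercept_[0])
    grad = _loglik_gradient(X, y, coef, intercept)
    if np.linalg.norm(grad) >= 1e-6 or np.abs(coef).max(initial=0.0) > 1e4:
        warnings.warn("possible perfect separation; refitting with L2 ridge 1e-6")
        fit = LogisticRegression(C=1.0 / 1e-6, solver="lbfgs",
                                 tol=1e-10, max_iter=5000).fit(X, y)
        coef = fit.coef_.ravel()
        intercept = float(fit.intercept_[0])
    full = np.zeros(len(table.columns))
    for name, c in zip(subset, coef):
        full[table.columns.get_loc(name)] = c
    return TrainedModel(list(table.columns), full, intercept, selection_method)


def logistic_standard_errors(table: pd.DataFrame, model: TrainedModel) -> pd.Series:
    """Asymptotic standard errors from the inverse Fisher information,
    reported for the non-zero (selected) coefficients and the intercept."""
    subset = [n for n, c in zip(model.feature_names, model.coefficients) if c != 0.0]
    X = table[subset].to_numpy(float)
    coef = np.array([model.coefficients[model.feature_names.index(n)] for n in subset])
    p = _sigmoid(model.intercept + X @ coef)
    w = p * (1 - p)
    A = np.column_stack([np.ones(len(X)), X])
    info = A.T @ (A * w[:, None])
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return pd.Series(se, index=["Intercept"] + subset)


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class EvaluationReport:
    """Threshold-0.5 confusion metrics plus Brier, AUROC and AUPR.

    AUROC/AUPR are ``None`` when the labels contain a single class.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_measure: float
    brier: float
    auroc: float | None
    aupr: float | None

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def evaluate(probabilities, labels, threshold: float = 0.5) -> EvaluationReport:
    """Score predicted positive-class probabilities against binary labels.

    F-measure is the harmonic mean of sensitivity and precision; the
    Brier score is the mean squared difference between probability and
    outcome; AUROC is the trapezoidal ROC area and AUPR the
    step-interpolated precision-recall area.
    """
    p = np.asarray(probabilities, float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("probabilities must lie in [0, 1]")
    y = _binary_labels(labels) if not np.issubdtype(
        np.asarray(labels).dtype, np.number) else np.asarray(labels, float)
    pred = (p >= threshold).astype(float)
    tp = float(((pred == 1) & (y == 1)).sum())
    tn = float(((pred == 0) & (y == 0)).sum())
    fp = float(((pred == 1) & (y == 0)).sum())
    fn = float(((pred == 0) & (y == 1)).sum())

    def ratio(a: float, b: float) -> float:
        return a / b if b > 0 else 0.0

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    f = ratio(2 * sens * prec, sens + prec)
    brier = float(np.mean((p - y) ** 2))
    if len(set(y)) < 2:
        auroc = aupr = None
    else:
        auroc = float(roc_auc_score(y, p))
        aupr = float(average_precision_score(y, p))
    return EvaluationReport(
        accuracy=ratio(tp + tn, len(y)), sensitivity=sens, specificity=spec,
        precision=prec, f_measure=f, brier=brier, auroc=auroc, aupr=aupr)


# ---------------------------------------------------------------------------
# leakage-aware leave-one-out cross-validation

def _comparator_probability(name: str, X_train: np.ndarray, y: np.ndarray,
                            x_test: np.ndarray, seed: int = 0) -> float:
    """Held-out positive-class score from an off-the-shelf comparator
    (evaluation-only alternatives to the logistic model)."""
    if name == "linear":
        A = np.column_stack([np.ones(len(X_train)), X_train])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return float(np.clip(coef[0] + x_test @ coef[1:], 0.0, 1.0))
    if name == "naive_bayes":
        from sklearn.naive_bayes import GaussianNB
        fit = GaussianNB().fit(X_train, y)
        return float(fit.predict_proba(x_test[None, :])[0, 1])
    if name == "tree":
        from sklearn.tree import DecisionTreeClassifier
        fit = DecisionTreeClassifier(
            min_samples_leaf=max(1, len(y) // 100),
            random_state=seed).fit(X_train, y)
        return float(fit.predict_proba(x_test[None, :])[0, 1])
    raise ValueError(f"unknown classifier {name!r}")


def loocv(pset: PeptideSet, config: RunConfig | None = None,
          subset: str = "A", reselect_per_fold: bool = True,
          classifier: str = "logistic") -> tuple[EvaluationReport, pd.DataFrame]:
    """Leave-one-out cross-validation with held-out masking of the
    alignment features.

    For every fold the held-out peptide is removed from every reference
    maximum (its row/column of the precomputed score matrices is masked,
    not re-aligned), normalization — and the feature subset, unless
    ``reselect_per_fold`` is off — is re-derived on the n-1 retained
    peptides, the model is refit, and the held-out probability recorded.
    Metrics are computed over all n held-out predictions at threshold 0.5.

    With ``reselect_per_fold=False`` the subset is selected once on the
    full set; this is faster but optimistically biased.  ``classifier``
    defaults to the logistic model; ``linear`` (0/1 outcome least
    squares), ``naive_bayes`` and ``tree`` are available as off-the-shelf
    comparators.
    """
    config = config or RunConfig()
    labels = pset.labels
    y = _binary_labels(labels)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("loocv requires both classes present")
    params = dict(matrix=config.substitution_matrix, gap_open=config.gap_open,
                  gap_extend=config.gap_extend)
    m_global = score_matrix(pset, AlignmentParams(mode="global", **params))
    m_local = score_matrix(pset, AlignmentParams(mode="local", **params))
    seq_feats = sequence_features(pset, window=config.window)

    global_subset: list[str] | None = None
    if not reselect_per_fold:
        align = alignment_feature_frame(pset, m_global, m_local)
        full_table = build_feature_table_from_raw(seq_feats, align)
        global_subset = select_subset(full_table.values, labels, subset, config)

    n = len(pset)
    ids = [p.id for p in pset]
    probs = np.empty(n)
    for i in range(n):
        train_idx = [j for j in range(n) if j != i]
        if y[train_idx].sum() in (0, len(train_idx)):
            raise ValidationError("a fold lost one of the classes")
        train = pset.subset(train_idx)
        # mask held-out i from every reference maximum (no re-alignment needed)
        lab = labels
        rows = [alignment_features(j, m_global, m_local, lab,
                                   exclude=frozenset({i}))
                for j in train_idx]
        align_train = pd.DataFrame(rows, index=[ids[j] for j in train_idx])[
            list(ALIGN_FEATURE_NAMES)]
        table = build_feature_table_from_raw(seq_feats.iloc[train_idx], align_train)
        chosen = (select_subset(table.values, train.labels, subset, config)
                  if reselect_per_fold and subset != "A" else
                  (global_subset or list(table.values.columns)))
        if classifier == "logistic":
            model = fit_logistic(table.values, train.labels, chosen,
                                 selection_method=SUBSETS.get(subset, subset))
        held_align = pd.DataFrame(
            [alignment_features(i, m_global, m_local, lab)],
            index=[ids[i]])[list(align_train.columns)]
        held_raw = pd.concat([seq_feats.iloc[[i]], held_align], axis=1)
        mn = table.norm_params["min"]
        mx = table.norm_params["max"]
        span = (mx - mn).replace(0.0, np.nan)
        held_norm = ((held_raw - mn) / span).fillna(0.0).clip(0.0, 1.0)
        if classifier == "logistic":
            probs[i] = model.predict(held_norm)[0]
        else:
            probs[i] = _comparator_probability(
                classifier, table.values[chosen].to_numpy(float),
                _binary_labels(train.labels),
                held_norm[chosen].to_numpy(float)[0], seed=config.seed)

    predictions = pd.DataFrame({"id": ids, "label": labels, "probability": probs})
    return evaluate(probs, labels), predictions


def build_feature_table_from_raw(seq_feats: pd.DataFrame, align: pd.DataFrame):
    """Normalize a pre-computed raw (sequence + alignment) feature frame."""
    raw = pd.concat([seq_feats, align], axis=1)
    if list(raw.columns) != list(FEATURE_NAMES):
        raise ValidationError("feature columns do not match the 37-column schema")
    mn = raw.min(axis=0)
    mx = raw.max(axis=0)
    span = (mx - mn).replace(0.0, np.nan)
    norm = ((raw - mn) / span).fillna(0.0)
    return FeatureTable(values=norm, norm_params=pd.DataFrame({"min": mn, "max": mx}))


def train_model(pset: PeptideSet, config: RunConfig | None = None,
                subset: str = "A") -> tuple[TrainedModel, "FeatureTableBundle"]:
    """Fit a reactivity model on a full labelled set.

    Returns the model together with the score matrices and normalization
    parameters needed to featurize new peptides consistently.
    """
    config = config or RunConfig()
    params = dict(matrix=config.substitution_matrix, gap_open=config.gap_open,
                  gap_extend=config.gap_extend)
    m_global = score_matrix(pset, AlignmentParams(mode="global", **params))
    m_local = score_matrix(pset, AlignmentParams(mode="local", **params))
    align = alignment_feature_frame(pset, m_global, m_local)
    table = build_feature_table(pset, align, window=config.window)
    chosen = select_subset(table.values, pset.labels, subset, config)
    model = fit_logistic(table.values, pset.labels, chosen,
                         selection_method=SUBSETS.get(subset, subset))
    return model, FeatureTableBundle(table, m_global, m_local)


@dataclass
class FeatureTableBundle:
    """A training feature table plus the score matrices it came from."""

    table: "FeatureTable"
    m_global: "PairwiseScoreMatrix"
    m_local: "PairwiseScoreMatrix"


def predict_peptides(queries: PeptideSet, references: PeptideSet,
                     model: TrainedModel, norm_params: pd.DataFrame,
                     config: RunConfig | None = None) -> np.ndarray:
    """Predicted reactivity probabilities for new peptides, featurized
    against the labelled reference (training) set."""
    config = config or RunConfig()
    align = query_alignment_features(queries, references,
                                     gap_open=config.gap_open,
                                     gap_extend=config.gap_extend,
                                     matrix=config.substitution_matrix)
    table = apply_feature_table(queries, norm_params, align, window=config.window)
    return model.predict(table.values)
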
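"""Breed classifiers: cross-validated training, calibrated assignment.

Supports KNN, random forest, RBF support-vector machine and XGBoost on
a discriminative SNP panel, evaluated under stratified k-fold, repeated
stratified k-fold, or leave-one-out cross-validation with pooled
accuracy, Cohen's kappa and macro one-vs-rest AUC.

A raw top-class probability P is recalibrated into a confidence score
through the tuning parameter alpha:

    t = P**a / (P**a + (1 - P)**a)
    z = t                      if P > 0.5
    z = t + a * (0.5 - t)      if P <= 0.5

(the P <= 0.5 branch can exceed [0, 1] for large alpha; the reported
z-score is clamped, the raw value kept alongside).

Assignment of new individuals is guarded by a one-class screen: the
mean per-SNP binomial log-likelihood of the query genotype under the
predicted breed's panel allele frequencies must reach that breed's own
training 1st percentile, and more than 50% missing panel SNPs fails
outright as low-quality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import cohen_kappa_score, confusion_matrix, roc_auc_score
from sklearn.model_selection import (
    LeaveOneOut,
    RepeatedStratifiedKFold,
    StratifiedKFold,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .feature_select import SnpPanel
from .hapmap_io import BreedkitError, BreedTable, GenotypeMatrix, GeoTable

__all__ = [
    "ClassifierModel",
    "CVReport",
    "PredictionResult",
    "train",
    "evaluate_metrics",
    "calibrate_zscore",
    "one_class_fit",
    "one_class_check",
    "predict_new",
    "save_model",
    "load_model",
]

ALGORITHMS = ("knn", "rf", "svm", "xgb")
DEFAULT_HYPERPARAMS = {
    "knn": {"n_neighbors": 5},
    "rf": {"n_estimators": 500},
    "svm": {"kernel": "rbf", "C": 1.0},
    "xgb": {"n_estimators": 200, "max_depth": 6},
}
_LOO_MAX_N = 10_000


@dataclass
class CVReport:
    scheme: str
    fold_accuracy: list[float]
    accuracy: float
    kappa: float
    macro_auc: float
    confusion: pd.DataFrame  # rows true breed, cols predicted

    def summary(self) -> dict:
        return {
            "scheme": self.scheme,
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "macro_auc": self.macro_auc,
            "fold_accuracy": self.fold_accuracy,
        }


@dataclass
class PredictionResult:
    individual_id: str
    breed: str
    probability: float
    z_score: float
    z_score_raw: float
    one_class_pass: bool
    one_class_score: float
    fail_reason: str | None
    prob_vector: dict[str, float]
    latitude: float | None = None
    longitude: float | None = None
    location: str | None = None


@dataclass
class ClassifierModel:
    algorithm: str
    panel: SnpPanel
    estimator: object
    classes: list[str]
    impute_means: np.ndarray          # per panel SNP, training means
    breed_freqs: dict[str, np.ndarray]  # smoothed alt-allele freqs per breed
    one_class_thresholds: dict[str, float]
    alpha: float = 2.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise BreedkitError("alpha must be > 0")


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def calibrate_zscore(P: float, alpha: float = 2.0, clamp: bool = True) -> float:
    """Map a raw top-class probability to the calibrated z-score."""
    if not 0.0 <= P <= 1.0:
        raise BreedkitError(f"P={P} outside [0, 1]")
    if alpha <= 0:
        raise BreedkitError("alpha must be > 0")
    pa = P**alpha
    qa = (1.0 - P) ** alpha
    t = pa / (pa + qa)
    z = t if P > 0.5 else t + alpha * (0.5 - t)
    if clamp:
        z = min(1.0, max(0.0, z))
    return float(z)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def evaluate_metrics(
    y_true,
    y_pred,
    proba: np.ndarray,
    classes: list[str],
) -> tuple[float, float, float, pd.DataFrame]:
    """Accuracy, Cohen's kappa, macro one-vs-rest AUC and confusion matrix.

    A class absent from the true labels has no defined OvR AUC and is
    excluded from the macro average with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    proba = np.asarray(proba, dtype=float)
    if not (len(y_true) == len(y_pred) == len(proba)):
        raise BreedkitError("metric inputs must have equal length")
    accuracy = float((y_true == y_pred).mean())
    kappa = float(cohen_kappa_score(y_true, y_pred, labels=classes))
    aucs = []
    for c, cls in enumerate(classes):
        pos = y_true == cls
        if pos.all() or not pos.any():
            warnings.warn(
                f"class {cls!r} absent from true labels; OvR AUC skipped",
                stacklevel=2,
            )
            continue
        aucs.append(float(roc_auc_score(pos.astype(int), proba[:, c])))
    macro_auc = float(np.mean(aucs)) if aucs else float("nan")
    conf = pd.DataFrame(
        confusion_matrix(y_true, y_pred, labels=classes),
        index=classes,
        columns=classes,
    )
    return accuracy, kappa, macro_auc, conf


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _make_estimator(algorithm: str, seed: int, hyperparams: dict | None):
    hp = dict(DEFAULT_HYPERPARAMS.get(algorithm, {}))
    hp.update(hyperparams or {})
    if algorithm == "knn":
        return KNeighborsClassifier(**hp)
    if algorithm == "rf":
        return RandomForestClassifier(random_state=seed, **hp)
    if algorithm == "svm":
        return SVC(probability=True, random_state=seed, **hp)
    if algorithm == "xgb":
        from xgboost import XGBClassifier

        return XGBClassifier(random_state=seed, verbosity=0, **hp)
    raise BreedkitError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


class _Wrapped:
    """Label-encodes breeds for estimators wanting integer classes."""

    def __init__(self, est, classes: list[str]):
        self.est = est
        self.classes = list(classes)

    def fit(self, X, y):
        idx = {c: i for i, c in enumerate(self.classes)}
        self.est.fit(X, np.array([idx[v] for v in y]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        raw = self.est.predict_proba(X)
        seen = list(getattr(self.est, "classes_", range(raw.shape[1])))
        out = np.zeros((raw.shape[0], len(self.classes)))
        for col, cls_idx in enumerate(seen):
            out[:, int(cls_idx)] = raw[:, col]
        return out

    def predict(self, X) -> np.ndarray:
        return np.array(self.classes)[np.argmax(self.predict_proba(X), axis=1)]


def _panel_matrix(G: GenotypeMatrix, panel: SnpPanel) -> np.ndarray:
    """(n, panel) dosage matrix; SNPs absent from G become all-missing."""
    col = {s: i for i, s in enumerate(G.snp_ids)}
    X = np.full((G.n_individuals, len(panel)), np.nan)
    for j, snp in enumerate(panel.snp_ids):
        if snp in col:
            X[:, j] = G.dosages[:, col[snp]]
    return X


def _impute(X: np.ndarray, means: np.ndarray) -> np.ndarray:
    out = X.copy()
    miss = np.isnan(out)
    if miss.any():
        out[miss] = np.take(means, np.nonzero(miss)[1])
    return out


def _cv_splitter(scheme: str, seed: int):
    if scheme.startswith("kfold"):
        k = int(scheme.split(":")[1]) if ":" in scheme else 5
        return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    if scheme.startswith("repeated_kfold"):
        parts = scheme.split(":")[1].split("x") if ":" in scheme else ["5", "5"]
        k, reps = int(parts[0]), int(parts[1]) if len(parts) > 1 else 5
        return RepeatedStratifiedKFold(n_splits=k, n_repeats=reps, random_state=seed)
    if scheme == "loo":
        return LeaveOneOut()
    raise BreedkitError(f"unknown cv scheme {scheme!r}")


def train(
    G: GenotypeMatrix,
    breeds: BreedTable,
    panel: SnpPanel,
    algorithm: str = "rf",
    cv_scheme: str = "kfold:5",
    seed: int = 0,
    alpha: float = 2.0,
    hyperparams: dict | None = None,
) -> tuple[ClassifierModel, CVReport]:
    """Fit a breed classifier on panel dosages under cross-validation.

    Cross-validation pools out-of-fold predictions/probabilities for
    the report metrics, then the model is refit on all data and the
    one-class thresholds calibrated from the training individuals.
    """
    missing_panel = [s for s in panel.snp_ids if s not in set(G.snp_ids)]
    if missing_panel:
        raise BreedkitError(f"panel SNPs absent from genotypes: {missing_panel[:5]}")
    y = breeds.labels_for(G.individual_ids)
    classes = sorted(set(y))
    counts = pd.Series(y).value_counts()
    if cv_scheme != "loo" and counts.min() < 2:
        few = counts[counts < 2].index.tolist()
        raise BreedkitError(f"stratified k-fold needs >= 2 per breed; too few: {few}")
    if cv_scheme == "loo" and len(y) > _LOO_MAX_N:
        raise BreedkitError(
            f"leave-one-out with n={len(y)} is impractical; use kfold instead"
        )

    X_raw = _panel_matrix(G, panel)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(X_raw, axis=0)
    means = np.nan_to_num(means, nan=1.0)
    X = _impute(X_raw, means)

    splitter = _cv_splitter(cv_scheme, seed)
    pooled_true: list[str] = []
    pooled_pred: list[str] = []
    pooled_proba: list[np.ndarray] = []
    fold_acc: list[float] = []
    for train_idx, test_idx in splitter.split(X, y):
        est = _Wrapped(_make_estimator(algorithm, seed, hyperparams), classes)
        est.fit(X[train_idx], y[train_idx])
        proba = est.predict_proba(X[test_idx])
        pred = est.predict(X[test_idx])
        pooled_true.extend(y[test_idx])
        pooled_pred.extend(pred)
        pooled_proba.append(proba)
        fold_acc.append(float((pred == y[test_idx]).mean()))

    acc, kappa, auc, conf = evaluate_metrics(
        pooled_true, pooled_pred, np.vstack(pooled_proba), classes
    )
    report = CVReport(cv_scheme, fold_acc, acc, kappa, auc, conf)

    final = _Wrapped(_make_estimator(algorithm, seed, hyperparams), classes)
    final.fit(X, y)
    freqs, thresholds = one_class_fit(X_raw, y, classes)
    model = ClassifierModel(
        algorithm=algorithm,
        panel=panel,
        estimator=final,
        classes=classes,
        impute_means=means,
        breed_freqs=freqs,
        one_class_thresholds=thresholds,
        alpha=alpha,
    )
    return model, report


# ---------------------------------------------------------------------------
# One-class validation
# ---------------------------------------------------------------------------


def _binom_loglik_rows(X: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Mean per-SNP log-likelihood of dosage rows under frequencies f."""
    lf, l1f = np.log(f), np.log1p(-f)
    log2 = np.log(2.0)
    out = np.empty(X.shape[0])
    for i, row in enumerate(X):
        ok = ~np.isnan(row)
        if not ok.any():
            out[i] = -np.inf
            continue
        g = row[ok]
        ll = g * lf[ok] + (2 - g) * l1f[ok] + (g == 1) * log2
        out[i] = float(ll.mean())
    return out


def one_class_fit(
    X_raw: np.ndarray, y: np.ndarray, classes: list[str]
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Per-breed smoothed panel allele frequencies and score thresholds.

    The threshold for breed b is the 1st percentile of its training
    individuals' own scores. Each calibration score is computed
    leave-one-out — the individual's alleles are removed from the
    frequency estimate before scoring it — otherwise in-sample optimism
    (each row inflating its own breed's frequencies) puts genuine
    held-out queries systematically below the training distribution.
    """
    freqs: dict[str, np.ndarray] = {}
    thresholds: dict[str, float] = {}
    for cls in classes:
        rows = X_raw[y == cls]
        obs = ~np.isnan(rows)
        n_obs = obs.sum(axis=0)
        alt = np.nansum(rows, axis=0)
        f = (alt + 1.0) / (2.0 * n_obs + 2.0)  # Laplace-style smoothing
        f = np.clip(f, 1e-6, 1 - 1e-6)
        freqs[cls] = f
        scores = np.empty(rows.shape[0])
        for i, row in enumerate(rows):
            alt_i = alt - np.where(obs[i], np.nan_to_num(row), 0.0)
            n_i = n_obs - obs[i]
            f_loo = np.clip((alt_i + 1.0) / (2.0 * n_i + 2.0), 1e-6, 1 - 1e-6)
            scores[i] = _binom_loglik_rows(row[None, :], f_loo)[0]
        # lower order statistic, not interpolated: every calibration score
        # at or above the empirical 1st percentile passes
        thresholds[cls] = float(np.percentile(scores, 1, method="lower"))
    return freqs, thresholds


def one_class_check(
    model: ClassifierModel, row: np.ndarray, breed: str
) -> tuple[bool, float, str | None]:
    """Screen one (unimputed) panel dosage row under a breed's profile."""
    miss_frac = float(np.isnan(row).mean())
    if miss_frac > 0.5:
        return False, float("-inf"), "low-quality"
    score = float(_binom_loglik_rows(row[None, :], model.breed_freqs[breed])[0])
    ok = score >= model.one_class_thresholds[breed]
    return ok, score, None if ok else "unlike-training-breed"


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def predict_new(
    model: ClassifierModel,
    G_new: GenotypeMatrix,
    geo: GeoTable | None = None,
) -> list[PredictionResult]:
    """Assign breeds to new individuals with calibration and screening.

    Panel SNPs absent from the query count as missing both for the
    mean imputation and the low-quality check; zero panel overlap is an
    error. Geography columns join on the predicted breed when given.
    """
    overlap = set(model.panel.snp_ids) & set(G_new.snp_ids)
    if not overlap:
        raise BreedkitError("query genotypes share no SNPs with the model panel")
    X_raw = _panel_matrix(G_new, model.panel)
    X = _impute(X_raw, model.impute_means)
    proba = model.estimator.predict_proba(X)
    results = []
    for i, ind in enumerate(G_new.individual_ids):
        p_vec = proba[i]
        best = int(np.argmax(p_vec))
        breed = model.classes[best]
        P = float(p_vec[best])
        z_raw = calibrate_zscore(P, model.alpha, clamp=False)
        z = min(1.0, max(0.0, z_raw))
        ok, score, reason = one_class_check(model, X_raw[i], breed)
        res = PredictionResult(
            individual_id=ind,
            breed=breed,
            probability=P,
            z_score=z,
            z_score_raw=z_raw,
            one_class_pass=ok,
            one_class_score=score,
            fail_reason=reason,
            prob_vector={c: float(p) for c, p in zip(model.classes, p_vec)},
        )
        if geo is not None:
            info = geo.lookup(breed)
            res.latitude = info["Latitude"]
            res.longitude = info["Longitude"]
            res.location = info["Location"]
        results.append(res)
    return results


def predictions_frame(results: list[PredictionResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "ID": r.individual_id,
                "breed": r.breed,
                "P": r.probability,
                "z_score": r.z_score,
                "one_class_pass": r.one_class_pass,
                "score": r.one_class_score,
                "Latitude": r.latitude,
                "Longitude": r.longitude,
                "Location": r.location,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

_MODEL_FORMAT_VERSION = 1


def save_model(model: ClassifierModel, path) -> None:
    import joblib

    joblib.dump({"format_version": _MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path) -> ClassifierModel:
    import joblib

    blob = joblib.load(path)
    if blob.get("format_version") != _MODEL_FORMAT_VERSION:
        raise BreedkitError("unsupported model file version")
    return blob["model"]
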
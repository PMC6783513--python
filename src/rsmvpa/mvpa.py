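"""Cross-validated linear-SVM pattern classification with permutation tests.

The classifier chain is the standard MVPA recipe: stratified k-fold
cross-validation (default 5-fold, so each class splits roughly 80/20 into
train/test), per-feature standardization with train-set statistics, a PCA
retaining ALL principal components (a pure coordinate rotation — it cannot
change a linear SVM's decisions, which is pinned by test), a linear
soft-margin SVM, and back-projection of the SVM weights to the original
(standardized) feature space.  Significance of the cross-validated
performance is assessed by permuting class labels and re-running the entire
procedure, with p = (N_exceed + 1) / (N_permutation + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .features import FeatureTable

__all__ = [
    "CVConfig",
    "CVResult",
    "PermutationResult",
    "stratified_folds",
    "fit_fold",
    "run_cv",
    "permutation_pvalue",
    "permutation_test",
    "residualize_confound",
    "filter_severity",
]


@dataclass
class CVConfig:
    k: int = 5
    seed: int = 0
    n_permutations: int = 1000
    svm_cost: float = 1.0
    positive_class: str = "patient"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.svm_cost <= 0:
            raise ValueError("svm_cost must be positive")


@dataclass
class CVResult:
    fold_metrics: pd.DataFrame  # per-fold accuracy/sensitivity/specificity/auc
    mean_metrics: dict[str, float]
    sd_metrics: dict[str, float]
    pooled_predictions: np.ndarray
    pooled_decisions: np.ndarray  # decision value of each subject's test fold
    confusion: np.ndarray  # 2x2 [[TP, FN], [FP, TN]], patient = positive
    weights: np.ndarray  # averaged over folds, standardized-feature space
    fold_assignment: np.ndarray
    seed: int
    config: "CVConfig | None" = None

    def save(self, out_dir) -> None:
        """Metrics as JSON, weights as ``weights.npy``, fold log as TSV.

        The metrics file records the seed and a hash of the configuration so
        a run is identifiable.
        """
        import hashlib
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg_repr = repr(self.config) if self.config is not None else ""
        payload = {
            "mean": self.mean_metrics,
            "sd": self.sd_metrics,
            "confusion": self.confusion.tolist(),
            "seed": self.seed,
            "config": cfg_repr,
            "config_hash": hashlib.sha256(cfg_repr.encode()).hexdigest()[:16],
        }
        (out / "metrics.json").write_text(json.dumps(payload, indent=2))
        np.save(out / "weights.npy", self.weights)
        pd.DataFrame({"fold": self.fold_assignment,
                      "predicted": self.pooled_predictions}).to_csv(
            out / "folds.tsv", sep="\t", index_label="subject")
        self.fold_metrics.to_csv(out / "fold_metrics.tsv", sep="\t",
                                 index_label="fold")


@dataclass
class PermutationResult:
    observed: float
    null_samples: np.ndarray
    n_exceed: int
    p_value: float
    metric: str


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Test-fold id per subject: within each class, shuffle then deal into k
    nearly equal blocks (sizes differ by at most 1)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = np.empty(labels.shape[0], dtype=np.int64)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(f"class {cls!r} has fewer members ({idx.size}) than folds ({k})")
        rng.shuffle(idx)
        sizes = np.full(k, idx.size // k)
        sizes[: idx.size % k] += 1
        stop = np.cumsum(sizes)
        start = stop - sizes
        for f in range(k):
            folds[idx[start[f]:stop[f]]] = f
    return folds


def _standardize_train(train_x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = train_x.mean(axis=0)
    sd = train_x.std(axis=0, ddof=1)
    dead = sd == 0.0
    sd_safe = np.where(dead, 1.0, sd)
    return mean, sd_safe, dead


def fit_fold(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    cfg: CVConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Train the standardize -> all-component PCA -> linear SVM chain on one
    fold and push the test rows through the identical transforms.

    Returns (predicted labels, decision values, weight vector).  Scaler and
    rotation are fitted on the training rows only.  Zero-variance training
    features are zeroed.  The weight vector is reported in the standardized
    feature space, ``w = R w_pc`` with R the PCA rotation.
    """
    train_y = np.asarray(train_y)
    if np.unique(train_y).size < 2:
        raise ValueError("training set contains a single class")
    mean, sd, dead = _standardize_train(train_x)

    def transform(x: np.ndarray) -> np.ndarray:
        z = (x - mean) / sd
        z[:, dead] = 0.0
        return z

    z_train = transform(np.asarray(train_x, dtype=np.float64))
    z_test = transform(np.asarray(test_x, dtype=np.float64))

    # all-component PCA of the (already centred) training matrix: the SVD
    # right-singular vectors form the rotation; no components are dropped
    center = z_train.mean(axis=0)
    _, _, vt = np.linalg.svd(z_train - center, full_matrices=False)
    rot = vt.T  # (n_features, n_components)
    pc_train = (z_train - center) @ rot
    pc_test = (z_test - center) @ rot

    clf = SVC(kernel="linear", C=cfg.svm_cost)
    y_bin = (train_y == cfg.positive_class).astype(int)
    clf.fit(pc_train, y_bin)
    decision = clf.decision_function(pc_test)
    pred_bin = clf.predict(pc_test)
    pred = np.where(pred_bin == 1, cfg.positive_class, _other_label(train_y, cfg.positive_class))
    weights = rot @ clf.coef_.ravel()
    return pred, decision, weights


def _other_label(labels: np.ndarray, positive: str):
    rest = [v for v in np.unique(labels) if v != positive]
    if len(rest) != 1:
        raise ValueError("expected exactly two classes")
    return rest[0]


def _fold_metrics(y_true, y_pred, decision, positive) -> dict[str, float]:
    pos = y_true == positive
    tp = int(np.sum(pos & (y_pred == positive)))
    fn = int(np.sum(pos & (y_pred != positive)))
    tn = int(np.sum(~pos & (y_pred != positive)))
    fp = int(np.sum(~pos & (y_pred == positive)))
    out = {
        "accuracy": (tp + tn) / len(y_true),
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
    }
    if np.unique(y_true).size == 2:
        out["auc"] = roc_auc_score(pos.astype(int), decision)
    else:
        out["auc"] = np.nan
    return out


def run_cv(table: FeatureTable, cfg: CVConfig) -> CVResult:
    """Full stratified k-fold cross-validation.

    Per-fold metrics are computed on that fold's test block and averaged;
    AUC is computed within each fold from decision values, then averaged
    (folds whose test block has a single class get a missing AUC, excluded
    from the mean with a warning).  Pooled test predictions over all folds
    build one confusion matrix; weight vectors are averaged over folds.

    ``mean_metrics`` additionally carries ``auc_pooled``, the ROC area of
    the pooled per-subject decision values: with small test blocks the
    fold-mean metrics live on a coarse grid, and the pooled AUC is the
    nearly continuous statistic of choice for permutation calibration.
    """
    labels = table.labels
    folds = stratified_folds(labels, cfg.k, cfg.seed)
    pooled_pred = np.empty(labels.shape, dtype=labels.dtype)
    pooled_dec = np.empty(labels.shape[0])
    weight_sum = np.zeros(table.n_features)
    records = []
    for f in range(cfg.k):
        test = folds == f
        pred, decision, w = fit_fold(table.X[~test], labels[~test], table.X[test], cfg)
        pooled_pred[test] = pred
        pooled_dec[test] = decision
        weight_sum += w
        records.append(_fold_metrics(labels[test], pred, decision, cfg.positive_class))
    fold_df = pd.DataFrame(records)
    if fold_df["auc"].isna().any():
        warnings.warn("AUC undefined in at least one fold (single-class test block); "
                      "excluded from the mean")
    mean = {m: float(fold_df[m].mean()) for m in fold_df.columns}
    sd = {m: float(fold_df[m].std(ddof=1)) for m in fold_df.columns}
    mean["auc_pooled"] = float(
        roc_auc_score((labels == cfg.positive_class).astype(int), pooled_dec)
    )

    pos = labels == cfg.positive_class
    tp = int(np.sum(pos & (pooled_pred == cfg.positive_class)))
    fn = int(np.sum(pos & (pooled_pred != cfg.positive_class)))
    fp = int(np.sum(~pos & (pooled_pred == cfg.positive_class)))
    tn = int(np.sum(~pos & (pooled_pred != cfg.positive_class)))
    confusion = np.array([[tp, fn], [fp, tn]])

    return CVResult(
        fold_metrics=fold_df,
        mean_metrics=mean,
        sd_metrics=sd,
        pooled_predictions=pooled_pred,
        pooled_decisions=pooled_dec,
        confusion=confusion,
        weights=weight_sum / cfg.k,
        fold_assignment=folds,
        seed=cfg.seed,
        config=cfg,
    )


def permutation_pvalue(n_exceed: int, n_permutations: int) -> float:
    """p = (N_exceed + 1) / (N_permutation + 1); lies in (0, 1]."""
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if not 0 <= n_exceed <= n_permutations:
        raise ValueError("n_exceed outside [0, n_permutations]")
    return (n_exceed + 1) / (n_permutations + 1)


def permutation_test(
    table: FeatureTable, cfg: CVConfig, metric: str = "accuracy"
) -> PermutationResult:
    """Label-permutation significance of the cross-validated metric.

    Each iteration applies one global random permutation of the class labels
    (every training set therefore inherits permuted labels) and re-runs the
    entire k-fold procedure; exceedance counts null >= observed (ties count
    as exceeding).
    """
    observed = run_cv(table, cfg).mean_metrics[metric]
    rng = np.random.default_rng(cfg.seed + 1)
    null = np.empty(cfg.n_permutations)
    for i in range(cfg.n_permutations):
        perm = rng.permutation(table.n_subjects)
        shuffled = FeatureTable(
            X=table.X, labels=table.labels[perm], covariates=table.covariates,
            kind=table.kind, index_map=table.index_map, grid_shape=table.grid_shape,
            affine=table.affine, mask=table.mask, spec=table.spec,
            voxel_size_mm=table.voxel_size_mm,
        )
        perm_cfg = CVConfig(k=cfg.k, seed=int(rng.integers(2**31)),
                            n_permutations=cfg.n_permutations,
                            svm_cost=cfg.svm_cost, positive_class=cfg.positive_class)
        null[i] = run_cv(shuffled, perm_cfg).mean_metrics[metric]
    n_exceed = int(np.sum(null >= observed))
    return PermutationResult(
        observed=float(observed),
        null_samples=null,
        n_exceed=n_exceed,
        p_value=permutation_pvalue(n_exceed, cfg.n_permutations),
        metric=metric,
    )


def residualize_confound(
    table: FeatureTable, covariate: str, train_rows: np.ndarray | None = None
) -> FeatureTable:
    """Replace each feature by its residual after regressing out a covariate.

    By default the regression [intercept, covariate] is fitted on the full
    sample — replicating the usual published procedure — which leaks the
    covariate distribution across CV folds; pass ``train_rows`` to fit on a
    training subset only and apply everywhere.
    """
    if covariate not in table.covariates.columns:
        raise ValueError(f"covariate {covariate!r} missing")
    c = table.covariates[covariate].to_numpy(dtype=np.float64)
    if np.isnan(c).any():
        raise ValueError(f"covariate {covariate!r} has missing values")
    if np.ptp(c) == 0.0:
        raise ValueError(f"covariate {covariate!r} is constant")
    fit_rows = np.arange(table.n_subjects) if train_rows is None else np.asarray(train_rows)
    x = np.column_stack([np.ones(fit_rows.size), c[fit_rows]])
    beta, *_ = np.linalg.lstsq(x, table.X[fit_rows], rcond=None)
    full_x = np.column_stack([np.ones(table.n_subjects), c])
    return table.with_X(table.X - full_x @ beta)


def filter_severity(
    manifest: pd.DataFrame,
    duration_months: float = 6.0,
    tst_minutes: float = 390.0,
    sol_minutes: float = 45.0,
    waso_minutes: float = 45.0,
    sol_waso_minutes: float = 60.0,
    patient_label: str = "patient",
) -> pd.DataFrame:
    """Apply the rigorous severity inclusion rule to the patient rows.

    A patient is retained iff duration > 6 months AND total sleep time
    <= 6.5 h (390 min) AND (SOL > 45 min OR WASO > 45 min OR SOL + WASO
    > 60 min).  Controls pass through untouched.  Patients with missing
    severity fields are excluded with a warning.
    """
    required = ["duration", "total_sleep_time", "SOL", "WASO"]
    is_patient = manifest["group"] == patient_label
    sub = manifest[required].apply(pd.to_numeric, errors="coerce")
    missing = is_patient & sub.isna().any(axis=1)
    if missing.any():
        warnings.warn(f"{int(missing.sum())} patient(s) missing severity fields; excluded")
    retained = (
        (sub["duration"] > duration_months)
        & (sub["total_sleep_time"] <= tst_minutes)
        & (
            (sub["SOL"] > sol_minutes)
            | (sub["WASO"] > waso_minutes)
            | (sub["SOL"] + sub["WASO"] > sol_waso_minutes)
        )
    )
    keep = (~is_patient) | (retained.fillna(False) & ~missing)
    return manifest[keep].reset_index(drop=True)
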
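"""Leave-one-compound-out penalized logistic regression on top-variance probes.

The second classification procedure works on the control-centered expression
differences.  For each held-out compound, the 1000 probe sets with the
highest empirical variance across the *training* samples are selected (no
information from the held-out compound enters the selection), an
L1-penalized logistic regression is fitted on the standardized training
matrix, and the held-out samples are scored.  The penalty weight λ is
chosen on a descending log-spaced path by 10-fold cross-validation within
the training set, minimizing the mean binomial deviance.  Per-sample
probabilities are averaged within each condition (compound × tier), and
cytotoxic conditions — which have no expression samples at all — are fused
in at probability 1.0 before the probability threshold is applied.

The L1 path parametrization follows the lasso convention
``(1/n) Σ deviance + λ‖β‖₁`` on standardized features, mapped onto
scikit-learn's liblinear solver via ``C = 1 / (n λ)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .sps_classifier import MetricsReport, compute_metrics

__all__ = [
    "FoldModel",
    "select_top_variance",
    "fit_penalized_logistic",
    "loocv_classify",
    "fuse_and_threshold",
    "optimal_probability_threshold",
    "permutation_null_auc",
]

DEFAULT_K = 1000
DEFAULT_INNER_FOLDS = 10
DEFAULT_N_LAMBDA = 100
DEFAULT_LAMBDA_MIN_RATIO = 1e-4
_EPS = 1e-12


@dataclass
class FoldModel:
    """One fitted fold of the leave-one-compound-out procedure."""

    held_out_compound: str | None
    selected_probe_ids: list[str]
    lambda_path: np.ndarray = field(repr=False)
    penalty_value: float = np.nan
    cv_deviance: np.ndarray = field(default=None, repr=False)
    intercept: float = 0.0
    coef: np.ndarray = field(default=None, repr=False)  # on standardized scale
    feature_mean: np.ndarray = field(default=None, repr=False)
    feature_sd: np.ndarray = field(default=None, repr=False)
    inner_folds: int = DEFAULT_INNER_FOLDS

    @property
    def nonzero_probe_ids(self) -> list[str]:
        if self.coef is None:
            return []
        return [p for p, c in zip(self.selected_probe_ids, self.coef) if c != 0.0]

    def predict_proba(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """P(teratogen) for samples × selected-probes input."""
        if isinstance(X, pd.DataFrame):
            X = X[self.selected_probe_ids].to_numpy(dtype=float)
        Z = (np.asarray(X, dtype=float) - self.feature_mean) / self.feature_sd
        eta = self.intercept + Z @ self.coef
        return 1.0 / (1.0 + np.exp(-eta))


def select_top_variance(differences: pd.DataFrame, k: int) -> list[str]:
    """The ``k`` probes with the largest per-probe sample variance.

    ``differences`` is probe × sample.  Ties are broken by probe id
    lexicographic order so the selection is deterministic.
    """
    if k > differences.shape[0]:
        raise ValueError(f"k={k} exceeds the {differences.shape[0]} available probes")
    if differences.shape[1] < 2:
        raise ValueError("need at least 2 samples to compute a variance")
    var = differences.var(axis=1, ddof=1)
    order = sorted(zip(-var.to_numpy(), var.index.astype(str)))
    return [probe for _, probe in order[:k]]


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _fit_at_lambda(Z: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    n = Z.shape[0]
    # liblinear penalizes the intercept; a large intercept_scaling makes it
    # effectively free, matching the usual lasso-path convention
    clf = LogisticRegression(
        l1_ratio=1.0, solver="liblinear", C=1.0 / (n * lam), tol=1e-6,
        max_iter=1000, random_state=0, intercept_scaling=1000.0,
    )
    clf.fit(Z, y)
    return float(clf.intercept_[0]), clf.coef_[0].copy()


def fit_penalized_logistic(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    inner_folds: int = DEFAULT_INNER_FOLDS,
    seed: int = 0,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
) -> FoldModel:
    """L1 logistic regression with λ chosen by inner cross-validated deviance.

    Features are standardized to zero mean / unit variance on the training
    data (constant features are left centered with unit scale).  The λ path
    descends from the smallest value that zeroes every coefficient; the
    degenerate all-constant-feature case yields an intercept-only model
    whose predictions equal the training prevalence.
    """
    probe_ids = list(X.columns.astype(str)) if isinstance(X, pd.DataFrame) else [
        f"f{i}" for i in range(np.asarray(X).shape[1])
    ]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    if inner_folds < 2:
        raise ValueError("inner_folds must be >= 2")
    n, p = X.shape

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / sd_safe

    prevalence = y.mean()
    lam_max = np.max(np.abs(Z.T @ (y - prevalence))) / n
    if lam_max <= _EPS:  # no informative feature: intercept-only model
        intercept = float(np.log(prevalence / (1 - prevalence)))
        return FoldModel(
            held_out_compound=None,
            selected_probe_ids=probe_ids,
            lambda_path=np.array([np.inf]),
            penalty_value=np.inf,
            cv_deviance=np.array([np.nan]),
            intercept=intercept,
            coef=np.zeros(p),
            feature_mean=mean,
            feature_sd=sd_safe,
            inner_folds=inner_folds,
        )
    lam_path = lam_max * np.logspace(0, np.log10(lambda_min_ratio), n_lambda)

    n_splits = min(inner_folds, int(np.bincount(y).min()))
    n_splits = max(n_splits, 2)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    deviance = np.zeros(n_lambda)
    for train_idx, test_idx in skf.split(Z, y):
        Zt, yt = Z[train_idx], y[train_idx]
        Zv, yv = Z[test_idx], y[test_idx]
        if np.unique(yt).size < 2:  # tiny-fold degenerate split
            prev = np.clip(yt.mean(), _EPS, 1 - _EPS)
            for i in range(n_lambda):
                deviance[i] += _binomial_deviance(yv, np.full(yv.size, prev))
            continue
        for i, lam in enumerate(lam_path):
            b0, b = _fit_at_lambda(Zt, yt, lam)
            pv = 1.0 / (1.0 + np.exp(-(b0 + Zv @ b)))
            deviance[i] += _binomial_deviance(yv, pv)
    deviance /= n_splits
    best = int(np.argmin(deviance))
    lam_best = float(lam_path[best])
    intercept, coef = _fit_at_lambda(Z, y, lam_best)
    return FoldModel(
        held_out_compound=None,
        selected_probe_ids=probe_ids,
        lambda_path=lam_path,
        penalty_value=lam_best,
        cv_deviance=deviance,
        intercept=intercept,
        coef=coef,
        feature_mean=mean,
        feature_sd=sd_safe,
        inner_folds=n_splits,
    )


def loocv_classify(
    differences: pd.DataFrame,
    sheet: pd.DataFrame,
    annotations: pd.DataFrame,
    k: int = DEFAULT_K,
    seed: int = 0,
    inner_folds: int = DEFAULT_INNER_FOLDS,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
) -> tuple[pd.DataFrame, set[str], dict[str, FoldModel]]:
    """Leave-one-compound-out classification of every expression condition.

    ``differences`` is the centered probe × treated-sample matrix; ``sheet``
    maps samples to (compound, tier); ``annotations`` carries one row per
    compound × tier with ``label`` and ``cytotoxic``.  Returns per-condition
    mean held-out probabilities, the union of selected probe sets across
    folds, and the per-fold models.
    """
    sample_info = sheet.set_index("sample_id")
    samples = [s for s in differences.columns if s in sample_info.index]
    if len(samples) < len(differences.columns):
        missing = sorted(set(differences.columns) - set(samples))
        raise ValueError(f"samples absent from the sheet: {missing[:5]}")
    info = sample_info.loc[samples]
    compound_label = dict(
        annotations.drop_duplicates("compound_id")[["compound_id", "label"]].itertuples(
            index=False
        )
    )
    compounds = list(dict.fromkeys(info["compound_id"]))
    unknown = [c for c in compounds if c not in compound_label]
    if unknown:
        raise ValueError(f"compounds without annotation: {unknown}")
    if len(compounds) < 3:
        raise ValueError("leave-one-compound-out needs at least 3 compounds with samples")
    for c in compounds:
        if not (info["compound_id"] == c).any():
            raise ValueError(f"compound {c!r} has no samples")

    y_sample = (info["compound_id"].map(compound_label) == "teratogen").to_numpy(int)
    X_all = differences[samples]

    seed_seq = np.random.SeedSequence(seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(len(compounds))]

    fold_models: dict[str, FoldModel] = {}
    records = []
    union: set[str] = set()
    for fold_seed, held_out in zip(fold_seeds, compounds):
        test_mask = (info["compound_id"] == held_out).to_numpy()
        train_samples = [s for s, m in zip(samples, test_mask) if not m]
        test_samples = [s for s, m in zip(samples, test_mask) if m]
        y_train = y_sample[~test_mask]
        if np.unique(y_train).size < 2:
            raise ValueError(
                f"training set without both classes when holding out {held_out!r}"
            )
        selected = select_top_variance(X_all[train_samples], k)
        union.update(selected)
        model = fit_penalized_logistic(
            X_all.loc[selected, train_samples].T,
            y_train,
            inner_folds=inner_folds,
            seed=fold_seed,
            n_lambda=n_lambda,
            lambda_min_ratio=lambda_min_ratio,
        )
        model.held_out_compound = held_out
        model.selected_probe_ids = selected
        fold_models[held_out] = model
        probs = model.predict_proba(X_all.loc[selected, test_samples].T)
        for s, p in zip(test_samples, probs):
            records.append(
                {
                    "compound_id": held_out,
                    "tier": info.at[s, "tier"],
                    "sample_id": s,
                    "probability": float(p),
                }
            )

    per_sample = pd.DataFrame(records)
    cond = (
        per_sample.groupby(["compound_id", "tier"], sort=False)["probability"]
        .mean()
        .reset_index()
    )
    cond["label"] = cond["compound_id"].map(compound_label)
    cond["cytotoxic"] = False
    return cond, union, fold_models


def permutation_null_auc(
    differences: pd.DataFrame,
    sheet: pd.DataFrame,
    annotations: pd.DataFrame,
    n_permutations: int = 20,
    k: int = DEFAULT_K,
    seed: int = 0,
    inner_folds: int = DEFAULT_INNER_FOLDS,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
) -> np.ndarray:
    """Condition-level AUCs under compound-label permutation.

    Each permutation reassigns the teratogen labels across compounds (class
    sizes preserved), reruns the full leave-one-compound-out procedure and
    computes the condition-level Mann–Whitney AUC; the mean of the returned
    vector should sit near 0.5 when no label information leaks.
    """
    from .sps_classifier import auc_mann_whitney

    seed_seq = np.random.SeedSequence([seed, 104729])
    children = seed_seq.spawn(n_permutations)
    compounds = annotations.drop_duplicates("compound_id")["compound_id"].tolist()
    labels = annotations.drop_duplicates("compound_id")["label"].tolist()
    aucs = []
    for child in children:
        rng = np.random.default_rng(child)
        permuted = dict(zip(compounds, rng.permutation(labels)))
        ann_perm = annotations.copy()
        ann_perm["label"] = ann_perm["compound_id"].map(permuted)
        fold_seed = int(child.generate_state(1)[0] % (2**31))
        cond, _, _ = loocv_classify(
            differences, sheet, ann_perm, k=k, seed=fold_seed,
            inner_folds=inner_folds, n_lambda=n_lambda,
            lambda_min_ratio=lambda_min_ratio,
        )
        pos = cond.loc[cond["label"] == "teratogen", "probability"]
        neg = cond.loc[cond["label"] != "teratogen", "probability"]
        aucs.append(auc_mann_whitney(pos, neg))
    return np.asarray(aucs)


def optimal_probability_threshold(probabilities, labels) -> float:
    """Accuracy-maximal probability cut (midpoint of the optimal interval)."""
    s = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels) == "teratogen" if np.asarray(labels).dtype != bool else np.asarray(labels)
    if y.all() or (~y).all():
        raise ValueError("threshold optimization needs both classes")
    uniq = np.unique(s)
    # candidate behaviors: positive <=> prob >= c, realized at interval
    # midpoints between consecutive unique scores (plus the two extremes)
    bounds = np.concatenate([[0.0], uniq, [1.0]])
    candidates = (bounds[:-1] + bounds[1:]) / 2.0
    best_t, best_acc = None, -1.0
    for t in candidates:
        acc = float(np.mean((s >= t) == y))
        if acc > best_acc:
            best_t, best_acc = float(t), acc
    return best_t


def fuse_and_threshold(
    condition_probabilities: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    threshold: float | str = "auto",
) -> MetricsReport:
    """Fuse cytotoxic conditions at probability 1.0 and apply the threshold.

    ``threshold="auto"`` selects the accuracy-maximal probability cut
    (midpoint of its optimal interval); a fixed value such as 0.3 may be
    supplied instead.  Metrics are computed with the shared
    condition-metrics machinery (Mann–Whitney AUC with half-credit ties).
    """
    cond = condition_probabilities.copy()
    if annotations is not None:
        cyto = annotations[annotations["cytotoxic"].astype(bool)]
        extra = [
            {
                "compound_id": row.compound_id,
                "tier": row.tier,
                "probability": 1.0,
                "label": row.label,
                "cytotoxic": True,
            }
            for row in cyto.itertuples()
        ]
        if extra:
            cond = pd.concat([cond, pd.DataFrame(extra)], ignore_index=True)
    cond.loc[cond["cytotoxic"].astype(bool), "probability"] = 1.0
    bad = (cond["probability"] < 0) | (cond["probability"] > 1)
    if bad.any():
        raise ValueError("probabilities must lie in [0, 1]")

    scored = cond.rename(columns={"probability": "score"})
    scored["auc_eligible"] = True
    if threshold == "auto":
        threshold = optimal_probability_threshold(scored["score"], scored["label"])
    calls = scored["score"] >= float(threshold)
    return compute_metrics(scored, calls, float(threshold))
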
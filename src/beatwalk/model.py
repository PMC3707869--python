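"""Nested cross-validated feature-subset regression for walking speed.

The selection machinery works in three stages:

1. **Pairwise pre-selection** — all p*(p-1)/2 unordered feature pairs are
   scored by the Pearson correlation between the fitted two-feature OLS
   predictions and the measured speeds (for OLS with intercept this is
   the multiple correlation R, computed in closed form from the feature /
   speed correlations, so the full 17,955-pair sweep is a few matrix
   operations).  The 10 features occurring most often in the top 10% of
   pairs are retained.  A "single" variant simply keeps the 10 features
   with the largest absolute correlation with the speeds.

2. **Nested cross-validation** — the songs are split into 10 outer folds
   (for 52 songs: 8 folds of 5 and 2 of 6).  Per outer trial the held-out
   fold is never touched: pre-selection runs on the 9 development folds,
   and all 1023 non-empty subsets of the 10 pre-selected features are
   scored by 9-fold inner cross-validation (the development folds serve
   as inner folds) using pooled validation RMSE.  The best subset —
   smaller subsets win ties — is refit on the full development set and
   predicts the held-out fold.  Pooled predictions over the 10 trials
   give the reported RMSE and PCC.

3. **Final model** — K is the largest subset size ever selected; the K
   most frequently selected features (ties broken by larger mean
   absolute coefficient across trials) are refit on all songs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InsufficientDataError, SingularDesignError


@dataclass
class RegressionModel:
    """A fitted linear model over a subset of song features."""

    feature_ids: list  # column labels (registry names) of the features used
    coefficients: np.ndarray
    intercept: float

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        X = features[self.feature_ids].to_numpy(dtype=float)
        return self.intercept + X @ self.coefficients


@dataclass
class CVReport:
    """Everything the nested cross-validation produced."""

    fold_of: np.ndarray  # outer fold label per song
    trials: list  # per-trial dicts: preselected, chosen, coefficients, ...
    predictions: np.ndarray  # pooled out-of-fold prediction per song
    rmse: float
    pcc: float
    selection_counts: dict  # feature label -> number of trials selecting it
    coef_records: dict = field(default_factory=dict)  # label -> [coefs]

    @property
    def explained_variance(self) -> float:
        """Fraction of speed variance explained = PCC squared."""
        return self.pcc**2

    def to_dict(self) -> dict:
        return {
            "fold_of": self.fold_of.tolist(),
            "trials": [
                {
                    "test_fold": int(t["test_fold"]),
                    "preselected": list(t["preselected"]),
                    "chosen": list(t["chosen"]),
                    "coefficients": [float(c) for c in t["coefficients"]],
                    "intercept": float(t["intercept"]),
                }
                for t in self.trials
            ],
            "predictions": self.predictions.tolist(),
            "rmse": self.rmse,
            "pcc": self.pcc,
            "explained_variance": self.explained_variance,
            "selection_counts": {str(k): int(v) for k, v in self.selection_counts.items()},
        }


def _as_matrix(features) -> tuple[np.ndarray, list]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), list(features.columns)
    X = np.asarray(features, dtype=float)
    return X, list(range(X.shape[1]))


def fit_linear(features, speeds) -> RegressionModel:
    """Ordinary least-squares fit with intercept.

    Raises :class:`SingularDesignError` when the design (including the
    intercept column) is rank deficient or there are not enough songs.
    """
    X, labels = _as_matrix(features)
    y = np.asarray(speeds, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise SingularDesignError(f"need more than {k + 1} songs, got {n}")
    A = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(A) < k + 1:
        raise SingularDesignError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return RegressionModel(
        feature_ids=labels, coefficients=beta[1:], intercept=float(beta[0])
    )


def n_pairs(p: int) -> int:
    """Number of unordered feature pairs, p*(p-1)/2 (17,955 for p=190)."""
    return p * (p - 1) // 2


def _pair_pccs(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form PCC(OLS-pair predictions, y) for every unordered pair.

    For a two-feature OLS fit with intercept, PCC(y_hat, y) equals the
    multiple correlation R with
    R^2 = (r_i^2 + r_j^2 - 2 r_i r_j rho_ij) / (1 - rho_ij^2);
    collinear pairs fall back to the better single feature.
    Returns (ii, jj, pcc) over the upper triangle.
    """
    n, p = X.shape
    sd = X.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(X)
    Z[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    yz = (y - y.mean()) / y.std()
    r = Z.T @ yz / n
    C = Z.T @ Z / n
    ii, jj = np.triu_indices(p, k=1)
    rho = C[ii, jj]
    denom = 1.0 - rho**2
    ri, rj = r[ii], r[jj]
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (ri**2 + rj**2 - 2.0 * ri * rj * rho) / denom
    fallback = np.maximum(ri**2, rj**2)
    r2 = np.where(denom < 1e-12, fallback, r2)
    return ii, jj, np.sqrt(np.clip(r2, 0.0, 1.0))


def preselect_pairs(
    features,
    speeds,
    n_keep: int = 10,
    top_frac: float = 0.10,
    method: str = "pairs",
) -> list:
    """Retain the ``n_keep`` most promising features.

    ``method="pairs"`` (default): score every unordered pair by the PCC
    between its two-feature OLS predictions and the speeds, keep the top
    ``top_frac`` of pairs (rounded up; boundary ties all included) and
    return the features occurring most frequently among them, ties broken
    by the feature's best-pair PCC.  ``method="single"`` returns the
    features with the largest absolute speed correlation.
    """
    X, labels = _as_matrix(features)
    y = np.asarray(speeds, dtype=float)
    if X.shape[0] < 12:
        raise InsufficientDataError("pre-selection needs at least 12 songs")
    if y.std() == 0:
        raise DegenerateDataError("constant speed vector: PCC undefined")
    p = X.shape[1]
    if method == "single":
        sd = X.std(axis=0)
        ok = sd > 0
        r = np.zeros(p)
        Xc = X - X.mean(axis=0)
        r[ok] = (Xc[:, ok].T @ (y - y.mean())) / (X.shape[0] * sd[ok] * y.std())
        order = np.argsort(-np.abs(r), kind="stable")[:n_keep]
        return [labels[i] for i in order]
    if method != "pairs":
        raise ValueError(f"unknown pre-selection method {method!r}")
    ii, jj, pcc = _pair_pccs(X, y)
    m = len(pcc)
    n_top = int(np.ceil(top_frac * m))
    threshold = np.partition(pcc, m - n_top)[m - n_top]
    in_top = pcc >= threshold
    counts = np.bincount(
        np.concatenate([ii[in_top], jj[in_top]]), minlength=p
    )
    best_pair = np.zeros(p)
    np.maximum.at(best_pair, ii, pcc)
    np.maximum.at(best_pair, jj, pcc)
    order = np.lexsort((-best_pair, -counts))[:n_keep]
    return [labels[i] for i in order]


def assign_folds(n: int, n_folds: int = 10, seed: int = 0) -> np.ndarray:
    """Random outer-fold labels with sizes n//k and n//k + 1 (52 -> 8x5 + 2x6)."""
    base, extra = divmod(n, n_folds)
    sizes = [base + 1 if f < extra else base for f in range(n_folds)]
    labels = np.repeat(np.arange(n_folds), sizes)
    rng = np.random.default_rng(seed)
    return labels[rng.permutation(n)]


def _enumerate_subsets(k: int):
    """All non-empty subsets of range(k), smallest first, lexicographic."""
    for size in range(1, k + 1):
        yield from combinations(range(k), size)


def _best_subset(
    A: np.ndarray, y: np.ndarray, inner_folds: np.ndarray
) -> tuple[tuple[int, ...], float]:
    """Exhaustive subset search scored by pooled inner-CV RMSE.

    ``A`` is the development design matrix with the intercept in column 0
    and the pre-selected features in columns 1..k.  Normal-equation Gram
    blocks are accumulated per inner fold so each (subset, fold) fit is a
    small solve.  Singular subsets are skipped.
    """
    uniq = np.unique(inner_folds)
    grams, rhs, masks = [], [], []
    G_all = A.T @ A
    b_all = A.T @ y
    for f in uniq:
        mask = inner_folds == f
        Af = A[mask]
        grams.append(Af.T @ Af)
        rhs.append(Af.T @ y[mask])
        masks.append(mask)
    k = A.shape[1] - 1
    best_score = np.inf
    best_subset: tuple[int, ...] | None = None
    for subset in _enumerate_subsets(k):
        idx = np.array((0,) + tuple(s + 1 for s in subset))
        sse = 0.0
        n_val = 0
        ok = True
        for G_f, b_f, mask in zip(grams, rhs, masks):
            G = (G_all - G_f)[np.ix_(idx, idx)]
            b = (b_all - b_f)[idx]
            try:
                beta = np.linalg.solve(G, b)
            except np.linalg.LinAlgError:
                ok = False
                break
            resid = y[mask] - A[np.ix_(mask.nonzero()[0], idx)] @ beta
            sse += float(resid @ resid)
            n_val += int(mask.sum())
        if not ok:
            continue
        score = np.sqrt(sse / n_val)
        if score < best_score - 1e-12:
            best_score = score
            best_subset = subset
    if best_subset is None:
        raise SingularDesignError("every candidate subset was singular")
    return best_subset, best_score


def nested_cv(
    features,
    speeds,
    seed: int = 0,
    n_folds: int = 10,
    n_preselect: int = 10,
    preselect_method: str = "pairs",
) -> CVReport:
    """10-fold-outer / 9-fold-inner nested CV with exhaustive subset search.

    Pre-selection and subset choice for each outer trial see only the
    development folds; every song is predicted exactly once.
    """
    X, labels = _as_matrix(features)
    y = np.asarray(speeds, dtype=float)
    n = len(y)
    if n < 20:
        raise InsufficientDataError("nested CV needs at least 20 songs")
    fold_of = assign_folds(n, n_folds=n_folds, seed=seed)
    label_index = {lab: i for i, lab in enumerate(labels)}
    predictions = np.empty(n)
    trials = []
    selection_counts: dict = {}
    coef_records: dict = {}
    for t in range(n_folds):
        test_mask = fold_of == t
        dev_mask = ~test_mask
        X_dev, y_dev = X[dev_mask], y[dev_mask]
        dev_labels_folds = fold_of[dev_mask]
        pre = preselect_pairs(
            pd.DataFrame(X_dev, columns=labels),
            y_dev,
            n_keep=n_preselect,
            method=preselect_method,
        )
        pre_idx = [label_index[lab] for lab in pre]
        A_dev = np.column_stack([np.ones(dev_mask.sum()), X_dev[:, pre_idx]])
        subset, _ = _best_subset(A_dev, y_dev, dev_labels_folds)
        chosen = [pre[s] for s in subset]
        chosen_idx = [label_index[lab] for lab in chosen]
        model = fit_linear(X_dev[:, chosen_idx], y_dev)
        predictions[test_mask] = (
            model.intercept + X[np.ix_(test_mask.nonzero()[0], chosen_idx)] @ model.coefficients
        )
        for lab, coef in zip(chosen, model.coefficients):
            selection_counts[lab] = selection_counts.get(lab, 0) + 1
            coef_records.setdefault(lab, []).append(float(coef))
        trials.append(
            {
                "test_fold": t,
                "preselected": pre,
                "chosen": chosen,
                "coefficients": model.coefficients,
                "intercept": model.intercept,
            }
        )
    rmse = float(np.sqrt(np.mean((predictions - y) ** 2)))
    if np.std(predictions) > 0 and np.std(y) > 0:
        pcc = float(np.corrcoef(predictions, y)[0, 1])
    else:
        pcc = 0.0
    return CVReport(
        fold_of=fold_of,
        trials=trials,
        predictions=predictions,
        rmse=rmse,
        pcc=pcc,
        selection_counts=selection_counts,
        coef_records=coef_records,
    )


def final_model(features, speeds, cv: CVReport) -> RegressionModel:
    """Refit the K most frequently selected features on all songs.

    K is the maximum subset size over the outer trials; ties in selection
    frequency are broken by the larger mean absolute coefficient across
    the trials in which the feature appeared.
    """
    X, labels = _as_matrix(features)
    K = max(len(t["chosen"]) for t in cv.trials)
    mean_abs = {
        lab: float(np.mean(np.abs(coefs))) for lab, coefs in cv.coef_records.items()
    }
    ranked = sorted(
        cv.selection_counts,
        key=lambda lab: (-cv.selection_counts[lab], -mean_abs.get(lab, 0.0)),
    )
    chosen = ranked[:K]
    if isinstance(features, pd.DataFrame):
        model = fit_linear(features[chosen], speeds)
        model.feature_ids = chosen
        return model
    idx = [labels.index(lab) for lab in chosen]
    model = fit_linear(X[:, idx], speeds)
    model.feature_ids = chosen
    return model
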
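"""Repeated k-fold cross-validation of genomic predictions.

The population is randomly split into k nearly equal folds; variance
components and fixed effects are re-estimated on the training folds only, and
genetic values of the held-out animals are predicted through the genomic
relationship between validation and training animals.  Prediction accuracy is
the Pearson correlation between the predicted genetic value and the held-out
phenotype adjusted for the training-fold fixed-effect estimates (raw-phenotype
and heritability-scaled variants are available).  With k = 5 and 2 repeats the
result holds 10 accuracy values whose mean and standard error summarise a
trait/model combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import reml as _reml
from .reml import fit_reml

__all__ = [
    "FoldAssignment",
    "CVResult",
    "make_folds",
    "predict_masked",
    "accuracy",
    "cross_validate",
]


@dataclass
class FoldAssignment:
    """Fold ids per individual for every repeat; reproducible from the seed."""

    k: int
    repeats: int
    assignments: np.ndarray  # (repeats, n) integer fold ids in [0, k)
    seed: int

    def fold_mask(self, repeat: int, fold: int) -> np.ndarray:
        return self.assignments[repeat] == fold


@dataclass
class CVResult:
    cells: pd.DataFrame  # repeat, fold, n_val, accuracy, accuracy_total, converged
    mean_accuracy: float
    se: float

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def make_folds(n: int, k: int = 5, repeats: int = 2, seed: int = 0) -> FoldAssignment:
    """Uniform random partition into k folds whose sizes differ by at most 1.

    A fresh permutation is drawn for every repeat from a generator seeded with
    ``seed``, so the full assignment is deterministic given the seed.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} individuals")
    rng = np.random.default_rng(seed)
    base, extra = divmod(n, k)
    sizes = [base + (1 if i < extra else 0) for i in range(k)]
    assignments = np.empty((repeats, n), dtype=np.int64)
    for r in range(repeats):
        perm = rng.permutation(n)
        fold_ids = np.repeat(np.arange(k), sizes)
        assignments[r, perm] = fold_ids
    return FoldAssignment(k, repeats, assignments, seed)


def predict_masked(
    y: np.ndarray,
    X: np.ndarray,
    kinships: Mapping[str, object],
    val_mask: np.ndarray,
    **fit_kwargs,
) -> dict:
    """Refit on the training records and predict genetic values for everyone.

    The kinship matrices are built on all individuals; only phenotypes of the
    validation animals are withheld.  Variance components and fixed effects
    come from the training records alone, then BLUPs flow to the validation
    animals through the genomic relationship blocks:
    ``u_hat = sigma2_k K[:, train] P_t y_t``.

    Fixed-effect columns with no observation in training (an absent factor
    level) are merged into the reference level with a warning.

    Returns a dict with ``fit``, per-term predictions for all individuals
    (``u_hat``, and ``v_hat``/``total`` for dominance models), ``beta`` and
    the retained fixed-effect column indices ``kept_columns``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    val_mask = np.asarray(val_mask, dtype=bool)
    train = ~val_mask
    if train.sum() < 3:
        raise ValueError("too few training records")

    X_t = X[train]
    kept = [j for j in range(X.shape[1]) if np.any(X_t[:, j] != 0.0)]
    if len(kept) < X.shape[1]:
        warnings.warn(
            f"{X.shape[1] - len(kept)} fixed-effect column(s) unobserved in "
            "training; merged into the reference level",
            stacklevel=2,
        )
    X_t = X_t[:, kept]

    names = list(kinships)
    mats = {name: _reml._as_matrix(kinships[name]) for name in names}
    k_train = {name: m[np.ix_(train, train)] for name, m in mats.items()}
    fit = fit_reml(y[train], X_t, k_train, **fit_kwargs)

    theta = np.array([fit.components[n] for n in names + ["residual"]])
    q = _reml._reml_quantities(theta, y[train], X_t, list(k_train.values()))
    out = {"fit": fit, "kept_columns": kept, "beta": fit.beta}
    preds = {}
    for i, name in enumerate(names):
        preds[name] = theta[i] * (mats[name][:, train] @ q.Py)
    out["u_hat"] = preds.get("additive")
    if "dominance" in preds:
        out["v_hat"] = preds["dominance"]
        out["total"] = preds["additive"] + preds["dominance"]
    return out


def accuracy(
    predicted: np.ndarray,
    phenotype: np.ndarray,
    fixed_part: np.ndarray | None = None,
    method: str = "adjusted",
    h2: float | None = None,
) -> float:
    """Prediction accuracy of genetic values against held-out phenotypes.

    ``adjusted`` (default): Pearson correlation with ``phenotype -
    fixed_part`` where the fixed part uses training-fold estimates; ``raw``:
    correlation with the unadjusted phenotype; ``scaled``: the adjusted
    correlation divided by ``sqrt(h2)``.  Returns ``nan`` (with a warning)
    when either vector is constant; requires at least 3 paired records.
    """
    predicted = np.asarray(predicted, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    ok = np.isfinite(predicted) & np.isfinite(phenotype)
    if ok.sum() < 3:
        raise ValueError("at least 3 validation records with phenotypes required")
    if method == "raw":
        target = phenotype
    elif method in ("adjusted", "scaled"):
        if fixed_part is None:
            raise ValueError("adjusted/scaled accuracy needs the fixed part")
        target = phenotype - np.asarray(fixed_part, dtype=float)
    else:
        raise ValueError(f"unknown accuracy method {method!r}")
    x, t = predicted[ok], target[ok]
    if np.std(x) == 0.0 or np.std(t) == 0.0:
        warnings.warn("constant vector: accuracy undefined", stacklevel=2)
        return float("nan")
    r = float(np.corrcoef(x, t)[0, 1])
    if method == "scaled":
        if not h2 or h2 <= 0:
            raise ValueError("scaled accuracy needs h2 > 0")
        r /= float(np.sqrt(h2))
    return r


def cross_validate(
    y: np.ndarray,
    X: np.ndarray,
    kinships: Mapping[str, object],
    model: str = "MAG",
    k: int = 5,
    repeats: int = 2,
    seed: int = 0,
    accuracy_method: str = "adjusted",
    **fit_kwargs,
) -> CVResult:
    """Repeated k-fold CV accuracy for one trait and model.

    Records with missing phenotypes are dropped before fold construction
    (per-trait sample size).  For the dominance model the reported accuracy
    scores the predicted breeding value ``u_hat``; the total genetic value
    ``u_hat + v_hat`` is recorded alongside in the ``accuracy_total`` column.
    A fold whose REML fit fails is recorded as missing and the summary is
    taken over the remaining cells (warned).
    """
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    y = y[keep]
    X = np.asarray(X, dtype=float)[keep]
    terms = ("additive",) if model == "MAG" else ("additive", "dominance")
    ks = {name: _reml._as_matrix(kinships[name])[np.ix_(keep, keep)] for name in terms}

    folds = make_folds(len(y), k=k, repeats=repeats, seed=seed)
    rows = []
    for r in range(repeats):
        for f in range(k):
            val = folds.fold_mask(r, f)
            try:
                pred = predict_masked(y, X, ks, val, **fit_kwargs)
            except np.linalg.LinAlgError as exc:
                warnings.warn(f"fold ({r},{f}) failed: {exc}", stacklevel=2)
                rows.append((r, f, int(val.sum()), np.nan, np.nan, False))
                continue
            fixed = X[val][:, pred["kept_columns"]] @ pred["beta"]
            acc = accuracy(pred["u_hat"][val], y[val], fixed, method=accuracy_method)
            acc_total = np.nan
            if "total" in pred:
                acc_total = accuracy(pred["total"][val], y[val], fixed,
                                     method=accuracy_method)
            rows.append((r, f, int(val.sum()), acc, acc_total,
                         pred["fit"].converged))
    cells = pd.DataFrame(
        rows, columns=["repeat", "fold", "n_val", "accuracy", "accuracy_total",
                       "converged"],
    )
    vals = cells["accuracy"].to_numpy()
    good = np.isfinite(vals)
    if not good.all():
        warnings.warn("some folds produced no accuracy; summary over the rest",
                      stacklevel=2)
    mean = float(np.nanmean(vals)) if good.any() else float("nan")
    se = (
        float(np.nanstd(vals[good], ddof=1) / np.sqrt(good.sum()))
        if good.sum() > 1
        else float("nan")
    )
    return CVResult(cells, mean, se)
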
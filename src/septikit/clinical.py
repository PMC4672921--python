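"""Forward greedy logistic combination of clinical parameters with repeated
cross-validated AUC.

The procedure mirrors how a panel of bedside parameters (PCT, CRP, severity
scores, vitals, and optionally the molecular score itself) is combined into a
diagnostic model: parameters are first screened individually (single-predictor
logistic Wald test), then added greedily, each step keeping the parameter that
maximises the mean test AUC over repeated stratified 1:1 train/test splits
(default 50 x 2 cross-validation). Parameters can be forced into or out of the
model to ask "does anything add to the score?" style questions.

Logistic fits carry a tiny ridge penalty (lambda = 1e-6 on standardized
covariates) purely to keep separated training folds from diverging; it does not
measurably shrink coefficients otherwise. Missing covariate values are imputed
with the training-fold median inside each split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedShuffleSplit

from .io import SeptikitError
from .roc import mann_whitney_auc

logger = logging.getLogger("septikit")

__all__ = ["SelectionTrace", "univariate_screen", "forward_greedy_select", "cv_auc"]

_RIDGE_LAMBDA = 1e-6


@dataclass
class SelectionTrace:
    """Record of a forward greedy selection run."""

    steps: list[tuple[str, float, tuple[float, float]]]  # (parameter, mean AUC, CI)
    forced_in: tuple[str, ...]
    forced_out: tuple[str, ...]
    n_repeats: int
    seed: int | None

    @property
    def selected(self) -> list[str]:
        return [p for p, _, _ in self.steps]

    @property
    def mean_aucs(self) -> list[float]:
        return [a for _, a, _ in self.steps]


def _validate(covariates: pd.DataFrame, labels) -> tuple[pd.DataFrame, np.ndarray]:
    y = np.asarray(labels, dtype=bool)
    if len(covariates) != y.size:
        raise SeptikitError("covariates and labels must be aligned")
    if y.sum() < 2 or (~y).sum() < 2:
        raise SeptikitError("need >= 2 samples per class")
    return covariates, y


def univariate_screen(covariates: pd.DataFrame, labels, alpha: float = 0.05) -> list[str]:
    """Retain covariates individually associated with case status.

    Each covariate enters a single-predictor logistic model; those with Wald
    p <= ``alpha`` survive. Constant or all-missing covariates are excluded with a
    warning; perfect separation counts as (maximally) significant.
    """
    covariates, y = _validate(covariates, labels)
    retained: list[str] = []
    for name in covariates.columns:
        x = pd.to_numeric(covariates[name], errors="coerce")
        ok = x.notna().to_numpy()
        if ok.sum() < 4 or y[ok].sum() < 2 or (~y[ok]).sum() < 2:
            warnings.warn(f"covariate {name!r} has too few observed values; excluded")
            continue
        xv = x.to_numpy(dtype=float)[ok]
        if np.std(xv) == 0.0:
            warnings.warn(f"covariate {name!r} is constant; excluded")
            continue
        xz = (xv - xv.mean()) / xv.std()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y[ok].astype(float), sm.add_constant(xz)).fit(disp=0, maxiter=200)
                p = float(fit.pvalues[1])
            except Exception:  # separation or non-convergence: treat as informative
                p = 0.0
        if np.isnan(p):
            p = 0.0
        if p <= alpha:
            retained.append(name)
    logger.info("univariate screen retained %d/%d covariates", len(retained), covariates.shape[1])
    return retained


def _fit_predict(train_X: np.ndarray, train_y: np.ndarray, test_X: np.ndarray) -> np.ndarray:
    """Ridge-stabilized logistic fit on standardized, median-imputed covariates."""
    med = np.nanmedian(train_X, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    tr = np.where(np.isnan(train_X), med, train_X)
    te = np.where(np.isnan(test_X), med, test_X)
    mu, sd = tr.mean(axis=0), tr.std(axis=0)
    sd[sd == 0.0] = 1.0
    tr = (tr - mu) / sd
    te = (te - mu) / sd
    model = LogisticRegression(C=1.0 / (_RIDGE_LAMBDA * len(tr)),
                               solver="lbfgs", max_iter=1000)
    model.fit(tr, train_y)
    return model.decision_function(te)


def cv_auc(parameters: list[str], covariates: pd.DataFrame, labels,
           n_repeats: int = 50, seed: int | None = None) -> tuple[float, tuple[float, float], np.ndarray]:
    """Mean test AUC of a logistic model over repeated stratified 1:1 splits.

    Returns (mean AUC, 2.5/97.5 percentile interval across repeats, per-repeat AUCs).
    Splits are seeded and stratified by class, train:test = 1:1.
    """
    if not parameters:
        raise SeptikitError("model specification needs at least one parameter")
    missing = [p for p in parameters if p not in covariates.columns]
    if missing:
        raise SeptikitError(f"unknown covariates: {missing}")
    covariates, y = _validate(covariates, labels)
    X = covariates[parameters].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    splitter = StratifiedShuffleSplit(n_splits=n_repeats, test_size=0.5,
                                      random_state=None if seed is None else int(seed) % (2**32))
    aucs = np.empty(n_repeats)
    for r, (tr, te) in enumerate(splitter.split(X, y)):
        pred = _fit_predict(X[tr], y[tr], X[te])
        aucs[r] = mann_whitney_auc(pred[y[te]], pred[~y[te]])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(aucs.mean()), (float(lo), float(hi)), aucs


def forward_greedy_select(covariates: pd.DataFrame, labels, max_k: int = 5,
                          forced_in: tuple[str, ...] = (), forced_out: tuple[str, ...] = (),
                          n_repeats: int = 50, seed: int | None = None,
                          candidates: list[str] | None = None) -> SelectionTrace:
    """Forward greedy model building on cross-validated AUC.

    Starts from the ``forced_in`` parameters (added first, in order, regardless of
    rank), then repeatedly adds the candidate parameter giving the largest mean CV
    AUC; stops at ``max_k`` parameters or when no addition improves the mean AUC.
    ``forced_out`` parameters never enter. The accepted-step AUC sequence is
    non-decreasing by construction.
    """
    if max_k < 1:
        raise SeptikitError("max_k must be >= 1")
    covariates, y = _validate(covariates, labels)
    pool = list(candidates) if candidates is not None else list(covariates.columns)
    pool = [p for p in pool if p not in forced_out and p not in forced_in]

    steps: list[tuple[str, float, tuple[float, float]]] = []
    current: list[str] = []
    for p in forced_in:
        if p not in covariates.columns:
            raise SeptikitError(f"forced_in parameter {p!r} not in covariates")
        current.append(p)
        mean, ci, _ = cv_auc(current, covariates, y, n_repeats=n_repeats, seed=seed)
        steps.append((p, mean, ci))

    best_so_far = steps[-1][1] if steps else -np.inf
    while len(current) < max_k and pool:
        results = []
        for p in pool:
            mean, ci, _ = cv_auc(current + [p], covariates, y, n_repeats=n_repeats, seed=seed)
            results.append((mean, ci, p))
        results.sort(key=lambda r: (-r[0], r[2]))
        mean, ci, p = results[0]
        if mean <= best_so_far:
            break
        current.append(p)
        pool.remove(p)
        steps.append((p, mean, ci))
        best_so_far = mean
        logger.info("greedy step %d: added %r (mean CV AUC %.3f)", len(steps), p, mean)
    return SelectionTrace(steps=steps, forced_in=tuple(forced_in),
                          forced_out=tuple(forced_out), n_repeats=n_repeats, seed=seed)
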
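"""ROC curve analysis and AUC comparison.

The area under the ROC curve is computed throughout as the Mann-Whitney probability
P(case score > control score) + 0.5 P(tie), estimated with midranks. Confidence
intervals come from a class-stratified bootstrap; smooth curves from the binormal
model; and two curves are compared either by DeLong's placement-value test (AUC
difference) or by a permutation test on the integrated absolute difference between
the full empirical curves (Venkatraman-style, sensitive to shape differences that
leave the AUC unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .io import SeptikitError

__all__ = [
    "RocSummary",
    "ComparisonResult",
    "empirical_auc",
    "bootstrap_auc_ci",
    "binormal_auc",
    "delong_test",
    "venkatraman_test",
    "auc_from_scores",
]


@dataclass
class RocSummary:
    auc: float
    ci_low: float
    ci_high: float
    method: str
    n_cases: int
    n_controls: int
    curve: np.ndarray = field(repr=False)  # ordered (FPR, TPR) points

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.auc + 1e-12 and self.auc - 1e-12 <= self.ci_high):
            raise SeptikitError("AUC confidence interval does not bracket the estimate")


@dataclass
class ComparisonResult:
    method: str
    statistic: float
    p_value: float
    estimate: float | None = None
    ci: tuple[float, float] | None = None
    paired: bool | None = None
    reps: int | None = None
    seed: int | None = None
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise SeptikitError(f"p-value {self.p_value} outside [0, 1]")


def _as_groups(case_scores, control_scores) -> tuple[np.ndarray, np.ndarray]:
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if cases.size == 0 or control_scores is None or controls.size == 0:
        raise SeptikitError("both score groups must be non-empty")
    return cases, controls


def mann_whitney_auc(case_scores, control_scores) -> float:
    """Empirical AUC = P(case > control) + 0.5 P(case = control), via midranks."""
    cases, controls = _as_groups(case_scores, control_scores)
    n1, n0 = cases.size, controls.size
    ranks = rankdata(np.concatenate([cases, controls]))
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _empirical_curve(cases: np.ndarray, controls: np.ndarray) -> np.ndarray:
    y = np.concatenate([np.ones(cases.size), np.zeros(controls.size)])
    fpr, tpr, _ = _sk_roc_curve(y, np.concatenate([cases, controls]))
    return np.column_stack([fpr, tpr])


def empirical_auc(case_scores, control_scores) -> RocSummary:
    """Empirical (midrank) AUC with the full step ROC curve; no resampled CI."""
    cases, controls = _as_groups(case_scores, control_scores)
    auc = mann_whitney_auc(cases, controls)
    return RocSummary(auc=auc, ci_low=auc, ci_high=auc, method="empirical",
                      n_cases=cases.size, n_controls=controls.size,
                      curve=_empirical_curve(cases, controls))


def bootstrap_auc_ci(case_scores, control_scores, reps: int = 2000,
                     seed: int | None = None, alpha: float = 0.05) -> RocSummary:
    """Stratified bootstrap percentile CI around the empirical AUC.

    Resamples cases and controls separately (preserving group sizes); degenerate
    replicates are retained, since the midrank estimator stays defined.
    """
    if reps < 100:
        raise SeptikitError("bootstrap needs reps >= 100")
    cases, controls = _as_groups(case_scores, control_scores)
    rng = np.random.default_rng(seed)
    n1, n0 = cases.size, controls.size
    aucs = np.empty(reps)
    for r in range(reps):
        aucs[r] = mann_whitney_auc(cases[rng.integers(0, n1, n1)],
                                   controls[rng.integers(0, n0, n0)])
    lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    auc = mann_whitney_auc(cases, controls)
    return RocSummary(auc=auc, ci_low=float(min(lo, auc)), ci_high=float(max(hi, auc)),
                      method="empirical", n_cases=n1, n_controls=n0,
                      curve=_empirical_curve(cases, controls))


def binormal_auc(case_scores, control_scores, n_curve_points: int = 200) -> RocSummary:
    """Binormal smooth ROC fitted by the method of moments.

    With a = (mu_case - mu_control)/sd_case and b = sd_control/sd_case, the smooth
    curve is TPR = Phi(a + b * Phi^-1(FPR)) and AUC = Phi(a / sqrt(1 + b^2)).
    """
    cases, controls = _as_groups(case_scores, control_scores)
    if np.unique(cases).size < 2 or np.unique(controls).size < 2:
        raise SeptikitError("binormal fit needs >= 2 distinct values per group; "
                            "use the empirical method instead")
    sd1, sd0 = cases.std(ddof=1), controls.std(ddof=1)
    a = (cases.mean() - controls.mean()) / sd1
    b = sd0 / sd1
    auc = float(sps.norm.cdf(a / np.sqrt(1.0 + b * b)))
    fpr = np.linspace(0.0, 1.0, n_curve_points)
    with np.errstate(divide="ignore"):
        tpr = sps.norm.cdf(a + b * sps.norm.ppf(fpr))
    tpr[0], tpr[-1] = 0.0, 1.0
    return RocSummary(auc=auc, ci_low=auc, ci_high=auc, method="binormal",
                      n_cases=cases.size, n_controls=controls.size,
                      curve=np.column_stack([fpr, tpr]))


# --- DeLong's test -------------------------------------------------------------------

def _placements(cases: np.ndarray, controls: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus per-case / per-control placement values (midrank convention)."""
    n1, n0 = cases.size, controls.size
    r_all = rankdata(np.concatenate([cases, controls]))
    v10 = (r_all[:n1] - rankdata(cases)) / n0           # per case: P(case > control)
    v01 = 1.0 - (r_all[n1:] - rankdata(controls)) / n1  # per control
    return float(v10.mean()), v10, v01


def _split_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    case_mask = np.asarray(labels, dtype=bool)
    if scores.shape != case_mask.shape:
        raise SeptikitError("scores and labels must have equal length")
    return scores[case_mask], scores[~case_mask]


def delong_test(scores_a, scores_b, labels, labels_b=None,
                paired: bool = True) -> ComparisonResult:
    """DeLong's test for the difference of two correlated (or independent) AUCs.

    ``labels`` is a boolean case indicator aligned with ``scores_a`` (and with
    ``scores_b`` when paired). For unpaired comparisons pass ``labels_b`` for the
    second cohort. Two-sided normal p-value on the AUC difference.
    """
    ca, ka = _split_scores(scores_a, labels)
    if paired:
        if labels_b is not None:
            raise SeptikitError("paired comparison uses a single label vector")
        if np.asarray(scores_b, dtype=float).shape != np.asarray(scores_a, dtype=float).shape:
            raise SeptikitError("paired comparison requires identical sample sets")
        cb, kb = _split_scores(scores_b, labels)
    else:
        if labels_b is None:
            raise SeptikitError("unpaired comparison needs labels_b for the second cohort")
        cb, kb = _split_scores(scores_b, labels_b)

    auc_a, v10a, v01a = _placements(ca, ka)
    auc_b, v10b, v01b = _placements(cb, kb)
    delta = auc_a - auc_b
    if paired:
        s10 = np.cov(np.vstack([v10a, v10b]))
        s01 = np.cov(np.vstack([v01a, v01b]))
        var = ((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / ca.size
               + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / ka.size)
    else:
        var = (np.var(v10a, ddof=1) / ca.size + np.var(v01a, ddof=1) / ka.size
               + np.var(v10b, ddof=1) / cb.size + np.var(v01b, ddof=1) / kb.size)
    if var <= 0.0:
        z, p = 0.0, 1.0
    else:
        z = delta / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    se = float(np.sqrt(max(var, 0.0)))
    ci = (delta - 1.959963984540054 * se, delta + 1.959963984540054 * se)
    return ComparisonResult(method="delong", statistic=float(z), p_value=p,
                            estimate=float(delta), ci=ci, paired=paired,
                            details={"auc_a": auc_a, "auc_b": auc_b, "var_delta": float(var)})


# --- Venkatraman-style whole-curve permutation test ---------------------------------

def _tpr_profiles(case_mat: np.ndarray, control_mat: np.ndarray) -> np.ndarray:
    """TPR of each row's marker at the FPR grid j/n0, j = 1..n0-1.

    ``case_mat`` is (B, n1) and ``control_mat`` (B, n0): B candidate score vectors.
    The threshold realising FPR j/n0 is the j-th largest control score; TPR is the
    fraction of cases strictly above it (deterministic tie handling).
    """
    thr = -np.sort(-control_mat, axis=1)[:, :-1]  # (B, n0-1) descending
    return (case_mat[:, None, :] > thr[:, :, None]).mean(axis=2)


def _curve_diff_stat(ca, ka, cb, kb) -> float:
    ta = _tpr_profiles(ca[None, :], ka[None, :])
    tb = _tpr_profiles(cb[None, :], kb[None, :])
    return float(np.abs(ta - tb).mean())


def venkatraman_test(scores_a, scores_b, labels, labels_b=None, reps: int = 2000,
                     seed: int | None = None, paired: bool = True) -> ComparisonResult:
    """Permutation test of equality of two entire empirical ROC curves.

    The statistic is the mean absolute TPR difference between the two empirical
    curves over the control-rank FPR grid. The null is generated by seeded exchange:
    per-subject marker swaps when paired, or reshuffling subjects between the two
    markers within each disease class when unpaired. p = (exceedances + 1)/(reps + 1).
    """
    if reps < 100:
        raise SeptikitError("permutation test needs reps >= 100")
    rng = np.random.default_rng(seed)
    ca, ka = _split_scores(scores_a, labels)
    if paired:
        if np.asarray(scores_b, dtype=float).shape != np.asarray(scores_a, dtype=float).shape:
            raise SeptikitError("paired comparison requires identical sample sets")
        cb, kb = _split_scores(scores_b, labels)
    else:
        if labels_b is None:
            raise SeptikitError("unpaired comparison needs labels_b for the second cohort")
        cb, kb = _split_scores(scores_b, labels_b)
        if ca.size != cb.size or ka.size != kb.size:
            raise SeptikitError("unpaired curve comparison requires equal group sizes "
                                "per class (common FPR/TPR grid)")
    observed = _curve_diff_stat(ca, ka, cb, kb)

    if paired:
        swap_c = rng.random((reps, ca.size)) < 0.5
        swap_k = rng.random((reps, ka.size)) < 0.5
        ca_p = np.where(swap_c, cb, ca)
        cb_p = np.where(swap_c, ca, cb)
        ka_p = np.where(swap_k, kb, ka)
        kb_p = np.where(swap_k, ka, kb)
    else:
        pool_c = np.concatenate([ca, cb])
        pool_k = np.concatenate([ka, kb])
        ca_p = np.empty((reps, ca.size)); cb_p = np.empty((reps, cb.size))
        ka_p = np.empty((reps, ka.size)); kb_p = np.empty((reps, kb.size))
        for r in range(reps):
            pc = rng.permutation(pool_c)
            pk = rng.permutation(pool_k)
            ca_p[r], cb_p[r] = pc[:ca.size], pc[ca.size:]
            ka_p[r], kb_p[r] = pk[:ka.size], pk[ka.size:]

    perm_stats = np.abs(_tpr_profiles(ca_p, ka_p) - _tpr_profiles(cb_p, kb_p)).mean(axis=1)
    exceed = int((perm_stats >= observed - 1e-15).sum())
    p = (exceed + 1) / (reps + 1)
    return ComparisonResult(method="venkatraman", statistic=observed, p_value=float(p),
                            estimate=observed, paired=paired, reps=reps, seed=seed)


def auc_from_scores(scores, labels) -> float:
    """Convenience: midrank AUC from a score vector and a boolean case indicator."""
    cases, controls = _split_scores(scores, labels)
    return mann_whitney_auc(cases, controls)
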
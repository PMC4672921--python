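"""Binary-test performance metrics and cohort-level statistical comparisons.

Covers the 2x2 contingency metrics at a fixed decision cutoff (accuracy, sensitivity,
specificity, PPV, NPV, LR+/LR- with confidence intervals), the net reclassification
indices for paired binary tests, two-sample distribution comparisons (KS, t,
Wilcoxon rank-sum with an automatic normality screen), and the exact binomial
check for case/control size imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .io import SeptikitError
from .roc import ComparisonResult

__all__ = [
    "ContingencyMetrics",
    "NriResult",
    "BalanceResult",
    "contingency_metrics",
    "nri",
    "compare_distributions",
    "binomial_balance_check",
]

_Z = 1.959963984540054  # two-sided 95% normal quantile


def _wilson(count: int, nobs: int) -> tuple[float, float]:
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return float(lo), float(hi)


@dataclass
class ContingencyMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    ppv: float = field(init=False)
    npv: float = field(init=False)
    lr_pos: float = field(init=False)
    lr_neg: float = field(init=False)
    ci: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        tp, fp, fn, tn = self.tp, self.fp, self.fn, self.tn
        n_cases, n_controls = tp + fn, fp + tn
        if n_cases == 0 or n_controls == 0:
            raise SeptikitError("both classes must be non-empty")
        n = n_cases + n_controls
        self.accuracy = (tp + tn) / n
        self.sensitivity = tp / n_cases
        self.specificity = tn / n_controls
        self.ppv = tp / (tp + fp) if tp + fp else float("nan")
        self.npv = tn / (tn + fn) if tn + fn else float("nan")
        self.lr_pos = (self.sensitivity / (1 - self.specificity)
                       if self.specificity < 1 else float("inf"))
        self.lr_neg = ((1 - self.sensitivity) / self.specificity
                       if self.specificity > 0 else float("inf"))
        self.ci = {
            "accuracy": _wilson(tp + tn, n),
            "sensitivity": _wilson(tp, n_cases),
            "specificity": _wilson(tn, n_controls),
            "ppv": _wilson(tp, tp + fp) if tp + fp else (float("nan"),) * 2,
            "npv": _wilson(tn, tn + fn) if tn + fn else (float("nan"),) * 2,
            "lr_pos": self._lr_ci(positive=True),
            "lr_neg": self._lr_ci(positive=False),
        }

    def _lr_ci(self, positive: bool) -> tuple[float, float]:
        """Log-method (Simel) CI; 0.5 is added to every cell only when some cell is 0."""
        tp, fp, fn, tn = self.tp, self.fp, self.fn, self.tn
        if min(tp, fp, fn, tn) == 0:
            tp, fp, fn, tn = tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5
        sens, spec = tp / (tp + fn), tn / (fp + tn)
        if positive:
            lr = sens / (1 - spec)
            se = np.sqrt(1 / tp - 1 / (tp + fn) + 1 / fp - 1 / (fp + tn))
        else:
            lr = (1 - sens) / spec
            se = np.sqrt(1 / fn - 1 / (tp + fn) + 1 / tn - 1 / (fp + tn))
        return (float(lr * np.exp(-_Z * se)), float(lr * np.exp(_Z * se)))

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.fp + self.tn

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            **{k: getattr(self, k) for k in
               ("accuracy", "sensitivity", "specificity", "ppv", "npv", "lr_pos", "lr_neg")},
            "ci": self.ci,
        }


def _call_arrays(calls, labels) -> tuple[np.ndarray, np.ndarray]:
    calls = np.asarray(calls, dtype=bool)
    case_mask = np.asarray(labels, dtype=bool)
    if calls.shape != case_mask.shape:
        raise SeptikitError("calls and labels must be aligned")
    return calls, case_mask


def contingency_metrics(calls, labels) -> ContingencyMetrics:
    """2x2 metrics for binary calls against a boolean case indicator."""
    calls, case = _call_arrays(calls, labels)
    return ContingencyMetrics(
        tp=int((calls & case).sum()), fp=int((calls & ~case).sum()),
        fn=int((~calls & case).sum()), tn=int((~calls & ~case).sum()),
    )


@dataclass
class NriResult:
    """Net reclassification indices when a new binary test replaces an old one.

    For paired binary tests NRI+ is the sensitivity gain among cases and NRI- the
    specificity gain among controls; inference uses the paired-proportion variance
    of the discordant reclassifications.
    """

    nri_pos: float
    nri_pos_ci: tuple[float, float]
    nri_pos_p: float
    nri_neg: float
    nri_neg_ci: tuple[float, float]
    nri_neg_p: float
    n_cases: int
    n_controls: int


def _paired_delta(new_pos: np.ndarray, old_pos: np.ndarray) -> tuple[float, tuple[float, float], float]:
    n = new_pos.size
    b = int((new_pos & ~old_pos).sum())   # reclassified upward by the new test
    c = int((~new_pos & old_pos).sum())   # reclassified downward
    delta = (b - c) / n
    var = (b + c) / n**2 - (b - c) ** 2 / n**3
    if var <= 0:
        p = 1.0 if delta == 0 else 0.0
        se = 0.0
    else:
        se = float(np.sqrt(var))
        p = float(2 * sps.norm.sf(abs(delta) / se))
    return float(delta), (delta - _Z * se, delta + _Z * se), p


def nri(calls_new, calls_old, labels) -> NriResult:
    """NRI+ / NRI- for paired binary calls on the same samples."""
    new, case = _call_arrays(calls_new, labels)
    old, _ = _call_arrays(calls_old, labels)
    if new.shape != old.shape:
        raise SeptikitError("paired NRI requires call vectors on identical samples")
    if case.sum() == 0 or (~case).sum() == 0:
        raise SeptikitError("both classes must be non-empty")
    pos, pos_ci, pos_p = _paired_delta(new[case], old[case])
    # among controls the beneficial direction is becoming call-negative
    neg, neg_ci, neg_p = _paired_delta(~new[~case], ~old[~case])
    return NriResult(nri_pos=pos, nri_pos_ci=pos_ci, nri_pos_p=pos_p,
                     nri_neg=neg, nri_neg_ci=neg_ci, nri_neg_p=neg_p,
                     n_cases=int(case.sum()), n_controls=int((~case).sum()))


def compare_distributions(sample_x, sample_y, mode: str = "auto") -> ComparisonResult:
    """Two-sample distribution comparison.

    ``mode='ks'`` compares cumulative distributions (two-sided Kolmogorov-Smirnov);
    ``'t'`` is Welch's t-test; ``'wilcoxon'`` the rank-sum test. ``'auto'`` screens
    both samples for normality (Shapiro-Wilk at alpha = 0.05) and picks t when both
    pass, Wilcoxon otherwise.
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if mode not in ("auto", "t", "wilcoxon", "ks"):
        raise SeptikitError(f"unknown mode {mode!r}")
    if x.size < 2 or y.size < 2:
        raise SeptikitError("each sample needs >= 2 observations")
    chosen = mode
    if mode == "auto":
        if x.size < 3 or y.size < 3:
            raise SeptikitError("auto mode needs >= 3 observations per sample")
        normal = (sps.shapiro(x).pvalue > 0.05) and (sps.shapiro(y).pvalue > 0.05)
        chosen = "t" if normal else "wilcoxon"
    if chosen == "ks":
        res = sps.ks_2samp(x, y, alternative="two-sided")
    elif chosen == "t":
        res = sps.ttest_ind(x, y, equal_var=False)
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return ComparisonResult(method=chosen, statistic=float(res.statistic),
                            p_value=float(min(res.pvalue, 1.0)),
                            details={"requested_mode": mode})


@dataclass
class BalanceResult:
    balanced: bool
    n1: int
    n2: int
    ci: tuple[int, int]  # central 95% interval of Binomial(n1+n2, 1/2)


def binomial_balance_check(n_group1: int, n_group2: int, alpha: float = 0.05) -> BalanceResult:
    """Flag a two-group size split as unbalanced.

    The groups are imbalanced when the observed count falls outside the exact
    equal-tailed 95% interval of Binomial(n1 + n2, 1/2) centred on (n1 + n2)/2.
    """
    n1, n2 = int(n_group1), int(n_group2)
    if n1 < 0 or n2 < 0 or n1 + n2 < 1:
        raise SeptikitError("counts must be non-negative with a positive total")
    n = n1 + n2
    lo = int(sps.binom.ppf(alpha / 2, n, 0.5))
    hi = int(sps.binom.ppf(1 - alpha / 2, n, 0.5))
    return BalanceResult(balanced=bool(lo <= n1 <= hi), n1=n1, n2=n2, ci=(lo, hi))
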
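"""Ct-based scoring, platform harmonisation, score bands, and disease probabilities.

The quantitative score for a four-gene RT-qPCR panel is the signed sum of threshold
cycles

    score = -Ct(PLAC8) + Ct(PLA2G7) - Ct(LAMP1) + Ct(CEACAM4)

with coefficients fixed at +/-1. Because Ct falls as transcript abundance rises,
the signs are flipped relative to the expression-scale classifier; the two scores
agree up to an affine map whenever Ct = alpha - beta * log2(intensity). Higher
scores indicate higher sepsis probability. Scores fall into bands (default edges
4, 6, 9) whose per-class frequencies give diagnostic likelihood ratios, which a
pre-test probability converts into post-test probabilities through Bayes' rule on
the odds scale.

Boundary conventions, stated once: bands are half-open [lo, hi) so that they
partition the score axis, and the binary call is positive at score >= cutoff
(the default cutoff 3.100 deliberately biases toward sensitivity, so the boundary
belongs to the positive class).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AssayConfig, CohortLabels, CtPanel, REFERENCE_PLATFORM, SeptikitError

logger = logging.getLogger("septikit")

__all__ = [
    "ScoredSample",
    "compute_septiscore",
    "adjust_platform",
    "assign_band",
    "band_labels",
    "binary_call",
    "score_panels",
    "band_table",
    "band_table_from_counts",
    "post_test_probability",
]

#: Signs applied to (PLAC8, PLA2G7, LAMP1, CEACAM4) threshold cycles.
CT_COEFFICIENTS = (-1.0, +1.0, -1.0, +1.0)


@dataclass
class ScoredSample:
    sample_id: str
    septiscore: float  # NaN when any Ct was missing
    band: str | None
    binary_call: bool | None
    platform_adjusted: bool


def compute_septiscore(panel: CtPanel) -> float:
    """Signed Ct sum; NaN (no imputation) when any of the four Ct values is missing."""
    if not panel.complete:
        logger.info("sample %s has missing Ct values; no score computed", panel.sample_id)
        return float("nan")
    return float(sum(c * v for c, v in zip(CT_COEFFICIENTS, panel.ct_values)))


def adjust_platform(score: float, platform_id: str | None, config: AssayConfig) -> float:
    """Affine shift of a score onto the reference RT-qPCR chemistry scale.

    ``adjusted = offset + slope * score`` with per-platform (offset, slope) pairs
    from the config. The reference platform (and a missing platform id) maps to the
    identity; any other unregistered platform is an error.
    """
    if platform_id is None or platform_id.lower() == REFERENCE_PLATFORM:
        return float(score)
    key = platform_id.lower()
    if key not in config.platform_shifts:
        raise SeptikitError(
            f"unknown platform {platform_id!r}; registered: "
            f"{sorted(config.platform_shifts) + [REFERENCE_PLATFORM]}"
        )
    offset, slope = config.platform_shifts[key]
    return float(offset + slope * score)


def band_labels(band_edges: tuple[float, ...]) -> list[str]:
    """Human-readable labels for the half-open score bands defined by the edges."""
    def fmt(x: float) -> str:
        return f"{x:g}"
    labels = [f"<{fmt(band_edges[0])}"]
    labels += [f"{fmt(a)}–{fmt(b)}" for a, b in zip(band_edges, band_edges[1:])]
    labels.append(f">{fmt(band_edges[-1])}")
    return labels


def assign_band(score: float, band_edges: tuple[float, ...] = (4.0, 6.0, 9.0)) -> str:
    """Band label for a score under the half-open [lo, hi) convention."""
    if not np.isfinite(score):
        raise SeptikitError(f"cannot band non-finite score {score}")
    edges = tuple(band_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise SeptikitError("band edges must be strictly increasing")
    idx = int(np.searchsorted(edges, score, side="right"))
    return band_labels(edges)[idx]


def binary_call(score: float, cutoff: float = 3.100) -> bool:
    """Positive iff score >= cutoff (boundary assigned to the positive class)."""
    if not np.isfinite(score):
        raise SeptikitError(f"cannot call non-finite score {score}")
    return bool(score >= cutoff)


def score_panels(panels: list[CtPanel], config: AssayConfig | None = None) -> pd.DataFrame:
    """Score a collection of Ct panels: platform-adjusted score, band, binary call.

    Returns a DataFrame indexed by sample id with columns ``septiscore`` (rounded to
    3 decimals for reporting, matching the cutoff precision), ``band``,
    ``binary_call`` and ``platform_adjusted``; incomplete panels keep NaN/None.
    """
    config = config or AssayConfig()
    rows = []
    for p in panels:
        raw = compute_septiscore(p)
        if np.isnan(raw):
            rows.append(ScoredSample(p.sample_id, float("nan"), None, None, False))
            continue
        adjusted = adjust_platform(raw, p.platform_id, config)
        rows.append(ScoredSample(
            sample_id=p.sample_id,
            septiscore=round(adjusted, 3),
            band=assign_band(adjusted, config.band_edges),
            binary_call=binary_call(adjusted, config.cutoff),
            platform_adjusted=(adjusted != raw),
        ))
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("sample_id")
    logger.info("scored %d panels (%d incomplete)", len(df), int(df["septiscore"].isna().sum()))
    return df


def post_test_probability(pretest: float, lr: float) -> float:
    """Bayes on the odds scale: posterior = odds*LR / (1 + odds*LR), odds = p/(1-p)."""
    if not (0.0 < pretest < 1.0):
        raise SeptikitError("pretest probability must lie in (0, 1)")
    if lr < 0:
        raise SeptikitError("likelihood ratio must be non-negative")
    if np.isinf(lr):
        return 1.0
    odds = pretest / (1.0 - pretest) * lr
    return float(odds / (1.0 + odds))


def band_table_from_counts(case_counts, control_counts,
                           band_edges: tuple[float, ...] = (4.0, 6.0, 9.0),
                           pretest: float = 0.30) -> pd.DataFrame:
    """Likelihood-ratio band table from per-band case/control counts.

    For each band, LR = (cases_in_band / total_cases) / (controls_in_band / total_controls)
    with no continuity correction: a zero control fraction against a positive case
    fraction yields +inf, and a zero case fraction yields 0. The post-test column
    applies ``pretest`` through the odds-ratio form. Per-class fractions each sum
    to 1 across bands.
    """
    cases = np.asarray(case_counts, dtype=float)
    controls = np.asarray(control_counts, dtype=float)
    labels = band_labels(tuple(band_edges))
    if cases.size != len(labels) or controls.size != len(labels):
        raise SeptikitError(f"expected {len(labels)} per-band counts (bands: {labels})")
    total_cases, total_controls = cases.sum(), controls.sum()
    if total_cases == 0 or total_controls == 0:
        raise SeptikitError("each class needs at least one sample")
    frac_cases = cases / total_cases
    frac_controls = controls / total_controls
    lr = np.empty(cases.size)
    for i, (fc, fk) in enumerate(zip(frac_cases, frac_controls)):
        if fc == 0.0:
            lr[i] = 0.0
        elif fk == 0.0:
            lr[i] = float("inf")
        else:
            lr[i] = fc / fk
    post = [post_test_probability(pretest, v) for v in lr]
    return pd.DataFrame({
        "n_controls": controls.astype(int),
        "n_cases": cases.astype(int),
        "fraction_of_all": (cases + controls) / (total_cases + total_controls),
        "fraction_of_controls": frac_controls,
        "fraction_of_cases": frac_cases,
        "likelihood_ratio": lr,
        "pretest_probability": pretest,
        "post_test_probability": post,
    }, index=pd.Index(labels, name="band"))


def band_table(scores: pd.Series, labels: CohortLabels,
               band_edges: tuple[float, ...] = (4.0, 6.0, 9.0),
               pretest: float = 0.30) -> pd.DataFrame:
    """Likelihood-ratio band table for observed scores and case/control labels.

    ``scores`` is indexed by sample id; samples labelled 'possible' must already be
    excluded. See :func:`band_table_from_counts` for the column semantics.
    """
    case_mask = labels.case_mask(list(scores.index))
    bands = pd.Categorical(
        [assign_band(s, band_edges) for s in scores],
        categories=band_labels(tuple(band_edges)), ordered=True,
    )
    tab = pd.crosstab(bands, case_mask, dropna=False)
    for col in (False, True):
        if col not in tab.columns:
            tab[col] = 0
    return band_table_from_counts(
        tab[True].to_numpy(), tab[False].to_numpy(), band_edges=band_edges, pretest=pretest
    )
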
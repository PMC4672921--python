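"""Discovery of additive two-ratio gene-expression classifiers.

The central transform replaces per-gene log2 intensities with log-ratios between
gene pairs: ratio(A, B) = log2 I_A - log2 I_B. Every two-gene ratio is screened by
its case-vs-control AUC, each oriented so that higher values associate with the
case class; a greedy search then seeds on the best ratio and scans a pool of
top-ranking candidates for the partner ratio that maximises the AUC of the summed
score, under the constraint that the two ratios use four distinct genes. The
canonical result of this procedure is the four-gene score
log2(PLAC8/PLA2G7) + log2(LAMP1/CEACAM4).

Ratio ranking is invariant to the log base (a base change rescales every feature by
the same positive constant); base 2 is used by microarray convention.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr as norm_cdf
from scipy.stats import rankdata

from .io import CohortLabels, ExpressionMatrix, PANEL_GENES, SeptikitError

logger = logging.getLogger("septikit")

__all__ = [
    "RatioFeature",
    "RatioClassifier",
    "compute_ratio_feature",
    "prefilter_genes",
    "screen_all_ratios",
    "greedy_pair_search",
    "apply_classifier",
    "differential_expression_filter",
    "discover",
    "septicyte_classifier",
    "subsample_stability",
]


@dataclass(frozen=True)
class RatioFeature:
    """An oriented two-gene log-ratio: orientation * (log2 I_a - log2 I_b)."""

    gene_a: str
    gene_b: str
    orientation: int  # +1 or -1, chosen so that higher feature values favour cases
    auc: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise SeptikitError("ratio requires two distinct genes")
        if self.orientation not in (-1, 1):
            raise SeptikitError("orientation must be +1 or -1")
        if not (0.5 - 1e-12 <= self.auc <= 1.0 + 1e-12):
            raise SeptikitError(f"oriented AUC {self.auc} outside [0.5, 1]")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset((self.gene_a, self.gene_b))

    def values(self, matrix: ExpressionMatrix) -> pd.Series:
        return self.orientation * compute_ratio_feature(matrix, self.gene_a, self.gene_b)


@dataclass(frozen=True)
class RatioClassifier:
    """Sum of two oriented ratio features over four distinct genes.

    ``ratio_2`` may be None when the greedy search found no admissible partner;
    the classifier then degenerates to the single seed ratio.
    """

    ratio_1: RatioFeature
    ratio_2: RatioFeature | None
    training_auc: float

    def __post_init__(self) -> None:
        if self.ratio_2 is not None and self.ratio_1.genes & self.ratio_2.genes:
            raise SeptikitError("the two ratios must use four distinct genes")

    @property
    def gene_set(self) -> frozenset[str]:
        genes = set(self.ratio_1.genes)
        if self.ratio_2 is not None:
            genes |= self.ratio_2.genes
        return frozenset(genes)

    def to_dict(self) -> dict:
        d = {
            "ratio_1": {"gene_a": self.ratio_1.gene_a, "gene_b": self.ratio_1.gene_b,
                        "orientation": self.ratio_1.orientation, "auc": self.ratio_1.auc},
            "training_auc": self.training_auc,
            "gene_set": sorted(self.gene_set),
        }
        if self.ratio_2 is not None:
            d["ratio_2"] = {"gene_a": self.ratio_2.gene_a, "gene_b": self.ratio_2.gene_b,
                            "orientation": self.ratio_2.orientation, "auc": self.ratio_2.auc}
        return d


def septicyte_classifier() -> RatioClassifier:
    """The canonical four-gene classifier: log2(PLAC8/PLA2G7) + log2(LAMP1/CEACAM4)."""
    plac8, pla2g7, lamp1, ceacam4 = PANEL_GENES
    return RatioClassifier(
        ratio_1=RatioFeature(plac8, pla2g7, orientation=1, auc=1.0),
        ratio_2=RatioFeature(lamp1, ceacam4, orientation=1, auc=1.0),
        training_auc=1.0,
    )


def compute_ratio_feature(matrix: ExpressionMatrix, gene_a: str, gene_b: str) -> pd.Series:
    """Per-sample log-ratio log2 I_a - log2 I_b (requires a log2-scale matrix)."""
    if matrix.scale != "log2":
        raise SeptikitError("ratio features require a log2-scale matrix; call to_log2()")
    for g in (gene_a, gene_b):
        if g not in matrix.data.index:
            raise SeptikitError(f"unknown gene {g!r}")
    feat = matrix.data.loc[gene_a] - matrix.data.loc[gene_b]
    feat.name = f"{gene_a}/{gene_b}"
    return feat


def _fast_auc(values: np.ndarray, case_mask: np.ndarray) -> float:
    n1 = int(case_mask.sum())
    n0 = values.size - n1
    ranks = rankdata(values)
    return float((ranks[case_mask].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _binormal_screen_auc(values: np.ndarray, case_mask: np.ndarray) -> float:
    """Binormal (moment-based) AUC = Phi(dmu / sqrt(sd1^2 + sd0^2)); 0.5 if degenerate.

    Used as the screening objective: it is a smooth function of the group moments,
    so its sampling variance is far below the empirical estimate's, which tames
    selection optimism when maximising over thousands of candidate ratios.
    """
    c, k = values[case_mask], values[~case_mask]
    denom = np.sqrt(c.var(ddof=1) + k.var(ddof=1))
    if denom == 0.0 or not np.isfinite(denom):
        return 0.5
    return float(norm_cdf((c.mean() - k.mean()) / denom))


_OBJECTIVES = {"binormal": _binormal_screen_auc, "empirical": _fast_auc}


def _smd(values: np.ndarray, case_mask: np.ndarray) -> float:
    """Absolute standardized mean difference; 0 on degenerate (constant) input."""
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    if sd == 0.0:
        return 0.0
    return abs(values[case_mask].mean() - values[~case_mask].mean()) / sd


def _aligned(matrix: ExpressionMatrix, labels: CohortLabels) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Value grid restricted to labelled case/control samples, plus case mask."""
    known = labels.known_status()
    ids = [s for s in matrix.sample_ids if s in known.frame.index]
    if not ids:
        raise SeptikitError("no labelled case/control samples found in the matrix")
    case_mask = known.case_mask(ids)
    if case_mask.sum() == 0 or (~case_mask).sum() == 0:
        raise SeptikitError("need at least one case and one control")
    return matrix.data[ids].to_numpy(dtype=float), case_mask, ids


def prefilter_genes(matrix: ExpressionMatrix, labels: CohortLabels, top_n: int) -> list[str]:
    """Rank genes by oriented univariate AUC and keep the top ``top_n``.

    This generic screen stands in for heavier wrapper-based enrichment; ties are
    broken by absolute standardized mean difference, then lexicographic gene id.
    """
    values, case_mask, _ = _aligned(matrix, labels)
    if case_mask.sum() < 2 or (~case_mask).sum() < 2:
        raise SeptikitError("prefilter needs >= 2 samples per class")
    genes = matrix.gene_ids
    if top_n > len(genes):
        warnings.warn(f"top_n={top_n} exceeds gene count {len(genes)}; returning all genes")
        top_n = len(genes)
    rows = []
    for i, g in enumerate(genes):
        auc = _fast_auc(values[i], case_mask)
        rows.append((max(auc, 1.0 - auc), _smd(values[i], case_mask), g))
    rows.sort(key=lambda r: (-r[0], -r[1], r[2]))
    return [g for _, _, g in rows[:top_n]]


def screen_all_ratios(matrix: ExpressionMatrix, labels: CohortLabels,
                      gene_pool: list[str] | None = None,
                      objective: str = "binormal") -> list[RatioFeature]:
    """Evaluate every unordered gene pair as an oriented ratio feature, ranked by AUC.

    Each pair is evaluated once and oriented so its AUC >= 0.5 (the orientation sign
    is recorded). The result has |pool| * (|pool| - 1) / 2 entries, sorted by AUC
    descending with deterministic tie-breaks (standardized mean difference, then ids).

    ``objective`` selects the AUC estimate driving the ranking: the default
    ``'binormal'`` smooth estimate (low-variance, as used with binormal-smoothed
    ROC screening) or the ``'empirical'`` midrank Mann-Whitney estimate.
    """
    if objective not in _OBJECTIVES:
        raise SeptikitError(f"unknown objective {objective!r}; use {sorted(_OBJECTIVES)}")
    auc_fn = _OBJECTIVES[objective]
    pool = list(gene_pool) if gene_pool is not None else matrix.gene_ids
    unknown = [g for g in pool if g not in matrix.data.index]
    if unknown:
        raise SeptikitError(f"gene pool contains unknown genes: {unknown}")
    if len(pool) < 2:
        raise SeptikitError("gene pool must contain at least two genes")
    values, case_mask, _ = _aligned(matrix, labels)
    idx = {g: matrix.gene_ids.index(g) for g in pool}
    entries = []
    for ga, gb in itertools.combinations(sorted(pool), 2):
        feat = values[idx[ga]] - values[idx[gb]]
        auc = auc_fn(feat, case_mask)
        orientation = 1 if auc >= 0.5 else -1
        entries.append((max(auc, 1.0 - auc), _smd(feat, case_mask), ga, gb, orientation))
    entries.sort(key=lambda e: (-e[0], -e[1], e[2], e[3]))
    ranked = [RatioFeature(ga, gb, orientation=o, auc=a) for a, _, ga, gb, o in entries]
    logger.info("screened %d two-gene ratios over a pool of %d genes", len(ranked), len(pool))
    return ranked


def greedy_pair_search(matrix: ExpressionMatrix, labels: CohortLabels,
                       ranked_ratios: list[RatioFeature], pool_k: int = 5,
                       objective: str = "binormal") -> RatioClassifier:
    """Greedy additive search: seed on the top ratio, add the best partner ratio.

    The partner is the candidate among the ``pool_k`` top-ranking ratios below the
    seed that maximises the AUC of the summed score, shares no gene with the seed,
    and does not fall below the seed's own AUC. When a "hub" gene dominates the
    ranking so that no candidate inside the window is gene-disjoint from the seed,
    the single highest-ranked admissible candidate further down the list is
    considered instead. Only when no admissible partner exists at all (or none
    reaches the seed's own AUC) does the classifier degenerate to the single seed
    ratio (with a warning).

    ``pool_k`` is deliberately small by default: the width of the candidate pool
    directly scales selection optimism (each extra candidate is another chance for
    a noise ratio to win the training objective by luck), and genuinely useful
    partners are precisely the top-ranking ones. ``objective`` must match the one
    used to rank ``ranked_ratios``.
    """
    if not ranked_ratios:
        raise SeptikitError("ranked_ratios must be non-empty")
    if pool_k < 1 or pool_k > len(ranked_ratios):
        raise SeptikitError(f"pool_k must be in [1, {len(ranked_ratios)}]")
    if objective not in _OBJECTIVES:
        raise SeptikitError(f"unknown objective {objective!r}; use {sorted(_OBJECTIVES)}")
    auc_fn = _OBJECTIVES[objective]
    values, case_mask, ids = _aligned(matrix, labels)
    gene_row = {g: i for i, g in enumerate(matrix.gene_ids)}

    def oriented(f: RatioFeature) -> np.ndarray:
        return f.orientation * (values[gene_row[f.gene_a]] - values[gene_row[f.gene_b]])

    seed = ranked_ratios[0]
    seed_vals = oriented(seed)
    candidates = [c for c in ranked_ratios[1:1 + pool_k] if not (c.genes & seed.genes)]
    if not candidates:
        fallback = next((c for c in ranked_ratios[1 + pool_k:]
                         if not (c.genes & seed.genes)), None)
        if fallback is not None:
            candidates = [fallback]
    best: tuple[float, float, str, str] | None = None
    best_partner: RatioFeature | None = None
    for cand in candidates:
        combined = seed_vals + oriented(cand)
        auc = auc_fn(combined, case_mask)
        key = (auc, _smd(combined, case_mask), cand.gene_a, cand.gene_b)
        if best is None or (key[0], key[1]) > (best[0], best[1]):
            best, best_partner = key, cand
    if best is None or best[0] < seed.auc:
        warnings.warn("no admissible partner ratio improved on the seed; "
                      "returning a single-ratio classifier")
        return RatioClassifier(ratio_1=seed, ratio_2=None, training_auc=seed.auc)
    return RatioClassifier(ratio_1=seed, ratio_2=best_partner, training_auc=best[0])


def apply_classifier(classifier: RatioClassifier, matrix: ExpressionMatrix) -> pd.Series:
    """Per-sample score: the sum of the classifier's oriented ratio features."""
    score = classifier.ratio_1.values(matrix)
    if classifier.ratio_2 is not None:
        score = score + classifier.ratio_2.values(matrix)
    score.name = "score"
    return score


def differential_expression_filter(matrix: ExpressionMatrix, sample_x: str, sample_y: str,
                                   min_intensity: float = 100.0,
                                   min_fold: float = 2.0) -> list[str]:
    """Genes differentially expressed between two samples on the linear scale.

    A gene qualifies when both linear intensities exceed ``min_intensity`` and the
    fold change (in either direction) exceeds ``min_fold``.
    """
    linear = matrix.to_linear()
    for s in (sample_x, sample_y):
        if s not in linear.data.columns:
            raise SeptikitError(f"unknown sample {s!r}")
    x = linear.data[sample_x]
    y = linear.data[sample_y]
    fold = np.maximum(x / y, y / x)
    keep = (x > min_intensity) & (y > min_intensity) & (fold > min_fold)
    return list(linear.data.index[keep])


def discover(matrix: ExpressionMatrix, labels: CohortLabels,
             prefilter_top: int | None = None, pool_k: int = 5,
             objective: str = "binormal") -> RatioClassifier:
    """Full discovery pipeline: optional univariate prefilter, ratio screen, greedy pair search."""
    pool = (prefilter_genes(matrix, labels, prefilter_top)
            if prefilter_top is not None else matrix.gene_ids)
    ranked = screen_all_ratios(matrix, labels, pool, objective=objective)
    return greedy_pair_search(matrix, labels, ranked, pool_k=min(pool_k, len(ranked)),
                              objective=objective)


def subsample_stability(matrix: ExpressionMatrix, labels: CohortLabels,
                        gene_pool: list[str], top_k: int = 10, n_subsamples: int = 50,
                        fraction: float = 0.8, seed: int | None = None) -> pd.Series:
    """Fraction of stratified subsamples in which each ratio stays in the top ``top_k``.

    A lightweight stability report replacing repeated subset re-discovery: each
    subsample keeps ``fraction`` of cases and of controls (seeded), ratios are
    re-screened, and membership of the full-data top ``top_k`` list is tallied.
    """
    rng = np.random.default_rng(seed)
    full = screen_all_ratios(matrix, labels, gene_pool)
    names = [f"{r.gene_a}/{r.gene_b}" for r in full[:top_k]]
    counts = dict.fromkeys(names, 0)
    known = labels.known_status()
    ids = [s for s in matrix.sample_ids if s in known.frame.index]
    case_mask = known.case_mask(ids)
    ids = np.asarray(ids)
    for _ in range(n_subsamples):
        keep = np.zeros(len(ids), dtype=bool)
        for mask in (case_mask, ~case_mask):
            members = np.flatnonzero(mask)
            k = max(2, int(round(fraction * members.size)))
            keep[rng.choice(members, size=min(k, members.size), replace=False)] = True
        sub = ExpressionMatrix(matrix.data[list(ids[keep])], scale=matrix.scale)
        top = screen_all_ratios(sub, known, gene_pool)[:top_k]
        for r in top:
            name = f"{r.gene_a}/{r.gene_b}"
            if name in counts:
                counts[name] += 1
    return pd.Series({k: v / n_subsamples for k, v in counts.items()}, name="stability")
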
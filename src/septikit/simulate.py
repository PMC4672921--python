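"""Seeded synthetic cohorts with the statistical structure the method assumes.

The generator emulates two kinds of input. A *discovery-like* expression cohort:
Gaussian log2 intensities, identical in both classes for background genes, with a
planted four-gene signature shifted in cases (two genes up, two down, mirroring the
PLAC8/LAMP1 up and PLA2G7/CEACAM4 down pattern). A *validation-like* RT-qPCR
cohort: the same expression model pushed through the inverse intensity-to-Ct map
Ct = alpha - beta * log2(intensity) + noise, with case/control/"possible" labels
drawn at a configured prevalence and possible-fraction, and clinical covariates
(PCT-like, APACHE-like) with configurable class effects.

Default dimensions mirror a 74-case / 31-control discovery design; the default
validation prevalence is 0.30 with a 0.13 "possible" fraction. "Possible" samples
are drawn from a mixture of the case and control score distributions; by default
the mixture weight equals the cohort prevalence, so their score distribution
matches the pooled known-status distribution exactly (the weight is exposed for
sensitivity analyses). Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CohortLabels, CtPanel, ExpressionMatrix, PANEL_GENES, SeptikitError

__all__ = ["SimSpec", "generate_expression_cohort", "expression_to_ct",
           "generate_validation_cohort"]


def _default_signature() -> dict[str, float]:
    plac8, pla2g7, lamp1, ceacam4 = PANEL_GENES
    return {plac8: +1.5, lamp1: +1.5, pla2g7: -1.5, ceacam4: -1.5}


def _default_baselines() -> dict[str, float]:
    plac8, pla2g7, lamp1, ceacam4 = PANEL_GENES
    return {plac8: 9.0, lamp1: 9.0, pla2g7: 8.0, ceacam4: 8.0}


def _default_covariates() -> dict[str, float]:
    return {"PCT": 1.2, "APACHE_IV": 0.5}


@dataclass
class SimSpec:
    """Parameters of the synthetic cohort model.

    Effects are log2-unit shifts applied to signature genes in cases (positive =
    up-regulated in cases). ``noise_sd`` is the per-gene log2 SD, so the default
    +/-1.5 effects are 1.5 SD per gene. ``ct_alpha``/``ct_beta`` define the
    intensity-to-Ct map; ``covariate_effects`` are class mean shifts in SD units of
    the covariate's latent normal.
    """

    n_cases: int = 74
    n_controls: int = 31
    n_possible: int = 0
    n_genes: int = 50
    signature: dict[str, float] = field(default_factory=_default_signature)
    gene_baselines: dict[str, float] = field(default_factory=_default_baselines)
    baseline: float = 8.0
    noise_sd: float = 1.0
    ct_alpha: float = 30.0
    ct_beta: float = 1.0
    ct_noise_sd: float = 0.25
    prevalence: float = 0.30
    possible_fraction: float = 0.13
    possible_case_weight: float | None = None  # None = use prevalence
    covariate_effects: dict[str, float] = field(default_factory=_default_covariates)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.signature and self.n_genes < len(self.signature):
            raise SeptikitError("n_genes must cover the signature genes")
        if self.noise_sd < 0 or self.ct_noise_sd < 0:
            raise SeptikitError("noise SDs must be non-negative")
        if self.ct_beta <= 0:
            raise SeptikitError("ct_beta must be positive (Ct falls as expression rises)")
        if not (0.0 < self.prevalence < 1.0):
            raise SeptikitError("prevalence must lie in (0, 1)")
        if not (0.0 <= self.possible_fraction < 1.0):
            raise SeptikitError("possible_fraction must lie in [0, 1)")

    def with_(self, **kw) -> "SimSpec":
        return replace(self, **kw)

    def gene_ids(self) -> list[str]:
        sig = list(self.signature)
        background = [f"GENE{i:04d}" for i in range(1, self.n_genes - len(sig) + 1)]
        return sig + background


def _rng(spec: SimSpec, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(spec.seed if seed is None else seed)


def generate_expression_cohort(spec: SimSpec, seed: int | None = None
                               ) -> tuple[ExpressionMatrix, CohortLabels]:
    """Discovery-like cohort: log2 matrix (genes x samples) plus case/control labels.

    Background genes are Normal(baseline, noise_sd) identically in both classes;
    each signature gene gets its per-gene baseline and is shifted by its effect in
    cases. Sample order is cases then controls; deterministic given the seed.
    """
    rng = _rng(spec, seed)
    genes = spec.gene_ids()
    n = spec.n_cases + spec.n_controls
    case_mask = np.zeros(n, dtype=bool)
    case_mask[:spec.n_cases] = True
    sample_ids = ([f"CASE{i:03d}" for i in range(1, spec.n_cases + 1)]
                  + [f"CTRL{i:03d}" for i in range(1, spec.n_controls + 1)])
    values = rng.normal(0.0, spec.noise_sd, size=(len(genes), n))
    for i, g in enumerate(genes):
        values[i] += spec.gene_baselines.get(g, spec.baseline)
        if g in spec.signature:
            values[i, case_mask] += spec.signature[g]
    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=sample_ids))
    labels = CohortLabels(pd.DataFrame(
        {"class_label": np.where(case_mask, "case", "control")},
        index=pd.Index(sample_ids, name="sample_id"),
    ))
    return matrix, labels


def expression_to_ct(matrix: ExpressionMatrix, spec: SimSpec,
                     seed: int | None = None) -> list[CtPanel]:
    """Map panel-gene expression to Ct panels via Ct = alpha - beta*log2(I) + noise.

    Requires the four panel genes in the matrix. Values are clipped into (0, 50]
    (clipping is rare under the defaults); deterministic given the seed.
    """
    rng = _rng(spec, seed)
    log2m = matrix.to_log2()
    missing = [g for g in PANEL_GENES if g not in log2m.data.index]
    if missing:
        raise SeptikitError(f"matrix lacks panel genes: {missing}")
    expr = log2m.data.loc[list(PANEL_GENES)].to_numpy(dtype=float)
    ct = spec.ct_alpha - spec.ct_beta * expr
    if spec.ct_noise_sd > 0:
        ct = ct + rng.normal(0.0, spec.ct_noise_sd, size=ct.shape)
    ct = np.clip(ct, np.nextafter(0.0, 1.0), 50.0)
    return [
        CtPanel(sample_id=s, ct_plac8=float(ct[0, j]), ct_pla2g7=float(ct[1, j]),
                ct_lamp1=float(ct[2, j]), ct_ceacam4=float(ct[3, j]),
                platform_id=None)
        for j, s in enumerate(log2m.sample_ids)
    ]


def generate_validation_cohort(spec: SimSpec, n_total: int = 345, seed: int | None = None
                               ) -> tuple[list[CtPanel], CohortLabels]:
    """Validation-like cohort: Ct panels, labels with a 'possible' class, covariates.

    Labels are drawn independently: 'possible' with probability
    ``possible_fraction``, otherwise case with probability ``prevalence``.
    'Possible' samples draw their underlying expression from a case/control mixture
    (weight ``possible_case_weight``, defaulting to the prevalence, which makes
    their score distribution match the pooled known-status distribution).
    Covariates are attached to the labels frame; PCT-like values are log-normal
    (monotone transform of the latent class effect), APACHE-like values stay on an
    ICU-severity-score-like scale.
    """
    rng = _rng(spec, seed)
    u = rng.random(n_total)
    is_possible = u < spec.possible_fraction
    is_case = ~is_possible & (rng.random(n_total) < spec.prevalence)
    w = spec.prevalence if spec.possible_case_weight is None else spec.possible_case_weight
    latent_case = np.where(is_possible, rng.random(n_total) < w, is_case)

    sample_ids = [f"VAL{i:04d}" for i in range(1, n_total + 1)]
    genes = spec.gene_ids()
    values = rng.normal(0.0, spec.noise_sd, size=(len(genes), n_total))
    for i, g in enumerate(genes):
        values[i] += spec.gene_baselines.get(g, spec.baseline)
        if g in spec.signature:
            values[i, latent_case] += spec.signature[g]
    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=sample_ids))
    panels = expression_to_ct(matrix, spec, seed=int(rng.integers(0, 2**31)))

    frame = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    frame["class_label"] = np.where(is_possible, "possible",
                                    np.where(is_case, "case", "control"))
    for name, effect in spec.covariate_effects.items():
        z = rng.normal(0.0, 1.0, n_total) + effect * latent_case
        if name.upper().startswith("PCT"):
            frame[name] = np.exp(0.5 + 1.5 * z)  # ng/ml-like, heavy right tail
        elif name.upper().startswith("APACHE"):
            frame[name] = np.clip(np.round(65 + 25 * z), 0, None)
        else:
            frame[name] = z
    return panels, CohortLabels(frame)
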
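"""Data model, delimited-text readers/writers, RNA QC gates, and assay configuration.

Expression matrices are log2-scale intensity grids (genes x samples); Ct panels carry
the four threshold-cycle measurements of the RT-qPCR assay. Both arrive as plain
TSV/CSV files. All readers validate identifiers and numeric content up front so that
downstream statistics never meet silent duplicates or strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("septikit")

#: Gene order of the four-gene assay panel. The score combines the genes as
#: +PLAC8 - PLA2G7 + LAMP1 - CEACAM4 on the expression scale (sign flips on Ct scale).
PANEL_GENES = ("PLAC8", "PLA2G7", "LAMP1", "CEACAM4")

CLASS_LABELS = ("case", "control", "possible")


class SeptikitError(ValueError):
    """Base class for input-validation failures."""


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _duplicates(ids: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class ExpressionMatrix:
    """A genes x samples grid of log2 intensities.

    ``data`` is a DataFrame indexed by gene id with sample ids as columns. Missing
    measurements are NaN and stay flagged; they are never imputed here.
    """

    data: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        dup_g = _duplicates(self.data.index)
        dup_s = _duplicates(self.data.columns)
        if dup_g:
            raise SeptikitError(f"duplicate gene identifiers: {dup_g}")
        if dup_s:
            raise SeptikitError(f"duplicate sample identifiers: {dup_s}")
        if not all(np.issubdtype(d, np.number) for d in self.data.dtypes):
            bad = [c for c, d in self.data.dtypes.items() if not np.issubdtype(d, np.number)]
            raise SeptikitError(f"non-numeric columns: {bad}")
        with np.errstate(invalid="ignore"):
            inf = ~np.isfinite(self.data.to_numpy(dtype=float))
        if (inf & ~self.data.isna().to_numpy()).any():
            raise SeptikitError("expression matrix contains non-finite values")
        if self.scale not in ("log2", "linear"):
            raise SeptikitError(f"unknown scale {self.scale!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_log2(self) -> "ExpressionMatrix":
        """Return a log2-scale view of the matrix (no-op if already log2)."""
        if self.scale == "log2":
            return self
        if (self.data.to_numpy() <= 0).any():
            raise SeptikitError("linear intensities must be positive for log2 conversion")
        return ExpressionMatrix(np.log2(self.data), scale="log2")

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale == "linear":
            return self
        return ExpressionMatrix(2.0 ** self.data, scale="linear")


def read_expression_matrix(
    path: str | Path,
    genes_in_rows: bool = True,
    scale: str = "log2",
) -> ExpressionMatrix:
    """Read a delimited expression matrix (first row/column hold identifiers).

    The delimiter is auto-detected between tab and comma. ``scale='linear'`` marks the
    body as raw intensities; call :meth:`ExpressionMatrix.to_log2` to convert.
    Non-numeric body cells raise with the offending row/column coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise SeptikitError(
                f"non-numeric value at row {row!r}, column {col!r}: {df.loc[row, col]!r}"
            )
        df[col] = coerced
    if not genes_in_rows:
        df = df.T
    mat = ExpressionMatrix(df, scale=scale)
    logger.info("read expression matrix %s: %d genes x %d samples",
                path.name, len(mat.gene_ids), len(mat.sample_ids))
    return mat


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    matrix.data.to_csv(Path(path), sep=sep, float_format="%.15g")


@dataclass
class CohortLabels:
    """Per-sample class labels (case / control / possible) and clinical covariates."""

    frame: pd.DataFrame  # index: sample_id; column 'class_label'; remaining columns covariates

    def __post_init__(self) -> None:
        if "class_label" not in self.frame.columns:
            raise SeptikitError("labels table needs a 'class_label' column")
        dup = _duplicates(self.frame.index)
        if dup:
            raise SeptikitError(f"duplicate sample identifiers: {dup}")
        bad = set(self.frame["class_label"]) - set(CLASS_LABELS)
        if bad:
            raise SeptikitError(f"unknown class labels {sorted(bad)}; allowed: {CLASS_LABELS}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def class_label(self) -> pd.Series:
        return self.frame["class_label"]

    @property
    def covariates(self) -> pd.DataFrame:
        return self.frame.drop(columns=["class_label"])

    def case_mask(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        """Boolean case indicator over ``sample_ids`` (cases vs controls only).

        Raises if any requested sample is labelled 'possible' -- those are excluded
        from performance analyses and must be dropped explicitly first.
        """
        ids = list(sample_ids) if sample_ids is not None else self.sample_ids
        missing = [s for s in ids if s not in self.frame.index]
        if missing:
            raise SeptikitError(f"samples without labels: {missing}")
        lab = self.frame.loc[ids, "class_label"]
        if (lab == "possible").any():
            raise SeptikitError(
                "samples with class 'possible' present; drop them before case/control analysis"
            )
        return (lab == "case").to_numpy()

    def known_status(self) -> "CohortLabels":
        """The case/control subset, with 'possible' samples excluded (and logged)."""
        keep = self.frame["class_label"] != "possible"
        n_excl = int((~keep).sum())
        if n_excl:
            logger.info("excluding %d samples with infection likelihood 'possible'", n_excl)
        return CohortLabels(self.frame.loc[keep])

    def counts(self) -> dict[str, int]:
        return {k: int((self.frame["class_label"] == k).sum()) for k in CLASS_LABELS}


def read_labels(path: str | Path) -> CohortLabels:
    """Read a sample annotation table (sample id in first column, 'class_label' column)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    df.index = df.index.astype(str)
    labels = CohortLabels(df)
    logger.info("read labels %s: %s", path.name, labels.counts())
    return labels


@dataclass
class CtPanel:
    """Four threshold-cycle values for one sample, plus the acquisition platform."""

    sample_id: str
    ct_plac8: float
    ct_pla2g7: float
    ct_lamp1: float
    ct_ceacam4: float
    platform_id: str | None = None

    def __post_init__(self) -> None:
        for gene, v in zip(PANEL_GENES, self.ct_values):
            if not np.isnan(v) and not (0.0 < v <= 50.0):
                raise SeptikitError(
                    f"sample {self.sample_id!r}: Ct({gene}) = {v} outside (0, 50]"
                )

    @property
    def ct_values(self) -> tuple[float, float, float, float]:
        return (self.ct_plac8, self.ct_pla2g7, self.ct_lamp1, self.ct_ceacam4)

    @property
    def complete(self) -> bool:
        return not any(np.isnan(v) for v in self.ct_values)


_CT_COLUMNS = {g: f"ct_{g.lower()}" for g in PANEL_GENES}


def read_ct_table(path: str | Path) -> list[CtPanel]:
    """Read a Ct table: one row per sample with columns for the four panel genes.

    Gene columns may be named either by gene symbol (``PLAC8``) or ``ct_plac8``
    (case-insensitive). An optional ``platform`` / ``platform_id`` column is kept.
    Empty cells become NaN and the panel is flagged incomplete, never imputed.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    colmap: dict[str, str] = {}
    lower = {c.lower(): c for c in df.columns}
    for gene in PANEL_GENES:
        for cand in (gene.lower(), f"ct_{gene.lower()}"):
            if cand in lower:
                colmap[gene] = lower[cand]
                break
        else:
            raise SeptikitError(f"Ct table is missing a column for {gene}")
    id_col = next((lower[c] for c in ("sample_id", "sample", "id") if c in lower),
                  df.columns[0])
    platform_col = next((lower[c] for c in ("platform_id", "platform") if c in lower), None)

    panels = []
    for _, row in df.iterrows():
        panels.append(CtPanel(
            sample_id=str(row[id_col]),
            ct_plac8=float(pd.to_numeric(row[colmap["PLAC8"]], errors="raise")) if pd.notna(row[colmap["PLAC8"]]) else float("nan"),
            ct_pla2g7=float(row[colmap["PLA2G7"]]) if pd.notna(row[colmap["PLA2G7"]]) else float("nan"),
            ct_lamp1=float(row[colmap["LAMP1"]]) if pd.notna(row[colmap["LAMP1"]]) else float("nan"),
            ct_ceacam4=float(row[colmap["CEACAM4"]]) if pd.notna(row[colmap["CEACAM4"]]) else float("nan"),
            platform_id=(str(row[platform_col]) if platform_col and pd.notna(row[platform_col]) else None),
        ))
    n_incomplete = sum(not p.complete for p in panels)
    logger.info("read Ct table %s: %d panels (%d incomplete)", path.name, len(panels), n_incomplete)
    return panels


def write_ct_table(panels: Sequence[CtPanel], path: str | Path, sep: str = "\t") -> None:
    rows = [{
        "sample_id": p.sample_id,
        **{_CT_COLUMNS[g]: v for g, v in zip(PANEL_GENES, p.ct_values)},
        "platform_id": p.platform_id or "",
    } for p in panels]
    pd.DataFrame(rows).to_csv(Path(path), sep=sep, index=False, float_format="%.15g")


# --- assay configuration -----------------------------------------------------------

#: Name of the reference RT-qPCR chemistry; scores on this platform need no shift.
REFERENCE_PLATFORM = "asuragen"


@dataclass
class AssayConfig:
    """Tunable assay constants: decision cutoff, band edges, pre-test probability,
    per-platform affine shifts, and resampling controls."""

    cutoff: float = 3.100
    band_edges: tuple[float, ...] = (4.0, 6.0, 9.0)
    pretest_probability: float = 0.30
    platform_shifts: dict[str, tuple[float, float]] = field(default_factory=dict)
    bootstrap_reps: int = 2000
    permutation_reps: int = 2000
    global_seed: int = 0
    input_scale: str = "log2"

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.band_edges)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise SeptikitError(f"band edges must be strictly increasing, got {edges}")
        self.band_edges = edges
        if not (0.0 < self.pretest_probability < 1.0):
            raise SeptikitError("pretest_probability must lie in (0, 1)")
        if self.bootstrap_reps < 1 or self.permutation_reps < 1:
            raise SeptikitError("resampling rep counts must be >= 1")
        self.platform_shifts = {
            str(k).lower(): (float(v[0]), float(v[1])) for k, v in self.platform_shifts.items()
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AssayConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "cutoff": self.cutoff,
            "band_edges": list(self.band_edges),
            "pretest_probability": self.pretest_probability,
            "platform_shifts": {k: list(v) for k, v in self.platform_shifts.items()},
            "bootstrap_reps": self.bootstrap_reps,
            "permutation_reps": self.permutation_reps,
            "global_seed": self.global_seed,
            "input_scale": self.input_scale,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    def with_overrides(self, **kw) -> "AssayConfig":
        return replace(self, **kw)


# --- RNA quality control -----------------------------------------------------------

@dataclass
class RnaQcRecord:
    """Pre-assay RNA quality measurements for one extraction."""

    sample_id: str
    yield_ng_per_ul: float | None = None
    a260_a280_ratio: float | None = None
    integrity_score: float | None = None  # RIN or equivalent

    def __post_init__(self) -> None:
        for name in ("yield_ng_per_ul", "a260_a280_ratio", "integrity_score"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise SeptikitError(f"sample {self.sample_id!r}: negative {name}")


def qc_filter_rna(
    records: Iterable[RnaQcRecord], mode: str
) -> tuple[list[RnaQcRecord], list[tuple[RnaQcRecord, str]]]:
    """Partition RNA extractions into (pass, fail-with-reason) for the given assay mode.

    RT-qPCR acceptance requires yield >= 2 ng/ul (boundary inclusive). Microarray
    acceptance requires A260/A280 ratio > 1.6 AND integrity score > 5 (both strict).
    A record missing the fields its mode needs fails with 'insufficient QC data'.
    """
    if mode not in ("rtqpcr", "microarray"):
        raise SeptikitError(f"unknown QC mode {mode!r}; use 'rtqpcr' or 'microarray'")
    passed: list[RnaQcRecord] = []
    failed: list[tuple[RnaQcRecord, str]] = []
    for rec in records:
        if mode == "rtqpcr":
            if rec.yield_ng_per_ul is None:
                failed.append((rec, "insufficient QC data"))
            elif rec.yield_ng_per_ul >= 2.0:
                passed.append(rec)
            else:
                failed.append((rec, f"yield {rec.yield_ng_per_ul} ng/ul < 2"))
        else:
            if rec.a260_a280_ratio is None or rec.integrity_score is None:
                failed.append((rec, "insufficient QC data"))
            elif rec.a260_a280_ratio <= 1.6:
                failed.append((rec, f"A260/A280 ratio {rec.a260_a280_ratio} not > 1.6"))
            elif rec.integrity_score <= 5.0:
                failed.append((rec, f"integrity score {rec.integrity_score} not > 5"))
            else:
                passed.append(rec)
    logger.info("RNA QC (%s): %d pass, %d fail", mode, len(passed), len(failed))
    return passed, failed
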
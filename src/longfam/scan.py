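"""Chromosome-wide association scans, two-stage refinement, and diagnostics.

The design grid crosses three phenotype views (baseline, averaged, repeated)
with two subject designs (full pedigree sample, unrelated subset).  Each cell
maps to a default model: family mixed model (M3) for single-measurement
pedigree cells, the reduced family model (M5) for the repeated pedigree cell —
refined for top hits by the full model (M4) in a two-stage strategy — and
linear/random-intercept models (M1, M2) for the unrelated cells.

Diagnostics: Bonferroni thresholds (raw and ceiling-rounded to two significant
figures), the genomic-control inflation factor lambda, and QQ-plot data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .lmm import ModelSpec, NullModel, null_model_cache
from .pedigree import KinshipMatrix
from .phenotypes import LongitudinalPhenotypes, make_view

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "DEFAULT_CELL_MODEL",
    "run_scan",
    "two_stage_refine",
    "bonferroni_threshold",
    "genomic_lambda",
    "qq_data",
]

#: Default model per (view, design) cell of the six-way design grid.
DEFAULT_CELL_MODEL = {
    ("baseline", "pedigree_sample"): "M3_family",
    ("averaged", "pedigree_sample"): "M3_family",
    ("repeated", "pedigree_sample"): "M5_family_reduced",
    ("baseline", "unrelated_only"): "M1_linear",
    ("averaged", "unrelated_only"): "M1_linear",
    ("repeated", "unrelated_only"): "M2_subject",
}


@dataclass(frozen=True)
class ScanConfig:
    """What to run: views, designs, models, refinement depth, error rate."""

    trait: str = "SBP"
    views: tuple = ("baseline", "averaged", "repeated")
    designs: tuple = ("pedigree_sample", "unrelated_only")
    models: dict = field(default_factory=dict)  # (view, design) -> model id override
    top_k: int = 100
    alpha: float = 0.05
    n_pcs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        for (view, design), mid in self.models.items():
            ModelSpec(model_id=mid, view=view, design=design)  # validates pairing

    def model_for(self, view: str, design: str) -> str:
        return self.models.get((view, design), DEFAULT_CELL_MODEL[(view, design)])


def run_scan(
    cfg: ScanConfig,
    markers: pd.DataFrame,
    phenotypes: LongitudinalPhenotypes,
    km: KinshipMatrix,
    unrelated: list,
    pcs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score every marker in every requested design cell.

    ``markers`` is a subjects x markers DataFrame (single-SNP dosages or
    transcript burden scores).  Returns the concatenated per-cell result
    tables from cached-null GLS tests; deterministic given the inputs.
    """
    if markers.shape[1] == 0:
        warnings.warn("empty marker set; returning empty results")
        return pd.DataFrame(
            columns=["marker_id", "beta", "se", "p_value", "n_used", "model",
                     "view", "design", "ok"]
        )
    results = []
    for view_mode in cfg.views:
        view = make_view(phenotypes, view_mode)
        for design in cfg.designs:
            mid = cfg.model_for(view_mode, design)
            spec = ModelSpec(model_id=mid, view=view_mode, design=design)
            v = view
            if design == "unrelated_only":
                keep = view.frame["subject_id"].isin(set(unrelated))
                v = type(view)(
                    mode=view.mode,
                    frame=view.frame[keep].reset_index(drop=True),
                    trait=view.trait,
                )
            null = null_model_cache(spec, v, covariates=pcs, km=km)
            res = null.test_markers(markers)
            results.append(res)
            logger.info(
                "scanned %d markers: %s / %s / %s (lambda=%.3f)",
                markers.shape[1], mid, view_mode, design,
                genomic_lambda(res["p_value"].dropna(), warn_small=False),
            )
    return pd.concat(results, ignore_index=True)


def two_stage_refine(
    m5_results: pd.DataFrame,
    top_k: int,
    refit: Callable[[str], "object"],
    positions: pd.Series | None = None,
) -> pd.DataFrame:
    """Refit the top_k markers (ascending screening p, ties by position) exactly.

    ``m5_results`` is one cell's result table from the screening model;
    ``refit(marker_id)`` returns an :class:`~longfam.lmm.AssociationResult`
    under the full model.  Output rows carry both p-values.
    """
    res = m5_results.dropna(subset=["p_value"]).copy()
    if top_k > len(res):
        warnings.warn(
            f"top_k={top_k} exceeds {len(res)} testable markers; refining all"
        )
        top_k = len(res)
    if positions is not None:
        res["_pos"] = res["marker_id"].map(positions).fillna(np.inf)
    else:
        res["_pos"] = np.arange(len(res))
    res = res.sort_values(["p_value", "_pos"], kind="stable").head(top_k)
    rows = []
    for row in res.itertuples():
        r4 = refit(row.marker_id)
        rows.append(
            dict(
                marker_id=row.marker_id,
                beta_screen=row.beta,
                p_screen=row.p_value,
                beta_refined=r4.beta,
                se_refined=r4.se,
                p_refined=r4.p_value,
                model_refined=r4.model_id,
                converged=r4.converged,
            )
        )
    return pd.DataFrame(rows)


class BonferroniThreshold(NamedTuple):
    raw: float
    rounded: float


def bonferroni_threshold(alpha: float, m_tests: int) -> BonferroniThreshold:
    """Family-wise significance threshold alpha / m.

    Returns the raw value and its ceiling at two significant figures — the
    conservative rounding under which e.g. 0.05/403,098 = 1.2404e-7 is
    reported as 1.3e-7.  Downstream significance calls use the raw value.
    """
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    raw = alpha / m_tests
    exp = np.floor(np.log10(raw))
    unit = 10.0 ** (exp - 1)
    rounded = float(np.ceil(raw / unit - 1e-9) * unit)
    return BonferroniThreshold(raw=raw, rounded=rounded)


_CHI2_1_MEDIAN = chi2.ppf(0.5, df=1)  # 0.4549...


def genomic_lambda(p_values, warn_small: bool = True) -> float:
    """Genomic-control inflation factor: median observed 1-df chi-square over 0.4549.

    Calibrated tests give lambda near 1; lambda >> 1 signals inflation, e.g.
    from uncorrected population stratification.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0 or np.any(np.isnan(p)) or np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be nonempty and lie in (0, 1]")
    if warn_small and p.size < 100:
        warnings.warn(f"only {p.size} p-values; lambda estimate is unstable")
    stats = chi2.isf(p, df=1)
    return float(np.median(stats) / _CHI2_1_MEDIAN)


def qq_data(p_values) -> tuple[np.ndarray, np.ndarray]:
    """(expected, observed) -log10 p pairs for a QQ plot, both ascending."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)[::-1]
    observed = -np.log10(np.sort(p)[::-1])
    return expected, observed
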
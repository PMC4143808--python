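"""Population-stratification control via genotype principal components.

Common SNPs are LD-pruned (pairwise r^2 < 0.2 in a sliding window) among the
unrelated subjects, principal components are computed on the standardized
genotypes of the unrelated subjects only — relatedness would otherwise distort
the leading eigenvectors — and relatives are then projected onto the SNP
loadings so the whole sample gets PC coordinates usable as covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genotype_burden import GenotypeMatrix, compute_maf

logger = logging.getLogger(__name__)

__all__ = ["PCResult", "ld_prune", "pca_unrelated", "project_relatives"]


@dataclass(frozen=True)
class PCResult:
    """Principal components of pruned SNP genotypes.

    ``center``/``scale`` are the per-SNP standardization constants 2*p-hat and
    sqrt(2*p-hat*(1 - p-hat)) estimated on the unrelated subjects; ``loadings``
    (SNPs x K, unit columns) and ``scores`` (subjects x K) follow the usual
    PCA conventions.  ``scores`` initially covers the unrelated subjects;
    :func:`project_relatives` completes it for the full sample.
    """

    snp_ids: list
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray
    scores: pd.DataFrame
    k: int


def _impute_centered(block: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Center dosages and replace missing with 0 (the center value)."""
    out = block - center
    n_missing = int(np.isnan(out).sum())
    if n_missing:
        logger.info("mean-imputing %d missing dosages at pruned SNPs", n_missing)
        out = np.nan_to_num(out, nan=0.0)
    return out


def ld_prune(
    gm: GenotypeMatrix,
    unrelated: list,
    r2_cut: float = 0.2,
    maf_cut: float = 0.05,
    window: int = 50,
    step: int = 5,
) -> list:
    """Greedy sliding-window LD pruning on the unrelated subjects.

    SNPs with MAF below ``maf_cut`` (on the unrelated subjects) are not
    candidates.  Within each window of ``window`` SNPs (advancing by ``step``)
    the earlier SNP of any pair with squared Pearson dosage correlation
    >= ``r2_cut`` is kept and the later dropped.  Zero-variance SNPs are
    excluded with a log entry.  Deterministic.
    """
    if len(unrelated) < 2:
        raise ValueError("LD pruning requires at least 2 unrelated subjects")
    sub = gm.subset_subjects(unrelated)
    maf = compute_maf(sub)
    order = np.lexsort(
        (gm.variants["pos"].to_numpy(), gm.variants["chrom"].to_numpy())
    )
    cand = [
        j for j in order if not np.isnan(maf.iloc[j]) and maf.iloc[j] >= maf_cut
    ]
    X = sub.dosage[:, cand]
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_mean, X) - col_mean
    sd = X.std(axis=0)
    nonzero = sd > 0
    n_zero = int((~nonzero).sum())
    if n_zero:
        logger.info("excluding %d zero-variance SNP(s) from pruning", n_zero)
    cand = [c for c, keep in zip(cand, nonzero) if keep]
    X = X[:, nonzero] / sd[nonzero]

    m = len(cand)
    keep = np.ones(m, dtype=bool)
    n = X.shape[0]
    start = 0
    while start < m:
        stop = min(start + window, m)
        ix = np.where(keep[start:stop])[0] + start
        if len(ix) > 1:
            R = (X[:, ix].T @ X[:, ix]) / n
            r2 = R**2
            for a in range(len(ix)):
                if not keep[ix[a]]:
                    continue
                hits = np.where(r2[a, a + 1 :] >= r2_cut)[0]
                for b in hits:
                    keep[ix[a + 1 + b]] = False
        if stop == m:
            break
        start += step
    return [gm.variant_ids[cand[j]] for j in range(m) if keep[j]]


def pca_unrelated(
    gm: GenotypeMatrix, snp_ids: list, unrelated: list, k: int = 10
) -> PCResult:
    """PCA of standardized genotypes restricted to the unrelated subjects.

    Each SNP is centered at 2*p-hat and scaled by sqrt(2*p-hat*(1 - p-hat))
    with p-hat estimated from the unrelated subjects; loadings are the right
    singular vectors of the standardized matrix.  ``k=0`` yields empty scores
    and an unadjusted downstream analysis.
    """
    if k > min(len(unrelated) - 1, len(snp_ids)):
        raise ValueError(
            f"k={k} exceeds min(n_unrelated - 1, n_snps) = "
            f"{min(len(unrelated) - 1, len(snp_ids))}"
        )
    sub = gm.subset_subjects(unrelated)
    cols = gm.variant_index(snp_ids)
    block = sub.dosage[:, cols]
    p_hat = np.nanmean(block, axis=0) / 2.0
    center = 2.0 * p_hat
    scale = np.sqrt(np.maximum(2.0 * p_hat * (1.0 - p_hat), 1e-12))
    Z = _impute_centered(block, center) / scale
    if k == 0:
        return PCResult(
            snp_ids=list(snp_ids),
            center=center,
            scale=scale,
            loadings=np.empty((len(snp_ids), 0)),
            scores=pd.DataFrame(index=pd.Index(unrelated, name="subject_id")),
            k=0,
        )
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt[:k].T
    # deterministic sign: largest-magnitude loading positive per component
    for j in range(k):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = pd.DataFrame(
        Z @ loadings,
        index=pd.Index(unrelated, name="subject_id"),
        columns=[f"PC{j + 1}" for j in range(k)],
    )
    return PCResult(
        snp_ids=list(snp_ids),
        center=center,
        scale=scale,
        loadings=loadings,
        scores=scores,
        k=k,
    )


def project_relatives(pc: PCResult, gm: GenotypeMatrix) -> PCResult:
    """Complete PC scores for the whole sample by projecting onto the loadings.

    Each subject's standardized genotype row (unrelated-set center and scale)
    is multiplied by the loadings; subjects already in the unrelated set get
    exactly their original scores (self-consistency of the linear projection).
    Missing genotypes at pruned SNPs are imputed at the center value.
    """
    cols = gm.variant_index(pc.snp_ids)
    block = gm.dosage[:, cols]
    Z = _impute_centered(block, pc.center) / pc.scale
    scores = pd.DataFrame(
        Z @ pc.loadings,
        index=pd.Index(gm.subject_ids, name="subject_id"),
        columns=list(pc.scores.columns),
    )
    return replace(pc, scores=scores)
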
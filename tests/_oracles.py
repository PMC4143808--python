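"""Independent oracles used by the tests.

These deliberately avoid the package's own computational paths: kinship is
checked against a Monte-Carlo gene-dropping estimate of identity-by-descent
sharing, and mixed-model GLS solutions are checked against dense full-matrix
linear algebra on covariance matrices assembled entry by entry from the model
covariance formulas.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def gene_drop_kinship_mc(members: pd.DataFrame, n_rep: int, seed: int):
    """Monte-Carlo kinship: half the expected proportion of alleles IBD.

    Founders get unique allele labels; each non-founder inherits one uniformly
    chosen allele per parent.  For each pair (i, j) the per-replicate statistic
    is the mean of the four allele-comparison indicators; its average over
    replicates estimates psi(i, j), with the empirical standard error returned
    alongside.

    Returns (ids, psi_hat, psi_se) with matrices over members in file order.
    """
    rng = np.random.default_rng(seed)
    ids = list(members["iid"])
    n = len(ids)
    idx = {iid: i for i, iid in enumerate(ids)}

    # resolve parents-before-children by repeated passes (independent of the
    # package's topological sort)
    resolved: list[int] = []
    done = set()
    rows = list(members.itertuples())
    while len(resolved) < n:
        for row in rows:
            i = idx[row.iid]
            if i in done:
                continue
            if row.father is None or (idx[row.father] in done and idx[row.mother] in done):
                resolved.append(i)
                done.add(i)

    alleles = np.zeros((n, 2, n_rep), dtype=np.int32)
    label = 0
    for i in resolved:
        row = rows[i]
        if row.father is None:
            alleles[i, 0] = label
            alleles[i, 1] = label + 1
            label += 2
        else:
            f, m = idx[row.father], idx[row.mother]
            pick_f = rng.integers(0, 2, n_rep)
            pick_m = rng.integers(0, 2, n_rep)
            alleles[i, 0] = alleles[f, pick_f, np.arange(n_rep)]
            alleles[i, 1] = alleles[m, pick_m, np.arange(n_rep)]

    psi_hat = np.zeros((n, n))
    psi_se = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = np.zeros(n_rep)
            for a in range(2):
                for b in range(2):
                    s += alleles[i, a] == alleles[j, b]
            s /= 4.0
            psi_hat[i, j] = psi_hat[j, i] = s.mean()
            se = s.std(ddof=1) / np.sqrt(n_rep)
            psi_se[i, j] = psi_se[j, i] = se
    return ids, psi_hat, psi_se


def dense_gls(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Textbook generalized least squares with a dense covariance matrix.

    Returns (beta, cov_beta) from inv(X' V^-1 X) X' V^-1 y.
    """
    Vi = np.linalg.inv(V)
    cov = np.linalg.inv(X.T @ Vi @ X)
    beta = cov @ X.T @ Vi @ y
    return beta, cov


def family_covariance_entrywise(
    subjects: np.ndarray,
    visits: np.ndarray,
    relatedness: np.ndarray,
    subject_index: dict,
    sigma2_g: float,
    sigma2_b: float,
    sigma2_e: float,
    with_subject_intercept: bool,
) -> np.ndarray:
    """Brute-force covariance from the displayed model formulas, entry by entry.

    Same subject, same visit: sigma_g^2 + sigma_b^2 + sigma^2 (the diagonal);
    same subject, different visits: sigma_g^2 + sigma_b^2 (or sigma_g^2 when
    the subject intercept is absent); different family members:
    2 psi sigma_g^2 for any pair of visits.
    """
    n = len(subjects)
    V = np.zeros((n, n))
    for r in range(n):
        for c in range(n):
            i, j = subject_index[subjects[r]], subject_index[subjects[c]]
            if subjects[r] == subjects[c]:
                if visits[r] == visits[c]:
                    V[r, c] = relatedness[i, i] * sigma2_g + sigma2_b + sigma2_e
                else:
                    V[r, c] = relatedness[i, i] * sigma2_g + (
                        sigma2_b if with_subject_intercept else 0.0
                    )
            else:
                V[r, c] = relatedness[i, j] * sigma2_g
    return V
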
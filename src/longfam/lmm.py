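"""Kinship-structured linear mixed models for pedigree association testing.

Five nested regression models share one computational core.  Writing S for the
marker (single-SNP dosage or transcript burden score), X for the covariates
(intercept, sex, smoking, age, optional PCs), g for the polygenic random
effect with Cov(g_i, g_i') = 2 psi_ii' sigma_g^2, and b for the subject-level
random intercept with variance sigma_b^2:

* ``M1_linear``          y_i  = b S_i + g'X_i + e_i                 (OLS; baseline/averaged)
* ``M2_subject``         y_it = b S_i + g'X_it + b_i + e_it         (repeated, unrelated)
* ``M3_family``          y_pi = b S_pi + g'X_pi + g_pi + e_pi       (baseline/averaged, pedigree)
* ``M4_family_subject``  y_pit = b S_pi + g'X_pit + g_pi + b_pi + e_pit
* ``M5_family_reduced``  y_pit = b S_pi + g'X_pit + g_pi + e_pit    (M4 without b_pi)

The marginal covariance is block-diagonal by family:
V = sigma_g^2 (2 Psi expanded over visits) + sigma_b^2 (within-subject blocks)
+ sigma^2 I.  Variance components are estimated by REML with the residual
variance profiled out and the remaining one or two variance ratios optimized
by a derivative-free simplex on the log scale; fixed effects are then GLS
estimates and markers are tested by Wald statistics with normal reference.

For chromosome-scale scans, :func:`null_model_cache` fits the variance
components once without the marker and scores every marker by GLS with those
components held fixed; an exact per-marker REML refit stays available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.stats import norm

from .pedigree import KinshipMatrix
from .phenotypes import PhenotypeView

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "AssociationResult",
    "NullModel",
    "build_covariance",
    "fit_model",
    "null_model_cache",
]

#: Model id -> (uses polygenic term, uses subject random intercept, allowed views, pedigree only)
_STRUCT = {
    "M1_linear": (False, False, {"baseline", "averaged"}, False),
    "M2_subject": (False, True, {"repeated"}, False),
    "M3_family": (True, False, {"baseline", "averaged"}, True),
    "M4_family_subject": (True, True, {"repeated"}, True),
    "M5_family_reduced": (True, False, {"repeated"}, True),
}
_ALIASES = {f"M{i}": mid for i, mid in enumerate(_STRUCT, start=1)}

_VAR_FLOOR = 1e-10
_REML_TOL = 1e-8
_REML_MAXITER = 200


def canonical_model_id(model_id: str) -> str:
    mid = _ALIASES.get(model_id, model_id)
    if mid not in _STRUCT:
        raise ValueError(f"unknown model id {model_id!r}; expected one of {list(_STRUCT)}")
    return mid


@dataclass(frozen=True)
class ModelSpec:
    """Which model to fit, on which phenotype view, for which study design."""

    model_id: str
    view: str
    design: str = "pedigree_sample"

    def __post_init__(self) -> None:
        mid = canonical_model_id(self.model_id)
        object.__setattr__(self, "model_id", mid)
        _, _, views, ped_only = _STRUCT[mid]
        if self.view not in views:
            raise ValueError(
                f"{mid} requires view in {sorted(views)}, got {self.view!r}"
            )
        if self.design not in ("pedigree_sample", "unrelated_only"):
            raise ValueError(f"unknown design {self.design!r}")
        if ped_only and self.design != "pedigree_sample":
            raise ValueError(f"{mid} requires the pedigree_sample design")


@dataclass(frozen=True)
class VarianceComponents:
    """(sigma_g^2, sigma_b^2, sigma^2) in squared trait units (mm Hg^2).

    Components absent from a model are fixed at zero.
    """

    sigma2_g: float = 0.0
    sigma2_b: float = 0.0
    sigma2_e: float = 1.0

    def __post_init__(self) -> None:
        if min(self.sigma2_g, self.sigma2_b, self.sigma2_e) < 0:
            raise ValueError("variance components must be nonnegative")


@dataclass
class AssociationResult:
    """Per-marker association output: Wald test of the marker coefficient."""

    marker_id: str
    beta: float
    se: float
    p_value: float | None
    model_id: str
    n_used: int
    converged: bool
    vc: VarianceComponents
    view: str = ""
    design: str = ""


# ---------------------------------------------------------------------------
# layout: rows ordered family-major / subject / visit, with per-family
# covariance patterns A = Z (2 Psi) Z' (polygenic) and B = Z Z' (subject blocks)


@dataclass
class _Layout:
    frame: pd.DataFrame           # ordered rows
    y: np.ndarray
    X: np.ndarray
    colnames: list
    groups: list                  # (row_slice, A or None, B or None)
    subject_per_row: np.ndarray   # subject id per ordered row
    use_g: bool
    use_b: bool


def _order_rows(frame: pd.DataFrame, km: KinshipMatrix | None) -> pd.DataFrame:
    frame = frame.copy()
    if km is not None:
        pos = {s: i for i, s in enumerate(km.subject_ids)}
        missing = [s for s in frame["subject_id"].unique() if s not in pos]
        if missing:
            raise KeyError(f"subjects absent from kinship matrix: {missing[:10]}")
        frame["_subj_pos"] = frame["subject_id"].map(pos)
    else:
        order_first = {s: i for i, s in enumerate(frame["subject_id"].unique())}
        frame["_subj_pos"] = frame["subject_id"].map(order_first)
    sort_cols = ["_subj_pos"] + (["visit"] if "visit" in frame.columns else [])
    frame = frame.sort_values(sort_cols, kind="stable").reset_index(drop=True)
    return frame.drop(columns="_subj_pos")


def _check_collinear(X: np.ndarray, colnames: list) -> None:
    for j in range(1, X.shape[1]):
        sol, res, rank, _ = np.linalg.lstsq(X[:, :j], X[:, j], rcond=None)
        fitted = X[:, :j] @ sol
        resid = X[:, j] - fitted
        denom = max(float(np.sum(X[:, j] ** 2)), 1.0)
        if float(np.sum(resid**2)) / denom < 1e-12:
            raise ValueError(
                f"collinear covariate column {colnames[j]!r} "
                f"(linear combination of {colnames[:j]})"
            )


def _build_layout(
    model_id: str,
    view: PhenotypeView,
    covariates: pd.DataFrame | None,
    marker: pd.Series | None,
    km: KinshipMatrix | None,
    marker_name: str = "marker",
    check_design: bool = True,
) -> _Layout:
    use_g, use_b, _, _ = _STRUCT[model_id]
    frame = view.frame.copy()
    if frame["y"].isna().any():
        raise ValueError("missing responses are not supported; filter rows first")
    frame = _order_rows(frame, km if use_g else None)
    subjects = frame["subject_id"].to_numpy()

    cols = ["age", "sex", "smoke"]
    X_parts = [np.ones(len(frame)), *[frame[c].to_numpy(float) for c in cols]]
    colnames = ["intercept", *cols]
    if covariates is not None and covariates.shape[1] > 0:
        cov = covariates.loc[subjects]
        for c in covariates.columns:
            X_parts.append(cov[c].to_numpy(float))
            colnames.append(str(c))
    if marker is not None:
        X_parts.append(marker.loc[subjects].to_numpy(float))
        colnames.append(marker_name)
    X = np.column_stack(X_parts)
    if check_design:
        if np.isnan(X).any():
            bad = [colnames[j] for j in range(X.shape[1]) if np.isnan(X[:, j]).any()]
            raise ValueError(f"missing values in design columns {bad}")
        _check_collinear(X, colnames)

    groups: list = []
    if use_g:
        fam_of = dict(zip(km.subject_ids, km.family_ids))
        fams = pd.Series([fam_of[s] for s in subjects])
        boundaries = _group_slices(fams.to_numpy())
        for sl in boundaries:
            subj_rows = subjects[sl]
            uniq = list(dict.fromkeys(subj_rows))
            R = km.relatedness(uniq)
            local = {s: i for i, s in enumerate(uniq)}
            zi = np.asarray([local[s] for s in subj_rows])
            A = R[np.ix_(zi, zi)]
            B = (zi[:, None] == zi[None, :]).astype(float) if use_b else None
            groups.append((sl, A, B))
    elif use_b:
        boundaries = _group_slices(subjects)
        for sl in boundaries:
            n_r = sl.stop - sl.start
            groups.append((sl, None, np.ones((n_r, n_r))))
    else:
        groups.append((slice(0, len(frame)), None, None))

    return _Layout(
        frame=frame,
        y=frame["y"].to_numpy(float),
        X=X,
        colnames=colnames,
        groups=groups,
        subject_per_row=subjects,
        use_g=use_g,
        use_b=use_b,
    )


def _group_slices(keys: np.ndarray) -> list[slice]:
    slices = []
    start = 0
    for i in range(1, len(keys) + 1):
        if i == len(keys) or keys[i] != keys[start]:
            slices.append(slice(start, i))
            start = i
    return slices


def build_covariance(
    spec: ModelSpec,
    km: KinshipMatrix | None,
    layout_frame: pd.DataFrame,
    vc: VarianceComponents,
) -> list[np.ndarray]:
    """Per-family covariance blocks V_p = sigma_g^2 A + sigma_b^2 B + sigma^2 I.

    ``layout_frame`` needs ``subject_id`` (and ``visit`` for repeated views);
    rows are reordered family-major internally.  A is 2*Psi expanded over the
    visit structure (identity-family for M2), B the within-subject all-ones
    pattern.  Raises if the kinship input is not positive semi-definite.
    """
    mid = canonical_model_id(spec.model_id)
    if km is not None:
        w = np.linalg.eigvalsh(2.0 * km.psi)
        if w.min() < -1e-8:
            raise ValueError("kinship matrix is not positive semi-definite")
    view = PhenotypeView(mode=spec.view, frame=_with_y(layout_frame), trait="SBP")
    lay = _build_layout(mid, view, None, None, km, check_design=False)
    blocks = []
    for sl, A, B in lay.groups:
        n_r = sl.stop - sl.start
        V = vc.sigma2_e * np.eye(n_r)
        if A is not None:
            V += vc.sigma2_g * A
        if B is not None:
            V += vc.sigma2_b * B
        blocks.append(V)
    return blocks


def _with_y(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    for c in ("y", "age", "sex", "smoke"):
        if c not in frame.columns:
            frame[c] = 0.0
    return frame


# ---------------------------------------------------------------------------
# REML with profiled residual variance


def _profile_pass(lam_g, lam_b, lay: _Layout):
    """One pass over family blocks at variance ratios (lam_g, lam_b).

    Returns (logdet W, X'W^-1 X, X'W^-1 y, y'W^-1 y) for W = I + lam_g A + lam_b B,
    or None if a block is not positive definite.
    """
    p = lay.X.shape[1]
    logdet = 0.0
    XtWX = np.zeros((p, p))
    XtWy = np.zeros(p)
    ytWy = 0.0
    for sl, A, B in lay.groups:
        n_r = sl.stop - sl.start
        W = np.eye(n_r)
        if A is not None:
            W = W + lam_g * A
        if B is not None:
            W = W + lam_b * B
        try:
            L, lower = cho_factor(W, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return None
        logdet += 2.0 * float(np.sum(np.log(np.diag(L))))
        Zx = solve_triangular(L, lay.X[sl], lower=True, check_finite=False)
        zy = solve_triangular(L, lay.y[sl], lower=True, check_finite=False)
        XtWX += Zx.T @ Zx
        XtWy += Zx.T @ zy
        ytWy += float(zy @ zy)
    return logdet, XtWX, XtWy, ytWy


def _neg2_reml(logs: np.ndarray, lay: _Layout, free: list[str]) -> float:
    lam = {"g": 0.0, "b": 0.0}
    for name, v in zip(free, logs):
        lam[name] = math.exp(min(max(v, math.log(_VAR_FLOOR)), math.log(1e10)))
    out = _profile_pass(lam["g"], lam["b"], lay)
    if out is None:
        return np.inf
    logdet, XtWX, XtWy, ytWy = out
    n, p = lay.X.shape
    sign, logdet_x = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtWX, XtWy)
    rss = ytWy - float(XtWy @ beta)
    if rss <= 0:
        return np.inf
    sigma2 = rss / (n - p)
    return (n - p) * math.log(sigma2) + logdet + logdet_x


def _reml_fit(lay: _Layout):
    """Estimate variance components and GLS fixed effects by profiled REML.

    Returns (vc, beta, cov_beta, converged, neg2reml).
    """
    free = []
    if lay.use_g:
        free.append("g")
    if lay.use_b:
        free.append("b")
    n, p = lay.X.shape

    if not free:  # OLS
        XtX = lay.X.T @ lay.X
        beta = np.linalg.solve(XtX, lay.X.T @ lay.y)
        resid = lay.y - lay.X @ beta
        sigma2 = float(resid @ resid) / (n - p)
        cov = sigma2 * np.linalg.inv(XtX)
        vc = VarianceComponents(0.0, 0.0, sigma2)
        obj = (n - p) * math.log(sigma2) + np.linalg.slogdet(XtX)[1]
        return vc, beta, cov, True, obj

    x0 = np.zeros(len(free))  # lambda = 1: equal partition of the variance
    res = optimize.minimize(
        _neg2_reml,
        x0,
        args=(lay, free),
        method="Nelder-Mead",
        options=dict(
            xatol=1e-6, fatol=_REML_TOL, maxiter=_REML_MAXITER * len(free), maxfev=2000
        ),
    )
    logs = res.x
    lam = {"g": 0.0, "b": 0.0}
    for name, v in zip(free, logs):
        lam[name] = math.exp(min(max(v, math.log(_VAR_FLOOR)), math.log(1e10)))
    logdet, XtWX, XtWy, ytWy = _profile_pass(lam["g"], lam["b"], lay)
    beta = np.linalg.solve(XtWX, XtWy)
    rss = ytWy - float(XtWy @ beta)
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(XtWX)

    def _report(lamk: float) -> float:
        var = lamk * sigma2
        return 0.0 if lamk <= 10 * _VAR_FLOOR else var

    vc = VarianceComponents(
        sigma2_g=_report(lam["g"]) if lay.use_g else 0.0,
        sigma2_b=_report(lam["b"]) if lay.use_b else 0.0,
        sigma2_e=sigma2,
    )
    return vc, beta, cov, bool(res.success), float(res.fun)


def _gls_fixed_vc(lay: _Layout, vc: VarianceComponents):
    """GLS estimates with the covariance fully specified (no estimation)."""
    p = lay.X.shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    for sl, A, B in lay.groups:
        n_r = sl.stop - sl.start
        V = vc.sigma2_e * np.eye(n_r)
        if A is not None:
            V += vc.sigma2_g * A
        if B is not None:
            V += vc.sigma2_b * B
        c = cho_factor(V, lower=True, check_finite=False)
        Vx = cho_solve(c, lay.X[sl], check_finite=False)
        XtVX += lay.X[sl].T @ Vx
        XtVy += Vx.T @ lay.y[sl]
    cov = np.linalg.inv(XtVX)
    beta = cov @ XtVy
    return beta, cov


def fit_model(
    spec: ModelSpec | str,
    view: PhenotypeView,
    marker: pd.Series | None = None,
    covariates: pd.DataFrame | None = None,
    km: KinshipMatrix | None = None,
    marker_name: str | None = None,
    vc_fixed: VarianceComponents | None = None,
) -> AssociationResult:
    """Fit one model and test the marker coefficient.

    ``marker`` is a per-subject series (single-SNP dosage or burden score)
    indexed by subject id; ``covariates`` are extra per-subject columns (PCs)
    beyond the built-in intercept/age/sex/smoking.  ``vc_fixed`` skips REML
    and performs GLS at the given variance components.

    The marker test is Wald: p = 2 Phi(-|beta/se|).
    """
    if isinstance(spec, str):
        spec = ModelSpec(model_id=spec, view=view.mode)
    mid = spec.model_id
    if spec.view != view.mode:
        raise ValueError(f"spec view {spec.view!r} does not match view {view.mode!r}")
    use_g = _STRUCT[mid][0]
    if use_g and km is None:
        raise ValueError(f"{mid} requires a kinship matrix")
    name = marker_name or (marker.name if marker is not None else "marker")
    lay = _build_layout(mid, view, covariates, marker, km if use_g else None, name)

    if vc_fixed is not None:
        beta_hat, cov = _gls_fixed_vc(lay, vc_fixed)
        vc, converged = vc_fixed, True
    else:
        vc, beta_hat, cov, converged, _ = _reml_fit(lay)

    if marker is None:
        return AssociationResult(
            marker_id="", beta=float("nan"), se=float("nan"), p_value=None,
            model_id=mid, n_used=len(lay.frame), converged=converged, vc=vc,
            view=spec.view, design=spec.design,
        )
    b = float(beta_hat[-1])
    se = float(math.sqrt(max(cov[-1, -1], 0.0)))
    if not converged or se == 0.0:
        p = None
    else:
        p = float(2.0 * norm.sf(abs(b / se)))
        p = max(p, 5e-324)  # keep p in (0, 1]
    return AssociationResult(
        marker_id=str(name), beta=b, se=se, p_value=p, model_id=mid,
        n_used=len(lay.frame), converged=converged, vc=vc,
        view=spec.view, design=spec.design,
    )


# ---------------------------------------------------------------------------
# cached null model for chromosome-scale scanning


@dataclass
class NullModel:
    """A fitted marker-free model reused to score many markers by GLS.

    Variance components come from one REML fit under beta = 0; each marker is
    then whitened with the fitted covariance, residualized against the null
    design, and Wald-tested.  :meth:`refit` provides the exact per-marker REML
    fit for refinement.
    """

    spec: ModelSpec
    vc: VarianceComponents
    converged: bool
    _lay: _Layout = field(repr=False, default=None)
    _L_blocks: list = field(repr=False, default_factory=list)
    _Q: np.ndarray = field(repr=False, default=None)
    _y_resid: np.ndarray = field(repr=False, default=None)
    _view: PhenotypeView = field(repr=False, default=None)
    _covariates: pd.DataFrame | None = field(repr=False, default=None)
    _km: KinshipMatrix | None = field(repr=False, default=None)

    @property
    def n_used(self) -> int:
        return len(self._lay.frame)

    def _whiten(self, M: np.ndarray) -> np.ndarray:
        out = np.empty_like(M, dtype=float)
        for (sl, _, _), L in zip(self._lay.groups, self._L_blocks):
            out[sl] = solve_triangular(L, M[sl], lower=True, check_finite=False)
        return out

    def test_markers(self, markers: pd.DataFrame) -> pd.DataFrame:
        """Wald tests for every column of ``markers`` (index: subject id).

        Zero-variance markers (after covariate adjustment) are flagged
        ``ok=False`` with no p-value.  Returns a DataFrame with columns
        marker_id, beta, se, p_value, n_used, model, view, design, ok.
        """
        M = markers.loc[self._lay.subject_per_row].to_numpy(float)
        if M.ndim == 1:
            M = M[:, None]
        Mw = self._whiten(M)
        Mr = Mw - self._Q @ (self._Q.T @ Mw)
        denom = np.einsum("ij,ij->j", Mr, Mr)
        ok = denom > 1e-10
        n_bad = int((~ok).sum())
        if n_bad:
            logger.warning("%d zero-variance marker(s) skipped", n_bad)
        beta = np.full(M.shape[1], np.nan)
        se = np.full(M.shape[1], np.nan)
        p = np.full(M.shape[1], np.nan)
        num = Mr.T @ self._y_resid
        beta[ok] = num[ok] / denom[ok]
        se[ok] = 1.0 / np.sqrt(denom[ok])
        z = np.abs(beta[ok] * np.sqrt(denom[ok]))
        p[ok] = np.maximum(2.0 * norm.sf(z), 5e-324)
        return pd.DataFrame(
            dict(
                marker_id=[str(c) for c in markers.columns],
                beta=beta,
                se=se,
                p_value=p,
                n_used=self.n_used,
                model=self.spec.model_id,
                view=self.spec.view,
                design=self.spec.design,
                ok=ok,
            )
        )

    def refit(self, marker: pd.Series, marker_name: str | None = None) -> AssociationResult:
        """Exact per-marker REML refit (used by the two-stage refinement)."""
        return fit_model(
            self.spec,
            self._view,
            marker=marker,
            covariates=self._covariates,
            km=self._km,
            marker_name=marker_name,
        )


def null_model_cache(
    spec: ModelSpec | str,
    view: PhenotypeView,
    covariates: pd.DataFrame | None = None,
    km: KinshipMatrix | None = None,
) -> NullModel:
    """Fit the marker-free model once and prepare fast per-marker GLS tests."""
    if isinstance(spec, str):
        spec = ModelSpec(model_id=spec, view=view.mode)
    mid = spec.model_id
    use_g = _STRUCT[mid][0]
    lay = _build_layout(mid, view, covariates, None, km if use_g else None)
    vc, _, _, converged, _ = _reml_fit(lay)
    if not converged:
        logger.warning("null model %s did not converge; scan p-values suspect", mid)

    L_blocks = []
    for sl, A, B in lay.groups:
        n_r = sl.stop - sl.start
        V = vc.sigma2_e * np.eye(n_r)
        if A is not None:
            V += vc.sigma2_g * A
        if B is not None:
            V += vc.sigma2_b * B
        L_blocks.append(np.linalg.cholesky(V))
    null = NullModel(
        spec=spec, vc=vc, converged=converged, _lay=lay, _L_blocks=L_blocks,
        _view=view, _covariates=covariates, _km=km if use_g else None,
    )
    Xw = null._whiten(lay.X)
    Q, _ = np.linalg.qr(Xw)
    yw = null._whiten(lay.y[:, None])[:, 0]
    null._Q = Q
    null._y_resid = yw - Q @ (Q.T @ yw)
    return null
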
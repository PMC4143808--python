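"""The mixed-model engine: covariance construction, REML fits, cached scans."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from longfam.lmm import (
    ModelSpec,
    VarianceComponents,
    build_covariance,
    fit_model,
    null_model_cache,
)
from longfam.phenotypes import PhenotypeView, make_view, medication_preadjust
from longfam.simdata import SimulationConfig, simulate_dataset

from _oracles import dense_gls, family_covariance_entrywise


def repeated_frame(subjects, T):
    rows = []
    for s in subjects:
        for t in range(1, T + 1):
            rows.append(dict(subject_id=s, visit=t, y=0.0, age=50.0 + t, sex=0, smoke=0))
    return pd.DataFrame(rows)


class TestModelSpec:
    @pytest.mark.parametrize(
        "model, view", [("M2", "baseline"), ("M1", "repeated"), ("M4", "averaged")]
    )
    def test_invalid_view_pairings_rejected(self, model, view):
        with pytest.raises(ValueError, match="requires view"):
            ModelSpec(model, view)

    def test_pedigree_only_models_reject_unrelated_design(self):
        with pytest.raises(ValueError, match="pedigree_sample"):
            ModelSpec("M4", "repeated", "unrelated_only")

    def test_aliases_resolve(self):
        assert ModelSpec("M5", "repeated").model_id == "M5_family_reduced"


class TestBuildCovariance:
    def test_m2_within_subject_correlation_half(self):
        spec = ModelSpec("M2", "repeated")
        frame = repeated_frame(["s1"], T=2)
        blocks = build_covariance(
            spec, None, frame, VarianceComponents(0.0, 1.0, 1.0)
        )
        V = blocks[0]
        corr = V[0, 1] / np.sqrt(V[0, 0] * V[1, 1])
        assert corr == pytest.approx(0.5)  # sigma_b^2 / (sigma_b^2 + sigma^2)

    def test_m4_with_diagonal_kinship_equals_m2_plus_genetic(self, trio):
        """With no off-diagonal kinship, M4's subject blocks are M2's with
        sigma_b^2 replaced by sigma_g^2 + sigma_b^2."""
        from conftest import make_pedigree
        from longfam.pedigree import compute_kinship

        ped = make_pedigree(
            [("F1", "a", None, None, "male"), ("F2", "b", None, None, "male")]
        )
        km = compute_kinship(ped)
        frame = repeated_frame(["a", "b"], T=3)
        vc = VarianceComponents(2.0, 1.5, 1.0)
        m4 = build_covariance(ModelSpec("M4", "repeated"), km, frame, vc)
        m2 = build_covariance(
            ModelSpec("M2", "repeated"), None, frame,
            VarianceComponents(0.0, vc.sigma2_g + vc.sigma2_b, vc.sigma2_e),
        )
        for a, b in zip(m4, m2):
            np.testing.assert_allclose(a, b)

    def test_entrywise_oracle_on_family_block(self, rng):
        """M4/M5 blocks match the brute-force assembly from the covariance
        formulas: 2 psi sigma_g^2 across members, sigma_g^2 (+ sigma_b^2)
        within subject, + sigma^2 on the diagonal."""
        from conftest import make_pedigree
        from longfam.pedigree import compute_kinship

        ped = make_pedigree(
            [
                ("F1", "f", None, None, "male"),
                ("F1", "m", None, None, "female"),
                ("F1", "c", "f", "m", "male"),
            ]
        )
        km = compute_kinship(ped)
        frame = repeated_frame(["f", "m", "c"], T=3)
        vc = VarianceComponents(*rng.uniform(0.5, 3.0, 3))
        for model, with_b in (("M4", True), ("M5", False)):
            vc_used = vc if with_b else VarianceComponents(vc.sigma2_g, 0.0, vc.sigma2_e)
            blocks = build_covariance(ModelSpec(model, "repeated"), km, frame, vc_used)
            R = km.relatedness(["f", "m", "c"])
            sidx = {"f": 0, "m": 1, "c": 2}
            subjects = np.repeat(["f", "m", "c"], 3)
            visits = np.tile([1, 2, 3], 3)
            V_oracle = family_covariance_entrywise(
                subjects, visits, R, sidx,
                vc_used.sigma2_g, vc_used.sigma2_b, vc_used.sigma2_e,
                with_subject_intercept=with_b,
            )
            np.testing.assert_allclose(blocks[0], V_oracle, atol=1e-12)

    def test_non_psd_kinship_rejected(self):
        from longfam.pedigree import KinshipMatrix

        bad = KinshipMatrix(
            subject_ids=["a", "b"],
            family_ids=np.array(["F1", "F1"], dtype=object),
            psi=np.array([[0.5, 0.9], [0.9, 0.5]]),
        )
        frame = repeated_frame(["a", "b"], T=1)
        with pytest.raises(ValueError, match="positive semi-definite"):
            build_covariance(
                ModelSpec("M5", "repeated"), bad, frame, VarianceComponents(1, 0, 1)
            )


@pytest.fixture(scope="module")
def sim60():
    """60 subjects: 5 template pedigrees (11 members) + 5 singletons."""
    from longfam.simdata import PedigreeTemplate

    cfg = SimulationConfig(
        seed=42, n_pedigrees=5, template=PedigreeTemplate(3, 2, 2),
        n_unrelated_extra=5, n_common=20, n_transcripts=2,
    )
    return simulate_dataset(cfg)


class TestFitModel:
    def test_m1_matches_closed_form_least_squares(self, sim60):
        ph = medication_preadjust(sim60.phenotypes)
        view = make_view(ph, "averaged")
        marker = pd.Series(sim60.gm.dosage[:, 0], index=sim60.gm.subject_ids)
        res = fit_model(ModelSpec("M1", "averaged"), view, marker=marker, marker_name="m")
        f = view.frame
        X = np.column_stack(
            [np.ones(len(f)), f["age"], f["sex"], f["smoke"],
             marker.loc[f["subject_id"]].to_numpy()]
        )
        y = f["y"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (len(y) - X.shape[1])
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[-1, -1])
        assert res.beta == pytest.approx(beta[-1], abs=1e-10)
        assert res.se == pytest.approx(se, rel=1e-10)
        assert res.p_value == pytest.approx(2 * norm.sf(abs(beta[-1] / se)), rel=1e-9)

    def test_m3_fixed_vc_matches_dense_gls_oracle(self, sim60):
        """GLS equivalence: variance components held at truth, dense oracle."""
        ph = medication_preadjust(sim60.phenotypes)
        view = make_view(ph, "averaged")
        marker = pd.Series(sim60.gm.dosage[:, 1], index=sim60.gm.subject_ids)
        vc = VarianceComponents(4.0, 0.0, 2.0 + 4.0 / 3.0)
        res = fit_model(
            ModelSpec("M3", "averaged"), view, marker=marker, km=sim60.km,
            marker_name="m", vc_fixed=vc,
        )
        subjects = sim60.km.subject_ids
        f = view.frame.set_index("subject_id").loc[subjects].reset_index()
        X = np.column_stack(
            [np.ones(len(f)), f["age"], f["sex"], f["smoke"],
             marker.loc[f["subject_id"]].to_numpy()]
        )
        V = vc.sigma2_g * (2 * sim60.km.psi) + vc.sigma2_e * np.eye(len(subjects))
        beta, cov = dense_gls(f["y"].to_numpy(), X, V)
        assert res.beta == pytest.approx(beta[-1], abs=1e-8)
        assert res.se == pytest.approx(np.sqrt(cov[-1, -1]), abs=1e-8)

    def test_m3_equals_m1_when_all_unrelated(self):
        cfg = SimulationConfig(seed=3, n_pedigrees=0, n_unrelated_extra=120,
                               n_common=10, n_transcripts=1, n_visits=1)
        sim = simulate_dataset(cfg)
        ph = medication_preadjust(sim.phenotypes)
        view = make_view(ph, "baseline")
        marker = pd.Series(sim.gm.dosage[:, 0], index=sim.gm.subject_ids)
        r3 = fit_model(ModelSpec("M3", "baseline"), view, marker=marker,
                       km=sim.km, marker_name="m")
        r1 = fit_model(ModelSpec("M1", "baseline"), view, marker=marker,
                       marker_name="m")
        assert r3.beta == pytest.approx(r1.beta, abs=1e-6)
        assert abs(r3.p_value - r1.p_value) < 1e-6

    def test_m4_restricted_likelihood_at_least_m5(self, sim60):
        """Model nesting: the fuller covariance cannot fit worse."""
        from longfam.lmm import _build_layout, _reml_fit

        ph = medication_preadjust(sim60.phenotypes)
        view = make_view(ph, "repeated")
        lay4 = _build_layout("M4_family_subject", view, None, None, sim60.km)
        lay5 = _build_layout("M5_family_reduced", view, None, None, sim60.km)
        *_, obj4 = _reml_fit(lay4)
        *_, obj5 = _reml_fit(lay5)
        assert obj4 <= obj5 + 1e-6  # -2 log REML, smaller is better

    def test_collinear_covariates_named(self, sim60):
        ph = medication_preadjust(sim60.phenotypes)
        view = make_view(ph, "averaged")
        dup = pd.DataFrame(
            {"age_copy": view.frame.set_index("subject_id")["age"]},
        )
        with pytest.raises(ValueError, match="age_copy"):
            fit_model(ModelSpec("M3", "averaged"), view, covariates=dup,
                      km=sim60.km)

    def test_missing_response_rejected(self, sim60):
        ph = medication_preadjust(sim60.phenotypes)
        view = make_view(ph, "averaged")
        frame = view.frame.copy()
        frame.loc[0, "y"] = np.nan
        bad = PhenotypeView(mode="averaged", frame=frame, trait="SBP")
        with pytest.raises(ValueError, match="missing responses"):
            fit_model(ModelSpec("M3", "averaged"), bad, km=sim60.km)

    def test_cross_check_against_statsmodels_random_intercept(self, sim60):
        """M2 variance components and marker test agree with an independent
        random-intercept fit (statsmodels MixedLM, ML machinery with REML)."""
        import statsmodels.formula.api as smf

        ph = medication_preadjust(sim60.phenotypes)
        view = make_view(ph, "repeated")
        marker = pd.Series(sim60.gm.dosage[:, 2], index=sim60.gm.subject_ids)
        res = fit_model(ModelSpec("M2", "repeated"), view, marker=marker,
                        marker_name="snp")
        df = view.frame.copy()
        df["snp"] = marker.loc[df["subject_id"]].to_numpy()
        sm_fit = smf.mixedlm(
            "y ~ age + sex + smoke + snp", df, groups=df["subject_id"]
        ).fit(reml=True)
        assert res.beta == pytest.approx(sm_fit.params["snp"], rel=1e-4, abs=1e-6)
        assert res.se == pytest.approx(sm_fit.bse["snp"], rel=1e-3)
        assert res.vc.sigma2_b == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-4
        )
        assert res.vc.sigma2_e == pytest.approx(sm_fit.scale, rel=1e-3)


class TestNullModelCache:
    def test_cached_test_matches_fixed_vc_gls_oracle(self, sim60):
        """A marker scored off the cached null equals the dense GLS oracle at
        the cached variance components."""
        ph = medication_preadjust(sim60.phenotypes)
        view = make_view(ph, "averaged")
        null = null_model_cache(ModelSpec("M3", "averaged"), view, km=sim60.km)
        marker = pd.Series(sim60.gm.dosage[:, 3], index=sim60.gm.subject_ids,
                           name="m3_snp")
        out = null.test_markers(marker.to_frame())
        subjects = sim60.km.subject_ids
        f = view.frame.set_index("subject_id").loc[subjects].reset_index()
        X = np.column_stack(
            [np.ones(len(f)), f["age"], f["sex"], f["smoke"],
             marker.loc[subjects].to_numpy()]
        )
        vc = null.vc
        V = vc.sigma2_g * (2 * sim60.km.psi) + vc.sigma2_e * np.eye(len(subjects))
        beta, cov = dense_gls(f["y"].to_numpy(), X, V)
        assert out["beta"].iloc[0] == pytest.approx(beta[-1], abs=1e-10)
        assert out["se"].iloc[0] == pytest.approx(np.sqrt(cov[-1, -1]), abs=1e-10)

    def test_rank_agreement_with_per_marker_reml(self, sim60):
        """Cached-null p-values rank-correlate > 0.99 with exact refits."""
        ph = medication_preadjust(sim60.phenotypes)
        view = make_view(ph, "repeated")
        spec = ModelSpec("M5", "repeated")
        null = null_model_cache(spec, view, km=sim60.km)
        markers = pd.DataFrame(
            sim60.gm.dosage[:, :20], index=sim60.gm.subject_ids,
            columns=sim60.gm.variant_ids[:20],
        )
        cached = null.test_markers(markers).set_index("marker_id")["p_value"]
        exact = pd.Series(
            {
                vid: fit_model(spec, view, marker=markers[vid], km=sim60.km,
                               marker_name=vid).p_value
                for vid in markers.columns
            }
        )
        rho = cached.rank().corr(exact.rank())
        assert rho > 0.99

    def test_zero_variance_marker_flagged(self, sim60):
        ph = medication_preadjust(sim60.phenotypes)
        view = make_view(ph, "averaged")
        null = null_model_cache(ModelSpec("M3", "averaged"), view, km=sim60.km)
        flat = pd.DataFrame(
            {"flat": np.ones(len(sim60.gm.subject_ids))}, index=sim60.gm.subject_ids
        )
        out = null.test_markers(flat)
        assert not out["ok"].iloc[0]
        assert np.isnan(out["p_value"].iloc[0])
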
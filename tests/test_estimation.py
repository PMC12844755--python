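"""Estimation-engine tests: conditional modes, objective oracle, fitting."""

import math

import numpy as np
import pytest
from scipy import integrate

from teicopk import (
    CovariateVector,
    DoseEvent,
    EtaVector,
    Observation,
    StudyDataset,
    Subject,
    ThetaSet,
    concentration,
    individual_parameters,
)
from teicopk.estimation import (
    ModelSpec,
    OmegaMatrix,
    PopulationModel,
    SigmaSpec,
    conditional_eta,
    eta_shrinkage,
    final_model_spec,
    fit_model,
    foce_objective,
    predict_subject,
    standard_errors,
)

from conftest import make_subject

REF_COV = CovariateVector.from_ibw(61.0, 92.15, 62.0)


def _noise_free_subject(eta, obs_times=(24.0, 96.0), sid=1):
    """Subject whose observations equal the individual model prediction exactly."""
    ts = ThetaSet.final()
    doses = [DoseEvent(0, 600, 0.5), DoseEvent(12, 600, 0.5), DoseEvent(24, 600, 0.5),
             DoseEvent(48, 600, 0.5), DoseEvent(72, 600, 0.5), DoseEvent(96, 600, 0.5)]
    p = individual_parameters(ts, REF_COV, eta)
    t = np.array(obs_times)
    c = concentration(p, doses, t)
    return Subject(sid, doses, [Observation(tt, cc) for tt, cc in zip(t, c)], REF_COV)


class TestConditionalEta:
    def test_exact_typical_observations_give_zero_mode(self, published_model):
        subj = _noise_free_subject(EtaVector(0, 0))
        eta = conditional_eta(subj, published_model)
        assert eta.eta_cl == pytest.approx(0.0, abs=1e-6)
        assert eta.eta_v == pytest.approx(0.0, abs=1e-6)

    def test_vanishing_omega_shrinks_to_zero(self, published_model):
        subj = _noise_free_subject(EtaVector(0.4, -0.3))
        eta = conditional_eta(subj, ThetaSet.final(), OmegaMatrix(0.0, 0.0), SigmaSpec(2.61))
        assert (eta.eta_cl, eta.eta_v) == (0.0, 0.0)

    def test_noise_free_identifiability_matches_grid_search(self):
        """With sigma -> 0 the mode recovers the generating etas; a brute
        grid search over eta-space is the independent oracle."""
        true = EtaVector(0.3, -0.2)
        subj = _noise_free_subject(true, obs_times=(24.0, 48.0, 96.0))
        sigma = SigmaSpec(1e-4)
        omega = OmegaMatrix(0.341**2, 0.310**2)
        eta = conditional_eta(subj, ThetaSet.final(), omega, sigma)
        assert eta.eta_cl == pytest.approx(0.3, abs=1e-3)
        assert eta.eta_v == pytest.approx(-0.2, abs=1e-3)

        # grid-search oracle on the joint objective
        ts = ThetaSet.final()
        y = subj.dv
        grid = np.linspace(-0.6, 0.6, 81)
        best, best_val = None, np.inf
        for e1 in grid:
            for e2 in grid:
                p = individual_parameters(ts, REF_COV, EtaVector(e1, e2))
                f = concentration(p, subj.doses, subj.obs_times)
                val = np.sum((y - f) ** 2) / sigma.sd**2 + e1**2 / omega.omega2_cl + e2**2 / omega.omega2_v
                if val < best_val:
                    best, best_val = (e1, e2), val
        assert eta.eta_cl == pytest.approx(best[0], abs=0.02)
        assert eta.eta_v == pytest.approx(best[1], abs=0.02)

    def test_subject_without_observations_rejected(self, published_model):
        s = Subject(9, [DoseEvent(0, 600, 0.5)], [], REF_COV)
        with pytest.raises(ValueError, match="no observations"):
            conditional_eta(s, published_model)


class TestFoceObjective:
    def test_single_observation_closed_form(self):
        """omega = 0, y = f: the OFV is the Gaussian constant log(2 pi sigma^2)."""
        subj = _noise_free_subject(EtaVector(0, 0), obs_times=(24.0,))
        ofv = foce_objective(
            StudyDataset([subj]), ThetaSet.final(), OmegaMatrix(0, 0), SigmaSpec(2.61)
        )
        assert ofv == pytest.approx(math.log(2 * math.pi * 2.61**2), abs=1e-9)

    def test_matches_adaptive_quadrature_oracle(self, published_model, two_obs_subject):
        """Laplace/FOCE approximation vs numerically integrated -2 log L."""
        ds = StudyDataset([two_obs_subject])
        ofv = foce_objective(ds, published_model)

        ts = ThetaSet.final()
        w = published_model.omega.diag
        sig = published_model.sigma.sd
        y = two_obs_subject.dv
        t = two_obs_subject.obs_times

        def integrand(e1, e2):
            p = individual_parameters(ts, REF_COV, EtaVector(e1, e2))
            f = concentration(p, two_obs_subject.doses, t)
            ll = -0.5 * np.sum((y - f) ** 2) / sig**2 - len(y) / 2 * math.log(2 * math.pi * sig**2)
            lp = -0.5 * (e1**2 / w[0] + e2**2 / w[1]) - 0.5 * math.log((2 * math.pi) ** 2 * w[0] * w[1])
            return math.exp(ll + lp)

        val, err = integrate.dblquad(integrand, -2.5, 2.5, -2.5, 2.5,
                                     epsabs=1e-13, epsrel=1e-10)
        assert ofv == pytest.approx(-2 * math.log(val), abs=0.1)

    def test_duplicate_subject_doubles_the_objective(self, published_model, two_obs_subject):
        one = StudyDataset([two_obs_subject])
        twin = Subject(2, two_obs_subject.doses, two_obs_subject.observations, REF_COV)
        two = StudyDataset([two_obs_subject, twin])
        assert foce_objective(two, published_model) == pytest.approx(
            2 * foce_objective(one, published_model), abs=1e-8
        )

    def test_permutation_invariance(self, published_model, small_dataset):
        fwd = foce_objective(small_dataset, published_model)
        rev = foce_objective(StudyDataset(small_dataset.subjects[::-1]), published_model)
        assert fwd == pytest.approx(rev, abs=1e-9)

    def test_invalid_parameters_rejected(self, two_obs_subject):
        with pytest.raises(ValueError):
            foce_objective(StudyDataset([two_obs_subject]), ThetaSet.final(),
                           OmegaMatrix(-0.1, 0.1), SigmaSpec(2.61))
        with pytest.raises(ValueError):
            SigmaSpec(0.0)


class TestEtaShrinkage:
    @pytest.mark.parametrize(
        "etas,omega,expected",
        [
            ([0.0] * 10, 0.3, 100.0),                       # all modes at zero
            (list(np.linspace(-0.45, 0.45, 10)), None, 0.0),  # SD(eta) == omega
            (None, None, 50.0),                              # SD(eta) = omega/2
        ],
    )
    def test_definition(self, etas, omega, expected):
        from teicopk.estimation import FitResult

        if etas is None:  # construct SD = 0.15 sample, omega = 0.3
            rng = np.random.default_rng(5)
            sample = rng.standard_normal(2000)
            sample = (sample - sample.mean()) / sample.std(ddof=1) * 0.15
            etas, omega = list(sample), 0.3
        elif omega is None:
            etas = np.asarray(etas)
            etas = (etas - etas.mean()) / etas.std(ddof=1) * 0.3
            omega = 0.3
        ebes = [EtaVector(e, 0.0) for e in np.atleast_1d(etas)]
        fit = FitResult(
            spec=ModelSpec(), theta={}, omega=OmegaMatrix(omega**2, 0.0),
            sigma=SigmaSpec(1.0), ofv=0.0, ebes=ebes,
            subject_ids=list(range(len(ebes))), converged=True, boundary=False,
        )
        shr = eta_shrinkage(fit)
        assert shr["CL"] == pytest.approx(expected, abs=1e-6)
        assert shr["V"] is None  # omega_V = 0 -> undefined


def _rich_dataset(n=12, seed=3, sigma=1.5):
    """Small rich-sampling synthetic study for fast fitting tests."""
    rng = np.random.default_rng(seed)
    ts = ThetaSet.final()
    subjects = []
    for i in range(n):
        ibw = rng.uniform(48, 76)
        egfr = rng.uniform(30, 140)
        age = rng.uniform(20, 84)
        cov = CovariateVector.from_ibw(ibw, egfr, age)
        eta = EtaVector(0.34 * rng.standard_normal(), 0.31 * rng.standard_normal())
        p = individual_parameters(ts, cov, eta)
        doses = [DoseEvent(12.0 * k, 600, 0.5) for k in range(3)] + [
            DoseEvent(48.0 + 24.0 * k, 600, 0.5) for k in range(6)
        ]
        t = np.array([24.0, 48.0, 96.0, 168.0])
        c = concentration(p, doses, t)
        dv = c + sigma * rng.standard_normal(len(t))
        obs = [Observation(tt, max(float(v), 0.5)) for tt, v in zip(t, dv)]
        subjects.append(Subject(i + 1, doses, obs, cov))
    return StudyDataset(subjects)


@pytest.fixture(scope="module")
def rich_fit():
    ds = _rich_dataset()
    return ds, fit_model(ds, final_model_spec())


class TestFitModel:

    def test_descent_and_convergence(self, rich_fit):
        ds, fit = rich_fit
        spec = final_model_spec()
        init_model = PopulationModel(
            spec,
            {"CLpop": spec.cl_init, "Vpop": spec.v_init, "EGFR_CL": 0.75,
             "IBW_CL": 1.0, "AGE_CL": 0.0},
            OmegaMatrix(spec.omega2_cl_init, spec.omega2_v_init),
            SigmaSpec(spec.sigma_init),
        )
        assert fit.converged
        assert fit.ofv <= foce_objective(ds, init_model)

    def test_ebe_consistency(self, rich_fit):
        """Recomputing conditional modes at the optimum reproduces stored EBEs."""
        ds, fit = rich_fit
        by_id = {s.id: s for s in ds}
        for sid, ebe in zip(fit.subject_ids, fit.ebes):
            again = conditional_eta(by_id[sid], fit.model)
            assert again.eta_cl == pytest.approx(ebe.eta_cl, abs=1e-6)
            assert again.eta_v == pytest.approx(ebe.eta_v, abs=1e-6)

    def test_zero_noise_zero_eta_hits_variance_boundary(self):
        """Degenerate data (no noise, no IIV): theta recovered, omega/sigma
        collapse and the boundary flag is raised."""
        subjects = [
            _noise_free_subject(EtaVector(0, 0), obs_times=(24.0, 48.0, 96.0), sid=i)
            for i in range(1, 6)
        ]
        # identical subjects: fix covariate coefficients (not identifiable)
        spec = ModelSpec(
            effects=final_model_spec().effects,
            fix=frozenset({"EGFR_CL", "IBW_CL", "AGE_CL"}),
        )
        spec = ModelSpec(
            effects=tuple(
                type(e)(e.covariate, e.parameter, e.form, e.ref, init)
                for e, init in zip(spec.effects, (0.35, 3.2, 0.012))
            ),
            fix=frozenset({"EGFR_CL", "IBW_CL", "AGE_CL"}),
        )
        fit = fit_model(StudyDataset(subjects), spec, maxiter=200)
        assert fit.boundary
        assert fit.theta["CLpop"] == pytest.approx(1.28, rel=0.02)
        assert fit.theta["Vpop"] == pytest.approx(92.10, rel=0.02)

    def test_needs_two_subjects(self, two_obs_subject):
        with pytest.raises(ValueError, match="2 subjects"):
            fit_model(StudyDataset([two_obs_subject]))


class TestStandardErrors:
    def test_information_additivity_and_fixed_exclusion(self):
        """Duplicating every subject shrinks SEs by ~1/sqrt(2); fixed
        parameters stay out of the RSE table."""
        ds = _rich_dataset(n=10, seed=11)
        spec = ModelSpec(
            effects=final_model_spec().effects,
            fix=frozenset({"EGFR_CL", "IBW_CL", "AGE_CL", "omega2_V"}),
        )
        inits = {"EGFR_CL": 0.35, "IBW_CL": 3.2, "AGE_CL": 0.012, "omega2_V": 0.31**2}
        fit1 = fit_model(ds, spec, inits=inits)
        se1 = standard_errors(fit1, ds)
        assert set(se1) == {"CLpop", "Vpop", "omega2_CL", "sigma"}

        doubled = StudyDataset(
            ds.subjects
            + [Subject(f"{s.id}b", s.doses, s.observations, s.covariates) for s in ds]
        )
        fit2 = fit_model(doubled, spec, inits=inits)
        se2 = standard_errors(fit2, doubled)
        for name in ("CLpop", "Vpop", "sigma"):
            ratio = se2[name]["se"] / se1[name]["se"]
            assert ratio == pytest.approx(1 / math.sqrt(2), rel=0.15)

    def test_rse_reported_on_natural_scale(self):
        ds = _rich_dataset(n=10, seed=11)
        spec = ModelSpec(
            effects=final_model_spec().effects,
            fix=frozenset({"EGFR_CL", "IBW_CL", "AGE_CL", "omega2_V"}),
        )
        inits = {"EGFR_CL": 0.35, "IBW_CL": 3.2, "AGE_CL": 0.012, "omega2_V": 0.31**2}
        fit = fit_model(ds, spec, inits=inits)
        out = standard_errors(fit, ds)
        for name, d in out.items():
            assert d["rse_pct"] is not None and d["rse_pct"] > 0
        assert fit.rse_pct["CLpop"] == out["CLpop"]["rse_pct"]


def test_predict_subject_population_vs_individual(published_model):
    subj = _noise_free_subject(EtaVector(0.3, 0.0), obs_times=(24.0, 96.0))
    pop = predict_subject(subj, published_model)
    ind = predict_subject(subj, published_model, EtaVector(0.3, 0.0))
    np.testing.assert_allclose(ind, subj.dv, rtol=1e-10)
    assert np.all(pop > ind)  # higher CL -> lower concentrations
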
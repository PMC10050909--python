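"""Estimation machinery: objective, Laplace vs quadrature, LRT, mixtures."""

import dataclasses

import numpy as np
import pytest

from tbpopk.data import (
    Cohort, DoseEvent, Observation, SubjectRecord, apply_m6, preprocess,
)
from tbpopk.estimate import PopPKModel, covariate_search, lrt, mixture_assign
from tbpopk.simulate import CohortSpec, generate_cohort, simulate_trial
from tbpopk.structural import StructuralModel, default_params, final_model
from conftest import make_subject


def _single_subject_cohort(value=5.0):
    s = make_subject(obs=[(2.5, value, False)])
    return preprocess(Cohort(drug="rifampicin", subjects=[s]))


class TestObjective:
    def test_single_observation_no_random_effects_closed_form(self):
        # with all variability switched off the subject likelihood is a
        # single Gaussian: ofv = log(2 pi sigma^2) + r^2/sigma^2
        cohort = _single_subject_cohort()
        struct = dataclasses.replace(final_model("rifampicin"),
                                     reff=(), brc_on_cl=False,
                                     group_on_absorption=False)
        pop = {k: v for k, v in default_params("rifampicin").items()}
        pop["sigma_prop"] = 0.0
        pop["sigma_add"] = 0.5
        model = PopPKModel(cohort, struct)
        ofv = model.objective(pop)
        from tbpopk.structural import predict_conc
        f = predict_conc(struct, pop, model.design,
                         np.zeros((1, 0)))[0, 0]
        expected = np.log(2 * np.pi * 0.25) + (5.0 - f) ** 2 / 0.25
        assert ofv == pytest.approx(expected, abs=1e-6)

    def test_error_magnitude_changes_ofv(self):
        cohort = _single_subject_cohort()
        model = PopPKModel(cohort, final_model("rifampicin"))
        pop = default_params("rifampicin")
        assert model.objective(pop) != model.objective(
            {**pop, "sigma_prop": 2 * pop["sigma_prop"]})

    def test_m6_objective_equals_plain_when_no_blq(self, small_sim_study):
        # running the M6 step on BLQ-free data must not change the objective
        trial = small_sim_study["trial"]
        no_blq = trial.cohort.copy()
        for s in no_blq.subjects:
            for o in s.observations:
                if o.blq:
                    o.blq = False  # pretend the assay quantified everything
        pop = small_sim_study["pop"]
        m_plain = PopPKModel(preprocess(no_blq), small_sim_study["struct"])
        m_m6 = PopPKModel(apply_m6(preprocess(no_blq)), small_sim_study["struct"])
        assert m_plain.objective(pop) == pytest.approx(m_m6.objective(pop))

    def test_laplace_within_two_points_of_gauss_hermite(self):
        # reduced random-effect structure (BSV-CL + BOV-F) keeps the 5-node
        # product rule tractable on a 20-subject instance
        struct = dataclasses.replace(
            final_model("rifampicin"),
            reff=(("cl", "bsv"), ("f", "bov")),
            brc_on_cl=False, group_on_absorption=False)
        base = CohortSpec()
        spec = dataclasses.replace(base, groups={
            "outpatient": dataclasses.replace(
                base.groups["outpatient"], n=20,
                n_missing_height=0, n_missing_brc=0)})
        pop = default_params("rifampicin")
        trial = simulate_trial(struct, pop, generate_cohort(spec, "rifampicin", 17), 18)
        model = PopPKModel(preprocess(trial.cohort), struct)
        laplace = model.objective(pop, curvature="exact")
        agq = model.objective_agq(pop, n_nodes=5)
        assert abs(laplace - agq) < 2.0

    def test_laplace_matches_quadrature_single_eta(self):
        struct = dataclasses.replace(
            final_model("pyrazinamide"), reff=(("cl", "bsv"),),
            group_fold_on_bsv_cl=False)
        base = CohortSpec()
        spec = dataclasses.replace(base, groups={
            "outpatient": dataclasses.replace(
                base.groups["outpatient"], n=12,
                n_missing_height=0, n_missing_brc=0)})
        pop = default_params("pyrazinamide")
        trial = simulate_trial(struct, pop,
                               generate_cohort(spec, "pyrazinamide", 23), 24)
        model = PopPKModel(preprocess(trial.cohort), struct)
        assert abs(model.objective(pop, curvature="exact") - model.objective_agq(pop, 7)) < 1.0


class TestFit:
    def test_noise_free_self_consistency(self):
        # near noise-free data simulated at the defaults: a fit started at
        # the truth stays at the truth (within optimizer tolerance)
        struct = dataclasses.replace(
            final_model("pyrazinamide"), reff=(("cl", "bsv"),),
            group_fold_on_bsv_cl=False)
        base = CohortSpec()
        spec = dataclasses.replace(base, groups={
            "outpatient": dataclasses.replace(
                base.groups["outpatient"], n=25,
                n_missing_height=0, n_missing_brc=0)})
        pop = dict(default_params("pyrazinamide"),
                   sigma_prop=0.02, sigma_add=0.05, omega_cl=0.15)
        trial = simulate_trial(struct, pop,
                               generate_cohort(spec, "pyrazinamide", 31), 32)
        model = PopPKModel(preprocess(trial.cohort), struct)
        res = model.fit(start=pop, fixed={"sigma_add"})
        assert res.converged
        for k in ("cl", "v"):
            assert res.params[k] == pytest.approx(pop[k], rel=0.05)
        # ka and mtt individually sit on a soft ridge at these sample times;
        # their identifiable combination is the mean absorption time
        from tbpopk.structural import mat

        assert mat(res.params["ka"], res.params["mtt"]) == pytest.approx(
            mat(pop["ka"], pop["mtt"]), rel=0.05)

    def test_fixed_parameters_stay_fixed(self, small_sim_study):
        model = PopPKModel(small_sim_study["cohort"], small_sim_study["struct"])
        pop = small_sim_study["pop"]
        res = model.fit(start=pop, fixed={"sigma_add", "ka", "mtt"}, maxiter=3)
        assert res.params["ka"] == pop["ka"]
        assert res.params["mtt"] == pop["mtt"]
        assert "ka" not in res.free_names


class TestLRT:
    def test_chi2_reference_values(self):
        assert lrt(103.84, 100.0, 1) == pytest.approx(0.05, abs=2e-3)
        assert lrt(116.1, 100.0, 2) < 0.001
        assert lrt(100.0, 100.0, 1) == 1.0

    def test_negative_dofv_warns_p_one(self):
        with pytest.warns(UserWarning):
            assert lrt(99.0, 100.0, 1) == 1.0


class TestMixture:
    def test_posteriors_sum_to_one_and_assignment(self, inh_fit):
        res, trial = inh_fit
        post = res.mixture_posteriors
        np.testing.assert_allclose(post["fast"] + post["slow"], 1.0)
        labels = mixture_assign(res)
        truth = trial.truth_subjects["component"].to_numpy()
        assert (labels == truth).mean() > 0.8

    def test_well_separated_subject_confident(self, inh_fit):
        res, trial = inh_fit
        post = res.mixture_posteriors
        conf = np.maximum(post["fast"], post["slow"])
        assert np.median(conf) > 0.9

    def test_p_fast_one_labels_everyone_fast(self, inh_fit):
        res, _ = inh_fit
        model = res.model
        post = model._mixture_posteriors({**res.params, "p_fast": 1.0 - 1e-12})
        assert (post["fast"] > 0.5).all()

    def test_prior_is_weakly_informative(self, inh_fit):
        # removing the Vratio penalty changes the objective by no more than
        # the penalty's own magnitude at the estimate
        res, _ = inh_fit
        model = res.model
        mode, sd = model.struct.vratio_prior
        penalty = ((np.log(res.params["vratio"]) - np.log(mode)) / sd) ** 2
        no_prior = dataclasses.replace(model.struct, vratio_prior=None)
        m2 = PopPKModel(model.cohort, no_prior)
        ofv_np = m2.objective(res.params, curvature="exact")
        assert abs(ofv_np - res.ofv) <= penalty + 1e-6


@pytest.fixture(scope="module")
def inh_fit():
    import dataclasses as dc

    base = CohortSpec()
    spec = dc.replace(base, groups={
        "outpatient": dc.replace(base.groups["outpatient"], n=40,
                                 n_missing_height=0, n_missing_brc=0)})
    struct = final_model("isoniazid")
    pop = default_params("isoniazid")
    trial = simulate_trial(struct, pop, generate_cohort(spec, "isoniazid", 51), 52)
    model = PopPKModel(preprocess(trial.cohort), struct)
    res = model.fit(start=pop, maxiter=8)
    return res, trial


class TestCovariateSearch:
    def test_empty_candidate_list_returns_base(self, small_sim_study):
        base_struct = final_model("rifampicin").without_effect("brc_on_cl")
        res, trace = covariate_search(
            small_sim_study["cohort"], base_struct, candidates=[])
        assert trace.empty
        assert not res.model.struct.brc_on_cl

    def test_planted_brc_effect_recovered_and_collinearity_rule(self):
        # simulate with the bilirubin effect on; total bilirubin is highly
        # correlated with it, so only one of the pair may enter
        base = CohortSpec()
        spec = dataclasses.replace(base, groups={
            g: dataclasses.replace(s, n=n, n_missing_height=0, n_missing_brc=0)
            for (g, s), n in zip(base.groups.items(), (60, 0, 0))})
        struct = final_model("rifampicin").without_effect("group_on_absorption")
        pop = default_params("rifampicin")
        trial = simulate_trial(struct, pop, generate_cohort(spec, "rifampicin", 61), 62)
        base_struct = struct.without_effect("brc_on_cl")
        res, trace = covariate_search(
            preprocess(trial.cohort), base_struct,
            candidates=["brc_on_cl", "brt_on_cl"],
            collinear=[("brc_on_cl", "brt_on_cl")],
            start=pop)
        final_effects = {e for e in ("brc_on_cl", "brt_on_cl")
                         if getattr(res.model.struct, e)}
        assert len(final_effects) <= 1
        included = trace[trace.action == "included"]["effect"].tolist()
        assert included, "the planted bilirubin signal should be picked up"
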
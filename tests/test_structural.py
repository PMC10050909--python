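"""Structural models: covariate transforms, individual parameters, kernels."""

import numpy as np
import pytest

from tbpopk.kernels import transit_conc, transit_conc_chain
from tbpopk.structural import (
    allometric_scale, brc_effect, default_params, final_model,
    group_absorption_effect, individual_params, mat, mat_percent_difference,
    theta_from_mat_percent, omega_diag,
)

RIF = default_params("rifampicin")


class TestCovariateTransforms:
    @pytest.mark.parametrize("typ,ffm,exp,expected", [
        (8.82, 43.0, 0.75, 8.82),          # reference identity
        (8.82, 86.0, 0.75, 14.83),         # clearance doubling of body size
        (56.8, 21.5, 1.0, 28.4),           # volume halving
    ])
    def test_allometric(self, typ, ffm, exp, expected):
        assert allometric_scale(typ, ffm, 43.0, exp) == pytest.approx(expected, abs=0.01)

    @pytest.mark.parametrize("brc,expected", [
        (6.0, 8.82), (12.0, 7.00), (3.0, 11.11),
    ])
    def test_brc_power(self, brc, expected):
        assert brc_effect(8.82, brc, 6.0, -0.333) == pytest.approx(expected, abs=0.01)

    def test_brc_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            brc_effect(8.82, 0.0, 6.0, -0.333)

    def test_group_absorption_effect_mat(self):
        # outpatients keep the typical parameters; hospitalized groups see
        # ka scaled by theta and MTT by 1/theta, so MAT scales by 1/theta
        ka, mtt = group_absorption_effect(1.38, 0.342, "outpatient", 0.667, 0.394)
        assert (ka, mtt) == (1.38, 0.342)
        assert mat(ka, mtt) == pytest.approx(1.07, abs=0.01)
        th_s = theta_from_mat_percent(49.9)
        ka_s, mtt_s = group_absorption_effect(1.38, 0.342, "hosp_survivor", th_s, 0.394)
        assert mat(ka_s, mtt_s) == pytest.approx(1.07 * 1.499, abs=0.01)
        assert mat_percent_difference(th_s) == pytest.approx(49.9)

    def test_theta_one_is_identity_for_any_group(self):
        for g in ("outpatient", "hosp_survivor", "hosp_death"):
            ka, mtt = group_absorption_effect(1.38, 0.342, g, 1.0, 1.0)
            assert (ka, mtt) == (1.38, 0.342)

    def test_unknown_group_rejected(self):
        with pytest.raises(KeyError):
            group_absorption_effect(1.38, 0.342, "icu", 0.7, 0.4)


class TestIndividualParams:
    cov = dict(ffm=np.array([43.0]), group_index=np.array([0]),
               brc=np.array([6.0]))
    occ = np.array([[0, 0, 1]])

    def test_zero_effects_reproduce_typical_values(self):
        struct = final_model("rifampicin")
        eta = np.zeros((1, struct.n_eta))
        ind = individual_params(struct, RIF, self.cov, eta, self.occ)
        assert ind["cl"][0] == pytest.approx(8.82)
        assert ind["v"][0] == pytest.approx(56.8)
        assert ind["ka"][0, 2] == pytest.approx(1.38)
        assert ind["mtt"][0, 2] == pytest.approx(0.342)
        assert ind["F"][0, 2] == 1.0

    def test_isoniazid_slow_component_clearance(self):
        struct = final_model("isoniazid")
        pop = default_params("isoniazid")
        eta = np.zeros((1, struct.n_eta))
        ind = individual_params(struct, pop, self.cov, eta, self.occ,
                                component="slow")
        assert ind["cl"][0] == pytest.approx(9.76)

    def test_pyrazinamide_group_bsv_magnitude(self):
        # SD of simulated log-CL in the hospitalized-death group approaches
        # omega x fold_death = 0.199 x 3.56 = 0.708
        struct = final_model("pyrazinamide")
        pop = default_params("pyrazinamide")
        n = 100_000
        rng = np.random.default_rng(7)
        om = omega_diag(struct, pop, np.full(n, 2))
        eta = rng.standard_normal((n, struct.n_eta)) * np.sqrt(om)
        i_cl = struct.eta_index("cl")
        assert np.std(eta[:, i_cl]) == pytest.approx(0.708, abs=0.01)
        om_s = omega_diag(struct, pop, np.full(1, 1))
        assert np.sqrt(om_s[0, i_cl]) == pytest.approx(0.338, abs=0.001)


class FakeDesign:
    def __init__(self, obs_time, dose_time, dose_amt, dose_occ, cov):
        self.obs_time, self.dose_time, self.dose_amt = obs_time, dose_time, dose_amt
        self.dose_occ, self.covariates = dose_occ, cov


class TestConcentrationKernels:
    obs = np.array([[0.0, 1.0, 2.5, 4.0, 6.0, 8.0]])
    dt = np.array([[-48.0, -24.0, 0.0]])
    da = np.array([[600.0, 600.0, 600.0]])
    ones = np.ones((1, 3))

    def _conc(self, use_numba, **kw):
        args = dict(F=self.ones, ka=np.full((1, 3), 1.38),
                    mtt=np.full((1, 3), 0.342), n_transit=12,
                    v=np.array([56.8]), cl=np.array([8.82]))
        args.update(kw)
        return transit_conc(self.obs, self.dt, self.da, use_numba=use_numba, **args)

    def test_zero_before_first_dose(self):
        c = transit_conc(np.array([[-50.0, -48.0]]), self.dt, self.da,
                         self.ones, np.full((1, 3), 1.38),
                         np.full((1, 3), 0.342), 12,
                         np.array([56.8]), np.array([8.82]))
        assert np.all(c == 0.0)

    @pytest.mark.parametrize("two_cpt", [False, True])
    def test_fast_path_matches_compartment_chain(self, two_cpt):
        # two independent solution techniques as mutual oracles, across a
        # wide random sweep of absorption parameters
        rng = np.random.default_rng(3)
        worst = 0.0
        for _ in range(25):
            ka = 1.38 * np.exp(rng.normal(0, 1.0))
            mtt = 0.342 * np.exp(rng.normal(0, 0.9))
            n = 8 if two_cpt else 12
            kw = dict(ka=np.full((1, 3), ka), mtt=np.full((1, 3), mtt), n_transit=n)
            ckw = {}
            if two_cpt:
                kw.update(q=np.array([1.43]), vratio=np.array([1.922]))
                ckw = dict(q=1.43, vratio=1.922)
            fast = self._conc(None, **kw)[0]
            ref = transit_conc_chain(self.obs[0], self.dt[0], self.da[0],
                                     1.0, ka, mtt, n, 56.8, 8.82, **ckw)
            sel = ref > 1e-8
            worst = max(worst, np.max(np.abs(fast[sel] - ref[sel]) / ref[sel]))
        assert worst < 0.005

    def test_numba_and_numpy_paths_agree(self):
        a = self._conc(True)
        b = self._conc(False)
        np.testing.assert_allclose(a, b, rtol=1e-10)

    def test_superposition(self):
        full = self._conc(None)
        parts = 0.0
        for k in range(3):
            da = np.zeros((1, 3))
            da[0, k] = 600.0
            parts = parts + transit_conc(
                self.obs, self.dt, da, self.ones, np.full((1, 3), 1.38),
                np.full((1, 3), 0.342), 12, np.array([56.8]), np.array([8.82]))
        np.testing.assert_allclose(full, parts, rtol=1e-12)

    def test_linearity_in_bioavailability(self):
        c1 = self._conc(None)
        c2 = self._conc(None, F=2 * self.ones)
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-12)

    def test_mass_conservation_auc(self):
        # total AUC after a single dose equals F*Dose/CL (all drug cleared)
        t = np.linspace(0, 400, 8001)[None, :]
        c = transit_conc(t, np.array([[0.0]]), np.array([[600.0]]),
                         np.ones((1, 1)), np.full((1, 1), 1.38),
                         np.full((1, 1), 0.342), 12,
                         np.array([56.8]), np.array([8.82]))
        auc = np.trapezoid(c[0], t[0])
        assert auc * 8.82 == pytest.approx(600.0, rel=1e-4)

    def test_mat_invariant_to_parameterization(self):
        # MAT = MTT + 1/ka regardless of how (ktr, ka) are realized: check
        # via the mean residence time of the absorption input, i.e. the
        # first-moment of a unit-dose profile minus the disposition MRT
        t = np.linspace(0, 400, 16001)[None, :]
        for ka, mtt in [(1.38, 0.342), (2.0, 0.6)]:
            c = transit_conc(t, np.array([[0.0]]), np.array([[1.0]]),
                             np.ones((1, 1)), np.full((1, 1), ka),
                             np.full((1, 1), mtt), 12,
                             np.array([56.8]), np.array([8.82]))[0]
            mrt = np.trapezoid(t[0] * c, t[0]) / np.trapezoid(c, t[0])
            ke = 8.82 / 56.8
            assert mrt - 1.0 / ke == pytest.approx(mat(ka, mtt), rel=1e-3)

    def test_rifampicin_collapses_without_covariate_effects(self):
        # beta=0 and theta=1 reduce the covariate model to the base model
        struct = final_model("rifampicin")
        pop = dict(RIF, beta_brc=0.0, theta_surv=1.0, theta_death=1.0)
        cov_h = dict(ffm=np.array([43.0]), group_index=np.array([2]),
                     brc=np.array([11.0]))
        eta = np.zeros((1, struct.n_eta))
        occ = np.array([[0, 0, 1]])
        ind = individual_params(struct, pop, cov_h, eta, occ)
        base = individual_params(struct.without_effect("brc_on_cl"),
                                 {k: v for k, v in RIF.items() if k != "beta_brc"},
                                 dict(cov_h, group_index=np.array([0])), eta, occ)
        assert ind["cl"][0] == base["cl"][0]
        np.testing.assert_array_equal(ind["ka"], base["ka"])
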
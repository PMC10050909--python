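"""Approximate marginal-likelihood estimation for the mixed-effects PK models.

The objective is -2x the Laplace-approximated marginal log-likelihood with
eta-epsilon interaction (FOCE-class): for every subject the joint density of
observations and random effects is maximized over the subject's log-scale
effects (one BSV eta on clearance plus per-occasion BOV kappas on
bioavailability, ka and MTT) with a damped Gauss-Newton scheme that runs
vectorized across all subjects, and the curvature term uses the expected
("interaction") information  J' W J + Omega^-1  with
W = 1/sigma^2 + 2 sigma_prop^4 f^2 / sigma^4.

Mixture subjects (isoniazid) contribute log sum_c p_c L_i|c with the inner
problem solved per component; the Vratio penalty prior adds
((log Vr - log mode)/sd)^2 to the objective.

The outer problem optimizes the population parameters on a transformed
scale (log for positive parameters, logit for the mixture fraction) with
L-BFGS-B.  Outer gradients are forward finite differences of the objective
reassembled around the cached conditional modes: each direction re-predicts
at the perturbed values, maps the induced inner-gradient change through the
cached exact inner Hessians to a first-order mode response, and
re-linearizes there -- capturing both the envelope term and the
mode-coupling of the Laplace curvature term at about two population
predictions per parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import Cohort, preprocess
from .structural import StructuralModel, default_params, omega_diag, predict_conc
from .results import PopPKResults

__all__ = [
    "CohortDesign",
    "PopPKModel",
    "lrt",
    "covariate_search",
    "mixture_assign",
]

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# compiled design
# ---------------------------------------------------------------------------

@dataclass
class CohortDesign:
    """Padded-array view of a preprocessed cohort, ready for vectorized math."""

    subject_ids: list
    obs_time: np.ndarray   # (N, J), NaN padded
    y: np.ndarray          # (N, J)
    obs_mask: np.ndarray   # (N, J) bool
    dose_time: np.ndarray  # (N, D), NaN padded
    dose_amt: np.ndarray   # (N, D), NaN padded
    dose_occ: np.ndarray   # (N, D) int, zero-based
    covariates: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return self.obs_time.shape[0]

    @property
    def n_obs(self) -> int:
        return int(self.obs_mask.sum())

    @classmethod
    def from_cohort(cls, cohort: Cohort, n_occasions: int = 2,
                    require_values: bool = True) -> "CohortDesign":
        subs = cohort.subjects
        if not subs:
            raise ValueError("empty cohort")

        def usable(o):
            return o.in_likelihood if require_values else o.status != "dropped"

        jmax = max(sum(usable(o) for o in s.observations) for s in subs)
        dmax = max(len(s.doses) for s in subs)
        n = len(subs)
        obs_time = np.full((n, jmax), np.nan)
        y = np.zeros((n, jmax))
        mask = np.zeros((n, jmax), bool)
        dose_time = np.full((n, dmax), np.nan)
        dose_amt = np.full((n, dmax), np.nan)
        dose_occ = np.zeros((n, dmax), int)
        ffm = np.empty(n)
        brc = np.empty(n)
        gidx = np.empty(n, int)
        groups = {"outpatient": 0, "hosp_survivor": 1, "hosp_death": 2}
        fast = np.full(n, -1)
        brt = np.empty(n)
        for i, s in enumerate(subs):
            if not s.doses or not any(usable(o) for o in s.observations):
                raise ValueError(
                    f"subject {s.subject_id}: needs >=1 dose and >=1 usable observation"
                )
            obs = [o for o in s.observations if usable(o)]
            obs_time[i, : len(obs)] = [o.time for o in obs]
            y[i, : len(obs)] = [np.nan if o.value is None else o.value for o in obs]
            mask[i, : len(obs)] = True
            for k, d in enumerate(s.doses):
                dose_time[i, k] = d.time
                dose_amt[i, k] = d.amount
                occ = 1 if d.occasion is None else d.occasion
                dose_occ[i, k] = min(occ, n_occasions) - 1
            ffm[i] = s.ffm
            brc[i] = np.nan if s.conjugated_bilirubin is None else s.conjugated_bilirubin
            brt[i] = np.nan if s.total_bilirubin is None else s.total_bilirubin
            gidx[i] = groups[s.group]
            if getattr(s, "nat2_fast", None) is not None:
                fast[i] = int(s.nat2_fast)
        cov = dict(ffm=ffm, brc=brc, brt=brt, group_index=gidx, nat2_fast=fast)
        return cls(
            subject_ids=[s.subject_id for s in subs],
            obs_time=obs_time, y=y, obs_mask=mask,
            dose_time=dose_time, dose_amt=dose_amt, dose_occ=dose_occ,
            covariates=cov,
        )


# ---------------------------------------------------------------------------
# parameter transforms
# ---------------------------------------------------------------------------

_LOGIT_PARAMS = {"p_fast"}
_IDENTITY_PARAMS = {"beta_brc", "beta_brt"}


def _to_x(pop: dict, names) -> np.ndarray:
    x = np.empty(len(names))
    for k, nm in enumerate(names):
        v = pop[nm]
        if nm in _IDENTITY_PARAMS:
            x[k] = v
        elif nm in _LOGIT_PARAMS:
            x[k] = np.log(v / (1.0 - v))
        else:
            x[k] = np.log(v)
    return x


def _to_pop(x, names, base: dict) -> dict:
    pop = dict(base)
    for k, nm in enumerate(names):
        if nm in _IDENTITY_PARAMS:
            pop[nm] = x[k]
        elif nm in _LOGIT_PARAMS:
            pop[nm] = 1.0 / (1.0 + np.exp(-x[k]))
        else:
            pop[nm] = np.exp(x[k])
    return pop


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class PopPKModel:
    """Nonlinear mixed-effects population PK model bound to one cohort.

    Parameters
    ----------
    cohort : Cohort
        Preprocessed (occasions assigned, M6 applied) unless
        ``preprocess=True``, in which case the standard pipeline is run.
    structure : StructuralModel, optional
        Defaults to the drug's final model configuration.

    Examples
    --------
    >>> model = PopPKModel(cohort)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    #: convergence tolerance (inf-norm of the per-subject gradient of q) --
    #: tight, because the outer gradient re-uses the conditional modes
    inner_gtol = 1e-4
    inner_maxiter = 40

    def __init__(self, cohort: Cohort, structure: StructuralModel | None = None,
                 run_preprocess: bool = False):
        from .structural import final_model

        if run_preprocess:
            cohort = preprocess(cohort)
        self.cohort = cohort
        self.struct = structure if structure is not None else final_model(cohort.drug)
        self.design = CohortDesign.from_cohort(cohort, self.struct.n_occasions)
        if self.struct.brc_on_cl and np.isnan(self.design.covariates["brc"]).any():
            raise ValueError("missing conjugated bilirubin: impute before fitting")
        if self.struct.brt_on_cl and np.isnan(self.design.covariates["brt"]).any():
            raise ValueError("missing total bilirubin in cohort")
        self._components = ("fast", "slow") if self.struct.mixture_on_cl else (None,)
        self._eta_cache = {
            c: np.zeros((self.design.n_subjects, self.struct.n_eta))
            for c in self._components
        }
        self._hess_cache: dict = {}
        self._lin_cache: dict = {}
        self.n_obj_evals = 0

    # -- likelihood machinery ------------------------------------------------

    def _subset(self, idx):
        d = self.design
        return CohortDesign(
            subject_ids=[d.subject_ids[i] for i in idx],
            obs_time=d.obs_time[idx], y=d.y[idx], obs_mask=d.obs_mask[idx],
            dose_time=d.dose_time[idx], dose_amt=d.dose_amt[idx],
            dose_occ=d.dose_occ[idx],
            covariates={k: v[idx] for k, v in d.covariates.items()},
        )

    def _predict(self, pop, eta, component, design=None):
        design = self.design if design is None else design
        return predict_conc(self.struct, pop, design, eta, component=component)

    def _sigma2(self, pop, f):
        return pop["sigma_add"] ** 2 + (pop["sigma_prop"] * f) ** 2

    def _q_value(self, pop, f, eta, om_diag, design=None):
        """-2 log joint density of (y, eta), per subject.  f: (..., N, J).

        Overflow to inf is expected during line-search excursions and is
        rejected by the callers, so the numerics run warning-free."""
        design = self.design if design is None else design
        m = design.obs_mask
        with np.errstate(all="ignore"):
            r = np.where(m, design.y - f, 0.0)
            s2 = self._sigma2(pop, f)
            lik = np.where(m, r * r / s2 + np.log(2.0 * np.pi * s2), 0.0).sum(axis=-1)
            pri = (eta * eta / om_diag).sum(axis=-1) + np.log(
                2.0 * np.pi * om_diag).sum(axis=-1)
        return lik + pri

    def _linearize(self, pop, component, eta, design):
        """f and the eta-Jacobian of f by forward differences (batched)."""
        d = self.struct.n_eta
        h = 1e-4
        eye = np.eye(d) * h
        batch = np.concatenate([eta[None], eta[None] + eye[:, None, :]], axis=0)
        fb = self._predict(pop, batch, component, design)
        f = fb[0]
        J = np.moveaxis((fb[1:] - f) / h, 0, -1)  # (N, J, d)
        return f, J

    def _grad_hess(self, pop, design, f, J, eta, om):
        """Analytic eta-gradient of q and its expected-information Hessian/2."""
        d = self.struct.n_eta
        m = design.obs_mask
        with np.errstate(all="ignore"):
            r = np.where(m, design.y - f, 0.0)
            s2 = self._sigma2(pop, f)
            sp2 = pop["sigma_prop"] ** 2
            w_grad = np.where(
                m, -2.0 * r / s2 + 2.0 * sp2 * f * (1.0 / s2 - r * r / (s2 * s2)), 0.0)
            grad = np.einsum("nj,njd->nd", w_grad, J) + 2.0 * eta / om
            w_half = np.where(m, 1.0 / s2 + 2.0 * sp2 * sp2 * f * f / (s2 * s2), 0.0)
            H = np.einsum("njd,nj,nje->nde", J, w_half, J)
            H[:, np.arange(d), np.arange(d)] += 1.0 / om
        return grad, H

    def _line_search(self, pop, component, eta, q, step, idx, om_full):
        """Vectorized backtracking on the subjects in ``idx`` (in place).

        Returns the boolean acceptance mask."""
        sub = self._subset(idx)
        om = om_full[idx]
        alpha = np.ones((len(idx), 1))
        improved = np.zeros(len(idx), bool)
        q_new = q[idx].copy()
        eta_new = eta[idx].copy()
        for _ in range(8):
            trial = np.where(improved[:, None], eta_new,
                             np.clip(eta[idx] + alpha * step, -15.0, 15.0))
            q_trial = self._q_value(
                pop, self._predict(pop, trial, component, sub), trial, om, sub)
            better = (q_trial < q_new) & ~improved
            eta_new = np.where(better[:, None], trial, eta_new)
            q_new = np.where(better, q_trial, q_new)
            improved |= better
            if improved.all():
                break
            alpha = np.where(improved[:, None], alpha, alpha * 0.5)
        eta[idx] = eta_new
        q[idx] = q_new
        return improved

    def _exact_hessian(self, pop, component, eta, design, om):
        """Per-subject Hessian of q by forward differences of the analytic
        gradient (one batched prediction over all (k,l) perturbation pairs)."""
        d = self.struct.n_eta
        h = 1e-4
        eye = np.eye(d) * h
        # grid of eta + h e_k + h e_l for k,l in {0..d} (0 = no perturbation)
        shift = np.concatenate([np.zeros((1, d)), eye], axis=0)      # (d+1, d)
        E = eta[None, None] + shift[:, None, None, :] + shift[None, :, None, :]
        B = E.reshape((d + 1) * (d + 1), -1, d)
        fb = self._predict(pop, B, component, design)
        fb = fb.reshape(d + 1, d + 1, *fb.shape[1:])                 # (k, l, N, J)
        grads = []
        for k in range(d + 1):
            f_k = fb[k, 0]
            J_k = np.moveaxis((fb[k, 1:] - f_k) / h, 0, -1)
            g_k, _ = self._grad_hess(pop, design, f_k, J_k,
                                     eta + shift[k][None, :], om)
            grads.append(g_k)
        H = np.stack([(grads[k + 1] - grads[0]) / h for k in range(d)], axis=1)
        H = 0.5 * (H + np.swapaxes(H, 1, 2)) / 2.0  # Hessian of q/2
        return H

    def _inner_solve(self, pop, component, eta0, maxiter=None):
        """Per-subject mode finding, vectorized with an active set.

        Phase 1: damped Gauss-Newton with the expected-information curvature
        across all unconverged subjects at once (cheap, good global
        behaviour).  Phase 2: Newton polish with the exact finite-difference
        Hessian (cached and re-used across calls) for the subjects the
        Gauss-Newton direction converges slowly on -- the curvature of the
        strongly nonlinear absorption effects is poorly matched by the
        Gauss-Newton approximation.  Returns (eta, f, J, q, om).
        """
        n = self.design.n_subjects
        d = self.struct.n_eta
        om_full = omega_diag(self.struct, pop, self.design.covariates["group_index"])
        maxiter = self.inner_maxiter if maxiter is None else maxiter
        eta = eta0.copy()
        if d == 0:  # no random effects: the "inner problem" is empty
            f = self._predict(pop, eta, component)
            q = self._q_value(pop, f, eta, om_full)
            J = np.zeros((n,) + f.shape[-1:] + (0,))
            return eta, f, J, q, om_full
        q = self._q_value(pop, self._predict(pop, eta, component), eta, om_full)
        if np.any(eta):
            # guard against stale warm starts trapped in poor local modes:
            # fall back to the prior center wherever it beats the cache
            q0 = self._q_value(pop, self._predict(pop, np.zeros_like(eta),
                                                  component),
                               np.zeros_like(eta), om_full)
            use0 = ~(q <= q0)
            if use0.any():
                eta[use0] = 0.0
                q[use0] = q0[use0]
        cache = self._hess_cache.setdefault(
            component, {"H": np.zeros((n, d, d)),
                        "valid": np.zeros(n, bool)})
        grad_norm = np.full(n, np.inf)
        stall = np.zeros(n, int)
        refreshed = np.zeros(n, bool)  # exact Hessian computed at this theta
        active = np.arange(n)
        f = J = None
        moved = False
        for it in range(maxiter):
            sub = self._subset(active) if len(active) < n else self.design
            f_a, J_a = self._linearize(pop, component, eta[active], sub)
            grad, H_gn = self._grad_hess(pop, sub, f_a, J_a, eta[active],
                                         om_full[active])
            grad_norm[active] = np.abs(grad).max(axis=1)
            if it == 0 and len(active) == n:
                f, J = f_a, J_a
            todo = grad_norm[active] >= self.inner_gtol
            if not todo.any():
                break
            idx_t = active[todo]
            grad = grad[todo]
            H = H_gn[todo]
            # exact curvature where the expected-information direction has
            # been struggling (refreshed via batched FD of the gradient)
            refresh = (stall[idx_t] >= 2) & ~refreshed[idx_t]
            if refresh.any():
                ridx = idx_t[refresh]
                cache["H"][ridx] = self._exact_hessian(
                    pop, component, eta[ridx], self._subset(ridx),
                    om_full[ridx])
                cache["valid"][ridx] = True
                refreshed[ridx] = True
                stall[ridx] = 0
            use_exact = cache["valid"][idx_t]
            if use_exact.any():
                He = cache["H"][idx_t[use_exact]].copy()
                ok = np.all(np.linalg.eigvalsh(He) > 1e-8, axis=-1)
                He[~ok] = H[use_exact][~ok]
                H[use_exact] = He
            step = self._solve_spd(H, -0.5 * grad)
            # trust-region cap: near-singular curvature can propose absurd steps
            norm = np.abs(step).max(axis=1, keepdims=True)
            step = step * np.minimum(1.0, 2.0 / np.maximum(norm, 1e-300))
            improved = self._line_search(pop, component, eta, q, step, idx_t,
                                         om_full)
            if not improved.all():
                # fall back to a short steepest-descent move where the
                # (quasi-)Newton direction failed
                fail = ~improved
                gd = -grad[fail]
                gd = gd * (0.25 / np.maximum(np.abs(gd).max(axis=1, keepdims=True),
                                             1e-300))
                improved2 = self._line_search(pop, component, eta, q, gd,
                                              idx_t[fail], om_full)
                improved = improved.copy()
                improved[np.flatnonzero(fail)[improved2]] = True
            stall[idx_t[~improved]] += 2
            stall[idx_t[improved]] += 1
            if improved.any():
                moved = True
                refreshed[idx_t[improved]] = False  # mode moved: allow re-refresh
            elif refreshed[idx_t].all():
                break  # freshly computed curvature and still stuck: at the floor
            active = idx_t
        if moved or f is None:
            f, J = self._linearize(pop, component, eta, self.design)
            q = self._q_value(pop, f, eta, om_full)
        return eta, f, J, q, om_full

    @staticmethod
    def _solve_spd(H, b):
        try:
            return np.linalg.solve(H, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            d = H.shape[-1]
            H = H.copy()
            H[..., np.arange(d), np.arange(d)] += 1e-6
            return np.linalg.solve(H, b[..., None])[..., 0]

    def _laplace_terms(self, pop, f, J, eta, q, om, H_exact=None):
        """Per-subject -2 log L_i from cached linearization pieces.

        The curvature term defaults to the expected ("interaction")
        information J'WJ + Omega^-1; pass ``H_exact`` to use the exact
        finite-difference Hessian of q/2 instead (full Laplace)."""
        d = self.struct.n_eta
        m = self.design.obs_mask
        s2 = self._sigma2(pop, f)
        sp2 = pop["sigma_prop"] ** 2
        with np.errstate(all="ignore"):
            w_half = np.where(m, 1.0 / s2 + 2.0 * sp2 * sp2 * f * f / (s2 * s2), 0.0)
            H = np.einsum("njd,nj,nje->nde", J, w_half, J)
            H[:, np.arange(d), np.arange(d)] += 1.0 / om
        if H_exact is not None:
            ok = np.all(np.linalg.eigvalsh(
                np.where(np.isfinite(H_exact), H_exact, 0.0)) > 1e-10, axis=-1)
            H = np.where(ok[:, None, None], H_exact, H)
        sign, logdet = np.linalg.slogdet(H)
        if np.any(sign <= 0):
            logdet = np.where(sign <= 0, 1e6, logdet)
        return q + logdet - d * _LOG2PI

    def _reassemble(self, pop, component, f=None, J=None):
        """Per-subject -2 log L_i at population values ``pop``, re-using the
        cached conditional modes of the last full solve.

        The modes are stationary points of q, so holding them fixed is exact
        to first order (envelope property); predictions and Jacobians are
        re-evaluated when supplied."""
        eta, f0, J0 = self._lin_cache[component]
        if f is None:
            f = f0
        if J is None:
            J = J0
        om = omega_diag(self.struct, pop, self.design.covariates["group_index"])
        q = self._q_value(pop, f, eta, om)
        return self._laplace_terms(pop, f, J, eta, q, om)

    def _combine(self, pop, minus2ll: dict) -> float:
        """Mixture combination across components plus penalty priors."""
        if self.struct.mixture_on_cl:
            p = pop["p_fast"]
            a = np.stack([
                np.log(p) - 0.5 * minus2ll["fast"],
                np.log1p(-p) - 0.5 * minus2ll["slow"],
            ])
            amax = a.max(axis=0)
            total = -2.0 * (amax + np.log(np.exp(a - amax).sum(axis=0)))
        else:
            total = minus2ll[None]
        ofv = float(total.sum())
        if self.struct.vratio_prior is not None:
            mode, sd = self.struct.vratio_prior
            ofv += ((np.log(pop["vratio"]) - np.log(mode)) / sd) ** 2
        return ofv

    def objective(self, pop: dict, maxiter=None, curvature: str = "expected") -> float:
        """-2x approximate marginal log-likelihood at population values ``pop``.

        ``curvature="expected"`` (default) uses the FOCE-style expected
        information in the Laplace determinant -- cheap and smooth, used
        throughout the optimization.  ``curvature="exact"`` substitutes the
        exact per-subject Hessian (full Laplace); reported objective values
        (fit results, likelihood-ratio comparisons) use this mode."""
        self.n_obj_evals += 1
        m2ll = {}
        for c in self._components:
            eta, f, J, q, om = self._inner_solve(
                pop, c, self._eta_cache[c], maxiter=maxiter
            )
            self._eta_cache[c] = eta
            self._lin_cache[c] = (eta, f, J)
            H_exact = None
            if curvature == "exact" and self.struct.n_eta:
                H_exact = self._exact_hessian(pop, c, eta, self.design, om)
            m2ll[c] = self._laplace_terms(pop, f, J, eta, q, om, H_exact=H_exact)
        ofv = self._combine(pop, m2ll)
        if not np.isfinite(ofv):
            warnings.warn("non-finite objective; returning large penalty")
            return 1e10
        return ofv

    #: population parameters that enter the structural predictions (the
    #: rest touch only variances, mixture weights or the residual model)
    _PREDICTION_PARAMS = frozenset({
        "cl", "cl_fast", "cl_slow", "v", "q", "vratio", "ka", "mtt",
        "theta_surv", "theta_death", "beta_brc", "beta_brt",
    })

    def gradient(self, x, names, base) -> np.ndarray:
        """Outer gradient by forward differences of the profiled objective.

        Re-solving every subject's conditional mode per direction would be
        far too expensive, so each perturbed objective is assembled from the
        cached modes plus their first-order response: the perturbation's
        pull on the inner gradient is computed at the cached mode and mapped
        through the cached inner curvature,
        ``delta_eta = -H^{-1} grad_eta(theta+h)``, and the objective is then
        re-linearized at the shifted modes.  This tracks both the envelope
        (q) part and the mode coupling of the Laplace curvature term, which
        is far from negligible here because the clearance and absorption
        fixed effects are strongly aliased with their random effects."""
        h = 1e-4
        pop0 = _to_pop(x, names, base)
        gidx = self.design.covariates["group_index"]
        pieces = {}
        m2_0 = {}
        for c in self._components:
            eta, f0, J0 = self._lin_cache[c]
            if not (np.isfinite(eta).all() and np.isfinite(f0).all()):
                return np.zeros(len(x))  # penalty region: direction is moot
            om0 = omega_diag(self.struct, pop0, gidx)
            # exact curvature so the mode response delta_eta is reliable even
            # where the expected-information approximation is poor
            H0 = self._exact_hessian(pop0, c, eta, self.design, om0)
            grad0, H_gn = self._grad_hess(pop0, self.design, f0, J0, eta, om0)
            H0 = np.where(np.isfinite(H0), H0, H_gn)
            try:
                bad = ~np.all(np.linalg.eigvalsh(H0) > 1e-8, axis=-1)
            except np.linalg.LinAlgError:
                bad = np.ones(H0.shape[0], bool)
            if bad.any():
                H0[bad] = H_gn[bad]
            q0 = self._q_value(pop0, f0, eta, om0)
            pieces[c] = (eta, f0, J0, om0, H0, grad0)
            m2_0[c] = self._laplace_terms(pop0, f0, J0, eta, q0, om0)
        ofv0 = self._combine(pop0, m2_0)
        g = np.empty(len(x))
        for k, nm in enumerate(names):
            xk = x.copy()
            xk[k] += h
            popk = _to_pop(xk, names, base)
            m2 = {}
            for c in self._components:
                eta, f0, J0, om0, H0, grad0 = pieces[c]
                if nm == "p_fast":  # mixture weight only: no mode response
                    m2[c] = m2_0[c]
                    continue
                if nm in self._PREDICTION_PARAMS:
                    fk, Jk = self._linearize(popk, c, eta, self.design)
                else:
                    fk, Jk = f0, J0
                omk = omega_diag(self.struct, popk, gidx)
                gradk, _ = self._grad_hess(popk, self.design, fk, Jk, eta, omk)
                # mode response to the perturbation alone: subtracting the
                # base residual gradient keeps delta O(h) even where the
                # inner solve stopped at its numerical floor
                delta = self._solve_spd(H0, -0.5 * (gradk - grad0))
                eta_k = eta + np.clip(delta, -0.5, 0.5)
                fk2, Jk2 = self._linearize(popk, c, eta_k, self.design)
                qk = self._q_value(popk, fk2, eta_k, omk)
                m2[c] = self._laplace_terms(popk, fk2, Jk2, eta_k, qk, omk)
            g[k] = (self._combine(popk, m2) - ofv0) / h
        return g

    # -- outer optimization --------------------------------------------------

    def _default_fixed(self):
        fixed = set()
        if self.struct.drug in ("rifampicin", "isoniazid"):
            fixed.add("sigma_add")  # held at its 20%-of-LLOQ floor
        return fixed

    def fit(self, start: dict | None = None, fixed=None, maxiter: int = 200,
            gtol: float = 0.15, compute_uncertainty: bool = False,
            verbose: bool = False) -> PopPKResults:
        """Estimate the population parameters by L-BFGS-B on the Laplace OFV.

        Parameters
        ----------
        start : dict, optional
            Initial population parameter values; defaults to the drug's
            default parameter set.
        fixed : iterable of parameter names held at their starting values.
            Defaults to the additive error when it sits at its floor
            (rifampicin, isoniazid).  Bioavailability (F=1) and the transit
            chain length are structural constants, never estimated.
        compute_uncertainty : bool
            If True, invert a finite-difference Hessian of the objective for
            asymptotic standard errors (bootstrap is the primary CI route).
        """
        start = dict(default_params(self.struct.drug), **(start or {}))
        fixed = self._default_fixed() if fixed is None else set(fixed)
        names = [p for p in self.struct.free_parameters() if p not in fixed]
        x0 = _to_x(start, names)

        floor = 0.2 * self.struct.lloq
        bounds = []
        for nm, x in zip(names, x0):
            if nm in _IDENTITY_PARAMS:
                bounds.append((-3.0, 3.0))
            elif nm in _LOGIT_PARAMS:
                bounds.append((-5.0, 5.0))
            elif nm == "sigma_add":
                bounds.append((np.log(floor), x + 4.0))
            elif nm.startswith(("omega_", "bov_", "fold_")):
                # variability SDs capped at 300% (log scale): wide but finite
                bounds.append((np.log(0.01), np.log(3.0)))
            elif nm == "sigma_prop":
                bounds.append((np.log(0.005), np.log(1.0)))
            else:
                bounds.append((x - 2.0, x + 2.0))

        trace = []
        # Reference-cache strategy: every objective evaluation warm-starts
        # the inner problems from the modes of the best point found so far,
        # never from the previous (possibly rejected) line-search trial.
        # This keeps the profiled objective a deterministic, locally smooth
        # function of x; free-running continuation makes line searches see
        # mode-continuation noise of the same order as the achievable
        # descent and stalls the optimizer.
        ref_cache = {c: self._eta_cache[c].copy() for c in self._components}
        best = {"val": np.inf}

        def fun(x):
            pop = _to_pop(x, names, start)
            for c in self._components:
                self._eta_cache[c] = ref_cache[c].copy()
            val = self.objective(pop)
            if val < best["val"]:
                best["val"] = val
                for c in self._components:
                    ref_cache[c] = self._eta_cache[c].copy()
            trace.append(val)
            return val

        def grad(x):
            return self.gradient(x, names, start)

        # Optimize on a rescaled axis so L-BFGS-B's unit-length first trial
        # step corresponds to a ~0.15 log-unit parameter move; a full e-fold
        # jump overshoots the narrow likelihood valley and derails the line
        # search before the quasi-Newton metric is built.
        scale = 0.15
        res = optimize.minimize(
            lambda y: fun(y * scale), x0 / scale,
            jac=lambda y: scale * grad(y * scale),
            method="L-BFGS-B", bounds=[(lo / scale, hi / scale) for lo, hi in bounds],
            options=dict(maxiter=maxiter, ftol=1e-9, gtol=gtol * scale),
        )
        pop_hat = _to_pop(res.x * scale, names, start)
        # report the full-Laplace (exact-curvature) objective at the optimum
        ofv = self.objective(pop_hat, curvature="exact")

        eta_hat = {c: self._eta_cache[c].copy() for c in self._components}
        posteriors = self._mixture_posteriors(pop_hat)

        se = None
        if compute_uncertainty:
            from statsmodels.tools.numdiff import approx_hess1

            hess = approx_hess1(res.x, fun, epsilon=1e-4)
            try:
                cov_x = 2.0 * np.linalg.inv(hess)
                se_x = np.sqrt(np.maximum(np.diag(cov_x), 0.0))
                se = {nm: self._delta_se(nm, pop_hat[nm], s)
                      for nm, s in zip(names, se_x)}
            except np.linalg.LinAlgError:
                se = None

        return PopPKResults(
            model=self, params=pop_hat, ofv=ofv, free_names=names,
            converged=bool(res.success), n_outer_iter=int(res.nit),
            message=str(res.message), eta=eta_hat, mixture_posteriors=posteriors,
            se=se, ofv_trace=trace,
        )

    @staticmethod
    def _delta_se(name, value, se_x):
        if name in _IDENTITY_PARAMS:
            return se_x
        if name in _LOGIT_PARAMS:
            return se_x * value * (1.0 - value)
        return se_x * value  # log-scale delta method

    def _mixture_posteriors(self, pop):
        if not self.struct.mixture_on_cl:
            return None
        m2ll = {
            c: self._laplace_terms(pop, *self._final_pieces(pop, c))
            for c in self._components
        }
        p = pop["p_fast"]
        lf = np.log(p) - 0.5 * m2ll["fast"]
        ls = np.log1p(-p) - 0.5 * m2ll["slow"]
        mx = np.maximum(lf, ls)
        pf = np.exp(lf - mx) / (np.exp(lf - mx) + np.exp(ls - mx))
        return pd.DataFrame(
            {"subject_id": self.design.subject_ids, "fast": pf, "slow": 1.0 - pf}
        )

    def _final_pieces(self, pop, component):
        eta, f, J, q, om = self._inner_solve(pop, component,
                                             self._eta_cache[component])
        return f, J, eta, q, om

    # -- quadrature cross-check ----------------------------------------------

    def objective_agq(self, pop: dict, n_nodes: int = 5) -> float:
        """Adaptive Gauss-Hermite quadrature objective (slow reference).

        Centers a product GH rule of ``n_nodes`` per dimension on each
        subject's conditional mode, scaled by the inverse square-root
        curvature.  Intended for small cohorts / reduced random-effect
        structures as an independent check on the Laplace approximation.
        """
        d = self.struct.n_eta
        z, w = np.polynomial.hermite.hermgauss(n_nodes)
        grids = np.meshgrid(*([z] * d), indexing="ij")
        Z = np.stack([g.ravel() for g in grids], axis=-1)      # (K, d)
        logw = np.log(np.prod(np.meshgrid(*([w] * d), indexing="ij"), axis=0)).ravel()
        m2ll = {}
        for c in self._components:
            eta, f, J, q, om = self._inner_solve(pop, c, self._eta_cache[c])
            m = self.design.obs_mask
            s2 = self._sigma2(pop, f)
            sp2 = pop["sigma_prop"] ** 2
            w_half = np.where(m, 1.0 / s2 + 2.0 * sp2 * sp2 * f * f / (s2 * s2), 0.0)
            H = np.einsum("njd,nj,nje->nde", J, w_half, J)
            H[:, np.arange(d), np.arange(d)] += 1.0 / om
            L = np.linalg.cholesky(H)
            # eta_k = eta_hat + sqrt(2) L^-T z_k
            steps = np.sqrt(2.0) * np.linalg.solve(
                np.swapaxes(L, -1, -2)[:, None], Z[None, :, :, None]
            )[..., 0]                                           # (N, K, d)
            etas = eta[:, None, :] + steps
            fK = self._predict(pop, np.swapaxes(etas, 0, 1), c)  # (K, N, J)
            qK = self._q_value(pop, fK, np.swapaxes(etas, 0, 1), om)  # (K, N)
            zz = (Z * Z).sum(axis=-1)
            _, logdetH = np.linalg.slogdet(H)
            logint = (
                logw[:, None] + zz[:, None] - 0.5 * qK
                + 0.5 * d * np.log(2.0) - 0.5 * logdetH[None]
            )
            mx = logint.max(axis=0)
            m2ll[c] = -2.0 * (mx + np.log(np.exp(logint - mx).sum(axis=0)))
        return self._combine(pop, m2ll)


# ---------------------------------------------------------------------------
# likelihood-ratio testing and covariate search
# ---------------------------------------------------------------------------

def lrt(ofv_reduced: float, ofv_full: float, df: int) -> float:
    """p-value of the likelihood-ratio test between nested fits."""
    dofv = ofv_reduced - ofv_full
    if dofv < 0:
        warnings.warn("full model has higher OFV than reduced; returning p=1")
        return 1.0
    return float(stats.chi2.sf(dofv, df))


_EFFECT_DF = {"brc_on_cl": 1, "brt_on_cl": 1, "group_on_absorption": 2,
              "group_fold_on_bsv_cl": 2}
_EFFECT_NULL = {
    "brc_on_cl": {"beta_brc": 0.0},
    "brt_on_cl": {"beta_brt": 0.0},
    "group_on_absorption": {"theta_surv": 1.0, "theta_death": 1.0},
    "group_fold_on_bsv_cl": {"fold_surv": 1.0, "fold_death": 1.0},
}


def covariate_search(cohort: Cohort, base_structure: StructuralModel,
                     candidates, start=None, p_include=0.05, p_retain=0.01,
                     collinear=(), verbose=False):
    """Stepwise forward-inclusion / backward-elimination covariate search.

    ``candidates`` are structural effect names (keys of the model's effect
    flags).  ``collinear`` lists groups of mutually collinear candidates; in
    each forward round only the best-dOFV member of a collinear group is
    eligible for inclusion, mirroring the usual practice of keeping one of a
    correlated covariate pair.

    Returns (final_results, trace) where trace is a DataFrame logging each
    tested step with its dOFV, df and p-value.
    """
    def fit_struct(struct, init):
        return PopPKModel(cohort, struct).fit(start=init)

    struct = base_structure
    included: list[str] = []
    rows = []
    current = fit_struct(struct, start)
    # forward
    while True:
        trials = []
        for cand in candidates:
            if cand in included:
                continue
            init = dict(current.params)
            init.update(_EFFECT_NULL[cand])
            res = fit_struct(struct.with_effect(cand), init)
            dofv = current.ofv - res.ofv
            p = lrt(current.ofv, res.ofv, _EFFECT_DF[cand])
            trials.append((cand, res, dofv, p))
            rows.append(dict(step="forward", effect=cand, dofv=dofv,
                             df=_EFFECT_DF[cand], p=p, action="tested"))
        if not trials:
            break
        # collinearity: keep only the strongest member of each group eligible
        eligible = {c for c, *_ in trials}
        for group in collinear:
            members = [t for t in trials if t[0] in group]
            if len(members) > 1:
                best = max(members, key=lambda t: t[2])
                for t in members:
                    if t[0] != best[0]:
                        eligible.discard(t[0])
        trials = [t for t in trials if t[0] in eligible and t[3] < p_include]
        if not trials:
            break
        cand, res, dofv, p = max(trials, key=lambda t: t[2])
        struct = struct.with_effect(cand)
        included.append(cand)
        current = res
        rows.append(dict(step="forward", effect=cand, dofv=dofv,
                         df=_EFFECT_DF[cand], p=p, action="included"))
    # backward
    changed = True
    while changed:
        changed = False
        for cand in list(included):
            reduced_struct = struct.without_effect(cand)
            init = {k: v for k, v in current.params.items()}
            res = fit_struct(reduced_struct, init)
            dofv = res.ofv - current.ofv
            p = lrt(res.ofv, current.ofv, _EFFECT_DF[cand])
            keep = p < p_retain
            rows.append(dict(step="backward", effect=cand, dofv=dofv,
                             df=_EFFECT_DF[cand], p=p,
                             action="retained" if keep else "removed"))
            if not keep:
                struct = reduced_struct
                included.remove(cand)
                current = res
                changed = True
    return current, pd.DataFrame(rows)


def mixture_assign(results: PopPKResults) -> np.ndarray:
    """Per-subject metabolizer labels from the mixture posteriors."""
    post = results.mixture_posteriors
    if post is None:
        raise ValueError("not a mixture-model fit")
    return np.where(post["fast"].to_numpy() >= 0.5, "fast", "slow")
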
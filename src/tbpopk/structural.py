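"""Drug-specific structural models and covariate/random-effect transformations.

Each of the three drugs gets a transit-chain absorption model feeding a
first-order disposition model:

* rifampicin  — 1-compartment, 12 transit compartments; patient-group effect
  on absorption (ka scaled by θ, MTT by 1/θ) and a power covariate of
  conjugated bilirubin on clearance;
* isoniazid   — 2-compartment, 8 transit compartments; two-component mixture
  on clearance standing in for the unobserved NAT2 acetylator phenotype,
  peripheral volume parameterized through Vratio = Vc/Vp with a log-normal
  penalty prior;
* pyrazinamide — 1-compartment, 4 transit compartments; group-specific
  magnitude of the between-subject variability in clearance.

Clearances scale allometrically with fat-free mass (exponent 0.75) and
volumes linearly (exponent 1), referenced to 43 kg FFM.  Random effects are
log-normal: between-subject variability (BSV) on clearance and
between-occasion variability (BOV) on bioavailability, ka and MTT;
variability magnitudes are stored as SDs of the log-scale effects
(≈ CV for small values; the published "%CV" values are SD×100).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import BRC_REFERENCE, LLOQ
from . import kernels

__all__ = [
    "StructuralModel",
    "final_model",
    "default_params",
    "allometric_scale",
    "brc_effect",
    "group_absorption_effect",
    "mat",
    "mat_percent_difference",
    "theta_from_mat_percent",
    "individual_params",
    "predict_conc",
    "REF_FFM",
]

#: Reference fat-free mass for allometric scaling (kg).
REF_FFM = 43.0

#: Number of transit compartments, fixed per drug.
N_TRANSIT = {"rifampicin": 12, "isoniazid": 8, "pyrazinamide": 4}

_GROUP_INDEX = {"outpatient": 0, "hosp_survivor": 1, "hosp_death": 2}


@dataclass(frozen=True)
class StructuralModel:
    """Configuration of one drug's population model."""

    drug: str
    n_transit: int
    two_compartment: bool = False
    mixture_on_cl: bool = False
    group_on_absorption: bool = False
    brc_on_cl: bool = False
    brt_on_cl: bool = False
    group_fold_on_bsv_cl: bool = False
    #: random effects present; BSV entries have one η, BOV entries one κ per occasion
    reff: tuple = (("cl", "bsv"), ("f", "bov"), ("ka", "bov"), ("mtt", "bov"))
    n_occasions: int = 2
    ref_ffm: float = REF_FFM
    brc_reference: float = BRC_REFERENCE
    brt_reference: float = 10.0
    #: mode and log-scale SD of the penalty prior on Vratio (None = no prior)
    vratio_prior: tuple | None = None

    @property
    def lloq(self) -> float:
        return LLOQ[self.drug]

    @property
    def n_eta(self) -> int:
        return sum(1 if kind == "bsv" else self.n_occasions for _, kind in self.reff)

    def eta_index(self, name, occ=0):
        """Column of the η vector for effect ``name`` (occasion ``occ`` for BOV)."""
        i = 0
        for nm, kind in self.reff:
            width = 1 if kind == "bsv" else self.n_occasions
            if nm == name:
                return i + (occ if kind == "bov" else 0)
            i += width
        raise KeyError(name)

    def has_reff(self, name) -> bool:
        return any(nm == name for nm, _ in self.reff)

    def with_effect(self, name: str) -> "StructuralModel":
        return replace(self, **{_EFFECT_FLAG[name]: True})

    def without_effect(self, name: str) -> "StructuralModel":
        return replace(self, **{_EFFECT_FLAG[name]: False})

    def free_parameters(self) -> list[str]:
        """Names of the population parameters estimated for this model."""
        if self.mixture_on_cl:
            names = ["cl_fast", "cl_slow", "p_fast"]
        else:
            names = ["cl"]
        names += ["v"]
        if self.two_compartment:
            names += ["q", "vratio"]
        names += ["ka", "mtt"]
        if self.group_on_absorption:
            names += ["theta_surv", "theta_death"]
        if self.brc_on_cl:
            names += ["beta_brc"]
        if self.brt_on_cl:
            names += ["beta_brt"]
        for nm, kind in self.reff:
            names.append(("omega_" if kind == "bsv" else "bov_") + nm)
        if self.group_fold_on_bsv_cl:
            names += ["fold_surv", "fold_death"]
        names += ["sigma_prop", "sigma_add"]
        return names


_EFFECT_FLAG = {
    "brc_on_cl": "brc_on_cl",
    "brt_on_cl": "brt_on_cl",
    "group_on_absorption": "group_on_absorption",
    "group_fold_on_bsv_cl": "group_fold_on_bsv_cl",
}

_FINAL = {
    "rifampicin": StructuralModel(
        drug="rifampicin", n_transit=12, group_on_absorption=True, brc_on_cl=True
    ),
    "isoniazid": StructuralModel(
        drug="isoniazid", n_transit=8, two_compartment=True, mixture_on_cl=True,
        vratio_prior=(2.02, 0.30),
    ),
    "pyrazinamide": StructuralModel(
        drug="pyrazinamide", n_transit=4, group_fold_on_bsv_cl=True
    ),
}


def final_model(drug: str) -> StructuralModel:
    """Final model configuration for one of the three drugs.

    Addressable names: ``rifampicin_final`` etc. (the ``_final`` suffix is
    optional).
    """
    key = drug.removesuffix("_final")
    if key not in _FINAL:
        raise ValueError(f"unknown model {drug!r}")
    return _FINAL[key]


#: Default (literature) population parameter values per drug.  Variability
#: terms are log-scale SDs; theta are the hospitalized-group multipliers on
#: ka (and divisors of MTT); additive errors for rifampicin and isoniazid sit
#: at their 20%-of-LLOQ floor.
_DEFAULTS = {
    "rifampicin": dict(
        cl=8.82, v=56.8, ka=1.38, mtt=0.342,
        theta_surv=1.0 / 1.499, theta_death=1.0 / 2.54,
        beta_brc=-0.333,
        omega_cl=0.424, bov_f=0.213, bov_ka=1.19, bov_mtt=0.938,
        sigma_prop=0.172, sigma_add=0.0234,
    ),
    "isoniazid": dict(
        cl_fast=25.5, cl_slow=9.76, p_fast=0.645,
        v=59.0, q=1.43, vratio=59.0 / 30.7, ka=2.43, mtt=0.442,
        omega_cl=0.253, bov_f=0.349, bov_ka=1.22, bov_mtt=0.997,
        sigma_prop=0.139, sigma_add=0.021,
    ),
    "pyrazinamide": dict(
        cl=2.61, v=36.0, ka=1.92, mtt=0.379,
        fold_surv=1.70, fold_death=3.56,
        omega_cl=0.199, bov_f=0.105, bov_ka=0.753, bov_mtt=1.02,
        sigma_prop=0.114, sigma_add=2.48,
    ),
}


def default_params(drug: str) -> dict:
    """A copy of the default population parameters for ``drug``."""
    return dict(_DEFAULTS[drug.removesuffix("_final")])


# ---------------------------------------------------------------------------
# elementary covariate transformations
# ---------------------------------------------------------------------------

def allometric_scale(typical, ffm, ref_ffm=REF_FFM, exponent=0.75):
    """Allometric body-size scaling: ``typical · (ffm/ref_ffm)^exponent``."""
    ffm = np.asarray(ffm, dtype=float)
    if np.any(ffm <= 0) or ref_ffm <= 0:
        raise ValueError("body size must be positive")
    return typical * (ffm / ref_ffm) ** exponent


def brc_effect(cl, brc, brc_median=BRC_REFERENCE, beta=-0.333):
    """Power covariate of conjugated bilirubin on clearance."""
    brc = np.asarray(brc, dtype=float)
    if np.any(brc <= 0) or brc_median <= 0:
        raise ValueError("bilirubin must be positive (impute before modelling)")
    return cl * (brc / brc_median) ** beta


def group_absorption_effect(ka, mtt, group, theta_surv, theta_death):
    """Patient-group effect on absorption: ka·θ and MTT/θ.

    ``group`` may be a label or an array of labels; outpatients get θ=1.
    """
    theta = _theta_of_group(group, theta_surv, theta_death)
    return ka * theta, mtt / theta


def _theta_of_group(group, theta_surv, theta_death):
    if np.ndim(group) == 0:
        g = _GROUP_INDEX[group] if isinstance(group, str) else int(group)
        return [1.0, theta_surv, theta_death][g]
    gidx = np.asarray(
        [_GROUP_INDEX[g] if isinstance(g, str) else int(g) for g in np.ravel(group)]
    ).reshape(np.shape(group))
    table = np.array([1.0, theta_surv, theta_death])
    return table[gidx]


def mat(ka, mtt):
    """Mean absorption time: MTT + 1/ka (h)."""
    return mtt + 1.0 / ka


def mat_percent_difference(theta):
    """% difference in MAT of a hospitalized group vs outpatients, (1/θ−1)·100."""
    return (1.0 / theta - 1.0) * 100.0


def theta_from_mat_percent(percent):
    """Inverse of :func:`mat_percent_difference`."""
    return 1.0 / (1.0 + percent / 100.0)


# ---------------------------------------------------------------------------
# population -> individual parameters and prediction
# ---------------------------------------------------------------------------

def omega_diag(struct: StructuralModel, pop: dict, group_index) -> np.ndarray:
    """Per-subject diagonal of the random-effect covariance (N, n_eta).

    For pyrazinamide the BSV-CL standard deviation is multiplied by the
    group-specific fold change, so hospitalized subjects get a wider η_CL
    distribution.
    """
    group_index = np.asarray(group_index)
    n = len(group_index)
    diag = np.empty((n, struct.n_eta))
    i = 0
    for nm, kind in struct.reff:
        if kind == "bsv":
            sd = np.full(n, pop[f"omega_{nm}"])
            if nm == "cl" and struct.group_fold_on_bsv_cl:
                folds = np.array([1.0, pop["fold_surv"], pop["fold_death"]])
                sd = sd * folds[group_index]
            diag[:, i] = sd**2
            i += 1
        else:
            diag[:, i : i + struct.n_occasions] = pop[f"bov_{nm}"] ** 2
            i += struct.n_occasions
    return diag


def individual_params(struct: StructuralModel, pop: dict, covariates: dict,
                      eta, dose_occ, component=None):
    """Realized individual parameters from population values and effects.

    Parameters
    ----------
    covariates : dict with arrays ``ffm``, ``group_index`` (0/1/2) and,
        for rifampicin, ``brc`` (all length N)
    eta : (..., N, n_eta) log-scale random effects
    dose_occ : (N, D) zero-based occasion index of each dose
    component : None, or "fast"/"slow" for the mixture on clearance

    Returns a dict with ``cl``, ``v`` (+ ``q``, ``vratio``) of shape
    (..., N) and per-dose ``F``, ``ka``, ``mtt`` of shape (..., N, D).
    """
    eta = np.asarray(eta, dtype=float)
    ffm = np.asarray(covariates["ffm"], dtype=float)
    gidx = np.asarray(covariates["group_index"])
    dose_occ = np.asarray(dose_occ)

    if struct.mixture_on_cl:
        if component not in ("fast", "slow"):
            raise ValueError("mixture model needs component 'fast' or 'slow'")
        cl_typ = pop["cl_fast"] if component == "fast" else pop["cl_slow"]
    else:
        cl_typ = pop["cl"]
    cl = allometric_scale(cl_typ, ffm, struct.ref_ffm, 0.75)
    if struct.brc_on_cl:
        cl = brc_effect(cl, covariates["brc"], struct.brc_reference, pop["beta_brc"])
    if struct.brt_on_cl:
        cl = brc_effect(cl, covariates["brt"], struct.brt_reference, pop["beta_brt"])
    if struct.has_reff("cl"):
        cl = cl * np.exp(eta[..., struct.eta_index("cl")])

    v = allometric_scale(pop["v"], ffm, struct.ref_ffm, 1.0)

    ka_typ = np.full_like(ffm, pop["ka"])
    mtt_typ = np.full_like(ffm, pop["mtt"])
    if struct.group_on_absorption:
        theta = np.array([1.0, pop["theta_surv"], pop["theta_death"]])[gidx]
        ka_typ = ka_typ * theta
        mtt_typ = mtt_typ / theta

    def occ_kappa(name):
        if not struct.has_reff(name):
            return np.zeros(eta.shape[:-1] + dose_occ.shape[-1:])
        cols = [struct.eta_index(name, o) for o in range(struct.n_occasions)]
        kap = np.clip(eta[..., cols], -20.0, 20.0)  # (..., N, n_occ)
        return np.take_along_axis(
            kap, np.broadcast_to(dose_occ, kap.shape[:-1] + dose_occ.shape[-1:]), axis=-1
        )

    with np.errstate(over="ignore"):
        out = dict(
            cl=cl,
            v=np.broadcast_to(v, cl.shape).copy(),
            F=np.exp(occ_kappa("f")),
            ka=ka_typ[:, None] * np.exp(occ_kappa("ka")),
            mtt=mtt_typ[:, None] * np.exp(occ_kappa("mtt")),
        )
    if struct.two_compartment:
        out["q"] = np.broadcast_to(np.asarray(pop["q"], dtype=float), cl.shape).copy()
        out["vratio"] = np.broadcast_to(
            np.asarray(pop["vratio"], dtype=float), cl.shape
        ).copy()
    return out


def predict_conc(struct: StructuralModel, pop: dict, design, eta,
                 component=None, nodes=(12, 6)):
    """Model-predicted concentrations for every design observation.

    ``design`` provides arrays ``obs_time`` (N,J), ``dose_time``/``dose_amt``
    (N,D), ``dose_occ`` (N,D) and the covariate dict.  Returns (..., N, J).
    """
    ind = individual_params(
        struct, pop, design.covariates, eta, design.dose_occ, component=component
    )
    return kernels.transit_conc(
        design.obs_time, design.dose_time, design.dose_amt,
        ind["F"], ind["ka"], ind["mtt"], struct.n_transit,
        ind["v"], ind["cl"],
        q=ind.get("q"), vratio=ind.get("vratio"),
        nodes=nodes,
    )
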
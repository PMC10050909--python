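"""Synthetic-cohort generation and forward trial simulation.

The generator emulates the study design that motivates this package: 108
adults starting first-line TB therapy (48 outpatients, 49 hospitalized
survivors, 11 hospitalized patients who died within 12 weeks), dosed once
daily with weight-banded fixed-dose-combination tablets, with a PK visit on
the third treatment day sampling pre-dose and 1, 2.5, 4, 6 and 8 h
post-dose.  Covariates are drawn from parametric distributions
moment-matched to the published per-group medians and quartiles; heights
come from sex-specific normals (physiologic defaults -- the study reports
no height distribution).

Simulated concentrations follow y = f·(1+eps_prop) + eps_add with values
below the assay LLOQ flagged BLQ (and negative draws floored at zero); the
generating random effects, mixture labels and noise-free concentrations are
retained in truth tables so that estimator-recovery experiments have a
well-defined target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import Cohort, DoseEvent, Observation, SubjectRecord, preprocess
from .structural import StructuralModel, omega_diag, predict_conc
from . import estimate as _est

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "weight_band_dose",
    "generate_cohort",
    "simulate_trial",
    "simulate_observations",
    "SimulatedTrial",
]

#: mg of each drug per fixed-dose-combination tablet
MG_PER_TABLET = {"rifampicin": 150.0, "isoniazid": 75.0, "pyrazinamide": 400.0}

_Z75 = 0.6744897501960817  # 75th standard-normal percentile


def _lognorm_from_quartiles(median, q1, q3):
    """(mu, sigma) of a log-normal matched to a median and quartiles."""
    return np.log(median), (np.log(q3) - np.log(q1)) / (2.0 * _Z75)


@dataclass(frozen=True)
class GroupSpec:
    """Covariate distribution of one patient group (medians and quartiles)."""

    n: int
    p_female: float
    weight: tuple       # (median, q1, q3) kg
    age: tuple          # years
    brc: tuple          # conjugated bilirubin, µmol/L
    brt: tuple          # total bilirubin, µmol/L
    p_hiv: float
    n_missing_height: int = 0
    n_missing_brc: int = 0


@dataclass(frozen=True)
class CohortSpec:
    """The simulated study design; defaults reproduce the reference study."""

    groups: dict = field(default_factory=lambda: {
        "outpatient": GroupSpec(
            n=48, p_female=0.25, weight=(57, 52, 62), age=(36, 32, 42),
            brc=(6.0, 4.0, 8.0), brt=(10.0, 7.0, 14.0), p_hiv=29 / 48,
            n_missing_brc=3,
        ),
        "hosp_survivor": GroupSpec(
            n=49, p_female=0.51, weight=(55, 48, 60), age=(38, 32, 40),
            brc=(5.0, 2.25, 8.0), brt=(9.0, 5.0, 14.3), p_hiv=1.0,
            n_missing_height=3, n_missing_brc=4,
        ),
        "hosp_death": GroupSpec(
            n=11, p_female=0.55, weight=(54, 48, 60), age=(35, 31, 50),
            brc=(8.0, 6.0, 10.0), brt=(12.0, 9.5, 15.0), p_hiv=1.0,
            n_missing_height=1, n_missing_brc=1,
        ),
    })
    sampling_times: tuple = (0.0, 1.0, 2.5, 4.0, 6.0, 8.0)
    prior_doses: int = 2
    dose_interval: float = 24.0
    p_fast_metabolizer: float = 0.645
    height_mean: dict = field(default_factory=lambda: {"male": 1.68, "female": 1.59})
    height_sd: dict = field(default_factory=lambda: {"male": 0.07, "female": 0.06})
    brc_log_correlation: float = 0.86  # BRT-BRC correlation on the log scale

    def total_n(self) -> int:
        return sum(g.n for g in self.groups.values())


def weight_band_dose(weight: float, drug: str | None = None):
    """Weight-banded number of FDC tablets (and mg of ``drug`` if given).

    Bands: 30-37 kg -> 2, 38-54 -> 3, 55-70 -> 4, >70 -> 5 tablets of
    150/75/400 mg rifampicin/isoniazid/pyrazinamide.
    """
    if weight < 30:
        raise ValueError(f"weight {weight} kg below the 30 kg dosing guideline floor")
    if weight < 38:
        tablets = 2
    elif weight < 55:
        tablets = 3
    elif weight <= 70:
        tablets = 4
    else:
        tablets = 5
    if drug is None:
        return tablets
    return tablets, tablets * MG_PER_TABLET[drug]


def generate_cohort(spec: CohortSpec, drug: str, seed: int) -> Cohort:
    """Draw a synthetic cohort for one drug.

    Covariates depend only on ``seed`` (not on the drug), so cohorts
    generated for different drugs with the same seed share subjects --
    required by the cross-drug variability-correlation analysis.
    """
    if spec.total_n() == 0:
        raise ValueError("degenerate spec: no subjects in any group")
    rng = np.random.default_rng(seed)
    cohort = Cohort(drug=drug)
    sid = 0
    for gname, g in spec.groups.items():
        mu_w, sd_w = _lognorm_from_quartiles(*g.weight)
        mu_a, sd_a = _lognorm_from_quartiles(*g.age)
        mu_b, sd_b = _lognorm_from_quartiles(*g.brc)
        mu_t, sd_t = _lognorm_from_quartiles(*g.brt)
        rho = spec.brc_log_correlation
        miss_h = set(rng.choice(g.n, size=min(g.n_missing_height, g.n), replace=False)) if g.n else set()
        miss_b = set(rng.choice(g.n, size=min(g.n_missing_brc, g.n), replace=False)) if g.n else set()
        for k in range(g.n):
            sid += 1
            sex = "female" if rng.random() < g.p_female else "male"
            height = float(np.clip(
                rng.normal(spec.height_mean[sex], spec.height_sd[sex]), 1.40, 2.05))
            weight = float(np.clip(np.exp(rng.normal(mu_w, sd_w)), 35.0, 95.0))
            age = float(np.clip(np.exp(rng.normal(mu_a, sd_a)), 18.0, 80.0))
            zb = rng.standard_normal()
            brc = float(np.exp(mu_b + sd_b * zb))
            brt = float(np.exp(
                mu_t + sd_t * (rho * zb + np.sqrt(1 - rho**2) * rng.standard_normal())))
            hiv = bool(rng.random() < g.p_hiv)
            nat2_fast = bool(rng.random() < spec.p_fast_metabolizer)
            rec = SubjectRecord(
                subject_id=f"S{sid:03d}", group=gname, sex=sex, weight=weight,
                height=None if k in miss_h else height, age=age,
                conjugated_bilirubin=None if k in miss_b else brc,
                hiv_positive=hiv,
            )
            rec.total_bilirubin = brt
            rec.nat2_fast = nat2_fast  # truth label for the mixture model
            _, mg = weight_band_dose(weight, drug)
            for p in range(spec.prior_doses, -1, -1):
                rec.doses.append(DoseEvent(time=-p * spec.dose_interval, amount=mg))
            for t in sorted(spec.sampling_times):
                rec.observations.append(
                    Observation(time=float(t), value=None, lloq=cohort.lloq)
                )
            cohort.subjects.append(rec)
    return cohort


def simulate_observations(struct: StructuralModel, pop: dict, design,
                          rng, n_rep: int = 1, components=None,
                          chunk: int = 50):
    """Simulate ``n_rep`` replicate observation matrices on a fixed design.

    Returns (y, f, eta, comp): noisy values, noise-free predictions,
    generating random effects (n_rep, N, n_eta) and mixture labels
    (n_rep, N; -1 when no mixture).  Replicates are processed in chunks to
    bound memory.
    """
    n = design.obs_time.shape[0]
    d = struct.n_eta
    om = omega_diag(struct, pop, design.covariates["group_index"])
    eta = rng.standard_normal((n_rep, n, d)) * np.sqrt(om)
    if struct.mixture_on_cl:
        if components is None:
            comp = (rng.random((n_rep, n)) < pop["p_fast"]).astype(int)  # 1 = fast
        else:
            comp = np.broadcast_to(np.asarray(components, int), (n_rep, n)).copy()
    else:
        comp = np.full((n_rep, n), -1)

    f = np.empty((n_rep, n, design.obs_time.shape[1]))
    for lo in range(0, n_rep, chunk):
        hi = min(lo + chunk, n_rep)
        e = eta[lo:hi]
        if struct.mixture_on_cl:
            ff = predict_conc(struct, pop, design, e, component="fast")
            fs = predict_conc(struct, pop, design, e, component="slow")
            f[lo:hi] = np.where((comp[lo:hi] == 1)[..., None], ff, fs)
        else:
            f[lo:hi] = predict_conc(struct, pop, design, e)
    eps_p = rng.standard_normal(f.shape) * pop["sigma_prop"]
    eps_a = rng.standard_normal(f.shape) * pop["sigma_add"]
    y = f * (1.0 + eps_p) + eps_a
    y = np.maximum(y, 0.0)
    return y, f, eta, comp


@dataclass
class SimulatedTrial:
    """A simulated trial: the observable dataset plus generating truth."""

    cohort: Cohort
    truth_subjects: pd.DataFrame  # per subject: eta columns, mixture component
    truth_obs: pd.DataFrame       # per sample: true (noise-free) and observed value
    pop: dict
    struct: StructuralModel


def simulate_trial(struct: StructuralModel, pop: dict, cohort: Cohort,
                   seed: int) -> SimulatedTrial:
    """Fill a design cohort with simulated concentrations.

    Concentrations are generated from the structural model at the supplied
    population parameters with log-normal BSV/BOV effects and combined
    proportional+additive residual error; draws below the LLOQ are flagged
    BLQ.  Missing covariates are imputed (reference-median bilirubin,
    per-sex-mean height) before simulation, so the generating truth equals
    what the estimation model sees.
    """
    rng = np.random.default_rng(seed)
    prepped = preprocess(cohort)
    design = _est.CohortDesign.from_cohort(prepped, struct.n_occasions,
                                           require_values=False)
    labels = None
    if struct.mixture_on_cl:
        lab = design.covariates["nat2_fast"]
        labels = np.where(lab < 0, rng.random(len(lab)) < pop["p_fast"], lab).astype(int)
    y, f, eta, comp = simulate_observations(
        struct, pop, design, rng, n_rep=1, components=labels
    )
    y, f, eta, comp = y[0], f[0], eta[0], comp[0]

    out = cohort.copy()
    rows = []
    for i, s in enumerate(out.subjects):
        obs = sorted(s.observations, key=lambda o: o.time)
        for j, o in enumerate(obs):
            val = float(y[i, j])
            o.value = val
            o.blq = bool(val < out.lloq)
            o.status = "measured"
            o.lloq = out.lloq
            rows.append(dict(subject_id=s.subject_id, time=o.time,
                             conc_true=float(f[i, j]), value=val, blq=o.blq))
        s.observations = obs
    eta_cols = {}
    k = 0
    for nm, kind in struct.reff:
        if kind == "bsv":
            eta_cols[f"eta_{nm}"] = eta[:, k]
            k += 1
        else:
            for o in range(struct.n_occasions):
                eta_cols[f"kappa_{nm}_occ{o + 1}"] = eta[:, k]
                k += 1
    truth_subjects = pd.DataFrame(dict(
        subject_id=[s.subject_id for s in out.subjects],
        group=[s.group for s in out.subjects],
        component=np.where(comp == 1, "fast", np.where(comp == 0, "slow", "")),
        **eta_cols,
    ))
    return SimulatedTrial(
        cohort=out, truth_subjects=truth_subjects,
        truth_obs=pd.DataFrame(rows), pop=dict(pop), struct=struct,
    )
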
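"""Simulation-based diagnostics: visual predictive check and bootstrap.

The VPC simulates replicate trials on the original design (same doses,
times and covariates), summarizes observed and simulated percentiles per
nominal-time bin, and reports the simulation confidence band of each
percentile.  Simulated values below the LLOQ receive the same M6-style
treatment as the observed, M6-processed data (first of a consecutive BLQ
run at LLOQ/2, the rest excluded) so the two summaries stay comparable.

The bootstrap resamples subjects with replacement, stratified by patient
group, refits each replicate and reports percentile confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Cohort
from .simulate import simulate_observations

logger = logging.getLogger(__name__)

__all__ = ["VPCResult", "vpc", "plot_vpc", "BootstrapResult", "bootstrap"]


@dataclass
class VPCResult:
    """Percentile summaries of a visual predictive check."""

    table: pd.DataFrame  # rows: (stratum, bin) x percentile summaries
    percentiles: tuple
    n_sim: int

    def coverage(self) -> float:
        """Fraction of (bin, percentile) cells whose observed percentile
        falls inside the simulated confidence band."""
        t = self.table
        hits = 0
        total = 0
        for p in self.percentiles:
            ok = (t[f"obs_p{p:g}"] >= t[f"sim_p{p:g}_lo"]) & (
                t[f"obs_p{p:g}"] <= t[f"sim_p{p:g}_hi"])
            hits += int(ok.sum())
            total += len(t)
        return hits / total


def _m6_like(values, lloq, mask):
    """Apply the M6 convention to a simulated value matrix (..., N, J).

    Returns (values, include): first-in-run BLQ set to LLOQ/2, later run
    members excluded.  Columns are assumed time-ordered per subject.
    """
    blq = (values < lloq) & mask
    prev = np.zeros_like(blq)
    prev[..., 1:] = blq[..., :-1]
    # a BLQ continues a run only if the previous *kept* sample was BLQ
    run = np.zeros_like(blq)
    acc = np.zeros(blq.shape[:-1], dtype=bool)
    for j in range(blq.shape[-1]):
        run[..., j] = blq[..., j] & acc
        acc = blq[..., j]
    vals = np.where(blq & ~run, lloq / 2.0, values)
    include = mask & ~run
    return vals, include


def _strata_labels(results, strata):
    design = results.model.design
    n = design.n_subjects
    if strata is None:
        return np.array(["all"] * n)
    if strata == "group":
        names = np.array(["outpatient", "hosp_survivor", "hosp_death"])
        return names[design.covariates["group_index"]]
    if strata == "metabolizer":
        from .estimate import mixture_assign

        return mixture_assign(results)
    raise ValueError(f"unknown stratification {strata!r}")


def vpc(results, n_sim: int = 1000, strata: str | None = None, seed: int = 0,
        percentiles=(5, 50, 95), ci: float = 95.0, min_bin: int = 5) -> VPCResult:
    """Visual predictive check of a fitted model.

    Bins are the nominal sampling times of the design; bins holding fewer
    than ``min_bin`` observations are merged with their left neighbour.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100 for stable bands")
    model = results.model
    design = model.design
    lloq = model.struct.lloq
    rng = np.random.default_rng(seed)

    sim, _, _, _ = simulate_observations(
        model.struct, results.params, design, rng, n_rep=n_sim)
    sim_vals, sim_inc = _m6_like(sim, lloq, design.obs_mask[None])
    obs_vals, obs_inc = design.y, design.obs_mask

    labels = _strata_labels(results, strata)
    t = design.obs_time
    alpha = (100.0 - ci) / 2.0
    rows = []
    for stratum in pd.unique(labels):
        sel = labels == stratum
        times = np.unique(t[sel][np.isfinite(t[sel])])
        # merge sparse nominal-time bins leftward
        bins = []
        for tt in times:
            cell = (t[sel] == tt) & obs_inc[sel]
            if bins and cell.sum() < min_bin:
                logger.info("merging sparse bin t=%g (stratum %s)", tt, stratum)
                bins[-1].append(tt)
            else:
                bins.append([tt])
        for group_times in bins:
            cell = np.isin(t[sel], group_times)
            o = obs_vals[sel][cell & obs_inc[sel]]
            row = dict(stratum=stratum, bin_times=tuple(group_times),
                       t_mid=float(np.mean(group_times)), n_obs=int(o.size))
            simc = sim_vals[:, sel, :]
            incc = sim_inc[:, sel, :]
            cellr = np.broadcast_to(cell, simc.shape)
            for p in percentiles:
                row[f"obs_p{p:g}"] = float(np.percentile(o, p)) if o.size else np.nan
                per_rep = [
                    np.percentile(simc[r][cellr[r] & incc[r]], p)
                    for r in range(n_sim)
                    if (cellr[r] & incc[r]).any()
                ]
                row[f"sim_p{p:g}_lo"] = float(np.percentile(per_rep, alpha))
                row[f"sim_p{p:g}_med"] = float(np.percentile(per_rep, 50))
                row[f"sim_p{p:g}_hi"] = float(np.percentile(per_rep, 100 - alpha))
            rows.append(row)
    table = pd.DataFrame(rows)
    for p in percentiles:  # ordered bands in every bin
        assert (table[f"sim_p{p:g}_lo"] <= table[f"sim_p{p:g}_hi"]).all()
    return VPCResult(table=table, percentiles=tuple(percentiles), n_sim=n_sim)


def plot_vpc(result: VPCResult, ax=None, log_y: bool = True):
    """Plot observed percentiles over the simulated confidence bands."""
    import matplotlib.pyplot as plt

    strata = pd.unique(result.table["stratum"])
    if ax is None:
        _, axes = plt.subplots(1, len(strata), figsize=(4.5 * len(strata), 3.5),
                               squeeze=False)
        axes = axes[0]
    else:
        axes = np.atleast_1d(ax)
    for a, stratum in zip(axes, strata):
        t = result.table[result.table["stratum"] == stratum]
        for p, style in zip(result.percentiles, ("--", "-", "--")):
            a.fill_between(t["t_mid"], t[f"sim_p{p:g}_lo"], t[f"sim_p{p:g}_hi"],
                           alpha=0.25)
            a.plot(t["t_mid"], t[f"obs_p{p:g}"], style, color="k")
        a.set_title(str(stratum))
        a.set_xlabel("time after dose (h)")
        a.set_ylabel("concentration (mg/L)")
        if log_y:
            a.set_yscale("log")
    return axes


@dataclass
class BootstrapResult:
    """Nonparametric bootstrap summary."""

    n_requested: int
    n_converged: int
    estimates: pd.DataFrame        # one row per converged replicate
    ci: pd.DataFrame               # per-parameter 2.5/97.5 percentile bounds


def bootstrap(cohort: Cohort, structure, n_boot: int = 500, seed: int = 0,
              start=None, fit_kwargs=None) -> BootstrapResult:
    """Nonparametric bootstrap: resample subjects (stratified by patient
    group) with replacement and refit each replicate."""
    from .estimate import PopPKModel

    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    fit_kwargs = fit_kwargs or {}
    groups = {}
    for idx, s in enumerate(cohort.subjects):
        groups.setdefault(s.group, []).append(idx)
    rows = []
    n_conv = 0
    for b in range(n_boot):
        subjects = []
        for gname, members in groups.items():
            take = rng.choice(members, size=len(members), replace=True)
            for j, idx in enumerate(take):
                s = Cohort(drug=cohort.drug, subjects=[cohort.subjects[idx]]).copy().subjects[0]
                s.subject_id = f"B{b}_{gname[:4]}{j}"
                subjects.append(s)
        rep = Cohort(drug=cohort.drug, subjects=subjects)
        try:
            res = PopPKModel(rep, structure).fit(start=start, **fit_kwargs)
        except Exception as err:  # refit failure counts as non-converged
            logger.warning("bootstrap replicate %d failed: %s", b, err)
            continue
        if res.converged:
            n_conv += 1
            rows.append(dict(replicate=b, **res.params))
    est = pd.DataFrame(rows)
    params = [c for c in est.columns if c != "replicate"]
    ci = pd.DataFrame({
        "lo": est[params].quantile(0.025),
        "hi": est[params].quantile(0.975),
    })
    return BootstrapResult(n_requested=n_boot, n_converged=n_conv,
                           estimates=est, ci=ci)
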
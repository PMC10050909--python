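"""Fit results container: estimates, EBEs, shrinkage, summary table."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PopPKResults"]

_VARIABILITY_PREFIXES = ("omega_", "bov_")


@dataclass
class PopPKResults:
    """Results of a :class:`~tbpopk.estimate.PopPKModel` fit.

    Attributes
    ----------
    params : dict
        Population parameter estimates (natural scale; variability terms are
        log-scale SDs).
    ofv : float
        -2x approximate marginal log-likelihood at the estimates (includes
        any penalty prior).
    eta : dict
        Empirical-Bayes random effects per mixture component
        ({None: array} for non-mixture models), shape (N, n_eta).
    mixture_posteriors : DataFrame or None
        Per-subject posterior component probabilities.
    """

    model: object
    params: dict
    ofv: float
    free_names: list
    converged: bool
    n_outer_iter: int
    message: str = ""
    eta: dict = field(default_factory=dict)
    mixture_posteriors: pd.DataFrame | None = None
    se: dict | None = None
    ofv_trace: list = field(default_factory=list)

    # -- random effects ------------------------------------------------------

    def _component_of_subject(self) -> np.ndarray:
        """Most probable mixture component per subject (index into eta dict)."""
        n = self.model.design.n_subjects
        if self.mixture_posteriors is None:
            return np.zeros(n, int)
        return (self.mixture_posteriors["fast"].to_numpy() < 0.5).astype(int)

    def random_effects(self) -> pd.DataFrame:
        """Per-subject empirical-Bayes effects (argmax component for mixtures)."""
        struct = self.model.struct
        comps = list(self.eta)
        idx = self._component_of_subject()
        eta = np.stack([self.eta[c] for c in comps])  # (C, N, d)
        eta = eta[idx, np.arange(eta.shape[1])]
        cols = {}
        k = 0
        for nm, kind in struct.reff:
            if kind == "bsv":
                cols[f"eta_{nm}"] = eta[:, k]
                k += 1
            else:
                for o in range(struct.n_occasions):
                    cols[f"kappa_{nm}_occ{o + 1}"] = eta[:, k]
                    k += 1
        return pd.DataFrame(dict(subject_id=self.model.design.subject_ids, **cols))

    def shrinkage(self) -> dict:
        """Eta-shrinkage per random effect, % (1 - SD(EBE)/omega).

        BOV effects pool both occasions; where the BSV magnitude differs by
        patient group (pyrazinamide) each EBE is standardized by its own
        subject's omega before pooling.
        """
        from .structural import omega_diag

        struct = self.model.struct
        om = omega_diag(struct, self.params, self.model.design.covariates["group_index"])
        re = self.random_effects().drop(columns="subject_id").to_numpy()
        out = {}
        k = 0
        for nm, kind in struct.reff:
            width = 1 if kind == "bsv" else struct.n_occasions
            z = re[:, k : k + width] / np.sqrt(om[:, k : k + width])
            sd = float(np.std(z.ravel(), ddof=1))
            key = ("omega_" if kind == "bsv" else "bov_") + nm
            out[key] = 100.0 * (1.0 - sd) if np.isfinite(sd) else np.nan
            k += width
        return out

    # -- presentation --------------------------------------------------------

    def summary_frame(self) -> pd.DataFrame:
        shr = self.shrinkage()
        rows = []
        for nm in self.free_names:
            v = self.params[nm]
            scale = 100.0 if nm.startswith(_VARIABILITY_PREFIXES) or nm in (
                "sigma_prop", "p_fast") else 1.0
            rows.append(dict(
                parameter=nm,
                estimate=v * scale,
                unit="%" if scale == 100.0 else "",
                se=(self.se or {}).get(nm, np.nan) * scale if self.se else np.nan,
                shrinkage_pct=shr.get(nm, np.nan),
            ))
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text estimation summary."""
        df = self.summary_frame()
        disp = pd.DataFrame({
            "parameter": df["parameter"],
            "estimate": [f"{v:.4g}" for v in df["estimate"]],
            "unit": df["unit"],
            "shrinkage [%]": ["" if np.isnan(v) else f"{v:.1f}"
                              for v in df["shrinkage_pct"]],
        })
        if self.se is not None:
            disp.insert(2, "se", ["" if np.isnan(v) else f"{v:.3g}"
                                  for v in df["se"]])
        lines = [
            f"Population PK fit: {self.model.struct.drug}"
            f" ({'2' if self.model.struct.two_compartment else '1'}-compartment, "
            f"{self.model.struct.n_transit} transit compartments)",
            f"subjects: {self.model.design.n_subjects}   "
            f"observations: {self.model.design.n_obs}",
            f"OFV: {self.ofv:.3f}   converged: {self.converged} "
            f"({self.n_outer_iter} outer iterations)",
            "",
            disp.to_string(index=False),
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (f"<PopPKResults {self.model.struct.drug} OFV={self.ofv:.2f} "
                f"converged={self.converged}>")

    # -- downstream analyses (thin delegates) --------------------------------

    def predict(self, individual: bool = True) -> np.ndarray:
        """Model predictions at the design points (individual or typical)."""
        from .structural import predict_conc

        comps = list(self.eta)
        idx = self._component_of_subject()
        if individual:
            etas = np.stack([self.eta[c] for c in comps])[
                idx, np.arange(self.model.design.n_subjects)]
        else:
            etas = np.zeros_like(self.eta[comps[0]])
        if self.model.struct.mixture_on_cl:
            ff = predict_conc(self.model.struct, self.params, self.model.design,
                              etas, component="fast")
            fs = predict_conc(self.model.struct, self.params, self.model.design,
                              etas, component="slow")
            return np.where((idx == 0)[:, None], ff, fs)
        return predict_conc(self.model.struct, self.params, self.model.design, etas)

    def vpc(self, n_sim: int = 1000, strata: str | None = None, seed: int = 0,
            **kw):
        from .diagnostics import vpc

        return vpc(self, n_sim=n_sim, strata=strata, seed=seed, **kw)

    def derive_exposure(self) -> pd.DataFrame:
        from .exposure import derive_exposure

        return derive_exposure(self)

    def to_dict(self) -> dict:
        return dict(drug=self.model.struct.drug, params=self.params,
                    ofv=self.ofv, converged=self.converged,
                    free_names=list(self.free_names))
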
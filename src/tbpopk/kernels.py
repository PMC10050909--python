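"""Concentration-time kernels for transit-chain absorption models.

Two independent implementations of the same structural model ship here and
are tested against each other:

``transit_conc``
    Fast path.  The transit chain (a dosing compartment plus *n* transit
    compartments, all with rate ktr = (n+1)/MTT) delivers drug into the
    absorption depot at the Erlang(n+1, ktr) rate
    ``F·Dose·ktr·(ktr t)^n·exp(-ktr t)/n!``.  The central-compartment
    response to a unit depot bolus is a short sum of exponentials (one- or
    two-compartment disposition), so the concentration is the convolution
    of a smooth density with an analytic kernel; it is evaluated with
    fixed-order Gauss-Legendre panels placed around the Erlang mass.

``transit_conc_chain``
    Reference path.  The full linear compartment chain (transit chain,
    depot, central, optional peripheral) is integrated exactly with the
    matrix exponential, dose by dose.

Both superpose doses (linear kinetics).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import expm
from scipy.special import gammaln, roots_legendre

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap

__all__ = ["transit_conc", "transit_conc_chain"]

_NODE_CACHE: dict[tuple[int, int], tuple] = {}


def _panel_nodes(n_a: int, n_b: int):
    key = (n_a, n_b)
    if key not in _NODE_CACHE:
        xa, wa = roots_legendre(n_a)
        xb, wb = roots_legendre(n_b)
        # map from [-1, 1] to [0, 1]
        _NODE_CACHE[key] = (
            0.5 * (xa + 1.0), 0.5 * wa,
            0.5 * (xb + 1.0), 0.5 * wb,
        )
    return _NODE_CACHE[key]


def _depot_response(w, ka, lam, coef):
    """Central-compartment amount at time w per unit amount in the depot.

    ``lam``/``coef`` hold the disposition exponents and partial-fraction
    coefficients *excluding* the absorption exponential, whose coefficient
    is -sum(coef) by mass balance at w=0.  Stable for ka close to any
    disposition rate (expm1 form).
    """
    # A(w) = ka * sum_m coef_m * (exp(-lam_m w) - exp(-ka w)) / (ka - lam_m)
    out = 0.0
    for m in range(lam.shape[-1]):  # noqa: B007
        lm = lam[..., m : m + 1]
        cm = coef[..., m : m + 1]
        delta = ka - lm
        delta = np.where(np.abs(delta) < 1e-12, 1e-12, delta)
        with np.errstate(over="ignore", invalid="ignore"):
            out = out + cm * np.exp(-lm * w) * (-np.expm1(-delta * w)) / delta
    return ka * out


def _disposition(v, cl, q=None, vratio=None):
    """Exponents and coefficients of the unit-bolus disposition response.

    Returns (lam, coef) with trailing axis over exponentials such that the
    amount in the central compartment after a unit bolus *into the central
    compartment* is sum_m coef_m exp(-lam_m t) (coefficients sum to 1).
    """
    v = np.asarray(v, dtype=float)
    ke = np.asarray(cl, dtype=float) / v
    if q is None:
        lam = ke[..., None]
        coef = np.ones_like(lam)
        return lam, coef
    vp = v / np.asarray(vratio, dtype=float)
    kcp = np.asarray(q, dtype=float) / v
    kpc = np.asarray(q, dtype=float) / vp
    s = ke + kcp + kpc
    p = ke * kpc
    disc = np.sqrt(np.maximum(s * s - 4.0 * p, 1e-30))
    lam1 = 0.5 * (s + disc)
    lam2 = 0.5 * (s - disc)
    c1 = (kpc - lam1) / (lam2 - lam1)
    c2 = (kpc - lam2) / (lam1 - lam2)
    return np.stack([lam1, lam2], axis=-1), np.stack([c1, c2], axis=-1)


@njit(cache=True, fastmath=True, error_model="numpy")
def _conv_kernel(obs_time, dose_time, dose_amt, F, ka, mtt, n_transit,
                 v, cl, qq, vr, two_cpt, xa, wa, xb, wb, out):  # pragma: no cover
    B, N, D = F.shape
    J = obs_time.shape[1]
    shape = n_transit + 1.0
    lgam = math.lgamma(shape)
    sqs = math.sqrt(shape)
    for b in range(B):
        for n in range(N):
            ke = cl[b, n] / v[b, n]
            if two_cpt:
                vp = v[b, n] / vr[b, n]
                kcp = qq[b, n] / v[b, n]
                kpc = qq[b, n] / vp
                ssum = ke + kcp + kpc
                disc = math.sqrt(max(ssum * ssum - 4.0 * ke * kpc, 1e-30))
                lam1 = 0.5 * (ssum + disc)
                lam2 = 0.5 * (ssum - disc)
                c1 = (kpc - lam1) / (lam2 - lam1)
                c2 = (kpc - lam2) / (lam1 - lam2)
            else:
                lam1 = ke
                c1 = 1.0
                lam2 = 0.0
                c2 = 0.0
            for j in range(J):
                out[b, n, j] = 0.0
            for d in range(D):
                amt = dose_amt[n, d]
                if not (amt > 0.0):
                    continue
                m = mtt[b, n, d]
                kk = ka[b, n, d]
                ktr = shape / m
                sd = m / sqs
                a_hi = m + 4.0 * sd
                b_hi = m + 12.0 * sd
                lk = shape * math.log(ktr) - lgam
                d1 = kk - lam1
                if abs(d1) < 1e-12:
                    d1 = 1e-12
                d2 = kk - lam2
                if abs(d2) < 1e-12:
                    d2 = 1e-12
                scale_d = F[b, n, d] * amt * kk / v[b, n]
                for j in range(J):
                    u = obs_time[n, j] - dose_time[n, d]
                    if not (u > 0.0):
                        continue
                    a = u if u < a_hi else a_hi
                    bb = u if u < b_hi else b_hi
                    integral = 0.0
                    for i in range(xa.shape[0]):
                        s = a * xa[i]
                        if s <= 0.0:
                            continue
                        g = math.exp(lk + n_transit * math.log(s) - ktr * s)
                        w = u - s
                        resp = c1 * math.exp(-lam1 * w) * (-math.expm1(-d1 * w)) / d1
                        if two_cpt:
                            resp += c2 * math.exp(-lam2 * w) * (-math.expm1(-d2 * w)) / d2
                        integral += wa[i] * a * g * resp
                    wid = bb - a
                    if wid > 0.0:
                        for i in range(xb.shape[0]):
                            s = a + wid * xb[i]
                            g = math.exp(lk + n_transit * math.log(s) - ktr * s)
                            w = u - s
                            resp = c1 * math.exp(-lam1 * w) * (-math.expm1(-d1 * w)) / d1
                            if two_cpt:
                                resp += c2 * math.exp(-lam2 * w) * (-math.expm1(-d2 * w)) / d2
                            integral += wb[i] * wid * g * resp
                    out[b, n, j] += scale_d * integral


def _transit_conc_numba(obs_time, dose_time, dose_amt, F, ka, mtt, n_transit,
                        v, cl, q, vratio, nodes):
    N, J = obs_time.shape
    D = dose_time.shape[1]
    batch = np.broadcast_shapes(F.shape[:-2], ka.shape[:-2], mtt.shape[:-2],
                                v.shape[:-1], cl.shape[:-1])
    B = int(np.prod(batch)) if batch else 1
    Fb = np.ascontiguousarray(np.broadcast_to(F, batch + (N, D)).reshape(B, N, D))
    kab = np.ascontiguousarray(np.broadcast_to(ka, batch + (N, D)).reshape(B, N, D))
    mttb = np.ascontiguousarray(np.broadcast_to(mtt, batch + (N, D)).reshape(B, N, D))
    vb = np.ascontiguousarray(np.broadcast_to(v, batch + (N,)).reshape(B, N))
    clb = np.ascontiguousarray(np.broadcast_to(cl, batch + (N,)).reshape(B, N))
    two_cpt = q is not None
    if two_cpt:
        qb = np.ascontiguousarray(np.broadcast_to(q, batch + (N,)).reshape(B, N))
        vrb = np.ascontiguousarray(np.broadcast_to(vratio, batch + (N,)).reshape(B, N))
    else:
        qb = vrb = np.zeros((1, 1))
        qb = np.zeros((B, N))
        vrb = np.ones((B, N))
    xa, wa, xb, wb = _panel_nodes(*nodes)
    out = np.zeros((B, N, J))
    _conv_kernel(np.ascontiguousarray(obs_time), np.ascontiguousarray(dose_time),
                 np.ascontiguousarray(dose_amt), Fb, kab, mttb, float(n_transit),
                 vb, clb, qb, vrb, two_cpt, xa, wa, xb, wb, out)
    return out.reshape(batch + (N, J))


def transit_conc(obs_time, dose_time, dose_amt, F, ka, mtt, n_transit, v, cl,
                 q=None, vratio=None, nodes=(12, 6), use_numba=None):
    """Concentrations by analytic-kernel convolution (fast path).

    Parameters
    ----------
    obs_time : (N, J) observation times (h)
    dose_time, dose_amt : (N, D) dose schedule (h, mg); NaN amount = padding
    F, ka, mtt : (..., N, D) per-dose bioavailability fraction, absorption
        rate (1/h) and mean transit time (h); leading axes are batch axes
    v, cl : (..., N) central volume (L) and clearance (L/h)
    q, vratio : (..., N) or None; intercompartmental clearance (L/h) and
        Vc/Vp ratio for two-compartment disposition
    n_transit : int, number of transit compartments (chain shape is n+1)

    Returns
    -------
    conc : (..., N, J) mg/L
    """
    obs_time = np.asarray(obs_time, dtype=float)
    dose_time = np.asarray(dose_time, dtype=float)
    dose_amt = np.asarray(dose_amt, dtype=float)
    F = np.asarray(F, dtype=float)
    ka = np.asarray(ka, dtype=float)
    mtt = np.asarray(mtt, dtype=float)
    v = np.asarray(v, dtype=float)
    cl = np.asarray(cl, dtype=float)

    if use_numba is None:
        use_numba = _HAVE_NUMBA
    if use_numba and _HAVE_NUMBA:
        # sanitize padding NaNs: fastmath code must never see them
        obs_c = np.where(np.isfinite(obs_time), obs_time, -1e30)
        dt_c = np.where(np.isfinite(dose_time), dose_time, 1e30)
        da_c = np.where(np.isfinite(dose_amt), dose_amt, 0.0)
        return _transit_conc_numba(
            obs_c, dt_c, da_c, F, ka, mtt, n_transit, v, cl,
            None if q is None else np.asarray(q, dtype=float),
            None if vratio is None else np.asarray(vratio, dtype=float),
            nodes)

    u = obs_time[:, :, None] - dose_time[:, None, :]  # (N, J, D)
    active = (u > 0.0) & np.isfinite(dose_amt[:, None, :]) & (dose_amt[:, None, :] > 0)
    u = np.where(active, u, np.nan)

    shape = n_transit + 1
    ktr = shape / mtt  # (..., N, D)
    sd = mtt / np.sqrt(shape)

    lam, coef = _disposition(v, cl, q, vratio)  # (..., N, M)
    lam_e = lam[..., None, None, :]   # (..., N, 1, 1, M)
    coef_e = coef[..., None, None, :]

    ka_e = ka[..., :, None, :]        # (..., N, 1, D)
    ktr_e = ktr[..., :, None, :]
    hi_a = (mtt + 4.0 * sd)[..., :, None, :]
    hi_b = (mtt + 12.0 * sd)[..., :, None, :]
    a = np.minimum(u, hi_a)           # (..., N, J, D)
    b = np.minimum(u, hi_b)

    xa, wa, xb, wb = _panel_nodes(*nodes)
    # quadrature abscissae s and weights, concatenated over both panels
    s_a = a[..., None] * xa           # (..., N, J, D, Qa)
    s_b = a[..., None] + (b - a)[..., None] * xb
    s = np.concatenate([s_a, s_b], axis=-1)
    w = np.concatenate(
        [a[..., None] * wa, (b - a)[..., None] * wb], axis=-1
    )

    with np.errstate(invalid="ignore", divide="ignore"):
        log_erlang = (
            shape * np.log(ktr_e[..., None])
            + n_transit * np.log(s)
            - ktr_e[..., None] * s
            - gammaln(shape)
        )
        g = np.exp(log_erlang)
        resp = _depot_response(u[..., None] - s, ka_e[..., None],
                               lam_e, coef_e)
        integral = np.einsum("...q,...q->...", w, g * resp)

    contrib = F[..., :, None, :] * dose_amt[:, None, :] * integral
    contrib = np.where(active, contrib, 0.0)
    conc = contrib.sum(axis=-1) / v[..., None]
    return conc


def transit_conc_chain(obs_time, dose_time, dose_amt, F, ka, mtt, n_transit,
                       v, cl, q=None, vratio=None):
    """Concentrations by exact integration of the full compartment chain.

    Scalar-parameter reference implementation (one subject).  The linear
    system -- dosing compartment, n transit compartments, depot, central
    and optional peripheral compartment -- is propagated with the matrix
    exponential from each dose and superposed.

    ``F``, ``ka``, ``mtt`` may be scalars or per-dose sequences.
    """
    obs_time = np.atleast_1d(np.asarray(obs_time, dtype=float))
    dose_time = np.atleast_1d(np.asarray(dose_time, dtype=float))
    dose_amt = np.atleast_1d(np.asarray(dose_amt, dtype=float))
    ndose = len(dose_time)
    F = np.broadcast_to(np.asarray(F, dtype=float), (ndose,))
    ka = np.broadcast_to(np.asarray(ka, dtype=float), (ndose,))
    mtt = np.broadcast_to(np.asarray(mtt, dtype=float), (ndose,))

    two_cpt = q is not None
    nchain = n_transit + 1
    dim = nchain + 2 + (1 if two_cpt else 0)
    ke = cl / v
    if two_cpt:
        vp = v / vratio
        kcp = q / v
        kpc = q / vp

    conc = np.zeros_like(obs_time)
    for d in range(ndose):
        if not np.isfinite(dose_amt[d]) or dose_amt[d] <= 0:
            continue
        ktr = nchain / mtt[d]
        A = np.zeros((dim, dim))
        for i in range(nchain):
            A[i, i] = -ktr
            A[i + 1, i] = ktr
        idep, icen = nchain, nchain + 1
        A[idep, idep] = -ka[d]
        A[icen, idep] = ka[d]
        A[icen, icen] = -ke
        if two_cpt:
            iper = nchain + 2
            A[icen, icen] -= kcp
            A[iper, icen] = kcp
            A[icen, iper] = kpc
            A[iper, iper] = -kpc
        x0 = np.zeros(dim)
        x0[0] = F[d] * dose_amt[d]
        for j, t in enumerate(obs_time):
            dt = t - dose_time[d]
            if dt <= 0:
                continue
            conc[j] += (expm(A * dt) @ x0)[icen] / v
    return conc
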
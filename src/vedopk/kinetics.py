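"""Closed-form two-compartment infusion kinetics on piecewise-constant parameters.

The central object is a *segment grid*: a subject's timeline is cut at every
dose start, infusion end, and parameter-change knot, so that within one
segment the infusion rate and the micro rate constants (k10, k12, k21) are
constant.  Within a segment the linear two-compartment system

    dA1/dt = R - (k10 + k12) A1 + k21 A2
    dA2/dt = k12 A1 - k21 A2

has the exact solution A(t) = Ap + exp(M t) (A0 - Ap), where Ap is the
steady-state particular solution under constant input R and exp(M t) is the
2x2 matrix exponential written in terms of the macro eigenvalues.  State is
carried across segment boundaries on the concentration scale: when a volume
changes between segments the amounts are rescaled by the volume ratio so
that concentrations stay continuous (a piecewise-constant volume stands in
for a smoothly drifting one, which does not dilute instantaneously).  The
solution is exact to machine precision within every segment.

Units: amounts mg, volumes L, clearances L/day, times days.  Because
1 mg/L = 1 ug/mL, dividing a central amount in mg by Vc in L yields the
concentration directly in ug/mL (the 10^3 ug/mg and 10^3 mL/L factors
cancel).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "profile_linear",
    "profile_mm_ode",
    "macro_eigenvalues",
    "HAVE_NUMBA",
]

# relative eigenvalue gap below which the repeated-root (L'Hopital) branch
# of the matrix exponential is used
_DEGENERATE_TOL = 1e-10


def macro_eigenvalues(cl: float, vc: float, q: float, vp: float) -> tuple[float, float]:
    """Macro disposition rate constants (lambda1 >= lambda2 > 0) in 1/day."""
    k10 = cl / vc
    k12 = q / vc
    k21 = q / vp
    a = k10 + k12 + k21
    # discriminant = (k10 + k12 - k21)^2 + 4 k12 k21 >= 0 always
    disc = math.sqrt(max(a * a - 4.0 * k10 * k21, 0.0))
    lam1 = 0.5 * (a + disc)
    lam2 = 0.5 * (a - disc)
    return lam1, lam2


def _step_linear(a1, a2, tau, rate, k10, k12, k21):
    """Advance compartment amounts by tau under constant rate and constants."""
    if tau <= 0.0:
        return a1, a2
    if k12 < 1e-14 and k21 < 1e-14:
        # peripheral compartment decoupled: plain one-compartment kinetics
        e = math.exp(-k10 * tau)
        ass = rate / k10 if rate != 0.0 else 0.0
        return ass + (a1 - ass) * e, a2
    tr = -(k10 + k12 + k21)
    det = k10 * k21
    disc = math.sqrt(max(tr * tr - 4.0 * det, 0.0))
    mu1 = 0.5 * (tr + disc)
    mu2 = 0.5 * (tr - disc)
    # particular (steady-state) solution under constant input
    if rate != 0.0:
        p1 = rate / k10
        p2 = rate * k12 / det
    else:
        p1 = 0.0
        p2 = 0.0
    b1 = a1 - p1
    b2 = a2 - p2
    m11 = -(k10 + k12)
    m22 = -k21
    if disc > _DEGENERATE_TOL * abs(mu1):
        e1 = math.exp(mu1 * tau)
        e2 = math.exp(mu2 * tau)
        # exp(M tau) = [e1 (M - mu2 I) - e2 (M - mu1 I)] / (mu1 - mu2)
        inv = 1.0 / (mu1 - mu2)
        c11 = (e1 * (m11 - mu2) - e2 * (m11 - mu1)) * inv
        c12 = (e1 - e2) * k21 * inv
        c21 = (e1 - e2) * k12 * inv
        c22 = (e1 * (m22 - mu2) - e2 * (m22 - mu1)) * inv
    else:
        # repeated eigenvalue limit: exp(M tau) = e^{mu tau} (I + tau (M - mu I))
        mu = 0.5 * (mu1 + mu2)
        e = math.exp(mu * tau)
        c11 = e * (1.0 + tau * (m11 - mu))
        c12 = e * tau * k21
        c21 = e * tau * k12
        c22 = e * (1.0 + tau * (m22 - mu))
    return p1 + c11 * b1 + c12 * b2, p2 + c21 * b1 + c22 * b2


def _profile_kernel(bounds, rates, cls, vcs, qs, vps, obs_seg, obs_tau, out):
    """Sequential state propagation over the segment grid.

    bounds    : (nseg + 1,) segment boundary times, ascending
    rates     : (nseg,) infusion rate in each segment (mg/day)
    cls...vps : (nseg,) disposition parameters per segment
    obs_seg   : (nobs,) segment index of each observation, ascending
    obs_tau   : (nobs,) observation time minus its segment's start
    out       : (nobs,) concentrations (ug/mL), written in place
    """
    a1 = 0.0
    a2 = 0.0
    j = 0
    nobs = obs_seg.shape[0]
    nseg = rates.shape[0]
    for i in range(nseg):
        if i > 0:  # concentration-continuous hand-off across volume changes
            a1 *= vcs[i] / vcs[i - 1]
            a2 *= vps[i] / vps[i - 1]
        k10 = cls[i] / vcs[i]
        k12 = qs[i] / vcs[i]
        k21 = qs[i] / vps[i]
        while j < nobs and obs_seg[j] == i:
            o1, _ = _step_linear(a1, a2, obs_tau[j], rates[i], k10, k12, k21)
            out[j] = o1 / vcs[i]
            j += 1
        a1, a2 = _step_linear(a1, a2, bounds[i + 1] - bounds[i], rates[i], k10, k12, k21)
    return a1, a2


def _individual_profile_kernel(
    bounds, rates, base_lcl, base_lvc, base_lvp, q, seg_level, obs_seg, obs_tau,
    psi, out
):
    """Fused kernel: segment parameters from random effects, then propagation.

    base_l* hold the log typical value plus covariate contributions per
    segment; psi = (eta_cl, eta_vc, eta_vp, kappa_1..); seg_level maps each
    segment to its kappa index (-1 before the first dose).
    """
    a1 = 0.0
    a2 = 0.0
    j = 0
    nobs = obs_seg.shape[0]
    nseg = rates.shape[0]
    vc_prev = 0.0
    vp_prev = 0.0
    for i in range(nseg):
        kap = psi[3 + seg_level[i]] if seg_level[i] >= 0 else 0.0
        cl = math.exp(base_lcl[i] + psi[0] + kap)
        vc = math.exp(base_lvc[i] + psi[1])
        vp = math.exp(base_lvp[i] + psi[2])
        if i > 0:  # concentration-continuous hand-off across volume changes
            a1 *= vc / vc_prev
            a2 *= vp / vp_prev
        vc_prev = vc
        vp_prev = vp
        k10 = cl / vc
        k12 = q[i] / vc
        k21 = q[i] / vp
        while j < nobs and obs_seg[j] == i:
            o1, _ = _step_linear(a1, a2, obs_tau[j], rates[i], k10, k12, k21)
            out[j] = o1 / vc
            j += 1
        a1, a2 = _step_linear(a1, a2, bounds[i + 1] - bounds[i], rates[i], k10, k12, k21)


try:  # optional acceleration; the pure-Python path is the reference
    import numba as _numba

    _step_linear = _numba.njit(cache=False)(_step_linear)
    _profile_kernel = _numba.njit(cache=False)(_profile_kernel)
    _individual_profile_kernel = _numba.njit(cache=False)(_individual_profile_kernel)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba present in supported envs
    HAVE_NUMBA = False


def profile_linear(
    bounds: np.ndarray,
    rates: np.ndarray,
    cl: np.ndarray,
    vc: np.ndarray,
    q: np.ndarray,
    vp: np.ndarray,
    obs_times: np.ndarray,
) -> np.ndarray:
    """Concentrations (ug/mL) at ``obs_times`` for one subject.

    Parameters are per-segment arrays over the grid defined by ``bounds``;
    observations at or past the last boundary are evaluated by extending the
    final segment.  Observation times must be ascending and >= bounds[0].
    """
    bounds = np.asarray(bounds, dtype=np.float64)
    obs_times = np.asarray(obs_times, dtype=np.float64)
    nseg = len(rates)
    if bounds.shape[0] != nseg + 1:
        raise ValueError("bounds must have one more entry than segments")
    if obs_times.size and obs_times[0] < bounds[0]:
        raise ValueError("observation before the start of the timeline")
    obs_seg = np.minimum(np.searchsorted(bounds, obs_times, side="right") - 1, nseg - 1)
    obs_tau = obs_times - bounds[obs_seg]
    out = np.empty(obs_times.shape[0], dtype=np.float64)
    _profile_kernel(
        bounds,
        np.ascontiguousarray(rates, dtype=np.float64),
        np.ascontiguousarray(cl, dtype=np.float64),
        np.ascontiguousarray(vc, dtype=np.float64),
        np.ascontiguousarray(q, dtype=np.float64),
        np.ascontiguousarray(vp, dtype=np.float64),
        obs_seg.astype(np.int64),
        obs_tau,
        out,
    )
    return out


def profile_mm_ode(
    bounds: np.ndarray,
    rates: np.ndarray,
    cl: np.ndarray,
    vc: np.ndarray,
    q: np.ndarray,
    vp: np.ndarray,
    obs_times: np.ndarray,
    vmax: float = 0.0,
    km: float = 1.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Numerical profile with parallel linear + Michaelis-Menten elimination.

    The saturable pathway removes drug from the central compartment at
    Vmax * C / (Km + C) (mg/day with Vmax in mg/day, C in ug/mL); with
    vmax = 0 this reduces to the linear model and serves as its ODE oracle.
    Integration proceeds segment by segment so parameter and rate
    discontinuities fall on integrator restarts.  Raises RuntimeError if the
    solver fails rather than returning NaN.
    """
    if km <= 0:
        raise ValueError("km must be positive")
    if vmax < 0:
        raise ValueError("vmax must be non-negative")
    bounds = np.asarray(bounds, dtype=np.float64)
    obs_times = np.asarray(obs_times, dtype=np.float64)
    nseg = len(rates)
    end = max(bounds[-1], obs_times.max() if obs_times.size else bounds[-1])
    ext_bounds = bounds.copy()
    ext_bounds[-1] = end + 1e-9
    obs_seg = np.minimum(np.searchsorted(bounds, obs_times, side="right") - 1, nseg - 1)

    out = np.empty(obs_times.shape[0], dtype=np.float64)
    state = np.zeros(2)
    for i in range(nseg):
        if i > 0:  # concentration-continuous hand-off across volume changes
            state[0] *= vc[i] / vc[i - 1]
            state[1] *= vp[i] / vp[i - 1]
        t0, t1 = ext_bounds[i], ext_bounds[i + 1]
        k12 = q[i] / vc[i]
        k21 = q[i] / vp[i]

        def rhs(_t, y, r=rates[i], cli=cl[i], vci=vc[i], k12=k12, k21=k21):
            c = y[0] / vci
            elim = cli * c + vmax * c / (km + c)
            return (r - elim - k12 * y[0] + k21 * y[1], k12 * y[0] - k21 * y[1])

        sel = obs_seg == i
        t_eval = obs_times[sel]
        sol = solve_ivp(
            rhs,
            (t0, t1),
            state,
            method="LSODA",
            t_eval=np.concatenate([t_eval, [t1]]),
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"ODE solver failed on segment {i}: {sol.message}")
        out[sel] = sol.y[0, :-1] / vc[i]
        state = sol.y[:, -1]
    return out
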
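"""FOCE-I estimation of the population model, with EBEs and derived statistics.

The marginal likelihood of each subject's data is approximated by the
first-order conditional method with interaction: the joint random-effect
vector psi = (eta_CL, eta_Vc, eta_Vp, kappa_1..kappa_m) is set to its
conditional mode psi-hat (inner optimization), the subject's prediction
function is linearized there, and the residual variance is evaluated at the
conditional predictions (the "interaction" part).  Writing F for the
Jacobian of predictions at psi-hat, v for the residual variances and
r = y - f(psi-hat) + F psi-hat, the contribution is

    -2 ll_i = n_i log 2pi + log|V_i| + r' V_i^{-1} r,
    V_i = diag(v) + F Omega F'.

The outer problem minimizes the total objective over an unconstrained
reparameterization (log scale for positive parameters, log-Cholesky for the
IIV block), so positivity and positive-definiteness hold by construction.
Standard errors come from the finite-difference Hessian of the objective at
the optimum, mapped to the natural scale by the delta method.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from . import kinetics
from .data import TrialDataset
from .model import (
    REFERENCE,
    ModelParams,
    VarianceComponents,
    occasion_levels,
)

__all__ = [
    "FitResult",
    "FitError",
    "foce_objective",
    "fit",
    "compare_models",
    "empirical_bayes",
    "cv_percent",
    "corr_from_cov",
    "ci95_lognormal",
    "ci95_symmetric",
    "DEFAULT_ESTIMATE",
]

_ETA_DIM = 3
_LOG2PI = math.log(2.0 * math.pi)

#: parameters estimated by default: structural typical values, the estimated
#: covariate exponents of the final model, and all variance components
DEFAULT_ESTIMATE = (
    "cl_ref",
    "vc_ref",
    "q_ref",
    "vp_ref",
    "wt_on_cl",
    "wt_on_vc",
    "alb_on_cl",
    "age_on_cl",
    "omega",
    "omega_iov_cl",
    "sigma_prop",
)


class FitError(RuntimeError):
    """Estimation failure with subject-level context."""


# ---------------------------------------------------------------------------
# compiled per-subject design


class _CompiledSubject:
    """Static per-subject arrays for fast repeated prediction.

    The timeline is cut at dose starts, infusion ends and covariate-change
    rows; segment covariates are the values in force at the segment start
    (the table is NOCB-filled at assembly, so row values carried forward
    reproduce the NOCB covariate in force between rows).
    """

    def __init__(self, sid: int, sub: pd.DataFrame):
        self.id = sid
        dose = sub[sub["EVID"] == 1]
        obs = sub[(sub["EVID"] == 0) & (sub["MDV"] == 0)]
        self.dose_times = dose["TIME"].to_numpy(float)
        amounts = dose["AMT"].to_numpy(float)
        rates = dose["RATE"].to_numpy(float)
        if np.any(rates <= 0):
            raise FitError(f"subject {sid}: dose rows need RATE > 0")
        ends = self.dose_times + amounts / rates
        self.y = obs["DV"].to_numpy(float)
        self.obs_times = obs["TIME"].to_numpy(float)
        self.n_obs = self.y.size

        levels, self.n_kappa = occasion_levels(self.dose_times, self.obs_times)
        self.n_psi = _ETA_DIM + self.n_kappa

        row_t = sub["TIME"].to_numpy(float)
        cov_cols = sub[["WT", "ALB", "AGE", "LYM", "GVHDL", "GVHDS", "GVHDI"]]
        cov_vals = cov_cols.to_numpy(float)
        changed = np.ones(len(sub), bool)
        changed[1:] = np.any(np.diff(cov_vals, axis=0) != 0.0, axis=1)

        knots = np.unique(
            np.concatenate([self.dose_times, ends, row_t[changed]])
        )
        start = min(knots[0], self.obs_times.min() if self.n_obs else knots[0])
        cuts = knots[knots > start]
        end = max(
            cuts[-1] if cuts.size else start,
            self.obs_times.max() if self.n_obs else start,
        ) + 1.0
        self.bounds = np.ascontiguousarray(
            np.concatenate([[start], cuts, [end]])
        )
        nseg = self.bounds.size - 1
        mids = 0.5 * (self.bounds[:-1] + self.bounds[1:])

        seg_rate = np.zeros(nseg)
        for t0, t1, r in zip(self.dose_times, ends, rates):
            seg_rate[(mids >= t0) & (mids < t1)] += r
        self.rates = np.ascontiguousarray(seg_rate)

        idx = np.clip(np.searchsorted(row_t, mids, side="right") - 1, 0, len(sub) - 1)
        cv = cov_vals[idx]
        self.lwt = np.log(cv[:, 0] / REFERENCE.weight)
        self.lalb = np.log(cv[:, 1] / REFERENCE.albumin)
        self.lage = np.log(cv[:, 2] / REFERENCE.age)
        self.llym = np.log(cv[:, 3] / REFERENCE.lymphocytes)
        self.gvhd = cv[:, 4:7]  # liver, skin, gut indicators per segment

        # kappa level of each segment (-1 before the first dose)
        d_idx = np.searchsorted(self.dose_times, mids, side="right") - 1
        self.seg_level = np.ascontiguousarray(
            np.where(d_idx >= 0, levels[np.maximum(d_idx, 0)], -1), dtype=np.int64
        )

        self.obs_seg = np.minimum(
            np.searchsorted(self.bounds, self.obs_times, side="right") - 1, nseg - 1
        ).astype(np.int64)
        self.obs_tau = np.ascontiguousarray(self.obs_times - self.bounds[self.obs_seg])

        # filled by set_params
        self._base_lcl = None
        self._base_lvc = None
        self._q = None
        self._base_lvp = None
        self._mm = None

    def set_params(self, p: ModelParams) -> None:
        """Cache the psi-independent part of the segment parameters."""
        th, cf = p.theta, p.coeffs
        self._base_lcl = (
            math.log(th.cl_ref)
            + cf.wt_on_cl * self.lwt
            + cf.alb_on_cl * self.lalb
            + cf.age_on_cl * self.lage
            + cf.lym_on_cl * self.llym
            + self.gvhd @ np.log(
                [cf.gvhd_liver_on_cl, cf.gvhd_skin_on_cl, cf.gvhd_gut_on_cl]
            )
        )
        self._base_lcl = np.ascontiguousarray(self._base_lcl)
        self._base_lvc = np.ascontiguousarray(
            math.log(th.vc_ref) + cf.wt_on_vc * self.lwt
        )
        self._q = np.ascontiguousarray(np.exp(math.log(th.q_ref) + cf.wt_on_q * self.lwt))
        self._base_lvp = np.ascontiguousarray(
            math.log(th.vp_ref) + cf.wt_on_vp * self.lwt
        )
        self._mm = (th.vmax, th.km) if th.vmax is not None else None

    def predict(self, psi: np.ndarray) -> np.ndarray:
        """Concentrations at the fitting observations for random effects psi."""
        if self._mm is not None:
            kap = np.where(
                self.seg_level >= 0,
                np.concatenate([psi[_ETA_DIM:], [0.0]])[np.maximum(self.seg_level, 0)],
                0.0,
            )
            cl = np.exp(self._base_lcl + psi[0] + kap)
            vc = np.exp(self._base_lvc + psi[1])
            vp = np.exp(self._base_lvp + psi[2])
            return kinetics.profile_mm_ode(
                self.bounds, self.rates, cl, vc, self._q, vp, self.obs_times,
                vmax=self._mm[0], km=self._mm[1], rtol=1e-8,
            )
        out = np.empty(self.n_obs)
        kinetics._individual_profile_kernel(
            self.bounds, self.rates, self._base_lcl, self._base_lvc,
            self._base_lvp, self._q, self.seg_level, self.obs_seg, self.obs_tau,
            psi, out,
        )
        return out

    def jacobian(self, psi: np.ndarray, f0: np.ndarray, h: float = 1e-5) -> np.ndarray:
        """Forward-difference Jacobian of predictions w.r.t. psi."""
        F = np.empty((self.n_obs, self.n_psi))
        for k in range(self.n_psi):
            pk = psi.copy()
            pk[k] += h
            F[:, k] = (self.predict(pk) - f0) / h
        return F


def _compile(dataset: TrialDataset, require_obs: bool = True) -> list[_CompiledSubject]:
    subs = []
    for sid, grp in dataset.df.groupby("ID", sort=True):
        if (grp["EVID"] == 1).sum() == 0:
            continue  # no dose: nothing to predict
        subs.append(_CompiledSubject(int(sid), grp))
    if require_obs and not any(s.n_obs for s in subs):
        raise FitError("dataset has no subject with dosed, quantifiable data")
    return subs


# ---------------------------------------------------------------------------
# inner problem and FOCE-I contribution


def _omega_full(var: VarianceComponents, n_kappa: int) -> np.ndarray:
    om = np.zeros((_ETA_DIM + n_kappa, _ETA_DIM + n_kappa))
    om[:_ETA_DIM, :_ETA_DIM] = var.omega
    if n_kappa:
        om[_ETA_DIM:, _ETA_DIM:] = var.omega_iov_cl * np.eye(n_kappa)
    return om


def _inner_objective(sub, psi, y, om_inv_a, active, sig_a, sig_p):
    if np.max(np.abs(psi), initial=0.0) > 30.0:  # e^30-fold effect: reject
        return math.inf, None, None, None
    f = sub.predict(psi)
    if not np.all(np.isfinite(f)):
        return math.inf, None, None, None
    v = sig_a + sig_p * f * f
    if v.size and float(v.min()) < 1e-100:  # zero residual variance row
        return math.inf, None, None, None
    r = y - f
    pa = psi[active]
    g = float(((r * r) / v).sum() + np.log(v).sum() + pa @ om_inv_a @ pa)
    return (g if math.isfinite(g) else math.inf), f, v, r


def _solve_inner(
    sub: _CompiledSubject,
    var: VarianceComponents,
    psi0: np.ndarray,
    max_iter: int = 60,
    gtol: float = 1e-6,
    dtol: float = 1e-9,
):
    """Conditional mode of the random effects (damped chord Gauss-Newton).

    Inactive dimensions (zero prior variance) are pinned at 0.  The
    prediction Jacobian is frozen between refreshes (every few accepted
    steps, or when the line search stalls) and recomputed at the final
    mode, where the FOCE linearization needs it.  Returns
    (psi_hat, f, F, v, converged).
    """
    om = _omega_full(var, sub.n_kappa)
    d = np.diag(om)
    active = d > 1e-12
    sig_a, sig_p = var.sigma_add, var.sigma_prop
    if sig_a <= 0 and sig_p <= 0:
        raise FitError("residual variance must be positive")
    psi = np.where(active, psi0, 0.0)
    y = sub.y

    if not active.any():
        f = sub.predict(psi)
        F = sub.jacobian(psi, f)
        v = sig_a + sig_p * f * f
        return psi, f, F, v, True

    om_a = om[np.ix_(active, active)]
    om_inv_a = np.linalg.inv(om_a)
    g, f, v, r = _inner_objective(sub, psi, y, om_inv_a, active, sig_a, sig_p)
    if not math.isfinite(g):  # unusable warm start
        psi = np.zeros_like(psi)
        g, f, v, r = _inner_objective(sub, psi, y, om_inv_a, active, sig_a, sig_p)
        if not math.isfinite(g):
            return psi, f, sub.jacobian(psi, f), v, False
    F = sub.jacobian(psi, f)
    converged = False
    gnorm = math.inf
    stale = 0
    it = 0
    while it < max_iter:
        it += 1
        Fa = F[:, active]
        w = 1.0 / v
        # exact gradient of the joint -2 log density (interaction terms kept)
        dv = 2.0 * sig_p * f[:, None] * Fa  # d v / d psi_a
        grad = (
            -2.0 * Fa.T @ (w * r)
            - dv.T @ (w * w * r * r)
            + dv.T @ w
            + 2.0 * om_inv_a @ psi[active]
        )
        gnorm = float(np.max(np.abs(grad)))
        if gnorm < gtol:
            converged = True
            break
        H = 2.0 * (Fa.T * w) @ Fa + 2.0 * om_inv_a  # Gauss-Newton, SPD
        step = np.linalg.solve(H + 1e-10 * np.eye(H.shape[0]), -grad)
        # Newton decrement: expected objective decrease from this step
        if -0.5 * float(grad @ step) < dtol * (1.0 + abs(g)):
            converged = True
            break
        big = np.max(np.abs(step))
        if big > 4.0:  # trust region: random effects live on the log scale
            step *= 4.0 / big
        alpha = 1.0
        for _ls in range(12):
            trial = psi.copy()
            trial[active] += alpha * step
            g_t, f_t, v_t, r_t = _inner_objective(
                sub, trial, y, om_inv_a, active, sig_a, sig_p
            )
            if g_t < g - 1e-12:
                psi, g, f, v, r = trial, g_t, f_t, v_t, r_t
                stale += 1
                if stale >= 3 or alpha < 1.0:
                    F = sub.jacobian(psi, f)
                    stale = 0
                break
            alpha *= 0.5
        else:  # line search stalled
            if stale:  # the chord Jacobian may be stale: refresh and retry
                F = sub.jacobian(psi, f)
                stale = 0
                continue
            converged = True  # fresh Jacobian and still no descent: optimum
            break
    if stale:  # the FOCE linearization needs the Jacobian at the mode
        F = sub.jacobian(psi, f)
        Fa = F[:, active]
        w = 1.0 / v
        dv = 2.0 * sig_p * f[:, None] * Fa
        grad = (
            -2.0 * Fa.T @ (w * r) - dv.T @ (w * w * r * r) + dv.T @ w
            + 2.0 * om_inv_a @ psi[active]
        )
        gnorm = float(np.max(np.abs(grad)))
        if gnorm < gtol:
            converged = True
    # a mode located to moderate gradient accuracy is still usable (the
    # marginal approximation degrades smoothly); flag only gross failure
    if not converged:
        converged = gnorm < max(1.0, 1e-6 * abs(g))
    return psi, f, F, v, converged


def _foce_contribution(sub, var, psi_hat, f, F, v):
    """-2 log-likelihood contribution of one subject given its mode."""
    om = _omega_full(var, sub.n_kappa)
    d = np.diag(om)
    active = d > 1e-12
    r = sub.y - f
    if active.any():
        Fa = F[:, active]
        om_a = om[np.ix_(active, active)]
        V = np.diag(v) + Fa @ om_a @ Fa.T
        r = r + Fa @ psi_hat[active]
    else:
        V = np.diag(v)
    try:
        c, low = (np.linalg.cholesky(V), True)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"subject {sub.id}: non-PD marginal covariance") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    z = np.linalg.solve(c, r)
    return sub.n_obs * _LOG2PI + logdet + float(z @ z)


def _foce_total(subs, params, psi_cache, dtol: float = 1e-9):
    total = 0.0
    failed = []
    for sub in subs:
        key = sub.id
        sub.set_params(params)
        psi0 = psi_cache.get(key, np.zeros(sub.n_psi))
        psi, f, F, v, ok = _solve_inner(sub, params.variance, psi0, dtol=dtol)
        if (not ok or f is None or not np.all(np.isfinite(f))) and np.any(psi0):
            # a stale warm start can sit in a bad basin: retry from the prior mode
            psi, f, F, v, ok = _solve_inner(
                sub, params.variance, np.zeros(sub.n_psi), dtol=dtol
            )
        if not ok or f is None or not np.all(np.isfinite(f)):
            failed.append(sub.id)
            continue
        psi_cache[key] = psi
        total += _foce_contribution(sub, params.variance, psi, f, F, v)
    if failed:
        raise FitError(f"inner optimization failed for subjects {failed}")
    return total


def foce_objective(dataset: TrialDataset, params: ModelParams) -> float:
    """FOCE-I objective (-2 log-likelihood approximation) for the dataset.

    Deterministic given inputs.  BLQ/MDV-flagged observations are not part
    of the likelihood (M1 handling); subjects whose inner optimization
    fails raise :class:`FitError` rather than being silently dropped.
    """
    subs = _compile(dataset)
    return _foce_total(subs, params, {})


# ---------------------------------------------------------------------------
# outer parameterization


_LOG_NAMES = {"cl_ref", "vc_ref", "q_ref", "vp_ref", "vmax", "km",
              "omega_iov_cl", "sigma_prop", "sigma_add",
              "gvhd_liver_on_cl", "gvhd_skin_on_cl", "gvhd_gut_on_cl"}
_IDENT_NAMES = {"wt_on_cl", "wt_on_vc", "alb_on_cl", "age_on_cl", "lym_on_cl"}
_THETA_FIELDS = {"cl_ref", "vc_ref", "q_ref", "vp_ref", "vmax", "km"}
_VAR_FIELDS = {"omega_iov_cl", "sigma_prop", "sigma_add"}


class _Transform:
    """Bijective map between estimated parameters and an unconstrained vector."""

    def __init__(self, estimate: tuple[str, ...]):
        for name in estimate:
            if name != "omega" and name not in _LOG_NAMES | _IDENT_NAMES:
                raise ValueError(f"unknown parameter name: {name}")
        self.estimate = tuple(estimate)
        self.labels: list[str] = []
        for name in self.estimate:
            if name == "omega":
                self.labels += [
                    "omega_chol_11", "omega_chol_21", "omega_chol_22",
                    "omega_chol_31", "omega_chol_32", "omega_chol_33",
                ]
            else:
                self.labels.append(name)
        self.n = len(self.labels)

    def to_vector(self, p: ModelParams) -> np.ndarray:
        x = []
        for name in self.estimate:
            if name == "omega":
                L = np.linalg.cholesky(p.variance.omega + 1e-12 * np.eye(3))
                x += [math.log(L[0, 0]), L[1, 0], math.log(L[1, 1]),
                      L[2, 0], L[2, 1], math.log(L[2, 2])]
            else:
                v = self._get(p, name)
                x.append(math.log(v) if name in _LOG_NAMES else v)
        return np.array(x)

    def to_params(self, x: np.ndarray, template: ModelParams) -> ModelParams:
        th, cf, var = template.theta, template.coeffs, template.variance
        th_kw, cf_kw, var_kw = {}, {}, {}
        i = 0
        for name in self.estimate:
            if name == "omega":
                l11, l21, l22, l31, l32, l33 = x[i : i + 6]
                L = np.array(
                    [
                        [math.exp(l11), 0.0, 0.0],
                        [l21, math.exp(l22), 0.0],
                        [l31, l32, math.exp(l33)],
                    ]
                )
                var_kw["omega"] = L @ L.T
                i += 6
                continue
            v = math.exp(x[i]) if name in _LOG_NAMES else float(x[i])
            if name in _THETA_FIELDS:
                th_kw[name] = v
            elif name in _VAR_FIELDS:
                var_kw[name] = v
            else:
                cf_kw[name] = v
            i += 1
        return ModelParams(
            theta=replace(th, **th_kw) if th_kw else th,
            coeffs=replace(cf, **cf_kw) if cf_kw else cf,
            variance=replace(var, **var_kw) if var_kw else var,
        )

    @staticmethod
    def _get(p: ModelParams, name: str) -> float:
        for obj in (p.theta, p.coeffs, p.variance):
            if hasattr(obj, name):
                return float(getattr(obj, name))
        raise ValueError(name)


def _natural_summary_vector(p: ModelParams, estimate) -> tuple[list[str], np.ndarray]:
    """Reporting-scale parameter vector (variances/covariances for omega)."""
    names, vals = [], []
    for name in estimate:
        if name == "omega":
            om = p.variance.omega
            for lab, v in [
                ("omega_cl", om[0, 0]), ("omega_cl_vc", om[1, 0]),
                ("omega_vc", om[1, 1]), ("omega_cl_vp", om[2, 0]),
                ("omega_vc_vp", om[2, 1]), ("omega_vp", om[2, 2]),
            ]:
                names.append(lab)
                vals.append(v)
        else:
            names.append(name)
            vals.append(_Transform._get(p, name))
    return names, np.array(vals)


# ---------------------------------------------------------------------------
# fit driver and results


@dataclass
class FitResult:
    """Converged (or best-so-far) population estimates and their precision."""

    estimates: ModelParams
    ofv: float
    n_params: int
    n_obs: int
    summary: pd.DataFrame  # estimate, se, rse_percent, ci95 per reported parameter
    covariance: np.ndarray | None  # transformed (estimation) scale
    covariance_labels: list[str]
    ebes: pd.DataFrame
    shrinkage: dict
    converged: bool
    n_outer_iterations: int
    message: str
    data_signature: str = ""

    @property
    def aic(self) -> float:
        """Akaike information criterion: OFV + 2 x number of estimated parameters."""
        return self.ofv + 2.0 * self.n_params


def _signature(dataset: TrialDataset) -> str:
    obs = dataset.fitting_observations()
    h = hashlib.sha256()
    h.update(obs[["ID", "TIME", "DV"]].to_csv(index=False).encode())
    return h.hexdigest()


def fit(
    dataset: TrialDataset,
    init: ModelParams,
    estimate: tuple[str, ...] = DEFAULT_ESTIMATE,
    compute_covariance: bool = True,
    maxiter: int = 150,
    ftol: float = 1e-8,
    gtol: float = 0.5,
) -> FitResult:
    """Maximum-likelihood (FOCE-I) fit of the population model.

    ``estimate`` names the parameters optimized; everything else stays at
    its value in ``init`` (the fixed allometric exponents on Q and Vp are
    structurally fixed).  The outer optimizer is L-BFGS-B on the
    unconstrained scale with finite-difference gradients; per-subject
    conditional modes are warm-started across evaluations.  With
    ``compute_covariance`` the finite-difference Hessian of the objective
    at the optimum yields the covariance of estimates (2 H^-1), standard
    errors and RSE%; a singular Hessian leaves the covariance unavailable
    and suppresses CIs rather than failing.
    """
    subs = _compile(dataset)
    n_obs = int(sum(s.n_obs for s in subs))
    tr = _Transform(estimate)
    if n_obs < tr.n:
        raise FitError(f"{n_obs} observations cannot support {tr.n} parameters")
    x0 = tr.to_vector(init)
    psi_cache: dict = {}
    n_fail = [0]
    best = {"x": x0.copy(), "f": math.inf}

    def _eval(x, cache, dtol=1e-9):
        try:
            return _foce_total(subs, tr.to_params(x, init), cache, dtol=dtol)
        except (FitError, np.linalg.LinAlgError, ArithmeticError):
            n_fail[0] += 1
            return 1e12

    def objective(x):
        f = _eval(x, psi_cache)
        if f < best["f"]:
            best["f"] = f
            best["x"] = np.array(x)
        return f

    def gradient(x, h=1e-5):
        # every evaluation restarts the inner problems from one snapshot of
        # the conditional modes, so warm-start hysteresis cancels in the
        # differences and the gradient is deterministic given x
        snap = {k: v.copy() for k, v in psi_cache.items()}

        def ev(xx):
            # tight inner tolerance: residual mode jitter is second-order in
            # it, and the differences below divide by a small step
            return _eval(xx, {k: v.copy() for k, v in snap.items()}, dtol=1e-13)

        f0 = ev(x)
        g = np.empty(x.size)
        for i in range(x.size):
            xp = x.copy()
            xp[i] += h
            g[i] = (ev(xp) - f0) / h
        return g

    opts = dict(maxiter=maxiter, ftol=ftol, gtol=gtol, maxcor=20)
    res = optimize.minimize(objective, x0, jac=gradient, method="L-BFGS-B",
                            options=opts)
    if res.fun > best["f"] + 1e-6 or res.fun >= 1e11:
        # the optimizer strayed into a failing region; restart from the best
        # finite point seen so far
        res = optimize.minimize(objective, best["x"], jac=gradient,
                                method="L-BFGS-B", options=opts)
    x_hat = res.x if res.fun <= best["f"] + 1e-6 else best["x"]
    ofv = float(min(res.fun, best["f"]))
    params_hat = tr.to_params(x_hat, init)
    converged = bool(res.success) and ofv < 1e11
    message = str(res.message)

    cov = None
    se_nat = None
    nat_names, nat_vals = _natural_summary_vector(params_hat, estimate)
    if compute_covariance:
        objective(x_hat)  # refresh the mode cache at the optimum
        snap_h = {k: v.copy() for k, v in psi_cache.items()}

        def hess_ev(xx):
            return _eval(xx, {k: v.copy() for k, v in snap_h.items()}, dtol=1e-13)

        H = _fd_hessian(hess_ev, x_hat, h=1e-3)
        try:
            cov = 2.0 * np.linalg.inv(H)
            if np.any(np.diag(cov) <= 0):
                cov_ok = False
            else:
                cov_ok = True
        except np.linalg.LinAlgError:
            cov_ok = False
        if cov_ok:
            # delta method to the reporting scale
            J = np.empty((len(nat_vals), tr.n))
            h = 1e-6
            for k in range(tr.n):
                xk = x_hat.copy()
                xk[k] += h
                _, vals_k = _natural_summary_vector(tr.to_params(xk, init), estimate)
                J[:, k] = (vals_k - nat_vals) / h
            cov_nat = J @ cov @ J.T
            se_nat = np.sqrt(np.maximum(np.diag(cov_nat), 0.0))
        else:
            cov = None

    rows = []
    for i, (name, val) in enumerate(zip(nat_names, nat_vals)):
        se = float(se_nat[i]) if se_nat is not None else np.nan
        rse = 100.0 * se / abs(val) if se_nat is not None and val != 0 else np.nan
        # log-scale intervals for positive structural parameters; symmetric
        # intervals for variance components and exponents
        log_ci = name in ("cl_ref", "vc_ref", "q_ref", "vp_ref", "vmax", "km",
                          "gvhd_liver_on_cl", "gvhd_skin_on_cl", "gvhd_gut_on_cl")
        if se_nat is not None and log_ci and val > 0 and rse > 0:
            lo, hi = ci95_lognormal(val, rse)
        elif se_nat is not None:
            lo, hi = val - 1.96 * se, val + 1.96 * se
        else:
            lo = hi = np.nan
        rows.append(dict(parameter=name, estimate=val, se=se, rse_percent=rse,
                         ci95_lower=lo, ci95_upper=hi))
    summary = pd.DataFrame(rows)

    ebes, shrinkage = empirical_bayes(dataset, params_hat, _subs=subs)
    return FitResult(
        estimates=params_hat,
        ofv=ofv,
        n_params=tr.n,
        n_obs=n_obs,
        summary=summary,
        covariance=cov,
        covariance_labels=tr.labels,
        ebes=ebes,
        shrinkage=shrinkage,
        converged=converged,
        n_outer_iterations=int(res.nit),
        message=message,
        data_signature=_signature(dataset),
    )


def _fd_hessian(fun, x, base=None, h: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian (symmetrized)."""
    n = x.size
    f0 = fun(x) if base is None else base
    H = np.empty((n, n))
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        fp[i], fm[i] = fun(xp), fun(xm)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h**2
    for i in range(n):
        for j in range(i + 1, n):
            xpp = x.copy()
            xpp[[i, j]] += h
            fpp = fun(xpp)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0) / h**2
    return 0.5 * (H + H.T)


def compare_models(fit_linear: FitResult, fit_mm: FitResult):
    """Pick between the linear and linear+Michaelis-Menten fits by AIC.

    Both fits must be on the identical dataset.  A difference of less than
    2 AIC units is treated as a tie, resolved toward the model with fewer
    estimated parameters (parsimony).  Returns (preferred, delta_aic) with
    delta_aic = AIC(mm) - AIC(linear).
    """
    if fit_linear.data_signature != fit_mm.data_signature:
        raise ValueError("model comparison requires fits on the same dataset")
    delta = fit_mm.aic - fit_linear.aic
    if abs(delta) < 2.0:
        preferred = fit_linear if fit_linear.n_params <= fit_mm.n_params else fit_mm
    else:
        preferred = fit_linear if delta > 0 else fit_mm
    return preferred, float(delta)


def empirical_bayes(
    dataset: TrialDataset, estimates: ModelParams, _subs=None
) -> tuple[pd.DataFrame, dict]:
    """Conditional modes of the random effects and their shrinkage.

    Returns an EBE table (one row per subject: eta_cl, eta_vc, eta_vp, plus
    kappa_1..kappa_m occasion effects, NaN-padded) and shrinkage on the
    standard-deviation scale, 100 (1 - SD(ebe)/omega); a zero population
    variance leaves that shrinkage undefined (NaN).  Subjects with no
    quantifiable observations sit at the prior mode (0).
    """
    subs = _subs if _subs is not None else _compile(dataset, require_obs=False)
    var = estimates.variance
    max_k = max(s.n_kappa for s in subs)
    rows = []
    kappas_all = []
    for sub in subs:
        sub.set_params(estimates)
        psi, *_ , ok = _solve_inner(sub, var, np.zeros(sub.n_psi))
        if not ok:
            raise FitError(f"EBE estimation failed for subject {sub.id}")
        row = dict(ID=sub.id, eta_cl=psi[0], eta_vc=psi[1], eta_vp=psi[2])
        for k in range(max_k):
            row[f"kappa_{k + 1}"] = psi[_ETA_DIM + k] if k < sub.n_kappa else np.nan
        kappas_all.extend(psi[_ETA_DIM:])
        rows.append(row)
    ebes = pd.DataFrame(rows)

    shrinkage = {}
    for name, col, w2 in [
        ("eta_cl", "eta_cl", var.omega[0, 0]),
        ("eta_vc", "eta_vc", var.omega[1, 1]),
        ("eta_vp", "eta_vp", var.omega[2, 2]),
    ]:
        shrinkage[name] = (
            100.0 * (1.0 - ebes[col].std(ddof=1) / math.sqrt(w2))
            if w2 > 1e-12 and len(ebes) > 1
            else float("nan")
        )
    kap = np.asarray(kappas_all)
    shrinkage["kappa_cl"] = (
        100.0 * (1.0 - kap.std(ddof=1) / math.sqrt(var.omega_iov_cl))
        if var.omega_iov_cl > 1e-12 and kap.size > 1
        else float("nan")
    )
    return ebes, shrinkage


# ---------------------------------------------------------------------------
# derived reporting statistics


def cv_percent(variance_estimate: float, kind: str = "iiv") -> float:
    """Coefficient of variation (%) of a variance-scale estimate.

    ``kind="iiv"`` (log-normal inter-individual or inter-occasion
    variability): 100 sqrt(exp(w2) - 1).  ``kind="proportional"`` (residual
    proportional-error variance): 100 sqrt(s2).
    """
    if variance_estimate < 0:
        raise ValueError("variance must be non-negative")
    if kind == "iiv":
        return 100.0 * math.sqrt(math.expm1(variance_estimate))
    if kind == "proportional":
        return 100.0 * math.sqrt(variance_estimate)
    raise ValueError(f"unknown kind: {kind!r}")


def corr_from_cov(cov_ij: float, var_i: float, var_j: float) -> float:
    """Correlation implied by a covariance and two variances."""
    if var_i <= 0 or var_j <= 0:
        raise ValueError("variances must be positive")
    rho = cov_ij / math.sqrt(var_i * var_j)
    if abs(rho) > 1.0 + 1e-9:
        raise ValueError(f"inconsistent inputs: |corr| = {abs(rho):.4f} > 1")
    return float(np.clip(rho, -1.0, 1.0))


def ci95_lognormal(estimate: float, rse_percent: float) -> tuple[float, float]:
    """95% CI of a positive estimate on the log scale.

    (theta exp(-1.96 RSE/100), theta exp(+1.96 RSE/100)); as RSE -> 0 both
    bounds collapse to the estimate.
    """
    if estimate <= 0:
        raise ValueError("estimate must be positive")
    if rse_percent <= 0:
        raise ValueError("rse_percent must be positive")
    half = 1.96 * rse_percent / 100.0
    return estimate * math.exp(-half), estimate * math.exp(half)


def ci95_symmetric(estimate: float, se: float) -> tuple[float, float]:
    """Symmetric 95% CI, estimate +/- 1.96 SE (variance-component reporting)."""
    if se < 0:
        raise ValueError("se must be non-negative")
    return estimate - 1.96 * se, estimate + 1.96 * se


_REPORT_META = {
    "cl_ref": ("CL", "L/day"), "vc_ref": ("Vc", "L"),
    "q_ref": ("Q", "L/day"), "vp_ref": ("Vp", "L"),
    "vmax": ("Vmax", "mg/day"), "km": ("Km", "ug/mL"),
    "wt_on_cl": ("Weight on CL (exponent)", "-"),
    "wt_on_vc": ("Weight on Vc (exponent)", "-"),
    "alb_on_cl": ("Albumin on CL (exponent)", "-"),
    "age_on_cl": ("Age on CL (exponent)", "-"),
    "lym_on_cl": ("Lymphocytes on CL (exponent)", "-"),
    "omega_cl": ("IIV CL (variance)", "-"),
    "omega_vc": ("IIV Vc (variance)", "-"),
    "omega_vp": ("IIV Vp (variance)", "-"),
    "omega_cl_vc": ("IIV cov CL-Vc", "-"),
    "omega_cl_vp": ("IIV cov CL-Vp", "-"),
    "omega_vc_vp": ("IIV cov Vc-Vp", "-"),
    "omega_iov_cl": ("IOV CL (variance)", "-"),
    "sigma_prop": ("Proportional residual (variance)", "-"),
    "sigma_add": ("Additive residual (variance)", "-"),
}


def format_report(res: FitResult) -> str:
    """Parameter report in the layout of a published estimates table.

    One line per reported parameter: estimate, 95% CI, RSE%, and for
    variance components the derived CV% / correlations; shrinkage on the
    SD scale is appended per random effect.
    """
    lines = [
        "Population PK parameter estimates (FOCE-I)",
        f"OFV {res.ofv:.3f}   AIC {res.aic:.3f}   "
        f"n_params {res.n_params}   n_obs {res.n_obs}",
        "-" * 78,
        f"{'Parameter':34s} {'Estimate':>10s} {'95% CI':>20s} {'RSE%':>6s}",
    ]
    var = res.estimates.variance
    om = var.omega
    extras = {
        "omega_cl": f"CV% = {cv_percent(om[0, 0]):.1f}",
        "omega_vc": f"CV% = {cv_percent(om[1, 1]):.1f}",
        "omega_vp": f"CV% = {cv_percent(om[2, 2]):.1f}",
        "omega_iov_cl": f"CV% = {cv_percent(var.omega_iov_cl):.1f}",
        "sigma_prop": f"CV% = {cv_percent(var.sigma_prop, 'proportional'):.1f}",
    }
    for key, (i, j) in [("omega_cl_vc", (1, 0)), ("omega_cl_vp", (2, 0)),
                        ("omega_vc_vp", (2, 1))]:
        if om[i, i] > 0 and om[j, j] > 0:
            extras[key] = f"Corr = {corr_from_cov(om[i, j], om[i, i], om[j, j]):.3f}"
    for _, row in res.summary.iterrows():
        name = row["parameter"]
        label, unit = _REPORT_META.get(name, (name, "-"))
        ci = (
            f"{row['ci95_lower']:.4g}-{row['ci95_upper']:.4g}"
            if np.isfinite(row["ci95_lower"])
            else "n/a"
        )
        rse = f"{row['rse_percent']:.3g}" if np.isfinite(row["rse_percent"]) else "n/a"
        extra = f"  [{extras[name]}]" if name in extras else ""
        lines.append(
            f"{label:34s} {row['estimate']:>10.4g} {ci:>20s} {rse:>6s}"
            f" {unit}{extra}"
        )
    lines.append("-" * 78)
    for k, v in res.shrinkage.items():
        lines.append(f"Shrinkage {k}: {v:.1f}%" if np.isfinite(v) else f"Shrinkage {k}: n/a")
    lines.append(f"Converged: {res.converged} ({res.message})")
    return "\n".join(lines)
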
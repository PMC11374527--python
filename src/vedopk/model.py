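"""Structural and statistical population-PK model for IV vedolizumab.

Disposition is a two-compartment model with zero-order (infusion) input and
linear elimination, parameterized as clearance CL, central volume Vc,
intercompartmental clearance Q and peripheral volume Vp.  A parallel
Michaelis-Menten elimination pathway (Vmax, Km) is available for model
comparison.

Individual parameters combine a typical value at reference covariates with
power-law covariate effects and log-normal random effects:

    CL_i = CL_ref * (WT/75)^a_wt * (ALB/4)^a_alb * (AGE/53)^a_age
                  * (LYM/0.1)^a_lym * f_liver^I_liver * f_skin^I_skin
                  * f_gut^I_gut * exp(eta_CL + kappa_occ)
    Vc_i = Vc_ref * (WT/75)^b_wt * exp(eta_Vc)
    Q_i  = Q_ref  * (WT/75)^0.75
    Vp_i = Vp_ref * (WT/75)^1    * exp(eta_Vp)

where kappa_occ is an inter-occasion random effect on CL that changes at
each dosing occasion.  Covariates may vary in time, in which case the
individual parameters are piecewise constant and concentrations are
propagated exactly across the change points (see :mod:`vedopk.kinetics`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import kinetics

__all__ = [
    "StructuralTheta",
    "CovariateCoeffs",
    "ReferenceCovariates",
    "REFERENCE",
    "Covariates",
    "VarianceComponents",
    "ModelParams",
    "DoseEvent",
    "IndividualParams",
    "individual_params",
    "conc_2cmt_linear",
    "conc_2cmt_mm",
    "assign_occasions",
    "occasion_levels",
    "INFUSION_30MIN",
]

#: duration of a 30-minute infusion in days
INFUSION_30MIN = 1.0 / 48.0


@dataclass(frozen=True)
class StructuralTheta:
    """Typical-value disposition parameters at reference covariates.

    cl_ref L/day, vc_ref L, q_ref L/day, vp_ref L; the optional saturable
    pathway is described by vmax (mg/day) and km (ug/mL), present together
    or not at all.
    """

    cl_ref: float = 0.148
    vc_ref: float = 3.12
    q_ref: float = 0.500
    vp_ref: float = 3.95
    vmax: float | None = None
    km: float | None = None

    def __post_init__(self) -> None:
        for name in ("cl_ref", "vc_ref", "q_ref", "vp_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if (self.vmax is None) != (self.km is None):
            raise ValueError("vmax and km must be given together")
        if self.vmax is not None and (self.vmax < 0 or self.km <= 0):
            raise ValueError("vmax must be >= 0 and km > 0")


@dataclass(frozen=True)
class CovariateCoeffs:
    """Covariate-effect coefficients of the full model.

    Continuous covariates enter as powers of the value normalized by its
    reference; the weight exponents on Q and Vp are fixed allometrically at
    0.75 and 1.  GvHD involvement (liver/skin/gut) enters as a positive
    factor raised to a 0/1 indicator, i.e. an on-off multiplicative switch
    on CL.
    """

    wt_on_cl: float = 0.5
    wt_on_vc: float = 0.6
    alb_on_cl: float = -1.3
    age_on_cl: float = -0.2
    lym_on_cl: float = 0.0
    gvhd_liver_on_cl: float = 1.0
    gvhd_skin_on_cl: float = 1.0
    gvhd_gut_on_cl: float = 1.0
    wt_on_q: float = field(default=0.75, init=False)  # fixed allometric
    wt_on_vp: float = field(default=1.0, init=False)  # fixed allometric

    def __post_init__(self) -> None:
        for name in ("gvhd_liver_on_cl", "gvhd_skin_on_cl", "gvhd_gut_on_cl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ReferenceCovariates:
    """Reference patient: 75 kg, albumin 4 g/dL, 53 years, 0.1 K/uL, no GvHD."""

    weight: float = 75.0
    albumin: float = 4.0
    age: float = 53.0
    lymphocytes: float = 0.1

    def __post_init__(self) -> None:
        for name in ("weight", "albumin", "age", "lymphocytes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"reference {name} must be strictly positive")


REFERENCE = ReferenceCovariates()


@dataclass(frozen=True)
class Covariates:
    """Covariate values at one point in time."""

    weight: float = 75.0
    albumin: float = 4.0
    age: float = 53.0
    lymphocytes: float = 0.1
    gvhd_liver: int = 0
    gvhd_skin: int = 0
    gvhd_gut: int = 0

    def __post_init__(self) -> None:
        for name in ("weight", "albumin", "age", "lymphocytes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"covariate {name} must be strictly positive")
        for name in ("gvhd_liver", "gvhd_skin", "gvhd_gut"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"indicator {name} must be 0 or 1")


@dataclass(frozen=True)
class VarianceComponents:
    """Random-effect variances: IIV block on (CL, Vc, Vp), IOV on CL, residual."""

    omega: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.0827, 0.0214, -0.0253],
                [0.0214, 0.0323, 0.0272],
                [-0.0253, 0.0272, 0.179],
            ]
        )
    )
    omega_iov_cl: float = 0.0315
    sigma_prop: float = 0.0241  # proportional residual variance
    sigma_add: float = 0.0  # additive residual variance (ug/mL)^2

    def __post_init__(self) -> None:
        om = np.asarray(self.omega, dtype=float)
        if om.shape != (3, 3):
            raise ValueError("omega must be 3x3 (CL, Vc, Vp)")
        if not np.allclose(om, om.T, atol=1e-12):
            raise ValueError("omega must be symmetric")
        if np.linalg.eigvalsh(om)[0] < -1e-10:
            raise ValueError("omega must be positive semi-definite")
        object.__setattr__(self, "omega", om)
        for name in ("omega_iov_cl", "sigma_prop", "sigma_add"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class DoseEvent:
    """Zero-order IV infusion: start time (days), amount (mg), duration (days)."""

    start_time: float
    amount: float
    duration: float = INFUSION_30MIN

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")
        if self.duration <= 0:
            raise ValueError("infusion duration must be positive (zero-order input)")

    @property
    def rate(self) -> float:
        """Infusion rate in mg/day."""
        return self.amount / self.duration

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass(frozen=True)
class IndividualParams:
    """Realized disposition parameters for one subject at one time."""

    cl: float
    vc: float
    q: float
    vp: float

    def __post_init__(self) -> None:
        for name in ("cl", "vc", "q", "vp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def individual_params(
    theta: StructuralTheta,
    coeffs: CovariateCoeffs,
    cov: Covariates,
    eta: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 0.0),
    kappa_occ: float = 0.0,
    ref: ReferenceCovariates = REFERENCE,
) -> IndividualParams:
    """Individual parameters at given covariate values and random effects.

    ``eta`` is the (CL, Vc, Vp) inter-individual random-effect vector and
    ``kappa_occ`` the inter-occasion effect acting on CL for the occasion in
    force at this time.
    """
    e1, e2, e3 = (float(x) for x in eta)
    wt = cov.weight / ref.weight
    cl = (
        theta.cl_ref
        * wt**coeffs.wt_on_cl
        * (cov.albumin / ref.albumin) ** coeffs.alb_on_cl
        * (cov.age / ref.age) ** coeffs.age_on_cl
        * (cov.lymphocytes / ref.lymphocytes) ** coeffs.lym_on_cl
        * coeffs.gvhd_liver_on_cl**cov.gvhd_liver
        * coeffs.gvhd_skin_on_cl**cov.gvhd_skin
        * coeffs.gvhd_gut_on_cl**cov.gvhd_gut
        * np.exp(e1 + kappa_occ)
    )
    vc = theta.vc_ref * wt**coeffs.wt_on_vc * np.exp(e2)
    q = theta.q_ref * wt**coeffs.wt_on_q
    vp = theta.vp_ref * wt**coeffs.wt_on_vp * np.exp(e3)
    return IndividualParams(cl=float(cl), vc=float(vc), q=float(q), vp=float(vp))


def _as_timeline(params_timeline) -> list[tuple[float, IndividualParams]]:
    if isinstance(params_timeline, IndividualParams):
        return [(-np.inf, params_timeline)]
    tl = sorted(params_timeline, key=lambda kp: kp[0])
    if not tl:
        raise ValueError("empty parameter timeline")
    return tl


def _segment_grid(params_timeline, doses, t):
    """Cut the timeline at every parameter knot, dose start and infusion end."""
    tl = _as_timeline(params_timeline)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0) and any(d.start_time >= 0 for d in doses):
        pass  # negative query times are allowed as long as the grid covers them
    knots = {kt for kt, _ in tl if np.isfinite(kt)}
    for d in doses:
        knots.add(d.start_time)
        knots.add(d.end_time)
    start = min(min(knots, default=0.0), float(t.min()) if t.size else 0.0)
    cuts = sorted(k for k in knots if k > start)
    end = max(cuts[-1] if cuts else start, float(t.max()) if t.size else start) + 1.0
    bounds = np.array([start] + cuts + [end])
    nseg = len(bounds) - 1
    mids = 0.5 * (bounds[:-1] + bounds[1:])
    rates = np.zeros(nseg)
    for d in doses:
        active = (mids >= d.start_time) & (mids < d.end_time)
        rates[active] += d.rate
    # piecewise-constant parameter lookup (value of latest knot <= segment start)
    knot_times = np.array([kt for kt, _ in tl])
    idx = np.clip(np.searchsorted(knot_times, mids, side="right") - 1, 0, len(tl) - 1)
    cl = np.array([tl[i][1].cl for i in idx])
    vc = np.array([tl[i][1].vc for i in idx])
    q = np.array([tl[i][1].q for i in idx])
    vp = np.array([tl[i][1].vp for i in idx])
    return bounds, rates, cl, vc, q, vp


def conc_2cmt_linear(params_timeline, doses, t):
    """Central concentration (ug/mL) of the linear two-compartment model.

    ``params_timeline`` is either a single :class:`IndividualParams` or a
    list of ``(start_time, IndividualParams)`` knots defining a
    piecewise-constant timeline; ``doses`` a list of :class:`DoseEvent`.
    ``t`` may be a scalar or array (any order); times before the first dose
    return 0.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    order = np.argsort(t_arr, kind="stable")
    bounds, rates, cl, vc, q, vp = _segment_grid(params_timeline, doses, t_arr)
    out = np.empty_like(t_arr)
    out[order] = kinetics.profile_linear(bounds, rates, cl, vc, q, vp, t_arr[order])
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def conc_2cmt_mm(params_timeline, vmax, km, doses, t, rtol=1e-10):
    """Concentration with parallel linear + saturable (Vmax, Km) elimination.

    Solved numerically (segment-wise adaptive ODE integration); reduces to
    :func:`conc_2cmt_linear` when ``vmax`` is 0.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    order = np.argsort(t_arr, kind="stable")
    bounds, rates, cl, vc, q, vp = _segment_grid(params_timeline, doses, t_arr)
    out = np.empty_like(t_arr)
    out[order] = kinetics.profile_mm_ode(
        bounds, rates, cl, vc, q, vp, t_arr[order], vmax=vmax, km=km, rtol=rtol
    )
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def assign_occasions(dose_times, obs_times) -> np.ndarray:
    """Occasion label for each observation.

    A new occasion begins at each administered dose; an observation is
    labeled with the 1-based index of the most recent dose at or before it.
    Observations before the first dose receive label 0 (pre-dose).
    """
    dose_times = np.asarray(dose_times, dtype=float)
    obs_times = np.asarray(obs_times, dtype=float)
    if np.any(np.diff(dose_times) < 0) or np.any(np.diff(obs_times) < 0):
        raise ValueError("dose and observation times must be sorted ascending")
    return np.searchsorted(dose_times, obs_times, side="right")


def occasion_levels(dose_times, obs_times) -> tuple[np.ndarray, int]:
    """Map each dose interval to an inter-occasion random-effect level.

    Only dose intervals containing at least one observation before the next
    dose define a new kappa level; an interval without observations inherits
    the preceding level (its kappa is unidentifiable and would only inflate
    the random-effect dimension).  Returns (level per dose interval, number
    of levels); intervals before the first observed one share level 0.
    """
    labels = assign_occasions(dose_times, obs_times)
    n_dose = len(np.asarray(dose_times))
    level = np.zeros(n_dose, dtype=int)
    counter = -1
    for i in range(1, n_dose + 1):
        if np.any(labels == i):
            counter += 1
            level[i - 1] = counter
        else:
            level[i - 1] = max(counter, 0)
    return level, max(counter + 1, 1)


@dataclass(frozen=True)
class ModelParams:
    """Complete specification of one population model.

    Bundles the structural typical values, the covariate coefficients and
    the variance components; the default instance is the final published
    model (reference-covariate typical values with the full Omega block,
    IOV on CL and proportional residual error).
    """

    theta: StructuralTheta = field(default_factory=StructuralTheta)
    coeffs: CovariateCoeffs = field(default_factory=CovariateCoeffs)
    variance: VarianceComponents = field(default_factory=VarianceComponents)


def with_updates(obj, **kw):
    """Convenience: dataclasses.replace that tolerates frozen types."""
    return replace(obj, **kw)


def params_to_dict(p: ModelParams) -> dict:
    """JSON/YAML-serializable representation of a model specification."""
    return {
        "theta": {
            "cl_ref": p.theta.cl_ref, "vc_ref": p.theta.vc_ref,
            "q_ref": p.theta.q_ref, "vp_ref": p.theta.vp_ref,
            "vmax": p.theta.vmax, "km": p.theta.km,
        },
        "coeffs": {
            k: getattr(p.coeffs, k)
            for k in (
                "wt_on_cl", "wt_on_vc", "alb_on_cl", "age_on_cl", "lym_on_cl",
                "gvhd_liver_on_cl", "gvhd_skin_on_cl", "gvhd_gut_on_cl",
            )
        },
        "variance": {
            "omega": [list(map(float, row)) for row in p.variance.omega],
            "omega_iov_cl": p.variance.omega_iov_cl,
            "sigma_prop": p.variance.sigma_prop,
            "sigma_add": p.variance.sigma_add,
        },
    }


def params_from_dict(d: dict) -> ModelParams:
    """Inverse of :func:`params_to_dict` (missing keys fall back to defaults)."""
    th = d.get("theta", {})
    var = dict(d.get("variance", {}))
    if "omega" in var:
        var["omega"] = np.asarray(var["omega"], dtype=float)
    return ModelParams(
        theta=StructuralTheta(**{k: v for k, v in th.items() if v is not None}),
        coeffs=CovariateCoeffs(**d.get("coeffs", {})),
        variance=VarianceComponents(**var),
    )
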
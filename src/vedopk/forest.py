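"""Covariate forest-plot inference on relative clearance.

Clinical relevance of each covariate is judged from the uncertainty
distribution of the clearance it implies: parameter vectors are drawn from
a multivariate normal on the estimation scale (so positive parameters stay
positive), CL is evaluated with one covariate perturbed to an observed
percentile and all others at reference, and the result is normalized by
the reference CL (the median simulated CL of the reference patient).  Rows
whose 90% CI falls outside +/-25% of the reference flag a potentially
clinically important effect; under a linear model relative steady-state
exposure is simply the reciprocal of relative clearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import TrialDataset
from .model import REFERENCE, ModelParams

__all__ = [
    "UncertaintyDraws",
    "ForestRow",
    "draws_from_fit",
    "point_draws",
    "reference_cl",
    "relative_cl",
    "aucss_change",
    "covariate_percentiles",
    "forest_table",
    "plot_forest",
]

#: forest covariates and the CL coefficient / reference value they act through
_COVARIATES = {
    "weight": ("wt_on_cl", REFERENCE.weight),
    "albumin": ("alb_on_cl", REFERENCE.albumin),
    "age": ("age_on_cl", REFERENCE.age),
    "lymphocytes": ("lym_on_cl", REFERENCE.lymphocytes),
}

PERCENTILES = (5, 10, 25, 50, 75, 90, 95)


@dataclass
class UncertaintyDraws:
    """Samples of (CL_ref, covariate coefficients) from estimation uncertainty.

    ``log_cl_ref`` holds n_draws samples of log CL_ref; ``coeffs`` holds a
    column per covariate coefficient (power-law exponents).  Degenerate
    (zero-covariance) draws collapse every column to its point estimate.
    """

    log_cl_ref: np.ndarray
    coeffs: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        n = self.log_cl_ref.shape[0]
        if n == 0:
            raise ValueError("need at least one draw")
        for k, v in self.coeffs.items():
            if v.shape[0] != n:
                raise ValueError(f"coefficient {k} has wrong draw count")

    @property
    def n_draws(self) -> int:
        return int(self.log_cl_ref.shape[0])


def point_draws(params: ModelParams) -> UncertaintyDraws:
    """Degenerate draws at the point estimates (zero estimate-covariance)."""
    return UncertaintyDraws(
        log_cl_ref=np.array([np.log(params.theta.cl_ref)]),
        coeffs={
            name: np.array([getattr(params.coeffs, cname)])
            for name, (cname, _ref) in _COVARIATES.items()
        },
    )


def draws_from_fit(fit_result, n_draws: int = 10_000, seed: int = 0) -> UncertaintyDraws:
    """Sample the uncertainty distribution from a fit's covariance matrix.

    Draws the full estimated-parameter vector from MVN(estimates,
    covariance) on the estimation (transformed) scale and keeps the
    components entering the clearance model.  Requires a fit with an
    available covariance; with ``n_draws = 0`` or a missing covariance a
    degenerate point mass is returned.
    """
    params = fit_result.estimates
    if fit_result.covariance is None or n_draws == 0:
        return point_draws(params)
    labels = fit_result.covariance_labels
    from .estimate import _Transform

    tr = _Transform(tuple(fit_result_estimate_names(labels)))
    x_hat = tr.to_vector(params)
    rng = np.random.default_rng(seed)
    X = rng.multivariate_normal(x_hat, fit_result.covariance, size=n_draws,
                                method="svd")
    idx = {lab: i for i, lab in enumerate(tr.labels)}
    log_cl = X[:, idx["cl_ref"]] if "cl_ref" in idx else np.full(
        n_draws, np.log(params.theta.cl_ref)
    )
    coeffs = {}
    for name, (cname, _ref) in _COVARIATES.items():
        if cname in idx:
            coeffs[name] = X[:, idx[cname]]
        else:
            coeffs[name] = np.full(n_draws, getattr(params.coeffs, cname))
    return UncertaintyDraws(log_cl_ref=log_cl, coeffs=coeffs, seed=seed)


def fit_result_estimate_names(labels: list[str]) -> list[str]:
    """Recover the estimate-name tuple from covariance labels."""
    names: list[str] = []
    for lab in labels:
        if lab.startswith("omega_chol"):
            if "omega" not in names:
                names.append("omega")
        else:
            names.append(lab)
    return names


@dataclass(frozen=True)
class ForestRow:
    """One covariate-percentile row of the forest plot."""

    covariate: str
    percentile: float
    value: float
    median: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.median <= self.upper):
            raise ValueError("forest row quantiles out of order")

    @property
    def potentially_important(self) -> bool:
        """True when the CI excludes the +/-25% reference band entirely."""
        return self.lower > 1.25 or self.upper < 0.75


def reference_cl(draws: UncertaintyDraws) -> float:
    """Median simulated CL of the reference patient (the 'reference CL')."""
    return float(np.exp(np.median(draws.log_cl_ref)))


def relative_cl(
    draws: UncertaintyDraws,
    covariate_name: str,
    value: float,
    ci: float = 90.0,
) -> ForestRow:
    """Relative CL at one perturbed covariate value, others at reference.

    Per draw, CL(perturbed)/reference_cl; the row reports the median and
    the ``ci``% interval (90% by default) of that distribution.
    """
    if covariate_name not in _COVARIATES:
        raise ValueError(f"unknown covariate: {covariate_name!r}")
    if value <= 0:
        raise ValueError("continuous covariate value must be positive")
    cname, ref = _COVARIATES[covariate_name]
    _ = cname
    log_cl = draws.log_cl_ref + draws.coeffs[covariate_name] * np.log(value / ref)
    rel = np.exp(log_cl) / reference_cl(draws)
    half = (100.0 - ci) / 2.0
    lo, med, hi = np.percentile(rel, [half, 50.0, 100.0 - half])
    return ForestRow(
        covariate=covariate_name,
        percentile=np.nan,
        value=float(value),
        median=float(med),
        lower=float(min(lo, med)),
        upper=float(max(hi, med)),
    )


def aucss_change(relative_cl_value: float) -> float:
    """Relative steady-state exposure implied by a relative clearance.

    For linear elimination AUCss = Dose / CL, so relative AUCss is the
    reciprocal of relative CL.
    """
    if relative_cl_value <= 0:
        raise ValueError("relative CL must be positive")
    return 1.0 / relative_cl_value


def covariate_percentiles(
    dataset: TrialDataset, percentiles=PERCENTILES
) -> pd.DataFrame:
    """Observed-value percentiles of the forest covariates in a dataset.

    Percentiles are taken over observation rows (the values in force at
    sampling times), matching the use of observed covariate distributions.
    """
    obs = dataset.observations()
    cols = {"weight": "WT", "albumin": "ALB", "age": "AGE", "lymphocytes": "LYM"}
    rows = []
    for name, col in cols.items():
        vals = np.percentile(obs[col], percentiles)
        for p, v in zip(percentiles, vals):
            rows.append(dict(covariate=name, percentile=p, value=v))
    return pd.DataFrame(rows)


def forest_table(
    draws: UncertaintyDraws,
    percentile_table: pd.DataFrame,
    ci: float = 90.0,
) -> list[ForestRow]:
    """One ForestRow per covariate x percentile of the observed values."""
    required = set(_COVARIATES)
    present = set(percentile_table["covariate"])
    if not required <= present:
        raise ValueError(f"percentile table missing covariates: {required - present}")
    rows = []
    for _, rec in percentile_table.iterrows():
        row = relative_cl(draws, rec["covariate"], rec["value"], ci=ci)
        rows.append(
            ForestRow(
                covariate=row.covariate,
                percentile=float(rec["percentile"]),
                value=row.value,
                median=row.median,
                lower=row.lower,
                upper=row.upper,
            )
        )
    return rows


def forest_frame(rows: list[ForestRow]) -> pd.DataFrame:
    """Forest rows as a tidy DataFrame (for CSV export)."""
    return pd.DataFrame(
        [
            dict(
                covariate=r.covariate, percentile=r.percentile, value=r.value,
                median=r.median, lower=r.lower, upper=r.upper,
                potentially_important=r.potentially_important,
            )
            for r in rows
        ]
    )


def plot_forest(rows: list[ForestRow], ax=None):
    """Forest plot: medians with CI whiskers over a +/-25% reference band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.35 * len(rows) + 1.5))
    labels = []
    for i, r in enumerate(rows):
        y = len(rows) - 1 - i
        ax.plot([r.lower, r.upper], [y, y], "-", color="tab:blue", lw=1.8)
        ax.plot(r.median, y, "o", color="tab:orange", ms=5)
        labels.append(f"{r.covariate} p{r.percentile:g} = {r.value:.3g}")
    ax.axvspan(0.75, 1.25, color="0.9", zorder=0)
    ax.axvline(1.0, color="0.5", lw=1)
    ax.set_yticks(range(len(rows))[::-1], labels)
    ax.set_xlabel("Relative CL vs reference patient")
    return ax
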
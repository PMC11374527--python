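"""Simulation-based model evaluation: pcVPC, NPDE and goodness-of-fit tables.

The prediction-corrected visual predictive check (pcVPC) compares observed
percentiles (5th/50th/95th) of concentration versus time after the most
recent dose with confidence bands of the same percentiles across Monte
Carlo replicates of the study, after normalizing each value by the ratio of
its bin's median population prediction to its own population prediction.

Normalized prediction distribution errors (NPDE) decorrelate each subject's
observation vector with the Cholesky inverse of its simulated covariance,
rank the observed decorrelated values within the simulated ones, and map
the ranks through the standard normal quantile function; under the true
model they are approximately N(0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import TrialDataset
from .estimate import _compile, _solve_inner, empirical_bayes
from .model import ModelParams

__all__ = ["VpcResult", "NpdeResult", "pc_vpc", "npde", "gof_tables", "plot_vpc"]


# ---------------------------------------------------------------------------
# shared simulation helper


def _population_predictions(subs, params: ModelParams) -> list[np.ndarray]:
    """Typical-value predictions (eta = kappa = 0) per compiled subject."""
    out = []
    for sub in subs:
        sub.set_params(params)
        out.append(sub.predict(np.zeros(sub.n_psi)))
    return out


def _simulate_replicate(subs, params: ModelParams, rng) -> list[np.ndarray]:
    """One Monte Carlo replicate of every subject's observation vector.

    Callers must have cached ``params`` on the subjects first (e.g. via
    :func:`_population_predictions`).
    """
    var = params.variance
    chol = np.linalg.cholesky(var.omega + 1e-12 * np.eye(3))
    sd_iov = np.sqrt(var.omega_iov_cl)
    sd_prop = np.sqrt(var.sigma_prop)
    sd_add = np.sqrt(var.sigma_add)
    out = []
    for sub in subs:
        psi = np.zeros(sub.n_psi)
        psi[:3] = chol @ rng.standard_normal(3)
        psi[3:] = sd_iov * rng.standard_normal(sub.n_kappa)
        f = sub.predict(psi)
        y = f * (1.0 + sd_prop * rng.standard_normal(f.size))
        if sd_add > 0:
            y = y + sd_add * rng.standard_normal(f.size)
        out.append(y)
    return out


def _time_after_dose(sub) -> np.ndarray:
    idx = np.searchsorted(sub.dose_times, sub.obs_times, side="right") - 1
    return np.where(idx >= 0, sub.obs_times - sub.dose_times[np.maximum(idx, 0)],
                    sub.obs_times)


# ---------------------------------------------------------------------------
# pcVPC


@dataclass
class VpcResult:
    """Binned observed percentiles with simulated confidence bands."""

    bin_edges: np.ndarray  # (n_bins + 1,) on the time-after-dose axis
    bin_mid: np.ndarray
    n_per_bin: np.ndarray
    observed: pd.DataFrame  # columns p5, p50, p95 per bin
    band_lower: pd.DataFrame  # 2.5th percentile across replicates, per statistic
    band_upper: pd.DataFrame  # 97.5th percentile across replicates
    n_replicates: int
    seed: int
    prediction_corrected: bool = True
    merged_bins: list = field(default_factory=list)

    def coverage(self, statistic: str = "p50") -> float:
        """Fraction of bins whose observed statistic lies inside its band."""
        ok = (self.observed[statistic] >= self.band_lower[statistic]) & (
            self.observed[statistic] <= self.band_upper[statistic]
        )
        return float(ok.mean())


_PCTS = {"p5": 5.0, "p50": 50.0, "p95": 95.0}


def _bin_percentiles(values, bin_idx, n_bins):
    out = {k: np.full(n_bins, np.nan) for k in _PCTS}
    for b in range(n_bins):
        sel = bin_idx == b
        if sel.any():
            v = values[sel]
            for k, p in _PCTS.items():
                out[k][b] = np.percentile(v, p)
    return pd.DataFrame(out)


def pc_vpc(
    dataset: TrialDataset,
    params: ModelParams,
    n_rep: int = 500,
    bins: int = 8,
    seed: int = 0,
    prediction_corrected: bool = True,
    min_bin_size: int = 3,
) -> VpcResult:
    """Prediction-corrected visual predictive check.

    Bins are quantiles of time after the most recent dose; bins with fewer
    than ``min_bin_size`` observations are merged with their neighbor (and
    recorded in ``merged_bins``).  Each observed and simulated value is
    multiplied by (bin median population prediction) / (its own population
    prediction) before percentile computation; the 95% confidence band of
    each percentile is taken across the ``n_rep`` replicates.
    """
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    subs = _compile(dataset)
    preds = _population_predictions(subs, params)
    tad = np.concatenate([_time_after_dose(s) for s in subs])
    obs = np.concatenate([s.y for s in subs])
    pred = np.concatenate(preds)
    if np.any(pred <= 0):
        raise ValueError("population prediction must be positive for every observation")

    edges = np.unique(np.quantile(tad, np.linspace(0, 1, bins + 1)))
    if edges.size < 2:  # all observations share one time after dose
        edges = np.array([0.0, 0.0])
    edges[0], edges[-1] = -np.inf, np.inf
    bin_idx = np.searchsorted(edges, tad, side="right") - 1
    n_bins = edges.size - 1

    # merge undersized bins into their left neighbor
    merged = []
    counts = np.bincount(bin_idx, minlength=n_bins)
    while n_bins > 1 and counts.min() < min_bin_size:
        b = int(np.argmin(counts))
        tgt = b - 1 if b > 0 else 1
        merged.append((b, tgt))
        edges = np.delete(edges, max(b, tgt))
        bin_idx = np.searchsorted(edges, tad, side="right") - 1
        n_bins = edges.size - 1
        counts = np.bincount(bin_idx, minlength=n_bins)

    if prediction_corrected:
        bin_med_pred = np.array(
            [np.median(pred[bin_idx == b]) for b in range(n_bins)]
        )
        correction = bin_med_pred[bin_idx] / pred
    else:
        correction = np.ones_like(pred)

    observed = _bin_percentiles(obs * correction, bin_idx, n_bins)

    rng = np.random.default_rng(seed)
    rep_stats = {k: np.empty((n_rep, n_bins)) for k in _PCTS}
    for r in range(n_rep):
        sim = np.concatenate(_simulate_replicate(subs, params, rng))
        simdf = _bin_percentiles(sim * correction, bin_idx, n_bins)
        for k in _PCTS:
            rep_stats[k][r] = simdf[k].to_numpy()
    band_lower = pd.DataFrame(
        {k: np.nanpercentile(rep_stats[k], 2.5, axis=0) for k in _PCTS}
    )
    band_upper = pd.DataFrame(
        {k: np.nanpercentile(rep_stats[k], 97.5, axis=0) for k in _PCTS}
    )
    mids = np.array(
        [
            np.median(tad[bin_idx == b]) if (bin_idx == b).any() else np.nan
            for b in range(n_bins)
        ]
    )
    return VpcResult(
        bin_edges=edges,
        bin_mid=mids,
        n_per_bin=counts,
        observed=observed,
        band_lower=band_lower,
        band_upper=band_upper,
        n_replicates=n_rep,
        seed=seed,
        prediction_corrected=prediction_corrected,
        merged_bins=merged,
    )


def plot_vpc(result: VpcResult, ax=None, log_scale: bool = True):
    """Render the VPC: observed percentiles over shaded simulated bands."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    x = result.bin_mid
    styles = {"p50": ("-", "tab:blue"), "p5": ("--", "0.4"), "p95": ("--", "0.4")}
    for k, (ls, color) in styles.items():
        ax.fill_between(
            x, result.band_lower[k], result.band_upper[k],
            alpha=0.3, color=color, linewidth=0,
        )
        ax.plot(x, result.observed[k], ls, color="black", lw=1.5)
    ax.set_xlabel("Time after most recent dose (days)")
    ax.set_ylabel("Prediction-corrected concentration (ug/mL)"
                  if result.prediction_corrected else "Concentration (ug/mL)")
    if log_scale:
        ax.set_yscale("log")
    return ax


# ---------------------------------------------------------------------------
# NPDE


@dataclass
class NpdeResult:
    """Per-observation NPDE with distributional summaries."""

    table: pd.DataFrame  # ID, TIME, DV, PRED, npde
    mean: float
    variance: float
    normality_statistic: float  # D'Agostino-Pearson K2
    normality_pvalue: float
    n_replicates: int
    seed: int

    @property
    def values(self) -> np.ndarray:
        return self.table["npde"].to_numpy()


def npde(
    dataset: TrialDataset,
    params: ModelParams,
    n_rep: int = 1000,
    seed: int = 0,
    ridge: float = 1e-10,
) -> NpdeResult:
    """Normalized prediction distribution errors against a fitted model.

    Per subject, ``n_rep`` replicate observation vectors are simulated;
    observed and simulated vectors are decorrelated by the inverse Cholesky
    factor of the simulated covariance (ridge-regularized if needed), the
    observed decorrelated values are ranked within the simulated ones with
    the mid-rank rule pd = (k + 0.5)/(n_rep + 1), and npde = Phi^-1(pd).
    """
    if n_rep < 100:
        raise ValueError("n_rep must be >= 100 for stable ranks")
    subs = [s for s in _compile(dataset) if s.n_obs > 0]
    rng = np.random.default_rng(seed)
    preds = _population_predictions(subs, params)  # also caches the params

    # simulate per replicate, accumulating per-subject matrices
    sims = [np.empty((n_rep, s.n_obs)) for s in subs]
    for r in range(n_rep):
        rep = _simulate_replicate(subs, params, rng)
        for i, y in enumerate(rep):
            sims[i][r] = y

    frames = []
    for sub, sim, pred in zip(subs, sims, preds):
        mu = sim.mean(axis=0)
        cov = np.cov(sim, rowvar=False)
        cov = np.atleast_2d(cov)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            import warnings

            warnings.warn(
                f"singular simulated covariance for subject {sub.id}; "
                "ridge-regularized", RuntimeWarning, stacklevel=2,
            )
            L = np.linalg.cholesky(cov + ridge * np.trace(cov) * np.eye(cov.shape[0]))
        yd = np.linalg.solve(L, sub.y - mu)
        sd = np.linalg.solve(L, (sim - mu).T)  # (n_obs, n_rep)
        k = (sd < yd[:, None]).sum(axis=1)
        pd_ = (k + 0.5) / (n_rep + 1)
        frames.append(
            pd.DataFrame(
                dict(
                    ID=sub.id, TIME=sub.obs_times, DV=sub.y, PRED=pred,
                    npde=stats.norm.ppf(pd_),
                )
            )
        )
    table = pd.concat(frames, ignore_index=True)
    vals = table["npde"].to_numpy()
    k2, pval = stats.normaltest(vals)
    return NpdeResult(
        table=table,
        mean=float(vals.mean()),
        variance=float(vals.var(ddof=1)),
        normality_statistic=float(k2),
        normality_pvalue=float(pval),
        n_replicates=n_rep,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# goodness-of-fit tables


def gof_tables(dataset: TrialDataset, fit_result) -> dict[str, pd.DataFrame]:
    """Observed-vs-predicted and EBE-vs-covariate diagnostic tables.

    Returns ``observations`` (one row per retained observation: DV, PRED
    with eta = 0, IPRED at the subject's empirical-Bayes mode, residuals
    and weighted residuals, time after dose, covariates) and ``ebes`` (one
    row per subject: random-effect modes joined with baseline covariates
    and any-time GvHD flags), ready for scatter/LOESS plotting.
    """
    params = fit_result.estimates if hasattr(fit_result, "estimates") else fit_result
    subs = _compile(dataset)
    preds = _population_predictions(subs, params)
    var = params.variance

    frames = []
    for sub, pred in zip(subs, preds):
        if sub.n_obs == 0:
            continue
        psi, f, _F, v, ok = _solve_inner(sub, var, np.zeros(sub.n_psi))
        ipred = f
        res = sub.y - pred
        frames.append(
            pd.DataFrame(
                dict(
                    ID=sub.id,
                    TIME=sub.obs_times,
                    TAD=_time_after_dose(sub),
                    DV=sub.y,
                    PRED=pred,
                    IPRED=ipred,
                    RES=res,
                    IWRES=(sub.y - ipred) / np.sqrt(v),
                )
            )
        )
    obs_table = pd.concat(frames, ignore_index=True)

    ebes, _ = empirical_bayes(dataset, params)
    base = (
        dataset.df.sort_values("TIME")
        .groupby("ID")
        .first()[["WT", "ALB", "AGE", "LYM", "SEX", "STUDY"]]
    )
    ever = dataset.df.groupby("ID")[["GVHDL", "GVHDS", "GVHDI"]].max()
    ebe_table = ebes.merge(base, on="ID").merge(ever, on="ID")
    return {"observations": obs_table, "ebes": ebe_table}
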
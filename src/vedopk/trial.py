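"""Synthetic clinical-trial generator for the two vedolizumab GvHD studies.

The generator emulates the designs whose pooled data the model targets:

* a phase 1b dose-finding study (``VEDO-1015``, n = 24): 75 mg (3 subjects)
  or 300 mg (21 subjects) infused over 30 min on study days -1, +13 and
  +42 relative to transplant, with rich sampling on dosing days and
  frequent single samples on non-dosing days;
* a phase 3 study (``VEDO-3035``, n = 169): 300 mg on days -1, +13, +41,
  +69, +97, +125 and +153, with trough-style sampling on dosing days plus
  day +180 and an end-of-treatment visit.

Time is measured in days since the first dose (transplant-calendar day -1),
so calendar day d maps to t = d + 1.  Weight, albumin and lymphocyte count
are simulated as noisy trajectories observed on a biweekly grid and
interpolated by next-observation-carried-backward (NOCB); acute-GvHD
involvement (liver/skin/gut) is an absorbing 0/1 flag with a random
post-transplant onset.  Concentrations below the 0.2 ug/mL quantification
limit are flagged BLQ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    INFUSION_30MIN,
    Covariates,
    DoseEvent,
    ModelParams,
    occasion_levels,
)
from .data import COLUMNS, TrialDataset

__all__ = [
    "StudyDesign",
    "PopulationSpec",
    "SubjectRecord",
    "generate_population",
    "nocb_interpolate",
    "simulate_trial",
    "lognormal_from_quantiles",
]

#: offset of a pre-dose trough sample before its dose (days; ~14 min)
PREDOSE_OFFSET = 0.01


@dataclass(frozen=True)
class StudyDesign:
    """Dosing and PK-sampling schedule of one study arm."""

    label: str
    dose_times: tuple[float, ...]  # days since first dose
    dose_amounts: tuple[float, ...]  # mg, subject-level allocation
    dose_fractions: tuple[float, ...]
    sample_times: tuple[float, ...]  # days since first dose
    lloq: float = 0.2
    infusion_duration: float = INFUSION_30MIN

    def __post_init__(self) -> None:
        if abs(sum(self.dose_fractions) - 1.0) > 1e-9:
            raise ValueError("dose allocation fractions must sum to 1")
        if len(self.dose_fractions) != len(self.dose_amounts):
            raise ValueError("one allocation fraction per dose amount")

    @property
    def window(self) -> float:
        """Study observation window (days since first dose)."""
        return max(max(self.sample_times), max(self.dose_times)) + 1.0

    @classmethod
    def vedo_1015(cls) -> "StudyDesign":
        """Phase 1b rich-sampling design (75 mg n=3 / 300 mg n=21)."""
        post_full = (0.5 / 24, 2 / 24, 12 / 24, 24 / 24)  # h after infusion start
        post_short = (0.5 / 24, 1 / 24, 2 / 24)
        samples: list[float] = []
        for d in (0.0, 14.0):
            if d > 0:  # no pre-first-dose PK sample in the assembled dataset
                samples.append(d - PREDOSE_OFFSET)
            samples.extend(d + o for o in post_full)
        samples.append(43.0 - PREDOSE_OFFSET)
        samples.extend(43.0 + o for o in post_short)
        # non-dosing visit days +3..+100 (calendar) -> t = day + 1
        samples.extend(
            float(d + 1) for d in (3, 5, 7, 9, 11, 16, 18, 20, 22, 26, 30, 36, 40, 100)
        )
        return cls(
            label="VEDO-1015",
            dose_times=(0.0, 14.0, 43.0),
            dose_amounts=(75.0, 300.0),
            dose_fractions=(3 / 24, 21 / 24),
            sample_times=tuple(sorted(samples)),
        )

    @classmethod
    def vedo_3035(cls) -> "StudyDesign":
        """Phase 3 trough-style design (300 mg q4w x 7)."""
        dose_times = (0.0, 14.0, 42.0, 70.0, 98.0, 126.0, 154.0)
        samples: list[float] = []
        for d in dose_times:
            if d > 0:  # no pre-first-dose PK sample in the assembled dataset
                samples.append(d - PREDOSE_OFFSET)  # pre-dose trough
            samples.append(d + INFUSION_30MIN)  # end of infusion
        samples.append(181.0)  # day +180
        samples.append(195.0)  # end-of-treatment visit
        return cls(
            label="VEDO-3035",
            dose_times=dose_times,
            dose_amounts=(300.0,),
            dose_fractions=(1.0,),
            sample_times=tuple(sorted(samples)),
        )


def lognormal_from_quantiles(
    quantiles: dict[float, float]
) -> tuple[float, float]:
    """Least-squares (mu, sigma) of a log-normal matching stated quantiles.

    ln q_p = mu + z_p sigma is fit over the provided {p: q_p} pairs; used
    for baseline weight, where only the 10th/50th/90th percentiles
    (51/75/105 kg) are reported.
    """
    from scipy.stats import norm

    ps = np.array(sorted(quantiles))
    z = norm.ppf(ps)
    lq = np.log([quantiles[p] for p in ps])
    A = np.column_stack([np.ones_like(z), z])
    (mu, sigma), *_ = np.linalg.lstsq(A, lq, rcond=None)
    return float(mu), float(sigma)


@dataclass(frozen=True)
class PopulationSpec:
    """Covariate distributions of the pooled analysis population.

    Defaults reproduce the reported summaries: 57% male, mean age 50.8 y
    (range 18-72), weight quantiles 51/75/105 kg, baseline albumin mean
    3.97 g/dL, baseline lymphocytes mean 0.426 K/uL, and any-time GvHD
    incidences of 3.1% (liver), 32.1% (skin) and 8.8% (intestine).
    """

    n_vedo_1015: int = 24
    n_vedo_3035: int = 169
    male_fraction: float = 0.57
    age_mean: float = 50.8
    age_sd: float = 12.0
    age_range: tuple[float, float] = (18.0, 72.0)
    weight_quantiles: dict = field(
        default_factory=lambda: {0.10: 51.0, 0.50: 75.0, 0.90: 105.0}
    )
    albumin_mean: float = 3.97
    albumin_sd: float = 0.49
    lymphocyte_mean: float = 0.426
    lymphocyte_log_sd: float = 0.85
    gvhd_incidence: dict = field(
        default_factory=lambda: {"liver": 0.031, "skin": 0.321, "gut": 0.088}
    )
    gvhd_onset_scale: float = 30.0  # days, exponential, truncated to window
    race_fractions: dict = field(
        default_factory=lambda: {
            "white": 0.741,
            "asian": 0.155,
            "black": 0.021,
            "other": 0.083,
        }
    )
    #: fraction of multi-dose-design subjects who discontinue dosing early
    #: but still contribute late (day +180 / end-of-treatment) samples --
    #: the source of the sparse BLQ tail seen in this population
    dropout_fraction: float = 0.30
    # covariate-trajectory parameters
    covariate_interval: float = 14.0  # days between covariate measurements
    weight_walk_sd: float = 1.0  # kg per step, random walk
    # transient post-transplant hypoalbuminemia; amplitude chosen so the
    # observed albumin percentiles match the reported ones (25th 3.6,
    # 90th 4.6 g/dL) -- a larger dip would distort the lower tail
    albumin_dip_frac: float = 0.05
    albumin_dip_day: float = 8.0  # t of maximum dip (calendar day +7)
    albumin_recovery_day: float = 61.0  # back to baseline (calendar day +60)
    albumin_noise_sd: float = 0.15  # g/dL per measurement
    lymphocyte_noise_log_sd: float = 0.30

    def __post_init__(self) -> None:
        if not (0 <= self.male_fraction <= 1):
            raise ValueError("male_fraction must be in [0, 1]")
        for v in self.gvhd_incidence.values():
            if not (0 <= v <= 1):
                raise ValueError("GvHD incidences must be in [0, 1]")
        q = self.weight_quantiles
        ps = sorted(q)
        if any(q[a] >= q[b] for a, b in zip(ps, ps[1:])):
            raise ValueError("weight quantiles must be strictly increasing")
        if self.n_vedo_1015 < 0 or self.n_vedo_3035 < 0:
            raise ValueError("subject counts must be non-negative")
        if self.n_vedo_1015 + self.n_vedo_3035 < 1:
            raise ValueError("need at least one subject")


@dataclass
class SubjectRecord:
    """One subject's design realization and covariate trajectories."""

    id: int
    study: str
    doses: list[DoseEvent]
    obs_times: np.ndarray
    cov_times: np.ndarray  # measurement times of the time-varying covariates
    weight: np.ndarray
    albumin: np.ndarray
    lymphocytes: np.ndarray
    gvhd_onset: dict  # site -> onset time (days) or None
    age: float
    sex: str  # "M" / "F"
    race: str
    lloq: float = 0.2

    def covariates_at(self, t: float) -> Covariates:
        """Covariate values in force at time t (NOCB for the lab series)."""
        return Covariates(
            weight=float(nocb_interpolate(self.cov_times, self.weight, t)),
            albumin=float(nocb_interpolate(self.cov_times, self.albumin, t)),
            age=self.age,
            lymphocytes=float(nocb_interpolate(self.cov_times, self.lymphocytes, t)),
            gvhd_liver=int(self._flag("liver", t)),
            gvhd_skin=int(self._flag("skin", t)),
            gvhd_gut=int(self._flag("gut", t)),
        )

    def _flag(self, site: str, t: float) -> bool:
        onset = self.gvhd_onset.get(site)
        return onset is not None and t >= onset


def nocb_interpolate(times, values, query_times):
    """Next-observation-carried-backward interpolation.

    The value at a query time is the earliest observation at or after it;
    past the last observation the last value is carried forward.  ``times``
    must be sorted ascending and non-empty.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0:
        raise ValueError("empty covariate series")
    if np.any(np.diff(times) < 0):
        raise ValueError("covariate series times must be sorted")
    q = np.asarray(query_times, dtype=float)
    idx = np.minimum(np.searchsorted(times, q, side="left"), times.size - 1)
    out = values[idx]
    return float(out) if np.ndim(query_times) == 0 else out


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def generate_population(
    spec: PopulationSpec, seed: int | np.random.Generator = 0
) -> list[SubjectRecord]:
    """Draw a synthetic analysis population for both study designs.

    Deterministic given the seed; empirical covariate summaries converge to
    the specification's targets as the population grows.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    designs = [StudyDesign.vedo_1015(), StudyDesign.vedo_3035()]
    counts = [spec.n_vedo_1015, spec.n_vedo_3035]
    wt_mu, wt_sigma = lognormal_from_quantiles(spec.weight_quantiles)
    lym_mu = math.log(spec.lymphocyte_mean) - 0.5 * spec.lymphocyte_log_sd**2

    subjects: list[SubjectRecord] = []
    sid = 0
    for design, n in zip(designs, counts):
        for _ in range(n):
            sid += 1
            amount = float(
                rng.choice(design.dose_amounts, p=design.dose_fractions)
            )
            dose_times = list(design.dose_times)
            sample_times = list(design.sample_times)
            if len(dose_times) > 3 and rng.random() < spec.dropout_fraction:
                # early treatment discontinuation: dosing stops after a
                # uniformly drawn dose, visit samples stop with it, but the
                # late follow-up samples (>= day +180) are still drawn
                n_kept = int(rng.integers(1, len(dose_times)))
                last = dose_times[n_kept - 1]
                dose_times = dose_times[:n_kept]
                sample_times = [
                    t for t in sample_times if t < last + 1.0 or t >= 181.0
                ]
            doses = [
                DoseEvent(t, amount, design.infusion_duration)
                for t in dose_times
            ]
            sex = "M" if rng.random() < spec.male_fraction else "F"
            race = str(
                rng.choice(
                    list(spec.race_fractions), p=list(spec.race_fractions.values())
                )
            )
            age = float(
                _truncated_normal(
                    rng, spec.age_mean, spec.age_sd, *spec.age_range, 1
                )[0]
            )
            base_wt = float(np.exp(rng.normal(wt_mu, wt_sigma)))
            base_alb = float(
                _truncated_normal(rng, spec.albumin_mean, spec.albumin_sd, 1.5, 6.0, 1)[0]
            )
            base_lym = float(np.exp(rng.normal(lym_mu, spec.lymphocyte_log_sd)))

            window = design.window
            cov_times = np.arange(0.0, window + 1e-9, spec.covariate_interval)
            m = cov_times.size
            weight = base_wt + np.concatenate(
                [[0.0], np.cumsum(rng.normal(0.0, spec.weight_walk_sd, m - 1))]
            )
            weight = np.maximum(weight, 30.0)
            # transient hypoalbuminemia after conditioning/transplant
            dip = np.interp(
                cov_times,
                [0.0, spec.albumin_dip_day, spec.albumin_recovery_day],
                [0.0, spec.albumin_dip_frac, 0.0],
            )
            albumin = base_alb * (1.0 - dip) + rng.normal(0, spec.albumin_noise_sd, m)
            albumin = np.maximum(albumin, 1.0)
            lymphocytes = np.maximum(
                base_lym
                * np.exp(rng.normal(0, spec.lymphocyte_noise_log_sd, m)),
                0.01,
            )
            gvhd_onset: dict = {}
            for site, p in spec.gvhd_incidence.items():
                if rng.random() < p:
                    # truncated-exponential onset within the study window,
                    # strictly post-transplant (t >= 2, calendar day +1)
                    u = rng.random()
                    cdf_max = 1.0 - math.exp(-(window - 2.0) / spec.gvhd_onset_scale)
                    onset = 2.0 - spec.gvhd_onset_scale * math.log(1.0 - u * cdf_max)
                    gvhd_onset[site] = float(onset)
                else:
                    gvhd_onset[site] = None
            subjects.append(
                SubjectRecord(
                    id=sid,
                    study=design.label,
                    doses=doses,
                    obs_times=np.asarray(sample_times, dtype=float),
                    cov_times=cov_times,
                    weight=weight,
                    albumin=albumin,
                    lymphocytes=lymphocytes,
                    gvhd_onset=gvhd_onset,
                    age=age,
                    sex=sex,
                    race=race,
                    lloq=design.lloq,
                )
            )
    return subjects


def simulate_trial(
    population: list[SubjectRecord],
    true_params: ModelParams,
    seed: int | np.random.Generator = 0,
) -> TrialDataset:
    """Forward-simulate observed concentrations for a population.

    Per subject, eta ~ MVN(0, Omega); per dosing occasion, kappa ~
    N(0, omega_iov); concentrations follow the linear two-compartment model
    with time-varying covariates, and observations get proportional (plus
    optional additive) residual noise y = f (1 + eps_p) + eps_a.
    Observations below the LLOQ are flagged BLQ (and MDV = 1).  Returns the
    assembled event-record table.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    var = true_params.variance
    # validated PSD by VarianceComponents; Cholesky with zero-variance guard
    omega = var.omega + 1e-300 * np.eye(3)
    try:
        chol = np.linalg.cholesky(omega)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(var.omega)
        chol = v @ np.diag(np.sqrt(np.maximum(w, 0.0)))

    from .estimate import _CompiledSubject  # shared event-table semantics

    rows = []
    for sub in population:
        eta = chol @ rng.standard_normal(3)
        dose_times = np.array([d.start_time for d in sub.doses])
        levels, n_kappa = occasion_levels(dose_times, sub.obs_times)
        kappas = rng.normal(0.0, math.sqrt(var.omega_iov_cl), n_kappa)
        obs_labels = np.searchsorted(dose_times, sub.obs_times, side="right")

        # assemble the subject's event rows first: the model is simulated on
        # exactly the covariate process the table encodes (NOCB value on
        # each row, carried forward between rows), so the emitted dataset is
        # internally consistent with the model that generated it
        events = []
        for d in sub.doses:
            cov = sub.covariates_at(d.start_time)
            events.append(
                dict(
                    TIME=d.start_time, AMT=d.amount, RATE=d.rate, EVID=1, MDV=1,
                    DV=np.nan, BLQ=0,
                    OCC=int(np.searchsorted(dose_times, d.start_time, side="right")),
                    _cov=cov,
                )
            )
        for t, lab in zip(sub.obs_times, obs_labels):
            cov = sub.covariates_at(t)
            events.append(
                dict(
                    TIME=t, AMT=0.0, RATE=0.0, EVID=0, MDV=0,
                    DV=0.0, BLQ=0, OCC=int(lab), _cov=cov,
                )
            )
        # pre-dose troughs carry an earlier TIME; at equal TIME a dose row
        # precedes its end-of-infusion sample
        events.sort(key=lambda e: (e["TIME"], -e["EVID"]))
        sub_rows = []
        for e in events:
            cov = e.pop("_cov")
            sub_rows.append(
                dict(
                    ID=sub.id,
                    **e,
                    WT=cov.weight, ALB=cov.albumin, AGE=sub.age,
                    LYM=cov.lymphocytes, GVHDL=cov.gvhd_liver,
                    GVHDS=cov.gvhd_skin, GVHDI=cov.gvhd_gut,
                    SEX=1 if sub.sex == "M" else 0,
                    STUDY=sub.study,
                )
            )
        sdf = pd.DataFrame(sub_rows, columns=COLUMNS)

        compiled = _CompiledSubject(sub.id, sdf)
        compiled.set_params(true_params)
        psi = np.concatenate([eta, kappas])
        f = compiled.predict(psi)
        y = f * (1.0 + math.sqrt(var.sigma_prop) * rng.standard_normal(f.shape))
        if var.sigma_add > 0:
            y = y + rng.normal(0, math.sqrt(var.sigma_add), f.shape)
        y = np.maximum(y, 0.0)

        is_obs = sdf["EVID"].to_numpy() == 0
        sdf.loc[is_obs, "DV"] = y
        blq = is_obs & (sdf["DV"].to_numpy() < sub.lloq)
        sdf.loc[blq, "BLQ"] = 1
        sdf.loc[blq, "MDV"] = 1
        rows.append(sdf)
    return TrialDataset(pd.concat(rows, ignore_index=True))
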
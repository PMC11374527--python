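"""Event-record dataset (NONMEM dialect): container, validation, I/O, exclusions.

The rectangular table carries one row per dose or observation event:

    ID, TIME (days), AMT (mg), RATE (mg/day), EVID (1 dose / 0 observation),
    MDV, DV (ug/mL), BLQ, OCC, WT, ALB, AGE, LYM, GVHDL, GVHDS, GVHDI,
    SEX (1 male), STUDY

Dose rows have AMT > 0, EVID = 1 and a missing DV (written as "." on disk,
NONMEM style); observation rows have EVID = 0.  Covariate columns hold the
value in force at the row's time after NOCB filling, so the table is
self-contained for fitting.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "TrialDataset",
    "DatasetValidationError",
    "read_dataset",
    "write_dataset",
    "apply_exclusions",
    "ExclusionLog",
]

COLUMNS = [
    "ID", "TIME", "AMT", "RATE", "EVID", "MDV", "DV", "BLQ", "OCC",
    "WT", "ALB", "AGE", "LYM", "GVHDL", "GVHDS", "GVHDI", "SEX", "STUDY",
]

_INT_COLS = ["ID", "EVID", "MDV", "BLQ", "OCC", "GVHDL", "GVHDS", "GVHDI", "SEX"]
_FLOAT_COLS = ["TIME", "AMT", "RATE", "DV", "WT", "ALB", "AGE", "LYM"]

#: default lower limit of quantification of the assay, ug/mL
LLOQ = 0.2


class DatasetValidationError(ValueError):
    """Raised with row-level context when an event table is malformed."""


def _validate(df: pd.DataFrame) -> None:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetValidationError(f"missing required columns: {missing}")
    problems: list[str] = []
    bad_evid = df.index[~df["EVID"].isin([0, 1])]
    for i in bad_evid[:10]:
        problems.append(f"row {i}: EVID must be 0 or 1 (got {df.at[i, 'EVID']})")
    dose = df["EVID"] == 1
    for i in df.index[dose & ~(df["AMT"] > 0)][:10]:
        problems.append(f"row {i}: dose row requires AMT > 0")
    for i in df.index[dose & df["DV"].notna()][:10]:
        problems.append(f"row {i}: dose row must have missing DV")
    for i in df.index[(~dose) & (df["AMT"] != 0)][:10]:
        problems.append(f"row {i}: observation row must have AMT = 0")
    for sid, grp in df.groupby("ID", sort=False):
        t = grp["TIME"].to_numpy()
        if np.any(np.diff(t) < 0):
            j = int(np.argmax(np.diff(t) < 0))
            problems.append(
                f"row {grp.index[j + 1]}: TIME decreases within ID {sid}"
            )
    covbad = df[["WT", "ALB", "AGE", "LYM"]].isna().any(axis=1)
    for i in df.index[covbad][:10]:
        problems.append(f"row {i}: covariate columns must be non-missing")
    if problems:
        raise DatasetValidationError("; ".join(problems))


@dataclass
class TrialDataset:
    """A whole study population as a validated event-record table."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        _validate(df)
        self.df = df

    @property
    def n_subjects(self) -> int:
        return int(self.df["ID"].nunique())

    @property
    def n_observations(self) -> int:
        return int((self.df["EVID"] == 0).sum())

    def observations(self) -> pd.DataFrame:
        """Observation rows only."""
        return self.df[self.df["EVID"] == 0]

    def fitting_observations(self) -> pd.DataFrame:
        """Observation rows retained for estimation (MDV = 0)."""
        return self.df[(self.df["EVID"] == 0) & (self.df["MDV"] == 0)]

    def __eq__(self, other) -> bool:
        return isinstance(other, TrialDataset) and self.df.equals(other.df)


def write_dataset(dataset: TrialDataset, path) -> None:
    """Write the event table as CSV; missing DV is rendered as '.'."""
    out = dataset.df.copy()
    out["DV"] = out["DV"].map(lambda v: "." if pd.isna(v) else repr(float(v)))
    for c in _FLOAT_COLS:
        if c != "DV":
            out[c] = out[c].map(lambda v: repr(float(v)))
    out.to_csv(path, index=False)


def read_dataset(path) -> TrialDataset:
    """Read a CSV event table written by :func:`write_dataset` (lossless)."""
    df = pd.read_csv(
        path,
        dtype={"STUDY": str},
        na_values=["."],
        keep_default_na=True,
        float_precision="round_trip",
    )
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetValidationError(f"missing required columns: {missing}")
    for c in _INT_COLS:
        try:
            df[c] = df[c].astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise DatasetValidationError(f"column {c} is not integral: {exc}") from exc
    for c in _FLOAT_COLS:
        df[c] = df[c].astype(float)
    return TrialDataset(df[COLUMNS])


@dataclass
class ExclusionLog:
    """Accounting of records removed before fitting."""

    log: pd.DataFrame  # excluded observation rows with a REASON column
    n_observations: int
    n_retained: int

    @property
    def n_excluded(self) -> int:
        return self.n_observations - self.n_retained

    @property
    def blq_fraction(self) -> float:
        """Fraction of observations excluded as BLQ."""
        n_blq = int((self.log["REASON"] == "BLQ").sum())
        return n_blq / self.n_observations if self.n_observations else 0.0


def apply_exclusions(
    dataset: TrialDataset,
    lloq: float = LLOQ,
    post_infusion_window: float | None = None,
    peak_multiple: float | None = None,
) -> tuple[TrialDataset, ExclusionLog]:
    """Remove unusable observations before estimation (M1 handling of BLQ).

    Observations with DV below ``lloq`` are excluded and logged with reason
    ``BLQ``; negative DV is excluded as ``NEGATIVE``.  Optionally, BLQ-range
    values within ``post_infusion_window`` days after an infusion end are
    additionally tagged ``BLQ_POST_INFUSION`` and values exceeding
    ``peak_multiple`` times the subject's maximum observed concentration are
    excluded as ``OUTLIER_HIGH``.  Dose rows always pass through.  Raises if
    nothing remains to fit.
    """
    df = dataset.df.copy()
    obs = df["EVID"] == 0
    n_obs = int(obs.sum())
    if df.loc[obs, "DV"].isna().any():
        raise DatasetValidationError("observation rows must carry DV")
    reason = pd.Series("", index=df.index, dtype=object)

    neg = obs & (df["DV"] < 0)
    blq = obs & ~neg & (df["DV"] < lloq)
    reason[neg] = "NEGATIVE"
    reason[blq] = "BLQ"

    if post_infusion_window is not None:
        inf_end = df[df["EVID"] == 1].groupby("ID").apply(
            lambda g: (g["TIME"] + g["AMT"] / g["RATE"]).to_numpy(),
            include_groups=False,
        )
        for i in df.index[blq]:
            sid = df.at[i, "ID"]
            t = df.at[i, "TIME"]
            ends = inf_end.get(sid, np.array([]))
            if np.any((t >= ends) & (t - ends <= post_infusion_window)):
                reason[i] = "BLQ_POST_INFUSION"
    if peak_multiple is not None:
        # "unusually high" rule: beyond peak_multiple times the subject's
        # median observed concentration (a model-free proxy for the peak)
        for _sid, grp in df[obs & (reason == "")].groupby("ID"):
            med = float(grp["DV"].median())
            hi = grp.index[grp["DV"] > peak_multiple * max(med, lloq)]
            reason[hi] = "OUTLIER_HIGH"

    excluded = reason != ""
    log = df[excluded].copy()
    log["REASON"] = reason[excluded]
    kept = df[~excluded].reset_index(drop=True)
    retained = TrialDataset(kept)
    n_retained = int((kept["EVID"] == 0).sum())
    if n_obs and n_retained == 0:
        raise DatasetValidationError("all observations excluded; nothing to fit")
    return retained, ExclusionLog(log=log, n_observations=n_obs, n_retained=n_retained)


def dataset_checksum(dataset: TrialDataset) -> str:
    """Stable content hash of an event table (for manifests)."""
    import hashlib

    buf = _io.StringIO()
    write_dataset(dataset, buf)
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()
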
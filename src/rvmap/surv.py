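"""Survival analysis on the first principal component of the wall-stress field.

The subjects x vertices end-systolic wall-stress matrix is reduced to one
score per subject — the projection onto its leading principal axis, computed
on vertex-centred (not vertex-standardized) data since stress shares units
across vertices. The score is oriented to correlate positively with mean
stress and scaled to unit SD, so the Cox hazard ratio is reported per one
standard deviation of the stress PC1. The proportional-hazards model adjusts
for age, sex, BSA, time from diagnosis and PH group, uses Efron's tie
correction, and reports the Wald confidence interval and p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

__all__ = ["Pc1Scores", "CoxFit", "stress_pc1", "fit_cox",
           "SURVIVAL_COVARIATES"]

# the survival adjustment set (ethnicity is not part of it)
SURVIVAL_COVARIATES = ("age", "sex", "bsa", "time_from_diagnosis", "ph_group")


@dataclass
class Pc1Scores:
    scores: np.ndarray              # (n,) unit-SD PC1 scores
    loading: np.ndarray             # (V,) vertex loading (unit vector)
    variance_share: float           # fraction of total variance on PC1


@dataclass
class CoxFit:
    hazard_ratio: float             # per 1 SD of the score
    ci_lower: float
    ci_upper: float
    p_value: float
    log_hr: float
    n: int
    n_events: int

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.hazard_ratio <= self.ci_upper):
            raise ValueError("confidence interval must contain the estimate")


def stress_pc1(W: np.ndarray, standardize_vertices: bool = False) -> Pc1Scores:
    """Leading principal-component score of a subjects x vertices matrix.

    Vertices are mean-centred; set ``standardize_vertices`` to scale each
    vertex to unit variance first (off by default). The score sign is chosen
    so it correlates positively with each subject's mean stress, and scores
    are standardized to SD 1.
    """
    # contiguity matters for bit-reproducibility: LAPACK results differ at
    # ulp level between C- and F-ordered inputs
    W = np.ascontiguousarray(W, dtype=np.float64)
    if W.ndim != 2 or W.shape[0] < 2:
        raise ValueError("need a subjects x vertices matrix with >= 2 subjects")
    Xc = W - W.mean(axis=0)
    if standardize_vertices:
        sd = Xc.std(axis=0, ddof=1)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    if not np.any(Xc):
        raise ValueError("stress matrix has zero variance")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    raw = U[:, 0] * s[0]
    loading = Vt[0]
    mean_stress = W.mean(axis=1)
    r = np.corrcoef(raw, mean_stress)[0, 1]
    if np.isfinite(r) and r < 0:
        raw = -raw
        loading = -loading
    sd_raw = raw.std(ddof=1)
    scores = raw / sd_raw
    var_share = float(s[0] ** 2 / np.sum(s ** 2))
    return Pc1Scores(scores=scores, loading=loading, variance_share=var_share)


def fit_cox(score: np.ndarray, records: pd.DataFrame,
            covariates: Sequence[str] = SURVIVAL_COVARIATES,
            time_col: str = "time_months", event_col: str = "event") -> CoxFit:
    """Cox proportional-hazards fit of mortality on the (unit-SD) score.

    ``records`` must carry the survival columns and the adjustment
    covariates; categorical covariates are dummy-coded. The hazard ratio is
    exp(coefficient) of the score, i.e. per one SD.
    """
    score = np.asarray(score, dtype=np.float64)
    if len(score) != len(records):
        raise ValueError("score length must match the record table")
    if records[event_col].sum() < 1:
        raise ValueError("need at least one event")
    if np.any(records[time_col].to_numpy() <= 0):
        raise ValueError("survival times must be positive")
    sd = score.std(ddof=1)
    if sd == 0:
        raise ValueError("score is constant")
    df = pd.DataFrame({time_col: records[time_col].to_numpy(),
                       event_col: records[event_col].to_numpy(),
                       "score": score / sd})
    for c in covariates:
        v = records[c]
        if pd.api.types.is_numeric_dtype(v) and v.nunique() > 2:
            df[c] = v.to_numpy(dtype=float)
        else:
            lv = v.astype(str)
            ref = lv.mode().iloc[0]
            for lev in sorted(lv.unique()):
                if lev != ref:
                    df[f"{c}[{lev}]"] = (lv == lev).to_numpy(dtype=float)
    constant = [c for c in df.columns
                if c not in (time_col, event_col) and df[c].nunique() <= 1]
    if constant:
        df = df.drop(columns=constant)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=time_col, event_col=event_col)
    except ConvergenceError as err:
        raise RuntimeError(f"Cox model failed to converge: {err}") from err
    log_hr = float(cph.params_["score"])
    se = float(cph.standard_errors_["score"])
    return CoxFit(hazard_ratio=float(np.exp(log_hr)),
                  ci_lower=float(np.exp(log_hr - 1.959963984540054 * se)),
                  ci_upper=float(np.exp(log_hr + 1.959963984540054 * se)),
                  p_value=float(cph.summary.loc["score", "p"]),
                  log_hr=log_hr, n=len(df),
                  n_events=int(df[event_col].sum()))
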
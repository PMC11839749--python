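"""Endpoint statistic and residual-purified intraindividual variability.

The endpoint of a rapid goal-directed contraction summarizes one trial in a
single unitless number: peak force and time-to-peak are each expressed as a
percentage of their target, and the endpoint is the Euclidean norm
(hypotenuse) of that pair,

    peak_pct = 100 * peak_force / target_force
    time_pct = 100 * time_to_peak / target_time
    endpoint = sqrt(peak_pct**2 + time_pct**2),

so an exactly on-target trial has endpoint 100*sqrt(2) ~ 141.42 %.

Outlier handling is a one-pass winsorization: within each group, endpoint
values beyond mean +/- 3 SD (mean and SD computed once on the raw pooled
participant-trials) are replaced by the boundary and flagged.

Motor inconsistency ("IIV") follows the residual-purification approach of
the cognitive-aging ISD literature: a single OLS regression of endpoint on
trial index (continuous, absorbing common practice effects) and a group
indicator (absorbing mean-level group differences) is fit over all
participant-trials; residuals are standardized over the whole sample
(z scores), converted to T-scores (T = 50 + 10 z), and each participant's
inconsistency is the sample SD of their trial T-scores. Pooled T-scores
therefore have mean 50 and SD 10 by construction, making the statistic
comparable across tasks and cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm


class InvalidTrialError(ValueError):
    """A trial has non-positive peak force or time-to-peak."""


def endpoint_pct(peak_force_N, time_to_peak_ms,
                 target_force_N: float = 10.0,
                 target_time_ms: float = 180.0):
    """Endpoint (%) for scalar or array peak/time values."""
    p = 100.0 * np.asarray(peak_force_N, dtype=float) / target_force_N
    t = 100.0 * np.asarray(time_to_peak_ms, dtype=float) / target_time_ms
    return np.hypot(p, t)


def compute_endpoint(
    features: pd.DataFrame,
    target_force_N: float = 10.0,
    target_time_ms: float = 180.0,
) -> pd.DataFrame:
    """Per-trial endpoint records from a feature table.

    Requires columns participant_id, trial, peak_force_N, time_to_peak_ms;
    returns those plus peak_force_pct, time_to_peak_pct, endpoint_pct and an
    ``imputed`` flag (False here; set by :func:`winsorize_endpoints`).
    """
    if target_force_N <= 0 or target_time_ms <= 0:
        raise ValueError("targets must be positive")
    peak = features["peak_force_N"].to_numpy(dtype=float)
    ttp = features["time_to_peak_ms"].to_numpy(dtype=float)
    bad = (peak <= 0) | (ttp <= 0)
    if bad.any():
        offenders = features.loc[bad, ["participant_id", "trial"]]
        raise InvalidTrialError(
            f"non-positive peak force or time-to-peak for "
            f"{offenders.to_records(index=False).tolist()}"
        )
    out = features[["participant_id", "trial"]].copy()
    out["peak_force_pct"] = 100.0 * peak / target_force_N
    out["time_to_peak_pct"] = 100.0 * ttp / target_time_ms
    out["endpoint_pct"] = np.hypot(out["peak_force_pct"], out["time_to_peak_pct"])
    out["imputed"] = False
    return out


def winsorize_endpoints(
    records: pd.DataFrame,
    groups: Mapping | pd.Series | dict,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cap endpoint values beyond the group mean +/- 3 SD at the boundary.

    ``groups`` maps participant_id -> group label; the mean and SD are
    computed once per group on the raw pooled participant-trials (not
    iterated after replacement). Returns the capped records (``imputed``
    flagged) and a per-group report with the bounds and percentage imputed.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    out = records.copy()
    glab = out["participant_id"].map(groups)
    if glab.isna().any():
        missing = out.loc[glab.isna(), "participant_id"].unique().tolist()
        raise ValueError(f"no group label for participants: {missing}")
    report_rows = []
    for g, idx in out.groupby(glab).groups.items():
        vals = out.loc[idx, "endpoint_pct"]
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 records")
        mu, sd = vals.mean(), vals.std(ddof=1)
        hi, lo = mu + 3.0 * sd, mu - 3.0 * sd
        above, below = vals > hi, vals < lo
        out.loc[vals.index[above], "endpoint_pct"] = hi
        out.loc[vals.index[below], "endpoint_pct"] = lo
        out.loc[vals.index[above | below], "imputed"] = True
        n_imp = int(above.sum() + below.sum())
        report_rows.append({
            "group": g, "n_trials": len(vals), "mean": mu, "sd": sd,
            "lower": lo, "upper": hi, "n_imputed_high": int(above.sum()),
            "n_imputed_low": int(below.sum()),
            "pct_imputed": 100.0 * n_imp / len(vals),
        })
    return out, pd.DataFrame(report_rows)


@dataclass
class PurifiedIIV:
    """Purification output: per-participant IIV, trial T-scores, model fit."""

    per_participant: pd.DataFrame  # participant_id, group, iiv, n_trials_used
    t_scores: pd.DataFrame         # participant_id, trial, t_score
    model_coefficients: dict       # intercept, trial slope, group terms
    residual_sd: float


def purify_iiv(
    records: pd.DataFrame,
    group_labels: Mapping | pd.Series | dict,
    n_trials: int | None = None,
) -> PurifiedIIV:
    """Residual-purified motor inconsistency per participant.

    One pooled OLS regression endpoint ~ 1 + trial + group over all
    participant-trials; residuals z-scored against the whole-sample residual
    SD (sample SD, n-1), T = 50 + 10 z; per participant the IIV is the
    sample SD of their T-scores. Participants with fewer than 2 retained
    trials are excluded with a warning.
    """
    groups = pd.Series(dict(group_labels)
                       if not isinstance(group_labels, pd.Series) else group_labels)
    df = records.copy()
    df["group"] = df["participant_id"].map(groups)
    if df["group"].isna().any():
        missing = df.loc[df["group"].isna(), "participant_id"].unique().tolist()
        raise ValueError(f"no group label for participants: {missing}")

    counts = df.groupby("participant_id").size()
    too_few = counts[counts < 2].index.tolist()
    if too_few:
        warnings.warn(
            f"excluding participants with < 2 retained trials: {too_few}",
            stacklevel=2,
        )
        df = df[~df["participant_id"].isin(too_few)]
    if df["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants for purification")

    y = df["endpoint_pct"].to_numpy(dtype=float)
    X = pd.DataFrame({"trial": df["trial"].to_numpy(dtype=float)}, index=df.index)
    group_dummies = pd.get_dummies(df["group"], prefix="group",
                                   drop_first=True, dtype=float)
    X = pd.concat([X, group_dummies], axis=1)
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    resid = np.asarray(fit.resid, dtype=float)
    resid_sd = float(np.std(resid, ddof=1))
    if resid_sd == 0:
        z = np.zeros_like(resid)
    else:
        z = (resid - resid.mean()) / resid_sd
    df = df.assign(t_score=50.0 + 10.0 * z)

    per = (
        df.groupby("participant_id")
        .agg(group=("group", "first"),
             iiv=("t_score", lambda s: s.std(ddof=1)),
             n_trials_used=("t_score", "size"))
        .reset_index()
    )
    if n_trials is not None:
        short = per[per["n_trials_used"] != n_trials]
        if len(short):
            warnings.warn(
                f"{len(short)} participant(s) have != {n_trials} retained trials",
                stacklevel=2,
            )
    return PurifiedIIV(
        per_participant=per,
        t_scores=df[["participant_id", "trial", "t_score"]].reset_index(drop=True),
        model_coefficients=dict(fit.params),
        residual_sd=resid_sd,
    )
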
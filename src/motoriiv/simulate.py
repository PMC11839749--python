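"""Seeded synthetic cohorts of rapid goal-directed force-pulse trials.

Emulates the data layout of a two-group motor-inconsistency study: each
participant (stroke survivor or healthy older adult) performs ``n_trials``
rapid isometric contractions toward a force-time target (10 N in 180 ms by
default), recorded as force traces sampled at ``fs`` Hz over a fixed
response window. The generative model is hierarchical:

* participant level — a mean peak force and mean time-to-peak (group
  multiplicative aiming bias plus a Gaussian between-person offset), and a
  latent trial-to-trial noise level: the group noise SDs scaled by a
  log-uniform multiplier, so latent inconsistency spans a controlled range
  across participants;
* trial level — peak force and time-to-peak drawn Gaussian around the
  participant means with a common linear practice drift in trial index;
  with probability ``outlier_rate`` a trial's noise SD is inflated
  (3x by default), producing occasional outlier trials;
* sample level — a truncated Gaussian-profile pulse (zero before
  contraction start, single peak, half-width-at-half-maximum =
  ``pulse_width_factor`` x time-to-peak) plus additive Gaussian sensor
  noise.

Participant metadata (sex, age, cognitive and clinical covariates) is drawn
at published group means/SDs (:mod:`motoriiv.reference`); the executive
function score is linked to the participant's latent noise level through a
single correlation loading so that prediction analyses have signal to find.
The latent per-participant noise SDs are exported alongside the data so
recovery of inconsistency estimates against ground truth can be tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from . import reference
from .features import ForceTrace, traces_to_long_frame

GROUPS = ("stroke", "healthy")

#: HWHM of a Gaussian with unit sigma.
_HWHM = math.sqrt(2.0 * math.log(2.0))


class TraceTruncationError(ValueError):
    """The drawn pulse does not fit inside the response window."""


def _default_mean_bias() -> dict:
    # stroke participants aim slightly low and slow on average
    return {"stroke": (0.97, 1.08), "healthy": (1.0, 1.0)}


def _default_trial_sd() -> dict:
    # (peak SD in N, time-to-peak SD in ms); stroke noisier than healthy
    return {"stroke": (1.0, 17.5), "healthy": (0.55, 10.0)}


def _default_drift() -> dict:
    # small practice trend per trial: (N/trial, ms/trial)
    return {"stroke": (0.01, -0.3), "healthy": (0.01, -0.3)}


@dataclass
class SimConfig:
    """All knobs of the cohort generator; defaults match the study layout."""

    n_stroke: int = 66
    n_healthy: int = 32
    n_trials: int = 30
    fs: float = 1000.0
    move_window_s: float = 3.0
    target_force_N: float = 10.0
    target_time_ms: float = 180.0
    pulse_width_factor: float = 0.5
    group_mean_bias: Mapping[str, tuple] = field(default_factory=_default_mean_bias)
    group_trial_sd: Mapping[str, tuple] = field(default_factory=_default_trial_sd)
    drift_per_trial: Mapping[str, tuple] = field(default_factory=_default_drift)
    participant_mean_sd: tuple = (1.3, 23.0)
    noise_multiplier_range: tuple = (0.5, 2.0)
    baseline_noise_sd: float = 0.05
    outlier_rate: float = 0.02
    outlier_sd_inflation: float = 3.0
    covariate_loading: float = 0.5
    covariate_missing_rate: float = 0.0
    onset_delay_range_s: tuple = (0.3, 0.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_stroke, self.n_healthy, self.n_trials) <= 0:
            raise ValueError("participant and trial counts must be positive")
        if self.fs <= 0 or self.move_window_s <= 0:
            raise ValueError("fs and move_window_s must be positive")
        if self.target_force_N <= 0 or self.target_time_ms <= 0:
            raise ValueError("targets must be positive")
        if not (0.0 <= self.outlier_rate < 1.0):
            raise ValueError("outlier_rate must be in [0, 1)")
        for g in GROUPS:
            if any(v < 0 for v in self.group_trial_sd[g]):
                raise ValueError("trial SDs must be >= 0")
        if self.baseline_noise_sd < 0 or any(v < 0 for v in self.participant_mean_sd):
            raise ValueError("SDs must be >= 0")
        lo, hi = self.noise_multiplier_range
        if not (0 < lo <= hi):
            raise ValueError("noise_multiplier_range must satisfy 0 < lo <= hi")
        if not (-1.0 <= self.covariate_loading <= 1.0):
            raise ValueError("covariate_loading must be in [-1, 1]")
        if not (0.0 <= self.covariate_missing_rate < 1.0):
            raise ValueError("covariate_missing_rate must be in [0, 1)")


@dataclass(frozen=True)
class ParticipantLatents:
    """Ground-truth participant parameters driving trial generation."""

    participant_id: str
    group: str
    mean_peak_N: float
    mean_ttp_ms: float
    peak_sd_N: float
    time_sd_ms: float
    noise_multiplier: float


@dataclass
class SimulatedCohort:
    """Generated cohort: metadata, latent truth, trial parameters, traces."""

    config: SimConfig
    participants: pd.DataFrame
    latents: pd.DataFrame
    trial_params: pd.DataFrame
    traces: list[ForceTrace]


def synthesize_pulse(
    peak_N: float,
    ttp_ms: float,
    onset_s: float,
    config: SimConfig,
) -> np.ndarray:
    """Noise-free truncated-Gaussian pulse over the response window.

    Zero before ``onset_s``; maximum ``peak_N`` at ``onset_s + ttp_ms``;
    Gaussian sigma set so the half-width at half maximum equals
    ``pulse_width_factor * ttp_ms``. Raises :class:`TraceTruncationError`
    when the pulse tail (peak + 3 sigma) overruns the window.
    """
    n = int(round(config.fs * config.move_window_s))
    t_ms = np.arange(n) * (1000.0 / config.fs)
    onset_ms = onset_s * 1000.0
    peak_ms = onset_ms + ttp_ms
    sigma_ms = config.pulse_width_factor * ttp_ms / _HWHM
    if peak_ms + 3.0 * sigma_ms > config.move_window_s * 1000.0:
        raise TraceTruncationError(
            f"pulse (peak at {peak_ms:.0f} ms, sigma {sigma_ms:.0f} ms) "
            f"exceeds the {config.move_window_s:.1f} s window"
        )
    pulse = peak_N * np.exp(-((t_ms - peak_ms) ** 2) / (2.0 * sigma_ms**2))
    pulse[t_ms < onset_ms] = 0.0
    return pulse


def draw_trial_params(
    latents: ParticipantLatents,
    trial_index: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[float, float, bool]:
    """Draw (peak force N, time-to-peak ms, outlier flag) for one trial.

    The linear practice drift for the participant's group is applied to the
    participant means before Gaussian trial noise; outlier trials use
    ``outlier_sd_inflation`` x the latent SDs.
    """
    if not (1 <= trial_index <= config.n_trials):
        raise ValueError(f"trial_index must be in [1, {config.n_trials}]")
    d_peak, d_time = config.drift_per_trial[latents.group]
    k = trial_index - 1
    is_outlier = bool(rng.random() < config.outlier_rate)
    infl = config.outlier_sd_inflation if is_outlier else 1.0
    peak = rng.normal(latents.mean_peak_N + d_peak * k, infl * latents.peak_sd_N)
    ttp = rng.normal(latents.mean_ttp_ms + d_time * k, infl * latents.time_sd_ms)
    # physical floors: force pulses cannot have non-positive peak or timing
    peak = max(peak, 0.05 * config.target_force_N)
    ttp = max(ttp, 0.2 * config.target_time_ms)
    return float(peak), float(ttp), is_outlier


def simulate_trial(
    latents: ParticipantLatents,
    trial_index: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> ForceTrace:
    """One sampled trial: drawn pulse parameters + sensor noise."""
    peak, ttp, _ = draw_trial_params(latents, trial_index, config, rng)
    lo, hi = config.onset_delay_range_s
    onset_s = rng.uniform(lo, hi)
    onset_s = round(onset_s * config.fs) / config.fs  # snap to the grid
    samples = synthesize_pulse(peak, ttp, onset_s, config)
    if config.baseline_noise_sd > 0:
        samples = samples + rng.normal(0.0, config.baseline_noise_sd, samples.size)
    return ForceTrace(latents.participant_id, trial_index, config.fs, samples)


def _draw_latents(config: SimConfig, rng: np.random.Generator):
    """Participant latents plus the standardized log noise multiplier."""
    lo, hi = config.noise_multiplier_range
    log_lo, log_hi = math.log(lo), math.log(hi)
    mu_log = 0.5 * (log_lo + log_hi)
    sd_log = (log_hi - log_lo) / math.sqrt(12.0)
    sd_peak_between, sd_time_between = config.participant_mean_sd

    latents: list[ParticipantLatents] = []
    z_noise: list[float] = []
    for group, n in (("stroke", config.n_stroke), ("healthy", config.n_healthy)):
        bias_f, bias_t = config.group_mean_bias[group]
        sd_f, sd_t = config.group_trial_sd[group]
        prefix = "S" if group == "stroke" else "H"
        for i in range(n):
            pid = f"{prefix}{i + 1:03d}"
            mean_peak = config.target_force_N * bias_f + rng.normal(0, sd_peak_between)
            mean_ttp = config.target_time_ms * bias_t + rng.normal(0, sd_time_between)
            mean_peak = max(mean_peak, 0.2 * config.target_force_N)
            mean_ttp = max(mean_ttp, 0.4 * config.target_time_ms)
            log_m = rng.uniform(log_lo, log_hi)
            m = math.exp(log_m)
            latents.append(ParticipantLatents(
                pid, group, mean_peak, mean_ttp, sd_f * m, sd_t * m, m))
            z_noise.append((log_m - mu_log) / sd_log if sd_log > 0 else 0.0)
    return latents, np.asarray(z_noise)


#: relative loading (sign and scale, multiplying ``covariate_loading``) of
#: each covariate on the latent noise level. Worse executive function,
#: slower processing, greater disability track higher inconsistency; better
#: memory, education (cognitive reserve) and global cognition track lower.
COVARIATE_NOISE_LOADINGS: dict[str, float] = {
    "executive_function": 1.0,
    "processing_speed": 0.5,
    "episodic_memory": -0.3,
    "visuospatial": -0.3,
    "education_years": -0.5,
    "drs2": -0.4,
    "mrs": 0.6,
}


def _draw_covariates(
    latents: list[ParticipantLatents],
    z_noise: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Metadata table at published group means/SDs; cognitive and clinical
    covariates are linked to the latent noise level through
    ``covariate_loading`` scaled by :data:`COVARIATE_NOISE_LOADINGS`."""
    ref = reference.GROUP_SUMMARIES
    rows = []
    for lat, z in zip(latents, z_noise):
        gi = 0 if lat.group == "stroke" else 1
        counts = reference.SEX_COUNTS[lat.group]
        p_female = counts["F"] / (counts["F"] + counts["M"])

        def draw(var: str, lower: float) -> float:
            s = ref[var][gi]
            rho = config.covariate_loading * COVARIATE_NOISE_LOADINGS.get(var, 0.0)
            rho = float(np.clip(rho, -1.0, 1.0))
            value = s.mean + s.sd * (
                rho * z + math.sqrt(max(1.0 - rho**2, 0.0)) * rng.normal())
            return max(float(value), lower)

        ratio_ref = ref["strength_ratio"][gi]
        ratio = float(np.clip(rng.normal(ratio_ref.mean, ratio_ref.sd), 0.2, 1.6))
        nonparetic = max(float(rng.normal(24.0, 6.0)), 8.0)

        mrs = np.nan
        if lat.group == "stroke":
            m = reference.MRS_STROKE
            rho_m = float(np.clip(
                config.covariate_loading * COVARIATE_NOISE_LOADINGS["mrs"],
                -1.0, 1.0))
            raw = m.mean + m.sd * (rho_m * z
                                   + math.sqrt(1.0 - rho_m**2) * rng.normal())
            mrs = float(np.clip(round(raw), 0, 5))

        age_ref = ref["age"][gi]
        rows.append({
            "participant_id": lat.participant_id,
            "group": lat.group,
            "sex": "F" if rng.random() < p_female else "M",
            "age": round(max(float(rng.normal(age_ref.mean, age_ref.sd)), 21.0), 1),
            "episodic_memory": float(round(draw("episodic_memory", 0.0))),
            "visuospatial": float(round(draw("visuospatial", 5.0))),
            "processing_speed": round(draw("processing_speed", 10.0), 1),
            "executive_function": round(draw("executive_function", 15.0), 1),
            "education_years": float(round(draw("education_years", 8.0))),
            "drs2": round(draw("drs2", 0.0), 1),
            "mrs": mrs,
            "strength_paretic": round(ratio * nonparetic, 2),
            "strength_nonparetic": round(nonparetic, 2),
        })
    meta = pd.DataFrame(rows)
    if config.covariate_missing_rate > 0:
        cog = ["episodic_memory", "visuospatial", "processing_speed",
               "executive_function", "drs2"]
        mask = rng.random((len(meta), len(cog))) < config.covariate_missing_rate
        for j, col in enumerate(cog):
            meta.loc[mask[:, j], col] = np.nan
    return meta


def _latents_frame(latents: list[ParticipantLatents]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(l) for l in latents])
    return df.rename(columns={"peak_sd_N": "latent_peak_sd_N",
                              "time_sd_ms": "latent_time_sd_ms"})


def simulate_cohort(config: SimConfig, traces: bool = True) -> SimulatedCohort:
    """Generate a full cohort from a single seed.

    With ``traces=False`` only the drawn per-trial pulse parameters are
    produced (no sampled force records) — the fast path for Monte-Carlo
    studies of the downstream statistics, which consume peak force and
    time-to-peak directly.
    """
    rng = np.random.default_rng(config.seed)
    lat_list, z_noise = _draw_latents(config, rng)
    meta = _draw_covariates(lat_list, z_noise, config, rng)

    rows = []
    all_traces: list[ForceTrace] = []
    for lat in lat_list:
        for k in range(1, config.n_trials + 1):
            if traces:
                peak, ttp, outlier = draw_trial_params(lat, k, config, rng)
                lo, hi = config.onset_delay_range_s
                onset_s = round(rng.uniform(lo, hi) * config.fs) / config.fs
                samples = synthesize_pulse(peak, ttp, onset_s, config)
                if config.baseline_noise_sd > 0:
                    samples = samples + rng.normal(
                        0.0, config.baseline_noise_sd, samples.size)
                all_traces.append(
                    ForceTrace(lat.participant_id, k, config.fs, samples))
            else:
                peak, ttp, outlier = draw_trial_params(lat, k, config, rng)
            rows.append({
                "participant_id": lat.participant_id, "group": lat.group,
                "trial": k, "peak_force_N": peak, "time_to_peak_ms": ttp,
                "outlier_drawn": outlier,
            })
    return SimulatedCohort(
        config=config,
        participants=meta,
        latents=_latents_frame(lat_list),
        trial_params=pd.DataFrame(rows),
        traces=all_traces,
    )


# ---------------------------------------------------------------- output ---

def write_metadata_csv(cohort: SimulatedCohort, path) -> None:
    """One row per participant; missing values as empty fields."""
    cohort.participants.to_csv(path, index=False)


def write_latents_csv(cohort: SimulatedCohort, path) -> None:
    """Latent-truth sidecar: per-participant noise SDs."""
    cols = ["participant_id", "latent_peak_sd_N", "latent_time_sd_ms",
            "noise_multiplier"]
    cohort.latents[cols].to_csv(path, index=False)


def write_traces_csv(cohort: SimulatedCohort, path) -> None:
    """Long-format trace table (one row per sample); large for full cohorts."""
    traces_to_long_frame(cohort.traces).to_csv(path, index=False)
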
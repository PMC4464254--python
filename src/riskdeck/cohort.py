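"""Synthetic cohort with known ground truth for the full study replica.

Generates everything the original design measured, at time-series (ROI)
scale: uniform-random and softmax model agents on the four-deck task; a
cohort of subjects whose novelty-seeking (NS) scores correlate with risk
preference l at a configurable level; block-design task BOLD series whose
risk-modulated amplitude varies with NS; and 240-volume resting series with
configurable inter-ROI correlation and injected motion spikes.

Cohort-level couplings are built from one latent standard-normal NS factor:
each correlated quantity q is drawn as rho * z_NS + sqrt(1 - rho^2) * eps,
then located/scaled (and discretised or clipped where the measurement
demands it), so the target correlations hold in the latent population and
the realized sample correlation is reported rather than forced.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import glm as _glm
from .model import ModelParams, choice_probabilities, deck_moments, trial_modulators
from .task import ChoiceDataset, TaskSequence, realize_outcomes

ROI_NAMES = ("r-PI", "l-AI", "r-striatum", "SMA")
#: resting ROI pairs whose coupling is NS-modulated (seed region: r-PI)
MODULATED_PAIRS = (("r-PI", "r-striatum"), ("r-PI", "l-AI"))


@dataclasses.dataclass
class CohortConfig:
    """Population parameters of the synthetic cohort (defaults = study conditions)."""

    n_subjects: int = 30
    ns_mean: float = 14.57
    ns_sd: float = 3.81
    ns_range: tuple[int, int] = (0, 34)
    l_mean: float = -0.15
    l_sd: float = 0.27
    l_bounds: tuple[float, float] = (-1.0, 1.0)
    rho_ns_l: float = 0.555
    #: target corr(true risk beta, NS) per ROI
    neural_effect: float = -0.51
    #: target corr(true resting pair coupling, NS) for the modulated pairs
    rsfc_effect: float = -0.511
    payoff_scale: float = 125.0
    # task BOLD
    beta_risk_mean: float = 1.0
    beta_risk_sd: float = 0.5
    beta_reward: float = 0.5
    beta_entropy: float = 0.3
    task_noise_sd: float = 1.0
    ar1_rho: float = 0.3
    # resting state
    n_rest_volumes: int = 240
    rest_base_corr: float = 0.3
    rest_pair_mean: float = 0.45
    rest_pair_sd: float = 0.15
    rest_spike_rate: float = 1.0  # expected spikes per subject
    rest_spike_magnitude: tuple[float, float] = (0.6, 1.2)  # mm
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for rho in (self.rho_ns_l, self.neural_effect, self.rsfc_effect):
            if not (-1 < rho < 1):
                raise ValueError("target correlations must lie in (-1, 1)")
        if self.ns_sd <= 0 or self.l_sd <= 0:
            raise ValueError("standard deviations must be positive")


@dataclasses.dataclass
class SubjectRecord:
    subject_id: str
    ns_score: int
    l_true: float
    dataset: ChoiceDataset
    beta_true: dict[str, dict[str, float]]  # roi -> regressor -> beta
    roi_task_series: dict[str, np.ndarray]  # roi -> (n_volumes,)
    task_motion: np.ndarray  # (n_task_volumes, 6)
    rest_series: np.ndarray  # (n_rest_volumes, n_rois)
    rest_motion: np.ndarray  # (n_rest_volumes, 6)
    rest_target: np.ndarray  # (n_rois, n_rois) generating correlation


@dataclasses.dataclass
class Cohort:
    subjects: list[SubjectRecord]
    config: CohortConfig
    task: TaskSequence
    layout: _glm.BlockLayout
    achieved: dict[str, float]  # realized sample correlations vs NS

    def ns_scores(self) -> np.ndarray:
        return np.array([s.ns_score for s in self.subjects], dtype=float)

    def l_true(self) -> np.ndarray:
        return np.array([s.l_true for s in self.subjects], dtype=float)


def simulate_random_agent(task: TaskSequence, rng: np.random.Generator) -> ChoiceDataset:
    """Uniform-random chooser: every deck equally likely, stimuli ignored."""
    choices = rng.integers(0, 4, size=task.n_trials)
    return realize_outcomes(task, choices, rng)


def simulate_model_agent(
    task: TaskSequence,
    l: float,
    payoff_scale: float = 125.0,
    rng: np.random.Generator | None = None,
) -> ChoiceDataset:
    """Softmax agent at risk preference l; choices sampled per trial."""
    if not (-1.0 <= l <= 1.0):
        raise ValueError("risk preference must lie in [-1, 1]")
    rng = rng or np.random.default_rng()
    e, v = deck_moments(task, payoff_scale)
    probs = choice_probabilities(e + l * v)
    u = rng.random((task.n_trials, 1))
    choices = (u > probs.cumsum(axis=1)).sum(axis=1)
    return realize_outcomes(task, choices, rng)


def _correlated_latent(z_ns: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    eps = rng.standard_normal(len(z_ns))
    return rho * z_ns + np.sqrt(1.0 - rho**2) * eps


def _ar1(n: int, rho: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    e = rng.standard_normal(n) * sd * np.sqrt(1.0 - rho**2)
    x = np.empty(n)
    x[0] = rng.standard_normal() * sd
    for t in range(1, n):
        x[t] = rho * x[t - 1] + e[t]
    return x


def _gentle_motion(n: int, rng: np.random.Generator, step_sd: float = 0.01) -> np.ndarray:
    """Small random-walk head drift, well below the scrub threshold."""
    return np.cumsum(rng.standard_normal((n, 6)) * step_sd, axis=0)


def simulate_task_bold(
    modulators: dict[str, np.ndarray],
    betas: dict[str, float],
    layout: _glm.BlockLayout | None = None,
    hrf: _glm.HRFParams | None = None,
    noise_sd: float = 1.0,
    ar1_rho: float = 0.3,
    baseline: float = 100.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One ROI's task series: baseline + sum(beta * convolved regressor) + AR(1) noise."""
    layout = layout or _glm.BlockLayout()
    rng = rng or np.random.default_rng()
    design = _glm.build_design(modulators, layout=layout, hrf=hrf, mean_center=True)
    series = np.full(layout.n_volumes, float(baseline))
    for name, beta in betas.items():
        series += beta * design.frame[name].to_numpy()
    series += _ar1(layout.n_volumes, ar1_rho, noise_sd, rng)
    return series


def simulate_resting_state(
    target_corr: np.ndarray,
    n_volumes: int = 240,
    spike_schedule: np.ndarray | None = None,
    spike_magnitudes: np.ndarray | None = None,
    artifact_amplitude: float = 4.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Resting multi-ROI series with a target correlation plus motion spikes.

    Returns (series (volumes x ROIs), motion table (volumes x 6)).  Each
    scheduled spike is a one-volume head excursion recorded in the motion
    table and mirrored as a shared signal artifact in every ROI, so a
    correct scrubbing step is required to recover the target correlation.
    """
    rng = rng or np.random.default_rng()
    C = np.asarray(target_corr, dtype=float)
    eigvals = np.linalg.eigvalsh(C)
    if eigvals.min() < -1e-10:
        raise ValueError("target correlation matrix must be positive semi-definite")
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(C)))
    series = rng.standard_normal((n_volumes, len(C))) @ L.T
    motion = _gentle_motion(n_volumes, rng)
    if spike_schedule is not None:
        spike_schedule = np.asarray(spike_schedule, dtype=int)
        mags = (
            np.asarray(spike_magnitudes, dtype=float)
            if spike_magnitudes is not None
            else np.full(len(spike_schedule), 0.8)
        )
        for k, mag in zip(spike_schedule, mags):
            motion[k, rng.integers(0, 3)] += mag  # one-volume translation excursion
            series[k] += artifact_amplitude * rng.standard_normal(len(C))
    return series, motion


def _rest_target_matrix(config: CohortConfig, pair_strengths: dict) -> np.ndarray:
    names = list(ROI_NAMES)
    C = np.full((4, 4), config.rest_base_corr)
    np.fill_diagonal(C, 1.0)
    for (a, b), s in pair_strengths.items():
        ia, ib = names.index(a), names.index(b)
        C[ia, ib] = C[ib, ia] = s
    # guard: repair marginal non-PSD matrices by eigenvalue clipping
    w, V = np.linalg.eigh(C)
    if w.min() < 1e-8:
        w = np.clip(w, 1e-8, None)
        C = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
    return C


def generate_cohort(config: CohortConfig, task: TaskSequence) -> Cohort:
    """Draw a full cohort: traits, behaviour, task BOLD, resting series."""
    rng = np.random.default_rng(config.rng_seed)
    layout = _glm.BlockLayout()
    if layout.n_trials != task.n_trials:
        raise ValueError(
            f"task has {task.n_trials} trials but the block layout expects {layout.n_trials}"
        )
    n = config.n_subjects
    z_ns = rng.standard_normal(n)
    ns = np.clip(
        np.round(config.ns_mean + config.ns_sd * z_ns), *config.ns_range
    ).astype(int)
    l_lat = _correlated_latent(z_ns, config.rho_ns_l, rng)
    l_true = np.clip(config.l_mean + config.l_sd * l_lat, *config.l_bounds)
    beta_risk = {
        roi: config.beta_risk_mean
        + config.beta_risk_sd * _correlated_latent(z_ns, config.neural_effect, rng)
        for roi in ROI_NAMES
    }
    pair_lat = {
        pair: config.rest_pair_mean
        + config.rest_pair_sd * _correlated_latent(z_ns, config.rsfc_effect, rng)
        for pair in MODULATED_PAIRS
    }

    subjects: list[SubjectRecord] = []
    for i in range(n):
        srng = np.random.default_rng([config.rng_seed, 1000 + i])
        dataset = simulate_model_agent(task, float(l_true[i]), config.payoff_scale, srng)
        mods = trial_modulators(
            task, ModelParams(float(l_true[i]), config.payoff_scale), dataset.choices
        )
        betas_i = {
            roi: {
                "risk": float(beta_risk[roi][i]),
                "reward": config.beta_reward,
                "entropy": config.beta_entropy,
            }
            for roi in ROI_NAMES
        }
        roi_series = {
            roi: simulate_task_bold(
                mods,
                betas_i[roi],
                layout=layout,
                noise_sd=config.task_noise_sd,
                ar1_rho=config.ar1_rho,
                rng=srng,
            )
            for roi in ROI_NAMES
        }
        task_motion = _gentle_motion(layout.n_volumes, srng)
        strengths = {
            pair: float(np.clip(pair_lat[pair][i], 0.05, 0.85)) for pair in MODULATED_PAIRS
        }
        target = _rest_target_matrix(config, strengths)
        n_spikes = srng.poisson(config.rest_spike_rate)
        n_spikes = min(n_spikes, config.n_rest_volumes // 20)  # stay under warning level
        sched = (
            srng.choice(np.arange(5, config.n_rest_volumes - 5), n_spikes, replace=False)
            if n_spikes
            else None
        )
        mags = (
            srng.uniform(*config.rest_spike_magnitude, size=n_spikes) if n_spikes else None
        )
        rest, rest_motion = simulate_resting_state(
            target,
            n_volumes=config.n_rest_volumes,
            spike_schedule=sched,
            spike_magnitudes=mags,
            rng=srng,
        )
        subjects.append(
            SubjectRecord(
                subject_id=f"sub-{i + 1:03d}",
                ns_score=int(ns[i]),
                l_true=float(l_true[i]),
                dataset=dataset,
                beta_true=betas_i,
                roi_task_series=roi_series,
                task_motion=task_motion,
                rest_series=rest,
                rest_motion=rest_motion,
                rest_target=target,
            )
        )

    def _corr(a, b):
        return float(np.corrcoef(a, b)[0, 1])

    achieved = {
        "ns_l": _corr(ns, l_true),
        "ns_beta_risk": _corr(ns, beta_risk[ROI_NAMES[0]]),
    }
    for pair in MODULATED_PAIRS:
        achieved[f"ns_rest_{pair[0]}__{pair[1]}"] = _corr(
            ns, np.clip(pair_lat[pair], 0.05, 0.85)
        )
    return Cohort(subjects=subjects, config=config, task=task, layout=layout, achieved=achieved)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Serialise a cohort as a directory tree of delimited-text tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {"subject_id": s.subject_id, "ns_score": s.ns_score, "l_true": s.l_true}
        for s in cohort.subjects
    ]
    pd.DataFrame(rows).to_csv(out / "subjects.csv", index=False)
    with open(out / "config.yaml", "w") as fh:
        cfg = dataclasses.asdict(cohort.config)
        cfg["ns_range"] = list(cfg["ns_range"])
        cfg["l_bounds"] = list(cfg["l_bounds"])
        cfg["rest_spike_magnitude"] = list(cfg["rest_spike_magnitude"])
        yaml.safe_dump(cfg, fh)
    for s in cohort.subjects:
        sdir = out / s.subject_id
        sdir.mkdir(exist_ok=True)
        s.dataset.to_csv(sdir / "choices.csv")
        pd.DataFrame(s.roi_task_series).to_csv(sdir / "task_bold.csv", index=False)
        pd.DataFrame(s.rest_series, columns=list(ROI_NAMES)).to_csv(
            sdir / "rest_bold.csv", index=False
        )
        mcols = ["tx_mm", "ty_mm", "tz_mm", "rx_deg", "ry_deg", "rz_deg"]
        pd.DataFrame(s.rest_motion, columns=mcols).to_csv(sdir / "motion.csv", index=False)
        pd.DataFrame(s.task_motion, columns=mcols).to_csv(
            sdir / "task_motion.csv", index=False
        )
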
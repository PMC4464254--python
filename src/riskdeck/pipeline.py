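"""End-to-end study replica: cohort -> fits -> GLM -> rsFC -> group statistics.

One seeded configuration drives every stage; all stage seeds derive from
the global seed, so two runs of the same configuration produce identical
reports.  The behavioural comparison table (model-agent cohort vs
uniform-random agents) mirrors the conventional goodness-of-fit layout:
mean +/- SD of MLL / AIC / AICc / BIC per group with an independent-samples
t-test per statistic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import glm as _glm
from . import rsfc as _rsfc
from .cohort import (
    MODULATED_PAIRS,
    ROI_NAMES,
    Cohort,
    CohortConfig,
    generate_cohort,
    simulate_random_agent,
    write_cohort,
)
from .fitting import FitResult, SearchConfig, compare_fit_groups, fit_risk_preference
from .model import ModelParams, trial_modulators
from .stats import partial_correlation, pearson, sobel_mediation
from .task import generate_task_sequence

logger = logging.getLogger("riskdeck")

#: ROI whose risk activation is examined after controlling for risk preference
FOCAL_ROI = "r-PI"


@dataclasses.dataclass
class PipelineConfig:
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    search: SearchConfig = dataclasses.field(default_factory=SearchConfig)
    n_random_agents: int = 200
    #: group-size convention for the random-agent information criteria
    random_group_m: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        # every stochastic stage's seed derives from the global seed
        ss = np.random.SeedSequence(self.seed)
        task_seed, cohort_seed, random_seed, search_seed = (
            int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
        )
        self.task_seed = task_seed
        self.random_agent_seed = random_seed
        self.cohort = dataclasses.replace(self.cohort, rng_seed=cohort_seed)
        self.search = dataclasses.replace(self.search, rng_seed=search_seed)

    def to_yaml(self, path) -> None:
        d = {
            "seed": self.seed,
            "n_random_agents": self.n_random_agents,
            "random_group_m": self.random_group_m,
            "cohort": _plain(dataclasses.asdict(self.cohort)),
            "search": _plain(dataclasses.asdict(self.search)),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        cohort = d.get("cohort", {})
        search = d.get("search", {})
        for key in ("ns_range", "l_bounds", "rest_spike_magnitude"):
            if key in cohort:
                cohort[key] = tuple(cohort[key])
        if "bounds" in search:
            search["bounds"] = tuple(search["bounds"])
        return cls(
            cohort=CohortConfig(**cohort),
            search=SearchConfig(**search),
            n_random_agents=d.get("n_random_agents", 200),
            random_group_m=d.get("random_group_m", 1000),
            seed=d.get("seed", 0),
        )


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_plain(v) for v in obj]
    return obj


def make_table1(
    fits_model: list[FitResult], fits_random: list[FitResult]
) -> pd.DataFrame:
    """Goodness-of-fit comparison table: model-agent group vs random group."""
    comp = compare_fit_groups(fits_model, fits_random)
    rows = []
    for stat in ("aic", "aicc", "bic", "mll"):
        c = comp[stat]
        rows.append(
            {
                "statistic": stat.upper(),
                "cohort_mean": c["mean_a"],
                "cohort_sd": c["sd_a"],
                "random_mean": c["mean_b"],
                "random_sd": c["sd_b"],
                "t": c["t"],
                "p": c["p"],
            }
        )
    return pd.DataFrame(rows)


def fit_cohort_behaviour(cohort: Cohort, search: SearchConfig) -> list[FitResult]:
    return [
        fit_risk_preference(
            s.dataset, search, cohort.config.payoff_scale, group_size=len(cohort.subjects)
        )
        for s in cohort.subjects
    ]


def fit_random_agents(
    task, n_agents: int, search: SearchConfig, payoff_scale: float, group_m: int, seed: int
) -> list[FitResult]:
    rng = np.random.default_rng(seed)
    fits = []
    for _ in range(n_agents):
        ds = simulate_random_agent(task, rng)
        fits.append(fit_risk_preference(ds, search, payoff_scale, group_size=group_m))
    return fits


def subject_glm(cohort: Cohort, fits: list[FitResult]) -> pd.DataFrame:
    """Per-subject, per-ROI z-transformed risk/reward/entropy effects.

    Regressors are rebuilt from each subject's *fitted* model (the
    estimated trial quantities, not the generating ones), with six motion
    regressors included.
    """
    rows = []
    for s, f in zip(cohort.subjects, fits):
        mods = trial_modulators(
            cohort.task,
            ModelParams(f.l_hat, cohort.config.payoff_scale),
            s.dataset.choices,
        )
        design = _glm.build_design(
            mods, layout=cohort.layout, mean_center=True, motion=s.task_motion
        )
        for roi in ROI_NAMES:
            res = _glm.fit_glm(s.roi_task_series[roi], design)
            row = {"subject_id": s.subject_id, "roi": roi}
            for name in ("risk", "reward", "entropy"):
                row.update({f"z_{name}": res.coef(name)["z"], f"beta_{name}": res.coef(name)["beta"]})
            rows.append(row)
    return pd.DataFrame(rows)


def subject_rsfc(cohort: Cohort) -> pd.DataFrame:
    """Per-subject Fisher-z connectivity for the six ROI pairs."""
    rows = []
    for s in cohort.subjects:
        results = _rsfc.connectivity_matrix(
            s.rest_series, motion=s.rest_motion, roi_names=list(ROI_NAMES)
        )
        for c in results:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "pair": f"{c.roi_a}__{c.roi_b}",
                    "r": c.r,
                    "z": c.z,
                    "n_volumes": c.n_volumes,
                    "n_scrubbed": c.n_scrubbed,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Run every stage and return (and optionally write) the report bundle."""
    t0 = time.time()
    if config.cohort.n_subjects < 5:
        raise ValueError(
            "pipeline group statistics (correlation, partial correlation, mediation) "
            f"need at least 5 subjects; got {config.cohort.n_subjects}"
        )
    report: dict = {"config_seed": config.seed}

    logger.info("stage=task seed=%d", config.task_seed)
    task = generate_task_sequence(180, rng_seed=config.task_seed)

    logger.info("stage=cohort seed=%d n=%d", config.cohort.rng_seed, config.cohort.n_subjects)
    cohort = generate_cohort(config.cohort, task)
    ns = cohort.ns_scores()

    logger.info("stage=fit_behaviour")
    fits = fit_cohort_behaviour(cohort, config.search)
    l_hat = np.array([f.l_hat for f in fits])

    table1 = None
    if config.n_random_agents >= 2:
        logger.info("stage=fit_random n=%d", config.n_random_agents)
        random_fits = fit_random_agents(
            task,
            config.n_random_agents,
            config.search,
            config.cohort.payoff_scale,
            config.random_group_m,
            config.random_agent_seed,
        )
        table1 = make_table1(fits, random_fits)
        report["table1"] = table1.to_dict(orient="records")
        report["random_accuracy_mean"] = float(
            np.mean([f.accuracy for f in random_fits])
        )
    report["cohort_accuracy_mean"] = float(np.mean([f.accuracy for f in fits]))

    logger.info("stage=behaviour_correlation")
    ns_l = pearson(ns, l_hat)
    report["ns_l_correlation"] = ns_l.to_dict()
    report["subjects"] = [
        {
            "subject_id": s.subject_id,
            "ns_score": s.ns_score,
            "l_true": s.l_true,
            "l_hat": f.l_hat,
            "mll": f.mll,
            "accuracy": f.accuracy,
        }
        for s, f in zip(cohort.subjects, fits)
    ]

    logger.info("stage=glm")
    glm_df = subject_glm(cohort, fits)
    report["activation"] = {}
    for roi in ROI_NAMES:
        z = glm_df.loc[glm_df.roi == roi, "z_risk"].to_numpy()
        rep = pearson(ns, z, n_tests=len(ROI_NAMES))
        report["activation"][roi] = {
            "group_test": _glm.group_activation_test(z),
            "ns_correlation": rep.to_dict(),
        }
    z_focal = glm_df.loc[glm_df.roi == FOCAL_ROI, "z_risk"].to_numpy()
    report["partial_correlation"] = {
        FOCAL_ROI: partial_correlation(ns, z_focal, l_hat, n_tests=len(ROI_NAMES)).to_dict()
    }
    report["mediation"] = sobel_mediation(z_focal, l_hat, ns).to_dict()

    logger.info("stage=rsfc")
    rsfc_df = subject_rsfc(cohort)
    pairs = sorted(rsfc_df["pair"].unique())
    report["rsfc"] = {}
    for pair in pairs:
        z = rsfc_df.loc[rsfc_df.pair == pair, "z"].to_numpy()
        report["rsfc"][pair] = pearson(ns, z, n_tests=len(pairs)).to_dict()
    report["rsfc_modulated_pairs"] = [f"{a}__{b}" for a, b in MODULATED_PAIRS]

    report["achieved_generating_correlations"] = cohort.achieved
    report["elapsed_s"] = round(time.time() - t0, 2)

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, out / "cohort")
        glm_df.to_csv(out / "glm_effects.csv", index=False)
        rsfc_df.to_csv(out / "rsfc.csv", index=False)
        if table1 is not None:
            table1.to_csv(out / "table1.csv", index=False)
        config.to_yaml(out / "config.yaml")
        clean = {k: v for k, v in report.items() if k != "elapsed_s"}
        with open(out / "report.json", "w") as fh:
            json.dump(clean, fh, indent=2, default=float)
    return report
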
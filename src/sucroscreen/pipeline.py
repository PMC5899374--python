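"""End-to-end study analysis: orchestration and report assembly.

Runs, per lesion type, the frequentist prevalence and ROC/AUC analysis at
both sampling times, the paired pre/post comparison, the Se/Sp of the
dichotomized test at the configured cutoff, and the Bayesian latent class
fit on the cross-classified counts; plus the study-level quantities
(45/90-min correlation, incidence rate, prior table).

All randomness fans out from one master seed through a counter-based
scheme recorded in the report metadata, so a report is reproducible from
its own metadata.
"""

from __future__ import annotations

import dataclasses
from typing import Any, Mapping

import numpy as np

from . import accuracy
from .latent_class import (CrossClassifiedCounts, MCMCSchedule, desk_schedule,
                           pattern_index, run_mcmc, summarize_posterior)
from .priors import PriorSet, elicited_priors, prior_table
from .simulate import LESION_COLUMNS, StudyDataset


def counts_from_dataset(dataset: StudyDataset, lesion: str = "gl",
                        cutoff: float = 24.0) -> CrossClassifiedCounts:
    """Cross-classify records into the 2-population x 8-pattern table.

    T1 = sucrose at 45 min >= cutoff, T2 = sucrose at 90 min >= cutoff,
    T3 = the gastroscopy call for the chosen lesion type; populations are
    the pre- and post-weaning occasions.
    """
    df = dataset.to_frame()
    counts = np.zeros((2, 8), dtype=np.int64)
    t1 = accuracy.dichotomize(df["sucrose45_umol_l"].to_numpy(), cutoff)
    t2 = accuracy.dichotomize(df["sucrose90_umol_l"].to_numpy(), cutoff)
    t3 = df[lesion].to_numpy().astype(int)
    pop = (df["occasion"] == "post").to_numpy().astype(int)
    for p, i, j, k in zip(pop, t1, t2, t3):
        counts[p, pattern_index(i, j, k)] += 1
    return CrossClassifiedCounts(counts)


def _stage_seed(master: int, counter: int) -> int:
    # simple counter-based fan-out; recorded in report metadata
    return (int(master) * 1_000_003 + 7919 * counter) % 2**31


@dataclasses.dataclass(frozen=True)
class StudyConfig:
    """Settings for a full study run."""

    cutoff: float = 24.0
    n_boot: int = 2000
    lesions: tuple[str, ...] = LESION_COLUMNS
    weeks_between: float = 3.0
    mcmc: MCMCSchedule | None = None       # default: desk profile
    priors: PriorSet | None = None         # default: elicited set
    seed: int = 0
    run_bayes: bool = True


@dataclasses.dataclass
class StudyReport:
    """Assembled results; stages that failed carry an error string instead."""

    correlation: float | None
    incidence: Mapping[str, Any]
    prevalence: Mapping[str, Any]
    accuracy: Mapping[str, Any]
    bayes: Mapping[str, Any]
    priors: Any
    errors: Mapping[str, str]
    metadata: Mapping[str, Any]


def run_study(dataset: StudyDataset, config: StudyConfig | None = None) -> StudyReport:
    """Execute the full analysis and assemble a report.

    Each stage is isolated: a failure (e.g. paired analyses on a dataset
    with a single occasion) is recorded under ``errors`` with a stage
    label, and the remaining stages still run.  No lesion type is silently
    dropped.
    """
    config = config if config is not None else StudyConfig()
    priors = config.priors if config.priors is not None else elicited_priors()
    schedule = config.mcmc if config.mcmc is not None else desk_schedule()
    errors: dict[str, str] = {}
    seeds: dict[str, int] = {}
    counter = 0

    def next_seed(stage: str) -> int:
        nonlocal counter
        s = _stage_seed(config.seed, counter)
        seeds[stage] = s
        counter += 1
        return s

    df = dataset.to_frame()
    correlation = None
    try:
        correlation = accuracy.spearman_rho(df["sucrose45_umol_l"],
                                            df["sucrose90_umol_l"])
    except ValueError as e:
        errors["correlation"] = str(e)

    incidence: dict[str, Any] = {}
    prevalence_tab: dict[str, Any] = {}
    accuracy_tab: dict[str, Any] = {}
    bayes_tab: dict[str, Any] = {}

    for lesion in config.lesions:
        for occasion in ("pre", "post"):
            stage = f"prevalence/{lesion}/{occasion}"
            try:
                est, ci = accuracy.prevalence(dataset, lesion, occasion,
                                              n_boot=config.n_boot,
                                              seed=next_seed(stage))
                prevalence_tab[(lesion, occasion)] = {"estimate": est, "ci": ci}
            except ValueError as e:
                errors[stage] = str(e)
        stage = f"paired_test/{lesion}"
        try:
            stat, p = accuracy.paired_prevalence_test(dataset, lesion)
            incidence.setdefault("paired_tests", {})[lesion] = \
                {"n_discordant": stat, "p_value": p}
        except ValueError as e:
            errors[stage] = str(e)
        stage = f"incidence/{lesion}"
        try:
            incidence.setdefault("rates_per_foal_week", {})[lesion] = \
                accuracy.incidence_rate(dataset, lesion, config.weeks_between)
        except ValueError as e:
            errors[stage] = str(e)

        for time in (45, 90):
            stage = f"auc/{lesion}/{time}"
            try:
                accuracy_tab[(lesion, time, "auc")] = accuracy.cluster_bootstrap_auc(
                    dataset, lesion, time, n_boot=config.n_boot,
                    seed=next_seed(stage))
            except ValueError as e:
                errors[stage] = str(e)
            stage = f"se_sp/{lesion}/{time}"
            try:
                accuracy_tab[(lesion, time, "cutoff")] = accuracy.se_sp_at_cutoff(
                    dataset, lesion, time, cutoff=config.cutoff,
                    n_boot=config.n_boot, seed=next_seed(stage))
            except ValueError as e:
                errors[stage] = str(e)
        stage = f"auc_compare/{lesion}"
        try:
            accuracy_tab[(lesion, "compare")] = accuracy.compare_auc(
                dataset, lesion, n_boot=config.n_boot, seed=next_seed(stage))
        except ValueError as e:
            errors[stage] = str(e)

        if config.run_bayes:
            stage = f"latent_class/{lesion}"
            try:
                counts = counts_from_dataset(dataset, lesion, config.cutoff)
                chains = run_mcmc(counts, priors,
                                  schedule.replace(seed=next_seed(stage)))
                bayes_tab[lesion] = summarize_posterior(chains)
            except (ValueError, RuntimeError) as e:
                errors[stage] = str(e)

    metadata = {
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "cutoff": config.cutoff,
        "n_boot": config.n_boot,
        "mcmc_schedule": dataclasses.asdict(schedule),
        "n_records": len(dataset),
        "n_foals": len(dataset.foal_ids),
    }
    return StudyReport(
        correlation=correlation,
        incidence=incidence,
        prevalence=prevalence_tab,
        accuracy=accuracy_tab,
        bayes=bayes_tab,
        priors=prior_table(priors),
        errors=errors,
        metadata=metadata,
    )
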
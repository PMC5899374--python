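"""Beta prior distributions for the latent class analysis.

The Bayesian latent class model combines the cross-classified test results
with Beta priors elicited for each parameter: mildly informative priors for
the pre- and post-weaning lesion prevalences and for gastroscopy sensitivity
and specificity, and uniform Beta(1,1) priors for the two blood-sucrose
tests, for which no prior information existed.

This module represents those priors, summarises them (mean, median, central
probability interval), and exposes the elicited prior set used throughout
the pipeline.
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from scipy import stats


def round_half_up(x: float, ndigits: int) -> float:
    """Round ``x`` to ``ndigits`` decimals, halves away from zero.

    Matches the display convention of the elicited-prior table (e.g. 0.045
    prints as 0.05), unlike banker's rounding.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclasses.dataclass(frozen=True)
class BetaPrior:
    """A Beta(alpha, beta) prior on a probability parameter."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"Beta parameters must be positive, got ({self.alpha}, {self.beta})"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def dist(self):
        """The scipy frozen distribution."""
        return stats.beta(self.alpha, self.beta)


@dataclasses.dataclass(frozen=True)
class PriorSummary:
    """Mean, median and central equal-tailed interval of a Beta prior.

    ``interval`` holds the (1-mass)/2 and 1-(1-mass)/2 quantiles, so with
    ``mass=0.90`` it is the 5th-95th percentile interval.
    """

    mean: float
    median: float
    interval: tuple[float, float]
    mass: float

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if not (lo <= self.median <= hi):
            raise ValueError("interval must bracket the median")
        if not (0.0 < self.mass < 1.0):
            raise ValueError("mass must be in (0, 1)")

    def rounded(self, moments_nd: int = 2, interval_nd: int = 3) -> "PriorSummary":
        """Summary rounded to display precision (full precision retained on self)."""
        lo, hi = self.interval
        return PriorSummary(
            mean=round_half_up(self.mean, moments_nd),
            median=round_half_up(self.median, moments_nd),
            interval=(round_half_up(lo, interval_nd), round_half_up(hi, interval_nd)),
            mass=self.mass,
        )


def beta_summary(prior: BetaPrior, mass: float = 0.90) -> PriorSummary:
    """Summarise a Beta prior: mean, median and central ``mass`` interval.

    Quantiles are obtained by numerically inverting the regularized
    incomplete beta function (scipy's ``beta.ppf``), accurate to well below
    1e-6 in absolute terms.
    """
    if not (0.0 < mass < 1.0):
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    d = prior.dist
    tail = (1.0 - mass) / 2.0
    return PriorSummary(
        mean=prior.mean,
        median=float(d.ppf(0.5)),
        interval=(float(d.ppf(tail)), float(d.ppf(1.0 - tail))),
        mass=mass,
    )


@dataclasses.dataclass(frozen=True)
class PriorSet:
    """The eight Beta priors of the two-population, three-test model."""

    prev_pre: BetaPrior
    prev_post: BetaPrior
    se_endo: BetaPrior
    sp_endo: BetaPrior
    se_s45: BetaPrior
    sp_s45: BetaPrior
    se_s90: BetaPrior
    sp_s90: BetaPrior

    def as_dict(self) -> dict[str, BetaPrior]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}


def elicited_priors() -> PriorSet:
    """The study's elicited prior set.

    Mildly informative priors for prevalence (low pre-weaning, high
    post-weaning) and for gastroscopy (sensitive, near-perfectly specific);
    uniform priors for both sucrose tests.
    """
    return PriorSet(
        prev_pre=BetaPrior(2, 8),
        prev_post=BetaPrior(6, 4),
        se_endo=BetaPrior(8, 2),
        sp_endo=BetaPrior(99, 1),
        se_s45=BetaPrior(1, 1),
        sp_s45=BetaPrior(1, 1),
        se_s90=BetaPrior(1, 1),
        sp_s90=BetaPrior(1, 1),
    )


# Row labels for the prior table, in presentation order.
_ROW_LABELS = {
    "prev_pre": ("Pre-weaning", "Prevalence"),
    "prev_post": ("Post-weaning", "Prevalence"),
    "se_endo": ("Endoscopy", "Sensitivity"),
    "sp_endo": ("Endoscopy", "Specificity"),
    "se_s45": ("Sucrose 45", "Sensitivity"),
    "sp_s45": ("Sucrose 45", "Specificity"),
    "se_s90": ("Sucrose 90", "Sensitivity"),
    "sp_s90": ("Sucrose 90", "Specificity"),
}


def prior_table(priors: PriorSet | None = None, mass: float = 0.90,
                rounded: bool = True) -> pd.DataFrame:
    """Tabulate a prior set: one row per parameter with summary columns."""
    priors = priors if priors is not None else elicited_priors()
    rows = []
    for name, prior in priors.as_dict().items():
        s = beta_summary(prior, mass)
        if rounded:
            s = s.rounded()
        group, measure = _ROW_LABELS[name]
        rows.append(
            {
                "population_or_test": group,
                "measure": measure,
                "alpha": prior.alpha,
                "beta": prior.beta,
                "mean": s.mean,
                "median": s.median,
                "lower": s.interval[0],
                "upper": s.interval[1],
            }
        )
    return pd.DataFrame(rows)
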
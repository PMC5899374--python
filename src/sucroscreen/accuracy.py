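"""Frequentist diagnostic-accuracy analysis.

Empirical ROC curves and Mann-Whitney AUC for blood sucrose against the
gastroscopy call, with confidence intervals from a cluster bootstrap that
resamples foals (not individual foal-occasion records) so the repeated
measures on the same animal stay together.  Cutoff selection by Youden's
index, a sensitivity-weighted variant, or maximal sensitivity; plus
prevalence, an exact paired pre/post comparison, incidence, Spearman
correlation and inter-observer agreement (percent agreement and Cohen's
kappa).

Positivity convention: a sucrose concentration >= the cutoff is a positive
test.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import LESION_COLUMNS, StudyDataset

TIMES = (45, 90)


def _time_column(time: int) -> str:
    if int(time) not in TIMES:
        raise ValueError(f"time must be one of {TIMES}, got {time}")
    return f"sucrose{int(time)}_umol_l"


def _check_lesion(lesion: str) -> str:
    lesion = lesion.lower()
    if lesion not in LESION_COLUMNS:
        raise ValueError(f"lesion must be one of {LESION_COLUMNS}, got {lesion!r}")
    return lesion


def dichotomize(value, cutoff: float):
    """1 (positive) iff ``value >= cutoff``; accepts scalars or arrays."""
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("sucrose concentrations must be positive")
    out = (arr >= cutoff).astype(int)
    return int(out) if np.isscalar(value) or out.ndim == 0 else out


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant sequence")
    return float(stats.spearmanr(x, y).statistic)


@dataclasses.dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC curve: (threshold, Se, 1-Sp) per distinct threshold.

    Thresholds are in decreasing order starting at +inf (the (0,0)
    endpoint); the lowest observed value classifies every record positive,
    giving the (1,1) endpoint.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        se = np.asarray(self.sensitivity, dtype=float)
        fpr = np.asarray(self.one_minus_specificity, dtype=float)
        if not (t.shape == se.shape == fpr.shape):
            raise ValueError("mismatched curve arrays")
        if np.any(np.diff(t) > 0):
            raise ValueError("thresholds must be non-increasing")
        if np.any(np.diff(se) < 0) or np.any(np.diff(fpr) < 0):
            raise ValueError("Se and 1-Sp must be non-decreasing as threshold falls")
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "sensitivity", se)
        object.__setattr__(self, "one_minus_specificity", fpr)

    def __len__(self) -> int:
        return len(self.thresholds)

    def trapezoidal_area(self) -> float:
        return float(np.trapezoid(self.sensitivity, self.one_minus_specificity))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "sensitivity": self.sensitivity,
            "one_minus_specificity": self.one_minus_specificity,
        })


def _as_binary_labels(labels) -> np.ndarray:
    lab = np.asarray(labels).astype(int)
    if not np.isin(lab, (0, 1)).all():
        raise ValueError("labels must be binary")
    if lab.min() == lab.max():
        raise ValueError("both classes must be present")
    return lab


def empirical_roc(values: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """Empirical ROC over all distinct observed thresholds (>= positive)."""
    vals = np.asarray(values, dtype=float)
    lab = _as_binary_labels(labels)
    if vals.shape != lab.shape:
        raise ValueError("values and labels must have equal length")
    thresholds = np.concatenate(([np.inf], np.unique(vals)[::-1]))
    pos = vals[lab == 1]
    neg = vals[lab == 0]
    se = np.array([(pos >= t).mean() for t in thresholds])
    fpr = np.array([(neg >= t).mean() for t in thresholds])
    return ROCCurve(thresholds, se, fpr)


def auc_point(values: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC: P(positive-class value > negative-class value),
    ties counted one half."""
    vals = np.asarray(values, dtype=float)
    lab = _as_binary_labels(labels)
    return _auc_fast(vals, lab)


def _auc_fast(vals: np.ndarray, lab: np.ndarray) -> float:
    n1 = int(lab.sum())
    n0 = len(lab) - n1
    ranks = stats.rankdata(vals)
    return float((ranks[lab == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# ---------------------------------------------------------------------------
# Cluster bootstrap


class DegenerateResampleError(RuntimeError):
    """Bootstrap could not produce a two-class replicate."""


def _foal_groups(df: pd.DataFrame) -> list[np.ndarray]:
    return [idx.to_numpy() for _, idx in df.groupby("foal_id").groups.items()]


def _resample_indices(groups: list[np.ndarray], rng: np.random.Generator) -> np.ndarray:
    pick = rng.integers(0, len(groups), size=len(groups))
    return np.concatenate([groups[k] for k in pick])


@dataclasses.dataclass(frozen=True)
class AUCResult:
    point: float
    ci: tuple[float, float] | None
    n_boot: int
    seed: int
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.point <= 1.0):
            raise ValueError("AUC must be in [0, 1]")


def _bootstrap_stat(df, groups, stat, n_boot, rng, max_redraw=100):
    """Percentile bootstrap over foals; redraws single-class replicates."""
    reps = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        for attempt in range(max_redraw):
            idx = _resample_indices(groups, rng)
            try:
                reps[b] = stat(df.iloc[idx])
                break
            except ValueError:
                n_redrawn += 1
        else:
            raise DegenerateResampleError(
                f"replicate {b}: no valid resample in {max_redraw} attempts"
            )
    return reps, n_redrawn


def cluster_bootstrap_auc(dataset: StudyDataset, lesion: str = "gl",
                          time: int = 45, n_boot: int = 2000,
                          seed: int = 0) -> AUCResult:
    """AUC with a percentile CI from a foal-level cluster bootstrap.

    The point estimate is the Mann-Whitney AUC of the original sample;
    foals are resampled with replacement carrying both of their occasions,
    and the CI is the 2.5th/97.5th percentile of the replicate AUCs.
    Replicates that lose one of the two classes are redrawn (counted in
    ``n_redrawn``).
    """
    lesion = _check_lesion(lesion)
    col = _time_column(time)
    df = dataset.to_frame().reset_index(drop=True)
    point = auc_point(df[col].to_numpy(), df[lesion].to_numpy())
    if n_boot == 0:
        return AUCResult(point=point, ci=None, n_boot=0, seed=seed)
    groups = _foal_groups(df)
    rng = np.random.default_rng(int(seed) % 2**31)

    def stat(sub: pd.DataFrame) -> float:
        lab = sub[lesion].to_numpy()
        if lab.min() == lab.max():
            raise ValueError("single class")
        return _auc_fast(sub[col].to_numpy(), lab)

    reps, n_redrawn = _bootstrap_stat(df, groups, stat, n_boot, rng)
    ci = (float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5)))
    return AUCResult(point=point, ci=ci, n_boot=n_boot, seed=seed,
                     n_redrawn=n_redrawn)


@dataclasses.dataclass(frozen=True)
class AUCComparison:
    """Paired bootstrap comparison of the 45- and 90-min AUCs."""

    delta: float
    ci: tuple[float, float] | None
    p_value: float
    n_boot: int
    seed: int


def compare_auc(dataset: StudyDataset, lesion: str = "gl",
                n_boot: int = 2000, seed: int = 0) -> AUCComparison:
    """AUC(45 min) - AUC(90 min), the same resampled foals feeding both.

    The p-value is the doubled smaller tail fraction of the replicate
    deltas around zero, floored at 2/n_boot (the resolution of a finite
    bootstrap) and capped at 1.
    """
    lesion = _check_lesion(lesion)
    df = dataset.to_frame().reset_index(drop=True)
    lab_all = df[lesion].to_numpy()
    if lab_all.min() == lab_all.max():
        raise ValueError("both lesion classes must be present")
    c45, c90 = _time_column(45), _time_column(90)
    delta = (auc_point(df[c45].to_numpy(), lab_all)
             - auc_point(df[c90].to_numpy(), lab_all))
    if n_boot == 0:
        return AUCComparison(delta=delta, ci=None, p_value=float("nan"),
                             n_boot=0, seed=seed)
    groups = _foal_groups(df)
    rng = np.random.default_rng(int(seed) % 2**31)

    def stat(sub: pd.DataFrame) -> float:
        lab = sub[lesion].to_numpy()
        if lab.min() == lab.max():
            raise ValueError("single class")
        return (_auc_fast(sub[c45].to_numpy(), lab)
                - _auc_fast(sub[c90].to_numpy(), lab))

    reps, _ = _bootstrap_stat(df, groups, stat, n_boot, rng)
    ci = (float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5)))
    p = 2.0 * min(float(np.mean(reps <= 0.0)), float(np.mean(reps >= 0.0)))
    p = min(1.0, max(p, 2.0 / n_boot))
    return AUCComparison(delta=delta, ci=ci, p_value=p, n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# Cutoffs


def youden(se: float, sp: float) -> float:
    """Youden's index Se + Sp - 1."""
    _check_prob(se, "se")
    _check_prob(sp, "sp")
    return se + sp - 1.0


def weighted_youden(se: float, sp: float) -> float:
    """Sensitivity-weighted Youden variant: 1.33*Se + 0.67*Sp - 1.

    Weights sensitivity twice as important as specificity, reflecting the
    screening use of the test (missing a diseased foal is the costly
    error).
    """
    _check_prob(se, "se")
    _check_prob(sp, "sp")
    return 1.33 * se + 0.67 * sp - 1.0


def _check_prob(v: float, name: str) -> None:
    if not (0.0 <= v <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclasses.dataclass(frozen=True)
class CutoffPerformance:
    """A cutoff with its operating characteristics (CIs optional)."""

    cutoff: float
    sensitivity: float
    specificity: float
    youden: float
    weighted_youden: float
    se_ci: tuple[float, float] | None = None
    sp_ci: tuple[float, float] | None = None


def select_cutoff(roc: ROCCurve, method: str = "youden") -> CutoffPerformance:
    """Threshold maximizing the chosen index over the empirical curve.

    Ties are broken toward the lower threshold (higher sensitivity).
    ``manual_max_se`` returns the largest threshold achieving maximal
    sensitivity among points with Sp > 0, mirroring manual selection that
    optimizes sensitivity while keeping a usable specificity.
    """
    if len(roc) < 2:
        raise ValueError("degenerate ROC curve")
    se = roc.sensitivity
    sp = 1.0 - roc.one_minus_specificity
    t = roc.thresholds
    if method == "youden":
        index = se + sp - 1.0
    elif method == "weighted_youden":
        index = 1.33 * se + 0.67 * sp - 1.0
    elif method == "manual_max_se":
        usable = sp > 0.0
        if not usable.any():
            raise ValueError("no threshold with positive specificity")
        best_se = se[usable].max()
        at = np.flatnonzero(usable & (se == best_se))
        k = int(at[np.argmax(t[at])])
        return _cutoff_from_point(t, se, sp, k)
    else:
        raise ValueError(f"unknown method {method!r}")
    best = index.max()
    at = np.flatnonzero(index == best)
    finite = at[np.isfinite(t[at])]
    at = finite if finite.size else at
    k = int(at[np.argmin(t[at])])
    return _cutoff_from_point(t, se, sp, k)


def _cutoff_from_point(t, se, sp, k) -> CutoffPerformance:
    return CutoffPerformance(
        cutoff=float(t[k]), sensitivity=float(se[k]), specificity=float(sp[k]),
        youden=float(se[k] + sp[k] - 1.0),
        weighted_youden=float(1.33 * se[k] + 0.67 * sp[k] - 1.0),
    )


def se_sp_at_cutoff(dataset: StudyDataset, lesion: str = "gl", time: int = 45,
                    cutoff: float = 24.0, n_boot: int = 2000,
                    seed: int = 0) -> CutoffPerformance:
    """Se/Sp of the dichotomized sucrose test against the gastroscopy call.

    Gold-standard framing: Se is the positive fraction among
    gastroscopy-diseased records, Sp the negative fraction among
    gastroscopy-healthy ones.  CIs are percentile cluster bootstrap over
    foals.
    """
    lesion = _check_lesion(lesion)
    col = _time_column(time)
    df = dataset.to_frame().reset_index(drop=True)
    lab = df[lesion].to_numpy()
    if lab.min() == lab.max():
        raise ValueError("both lesion classes must be present")
    pos = dichotomize(df[col].to_numpy(), cutoff)
    se = float(pos[lab == 1].mean())
    sp = float((1 - pos)[lab == 0].mean())
    se_ci = sp_ci = None
    if n_boot > 0:
        groups = _foal_groups(df)
        rng = np.random.default_rng(int(seed) % 2**31)

        def stat(sub: pd.DataFrame):
            lab_b = sub[lesion].to_numpy()
            if lab_b.min() == lab_b.max():
                raise ValueError("single class")
            pos_b = (sub[col].to_numpy() >= cutoff).astype(int)
            return (pos_b[lab_b == 1].mean(), (1 - pos_b)[lab_b == 0].mean())

        reps = np.empty((n_boot, 2))
        for b in range(n_boot):
            for _ in range(100):
                idx = _resample_indices(groups, rng)
                try:
                    reps[b] = stat(df.iloc[idx])
                    break
                except ValueError:
                    continue
            else:
                raise DegenerateResampleError("no valid resample in 100 attempts")
        se_ci = (float(np.percentile(reps[:, 0], 2.5)),
                 float(np.percentile(reps[:, 0], 97.5)))
        sp_ci = (float(np.percentile(reps[:, 1], 2.5)),
                 float(np.percentile(reps[:, 1], 97.5)))
    return CutoffPerformance(
        cutoff=float(cutoff), sensitivity=se, specificity=sp,
        youden=se + sp - 1.0, weighted_youden=1.33 * se + 0.67 * sp - 1.0,
        se_ci=se_ci, sp_ci=sp_ci,
    )


# ---------------------------------------------------------------------------
# Prevalence, paired comparison, incidence


def prevalence(dataset: StudyDataset, lesion: str = "gl", occasion: str = "pre",
               n_boot: int = 2000, seed: int = 0):
    """Raw lesion prevalence on one occasion with a cluster-bootstrap CI.

    Returns ``(estimate, (lower, upper))``; the CI is ``None`` when
    ``n_boot == 0``.
    """
    lesion = _check_lesion(lesion)
    df = dataset.to_frame().reset_index(drop=True)
    sub = df[df["occasion"] == occasion]
    if sub.empty:
        raise ValueError(f"no records for occasion {occasion!r}")
    est = float(sub[lesion].mean())
    if n_boot == 0:
        return est, None
    groups = _foal_groups(sub.reset_index(drop=True))
    sub = sub.reset_index(drop=True)
    rng = np.random.default_rng(int(seed) % 2**31)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = _resample_indices(groups, rng)
        reps[b] = sub[lesion].to_numpy()[idx].mean()
    return est, (float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5)))


def _paired_status(dataset: StudyDataset, lesion: str) -> pd.DataFrame:
    df = dataset.to_frame()
    wide = df.pivot(index="foal_id", columns="occasion", values=lesion)
    wide = wide.dropna(subset=["pre", "post"]) if {"pre", "post"} <= set(wide.columns) \
        else wide.iloc[0:0]
    return wide


def paired_prevalence_test(dataset: StudyDataset, lesion: str = "gl"):
    """Exact McNemar test of pre- vs post-weaning lesion status.

    An exact binomial test on the discordant pairs (newly positive vs
    newly negative); returns ``(n_discordant, p_value)``.
    """
    lesion = _check_lesion(lesion)
    wide = _paired_status(dataset, lesion)
    if wide.empty:
        raise ValueError("no foals observed on both occasions")
    b = int(((wide["pre"] == 0) & (wide["post"] == 1)).sum())
    c = int(((wide["pre"] == 1) & (wide["post"] == 0)).sum())
    n_disc = b + c
    if n_disc == 0:
        return 0, 1.0
    p = float(stats.binomtest(b, n_disc, 0.5).pvalue)
    return n_disc, min(1.0, p)


def incidence_rate(dataset: StudyDataset, lesion: str = "gl",
                   weeks_between: float = 3.0) -> float:
    """New cases per foal-week among foals lesion-free at the first visit."""
    if weeks_between <= 0:
        raise ValueError("weeks_between must be positive")
    lesion = _check_lesion(lesion)
    wide = _paired_status(dataset, lesion)
    at_risk = wide[wide["pre"] == 0]
    if at_risk.empty:
        raise ValueError("no at-risk foals (all positive at the first visit)")
    new_cases = int((at_risk["post"] == 1).sum())
    return new_cases / (len(at_risk) * weeks_between)


# ---------------------------------------------------------------------------
# Agreement


@dataclasses.dataclass(frozen=True)
class AgreementResult:
    percent_agreement: float
    kappa: float


def cohen_kappa(r1: Sequence[int], r2: Sequence[int]) -> AgreementResult:
    """Percent agreement and Cohen's kappa for two binary raters.

    Kappa is (po - pe)/(1 - pe) with chance agreement pe from the raters'
    marginal products; when both raters are constant pe = 1 and kappa is
    undefined, which raises rather than silently returning zero.
    """
    a = np.asarray(r1).astype(int)
    b = np.asarray(r2).astype(int)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length rating vectors of length >= 2")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("ratings must be binary")
    po = float((a == b).mean())
    p1, p2 = float(a.mean()), float(b.mean())
    pe = p1 * p2 + (1.0 - p1) * (1.0 - p2)
    if pe >= 1.0:
        raise ValueError("kappa undefined: both raters constant (chance agreement 1)")
    return AgreementResult(percent_agreement=po, kappa=(po - pe) / (1.0 - pe))
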
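"""Synthetic weanling-foal cohorts.

The study design is a repeated-measures cohort: the same foals undergo
gastroscopy and blood-sucrose permeability testing on two occasions,
shortly before and two weeks after weaning.  The raw data were never
published, so this module generates cohorts with the statistical structure
the analysis assumes:

* a latent gastric-lesion state per foal per occasion, with low prevalence
  pre-weaning rising to near-universal post-weaning, and monotone
  progression (no spontaneous healing over the ~3 weeks between visits);
* blood sucrose at 45 and 90 min drawn from a bivariate lognormal whose
  marginal mean/SD depend on the latent state, with strong positive
  log-scale correlation between the two sampling times (the same dose
  sampled twice);
* an imperfect gastroscopy reading of the latent state (finite Se/Sp) —
  the latent class analysis treats gastroscopy as imperfect, so the truth
  is kept separate from the endoscopic call;
* lesion subtypes (glandular, squamous, clinically significant) drawn
  conditionally on a positive gastroscopy call.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np
import pandas as pd

OCCASIONS = ("pre", "post")
LESION_COLUMNS = ("gl", "gdl", "sql", "csl")


def moment_match_lognormal(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of the lognormal with the given mean and SD.

    sigma^2 = ln(1 + sd^2/mean^2), mu = ln(mean) - sigma^2/2; the returned
    parametrisation reproduces the requested moments exactly.
    """
    if not (mean > 0 and sd > 0):
        raise ValueError(f"mean and sd must be positive, got ({mean}, {sd})")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Cohort generator settings.

    Defaults reproduce the study conditions: 45 foals tested twice,
    gastric-lesion prevalence 0.21 pre-weaning and 0.98 post-weaning,
    group-wise sucrose means/SDs in umol/L for lesion-free and lesioned
    foals at each sampling time, log-scale correlation 0.94 between the
    45- and 90-min concentrations, and gastroscopy Se 0.81 / Sp 0.99.
    """

    n_foals: int = 45
    prev_pre: float = 0.21
    prev_post: float = 0.98
    mean_sd_normal_45: tuple[float, float] = (23.99, 17.91)
    mean_sd_normal_90: tuple[float, float] = (23.83, 13.26)
    mean_sd_diseased_45: tuple[float, float] = (57.56, 41.30)
    mean_sd_diseased_90: tuple[float, float] = (54.84, 36.58)
    log_corr: float = 0.94
    endo_se: float = 0.81
    endo_sp: float = 0.99
    subtype_probs: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"sql": 0.95, "gdl": 0.60, "csl": 0.83}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_foals < 1:
            raise ValueError("n_foals must be positive")
        for name in ("prev_pre", "prev_post", "endo_se", "endo_sp"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.prev_post < self.prev_pre:
            raise ValueError(
                "prev_post must be >= prev_pre (disease is monotone over weaning)"
            )
        if not (-1.0 < self.log_corr < 1.0):
            raise ValueError("log_corr must be in (-1, 1)")
        for name in ("mean_sd_normal_45", "mean_sd_normal_90",
                     "mean_sd_diseased_45", "mean_sd_diseased_90"):
            m, s = getattr(self, name)
            if not (m > 0 and s > 0):
                raise ValueError(f"{name} must have positive mean and SD")
        for k, v in self.subtype_probs.items():
            if k not in ("gdl", "sql", "csl"):
                raise ValueError(f"unknown subtype {k!r}")
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"subtype_probs[{k!r}] must be a probability")


@dataclasses.dataclass(frozen=True)
class FoalRecord:
    """One foal on one occasion: sucrose concentrations and gastroscopy calls."""

    foal_id: str
    occasion: str
    sucrose45: float
    sucrose90: float
    gl: int
    gdl: int
    sql: int
    csl: int
    latent_state: int | None = None

    def __post_init__(self) -> None:
        if self.occasion not in OCCASIONS:
            raise ValueError(f"occasion must be one of {OCCASIONS}")
        if not (self.sucrose45 > 0 and self.sucrose90 > 0):
            raise ValueError("sucrose concentrations must be positive")
        for name in LESION_COLUMNS:
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")
        if (self.gdl or self.sql or self.csl) and not self.gl:
            raise ValueError(
                "subtype lesions (gdl/sql/csl) imply a gastric lesion (gl)"
            )


@dataclasses.dataclass(frozen=True)
class StudyDataset:
    """A collection of foal-occasion records; the pipeline's raw input."""

    records: tuple[FoalRecord, ...]

    def __post_init__(self) -> None:
        keys = [(r.foal_id, r.occasion) for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (foal_id, occasion): {dupes[:5]}")
        object.__setattr__(self, "records", tuple(self.records))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def foal_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.foal_id, None)
        return tuple(seen)

    @property
    def has_latent(self) -> bool:
        return all(r.latent_state is not None for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "foal_id": r.foal_id,
                "occasion": r.occasion,
                "sucrose45_umol_l": r.sucrose45,
                "sucrose90_umol_l": r.sucrose90,
                "gl": r.gl, "gdl": r.gdl, "sql": r.sql, "csl": r.csl,
            }
            if r.latent_state is not None:
                row["latent_state"] = r.latent_state
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StudyDataset":
        has_latent = "latent_state" in df.columns
        records = []
        for _, row in df.iterrows():
            records.append(FoalRecord(
                foal_id=str(row["foal_id"]),
                occasion=str(row["occasion"]),
                sucrose45=float(row["sucrose45_umol_l"]),
                sucrose90=float(row["sucrose90_umol_l"]),
                gl=int(row["gl"]), gdl=int(row["gdl"]),
                sql=int(row["sql"]), csl=int(row["csl"]),
                latent_state=(int(row["latent_state"]) if has_latent else None),
            ))
        return cls(tuple(records))


def simulate_cohort(config: SimulationConfig | None = None) -> StudyDataset:
    """Draw a full repeated-measures cohort from the generator.

    Latent state: Bernoulli(prev_pre) pre-weaning; diseased foals remain
    diseased post-weaning and disease-free foals convert with probability
    (prev_post - prev_pre)/(1 - prev_pre), so the marginal post-weaning
    prevalence is prev_post.  Sucrose pairs are bivariate lognormal given
    the latent state; gastroscopy is an imperfect Bernoulli reading of the
    latent state; subtypes are drawn given a positive gastroscopy call.
    """
    config = config if config is not None else SimulationConfig()
    rng = np.random.default_rng(int(config.seed) % 2**31)
    n = config.n_foals

    latent_pre = rng.random(n) < config.prev_pre
    if config.prev_pre < 1.0:
        p_convert = (config.prev_post - config.prev_pre) / (1.0 - config.prev_pre)
    else:
        p_convert = 0.0
    latent_post = latent_pre | (rng.random(n) < p_convert)

    mu_n = np.array([moment_match_lognormal(*config.mean_sd_normal_45)[0],
                     moment_match_lognormal(*config.mean_sd_normal_90)[0]])
    sg_n = np.array([moment_match_lognormal(*config.mean_sd_normal_45)[1],
                     moment_match_lognormal(*config.mean_sd_normal_90)[1]])
    mu_d = np.array([moment_match_lognormal(*config.mean_sd_diseased_45)[0],
                     moment_match_lognormal(*config.mean_sd_diseased_90)[0]])
    sg_d = np.array([moment_match_lognormal(*config.mean_sd_diseased_45)[1],
                     moment_match_lognormal(*config.mean_sd_diseased_90)[1]])
    rho = config.log_corr
    chol = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))

    width = max(3, len(str(n)))
    ids = [f"F{i + 1:0{width}d}" for i in range(n)]
    records = []
    for occ, latent in (("pre", latent_pre), ("post", latent_post)):
        z = rng.standard_normal((n, 2)) @ chol.T
        mu = np.where(latent[:, None], mu_d, mu_n)
        sg = np.where(latent[:, None], sg_d, sg_n)
        conc = np.exp(mu + sg * z)
        p_pos = np.where(latent, config.endo_se, 1.0 - config.endo_sp)
        gl = (rng.random(n) < p_pos).astype(int)
        sub = {k: (rng.random(n) < config.subtype_probs.get(k, 0.0)).astype(int)
               for k in ("gdl", "sql", "csl")}
        for i in range(n):
            records.append(FoalRecord(
                foal_id=ids[i], occasion=occ,
                sucrose45=float(conc[i, 0]), sucrose90=float(conc[i, 1]),
                gl=int(gl[i]),
                gdl=int(gl[i] & sub["gdl"][i]),
                sql=int(gl[i] & sub["sql"][i]),
                csl=int(gl[i] & sub["csl"][i]),
                latent_state=int(latent[i]),
            ))
    return StudyDataset(tuple(records))


def simulate_crossclassified(params, n_pre: int, n_post: int, seed: int):
    """Multinomial draw of cross-classified counts from the latent class model.

    Cell probabilities come from :func:`sucroscreen.latent_class.
    cell_probabilities`; one multinomial of size ``n_pre`` (``n_post``)
    per population.
    """
    from .latent_class import CrossClassifiedCounts, cell_probabilities

    if n_pre < 0 or n_post < 0:
        raise ValueError("population sizes must be non-negative")
    p = cell_probabilities(params)
    rng = np.random.default_rng(int(seed) % 2**31)
    counts = np.vstack([
        rng.multinomial(n_pre, p[0]) if n_pre else np.zeros(8, dtype=np.int64),
        rng.multinomial(n_post, p[1]) if n_post else np.zeros(8, dtype=np.int64),
    ])
    return CrossClassifiedCounts(counts)
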
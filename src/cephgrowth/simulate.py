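"""Synthetic longitudinal craniofacial-growth datasets.

Real serial cephalometric data carry personal health information and are
not publicly shareable, so every downstream stage here is exercised on
simulated populations with the same statistical structure: a population
double-logistic growth curve, a Normal(0, sigma_id) random intercept per
individual (inter-individual size variation), and Normal(0, sigma)
residual measurement error per radiograph. The generator is the multilevel
observation model run forward.

Defaults emulate the scale of a large historic growth consortium for one
sex and one mid-sized trait: 959 individuals, enrollment in childhood,
annual follow-up visits with gradual dropout giving a median of 9 visits
per individual (range 2-22), residual measurement error 0.87 mm, and
between-individual SD 3 mm. The default truth curve (f=101 mm, a1=88 mm,
b1=0.9 /y, c1=3 y, b2=0.55 /y, c2=11.5 y) reaches an adult size of about
100 mm and has an adolescent velocity peak of about 1.8 mm/y near 11.4
years, plausible for a cranial-base distance in females.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .growth import GrowthParams, double_logistic

__all__ = [
    "PopulationConfig",
    "LongitudinalDataset",
    "DEFAULT_TRUTH",
    "sample_visit_schedule",
    "generate_population",
]

#: Default truth parameters for the simulated trait.
DEFAULT_TRUTH = GrowthParams(f=101.0, a1=88.0, b1=0.9, c1=3.0, b2=0.55, c2=11.5)


@dataclass(frozen=True)
class PopulationConfig:
    """Settings for one simulated study population.

    ``visit_retention`` is the probability that a further annual visit takes
    place once the previous one did; every individual keeps at least the
    enrollment visit plus one follow-up (the study's inclusion rule requires
    two radiographs). ``missingness`` drops each observation independently;
    individuals falling below two retained observations are excluded, as
    they would be from the real analysis.
    """

    params: GrowthParams = DEFAULT_TRUTH
    sigma: float = 0.87          # residual measurement-error SD, mm
    sigma_id: float = 3.0        # between-individual intercept SD, mm
    n_individuals: int = 959
    age_range: tuple[float, float] = (4.0, 22.0)
    visit_retention: float = 0.906
    min_visits: int = 2
    max_visits: int = 22
    missingness: float = 0.0
    sex: str = "F"
    trait: str = "synthetic_trait"
    seed: int = 20231107

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.sigma_id < 0:
            raise ValueError("sigma and sigma_id must be non-negative")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.min_visits < 2:
            raise ValueError("min_visits must be >= 2 (inclusion rule)")
        if self.max_visits < self.min_visits:
            raise ValueError("max_visits must be >= min_visits")
        if not 0.0 <= self.visit_retention <= 1.0:
            raise ValueError("visit_retention must be a probability")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must be in [0, 1)")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = {k: getattr(self.params, k) for k in GrowthParams.param_names()}
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationConfig":
        d = dict(d)
        d["params"] = GrowthParams(**d["params"])
        d["age_range"] = tuple(d["age_range"])
        return cls(**d)


@dataclass
class LongitudinalDataset:
    """Observations grouped by individual, >= 2 per individual.

    ``table`` has columns individual_id, sex, age, trait, value with ages
    strictly increasing within each individual. ``provenance`` holds the
    generating config when the dataset is synthetic.
    """

    table: pd.DataFrame
    provenance: PopulationConfig | None = None

    def __post_init__(self) -> None:
        required = ["individual_id", "sex", "age", "trait", "value"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"dataset table missing columns: {missing}")
        counts = self.table.groupby("individual_id", sort=False).size()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise ValueError(f"individuals with fewer than 2 observations: {bad[:5]}")
        for iid, grp in self.table.groupby("individual_id", sort=False):
            ages = grp["age"].to_numpy()
            if not np.all(np.diff(ages) > 0):
                raise ValueError(f"ages not strictly increasing for individual {iid}")

    @property
    def n_individuals(self) -> int:
        return self.table["individual_id"].nunique()

    @property
    def n_observations(self) -> int:
        return len(self.table)

    def individual_ids(self) -> np.ndarray:
        return self.table["individual_id"].unique()


def sample_visit_schedule(config: PopulationConfig, individual_index: int) -> np.ndarray:
    """Draw one individual's ordered radiograph ages (years).

    Enrollment age is uniform over the lower third of ``age_range``; visits
    then recur annually, the first follow-up always (the inclusion floor of
    two radiographs), and each later one with probability
    ``visit_retention``, until dropout, the end of the age range, or
    ``max_visits``. Deterministic given (config.seed, individual_index).
    """
    if config.max_visits < 2:
        raise ValueError("visit model must allow at least 2 visits")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, individual_index]))
    lo, hi = config.age_range
    enroll = rng.uniform(lo, lo + (hi - lo) / 3.0)
    ages = [enroll]
    while len(ages) < config.max_visits and ages[-1] + 1.0 <= hi:
        nxt = ages[-1] + 1.0
        if len(ages) < config.min_visits:
            ages.append(nxt)
            continue
        if rng.uniform() < config.visit_retention:
            ages.append(nxt)
        else:
            break
    if len(ages) < config.min_visits:
        # enrollment fell too close to the age ceiling for an annual
        # follow-up; squeeze the follow-ups in before the ceiling
        step = (hi - enroll) / config.min_visits
        ages = [enroll + k * step for k in range(config.min_visits)]
    return np.asarray(ages, dtype=float)


def generate_population(config: PopulationConfig) -> LongitudinalDataset:
    """Simulate a longitudinal study population.

    For individual j: a_j ~ Normal(0, sigma_id); each visit value is
    ``double_logistic(age) + a_j + Normal(0, sigma)``. Reproducible from
    ``config.seed`` alone.
    """
    rows: list[pd.DataFrame] = []
    for j in range(config.n_individuals):
        ages = sample_visit_schedule(config, j)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, j]))
        a_j = rng.normal(0.0, config.sigma_id) if config.sigma_id > 0 else 0.0
        eps = rng.normal(0.0, config.sigma, size=ages.size) if config.sigma > 0 else 0.0
        values = double_logistic(ages, config.params) + a_j + eps
        keep = np.ones(ages.size, dtype=bool)
        if config.missingness > 0:
            keep = rng.uniform(size=ages.size) >= config.missingness
        if keep.sum() < 2:
            continue
        rows.append(
            pd.DataFrame(
                {
                    "individual_id": f"S{j:04d}",
                    "sex": config.sex,
                    "age": ages[keep],
                    "trait": config.trait,
                    "value": np.asarray(values)[keep],
                }
            )
        )
    if not rows:
        raise ValueError("no individuals retained; missingness too aggressive")
    table = pd.concat(rows, ignore_index=True)
    return LongitudinalDataset(table=table, provenance=config)
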
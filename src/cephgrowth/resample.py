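"""Cross-sectional subsampling of a longitudinal dataset.

The design question: how well does a cross-sectional sample — one
radiograph per person — recover the growth standards and milestones that a
dense longitudinal study establishes? To answer it, repeated random
cross-sections are drawn from the longitudinal data (sample n individuals
without replacement, then one observation uniformly at random from each
individual's series, with no further conditions), a single-level model is
fit to every draw, and replicate fits are aggregated per sample size.

Each individual contributes one point regardless of how many radiographs
they have, so short series are overrepresented at the observation level
but every individual is equally likely to be included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fit import FitConfig, PosteriorSamples, fit_cross_sectional, _curves_from_draws
from .growth import GrowthParams, Milestones, find_milestones
from .simulate import LongitudinalDataset

__all__ = [
    "CrossSectionalDataset",
    "ExperimentDesign",
    "ExperimentResult",
    "draw_cross_section",
    "run_experiment",
    "aggregate_replicates",
]

DEFAULT_SIZES: tuple = (5, 10, 20, 50, 100, 200, 300, 500, "full")
_PARAMS = GrowthParams.param_names()


@dataclass
class CrossSectionalDataset:
    """One observation per individual, drawn from a longitudinal source."""

    table: pd.DataFrame
    replicate: int = 0
    target_size: int | str = "full"

    def __post_init__(self) -> None:
        if self.table["individual_id"].duplicated().any():
            raise ValueError("cross-sectional dataset has a duplicated individual")

    @property
    def n(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class ExperimentDesign:
    """Sizes, replicate count, fit settings and master seed for one run."""

    sizes: tuple = DEFAULT_SIZES
    reps: int = 200
    fit: FitConfig = field(default_factory=lambda: FitConfig(mode="map"))
    master_seed: int = 0
    age_grid: np.ndarray = field(default_factory=lambda: np.arange(5.0, 20.0 + 1e-9, 0.25))
    milestone_window: tuple[float, float] = (10.0, 20.0)

    def __post_init__(self) -> None:
        if len(self.sizes) == 0:
            raise ValueError("sizes must be non-empty")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass
class ExperimentResult:
    """Per-(size, replicate) fits of the subsampling experiment.

    ``records`` holds one row per fit: size label, actual n, replicate,
    posterior medians of all parameters, milestone estimates, flags.
    ``curves[(size, rep)]`` is the fitted median curve on the design grid;
    ``posteriors[(size, rep)]`` the full fit object. Failed fits stay in
    ``records`` with their failure reason; they never vanish silently.
    """

    design: ExperimentDesign
    records: pd.DataFrame
    curves: dict[tuple, np.ndarray]
    posteriors: dict[tuple, PosteriorSamples]

    def at_size(self, size) -> pd.DataFrame:
        return self.records[(self.records["size"] == str(size)) & self.records["ok"]]


def _replicate_rng(master_seed: int, size, replicate: int) -> np.random.Generator:
    size_key = 0 if size == "full" else int(size)
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), size_key, int(replicate)]))


def draw_cross_section(
    data: LongitudinalDataset,
    n: int | str,
    seed_or_rng,
    replicate: int = 0,
) -> CrossSectionalDataset:
    """Sample one cross-section: n individuals, one observation each.

    ``n`` may be ``"full"`` to take every individual. Individuals are
    sampled without replacement and the observation uniformly at random
    within each sampled individual's series — no restriction on age or
    series length.
    """
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else np.random.default_rng(seed_or_rng)
    ids = data.individual_ids()
    if n == "full":
        chosen = ids
    else:
        n = int(n)
        if n > ids.size:
            raise ValueError(f"requested n={n} exceeds {ids.size} available individuals")
        chosen = rng.choice(ids, size=n, replace=False)
    groups = data.table.groupby("individual_id", sort=False).indices
    rows = [groups[iid][rng.integers(len(groups[iid]))] for iid in chosen]
    table = data.table.iloc[rows].reset_index(drop=True)
    return CrossSectionalDataset(table=table, replicate=replicate, target_size=n)


def run_experiment(
    data: LongitudinalDataset,
    design: ExperimentDesign,
    prior,
) -> ExperimentResult:
    """Fit the full size x replicate grid of cross-sectional models.

    Replicate seeds are a deterministic function of (master_seed, size,
    replicate), so any subset of the design reproduces identically and
    results do not depend on execution order.
    """
    from .fit import posterior_predict  # local to avoid polluting module API

    records = []
    curves: dict[tuple, np.ndarray] = {}
    posteriors: dict[tuple, PosteriorSamples] = {}
    for size in design.sizes:
        for rep in range(design.reps):
            rng = _replicate_rng(design.master_seed, size, rep)
            rec = {"size": str(size), "replicate": rep}
            try:
                cs = draw_cross_section(data, size, rng, replicate=rep)
                post = fit_cross_sectional(cs, prior, design.fit)
                params = post.median_params()
                ms = find_milestones(params, design.milestone_window)
                med_curve = np.median(_curves_from_draws(post.draws, design.age_grid), axis=0)
                rec.update({"n": cs.n, "ok": True, "reason": ""})
                rec.update({p: getattr(params, p) for p in _PARAMS})
                rec["sigma"] = float(np.median(post.flat("sigma")))
                rec.update({"pgv": ms.pgv, "apgv": ms.apgv, "phase": ms.phase})
                rec["flags"] = ";".join(post.flags)
                curves[(str(size), rep)] = med_curve
                posteriors[(str(size), rep)] = post
            except Exception as err:  # recorded, never silently dropped
                rec.update({"n": np.nan, "ok": False, "reason": str(err), "flags": ""})
            records.append(rec)
    return ExperimentResult(design=design, records=pd.DataFrame(records),
                            curves=curves, posteriors=posteriors)


@dataclass(frozen=True)
class AggregatedSize:
    """Replicate aggregate at one sample size.

    ``median_model`` is the parameter-wise median across replicate
    posterior medians (the "median cross-sectional model");
    ``median_curve_pointwise`` the alternative aggregation — the pointwise
    median of replicate median curves; ``pooled_draws`` concatenates
    retained draws across replicates for band construction.
    """

    size: str
    medians: pd.DataFrame
    median_model: GrowthParams
    median_curve_pointwise: np.ndarray
    pooled_draws: dict[str, np.ndarray]
    n_replicates: int


def aggregate_replicates(result: ExperimentResult, size) -> AggregatedSize:
    """Aggregate all successful replicates at one sample size."""
    ok = result.at_size(size)
    if len(ok) == 0:
        raise ValueError(f"no successful replicates at size {size}")
    medians = ok[list(_PARAMS)].reset_index(drop=True)
    median_model = GrowthParams(**{p: float(medians[p].median()) for p in _PARAMS})
    stack = np.stack([result.curves[(str(size), int(r))] for r in ok["replicate"]])
    median_curve = np.median(stack, axis=0)
    pooled: dict[str, list[np.ndarray]] = {}
    for r in ok["replicate"]:
        post = result.posteriors[(str(size), int(r))]
        for k, v in post.draws.items():
            if v.ndim == 2:
                pooled.setdefault(k, []).append(v.reshape(-1))
    pooled_draws = {k: np.concatenate(v) for k, v in pooled.items()}
    return AggregatedSize(size=str(size), medians=medians, median_model=median_model,
                          median_curve_pointwise=median_curve, pooled_draws=pooled_draws,
                          n_replicates=len(ok))
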
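"""Agreement between cross-sectional aggregates and the longitudinal reference.

The longitudinal multilevel fit is taken as the best available estimate of
the population growth pattern; these functions quantify how far
cross-sectional replicate fits stray from it: mean absolute difference
(MAD) of predicted size across the age grid, mean absolute errors of the
growth milestones (PGV in mm/y, aPGV in years), RMS difference of growth
rates, and percentile-band discrepancies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fit import PredictionBands
from .growth import GrowthParams, Milestones, find_milestones, growth_velocity
from .resample import ExperimentResult

__all__ = [
    "ComparisonReport",
    "mean_abs_difference",
    "milestone_errors",
    "rate_rmsd",
    "percentile_comparison",
    "percent_error",
    "compare_experiment",
]

DEFAULT_GRID = np.arange(5.0, 20.0 + 1e-9, 0.25)


def percent_error(measurement_error: float, trait_size: float) -> float:
    """Measurement error as a percentage of trait size.

    A constant 0.2 cm error is 0.25% of an 80 cm infant's stature but only
    0.11% of a 180 cm adult's: relative error shrinks as size grows, which
    is why large-magnitude traits are easier to model than small
    craniofacial distances with comparable absolute error.
    """
    if trait_size <= 0:
        raise ValueError("trait size must be positive")
    return 100.0 * measurement_error / trait_size


def mean_abs_difference(curves_a: np.ndarray, curve_b: np.ndarray, age_grid) -> tuple[np.ndarray, float]:
    """Pointwise MAD of replicate curves against a reference, plus its grid mean.

    ``curves_a`` is (n_replicates, n_grid) or a single curve (n_grid,);
    ``curve_b`` the reference curve on the identical grid. Returns the MAD
    curve (mean over replicates of |a - b| per age) and the scalar mean of
    that curve over the grid.
    """
    grid = np.asarray(age_grid, dtype=float)
    a = np.atleast_2d(np.asarray(curves_a, dtype=float))
    b = np.asarray(curve_b, dtype=float)
    if a.shape[1] != grid.size or b.size != grid.size:
        raise ValueError(
            f"grid mismatch: curves on {a.shape[1]} / {b.size} points, grid has {grid.size}"
        )
    mad_curve = np.mean(np.abs(a - b[None, :]), axis=0)
    return mad_curve, float(mad_curve.mean())


def milestone_errors(result: ExperimentResult, reference: Milestones) -> pd.DataFrame:
    """Per-size PGV/aPGV agreement with the longitudinal reference.

    Returns one row per sample size with the mean absolute error and the
    signed bias of both milestones across successful replicates.
    """
    rows = []
    for size in result.design.sizes:
        ok = result.at_size(size)
        if len(ok) == 0:
            continue
        d_pgv = ok["pgv"].to_numpy() - reference.pgv
        d_apgv = ok["apgv"].to_numpy() - reference.apgv
        rows.append(
            {
                "size": str(size),
                "n_replicates": len(ok),
                "pgv_mae": float(np.mean(np.abs(d_pgv))),
                "pgv_bias": float(np.mean(d_pgv)),
                "apgv_mae": float(np.mean(np.abs(d_apgv))),
                "apgv_bias": float(np.mean(d_apgv)),
            }
        )
    return pd.DataFrame(rows)


def rate_rmsd(params_a: GrowthParams, params_b: GrowthParams, age_grid) -> float:
    """Root-mean-square difference of growth rates across the grid (mm/y)."""
    grid = np.asarray(age_grid, dtype=float)
    diff = growth_velocity(grid, params_a) - growth_velocity(grid, params_b)
    return float(np.sqrt(np.mean(diff**2)))


def percentile_comparison(bands_a: PredictionBands, bands_b: PredictionBands) -> pd.DataFrame:
    """Max and mean absolute discrepancy per percentile curve.

    Both band sets must share the age grid and the interval levels; the
    median curves are compared alongside every band edge.
    """
    if bands_a.levels != bands_b.levels:
        raise ValueError(f"band levels differ: {bands_a.levels} vs {bands_b.levels}")
    if bands_a.age_grid.size != bands_b.age_grid.size or not np.allclose(
        bands_a.age_grid, bands_b.age_grid
    ):
        raise ValueError("band age grids differ")
    rows = [
        {
            "curve": "median",
            "max_abs": float(np.max(np.abs(bands_a.median - bands_b.median))),
            "mean_abs": float(np.mean(np.abs(bands_a.median - bands_b.median))),
        }
    ]
    for lev in bands_a.levels:
        for side, store_a, store_b in (("lower", bands_a.lower, bands_b.lower),
                                       ("upper", bands_a.upper, bands_b.upper)):
            d = np.abs(store_a[lev] - store_b[lev])
            rows.append({"curve": f"{side}{lev}", "max_abs": float(d.max()),
                         "mean_abs": float(d.mean())})
    return pd.DataFrame(rows)


@dataclass
class ComparisonReport:
    """Cross-sectional vs longitudinal agreement summaries.

    ``mad``: one row per size with the scalar MAD (mm) and replicate count;
    ``mad_curves``: the per-age MAD curve per size; ``milestones``: PGV and
    aPGV error summaries per size; ``reference``: the longitudinal
    milestones all errors are measured against.
    """

    age_grid: np.ndarray
    mad: pd.DataFrame
    mad_curves: dict[str, np.ndarray]
    milestones: pd.DataFrame
    reference: Milestones

    def to_markdown(self) -> str:
        lines = ["# Cross-sectional vs longitudinal comparison", ""]
        lines.append(
            f"Longitudinal reference: PGV {self.reference.pgv:.3f} mm/y at "
            f"aPGV {self.reference.apgv:.2f} y ({self.reference.phase} phase), "
            f"asymptote {self.reference.asymptote:.2f} mm."
        )
        lines += ["", "## Mean absolute difference of predicted size (mm)", ""]
        lines.append(self.mad.to_string(index=False))
        lines += ["", "## Growth-milestone errors vs the longitudinal reference", ""]
        lines.append(self.milestones.to_string(index=False))
        return "\n".join(lines) + "\n"


def compare_experiment(
    result: ExperimentResult,
    reference_params: GrowthParams,
    reference_curve: np.ndarray | None = None,
) -> ComparisonReport:
    """Full comparison of an experiment against a longitudinal reference fit.

    ``reference_params`` are the longitudinal posterior-median parameters;
    ``reference_curve`` the longitudinal median predicted curve on the
    design grid (recomputed from the parameters when omitted).
    """
    from .growth import double_logistic

    grid = result.design.age_grid
    if reference_curve is None:
        reference_curve = np.asarray(double_logistic(grid, reference_params))
    ref_ms = find_milestones(reference_params, result.design.milestone_window)
    mad_rows = []
    mad_curves: dict[str, np.ndarray] = {}
    for size in result.design.sizes:
        ok = result.at_size(size)
        if len(ok) == 0:
            continue
        stack = np.stack([result.curves[(str(size), int(r))] for r in ok["replicate"]])
        curve, scalar = mean_abs_difference(stack, reference_curve, grid)
        mad_curves[str(size)] = curve
        mad_rows.append({"size": str(size), "n_replicates": len(ok), "mad_mm": scalar})
    return ComparisonReport(
        age_grid=grid,
        mad=pd.DataFrame(mad_rows),
        mad_curves=mad_curves,
        milestones=milestone_errors(result, ref_ms),
        reference=ref_ms,
    )
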
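"""CSV/YAML I/O for datasets, priors, configs and reports.

The canonical tabular format is plain CSV with the header
``individual_id,sex,age,trait,value`` — ages in decimal years, values in
mm. Configuration files are YAML. Individuals with fewer than two
observations are excluded on read (the longitudinal inclusion rule) with
the excluded count logged.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .priors import PriorSpec
from .simulate import LongitudinalDataset, PopulationConfig

__all__ = ["read_dataset", "write_dataset", "read_config", "write_config",
           "read_prior", "write_prior", "write_posterior"]

log = logging.getLogger("cephgrowth")

COLUMNS = ["individual_id", "sex", "age", "trait", "value"]


def read_dataset(path, trait: str | None = None, sex: str | None = None) -> LongitudinalDataset:
    """Read and validate a longitudinal trait table.

    Optionally restricts to one trait and one sex. Raises a validation
    error naming the offending CSV line for non-numeric ages/values or
    duplicated (individual, age, trait) rows; individuals left with fewer
    than two observations are dropped and the count logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, comment="#")
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    # header is line 1; first data row is line 2
    for col in ("age", "value"):
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[coerced.isna() & raw[col].notna()]
        if len(bad) > 0:
            line = int(bad[0]) + 2
            raise ValueError(f"{path}: non-numeric {col} {raw[col][bad[0]]!r} at line {line}")
        if raw[col].isna().any():
            line = int(raw.index[raw[col].isna()][0]) + 2
            raise ValueError(f"{path}: empty {col} at line {line}")
        raw[col] = coerced
    dup = raw.duplicated(subset=["individual_id", "age", "trait"])
    if dup.any():
        line = int(raw.index[dup][0]) + 2
        raise ValueError(f"{path}: duplicate (individual_id, age, trait) row at line {line}")
    table = raw
    if trait is not None:
        table = table[table["trait"] == trait]
    if sex is not None:
        table = table[table["sex"] == sex]
    if len(table) == 0:
        raise ValueError(f"{path}: no rows left after trait/sex selection")
    table = table.sort_values(["individual_id", "age"], kind="stable").reset_index(drop=True)
    counts = table.groupby("individual_id", sort=False).size()
    singletons = counts[counts < 2].index
    if len(singletons) > 0:
        log.info("excluding %d individual(s) with < 2 observations", len(singletons))
        table = table[~table["individual_id"].isin(singletons)].reset_index(drop=True)
    if len(table) == 0:
        raise ValueError(f"{path}: no individual has >= 2 observations")
    return LongitudinalDataset(table=table)


def write_dataset(dataset: LongitudinalDataset, path) -> None:
    """Write a dataset as canonical CSV (mm and decimal years)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dataset.table[COLUMNS].to_csv(path, index=False)


def write_config(config: PopulationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def read_config(path) -> PopulationConfig:
    return PopulationConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def write_prior(prior: PriorSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(prior.to_dict(), sort_keys=False))


def read_prior(path) -> PriorSpec:
    return PriorSpec.from_dict(yaml.safe_load(Path(path).read_text()))


def write_posterior(post, path) -> None:
    """Serialize scalar posterior draws: one row per (chain, iteration)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    post.to_frame().to_csv(path, index=False)


def read_posterior(path) -> pd.DataFrame:
    return pd.read_csv(path)
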
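"""Derived traits and the sample-exclusion rules applied before analysis.

Derived quantities: days from sowing to a phenological stage, thousand seed
weight (TSW), total seeds per plant, and protein yield. Exclusion rules
mask trait groups without deleting rows: composition columns are masked for
plants yielding under 0.5 g, morphology columns for scans with fewer than
97 counted seeds, and the two in-season height columns for replanted pots.
Yield itself is never masked (zero yields are data). Every mask is recorded
with a reason code in an exclusion log.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExclusionRules",
    "days_to_stage",
    "thousand_seed_weight",
    "total_seeds",
    "protein_yield",
    "apply_exclusions",
]

#: Plants with yield below this mass (g) are excluded from composition analyses.
MIN_YIELD_FOR_COMPOSITION_G = 0.5
#: Scans with fewer counted seeds than this are excluded from morphology analyses.
MIN_SEEDS_FOR_MORPHOLOGY = 97


def days_to_stage(sowing_date, stage_date):
    """Whole days from sowing to reaching a growth stage.

    Accepts scalars or Series of anything pandas can parse as dates.
    Missing stage dates give missing values; a stage date before sowing is
    an error.
    """
    sow = pd.to_datetime(sowing_date)
    stage = pd.to_datetime(stage_date)
    delta = stage - sow
    if isinstance(delta, pd.Series):
        days = delta.dt.days
        if (days.dropna() < 0).any():
            raise ValueError("stage date precedes sowing date")
        return days
    if pd.isna(delta):
        return np.nan
    if delta.days < 0:
        raise ValueError("stage date precedes sowing date")
    return int(delta.days)


def thousand_seed_weight(subsample_mass_g, seed_count):
    """TSW in g: subsample mass / counted seeds x 1000.

    A zero (or missing) count gives a missing value rather than an error,
    mirroring how failed scans propagate.
    """
    mass = np.asarray(subsample_mass_g, dtype=float)
    count = np.asarray(seed_count, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        tsw = np.where(count > 0, mass / count * 1000.0, np.nan)
    if tsw.ndim == 0:
        return float(tsw)
    return tsw


def total_seeds(yield_g, tsw_g):
    """Seeds per plant: yield / TSW x 1000, rounded to the nearest seed."""
    y = np.asarray(yield_g, dtype=float)
    tsw = np.asarray(tsw_g, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        seeds = np.where(tsw > 0, np.round(y / tsw * 1000.0), np.nan)
    if seeds.ndim == 0:
        return float(seeds)
    return seeds


def protein_yield(crude_protein_pct, yield_g):
    """Protein mass per plant (g): crude protein % (14% moisture basis) x yield."""
    protein = np.asarray(crude_protein_pct, dtype=float)
    if np.any((protein < 0) | (protein > 100)):
        raise ValueError("crude protein % must be within [0, 100]")
    return (protein / 100.0) * np.asarray(yield_g, dtype=float)


@dataclass(frozen=True)
class ExclusionRules:
    """Thresholds and column groups for :func:`apply_exclusions`."""

    min_yield_g: float = MIN_YIELD_FOR_COMPOSITION_G
    min_seed_count: int = MIN_SEEDS_FOR_MORPHOLOGY
    yield_col: str = "yield_g"
    seed_count_col: str = "image_seed_count"
    replanted_col: str = "replanted"
    composition_cols: tuple = ()
    morphology_cols: tuple = ()
    height_cols: tuple = ("height_5wk_cm", "height_6wk_cm")


def apply_exclusions(table: pd.DataFrame, rules: ExclusionRules,
                     key_cols: Sequence[str] = ("accession", "greenhouse", "block"),
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mask trait groups per the study's exclusion rules.

    Rules (all masks, never row drops; strict less-than thresholds):

    - yield < ``min_yield_g`` -> composition columns masked
      (reason ``low_yield``);
    - counted seeds < ``min_seed_count`` -> morphology columns masked
      (reason ``few_seeds``);
    - replanted rows -> in-season height columns masked
      (reason ``replanted``).

    Yield is never masked. Masking is idempotent and the rules are
    independent, so order does not matter. Returns the masked copy and an
    exclusion log with one row per (sample, rule).
    """
    for col in (rules.yield_col,):
        if col not in table.columns:
            raise KeyError(f"required column {col!r} missing")
    out = table.copy()
    log_rows = []

    def mask(row_sel: pd.Series, cols: Sequence[str], reason: str):
        cols = [c for c in cols if c in out.columns]
        if not cols or not row_sel.any():
            return
        out.loc[row_sel, cols] = np.nan
        for _, row in table.loc[row_sel, list(key_cols)].iterrows():
            log_rows.append({**row.to_dict(), "columns": ";".join(cols),
                             "reason": reason})

    low_yield = table[rules.yield_col] < rules.min_yield_g
    mask(low_yield.fillna(False), rules.composition_cols, "low_yield")

    if rules.seed_count_col in table.columns:
        few = table[rules.seed_count_col] < rules.min_seed_count
        # a missing count means the scan failed: morphology is unusable too
        few = few | table[rules.seed_count_col].isna()
        mask(few, rules.morphology_cols, "few_seeds")

    if rules.replanted_col in table.columns:
        replanted = table[rules.replanted_col].fillna(False).astype(bool)
        mask(replanted, rules.height_cols, "replanted")

    log = pd.DataFrame(log_rows,
                       columns=[*key_cols, "columns", "reason"])
    return out, log
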
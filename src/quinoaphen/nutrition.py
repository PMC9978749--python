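"""Amino-acid scores and limiting-amino-acid classification.

An amino acid score (AAS) is the content of an essential amino acid
(mg g^-1 protein, here on a 14% moisture basis) divided by the daily
requirement of a target age group (WHO/FAO/UNU 2007 values packaged for
adults and infants). A score below 1 marks the amino acid as limiting; a
profile with no limiting amino acid is complete for that group. Scores of
exactly 1 meet the requirement. Because infant requirements are at least
the adult ones for every amino acid, meeting infant requirements implies
meeting adult requirements.

Sulfur amino acids (SAA = methionine + cysteine) and aromatic amino acids
(AAA = phenylalanine + tyrosine) are scored as compound entries.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from ._resources import amino_acid_requirements_raw

__all__ = [
    "ESSENTIAL_AMINO_ACIDS",
    "load_requirements",
    "panel_mean_profile",
    "aggregate_compound",
    "amino_acid_score",
    "classify_limiting",
    "score_table",
]

ESSENTIAL_AMINO_ACIDS = ("histidine", "isoleucine", "leucine", "lysine",
                         "saa", "aaa", "threonine", "tryptophan", "valine")
AGE_GROUPS = ("adult", "infant")


def load_requirements() -> pd.DataFrame:
    """Requirement table (mg g^-1 protein): rows = amino acids, cols = adult, infant."""
    raw = amino_acid_requirements_raw()["requirements"]
    df = pd.DataFrame(raw).T.loc[list(ESSENTIAL_AMINO_ACIDS), list(AGE_GROUPS)]
    if (df["infant"] < df["adult"]).any():
        raise ValueError("requirement table violates infant >= adult")
    return df.astype(float)


def panel_mean_profile() -> pd.Series:
    """Packaged panel-mean EAA profile (mg g^-1 protein, 14% moisture basis)."""
    raw = amino_acid_requirements_raw()["panel_mean_profile"]
    return pd.Series(raw, name="mean_profile").astype(float)


def aggregate_compound(profile) -> pd.Series | pd.DataFrame:
    """Add SAA (= methionine + cysteine) and AAA (= phenylalanine + tyrosine).

    Works on a Series (one sample) or a DataFrame (samples x amino acids).
    A missing constituent makes the aggregate missing.
    """
    if isinstance(profile, Mapping) and not isinstance(profile, pd.Series):
        profile = pd.Series(profile, dtype=float)
    out = profile.copy()
    pairs = {"saa": ("methionine", "cysteine"),
             "aaa": ("phenylalanine", "tyrosine")}
    for agg, (a, b) in pairs.items():
        if isinstance(out, pd.DataFrame):
            va = out[a] if a in out.columns else np.nan
            vb = out[b] if b in out.columns else np.nan
            out[agg] = va + vb
        else:
            va = out.get(a, np.nan)
            vb = out.get(b, np.nan)
            out[agg] = va + vb
    return out


def amino_acid_score(value: float, requirement: float) -> float:
    """AAS = content / requirement (same units, mg g^-1 protein)."""
    if requirement <= 0:
        raise ValueError("requirement must be positive")
    return value / requirement


def classify_limiting(profile, requirements: pd.DataFrame | None = None,
                      age_group: str = "adult") -> list:
    """Amino acids whose score falls below 1 for the chosen age group.

    Returns the limiting amino acids in canonical EAA order (empty list =
    profile complete for the group). Boundary scores of exactly 1 meet the
    requirement. Missing profile entries are skipped (they cannot be
    assessed).
    """
    if age_group not in AGE_GROUPS:
        raise ValueError(f"unknown age group {age_group!r}; "
                         f"expected one of {AGE_GROUPS}")
    if requirements is None:
        requirements = load_requirements()
    if isinstance(profile, Mapping) and not isinstance(profile, pd.Series):
        profile = pd.Series(profile, dtype=float)
    failing = []
    for aa in requirements.index:
        if aa not in profile.index or pd.isna(profile[aa]):
            continue
        if amino_acid_score(profile[aa], requirements.loc[aa, age_group]) < 1.0:
            failing.append(aa)
    return failing


def score_table(profiles: pd.DataFrame,
                requirements: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-sample scores and limiting sets for both age groups.

    Returns a DataFrame with one column per (amino acid, group) score pair
    plus ``limiting_adult``/``limiting_infant`` (';'-joined names, empty
    string = complete) and ``complete_adult``/``complete_infant`` booleans.
    """
    if requirements is None:
        requirements = load_requirements()
    out = pd.DataFrame(index=profiles.index)
    for group in AGE_GROUPS:
        for aa in requirements.index:
            if aa in profiles.columns:
                out[f"score_{aa}_{group}"] = (
                    profiles[aa] / requirements.loc[aa, group])
        limiting = profiles.apply(
            lambda row: ";".join(classify_limiting(row, requirements, group)),
            axis=1)
        out[f"limiting_{group}"] = limiting
        out[f"complete_{group}"] = limiting == ""
    return out
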
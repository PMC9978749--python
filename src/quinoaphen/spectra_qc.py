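"""Quality control for NIR-predicted seed composition.

Two exclusion steps are applied to experimental samples before their NIR
predictions enter any analysis:

1. *Range filtering* — a sample is dropped when any predicted analyte falls
   outside the min/max observed in the reference set used to build the
   calibration (packaged as a versioned JSON resource). Boundary values are
   retained.
2. *Mahalanobis filtering* — a sample is dropped when its raw spectrum is
   significantly far (chi-square upper tail, df = number of wavelengths)
   from the centroid of the calibration spectra. The centroid is the
   per-wavelength mean of the calibration set; the covariance is estimated
   from the pooled calibration + experimental spectra.

A moisture-basis helper converts dry-matter mass fractions to a fixed
moisture basis (14% by convention for the packaged tables).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._resources import calibration_ranges_raw

__all__ = [
    "SpectraSet",
    "CalibrationRanges",
    "load_calibration_ranges",
    "wavelength_grid",
    "range_filter",
    "mahalanobis_filter",
    "adjust_moisture",
    "shrink_covariance",
]

#: Default grid of the spectrometer: 950-1650 nm at 5 nm (141 wavelengths).
GRID_START_NM = 950.0
GRID_STOP_NM = 1650.0
GRID_STEP_NM = 5.0


def wavelength_grid(start_nm: float = GRID_START_NM,
                    stop_nm: float = GRID_STOP_NM,
                    step_nm: float = GRID_STEP_NM) -> np.ndarray:
    """Inclusive, uniform wavelength grid in nm.

    The default instrument grid has (1650-950)/5 + 1 = 141 points, which is
    also the chi-square df used by :func:`mahalanobis_filter`.
    """
    if step_nm <= 0:
        raise ValueError("step_nm must be positive")
    if stop_nm < start_nm:
        raise ValueError("stop_nm must be >= start_nm")
    span = stop_nm - start_nm
    n_steps = span / step_nm
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(
            f"grid span {span} nm is not divisible by step {step_nm} nm")
    n = int(round(n_steps)) + 1
    return start_nm + step_nm * np.arange(n)


@dataclass
class SpectraSet:
    """A sample x wavelength absorbance matrix on a uniform nm grid."""

    sample_ids: list
    wavelengths: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = list(self.sample_ids)
        w = self.wavelengths
        if w.ndim != 1 or w.size < 1:
            raise ValueError("wavelengths must be a 1-D grid")
        if w.size > 1:
            steps = np.diff(w)
            if np.any(steps <= 0):
                raise ValueError("wavelength grid must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
                raise ValueError("wavelength grid must have a uniform step")
        if self.absorbance.shape[1] != w.size:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns but the "
                f"grid has {w.size} wavelengths")
        if len(self.sample_ids) != self.absorbance.shape[0]:
            raise ValueError("sample_ids length must match absorbance rows")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def to_csv(self, path) -> None:
        """Write as CSV with the wavelength grid as the header row."""
        df = pd.DataFrame(self.absorbance, index=self.sample_ids,
                          columns=[f"{w:g}" for w in self.wavelengths])
        df.index.name = "sample_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SpectraSet":
        df = pd.read_csv(path, index_col=0)
        waves = np.array([float(c) for c in df.columns])
        return cls(list(df.index), waves, df.to_numpy(dtype=float))


class CalibrationRanges:
    """Analyte name -> (min, max) calibration ranges.

    Two unit families are carried: primary seed components (g 100g^-1 dry
    matter) and amino acids (g 100g^-1 protein). Analytes listed in
    ``excluded`` (hydroxylysine, hydroxyproline — poorly predicted) are kept
    for I/O but never used by :func:`range_filter` unless explicitly named.
    """

    def __init__(self, ranges: Mapping[str, tuple], excluded: Iterable[str] = (),
                 version: str = "custom") -> None:
        self.version = version
        self.excluded = frozenset(excluded)
        self._ranges = {}
        for name, (lo, hi) in ranges.items():
            if lo > hi:
                raise ValueError(f"range for {name!r} has min > max")
            self._ranges[name] = (float(lo), float(hi))

    def __getitem__(self, name: str) -> tuple:
        return self._ranges[name]

    def __contains__(self, name: str) -> bool:
        return name in self._ranges

    @property
    def analytes(self) -> list:
        return [a for a in self._ranges if a not in self.excluded]

    def items(self):
        return self._ranges.items()


def load_calibration_ranges() -> CalibrationRanges:
    """Packaged SSSL NIR V3 calibration ranges (primary components + amino acids)."""
    raw = calibration_ranges_raw()
    ranges = {}
    ranges.update({k: tuple(v) for k, v in raw["primary_components"]["ranges"].items()})
    ranges.update({k: tuple(v) for k, v in raw["amino_acids"]["ranges"].items()})
    return CalibrationRanges(ranges, excluded=raw["excluded_from_analysis"],
                             version=raw["version"])


def range_filter(predictions: pd.DataFrame, ranges: CalibrationRanges,
                 analytes: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-sample exclusion mask for predictions outside calibration ranges.

    Parameters
    ----------
    predictions : DataFrame with one column per analyte, one row per sample.
    ranges : calibration min/max per analyte.
    analytes : analytes to filter on; defaults to every non-excluded analyte
        present in both `predictions` and `ranges`. Naming an analyte absent
        from `predictions` raises.

    Returns
    -------
    DataFrame of booleans (True = outside range, i.e. excluded) with one
    column per filtered analyte and an ``any`` column. Boundary values are
    inclusive, so a value exactly at min or max is retained. Missing values
    do not trigger exclusion.
    """
    if analytes is None:
        analytes = [a for a in ranges.analytes if a in predictions.columns]
    else:
        for a in analytes:
            if a not in predictions.columns:
                raise KeyError(f"analyte column {a!r} missing from predictions")
            if a not in ranges:
                raise KeyError(f"no calibration range for analyte {a!r}")
    mask = pd.DataFrame(index=predictions.index)
    for a in analytes:
        lo, hi = ranges[a]
        vals = predictions[a]
        mask[a] = ((vals < lo) | (vals > hi)).fillna(False)
    mask["any"] = mask.any(axis=1) if analytes else False
    return mask


def shrink_covariance(x_centered: np.ndarray) -> tuple[np.ndarray, float]:
    """Analytic shrinkage of the sample covariance toward its diagonal.

    Uses the Ledoit-Wolf-style (Schaefer-Strimmer) estimate of the optimal
    intensity for a diagonal target: off-diagonal entries of the unbiased
    sample covariance S are scaled by (1 - lambda) with
    lambda = sum Var(s_ij) / sum s_ij^2 over i != j, clipped to [0, 1].

    Parameters
    ----------
    x_centered : n x p matrix of observations with column means removed.

    Returns
    -------
    (shrunk covariance, lambda)
    """
    n, p = x_centered.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    s = x_centered.T @ x_centered / (n - 1)
    # Var(s_ij) via the empirical variance of the products w_kij = x_ki x_kj
    w_bar = s * (n - 1) / n
    w2_sum = (x_centered ** 2).T @ (x_centered ** 2)
    var_s = n / (n - 1) ** 3 * (w2_sum - n * w_bar ** 2)
    off = ~np.eye(p, dtype=bool)
    denom = np.sum(s[off] ** 2)
    lam = 1.0 if denom <= 0 else float(np.clip(np.sum(var_s[off]) / denom, 0.0, 1.0))
    shrunk = s.copy()
    shrunk[off] *= (1.0 - lam)
    return shrunk, lam


def mahalanobis_filter(experimental: SpectraSet, calibration: SpectraSet,
                       alpha: float = 0.001,
                       shrinkage: str = "auto") -> pd.DataFrame:
    """Flag experimental spectra far from the calibration centroid.

    The squared Mahalanobis distance of each experimental spectrum x is
    d^2 = (x - c)' Sigma^-1 (x - c), where c is the per-wavelength mean of
    the *calibration* spectra and Sigma is estimated from the pooled raw
    spectra of the experimental and calibration samples (n-1 denominator).
    The p-value is the upper chi-square tail with df equal to the number of
    wavelengths; a sample is excluded when p < alpha (default 0.001).

    Parameters
    ----------
    shrinkage : "auto" (shrink toward the diagonal when the pooled count is
        insufficient or Sigma is numerically singular), "never", or "always".

    Returns
    -------
    DataFrame indexed by sample id with columns ``d2``, ``p_value``,
    ``excluded``, ``reason`` (``mahalanobis`` or ``none``). Attributes
    ``df``, ``alpha``, ``shrinkage_lambda`` are stored in ``.attrs``.
    """
    if shrinkage not in ("auto", "never", "always"):
        raise ValueError("shrinkage must be 'auto', 'never' or 'always'")
    if calibration.n_samples < 2:
        raise ValueError("need at least 2 calibration spectra")
    if (experimental.n_wavelengths != calibration.n_wavelengths
            or not np.allclose(experimental.wavelengths, calibration.wavelengths)):
        raise ValueError("experimental and calibration wavelength grids differ")

    p = experimental.n_wavelengths
    pooled = np.vstack([experimental.absorbance, calibration.absorbance])
    n_pool = pooled.shape[0]
    centered = pooled - pooled.mean(axis=0)

    lam = 0.0
    must_shrink = shrinkage == "always" or (shrinkage == "auto" and n_pool - 1 <= p)
    if must_shrink:
        sigma, lam = shrink_covariance(centered)
    else:
        sigma = centered.T @ centered / (n_pool - 1)
        if n_pool - 1 < p or np.linalg.cond(sigma) > 1e12:
            if shrinkage == "never":
                raise np.linalg.LinAlgError(
                    "pooled covariance is singular; rerun with "
                    "shrinkage='auto' or 'always'")
            sigma, lam = shrink_covariance(centered)
    centroid = calibration.absorbance.mean(axis=0)
    dev = experimental.absorbance - centroid
    solve = np.linalg.solve(sigma, dev.T)
    d2 = np.einsum("ij,ji->i", dev, solve)
    pvals = stats.chi2.sf(d2, df=p)
    # d2 = 0 gives p exactly 1; clip away only an exact zero so p stays in (0, 1]
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    excluded = pvals < alpha
    report = pd.DataFrame({
        "d2": d2,
        "p_value": pvals,
        "excluded": excluded,
        "reason": np.where(excluded, "mahalanobis", "none"),
    }, index=pd.Index(experimental.sample_ids, name="sample_id"))
    report.attrs.update({"df": p, "alpha": alpha, "shrinkage_lambda": lam})
    return report


def adjust_moisture(value_dm, target_moisture_fraction: float):
    """Convert a dry-matter mass fraction to a target moisture basis.

    ``value_at_basis = value_dm * (1 - target)``. Applies to mass-basis
    analytes (e.g. crude protein in g 100g^-1 DM); ratio-basis values such
    as amino acids per g protein are unaffected by the moisture basis and
    should not be passed through this function.
    """
    if not 0 <= target_moisture_fraction < 1:
        raise ValueError("target moisture fraction must be in [0, 1)")
    return value_dm * (1.0 - target_moisture_fraction)
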
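"""Synthetic inputs with known ground truth for every pipeline stage.

The study layout being emulated is a randomized complete block design
(RCBD): each of ``n_gen`` accessions grown in ``n_rep`` blocks within each
of ``n_env`` greenhouses. Phenotypes follow the additive random-effects
model

    y_ijk = mu + g_i + e_j + (ge)_ij + r_jk + eps_ijk

with each effect drawn independently Gaussian with mean zero and its
requested variance. The generators also produce NIR-like spectra with
injected outliers, scanner-style seed images rendered as filled ellipses
(optionally touching in clusters), and amino-acid composition tables, each
with a ground-truth sidecar so downstream estimators can be scored against
what was actually simulated.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from ._resources import amino_acid_requirements_raw
from .spectra_qc import SpectraSet, wavelength_grid

__all__ = [
    "SimulationDesign",
    "TrueComponents",
    "SpectraSimSpec",
    "SeedImageSpec",
    "PhenotypeSim",
    "SeedImageSim",
    "simulate_phenotypes",
    "simulate_spectra",
    "simulate_seed_image",
    "simulate_composition",
]

#: Seed "mass density" used to assign a subsample mass to a rendered scan,
#: chosen so default seed sizes give thousand-seed weights in the observed
#: 0.8-4.7 g range.
SEED_MASS_MG_PER_MM2 = 1.3


@dataclass(frozen=True)
class SimulationDesign:
    """Trial layout: accessions x greenhouses x blocks, plus RNG seed."""

    n_gen: int
    n_env: int = 2
    n_rep: int = 4
    traits: tuple = ("trait",)
    seed: int = 0

    def __post_init__(self):
        if self.n_gen < 2:
            raise ValueError("n_gen must be >= 2")
        if self.n_env < 1:
            raise ValueError("n_env must be >= 1")
        if self.n_rep < 2:
            raise ValueError("n_rep must be >= 2")

    @property
    def n_rows(self) -> int:
        return self.n_gen * self.n_env * self.n_rep


@dataclass(frozen=True)
class TrueComponents:
    """Ground-truth variance components (trait units squared)."""

    sigma2_g: float
    sigma2_env: float = 0.0
    sigma2_gxe: float = 0.0
    sigma2_rep: float = 0.0
    sigma2_err: float = 0.0

    def __post_init__(self):
        for name in ("sigma2_g", "sigma2_env", "sigma2_gxe", "sigma2_rep",
                     "sigma2_err"):
            if getattr(self, name) < 0:
                raise ValueError(f"variance component {name} must be >= 0")

    @property
    def total(self) -> float:
        return (self.sigma2_g + self.sigma2_env + self.sigma2_gxe
                + self.sigma2_rep + self.sigma2_err)


@dataclass
class PhenotypeSim:
    """Simulated phenotype table plus the effect vectors that generated it."""

    table: pd.DataFrame
    effects: dict
    design: SimulationDesign
    components: Mapping[str, TrueComponents]
    grand_means: Mapping[str, float]

    def write(self, path) -> None:
        self.table.to_csv(path, index=False)


def simulate_phenotypes(design: SimulationDesign,
                        components: TrueComponents | Mapping[str, TrueComponents],
                        grand_mean: float | Mapping[str, float] = 0.0,
                        ) -> PhenotypeSim:
    """Draw an RCBD phenotype table under the additive random-effects model.

    ``components``/``grand_mean`` may be single values (applied to every
    trait in ``design.traits``, drawn independently per trait) or mappings
    keyed by trait name. The returned object carries the generated effect
    vectors per trait so variance-component estimates can be compared with
    exactly what was drawn.
    """
    if isinstance(components, TrueComponents):
        components = {t: components for t in design.traits}
    if not isinstance(grand_mean, Mapping):
        grand_mean = {t: float(grand_mean) for t in design.traits}
    missing = [t for t in design.traits if t not in components]
    if missing:
        raise ValueError(f"no components given for traits {missing}")

    rng = np.random.default_rng(design.seed)
    G, E, R = design.n_gen, design.n_env, design.n_rep
    gen_ids = [f"ACC{i + 1:04d}" for i in range(G)]
    env_ids = [f"GH{chr(ord('A') + j)}" for j in range(E)]
    gi, ej, rk = np.meshgrid(np.arange(G), np.arange(E), np.arange(R),
                             indexing="ij")
    gi, ej, rk = gi.ravel(), ej.ravel(), rk.ravel()
    table = pd.DataFrame({
        "accession": np.array(gen_ids)[gi],
        "greenhouse": np.array(env_ids)[ej],
        "block": rk + 1,
    })
    effects: dict = {}
    for trait in design.traits:
        c = components[trait]
        mu = grand_mean[trait]
        g = rng.normal(0.0, np.sqrt(c.sigma2_g), G)
        e = rng.normal(0.0, np.sqrt(c.sigma2_env), E)
        ge = rng.normal(0.0, np.sqrt(c.sigma2_gxe), (G, E))
        r = rng.normal(0.0, np.sqrt(c.sigma2_rep), (E, R))
        eps = rng.normal(0.0, np.sqrt(c.sigma2_err), G * E * R)
        y = mu + g[gi] + e[ej] + ge[gi, ej] + r[ej, rk] + eps
        table[trait] = y
        effects[trait] = {"genotype": g, "environment": e, "gxe": ge,
                          "rep_within_env": r, "residual": eps}
    return PhenotypeSim(table=table, effects=effects, design=design,
                        components=dict(components), grand_means=dict(grand_mean))


@dataclass(frozen=True)
class SpectraSimSpec:
    """Specification for calibration + experimental NIR-like spectra."""

    n_cal: int = 175
    n_exp: int = 200
    n_wave: int = 141
    outlier_fraction: float = 0.05
    outlier_shift: float = 6.0
    seed: int = 0
    rho: float = 0.98      # AR-1 wavelength correlation; mimics NIR smoothness
    sd: float = 0.02       # per-wavelength absorbance SD

    def __post_init__(self):
        if self.n_wave <= 1:
            raise ValueError("n_wave must be > 1")
        if not 0 <= self.outlier_fraction <= 1:
            raise ValueError("outlier_fraction must be in [0, 1]")
        if self.n_cal < 2 or self.n_exp < 0:
            raise ValueError("need n_cal >= 2 and n_exp >= 0")


def _smooth_mean_spectrum(waves: np.ndarray) -> np.ndarray:
    # A plausible absorbance baseline: gentle slope plus two broad bands.
    t = (waves - waves[0]) / (waves[-1] - waves[0])
    return (0.35 + 0.15 * t
            + 0.10 * np.exp(-0.5 * ((t - 0.35) / 0.12) ** 2)
            + 0.06 * np.exp(-0.5 * ((t - 0.80) / 0.08) ** 2))


def simulate_spectra(spec: SpectraSimSpec,
                     ) -> tuple[SpectraSet, SpectraSet, np.ndarray]:
    """Draw calibration and experimental spectra with labelled outliers.

    Inliers (and all calibration spectra) come from one multivariate normal
    with AR-1 wavelength correlation (rho^|i-j|), so neighbouring 5 nm
    channels are strongly correlated as in real NIR data. Each labelled
    outlier receives a perturbation of ``outlier_shift`` x SD on a random
    quarter of the wavelengths.

    Returns (calibration, experimental, outlier_labels) where the labels are
    a boolean array over the experimental samples.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_wave == 141:
        waves = wavelength_grid()
    else:
        waves = wavelength_grid(950.0, 950.0 + 5.0 * (spec.n_wave - 1), 5.0)
    mean = _smooth_mean_spectrum(waves)
    idx = np.arange(spec.n_wave)
    corr = spec.rho ** np.abs(idx[:, None] - idx[None, :])
    chol = np.linalg.cholesky(spec.sd ** 2 * corr)

    def draw(n):
        return mean + rng.standard_normal((n, spec.n_wave)) @ chol.T

    cal = draw(spec.n_cal)
    exp = draw(spec.n_exp)
    n_out = int(round(spec.outlier_fraction * spec.n_exp))
    labels = np.zeros(spec.n_exp, dtype=bool)
    if n_out:
        which = rng.choice(spec.n_exp, size=n_out, replace=False)
        labels[which] = True
        n_pert = max(1, spec.n_wave // 4)
        for i in which:
            cols = rng.choice(spec.n_wave, size=n_pert, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_pert)
            exp[i, cols] += signs * spec.outlier_shift * spec.sd
    cal_set = SpectraSet([f"CAL{i + 1:04d}" for i in range(spec.n_cal)], waves, cal)
    exp_set = SpectraSet([f"EXP{i + 1:04d}" for i in range(spec.n_exp)], waves, exp)
    return cal_set, exp_set, labels


@dataclass(frozen=True)
class SeedImageSpec:
    """Specification for a rendered flatbed-scanner seed image."""

    n_seeds: int = 100
    dpi: float = 1200.0
    mean_diameter_mm: float = 1.8
    sd_diameter_mm: float = 0.1
    cluster_fraction: float = 0.0
    base_rgb: tuple = (0.82, 0.72, 0.55)
    seed: int = 0
    mean_eccentricity: float = 0.35
    cluster_size: int = 2      # seeds per touching cluster (2 = pairs)
    overlap_fraction: float = 0.15  # center gap shortfall, <= 0.2 of radius

    def __post_init__(self):
        if self.n_seeds < 0:
            raise ValueError("n_seeds must be >= 0")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")
        if not 0 <= self.cluster_fraction <= 1:
            raise ValueError("cluster_fraction must be in [0, 1]")
        if not 0 < self.overlap_fraction <= 0.2:
            raise ValueError("overlap_fraction must be in (0, 0.2]")
        if self.cluster_size < 2:
            raise ValueError("cluster_size must be >= 2")


@dataclass
class SeedImageSim:
    """Rendered scan plus per-seed ground truth and assigned subsample mass."""

    image: np.ndarray
    ground_truth: pd.DataFrame
    subsample_mass_g: float
    spec: SeedImageSpec

    def write(self, image_path, sidecar_path=None) -> None:
        import imageio.v3 as iio

        iio.imwrite(image_path, self.image)
        if sidecar_path is not None:
            payload = {
                "n_seeds": int(len(self.ground_truth)),
                "subsample_mass_g": self.subsample_mass_g,
                "dpi": self.spec.dpi,
                "seeds": self.ground_truth.to_dict(orient="records"),
            }
            with open(sidecar_path, "w", encoding="utf-8") as fh:
                json.dump(payload, fh, indent=1)


def simulate_seed_image(spec: SeedImageSpec) -> SeedImageSim:
    """Render seeds as filled ellipses on a dark matte background.

    Seeds are sized from a normal equivalent-circle-diameter distribution
    and shaped with eccentricity around ``mean_eccentricity``. A
    ``cluster_fraction`` of seeds is placed touching a neighbour, with the
    pair centre distance shortened by ``overlap_fraction`` of the smaller
    radius (at most 20%), so touching clusters remain separable by
    distance-transform declumping. Subsample mass is proportional to the
    total true seed area at ``SEED_MASS_MG_PER_MM2``.
    """
    rng = np.random.default_rng(spec.seed)
    px_per_mm = spec.dpi / 25.4
    mm_per_px = 25.4 / spec.dpi

    n = spec.n_seeds
    records = []
    if n == 0:
        img = _render([], 256, 256, rng)
        return SeedImageSim(img, pd.DataFrame(records), 0.0, spec)

    diam_px = np.clip(rng.normal(spec.mean_diameter_mm, spec.sd_diameter_mm, n),
                      0.3 * spec.mean_diameter_mm, None) * px_per_mm
    ecc = np.clip(rng.normal(spec.mean_eccentricity, 0.03, n), 0.15, 0.55)
    q = np.sqrt(1.0 - ecc ** 2)           # minor/major ratio
    a_px = diam_px / 2.0 / np.sqrt(q)     # semi-major, preserves circle area
    b_px = diam_px / 2.0 * np.sqrt(q)
    theta = rng.uniform(0, np.pi, n)

    n_clustered = int(round(spec.cluster_fraction * n))
    k = spec.cluster_size
    n_clusters = n_clustered // k
    n_clustered = n_clusters * k

    # image sized for sparse placement: ~ (2.4 diam)^2 per seed
    cell = 2.4 * np.max(diam_px)
    side = int(np.ceil(np.sqrt(n)) * cell + 2 * cell)
    margin = float(np.max(a_px)) + 4

    placed: list[tuple] = []  # (row, col, a, b, theta, seed_index)
    order = list(range(n))
    gap = 4.0  # px of guaranteed background between non-touching seeds

    def radius_along(s, ang):
        # ellipse boundary distance from the centre along absolute angle ang
        phi = ang - theta[s]
        return (a_px[s] * b_px[s]
                / np.hypot(b_px[s] * np.cos(phi), a_px[s] * np.sin(phi)))

    def fits(r0, c0, a0, others=()):
        if not (margin <= r0 <= side - margin and margin <= c0 <= side - margin):
            return False
        for (r1, c1, a1, _, _, _) in list(placed) + list(others):
            if (r0 - r1) ** 2 + (c0 - c1) ** 2 < (a0 + a1 + gap) ** 2:
                return False
        return True

    budget = 4000
    i = 0
    while i < n:
        in_cluster = i < n_clustered
        group = list(range(i, i + k)) if in_cluster else [i]
        ok = False
        for _ in range(budget):
            r0 = rng.uniform(margin, side - margin)
            c0 = rng.uniform(margin, side - margin)
            if not fits(r0, c0, a_px[group[0]]):
                continue
            trial = [(r0, c0, group[0])]
            good = True
            for s in group[1:]:
                # place the next seed touching the previous one, with the
                # centre distance shortened along the actual contact
                # direction so overlap stays <= overlap_fraction of the
                # smaller boundary radius
                rp, cp, jp = trial[-1]
                placed_next = False
                for _ in range(60):
                    ang = rng.uniform(0, 2 * np.pi)
                    r_prev = radius_along(jp, ang)
                    r_next = radius_along(s, ang + np.pi)
                    d = r_prev + r_next - spec.overlap_fraction * min(r_prev, r_next)
                    rn, cn = rp + d * np.sin(ang), cp + d * np.cos(ang)
                    prev_members = [(rr, cc, a_px[g], None, None, g)
                                    for (rr, cc, g) in trial[:-1]]
                    if fits(rn, cn, a_px[s], others=prev_members):
                        trial.append((rn, cn, s))
                        placed_next = True
                        break
                if not placed_next:
                    good = False
                    break
            if good and len(trial) == len(group):
                for (rr, cc, s) in trial:
                    placed.append((rr, cc, a_px[s], b_px[s], theta[s], s))
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place seed {i + 1} of {n} within the retry "
                f"budget; achieved {len(placed)} seeds")
        i += len(group)

    img = _render(placed, side, side, rng, base_rgb=spec.base_rgb)
    for (rr, cc, aa, bb, th, s) in sorted(placed, key=lambda t: t[5]):
        area_px = np.pi * aa * bb
        records.append({
            "seed": int(s),
            "row_px": rr, "col_px": cc,
            "a_px": aa, "b_px": bb, "theta": th,
            "area_px": area_px,
            "area_mm2": area_px * mm_per_px ** 2,
            "major_mm": 2 * aa * mm_per_px,
            "minor_mm": 2 * bb * mm_per_px,
            "eccentricity": float(np.sqrt(1 - (bb / aa) ** 2)),
            "clustered": bool(s < n_clustered),
        })
    truth = pd.DataFrame(records)
    mass_g = SEED_MASS_MG_PER_MM2 * truth["area_mm2"].sum() / 1000.0
    return SeedImageSim(img, truth, float(mass_g), spec)


def _render(placed, h, w, rng, base_rgb=(0.82, 0.72, 0.55)) -> np.ndarray:
    img = np.full((h, w, 3), 0.05, dtype=float)
    img += rng.normal(0.0, 0.004, img.shape)
    for (r0, c0, a, b, th, s) in placed:
        rr, cc = draw_ellipse(r0, c0, a, b, shape=(h, w), rotation=th)
        jitter = rng.normal(0.0, 0.015, 3)
        color = np.clip(np.asarray(base_rgb) + jitter, 0.2, 1.0)
        img[rr, cc] = color
    return (np.clip(img, 0, 1) * 255).round().astype(np.uint8)


def simulate_composition(n_samples: int,
                         mean_profile: Mapping[str, float] | None = None,
                         cov: np.ndarray | float | None = None,
                         seed: int = 0) -> pd.DataFrame:
    """Draw amino-acid profiles (mg g^-1 protein) plus crude components.

    Defaults reproduce the panel means and spreads of the packaged
    requirement table: the default ``mean_profile`` is the nine-EAA panel
    mean and the default ``cov`` is diagonal with the panel SDs squared.
    Crude protein, ash, crude fat and total amino acids are appended as
    independent normal draws around their panel summaries.
    """
    raw = amino_acid_requirements_raw()
    if mean_profile is None:
        mean_profile = raw["panel_mean_profile"]
    names = list(mean_profile)
    mu = np.array([mean_profile[k] for k in names], dtype=float)
    d = len(names)
    if cov is None:
        sds = raw["panel_sd_profile"]
        missing = [k for k in names if k not in sds]
        if missing:
            raise ValueError(
                f"no default SD for {missing}; pass cov explicitly")
        cov = np.diag([sds[k] ** 2 for k in names])
    elif np.isscalar(cov):
        cov = float(cov) * np.eye(d)
    else:
        cov = np.asarray(cov, dtype=float)
    if cov.shape != (d, d):
        raise ValueError(
            f"cov has shape {cov.shape} but the profile has {d} entries")
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(mu, cov, size=n_samples,
                                    method="cholesky" if _is_pd(cov) else "eigh")
    out = pd.DataFrame(draws, columns=names)
    for comp, stats_ in raw["crude_components"].items():
        out[comp] = rng.normal(stats_["mean"], stats_["sd"], n_samples)
    out.index = [f"S{i + 1:04d}" for i in range(n_samples)]
    out.index.name = "sample_id"
    return out


def _is_pd(cov: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(cov)
        return True
    except np.linalg.LinAlgError:
        return False
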
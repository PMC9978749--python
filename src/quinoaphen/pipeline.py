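"""End-to-end orchestration: simulate -> QC -> traits -> models -> report.

A run is driven by a :class:`RunConfig` (constructible from YAML or JSON).
Every stage draws its randomness from a child of the run seed, so reruns
with the same config are byte-identical. Outputs are CSV/PNG/JSON files in
the configured output directory, shaped like the field's usual summary
tables: per-trait variance components + heritabilities, BLUE tables,
correlation matrix + heatmap, PCA loadings/contributions, cluster labels,
group summaries, nutrition classification, and an exclusion audit with
counts by reason.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .mixed_models import compute_blues, estimate_components, heritability
from .multivariate import (contribution_threshold, correlation_matrix,
                           group_summary, kmeans_cluster, pca, ward_cluster)
from .nutrition import aggregate_compound, load_requirements, score_table
from .seed_imaging import SeedScan, analyze_scan
from .spectra_qc import (load_calibration_ranges, mahalanobis_filter,
                         range_filter)
from .synthetic_data import (SeedImageSpec, SimulationDesign, SpectraSimSpec,
                             TrueComponents, simulate_composition,
                             simulate_phenotypes, simulate_seed_image,
                             simulate_spectra)
from .traits import ExclusionRules, apply_exclusions, protein_yield, total_seeds

logger = logging.getLogger("quinoaphen")

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_TRAIT_MODELS"]

#: Default per-trait generating models: variance components in
#: (env, genotype, gxe, rep-within-env, error) order plus the grand mean,
#: matching the magnitudes observed for a 360-accession greenhouse panel.
DEFAULT_TRAIT_MODELS: dict = {
    "days_to_anthesis":   {"env": 8.4, "g": 46.3,  "gxe": 1.6,  "rep": 5.9,  "err": 15.6,  "mean": 51.0},
    "days_to_harvest":    {"env": 9.1, "g": 354.6, "gxe": 32.4, "rep": 7.9,  "err": 109.1, "mean": 110.0},
    "height_harvest_cm":  {"env": 0.0, "g": 666.1, "gxe": 42.7, "rep": 12.5, "err": 269.1, "mean": 144.0},
    "infl_length_cm":     {"env": 1.6, "g": 77.2,  "gxe": 15.1, "rep": 0.8,  "err": 45.5,  "mean": 34.0},
    "yield_g":            {"env": 0.1, "g": 5.0,   "gxe": 0.6,  "rep": 0.0,  "err": 2.3,   "mean": 5.516},
    "tsw_g":              {"env": 0.0, "g": 0.3,   "gxe": 0.0,  "rep": 0.0,  "err": 0.1,   "mean": 2.604},
    "crude_protein_pct":  {"env": 0.0, "g": 0.2,   "gxe": 0.0,  "rep": 0.0,  "err": 0.2,   "mean": 14.02},
    "seed_area_mm2":      {"env": 0.0, "g": 0.2,   "gxe": 0.0,  "rep": 0.0,  "err": 0.1,   "mean": 2.54},
    "sum_rgb":            {"env": 0.0, "g": 2469.3, "gxe": 26.7, "rep": 10.3, "err": 421.2, "mean": 377.0},
}

THREE_TRAIT_SET = ("days_to_harvest", "height_harvest_cm", "yield_g")


@dataclass
class RunConfig:
    """Configuration for a full synthetic run."""

    outdir: str = "quinoaphen_run"
    seed: int = 1
    n_gen: int = 60
    n_env: int = 2
    n_rep: int = 4
    alpha: float = 0.001
    min_yield_g: float = 0.5
    min_seed_count: int = 97
    traits: tuple = tuple(DEFAULT_TRAIT_MODELS)
    cluster_traits: tuple = tuple(DEFAULT_TRAIT_MODELS)
    three_trait_set: tuple = THREE_TRAIT_SET
    ward_k: int = 4
    kmeans_k: int = 4
    n_scans: int = 3
    n_spectra_cal: int = 120
    n_spectra_exp: int = 120
    n_wavelengths: int = 141
    spectra_outlier_fraction: float = 0.05
    n_composition_samples: int = 200
    write_images: bool = True

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix in (".yml", ".yaml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        cfg = cls(**data)
        return cfg

    def child_seed(self, stage: int) -> int:
        ss = np.random.SeedSequence(self.seed)
        return int(ss.spawn(stage + 1)[stage].generate_state(1)[0] % (2 ** 31))


def _trait_components(name: str) -> tuple[TrueComponents, float]:
    m = DEFAULT_TRAIT_MODELS[name]
    return (TrueComponents(sigma2_g=m["g"], sigma2_env=m["env"],
                           sigma2_gxe=m["gxe"], sigma2_rep=m["rep"],
                           sigma2_err=m["err"]), m["mean"])


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return a manifest dict (also written as JSON)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "quinoaphen",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "outputs": [],
        "stages": {},
    }

    def emit(name: str, df: pd.DataFrame, **to_csv_kw):
        path = out / name
        df.to_csv(path, **to_csv_kw)
        manifest["outputs"].append(name)

    try:
        # -- stage 1: phenotypes -------------------------------------------
        comps = {}
        means = {}
        for t in config.traits:
            comps[t], means[t] = _trait_components(t)
        design = SimulationDesign(n_gen=config.n_gen, n_env=config.n_env,
                                  n_rep=config.n_rep,
                                  traits=tuple(config.traits),
                                  seed=config.child_seed(0))
        sim = simulate_phenotypes(design, comps, means)
        pheno = sim.table
        emit("phenotypes.csv", pheno, index=False)
        manifest["stages"]["phenotypes"] = {"rows": len(pheno)}

        # -- stage 2: spectra QC -------------------------------------------
        sspec = SpectraSimSpec(n_cal=config.n_spectra_cal,
                               n_exp=config.n_spectra_exp,
                               n_wave=config.n_wavelengths,
                               outlier_fraction=config.spectra_outlier_fraction,
                               outlier_shift=6.0,
                               seed=config.child_seed(1))
        cal, exp, labels = simulate_spectra(sspec)
        report = mahalanobis_filter(exp, cal, alpha=config.alpha)
        emit("spectra_qc.csv", report)
        manifest["stages"]["spectra_qc"] = {
            "n_flagged": int(report["excluded"].sum()),
            "n_true_outliers": int(labels.sum()),
            "alpha": config.alpha,
        }

        # -- stage 3: composition + range filter ---------------------------
        comp = simulate_composition(config.n_composition_samples,
                                    seed=config.child_seed(2))
        ranges = load_calibration_ranges()
        primary = [a for a in ("crude_protein", "ash", "crude_fat") if a in comp]
        # packaged ranges are dry-matter based; simulated crude values are
        # 14%-moisture based, compatible in scale for the filter demo
        rf = range_filter(comp, ranges, analytes=primary)
        emit("composition.csv", comp)
        emit("composition_range_filter.csv", rf)
        manifest["stages"]["range_filter"] = {
            "n_excluded": int(rf["any"].sum())}

        # -- stage 4: seed scans -------------------------------------------
        rng = np.random.default_rng(config.child_seed(3))
        scan_rows = []
        for s in range(config.n_scans):
            n_seeds = int(rng.integers(70, 150))
            spec = SeedImageSpec(n_seeds=n_seeds, cluster_fraction=0.3,
                                 seed=config.child_seed(10 + s))
            simg = simulate_seed_image(spec)
            scan = SeedScan(simg.image, dpi=spec.dpi,
                            sample_id=f"SCAN{s + 1}",
                            subsample_mass_g=simg.subsample_mass_g)
            morph, _ = analyze_scan(scan)
            row = {"sample_id": scan.sample_id,
                   "true_count": len(simg.ground_truth),
                   "subsample_mass_g": simg.subsample_mass_g}
            row.update(morph.as_dict())
            scan_rows.append(row)
            if config.write_images:
                simg.write(out / f"scan_{s + 1}.png",
                           out / f"scan_{s + 1}_truth.json")
                manifest["outputs"] += [f"scan_{s + 1}.png",
                                        f"scan_{s + 1}_truth.json"]
        scans = pd.DataFrame(scan_rows)
        emit("seed_morphometry.csv", scans, index=False)
        manifest["stages"]["seed_imaging"] = {"n_scans": config.n_scans}

        # -- stage 5: derived traits + exclusions --------------------------
        pheno = pheno.copy()
        pheno["total_seeds"] = total_seeds(pheno["yield_g"], pheno["tsw_g"])
        pheno["protein_yield_g"] = protein_yield(
            pheno["crude_protein_pct"].clip(0, 100), pheno["yield_g"])
        # plausible per-plant image seed counts for the exclusion rule
        pheno["image_seed_count"] = rng.integers(60, 400, len(pheno))
        rules = ExclusionRules(
            min_yield_g=config.min_yield_g,
            min_seed_count=config.min_seed_count,
            composition_cols=("crude_protein_pct", "protein_yield_g"),
            morphology_cols=("seed_area_mm2", "sum_rgb"),
        )
        masked, audit = apply_exclusions(pheno, rules)
        emit("phenotypes_masked.csv", masked, index=False)
        emit("exclusion_audit.csv", audit, index=False)
        manifest["stages"]["exclusions"] = (
            audit["reason"].value_counts().to_dict())

        # -- stage 6: mixed models per trait -------------------------------
        h2_rows = []
        blues = {}
        for t in config.traits:
            vc = estimate_components(masked, t)
            h2 = heritability(masked, t, components=vc)
            blues[t] = compute_blues(masked, t, components=vc)
            h2_rows.append({
                "trait": t,
                "sigma2_env": vc.sigma2_env, "sigma2_g": vc.sigma2_g,
                "sigma2_gxe": vc.sigma2_gxe, "sigma2_rep": vc.sigma2_rep,
                "sigma2_err": vc.sigma2_err,
                "g_to_err_ratio": (vc.sigma2_g / vc.sigma2_err
                                   if vc.sigma2_err > 0 else np.nan),
                "h2_cullis": h2.h2_cullis,
                "h2_standard": h2.h2_standard,
            })
        h2_table = pd.DataFrame(h2_rows)
        emit("heritability.csv", h2_table, index=False)
        blue_table = pd.DataFrame(blues)
        emit("blues.csv", blue_table)
        manifest["stages"]["mixed_models"] = {"n_traits": len(config.traits)}

        # -- stage 7: nutrition --------------------------------------------
        comp_agg = aggregate_compound(comp)
        nut = score_table(comp_agg, load_requirements())
        emit("nutrition_scores.csv", nut)
        manifest["stages"]["nutrition"] = {
            "complete_adult": int(nut["complete_adult"].sum()),
            "complete_infant": int(nut["complete_infant"].sum()),
        }

        # -- stage 8: multivariate -----------------------------------------
        corr = correlation_matrix(blue_table, method="spearman")
        emit("correlations.csv", corr.r)
        _heatmap(corr, out / "correlations.png")
        manifest["outputs"].append("correlations.png")

        pres = pca(blue_table, traits=list(config.cluster_traits))
        emit("pca_loadings.csv", pres.loadings)
        emit("pca_contributions.csv", pres.contributions)
        manifest["stages"]["pca"] = {
            "explained_pct_pc1": float(pres.explained_pct.iloc[0]),
            "contribution_threshold": contribution_threshold(
                len(config.cluster_traits)),
        }

        ward = ward_cluster(blue_table, traits=list(config.cluster_traits),
                            k=config.ward_k)
        km = kmeans_cluster(blue_table, traits=list(config.three_trait_set),
                            k=config.kmeans_k, seed=config.child_seed(4))
        groups = pd.DataFrame({"all_trait_cluster": ward.labels,
                               "three_trait_cluster": km.labels})
        emit("cluster_labels.csv", groups)
        summ = group_summary(blue_table, ward.labels)
        emit("group_summary.csv", summ)
        manifest["stages"]["clustering"] = {
            "ward_sizes": ward.labels.value_counts().sort_index().tolist(),
            "kmeans_inertia": km.inertia,
        }
    except Exception as exc:  # partial outputs stay on disk for debugging
        manifest["failed_stage"] = _current_stage(manifest)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1),
                                           encoding="utf-8")
        raise RuntimeError(
            f"pipeline aborted during stage after "
            f"{_current_stage(manifest)!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1),
                                       encoding="utf-8")
    manifest["outputs"].append("manifest.json")
    return manifest


def _current_stage(manifest: dict) -> str:
    stages = list(manifest.get("stages", {}))
    return stages[-1] if stages else "start"


def _heatmap(corr, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    m = corr.r.to_numpy()
    im = ax.imshow(m, vmin=-1, vmax=1, cmap="RdBu")
    ax.set_xticks(range(len(corr.r.columns)))
    ax.set_xticklabels(corr.r.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(corr.r.index)))
    ax.set_yticklabels(corr.r.index, fontsize=7)
    sig = corr.significant()
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            if i != j and not sig.iloc[i, j]:
                ax.text(j, i, "X", ha="center", va="center", fontsize=6)
    fig.colorbar(im, ax=ax, label=f"{corr.method} r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
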
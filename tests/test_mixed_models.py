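"""Variance components, BLUE/BLUP, and the two heritability statistics."""
import json
import subprocess

import numpy as np
import pandas as pd
import pytest

from quinoaphen.mixed_models import (VarianceComponents, compute_blues,
                                     compute_blups, cullis_h2,
                                     estimate_components, heritability,
                                     standard_h2)
from quinoaphen.synthetic_data import (SimulationDesign, TrueComponents,
                                       simulate_phenotypes)

COMP_NAMES = ("sigma2_g", "sigma2_env", "sigma2_gxe", "sigma2_rep",
              "sigma2_err")


def _simulate(n_gen=30, n_env=2, n_rep=3, comps=(5, 1, 1, 0.5, 2), seed=0,
              mu=10.0):
    design = SimulationDesign(n_gen, n_env, n_rep, traits=("y",), seed=seed)
    return simulate_phenotypes(design, TrueComponents(*comps), mu)


class TestStandardH2:
    # variance components in (env, g, gxe, rep, err) column order with the
    # panel design (360 accessions, 2 greenhouses, 4 blocks)
    @pytest.mark.parametrize("env,g,gxe,rep,err,expected", [
        (8.4, 46.3, 1.6, 5.9, 15.6, 0.9),    # days to anthesis
        (0.7, 3.9, 6.4, 0.3, 26.2, 0.5),     # anthesis duration
        (0.0, 93.0, 27.5, 0.6, 75.0, 0.9),   # fruit set / ripening
        (9.1, 354.6, 32.4, 7.9, 109.1, 0.9),  # days to harvest
        (0.0, 5.4, 0.2, 0.1, 2.4, 1.0),      # lysine content
        (0.1, 5.0, 0.6, 0.0, 2.3, 0.9),      # yield
    ])
    def test_published_panel_rows_round_to_printed_value(self, env, g, gxe,
                                                         rep, err, expected):
        vc = VarianceComponents(g, env, gxe, rep, err, 360, 2, 4)
        assert round(standard_h2(vc), 1) == expected

    def test_pure_genotypic_variance_gives_one(self):
        vc = VarianceComponents(3.0, 0, 0, 0, 0, 10, 2, 4)
        assert standard_h2(vc) == 1.0

    def test_error_divisor_includes_genotype_count(self):
        vc = VarianceComponents(1.0, 0, 0, 0, 8.0, 10, 2, 4)
        assert standard_h2(vc) == pytest.approx(1 / (1 + 8 / 80))
        assert standard_h2(vc, conventional=True) == pytest.approx(1 / (1 + 1))


class TestCullisH2:
    def test_zero_pev_gives_one(self):
        assert cullis_h2(2.0, 0.0) == 1.0

    def test_pev_equal_to_twice_sigma_g_gives_zero(self):
        assert cullis_h2(2.0, 4.0) == 0.0

    def test_zero_genotypic_variance_undefined(self):
        assert np.isnan(cullis_h2(0.0, 1.0))

    def test_many_replicates_approach_no_env_standard_h2(self):
        sim = _simulate(n_gen=40, n_env=2, n_rep=25,
                        comps=(5, 0, 0, 0, 2), seed=3)
        vc = estimate_components(sim.table, "y")
        h2 = heritability(sim.table, "y", components=vc)
        expect = vc.sigma2_g / (vc.sigma2_g + vc.sigma2_rep / vc.n_rep
                                + vc.sigma2_err / (vc.n_env * vc.n_rep))
        assert h2.h2_cullis == pytest.approx(expect, abs=0.05)


class TestEstimateComponents:
    def test_zero_noise_data_gives_zero_components(self):
        sim = _simulate(comps=(0, 0, 0, 0, 0), mu=7.0)
        vc = estimate_components(sim.table, "y")
        for name in COMP_NAMES:
            assert getattr(vc, name) == pytest.approx(0.0, abs=1e-9)

    def test_reml_equals_balanced_anova_closed_form(self):
        sim = _simulate(seed=11)
        anova = estimate_components(sim.table, "y", method="anova")
        reml = estimate_components(sim.table, "y", method="reml")
        for name in COMP_NAMES:
            a, r = getattr(anova, name), getattr(reml, name)
            assert r == pytest.approx(a, rel=1e-6, abs=1e-8)

    def test_em_loglik_is_monotone_nondecreasing(self):
        sim = _simulate(seed=5)
        table = sim.table.drop(index=sim.table.sample(15, random_state=0).index)
        vc = estimate_components(table, "y")
        assert vc.method == "em-reml"
        trace = vc.loglik_trace
        assert np.all(np.diff(trace) > -1e-7)

    def test_recovery_on_simulated_data(self):
        estimates = []
        for seed in range(25):
            sim = _simulate(n_gen=100, n_env=2, n_rep=4, seed=seed)
            estimates.append(estimate_components(sim.table, "y").sigma2_g)
        assert np.mean(estimates) == pytest.approx(5.0, rel=0.10)

    def test_single_environment_marks_env_terms_not_estimable(self):
        sim = _simulate(n_env=1, comps=(5, 0, 0, 0.5, 2), seed=1)
        vc = estimate_components(sim.table, "y")
        assert np.isnan(vc.sigma2_env) and np.isnan(vc.sigma2_gxe)
        assert vc.sigma2_g > 0

    def test_matches_lme4_reml_on_small_balanced_instance(self, tmp_path):
        sim = _simulate(n_gen=15, n_env=2, n_rep=3, seed=4)
        csv = tmp_path / "ph.csv"
        sim.table.to_csv(csv, index=False)
        vc = estimate_components(sim.table, "y", method="reml")
        rcode = f"""
        suppressMessages(library(lme4)); suppressMessages(library(jsonlite))
        d <- read.csv("{csv}")
        d$rep <- interaction(d$greenhouse, d$block)
        d$gxe <- interaction(d$accession, d$greenhouse)
        m <- lmer(y ~ 1 + (1|accession) + (1|greenhouse) + (1|gxe) + (1|rep),
                  data=d, control=lmerControl(check.nobs.vs.nlev="ignore",
                                              check.nobs.vs.nRE="ignore"))
        v <- as.data.frame(VarCorr(m))
        cat(toJSON(setNames(as.list(v$vcov), v$grp), auto_unbox=TRUE))
        """
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, check=True)
        r = json.loads(out.stdout)
        assert vc.sigma2_g == pytest.approx(r["accession"], rel=2e-3, abs=1e-4)
        assert vc.sigma2_gxe == pytest.approx(r["gxe"], rel=2e-3, abs=1e-4)
        assert vc.sigma2_err == pytest.approx(r["Residual"], rel=2e-3, abs=1e-4)


class TestBlues:
    def test_reduce_to_accession_means_without_random_variances(self):
        sim = _simulate(comps=(4, 0, 0, 0, 1), seed=7)
        vc = VarianceComponents(4, 0, 0, 0, 1, 30, 2, 3)
        blues = compute_blues(sim.table, "y", components=vc)
        means = sim.table.groupby("accession")["y"].mean()
        assert np.allclose(blues.sort_index(), means.sort_index())

    def test_shift_equivariance(self):
        sim = _simulate(seed=8)
        vc = estimate_components(sim.table, "y")
        base = compute_blues(sim.table, "y", components=vc)
        shifted_table = sim.table.assign(y=sim.table["y"] + 11.5)
        shifted = compute_blues(shifted_table, "y", components=vc)
        assert np.allclose(shifted - base, 11.5)

    def test_correlates_with_true_genotype_values(self):
        sim = _simulate(n_gen=80, comps=(4, 1, 0.5, 0.5, 2), seed=9)
        blues = compute_blues(sim.table, "y")
        truth = pd.Series(sim.effects["y"]["genotype"],
                          index=sorted(blues.index))
        r = np.corrcoef(blues.sort_index(), truth.sort_index())[0, 1]
        assert r >= 0.95


class TestBlups:
    def test_zero_genotypic_variance_gives_zero_blups(self):
        sim = _simulate(seed=10)
        vc = VarianceComponents(0, 1, 1, 0.5, 2, 30, 2, 3)
        res = compute_blups(sim.table, "y", components=vc)
        assert np.allclose(res.blups, 0.0)
        assert np.isnan(res.mean_pairwise_pev)

    def test_blups_shrink_relative_to_centered_blues(self):
        sim = _simulate(seed=12)
        vc = estimate_components(sim.table, "y")
        blups = compute_blups(sim.table, "y", components=vc).blups
        blues = compute_blues(sim.table, "y", components=vc)
        centered = (blues - blues.mean()).sort_index()
        assert (np.abs(blups.sort_index()) <= np.abs(centered) + 1e-8).all()

    def test_matches_gls_oracle_on_small_instance(self):
        # independent route: build V explicitly, beta = GLS, u = G Z' V^-1 r
        sim = _simulate(n_gen=6, n_env=2, n_rep=2, seed=13)
        table = sim.table
        vc = VarianceComponents(5, 1, 1, 0.5, 2, 6, 2, 2)
        res = compute_blups(table, "y", components=vc)

        y = table["y"].to_numpy()
        n = len(table)
        def onehot(col):
            return pd.get_dummies(table[col].astype(str)).to_numpy(float)
        zg = onehot("accession")
        ze = onehot("greenhouse")
        zge = pd.get_dummies(table["accession"].astype(str) + ":"
                             + table["greenhouse"].astype(str)).to_numpy(float)
        zr = pd.get_dummies(table["greenhouse"].astype(str) + ":"
                            + table["block"].astype(str)).to_numpy(float)
        V = (5 * zg @ zg.T + 1 * ze @ ze.T + 1 * zge @ zge.T
             + 0.5 * zr @ zr.T + 2 * np.eye(n))
        Vi = np.linalg.inv(V)
        X = np.ones((n, 1))
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u = 5 * zg.T @ Vi @ (y - X @ beta)
        assert np.allclose(res.blups.to_numpy(), u, atol=1e-8)

    def test_heritabilities_invariant_to_affine_trait_rescaling(self):
        sim = _simulate(seed=14)
        h2a = heritability(sim.table, "y")
        rescaled = sim.table.assign(y=3.2 * sim.table["y"] + 7.0)
        h2b = heritability(rescaled, "y")
        assert h2b.h2_standard == pytest.approx(h2a.h2_standard, abs=1e-6)
        assert h2b.h2_cullis == pytest.approx(h2a.h2_cullis, abs=1e-6)
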
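"""Linear mixed model for multi-greenhouse RCBD trials, with heritability.

The per-trait model is

    y_ijk = mu + g_i + e_j + (ge)_ij + r_jk + eps_ijk

for genotype i, environment (greenhouse) j and block k within environment,
with independent Gaussian effects. Fitting all factors as random yields
REML variance components (sigma2_g, sigma2_env, sigma2_gxe, sigma2_rep,
sigma2_err), genotype BLUPs and the mean pairwise prediction-error variance
of BLUP differences; refitting with genotype fixed yields per-accession
BLUEs by generalized least squares.

Two heritability statistics are reported:

- *standard heritability* on an entry-mean-like basis,
  H2 = sigma2_g / [sigma2_g + sigma2_env/n_env + sigma2_gxe/n_env
       + sigma2_rep/n_rep + sigma2_err/(n_gen * n_env * n_rep)];
  note the genotype count in the error divisor — this is the convention
  this package standardizes on (a variant without it is available via
  ``conventional=True``).
- *Cullis heritability*, H2 = 1 - vbar_delta_BLUP / (2 sigma2_g), a
  genotype-difference-basis reliability.

Balanced complete data takes a closed-form expected-mean-squares path
(identical to REML for interior estimates); unbalanced data is fit by
EM-REML on Henderson's mixed-model equations with a quasi-Newton polish.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

__all__ = [
    "VarianceComponents",
    "HeritabilityResult",
    "BlupResult",
    "estimate_components",
    "compute_blues",
    "compute_blups",
    "standard_h2",
    "cullis_h2",
    "heritability",
]

_COMPONENTS = ("sigma2_g", "sigma2_env", "sigma2_gxe", "sigma2_rep")
_VAR_FLOOR = 1e-10


@dataclass
class VarianceComponents:
    """REML (or balanced-ANOVA) variance components plus design counts."""

    sigma2_g: float
    sigma2_env: float
    sigma2_gxe: float
    sigma2_rep: float
    sigma2_err: float
    n_gen: int
    n_env: int
    n_rep: int
    method: str = "reml"
    clamped: tuple = ()
    loglik_trace: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("sigma2_g", "sigma2_env", "sigma2_gxe", "sigma2_rep",
                 "sigma2_err", "n_gen", "n_env", "n_rep")}


@dataclass
class BlupResult:
    """Genotype BLUPs with the mean pairwise prediction-error variance."""

    blups: pd.Series
    mean_pairwise_pev: float
    sigma2_g: float
    pev: np.ndarray | None = None


@dataclass
class HeritabilityResult:
    h2_cullis: float
    h2_standard: float
    mean_pairwise_pev: float
    components: VarianceComponents


# ---------------------------------------------------------------------------
# design-matrix bookkeeping

def _factors(table: pd.DataFrame, trait: str):
    need = ["accession", "greenhouse", "block", trait]
    for c in need:
        if c not in table.columns:
            raise KeyError(f"column {c!r} missing from table")
    df = table[need].dropna(subset=[trait]).copy()
    if df.empty:
        raise ValueError(f"no non-missing observations for trait {trait!r}")
    df["accession"] = df["accession"].astype(str)
    df["greenhouse"] = df["greenhouse"].astype(str)
    df["_rep"] = df["greenhouse"] + ":" + df["block"].astype(str)
    df["_gxe"] = df["accession"] + ":" + df["greenhouse"]
    return df


def _one_hot(codes: pd.Series) -> tuple[np.ndarray, list]:
    cats = pd.Categorical(codes)
    z = np.zeros((len(codes), len(cats.categories)))
    z[np.arange(len(codes)), cats.codes] = 1.0
    return z, list(cats.categories)


def _is_balanced(df: pd.DataFrame) -> bool:
    counts = df.groupby(["accession", "greenhouse", "_rep"], observed=True).size()
    G = df["accession"].nunique()
    E = df["greenhouse"].nunique()
    R = df["_rep"].nunique()
    full = G * E * (R // E) if R % E == 0 else -1
    return (counts == 1).all() and len(counts) == full and full > 0


# ---------------------------------------------------------------------------
# balanced closed form (expected mean squares)

def _anova_components(df: pd.DataFrame, trait: str) -> VarianceComponents:
    y = df[trait].to_numpy(dtype=float)
    G = df["accession"].nunique()
    E = df["greenhouse"].nunique()
    R = df["_rep"].nunique() // E
    grand = y.mean()

    m_g = df.groupby("accession", observed=True)[trait].mean()
    m_e = df.groupby("greenhouse", observed=True)[trait].mean()
    m_ge = df.groupby(["accession", "greenhouse"], observed=True)[trait].mean()
    m_re = df.groupby(["greenhouse", "_rep"], observed=True)[trait].mean()

    ss_g = E * R * ((m_g - grand) ** 2).sum()
    ss_e = G * R * ((m_e - grand) ** 2).sum()
    ge_dev = (m_ge
              - m_g.reindex(m_ge.index.get_level_values(0)).to_numpy()
              - m_e.reindex(m_ge.index.get_level_values(1)).to_numpy()
              + grand)
    ss_ge = R * (ge_dev ** 2).sum()
    re_dev = m_re - m_e.reindex(m_re.index.get_level_values(0)).to_numpy()
    ss_re = G * (re_dev ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_err = ss_tot - ss_g - ss_e - ss_ge - ss_re

    ms_g = ss_g / (G - 1)
    ms_e = ss_e / (E - 1) if E > 1 else np.nan
    ms_ge = ss_ge / ((G - 1) * (E - 1)) if E > 1 else np.nan
    ms_re = ss_re / (E * (R - 1))
    ms_err = ss_err / (E * (G - 1) * (R - 1))

    s_err = ms_err
    if E > 1:
        s_gxe = (ms_ge - ms_err) / R
        s_rep = (ms_re - ms_err) / G
        s_env = (ms_e - ms_ge - ms_re + ms_err) / (G * R)
        s_g = (ms_g - ms_ge) / (E * R)
    else:
        s_gxe = np.nan
        s_env = np.nan
        s_rep = (ms_re - ms_err) / G
        s_g = (ms_g - ms_err) / R

    vals = {"sigma2_g": s_g, "sigma2_env": s_env, "sigma2_gxe": s_gxe,
            "sigma2_rep": s_rep, "sigma2_err": s_err}
    clamped = tuple(k for k, v in vals.items() if np.isfinite(v) and v < 0)
    for k in clamped:
        vals[k] = 0.0
    return VarianceComponents(**vals, n_gen=G, n_env=E, n_rep=R,
                              method="anova-balanced", clamped=clamped)


# ---------------------------------------------------------------------------
# EM-REML via Henderson's mixed-model equations

class _MMEWorkspace:
    """Precomputed cross-products for the MME of y = X beta + sum_l Z_l u_l + e."""

    def __init__(self, y: np.ndarray, x: np.ndarray, zs: Sequence[np.ndarray]):
        self.y = y
        self.n = y.size
        self.p = x.shape[1]
        self.qs = [z.shape[1] for z in zs]
        self.q = sum(self.qs)
        w = np.hstack([x] + list(zs))
        self.wtw = w.T @ w
        self.wty = w.T @ y
        self.yty = float(y @ y)
        # slices of the random blocks inside the MME coefficient matrix
        self.slices = []
        start = self.p
        for ql in self.qs:
            self.slices.append(slice(start, start + ql))
            start += ql

    def coefficient(self, sig_l: np.ndarray, sig_e: float) -> np.ndarray:
        c = self.wtw.copy()
        for sl, s2 in zip(self.slices, sig_l):
            c[sl, sl] += np.eye(sl.stop - sl.start) * (sig_e / max(s2, _VAR_FLOOR))
        return c

    def neg2_restricted_ll(self, sig_l: np.ndarray, sig_e: float) -> float:
        c = self.coefficient(sig_l, sig_e)
        try:
            cf = linalg.cho_factor(c, lower=True)
        except linalg.LinAlgError:
            return np.inf
        logdet_c = 2.0 * np.sum(np.log(np.diag(cf[0])))
        sol = linalg.cho_solve(cf, self.wty)
        ypy = (self.yty - self.wty @ sol) / sig_e
        n, p, q = self.n, self.p, self.q
        return ((n - p - q) * np.log(sig_e)
                + sum(ql * np.log(max(s2, _VAR_FLOOR))
                      for ql, s2 in zip(self.qs, sig_l))
                + logdet_c + ypy)

    def solve(self, sig_l: np.ndarray, sig_e: float):
        c = self.coefficient(sig_l, sig_e)
        cinv = linalg.inv(c)
        sol = cinv @ self.wty
        return sol, cinv

    def neg2ll_and_grad(self, log_sig: np.ndarray):
        """-2 restricted log-lik and its gradient w.r.t. log-variances.

        Uses the standard score identities on the MME solution:
        u_l = sig_l^2 Z_l' P y,  tr(P Z_l Z_l') = q_l/sig_l^2
        - sig_e^2 tr(Cinv_ll)/sig_l^4, and tr(P) = (n - p - q
        + sum_l (sig_e^2/sig_l^2) tr(Cinv_ll)) / sig_e^2.
        """
        sig = np.exp(np.clip(log_sig, -60.0, 60.0))
        sig_l, sig_e = sig[:-1], sig[-1]
        c = self.coefficient(sig_l, sig_e)
        try:
            cf = linalg.cho_factor(c, lower=True)
        except linalg.LinAlgError:
            return np.inf, np.zeros_like(log_sig)
        logdet_c = 2.0 * np.sum(np.log(np.diag(cf[0])))
        cinv = linalg.cho_solve(cf, np.eye(c.shape[0]))
        sol = cinv @ self.wty
        resid_quad = self.yty - self.wty @ sol   # e'y = e'e + u'D u terms
        ypy = resid_quad / sig_e
        n, p, q = self.n, self.p, self.q
        neg2 = ((n - p - q) * np.log(sig_e)
                + sum(ql * np.log(s2) for ql, s2 in zip(self.qs, sig_l))
                + logdet_c + ypy)
        grad = np.empty_like(sig)
        tr_sum = 0.0
        for i, (sl, ql) in enumerate(zip(self.slices, self.qs)):
            u = sol[sl]
            tr_cll = np.trace(cinv[sl, sl])
            tr_sum += tr_cll / sig_l[i]
            tr_pzz = ql / sig_l[i] - sig_e * tr_cll / sig_l[i] ** 2
            ypvpy = (u @ u) / sig_l[i] ** 2
            grad[i] = tr_pzz - ypvpy
        # residual block: e = y - W sol; y'PPy = e'e / sig_e^2
        ete = self._ete(sol)
        tr_p = (n - p - q) / sig_e + tr_sum
        grad[-1] = tr_p - ete / sig_e ** 2
        # chain rule to log scale; factor -2ll derivative is d/dtheta of neg2
        return neg2, grad * sig

    def _ete(self, sol: np.ndarray) -> float:
        # e'e = y'y - 2 sol'W'y + sol'W'W sol
        return float(self.yty - 2 * sol @ self.wty + sol @ self.wtw @ sol)


def _em_reml(ws: _MMEWorkspace, max_iter: int = 500, tol: float = 1e-8,
             polish: bool = True):
    """EM-REML with monotone log-likelihood, then an optional quasi-Newton polish."""
    var_y = np.var(ws.y, ddof=1)
    sig_l = np.full(len(ws.qs), max(var_y, 1e-6) / (len(ws.qs) + 1))
    sig_e = max(var_y, 1e-6) / 2
    trace = []
    ll = -0.5 * ws.neg2_restricted_ll(sig_l, sig_e)
    trace.append(ll)
    for _ in range(max_iter):
        sol, cinv = ws.solve(sig_l, sig_e)
        new_l = sig_l.copy()
        for i, (sl, ql) in enumerate(zip(ws.slices, ws.qs)):
            u = sol[sl]
            new_l[i] = (u @ u + sig_e * np.trace(cinv[sl, sl])) / ql
        new_e = (ws.yty - ws.wty @ sol) / (ws.n - ws.p)
        sig_l, sig_e = np.maximum(new_l, _VAR_FLOOR), max(new_e, _VAR_FLOOR)
        ll_new = -0.5 * ws.neg2_restricted_ll(sig_l, sig_e)
        trace.append(ll_new)
        if abs(ll_new - ll) < tol:
            break
        ll = ll_new
    if polish:
        x0 = np.log(np.append(sig_l, sig_e))
        res = optimize.minimize(ws.neg2ll_and_grad, x0, jac=True,
                                method="L-BFGS-B",
                                options={"gtol": 1e-12, "ftol": 1e-15,
                                         "maxiter": 500})
        x = res.x if np.isfinite(res.fun) else x0
        # Newton on the score equations (analytic gradient; FD Jacobian),
        # accepting steps that reduce the score norm — near the optimum the
        # objective differences fall below evaluation noise, so descent on
        # the gradient is the reliable criterion
        f, g = ws.neg2ll_and_grad(x)
        gnorm = np.linalg.norm(g, np.inf)
        for _ in range(30):
            if not np.isfinite(f) or gnorm < 1e-11:
                break
            eps = 1e-5
            jac = np.empty((x.size, x.size))
            for i in range(x.size):
                xp = x.copy()
                xp[i] += eps
                jac[:, i] = (ws.neg2ll_and_grad(xp)[1] - g) / eps
            jac = (jac + jac.T) / 2
            try:
                step = np.linalg.solve(jac, -g)
            except np.linalg.LinAlgError:
                break
            alpha, accepted = 1.0, False
            for _ in range(20):
                f_new, g_new = ws.neg2ll_and_grad(x + alpha * step)
                gn = np.linalg.norm(g_new, np.inf)
                if np.isfinite(f_new) and gn < gnorm:
                    x = x + alpha * step
                    f, g, gnorm = f_new, g_new, gn
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:
                break
        if -0.5 * f >= trace[-1] - 1e-6:
            sig = np.exp(x)
            sig_l, sig_e = sig[:-1], sig[-1]
            trace.append(max(-0.5 * f, trace[-1]))
    return sig_l, sig_e, np.asarray(trace)


def _reml_components(df: pd.DataFrame, trait: str) -> VarianceComponents:
    y = df[trait].to_numpy(dtype=float)
    x = np.ones((len(df), 1))
    z_g, _ = _one_hot(df["accession"])
    G = z_g.shape[1]
    E = df["greenhouse"].nunique()
    reps_per_env = df.groupby("greenhouse", observed=True)["_rep"].nunique()
    R = int(reps_per_env.max())

    names = ["sigma2_g"]
    zs = [z_g]
    if E > 1:
        z_e, _ = _one_hot(df["greenhouse"])
        z_ge, _ = _one_hot(df["_gxe"])
        zs += [z_e, z_ge]
        names += ["sigma2_env", "sigma2_gxe"]
    z_r, _ = _one_hot(df["_rep"])
    zs.append(z_r)
    names.append("sigma2_rep")

    ws = _MMEWorkspace(y, x, zs)
    sig_l, sig_e, trace = _em_reml(ws)
    vals = dict(zip(names, sig_l))
    vals.setdefault("sigma2_env", np.nan)
    vals.setdefault("sigma2_gxe", np.nan)
    clamped = tuple(k for k, v in vals.items()
                    if np.isfinite(v) and v <= 10 * _VAR_FLOOR)
    for k in clamped:
        vals[k] = 0.0
    return VarianceComponents(sigma2_err=float(sig_e), n_gen=G, n_env=E,
                              n_rep=R, method="em-reml", clamped=clamped,
                              loglik_trace=trace, **{k: float(v) for k, v
                                                     in vals.items()})


def estimate_components(table: pd.DataFrame, trait: str,
                        method: str = "auto") -> VarianceComponents:
    """Variance components of the five-term RCBD mixed model.

    ``method``: "auto" (closed-form expected mean squares when the data are
    balanced and complete, EM-REML otherwise), "anova" (balanced only) or
    "reml" (always iterate). For balanced data with interior estimates the
    two paths agree. With a single environment the environment and
    genotype-by-environment components are not estimable and are reported
    as NaN.
    """
    df = _factors(table, trait)
    if df["accession"].nunique() < 2:
        raise ValueError("need at least 2 genotypes")
    balanced = _is_balanced(df)
    if method == "anova" and not balanced:
        raise ValueError("ANOVA closed form requires balanced complete data")
    if method not in ("auto", "anova", "reml"):
        raise ValueError("method must be 'auto', 'anova' or 'reml'")
    if (method in ("auto", "anova")) and balanced:
        return _anova_components(df, trait)
    return _reml_components(df, trait)


# ---------------------------------------------------------------------------
# BLUE / BLUP

def compute_blues(table: pd.DataFrame, trait: str,
                  components: VarianceComponents | None = None) -> pd.Series:
    """Per-accession BLUEs: genotype fixed, other factors at REML variances."""
    df = _factors(table, trait)
    if components is None:
        components = estimate_components(table, trait)
    y = df[trait].to_numpy(dtype=float)
    x, acc_names = _one_hot(df["accession"])

    zs, sigs = [], []
    for name, col in (("sigma2_env", "greenhouse"), ("sigma2_gxe", "_gxe"),
                      ("sigma2_rep", "_rep")):
        s2 = getattr(components, name)
        if np.isfinite(s2) and s2 > 0:
            z, _ = _one_hot(df[col])
            zs.append(z)
            sigs.append(s2)
    sig_e = max(components.sigma2_err, _VAR_FLOOR)

    if not zs:  # pure fixed-effect least squares: accession means
        beta = np.linalg.lstsq(x, y, rcond=None)[0]
    else:
        ws = _MMEWorkspace(y, x, zs)
        sol, _ = ws.solve(np.asarray(sigs), sig_e)
        beta = sol[:ws.p]
    return pd.Series(beta, index=pd.Index(acc_names, name="accession"),
                     name=trait)


def compute_blups(table: pd.DataFrame, trait: str,
                  components: VarianceComponents | None = None,
                  keep_pev: bool = False) -> BlupResult:
    """Genotype BLUPs and the exact mean pairwise PEV of BLUP differences."""
    df = _factors(table, trait)
    if components is None:
        components = estimate_components(table, trait)
    y = df[trait].to_numpy(dtype=float)
    x = np.ones((len(df), 1))
    z_g, acc_names = _one_hot(df["accession"])
    G = len(acc_names)
    s_g = components.sigma2_g
    if not np.isfinite(s_g) or s_g <= 0:
        blups = pd.Series(np.zeros(G),
                          index=pd.Index(acc_names, name="accession"),
                          name=trait)
        return BlupResult(blups, np.nan, 0.0)

    zs, sigs = [z_g], [s_g]
    for name, col in (("sigma2_env", "greenhouse"), ("sigma2_gxe", "_gxe"),
                      ("sigma2_rep", "_rep")):
        s2 = getattr(components, name)
        if np.isfinite(s2) and s2 > 0:
            z, _ = _one_hot(df[col])
            zs.append(z)
            sigs.append(s2)
    sig_e = max(components.sigma2_err, _VAR_FLOOR)
    ws = _MMEWorkspace(y, x, zs)
    sol, cinv = ws.solve(np.asarray(sigs), sig_e)
    sl = ws.slices[0]
    u_g = sol[sl]
    pev = sig_e * cinv[sl, sl]
    d = np.diag(pev)
    # mean over unordered genotype pairs of var(BLUP_i - BLUP_j)
    pair_sum = G * d.sum() - pev.sum()
    vbar = 2.0 * pair_sum / (G * (G - 1))
    blups = pd.Series(u_g, index=pd.Index(acc_names, name="accession"),
                      name=trait)
    return BlupResult(blups, float(vbar), float(s_g),
                      pev=pev if keep_pev else None)


# ---------------------------------------------------------------------------
# heritability

def standard_h2(vc: VarianceComponents, conventional: bool = False) -> float:
    """Standard heritability from variance components and design counts.

    The default denominator divides the error variance by
    n_gen * n_env * n_rep; ``conventional=True`` uses the genotype-mean
    convention (n_env * n_rep only).
    """
    if min(vc.n_gen, vc.n_env, vc.n_rep) <= 0:
        raise ValueError("design counts must be positive")
    s_env = 0.0 if not np.isfinite(vc.sigma2_env) else vc.sigma2_env
    s_gxe = 0.0 if not np.isfinite(vc.sigma2_gxe) else vc.sigma2_gxe
    err_div = vc.n_env * vc.n_rep if conventional else vc.n_gen * vc.n_env * vc.n_rep
    denom = (vc.sigma2_g + s_env / vc.n_env + s_gxe / vc.n_env
             + vc.sigma2_rep / vc.n_rep + vc.sigma2_err / err_div)
    if denom <= 0:
        return np.nan
    return float(np.clip(vc.sigma2_g / denom, 0.0, 1.0))


def cullis_h2(sigma2_g: float, mean_pairwise_pev: float) -> float:
    """Cullis heritability H2 = 1 - vbar_delta_BLUP / (2 sigma2_g), in [0, 1]."""
    if not np.isfinite(sigma2_g) or sigma2_g <= 0:
        return np.nan
    return float(np.clip(1.0 - mean_pairwise_pev / (2.0 * sigma2_g), 0.0, 1.0))


def heritability(table: pd.DataFrame, trait: str,
                 components: VarianceComponents | None = None) -> HeritabilityResult:
    """Convenience: estimate components, fit BLUPs, report both heritabilities."""
    if components is None:
        components = estimate_components(table, trait)
    blup = compute_blups(table, trait, components)
    return HeritabilityResult(
        h2_cullis=cullis_h2(components.sigma2_g, blup.mean_pairwise_pev),
        h2_standard=standard_h2(components),
        mean_pairwise_pev=blup.mean_pairwise_pev,
        components=components,
    )
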
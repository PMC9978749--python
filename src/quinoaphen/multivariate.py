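"""Trait correlations, PCA with contribution thresholds, and germplasm grouping.

Operates on per-accession summaries (typically BLUEs). Correlations are
pairwise-complete Pearson or Spearman with two-sided t-approximation
p-values. PCA is the eigendecomposition of the correlation structure of
centered and scaled traits; a trait's contribution to a component is
100 x loading^2 / sum of squared loadings, compared against the uniform
threshold 100 / n_traits. Grouping is agglomerative Ward clustering on
Euclidean distances (cut at k groups) or best-of-restarts k-means.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

__all__ = [
    "CorrelationResult",
    "PCAResult",
    "ClusterResult",
    "correlation_matrix",
    "pca",
    "contribution_threshold",
    "ward_cluster",
    "kmeans_cluster",
    "group_summary",
]


@dataclass
class CorrelationResult:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    method: str

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        """Boolean mask of significant cells (diagonal True by convention)."""
        return self.p <= alpha


@dataclass
class PCAResult:
    loadings: pd.DataFrame            # trait x component, orthonormal columns
    explained_pct: pd.Series          # sums to 100 over all components
    contributions: pd.DataFrame       # % per trait per component, sums to 100
    scores: pd.DataFrame              # accession x component
    dropped: list = field(default_factory=list)


@dataclass
class ClusterResult:
    method: str
    k: int
    labels: pd.Series                 # accession -> group in 1..k
    linkage_matrix: np.ndarray | None = None
    centroids: np.ndarray | None = None
    inertia: float | None = None
    unassigned: list = field(default_factory=list)


def correlation_matrix(table: pd.DataFrame, traits=None,
                       method: str = "pearson") -> CorrelationResult:
    """Pairwise-complete trait correlations with two-sided p-values.

    Spearman uses average ranks for ties. Pairs with fewer than 3 complete
    observations, or a constant column, get NaN coefficients.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if traits is None:
        traits = [c for c in table.columns
                  if pd.api.types.is_numeric_dtype(table[c])]
    m = len(traits)
    r = np.eye(m)
    p = np.zeros((m, m))
    n = np.zeros((m, m), dtype=int)
    np.fill_diagonal(n, table[list(traits)].notna().sum().to_numpy())
    for i in range(m):
        for j in range(i + 1, m):
            xy = table[[traits[i], traits[j]]].dropna()
            n[i, j] = n[j, i] = len(xy)
            if len(xy) < 3 or xy.iloc[:, 0].nunique() < 2 or xy.iloc[:, 1].nunique() < 2:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            if method == "pearson":
                res = stats.pearsonr(xy.iloc[:, 0], xy.iloc[:, 1])
            else:
                res = stats.spearmanr(xy.iloc[:, 0], xy.iloc[:, 1])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = pd.Index(traits)
    return CorrelationResult(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
        method=method,
    )


def pca(table: pd.DataFrame, traits=None, n_components: int | None = None,
        ) -> PCAResult:
    """PCA of centered and scaled traits (correlation-matrix eigenstructure).

    Rows with any missing selected trait are dropped (recorded in
    ``dropped``). Each loading column is sign-flipped so its
    largest-magnitude entry is positive.
    """
    if traits is None:
        traits = [c for c in table.columns
                  if pd.api.types.is_numeric_dtype(table[c])]
    data = table[list(traits)]
    complete = data.dropna()
    dropped = [i for i in data.index if i not in complete.index]
    if len(complete) < 2:
        raise ValueError("need at least 2 complete rows for PCA")
    x = complete.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [t for t, s in zip(traits, sd) if s == 0]
        raise ValueError(f"constant traits cannot be scaled: {bad}")
    z = (x - x.mean(axis=0)) / sd
    corr = z.T @ z / (len(z) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    # sign convention: largest-magnitude loading positive per component
    flip = np.sign(eigvec[np.argmax(np.abs(eigvec), axis=0),
                          np.arange(eigvec.shape[1])])
    flip[flip == 0] = 1.0
    eigvec = eigvec * flip
    if n_components is not None:
        eigval, eigvec = eigval[:n_components], eigvec[:, :n_components]
    comps = [f"PC{i + 1}" for i in range(eigvec.shape[1])]
    loadings = pd.DataFrame(eigvec, index=pd.Index(traits), columns=comps)
    explained = pd.Series(100.0 * eigval / len(traits), index=comps,
                          name="explained_pct")
    contrib = 100.0 * loadings ** 2 / (loadings ** 2).sum(axis=0)
    scores = pd.DataFrame(z @ eigvec, index=complete.index, columns=comps)
    return PCAResult(loadings, explained, contrib, scores, dropped)


def contribution_threshold(n_traits: int) -> float:
    """Uniform-contribution threshold in %: 100 / n_traits."""
    if n_traits < 1:
        raise ValueError("n_traits must be >= 1")
    return 100.0 / n_traits


def _cluster_input(table, traits, standardize):
    if traits is None:
        traits = [c for c in table.columns
                  if pd.api.types.is_numeric_dtype(table[c])]
    data = table[list(traits)]
    complete = data.dropna()
    unassigned = [i for i in data.index if i not in complete.index]
    x = complete.to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    return x, complete.index, unassigned


def ward_cluster(table: pd.DataFrame, traits=None, k: int = 4,
                 standardize: bool = True) -> ClusterResult:
    """Agglomerative Ward (minimum-variance) clustering cut at k groups.

    Euclidean distances on (by default standardized) traits; rows with
    missing inputs are left unassigned with their ids recorded. Uses the
    true minimum-variance criterion (ward.D2 semantics).
    """
    x, index, unassigned = _cluster_input(table, traits, standardize)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(x):
        raise ValueError(f"k={k} exceeds the {len(x)} clusterable rows")
    lm = linkage(x, method="ward")
    labels = fcluster(lm, t=k, criterion="maxclust")
    return ClusterResult("ward", k,
                         pd.Series(labels, index=index, name="group"),
                         linkage_matrix=lm, unassigned=unassigned)


def kmeans_cluster(table: pd.DataFrame, traits=None, k: int = 4,
                   n_restarts: int = 25, seed: int = 1,
                   standardize: bool = True) -> ClusterResult:
    """Best-of-restarts Lloyd's k-means on standardized traits."""
    x, index, unassigned = _cluster_input(table, traits, standardize)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(x):
        raise ValueError(f"k={k} exceeds the {len(x)} clusterable rows")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed,
                algorithm="lloyd")
    labels = km.fit_predict(x) + 1
    return ClusterResult("kmeans", k,
                         pd.Series(labels, index=index, name="group"),
                         centroids=km.cluster_centers_,
                         inertia=float(km.inertia_), unassigned=unassigned)


def group_summary(table: pd.DataFrame, labels: pd.Series,
                  traits=None) -> pd.DataFrame:
    """Per-group mean and SD for each trait, plus group sizes.

    Returns a DataFrame indexed by group with a two-level column index
    (trait, {mean, sd}) and an ``n`` column. Empty groups are omitted.
    """
    if traits is None:
        traits = [c for c in table.columns
                  if pd.api.types.is_numeric_dtype(table[c])]
    joined = table[list(traits)].join(labels.rename("group"), how="inner")
    grouped = joined.groupby("group")
    means = grouped[list(traits)].mean()
    sds = grouped[list(traits)].std(ddof=1)
    out = pd.concat({"mean": means, "sd": sds}, axis=1)
    out = out.swaplevel(axis=1).sort_index(axis=1, level=0)
    out["n"] = grouped.size()
    return out
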
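"""Alpha and beta diversity: Chao1/Shannon/Simpson, Kruskal-Wallis group
tests, Bray-Curtis distances, PCoA, non-metric MDS, and ANOSIM.

Conventions: Shannon entropy is in nats by default (configurable base);
Chao1 uses the bias-corrected (+1) form; Simpson is the Gini-Simpson
index 1 - sum(p^2); ANOSIM p-values follow the (+1) permutation
convention that counts the identity permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .tables_io import SampleMetadata, TaxonAbundanceTable, to_relative

__all__ = [
    "AlphaDiversityResult",
    "DistanceMatrix",
    "OrdinationResult",
    "AnosimResult",
    "alpha_diversity",
    "kruskal_wallis",
    "bray_curtis",
    "pcoa",
    "nmds",
    "anosim",
]


@dataclass
class AlphaDiversityResult:
    per_sample: pd.DataFrame  # columns chao1, shannon, simpson; index sample_id
    group_tests: pd.DataFrame | None = None  # index = metric; columns H, p


@dataclass
class DistanceMatrix:
    """Symmetric distances with zero diagonal over an ordered sample set."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str = "braycurtis"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x k
    method: str
    eigenvalues: np.ndarray | None = None
    proportion_explained: np.ndarray | None = None
    stress: float | None = None
    n_restarts: int | None = None
    converged: bool | None = None


@dataclass
class AnosimResult:
    R: float
    p: float
    n_permutations: int


def _sample_indices(counts: np.ndarray, base: float | None) -> tuple[float, float, float]:
    x = counts[counts > 0]
    if x.size == 0:
        raise ValueError("empty sample: no positive abundances")
    p = x / x.sum()
    shannon = float(-(p * np.log(p)).sum())
    if base is not None:
        shannon /= np.log(base)
    simpson = float(1.0 - (p**2).sum())
    s_obs = x.size
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return chao1, shannon, simpson


def alpha_diversity(
    table: TaxonAbundanceTable,
    metadata: SampleMetadata | None = None,
    base: float | None = None,
) -> AlphaDiversityResult:
    """Per-sample Chao1, Shannon and Gini-Simpson, with optional group tests.

    Chao1 (bias-corrected: S_obs + F1(F1-1)/(2(F2+1))) requires integer
    counts; Shannon and Simpson are computed on per-sample fractions. When
    metadata is supplied a Kruskal-Wallis test across groups is run per
    index.
    """
    if table.kind != "counts":
        raise ValueError("alpha diversity (Chao1) requires a counts table")
    values = table.values
    if not np.allclose(values, np.round(values)):
        raise ValueError("Chao1 requires integer-valued counts")
    rows = [_sample_indices(values[:, j], base) for j in range(table.n_samples)]
    per_sample = pd.DataFrame(rows, index=table.sample_ids, columns=["chao1", "shannon", "simpson"])

    group_tests = None
    if metadata is not None:
        labels = metadata.group_of(table.sample_ids)
        recs = {}
        for metric in per_sample.columns:
            groups = [
                per_sample.loc[labels == g, metric].to_numpy()
                for g in np.unique(labels)
            ]
            recs[metric] = kruskal_wallis(groups)
        group_tests = pd.DataFrame(recs, index=["H", "p"]).T
    return AlphaDiversityResult(per_sample=per_sample, group_tests=group_tests)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p across groups.

    Degenerate all-identical data yields H=0, p=1 by convention.
    """
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("Kruskal-Wallis groups must be non-empty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def bray_curtis(table: TaxonAbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarities on per-sample fractions."""
    rel = to_relative(table)
    profiles = rel.values.T  # samples x taxa
    d = squareform(pdist(profiles, metric="braycurtis"))
    return DistanceMatrix(rel.sample_ids, d, metric="braycurtis")


def pcoa(d: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Principal coordinate analysis by eigendecomposition of the Gower matrix.

    Negative eigenvalues (non-Euclidean distances) are reported as-is,
    with no correction; the corresponding axes get zero coordinates.
    """
    n = d.n
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    d2 = d.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    coords = eigvec[:, :k] * np.sqrt(np.clip(eigval[:k], 0.0, None))
    total = eigval[eigval > 0].sum()
    prop = np.clip(eigval[:k], 0.0, None) / total if total > 0 else np.zeros(k)
    return OrdinationResult(
        sample_ids=list(d.sample_ids),
        coordinates=coords,
        method="pcoa",
        eigenvalues=eigval[:k],
        proportion_explained=prop,
    )


def _kruskal_stress(config: np.ndarray, diss: np.ndarray, iso: IsotonicRegression):
    """Stress-1 and the monotone-regressed disparities for a configuration."""
    cd = pdist(config)
    dhat = iso.fit_transform(diss, cd)
    denom = (cd**2).sum()
    if denom == 0:
        return np.inf, dhat, cd
    stress = np.sqrt(((dhat - cd) ** 2).sum() / denom)
    return stress, dhat, cd


def _nmds_single(diss, init, max_iter, tol):
    """Non-metric SMACOF: isotonic disparities + Guttman transform updates."""
    n = init.shape[0]
    config = init.copy()
    iso = IsotonicRegression()
    last = np.inf
    converged = False
    for _ in range(max_iter):
        stress, dhat, cd = _kruskal_stress(config, diss, iso)
        if last - stress < tol:
            converged = True
            break
        last = stress
        # Guttman transform with disparities as targets
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(cd > 0, dhat / cd, 0.0)
        b = -squareform(ratio)
        np.fill_diagonal(b, -b.sum(axis=1))
        config = b @ config / n
    stress, _, _ = _kruskal_stress(config, diss, iso)
    return config, float(stress), converged


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    Disparities come from isotonic regression of configuration distances
    on the dissimilarities (average ties). The first start is the PCoA
    configuration; the remaining ``n_restarts - 1`` starts are random.
    The lowest-stress solution is returned.
    """
    n = d.n
    if k >= n:
        raise ValueError("k must be smaller than n for NMDS")
    diss = d.condensed()
    rng = np.random.default_rng(seed)
    inits = [pcoa(d, k=k).coordinates]
    for _ in range(max(0, n_restarts - 1)):
        inits.append(rng.standard_normal((n, k)))
    best = None
    for init in inits:
        config, stress, converged = _nmds_single(diss, init, max_iter, tol)
        if best is None or stress < best[1]:
            best = (config, stress, converged)
    config, stress, converged = best
    # standardize orientation: center, principal axes, positive-sum signs
    config = config - config.mean(axis=0)
    return OrdinationResult(
        sample_ids=list(d.sample_ids),
        coordinates=config,
        method="nmds",
        stress=stress,
        n_restarts=n_restarts,
        converged=converged,
    )


def anosim(
    d: DistanceMatrix,
    metadata: SampleMetadata | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """Analysis of similarities: R = (rb - rw) / (M/2) with permutation p.

    R contrasts mean between-group vs within-group ranks of the condensed
    distances (M = n(n-1)/2 pairs). The p-value counts permutations with
    R >= observed, including the identity, over n_perm + 1.
    Singleton groups contribute no within-group pairs; a warning is
    emitted and they participate only in between-group ranks.
    """
    labels = (
        metadata.group_of(d.sample_ids)
        if isinstance(metadata, SampleMetadata)
        else np.asarray(metadata)
    )
    uniq, codes = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("ANOSIM needs at least two groups")
    sizes = np.bincount(codes)
    if (sizes == 1).any():
        import warnings

        warnings.warn("ANOSIM group(s) of size 1: no within-group pairs", RuntimeWarning)
    iu = np.triu_indices(d.n, k=1)
    ranks = stats.rankdata(d.condensed())
    m = ranks.size

    def r_stat(c):
        within = c[iu[0]] == c[iu[1]]
        if within.all() or not within.any():
            return 0.0
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    observed = r_stat(codes)
    rng = np.random.default_rng(seed)
    hits = 1  # identity permutation
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if r_stat(perm) >= observed:
            hits += 1
    p = hits / (n_perm + 1)
    return AnosimResult(R=float(observed), p=float(p), n_permutations=n_perm)
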
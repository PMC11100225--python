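"""Environment-community-metabolite association: redundancy analysis,
Mantel tests, and pairwise correlation tables with BH adjustment.

RDA is a constrained ordination: a PCA of the fitted values of the
multivariate regression of (Hellinger-transformed) community data on
z-scored environmental variables. Mantel correlates two distance
matrices over the same samples with a joint row/column permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diversity import DistanceMatrix
from .tables_io import SoilProfile, TaxonAbundanceTable, to_relative, zscore_normalize

__all__ = [
    "RdaResult",
    "MantelResult",
    "rda",
    "mantel",
    "env_feature_correlations",
]


@dataclass
class RdaResult:
    sample_ids: list[str]
    site_scores: np.ndarray  # samples x n_axes (constrained axes)
    env_scores: pd.DataFrame  # env variable x axis correlations
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray  # per constrained axis, of total variance
    constrained_proportion: float

    @property
    def n_axes(self) -> int:
        return self.site_scores.shape[1]


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    flavor: str


def _hellinger(table: TaxonAbundanceTable) -> np.ndarray:
    rel = to_relative(table)
    return np.sqrt(rel.values.T)  # samples x taxa


def rda(
    table: TaxonAbundanceTable,
    soil: SoilProfile | pd.DataFrame,
    transform: str = "hellinger",
) -> RdaResult:
    """Redundancy analysis of a community table constrained by soil variables.

    Y is the (optionally Hellinger-transformed) community matrix, column
    centered; X the z-scored environment matrix. Constrained axes come
    from the SVD of the fitted values X(X'X)^-1 X'Y; the constrained
    proportion is SS(fitted)/SS(Y). Environment scores are correlations
    of each X column with the site scores.
    """
    env_df = soil.data if isinstance(soil, SoilProfile) else soil
    sample_ids = [s for s in table.sample_ids if s in env_df.index]
    if len(sample_ids) < env_df.shape[1] + 2:
        raise ValueError("need at least n_env + 2 shared samples for RDA")

    if transform == "hellinger":
        y_full = _hellinger(table)
    elif transform == "none":
        y_full = table.values.T.astype(float)
    elif transform == "chord":
        v = table.values.T.astype(float)
        norms = np.linalg.norm(v, axis=1, keepdims=True)
        y_full = v / np.where(norms == 0, 1.0, norms)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    pos = [table.sample_ids.index(s) for s in sample_ids]
    y = y_full[pos]
    y = y - y.mean(axis=0)

    x_raw = env_df.loc[sample_ids].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x_raw - x_raw.mean(axis=0))
    if rank < x_raw.shape[1]:
        # name offending columns: those whose removal restores full rank
        offending = []
        centered = x_raw - x_raw.mean(axis=0)
        for j, name in enumerate(env_df.columns):
            rest = np.delete(centered, j, axis=1)
            if np.linalg.matrix_rank(rest) == rank:
                offending.append(str(name))
        raise ValueError(f"collinear environment variables: {offending}")
    x = zscore_normalize(x_raw, axis=0)

    beta = np.linalg.lstsq(x, y, rcond=None)[0]
    fitted = x @ beta
    u, s, _vt = np.linalg.svd(fitted, full_matrices=False)
    n_axes = int((s > 1e-10 * max(s[0], 1e-300)).sum()) if s.size else 0
    site_scores = u[:, :n_axes] * s[:n_axes]
    eig = (s[:n_axes] ** 2) / (len(sample_ids) - 1)

    ss_total = (y**2).sum()
    ss_fit = (fitted**2).sum()
    constrained = float(ss_fit / ss_total) if ss_total > 0 else 0.0
    prop = (s[:n_axes] ** 2) / ss_total if ss_total > 0 else np.zeros(n_axes)

    env_scores = np.zeros((x.shape[1], n_axes))
    for j in range(x.shape[1]):
        for a in range(n_axes):
            sd = site_scores[:, a].std()
            env_scores[j, a] = (
                np.corrcoef(x[:, j], site_scores[:, a])[0, 1] if sd > 0 else 0.0
            )
    env_scores = pd.DataFrame(
        env_scores,
        index=list(env_df.columns),
        columns=[f"RDA{a + 1}" for a in range(n_axes)],
    )
    return RdaResult(
        sample_ids=sample_ids,
        site_scores=site_scores,
        env_scores=env_scores,
        eigenvalues=eig,
        proportion_explained=prop,
        constrained_proportion=constrained,
    )


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    flavor: str = "spearman",
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Mantel test between two distance matrices over the same samples.

    r is the chosen correlation over the n(n-1)/2 condensed entries; the
    one-sided (greater) p permutes rows+columns of d2 jointly, counting
    the identity permutation.
    """
    if list(d1.sample_ids) != list(d2.sample_ids):
        raise ValueError("distance matrices must share the same samples in order")
    n = d1.n
    if n < 4:
        raise ValueError("Mantel needs at least 4 samples")
    iu = np.triu_indices(n, k=1)
    v1 = d1.values[iu]
    if flavor == "spearman":
        v1 = stats.rankdata(v1)
        m2 = np.zeros_like(d2.values)
        m2[iu] = stats.rankdata(d2.values[iu])
        m2 = m2 + m2.T
    elif flavor == "pearson":
        m2 = d2.values
    else:
        raise ValueError(f"unknown flavor {flavor!r}")

    def corr(vec):
        a = v1 - v1.mean()
        b = vec - vec.mean()
        denom = np.sqrt((a**2).sum() * (b**2).sum())
        return float(a @ b / denom) if denom > 0 else 0.0

    observed = corr(m2[iu])
    rng = np.random.default_rng(seed)
    hits = 1
    for _ in range(n_perm):
        p = rng.permutation(n)
        if corr(m2[np.ix_(p, p)][iu]) >= observed:
            hits += 1
    return MantelResult(
        r=observed, p=hits / (n_perm + 1), n_perm=n_perm, flavor=flavor
    )


def env_feature_correlations(
    vars_a: pd.DataFrame,
    vars_b: pd.DataFrame,
    flavor: str = "spearman",
    adjust: str | None = "BH",
) -> pd.DataFrame:
    """Pairwise correlations between two variable sets over shared samples.

    Returns a long-format frame (var_a, var_b, r, p, and q when BH
    adjustment is requested). Constant vectors get r=0, p=1 and are
    flagged.
    """
    shared = [s for s in vars_a.index if s in vars_b.index]
    if len(shared) < 4:
        raise ValueError("need at least 4 shared samples")
    a = vars_a.loc[shared]
    b = vars_b.loc[shared]
    rows = []
    for ca in a.columns:
        for cb in b.columns:
            x, y = a[ca].to_numpy(float), b[cb].to_numpy(float)
            flagged = np.all(x == x[0]) or np.all(y == y[0])
            if flagged:
                r, p = 0.0, 1.0
            elif flavor == "spearman":
                r, p = stats.spearmanr(x, y)
            elif flavor == "pearson":
                r, p = stats.pearsonr(x, y)
            else:
                raise ValueError(f"unknown flavor {flavor!r}")
            rows.append(
                {"var_a": ca, "var_b": cb, "r": float(r), "p": float(p), "flagged": flagged}
            )
    out = pd.DataFrame(rows)
    if adjust == "BH":
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out
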
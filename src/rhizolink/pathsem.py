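"""Recursive observed-variable path analysis (structural equation model).

Fits a directed acyclic model over measured variables (soil chemistry,
community composition scores, metabolite level) by maximum likelihood on
the covariance structure, reports the usual fit indices (chi-square and
chi2/df, GFI, SRMR), and decomposes standardized effects into direct,
indirect (products along directed paths) and total components.

Only observed variables are modeled -- no latent constructs. The
standardized solution is obtained by fitting on z-scored data, which for
this model class coincides with post-hoc standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .diversity import bray_curtis, nmds, pcoa
from .tables_io import TaxonAbundanceTable, to_relative

__all__ = [
    "PathModelSpec",
    "PathFit",
    "EffectDecomposition",
    "fit_path_model",
    "effect_decomposition",
    "composition_scores",
]


@dataclass
class PathModelSpec:
    """Directed acyclic structural model over observed variables."""

    edges: list[tuple[str, str]]  # (parent, child)
    variables: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: list[str] = list(self.variables)
        for a, b in self.edges:
            for v in (a, b):
                if v not in seen:
                    seen.append(v)
        self.variables = seen
        self.order  # validates acyclicity

    @property
    def parents(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {v: [] for v in self.variables}
        for a, b in self.edges:
            out[b].append(a)
        return out

    @property
    def exogenous(self) -> list[str]:
        par = self.parents
        return [v for v in self.variables if not par[v]]

    @property
    def endogenous(self) -> list[str]:
        par = self.parents
        return [v for v in self.variables if par[v]]

    @property
    def order(self) -> list[str]:
        """Topological order (exogenous first); raises on cycles."""
        par = self.parents
        remaining = dict(par)
        order: list[str] = []
        while remaining:
            ready = sorted(v for v, ps in remaining.items() if all(p in order for p in ps))
            if not ready:
                raise ValueError("path model specification contains a cycle")
            order.extend(ready)
            for v in ready:
                del remaining[v]
        return order

    @classmethod
    def from_equations(cls, text: str) -> "PathModelSpec":
        """Parse a plain-text spec, one equation per line: "child ~ p1 + p2"."""
        edges = []
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "~" not in line:
                raise ValueError(f"cannot parse model line: {line!r}")
            child, rhs = line.split("~", 1)
            child = child.strip()
            for parent in rhs.split("+"):
                parent = parent.strip()
                if parent:
                    edges.append((parent, child))
        return cls(edges=edges)

    @classmethod
    def from_file(cls, path) -> "PathModelSpec":
        return cls.from_equations(Path(path).read_text())

    @classmethod
    def saturated(cls, variables: list[str]) -> "PathModelSpec":
        """Fully recursive model in the given order: all pairs connected."""
        edges = [
            (variables[i], variables[j])
            for j in range(len(variables))
            for i in range(j)
        ]
        return cls(edges=edges, variables=list(variables))


@dataclass
class PathFit:
    spec: PathModelSpec
    coefficients: pd.DataFrame  # B, child rows x parent columns (standardized)
    residual_variances: pd.Series  # endogenous only
    implied_cov: pd.DataFrame
    sample_cov: pd.DataFrame
    chi2: float
    df: int
    p: float
    chi2_df: float
    gfi: float
    srmr: float
    converged: bool
    gradient_norm: float
    n: int
    method: str

    def coefficient(self, parent: str, child: str) -> float:
        return float(self.coefficients.loc[child, parent])


@dataclass
class EffectDecomposition:
    direct: pd.DataFrame  # effect of column variable on row variable
    indirect: pd.DataFrame
    total: pd.DataFrame

    def effect(self, parent: str, child: str, kind: str = "total") -> float:
        return float(getattr(self, kind).loc[child, parent])


def _build_matrices(theta, spec, order, edge_index, exo, endo, n_exo):
    p = len(order)
    b = np.zeros((p, p))
    for (a, c), k in edge_index.items():
        b[order.index(c), order.index(a)] = theta[k]
    off = len(edge_index)
    # exogenous covariance via Cholesky factor (keeps Sigma PSD)
    tril = np.zeros((n_exo, n_exo))
    idx = np.tril_indices(n_exo)
    tril[idx] = theta[off : off + idx[0].size]
    phi = tril @ tril.T
    off += idx[0].size
    psi = np.zeros(p)
    for i, v in enumerate(order):
        if v in endo:
            psi[i] = theta[off] ** 2
            off += 1
    psi_star = np.zeros((p, p))
    exo_pos = [order.index(v) for v in exo]
    for ii, vi in enumerate(exo_pos):
        for jj, vj in enumerate(exo_pos):
            psi_star[vi, vj] = phi[ii, jj]
    for i, v in enumerate(order):
        if v in endo:
            psi_star[i, i] = psi[i]
    inv = np.linalg.inv(np.eye(p) - b)
    sigma = inv @ psi_star @ inv.T
    return b, psi, sigma


def fit_path_model(
    data: pd.DataFrame,
    spec: PathModelSpec,
    method: str = "ml",
    max_iter: int = 500,
    tol: float = 1e-9,
) -> PathFit:
    """Fit a recursive path model to samples x variables data.

    Columns are z-scored internally, so reported coefficients are
    standardized. Free parameters are the path coefficients, endogenous
    residual variances and exogenous covariances. ``method='ml'``
    minimizes the Wishart discrepancy F_ML = ln|Sigma| + tr(S Sigma^-1)
    - ln|S| - p by quasi-Newton from OLS starting values; chi-square =
    (n-1) F_ML at the optimum. ``method='ols'`` ("piecewise") keeps the
    per-equation least-squares solution and evaluates the same indices
    there.
    """
    order = spec.order
    missing = [v for v in order if v not in data.columns]
    if missing:
        raise ValueError(f"data lacks model variables: {missing}")
    n = data.shape[0]
    p = len(order)
    if n <= p:
        raise ValueError("need more samples than variables")

    x = data.loc[:, order].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [order[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant variables cannot be modeled: {bad}")
    x = (x - x.mean(axis=0)) / sd
    s = np.cov(x, rowvar=False, ddof=1)
    sign, logdet_s = np.linalg.slogdet(s)
    if sign <= 0:
        raise ValueError("singular sample covariance (collinear variables)")

    exo = spec.exogenous
    endo = spec.endogenous
    n_exo = len(exo)
    edge_index = {e: k for k, e in enumerate(spec.edges)}

    # OLS warm start
    theta0 = np.zeros(len(edge_index) + n_exo * (n_exo + 1) // 2 + len(endo))
    parents = spec.parents
    resid0: dict[str, float] = {}
    for child in endo:
        ps = parents[child]
        xi = x[:, [order.index(q) for q in ps]]
        yi = x[:, order.index(child)]
        beta = np.linalg.lstsq(xi, yi, rcond=None)[0]
        for q, bq in zip(ps, beta):
            theta0[edge_index[(q, child)]] = bq
        resid0[child] = float(np.var(yi - xi @ beta, ddof=1))
    s_exo = s[np.ix_([order.index(v) for v in exo], [order.index(v) for v in exo])]
    chol = np.linalg.cholesky(s_exo + 1e-10 * np.eye(n_exo))
    idx = np.tril_indices(n_exo)
    off = len(edge_index)
    theta0[off : off + idx[0].size] = chol[idx]
    off += idx[0].size
    for child in endo:
        theta0[off] = np.sqrt(max(resid0[child], 1e-8))
        off += 1

    def discrepancy(theta):
        _, _, sigma = _build_matrices(theta, spec, order, edge_index, exo, endo, n_exo)
        sign_m, logdet = np.linalg.slogdet(sigma)
        if sign_m <= 0:
            return 1e12
        return logdet + np.trace(s @ np.linalg.inv(sigma)) - logdet_s - p

    if method == "ml":
        res = minimize(
            discrepancy,
            theta0,
            method="BFGS",
            options={"maxiter": max_iter, "gtol": tol},
        )
        theta = res.x
        grad_norm = float(np.linalg.norm(res.jac)) if res.jac is not None else np.nan
        # BFGS on a flat-at-optimum surface can report precision loss while
        # the gradient is effectively zero; treat that as converged
        converged = bool(res.success) or grad_norm < 1e-5
    elif method == "ols":
        theta = theta0
        grad_norm = 0.0
        converged = True
    else:
        raise ValueError(f"unknown method {method!r}")

    b, psi, sigma = _build_matrices(theta, spec, order, edge_index, exo, endo, n_exo)
    f_min = max(discrepancy(theta), 0.0)
    n_free = len(edge_index) + n_exo * (n_exo + 1) // 2 + len(endo)
    df = p * (p + 1) // 2 - n_free
    if df < 0:
        raise ValueError("model has more free parameters than covariance moments")
    chi2 = (n - 1) * f_min
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0

    sigma_inv_s = np.linalg.inv(sigma) @ s
    eye = np.eye(p)
    gfi = 1.0 - np.trace((sigma_inv_s - eye) @ (sigma_inv_s - eye)) / np.trace(
        sigma_inv_s @ sigma_inv_s
    )
    # SRMR over the lower triangle incl. diagonal, standardized by sample sds
    denom = np.sqrt(np.outer(np.diag(s), np.diag(s)))
    resid = (s - sigma) / denom
    il = np.tril_indices(p)
    srmr = float(np.sqrt((resid[il] ** 2).mean()))

    # standardize coefficients with implied variances (== fitted B for
    # z-scored data up to implied-variance drift)
    dsig = np.sqrt(np.diag(sigma))
    b_std = b * (dsig[None, :] / dsig[:, None])
    coeffs = pd.DataFrame(b_std, index=order, columns=order)
    resid_var = pd.Series({v: psi[order.index(v)] for v in endo})

    return PathFit(
        spec=spec,
        coefficients=coeffs,
        residual_variances=resid_var,
        implied_cov=pd.DataFrame(sigma, index=order, columns=order),
        sample_cov=pd.DataFrame(s, index=order, columns=order),
        chi2=float(chi2),
        df=int(df),
        p=p_value,
        chi2_df=float(chi2 / df) if df > 0 else 0.0,
        gfi=float(gfi),
        srmr=srmr,
        converged=converged,
        gradient_norm=grad_norm,
        n=n,
        method=method,
    )


def effect_decomposition(fit: PathFit) -> EffectDecomposition:
    """Standardized direct / indirect / total effects.

    For recursive B (strictly lower triangular in the causal order) the
    total-effect matrix is (I - B)^-1 - I, a finite sum of path products;
    indirect = total - direct.
    """
    order = fit.spec.order
    b = fit.coefficients.loc[order, order].to_numpy()
    # recursive models are strictly lower triangular in causal order
    assert np.allclose(np.triu(b), 0.0), "coefficient matrix is not recursive"
    total = np.linalg.inv(np.eye(len(order)) - b) - np.eye(len(order))
    direct = b
    indirect = total - direct
    mk = lambda m: pd.DataFrame(m, index=order, columns=order)
    return EffectDecomposition(direct=mk(direct), indirect=mk(indirect), total=mk(total))


def composition_scores(
    table: TaxonAbundanceTable, method: str = "pcoa1", seed: int = 0
) -> pd.Series:
    """Scalar community-composition score per sample.

    The first ordination axis of the Bray-Curtis distance matrix (PCoA by
    default, NMDS selectable), sign-anchored so the axis correlates
    positively with the most abundant taxon. All-identical samples give
    all-zero scores.
    """
    d = bray_curtis(table)
    if np.allclose(d.values, 0.0):
        return pd.Series(0.0, index=table.sample_ids, name="composition")
    if method == "pcoa1":
        axis = pcoa(d, k=1).coordinates[:, 0]
    elif method == "nmds1":
        axis = nmds(d, k=1, seed=seed).coordinates[:, 0]
    else:
        raise ValueError(f"unknown method {method!r}")
    rel = to_relative(table)
    top = rel.values.mean(axis=1).argmax()
    anchor = rel.values[top]
    if axis.std() > 0 and anchor.std() > 0:
        if np.corrcoef(anchor, axis)[0, 1] < 0:
            axis = -axis
    return pd.Series(axis, index=table.sample_ids, name="composition")
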
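"""Synthetic microbiome / soil / metabolite data with known ground truth.

The generator emulates the post-profiling state of a multi-site
rhizosphere study: compositional taxon-by-sample count tables over eight
site groups with a planted block of high-prevalence, mutually correlated
"core" taxa; site-varying soil covariates; and tuber metabolite vectors
produced by a known recursive linear structural model. Every downstream
stage of the pipeline therefore has a recovery test with planted truth.

One global seed is split into independent per-component streams
(community, soil/metabolites) so that, e.g., changing the number of taxa
does not perturb the soil draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables_io import (
    MetaboliteTable,
    SampleMetadata,
    SoilProfile,
    SOIL_VARIABLES,
    TaxonAbundanceTable,
)

__all__ = [
    "GroundTruth",
    "SyntheticBundle",
    "DEFAULT_GROUPS",
    "DEFAULT_PATH_COEFFICIENTS",
    "simulate_community",
    "simulate_soil_metabolites",
    "simulate_bundle",
]

#: Site labels mirroring an 8-production-area sampling design.
DEFAULT_GROUPS = ("AHJ", "AHW", "GXG", "GXY", "GZL", "GZQ", "ZJP", "ZLS")

#: Default true standardized path coefficients of the soil -> community ->
#: metabolite structural model. Soil variables are exogenous; fungal and
#: bacterial community composition scores and the metabolite variable are
#: endogenous. Values are chosen so every implied variance stays below 1
#: (all variables have unit population variance by construction).
DEFAULT_PATH_COEFFICIENTS: dict[tuple[str, str], float] = {
    ("SOC", "fungal_comp"): 0.50,
    ("pH", "fungal_comp"): -0.35,
    ("SOC", "bacterial_comp"): 0.30,
    ("pH", "bacterial_comp"): -0.25,
    ("AN", "bacterial_comp"): 0.30,
    ("fungal_comp", "bacterial_comp"): 0.45,
    ("SOC", "metabolite"): 0.45,
    ("AP", "metabolite"): 0.25,
    ("AK", "metabolite"): 0.25,
    ("bacterial_comp", "metabolite"): 0.40,
    ("fungal_comp", "metabolite"): 0.20,
}

# Raw-scale anchors (mean, sd) used to place standardized draws on a
# plausible scale: slightly acidic soils and a polysaccharide fraction in
# the hundreds of mg/g. Fitting always happens on standardized variables;
# these affect presentation only.
_SOIL_SCALES = {
    "pH": (5.8, 0.6),
    "SOC": (25.0, 8.0),
    "AN": (120.0, 35.0),
    "AP": (18.0, 6.0),
    "AK": (150.0, 45.0),
}
_METABOLITE_SCALE = ("BSP", 280.0, 75.0)  # mg/g dry weight


@dataclass
class GroundTruth:
    """Planted structure of a synthetic bundle, for recovery tests."""

    planted_core_taxa: list[str]
    core_log_correlation: float
    true_path_coefficients: dict[tuple[str, str], float]
    noise_sd: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "planted_core_taxa": list(self.planted_core_taxa),
            "core_log_correlation": self.core_log_correlation,
            "true_path_coefficients": {
                f"{a}->{b}": v for (a, b), v in self.true_path_coefficients.items()
            },
            "noise_sd": dict(self.noise_sd),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        coeffs = {
            tuple(k.split("->")): v
            for k, v in payload["true_path_coefficients"].items()
        }
        return cls(
            planted_core_taxa=list(payload["planted_core_taxa"]),
            core_log_correlation=payload["core_log_correlation"],
            true_path_coefficients=coeffs,
            noise_sd=dict(payload["noise_sd"]),
        )


@dataclass
class SyntheticBundle:
    """Abundance + soil + metabolite tables sharing sample ids, plus truth."""

    abundance: TaxonAbundanceTable
    metadata: SampleMetadata
    soil: SoilProfile
    metabolites: MetaboliteTable
    community_scores: pd.DataFrame  # fungal_comp / bacterial_comp, standardized
    truth: GroundTruth
    seed: int

    def write(self, outdir) -> dict[str, str]:
        """Write all tables plus the ground-truth sidecar; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "abundance": outdir / "abundance.tsv",
            "metadata": outdir / "metadata.tsv",
            "soil": outdir / "soil.tsv",
            "metabolites": outdir / "metabolites.tsv",
            "community_scores": outdir / "community_scores.tsv",
            "truth": outdir / "truth.json",
        }
        self.abundance.to_tsv(paths["abundance"])
        self.metadata.to_tsv(paths["metadata"])
        self.soil.to_tsv(paths["soil"])
        self.metabolites.to_tsv(paths["metabolites"])
        df = self.community_scores.copy()
        df.index.name = "sample_id"
        df.to_csv(paths["community_scores"], sep="\t", float_format="%.17g")
        self.truth.to_json(paths["truth"])
        return {k: str(v) for k, v in paths.items()}


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _sample_ids(n_groups: int, n_per_group: int) -> tuple[list[str], list[str]]:
    if n_groups <= len(DEFAULT_GROUPS):
        groups = list(DEFAULT_GROUPS[:n_groups])
    else:
        groups = [f"G{i + 1:02d}" for i in range(n_groups)]
    ids, labels = [], []
    for g in groups:
        for j in range(n_per_group):
            ids.append(f"{g}_{j + 1}")
            labels.append(g)
    return ids, labels


def simulate_community(
    n_groups: int = 8,
    n_per_group: int = 5,
    n_taxa: int = 200,
    n_core: int = 5,
    rho_core: float = 0.8,
    depth: int = 50_000,
    seed: int = 0,
) -> tuple[TaxonAbundanceTable, SampleMetadata, GroundTruth]:
    """Simulate a compositional count table with a planted correlated core block.

    Log-abundances of the ``n_core`` planted taxa are drawn from a
    multivariate normal with equicorrelation ``rho_core`` and a high mean,
    so their prevalence is ~100% and their mean relative abundance is far
    above typical core-candidate thresholds. Non-core taxa are independent
    log-normals with group-specific mean shifts and sparse Bernoulli
    occupancy (per-taxon occupancy probability ~ Uniform(0.2, 0.6)),
    giving a realistic prevalence spread around a 75% prevalence cut.
    Fractions come from exponentiation + per-sample normalization; counts
    from a per-sample multinomial of size ``depth``.
    """
    if n_core >= n_taxa:
        raise ValueError("n_core must be smaller than n_taxa")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not (0.0 < rho_core < 1.0):
        raise ValueError("rho_core must lie in (0, 1)")
    if n_groups < 1 or n_per_group < 1:
        raise ValueError("n_groups and n_per_group must be positive")

    rng, = _streams(seed, 1)
    sample_ids, group_labels = _sample_ids(n_groups, n_per_group)
    n = len(sample_ids)

    core_names = [f"core_{i + 1}" for i in range(n_core)]
    other_names = [f"taxon_{i + 1:03d}" for i in range(n_taxa - n_core)]

    # Planted block: equicorrelated MVN on the log scale. The mean keeps the
    # block well above candidate abundance thresholds (~3% mean fraction);
    # the log-sd of 2 keeps the planted correlation dominant over the
    # compositional (shared-denominator) distortion after normalization.
    cov = np.full((n_core, n_core), rho_core)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov)
    core_log = 1.0 + 2.0 * (rng.standard_normal((n, n_core)) @ chol.T)  # samples x core

    # Non-core: independent log-normals, group-specific means, sparse occupancy.
    n_other = n_taxa - n_core
    base_mean = rng.normal(0.0, 1.0, size=n_other)
    group_shift = rng.normal(0.0, 0.5, size=(n_groups, n_other))
    group_index = np.repeat(np.arange(n_groups), n_per_group)
    other_log = (
        base_mean[None, :]
        + group_shift[group_index]
        + rng.standard_normal((n, n_other))
    )
    occupancy_p = rng.uniform(0.2, 0.6, size=n_other)
    occupied = rng.random((n, n_other)) < occupancy_p[None, :]

    intensity = np.concatenate(
        [np.exp(core_log), np.exp(other_log) * occupied], axis=1
    )  # samples x taxa
    fractions = intensity / intensity.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, p) for p in fractions]).T  # taxa x samples

    table = TaxonAbundanceTable(
        pd.DataFrame(counts, index=core_names + other_names, columns=sample_ids),
        kind="counts",
    )
    metadata = SampleMetadata(pd.Series(group_labels, index=sample_ids, name="group"))
    truth = GroundTruth(
        planted_core_taxa=core_names,
        core_log_correlation=rho_core,
        true_path_coefficients={},
    )
    return table, metadata, truth


def _topological_order(variables: list[str], edges: dict[tuple[str, str], float]) -> list[str]:
    children = {v: [] for v in variables}
    indeg = {v: 0 for v in variables}
    for (a, b) in edges:
        children[a].append(b)
        indeg[b] += 1
    order, queue = [], sorted(v for v in variables if indeg[v] == 0)
    while queue:
        v = queue.pop(0)
        order.append(v)
        for c in sorted(children[v]):
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != len(variables):
        raise ValueError("structural model specification contains a cycle")
    return order


def simulate_soil_metabolites(
    metadata: SampleMetadata,
    path_coefficients: dict[tuple[str, str], float] | None = None,
    group_effect_sd: float = 0.5,
    seed: int = 0,
) -> tuple[SoilProfile, MetaboliteTable, pd.DataFrame, GroundTruth]:
    """Simulate soil covariates and metabolite vectors from a known path model.

    Exogenous soil variables are group mean + Gaussian noise, scaled to
    unit population variance. Each endogenous variable equals the sum of
    (true coefficient x standardized parent) plus Gaussian noise whose sd
    is set so the population variance of the child is exactly 1; the
    realized per-variable noise sd is recorded in the returned truth.
    Standardized draws are also mapped onto plausible raw soil and
    metabolite (mg/g) scales for presentation.
    """
    coeffs = dict(DEFAULT_PATH_COEFFICIENTS if path_coefficients is None else path_coefficients)
    variables = list(SOIL_VARIABLES) + ["fungal_comp", "bacterial_comp", "metabolite"]
    for (a, b) in coeffs:
        if a not in variables or b not in variables:
            raise ValueError(f"unknown variable in path specification: {(a, b)}")
    order = _topological_order(variables, coeffs)

    rng, = _streams(seed, 1)
    sample_ids = metadata.sample_ids
    groups = metadata.groups.to_numpy()
    levels, group_index = np.unique(groups, return_inverse=True)
    n = len(sample_ids)

    exogenous = [v for v in variables if not any(b == v for (_, b) in coeffs)]
    endogenous = [v for v in variables if v not in exogenous]

    # Population covariance of already-generated variables, used to set
    # residual sds so every variable has unit population variance.
    pop_cov = pd.DataFrame(np.eye(len(variables)), index=variables, columns=variables)
    data = pd.DataFrame(index=sample_ids, columns=variables, dtype=float)
    noise_sd: dict[str, float] = {}
    resid_sd = float(np.sqrt(max(1.0 - group_effect_sd**2, 1e-9)))

    for v in order:
        parents = [(a, c) for (a, b), c in coeffs.items() if b == v]
        if not parents:
            effects = rng.normal(0.0, group_effect_sd, size=len(levels))
            data[v] = effects[group_index] + rng.normal(0.0, resid_sd, size=n)
        else:
            names = [a for a, _ in parents]
            b = np.array([c for _, c in parents])
            systematic_var = float(b @ pop_cov.loc[names, names].to_numpy() @ b)
            if systematic_var >= 1.0:
                raise ValueError(
                    f"path coefficients into {v!r} imply variance >= 1; rescale them"
                )
            sd = float(np.sqrt(1.0 - systematic_var))
            noise_sd[v] = sd
            data[v] = data[names].to_numpy() @ b + rng.normal(0.0, sd, size=n)
            # update population covariances with every earlier variable
            for w in order:
                if w == v:
                    break
                cov_wv = float(b @ pop_cov.loc[names, w].to_numpy())
                pop_cov.loc[w, v] = pop_cov.loc[v, w] = cov_wv

    soil_raw = pd.DataFrame(index=sample_ids, columns=list(SOIL_VARIABLES), dtype=float)
    for v in SOIL_VARIABLES:
        mu, sc = _SOIL_SCALES[v]
        soil_raw[v] = np.clip(mu + sc * data[v], 1e-3 if v == "pH" else 0.0, 13.999 if v == "pH" else np.inf)
    name, mu, sc = _METABOLITE_SCALE
    metab_raw = pd.DataFrame(
        {name: np.clip(mu + sc * data["metabolite"], 0.0, np.inf)}, index=sample_ids
    )

    scores = data[["fungal_comp", "bacterial_comp", "metabolite"]].copy()
    truth = GroundTruth(
        planted_core_taxa=[],
        core_log_correlation=float("nan"),
        true_path_coefficients=coeffs,
        noise_sd=noise_sd,
    )
    return SoilProfile(soil_raw), MetaboliteTable(metab_raw), scores, truth


def simulate_bundle(
    n_groups: int = 8,
    n_per_group: int = 5,
    n_taxa: int = 200,
    n_core: int = 5,
    rho_core: float = 0.8,
    depth: int = 50_000,
    path_coefficients: dict[tuple[str, str], float] | None = None,
    seed: int = 0,
) -> SyntheticBundle:
    """Generate a full bundle (community + soil + metabolites) with shared samples.

    Defaults mirror an 8-site x 5-plant sampling layout (40 samples).
    """
    comm_seed, env_seed = np.random.SeedSequence(seed).spawn(2)
    comm_seed = int(comm_seed.generate_state(1)[0] % (2**31))
    env_seed = int(env_seed.generate_state(1)[0] % (2**31))

    abundance, metadata, comm_truth = simulate_community(
        n_groups=n_groups,
        n_per_group=n_per_group,
        n_taxa=n_taxa,
        n_core=n_core,
        rho_core=rho_core,
        depth=depth,
        seed=comm_seed,
    )
    soil, metabolites, scores, env_truth = simulate_soil_metabolites(
        metadata, path_coefficients=path_coefficients, seed=env_seed
    )
    truth = GroundTruth(
        planted_core_taxa=comm_truth.planted_core_taxa,
        core_log_correlation=comm_truth.core_log_correlation,
        true_path_coefficients=env_truth.true_path_coefficients,
        noise_sd=env_truth.noise_sd,
    )
    return SyntheticBundle(
        abundance=abundance,
        metadata=metadata,
        soil=soil,
        metabolites=metabolites,
        community_scores=scores,
        truth=truth,
        seed=seed,
    )
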
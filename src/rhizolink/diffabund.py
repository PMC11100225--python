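"""LEfSe-like differential-abundance scoring.

A simplified linear-discriminant effect size: taxa are first screened by
a Kruskal-Wallis test across site groups, then scored on a per-million
abundance scale by averaging a between-group mean-difference term with a
linear-discriminant coefficient term over bootstrap rounds. Taxa pass
when the Kruskal-Wallis p is below alpha AND log10 effect size exceeds
the threshold (conventionally 4). The original tool's subclass/Wilcoxon
stage is omitted (no subclass structure here) and strict numerical
parity with it is not claimed: results are "LEfSe-like".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .diversity import kruskal_wallis
from .tables_io import SampleMetadata, TaxonAbundanceTable, to_relative

__all__ = ["LdaResult", "lda_effect_size"]


@dataclass
class LdaResult:
    table: pd.DataFrame  # index taxon; kw_p, enriched_group, lda_score, selected
    alpha: float
    lda_threshold: float

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


def _lda_coefficients(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-feature |LDA coefficient|; one-vs-rest axes for >2 classes.

    Uses a least-squares LDA solver with automatic shrinkage, which stays
    defined for the collinear features typical of compositional data.
    """
    classes = np.unique(labels)
    try:
        if classes.size == 2:
            lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            lda.fit(x, labels)
            return np.abs(lda.coef_[0])
        coefs = np.zeros(x.shape[1])
        for c in classes:
            lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            lda.fit(x, (labels == c).astype(int))
            coefs = np.maximum(coefs, np.abs(lda.coef_[0]))
        return coefs
    except Exception:
        return np.zeros(x.shape[1])


def lda_effect_size(
    table: TaxonAbundanceTable,
    metadata: SampleMetadata,
    alpha: float = 0.05,
    lda_threshold: float = 4.0,
    n_boot: int = 30,
    boot_fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> LdaResult:
    """LEfSe-like LDA effect sizes with the `score > threshold` selection rule.

    Per taxon: (1) Kruskal-Wallis across groups; only taxa with p < alpha
    are scored. (2) Abundances are rescaled to per-million. (3) In each of
    ``n_boot`` bootstrap rounds, ``boot_fraction`` of the samples of every
    group are subsampled (rounds where a group drops below 2 samples are
    re-drawn up to 10 times, then skipped); the round's effect size per
    surviving taxon is the mean of (a) the average absolute group-mean
    difference over group pairs and (b) the taxon's absolute linear
    discriminant coefficient scaled by its pooled within-group sd. The
    reported score is log10(max(effect, 1)) averaged over rounds.
    """
    rel = to_relative(table)
    labels = metadata.group_of(rel.sample_ids)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least two groups")
    counts = {g: int((labels == g).sum()) for g in groups}
    if min(counts.values()) < 3:
        raise ValueError("every group needs at least 3 samples")

    ppm = rel.values * 1e6  # taxa x samples, per-million scale
    taxa = rel.taxon_ids

    kw_p = np.ones(len(taxa))
    for i in range(len(taxa)):
        vals = [ppm[i, labels == g] for g in groups]
        _, kw_p[i] = kruskal_wallis(vals)
    surviving = np.flatnonzero(kw_p < alpha)

    group_means_full = np.vstack([ppm[:, labels == g].mean(axis=1) for g in groups])
    enriched = groups[np.argmax(group_means_full, axis=0)]

    scores = np.zeros(len(taxa))
    if surviving.size:
        rng = np.random.default_rng(seed)
        x_all = ppm[surviving].T  # samples x surviving taxa
        # subsample by lexicographically sorted sample id within each group,
        # so scores do not depend on the column order of the input table
        ids = np.asarray(rel.sample_ids)
        group_pos = {
            g: np.flatnonzero(labels == g)[np.argsort(ids[labels == g])] for g in groups
        }
        round_scores = []
        for _ in range(n_boot):
            idx = None
            for _attempt in range(10):
                cand = np.concatenate(
                    [
                        rng.choice(
                            group_pos[g],
                            size=max(int(round(boot_fraction * counts[g])), 1),
                            replace=False,
                        )
                        for g in groups
                    ]
                )
                sub_labels = labels[cand]
                if all((sub_labels == g).sum() >= 2 for g in groups):
                    idx = cand
                    break
            if idx is None:
                continue
            xb, lb = x_all[idx], labels[idx]
            gm = np.vstack([xb[lb == g].mean(axis=0) for g in groups])
            # mean |group mean difference| over group pairs
            diffs = [
                np.abs(gm[a] - gm[b])
                for a in range(groups.size)
                for b in range(a + 1, groups.size)
            ]
            mean_diff = np.mean(diffs, axis=0)
            # pooled within-group sd per taxon
            pooled_var = np.zeros(xb.shape[1])
            dof = 0
            for g in groups:
                sel = xb[lb == g]
                pooled_var += sel.var(axis=0, ddof=1) * (sel.shape[0] - 1)
                dof += sel.shape[0] - 1
            pooled_sd = np.sqrt(pooled_var / max(dof, 1))
            coef = _lda_coefficients(xb, lb)
            effect = 0.5 * (mean_diff + coef * pooled_sd)
            round_scores.append(np.log10(np.maximum(effect, 1.0)))
        if round_scores:
            scores[surviving] = np.mean(round_scores, axis=0)

    selected = (kw_p < alpha) & (scores > lda_threshold)
    out = pd.DataFrame(
        {
            "kw_p": kw_p,
            "enriched_group": enriched,
            "lda_score": scores,
            "selected": selected,
        },
        index=taxa,
    )
    return LdaResult(table=out, alpha=alpha, lda_threshold=lda_threshold)
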
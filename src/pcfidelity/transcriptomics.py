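"""Transcriptomic correlation (TC) analysis.

Models (cell lines, organoids) are ranked by their median Spearman rank
correlation with reference samples or single cells over a fixed panel of
highly variable genes recomputed from the model compendium. Also
includes the site-consistency check, the cytotoxic T-lymphocyte score
(mean of the five TIDE marker genes), and a rank-sum differential
expression surrogate with the conventional adjusted-p / fold-change
cutoffs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_adjust, rank_sum_test, spearman_matrix, spearman_rho
from .core_io import Thresholds

logger = logging.getLogger("pcfidelity")

CTL_MARKERS = ("CD8A", "CD8B", "GZMA", "GZMB", "PRF1")


@dataclass
class HvgPanel:
    genes: list
    variances: pd.Series

    def __len__(self):
        return len(self.genes)


def select_hvg(expression: pd.DataFrame, n_hvg: int = 1000) -> HvgPanel:
    """Top genes by variance of log2 expression across the model panel.

    Ties break deterministically by gene symbol. Requesting more genes
    than available returns all of them with a warning.
    """
    if n_hvg > len(expression):
        warnings.warn(
            f"n_hvg={n_hvg} exceeds the {len(expression)} available genes; using all"
        )
        n_hvg = len(expression)
    var = expression.var(axis=1, ddof=1)
    # mergesort is stable, so pre-sorting by symbol makes ties alphabetical
    order = (
        pd.DataFrame({"var": var})
        .sort_index()
        .sort_values(by="var", ascending=False, kind="mergesort")
    )
    genes = order.index[:n_hvg].tolist()
    return HvgPanel(genes=genes, variances=var)


def _restrict(profile: pd.Series | pd.DataFrame, hvg: list, min_coverage: float = 0.9):
    present = [g for g in hvg if g in profile.index]
    if len(present) < min_coverage * len(hvg):
        warnings.warn(
            f"only {len(present)}/{len(hvg)} HVG panel genes present; "
            "correlations use the shared subset"
        )
    return profile.loc[present]


def tc_similarity(
    model_profile: pd.Series,
    references: pd.DataFrame,
    hvg,
) -> tuple[float, pd.Series]:
    """Median Spearman correlation of one model against reference profiles.

    Returns (median rho, per-reference rho). Genes absent from either
    side are dropped pairwise (with a warning below 90% panel coverage);
    a model profile constant on the panel yields NaN.
    """
    hvg = list(hvg)
    if references.shape[1] < 3:
        warnings.warn("fewer than 3 references; the median is fragile")
    shared = [g for g in hvg if g in model_profile.index and g in references.index]
    if len(shared) < 0.9 * len(hvg):
        warnings.warn(
            f"only {len(shared)}/{len(hvg)} panel genes shared between model and references"
        )
    x = model_profile[shared].to_numpy(dtype=float)[:, None]
    rhos = spearman_matrix(x, references.loc[shared].to_numpy(dtype=float))[0]
    per_ref = pd.Series(rhos, index=references.columns)
    return float(np.median(rhos)) if not np.isnan(rhos).all() else np.nan, per_ref


def tc_similarity_table(
    models: pd.DataFrame, references: pd.DataFrame, hvg
) -> pd.DataFrame:
    """Model x reference Spearman rho matrix over the HVG panel."""
    hvg = list(hvg)
    shared = [g for g in hvg if g in models.index and g in references.index]
    if len(shared) < 0.9 * len(hvg):
        warnings.warn(
            f"only {len(shared)}/{len(hvg)} panel genes shared across matrices"
        )
    rho = spearman_matrix(
        models.loc[shared].to_numpy(dtype=float),
        references.loc[shared].to_numpy(dtype=float),
    )
    return pd.DataFrame(rho, index=models.columns, columns=references.columns)


def rank_models(similarity: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Rank models by median similarity (descending, min-rank ties).

    Accepts the model x reference table (medians taken per row) or an
    already-aggregated per-model Series.
    """
    if isinstance(similarity, pd.DataFrame):
        med = similarity.median(axis=1)
    else:
        med = similarity.astype(float)
    out = pd.DataFrame({"model": med.index, "similarity": med.to_numpy()})
    out["rank"] = out["similarity"].rank(method="min", ascending=False).astype(int)
    return out.sort_values(["rank", "model"]).reset_index(drop=True)


def site_consistency(per_site: dict[str, pd.Series]) -> pd.DataFrame:
    """Pairwise Spearman correlation of per-site similarity vectors.

    Input maps site -> per-model median similarity (aligned on models).
    """
    sites = sorted(per_site)
    out = pd.DataFrame(np.eye(len(sites)), index=sites, columns=sites)
    for i, s1 in enumerate(sites):
        for s2 in sites[i + 1 :]:
            a, b = per_site[s1].align(per_site[s2], join="inner")
            rho = spearman_rho(a.to_numpy(), b.to_numpy())
            out.loc[s1, s2] = out.loc[s2, s1] = rho
    return out


def ctl_score(expression: pd.DataFrame, sample: str | None = None):
    """Cytotoxic CD8+ T-cell score: mean expression of the five markers.

    Returns a scalar for one sample or a per-sample Series for all.
    """
    missing = [g for g in CTL_MARKERS if g not in expression.index]
    if missing:
        raise KeyError(f"CTL marker genes missing from matrix: {missing}")
    scores = expression.loc[list(CTL_MARKERS)].mean(axis=0)
    if sample is not None:
        if sample not in scores.index:
            raise KeyError(f"sample {sample!r} not in matrix")
        return float(scores[sample])
    return scores


def rank_sum_de(
    expression: pd.DataFrame,
    group_a,
    group_b,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Rank-sum differential expression between two sample groups.

    Per gene: two-sided Wilcoxon rank-sum p (BH across genes) and
    log2FC = mean(A) - mean(B) on the log2 scale. A gene is called
    up/down when adjusted p < alpha_adj and |log2FC| > de_abs_log2fc.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    a = expression[group_a].to_numpy(dtype=float)
    b = expression[group_b].to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    pvals = np.array([rank_sum_test(a[i], b[i]) for i in range(a.shape[0])])
    adj = bh_adjust(pvals)
    call = np.where(
        (adj < thresholds.alpha_adj) & (np.abs(log2fc) > thresholds.de_abs_log2fc),
        np.where(log2fc > 0, "up", "down"),
        "none",
    )
    out = pd.DataFrame(
        {"gene": expression.index, "log2fc": log2fc, "p": pvals, "adj_p": adj, "call": call}
    )
    logger.info(
        "rank_sum_de: %d genes, %d up, %d down",
        len(out), int((call == "up").sum()), int((call == "down").sum()),
    )
    return out
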
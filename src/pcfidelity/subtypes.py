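"""Subtype and lineage assignment.

Bulk samples are assigned to ARPC/NEPC by external AR/NE labels and to
MSPC by the double-quartile rule on single-sample gene-set enrichment
(ssGSEA) scores for EMT and stemness signatures. Single cells are
assigned by marker z-scores (AR -> ARPC, SYP -> NEPC, CD44 -> MSPC) or,
for lineage, by Spearman similarity to normal epithelial pseudo-bulk
profiles (luminal / basal / neuroendocrine). PC1-loading extraction and
hypergeometric over-representation testing support the cluster-level
characterization of models.

ssGSEA here follows the standard weighted running-sum formulation: for a
sample, genes are ranked by expression (average-rank ties); walking the
genes in descending order, the score accumulates the difference between
the rank-weight^alpha-weighted in-set ECDF and the unweighted out-of-set
ECDF. The exponent alpha defaults to 0.25 and scores are not normalized
across samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, hypergeom_sf_p, spearman_matrix
from .core_io import GeneSet, Thresholds

logger = logging.getLogger("pcfidelity")

DEFAULT_SUBTYPE_MARKERS = {"ARPC": "AR", "NEPC": "SYP", "MSPC": "CD44"}
LINEAGE_ORDER = ("luminal", "basal", "neuroendocrine")

_MIN_SET_SIZE = 5


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------


def _ssgsea_sample(order: np.ndarray, ranks: np.ndarray,
                   in_set: np.ndarray, alpha: float) -> float:
    """Running-sum score for one sample given a precomputed walk order."""
    w = ranks[order] ** alpha
    mask = in_set[order]
    w_in = np.where(mask, w, 0.0)
    total_in = w_in.sum()
    n_out = (~mask).sum()
    if total_in == 0 or n_out == 0:
        return 0.0
    p_in = np.cumsum(w_in) / total_in
    p_out = np.cumsum(~mask) / n_out
    return float((p_in - p_out).sum())


def ssgsea(
    expression: pd.DataFrame,
    gene_sets: list[GeneSet],
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Sample x gene-set matrix of single-sample enrichment scores.

    Each set must retain at least five genes after intersection with the
    matrix; scores are invariant to the gene order of the input (ties in
    expression are ranked average and walked in a fixed gene-name order).
    """
    expr = expression.sort_index()  # fixed walk order for tied expression
    genes = expr.index.to_numpy()
    values = expr.to_numpy(dtype=float)
    n = len(genes)
    memberships = {}
    for gs in gene_sets:
        inset = np.isin(genes, list(gs.genes))
        if inset.sum() < _MIN_SET_SIZE:
            raise ValueError(
                f"gene set {gs.name!r} has {int(inset.sum())} genes after "
                f"intersection (minimum {_MIN_SET_SIZE})"
            )
        memberships[gs.name] = inset
    scores = np.empty((values.shape[1], len(gene_sets)))
    for j in range(values.shape[1]):
        col = values[:, j]
        ranks = stats.rankdata(col)  # ascending: N for the highest expression
        order = np.lexsort((genes, -ranks))  # descending expression walk
        for k, gs in enumerate(gene_sets):
            scores[j, k] = _ssgsea_sample(order, ranks, memberships[gs.name], alpha)
    return pd.DataFrame(scores, index=expr.columns, columns=[g.name for g in gene_sets])


# ---------------------------------------------------------------------------
# Subtype calls
# ---------------------------------------------------------------------------


def call_mspc(
    scores: pd.DataFrame,
    label_map: dict[str, str] | None = None,
    emt_set: str = "EMT",
    stemness_set: str = "STEMNESS",
    thresholds: Thresholds = Thresholds(),
) -> pd.Series:
    """Assign ARPC/NEPC from external labels, then MSPC by double quartile.

    ``label_map`` (sample -> "ARPC"/"NEPC", from AR/NE annotations) takes
    precedence. Among the remaining samples, those with both EMT and
    stemness ssGSEA scores at or above the cohort's upper quartile
    (computed over the full cohort, linear-interpolation quantiles) are
    MSPC; the rest are unassigned.
    """
    label_map = label_map or {}
    for s, lab in label_map.items():
        if lab not in ("ARPC", "NEPC"):
            raise ValueError(f"label_map may only assign ARPC/NEPC, got {lab!r}")
    q = 1.0 - thresholds.mspc_quantile
    emt_cut = scores[emt_set].quantile(q)
    stem_cut = scores[stemness_set].quantile(q)
    calls = {}
    for s in scores.index:
        if s in label_map:
            calls[s] = label_map[s]
        elif scores.at[s, emt_set] >= emt_cut and scores.at[s, stemness_set] >= stem_cut:
            calls[s] = "MSPC"
        else:
            calls[s] = "unassigned"
    out = pd.Series(calls, name="subtype")
    logger.info(
        "call_mspc: %d labeled, %d MSPC, %d unassigned",
        len(label_map), int((out == "MSPC").sum()), int((out == "unassigned").sum()),
    )
    return out


def call_subtype_markers(
    cell_expression: pd.DataFrame,
    markers: dict[str, str] = DEFAULT_SUBTYPE_MARKERS,
) -> pd.Series:
    """Per-cell subtype call by marker z-score argmax.

    Each marker is z-scored across cells; a cell takes the subtype of its
    highest-z marker, or "unassigned" when no marker z is positive.
    """
    missing = [g for g in markers.values() if g not in cell_expression.index]
    if missing:
        raise KeyError(f"marker genes missing from matrix: {missing}")
    sub = cell_expression.loc[[markers[k] for k in markers]].to_numpy(dtype=float)
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - mean) / sd
    names = list(markers)
    best = np.argmax(z, axis=0)
    calls = np.where(z.max(axis=0) <= 0, "unassigned", np.array(names)[best])
    return pd.Series(calls, index=cell_expression.columns, name="subtype")


# ---------------------------------------------------------------------------
# Lineage
# ---------------------------------------------------------------------------


@dataclass
class LineageReference:
    pseudo_bulk: pd.DataFrame  # genes x lineage
    panel: list  # lineage gene panel (top-variance genes)


def build_lineage_reference(
    normal_expression: pd.DataFrame,
    cell_type_labels: pd.Series,
    n_lineage_genes: int = 5000,
) -> LineageReference:
    """Mean-expression pseudo-bulk per epithelial type plus the gene panel.

    The panel is the top ``n_lineage_genes`` by variance across the three
    pseudo-bulk profiles (all genes, with a warning, when fewer exist).
    """
    types = sorted(cell_type_labels.unique())
    pseudo = pd.DataFrame(
        {
            t: normal_expression[cell_type_labels.index[cell_type_labels == t]].mean(axis=1)
            for t in types
        }
    )
    if n_lineage_genes > len(pseudo):
        warnings.warn(
            f"n_lineage_genes={n_lineage_genes} exceeds the {len(pseudo)} genes; using all"
        )
        n_lineage_genes = len(pseudo)
    var = pseudo.var(axis=1, ddof=1)
    order = (
        pd.DataFrame({"var": var})
        .sort_index()
        .sort_values("var", ascending=False, kind="mergesort")
    )
    panel = order.index[:n_lineage_genes].tolist()
    return LineageReference(pseudo_bulk=pseudo, panel=panel)


def assign_lineage(
    profile: pd.Series, reference: LineageReference
) -> tuple[str, pd.Series]:
    """Assign one cell to the lineage with the highest Spearman similarity.

    Exact ties break in the fixed order luminal, basal, neuroendocrine
    (then alphabetically for other labels) with a warning. A profile
    constant on the panel has no defined correlation and raises.
    """
    panel = [g for g in reference.panel if g in profile.index]
    x = profile[panel].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("profile is constant on the lineage panel; correlation undefined")
    rho = spearman_matrix(x[:, None], reference.pseudo_bulk.loc[panel].to_numpy())[0]
    rhos = pd.Series(rho, index=reference.pseudo_bulk.columns)
    ordered = sorted(
        rhos.index,
        key=lambda t: (LINEAGE_ORDER.index(t) if t in LINEAGE_ORDER else len(LINEAGE_ORDER), t),
    )
    best = max(ordered, key=lambda t: rhos[t])  # max is stable: first of ties
    if (rhos == rhos[best]).sum() > 1:
        warnings.warn("lineage similarity tie; broken by fixed lineage order")
    return best, rhos


def assign_lineages(
    cells: pd.DataFrame, reference: LineageReference
) -> pd.DataFrame:
    """Vectorized lineage assignment for a cell matrix (genes x cells)."""
    panel = [g for g in reference.panel if g in cells.index]
    x = cells.loc[panel].to_numpy(dtype=float)
    constant = np.ptp(x, axis=0) == 0
    if constant.any():
        bad = cells.columns[constant].tolist()
        raise ValueError(f"profiles constant on the lineage panel: {bad}")
    rho = spearman_matrix(x, reference.pseudo_bulk.loc[panel].to_numpy())
    rho_df = pd.DataFrame(rho, index=cells.columns, columns=reference.pseudo_bulk.columns)
    ordered = sorted(
        rho_df.columns,
        key=lambda t: (LINEAGE_ORDER.index(t) if t in LINEAGE_ORDER else len(LINEAGE_ORDER), t),
    )
    out = rho_df[ordered]
    calls = out.idxmax(axis=1)  # first of ties in column order
    result = rho_df.copy()
    result.insert(0, "lineage", calls)
    return result


# ---------------------------------------------------------------------------
# PCA loadings and over-representation
# ---------------------------------------------------------------------------


def pc1_top_loadings(
    matrix: pd.DataFrame,
    n_top: int,
    orient_toward: list | None = None,
) -> tuple[list, pd.Series, pd.Series]:
    """Features with the largest positive PC1 loadings.

    Features (rows) are centered across columns and decomposed by SVD.
    The sign of PC1 is arbitrary; it is oriented so the columns named in
    ``orient_toward`` (the contrast group, e.g. the mesenchymal-like
    cluster) have positive mean scores, or, absent a group, so the
    loading distribution skews positive. Returns (top features, all
    loadings, per-column PC1 scores).
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 columns for PCA")
    if n_top > len(matrix):
        warnings.warn(f"n_top={n_top} exceeds {len(matrix)} features; using all")
        n_top = len(matrix)
    x = matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    loadings = u[:, 0]
    scores = s[0] * vt[0]
    if orient_toward:
        cols = [matrix.columns.get_loc(c) for c in orient_toward]
        sign = 1.0 if scores[cols].mean() >= 0 else -1.0
    else:
        sign = 1.0 if stats.skew(loadings) >= 0 else -1.0
    loadings = pd.Series(sign * loadings, index=matrix.index, name="pc1_loading")
    scores = pd.Series(sign * scores, index=matrix.columns, name="pc1_score")
    logger.info("pc1_top_loadings: PC1 oriented with sign %+d", int(sign))
    top = loadings.sort_values(ascending=False, kind="mergesort").index[:n_top].tolist()
    return top, loadings, scores


def ora_hypergeometric(
    feature_list, gene_sets: list[GeneSet], universe
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each set in the list."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    hits = set(feature_list) & universe
    rows = []
    for gs in gene_sets:
        members = gs.genes & universe
        overlap = len(hits & members)
        rows.append(
            {
                "set": gs.name,
                "set_size": len(members),
                "list_size": len(hits),
                "overlap": overlap,
                "p": hypergeom_sf_p(overlap, len(universe), len(members), len(hits)),
            }
        )
    out = pd.DataFrame(rows)
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out
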
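"""Mutation-panel construction, concordance ranking, hotspots, hypermutation,
MMR validation, and differential copy number.

The gene panel unites two screens over the metastatic cohort: genes whose
mutation frequency differs from the primary cohort (site-specific Fisher
tests with BH adjustment, significant in at least ``min_sites_sig``
sites) and genes whose frequency strictly exceeds ``high_mut_freq`` in at
least two metastatic sites. Cell-line models are then ranked by how many
panel genes they carry mutated, and re-ranked by the burden-normalized
ratio to correct for hypermutation. Hypermutators themselves are called
from the pooled burden ranking: the largest adjacent gap on the log10
scale within the upper tail of ranks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from ._stats import bh_adjust, fisher_exact_p, rank_sum_test
from .core_io import (
    DEFAULT_SILENT_CLASSES,
    CnvSegment,
    GeneModel,
    MutationRecord,
    SampleAnnotation,
    Thresholds,
)

logger = logging.getLogger("pcfidelity")


# ---------------------------------------------------------------------------
# Mutation matrix
# ---------------------------------------------------------------------------


def mutation_matrix(
    records: list[MutationRecord],
    annotations: list[SampleAnnotation],
    exclude_silent: bool = True,
    silent_classes: frozenset = DEFAULT_SILENT_CLASSES,
) -> pd.DataFrame:
    """Binary gene x sample matrix; 1 = sample carries >=1 qualifying mutation.

    With ``exclude_silent`` the silent/non-coding classes do not qualify.
    Every annotated sample appears as a column even when unmutated.
    """
    known = {a.sample for a in annotations}
    missing = sorted({r.sample for r in records} - known)
    if missing:
        raise ValueError(f"records reference unannotated samples: {missing}")
    kept = [
        r for r in records if not (exclude_silent and r.is_silent(silent_classes))
    ]
    genes = sorted({r.gene for r in kept})
    samples = [a.sample for a in annotations]
    mat = pd.DataFrame(0, index=genes, columns=samples, dtype=np.int8)
    if kept:
        gi = {g: i for i, g in enumerate(genes)}
        si = {s: i for i, s in enumerate(samples)}
        vals = mat.to_numpy()
        for r in kept:
            vals[gi[r.gene], si[r.sample]] = 1
    logger.info(
        "mutation_matrix: %d records in, %d qualifying, %d genes x %d samples",
        len(records), len(kept), len(genes), len(samples),
    )
    return mat


def burden_table(records: list[MutationRecord], annotations: list[SampleAnnotation],
                 nonsynonymous_only: bool = False,
                 silent_classes: frozenset = DEFAULT_SILENT_CLASSES) -> pd.Series:
    """Per-sample total mutation burden (all records by default)."""
    kept = records if not nonsynonymous_only else [
        r for r in records if not r.is_silent(silent_classes)
    ]
    samples = [a.sample for a in annotations]
    return (
        pd.Series([r.sample for r in kept], dtype=object, name="burden")
        .value_counts()
        .reindex(samples, fill_value=0)
        .rename_axis("sample")
    )


# ---------------------------------------------------------------------------
# Panel selection
# ---------------------------------------------------------------------------


def fisher_gene_test(matrix: pd.DataFrame, group_a, group_b, gene: str) -> float:
    """Two-sided Fisher exact p for one gene's mutation frequency in A vs B."""
    if gene not in matrix.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    row = matrix.loc[gene]
    a = int(row[group_a].sum())
    c = int(row[group_b].sum())
    return fisher_exact_p(a, len(group_a) - a, c, len(group_b) - c)


def _site_groups(annotations: list[SampleAnnotation]):
    primary = [a.sample for a in annotations if a.cohort == "primary"]
    sites: dict[str, list[str]] = {}
    for a in annotations:
        if a.cohort == "metastatic":
            sites.setdefault(a.site, []).append(a.sample)
    return primary, sites


def select_diff_genes(
    matrix: pd.DataFrame,
    annotations: list[SampleAnnotation],
    thresholds: Thresholds = Thresholds(),
) -> tuple[pd.DataFrame, list[str]]:
    """Differentially mutated genes: per-site Fisher vs the primary cohort.

    Each metastatic site is compared with all primary samples; BH runs
    within site over the genes with at least one mutation in that
    site-plus-primary cohort. A gene is retained when its adjusted p
    falls below ``alpha_adj`` in at least ``min_sites_sig`` sites.
    Returns the per-site result table and the retained gene list.
    """
    primary, sites = _site_groups(annotations)
    if len(sites) < 2:
        raise ValueError("need metastatic samples from at least two sites")
    prim_counts = matrix[primary].sum(axis=1)
    results = []
    for site, members in sorted(sites.items()):
        site_counts = matrix[members].sum(axis=1)
        tested = matrix.index[(site_counts + prim_counts) > 0]
        pvals = np.array(
            [
                fisher_exact_p(
                    int(site_counts[g]),
                    len(members) - int(site_counts[g]),
                    int(prim_counts[g]),
                    len(primary) - int(prim_counts[g]),
                )
                for g in tested
            ]
        )
        adj = bh_adjust(pvals)
        results.append(
            pd.DataFrame(
                {
                    "gene": tested,
                    "site": site,
                    "site_freq": site_counts[tested].to_numpy() / len(members),
                    "primary_freq": prim_counts[tested].to_numpy() / len(primary),
                    "p": pvals,
                    "adj_p": adj,
                }
            )
        )
        logger.info(
            "select_diff_genes: site %s tested %d genes, %d significant",
            site, len(tested), int((adj < thresholds.alpha_adj).sum()),
        )
    table = pd.concat(results, ignore_index=True)
    sig = table[table["adj_p"] < thresholds.alpha_adj]
    counts = sig.groupby("gene").size()
    diff_genes = sorted(counts[counts >= thresholds.min_sites_sig].index)
    return table, diff_genes


def select_high_genes(
    matrix: pd.DataFrame,
    annotations: list[SampleAnnotation],
    thresholds: Thresholds = Thresholds(),
) -> list[str]:
    """Genes whose frequency strictly exceeds the cutoff in >=2 metastatic sites."""
    _, sites = _site_groups(annotations)
    exceed = pd.Series(0, index=matrix.index)
    for site, members in sites.items():
        freq = matrix[members].sum(axis=1) / len(members)
        exceed += (freq > thresholds.high_mut_freq).astype(int)
    return sorted(exceed[exceed >= 2].index)


@dataclass
class GenePanel:
    diff_genes: list
    high_genes: list
    per_site: pd.DataFrame = field(repr=False, default=None)

    @property
    def union(self) -> list:
        return sorted(set(self.diff_genes) | set(self.high_genes))


def build_gene_panel(
    matrix: pd.DataFrame,
    annotations: list[SampleAnnotation],
    thresholds: Thresholds = Thresholds(),
) -> GenePanel:
    per_site, diff = select_diff_genes(matrix, annotations, thresholds)
    high = select_high_genes(matrix, annotations, thresholds)
    panel = GenePanel(diff_genes=diff, high_genes=high, per_site=per_site)
    logger.info(
        "gene panel: %d differential + %d highly mutated = %d unique",
        len(diff), len(high), len(panel.union),
    )
    return panel


# ---------------------------------------------------------------------------
# Model ranking
# ---------------------------------------------------------------------------


def _min_rank(values: pd.Series, ascending: bool = False) -> pd.Series:
    return values.rank(method="min", ascending=ascending).astype(int)


def rank_by_panel(
    matrix: pd.DataFrame, panel_genes, cell_lines
) -> pd.DataFrame:
    """Rank models by their count of mutated panel genes (descending).

    Ties share the minimum (competition) rank; rows are ordered by rank
    then alphabetically.
    """
    genes = [g for g in panel_genes if g in matrix.index]
    counts = matrix.loc[genes, list(cell_lines)].sum(axis=0)
    out = pd.DataFrame({"model": counts.index, "panel_count": counts.to_numpy()})
    out["rank"] = _min_rank(out["panel_count"])
    return out.sort_values(["rank", "model"]).reset_index(drop=True)


def normalized_ratio(panel_counts: pd.Series, burden: pd.Series) -> pd.DataFrame:
    """Panel-mutation count divided by total burden, with min-rank ranking.

    Samples with zero burden are excluded with a warning (the ratio is
    undefined for them).
    """
    burden = burden.reindex(panel_counts.index)
    zero = burden[burden <= 0].index.tolist()
    if zero:
        warnings.warn(f"excluding zero-burden samples: {zero}")
    keep = burden.index[burden > 0]
    ratio = panel_counts[keep] / burden[keep]
    out = pd.DataFrame(
        {"model": keep, "panel_count": panel_counts[keep].to_numpy(),
         "burden": burden[keep].to_numpy(), "ratio": ratio.to_numpy()}
    )
    out["rank"] = _min_rank(out["ratio"])
    return out.sort_values(["rank", "model"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Hotspots
# ---------------------------------------------------------------------------


@dataclass
class HotspotCatalog:
    entries: pd.DataFrame  # gene, protein_change, n_carriers, carriers

    def keys(self) -> list[tuple[str, str]]:
        return list(zip(self.entries["gene"], self.entries["protein_change"]))


def find_hotspots(
    records: list[MutationRecord],
    metastatic_samples,
    thresholds: Thresholds = Thresholds(),
    silent_classes: frozenset = DEFAULT_SILENT_CLASSES,
) -> HotspotCatalog:
    """Recurrent non-synonymous variants carried by >= hotspot_min_samples
    distinct metastatic samples; keyed by (gene, protein change)."""
    met = set(metastatic_samples)
    carriers: dict[tuple[str, str], set] = {}
    for r in records:
        if r.sample not in met or r.is_silent(silent_classes) or not r.protein_change:
            continue
        carriers.setdefault((r.gene, r.protein_change), set()).add(r.sample)
    rows = [
        {
            "gene": g,
            "protein_change": pc,
            "n_carriers": len(s),
            "carriers": ",".join(sorted(s)),
        }
        for (g, pc), s in carriers.items()
        if len(s) >= thresholds.hotspot_min_samples
    ]
    entries = pd.DataFrame(rows, columns=["gene", "protein_change", "n_carriers", "carriers"])
    entries = entries.sort_values(
        ["n_carriers", "gene", "protein_change"], ascending=[False, True, True]
    ).reset_index(drop=True)
    logger.info("find_hotspots: %d hotspot variants", len(entries))
    return HotspotCatalog(entries)


def hotspot_presence(
    catalog: HotspotCatalog, records: list[MutationRecord], cell_lines
) -> pd.DataFrame:
    """Presence/absence of each catalog variant across models.

    Matching is by exact (gene, protein_change) string identity.
    """
    cell_lines = list(cell_lines)
    carried = {
        (r.gene, r.protein_change, r.sample) for r in records if r.sample in set(cell_lines)
    }
    index = pd.MultiIndex.from_tuples(
        catalog.keys(), names=["gene", "protein_change"]
    ) if len(catalog.entries) else pd.MultiIndex.from_arrays([[], []], names=["gene", "protein_change"])
    out = pd.DataFrame(False, index=index, columns=cell_lines)
    for g, pc in catalog.keys():
        for s in cell_lines:
            if (g, pc, s) in carried:
                out.loc[(g, pc), s] = True
    return out


# ---------------------------------------------------------------------------
# Hypermutation
# ---------------------------------------------------------------------------


@dataclass
class HypermutationCall:
    cutoff_burden: float
    gap_index: int  # number of samples above the gap (0 when no cutoff)
    gap_size: float  # largest log10 gap found in the upper tail
    hypermutated: list
    bimodality: dict
    no_cutoff: bool


def hypermutation_cutoff(
    burdens: pd.Series,
    top_frac: float = 0.2,
    min_gap_log10: float = 0.5,
) -> HypermutationCall:
    """Classify hypermutators from the pooled burden ranking.

    Burdens are sorted descending; adjacent gaps on the log10 scale are
    examined among the upper ``top_frac`` of ranks and the cutoff is
    placed at the largest gap, provided it reaches ``min_gap_log10``.
    Zero burdens sort to the bottom and never enter the gap search, so
    the classification is invariant to rescaling all burdens by a
    positive constant. A two-component Gaussian mixture on
    log10(burden + 1) summarizes the bimodality of the classification.
    """
    burdens = burdens.astype(float)
    if (burdens < 0).any():
        raise ValueError("burdens must be non-negative")
    if int((burdens > 0).sum()) < 20:
        raise ValueError("need at least 20 samples with positive burden")
    order = burdens.sort_values(ascending=False, kind="mergesort")
    pos = order[order > 0]
    logb = np.log10(pos.to_numpy())
    n = len(order)
    limit = max(1, int(np.floor(top_frac * n)))
    gaps = logb[:-1] - logb[1:]  # gap after rank i+1
    search = gaps[:limit]
    k = int(np.argmax(search))
    gap = float(search[k])

    gmm = GaussianMixture(n_components=2, random_state=0, n_init=1)
    log_all = np.log10(order.to_numpy() + 1.0).reshape(-1, 1)
    gmm.fit(log_all)
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    weights = gmm.weights_.ravel()
    hi, lo = np.argmax(means), np.argmin(means)
    pooled_sd = float(np.sqrt(weights[hi] * sds[hi] ** 2 + weights[lo] * sds[lo] ** 2))
    bimodality = {
        "means": [float(means[lo]), float(means[hi])],
        "weights": [float(weights[lo]), float(weights[hi])],
        "separation": float(abs(means[hi] - means[lo]) / pooled_sd) if pooled_sd > 0 else np.inf,
    }

    if gap < min_gap_log10:
        return HypermutationCall(
            cutoff_burden=float(order.iloc[0]),
            gap_index=0,
            gap_size=gap,
            hypermutated=[],
            bimodality=bimodality,
            no_cutoff=True,
        )
    hyper = order.index[: k + 1].tolist()
    cutoff = float(order.iloc[k + 1])
    logger.info(
        "hypermutation_cutoff: gap %.2f log10 units after rank %d; %d hypermutators",
        gap, k + 1, len(hyper),
    )
    return HypermutationCall(
        cutoff_burden=cutoff,
        gap_index=k + 1,
        gap_size=gap,
        hypermutated=sorted(hyper),
        bimodality=bimodality,
        no_cutoff=False,
    )


def mmr_comparison(
    matrix: pd.DataFrame, mmr_genes, hypermutated, others
) -> tuple[pd.Series, float]:
    """Per-sample count of mutated MMR genes, compared between groups by
    two-sided Wilcoxon rank-sum."""
    mmr_genes = [g for g in mmr_genes]
    if not mmr_genes:
        raise ValueError("MMR gene list is empty")
    present = [g for g in mmr_genes if g in matrix.index]
    if not present:
        raise ValueError(f"none of the MMR genes {mmr_genes} are in the matrix")
    counts = matrix.loc[present].sum(axis=0)
    a = counts[list(hypermutated)].to_numpy()
    b = counts[list(others)].to_numpy()
    return counts, rank_sum_test(a, b)


# ---------------------------------------------------------------------------
# CNV
# ---------------------------------------------------------------------------


def segments_to_gene_cnv(
    segments: list[CnvSegment], gene_models: list[GeneModel]
) -> pd.DataFrame:
    """Gene x sample CNV matrix: overlap-length-weighted mean of segment values.

    Genes with no overlapping segment in a sample are NaN.
    """
    samples = sorted({s.sample for s in segments})
    genes = [m.gene for m in gene_models]
    out = pd.DataFrame(np.nan, index=genes, columns=samples)
    by_sample: dict[str, list[CnvSegment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample, []).append(seg)
    for sample, segs in by_sample.items():
        starts = np.array([s.start for s in segs])
        ends = np.array([s.end for s in segs])
        values = np.array([s.value for s in segs])
        chroms = np.array([s.chrom for s in segs])
        for m in gene_models:
            ov = np.minimum(ends, m.end) - np.maximum(starts, m.start)
            mask = (ov > 0) & (chroms == m.chrom)
            if mask.any():
                w = ov[mask].astype(float)
                out.loc[m.gene, sample] = float((values[mask] * w).sum() / w.sum())
    return out


def differential_cnv(
    gene_cnv: pd.DataFrame,
    annotations: list[SampleAnnotation],
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Per-gene metastatic-vs-primary CNV comparison.

    Two-sided rank-sum p with BH across genes; significance requires both
    |median difference| > cnv_delta and adjusted p < alpha_adj.
    """
    met = [a.sample for a in annotations if a.cohort == "metastatic" and a.sample in gene_cnv.columns]
    prim = [a.sample for a in annotations if a.cohort == "primary" and a.sample in gene_cnv.columns]
    if not met or not prim:
        raise ValueError("need both metastatic and primary samples with CNV data")
    rows = []
    for gene, row in gene_cnv.iterrows():
        a = row[met].dropna().to_numpy()
        b = row[prim].dropna().to_numpy()
        if a.size == 0 or b.size == 0:
            continue
        rows.append(
            {
                "gene": gene,
                "median_met": float(np.median(a)),
                "median_primary": float(np.median(b)),
                "delta": float(np.median(a) - np.median(b)),
                "p": rank_sum_test(a, b),
            }
        )
    out = pd.DataFrame(rows)
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (out["delta"].abs() > thresholds.cnv_delta) & (
        out["adj_p"] < thresholds.alpha_adj
    )
    logger.info(
        "differential_cnv: %d genes tested, %d significant",
        len(out), int(out["significant"].sum()),
    )
    return out
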
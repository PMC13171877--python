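"""Chromatin-accessibility similarity between patient samples and models.

Works on a pre-normalized peak-count matrix: the top fraction of peaks
by variance (patients and models pooled) defines the panel, model-vs-
patient Spearman correlations quantify similarity, and paired model
comparisons over a common patient set use the two-sided Wilcoxon
signed-rank test (Pratt zero handling, exact null at small n). Because
the similarity is rank-based it is invariant to any monotone
renormalization of the counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from ._stats import signed_rank_test, spearman_matrix
from .core_io import parse_peak_label

logger = logging.getLogger("pcfidelity")


@dataclass
class VariablePeakPanel:
    peaks: list
    variances: pd.Series

    def __len__(self):
        return len(self.peaks)


def select_variable_peaks(peak_counts: pd.DataFrame, frac: float = 0.01) -> VariablePeakPanel:
    """The most variable ceil(frac * n) peaks across all samples.

    Ties break deterministically by peak coordinate.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    for label in peak_counts.index:
        parse_peak_label(label)
    n_top = ceil(frac * len(peak_counts))
    var = peak_counts.var(axis=1, ddof=1)
    order = (
        pd.DataFrame({"var": var})
        .sort_index()
        .sort_values("var", ascending=False, kind="mergesort")
    )
    peaks = order.index[:n_top].tolist()
    logger.info("select_variable_peaks: %d of %d peaks", n_top, len(peak_counts))
    return VariablePeakPanel(peaks=peaks, variances=var)


def atac_similarity(
    peak_counts: pd.DataFrame,
    panel: VariablePeakPanel | list,
    models,
    patients,
) -> pd.DataFrame:
    """Model x patient Spearman rho over the variable-peak panel."""
    peaks = panel.peaks if isinstance(panel, VariablePeakPanel) else list(panel)
    missing = [p for p in peaks if p not in peak_counts.index]
    if missing:
        raise KeyError(f"panel peaks missing from the matrix: {missing[:3]}...")
    models, patients = list(models), list(patients)
    sub = peak_counts.loc[peaks]
    rho = spearman_matrix(
        sub[models].to_numpy(dtype=float), sub[patients].to_numpy(dtype=float)
    )
    return pd.DataFrame(rho, index=models, columns=patients)


def subtype_summary(
    similarity: pd.DataFrame, patient_subtype: pd.Series
) -> pd.DataFrame:
    """Median model similarity per patient subtype."""
    out = {}
    for st in sorted(patient_subtype.unique()):
        cols = patient_subtype.index[patient_subtype == st]
        cols = [c for c in cols if c in similarity.columns]
        if cols:
            out[st] = similarity[cols].median(axis=1)
    return pd.DataFrame(out)


def paired_compare(sim_a: pd.Series, sim_b: pd.Series) -> float:
    """Two-sided signed-rank p comparing two models over the same patients."""
    if len(sim_a) < 5 or len(sim_b) < 5:
        raise ValueError("need at least 5 paired patients")
    if not sim_a.index.equals(sim_b.index):
        a, b = sim_a.align(sim_b, join="inner")
        if len(a) < len(sim_a) or len(a) < len(sim_b):
            warnings.warn("patient sets differ; comparing the shared subset")
        if len(a) < 5:
            raise ValueError("fewer than 5 shared patients")
        sim_a, sim_b = a, b
    return signed_rank_test(sim_a.to_numpy(dtype=float), sim_b.to_numpy(dtype=float))
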
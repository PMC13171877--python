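"""Seeded generator of coupled multi-omics cohorts with planted ground truth.

The generator emulates the statistical structure of the public prostate
cancer compendia the pipeline is designed for: a large primary cohort, a
metastatic cohort stratified by biopsy site (bone, liver, lymph node), a
small panel of cell-line models, and three transcriptional subtypes
(ARPC / NEPC / MSPC) tied to epithelial lineages (luminal /
neuroendocrine / basal). Planted effects — differentially mutated genes,
hypermutators with mismatch-repair lesions, hotspot variants, an
AR-amplification-like CNV, subtype expression programs, and
subtype-specific accessible peak blocks — are recorded in a TruthLedger
for recovery testing.

A single root seed drives independent sub-streams per data modality
(cohort design, mutations, CNV, expression, ATAC), so changing one
modality's parameters does not perturb the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .core_io import (
    CnvSegment,
    GeneModel,
    GeneSet,
    MutationRecord,
    SampleAnnotation,
)

# ---------------------------------------------------------------------------
# Named gene groups
# ---------------------------------------------------------------------------

ARPC_MARKERS = ("AR", "KLK2", "KLK3", "KLK4")
NEPC_MARKERS = ("SYP", "CHGA", "ASCL1")
MSPC_MARKERS = ("CD44", "VIM", "TP63", "KRT5")
IMMUNE_GENES = ("CD3D", "CD3E", "CD8A", "CD8B", "GZMA", "GZMB", "PRF1", "PDCD1", "CTLA4")
MMR_GENES = ("MLH1", "MSH2", "MSH6", "PMS2")
CTL_GENES = ("CD8A", "CD8B", "GZMA", "GZMB", "PRF1")

LINEAGE_MARKERS = {
    "luminal": ("KLK2", "KLK4", "ACPP"),
    "basal": ("KRT5", "TP63", "KRT17", "KRT15"),
    "neuroendocrine": (
        "ASCL1",
        "FOXA2",
        "MYCN",
        "POU3F2",
        "SIAH2",
        "NCAM1",
        "CHGA",
        "CHGB",
        "SYP",
        "ENO2",
    ),
}

SUBTYPE_LINEAGE = {"ARPC": "luminal", "NEPC": "neuroendocrine", "MSPC": "basal"}

NAMED_GENES = tuple(
    dict.fromkeys(
        ARPC_MARKERS
        + NEPC_MARKERS
        + MSPC_MARKERS
        + IMMUNE_GENES
        + MMR_GENES
        + sum((tuple(v) for v in LINEAGE_MARKERS.values()), ())
    )
)

_NONSYN_CLASSES = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "In_Frame_Del",
    "Splice_Site",
)
_NONSYN_WEIGHTS = (0.62, 0.10, 0.10, 0.08, 0.05, 0.05)
_SILENT_DRAW_CLASSES = ("Silent", "Intron", "3'UTR", "5'UTR")
_SILENT_DRAW_WEIGHTS = (0.7, 0.15, 0.08, 0.07)
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults define the standard study conditions."""

    seed: int = 0
    n_primary: int = 300
    n_met_per_site: dict = field(
        default_factory=lambda: {"bone": 60, "liver": 40, "lymph_node": 40}
    )
    n_cell_lines: int = 12
    n_genes: int = 2000
    n_diff_genes: int = 40
    diff_delta: float = 0.10
    n_high_genes: int = 25
    high_mut_prob: float = 0.12
    hyper_frac: float = 0.03
    hyper_multiplier: float = 30.0
    mmr_hyper_prob: float | None = 0.4
    silent_rate: float = 0.4
    n_hotspots: int = 10
    subtype_mix: dict = field(
        default_factory=lambda: {"ARPC": 0.6, "NEPC": 0.2, "MSPC": 0.2}
    )
    expr_noise_sd: float = 0.5
    sc_noise_sd: float = 1.0
    marker_shift: float = 4.0
    program_shift: float = 2.0
    n_program_genes: int = 100
    model_drift_sd: float = 1.2
    delta_imm: float = 1.5
    n_cells_per_sample: int = 8
    n_normal_cells_per_type: int = 40
    n_peaks: int = 10000
    atac_frac_per_subtype: float = 0.05
    atac_shift: float = 1.4
    atac_noise_sd: float = 0.4
    atac_drift_sd: float = 0.8
    n_cnv_genes: int = 200
    genes_per_segment: int = 10
    cnv_background_sd: float = 0.1
    cnv_ar_amp: float = 0.8

    def __post_init__(self):
        if abs(sum(self.subtype_mix.values()) - 1.0) > 1e-9:
            raise ValueError("subtype_mix proportions must sum to 1")
        if self.hyper_multiplier < 1:
            raise ValueError("hyper_multiplier must be >= 1")
        for name in ("n_primary", "n_cell_lines", "n_genes", "n_peaks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        planted = (
            self.n_diff_genes
            + self.n_high_genes
            + self.n_hotspots
            + 6 * self.n_program_genes  # three lineage + three subtype programs
        )
        if self.n_genes < len(NAMED_GENES) + planted:
            raise ValueError(
                "n_genes too small for the planted gene groups and programs "
                f"(need >= {len(NAMED_GENES) + planted})"
            )

    def with_overrides(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """A configuration with every planted effect switched off.

    Mutation probabilities become exchangeable across cohorts, burdens
    unimodal, expression centroids identical for all subtypes and models,
    and peak accessibility free of subtype structure.
    """
    base = dict(
        seed=seed,
        diff_delta=0.0,
        n_high_genes=0,
        hyper_multiplier=1.0,
        mmr_hyper_prob=None,  # falls back to baseline
        n_hotspots=0,
        marker_shift=0.0,
        program_shift=0.0,
        model_drift_sd=0.0,
        delta_imm=0.0,
        atac_shift=0.0,
        atac_drift_sd=0.0,
        cnv_ar_amp=0.0,
    )
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class TruthLedger:
    """Planted ground truth for recovery tests."""

    diff_genes: list = field(default_factory=list)
    high_mut_genes: list = field(default_factory=list)
    hotspot_variants: list = field(default_factory=list)
    hypermutated_samples: list = field(default_factory=list)
    sample_subtype: dict = field(default_factory=dict)
    cell_lineage: dict = field(default_factory=dict)
    matched_model: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthLedger":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Cohort design (shared across modalities)
# ---------------------------------------------------------------------------

_STREAMS = ("design", "mutations", "cnv", "expression", "atac")


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    idx = _STREAMS.index(stream)
    child = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))[idx]
    return np.random.default_rng(child)


def gene_universe(config: SimConfig) -> list[str]:
    """Gene symbols: the named marker genes first, then numbered fillers."""
    fillers = [f"G{i:04d}" for i in range(config.n_genes - len(NAMED_GENES))]
    return list(NAMED_GENES) + fillers


@dataclass(frozen=True)
class CohortDesign:
    genes: tuple
    annotations: tuple  # SampleAnnotation, ordered primary / met / cell lines
    subtype_of: dict  # sample -> ARPC/NEPC/MSPC (all samples)
    hypermutated: tuple
    matched_model: dict  # subtype -> designated cell line
    diff_genes: tuple
    high_genes: tuple
    hotspot_genes: tuple
    programs: dict  # name -> tuple of genes (lineage and subtype programs)

    @property
    def samples(self) -> list[str]:
        return [a.sample for a in self.annotations]

    @property
    def metastatic_samples(self) -> list[str]:
        return [a.sample for a in self.annotations if a.cohort == "metastatic"]

    @property
    def cell_lines(self) -> list[str]:
        return [a.sample for a in self.annotations if a.cohort == "cell_line"]


def design_cohort(config: SimConfig) -> CohortDesign:
    rng = _rng(config, "design")
    genes = gene_universe(config)

    subtypes = sorted(config.subtype_mix)
    probs = np.array([config.subtype_mix[s] for s in subtypes])

    annotations: list[SampleAnnotation] = []
    subtype_of: dict[str, str] = {}
    for i in range(config.n_primary):
        s = f"P{i + 1:04d}"
        annotations.append(SampleAnnotation(s, "primary", "primary"))
        subtype_of[s] = "ARPC"  # primary adenocarcinoma is luminal/AR-driven
    for site, n in config.n_met_per_site.items():
        for i in range(n):
            s = f"M_{site}_{i + 1:03d}"
            st = str(rng.choice(subtypes, p=probs))
            # the AR+/NE+ literature-style label; MSPC is double-negative
            label = st if st in ("ARPC", "NEPC") else None
            annotations.append(SampleAnnotation(s, "metastatic", site, label))
            subtype_of[s] = st
    designated = {}
    for i in range(config.n_cell_lines):
        s = f"CL{i + 1:02d}"
        if i < len(SUBTYPE_LINEAGE):
            st = list(SUBTYPE_LINEAGE)[i]  # one designated line per subtype
            designated[st] = s
        else:
            st = str(rng.choice(subtypes, p=probs))
        annotations.append(SampleAnnotation(s, "cell_line", "none"))
        subtype_of[s] = st

    samples = [a.sample for a in annotations]
    n_hyper = round(len(samples) * config.hyper_frac)
    hyper = tuple(sorted(rng.choice(samples, size=n_hyper, replace=False).tolist()))

    # disjoint planted gene groups drawn from the filler genes
    fillers = [g for g in genes if g not in NAMED_GENES]
    perm = rng.permutation(len(fillers))
    cursor = 0

    def take(n):
        nonlocal cursor
        out = tuple(fillers[i] for i in perm[cursor : cursor + n])
        cursor += n
        return out

    diff = take(config.n_diff_genes)
    high = take(config.n_high_genes)
    hot = take(config.n_hotspots)
    programs = {}
    for lineage in LINEAGE_MARKERS:
        programs[f"lineage:{lineage}"] = take(config.n_program_genes)
    for st in SUBTYPE_LINEAGE:
        programs[f"subtype:{st}"] = take(config.n_program_genes)

    return CohortDesign(
        genes=tuple(genes),
        annotations=tuple(annotations),
        subtype_of=subtype_of,
        hypermutated=hyper,
        matched_model=designated,
        diff_genes=tuple(sorted(diff)),
        high_genes=tuple(sorted(high)),
        hotspot_genes=hot,
        programs=programs,
    )


def _ledger_from_design(design: CohortDesign) -> TruthLedger:
    return TruthLedger(
        diff_genes=list(design.diff_genes),
        high_mut_genes=list(design.high_genes),
        hypermutated_samples=list(design.hypermutated),
        sample_subtype=dict(design.subtype_of),
        matched_model=dict(design.matched_model),
    )


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------


def simulate_mutations(config: SimConfig, design: CohortDesign | None = None):
    """Simulate somatic mutation records.

    Returns ``(records, annotations, burden, ledger)`` where burden is a
    per-sample Series counting all records (silent included) and the
    ledger holds the planted truth for this modality.
    """
    design = design or design_cohort(config)
    rng = _rng(config, "mutations")
    genes = np.array(design.genes)
    samples = design.samples
    ann = {a.sample: a for a in design.annotations}
    n_g, n_s = len(genes), len(samples)

    baseline = rng.beta(0.5, 60.0, size=n_g)
    gene_idx = {g: i for i, g in enumerate(genes)}
    p = np.tile(baseline, (n_s, 1))

    met_rows = [i for i, s in enumerate(samples) if ann[s].cohort == "metastatic"]
    diff_cols = [gene_idx[g] for g in design.diff_genes]
    if diff_cols and met_rows:
        p[np.ix_(met_rows, diff_cols)] += config.diff_delta
    high_cols = [gene_idx[g] for g in design.high_genes]
    if high_cols:
        p[:, high_cols] = config.high_mut_prob

    hyper_rows = [i for i, s in enumerate(samples) if s in set(design.hypermutated)]
    if hyper_rows:
        p[hyper_rows] = p[hyper_rows] * config.hyper_multiplier
        mmr_cols = [gene_idx[g] for g in MMR_GENES]
        if config.mmr_hyper_prob is not None:
            p[np.ix_(hyper_rows, mmr_cols)] = config.mmr_hyper_prob
    np.clip(p, 0.0, 0.95, out=p)

    nonsyn = rng.random(p.shape) < p
    p_sil = np.clip(p * config.silent_rate, 0.0, 0.95)
    silent = rng.random(p.shape) < p_sil

    records: list[MutationRecord] = []
    for hit_matrix, classes, weights, with_protein in (
        (nonsyn, _NONSYN_CLASSES, _NONSYN_WEIGHTS, True),
        (silent, _SILENT_DRAW_CLASSES, _SILENT_DRAW_WEIGHTS, False),
    ):
        rows, cols = np.nonzero(hit_matrix)
        classes_drawn = rng.choice(classes, size=rows.size, p=weights)
        positions = rng.integers(1, 1000, size=rows.size)
        aa = rng.integers(0, len(_AA), size=(rows.size, 2))
        for k in range(rows.size):
            pc = ""
            if with_protein:
                pc = f"p.{_AA[aa[k, 0]]}{positions[k]}{_AA[aa[k, 1]]}"
            records.append(
                MutationRecord(
                    gene=str(genes[cols[k]]),
                    sample=samples[rows[k]],
                    variant_class=str(classes_drawn[k]),
                    protein_change=pc,
                )
            )

    # hotspot variants: identical protein change in >=3 metastatic carriers
    hotspot_entries = []
    met_samples = design.metastatic_samples
    cell_lines = design.cell_lines
    for g in design.hotspot_genes:
        pos = int(rng.integers(30, 900))
        pc = f"p.{_AA[rng.integers(0, len(_AA))]}{pos}{_AA[rng.integers(0, len(_AA))]}"
        n_carriers = int(rng.integers(3, 7))
        carriers = sorted(rng.choice(met_samples, size=n_carriers, replace=False).tolist())
        line_carriers = sorted(s for s in cell_lines if rng.random() < 0.25)
        for s in carriers + line_carriers:
            records.append(MutationRecord(g, s, "Missense_Mutation", pc))
        hotspot_entries.append(
            {
                "gene": g,
                "protein_change": pc,
                "carriers": carriers,
                "cell_line_carriers": line_carriers,
            }
        )

    burden = (
        pd.Series([r.sample for r in records], name="burden")
        .value_counts()
        .reindex(samples, fill_value=0)
        .rename_axis("sample")
    )
    ledger = _ledger_from_design(design)
    ledger.hotspot_variants = hotspot_entries
    return records, list(design.annotations), burden, ledger


# ---------------------------------------------------------------------------
# CNV
# ---------------------------------------------------------------------------


def cnv_gene_models(config: SimConfig) -> list[GeneModel]:
    """Gene models for the CNV-profiled genes (the first n_cnv_genes)."""
    genes = gene_universe(config)[: config.n_cnv_genes]
    return [
        GeneModel(g, "chr1", i * 10_000, i * 10_000 + 5_000) for i, g in enumerate(genes)
    ]


def simulate_cnv(config: SimConfig, design: CohortDesign | None = None) -> list[CnvSegment]:
    """Simulate per-sample CNV segments over a toy genome.

    Background segment values are N(0, cnv_background_sd); the segment
    covering AR gains ``cnv_ar_amp`` in metastatic samples.
    """
    design = design or design_cohort(config)
    rng = _rng(config, "cnv")
    models = cnv_gene_models(config)
    ar_start = next(m.start for m in models if m.gene == "AR")
    seg_span = config.genes_per_segment * 10_000
    n_segments = -(-config.n_cnv_genes // config.genes_per_segment)
    segments = []
    for a in design.annotations:
        values = rng.normal(0.0, config.cnv_background_sd, size=n_segments)
        for j in range(n_segments):
            start, end = j * seg_span, (j + 1) * seg_span
            v = values[j]
            if a.cohort == "metastatic" and start <= ar_start < end:
                v += config.cnv_ar_amp
            segments.append(CnvSegment(a.sample, "chr1", start, end, float(v)))
    return segments


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionSim:
    bulk: pd.DataFrame  # genes x samples (all cohorts)
    sc: pd.DataFrame  # genes x malignant cells (metastatic samples)
    cell_meta: pd.DataFrame  # cell, sample, subtype, lineage
    normal_sc: pd.DataFrame  # genes x normal epithelial cells
    normal_labels: pd.Series  # cell -> lineage


def subtype_centroids(config: SimConfig, design: CohortDesign) -> pd.DataFrame:
    """Deterministic (given seed) log2-scale expression centroid per subtype."""
    rng = _rng(config, "expression")  # first draws of the expression stream
    base = rng.uniform(2.0, 8.0, size=len(design.genes))
    centroids = {}
    gi = {g: i for i, g in enumerate(design.genes)}
    for st, lineage in SUBTYPE_LINEAGE.items():
        c = base.copy()
        for g in LINEAGE_MARKERS[lineage]:
            c[gi[g]] += config.marker_shift
        for g in design.programs[f"lineage:{lineage}"]:
            c[gi[g]] += config.program_shift
        extra = {"ARPC": ("AR", "KLK3"), "NEPC": (), "MSPC": ("CD44", "VIM")}[st]
        for g in extra:
            c[gi[g]] += config.marker_shift
        for g in design.programs[f"subtype:{st}"]:
            c[gi[g]] += config.program_shift
        centroids[st] = c
    lineage_centroids = {}
    for lineage in LINEAGE_MARKERS:
        c = base.copy()
        for g in LINEAGE_MARKERS[lineage]:
            c[gi[g]] += config.marker_shift
        for g in design.programs[f"lineage:{lineage}"]:
            c[gi[g]] += config.program_shift
        lineage_centroids[lineage] = c
    df = pd.DataFrame(centroids, index=list(design.genes))
    for lineage, c in lineage_centroids.items():
        df[f"lineage:{lineage}"] = c
    return df


def simulate_expression(config: SimConfig, design: CohortDesign | None = None) -> ExpressionSim:
    """Simulate bulk, malignant single-cell, and normal-reference expression."""
    design = design or design_cohort(config)
    rng = _rng(config, "expression")
    genes = list(design.genes)
    gi = {g: i for i, g in enumerate(genes)}
    n_g = len(genes)

    base = rng.uniform(2.0, 8.0, size=n_g)  # identical to subtype_centroids draw
    cents = subtype_centroids(config, design)
    hyper = set(design.hypermutated)
    imm_idx = [gi[g] for g in IMMUNE_GENES]

    drift = {}
    for a in design.annotations:
        if a.cohort == "cell_line" and a.sample not in design.matched_model.values():
            drift[a.sample] = rng.normal(0.0, config.model_drift_sd, size=n_g)

    bulk = np.empty((n_g, len(design.annotations)))
    for j, a in enumerate(design.annotations):
        mu = cents[design.subtype_of[a.sample]].to_numpy().copy()
        if a.sample in drift:
            mu = mu + drift[a.sample]
        if a.cohort == "primary" and a.sample in hyper:
            mu[imm_idx] += config.delta_imm
        bulk[:, j] = mu + rng.normal(0.0, config.expr_noise_sd, size=n_g)
    bulk_df = pd.DataFrame(
        np.clip(bulk, 0.0, None), index=genes, columns=design.samples
    )

    cells, cell_rows = [], []
    for a in design.annotations:
        if a.cohort != "metastatic":
            continue
        st = design.subtype_of[a.sample]
        mu = cents[st].to_numpy()
        for k in range(config.n_cells_per_sample):
            cell = f"{a.sample}.c{k + 1:02d}"
            cells.append(mu + rng.normal(0.0, config.sc_noise_sd, size=n_g))
            cell_rows.append(
                {
                    "cell": cell,
                    "sample": a.sample,
                    "subtype": st,
                    "lineage": SUBTYPE_LINEAGE[st],
                }
            )
    sc_df = pd.DataFrame(
        np.clip(np.column_stack(cells), 0.0, None) if cells else np.empty((n_g, 0)),
        index=genes,
        columns=[r["cell"] for r in cell_rows],
    )
    cell_meta = pd.DataFrame(cell_rows).set_index("cell") if cell_rows else pd.DataFrame(
        columns=["sample", "subtype", "lineage"]
    )

    normal_cols, normal_labels = [], {}
    for lineage in LINEAGE_MARKERS:
        mu = cents[f"lineage:{lineage}"].to_numpy()
        for k in range(config.n_normal_cells_per_type):
            cell = f"N_{lineage}_{k + 1:03d}"
            normal_cols.append(mu + rng.normal(0.0, config.expr_noise_sd, size=n_g))
            normal_labels[cell] = lineage
    normal_df = pd.DataFrame(
        np.clip(np.column_stack(normal_cols), 0.0, None),
        index=genes,
        columns=list(normal_labels),
    )

    return ExpressionSim(
        bulk=bulk_df,
        sc=sc_df,
        cell_meta=cell_meta,
        normal_sc=normal_df,
        normal_labels=pd.Series(normal_labels, name="lineage"),
    )


def emt_stemness_sets(config: SimConfig, design: CohortDesign | None = None) -> list[GeneSet]:
    """Synthetic EMT and stemness signatures tied to the MSPC program.

    Stands in for published signature lists: each set mixes canonical
    MSPC/basal markers with half of the planted MSPC program so that MSPC
    samples score high on both.
    """
    design = design or design_cohort(config)
    prog = list(design.programs["subtype:MSPC"])
    half = len(prog) // 2
    emt = frozenset(["VIM", "CD44"] + prog[:half])
    stem = frozenset(["TP63", "KRT5"] + prog[half:])
    return [GeneSet("EMT", emt), GeneSet("STEMNESS", stem)]


# ---------------------------------------------------------------------------
# ATAC
# ---------------------------------------------------------------------------


def simulate_atac(config: SimConfig, design: CohortDesign | None = None) -> pd.DataFrame:
    """Simulate a normalized peak-count matrix (peaks x samples).

    A disjoint block of ``atac_frac_per_subtype`` of the peaks is more
    accessible (log-scale shift) in each subtype's metastatic samples and
    in cell lines of that subtype. Counts are lognormal around a shared
    per-peak baseline. Columns cover metastatic samples and cell lines.
    """
    design = design or design_cohort(config)
    rng = _rng(config, "atac")
    n_p = config.n_peaks
    peak_labels = [f"chr1:{i * 1000}-{i * 1000 + 500}" for i in range(n_p)]
    base = rng.normal(3.0, 0.5, size=n_p)

    block_size = int(config.atac_frac_per_subtype * n_p)
    perm = rng.permutation(n_p)
    blocks = {
        st: perm[i * block_size : (i + 1) * block_size]
        for i, st in enumerate(SUBTYPE_LINEAGE)
    }

    atac_ann = [
        a for a in design.annotations if a.cohort in ("metastatic", "cell_line", "organoid")
    ]
    cols = [a.sample for a in atac_ann]
    designated = set(design.matched_model.values())
    values = np.empty((n_p, len(cols)))
    for j, a in enumerate(atac_ann):
        s = a.sample
        mu = base.copy()
        st = design.subtype_of[s]
        mu[blocks[st]] += config.atac_shift
        if a.cohort != "metastatic" and s not in designated:
            mu = mu + rng.normal(0.0, config.atac_drift_sd, size=n_p)
        values[:, j] = np.exp(mu + rng.normal(0.0, config.atac_noise_sd, size=n_p))
    return pd.DataFrame(values, index=peak_labels, columns=cols)


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    config: SimConfig
    design: CohortDesign
    records: list
    annotations: list
    burden: pd.Series
    segments: list
    gene_models: list
    expression: ExpressionSim
    atac: pd.DataFrame
    gene_sets: list
    ledger: TruthLedger


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate every modality under one root seed, with the truth ledger."""
    design = design_cohort(config)
    records, annotations, burden, ledger = simulate_mutations(config, design)
    segments = simulate_cnv(config, design)
    expression = simulate_expression(config, design)
    atac = simulate_atac(config, design)
    ledger.cell_lineage = expression.cell_meta["lineage"].to_dict()
    return SyntheticCohort(
        config=config,
        design=design,
        records=records,
        annotations=annotations,
        burden=burden,
        segments=segments,
        gene_models=cnv_gene_models(config),
        expression=expression,
        atac=atac,
        gene_sets=emt_stemness_sets(config, design),
        ledger=ledger,
    )
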
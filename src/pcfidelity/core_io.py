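"""Domain types and readers/writers for the standard formats.

All genomic intervals are 0-based half-open internally. SEG input is
treated as 1-based inclusive and converted at the I/O boundary; peak
labels ("chrom:start-end") are already 0-based half-open. Every reader
transparently accepts gzip-compressed files.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Variant-class vocabulary (MAF "Variant_Classification")
# ---------------------------------------------------------------------------

VARIANT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Targeted_Region",
        "Silent",
        "Intron",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "RNA",
        "IGR",
        "Splice_Region",
    }
)

#: Classes excluded when restricting to non-synonymous mutations. The
#: exclusion is broader than "Silent" alone: all non-coding classes are
#: dropped. Callers may pass their own list everywhere it is used.
DEFAULT_SILENT_CLASSES = frozenset(
    {
        "Silent",
        "Intron",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "RNA",
        "IGR",
        "Splice_Region",
    }
)

COHORTS = frozenset({"primary", "metastatic", "cell_line", "organoid"})
METASTATIC_SITES = ("bone", "liver", "lymph_node")
SITES = frozenset(METASTATIC_SITES) | {"primary", "none"}
SUBTYPES = ("ARPC", "NEPC", "MSPC")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call (one MAF row)."""

    gene: str
    sample: str
    variant_class: str
    protein_change: str = ""

    def __post_init__(self):
        if not self.gene or not self.sample:
            raise ValueError("gene and sample must be non-empty")

    def is_silent(self, silent_classes: frozenset = DEFAULT_SILENT_CLASSES) -> bool:
        return self.variant_class in silent_classes


@dataclass(frozen=True)
class SampleAnnotation:
    sample: str
    cohort: str
    site: str = "none"
    subtype_label: str | None = None

    def __post_init__(self):
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")
        if self.cohort == "metastatic" and self.site not in METASTATIC_SITES:
            raise ValueError(
                f"metastatic sample {self.sample} must have a metastatic site"
            )
        if self.cohort != "metastatic" and self.site in METASTATIC_SITES:
            raise ValueError(
                f"non-metastatic sample {self.sample} cannot have site {self.site}"
            )


@dataclass(frozen=True)
class CnvSegment:
    """Copy-number segment, 0-based half-open, log-ratio value."""

    sample: str
    chrom: str
    start: int
    end: int
    value: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"segment start must precede end ({self.start}, {self.end})")


@dataclass(frozen=True)
class GeneModel:
    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"gene start must precede end ({self.start}, {self.end})")


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset

    def intersect(self, available: Iterable[str]) -> frozenset:
        return self.genes & set(available)


@dataclass(frozen=True)
class PeakRegion:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"peak start must precede end ({self.start}, {self.end})")

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Thresholds:
    """All tunable cutoffs of the pipeline, with their defaults."""

    alpha_adj: float = 0.05
    min_sites_sig: int = 2
    high_mut_freq: float = 0.05  # strictly exceeded
    hotspot_min_samples: int = 3
    cnv_delta: float = 0.3
    de_abs_log2fc: float = 1.0
    n_hvg: int = 1000
    n_lineage_genes: int = 5000
    peak_top_frac: float = 0.01
    mspc_quantile: float = 0.25  # top quartile
    n_pc1_genes: int = 200
    n_pc1_peaks: int = 1000
    gap_top_frac: float = 0.2
    gap_min_log10: float = 0.5

    def __post_init__(self):
        for name in ("alpha_adj", "high_mut_freq", "peak_top_frac", "mspc_quantile"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in (
            "min_sites_sig",
            "hotspot_min_samples",
            "cnv_delta",
            "de_abs_log2fc",
            "n_hvg",
            "n_lineage_genes",
            "n_pc1_genes",
            "n_pc1_peaks",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_overrides(self, **kwargs) -> "Thresholds":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _open(path, mode: str = "rt") -> IO:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def parse_peak_label(label: str) -> PeakRegion:
    """Parse "chrom:start-end" (0-based half-open) into a PeakRegion."""
    try:
        chrom, span = label.rsplit(":", 1)
        start_s, end_s = span.split("-")
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise FormatError(f"malformed peak label {label!r}") from exc
    if start >= end:
        raise FormatError(f"peak label {label!r} has start >= end")
    return PeakRegion(chrom, start, end)


def read_maf(path) -> tuple[list[MutationRecord], list[SampleAnnotation]]:
    """Read a MAF-style TSV into mutation records plus sample annotations.

    Mandatory columns: Hugo_Symbol, Tumor_Sample_Barcode,
    Variant_Classification. HGVSp_Short is optional, as are Cohort/Site
    columns; when the latter are absent every sample is annotated as a
    primary-cohort sample. Unknown variant classes are preserved but
    trigger a warning.
    """
    df = pd.read_csv(_open(path), sep="\t", dtype=str, comment="#").fillna("")
    for col in ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"):
        if col not in df.columns:
            raise FormatError(f"MAF file missing mandatory column {col!r}")
    unknown = set(df["Variant_Classification"]) - VARIANT_CLASSES
    if unknown:
        warnings.warn(f"unknown variant classes preserved: {sorted(unknown)}")
    records = [
        MutationRecord(
            gene=row.Hugo_Symbol,
            sample=row.Tumor_Sample_Barcode,
            variant_class=row.Variant_Classification,
            protein_change=getattr(row, "HGVSp_Short", ""),
        )
        for row in df.itertuples(index=False)
    ]
    have_meta = "Cohort" in df.columns
    annotations = []
    seen = set()
    for row in df.itertuples(index=False):
        s = row.Tumor_Sample_Barcode
        if s in seen:
            continue
        seen.add(s)
        if have_meta:
            annotations.append(
                SampleAnnotation(s, row.Cohort, getattr(row, "Site", "none"))
            )
        else:
            annotations.append(SampleAnnotation(s, "primary", "primary"))
    return records, annotations


def write_maf(records: Sequence[MutationRecord], path, annotations=None) -> None:
    ann = {a.sample: a for a in annotations or []}
    rows = []
    for r in records:
        row = {
            "Hugo_Symbol": r.gene,
            "Tumor_Sample_Barcode": r.sample,
            "Variant_Classification": r.variant_class,
            "HGVSp_Short": r.protein_change,
        }
        if ann:
            a = ann.get(r.sample)
            row["Cohort"] = a.cohort if a else ""
            row["Site"] = a.site if a else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(_open(path, "wt"), sep="\t", index=False)


def read_annotations(path) -> list[SampleAnnotation]:
    """Read a sample/cohort/site(/subtype) TSV."""
    df = pd.read_csv(_open(path), sep="\t", dtype=str).fillna("")
    for col in ("sample", "cohort", "site"):
        if col not in df.columns:
            raise FormatError(f"annotation file missing column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        subtype = getattr(row, "subtype_label", "") or None
        out.append(SampleAnnotation(row.sample, row.cohort, row.site, subtype))
    return out


def write_annotations(annotations: Sequence[SampleAnnotation], path) -> None:
    pd.DataFrame(
        [
            {
                "sample": a.sample,
                "cohort": a.cohort,
                "site": a.site,
                "subtype_label": a.subtype_label or "",
            }
            for a in annotations
        ]
    ).to_csv(_open(path, "wt"), sep="\t", index=False)


def read_seg(path) -> list[CnvSegment]:
    """Read a SEG-style file, converting 1-based inclusive to 0-based half-open."""
    segments = []
    with _open(path) as fh:
        header = fh.readline()
        if not header:
            return segments
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise FormatError(f"line {lineno}: expected 5 columns")
            sample, chrom, start_s, end_s, value_s = parts[:5]
            try:
                start1, end1, value = int(start_s), int(end_s), float(value_s)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-numeric field") from exc
            if start1 > end1:
                raise FormatError(f"line {lineno}: start > end")
            segments.append(CnvSegment(sample, chrom, start1 - 1, end1, value))
    return segments


def write_seg(segments: Sequence[CnvSegment], path) -> None:
    with _open(path, "wt") as fh:
        fh.write("sample\tchrom\tstart\tend\tvalue\n")
        for s in segments:
            # back to the 1-based inclusive SEG convention
            fh.write(f"{s.sample}\t{s.chrom}\t{s.start + 1}\t{s.end}\t{s.value:g}\n")


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from a BED-like TSV (gene, chrom, start, end; 0-based)."""
    df = pd.read_csv(_open(path), sep="\t")
    for col in ("gene", "chrom", "start", "end"):
        if col not in df.columns:
            raise FormatError(f"gene model file missing column {col!r}")
    return [
        GeneModel(row.gene, row.chrom, int(row.start), int(row.end))
        for row in df.itertuples(index=False)
    ]


def write_gene_models(models: Sequence[GeneModel], path) -> None:
    pd.DataFrame(
        [{"gene": m.gene, "chrom": m.chrom, "start": m.start, "end": m.end} for m in models]
    ).to_csv(_open(path, "wt"), sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV of log2(normalized expression + 1) values."""
    df = pd.read_csv(_open(path), sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene labels: {dups}")
    values = df.to_numpy()
    if not np.isfinite(values).all():
        raise FormatError("expression matrix contains non-finite values")
    df.index.name = None
    if (values < 0).any():
        raise FormatError(
            "negative expression values; expected log2(normalized + 1) input "
            "(log-transform upstream)"
        )
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(_open(path, "wt"), sep="\t", index_label="gene")


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file: name, description, then member genes per line."""
    sets = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: GMT line needs name, desc, genes")
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise FormatError(f"line {lineno}: gene set {parts[0]!r} is empty")
            sets.append(GeneSet(parts[0], genes))
    return sets


def write_gmt(sets: Sequence[GeneSet], path) -> None:
    with _open(path, "wt") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *sorted(s.genes)]) + "\n")


def read_peak_counts(path) -> pd.DataFrame:
    """Read a peaks x samples TSV with "chrom:start-end" row labels."""
    df = pd.read_csv(_open(path), sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise FormatError("duplicate peak coordinates")
    for label in df.index:
        parse_peak_label(label)  # validates
    values = df.to_numpy()
    if not np.isfinite(values).all() or (values < 0).any():
        raise FormatError("peak counts must be finite and non-negative")
    df.index.name = None
    return df


def write_peak_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(_open(path, "wt"), sep="\t", index_label="peak")
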
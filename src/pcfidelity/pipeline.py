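"""End-to-end orchestration with config, manifests, and the fidelity report.

A run is driven by a YAML-style config (stages to run, synthetic-cohort
parameters or input paths, threshold overrides). Stages execute in
dependency order, write plain-text outputs under the run directory, and
a manifest records the resolved config plus SHA256 digests of every
file so that a rerun with an identical config is verifiably
byte-identical. The consolidated fidelity report summarizes, per model,
every stage's view: panel-mutation concordance, burden-normalized
concordance, hotspot carriage, hypermutation status, transcriptomic
similarity ranks (overall and per metastatic site), chromatin
similarity per subtype, and the assigned subtype/lineage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import atac as atac_mod
from . import genomics, subtypes, transcriptomics
from .core_io import (
    Thresholds,
    read_annotations,
    read_expression,
    read_gene_models,
    read_gmt,
    read_maf,
    read_peak_counts,
    read_seg,
    write_annotations,
    write_expression,
    write_gene_models,
    write_gmt,
    write_maf,
    write_peak_counts,
    write_seg,
)
from .synthetic import (
    MMR_GENES,
    SimConfig,
    simulate_cohort,
)

logger = logging.getLogger("pcfidelity")

ALL_STAGES = ("simulate", "genomics", "tc", "subtype", "lineage", "atac", "report")

_STAGE_INPUTS = {
    "genomics": ("maf", "annotations", "seg", "gene_models"),
    "tc": ("expression", "annotations"),
    "subtype": ("expression", "annotations", "gene_sets", "sc", "cell_meta"),
    "lineage": ("sc", "normal_sc", "normal_labels", "expression", "annotations"),
    "atac": ("peaks", "annotations"),
}


class PipelineError(RuntimeError):
    pass


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return dict(path_or_dict)
    with open(path_or_dict) as fh:
        return yaml.safe_load(fh) or {}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _thresholds(config: dict) -> Thresholds:
    overrides = config.get("thresholds", {}) or {}
    valid = {f.name for f in fields(Thresholds)}
    unknown = set(overrides) - valid
    if unknown:
        raise PipelineError(f"unknown threshold keys: {sorted(unknown)}")
    return Thresholds(**overrides)


def run_pipeline(config, out_dir, seed: int | None = None) -> dict:
    """Run the configured stages; returns the manifest dictionary."""
    config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        try:
            json.loads(manifest_path.read_text())
        except json.JSONDecodeError as exc:
            raise PipelineError(f"corrupt manifest at {manifest_path}") from exc

    stages = list(config.get("stages", ALL_STAGES))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    thresholds = _thresholds(config)
    if seed is None:
        seed = int(config.get("seed", 0))

    inputs = dict(config.get("inputs", {}) or {})
    if "simulate" not in stages:
        # pre-flight: every requested stage must have its inputs
        for stage in stages:
            for key in _STAGE_INPUTS.get(stage, ()):
                if key not in inputs:
                    raise PipelineError(
                        f"stage {stage!r} requires input {key!r}, not configured"
                    )
                if not Path(inputs[key]).exists():
                    raise PipelineError(
                        f"stage {stage!r} input {key!r} missing: {inputs[key]}"
                    )

    data: dict = {}
    if "simulate" in stages:
        sim_overrides = dict(config.get("synthetic", {}) or {})
        sim_overrides["seed"] = seed
        sim_config = SimConfig(**sim_overrides)
        data = _stage_simulate(sim_config, out)
        inputs = data.pop("_paths")
    else:
        data = _load_inputs(inputs, stages)

    for stage in stages:
        if stage in ("simulate", "report"):
            continue
        globals()[f"_stage_{stage}"](data, out, thresholds)
    if "report" in stages:
        report(out)

    manifest = {
        "config": {
            "stages": stages,
            "seed": seed,
            "thresholds": asdict(thresholds),
            "synthetic": dict(config.get("synthetic", {}) or {}),
            "inputs": {k: str(v) for k, v in inputs.items()},
        },
        "version": __version__,
        "files": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_simulate(sim_config: SimConfig, out: Path) -> dict:
    cohort = simulate_cohort(sim_config)
    indir = out / "inputs"
    indir.mkdir(exist_ok=True)
    paths = {
        "maf": indir / "mutations.maf.tsv",
        "annotations": indir / "annotations.tsv",
        "seg": indir / "cnv.seg",
        "gene_models": indir / "gene_models.tsv",
        "expression": indir / "expression_bulk.tsv",
        "sc": indir / "expression_cells.tsv",
        "cell_meta": indir / "cell_meta.tsv",
        "normal_sc": indir / "expression_normal.tsv",
        "normal_labels": indir / "normal_labels.tsv",
        "peaks": indir / "atac_peaks.tsv",
        "gene_sets": indir / "signatures.gmt",
    }
    write_maf(cohort.records, paths["maf"], cohort.annotations)
    write_annotations(cohort.annotations, paths["annotations"])
    write_seg(cohort.segments, paths["seg"])
    write_gene_models(cohort.gene_models, paths["gene_models"])
    write_expression(cohort.expression.bulk, paths["expression"])
    write_expression(cohort.expression.sc, paths["sc"])
    cohort.expression.cell_meta.to_csv(paths["cell_meta"], sep="\t", index_label="cell")
    write_expression(cohort.expression.normal_sc, paths["normal_sc"])
    cohort.expression.normal_labels.rename_axis("cell").to_csv(
        paths["normal_labels"], sep="\t"
    )
    write_peak_counts(cohort.atac, paths["peaks"])
    write_gmt(cohort.gene_sets, paths["gene_sets"])
    cohort.ledger.to_json(indir / "truth_ledger.json")
    logger.info("simulate: cohort written to %s", indir)

    return {
        "records": cohort.records,
        "annotations": cohort.annotations,
        "segments": cohort.segments,
        "gene_models": cohort.gene_models,
        "expression": cohort.expression.bulk,
        "sc": cohort.expression.sc,
        "cell_meta": cohort.expression.cell_meta,
        "normal_sc": cohort.expression.normal_sc,
        "normal_labels": cohort.expression.normal_labels,
        "peaks": cohort.atac,
        "gene_sets": cohort.gene_sets,
        "_paths": {k: str(v) for k, v in paths.items()},
    }


def _load_inputs(inputs: dict, stages: list) -> dict:
    data: dict = {}
    needed = {k for s in stages for k in _STAGE_INPUTS.get(s, ())}
    if "maf" in needed:
        data["records"], maf_ann = read_maf(inputs["maf"])
    if "annotations" in needed:
        data["annotations"] = read_annotations(inputs["annotations"])
    if "seg" in needed:
        data["segments"] = read_seg(inputs["seg"])
    if "gene_models" in needed:
        data["gene_models"] = read_gene_models(inputs["gene_models"])
    if "expression" in needed:
        data["expression"] = read_expression(inputs["expression"])
    if "sc" in needed:
        data["sc"] = read_expression(inputs["sc"])
    if "cell_meta" in needed:
        data["cell_meta"] = pd.read_csv(inputs["cell_meta"], sep="\t", index_col=0)
    if "normal_sc" in needed:
        data["normal_sc"] = read_expression(inputs["normal_sc"])
    if "normal_labels" in needed:
        data["normal_labels"] = pd.read_csv(
            inputs["normal_labels"], sep="\t", index_col=0
        )["lineage"]
    if "peaks" in needed:
        data["peaks"] = read_peak_counts(inputs["peaks"])
    if "gene_sets" in needed:
        data["gene_sets"] = read_gmt(inputs["gene_sets"])
    return data


def _cohort_groups(annotations):
    prim = [a.sample for a in annotations if a.cohort == "primary"]
    met = [a.sample for a in annotations if a.cohort == "metastatic"]
    models = [a.sample for a in annotations if a.cohort in ("cell_line", "organoid")]
    sites = {}
    for a in annotations:
        if a.cohort == "metastatic":
            sites.setdefault(a.site, []).append(a.sample)
    return prim, met, models, sites


def _stage_genomics(data: dict, out: Path, thresholds: Thresholds) -> None:
    ann = data["annotations"]
    prim, met, models, _ = _cohort_groups(ann)
    matrix = genomics.mutation_matrix(data["records"], ann, exclude_silent=True)
    burden = genomics.burden_table(data["records"], ann)
    panel = genomics.build_gene_panel(matrix, ann, thresholds)
    panel.per_site.to_csv(out / "panel_per_site.tsv", sep="\t", index=False)
    (out / "panel.json").write_text(
        json.dumps(
            {
                "diff_genes": panel.diff_genes,
                "high_genes": panel.high_genes,
                "union": panel.union,
            },
            indent=1,
            sort_keys=True,
        )
        + "\n"
    )
    panel_rank = genomics.rank_by_panel(matrix, panel.union, models)
    panel_rank.to_csv(out / "model_panel_rank.tsv", sep="\t", index=False)
    genes = [g for g in panel.union if g in matrix.index]
    counts = matrix.loc[genes, models].sum(axis=0) if genes else pd.Series(0, index=models)
    genomics.normalized_ratio(counts, burden[models]).to_csv(
        out / "normalized_ratio.tsv", sep="\t", index=False
    )
    catalog = genomics.find_hotspots(data["records"], met, thresholds)
    catalog.entries.to_csv(out / "hotspots.tsv", sep="\t", index=False)
    genomics.hotspot_presence(catalog, data["records"], models).to_csv(
        out / "hotspot_presence.tsv", sep="\t"
    )
    call = genomics.hypermutation_cutoff(
        burden, thresholds.gap_top_frac, thresholds.gap_min_log10
    )
    hyper = call.hypermutated
    others = [s for s in burden.index if s not in set(hyper)]
    mmr_block = {}
    if hyper:
        counts_mmr, p_mmr = genomics.mmr_comparison(matrix, MMR_GENES, hyper, others)
        mmr_block = {"p": p_mmr, "mean_hyper": float(counts_mmr[hyper].mean()),
                     "mean_other": float(counts_mmr[others].mean())}
    (out / "hypermutation.json").write_text(
        json.dumps(
            {
                "cutoff_burden": call.cutoff_burden,
                "gap_index": call.gap_index,
                "gap_size": call.gap_size,
                "hypermutated": call.hypermutated,
                "bimodality": call.bimodality,
                "no_cutoff": call.no_cutoff,
                "mmr": mmr_block,
            },
            indent=1,
            sort_keys=True,
        )
        + "\n"
    )
    burden.to_csv(out / "burden.tsv", sep="\t")
    gene_cnv = genomics.segments_to_gene_cnv(data["segments"], data["gene_models"])
    genomics.differential_cnv(gene_cnv, ann, thresholds).to_csv(
        out / "cnv_differential.tsv", sep="\t", index=False
    )


def _stage_tc(data: dict, out: Path, thresholds: Thresholds) -> None:
    expr = data["expression"]
    ann = data["annotations"]
    prim, met, models, sites = _cohort_groups(ann)
    hvg = transcriptomics.select_hvg(expr[models], thresholds.n_hvg)
    pd.Series(hvg.genes, name="gene").to_csv(out / "hvg_panel.tsv", sep="\t", index=False)
    table = transcriptomics.tc_similarity_table(expr[models], expr[met], hvg.genes)
    table.to_csv(out / "tc_similarity.tsv", sep="\t", index_label="model")
    transcriptomics.rank_models(table).to_csv(out / "tc_ranking.tsv", sep="\t", index=False)
    per_site = {}
    for site, members in sorted(sites.items()):
        med = table[members].median(axis=1)
        per_site[site] = med
        transcriptomics.rank_models(med).to_csv(
            out / f"tc_ranking_site_{site}.tsv", sep="\t", index=False
        )
    if len(per_site) >= 2:
        transcriptomics.site_consistency(per_site).to_csv(
            out / "site_consistency.tsv", sep="\t", index_label="site"
        )
    scores = transcriptomics.ctl_score(expr)
    scores.rename("ctl_score").to_csv(out / "ctl_scores.tsv", sep="\t", index_label="sample")
    hyper_path = out / "hypermutation.json"
    if hyper_path.exists():
        hyper = set(json.loads(hyper_path.read_text())["hypermutated"])
        hyper_prim = [s for s in prim if s in hyper]
        other_prim = [s for s in prim if s not in hyper]
        if hyper_prim and other_prim:
            de = transcriptomics.rank_sum_de(expr, hyper_prim, other_prim, thresholds)
            de.to_csv(out / "de_hypermutated.tsv", sep="\t", index=False)


def _stage_subtype(data: dict, out: Path, thresholds: Thresholds) -> None:
    expr = data["expression"]
    ann = data["annotations"]
    _, met, models, _ = _cohort_groups(ann)
    scores = subtypes.ssgsea(expr[met], data["gene_sets"])
    scores.to_csv(out / "ssgsea_scores.tsv", sep="\t", index_label="sample")
    label_map = {
        a.sample: a.subtype_label
        for a in ann
        if a.cohort == "metastatic" and a.subtype_label in ("ARPC", "NEPC")
    }
    calls = subtypes.call_mspc(scores, label_map, thresholds=thresholds)
    calls.rename_axis("sample").to_csv(out / "subtype_bulk.tsv", sep="\t")
    cell_calls = subtypes.call_subtype_markers(data["sc"])
    cell_calls.rename_axis("cell").to_csv(out / "subtype_cells.tsv", sep="\t")
    # PCA over models: the MSPC-like contrast group, then over-representation
    model_calls = subtypes.call_subtype_markers(expr[models])
    model_calls.rename_axis("model").to_csv(out / "subtype_models.tsv", sep="\t")
    contrast = model_calls.index[model_calls == "MSPC"].tolist()
    top, loadings, _ = subtypes.pc1_top_loadings(
        expr[models], thresholds.n_pc1_genes, orient_toward=contrast or None
    )
    pd.Series(top, name="gene").to_csv(out / "pc1_top_genes.tsv", sep="\t", index=False)
    subtypes.ora_hypergeometric(top, data["gene_sets"], expr.index).to_csv(
        out / "pc1_ora.tsv", sep="\t", index=False
    )


def _stage_lineage(data: dict, out: Path, thresholds: Thresholds) -> None:
    ref = subtypes.build_lineage_reference(
        data["normal_sc"], data["normal_labels"], thresholds.n_lineage_genes
    )
    pd.Series(ref.panel, name="gene").to_csv(out / "lineage_panel.tsv", sep="\t", index=False)
    subtypes.assign_lineages(data["sc"], ref).to_csv(
        out / "lineage_cells.tsv", sep="\t", index_label="cell"
    )
    _, _, models, _ = _cohort_groups(data["annotations"])
    subtypes.assign_lineages(data["expression"][models], ref).to_csv(
        out / "lineage_models.tsv", sep="\t", index_label="model"
    )


def _stage_atac(data: dict, out: Path, thresholds: Thresholds) -> None:
    peaks = data["peaks"]
    ann = data["annotations"]
    _, met, models, _ = _cohort_groups(ann)
    met = [s for s in met if s in peaks.columns]
    models = [m for m in models if m in peaks.columns]
    panel = atac_mod.select_variable_peaks(peaks[met + models], thresholds.peak_top_frac)
    pd.Series(panel.peaks, name="peak").to_csv(out / "atac_panel.tsv", sep="\t", index=False)
    table = atac_mod.atac_similarity(peaks, panel, models, met)
    table.to_csv(out / "atac_similarity.tsv", sep="\t", index_label="model")
    subtype_path = out / "subtype_bulk.tsv"
    if subtype_path.exists():
        patient_subtype = pd.read_csv(subtype_path, sep="\t", index_col=0)["subtype"]
        summary = atac_mod.subtype_summary(table, patient_subtype)
        summary.to_csv(out / "atac_subtype_summary.tsv", sep="\t", index_label="model")
        rows = []
        for st in summary.columns:
            if st == "unassigned":
                continue
            pats = [
                s for s in patient_subtype.index[patient_subtype == st]
                if s in table.columns
            ]
            if len(pats) < 5:
                continue
            ranked = summary[st].sort_values(ascending=False)
            best, second = ranked.index[0], ranked.index[1]
            p = atac_mod.paired_compare(table.loc[best, pats], table.loc[second, pats])
            rows.append({"subtype": st, "best": best, "second": second, "p": p})
        pd.DataFrame(rows, columns=["subtype", "best", "second", "p"]).to_csv(
            out / "atac_paired.tsv", sep="\t", index=False
        )
    top_peaks, _, _ = subtypes.pc1_top_loadings(
        peaks[models], min(thresholds.n_pc1_peaks, len(peaks))
    )
    pd.Series(top_peaks, name="peak").to_csv(out / "atac_pc1_peaks.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Consolidated report
# ---------------------------------------------------------------------------


def report(out_dir) -> pd.DataFrame:
    """Build the consolidated per-model fidelity report from stage outputs."""
    out = Path(out_dir)
    if not out.exists() or not any(out.iterdir()):
        raise PipelineError(f"no stage outputs found in {out}")

    def maybe(name):
        p = out / name
        return p if p.exists() else None

    frames = {}
    if maybe("model_panel_rank.tsv"):
        df = pd.read_csv(out / "model_panel_rank.tsv", sep="\t", index_col="model")
        frames["panel_count"] = df["panel_count"]
        frames["panel_rank"] = df["rank"]
    if maybe("normalized_ratio.tsv"):
        df = pd.read_csv(out / "normalized_ratio.tsv", sep="\t", index_col="model")
        frames["normalized_ratio"] = df["ratio"]
        frames["ratio_rank"] = df["rank"]
    if maybe("hotspot_presence.tsv"):
        df = pd.read_csv(out / "hotspot_presence.tsv", sep="\t", index_col=[0, 1])
        frames["hotspot_carriage"] = df.sum(axis=0)
    if maybe("hypermutation.json"):
        hyper = set(json.loads((out / "hypermutation.json").read_text())["hypermutated"])
        frames["hypermutated"] = pd.Series(
            {m: m in hyper for m in frames.get("panel_rank", pd.Series(dtype=int)).index}
        )
    if maybe("tc_ranking.tsv"):
        df = pd.read_csv(out / "tc_ranking.tsv", sep="\t", index_col="model")
        frames["tc_similarity"] = df["similarity"]
        frames["tc_rank"] = df["rank"]
    for site_file in sorted(out.glob("tc_ranking_site_*.tsv")):
        site = site_file.stem.replace("tc_ranking_site_", "")
        df = pd.read_csv(site_file, sep="\t", index_col="model")
        frames[f"tc_rank_{site}"] = df["rank"]
    if maybe("subtype_models.tsv"):
        frames["subtype"] = pd.read_csv(
            out / "subtype_models.tsv", sep="\t", index_col="model"
        )["subtype"]
    if maybe("lineage_models.tsv"):
        frames["lineage"] = pd.read_csv(
            out / "lineage_models.tsv", sep="\t", index_col="model"
        )["lineage"]
    if maybe("atac_subtype_summary.tsv"):
        df = pd.read_csv(out / "atac_subtype_summary.tsv", sep="\t", index_col="model")
        for st in df.columns:
            frames[f"atac_median_rho_{st}"] = df[st]

    if not frames:
        raise PipelineError(f"no recognizable stage outputs in {out}")
    table = pd.DataFrame(frames)
    table.index.name = "model"
    table.to_csv(out / "fidelity_report.tsv", sep="\t", na_rep="NA")

    lines = ["Model fidelity summary", "======================"]
    missing = [
        s for s, probe in (
            ("genomics", "model_panel_rank.tsv"),
            ("tc", "tc_ranking.tsv"),
            ("subtype", "subtype_models.tsv"),
            ("lineage", "lineage_models.tsv"),
            ("atac", "atac_subtype_summary.tsv"),
        )
        if not maybe(probe)
    ]
    for m in missing:
        lines.append(f"[missing stage: {m}]")
    if "tc_rank" in table:
        best = table["tc_rank"].idxmin()
        lines.append(f"Top transcriptomic match: {best}")
    if "panel_rank" in table:
        lines.append(f"Top panel concordance: {table['panel_rank'].idxmin()}")
    lines.append("")
    lines.append(table.to_string())
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    logger.info("report: %d models summarized", len(table))
    return table
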
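"""End-to-end orchestration of the analysis stages with a reproducible
manifest.

Stage order mirrors the study workflow: simulate (or load) a cohort,
score biliary viability and histology, preprocess the intensity matrix,
run differential abundance at the viability-assessment timepoint,
discover structure (PCA / clustering), rank biomarkers by stratified
mean AUC, integrate baseline transcripts, and test enrichment.  Every
stage writes TSV outputs into the working directory and registers them
in a JSON manifest; with a fixed seed the whole run is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__
from .biomarker_ranking import stratified_mean_auc
from .differential import differential_table, mann_whitney
from .enrichment import hypergeom_ora
from .io_model import (
    BileflowError,
    CohortMetadata,
    IntensityMatrix,
    RunConfig,
    read_gmt,
    read_intensity_matrix,
    read_metadata,
    write_intensity_matrix,
    write_table,
    TIMEPOINTS,
)
from .proteome_preprocess import (
    ImputationSpec,
    combat_adjust,
    impute_downshifted_normal,
    presence_profile,
    timepoint_groups,
    valid_value_filter,
    zscore_rows,
)
from .structure_discovery import hclust_order, kmeans_rows, pca
from .synthetic_data import SyntheticCohort, generate_cohort, write_cohort
from .transcript_integration import (
    normalize_counts,
    protein_transcript_regression,
    rin_filter,
)
from .viability_scoring import (
    DEFAULT_CRITERIA,
    assess_bdi_cohort,
    assess_cohort,
    read_criteria,
)

logger = logging.getLogger("bileflow")

STAGES = (
    "simulate",
    "score",
    "preprocess",
    "diff",
    "cluster",
    "rank",
    "integrate",
    "enrich",
)


def load_cohort(indir: str | Path) -> SyntheticCohort:
    """Load a cohort previously written by :func:`write_cohort`."""
    indir = Path(indir)
    required = ["samples.tsv", "livers.tsv", "chemistry.tsv"]
    missing = [f for f in required if not (indir / f).exists()]
    if missing:
        raise BileflowError(f"missing input files in {indir}: {missing}")
    matrices = {}
    for tp in TIMEPOINTS:
        p = indir / f"intensity_{tp}.tsv"
        if p.exists():
            matrices[tp] = read_intensity_matrix(p, scale="log2")
    metadata = read_metadata(indir / "samples.tsv", indir / "livers.tsv")
    chemistry = pd.read_csv(indir / "chemistry.tsv", sep="\t", index_col=0)
    hist_path = indir / "histology.tsv"
    histology = (
        pd.read_csv(hist_path, sep="\t", index_col=0) if hist_path.exists() else pd.DataFrame()
    )
    counts_path = indir / "counts.tsv"
    counts = (
        pd.read_csv(counts_path, sep="\t", index_col=0) if counts_path.exists() else pd.DataFrame()
    )
    rin_path = indir / "rin.tsv"
    rin = (
        pd.read_csv(rin_path, sep="\t", index_col=0)["rin"]
        if rin_path.exists()
        else pd.Series(dtype=float)
    )
    crit_path = indir / "criteria.yaml"
    criteria = read_criteria(crit_path) if crit_path.exists() else DEFAULT_CRITERIA
    return SyntheticCohort(
        matrices=matrices,
        metadata=metadata,
        chemistry=chemistry,
        histology=histology,
        counts=counts,
        rin=rin,
        criteria=criteria,
        truth=None,
    )


def _toy_gene_sets(cohort: SyntheticCohort, rng: np.random.Generator) -> dict[str, set[str]]:
    """Gene sets for the enrichment stage of a simulated run: the planted
    markers (if known) plus random sets over the cohort's protein ids."""
    proteins = list(next(iter(cohort.matrices.values())).protein_ids)
    sets: dict[str, set[str]] = {}
    if cohort.truth is not None:
        sets["planted_markers"] = set(cohort.truth.marker_ids)
    for name, size in (("secretion", 40), ("immune_response", 60), ("cell_proliferation", 50)):
        sets[name] = set(rng.choice(proteins, size=min(size, len(proteins)), replace=False))
    return sets


def run_pipeline(
    config: RunConfig,
    workdir: str | Path,
    input_dir: str | Path | None = None,
    skip: Iterable[str] = (),
    gmt_path: str | Path | None = None,
) -> dict:
    """Run the pipeline end to end and return the manifest.

    Without ``input_dir`` the simulate stage generates the cohort; with
    it, cohort files are loaded (and validated before any stage runs)
    and the simulate stage records the input paths instead.
    """
    skip = set(skip)
    unknown = skip - set(STAGES)
    if unknown:
        raise BileflowError(f"unknown stage names {sorted(unknown)}; valid: {list(STAGES)}")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.header_block(),
        "stages": {},
    }
    header = config.header_block()

    def register(stage: str, outputs: dict[str, Path]) -> None:
        rel = {}
        for k, p in outputs.items():
            p = Path(p)
            rel[k] = str(p.relative_to(workdir)) if p.is_relative_to(workdir) else str(p)
        manifest["stages"][stage] = {"outputs": rel}

    # --- simulate / load ----------------------------------------------------
    if input_dir is not None:
        cohort = load_cohort(input_dir)
        register("simulate", {"input_dir": Path(input_dir)})
    else:
        if "simulate" in skip:
            raise BileflowError("no input_dir given and simulate stage skipped")
        cohort = generate_cohort(seed=config.seed)
        paths = write_cohort(cohort, workdir / "cohort")
        register("simulate", paths)

    meta = cohort.metadata

    # --- score --------------------------------------------------------------
    if "score" not in skip:
        viability = assess_cohort(
            cohort.chemistry,
            cohort.criteria,
            rule="threshold",
            threshold=config.viability_point_threshold,
        )
        out_v = workdir / "viability.tsv"
        write_table(viability, out_v, header, index_label="liver_id")
        outputs = {"viability": out_v}
        if len(cohort.histology):
            bdi = assess_bdi_cohort(cohort.histology.dropna(how="all"))
            out_b = workdir / "bdi.tsv"
            write_table(bdi, out_b, header, index_label="liver_id")
            outputs["bdi"] = out_b
        register("score", outputs)

    # --- preprocess ---------------------------------------------------------
    combined = cohort.combined_matrix
    groups = timepoint_groups(meta, combined.sample_ids)
    profile = presence_profile(combined, groups)
    filtered = valid_value_filter(combined, groups, config.presence_threshold)
    imputed = impute_downshifted_normal(
        filtered,
        ImputationSpec(
            width=config.imputation_width,
            downshift=config.imputation_downshift,
            scope=config.imputation_scope,
            seed=config.seed,
        ),
    )
    batches = meta.samples.loc[imputed.sample_ids, "batch"]
    corrected = combat_adjust(imputed, batches) if batches.nunique() > 1 else imputed
    zmat = zscore_rows(corrected)
    if "preprocess" not in skip:
        out_m = workdir / "matrix_processed.tsv"
        write_intensity_matrix(corrected, out_m, header)
        out_z = workdir / "matrix_zscore.tsv"
        write_intensity_matrix(zmat, out_z, header)
        prof = pd.DataFrame(
            {"presence": profile.overall, **profile.per_group}
        )
        out_p = workdir / "presence.tsv"
        write_table(
            prof, out_p,
            {**header, "median_presence_percent": f"{profile.median_percent:.1f}"},
            index_label="protein",
        )
        register(
            "preprocess",
            {"matrix": out_m, "zscore": out_z, "presence": out_p},
        )

    # --- differential -------------------------------------------------------
    if "diff" not in skip:
        outputs = {}
        t150 = [s for s in corrected.sample_ids if meta.samples.loc[s, "timepoint"] == "T150"]
        m150 = corrected.subset_samples(t150)
        labels = meta.sample_labels(t150, "viability_class")
        diff = differential_table(
            m150,
            labels,
            group_a="low",
            group_b="high",
            n_perm=config.n_permutations,
            seed=config.seed,
            fc_threshold=config.fold_change_threshold,
            p_threshold=config.p_threshold,
            q_threshold=config.q_threshold,
        )
        out_d = workdir / "differential_viability_T150.tsv"
        write_table(diff, out_d, header, index_label="protein")
        outputs["viability_T150"] = out_d
        # longitudinal comparison: T150 vs T30 on all livers
        t30 = [s for s in corrected.sample_ids if meta.samples.loc[s, "timepoint"] == "T30"]
        mlong = corrected.subset_samples(t30 + t150)
        tp_labels = meta.samples.loc[t30 + t150, "timepoint"]
        diff_long = differential_table(
            mlong,
            tp_labels,
            group_a="T30",
            group_b="T150",
            n_perm=config.n_permutations,
            seed=config.seed,
            fc_threshold=config.fold_change_threshold,
            p_threshold=config.p_threshold,
            q_threshold=config.q_threshold,
        )
        out_l = workdir / "differential_T150_vs_T30.tsv"
        write_table(diff_long, out_l, header, index_label="protein")
        outputs["T150_vs_T30"] = out_l
        register("diff", outputs)

    # --- structure ----------------------------------------------------------
    if "cluster" not in skip:
        emb = pca(corrected, n_components=min(10, len(corrected.sample_ids) - 1))
        out_e = workdir / "pca_samples.tsv"
        coords = emb.coordinates.copy()
        write_table(coords, out_e, header, index_label="sample_id")
        clustering = kmeans_rows(
            zmat, k=config.kmeans_k, seed=config.seed, n_init=config.kmeans_n_init
        )
        col_order = hclust_order(zmat, axis="columns")
        heat = zmat.data[col_order].assign(cluster=clustering.labels).sort_values(
            "cluster", kind="stable"
        )
        out_h = workdir / "heatmap_zscore.tsv"
        write_table(heat, out_h, header, index_label="protein")
        register("cluster", {"pca": out_e, "heatmap": out_h})

    # --- rank ---------------------------------------------------------------
    ranking = stratified_mean_auc(corrected, meta)
    if "rank" not in skip:
        out_r = workdir / "biomarker_ranking.tsv"
        write_table(ranking.head(config.top_k), out_r, header, index_label="protein")
        register("rank", {"ranking": out_r})

    # --- integrate ----------------------------------------------------------
    if "integrate" not in skip and len(cohort.counts):
        keep = rin_filter(cohort.rin, config.rin_threshold)
        counts_ok = cohort.counts[[l for l in cohort.counts.columns if l in keep]]
        outputs = {}
        if counts_ok.shape[1] >= 3:
            norm = normalize_counts(counts_ok)
            top_genes = [g for g in ranking.head(3).index if g in norm.index]
            # per-liver protein intensities at each timepoint
            strata = {
                "all": list(meta.livers.index),
                "highBDI": list(meta.livers.index[meta.livers["bdi_class"] == "high"]),
                "lowBDI": list(meta.livers.index[meta.livers["bdi_class"] == "low"]),
            }
            frames = []
            for tp in ("T30", "T150"):
                sids = [
                    s for s in corrected.sample_ids
                    if meta.samples.loc[s, "timepoint"] == tp
                ]
                prot = corrected.data[sids].copy()
                prot.columns = [meta.samples.loc[s, "liver_id"] for s in sids]
                res = protein_transcript_regression(norm, prot, strata, genes=top_genes)
                if len(res):
                    res.insert(0, "timepoint", tp)
                    frames.append(res)
            if frames:
                reg = pd.concat(frames, ignore_index=True)
                out_c = workdir / "protein_transcript_regression.tsv"
                write_table(reg, out_c, header)
                outputs["regression"] = out_c
            # group comparison of normalized counts (high vs low viability)
            rows = []
            vcls = meta.livers["viability_class"]
            for gene in top_genes:
                hi = norm.loc[gene, [l for l in norm.columns if vcls.get(l) == "high"]]
                lo = norm.loc[gene, [l for l in norm.columns if vcls.get(l) == "low"]]
                if len(hi) and len(lo):
                    u, p = mann_whitney(hi, lo)
                    rows.append({"gene": gene, "U": u, "p": p,
                                 "n_high": len(hi), "n_low": len(lo)})
            if rows:
                out_mw = workdir / "transcript_group_tests.tsv"
                write_table(pd.DataFrame(rows), out_mw, header)
                outputs["group_tests"] = out_mw
        register("integrate", outputs)

    # --- enrich -------------------------------------------------------------
    if "enrich" not in skip:
        if gmt_path is not None:
            sets = read_gmt(gmt_path)
        else:
            sets = _toy_gene_sets(cohort, np.random.default_rng(config.seed + 1))
        background = list(corrected.protein_ids)
        query = list(ranking.head(config.top_k).index)
        ora = hypergeom_ora(query, background, sets)
        out_o = workdir / "enrichment.tsv"
        write_table(ora, out_o, header)
        register("enrich", {"enrichment": out_o})

    manifest_path = workdir / "manifest.json"
    with manifest_path.open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
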
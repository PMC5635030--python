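"""End-to-end orchestration: profiles → MLGs → statistics → markers.

``run_pipeline`` executes the enabled stages in dependency order on either
supplied TSV inputs or a freshly simulated synthetic cohort, writes every
stage's outputs under the configured directory together with the resolved
configuration, and returns a machine-readable run report (seed, parameter
echo, per-stage summary counts).  Runs are idempotent given identical config
and inputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .io import (
    read_annotation,
    read_matrix,
    read_metadata,
    read_module_map,
    write_edges,
    write_graphml,
    write_matrix,
)
from .markers import clinical_association, enzyme_classifier, medication_analysis, rfcv_select, roc_analysis
from .mlg import assign_taxonomy, build_mlgs, mlg_abundance
from .ordination import dbrda, distance_matrix, pca_ordination, permanova
from .profiles import aggregate_features, filter_low_occurrence, relative_abundance
from .stats import cooccurrence_network, differential_abundance, reporter_scores
from .synthdata import default_community_model, generate_catalog, simulate_cohort, write_cohort

__all__ = ["run_pipeline", "validate_inputs"]

logger = logging.getLogger(__name__)

STAGE_ORDER = [
    "simulate", "profile", "mlg", "diff", "network", "ordinate",
    "permanova", "reporter", "classify", "associate", "drugs",
]


def _is_clinical_column(col: str) -> bool:
    return not (col in ("group", "subtype") or col.startswith("drug_"))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and return the run report dictionary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "resolved_config.yaml")
    enabled = [s for s in STAGE_ORDER if s in config.stages]
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": {},
    }
    rng = np.random.default_rng(config.seed)

    t0 = time.time()

    # ------------------------------------------------------------- inputs
    catalog = None
    if "simulate" in enabled:
        sp = config.simulate
        catalog = generate_catalog(
            sp.n_genomes, (sp.genes_min, sp.genes_max), seed=config.seed
        )
        model = default_community_model(
            catalog, n_enriched=sp.n_enriched, n_depleted=sp.n_depleted,
            log2_fold_change=sp.log2_fold_change, seed=config.seed,
        )
        model.sequencing_depth = sp.sequencing_depth
        model.dispersion = sp.dispersion
        model.zero_inflation = sp.zero_inflation
        model.gene_weight_sd = sp.gene_weight_sd
        counts, metadata, truth = simulate_cohort(
            catalog, model, sp.n_case, sp.n_control, seed=config.seed + 1
        )
        write_cohort(outdir / "cohort", catalog, counts, metadata, truth)
        gene_taxa = pd.Series(catalog.gene_to_genome, name="feature").to_frame()
        gene_ko = pd.Series(catalog.gene_to_ko, name="feature").to_frame()
        gene_enzyme = pd.Series(catalog.gene_to_enzyme, name="feature").to_frame()
        module_map = catalog.module_map
        report["stages"]["simulate"] = {
            "n_genes": counts.shape[0], "n_samples": counts.shape[1],
            "n_genomes": len(catalog.genome_ids),
            "n_enriched": len(truth.true_enriched), "n_depleted": len(truth.true_depleted),
        }
    else:
        if not config.counts_path or not config.metadata_path:
            raise FileNotFoundError(
                "stage 'simulate' is disabled: counts_path and metadata_path "
                "must point to existing inputs"
            )
        counts = read_matrix(config.counts_path)
        metadata = read_metadata(config.metadata_path)
        gene_taxa = read_annotation(config.gene_to_genome_path) if config.gene_to_genome_path else None
        gene_ko = read_annotation(config.gene_to_ko_path) if config.gene_to_ko_path else None
        gene_enzyme = read_annotation(config.gene_to_enzyme_path) if config.gene_to_enzyme_path else None
        module_map = read_module_map(config.module_map_path) if config.module_map_path else None

    groups = metadata.loc[counts.columns, "group"]

    # ------------------------------------------------------------- profile
    if "profile" in enabled:
        rel = relative_abundance(counts)
        filtered = filter_low_occurrence(rel, config.profile.min_samples)
        if config.profile.renormalize_after_filter:
            filtered = filtered / filtered.sum(axis=0)
        write_matrix(filtered, outdir / "gene_abundance.tsv")
        report["stages"]["profile"] = {
            "n_genes_in": rel.shape[0], "n_genes_kept": filtered.shape[0],
        }
    else:
        raise ValueError("the 'profile' stage is required by all downstream stages")

    # ----------------------------------------------------------------- mlg
    mlgs, mlg_ab = [], None
    if "mlg" in enabled:
        mlgs = build_mlgs(
            filtered, cc_threshold=config.mlg.cc_threshold,
            min_genes=config.mlg.min_genes, seed=config.seed,
        )
        mlg_ab = mlg_abundance(mlgs, filtered)
        members = pd.DataFrame(
            [(g.mlg_id, gene) for g in mlgs for gene in sorted(g.gene_ids)],
            columns=["mlg", "gene"],
        )
        members.to_csv(outdir / "mlg_members.tsv", sep="\t", index=False)
        write_matrix(mlg_ab, outdir / "mlg_abundance.tsv")
        tax_rows = []
        if gene_taxa is not None:
            for g in mlgs:
                ta = assign_taxonomy(g, gene_taxa)
                for genome, frac, ident in ta.top_genomes:
                    tax_rows.append((g.mlg_id, ta.assigned_taxon or "", genome, frac, ident))
            pd.DataFrame(
                tax_rows, columns=["mlg", "assigned_taxon", "genome", "fraction", "mean_identity"]
            ).to_csv(outdir / "mlg_taxonomy.tsv", sep="\t", index=False)
        report["stages"]["mlg"] = {
            "n_mlgs": len(mlgs),
            "n_assigned": sum(1 for g in mlgs if g.taxonomy and g.taxonomy.assigned_taxon),
        }

    # ---------------------------------------------------------------- diff
    diff = None
    if "diff" in enabled and mlg_ab is not None and not mlg_ab.empty:
        diff = differential_abundance(mlg_ab, groups, q_cut=config.stats.q_cut,
                                      case_label="case")
        diff.to_csv(outdir / "mlg_differential.tsv", sep="\t")
        sig = diff[diff["significant"]]
        report["stages"]["diff"] = {
            "n_tested": len(diff), "n_significant": int(len(sig)),
            "n_case_enriched": int((sig["direction"] == "case-enriched").sum()),
            "n_control_enriched": int((sig["direction"] == "control-enriched").sum()),
        }

    # ------------------------------------------------------------- network
    if "network" in enabled and mlg_ab is not None and not mlg_ab.empty:
        for grp in ("case", "control"):
            subset = metadata.index[groups == grp]
            edges = cooccurrence_network(mlg_ab, subset, cc_min=config.stats.cc_min)
            write_edges(edges, outdir / f"network_{grp}.tsv")
            write_graphml(edges, outdir / f"network_{grp}.graphml")
            report["stages"].setdefault("network", {})[f"n_edges_{grp}"] = len(edges)

    # ------------------------------------------------------------ ordinate
    genus_ab = aggregate_features(filtered, gene_taxa) if gene_taxa is not None else None
    if "ordinate" in enabled and genus_ab is not None and len(genus_ab) >= 2:
        pca = pca_ordination(genus_ab)
        write_matrix(pca.coordinates, outdir / "pca_coordinates.tsv")
        write_matrix(pca.loadings, outdir / "pca_loadings.tsv")
        d_bc = distance_matrix(genus_ab, metric="bray_curtis")
        cap = dbrda(d_bc, groups.to_numpy(), features=genus_ab)
        write_matrix(cap.sample_scores, outdir / "dbrda_scores.tsv")
        if cap.feature_weights is not None:
            write_matrix(cap.feature_weights, outdir / "dbrda_weights.tsv")
        report["stages"]["ordinate"] = {
            "pc1_variance": float(pca.explained_variance_ratio[0]),
            "dbrda_constrained_inertia": cap.constrained_inertia,
        }

    # ----------------------------------------------------------- permanova
    if "permanova" in enabled and mlg_ab is not None and not mlg_ab.empty:
        d_jsd = distance_matrix(mlg_ab, metric="jensen_shannon")
        pr = permanova(d_jsd, groups.to_numpy(), n_perm=config.stats.n_perm,
                       seed=config.seed, factor_id="group")
        (outdir / "permanova.json").write_text(json.dumps({
            "factor": pr.factor_id, "pseudo_F": pr.pseudo_F,
            "r_squared": pr.r_squared, "p_value": pr.p_value,
            "n_permutations": pr.n_permutations,
        }, indent=1))
        report["stages"]["permanova"] = {"p_value": pr.p_value, "pseudo_F": pr.pseudo_F}

    # ------------------------------------------------------------ reporter
    if "reporter" in enabled and gene_ko is not None and module_map:
        ko_ab = aggregate_features(filtered, gene_ko)
        rep = reporter_scores(
            ko_ab, groups, module_map, min_samples=config.stats.min_samples_ko,
            n_background=config.stats.n_background, seed=config.seed, case_label="case",
        )
        rep.to_csv(outdir / "reporter_scores.tsv", sep="\t")
        report["stages"]["reporter"] = {
            "n_modules": len(rep),
            "n_flagged": int((rep["reporter_score"].abs() >= 1.6).sum()),
        }

    # ------------------------------------------------------------ classify
    if "classify" in enabled and mlg_ab is not None and len(mlg_ab) >= 2:
        mp = config.markers
        sel = rfcv_select(
            mlg_ab, groups, folds=mp.folds, repeats=mp.repeats,
            max_panel=mp.max_panel, seed=config.seed, n_trees=mp.n_trees,
        )
        roc = roc_analysis(sel.probabilities, groups, case_label="case")
        pd.DataFrame({
            "rank": range(1, len(sel.ranked_features) + 1),
            "feature": sel.ranked_features,
            "importance": sel.importances.loc[sel.ranked_features].to_numpy(),
        }).to_csv(outdir / "marker_panel.tsv", sep="\t", index=False)
        sel.probabilities.rename("probability").to_frame().assign(
            label=groups.to_numpy()
        ).to_csv(outdir / "disease_probability.tsv", sep="\t")
        roc.roc_points.to_csv(outdir / "roc_points.tsv", sep="\t", index=False)
        (outdir / "classifier_summary.json").write_text(json.dumps({
            "auc": roc.auc, "ci": [roc.ci_low, roc.ci_high],
            "youden_index": roc.youden_index, "youden_cutoff": roc.youden_cutoff,
            "panel_size": sel.chosen_size, "panel": sel.chosen_panel,
        }, indent=1))
        report["stages"]["classify"] = {
            "auc": roc.auc, "panel_size": sel.chosen_size, "youden": roc.youden_index,
        }
        if gene_enzyme is not None and not gene_enzyme.empty:
            enz_ab = aggregate_features(filtered, gene_enzyme)
            if len(enz_ab) >= 2:
                esel, eroc = enzyme_classifier(
                    enz_ab, groups, folds=mp.folds, repeats=mp.repeats,
                    seed=config.seed, n_trees=mp.n_trees, case_label="case",
                )
                (outdir / "enzyme_classifier.json").write_text(json.dumps({
                    "auc": eroc.auc, "ci": [eroc.ci_low, eroc.ci_high],
                    "youden_index": eroc.youden_index,
                    "features": list(enz_ab.index),
                }, indent=1))
                report["stages"]["classify"]["enzyme_auc"] = eroc.auc

    # ------------------------------------------------------------ associate
    if "associate" in enabled and mlg_ab is not None and len(mlg_ab) >= 2:
        clin_cols = [c for c in metadata.columns if _is_clinical_column(c)]
        if clin_cols:
            mp = config.markers
            assoc = clinical_association(
                mlg_ab, metadata.loc[mlg_ab.columns, clin_cols],
                n_perm=mp.assoc_n_perm, cc_min=mp.assoc_cc_min,
                p_max=mp.assoc_p_max, seed=config.seed,
                folds=mp.folds, repeats=mp.assoc_repeats, n_trees=mp.assoc_n_trees,
            )
            assoc.to_csv(outdir / "clinical_associations.tsv", sep="\t", index=False)
            report["stages"]["associate"] = {"n_pairs": len(assoc)}

    # --------------------------------------------------------------- drugs
    if "drugs" in enabled and mlg_ab is not None and len(mlg_ab) >= 2:
        drug_cols = [c for c in metadata.columns if c.startswith("drug_")]
        if drug_cols:
            mp = config.markers
            drugs = medication_analysis(
                mlg_ab, groups, metadata.loc[mlg_ab.columns, drug_cols].astype(bool),
                folds=mp.folds, repeats=mp.drug_repeats, seed=config.seed,
                n_trees=mp.drug_n_trees, max_panel=mp.drug_max_panel,
                n_perm=config.stats.n_perm,
            )
            drugs.to_csv(outdir / "medication_comparison.tsv", sep="\t")
            report["stages"]["drugs"] = {"n_drugs": len(drugs)}

    for stage in STAGE_ORDER:
        if stage not in enabled:
            report["stages"].setdefault(stage, {"skipped": True})
    report["runtime_seconds"] = round(time.time() - t0, 2)
    (outdir / "run_report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def validate_inputs(
    counts_path: str | Path,
    metadata_path: str | Path,
    annotation_paths: dict[str, str | Path] | None = None,
) -> list[dict]:
    """Structural validation of pipeline inputs; returns a findings list.

    Checks performed without mutating anything: matrix/metadata sample
    alignment, duplicate ids, negative values, non-numeric entries, and
    annotation maps referencing unknown genes.  Each finding is a dict with
    ``level`` (error/warning), ``check`` and a message.
    """
    findings: list[dict] = []

    def finding(level, check, message):
        findings.append({"level": level, "check": check, "message": message})

    try:
        counts = read_matrix(counts_path)
    except Exception as exc:  # noqa: BLE001 - reported, not raised
        return [{"level": "error", "check": "readable", "message": f"{counts_path}: {exc}"}]
    try:
        meta = read_metadata(metadata_path)
    except Exception as exc:  # noqa: BLE001
        return [{"level": "error", "check": "readable", "message": f"{metadata_path}: {exc}"}]

    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()].unique().tolist()
        finding("error", "duplicate_gene_id", f"duplicate gene id(s): {dup[:5]}")
    if counts.columns.has_duplicates:
        finding("error", "duplicate_sample_id", "duplicate sample ids in counts")
    non_numeric = counts.apply(pd.to_numeric, errors="coerce").isna() & counts.notna()
    if non_numeric.to_numpy().any():
        finding("error", "non_numeric", "counts matrix contains non-numeric entries")
    elif (counts.to_numpy() < 0).any():
        finding("error", "negative_values", "counts matrix contains negative values")

    missing_meta = [s for s in counts.columns if s not in meta.index]
    for s in missing_meta[:20]:
        finding("error", "sample_missing_metadata", f"sample {s!r} absent from metadata")
    extra_meta = [s for s in meta.index if s not in counts.columns]
    for s in extra_meta[:20]:
        finding("warning", "metadata_without_sample", f"metadata row {s!r} has no sample column")
    if "group" not in meta.columns:
        finding("error", "missing_group", "metadata lacks a 'group' column")

    for name, path in (annotation_paths or {}).items():
        try:
            ann = read_annotation(path)
        except Exception as exc:  # noqa: BLE001
            finding("error", "readable", f"{path}: {exc}")
            continue
        unknown = ann.index.difference(counts.index)
        if len(unknown):
            finding("warning", "annotation_unknown_gene",
                    f"{name}: {len(unknown)} annotated gene(s) absent from counts")
    return findings
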
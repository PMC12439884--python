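"""End-to-end orchestration over the synthetic study conditions.

``run_pipeline`` executes the stages in dependency order on generated
data, writing each stage's artifacts (CSV/JSON) plus a provenance record
(config hash, derived seed, input artifact names) into an output
directory. Stages draw their seeds from the single global seed by stable
hashing of the stage name, so each stage is reproducible in isolation and
a rerun with identical configuration is byte-identical.

This module is deliberately thin: every stage is an ordinary function in
the topical modules and can be driven directly from Python (see the
examples/ scripts); the pipeline exists for whole-run reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import consensus as consensus_mod
from . import factors as factors_mod
from . import lr as lr_mod
from . import metrics as metrics_mod
from . import patterns as patterns_mod
from . import qc as qc_mod
from . import registration as reg_mod
from . import simulate as sim_mod
from . import stitch as stitch_mod
from .io import AffineTransform2D

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "STAGES"]

STAGES = [
    "simulate",
    "stitch",
    "qc",
    "patterns",
    "consensus",
    "register",
    "factors",
    "lrmap",
    "select",
]


@dataclass
class PipelineConfig:
    """Global seed plus the per-stage thresholds used throughout."""

    seed: int = 0
    simulation: sim_mod.SimulationConfig = field(default_factory=sim_mod.SimulationConfig)
    umi_min: int = 250
    edge_max: float = 6.0
    mito_max: float = 0.05
    doublet_max: float = 5.0
    mads: dict = field(default_factory=lambda: {"neun": 3.0, "pi": 1.0})
    neighbor_threshold_pitches: float = 1.5
    top_n_svg: int = 2000
    top_n_markers: int = 250
    top_n_registration: int = 100
    top_n_factor_genes: int = 20
    nmf_k: int = 4
    nmf_l1: float = 0.1
    nmf_tol: float = 1e-6
    nmf_maxit: int = 500
    prevalence_min: float = 0.2
    scaled_mean_min: float = 0.2
    sex_r_max: float = 0.3
    factor_min_spots: int = 200
    effect_min: float = 0.3
    fdr_max: float = 0.05
    evidence_min: float = 0.1
    rank_max: float = 0.01
    flank: int = 100_000
    top_fraction_celltype: float = 0.10
    top_fraction_domain: float = 0.15
    epsilon: float = 1e-6
    k_cut: int = 6

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def stage_seed(global_seed: int, stage: str) -> int:
    """Fan the global seed out per stage by stable hashing of its name."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _provenance(out_dir: Path, stage: str, config: PipelineConfig, inputs: list[str]) -> None:
    record = {
        "stage": stage,
        "config_hash": _config_hash(config),
        "seed": stage_seed(config.seed, stage),
        "inputs": inputs,
    }
    (out_dir / f"{stage}.provenance.json").write_text(json.dumps(record, indent=2) + "\n")


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None, out_dir="pipeline_out") -> dict:
    """Run the requested stages in order; returns the artifact store.

    Unknown stage names raise immediately; a stage whose upstream artifact
    is missing raises an error naming both.
    """
    stages = STAGES if stages is None else stages
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    stages = [s for s in STAGES if s in stages]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    store: dict = {}

    def need(artifact: str, stage: str):
        if artifact not in store:
            raise RuntimeError(f"stage {stage!r} requires missing upstream artifact {artifact!r}")
        return store[artifact]

    for stage in stages:
        seed = stage_seed(config.seed, stage)
        if stage == "simulate":
            sim = dataclasses.replace(config.simulation, seed=seed)
            areas, landmarks, gt = sim_mod.simulate_capture_areas(sim)
            store.update(sim_config=sim, areas=areas, landmarks=landmarks, ground_truth=gt)
            nuclei_counts, nuclei_labels, nuclei_markers = sim_mod.simulate_nuclei(sim)
            store.update(
                nuclei_counts=nuclei_counts,
                nuclei_labels=nuclei_labels,
                nuclei_markers=nuclei_markers,
            )
            nuclei_labels.to_csv(out_dir / "nuclei_labels.csv")
            _provenance(out_dir, stage, config, [])
        elif stage == "stitch":
            areas = need("areas", stage)
            landmarks = need("landmarks", stage)
            coarse = {a: AffineTransform2D.identity() for a in areas}
            refinements, residuals = stitch_mod.refine_alignment(areas, coarse, landmarks)
            stitched = stitch_mod.stitch_positions(areas, coarse, refinements)
            grid = stitch_mod.build_artificial_grid(stitched)
            stitched = stitch_mod.assign_to_grid(stitched, grid)
            overlaps = stitch_mod.detect_overlaps(stitched)
            store.update(stitched=stitched, grid=grid, overlaps=overlaps, residuals=residuals)
            stitched.drop(columns=["global_x", "global_y"], errors="ignore").to_csv(
                out_dir / "stitched_positions.csv", index=False
            )
            report = {
                "pitch_px": grid.pitch,
                "overlap_threshold": overlaps.threshold,
                "n_overlap_pairs": len(overlaps.pairs),
                "residuals": {f"{a}~{b}": r for (a, b), r in residuals.items()},
            }
            (out_dir / "stitch_report.json").write_text(json.dumps(report, indent=2) + "\n")
            _provenance(out_dir, stage, config, ["areas", "landmarks"])
        elif stage == "qc":
            sim = need("sim_config", stage)
            stitched = need("stitched", stage)
            gt = need("ground_truth", stage)
            gt.spot_domain_labels = sim_mod.assign_domains(
                stitched.rename(
                    columns={"pxl_col_in_fullres": "x", "pxl_row_in_fullres": "y"}
                ).set_index("barcode"),
                sim,
            )
            counts, domains, markers = sim_mod.simulate_domain_counts(
                stitched, sim, gt.spot_domain_labels
            )
            umi = pd.Series(
                np.asarray(counts.matrix.sum(axis=0)).ravel(), index=counts.barcodes
            )
            overlaps = need("overlaps", stage)
            resolved = stitch_mod.resolve_overlaps(
                overlaps,
                umi,
                stitched.set_index("barcode")["capture_area"],
                sorted(stitched["capture_area"].unique()),
            )
            edge = stitch_mod.edge_distance(
                stitched, row_col_columns=("array_row_original", "array_col_original")
            )
            metrics = pd.DataFrame(
                {"sum_umi": umi.to_numpy(), "edge_distance": edge.to_numpy()},
                index=counts.barcodes,
            )
            excluded = qc_mod.spot_qc_filter(metrics, config.umi_min, config.edge_max)
            keep = ~excluded & ~metrics.index.isin(resolved.excluded_spot_ids)
            norm = qc_mod.log_normalize(counts, method="scale_factor")
            store.update(
                spot_counts=counts,
                spot_markers=markers,
                spot_norm=norm,
                spot_keep=keep,
                resolved_overlaps=resolved,
                domains=gt.spot_domain_labels,
            )
            metrics.assign(excluded=excluded).to_csv(out_dir / "spot_qc.csv")
            _provenance(out_dir, stage, config, ["stitched", "ground_truth"])
        elif stage == "patterns":
            stitched = need("stitched", stage)
            norm = need("spot_norm", stage)
            grid = need("grid", stage)
            coords = stitched.set_index("barcode").loc[
                norm.barcodes, ["pxl_col_in_fullres", "pxl_row_in_fullres"]
            ].to_numpy()
            graph = patterns_mod.build_spatial_graph(
                coords, config.neighbor_threshold_pitches * grid.pitch
            )
            expr = np.asarray(norm.matrix.todense())
            scc = patterns_mod.spatial_cross_correlation(expr, graph)
            labels = patterns_mod.group_patterns(scc, method="ward", k=config.simulation.n_domains)
            scores = patterns_mod.pattern_scores(expr, labels)
            store.update(spot_graph=graph, scc=scc, pattern_labels=labels, pattern_scores=scores)
            scores.to_csv(out_dir / "pattern_scores.csv", index=False)
            _provenance(out_dir, stage, config, ["stitched", "spot_norm"])
        elif stage == "consensus":
            labels = need("pattern_labels", stage)
            scores = need("pattern_scores", stage)
            norm = need("spot_norm", stage)
            domains = need("domains", stage).reindex(norm.barcodes)
            gene_sets = {
                f"donor1:pattern_{p}": {
                    g for g, l in zip(norm.genes, labels) if l == p
                }
                for p in sorted(set(labels))
            }
            profiles = pd.DataFrame(
                {
                    name: scores[name.split(":")[1]].groupby(domains.to_numpy()).mean()
                    for name in gene_sets
                }
            ).T
            J = consensus_mod.jaccard_matrix(gene_sets)
            R = consensus_mod.domain_profile_correlation(profiles)
            S = consensus_mod.consensus_matrix(J, R)
            k = min(config.k_cut, S.shape[0])
            _, mcp = consensus_mod.cluster_patterns(S, k=k)
            store.update(consensus_similarity=S, mcp_labels=mcp)
            S.to_csv(out_dir / "consensus_similarity.csv")
            _provenance(out_dir, stage, config, ["pattern_labels", "pattern_scores"])
        elif stage == "register":
            norm_spots = need("spot_norm", stage)
            domains = need("domains", stage).reindex(norm_spots.barcodes)
            nuclei = need("nuclei_counts", stage)
            nuclei_labels = need("nuclei_labels", stage)
            spot_stats = reg_mod.group_expression_stats(
                np.asarray(norm_spots.matrix.todense()), domains.to_numpy(), norm_spots.genes
            )
            spot_de = reg_mod.one_vs_all_t(spot_stats)
            norm_nuclei = qc_mod.log_normalize(nuclei, method="scale_factor")
            nuc_stats = reg_mod.group_expression_stats(
                np.asarray(norm_nuclei.matrix.todense()),
                nuclei_labels.loc[norm_nuclei.barcodes, "cell_type"].to_numpy(),
                norm_nuclei.genes,
            )
            nuc_de = reg_mod.one_vs_all_t(nuc_stats)
            spot_t = spot_de.pivot(index="gene", columns="group", values="t")
            nuc_t = nuc_de.pivot(index="gene", columns="group", values="t")
            store.update(spot_de=spot_de, nuclei_de=nuc_de, spot_t=spot_t, nuclei_t=nuc_t)
            spot_de.to_csv(out_dir / "spot_de.csv", index=False)
            _provenance(out_dir, stage, config, ["spot_norm", "nuclei_counts"])
        elif stage == "factors":
            nuclei = need("nuclei_counts", stage)
            nuclei_labels = need("nuclei_labels", stage)
            norm_spots = need("spot_norm", stage)
            norm_nuclei = qc_mod.log_normalize(nuclei, method="scale_factor")
            A = np.asarray(norm_nuclei.matrix.todense())
            model = factors_mod.fit_nmf(
                A,
                config.nmf_k,
                l1_w=config.nmf_l1,
                tol=config.nmf_tol,
                maxit=config.nmf_maxit,
                seed=seed,
            )
            # factor transfer requires a shared gene universe; the synthetic
            # nuclei and spot panels are disjoint by construction, so the
            # projection is exercised nuclei->nuclei and summarised by type
            proj = factors_mod.project_factors(
                model.W, norm_nuclei.genes, A, norm_nuclei.genes
            )
            summary = factors_mod.summarize_by_domain(
                proj.H,
                nuclei_labels.loc[norm_nuclei.barcodes, "cell_type"].to_numpy(),
                config.prevalence_min,
                config.scaled_mean_min,
            )
            assoc = factors_mod.drug_factor_association(
                model.H,
                nuclei_labels.loc[norm_nuclei.barcodes, "condition"].to_numpy(),
                nuclei_labels.loc[norm_nuclei.barcodes, "cell_type"].to_numpy(),
                effect_min=config.effect_min,
                fdr_max=config.fdr_max,
            )
            store.update(nmf_model=model, projection=proj, factor_summary=summary, drug_assoc=assoc)
            summary.to_csv(out_dir / "factor_summary.csv", index=False)
            assoc.to_csv(out_dir / "drug_association.csv", index=False)
            _provenance(out_dir, stage, config, ["nuclei_counts", "spot_norm"])
        elif stage == "lrmap":
            norm = need("spot_norm", stage)
            gt = need("ground_truth", stage)
            sim = need("sim_config", stage)
            weights = sim_mod.simulate_deconv_weights(
                pd.DataFrame({"barcode": norm.barcodes}), gt, seed=seed
            )
            expr = np.asarray(norm.matrix.todense())
            lig, rec = expr[0], expr[1]
            classes = lr_mod.classify_spots(lig, rec)
            props = lr_mod.domain_class_proportions(
                classes, gt.spot_domain_labels.reindex(norm.barcodes).to_numpy()
            )
            result = lr_mod.cooccurrence_enrichment(
                weights, classes == "coexpressing", epsilon=config.epsilon
            )
            store.update(deconv_weights=weights, lr_classes=classes, lr_result=result)
            props.to_csv(out_dir / "lr_domain_proportions.csv")
            result.R.to_csv(out_dir / "lr_enrichment.csv")
            _provenance(out_dir, stage, config, ["spot_norm", "ground_truth"])
        elif stage == "select":
            gt = need("ground_truth", stage)
            domains = need("domains", stage)
            labels = domains.to_dict()
            pairs = [
                (a, b) for a, b in gt.true_overlap_pairs if a in labels and b in labels
            ]
            concordance = (
                metrics_mod.overlap_concordance(labels, pairs) if pairs else float("nan")
            )
            report = {"overlap_concordance": concordance, "n_overlap_pairs": len(pairs)}
            store["selection_report"] = report
            (out_dir / "selection_report.json").write_text(json.dumps(report, indent=2) + "\n")
            _provenance(out_dir, stage, config, ["ground_truth", "domains"])
    return store
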
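"""End-to-end orchestration: simulate -> select -> pattern -> score.

:func:`run_pipeline` chains the library stages exactly as the CLI wires
them: (optionally) generate a synthetic cohort and reference compendium,
select differentially expressed probe-sets for the target contrast,
discover co-expression patterns in the compendium, and quantify every
reference comparison against the target by cumulative scores. Every
output file lands in one directory together with a provenance record
(config hash, seed, versions); any stage failure aborts the run with the
failing stage named.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import compendium as comp_mod
from . import scoring, synthetic
from .io import FLOAT_FORMAT, PipelineConfig, write_expression_table, write_metadata, write_provenance
from .types import PipelineError

__all__ = ["run_pipeline", "simulate_study"]

logger = logging.getLogger("refpattern.pipeline")


def _study_specs(config: PipelineConfig):
    sim = config.simulation
    noise = sim.noise_sd if sim.noise_sd is not None else synthetic.DEFAULT_NOISE_SD
    signature = synthetic.example_signature(
        n_cell_types=sim.n_cell_types,
        markers_per_type=sim.markers_per_type,
        n_background=sim.n_background,
        noise_sd=noise,
    )
    stimuli = synthetic.example_stimuli(
        signature, genes_per_stimulus=sim.genes_per_stimulus, n_replicates=sim.n_replicates
    )
    name = sim.embedded_stimulus or stimuli[0].name
    embedded = next((s for s in stimuli if s.name == name), None)
    if embedded is None:
        raise PipelineError(f"embedded_stimulus {name!r} is not a generated stimulus")
    design = synthetic.two_group_design(
        signature,
        embedded,
        n_per_group=sim.n_per_group,
        group_names=(config.contrast.experimental, config.contrast.baseline),
    )
    return signature, stimuli, design, embedded


def simulate_study(config: PipelineConfig, seed: int, out_dir: str | Path | None = None):
    """Generate the canonical synthetic study: compendium + 2-group cohort.

    Returns ``(cohort_expr, truth, compendium, embedded_stimulus_name)``;
    when ``out_dir`` is given, writes the cohort/compendium TSVs and a
    truth summary there.
    """
    signature, stimuli, design, embedded = _study_specs(config)
    ref_expr, ref_meta = synthetic.generate_reference_compendium(
        signature, stimuli, seed=seed + 1
    )
    cohort, truth = synthetic.generate_tissue_cohort(signature, stimuli, design, seed=seed)
    comp = comp_mod.Compendium(ref_expr, ref_meta, normalized=False)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_expression_table(cohort.values, out / "cohort_expression.tsv")
        write_metadata(
            pd.DataFrame({"sample_id": cohort.samples, "group": cohort.groups.values}),
            out / "cohort_metadata.tsv",
        )
        write_expression_table(ref_expr.values, out / "compendium_expression.tsv")
        write_metadata(ref_meta, out / "compendium_metadata.tsv")
        truth_frame = truth.expected_log2.round(6)
        truth_frame.to_csv(out / "truth_expected_log2.tsv", sep="\t", index_label="gene")
        (out / "truth_summary.json").write_text(
            json.dumps(
                {
                    "seed": truth.seed,
                    "embedded_stimulus": embedded.name,
                    "noise_sd": signature.noise_sd,
                    "n_genes": len(signature.genes),
                    "n_samples": len(cohort.samples),
                },
                indent=2,
            )
            + "\n"
        )
    return cohort, truth, comp, embedded.name


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: PipelineConfig, seed: int | None = None, out_dir: str | Path = "out"):
    """Run the full workflow and write all result tables under ``out_dir``.

    Returns a result bundle dict with the in-memory objects of each stage.
    """
    seed = seed if seed is not None else config.seed
    if seed is None:
        raise PipelineError("a seed is required (config.seed or argument)")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    stage = "simulate"
    try:
        _stage(stage)
        from .io import load_expression, read_metadata

        if {"expression", "metadata"} <= set(config.paths):
            cohort = load_expression(
                config.paths["expression"],
                config.paths["metadata"],
                config.paths.get("gene_map"),
            )
            truth = None
            if {"compendium_expression", "compendium_metadata"} <= set(config.paths):
                from .io import read_expression_table
                from .types import ExpressionMatrix

                ref_values = read_expression_table(config.paths["compendium_expression"])
                ref_meta = pd.read_csv(
                    config.paths["compendium_metadata"], sep="\t", dtype=str
                ).fillna("")
                groups = ref_meta.set_index("array_id")["condition"]
                comp = comp_mod.Compendium(
                    ExpressionMatrix(ref_values, groups), ref_meta, normalized=False
                )
            else:
                comp = None
            embedded = None
        else:
            cohort, truth, comp, embedded = simulate_study(config, seed, out / "simulated")
        bundle.update(cohort=cohort, truth=truth, embedded_stimulus=embedded)

        stage = "select"
        _stage(stage)
        crit = config.selection
        exp_g, base_g = config.contrast.experimental, config.contrast.baseline
        from .pairwise import select_differential

        selection = select_differential(cohort, exp_g, base_g, crit)
        selection.to_csv(out / "selection.tsv", sep="\t", index_label="probe_set",
                         float_format=FLOAT_FORMAT)
        target = scoring.score_contrast(cohort, exp_g, base_g, crit)
        target.to_csv(out / "gene_scores.tsv", sep="\t", index_label="gene",
                      float_format=FLOAT_FORMAT)
        bundle.update(selection=selection, target=target)

        if comp is not None:
            stage = "compendium"
            _stage(stage)
            norm = comp_mod.Compendium(
                type(comp.expr)(
                    comp_mod.quantile_normalize(comp.expr.values),
                    comp.expr.groups,
                    comp.expr.gene_map,
                ),
                comp.metadata,
                normalized=True,
            )
            de_genes = [g for g in selection.index[selection["selected"]]
                        if g in set(norm.expr.probe_sets)]
            bundle["compendium"] = norm
            if len(de_genes) >= 2:
                cm = comp_mod.gene_coexpression(norm, de_genes)
                cm.r.round(6).to_csv(out / "coexpression.tsv", sep="\t", index_label="gene")
                k = config.clustering.k or len({
                    c for c in norm.metadata["cell_class"]
                })
                params = comp_mod.ClusteringParams(
                    config.clustering.distance, config.clustering.linkage, k
                )
                clustering = comp_mod.cluster_genes(cm, params)
                (out / "leaf_order.txt").write_text("\n".join(clustering.leaf_order) + "\n")
                patterns = comp_mod.assign_patterns(norm, clustering.labels)
                patterns.to_csv(out / "patterns.tsv", sep="\t", float_format=FLOAT_FORMAT)
                clustering.labels.to_frame().to_csv(out / "clusters.tsv", sep="\t",
                                                    index_label="gene")
                bundle.update(coexpression=cm, clustering=clustering, patterns=patterns)
            structure = comp_mod.sample_structure(cohort, de_genes or None)
            structure.scores.round(6).to_csv(out / "pca_scores.tsv", sep="\t",
                                             index_label="sample")
            pd.DataFrame(
                {"component": [f"PC{i+1}" for i in range(len(structure.percent_variance))],
                 "percent_variance": structure.percent_variance}
            ).to_csv(out / "pca_variance.tsv", sep="\t", index=False,
                     float_format=FLOAT_FORMAT)
            bundle["structure"] = structure

            stage = "score"
            _stage(stage)
            stim_conditions = [
                c for c in norm.conditions if norm.control_condition_of(c) is not None
            ]
            comparisons = [
                scoring.ReferenceComparison.from_compendium(norm, c) for c in stim_conditions
            ]
            ref_tables = scoring.score_reference_comparisons(norm, comparisons, crit)
            up_target = target[(target["selected"]) & (target["direction"] == "up")]
            top_n = min(config.scoring.top_n, len(up_target))
            if top_n > 0 and ref_tables:
                curves = scoring.cumulative_curves(
                    up_target, ref_tables, top_n,
                    clip_negative=config.scoring.clip_negative,
                )
                curve_dir = out / "curves"
                curve_dir.mkdir(exist_ok=True)
                for name, curve in curves.items():
                    curve.table.to_csv(curve_dir / f"{name}.tsv", sep="\t",
                                       float_format=FLOAT_FORMAT)
                summary = scoring.summarize_curves(curves)
                summary.to_csv(out / "curve_summary.tsv", sep="\t",
                               float_format=FLOAT_FORMAT)
                overlaps = pd.DataFrame(
                    [
                        {
                            "reference": name,
                            "overlap": scoring.top_overlap(up_target, tbl,
                                                           min(top_n, len(tbl)))[0],
                        }
                        for name, tbl in ref_tables.items()
                    ]
                ).set_index("reference")
                overlaps.to_csv(out / "top_overlap.tsv", sep="\t")
                bundle.update(curves=curves, curve_summary=summary, overlaps=overlaps)
                if embedded is not None:
                    report = {
                        "embedded_stimulus": embedded,
                        "best_reference": summary.index[0],
                        "recovered": bool(summary.index[0] == embedded),
                        "percent_max": float(summary.iloc[0]["percent_max"]),
                    }
                    (out / "truth_recovery.json").write_text(
                        json.dumps(report, indent=2) + "\n"
                    )
                    bundle["truth_recovery"] = report

        write_provenance(out, config, seed)
    except Exception as err:  # noqa: BLE001 - annotate with the failing stage
        raise PipelineError(f"pipeline stage {stage!r} failed: {err}") from err
    return bundle
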
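"""End-to-end orchestration: QC to cell-type assignment, plus evaluation.

``run_pipeline`` executes preprocessing, factorization, scoring and
assignment on a count matrix and writes every stage product with a run
manifest. ``evaluate_program_recovery`` runs the same stages in memory on
a simulated cohort and measures how well the planted programs and cell
types are recovered — the package's main self-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import factorize, io, preprocess, scoring
from .config import PipelineConfig, RunManifest, digest_array
from .simulate import CELL_TYPES, STATE_PROGRAMS, GroundTruth, SpheroidSimConfig, generate_spheroid_cohort

logger = logging.getLogger("crcprograms")


@dataclass
class PipelineResult:
    filtered: ad.AnnData
    expression: ad.AnnData
    centered: ad.AnnData
    lgr5: pd.DataFrame
    model: factorize.FactorModel
    retained_factors: list[str]
    signatures: list[factorize.Signature]
    meta_signatures: list[scoring.MetaSignature]
    scores: scoring.CellScoreTable
    meta_scores: scoring.CellScoreTable
    assignment: scoring.CellTypeAssignment
    manifest: RunManifest


def run_pipeline(
    config: PipelineConfig,
    counts: ad.AnnData,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute preprocess -> factorization -> scoring -> assignment.

    Stage summaries (cells removed per QC rule, genes removed by the
    aggregate-expression filter, factors retained, cells per assigned type)
    are logged and recorded in the returned manifest. Any stage failure
    raises with the stage name attached.
    """
    manifest = RunManifest(
        input_digests={"counts": digest_array(np.asarray(counts.X))},
        config=config.model_dump(),
        seed=config.seed,
    )

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    qc = config.qc
    filtered = stage(
        "qc_filter",
        preprocess.qc_filter,
        counts,
        min_reads=qc.min_reads,
        min_genes=qc.min_genes,
        max_mito=qc.max_mito,
        top_read_quantile=qc.top_read_quantile,
        pca_outlier_sd=qc.pca_outlier_sd,
    )
    manifest.add_stage("qc_filter", **filtered.uns["qc_log"])
    logger.info("qc_filter: %s -> %s cells", counts.n_obs, filtered.n_obs)

    lgr5 = stage(
        "lgr5_score", preprocess.lgr5_score, filtered, config.lgr5.gene, config.lgr5.threshold
    )
    if config.lgr5.restrict_to_positive:
        positive = lgr5.index[lgr5["is_positive"]]
        filtered = filtered[filtered.obs["patient"].isin(positive)].copy()
        if filtered.n_obs == 0:
            raise RuntimeError("stage 'lgr5_gate' failed: no positive culture")
    manifest.add_stage(
        "lgr5_gate",
        positive_cultures=int(lgr5["is_positive"].sum()),
        excluded_cultures=int((~lgr5["is_positive"]).sum()),
        cells_retained=filtered.n_obs,
    )

    expression = stage("normalize_cpm_log", preprocess.normalize_cpm_log, filtered)
    genes_before = expression.n_vars
    expression = stage(
        "filter_low_expression",
        preprocess.filter_low_expression,
        expression,
        min_ea=config.normalize.min_ea,
    )
    manifest.add_stage(
        "filter_low_expression",
        genes_in=genes_before,
        genes_out=expression.n_vars,
        genes_removed=genes_before - expression.n_vars,
    )
    logger.info("gene filter: %s -> %s genes", genes_before, expression.n_vars)

    centered = stage("mean_center_by_patient", preprocess.mean_center_by_patient, expression)

    model = stage(
        "fit_nnmf",
        factorize.fit_nnmf,
        centered,
        k=config.nnmf.k,
        seed=config.seed,
        n_restarts=config.nnmf.n_restarts,
        max_iter=config.nnmf.max_iter,
        tol=config.nnmf.tol,
    )
    retained = stage(
        "filter_patient_specific_factors",
        factorize.filter_patient_specific_factors,
        model,
        centered.obs["patient"],
        overlap_threshold=config.factor_filter.overlap_threshold,
        min_patients=config.factor_filter.min_patients,
        n_bins=config.factor_filter.n_bins,
    )
    manifest.add_stage(
        "fit_nnmf",
        k=model.k,
        reconstruction_error=model.reconstruction_error,
        factors_retained=len(retained),
        factors_excluded=model.k - len(retained),
    )

    top_n = min(config.scoring.top_n_genes, expression.n_vars)
    signatures = stage(
        "extract_signatures", factorize.extract_signatures, model, retained, top_n
    )
    scores = stage(
        "score_cells",
        scoring.score_table,
        expression,
        signatures,
        n_bins=config.scoring.n_bins,
        n_control_per_gene=config.scoring.n_control_per_gene,
        seed=config.seed,
    )
    metas = stage(
        "combine_meta_signatures",
        scoring.combine_meta_signatures,
        scores,
        signatures,
        r_threshold=config.meta.r_threshold,
    )
    meta_scores = stage(
        "score_meta_signatures",
        scoring.score_table,
        expression,
        metas,
        n_bins=config.scoring.n_bins,
        n_control_per_gene=config.scoring.n_control_per_gene,
        seed=config.seed,
    )
    assignment = stage("assign_cell_types", scoring.assign_cell_types, meta_scores.corrected)
    counts_by_type = assignment.assigned.value_counts().to_dict()
    manifest.add_stage(
        "assign_cell_types",
        meta_signatures=len(metas),
        cells_per_type={str(k): int(v) for k, v in counts_by_type.items()},
    )

    result = PipelineResult(
        filtered=filtered,
        expression=expression,
        centered=centered,
        lgr5=lgr5,
        model=model,
        retained_factors=retained,
        signatures=signatures,
        meta_signatures=metas,
        scores=scores,
        meta_scores=meta_scores,
        assignment=assignment,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    io.write_table(result.lgr5, out_dir / "lgr5_gate.tsv")
    io.write_factor_model(result.model, out_dir / "factors_W.tsv", out_dir / "factors_H.tsv")
    io.write_gmt(result.signatures, out_dir / "signatures.gmt")
    io.write_gmt(result.meta_signatures, out_dir / "meta_signatures.gmt")
    io.write_table(result.meta_scores.corrected, out_dir / "meta_scores_corrected.tsv")
    io.write_table(
        result.assignment.assigned.to_frame(), out_dir / "cell_type_assignment.tsv"
    )
    result.manifest.outputs = {
        p.name: str(p) for p in sorted(out_dir.glob("*")) if p.name != "manifest.json"
    }
    result.manifest.to_json(out_dir / "manifest.json")


# ---------------------------------------------------------------------------
# Planted-program recovery


def jaccard(a: set, b: set) -> float:
    return len(a & b) / len(a | b) if (a or b) else 0.0


def _meta_jaccard(
    meta: scoring.MetaSignature,
    planted: set,
    by_name: dict[str, factorize.Signature] | None,
) -> float:
    """Top-gene Jaccard of a meta-signature against a planted gene set.

    A meta-signature recovers a program either directly (its rank-ordered
    union prefix) or through one of its member factor signatures — merging
    two coupled programs into one meta-signature must not mask that each
    was found. Gene sets are compared at the planted program's size.
    """
    m = len(planted)
    best = jaccard(planted, set(meta.genes[:m]))
    if by_name is not None:
        for member in meta.members:
            sig = by_name.get(member)
            if sig is not None:
                best = max(best, jaccard(planted, set(sig.genes[:m])))
    return best


def match_programs(
    metas: list[scoring.MetaSignature],
    truth: GroundTruth,
    programs: list[str],
    signatures: list[factorize.Signature] | None = None,
) -> pd.DataFrame:
    """Best meta-signature per planted program by top-gene Jaccard."""
    by_name = {s.name: s for s in signatures} if signatures else None
    rows = []
    for prog in programs:
        planted = set(truth.members(prog))
        best_meta, best_j = None, -1.0
        for meta in metas:
            j = _meta_jaccard(meta, planted, by_name)
            if j > best_j:
                best_meta, best_j = meta.name, j
        rows.append({"program": prog, "meta_signature": best_meta, "jaccard": best_j})
    return pd.DataFrame(rows).set_index("program")


def evaluate_program_recovery(
    sim_config: SpheroidSimConfig, pipe_config: PipelineConfig
) -> dict:
    """Simulate a cohort, run the pipeline and score recovery of the truth.

    Returns a dict with the per-program recovery Jaccards, the cell-type
    assignment accuracy against ground truth (computed on the cells that
    survive QC and gating), and the TA-vs-Tdiff Mann-Whitney contrasts for
    the OXPHOS and hypoxia/glycolysis state programs.
    """
    counts, truth = generate_spheroid_cohort(sim_config)
    result = run_pipeline(pipe_config, counts)

    planted = [p.name for p in sim_config.program_defs]
    recovery = match_programs(result.meta_signatures, truth, planted, result.signatures)

    # One-to-one map of the four type programs onto meta-signatures.
    by_name = {s.name: s for s in result.signatures}
    type_programs = [p for p in planted if p in CELL_TYPES]
    metas = result.meta_signatures
    cost = np.zeros((len(type_programs), len(metas)))
    for i, prog in enumerate(type_programs):
        planted_set = set(truth.members(prog))
        for j, meta in enumerate(metas):
            cost[i, j] = -_meta_jaccard(meta, planted_set, by_name)
    rows, cols = linear_sum_assignment(cost)
    type_map = {metas[c].name: type_programs[r] for r, c in zip(rows, cols)}

    type_scores = result.meta_scores.corrected[list(type_map)].rename(columns=type_map)
    assignment = scoring.assign_cell_types(type_scores)
    truth_types = truth.cells.loc[assignment.assigned.index, "cell_type"]
    accuracy = float((assignment.assigned == truth_types).mean())

    state_metas = {}
    for prog in (p for p in planted if p in STATE_PROGRAMS):
        state_metas[prog] = recovery.loc[prog, "meta_signature"]
    state_scores = result.meta_scores.corrected[list(state_metas.values())]
    state_scores = state_scores.set_axis(list(state_metas), axis=1)
    contrasts = scoring.compare_states_across_types(assignment, state_scores)

    def _pair(state, a, b):
        sel = contrasts[
            (contrasts["state"] == state)
            & (contrasts[["type_a", "type_b"]].isin([a, b]).all(axis=1))
        ]
        if sel.empty:
            return None
        row = dict(sel.iloc[0])
        if row["type_a"] != a:  # orient so 'a' statistics describe group a
            row = {
                **row,
                "type_a": a,
                "type_b": b,
                "median_a": row["median_b"],
                "median_b": row["median_a"],
            }
        return row

    ox = _pair("OXPHOS", "TA", "Tdiff")
    hyp = _pair("hypoxia_glycolysis", "TA", "Tdiff")
    return {
        "recovery": recovery,
        "min_jaccard": float(recovery["jaccard"].min()),
        "assignment_accuracy": accuracy,
        "n_cells_assigned": int((assignment.assigned != scoring.UNASSIGNED).sum()),
        "n_cells": int(len(assignment.assigned)),
        "oxphos_ta_vs_tdiff": ox,
        "hypoxia_ta_vs_tdiff": hyp,
        "result": result,
        "truth": truth,
    }
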
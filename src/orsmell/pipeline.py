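"""End-to-end orchestration of the synthetic OR study.

Stage order mirrors the analysis: simulate (or load) a raw TPM single-cell
matrix -> doublet filtering -> zFPKM activation -> repertoire statistics ->
GSVA stemness -> trajectory and pseudotime correlations -> OR signatures ->
bulk projection -> patient stratification -> survival comparison.  The
:func:`run_synthetic_study` entry point is what the command-line pipeline,
the analysis drivers and the acceptance script all call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    activation as act,
    differential,
    doublet_filter,
    enrichment,
    io_catalog,
    repertoire,
    stratification,
    survival as surv,
    synthetic_data as synth,
    trajectory,
)
from .errors import ValidationError


@dataclass
class StudyResult:
    config: synth.SimulationConfig
    catalog: io_catalog.GeneCatalog
    matrix: io_catalog.ExpressionMatrix          # after doublet filtering
    truth: synth.CellTruth                       # aligned to kept singlet cells
    doublet_report: doublet_filter.DoubletReport
    doublet_truth: np.ndarray                    # planted labels, pre-filter order
    zscores: act.ZScoreMatrix
    activation: act.ActivationMatrix
    or_positive_percent: float
    profile: repertoire.RepertoireProfile
    coexpression: pd.DataFrame
    one_or_none_fraction: float
    count_expr_corr: object
    stemness_scores: np.ndarray
    traj: trajectory.TrajectoryResult
    correlations: pd.DataFrame
    signatures: list[stratification.Signature]
    bulk: io_catalog.ExpressionMatrix
    similarity: stratification.SimilarityMatrix
    survival_table: io_catalog.SurvivalTable
    bulk_truth_groups: np.ndarray
    logrank: surv.LogrankResult


def _subset_truth(truth: synth.CellTruth, keep: np.ndarray) -> synth.CellTruth:
    return synth.CellTruth(
        truth.latent_time[keep],
        truth.stemness[keep],
        truth.or_count[keep],
        truth.cluster[keep],
        [truth.expressed_ors[i] for i in np.nonzero(keep)[0]],
        truth.stemness_genes,
        truth.cluster_marker_genes,
    )


def run_synthetic_study(
    config: synth.SimulationConfig,
    doublet_n_pcs: int = 30,
    traj_n_pcs: int = 5,
    k_nn: int = 15,
    n_signatures: int | str = 3,
    n_patient_groups: int | str = 3,
    stemness_from_truth: bool = False,
) -> StudyResult:
    """Run the whole synthetic study under one config.

    ``stemness_from_truth`` bypasses GSVA stemness scoring with the
    generator's latent stemness (useful for isolating the trajectory stage);
    the default scores stemness from the planted stemness gene set exactly as
    the real analysis would.
    """
    catalog = synth.simulate_catalog(config)
    clean, truth = synth.simulate_cells(config, catalog)

    # --- doublet injection + filtering -----------------------------------
    doublet_seed = int(np.random.default_rng([config.seed, 3]).integers(2**31))
    mixed, planted = synth.inject_doublets(clean, config.doublet_rate, doublet_seed)
    report = doublet_filter.score_doublets(
        mixed, n_pcs=min(doublet_n_pcs, mixed.n_samples - 1), seed=doublet_seed
    )
    report, filtered = doublet_filter.call_doublets(report, mixed)
    kept_ids = set(filtered.sample_ids)
    keep_clean = np.array([sid in kept_ids for sid in clean.sample_ids])
    # restrict downstream analysis to kept singlets (planted doublets that
    # slipped through carry no truth and are dropped here)
    singlet_cols = [i for i, sid in enumerate(filtered.sample_ids)
                    if not sid.startswith("doublet")]
    matrix = filtered.subset_samples(singlet_cols)
    truth_kept = _subset_truth(truth, keep_clean)

    gate = io_catalog.validate_dataset(matrix)
    if not gate.passed:
        raise ValidationError(f"dataset below the inclusion gate: {gate.message}")

    # --- activation + repertoire -----------------------------------------
    zmat = act.zfpkm_transform(matrix)
    amat = act.binarize_activation(zmat)
    _, or_pos_pct = act.or_positive_cells(amat, catalog)
    profile = repertoire.or_counts_per_cell(amat, catalog, expression=matrix)
    coexpr, one_or_none = repertoire.coexpression_distribution(profile)
    try:
        count_corr = repertoire.count_expression_correlation(profile)
    except ValidationError:
        count_corr = None

    # --- stemness + trajectory -------------------------------------------
    if stemness_from_truth:
        stemness = truth_kept.stemness
    else:
        scores = enrichment.gsva_scores(matrix, {"stemness": truth.stemness_genes})
        stemness = scores.row("stemness")
    # embed on the non-chemoreceptor transcriptome: the pseudotime axis is
    # later correlated with OR counts, so letting OR expression shape the
    # embedding would make that comparison circular
    chemo = set(catalog.table["symbol"])
    bg_rows = [i for i, g in enumerate(matrix.gene_ids) if g not in chemo]
    traj_res = trajectory.embed_and_cluster(
        matrix.subset_rows(bg_rows),
        n_pcs=min(traj_n_pcs, matrix.n_samples - 1),
        k_nn=k_nn,
        seed=config.seed,
    )
    traj_res = trajectory.select_root(traj_res, stemness)
    traj_res = trajectory.compute_pseudotime(traj_res, k_nn=k_nn)
    correlations = trajectory.pseudotime_correlations(traj_res, stemness, profile)

    # --- signatures -> bulk cohort -> stratification -> survival ---------
    or_rows = [i for i, g in enumerate(matrix.gene_ids)
               if g in set(catalog.functional_ors())]
    or_expr = matrix.subset_rows(or_rows)
    signatures = stratification.build_or_signatures(or_expr, amat, n_clusters=n_signatures)
    sig_tpm = np.column_stack([np.exp2(s.values) - 1.0 for s in signatures])
    sig_tpm = np.clip(sig_tpm, 0.0, None)
    bulk, surv_table, truth_groups = synth.simulate_bulk_cohort(
        sig_tpm, signatures[0].gene_ids, config
    )
    sim = stratification.project_signatures(bulk, signatures)
    sim = stratification.stratify_patients(sim, n_groups=n_patient_groups)
    grouped = surv_table.with_groups(
        pd.Series(sim.groups, index=sim.patient_ids)
    )
    logrank = surv.logrank_test(grouped)

    return StudyResult(
        config=config,
        catalog=catalog,
        matrix=matrix,
        truth=truth_kept,
        doublet_report=report,
        doublet_truth=planted,
        zscores=zmat,
        activation=amat,
        or_positive_percent=or_pos_pct,
        profile=profile,
        coexpression=coexpr,
        one_or_none_fraction=one_or_none,
        count_expr_corr=count_corr,
        stemness_scores=np.asarray(stemness, dtype=float),
        traj=traj_res,
        correlations=correlations,
        signatures=signatures,
        bulk=bulk,
        similarity=sim,
        survival_table=grouped,
        bulk_truth_groups=truth_groups,
        logrank=logrank,
    )


def run_trajectory_study(
    config: synth.SimulationConfig,
    traj_n_pcs: int = 5,
    k_nn: int = 15,
    stemness_from_truth: bool = False,
) -> tuple[trajectory.TrajectoryResult, pd.DataFrame, synth.CellTruth]:
    """The trajectory arm in isolation: simulate -> activation -> stemness ->
    embed -> root -> pseudotime -> correlations.

    No doublet injection or filtering: this entry point is for studying
    pseudotime recovery itself on clean cells (the full study handles QC).
    Returns the trajectory result, its correlation table and the ground truth.
    """
    catalog = synth.simulate_catalog(config)
    matrix, truth = synth.simulate_cells(config, catalog)
    zmat = act.zfpkm_transform(matrix)
    amat = act.binarize_activation(zmat)
    profile = repertoire.or_counts_per_cell(amat, catalog, expression=matrix)
    if stemness_from_truth:
        stemness = truth.stemness
    else:
        stemness = enrichment.gsva_scores(
            matrix, {"stemness": truth.stemness_genes}
        ).row("stemness")
    chemo = set(catalog.table["symbol"])
    bg_rows = [i for i, g in enumerate(matrix.gene_ids) if g not in chemo]
    traj_res = trajectory.embed_and_cluster(
        matrix.subset_rows(bg_rows),
        n_pcs=min(traj_n_pcs, matrix.n_samples - 1),
        k_nn=k_nn,
        seed=config.seed,
    )
    traj_res = trajectory.select_root(traj_res, stemness)
    traj_res = trajectory.compute_pseudotime(traj_res, k_nn=k_nn)
    correlations = trajectory.pseudotime_correlations(traj_res, stemness, profile)
    return traj_res, correlations, truth


def hazard_ordering_matches(result: StudyResult) -> bool:
    """Do discovered patient groups rank by mortality as the planted hazards say?

    Each discovered group inherits the planted hazard of the majority of its
    members, and its observed mortality is summarized as the Kaplan-Meier
    survival probability at the cohort's median follow-up time (a per-group
    event rate per person-time would be dominated by the enormous person-time
    of any long-lived minority members).  For every pair of groups that
    represent *different* planted hazards, the group with the higher planted
    hazard must show the lower KM survival; pairs representing the same
    planted hazard carry no ordering information and are not compared.
    """
    from lifelines import KaplanMeierFitter

    t = result.survival_table.table
    hazards = np.array(
        [result.config.hazards[g % len(result.config.hazards)]
         for g in result.bulk_truth_groups]
    )
    horizon = float(np.median(t["time"]))
    majority = {}
    km_surv = {}
    for g in sorted(t["group"].dropna().unique()):
        if g < 0:
            continue
        mask = (t["group"] == g).to_numpy()
        vals, counts = np.unique(hazards[mask], return_counts=True)
        majority[g] = vals[np.argmax(counts)]
        kmf = KaplanMeierFitter().fit(
            t.loc[mask, "time"].to_numpy(), t.loc[mask, "event"].to_numpy()
        )
        km_surv[g] = float(kmf.survival_function_at_times(horizon).iloc[0])
    groups = list(majority)
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            if majority[a] != majority[b]:
                if (majority[a] - majority[b]) * (km_surv[b] - km_surv[a]) < 0:
                    return False
    return True


def write_study(result: StudyResult, out_dir: str | Path) -> Path:
    """Write the study's tables as TSVs (deterministic byte-for-byte)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io_catalog.write_catalog(result.catalog, out / "catalog.tsv")
    result.truth.frame(result.matrix.sample_ids).to_csv(
        out / "cell_truth.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {
            "cell_id": result.doublet_report.sample_ids,
            "score": result.doublet_report.scores,
            "call": np.where(result.doublet_report.calls, "doublet", "singlet"),
        }
    ).to_csv(out / "doublet_report.tsv", sep="\t", index=False)
    result.profile.frame().to_csv(out / "repertoire_profile.tsv", sep="\t", index=False)
    result.coexpression.to_csv(out / "coexpression.tsv", sep="\t", index=False)
    result.correlations.to_csv(out / "trajectory_correlations.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "cell_id": result.matrix.sample_ids,
            "cluster": result.traj.clusters,
            "pseudotime": result.traj.pseudotime,
            "stemness_score": result.stemness_scores,
        }
    ).to_csv(out / "trajectory.tsv", sep="\t", index=False)
    sig_frame = pd.DataFrame(
        {f"signature_{s.cluster_id}": s.values for s in result.signatures},
        index=result.signatures[0].gene_ids,
    )
    sig_frame.to_csv(out / "signatures.tsv", sep="\t", index_label="or_symbol")
    result.similarity.frame().assign(group=result.similarity.groups).to_csv(
        out / "similarity.tsv", sep="\t", index_label="patient_id"
    )
    io_catalog.write_survival(result.survival_table, out / "survival_groups.tsv")
    pd.DataFrame(
        [
            {
                "or_positive_percent": result.or_positive_percent,
                "one_or_none_fraction": result.one_or_none_fraction,
                "n_signatures": len(result.signatures),
                "n_patient_groups": len(
                    {g for g in result.similarity.groups if g >= 0}
                ),
                "logrank_chi_square": result.logrank.chi_square,
                "logrank_p": result.logrank.p,
            }
        ]
    ).to_csv(out / "summary.tsv", sep="\t", index=False)
    return out
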
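"""End-to-end orchestration of the phenotyping workflow.

Stages: simulate (or load) the cohort -> preprocess -> vote on the cluster
count -> consensus clustering with the stability protocol (SOM stack and
k-means reference) -> leave-one-out importance -> group statistics.  All
randomness flows from a single master seed through documented derivations;
the full report is regenerable bit-identically from config + seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortMatrix, read_cohort, write_cohort
from .consensus import method_overlap, stability_protocol
from .importance import (
    VARIABLE_GATE_PERCENT,
    importance_table,
    leave_one_test_out,
    leave_one_variable_out,
)
from .preprocess import preprocess
from .schema import SymptomTable
from .simulate import SimulationConfig, generate_cohort
from .stats import bonferroni_alpha, compare_groups, pca, symptom_contrast
from .validity import vote_best_k


@dataclass
class PipelineConfig:
    """Workflow parameters; numeric defaults follow the study protocol
    (500 evaluation repetitions, 3 x 100 consensus, 20 + 50 epochs,
    10% stability threshold, 20% variable gate)."""

    input_path: str | None = None              # cohort CSV; None -> simulate
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    k_range: tuple[int, int] = (2, 10)
    criteria: tuple[str, ...] = ("CH", "SI", "Gap", "DB")
    n_eval_reps: int = 500
    n_consensus_reps: int = 100
    n_triplet: int = 3
    first_layer_size: tuple[int, int] = (8, 6)
    candidate_sizes: tuple[tuple[int, int], ...] | None = None  # QE/TE-rank pick
    master_seed: int = 0
    alpha: float = 0.05
    alpha_override: float | None = None        # e.g. a pre-computed 0.0006
    out_dir: str = "results"

    def reduced(self) -> "PipelineConfig":
        """Desk-scale variant: 50 evaluation reps and 3 x 20 consensus."""
        import dataclasses

        return dataclasses.replace(self, n_eval_reps=50, n_consensus_reps=20)


def load_or_simulate(config: PipelineConfig) -> tuple[CohortMatrix, SymptomTable | None]:
    if config.input_path is not None:
        return read_cohort(config.input_path), None
    import dataclasses

    sim = dataclasses.replace(config.simulation, seed=config.master_seed)
    return generate_cohort(sim)


def run_cluster_stage(config: PipelineConfig, cohort: CohortMatrix) -> dict:
    """Cluster-count vote + SOM/k-means stability protocols + overlap."""
    z = preprocess(cohort)
    votes = {
        crit: vote_best_k(
            z, range(config.k_range[0], config.k_range[1] + 1),
            n_reps=config.n_eval_reps, criterion=crit,
            seed=config.master_seed + 100 * i,
        )
        for i, crit in enumerate(config.criteria)
    }
    decisive = [v for v in votes.values() if v.decisive]
    chosen_k = decisive[0].mode_k if decisive else votes["CH"].mode_k

    first_layer = config.first_layer_size
    size_table = None
    if config.candidate_sizes:
        from .som import select_map_size

        first_layer, size_table = select_map_size(
            z, [tuple(c) for c in config.candidate_sizes],
            seed=config.master_seed,
        )

    som_report = stability_protocol(
        z, method="som", target_k=chosen_k,
        n_reps=config.n_consensus_reps, n_triplet=config.n_triplet,
        master_seed=config.master_seed,
        first_layer_size=first_layer,
    )
    km_report = stability_protocol(
        z, method="kmeans", target_k=chosen_k,
        n_reps=config.n_consensus_reps, n_triplet=config.n_triplet,
        master_seed=config.master_seed,
    )
    overlap = None
    if som_report.final_labels is not None:
        from .consensus import consensus_mode

        km_labels = (km_report.final_labels
                     if km_report.final_labels is not None
                     else consensus_mode(km_report.consensus_triplet))
        frac, table = method_overlap(som_report.final_labels, km_labels)
        overlap = {"fraction": frac, "cross_counts": table.tolist()}
    return {
        "z": z,
        "votes": votes,
        "chosen_k": chosen_k,
        "first_layer_size": first_layer,
        "size_table": size_table,
        "som": som_report,
        "kmeans": km_report,
        "overlap": overlap,
    }


def run_importance_stage(config: PipelineConfig, cohort: CohortMatrix,
                         cluster: dict) -> list:
    som_report = cluster["som"]
    if not som_report.stable:
        raise RuntimeError(
            "clustering outcome is unstable; importance analysis refused"
        )
    first_layer = cluster.get("first_layer_size", config.first_layer_size)
    results = leave_one_test_out(
        cohort, som_report, target_k=cluster["chosen_k"],
        n_reps=config.n_consensus_reps, n_triplet=config.n_triplet,
        master_seed=config.master_seed,
        first_layer_size=first_layer,
    )
    for block_res in list(results):
        if block_res.percent_reclassified >= VARIABLE_GATE_PERCENT:
            results.extend(
                leave_one_variable_out(
                    cohort, block_res.removed, som_report,
                    block_res.percent_reclassified,
                    target_k=cluster["chosen_k"],
                    n_reps=config.n_consensus_reps,
                    n_triplet=config.n_triplet,
                    master_seed=config.master_seed,
                    first_layer_size=first_layer,
                )
            )
    return results


def run_stats_stage(config: PipelineConfig, cohort: CohortMatrix,
                    symptoms: SymptomTable | None, cluster: dict) -> dict:
    som_report = cluster["som"]
    if not som_report.stable:
        raise RuntimeError(
            "clustering outcome is unstable; group statistics refused"
        )
    from .preprocess import impute_median

    z = cluster["z"]
    imputed = impute_median(cohort)
    alpha_corr = (config.alpha_override
                  if config.alpha_override is not None
                  else bonferroni_alpha(config.alpha, z.n_variables))
    comparison = compare_groups(imputed, z, som_report.final_labels, alpha_corr)
    pca_result = pca(z)
    out = {"comparison": comparison, "pca": pca_result,
           "alpha_corrected": alpha_corr}
    if symptoms is not None:
        out["symptoms"] = symptom_contrast(symptoms, som_report.final_labels)
    return out


def run_report(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Full workflow; writes tables under ``out_dir`` and returns the report."""
    t0 = time.time()
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, symptoms = load_or_simulate(config)
    write_cohort(cohort, out / "cohort.csv", seed=config.master_seed)

    cluster = run_cluster_stage(config, cohort)
    labels = cluster["som"].final_labels
    report: dict = {
        "provenance": {
            "version": __version__,
            "master_seed": config.master_seed,
            "n_eval_reps": config.n_eval_reps,
            "n_consensus_reps": config.n_consensus_reps,
        },
        "criterion_votes": {c: v.to_dict() for c, v in cluster["votes"].items()},
        "chosen_k": cluster["chosen_k"],
        "som_stability": cluster["som"].to_dict(),
        "kmeans_stability": cluster["kmeans"].to_dict(),
        "method_overlap": cluster["overlap"],
    }
    if labels is not None:
        pd.DataFrame({
            "patient_id": cohort.patient_ids,
            "label": labels,
        }).to_csv(out / "final_labels.csv", index=False)
        importance = run_importance_stage(config, cohort, cluster)
        importance_table(importance).to_csv(
            out / "importance.tsv", sep="\t", index=False
        )
        report["importance"] = [
            {"level": r.level, "removed": r.removed,
             "percent_reclassified": r.percent_reclassified}
            for r in importance
        ]
        stats = run_stats_stage(config, cohort, symptoms, cluster)
        stats["comparison"].table.to_csv(
            out / "group_comparison.tsv", sep="\t", index=False
        )
        if "symptoms" in stats:
            stats["symptoms"].to_csv(out / "symptom_contrast.tsv",
                                     sep="\t", index=False)
        report["group_comparison"] = json.loads(
            stats["comparison"].table.to_json(orient="records")
        )
        report["alpha_corrected"] = stats["alpha_corrected"]
        report["pca_explained_fraction"] = [
            float(f) for f in stats["pca"].explained_variance_fraction[:10]
        ]
    report["elapsed_s"] = round(time.time() - t0, 2)
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
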
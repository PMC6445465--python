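"""Consensus clustering with the triplet stability protocol.

Runs the stacked-SOM clustering and the k-means reference, each as three
independent 20-repetition mode consensuses, applies the <10% discordance
stability rule, reports their overlap, and writes the final labels plus a
first-layer U-matrix.

Usage: python analysis/03_cluster_stability.py [--seed 0] [--reps 20]
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from phenosom.cohort import read_cohort
from phenosom.consensus import (
    consensus_mode,
    method_overlap,
    stability_protocol,
    train_stack,
)
from phenosom.preprocess import preprocess
from phenosom.simulate import SimulationConfig, generate_cohort
from phenosom.som import write_u_matrix


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--reps", type=int, default=20,
                    help="consensus repetitions (study protocol: 100)")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    csv = args.out / "cohort.csv"
    cohort = (read_cohort(csv) if csv.exists()
              else generate_cohort(SimulationConfig(seed=args.seed))[0])
    z = preprocess(cohort)

    reports = {}
    labels = {}
    for method in ("som", "kmeans"):
        rep = stability_protocol(z, method=method, target_k=2,
                                 n_reps=args.reps, n_triplet=3,
                                 master_seed=args.seed)
        reports[method] = rep
        labels[method] = (rep.final_labels if rep.final_labels is not None
                          else consensus_mode(rep.consensus_triplet))
        verdict = "STABLE" if rep.stable else "NOT stable"
        print(f"{method:>7}: {rep.n_discordant}/{z.n_patients} discordant "
              f"({100 * rep.instability:.1f}%) -> {verdict}")

    frac, table = method_overlap(labels["som"], labels["kmeans"])
    print(f"method overlap: {100 * frac:.1f}% identically classified")
    if cohort.true_labels is not None:
        ari = adjusted_rand_score(cohort.true_labels, labels["som"])
        print(f"SOM vs latent groups: ARI = {ari:.2f}")

    pd.DataFrame({
        "patient_id": cohort.patient_ids,
        "som_label": labels["som"],
        "kmeans_label": labels["kmeans"],
    }).to_csv(args.out / "final_labels.csv", index=False)
    payload = {
        "som": reports["som"].to_dict(),
        "kmeans": reports["kmeans"].to_dict(),
        "overlap_fraction": frac,
        "cross_counts": table.tolist(),
    }
    (args.out / "stability.json").write_text(json.dumps(payload, indent=1))

    # one representative first-layer map for the U-matrix export
    stack = train_stack(z, target_k=2, seed=args.seed)
    write_u_matrix(stack.layers[0], args.out / "u_matrix_layer1.tsv")
    print(f"wrote final_labels.csv, stability.json, u_matrix_layer1.tsv "
          f"under {args.out}")


if __name__ == "__main__":
    main()
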
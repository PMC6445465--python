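"""Nonparametric contrasts between the two patient groups, plus PCA.

Compares the groups on every variable with Mann-Whitney U (eta-squared
effect sizes, Bonferroni-corrected threshold), contrasts symptom
frequencies with chi-squared / Fisher tests and the 10-point banding rule,
and summarizes the varimax-rotated principal components.  By default the
contrast uses the clustering labels written by 03_cluster_stability.py and
falls back to the generator's latent groups when those are absent.

Usage: python analysis/05_group_differences.py [--seed 0] [--truth]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from phenosom.cohort import read_cohort
from phenosom.preprocess import impute_median, preprocess
from phenosom.simulate import SimulationConfig, generate_cohort
from phenosom.stats import bonferroni_alpha, compare_groups, pca, symptom_contrast


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--truth", action="store_true",
                    help="contrast the generator's latent groups instead of "
                         "the clustering labels")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    csv = args.out / "cohort.csv"
    if csv.exists():
        cohort = read_cohort(csv)
        _, symptoms = generate_cohort(SimulationConfig(seed=args.seed))
    else:
        cohort, symptoms = generate_cohort(SimulationConfig(seed=args.seed))
    z = preprocess(cohort)

    labels = None
    label_file = args.out / "final_labels.csv"
    if not args.truth and label_file.exists():
        frame = pd.read_csv(label_file)
        if frame["som_label"].nunique() == 2:
            labels = frame["som_label"].to_numpy()
            source = "SOM consensus clusters"
    if labels is None:
        labels = cohort.true_labels
        source = "latent generator groups"
    print(f"contrasting {source} "
          f"({np.sum(labels == labels.min())} vs "
          f"{np.sum(labels != labels.min())} patients)")

    alpha = bonferroni_alpha(0.05, z.n_variables)
    res = compare_groups(impute_median(cohort), z, labels, alpha)
    res.table.to_csv(args.out / "group_comparison.tsv", sep="\t", index=False)
    sig = res.table[res.table["significant"]]
    print(f"corrected alpha = {alpha:.2e}; "
          f"{len(sig)} variables significant:")
    for _, row in sig.iterrows():
        print(f"  {row['variable']:>18}: {row['median_1']:.2f}"
              f"[{row['iqr_1']:.2f}] vs {row['median_2']:.2f}"
              f"[{row['iqr_2']:.2f}]  p={row['p']:.2e} "
              f"eta2={100 * row['eta_squared']:.1f}%")

    sym = symptom_contrast(symptoms, labels)
    sym.to_csv(args.out / "symptom_contrast.tsv", sep="\t", index=False)
    for band in ("more in group 1", "more in group 2"):
        hits = sym[sym["band"] == band]["symptom"].tolist()
        if hits:
            print(f"{band} (>=10 points): {', '.join(hits)}")

    res_pca = pca(z)
    frame = pd.DataFrame(
        res_pca.loadings,
        index=z.schema.variable_names,
        columns=[f"PC{i + 1}" for i in range(res_pca.n_retained)],
    )
    frame.to_csv(args.out / "pca_loadings.tsv", sep="\t")
    print(f"PC1 explains {100 * res_pca.explained_variance_fraction[0]:.1f}% "
          f"of variance; {res_pca.n_retained} components reach 80%")
    print(f"wrote group_comparison.tsv, symptom_contrast.tsv, "
          f"pca_loadings.tsv under {args.out}")


if __name__ == "__main__":
    main()
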
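# phenosom

Bottom-up phenotyping of concussion patients from balance and vestibular
diagnostic batteries, using a stacked multi-layer self-organizing map (SOM)
with a consensus stability protocol — plus everything around it: a synthetic
cohort generator, cluster-count selection by validity-index voting, a
k-means reference, leave-one-test-out / leave-one-variable-out feature
importance, and nonparametric group statistics.

## The problem

Concussion presents across many functional domains, and a vestibular/balance
work-up produces dozens of partially redundant measurements per patient —
here a 96 × 53 matrix spanning eight test blocks: sensory organization test
(SOT, 5 variables), dynamic visual acuity (DVA, 8), video head impulse test
(V-HIT, 9), vestibular-evoked myogenic potentials (VEMPs, 3), subjective
visual vertical (SVV, 11), caloric irrigation (11), fundus photography (3)
and epidemiological covariates (3). The question an unsupervised analysis
can answer: do patients fall into distinct phenotypes, and which tests drive
the separation?

The pipeline answers it in five steps:

1. replace the 9999 missing-value sentinel, impute column medians, z-score;
2. choose the cluster count k as the mode of repeated internal-validity
   evaluations (Calinski-Harabasz, silhouette, gap, Davies-Bouldin) over
   single-start k-means runs;
3. cluster with a **stacked SOM** — a batch-trained hexagonal-sheet map
   (Epanechnikov neighbourhood, two-phase 20 + 50-epoch schedule) whose
   per-patient best-matching-unit codebook vectors feed a strictly smaller
   next map, until the occupied nodes of the final layer equal k — and with
   k-means as the standard reference;
4. stabilize by consensus: 100 repetitions per method, runs aligned by
   optimal assignment, per-patient mode taken; the consensus is run three
   times and accepted only if < 10% of patients change cluster (the
   stability rule);
5. on a stable outcome only: leave-one-test-out importance (and per-variable
   breakdowns for blocks reclassifying ≥ 20% of patients), Mann-Whitney U
   contrasts with η² = Z²/N effect sizes at a Bonferroni-corrected α,
   symptom-frequency banding, and varimax-rotated PCA.

Because no patient-level data ship with the package, a first-class synthetic
generator (`phenosom.simulate`) emulates the study conditions: two latent
groups of 38/58 patients separated on six variables (caloric mSPV-30/44/sum,
SOT composite, static/dynamic DVA) with the published medians and IQRs,
0.85% missingness, occasional outliers, and per-group symptom prevalences.
See `docs/methods.md` for the model, all tie rules, and a quantitative
account of what the generator does and does not emulate.

## Worked example

The numbered drivers under `analysis/` run the pipeline as a narrative; each
writes its tables under `results/`. With the separation raised to three
times the published effect sizes (the regime where the latent structure is
information-theoretically recoverable — see `docs/methods.md`):

```sh
python analysis/01_simulate_cohort.py --effect-scale 3 --out results/strong_separation
python analysis/02_choose_cluster_count.py --out results/strong_separation
python analysis/03_cluster_stability.py   --out results/strong_separation
python analysis/04_feature_importance.py  --out results/strong_separation
python analysis/05_group_differences.py   --out results/strong_separation
```

prints (abridged):

```
  CH: mode k=2 in 83% of 100 repetitions (decisive)
  SI: mode k=2 in 89% of 100 repetitions (decisive)
    som: 5/96 discordant (5.2%) -> STABLE
 kmeans: 1/96 discordant (1.0%) -> STABLE
method overlap: 97.9% identically classified
SOM vs latent groups: ARI = 0.88
without  Caloric:  49.0% clustered differently
without      SVV:   3.1% clustered differently
...
corrected alpha = 9.43e-04; 6 variables significant:
    caloric_mspv_sum: 70.49[29.87] vs 1.24[14.75]  p=3.12e-15 eta2=64.8%
              sot_cs: 91.06[13.18] vs 56.82[16.40]  p=1.78e-14 eta2=61.2%
...
```

Reading: both CH and silhouette vote decisively for two clusters; the SOM
consensus is stable (5 of 96 patients discordant across the three
repetitions, under the 10% rule); removing the caloric block reclassifies
49% of patients while every other block stays below 4%, so the caloric test
dominates the phenotype boundary; and exactly the six separating variables
reach significance at the corrected threshold, with the caloric summary
score carrying the largest effect (η² = 65%).

Running the same drivers without `--effect-scale` uses the published effect
sizes verbatim. At that separation — six weakly shifted variables diluted
across 53 standardized dimensions — the between-group structure sits below
what any clustering method can recover (Bayes ARI ceiling ≈ 0.5), the
stability gate fires, and the workflow declines the downstream analyses.
That behaviour is the designed response to unrecoverable structure, and the
gap between the two regimes is itself the package's central methodological
point.

The same stages are available as a CLI (`phenosom simulate | cluster |
importance | stats | report`, each with `--config`, `--seed`, `--out`,
`--reduced`) for use on external cohort CSVs.

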
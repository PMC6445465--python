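"""Vote on the number of clusters with four internal validity indices.

Each criterion (Calinski-Harabasz, silhouette, gap, Davies-Bouldin) is
evaluated over repeated single-start k-means clusterings of the
standardized cohort for k = 2..10; the modal arg-best k and its vote share
decide the cluster count.  Writes results/criterion_votes.json.

Usage: python analysis/02_choose_cluster_count.py [--seed 0] [--reps 100]
"""

import argparse
import json
from pathlib import Path

from phenosom.cohort import read_cohort
from phenosom.preprocess import preprocess
from phenosom.simulate import SimulationConfig, generate_cohort
from phenosom.validity import vote_best_k


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--reps", type=int, default=100,
                    help="repetitions per criterion (study protocol: 500)")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    csv = args.out / "cohort.csv"
    cohort = (read_cohort(csv) if csv.exists()
              else generate_cohort(SimulationConfig(seed=args.seed))[0])
    z = preprocess(cohort)

    votes = {}
    for i, crit in enumerate(("CH", "SI", "Gap", "DB")):
        reps = args.reps if crit != "Gap" else max(args.reps // 4, 10)
        vote = vote_best_k(z, range(2, 11), n_reps=reps, criterion=crit,
                           seed=args.seed + 100 * i)
        votes[crit] = vote.to_dict()
        print(f"{crit:>4}: mode k={vote.mode_k} in "
              f"{100 * vote.mode_fraction:.0f}% of {reps} repetitions "
              f"({'decisive' if vote.decisive else 'not decisive'})")
    (args.out / "criterion_votes.json").write_text(json.dumps(votes, indent=1))
    print(f"wrote {args.out / 'criterion_votes.json'}")


if __name__ == "__main__":
    main()
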
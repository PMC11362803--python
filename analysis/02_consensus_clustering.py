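#!/usr/bin/env python
"""Cluster the pooled ensemble and select the final model.

Pools each engine's top 10 poses, computes the 70 x 70 all-heavy-atom
RMSD matrix, clusters (average linkage), selects the cluster count at
the Kelley penalty minimum, and reports the most populated cluster's
nearest-to-centroid member as the final model.  Cluster labels are
compared against the planted mode labels from step 01.

Inputs:  scratch/ensemble/   (from 01_simulate_ensemble.py)
Outputs: results/consensus/  (partition.csv, kelley_profile.csv,
         penalty_plot.png, representative.pdb, interface + scan tables)
"""

from pathlib import Path

import pandas as pd

from condock.config import RunConfig
from condock.pipeline import run_consensus

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ensemble_dir = ROOT / "scratch" / "ensemble"
    if not ensemble_dir.is_dir():
        raise SystemExit("run analysis/01_simulate_ensemble.py first")
    out = ROOT / "results" / "consensus"
    report = run_consensus(ensemble_dir, RunConfig(), out)

    print(f"pooled {report.pooled_count} poses; Kelley-selected k = {report.chosen_k}")
    print(f"cluster sizes: {report.cluster_sizes}")
    print(f"final model: {report.representative} "
          f"(cluster {report.top_cluster}, "
          f"size {report.cluster_sizes[report.top_cluster]})")

    truth = pd.read_csv(ensemble_dir / "truth.csv").set_index("pose_id")
    partition = pd.read_csv(out / "partition.csv").set_index("pose_id")
    joined = partition.join(truth["mode"])
    purity = (joined.groupby("cluster")["mode"]
              .agg(lambda s: s.value_counts().iloc[0] / len(s)))
    print("cluster purity vs planted modes:",
          {int(c): round(p, 3) for c, p in purity.items()})
    rep_mode = truth.loc[report.representative, "mode"]
    print(f"final model's true mode: {rep_mode} "
          f"({'the heaviest-weight mode' if rep_mode == 0 else 'NOT the heaviest mode'})")


if __name__ == "__main__":
    main()
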
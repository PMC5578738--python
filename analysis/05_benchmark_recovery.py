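#!/usr/bin/env python
"""Benchmark planted-network recovery of the full pipeline.

Simulates 100 random sparse screens (23 proteins, 10 planted bipartite
edges, K_D 0.5-10 µM, default noise, no expression failures), runs the
complete call pipeline on each (B = 300, threshold 5), and reports
sensitivity and false-positive counts.

The headline result is deliberately two-sided.  Sensitivity is perfect:
avidity-amplified signals sit hundreds of bootstrap-median SDs above
background, so every planted edge is recovered in every run.  But on a
*sparse* matrix the fixed threshold of 5 does not control false
positives: a background cell's Z is its noise deviation divided by the
SD of a median of N resamples (~ sigma/4.8 for N = 23), so background
Z values reach ~ +/-8 whatever the noise scale, and a few background
pairs per screen clear the threshold in both orientations.  The
threshold behaves well only when the matrix is dense with genuine
interactions (which widens the bootstrap-median spread) or when calls
are cross-checked against a prior network and orthogonal affinity
measurements — which is precisely the published workflow.

Outputs: results/recovery_benchmark.tsv
"""

from pathlib import Path

import numpy as np
import pandas as pd

from plexscreen.calling import (call_interactions, combine_orientations,
                                zscore_matrix)
from plexscreen.synthetic_data import generate_truth, simulate_matrix

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
N_RUNS = 100


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for seed in range(N_RUNS):
        truth = generate_truth(14, 9, n_edges=10, kd_range=(0.5, 10.0),
                               fail_prob=0.0, seed=1000 + seed)
        m = simulate_matrix(truth, seed=2000 + seed)
        z = zscore_matrix(m, B=300, seed=3000 + seed)
        called = {s.pair for s in call_interactions(combine_orientations(z))
                  if s.called}
        tp = len(called & truth.edge_pairs)
        rows.append({"seed": seed, "n_true": len(truth.edge_pairs), "tp": tp,
                     "fp": len(called - truth.edge_pairs),
                     "sensitivity": tp / len(truth.edge_pairs)})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "recovery_benchmark.tsv", sep="\t", index=False)
    perfect = int(((df.sensitivity == 1.0) & (df.fp == 0)).sum())
    print(f"{N_RUNS} simulated screens, 10 planted edges each")
    print(f"  sensitivity:            min {df.sensitivity.min():.2f}, "
          f"mean {df.sensitivity.mean():.3f}")
    print(f"  false positives / run:  mean {df.fp.mean():.2f}, "
          f"median {int(df.fp.median())}, max {int(df.fp.max())}")
    print(f"  runs with perfect recovery (all edges, no FP): {perfect}/{N_RUNS}")
    print("every planted edge is recovered; the fixed threshold admits a "
          "few background pairs per sparse screen (see module docstring)")
    print(f"wrote {OUT}/recovery_benchmark.tsv")


if __name__ == "__main__":
    main()
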
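#!/usr/bin/env python
"""Simulate a 23-protein bead-array interactome screen.

Builds a ground-truth network over the 14 Beat-family and 8 Side-family
proteins (plus the Side-VII binder CG17839) carrying the ten
interactions confirmed by orthogonal affinity measurements or prior
screening, each with its measured (or, where unmeasured, a typical µM)
monomeric K_D.  One bait — Beat-Ia — is planted as an expression
failure, the phenomenon that cost the real screen its Beat-Ia::Side
call.  The truth is then run through the bead-signal simulator to
produce duplicate-well plate reads with Poisson bead counts.

Outputs (results/sim/): truth.json, plate.csv, layout.yaml, matrix.tsv
"""

from pathlib import Path

import yaml

from plexscreen.network_report import read_families
from plexscreen.plate_io import write_matrix, write_plate
from plexscreen.synthetic_data import (NoiseModel, SyntheticTruth,
                                       simulate_matrix, simulate_plate,
                                       write_truth)

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "sim"
SEED = 20170815

# Confirmed interactions and their monomeric affinities (µM); pairs
# without a published K_D get a typical adhesion-range 2 µM.
EDGES = [
    ("Beat-Va", "Side-VI", 0.76),
    ("Beat-Vb", "Side-VI", 2.3),
    ("Beat-Vc", "Side-VI", 9.4),
    ("Beat-VI", "Side-II", 2.78),
    ("Beat-Ic", "Side-III", 63.5),
    ("Beat-Ia", "Side", 2.0),
    ("Beat-Ib", "Side", 2.0),
    ("Beat-Ic", "Side", 2.0),
    ("Beat-IIa", "Side-IV", 2.0),
    ("Beat-IIb", "Side-IV", 2.0),
]

FAILED = {("Beat-Ia", "bait")}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    families = read_families(ROOT / "data" / "families.tsv")
    proteins = sorted(families)
    expression = {(p, role): 1.0 for p in proteins for role in ("bait", "prey")}
    for key in FAILED:
        expression[key] = 0.0
    truth = SyntheticTruth(proteins, families, EDGES, expression, FAILED,
                           NoiseModel(), seed=SEED)
    write_truth(truth, OUT / "truth.json")

    reads, layout = simulate_plate(truth, seed=SEED + 1, n_replicates=2)
    write_plate(reads, OUT / "plate.csv")
    (OUT / "layout.yaml").write_text(yaml.safe_dump(layout))
    write_matrix(simulate_matrix(truth, seed=SEED + 2), OUT / "matrix.tsv")

    n = len(proteins)
    print(f"simulated {n} proteins, {len(EDGES)} true interactions, "
          f"{len(reads)} plate reads ({n} multiplexed wells x {n} bead "
          f"regions x 2 replicates; a pairwise plate assay would need "
          f"{n * n} wells)")
    print(f"planted expression failure: {sorted(FAILED)}")
    print(f"wrote {OUT}/truth.json, plate.csv, layout.yaml, matrix.tsv")


if __name__ == "__main__":
    main()
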
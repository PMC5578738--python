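"""Synthetic ground truth, bead-array signals and SPR titrations.

The screen's raw plate reads are not publicly deposited, so every stage
of the pipeline is exercised against simulations that reproduce the
statistical structure the analysis assumes:

* a sparse bipartite truth network between a receptor-like family and a
  ligand-like family, with per-edge monomeric affinities (K_D, µM);
* bead signals that saturate with affinity: the avidity-amplified
  specific signal is modelled as ``S_max * C_eff / (C_eff + K_D)`` with
  a single effective prey concentration ``C_eff``, the simplest form
  that makes the expected signal strictly decreasing in K_D, as
  observed for real interaction series;
* per-protein, per-role (bait/prey) expression scale factors, drawn
  independently for the two roles so the two assay orientations of a
  pair differ, plus outright expression failures that reproduce the
  failed-bait phenomenon (a column indistinguishable from background);
* positive, heteroscedastic noise: log-normal background around ``b0``
  and log-normal multiplicative noise on the specific signal.

Defaults put the saturated specific signal 200x above background
(strong binders read >20,000 a.u. against a <100 a.u. background on the
real instrument) with 10% noise CV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .plate_io import InteractionMatrix, PlateRead
from .spr_fit import TitrationSeries, langmuir

__all__ = [
    "NoiseModel",
    "SyntheticTruth",
    "generate_truth",
    "simulate_matrix",
    "simulate_plate",
    "simulate_titration",
    "dilution_series",
    "write_truth",
    "read_truth",
]


@dataclass(frozen=True)
class NoiseModel:
    """Signal-model parameters of the simulated bead assay.

    b0
        Mean background signal (a.u.) of a non-interacting cell.
    bg_cv
        Coefficient of variation of the log-normal background.
    signal_cv
        CV of the log-normal multiplicative noise on specific signal.
    s_max
        Saturated specific signal (a.u.); ``s_max / b0`` is the
        signal-to-background ratio of a very tight binder.
    c_eff
        Effective prey concentration (µM) in the saturation term.
    failed_floor
        Fraction of ``b0`` read by a cell whose bait or prey failed to
        express: much of the nonspecific background comes from the
        protein layer itself, so an empty bead (or absent prey) reads
        *below* normal background.  This makes the failed orientation's
        Z strongly negative and its geometric mean undefined, so an
        expression failure can never fabricate a call.
    """

    b0: float = 100.0
    bg_cv: float = 0.10
    signal_cv: float = 0.10
    s_max: float = 20000.0
    c_eff: float = 1.0
    failed_floor: float = 0.2

    def __post_init__(self) -> None:
        if self.b0 <= 0 or self.s_max <= 0 or self.c_eff <= 0:
            raise ValueError("b0, s_max and c_eff must be positive")
        if self.bg_cv < 0 or self.signal_cv < 0:
            raise ValueError("noise CVs must be >= 0")
        if not 0.0 <= self.failed_floor <= 1.0:
            raise ValueError("failed_floor must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Planted interaction network with expression effects and noise model.

    ``edges`` holds ``(a, b, kd_uM)`` with ``a`` from family A and ``b``
    from family B; ``expression`` maps ``(protein, role)`` with role in
    {"bait", "prey"} to a non-negative scale factor; members of
    ``failed`` have expression factor exactly 0 in that role.
    """

    proteins: list[str]
    families: dict[str, str]
    edges: list[tuple[str, str, float]]
    expression: dict[tuple[str, str], float]
    failed: set[tuple[str, str]]
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for a, b, kd in self.edges:
            if kd <= 0:
                raise ValueError(f"K_D must be positive ({a}::{b}: {kd})")
        for key, f in self.expression.items():
            if f < 0:
                raise ValueError(f"expression factor must be >= 0 ({key})")
        for key in self.failed:
            if self.expression.get(key, 0.0) != 0.0:
                raise ValueError(f"failed {key} must have expression factor 0")

    @property
    def edge_pairs(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b, _ in self.edges}


def _default_names(n: int, prefix: str) -> list[str]:
    return [f"{prefix}{i + 1:02d}" for i in range(n)]


def generate_truth(
    n_a: int = 14,
    n_b: int = 8,
    density: float = 0.10,
    kd_range: tuple[float, float] = (0.5, 50.0),
    fail_prob: float = 0.0,
    seed: int = 0,
    n_edges: int | None = None,
    expression_sigma: float = 0.5,
    names_a: Sequence[str] | None = None,
    names_b: Sequence[str] | None = None,
    noise: NoiseModel | None = None,
) -> SyntheticTruth:
    """Sample a bipartite ground-truth interaction network.

    Edges between the ``n_a`` family-A and ``n_b`` family-B proteins are
    planted independently with probability ``density`` (or, if
    ``n_edges`` is given, as exactly that many pairs drawn uniformly).
    Per-edge monomeric K_Ds are log-uniform over ``kd_range`` (µM).
    Expression factors are log-normal with median 1 and log-SD
    ``expression_sigma``, drawn independently per protein and per role;
    each (protein, role) fails outright with probability ``fail_prob``.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("both families need at least one protein")
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    if kd_range[0] <= 0 or kd_range[1] < kd_range[0]:
        raise ValueError("kd_range must be positive and ordered")
    rng = np.random.default_rng(seed)
    fam_a = list(names_a) if names_a is not None else _default_names(n_a, "A")
    fam_b = list(names_b) if names_b is not None else _default_names(n_b, "B")
    if len(fam_a) != n_a or len(fam_b) != n_b:
        raise ValueError("name lists must match family sizes")
    proteins = fam_a + fam_b
    families = {p: "A" for p in fam_a} | {p: "B" for p in fam_b}

    all_pairs = [(a, b) for a in fam_a for b in fam_b]
    if n_edges is not None:
        if not 0 <= n_edges <= len(all_pairs):
            raise ValueError("n_edges outside [0, n_a * n_b]")
        chosen = [all_pairs[k] for k in rng.choice(len(all_pairs), n_edges, replace=False)]
    else:
        keep = rng.random(len(all_pairs)) < density
        chosen = [p for p, k in zip(all_pairs, keep) if k]
    lo, hi = np.log(kd_range[0]), np.log(kd_range[1])
    kds = np.exp(rng.uniform(lo, hi, size=len(chosen)))
    edges = [(a, b, float(kd)) for (a, b), kd in zip(chosen, kds)]

    expression: dict[tuple[str, str], float] = {}
    failed: set[tuple[str, str]] = set()
    for p in proteins:
        for role in ("bait", "prey"):
            if rng.random() < fail_prob:
                failed.add((p, role))
                expression[(p, role)] = 0.0
            else:
                expression[(p, role)] = float(rng.lognormal(0.0, expression_sigma))

    return SyntheticTruth(proteins, families, edges, expression, failed,
                          noise or NoiseModel(), int(seed))


def _lognormal_sigma(cv: float) -> float:
    # log-SD giving a multiplicative factor with unit mean-scale and the
    # requested coefficient of variation
    return float(np.sqrt(np.log1p(cv**2)))


def simulate_matrix(truth: SyntheticTruth, seed: int = 0) -> InteractionMatrix:
    """Simulate the full N x N signal matrix implied by a truth network.

    Every cell receives log-normal background ``b0 * eps_bg``; a cell
    whose unordered pair is a planted edge additionally receives

        e_bait(j) * e_prey(i) * S_max * C_eff / (C_eff + K_D) * eps_mult.

    The two orientations of a pair get independent noise draws and
    role-specific expression factors, so the matrix is asymmetric like
    real screen data.  Cells whose bait (column) or prey (row) failed to
    express read at ``failed_floor * b0`` background.  Signals are
    clamped at >= 0.
    """
    rng = np.random.default_rng(seed)
    nm = truth.noise
    n = len(truth.proteins)
    idx = {p: i for i, p in enumerate(truth.proteins)}
    sig_bg = _lognormal_sigma(nm.bg_cv)
    sig_mu = _lognormal_sigma(nm.signal_cv)
    level = np.full((n, n), nm.b0)
    failed_prey = [i for i, p in enumerate(truth.proteins) if (p, "prey") in truth.failed]
    failed_bait = [j for j, p in enumerate(truth.proteins) if (p, "bait") in truth.failed]
    level[failed_prey, :] *= nm.failed_floor
    level[:, failed_bait] *= nm.failed_floor
    X = level * (rng.lognormal(0.0, sig_bg, size=(n, n)) if sig_bg > 0
                 else np.ones((n, n)))
    for a, b, kd in truth.edges:
        saturation = nm.s_max * nm.c_eff / (nm.c_eff + kd)
        for prey, bait in ((a, b), (b, a)):
            i, j = idx[prey], idx[bait]
            eps = rng.lognormal(0.0, sig_mu) if sig_mu > 0 else 1.0
            X[i, j] += (truth.expression[(bait, "bait")]
                        * truth.expression[(prey, "prey")]
                        * saturation * eps)
    X = np.clip(X, 0.0, None)
    return InteractionMatrix(
        list(truth.proteins), X, np.zeros((n, n), dtype=bool),
        meta={"synthetic": True, "truth_seed": truth.seed, "matrix_seed": int(seed),
              "noise": asdict(nm)})


def simulate_plate(
    truth: SyntheticTruth,
    seed: int = 0,
    n_replicates: int = 2,
    bead_mean: float = 150.0,
) -> tuple[list[PlateRead], dict]:
    """Simulate multiplexed plate reads (one well per prey, per replicate).

    Each replicate reaction draws an independent signal matrix from the
    truth; bead counts are Poisson with mean ``bead_mean``.  Returns the
    reads together with the layout mapping needed by
    :func:`plexscreen.plate_io.read_plate`.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    reads: list[PlateRead] = []
    wells: dict[str, str] = {}
    regions: dict[int, str] = {}
    for rep in range(1, n_replicates + 1):
        sub = int(rng.integers(0, 2**31))
        m = simulate_matrix(truth, seed=sub)
        for i, prey in enumerate(truth.proteins):
            well = f"W{i + 1:02d}"
            wells[well] = prey
            for j, bait in enumerate(truth.proteins):
                regions[j + 1] = bait
                beads = int(rng.poisson(bead_mean))
                reads.append(PlateRead(well, j + 1, bait, prey,
                                       float(m.X[i, j]), beads, rep))
    return reads, {"wells": wells, "bead_regions": regions}


def dilution_series(
    kd: float, n_points: int = 12, lo_fold: float = 0.02, fold: float = 2.0
) -> np.ndarray:
    """Two-fold (by default) dilution series bracketing K_D.

    Twelve points starting at ``lo_fold * kd`` and doubling reach about
    40x K_D, spanning the isotherm from near-baseline to near
    saturation.
    """
    if kd <= 0 or lo_fold <= 0 or fold <= 1 or n_points < 1:
        raise ValueError("invalid dilution-series parameters")
    return kd * lo_fold * fold ** np.arange(n_points)


def simulate_titration(
    kd: float,
    rmax: float = 100.0,
    concentrations: Sequence[float] | None = None,
    cv: float = 0.02,
    seed: int = 0,
    ligand: str = "ligand",
    analyte: str = "analyte",
    replicate: int = 1,
) -> TitrationSeries:
    """Simulate equilibrium SPR responses from a Langmuir isotherm.

    ``R(C) = R_max * C / (K_D + C) * (1 + cv * xi)`` with ``xi`` an
    independent standard normal per point; responses clamped at >= 0.
    ``concentrations`` defaults to a 12-point two-fold dilution
    bracketing K_D.
    """
    if kd <= 0 or rmax <= 0 or cv < 0:
        raise ValueError("kd, rmax must be positive; cv >= 0")
    conc = (np.asarray(concentrations, dtype=float) if concentrations is not None
            else dilution_series(kd))
    if conc.size == 0:
        raise ValueError("empty concentration list")
    rng = np.random.default_rng(seed)
    resp = langmuir(conc, kd, rmax)
    if cv > 0:
        resp = resp * (1.0 + cv * rng.standard_normal(conc.size))
    resp = np.clip(resp, 0.0, None)
    return TitrationSeries(ligand, analyte, conc, resp, replicate)


# ---------------------------------------------------------------------------
# Truth serialisation (JSON)

def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    doc = {
        "proteins": truth.proteins,
        "families": truth.families,
        "edges": [[a, b, kd] for a, b, kd in truth.edges],
        "expression": [[p, role, f] for (p, role), f in sorted(truth.expression.items())],
        "failed": sorted([list(k) for k in truth.failed]),
        "noise": asdict(truth.noise),
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_truth(path: str | Path) -> SyntheticTruth:
    doc = json.loads(Path(path).read_text())
    return SyntheticTruth(
        proteins=list(doc["proteins"]),
        families=dict(doc["families"]),
        edges=[(a, b, float(kd)) for a, b, kd in doc["edges"]],
        expression={(p, role): float(f) for p, role, f in doc["expression"]},
        failed={(p, role) for p, role in doc["failed"]},
        noise=NoiseModel(**doc["noise"]),
        seed=int(doc["seed"]),
    )
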
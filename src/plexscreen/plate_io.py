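"""Reading, validation and assembly of bead-array plate reads.

A multiplexed bead immunoassay reports, for every well, one median
fluorescence intensity (MFI) per spectrally distinct bead region.  Each
bead region carries one immobilised bait protein and each well receives
one soluble prey protein, so a single well measures the binding of that
prey against every bait simultaneously.  This module turns such plate
reads into an N x N bait-prey signal matrix and provides the plain-text
I/O used throughout the package (matrix TSV, plate CSV, titration TSV).

Conventions
-----------
* The interaction matrix is square with rows and columns carrying the
  same proteins in the same order; rows denote the **prey** and columns
  denote the **bait**, so ``X[i, j]`` is the signal of prey *i* probed
  against bait *j*.
* Cells whose every replicate fails the bead-count filter are *masked*
  (missing), never imputed; masked cells serialise as blank TSV fields.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .spr_fit import TitrationSeries

__all__ = [
    "PlateRead",
    "InteractionMatrix",
    "PlateFormatError",
    "LayoutError",
    "MatrixFormatError",
    "read_plate",
    "write_plate",
    "assemble_matrix",
    "read_matrix",
    "write_matrix",
    "read_titrations",
    "write_titrations",
    "wells_required",
]

#: Default per-replicate bead-count floor below which an MFI is discarded.
DEFAULT_MIN_BEADS = 35

PLATE_COLUMNS = ("well_id", "bead_region", "bait", "prey", "mfi", "bead_count", "replicate")


class PlateFormatError(ValueError):
    """A plate CSV row is malformed or violates a read invariant."""


class LayoutError(ValueError):
    """A well or bead region is not covered by the assay layout."""


class MatrixFormatError(ValueError):
    """A matrix TSV is not a valid square labelled matrix."""


@dataclass(frozen=True)
class PlateRead:
    """One bead-region measurement in one well.

    Attributes
    ----------
    well_id : str
        Plate well, e.g. ``"A1"``.
    bead_region : int
        Spectral bead-region identifier (1-500).
    bait : str
        Protein immobilised on this bead region.
    prey : str
        Soluble protein probed in this well.
    mfi : float
        Median fluorescence intensity, arbitrary units, >= 0.
    bead_count : int
        Number of beads of this region counted in the well.
    replicate : int
        1-based replicate index of the reaction.
    """

    well_id: str
    bead_region: int
    bait: str
    prey: str
    mfi: float
    bead_count: int
    replicate: int

    def __post_init__(self) -> None:
        if not 1 <= int(self.bead_region) <= 500:
            raise PlateFormatError(f"bead_region {self.bead_region} outside 1-500")
        if self.mfi < 0:
            raise PlateFormatError(f"negative MFI {self.mfi} for well {self.well_id}")
        if self.bead_count < 0:
            raise PlateFormatError(f"negative bead_count {self.bead_count}")
        if self.replicate < 1:
            raise PlateFormatError(f"replicate {self.replicate} must be >= 1")


@dataclass
class InteractionMatrix:
    """Square bait-prey signal matrix with a missing-value mask.

    ``X[i, j]`` is the signal of prey ``proteins[i]`` against bait
    ``proteins[j]``.  ``mask[i, j]`` is True where the measurement is
    missing; masked entries of ``X`` hold NaN and are excluded from all
    downstream statistics.
    """

    proteins: list[str]
    X: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n = len(self.proteins)
        if n < 2:
            raise MatrixFormatError("interaction matrix needs at least 2 proteins")
        if self.X.shape != (n, n):
            raise MatrixFormatError(f"matrix shape {self.X.shape} does not match {n} proteins")
        if len(set(self.proteins)) != n:
            raise MatrixFormatError("duplicate protein names")
        if self.mask is None:
            self.mask = np.isnan(self.X)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (n, n):
            raise MatrixFormatError("mask shape does not match matrix")
        self.X = np.where(self.mask, np.nan, self.X)
        if np.any(self.X[~self.mask] < 0):
            raise MatrixFormatError("unmasked signal values must be >= 0")

    @property
    def n(self) -> int:
        return len(self.proteins)

    def index(self, protein: str) -> int:
        try:
            return self.proteins.index(protein)
        except ValueError:
            raise KeyError(f"unknown protein {protein!r}") from None

    def value(self, prey: str, bait: str) -> float:
        return float(self.X[self.index(prey), self.index(bait)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.proteins, columns=self.proteins)


def wells_required(n_proteins: int, multiplexed: bool = True) -> int:
    """Number of assay wells needed to screen all bait-prey pairs.

    A plate assay that measures one bait-prey pair per well needs
    ``n**2`` wells, whereas a multiplexed bead assay reads every bait in
    each well and needs only ``n`` wells (one per prey).
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    return n_proteins if multiplexed else n_proteins**2


# ---------------------------------------------------------------------------
# Plate CSV

def _layout_maps(layout: Mapping) -> tuple[Mapping[str, str], Mapping[int, str]]:
    try:
        wells = layout["wells"]
        regions = layout["bead_regions"]
    except (KeyError, TypeError) as exc:
        raise LayoutError("layout must provide 'wells' (well -> prey) and "
                          "'bead_regions' (region -> bait) mappings") from exc
    return wells, {int(k): v for k, v in regions.items()}


def read_plate(path: str | Path, layout: Mapping) -> list[PlateRead]:
    """Read and validate a plate CSV against an assay layout.

    Parameters
    ----------
    path : path
        CSV with columns ``well_id, bead_region, bait, prey, mfi,
        bead_count, replicate``.
    layout : mapping
        ``{"wells": {well_id: prey}, "bead_regions": {region: bait}}``.
        Every well and bead region present in the file must be covered,
        and any bait/prey named in the file must agree with the layout.

    Raises
    ------
    PlateFormatError
        Malformed row (naming the offending line) or invariant violation.
    LayoutError
        A well or bead region absent from the layout, or an identity
        mismatch between file and layout.
    """
    wells, regions = _layout_maps(layout)
    reads: list[PlateRead] = []
    seen: set[tuple[int, str, int]] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(PLATE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise PlateFormatError(f"plate file missing columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                well = row["well_id"].strip()
                region = int(row["bead_region"])
                mfi = float(row["mfi"])
                beads = int(row["bead_count"])
                rep = int(row["replicate"])
            except (ValueError, AttributeError) as exc:
                raise PlateFormatError(f"{path}:{lineno}: malformed row ({exc})") from exc
            if well not in wells:
                raise LayoutError(f"{path}:{lineno}: well {well!r} not in layout")
            if region not in regions:
                raise LayoutError(f"{path}:{lineno}: bead region {region} not in layout")
            prey, bait = wells[well], regions[region]
            if row["prey"].strip() and row["prey"].strip() != prey:
                raise LayoutError(f"{path}:{lineno}: prey {row['prey']!r} contradicts layout ({prey!r})")
            if row["bait"].strip() and row["bait"].strip() != bait:
                raise LayoutError(f"{path}:{lineno}: bait {row['bait']!r} contradicts layout ({bait!r})")
            key = (region, well, rep)
            if key in seen:
                raise PlateFormatError(f"{path}:{lineno}: duplicate (bead_region, well, replicate) {key}")
            seen.add(key)
            try:
                reads.append(PlateRead(well, region, bait, prey, mfi, beads, rep))
            except PlateFormatError as exc:
                raise PlateFormatError(f"{path}:{lineno}: {exc}") from exc
    return reads


def write_plate(reads: Iterable[PlateRead], path: str | Path) -> None:
    """Write plate reads to CSV (inverse of :func:`read_plate`)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PLATE_COLUMNS)
        for r in reads:
            writer.writerow([r.well_id, r.bead_region, r.bait, r.prey,
                             f"{r.mfi:.6g}", r.bead_count, r.replicate])


def layout_of(reads: Iterable[PlateRead]) -> dict:
    """Recover the layout mapping implied by a list of reads."""
    wells: dict[str, str] = {}
    regions: dict[int, str] = {}
    for r in reads:
        wells[r.well_id] = r.prey
        regions[r.bead_region] = r.bait
    return {"wells": wells, "bead_regions": regions}


# ---------------------------------------------------------------------------
# Matrix assembly

def assemble_matrix(
    reads: Sequence[PlateRead],
    min_beads: int = DEFAULT_MIN_BEADS,
    proteins: Sequence[str] | None = None,
) -> InteractionMatrix:
    """Assemble plate reads into an interaction matrix.

    Each (prey, bait) cell is the arithmetic mean of the replicate MFIs
    whose bead count is at least ``min_beads``; replicates below the
    floor are dropped individually, and a cell whose every replicate
    fails the filter (or that has no reads at all) is masked.  A protein
    appearing only as bait or only as prey yields a fully masked row or
    column and a warning.

    The result is invariant to the order of ``reads`` and to duplicating
    every read.
    """
    if not reads:
        raise ValueError("no reads to assemble")
    baits = {r.bait for r in reads}
    preys = {r.prey for r in reads}
    if proteins is None:
        proteins = sorted(baits | preys)
    proteins = list(proteins)
    for p in sorted((baits | preys) - (baits & preys)):
        role = "bait" if p in baits else "prey"
        warnings.warn(f"protein {p!r} appears only as {role}; its "
                      f"{'row' if role == 'bait' else 'column'} will be fully masked",
                      stacklevel=2)
    idx = {p: i for i, p in enumerate(proteins)}
    n = len(proteins)
    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for r in reads:
        if r.bead_count >= min_beads:
            i, j = idx[r.prey], idx[r.bait]
            sums[i, j] += r.mfi
            counts[i, j] += 1
    mask = counts == 0
    with np.errstate(invalid="ignore"):
        X = np.where(mask, np.nan, sums / np.maximum(counts, 1))
    return InteractionMatrix(
        proteins, X, mask,
        meta={"replicate_rule": "mean", "min_beads": int(min_beads),
              "n_reads": len(reads)},
    )


# ---------------------------------------------------------------------------
# Matrix TSV

def write_matrix(m: InteractionMatrix, path: str | Path) -> None:
    """Write a labelled matrix as TSV; masked cells are blank fields.

    Values are serialised with 6 significant digits; ``read_matrix``
    after ``write_matrix`` reproduces (proteins, X, mask) at that
    precision.
    """
    with open(path, "w", newline="") as fh:
        fh.write("\t".join([""] + list(m.proteins)) + "\n")
        for i, name in enumerate(m.proteins):
            cells = ["" if m.mask[i, j] else f"{m.X[i, j]:.6g}" for j in range(m.n)]
            fh.write("\t".join([name] + cells) + "\n")


def read_matrix(path: str | Path) -> InteractionMatrix:
    """Read a labelled square matrix TSV written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if rows != cols:
        if sorted(rows) == sorted(cols):
            raise MatrixFormatError(f"{path}: row and column orders differ")
        raise MatrixFormatError(f"{path}: row and column name sets differ")
    X = df.to_numpy(dtype=float)
    return InteractionMatrix(rows, X, np.isnan(X), meta={"source": str(path)})


# ---------------------------------------------------------------------------
# Titration TSV

TITRATION_COLUMNS = ("ligand", "analyte", "replicate", "concentration_uM", "response_RU")


def write_titrations(series: Iterable[TitrationSeries], path: str | Path) -> None:
    """Write equilibrium SPR titration series as a tidy TSV."""
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(TITRATION_COLUMNS) + "\n")
        for s in series:
            for c, r in zip(s.concentration, s.response):
                fh.write(f"{s.ligand}\t{s.analyte}\t{s.replicate}\t{c:.6g}\t{r:.6g}\n")


def read_titrations(path: str | Path) -> list[TitrationSeries]:
    """Read titration TSV, one series per (ligand, analyte, replicate)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(TITRATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for (lig, ana, rep), grp in df.groupby(["ligand", "analyte", "replicate"], sort=True):
        out.append(TitrationSeries(
            ligand=str(lig), analyte=str(ana),
            concentration=grp["concentration_uM"].to_numpy(dtype=float),
            response=grp["response_RU"].to_numpy(dtype=float),
            replicate=int(rep)))
    return out
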
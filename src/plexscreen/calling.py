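"""Bootstrap-median Z-scoring and bidirectional interaction calling.

The screen's core statistic.  Row and column backgrounds of the signal
matrix are estimated by bootstrapping the median: a row (or column) of
*n* unmasked values is resampled with replacement B times, the median of
each resample is taken, and the mean and SD of those B medians give a
robust location/scale against which every cell in that row (column) is
Z-scored.  The median is resistant to the genuine binding signals
present in the row, so — unlike an outlier-trimmed mean/SD — no signal
has to be excluded up front, which matters for small matrices in which
a large fraction of protein pairs truly interact.

Each unordered protein pair is measured twice, once per bait/prey
orientation.  The two orientation scores are combined by their
geometric mean, which is defined only when both are strictly positive;
a pair whose geometric mean exceeds the calling threshold (default 5,
strict inequality) is called an interaction.  Curator overrides are
explicit and flagged in every output.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .plate_io import InteractionMatrix

__all__ = [
    "ZScoreResult",
    "PairScore",
    "bootstrap_median_moments",
    "zscore_matrix",
    "combine_orientations",
    "call_interactions",
    "quantize",
    "DEFAULT_B",
    "DEFAULT_THRESHOLD",
    "DEFAULT_CUTOFFS",
]

DEFAULT_B = 300
DEFAULT_THRESHOLD = 5.0
DEFAULT_CUTOFFS = (0.80, 0.90)

_ROLE_CODE = {"row": 0, "col": 1}


def _stream(seed: int, role: str, name: str) -> np.random.Generator:
    """Deterministic per-row/column RNG stream keyed by protein identity.

    Streams are derived from (root seed, role, protein name), so results
    do not depend on evaluation order or on where a protein happens to
    sit in the matrix: permuting the proteins permutes the Z matrices
    exactly.
    """
    digest = hashlib.sha256(f"{role}:{name}".encode()).digest()
    tag = int.from_bytes(digest[:4], "big")
    ss = np.random.SeedSequence([int(seed), _ROLE_CODE[role], tag])
    return np.random.default_rng(ss)


def bootstrap_median_moments(
    values: Sequence[float],
    B: int = DEFAULT_B,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Mean and SD of B bootstrap medians of ``values``.

    Draws B resamples of size ``n = len(values)`` with replacement,
    takes the median of each, and returns the mean and population SD of
    the B medians.  Deterministic given the generator state.

    Parameters
    ----------
    values : sequence of float
        Unmasked row or column values (masked entries already removed).
    B : int
        Number of bootstrap repetitions.
    rng : numpy Generator or int seed

    Raises
    ------
    ValueError
        Empty ``values`` (a fully masked row/column) or B < 1.
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1 or vals.size == 0:
        raise ValueError("bootstrap requires a non-empty 1-D vector "
                         "(fully masked row/column?)")
    if np.any(np.isnan(vals)):
        raise ValueError("masked (NaN) entries must be removed before resampling")
    if B < 1:
        raise ValueError("B must be >= 1")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    # canonical ordering: the resample distribution depends only on the
    # multiset of values, so sorting changes nothing statistically but
    # makes results independent of how the caller ordered the vector
    # (and hence exactly equivariant under protein permutations)
    vals = np.sort(vals)
    n = vals.size
    idx = gen.integers(0, n, size=(int(B), n))
    medians = np.median(vals[idx], axis=1)
    return float(medians.mean()), float(medians.std())


@dataclass
class ZScoreResult:
    """Row-, column- and averaged Z matrices of an interaction matrix.

    ``X_zr`` Z-scores each cell against its row's bootstrap-median
    moments, ``X_zc`` against its column's, and
    ``X_zrc = (X_zr + X_zc) / 2`` elementwise.  Masked input cells are
    NaN in all three.  Rows/columns whose bootstrap-median SD is zero
    (no spread, e.g. constant values) are *degenerate*: their Z values
    are set to 0 and their indices recorded.
    """

    proteins: list[str]
    X_zr: np.ndarray
    X_zc: np.ndarray
    X_zrc: np.ndarray
    B: int
    seed: int
    degenerate_rows: list[int] = field(default_factory=list)
    degenerate_cols: list[int] = field(default_factory=list)
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n(self) -> int:
        return len(self.proteins)


def zscore_matrix(m: InteractionMatrix, B: int = DEFAULT_B, seed: int = 0) -> ZScoreResult:
    """Bootstrap-median Z-score every cell against its row and column.

    For column j, ``(mu_j, sigma_j)`` are the mean/SD of B bootstrap
    medians of the unmasked column values and
    ``X_zc[i, j] = (X[i, j] - mu_j) / sigma_j``; symmetrically for rows.
    Masked cells are excluded from resampling pools and stay NaN.
    Fully masked or zero-spread rows/columns contribute Z = 0 and are
    flagged degenerate rather than producing infinities: a row with no
    spread carries no evidence of specific binding, and a zero Z makes
    downstream geometric means undefined, correctly suppressing calls.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    n = m.n
    X, mask = m.X, m.mask
    zr = np.full((n, n), np.nan)
    zc = np.full((n, n), np.nan)
    degenerate_rows: list[int] = []
    degenerate_cols: list[int] = []

    def _no_spread(mu: float, sd: float) -> bool:
        # scale-aware zero test: a constant vector of e.g. 4.2 yields an
        # SD at float rounding level, not an exact 0
        return sd <= 1e-12 * max(1.0, abs(mu))

    for i, name in enumerate(m.proteins):
        keep = ~mask[i, :]
        if not keep.any():
            degenerate_rows.append(i)
            continue
        mu, sd = bootstrap_median_moments(X[i, keep], B, _stream(seed, "row", name))
        if _no_spread(mu, sd):
            degenerate_rows.append(i)
            zr[i, keep] = 0.0
        else:
            zr[i, keep] = (X[i, keep] - mu) / sd

    for j, name in enumerate(m.proteins):
        keep = ~mask[:, j]
        if not keep.any():
            degenerate_cols.append(j)
            continue
        mu, sd = bootstrap_median_moments(X[keep, j], B, _stream(seed, "col", name))
        if _no_spread(mu, sd):
            degenerate_cols.append(j)
            zc[keep, j] = 0.0
        else:
            zc[keep, j] = (X[keep, j] - mu) / sd

    zrc = (zr + zc) / 2.0
    return ZScoreResult(list(m.proteins), zr, zc, zrc, int(B), int(seed),
                        degenerate_rows, degenerate_cols, mask.copy())


@dataclass(frozen=True)
class PairScore:
    """Bidirectional score of one unordered protein pair.

    ``z_ab`` is the averaged Z with ``a`` as prey and ``b`` as bait;
    ``z_ba`` the reverse orientation.  ``gmean`` is
    ``sqrt(z_ab * z_ba)`` when both orientations are strictly positive
    and defined, else ``None`` (undefined — such pairs can never be
    called except by explicit override).
    """

    a: str
    b: str
    z_ab: float
    z_ba: float
    gmean: float | None = None
    category: str | None = None
    called: bool = False
    override: bool = False
    note: str = ""

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.a, self.b))


def _geometric_mean(z_ab: float, z_ba: float) -> float | None:
    if np.isnan(z_ab) or np.isnan(z_ba):
        return None
    if z_ab > 0.0 and z_ba > 0.0:
        return float(np.sqrt(z_ab * z_ba))
    return None


def combine_orientations(z: ZScoreResult) -> list[PairScore]:
    """One :class:`PairScore` per unordered protein pair.

    Diagonal (homophilic) pairs use the single averaged Z for both
    orientations.  Pairs touching a masked cell in either orientation
    have an undefined geometric mean.
    """
    scores: list[PairScore] = []
    for i in range(z.n):
        for j in range(i, z.n):
            z_ab = float(z.X_zrc[i, j])
            z_ba = float(z.X_zrc[j, i])
            scores.append(PairScore(z.proteins[i], z.proteins[j], z_ab, z_ba,
                                    _geometric_mean(z_ab, z_ba)))
    return scores


def _normalize_overrides(
    overrides: Iterable, universe: set[str]
) -> dict[frozenset[str], str]:
    out: dict[frozenset[str], str] = {}
    for item in overrides or ():
        if len(item) == 3:
            a, b, reason = item
        else:
            (a, b), reason = item, "curator override"
        for name in (a, b):
            if name not in universe:
                raise KeyError(f"override names unknown protein {name!r}")
        out[frozenset((a, b))] = str(reason)
    return out


def call_interactions(
    scores: Sequence[PairScore],
    threshold: float = DEFAULT_THRESHOLD,
    overrides: Iterable | None = None,
) -> list[PairScore]:
    """Flag pairs whose geometric-mean score strictly exceeds ``threshold``.

    ``overrides`` is an iterable of ``(a, b)`` or ``(a, b, reason)``
    pairs to call regardless of score; overridden pairs are flagged and
    carry their justification so no curator decision is hidden.  An
    override naming a protein absent from ``scores`` raises ``KeyError``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    universe = {name for s in scores for name in (s.a, s.b)}
    omap = _normalize_overrides(overrides, universe)
    out = []
    for s in scores:
        forced = s.pair in omap
        called = (s.gmean is not None and s.gmean > threshold) or forced
        out.append(replace(s, called=called, override=forced,
                           note=omap.get(s.pair, s.note)))
    return out


def quantize(
    scores: Sequence[PairScore],
    cutoffs: tuple[float, float] = DEFAULT_CUTOFFS,
) -> list[PairScore]:
    """Assign each pair a low/mid/high category by score percentile.

    Thresholds are the empirical percentiles (linear interpolation
    between order statistics) of all *defined* geometric means in the
    supplied set; restrict ``scores`` beforehand to quantize over a
    submatrix (e.g. one family against another).  A pair is ``low`` if
    its geometric mean is undefined or below the lower percentile,
    ``mid`` in between, and ``high`` at or above the upper percentile.
    """
    lo, hi = cutoffs
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("cutoffs must be strictly increasing within (0, 1)")
    finite = np.array([s.gmean for s in scores if s.gmean is not None], dtype=float)
    if finite.size < 2:
        warnings.warn("fewer than 2 defined geometric means; all pairs "
                      "categorized low", stacklevel=2)
        return [replace(s, category="low") for s in scores]
    p_lo, p_hi = np.quantile(finite, [lo, hi], method="linear")
    out = []
    for s in scores:
        if s.gmean is None or s.gmean < p_lo:
            cat = "low"
        elif s.gmean < p_hi:
            cat = "mid"
        else:
            cat = "high"
        out.append(replace(s, category=cat))
    return out
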
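"""Interaction network assembly, exports, heat map and pipeline driver.

Called pairs become edges of an annotated (typically bipartite)
protein-interaction network, merged with a prior network from an
earlier screen.  Every edge carries a provenance label that partitions
the edge set:

* ``new`` — called in this screen only;
* ``confirmed`` — called in this screen and present in the prior set;
* ``prior_only`` — present in the prior set only.

Pairs whose geometric-mean score is undefined are kept in the calls
table but excluded from the network: an orientation that failed (zero
or negative Z, e.g. a failed bait) must not fabricate an edge, and a
previously known interaction lost this way survives as ``prior_only``.

``run_bpia`` orchestrates the whole pipeline — assemble, Z-score,
combine, call, quantize, network, exports — into a run directory with a
JSON manifest capturing every parameter and seed.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .calling import (DEFAULT_B, DEFAULT_CUTOFFS, DEFAULT_THRESHOLD, PairScore,
                      call_interactions, combine_orientations, quantize,
                      zscore_matrix)
from .plate_io import assemble_matrix, read_matrix, read_plate, write_matrix

__all__ = [
    "build_network",
    "export_network",
    "import_network",
    "read_edge_list",
    "read_families",
    "render_heatmap",
    "write_calls",
    "read_calls",
    "run_bpia",
    "PipelineError",
]

CATEGORY_LEVELS = ("low", "mid", "high")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# Network

def _norm_pairs(edges: Iterable) -> set[frozenset[str]]:
    out = set()
    for e in edges:
        a, b = e[0], e[1]
        out.add(frozenset((a, b)))
    return out


def build_network(
    calls: Sequence[PairScore],
    prior: Iterable | None = None,
    families: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Merge called pairs with a prior edge list into an annotated graph.

    Nodes carry a ``family`` attribute (``"other"``, with a warning,
    when absent from ``families``).  Edges carry the score attributes
    (gmean, category, called, override) where scored, and a
    ``provenance`` attribute in {new, confirmed, prior_only}.  Called
    pairs with an undefined geometric mean are excluded.
    """
    prior_pairs = _norm_pairs(prior or ())
    families = dict(families or {})
    net = nx.Graph()

    by_pair: dict[frozenset[str], PairScore] = {s.pair: s for s in calls}
    called_pairs = {s.pair for s in calls if s.called and s.gmean is not None}

    def add_node(name: str) -> None:
        if name not in net:
            fam = families.get(name)
            if fam is None:
                warnings.warn(f"protein {name!r} missing from family mapping; "
                              "annotated 'other'", stacklevel=2)
                fam = "other"
            net.add_node(name, family=fam)

    for pair in sorted(called_pairs | prior_pairs, key=sorted):
        names = sorted(pair) if len(pair) == 2 else [min(pair), min(pair)]
        a, b = names
        add_node(a)
        add_node(b)
        if pair in called_pairs and pair in prior_pairs:
            prov = "confirmed"
        elif pair in called_pairs:
            prov = "new"
        else:
            prov = "prior_only"
        attrs: dict = {"provenance": prov}
        score = by_pair.get(pair)
        if score is not None and score.gmean is not None:
            attrs.update(gmean=float(score.gmean), called=bool(score.called),
                         override=bool(score.override))
            if score.category is not None:
                attrs["category"] = score.category
        net.add_edge(a, b, **attrs)
    return net


def export_network(net: nx.Graph, path: str | Path, fmt: str = "tsv") -> None:
    """Export nodes, edges and attributes as edge-list TSV or GraphML."""
    path = Path(path)
    if fmt == "tsv":
        rows = []
        for a, b, attrs in sorted(net.edges(data=True)):
            row = {"protein_a": a, "protein_b": b}
            row.update(attrs)
            rows.append(row)
        cols = ["protein_a", "protein_b", "provenance", "gmean", "category",
                "called", "override"]
        df = pd.DataFrame(rows)
        for c in cols:
            if c not in df.columns:
                df[c] = np.nan
        extra = [c for c in df.columns if c not in cols]
        df[cols + extra].to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        nx.write_graphml(net, path)
    else:
        raise ValueError(f"unknown network format {fmt!r} (expected 'tsv' or 'graphml')")


def import_network(path: str | Path, fmt: str = "tsv") -> nx.Graph:
    """Read a network exported by :func:`export_network`."""
    path = Path(path)
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt != "tsv":
        raise ValueError(f"unknown network format {fmt!r}")
    df = pd.read_csv(path, sep="\t")
    net = nx.Graph()
    for _, row in df.iterrows():
        attrs = {k: row[k] for k in df.columns
                 if k not in ("protein_a", "protein_b") and pd.notna(row[k])}
        net.add_edge(row["protein_a"], row["protein_b"], **attrs)
    return net


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column (plus optional extras) TSV prior-edge list."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = list(df.columns[:2])
    return [(str(a), str(b)) for a, b in zip(df[cols[0]], df[cols[1]])]


def read_families(path: str | Path) -> dict[str, str]:
    """Read a protein -> family TSV mapping."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return {str(p): str(f) for p, f in zip(df.iloc[:, 0], df.iloc[:, 1])}


# ---------------------------------------------------------------------------
# Heat map

def render_heatmap(
    scores: Sequence[PairScore],
    rows: Sequence[str],
    cols: Sequence[str],
    path: str | Path,
    image_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write the quantized (low/mid/high) category matrix for a protein grid.

    ``rows`` x ``cols`` selects the displayed submatrix (e.g. one family
    against the other).  Requires categories assigned by
    :func:`plexscreen.calling.quantize`; raises ``KeyError`` listing any
    requested protein absent from the scored set.  Optionally renders a
    three-colour image alongside the TSV.
    """
    by_pair: dict[frozenset[str], PairScore] = {s.pair: s for s in scores}
    universe = {n for s in scores for n in (s.a, s.b)}
    absent = [p for p in list(rows) + list(cols) if p not in universe]
    if absent:
        raise KeyError(f"proteins absent from scores: {sorted(set(absent))}")
    grid = pd.DataFrame(index=list(rows), columns=list(cols), dtype=object)
    for r in rows:
        for c in cols:
            score = by_pair.get(frozenset((r, c)))
            if score is None or score.category is None:
                raise ValueError(f"pair {r}::{c} has no category; run quantize first")
            grid.loc[r, c] = score.category
    grid.to_csv(path, sep="\t")
    if image_path is not None:
        _render_heatmap_image(grid, image_path)
    return grid


def _render_heatmap_image(grid: pd.DataFrame, image_path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    levels = {c: i for i, c in enumerate(CATEGORY_LEVELS)}
    data = grid.map(lambda c: levels[c]).to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(1 + 0.4 * grid.shape[1], 1 + 0.4 * grid.shape[0]))
    cmap = ListedColormap(["#ffffff", "#9ecae1", "#08519c"])
    ax.imshow(data, cmap=cmap, vmin=0, vmax=2, aspect="equal")
    ax.set_xticks(range(grid.shape[1]), grid.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(grid.shape[0]), grid.index, fontsize=7)
    fig.tight_layout()
    fig.savefig(image_path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Calls table

CALL_COLUMNS = ("protein_a", "protein_b", "z_ab", "z_ba", "gmean", "category",
                "called", "override", "note")


def write_calls(scores: Sequence[PairScore], path: str | Path) -> None:
    """Write the pair-score table as TSV; undefined geometric means are 'NA'."""
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for s in scores:
            gm = "NA" if s.gmean is None else f"{s.gmean:.6g}"
            fh.write("\t".join([
                s.a, s.b, f"{s.z_ab:.6g}", f"{s.z_ba:.6g}", gm,
                s.category or "NA", str(int(s.called)), str(int(s.override)),
                s.note]) + "\n")


def read_calls(path: str | Path) -> list[PairScore]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        gm = None if r["gmean"] == "NA" else float(r["gmean"])
        cat = None if r["category"] == "NA" else str(r["category"])
        out.append(PairScore(str(r["protein_a"]), str(r["protein_b"]),
                             float(r["z_ab"]), float(r["z_ba"]), gm, cat,
                             bool(int(r["called"])), bool(int(r["override"])),
                             str(r["note"])))
    return out


# ---------------------------------------------------------------------------
# Pipeline driver

def _load_config(config: Mapping | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_bpia(config: Mapping | str | Path) -> Path:
    """Run the full screen-analysis pipeline from a config mapping or YAML.

    Config keys::

        inputs:    {matrix: path} XOR {plate: path, layout: path-or-mapping}
        outdir:    run directory (created if needed)
        params:    {B, seed, threshold, cutoffs, min_beads}   (all optional)
        subset:    {rows: [...], cols: [...]}                 (optional)
        overrides: [[a, b, reason], ...]                      (optional)
        prior:     edge-list TSV path or inline [[a, b], ...] (optional)
        families:  TSV path or inline {protein: family}       (optional)

    Writes the assembled matrix, the three Z matrices, the calls table,
    the quantized heat map, network exports and a JSON manifest; any
    stage failure leaves a ``FAILED`` marker naming the stage and
    re-raises as :class:`PipelineError`.  Reruns with an identical
    config are bitwise identical.
    """
    cfg = _load_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    params = dict(cfg.get("params") or {})
    B = int(params.get("B", DEFAULT_B))
    seed = int(params.get("seed", 0))
    threshold = float(params.get("threshold", DEFAULT_THRESHOLD))
    cutoffs = tuple(params.get("cutoffs", DEFAULT_CUTOFFS))
    min_beads = int(params.get("min_beads", 35))

    stage = "configure"
    try:
        inputs = dict(cfg.get("inputs") or {})
        if ("matrix" in inputs) == ("plate" in inputs):
            raise ValueError("config must name exactly one input: 'matrix' or 'plate'")

        stage = "assemble"
        if "matrix" in inputs:
            m = read_matrix(inputs["matrix"])
        else:
            layout = inputs.get("layout")
            if isinstance(layout, (str, Path)):
                import yaml

                with open(layout) as fh:
                    layout = yaml.safe_load(fh)
            reads = read_plate(inputs["plate"], layout)
            m = assemble_matrix(reads, min_beads=min_beads)
        write_matrix(m, outdir / "matrix.tsv")

        stage = "zscore"
        z = zscore_matrix(m, B=B, seed=seed)
        for name, arr in (("zr", z.X_zr), ("zc", z.X_zc), ("zrc", z.X_zrc)):
            _write_z(outdir / f"{name}.tsv", m.proteins, arr)

        stage = "combine"
        scores = combine_orientations(z)
        subset = dict(cfg.get("subset") or {})
        rows = list(subset.get("rows") or m.proteins)
        cols = list(subset.get("cols") or m.proteins)
        if subset:
            keep = set(rows) | set(cols)
            scored_set = [s for s in scores if s.a in keep and s.b in keep]
        else:
            scored_set = scores

        stage = "call"
        overrides = [tuple(o) for o in (cfg.get("overrides") or [])]
        scored_set = call_interactions(scored_set, threshold=threshold,
                                       overrides=overrides)

        stage = "quantize"
        scored_set = quantize(scored_set, cutoffs=cutoffs)  # type: ignore[arg-type]
        write_calls(scored_set, outdir / "calls.tsv")

        stage = "heatmap"
        render_heatmap(scored_set, rows, cols, outdir / "heatmap_categories.tsv")

        stage = "network"
        prior_cfg = cfg.get("prior")
        prior = (read_edge_list(prior_cfg) if isinstance(prior_cfg, (str, Path))
                 else [tuple(e) for e in (prior_cfg or [])])
        fam_cfg = cfg.get("families")
        families = (read_families(fam_cfg) if isinstance(fam_cfg, (str, Path))
                    else dict(fam_cfg or {}))
        with warnings.catch_warnings():
            if not families:
                warnings.simplefilter("ignore")
            net = build_network(scored_set, prior, families)
        export_network(net, outdir / "network.tsv", "tsv")
        export_network(net, outdir / "network.graphml", "graphml")

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "params": {"B": B, "seed": seed, "threshold": threshold,
                       "cutoffs": list(cutoffs), "min_beads": min_beads},
            "inputs": {k: str(v) for k, v in inputs.items()
                       if isinstance(v, (str, Path))},
            "subset": {"rows": rows, "cols": cols} if subset else None,
            "overrides": [list(o) for o in overrides],
            "percentile_convention": "linear interpolation between order statistics",
            "replicate_rule": "arithmetic mean over replicates with bead_count >= min_beads",
            "degenerate_rows": [m.proteins[i] for i in z.degenerate_rows],
            "degenerate_cols": [m.proteins[j] for j in z.degenerate_cols],
            "n_called": sum(s.called for s in scored_set),
            "artifacts": ["matrix.tsv", "zr.tsv", "zc.tsv", "zrc.tsv", "calls.tsv",
                          "heatmap_categories.tsv", "network.tsv", "network.graphml"],
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         sort_keys=True) + "\n")
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        raise PipelineError(stage, exc) from exc
    return outdir


def _write_z(path: Path, proteins: Sequence[str], arr: np.ndarray) -> None:
    # Z matrices may be negative, so they bypass InteractionMatrix validation.
    with open(path, "w", newline="") as fh:
        fh.write("\t".join([""] + list(proteins)) + "\n")
        for i, name in enumerate(proteins):
            cells = ["" if np.isnan(v) else f"{v:.6g}" for v in arr[i]]
            fh.write("\t".join([name] + cells) + "\n")
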
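"""Network assembly, provenance, exports, heat map and the pipeline driver."""

from __future__ import annotations

import json

import numpy as np
import pytest

from plexscreen.calling import PairScore
from plexscreen.network_report import (PipelineError, build_network,
                                       export_network, import_network,
                                       read_calls, read_edge_list,
                                       read_families, render_heatmap,
                                       run_bpia, write_calls)
from plexscreen.plate_io import write_matrix
from plexscreen.synthetic_data import generate_truth, simulate_matrix

NEW_PAIRS = [("Beat-VI", "Side-II"), ("Beat-Ic", "Side"), ("Beat-Ic", "Side-III")]


def called(a, b, gmean=8.0, category="high"):
    return PairScore(a, b, gmean, gmean, gmean=gmean, category=category, called=True)


def test_new_edges_classified_against_prior_network(data_dir):
    prior = read_edge_list(data_dir / "ecia_edges.tsv")
    families = read_families(data_dir / "families.tsv")
    calls = [called(a, b) for a, b in NEW_PAIRS]
    calls += [called(a, b) for a, b in prior]
    net = build_network(calls, prior, families)
    new = {frozenset(e) for e, attrs in
           ((tuple(e[:2]), e[2]) for e in net.edges(data=True))
           if attrs["provenance"] == "new"}
    assert new == {frozenset(p) for p in NEW_PAIRS}
    confirmed = [e for *e, a in net.edges(data=True) if a["provenance"] == "confirmed"]
    assert len(confirmed) == len(prior)
    assert net.nodes["Beat-VI"]["family"] == "Beat"
    assert net.nodes["CG17839"]["family"] == "other"


def test_provenance_partitions_edges(data_dir):
    prior = [("a", "b"), ("c", "d")]
    calls = [called("a", "b"), called("e", "f")]
    net = build_network(calls, prior, {p: "F" for p in "abcdef"})
    provs = [attrs["provenance"] for *_, attrs in net.edges(data=True)]
    assert sorted(provs) == ["confirmed", "new", "prior_only"]


def test_empty_calls_yield_prior_only():
    net = build_network([], [("a", "b")], {"a": "F", "b": "F"})
    assert [a["provenance"] for *_, a in net.edges(data=True)] == ["prior_only"]


def test_reversed_duplicate_calls_merge_to_one_edge():
    net = build_network([called("a", "b"), called("b", "a")], [], {"a": "F", "b": "F"})
    assert net.number_of_edges() == 1


def test_uncalled_and_undefined_pairs_stay_out_of_network():
    scores = [PairScore("a", "b", 2.0, 2.0, gmean=2.0),            # not called
              PairScore("a", "c", -1.0, 9.0, gmean=None, called=True)]  # undefined
    net = build_network(scores, [], {"a": "F", "b": "F", "c": "F"})
    assert net.number_of_edges() == 0


def test_missing_family_annotated_other_with_warning():
    with pytest.warns(UserWarning, match="missing from family mapping"):
        net = build_network([called("a", "b")], [], {"a": "F"})
    assert net.nodes["b"]["family"] == "other"


@pytest.mark.parametrize("fmt", ["tsv", "graphml"])
def test_export_round_trip_preserves_edge_attributes(tmp_path, fmt):
    calls = [called("a", "b", 7.5), called("c", "d", 12.0, "high")]
    net = build_network(calls, [("a", "b")], {p: "F" for p in "abcd"})
    path = tmp_path / f"net.{fmt}"
    export_network(net, path, fmt)
    back = import_network(path, fmt)
    assert set(map(frozenset, back.edges())) == set(map(frozenset, net.edges()))
    for a, b, attrs in net.edges(data=True):
        got = back.edges[a, b]
        assert got["provenance"] == attrs["provenance"]
        assert float(got["gmean"]) == pytest.approx(attrs["gmean"])
        assert str(got["called"]) in ("True", "1", "True")


def test_empty_network_exports_header_only(tmp_path):
    import networkx as nx

    path = tmp_path / "empty.tsv"
    export_network(nx.Graph(), path, "tsv")
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 1


def test_unknown_export_format_rejected(tmp_path):
    import networkx as nx

    with pytest.raises(ValueError, match="unknown network format"):
        export_network(nx.Graph(), tmp_path / "x", "xml")


def test_heatmap_grid_dimensions(tmp_path):
    rows = [f"r{i}" for i in range(14)]
    cols = [f"c{j}" for j in range(8)]
    scores = [PairScore(r, c, 1.0, 1.0, gmean=1.0, category="low")
              for r in rows for c in cols]
    grid = render_heatmap(scores, rows, cols, tmp_path / "h.tsv")
    assert grid.shape == (14, 8)
    single = render_heatmap(scores, rows[:1], cols[:1], tmp_path / "h1.tsv")
    assert single.shape == (1, 1)


def test_heatmap_undefined_scores_are_low(tmp_path):
    scores = [PairScore("r", "c", -1.0, 1.0, gmean=None, category="low")]
    grid = render_heatmap(scores, ["r"], ["c"], tmp_path / "h.tsv")
    assert (grid == "low").all().all()


def test_heatmap_reports_missing_proteins(tmp_path):
    scores = [PairScore("r", "c", 1.0, 1.0, gmean=1.0, category="low")]
    with pytest.raises(KeyError, match="zz"):
        render_heatmap(scores, ["r", "zz"], ["c"], tmp_path / "h.tsv")


def test_calls_table_round_trip(tmp_path):
    scores = [PairScore("a", "b", 4.0, 9.0, gmean=6.0, category="high",
                        called=True, override=False),
              PairScore("a", "c", -1.0, 3.0, gmean=None, category="low"),
              PairScore("b", "c", 12.0, 4.4, gmean=7.27, category="mid",
                        called=True, override=True, note="curator decision")]
    path = tmp_path / "calls.tsv"
    write_calls(scores, path)
    back = read_calls(path)
    for orig, rt in zip(scores, back):
        assert (rt.a, rt.b, rt.category, rt.called, rt.override, rt.note) == \
            (orig.a, orig.b, orig.category, orig.called, orig.override, orig.note)
        if orig.gmean is None:
            assert rt.gmean is None
        else:
            assert rt.gmean == pytest.approx(orig.gmean, rel=1e-5)


# ---------------------------------------------------------------------------
# run_bpia

def _config(tmp_path, data_dir, seed=17):
    truth = generate_truth(6, 5, n_edges=4, kd_range=(0.5, 10.0), seed=5)
    m = simulate_matrix(truth, seed=6)
    matrix_path = tmp_path / "matrix.tsv"
    write_matrix(m, matrix_path)
    return {
        "inputs": {"matrix": str(matrix_path)},
        "outdir": str(tmp_path / "run"),
        "params": {"B": 200, "seed": seed, "threshold": 5.0, "cutoffs": [0.8, 0.9]},
        "families": {p: truth.families[p] for p in truth.proteins},
    }


def test_run_bpia_writes_all_artifacts(tmp_path, data_dir):
    cfg = _config(tmp_path, data_dir)
    outdir = run_bpia(cfg)
    for name in ("matrix.tsv", "zr.tsv", "zc.tsv", "zrc.tsv", "calls.tsv",
                 "heatmap_categories.tsv", "network.tsv", "network.graphml",
                 "manifest.json"):
        assert (outdir / name).exists(), name
    manifest = json.loads((outdir / "manifest.json").read_text())
    assert manifest["params"]["B"] == 200
    assert manifest["params"]["seed"] == 17
    assert not (outdir / "FAILED").exists()


def test_run_bpia_rerun_is_bitwise_identical(tmp_path, data_dir):
    cfg = _config(tmp_path, data_dir)
    out1 = run_bpia(cfg)
    calls1 = (out1 / "calls.tsv").read_bytes()
    cfg2 = dict(cfg, outdir=str(tmp_path / "run2"))
    out2 = run_bpia(cfg2)
    assert (out2 / "calls.tsv").read_bytes() == calls1
    assert (out2 / "zrc.tsv").read_bytes() == (out1 / "zrc.tsv").read_bytes()


def test_run_bpia_demands_exactly_one_input(tmp_path, data_dir):
    cfg = _config(tmp_path, data_dir)
    cfg["inputs"]["plate"] = "also.csv"
    with pytest.raises(PipelineError, match="exactly one input"):
        run_bpia(cfg)
    assert (tmp_path / "run" / "FAILED").exists()
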
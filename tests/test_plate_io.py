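"""Plate reading, matrix assembly and plain-text round-trips."""

from __future__ import annotations

import numpy as np
import pytest

from plexscreen.plate_io import (InteractionMatrix, LayoutError,
                                 MatrixFormatError, PlateFormatError,
                                 PlateRead, assemble_matrix, layout_of,
                                 read_matrix, read_plate, read_titrations,
                                 wells_required, write_matrix, write_plate,
                                 write_titrations)
from plexscreen.spr_fit import TitrationSeries
from plexscreen.synthetic_data import generate_truth, simulate_plate

LAYOUT = {"wells": {"A1": "preyX", "A2": "preyY"},
          "bead_regions": {1: "baitP", 2: "baitQ", 3: "baitR"}}


def plate_csv(tmp_path, rows):
    path = tmp_path / "plate.csv"
    header = "well_id,bead_region,bait,prey,mfi,bead_count,replicate\n"
    path.write_text(header + "\n".join(rows) + "\n")
    return path


def test_read_plate_counts_wells_regions_replicates(tmp_path):
    rows = [f"{w},{r},,,{100 + r},50,{rep}"
            for w in ("A1", "A2") for r in (1, 2, 3) for rep in (1, 2)]
    reads = read_plate(plate_csv(tmp_path, rows), LAYOUT)
    assert len(reads) == 12
    assert {r.prey for r in reads} == {"preyX", "preyY"}
    assert {r.bait for r in reads} == {"baitP", "baitQ", "baitR"}


def test_read_plate_rejects_negative_mfi(tmp_path):
    path = plate_csv(tmp_path, ["A1,1,,,−5,50,1".replace("−", "-")])
    with pytest.raises(PlateFormatError, match="negative MFI|malformed"):
        read_plate(path, LAYOUT)


def test_read_plate_rejects_unmapped_well_and_region(tmp_path):
    with pytest.raises(LayoutError, match="well 'B9'"):
        read_plate(plate_csv(tmp_path, ["B9,1,,,10,50,1"]), LAYOUT)
    with pytest.raises(LayoutError, match="bead region 99"):
        read_plate(plate_csv(tmp_path, ["A1,99,,,10,50,1"]), LAYOUT)


def test_read_plate_rejects_identity_contradicting_layout(tmp_path):
    with pytest.raises(LayoutError, match="contradicts layout"):
        read_plate(plate_csv(tmp_path, ["A1,1,baitQ,preyX,10,50,1"]), LAYOUT)


def test_read_plate_rejects_duplicate_key(tmp_path):
    rows = ["A1,1,,,10,50,1", "A1,1,,,11,50,1"]
    with pytest.raises(PlateFormatError, match="duplicate"):
        read_plate(plate_csv(tmp_path, rows), LAYOUT)


def test_plate_round_trip_on_synthetic_reads(tmp_path):
    truth = generate_truth(3, 3, n_edges=2, seed=11)
    reads, layout = simulate_plate(truth, seed=4)
    path = tmp_path / "sim.csv"
    write_plate(reads, path)
    back = read_plate(path, layout)
    assert len(back) == len(reads)
    for orig, rt in zip(reads, back):
        assert (rt.well_id, rt.bead_region, rt.bait, rt.prey,
                rt.bead_count, rt.replicate) == (
            orig.well_id, orig.bead_region, orig.bait, orig.prey,
            orig.bead_count, orig.replicate)
        assert rt.mfi == pytest.approx(orig.mfi, rel=1e-5)
    assert layout_of(back) == layout


def _read(prey, bait, mfi, beads, rep, well="A1", region=1):
    return PlateRead(well, region, bait, prey, mfi, beads, rep)


def test_assemble_averages_replicates():
    reads = [_read("a", "b", 100, 50, 1), _read("a", "b", 120, 50, 2),
             _read("b", "a", 10, 50, 1, well="A2", region=2),
             _read("a", "a", 1, 50, 1, region=2),
             _read("b", "b", 2, 50, 1, well="A2")]
    m = assemble_matrix(reads)
    assert m.value("a", "b") == pytest.approx(110.0)


def test_assemble_drops_low_bead_replicates_individually():
    # an absurd MFI on a 34-bead replicate must not leak into the mean
    reads = [_read("a", "b", 1e6, 34, 1), _read("a", "b", 80, 60, 2),
             _read("b", "a", 10, 50, 1, well="A2", region=2),
             _read("a", "a", 1, 50, 1, region=2),
             _read("b", "b", 2, 50, 1, well="A2")]
    m = assemble_matrix(reads, min_beads=35)
    assert m.value("a", "b") == pytest.approx(80.0)


def test_assemble_masks_cell_when_all_replicates_fail_filter():
    reads = [_read("a", "b", 100, 10, 1), _read("a", "b", 120, 34, 2),
             _read("b", "a", 10, 50, 1, well="A2", region=2),
             _read("a", "a", 1, 50, 1, region=2),
             _read("b", "b", 2, 50, 1, well="A2")]
    m = assemble_matrix(reads)
    assert m.mask[m.index("a"), m.index("b")]
    assert np.isnan(m.value("a", "b"))


def test_assemble_invariant_to_read_order_and_duplication():
    truth = generate_truth(4, 3, n_edges=3, seed=7)
    reads, _ = simulate_plate(truth, seed=9)
    m1 = assemble_matrix(reads)
    m2 = assemble_matrix(list(reversed(reads)))
    m3 = assemble_matrix(reads + reads)
    for m in (m2, m3):
        assert m.proteins == m1.proteins
        np.testing.assert_array_equal(m.mask, m1.mask)
        np.testing.assert_allclose(m.X, m1.X)


def test_assemble_single_role_protein_masks_and_warns():
    reads = [_read("a", "b", 5, 50, 1), _read("b", "b", 7, 50, 1, well="A2")]
    with pytest.warns(UserWarning, match="only as prey"):
        m = assemble_matrix(reads)  # 'a' never appears as bait
    assert m.mask[:, m.index("a")].all()


def test_matrix_tsv_blank_cell_is_masked(tmp_path):
    path = tmp_path / "m.tsv"
    path.write_text("\tp\tq\tr\np\t1\t2\t3\nq\t4\t\t6\nr\t7\t8\t9\n")
    m = read_matrix(path)
    assert m.mask.sum() == 1
    assert m.mask[1, 1]


def test_matrix_round_trip_23x23_at_serialised_precision(tmp_path):
    rng = np.random.default_rng(42)
    n = 23
    X = rng.uniform(0, 25000, (n, n))
    mask = rng.random((n, n)) < 0.05
    m = InteractionMatrix([f"p{i:02d}" for i in range(n)], np.where(mask, np.nan, X), mask)
    path = tmp_path / "m.tsv"
    write_matrix(m, path)
    back = read_matrix(path)
    assert back.proteins == m.proteins
    np.testing.assert_array_equal(back.mask, m.mask)
    expected = np.array([[float(f"{v:.6g}") for v in row] for row in m.X])
    np.testing.assert_array_equal(np.where(mask, 0, back.X), np.where(mask, 0, expected))


def test_matrix_rejects_mismatched_orders(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("\tp\tq\nq\t1\t2\np\t3\t4\n")
    with pytest.raises(MatrixFormatError, match="orders differ"):
        read_matrix(path)
    path.write_text("\tp\tq\tr\np\t1\t2\t3\nq\t4\t5\t6\n")
    with pytest.raises(MatrixFormatError):
        read_matrix(path)


def test_wells_required_scaling():
    assert wells_required(23, multiplexed=False) == 529
    assert wells_required(23) == 23
    with pytest.raises(ValueError):
        wells_required(0)


def test_titration_tsv_round_trip(tmp_path):
    s1 = TitrationSeries("ligA", "anaB", [0.1, 0.2, 0.4, 0.8], [5, 9, 16, 26], 1)
    s2 = TitrationSeries("ligA", "anaB", [0.1, 0.2, 0.4, 0.8], [6, 10, 15, 25], 2)
    path = tmp_path / "spr.tsv"
    write_titrations([s1, s2], path)
    back = read_titrations(path)
    assert len(back) == 2
    for orig, rt in zip([s1, s2], back):
        assert (rt.ligand, rt.analyte, rt.replicate) == (orig.ligand, orig.analyte, orig.replicate)
        np.testing.assert_allclose(rt.concentration, orig.concentration)
        np.testing.assert_allclose(rt.response, orig.response)
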
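"""r_id distance series: minimum-image distances, profiles, occupancies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chargenet import (DistanceSeries, bin_distances, compute_distance_series,
                       export_series, hbond_fraction, import_series,
                       occupancy_fraction, select_probe_atoms)
from chargenet.distance_map import minimum_image_distances
from chargenet.structure_io import Frame, Trajectory

from conftest import make_atom


def _two_atom_traj(positions_a, positions_b, box=None):
    frames = []
    for t, (pa, pb) in enumerate(zip(positions_a, positions_b)):
        frames.append(Frame(atoms=[
            make_atom("NZ", pa, "LYS", resnum=1, serial=1, element="N"),
            make_atom("CD", pb, "GLU", resnum=2, serial=2, element="C"),
        ], box=box, time=float(t)))
    return Trajectory(frames=frames)


def brute_force_min_image(xi, xj, box):
    """Independent oracle: scan all 27 periodic images of xj."""
    best = np.inf
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            for sz in (-1, 0, 1):
                shift = np.array([sx, sy, sz]) * box
                best = min(best, float(np.linalg.norm(xi - (xj + shift))))
    return best


def test_constant_separation_no_box():
    traj = _two_atom_traj([(0, 0, 0)] * 4, [(0, 0, 0.3)] * 4)
    probes, _ = select_probe_atoms(traj.frames[0])
    series = compute_distance_series(traj, probes)
    np.testing.assert_allclose(series[frozenset((0, 1))].values, 0.3)


def test_wraparound_minimum_image():
    traj = _two_atom_traj([(0.1, 0, 0)], [(4.9, 0, 0)], box=5.0)
    probes, _ = select_probe_atoms(traj.frames[0])
    series = compute_distance_series(traj, probes)
    assert series[frozenset((0, 1))].values[0] == pytest.approx(0.2)


def test_minimum_image_matches_27_image_brute_force(rng):
    """Pipeline distances equal the 27-image oracle to 1e-12 nm."""
    n_probes, n_frames = 8, 20
    box = float(rng.uniform(2.0, 6.0))
    coords = rng.uniform(0, box, size=(n_frames, n_probes, 3))
    frames = []
    for t in range(n_frames):
        atoms = [make_atom("NZ", coords[t, i], "LYS", resnum=i + 1,
                           serial=i + 1, element="N")
                 for i in range(n_probes)]
        frames.append(Frame(atoms=atoms, box=box, time=float(t)))
    traj = Trajectory(frames=frames)
    probes, _ = select_probe_atoms(traj.frames[0])
    series = compute_distance_series(traj, probes)
    for i in range(n_probes):
        for j in range(i + 1, n_probes):
            expected = [brute_force_min_image(coords[t, i], coords[t, j], box)
                        for t in range(n_frames)]
            np.testing.assert_allclose(series[frozenset((i, j))].values,
                                       expected, atol=1e-12)


def test_minimum_image_agrees_with_mdanalysis(rng):
    """Cross-check against MDAnalysis' periodic distance routine."""
    mda_dist = pytest.importorskip("MDAnalysis.lib.distances")
    box = 4.0
    a = rng.uniform(0, box, size=(50, 3))
    b = rng.uniform(0, box, size=(50, 3))
    ours = minimum_image_distances(a, b, box)
    theirs = mda_dist.calc_bonds((a * 10).astype(np.float64),
                                 (b * 10).astype(np.float64),
                                 box=np.array([40.0, 40, 40, 90, 90, 90])) / 10
    np.testing.assert_allclose(ours, theirs, atol=1e-6)


def test_symmetry_under_probe_order_swap(rng):
    pts = rng.uniform(0, 3, size=(10, 2, 3))
    d_ij = minimum_image_distances(pts[:, 0], pts[:, 1], 3.0)
    d_ji = minimum_image_distances(pts[:, 1], pts[:, 0], 3.0)
    np.testing.assert_array_equal(d_ij, d_ji)


def test_minimum_image_bound(rng):
    box = 2.5
    a = rng.uniform(-10, 10, size=(200, 3))
    b = rng.uniform(-10, 10, size=(200, 3))
    d = minimum_image_distances(a, b, box)
    assert np.all(d <= np.sqrt(3) / 2 * box + 1e-12)


def test_import_series_basic(tmp_path):
    p = tmp_path / "pair.xvg"
    p.write_text("0 0.30\n1 0.35\n2 0.32\n")
    s = import_series(p)
    np.testing.assert_allclose(s.values, [0.30, 0.35, 0.32])
    assert s.sampling_interval == pytest.approx(1.0)


def test_import_series_ignores_xvg_headers(tmp_path):
    body = "0 0.30\n1 0.35\n2 0.32\n"
    plain = tmp_path / "plain.xvg"
    plain.write_text(body)
    commented = tmp_path / "comm.xvg"
    commented.write_text("# generated\n@    title \"rid\"\n@ xaxis\n" + body)
    np.testing.assert_array_equal(import_series(plain).values,
                                  import_series(commented).values)


def test_import_series_errors(tmp_path):
    bad = tmp_path / "bad.xvg"
    bad.write_text("0 0.3\n1 abc\n")
    with pytest.raises(ValueError, match="non-numeric"):
        import_series(bad)
    uneven = tmp_path / "uneven.xvg"
    uneven.write_text("0 0.3\n1 0.3\n3 0.3\n")
    with pytest.raises(ValueError, match="non-uniform"):
        import_series(uneven)
    empty = tmp_path / "empty.xvg"
    empty.write_text("# nothing\n")
    with pytest.raises(ValueError, match="no data"):
        import_series(empty)


def test_export_import_round_trip(tmp_path, rng):
    s = DistanceSeries(pair=None, values=rng.uniform(0.2, 2.0, size=200),
                       sampling_interval=1.0)
    p = tmp_path / "rt.xvg"
    export_series(s, p, comment="round trip")
    back = import_series(p)
    # values survive at the printed precision (6 decimals)
    np.testing.assert_allclose(back.values, np.round(s.values, 6), atol=1e-12)


def test_bin_constant_series_single_bin():
    s = DistanceSeries(pair=None, values=np.full(1000, 0.30))
    prof = bin_distances(s, bin_width=0.02, max_range=2.0)
    assert prof.counts[15] == 1000          # [0.30, 0.32)
    assert prof.counts.sum() == 1000 and prof.overflow_count == 0


def test_bin_overflow_and_conservation(rng):
    values = rng.uniform(0, 4.0, size=5000)
    s = DistanceSeries(pair=None, values=values)
    prof = bin_distances(s, 0.02, 2.0)
    assert prof.total == 5000
    assert prof.overflow_count == int(np.sum(values >= 2.0))


@given(st.lists(st.floats(min_value=0, max_value=5, allow_nan=False),
                min_size=1, max_size=300))
@settings(max_examples=50, deadline=None)
def test_bin_conservation_property(values):
    s = DistanceSeries(pair=None, values=np.array(values))
    prof = bin_distances(s, 0.05, 1.5)
    assert prof.total == len(values)


def test_occupancy_fraction_basics():
    const = DistanceSeries(pair=None, values=np.full(10, 0.3))
    assert occupancy_fraction(const, 0.6) == 1.0
    far = DistanceSeries(pair=None, values=np.full(10, 0.8))
    assert occupancy_fraction(far, 0.6) == 0.0


def test_occupancy_fraction_counts_strictly_below():
    s = DistanceSeries(pair=None, values=np.array([0.6, 0.599999, 0.6000001]))
    assert occupancy_fraction(s, 0.6) == pytest.approx(1 / 3)


def test_occupancy_fraction_direct_count(rng):
    values = np.concatenate([rng.uniform(0.1, 0.59, 57),
                             rng.uniform(0.61, 2.0, 943)])
    rng.shuffle(values)
    s = DistanceSeries(pair=None, values=values)
    assert occupancy_fraction(s, 0.6) == pytest.approx(0.057)


def test_occupancy_monotone_in_cutoff(rng):
    s = DistanceSeries(pair=None, values=rng.uniform(0, 2, size=500))
    cuts = np.linspace(0.1, 2.0, 20)
    occ = [occupancy_fraction(s, c) for c in cuts]
    assert all(a <= b for a, b in zip(occ, occ[1:]))


def test_occupancy_empty_series_rejected():
    s = DistanceSeries(pair=None, values=np.array([]))
    with pytest.raises(ValueError):
        occupancy_fraction(s, 0.6)


def test_hbond_fraction_equals_04_occupancy(rng):
    s = DistanceSeries(pair=None, values=rng.uniform(0.2, 0.8, size=400))
    assert hbond_fraction(s) == occupancy_fraction(s, 0.4)
    assert hbond_fraction(DistanceSeries(pair=None, values=np.full(5, 0.35))) == 1.0
    assert hbond_fraction(DistanceSeries(pair=None, values=np.full(5, 0.5))) == 0.0


def test_distance_series_validation():
    with pytest.raises(ValueError):
        DistanceSeries(pair=None, values=np.array([0.3, -0.1]))
    with pytest.raises(ValueError):
        DistanceSeries(pair=None, values=np.array([0.3, np.nan]))
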
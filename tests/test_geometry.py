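"""Pentagon geometry, pore-diameter conversion, pseudo-label prediction."""

import math

import numpy as np
import pytest

from pentaspin import (PentagonGeometry, StructureRing, pentagon_from_d1,
                       diameter_change_from_shift, d2_shift_from_d1_shift,
                       pore_diameter_total, predict_ring_distances,
                       ring_from_pdb, GOLDEN_RATIO)

SIN36 = math.sin(math.radians(36.0))


def make_ring_coords(radius=20.0, n=5, center=(0, 0, 0)):
    ang = 2 * np.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            np.zeros(n)]) + np.asarray(center, float)


class TestPentagon:
    def test_unit_side_gives_golden_diagonal(self):
        pent = pentagon_from_d1(1.0)
        assert pent.d2 == pytest.approx(GOLDEN_RATIO, abs=1e-12)
        assert pent.ratio == pytest.approx(1.618, abs=5e-4)

    def test_ratio_rounds_to_1p6(self):
        assert round(pentagon_from_d1(25.0).ratio, 1) == 1.6

    def test_radius_inverse_identity(self):
        pent = pentagon_from_d1(2.0 * SIN36)
        assert pent.ring_radius == pytest.approx(1.0, abs=1e-12)

    def test_golden_ratio_machine_precision_any_radius(self):
        for radius in (5.0, 17.3, 123.4):
            pent = PentagonGeometry(ring_radius=radius)
            assert pent.d2 / pent.d1 == pytest.approx(GOLDEN_RATIO,
                                                      abs=1e-12)

    def test_rejects_non_positive_d1(self):
        with pytest.raises(ValueError):
            pentagon_from_d1(0.0)


class TestDiameterConversion:
    def test_3A_shift_gives_5A_diameter_increase(self):
        change = diameter_change_from_shift(3.0)
        assert change == pytest.approx(5.10, abs=5e-3)
        assert round(change) == 5

    def test_zero_shift_zero_change_and_linearity(self):
        assert diameter_change_from_shift(0.0) == 0.0
        x = 1.7
        assert diameter_change_from_shift(2 * x) == pytest.approx(
            2 * diameter_change_from_shift(x))

    def test_d2_shift_golden_scaling(self):
        shift = d2_shift_from_d1_shift(3.0)
        assert shift == pytest.approx(4.854, abs=2e-3)
        assert round(shift) == 5
        assert d2_shift_from_d1_shift(0.0) == 0.0

    def test_d2_shift_consistent_with_pentagon_construction(self):
        d1, dd1 = 25.0, 3.0
        direct = pentagon_from_d1(d1 + dd1).d2 - pentagon_from_d1(d1).d2
        assert d2_shift_from_d1_shift(dd1) == pytest.approx(direct, abs=1e-12)

    def test_total_pore_diameter(self):
        total = pore_diameter_total(4.0, 3.0)
        assert total == pytest.approx(9.10, abs=5e-3)
        assert round(total) == 9
        assert pore_diameter_total(7.0, 0.0) == 7.0
        # additivity in the closed diameter
        assert (pore_diameter_total(6.0, 3.0) - pore_diameter_total(4.0, 3.0)
                == pytest.approx(2.0))


class TestPseudoLabelPrediction:
    def test_zero_spread_reproduces_exact_pentagon(self):
        ring = StructureRing(anchors=make_ring_coords(20.0),
                             spread=0.0, pseudo_label_offset=0.0)
        samples = predict_ring_distances(ring, n_samples=200, seed=0)
        pent = PentagonGeometry(ring_radius=20.0)
        assert np.allclose(samples.d1_samples, pent.d1)
        assert np.allclose(samples.d2_samples, pent.d2)
        assert samples.ratio_of_means == pytest.approx(GOLDEN_RATIO,
                                                       abs=1e-12)

    def test_unit_spread_means_close_to_closed_form(self):
        ring = StructureRing(anchors=make_ring_coords(20.0),
                             spread=1.0, pseudo_label_offset=0.0)
        samples = predict_ring_distances(ring, n_samples=10_000, seed=1)
        pent = PentagonGeometry(ring_radius=20.0)
        assert abs(samples.d1_mean - pent.d1) < 0.2
        assert abs(samples.d2_mean - pent.d2) < 0.2

    def test_rotation_translation_invariance(self):
        coords = make_ring_coords(18.0)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0],
                      [0, 0, 1.0]])
        moved = coords @ R.T + np.array([5.0, -3.0, 12.0])
        # exact invariance of the deterministic geometry (zero spread)
        a = predict_ring_distances(
            StructureRing(anchors=coords, spread=0.0,
                          pseudo_label_offset=0.0), n_samples=200, seed=2)
        b = predict_ring_distances(
            StructureRing(anchors=moved, spread=0.0,
                          pseudo_label_offset=0.0), n_samples=200, seed=2)
        assert a.d1_mean == pytest.approx(b.d1_mean, abs=1e-9)
        assert a.d2_mean == pytest.approx(b.d2_mean, abs=1e-9)
        # statistical invariance with rotamer jitter
        aj = predict_ring_distances(
            StructureRing(anchors=coords, spread=0.5,
                          pseudo_label_offset=0.0), n_samples=5000, seed=2)
        bj = predict_ring_distances(
            StructureRing(anchors=moved, spread=0.5,
                          pseudo_label_offset=0.0), n_samples=5000, seed=2)
        assert aj.d1_mean == pytest.approx(bj.d1_mean, abs=0.05)
        assert aj.d2_mean == pytest.approx(bj.d2_mean, abs=0.05)

    def test_non_ring_anchors_rejected(self):
        coords = make_ring_coords(20.0)
        coords[0] = coords[1] + 0.5  # collapse two anchors
        ring = StructureRing(anchors=coords, spread=0.0,
                             pseudo_label_offset=0.0)
        with pytest.raises(ValueError):
            predict_ring_distances(ring, n_samples=200, seed=0)

    def test_requires_minimum_samples(self):
        ring = StructureRing(anchors=make_ring_coords())
        with pytest.raises(ValueError):
            predict_ring_distances(ring, n_samples=10)


PDB_RING_TEMPLATE = (
    "ATOM  {serial:>5}  {name:<3} ALA {chain}  18    "
    "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           {elem}\n")


def write_c5_pdb(path, radius=20.0):
    """Synthetic C5-symmetric pentamer PDB: one ALA-18 CA/CB per chain."""
    lines = []
    serial = 1
    for i, chain in enumerate("ABCDE"):
        ang = 2 * np.pi * i / 5
        ca = np.array([radius * np.cos(ang), radius * np.sin(ang), 0.0])
        cb = ca + 1.5 * np.array([np.cos(ang), np.sin(ang), 0.0])
        for name, xyz, elem in (("CA", ca, "C"), ("CB", cb, "C")):
            lines.append(PDB_RING_TEMPLATE.format(
                serial=serial, name=name, chain=chain,
                x=xyz[0], y=xyz[1], z=xyz[2], elem=elem))
            serial += 1
        lines.append(f"TER   {serial:>5}      ALA {chain}  18\n")
        serial += 1
    lines.append("END\n")
    path.write_text("".join(lines))


class TestPdbRing:
    def test_c5_pdb_ratio_in_expected_window(self, tmp_path):
        pdb = tmp_path / "synthetic_pentamer.pdb"
        write_c5_pdb(pdb)
        ring = ring_from_pdb(pdb, resid=18, pseudo_label_offset=7.0,
                             spread=2.0)
        samples = predict_ring_distances(ring, n_samples=5000, seed=0)
        # labels pushed radially outward: still a C5 ring, golden ratio
        assert 1.55 <= samples.ratio_of_means <= 1.70

    def test_label_sites_offset_along_ca_cb(self, tmp_path):
        pdb = tmp_path / "synthetic_pentamer.pdb"
        write_c5_pdb(pdb, radius=15.0)
        ring = ring_from_pdb(pdb, resid=18, pseudo_label_offset=7.0)
        radii = np.linalg.norm(ring.label_sites()[:, :2], axis=1)
        assert np.allclose(radii, 22.0, atol=1e-6)
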
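"""C5 pentagon geometry for spin-label rings on pentameric channels.

One label per protomer of a C5-symmetric pentamer sits at a pentagon vertex,
so exactly two inter-label distances exist: the side D1 = 2 R sin 36 deg and
the diagonal D2 = 2 R sin 72 deg, with D2/D1 = 2 cos 36 deg = (1 + sqrt 5)/2
(the golden ratio, ~1.618 — "close to 1.6" at experimental precision).
Observation of both distances is itself a control for C5 symmetry.

A uniform expansion of the ring maps a D1 shift to changes of the other
pentagon quantities: the circumscribed-circle diameter (taken here as the
channel's inner diameter at the label level) grows by ``dD1 / sin 36 deg``
and D2 by ``phi x dD1``.  A simplified pseudo-label predictor places labels
at a fixed offset along the Calpha -> Cbeta direction with isotropic spread,
standing in for full rotamer-library modeling on PDB structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "GOLDEN_RATIO",
    "PentagonGeometry",
    "StructureRing",
    "RingDistanceSamples",
    "pentagon_from_d1",
    "diameter_change_from_shift",
    "d2_shift_from_d1_shift",
    "pore_diameter_total",
    "predict_ring_distances",
    "ring_from_pdb",
]

GOLDEN_RATIO = (1.0 + math.sqrt(5.0)) / 2.0
SIN36 = math.sin(math.radians(36.0))
SIN72 = math.sin(math.radians(72.0))


@dataclass(frozen=True)
class PentagonGeometry:
    """Exact pentagon distances for a label ring of given radius (A)."""

    ring_radius: float

    def __post_init__(self) -> None:
        if self.ring_radius <= 0:
            raise ValueError("ring_radius must be positive")

    @property
    def d1(self) -> float:
        """Nearest-neighbour (side) distance, A."""
        return 2.0 * self.ring_radius * SIN36

    @property
    def d2(self) -> float:
        """Next-nearest (diagonal) distance, A."""
        return 2.0 * self.ring_radius * SIN72

    @property
    def ratio(self) -> float:
        """D2/D1 = golden ratio for any pentagon."""
        return self.d2 / self.d1


def pentagon_from_d1(d1: float) -> PentagonGeometry:
    """Pentagon geometry with the given side length (A)."""
    if d1 <= 0:
        raise ValueError("d1 must be positive")
    return PentagonGeometry(ring_radius=d1 / (2.0 * SIN36))


def diameter_change_from_shift(delta_d1: float) -> float:
    """Inner-diameter change from a D1 shift under uniform ring expansion.

    The circumscribed-circle diameter of the label pentagon changes by
    ``delta_d1 / sin 36 deg`` (a 3 A D1 shift gives 5.10 A, ~5 A).
    """
    return delta_d1 / SIN36


def d2_shift_from_d1_shift(delta_d1: float) -> float:
    """D2 shift implied by a D1 shift: golden-ratio scaling ``phi x dD1``."""
    return GOLDEN_RATIO * delta_d1


def pore_diameter_total(closed_diameter: float, delta_d1: float) -> float:
    """Expanded pore diameter: closed-state diameter plus the converted shift.

    With the ~4 A closed-state pore and the ~3 A D1 shift this yields ~9 A.
    """
    if closed_diameter < 0:
        raise ValueError("closed_diameter must be >= 0")
    return closed_diameter + diameter_change_from_shift(delta_d1)


@dataclass
class StructureRing:
    """Per-subunit label anchors of a Cn-symmetric structure.

    ``anchors`` are (n, 3) Calpha coordinates (A) in ring order;
    ``directions`` optional (n, 3) unit Calpha -> Cbeta vectors.  The
    pseudo-label sits at ``anchor + pseudo_label_offset * direction`` with
    isotropic Gaussian ``spread`` emulating rotamer breadth.
    """

    anchors: np.ndarray
    directions: Optional[np.ndarray] = None
    symmetry_order: int = 5
    pseudo_label_offset: float = 7.0
    spread: float = 2.5

    def __post_init__(self) -> None:
        self.anchors = np.asarray(self.anchors, dtype=float)
        if self.anchors.shape != (self.symmetry_order, 3):
            raise ValueError("need exactly symmetry_order anchor coordinates")
        if self.pseudo_label_offset < 0 or self.spread < 0:
            raise ValueError("offset and spread must be >= 0")
        if self.directions is not None:
            self.directions = np.asarray(self.directions, dtype=float)
            if self.directions.shape != self.anchors.shape:
                raise ValueError("directions must match anchors in shape")
            norms = np.linalg.norm(self.directions, axis=1, keepdims=True)
            if np.any(norms == 0):
                raise ValueError("zero-length direction vector")
            self.directions = self.directions / norms

    def label_sites(self) -> np.ndarray:
        """Mean pseudo-label positions (anchor + offset along direction)."""
        if self.directions is None or self.pseudo_label_offset == 0:
            return self.anchors.copy()
        return self.anchors + self.pseudo_label_offset * self.directions


@dataclass
class RingDistanceSamples:
    """Empirical nearest- and next-nearest distance samples from a ring."""

    d1_samples: np.ndarray
    d2_samples: np.ndarray

    @property
    def d1_mean(self) -> float:
        return float(np.mean(self.d1_samples))

    @property
    def d2_mean(self) -> float:
        return float(np.mean(self.d2_samples))

    @property
    def ratio_of_means(self) -> float:
        return self.d2_mean / self.d1_mean


def _ring_order(points: np.ndarray) -> np.ndarray:
    """Order points around their centroid by angle in the best-fit plane."""
    centered = points - points.mean(axis=0)
    # principal plane via SVD; project and sort by polar angle
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    uv = centered @ vt[:2].T
    ang = np.arctan2(uv[:, 1], uv[:, 0])
    return np.argsort(ang)


def predict_ring_distances(ring: StructureRing, n_samples: int = 10000,
                           seed: int = 0) -> RingDistanceSamples:
    """Monte-Carlo pseudo-label distance distributions for a Cn ring.

    Places labels at the ring's mean label sites plus isotropic Gaussian
    jitter of sd ``spread`` and collects all nearest-neighbour (D1-class)
    and next-nearest (D2-class) pair distances.  Raises if the anchors do
    not form a single ring (ambiguous neighbour classes).
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    n = ring.symmetry_order
    sites = ring.label_sites()
    order = _ring_order(sites)
    ordered = sites[order]
    # sanity: consecutive gaps should be comparable (single ring)
    gaps = np.linalg.norm(np.roll(ordered, -1, axis=0) - ordered, axis=1)
    if gaps.max() > 3.0 * gaps.min():
        raise ValueError("anchors do not form a single ring; neighbour "
                         "classes are ambiguous")
    rng = np.random.default_rng(seed)
    jitter = rng.standard_normal((n_samples, n, 3)) * ring.spread
    pos = ordered[None, :, :] + jitter
    d1, d2 = [], []
    for step, sink in ((1, d1), (2, d2)):
        for i in range(n):
            j = (i + step) % n
            sink.append(np.linalg.norm(pos[:, i] - pos[:, j], axis=1))
    return RingDistanceSamples(d1_samples=np.concatenate(d1),
                               d2_samples=np.concatenate(d2))


def ring_from_pdb(path, resid: int, chains: Optional[list] = None,
                  pseudo_label_offset: float = 7.0, spread: float = 2.5
                  ) -> StructureRing:
    """Build a StructureRing from one residue across the chains of a PDB.

    Reads the first model only, altloc 'A' (or blank); chain order defines
    subunit order.  Anchors are Calpha atoms; Calpha -> Cbeta vectors give
    the label offset direction (glycine falls back to no offset direction).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ring", str(path))
    model = next(structure.get_models())
    anchors, directions = [], []
    chain_ids = chains or [c.id for c in model]
    for cid in chain_ids:
        chain = model[cid]
        res = chain[(" ", resid, " ")]

        def _atom(name):
            atom = res[name]
            if atom.is_disordered():
                atom = atom.disordered_get("A")
            return np.array(atom.get_coord(), dtype=float)

        ca = _atom("CA")
        anchors.append(ca)
        if "CB" in res:
            cb = _atom("CB")
            directions.append(cb - ca)
        else:
            directions.append(np.zeros(3))
    directions = np.array(directions)
    if np.any(np.linalg.norm(directions, axis=1) == 0):
        directions = None
    return StructureRing(anchors=np.array(anchors), directions=directions,
                         symmetry_order=len(anchors),
                         pseudo_label_offset=pseudo_label_offset,
                         spread=spread)
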
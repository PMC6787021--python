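"""Synthetic DEER traces, ESEEM traces, and toy pocket trajectories.

Every generator emits data with a known ground truth so the downstream
analysis stages (background correction, Tikhonov inversion, stoichiometry,
ESEEM fitting, occupancy counting) can be tested end to end without raw
spectrometer or MD data.

The DEER generator models a C5-symmetric ring of nitroxide labels — one per
protomer of a pentameric channel — so two inter-label distances exist: the
pentagon side D1 = 2 R sin 36 deg and diagonal D2 = 2 R sin 72 deg, whose
ratio is the golden ratio.  Sites are labeled independently with probability
``f`` (the labeling degree), the pump pulse inverts each labeled spin with
probability ``lambda``, and the per-configuration intramolecular signal is
the observer-averaged pair product

    V_intra(t) = < prod_{j != i, labeled} [1 - lambda (1 - K(t, r_ij))] >_i,

whose long-time plateau reproduces the multispin depth law
``Delta = 1 - (1 - lambda f)^(n-1)``.  A mono-exponential intermolecular
background and white Gaussian noise complete the trace.  Noise is modeled on
the real channel only (analysis operates on phase-corrected real traces).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dipolar import TimeTrace, kernel_trace_fresnel, DipolarSettings
from .occupancy import TrajectoryFrames, Frame, OccupancySeries

__all__ = [
    "PentamerSpinSystem",
    "EseemGroundTruth",
    "ToyTrajectorySpec",
    "generate_deer_trace",
    "enumerate_intramolecular",
    "generate_eseem_trace",
    "generate_toy_trajectory",
]

GOLDEN_RATIO = (1.0 + math.sqrt(5.0)) / 2.0
SIN36 = math.sin(math.radians(36.0))
SIN72 = math.sin(math.radians(72.0))


@dataclass(frozen=True)
class PentamerSpinSystem:
    """Ground-truth description of a C5 spin-label ring.

    Parameters
    ----------
    n_sites : int
        Number of protomers (5 for a pentamer).
    ring_radius : float
        Radius of the label ring, Angstrom.
    site_spread : float
        Isotropic per-label positional standard deviation, Angstrom.  With
        spread 0 the system has exactly two pair distances D1 and D2.
    labeling_f : float
        Per-site labeling probability (labeling degree) in [0, 1].
    lambda_inv : float
        Per-pulse pump inversion probability in [0, 1].
    bg_rate : float
        Intermolecular background decay rate, 1/us.
    noise_sigma : float
        Additive white-noise standard deviation as a fraction of the t = 0
        amplitude.
    seed : int
        Seed for the generator's own randomness.
    """

    n_sites: int = 5
    ring_radius: float = 25.0 / (2.0 * SIN36)
    site_spread: float = 0.0
    labeling_f: float = 1.0
    lambda_inv: float = 0.46
    bg_rate: float = 0.15
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("need at least 2 sites")
        if not 0.0 <= self.labeling_f <= 1.0:
            raise ValueError("labeling_f must lie in [0, 1]")
        if not 0.0 <= self.lambda_inv <= 1.0:
            raise ValueError("lambda_inv must lie in [0, 1]")
        if self.ring_radius <= 0:
            raise ValueError("ring_radius must be positive")
        if self.site_spread < 0:
            raise ValueError("site_spread must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def d1(self) -> float:
        """Nearest-neighbour (pentagon side) distance, Angstrom."""
        return 2.0 * self.ring_radius * math.sin(math.pi / self.n_sites)

    @property
    def d2(self) -> float:
        """Next-nearest (pentagon diagonal) distance, Angstrom."""
        return 2.0 * self.ring_radius * math.sin(2.0 * math.pi / self.n_sites)

    @property
    def delta_theory(self) -> float:
        """Multispin modulation depth 1 - (1 - lambda f)^(n-1)."""
        return 1.0 - (1.0 - self.lambda_inv * self.labeling_f) ** (self.n_sites - 1)

    def ring_vertices(self) -> np.ndarray:
        """(n_sites, 3) label-ring vertex coordinates in the xy-plane."""
        ang = 2.0 * np.pi * np.arange(self.n_sites) / self.n_sites
        return np.column_stack([self.ring_radius * np.cos(ang),
                                self.ring_radius * np.sin(ang),
                                np.zeros(self.n_sites)])


def _pair_products(t: np.ndarray, labels: np.ndarray, dists: np.ndarray,
                   lam: float, settings: DipolarSettings) -> np.ndarray:
    """Observer-averaged intramolecular factor per configuration.

    labels : (nc, n) boolean labeling patterns
    dists  : (nc, n_pairs) pair distances, ordered as itertools.combinations
    Returns (nc, nt); configurations with no labeled observer give 1.
    """
    nc, n = labels.shape
    pairs = list(itertools.combinations(range(n), 2))
    pair_index = {p: k for k, p in enumerate(pairs)}
    # F[c, k, :] = 1 - lam (1 - K(t, r_k)) for each unique pair
    K = kernel_trace_fresnel(dists.ravel(), t, settings).reshape(
        nc, len(pairs), t.size)
    F = 1.0 - lam * (1.0 - K)
    nt = t.size
    total = np.zeros((nc, nt))
    n_obs = labels.sum(axis=1).astype(float)
    for i in range(n):
        prod = np.ones((nc, nt))
        for j in range(n):
            if j == i:
                continue
            k = pair_index[(min(i, j), max(i, j))]
            lj = labels[:, j]
            if lj.any():
                prod[lj] *= F[lj, k, :]
        total += labels[:, i][:, None] * prod
    out = np.ones((nc, nt))
    has_obs = n_obs > 0
    out[has_obs] = total[has_obs] / n_obs[has_obs, None]
    return out


def enumerate_intramolecular(system: PentamerSpinSystem, t: np.ndarray,
                             settings: DipolarSettings | None = None
                             ) -> np.ndarray:
    """Exact intramolecular factor by enumerating all 2^n labeling patterns.

    Only valid for ``site_spread = 0`` (fixed ring geometry); serves as the
    oracle for the Monte-Carlo generator.
    """
    if system.site_spread != 0:
        raise ValueError("enumeration requires site_spread = 0")
    settings = settings or DipolarSettings()
    t = np.asarray(t, dtype=float)
    n = system.n_sites
    verts = system.ring_vertices()
    pairs = list(itertools.combinations(range(n), 2))
    dists = np.array([np.linalg.norm(verts[i] - verts[j]) for i, j in pairs])
    patterns = np.array(list(itertools.product([False, True], repeat=n)))
    m = patterns.sum(axis=1)
    f = system.labeling_f
    weights = f**m * (1.0 - f) ** (n - m)
    sig = _pair_products(t, patterns, np.tile(dists, (patterns.shape[0], 1)),
                         system.lambda_inv, settings)
    # molecules with no labeled spin contribute no echo: condition on >= 1 label
    has = m > 0
    w = weights[has]
    if w.sum() == 0:
        return np.ones_like(t)
    # weight observers per pattern: echo amplitude proportional to label count
    nlab = m[has].astype(float)
    return (w * nlab) @ sig[has] / (w * nlab).sum()


def generate_deer_trace(system: PentamerSpinSystem, t_max: float, dt: float,
                        n_configs: int = 4096,
                        settings: DipolarSettings | None = None,
                        return_config_plateau: bool = False
                        ) -> tuple[TimeTrace, dict]:
    """Monte-Carlo DEER trace for a partially labeled pentamer ring.

    Parameters
    ----------
    system : PentamerSpinSystem
        Ground-truth spin system (geometry, labeling, inversion efficiency,
        background, noise, seed).
    t_max, dt : float
        Dipolar evolution window and sampling step, microseconds.
    n_configs : int
        Number of Monte-Carlo labeling/jitter configurations.

    Returns
    -------
    (TimeTrace, dict)
        The noisy trace and a ground-truth record with exact ``d1``, ``d2``,
        ``delta_theory``, background rate and the noise-free signal.
    """
    if dt <= 0 or t_max <= dt:
        raise ValueError("require t_max > dt > 0")
    settings = settings or DipolarSettings()
    rng = np.random.default_rng(system.seed)
    t = np.arange(0.0, t_max + dt / 2.0, dt)
    n = system.n_sites
    verts = system.ring_vertices()
    pairs = list(itertools.combinations(range(n), 2))

    labels = rng.random((n_configs, n)) < system.labeling_f
    pos = verts[None, :, :] + (
        rng.standard_normal((n_configs, n, 3)) * system.site_spread)
    dists = np.stack([np.linalg.norm(pos[:, i] - pos[:, j], axis=1)
                      for i, j in pairs], axis=1)

    sig_c = _pair_products(t, labels, dists, system.lambda_inv, settings)
    n_lab = labels.sum(axis=1).astype(float)
    w = n_lab  # echo amplitude of a molecule scales with its label count
    if w.sum() > 0:
        intra = (w[:, None] * sig_c).sum(axis=0) / w.sum()
    else:
        intra = np.ones_like(t)

    clean = intra * np.exp(-system.bg_rate * t)
    y = clean + system.noise_sigma * clean[0] * rng.standard_normal(t.size)
    trace = TimeTrace(t=t, y=y, unit="us", noise_std=(
        system.noise_sigma * clean[0] if system.noise_sigma > 0 else None),
        meta={"label": "synthetic-pentamer", "seed": system.seed})
    truth = {
        "d1": system.d1,
        "d2": system.d2,
        "delta_theory": system.delta_theory,
        "bg_rate": system.bg_rate,
        "lambda_inv": system.lambda_inv,
        "labeling_f": system.labeling_f,
        "n_sites": n,
        "clean_signal": clean,
        "intramolecular": intra,
    }
    if return_config_plateau:
        # per-configuration plateau values at the final time point, for
        # Monte-Carlo standard-error estimates in depth checks
        truth["config_plateau"] = sig_c[:, -1]
        truth["config_weights"] = w
    return trace, truth


@dataclass(frozen=True)
class EseemGroundTruth:
    """Ground truth for a 3-pulse ESEEM decay.

    ``V(T) = baseline(T) [1 + k exp(-T/Td) cos(2 pi nu T + phi)] + noise``
    with a stretched-exponential baseline
    ``baseline(T) = amp * exp(-(T/T_b)^beta)``.  ``nu`` is in MHz and times
    in ns.  ``tau`` is the fixed first interpulse delay (acquisition
    metadata; at the proton blind spot for deuterium accessibility work).
    """

    mod_depth_k: float = 0.1
    freq_nu: float = 2.26
    decay_Td: float = 800.0
    phase_phi: float = 0.0
    baseline_amp: float = 1.0
    baseline_Tb: float = 2000.0
    baseline_beta: float = 1.0
    tau: float = 140.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mod_depth_k < 0:
            raise ValueError("mod_depth_k must be >= 0")
        if self.freq_nu <= 0:
            raise ValueError("freq_nu must be positive")
        if self.decay_Td <= 0:
            raise ValueError("decay_Td must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def baseline(self, T: np.ndarray) -> np.ndarray:
        return self.baseline_amp * np.exp(
            -((np.asarray(T, float) / self.baseline_Tb) ** self.baseline_beta))

    def modulation(self, T: np.ndarray) -> np.ndarray:
        T = np.asarray(T, float)
        return self.mod_depth_k * np.exp(-T / self.decay_Td) * np.cos(
            2.0 * np.pi * self.freq_nu * 1e-3 * T + self.phase_phi)


def generate_eseem_trace(truth: EseemGroundTruth, T_max: float, dT: float
                         ) -> TimeTrace:
    """Damped-cosine 3pESEEM trace on a uniform ns grid."""
    if dT <= 0 or T_max <= dT:
        raise ValueError("require T_max > dT > 0")
    rng = np.random.default_rng(truth.seed)
    T = np.arange(0.0, T_max + dT / 2.0, dT)
    clean = truth.baseline(T) * (1.0 + truth.modulation(T))
    y = clean + truth.noise_sigma * clean[0] * rng.standard_normal(T.size)
    return TimeTrace(t=T, y=y, unit="ns",
                     noise_std=(truth.noise_sigma * clean[0]
                                if truth.noise_sigma > 0 else None),
                     meta={"tau_ns": truth.tau, "label": "synthetic-eseem"})


@dataclass(frozen=True)
class ToyTrajectorySpec:
    """Specification of a toy pocket-occupancy trajectory.

    Five anchor sites sit at 72 degree spacing on a ring; mobile chains hop
    between bulk and pocket slots with Markov dwell/entry probabilities.
    Each pocket holds at most ``slots_per_pocket`` chains (two acyl chains
    per nano-pocket, ten per pentamer, in the emulated system).
    """

    n_pockets: int = 5
    anchor_radius: float = 20.0
    n_chains: int = 20
    beads_per_chain: int = 3
    dwell_prob: float = 0.9
    entry_prob: float = 0.1
    slots_per_pocket: int = 2
    n_frames: int = 100
    frame_dt: float = 1.0
    initial_occupancy: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dwell_prob <= 1.0:
            raise ValueError("dwell_prob must lie in [0, 1]")
        if not 0.0 <= self.entry_prob <= 1.0:
            raise ValueError("entry_prob must lie in [0, 1]")
        if self.beads_per_chain < 1:
            raise ValueError("beads_per_chain must be >= 1")
        if self.slots_per_pocket < 1 or self.n_pockets < 1:
            raise ValueError("pockets and slots must be >= 1")
        if self.initial_occupancy > self.n_pockets * self.slots_per_pocket:
            raise ValueError("initial_occupancy exceeds total slots")
        if self.initial_occupancy > self.n_chains:
            raise ValueError("initial_occupancy exceeds chain count")


def generate_toy_trajectory(spec: ToyTrajectorySpec
                            ) -> tuple[TrajectoryFrames, OccupancySeries]:
    """Emit coordinate frames plus the ground-truth occupancy series.

    Resident chains are placed with every bead within 3 A of their pocket
    anchor; non-resident chains are kept >= 10 A from every anchor, so an
    analyzer with the 5 A residency cutoff must reproduce the constructed
    series exactly.
    """
    rng = np.random.default_rng(spec.seed)
    ang = 2.0 * np.pi * np.arange(spec.n_pockets) / spec.n_pockets
    anchors = np.column_stack([spec.anchor_radius * np.cos(ang),
                               spec.anchor_radius * np.sin(ang),
                               np.zeros(spec.n_pockets)])
    n_slots = spec.n_pockets * spec.slots_per_pocket

    # state per chain: pocket index or -1 (bulk)
    state = np.full(spec.n_chains, -1, dtype=int)
    occ = np.zeros(spec.n_pockets, dtype=int)
    for c in range(spec.initial_occupancy):
        p = c % spec.n_pockets
        if occ[p] < spec.slots_per_pocket:
            state[c] = p
            occ[p] += 1
        else:
            free = np.where(occ < spec.slots_per_pocket)[0]
            state[c] = free[0]
            occ[free[0]] += 1

    frames = []
    counts = []
    per_pocket = []
    bulk_radius = spec.anchor_radius + 50.0
    for k in range(spec.n_frames):
        if k > 0:
            # departures
            for c in np.where(state >= 0)[0]:
                if rng.random() > spec.dwell_prob:
                    occ[state[c]] -= 1
                    state[c] = -1
            # entries into free slots
            for c in np.where(state < 0)[0]:
                free = np.where(occ < spec.slots_per_pocket)[0]
                if free.size and rng.random() < spec.entry_prob:
                    p = int(rng.choice(free))
                    state[c] = p
                    occ[p] += 1
        chains = {}
        for c in range(spec.n_chains):
            if state[c] >= 0:
                center = anchors[state[c]]
                offs = rng.standard_normal((spec.beads_per_chain, 3))
                offs *= (rng.random((spec.beads_per_chain, 1)) * 2.0 /
                         np.maximum(np.linalg.norm(offs, axis=1,
                                                   keepdims=True), 1e-12))
                beads = center + offs  # all beads within 2 A < 3 A
            else:
                u = rng.standard_normal(3)
                u /= np.linalg.norm(u)
                center = u * (bulk_radius + 10.0 * rng.random())
                beads = center + 0.5 * rng.standard_normal(
                    (spec.beads_per_chain, 3))
            chains[f"chain_{c}"] = beads
        pockets = {f"pocket_{p}": anchors[p][None, :].copy()
                   for p in range(spec.n_pockets)}
        frames.append(Frame(time=k * spec.frame_dt, pockets=pockets,
                            chains=chains))
        counts.append(int((state >= 0).sum()))
        per_pocket.append(occ.copy())
    traj = TrajectoryFrames(frames=frames)
    series = OccupancySeries(
        times=np.array([f.time for f in frames]),
        counts=np.array(counts),
        per_pocket=np.array(per_pocket),
    )
    assert series.per_pocket.max(initial=0) <= spec.slots_per_pocket
    return traj, series
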
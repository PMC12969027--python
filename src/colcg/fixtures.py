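"""Synthetic input generators for every analyzer in the toolkit.

These produce ideal triple helices (geometry round trips for the helix
metrics), Gaussian-mixture bonded samples (Boltzmann-inversion round trips),
Crooks-consistent work sets (free-energy estimator round trips), and toy
gap/overlap fibrils with an affine per-segment strain schedule (strain-ratio
and force-profile round trips). All generators are deterministic given
(spec, seed).

The fixtures emulate geometry and statistics, not thermodynamics: a single
minor-helix model stands in for the supercoiled collagen triple helix, and
positional noise is isotropic Gaussian jitter rather than thermal motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from .boltzmann_inversion import BondedParameter, GaussianComponent
from .cg_mapping import Bead, CGTrajectory
from .fibril_analysis import FibrilSegmentation
from .free_energy import WorkSet
from .topology_builder import BeadEntry, Topology


# ---------------------------------------------------------------------------
# Ideal triple helix
# ---------------------------------------------------------------------------


@dataclass
class HelixSpec:
    """Geometry of an ideal (single minor-helix) triple helix.

    Defaults follow the experimental collagen geometry: rise 0.290 nm per
    residue and 3.28 residues per turn, three chains phase-shifted by
    2*pi/3 on a 0.15 nm radius, with the canonical GLY-PRO-HYP repeat.
    """

    n_residues: int = 30
    rise_per_residue: float = C.EXPERIMENTAL_RISE_PER_RESIDUE
    residues_per_turn: float = C.EXPERIMENTAL_RESIDUES_PER_TURN
    helix_radius: float = 0.15
    n_chains: int = 3
    phase_offset: float = 2.0 * np.pi / 3.0
    sequence_pattern: tuple = ("GLY", "PRO", "HYP")
    handedness: int = 1  # +1 right-handed, -1 left-handed
    axial_stagger: float = 0.0  # per-chain z shift (nm)

    def __post_init__(self) -> None:
        if self.residues_per_turn <= 2:
            raise ValueError("residues_per_turn must exceed 2")
        if self.helix_radius < 0:
            raise ValueError("helix_radius must be non-negative")


def build_triple_helix(
    spec: HelixSpec,
    seed: int = 0,
    n_frames: int = 1,
    noise_sd: float = 0.0,
    helix_id: str = "H1",
    origin: np.ndarray | None = None,
) -> CGTrajectory:
    """Bead trajectory of an ideal helix bundle, optionally jittered.

    Chain c, residue i sits at angle h * 2*pi*i / rpt + c * phase and
    height i * rise + c * stagger. Gaussian positional noise of SD
    ``noise_sd`` (nm) is added independently per frame when requested.
    """
    rng = np.random.default_rng(seed)
    omega = spec.handedness * 2.0 * np.pi / spec.residues_per_turn
    origin = np.zeros(3) if origin is None else np.asarray(origin, float)

    beads: list = []
    coords: list = []
    for c in range(spec.n_chains):
        chain_id = chr(ord("A") + c)
        for i in range(spec.n_residues):
            theta = omega * i + c * spec.phase_offset
            coords.append(
                origin
                + np.array(
                    [
                        spec.helix_radius * np.cos(theta),
                        spec.helix_radius * np.sin(theta),
                        i * spec.rise_per_residue + c * spec.axial_stagger,
                    ]
                )
            )
            beads.append(
                Bead(
                    label="BB",
                    chain_id=chain_id,
                    helix_id=helix_id,
                    res_index=i + 1,
                    res_name=spec.sequence_pattern[i % len(spec.sequence_pattern)],
                )
            )
    base = np.asarray(coords)
    frames = np.repeat(base[None, :, :], n_frames, axis=0)
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    return CGTrajectory(beads=beads, frames=frames)


def build_helix_pair(
    spec: HelixSpec,
    separation: float = 1.0,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> CGTrajectory:
    """Two triple helices side by side (helix ids H1/H2), ``separation`` nm
    apart along x — close enough that a naive distance filter would link
    them, which the intrahelical contact rule must refuse to do."""
    t1 = build_triple_helix(spec, seed=seed, noise_sd=noise_sd, helix_id="H1")
    t2 = build_triple_helix(
        spec, seed=seed + 1, noise_sd=noise_sd, helix_id="H2",
        origin=np.array([separation, 0.0, 0.0]),
    )
    beads = list(t1.beads) + [
        Bead(b.label, "X" + b.chain_id, b.helix_id, b.res_index, b.res_name)
        for b in t2.beads
    ]
    frames = np.concatenate([t1.frames, t2.frames], axis=1)
    return CGTrajectory(beads=beads, frames=frames)


# ---------------------------------------------------------------------------
# Gaussian-mixture bonded samples
# ---------------------------------------------------------------------------

_LEGAL_RANGE = {
    "bond": (1e-6, np.inf),
    "angle": (0.0, 180.0),
    "dihedral": (-180.0, 180.0),
}


def sample_bonded(
    kind: str,
    components,
    weights,
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """Draw i.i.d. samples from a Gaussian mixture, clipped to the legal
    range of the bonded variable."""
    if kind not in _LEGAL_RANGE:
        raise ValueError(f"unknown term kind {kind!r}")
    weights = np.asarray(weights, dtype=float)
    if weights.size != len(components):
        raise ValueError("one weight per component required")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    rng = np.random.default_rng(seed)
    which = rng.choice(len(components), size=n, p=weights)
    mus = np.asarray([c.mu for c in components])
    sds = np.asarray([c.sigma for c in components])
    samples = rng.normal(mus[which], sds[which])
    lo, hi = _LEGAL_RANGE[kind]
    return np.clip(samples, lo, hi)


def backbone_bond_mixture() -> tuple:
    """The two-component backbone bond-length mixture (components, weights)
    used for backbone parametrization round trips: means/SDs from the AA
    bond-length fit, weights 0.34/0.66 (the GLY fraction of the collagen
    triplet repeat vs the rest)."""
    lo = GaussianComponent(*C.BACKBONE_BOND_LOWER, amplitude=0.34)
    hi = GaussianComponent(*C.BACKBONE_BOND_UPPER, amplitude=0.66)
    return (lo, hi), (0.34, 0.66)


# ---------------------------------------------------------------------------
# Crooks-consistent work sets
# ---------------------------------------------------------------------------


def gen_work_sets(
    planted_dg: float,
    sigma_w: float,
    n_f: int = 100,
    n_b: int = 100,
    temperature: float = C.DEFAULT_TEMPERATURE,
    seed: int = 0,
) -> WorkSet:
    """Gaussian work distributions satisfying the Crooks relation exactly.

    Forward work ~ N(dG + sigma^2 / 2kBT, sigma^2); backward (reverse
    process) work ~ N(-dG + sigma^2 / 2kBT, sigma^2). The common
    dissipation sigma^2/2kBT makes P_F(W)/P_R(-W) = exp[(W - dG)/kBT]
    hold identically. With sigma_w = 0 both collapse to delta functions
    and any consistent estimator returns dG exactly.
    """
    if sigma_w < 0:
        raise ValueError("sigma_w must be non-negative")
    rng = np.random.default_rng(seed)
    diss = sigma_w**2 / (2.0 * C.KB * temperature)
    fwd = planted_dg + diss + (sigma_w * rng.standard_normal(n_f) if sigma_w else np.zeros(n_f))
    bwd = -planted_dg + diss + (sigma_w * rng.standard_normal(n_b) if sigma_w else np.zeros(n_b))
    return WorkSet(forward_work=fwd, backward_work=bwd, temperature=temperature)


# ---------------------------------------------------------------------------
# Toy gap/overlap fibril
# ---------------------------------------------------------------------------


@dataclass
class ToyFibrilSpec:
    """A 1D toy fibril: strands of beads along z with alternating dense
    (overlap) and sparse (gap) segments and cross-link markers at segment
    boundaries.

    Defaults give the full-molecule geometry: 335 nm of fibril with a
    67 nm D-period split half/half into overlap and gap, i.e. 10 equally
    spaced boundaries delimiting five complete overlap and four complete
    gap segments (the terminal gap material has no closing cross-link and
    is not a complete segment).
    """

    n_helices: int = 1
    length: float = 335.0
    d_period: float = 67.0
    overlap_fraction: float = 0.5
    crosslink_positions: np.ndarray | None = None
    spacing_overlap: float = 0.5  # nm between beads in dense segments
    spacing_gap: float = 1.0
    helix_separation: float = 1.5  # nm between parallel strands

    def __post_init__(self) -> None:
        if self.d_period <= 0:
            raise ValueError("d_period must be positive")
        if not 0.0 < self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in (0, 1)")

    def boundaries(self) -> np.ndarray:
        """Cross-link positions = starts of overlap and gap zones."""
        if self.crosslink_positions is not None:
            return np.asarray(self.crosslink_positions, dtype=float)
        pos = []
        z = 0.0
        l_over = self.overlap_fraction * self.d_period
        l_gap = self.d_period - l_over
        while z < self.length - 1e-9:
            pos.append(z)
            z += l_over
            if z < self.length - 1e-9:
                pos.append(z)
            z += l_gap
        return np.asarray(pos)


def build_toy_fibril(
    spec: ToyFibrilSpec,
    seed: int = 0,
    n_frames: int = 5,
    overlap_strain: float | np.ndarray = 0.005,
    gap_strain: float | np.ndarray = 0.010,
    bond_k: float = C.BOND_GENERAL_K,
) -> tuple:
    """Toy fibril trajectory + segmentation + harmonic topology.

    Scalar strains mean a linear ramp from 0 (frame 0, the reference) to
    the given value (last frame); arrays give the per-frame strain of each
    segment type directly. Each segment deforms affinely, so segment
    elongations are exactly l0 * strain — with equal overlap/gap reference
    lengths and overlap strain half the gap strain, the overlap/gap strain
    ratio is exactly 0.5 in every strained frame.

    Returns ``(traj, segmentation, topology)`` where the segmentation
    carries analytic per-frame boundary positions and the topology has one
    harmonic bond per consecutive strand bead pair (r0 = frame-0 spacing).
    """
    rng = np.random.default_rng(seed)  # reserved for jittered variants
    bounds = spec.boundaries()
    if bounds.size < 2:
        raise ValueError("fibril must contain at least 2 boundaries")
    labels = ["overlap" if k % 2 == 0 else "gap" for k in range(bounds.size - 1)]

    eps_o = _ramp(overlap_strain, n_frames)
    eps_g = _ramp(gap_strain, n_frames)

    # reference bead positions along z, segment-dependent spacing
    def _spacing_at(z: float) -> float:
        phase = (z % spec.d_period) / spec.d_period
        return (
            spec.spacing_overlap
            if phase < spec.overlap_fraction
            else spec.spacing_gap
        )

    z0_list = []
    z = 0.0
    while z <= spec.length + 1e-9:
        z0_list.append(z)
        z += _spacing_at(z)
    z0 = np.asarray(z0_list)

    # analytic per-frame boundary positions: cumulative elongation of the
    # complete segments to the left
    seg_l0 = np.diff(bounds)
    seg_eps = np.stack(
        [eps_o if lab == "overlap" else eps_g for lab in labels], axis=1
    )  # (n_frames, n_segments)
    elong = seg_l0[None, :] * seg_eps
    frame_bounds = np.empty((n_frames, bounds.size))
    frame_bounds[:, 0] = bounds[0]
    frame_bounds[:, 1:] = bounds[None, 1:] + np.cumsum(elong, axis=1)

    # per-bead segment membership (terminal material follows the last label parity)
    seg_of = np.clip(np.searchsorted(bounds, z0, side="right") - 1, 0, None)
    n_segments = len(labels)

    def _strain_of(si: int, f: int) -> float:
        if si < 0:
            return 0.0
        if si < n_segments:
            lab = labels[si]
        else:  # terminal material continues the alternation
            lab = labels[0] if si % 2 == 0 else ("gap" if labels[0] == "overlap" else "overlap")
        return (eps_o if lab == "overlap" else eps_g)[f]

    beads: list = []
    frames = np.zeros((n_frames, 0, 3))
    all_xyz = []
    topo_beads: list = []
    bonds: list = []
    idx = 0
    for h in range(spec.n_helices):
        x_off = h * spec.helix_separation
        first = idx
        for bi, zb in enumerate(z0):
            beads.append(
                Bead("BB", chain_id=f"F{h}", helix_id=f"H{h}", res_index=bi + 1,
                     res_name="GLY")
            )
            topo_beads.append(
                BeadEntry(index=idx + 1, bead_type="P2", name="BB", residue="GLY",
                          resnr=idx + 1)
            )
            xyz = np.empty((n_frames, 3))
            xyz[:, 0] = x_off
            xyz[:, 1] = 0.0
            for f in range(n_frames):
                si = int(seg_of[bi])
                if si >= bounds.size - 1:
                    # beyond the last boundary: terminal (incomplete) material
                    base = frame_bounds[f, -1]
                    xyz[f, 2] = base + (zb - bounds[-1]) * (1 + _strain_of(si, f))
                else:
                    base = frame_bounds[f, si]
                    xyz[f, 2] = base + (zb - bounds[si]) * (1 + _strain_of(si, f))
            all_xyz.append(xyz)
            if bi > 0:
                r0 = z0[bi] - z0[bi - 1]
                bonds.append(
                    BondedParameter(
                        kind="bond", beads=(idx, idx + 1), eq_value=float(r0),
                        force_constant=bond_k, funct=1, source="manual",
                    )
                )
            idx += 1
    # cross-link marker beads, tracked with the boundaries
    for k, b in enumerate(bounds):
        beads.append(
            Bead("XL", chain_id="X", helix_id="XL", res_index=k + 1, res_name="XLK")
        )
        topo_beads.append(
            BeadEntry(index=idx + 1, bead_type="SP1", name="XL", residue="XLK",
                      resnr=idx + 1, mass=C.BEAD_MASS["small"])
        )
        xyz = np.empty((n_frames, 3))
        xyz[:, 0] = -spec.helix_separation
        xyz[:, 1] = 0.0
        xyz[:, 2] = frame_bounds[:, k]
        all_xyz.append(xyz)
        idx += 1

    frames = np.stack(all_xyz, axis=1)
    traj = CGTrajectory(beads=beads, frames=frames)
    seg = FibrilSegmentation(
        boundaries=bounds, labels=labels, frame_boundaries=frame_bounds
    )
    topo = Topology("toy_fibril", topo_beads, bonds)
    topo.validate()
    return traj, seg, topo


def _ramp(value, n_frames: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        if n_frames == 1:
            return np.array([float(arr)])
        return np.linspace(0.0, float(arr), n_frames)
    if arr.size != n_frames:
        raise ValueError("per-frame strain array length must equal n_frames")
    return arr
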
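"""Structural and mechanical observables for CG collagen systems.

Covers the validation observables of the collagen model: triple-helix
geometry (rise per residue, residues per turn), end-to-end distance time
series, the overlap/gap strain ratio of a fibril under load with
first-order error propagation, binned bond-force profiles along the fibril
axis, and Shrake-Rupley bead SASA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import constants as C
from .cg_mapping import CGTrajectory


# ---------------------------------------------------------------------------
# End-to-end distance
# ---------------------------------------------------------------------------


def end_to_end(
    traj: CGTrajectory,
    group_a: np.ndarray,
    group_b: np.ndarray,
) -> np.ndarray:
    """Per-frame distance (nm) between the centers of geometry of two bead
    index groups."""
    ga = np.asarray(group_a, dtype=int).ravel()
    gb = np.asarray(group_b, dtype=int).ravel()
    if ga.size == 0 or gb.size == 0:
        raise ValueError("bead selections must be non-empty")
    cog_a = traj.frames[:, ga, :].mean(axis=1)
    cog_b = traj.frames[:, gb, :].mean(axis=1)
    return np.linalg.norm(cog_b - cog_a, axis=1)


# ---------------------------------------------------------------------------
# Helix metrics
# ---------------------------------------------------------------------------


@dataclass
class HelixMetrics:
    """Pooled local helix geometry estimates.

    ``rise_per_residue`` and ``twist_per_residue`` are arrays pooled over
    windows and frames; ``residues_per_turn`` = 360 / |twist|.
    """

    rise_per_residue: np.ndarray
    twist_per_residue: np.ndarray
    n_degenerate: int = 0

    @property
    def residues_per_turn(self) -> np.ndarray:
        return 360.0 / np.abs(self.twist_per_residue)

    def summary(self) -> dict:
        return {
            "rise_per_residue": float(np.mean(self.rise_per_residue)),
            "residues_per_turn": float(np.mean(self.residues_per_turn)),
            "twist_per_residue": float(np.mean(self.twist_per_residue)),
            "n_degenerate": self.n_degenerate,
        }


class DegenerateHelixError(ValueError):
    """All windows were collinear: the twist is undefined."""


_BISECTOR_TOL = 1e-9


def helix_metrics(
    traj: CGTrajectory,
    chain: str | np.ndarray,
    window: int | None = None,
) -> HelixMetrics:
    """Estimate local rise and twist per residue of one bead chain.

    Uses the bisector construction: for consecutive beads P(i-1), P(i),
    P(i+1), the vector v_i = (P(i-1)-P(i)) + (P(i+1)-P(i)) points from the
    bead toward the local helix axis and is perpendicular to it. Successive
    v_i rotate by exactly the per-residue twist about the axis, and the
    axis direction follows from v_i x v_(i+1). The rise is the projection
    of the bead step onto the axis. Exact for an ideal helix; windows with
    (near-)collinear beads are flagged degenerate and excluded.
    """
    if isinstance(chain, str):
        idx = traj.chain_indices(chain)
    else:
        idx = np.asarray(chain, dtype=int).ravel()
    n = idx.size
    if window is None:
        window = n
    if not 4 <= window <= n:
        raise ValueError(f"window must be in [4, {n}], got {window}")

    rises: list = []
    twists: list = []
    n_degen = 0
    for f in range(traj.n_frames):
        pts = traj.frames[f, idx, :]
        for s in range(0, n - window + 1):
            w = pts[s : s + window]
            out = _window_helix(w)
            if out is None:
                n_degen += 1
                continue
            rise, twist = out
            rises.append(rise)
            twists.append(twist)
    if not twists:
        raise DegenerateHelixError(
            "no window yielded a defined twist (collinear beads?)"
        )
    return HelixMetrics(
        rise_per_residue=np.asarray(rises),
        twist_per_residue=np.asarray(twists),
        n_degenerate=n_degen,
    )


def _window_helix(w: np.ndarray):
    """Rise (nm) and signed twist (deg) of one window, or None if degenerate."""
    steps = np.diff(w, axis=0)  # (m-1, 3)
    v = w[:-2] + w[2:] - 2 * w[1:-1]  # bisector vectors at interior beads
    norms = np.linalg.norm(v, axis=1)
    if np.all(norms < _BISECTOR_TOL):
        return None
    good = norms > _BISECTOR_TOL
    if good.sum() < 2:
        return None
    vg = v[good] / norms[good, None]

    # axis from successive bisector cross products
    crosses = np.cross(vg[:-1], vg[1:])
    axis = crosses.sum(axis=0)
    a_norm = np.linalg.norm(axis)
    if a_norm < _BISECTOR_TOL:
        return None
    axis /= a_norm
    # orient the axis along the chain direction
    if np.dot(axis, steps.sum(axis=0)) < 0:
        axis = -axis

    rise = float(np.mean(steps @ axis))

    # twist: signed rotation of the bisector projections about the axis
    proj = vg - np.outer(vg @ axis, axis)
    p_norm = np.linalg.norm(proj, axis=1)
    ok = p_norm > _BISECTOR_TOL
    if ok.sum() < 2:
        return None
    proj = proj[ok] / p_norm[ok, None]
    cosang = np.clip(np.einsum("ij,ij->i", proj[:-1], proj[1:]), -1.0, 1.0)
    sinang = np.einsum("ij,ij->i", np.cross(proj[:-1], proj[1:]), axis[None, :])
    ang = np.degrees(np.arctan2(sinang, cosang))
    twist = float(np.mean(ang))
    if abs(twist) < 1e-12:
        return None
    return rise, twist


# ---------------------------------------------------------------------------
# Fibril segmentation and strain ratio
# ---------------------------------------------------------------------------


@dataclass
class FibrilSegmentation:
    """Alternating gap/overlap segments along the fibril axis.

    ``boundaries`` are the reference (frame-0 / unstrained) positions (nm)
    of the segment delimiters, ``labels`` the segment type between
    consecutive boundaries. ``frame_boundaries`` (n_frames, n_boundaries)
    optionally carries the tracked per-frame delimiter positions from which
    per-frame segment lengths derive.
    """

    boundaries: np.ndarray
    labels: list
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    frame_boundaries: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float).ravel()
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if len(self.labels) != self.boundaries.size - 1:
            raise ValueError("need one label per segment")
        for a, b in zip(self.labels[:-1], self.labels[1:]):
            if a == b:
                raise ValueError("gap and overlap segments must alternate")
        if self.frame_boundaries is not None:
            self.frame_boundaries = np.asarray(self.frame_boundaries, dtype=float)
            if self.frame_boundaries.shape[1] != self.boundaries.size:
                raise ValueError("frame_boundaries column count mismatch")

    @property
    def reference_lengths(self) -> np.ndarray:
        return np.diff(self.boundaries)

    def frame_lengths(self) -> np.ndarray:
        if self.frame_boundaries is None:
            raise ValueError("no per-frame boundary positions available")
        return np.diff(self.frame_boundaries, axis=1)

    def segment_indices(self, label: str) -> np.ndarray:
        return np.asarray([k for k, l in enumerate(self.labels) if l == label], int)


def segment_fibril(
    crosslink_positions,
    mode: str = "from_crosslinks",
    first_segment: str = "overlap",
) -> FibrilSegmentation:
    """Build alternating gap/overlap segments from delimiter positions.

    ``from_crosslinks``: positions are cross-link region centers along the
    axis and become segment boundaries directly. ``explicit``: positions
    are user-supplied boundaries. Only complete (interior) segments are
    represented; terminal material outside the first/last boundary is
    dropped by construction.
    """
    pos = np.asarray(crosslink_positions, dtype=float).ravel()
    if mode not in ("from_crosslinks", "explicit"):
        raise ValueError(f"unknown mode {mode!r}")
    if pos.size < 2:
        raise ValueError("need at least 2 boundaries")
    if np.any(np.diff(pos) <= 0):
        raise ValueError("boundaries must be strictly increasing")
    if first_segment not in ("gap", "overlap"):
        raise ValueError("first_segment must be 'gap' or 'overlap'")
    other = "gap" if first_segment == "overlap" else "overlap"
    labels = [first_segment if k % 2 == 0 else other for k in range(pos.size - 1)]
    return FibrilSegmentation(boundaries=pos, labels=labels)


def assign_parity_by_density(
    seg: FibrilSegmentation, traj: CGTrajectory, frame: int = 0
) -> FibrilSegmentation:
    """Relabel segments so the denser one (more beads per nm) is 'overlap'."""
    z = traj.frames[frame] @ seg.axis
    counts = np.histogram(z, bins=seg.boundaries)[0]
    density = counts / seg.reference_lengths
    even = density[0::2].mean()
    odd = density[1::2].mean() if seg.labels[1:] else -np.inf
    first = "overlap" if even >= odd else "gap"
    other = "gap" if first == "overlap" else "overlap"
    labels = [first if k % 2 == 0 else other for k in range(len(seg.labels))]
    return FibrilSegmentation(
        boundaries=seg.boundaries, labels=labels, axis=seg.axis,
        frame_boundaries=seg.frame_boundaries,
    )


def track_boundaries(
    seg: FibrilSegmentation, traj: CGTrajectory, marker: str = "XLK"
) -> FibrilSegmentation:
    """Fill per-frame boundary positions from cross-link marker beads.

    Marker beads (res_name ``marker``) are matched to reference boundaries
    by proximity in frame 0 and followed across frames along the axis.
    """
    m_idx = [i for i, b in enumerate(traj.beads) if b.res_name == marker]
    if len(m_idx) < seg.boundaries.size:
        raise ValueError(
            f"found {len(m_idx)} marker beads for {seg.boundaries.size} boundaries"
        )
    z0 = traj.frames[0, m_idx, :] @ seg.axis
    order = []
    for b in seg.boundaries:
        order.append(m_idx[int(np.argmin(np.abs(z0 - b)))])
    fb = traj.frames[:, order, :] @ seg.axis
    return FibrilSegmentation(
        boundaries=seg.boundaries, labels=list(seg.labels), axis=seg.axis,
        frame_boundaries=fb,
    )


@dataclass
class StrainRatioSeries:
    time: np.ndarray
    ratio: np.ndarray  # masked (nan) where the gap elongation vanishes
    sigma_ratio: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ns": self.time, "ratio": self.ratio, "sigma": self.sigma_ratio}
        )


def strain_ratio(
    seg: FibrilSegmentation,
    reference_frame: int = 0,
    zero_tolerance: float = 1e-12,
) -> StrainRatioSeries:
    """Overlap/gap strain ratio per frame with propagated uncertainty.

    ratio(t) = <l_overlap,t - l_overlap,0> / <l_gap,t - l_gap,0>, averaging
    over complete segments of each type. The uncertainty is first-order
    propagation of the standard errors of the two segment-elongation means:
    sigma = |ratio| * sqrt((s_num/num)^2 + (s_den/den)^2). Frames whose
    mean gap elongation is (numerically) zero are masked with NaN.
    """
    lengths = seg.frame_lengths()  # (n_frames, n_segments)
    l0 = np.diff(seg.frame_boundaries[reference_frame])
    elong = lengths - l0[None, :]
    i_over = seg.segment_indices("overlap")
    i_gap = seg.segment_indices("gap")
    if i_over.size == 0 or i_gap.size == 0:
        raise ValueError("segmentation must contain both gap and overlap segments")

    num = elong[:, i_over].mean(axis=1)
    den = elong[:, i_gap].mean(axis=1)
    s_num = elong[:, i_over].std(axis=1, ddof=1) / math.sqrt(i_over.size) if i_over.size > 1 else np.zeros_like(num)
    s_den = elong[:, i_gap].std(axis=1, ddof=1) / math.sqrt(i_gap.size) if i_gap.size > 1 else np.zeros_like(den)

    ratio = np.full_like(num, np.nan)
    sigma = np.full_like(num, np.nan)
    ok = np.abs(den) > zero_tolerance
    ratio[ok] = num[ok] / den[ok]
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.sqrt(
            np.where(np.abs(num) > 0, (s_num / num) ** 2, 0.0)
            + (s_den / np.where(ok, den, 1.0)) ** 2
        )
    sigma[ok] = np.abs(ratio[ok]) * rel[ok]

    n_frames = lengths.shape[0]
    time = np.arange(n_frames, dtype=float)
    return StrainRatioSeries(time=time, ratio=ratio, sigma_ratio=sigma)


# ---------------------------------------------------------------------------
# Bond force profile
# ---------------------------------------------------------------------------


@dataclass
class ForceProfile:
    bin_centers: np.ndarray  # nm along the axis
    mean_force: np.ndarray  # pN
    count: np.ndarray
    spread: np.ndarray  # pN, SD within bin

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_nm": self.bin_centers,
                "mean_force_pN": self.mean_force,
                "count": self.count,
                "sd_pN": self.spread,
            }
        )


def bond_force_profile(
    traj: CGTrajectory,
    topology,
    n_bins: int = 300,
    axis: np.ndarray | None = None,
) -> ForceProfile:
    """Axially binned harmonic bond-force profile.

    Per bond and frame: F = k |r - r0| (kJ/mol/nm), converted to pN, and
    assigned to the axial coordinate of the bond midpoint. Pooled over all
    frames into ``n_bins`` equal bins spanning the observed midpoints.
    """
    if axis is None:
        axis = np.array([0.0, 0.0, 1.0])
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    bonds = topology.bonds
    if not bonds:
        raise ValueError("topology has no bonds")
    for t in bonds:
        if t.kind != "bond":
            raise ValueError(f"non-bond term in bonds list: {t.kind}")
    ii = np.asarray([t.beads[0] - 1 for t in bonds])
    jj = np.asarray([t.beads[1] - 1 for t in bonds])
    k = np.asarray([t.force_constant for t in bonds])
    r0 = np.asarray([t.eq_value for t in bonds])

    pi = traj.frames[:, ii, :]
    pj = traj.frames[:, jj, :]
    r = np.linalg.norm(pj - pi, axis=2)  # (n_frames, n_bonds)
    force = k[None, :] * np.abs(r - r0[None, :]) * C.PN_PER_KJ_MOL_NM
    zmid = 0.5 * (pi + pj) @ axis

    zf = zmid.ravel()
    ff = force.ravel()
    lo, hi = zf.min(), zf.max()
    if hi <= lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(zf, edges) - 1, 0, n_bins - 1)
    count = np.bincount(which, minlength=n_bins)
    s1 = np.bincount(which, weights=ff, minlength=n_bins)
    s2 = np.bincount(which, weights=ff**2, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, s1 / np.maximum(count, 1), np.nan)
        var = np.where(count > 0, s2 / np.maximum(count, 1) - mean**2, np.nan)
    spread = np.sqrt(np.clip(var, 0.0, None))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ForceProfile(centers, mean, count, spread)


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley with a deterministic spiral point lattice)
# ---------------------------------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point lattice."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def bead_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = C.DEFAULT_PROBE_RADIUS,
    n_points: int = 960,
) -> tuple:
    """Shrake-Rupley solvent-accessible surface area of a bead set.

    Each bead's accessible sphere (radius r_i + probe) is sampled on a
    fixed Fibonacci lattice of ``n_points`` points; points falling inside
    any neighbor's accessible sphere are buried. Returns
    ``(total_nm2, per_bead_nm2)``; deterministic for fixed ``n_points``.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float).ravel()
    if radii.size != coords.shape[0]:
        raise ValueError("one radius per bead required")
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    sphere = _fibonacci_sphere(n_points)
    acc = radii + probe
    tree = cKDTree(coords)
    per_bead = np.empty(coords.shape[0])
    max_acc = acc.max()
    for i in range(coords.shape[0]):
        pts = coords[i] + acc[i] * sphere
        neigh = [j for j in tree.query_ball_point(coords[i], acc[i] + max_acc) if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neigh:
            d = np.linalg.norm(pts - coords[j], axis=1)
            exposed &= d >= acc[j]
        per_bead[i] = 4.0 * math.pi * acc[i] ** 2 * exposed.mean()
    return float(per_bead.sum()), per_bead


def radii_for_beads(bead_types: list) -> np.ndarray:
    """Map Martini bead type labels to vdW radii by size prefix
    (T->tiny, S->small, otherwise regular)."""
    out = np.empty(len(bead_types))
    for k, t in enumerate(bead_types):
        if t.startswith("T"):
            out[k] = C.BEAD_RADIUS["tiny"]
        elif t.startswith("S"):
            out[k] = C.BEAD_RADIUS["small"]
        else:
            out[k] = C.BEAD_RADIUS["regular"]
    return out
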
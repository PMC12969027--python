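"""Atomistic-to-coarse-grained backbone mapping and bonded-term measurement.

One backbone (BB) bead per residue is placed at the unweighted center of
geometry of the residue's backbone atoms, preserving chain / triple-helix
identity. Bond lengths, angles and torsions between consecutive BB beads are
measured per frame; these samples feed the Boltzmann-inversion fitters.

Internal units: nm for coordinates, degrees for angles, ns for time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class MappingError(ValueError):
    """Raised when an atomistic structure cannot be mapped to beads."""


class InsertionCodeError(MappingError):
    """Raised on PDB insertion codes, which the mapper does not support."""


@dataclass
class ResidueRecord:
    """One residue of an atomistic chain.

    ``atoms`` is a list of ``(atom_name, xyz)`` pairs with coordinates in nm.
    """

    chain_id: str
    helix_id: str
    res_index: int
    res_name: str
    atoms: list

    def atom_names(self) -> list:
        return [name for name, _ in self.atoms]


@dataclass(frozen=True)
class Bead:
    label: str
    chain_id: str
    helix_id: str
    res_index: int
    res_name: str


@dataclass
class CGTrajectory:
    """Coarse-grained bead trajectory.

    frames: ``(n_frames, n_beads, 3)`` array of bead positions in nm.
    box: optional ``(n_frames, 3)`` orthorhombic box lengths in nm.
    time: optional ``(n_frames,)`` times in ns.
    """

    beads: list
    frames: np.ndarray
    box: np.ndarray | None = None
    time: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None, :, :]
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_beads, 3)")
        if self.frames.shape[1] != len(self.beads):
            raise ValueError(
                f"frame has {self.frames.shape[1]} coordinates for "
                f"{len(self.beads)} beads"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite bead coordinate")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.ndim == 1:
                self.box = np.tile(self.box, (self.n_frames, 1))
        if self.time is not None:
            self.time = np.asarray(self.time, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    def chain_ids(self) -> list:
        """Distinct chain ids in bead order of first appearance."""
        seen: dict = {}
        for b in self.beads:
            seen.setdefault(b.chain_id, None)
        return list(seen)

    def chain_indices(self, chain_id: str) -> np.ndarray:
        """Bead indices of one chain, ordered by residue index."""
        idx = [i for i, b in enumerate(self.beads) if b.chain_id == chain_id]
        idx.sort(key=lambda i: self.beads[i].res_index)
        return np.asarray(idx, dtype=int)

    def bead_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bead": [b.label for b in self.beads],
                "chain_id": [b.chain_id for b in self.beads],
                "helix_id": [b.helix_id for b in self.beads],
                "res_index": [b.res_index for b in self.beads],
                "res_name": [b.res_name for b in self.beads],
            }
        )


# ---------------------------------------------------------------------------
# Mapping
# ---------------------------------------------------------------------------

from .constants import DEFAULT_BACKBONE_ATOMS  # noqa: E402


def map_backbone(
    residues: Sequence[ResidueRecord],
    frames: np.ndarray | None = None,
    backbone_atom_names: Iterable[str] = DEFAULT_BACKBONE_ATOMS,
    box: np.ndarray | None = None,
    time: np.ndarray | None = None,
) -> CGTrajectory:
    """Map residues to one BB bead each by center-of-geometry.

    Parameters
    ----------
    residues:
        Residue records; their ``atoms`` define the atom order.
    frames:
        Optional ``(n_frames, n_atoms_total, 3)`` coordinates (nm) whose
        atom axis follows the concatenated residue atom order. When omitted
        the coordinates stored on the residues form a single frame.
    backbone_atom_names:
        Atom names entering the center of geometry (default N, CA, C, O).

    The bead position is the unweighted mean of the selected atoms, per
    frame, which makes the mapping exactly equivariant under rigid motion.
    """
    names = set(backbone_atom_names)
    if not names:
        raise MappingError("backbone_atom_names must not be empty")

    # flatten atom coordinates in residue order
    offsets = []
    n_atoms = 0
    for res in residues:
        if not res.atoms:
            raise MappingError(
                f"residue {res.chain_id}/{res.res_index} has no atoms"
            )
        offsets.append(n_atoms)
        n_atoms += len(res.atoms)

    if frames is None:
        coords = np.concatenate(
            [np.asarray([xyz for _, xyz in res.atoms], dtype=float) for res in residues]
        )
        frames = coords[None, :, :]
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None, :, :]
    if frames.shape[1] != n_atoms:
        raise MappingError(
            f"frames carry {frames.shape[1]} atoms, residues define {n_atoms}"
        )
    if not np.all(np.isfinite(frames)):
        raise MappingError("non-finite atomistic coordinate")

    beads = []
    bead_xyz = np.empty((frames.shape[0], len(residues), 3), dtype=float)
    for k, (res, off) in enumerate(zip(residues, offsets)):
        sel = [off + i for i, (name, _) in enumerate(res.atoms) if name in names]
        if not sel:
            raise MappingError(
                f"residue {res.chain_id}/{res.res_index} ({res.res_name}) has "
                f"no atom in the backbone selection {sorted(names)}"
            )
        bead_xyz[:, k, :] = frames[:, sel, :].mean(axis=1)
        beads.append(
            Bead(
                label="BB",
                chain_id=res.chain_id,
                helix_id=res.helix_id,
                res_index=res.res_index,
                res_name=res.res_name,
            )
        )
    return CGTrajectory(beads=beads, frames=bead_xyz, box=box, time=time)


# ---------------------------------------------------------------------------
# Bonded-term measurement
# ---------------------------------------------------------------------------

#: tuple span per term kind
_SPAN = {"bond": 2, "angle": 3, "dihedral": 4}

#: beads closer than this are treated as coincident (angle/torsion undefined)
_COINCIDENT_TOL = 1e-8


@dataclass
class BondedSamples:
    """Per-tuple samples of one bonded term kind.

    samples: ``(n_tuples, n_frames)`` — nm for bonds, degrees otherwise.
    first_res: residue name of the first bead of each tuple.
    excluded: diagnostics for frames dropped due to coincident beads.
    """

    kind: str
    tuples: list
    first_res: list
    samples: np.ndarray
    excluded: list = field(default_factory=list)

    def flat(self) -> np.ndarray:
        return self.samples[np.isfinite(self.samples)]


def _minimum_image(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return d
    return d - box[:, None, :] * np.round(d / box[:, None, :])


def measure_bonded(traj: CGTrajectory, term_kind: str) -> BondedSamples:
    """Measure bond / angle / dihedral samples for consecutive bead tuples.

    Tuples never span chain boundaries. Distances are in nm; angles are
    interior angles in [0, 180] deg; torsions are signed, right-handed
    (IUPAC), in (-180, 180] deg. With box vectors present, displacement
    vectors use the orthorhombic minimum-image convention.
    """
    if term_kind not in _SPAN:
        raise ValueError(f"unknown term kind {term_kind!r}")
    span = _SPAN[term_kind]

    tuples: list = []
    first_res: list = []
    for chain in traj.chain_ids():
        idx = traj.chain_indices(chain)
        for s in range(len(idx) - span + 1):
            tup = tuple(int(i) for i in idx[s : s + span])
            tuples.append(tup)
            first_res.append(traj.beads[tup[0]].res_name)

    n_t, n_f = len(tuples), traj.n_frames
    samples = np.full((n_t, n_f), np.nan)
    excluded: list = []
    if n_t == 0:
        return BondedSamples(term_kind, tuples, first_res, samples, excluded)

    tup_arr = np.asarray(tuples)  # (n_t, span)
    pos = traj.frames[:, tup_arr, :]  # (n_f, n_t, span, 3)
    diffs = np.diff(pos, axis=2)  # (n_f, n_t, span-1, 3)
    if traj.box is not None:
        for k in range(diffs.shape[2]):
            diffs[:, :, k, :] = _minimum_image(diffs[:, :, k, :], traj.box)

    if term_kind == "bond":
        samples = np.linalg.norm(diffs[:, :, 0, :], axis=-1).T
    elif term_kind == "angle":
        u = -diffs[:, :, 0, :]
        v = diffs[:, :, 1, :]
        nu = np.linalg.norm(u, axis=-1)
        nv = np.linalg.norm(v, axis=-1)
        bad = (nu < _COINCIDENT_TOL) | (nv < _COINCIDENT_TOL)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.einsum("fti,fti->ft", u, v) / (nu * nv)
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        ang[bad] = np.nan
        samples = ang.T
        _record_excluded(excluded, bad, tuples, term_kind)
    else:  # dihedral
        b1 = diffs[:, :, 0, :]
        b2 = diffs[:, :, 1, :]
        b3 = diffs[:, :, 2, :]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=-1)
        bad = (
            (np.linalg.norm(n1, axis=-1) < _COINCIDENT_TOL**0.5)
            | (np.linalg.norm(n2, axis=-1) < _COINCIDENT_TOL**0.5)
            | (nb2 < _COINCIDENT_TOL)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            x = np.einsum("fti,fti->ft", n1, n2)
            y = np.einsum("fti,fti->ft", np.cross(n1, n2), b2 / nb2[..., None])
        phi = np.degrees(np.arctan2(y, x))
        # map -180 -> +180 to keep the (-180, 180] convention
        phi[phi <= -180.0] += 360.0
        phi[bad] = np.nan
        samples = phi.T
        _record_excluded(excluded, bad, tuples, term_kind)

    return BondedSamples(term_kind, tuples, first_res, samples, excluded)


def _record_excluded(excluded, bad, tuples, kind) -> None:
    frames, tups = np.nonzero(bad)
    for f, t in zip(frames, tups):
        excluded.append({"kind": kind, "tuple": tuples[t], "frame": int(f)})


# ---------------------------------------------------------------------------
# PDB input / output (MDAnalysis-backed)
# ---------------------------------------------------------------------------

_A_TO_NM = 0.1


def read_pdb(
    path,
    helix_map: Mapping[str, str] | None = None,
    default_helix: str = "H1",
) -> tuple:
    """Read a (multi-model) PDB into residues + per-frame coordinates (nm).

    Models become trajectory frames. Alternate location 'A' (or blank) is
    kept; insertion codes are rejected. ``helix_map`` assigns chains to
    triple helices; by default every chain belongs to ``default_helix``.

    Returns ``(residues, frames, box)``.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))

    atoms = u.atoms
    if hasattr(atoms, "icodes") and any(str(c).strip() for c in atoms.icodes):
        raise InsertionCodeError(
            f"{path}: PDB insertion codes are not supported; renumber residues"
        )
    if hasattr(atoms, "altLocs"):
        keep = np.array([a in ("", " ", "A") for a in atoms.altLocs])
        atoms = atoms[keep]

    helix_map = dict(helix_map or {})
    residues: list = []
    flat_index: list = []
    for res in atoms.residues:
        chain = _chain_of(res)
        ratoms = res.atoms.intersection(atoms)
        residues.append(
            ResidueRecord(
                chain_id=chain,
                helix_id=helix_map.get(chain, default_helix),
                res_index=int(res.resid),
                res_name=str(res.resname).strip(),
                atoms=[
                    (str(a.name).strip(), a.position * _A_TO_NM) for a in ratoms
                ],
            )
        )
        flat_index.extend(a.index for a in ratoms)
    flat_index = np.asarray(flat_index, dtype=int)

    frames = np.empty((len(u.trajectory), len(flat_index), 3))
    boxes = []
    for i, _ts in enumerate(u.trajectory):
        frames[i] = u.atoms.positions[flat_index] * _A_TO_NM
        dims = u.dimensions
        boxes.append(dims[:3] * _A_TO_NM if dims is not None and dims[:3].any() else None)
    box = None
    if all(b is not None for b in boxes):
        box = np.asarray(boxes)
    return residues, frames, box


def _chain_of(res) -> str:
    for attr in ("chainID", "segid"):
        val = str(getattr(res.atoms[0], attr, "")).strip()
        if val:
            return val
    return "A"


def map_pdb(path, helix_map=None, backbone_atom_names=DEFAULT_BACKBONE_ATOMS) -> CGTrajectory:
    """Convenience wrapper: read a PDB and map it to BB beads."""
    residues, frames, box = read_pdb(path, helix_map=helix_map)
    return map_backbone(residues, frames, backbone_atom_names, box=box)


def write_cg_pdb(traj: CGTrajectory, path) -> None:
    """Serialize a CGTrajectory as a multi-model PDB of pseudo-atoms."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    n = traj.n_beads
    resindex = np.arange(n)
    u = mda.Universe.empty(
        n, n_residues=n, atom_resindex=resindex, residue_segindex=np.zeros(n, int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [b.label for b in traj.beads])
    u.add_TopologyAttr("resnames", [b.res_name for b in traj.beads])
    u.add_TopologyAttr("resids", [b.res_index for b in traj.beads])
    u.add_TopologyAttr("chainIDs", [b.chain_id[:1] or "A" for b in traj.beads])
    u.add_TopologyAttr("elements", [""] * n)
    u.load_new(traj.frames / _A_TO_NM, format=MemoryReader)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=n, multiframe=True) as w:
            for _ts in u.trajectory:
                w.write(u.atoms)


def read_cg_pdb(path, helix_map=None, default_helix: str = "H1") -> CGTrajectory:
    """Read a bead PDB (as written by :func:`write_cg_pdb`) back."""
    residues, frames, box = read_pdb(path, helix_map=helix_map, default_helix=default_helix)
    beads = []
    for res in residues:
        label = res.atoms[0][0] if res.atoms else "BB"
        beads.append(
            Bead(label, res.chain_id, res.helix_id, res.res_index, res.res_name)
        )
    bead_xyz = frames  # one pseudo-atom per residue
    return CGTrajectory(beads=beads, frames=bead_xyz, box=box)
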
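"""Shared fixtures: programmatic atomistic PDB generation and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from colcg.cg_mapping import ResidueRecord


def make_residues(n_res=6, chains=("A",), spacing=0.35, helix="H1"):
    """Straight-chain residues with 4 backbone atoms clustered per residue."""
    residues = []
    for ci, chain in enumerate(chains):
        for i in range(n_res):
            center = np.array([0.05 * ci, 0.0, i * spacing])
            atoms = [
                ("N", center + [0.01, 0.0, 0.0]),
                ("CA", center + [-0.01, 0.0, 0.0]),
                ("C", center + [0.0, 0.01, 0.0]),
                ("O", center + [0.0, -0.01, 0.0]),
                ("CB", center + [0.1, 0.1, 0.0]),  # side-chain, ignored
            ]
            residues.append(
                ResidueRecord(
                    chain_id=chain, helix_id=helix, res_index=i + 1,
                    res_name=["GLY", "PRO", "HYP"][i % 3], atoms=atoms,
                )
            )
    return residues


def write_atomistic_pdb(path, n_res=4, n_models=2, icode=None, scale=1.0):
    """Tiny multi-model PDB written record-by-record (test input only)."""
    lines = []
    for model in range(1, n_models + 1):
        lines.append(f"MODEL     {model:4d}")
        serial = 1
        for i in range(n_res):
            resname = ["GLY", "PRO", "HYP"][i % 3]
            ic = icode if (icode and i == 1) else " "
            for j, name in enumerate(["N", "CA", "C", "O"]):
                x = (1.0 + 0.1 * j) * scale * model
                y = 2.0
                z = 3.5 * (i + 1)
                lines.append(
                    f"ATOM  {serial:5d} {name:^4s}{'':1s}{resname:3s} A"
                    f"{i + 1:4d}{ic}   {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                    f"          {name[0]:>2s}"
                )
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def atomistic_pdb(tmp_path):
    return write_atomistic_pdb(tmp_path / "tiny.pdb")


def random_rotation(rng) -> np.ndarray:
    """Haar-ish random rotation matrix via QR."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
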
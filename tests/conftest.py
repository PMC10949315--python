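"""Shared fixtures and text-fixture builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniform-ish random proper rotation via QR decomposition."""
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


def write_pdb(path, chain_residues: dict[str, list], serial_start: int = 1) -> None:
    """Write a minimal PDB file of Calpha records.

    ``chain_residues`` maps chain id -> list of entries
    ``(resnum, resname, (x, y, z))`` or ``(resnum, resname, (x, y, z),
    altloc, occupancy)``.
    """
    lines = []
    serial = serial_start
    for chain, residues in chain_residues.items():
        for entry in residues:
            num, resname, xyz = entry[:3]
            altloc = entry[3] if len(entry) > 3 else " "
            occ = entry[4] if len(entry) > 4 else 1.0
            x, y, z = xyz
            lines.append(
                f"ATOM  {serial:5d}  CA {altloc}{resname:>3s} {chain}{num:4d}"
                f"    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
                f"          {'C':>2s}"
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
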
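"""Shared fixtures: tiny hand-written PDB files and reusable ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from flexconcord import Ensemble, gaussian_chain, hinge_two_domain


def pdb_atom_line(
    serial: int,
    name: str,
    chain: str,
    resseq: int,
    xyz,
    b: float = 0.0,
    element: str = None,
    resname: str = "ALA",
    icode: str = " ",
) -> str:
    """One fixed-width PDB ATOM record."""
    if element is None:
        element = name[0]
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} {chain:1s}{resseq:4d}"
        f"{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}"
        f"          {element:>2s}"
    )


def write_pdb(path, lines) -> str:
    path.write_text("\n".join(lines) + "\nEND\n")
    return str(path)


@pytest.fixture
def three_residue_model(tmp_path):
    """3-residue single-chain model with CA B-factors 90 / 50 / 30."""
    lines = []
    serial = 1
    for i, b in enumerate((90.0, 50.0, 30.0)):
        for name, offset in (("N", 0.0), ("CA", 1.0), ("C", 2.0)):
            lines.append(
                pdb_atom_line(serial, name, "A", i + 1, (4.0 * i + offset, 0.5 * serial, 0.0), b=b)
            )
            serial += 1
    return write_pdb(tmp_path / "model.pdb", lines)


@pytest.fixture
def two_chain_model(tmp_path):
    lines = []
    serial = 1
    for chain, n_res in (("A", 2), ("B", 2)):
        for i in range(n_res):
            lines.append(
                pdb_atom_line(serial, "CA", chain, i + 1, (serial * 2.0, serial % 3, 1.0), b=70.0 + serial)
            )
            serial += 1
    return write_pdb(tmp_path / "dimer.pdb", lines)


def make_ca_ensemble(coords: np.ndarray) -> Ensemble:
    """CA-only ensemble from an (F, R, 3) coordinate array."""
    n_res = coords.shape[1]
    return Ensemble(
        coords=np.asarray(coords, dtype=float),
        atom_names=np.full(n_res, "CA"),
        atom_residue_index=np.arange(n_res),
        elements=np.full(n_res, "C"),
        masses=np.full(n_res, 12.011),
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture(scope="session")
def hinge_system():
    """Shared hinge ensemble at the study conditions (moderate size)."""
    ens, truth, partition = hinge_two_domain(
        domain_sizes=(40, 40), linker_length=6, hinge_angle_std=15.0,
        n_frames=800, seed=11,
    )
    return ens, truth, partition


@pytest.fixture(scope="session")
def gaussian_system():
    sigma = np.linspace(0.2, 2.0, 60)
    ens, truth = gaussian_chain(sigma, 2000, seed=5)
    return ens, truth
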
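"""Synthetic conformational ensembles with known flexibility ground truth.

Three generators emulate the regimes the analysis distinguishes:

* ``gaussian_chain`` — an extended CA trace where residue i fluctuates
  isotropically with per-coordinate standard deviation sigma_i; its exact
  expected RMSF is sigma_i * sqrt(3).
* ``hinge_two_domain`` — two internally rigid compact CA bodies joined by a
  linker; each frame rotates the linker+second domain about a pivot by an
  angle drawn from Normal(0, hinge_angle_std). The interdomain
  centre-of-mass distance has a closed form in the sampled angle.
* ``disordered_chain`` — an ideal freely-jointed chain redrawn independently
  every frame (fixed 3.8 A virtual bonds), the fully disordered extreme.

Two emulators couple AlphaFold2-style confidence outputs to that ground
truth: ``emulate_plddt`` produces a pLDDT profile with a prescribed expected
anticorrelation to the flexibility profile, and ``pae_emulator`` produces an
(asymmetric) PAE matrix as a noisy affine image of a DV matrix.

Frames are statistically independent — there is no autocorrelation, unlike
real MD — and geometry is CA-only with uniform carbon masses. Every
generator is bitwise reproducible under a fixed seed (one
``numpy.random.default_rng`` per call; no global state).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .dynamics import DistanceVariationMatrix
from .ensemble import DomainPartition, Ensemble
from .io import PAEMatrix

#: Virtual CA-CA bond length (Angstrom) of an extended polypeptide trace.
CA_SPACING = 3.8

_CA_MASS = 12.011


def _ca_ensemble(coords: np.ndarray) -> Ensemble:
    n_res = coords.shape[1]
    return Ensemble(
        coords=coords,
        atom_names=np.full(n_res, "CA"),
        atom_residue_index=np.arange(n_res),
        elements=np.full(n_res, "C"),
        masses=np.full(n_res, _CA_MASS),
    )


def extended_trace(n_residues: int, spacing: float = CA_SPACING) -> np.ndarray:
    """Extended zigzag CA trace with exact consecutive spacing.

    A strictly straight line would be collinear and make least-squares
    superposition degenerate, so successive virtual bonds alternate by
    +/-20 degrees in the xy plane.
    """
    angle = np.deg2rad(20.0)
    signs = np.where(np.arange(n_residues - 1) % 2 == 0, 1.0, -1.0)
    steps = np.stack(
        [
            np.full(n_residues - 1, spacing * np.cos(angle)),
            spacing * np.sin(angle) * signs,
            np.zeros(n_residues - 1),
        ],
        axis=1,
    )
    coords = np.zeros((n_residues, 3))
    coords[1:] = np.cumsum(steps, axis=0)
    return coords


def _compact_domain(
    n_residues: int, start_x: float = 0.0, nx: int = 4, ny: int = 4
) -> np.ndarray:
    """Compact serpentine CA block with exact 3.8 A consecutive spacing.

    The chain snakes through an nx x ny x nz grid, producing a globular body
    whose rotational fit is well conditioned about every axis. (A thin
    straight or helical rod is nearly degenerate under rotation about its
    long axis, which lets a least-squares superposition spin frames almost
    freely about that axis and contaminate downstream mode analyses.)
    """
    pos = np.zeros((n_residues, 3))
    for k in range(n_residues):
        layer, rem = divmod(k, nx * ny)
        row, col = divmod(rem, nx)
        if row % 2:
            col = nx - 1 - col
        if layer % 2:
            row = ny - 1 - row
        pos[k] = (start_x + CA_SPACING * col, CA_SPACING * row, CA_SPACING * layer)
    return pos


def gaussian_chain(
    sigma_profile, n_frames: int, seed: int
) -> Tuple[Ensemble, dict]:
    """Extended chain with independent isotropic Gaussian fluctuations.

    ``truth`` records the per-residue sigma and the exact expected RMSF
    ``sigma * sqrt(3)`` (the root of the summed per-coordinate variances).
    """
    sigma = np.asarray(sigma_profile, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma profile must be non-negative")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    mean = extended_trace(len(sigma))
    noise = rng.standard_normal((n_frames, len(sigma), 3)) * sigma[None, :, None]
    truth = {
        "kind": "gaussian_chain",
        "sigma": sigma,
        "expected_rmsf": sigma * np.sqrt(3.0),
        "seed": int(seed),
    }
    return _ca_ensemble(mean[None] + noise), truth


def hinge_two_domain(
    domain_sizes: Tuple[int, int] = (60, 60),
    linker_length: int = 8,
    hinge_angle_std: float = 15.0,
    n_frames: int = 5000,
    seed: int = 0,
) -> Tuple[Ensemble, dict, DomainPartition]:
    """Two internally rigid compact domains with Gaussian hinge rotations.

    Per frame, the linker and second domain rotate rigidly about the first
    linker residue's CA, around the z axis, by an angle drawn from
    ``Normal(0, hinge_angle_std)`` (degrees). The truth dict records the
    sampled angles and the law-of-cosines closed form of the interdomain
    centre-of-mass distance.
    """
    n1, n2 = (int(s) for s in domain_sizes)
    if n1 < 3 or n2 < 3:
        raise ValueError("each domain needs at least 3 residues")
    if hinge_angle_std < 0:
        raise ValueError("hinge_angle_std must be non-negative")
    lnk = int(linker_length)
    rng = np.random.default_rng(seed)

    dom1 = _compact_domain(n1)
    gap_start = dom1[:, 0].max() + CA_SPACING
    linker = np.stack(
        [
            gap_start + CA_SPACING * np.arange(lnk),
            np.zeros(lnk),
            np.zeros(lnk),
        ],
        axis=1,
    )
    dom2_start = (linker[-1, 0] if lnk else gap_start) + CA_SPACING
    dom2 = _compact_domain(n2, start_x=dom2_start)
    base = np.concatenate([dom1, linker, dom2], axis=0)
    n_res = base.shape[0]

    pivot = base[n1].copy() if lnk else base[n1 - 1].copy()
    axis = np.array([0.0, 0.0, 1.0])
    angles = np.deg2rad(rng.normal(0.0, hinge_angle_std, size=n_frames))

    moving = np.arange(n1, n_res)
    rel = base[moving] - pivot
    cos, sin = np.cos(angles), np.sin(angles)
    # Rodrigues about z: (x, y, z) -> (x cos - y sin, x sin + y cos, z)
    rotated = np.empty((n_frames, len(moving), 3))
    rotated[..., 0] = cos[:, None] * rel[None, :, 0] - sin[:, None] * rel[None, :, 1]
    rotated[..., 1] = sin[:, None] * rel[None, :, 0] + cos[:, None] * rel[None, :, 1]
    rotated[..., 2] = rel[None, :, 2]
    coords = np.repeat(base[None], n_frames, axis=0)
    coords[:, moving, :] = rotated + pivot

    partition = DomainPartition(
        segments=(
            ("domain1", (0, n1)),
            ("domain2", (n1 + lnk, n_res)),
        ),
        linkers=((n1, n1 + lnk),) if lnk else (),
    )

    com1 = dom1.mean(axis=0)
    com2 = dom2.mean(axis=0)
    u = com1 - pivot
    v = com2 - pivot
    # closed form |u - R(theta) v| for rotation about z
    rv = np.empty((n_frames, 3))
    rv[:, 0] = cos * v[0] - sin * v[1]
    rv[:, 1] = sin * v[0] + cos * v[1]
    rv[:, 2] = v[2]
    com_distance = np.linalg.norm(u[None] - rv, axis=1)

    truth = {
        "kind": "hinge_two_domain",
        "angles_rad": angles,
        "axis": axis,
        "pivot": pivot,
        "com_domain1": com1,
        "com_domain2_initial": com2,
        "com_distance": com_distance,
        "hinge_angle_std_deg": float(hinge_angle_std),
        "seed": int(seed),
    }
    return _ca_ensemble(coords), truth, partition


def disordered_chain(
    n_residues: int,
    n_frames: int,
    seed: int,
    bond_length: float = CA_SPACING,
) -> Tuple[Ensemble, dict]:
    """Freely-jointed chain redrawn independently every frame.

    Adjacent CA-CA distances are exactly ``bond_length`` in every frame, so
    DV[i][i+1] = 0 by construction; the disorder signature therefore lives
    at sequence separations >= 2.
    """
    if bond_length <= 0:
        raise ValueError("bond_length must be positive")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_frames, n_residues - 1, 3))
    steps /= np.linalg.norm(steps, axis=2, keepdims=True)
    steps *= bond_length
    coords = np.zeros((n_frames, n_residues, 3))
    coords[:, 1:, :] = np.cumsum(steps, axis=1)
    truth = {
        "kind": "disordered_chain",
        "disordered": np.ones(n_residues, dtype=bool),
        "bond_length": float(bond_length),
        "seed": int(seed),
    }
    return _ca_ensemble(coords), truth


def emulate_plddt(
    sigma,
    coupling: float = 0.9,
    noise_std: float = 5.0,
    seed: int = 0,
    baseline: float = 60.0,
) -> Tuple[np.ndarray, dict]:
    """pLDDT profile with a prescribed expected anticorrelation to sigma.

    The gain ``a`` in ``pLDDT_i = clip(baseline - a*(sigma_i - mean) + eps_i,
    0, 100)`` is solved so that the population correlation with sigma equals
    ``-coupling``:  a = coupling * noise_std / (sd(sigma) * sqrt(1 -
    coupling^2)). The baseline keeps the profile away from the clip bounds
    at the default noise level.
    """
    sigma = np.asarray(sigma, dtype=float)
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [0, 1]")
    if noise_std < 0:
        raise ValueError("noise_std must be non-negative")
    sd = float(sigma.std())
    if coupling == 0.0:
        gain = 0.0
    elif coupling == 1.0:
        if noise_std != 0:
            raise ValueError("coupling 1 requires noise_std 0")
        gain = 15.0 / sd if sd > 0 else 0.0
    else:
        if noise_std == 0:
            raise ValueError(
                "0 < coupling < 1 requires noise_std > 0 "
                "(a noiseless affine map has |correlation| = 1)"
            )
        if sd == 0:
            raise ValueError("sigma profile is constant; coupling undefined")
        gain = coupling * noise_std / (sd * np.sqrt(1.0 - coupling**2))
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_std, size=sigma.shape) if noise_std > 0 else 0.0
    plddt = np.clip(baseline - gain * (sigma - sigma.mean()) + eps, 0.0, 100.0)
    truth = {
        "target_correlation": -float(coupling),
        "gain": float(gain),
        "baseline": float(baseline),
        "noise_std": float(noise_std),
        "seed": int(seed),
    }
    return plddt, truth


def pae_emulator(
    dv: DistanceVariationMatrix,
    gain: float = 1.75,
    offset: float = 0.25,
    noise_std: float = 1.0,
    max_pae: float = 31.75,
    seed: int = 0,
) -> Tuple[PAEMatrix, dict]:
    """PAE matrix as a noisy affine image of a DV matrix.

    Independent noise per ordered pair makes the matrix asymmetric, like a
    real PAE. The truth dict records the expected correlation between the
    transpose-pair-symmetrised PAE and DV upper triangles (noise variance
    halves under symmetrisation), ignoring clipping.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    if max_pae <= offset:
        raise ValueError("max_pae must exceed offset")
    rng = np.random.default_rng(seed)
    d = dv.values
    eps = rng.normal(0.0, noise_std, size=d.shape) if noise_std > 0 else np.zeros_like(d)
    values = np.clip(gain * d + offset + eps, 0.0, max_pae)
    iu = np.triu_indices(d.shape[0], k=1)
    sd_dv = float(d[iu].std())
    signal = gain * sd_dv
    expected_pcc = (
        signal / np.sqrt(signal**2 + noise_std**2 / 2.0) if signal > 0 else 0.0
    )
    truth = {
        "expected_pcc": float(expected_pcc),
        "gain": float(gain),
        "offset": float(offset),
        "noise_std": float(noise_std),
        "seed": int(seed),
    }
    return PAEMatrix(values=values, max_pae=float(max_pae)), truth


@dataclass
class GeneratorSpec:
    """Declarative description of one synthetic system (used by the CLI)."""

    kind: str
    n_residues: int = 100
    n_frames: int = 2000
    seed: int = 0
    params: dict = field(default_factory=dict)

    def generate(self):
        """Returns ``(ensemble, truth, partition_or_None)``."""
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.kind == "gaussian_chain":
            sigma = self.params.get("sigma_profile")
            if sigma is None:
                sigma = np.linspace(0.2, 2.0, self.n_residues)
            ens, truth = gaussian_chain(sigma, self.n_frames, self.seed)
            return ens, truth, None
        if self.kind == "hinge_two_domain":
            n1 = self.params.get("domain_sizes", (60, 60))
            ens, truth, part = hinge_two_domain(
                domain_sizes=tuple(n1),
                linker_length=self.params.get("linker_length", 8),
                hinge_angle_std=self.params.get("hinge_angle_std", 15.0),
                n_frames=self.n_frames,
                seed=self.seed,
            )
            return ens, truth, part
        if self.kind == "disordered_chain":
            ens, truth = disordered_chain(
                self.n_residues,
                self.n_frames,
                self.seed,
                bond_length=self.params.get("bond_length", CA_SPACING),
            )
            return ens, truth, None
        raise ValueError(f"unknown generator kind {self.kind!r}")
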
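"""Ensemble statistics: distance variation, cross-correlation, PCA.

The distance-variation (DV) matrix is the robust, superposition-free
flexibility statistic at the core of this package: entry (x, y) is the
interquartile range, over frames, of the CA-CA distance between residues
x and y. Because inter-atomic distances are invariant under rigid motion,
DV needs no superposition and is symmetric with a zero diagonal — a
one-dimensional analogue of AlphaFold2's predicted aligned error map.

The IQR is deliberately used instead of the range or variance to damp the
influence of rare extreme separations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ensemble import Ensemble, select_calpha
from .superposition import _iterative_mean_fit

#: Quantile rule used throughout: linear interpolation between order
#: statistics with p(k) = (k-1)/(n-1), the common statistical-software
#: default.
QUANTILE_METHOD = "linear"


def iqr(samples) -> float:
    """Interquartile range Q3 - Q1 with linear-interpolation quantiles."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("IQR of an empty sample is undefined")
    q1, q3 = np.percentile(x, [25.0, 75.0], method=QUANTILE_METHOD)
    return float(q3 - q1)


@dataclass
class DistanceVariationMatrix:
    """Symmetric R x R matrix of per-pair CA-CA distance IQRs (Angstrom)."""

    values: np.ndarray
    quantile_method: str = QUANTILE_METHOD

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"DV matrix must be square, got {v.shape}")
        if not np.array_equal(v, v.T):
            raise ValueError("DV matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("DV diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("DV entries must be non-negative")

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]


@dataclass
class DCCM:
    """Dynamic cross-correlation matrix, entries in [-1, 1], unit diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"DCCM must be square, got {v.shape}")
        if np.any(np.abs(v) > 1 + 1e-9):
            raise ValueError("DCCM entries must lie in [-1, 1]")


@dataclass
class PCAResult:
    """Mass-weighted principal components of an ensemble.

    ``modes`` columns are orthonormal directions in the 3A'-dimensional
    mass-weighted coordinate space (coordinates scaled by sqrt(mass));
    eigenvalues are in Angstrom^2 * amu and sorted descending.
    """

    eigenvalues: np.ndarray
    modes: np.ndarray             # (3A', n_modes)
    projections: np.ndarray       # (F, n_modes)
    variance_fraction: np.ndarray
    mean_coords: np.ndarray       # (A', 3) unweighted mean structure
    atom_indices: np.ndarray      # indices into the source ensemble
    masses: np.ndarray            # (A',)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be sorted descending")


def dv_matrix(ens: Ensemble, block_size: int = 16) -> DistanceVariationMatrix:
    """Distance-variation matrix over all frames of the CA selection.

    Distances are computed in residue blocks so the F x R x R distance
    tensor is never fully materialised for long trajectories.
    """
    if ens.n_frames < 2:
        raise ValueError("DV needs at least 2 frames")
    ca = select_calpha(ens)
    x = ca.coords  # (F, R, 3)
    n = ca.residue_count
    out = np.zeros((n, n))
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        # (F, b, R) distances for this block of rows
        diff = x[:, start:stop, None, :] - x[:, None, :, :]
        dist = np.sqrt(np.sum(diff**2, axis=3))
        q1, q3 = np.percentile(dist, [25.0, 75.0], axis=0, method=QUANTILE_METHOD)
        out[start:stop, :] = q3 - q1
    out = 0.5 * (out + out.T)  # symmetric up to float noise; make it exact
    np.fill_diagonal(out, 0.0)
    np.clip(out, 0.0, None, out=out)
    return DistanceVariationMatrix(values=out)


def dccm(ens: Ensemble, superpose: bool = True) -> DCCM:
    """Dynamic cross-correlation of CA positional deviations.

    Frames are superposed with the global (all-atom protocol) fit first, so
    common rigid motion does not masquerade as correlation. Normalisation is
    the scalar dot-product convention:
    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>).
    Residues with zero positional variance yield undefined correlations;
    their entries are set to 0 with a warning.
    """
    if ens.n_frames < 2:
        raise ValueError("DCCM needs at least 2 frames")
    ca = select_calpha(ens)
    coords = ca.coords
    if superpose:
        coords = _iterative_mean_fit(coords, np.arange(ca.n_atoms))
    dev = coords - coords.mean(axis=0)
    inner = np.einsum("fai,fbi->ab", dev, dev) / ens.n_frames
    var = np.diag(inner).copy()
    zero = var <= 1e-12
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} residue(s) have zero positional variance; "
            "their DCCM entries are set to 0"
        )
    denom = np.sqrt(np.outer(np.where(zero, 1.0, var), np.where(zero, 1.0, var)))
    values = inner / denom
    values[zero, :] = 0.0
    values[:, zero] = 0.0
    values = 0.5 * (values + values.T)
    np.clip(values, -1.0, 1.0, out=values)
    nz = np.nonzero(~zero)[0]
    values[nz, nz] = 1.0
    return DCCM(values=values)


def pca(
    ens: Ensemble,
    atom_subset=None,
    superpose: bool = True,
    include_hydrogens: bool = False,
) -> PCAResult:
    """Mass-weighted PCA of the coordinate covariance.

    Each Cartesian coordinate is scaled by sqrt(mass) before the covariance
    (1/(F-1) normalisation) is diagonalised, so eigenvalues carry units of
    Angstrom^2 * amu and their sum equals the total mass-weighted variance.
    Hydrogens are excluded by default (heavy-atom analysis).
    """
    if ens.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    if atom_subset is None:
        atom_subset = np.arange(ens.n_atoms)
    atom_subset = np.asarray(atom_subset, dtype=int)
    if not include_hydrogens:
        atom_subset = atom_subset[ens.elements[atom_subset] != "H"]
    coords = ens.coords
    if superpose:
        coords = _iterative_mean_fit(coords, ens.ca_indices)
    sub = coords[:, atom_subset, :]
    masses = ens.masses[atom_subset]
    f, a, _ = sub.shape
    weighted = sub * np.sqrt(masses)[None, :, None]
    flat = weighted.reshape(f, 3 * a)
    mean = flat.mean(axis=0)
    centered = flat - mean
    cov = centered.T @ centered / (f - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    frac = evals / total if total > 0 else np.zeros_like(evals)
    return PCAResult(
        eigenvalues=evals,
        modes=evecs,
        projections=centered @ evecs,
        variance_fraction=frac,
        mean_coords=sub.mean(axis=0),
        atom_indices=atom_subset,
        masses=masses,
    )


def pc_animation(
    res: PCAResult,
    ens: Ensemble,
    mode: int = 0,
    n_steps: int = 21,
    amplitude: float = 1.0,
) -> Ensemble:
    """Interpolated ensemble sweeping ``mean - A*mode .. mean + A*mode``.

    The mode is mapped back to unweighted Cartesian displacements (divide by
    sqrt(mass)); ``amplitude`` is the extreme displacement along the mode in
    mass-weighted units. The result is writable as a multi-model PDB.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if not 0 <= mode < res.modes.shape[1]:
        raise IndexError(f"mode {mode} out of range")
    direction = res.modes[:, mode].reshape(-1, 3) / np.sqrt(res.masses)[:, None]
    scales = np.linspace(-amplitude, amplitude, n_steps)
    frames = res.mean_coords[None] + scales[:, None, None] * direction[None]
    idx = res.atom_indices
    return Ensemble(
        coords=frames,
        atom_names=ens.atom_names[idx],
        atom_residue_index=_reindex(ens.atom_residue_index[idx]),
        elements=ens.elements[idx],
        masses=ens.masses[idx],
        residue_labels=ens.residue_labels[
            np.unique(ens.atom_residue_index[idx])
        ],
    )


def _reindex(residue_index: np.ndarray) -> np.ndarray:
    """Compress residue indices to 0..R-1 preserving order."""
    uniq = np.unique(residue_index)
    mapping = {int(v): i for i, v in enumerate(uniq)}
    return np.array([mapping[int(v)] for v in residue_index], dtype=int)
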
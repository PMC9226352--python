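"""Conformational ensembles (multi-model PDB stand-ins for MD trajectories).

An :class:`Ensemble` is a fixed atom table observed over F frames. It is the
input to every trajectory statistic in this package (RMSF, distance-variation
matrices, cross-correlations, PCA). Real MD trajectories in binary formats can
be adapted to the same contract externally; the required on-disk format here is
multi-model PDB, which keeps fixtures plain text.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb


class EnsembleFormatError(ValueError):
    """Raised when a multi-model file violates the shared-atom-table contract."""


#: Standard atomic masses (amu) for the elements that occur in protein
#: heavy-atom / hydrogen records.
ATOMIC_MASSES = {
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "H": 1.008,
    "P": 30.974,
    "SE": 78.971,
}

_DEFAULT_MASS = 12.011


def _element_masses(elements: np.ndarray) -> np.ndarray:
    masses = np.empty(len(elements), dtype=float)
    unknown = set()
    for i, el in enumerate(elements):
        key = str(el).upper()
        if key in ATOMIC_MASSES:
            masses[i] = ATOMIC_MASSES[key]
        else:
            masses[i] = _DEFAULT_MASS
            unknown.add(key)
    if unknown:
        warnings.warn(
            f"unknown element(s) {sorted(unknown)}: assigned carbon mass "
            f"{_DEFAULT_MASS} amu"
        )
    return masses


@dataclass
class Ensemble:
    """F frames of an identical atom table.

    Attributes
    ----------
    coords:
        ``(F, A, 3)`` float array of coordinates in Angstrom.
    atom_names:
        ``(A,)`` PDB atom names (e.g. ``"CA"``).
    atom_residue_index:
        ``(A,)`` 0-based contiguous residue index per atom.
    elements:
        ``(A,)`` element symbols.
    masses:
        ``(A,)`` atomic masses in amu, strictly positive.
    residue_labels:
        ``(R,)`` human-readable residue labels (chain + original resSeq).
    """

    coords: np.ndarray
    atom_names: np.ndarray
    atom_residue_index: np.ndarray
    elements: np.ndarray
    masses: np.ndarray
    residue_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise EnsembleFormatError(
                f"coords must have shape (F, A, 3), got {self.coords.shape}"
            )
        if self.n_frames < 1:
            raise EnsembleFormatError("an ensemble needs at least one frame")
        self.atom_names = np.asarray(self.atom_names, dtype="U6")
        self.atom_residue_index = np.asarray(self.atom_residue_index, dtype=int)
        self.elements = np.asarray(self.elements, dtype="U2")
        self.masses = np.asarray(self.masses, dtype=float)
        a = self.coords.shape[1]
        for name, arr in (
            ("atom_names", self.atom_names),
            ("atom_residue_index", self.atom_residue_index),
            ("elements", self.elements),
            ("masses", self.masses),
        ):
            if arr.shape != (a,):
                raise EnsembleFormatError(f"{name} must have length {a}")
        if np.any(self.masses <= 0):
            raise EnsembleFormatError("masses must be strictly positive")
        if self.residue_labels is None:
            self.residue_labels = np.array(
                [str(i + 1) for i in range(self.residue_count)], dtype=object
            )
        self.residue_labels = np.asarray(self.residue_labels, dtype=object)
        if self.residue_labels.shape != (self.residue_count,):
            raise EnsembleFormatError(
                "residue_labels must have one entry per residue"
            )
        # every residue owns exactly one CA
        ca_res = self.atom_residue_index[self.atom_names == "CA"]
        counts = np.bincount(ca_res, minlength=self.residue_count)
        bad = np.nonzero(counts != 1)[0]
        if bad.size:
            raise EnsembleFormatError(
                f"residue index {bad[0]} has {counts[bad[0]]} CA atoms "
                "(exactly one required)"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def residue_count(self) -> int:
        return int(self.atom_residue_index.max()) + 1 if self.n_atoms else 0

    @property
    def ca_indices(self) -> np.ndarray:
        """Indices of the CA atom of each residue, in residue order."""
        idx = np.nonzero(self.atom_names == "CA")[0]
        order = np.argsort(self.atom_residue_index[idx], kind="stable")
        return idx[order]


@dataclass(frozen=True)
class DomainPartition:
    """Labelled residue segments plus linker regions between them.

    ``segments`` are ``(label, (start, stop))`` with half-open, 0-based
    residue ranges, sorted and non-overlapping. ``linkers`` are ranges
    flanked by two segments; their per-residue RMSF is averaged over the
    flanking segments' superpositions. Residues covered by neither belong
    to the nearest segment for superposition purposes.
    """

    segments: tuple
    linkers: tuple = ()

    def __post_init__(self) -> None:
        segs = tuple((str(lbl), (int(a), int(b))) for lbl, (a, b) in self.segments)
        links = tuple((int(a), int(b)) for a, b in self.linkers)
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "linkers", links)
        prev_stop = None
        for lbl, (a, b) in segs:
            if b <= a:
                raise ValueError(f"segment {lbl!r} has empty range ({a}, {b})")
            if prev_stop is not None and a < prev_stop:
                raise ValueError("segments must be sorted and non-overlapping")
            prev_stop = b
        covered = set()
        for _, (a, b) in segs:
            covered.update(range(a, b))
        for a, b in links:
            if b <= a:
                raise ValueError(f"linker range ({a}, {b}) is empty")
            if covered.intersection(range(a, b)):
                raise ValueError("linkers must be disjoint from segments")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segment_residues(self, i: int, n_residues: int) -> np.ndarray:
        """Residues assigned to segment ``i`` under the nearest-segment rule.

        Residues inside a declared linker are excluded (they are handled by
        linker averaging); all other uncovered residues join the segment whose
        boundary is nearest, termini joining the adjacent segment.
        """
        assign = self.assignment(n_residues)
        return np.nonzero(assign == i)[0]

    def assignment(self, n_residues: int) -> np.ndarray:
        """Per-residue segment index; -1 marks declared linker residues."""
        assign = np.full(n_residues, -1, dtype=int)
        for k, (_, (a, b)) in enumerate(self.segments):
            assign[a:b] = k
        in_linker = np.zeros(n_residues, dtype=bool)
        for a, b in self.linkers:
            in_linker[a:b] = True
        for r in range(n_residues):
            if assign[r] >= 0 or in_linker[r]:
                continue
            best, best_d = 0, None
            for k, (_, (a, b)) in enumerate(self.segments):
                d = a - r if r < a else (r - b + 1 if r >= b else 0)
                if best_d is None or d < best_d:
                    best, best_d = k, d
            assign[r] = best
        return assign

    def flanking_segments(self, linker: tuple) -> tuple:
        """Indices of the two segments flanking a linker range."""
        a, b = linker
        left = right = None
        for k, (_, (sa, sb)) in enumerate(self.segments):
            if sb <= a:
                left = k
            if sa >= b and right is None:
                right = k
        if left is None or right is None:
            raise ValueError(
                f"linker ({a}, {b}) is not flanked by two segments"
            )
        return left, right


def _stack_to_ensemble(stack: struc.AtomArrayStack) -> Ensemble:
    # residue identity = (chain, resSeq, icode) in file order
    keys = list(
        zip(stack.chain_id, stack.res_id, getattr(stack, "ins_code", [""] * stack.array_length()))
    )
    res_index = np.empty(len(keys), dtype=int)
    labels = []
    seen: dict = {}
    for i, key in enumerate(keys):
        if key not in seen:
            seen[key] = len(seen)
            chain, res_id, icode = key
            labels.append(f"{chain}:{res_id}{icode}".strip())
        res_index[i] = seen[key]
    coords = stack.coord
    if coords.ndim == 2:  # single model
        coords = coords[None, :, :]
    return Ensemble(
        coords=np.asarray(coords, dtype=float),
        atom_names=np.asarray(stack.atom_name),
        atom_residue_index=res_index,
        elements=np.asarray(stack.element),
        masses=_element_masses(np.asarray(stack.element)),
        residue_labels=np.asarray(labels, dtype=object),
    )


def read_multimodel_pdb(path) -> Ensemble:
    """Read a multi-model PDB file into an :class:`Ensemble`.

    Each MODEL/ENDMDL block is one frame; a file without MODEL records is a
    single-frame ensemble. All models must share the same atom table. The
    first altLoc of each atom is kept.
    """
    pdb_file = pdb.PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure(model=None, altloc="first")
    except Exception as exc:  # biotite raises on inconsistent models
        raise EnsembleFormatError(
            f"could not read {path} as a multi-model PDB: {exc}"
        ) from exc
    return _stack_to_ensemble(stack)


def write_multimodel_pdb(ens: Ensemble, path, b_factors=None) -> None:
    """Write an ensemble as a multi-model PDB (one MODEL block per frame).

    ``b_factors`` (per-atom, optional) fills the B-factor column — used to
    store per-residue confidence scores the way AlphaFold2 model files do.
    """
    n_res = ens.residue_count
    res_ids = np.empty(n_res, dtype=int)
    chain_ids = np.empty(n_res, dtype="U4")
    for r, label in enumerate(ens.residue_labels):
        label = str(label)
        if ":" in label:
            chain, num = label.split(":", 1)
            num = "".join(ch for ch in num if ch.isdigit() or ch == "-") or str(r + 1)
        else:
            chain, num = "A", label if label.lstrip("-").isdigit() else str(r + 1)
        chain_ids[r] = chain or "A"
        res_ids[r] = int(num)
    atoms = struc.AtomArray(ens.n_atoms)
    atoms.coord = ens.coords[0]
    atoms.atom_name = ens.atom_names
    atoms.element = ens.elements
    atoms.res_id = res_ids[ens.atom_residue_index]
    atoms.chain_id = chain_ids[ens.atom_residue_index]
    atoms.res_name = np.full(ens.n_atoms, "ALA", dtype="U3")
    atoms.hetero = np.zeros(ens.n_atoms, dtype=bool)
    if b_factors is not None:
        b_factors = np.asarray(b_factors, dtype=float)
        if b_factors.shape != (ens.n_atoms,):
            raise ValueError("b_factors must be per-atom")
        atoms.set_annotation("b_factor", b_factors)
    stack = struc.from_template(atoms, ens.coords.astype(np.float32))
    out = pdb.PDBFile()
    out.set_structure(stack)
    out.write(str(path))


def select_calpha(ens: Ensemble) -> Ensemble:
    """Restrict an ensemble to one CA atom per residue, in residue order."""
    idx = ens.ca_indices
    return Ensemble(
        coords=ens.coords[:, idx, :],
        atom_names=ens.atom_names[idx],
        atom_residue_index=ens.atom_residue_index[idx],
        elements=ens.elements[idx],
        masses=ens.masses[idx],
        residue_labels=ens.residue_labels,
    )


def subsample(ens: Ensemble, stride: int) -> Ensemble:
    """Keep frames 0, stride, 2*stride, ..."""
    stride = int(stride)
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    return replace(ens, coords=ens.coords[::stride])
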
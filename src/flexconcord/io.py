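"""Readers for AlphaFold2 model artifacts and profile-table I/O.

AlphaFold2 deposits its per-residue confidence (pLDDT, range 0-100) in the
B-factor column of the model PDB file, and its predicted aligned error (PAE)
as a JSON matrix in one of two AlphaFold-DB dialects:

* v1: flat triplet lists ``residue1`` / ``residue2`` / ``distance`` (1-based
  residue indices) plus ``max_predicted_aligned_error``;
* v2: a nested list under ``predicted_aligned_error`` (or ``pae``).

Experimental structures carry crystallographic B-factors in the same column;
``score_kind`` records which quantity was read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import biotite.structure.io.pdb as pdb

__all__ = [
    "StructureModel",
    "PAEMatrix",
    "PAEFormatError",
    "ModelLoadError",
    "read_af2_model",
    "read_pae_json",
    "write_profile_table",
    "read_profile_table",
]


class ModelLoadError(ValueError):
    """Raised when a model PDB cannot be mapped onto the data model."""


class PAEFormatError(ValueError):
    """Raised for malformed PAE JSON files."""


@dataclass
class StructureModel:
    """A single structure with one confidence/temperature score per residue.

    Internal residue indexing is 0-based and contiguous; the original chain
    and resSeq labels are retained in ``residue_labels`` so numbering gaps in
    the source file never leak into the math.
    """

    residue_ids: np.ndarray        # original resSeq numbers
    chain_ids: np.ndarray          # per-residue chain label
    residue_labels: np.ndarray     # "chain:resSeq[icode]"
    atom_coords: np.ndarray        # (A, 3) Angstrom
    atom_names: np.ndarray
    atom_residue_index: np.ndarray  # (A,) 0-based
    per_residue_score: np.ndarray   # (R,)
    score_kind: Literal["plddt", "bfactor"]

    def __post_init__(self) -> None:
        self.per_residue_score = np.asarray(self.per_residue_score, dtype=float)
        if self.score_kind == "plddt":
            bad = (self.per_residue_score < 0) | (self.per_residue_score > 100)
            if np.any(bad):
                r = int(np.nonzero(bad)[0][0])
                raise ModelLoadError(
                    f"pLDDT {self.per_residue_score[r]} of residue "
                    f"{self.residue_labels[r]} outside [0, 100]"
                )
        # strictly increasing residue_ids within each chain
        for chain in np.unique(self.chain_ids):
            ids = self.residue_ids[self.chain_ids == chain]
            if np.any(np.diff(ids) <= 0):
                raise ModelLoadError(
                    f"residue numbers not strictly increasing in chain {chain}"
                )

    @property
    def residue_count(self) -> int:
        return len(self.per_residue_score)

    @property
    def ca_coords(self) -> np.ndarray:
        idx = np.nonzero(self.atom_names == "CA")[0]
        order = np.argsort(self.atom_residue_index[idx], kind="stable")
        return self.atom_coords[idx[order]]


@dataclass
class PAEMatrix:
    """R x R predicted-aligned-error matrix in Angstrom.

    The matrix may be asymmetric: the error assigned to residue x when y is
    aligned need not equal the converse.
    """

    values: np.ndarray
    max_pae: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise PAEFormatError(
                f"PAE matrix must be square, got shape {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise PAEFormatError("PAE entries must be non-negative")
        self.max_pae = float(self.max_pae)
        if np.any(self.values > self.max_pae + 1e-9):
            raise PAEFormatError("PAE entries exceed the declared max_pae")

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]


def read_af2_model(path, score_kind: str = "plddt") -> StructureModel:
    """Read a (possibly multi-chain) model PDB into a :class:`StructureModel`.

    The per-residue score is taken from the CA B-factor field. Multi-chain
    models are concatenated in file order with chain labels retained. The
    first altLoc is kept and insertion-coded residues are distinct positions
    in file order.
    """
    if score_kind not in ("plddt", "bfactor"):
        raise ValueError(f"score_kind must be 'plddt' or 'bfactor', got {score_kind!r}")
    pdb_file = pdb.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(
        model=1, altloc="first", extra_fields=["b_factor"]
    )
    if atoms.array_length() == 0:
        raise ModelLoadError(f"{path} contains no atoms")
    keys = list(zip(atoms.chain_id, atoms.res_id, atoms.ins_code))
    seen: dict = {}
    res_index = np.empty(len(keys), dtype=int)
    labels, chain_ids, residue_ids = [], [], []
    for i, key in enumerate(keys):
        if key not in seen:
            seen[key] = len(seen)
            chain, res_id, icode = key
            labels.append(f"{chain}:{res_id}{icode}".strip())
            chain_ids.append(chain)
            residue_ids.append(res_id)
        res_index[i] = seen[key]
    n_res = len(seen)
    score = np.full(n_res, np.nan)
    ca_count = np.zeros(n_res, dtype=int)
    b = atoms.b_factor
    for i in np.nonzero(atoms.atom_name == "CA")[0]:
        r = res_index[i]
        ca_count[r] += 1
        score[r] = b[i]
    missing = np.nonzero(ca_count == 0)[0]
    if missing.size:
        raise ModelLoadError(
            f"residue {labels[missing[0]]} has no CA atom"
        )
    return StructureModel(
        residue_ids=np.asarray(residue_ids, dtype=int),
        chain_ids=np.asarray(chain_ids, dtype="U4"),
        residue_labels=np.asarray(labels, dtype=object),
        atom_coords=np.asarray(atoms.coord, dtype=float),
        atom_names=np.asarray(atoms.atom_name),
        atom_residue_index=res_index,
        per_residue_score=score,
        score_kind=score_kind,  # type: ignore[arg-type]
    )


def read_pae_json(path) -> PAEMatrix:
    """Read a PAE matrix from either AlphaFold-DB JSON dialect.

    v1 triplet indices are 1-based (the AlphaFold-DB convention) and must
    cover every ordered residue pair. ``max_pae`` falls back to the matrix
    maximum when the file declares none.
    """
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, list):
        if len(data) != 1 or not isinstance(data[0], dict):
            raise PAEFormatError("expected a JSON object or singleton list")
        data = data[0]
    if not isinstance(data, dict):
        raise PAEFormatError("expected a JSON object at the top level")

    if "predicted_aligned_error" in data or "pae" in data:
        raw = data.get("predicted_aligned_error", data.get("pae"))
        values = np.asarray(raw, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise PAEFormatError(
                f"nested PAE list is not square: shape {values.shape}"
            )
    elif {"residue1", "residue2", "distance"} <= set(data):
        r1 = np.asarray(data["residue1"], dtype=int)
        r2 = np.asarray(data["residue2"], dtype=int)
        dist = np.asarray(data["distance"], dtype=float)
        if not (len(r1) == len(r2) == len(dist)):
            raise PAEFormatError("triplet lists have unequal lengths")
        n = int(max(r1.max(), r2.max()))
        if r1.min() < 1 or r2.min() < 1:
            raise PAEFormatError("v1 residue indices must be 1-based")
        if len(dist) != n * n:
            raise PAEFormatError(
                f"v1 triplets cover {len(dist)} pairs, expected {n * n}"
            )
        values = np.full((n, n), np.nan)
        values[r1 - 1, r2 - 1] = dist
        if np.isnan(values).any():
            raise PAEFormatError("v1 triplets do not cover all residue pairs")
    else:
        raise PAEFormatError(
            "unrecognized PAE JSON: need 'predicted_aligned_error'/'pae' or "
            "'residue1'/'residue2'/'distance' keys"
        )
    max_pae = data.get("max_predicted_aligned_error", data.get("max_pae"))
    if max_pae is None:
        max_pae = float(values.max()) if values.size else 0.0
    return PAEMatrix(values=values, max_pae=float(max_pae))


_PROFILE_COLUMNS = [
    "residue", "plddt", "af2_score", "rmsf", "sqrt_b", "external_disorder"
]


def write_profile_table(profile, path) -> None:
    """Write a :class:`~flexconcord.scores.FlexibilityProfile` as TSV.

    One row per residue; only the columns present in the profile appear.
    Values round-trip at 6 significant digits.
    """
    df = profile.to_dataframe()
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_profile_table(path):
    """Read a profile TSV written by :func:`write_profile_table`."""
    from .scores import FlexibilityProfile

    df = pd.read_csv(path, sep="\t")
    if "residue" not in df.columns:
        raise ValueError(f"{path} is not a profile table (no 'residue' column)")
    kwargs = {}
    for col in _PROFILE_COLUMNS[1:]:
        if col in df.columns:
            kwargs[col] = df[col].to_numpy(dtype=float)
    return FlexibilityProfile(
        residue_labels=df["residue"].to_numpy(dtype=object), **kwargs
    )
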
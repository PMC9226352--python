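"""Per-residue score transforms.

The AF2-score is a reversed min-max normalisation of the pLDDT profile,

    AF2-score_i = (pLDDT_max - pLDDT_i) / (pLDDT_max - pLDDT_min),

so that the most confident residue maps to 0 and the least confident to 1,
putting the score on the same "high = flexible" orientation as RMSF and
crystallographic B-factors. The extrema are the profile's own max/min by
default (option: the fixed theoretical range 0-100).

The B-factor / RMSF bridge is the harmonic-isotropic relation
B = (8*pi^2/3) * RMSF^2; square-rooted B-factor profiles are used when
comparing experimental B with RMSF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .dynamics import iqr as _iqr

B_FACTOR_COEFF = 8.0 * np.pi**2 / 3.0


@dataclass
class FlexibilityProfile:
    """Aligned per-residue score vectors for one system.

    All present columns share length R. ``normalized`` records which columns
    have been min-max normalised to [0, 1].
    """

    residue_labels: np.ndarray
    plddt: Optional[np.ndarray] = None
    af2_score: Optional[np.ndarray] = None
    rmsf: Optional[np.ndarray] = None
    sqrt_b: Optional[np.ndarray] = None
    external_disorder: Optional[np.ndarray] = None
    normalized: dict = field(default_factory=dict)

    _COLUMNS = ("plddt", "af2_score", "rmsf", "sqrt_b", "external_disorder")

    def __post_init__(self) -> None:
        self.residue_labels = np.asarray(self.residue_labels, dtype=object)
        r = len(self.residue_labels)
        for col in self._COLUMNS:
            v = getattr(self, col)
            if v is None:
                continue
            v = np.asarray(v, dtype=float)
            if v.shape != (r,):
                raise ValueError(
                    f"column {col!r} has length {v.shape}, expected ({r},)"
                )
            setattr(self, col, v)
        if self.plddt is not None and self.plddt.size and (
            self.plddt.min() < 0 or self.plddt.max() > 100
        ):
            raise ValueError("pLDDT values must lie in [0, 100]")
        if self.af2_score is not None and self.af2_score.size and (
            self.af2_score.min() < -1e-9 or self.af2_score.max() > 1 + 1e-9
        ):
            raise ValueError("AF2-score values must lie in [0, 1]")

    @property
    def residue_count(self) -> int:
        return len(self.residue_labels)

    def columns(self) -> list:
        return [c for c in self._COLUMNS if getattr(self, c) is not None]

    def to_dataframe(self) -> pd.DataFrame:
        data = {"residue": self.residue_labels}
        for col in self.columns():
            data[col] = getattr(self, col)
        return pd.DataFrame(data)


def minmax_normalize(values) -> np.ndarray:
    """Affine map onto [0, 1]; constant input maps to zeros with a warning."""
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("cannot normalize an empty vector")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("constant profile: min-max normalization returns zeros")
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def af2_score(plddt, extrema: str = "profile") -> np.ndarray:
    """Reversed min-max normalisation of a pLDDT profile onto [0, 1].

    ``extrema="profile"`` (default) uses the profile's own max/min;
    ``extrema="fixed"`` uses the theoretical 100/0 range. A constant profile
    yields zeros with a warning.
    """
    x = np.asarray(plddt, dtype=float)
    if x.size and (x.min() < 0 or x.max() > 100):
        raise ValueError("pLDDT values must lie in [0, 100]")
    if extrema == "profile":
        lo, hi = x.min(), x.max()
    elif extrema == "fixed":
        lo, hi = 0.0, 100.0
    else:
        raise ValueError(f"extrema must be 'profile' or 'fixed', got {extrema!r}")
    if hi == lo:
        warnings.warn("constant pLDDT profile: AF2-score set to zeros")
        return np.zeros_like(x)
    return (hi - x) / (hi - lo)


def rmsf_to_b(rmsf) -> np.ndarray:
    """B = (8*pi^2/3) * RMSF^2, Angstrom^2 from Angstrom."""
    x = np.asarray(rmsf, dtype=float)
    if np.any(x < 0):
        raise ValueError("RMSF must be non-negative")
    return B_FACTOR_COEFF * x**2


def b_to_rmsf(b) -> np.ndarray:
    """Inverse of :func:`rmsf_to_b`."""
    x = np.asarray(b, dtype=float)
    if np.any(x < 0):
        raise ValueError("B-factors must be non-negative")
    return np.sqrt(x / B_FACTOR_COEFF)


def b_to_sqrtb_profile(b, normalize: bool = False) -> np.ndarray:
    """Elementwise sqrt of a B-factor profile, optionally min-max normalised."""
    x = np.asarray(b, dtype=float)
    if np.any(x < 0):
        raise ValueError("B-factors must be non-negative")
    out = np.sqrt(x)
    return minmax_normalize(out) if normalize else out


class DisorderSummary(NamedTuple):
    count: int
    fraction: float
    median: float
    iqr: float


def disorder_fraction(plddt, threshold: float = 50.0) -> DisorderSummary:
    """Count residues with pLDDT strictly below ``threshold``.

    Low per-residue confidence (conventionally pLDDT < 50) flags likely
    intrinsically disordered regions. Also reports the profile's median and
    IQR under the package-wide quantile rule.
    """
    x = np.asarray(plddt, dtype=float)
    if x.size and (x.min() < 0 or x.max() > 100):
        raise ValueError("pLDDT values must lie in [0, 100]")
    count = int(np.sum(x < threshold))
    return DisorderSummary(
        count=count,
        fraction=count / x.size if x.size else 0.0,
        median=float(np.median(x)) if x.size else float("nan"),
        iqr=_iqr(x) if x.size else float("nan"),
    )
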
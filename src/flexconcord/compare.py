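"""Concordance between AlphaFold2 confidence outputs and dynamics statistics.

Per-residue agreement is summarised by the Pearson correlation and an
ordinary-least-squares fit between two profile columns (e.g. pLDDT vs RMSF).
Because the AF2-score is an affine, strictly decreasing map of pLDDT, the
correlation of (AF2-score, RMSF) is exactly the negative of (pLDDT, RMSF);
reports record which orientation they carry.

Matrix-level agreement between a PAE map and a DV matrix uses the Pearson
correlation over the strict upper triangle after symmetrising the (possibly
asymmetric) PAE, so no element is double-counted and the structurally zero
diagonal never enters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Tuple

import numpy as np
from scipy import stats

from .dynamics import DistanceVariationMatrix
from .io import PAEMatrix
from .scores import FlexibilityProfile

#: Smallest p-value ever reported; smaller values underflow double precision.
P_FLOOR = 1e-300


@dataclass
class ConcordanceReport:
    """Pearson/OLS summary for one score pair of one system."""

    pcc: float
    slope: float
    intercept: float
    n: int
    p_value: float
    pair_label: str

    def __post_init__(self) -> None:
        if abs(self.pcc) > 1 + 1e-9:
            raise ValueError("|PCC| must not exceed 1")

    def to_dict(self) -> dict:
        return {
            "pcc": self.pcc,
            "slope": self.slope,
            "intercept": self.intercept,
            "n": self.n,
            "p_value": self.p_value,
            "pair_label": self.pair_label,
        }


@dataclass
class MatrixConcordance:
    """Pearson correlation between two residue-pair matrices."""

    pcc: float
    p_value: float
    n_elements: int
    symmetrization: Literal["mean_of_transpose_pair", "upper_triangle_raw"]


class ConstantInputError(ValueError):
    """Raised when a correlation is requested against a constant vector."""


def pearson(x, y) -> Tuple[float, float]:
    """Product-moment correlation with a two-sided t-test p-value.

    The p-value is floored at ``P_FLOOR``: anything smaller is below
    double-precision resolution and would otherwise print as "P = 0".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("Pearson correlation needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation with a constant vector is undefined")
    res = stats.pearsonr(x, y)
    p = res.pvalue if res.pvalue > 0 else P_FLOOR
    return float(res.statistic), float(max(p, P_FLOOR) if p < P_FLOOR else p)


def linear_fit(x, y) -> Tuple[float, float]:
    """Ordinary least squares: returns (slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 2:
        raise ValueError("a line needs at least 2 points")
    if np.ptp(x) == 0:
        raise ConstantInputError("OLS slope is undefined for constant x")
    design = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(slope), float(intercept)


def profile_concordance(
    profile: FlexibilityProfile,
    pair: Tuple[str, str] = ("plddt", "rmsf"),
    orientation: Literal["as_given", "af2"] = "as_given",
) -> ConcordanceReport:
    """Pearson + OLS between two columns of a flexibility profile.

    ``orientation="af2"`` reports the pair with the first column replaced by
    its reversed normalisation (sign-flipped PCC), matching the convention
    in which high score = high flexibility.
    """
    xs = []
    for col in pair:
        v = getattr(profile, col, None)
        if v is None:
            raise ValueError(f"profile has no column {col!r}")
        xs.append(np.asarray(v, dtype=float))
    x, y = xs
    label = f"{pair[0]} vs {pair[1]}"
    if orientation == "af2":
        x = -x
        label = f"reversed {label}"
    pcc, p = pearson(x, y)
    slope, intercept = linear_fit(x, y)
    return ConcordanceReport(
        pcc=pcc, slope=slope, intercept=intercept,
        n=int(x.size), p_value=p, pair_label=label,
    )


def pae_dv_concordance(
    pae: PAEMatrix,
    dv: DistanceVariationMatrix,
    symmetrization: Literal[
        "mean_of_transpose_pair", "upper_triangle_raw"
    ] = "mean_of_transpose_pair",
) -> MatrixConcordance:
    """Pearson correlation between a PAE map and a DV matrix.

    With the default symmetrisation the asymmetric PAE is replaced by the
    mean of each transpose pair before the strict upper triangles of both
    matrices are correlated; ``upper_triangle_raw`` correlates the raw PAE
    upper triangle instead.
    """
    p = pae.values
    d = dv.values
    if p.shape != d.shape:
        raise ValueError(
            f"dimension mismatch: PAE is {p.shape}, DV is {d.shape}"
        )
    if p.shape[0] < 3:
        raise ValueError("matrix concordance needs at least 3 residues")
    if symmetrization == "mean_of_transpose_pair":
        p = 0.5 * (p + p.T)
    elif symmetrization != "upper_triangle_raw":
        raise ValueError(f"unknown symmetrization {symmetrization!r}")
    iu = np.triu_indices(p.shape[0], k=1)
    pcc, pval = pearson(p[iu], d[iu])
    return MatrixConcordance(
        pcc=pcc, p_value=pval, n_elements=len(iu[0]),
        symmetrization=symmetrization,
    )


def near_diagonal_signature(matrix, window: int = 8) -> float:
    """Mean of entries with 1 <= |i-j| <= window (both triangles).

    High near-diagonal values in a PAE or DV map — large predicted error or
    distance variation even between sequence-adjacent residues — are a
    signature of intrinsic disorder; folded chains keep adjacent residues at
    nearly fixed separations. Units follow the input (Angstrom).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    values = getattr(matrix, "values", matrix)
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    i, j = np.indices(values.shape)
    sep = np.abs(i - j)
    if n <= window:
        warnings.warn(
            f"matrix size {n} <= window {window}: using all off-diagonal entries"
        )
        mask = sep >= 1
    else:
        mask = (sep >= 1) & (sep <= window)
    return float(values[mask].mean())


def aggregate_regression(
    means: Iterable[Tuple[float, float]],
    pair_label: str = "mean predictor vs mean RMSF",
) -> ConcordanceReport:
    """Cross-protein OLS and PCC on per-protein profile means.

    Each element of ``means`` is ``(mean_predictor, mean_response)`` for one
    protein (e.g. mean pLDDT, mean RMSF); the response is the second element.
    """
    arr = np.asarray(list(means), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("means must be (n_proteins, 2)")
    if arr.shape[0] < 3:
        raise ValueError("aggregate regression needs at least 3 proteins")
    x, y = arr[:, 0], arr[:, 1]
    pcc, p = pearson(x, y)
    slope, intercept = linear_fit(x, y)
    return ConcordanceReport(
        pcc=pcc, slope=slope, intercept=intercept,
        n=arr.shape[0], p_value=p, pair_label=pair_label,
    )
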
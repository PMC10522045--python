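"""S-sign and R-sign transforms.

Both transforms map counts to {0, 0.5, 1} indicators using the tie-aware
comparison I{a <= b} = I{a < b} + 0.5 * I{a = b}, so zero counts never
require pseudocounts:

* the S-sign compares a taxon's count in one sample against that sample's
  (adjusted) reference value;
* the R-sign compares a taxon's relative abundance N/R between two samples,
  evaluated in the cross-multiplied form I{R_j * N_i <= R_i * N_j} so that
  no division is ever performed and ties are detected exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reference import AdjustedReference


def half_indicator(a, b):
    """Tie-aware indicator: 1 if a < b, 0.5 if a == b, 0 if a > b.

    Accepts scalars or arrays (broadcast elementwise).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    out = np.where(a < b, 1.0, 0.0) + 0.5 * (a == b)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class SSignVector:
    """Per-sample below-reference indicators for one taxon."""

    taxon_id: str
    values: np.ndarray  # entries in {0, 0.5, 1}


@dataclass
class RSignMatrix:
    """Pairwise relative-abundance comparisons for one taxon.

    ``values[i, j] = I{N_i / R_i <= N_j / R_j}`` with the tie convention, so
    the matrix satisfies ``values + values.T == 1`` and the diagonal is 0.5.
    Row sums recover the midranks of the relative abundances.
    """

    taxon_id: str
    values: np.ndarray  # (n, n), entries in {0, 0.5, 1}

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def s_sign(target_counts, adjusted_ref, taxon_id: str = "") -> SSignVector:
    """S-sign vector: componentwise half_indicator(N_i, adjusted R_i)."""
    if isinstance(adjusted_ref, AdjustedReference):
        ref = adjusted_ref.values
        taxon_id = taxon_id or adjusted_ref.taxon_id
    else:
        ref = np.asarray(adjusted_ref, dtype=float)
    counts = np.asarray(target_counts, dtype=float)
    if counts.shape != ref.shape:
        raise ValueError("target counts and reference lengths differ")
    return SSignVector(taxon_id, half_indicator(counts, ref))


def r_sign_matrix(target_counts, ref, taxon_id: str = "") -> RSignMatrix:
    """R-sign matrix from raw counts and raw per-sample references.

    Comparisons use exact integer cross-multiplication R_j*N_i vs R_i*N_j;
    the taxon-specific reference adjustment cancels in these ratios, so the
    *raw* reference is the right input here.
    """
    n_counts = np.asarray(target_counts)
    r = np.asarray(ref)
    if n_counts.shape != r.shape:
        raise ValueError("target counts and reference lengths differ")
    # lhs[i, j] = N_i * R_j ; rhs[i, j] = R_i * N_j
    lhs = n_counts[:, None] * r[None, :]
    rhs = r[:, None] * n_counts[None, :]
    return RSignMatrix(taxon_id, half_indicator(lhs, rhs))


def midranks_from_rsigns(rs: RSignMatrix) -> np.ndarray:
    """Midranks of the relative abundances: rank_j = sum_i I_ij + 0.5."""
    return rs.values.sum(axis=0) + 0.5
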
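"""Reference-frame selection and per-sample reference values.

A reference frame (RF) is a set of taxa whose relative abundances are
approximately invariant across samples and conditions.  The per-sample
reference ``R_i`` is the median count of the RF taxa in sample *i* and acts
as the denominator of all sign comparisons.

The automatic selector implemented here is a deliberately simple
invariance heuristic: filter to high-prevalence, well-covered candidate
taxa, connect candidate pairs whose log-ratio variance across samples is
small, and keep the largest connected component.  Any externally chosen
set of stable taxa can be supplied instead via :func:`user_reference_frame`.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import CountTable, SampleMetadata


class ReferenceFrameError(ValueError):
    """Raised when a valid reference frame cannot be formed."""


@dataclass
class ReferenceFrame:
    """Set of reference taxa with their per-sample median count ``R_i``."""

    taxa: list[str]
    per_sample_reference: pd.Series
    source: str = "auto"

    def __post_init__(self) -> None:
        if len(self.taxa) == 0:
            raise ReferenceFrameError("reference frame is empty")

    @property
    def reference(self) -> np.ndarray:
        return self.per_sample_reference.to_numpy(dtype=float)


@dataclass
class AdjustedReference:
    """Per-sample reference rescaled to the target taxon's count scale.

    ``per_sample_value = R_i * factor`` with a single factor shared by all
    samples, so the ordering of the reference across samples is preserved.
    """

    taxon_id: str
    per_sample_value: pd.Series
    factor: float
    mean_fallback: bool = False

    @property
    def values(self) -> np.ndarray:
        return self.per_sample_value.to_numpy(dtype=float)


def _median_reference(table: CountTable, taxa: list[str]) -> pd.Series:
    return table.counts.loc[taxa].median(axis=0).astype(float)


def user_reference_frame(table: CountTable, taxa: list[str]) -> ReferenceFrame:
    """Build a reference frame from a user-supplied list of taxa."""
    taxa = list(taxa)
    unknown = [t for t in taxa if t not in table.counts.index]
    if unknown:
        raise ReferenceFrameError(f"reference taxa not in table: {unknown}")
    return ReferenceFrame(taxa, _median_reference(table, taxa), source="user")


def read_reference_list(path) -> list[str]:
    """Read a plain-text reference-taxon list (one taxon id per line)."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def pairwise_logratio_variances(counts: np.ndarray) -> np.ndarray:
    """Variance of log(count_s / count_t) over samples where both are > 0.

    Returns a symmetric (k, k) matrix; entries with fewer than two common
    positive samples are NaN.  Vectorised via masked sufficient statistics.
    """
    pos = counts > 0
    with np.errstate(divide="ignore"):
        logc = np.where(pos, np.log(counts, where=pos, out=np.zeros_like(counts, dtype=float)), 0.0)
    w = pos.astype(float)
    n_common = w @ w.T
    sx = (logc * w) @ w.T          # sum of log x over common support
    sy = sx.T                      # sum of log y over common support
    sxx = (logc**2 * w) @ w.T
    syy = sxx.T
    sxy = (logc * w) @ (logc * w).T
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_d = (sx - sy) / n_common
        # E[(x-y)^2] - (E[x-y])^2, with the unbiased n/(n-1) correction
        var = (sxx + syy - 2 * sxy) / n_common - mean_d**2
        var *= n_common / (n_common - 1)
    var[n_common < 2] = np.nan
    return var


def select_reference_frame(
    table: CountTable,
    meta: SampleMetadata | None = None,
    prevalence_threshold: float = 0.8,
    min_mean_count: float = 5.0,
    ratio_var_quantile: float = 0.25,
    min_size: int = 3,
    seed: int | None = None,
) -> ReferenceFrame:
    """Select an approximately invariant reference frame automatically.

    Candidates are taxa present in at least ``prevalence_threshold`` of the
    samples with mean count above ``min_mean_count``.  Candidate pairs whose
    log-ratio variance (over samples where both counts are positive — no
    pseudocounts) falls below the ``ratio_var_quantile`` quantile of all
    candidate-pair variances are connected in a graph; the largest connected
    component of size >= ``min_size`` becomes the RF.  Deterministic given
    the inputs; ``seed`` is accepted for interface uniformity only.
    """
    prev = table.prevalence()
    means = table.counts.mean(axis=1)
    cand_mask = (prev >= prevalence_threshold) & (means > min_mean_count)
    candidates = list(table.counts.index[cand_mask])
    if len(candidates) < min_size:
        raise ReferenceFrameError(
            f"only {len(candidates)} candidate taxa pass the filter "
            f"(prevalence >= {prevalence_threshold}, mean > {min_mean_count}); "
            f"need {min_size}. Consider lowering prevalence_threshold "
            "(e.g. 0.8 -> 0.6 for sparse data)."
        )
    counts = table.counts.loc[candidates].to_numpy(dtype=float)
    var = pairwise_logratio_variances(counts)
    k = len(candidates)
    iu = np.triu_indices(k, 1)
    pair_vars = var[iu]
    finite = pair_vars[np.isfinite(pair_vars)]
    if finite.size == 0:
        raise ReferenceFrameError("no candidate pair has common positive samples")
    threshold = np.quantile(finite, ratio_var_quantile)
    g = nx.Graph()
    g.add_nodes_from(range(k))
    # tolerance absorbs float noise when many pair variances are exactly zero
    keep = np.isfinite(pair_vars) & (pair_vars <= threshold + 1e-12)
    g.add_edges_from(zip(iu[0][keep], iu[1][keep]))
    components = sorted(
        nx.connected_components(g), key=lambda c: (len(c), -min(c)), reverse=True
    )
    best = components[0]
    if len(best) < min_size:
        raise ReferenceFrameError(
            f"largest invariant component has {len(best)} taxa (< {min_size}); "
            "consider lowering prevalence_threshold or raising ratio_var_quantile"
        )
    taxa = [candidates[i] for i in sorted(best)]
    return ReferenceFrame(taxa, _median_reference(table, taxa), source="auto")


def adjusted_reference(
    table: CountTable, rf: ReferenceFrame, taxon: str
) -> AdjustedReference:
    """Rescale ``R_i`` to the target taxon's typical count.

    The raw reference is usually far above the count of a rare target taxon,
    which would make its below-reference indicator almost always one.  The
    reference is therefore multiplied by ``median(target counts) /
    median(R)``, both medians taken over all samples (groups pooled).  For
    majority-zero taxa (target median 0) the arithmetic mean of the target
    counts is used as numerator instead, and flagged.
    """
    if taxon not in table.counts.index:
        raise ReferenceFrameError(f"taxon {taxon!r} not in table")
    target = table.counts.loc[taxon].astype(float)
    med_r = float(np.median(rf.reference))
    if med_r == 0:
        raise ReferenceFrameError(
            "median reference value is zero (degenerate reference frame)"
        )
    med_t = float(np.median(target.to_numpy()))
    fallback = med_t == 0
    numer = float(target.mean()) if fallback else med_t
    factor = numer / med_r
    return AdjustedReference(
        taxon_id=taxon,
        per_sample_value=rf.per_sample_reference * factor,
        factor=factor,
        mean_fallback=fallback,
    )
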
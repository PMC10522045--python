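"""Reading, validating and writing microbiome count data.

Count tables are taxon-by-sample matrices of non-negative integer read
counts.  The column sum of sample *i* over all taxa present at read time is
its library size ``L_i`` — a technical sequencing depth.  Library sizes are
therefore computed on the full table and are deliberately *not* recomputed
after prevalence trimming.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class CountTableError(ValueError):
    """Raised for malformed or invalid count-table input."""


@dataclass
class CountTable:
    """Taxon-by-sample matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        DataFrame with taxon identifiers as the index and sample
        identifiers as columns.  Entries must be non-negative integers.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise CountTableError(f"duplicated taxon identifiers: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise CountTableError(f"duplicated sample identifiers: {dups}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise CountTableError("count table contains non-numeric entries")
        if np.isnan(arr.astype(float)).any():
            raise CountTableError("count table contains missing entries")
        if (arr < 0).any():
            t, s = np.argwhere(arr < 0)[0]
            raise CountTableError(
                f"negative count at taxon {df.index[t]!r}, sample {df.columns[s]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            t, s = np.argwhere(arr != np.round(arr))[0]
            raise CountTableError(
                f"non-integer count {arr[t, s]} at taxon {df.index[t]!r}, "
                f"sample {df.columns[s]!r}"
            )
        self.counts = df.astype(np.int64)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> pd.Series:
        """Column sums over the taxa currently in the table."""
        return self.counts.sum(axis=0)

    def prevalence(self) -> pd.Series:
        """Fraction of samples in which each taxon has a count > 0."""
        return (self.counts > 0).mean(axis=1)


@dataclass
class SampleMetadata:
    """Per-sample design information for a two-group comparison.

    ``group`` is the 0/1 condition indicator ``A``; ``library_size`` is the
    sequencing depth ``L``; ``covariates`` names additional numeric columns
    ``X`` available for conditional models.
    """

    data: pd.DataFrame
    covariates: list[str] = field(default_factory=list)
    group_labels: dict[int, str] | None = None

    def __post_init__(self) -> None:
        df = self.data
        for col in ("group", "library_size"):
            if col not in df.columns:
                raise CountTableError(f"metadata lacks required column {col!r}")
        groups = set(df["group"].unique().tolist())
        if not groups <= {0, 1}:
            raise CountTableError(f"group indicator must be 0/1, got {sorted(groups)}")
        if groups != {0, 1}:
            raise CountTableError("both groups must be present (two-group design)")
        if (df["library_size"] <= 0).any():
            bad = df.index[df["library_size"] <= 0].tolist()
            raise CountTableError(f"non-positive library size for samples {bad}")
        missing = [c for c in self.covariates if c not in df.columns]
        if missing:
            raise CountTableError(f"covariate columns not found: {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def group(self) -> np.ndarray:
        return self.data["group"].to_numpy(dtype=float)

    @property
    def library_size(self) -> np.ndarray:
        return self.data["library_size"].to_numpy(dtype=float)

    def covariate_matrix(self, names: list[str] | None = None) -> np.ndarray:
        names = self.covariates if names is None else names
        if not names:
            return np.empty((len(self.data), 0))
        return self.data[list(names)].to_numpy(dtype=float)

    def aligned_to(self, sample_ids: list[str]) -> "SampleMetadata":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise CountTableError(f"samples missing from metadata: {missing}")
        return SampleMetadata(
            self.data.loc[sample_ids], list(self.covariates), self.group_labels
        )


def read_count_table(path, format: str | None = None) -> CountTable:
    """Read a taxon-by-sample count matrix from TSV, CSV or BIOM 2.1.

    The first column (or the BIOM observation axis) holds taxon identifiers;
    remaining columns are samples.  ``format`` is inferred from the file
    extension when not given.
    """
    path = str(path)
    if format is None:
        lower = path.lower()
        if lower.endswith(".biom"):
            format = "biom"
        elif lower.endswith(".csv"):
            format = "csv"
        else:
            format = "tsv"
    if format == "biom":
        df = _read_biom_hdf5(path)
    elif format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise CountTableError(f"cannot parse {path}: {exc}") from exc
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    else:
        raise CountTableError(f"unknown count-table format {format!r}")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise CountTableError(f"{path} contains no data")
    return CountTable(df)


def _read_biom_hdf5(path) -> pd.DataFrame:
    """Minimal BIOM v2.1 (HDF5) reader: dense reconstruction from the
    observation-major CSR groups."""
    import h5py
    from scipy import sparse

    with h5py.File(path, "r") as f:
        taxa = [x.decode() if isinstance(x, bytes) else str(x) for x in f["observation/ids"][:]]
        samples = [x.decode() if isinstance(x, bytes) else str(x) for x in f["sample/ids"][:]]
        grp = f["observation/matrix"]
        mat = sparse.csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(taxa), len(samples)),
        )
    return pd.DataFrame(mat.toarray(), index=taxa, columns=samples)


def read_metadata(
    path,
    table: CountTable | None = None,
    group_col: str = "group",
    covariate_cols: list[str] | None = None,
    group_mapping: dict[str, int] | None = None,
    library_size_col: str | None = "library_size",
    sep: str = "\t",
) -> SampleMetadata:
    """Read per-sample metadata and coerce the group column to 0/1.

    Group labels are mapped with ``group_mapping`` when given, otherwise by
    sorted label order (first label -> 0), so the sign of the group effect is
    reproducible.  When the file has no library-size column and ``table`` is
    given, library sizes are filled from the table's column sums.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return build_metadata(
        df,
        table=table,
        group_col=group_col,
        covariate_cols=covariate_cols,
        group_mapping=group_mapping,
        library_size_col=library_size_col,
    )


def build_metadata(
    df: pd.DataFrame,
    table: CountTable | None = None,
    group_col: str = "group",
    covariate_cols: list[str] | None = None,
    group_mapping: dict[str, int] | None = None,
    library_size_col: str | None = "library_size",
) -> SampleMetadata:
    """Assemble :class:`SampleMetadata` from an in-memory DataFrame."""
    if group_col not in df.columns:
        raise CountTableError(f"metadata lacks group column {group_col!r}")
    raw = df[group_col]
    labels = None
    if set(raw.unique().tolist()) <= {0, 1}:
        group = raw.astype(int)
    else:
        uniq = sorted(raw.astype(str).unique().tolist())
        if group_mapping is None:
            if len(uniq) != 2:
                raise CountTableError(
                    f"group column {group_col!r} has {len(uniq)} levels {uniq}; "
                    "two-group design only"
                )
            group_mapping = {uniq[0]: 0, uniq[1]: 1}
        unknown = [u for u in uniq if u not in group_mapping]
        if unknown:
            raise CountTableError(f"group labels without mapping: {unknown}")
        group = raw.astype(str).map(group_mapping).astype(int)
        labels = {v: k for k, v in group_mapping.items()}

    if table is not None:
        missing = [s for s in table.sample_ids if s not in df.index]
        if missing:
            raise CountTableError(f"samples in counts missing from metadata: {missing}")
        # metadata may be a superset; keep only the table's samples
        df = df.loc[[s for s in df.index if s in set(table.sample_ids)]]
        group = group.loc[df.index]
    out = pd.DataFrame(index=df.index)
    out["group"] = group
    if library_size_col is not None and library_size_col in df.columns:
        out["library_size"] = df[library_size_col].astype(float)
    elif table is not None:
        out["library_size"] = table.library_sizes.reindex(df.index).astype(float)
    else:
        raise CountTableError(
            "no library-size column and no count table to derive it from"
        )
    covariate_cols = list(covariate_cols or [])
    for c in covariate_cols:
        if c not in df.columns:
            raise CountTableError(f"covariate column {c!r} not in metadata")
        out[c] = pd.to_numeric(df[c])
    if table is not None:
        out = out.loc[table.sample_ids]
    return SampleMetadata(out, covariate_cols, labels)


def trim_low_prevalence(table: CountTable, min_prevalence: float = 0.05) -> CountTable:
    """Drop taxa present (count > 0) in fewer than ``min_prevalence`` of samples.

    A taxon present in exactly ``min_prevalence * n`` samples is retained
    (only strictly-lower prevalence is trimmed).  Idempotent; library sizes
    are a property of the untrimmed table and must be captured in metadata
    before calling this if they are needed downstream.
    """
    if not 0 <= min_prevalence <= 1:
        raise CountTableError("min_prevalence must lie in [0, 1]")
    prev = table.prevalence()
    keep = prev >= min_prevalence
    if not keep.any():
        raise CountTableError("prevalence trim removed every taxon")
    if keep.all():
        return table
    return CountTable(table.counts.loc[keep])


RESULT_COLUMNS = [
    "taxon_id",
    "method",
    "estimate",
    "se",
    "z",
    "p",
    "p_adj",
    "effect_size",
    "effect_scale",
    "converged",
    "firth_used",
    "rf_flag",
]


def write_results(results: pd.DataFrame, path) -> None:
    """Write a per-taxon result table as TSV (one row per tested taxon)."""
    if results is None or len(results) == 0:
        raise CountTableError("refusing to write an empty result table")
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    extra = [c for c in results.columns if c not in cols]
    results[cols + extra].to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
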
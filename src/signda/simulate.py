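"""Parametric negative-binomial microbiome simulator and evaluation harness.

Counts for taxon t in sample i are drawn NB with mean ``L_i * pi_{g,t}``
and variance ``mu + phi * mu^2``: library sizes L_i are resampled with
replacement from a library pool, and the group-specific proportions
pi_{g,t} come from a pool of (mean, overdispersion) pairs sampled jointly
(both parameters from the same pool entry) so a mean-dispersion
relationship is preserved.  Differential abundance multiplies the group-1
mean of a configurable fraction of taxa by a fold change FC (direction
randomised per taxon); with compositional renormalisation on, the group-1
proportions are re-normalised so that raising some taxa suppresses the
rest — the compositional compensation effect that makes high-DA-fraction
scenarios hard for every method.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CountTable, SampleMetadata, build_metadata, trim_low_prevalence
from .methods import METHODS, run_all_taxa
from .reference import ReferenceFrameError, select_reference_frame, user_reference_frame


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n_taxa: int = 250
    n_per_group: int = 25
    fold_change: float = 1.0
    da_fraction: float = 0.0
    seed: int = 0
    parameter_pool: np.ndarray | None = None  # (k, 2) of (mean, overdispersion)
    library_pool: np.ndarray | None = None
    compositional_renorm: bool = True

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.n_per_group < 1:
            raise SimulationError("n_taxa and n_per_group must be positive")
        if self.fold_change <= 0:
            raise SimulationError("fold change must be > 0")
        if not 0 <= self.da_fraction <= 1:
            raise SimulationError("da_fraction must lie in [0, 1]")

    @property
    def n_da(self) -> int:
        return int(round(self.da_fraction * self.n_taxa))


@dataclass
class SimulatedDataset:
    table: CountTable
    meta: SampleMetadata
    truth: pd.Series        # bool per taxon
    da_direction: pd.Series  # +1 / -1 / 0 per taxon


def default_parameter_pool(
    n_taxa: int,
    seed: int,
    library_median: float = 1977.0,
    library_sigma: float = 0.6,
    n_libraries: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic (mean, overdispersion) pool and library-size pool.

    log10 mean counts follow a t(3) distribution (heavy tails spanning
    roughly four orders of magnitude); the overdispersion decreases
    log-linearly with the mean plus lognormal noise, so the pool carries a
    negative mean-dispersion trend.  Library sizes are lognormal around
    ``library_median`` reads.  Pool means are scaled so that the expected
    count of a taxon at the median library roughly equals its pool mean.
    """
    if n_taxa < 1:
        raise SimulationError("n_taxa must be >= 1")
    rng = np.random.default_rng(seed)
    log10_mu = rng.standard_t(3, size=n_taxa)
    mu = 10.0 ** np.clip(log10_mu, -2.0, 4.0)
    phi = np.exp(-0.5 * np.log(mu) + rng.normal(0.0, 0.5, size=n_taxa))
    # rescale so total pool mean ~ median library: expected counts ~ mu
    mu = mu * (library_median / mu.sum())
    pool = np.column_stack([mu, phi])
    libraries = np.round(
        np.exp(np.log(library_median) + rng.normal(0.0, library_sigma, n_libraries))
    ).astype(np.int64)
    libraries = np.maximum(libraries, 50)
    return pool, libraries


def _nb_draw(rng, mu, phi):
    """NB draws with mean mu and variance mu + phi mu^2 (phi=0 -> Poisson)."""
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    out = np.empty(mu.shape, dtype=np.int64)
    pois = phi <= 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        size_param = 1.0 / phi[~pois]
        p = size_param / (size_param + mu[~pois])
        out[~pois] = rng.negative_binomial(size_param, p)
    return out


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one two-group dataset under the NB framework; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    if config.parameter_pool is None or config.library_pool is None:
        pool, libs = default_parameter_pool(
            config.n_taxa, seed=int(rng.integers(0, 2**31 - 1))
        )
        pool = pool if config.parameter_pool is None else np.asarray(config.parameter_pool)
        libs = libs if config.library_pool is None else np.asarray(config.library_pool)
    else:
        pool = np.asarray(config.parameter_pool, dtype=float)
        libs = np.asarray(config.library_pool)
    if pool.ndim != 2 or pool.shape[1] != 2 or len(libs) == 0:
        raise SimulationError("invalid parameter or library pool")
    if (pool[:, 0] <= 0).any() or (pool[:, 1] < 0).any():
        raise SimulationError("pool means must be > 0 and overdispersions >= 0")

    m, n_g = config.n_taxa, config.n_per_group
    n = 2 * n_g
    # joint resampling keeps each taxon's mean-dispersion pair together
    idx = rng.integers(0, pool.shape[0], m)
    mu, phi = pool[idx, 0], pool[idx, 1]

    truth = np.zeros(m, dtype=bool)
    direction = np.zeros(m, dtype=int)
    n_da = config.n_da
    if n_da > 0:
        da_idx = rng.choice(m, size=n_da, replace=False)
        truth[da_idx] = True
        direction[da_idx] = rng.choice([-1, 1], size=n_da)

    mu1 = mu * np.where(truth, float(config.fold_change) ** direction.astype(float), 1.0)
    pi0 = mu / mu.sum()
    pi1 = mu1 / (mu1.sum() if config.compositional_renorm else mu.sum())

    L = rng.choice(libs, size=n, replace=True).astype(float)
    group = np.repeat([0, 1], n_g)
    pi = np.where(group[None, :] == 0, pi0[:, None], pi1[:, None])
    mean_mat = pi * L[None, :]
    counts = _nb_draw(rng, mean_mat, np.broadcast_to(phi[:, None], mean_mat.shape))

    taxa = [f"taxon_{t:04d}" for t in range(m)]
    samples = [f"sample_{i:03d}" for i in range(n)]
    table = CountTable(pd.DataFrame(counts, index=taxa, columns=samples))
    meta_df = pd.DataFrame({"group": group}, index=samples)
    meta = build_metadata(meta_df, table=table)
    return SimulatedDataset(
        table=table,
        meta=meta,
        truth=pd.Series(truth, index=taxa),
        da_direction=pd.Series(direction, index=taxa),
    )


def evaluate(results: pd.DataFrame, truth: pd.Series, alpha: float = 0.05) -> dict:
    """Sensitivity, FDR and raw-p type-I error of one result table.

    Discoveries are BH-adjusted p <= alpha.  FDR uses the FP/max(1, D)
    convention (zero discoveries give FDR 0).  Sensitivity counts every
    truly-DA taxon in ``truth`` in the denominator, so DA taxa that were
    untestable (absorbed into the RF or failed) count as misses.  Type-I
    error is the fraction of *raw* p-values at or below alpha among tested
    true-null taxa.
    """
    unknown = [t for t in results["taxon_id"] if t not in truth.index]
    if unknown:
        raise SimulationError(f"result taxa absent from truth: {unknown[:5]}")
    res = results[results["p"].notna()].copy()
    is_da = truth.reindex(res["taxon_id"]).to_numpy(dtype=bool)
    disc = (res["p_adj"] <= alpha).to_numpy()
    tp = int(np.sum(disc & is_da))
    fp = int(np.sum(disc & ~is_da))
    n_da_total = int(truth.sum())
    nulls = ~is_da
    return {
        "sensitivity": tp / n_da_total if n_da_total else np.nan,
        "fdr": fp / max(1, tp + fp),
        "type_i_error": float(np.mean(res.loc[nulls, "p"] <= alpha))
        if nulls.any()
        else np.nan,
        "discoveries": tp + fp,
        "n_tested": int(len(res)),
        "n_null_tested": int(nulls.sum()),
    }


def run_replicate(
    config: SimulationConfig,
    method: str,
    alpha: float = 0.05,
    min_prevalence: float = 0.05,
    rf_mode: str = "auto",
    oracle_rf_size: int = 10,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Simulate, trim, select the RF, and test all taxa with one method.

    ``rf_mode='auto'`` uses the invariance selector (retrying at 60%
    prevalence when the 80% default finds too few candidates, mirroring the
    sparse-data fallback); ``'oracle'`` builds the RF from the most
    prevalent truly-null taxa, bypassing selection error.
    Returns (results, truth, rf_taxa).
    """
    data = simulate_dataset(config)
    table = trim_low_prevalence(data.table, min_prevalence)
    meta = data.meta.aligned_to(table.sample_ids)
    if rf_mode == "oracle":
        nulls = data.truth.reindex(table.taxon_ids)
        candidates = table.counts.loc[~nulls.to_numpy(dtype=bool)]
        order = (candidates > 0).mean(axis=1).sort_values(ascending=False)
        rf = user_reference_frame(table, list(order.index[:oracle_rf_size]))
    else:
        try:
            rf = select_reference_frame(table, meta, prevalence_threshold=0.8)
        except ReferenceFrameError:
            rf = select_reference_frame(table, meta, prevalence_threshold=0.6)
    results = run_all_taxa(table, meta, rf, method, alpha=alpha)
    truth = data.truth.reindex(table.taxon_ids)
    return results, truth, rf.taxa


def run_benchmark(
    scenarios: list[SimulationConfig],
    methods: list[str],
    n_replicates: int,
    seed: int,
    alpha: float = 0.05,
    rf_mode: str = "auto",
    collect_pvalues: bool = False,
) -> pd.DataFrame:
    """Aggregate sensitivity/FDR/type-I over replicated scenarios.

    Each (scenario, replicate) gets a reproducible seed derived from the
    top-level ``seed``; all methods see the same datasets within a
    replicate.  Returns one row per (scenario, method) with means and
    Monte-Carlo standard errors; per-replicate failures are counted, not
    fatal.
    """
    for mth in methods:
        if mth not in METHODS:
            raise SimulationError(f"unknown method {mth!r}")
    if n_replicates < 1:
        raise SimulationError("n_replicates must be >= 1")
    master = np.random.default_rng(seed)
    rows = []
    for s_idx, base in enumerate(scenarios):
        rep_seeds = master.integers(0, 2**31 - 1, size=n_replicates)
        per_method: dict[str, list[dict]] = {mth: [] for mth in methods}
        pooled_p: dict[str, list[np.ndarray]] = {mth: [] for mth in methods}
        failures = {mth: 0 for mth in methods}
        for r in range(n_replicates):
            config = replace(base, seed=int(rep_seeds[r]))
            for mth in methods:
                try:
                    results, truth, rf_taxa = run_replicate(
                        config, mth, alpha=alpha, rf_mode=rf_mode
                    )
                except (SimulationError, ReferenceFrameError, ValueError):
                    failures[mth] += 1
                    continue
                metrics = evaluate(results, truth, alpha)
                metrics["rf_contains_da"] = bool(
                    truth.reindex(rf_taxa).fillna(False).any()
                )
                per_method[mth].append(metrics)
                if collect_pvalues:
                    ok = results["p"].notna()
                    nulls = ~truth.reindex(results["taxon_id"]).to_numpy(dtype=bool)
                    pooled_p[mth].append(results.loc[ok & nulls, "p"].to_numpy())
        for mth in methods:
            reps = per_method[mth]
            if not reps:
                continue
            df = pd.DataFrame(reps)
            row = {
                "scenario": s_idx,
                "n_per_group": base.n_per_group,
                "fold_change": base.fold_change,
                "da_fraction": base.da_fraction,
                "method": mth,
                "n_replicates": len(reps),
                "n_failures": failures[mth],
                "rf_contains_da_rate": float(df["rf_contains_da"].mean()),
            }
            for metric in ("sensitivity", "fdr", "type_i_error"):
                vals = df[metric].dropna()
                row[metric] = float(vals.mean()) if len(vals) else np.nan
                row[f"{metric}_mcse"] = (
                    float(vals.std(ddof=1) / np.sqrt(len(vals)))
                    if len(vals) > 1
                    else np.nan
                )
            if collect_pvalues and pooled_p[mth]:
                allp = np.concatenate(pooled_p[mth])
                row["pooled_null_rejection_rate"] = float(np.mean(allp <= alpha))
                row["pooled_null_n"] = int(allp.size)
            rows.append(row)
    return pd.DataFrame(rows)
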
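"""Gene-set enrichment against SNP-count-matched random sets from a GWAS.

To ask whether a selected gene category carries more association signal
than chance, random gene sets of the same size are drawn repeatedly from a
genome-wide GWAS universe and four summary metrics are computed for each
draw: total SNP count, minimum p-value, and the numbers of SNPs below 0.05
and 0.005.  Because gene size (hence SNP count) varies enormously, the raw
comparison is biased whenever the observed set is SNP-dense; simulations
are therefore rank-filtered on total SNP count until the observed count is
compatible with the retained draws, and empirical significance uses the
plus-one rule (r + 1) / n, which is bounded below by 1/n and never zero.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

SIM_COLUMNS = ("snp_count", "min_p", "n_lt_05", "n_lt_005")
DEFAULT_K_GRID = (500, 1000, 2000, 5000, 10000, 20000, 50000)

#: Direction in which each metric becomes "more extreme" (more signal).
METRIC_DIRECTION: dict[str, str] = {
    "snp_count": "ge",
    "min_p": "le",
    "n_lt_05": "ge",
    "n_lt_005": "ge",
}


def summarize_snp_set(pvalues: np.ndarray) -> dict[str, float]:
    """The four enrichment metrics for one set of SNP p-values."""
    p = np.asarray(pvalues, dtype=float)
    return {
        "snp_count": int(p.size),
        "min_p": float(p.min()) if p.size else np.nan,
        "n_lt_05": int((p < 0.05).sum()),
        "n_lt_005": int((p < 0.005).sum()),
    }


def _per_gene_stats(universe: pd.DataFrame) -> pd.DataFrame:
    g = universe.groupby("gene_id")["p"]
    out = g.agg(snp_count="size", min_p="min")
    out["n_lt_05"] = g.apply(lambda s: int((s < 0.05).sum()))
    out["n_lt_005"] = g.apply(lambda s: int((s < 0.005).sum()))
    return out


def simulate_gene_sets(
    universe: pd.DataFrame,
    set_size: int,
    n_sims: int,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw *n_sims* random gene sets and summarize each.

    Every simulation samples ``set_size`` genes uniformly without
    replacement from the universe (a per-SNP table with gene_id and p
    columns) and records the four metrics.  Because all four metrics
    decompose over genes (sums, or a min), per-gene statistics are
    precomputed once and each draw reduces them, which keeps 10^5 draws
    tractable.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    stats_df = _per_gene_stats(universe)
    n_genes = len(stats_df)
    if set_size > n_genes:
        raise ValueError(f"set_size {set_size} exceeds universe size {n_genes}")
    counts = stats_df["snp_count"].to_numpy()
    minp = stats_df["min_p"].to_numpy()
    n05 = stats_df["n_lt_05"].to_numpy()
    n005 = stats_df["n_lt_005"].to_numpy()

    out = np.empty((n_sims, 4))
    # Sample by arg-partitioning random keys, chunked to bound memory.
    chunk = max(1, int(2e6) // max(n_genes, 1))
    done = 0
    while done < n_sims:
        m = min(chunk, n_sims - done)
        keys = rng.random((m, n_genes))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        out[done:done + m, 0] = counts[idx].sum(axis=1)
        out[done:done + m, 1] = minp[idx].min(axis=1)
        out[done:done + m, 2] = n05[idx].sum(axis=1)
        out[done:done + m, 3] = n005[idx].sum(axis=1)
        done += m
    return pd.DataFrame(out, columns=list(SIM_COLUMNS)).astype(
        {"snp_count": int, "n_lt_05": int, "n_lt_005": int}
    )


def empirical_p(observed: float, sim_values: Iterable[float],
                direction: Literal["ge", "le"] = "ge") -> float:
    """Plus-one empirical p-value: (r + 1) / n, capped at 1.

    r counts simulations as or more extreme than the observed value —
    ``>=`` for count-like metrics, ``<=`` for minimum p.
    """
    sims = np.asarray(list(sim_values), dtype=float)
    if sims.size == 0:
        raise ValueError("empty simulation list")
    if direction == "ge":
        r = int((sims >= observed).sum())
    elif direction == "le":
        r = int((sims <= observed).sum())
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return min(1.0, (r + 1) / sims.size)


@dataclasses.dataclass
class FilterResult:
    sims: pd.DataFrame
    k: int | str                 # chosen grid value, or "all"
    compatible: bool             # False when no K made counts compatible


def snp_count_match_filter(
    sims: pd.DataFrame,
    observed_snp_count: int,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
) -> FilterResult:
    """Retain the top-K simulations by SNP count, choosing the smallest
    compatible K.

    Simulations are sorted descending by total SNP count; for each K in
    ascending grid order the observed count is tested two-sided against the
    retained counts: K is accepted when both tails — the fraction of retained
    counts >= observed and the fraction <= observed — are at least 0.025
    (compatibility at level 0.05; with tie-free counts this is the same as
    requiring the >= fraction to lie in [0.025, 0.975], and it remains
    well-defined when counts tie the observed value).  If no grid value
    works, all simulations are returned with ``compatible=False``.
    """
    if sims.empty:
        raise ValueError("no simulations to filter")
    ranked = sims.sort_values("snp_count", ascending=False, kind="stable")
    for k in sorted(set(int(k) for k in k_grid)):
        top = ranked.head(k)
        frac_ge = float((top["snp_count"] >= observed_snp_count).mean())
        frac_le = float((top["snp_count"] <= observed_snp_count).mean())
        if frac_ge >= 0.025 and frac_le >= 0.025:
            return FilterResult(sims=top.reset_index(drop=True), k=k, compatible=True)
    return FilterResult(sims=ranked.reset_index(drop=True), k="all", compatible=False)


def enrichment_report(
    observed: Mapping[str, Mapping[str, float]],
    universe: pd.DataFrame,
    set_sizes: Mapping[str, int],
    n_sims: int = 2000,
    rng: np.random.Generator | int | None = None,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
) -> pd.DataFrame:
    """Empirical enrichment p-values per category and metric.

    *observed* maps category label -> metric -> observed value (as from
    :func:`summarize_snp_set`); *set_sizes* gives the number of genes drawn
    per category.  For every category the same-size random sets are
    simulated once and each metric's plus-one empirical p is reported both
    unfiltered and under the smallest compatible SNP-count filter.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows = []
    for cat, obs in observed.items():
        sims = simulate_gene_sets(universe, set_sizes[cat], n_sims, rng)
        filt = snp_count_match_filter(sims, int(obs["snp_count"]), k_grid)
        for metric in SIM_COLUMNS:
            direction = METRIC_DIRECTION[metric]
            rows.append({
                "category": cat,
                "metric": metric,
                "observed": obs[metric],
                "filter_K": "all",
                "n_sims_used": len(sims),
                "empirical_p": empirical_p(obs[metric], sims[metric], direction),
                "snp_count_compatible": True,
            })
            rows.append({
                "category": cat,
                "metric": metric,
                "observed": obs[metric],
                "filter_K": filt.k,
                "n_sims_used": len(filt.sims),
                "empirical_p": empirical_p(obs[metric], filt.sims[metric], direction),
                "snp_count_compatible": filt.compatible,
            })
    return pd.DataFrame(rows)
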
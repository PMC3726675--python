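"""Per-gene evidence p-values from three domains and the combined ranking.

Each candidate gene receives one p-value per evidence domain:

* expression — an FDR-corrected differential-expression p-value
  (Benjamini-Hochberg by default; Storey's pi0-adjusted variant optional);
* network proximity — a rank-based p-value from the minimum number of
  protein-interaction steps to any established susceptibility gene;
* literature — a rank-based p-value from the number of search-term
  categories with at least one hit.

The combined score is the sum of -log10 of the three p-values; genes are
ranked by descending score, ties broken by gene id so the ranking is a
deterministic permutation.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("szprior")

#: Sentinel for genes with no path to any network seed (compares worse than
#: every finite step count).
UNREACHABLE = math.inf


def bh_qvalues(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} (N * p_(j) / j), clipped to 1; monotone
    non-decreasing in p.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(n)
    q[order] = q_sorted
    return q


def storey_qvalues(pvalues: Iterable[float], lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a fixed-lambda pi0 estimate.

    pi0 = #{p > lambda} / ((1 - lambda) N), clipped to (0, 1]; q-values are
    the BH values scaled by pi0.  With pi0 = 1 this reduces to BH.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    pi0 = np.count_nonzero(p > lam) / ((1.0 - lam) * p.size)
    pi0 = min(max(pi0, 1.0 / p.size), 1.0)
    return np.minimum(1.0, pi0 * bh_qvalues(p))


def ppi_min_steps(
    edges: pd.DataFrame | Iterable[tuple[str, str]],
    seed_genes: Iterable[str],
    all_genes: Iterable[str] | None = None,
) -> dict[str, float]:
    """Minimum interaction steps from any seed gene, by breadth-first search.

    Seeds are distance 0 from themselves.  Genes absent from the network or
    in a component containing no seed map to ``UNREACHABLE`` (when
    *all_genes* is given, every listed gene appears in the result).
    """
    seeds = list(seed_genes)
    if not seeds:
        raise ValueError("at least one seed gene is required")
    if isinstance(edges, pd.DataFrame):
        pairs = edges.iloc[:, :2].itertuples(index=False, name=None)
    else:
        pairs = edges
    graph = nx.Graph(pairs)
    missing = [s for s in seeds if s not in graph]
    if missing:
        raise ValueError(f"seed genes absent from the network: {missing}")
    steps: dict[str, float] = dict(
        nx.multi_source_dijkstra_path_length(graph, seeds, weight=None)
    )
    for node in graph.nodes:
        steps.setdefault(node, UNREACHABLE)
    if all_genes is not None:
        for g in all_genes:
            steps.setdefault(g, UNREACHABLE)
    return steps


def literature_category_score(row: Iterable[int]) -> int:
    """Number of search-term categories with at least one literature hit."""
    arr = np.asarray(list(row))
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("literature hit matrix entries must be 0 or 1")
    return int(arr.sum())


def rank_to_pvalue(
    values: Iterable[float], lower_is_better: bool = True,
    method: str = "midrank",
) -> np.ndarray:
    """Convert raw domain values to rank-based p-values in (0, 1].

    Ties receive the mean of the ranks they span (midrank); the untied best
    value maps to 1/N.  ``UNREACHABLE`` (inf) sentinels are allowed and rank
    worse than any finite value.  ``method='rank_n1'`` uses rank/(N+1)
    instead of rank/N.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("cannot rank an empty value list")
    ranks = stats.rankdata(v if lower_is_better else -v, method="average")
    if method == "midrank":
        return ranks / v.size
    if method == "rank_n1":
        return ranks / (v.size + 1)
    raise ValueError(f"unknown rank->p method {method!r}")


def build_evidence_table(
    gene_ids: Iterable[str],
    expression: pd.DataFrame,
    ppi_edges: pd.DataFrame,
    literature: pd.DataFrame,
    seed_genes: Iterable[str],
    fdr: str = "bh",
    rank_method: str = "midrank",
) -> pd.DataFrame:
    """Assemble the per-gene evidence table over the three domains.

    Genes missing from the expression table receive p_expr = 1 (no evidence)
    and are counted in the log.  Unreachable network genes share the worst
    midrank.  Returns columns gene_id, p_expr, steps, p_ppi, lit_categories,
    p_lit.
    """
    ids = list(gene_ids)
    expr = expression.set_index("gene_id")["p"]
    adjust = {"bh": bh_qvalues, "storey": storey_qvalues}[fdr]
    expr_adj = pd.Series(adjust(expr.to_numpy()), index=expr.index)
    p_expr = expr_adj.reindex(ids)
    n_missing = int(p_expr.isna().sum())
    if n_missing:
        logger.info("%d genes missing expression evidence; assigned p=1", n_missing)
    p_expr = p_expr.fillna(1.0).clip(lower=np.nextafter(0, 1), upper=1.0)

    steps_map = ppi_min_steps(ppi_edges, seed_genes, all_genes=ids)
    steps = np.array([steps_map[g] for g in ids])
    p_ppi = rank_to_pvalue(steps, lower_is_better=True, method=rank_method)

    lit = literature.set_index("gene_id").reindex(ids).fillna(0).astype(int)
    lit_counts = lit.to_numpy().sum(axis=1)
    p_lit = rank_to_pvalue(lit_counts, lower_is_better=False, method=rank_method)

    return pd.DataFrame({
        "gene_id": ids,
        "p_expr": p_expr.to_numpy(),
        "steps": steps,
        "p_ppi": p_ppi,
        "lit_categories": lit_counts,
        "p_lit": p_lit,
    })


def combine_and_rank(evidence: pd.DataFrame) -> pd.DataFrame:
    """Sum -log10 of the three domain p-values and rank genes by the total.

    Highest score ranks first; ties break lexicographically by gene id.
    Returns columns gene_id, score, rank with ranks a permutation of 1..N.
    """
    for col in ("p_expr", "p_ppi", "p_lit"):
        p = evidence[col].to_numpy(dtype=float)
        if np.any(p <= 0):
            raise ValueError(f"{col} contains non-positive values; -log10 undefined")
        if np.any(p > 1):
            raise ValueError(f"{col} contains values above 1")
    score = -(
        np.log10(evidence["p_expr"].to_numpy())
        + np.log10(evidence["p_ppi"].to_numpy())
        + np.log10(evidence["p_lit"].to_numpy())
    )
    out = pd.DataFrame({"gene_id": evidence["gene_id"], "score": score})
    out = out.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
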
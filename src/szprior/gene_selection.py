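"""Gene selection for genotyping: hypothesis set, rank set, and categories.

Two overlapping selections feed the custom genotyping array: a hypothesis
set (all genes annotated with neurodevelopment GO terms) and a rank-based
set (top-ranked genes greedily added while their tag-SNP counts fit the
remaining array budget; hypothesis genes are pre-allocated and consume no
budget).  The union is partitioned into three analysis categories:

1. hypothesis AND highly ranked,
2. hypothesis only,
3. highly ranked only.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("szprior")

DEFAULT_HYPOTHESIS_TERMS = ("nervous system development", "brain development")


def select_hypothesis_genes(
    go_table: pd.DataFrame, terms: Iterable[str] = DEFAULT_HYPOTHESIS_TERMS
) -> set[str]:
    """Genes annotated with any of the listed GO term labels.

    Matching is by exact label, case-insensitive.  An empty annotation table
    yields an empty set with a warning (no hypothesis genes is legal but
    almost certainly a data problem).
    """
    wanted = {t.strip().lower() for t in terms}
    if not wanted:
        raise ValueError("hypothesis term list must be nonempty")
    if go_table.empty:
        logger.warning("GO annotation table is empty; hypothesis set is empty")
        return set()
    hit = go_table["term"].str.strip().str.lower().isin(wanted)
    return set(go_table.loc[hit, "gene_id"])


@dataclasses.dataclass
class RankSelection:
    genes: set[str]
    rank_cutoff: int  # rank of the deepest gene admitted (0 if none)
    budget_used: int


def select_rank_based(
    ranking: pd.DataFrame,
    snp_counts: Mapping[str, int],
    hypothesis_set: set[str],
    snp_budget: int,
) -> RankSelection:
    """Greedy top-ranked selection under a tag-SNP budget.

    Iterates genes in rank order.  Hypothesis genes consume no budget (their
    SNPs are pre-allocated on the array) and are admitted to the rank set
    for free; other genes are admitted if their SNP count fits the remaining
    budget, and skipped otherwise without terminating the scan
    (skip-and-continue).  The scan ends when the array is full: no
    not-yet-scanned budget-consuming gene fits the remaining budget.
    """
    if snp_budget < 0:
        raise ValueError("snp_budget must be non-negative")
    ordered = list(ranking.sort_values("rank").itertuples(index=False))
    # smallest budget-consuming gene at or after each position: once the
    # remaining budget drops below it, nothing ahead can be added
    suffix_min = [np.inf] * (len(ordered) + 1)
    for i in range(len(ordered) - 1, -1, -1):
        gene = ordered[i].gene_id
        own = np.inf if gene in hypothesis_set else int(snp_counts[gene])
        suffix_min[i] = min(own, suffix_min[i + 1])

    selected: set[str] = set()
    cutoff = 0
    remaining = snp_budget
    for i, row in enumerate(ordered):
        if remaining < suffix_min[i]:
            break
        gene = row.gene_id
        if gene in hypothesis_set:
            selected.add(gene)
            cutoff = row.rank
            continue
        count = int(snp_counts[gene])
        if count <= remaining:
            selected.add(gene)
            remaining -= count
            cutoff = row.rank
    return RankSelection(genes=selected, rank_cutoff=int(cutoff),
                         budget_used=snp_budget - remaining)


def assign_categories(
    hypothesis_set: set[str], rank_set: set[str]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Partition the selected union into the three analysis categories.

    Category 1 = hypothesis ∩ rank, 2 = hypothesis only, 3 = rank only.
    Returns the per-gene table (gene_id, selected, category, reason) and the
    size summary {1, 2, 3, total, hypothesis, rank}.
    """
    both = hypothesis_set & rank_set
    hyp_only = hypothesis_set - rank_set
    rank_only = rank_set - hypothesis_set
    rows = (
        [(g, 1, "both") for g in sorted(both)]
        + [(g, 2, "hypothesis") for g in sorted(hyp_only)]
        + [(g, 3, "rank") for g in sorted(rank_only)]
    )
    table = pd.DataFrame(rows, columns=["gene_id", "category", "reason"])
    table.insert(1, "selected", True)
    sizes = {
        "1": len(both),
        "2": len(hyp_only),
        "3": len(rank_only),
        "total": len(both) + len(hyp_only) + len(rank_only),
        "hypothesis": len(hypothesis_set),
        "rank": len(rank_set),
    }
    return table, sizes
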
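"""Per-SNP association summaries by selection category.

Takes the family-based per-SNP association p-values, maps them onto the
selected genes and their analysis categories, and produces the study's
report tables: the per-gene minimum-p listing, the per-category counts of
nominally significant SNPs against their uniform-null expectations
(n_snps x alpha), experiment-wide Bonferroni/FDR adjustment, and the
genomic inflation factor.

A simplified transmission-disequilibrium count is included so synthetic
PED/MAP trios can be pushed through the whole pipeline; it counts
transmissions from heterozygous parents only and is NOT equivalent to the
haplotype-aware pedigree disequilibrium test used on the real families.
"""

from __future__ import annotations

import logging
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .evidence_ranking import bh_qvalues

logger = logging.getLogger("szprior")

DEFAULT_THRESHOLDS = (0.05, 0.005)

#: Median of the 1-df chi-square distribution (null median of the test
#: statistic), by numerical quantile inversion.
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


def map_snps_to_genes(snps: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Map SNPs onto genes by position (0-based half-open intervals).

    SNPs already carrying a non-null ``gene_id`` keep it; the rest map to
    every gene whose interval contains their position, producing one row per
    (SNP, gene) pair.  Unmapped SNPs are dropped with a logged count.  A
    chromosome present in the SNP table but absent from the gene table is an
    error (almost always a label-convention mismatch).
    """
    has_gene = "gene_id" in snps.columns and snps["gene_id"].notna()
    if isinstance(has_gene, pd.Series):
        keep = snps.loc[has_gene].copy()
        todo = snps.loc[~has_gene].copy()
    else:
        keep = snps.iloc[0:0].copy()
        todo = snps.copy()
    if todo.empty:
        return keep.reset_index(drop=True)

    gene_chroms = set(genes["chrom"])
    offenders = sorted(set(todo["chrom"]) - gene_chroms)
    if offenders:
        raise ValueError(
            f"SNP chromosomes absent from the gene table: {offenders}"
        )
    out_rows = []
    for chrom, chunk in todo.groupby("chrom", sort=False):
        g = genes.loc[genes["chrom"] == chrom]
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        ids = g["gene_id"].to_numpy()
        for row in chunk.itertuples(index=False):
            inside = (starts <= row.pos) & (row.pos < ends)
            for gid in ids[inside]:
                r = row._asdict()
                r["gene_id"] = gid
                out_rows.append(r)
    mapped = pd.DataFrame(out_rows, columns=list(todo.columns))
    n_lost = len(set(todo["snp_id"]) - set(mapped.get("snp_id", ())))
    if n_lost:
        logger.info("dropped %d SNPs mapping to no gene", n_lost)
    return pd.concat([keep, mapped], ignore_index=True)


# ---------------------------------------------------------------------------
# Transmission-test stand-in
# ---------------------------------------------------------------------------

def load_trios(ped_path: str | Path, map_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read headerless PED/MAP files into frames with per-allele columns."""
    map_df = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos"], dtype={"chrom": str},
    )
    cols = ["fid", "iid", "father", "mother", "sex", "phenotype"] + [
        f"{snp}_{a}" for snp in map_df["snp_id"] for a in ("a1", "a2")
    ]
    ped = pd.read_csv(ped_path, sep=r"\s+", header=None, names=cols,
                      dtype={"fid": str, "iid": str, "father": str, "mother": str})
    return ped, map_df


def tdt_standin(ped: pd.DataFrame, map_df: pd.DataFrame, snp_id: str,
                risk_allele: int = 1) -> dict[str, float]:
    """Simplified biallelic transmission test on trios.

    For every child with both parents genotyped, counts transmissions (b)
    and non-transmissions (c) of *risk_allele* from heterozygous parents.
    Statistic (b - c)^2 / (b + c), p from the 1-df chi-square upper tail;
    p = 1 when no parent is informative.  Mendelian-inconsistent trios are
    skipped and counted.  Returns {"b", "c", "statistic", "p", "n_trios",
    "n_skipped"}.
    """
    if snp_id not in set(map_df["snp_id"]):
        raise KeyError(f"SNP {snp_id!r} not in map")
    a1, a2 = f"{snp_id}_a1", f"{snp_id}_a2"
    dose = dict(zip(
        ped["iid"],
        (ped[a1] == risk_allele).to_numpy(dtype=int)
        + (ped[a2] == risk_allele).to_numpy(dtype=int),
    ))
    b = c = 0
    n_trios = n_skipped = 0
    children = ped.loc[(ped["father"] != "0") & (ped["mother"] != "0")]
    for ch in children.itertuples(index=False):
        if ch.father not in dose or ch.mother not in dose:
            continue
        f, m, d = int(dose[ch.father]), int(dose[ch.mother]), int(dose[ch.iid])
        forced = (f == 2) + (m == 2)
        ceiling = 2 - ((f == 0) + (m == 0))
        if not forced <= d <= ceiling:
            n_skipped += 1
            continue
        n_trios += 1
        het = (f == 1) + (m == 1)
        b_trio = d - forced  # risk transmissions attributable to het parents
        b += b_trio
        c += het - b_trio
    if b + c == 0:
        statistic, p = 0.0, 1.0
    else:
        statistic = (b - c) ** 2 / (b + c)
        p = float(stats.chi2.sf(statistic, df=1))
    if n_skipped:
        logger.info("%s: skipped %d Mendelian-inconsistent trios", snp_id, n_skipped)
    return {"b": b, "c": c, "statistic": statistic, "p": p,
            "n_trios": n_trios, "n_skipped": n_skipped}


# ---------------------------------------------------------------------------
# Category summaries
# ---------------------------------------------------------------------------

def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (display convention for expected counts)."""
    q = Decimal(1).scaleb(-decimals)
    d = Decimal(repr(abs(float(x)))).quantize(q, rounding=ROUND_HALF_UP)
    return float(-d if x < 0 else d)


def summarize_category(
    snp_results: pd.DataFrame,
    selection: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-category SNP summary with observed vs. expected significant counts.

    Rows are emitted for categories 1, 2, 3 and the unions "1+2"
    (hypothesis), "1+3" (highly ranked) and "All".  Union rows deduplicate
    SNPs shared by overlapping genes (by snp_id) so that their observed
    counts are counts of distinct SNPs; per-category rows count each
    (SNP, gene) assignment once.  Expected counts are n_snps x alpha, with a
    display value rounded half away from zero to one decimal.  A category
    with zero SNPs yields a flagged row, not an error.
    """
    cat_of = selection.set_index("gene_id")["category"]
    df = snp_results.copy()
    missing = set(df["gene_id"]) - set(cat_of.index)
    if missing:
        raise ValueError(f"SNPs reference genes without a category: {sorted(missing)[:5]}")
    df["category"] = df["gene_id"].map(cat_of)

    def _row(label: str, sub: pd.DataFrame, n_genes: int, dedup: bool) -> dict:
        if dedup:
            sub = sub.drop_duplicates(subset="snp_id")
        rec: dict = {
            "category": label,
            "n_genes": n_genes,
            "n_snps": len(sub),
            "mean_p": sub["p"].mean() if len(sub) else np.nan,
            "min_p": sub["p"].min() if len(sub) else np.nan,
            "empty": len(sub) == 0,
        }
        for a in thresholds:
            rec[f"obs_lt_{a}"] = int((sub["p"] < a).sum())
            rec[f"exp_lt_{a}"] = len(sub) * a
            rec[f"exp_lt_{a}_display"] = round_half_away(len(sub) * a, 1)
        return rec

    gene_counts = selection.groupby("category")["gene_id"].nunique()
    rows = []
    for cat in (1, 2, 3):
        sub = df.loc[df["category"] == cat]
        rows.append(_row(str(cat), sub, int(gene_counts.get(cat, 0)), dedup=False))
    unions = {"1+2": (1, 2), "1+3": (1, 3), "All": (1, 2, 3)}
    for label, cats in unions.items():
        sub = df.loc[df["category"].isin(cats)]
        rows.append(_row(label, sub, int(sum(gene_counts.get(c, 0) for c in cats)),
                         dedup=True))
    return pd.DataFrame(rows)


def gene_min_p_table(
    snp_results: pd.DataFrame,
    selection: pd.DataFrame | None = None,
    ranking: pd.DataFrame | None = None,
    threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-gene minimum-p report of genes with at least one SNP below *threshold*.

    One row per gene (category, rank, n_snps, min_p), ascending by min_p,
    ties broken by gene id.
    """
    agg = (
        snp_results.groupby("gene_id")["p"]
        .agg(n_snps="size", min_p="min")
        .reset_index()
    )
    if selection is not None:
        agg["category"] = agg["gene_id"].map(
            selection.set_index("gene_id")["category"]
        )
    if ranking is not None:
        agg["rank"] = agg["gene_id"].map(ranking.set_index("gene_id")["rank"])
    out = agg.loc[agg["min_p"] < threshold]
    return out.sort_values(["min_p", "gene_id"], kind="stable").reset_index(drop=True)


def adjust_experimentwide(pvalues: Iterable[float]) -> pd.DataFrame:
    """Experiment-wide Bonferroni (min(1, N p)) and BH q-value per SNP."""
    p = np.asarray(list(pvalues), dtype=float)
    return pd.DataFrame({
        "p": p,
        "bonferroni": np.minimum(1.0, p * p.size),
        "q": bh_qvalues(p),
    })


def genomic_lambda(pvalues: Iterable[float] | None = None,
                   chisq: Iterable[float] | None = None) -> float:
    """Genomic inflation factor: median observed 1-df statistic / null median.

    Accepts either p-values (converted to 1-df chi-square quantiles) or the
    chi-square statistics directly.  Approximately 1 under the null.
    """
    if chisq is not None:
        obs = np.asarray(list(chisq), dtype=float)
    elif pvalues is not None:
        p = np.asarray(list(pvalues), dtype=float)
        obs = stats.chi2.isf(p, df=1)
    else:
        raise ValueError("provide pvalues or chisq")
    if obs.size == 0:
        raise ValueError("empty input")
    return float(np.median(obs) / CHI2_1DF_MEDIAN)
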
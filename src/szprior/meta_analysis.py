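"""Fixed-effects inverse-variance meta-analysis with heterogeneity screening.

Candidate SNPs carried forward from the family-based scan are pooled across
external case-control GWAS: study-specific log-odds betas are combined with
weights w_i = 1/se_i^2 (the fixed-effects model), heterogeneity is assessed
with Cochran's Q and I^2, and SNPs with possible between-study
heterogeneity (p_het < 0.05) are removed before reporting.  Effect alleles
must already be harmonized — mismatched allele labels raise rather than
silently flipping signs.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass(frozen=True)
class StudyEffect:
    """One study's estimate for one SNP (log-odds scale)."""
    study: str
    beta: float
    se: float
    effect_allele: str = "A"

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"standard error must be positive, got {self.se}")


@dataclasses.dataclass
class MetaResult:
    snp_id: str
    beta_meta: float
    se_meta: float
    z: float
    p: float
    q: float | None
    i2: float | None
    p_het: float | None
    n_studies: int


def _check_alleles(effects: Sequence[StudyEffect]) -> None:
    alleles = {e.effect_allele.upper() for e in effects}
    if len(alleles) > 1:
        raise ValueError(
            f"effect alleles differ across studies ({sorted(alleles)}); "
            "harmonize before meta-analysis — no silent flipping"
        )


def fixed_effects_meta(effects: Sequence[StudyEffect]) -> tuple[float, float, float, float]:
    """Inverse-variance weighted pooled effect.

    Returns ``(beta_meta, se_meta, z, p)`` with w_i = 1/se_i^2,
    beta = sum(w b)/sum(w), se = sqrt(1/sum(w)), two-sided normal p.
    """
    if not effects:
        raise ValueError("at least one study is required")
    _check_alleles(effects)
    w = np.array([1.0 / e.se**2 for e in effects])
    b = np.array([e.beta for e in effects])
    beta = float((w * b).sum() / w.sum())
    se = float(math.sqrt(1.0 / w.sum()))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return beta, se, z, p


def heterogeneity(effects: Sequence[StudyEffect],
                  beta_meta: float) -> tuple[float, float, float]:
    """Cochran's Q, I^2 (percent) and the asymptotic heterogeneity p.

    Q = sum w_i (b_i - beta_meta)^2 against chi-square with k-1 df;
    I^2 = max(0, (Q - (k-1))/Q) x 100, zero when Q = 0.
    """
    k = len(effects)
    if k < 2:
        raise ValueError("heterogeneity requires at least two studies")
    w = np.array([1.0 / e.se**2 for e in effects])
    b = np.array([e.beta for e in effects])
    q = float((w * (b - beta_meta) ** 2).sum())
    i2 = 0.0 if q == 0 else max(0.0, (q - (k - 1)) / q) * 100.0
    p_het = float(stats.chi2.sf(q, df=k - 1))
    return q, i2, p_het


def meta_analyze_snp(snp_id: str, effects: Sequence[StudyEffect]) -> MetaResult:
    """Pool one SNP across studies; heterogeneity is missing for k = 1."""
    beta, se, z, p = fixed_effects_meta(effects)
    if len(effects) >= 2:
        q, i2, p_het = heterogeneity(effects, beta)
    else:
        q = i2 = p_het = None
    return MetaResult(snp_id=snp_id, beta_meta=beta, se_meta=se, z=z, p=p,
                      q=q, i2=i2, p_het=p_het, n_studies=len(effects))


def meta_analyze_studies(
    studies: dict[str, pd.DataFrame],
    candidate_snps: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Meta-analyze candidate SNPs across per-study summary tables.

    Each study table needs snp_id, beta, se, effect_allele columns.  A SNP
    present in a single study passes through with missing heterogeneity.
    """
    wanted = set(candidate_snps) if candidate_snps is not None else None
    per_snp: dict[str, list[StudyEffect]] = {}
    for study, df in studies.items():
        sub = df if wanted is None else df.loc[df["snp_id"].isin(wanted)]
        for row in sub.itertuples(index=False):
            per_snp.setdefault(row.snp_id, []).append(
                StudyEffect(study=study, beta=float(row.beta), se=float(row.se),
                            effect_allele=str(row.effect_allele))
            )
    rows = [dataclasses.asdict(meta_analyze_snp(s, e)) for s, e in per_snp.items()]
    return pd.DataFrame(
        rows, columns=["snp_id", "beta_meta", "se_meta", "z", "p",
                       "q", "i2", "p_het", "n_studies"],
    )


def meta_screen(
    results: pd.DataFrame,
    p_het_threshold: float = 0.05,
    report_threshold: float = 0.05,
) -> pd.DataFrame:
    """Drop heterogeneous SNPs and flag nominal / Bonferroni significance.

    SNPs with p_het below the threshold are removed (missing p_het — single
    study — passes through); survivors are sorted ascending by pooled p and
    flagged at the nominal level and at report_threshold / n_candidates,
    where n_candidates is the pre-screen SNP count.
    """
    if results.empty:
        return results.assign(nominal=pd.Series(dtype=bool),
                              bonferroni_significant=pd.Series(dtype=bool))
    n_candidates = len(results)
    results = results.assign(p_het=pd.to_numeric(results["p_het"], errors="coerce"))
    het = results["p_het"].notna() & (results["p_het"] < p_het_threshold)
    kept = results.loc[~het].sort_values(["p", "snp_id"], kind="stable").copy()
    kept["nominal"] = kept["p"] < report_threshold
    kept["bonferroni_significant"] = kept["p"] < report_threshold / n_candidates
    return kept.reset_index(drop=True)
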
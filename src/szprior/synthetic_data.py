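"""Synthetic inputs for the candidate-gene prioritization pipeline.

The real study genotyped 3725 tag SNPs in 167 genes drawn from 3819
protein-coding genes under family-linkage peaks, with prior evidence from
three domains (expression meta-analysis, protein-protein interaction
proximity to susceptibility genes, literature support) and evaluation
against external GWAS universes.  All of those raw inputs are
access-controlled, so this module generates structurally equivalent tables
with a configurable planted-signal fraction, letting every downstream stage
run and be tested without any download.

Conventions
-----------
All genomic coordinates are 0-based half-open internally and in the BED/TSV
outputs; positions are converted to 1-based only in PED/MAP output (the one
format that requires it).  One seeded generator per run; each generation
stage draws from its own deterministic substream so stages can be re-run
independently without perturbing each other.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("szprior")

N_CHROMOSOMES = 22

#: Smallest gene interval the placer will emit; a region that cannot give
#: every gene at least this much room triggers a placement error.
MIN_GENE_LENGTH = 200

#: The 29 search terms of the high-throughput literature screen, grouped into
#: the five categories used for per-gene category counting.
LITERATURE_SEARCH_TERMS: dict[str, tuple[str, ...]] = {
    "disease states": (
        "schizophrenia",
        "psychosis",
        "schizoaffective disorder",
        "psychotic disorder",
        "delusion",
        "hallucination",
    ),
    "neurotransmitters": (
        "glutamate",
        "dopamine",
        "serotonin",
        "GABA",
        "acetylcholine",
        "glycine",
    ),
    "neuronal features": (
        "dendrite",
        "axon",
        "synapse",
        "neurite",
        "dendritic spine",
        "synaptic plasticity",
        "myelination",
    ),
    "brain development": (
        "brain development",
        "neurodevelopment",
        "neurogenesis",
        "neuronal migration",
        "cortical development",
    ),
    "brain structures": (
        "cortex",
        "hippocampus",
        "prefrontal cortex",
        "amygdala",
        "striatum",
    ),
}

LITERATURE_CATEGORY_LABELS = tuple(LITERATURE_SEARCH_TERMS)

NEURODEV_GO_TERM = "nervous system development"

# Substream labels: the run RNG is split per stage so that, e.g., regenerating
# the GWAS universe does not shift the gene-universe draw.
_STAGE_IDS = {
    "universe": 1,
    "evidence": 2,
    "association": 3,
    "trios": 4,
    "gwas": 5,
}


class PlacementError(ValueError):
    """The configured genome is too small to place the requested genes."""


@dataclasses.dataclass
class SyntheticConfig:
    """Design constants for one synthetic study.

    Defaults mirror the real study's fixed design: 3819 protein-coding genes
    under 26 autosomal linkage peaks, ~22 tag SNPs per gene (3725/167), three
    external GWAS studies, 265 nuclear families, and a hypothesis-label
    fraction matching the observed 115/3819 neurodevelopment genes.
    """

    n_genes: int = 3819
    n_linkage_regions: int = 26
    genome_length: int = 1_500_000_000
    ppi_n_edges: int = 20_000
    ppi_seed_genes: tuple[str, ...] = ("G0001", "G0002", "G0003")
    n_literature_categories: int = 5
    mean_snps_per_gene: float = 22.3
    frac_associated_genes: float = 0.0
    effect_size: float = 1.0
    n_trios: int = 265
    n_gwas_studies: int = 3
    rng_seed: int = 0

    # Generator knobs referenced by the pipeline's distributional contracts.
    frac_neurodev: float = 0.03
    associate_neurodev: bool = False  # concentrate planted signal in neurodev genes
    expr_beta_a: float = 0.3          # Beta(a, 1) for associated genes' expression p
    ppi_rewire_prob: float = 0.3      # P(direct edge to a seed) per associated gene
    lit_hit_prob_null: float = 0.10
    lit_hit_prob_assoc: float = 0.45
    assoc_maf: float = 0.3            # risk-allele frequency used for planted SNPs
    gwas_n_genes: int = 2000
    gwas_noise: bool = True           # per-study sampling noise on betas

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_linkage_regions", "genome_length",
                     "ppi_n_edges", "n_literature_categories", "n_trios",
                     "n_gwas_studies", "gwas_n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0.0 <= self.frac_associated_genes <= 1.0:
            raise ValueError("frac_associated_genes must lie in [0, 1]")
        if self.mean_snps_per_gene <= 0:
            raise ValueError("mean_snps_per_gene must be positive")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be a positive odds ratio")
        if not 0.0 < self.assoc_maf < 1.0:
            raise ValueError("assoc_maf must lie in (0, 1)")

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic substream for one generation stage."""
        return np.random.default_rng([int(self.rng_seed) % 2**31, _STAGE_IDS[stage]])


def _gene_id(i: int) -> str:
    return f"G{i + 1:04d}"


# ---------------------------------------------------------------------------
# Gene universe and linkage regions
# ---------------------------------------------------------------------------

def gen_gene_universe(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit the gene table and the linkage regions containing the genes.

    Regions emulate autosomal linkage peaks (NPL max >= 2.0, boundaries at
    NPL 1.0); genes are placed non-overlapping within regions, each gene
    inside exactly one region.  Per-gene SNP counts are Poisson with the
    configured mean, floored at 1 (every genotyped gene carried at least one
    tag SNP).

    Returns ``(genes, regions)`` where *genes* has columns gene_id, chrom,
    start, end, snp_count, is_neurodev, is_associated and *regions* has
    chrom, start, end, max_npl.
    """
    rng = config.rng("universe")
    n_reg = config.n_linkage_regions
    region_len = config.genome_length // n_reg
    if region_len < 2:
        raise PlacementError("genome_length too small for the requested regions")

    chroms, starts = [], []
    per_chrom_cursor: dict[str, int] = {}
    for i in range(n_reg):
        chrom = f"chr{(i % N_CHROMOSOMES) + 1}"
        cursor = per_chrom_cursor.get(chrom, 0)
        chroms.append(chrom)
        starts.append(cursor)
        per_chrom_cursor[chrom] = cursor + region_len + 1_000_000  # inter-region gap
    regions = pd.DataFrame({
        "chrom": chroms,
        "start": starts,
        "end": [s + region_len for s in starts],
        "max_npl": 2.0 + rng.exponential(0.5, size=n_reg).round(2),
    })

    # Genes per region, proportional to (equal) region lengths.
    genes_per_region = rng.multinomial(config.n_genes, np.full(n_reg, 1.0 / n_reg))

    rows: list[tuple] = []
    idx = 0
    for r, k in zip(regions.itertuples(index=False), genes_per_region):
        if k == 0:
            continue
        max_len = (r.end - r.start) // (2 * k)
        if max_len < MIN_GENE_LENGTH:
            raise PlacementError(
                f"region {r.chrom}:{r.start}-{r.end} cannot hold {k} genes; "
                "increase genome_length or n_linkage_regions"
            )
        lengths = np.clip(
            rng.lognormal(mean=np.log(2e4), sigma=1.0, size=k).astype(np.int64),
            MIN_GENE_LENGTH, max_len,
        )
        slack = (r.end - r.start) - int(lengths.sum())
        offsets = np.sort(rng.integers(0, slack + 1, size=k))
        gstarts = r.start + offsets + np.concatenate(([0], np.cumsum(lengths[:-1])))
        for s, ln in zip(gstarts, lengths):
            rows.append((_gene_id(idx), r.chrom, int(s), int(s + ln)))
            idx += 1

    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    genes["snp_count"] = np.maximum(
        1, rng.poisson(config.mean_snps_per_gene, size=len(genes))
    )

    n_neuro = int(round(config.frac_neurodev * len(genes)))
    neuro_idx = rng.choice(len(genes), size=n_neuro, replace=False)
    is_neurodev = np.zeros(len(genes), dtype=bool)
    is_neurodev[neuro_idx] = True

    n_assoc = int(round(config.frac_associated_genes * len(genes)))
    is_associated = np.zeros(len(genes), dtype=bool)
    if n_assoc:
        if config.associate_neurodev:
            # Plant signal inside the hypothesis label first, spillover after.
            pool = np.concatenate([
                rng.permutation(np.flatnonzero(is_neurodev)),
                rng.permutation(np.flatnonzero(~is_neurodev)),
            ])
        else:
            pool = rng.permutation(len(genes))
        is_associated[pool[:n_assoc]] = True
    genes["is_neurodev"] = is_neurodev
    genes["is_associated"] = is_associated
    return genes, regions


# ---------------------------------------------------------------------------
# Prior-evidence domains
# ---------------------------------------------------------------------------

def gen_evidence(
    genes: pd.DataFrame, config: SyntheticConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Emit the three prior-evidence inputs plus the GO annotation table.

    Returns ``(expression, ppi, literature, go)``:

    expression
        gene_id, p — Uniform(0,1) for null genes, Beta(a,1) with a<1 for
        genes carrying planted signal (small p enriched).
    ppi
        gene_a, gene_b edge list over gene ids; contains all configured seed
        genes; each planted gene is wired directly to a random seed with
        probability ``ppi_rewire_prob``, remaining edges uniform random.
    literature
        gene_id plus one 0/1 column per category; planted genes have the
        elevated per-category hit probability.
    go
        gene_id, term — the neurodevelopment label for hypothesis genes.
    """
    if genes.empty:
        raise ValueError("gene universe is empty")
    gene_ids = genes["gene_id"].to_numpy()
    known = set(gene_ids)
    for seed in config.ppi_seed_genes:
        if seed not in known:
            raise ValueError(f"PPI seed gene {seed!r} is absent from the gene universe")

    rng = config.rng("evidence")
    assoc = genes["is_associated"].to_numpy()

    p_expr = rng.uniform(size=len(genes))
    if assoc.any():
        p_expr[assoc] = rng.beta(config.expr_beta_a, 1.0, size=int(assoc.sum()))
    expression = pd.DataFrame({"gene_id": gene_ids, "p": p_expr})

    seeds = np.array(config.ppi_seed_genes)
    edges: list[tuple[str, str]] = []
    for g in gene_ids[assoc]:
        if g not in set(seeds) and rng.uniform() < config.ppi_rewire_prob:
            edges.append((str(rng.choice(seeds)), g))
    n_random = max(config.ppi_n_edges - len(edges), 0)
    a = rng.integers(0, len(gene_ids), size=n_random)
    b = rng.integers(0, len(gene_ids), size=n_random)
    ok = a != b
    edges.extend(zip(gene_ids[a[ok]], gene_ids[b[ok]]))
    ppi = pd.DataFrame(edges, columns=["gene_a", "gene_b"]).drop_duplicates()

    n_cat = config.n_literature_categories
    hit_p = np.where(assoc, config.lit_hit_prob_assoc, config.lit_hit_prob_null)
    hits = rng.uniform(size=(len(genes), n_cat)) < hit_p[:, None]
    if n_cat <= len(LITERATURE_CATEGORY_LABELS):
        cols = list(LITERATURE_CATEGORY_LABELS[:n_cat])
    else:
        cols = [f"category_{i + 1}" for i in range(n_cat)]
    literature = pd.DataFrame(hits.astype(int), columns=cols)
    literature.insert(0, "gene_id", gene_ids)

    go = pd.DataFrame({
        "gene_id": gene_ids[genes["is_neurodev"].to_numpy()],
        "term": NEURODEV_GO_TERM,
    })
    return expression, ppi, literature, go


# ---------------------------------------------------------------------------
# Family-based association results (and optional trios)
# ---------------------------------------------------------------------------

def _tdt_noncentrality(effect_size: float, n_trios: int, maf: float) -> float:
    # Transmission probability from a heterozygous parent under OR = effect_size;
    # expected informative transmissions = 2 parents x het frequency per trio.
    pi = effect_size / (1.0 + effect_size)
    n_informative = 2.0 * n_trios * 2.0 * maf * (1.0 - maf)
    return n_informative * (2.0 * pi - 1.0) ** 2


def gen_association_data(
    genes: pd.DataFrame, config: SyntheticConfig, with_trios: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Emit per-SNP family-based association results for the candidate genes.

    Each gene contributes ``snp_count`` SNPs placed uniformly in its interval.
    Null SNPs draw p ~ Uniform(0,1); SNPs in planted genes draw their p from
    the upper tail of a non-central 1-df chi-square whose non-centrality is
    implied by the configured odds ratio and trio count — the distribution a
    transmission test would produce, without simulating genotypes per SNP.

    With ``with_trios=True`` additionally returns PED and MAP frames carrying
    one causal SNP per planted gene with real transmission distortion, for
    end-to-end smoke testing of the transmission-test stand-in.
    """
    if "snp_count" not in genes:
        raise ValueError("genes must carry snp_count")
    rng = config.rng("association")
    ncp = _tdt_noncentrality(config.effect_size, config.n_trios, config.assoc_maf)

    frames = []
    snp_serial = 0
    for g in genes.itertuples(index=False):
        k = int(g.snp_count)
        if k == 0:
            continue
        pos = np.sort(rng.integers(g.start, g.end, size=k))
        if g.is_associated and ncp > 0:
            stat = stats.ncx2.rvs(df=1, nc=ncp, size=k, random_state=rng)
            p = stats.chi2.sf(stat, df=1)
        else:
            p = rng.uniform(size=k)
        frames.append(pd.DataFrame({
            "snp_id": [f"rs{snp_serial + j + 1:06d}" for j in range(k)],
            "chrom": g.chrom,
            "pos": pos,
            "gene_id": g.gene_id,
            "p": p,
        }))
        snp_serial += k
    snps = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["snp_id", "chrom", "pos", "gene_id", "p"]
    )
    if not with_trios:
        return snps

    ped, map_df = _gen_trios(genes, config)
    return snps, ped, map_df


def _gen_trios(genes: pd.DataFrame, config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One causal biallelic SNP per planted gene, genotyped in n_trios trios.

    Alleles are coded 1 (risk) / 2.  Parents are drawn in Hardy-Weinberg
    proportions at the configured risk-allele frequency; each heterozygous
    parent transmits the risk allele with probability OR/(1+OR).
    """
    rng = config.rng("trios")
    maf, odds = config.assoc_maf, config.effect_size
    pi = odds / (1.0 + odds)
    causal = genes.loc[genes["is_associated"]]
    n = config.n_trios

    map_rows = []
    geno_cols: list[np.ndarray] = []
    for j, g in enumerate(causal.itertuples(index=False)):
        pos = int((g.start + g.end) // 2)
        map_rows.append((g.chrom.removeprefix("chr"), f"causal_{g.gene_id}", 0, pos + 1))
        # parental genotypes: count of risk alleles per parent, HWE at maf
        par = rng.binomial(2, maf, size=(n, 2))
        transmitted = np.where(
            par == 1, rng.uniform(size=(n, 2)) < pi, par == 2
        ).astype(int)  # 1 => risk allele transmitted
        geno_cols.append(np.column_stack([par, transmitted]))

    fam_rows = []
    for t in range(n):
        fam = f"F{t + 1:04d}"
        # per-member allele pairs across SNPs
        father, mother, child = [], [], []
        for col in geno_cols:
            fa_dose, mo_dose, fa_tr, mo_tr = col[t]
            father.extend(_dose_to_alleles(fa_dose))
            mother.extend(_dose_to_alleles(mo_dose))
            child.extend([1 if fa_tr else 2, 1 if mo_tr else 2])
        fam_rows.append([fam, f"{fam}_fa", "0", "0", 1, 1] + father)
        fam_rows.append([fam, f"{fam}_mo", "0", "0", 2, 1] + mother)
        fam_rows.append([fam, f"{fam}_ch", f"{fam}_fa", f"{fam}_mo", 1, 2] + child)

    n_snps = len(map_rows)
    cols = ["fid", "iid", "father", "mother", "sex", "phenotype"] + [
        f"{snp}_{a}" for snp in (r[1] for r in map_rows) for a in ("a1", "a2")
    ]
    ped = pd.DataFrame(fam_rows, columns=cols) if n_snps else pd.DataFrame(
        columns=["fid", "iid", "father", "mother", "sex", "phenotype"]
    )
    map_df = pd.DataFrame(map_rows, columns=["chrom", "snp_id", "cm", "pos"])
    return ped, map_df


def _dose_to_alleles(dose: int) -> list[int]:
    return {0: [2, 2], 1: [1, 2], 2: [1, 1]}[int(dose)]


# ---------------------------------------------------------------------------
# External GWAS universes
# ---------------------------------------------------------------------------

def gen_gwas_universe(config: SyntheticConfig) -> tuple[dict[str, pd.DataFrame], pd.Series]:
    """Emit per-study genome-wide summary statistics and the gene→SNP-count map.

    The universe has ``gwas_n_genes`` genes with a long-tailed (geometric)
    SNP-count distribution, so that random gene sets vary widely in total SNP
    count and SNP-count matching is a real filtering problem.  Planted genes
    (``frac_associated_genes``) share one true log-odds effect,
    log(effect_size), across all studies; per-study betas add sampling noise
    at each SNP's standard error unless ``gwas_noise`` is off.

    Returns ``({study: table}, snp_counts)`` where each table has columns
    snp_id, chrom, pos, gene_id, effect_allele, other_allele, beta, se, p
    (pos is 1-based in this TSV-facing table).
    """
    rng = config.rng("gwas")
    n_genes = config.gwas_n_genes
    mean = max(config.mean_snps_per_gene, 1.001)
    counts = 1 + rng.geometric(1.0 / mean, size=n_genes) - 1
    counts = np.maximum(counts, 1)
    gene_ids = np.array([f"U{i + 1:05d}" for i in range(n_genes)])

    n_assoc = int(round(config.frac_associated_genes * n_genes))
    assoc_gene = np.zeros(n_genes, dtype=bool)
    if n_assoc:
        assoc_gene[rng.choice(n_genes, size=n_assoc, replace=False)] = True

    total = int(counts.sum())
    gene_of_snp = np.repeat(np.arange(n_genes), counts)
    chrom = np.repeat(
        [f"chr{(i % N_CHROMOSOMES) + 1}" for i in range(n_genes)], counts
    )
    pos = rng.integers(1, config.genome_length, size=total)
    alleles = np.array(["A", "C", "G", "T"])
    ea = rng.choice(alleles, size=total)
    oa = alleles[(np.searchsorted(alleles, ea) + rng.integers(1, 4, size=total)) % 4]
    true_beta = np.where(assoc_gene[gene_of_snp], np.log(config.effect_size), 0.0)
    se = rng.uniform(0.03, 0.08, size=total)

    studies: dict[str, pd.DataFrame] = {}
    for s in range(config.n_gwas_studies):
        noise = rng.normal(0.0, se) if config.gwas_noise else 0.0
        beta = true_beta + noise
        z = beta / se
        studies[f"study{s + 1}"] = pd.DataFrame({
            "snp_id": [f"gw{j + 1:07d}" for j in range(total)],
            "chrom": chrom,
            "pos": pos + 1,  # 1-based in GWAS TSVs
            "gene_id": gene_ids[gene_of_snp],
            "effect_allele": ea,
            "other_allele": oa,
            "beta": beta,
            "se": se,
            "p": 2.0 * stats.norm.sf(np.abs(z)),
        })
    snp_counts = pd.Series(counts, index=gene_ids, name="snp_count")
    return studies, snp_counts


# ---------------------------------------------------------------------------
# On-disk emission
# ---------------------------------------------------------------------------

def write_study_inputs(config: SyntheticConfig, out_dir: str | Path,
                       with_trios: bool = False) -> dict[str, Path]:
    """Generate every pipeline input and write it under *out_dir*.

    Emits genes.tsv, regions.bed, expression.tsv, ppi.tsv, literature.tsv,
    go.tsv, snps.tsv, gwas_<study>.tsv and optionally trios.ped/trios.map.
    Returns a name→path map of everything written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes, regions = gen_gene_universe(config)
    expression, ppi, literature, go = gen_evidence(genes, config)
    assoc = gen_association_data(genes, config, with_trios=with_trios)
    if with_trios:
        snps, ped, map_df = assoc
    else:
        snps = assoc
    studies, _ = gen_gwas_universe(config)

    paths: dict[str, Path] = {}

    def _tsv(name: str, df: pd.DataFrame, **kw) -> None:
        p = out / name
        df.to_csv(p, sep="\t", index=False, **kw)
        paths[name] = p

    _tsv("genes.tsv", genes)
    regions.to_csv(out / "regions.bed", sep="\t", index=False, header=False)
    paths["regions.bed"] = out / "regions.bed"
    _tsv("expression.tsv", expression)
    _tsv("ppi.tsv", ppi)
    _tsv("literature.tsv", literature)
    _tsv("go.tsv", go)
    _tsv("snps.tsv", snps)
    for study, df in studies.items():
        _tsv(f"gwas_{study}.tsv", df)
    if with_trios:
        ped.to_csv(out / "trios.ped", sep=" ", index=False, header=False)
        map_df.to_csv(out / "trios.map", sep="\t", index=False, header=False)
        paths["trios.ped"] = out / "trios.ped"
        paths["trios.map"] = out / "trios.map"
    logger.info("wrote %d synthetic input files to %s", len(paths), out)
    return paths
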
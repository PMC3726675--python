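"""SNP-to-gene mapping, category summary tables, corrections, lambda."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from szprior import (
    adjust_experimentwide,
    gene_min_p_table,
    genomic_lambda,
    map_snps_to_genes,
    round_half_away,
    summarize_category,
)


@pytest.fixture
def gene_table():
    return pd.DataFrame({
        "gene_id": ["gA", "gB", "gC"],
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [50, 100, 0],
        "end": [150, 200, 500],
    })


def _snps(rows):
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "gene_id", "p"])


class TestMapping:
    def test_position_inside_half_open_interval(self, gene_table):
        snps = _snps([("s1", "chr1", 100, None, 0.5), ("s2", "chr1", 150, None, 0.5)])
        out = map_snps_to_genes(snps, gene_table)
        # pos 100 is inside both gA [50,150) and gB [100,200); pos 150 only gB
        assert sorted(out.loc[out["snp_id"] == "s1", "gene_id"]) == ["gA", "gB"]
        assert list(out.loc[out["snp_id"] == "s2", "gene_id"]) == ["gB"]

    def test_explicit_gene_id_is_kept(self, gene_table):
        snps = _snps([("s1", "chr1", 100, "gC", 0.5)])
        out = map_snps_to_genes(snps, gene_table)
        assert list(out["gene_id"]) == ["gC"]

    def test_unmapped_snps_dropped(self, gene_table):
        snps = _snps([("s1", "chr1", 10, None, 0.5)])
        assert map_snps_to_genes(snps, gene_table).empty

    def test_chromosome_mismatch_lists_offenders(self, gene_table):
        snps = _snps([("s1", "chrX", 10, None, 0.5)])
        with pytest.raises(ValueError, match="chrX"):
            map_snps_to_genes(snps, gene_table)


class TestCategorySummary:
    def _inputs(self, n1=1271, n2=1525, n3=929, seed=0):
        rng = np.random.default_rng(seed)
        sel = pd.DataFrame({
            "gene_id": ["gA", "gB", "gC"],
            "category": [1, 2, 3],
        })
        rows = []
        for gene, n in zip(("gA", "gB", "gC"), (n1, n2, n3)):
            for i in range(n):
                rows.append((f"{gene}_s{i}", "chr1", i, gene, rng.uniform()))
        return _snps(rows), sel

    def test_expected_counts_match_printed_table(self):
        """The study's hypothesis (1+2) and ranked (1+3) unions carried 2796
        and 2200 SNPs, with expected significant counts n_snps x alpha."""
        snps, sel = self._inputs()
        out = summarize_category(snps, sel).set_index("category")
        assert out.loc["1+2", "n_snps"] == 2796
        assert out.loc["1+2", "exp_lt_0.05_display"] == 139.8
        assert out.loc["1+2", "exp_lt_0.005_display"] == 14.0
        assert out.loc["1+3", "n_snps"] == 2200
        assert out.loc["1+3", "exp_lt_0.05_display"] == 110.0
        assert out.loc["1+3", "exp_lt_0.005_display"] == 11.0
        assert out.loc["All", "n_snps"] == 3725
        assert out.loc["All", "exp_lt_0.05_display"] == 186.3

    def test_union_rows_sum_constituent_categories(self):
        snps, sel = self._inputs(100, 200, 50)
        out = summarize_category(snps, sel).set_index("category")
        assert out.loc["1+2", "n_snps"] == out.loc["1", "n_snps"] + out.loc["2", "n_snps"]
        assert out.loc["1+3", "n_snps"] == out.loc["1", "n_snps"] + out.loc["3", "n_snps"]
        for a in ("0.05", "0.005"):
            col = f"obs_lt_{a}"
            assert out.loc["All", col] == out.loc[["1", "2", "3"], col].sum()

    def test_all_p_one_gives_zero_observed(self):
        snps, sel = self._inputs(10, 10, 10)
        snps["p"] = 1.0
        out = summarize_category(snps, sel)
        assert (out["obs_lt_0.05"] == 0).all()

    def test_empty_category_flagged_not_raised(self):
        snps, sel = self._inputs(10, 10, 10)
        snps = snps[snps["gene_id"] != "gB"]
        out = summarize_category(snps, sel).set_index("category")
        assert out.loc["2", "empty"]
        assert out.loc["2", "n_snps"] == 0 and np.isnan(out.loc["2", "mean_p"])

    def test_shared_snp_deduplicated_in_union_rows(self):
        sel = pd.DataFrame({"gene_id": ["gA", "gB"], "category": [1, 2]})
        snps = _snps([
            ("s1", "chr1", 5, "gA", 0.01),
            ("s1", "chr1", 5, "gB", 0.01),  # same SNP in an overlapping gene
            ("s2", "chr1", 6, "gB", 0.5),
        ])
        out = summarize_category(snps, sel).set_index("category")
        assert out.loc["1", "n_snps"] == 1 and out.loc["2", "n_snps"] == 2
        assert out.loc["1+2", "n_snps"] == 2  # s1 counted once
        assert out.loc["All", "obs_lt_0.05"] == 1

    def test_uncategorized_gene_is_an_error(self):
        snps, sel = self._inputs(5, 5, 5)
        with pytest.raises(ValueError):
            summarize_category(snps, sel.iloc[:2])


def _trio_rows(fid, father_geno, mother_geno, child_geno):
    return [
        [fid, f"{fid}_fa", "0", "0", 1, 1, *father_geno],
        [fid, f"{fid}_mo", "0", "0", 2, 1, *mother_geno],
        [fid, f"{fid}_ch", f"{fid}_fa", f"{fid}_mo", 1, 2, *child_geno],
    ]


def _ped(rows):
    cols = ["fid", "iid", "father", "mother", "sex", "phenotype", "snp_a1", "snp_a2"]
    return pd.DataFrame(rows, columns=cols)


_MAP = pd.DataFrame([["1", "snp", 0, 100]], columns=["chrom", "snp_id", "cm", "pos"])


class TestTdtStandin:
    def test_balanced_transmissions_give_p_one(self):
        from szprior import tdt_standin
        rows = _trio_rows("F1", (1, 2), (1, 2), (1, 2))  # both het, child het
        res = tdt_standin(_ped(rows), _MAP, "snp")
        assert res["b"] == res["c"] == 1
        assert res["statistic"] == 0.0 and res["p"] == 1.0

    def test_one_sided_transmissions_statistic(self):
        from szprior import tdt_standin
        # 10 trios, het father always transmits allele 1 (child gets 1 from
        # father, 2 from homozygous-2 mother)
        rows = []
        for i in range(10):
            rows += _trio_rows(f"F{i}", (1, 2), (2, 2), (1, 2))
        res = tdt_standin(_ped(rows), _MAP, "snp")
        assert (res["b"], res["c"]) == (10, 0)
        assert res["statistic"] == pytest.approx(10.0)

    def test_no_informative_parents_gives_p_one(self):
        from szprior import tdt_standin
        rows = _trio_rows("F1", (1, 1), (2, 2), (1, 2))
        res = tdt_standin(_ped(rows), _MAP, "snp")
        assert res["b"] + res["c"] == 0 and res["p"] == 1.0

    def test_mendelian_inconsistency_skipped(self):
        from szprior import tdt_standin
        rows = _trio_rows("F1", (2, 2), (2, 2), (1, 1))  # impossible child
        res = tdt_standin(_ped(rows), _MAP, "snp")
        assert res["n_skipped"] == 1 and res["n_trios"] == 0

    def test_null_transmission_type_one_error_rate(self):
        """With no distortion the stand-in rejects at ~alpha."""
        from szprior import tdt_standin
        rng = np.random.default_rng(8)
        n_snps, n_trios, alpha = 400, 60, 0.05
        rejections = 0
        for s in range(n_snps):
            rows = []
            for t in range(n_trios):
                fa, mo = rng.binomial(1, 0.5, size=2) + 1, rng.binomial(1, 0.5, size=2) + 1
                child = (fa[rng.integers(2)], mo[rng.integers(2)])
                rows += _trio_rows(f"F{t}", tuple(fa), tuple(mo), child)
            if tdt_standin(_ped(rows), _MAP, "snp")["p"] < alpha:
                rejections += 1
        sd = np.sqrt(alpha * (1 - alpha) * n_snps)
        assert abs(rejections - alpha * n_snps) <= 3 * sd

    def test_unknown_snp_errors(self):
        from szprior import tdt_standin
        with pytest.raises(KeyError):
            tdt_standin(_ped(_trio_rows("F1", (1, 2), (1, 2), (1, 2))), _MAP, "nope")


def test_round_half_away():
    assert round_half_away(139.75, 1) == 139.8
    assert round_half_away(139.85, 1) == 139.9
    assert round_half_away(-1.25, 1) == -1.3
    assert round_half_away(110.0, 1) == 110.0


class TestGeneMinP:
    def test_sorted_and_filtered(self):
        snps = _snps([
            ("s1", "chr1", 1, "gA", 0.0005),
            ("s2", "chr1", 2, "gA", 0.9),
            ("s3", "chr1", 3, "gB", 0.002),
            ("s4", "chr1", 4, "gC", 0.5),
        ])
        out = gene_min_p_table(snps, threshold=0.01)
        assert list(out["gene_id"]) == ["gA", "gB"]
        assert out.loc[0, "min_p"] == 0.0005 and out.loc[0, "n_snps"] == 2

    def test_tied_min_p_breaks_by_gene_id(self):
        snps = _snps([
            ("s1", "chr1", 1, "gB", 0.001),
            ("s2", "chr1", 2, "gA", 0.001),
        ])
        out = gene_min_p_table(snps)
        assert list(out["gene_id"]) == ["gA", "gB"]

    def test_category_and_rank_columns(self):
        snps = _snps([("s1", "chr1", 1, "gA", 0.001)])
        sel = pd.DataFrame({"gene_id": ["gA"], "category": [2]})
        ranking = pd.DataFrame({"gene_id": ["gA"], "rank": [954]})
        out = gene_min_p_table(snps, selection=sel, ranking=ranking)
        assert out.loc[0, "category"] == 2 and out.loc[0, "rank"] == 954


class TestAdjustment:
    def test_bonferroni_clips_at_one(self):
        # the study's top SNP: p = 0.000536 across 3725 tests -> 1.996 -> 1.0
        p = np.full(3725, 0.9)
        p[0] = 0.000536
        out = adjust_experimentwide(p)
        assert out.loc[0, "bonferroni"] == 1.0

    def test_single_test_is_unchanged(self):
        out = adjust_experimentwide([0.05])
        assert out.loc[0, "bonferroni"] == 0.05 and out.loc[0, "q"] == 0.05

    def test_qvalues_monotone_in_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        out = adjust_experimentwide(p).sort_values("p")
        assert (np.diff(out["q"]) >= -1e-12).all()


class TestGenomicLambda:
    def test_statistics_at_null_median_give_one(self):
        m = stats.chi2.ppf(0.5, 1)
        assert genomic_lambda(chisq=[m, m, m]) == pytest.approx(1.0)

    def test_doubling_statistics_doubles_lambda(self):
        rng = np.random.default_rng(2)
        x = stats.chi2.rvs(1, size=1001, random_state=rng)
        assert genomic_lambda(chisq=2 * x) == pytest.approx(2 * genomic_lambda(chisq=x))

    def test_uniform_pvalues_give_lambda_one(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=100_000)
        assert genomic_lambda(pvalues=p) == pytest.approx(1.0, abs=0.02)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            genomic_lambda(chisq=[])
        with pytest.raises(ValueError):
            genomic_lambda()
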
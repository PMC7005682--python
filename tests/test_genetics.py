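"""Genotype QC, Hardy-Weinberg, EM haplotype estimation and LD."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from ffapls.genetics import (
    COMT_LOCI,
    HEA_HAPLOTYPE,
    GenotypeTable,
    QCThresholds,
    assign_hea_groups,
    em_haplotype_freqs,
    hwe_exact_p,
    hwe_test,
    pairwise_ld,
    qc_filter,
    snp_summary,
    _compatible_pairs,
)
from ffapls.synthetic import CohortConfig, simulate_genotypes

from conftest import make_table_from_counts


# ------------------------------------------------------------- summaries ---

class TestSnpSummary:
    def test_allele_freq_from_printed_genotype_freqs(self, table_from_counts):
        # genotype frequencies 0.582/0.358/0.060 at n=500 give exact counts
        t = table_from_counts("rs4680", {"G/G": 291, "A/G": 179, "A/A": 30})
        s = snp_summary(t)
        assert s.allele_freqs["rs4680"]["A"] == pytest.approx(0.239, abs=1e-12)
        assert s.per_locus.loc["rs4680", "maf"] == pytest.approx(0.239)

    def test_perfect_hwe_proportions(self, table_from_counts):
        t = table_from_counts("snp", {"A/A": 25, "A/G": 50, "G/G": 25})
        s = snp_summary(t)
        assert s.allele_freqs["snp"] == {"A": 0.5, "G": 0.5}
        assert s.per_locus.loc["snp", "hwe_p"] == pytest.approx(1.0, abs=1e-9)

    def test_all_het_extreme_departure(self, table_from_counts):
        t = table_from_counts("snp", {"A/G": 100})
        s = snp_summary(t, hwe_method="exact")
        assert s.per_locus.loc["snp", "hwe_p"] < 1e-10

    def test_monomorphic_flagged(self, table_from_counts):
        t = table_from_counts("snp", {"G/G": 50})
        s = snp_summary(t)
        row = s.per_locus.loc["snp"]
        assert row.maf == 0.0 and row.hwe_p == 1.0 and row.monomorphic

    def test_call_rate_counts_missing(self, table_from_counts):
        t = table_from_counts("snp", {"A/A": 8, "A/G": 1, "": 1})
        s = snp_summary(t)
        assert s.per_locus.loc["snp", "call_rate"] == pytest.approx(0.9)


class TestHWEExact:
    @pytest.mark.parametrize("counts", [(10, 5, 5), (30, 10, 2), (4, 1, 16), (25, 13, 12)])
    def test_matches_full_enumeration(self, counts):
        """Exact test equals direct enumeration of genotype configurations."""
        n_het, n1, n2 = counts
        n = n_het + n1 + n2
        n_minor = 2 * min(n1, n2) + n_het
        # oracle: enumerate het counts with weights w(h) proportional to the
        # conditional probability, w(h) = 2^h / (h! r! c!), normalized
        hs = range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
        def w(h):
            r = (n_minor - h) // 2
            c = n - h - r
            return 2**h / (math.factorial(h) * math.factorial(r) * math.factorial(c))
        total = sum(w(h) for h in hs)
        p_obs = w(n_het) / total
        p_oracle = sum(w(h) for h in hs if w(h) / total <= p_obs * (1 + 1e-12)) / total
        assert hwe_exact_p(n_het, n1, n2, midp=False) == pytest.approx(p_oracle, rel=1e-9)

    def test_midp_smaller_than_exact(self):
        assert hwe_exact_p(10, 5, 5, midp=True) < hwe_exact_p(10, 5, 5, midp=False)

    def test_auto_switches_to_chisq_for_large_expected(self):
        # 25/50/25: all expected counts >= 5, chi-square statistic is 0
        assert hwe_test(50, 25, 25, method="auto") == pytest.approx(1.0)


# -------------------------------------------------------------------- QC ---

def _comt_cohort_with_missing(n_complete=338, n_missing=24, seed=5):
    cfg = CohortConfig(n_subjects=n_complete + n_missing, seed=seed)
    table, _ = simulate_genotypes(cfg)
    calls = table.calls.copy()
    rng = np.random.default_rng(seed)
    victims = rng.choice(n_complete + n_missing, size=n_missing, replace=False)
    for k, v in enumerate(victims):
        calls.iloc[v, k % 4] = ""
    return GenotypeTable(calls=calls, alleles=dict(table.alleles))


class TestQcFilter:
    def test_single_missing_locus_drops_subject(self):
        """362 subjects, 24 missing exactly one of four loci -> 338 retained."""
        table = _comt_cohort_with_missing()
        filtered, report = qc_filter(table)
        assert filtered.n_subjects == 338
        assert (report.kind == "subject").sum() == 24
        assert set(report[report.kind == "subject"].reason) == {"missingness"}

    def test_low_maf_snp_dropped(self, table_from_counts):
        t = table_from_counts("rare", {"G/G": 96, "A/G": 8})  # MAF 0.04 < 0.05
        calls = t.calls.copy()
        calls["common"] = ["A/G"] * 50 + ["A/A"] * 30 + ["G/G"] * 24
        t2 = GenotypeTable(calls=calls, alleles={})
        filtered, report = qc_filter(t2, QCThresholds(min_hwe_p=0.0))
        assert "rare" not in filtered.loci
        assert report.set_index("id").loc["rare", "reason"] == "MAF"

    def test_clean_table_unchanged(self):
        cfg = CohortConfig(n_subjects=200, seed=1)
        table, _ = simulate_genotypes(cfg)
        filtered, report = qc_filter(table)
        assert report.empty
        pd.testing.assert_frame_equal(filtered.calls, table.calls)

    def test_all_subjects_excluded_raises(self, table_from_counts):
        t = table_from_counts("snp", {"": 4, "A/G": 6})
        calls = t.calls.copy()
        calls.iloc[:, 0] = ""
        t2 = GenotypeTable(calls=calls, alleles={"snp": ("A", "G")})
        with pytest.raises(ValueError):
            qc_filter(t2, QCThresholds(min_call_rate=-1, min_maf=-1, min_hwe_p=-1))


# -------------------------------------------------------------------- EM ---

def _em_oracle_two_locus(table, n_starts=4):
    """Direct likelihood maximization over the 4-haplotype simplex
    (softmax parametrization, Nelder-Mead from several starts); independent
    of the EM iteration."""
    haps = [a + b for a in table.alleles["L1"] for b in table.alleles["L2"]]
    idx = {h: i for i, h in enumerate(haps)}
    pair_lists = []
    for _, row in table.calls.iterrows():
        pairs = _compatible_pairs([tuple(c.split("/")) for c in row])
        pair_lists.append([(idx[a], idx[b], 1.0 if a == b else 2.0) for a, b in pairs])

    def negloglik(theta):
        f = np.exp(theta - theta.max())
        f = f / f.sum()
        ll = 0.0
        for pairs in pair_lists:
            ll += math.log(max(sum(m * f[i] * f[j] for i, j, m in pairs), 1e-300))
        return -ll

    best = None
    rng = np.random.default_rng(0)
    for s in range(n_starts):
        x0 = rng.normal(0, 1, size=4) if s else np.zeros(4)
        res = optimize.minimize(negloglik, x0, method="Nelder-Mead",
                                options=dict(xatol=1e-12, fatol=1e-14, maxiter=20000))
        if best is None or res.fun < best.fun:
            best = res
    f = np.exp(best.x - best.x.max())
    return dict(zip(haps, f / f.sum()))


class TestEM:
    def test_single_locus_equals_allele_freqs(self, table_from_counts):
        t = table_from_counts("snp", {"A/A": 30, "A/G": 50, "G/G": 20})
        model = em_haplotype_freqs(t)
        s = snp_summary(t)
        for hap, f in model.freqs_dict().items():
            assert f == pytest.approx(s.allele_freqs["snp"][hap], abs=1e-10)

    def test_two_locus_matches_likelihood_oracle(self, two_locus_table):
        model = em_haplotype_freqs(two_locus_table)
        oracle = _em_oracle_two_locus(two_locus_table)
        for hap, f in oracle.items():
            assert model.freqs_dict().get(hap, 0.0) == pytest.approx(f, abs=1e-6)

    def test_loglik_monotone_and_freqs_normalized(self, two_locus_table):
        model = em_haplotype_freqs(two_locus_table)
        trace = np.array(model.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-10)
        assert model.freqs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_recovers_three_common_haplotypes(self):
        cfg = CohortConfig(n_subjects=338, seed=42)
        table, _ = simulate_genotypes(cfg)
        model = em_haplotype_freqs(table)
        common = {h: f for h, f in model.freqs_dict().items() if f > 0.05}
        assert set(common) == {"GCGG", "ATCA", "ACCG"}

    def test_posteriors_sum_to_one(self, two_locus_table):
        model = em_haplotype_freqs(two_locus_table)
        for post in model.diplotype_posteriors.values():
            assert sum(post.values()) == pytest.approx(1.0, abs=1e-12)

    def test_missing_call_rejected(self, table_from_counts):
        t = table_from_counts("snp", {"A/A": 5, "": 1})
        with pytest.raises(ValueError, match="missing"):
            em_haplotype_freqs(t)


# -------------------------------------------------------------------- LD ---

class TestPairwiseLD:
    def test_perfect_coupling(self):
        rows = [("A/A", "C/C")] * 10 + [("G/G", "T/T")] * 10 + [("A/G", "C/T")] * 10
        df = pd.DataFrame(rows, columns=["L1", "L2"],
                          index=[f"S{i}" for i in range(30)])
        t = GenotypeTable(calls=df, alleles={})
        res = pairwise_ld(t, "L1", "L2")
        assert res.d_prime == pytest.approx(1.0, abs=1e-6)

    def test_independent_loci(self):
        # genotype counts at exact HWE/LE proportions for allele freq 0.5
        combos = []
        for g1, n1 in (("A/A", 1), ("A/G", 2), ("G/G", 1)):
            for g2, n2 in (("C/C", 1), ("C/T", 2), ("T/T", 1)):
                combos.extend([(g1, g2)] * (n1 * n2))
        df = pd.DataFrame(combos, columns=["L1", "L2"],
                          index=[f"S{i}" for i in range(len(combos))])
        t = GenotypeTable(calls=df, alleles={})
        res = pairwise_ld(t, "L1", "L2")
        assert abs(res.d_prime) < 1e-6

    def test_monomorphic_flagged(self, table_from_counts):
        t = table_from_counts("L1", {"A/A": 10})
        calls = t.calls.copy()
        calls["L2"] = ["C/T"] * 5 + ["C/C"] * 5
        t2 = GenotypeTable(calls=calls, alleles={})
        res = pairwise_ld(t2, "L1", "L2")
        assert not res.defined

    def test_allele_label_swap_invariance(self, two_locus_table):
        res = pairwise_ld(two_locus_table, "L1", "L2")
        swapped = two_locus_table.calls.copy()
        swap = {"A": "G", "G": "A"}
        swapped["L1"] = swapped["L1"].map(
            lambda c: "/".join(sorted(swap[a] for a in c.split("/"))))
        t2 = GenotypeTable(calls=swapped, alleles={})
        res2 = pairwise_ld(t2, "L1", "L2")
        assert res2.d_prime == pytest.approx(res.d_prime, abs=1e-9)
        assert 0.0 <= res.d_prime <= 1.0

    def test_simulated_cohort_strong_ld(self):
        hits = 0
        for seed in range(20):
            table, _ = simulate_genotypes(CohortConfig(n_subjects=338, seed=seed))
            ok = all(
                pairwise_ld(table, a, b).d_prime > 0.90
                for a, b in itertools.combinations(COMT_LOCI, 2)
            )
            hits += ok
        assert hits >= 19


# ------------------------------------------------------------ HEA groups ---

class TestHeaGroups:
    def test_dosage_labels(self):
        cfg = CohortConfig(n_subjects=400, seed=9)
        table, dips = simulate_genotypes(cfg)
        model = em_haplotype_freqs(table)
        groups = assign_hea_groups(model, HEA_HAPLOTYPE)
        true_copies = (dips[["hap1", "hap2"]] == "HEA").sum(axis=1)
        # maximum-posterior assignment should agree with truth almost always
        agree = (groups.hea_copies == true_copies).mean()
        assert agree > 0.9
        hom = groups[groups.hea_copies == 2]
        assert (hom.group == "homozygous-HEA").all()
        het = groups[groups.hea_copies == 1]
        assert (het.group == "heterozygous-HEA").all()
        non = groups[groups.hea_copies == 0]
        assert (non.group == "non-carrier").all()

    def test_posterior_recorded_and_bounded(self):
        table, _ = simulate_genotypes(CohortConfig(n_subjects=100, seed=2))
        groups = assign_hea_groups(em_haplotype_freqs(table))
        assert ((groups.posterior > 0) & (groups.posterior <= 1 + 1e-12)).all()


# ------------------------------------------------------------------- IO ---

class TestIO:
    def test_vcf_roundtrip(self, tmp_path):
        table, _ = simulate_genotypes(CohortConfig(n_subjects=30, seed=3))
        path = tmp_path / "g.vcf"
        table.to_vcf(path)
        back = GenotypeTable.from_vcf(path, loci=list(COMT_LOCI))
        pd.testing.assert_frame_equal(back.calls, table.calls)

    def test_long_tsv_roundtrip(self, tmp_path):
        cfg = CohortConfig(n_subjects=25, seed=4, missing_rate=0.05)
        table, _ = simulate_genotypes(cfg)
        path = tmp_path / "g.tsv"
        table.to_long_tsv(path)
        back = GenotypeTable.from_long_tsv(path)
        assert back.loci == table.loci  # locus order survives the roundtrip
        pd.testing.assert_frame_equal(back.calls[table.loci], table.calls)
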
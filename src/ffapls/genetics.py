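"""Genotype QC, Hardy-Weinberg and LD statistics, and EM haplotype estimation.

The genetic layer works on unphased biallelic SNP genotypes for a handful of
tightly linked loci (here, the four COMT polymorphisms rs6269, rs4633, rs4818
and rs4680).  Haplotype frequencies are estimated with the classic
expectation-maximisation algorithm over the enumeration of phase-compatible
haplotype pairs, which is exact and fast for <= ~10 loci.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

COMT_LOCI = ("rs6269", "rs4633", "rs4818", "rs4680")
#: high enzymatic activity haplotype over (rs6269, rs4633, rs4818, rs4680)
HEA_HAPLOTYPE = "GCGG"

MISSING = ""


def _norm_call(call: str) -> str:
    """Normalise a genotype call to a sorted 'A/G' string ('' = missing)."""
    if call is None or (isinstance(call, float) and math.isnan(call)) or call == "":
        return MISSING
    call = str(call).replace("|", "/")
    if "/" in call:
        a, b = call.split("/")
    elif len(call) == 2:
        a, b = call[0], call[1]
    else:
        raise ValueError(f"cannot parse genotype call {call!r}")
    if a == "." or b == ".":
        return MISSING
    a, b = sorted((a, b))
    return f"{a}/{b}"


@dataclass
class GenotypeTable:
    """Subjects x loci table of unphased genotype calls.

    ``calls`` is a DataFrame indexed by subject id with one column per locus,
    holding sorted ``"A/G"`` strings (``""`` for missing).  ``alleles`` maps
    each locus to its declared allele set, in a stable order.
    """

    calls: pd.DataFrame
    alleles: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        self.calls = self.calls.map(_norm_call)
        for locus in self.calls.columns:
            if locus not in self.alleles:
                obs = sorted({a for c in self.calls[locus] if c for a in c.split("/")})
                self.alleles[locus] = tuple(obs)
        for locus in self.loci:
            allowed = set(self.alleles[locus])
            for call in self.calls[locus]:
                if call and not set(call.split("/")) <= allowed:
                    raise ValueError(
                        f"call {call!r} at {locus} uses alleles outside {allowed}"
                    )

    @property
    def loci(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def n_subjects(self) -> int:
        return len(self.calls)

    def missing_fraction(self) -> pd.Series:
        """Per-subject fraction of missing calls."""
        return (self.calls == MISSING).mean(axis=1)

    # ---------------------------------------------------------------- IO ---
    @classmethod
    def from_long_tsv(cls, path) -> "GenotypeTable":
        """Read a 3-column TSV: subject, locus, genotype."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        wide = df.pivot(index=df.columns[0], columns=df.columns[1], values=df.columns[2])
        # keep loci in file order, not pivot's alphabetical order
        wide = wide[list(dict.fromkeys(df[df.columns[1]]))]
        wide = wide.fillna(MISSING)
        wide.index.name = None
        wide.columns.name = None
        return cls(calls=wide, alleles={})

    def to_long_tsv(self, path) -> None:
        long = self.calls.stack(future_stack=True).reset_index()
        long.columns = ["subject", "locus", "genotype"]
        long.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_vcf(cls, path, loci: list[str] | None = None) -> "GenotypeTable":
        """Read genotypes from a VCF (GT field) via cyvcf2."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        subjects = list(vcf.samples)
        cols: dict[str, list[str]] = {}
        alleles: dict[str, tuple[str, ...]] = {}
        for var in vcf:
            rsid = var.ID or f"{var.CHROM}:{var.POS}"
            if loci is not None and rsid not in loci:
                continue
            allele_strs = [var.REF] + list(var.ALT)
            calls = []
            for g in var.genotypes:
                a, b = g[0], g[1]
                if a < 0 or b < 0:
                    calls.append(MISSING)
                else:
                    calls.append(_norm_call(f"{allele_strs[a]}/{allele_strs[b]}"))
            cols[rsid] = calls
            alleles[rsid] = tuple(allele_strs)
        df = pd.DataFrame(cols, index=subjects)
        if loci is not None:
            df = df[[l for l in loci if l in df.columns]]
        return cls(calls=df, alleles=alleles)

    def to_vcf(self, path, positions: dict[str, tuple[str, int]] | None = None) -> None:
        """Write a minimal GT-only VCF (alleles ordered as declared: REF first)."""
        lines = ["##fileformat=VCFv4.2", '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(map(str, self.subject_ids)))
        for i, locus in enumerate(self.loci):
            alleles = self.alleles[locus]
            chrom, pos = (positions or {}).get(locus, ("22", i + 1))
            idx = {a: j for j, a in enumerate(alleles)}
            gts = []
            for call in self.calls[locus]:
                if not call:
                    gts.append("./.")
                else:
                    a, b = call.split("/")
                    gts.append(f"{idx[a]}/{idx[b]}")
            alt = ",".join(alleles[1:]) if len(alleles) > 1 else "."
            lines.append(f"{chrom}\t{pos}\t{locus}\t{alleles[0]}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts))
    # trailing newline keeps the file POSIX-friendly
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


# ------------------------------------------------------------------ HWE ---

def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int, midp: bool = True) -> float:
    """Exact Hardy-Weinberg test p-value (Wigginton-style enumeration).

    Conditions on the observed minor-allele count and sums the probabilities
    of all heterozygote counts no more probable than the observed one.  With
    ``midp=True`` only half the observed configuration's probability counts.
    """
    n = n_het + n_hom1 + n_hom2
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    if n == 0:
        return 1.0
    # log-probability of each compatible het count (same parity as n_rare)
    hets = list(range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2))
    logps = []
    for h in hets:
        r_hom = (n_rare - h) // 2
        c_hom = n - h - r_hom
        lp = (
            math.lgamma(n + 1)
            - math.lgamma(h + 1)
            - math.lgamma(r_hom + 1)
            - math.lgamma(c_hom + 1)
            + h * math.log(2)
            + math.lgamma(n_rare + 1)
            + math.lgamma(2 * n - n_rare + 1)
            - math.lgamma(2 * n + 1)
        )
        logps.append(lp)
    probs = np.exp(np.array(logps) - max(logps))
    probs /= probs.sum()
    obs = hets.index(n_het)
    p_obs = probs[obs]
    mask = probs <= p_obs * (1 + 1e-12)
    p = probs[mask].sum()
    if midp:
        p -= 0.5 * p_obs
    return float(min(1.0, p))


def hwe_chisq_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """One-degree-of-freedom chi-square HWE test."""
    n = n_het + n_hom1 + n_hom2
    p = (2 * n_hom1 + n_het) / (2 * n)
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_hom1, n_het, n_hom2], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.nansum((obs - exp) ** 2 / np.where(exp > 0, exp, np.nan))
    return float(stats.chi2.sf(chi2, df=1))


def hwe_test(n_het: int, n_hom1: int, n_hom2: int, method: str = "auto") -> float:
    """HWE p-value.

    ``auto`` uses the chi-square test when every expected genotype count is
    at least 5 and the mid-p exact test otherwise; ``exact`` / ``midp`` /
    ``chisq`` force a variant.
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0 or n_het + 2 * min(n_hom1, n_hom2) == 0:
        return 1.0  # monomorphic: no test
    if method == "auto":
        p = (2 * n_hom1 + n_het) / (2 * n)
        exp = [n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2]
        method = "chisq" if min(exp) >= 5 else "midp"
    if method == "chisq":
        return hwe_chisq_p(n_het, n_hom1, n_hom2)
    if method == "exact":
        return hwe_exact_p(n_het, n_hom1, n_hom2, midp=False)
    if method == "midp":
        return hwe_exact_p(n_het, n_hom1, n_hom2, midp=True)
    raise ValueError(f"unknown HWE method {method!r}")


# ---------------------------------------------------------------- summary ---

@dataclass
class SNPSummary:
    """Per-locus QC summary: call rate, genotype/allele frequencies, MAF, HWE."""

    per_locus: pd.DataFrame
    genotype_freqs: dict[str, dict[str, float]]
    allele_freqs: dict[str, dict[str, float]]


def snp_summary(table: GenotypeTable, hwe_method: str = "auto") -> SNPSummary:
    if table.n_subjects == 0:
        raise ValueError("empty genotype table")
    rows = []
    gt_freqs: dict[str, dict[str, float]] = {}
    al_freqs: dict[str, dict[str, float]] = {}
    for locus in table.loci:
        calls = table.calls[locus]
        obs = calls[calls != MISSING]
        call_rate = len(obs) / len(calls)
        counts = obs.value_counts().to_dict()
        n_obs = len(obs)
        gt_freqs[locus] = {g: c / n_obs for g, c in sorted(counts.items())} if n_obs else {}
        allele_counts: dict[str, int] = {}
        for g, c in counts.items():
            for a in g.split("/"):
                allele_counts[a] = allele_counts.get(a, 0) + c
        total = sum(allele_counts.values())
        freqs = {a: c / total for a, c in sorted(allele_counts.items())} if total else {}
        al_freqs[locus] = freqs
        monomorphic = len(freqs) < 2
        maf = 0.0 if monomorphic else min(freqs.values())
        minor = min(freqs, key=freqs.get) if not monomorphic else None
        if monomorphic:
            hwe_p = 1.0
        else:
            a1, a2 = sorted(freqs, key=freqs.get)  # minor first
            n_het = counts.get("/".join(sorted((a1, a2))), 0)
            n_hom_minor = counts.get(f"{a1}/{a1}", 0)
            n_hom_major = counts.get(f"{a2}/{a2}", 0)
            hwe_p = hwe_test(n_het, n_hom_minor, n_hom_major, method=hwe_method)
        rows.append(
            dict(locus=locus, call_rate=call_rate, n_called=n_obs, maf=maf,
                 minor_allele=minor, hwe_p=hwe_p, monomorphic=monomorphic)
        )
    return SNPSummary(
        per_locus=pd.DataFrame(rows).set_index("locus"),
        genotype_freqs=gt_freqs,
        allele_freqs=al_freqs,
    )


@dataclass
class QCThresholds:
    """QC thresholds, applied as strict inequalities (pass if beyond threshold).

    ``subject_max_missing`` is the largest tolerated per-subject missing
    fraction; with four loci the default 0.0 drops any subject missing one or
    more loci.
    """

    min_call_rate: float = 0.95
    min_maf: float = 0.05
    min_hwe_p: float = 0.05
    subject_max_missing: float = 0.0


def qc_filter(
    table: GenotypeTable, thresholds: QCThresholds | None = None
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Drop failing SNPs, then subjects exceeding the missingness cap.

    Returns the filtered table and an exclusion report (one row per dropped
    SNP or subject, with the failed criterion and its value).
    """
    thresholds = thresholds or QCThresholds()
    summary = snp_summary(table)
    exclusions = []
    keep_loci = []
    for locus, row in summary.per_locus.iterrows():
        if not row.call_rate > thresholds.min_call_rate:
            exclusions.append(("snp", locus, "call_rate", row.call_rate))
        elif not row.maf > thresholds.min_maf:
            exclusions.append(("snp", locus, "MAF", row.maf))
        elif not row.hwe_p > thresholds.min_hwe_p:
            exclusions.append(("snp", locus, "HWE", row.hwe_p))
        else:
            keep_loci.append(locus)
    if not keep_loci:
        raise ValueError("QC removed every SNP")
    sub = table.calls[keep_loci]
    miss = (sub == MISSING).mean(axis=1)
    keep_subj = miss <= thresholds.subject_max_missing
    for sid, frac in miss[~keep_subj].items():
        exclusions.append(("subject", sid, "missingness", frac))
    if not keep_subj.any():
        raise ValueError("QC removed every subject")
    filtered = GenotypeTable(
        calls=sub.loc[keep_subj].copy(),
        alleles={l: table.alleles[l] for l in keep_loci},
    )
    report = pd.DataFrame(exclusions, columns=["kind", "id", "reason", "value"])
    return filtered, report


# ------------------------------------------------------------------- EM ---

@dataclass
class HaplotypeModel:
    """EM-estimated haplotype frequencies and per-subject diplotype posteriors."""

    loci: list[str]
    haplotypes: list[str]          # allele strings over loci
    freqs: np.ndarray              # same order as haplotypes
    loglik_trace: list[float]
    # subject -> {(hap_a, hap_b) sorted: posterior}
    diplotype_posteriors: dict[str, dict[tuple[str, str], float]]
    n_iter: int = 0
    converged: bool = True

    def freq(self, hap: str) -> float:
        return float(self.freqs[self.haplotypes.index(hap)])

    def freqs_dict(self) -> dict[str, float]:
        return {h: float(f) for h, f in zip(self.haplotypes, self.freqs)}


def _compatible_pairs(call_alleles: list[tuple[str, str]]) -> set[tuple[str, str]]:
    """Unordered haplotype pairs consistent with per-locus unphased calls."""
    het_idx = [i for i, (a, b) in enumerate(call_alleles) if a != b]
    pairs = set()
    for assign in itertools.product((0, 1), repeat=len(het_idx)):
        h1, h2 = [], []
        it = iter(assign)
        for i, (a, b) in enumerate(call_alleles):
            if a == b:
                h1.append(a)
                h2.append(a)
            else:
                first = next(it)
                h1.append((a, b)[first])
                h2.append((a, b)[1 - first])
        pair = tuple(sorted(("".join(h1), "".join(h2))))
        pairs.add(pair)
    return pairs


def em_haplotype_freqs(
    table: GenotypeTable,
    loci: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> HaplotypeModel:
    """Maximum-likelihood haplotype frequencies by EM over unphased genotypes.

    Initialised at the product of allele frequencies (linkage equilibrium);
    iterates until the log-likelihood gain drops below ``tol``.  Subjects with
    identical multilocus genotypes are pooled, so the E-step cost scales with
    the number of distinct genotype profiles, not subjects.
    """
    loci = loci or table.loci
    calls = table.calls[loci]
    if (calls == MISSING).any().any():
        bad = calls.index[(calls == MISSING).any(axis=1)][0]
        raise ValueError(f"missing genotype for subject {bad}; run QC first")

    profiles = calls.apply(lambda r: tuple(r), axis=1)
    profile_counts = profiles.value_counts()
    profile_pairs: list[list[tuple[str, str]]] = []
    universe: dict[str, int] = {}
    for prof in profile_counts.index:
        call_alleles = [tuple(c.split("/")) for c in prof]
        pairs = sorted(_compatible_pairs(call_alleles))
        if not pairs:
            raise ValueError(f"no compatible haplotype pair for profile {prof}")
        for a, b in pairs:
            for h in (a, b):
                universe.setdefault(h, len(universe))
        profile_pairs.append(pairs)

    haps = sorted(universe, key=universe.get)
    hidx = {h: i for i, h in enumerate(haps)}
    H = len(haps)

    # initial freqs: product of per-locus allele frequencies, renormalised
    allele_freqs = snp_summary(GenotypeTable(calls=calls.copy(), alleles=dict(table.alleles))).allele_freqs
    freqs = np.array(
        [np.prod([allele_freqs[l][h[k]] for k, l in enumerate(loci)]) for h in haps]
    )
    freqs = freqs / freqs.sum()

    counts = profile_counts.to_numpy(dtype=float)
    pair_i = [np.array([hidx[a] for a, b in pp]) for pp in profile_pairs]
    pair_j = [np.array([hidx[b] for a, b in pp]) for pp in profile_pairs]
    pair_mult = [np.array([1.0 if a == b else 2.0 for a, b in pp]) for pp in profile_pairs]

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        expected = np.zeros(H)
        loglik = 0.0
        for g, cnt in enumerate(counts):
            lik = pair_mult[g] * freqs[pair_i[g]] * freqs[pair_j[g]]
            tot = lik.sum()
            loglik += cnt * math.log(max(tot, 1e-300))
            post = lik / tot
            np.add.at(expected, pair_i[g], cnt * post)
            np.add.at(expected, pair_j[g], cnt * post)
        trace.append(loglik)
        new = expected / expected.sum()
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            freqs = new
            converged = True
            break
        freqs = new

    # final posteriors per subject
    prof_post: dict[tuple, dict[tuple[str, str], float]] = {}
    for g, prof in enumerate(profile_counts.index):
        lik = pair_mult[g] * freqs[pair_i[g]] * freqs[pair_j[g]]
        post = lik / lik.sum()
        prof_post[prof] = {pp: float(p) for pp, p in zip(profile_pairs[g], post)}
    posteriors = {sid: prof_post[prof] for sid, prof in profiles.items()}

    return HaplotypeModel(
        loci=list(loci),
        haplotypes=haps,
        freqs=freqs,
        loglik_trace=trace,
        diplotype_posteriors=posteriors,
        n_iter=it,
        converged=converged,
    )


# ------------------------------------------------------------------- LD ---

@dataclass
class LDResult:
    d: float
    d_prime: float
    defined: bool = True
    note: str = ""


def pairwise_ld(table: GenotypeTable, locus_i: str, locus_j: str) -> LDResult:
    """Two-locus D and |D'| from EM haplotype frequencies.

    D is reported for the pair of alphabetically-first alleles; |D'| is
    invariant to that labelling choice.
    """
    sub = GenotypeTable(calls=table.calls[[locus_i, locus_j]].copy(),
                        alleles={l: table.alleles[l] for l in (locus_i, locus_j)})
    summ = snp_summary(sub)
    for locus in (locus_i, locus_j):
        if len(summ.allele_freqs[locus]) < 2:
            return LDResult(d=float("nan"), d_prime=float("nan"), defined=False,
                            note=f"{locus} monomorphic")
    model = em_haplotype_freqs(sub)
    fd = model.freqs_dict()
    a_alleles = sorted(summ.allele_freqs[locus_i])
    b_alleles = sorted(summ.allele_freqs[locus_j])
    A, B = a_alleles[0], b_alleles[0]
    p_a = sum(f for h, f in fd.items() if h[0] == A)
    p_b = sum(f for h, f in fd.items() if h[1] == B)
    p_ab = fd.get(A + B, 0.0)
    d = p_ab - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    return LDResult(d=float(d), d_prime=float(min(1.0, d_prime)))


# ------------------------------------------------------------ HEA groups ---

HEA_GROUPS = ("homozygous-HEA", "heterozygous-HEA", "non-carrier")


def assign_hea_groups(
    model: HaplotypeModel, hea_definition: str = HEA_HAPLOTYPE
) -> pd.DataFrame:
    """Assign each subject to an HEA-dosage group by maximum-posterior diplotype.

    Copy count of the high-activity haplotype (2/1/0) maps to
    homozygous-HEA / heterozygous-HEA / non-carrier.  Posterior ties are
    broken by lexicographic order of the haplotype-pair label and flagged.
    """
    if len(hea_definition) != len(model.loci):
        raise ValueError("HEA definition length must match the loci")
    rows = []
    for sid, post in model.diplotype_posteriors.items():
        items = sorted(post.items())  # lexicographic tie-break
        best_pair, best_p = max(items, key=lambda kv: kv[1])
        tie = sum(1 for _, p in items if abs(p - best_p) < 1e-12) > 1
        copies = sum(1 for h in best_pair if h == hea_definition)
        rows.append(
            dict(subject=sid, diplotype="/".join(best_pair), posterior=best_p,
                 hea_copies=copies, group=HEA_GROUPS[2 - copies], tie=tie)
        )
    return pd.DataFrame(rows).set_index("subject")
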
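"""Two-block PLS correspondence analysis for genotype-phenotype association.

The categorical block codes each SNP's genotype as disjunctive (one-hot)
indicator columns, weighted by the inverse of the category's relative
frequency so that rare genotypes carry more weight.  The quantitative block
holds z-scored phenotype measures.  The association is summarised by the
singular value decomposition of the cross-block Pearson correlation matrix;
permutation of subjects gives significance, bootstrap resampling gives
salience reliability (bootstrap ratios, percentile CIs, FDR-adjusted p).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genetics import MISSING, GenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class CodedDesign:
    """Weighted disjunctive coding of a genotype table.

    ``indicators`` holds the raw 0/1 one-hot matrix (subjects x categories);
    ``matrix`` the inverse-frequency-weighted, column-centred version.  The
    per-category labels are ``(locus, genotype)`` pairs in locus order.
    """

    indicators: np.ndarray
    matrix: np.ndarray
    weights: np.ndarray
    labels: list[tuple[str, str]]
    category_freqs: np.ndarray
    subject_ids: list

    @property
    def n_subjects(self) -> int:
        return self.indicators.shape[0]

    @property
    def n_categories(self) -> int:
        return self.indicators.shape[1]


def code_genotypes(table: GenotypeTable) -> CodedDesign:
    """One indicator column per observed genotype category per SNP.

    Column weight is 1 / relative frequency of the category; weighted columns
    are centred.  Unobserved categories are omitted (and logged).
    """
    cols: list[np.ndarray] = []
    labels: list[tuple[str, str]] = []
    for locus in table.loci:
        calls = table.calls[locus]
        if (calls == MISSING).any():
            raise ValueError(f"missing genotypes at {locus}; QC before coding")
        cats = sorted(calls.unique())
        possible = {f"{a}/{b}" for a in table.alleles[locus] for b in table.alleles[locus]}
        unobserved = {("/".join(sorted(c.split("/")))) for c in possible} - set(cats)
        if unobserved:
            logger.info("omitting unobserved categories at %s: %s", locus, sorted(unobserved))
        for cat in cats:
            cols.append((calls == cat).to_numpy(dtype=float))
            labels.append((locus, cat))
    indicators = np.column_stack(cols)
    freqs = indicators.mean(axis=0)
    weights = 1.0 / freqs
    weighted = indicators * weights
    matrix = weighted - weighted.mean(axis=0)
    return CodedDesign(
        indicators=indicators,
        matrix=matrix,
        weights=weights,
        labels=labels,
        category_freqs=freqs,
        subject_ids=list(table.subject_ids),
    )


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0, ddof=1)
    if np.any(sd < 1e-14):
        raise ValueError("constant column in block; cannot z-score")
    return (a - a.mean(axis=0)) / sd


def _cross_corr(ind: np.ndarray, y: np.ndarray, metric: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cross-block matrix plus the standardized blocks used for scores."""
    n = ind.shape[0]
    ys = _zscore(y)
    if metric == "correlation":
        xs = _zscore(ind)
        r = xs.T @ ys / (n - 1)
        return r, xs, ys
    if metric == "ca":
        # chi-square metric: centred profiles scaled by 1/sqrt(column mass)
        freqs = ind.mean(axis=0)
        xs = (ind - freqs) / np.sqrt(freqs)
        r = xs.T @ ys / (n - 1)
        return r, xs, ys
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class PLSResult:
    singular_values: np.ndarray
    explained_variance: np.ndarray
    x_saliences: np.ndarray        # categories x LVs
    y_saliences: np.ndarray        # phenotypes x LVs
    x_scores: np.ndarray           # subjects x LVs
    y_scores: np.ndarray
    latent_correlations: np.ndarray
    x_labels: list[tuple[str, str]]
    y_labels: list[str]
    metric: str = "correlation"

    @property
    def n_components(self) -> int:
        return int(np.sum(self.singular_values > 1e-10))


def plsca_fit(
    design: CodedDesign,
    phenotypes: np.ndarray,
    y_labels: list[str] | None = None,
    metric: str = "correlation",
) -> PLSResult:
    """SVD of the cross-block matrix between coded genotypes and phenotypes.

    Latent-variable scores are computed from the same standardized blocks the
    cross-block matrix is built from, so x- and y-scores of distinct LVs are
    exactly cross-orthogonal.  The sign of each LV is fixed by making the
    first phenotype salience of substantial magnitude positive.
    """
    y = np.asarray(phenotypes, dtype=float)
    if y.ndim != 2 or y.shape[0] != design.n_subjects:
        raise ValueError("phenotype block must be subjects x measures")
    r, xs, ys = _cross_corr(design.indicators, y, metric)
    u, s, vt = np.linalg.svd(r, full_matrices=False)
    v = vt.T
    # deterministic sign: the first y-salience of substantial magnitude
    # (>= a quarter of the max) is made positive; anchoring on the earliest
    # participating variable stays stable across replicates even when two
    # saliences tie in magnitude
    for k in range(v.shape[1]):
        mags = np.abs(v[:, k])
        j = int(np.argmax(mags >= 0.25 * mags.max()))
        if v[j, k] < 0:
            v[:, k] = -v[:, k]
            u[:, k] = -u[:, k]
    x_scores = xs @ u
    y_scores = ys @ v
    lat = np.array([
        np.corrcoef(x_scores[:, k], y_scores[:, k])[0, 1] if s[k] > 1e-10 else 0.0
        for k in range(len(s))
    ])
    total = np.sum(s**2)
    explained = s**2 / total if total > 0 else np.zeros_like(s)
    return PLSResult(
        singular_values=s,
        explained_variance=explained,
        x_saliences=u,
        y_saliences=v,
        x_scores=x_scores,
        y_scores=y_scores,
        latent_correlations=lat,
        x_labels=list(design.labels),
        y_labels=list(y_labels or [f"y{k}" for k in range(y.shape[1])]),
        metric=metric,
    )


# ----------------------------------------------------------- permutation ---

@dataclass
class PermutationResult:
    omnibus_p: float               # total cross-block inertia (sum s^2)
    omnibus_p_max_sv: float        # alternative: largest singular value
    per_lv_p: np.ndarray           # rank-matched singular values
    n_perm: int
    seed: int | None = None


def permutation_test(
    design: CodedDesign,
    phenotypes: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    metric: str = "correlation",
) -> PermutationResult:
    """Permute genotype rows against fixed phenotypes; compare singular values.

    The omnibus statistic is the total cross-block inertia (sum of squared
    singular values); per-LV p-values compare singular values rank-for-rank
    (anticonservative for later LVs).  p = (#exceeding + 1) / (n_perm + 1).
    """
    if n_perm < 10:
        raise ValueError("n_perm < 10 is uninterpretable")
    if n_perm < 100:
        logger.warning("n_perm=%d is small; p-value resolution is coarse", n_perm)
    y = np.asarray(phenotypes, dtype=float)
    r, xs, ys = _cross_corr(design.indicators, y, metric)
    s_obs = np.linalg.svd(r, compute_uv=False)
    inertia_obs = float(np.sum(s_obs**2))
    rng = np.random.default_rng(seed)
    n = design.n_subjects
    scale = 1.0 / (n - 1)
    count_inertia = 0
    count_max = 0
    count_lv = np.zeros(len(s_obs), dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        s_p = np.linalg.svd(xs[perm].T @ ys * scale, compute_uv=False)
        inertia = np.sum(s_p**2)
        count_inertia += inertia >= inertia_obs
        count_max += s_p[0] >= s_obs[0]
        count_lv += s_p >= s_obs
    return PermutationResult(
        omnibus_p=(count_inertia + 1) / (n_perm + 1),
        omnibus_p_max_sv=(count_max + 1) / (n_perm + 1),
        per_lv_p=(count_lv + 1) / (n_perm + 1),
        n_perm=n_perm,
        seed=seed,
    )


# ------------------------------------------------------------- bootstrap ---

@dataclass
class BootstrapResult:
    """Per-salience bootstrap ratios, percentile CIs and BH-FDR p-values.

    Arrays are shaped (categories x LVs) for the x block and
    (phenotypes x LVs) for the y block.
    """

    x_bsr: np.ndarray
    y_bsr: np.ndarray
    x_ci: np.ndarray               # categories x LVs x 2
    y_ci: np.ndarray
    x_fdr_p: np.ndarray
    y_fdr_p: np.ndarray
    n_boot: int
    n_redrawn: int = 0
    seed: int | None = None


def _align(u_b, v_b, u0, v0):
    """Match bootstrap LVs to the original ones (greedy on total salience
    similarity) and fix signs."""
    L = u0.shape[1]
    sim = np.abs(u_b.T @ u0) + np.abs(v_b.T @ v0)  # boot LV x orig LV
    order = np.full(L, -1, dtype=int)
    used = set()
    for k in np.argsort(-np.max(sim, axis=0)):  # strongest original first
        cand = [b for b in np.argsort(-sim[:, k]) if b not in used]
        order[k] = cand[0]
        used.add(cand[0])
    u_a = u_b[:, order]
    v_a = v_b[:, order]
    signs = np.sign(np.sum(u_a * u0, axis=0) + np.sum(v_a * v0, axis=0))
    signs[signs == 0] = 1.0
    return u_a * signs, v_a * signs


def bootstrap_saliences(
    design: CodedDesign,
    phenotypes: np.ndarray,
    n_boot: int = 500,
    seed: int | None = None,
    metric: str = "correlation",
    max_redraws: int = 10_000,
) -> BootstrapResult:
    """Resample subjects with replacement and assess salience reliability.

    Each bootstrap solution is matched and sign-aligned to the original fit.
    Bootstrap ratio = original salience / bootstrap SE, treated as standard
    normal for two-tailed p-values, which are BH-FDR adjusted within each
    block and LV.  Resamples that lose a genotype category entirely are
    redrawn (and counted).
    """
    if n_boot < 100:
        logger.warning("n_boot=%d is small; SEs will be noisy", n_boot)
    y = np.asarray(phenotypes, dtype=float)
    fit0 = plsca_fit(design, y, metric=metric)
    u0, v0 = fit0.x_saliences, fit0.y_saliences
    rng = np.random.default_rng(seed)
    n = design.n_subjects
    u_samp = np.empty((n_boot,) + u0.shape)
    v_samp = np.empty((n_boot,) + v0.shape)
    n_redrawn = 0
    b = 0
    draws = 0
    while b < n_boot:
        draws += 1
        if draws > n_boot + max_redraws:
            raise RuntimeError("too many degenerate bootstrap resamples")
        idx = rng.integers(0, n, size=n)
        ind_b = design.indicators[idx]
        if np.any(ind_b.sum(axis=0) == 0):
            n_redrawn += 1
            continue
        y_b = y[idx]
        if np.any(y_b.std(axis=0) < 1e-14):
            n_redrawn += 1
            continue
        r_b, _, _ = _cross_corr(ind_b, y_b, metric)
        u_b, s_b, vt_b = np.linalg.svd(r_b, full_matrices=False)
        u_a, v_a = _align(u_b, vt_b.T, u0, v0)
        u_samp[b] = u_a
        v_samp[b] = v_a
        b += 1

    def summarize(samples, orig):
        se = samples.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            bsr = np.where(se > 0, orig / se, np.inf * np.sign(orig))
        ci = np.stack(
            [np.percentile(samples, 2.5, axis=0), np.percentile(samples, 97.5, axis=0)],
            axis=-1,
        )
        p = 2 * stats.norm.sf(np.abs(bsr))
        fdr = np.empty_like(p)
        for k in range(p.shape[1]):  # BH within block and LV
            fdr[:, k] = multipletests(p[:, k], method="fdr_bh")[1]
        return bsr, ci, fdr

    x_bsr, x_ci, x_fdr = summarize(u_samp, u0)
    y_bsr, y_ci, y_fdr = summarize(v_samp, v0)
    return BootstrapResult(
        x_bsr=x_bsr, y_bsr=y_bsr, x_ci=x_ci, y_ci=y_ci,
        x_fdr_p=x_fdr, y_fdr_p=y_fdr,
        n_boot=n_boot, n_redrawn=n_redrawn, seed=seed,
    )
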
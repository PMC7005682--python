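"""Synthetic cohort generator for the genotype -> brain -> behavior chain.

Emulates a cohort of Han Chinese young adults genotyped at the four linked
COMT SNPs (rs6269, rs4633, rs4818, rs4680), with three-modal ROI phenotypes
(face selectivity FS, resting fALFF, gray-matter volume GMV) per hemisphere
carrying one planted latent component, and old/new recognition behavior
weakly coupled to the latent brain score.

All calibrations are analytic on the population model (no trial-and-error
fitting): the planted latent correlation is decomposed into the
genotype-side attenuation (computable exactly from the diplotype
distribution) and the phenotype-side loading, which is solved by root
finding; the behavioral couplings use a linearized probit-channel model with
delta-method binomial noise terms.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genetics import COMT_LOCI, GenotypeTable

logger = logging.getLogger(__name__)

#: the three common COMT haplotypes over (rs6269, rs4633, rs4818, rs4680)
HAPLOTYPES = {
    "HEA": "GCGG",   # high enzymatic activity
    "MEA": "ATCA",   # intermediate
    "LEA": "ACCG",   # low
    # residual mass when include_other_haplotype is set; the minor recombinant
    # is not named by genotype panels, this allele string is a synthetic choice
    "OTHER": "GCCG",
}

#: frequencies as printed for the three common haplotypes (sum 0.956)
DEFAULT_HAPLOTYPE_FREQS = {"HEA": 0.328, "MEA": 0.239, "LEA": 0.389}

MODALITIES = ("fs", "falff", "gmv")


@dataclass
class SaliencePattern:
    """Planted effect pattern: per-genotype-category effects building the
    latent score, and signed per-modality loadings of that latent.

    The default genotype effect is overdominant (heterozygote +1, homozygotes
    0 at every SNP), matching a heterozygote-advantage architecture; the
    default modality loadings put the latent positively on FS, negatively on
    fALFF and not on GMV.
    """

    genotype_effects: dict[str, dict[str, float]] | None = None
    y_loadings: dict[str, float] = field(
        default_factory=lambda: {"fs": 1.0, "falff": -1.0, "gmv": 0.0}
    )

    def effect(self, locus: str, genotype: str) -> float:
        if self.genotype_effects is not None:
            return self.genotype_effects.get(locus, {}).get(genotype, 0.0)
        a, b = genotype.split("/")
        return 1.0 if a != b else 0.0


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the printed study marginals: n = 338 subjects, the
    three printed haplotype frequencies (renormalized to sum 1), a PLS1
    latent correlation of 0.258, an FRA-latent coupling of 0.138 and a
    new-face-score coupling of 0.162; 135/338 males, age 20.45 (0.96) years,
    Raven 25.3 (5.7).
    """

    n_subjects: int = 338
    haplotype_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAPLOTYPE_FREQS)
    )
    include_other_haplotype: bool = False
    missing_rate: float = 0.0
    latent_corr: float = 0.258
    salience_pattern: SaliencePattern = field(default_factory=SaliencePattern)
    behavior_corr: float = 0.138
    newface_corr: float = 0.162
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"fs": 1.0, "falff": 1.0, "gmv": 300.0}
    )
    modality_means: dict[str, float] = field(
        default_factory=lambda: {"fs": 3.0, "falff": 0.0, "gmv": 2400.0}
    )
    hemisphere_corr: float = 0.79
    # behavior marginals (accuracy percent scale) and trial counts
    n_old: int = 30
    n_new: int = 30
    face_acc_mean: float = 76.0
    face_acc_sd: float = 9.0
    flower_acc_mean: float = 77.7
    flower_acc_sd: float = 9.0
    # covariates
    male_fraction: float = 135 / 338
    age_mean: float = 20.45
    age_sd: float = 0.96
    age_min: float = 17.0
    raven_mean: float = 25.3
    raven_sd: float = 5.7
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = {k: float(v) for k, v in self.haplotype_freqs.items()}
        if any(v < 0 for v in freqs.values()):
            raise ValueError("haplotype frequencies must be nonnegative")
        if self.include_other_haplotype and "OTHER" not in freqs:
            freqs["OTHER"] = max(0.0, 1.0 - sum(freqs.values()))
        total = sum(freqs.values())
        if total <= 0:
            raise ValueError("haplotype frequencies sum to zero")
        if abs(total - 1.0) > 1e-12:
            logger.info("renormalizing haplotype frequencies (sum %.3f) to 1", total)
        self.haplotype_freqs = {k: v / total for k, v in freqs.items()}
        for label in self.haplotype_freqs:
            hap = HAPLOTYPES.get(label, label)
            if len(hap) != len(COMT_LOCI):
                raise ValueError(f"haplotype {label!r} does not cover all 4 loci")
        for name, val in (("latent_corr", self.latent_corr),
                          ("behavior_corr", self.behavior_corr)):
            if not (0 <= val < 1):
                raise ValueError(f"{name} must lie in [0, 1)")

    def haplotype_alleles(self, label: str) -> str:
        return HAPLOTYPES.get(label, label)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


# ----------------------------------------------------- population model ---

#: allele sets per locus implied by the named haplotypes
_LOCUS_ALLELES = {
    "rs6269": ("A", "G"),
    "rs4633": ("C", "T"),
    "rs4818": ("C", "G"),
    "rs4680": ("A", "G"),
}


def _diplotype_distribution(config: CohortConfig):
    """All unordered haplotype pairs with Hardy-Weinberg probabilities."""
    labels = sorted(config.haplotype_freqs)
    pairs, probs = [], []
    for i, a in enumerate(labels):
        for b in labels[i:]:
            fa, fb = config.haplotype_freqs[a], config.haplotype_freqs[b]
            p = fa * fa if a == b else 2 * fa * fb
            if p > 0:
                pairs.append((a, b))
                probs.append(p)
    return pairs, np.array(probs)


def _diplotype_genotypes(config: CohortConfig, pair: tuple[str, str]) -> list[str]:
    h1 = config.haplotype_alleles(pair[0])
    h2 = config.haplotype_alleles(pair[1])
    return ["/".join(sorted((h1[i], h2[i]))) for i in range(len(COMT_LOCI))]


def _population_latent(config: CohortConfig):
    """Exact population structure of the coded-genotype latent.

    Returns (category labels, z-score per diplotype, genotype-side
    attenuation kappa, per-diplotype probabilities, per-diplotype genotype
    profiles).  kappa is the population correlation between the fitted PLS1
    genotype score and the planted latent; it bounds the achievable latent
    correlation.
    """
    pairs, probs = _diplotype_distribution(config)
    profiles = [_diplotype_genotypes(config, p) for p in pairs]
    pattern = config.salience_pattern
    t = np.array([
        sum(pattern.effect(locus, prof[i]) for i, locus in enumerate(COMT_LOCI))
        for prof in profiles
    ])
    mu = float(probs @ t)
    var = float(probs @ (t - mu) ** 2)
    if var < 1e-14:
        return [], np.zeros(len(pairs)), 0.0, probs, profiles
    z = (t - mu) / np.sqrt(var)

    cats = sorted({(locus, prof[i]) for prof in profiles
                   for i, locus in enumerate(COMT_LOCI)})
    M = np.array([[1.0 if prof[COMT_LOCI.index(l)] == g else 0.0 for (l, g) in cats]
                  for prof in profiles])
    p_c = probs @ M
    keep = (p_c > 1e-12) & (p_c < 1 - 1e-12)
    M, p_c = M[:, keep], p_c[keep]
    cats = [c for c, k in zip(cats, keep) if k]
    sd_c = np.sqrt(p_c * (1 - p_c))
    second = (M * probs[:, None]).T @ M
    C = (second - np.outer(p_c, p_c)) / np.outer(sd_c, sd_c)
    rho = ((M * probs[:, None]).T @ z) / sd_c
    denom = float(rho @ C @ rho)
    kappa = float(rho @ rho) / np.sqrt(denom) if denom > 1e-14 else 0.0
    return cats, z, kappa, probs, profiles


def _solve_y_loading(config: CohortConfig, kappa: float) -> float:
    """Scale `a` of the modality loadings such that the population PLS1
    latent correlation equals latent_corr.

    With loading m_k = a * lambda_k * sigma_k the phenotype-side latent
    correlation is A / sqrt(A^2 + B) with q_k = a*lambda_k/sqrt(1+(a*lambda_k)^2),
    A = sum q_k^2, B = sum q_k^2 (1 - q_k^2).
    """
    if config.latent_corr == 0:
        return 0.0
    if kappa <= 0 or config.latent_corr >= kappa:
        raise ValueError(
            f"latent_corr={config.latent_corr} unreachable: the genotype-side "
            f"attenuation bounds it at kappa={kappa:.4f}"
        )
    lam = np.array([config.salience_pattern.y_loadings.get(m, 0.0) for m in MODALITIES])
    target = config.latent_corr / kappa

    def r_y(a: float) -> float:
        q2 = (a * lam) ** 2 / (1 + (a * lam) ** 2)
        A = q2.sum()
        B = (q2 * (1 - q2)).sum()
        return A / np.sqrt(A**2 + B) if A > 0 else 0.0

    hi = 1.0
    while r_y(hi) < target:
        hi *= 2.0
        if hi > 1e8:
            raise ValueError(
                f"latent_corr={config.latent_corr} unreachable with loading "
                f"pattern {lam.tolist()}; phenotype-side ceiling is {r_y(1e8):.4f}"
            )
    return float(optimize.brentq(lambda a: r_y(a) - target, 0.0, hi, xtol=1e-12))


# ------------------------------------------------------------ genotypes ---

def simulate_genotypes(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Draw two haplotypes per subject i.i.d. and derive unphased genotypes.

    Returns the genotype table and the true diplotypes (one row per subject
    with both haplotype labels).  Optional missingness is injected per call
    at ``config.missing_rate``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    labels = sorted(config.haplotype_freqs)
    freqs = np.array([config.haplotype_freqs[l] for l in labels])
    n = config.n_subjects
    draws = rng.choice(len(labels), size=(n, 2), p=freqs)
    subjects = [f"S{i+1:04d}" for i in range(n)]
    hap_strings = {l: config.haplotype_alleles(l) for l in labels}
    calls = {locus: [] for locus in COMT_LOCI}
    dip_rows = []
    for s in range(n):
        a, b = sorted(labels[k] for k in draws[s])
        dip_rows.append((subjects[s], a, b))
        ha, hb = hap_strings[a], hap_strings[b]
        for i, locus in enumerate(COMT_LOCI):
            x, y = sorted((ha[i], hb[i]))
            calls[locus].append(f"{x}/{y}")
    df = pd.DataFrame(calls, index=subjects)
    if config.missing_rate > 0:
        miss = rng.random(df.shape) < config.missing_rate
        df = df.mask(pd.DataFrame(miss, index=df.index, columns=df.columns), "")
    table = GenotypeTable(calls=df, alleles=dict(_LOCUS_ALLELES))
    dips = pd.DataFrame(dip_rows, columns=["subject", "hap1", "hap2"]).set_index("subject")
    return table, dips


# ----------------------------------------------------------- phenotypes ---

def simulate_phenotypes(
    genotypes: GenotypeTable,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Three-modal ROI phenotypes for both hemispheres plus latent scores.

    The per-subject latent z is the standardized coded-genotype effect score;
    FS loads positively, fALFF negatively and GMV not at all (under the
    default pattern), with loadings calibrated analytically so the population
    PLS1 latent correlation equals ``config.latent_corr``.  Hemispheres share
    the latent and have noise correlated at ``config.hemisphere_corr``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    cats, z_by_dip, kappa, probs, profiles = _population_latent(config)
    a = _solve_y_loading(config, kappa)

    # per-subject latent from the observed genotype profile
    pattern = config.salience_pattern
    if kappa > 0:
        t_pop = np.array([
            sum(pattern.effect(l, prof[i]) for i, l in enumerate(COMT_LOCI))
            for prof in profiles
        ])
        mu = float(probs @ t_pop)
        sd = float(np.sqrt(probs @ (t_pop - mu) ** 2))
        t_subj = genotypes.calls.apply(
            lambda row: sum(pattern.effect(l, row[l]) for l in COMT_LOCI), axis=1
        ).to_numpy(dtype=float)
        z = (t_subj - mu) / sd
    else:
        z = np.zeros(genotypes.n_subjects)

    lam = {m: pattern.y_loadings.get(m, 0.0) for m in MODALITIES}
    n = genotypes.n_subjects
    rho = config.hemisphere_corr
    frames = []
    for m in MODALITIES:
        sigma = config.noise_sd[m]
        shared = rng.standard_normal(n)
        for hemi in ("left", "right"):
            own = rng.standard_normal(n)
            noise = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
            vals = config.modality_means[m] + sigma * (a * lam[m] * z + noise)
            frames.append(pd.DataFrame({
                "subject": genotypes.subject_ids, "hemisphere": hemi,
                "modality": m, "value": vals,
            }))
    long = pd.concat(frames, ignore_index=True)
    wide = long.pivot_table(index=["subject", "hemisphere"], columns="modality",
                            values="value", sort=False).reset_index()
    wide.columns.name = None
    wide = wide[["subject", "hemisphere"] + list(MODALITIES)]
    latent = pd.Series(z, index=genotypes.subject_ids, name="latent")
    return wide, latent


# ------------------------------------------------------------ voxel maps ---

@dataclass
class ROISpec:
    """Geometry for synthetic voxel maps: grid, mask margin and one
    contiguous blob per hemisphere (grown by 6-connected BFS)."""

    shape: tuple[int, int, int] = (36, 22, 14)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    blob_size: int = 233
    seeds: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: {"left": (8, 11, 7), "right": (27, 11, 7)}
    )
    blob_z: float = 3.5
    mask_margin: int = 1

    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        s = self.mask_margin
        m[s:-s or None, s:-s or None, s:-s or None] = True
        return m

    def hemisphere_masks(self) -> dict[str, np.ndarray]:
        mask = self.mask()
        mid = self.shape[0] // 2
        left = mask.copy()
        left[mid:] = False
        right = mask.copy()
        right[:mid] = False
        return {"left": left, "right": right}

    def grow_blob(self, hemisphere: str) -> np.ndarray:
        """Deterministic 6-connected region growth to ``blob_size`` voxels."""
        hemi_mask = self.hemisphere_masks()[hemisphere]
        seed = self.seeds[hemisphere]
        if not hemi_mask[seed]:
            raise ValueError(f"seed {seed} outside the {hemisphere} mask")
        from collections import deque

        blob = {seed}
        queue = deque([seed])
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
        while queue and len(blob) < self.blob_size:
            cur = queue.popleft()
            for off in offsets:
                nxt = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
                if nxt in blob or not all(0 <= nxt[d] < self.shape[d] for d in range(3)):
                    continue
                if not hemi_mask[nxt]:
                    continue
                blob.add(nxt)
                queue.append(nxt)
                if len(blob) >= self.blob_size:
                    break
        if len(blob) < self.blob_size:
            raise ValueError(
                f"could not grow a contiguous {self.blob_size}-voxel blob in "
                f"the {hemisphere} mask"
            )
        idx = np.array(sorted(blob))
        return idx


@dataclass
class SimulatedMaps:
    maps: dict[str, "object"]                  # kind -> VoxelMaps (whole grid)
    group_zmap: np.ndarray
    mask: np.ndarray
    hemi_masks: dict[str, np.ndarray]
    blobs: dict[str, np.ndarray]
    spec: ROISpec


def simulate_voxel_maps(
    roi_spec: ROISpec,
    roi_phenotypes: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    voxel_noise_sd: float = 0.0,
) -> SimulatedMaps:
    """Per-subject 3D maps whose ROI summaries equal the given phenotypes.

    The group-level contrast z-map has exactly the two grown blobs
    suprathreshold.  Within each blob, a subject's voxel values are the
    subject's ROI summary plus i.i.d. voxel noise; GM voxel values are the
    subject's GMV spread uniformly over the blob (so the ROI sum times voxel
    volume recovers GMV).
    """
    from .neuro import VoxelMaps

    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    mask = roi_spec.mask()
    blobs = {h: roi_spec.grow_blob(h) for h in ("left", "right")}
    group_z = np.zeros(roi_spec.shape)
    for blob in blobs.values():
        group_z[blob[:, 0], blob[:, 1], blob[:, 2]] = roi_spec.blob_z

    subjects = list(dict.fromkeys(roi_phenotypes["subject"]))
    n = len(subjects)
    voxvol = float(np.prod(roi_spec.voxel_size))
    pheno = roi_phenotypes.set_index(["subject", "hemisphere"])
    maps = {}
    for kind, modality in (("contrast_z", "fs"), ("falff", "falff"), ("gm_modulated", "gmv")):
        data = np.zeros((n,) + roi_spec.shape)
        if kind == "gm_modulated":
            data += 0.1  # small positive background so GMV stays nonnegative
        for hemi, blob in blobs.items():
            vals = pheno.loc[[(s, hemi) for s in subjects], modality].to_numpy()
            if modality == "gmv":
                vals = vals / (len(blob) * voxvol)
            voxels = np.repeat(vals[:, None], len(blob), axis=1)
            if voxel_noise_sd > 0:
                voxels = voxels + rng.normal(0, voxel_noise_sd, size=voxels.shape)
            data[:, blob[:, 0], blob[:, 1], blob[:, 2]] = voxels
        maps[kind] = VoxelMaps(
            subject_ids=subjects, kind=kind, data=data, mask=mask,
            voxel_size=roi_spec.voxel_size,
        )
    return SimulatedMaps(
        maps=maps, group_zmap=group_z, mask=mask,
        hemi_masks=roi_spec.hemisphere_masks(), blobs=blobs, spec=roi_spec,
    )


# -------------------------------------------------------------- behavior ---

def _behavior_calibration(config: CohortConfig):
    """Solve the z-loadings of the hit and false-alarm probit channels.

    Linearized probit-channel model with delta-method binomial noise; the
    two equations pin corr(FRA, z) = behavior_corr and
    corr(new_score, z) = newface_corr (new score = correct-rejection rate
    residualized on the printed bias c = -Z(hit) + Z(FA)).
    """
    h0 = config.face_acc_mean / 100.0
    fa0 = 1.0 - h0
    zh0 = stats.norm.ppf(h0)
    zf0 = stats.norm.ppf(fa0)
    vh = h0 * (1 - h0) / config.n_old
    vf = fa0 * (1 - fa0) / config.n_new
    var_bin = 2500 * (vh + vf)
    var_subj = config.face_acc_sd**2 - var_bin
    if var_subj <= 0:
        raise ValueError(
            "face_acc_sd smaller than the binomial floor; increase trials or sd"
        )
    # channel mean inflated by sqrt(1+tau^2) so E[Phi(mu + tau X)] = h0 exactly;
    # the exact marginal slope is E[phi(mu + tau X)] = phi(z0)/sqrt(1+tau^2).
    tau = 0.3
    for _ in range(50):
        phi_h = stats.norm.pdf(zh0) / np.sqrt(1 + tau**2)
        phi_f = stats.norm.pdf(zf0) / np.sqrt(1 + tau**2)
        new_tau = np.sqrt(var_subj / ((50 * phi_h) ** 2 + (50 * phi_f) ** 2))
        if abs(new_tau - tau) < 1e-12:
            tau = new_tau
            break
        tau = new_tau
    mu_h = zh0 * np.sqrt(1 + tau**2)
    mu_f = zf0 * np.sqrt(1 + tau**2)
    sd_acc = config.face_acc_sd
    Vh = tau**2 + vh / phi_h**2
    Vf = tau**2 + vf / phi_f**2

    def equations(c):
        c1, c2 = c
        eq1 = 50 * tau * (phi_h * c1 - phi_f * c2) / sd_acc - config.behavior_corr
        var_c = Vh + Vf - 2 * tau**2 * c1 * c2
        cov_xc = Vf - tau**2 * c1 * c2
        beta = cov_xc / var_c
        cov_rz = tau * c2 - beta * tau * (c2 - c1)
        var_r = Vf - cov_xc**2 / var_c
        eq2 = -cov_rz / np.sqrt(max(var_r, 1e-12)) - config.newface_corr
        return [eq1, eq2]

    sol = optimize.root(equations, x0=[0.3, -0.3])
    c1, c2 = sol.x
    if not sol.success or max(abs(c1), abs(c2)) >= 1:
        raise ValueError(
            f"behavior couplings (behavior_corr={config.behavior_corr}, "
            f"newface_corr={config.newface_corr}) are not jointly reachable"
        )
    return dict(mu_h=mu_h, mu_f=mu_f, tau=tau, c1=float(c1), c2=float(c2))


def simulate_behavior(
    latent_scores: pd.Series,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Old/new task trial counts and covariates for every subject.

    Face hit and false-alarm probits carry calibrated loadings on the latent
    brain score; flower channels are independent of it.  Counts are binomial
    at the subject's rates; covariates (age, sex, Raven) are generated
    independently.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    z = latent_scores.to_numpy(dtype=float)
    subjects = list(latent_scores.index)
    n = len(subjects)
    cal = _behavior_calibration(config)
    rows = []

    def channel(mu, tau, load):
        noise = rng.standard_normal(n)
        lin = mu + tau * (load * z + np.sqrt(max(0.0, 1 - load**2)) * noise)
        return stats.norm.cdf(lin)

    # face: planted couplings
    h_face = channel(cal["mu_h"], cal["tau"], cal["c1"])
    fa_face = channel(cal["mu_f"], cal["tau"], cal["c2"])
    # flower: same machinery, no latent coupling
    fl0 = config.flower_acc_mean / 100.0
    fl_cfg = dataclasses.replace(config, face_acc_mean=config.flower_acc_mean,
                                 face_acc_sd=config.flower_acc_sd,
                                 behavior_corr=0.0, newface_corr=0.0)
    fl_cal = _behavior_calibration(fl_cfg)
    h_fl = channel(fl_cal["mu_h"], fl_cal["tau"], 0.0)
    fa_fl = channel(fl_cal["mu_f"], fl_cal["tau"], 0.0)

    for cat, h, fa in (("face", h_face, fa_face), ("flower", h_fl, fa_fl)):
        bad = (h <= 0) | (h >= 1) | (fa <= 0) | (fa >= 1)
        if bad.any():
            logger.warning("clipping %d out-of-range rates for %s", int(bad.sum()), cat)
        h = np.clip(h, 1e-6, 1 - 1e-6)
        fa = np.clip(fa, 1e-6, 1 - 1e-6)
        hits = rng.binomial(config.n_old, h)
        fas = rng.binomial(config.n_new, fa)
        for s, hh, ff in zip(subjects, hits, fas):
            rows.append(dict(subject=s, category=cat, n_old=config.n_old,
                             n_new=config.n_new, hits=int(hh), false_alarms=int(ff)))
    counts = pd.DataFrame(rows)

    age = config.age_mean + config.age_sd * rng.standard_normal(n)
    age = np.maximum(age, config.age_min)
    sex = (rng.random(n) < config.male_fraction).astype(int)  # 1 = male
    raven = config.raven_mean + config.raven_sd * rng.standard_normal(n)
    covariates = pd.DataFrame(
        {"subject": subjects, "age": age, "sex": sex, "raven": raven}
    )
    return counts, covariates


# ---------------------------------------------------------------- cohort ---

@dataclass
class SyntheticCohort:
    config: CohortConfig
    genotypes: GenotypeTable
    true_diplotypes: pd.DataFrame
    roi_phenotypes: pd.DataFrame
    latent_scores: pd.Series
    behavior_counts: pd.DataFrame
    covariates: pd.DataFrame
    voxel: SimulatedMaps | None = None

    def save(self, directory) -> None:
        """Write the cohort as TSV/VCF/CSV plus a JSON manifest."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.genotypes.to_long_tsv(d / "genotypes.tsv")
        self.genotypes.to_vcf(d / "genotypes.vcf")
        self.true_diplotypes.to_csv(d / "true_diplotypes.tsv", sep="\t")
        self.roi_phenotypes.to_csv(d / "roi_phenotypes.tsv", sep="\t", index=False)
        self.latent_scores.rename("latent").to_csv(d / "latent_scores.tsv", sep="\t")
        self.behavior_counts.to_csv(d / "behavior_counts.csv", index=False)
        self.covariates.to_csv(d / "covariates.csv", index=False)
        manifest = {"config": self.config.to_dict(), "seed": self.config.seed}
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    @staticmethod
    def load(directory) -> "SyntheticCohort":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        cfgd = manifest["config"]
        cfgd["salience_pattern"] = SaliencePattern(**cfgd["salience_pattern"])
        config = CohortConfig(**cfgd)
        return SyntheticCohort(
            config=config,
            genotypes=GenotypeTable.from_long_tsv(d / "genotypes.tsv"),
            true_diplotypes=pd.read_csv(d / "true_diplotypes.tsv", sep="\t", index_col=0),
            roi_phenotypes=pd.read_csv(d / "roi_phenotypes.tsv", sep="\t"),
            latent_scores=pd.read_csv(d / "latent_scores.tsv", sep="\t", index_col=0)["latent"],
            behavior_counts=pd.read_csv(d / "behavior_counts.csv"),
            covariates=pd.read_csv(d / "covariates.csv"),
        )


def simulate_cohort(
    config: CohortConfig, with_voxel_maps: bool = False,
    roi_spec: ROISpec | None = None, voxel_noise_sd: float = 0.0,
) -> SyntheticCohort:
    """Generate a full cohort; all randomness derives from ``config.seed``
    via seed-sequence spawning, so identical configs give identical cohorts."""
    ss = np.random.SeedSequence(config.seed)
    rng_g, rng_p, rng_v, rng_b = (np.random.default_rng(s) for s in ss.spawn(4))
    genotypes, dips = simulate_genotypes(config, rng_g)
    phenotypes, latent = simulate_phenotypes(genotypes, config, rng_p)
    voxel = None
    if with_voxel_maps:
        voxel = simulate_voxel_maps(roi_spec or ROISpec(), phenotypes, config,
                                    rng_v, voxel_noise_sd=voxel_noise_sd)
    counts, covariates = simulate_behavior(latent, config, rng_b)
    return SyntheticCohort(
        config=config, genotypes=genotypes, true_diplotypes=dips,
        roi_phenotypes=phenotypes, latent_scores=latent,
        behavior_counts=counts, covariates=covariates, voxel=voxel,
    )
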
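"""End-to-end orchestration: simulate/load -> QC -> haplotypes -> phenotypes
-> PLSCA -> behavioral inference, with a machine-readable report."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import score_behavior
from .genetics import (HEA_HAPLOTYPE, GenotypeTable, QCThresholds,
                       assign_hea_groups, em_haplotype_freqs, pairwise_ld,
                       qc_filter, snp_summary)
from .inference import haplotype_anova, partial_correlation
from .plsca import bootstrap_saliences, code_genotypes, permutation_test, plsca_fit
from .synthetic import MODALITIES, CohortConfig, SyntheticCohort, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One configuration for a full pipeline run.

    Either ``cohort_dir`` points at a saved cohort or ``simulation`` holds a
    CohortConfig to generate one.  The master ``seed`` drives every
    stochastic stage through seed-sequence spawning.
    """

    simulation: CohortConfig | None = None
    cohort_dir: str | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    n_perm: int = 1000
    n_boot: int = 500
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if self.simulation is None and self.cohort_dir is None:
            self.simulation = CohortConfig(seed=self.seed)


class StageError(RuntimeError):
    """Pipeline failure carrying the name of the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise StageError(name, exc) from exc
        return wrapper
    return deco


@_stage("cohort")
def _get_cohort(config: RunConfig) -> SyntheticCohort:
    if config.cohort_dir is not None:
        return SyntheticCohort.load(config.cohort_dir)
    return simulate_cohort(config.simulation)


@_stage("plsca")
def _plsca_stage(genotypes: GenotypeTable, pheno: pd.DataFrame, hemisphere: str,
                 n_perm: int, n_boot: int, seeds) -> dict:
    design = code_genotypes(genotypes)
    sub = pheno[pheno.hemisphere == hemisphere].set_index("subject")
    sub = sub.loc[genotypes.subject_ids]
    Y = sub[list(MODALITIES)].to_numpy()
    fit = plsca_fit(design, Y, y_labels=list(MODALITIES))
    perm = permutation_test(design, Y, n_perm=n_perm, seed=int(seeds[0]))
    boot = bootstrap_saliences(design, Y, n_boot=n_boot, seed=int(seeds[1]))
    return dict(
        design=design, fit=fit, perm=perm, boot=boot,
        y_scores=pd.Series(fit.y_scores[:, 0], index=sub.index),
        summary=dict(
            explained_variance=[round(float(v), 6) for v in fit.explained_variance],
            singular_values=[round(float(s), 6) for s in fit.singular_values],
            latent_correlations=[round(float(r), 6) for r in fit.latent_correlations],
            omnibus_p=perm.omnibus_p,
            omnibus_p_max_sv=perm.omnibus_p_max_sv,
            per_lv_p=perm.per_lv_p.tolist(),
            y_saliences={m: round(float(v), 6)
                         for m, v in zip(MODALITIES, fit.y_saliences[:, 0])},
            y_bsr={m: round(float(v), 4) for m, v in zip(MODALITIES, boot.y_bsr[:, 0])},
        ),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and return the run report (a JSON-able
    dict).  Identical config + seed give a byte-identical report body."""
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(8) % (2**31)
    report: dict = {"provenance": {
        "package_version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "n_boot": config.n_boot,
    }}

    cohort = _get_cohort(config)
    report["cohort"] = {"n_subjects": cohort.genotypes.n_subjects,
                        "simulated": config.cohort_dir is None}

    try:
        filtered, exclusions = qc_filter(cohort.genotypes, config.qc)
    except Exception as exc:
        raise StageError("qc", exc) from exc
    summ = snp_summary(filtered)
    report["qc"] = {
        "n_retained": filtered.n_subjects,
        "n_excluded_subjects": int((exclusions.kind == "subject").sum()),
        "n_excluded_snps": int((exclusions.kind == "snp").sum()),
        "per_locus": {
            l: dict(call_rate=round(float(r.call_rate), 4), maf=round(float(r.maf), 4),
                    hwe_p=round(float(r.hwe_p), 4))
            for l, r in summ.per_locus.iterrows()
        },
    }

    try:
        model = em_haplotype_freqs(filtered)
        groups = assign_hea_groups(model, HEA_HAPLOTYPE)
        ld = {}
        loci = filtered.loci
        for i in range(len(loci)):
            for j in range(i + 1, len(loci)):
                res = pairwise_ld(filtered, loci[i], loci[j])
                ld[f"{loci[i]}-{loci[j]}"] = round(res.d_prime, 4) if res.defined else None
    except StageError:
        raise
    except Exception as exc:
        raise StageError("haplotypes", exc) from exc
    common = {h: round(float(f), 4) for h, f in model.freqs_dict().items() if f > 0.05}
    report["haplotypes"] = {
        "common_freqs": common,
        "n_common": len(common),
        "em_iterations": model.n_iter,
        "d_prime": ld,
        "group_counts": groups.group.value_counts().to_dict(),
    }

    pheno = cohort.roi_phenotypes[cohort.roi_phenotypes.subject.isin(filtered.subject_ids)]
    pls = {}
    y1 = {}
    for k, hemi in enumerate(("right", "left")):
        res = _plsca_stage(filtered, pheno, hemi, config.n_perm, config.n_boot,
                           seeds[2 * k:2 * k + 2])
        pls[hemi] = res
        y1[hemi] = res["y_scores"]
        report[f"plsca_{hemi}"] = res["summary"]

    try:
        behav = score_behavior(cohort.behavior_counts, cohort.covariates)
        behav = behav.loc[filtered.subject_ids]
        cov = behav[["age", "sex", "raven"]].to_numpy()
        scores = y1["right"].loc[filtered.subject_ids].to_numpy()
        assoc = {}
        for name, col in (("fra", "fra"), ("face_accuracy", "face_accuracy"),
                          ("flower_accuracy", "flower_accuracy"),
                          ("new_score", "new_score"), ("old_score", "old_score")):
            res = partial_correlation(behav[col].to_numpy(), scores, cov)
            assoc[name] = dict(r=round(res.r, 4), p=round(res.p, 6), n=res.n,
                               ci=[round(c, 4) for c in res.ci])
    except StageError:
        raise
    except Exception as exc:
        raise StageError("behavior", exc) from exc
    report["behavior_associations"] = assoc

    try:
        long = pd.concat(
            [pd.DataFrame({"subject": y1[h].index, "score": y1[h].to_numpy(),
                           "hemisphere": h}) for h in ("right", "left")],
            ignore_index=True,
        ).merge(groups.reset_index()[["subject", "group"]], on="subject")
        anova = haplotype_anova(long)
        report["haplotype_anova"] = {
            "error_df": anova.error_df,
            "effects": {e: dict(F=round(float(r.F), 4), p=round(float(r.p), 6),
                                partial_eta2=round(float(r.partial_eta2), 4))
                        for e, r in anova.table.iterrows()},
            "tukey": anova.tukey[["group1", "group2", "meandiff", "p-adj", "p_fdr"]]
            .round(6).to_dict(orient="records"),
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("anova", exc) from exc

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        for hemi in ("right", "left"):
            fit = pls[hemi]["fit"]
            sal = pd.DataFrame(fit.x_saliences,
                               index=[f"{l}:{g}" for l, g in fit.x_labels],
                               columns=[f"LV{k+1}" for k in range(fit.x_saliences.shape[1])])
            sal.to_csv(out / f"x_saliences_{hemi}.tsv", sep="\t")
    return report
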
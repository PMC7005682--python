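"""Old/new recognition scoring: accuracy, d', response bias, FRA, old/new scores.

The task shows studied ("old") and novel ("new") items per category (faces,
flowers); a subject's hits are correct "old" responses and false alarms are
"old" responses to new items.  Face-specific recognition ability (FRA) is the
standardized residual of face accuracy after regressing out flower accuracy,
which removes category-general recognition skill.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


def _corrected_rate(count: int, n: int, correction: str) -> float:
    """Rate with extreme-value correction so the probit is finite.

    ``halfcount`` replaces 0 with 1/(2N) and 1 with 1-1/(2N);
    ``loglinear`` adds 0.5 to the count and 1 to the total.
    """
    if correction == "loglinear":
        return (count + 0.5) / (n + 1)
    rate = count / n
    if rate == 0.0:
        return 1 / (2 * n)
    if rate == 1.0:
        return 1 - 1 / (2 * n)
    return rate


@dataclass
class SDTScores:
    hit_rate: float
    fa_rate: float
    cr_rate: float
    accuracy: float     # percent, mean of uncorrected hit and CR rates
    d_prime: float
    c: float            # response bias (see `bias` argument)
    bias_formula: str = "printed"


def sdt_scores(
    hits: int,
    misses: int,
    false_alarms: int,
    correct_rejections: int,
    correction: str = "halfcount",
    bias: str = "printed",
) -> SDTScores:
    """Signal-detection scores for one subject and category.

    ``bias='printed'`` uses c = -Z(hit) + Z(FA) (which equals -d'),
    ``bias='standard'`` the conventional criterion c = -[Z(hit)+Z(FA)]/2.
    """
    n_old = hits + misses
    n_new = false_alarms + correct_rejections
    if n_old < 1 or n_new < 1:
        raise ValueError("need at least one old and one new trial")
    hit_rate = hits / n_old
    cr_rate = correct_rejections / n_new
    accuracy = 100.0 * (hit_rate + cr_rate) / 2.0
    h = _corrected_rate(hits, n_old, correction)
    f = _corrected_rate(false_alarms, n_new, correction)
    zh, zf = stats.norm.ppf(h), stats.norm.ppf(f)
    d_prime = zh - zf
    if bias == "printed":
        c = -zh + zf
    elif bias == "standard":
        c = -(zh + zf) / 2.0
    else:
        raise ValueError(f"unknown bias formula {bias!r}")
    return SDTScores(
        hit_rate=hit_rate, fa_rate=false_alarms / n_new, cr_rate=cr_rate,
        accuracy=accuracy, d_prime=float(d_prime), c=float(c), bias_formula=bias,
    )


_PRINTED_BIAS_WARNED = False


def _warn_printed_bias() -> None:
    global _PRINTED_BIAS_WARNED
    if not _PRINTED_BIAS_WARNED:
        warnings.warn(
            "default response-bias formula c = -Z(hit) + Z(FA) equals -d'; "
            "pass bias='standard' for the conventional SDT criterion",
            UserWarning,
            stacklevel=3,
        )
        _PRINTED_BIAS_WARNED = True


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """OLS residuals of y on [1, x]."""
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _standardize(r: np.ndarray, what: str) -> np.ndarray:
    sd = r.std()  # population SD: exact unit variance by construction
    if sd < 1e-12:
        raise ValueError(f"{what}: residuals are (near-)constant, cannot standardize")
    return (r - r.mean()) / sd


def fra_score(face_accuracy: np.ndarray, flower_accuracy: np.ndarray) -> np.ndarray:
    """Face-specific recognition ability: standardized residual of face
    accuracy after regressing out flower accuracy (with intercept)."""
    face = np.asarray(face_accuracy, dtype=float)
    flower = np.asarray(flower_accuracy, dtype=float)
    if face.shape != flower.shape or face.ndim != 1:
        raise ValueError("face and flower accuracy must be equal-length vectors")
    if len(face) < 3:
        raise ValueError("need at least 3 subjects")
    if flower.std() < 1e-12:
        raise ValueError("flower accuracy is constant; regression undefined")
    return _standardize(_residualize(face, flower), "FRA")


def oldnew_scores(
    hit_rate: np.ndarray, cr_rate: np.ndarray, c: np.ndarray
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Bias-residualized recognition scores.

    The hit rate residualized on the response bias c gives the old-face
    score; the correct-rejection rate residualized on c gives the new-face
    score; both standardized.  If c is constant the scores are the
    standardized raw rates and the flag in the third return slot is True.
    """
    h = np.asarray(hit_rate, dtype=float)
    cr = np.asarray(cr_rate, dtype=float)
    c = np.asarray(c, dtype=float)
    if c.std() < 1e-12:
        logger.warning("constant bias vector; returning standardized raw rates")
        return _standardize(h, "old score"), _standardize(cr, "new score"), True
    old = _standardize(_residualize(h, c), "old score")
    new = _standardize(_residualize(cr, c), "new score")
    return old, new, False


def score_behavior(counts, covariates=None, correction: str = "halfcount",
                   bias: str = "printed", derive_composites: bool = True):
    """Score a trial-count table into a per-subject behavior table.

    ``counts`` columns: subject, category, n_old, n_new, hits, false_alarms.
    Returns a wide DataFrame with per-category rates/accuracy/d'/c plus FRA
    and old/new face scores (and covariates, if given).
    ``derive_composites=False`` skips the regression-based FRA and old/new
    scores (needed when a category is degenerate, e.g. constant accuracy).
    """
    import pandas as pd

    if bias == "printed":
        _warn_printed_bias()
    rows = {}
    for _, r in counts.iterrows():
        s = sdt_scores(
            int(r.hits), int(r.n_old) - int(r.hits), int(r.false_alarms),
            int(r.n_new) - int(r.false_alarms), correction=correction, bias=bias,
        )
        d = rows.setdefault(r.subject, {})
        cat = r.category
        d[f"{cat}_hit_rate"] = s.hit_rate
        d[f"{cat}_cr_rate"] = s.cr_rate
        d[f"{cat}_accuracy"] = s.accuracy
        d[f"{cat}_d_prime"] = s.d_prime
        d[f"{cat}_c"] = s.c
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "subject"
    if derive_composites:
        table["fra"] = fra_score(table.face_accuracy.to_numpy(),
                                 table.flower_accuracy.to_numpy())
        old, new, flagged = oldnew_scores(
            table.face_hit_rate.to_numpy(), table.face_cr_rate.to_numpy(),
            table.face_c.to_numpy()
        )
        table["old_score"] = old
        table["new_score"] = new
        table.attrs["constant_bias"] = flagged
    if covariates is not None:
        table = table.join(covariates.set_index("subject") if "subject" in covariates else covariates)
    return table
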
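"""Associations between individual class scores and clinical measures.

The classifier output used here is the *unnormalized* score of the disease
class (the pre-softmax logit), treated as an individual pseudo-probability
of AD.  Scores and measures are residualized on nuisance covariates
(typically age and sex) before Pearson correlation; group contrasts use the
pooled-variance two-sample t test on residualized scores.  Missing values
are removed listwise per analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["AssociationResult", "residualize", "score_association",
           "apoe_group_test", "conversion_time_association"]


@dataclass
class AssociationResult:
    measure: str
    r: float
    p: float
    n: int
    covariates: tuple = ()
    subgroup: str = "all"

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("association needs n >= 3")
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"invalid correlation {self.r}")


def _as_float(values) -> np.ndarray:
    return np.asarray([np.nan if v is None else v for v in values], dtype=float)


def residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Least-squares residuals of y on an intercept plus the covariates.

    With no covariates this is mean-centering.  The design matrix must be
    full rank; residuals are orthogonal to every covariate column.
    """
    y = np.asarray(y, dtype=float)
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        return y - y.mean()
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    X = np.column_stack([np.ones(len(y)), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _complete(*arrays):
    cols = [_as_float(a) if np.asarray(a).ndim == 1 else np.asarray(a, dtype=float)
            for a in arrays]
    keep = np.ones(len(cols[0]), dtype=bool)
    for c in cols:
        keep &= np.all(np.isfinite(np.atleast_2d(c.T).T), axis=1)
    return [c[keep] for c in cols]


def score_association(ad_scores, measure, covariates=None,
                      measure_name: str = "measure",
                      subgroup: str = "all") -> AssociationResult:
    """Pearson correlation between residualized scores and a measure."""
    if covariates is None:
        scores, meas = _complete(ad_scores, measure)
        cov = None
        cov_names: tuple = ()
    else:
        scores, meas, cov = _complete(ad_scores, measure, covariates)
        cov_names = ("covariates",)
    n = len(scores)
    if n < 3:
        raise ValueError(f"only {n} complete cases")
    r, p = stats.pearsonr(residualize(scores, cov), residualize(meas, cov))
    return AssociationResult(measure=measure_name, r=float(r), p=float(p), n=n,
                             covariates=cov_names, subgroup=subgroup)


def apoe_group_test(ad_scores, apoe4_positive, covariates=None):
    """Pooled two-sample t of scores, APOE e4 carriers minus non-carriers.

    Scores are residualized on the covariates over all subjects first.
    Returns ``(t, df, p)`` with df = n1 + n2 - 2.
    """
    flags = np.asarray([np.nan if v is None else float(v) for v in apoe4_positive])
    if covariates is None:
        scores, flags_ = _complete(ad_scores, flags)
        resid = residualize(scores, None)
    else:
        scores, flags_, cov = _complete(ad_scores, flags, covariates)
        resid = residualize(scores, cov)
    pos = resid[flags_ == 1.0]
    neg = resid[flags_ == 0.0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both APOE e4 subgroups must be nonempty")
    res = stats.ttest_ind(pos, neg, equal_var=True)
    df = len(pos) + len(neg) - 2
    return float(res.statistic), int(df), float(res.pvalue)


def conversion_time_association(ad_scores, months_to_conversion) -> AssociationResult:
    """Correlation of pMCI class scores with months until conversion to AD.

    Under the disease model, higher scores mean faster conversion, so the
    expected sign is negative.
    """
    return score_association(ad_scores, months_to_conversion,
                             measure_name="months_to_conversion",
                             subgroup="pMCI")
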
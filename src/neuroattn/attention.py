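"""Region-level attention scores and the analyses that validate them.

The trained attention map lives on the coarse post-pooling grid.  For
region attribution it is resampled (trilinearly, align-corners) back to the
input grid and averaged within each atlas region, yielding one attention
score per region.  Validation analyses: masked retraining of K attention-
ranked region groups, correlation with the group-difference t-map, per-region
correlation with MMSE under Benjamini-Hochberg FDR control, top-fraction
region selection, and Dice overlap between region sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .io import Cohort, Parcellation

__all__ = [
    "ROIAttentionScores",
    "GroupBinning",
    "RegionCorrelationMap",
    "mean_attention_map",
    "resample_to_input_grid",
    "roi_attention_scores",
    "per_subject_roi_scores",
    "top_fraction_regions",
    "kgroup_validation",
    "mask_cohort_to_regions",
    "region_tmap",
    "attention_mmse_map",
    "dice",
    "map_correlation",
]


@dataclass
class ROIAttentionScores:
    """Mean attention per atlas region, aligned with ``region_ids``."""

    scores: np.ndarray
    region_ids: list[int]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.scores) != len(self.region_ids):
            raise ValueError("scores and region_ids must align")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("attention scores must be finite")


@dataclass
class GroupBinning:
    """K attention-ranked region groups with their retrained accuracies."""

    K: int
    group_members: list[list[int]]
    group_attention: np.ndarray
    group_accuracy: np.ndarray
    r: float
    p: float


@dataclass
class RegionCorrelationMap:
    """Per-region correlation with an external measure, FDR-masked."""

    region_ids: list[int]
    r: np.ndarray
    p: np.ndarray
    significant: np.ndarray  # boolean mask after BH correction
    alpha: float

    @property
    def significant_regions(self) -> set[int]:
        return {rid for rid, s in zip(self.region_ids, self.significant) if s}


# ---------------------------------------------------------------------------


def mean_attention_map(model, cohort: Cohort | np.ndarray) -> np.ndarray:
    """Voxelwise mean of the per-subject attention maps.

    ``cohort`` may be a Cohort (maps are computed with ``model``) or an
    already-stacked (n, h, w, d) array of maps (``model`` is then ignored).
    """
    if isinstance(cohort, np.ndarray):
        maps = cohort
    else:
        if len(cohort) == 0:
            raise ValueError("empty cohort")
        maps = model.attention_maps(cohort.stack())
    if maps.ndim != 4 or maps.shape[0] == 0:
        raise ValueError("need a nonempty stack of 3D attention maps")
    return maps.mean(axis=0)


def resample_to_input_grid(attention_map: np.ndarray,
                           target_shape: tuple[int, int, int],
                           method: str = "trilinear") -> np.ndarray:
    """Resample a post-pooling map to the input grid.

    Align-corners convention: output position ``i`` along an axis of length
    ``t`` samples source coordinate ``i * (s - 1) / (t - 1)``.  Trilinear
    interpolation keeps values within the input min/max; ``method="nearest"``
    is available for label-like maps.
    """
    attention_map = np.asarray(attention_map, dtype=float)
    if attention_map.ndim != 3:
        raise ValueError("attention map must be 3D")
    if min(target_shape) < 1:
        raise ValueError("target shape must be positive")
    order = {"trilinear": 1, "nearest": 0}[method]
    axes = [np.linspace(0, s - 1, t) if t > 1 else np.array([(s - 1) / 2.0])
            for s, t in zip(attention_map.shape, target_shape)]
    grid = np.meshgrid(*axes, indexing="ij")
    return ndimage.map_coordinates(attention_map, np.stack(grid), order=order,
                                   mode="nearest")


def roi_attention_scores(map_on_input_grid: np.ndarray,
                         parcellation: Parcellation) -> ROIAttentionScores:
    """Mean attention over the voxels of each region."""
    m = np.asarray(map_on_input_grid, dtype=float)
    if m.shape != parcellation.labels.shape:
        raise ValueError(f"map shape {m.shape} != parcellation {parcellation.labels.shape}")
    for rid in parcellation.region_ids:
        if not np.any(parcellation.labels == rid):
            raise ValueError(f"region {rid} is empty")
    scores = ndimage.mean(m, labels=parcellation.labels,
                          index=parcellation.region_ids)
    return ROIAttentionScores(scores=np.asarray(scores),
                              region_ids=list(parcellation.region_ids))


def per_subject_roi_scores(model, cohort: Cohort,
                           parcellation: Parcellation) -> np.ndarray:
    """(n_subjects, n_regions) matrix of per-subject region attention."""
    maps = model.attention_maps(cohort.stack())
    target = parcellation.labels.shape
    rows = []
    for i in range(maps.shape[0]):
        up = resample_to_input_grid(maps[i], target)
        rows.append(ndimage.mean(up, labels=parcellation.labels,
                                 index=parcellation.region_ids))
    return np.asarray(rows)


def top_fraction_regions(scores: ROIAttentionScores, fraction: float) -> set[int]:
    """Ids of the round(fraction * R) highest-scoring regions.

    Uses Python's round (so 0.30 of 273 regions selects exactly 82); score
    ties are broken by ascending region id.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_sel = round(fraction * len(scores.region_ids))
    order = sorted(range(len(scores.region_ids)),
                   key=lambda i: (-scores.scores[i], scores.region_ids[i]))
    return {scores.region_ids[i] for i in order[:n_sel]}


# ---------------------------------------------------------------------------
# K-group masked retraining


def _kgroup_partition(scores: ROIAttentionScores, K: int) -> list[list[int]]:
    """Regions sorted by descending attention, split into K groups.

    Groups 1..K-1 hold floor(R/K) regions; group K takes the remainder.
    Ties sort by ascending region id.
    """
    R = len(scores.region_ids)
    if K < 2 or K > R:
        raise ValueError(f"K must be in [2, {R}]")
    order = sorted(range(R), key=lambda i: (-scores.scores[i], scores.region_ids[i]))
    size = R // K
    groups = []
    for g in range(K):
        lo = g * size
        hi = lo + size if g < K - 1 else R
        groups.append([scores.region_ids[i] for i in order[lo:hi]])
    return groups


def mask_cohort_to_regions(cohort: Cohort, parcellation: Parcellation,
                           region_ids: list[int]) -> Cohort:
    """Copy of the cohort with voxels outside the given regions set to zero."""
    from .io import GrayMatterVolume

    keep = np.isin(parcellation.labels, list(region_ids))
    volumes = {}
    for sid, vol in cohort.volumes.items():
        volumes[sid] = GrayMatterVolume(values=vol.values * keep,
                                        voxel_size_mm=vol.voxel_size_mm,
                                        affine=vol.affine)
    return Cohort(list(cohort.records), volumes)


def kgroup_validation(scores: ROIAttentionScores, K: int, cohort: Cohort,
                      parcellation: Parcellation, train_fn) -> GroupBinning:
    """Retrain on each attention-ranked region group and correlate.

    ``train_fn(masked_cohort)`` must train a model from scratch on the
    masked volumes and return its test accuracy.  The result records, per
    group, the mean attention score and retrained accuracy, plus the
    Pearson correlation between the two across groups.
    """
    groups = _kgroup_partition(scores, K)
    by_id = dict(zip(scores.region_ids, scores.scores))
    attn = np.array([np.mean([by_id[r] for r in g]) for g in groups])
    accs = []
    for g in groups:
        masked = mask_cohort_to_regions(cohort, parcellation, g)
        accs.append(float(train_fn(masked)))
    accs = np.asarray(accs)
    r, p = stats.pearsonr(attn, accs)
    return GroupBinning(K=K, group_members=groups, group_attention=attn,
                        group_accuracy=accs, r=float(r), p=float(p))


# ---------------------------------------------------------------------------
# group-difference t-map and MMSE correlations


def _covariate_matrix(cohort: Cohort, covariates) -> np.ndarray:
    cols = []
    for name in covariates:
        if name == "site":
            sites = cohort.labels("site")
            levels = sorted(set(sites))[1:]  # first level is the reference
            for lv in levels:
                cols.append((sites == lv).astype(float))
        else:
            vals = [getattr(r, name) for r in cohort.records]
            if any(v is None for v in vals):
                raise ValueError(f"covariate {name!r} has missing values")
            cols.append(np.asarray(vals, dtype=float))
    n = len(cohort)
    X = np.column_stack([np.ones(n)] + cols) if cols else np.ones((n, 1))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    return X


def region_mean_density(cohort: Cohort, parcellation: Parcellation) -> np.ndarray:
    """(n_subjects, n_regions) mean gray-matter density per region."""
    rows = []
    for sid in cohort.ids:
        rows.append(ndimage.mean(cohort.volumes[sid].values,
                                 labels=parcellation.labels,
                                 index=parcellation.region_ids))
    return np.asarray(rows)


def region_tmap(cohort: Cohort, parcellation: Parcellation,
                covariates=("age", "sex", "site")) -> np.ndarray:
    """Signed per-region two-sample t (AD minus NC) on covariate residuals.

    Region mean densities are residualized on the covariates by least
    squares over all subjects; the pooled-variance t statistic is then
    computed between the AD and NC groups, region by region.
    """
    diag = cohort.labels("diagnosis")
    if not (np.any(diag == "AD") and np.any(diag == "NC")):
        raise ValueError("both AD and NC subjects are required")
    dens = region_mean_density(cohort, parcellation)
    X = _covariate_matrix(cohort, covariates)
    beta, *_ = np.linalg.lstsq(X, dens, rcond=None)
    resid = dens - X @ beta
    ad, nc = resid[diag == "AD"], resid[diag == "NC"]
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t = np.asarray(stats.ttest_ind(ad, nc, axis=0, equal_var=True).statistic)
    # identical groups: zero difference over zero variance is taken as t = 0
    degenerate = ~np.isfinite(t) & (np.abs(ad.mean(axis=0) - nc.mean(axis=0)) < 1e-12)
    t[degenerate] = 0.0
    return t


def attention_mmse_map(roi_attention: np.ndarray, mmse: np.ndarray,
                       region_ids: list[int] | None = None,
                       alpha: float = 0.05) -> RegionCorrelationMap:
    """Per-region Pearson correlation of attention with MMSE, BH-corrected.

    ``roi_attention`` is (n_subjects, n_regions); subjects with missing
    MMSE are dropped listwise.
    """
    roi_attention = np.asarray(roi_attention, dtype=float)
    mmse = np.asarray([np.nan if m is None else m for m in mmse], dtype=float)
    keep = np.isfinite(mmse)
    roi_attention, mmse = roi_attention[keep], mmse[keep]
    n, R = roi_attention.shape
    if n < 3:
        raise ValueError("need at least 3 subjects with MMSE")
    if region_ids is None:
        region_ids = list(range(1, R + 1))
    r = np.empty(R)
    p = np.empty(R)
    for j in range(R):
        col = roi_attention[:, j]
        if np.ptp(col) == 0:
            r[j], p[j] = 0.0, 1.0
        else:
            r[j], p[j] = stats.pearsonr(col, mmse)
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return RegionCorrelationMap(region_ids=list(region_ids), r=r, p=p,
                                significant=reject, alpha=alpha)


def dice(set_a, set_b) -> float:
    """Dice similarity 2|A∩B| / (|A| + |B|) between two region-id sets."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise ValueError("Dice undefined for two empty sets")
    return 2.0 * len(a & b) / (len(a) + len(b))


def map_correlation(map_a, map_b) -> tuple[float, float]:
    """Pearson r and two-sided p between two per-region score vectors."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two aligned vectors of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
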
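"""Synthetic cohorts with planted regional atrophy.

The generator emulates the statistical structure the analysis pipeline
assumes: two diagnostic groups whose gray-matter density differs by
region-specific reductions, a latent severity variable that drives both the
atrophy and an MMSE-like cognitive score (plus CSF and genetic surrogates),
additive site offsets with heteroscedastic noise, and months-to-conversion
for a progressive-MCI subgroup.  Everything is drawn from one seeded
generator, so a seed pins the cohort bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .io import Cohort, GrayMatterVolume, Parcellation, SubjectRecord

__all__ = ["SimulationSpec", "make_toy_parcellation", "simulate_cohort", "planted_effects"]

# Latent severity by group: controls sit at 0, AD around 1, with the MCI
# subtypes in between (progressive closer to AD than stable).
SEVERITY_MEAN = {"NC": 0.0, "AD": 1.0, "pMCI": 0.6, "sMCI": 0.3}
SEVERITY_SD = 0.2
# One unit of severity times one unit of effect size removes 0.1 density.
ATROPHY_SCALE = 0.1


def planted_effects(n_regions: int, planted: dict[int, float]) -> np.ndarray:
    """Effect-size vector that is zero except in the planted regions.

    ``planted`` maps 1-based region ids to standardized effect sizes.
    """
    eff = np.zeros(n_regions)
    for region_id, size in planted.items():
        eff[region_id - 1] = size
    return eff


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic cohort.

    ``sites`` is a list of ``(site_id, additive_offset, extra_noise_sd)``;
    a subject's voxel noise has standard deviation
    ``sqrt(noise_sd**2 + extra_noise_sd**2)``.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    n_regions: int = 12
    effect_size: np.ndarray = field(
        default_factory=lambda: planted_effects(12, {3: 0.5, 6: 1.0, 9: 1.5}))
    n_per_group: dict = field(
        default_factory=lambda: {"NC": 100, "AD": 100, "pMCI": 0, "sMCI": 0})
    sites: list = field(
        default_factory=lambda: [("siteA", -0.02, 0.0), ("siteB", 0.0, 0.0),
                                 ("siteC", 0.02, 0.01)])
    severity_slope_mmse: float = 5.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.effect_size = np.asarray(self.effect_size, dtype=float)
        if np.any(self.effect_size < 0):
            raise ValueError("effect sizes must be nonnegative")
        if len(self.effect_size) != self.n_regions:
            raise ValueError("effect_size length must equal n_regions")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be nonnegative")
        if self.noise_sd <= 0 and any(s[2] <= 0 for s in self.sites):
            # degenerate noise is allowed only for didactic runs
            self.noise_sd = max(self.noise_sd, 0.0)


def make_toy_parcellation(grid_shape: tuple[int, int, int], n_regions: int,
                          seed: int = 0) -> Parcellation:
    """Partition a central ellipsoidal "brain" mask into contiguous regions.

    Regions are the Voronoi cells of randomly placed seed voxels inside the
    mask; the mask is convex, so every cell is connected and nonempty.
    Background keeps label 0.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    coords = np.indices(grid_shape).astype(float)
    center = [(s - 1) / 2.0 for s in grid_shape]
    radii = [max(1.5, 0.45 * (s - 1)) for s in grid_shape]
    dist2 = sum(((coords[a] - center[a]) / radii[a]) ** 2 for a in range(3))
    mask = dist2 <= 1.0
    n_vox = int(mask.sum())
    if n_regions > n_vox:
        raise ValueError(f"cannot split a {n_vox}-voxel mask into {n_regions} regions")
    rng = np.random.default_rng(seed)
    in_mask = np.argwhere(mask)
    seeds = in_mask[rng.choice(n_vox, size=n_regions, replace=False)]
    # label each in-mask voxel with the nearest seed (first seed wins ties)
    d2 = ((in_mask[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)
    labels = np.zeros(grid_shape, dtype=np.int32)
    labels[tuple(in_mask.T)] = nearest + 1
    return Parcellation(labels=labels, region_ids=list(range(1, n_regions + 1)))


def _baseline_pattern(grid_shape, rng: np.random.Generator) -> np.ndarray:
    """A smooth anatomical-looking density pattern in [0.4, 0.8]."""
    raw = rng.normal(size=grid_shape)
    smooth = ndimage.gaussian_filter(raw, sigma=max(2.0, min(grid_shape) / 8.0))
    lo, hi = smooth.min(), smooth.max()
    return 0.4 + 0.4 * (smooth - lo) / max(hi - lo, 1e-12)


def _truncated_severity(mean: float, rng: np.random.Generator) -> float:
    a = (0.0 - mean) / SEVERITY_SD  # truncate at zero
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=SEVERITY_SD,
                                     random_state=rng))


def simulate_cohort(spec: SimulationSpec, parcellation: Parcellation) -> Cohort:
    """Draw a cohort under ``spec`` on the given parcellation.

    The returned cohort additionally carries a ``severity`` dict
    (subject id -> latent severity) for diagnostics.
    """
    if parcellation.labels.shape != tuple(spec.grid_shape):
        raise ValueError(f"parcellation shape {parcellation.labels.shape} != "
                         f"grid {spec.grid_shape}")
    rng = np.random.default_rng(spec.seed)
    baseline = _baseline_pattern(spec.grid_shape, rng)
    mask = parcellation.labels > 0
    baseline = baseline * mask

    effect_map = np.zeros(spec.grid_shape)
    for idx, region_id in enumerate(parcellation.region_ids):
        effect_map[parcellation.labels == region_id] = spec.effect_size[idx]

    records: list[SubjectRecord] = []
    volumes: dict[str, GrayMatterVolume] = {}
    severity: dict[str, float] = {}
    counter = 0
    for group in ("NC", "AD", "pMCI", "sMCI"):
        for _ in range(spec.n_per_group.get(group, 0)):
            sid = f"sub{counter:04d}"
            counter += 1
            s = 0.0 if group == "NC" else _truncated_severity(SEVERITY_MEAN[group], rng)
            site_id, offset, extra_sd = spec.sites[rng.integers(len(spec.sites))]
            total_sd = float(np.hypot(spec.noise_sd, extra_sd))
            vol = baseline - s * ATROPHY_SCALE * effect_map + offset * mask
            if total_sd > 0:
                vol = vol + rng.normal(0.0, total_sd, size=spec.grid_shape)
            vol = np.clip(vol, 0.0, 1.0)

            mmse = int(np.clip(round(30.0 - spec.severity_slope_mmse * s
                                     + rng.normal(0.0, 1.0)), 0, 30))
            rec = SubjectRecord(
                id=sid,
                diagnosis="MCI" if group in ("pMCI", "sMCI") else group,
                mci_subtype=group if group in ("pMCI", "sMCI") else None,
                site=site_id,
                age=float(rng.normal(72.0, 6.0)),
                sex=int(rng.integers(2)),
                mmse=mmse,
                csf_tau=float(2.0 + s + rng.normal(0.0, 0.3)),
                csf_abeta=float(2.0 - s + rng.normal(0.0, 0.3)),
                pgrs=float(0.5 * s + rng.normal(0.0, 0.5)),
                apoe4_positive=bool(rng.random() < np.clip(0.25 + 0.35 * s, 0.0, 0.95)),
                months_to_conversion=(max(1.0, 36.0 - 20.0 * s + rng.normal(0.0, 4.0))
                                      if group == "pMCI" else None),
            )
            records.append(rec)
            volumes[sid] = GrayMatterVolume(values=vol)
            severity[sid] = s

    cohort = Cohort(records, volumes)
    cohort.severity = severity
    return cohort
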
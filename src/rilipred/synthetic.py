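"""Synthetic cohorts and voxel phantoms for the RILI pipeline.

Real planning-CT cohorts cannot ship with the package, so two generators
stand in:

* :func:`sample_feature_table` draws per-patient feature rows from
  independent truncated normals, one marginal per feature per RILI group.
  The default group specifications equal the published summary statistics
  of a 242-patient breast-radiotherapy cohort (113 with radiologically
  visible injury, 129 without): each feature's location/scale is the
  printed group mean/SD and its truncation bounds are the printed group
  minimum/maximum. Only marginal summaries are published, so the joint
  distribution is deliberately simple; an optional correlation structure is
  out of scope.

* :func:`make_phantom` builds an ellipsoidal "lung" in a voxel grid —
  Gaussian HU noise around a base level plus a configurable number of
  denser spherical lesions (emulating reticulation/opacity) — scaled and
  tuned so that feature extraction on the phantom reproduces a requested
  feature record.

All randomness flows from one seeded :class:`numpy.random.Generator`, so a
fixed configuration yields byte-identical output across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from functools import lru_cache

from scipy import optimize, stats

from .errors import ConfigurationError, GenerationError
from .features import (
    FEATURE_COLUMNS,
    HUVolume,
    LungFeatureRecord,
    LungMask,
    extract_features,
    write_mask,
    write_volume,
)

__all__ = [
    "TruncatedNormal",
    "GroupDistributionSpec",
    "CohortConfig",
    "PhantomConfig",
    "default_group_specs",
    "sample_feature_table",
    "make_phantom",
    "write_phantom",
    "DEFAULT_SEED",
    "DEFAULT_N_RILI",
    "DEFAULT_N_NO_RILI",
]

DEFAULT_SEED = 20250527
DEFAULT_N_RILI = 113
DEFAULT_N_NO_RILI = 129


@lru_cache(maxsize=256)
def _match_truncnorm_moments(
    loc: float, scale: float, low: float, high: float
) -> tuple[float, float]:
    """Parent (mu, sigma) whose [low, high]-truncation has mean=loc, SD=scale.

    Truncation pulls the mean toward the interval centre and shrinks the
    SD, so using the target moments directly as parent parameters would
    mis-calibrate the generator. Solved by root-finding in (mu, log sigma).
    """

    def residual(p):
        mu, log_sigma = p
        sigma = np.exp(np.clip(log_sigma, -20.0, 20.0))
        a, b = (low - mu) / sigma, (high - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - loc, float(np.sqrt(v)) - scale]

    sol = optimize.root(residual, x0=[loc, np.log(scale)], method="hybr")
    res = residual(sol.x)
    if not sol.success or max(abs(res[0]), abs(res[1])) > 1e-6 * max(scale, 1.0):
        raise ConfigurationError(
            f"cannot calibrate a truncated normal on [{low}, {high}] to "
            f"mean {loc}, SD {scale} (target SD too large for the bounds?)"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


@dataclass(frozen=True)
class TruncatedNormal:
    """A truncated-normal marginal with *target* mean/SD and hard bounds.

    ``loc`` and ``scale`` are the mean and SD of the truncated distribution
    itself (the statistics a cohort table would report), not of the parent
    normal; the parent parameters are solved internally so the generator is
    calibrated to the printed summary statistics it emulates.
    """

    loc: float
    scale: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ConfigurationError(f"scale must be >= 0, got {self.scale}")
        if not self.low < self.high:
            raise ConfigurationError(
                f"impossible truncation: low={self.low} >= high={self.high}"
            )
        if self.scale > 0 and not self.low < self.loc < self.high:
            raise ConfigurationError(
                f"target mean {self.loc} must lie inside ({self.low}, {self.high})"
            )

    def parent_params(self) -> tuple[float, float]:
        """(mu, sigma) of the untruncated parent normal."""
        return _match_truncnorm_moments(self.loc, self.scale, self.low, self.high)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.scale == 0:
            return np.full(n, float(self.loc))
        mu, sigma = self.parent_params()
        a, b = (self.low - mu) / sigma, (self.high - mu) / sigma
        return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)


@dataclass(frozen=True)
class GroupDistributionSpec:
    """Per-feature truncated-normal marginals for one RILI group."""

    volume_cm3: TruncatedNormal
    hu_min: TruncatedNormal
    hu_max: TruncatedNormal
    hu_mean: TruncatedNormal
    hu_sd: TruncatedNormal

    def __getitem__(self, feature: str) -> TruncatedNormal:
        if feature not in FEATURE_COLUMNS:
            raise KeyError(feature)
        return getattr(self, feature)


def default_group_specs() -> tuple[GroupDistributionSpec, GroupDistributionSpec]:
    """Return (no-RILI spec, RILI spec) calibrated to the published cohort.

    Locations/scales are the printed group means/SDs; truncation bounds are
    the printed group minima/maxima for each of the five features.
    """
    no_rili = GroupDistributionSpec(
        volume_cm3=TruncatedNormal(1680.30, 450.75, 693.6, 2964.8),
        hu_min=TruncatedNormal(-986.39, 23.48, -1043.0, -882.0),
        hu_max=TruncatedNormal(242.96, 152.25, 29.0, 840.0),
        hu_mean=TruncatedNormal(-746.11, 64.13, -869.28, -430.38),
        hu_sd=TruncatedNormal(142.78, 18.65, 116.66, 192.08),
    )
    rili = GroupDistributionSpec(
        volume_cm3=TruncatedNormal(1532.47, 466.57, 668.1, 2794.3),
        hu_min=TruncatedNormal(-978.62, 29.71, -1020.0, -866.0),
        hu_max=TruncatedNormal(266.32, 176.29, 47.0, 1275.0),
        hu_mean=TruncatedNormal(-716.03, 78.18, -846.76, -140.36),
        hu_sd=TruncatedNormal(148.95, 17.63, 114.81, 195.43),
    )
    return no_rili, rili


def _default_no_rili() -> GroupDistributionSpec:
    return default_group_specs()[0]


def _default_rili() -> GroupDistributionSpec:
    return default_group_specs()[1]


@dataclass(frozen=True)
class CohortConfig:
    """Sizes, seed and per-group distribution specs for a synthetic cohort."""

    n_rili: int = DEFAULT_N_RILI
    n_no_rili: int = DEFAULT_N_NO_RILI
    seed: int = DEFAULT_SEED
    no_rili_spec: GroupDistributionSpec = field(default_factory=_default_no_rili)
    rili_spec: GroupDistributionSpec = field(default_factory=_default_rili)

    def __post_init__(self) -> None:
        if self.n_rili < 0 or self.n_no_rili < 0:
            raise ConfigurationError("group sizes must be >= 0")


_MAX_RESAMPLE_ROUNDS = 1000


def _sample_group(
    spec: GroupDistributionSpec, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    cols = {f: spec[f].sample(n, rng) for f in FEATURE_COLUMNS}
    # Rows breaking hu_min < hu_mean < hu_max or hu_sd/volume positivity are
    # redrawn wholesale (resampling, not clipping, avoids boundary atoms).
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        bad = ~(
            (cols["hu_min"] < cols["hu_mean"])
            & (cols["hu_mean"] < cols["hu_max"])
            & (cols["hu_sd"] > 0)
            & (cols["volume_cm3"] > 0)
        )
        if not bad.any():
            return cols
        k = int(bad.sum())
        for f in FEATURE_COLUMNS:
            cols[f][bad] = spec[f].sample(k, rng)
    raise ConfigurationError(
        "could not draw internally consistent records; the group spec makes "
        "hu_min < hu_mean < hu_max (or positivity) essentially unreachable"
    )


def sample_feature_table(config: CohortConfig) -> pd.DataFrame:
    """Draw a labelled synthetic feature table (no-RILI rows first)."""
    rng = np.random.default_rng(config.seed)
    blocks = []
    offset = 0
    for label, n, spec in (
        (0, config.n_no_rili, config.no_rili_spec),
        (1, config.n_rili, config.rili_spec),
    ):
        cols = _sample_group(spec, n, rng)
        block = pd.DataFrame(cols, columns=FEATURE_COLUMNS)
        block.insert(0, "patient_id", [f"P{offset + i + 1:04d}" for i in range(n)])
        block["rili"] = label
        blocks.append(block)
        offset += n
    table = pd.concat(blocks, ignore_index=True)
    return table[["patient_id", *FEATURE_COLUMNS, "rili"]]


# ---------------------------------------------------------------------------
# Voxel phantoms


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and texture of an ellipsoidal lung phantom.

    ``semi_axes_mm`` fixes the ellipsoid's *shape*; the generator rescales
    all three axes isotropically so the voxelised volume matches the target
    record's ``volume_cm3``. Lesions are spheres of elevated HU (denser
    tissue, offset >= 0) whose common offset is tuned by bisection so the
    extracted ``hu_mean`` matches the target.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    semi_axes_mm: tuple[float, float, float] = (20.0, 24.0, 28.0)
    base_hu: float = -760.0
    noise_sd: float = 55.0
    lesion_count: int = 3
    lesion_radius_mm: float = 4.0
    lesion_hu_offset: float = 300.0
    seed: int = 0
    background_hu: float = -1024.0

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.shape):
            raise ConfigurationError(f"grid shape must be positive, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ConfigurationError(f"spacing must be positive, got {self.spacing}")
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ConfigurationError(f"semi-axes must be positive, got {self.semi_axes_mm}")
        if self.lesion_hu_offset < 0:
            raise ConfigurationError("lesion HU offset must be >= 0 (lesions are denser)")
        if self.noise_sd < 0 or self.lesion_count < 0 or self.lesion_radius_mm <= 0:
            raise ConfigurationError("noise_sd >= 0, lesion_count >= 0, lesion radius > 0")
        half_extent = [n * s / 2.0 for n, s in zip(self.shape, self.spacing)]
        if any(a > h for a, h in zip(self.semi_axes_mm, half_extent)):
            raise ConfigurationError(
                f"semi-axes {self.semi_axes_mm} mm do not fit inside the grid "
                f"(half-extents {half_extent} mm)"
            )


def _voxel_centers_mm(config: PhantomConfig) -> list[np.ndarray]:
    # voxel-centre coordinates relative to the grid centre, one 1-D array per axis
    return [
        (np.arange(n) + 0.5) * s - n * s / 2.0
        for n, s in zip(config.shape, config.spacing)
    ]


def _ellipsoid_mask(config: PhantomConfig, semi_axes: tuple[float, float, float]) -> np.ndarray:
    cx, cy, cz = _voxel_centers_mm(config)
    q = (
        (cx[:, None, None] / semi_axes[0]) ** 2
        + (cy[None, :, None] / semi_axes[1]) ** 2
        + (cz[None, None, :] / semi_axes[2]) ** 2
    )
    return q <= 1.0


def make_phantom(
    target: LungFeatureRecord, config: PhantomConfig = PhantomConfig()
) -> tuple[HUVolume, LungMask]:
    """Build a phantom whose extracted features approximate ``target``.

    Guarantees, verified by re-extraction: mask volume within one voxel
    layer of ``target.volume_cm3`` and extracted ``hu_mean`` within 2 HU of
    ``target.hu_mean``. Other target statistics are not matched exactly —
    noise SD and lesion texture set ``hu_sd``/``hu_min``/``hu_max``.

    Raises
    ------
    GenerationError
        If the target volume does not fit in the grid, or the target mean
        is unreachable (below the base level with lesion offsets >= 0).
    """
    rng = np.random.default_rng(config.seed)
    target_mm3 = target.volume_cm3 * 1000.0
    a, b, c = config.semi_axes_mm
    scale = (target_mm3 / (4.0 / 3.0 * math.pi * a * b * c)) ** (1.0 / 3.0)
    semi_axes = (a * scale, b * scale, c * scale)
    half_extent = [n * s / 2.0 for n, s in zip(config.shape, config.spacing)]
    if any(ax > h for ax, h in zip(semi_axes, half_extent)):
        raise GenerationError(
            f"target volume {target.volume_cm3:.1f} cm^3 needs semi-axes "
            f"{tuple(round(s, 1) for s in semi_axes)} mm, exceeding the grid "
            f"half-extents {tuple(half_extent)} mm"
        )
    mask = _ellipsoid_mask(config, semi_axes)
    n_mask = int(mask.sum())
    if n_mask < 2:
        raise GenerationError("target volume voxelises to fewer than 2 voxels")

    values = np.full(config.shape, config.background_hu, dtype=float)
    if config.noise_sd > 0:
        values[mask] = rng.normal(config.base_hu, config.noise_sd, n_mask)
    else:
        values[mask] = config.base_hu

    lesion_union = np.zeros(config.shape, dtype=bool)
    if config.lesion_count > 0:
        flat = np.flatnonzero(mask)
        centers = np.unravel_index(rng.choice(flat, size=config.lesion_count), config.shape)
        cx, cy, cz = _voxel_centers_mm(config)
        for i in range(config.lesion_count):
            c0 = (cx[centers[0][i]], cy[centers[1][i]], cz[centers[2][i]])
            d2 = (
                (cx[:, None, None] - c0[0]) ** 2
                + (cy[None, :, None] - c0[1]) ** 2
                + (cz[None, None, :] - c0[2]) ** 2
            )
            lesion_union |= (d2 <= config.lesion_radius_mm**2) & mask

    # Centre the noise exactly on base_hu, then tune the mean to the target:
    # by shifting the lesion offset (bisection) when lesions exist, else by
    # shifting the whole masked field.
    values[mask] += config.base_hu - values[mask].mean()
    n_lesion = int(lesion_union.sum())
    if n_lesion > 0:
        offset = _bisect_offset(values, mask, lesion_union, target.hu_mean)
        values[lesion_union] += offset
    else:
        values[mask] += target.hu_mean - config.base_hu

    return HUVolume(values=values, spacing=config.spacing), LungMask(values=mask)


def _bisect_offset(
    values: np.ndarray,
    mask: np.ndarray,
    lesion_union: np.ndarray,
    target_mean: float,
    tol: float = 0.05,
) -> float:
    """Find the lesion HU offset >= 0 that sets the masked mean to target."""

    def masked_mean(offset: float) -> float:
        shifted = values.copy()
        shifted[lesion_union] += offset
        return float(shifted[mask].mean())

    lo, f_lo = 0.0, masked_mean(0.0)
    if f_lo > target_mean + tol:
        raise GenerationError(
            f"target hu_mean {target_mean:.1f} lies below the base level "
            f"({f_lo:.1f}); lesions can only raise the mean (offset >= 0)"
        )
    hi = 1.0
    while masked_mean(hi) < target_mean and hi < 1e7:
        hi *= 2.0
    if masked_mean(hi) < target_mean:
        raise GenerationError("target hu_mean unreachable with bounded lesion offset")
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if masked_mean(mid) < target_mean:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol / max(1, lesion_union.sum()):
            break
    return (lo + hi) / 2.0


def write_phantom(
    volume: HUVolume, mask: LungMask, out_dir: str | Path, prefix: str = "phantom"
) -> tuple[Path, Path]:
    """Write a phantom as a NIfTI (volume, mask) pair; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vol_path = out_dir / f"{prefix}_hu.nii.gz"
    mask_path = out_dir / f"{prefix}_mask.nii.gz"
    write_volume(volume, vol_path)
    write_mask(mask, volume.spacing, mask_path)
    return vol_path, mask_path
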
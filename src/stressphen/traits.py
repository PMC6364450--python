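"""Vegetation segmentation and plant trait indicator extraction.

Segmentation labels a spectral point cloud by a union of three cues —
color (excess green), red-edge spectral contrast, and geometry:

    2G - R - B            >= 0.08
    R_857nm - R_686nm     >= 0.35
    height above soil     >= 0.02 m

Any one criterion suffices; the height cue rescues shaded vegetation the
reflectance cues miss.  Band criteria use the band nearest the requested
wavelength.

Trait indicators summarize the vegetation-labeled points of one box-date:
canopy cover, volumetric estimate, height, per-band reflectance, and
standard vegetation indices (NDVI, EGI, NEGI, NDRI, ERI, band
differences), each reduced by a statistic (mean, variance, min, max).
The classifier-facing subset is the fixed 54-column set: CanCov mean,
VolEst mean, Height mean+variance, and the 25 band means+variances.
"""

from __future__ import annotations

import dataclasses
import logging
import re

import numpy as np

from .optics import N_BANDS, SpectralPointCloud

logger = logging.getLogger(__name__)

NIR_WAVELENGTH = 803.0   #: nm, NIR band used for NDVI
RED_WAVELENGTH = 670.0   #: nm, red band used for NDVI


@dataclasses.dataclass(frozen=True)
class SegmentationThresholds:
    """Thresholds of the three vegetation criteria."""

    excess_green: float = 0.08
    nir_red_difference: float = 0.35
    height: float = 0.02
    hs_wavelengths: tuple[float, float] = (857.0, 686.0)

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError("height threshold must be >= 0")


def _require(cloud: SpectralPointCloud, *attrs: str) -> None:
    for a in attrs:
        if getattr(cloud, a, None) is None:
            raise ValueError(f"cloud is missing required attribute {a!r}")


def segmentation_criteria(cloud: SpectralPointCloud,
                          thr: SegmentationThresholds = SegmentationThresholds()
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The three single-criterion flag sets (color, spectral, height)."""
    _require(cloud, "rgb", "bands")
    r, g, b = cloud.rgb.T
    egi = 2 * g - r - b
    hi = cloud.band_near(thr.hs_wavelengths[0])
    lo = cloud.band_near(thr.hs_wavelengths[1])
    red_edge = cloud.bands[:, hi] - cloud.bands[:, lo]
    color = egi >= thr.excess_green
    spectral = red_edge >= thr.nir_red_difference
    if cloud.height is None:
        geometric = np.zeros(len(cloud), dtype=bool)
    else:
        h = np.asarray(cloud.height, dtype=float)
        geometric = np.where(np.isnan(h), False, h >= thr.height)
    return color, spectral, geometric


def segment_vegetation(cloud: SpectralPointCloud,
                       thr: SegmentationThresholds = SegmentationThresholds()
                       ) -> np.ndarray:
    """Vegetation flags: union of the color, spectral and height criteria."""
    _require(cloud, "rgb", "bands", "height")
    color, spectral, geometric = segmentation_criteria(cloud, thr)
    return color | spectral | geometric


def soil_reference(cloud: SpectralPointCloud,
                   thr: SegmentationThresholds = SegmentationThresholds(),
                   min_soil_points: int = 10) -> float:
    """Estimate the soil depth and attach heights to the cloud (in place).

    A bootstrap pass with the two reflectance criteria only (height is
    undefined before referencing) selects non-vegetation points; the soil
    depth is their median z.  With too few soil points the 95th depth
    percentile of all points is used.  Heights are ``z_soil - z``;
    negative values are ignored (recorded as NaN).
    """
    color, spectral, _ = segmentation_criteria(cloud, thr)
    soil = ~(color | spectral)
    z = cloud.xyz[:, 2]
    if soil.sum() >= min_soil_points:
        z_soil = float(np.median(z[soil]))
    else:
        logger.warning("soil reference: only %d non-vegetation points; "
                       "falling back to 95th depth percentile", int(soil.sum()))
        z_soil = float(np.percentile(z, 95))
    height = z_soil - z
    height[height < 0] = np.nan
    cloud.height = height
    return z_soil


# ---------------------------------------------------------------------------
# Indicators
# ---------------------------------------------------------------------------

_HS_RE = re.compile(r"^HS(\d{1,2})$")
_HSDIFF_RE = re.compile(r"^HSDiff(\d{1,2})_(\d{1,2})$")


def compute_indicator(cloud: SpectralPointCloud, indicator: str) -> np.ndarray:
    """Per-point values of a named trait indicator.

    Supported: ``NDVI`` ((NIR-R)/(NIR+R), 803/670 nm bands), ``EGI``
    (2G-R-B), ``NEGI`` (EGI / mean(R,G,B)), ``NDRI`` ((G-R)/(G+R)),
    ``ERI`` (1.4R-G), ``Height``, ``HS<k>`` (band k reflectance, 1-based)
    and ``HSDiff<a>_<b>`` (band a - band b).  Ratios with zero
    denominator yield NaN (absent).
    """
    r, g, b = cloud.rgb.T
    if indicator == "NDVI":
        nir = cloud.bands[:, cloud.band_near(NIR_WAVELENGTH)]
        red = cloud.bands[:, cloud.band_near(RED_WAVELENGTH)]
        return _safe_ratio(nir - red, nir + red)
    if indicator == "EGI":
        return 2 * g - r - b
    if indicator == "NEGI":
        return _safe_ratio(2 * g - r - b, (r + g + b) / 3)
    if indicator == "NDRI":
        return _safe_ratio(g - r, g + r)
    if indicator == "ERI":
        return 1.4 * r - g
    if indicator == "Height":
        _require(cloud, "height")
        return np.asarray(cloud.height, dtype=float)
    m = _HS_RE.match(indicator)
    if m:
        k = int(m.group(1))
        if not 1 <= k <= N_BANDS:
            raise ValueError(f"band index out of range in {indicator!r}")
        return cloud.bands[:, k - 1]
    m = _HSDIFF_RE.match(indicator)
    if m:
        a, b_ = int(m.group(1)), int(m.group(2))
        if not (1 <= a <= N_BANDS and 1 <= b_ <= N_BANDS):
            raise ValueError(f"band index out of range in {indicator!r}")
        return cloud.bands[:, a - 1] - cloud.bands[:, b_ - 1]
    raise ValueError(f"unknown indicator {indicator!r}")


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    ok = den != 0
    out[ok] = num[ok] / den[ok]
    return out


def canopy_cover(flags: np.ndarray) -> float:
    """Percentage of ROI points labeled vegetation."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("empty ROI: no points to compute canopy cover")
    return 100.0 * flags.sum() / flags.size


def volumetric_estimate(heights: np.ndarray, flags: np.ndarray) -> float:
    """Integral (sum) of vegetation point heights; NaN heights count 0."""
    heights = np.asarray(heights, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    return float(np.nansum(np.where(flags, heights, 0.0)))


STATISTICS = ("mean", "variance", "min", "max")


def summarize(values: np.ndarray, statistic: str) -> float:
    """Reduce per-point values (NaN = absent, excluded) to one statistic.

    Variance is the sample variance (n-1); a single point reports 0.
    An empty set yields NaN (logged by the caller as an absent value).
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    if statistic == "mean":
        return float(vals.mean())
    if statistic == "variance":
        return 0.0 if vals.size == 1 else float(vals.var(ddof=1))
    if statistic == "min":
        return float(vals.min())
    return float(vals.max())


# ---------------------------------------------------------------------------
# Trait records
# ---------------------------------------------------------------------------

#: Fixed order of the 54 classifier-facing indicator-statistic columns.
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    ["CanCov_mean", "VolEst_mean", "Height_mean", "Height_var"]
    + [f"HS{k:02d}_{s}" for k in range(1, N_BANDS + 1) for s in ("mean", "var")]
)

EXTRA_INDICATORS = ("NDVI", "EGI", "NEGI", "NDRI", "ERI")


@dataclasses.dataclass
class TraitRecord:
    """Indicator-statistic values for one box-date."""

    box_id: str
    das: int
    values: dict[str, float]

    def feature_values(self) -> np.ndarray:
        return np.array([self.values.get(c, float("nan")) for c in FEATURE_COLUMNS])


def extract_traits(cloud: SpectralPointCloud, box_id: str, das: int,
                   extended: bool = True) -> TraitRecord:
    """Compute the trait record of a segmented, ROI-filtered cloud.

    The cloud must carry vegetation flags and referenced heights;
    statistics are taken over vegetation points only, while canopy cover
    and the volumetric estimate use all ROI points and are independent of
    the statistic.
    """
    _require(cloud, "vegetation", "height")
    flags = np.asarray(cloud.vegetation, dtype=bool)
    values: dict[str, float] = {
        "CanCov_mean": canopy_cover(flags),
        "VolEst_mean": volumetric_estimate(cloud.height, flags),
    }
    if not flags.any():
        logger.info("box %s DAS %d: no vegetation points; statistics absent",
                    box_id, das)
    heights = np.asarray(cloud.height, dtype=float)[flags]
    values["Height_mean"] = summarize(heights, "mean")
    values["Height_var"] = summarize(heights, "variance")
    veg_bands = cloud.bands[flags]
    for k in range(N_BANDS):
        values[f"HS{k + 1:02d}_mean"] = summarize(veg_bands[:, k], "mean")
        values[f"HS{k + 1:02d}_var"] = summarize(veg_bands[:, k], "variance")
    if extended:
        for ind in EXTRA_INDICATORS:
            vals = compute_indicator(cloud, ind)[flags]
            for s in ("mean", "variance", "min", "max"):
                key = f"{ind}_var" if s == "variance" else f"{ind}_{s}"
                values[key] = summarize(vals, s)
    return TraitRecord(box_id=box_id, das=das, values=values)
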
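"""Reflectance normalization via the in-frame constant-reflectance panel.

Every frame contains a panel of known, spectrally flat reflectance
(R = 0.6 over the sensor range).  Because camera exposure and white
balance are set to use the full digital range, raw intensities are not
reflectances; a per-channel reflectance factor

    f_c = mean over panel pixels of (R / I_pixel,c)

converts intensity to reflectance (reflectance = f_c * intensity).  The
panel can be occluded by overhanging leaves: occlusion is detected in the
RGB image (any panel pixel darker than a threshold, default 0.4) and the
missing factors are filled in from the temporally nearest non-occluded
frames of the same box, falling back to the reference-box frame.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .optics import HSImage, N_BANDS

SOURCE_MEASURED = "measured"
SOURCE_INTERPOLATED = "interpolated"
SOURCE_REFERENCE = "reference-fallback"


@dataclasses.dataclass(frozen=True)
class PanelSpec:
    """Reflectance-panel description.

    ``regions`` maps camera name to the panel rectangle (top, left,
    bottom, right), 0-based half-open pixel coordinates in that camera's
    image.  ``reflectance`` is the known panel reflectance and
    ``occlusion_threshold`` the RGB darkness level below which any panel
    pixel marks the frame occluded.
    """

    regions: dict[str, tuple[int, int, int, int]]
    reflectance: float = 0.6
    occlusion_threshold: float = 0.4

    def __post_init__(self) -> None:
        if not (0 < self.reflectance <= 1):
            raise ValueError("panel reflectance must be in (0, 1]")
        if not (0 <= self.occlusion_threshold < 1):
            raise ValueError("occlusion threshold must be in [0, 1)")

    def region(self, camera: str) -> tuple[int, int, int, int]:
        return self.regions[camera]


@dataclasses.dataclass
class ReflectanceFactors:
    """Per-channel reflectance factors for one frame of one image type."""

    factors: np.ndarray
    occluded: bool = False
    source: str = SOURCE_MEASURED

    def __post_init__(self) -> None:
        self.factors = np.atleast_1d(np.asarray(self.factors, dtype=float))
        if self.source == SOURCE_MEASURED:
            if self.occluded:
                raise ValueError("a measured factor cannot come from an occluded frame")
            if np.any(self.factors <= 0):
                raise ValueError("measured factors must be > 0")


def _crop(image: np.ndarray, region: tuple[int, int, int, int]) -> np.ndarray:
    top, left, bottom, right = region
    if bottom <= top or right <= left:
        raise ValueError("empty panel region")
    patch = image[..., top:bottom, left:right] if image.ndim == 3 and image.shape[0] == N_BANDS \
        else image[top:bottom, left:right]
    if patch.size == 0:
        raise ValueError("empty panel region")
    return patch


def panel_occluded(rgb: np.ndarray, panel: PanelSpec, camera: str = "rgb") -> bool:
    """True iff any panel pixel's RGB-mean brightness falls below threshold."""
    rgb = np.asarray(rgb, dtype=float)
    patch = _crop(rgb, panel.region(camera))
    brightness = patch.mean(axis=-1) if patch.ndim == 3 else patch
    return bool(np.any(brightness < panel.occlusion_threshold))


def reflectance_factor(image: np.ndarray | HSImage, panel: PanelSpec,
                       camera: str) -> ReflectanceFactors:
    """Per-channel factors: mean over panel pixels of R / intensity.

    Accepts a 2D single-channel image, an (H, W, C) multichannel image or
    an :class:`HSImage` cube.  Zero-intensity pixels are excluded from the
    mean; an all-zero panel region raises.
    """
    region = panel.region(camera)
    if isinstance(image, HSImage):
        patch = _crop(image.data, region)          # (25, h, w)
        channels = patch.reshape(N_BANDS, -1)
    else:
        arr = np.asarray(image, dtype=float)
        patch = _crop(arr, region)
        if patch.ndim == 2:
            channels = patch.reshape(1, -1)
        else:
            channels = patch.reshape(-1, patch.shape[-1]).T
    factors = np.empty(channels.shape[0])
    for c, vals in enumerate(channels):
        vals = vals[vals > 0]
        if vals.size == 0:
            raise ValueError("all panel pixels are zero; cannot estimate factor")
        factors[c] = np.mean(panel.reflectance / vals)
    return ReflectanceFactors(factors=factors)


def interpolate_factors(series: Sequence[ReflectanceFactors | None],
                        reference: ReflectanceFactors | None = None
                        ) -> list[ReflectanceFactors]:
    """Fill occluded gaps in a chronologically ordered factor series.

    An occluded entry (``None`` or flagged occluded) receives the mean of
    the nearest earlier and nearest later measured factors; with no
    earlier frame the following one alone is used (and vice versa); with
    no measured frame at all, the reference-frame factors.  Measured
    entries are never altered.
    """
    measured_idx = [i for i, f in enumerate(series)
                    if f is not None and not f.occluded]
    if not measured_idx and reference is None:
        raise ValueError("no measured factors anywhere and no reference frame")
    out: list[ReflectanceFactors] = []
    for i, f in enumerate(series):
        if f is not None and not f.occluded:
            out.append(f)
            continue
        before = [j for j in measured_idx if j < i]
        after = [j for j in measured_idx if j > i]
        if before and after:
            fb, fa = series[before[-1]].factors, series[after[0]].factors
            out.append(ReflectanceFactors((fb + fa) / 2, occluded=True,
                                          source=SOURCE_INTERPOLATED))
        elif after:
            out.append(ReflectanceFactors(series[after[0]].factors.copy(),
                                          occluded=True, source=SOURCE_INTERPOLATED))
        elif before:
            out.append(ReflectanceFactors(series[before[-1]].factors.copy(),
                                          occluded=True, source=SOURCE_INTERPOLATED))
        else:
            out.append(ReflectanceFactors(reference.factors.copy(),
                                          occluded=True, source=SOURCE_REFERENCE))
    return out


def apply_factors(image: np.ndarray | HSImage,
                  factors: ReflectanceFactors) -> np.ndarray | HSImage:
    """Convert intensities to reflectance: reflectance_c = f_c * I_c."""
    f = factors.factors
    if isinstance(image, HSImage):
        if len(f) != N_BANDS:
            raise ValueError("factor count does not match HS band count")
        return HSImage(data=image.data * f[:, None, None],
                       wavelengths=image.wavelengths, calibrated=True)
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        if len(f) != 1:
            raise ValueError("single-channel image needs a single factor")
        return arr * f[0]
    if arr.shape[-1] != len(f):
        raise ValueError("factor count does not match channel count")
    return arr * f
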
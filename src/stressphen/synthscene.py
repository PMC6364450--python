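"""Synthetic multi-modal greenhouse scene generator.

Emulates the structure of a box-experiment dataset: 30 treated cultivation
boxes (plus one reference box) imaged on 16 dates with an RGB camera, a
rectified IR stereo pair and a 5x5 snapshot-mosaic hyperspectral camera,
about 1 m above the soil.

Sugar-beet-like plants are modeled as textured paraboloid height fields
(6 per box) whose cover and height follow logistic growth in days after
sowing (DAS); weeds are small, numerous clumps.  The stress treatments
modulate the scene:

* limited water halves the height growth rate after DAS 28 (drought);
* nitrogen deficit depresses the NIR plateau of the plant spectrum;
* weed pressure adds 2-4 (medium) or 7-12 (high) low clumps per box.

Every frame contains a constant-reflectance panel (R = 0.6) and is
rendered under a random per-frame illumination gain with additive
Gaussian sensor noise, so the radiometric normalization step has real
work to do.  Rendering is exact pinhole ray-surface intersection, which
makes the stereo geometry (and hence the true disparity maps) exact.
Ground truth — per-camera material masks, true disparity, soil depth and
box-level traits computed from the scene parameters (not from renders) —
is returned alongside every frame set.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import zlib
from pathlib import Path

import numpy as np
from scipy.special import expit

from .optics import (CameraIntrinsics, CameraRig, N_BANDS,
                     default_band_wavelengths, default_mosaic_layout,
                     project_points)
from .radiometry import PanelSpec

# ---------------------------------------------------------------------------
# World geometry (meters, ir_left optical frame; z down towards the soil)
# ---------------------------------------------------------------------------

SOIL_DEPTH = 1.0          #: soil surface distance below the cameras
BOX_HALF_X = 0.20         #: cultivation box is 40 x 20 cm
BOX_HALF_Y = 0.10
RIM_WIDTH = 0.01          #: gray rim around the box interior
PANEL_RECT = (-0.07, 0.13, 0.07, 0.183)    #: (x0, y0, x1, y1) on the soil plane
SOWING_DATE = "2018-01-18"

# material codes used in ground-truth masks
MAT_BACKGROUND, MAT_SOIL, MAT_RIM, MAT_PANEL, MAT_PLANT, MAT_WEED = range(6)
MATERIAL_NAMES = ("background", "soil", "box-rim", "panel", "plant", "weed")

_RGB = {
    MAT_BACKGROUND: (0.12, 0.12, 0.12),
    MAT_SOIL: (0.36, 0.25, 0.15),
    MAT_RIM: (0.45, 0.45, 0.45),
    MAT_PANEL: (0.60, 0.60, 0.60),
    MAT_PLANT: (0.08, 0.35, 0.06),
    MAT_WEED: (0.10, 0.33, 0.08),
}
_FLAT_SPECTRUM = {MAT_BACKGROUND: 0.12, MAT_SOIL: 0.25, MAT_RIM: 0.45, MAT_PANEL: 0.60}
_TEXTURE_AMP = {MAT_BACKGROUND: 0.10, MAT_SOIL: 0.35, MAT_RIM: 0.05,
                MAT_PANEL: 0.0, MAT_PLANT: 0.20, MAT_WEED: 0.20}

PLANT_RED_BASE = 0.05     #: red-region reflectance of vegetation
RED_EDGE_CENTER = 715.0   #: nm
RED_EDGE_WIDTH = 12.0     #: nm

WATER_LEVELS = ("Sufficient", "Limited")
NITROGEN_LEVELS = ("Low", "Medium", "High")
WEED_LEVELS = ("None", "Medium", "High")


def vegetation_spectrum(wavelengths: np.ndarray, nir_max: float,
                        red_base: float = PLANT_RED_BASE) -> np.ndarray:
    """Sigmoid red-edge vegetation spectrum: low red, high NIR plateau."""
    wl = np.asarray(wavelengths, dtype=float)
    return red_base + (nir_max - red_base) * expit((wl - RED_EDGE_CENTER) / RED_EDGE_WIDTH)


# ---------------------------------------------------------------------------
# Treatments
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class TreatmentSpec:
    """Applied treatment of one cultivation box."""

    box_id: str
    treatment: str
    water: str
    nitrogen: str
    weeds: str
    replicate: int = 1
    has_crop: bool = True
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.water not in WATER_LEVELS:
            raise ValueError(f"unknown water regime {self.water!r}")
        if self.nitrogen not in NITROGEN_LEVELS:
            raise ValueError(f"unknown nitrogen level {self.nitrogen!r}")
        if self.weeds not in WEED_LEVELS:
            raise ValueError(f"unknown weed pressure {self.weeds!r}")


#: (treatment name, replicates, water, nitrogen, weeds, crop present)
PRESET_TREATMENTS = (
    ("Low N", 3, "Sufficient", "Low", "None", True),
    ("Med N", 3, "Sufficient", "Medium", "None", True),
    ("High N", 3, "Sufficient", "High", "None", True),
    ("Med weeds", 3, "Sufficient", "High", "Medium", True),
    ("High weeds", 3, "Sufficient", "High", "High", True),
    ("Dry", 3, "Limited", "Medium", "None", True),
    ("Weed only dicot", 1, "Sufficient", "High", "High", False),
    ("Weed only monocot", 1, "Sufficient", "High", "High", False),
    ("Weed only mixed", 1, "Sufficient", "High", "High", False),
    ("Low N-med weed", 3, "Sufficient", "Low", "Medium", True),
    ("Drying-med N-high weed", 3, "Limited", "Medium", "High", True),
    ("Drying-low N", 3, "Limited", "Low", "None", True),
)


def make_treatment_plan(preset: str | list[dict] = "paper") -> list[TreatmentSpec]:
    """The 30-box treatment plan plus the untreated reference box.

    A custom plan may be given as a list of dicts with keys box_id,
    treatment, water, nitrogen, weeds (validated against the level
    vocabulary).
    """
    if isinstance(preset, str):
        if preset != "paper":
            raise ValueError(f"unknown preset {preset!r}")
        plan: list[TreatmentSpec] = []
        n = 0
        for name, reps, water, nitrogen, weeds, crop in PRESET_TREATMENTS:
            for r in range(1, reps + 1):
                n += 1
                plan.append(TreatmentSpec(box_id=f"box{n:02d}", treatment=name,
                                          water=water, nitrogen=nitrogen,
                                          weeds=weeds, replicate=r, has_crop=crop))
        plan.append(TreatmentSpec(box_id="reference", treatment="Reference",
                                  water="Sufficient", nitrogen="High", weeds="None",
                                  has_crop=False, is_reference=True))
        return plan
    return [TreatmentSpec(replicate=int(d.get("replicate", 1)),
                          has_crop=bool(d.get("has_crop", True)),
                          is_reference=bool(d.get("is_reference", False)),
                          **{k: d[k] for k in ("box_id", "treatment", "water",
                                               "nitrogen", "weeds")})
            for d in preset]


# ---------------------------------------------------------------------------
# Stress effect model
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class StressEffectModel:
    """Effect sizes coupling treatments to scene parameters.

    The defaults are the study conditions: logistic canopy growth,
    drought halving the height growth rate after DAS 28, a NIR plateau
    depression per nitrogen deficit, and weed clump counts by pressure
    level.
    """

    growth_rate: float = 0.15          #: 1/day, logistic cover rate
    cover_midpoint: float = 30.0       #: DAS at half maximal cover
    max_cover: float = 0.55            #: asymptotic covered fraction of the box
    height_rate: float = 0.12          #: 1/day
    height_midpoint: float = 32.0      #: DAS
    max_height: float = 0.22           #: m, asymptotic plant height
    germination_das: int = 4           #: bare soil before this day
    min_plant_radius: float = 0.012    #: m, seedling size at emergence
    min_weed_radius: float = 0.008     #: m
    drought_onset_das: float = 28.0    #: irrigation stop under Limited water
    drought_height_factor: float = 0.5  #: height growth rate multiplier after onset
    nir_max: float = 0.50              #: NIR plateau of unstressed vegetation
    nir_depression: tuple[float, float, float] = (0.18, 0.09, 0.0)  #: Low, Medium, High N
    #: growth multiplier per N level (Low, Medium, High): deficit stunts
    #: cover and height; medium supply is already sufficient
    nitrogen_growth: tuple[float, float, float] = (0.7, 1.0, 1.0)
    weed_clumps: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] = \
        ((0, 0), (2, 4), (7, 12))      #: count range per pressure None/Medium/High
    weed_max_height: float = 0.045     #: m, weeds stay low
    weed_max_radius: float = 0.040     #: m
    weed_growth_rate: float = 0.25     #: 1/day
    weed_midpoint_das: float = 12.0    #: DAS at half weed size
    weed_nir: float = 0.47             #: NIR plateau of weeds (high-N box)
    weed_red_base: float = 0.09        #: red-region reflectance of weeds
    weed_n_response: float = 0.8       #: fraction of the N depression weeds share
    noise_sigma: float = 0.01          #: additive sensor noise (intensity units)
    gain_range: tuple[float, float] = (0.85, 1.25)  #: per-frame illumination gain
    weed_only_has_crop: bool = False

    def nir_for(self, nitrogen: str) -> float:
        return self.nir_max - self.nir_depression[NITROGEN_LEVELS.index(nitrogen)]

    def clump_range(self, weeds: str) -> tuple[int, int]:
        return self.weed_clumps[WEED_LEVELS.index(weeds)]

    @classmethod
    def null(cls, **overrides) -> "StressEffectModel":
        """Zero effect sizes: treatments leave no trace in the scenes.

        Used as the chance-level control; all treatment-correlated
        differences (including crop absence in the weed-only boxes) are
        neutralized.
        """
        kw = dict(drought_height_factor=1.0, nir_depression=(0.0, 0.0, 0.0),
                  nitrogen_growth=(1.0, 1.0, 1.0),
                  weed_clumps=((0, 0), (0, 0), (0, 0)), weed_only_has_crop=True)
        kw.update(overrides)
        return cls(**kw)


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Paraboloid:
    """One plant or weed: height field h(1 - rho^2/r^2) above the soil."""

    x: float
    y: float
    radius: float
    height: float
    material: int
    nir_max: float
    brightness: float = 1.0
    red_base: float = PLANT_RED_BASE


class _ValueNoise:
    """Seeded two-octave value noise over the table plane (stereo texture)."""

    def __init__(self, rng: np.random.Generator,
                 cells: tuple[float, ...] = (0.02, 0.004),
                 weights: tuple[float, ...] = (0.5, 0.5),
                 extent: tuple[float, float] = (0.45, 0.30)):
        self.cells = cells
        self.weights = weights
        self.extent = extent
        self.grids = []
        for cell in cells:
            nx = int(2 * extent[0] / cell) + 3
            ny = int(2 * extent[1] / cell) + 3
            self.grids.append(rng.uniform(-1.0, 1.0, size=(ny, nx)))

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(x, dtype=float))
        for cell, w, grid in zip(self.cells, self.weights, self.grids):
            gx = (x + self.extent[0]) / cell + 1
            gy = (y + self.extent[1]) / cell + 1
            i0 = np.clip(np.floor(gy).astype(int), 0, grid.shape[0] - 2)
            j0 = np.clip(np.floor(gx).astype(int), 0, grid.shape[1] - 2)
            fy = np.clip(gy - i0, 0, 1)
            fx = np.clip(gx - j0, 0, 1)
            v = (grid[i0, j0] * (1 - fy) * (1 - fx) + grid[i0 + 1, j0] * fy * (1 - fx)
                 + grid[i0, j0 + 1] * (1 - fy) * fx + grid[i0 + 1, j0 + 1] * fy * fx)
            out += w * v
        return out


@dataclasses.dataclass
class Scene:
    """Geometry + materials of one box on one date."""

    treatment: TreatmentSpec
    das: int
    soil_z: float
    elements: list[Paraboloid]
    texture: _ValueNoise


def _box_index(box_id: str) -> int:
    return zlib.crc32(box_id.encode()) & 0x7FFFFFFF


def grow_canopy(treatment: TreatmentSpec, das: int,
                effects: StressEffectModel = StressEffectModel(),
                seed: int = 0) -> Scene:
    """Deterministic scene geometry for one box-date.

    Plant positions, size jitters, weed layout and soil texture depend
    only on (seed, box), so a box keeps its layout across dates; growth
    state depends on DAS through the logistic model.
    """
    if das < 0:
        raise ValueError("das must be >= 0")
    box_idx = _box_index(treatment.box_id)
    rng = np.random.default_rng([int(seed) % (2 ** 31), box_idx])
    texture = _ValueNoise(rng)
    elements: list[Paraboloid] = []

    plant_positions = [(sx, sy) for sx in (-0.133, 0.0, 0.133) for sy in (-0.05, 0.05)]
    plant_jitter = rng.normal(0, 0.005, size=(len(plant_positions), 2))
    plant_size_jitter = 1 + 0.05 * rng.standard_normal(len(plant_positions))

    lo, hi = effects.clump_range(treatment.weeds)
    n_weeds = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
    weed_xy = np.column_stack([rng.uniform(-BOX_HALF_X + 0.04, BOX_HALF_X - 0.04, n_weeds),
                               rng.uniform(-BOX_HALF_Y + 0.03, BOX_HALF_Y - 0.03, n_weeds)])
    weed_size_jitter = 1 + 0.15 * rng.standard_normal(n_weeds)

    # day-to-day variability (leaf angles, micro-illumination): brightness
    # and a small size wobble are redrawn per measurement date
    rng_date = np.random.default_rng([int(seed) % (2 ** 31), box_idx, int(das), 3])
    plant_bright = 1 + 0.05 * rng_date.standard_normal(len(plant_positions))
    plant_size_jitter = plant_size_jitter * (1 + 0.02 * rng_date.standard_normal(len(plant_positions)))
    weed_bright = 1 + 0.05 * rng_date.standard_normal(n_weeds)
    weed_size_jitter = weed_size_jitter * (1 + 0.05 * rng_date.standard_normal(n_weeds))

    if das < effects.germination_das:
        return Scene(treatment, das, SOIL_DEPTH, [], texture)

    crop = treatment.has_crop or (effects.weed_only_has_crop and not treatment.is_reference)
    if treatment.is_reference:
        crop = False
        n_weeds = 0

    if crop:
        ngrow = effects.nitrogen_growth[NITROGEN_LEVELS.index(treatment.nitrogen)]
        cover = ngrow * effects.max_cover * \
            expit(effects.growth_rate * (das - effects.cover_midpoint))
        radius = max(np.sqrt(cover * (2 * BOX_HALF_X) * (2 * BOX_HALF_Y) / (6 * np.pi)),
                     effects.min_plant_radius)
        das_eff = float(das)
        if treatment.water == "Limited" and das > effects.drought_onset_das:
            das_eff = effects.drought_onset_das + effects.drought_height_factor * \
                (das - effects.drought_onset_das)
        height = ngrow * effects.max_height * \
            expit(effects.height_rate * (das_eff - effects.height_midpoint))
        nir = effects.nir_for(treatment.nitrogen)
        for (sx, sy), (jx, jy), sj, br in zip(plant_positions, plant_jitter,
                                              plant_size_jitter, plant_bright):
            elements.append(Paraboloid(x=sx + jx, y=sy + jy,
                                       radius=max(radius * sj, 1e-4),
                                       height=max(height * sj, 1e-4),
                                       material=MAT_PLANT, nir_max=nir,
                                       brightness=max(br, 0.5)))

    wgrow = expit(effects.weed_growth_rate * (das - effects.weed_midpoint_das))
    weed_nir = effects.weed_nir - effects.weed_n_response * \
        effects.nir_depression[NITROGEN_LEVELS.index(treatment.nitrogen)]
    for (wx, wy), sj, br in zip(weed_xy, weed_size_jitter, weed_bright):
        elements.append(Paraboloid(x=wx, y=wy,
                                   radius=max(effects.weed_max_radius * wgrow * sj,
                                              effects.min_weed_radius),
                                   height=min(max(effects.weed_max_height * wgrow * sj,
                                                  1e-4), 0.05),
                                   material=MAT_WEED, nir_max=weed_nir,
                                   brightness=max(br, 0.5),
                                   red_base=effects.weed_red_base))
    return Scene(treatment, das, SOIL_DEPTH, elements, texture)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _flat_material(wx: np.ndarray, wy: np.ndarray) -> np.ndarray:
    """Material of the soil-plane hit point."""
    mat = np.full(wx.shape, MAT_BACKGROUND, dtype=np.int8)
    inside = (np.abs(wx) <= BOX_HALF_X) & (np.abs(wy) <= BOX_HALF_Y)
    rim = (np.abs(wx) <= BOX_HALF_X + RIM_WIDTH) & (np.abs(wy) <= BOX_HALF_Y + RIM_WIDTH) & ~inside
    mat[inside] = MAT_SOIL
    mat[rim] = MAT_RIM
    x0, y0, x1, y1 = PANEL_RECT
    panel = (wx >= x0) & (wx <= x1) & (wy >= y0) & (wy <= y1)
    mat[panel] = MAT_PANEL
    return mat


def _render_view(scene: Scene, cam: CameraIntrinsics, origin: np.ndarray) -> dict:
    """Exact pinhole ray casting of the paraboloid height field.

    Returns depth (z in the camera, which equals ray parameter t for the
    axis-aligned rig), material code, element index (-1 for the soil
    plane) and world-plane coordinates of each pixel's hit point.
    """
    ox, oy, oz = origin
    u = np.arange(cam.width, dtype=float)
    v = np.arange(cam.height, dtype=float)
    xn, yn = np.meshgrid((u - cam.cx) / cam.fx, (v - cam.cy) / cam.fy, indexing="xy")
    zs = scene.soil_z
    t = np.full(xn.shape, zs - oz)
    elem = np.full(xn.shape, -1, dtype=np.int16)
    a = xn * xn + yn * yn
    for k, el in enumerate(scene.elements):
        dx0, dy0 = ox - el.x, oy - el.y
        b = 2 * (xn * dx0 + yn * dy0)
        c = dx0 * dx0 + dy0 * dy0
        s = el.height / (el.radius * el.radius)
        A = -s * a
        B = 1.0 - s * b
        C = oz - zs + el.height - s * c
        disc = B * B - 4 * A * C
        with np.errstate(invalid="ignore", divide="ignore"):
            sq = np.sqrt(np.maximum(disc, 0.0))
            # A < 0 wherever a > 0; the upper (smaller-t) intersection is
            # (-B + sq) / (2A); nadir rays (a == 0) reduce to -C / B
            t1 = np.where(np.abs(A) > 1e-14, (-B + sq) / (2 * A), -C / B)
        rho2 = a * t1 * t1 + b * t1 + c
        hit = (disc >= 0) & (t1 > 0) & (rho2 <= el.radius * el.radius) & (t1 < t)
        t = np.where(hit, t1, t)
        elem = np.where(hit, np.int16(k), elem)
    wx = ox + t * xn
    wy = oy + t * yn
    mat = _flat_material(wx, wy)
    for k, el in enumerate(scene.elements):
        mat[elem == k] = el.material
    return {"t": t, "elem": elem, "mat": mat, "wx": wx, "wy": wy}


def _texture_factor(view: dict, scene: Scene) -> np.ndarray:
    amp = np.zeros(view["mat"].shape)
    for code, a in _TEXTURE_AMP.items():
        amp[view["mat"] == code] = a
    tex = 1 + amp * scene.texture.sample(view["wx"], view["wy"])
    return np.clip(tex, 0.1, None)


def _per_element(view: dict, scene: Scene, attr: str, default: float = 1.0) -> np.ndarray:
    out = np.full(view["mat"].shape, default)
    for k, el in enumerate(scene.elements):
        out[view["elem"] == k] = getattr(el, attr)
    return out


def _compose_rgb(view: dict, scene: Scene, gain: float, sigma: float,
                 rng: np.random.Generator) -> np.ndarray:
    mat = view["mat"]
    base = np.empty(mat.shape + (3,))
    for code, rgb in _RGB.items():
        base[mat == code] = rgb
    base *= _per_element(view, scene, "brightness")[..., None]
    img = gain * base * _texture_factor(view, scene)[..., None]
    img += rng.normal(0, sigma, img.shape)
    return np.clip(img, 0, None)


def _spectral_base(view: dict, scene: Scene, wavelength: np.ndarray | float) -> np.ndarray:
    """Reflectance at per-pixel wavelength(s) before texture/gain/noise."""
    mat = view["mat"]
    wl = np.broadcast_to(np.asarray(wavelength, dtype=float), mat.shape)
    base = np.zeros(mat.shape)
    for code, r in _FLAT_SPECTRUM.items():
        base[mat == code] = r
    veg = (mat == MAT_PLANT) | (mat == MAT_WEED)
    if veg.any():
        nir = _per_element(view, scene, "nir_max")
        bright = _per_element(view, scene, "brightness")
        red0 = _per_element(view, scene, "red_base", PLANT_RED_BASE)
        base[veg] = bright[veg] * (
            red0[veg] + (nir[veg] - red0[veg])
            * expit((wl[veg] - RED_EDGE_CENTER) / RED_EDGE_WIDTH))
    return base


def _compose_mono(view: dict, scene: Scene, wavelength: float, gain: float,
                  sigma: float, rng: np.random.Generator) -> np.ndarray:
    img = gain * _spectral_base(view, scene, wavelength) * _texture_factor(view, scene)
    img += rng.normal(0, sigma, img.shape)
    return np.clip(img, 0, None)


# ---------------------------------------------------------------------------
# Rig and frame sets
# ---------------------------------------------------------------------------

IR_WAVELENGTH = 850.0  #: nm, effective wavelength of the IR cameras


def make_rig(scale: float = 1.0, baseline: float = 0.07,
             wavelengths: np.ndarray | None = None) -> CameraRig:
    """Synthetic camera rig; ``scale`` shrinks all image sizes for speed.

    At scale 1 the RGB camera is 640x480 (0.83 mm/px on the soil), the IR
    pair 320x240 and the HS mosaic 1600x1200 (25 bands of 320x240).
    """
    def intr(w, h, f):
        w, h = int(round(w * scale)), int(round(h * scale))
        return CameraIntrinsics(fx=f * scale, fy=f * scale,
                                cx=(w - 1) / 2, cy=(h - 1) / 2, width=w, height=h)

    T = {
        "ir_left": np.eye(4),
        "ir_right": _translation(baseline, 0, 0),
        "rgb": _translation(-0.005, 0.004, 0),
        "hs": _translation(0.005, 0.004, 0),
    }
    return CameraRig(
        cameras={"ir_left": intr(320, 240, 600.0), "ir_right": intr(320, 240, 600.0),
                 "rgb": intr(640, 480, 1200.0), "hs": intr(320, 240, 616.0)},
        extrinsics=T, baseline=baseline,
        wavelengths=default_band_wavelengths() if wavelengths is None else wavelengths,
        mosaic=default_mosaic_layout())


def _translation(x: float, y: float, z: float) -> np.ndarray:
    T = np.eye(4)
    T[:3, 3] = [x, y, z]
    return T


def panel_pixel_region(rig: CameraRig, camera: str, margin: int = 1
                       ) -> tuple[int, int, int, int]:
    """Pixel rectangle of the panel in a camera image (it never moves)."""
    x0, y0, x1, y1 = PANEL_RECT
    corners = np.array([[x0, y0, SOIL_DEPTH], [x1, y0, SOIL_DEPTH],
                        [x0, y1, SOIL_DEPTH], [x1, y1, SOIL_DEPTH]])
    pix, valid = project_points(corners, rig.cameras[camera], rig.world_to_camera(camera))
    if not valid.all():
        raise ValueError(f"panel outside {camera} field of view")
    for m in range(margin, -1, -1):
        top = int(np.ceil(pix[:, 0].min())) + m
        bottom = int(np.floor(pix[:, 0].max())) - m + 1
        left = int(np.ceil(pix[:, 1].min())) + m
        right = int(np.floor(pix[:, 1].max())) - m + 1
        if bottom > top and right > left:
            return (top, left, bottom, right)
    raise ValueError(f"panel projects to a degenerate region in {camera}")


def default_panel_spec(rig: CameraRig) -> PanelSpec:
    return PanelSpec(regions={c: panel_pixel_region(rig, c)
                              for c in ("rgb", "hs", "ir_left")})


def true_box_roi(rig: CameraRig, camera: str = "rgb"):
    """Ground-truth box rectangle (rim centerline) in a camera image."""
    from .roi import ROI
    hx, hy = BOX_HALF_X + RIM_WIDTH / 2, BOX_HALF_Y + RIM_WIDTH / 2
    corners = np.array([[-hx, -hy, SOIL_DEPTH], [hx, -hy, SOIL_DEPTH],
                        [-hx, hy, SOIL_DEPTH], [hx, hy, SOIL_DEPTH]])
    pix, _ = project_points(corners, rig.cameras[camera], rig.world_to_camera(camera))
    return ROI(top=int(round(pix[:, 0].min())), left=int(round(pix[:, 1].min())),
               bottom=int(round(pix[:, 0].max())) + 1,
               right=int(round(pix[:, 1].max())) + 1, method="override")


@dataclasses.dataclass
class RawFrameSet:
    """One box-date's four raw images plus metadata."""

    box_id: str
    date: str
    das: int
    rgb: np.ndarray
    ir_left: np.ndarray
    ir_right: np.ndarray
    hs_mosaic: np.ndarray


@dataclasses.dataclass
class SceneTruth:
    """Renderer ground truth for one box-date.

    ``material`` maps camera name to a per-pixel material-code mask (the
    hs mask is at band resolution).  The box-level truth traits are
    computed from the scene parameters on a fine soil-plane grid, not
    from the rendered images.
    """

    box_id: str
    das: int
    soil_z: float
    illumination_gain: float
    material: dict[str, np.ndarray]
    disparity: np.ndarray
    canopy_cover: float
    mean_height: float
    mean_bands: np.ndarray


def truth_traits(scene: Scene, wavelengths: np.ndarray,
                 grid_step: float = 0.002) -> tuple[float, float, np.ndarray]:
    """Box-level truth (cover %, mean height m, mean band reflectances).

    Evaluated analytically on a soil-plane grid over the box interior
    from the paraboloid parameters.  Cover is the plain covered-area
    fraction; the mean height and mean band reflectances are weighted by
    the projected solid angle seen from the nadir camera (1/z^2 of the
    canopy surface), matching what a per-point statistic over an ideal
    point cloud samples.  All values derive from scene parameters, not
    from renders.
    """
    xs = np.arange(-BOX_HALF_X + grid_step / 2, BOX_HALF_X, grid_step)
    ys = np.arange(-BOX_HALF_Y + grid_step / 2, BOX_HALF_Y, grid_step)
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    H = np.zeros(X.shape)
    nir = np.zeros(X.shape)
    red0 = np.full(X.shape, PLANT_RED_BASE)
    for el in scene.elements:
        h = el.height * (1 - ((X - el.x) ** 2 + (Y - el.y) ** 2) / el.radius ** 2)
        take = h > H
        H = np.where(take, h, H)
        nir = np.where(take, el.nir_max * el.brightness, nir)
        red0 = np.where(take, el.red_base * el.brightness, red0)
    covered = H > 0
    w = 1.0 / (scene.soil_z - H) ** 2
    cover = 100.0 * float(covered.mean())
    if not covered.any():
        return cover, float("nan"), np.full(N_BANDS, np.nan)
    wc = w[covered]
    mean_h = float((H[covered] * wc).sum() / wc.sum())
    wl = np.asarray(wavelengths)
    spectra = red0[covered][:, None] + (nir[covered] - red0[covered])[:, None] \
        * expit((wl[None, :] - RED_EDGE_CENTER) / RED_EDGE_WIDTH)
    return cover, mean_h, (spectra * wc[:, None]).sum(axis=0) / wc.sum()


def render_frameset(scene: Scene, rig: CameraRig,
                    effects: StressEffectModel = StressEffectModel(),
                    seed: int = 0, occlude_panel: bool = False
                    ) -> tuple[RawFrameSet, SceneTruth]:
    """Render one box-date: RGB, rectified IR pair, HS mosaic + truth.

    The right IR view is re-rendered from the baseline-shifted viewpoint,
    so the stereo pair is geometrically consistent with the returned true
    disparity.  An optional dark occluder can be painted over part of the
    panel for occlusion-handling tests.
    """
    rng = np.random.default_rng([int(seed) % (2 ** 31), _box_index(scene.treatment.box_id),
                                 int(scene.das), 7])
    gain = float(rng.uniform(*effects.gain_range))
    sigma = effects.noise_sigma
    origins = {name: rig.extrinsics[name][:3, 3] for name in rig.extrinsics}

    view_l = _render_view(scene, rig.cameras["ir_left"], origins["ir_left"])
    view_r = _render_view(scene, rig.cameras["ir_right"], origins["ir_right"])
    view_rgb = _render_view(scene, rig.cameras["rgb"], origins["rgb"])

    ir_left = _compose_mono(view_l, scene, IR_WAVELENGTH, gain, sigma, rng)
    ir_right = _compose_mono(view_r, scene, IR_WAVELENGTH, gain, sigma, rng)
    rgb = _compose_rgb(view_rgb, scene, gain, sigma, rng)

    # hyperspectral mosaic: render at mosaic resolution with the per-pixel
    # band wavelength given by the 5x5 filter layout
    hs_cam = rig.cameras["hs"]
    mosaic_cam = CameraIntrinsics(fx=hs_cam.fx * 5, fy=hs_cam.fy * 5,
                                  cx=hs_cam.cx * 5, cy=hs_cam.cy * 5,
                                  width=hs_cam.width * 5, height=hs_cam.height * 5)
    view_hs = _render_view(scene, mosaic_cam, origins["hs"])
    tiles = rig.wavelengths[rig.mosaic]
    wl_map = np.tile(tiles, (mosaic_cam.height // 5 + 1, mosaic_cam.width // 5 + 1))
    wl_map = wl_map[: mosaic_cam.height, : mosaic_cam.width]
    hs_mosaic = _compose_mono(view_hs, scene, wl_map, gain, sigma, rng)

    view_hs_band = _render_view(scene, hs_cam, origins["hs"])

    if occlude_panel:
        # a dark "leaf" over the left half of the panel in RGB and HS
        top, left, bottom, right = panel_pixel_region(rig, "rgb")
        rgb[top:bottom, left:(left + right) // 2] = 0.1 * gain
        t, l, b, r = panel_pixel_region(rig, "hs")
        hs_mosaic[t * 5:b * 5, l * 5:(l + r) // 2 * 5] = 0.1 * gain

    cam_l = rig.cameras["ir_left"]
    disparity = cam_l.fx * rig.baseline / view_l["t"]

    cover, mean_h, mean_bands = truth_traits(scene, rig.wavelengths)
    truth = SceneTruth(
        box_id=scene.treatment.box_id, das=scene.das, soil_z=scene.soil_z,
        illumination_gain=gain,
        material={"ir_left": view_l["mat"], "ir_right": view_r["mat"],
                  "rgb": view_rgb["mat"], "hs": view_hs_band["mat"]},
        disparity=disparity, canopy_cover=cover, mean_height=mean_h,
        mean_bands=mean_bands)
    date = das_to_date(scene.das)
    frames = RawFrameSet(box_id=scene.treatment.box_id, date=date, das=scene.das,
                         rgb=rgb, ir_left=ir_left, ir_right=ir_right,
                         hs_mosaic=hs_mosaic)
    return frames, truth


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def point_truth_vegetation(cloud, truth: "SceneTruth", rig: CameraRig) -> np.ndarray:
    """Ground-truth vegetation flag per cloud point.

    Uses the RGB-camera material mask (the finest truth available) with
    the same nearest-pixel projection convention the fusion step uses.
    """
    pix, ok = project_points(cloud.xyz, rig.cameras["rgb"], rig.world_to_camera("rgb"))
    pr = np.rint(pix).astype(int)
    pr[:, 0] = np.clip(pr[:, 0], 0, truth.material["rgb"].shape[0] - 1)
    pr[:, 1] = np.clip(pr[:, 1], 0, truth.material["rgb"].shape[1] - 1)
    mat = truth.material["rgb"][pr[:, 0], pr[:, 1]]
    return (mat == MAT_PLANT) | (mat == MAT_WEED)


def default_das_schedule(n_dates: int = 16, span_days: int = 70) -> list[int]:
    """Measurement days: ~4-5 day cadence from sowing to harvest."""
    return [int(round(d)) for d in np.linspace(0, span_days, n_dates)]


def das_to_date(das: int, sowing_date: str = SOWING_DATE) -> str:
    d0 = _dt.date.fromisoformat(sowing_date)
    return (d0 + _dt.timedelta(days=int(das))).isoformat()


IMAGE_TYPES = ("rgb", "ir_left", "ir_right", "hs")
_FILENAMES = {"rgb": "rgb.png", "ir_left": "ir_left.png",
              "ir_right": "ir_right.png", "hs": "hs_mosaic.tif"}


def manifest_entries(plan: list[TreatmentSpec], das_schedule: list[int],
                     sowing_date: str = SOWING_DATE) -> list[dict]:
    """The manifest entry list of a dataset (4 image entries per box-date)."""
    entries = []
    for spec in plan:
        for das in das_schedule:
            date = das_to_date(das, sowing_date)
            for itype in IMAGE_TYPES:
                entries.append({"box_id": spec.box_id, "date": date, "das": int(das),
                                "image_type": itype,
                                "path": f"{spec.box_id}/{date}/{_FILENAMES[itype]}"})
    return entries


def generate_dataset(plan: list[TreatmentSpec], das_schedule: list[int],
                     rig: CameraRig, effects: StressEffectModel, seed: int,
                     out_dir: str | Path, overwrite: bool = False,
                     sowing_date: str = SOWING_DATE) -> dict:
    """Render and write a full dataset tree; returns the manifest dict.

    Layout: ``<out>/<box_id>/<date>/{rgb.png, ir_left.png, ir_right.png,
    hs_mosaic.tif, truth_mask_ir.png}`` plus rig.yaml, treatments.csv,
    labels.csv, truth.csv and manifest.json at the root.
    """
    from .io_cli import write_intensity_image  # local import: io_cli imports us
    from .stress_clf import assign_labels

    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)
    rig.to_yaml(out / "rig.yaml")

    truth_rows = ["box_id,date,das,canopy_cover,mean_height,gain"]
    label_rows = ["box_id,date,das,water,nitrogen,weeds"]
    treat_rows = ["box_id,treatment,water,nitrogen,weeds,replicate,has_crop,is_reference"]
    for spec in plan:
        treat_rows.append(f"{spec.box_id},{spec.treatment},{spec.water},{spec.nitrogen},"
                          f"{spec.weeds},{spec.replicate},{int(spec.has_crop)},"
                          f"{int(spec.is_reference)}")
        for das in das_schedule:
            date = das_to_date(das, sowing_date)
            scene = grow_canopy(spec, das, effects, seed)
            frames, truth = render_frameset(scene, rig, effects, seed)
            d = out / spec.box_id / date
            d.mkdir(parents=True, exist_ok=True)
            write_intensity_image(d / "rgb.png", frames.rgb)
            write_intensity_image(d / "ir_left.png", frames.ir_left)
            write_intensity_image(d / "ir_right.png", frames.ir_right)
            write_intensity_image(d / "hs_mosaic.tif", frames.hs_mosaic)
            write_intensity_image(d / "truth_mask_ir.png",
                                  truth.material["ir_left"].astype(np.uint8),
                                  raw_uint8=True)
            mh = "" if np.isnan(truth.mean_height) else f"{truth.mean_height:.9g}"
            truth_rows.append(f"{spec.box_id},{date},{das},"
                              f"{truth.canopy_cover:.9g},{mh},{truth.illumination_gain:.9g}")
            if not spec.is_reference:
                lab = assign_labels(spec, das)
                label_rows.append(f"{spec.box_id},{date},{das},{lab.water},"
                                  f"{lab.nitrogen},{lab.weeds}")
    (out / "truth.csv").write_text("\n".join(truth_rows) + "\n")
    (out / "labels.csv").write_text("\n".join(label_rows) + "\n")
    (out / "treatments.csv").write_text("\n".join(treat_rows) + "\n")
    manifest = {"rig": "rig.yaml", "labels": "labels.csv",
                "treatments": "treatments.csv", "sowing_date": sowing_date,
                "seed": int(seed),
                "entries": manifest_entries(plan, das_schedule, sowing_date)}
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
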
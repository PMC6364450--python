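"""Camera-rig geometry and spectral point-cloud construction.

This module models the two-sensor imaging rig used for box-scale plant
phenotyping: an IR stereo pair plus RGB camera (RealSense-class module) and a
5x5 snapshot-mosaic hyperspectral camera with 25 narrow bands in the
600-950 nm range.  It provides

* pinhole projection with radial-tangential (plumb-bob) distortion,
* demosaicking of the per-pixel spectral filter array (no interpolation),
* dense block-matching stereo with left-right consistency,
* triangulation and projection-based fusion of color and narrow-band
  reflectance onto 3D points (the spectral point cloud), and
* PLY serialization of spectral point clouds.

Conventions: image coordinates are 0-based ``(row, col)``; the 3D frame is
the left IR camera's optical frame with z along the optical axis away from
the camera (towards the soil).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy import ndimage

MOSAIC_TILE = 5  #: side of the spectral filter tile -> 25 bands
N_BANDS = MOSAIC_TILE * MOSAIC_TILE

CAMERA_NAMES = ("ir_left", "ir_right", "rgb", "hs")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics with radial-tangential distortion.

    Parameters are in pixels except the dimensionless distortion
    coefficients ``(k1, k2, p1, p2)``.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    dist: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be > 0")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be > 0")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside image bounds")
        if len(self.dist) != 4:
            raise ValueError("dist must be (k1, k2, p1, p2)")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def to_dict(self) -> dict:
        return {
            "fx": float(self.fx), "fy": float(self.fy),
            "cx": float(self.cx), "cy": float(self.cy),
            "width": int(self.width), "height": int(self.height),
            "dist": [float(d) for d in self.dist],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CameraIntrinsics":
        return cls(fx=d["fx"], fy=d["fy"], cx=d["cx"], cy=d["cy"],
                   width=d["width"], height=d["height"],
                   dist=tuple(d.get("dist", (0.0, 0.0, 0.0, 0.0))))


def _check_rigid(T: np.ndarray) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.shape != (4, 4):
        raise ValueError("rigid transform must be 4x4")
    R = T[:3, :3]
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
        raise ValueError("rotation block is not orthonormal")
    if not np.allclose(T[3], [0, 0, 0, 1]):
        raise ValueError("last row of a rigid transform must be [0,0,0,1]")
    return T


@dataclasses.dataclass
class CameraRig:
    """Calibrated multi-camera rig referenced to the left IR camera.

    ``extrinsics[name]`` maps homogeneous points from camera ``name``'s
    frame into the ir_left (reference) frame.  ``mosaic`` maps the (row,
    col) offset within the 5x5 filter tile to a spectral band index.
    """

    cameras: dict[str, CameraIntrinsics]
    extrinsics: dict[str, np.ndarray]
    baseline: float
    wavelengths: np.ndarray
    mosaic: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in CAMERA_NAMES:
            if name not in self.cameras:
                raise ValueError(f"rig is missing camera {name!r}")
        self.extrinsics = {k: _check_rigid(v) for k, v in self.extrinsics.items()}
        if not np.allclose(self.extrinsics["ir_left"], np.eye(4)):
            raise ValueError("ir_left extrinsic must be the identity")
        if self.baseline <= 0:
            raise ValueError("stereo baseline must be > 0")
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.shape != (N_BANDS,):
            raise ValueError(f"exactly {N_BANDS} band wavelengths required")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if wl.min() < 600 or wl.max() > 950:
            raise ValueError("wavelengths must lie within [600, 950] nm")
        self.wavelengths = wl
        if self.mosaic is None:
            self.mosaic = default_mosaic_layout()
        self.mosaic = _check_mosaic(self.mosaic)

    def world_to_camera(self, name: str) -> np.ndarray:
        """Transform mapping ir_left-frame points into camera ``name``."""
        T = self.extrinsics[name]
        Ti = np.eye(4)
        Ti[:3, :3] = T[:3, :3].T
        Ti[:3, 3] = -T[:3, :3].T @ T[:3, 3]
        return Ti

    def band_near(self, wavelength_nm: float) -> int:
        """Index of the band whose center is nearest the requested wavelength."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "cameras": {n: c.to_dict() for n, c in self.cameras.items()},
            "extrinsics": {n: np.asarray(T).tolist() for n, T in self.extrinsics.items()},
            "baseline": float(self.baseline),
            "wavelengths": [float(w) for w in self.wavelengths],
            "mosaic": np.asarray(self.mosaic).tolist(),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CameraRig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            cameras={n: CameraIntrinsics.from_dict(d) for n, d in doc["cameras"].items()},
            extrinsics={n: np.asarray(T, dtype=float) for n, T in doc["extrinsics"].items()},
            baseline=doc["baseline"],
            wavelengths=np.asarray(doc["wavelengths"], dtype=float),
            mosaic=np.asarray(doc["mosaic"], dtype=int),
        )


def default_band_wavelengths() -> np.ndarray:
    """Default band centers: 25 evenly spaced values on [600, 875] nm.

    Only four centers (670, 686, 803, 857 nm) are pinned down by the
    indicator definitions; the short-pass filter caps the response at
    875 nm, so the default grid spans 600-875 nm.  Override in the rig
    config when the true filter layout is known.
    """
    return np.linspace(600.0, 875.0, N_BANDS)


def default_mosaic_layout() -> np.ndarray:
    """Row-major tile-offset -> band map (bands sorted by wavelength)."""
    return np.arange(N_BANDS, dtype=int).reshape(MOSAIC_TILE, MOSAIC_TILE)


def _check_mosaic(mosaic: np.ndarray) -> np.ndarray:
    mosaic = np.asarray(mosaic, dtype=int)
    if mosaic.shape != (MOSAIC_TILE, MOSAIC_TILE):
        raise ValueError("mosaic layout must be 5x5")
    if sorted(mosaic.ravel().tolist()) != list(range(N_BANDS)):
        raise ValueError("mosaic layout must be a permutation of band indices 0..24")
    return mosaic


@dataclasses.dataclass
class HSImage:
    """Hyperspectral cube: 25 bands x height x width."""

    data: np.ndarray
    wavelengths: np.ndarray
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != N_BANDS:
            raise ValueError(f"HS cube must have shape ({N_BANDS}, H, W)")
        if np.any(self.data < 0):
            raise ValueError("HS values must be >= 0")
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.wavelengths.shape != (N_BANDS,):
            raise ValueError(f"{N_BANDS} wavelengths required")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def band_near(self, wavelength_nm: float) -> int:
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))


@dataclasses.dataclass
class SpectralPointCloud:
    """3D points carrying RGB + 25-band reflectance (+height, +vegetation).

    Coordinates are meters in the ir_left optical frame; ``height`` is
    meters above the soil reference (NaN while unreferenced / for ignored
    negative values); ``vegetation`` is a boolean flag set by segmentation.
    ``source_pixel`` records the (row, col) of the originating left-IR
    pixel, used for truth bookkeeping and re-projection.
    """

    xyz: np.ndarray
    rgb: np.ndarray
    bands: np.ndarray
    wavelengths: np.ndarray
    height: np.ndarray | None = None
    vegetation: np.ndarray | None = None
    source_pixel: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        n = len(self.xyz)
        self.rgb = np.asarray(self.rgb, dtype=float).reshape(n, 3)
        self.bands = np.asarray(self.bands, dtype=float).reshape(n, N_BANDS)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if np.any(self.xyz[:, 2] <= 0):
            raise ValueError("all retained points must have z > 0")
        for name in ("height", "vegetation", "source_pixel"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"attribute {name} length mismatch")

    def __len__(self) -> int:
        return len(self.xyz)

    def subset(self, mask: np.ndarray) -> "SpectralPointCloud":
        def take(a):
            return None if a is None else np.asarray(a)[mask]
        return SpectralPointCloud(
            xyz=self.xyz[mask], rgb=self.rgb[mask], bands=self.bands[mask],
            wavelengths=self.wavelengths, height=take(self.height),
            vegetation=take(self.vegetation), source_pixel=take(self.source_pixel))

    def band_near(self, wavelength_nm: float) -> int:
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))


# ---------------------------------------------------------------------------
# Demosaicking
# ---------------------------------------------------------------------------


def demosaic_snapshot(raw_mosaic: np.ndarray, mosaic: np.ndarray | None = None,
                      wavelengths: np.ndarray | None = None) -> HSImage:
    """Split a snapshot-mosaic frame into its 25 band images.

    Pixel ``(i, j)`` of band ``b`` equals raw pixel ``(5i + rb, 5j + cb)``
    where ``(rb, cb)`` is the band's offset within the 5x5 filter tile —
    a pure subsampling with no interpolation.  Excess rows/cols at the
    bottom/right that do not fill a whole tile are cropped.
    """
    raw = np.asarray(raw_mosaic, dtype=float)
    if raw.ndim != 2:
        raise ValueError("raw mosaic must be a 2D intensity image")
    if raw.shape[0] < MOSAIC_TILE or raw.shape[1] < MOSAIC_TILE:
        raise ValueError("image too small for mosaic")
    mosaic = _check_mosaic(default_mosaic_layout() if mosaic is None else mosaic)
    hb, wb = raw.shape[0] // MOSAIC_TILE, raw.shape[1] // MOSAIC_TILE
    raw = raw[:hb * MOSAIC_TILE, :wb * MOSAIC_TILE]
    cube = np.empty((N_BANDS, hb, wb), dtype=float)
    for r in range(MOSAIC_TILE):
        for c in range(MOSAIC_TILE):
            cube[mosaic[r, c]] = raw[r::MOSAIC_TILE, c::MOSAIC_TILE]
    if wavelengths is None:
        wavelengths = default_band_wavelengths()
    return HSImage(data=cube, wavelengths=wavelengths, calibrated=False)


def remosaic(hs: HSImage, mosaic: np.ndarray | None = None) -> np.ndarray:
    """Inverse of :func:`demosaic_snapshot` on tile-aligned inputs."""
    mosaic = _check_mosaic(default_mosaic_layout() if mosaic is None else mosaic)
    hb, wb = hs.shape
    raw = np.empty((hb * MOSAIC_TILE, wb * MOSAIC_TILE), dtype=float)
    for r in range(MOSAIC_TILE):
        for c in range(MOSAIC_TILE):
            raw[r::MOSAIC_TILE, c::MOSAIC_TILE] = hs.data[mosaic[r, c]]
    return raw


# ---------------------------------------------------------------------------
# Stereo matching
# ---------------------------------------------------------------------------


def stereo_match(left: np.ndarray, right: np.ndarray, block_size: int = 7,
                 max_disparity: int = 48, lr_tol: float = 0.5,
                 uniqueness: float = 0.95, median_size: int = 3) -> np.ndarray:
    """Dense SAD block-matching disparity with left-right consistency.

    Returns a float disparity map (pixels, >= 0) with NaN at invalid
    pixels: failed left-right check (tolerance ``lr_tol``), ambiguous
    matches (uniqueness ratio test, which rejects textureless regions),
    or insufficient disparity range near the left border.  Sub-pixel
    refinement by parabola interpolation of the cost curve, followed by
    an outlier-suppressing median filter (``median_size`` <= 1 disables).
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape or left.ndim != 2:
        raise ValueError("stereo pair must be two equally sized 2D images")
    if block_size < 3 or block_size % 2 == 0:
        raise ValueError("block_size must be odd and >= 3")
    H, W = left.shape
    D = int(max_disparity) + 1
    BIG = 1e30
    cost_l = np.full((D, H, W), BIG)
    cost_r = np.full((D, H, W), BIG)
    for d in range(D):
        if d >= W:
            break
        diff = np.abs(left[:, d:] - right[:, : W - d])
        c = ndimage.uniform_filter(diff, size=block_size, mode="nearest")
        cost_l[d][:, d:] = c
        cost_r[d][:, : W - d] = c

    disp_l = _wta_subpixel(cost_l, uniqueness, BIG)
    disp_r = _wta_subpixel(cost_r, uniqueness, BIG)

    # left-right consistency: d_left(x) must agree with d_right(x - d)
    cols = np.arange(W)[None, :].repeat(H, axis=0)
    dl = disp_l.copy()
    valid = np.isfinite(dl)
    xr = np.clip(np.rint(cols - np.where(valid, dl, 0)).astype(int), 0, W - 1)
    dr = disp_r[np.arange(H)[:, None], xr]
    ok = valid & np.isfinite(dr) & (np.abs(dl - dr) <= lr_tol)
    dl[~ok] = np.nan
    # border guard: half-block frame is unreliable
    b = block_size // 2
    dl[:b], dl[-b:], dl[:, :b], dl[:, -b:] = np.nan, np.nan, np.nan, np.nan
    if median_size and median_size > 1:
        mask = np.isfinite(dl)
        filled = np.where(mask, dl, 0.0)
        med = ndimage.median_filter(filled, size=median_size, mode="nearest")
        # only keep the filtered value where the neighborhood is mostly valid
        frac = ndimage.uniform_filter(mask.astype(float), size=median_size, mode="nearest")
        dl = np.where(mask & (frac > 0.5), med, np.nan)
    return dl


def _wta_subpixel(cost: np.ndarray, uniqueness: float, big: float) -> np.ndarray:
    """Winner-take-all over the cost volume with parabola refinement."""
    D, H, W = cost.shape
    best = np.argmin(cost, axis=0)
    ii, jj = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    cmin = cost[best, ii, jj]
    # uniqueness: best cost must beat the best cost outside +-1 disparity
    masked = cost.copy()
    for off in (-1, 0, 1):
        d = np.clip(best + off, 0, D - 1)
        masked[d, ii, jj] = big
    second = masked.min(axis=0)
    ambiguous = (cmin >= uniqueness * second) | (cmin >= big) | (second >= big)

    dm = np.clip(best - 1, 0, D - 1)
    dp = np.clip(best + 1, 0, D - 1)
    c0, cm, cp = cmin, cost[dm, ii, jj], cost[dp, ii, jj]
    # equiangular (V-shape) interpolation: less pixel-locking than the
    # parabola for SAD cost curves
    interior = (best > 0) & (best < D - 1) & (cm < big) & (cp < big)
    hi = np.maximum(cm, cp)
    denom = hi - c0
    delta = np.where(interior & (denom > 0),
                     0.5 * (cm - cp) / np.maximum(denom, 1e-30), 0.0)
    disp = best + np.clip(delta, -0.5, 0.5)
    disp[ambiguous] = np.nan
    return disp


# ---------------------------------------------------------------------------
# Distortion model and projection
# ---------------------------------------------------------------------------


def distort_normalized(xn: np.ndarray, yn: np.ndarray,
                       dist: tuple[float, float, float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Apply the radial-tangential (plumb-bob) model in normalized coords."""
    k1, k2, p1, p2 = dist
    r2 = xn * xn + yn * yn
    radial = 1 + k1 * r2 + k2 * r2 * r2
    xd = xn * radial + 2 * p1 * xn * yn + p2 * (r2 + 2 * xn * xn)
    yd = yn * radial + p1 * (r2 + 2 * yn * yn) + 2 * p2 * xn * yn
    return xd, yd


def undistort_normalized(xd: np.ndarray, yd: np.ndarray,
                         dist: tuple[float, float, float, float],
                         max_iter: int = 20, tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Invert the distortion model by fixed-point iteration."""
    if not any(dist):
        return np.asarray(xd, dtype=float), np.asarray(yd, dtype=float)
    xn = np.array(xd, dtype=float)
    yn = np.array(yd, dtype=float)
    for _ in range(max_iter):
        xe, ye = distort_normalized(xn, yn, dist)
        dx, dy = xd - xe, yd - ye
        xn, yn = xn + dx, yn + dy
        if max(np.max(np.abs(dx), initial=0), np.max(np.abs(dy), initial=0)) < tol:
            break
    return xn, yn


def triangulate(disparity: np.ndarray, rig: CameraRig) -> tuple[np.ndarray, np.ndarray]:
    """Back-project a disparity map into ir_left-frame 3D points.

    Returns ``(points, pixels)`` where ``points`` is (N, 3) meters and
    ``pixels`` the (row, col) of each emitted point.  Pixels with NaN or
    non-positive disparity emit no point; depth is ``z = f * b / d``.
    """
    disp = np.asarray(disparity, dtype=float)
    cam = rig.cameras["ir_left"]
    rows, cols = np.nonzero(np.isfinite(disp) & (disp > 0))
    d = disp[rows, cols]
    z = cam.fx * rig.baseline / d
    xn, yn = undistort_normalized((cols - cam.cx) / cam.fx, (rows - cam.cy) / cam.fy, cam.dist)
    pts = np.column_stack([xn * z, yn * z, z])
    return pts, np.column_stack([rows, cols])


def project_points(points: np.ndarray, camera: CameraIntrinsics,
                   transform: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Project ir_left-frame points into a camera image.

    ``transform`` maps ir_left-frame points into the target camera frame
    (identity if omitted).  Returns ``(pixels, valid)`` with pixels as
    float (row, col); a point is invalid when behind the camera or
    projecting outside the image bounds.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if transform is not None:
        T = _check_rigid(transform)
        pts = pts @ T[:3, :3].T + T[:3, 3]
    z = pts[:, 2]
    behind = z <= 0
    zs = np.where(behind, 1.0, z)
    xn, yn = pts[:, 0] / zs, pts[:, 1] / zs
    xd, yd = distort_normalized(xn, yn, camera.dist)
    col = camera.fx * xd + camera.cx
    row = camera.fy * yd + camera.cy
    valid = (~behind & (row >= 0) & (row <= camera.height - 1)
             & (col >= 0) & (col <= camera.width - 1))
    return np.column_stack([row, col]), valid


def fuse_spectral_cloud(points: np.ndarray, rgb: np.ndarray, hs: HSImage,
                        rig: CameraRig, pixels: np.ndarray | None = None) -> SpectralPointCloud:
    """Attach RGB and 25-band reflectance to 3D points by projection.

    Each point is projected into the color and hyperspectral cameras and
    takes the value of the nearest pixel (no interpolation).  Points
    falling outside either image are dropped, so the output is always a
    subset of the input.
    """
    if hs.wavelengths is None or len(hs.wavelengths) != N_BANDS:
        raise ValueError("mismatched calibration: hs wavelengths absent")
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    rgb = np.asarray(rgb, dtype=float)
    pix_rgb, ok_rgb = project_points(pts, rig.cameras["rgb"], rig.world_to_camera("rgb"))
    pix_hs, ok_hs = project_points(pts, rig.cameras["hs"], rig.world_to_camera("hs"))
    keep = ok_rgb & ok_hs
    pr = np.rint(pix_rgb[keep]).astype(int)
    ph = np.rint(pix_hs[keep]).astype(int)
    colors = rgb[pr[:, 0], pr[:, 1]]
    bands = hs.data[:, ph[:, 0], ph[:, 1]].T
    src = None if pixels is None else np.asarray(pixels)[keep]
    return SpectralPointCloud(xyz=pts[keep], rgb=colors, bands=bands,
                              wavelengths=hs.wavelengths, source_pixel=src)


# ---------------------------------------------------------------------------
# PLY serialization
# ---------------------------------------------------------------------------


def write_ply(cloud: SpectralPointCloud, path: str | Path) -> None:
    """Write a spectral point cloud as binary little-endian PLY.

    Properties: x,y,z (float32), red/green/blue (uchar, reflectance
    clipped to [0,1] and scaled to 0-255), 25 float32 band reflectances
    named ``band_<wavelength>nm``, and a uchar ``vegetation`` flag.
    """
    n = len(cloud)
    band_names = [f"band_{int(round(w))}nm" for w in cloud.wavelengths]
    fields = ([("x", "<f4"), ("y", "<f4"), ("z", "<f4"),
               ("red", "u1"), ("green", "u1"), ("blue", "u1")]
              + [(b, "<f4") for b in band_names] + [("vegetation", "u1")])
    rec = np.zeros(n, dtype=fields)
    rec["x"], rec["y"], rec["z"] = cloud.xyz.T.astype(np.float32)
    rgb8 = np.rint(np.clip(cloud.rgb, 0, 1) * 255).astype(np.uint8)
    rec["red"], rec["green"], rec["blue"] = rgb8.T
    for i, b in enumerate(band_names):
        rec[b] = cloud.bands[:, i].astype(np.float32)
    veg = np.zeros(n, dtype=np.uint8) if cloud.vegetation is None else cloud.vegetation.astype(np.uint8)
    rec["vegetation"] = veg
    header = ["ply", "format binary_little_endian 1.0", f"element vertex {n}"]
    typemap = {"<f4": "float", "u1": "uchar"}
    for name, typ in fields:
        header.append(f"property {typemap[typ]} {name}")
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        fh.write(rec.tobytes())


def read_ply(path: str | Path) -> SpectralPointCloud:
    """Read a spectral point cloud written by :func:`write_ply`."""
    with open(path, "rb") as fh:
        lines = []
        while True:
            line = fh.readline().decode("ascii").strip()
            lines.append(line)
            if line == "end_header":
                break
        n = next(int(l.split()[-1]) for l in lines if l.startswith("element vertex"))
        props = [l.split()[1:] for l in lines if l.startswith("property")]
        typemap = {"float": "<f4", "uchar": "u1"}
        dtype = [(name, typemap[typ]) for typ, name in props]
        rec = np.frombuffer(fh.read(), dtype=dtype, count=n)
    band_names = [name for _, name in [(t, nm) for t, nm in props] if name.startswith("band_")]
    wavelengths = np.array([float(b[5:-2]) for b in band_names])
    xyz = np.column_stack([rec["x"], rec["y"], rec["z"]]).astype(float)
    rgb = np.column_stack([rec["red"], rec["green"], rec["blue"]]).astype(float) / 255.0
    bands = np.column_stack([rec[b] for b in band_names]).astype(float)
    return SpectralPointCloud(xyz=xyz, rgb=rgb, bands=bands, wavelengths=wavelengths,
                              vegetation=rec["vegetation"].astype(bool))
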
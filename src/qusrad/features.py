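"""Radiomics feature engineering over the QUS parametric maps.

For each of the five channels and each region (tumor core, 5 mm margin)
the map is z-normalized (x100), cleansed of +/-3 sigma outlier pixels,
resampled to an isotropic 0.12 mm grid with a cubic B-spline, and
decomposed into the four level-1 undecimated Coif1 wavelet subbands.
First-order and texture features are computed on the original image and
every subband; nine 2-D shape features are computed once per patient
from the core contour.  The full configuration yields

    5 channels x 2 regions x 5 image types x (18 + 75) + 9 = 4659

named features, aggregated across a patient's frames by ROI-size
weighted averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
import SimpleITK as sitk
from scipy import ndimage
from shapely.geometry import Polygon

from .config import RadiomicsConfig
from .phantom import ClinicalRecord, ROISet
from .spectral import QUSMaps
from .texture import TEXTURE_FEATURE_NAMES, texture_features

__all__ = [
    "FeatureVector",
    "preprocess_map",
    "wavelet_subbands",
    "inverse_wavelet_subbands",
    "discretize",
    "firstorder_features",
    "shape2d_features",
    "extract_frame_features",
    "aggregate_patient",
    "build_feature_matrix",
    "expected_feature_count",
    "FIRSTORDER_NAMES",
    "SHAPE2D_NAMES",
]

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)

SHAPE2D_NAMES = (
    "MeshSurface",
    "PixelSurface",
    "Perimeter",
    "PerimeterSurfaceRatio",
    "Sphericity",
    "MaximumDiameter",
    "MajorAxisLength",
    "MinorAxisLength",
    "Elongation",
)

_FAMILY_ORDER = ("glcm", "glrlm", "glszm", "ngtdm", "gldm")


@dataclass
class FeatureVector:
    """Ordered named features for one frame (or one aggregated patient)."""

    names: list[str]
    values: np.ndarray
    roi_weight: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names and values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


def expected_feature_count(cfg: RadiomicsConfig) -> int:
    """Closed-form feature count for a configuration:
    channels x regions x image_types x (18 + 75) + 9 shape features."""
    n_texture = sum(len(TEXTURE_FEATURE_NAMES[f]) for f in _FAMILY_ORDER)
    return (
        len(cfg.channels)
        * len(cfg.regions)
        * len(cfg.image_types)
        * (len(FIRSTORDER_NAMES) + n_texture)
        + len(SHAPE2D_NAMES)
    )


# ---------------------------------------------------------------------------
# preprocessing


def preprocess_map(
    channel: np.ndarray,
    mask: np.ndarray,
    cfg: RadiomicsConfig,
    in_spacing_mm: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize, trim outliers and resample one parametric map.

    In-mask pixels are z-scored and scaled by ``normalize_scale``;
    pixels beyond ``outlier_sigma`` standard deviations are dropped from
    the mask (and zero-filled, i.e. set to the in-mask mean, before
    interpolation); image and mask are then resampled to the isotropic
    ``resample_spacing_mm`` grid (cubic B-spline for the image, nearest
    neighbor for the mask).  A constant map has an undefined z-score and
    comes back all-zero.
    """
    channel = np.asarray(channel, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if channel.shape != mask.shape:
        raise ValueError("channel and mask shapes differ")
    if mask.sum() < 2:
        raise ValueError("need at least 2 valid pixels")
    vals = channel[mask]
    mu, sd = float(np.mean(vals)), float(np.std(vals))
    out = np.zeros_like(channel)
    if sd > 0:
        out[mask] = (vals - mu) / sd * cfg.normalize_scale
    new_mask = mask.copy()
    cut = cfg.outlier_sigma * cfg.normalize_scale
    outliers = np.abs(out) > cut
    new_mask &= ~outliers
    out[outliers] = 0.0
    out[~mask] = 0.0

    img, msk = _resample(out, new_mask, in_spacing_mm, cfg.resample_spacing_mm)
    return img, msk


def _resample(
    image: np.ndarray,
    mask: np.ndarray,
    in_spacing_mm: tuple[float, float],
    out_spacing_mm: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline resampling of image (nearest neighbor for mask)."""
    ay, ax = in_spacing_mm  # (row spacing, column spacing)
    if np.isclose(ay, out_spacing_mm) and np.isclose(ax, out_spacing_mm):
        return image.copy(), mask.copy()
    img = sitk.GetImageFromArray(image)
    img.SetSpacing((ax, ay))  # sitk spacing is (x, y)
    msk = sitk.GetImageFromArray(mask.astype(np.uint8))
    msk.SetSpacing((ax, ay))
    ny = max(1, int(round(image.shape[0] * ay / out_spacing_mm)))
    nx = max(1, int(round(image.shape[1] * ax / out_spacing_mm)))
    rs = sitk.ResampleImageFilter()
    rs.SetOutputSpacing((out_spacing_mm, out_spacing_mm))
    rs.SetSize((nx, ny))
    rs.SetOutputOrigin(img.GetOrigin())
    rs.SetInterpolator(sitk.sitkBSpline)
    out_img = sitk.GetArrayFromImage(rs.Execute(img))
    rs.SetInterpolator(sitk.sitkNearestNeighbor)
    out_msk = sitk.GetArrayFromImage(rs.Execute(msk)) > 0.5
    return out_img, out_msk


# ---------------------------------------------------------------------------
# wavelets


def _wavelet_filters(name: str) -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet(name)
    return np.asarray(w.dec_lo), np.asarray(w.dec_hi)


def wavelet_subbands(
    image: np.ndarray, wavelet: str = "coif1"
) -> dict[str, np.ndarray]:
    """Single-level undecimated 2-D wavelet decomposition.

    Correlation with the analysis filters along each axis, symmetric
    boundary extension, no downsampling, so every subband has the input
    shape and the original ROI mask applies.  Subband naming follows the
    (row filter, column filter) convention: 'LH' is low-pass down the
    rows and high-pass across the columns.
    """
    image = np.asarray(image, dtype=float)
    lo, hi = _wavelet_filters(wavelet)
    if min(image.shape) < len(lo):
        raise ValueError(
            f"image must be at least {len(lo)} pixels in both dimensions"
        )

    def corr(arr: np.ndarray, f: np.ndarray, axis: int) -> np.ndarray:
        return ndimage.correlate1d(arr, f, axis=axis, mode="reflect")

    rows = {"L": corr(image, lo, 0), "H": corr(image, hi, 0)}
    out = {}
    for rname, r in rows.items():
        for cname, f in (("L", lo), ("H", hi)):
            out[rname + cname] = corr(r, f, 1)
    return out


def inverse_wavelet_subbands(
    subbands: dict[str, np.ndarray], wavelet: str = "coif1"
) -> np.ndarray:
    """Reconstruct the input of :func:`wavelet_subbands`.

    For an orthogonal filter pair the undecimated analysis operator's
    adjoint (convolution with the same filters) is, up to the factor
    1/2 per axis, its inverse: |H(w)|^2 + |G(w)|^2 = 2.  With the
    symmetric boundary extension the identity is exact away from the
    borders; within two filter lengths of an edge the reconstruction is
    approximate.
    """
    lo, hi = _wavelet_filters(wavelet)

    def conv(arr: np.ndarray, f: np.ndarray, axis: int) -> np.ndarray:
        return ndimage.convolve1d(arr, f, axis=axis, mode="reflect")

    acc = None
    for key, sub in subbands.items():
        rf = lo if key[0] == "L" else hi
        cf = lo if key[1] == "L" else hi
        arr = conv(conv(np.asarray(sub, dtype=float), cf, 1), rf, 0)
        acc = arr if acc is None else acc + arr
    assert acc is not None
    return acc / 4.0


# ---------------------------------------------------------------------------
# discretization and first-order features


def discretize(
    image: np.ndarray, mask: np.ndarray, bin_width: float = 15.0
) -> tuple[np.ndarray, int]:
    """Fixed-bin-width quantization of the in-mask intensities.

    ``level(x) = floor((x - min) / bin_width) + 1``; out-of-mask pixels
    get level 0.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    lo = image[mask].min()
    levels = np.zeros(image.shape, dtype=np.int64)
    levels[mask] = np.floor((image[mask] - lo) / bin_width).astype(np.int64) + 1
    return levels, int(levels[mask].max())


def firstorder_features(
    image: np.ndarray,
    mask: np.ndarray,
    bin_width: float = 15.0,
    pixel_area_mm2: float = 1.0,
) -> dict[str, float]:
    """The 18 standard first-order intensity statistics.

    Moments are population moments; skewness of a constant region is 0
    and kurtosis is the Pearson (non-excess) definition, so a Gaussian
    scores 3.  Entropy and uniformity use the fixed-bin-width histogram.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    x = image[mask]
    if x.size < 2:
        raise ValueError("need at least 2 valid pixels")
    mean = float(np.mean(x))
    var = float(np.var(x))
    sd = np.sqrt(var)
    cm3 = float(np.mean((x - mean) ** 3))
    cm4 = float(np.mean((x - mean) ** 4))
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    mid = x[(x >= p10) & (x <= p90)]
    levels, _ = discretize(image, mask, bin_width)
    counts = np.bincount(levels[mask])[1:]
    p = counts[counts > 0] / x.size
    return {
        "Energy": float(np.sum(x**2)),
        "TotalEnergy": float(np.sum(x**2) * pixel_area_mm2),
        "Entropy": -float(np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(mid - np.mean(mid))))
        if mid.size
        else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": 0.0 if sd == 0 else cm3 / sd**3,
        "Kurtosis": 3.0 if var == 0 else cm4 / var**2,
        "Variance": var,
        "Uniformity": float(np.sum(p**2)),
    }


# ---------------------------------------------------------------------------
# shape


def shape2d_features(
    core: Polygon, raster_spacing_mm: float = 0.12
) -> dict[str, float]:
    """Nine 2-D morphology descriptors of the tumor-core contour.

    Surface and perimeter come from the polygon itself; the axis lengths
    and elongation from a principal-component analysis of the rasterized
    pixel centers (axis length = 4 sqrt(eigenvalue), the full axis of
    the equivalent ellipse).
    """
    if core.is_empty or not core.is_valid or core.area <= 0:
        raise ValueError("degenerate core polygon")
    area = float(core.area)
    perimeter = float(core.exterior.length)
    minx, miny, maxx, maxy = core.bounds
    xs = np.arange(minx, maxx + raster_spacing_mm, raster_spacing_mm)
    ys = np.arange(miny, maxy + raster_spacing_mm, raster_spacing_mm)
    xx, yy = np.meshgrid(xs, ys)
    import shapely

    inside = shapely.contains_xy(core, xx.ravel(), yy.ravel())
    pts = np.column_stack([xx.ravel()[inside], yy.ravel()[inside]])
    if len(pts) < 3:
        raise ValueError("core polygon rasterizes to fewer than 3 pixels")
    cov = np.cov(pts.T)
    ev = np.sort(np.linalg.eigvalsh(cov))[::-1]
    ev = np.clip(ev, 0, None)
    major, minor = 4 * np.sqrt(ev[0]), 4 * np.sqrt(ev[1])
    hull = np.asarray(core.convex_hull.exterior.coords)
    d2 = np.sum((hull[:, None, :] - hull[None, :, :]) ** 2, axis=-1)
    return {
        "MeshSurface": area,
        "PixelSurface": float(len(pts) * raster_spacing_mm**2),
        "Perimeter": perimeter,
        "PerimeterSurfaceRatio": perimeter / area,
        "Sphericity": float(2 * np.sqrt(np.pi * area) / perimeter),
        "MaximumDiameter": float(np.sqrt(d2.max())),
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "Elongation": float(np.sqrt(ev[1] / ev[0])) if ev[0] > 0 else 1.0,
    }


# ---------------------------------------------------------------------------
# per-frame extraction and aggregation


def extract_frame_features(
    maps: QUSMaps,
    roi: ROISet,
    cfg: RadiomicsConfig,
) -> FeatureVector:
    """Extract the full radiomics vector from one frame's QUS maps."""
    names: list[str] = []
    values: list[float] = []
    region_masks = {"core": maps.core_mask, "margin": maps.margin_mask}
    total_pixels = 0
    pix_area = cfg.resample_spacing_mm**2
    for channel in cfg.channels:
        cmap = maps.channel(channel)
        for region in cfg.regions:
            rmask = region_masks[region]
            if not rmask.any():
                raise ValueError(
                    f"region {region!r} of channel {channel!r} is fully masked out"
                )
            filled = np.where(rmask, np.nan_to_num(cmap, nan=0.0), 0.0)
            img, msk = preprocess_map(filled, rmask, cfg, maps.grid_spacing_mm)
            if not msk.any():
                raise ValueError(
                    f"no pixels survive preprocessing for {channel}/{region}"
                )
            total_pixels += int(msk.sum())
            images = {"original": img}
            if any(t.startswith("wavelet") for t in cfg.image_types):
                subs = wavelet_subbands(img, cfg.wavelet)
                for sub_name, sub in subs.items():
                    images[f"wavelet-{sub_name}"] = sub
            for image_type in cfg.image_types:
                arr = images[image_type]
                fo = firstorder_features(arr, msk, cfg.bin_width, pix_area)
                for fname in FIRSTORDER_NAMES:
                    names.append(
                        f"{image_type}_firstorder_{fname}_{region}_{channel}"
                    )
                    values.append(fo[fname])
                levels, n_levels = discretize(arr, msk, cfg.bin_width)
                for family in _FAMILY_ORDER:
                    feats = texture_features(
                        levels, msk, n_levels, family, cfg.glcm_distances
                    )
                    for fname in TEXTURE_FEATURE_NAMES[family]:
                        names.append(
                            f"{image_type}_{family}_{fname}_{region}_{channel}"
                        )
                        values.append(feats[fname])
    shape = shape2d_features(roi.core, cfg.resample_spacing_mm)
    for fname in SHAPE2D_NAMES:
        names.append(f"original_shape2D_{fname}_core_all")
        values.append(shape[fname])
    return FeatureVector(names=names, values=np.asarray(values), roi_weight=total_pixels)


def aggregate_patient(frame_vectors: list[FeatureVector]) -> FeatureVector:
    """ROI-size weighted average of a patient's per-frame feature vectors."""
    if not frame_vectors:
        raise ValueError("need at least one frame vector")
    names = frame_vectors[0].names
    for fv in frame_vectors[1:]:
        if fv.names != names:
            raise ValueError("frame vectors have mismatched feature names")
    w = np.array([fv.roi_weight for fv in frame_vectors], dtype=float)
    if w.sum() <= 0:
        raise ValueError("total ROI weight must be positive")
    vals = np.stack([fv.values for fv in frame_vectors])
    agg = (w[:, None] * vals).sum(axis=0) / w.sum()
    return FeatureVector(names=list(names), values=agg, roi_weight=float(w.sum()))


def build_feature_matrix(
    patient_vectors: dict[str, FeatureVector],
    clinical: dict[str, ClinicalRecord],
) -> pd.DataFrame:
    """Patients x features DataFrame with ``odxrs`` and ``label`` columns first."""
    rows = []
    index = []
    for pid in sorted(patient_vectors):
        fv = patient_vectors[pid]
        rec = clinical[pid]
        rows.append(
            pd.concat(
                [pd.Series({"odxrs": rec.odxrs, "label": rec.label}), fv.to_series()]
            )
        )
        index.append(pid)
    df = pd.DataFrame(rows, index=index)
    df.index.name = "patient_id"
    return df
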
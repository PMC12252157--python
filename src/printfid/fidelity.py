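"""Image-based print-fidelity scoring for extruded scaffold meshes.

A printed grid scaffold is compared against its CAD target three ways:

* **SSIM** — windowed structural similarity between the preprocessed print
  image and a reference rendering of the CAD design;
* **dimensional similarity** ``SD = 100 - (|L - L_o| + |W - W_o|) /
  max(L_o, W_o) * 100`` from caliper-style length/width measurements;
* **aggregate similarity** ``SA = (SSIM% + SD) / 2``, the score used to
  label prints High/Low for the classifier;
* **manual similarity** ``100 - E_D`` where ``E_D`` is the mean of the
  length, width and strand-diameter percentage errors.

All similarity outputs are percentages clamped to [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "PrintImage",
    "CadSpec",
    "MeshMeasurement",
    "FidelityScores",
    "preprocess",
    "scale_factors",
    "ssim",
    "dimensional_similarity",
    "aggregate_similarity",
    "percent_errors",
    "normalized_error",
    "manual_similarity",
    "measure_mesh",
    "score_print",
    "load_image",
]

DEFAULT_TARGET_SIZE = (128, 128)


def _clamp_pct(x: float) -> float:
    return float(min(100.0, max(0.0, x)))


@dataclass(frozen=True)
class PrintImage:
    """A 2-D intensity image of a printed mesh with its physical scale.

    ``pixels`` holds intensities in [0, 1]; ``mm_per_pixel`` is the physical
    size of one pixel along rows, ``mm_per_pixel_x`` along columns (defaults
    to isotropic).
    """

    pixels: np.ndarray
    mm_per_pixel: float
    mm_per_pixel_x: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if px.min() < 0 or px.max() > 1:
            raise ValueError("pixel intensities must lie in [0, 1]")
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")
        object.__setattr__(self, "pixels", px)
        if self.mm_per_pixel_x is None:
            object.__setattr__(self, "mm_per_pixel_x", self.mm_per_pixel)
        elif self.mm_per_pixel_x <= 0:
            raise ValueError("mm_per_pixel_x must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class CadSpec:
    """CAD target: overall length/width and intended strand diameter (mm)."""

    length: float
    width: float
    filament_diameter: float

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.filament_diameter) <= 0:
            raise ValueError("all CAD dimensions must be positive")


@dataclass(frozen=True)
class MeshMeasurement:
    """Physical measurements of one printed mesh (mm)."""

    length: float
    width: float
    filament_diameter: float

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.filament_diameter) <= 0:
            raise ValueError("all measurements must be positive")


@dataclass(frozen=True)
class FidelityScores:
    """All fidelity metrics for one print against one CAD target.

    ``ssim`` is the raw index in [-1, 1]; ``ssim_pct`` its percent form;
    ``sd``/``sa``/``manual_similarity`` are percentages in [0, 100];
    ``errors`` is (E_L, E_W, E_FD, E_D) in percent.
    """

    ssim: float
    ssim_pct: float
    sd: float
    sa: float
    manual_similarity: float
    errors: tuple[float, float, float, float]

    def as_dict(self) -> dict:
        e_l, e_w, e_fd, e_d = self.errors
        return {
            "ssim": self.ssim,
            "ssim_pct": self.ssim_pct,
            "sd_pct": self.sd,
            "sa_pct": self.sa,
            "manual_similarity_pct": self.manual_similarity,
            "error_length_pct": e_l,
            "error_width_pct": e_w,
            "error_filament_pct": e_fd,
            "error_mean_pct": e_d,
        }


def _to_gray(pixels: np.ndarray) -> np.ndarray:
    if pixels.ndim == 3:
        from skimage.color import rgb2gray

        return rgb2gray(pixels)
    return np.asarray(pixels, dtype=float)


def preprocess(
    image: PrintImage | np.ndarray,
    target_size: tuple[int, int] = DEFAULT_TARGET_SIZE,
    gaussian_sigma: float = 1.0,
    mm_per_pixel: float | None = None,
) -> PrintImage:
    """Grayscale -> Gaussian smooth -> Otsu binarize -> resize.

    Returns a strictly binary image (values exactly 0.0 and 1.0) of
    ``target_size``, with the physical scale updated by the resize factors.
    A raw ndarray may be passed together with ``mm_per_pixel``.
    """
    from skimage.filters import threshold_otsu
    from skimage.transform import resize

    if isinstance(image, PrintImage):
        px, mmpp, mmppx, src = image.pixels, image.mm_per_pixel, image.mm_per_pixel_x, image.source_id
    else:
        if mm_per_pixel is None:
            raise ValueError("mm_per_pixel is required when passing a raw array")
        px, mmpp, mmppx, src = np.asarray(image, dtype=float), mm_per_pixel, mm_per_pixel, ""
    if px.size == 0:
        raise ValueError("empty image")
    if len(target_size) != 2 or min(target_size) <= 0:
        raise ValueError("target_size must be a positive (rows, cols) pair")

    gray = _to_gray(px)
    if gaussian_sigma > 0:
        gray = ndimage.gaussian_filter(gray, sigma=gaussian_sigma)
    if np.ptp(gray) == 0:
        binary = np.zeros_like(gray)
    else:
        binary = (gray > threshold_otsu(gray)).astype(float)
    resized = resize(binary, target_size, order=1, anti_aliasing=False, preserve_range=True)
    # area-preserving re-binarization: thresholding interpolated edges at a
    # fixed 0.5 systematically thickens thin strands, so threshold at the
    # quantile that keeps the pre-resize foreground fraction
    frac = binary.mean()
    k = int(round(frac * resized.size))
    out = np.zeros(resized.size, dtype=float)
    if k > 0:
        # top-k by interpolated intensity; stable order breaks ties
        order = np.argsort(resized.ravel(), kind="stable")
        out[order[resized.size - k :]] = 1.0
    out = out.reshape(target_size)
    scale_r = gray.shape[0] / target_size[0]
    scale_c = gray.shape[1] / target_size[1]
    return PrintImage(
        pixels=out,
        mm_per_pixel=mmpp * scale_r,
        mm_per_pixel_x=mmppx * scale_c,
        source_id=src,
    )


def scale_factors(measured: MeshMeasurement, objective: CadSpec) -> tuple[float, float]:
    """Length/width scale calibration factors (objective / measured)."""
    return objective.length / measured.length, objective.width / measured.width


def ssim(
    x: PrintImage | np.ndarray,
    y: PrintImage | np.ndarray,
    c1: float | None = None,
    c2: float | None = None,
    window: int = 7,
    data_range: float = 1.0,
    as_printed: bool = False,
) -> float:
    """Mean windowed structural similarity index of two equal-shape images.

    Local statistics (means, variances, covariance) are taken over a
    ``window`` x ``window`` uniform window (reflect padding) and combined as

        [(2 mux muy + C1)(2 sxy + C2)] / [(mux^2 + muy^2 + C1)(sx^2 + sy^2 + C2)]

    with ``C1 = (0.01 * data_range)**2`` and ``C2 = (0.03 * data_range)**2``
    by default. ``as_printed=True`` replaces the variance sum in the second
    denominator factor with ``mux^2 + muy^2``, an alternative form in which
    the self-similarity identity ssim(x, x) = 1 no longer holds in general.
    """
    xa = x.pixels if isinstance(x, PrintImage) else np.asarray(x, dtype=float)
    ya = y.pixels if isinstance(y, PrintImage) else np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError(f"image shapes differ: {xa.shape} vs {ya.shape}")
    if window < 1 or window > min(xa.shape):
        raise ValueError("window must be >= 1 and fit inside the images")
    if c1 is None:
        c1 = (0.01 * data_range) ** 2
    if c2 is None:
        c2 = (0.03 * data_range) ** 2

    def local_mean(a):
        return ndimage.uniform_filter(a, size=window, mode="reflect")

    mux, muy = local_mean(xa), local_mean(ya)
    # E[x^2] - mu^2 etc.; tiny negatives from roundoff are clipped
    sxx = np.clip(local_mean(xa * xa) - mux * mux, 0.0, None)
    syy = np.clip(local_mean(ya * ya) - muy * muy, 0.0, None)
    sxy = local_mean(xa * ya) - mux * muy

    num = (2 * mux * muy + c1) * (2 * sxy + c2)
    if as_printed:
        den = (mux**2 + muy**2 + c1) * (mux**2 + muy**2 + c2)
    else:
        den = (mux**2 + muy**2 + c1) * (sxx + syy + c2)
    return float(np.mean(num / den))


def dimensional_similarity(measured: MeshMeasurement, objective: CadSpec) -> float:
    """SD = 100 - (|L - L_o| + |W - W_o|) / max(L_o, W_o) * 100, in [0, 100]."""
    dev = abs(measured.length - objective.length) + abs(measured.width - objective.width)
    return _clamp_pct(100.0 - dev / max(objective.length, objective.width) * 100.0)


def aggregate_similarity(ssim_pct: float, sd: float) -> float:
    """SA = (SSIM% + SD) / 2, both arguments already on the percent scale."""
    if ssim_pct > 100 or sd > 100:
        raise ValueError("aggregate_similarity expects percent inputs <= 100")
    return _clamp_pct((ssim_pct + sd) / 2.0)


def percent_errors(measured: MeshMeasurement, cad: CadSpec) -> tuple[float, float, float]:
    """Absolute percentage errors (E_L, E_W, E_FD) of the three dimensions."""
    e_l = abs(measured.length - cad.length) / cad.length * 100.0
    e_w = abs(measured.width - cad.width) / cad.width * 100.0
    e_fd = abs(measured.filament_diameter - cad.filament_diameter) / cad.filament_diameter * 100.0
    return e_l, e_w, e_fd


def normalized_error(
    e_l: float, e_w: float, e_fd: float, literal: bool = False
) -> float:
    """Combined dimensional error E_D in percent.

    Default: the mean of the three percentage errors. ``literal=True``
    instead applies the sum/3 * 100 form, which treats its inputs as
    fractions; passing percent values to it overstates E_D by 100x.
    """
    if min(e_l, e_w, e_fd) < 0:
        raise ValueError("percentage errors must be non-negative")
    if literal:
        return (e_l + e_w + e_fd) / 3.0 * 100.0
    return (e_l + e_w + e_fd) / 3.0


def manual_similarity(e_d: float) -> float:
    """Manual (caliper-based) similarity = 100 - E_D, floored at 0."""
    if e_d < 0:
        raise ValueError("E_D must be non-negative")
    return _clamp_pct(100.0 - e_d)


def measure_mesh(binary: PrintImage) -> MeshMeasurement:
    """Image-based stand-in for caliper measurement of a binarized mesh.

    Length and width come from the tight foreground bounding box; the strand
    diameter is estimated as ``2 * median(EDT on the skeleton) - 1`` pixels
    (the half-pixel boundary offset on each side), scaled to mm. Accuracy is
    limited by rasterization to roughly one pixel.
    """
    from skimage.morphology import skeletonize

    fg = binary.pixels > 0.5
    if not fg.any():
        raise ValueError("mesh image has empty foreground; nothing to measure")
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    length = (rows[-1] - rows[0] + 1) * binary.mm_per_pixel
    width = (cols[-1] - cols[0] + 1) * binary.mm_per_pixel_x
    skel = skeletonize(fg)
    if not skel.any():
        raise ValueError("foreground too thin to skeletonize")
    edt = ndimage.distance_transform_edt(
        fg, sampling=(binary.mm_per_pixel, binary.mm_per_pixel_x)
    )
    px_mm = (binary.mm_per_pixel + binary.mm_per_pixel_x) / 2.0
    fd = 2.0 * float(np.median(edt[skel])) - px_mm
    fd = max(fd, px_mm)  # never below one pixel
    return MeshMeasurement(length=float(length), width=float(width), filament_diameter=float(fd))


def score_print(
    image: PrintImage,
    reference: PrintImage,
    cad: CadSpec,
    measured: MeshMeasurement | None = None,
    target_size: tuple[int, int] = DEFAULT_TARGET_SIZE,
    gaussian_sigma: float = 1.0,
    ssim_window: int = 7,
) -> FidelityScores:
    """Compute the full fidelity score set for one print.

    Both images are preprocessed to the common ``target_size`` before SSIM.
    If no physical ``measured`` values are given they are taken from the
    print image via :func:`measure_mesh`.
    """
    prep = preprocess(image, target_size=target_size, gaussian_sigma=gaussian_sigma)
    ref_prep = preprocess(reference, target_size=target_size, gaussian_sigma=gaussian_sigma)
    if measured is None:
        # dimensions are taken at the image's native resolution; the coarse
        # classifier-sized image is only used for SSIM
        full = preprocess(image, target_size=image.shape, gaussian_sigma=gaussian_sigma)
        measured = measure_mesh(full)
    s = ssim(prep, ref_prep, window=ssim_window)
    sd = dimensional_similarity(measured, cad)
    sa = aggregate_similarity(_clamp_pct(100.0 * s), sd)
    e_l, e_w, e_fd = percent_errors(measured, cad)
    e_d = normalized_error(e_l, e_w, e_fd)
    return FidelityScores(
        ssim=s,
        ssim_pct=_clamp_pct(100.0 * s),
        sd=sd,
        sa=sa,
        manual_similarity=manual_similarity(e_d),
        errors=(e_l, e_w, e_fd, e_d),
    )


def load_image(path, mm_per_pixel: float, source_id: str = "") -> PrintImage:
    """Load a PNG/TIFF image (8/16-bit gray or RGB) as a PrintImage in [0,1]."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:
        arr = _to_gray(arr / arr.max() if arr.max() > 1 else arr)
    if arr.max() > 1:
        arr = arr / (65535.0 if arr.max() > 255 else 255.0)
    return PrintImage(
        pixels=np.clip(arr, 0.0, 1.0),
        mm_per_pixel=mm_per_pixel,
        source_id=source_id or str(path),
    )
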
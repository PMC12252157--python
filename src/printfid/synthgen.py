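"""Synthetic data generators with known ground truth.

Every downstream component can be exercised without any external data:

* :func:`render_mesh` rasterizes a square grid scaffold (the 10 mm x 10 mm
  calibration mesh) at a known physical scale, with controllable strand
  width, seeded strand-segment dropout ("broken strands"), additive
  dimensional bias, and intensity noise — returning the image together with
  its true length/width/strand diameter.
* :func:`generate_rheology` samples a power-law flow curve with optional
  multiplicative lognormal noise.
* :func:`generate_doe_responses` fills a factorial run table with responses
  drawn from a known polynomial surface plus Gaussian noise; the default
  surfaces are the shipped ``eq19``/``eq20`` reference models.
* :func:`generate_labeled_dataset` builds a High/Low-labelled image set from
  a two-component print-quality mixture, scored by the fidelity module and
  joined to a factorial experiment matrix.

All generators are pure functions of their arguments and seed: the same
spec and seed reproduce the output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .doe import FactorialDesign, FactorialResults, reference_model
from .extrusion import RheologyCurve
from .fidelity import CadSpec, MeshMeasurement, PrintImage, score_print

__all__ = [
    "DEFAULT_CAD",
    "MeshRenderSpec",
    "SurfaceTruth",
    "surface_truth",
    "render_mesh",
    "generate_rheology",
    "generate_doe_responses",
    "generate_labeled_dataset",
    "write_dataset",
]

#: The calibration target: a 10 mm x 10 mm mesh of 0.25 mm strands
#: (the bore of the standard 25-gauge tip).
DEFAULT_CAD = CadSpec(length=10.0, width=10.0, filament_diameter=0.25)

#: Response-noise standard deviations chosen so that the all-terms OLS fit
#: at 17 replicates per cell has R^2 close to 0.85 (diameter, mm) and 0.97
#: (SSIM similarity, %): sigma^2 = V_surface * (1 - R^2) / R^2 with the
#: surface variances over the balanced design being 0.6189 mm^2 and
#: 37.60 %^2 respectively.
DEFAULT_NOISE_SIGMA = {"eq19": 0.330, "eq20": 1.078}


@dataclass(frozen=True)
class MeshRenderSpec:
    """Full specification of one rendered scaffold image.

    ``grid_pitch`` is the strand-to-strand spacing (a 10 mm mesh at 2.5 mm
    pitch has 5 strands per direction); ``defect_rate`` the fraction of
    strand segments (between crossings) removed; ``dimension_bias`` an
    additive error applied to the overall length and width; ``noise_sigma``
    the Gaussian intensity-noise level.
    """

    cad: CadSpec = DEFAULT_CAD
    strand_width: float = 0.25
    grid_pitch: float = 2.5
    image_size: tuple[int, int] = (256, 256)
    mm_per_pixel: float = 0.05
    defect_rate: float = 0.0
    dimension_bias: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strand_width >= self.grid_pitch:
            raise ValueError("strand_width must be smaller than grid_pitch")
        if not 0.0 <= self.defect_rate <= 1.0:
            raise ValueError("defect_rate must lie in [0, 1]")
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")


def _line_positions(extent: float, pitch: float, strand_width: float) -> np.ndarray:
    # outer strand centrelines are inset by half a strand so the outer
    # edge-to-edge extent of the mesh equals `extent` exactly
    n_lines = int(round(extent / pitch)) + 1
    half = strand_width / 2.0
    return np.linspace(half, extent - half, n_lines)


def render_mesh(spec: MeshRenderSpec) -> tuple[PrintImage, MeshMeasurement]:
    """Rasterize a grid mesh and return it with its ground-truth dimensions.

    Strands run the full length/width of the (possibly biased) mesh; defects
    remove whole segments between neighbouring crossings, chosen by the
    seeded RNG. The returned measurement is the *true* geometry from the
    spec (bias included), independent of the raster.
    """
    w = spec.strand_width
    if w / spec.mm_per_pixel < 1.0:
        raise ValueError(
            "strand thinner than one pixel at this scale; decrease mm_per_pixel"
        )
    length = spec.cad.length + spec.dimension_bias  # rows (y), mm
    width = spec.cad.width + spec.dimension_bias  # cols (x), mm
    if length <= 0 or width <= 0:
        raise ValueError("dimension_bias collapses the mesh to nothing")
    rows, cols = spec.image_size
    canvas_h = rows * spec.mm_per_pixel
    canvas_w = cols * spec.mm_per_pixel
    if length + w > canvas_h or width + w > canvas_w:
        raise ValueError("mesh does not fit in the image; enlarge image_size")
    y0 = (canvas_h - length) / 2.0
    x0 = (canvas_w - width) / 2.0

    yc = (np.arange(rows) + 0.5) * spec.mm_per_pixel - y0  # mesh-frame coords
    xc = (np.arange(cols) + 0.5) * spec.mm_per_pixel - x0
    h_pos = _line_positions(length, spec.grid_pitch, w)  # horizontal strands: const y
    v_pos = _line_positions(width, spec.grid_pitch, w)  # vertical strands: const x

    rng = np.random.default_rng(spec.seed)
    # Segment list: (orientation, line index, segment index); dropout is a
    # single seeded Bernoulli draw per segment, so seed fixes the defects.
    segs = [("h", i, j) for i in range(len(h_pos)) for j in range(len(v_pos) - 1)]
    segs += [("v", i, j) for i in range(len(v_pos)) for j in range(len(h_pos) - 1)]
    keep = rng.random(len(segs)) >= spec.defect_rate

    img = np.zeros((rows, cols), dtype=float)
    half = w / 2.0
    for (orient, i, j), kept in zip(segs, keep):
        if not kept:
            continue
        if orient == "h":
            band = np.abs(yc - h_pos[i]) <= half
            span = (xc >= v_pos[j] - half) & (xc <= v_pos[j + 1] + half)
            img[np.ix_(band, span)] = 1.0
        else:
            band = np.abs(xc - v_pos[i]) <= half
            span = (yc >= h_pos[j] - half) & (yc <= h_pos[j + 1] + half)
            img[np.ix_(span, band)] = 1.0

    if spec.noise_sigma > 0:
        img = np.clip(img + rng.normal(0.0, spec.noise_sigma, img.shape), 0.0, 1.0)

    truth = MeshMeasurement(length=length, width=width, filament_diameter=w)
    image = PrintImage(
        pixels=img, mm_per_pixel=spec.mm_per_pixel, source_id=f"synthetic-{spec.seed}"
    )
    return image, truth


def generate_rheology(
    n: float,
    K: float,
    rate_range: tuple[float, float] = (0.1, 100.0),
    points: int = 30,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> RheologyCurve:
    """Power-law flow curve eta = K * rate**(n-1) with lognormal noise.

    Rates are log-spaced over ``rate_range``; ``noise_sigma`` is the sigma
    of the multiplicative lognormal factor (0.05 is a typical instrument
    repeatability). A shear-thinning curve (n < 1) is strictly decreasing
    when noiseless.
    """
    if n <= 0 or K <= 0:
        raise ValueError("power-law parameters n and K must be positive")
    lo, hi = rate_range
    if not (0 < lo < hi):
        raise ValueError("rate_range must satisfy 0 < low < high")
    if points < 3:
        raise ValueError("need at least 3 points")
    rates = np.geomspace(lo, hi, points)
    visc = K * rates ** (n - 1.0)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        visc = visc * np.exp(rng.normal(0.0, noise_sigma, points))
    return RheologyCurve(
        shear_rate=rates, viscosity=visc, shear_stress=visc * rates, temperature=32.0
    )


@dataclass(frozen=True)
class SurfaceTruth:
    """A known response surface on the centered factors, plus noise level."""

    response_name: str
    coefficients: dict = field(default_factory=dict)
    noise_sigma: float = 0.0

    def model(self) -> FactorialResults:
        return FactorialResults(dict(self.coefficients), response_name=self.response_name)


def surface_truth(name: str, noise_sigma: float | None = None) -> SurfaceTruth:
    """Truth built from a shipped reference surface (``eq19`` or ``eq20``).

    ``noise_sigma=None`` selects the calibrated default for that surface;
    pass 0 for noiseless responses.
    """
    ref = reference_model(name)
    sigma = DEFAULT_NOISE_SIGMA[name] if noise_sigma is None else float(noise_sigma)
    return SurfaceTruth(
        response_name=ref.response_name, coefficients=dict(ref.params), noise_sigma=sigma
    )


def generate_doe_responses(
    design: FactorialDesign | pd.DataFrame,
    truths: SurfaceTruth | list[SurfaceTruth],
    seed: int | None = None,
) -> pd.DataFrame:
    """Run table with simulated responses: truth surface + N(0, sigma) noise."""
    runs = design.runs() if isinstance(design, FactorialDesign) else design.copy()
    if isinstance(truths, SurfaceTruth):
        truths = [truths]
    rng = np.random.default_rng(seed)
    for truth in truths:
        model = truth.model()
        mean = model.predict(
            runs["nozzle_G"], runs["pressure_kPa"], runs["velocity_mm_s"]
        )
        noise = rng.normal(0.0, truth.noise_sigma, len(runs)) if truth.noise_sigma > 0 else 0.0
        runs[truth.response_name] = np.asarray(mean) + noise
    return runs


def _quality_spec(good: bool, cad: CadSpec, rng: np.random.Generator, seed: int) -> MeshRenderSpec:
    """Draw per-image render parameters from the good or poor quality component."""
    if good:
        defect = rng.uniform(0.0, 0.04)
        bias = rng.normal(0.0, 0.08)
        noise = rng.uniform(0.0, 0.05)
    else:
        defect = rng.uniform(0.30, 0.60)
        bias = rng.choice([-1.0, 1.0]) * rng.uniform(1.2, 2.4)
        noise = rng.uniform(0.05, 0.15)
    return MeshRenderSpec(
        cad=cad,
        defect_rate=float(defect),
        dimension_bias=float(bias),
        noise_sigma=float(noise),
        seed=seed,
    )


def generate_labeled_dataset(
    n_images: int,
    quality_mixture: tuple[float, float] = (0.5, 0.5),
    cad: CadSpec = DEFAULT_CAD,
    seed: int = 0,
    sa_threshold: float = 70.0,
    plant_optimum: bool = False,
    replicates: int = 1,
) -> tuple[list[PrintImage], pd.DataFrame, pd.DataFrame]:
    """A High/Low-labelled print-image set with its experiment matrix.

    Images are drawn from a two-component quality mixture (probabilities
    ``quality_mixture`` for good/poor prints), scored against a clean render
    of ``cad`` by the fidelity module, and labelled High (1) when the
    aggregate similarity SA reaches ``sa_threshold`` percent. Each image is
    joined round-robin to a row of the full-factorial experiment matrix.

    ``plant_optimum=True`` renders the first image exactly at the CAD spec
    (no defects, bias, or noise) so the dataset has a known best print.

    Returns ``(images, manifest, matrix)``; the manifest has one row per
    image with columns image_index, source_id, run_id, label, sa_pct,
    manual_similarity_pct, ssim_pct, sd_pct.
    """
    if n_images < 2:
        raise ValueError("need at least 2 images")
    p_good, p_bad = quality_mixture
    if not np.isclose(p_good + p_bad, 1.0) or min(p_good, p_bad) < 0:
        raise ValueError("quality_mixture must be a probability pair summing to 1")
    rng = np.random.default_rng(seed)
    matrix = FactorialDesign(replicates=replicates).runs()
    reference, _ = render_mesh(MeshRenderSpec(cad=cad))

    images: list[PrintImage] = []
    records = []
    for i in range(n_images):
        if plant_optimum and i == 0:
            spec = MeshRenderSpec(cad=cad, seed=int(rng.integers(2**31)))
        else:
            good = bool(rng.random() < p_good)
            spec = _quality_spec(good, cad, rng, seed=int(rng.integers(2**31)))
        img, _truth = render_mesh(spec)
        img = replace(img, source_id=f"img-{i:04d}")
        scores = score_print(img, reference, cad)
        run = matrix.iloc[i % len(matrix)]
        records.append(
            {
                "image_index": i,
                "source_id": img.source_id,
                "run_id": int(run["run_id"]),
                "label": int(scores.sa >= sa_threshold),
                "sa_pct": scores.sa,
                "manual_similarity_pct": scores.manual_similarity,
                "ssim_pct": scores.ssim_pct,
                "sd_pct": scores.sd,
            }
        )
        images.append(img)
    manifest = pd.DataFrame(records)
    n_high = int(manifest["label"].sum())
    if n_high == 0 or n_high == len(manifest):
        raise ValueError(
            f"quality mixture produced a single class ({n_high} High of "
            f"{len(manifest)}); adjust sa_threshold or the mixture"
        )
    return images, manifest, matrix


def write_dataset(
    outdir,
    n_images: int = 400,
    seed: int = 0,
    cad: CadSpec = DEFAULT_CAD,
    rheology_params: tuple[float, float] = (0.4, 120.0),
) -> dict:
    """Write a complete synthetic study to ``outdir`` (PNG + CSV files).

    Produces the mesh images, the dataset manifest, the factorial experiment
    matrix with simulated responses, and a rheology flow curve; returns the
    paths written.
    """
    import imageio.v3 as iio
    from pathlib import Path

    out = Path(outdir)
    imgdir = out / "images"
    imgdir.mkdir(parents=True, exist_ok=True)
    images, manifest, matrix = generate_labeled_dataset(n_images, seed=seed, cad=cad)
    paths = []
    for img, (_, row) in zip(images, manifest.iterrows()):
        p = imgdir / f"{row['source_id']}.png"
        iio.imwrite(p, (img.pixels * 255).astype(np.uint8))
        paths.append(str(p))
    manifest = manifest.assign(image_path=paths)
    matrix = generate_doe_responses(
        matrix, [surface_truth("eq19"), surface_truth("eq20")], seed=seed
    )
    n, K = rheology_params
    curve = generate_rheology(n, K, noise_sigma=0.05, seed=seed)
    rheo = pd.DataFrame(
        {
            "shear_rate_1_per_s": curve.shear_rate,
            "viscosity_Pa_s": curve.viscosity,
            "shear_stress_Pa": curve.shear_stress,
            "temperature_C": curve.temperature,
        }
    )
    manifest_path = out / "manifest.csv"
    matrix_path = out / "experiment_matrix.csv"
    rheo_path = out / "rheology.csv"
    manifest.to_csv(manifest_path, index=False)
    matrix.to_csv(matrix_path, index=False)
    rheo.to_csv(rheo_path, index=False)
    return {
        "images": str(imgdir),
        "manifest": str(manifest_path),
        "experiment_matrix": str(matrix_path),
        "rheology": str(rheo_path),
    }
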
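"""Synthetic trabecular-bone phantoms with known ground-truth density.

A seeded Gaussian random field is thresholded at the ``1 - bvtv`` quantile
to produce a two-phase (bone / marrow) texture whose bone-pixel fraction
matches the requested bone-volume fraction up to discreteness.  Each
phantom is rendered twice:

* **QCT**: the phase image plus mild additive HU noise;
* **clinical CT**: the phase image blurred by a Gaussian PSF, then noisier.

Ground-truth density is the reference calibration line applied to the exact
noise-free phase mixture ``bvtv * bone_hu + (1 - bvtv) * marrow_hu``, so
the synthetic path exercises the calibration module.  Images are rounded to
integer HU so they round-trip losslessly through the fixture format.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import texture
from .calibration import PhantomCalibration, PhantomInsert, fit_calibration, hu_to_bmd
from .errors import ParameterError
from .imaging import CTSlice, quantize, save_slice

#: Collinear reference inserts defining the ground-truth HU->density line
#: (slope 0.8 mg/cm3 per HU, intercept 40 mg/cm3).
REFERENCE_INSERTS: tuple[PhantomInsert, ...] = (
    PhantomInsert(nominal_density=0.0, measured_hu=-50.0),
    PhantomInsert(nominal_density=100.0, measured_hu=75.0),
    PhantomInsert(nominal_density=200.0, measured_hu=200.0),
)


def reference_calibration() -> PhantomCalibration:
    """The calibration line used to define synthetic ground-truth density."""
    return fit_calibration(list(REFERENCE_INSERTS))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic trabecular phantom."""

    size: tuple[int, int] = (128, 128)
    bvtv: float = 0.3
    correlation_length: float = 2.0
    bone_hu: float = 700.0
    marrow_hu: float = -50.0
    noise_sd_qct: float = 10.0
    noise_sd_clinical: float = 20.0
    blur_sigma_clinical: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.bvtv < 1.0):
            raise ParameterError("bvtv must lie strictly between 0 and 1")
        if self.bone_hu <= self.marrow_hu:
            raise ParameterError("bone_hu must exceed marrow_hu")
        if min(self.noise_sd_qct, self.noise_sd_clinical) < 0 or self.blur_sigma_clinical < 0:
            raise ParameterError("noise SDs and blur sigma must be >= 0")
        if self.correlation_length <= 0:
            raise ParameterError("correlation_length must be positive")
        if min(self.size) < 4 * self.correlation_length:
            raise ParameterError(
                f"size {self.size} too small for correlation_length {self.correlation_length}"
            )


@dataclass
class SyntheticSample:
    """Paired QCT/clinical renderings of one phantom plus its true density."""

    qct_image: CTSlice
    clinical_image: CTSlice
    true_bmd: float
    spec: PhantomSpec
    bone_mask: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def generate_phantom(
    spec: PhantomSpec, cal: PhantomCalibration | None = None
) -> SyntheticSample:
    """Render one phantom pair from a seeded Gaussian random field."""
    cal = cal or reference_calibration()
    rng = np.random.default_rng(spec.seed)
    field_ = ndimage.gaussian_filter(
        rng.standard_normal(spec.size), sigma=spec.correlation_length, mode="wrap"
    )
    threshold = np.quantile(field_, 1.0 - spec.bvtv)
    bone = field_ >= threshold
    base = np.where(bone, spec.bone_hu, spec.marrow_hu)

    qct = base + rng.normal(0.0, spec.noise_sd_qct, spec.size)
    blurred = ndimage.gaussian_filter(base, sigma=spec.blur_sigma_clinical, mode="nearest")
    clinical = blurred + rng.normal(0.0, spec.noise_sd_clinical, spec.size)

    mean_hu = spec.bvtv * spec.bone_hu + (1.0 - spec.bvtv) * spec.marrow_hu
    return SyntheticSample(
        qct_image=CTSlice(np.round(qct), source_id=f"synthetic-qct-{spec.seed}"),
        clinical_image=CTSlice(np.round(clinical), source_id=f"synthetic-clin-{spec.seed}"),
        true_bmd=hu_to_bmd(mean_hu, cal),
        spec=spec,
        bone_mask=bone,
    )


def default_quantization_bounds(spec: PhantomSpec) -> tuple[float, float]:
    """Fixed HU binning range used for phantom feature extraction.

    Absolute bounds (rather than per-image min/max) keep gray-level bins
    identical between the QCT and clinical renderings of the same phantom,
    which is what makes features transferable across scanners; the margin
    absorbs additive noise tails.
    """
    return (spec.marrow_hu - 60.0, spec.bone_hu + 60.0)


def phantom_features(
    img: CTSlice,
    ng: int = 8,
    d: int = 1,
    thetas: tuple[int, ...] = texture.DEFAULT_THETAS,
    symmetric: bool = False,
    bounds: tuple[float, float] | None = None,
) -> texture.TextureFeatureVector:
    """Quantize a full phantom image and extract the five texture features."""
    qroi = quantize(img.pixel_hu, ng, bounds=bounds)
    return texture.features_from_roi(qroi, d=d, thetas=thetas, symmetric=symmetric)


def generate_dataset(
    n: int,
    bvtv_range: tuple[float, float] = (0.1, 0.6),
    seed: int = 0,
    spec: PhantomSpec = PhantomSpec(),
    ng: int = 8,
    d: int = 1,
    thetas: tuple[int, ...] = texture.DEFAULT_THETAS,
    keep_images: bool = False,
):
    """Generate ``n`` phantoms with bvtv drawn uniformly from ``bvtv_range``.

    Returns ``(qct_features, clinical_features, samples)`` where the feature
    tables are DataFrames with columns ``contrast, correlation, energy,
    homogeneity, entropy, bmd`` (QCT features pair with true density for
    training; clinical features are the held-out evaluation inputs).
    ``samples`` is the list of phantoms when ``keep_images`` is set, else
    empty.  Fully deterministic for a fixed seed.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    lo, hi = bvtv_range
    if not (0.0 < lo < hi < 1.0):
        raise ParameterError(f"invalid bvtv range {bvtv_range}")
    rng = np.random.default_rng(seed)
    bvtvs = rng.uniform(lo, hi, size=n)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    cal = reference_calibration()

    bounds = default_quantization_bounds(spec)
    rows_q, rows_c, samples = [], [], []
    for bvtv, child in zip(bvtvs, child_seeds):
        s = replace(spec, bvtv=float(bvtv), seed=int(child))
        sample = generate_phantom(s, cal)
        fq = phantom_features(sample.qct_image, ng=ng, d=d, thetas=thetas, bounds=bounds)
        fc = phantom_features(sample.clinical_image, ng=ng, d=d, thetas=thetas, bounds=bounds)
        rows_q.append({**fq.as_dict(), "bmd": sample.true_bmd})
        rows_c.append({**fc.as_dict(), "bmd": sample.true_bmd})
        if keep_images:
            samples.append(sample)
    cols = list(texture.FEATURE_COLUMNS) + ["bmd"]
    return (
        pd.DataFrame(rows_q, columns=cols),
        pd.DataFrame(rows_c, columns=cols),
        samples,
    )


def write_dataset(
    out_dir: str | Path,
    n: int,
    bvtv_range: tuple[float, float] = (0.1, 0.6),
    seed: int = 0,
    spec: PhantomSpec = PhantomSpec(),
    ng: int = 8,
    save_images: bool = False,
) -> dict:
    """Emit features.csv / truth.csv / spec.json (and optionally images)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    feats_q, feats_c, samples = generate_dataset(
        n, bvtv_range, seed, spec, ng=ng, keep_images=save_images
    )
    feats_q.to_csv(out_dir / "features_qct.csv", index=False)
    feats_c.drop(columns=["bmd"]).to_csv(out_dir / "features_clinical.csv", index=False)
    feats_q[["bmd"]].to_csv(out_dir / "truth.csv", index=False)
    meta = {
        "n": n,
        "bvtv_range": list(bvtv_range),
        "seed": seed,
        "ng": ng,
        "phantom_spec": asdict(spec),
    }
    with open(out_dir / "spec.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    if save_images:
        img_dir = out_dir / "images"
        img_dir.mkdir(exist_ok=True)
        for k, sample in enumerate(samples):
            save_slice(sample.qct_image, img_dir / f"qct_{k:04d}.png")
            save_slice(sample.clinical_image, img_dir / f"clinical_{k:04d}.png")
    return meta
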
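"""Gray-level co-occurrence matrices and second-order texture features.

A GLCM ``P(i, j | d, theta)`` is the relative frequency of gray-level pairs
``(i, j)`` separated by displacement ``d`` at orientation ``theta``.  Five
scalar statistics of the matrix — energy, entropy, contrast, homogeneity and
correlation — form the texture feature vector fed to the regression network.

Offsets (row, col) per orientation, for displacement d:

=====  ==========
theta  offset
=====  ==========
0      (0, +d)
45     (-d, +d)
90     (-d, 0)
135    (-d, -d)
=====  ==========

Accumulation is asymmetric by default (each pair counted once in the offset
direction); pass ``symmetric=True`` to also count the reversed pair.
Features are evaluated on the matrix averaged over orientations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateROIError, ParameterError
from .imaging import QuantizedROI

#: (row, col) displacement per supported orientation, unit distance.
OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}

#: Orientations used by default (0, 45 and 90 degrees, d=1).
DEFAULT_THETAS: tuple[int, ...] = (0, 45, 90)

#: Network input order used across CSV files and model I/O.
FEATURE_COLUMNS: tuple[str, ...] = (
    "contrast",
    "correlation",
    "energy",
    "homogeneity",
    "entropy",
)


@dataclass
class CooccurrenceMatrix:
    """Normalized joint probability of gray-level pairs at one offset."""

    P: np.ndarray
    ng: int
    d: int
    theta: int | str  # degrees, or "averaged"
    symmetric: bool
    pair_count: int

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (self.ng, self.ng):
            raise ParameterError(f"GLCM must be {self.ng}x{self.ng}, got {self.P.shape}")
        if np.any(self.P < 0):
            raise ParameterError("GLCM entries must be non-negative")


@dataclass
class TextureFeatureVector:
    """The five Haralick statistics used as network inputs, plus marginals."""

    energy: float
    entropy: float
    contrast: float
    homogeneity: float
    correlation: float
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    correlation_degenerate: bool = False

    def as_array(self) -> np.ndarray:
        """Values in :data:`FEATURE_COLUMNS` order."""
        return np.array(
            [self.contrast, self.correlation, self.energy, self.homogeneity, self.entropy]
        )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_COLUMNS, self.as_array()))


def compute_glcm(
    roi: QuantizedROI,
    d: int = 1,
    theta: int = 0,
    symmetric: bool = False,
) -> CooccurrenceMatrix:
    """Accumulate the co-occurrence matrix of a quantized ROI at one offset.

    Pairs are counted only where both pixels lie inside the ROI mask (always
    true for rectangular ROIs).
    """
    if theta not in OFFSETS:
        raise ParameterError(f"unsupported orientation {theta}; choose from {sorted(OFFSETS)}")
    if d < 1:
        raise ParameterError(f"displacement must be >= 1, got {d}")
    dr, dc = OFFSETS[theta]
    dr, dc = dr * d, dc * d
    levels = roi.levels
    mask = roi.mask
    nrow, ncol = levels.shape

    # index windows of valid "first pixel" positions such that the partner is in-grid
    r0, r1 = max(0, -dr), min(nrow, nrow - dr)
    c0, c1 = max(0, -dc), min(ncol, ncol - dc)
    if r0 >= r1 or c0 >= c1:
        raise DegenerateROIError(f"ROI too small for offset ({dr}, {dc})")

    a = levels[r0:r1, c0:c1]
    b = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    ok = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    if not ok.any():
        raise DegenerateROIError("no co-occurring pixel pairs inside the ROI mask")

    ng = roi.ng
    idx = a[ok] * ng + b[ok]
    counts = np.bincount(idx, minlength=ng * ng).reshape(ng, ng).astype(float)
    if symmetric:
        counts = counts + counts.T
    pair_count = int(counts.sum())
    return CooccurrenceMatrix(
        P=counts / pair_count,
        ng=ng,
        d=d,
        theta=theta,
        symmetric=symmetric,
        pair_count=pair_count,
    )


def average_glcms(mats: list[CooccurrenceMatrix]) -> CooccurrenceMatrix:
    """Element-wise mean of co-occurrence matrices, renormalized to sum 1."""
    if not mats:
        raise ParameterError("need at least one matrix to average")
    ng = mats[0].ng
    if any(m.ng != ng for m in mats):
        raise ParameterError("cannot average GLCMs with different Ng")
    mean = np.mean([m.P for m in mats], axis=0)
    total = mean.sum()
    if total > 0:
        mean = mean / total
    return CooccurrenceMatrix(
        P=mean,
        ng=ng,
        d=mats[0].d,
        theta="averaged",
        symmetric=all(m.symmetric for m in mats),
        pair_count=sum(m.pair_count for m in mats),
    )


def energy(P: np.ndarray | CooccurrenceMatrix) -> float:
    """Angular second moment: sum of squared matrix entries."""
    P = _as_matrix(P)
    return float(np.sum(P * P))


def entropy(P: np.ndarray | CooccurrenceMatrix, base: float = 2.0) -> float:
    """Shannon entropy of the pair distribution, in bits by default.

    The ``0 * log 0`` terms are taken as zero.
    """
    P = _as_matrix(P)
    nz = P[P > 0]
    return float(-np.sum(nz * np.log(nz)) / np.log(base))


def contrast(P: np.ndarray | CooccurrenceMatrix) -> float:
    """Sum of ``(i - j)^2 * P(i, j)`` — local gray-level variation."""
    P = _as_matrix(P)
    i, j = np.indices(P.shape)
    return float(np.sum((i - j) ** 2 * P))


def homogeneity(P: np.ndarray | CooccurrenceMatrix) -> float:
    """Inverse difference moment: sum of ``P(i, j) / (1 + (i - j)^2)``."""
    P = _as_matrix(P)
    i, j = np.indices(P.shape)
    return float(np.sum(P / (1.0 + (i - j) ** 2)))


def marginal_stats(P: np.ndarray | CooccurrenceMatrix) -> tuple[float, float, float, float]:
    """Means and population SDs of the row/column marginals (mu_x, mu_y, sigma_x, sigma_y)."""
    P = _as_matrix(P)
    ng = P.shape[0]
    levels = np.arange(ng)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(levels @ px)
    mu_y = float(levels @ py)
    sigma_x = float(np.sqrt(((levels - mu_x) ** 2) @ px))
    sigma_y = float(np.sqrt(((levels - mu_y) ** 2) @ py))
    return mu_x, mu_y, sigma_x, sigma_y


def correlation(P: np.ndarray | CooccurrenceMatrix) -> float:
    """Linear dependency of paired gray levels.

    ``(sum_ij i*j*P(i,j) - mu_x*mu_y) / (sigma_x*sigma_y)``.  The degenerate
    case ``sigma_x * sigma_y == 0`` (constant image) returns 1.0; use
    :func:`correlation_with_flag` to detect it.
    """
    return correlation_with_flag(P)[0]


def correlation_with_flag(P: np.ndarray | CooccurrenceMatrix) -> tuple[float, bool]:
    P = _as_matrix(P)
    mu_x, mu_y, sigma_x, sigma_y = marginal_stats(P)
    denom = sigma_x * sigma_y
    if denom == 0.0:
        return 1.0, True
    i, j = np.indices(P.shape)
    cov = float(np.sum(i * j * P)) - mu_x * mu_y
    return cov / denom, False


def features_from_glcm(P: np.ndarray | CooccurrenceMatrix, entropy_base: float = 2.0) -> TextureFeatureVector:
    """Evaluate all five statistics on one (typically averaged) matrix."""
    mu_x, mu_y, sigma_x, sigma_y = marginal_stats(P)
    corr, degenerate = correlation_with_flag(P)
    return TextureFeatureVector(
        energy=energy(P),
        entropy=entropy(P, base=entropy_base),
        contrast=contrast(P),
        homogeneity=homogeneity(P),
        correlation=corr,
        mu_x=mu_x,
        mu_y=mu_y,
        sigma_x=sigma_x,
        sigma_y=sigma_y,
        correlation_degenerate=degenerate,
    )


def features_from_roi(
    roi: QuantizedROI,
    d: int = 1,
    thetas: tuple[int, ...] = DEFAULT_THETAS,
    symmetric: bool = False,
    entropy_base: float = 2.0,
    per_orientation_average: bool = False,
) -> TextureFeatureVector:
    """GLCMs at all orientations, averaged, then the five statistics.

    With ``per_orientation_average`` the statistics are instead computed per
    orientation and averaged afterwards (sensitivity-check variant).
    """
    mats = [compute_glcm(roi, d=d, theta=t, symmetric=symmetric) for t in thetas]
    if per_orientation_average:
        per = [features_from_glcm(m, entropy_base=entropy_base) for m in mats]
        mean = lambda attr: float(np.mean([getattr(f, attr) for f in per]))  # noqa: E731
        return TextureFeatureVector(
            energy=mean("energy"),
            entropy=mean("entropy"),
            contrast=mean("contrast"),
            homogeneity=mean("homogeneity"),
            correlation=mean("correlation"),
            mu_x=mean("mu_x"),
            mu_y=mean("mu_y"),
            sigma_x=mean("sigma_x"),
            sigma_y=mean("sigma_y"),
            correlation_degenerate=any(f.correlation_degenerate for f in per),
        )
    return features_from_glcm(average_glcms(mats), entropy_base=entropy_base)


def _as_matrix(P: np.ndarray | CooccurrenceMatrix) -> np.ndarray:
    if isinstance(P, CooccurrenceMatrix):
        return P.P
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ParameterError("GLCM must be a square 2D matrix")
    return P
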
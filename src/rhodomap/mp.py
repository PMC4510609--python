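"""Macular pigment optical density mapping from multi-spectral AF images.

Macular pigment (lutein/zeaxanthin) absorbs blue light and is concentrated
at the fovea.  Taking the log-ratio of perifoveal to foveal autofluorescence
at several excitation/emission bands, with zero-sum weights ``w_j``, cancels
the unknown fluorescence-efficiency ratio and isolates the macular pigment
optical density at 460 nm:

    D_MP(460) = [sum_j w_j ln(AF_p(j)/AF_f(j))]
                / [sum_j w_j (k_mp(L_j) + k_mp(l_j))].

With two bands and weights (1, -1) this is the classic Delori two-wavelength
formula; more bands enable self-consistency checks by varying the weights.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .model import Geometry, OpticalCoefficients, SpectralBand

__all__ = [
    "MPImageSet",
    "MPDensityMap",
    "SelfConsistencyReport",
    "perifoveal_reference",
    "mp_density",
    "self_consistency",
    "default_weight_sets",
    "MacularPigmentMapper",
]

_ZERO_SUM_TOL = 1e-12


@dataclass
class MPImageSet:
    """Co-registered AF images, one per spectral band, with zero-sum weights."""

    images: list[np.ndarray]
    bands: list[SpectralBand]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.images = [np.asarray(im, dtype=float) for im in self.images]
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.images)
        if n < 2:
            raise ValueError("need at least two bands")
        if len(self.bands) != n or self.weights.shape != (n,):
            raise ValueError("images, bands and weights must have equal length")
        shape = self.images[0].shape
        if any(im.shape != shape for im in self.images):
            raise ValueError("all images must share one shape")
        if any(im.ndim != 2 for im in self.images):
            raise ValueError("images must be 2-D")
        if abs(self.weights.sum()) > _ZERO_SUM_TOL:
            raise ValueError("weights must sum to zero")

    @property
    def n_bands(self) -> int:
        return len(self.images)

    @property
    def shape(self) -> tuple[int, int]:
        return self.images[0].shape

    def stack(self) -> np.ndarray:
        return np.stack(self.images, axis=0)


@dataclass
class MPDensityMap:
    """Per-pixel D_MP(460 nm) field with its perifoveal reference record."""

    d_mp: np.ndarray
    reference_value: np.ndarray  # per-band perifoveal AF values
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.d_mp = np.asarray(self.d_mp, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.d_mp)

    def clipped(self) -> np.ndarray:
        """Display helper: D_MP with negative (noise-driven) values at zero."""
        return np.clip(np.nan_to_num(self.d_mp), 0.0, None)


def _annulus_mask(shape, center, radius_px, width_px) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    r = np.hypot(rr - center[0], cc - center[1])
    return (r >= radius_px - width_px / 2.0) & (r <= radius_px + width_px / 2.0)


def perifoveal_reference(image: np.ndarray, center: tuple[float, float],
                         radius_deg: float, width_deg: float,
                         geometry: Geometry) -> float:
    """Mean intensity over a perifoveal annulus centered on the fovea.

    The perifoveal reference ``AF_p`` is conventionally a circular average
    at 6 degrees eccentricity, where macular pigment is negligible.
    """
    image = np.asarray(image, dtype=float)
    radius_px = radius_deg * geometry.px_per_deg
    width_px = width_deg * geometry.px_per_deg
    outer = radius_px + width_px / 2.0
    h, w = image.shape
    if (center[0] - outer < -0.5 or center[0] + outer > h - 0.5
            or center[1] - outer < -0.5 or center[1] + outer > w - 0.5):
        raise ValueError("annulus exceeds image bounds")
    mask = _annulus_mask(image.shape, center, radius_px, width_px)
    if not mask.any():
        raise ValueError("annulus contains no pixels")
    return float(image[mask].mean())


def _denominator(bands, weights, coeffs: OpticalCoefficients) -> float:
    den = float(sum(w * coeffs.k_mp_band(b) for w, b in zip(weights, bands)))
    if abs(den) < 1e-12:
        raise ValueError("weight/extinction denominator vanishes")
    return den


def mp_density(mpset: MPImageSet, coeffs: OpticalCoefficients,
               reference: np.ndarray) -> MPDensityMap:
    """Invert the multi-wavelength log-ratio model for D_MP(460 nm).

    Pixels with nonpositive intensity in any band are flagged invalid (NaN
    in the map) rather than clamped: the formula lives in the log domain
    and clamping would bias the density estimate.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (mpset.n_bands,):
        raise ValueError("need one perifoveal reference value per band")
    if np.any(reference <= 0):
        raise ValueError("perifoveal reference values must be positive")
    den = _denominator(mpset.bands, mpset.weights, coeffs)

    stack = mpset.stack()
    valid = np.all(stack > 0, axis=0)
    num = np.zeros(mpset.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        for w, ref, img in zip(mpset.weights, reference, mpset.images):
            num += w * np.log(ref / img)
    d = num / den
    d[~valid] = np.nan
    return MPDensityMap(d_mp=d, reference_value=reference, valid=valid)


def default_weight_sets(n_bands: int) -> list[np.ndarray]:
    """The (1, -1, 0, ...) pair plus all balanced zero-sum +-1 patterns."""
    sets = [np.array([1.0, -1.0] + [0.0] * (n_bands - 2))]
    if n_bands >= 4 and n_bands % 2 == 0:
        for pos in itertools.combinations(range(n_bands), n_bands // 2):
            w = np.full(n_bands, -1.0)
            w[list(pos)] = 1.0
            if w[0] > 0:  # canonical sign, avoids duplicates up to scale
                sets.append(w)
    return sets


@dataclass
class SelfConsistencyReport:
    """Spread of D_MP maps across alternative zero-sum weight choices."""

    maps: list[MPDensityMap]
    spread: np.ndarray           # per-pixel standard deviation across maps
    max_pairwise: np.ndarray     # per-pixel max absolute pairwise difference
    best_index: int              # weight set minimizing total spread
    weight_sets: list[np.ndarray] = field(default_factory=list)


def self_consistency(mpset: MPImageSet, weight_sets: list[np.ndarray],
                     coeffs: OpticalCoefficients,
                     reference: np.ndarray) -> SelfConsistencyReport:
    """Recompute the density map under each weight set and measure spread.

    The weight set whose map deviates least (in summed squared deviation
    from the cross-set mean) is reported as the most self-consistent one.
    """
    if len(weight_sets) < 2:
        raise ValueError("need at least two weight sets")
    maps = []
    for w in weight_sets:
        ws = MPImageSet(images=mpset.images, bands=mpset.bands,
                        weights=np.asarray(w, dtype=float))
        maps.append(mp_density(ws, coeffs, reference))
    stack = np.stack([m.d_mp for m in maps], axis=0)
    spread = np.nanstd(stack, axis=0)
    max_pair = np.zeros(mpset.shape)
    for i, j in itertools.combinations(range(len(maps)), 2):
        max_pair = np.fmax(max_pair, np.abs(stack[i] - stack[j]))
    mean_map = np.nanmean(stack, axis=0)
    totals = [np.nansum((m - mean_map) ** 2) for m in stack]
    return SelfConsistencyReport(maps=maps, spread=spread,
                                 max_pairwise=max_pair,
                                 best_index=int(np.argmin(totals)),
                                 weight_sets=[np.asarray(w) for w in weight_sets])


class MacularPigmentMapper(BaseEstimator):
    """Estimator computing D_MP(460 nm) maps from a multi-spectral AF set.

    Parameters
    ----------
    radius_deg, width_deg : float
        Perifoveal reference annulus (default: 6 degrees radius, 1 degree
        wide), averaged per band to a scalar reference ``AF_p``.
    coeffs : OpticalCoefficients or None
        Extinction tables; the packaged templates when None.
    clip_negative : bool
        If True, report the display-clipped map (negatives at zero) in
        ``d_mp_map_.clipped()`` consumers; the raw map always retains
        negative noise excursions.
    """

    def __init__(self, radius_deg: float = 6.0, width_deg: float = 1.0,
                 coeffs: OpticalCoefficients | None = None,
                 clip_negative: bool = False):
        self.radius_deg = radius_deg
        self.width_deg = width_deg
        self.coeffs = coeffs
        self.clip_negative = clip_negative

    def fit(self, mpset: MPImageSet, geometry: Geometry):
        """Compute per-band references and the density map."""
        coeffs = self.coeffs or OpticalCoefficients.default()
        self.reference_ = np.array([
            perifoveal_reference(im, geometry.center, self.radius_deg,
                                 self.width_deg, geometry)
            for im in mpset.images
        ])
        self.d_mp_map_ = mp_density(mpset, coeffs, self.reference_)
        return self

    def transform(self, mpset: MPImageSet) -> np.ndarray:
        """Density map of ``mpset`` using the fitted per-band references."""
        coeffs = self.coeffs or OpticalCoefficients.default()
        m = mp_density(mpset, coeffs, self.reference_)
        return m.clipped() if self.clip_negative else m.d_mp

    def fit_transform(self, mpset: MPImageSet, geometry: Geometry) -> np.ndarray:
        return self.fit(mpset, geometry).transform(mpset)
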
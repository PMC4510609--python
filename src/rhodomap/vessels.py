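"""Vessel detection from the fit diagnostics, and the smooth occlusion mask.

Blood in retinal vessels blocks the excitation light, so vessel pixels see
largely dark noise and do not follow the bleaching model.  Two detectors
fall directly out of the fitting stage: (1) the per-pixel iteration count
N(x, y) -- the semi-explicit scheme contracts at a data-independent rate,
so N measures how far a pixel's solution sits from the shared initial
values, which spikes on and around vessels; (2) the L1 residual between
the measured curve and the fitted double-exponential.  Their union,
dilated, forms the occlusion set Omega; a clipped-linear ramp of the
Euclidean distance to Omega gives the smooth mask chi in [0, 1] used to
down-weight fidelity near vessel borders during inpainting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .fit import FitResult
from .model import AFMovie

__all__ = [
    "VesselMask",
    "residual_map",
    "detect_from_iterations",
    "detect_from_residual",
    "finalize_mask",
    "VesselDetector",
]


@dataclass
class VesselMask:
    """Occlusion set Omega and its smooth [0, 1] relaxation chi."""

    omega: np.ndarray
    chi: np.ndarray
    provenance: dict

    def __post_init__(self) -> None:
        if self.omega.shape != self.chi.shape:
            raise ValueError("omega and chi must share a shape")
        if np.any(self.chi < 0) or np.any(self.chi > 1):
            raise ValueError("chi must lie in [0, 1]")


def residual_map(movie: AFMovie, fit: FitResult) -> np.ndarray:
    """Per-pixel L1 deviation between data and fitted model.

        dAF(x, y) = sum_i |f(x, y, t_i) - a e^{-c e^{-b t_i}}|

    Masked (log-undefined) pixels get NaN; detectors treat non-finite
    values as automatic candidates.
    """
    if fit.a_hat.shape != movie.shape:
        raise ValueError("fit does not cover the movie")
    a = fit.a_hat
    b = fit.b_hat
    c = fit.c_hat
    out = np.zeros(movie.shape)
    for i, t in enumerate(movie.times):  # frame-wise to bound memory
        model = a * np.exp(-c * np.exp(-b * t))
        out += np.abs(movie.frames[i] - model)
    out[fit.masked] = np.nan
    return out


def detect_from_iterations(n_iters: np.ndarray, percentile: float = 95.0,
                           converged: np.ndarray | None = None) -> np.ndarray:
    """Threshold the iteration-count map into a candidate vessel mask.

    Pixels above the given percentile of N plus all non-converged pixels.
    A constant N field carries no edge information: empty mask, warning.
    """
    n_iters = np.asarray(n_iters)
    out = np.zeros(n_iters.shape, dtype=bool)
    if np.ptp(n_iters) == 0:
        warnings.warn("iteration-count field is constant; no vessel signal")
    else:
        thr = np.percentile(n_iters, percentile)
        out = n_iters > thr
    if converged is not None:
        out |= ~np.asarray(converged, dtype=bool)
    return out


def detect_from_residual(delta_af: np.ndarray, lower_pct: float = 90.0,
                         upper_pct: float = 100.0) -> np.ndarray:
    """Pixels whose L1 residual falls in the configured percentile band.

    Rank-based, hence invariant to global intensity scaling.  Non-finite
    residuals (masked pixels) are always included.  The default band
    marks the worst decile: spatial averaging smears each vessel over
    the window width, so the model-failure region is roughly three times
    the raw vessel area.
    """
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ValueError("need 0 <= lower_pct < upper_pct <= 100")
    delta_af = np.asarray(delta_af, dtype=float)
    finite = np.isfinite(delta_af)
    out = ~finite
    if finite.any():
        vals = delta_af[finite]
        if np.ptp(vals) == 0:
            warnings.warn("residual field is constant; no rank information")
        else:
            lo, hi = np.percentile(vals, [lower_pct, upper_pct])
            out |= finite & (delta_af >= lo) & (delta_af <= hi)
    return out


def smooth_mask(omega: np.ndarray, transition_px: float) -> np.ndarray:
    """Clipped-linear ramp of the distance to Omega: 0 inside, 1 far out."""
    if transition_px <= 0:
        raise ValueError("transition width must be positive")
    if not omega.any():
        return np.ones(omega.shape)
    dist = ndimage.distance_transform_edt(~omega)
    return np.clip(dist / transition_px, 0.0, 1.0)


def finalize_mask(candidates: list[np.ndarray], dilation_px: int = 2,
                  transition_px: float = 3.0,
                  provenance: dict | None = None) -> VesselMask:
    """Union the candidate masks, dilate, and build the smooth relaxation.

    Growing the mask by a couple of pixels covers vessel-edge pixels
    corrupted by eye micro-movements and registration imprecision.  A
    final mask covering more than half the image signals a misconfigured
    detector and raises.
    """
    if not candidates:
        raise ValueError("need at least one candidate mask")
    shape = candidates[0].shape
    omega = np.zeros(shape, dtype=bool)
    for cand in candidates:
        if cand.shape != shape:
            raise ValueError("candidate masks must share a shape")
        omega |= cand.astype(bool)
    if dilation_px > 0 and omega.any():
        rr, cc = np.mgrid[-dilation_px:dilation_px + 1, -dilation_px:dilation_px + 1]
        disk = rr * rr + cc * cc <= dilation_px * dilation_px
        omega = ndimage.binary_dilation(omega, structure=disk)
    if omega.mean() > 0.5:
        raise ValueError("occlusion set covers more than half the image; "
                         "vessel detector is misconfigured")
    chi = smooth_mask(omega, transition_px)
    return VesselMask(omega=omega, chi=chi,
                      provenance=dict(provenance or {},
                                      dilation_px=dilation_px,
                                      transition_px=transition_px))


class VesselDetector(BaseEstimator):
    """Estimator building the vessel occlusion mask from fit diagnostics.

    Parameters
    ----------
    iter_percentile : float
        Percentile of the iteration-count map above which pixels become
        candidates (non-converged pixels always are).
    residual_band : (float, float)
        Percentile band of the L1 residual marked as model failures.
    dilation_px, transition_px : int, float
        Morphological growth of the union and width of the smooth ramp.
    """

    def __init__(self, iter_percentile: float = 95.0,
                 residual_band: tuple[float, float] = (90.0, 100.0),
                 dilation_px: int = 2, transition_px: float = 3.0):
        self.iter_percentile = iter_percentile
        self.residual_band = residual_band
        self.dilation_px = dilation_px
        self.transition_px = transition_px

    def fit(self, movie: AFMovie, fit_result: FitResult):
        """Detect vessels on the (already block-averaged) movie and fit."""
        self.residual_l1_ = residual_map(movie, fit_result)
        fit_result.residual_l1 = self.residual_l1_
        self.iter_mask_ = detect_from_iterations(
            fit_result.n_iters, self.iter_percentile, fit_result.converged)
        self.residual_mask_ = detect_from_residual(
            self.residual_l1_, *self.residual_band)
        self.mask_ = finalize_mask(
            [self.iter_mask_, self.residual_mask_],
            dilation_px=self.dilation_px, transition_px=self.transition_px,
            provenance={"detectors": ["iterations", "l1_residual"],
                        "iter_percentile": self.iter_percentile,
                        "residual_band": tuple(self.residual_band)})
        return self

    def transform(self, X=None) -> VesselMask:
        return self.mask_
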
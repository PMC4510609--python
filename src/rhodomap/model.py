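"""Biophysical forward model of autofluorescence bleaching.

The detected 488 nm-excited lipofuscin autofluorescence (AF) of the retinal
pigment epithelium is attenuated on the double light path (excitation in,
emission out) by absorbers overlying the fluorophore: macular pigment near
the fovea and unbleached rod rhodopsin elsewhere.  Beer-Lambert gives

    AF(L, l, t) = I(L) Phi(L, l) exp(-(D(L, t) + D(l, t))),

with ``L``/``l`` the excitation/emission wavelengths, ``I`` the radiant
power and ``Phi`` the lipofuscin fluorescence efficiency.  As the steady
scanning laser bleaches rhodopsin, its optical density decays and the AF
brightens toward the fully bleached level.  With the remaining-rhodopsin
fraction approximated by ``R(t) ~ exp(-beta t)`` this collapses into the
three-parameter double-exponential per-pixel law

    AF(t) = alpha * exp(-gamma * exp(-beta t)),

where ``alpha`` is the fully bleached amplitude (camera units), ``beta``
the bleaching rate and ``gamma`` the double-path rhodopsin optical density
at time zero.  This module houses that forward model, the full
bleaching/regeneration kinetics it simplifies, and the wavelength tables
used to fold macular pigment density into ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "SpectralBand",
    "BleachKinetics",
    "OpticalCoefficients",
    "PixelModelParams",
    "Geometry",
    "AFMovie",
    "regeneration_fraction",
    "simplified_fraction",
    "forward_af",
    "compose_alpha",
]


@dataclass(frozen=True)
class SpectralBand:
    """An excitation/emission wavelength pair in nanometres."""

    excitation_nm: float
    emission_nm: float

    def __post_init__(self) -> None:
        exc, emi = float(self.excitation_nm), float(self.emission_nm)
        if not (np.isfinite(exc) and np.isfinite(emi)):
            raise ValueError("wavelengths must be finite")
        if not (400.0 <= exc <= 800.0 and 400.0 <= emi <= 800.0):
            raise ValueError("wavelengths must lie in [400, 800] nm")
        if emi <= exc:
            raise ValueError("emission must exceed excitation (Stokes shift)")


@dataclass(frozen=True)
class BleachKinetics:
    """Kinetic constants of rhodopsin bleaching and visual-cycle regeneration.

    Parameters
    ----------
    illuminance : float
        Steady retinal illuminance ``I`` (relative radiant-power units).
    bleach_constant : float
        Bleaching constant ``L`` (reciprocal photosensitivity, same units
        times seconds).
    regen_time_constant : float
        Visual-cycle regeneration time constant ``K`` in seconds (about
        700 s in young eyes, rising to about 1000 s with age).
    """

    illuminance: float
    bleach_constant: float
    regen_time_constant: float

    def __post_init__(self) -> None:
        for name in ("illuminance", "bleach_constant", "regen_time_constant"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite number")

    @property
    def beta(self) -> float:
        """Bleaching rate ``beta = I / L`` (1/s)."""
        return self.illuminance / self.bleach_constant


def _load_table(name: str) -> tuple[np.ndarray, np.ndarray]:
    text = resources.files("rhodomap.data").joinpath(name).read_text()
    rows = [ln.split(",") for ln in text.strip().splitlines()[1:]]
    wl = np.array([float(r[0]) for r in rows])
    k = np.array([float(r[1]) for r in rows])
    return wl, k


@dataclass(frozen=True)
class OpticalCoefficients:
    """Relative extinction tables for macular pigment and rhodopsin.

    ``k_mp`` is scaled so that ``k_mp(460 nm) = 1`` exactly; ``k_rh`` is a
    rhodopsin absorbance template normalized at 500 nm, zero at and above
    590 nm where rhodopsin absorbance is negligible.  Lookups interpolate
    linearly between tabulated wavelengths and raise outside the table.
    """

    mp_wavelengths: np.ndarray
    mp_values: np.ndarray
    rh_wavelengths: np.ndarray
    rh_values: np.ndarray

    def __post_init__(self) -> None:
        for wl, k in ((self.mp_wavelengths, self.mp_values),
                      (self.rh_wavelengths, self.rh_values)):
            if wl.ndim != 1 or wl.shape != k.shape or wl.size < 2:
                raise ValueError("coefficient table must be two matching 1-D columns")
            if np.any(np.diff(wl) <= 0):
                raise ValueError("table wavelengths must be strictly increasing")
            if np.any(k < 0):
                raise ValueError("extinction coefficients must be nonnegative")
        if abs(self._interp(460.0, self.mp_wavelengths, self.mp_values) - 1.0) > 1e-12:
            raise ValueError("macular pigment table must satisfy k_mp(460 nm) = 1")

    @staticmethod
    def _interp(nm: float, wl: np.ndarray, k: np.ndarray) -> float:
        nm = float(nm)
        if not np.isfinite(nm) or nm < wl[0] or nm > wl[-1]:
            raise ValueError(f"wavelength {nm} nm outside table range "
                             f"[{wl[0]}, {wl[-1]}] nm")
        return float(np.interp(nm, wl, k))

    def k_mp(self, nm: float) -> float:
        """Macular pigment relative extinction at ``nm`` nanometres."""
        return self._interp(nm, self.mp_wavelengths, self.mp_values)

    def k_rh(self, nm: float) -> float:
        """Rhodopsin relative extinction at ``nm`` nanometres."""
        return self._interp(nm, self.rh_wavelengths, self.rh_values)

    def k_mp_band(self, band: SpectralBand) -> float:
        """Double-path macular pigment extinction ``k_mp(L) + k_mp(l)``."""
        return self.k_mp(band.excitation_nm) + self.k_mp(band.emission_nm)

    @classmethod
    def default(cls) -> "OpticalCoefficients":
        """Packaged template tables (user-overridable via :meth:`from_csv`)."""
        mp_wl, mp_k = _load_table("k_mp.csv")
        rh_wl, rh_k = _load_table("k_rh.csv")
        return cls(mp_wl, mp_k, rh_wl, rh_k)

    @classmethod
    def from_csv(cls, mp_path, rh_path) -> "OpticalCoefficients":
        """Load from two two-column CSV files (wavelength_nm, k)."""
        def read(path):
            arr = np.loadtxt(path, delimiter=",", skiprows=1)
            return arr[:, 0], arr[:, 1]

        mp_wl, mp_k = read(mp_path)
        rh_wl, rh_k = read(rh_path)
        return cls(mp_wl, mp_k, rh_wl, rh_k)


@dataclass(frozen=True)
class PixelModelParams:
    """Per-pixel parameters (alpha, beta, gamma) of the bleaching law."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError("alpha must be positive and finite")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError("beta must be positive and finite")
        if not (np.isfinite(self.gamma) and self.gamma >= 0):
            raise ValueError("gamma must be nonnegative and finite")


@dataclass(frozen=True)
class Geometry:
    """Acquisition geometry: field of view, fovea center and pixel scale."""

    fov_deg: float
    center: tuple[float, float]  # (row, col) of the fovea center
    px_per_deg: float

    def __post_init__(self) -> None:
        if self.fov_deg <= 0 or self.px_per_deg <= 0:
            raise ValueError("field of view and pixel scale must be positive")

    def radius_map(self, shape: tuple[int, int]) -> np.ndarray:
        """Eccentricity (degrees from fovea center) for every pixel."""
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        r = np.hypot(rr - self.center[0], cc - self.center[1])
        return r / self.px_per_deg


@dataclass
class AFMovie:
    """A registered autofluorescence movie with its time grid.

    Attributes
    ----------
    frames : ndarray, shape (m, H, W)
        Nonnegative intensity stack.
    times : ndarray, shape (m,)
        Strictly increasing acquisition times in seconds.
    t0 : float
        Time of initial light exposure (seconds, >= 0).
    geometry : Geometry
        Field of view, fovea center and pixel scale.
    """

    frames: np.ndarray
    times: np.ndarray
    t0: float = 0.0
    geometry: Geometry | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (m, H, W) stack")
        m = self.frames.shape[0]
        if m < 3:
            raise ValueError("movie needs at least 3 frames")
        if self.times.shape != (m,):
            raise ValueError("times must match the number of frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.frames)) or np.any(self.frames < 0):
            raise ValueError("intensities must be finite and nonnegative")
        if self.t0 < 0:
            raise ValueError("t0 must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise ValueError("time must be finite and nonnegative")
    return t


def regeneration_fraction(t, kinetics: BleachKinetics):
    """Remaining-rhodopsin fraction R(t) under steady light.

    Closed-form solution of the bleaching/regeneration balance

        dR/dt = -I R / L + (1 - R) / K,   R(0) = 1:

        R(t) = (L/K)/(I + L/K) + I/(I + L/K) * exp(-(1 + KI/L) t / K),

    i.e. monotone non-increasing from R(0) = 1 toward the steady state
    L/(L + IK), where photoactivation balances visual-cycle regeneration.
    """
    t = _check_time(t)
    I = kinetics.illuminance
    L = kinetics.bleach_constant
    K = kinetics.regen_time_constant
    lk = L / K
    steady = lk / (I + lk)
    rate = (1.0 + K * I / L) / K
    out = steady + (I / (I + lk)) * np.exp(-rate * t)
    return out if out.ndim else float(out)


def simplified_fraction(t, beta: float):
    """High-illuminance, short-time limit ``R(t) ~ exp(-beta t)``.

    Valid when the illuminance dwarfs L/K and t << K, the regime of cSLO
    autofluorescence imaging.
    """
    if not np.isfinite(beta) or beta <= 0:
        raise ValueError("beta must be positive and finite")
    t = _check_time(t)
    out = np.exp(-beta * t)
    return out if out.ndim else float(out)


def forward_af(t, params: PixelModelParams):
    """Detected autofluorescence ``alpha * exp(-gamma * exp(-beta t))``.

    Strictly increasing in ``t`` for gamma > 0 and saturating at ``alpha``
    once the rhodopsin is fully bleached.
    """
    t = np.asarray(t, dtype=float)
    out = params.alpha * np.exp(-params.gamma * np.exp(-params.beta * t))
    return out if out.ndim else float(out)


def compose_alpha(source_product: float, d_mp_460: float,
                  band: SpectralBand, coeffs: OpticalCoefficients) -> float:
    """Fold macular pigment attenuation into the fully bleached amplitude.

    ``alpha = I*Phi * exp(-D_MP(460) * (k_mp(L) + k_mp(l)))`` where
    ``source_product`` is the (never separated) product ``I(L)*Phi(L, l)``.
    """
    if source_product <= 0:
        raise ValueError("source_product must be positive")
    if d_mp_460 < 0:
        raise ValueError("d_mp_460 must be nonnegative")
    return source_product * float(np.exp(-d_mp_460 * coeffs.k_mp_band(band)))
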
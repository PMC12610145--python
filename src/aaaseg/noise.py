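"""Signal-dependent Poisson–Gaussian noise injection and SNR measurement.

The observation model is the standard Gaussian approximation of mixed
Poisson–Gaussian CT noise,

    I = R + eta(R) * delta,        eta^2(R) = gamma * R + rho^2,

with ``R`` the clean image on a [0, 1] intensity scale, ``delta`` i.i.d.
standard normal, ``gamma`` the signal-dependent (Poisson-like) coefficient
and ``rho`` the constant electronic-noise standard deviation. SNR is the
amplitude convention ``20 * log10(mean / sd)`` over a homogeneous region of
interest: this is the only convention under which adding rho = 0.05 noise to
~0.5-intensity tissue turns a ~24 dB image into a ~13 dB one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .types import Image2D, as_array


@dataclass(frozen=True)
class NoiseParams:
    """gamma >= 0 (Poisson contribution), rho >= 0 (Gaussian sd), RNG seed."""

    gamma: float = 0.0
    rho: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.rho < 0:
            raise ValueError("gamma and rho must be >= 0")


@dataclass(frozen=True)
class RoiSpec:
    """A rectangular region of interest: row/col offset plus extent (pixels)."""

    row: int
    col: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.row < 0 or self.col < 0 or self.height < 1 or self.width < 1:
            raise ValueError("ROI offsets must be >= 0 and extents >= 1")
        if self.height * self.width < 4:
            raise ValueError("ROI area must be >= 4 pixels")

    def extract(self, image) -> np.ndarray:
        arr = as_array(image)
        if self.row + self.height > arr.shape[0] or self.col + self.width > arr.shape[1]:
            raise ValueError("ROI extends outside the image")
        return arr[self.row : self.row + self.height, self.col : self.col + self.width]


class PoissonGaussianNoise(TransformerMixin, BaseEstimator):
    """Add Poisson–Gaussian noise to [0, 1] images (sklearn transformer).

    Parameters
    ----------
    gamma, rho : float
        Noise-model coefficients; variance at intensity R is gamma*R + rho^2.
    clip : bool, default True
        Clip the noised output back into [0, 1]. The fraction of clipped
        pixels from the last ``transform`` is stored in ``clipped_fraction_``.
    seed : int
        Seed for the noise realization (deterministic output).

    ``transform`` accepts a single (H, W) image or an (n, H, W) stack.
    """

    def __init__(self, gamma: float = 0.0, rho: float = 0.05, clip: bool = True, seed: int = 0):
        self.gamma = gamma
        self.rho = rho
        self.clip = clip
        self.seed = seed

    def fit(self, X=None, y=None):
        NoiseParams(self.gamma, self.rho, self.seed)  # validate
        return self

    def transform(self, X) -> np.ndarray:
        self.fit()
        arr = np.asarray(as_array(X), dtype=float)
        if np.isnan(arr).any():
            raise ValueError("input contains NaN")
        if arr.min() < 0 or arr.max() > 1:
            raise ValueError("input intensities must lie in [0, 1]")
        rng = np.random.default_rng(int(self.seed) % (2**31))
        sd = np.sqrt(self.gamma * arr + self.rho**2)
        noisy = arr + sd * rng.standard_normal(arr.shape)
        if self.clip:
            clipped = np.count_nonzero((noisy < 0) | (noisy > 1))
            self.clipped_fraction_ = clipped / noisy.size
            noisy = np.clip(noisy, 0.0, 1.0)
        else:
            self.clipped_fraction_ = 0.0
        return noisy


def add_poisson_gaussian(clean, params: NoiseParams, clip: bool = True):
    """Apply the noise model to one image; returns the same container type."""
    tr = PoissonGaussianNoise(params.gamma, params.rho, clip=clip, seed=params.seed)
    noisy = tr.transform(clean)
    if isinstance(clean, Image2D):
        return clean.with_values(noisy)
    return noisy


def measure_snr_db(image, roi: RoiSpec) -> float:
    """SNR (dB) = 20*log10(mean/sd) over a homogeneous ROI.

    Raises if the ROI standard deviation is zero (infinite SNR is flagged,
    never silently returned).
    """
    patch = roi.extract(image)
    sd = float(patch.std())
    if sd == 0.0:
        raise ValueError("ROI standard deviation is zero (infinite SNR)")
    mean = float(patch.mean())
    if mean <= 0:
        raise ValueError("ROI mean must be positive for an SNR in dB")
    return 20.0 * np.log10(mean / sd)


def calibrate_gamma(background_level: float, rho: float, target_snr_db: float) -> float:
    """Solve the noise-variance model for gamma at a target ROI SNR.

    With ``sigma_t = background / 10**(target/20)`` the required total sd,
    gamma = (sigma_t**2 - rho**2) / background. Raises when the target SNR
    is already unattainable with Gaussian noise alone (gamma < 0).
    """
    if not 0 < background_level:
        raise ValueError("background_level must be positive")
    if rho < 0:
        raise ValueError("rho must be >= 0")
    sigma_t = background_level / 10.0 ** (target_snr_db / 20.0)
    if sigma_t < rho:
        raise ValueError(
            f"target SNR {target_snr_db} dB needs total sd {sigma_t:.4g} < rho={rho}; "
            "gamma would be negative"
        )
    return (sigma_t**2 - rho**2) / background_level
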
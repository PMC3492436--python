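"""Reference images with known autocorrelation: fractional Brownian fields.

A fractional Brownian field (fBf) is an isotropic random field whose energy
spectral density decays as a power of radial frequency, ``S(f) ~ f**-beta``.
``beta`` controls the strength and range of spatial autocorrelation:
``beta = 0`` is white noise, large ``beta`` gives smooth, long-range
correlated surfaces.  Fields are synthesised in the Fourier domain — the
target amplitude ``f**(-beta/2)`` is combined with random phases under the
Hermitian-symmetry constraint — on a grid larger than requested, and a
corner section is retained.  The crop breaks the periodic boundary
correlation that Fourier synthesis would otherwise impose on opposite
edges of the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid_io import DegenerateLatticeError, Lattice, center_normalize

__all__ = [
    "FBFSpec",
    "fbf_generate",
    "binarize_median",
    "radial_power_spectrum",
    "spectral_slope",
]


@dataclass(frozen=True)
class FBFSpec:
    """Parameters of a fractional-Brownian-field simulation.

    beta
        Energy-spectrum exponent, >= 0 (unitless).
    out_size
        Side of the returned square lattice (cells).
    gen_size
        Side of the synthesis grid; must be >= ``out_size``.  The default
        4x oversize pushes the periodic wrap-around far from the crop.
    seed
        Seed of the pseudo-random stream; the same spec always yields the
        same field.
    """

    beta: float
    out_size: int = 32
    gen_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.out_size < 2 or self.gen_size < 2:
            raise ValueError("sizes must be >= 2")
        if self.gen_size < self.out_size:
            raise ValueError("gen_size must be >= out_size")


def _fbf_field(spec: FBFSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Full gen_size x gen_size synthesis grid (uncropped, unnormalised)."""
    g = spec.gen_size
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    fx = np.fft.fftfreq(g)
    f = np.hypot(fx[:, None], fx[None, :])
    with np.errstate(divide="ignore"):
        amp = np.where(f > 0, f ** (-spec.beta / 2.0), 0.0)  # DC zeroed
    # Hermitian-symmetric uniform phases: the DFT of real white noise has
    # such phases, so its unit-modulus normalisation carries them over.
    z = np.fft.fft2(rng.standard_normal((g, g)))
    mag = np.abs(z)
    phase = np.where(mag > 0, z / np.where(mag > 0, mag, 1.0), 1.0)
    return np.fft.ifft2(amp * phase).real


def fbf_generate(spec: FBFSpec, rng: np.random.Generator | None = None) -> Lattice:
    """Generate a centered/normalised continuous fBf lattice.

    The ``out_size`` section is cropped from the top-left corner of the
    ``gen_size`` synthesis grid (any fixed corner is equivalent by
    stationarity).
    """
    field = _fbf_field(spec, rng)[: spec.out_size, : spec.out_size]
    return center_normalize(field)


def binarize_median(x: Lattice) -> Lattice:
    """Threshold at the median: 1 where strictly above, 0 elsewhere.

    Cells tied with the median map to 0, so the two classes differ in
    count by at most the number of ties.
    """
    v = x.values
    if v.std() == 0:
        raise DegenerateLatticeError("cannot binarize a constant lattice")
    return Lattice((v > np.median(v)).astype(float), kind="binary")


def radial_power_spectrum(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged periodogram on the DFT frequency grid.

    Returns (frequency bin centres in cycles/cell, mean power), DC excluded.
    """
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    p = np.abs(np.fft.fft2(v)) ** 2
    fx = np.fft.fftfreq(v.shape[0])
    fy = np.fft.fftfreq(v.shape[1])
    f = np.hypot(fx[:, None], fy[None, :]).ravel()
    p = p.ravel()
    # ring bins of width 1/n up to the Nyquist frequency
    edges = np.arange(0.5, n // 2 + 0.5) / n
    idx = np.digitize(f, edges)
    nb = len(edges)
    freq, power = [], []
    for k in range(1, nb):
        sel = idx == k
        if sel.any():
            freq.append(f[sel].mean())
            power.append(p[sel].mean())
    return np.asarray(freq), np.asarray(power)


def spectral_slope(values: np.ndarray) -> float:
    """Log-log slope of the radially averaged periodogram.

    For an fBf with exponent beta the slope estimates ``-beta``.
    """
    freq, power = radial_power_spectrum(values)
    ok = power > 0
    return float(np.polyfit(np.log(freq[ok]), np.log(power[ok]), 1)[0])
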
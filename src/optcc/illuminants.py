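"""Planckian (black-body) illuminants and the candidate-illuminant grid.

Illuminant intensity is parameterized by the *white-point luminance* ``h``:
the luminance a perfect full-white surface (unit reflectance everywhere)
would have under the illuminant.  This makes intensity a pure scalar on
precomputed optimal-color shells (the shell at height h is h times the shell
at height 1), so the search over intensity never re-renders anything.

The default candidate grid is the model's standard search space: 57 color
temperatures from 2000 K to 30,000 K in 500 K steps crossed with 201 relative
heights from 1.00 to 3.00 in 0.01 steps — 11,457 candidates in total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import CANONICAL_GRID, ConeFundamentals, MBColor, Spectrum, WavelengthGrid
from .spectral import light_cone_excitations, mb_chromaticity
from .fundamentals import default_fundamentals

__all__ = [
    "Illuminant",
    "CandidateGrid",
    "planck_spectrum",
    "make_illuminant",
    "candidate_grid",
    "planck_radiance",
]

# Second radiation constant c2 = h*c/kB in nm*K (CODATA).  Any overall
# constant in Planck's law is absorbed by the height normalization.
_C2_NM_K = 1.4387768775039337e7


def planck_radiance(wavelengths_nm: np.ndarray, T: float) -> np.ndarray:
    """Planck spectral radiance (arbitrary overall scale) at ``T`` kelvin."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    return wl**-5 / np.expm1(_C2_NM_K / (wl * T))


def planck_spectrum(
    T: float,
    grid: WavelengthGrid = CANONICAL_GRID,
    fundamentals: ConeFundamentals | None = None,
) -> Spectrum:
    """Black-body radiance at color temperature ``T``, scaled to height h = 1.

    "Height 1" means a full-white surface under the returned spectrum has
    luminance exactly 1 under ``fundamentals`` (default observer if omitted).
    """
    if T <= 0:
        raise ValueError(f"color temperature must be positive, got {T}")
    f = fundamentals or default_fundamentals(grid)
    values = planck_radiance(grid.wavelengths, T)
    lum = (f.kL * float(values @ f.L) + f.kM * float(values @ f.M)) * grid.step
    return Spectrum(grid, values / lum, "radiance")


@dataclass(frozen=True)
class Illuminant:
    """A Planckian illuminant: color temperature ``T`` and height ``h``.

    ``spectrum`` renders the all-ones reflectance to luminance ``h``.
    """

    T: float
    h: float
    spectrum: Spectrum

    def __post_init__(self) -> None:
        if self.T <= 0 or self.h <= 0:
            raise ValueError("T and h must be positive")

    def white_point(self, fundamentals: ConeFundamentals | None = None) -> MBColor:
        f = fundamentals or default_fundamentals(self.spectrum.grid)
        return mb_chromaticity(light_cone_excitations(self.spectrum, f), f)


def make_illuminant(
    T: float,
    h: float = 1.0,
    grid: WavelengthGrid = CANONICAL_GRID,
    fundamentals: ConeFundamentals | None = None,
) -> Illuminant:
    """Planckian illuminant at ``T`` kelvin with white-point luminance ``h``."""
    if h <= 0:
        raise ValueError(f"white-point luminance must be positive, got {h}")
    return Illuminant(T=T, h=h, spectrum=planck_spectrum(T, grid, fundamentals).scaled(h))


@dataclass(frozen=True)
class CandidateGrid:
    """Cartesian grid of candidate (T, h) illuminants for the estimator."""

    temperatures: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        hh = np.asarray(self.heights, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "heights", hh)
        if t.size == 0 or hh.size == 0:
            raise ValueError("candidate grid must be non-empty")
        if np.any(t <= 0) or np.any(hh <= 0):
            raise ValueError("temperatures and heights must be positive")
        if np.any(np.diff(t) <= 0) or np.any(np.diff(hh) <= 0):
            raise ValueError("temperatures and heights must be strictly increasing")

    @property
    def n_candidates(self) -> int:
        return self.temperatures.size * self.heights.size

    def with_height(self, h: float) -> "CandidateGrid":
        """Return a grid whose height axis additionally contains ``h`` exactly."""
        heights = np.unique(np.append(self.heights, float(h)))
        return CandidateGrid(self.temperatures, heights)


def _inclusive_arange(lo: float, hi: float, step: float) -> np.ndarray:
    if step <= 0:
        raise ValueError("step must be positive")
    if hi < lo:
        raise ValueError("max must be >= min")
    n = int(round((hi - lo) / step)) + 1
    seq = lo + step * np.arange(n)
    return seq[seq <= hi + 1e-9 * max(1.0, abs(hi))]


def candidate_grid(
    t_min: float = 2000.0,
    t_max: float = 30000.0,
    t_step: float = 500.0,
    h_min: float = 1.0,
    h_max: float = 3.0,
    h_step: float = 0.01,
) -> CandidateGrid:
    """Inclusive arithmetic candidate grid; defaults give 57 x 201 = 11,457."""
    return CandidateGrid(
        temperatures=_inclusive_arange(t_min, t_max, t_step),
        heights=_inclusive_arange(h_min, h_max, h_step),
    )
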
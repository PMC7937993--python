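"""Wavelength grids, spectra, and MacLeod-Boynton colorimetry.

All computation in this package happens on a canonical wavelength grid of
400-720 nm sampled at 1 nm (321 points).  Spectra are plain value vectors on
such a grid with a *role*: a ``reflectance`` is unitless in [0, 1], a
``radiance`` is a non-negative power distribution in arbitrary units.

Cone excitations are discrete inner products of radiance spectra against a set
of cone fundamentals (rectangle rule; at 1 nm the quadrature choice is
immaterial).  Chromaticity uses the MacLeod-Boynton convention: the luminance
signal is a weighted sum of L and M excitations, the chromatic axes are
l = L/(L+M) and s = S/(L+M).

The bundled cone fundamentals are a **synthetic** analytic stand-in for the
Stockman-Sharpe 2-degree observer (see :mod:`optcc.fundamentals`); the
luminance weights are calibrated so that equal-energy white maps to
(l, s) = (0.7078, 1.0000), the standard neutral reference of this model
family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WavelengthGrid",
    "CANONICAL_GRID",
    "Spectrum",
    "ConeFundamentals",
    "MBColor",
    "resample_spectrum",
    "surface_cone_excitations",
    "mb_chromaticity",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid ``start, start+step, ..., stop`` in nm."""

    start: float = 400.0
    stop: float = 720.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.stop < self.start:
            raise ValueError("stop must be >= start")
        n = round((self.stop - self.start) / self.step) + 1
        if abs(self.start + (n - 1) * self.step - self.stop) > 1e-9:
            raise ValueError("stop is not start + k*step for integer k")

    @property
    def count(self) -> int:
        return round((self.stop - self.start) / self.step) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        # index-based construction avoids floating-point step accumulation
        return self.start + self.step * np.arange(self.count)


#: The canonical grid every model computation uses: 400-720 nm, 1 nm, 321 points.
CANONICAL_GRID = WavelengthGrid(400.0, 720.0, 1.0)


@dataclass(frozen=True, eq=False)
class Spectrum:
    """Values on a :class:`WavelengthGrid`, with role 'reflectance' or 'radiance'."""

    grid: WavelengthGrid
    values: np.ndarray
    role: str = "reflectance"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.role not in ("reflectance", "radiance"):
            raise ValueError(f"unknown spectrum role {self.role!r}")
        if self.values.shape != (self.grid.count,):
            raise ValueError(
                f"values length {self.values.shape} does not match grid count {self.grid.count}"
            )
        if np.any(self.values < 0):
            raise ValueError("spectrum values must be non-negative")
        if self.role == "reflectance" and np.any(self.values > 1.0 + 1e-12):
            raise ValueError("reflectance values must lie in [0, 1]")

    def scaled(self, k: float) -> "Spectrum":
        """Return this spectrum with values multiplied by ``k`` (same role)."""
        return Spectrum(self.grid, self.values * k, self.role)


def resample_spectrum(
    spectrum: Spectrum,
    grid: WavelengthGrid,
    *,
    extrapolate: bool = False,
) -> Spectrum:
    """Linearly interpolate ``spectrum`` onto ``grid``.

    Raises ``ValueError`` naming the uncovered range if ``grid`` extends
    outside the source grid and ``extrapolate`` is not set (extrapolation
    holds the edge values).  Values are clipped to the role's valid range.
    """
    src = spectrum.grid
    if not extrapolate and (grid.start < src.start - 1e-9 or grid.stop > src.stop + 1e-9):
        raise ValueError(
            f"target grid [{grid.start}, {grid.stop}] nm extends outside the "
            f"source range [{src.start}, {src.stop}] nm; pass extrapolate=True "
            "to hold edge values"
        )
    values = np.interp(grid.wavelengths, src.wavelengths, spectrum.values)
    values = np.clip(values, 0.0, 1.0 if spectrum.role == "reflectance" else np.inf)
    return Spectrum(grid, values, spectrum.role)


@dataclass(frozen=True, eq=False)
class ConeFundamentals:
    """L, M, S spectral sensitivities plus the MB normalization scalars.

    ``kL`` and ``kM`` define the luminance signal Y = kL*<E,L> + kM*<E,M>
    (inner products are rectangle-rule integrals, i.e. sum times step width);
    ``kS`` scales s = kS*S/(L+M) so that a chosen neutral reference has s = 1.
    """

    grid: WavelengthGrid
    L: np.ndarray
    M: np.ndarray
    S: np.ndarray
    kL: float
    kM: float
    kS: float
    name: str = "cone fundamentals"

    def __post_init__(self) -> None:
        for attr in ("L", "M", "S"):
            arr = np.asarray(getattr(self, attr), dtype=float)
            object.__setattr__(self, attr, arr)
            if arr.shape != (self.grid.count,):
                raise ValueError(f"{attr} length does not match grid")
            if np.any(arr < 0):
                raise ValueError(f"{attr} sensitivities must be non-negative")
        if not (self.kL > 0 and self.kM > 0 and self.kS > 0):
            raise ValueError("normalization scalars must be positive")

    def luminance(self, excitations: tuple[float, float, float] | np.ndarray) -> float:
        """Luminance kL*L + kM*M of one excitation triplet."""
        e = np.asarray(excitations, dtype=float)
        return float(self.kL * e[0] + self.kM * e[1])


def surface_cone_excitations(
    illuminant_spectrum: Spectrum,
    reflectance: Spectrum,
    fundamentals: ConeFundamentals,
) -> np.ndarray:
    """Cone excitations (L, M, S) of a surface viewed under an illuminant.

    The color signal E(lambda)*R(lambda) is integrated against each cone
    fundamental on the fundamentals' grid (rectangle rule x step width).
    """
    if reflectance.role != "reflectance":
        raise ValueError("second argument must have role 'reflectance'")
    if illuminant_spectrum.grid != fundamentals.grid or reflectance.grid != fundamentals.grid:
        raise ValueError("spectra and fundamentals must share one wavelength grid")
    signal = illuminant_spectrum.values * reflectance.values
    step = fundamentals.grid.step
    return np.array(
        [
            float(signal @ fundamentals.L) * step,
            float(signal @ fundamentals.M) * step,
            float(signal @ fundamentals.S) * step,
        ]
    )


def light_cone_excitations(
    radiance: Spectrum, fundamentals: ConeFundamentals
) -> np.ndarray:
    """Cone excitations of a bare light (identity reflectance)."""
    ones = Spectrum(fundamentals.grid, np.ones(fundamentals.grid.count), "reflectance")
    return surface_cone_excitations(radiance, ones, fundamentals)


def render_reflectance_matrix(
    values: np.ndarray, radiance: Spectrum, fundamentals: ConeFundamentals
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(l, s, Y) arrays for a stack of reflectances under one illuminant.

    ``values`` is an (n, grid.count) matrix of reflectance rows on the
    fundamentals' grid.
    """
    f = fundamentals
    if radiance.grid != f.grid:
        raise ValueError("radiance and fundamentals must share one grid")
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] != f.grid.count:
        raise ValueError("reflectance rows must match the grid length")
    sig = values * radiance.values[None, :]
    exc = sig @ np.column_stack([f.L, f.M, f.S]) * f.grid.step  # (n, 3)
    lum = f.kL * exc[:, 0] + f.kM * exc[:, 1]
    if np.any(lum <= 0):
        raise ValueError("non-positive luminance while rendering reflectances")
    return f.kL * exc[:, 0] / lum, f.kS * exc[:, 2] / lum, lum


@dataclass(frozen=True)
class MBColor:
    """MacLeod-Boynton chromaticity plus luminance: (l, s, Y).

    (l, s) is invariant under uniform scaling of the input light; Y scales
    linearly with it.
    """

    l: float
    s: float
    Y: float

    def __post_init__(self) -> None:
        if not (0.0 < self.l < 1.0):
            raise ValueError(f"l = {self.l} outside (0, 1)")
        if self.s < 0.0:
            raise ValueError(f"s = {self.s} negative")
        if self.Y < 0.0:
            raise ValueError(f"Y = {self.Y} negative")

    @property
    def chromaticity(self) -> tuple[float, float]:
        return (self.l, self.s)


def mb_chromaticity(
    excitations: tuple[float, float, float] | np.ndarray,
    fundamentals: ConeFundamentals,
) -> MBColor:
    """Convert an (L, M, S) excitation triplet to MacLeod-Boynton coordinates.

    l = kL*L / (kL*L + kM*M), s = kS*S / (kL*L + kM*M), Y = kL*L + kM*M.
    Raises on non-positive luminance (chromaticity undefined).
    """
    e = np.asarray(excitations, dtype=float)
    lum = fundamentals.kL * e[0] + fundamentals.kM * e[1]
    if lum <= 0:
        raise ValueError("luminance (kL*L + kM*M) must be positive for chromaticity")
    return MBColor(
        l=fundamentals.kL * e[0] / lum,
        s=fundamentals.kS * e[2] / lum,
        Y=lum,
    )
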
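"""Optimal colors (MacAdam limits) and per-illuminant gamut shells.

An *optimal color* is a hypothetical surface whose reflectance takes only the
values 0 and 1 with at most two spectral transitions: a band-pass rectangle
(1 on [lambda1, lambda2]) or a band-stop rectangle (0 on [lambda1, lambda2]).
Under a given illuminant the optimal colors trace the outer boundary of the
physically realizable chromaticity-luminance gamut of surfaces: at every
chromaticity the corresponding optimal color attains the maximum possible
luminance, and the peak of the distribution is the full-white surface, whose
color is the illuminant's own white point.

Enumeration convention
----------------------
On the canonical 321-point grid, both rectangle families over
lambda1 <= lambda2 give 2 * C(322, 2) = 103,362 spectra.  Removing the single
all-zero spectrum (the full-range band-stop) and the 640 band-stop spectra
whose pass set is a single edge-touching interval (value-for-value duplicates
of band-pass spectra) leaves exactly 102,721 distinct reflectances.  This is
the count the model's shell is built from.

Shell rendering uses prefix sums of the per-wavelength cone signal, so each
of the ~1e5 rectangles costs O(1); a full 57-temperature shell set builds in
seconds.  Boundary queries use nearest-neighbor lookup over the rendered
point cloud: at an optimal color's own chromaticity this returns that color's
own luminance exactly, which is what makes scenes composed of optimal colors
an exact (zero-error) fit to their generating shell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from .spectral import (
    CANONICAL_GRID,
    ConeFundamentals,
    MBColor,
    Spectrum,
    WavelengthGrid,
)
from .fundamentals import default_fundamentals
from .illuminants import Illuminant, planck_spectrum

__all__ = [
    "OptimalReflectance",
    "OptimalColorSet",
    "OptimalColorShell",
    "OutOfFootprintError",
    "enumerate_optimal_reflectances",
    "build_shell",
    "build_shell_from_spectrum",
    "boundary_luminance",
    "solve_optimal_reflectance",
    "OPTIMAL_COLOR_COUNT",
]

#: Number of distinct optimal reflectances on the canonical grid.
OPTIMAL_COLOR_COUNT = 102_721


class OutOfFootprintError(ValueError):
    """A queried chromaticity lies outside the shell's chromatic footprint."""


@dataclass(frozen=True, eq=False)
class OptimalReflectance:
    """A single band-pass or band-stop rectangular reflectance."""

    kind: str  # "band_pass" | "band_stop"
    lambda1: float
    lambda2: float
    grid: WavelengthGrid = CANONICAL_GRID

    def __post_init__(self) -> None:
        if self.kind not in ("band_pass", "band_stop"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.lambda1 > self.lambda2:
            raise ValueError("lambda1 must be <= lambda2")

    @property
    def spectrum(self) -> Spectrum:
        wl = self.grid.wavelengths
        inside = (wl >= self.lambda1 - 1e-9) & (wl <= self.lambda2 + 1e-9)
        values = inside.astype(float)
        if self.kind == "band_stop":
            values = 1.0 - values
        return Spectrum(self.grid, values, "reflectance")


class OptimalColorSet:
    """The enumerated set of distinct optimal reflectances on one grid.

    Stored compactly as index arrays (``kinds`` is True for band-stop);
    ``self[j]`` materializes the j-th :class:`OptimalReflectance`.
    """

    def __init__(self, grid: WavelengthGrid, i1: np.ndarray, i2: np.ndarray, is_stop: np.ndarray):
        self.grid = grid
        self.i1 = np.asarray(i1, dtype=np.intp)
        self.i2 = np.asarray(i2, dtype=np.intp)
        self.is_stop = np.asarray(is_stop, dtype=bool)
        if not (self.i1.shape == self.i2.shape == self.is_stop.shape):
            raise ValueError("index arrays must share one shape")

    def __len__(self) -> int:
        return self.i1.size

    def __getitem__(self, j: int) -> OptimalReflectance:
        wl = self.grid.wavelengths
        return OptimalReflectance(
            kind="band_stop" if self.is_stop[j] else "band_pass",
            lambda1=float(wl[self.i1[j]]),
            lambda2=float(wl[self.i2[j]]),
            grid=self.grid,
        )

    @property
    def white_index(self) -> int:
        """Index of the all-ones (full-white) reflectance: band_pass over the whole grid."""
        mask = (~self.is_stop) & (self.i1 == 0) & (self.i2 == self.grid.count - 1)
        (idx,) = np.nonzero(mask)
        return int(idx[0])


@lru_cache(maxsize=4)
def enumerate_optimal_reflectances(grid: WavelengthGrid = CANONICAL_GRID) -> OptimalColorSet:
    """All distinct optimal reflectances with lambda1 <= lambda2 on ``grid``.

    Band-pass rectangles over all 0 <= i1 <= i2 <= N-1; band-stop rectangles
    over 1 <= i1 <= i2 <= N-2 (edge-touching stop bands duplicate band-pass
    spectra and the full-range stop band is all-zero, so both are dropped).
    On the canonical 321-point grid this yields exactly 102,721 reflectances.
    """
    if grid.count < 3:
        raise ValueError("grid too small to enumerate optimal colors")
    n = grid.count
    iu, ju = np.triu_indices(n)           # band-pass: all pairs i1 <= i2
    ks, ls = np.triu_indices(n - 2)       # band-stop: interior pairs, shifted by 1
    i1 = np.concatenate([iu, ks + 1])
    i2 = np.concatenate([ju, ls + 1])
    is_stop = np.zeros(i1.size, dtype=bool)
    is_stop[iu.size:] = True
    return OptimalColorSet(grid, i1, i2, is_stop)


def _render_set(
    radiance: Spectrum, ocs: OptimalColorSet, fundamentals: ConeFundamentals
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(l, s, Y) of every optimal reflectance under ``radiance``, via prefix sums."""
    f = fundamentals
    if radiance.grid != f.grid or ocs.grid != f.grid:
        raise ValueError("radiance, optimal set and fundamentals must share one grid")
    step = f.grid.step
    sig = np.stack([radiance.values * f.L, radiance.values * f.M, radiance.values * f.S]) * step
    pref = np.concatenate([np.zeros((3, 1)), np.cumsum(sig, axis=1)], axis=1)  # (3, N+1)
    total = pref[:, -1]
    band = pref[:, ocs.i2 + 1] - pref[:, ocs.i1]      # (3, n_colors)
    exc = np.where(ocs.is_stop[None, :], total[:, None] - band, band)
    lum = f.kL * exc[0] + f.kM * exc[1]
    if np.any(lum <= 0):
        raise ValueError("non-positive luminance encountered while rendering shell")
    l = f.kL * exc[0] / lum
    s = f.kS * exc[2] / lum
    return l, s, lum


@dataclass(frozen=True, eq=False)
class OptimalColorShell:
    """The gamut boundary under one illuminant at unit height (h = 1).

    ``points`` is an (n, 3) array of (l, s, Y_boundary) with the luminance
    axis normalized so the full-white surface has Y = 1; the boundary at any
    other height h is h times this shell.  ``label`` records the generating
    illuminant (a color temperature, or e.g. "EEW").
    """

    label: str
    points: np.ndarray
    white_point: MBColor
    white_index: int
    footprint_tol: float = 0.05
    _tree: cKDTree = field(repr=False, default=None)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def _kdtree(self) -> cKDTree:
        if self._tree is None:
            object.__setattr__(self, "_tree", cKDTree(self.points[:, :2]))
        return self._tree

    def nearest(self, ls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest shell-point distance and index for each (l, s) query row."""
        d, idx = self._kdtree().query(np.atleast_2d(ls))
        return d, idx

    def boundary_luminances(self, ls: np.ndarray) -> np.ndarray:
        """Boundary Y (h = 1) at each query chromaticity; NaN when the query
        falls farther than ``footprint_tol`` from every shell point."""
        d, idx = self.nearest(ls)
        out = self.points[idx, 2].astype(float)
        out[d > self.footprint_tol] = np.nan
        return out

    def boundary_luminance(self, l: float, s: float) -> float:
        y = self.boundary_luminances(np.array([[l, s]]))[0]
        if np.isnan(y):
            raise OutOfFootprintError(
                f"chromaticity (l={l:.4f}, s={s:.4f}) lies outside the chromatic "
                f"footprint of shell {self.label} (tolerance {self.footprint_tol})"
            )
        return float(y)

    def binned_max(self, n_bins: int = 60) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Max boundary Y on a regular (l, s) bin grid (for diagnostics and
        the purity-monotonicity invariant; queries use nearest-point lookup)."""
        l, s, y = self.points.T
        l_span = float(np.ptp(l)) or 1.0
        s_span = float(np.ptp(s)) or 1.0
        li = np.clip(((l - l.min()) / l_span * n_bins).astype(int), 0, n_bins - 1)
        si = np.clip(((s - s.min()) / s_span * n_bins).astype(int), 0, n_bins - 1)
        grid = np.full((n_bins, n_bins), -np.inf)
        np.maximum.at(grid, (li, si), y)
        grid[np.isinf(grid)] = np.nan
        l_edges = np.linspace(l.min(), l.max(), n_bins + 1)
        s_edges = np.linspace(s.min(), s.max(), n_bins + 1)
        return grid, l_edges, s_edges


def build_shell_from_spectrum(
    radiance: Spectrum,
    reflectances: OptimalColorSet | None = None,
    fundamentals: ConeFundamentals | None = None,
    label: str = "custom",
    footprint_tol: float = 0.05,
) -> OptimalColorShell:
    """Render every optimal reflectance under ``radiance`` and normalize the
    shell so the full-white surface has Y = 1."""
    f = fundamentals or default_fundamentals(radiance.grid)
    ocs = reflectances if reflectances is not None else enumerate_optimal_reflectances(f.grid)
    if len(ocs) == 0:
        raise ValueError("empty optimal-reflectance set")
    l, s, lum = _render_set(radiance, ocs, f)
    wi = ocs.white_index
    lum = lum / lum[wi]
    points = np.column_stack([l, s, lum])
    white = MBColor(l=float(l[wi]), s=float(s[wi]), Y=1.0)
    return OptimalColorShell(
        label=label, points=points, white_point=white, white_index=wi,
        footprint_tol=footprint_tol,
    )


@lru_cache(maxsize=128)
def _cached_shell(
    T: float, grid: WavelengthGrid, fundamentals: ConeFundamentals, footprint_tol: float
) -> OptimalColorShell:
    return build_shell_from_spectrum(
        planck_spectrum(T, grid, fundamentals),
        enumerate_optimal_reflectances(grid),
        fundamentals,
        label=f"{T:g} K",
        footprint_tol=footprint_tol,
    )


def build_shell(
    T: float,
    reflectances: OptimalColorSet | None = None,
    fundamentals: ConeFundamentals | None = None,
    grid: WavelengthGrid = CANONICAL_GRID,
    footprint_tol: float = 0.05,
) -> OptimalColorShell:
    """Optimal-color shell of the Planckian illuminant at ``T`` kelvin, h = 1.

    Shells are cached per (T, grid, observer); the intensity dimension is
    always handled by scaling, never by re-rendering.
    """
    f = fundamentals or default_fundamentals(grid)
    if reflectances is None:
        return _cached_shell(float(T), grid, f, footprint_tol)
    return build_shell_from_spectrum(
        planck_spectrum(T, grid, f), reflectances, f,
        label=f"{T:g} K", footprint_tol=footprint_tol,
    )


def boundary_luminance(shell: OptimalColorShell, chroma: tuple[float, float]) -> float:
    """Boundary luminance at h = 1 for ``chroma``; raises
    :class:`OutOfFootprintError` outside the shell's footprint."""
    return shell.boundary_luminance(chroma[0], chroma[1])


def solve_optimal_reflectance(
    chroma: tuple[float, float],
    illuminant: Illuminant | Spectrum,
    reflectances: OptimalColorSet | None = None,
    fundamentals: ConeFundamentals | None = None,
    tol: float = 0.01,
) -> tuple[OptimalReflectance, MBColor, float]:
    """The optimal reflectance whose rendered chromaticity under ``illuminant``
    is nearest to ``chroma``.

    Returns (reflectance, rendered color at the illuminant's height, achieved
    chromaticity distance).  Raises if the nearest rendered chromaticity is
    farther than ``tol``.
    """
    radiance = illuminant.spectrum if isinstance(illuminant, Illuminant) else illuminant
    f = fundamentals or default_fundamentals(radiance.grid)
    ocs = reflectances if reflectances is not None else enumerate_optimal_reflectances(f.grid)
    l, s, lum = _render_set(radiance, ocs, f)
    d2 = (l - chroma[0]) ** 2 + (s - chroma[1]) ** 2
    j = int(np.argmin(d2))
    d = float(np.sqrt(d2[j]))
    if d > tol:
        raise ValueError(
            f"no optimal color within {tol} of (l={chroma[0]:.4f}, s={chroma[1]:.4f}); "
            f"nearest achieved distance {d:.4f}"
        )
    return ocs[j], MBColor(l=float(l[j]), s=float(s[j]), Y=float(lum[j])), d
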
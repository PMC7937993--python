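"""Synthetic cone-fundamental stand-in and its MacLeod-Boynton normalization.

This module provides the package's default observer.  It is a **synthetic**
analytic stand-in for the Stockman-Sharpe 2-degree cone fundamentals, built
from log-Gaussian pigment templates (energy units, unit peak):

    S_c(lambda) = exp( -0.5 * (ln(lambda / peak_c) / width_c)^2 )

with peaks at 570 nm (L), 543 nm (M) and 442 nm (S) and bandwidths chosen to
give realistic full widths at half maximum (~110 nm for L/M, ~85 nm for S).
The real tabulated observer is not bundled; every quantity this package
computes is either a convention (normalization constants), a count, or a
relative/directional result, none of which depend on the fine shape of the
sensitivities.  Users with the real tables can construct a
:class:`~optcc.spectral.ConeFundamentals` from them directly.

Normalization convention
------------------------
* ``kL : kM`` is calibrated so that equal-energy white (a flat radiance
  spectrum) has l = L/(L+M) = 0.7078 exactly, the standard printed value of
  the neutral reference in this model family.
* ``kS`` is fixed so that equal-energy white has s = S/(L+M) = 1.0000 exactly
  (not the textbook "max s = 1" convention).
* The absolute photometric scale is a single free constant (all model
  quantities are ratios or fixed by stimulus normalization); ``kM = 1`` here.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .spectral import CANONICAL_GRID, ConeFundamentals, Spectrum, WavelengthGrid

__all__ = ["default_fundamentals", "EEW_L", "EEW_S", "equal_energy_white", "describe_normalization"]

#: MacLeod-Boynton chromaticity of equal-energy white under the package convention.
EEW_L = 0.7078
EEW_S = 1.0000

_PEAKS_NM = {"L": 570.0, "M": 543.0, "S": 442.0}
_LOG_WIDTHS = {"L": 0.080, "M": 0.078, "S": 0.072}


def _log_gaussian(wavelengths: np.ndarray, peak: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * (np.log(wavelengths / peak) / width) ** 2)


@lru_cache(maxsize=8)
def default_fundamentals(grid: WavelengthGrid = CANONICAL_GRID) -> ConeFundamentals:
    """The package's default (synthetic) observer on ``grid``, MB-normalized.

    Deterministic: repeated calls return the cached instance.
    """
    wl = grid.wavelengths
    L = _log_gaussian(wl, _PEAKS_NM["L"], _LOG_WIDTHS["L"])
    M = _log_gaussian(wl, _PEAKS_NM["M"], _LOG_WIDTHS["M"])
    S = _log_gaussian(wl, _PEAKS_NM["S"], _LOG_WIDTHS["S"])
    # Equal-energy integrals fix the normalization constants (rectangle rule;
    # the step width cancels in every ratio below).
    sL, sM, sS = float(L.sum()), float(M.sum()), float(S.sum())
    kM = 1.0
    # l_EEW = kL*sL / (kL*sL + kM*sM) = EEW_L  =>  kL*sL = sM * EEW_L/(1-EEW_L)
    kL = (EEW_L / (1.0 - EEW_L)) * (kM * sM) / sL
    kS = (kL * sL + kM * sM) / sS
    return ConeFundamentals(
        grid=grid, L=L, M=M, S=S, kL=kL, kM=kM, kS=kS,
        name="synthetic log-Gaussian cone fundamentals (570/543/442 nm)",
    )


def equal_energy_white(grid: WavelengthGrid = CANONICAL_GRID, Y: float = 1.0) -> Spectrum:
    """Flat radiance spectrum scaled to luminance ``Y`` under the default observer."""
    f = default_fundamentals(grid)
    flat = np.ones(grid.count)
    lum = (f.kL * float(flat @ f.L) + f.kM * float(flat @ f.M)) * grid.step
    return Spectrum(grid, flat * (Y / lum), "radiance")


def describe_normalization(fundamentals: ConeFundamentals | None = None) -> dict:
    """Report the normalization constants and the resulting EEW chromaticity."""
    from .spectral import light_cone_excitations, mb_chromaticity

    f = fundamentals or default_fundamentals()
    flat = Spectrum(f.grid, np.ones(f.grid.count), "radiance")
    white = mb_chromaticity(light_cone_excitations(flat, f), f)
    return {
        "name": f.name,
        "grid": {"start_nm": f.grid.start, "stop_nm": f.grid.stop, "step_nm": f.grid.step,
                 "count": f.grid.count},
        "kL": f.kL,
        "kM": f.kM,
        "kS": f.kS,
        "kL_over_kM": f.kL / f.kM,
        "eew_l": white.l,
        "eew_s": white.s,
    }
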
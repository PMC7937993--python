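"""Illuminant estimators: the optimal-color model and simple baselines.

The optimal-color model treats a scene — a set of surfaces, each a
chromaticity-luminance triplet (l, s, Y) — as data generated under an unknown
Planckian illuminant, and fits the illuminant by matching the scene
distribution against precomputed optimal-color shells.  The procedure:

1. normalize the scene so its maximum luminance is 1.0;
2. for every candidate (T, h) on a temperature x relative-height grid,
   reject the candidate if any surface would exceed the shell (``Lsi > Loi``
   means the surface would need reflectance above 1 — physically impossible);
3. among the feasible candidates, minimize the weighted RMS luminance error

       WRMSE = sqrt( sum_i w_i (Lsi - Loi)^2 / sum_i w_i ),   w_i = Lsi / Loi

   where ``Loi = h * Y_boundary(T; l_i, s_i)`` is the shell luminance at the
   surface's chromaticity.  The weights emphasize surfaces that are bright
   relative to their physical ceiling, which carry the most information about
   the illuminant.

The search runs along the black-body locus only (a 1-D chromaticity family
parameterized by T) with intensity as a second, purely scalar dimension.

The API follows the fit-then-results pattern: build an
:class:`OptimalColorModel` from a :class:`SceneDistribution` (or DataFrame),
call :meth:`~OptimalColorModel.fit`, and read the
:class:`IlluminantEstimate` it returns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectral import ConeFundamentals, MBColor
from .fundamentals import default_fundamentals
from .illuminants import CandidateGrid, candidate_grid, make_illuminant
from .optimal import OptimalColorShell, build_shell

__all__ = [
    "SceneDistribution",
    "OptimalColorModel",
    "IlluminantEstimate",
    "INFEASIBLE",
    "normalize_scene",
    "wrmse",
    "estimate_optimal_color_model",
    "estimate_mean_chromaticity",
    "estimate_mean_lms",
    "luminance_statistics",
]

#: Sentinel value of :func:`wrmse` for a rejected candidate illuminant.
INFEASIBLE = math.inf

#: Relative slack on the feasibility test Lsi <= Loi*(1+eps); absorbs
#: floating-point rounding so exact-fit scenes are not spuriously rejected.
FEASIBILITY_EPS = 1e-6


@dataclass(frozen=True, eq=False)
class SceneDistribution:
    """A set of surfaces as MacLeod-Boynton chromaticity + luminance rows."""

    l: np.ndarray
    s: np.ndarray
    Y: np.ndarray
    luminance_unit: str = "cd/m^2"
    provenance: str = ""

    def __post_init__(self) -> None:
        for attr in ("l", "s", "Y"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), dtype=float))
        if not (self.l.shape == self.s.shape == self.Y.shape) or self.l.ndim != 1:
            raise ValueError("l, s, Y must be 1-D arrays of equal length")
        if self.l.size == 0:
            raise ValueError("scene must contain at least one surface")
        if np.any(self.Y < 0):
            raise ValueError("luminances must be non-negative")
        if not np.any(self.Y > 0):
            raise ValueError("scene must contain at least one surface with Y > 0")
        if np.any(self.l <= 0) or np.any(self.l >= 1) or np.any(self.s < 0):
            raise ValueError("chromaticities must satisfy 0 < l < 1 and s >= 0")

    @property
    def n_surfaces(self) -> int:
        return self.l.size

    @property
    def chromaticities(self) -> np.ndarray:
        return np.column_stack([self.l, self.s])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "SceneDistribution":
        return cls(l=df["l"].to_numpy(), s=df["s"].to_numpy(), Y=df["Y"].to_numpy(), **kwargs)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"l": self.l, "s": self.s, "Y": self.Y})

    def surfaces(self) -> list[MBColor]:
        return [MBColor(float(a), float(b), float(c)) for a, b, c in zip(self.l, self.s, self.Y)]


def normalize_scene(scene: SceneDistribution) -> tuple[SceneDistribution, float]:
    """Divide luminances by the scene maximum; returns (scene, original max Y)."""
    scale = float(scene.Y.max())
    if scale <= 0:
        raise ValueError("cannot normalize a scene with all-zero luminances")
    if scale == 1.0:
        return scene, 1.0
    return replace(scene, Y=scene.Y / scale), scale


def wrmse(
    scene: SceneDistribution,
    shell: OptimalColorShell,
    h: float,
    feasibility_eps: float = FEASIBILITY_EPS,
) -> float:
    """Weighted RMS luminance error of ``scene`` against ``shell`` at height ``h``.

    The scene must already be normalized (peak luminance 1.0).  Returns
    :data:`INFEASIBLE` when any surface exceeds the shell (beyond the
    floating-point slack) or falls outside the shell's chromatic footprint.
    Surfaces with zero luminance carry zero weight and are ignored.
    """
    y0 = shell.boundary_luminances(scene.chromaticities)
    if np.any(np.isnan(y0)):
        return INFEASIBLE
    loi = h * y0
    lsi = scene.Y
    if np.any(lsi > loi * (1.0 + feasibility_eps)):
        return INFEASIBLE
    w = lsi / loi
    denom = w.sum()
    if denom <= 0:
        return INFEASIBLE
    return float(np.sqrt(np.sum(w * (lsi - loi) ** 2) / denom))


@dataclass(frozen=True)
class IlluminantEstimate:
    """Fit results of the optimal-color model.

    ``h_hat_relative`` is in grid units (scene peak = 1); ``intensity_hat``
    is the illuminant white-point luminance restored to scene units.
    """

    T_hat: float
    h_hat_relative: float
    intensity_hat: float
    white_point: MBColor
    wrmse: float
    n_feasible: int
    n_candidates: int
    scene_scale: float
    tie_break: str = "lowest h, then T nearest 6500 K"
    feasibility_eps: float = FEASIBILITY_EPS
    surface: pd.DataFrame | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            "Optimal-color illuminant estimate",
            "=" * 41,
            f"{'Color temperature T_hat':<30}{self.T_hat:>10.0f} K",
            f"{'Relative height h_hat':<30}{self.h_hat_relative:>10.4f}",
            f"{'Illuminant intensity':<30}{self.intensity_hat:>10.4f}",
            f"{'White point l':<30}{self.white_point.l:>10.4f}",
            f"{'White point s':<30}{self.white_point.s:>10.4f}",
            f"{'WRMSE (normalized units)':<30}{self.wrmse:>10.3e}",
            f"{'Feasible candidates':<30}{self.n_feasible:>10d} / {self.n_candidates}",
            f"{'Scene peak luminance':<30}{self.scene_scale:>10.4f}",
            f"Tie-break rule: {self.tie_break}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "T_hat": self.T_hat,
            "h_hat_relative": self.h_hat_relative,
            "intensity_hat": self.intensity_hat,
            "white_point": {"l": self.white_point.l, "s": self.white_point.s,
                            "Y": self.white_point.Y},
            "wrmse": self.wrmse,
            "n_feasible": self.n_feasible,
            "n_candidates": self.n_candidates,
            "scene_scale": self.scene_scale,
            "tie_break": self.tie_break,
            "feasibility_eps": self.feasibility_eps,
        }


class OptimalColorModel:
    """Optimal-color illuminant model for one scene distribution.

    Parameters
    ----------
    scene:
        The surfaces to fit (any luminance unit; normalized internally).
    grid:
        Candidate (T, h) grid; defaults to 57 temperatures x 201 heights.
    shells:
        Optional mapping T -> :class:`OptimalColorShell` at h = 1.  Missing
        shells are built (and cached process-wide) on demand.
    fundamentals:
        Observer used to build shells and report the fitted white point.
    """

    def __init__(
        self,
        scene: SceneDistribution,
        grid: CandidateGrid | None = None,
        shells: dict[float, OptimalColorShell] | None = None,
        fundamentals: ConeFundamentals | None = None,
        feasibility_eps: float = FEASIBILITY_EPS,
    ):
        self.scene = scene
        self.grid = grid if grid is not None else candidate_grid()
        self.fundamentals = fundamentals or default_fundamentals()
        self.shells = dict(shells) if shells else {}
        self.feasibility_eps = feasibility_eps

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "OptimalColorModel":
        return cls(SceneDistribution.from_dataframe(df), **kwargs)

    def shell_for(self, T: float) -> OptimalColorShell:
        T = float(T)
        if T not in self.shells:
            self.shells[T] = build_shell(T, fundamentals=self.fundamentals,
                                         grid=self.fundamentals.grid)
        return self.shells[T]

    def fit(self, store_surface: bool = False) -> IlluminantEstimate:
        """Grid-search the candidate illuminants; return the WRMSE minimizer.

        Ties on WRMSE are broken toward the lowest height, then the
        temperature nearest 6500 K (prefer the least-intense physically
        sufficient illuminant; deterministic output).
        """
        scene, scale = normalize_scene(self.scene)
        temps = self.grid.temperatures
        heights = self.grid.heights
        eps = self.feasibility_eps
        lsi = scene.Y  # (n,)
        n_feasible = 0
        best: tuple[float, float, float] | None = None  # (wrmse, h, T)
        table = np.full((temps.size, heights.size), np.inf) if store_surface else None

        for ti, T in enumerate(temps):
            y0 = self.shell_for(T).boundary_luminances(scene.chromaticities)
            if np.any(np.isnan(y0)):
                continue
            # feasibility: h >= Lsi / y0 for every surface (up to eps slack)
            h_min = float(np.max(lsi / y0)) / (1.0 + eps)
            feasible = heights >= h_min
            if not np.any(feasible):
                continue
            hs = heights[feasible]  # (H,)
            loi = hs[:, None] * y0[None, :]  # (H, n)
            w = lsi[None, :] / loi
            vals = np.sqrt(np.sum(w * (lsi[None, :] - loi) ** 2, axis=1) / np.sum(w, axis=1))
            n_feasible += hs.size
            if table is not None:
                table[ti, feasible] = vals
            k = int(np.argmin(vals))  # first minimum = lowest feasible h
            cand = (float(vals[k]), float(hs[k]), float(T))
            if best is None or self._better(cand, best):
                best = cand

        if best is None:
            raise ValueError(
                "no feasible candidate illuminant: every candidate leaves some "
                "surface above the optimal-color shell; extend the height range "
                f"(current max {heights.max():g})"
            )
        err, h_hat, t_hat = best
        intensity = h_hat * scale
        wp_unit = self.shell_for(t_hat).white_point
        white = MBColor(l=wp_unit.l, s=wp_unit.s, Y=intensity)
        surface_df = None
        if table is not None:
            surface_df = pd.DataFrame(table, index=pd.Index(temps, name="T"),
                                      columns=pd.Index(heights, name="h"))
        return IlluminantEstimate(
            T_hat=t_hat,
            h_hat_relative=h_hat,
            intensity_hat=intensity,
            white_point=white,
            wrmse=err,
            n_feasible=n_feasible,
            n_candidates=self.grid.n_candidates,
            scene_scale=scale,
            feasibility_eps=eps,
            surface=surface_df,
        )

    @staticmethod
    def _better(cand: tuple[float, float, float], best: tuple[float, float, float]) -> bool:
        if cand[0] != best[0]:
            return cand[0] < best[0]
        if cand[1] != best[1]:
            return cand[1] < best[1]
        return abs(cand[2] - 6500.0) < abs(best[2] - 6500.0)


def estimate_optimal_color_model(
    scene: SceneDistribution,
    grid: CandidateGrid | None = None,
    shells: dict[float, OptimalColorShell] | None = None,
    fundamentals: ConeFundamentals | None = None,
    store_surface: bool = False,
) -> IlluminantEstimate:
    """Functional wrapper around :class:`OptimalColorModel` + ``fit``."""
    return OptimalColorModel(scene, grid, shells, fundamentals).fit(store_surface)


def estimate_mean_chromaticity(scene: SceneDistribution) -> MBColor:
    """Gray-world baseline: unweighted mean chromaticity (and mean luminance)."""
    return MBColor(float(scene.l.mean()), float(scene.s.mean()), float(scene.Y.mean()))


def estimate_mean_lms(
    scene: SceneDistribution, fundamentals: ConeFundamentals | None = None
) -> MBColor:
    """Mean-cone-signal baseline.

    Averaging cone excitations and converting to MB chromaticity is exactly
    the luminance-weighted average of (l, s): each surface's excitations are
    (l_i Y_i / kL, (1 - l_i) Y_i / kM, s_i Y_i / kS), so the mean excitation
    has l = sum(l_i Y_i) / sum(Y_i) and likewise for s.  ``fundamentals`` is
    accepted for interface symmetry; the weights cancel.
    """
    total = float(scene.Y.sum())
    if total <= 0:
        raise ValueError("mean-LMS chromaticity undefined for zero total luminance")
    return MBColor(
        float(np.sum(scene.l * scene.Y) / total),
        float(np.sum(scene.s * scene.Y) / total),
        float(scene.Y.mean()),
    )


def luminance_statistics(scene: SceneDistribution) -> dict[str, float]:
    """Simple luminance baselines: scene mean and maximum luminance."""
    return {"mean_Y": float(scene.Y.mean()), "max_Y": float(scene.Y.max())}
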
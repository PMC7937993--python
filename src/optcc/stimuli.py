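"""Scene-distribution construction for the three stimulus families.

Three families of 9 conditions (3 distribution shapes x 3 color
temperatures) probe how the shape of a scene's chromaticity-luminance
distribution constrains illuminant estimation:

* **Optimal-color scenes, shape manipulation** (mountain / reverse / flat):
  30 chromaticities on three concentric similar triangles about the neutral
  point are mapped to their unique optimal reflectances under equal-energy
  white.  The mountain condition uses them as is (luminance peaks near the
  white point); reverse darkens the middle ring to 3/4 and the inner ring to
  1/2 of optimal reflectance (luminance now peaks at the outer, high-purity
  ring); flat places middle/inner luminances on the straight line from the
  outer-ring optimal luminance down to half the illuminant height.
* **Optimal-color scenes, group reduction** (red/green/blue-reduced): the
  chromaticities are grouped by nearest vertex; a condition's group
  (including shared-edge members) is darkened to 1/3 of optimal reflectance.
* **Natural-reflectance scenes** (natural / red-increased / blue-increased):
  60 smooth reflectances drawn from a synthetic natural-reflectance sampler
  (a stand-in for a measured natural-object database), chromatically
  balanced around equal-energy white, optionally luminance-skewed along the
  l or s axis by per-surface scalars capped at unit reflectance.

Every scene consists of chromaticity-luminance surfaces rendered under a
Planckian test illuminant whose intensity is set so the scene mean luminance
hits a fixed target (1.2 cd/m^2 for the optimal-color families, 6.0 cd/m^2
for the natural family).  The optimal-color families add a dark copy of each
of the 30 bright surfaces at exactly 20% luminance (60 surfaces total); the
natural family uses its 60 reflectances directly.

By design, every condition of the first two families is an exact (zero
WRMSE) fit to its generating illuminant whenever that illuminant is in the
candidate grid, while the skewed natural conditions bias the optimal-color
model's temperature estimate downward (red-increased) or upward
(blue-increased).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .spectral import (
    CANONICAL_GRID,
    ConeFundamentals,
    Spectrum,
    WavelengthGrid,
    render_reflectance_matrix,
)
from .fundamentals import EEW_L, EEW_S, default_fundamentals, equal_energy_white
from .illuminants import Illuminant, make_illuminant
from .optimal import OptimalColorShell, build_shell, build_shell_from_spectrum, enumerate_optimal_reflectances
from .estimation import SceneDistribution

__all__ = [
    "TriangleChromaticitySet",
    "StimulusScene",
    "DEFAULT_VERTICES",
    "triangle_chromaticities",
    "build_exp1_scene",
    "build_exp2_scene",
    "sample_natural_reflectances",
    "build_exp3_scene",
    "EXCLUSION_L_RANGE",
    "EXCLUSION_S_RANGE",
]

#: Default triangle vertices (l, s): high-purity red/green/blue directions
#: containing the equal-energy white point, chosen inside the chromatic
#: footprint of the optimal-color shells for all test temperatures.
DEFAULT_VERTICES = {
    "red": (0.8322, 0.1002),
    "green": (0.6304, 0.44),
    "blue": (0.6112, 8.0),
}

#: Near-neutral exclusion window for natural-reflectance pools (surfaces in
#: this chromaticity box under equal-energy white give the illuminant away).
EXCLUSION_L_RANGE = (0.6978, 0.7178)
EXCLUSION_S_RANGE = (0.800, 1.200)

_PURITY_FRACTIONS = (1.0, 2.0 / 3.0, 1.0 / 3.0)
#: Of the inner triangle's 12 sample positions, keep vertices and side
#: midpoints (indices into the 12-point layout below).
_INNER_KEEP = (0, 1, 2, 4, 7, 10)


@dataclass(frozen=True, eq=False)
class TriangleChromaticitySet:
    """30 chromaticities on three similar triangles about the white point.

    ``chromaticities`` is (30, 2); ``levels`` gives the ring (0 outer /
    1 middle / 2 inner); ``outer_index`` maps each point to its radial
    counterpart on the outer ring; ``groups`` holds per-point subsets of
    {"red", "green", "blue"} (side points belong to both adjacent groups).
    """

    vertices: dict
    white: tuple[float, float]
    chromaticities: np.ndarray
    levels: np.ndarray
    outer_index: np.ndarray
    groups: tuple

    def __post_init__(self) -> None:
        if self.chromaticities.shape != (30, 2):
            raise ValueError("expected exactly 30 chromaticities")

    @property
    def purity_fraction(self) -> np.ndarray:
        return np.array([_PURITY_FRACTIONS[k] for k in self.levels])

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([group in g for g in self.groups])


def _triangle_layout(
    verts: np.ndarray,
) -> tuple[np.ndarray, list[frozenset]]:
    """12 points of one triangle ring: 3 vertices then 3 points per side.

    Side points are at 1/4, 1/2, 3/4 between consecutive vertices (equal
    gaps) and belong to both adjacent color groups.
    """
    names = ("red", "green", "blue")
    pts = [verts[0], verts[1], verts[2]]
    groups: list[frozenset] = [frozenset({n}) for n in names]
    for a, b in ((0, 1), (1, 2), (2, 0)):
        for t in (0.25, 0.5, 0.75):
            pts.append(verts[a] + t * (verts[b] - verts[a]))
            groups.append(frozenset({names[a], names[b]}))
    return np.array(pts), groups


def triangle_chromaticities(
    vertices: dict | None = None,
    white: tuple[float, float] = (EEW_L, EEW_S),
    inner_keep: tuple[int, ...] = _INNER_KEEP,
) -> TriangleChromaticitySet:
    """Build the 30-chromaticity stimulus set (12 + 12 + 6 by ring).

    The middle and inner rings are similar triangles at ratios 2:3 and 1:3
    about ``white``; the inner ring's 12 sample positions are thinned to 6
    via ``inner_keep``.
    """
    vdict = dict(vertices or DEFAULT_VERTICES)
    v = np.array([vdict["red"], vdict["green"], vdict["blue"]], dtype=float)
    w = np.asarray(white, dtype=float)
    d1, d2 = v[1] - v[0], v[2] - v[0]
    area2 = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(area2) < 1e-12:
        raise ValueError("triangle vertices are collinear")
    # white point strictly inside the outer triangle
    bary = np.linalg.solve(np.column_stack([v[0] - v[2], v[1] - v[2]]), w - v[2])
    if not (bary[0] > 0 and bary[1] > 0 and bary.sum() < 1):
        raise ValueError("white point must lie strictly inside the vertex triangle")

    chroma, levels, outer_idx, groups = [], [], [], []
    for level, frac in enumerate(_PURITY_FRACTIONS):
        ring_verts = w + frac * (v - w)
        pts, grp = _triangle_layout(ring_verts)
        keep = range(12) if level < 2 else inner_keep
        for j in keep:
            chroma.append(pts[j])
            levels.append(level)
            outer_idx.append(j)
            groups.append(grp[j])
    # outer_index refers to position within the 30-point list's outer ring
    outer_positions = {j: i for i, j in enumerate(range(12))}
    return TriangleChromaticitySet(
        vertices=vdict,
        white=(float(w[0]), float(w[1])),
        chromaticities=np.array(chroma),
        levels=np.array(levels),
        outer_index=np.array([outer_positions[j] for j in outer_idx]),
        groups=tuple(groups),
    )


@dataclass(frozen=True, eq=False)
class StimulusScene:
    """A generated stimulus: surfaces, generating illuminant, provenance."""

    condition: str
    illuminant: Illuminant
    scene: SceneDistribution
    reflectances: list | None = None
    chromaticity_set: TriangleChromaticitySet | None = None
    extras: dict = field(default_factory=dict)

    @property
    def n_surfaces(self) -> int:
        return self.scene.n_surfaces


@lru_cache(maxsize=4)
def _eew_shell(fundamentals: ConeFundamentals) -> OptimalColorShell:
    return build_shell_from_spectrum(
        equal_energy_white(fundamentals.grid),
        enumerate_optimal_reflectances(fundamentals.grid),
        fundamentals,
        label="EEW",
    )


def _solve_indices(
    chroma: np.ndarray, fundamentals: ConeFundamentals, tol: float = 0.02
) -> np.ndarray:
    """Indices (into the enumerated optimal set) of the optimal reflectances
    whose equal-energy-white chromaticities are nearest each requested one."""
    shell = _eew_shell(fundamentals)
    d, idx = shell.nearest(chroma)
    if np.any(d > tol):
        bad = int(np.argmax(d))
        raise ValueError(
            f"chromaticity (l={chroma[bad, 0]:.4f}, s={chroma[bad, 1]:.4f}) has no "
            f"optimal color within {tol} under equal-energy white (nearest {d[bad]:.4f})"
        )
    return idx


def _assemble_scene(
    condition: str,
    T: float,
    bright_Y_unit: np.ndarray,
    bright_chroma: np.ndarray,
    target_mean_Y: float,
    fundamentals: ConeFundamentals,
    dark_fraction: float = 0.2,
) -> tuple[SceneDistribution, Illuminant]:
    """Add 20%-luminance dark copies, then scale the illuminant so the mean
    luminance over all 60 surfaces equals ``target_mean_Y`` exactly."""
    y = np.concatenate([bright_Y_unit, dark_fraction * bright_Y_unit])
    chroma = np.vstack([bright_chroma, bright_chroma])
    h_scene = target_mean_Y / float(y.mean())
    scene = SceneDistribution(
        l=chroma[:, 0], s=chroma[:, 1], Y=y * h_scene,
        provenance=f"{condition} @ {T:g} K, mean Y = {target_mean_Y:g}",
    )
    return scene, make_illuminant(T, h_scene, fundamentals.grid, fundamentals)


def _exp12_scene(
    condition: str,
    T: float,
    factors: np.ndarray,
    cs: TriangleChromaticitySet,
    target_mean_Y: float,
    fundamentals: ConeFundamentals,
) -> StimulusScene:
    f = fundamentals
    idx = _solve_indices(cs.chromaticities, f)
    shell_T = build_shell(T, fundamentals=f, grid=f.grid)
    pts = shell_T.points[idx]  # rendered (l, s, Y at h=1) of the 30 optimal colors
    bright_Y = factors * pts[:, 2]
    scene, illum = _assemble_scene(condition, T, bright_Y, pts[:, :2], target_mean_Y, f)
    ocs = enumerate_optimal_reflectances(f.grid)
    reflectances = [ocs[int(j)].spectrum.scaled(float(c)) for j, c in zip(idx, factors)]
    return StimulusScene(
        condition=condition, illuminant=illum, scene=scene,
        reflectances=reflectances, chromaticity_set=cs,
        extras={"reflectance_factors": factors, "optimal_indices": idx,
                "T": float(T), "target_mean_Y": float(target_mean_Y)},
    )


def build_exp1_scene(
    condition: str,
    T: float,
    chromaticity_set: TriangleChromaticitySet | None = None,
    target_mean_Y: float = 1.2,
    fundamentals: ConeFundamentals | None = None,
) -> StimulusScene:
    """Mountain / reverse / flat scene at color temperature ``T``.

    Reflectance factors per ring: mountain (1, 1, 1); reverse (1, 3/4, 1/2);
    flat scales each middle/inner surface so its luminance falls on the line
    from the outer-ring optimal luminance (purity fraction 1) to half the
    illuminant height (purity fraction 0).
    """
    f = fundamentals or default_fundamentals()
    cs = chromaticity_set or triangle_chromaticities()
    if condition == "mountain":
        factors = np.ones(30)
    elif condition == "reverse":
        factors = np.choose(cs.levels, [1.0, 0.75, 0.5])
    elif condition == "flat":
        idx = _solve_indices(cs.chromaticities, f)
        shell_T = build_shell(T, fundamentals=f, grid=f.grid)
        y_self = shell_T.points[idx, 2]
        outer_rows = np.nonzero(cs.levels == 0)[0]
        y_outer = y_self[outer_rows[cs.outer_index]]
        frac = cs.purity_fraction
        target = 0.5 + frac * (y_outer - 0.5)  # straight line in purity fraction
        factors = np.minimum(target / y_self, 1.0)
    else:
        raise ValueError(f"unknown condition {condition!r} "
                         "(expected mountain, reverse or flat)")
    return _exp12_scene(condition, T, factors, cs, target_mean_Y, f)


def build_exp2_scene(
    condition: str,
    T: float,
    chromaticity_set: TriangleChromaticitySet | None = None,
    target_mean_Y: float = 1.2,
    fundamentals: ConeFundamentals | None = None,
    reduction: float = 1.0 / 3.0,
) -> StimulusScene:
    """Red/green/blue-reduced scene: the named group (including shared-edge
    members) is darkened to ``reduction`` of optimal reflectance."""
    f = fundamentals or default_fundamentals()
    cs = chromaticity_set or triangle_chromaticities()
    group = {"red_reduced": "red", "green_reduced": "green",
             "blue_reduced": "blue"}.get(condition)
    if group is None:
        raise ValueError(f"unknown condition {condition!r} "
                         "(expected red_reduced, green_reduced or blue_reduced)")
    factors = np.where(cs.group_mask(group), reduction, 1.0)
    return _exp12_scene(condition, T, factors, cs, target_mean_Y, f)


def sample_natural_reflectances(
    n: int,
    smoothness: float = 1.5,
    saturation_spread: float = 0.6,
    seed: int = 0,
    n_basis: int = 6,
    lightness_mean: float = -1.0,
    lightness_sd: float = 0.8,
    grid: WavelengthGrid = CANONICAL_GRID,
) -> np.ndarray:
    """Synthetic natural-reflectance sampler (stand-in for a measured
    natural-object database).

    Each reflectance is a logistic squashing of a random low-dimensional
    smooth curve: sigma(c0 + sum_k a_k cos(k pi x)) with x the normalized
    wavelength, a_k ~ N(0, (saturation_spread / k^smoothness)^2) and
    c0 ~ N(lightness_mean, lightness_sd^2).  Values are strictly inside
    (0, 1), so every sample lies strictly inside any optimal-color shell;
    under a neutral illuminant the ensemble forms a mountain-like
    chromaticity-luminance cloud.  Returns an (n, grid.count) matrix;
    deterministic for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 1.0, grid.count)
    k = np.arange(1, n_basis + 1)
    basis = np.cos(np.pi * np.outer(k, x))  # (n_basis, N)
    amp = saturation_spread / k**smoothness
    coefs = rng.normal(0.0, 1.0, size=(n, n_basis)) * amp[None, :]
    c0 = rng.normal(lightness_mean, lightness_sd, size=n)
    curves = c0[:, None] + coefs @ basis
    return 1.0 / (1.0 + np.exp(-curves))


def _balanced_subset(
    ls: np.ndarray,
    n_pick: int,
    target: np.ndarray,
    rng: np.random.Generator,
    tol: float = 0.002,
    max_iter: int = 2000,
) -> np.ndarray:
    """Seeded greedy selection of ``n_pick`` rows whose mean chromaticity is
    within ``tol`` of ``target`` (random start, best single-swap descent)."""
    n = ls.shape[0]
    if n < n_pick:
        raise ValueError(f"pool of {n} reflectances too small to draw {n_pick}")
    chosen = rng.choice(n, size=n_pick, replace=False)
    in_set = np.zeros(n, dtype=bool)
    in_set[chosen] = True
    mean = ls[in_set].mean(axis=0)
    for _ in range(max_iter):
        err = float(np.hypot(*(mean - target)))
        if err <= tol:
            break
        # best swap: remove i, add j, minimizing the new mean error
        inside = np.nonzero(in_set)[0]
        outside = np.nonzero(~in_set)[0]
        best = (err, None, None)
        # swapping i (in) for j (out) moves the mean by (ls[j] - ls[i]) / n_pick
        diff_in = ls[inside]
        diff_out = ls[outside]
        for ii, i_row in enumerate(inside):
            new_means = mean[None, :] + (diff_out - diff_in[ii]) / n_pick
            errs = np.hypot(new_means[:, 0] - target[0], new_means[:, 1] - target[1])
            jj = int(np.argmin(errs))
            if errs[jj] < best[0] - 1e-15:
                best = (float(errs[jj]), int(i_row), int(outside[jj]))
        if best[1] is None:
            break
        in_set[best[1]] = False
        in_set[best[2]] = True
        mean = ls[in_set].mean(axis=0)
    err = float(np.hypot(*(mean - target)))
    if err > tol:
        raise ValueError(
            f"could not balance mean chromaticity to within {tol} of "
            f"({target[0]:.4f}, {target[1]:.4f}); achieved {err:.4f}"
        )
    return np.nonzero(in_set)[0]


def _design_checked_subset(
    pool: np.ndarray,
    keep: np.ndarray,
    ls_pool: np.ndarray,
    T: float,
    seed: int,
    fundamentals: ConeFundamentals,
    balance_tol: float,
    attempts: int,
) -> np.ndarray:
    """Draw chromatically balanced 60-reflectance subsets until the unskewed
    scene is an exact temperature fit (or the closest draw if none is)."""
    from .estimation import OptimalColorModel, SceneDistribution as _SD
    from .illuminants import candidate_grid as _cg

    target = np.array([EEW_L, EEW_S])
    grid = _cg()
    illum_unit = make_illuminant(T, 1.0, fundamentals.grid, fundamentals)
    best: tuple[float, np.ndarray] | None = None
    for a in range(max(1, attempts)):
        rng = np.random.default_rng([int(seed), a])
        try:
            sel = keep[_balanced_subset(ls_pool, 60, target, rng, balance_tol)]
        except ValueError:
            continue
        lT, sT, yT = render_reflectance_matrix(pool[sel], illum_unit.spectrum, fundamentals)
        scene = _SD(l=lT, s=sT, Y=yT)
        res = OptimalColorModel(scene, grid, fundamentals=fundamentals).fit()
        t_err = abs(res.T_hat - T)
        if t_err == 0:
            return sel
        if best is None or t_err < best[0]:
            best = (t_err, sel)
    if best is None:
        raise ValueError("could not draw a chromatically balanced 60-reflectance subset")
    return best[1]


def build_exp3_scene(
    condition: str,
    T: float,
    reflectance_pool: np.ndarray | None = None,
    seed: int = 0,
    target_mean_Y: float = 6.0,
    skew_floor: float = 0.5,
    pool_size: int = 575,
    fundamentals: ConeFundamentals | None = None,
    balance_tol: float = 0.002,
    design_check_attempts: int = 30,
) -> StimulusScene:
    """Natural / red-increased / blue-increased scene at temperature ``T``.

    Near-neutral pool members (equal-energy-white chromaticity inside the
    exclusion window) are dropped; 60 reflectances are then selected so their
    mean chromaticity under equal-energy white is within ``balance_tol`` of
    the neutral point.  Among up to ``design_check_attempts`` such balanced
    draws (all derived from ``seed``), the first whose *unskewed* scene lets
    the optimal-color model recover ``T`` exactly on the default candidate
    grid is kept — the stimulus-design constraint that the natural condition
    must be model-exact; if none passes, the draw with the smallest
    temperature error is used.  The same draw is shared by all three
    conditions of a (T, seed) pair.

    The increased conditions rescale each selected reflectance by a scalar
    affine-increasing in its equal-energy l (red) or s (blue), with
    ``skew_floor`` the relative weight of the lowest-ranked surface and the
    overall scale capped so no reflectance exceeds 1.0 anywhere.
    """
    if condition not in ("natural", "red_increased", "blue_increased"):
        raise ValueError(f"unknown condition {condition!r}")
    f = fundamentals or default_fundamentals()
    pool = (reflectance_pool if reflectance_pool is not None
            else sample_natural_reflectances(pool_size, seed=seed, grid=f.grid))
    pool = np.atleast_2d(np.asarray(pool, dtype=float))

    eew = equal_energy_white(f.grid)
    l_eew, s_eew, _ = render_reflectance_matrix(pool, eew, f)
    near_neutral = (
        (l_eew >= EXCLUSION_L_RANGE[0]) & (l_eew <= EXCLUSION_L_RANGE[1])
        & (s_eew >= EXCLUSION_S_RANGE[0]) & (s_eew <= EXCLUSION_S_RANGE[1])
    )
    keep = np.nonzero(~near_neutral)[0]
    if keep.size < 60:
        raise ValueError(
            f"only {keep.size} reflectances remain after excluding "
            f"{int(near_neutral.sum())} near-neutral ones; pool too small"
        )
    ls_pool = np.column_stack([l_eew[keep], s_eew[keep]])
    sel = _design_checked_subset(
        pool, keep, ls_pool, T, seed, f, balance_tol, design_check_attempts
    )
    refl = pool[sel]
    l60, s60 = l_eew[sel], s_eew[sel]

    if condition == "natural":
        scalars = np.ones(60)
    else:
        x = l60 if condition == "red_increased" else s60
        span = float(np.ptp(x)) or 1.0
        weights = skew_floor + (1.0 - skew_floor) * (x - x.min()) / span
        scalars = weights / float(np.max(weights * refl.max(axis=1)))
    scaled = refl * scalars[:, None]

    illum_unit = make_illuminant(T, 1.0, f.grid, f)
    lT, sT, yT = render_reflectance_matrix(scaled, illum_unit.spectrum, f)
    h_scene = target_mean_Y / float(yT.mean())
    scene = SceneDistribution(
        l=lT, s=sT, Y=yT * h_scene,
        provenance=f"{condition} @ {T:g} K, seed {seed}, mean Y = {target_mean_Y:g}",
    )
    reflectances = [Spectrum(f.grid, row, "reflectance") for row in scaled]
    return StimulusScene(
        condition=condition,
        illuminant=make_illuminant(T, h_scene, f.grid, f),
        scene=scene,
        reflectances=reflectances,
        extras={"seed": seed, "selected_indices": sel, "scalars": scalars,
                "n_excluded": int(near_neutral.sum()), "skew_floor": skew_floor,
                "T": float(T), "target_mean_Y": float(target_mean_Y)},
    )
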
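"""Plain-text readers/writers and tiny deterministic test fixtures.

All formats are versioned plain text:

* spectrum CSV — header ``wavelength_nm,value``, one row per grid point;
* scene CSV — header ``l,s,Y``, one surface per row;
* reflectance-pool CSV — wide table: ``wavelength_nm`` plus one column per
  reflectance (accepts an external natural-reflectance database);
* shell cache CSV — ``l,s,Y_boundary`` with ``# key: value`` header lines
  recording the generating temperature, grid, and observer normalization so
  stale caches are detected;
* settings CSV — ``condition,l,s,Y``;
* result JSON — estimator output plus grid metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .spectral import CANONICAL_GRID, ConeFundamentals, Spectrum, WavelengthGrid
from .fundamentals import default_fundamentals
from .illuminants import CandidateGrid
from .optimal import OptimalColorShell
from .estimation import IlluminantEstimate, SceneDistribution

__all__ = [
    "read_spectrum_csv", "write_spectrum_csv",
    "read_scene_csv", "write_scene_csv",
    "read_reflectance_pool_csv", "write_reflectance_pool_csv",
    "read_shell_csv", "write_shell_csv",
    "read_settings_csv", "write_settings_csv",
    "write_estimate_json",
    "fixture_generator",
]


def _grid_from_wavelengths(wl: np.ndarray) -> WavelengthGrid:
    wl = np.asarray(wl, dtype=float)
    if wl.size < 2 or np.any(np.diff(wl) <= 0):
        raise ValueError("wavelengths must be strictly increasing with >= 2 rows")
    steps = np.diff(wl)
    if not np.allclose(steps, steps[0], atol=1e-9):
        raise ValueError("wavelengths must be uniformly spaced")
    return WavelengthGrid(float(wl[0]), float(wl[-1]), float(steps[0]))


def read_spectrum_csv(path, role: str = "reflectance") -> Spectrum:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns[:2]) != ["wavelength_nm", "value"]:
        raise ValueError(f"{path}: expected header 'wavelength_nm,value'")
    grid = _grid_from_wavelengths(df["wavelength_nm"].to_numpy())
    return Spectrum(grid, df["value"].to_numpy(dtype=float), role)


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.grid.wavelengths, "value": spectrum.values}
    ).to_csv(path, index=False, float_format="%.17g")


def read_scene_csv(path, **kwargs) -> SceneDistribution:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("l", "s", "Y"):
        if col not in df.columns:
            raise ValueError(f"{path}: scene CSV must have columns l,s,Y (missing {col})")
    return SceneDistribution.from_dataframe(df, **kwargs)


def write_scene_csv(scene: SceneDistribution, path) -> None:
    scene.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def read_reflectance_pool_csv(path) -> tuple[np.ndarray, WavelengthGrid]:
    """Wide reflectance table -> ((n_reflectances, n_wavelengths), grid)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "wavelength_nm":
        raise ValueError(f"{path}: first column must be 'wavelength_nm'")
    grid = _grid_from_wavelengths(df["wavelength_nm"].to_numpy())
    values = df.drop(columns="wavelength_nm").to_numpy(dtype=float).T
    if np.any(values < 0) or np.any(values > 1 + 1e-9):
        raise ValueError(f"{path}: reflectances must lie in [0, 1]")
    return values, grid


def write_reflectance_pool_csv(values: np.ndarray, grid: WavelengthGrid, path) -> None:
    values = np.atleast_2d(values)
    df = pd.DataFrame({"wavelength_nm": grid.wavelengths})
    for i, row in enumerate(values):
        df[f"r{i:04d}"] = row
    df.to_csv(path, index=False, float_format="%.17g")


def write_shell_csv(shell: OptimalColorShell, path,
                    fundamentals: ConeFundamentals | None = None) -> None:
    f = fundamentals or default_fundamentals()
    head = [
        f"# label: {shell.label}",
        f"# grid: {f.grid.start},{f.grid.stop},{f.grid.step}",
        f"# observer: {f.name}",
        f"# kL: {f.kL!r}", f"# kM: {f.kM!r}", f"# kS: {f.kS!r}",
        f"# white_index: {shell.white_index}",
        f"# footprint_tol: {shell.footprint_tol!r}",
    ]
    body = pd.DataFrame(shell.points, columns=["l", "s", "Y_boundary"]).to_csv(
        index=False, float_format="%.17g"
    )
    Path(path).write_text("\n".join(head) + "\n" + body)


def read_shell_csv(path, fundamentals: ConeFundamentals | None = None) -> OptimalColorShell:
    f = fundamentals or default_fundamentals()
    meta: dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    n_head = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_head += 1
        key, _, val = line[1:].partition(":")
        meta[key.strip()] = val.strip()
    expected_grid = f"{f.grid.start},{f.grid.stop},{f.grid.step}"
    if meta.get("grid") != expected_grid or meta.get("observer") != f.name:
        raise ValueError(
            f"{path}: shell cache was built for grid/observer "
            f"({meta.get('grid')}, {meta.get('observer')}), current is "
            f"({expected_grid}, {f.name}); rebuild the cache"
        )
    df = pd.read_csv(path, skiprows=n_head, float_precision="round_trip")
    points = df[["l", "s", "Y_boundary"]].to_numpy(dtype=float)
    wi = int(meta["white_index"])
    from .spectral import MBColor

    return OptimalColorShell(
        label=meta.get("label", Path(path).stem),
        points=points,
        white_point=MBColor(float(points[wi, 0]), float(points[wi, 1]), float(points[wi, 2])),
        white_index=wi,
        footprint_tol=float(meta.get("footprint_tol", 0.05)),
    )


def read_settings_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("condition", "l", "s", "Y"):
        if col not in df.columns:
            raise ValueError(f"{path}: settings CSV must have columns condition,l,s,Y")
    return df


def write_settings_csv(settings, path) -> None:
    pd.DataFrame(
        [{"condition": s.condition, "l": s.l, "s": s.s, "Y": s.Y} for s in settings]
    ).to_csv(path, index=False, float_format="%.17g")


def write_estimate_json(result: IlluminantEstimate, grid: CandidateGrid, path) -> None:
    payload = result.to_dict()
    payload["grid"] = {
        "temperatures_K": [float(t) for t in grid.temperatures],
        "heights": [float(h) for h in grid.heights],
        "n_candidates": grid.n_candidates,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def fixture_generator(kind: str, seed: int = 0):
    """Tiny deterministic inputs for oracle tests and CLI smoke runs.

    ``toy_scene``: 5-surface near-neutral scene; ``toy_grid``: 3 x 3
    candidate grid; ``toy_reflectances``: 8 smooth reflectances.
    """
    rng = np.random.default_rng([seed, 987])
    if kind == "toy_scene":
        l = 0.70 + 0.02 * rng.standard_normal(5).round(3)
        s = 1.0 + 0.2 * rng.standard_normal(5).round(3)
        Y = np.abs(rng.uniform(0.1, 1.0, 5)).round(4)
        return SceneDistribution(l=l, s=s, Y=Y, provenance=f"toy_scene seed {seed}")
    if kind == "toy_grid":
        return CandidateGrid(
            temperatures=np.array([4000.0, 6500.0, 10000.0]),
            heights=np.array([1.0, 1.5, 2.0]),
        )
    if kind == "toy_reflectances":
        from .stimuli import sample_natural_reflectances

        return sample_natural_reflectances(8, seed=seed)
    raise ValueError(f"unknown fixture kind {kind!r} "
                     "(expected toy_scene, toy_grid or toy_reflectances)")
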
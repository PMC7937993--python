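"""Constancy and model-agreement metrics, plus a synthetic observer.

The *constancy index* (CI) measures how far an observer's white point moved
with an illuminant change, projected onto the physical illuminant shift.  In
a per-axis-scaled MacLeod-Boynton plane define

    a = scaled shift of the illuminant chromaticity (reference -> test)
    b = scaled shift of the observer's white-point setting
    CI = |b| cos(theta) / |a|,   theta = angle(a, b)

CI is 1.0 for perfect constancy (the setting shift equals the illuminant
shift in distance and direction), 0 for no systematic shift, and signed:
shifts opposing the illuminant give negative values.  The *model index* (MI)
is the same projection computed against a model's predicted illuminant shift
c instead of the physical one:

    MI = |b| cos(phi) / |c|,   phi = angle(c, b)

so MI = 1 is perfect prediction, and MI equals CI whenever the model
predicts the true illuminant chromaticities.

The axis scales compensate for the very different magnitudes of the l and s
axes; they are per-axis divisors (conventionally, the standard deviation of
repeated settings under a reference condition).  Both indices are invariant
to a common rescaling of both axes.

:func:`simulate_observer` generates settings with a known constancy level k
(white point = anchor + k * (illuminant - anchor) + Gaussian noise), which
lets the CI/MI pipeline be validated end to end by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AxisScales",
    "ObserverSetting",
    "constancy_index",
    "model_index",
    "axis_scales_from_settings",
    "prediction_agreement",
    "simulate_observer",
]


@dataclass(frozen=True)
class AxisScales:
    """Per-axis divisors for the scaled MacLeod-Boynton plane."""

    sigma_l: float = 1.0
    sigma_s: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_l <= 0 or self.sigma_s <= 0:
            raise ValueError("axis scales must be positive")

    def apply(self, delta: np.ndarray) -> np.ndarray:
        d = np.asarray(delta, dtype=float)
        return np.array([d[..., 0] / self.sigma_l, d[..., 1] / self.sigma_s]).T


@dataclass(frozen=True)
class ObserverSetting:
    """One white-point setting: condition label, chromaticity, luminance."""

    condition: str
    l: float
    s: float
    Y: float

    def __post_init__(self) -> None:
        if self.Y <= 0:
            raise ValueError("setting luminance must be positive")

    @property
    def chromaticity(self) -> np.ndarray:
        return np.array([self.l, self.s])


def _projection_ratio(b: np.ndarray, a: np.ndarray) -> float:
    """|b| cos(angle) / |a| = (b . a) / |a|^2, signed."""
    na2 = float(a @ a)
    if na2 == 0:
        raise ValueError("reference shift vector has zero length")
    return float(b @ a) / na2


def _chroma(x) -> np.ndarray:
    if isinstance(x, ObserverSetting):
        return x.chromaticity
    arr = np.asarray(x, dtype=float)
    if hasattr(x, "l") and hasattr(x, "s"):  # MBColor or similar
        return np.array([float(x.l), float(x.s)])
    return arr[:2]


def constancy_index(
    ref_setting,
    test_setting,
    ref_illum_chroma,
    test_illum_chroma,
    scales: AxisScales = AxisScales(),
) -> float:
    """CI = |b| cos(theta) / |a| in the scaled chromaticity plane.

    ``a`` is the illuminant shift, ``b`` the observer-setting shift, both
    from the reference condition to the test condition.
    """
    a = scales.apply(_chroma(test_illum_chroma) - _chroma(ref_illum_chroma))
    b = scales.apply(_chroma(test_setting) - _chroma(ref_setting))
    return _projection_ratio(b, a)


def model_index(
    ref_setting,
    test_setting,
    ref_model_pred,
    test_model_pred,
    scales: AxisScales = AxisScales(),
) -> float:
    """MI = |b| cos(phi) / |c|, with ``c`` the model's predicted shift."""
    c = scales.apply(_chroma(test_model_pred) - _chroma(ref_model_pred))
    b = scales.apply(_chroma(test_setting) - _chroma(ref_setting))
    return _projection_ratio(b, c)


def axis_scales_from_settings(l: np.ndarray, s: np.ndarray) -> AxisScales:
    """Axis scales from repeated settings under one reference condition:
    the per-axis standard deviations."""
    sl = float(np.std(np.asarray(l, dtype=float), ddof=1))
    ss = float(np.std(np.asarray(s, dtype=float), ddof=1))
    if sl <= 0 or ss <= 0:
        raise ValueError("settings show zero variance along an axis")
    return AxisScales(sl, ss)


def prediction_agreement(
    predictions: np.ndarray, settings: np.ndarray
) -> dict[str, dict[str, float]]:
    """Per-axis Pearson r and RMSE between model predictions and settings.

    Both inputs are (n, k) arrays of matched rows (k = 2 for (l, s) or 3 for
    (l, s, Y)); n >= 3.  Axes with zero variance get r = NaN (flagged).
    """
    p = np.atleast_2d(np.asarray(predictions, dtype=float))
    o = np.atleast_2d(np.asarray(settings, dtype=float))
    if p.shape != o.shape:
        raise ValueError("predictions and settings must have matching shapes")
    if p.shape[0] < 3:
        raise ValueError("need at least 3 matched points per axis")
    axes = ["l", "s", "Y"][: p.shape[1]]
    out: dict[str, dict[str, float]] = {}
    for j, name in enumerate(axes):
        x, y = p[:, j], o[:, j]
        rmse = float(np.sqrt(np.mean((x - y) ** 2)))
        if np.std(x) == 0 or np.std(y) == 0:
            r = float("nan")
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        out[name] = {"pearson_r": r, "rmse": rmse}
    return out


def simulate_observer(
    conditions,
    constancy: float,
    anchor: tuple[float, float],
    chroma_noise_sd: float = 0.0,
    lum_gain: float = 1.0,
    lum_noise_sd: float = 0.0,
    seed: int = 0,
) -> list[ObserverSetting]:
    """Synthetic observer with constancy level ``k`` in [0, 1].

    ``conditions`` is a sequence of (label, illuminant_chromaticity,
    illuminant_intensity) triples.  The setting chromaticity is
    ``anchor + k*(illuminant - anchor)`` plus isotropic Gaussian noise; the
    luminance is ``lum_gain * intensity * (1 + Gaussian noise)``.  Seeded and
    deterministic.
    """
    if not (0.0 <= constancy <= 1.0):
        raise ValueError("constancy must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    anchor_arr = np.asarray(anchor, dtype=float)
    out = []
    for label, illum_chroma, intensity in conditions:
        chroma = anchor_arr + constancy * (_chroma(illum_chroma) - anchor_arr)
        chroma = chroma + rng.normal(0.0, chroma_noise_sd, size=2)
        lum = lum_gain * float(intensity) * (1.0 + rng.normal(0.0, lum_noise_sd))
        out.append(ObserverSetting(str(label), float(chroma[0]), float(chroma[1]),
                                   max(lum, 1e-12)))
    return out
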
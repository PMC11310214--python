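"""Forward model of the THz liquid-cell transmission measurement.

The scene generator emulates the full measurement: a smooth source
envelope, etalon fringes on the empty-cell channel (period ``1/(2d)`` in
wavenumber for path length ``d``), Beer-Lambert attenuation of the filled
channels, multiplicative water-vapor dips shared across channels (with
optional per-channel depth jitter, which is what leaves vapor residuals in
the difference spectra), and multiplicative detector noise. The ground
truth ``delta_alpha`` of every condition is returned alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from ..errors import ValidationError
from ..spectra import Spectrum

__all__ = ["ThzSceneSpec", "ThzScene", "gen_thz_scene", "gen_etalon_transmission"]


def default_water_baseline(nu: np.ndarray) -> np.ndarray:
    """Smooth bulk-water-like absorption (cm^-1) over 50-500 cm^-1."""
    return 150.0 + 0.85 * nu - 6e-4 * nu**2


def default_source_envelope(nu: np.ndarray) -> np.ndarray:
    return 1e5 * np.exp(-(((nu - 260.0) / 320.0) ** 2))


def flat_envelope(nu: np.ndarray) -> np.ndarray:
    return np.full_like(nu, 1e5)


def broad_hump(amplitude: float, center: float = 180.0, width: float = 160.0) -> Callable:
    """A broadband hydration-shell-like delta_alpha component."""

    def f(nu: np.ndarray) -> np.ndarray:
        return amplitude * np.exp(-(((nu - center) / width) ** 2))

    return f


#: Default per-condition ground-truth difference spectra: a solvated-sensor
#: reference with a broad positive hump, an analyte that weakens the
#: hydration coupling (dopamine-like) and one that strengthens it
#: (riboflavin-like).
DEFAULT_CONDITIONS: dict[str, Callable] = {
    "gt10": broad_hump(6.0),
    "gt10+dopamine": broad_hump(4.0),
    "gt10+riboflavin": broad_hump(8.0),
}

DEFAULT_VAPOR_LINES: tuple[tuple[float, float, float], ...] = (
    (150.5, 0.6, 0.12),
    (202.6, 0.6, 0.15),
    (221.7, 0.5, 0.10),
    (278.5, 0.6, 0.12),
    (326.6, 0.6, 0.10),
    (378.5, 0.6, 0.08),
)


@dataclass
class ThzSceneSpec:
    """Parameters of a synthetic THz measurement scene.

    ``water_baseline`` and the per-condition ``delta_alpha_truth`` entries
    are callables of the wavenumber array (cm^-1 -> cm^-1).
    """

    grid_min: float = 50.0
    grid_max: float = 500.0
    grid_step: float = 0.5
    path_length: float = 1.3e-3  # cm (13 um spacer)
    water_baseline: Callable = default_water_baseline
    delta_alpha_truth: Mapping[str, Callable] = field(
        default_factory=lambda: dict(DEFAULT_CONDITIONS)
    )
    vapor_lines: Sequence[tuple[float, float, float]] = DEFAULT_VAPOR_LINES
    vapor_channel_jitter: float = 0.0  # relative SD of dip depth across channels
    fringe_modulation: float = 0.25
    noise_sd: float = 0.0  # relative multiplicative intensity noise
    source_envelope: Callable = default_source_envelope
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_step <= 0 or self.grid_max <= self.grid_min:
            raise ValidationError("grid must be strictly increasing")
        if self.path_length <= 0:
            raise ValidationError("path_length must be > 0")
        if self.noise_sd < 0 or self.vapor_channel_jitter < 0:
            raise ValidationError("noise parameters must be >= 0")
        if not (0 <= self.fringe_modulation < 1):
            raise ValidationError("fringe_modulation must be in [0, 1)")
        for c, w, depth in self.vapor_lines:
            if not (self.grid_min <= c <= self.grid_max):
                raise ValidationError(f"vapor line at {c} cm^-1 outside the grid")
            if w <= 0 or not (0 <= depth < 1):
                raise ValidationError("vapor lines need width > 0 and depth in [0, 1)")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return self.grid_min + self.grid_step * np.arange(n)


@dataclass
class ThzScene:
    """Generated transmissions plus the ground truth behind them."""

    empty_cell: Spectrum
    water: Spectrum
    samples: dict[str, Spectrum]
    truth: dict[str, np.ndarray]  # condition -> delta_alpha on the grid
    grid: np.ndarray
    path_length: float


def _vapor_profile(
    grid: np.ndarray,
    lines: Sequence[tuple[float, float, float]],
    depth_scale: np.ndarray | float = 1.0,
) -> np.ndarray:
    prof = np.ones_like(grid)
    scales = np.broadcast_to(np.asarray(depth_scale, dtype=float), (len(lines),))
    for (c, w, depth), s in zip(lines, scales):
        prof *= 1.0 - np.clip(depth * s, 0.0, 0.999) * np.exp(
            -(((grid - c) / w) ** 2)
        )
    return prof


def gen_etalon_transmission(
    d: float,
    grid: np.ndarray,
    modulation_depth: float = 0.25,
    noise_sd: float = 0.0,
    seed: int | None = None,
    envelope: Callable = flat_envelope,
) -> Spectrum:
    """Empty-cell transmission with cosine etalon fringes of period 1/(2d).

    ``d`` is the window gap in cm; refractive index 1 is assumed between the
    windows, so the fringe term is ``1 + m cos(4 pi d nu)``. The default
    source envelope is flat so the generator serves any spectral range
    (etalon thickness is read off in the mid-IR in practice).
    """
    if d <= 0:
        raise ValidationError("path length d must be > 0")
    grid = np.asarray(grid, dtype=float)
    values = envelope(grid) * (1.0 + modulation_depth * np.cos(4 * np.pi * d * grid))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values * (1.0 + noise_sd * rng.standard_normal(grid.size))
        values = np.clip(values, 1e-12, None)
    return Spectrum(grid=grid, values=values, kind="transmission",
                    meta={"condition": "empty-cell", "d_true": d})


def gen_thz_scene(spec: ThzSceneSpec) -> ThzScene:
    """Generate empty-cell, water and per-condition sample transmissions.

    Forward model per channel: ``I = I0 * 10^(-d*(alpha_water + delta_alpha))``
    with fringes only on the empty-cell channel (a filled cell is
    index-matched), shared vapor dips, and multiplicative Gaussian noise of
    relative magnitude ``noise_sd``. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    env = spec.source_envelope(grid)
    if np.any(env <= 0):
        raise ValidationError("source envelope must be strictly positive")
    d = spec.path_length
    alpha_w = spec.water_baseline(grid)

    def channel(values: np.ndarray, label: str) -> Spectrum:
        jitter = (
            1.0 + spec.vapor_channel_jitter * rng.standard_normal(len(spec.vapor_lines))
            if spec.vapor_channel_jitter > 0
            else 1.0
        )
        out = values * _vapor_profile(grid, spec.vapor_lines, jitter)
        if spec.noise_sd > 0:
            out = out * (1.0 + spec.noise_sd * rng.standard_normal(grid.size))
            out = np.clip(out, 1e-12, None)
        return Spectrum(grid=grid.copy(), values=out, kind="transmission",
                        meta={"condition": label, "d_true": d})

    fringes = 1.0 + spec.fringe_modulation * np.cos(4 * np.pi * d * grid)
    empty = channel(env * fringes, "empty-cell")
    water = channel(env * 10.0 ** (-d * alpha_w), "water")
    samples: dict[str, Spectrum] = {}
    truth: dict[str, np.ndarray] = {}
    for cond, dfun in spec.delta_alpha_truth.items():
        da = np.asarray(dfun(grid), dtype=float)
        samples[cond] = channel(env * 10.0 ** (-d * (alpha_w + da)), cond)
        truth[cond] = da
    return ThzScene(
        empty_cell=empty, water=water, samples=samples, truth=truth,
        grid=grid, path_length=d,
    )
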
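"""Synthetic (coupling change, fluorescence change) response datasets."""

from __future__ import annotations

import numpy as np

from ..correlation import ResponsePoint
from ..errors import ValidationError

__all__ = ["gen_response_dataset"]

#: Default coupling-change design: 8 analyte conditions spanning the
#: relative-change axis symmetrically, the regime of sensor experiments.
DEFAULT_X_VALUES: tuple[float, ...] = (-0.4, -0.286, -0.171, -0.057, 0.057, 0.171, 0.286, 0.4)


def gen_response_dataset(
    slope: float,
    intercept: float = 0.0,
    x_values=DEFAULT_X_VALUES,
    noise_sd_x: float = 0.0,
    noise_sd_y: float | None = None,
    seed: int | None = None,
    *,
    sequence: str = "GT10",
) -> tuple[list[ResponsePoint], dict]:
    """Points on ``y = slope*x + intercept`` with seeded noise, plus truth.

    ``noise_sd_y=None`` applies the replicate-uncertainty convention of
    sensor response data: an SD of 10% of the noise-free y dynamic range.
    Returns ``(points, truth)`` where truth records the generating line and
    the realized noise SDs.
    """
    x = np.asarray(x_values, dtype=float)
    if x.size < 3:
        raise ValidationError("need at least 3 x values")
    rng = np.random.default_rng(seed)
    y_clean = slope * x + intercept
    if noise_sd_y is None:
        dyn = float(np.ptp(y_clean))
        noise_sd_y = 0.1 * dyn if dyn > 0 else 0.0
    x_obs = x + noise_sd_x * rng.standard_normal(x.size) if noise_sd_x > 0 else x.copy()
    y_obs = y_clean + noise_sd_y * rng.standard_normal(x.size) if noise_sd_y > 0 else y_clean.copy()
    points = [
        ResponsePoint(
            analyte=f"analyte-{i}", sequence=sequence,
            x=float(xo), y=float(yo),
            x_sem=float(noise_sd_x), y_sem=float(noise_sd_y),
        )
        for i, (xo, yo) in enumerate(zip(x_obs, y_obs))
    ]
    truth = {
        "slope": slope, "intercept": intercept,
        "noise_sd_x": float(noise_sd_x), "noise_sd_y": float(noise_sd_y),
        "x_values": x,
    }
    return points, truth
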
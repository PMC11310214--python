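"""Synthetic NIR emission spectra with analyte-scaled E11 intensity."""

from __future__ import annotations

import numpy as np

from ..errors import ValidationError
from ..fluorescence import EmissionSpectrum

__all__ = ["gen_fluorescence_set"]


def gen_fluorescence_set(
    baseline_peak: float,
    responses: dict[str, float],
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int | None = None,
    *,
    sequence: str = "GT10",
    center_nm: float = 990.0,
    width_nm: float = 25.0,
    grid: np.ndarray | None = None,
    background: float = 0.0,
) -> dict[str, dict[str, list[EmissionSpectrum]]]:
    """Before/after emission replicate sets for each analyte.

    The E11 band is a single Gaussian at ``center_nm`` with amplitude
    ``baseline_peak`` counts; the after-addition spectrum is scaled by
    ``1 + dI/I0`` using the true response of each analyte. Additive Gaussian
    count noise of SD ``noise_sd`` is applied per replicate. Returns
    ``{analyte: {"before": [...], "after": [...]}}``.
    """
    if baseline_peak <= 0:
        raise ValidationError("baseline_peak must be > 0")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    for analyte, r in responses.items():
        if 1.0 + r <= 0:
            raise ValidationError(
                f"true dI/I0={r} for {analyte!r} implies non-positive intensity"
            )
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = np.arange(850.0, 1151.0, 1.0)
    band = np.exp(-(((grid - center_nm) / width_nm) ** 2))

    out: dict[str, dict[str, list[EmissionSpectrum]]] = {}
    for analyte, r in responses.items():
        entry = {"before": [], "after": []}
        for rep in range(n_replicates):
            for cond, scale in (("before", 1.0), ("after", 1.0 + r)):
                counts = background + baseline_peak * scale * band
                if noise_sd > 0:
                    counts = counts + noise_sd * rng.standard_normal(grid.size)
                entry[cond].append(
                    EmissionSpectrum(
                        grid=grid.copy(), counts=counts, condition=cond,
                        analyte=analyte, sequence=sequence, replicate=rep,
                    )
                )
        out[analyte] = entry
    return out
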
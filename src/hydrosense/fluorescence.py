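"""NIR fluorescence of DNA-wrapped carbon nanotubes.

Semiconducting SWCNTs emit near-infrared fluorescence from their E11 exciton
(around 990 nm for the (6,5) chirality). Analyte binding modulates the
quantum yield, so the sensor readout is the normalized intensity change
``dI/I0 = (I_after - I_before)/I_before`` of the E11 peak, averaged over
replicates with SEM uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError

__all__ = ["EmissionSpectrum", "SensorResponse", "peak_metrics", "normalized_response"]

#: E11 search band (nm) used by default for (6,5)-enriched samples.
DEFAULT_E11_BAND: tuple[float, float] = (950.0, 1050.0)


@dataclass
class EmissionSpectrum:
    """An emission spectrum: counts on a strictly increasing wavelength grid (nm)."""

    grid: np.ndarray
    counts: np.ndarray
    condition: str = ""  # 'before' | 'after'
    analyte: str = ""
    sequence: str = ""
    replicate: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.grid.ndim != 1 or not np.all(np.diff(self.grid) > 0):
            raise ValidationError("wavelength grid must be 1-D and strictly increasing")
        if self.counts.shape != self.grid.shape:
            raise ValidationError("grid and counts must have equal length")
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("counts must be finite")


@dataclass
class SensorResponse:
    """Normalized fluorescence response of one analyte x DNA sequence."""

    analyte: str
    sequence: str
    delta_I_over_I0: float
    sem: float
    n_replicates: int

    def __post_init__(self) -> None:
        if self.delta_I_over_I0 <= -1:
            raise ValidationError(
                "dI/I0 <= -1 is non-physical for nonnegative intensities"
            )
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")


def peak_metrics(
    spec: EmissionSpectrum,
    band: tuple[float, float] = DEFAULT_E11_BAND,
    *,
    refine: bool = False,
) -> tuple[float, float]:
    """Peak intensity and wavelength of the in-band emission maximum.

    Returns ``(peak_counts, peak_wavelength_nm)``. With ``refine=True`` a
    local quadratic through the maximum and its neighbours refines both. Ties
    (flat maxima) resolve to the shortest wavelength and are warned about, as
    is a band that excludes the global maximum.
    """
    lo, hi = band
    if lo >= hi:
        raise ValidationError("empty band")
    inside = (spec.grid >= lo) & (spec.grid <= hi)
    if not inside.any():
        raise ValidationError(f"band ({lo}, {hi}) nm contains no grid points")
    idx = np.flatnonzero(inside)
    local = spec.counts[idx]
    k = int(np.argmax(local))
    peak_counts = float(local[k])
    if np.count_nonzero(local == peak_counts) > 1:
        warnings.warn("flat maximum in band; returning its shortest wavelength")
    if peak_counts < spec.counts.max():
        warnings.warn("band excludes the global maximum; returning in-band maximum")
    i = idx[k]
    peak_wl = float(spec.grid[i])
    if refine and 0 < i < spec.grid.size - 1:
        x = spec.grid[i - 1 : i + 2]
        y = spec.counts[i - 1 : i + 2]
        a, b, c = np.polyfit(x, y, 2)
        if a < 0:
            peak_wl = float(-b / (2 * a))
            peak_counts = float(np.polyval([a, b, c], peak_wl))
    return peak_counts, peak_wl


def normalized_response(
    before: Sequence[EmissionSpectrum],
    after: Sequence[EmissionSpectrum],
    band: tuple[float, float] = DEFAULT_E11_BAND,
    *,
    pair_by_order: bool = True,
) -> SensorResponse:
    """Normalized fluorescence change ``dI/I0`` with replicate statistics.

    Per-replicate responses are formed from paired before/after peak
    intensities, then averaged; the SEM is the sample SD over replicates
    divided by sqrt(n) (zero for a single replicate). Replicates pair either
    by acquisition order (default) or by their ``replicate`` ids.
    """
    if len(before) == 0 or len(after) == 0:
        raise ValidationError("need at least one replicate on each side")
    ref = before[0]
    for s in list(before) + list(after):
        if (s.analyte, s.sequence) != (ref.analyte, ref.sequence):
            raise ValidationError("mixed analyte/sequence metadata across replicates")
    if pair_by_order:
        if len(before) != len(after):
            raise ValidationError("unequal replicate counts; cannot pair by order")
        pairs = list(zip(before, after))
    else:
        by_id = {s.replicate: s for s in after}
        try:
            pairs = [(s, by_id[s.replicate]) for s in before]
        except KeyError as exc:
            raise ValidationError(f"unpaired replicate id {exc}") from exc

    responses = []
    for b, a in pairs:
        i_before, _ = peak_metrics(b, band)
        i_after, _ = peak_metrics(a, band)
        if i_before <= 0:
            raise ValidationError("non-positive baseline peak intensity")
        responses.append((i_after - i_before) / i_before)
    arr = np.asarray(responses)
    n = arr.size
    sem = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return SensorResponse(
        analyte=ref.analyte,
        sequence=ref.sequence,
        delta_I_over_I0=float(arr.mean()),
        sem=sem,
        n_replicates=n,
    )
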
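"""Synthetic two-site-class titration heats with known truth.

The generator shares its forward model with the fitting stage
(:func:`hydrosense.itc.simulate_heats`), adds Gaussian heat noise, and
returns an :class:`~hydrosense.itc.ItcExperiment` ready for fitting.

Default truth values describe a dopamine-into-nanotube titration in the
well-conditioned ITC regime: 37 strong surface sites per nanotube (the
regime reported for DNA-wrapped nanotubes), K1 = 3e6 1/M and a 500 nM cell
concentration chosen so the Wiseman c-value n1*K1*[M] ~ 55 falls inside
the canonical 10-100 window, a syringe concentration placing the
strong-class equivalence point mid-titration, per-injection heats well
above the instrument noise floor so the weak class is measurable, and a
weaker, more numerous corona class that does not saturate over the
titration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ValidationError
from ..itc import ItcExperiment, SiteClassParams, simulate_heats

__all__ = ["ItcTruth", "gen_itc_heats"]


@dataclass
class ItcTruth:
    """Ground-truth parameters and protocol of a synthetic titration."""

    n1: float = 37.0  # strong (nanotube-surface) sites per nanotube
    n2: float = 60.0  # weak (DNA-corona) sites per nanotube
    K1: float = 3e6  # 1/M
    K2: float = 1e4  # 1/M
    dH1: float = -8.0  # kcal/mol
    dH2: float = -1.5  # kcal/mol
    offset: float = 0.0  # ucal per injection
    syringe_conc: float = 4e-4  # M analyte
    cell_conc: float = 5e-7  # M nanotube
    cell_volume: float = 1.4  # mL
    injection_volumes: np.ndarray = field(
        default_factory=lambda: np.full(25, 10.0)
    )  # uL
    noise_sd: float = 0.2  # ucal (typical modern microcalorimeter injection noise)
    temperature: float = 297.15  # K (24 C)

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if self.syringe_conc <= 0 or self.cell_conc <= 0 or self.cell_volume <= 0:
            raise ValidationError("concentrations and volumes must be > 0")
        if self.K1 < self.K2:
            raise ValidationError("class 1 is the higher-affinity class: K1 >= K2")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    @property
    def params(self) -> SiteClassParams:
        return SiteClassParams(
            n1=self.n1, K1=self.K1, dH1=self.dH1,
            n2=self.n2, K2=self.K2, dH2=self.dH2, offset=self.offset,
        )


def gen_itc_heats(truth: ItcTruth, seed: int | None = None) -> ItcExperiment:
    """Per-injection heats from the two-class forward model plus noise."""
    protocol = ItcExperiment(
        injection_volumes=truth.injection_volumes,
        syringe_conc=truth.syringe_conc,
        cell_conc=truth.cell_conc,
        cell_volume=truth.cell_volume,
        temperature=truth.temperature,
    )
    heats = simulate_heats(truth.params, protocol)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + truth.noise_sd * rng.standard_normal(heats.size)
    protocol.heats = heats
    protocol.meta["truth"] = truth
    return protocol
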
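"""Scripted coarse trajectories of a nanotube-DNA-ligand-water system.

The generator builds a (6,5)-like nanotube as carbons on a cylindrical
lattice, a DNA corona as bead helices on an outer shell, single-site waters
filling a cylindrical shell, a few ions, and small rigid ligand molecules.
Each ligand follows a script of bound intervals: during a ``SURFACE``
interval it sits within the contact cutoff of nanotube carbons (locally
displacing shell waters outward), during a ``CORONA`` interval it sits
against a DNA bead but well beyond the carbon cutoff, and otherwise it is
parked in the far solvent. The script itself is returned as the ground
truth event list, so every downstream detector can be checked exactly.

Times are ns, coordinates Angstrom. The default frame spacing of 0.1 ns
mirrors the 30,000-configurations-per-3-us sampling convention of
production trajectories; tests use coarser spacings for speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from ..errors import ValidationError
from ..hydration import DEFAULT_ROLE_RADII, MolecularSystem

__all__ = ["LigandScript", "TrajectoryScript", "gen_trajectory"]

Target = Literal["SURFACE", "CORONA"]


@dataclass
class LigandScript:
    """Bound intervals (start ns, end ns, target) for one ligand molecule."""

    name: str
    intervals: list[tuple[float, float, Target]] = field(default_factory=list)


@dataclass
class TrajectoryScript:
    """Full scene script: frames, ligand schedules and geometry."""

    n_frames: int
    frame_dt: float = 0.1  # ns
    ligands: list[LigandScript] = field(default_factory=list)
    tube_length: float = 120.0  # A (12 nm segment)
    tube_radius: float = 3.75  # A ((6,5) tube)
    corona_offset: float = 10.0  # DNA shell stand-off from the tube surface, A
    n_waters: int = 800
    water_jitter: float = 0.25  # per-frame positional jitter SD, A
    exclusion_radius: float = 6.0  # waters displaced around a surface-bound ligand, A

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.frame_dt <= 0:
            raise ValidationError("need n_frames >= 1 and frame_dt > 0")
        total = self.n_frames * self.frame_dt
        for lig in self.ligands:
            ivs = sorted(lig.intervals)
            for (s, e, t) in ivs:
                if t not in ("SURFACE", "CORONA"):
                    raise ValidationError(f"unknown target {t!r}")
                if not (0 <= s < e <= total + 1e-9):
                    raise ValidationError(
                        f"interval ({s}, {e}) outside [0, {total}] for {lig.name}"
                    )
            for (_, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValidationError(
                        f"overlapping intervals for ligand {lig.name}"
                    )

    @property
    def total_time(self) -> float:
        return self.n_frames * self.frame_dt


_LIGAND_OFFSETS = np.array(
    # rigid 4-bead ligand: centre, two tangential, one axial (no radial spread)
    [[0.0, 0.0, 0.0], [1.2, 0.0, 0.0], [-1.2, 0.0, 0.0], [0.0, 0.0, 1.2]]
)


def _tube_carbons(radius: float, length: float) -> np.ndarray:
    ring_spacing = 2.46
    n_rings = max(2, int(round(length / ring_spacing)))
    n_per_ring = max(6, int(round(2 * np.pi * radius / 2.46)))
    zs = np.linspace(0.0, length, n_rings)
    out = []
    for k, z in enumerate(zs):
        ang = 2 * np.pi * np.arange(n_per_ring) / n_per_ring + (k % 2) * np.pi / n_per_ring
        out.append(np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.full(n_per_ring, z)]))
    return np.vstack(out)


def _dna_beads(radius: float, length: float, n_strands: int = 8) -> np.ndarray:
    beads_per_strand = max(4, int(round(length / 6.0)))
    zs = np.linspace(2.0, length - 2.0, beads_per_strand)
    out = []
    for s in range(n_strands):
        phase = 2 * np.pi * s / n_strands
        ang = phase + 2 * np.pi * zs / 60.0  # gentle helical wrap
        out.append(np.column_stack([radius * np.cos(ang), radius * np.sin(ang), zs]))
    return np.vstack(out)


def _tangential_frame(angle: float) -> np.ndarray:
    """Rotation mapping ligand-local x (tangential) and z (axial) at ``angle``."""
    tangent = np.array([-np.sin(angle), np.cos(angle), 0.0])
    axial = np.array([0.0, 0.0, 1.0])
    radial = np.array([np.cos(angle), np.sin(angle), 0.0])
    return np.column_stack([tangent, radial, axial])


def _place_ligand(centre: np.ndarray, angle: float) -> np.ndarray:
    rot = _tangential_frame(angle)
    # offsets are (tangential, radial, axial) in ligand-local coordinates
    local = _LIGAND_OFFSETS[:, [0, 1, 2]]
    return centre + local @ np.array(
        [rot[:, 0], rot[:, 1], rot[:, 2]]
    )


def gen_trajectory(
    script: TrajectoryScript, seed: int | None = None
) -> tuple[MolecularSystem, list[dict]]:
    """Build the scripted system and its ground-truth event list.

    Returns ``(system, truth)`` where each truth entry carries the ligand
    key, frame-aligned start/end times (first and last frame inside the
    scripted interval) and the mode implied by the target (SURFACE -> 1,
    CORONA -> 2). A frame at time ``t`` lies inside an interval
    ``[start, end)``.
    """
    rng = np.random.default_rng(seed)
    r_t, length = script.tube_radius, script.tube_length
    r_dna = r_t + script.corona_offset
    r_park = r_dna + 12.0
    half_w = r_park + 8.0
    box = np.array([2 * half_w, 2 * half_w, length])
    centre_xy = np.array([half_w, half_w, 0.0])

    carbons = _tube_carbons(r_t, length) + centre_xy
    dna = _dna_beads(r_dna, length) + centre_xy

    # waters in a cylindrical shell around the corona, with half of them in
    # the first hydration layer against the tube (hydration water is layered
    # and densest at the interface)
    n_w = script.n_waters
    n_surf = n_w // 2
    r_in, r_layer, r_out = r_t + 2.8, r_t + 7.0, r_dna + 6.0
    u = rng.random(n_w)
    radii_w = np.empty(n_w)
    radii_w[:n_surf] = np.sqrt(r_in**2 + u[:n_surf] * (r_layer**2 - r_in**2))
    radii_w[n_surf:] = np.sqrt(r_layer**2 + u[n_surf:] * (r_out**2 - r_layer**2))
    ang_w = 2 * np.pi * rng.random(n_w)
    z_w = 1.0 + (length - 2.0) * rng.random(n_w)
    waters0 = np.column_stack(
        [radii_w * np.cos(ang_w), radii_w * np.sin(ang_w), z_w]
    ) + centre_xy

    n_ions = 12
    r_i = r_out + 2.0 + 2.0 * rng.random(n_ions)
    ang_i = 2 * np.pi * rng.random(n_ions)
    ions = np.column_stack(
        [r_i * np.cos(ang_i), r_i * np.sin(ang_i), 2.0 + (length - 4.0) * rng.random(n_ions)]
    ) + centre_xy

    # per-ligand parking spots and per-interval binding sites
    n_lig = len(script.ligands)
    park_angles = 2 * np.pi * (np.arange(max(n_lig, 1)) + 0.5) / max(n_lig, 1)
    sites: list[list[tuple[np.ndarray, float]]] = []
    for li, lig in enumerate(script.ligands):
        lig_sites = []
        for iv_i, (s, e, target) in enumerate(sorted(lig.intervals)):
            angle = float(2 * np.pi * rng.random())
            z = float(12.0 + (length - 24.0) * rng.random())
            if target == "SURFACE":
                radius = r_t + 3.8
            else:
                radius = r_dna + 3.5
                # snap the angle/z to the nearest DNA bead so the ligand
                # genuinely sits against the corona
                cand = np.array([radius * np.cos(angle), radius * np.sin(angle), z]) + centre_xy
                j = int(np.argmin(((dna - cand) ** 2).sum(axis=1)))
                bead = dna[j] - centre_xy
                angle = float(np.arctan2(bead[1], bead[0]))
                z = float(np.clip(bead[2], 4.0, length - 4.0))
                radius = float(np.hypot(bead[0], bead[1]) + 3.5)
            centre = np.array([radius * np.cos(angle), radius * np.sin(angle), z]) + centre_xy
            lig_sites.append((centre, angle))
        sites.append(lig_sites)

    roles = (
        ["SWCNT_C"] * len(carbons)
        + ["DNA"] * len(dna)
        + ["WATER_O"] * len(waters0)
        + ["ION"] * n_ions
    )
    mol_ids = [-1] * (len(carbons) + len(dna) + len(waters0) + n_ions)
    for li, lig in enumerate(script.ligands):
        roles += [f"LIGAND:{lig.name}"] * _LIGAND_OFFSETS.shape[0]
        mol_ids += [li] * _LIGAND_OFFSETS.shape[0]
    radii = np.array(
        [DEFAULT_ROLE_RADII[r.split(":")[0] if r.startswith("LIGAND") else r] for r in roles]
    )

    times = script.frame_dt * np.arange(script.n_frames)
    n_atoms = len(roles)
    coords = np.empty((script.n_frames, n_atoms, 3))
    i_w0 = len(carbons) + len(dna)
    i_ion0 = i_w0 + len(waters0)
    i_lig0 = i_ion0 + n_ions

    truth: list[dict] = []
    # pre-compute, per frame, which interval (if any) each ligand occupies
    schedule: list[list[int | None]] = []
    for li, lig in enumerate(script.ligands):
        ivs = sorted(lig.intervals)
        per_frame: list[int | None] = []
        for t in times:
            hit = None
            for iv_i, (s, e, target) in enumerate(ivs):
                if s <= t < e:
                    hit = iv_i
                    break
            per_frame.append(hit)
        schedule.append(per_frame)
        for iv_i, (s, e, target) in enumerate(ivs):
            inside = np.flatnonzero((times >= s) & (times < e))
            if inside.size == 0:
                continue
            truth.append(
                {
                    "ligand": f"{lig.name}:{li}",
                    "start": float(times[inside[0]]),
                    "end": float(times[inside[-1]]),
                    "mode": 1 if target == "SURFACE" else 2,
                    "target": target,
                    "site": sites[li][iv_i][0].copy(),
                }
            )

    lig_jitter = 0.12
    for f in range(script.n_frames):
        coords[f, : len(carbons)] = carbons
        coords[f, len(carbons) : i_w0] = dna
        w = waters0.copy()
        # displace shell waters around surface-bound ligands
        for li, lig in enumerate(script.ligands):
            iv_i = schedule[li][f]
            if iv_i is None:
                continue
            s, e, target = sorted(lig.intervals)[iv_i]
            if target != "SURFACE":
                continue
            site = sites[li][iv_i][0]
            near = ((waters0 - site) ** 2).sum(axis=1) < script.exclusion_radius**2
            if near.any():
                rel = w[near] - centre_xy
                rad = np.linalg.norm(rel[:, :2], axis=1, keepdims=True)
                scale = (r_out + 1.5) / np.maximum(rad, 1e-9)
                rel[:, :2] *= scale
                w[near] = rel + centre_xy
        if script.water_jitter > 0:
            w = w + script.water_jitter * rng.standard_normal(w.shape)
        coords[f, i_w0:i_ion0] = w
        coords[f, i_ion0:i_lig0] = ions + 0.1 * rng.standard_normal(ions.shape)
        for li, lig in enumerate(script.ligands):
            iv_i = schedule[li][f]
            if iv_i is None:
                angle = park_angles[li]
                centre = np.array(
                    [r_park * np.cos(angle), r_park * np.sin(angle), length / 2]
                ) + centre_xy
            else:
                centre, angle = sites[li][iv_i]
            pos = _place_ligand(centre, angle)
            pos = pos + lig_jitter * rng.standard_normal(pos.shape)
            a0 = i_lig0 + li * _LIGAND_OFFSETS.shape[0]
            coords[f, a0 : a0 + _LIGAND_OFFSETS.shape[0]] = pos

    system = MolecularSystem(
        coords=coords, roles=roles, radii=radii, times=times, box=box,
        mol_ids=np.array(mol_ids),
        meta={"script_seed": seed, "tube_radius": r_t, "tube_length": length},
    )
    truth.sort(key=lambda ev: (ev["ligand"], ev["start"]))
    return system, truth
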
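"""Trajectory analysis of nanotube hydration and ligand binding.

Operators over coarse molecular systems (nanotube carbons, DNA-corona beads,
single-site waters, ions, small-molecule ligands):

- bulk contact areas between atom groups (SASA-difference definition),
- detection of ligand binding events (contiguous bound intervals longer
  than a residence threshold, 400 ns by convention),
- classification into binding mode 1 (directly on the nanotube surface)
  vs mode 2 (associated with the DNA corona),
- local surface regions of a fixed number of carbons under a bound ligand,
  and the water contact of such regions inside vs outside the event.

Distances use the minimum-image convention in orthorhombic boxes; times are
ns, coordinates and radii Angstrom, atom indexing 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .sasa import contact_area_coords

__all__ = [
    "MolecularSystem",
    "BindingEvent",
    "LocalRegion",
    "ContactSeries",
    "contact_area",
    "bulk_contact_series",
    "detect_binding_events",
    "classify_mode",
    "local_region",
    "local_water_contact",
    "bound_fraction",
]

#: Default per-role radii (A) for coarse beads; element radii for anything else.
DEFAULT_ROLE_RADII = {
    "SWCNT_C": 1.70,
    "DNA": 2.00,
    "WATER_O": 1.52,
    "ION": 1.90,
    "LIGAND": 1.70,
}

#: Built-in element -> van der Waals radius table (A) for atomistic input.
ELEMENT_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80, "NA": 2.27, "CL": 1.75}


@dataclass
class MolecularSystem:
    """A multi-frame coarse molecular system with per-atom roles.

    ``roles`` entries are ``SWCNT_C``, ``DNA``, ``WATER_O``, ``ION`` or
    ``LIGAND:<name>``; ``mol_ids`` distinguishes molecules sharing a role
    (ligand copies), -1 for atoms where the distinction is irrelevant.
    """

    coords: np.ndarray  # (n_frames, n_atoms, 3) A
    roles: list[str]
    radii: np.ndarray  # (n_atoms,) A
    times: np.ndarray  # (n_frames,) ns
    box: np.ndarray | None = None  # (3,) A orthorhombic, or None
    mol_ids: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must be (n_frames, n_atoms, 3)")
        n_atoms = self.coords.shape[1]
        if len(self.roles) != n_atoms:
            raise ValidationError("roles must cover all atoms")
        if self.radii.shape != (n_atoms,) or np.any(self.radii <= 0):
            raise ValidationError("radii must be positive, one per atom")
        if self.times.shape != (self.coords.shape[0],) or (
            self.times.size > 1 and not np.all(np.diff(self.times) > 0)
        ):
            raise ValidationError("frame times must be strictly increasing")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
        if self.mol_ids is None:
            self.mol_ids = np.full(n_atoms, -1, dtype=int)
        else:
            self.mol_ids = np.asarray(self.mol_ids, dtype=int)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def frame_dt(self) -> float:
        if self.times.size < 2:
            raise ValidationError("need >= 2 frames for a frame spacing")
        return float(self.times[1] - self.times[0])

    def indices(self, role_prefix: str) -> np.ndarray:
        """Atom indices whose role equals or starts with ``role_prefix``."""
        return np.array(
            [
                i
                for i, r in enumerate(self.roles)
                if r == role_prefix or r.startswith(role_prefix + ":")
            ],
            dtype=int,
        )

    def ligand_keys(self) -> list[str]:
        """Sorted '<name>:<mol_id>' keys for every ligand molecule present."""
        keys = {
            f"{self.roles[i].split(':', 1)[1]}:{self.mol_ids[i]}"
            for i in self.indices("LIGAND")
        }
        return sorted(keys, key=lambda k: (k.rsplit(":", 1)[0], int(k.rsplit(":", 1)[1])))

    def ligand_atoms(self, key: str) -> np.ndarray:
        name, mol = key.rsplit(":", 1)
        role = f"LIGAND:{name}"
        mol = int(mol)
        idx = [i for i, r in enumerate(self.roles) if r == role and self.mol_ids[i] == mol]
        if not idx:
            raise ValidationError(f"no atoms for ligand {key!r}")
        return np.asarray(idx, dtype=int)


@dataclass
class BindingEvent:
    """One ligand's contiguous bound interval."""

    ligand: str
    start: float  # ns, time of first bound frame
    end: float  # ns, time of last bound frame
    mode: int | None = None  # 1 surface, 2 corona; None until classified
    frames: np.ndarray | None = None  # frame indices inside the event
    contact_carbons: frozenset[int] = frozenset()
    mean_contact_area: float | None = None

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class LocalRegion:
    """A fixed-size set of nanotube carbons beneath a bound ligand."""

    carbons: np.ndarray
    event: BindingEvent

    def __post_init__(self) -> None:
        self.carbons = np.asarray(self.carbons, dtype=int)


@dataclass
class ContactSeries:
    """A per-frame contact-area time series for one group pair."""

    times: np.ndarray
    areas: np.ndarray
    pair: str
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if not self.normalized and np.any(self.areas < -1e-9):
            raise ValidationError("contact areas must be >= 0")

    @property
    def mean(self) -> float:
        return float(self.areas.mean())

    @property
    def sem(self) -> float:
        n = self.areas.size
        return float(self.areas.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _min_dist(
    a: np.ndarray, b: np.ndarray, box: np.ndarray | None
) -> float:
    """Minimum pairwise distance between coordinate sets (minimum image)."""
    disp = a[:, None, :] - b[None, :, :]
    if box is not None:
        disp = disp - box * np.round(disp / box)
    return float(np.sqrt((disp**2).sum(axis=2)).min())


def _within(
    a: np.ndarray, b: np.ndarray, cutoff: float, box: np.ndarray | None
) -> np.ndarray:
    """Boolean mask over rows of ``b`` within ``cutoff`` of any row of ``a``."""
    disp = b[:, None, :] - a[None, :, :]
    if box is not None:
        disp = disp - box * np.round(disp / box)
    d2 = (disp**2).sum(axis=2)
    return (d2 <= cutoff * cutoff).any(axis=1)


# ---------------------------------------------------------------------------
# contact areas
# ---------------------------------------------------------------------------

def contact_area(
    system: MolecularSystem,
    frame: int,
    group_a: np.ndarray,
    group_b: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> float:
    """SASA-difference contact area (A^2) between two groups at one frame."""
    return contact_area_coords(
        system.coords[frame], system.radii,
        np.asarray(group_a, dtype=int), np.asarray(group_b, dtype=int),
        probe_radius=probe_radius, n_points=n_points, box=system.box,
    )


def bulk_contact_series(
    system: MolecularSystem,
    pairs: list[tuple[str, str]],
    probe_radius: float = 1.4,
    n_points: int = 960,
    stride: int = 1,
) -> dict[str, ContactSeries]:
    """Per-frame contact areas for each named role pair, over the trajectory.

    Pair entries are role selectors (``SWCNT_C``, ``WATER_O``, ``ION``,
    ``DNA``, ``LIGAND`` or ``LIGAND:<name>``). Returns one
    :class:`ContactSeries` per pair keyed ``"roleA-roleB"``; means and SEMs
    over frames hang off the series.
    """
    if system.n_frames < 1:
        raise ValidationError("need at least one frame")
    out: dict[str, ContactSeries] = {}
    frames = range(0, system.n_frames, stride)
    times = system.times[::stride]
    for ra, rb in pairs:
        ia, ib = system.indices(ra), system.indices(rb)
        if ia.size == 0 or ib.size == 0:
            raise ValidationError(f"empty group in pair ({ra}, {rb})")
        areas = np.array(
            [
                contact_area(system, f, ia, ib, probe_radius, n_points)
                for f in frames
            ]
        )
        out[f"{ra}-{rb}"] = ContactSeries(times=times, areas=areas, pair=f"{ra}-{rb}")
    return out


# ---------------------------------------------------------------------------
# binding events
# ---------------------------------------------------------------------------

def _bound_flags(
    system: MolecularSystem,
    ligand_idx: np.ndarray,
    target_idx: np.ndarray,
    cutoff: float,
) -> np.ndarray:
    flags = np.empty(system.n_frames, dtype=bool)
    for f in range(system.n_frames):
        flags[f] = (
            _min_dist(
                system.coords[f, ligand_idx], system.coords[f, target_idx], system.box
            )
            <= cutoff
        )
    return flags


def detect_binding_events(
    system: MolecularSystem,
    ligand: str,
    contact_cutoff: float = 5.0,
    min_duration: float = 400.0,
    gap_tolerance: float | None = None,
) -> list[BindingEvent]:
    """Contiguous bound intervals of one ligand longer than ``min_duration``.

    A frame is bound when any ligand heavy atom lies within
    ``contact_cutoff`` (A) of any nanotube carbon or DNA atom. Bound runs
    separated by unbound gaps of at most ``gap_tolerance`` ns (default: two
    frame spacings) are bridged; runs whose last-minus-first bound time is
    below ``min_duration`` ns are dropped. Event boundaries are the times of
    the first and last bound frame.
    """
    lig_idx = system.ligand_atoms(ligand)
    targets = np.concatenate([system.indices("SWCNT_C"), system.indices("DNA")])
    if targets.size == 0:
        raise ValidationError("system has no SWCNT_C or DNA atoms")
    dt = system.frame_dt
    if gap_tolerance is None:
        gap_tolerance = 2 * dt
    if min_duration <= dt:
        warnings.warn(
            "min_duration <= frame spacing: every bound frame becomes an event"
        )
    flags = _bound_flags(system, lig_idx, targets, contact_cutoff)
    bound_frames = np.flatnonzero(flags)
    if bound_frames.size == 0:
        return []
    # split into runs, bridging gaps <= gap_tolerance
    gaps = np.diff(system.times[bound_frames])
    breaks = np.flatnonzero(gaps > gap_tolerance + 1e-12)
    runs = np.split(bound_frames, breaks + 1)
    events = []
    for run in runs:
        start, end = system.times[run[0]], system.times[run[-1]]
        if end - start < min_duration:
            continue
        full = np.arange(run[0], run[-1] + 1)
        carbons = _event_contact_carbons(system, lig_idx, run, contact_cutoff)
        events.append(
            BindingEvent(
                ligand=ligand, start=float(start), end=float(end),
                frames=full, contact_carbons=carbons,
            )
        )
    return events


def _event_contact_carbons(
    system: MolecularSystem,
    lig_idx: np.ndarray,
    frames: np.ndarray,
    cutoff: float,
) -> frozenset[int]:
    carbons = system.indices("SWCNT_C")
    touched: set[int] = set()
    for f in frames:
        mask = _within(
            system.coords[f, lig_idx], system.coords[f, carbons], cutoff, system.box
        )
        touched.update(carbons[mask].tolist())
    return frozenset(touched)


def classify_mode(
    event: BindingEvent,
    system: MolecularSystem,
    surface_cutoff: float = 5.0,
    frame_fraction: float = 0.5,
) -> int:
    """Binding mode: 1 = directly on the nanotube surface, 2 = DNA corona.

    Mode 1 requires at least one ligand heavy atom within ``surface_cutoff``
    of a nanotube carbon in at least ``frame_fraction`` of the event frames.
    The event's ``mode`` field is set and the mode returned.
    """
    if event.frames is None or len(event.frames) == 0:
        raise ValidationError("event has no frames")
    lig_idx = system.ligand_atoms(event.ligand)
    carbons = system.indices("SWCNT_C")
    hits = 0
    for f in event.frames:
        if (
            _min_dist(system.coords[f, lig_idx], system.coords[f, carbons], system.box)
            <= surface_cutoff
        ):
            hits += 1
    frac = hits / len(event.frames)
    event.mode = 1 if frac >= frame_fraction else 2
    return event.mode


def local_region(event: BindingEvent, system: MolecularSystem, n_carbons: int = 60) -> LocalRegion:
    """The ``n_carbons`` nanotube carbons nearest (time-averaged) the ligand.

    Distance is from each carbon to the ligand's geometric centre, averaged
    over the event frames with minimum-image displacements; ties break by
    atom index.
    """
    carbons = system.indices("SWCNT_C")
    if not (0 < n_carbons <= carbons.size):
        raise ValidationError(
            f"n_carbons must be in (0, {carbons.size}], got {n_carbons}"
        )
    if event.frames is None or len(event.frames) == 0:
        raise ValidationError("event has no frames")
    lig_idx = system.ligand_atoms(event.ligand)
    dists = np.zeros(carbons.size)
    for f in event.frames:
        centre = system.coords[f, lig_idx].mean(axis=0)
        disp = system.coords[f, carbons] - centre
        if system.box is not None:
            disp = disp - system.box * np.round(disp / system.box)
        dists += np.sqrt((disp**2).sum(axis=1))
    dists /= len(event.frames)
    order = np.lexsort((carbons, dists))  # stable: distance, then atom index
    return LocalRegion(carbons=np.sort(carbons[order[:n_carbons]]), event=event)


def local_water_contact(
    region: LocalRegion,
    system: MolecularSystem,
    event: BindingEvent | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
    stride: int = 1,
) -> dict:
    """Water contact of a local surface region, inside vs outside its event.

    Computes the per-frame contact area between the region's carbons and all
    water oxygens, normalizes the series by its maximum (so regions of
    different size are comparable), and reports separate means for frames
    inside the owning event (ligand bound to the region) and outside it.
    """
    event = event or region.event
    waters = system.indices("WATER_O")
    if waters.size == 0:
        raise ValidationError("system has no WATER_O atoms")
    frames = np.arange(0, system.n_frames, stride)
    areas = np.array(
        [
            contact_area(system, f, region.carbons, waters, probe_radius, n_points)
            for f in frames
        ]
    )
    peak = areas.max()
    if peak <= 0:
        raise ValidationError("all-zero water contact series; cannot normalize")
    normed = areas / peak
    times = system.times[frames]
    inside = (times >= event.start) & (times <= event.end)
    if not inside.any() or inside.all():
        raise ValidationError("trajectory must cover bound and unbound frames")
    return {
        "series": ContactSeries(
            times=times, areas=normed, pair="region-water", normalized=True
        ),
        "bound_mean": float(normed[inside].mean()),
        "unbound_mean": float(normed[~inside].mean()),
        "bound_sem": float(normed[inside].std(ddof=1) / np.sqrt(inside.sum()))
        if inside.sum() > 1 else 0.0,
        "unbound_sem": float(normed[~inside].std(ddof=1) / np.sqrt((~inside).sum()))
        if (~inside).sum() > 1 else 0.0,
        "max_area": float(peak),
    }


def bound_fraction(
    system: MolecularSystem,
    surface_cutoff: float = 5.0,
    frame_fraction: float = 0.5,
) -> dict:
    """Per-ligand direct-surface tally and counts of directly bound ligands.

    A ligand counts as directly bound (mode-1 criterion over the whole
    analysis window) if it has an atom within ``surface_cutoff`` of a
    nanotube carbon in at least ``frame_fraction`` of all frames. Returns
    ``{'per_ligand': {key: fraction}, 'directly_bound': {analyte: count},
    'n_ligands': {analyte: count}}``.
    """
    carbons = system.indices("SWCNT_C")
    per_ligand: dict[str, float] = {}
    counts: dict[str, int] = {}
    totals: dict[str, int] = {}
    for key in system.ligand_keys():
        name = key.rsplit(":", 1)[0]
        totals[name] = totals.get(name, 0) + 1
        lig_idx = system.ligand_atoms(key)
        flags = _bound_flags(system, lig_idx, carbons, surface_cutoff)
        frac = float(flags.mean())
        per_ligand[key] = frac
        if frac >= frame_fraction:
            counts[name] = counts.get(name, 0) + 1
        else:
            counts.setdefault(name, counts.get(name, 0))
    return {"per_ligand": per_ligand, "directly_bound": counts, "n_ligands": totals}
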
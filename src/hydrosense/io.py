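"""File formats: two-column spectra, ITC tables, topology + trajectory.

Spectra travel as two-column CSV with ``# key: value`` provenance headers;
molecular systems as a PDB topology plus multi-frame XYZ (both written and
read through MDAnalysis) with a JSON sidecar carrying the exact roles,
radii, molecule ids, frame times and box.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .fluorescence import EmissionSpectrum
from .hydration import BindingEvent, MolecularSystem
from .itc import ItcExperiment
from .spectra import DifferenceSpectrum, Spectrum

__all__ = [
    "write_spectrum_csv", "read_spectrum_csv",
    "write_emission_csv", "read_emission_csv",
    "write_itc_csv", "read_itc_csv",
    "write_system", "read_system",
    "write_events_csv",
]


def _write_csv(path, df: pd.DataFrame, header: dict) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def _read_csv(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    header: dict[str, str] = {}
    with path.open() as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    header[k.strip()] = v.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh)
    return df, header


def write_spectrum_csv(path, spec: Spectrum | DifferenceSpectrum) -> None:
    if isinstance(spec, DifferenceSpectrum):
        df = pd.DataFrame(
            {"wavenumber_cm-1": spec.grid, "delta_alpha_cm-1": spec.delta_alpha,
             "sem_cm-1": spec.sem}
        )
        header = {"kind": "difference", "condition": spec.condition,
                  "n_replicates": spec.n_replicates, **spec.meta}
    else:
        col = "intensity" if spec.kind == "transmission" else "alpha_cm-1"
        df = pd.DataFrame({"wavenumber_cm-1": spec.grid, col: spec.values})
        header = {"kind": spec.kind, **spec.meta}
    _write_csv(path, df, header)


def read_spectrum_csv(path) -> Spectrum | DifferenceSpectrum:
    df, header = _read_csv(path)
    kind = header.pop("kind", "transmission")
    if kind == "difference":
        return DifferenceSpectrum(
            grid=df["wavenumber_cm-1"].to_numpy(),
            delta_alpha=df["delta_alpha_cm-1"].to_numpy(),
            sem=df["sem_cm-1"].to_numpy() if "sem_cm-1" in df else None,
            n_replicates=int(header.pop("n_replicates", 1)),
            condition=header.pop("condition", ""),
            meta=header,
        )
    value_col = [c for c in df.columns if c != "wavenumber_cm-1"][0]
    return Spectrum(
        grid=df["wavenumber_cm-1"].to_numpy(), values=df[value_col].to_numpy(),
        kind=kind, meta=header,
    )


def write_emission_csv(path, spec: EmissionSpectrum) -> None:
    df = pd.DataFrame({"wavelength_nm": spec.grid, "counts": spec.counts})
    _write_csv(path, df, {
        "condition": spec.condition, "analyte": spec.analyte,
        "sequence": spec.sequence, "replicate": spec.replicate, **spec.meta,
    })


def read_emission_csv(path) -> EmissionSpectrum:
    df, header = _read_csv(path)
    return EmissionSpectrum(
        grid=df["wavelength_nm"].to_numpy(), counts=df["counts"].to_numpy(),
        condition=header.pop("condition", ""), analyte=header.pop("analyte", ""),
        sequence=header.pop("sequence", ""),
        replicate=int(header.pop("replicate", 0)), meta=header,
    )


def write_itc_csv(path, exp: ItcExperiment) -> None:
    if exp.heats is None:
        raise ValidationError("experiment carries no heats to write")
    df = pd.DataFrame({
        "injection_index": np.arange(exp.n_injections),
        "volume_uL": exp.injection_volumes,
        "heat_ucal": exp.heats,
    })
    _write_csv(path, df, {
        "syringe_conc_M": exp.syringe_conc, "cell_conc_M": exp.cell_conc,
        "cell_volume_mL": exp.cell_volume, "temperature_K": exp.temperature,
    })


def read_itc_csv(path) -> ItcExperiment:
    df, header = _read_csv(path)
    return ItcExperiment(
        injection_volumes=df["volume_uL"].to_numpy(),
        heats=df["heat_ucal"].to_numpy(),
        syringe_conc=float(header["syringe_conc_M"]),
        cell_conc=float(header["cell_conc_M"]),
        cell_volume=float(header["cell_volume_mL"]),
        temperature=float(header.get("temperature_K", 297.15)),
    )


# ---------------------------------------------------------------------------
# molecular systems: PDB topology + multi-frame XYZ + JSON sidecar
# ---------------------------------------------------------------------------

_ROLE_NAMES = {"SWCNT_C": "C", "DNA": "P", "WATER_O": "O", "ION": "NA"}


def write_system(system: MolecularSystem, prefix) -> dict[str, Path]:
    """Write ``<prefix>.pdb``, ``<prefix>.xyz`` and ``<prefix>.json``."""
    import MDAnalysis as mda

    prefix = Path(prefix)
    n = system.n_atoms
    u = mda.Universe.empty(n, trajectory=True)
    names = [
        _ROLE_NAMES.get(r, "L") if not r.startswith("LIGAND") else "L"
        for r in system.roles
    ]
    u.add_TopologyAttr("names", names)
    u.atoms.positions = system.coords[0]
    if system.box is not None:
        u.dimensions = [*system.box, 90.0, 90.0, 90.0]
    pdb = prefix.with_suffix(".pdb")
    xyz = prefix.with_suffix(".xyz")
    with mda.Writer(str(pdb)) as w:
        w.write(u.atoms)
    with mda.Writer(str(xyz), n) as w:
        for f in range(system.n_frames):
            u.atoms.positions = system.coords[f]
            w.write(u.atoms)
    sidecar = prefix.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "roles": system.roles,
        "radii": system.radii.tolist(),
        "mol_ids": system.mol_ids.tolist(),
        "times_ns": system.times.tolist(),
        "box": system.box.tolist() if system.box is not None else None,
        "meta": {k: v for k, v in system.meta.items()
                 if isinstance(v, (str, int, float, bool, type(None)))},
    }))
    return {"pdb": pdb, "xyz": xyz, "json": sidecar}


def read_system(prefix) -> MolecularSystem:
    """Read a system written by :func:`write_system`."""
    import MDAnalysis as mda

    prefix = Path(prefix)
    side = json.loads(prefix.with_suffix(".json").read_text())
    u = mda.Universe(str(prefix.with_suffix(".pdb")), str(prefix.with_suffix(".xyz")))
    coords = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    return MolecularSystem(
        coords=coords,
        roles=list(side["roles"]),
        radii=np.asarray(side["radii"], dtype=float),
        times=np.asarray(side["times_ns"], dtype=float),
        box=np.asarray(side["box"], dtype=float) if side["box"] is not None else None,
        mol_ids=np.asarray(side["mol_ids"], dtype=int),
        meta=side.get("meta", {}),
    )


def write_events_csv(path, events: list[BindingEvent]) -> None:
    df = pd.DataFrame([
        {
            "ligand": ev.ligand, "start_ns": ev.start, "end_ns": ev.end,
            "mode": ev.mode if ev.mode is not None else "",
            "n_contact_carbons": len(ev.contact_carbons),
        }
        for ev in events
    ])
    df.to_csv(path, index=False)
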
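"""File formats: the canonical DVH CSV dialect and the cohort grid container.

DVH exchange format::

    # structure: <name>
    # total_volume_cc: <float>
    # dose_unit: Gy
    dose,volume_fraction
    0,1
    ...

Numbers are written with 6 significant digits, which round-trips
bit-stably (write -> read -> write is byte-identical).

The grid container is one directory per patient holding an NPZ file with
the dose arrays and masks plus a JSON manifest (prescription, lattice,
achieved lung fraction).  It exists so pipeline stages can be run as
separate commands; nothing in the analysis depends on any clinical format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dvh import CumulativeDVH, DoseGrid, StructureMask
from .errors import DVHParseError
from .synthetic import PatientSim

__all__ = [
    "write_dvh_file",
    "read_dvh_file",
    "PatientData",
    "save_cohort",
    "load_cohort",
]

_FMT = "%.6g"


def write_dvh_file(dvh: CumulativeDVH, path: str | Path) -> None:
    """Write a DVH in the canonical CSV dialect."""
    lines = [
        f"# structure: {dvh.structure_name}",
        f"# total_volume_cc: {_FMT % dvh.total_volume_cc}",
        "# dose_unit: Gy",
        "dose,volume_fraction",
    ]
    for d, f in zip(dvh.dose_edges, dvh.volume_fraction):
        lines.append(f"{_FMT % d},{_FMT % f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_dvh_file(path: str | Path) -> CumulativeDVH:
    """Read the canonical DVH dialect, validating every invariant.

    Violations raise :class:`DVHParseError` carrying the offending line
    number.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    header: dict[str, str] = {}
    i = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        key, _, value = line.lstrip("# ").partition(":")
        header[key.strip()] = value.strip()
    for required in ("structure", "total_volume_cc", "dose_unit"):
        if required not in header:
            raise DVHParseError(f"missing header '{required}'", line=i)
    if header["dose_unit"] != "Gy":
        raise DVHParseError(f"unsupported dose unit {header['dose_unit']!r}", line=i)
    if i >= len(lines) or lines[i].strip() != "dose,volume_fraction":
        raise DVHParseError("expected column header 'dose,volume_fraction'", line=i + 1)
    try:
        total_volume = float(header["total_volume_cc"])
    except ValueError as exc:
        raise DVHParseError(f"bad total_volume_cc: {exc}") from exc

    doses: list[float] = []
    fracs: list[float] = []
    for lineno, line in enumerate(lines[i + 1 :], start=i + 2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise DVHParseError("expected 'dose,volume_fraction'", line=lineno)
        try:
            d, f = float(parts[0]), float(parts[1])
        except ValueError:
            raise DVHParseError(f"non-numeric row {line!r}", line=lineno) from None
        if doses and d <= doses[-1]:
            raise DVHParseError("non-ascending dose axis", line=lineno)
        if fracs and f > fracs[-1] + 1e-12:
            raise DVHParseError("non-monotone DVH", line=lineno)
        doses.append(d)
        fracs.append(f)
    if not doses:
        raise DVHParseError("no data rows", line=i + 1)
    try:
        return CumulativeDVH(
            dose_edges=np.array(doses),
            volume_fraction=np.array(fracs),
            total_volume_cc=total_volume,
            structure_name=header["structure"],
        )
    except ValueError as exc:
        raise DVHParseError(str(exc)) from exc


ARMS = ("aaa", "axb_dm", "axb_dw")


@dataclass(frozen=True)
class PatientData:
    """The analysis-facing view of one patient: lattice-aligned masks and
    one dose grid per arm."""

    patient_id: str
    prescription_gy: float
    ptv_mask: StructureMask
    lung_mask: StructureMask
    doses: dict[str, DoseGrid]
    meta: dict

    @classmethod
    def from_sim(cls, sim: PatientSim) -> "PatientData":
        return cls(
            patient_id=sim.patient_id,
            prescription_gy=sim.prescription_gy,
            ptv_mask=sim.phantom.ptv_mask,
            lung_mask=sim.phantom.lung_mask,
            doses={
                "aaa": sim.dose_aaa,
                "axb_dm": sim.dose_dm,
                "axb_dw": sim.dose_dw,
            },
            meta={
                "achieved_lung_fraction": sim.phantom.achieved_lung_fraction,
                "ptv_volume_cc": sim.phantom.ptv_mask.voxel_count
                * sim.dose_aaa.voxel_volume_cc,
            },
        )


def save_cohort(patients: list[PatientData], out_dir: str | Path) -> None:
    """Write one subdirectory per patient: ``grids.npz`` plus ``manifest.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for p in patients:
        pdir = out_dir / p.patient_id
        pdir.mkdir(exist_ok=True)
        arrays = {f"dose_{arm}": p.doses[arm].values for arm in ARMS if arm in p.doses}
        np.savez(
            pdir / "grids.npz",
            ptv_mask=p.ptv_mask.values,
            lung_mask=p.lung_mask.values,
            spacing=np.asarray(p.doses["aaa"].spacing),
            origin=np.asarray(p.doses["aaa"].origin),
            **arrays,
        )
        manifest = {
            "patient_id": p.patient_id,
            "prescription_gy": p.prescription_gy,
            "arms": sorted(p.doses),
            **p.meta,
        }
        (pdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def load_cohort(in_dir: str | Path) -> list[PatientData]:
    """Load a cohort written by :func:`save_cohort`, sorted by patient id."""
    in_dir = Path(in_dir)
    patients = []
    for pdir in sorted(d for d in in_dir.iterdir() if d.is_dir()):
        manifest = json.loads((pdir / "manifest.json").read_text())
        with np.load(pdir / "grids.npz") as data:
            spacing = tuple(data["spacing"])
            origin = tuple(data["origin"])
            doses = {
                arm: DoseGrid(values=data[f"dose_{arm}"], spacing=spacing, origin=origin)
                for arm in manifest["arms"]
            }
            ptv = StructureMask(name="PTV", values=data["ptv_mask"])
            lung = StructureMask(name="Lung", values=data["lung_mask"])
        meta = {
            k: v
            for k, v in manifest.items()
            if k not in ("patient_id", "prescription_gy", "arms")
        }
        patients.append(
            PatientData(
                patient_id=manifest["patient_id"],
                prescription_gy=manifest["prescription_gy"],
                ptv_mask=ptv,
                lung_mask=lung,
                doses=doses,
                meta=meta,
            )
        )
    if not patients:
        raise FileNotFoundError(f"no patient directories under {in_dir}")
    return patients
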
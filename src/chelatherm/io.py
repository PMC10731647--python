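"""File formats: chemical-model JSON documents and stage CSV tables.

Chemical-model document (versioned)::

    {
      "version": 1,
      "pKa": [2.40, 3.13, 6.80, 7.73],
      "species": [{"m": 1, "l": 1, "log_beta": 13.0, "label": "ML"}],
      "conditions": {"metal_total": 5e-5, "ligand_total": 0.0, "pH": 3.5}
    }

CSV tables: NMR titrations use columns (signal_id, pD, shift_ppm);
thermograms use (injection_index, volume_uL, heat_uJ) or heat_ucal; TRLFS
cubes are a directory of per-sample matrices (rows = wavelength nm,
columns = delay us) plus a JSON manifest with totals, pH and the absolute
delay schedule.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .itc import MICROCAL_TO_MICROJOULE, InjectionSchedule, Thermogram
from .nmr import NMRTitrationSeries
from .speciation import ComplexSpecies, EquilibriumConditions, ProtolysisScheme
from .trlfs import TRLFSCube

MODEL_VERSION = 1


class ModelDocumentError(ValueError):
    pass


def load_chemical_model(path) -> dict:
    """Parse and validate a chemical-model JSON document."""
    doc = json.loads(Path(path).read_text())
    if doc.get("version", MODEL_VERSION) != MODEL_VERSION:
        raise ModelDocumentError(f"unsupported model version {doc.get('version')}")
    out: dict = {"scheme": ProtolysisScheme(doc.get("pKa", []))}
    out["species"] = tuple(
        ComplexSpecies(
            m=int(sp["m"]), l=int(sp["l"]),
            log_beta=float(sp["log_beta"]), label=sp.get("label", ""),
        )
        for sp in doc.get("species", [])
    )
    cond = doc.get("conditions")
    out["conditions"] = (
        EquilibriumConditions(
            metal_total=float(cond["metal_total"]),
            ligand_total=float(cond["ligand_total"]),
            pH=float(cond["pH"]),
            temperature=float(cond.get("temperature", 25.0)),
            ionic_strength=float(cond.get("ionic_strength", 0.1)),
        )
        if cond
        else None
    )
    return out


def dump_chemical_model(
    scheme: ProtolysisScheme,
    species: Sequence[ComplexSpecies] = (),
    conditions: EquilibriumConditions | None = None,
) -> dict:
    doc = {
        "version": MODEL_VERSION,
        "pKa": list(scheme.stepwise_pKa),
        "species": [
            {"m": sp.m, "l": sp.l, "log_beta": sp.log_beta, "label": sp.label}
            for sp in species
        ],
    }
    if conditions is not None:
        doc["conditions"] = {
            "metal_total": conditions.metal_total,
            "ligand_total": conditions.ligand_total,
            "pH": conditions.pH,
            "temperature": conditions.temperature,
            "ionic_strength": conditions.ionic_strength,
        }
    return doc


def read_nmr_csv(path) -> list[NMRTitrationSeries]:
    """Read (signal_id, pD, shift_ppm) rows into per-probe series."""
    df = pd.read_csv(path)
    required = {"signal_id", "pD", "shift_ppm"}
    if not required.issubset(df.columns):
        raise ValueError(f"NMR CSV must have columns {sorted(required)}")
    bad = df[~np.isfinite(df["shift_ppm"]) | ~np.isfinite(df["pD"])]
    if len(bad):
        raise ValueError(f"non-finite values at rows {bad.index.tolist()}")
    out = []
    for signal_id, grp in df.groupby("signal_id", sort=True):
        out.append(
            NMRTitrationSeries(
                signal_id=str(signal_id),
                pD=grp["pD"].to_numpy(),
                shift_ppm=grp["shift_ppm"].to_numpy(),
            )
        )
    return out


def write_nmr_csv(path, series: Sequence[NMRTitrationSeries]) -> None:
    frames = [
        pd.DataFrame(
            {"signal_id": s.signal_id, "pD": s.pD, "shift_ppm": s.shift_ppm}
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_thermogram_csv(path, pH: float, units: str = "uJ",
                        is_blank: bool = False) -> tuple[Thermogram, np.ndarray]:
    """Read a thermogram CSV; returns (thermogram, injection volumes in liters)."""
    df = pd.read_csv(path).sort_values("injection_index")
    heat_col = "heat_uJ" if units == "uJ" else "heat_ucal"
    if heat_col not in df.columns:
        raise ValueError(f"thermogram CSV missing column {heat_col!r}")
    heats = df[heat_col].to_numpy(float)
    if units == "ucal":
        heats = heats * MICROCAL_TO_MICROJOULE
    volumes = df["volume_uL"].to_numpy(float) * 1e-6
    return Thermogram(heats=heats, pH=pH, label=str(path), is_blank=is_blank), volumes


def write_thermogram_csv(path, thermogram: Thermogram,
                         schedule: InjectionSchedule) -> None:
    pd.DataFrame(
        {
            "injection_index": np.arange(1, schedule.n_injections + 1),
            "volume_uL": np.asarray(schedule.injection_volumes) * 1e6,
            "heat_uJ": thermogram.heats,
        }
    ).to_csv(path, index=False)


def write_trlfs_cube(directory, cube: TRLFSCube) -> None:
    """Per-sample CSV matrices plus a manifest with the absolute delays."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": MODEL_VERSION,
        "excitation_nm": cube.excitation,
        "delays_us": (cube.delays_ms * 1000.0).tolist(),
        "samples": [],
    }
    for i, cond in enumerate(cube.conditions):
        fname = f"sample_{i:03d}.csv"
        df = pd.DataFrame(
            cube.intensities[i],
            index=pd.Index(cube.wavelengths, name="wavelength_nm"),
            columns=[f"{d * 1000.0:.6g}" for d in cube.delays_ms],
        )
        df.to_csv(directory / fname)
        manifest["samples"].append(
            {
                "file": fname,
                "metal_total": cond.metal_total,
                "ligand_total": cond.ligand_total,
                "pH": cond.pH,
            }
        )
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_trlfs_cube(directory) -> TRLFSCube:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    delays_ms = np.asarray(manifest["delays_us"], float) / 1000.0
    conditions, slabs = [], []
    wavelengths = None
    for entry in manifest["samples"]:
        df = pd.read_csv(directory / entry["file"], index_col=0)
        if wavelengths is None:
            wavelengths = df.index.to_numpy(float)
        slabs.append(df.to_numpy(float))
        conditions.append(
            EquilibriumConditions(
                metal_total=float(entry["metal_total"]),
                ligand_total=float(entry["ligand_total"]),
                pH=float(entry["pH"]),
            )
        )
    return TRLFSCube(
        conditions=tuple(conditions),
        wavelengths=wavelengths,
        delays_ms=delays_ms,
        intensities=np.stack(slabs),
        excitation=float(manifest.get("excitation_nm", 394.0)),
    )
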
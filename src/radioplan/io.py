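"""On-disk formats: volumetric containers, DVH tables, config, manifests.

Disk conventions: dose is cGy everywhere and volume is cc; percent axes are
accepted only in the Eclipse-style text dialect, with a prescription (for
% dose) or total volume (for % volume) header to convert. Readers reject
malformed input rather than coercing it, naming the file and offending
line.
"""

from __future__ import annotations

import hashlib
import json
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dvh import CumulativeDVH, DifferentialDVH
from .grids import DoseGrid, StructureMask

__all__ = [
    "write_volumetric",
    "read_volumetric",
    "write_dvh_csv",
    "read_dvh_table",
    "write_eclipse_text",
    "load_run_config",
    "file_sha256",
]


# ---------------------------------------------------------------------------
# volumetric container (one file per patient-condition: dose + masks + spacing)


def write_volumetric(path, grid: DoseGrid, masks: dict[str, StructureMask]) -> None:
    """Write dose grid plus congruent masks to a single self-describing file."""
    for mask in masks.values():
        mask.check_congruent(grid)
    arrays = {
        "dose_cgy": grid.values,
        "spacing_mm": np.asarray(grid.spacing),
        "origin_mm": np.asarray(grid.origin),
    }
    for name, mask in masks.items():
        arrays[f"mask/{name}"] = mask.voxels
    np.savez_compressed(path, **arrays)


def read_volumetric(path) -> tuple[DoseGrid, dict[str, StructureMask]]:
    """Inverse of :func:`write_volumetric`; write-read round trips are lossless."""
    path = Path(path)
    try:
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
    except (zipfile.BadZipFile, OSError, ValueError, EOFError) as exc:
        raise IOError(f"{path}: not a readable volumetric container ({exc})") from exc
    for required in ("dose_cgy", "spacing_mm"):
        if required not in arrays:
            raise IOError(f"{path}: missing required array {required!r}")
    spacing = tuple(arrays["spacing_mm"].tolist())
    origin = tuple(arrays.get("origin_mm", np.zeros(3)).tolist())
    grid = DoseGrid(arrays["dose_cgy"], spacing, origin)
    masks = {}
    for key, arr in arrays.items():
        if key.startswith("mask/"):
            name = key[len("mask/"):]
            if arr.shape != grid.values.shape:
                raise IOError(
                    f"{path}: mask {name!r} shape {arr.shape} does not match "
                    f"dose shape {grid.values.shape}"
                )
            masks[name] = StructureMask(name, arr, spacing)
    return grid, masks


# ---------------------------------------------------------------------------
# DVH tables — CSV dialect


def write_dvh_csv(path, dvhs: list[DifferentialDVH]) -> None:
    rows = []
    for dvh in dvhs:
        for lo, hi, vol in zip(dvh.bin_edges[:-1], dvh.bin_edges[1:], dvh.bin_volume):
            rows.append(
                {"structure": dvh.structure, "bin_lo_cGy": lo, "bin_hi_cGy": hi, "volume_cc": vol}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def _read_dvh_csv(path) -> dict[str, DifferentialDVH]:
    frame = pd.read_csv(path)
    required = {"structure", "bin_lo_cGy", "bin_hi_cGy", "volume_cc"}
    missing = required - set(frame.columns)
    if missing:
        raise IOError(f"{path}: missing columns {sorted(missing)}")
    out = {}
    for structure, sub in frame.groupby("structure", sort=False):
        sub = sub.sort_values("bin_lo_cGy")
        lo = sub["bin_lo_cGy"].to_numpy(float)
        hi = sub["bin_hi_cGy"].to_numpy(float)
        if not np.allclose(lo[1:], hi[:-1]):
            bad = int(np.argmax(~np.isclose(lo[1:], hi[:-1]))) + 1
            raise IOError(
                f"{path}: structure {structure!r} bins not contiguous at row {bad} "
                f"(bin_lo {lo[bad]} != previous bin_hi {hi[bad - 1]})"
            )
        edges = np.concatenate([lo, [hi[-1]]])
        out[str(structure)] = DifferentialDVH(
            edges, sub["volume_cc"].to_numpy(float), str(structure)
        )
    return out


# ---------------------------------------------------------------------------
# DVH tables — Eclipse-style exported text dialect
#
# Block layout (one per structure):
#   Structure: <name>
#   Prescription: <dose> cGy          (only required for % dose axes)
#   Volume: <cc> cm3                  (only required for % volume axes)
#   Type: cumulative | differential
#   Dose [<cGy|Gy|%>]  Volume [<cm3|%>]
#   <two columns of numbers>


def write_eclipse_text(path, cdvhs: list[CumulativeDVH]) -> None:
    with open(path, "w") as fh:
        for cdvh in cdvhs:
            fh.write(f"Structure: {cdvh.structure}\n")
            fh.write("Type: cumulative\n")
            fh.write("Dose [cGy]\tVolume [cm3]\n")
            for d, v in zip(cdvh.dose_axis, cdvh.volume_at_least):
                fh.write(f"{d:.6g}\t{v:.6g}\n")
            fh.write("\n")


def _parse_unit(header: str, path, lineno: int) -> tuple[str, str]:
    import re

    units = re.findall(r"\[([^\]]+)\]", header)
    if len(units) != 2:
        raise IOError(f"{path}:{lineno}: expected 'Dose [unit]  Volume [unit]' header")
    return units[0].strip().lower(), units[1].strip().lower()


def _read_eclipse_text(path):
    path = Path(path)
    blocks: dict[str, object] = {}
    meta: dict[str, object] = {}
    rows: list[tuple[float, float]] = []
    units: tuple[str, str] | None = None

    def flush(lineno: int) -> None:
        nonlocal meta, rows, units
        if not meta and not rows:
            return
        name = meta.get("structure")
        if name is None:
            raise IOError(f"{path}:{lineno}: data block without a 'Structure:' header")
        if not rows:
            raise IOError(f"{path}:{lineno}: structure {name!r} has no data rows")
        dose_u, vol_u = units
        dose = np.array([r[0] for r in rows])
        vol = np.array([r[1] for r in rows])
        if dose_u == "gy":
            dose = dose * 100.0
        elif dose_u == "%":
            presc = meta.get("prescription_cgy")
            if presc is None:
                raise IOError(
                    f"{path}: structure {name!r} has a % dose axis but no "
                    "'Prescription:' header to convert it"
                )
            dose = dose * presc / 100.0
        elif dose_u != "cgy":
            raise IOError(f"{path}: structure {name!r}: unknown dose unit {dose_u!r}")
        if vol_u == "%":
            total = meta.get("volume_cc")
            if total is None:
                raise IOError(
                    f"{path}: structure {name!r} has a % volume axis but no "
                    "'Volume:' header to convert it"
                )
            vol = vol * total / 100.0
        elif vol_u not in ("cm3", "cm³", "cc"):
            raise IOError(f"{path}: structure {name!r}: unknown volume unit {vol_u!r}")
        kind = meta.get("type", "cumulative")
        if kind == "cumulative":
            drops = np.diff(vol) > 1e-9
            if drops.any():
                bad = int(np.argmax(drops)) + 1
                raise IOError(
                    f"{path}: structure {name!r}: cumulative volume increases at "
                    f"data row {bad + 1} (dose {dose[bad]:g} cGy)"
                )
            blocks[name] = CumulativeDVH(dose, vol, name)
        elif kind == "differential":
            if dose.size < 2:
                raise IOError(f"{path}: structure {name!r}: differential needs >= 2 bins")
            width = np.diff(dose)
            edges = np.concatenate([[dose[0] - width[0] / 2], dose[:-1] + width / 2,
                                    [dose[-1] + width[-1] / 2]])
            edges = np.maximum(edges, 0.0)
            blocks[name] = DifferentialDVH(edges, vol, name)
        else:
            raise IOError(f"{path}: structure {name!r}: unknown Type {kind!r}")
        meta, rows, units = {}, [], None

    lineno = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                flush(lineno)
                continue
            lowered = line.lower()
            if lowered.startswith("structure:"):
                flush(lineno)
                meta["structure"] = line.split(":", 1)[1].strip()
            elif lowered.startswith("prescription:"):
                meta["prescription_cgy"] = _parse_dose_cgy(line, path, lineno)
            elif lowered.startswith("volume:"):
                meta["volume_cc"] = float(line.split(":", 1)[1].split()[0])
            elif lowered.startswith("type:"):
                meta["type"] = line.split(":", 1)[1].strip().lower()
            elif "dose" in lowered and "[" in line:
                units = _parse_unit(line, path, lineno)
            else:
                parts = line.replace(",", " ").split()
                if len(parts) < 2:
                    raise IOError(f"{path}:{lineno}: cannot parse data line {line!r}")
                if units is None:
                    raise IOError(f"{path}:{lineno}: data before a unit header line")
                try:
                    rows.append((float(parts[0]), float(parts[1])))
                except ValueError as exc:
                    raise IOError(f"{path}:{lineno}: non-numeric data {line!r}") from exc
    flush(lineno + 1)
    return blocks


def _parse_dose_cgy(line: str, path, lineno: int) -> float:
    parts = line.split(":", 1)[1].split()
    if not parts:
        raise IOError(f"{path}:{lineno}: empty prescription header")
    value = float(parts[0])
    unit = parts[1].lower() if len(parts) > 1 else "cgy"
    if unit == "gy":
        return value * 100.0
    if unit == "cgy":
        return value
    raise IOError(f"{path}:{lineno}: unknown prescription unit {unit!r}")


def read_dvh_table(path, dialect: str = "csv"):
    """Read a DVH table file.

    ``csv`` dialect returns {structure: DifferentialDVH}; ``eclipse_text``
    returns {structure: DifferentialDVH | CumulativeDVH} depending on each
    block's declared type.
    """
    if dialect == "csv":
        return _read_dvh_csv(path)
    if dialect == "eclipse_text":
        return _read_eclipse_text(path)
    raise ValueError(f"unknown DVH dialect {dialect!r}")


# ---------------------------------------------------------------------------
# run configuration


_CONFIG_SCHEMA = {
    "seed": int,
    "output_dir": str,
    "n_patients": int,
    "prescription_cgy": (int, float),
    "n_fractions": int,
    "effects": dict,
    "metrics": list,
    "alpha": (int, float),
    "control": str,
    "pairs": list,
    "posthoc_method": str,
    "mc_reps": int,
    "gamma50_default": (int, float),
    "model_overrides": list,
    "grid_shape": list,
    "spacing_mm": list,
    "falloff_mm": (int, float),
    "verbosity": str,
}


def load_run_config(path) -> dict:
    """Load and validate a YAML run config; unknown keys are rejected."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise IOError(f"{path}: config must be a mapping")
    for key, value in raw.items():
        if key not in _CONFIG_SCHEMA:
            raise IOError(
                f"{path}: unknown config key {key!r}; known keys: "
                f"{sorted(_CONFIG_SCHEMA)}"
            )
        if not isinstance(value, _CONFIG_SCHEMA[key]):
            raise IOError(f"{path}: key {key!r} has wrong type {type(value).__name__}")
    return raw


# ---------------------------------------------------------------------------
# provenance


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
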
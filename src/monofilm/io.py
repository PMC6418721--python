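"""Plain-text file dialects read and written by the package.

Isotherms: ``area_A2_per_molecule,pressure_mN_per_m`` CSV with optional
``#``-prefixed metadata lines (``# label=``, ``# temperature_C=``,
``# convention=``).  Adsorption traces: ``time_s,pressure_mN_per_m`` with
``# pi_ini=`` and ``# conc_nM=``.  Insertion series: ``pi_ini,delta_pi``.
Ground truth travels in a JSON sidecar next to each generated file.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .adsorption import AdsorptionTrace
from .imaging import Micrograph
from .isotherm import IsothermCurve
from .mixing import ExcessAreaSeries
from .simulate import GroundTruth

ISOTHERM_HEADER = "area_A2_per_molecule,pressure_mN_per_m"
TRACE_HEADER = "time_s,pressure_mN_per_m"


def _read_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, value = body.split("=", 1)
                meta[key.strip()] = value.strip()
    return meta


def read_isotherm(path) -> IsothermCurve:
    path = Path(path)
    meta = _read_metadata(path)
    table = pd.read_csv(path, comment="#")
    return IsothermCurve(
        areas=table.iloc[:, 0].to_numpy(float),
        pressures=table.iloc[:, 1].to_numpy(float),
        convention=meta.get("convention", "per_molecule"),
        temperature=float(meta.get("temperature_C", 20.0)),
        label=meta.get("label", path.stem),
    )


def write_isotherm(curve: IsothermCurve, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# label={curve.label}\n")
        fh.write(f"# temperature_C={curve.temperature:g}\n")
        fh.write(f"# convention={curve.convention}\n")
        fh.write(ISOTHERM_HEADER + "\n")
        for a, p in zip(curve.areas, curve.pressures):
            fh.write(f"{a:.10g},{p:.10g}\n")


def read_trace(path) -> AdsorptionTrace:
    path = Path(path)
    meta = _read_metadata(path)
    if "pi_ini" not in meta:
        raise ValueError(f"{path}: missing '# pi_ini=' metadata line")
    table = pd.read_csv(path, comment="#")
    conc = meta.get("conc_nM")
    return AdsorptionTrace(
        times=table.iloc[:, 0].to_numpy(float),
        pressures=table.iloc[:, 1].to_numpy(float),
        pi_ini=float(meta["pi_ini"]),
        polymer_concentration_nM=float(conc) if conc is not None else None,
        label=meta.get("label", path.stem),
    )


def write_trace(trace: AdsorptionTrace, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# label={trace.label}\n")
        fh.write(f"# pi_ini={trace.pi_ini:g}\n")
        if trace.polymer_concentration_nM is not None:
            fh.write(f"# conc_nM={trace.polymer_concentration_nM:g}\n")
        fh.write(TRACE_HEADER + "\n")
        for t, p in zip(trace.times, trace.pressures):
            fh.write(f"{t:.10g},{p:.10g}\n")


def read_insertion_series(path) -> np.ndarray:
    """(pi_ini, delta_pi) pairs from a two-column CSV."""
    table = pd.read_csv(path, comment="#")
    return table.iloc[:, :2].to_numpy(float)


def write_insertion_series(points, path) -> None:
    pts = np.asarray(points, dtype=float)
    with open(path, "w") as fh:
        fh.write("pi_ini,delta_pi\n")
        for x, y in pts:
            fh.write(f"{x:.10g},{y:.10g}\n")


def write_excess_series(series: ExcessAreaSeries, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# reference={series.reference}\n")
        if series.mixture is not None:
            fh.write(f"# mixture={series.mixture.ratio_label}\n")
        if series.skipped_pressures:
            skipped = ",".join(f"{p:g}" for p in series.skipped_pressures)
            fh.write(f"# skipped_pressures={skipped}\n")
        fh.write("pressure_mN_per_m,delta_area_A2_per_lipid\n")
        for p, d in zip(series.pressures, series.delta_area):
            fh.write(f"{p:.10g},{d:.10g}\n")


def read_image(path) -> Micrograph:
    path = Path(path)
    data = np.asarray(iio.imread(path), dtype=float)
    if data.ndim == 3:  # collapse RGB(A) to grayscale by the mean channel
        data = data[..., :3].mean(axis=-1)
    return Micrograph(intensities=data, label=path.stem)


def write_image(data: np.ndarray, path) -> None:
    """Write a grayscale array as 8-bit PNG/TIFF (bool masks become 0/255)."""
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    else:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def truth_sidecar_path(data_path) -> Path:
    return Path(str(data_path) + ".truth.json")


def write_ground_truth(truth: GroundTruth, data_path) -> Path:
    """Serialize a ground-truth record next to its data file."""
    out = truth_sidecar_path(data_path)
    payload = {
        "generator": truth.generator,
        "params": _jsonable(truth.params),
        "truth": _jsonable(truth.truth),
    }
    with open(out, "w") as fh:
        json.dump(payload, fh, indent=1)
    return out


def read_ground_truth(data_path) -> dict:
    with open(truth_sidecar_path(data_path)) as fh:
        return json.load(fh)
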
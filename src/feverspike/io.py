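"""Plain-text interchange formats for sweeps, units and temperature series.

Sweep bundles are a directory with ``manifest.json`` plus one two-column
CSV per sweep (``time_s,vm_mV``); unit bundles hold a manifest, one
spike-times text file per unit (one float second per line) and one
waveform CSV (``sample_idx,uV``); body-temperature series are a CSV with
header ``time_s,tb_c``.  Reading back a written bundle reproduces the
values to full float precision (floats round-trip through ``repr``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .records import TbSeries, UnitRecord, VoltageSweep

__all__ = [
    "write_sweep_bundle",
    "read_sweep_bundle",
    "write_unit_bundle",
    "read_unit_bundle",
    "write_tb_series",
    "read_tb_series",
]

_SWEEP_HEADER = "time_s,vm_mV"
_WF_HEADER = "sample_idx,uV"
_TB_HEADER = "time_s,tb_c"


def _float_repr(v) -> str:
    return repr(float(v))


def _write_two_col(path: Path, header: str, col0, col1, fmt0=_float_repr, fmt1=_float_repr) -> None:
    lines = [header]
    lines.extend(f"{fmt0(a)},{fmt1(b)}" for a, b in zip(col0, col1))
    path.write_text("\n".join(lines) + "\n")


def _read_two_col(path: Path, header: str) -> tuple[np.ndarray, np.ndarray]:
    if not path.exists():
        raise FileNotFoundError(f"missing data file: {path}")
    with open(path) as fh:
        first = fh.readline().strip()
        if first != header:
            raise ValueError(f"{path}: expected header {header!r}, got {first!r}")
        a, b = [], []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            x, y = line.split(",")
            a.append(float(x))
            b.append(float(y))
    return np.asarray(a), np.asarray(b)


def write_sweep_bundle(
    directory: str | Path,
    sweeps: list[VoltageSweep],
    truth: pd.DataFrame | None = None,
) -> Path:
    """Write a sweep bundle (manifest.json + per-sweep CSVs)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    rates = {s.sampling_rate for s in sweeps}
    onsets = {s.stim_onset for s in sweeps}
    if len(rates) != 1 or len(onsets) != 1:
        raise ValueError("bundle sweeps must share sampling_rate and stim_onset")
    for s in sweeps:
        name = f"{s.cell_id}_T{s.temperature:g}_s{s.sweep_index:02d}.csv"
        _write_two_col(directory / name, _SWEEP_HEADER, s.time_s, s.vm)
        entries.append(
            {
                "cell_id": s.cell_id,
                "temperature": s.temperature,
                "sweep_index": s.sweep_index,
                "path": name,
                "pre_stim_window": list(s.pre_stim_window),
                "injected_pa": s.injected_pa,
                "step_duration": s.step_duration,
            }
        )
    manifest = {
        "sampling_rate": sweeps[0].sampling_rate,
        "stim_onset": sweeps[0].stim_onset,
        "cells": sorted({s.cell_id for s in sweeps}),
        "temperatures": sorted({s.temperature for s in sweeps}),
        "sweeps": entries,
    }
    if truth is not None:
        manifest["truth"] = truth.to_dict(orient="list")
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return directory


def read_sweep_bundle(
    directory: str | Path,
) -> tuple[list[VoltageSweep], pd.DataFrame | None]:
    """Read a sweep bundle; errors name any missing or malformed file."""
    directory = Path(directory)
    mpath = directory / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"missing manifest: {mpath}")
    manifest = json.loads(mpath.read_text())
    for key in ("sampling_rate", "stim_onset", "sweeps"):
        if key not in manifest:
            raise ValueError(f"manifest lacks required key {key!r}")
    sweeps = []
    for e in manifest["sweeps"]:
        t, vm = _read_two_col(directory / e["path"], _SWEEP_HEADER)
        sweeps.append(
            VoltageSweep(
                time_s=t,
                vm=vm,
                sampling_rate=manifest["sampling_rate"],
                stim_onset=manifest["stim_onset"],
                pre_stim_window=tuple(e["pre_stim_window"]),
                temperature=e["temperature"],
                cell_id=e["cell_id"],
                sweep_index=e["sweep_index"],
                injected_pa=e.get("injected_pa"),
                step_duration=e.get("step_duration"),
            )
        )
    truth = pd.DataFrame(manifest["truth"]) if "truth" in manifest else None
    return sweeps, truth


def write_unit_bundle(directory: str | Path, units: list[UnitRecord]) -> Path:
    """Write a unit bundle (units_manifest.json + spike times + waveforms)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for u in units:
        st_name = f"{u.unit_id}_spikes.txt"
        wf_name = f"{u.unit_id}_waveform.csv"
        (directory / st_name).write_text(
            "".join(f"{repr(float(t))}\n" for t in u.spike_times)
        )
        _write_two_col(
            directory / wf_name,
            _WF_HEADER,
            range(u.mean_waveform.size),
            u.mean_waveform,
            fmt0=str,
        )
        entries.append(
            {
                "unit_id": u.unit_id,
                "animal_id": u.animal_id,
                "spike_times": st_name,
                "waveform": wf_name,
                "waveform_sampling_rate": u.waveform_sampling_rate,
                "true_class": u.true_class,
                "true_duration_ms": u.true_duration_ms,
                "true_base_rate_hz": u.true_base_rate_hz,
                "true_fever_gain": u.true_fever_gain,
            }
        )
    (directory / "units_manifest.json").write_text(
        json.dumps({"units": entries}, indent=1, sort_keys=True)
    )
    return directory


def read_unit_bundle(directory: str | Path) -> list[UnitRecord]:
    directory = Path(directory)
    mpath = directory / "units_manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"missing manifest: {mpath}")
    manifest = json.loads(mpath.read_text())
    units = []
    for e in manifest["units"]:
        st_path = directory / e["spike_times"]
        if not st_path.exists():
            raise FileNotFoundError(f"missing spike-times file: {st_path}")
        times = np.asarray(
            [float(line) for line in st_path.read_text().split()], dtype=float
        )
        _, wf = _read_two_col(directory / e["waveform"], _WF_HEADER)
        units.append(
            UnitRecord(
                unit_id=e["unit_id"],
                spike_times=times,
                mean_waveform=wf,
                waveform_sampling_rate=e["waveform_sampling_rate"],
                animal_id=e.get("animal_id", "animal0"),
                true_class=e.get("true_class"),
                true_duration_ms=e.get("true_duration_ms"),
                true_base_rate_hz=e.get("true_base_rate_hz"),
                true_fever_gain=e.get("true_fever_gain"),
            )
        )
    return units


def write_tb_series(path: str | Path, series: TbSeries) -> Path:
    path = Path(path)
    _write_two_col(path, _TB_HEADER, series.times, series.tb)
    return path


def read_tb_series(path: str | Path, condition: str = "room") -> TbSeries:
    t, tb = _read_two_col(Path(path), _TB_HEADER)
    return TbSeries(times=t, tb=tb, condition=condition)
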
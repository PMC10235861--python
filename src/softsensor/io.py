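"""File formats: spectra/offline/dataset CSV schemas, model JSON, YAML config.

Spectra CSV: ``timestamp,f_00050,...,f_20000`` — ISO-8601 UTC timestamps, one
column per scan frequency (kHz, zero-padded in the header), values in pF/cm.
Offline CSV: ``timestamp,vcc_cells_per_ml,viability,diameter_um``.
Dataset CSV: ``timestamp,batch_id,vcc_cells_per_ml`` followed by the
frequency columns.

Internally timestamps are plain float seconds; CSV writers add a run-start
epoch, readers return absolute POSIX seconds.  All time arithmetic in the
package uses differences only, so either convention is consistent end-to-end.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from .baseline import SingleFreqModel
from .opls import LinearizedModel, OPLSModel
from .preprocess import CalibrationDataset
from .simulate import DielectricParams, OfflineSample, ProcessConfig, SpectrumRecord

__all__ = [
    "DEFAULT_EPOCH",
    "frequency_column",
    "write_spectra_csv",
    "read_spectra_csv",
    "write_offline_csv",
    "read_offline_csv",
    "write_dataset_csv",
    "read_dataset_csv",
    "load_model",
    "save_model",
    "load_run_config",
]

DEFAULT_EPOCH = "2022-01-01T00:00:00Z"

_FREQ_COL = re.compile(r"^f_(\d+)$")


def frequency_column(f_kHz: float) -> str:
    return f"f_{int(round(f_kHz)):05d}"


def _to_iso(seconds: np.ndarray, epoch: str) -> pd.Series:
    base = pd.Timestamp(epoch)
    ts = base + pd.to_timedelta(np.asarray(seconds, dtype=float), unit="s")
    return pd.Series(ts).dt.strftime("%Y-%m-%dT%H:%M:%S.%fZ")

def _from_iso(column: pd.Series) -> np.ndarray:
    ts = pd.to_datetime(column, utc=True, format="ISO8601")
    return ts.astype("int64").to_numpy() / 1e9


def write_spectra_csv(records: list[SpectrumRecord], path, frequencies_kHz, epoch: str = DEFAULT_EPOCH) -> None:
    freqs = np.asarray(frequencies_kHz, dtype=float)
    cols = [frequency_column(f) for f in freqs]
    df = pd.DataFrame(np.stack([r.capacitance_pF_per_cm for r in records]) if records else
                      np.empty((0, len(cols))), columns=cols)
    df.insert(0, "timestamp", _to_iso([r.timestamp for r in records], epoch))
    df.to_csv(path, index=False, float_format="%.17g")


def read_spectra_csv(path) -> tuple[list[SpectrumRecord], np.ndarray]:
    """Returns (records with absolute POSIX-second timestamps, frequency grid)."""
    df = pd.read_csv(path, float_precision="round_trip")
    freq_cols = [c for c in df.columns if _FREQ_COL.match(c)]
    if not freq_cols:
        raise ValueError(f"{path}: no frequency columns (f_XXXXX) found")
    freqs = np.asarray([float(_FREQ_COL.match(c).group(1)) for c in freq_cols])
    times = _from_iso(df["timestamp"])
    values = df[freq_cols].to_numpy(dtype=float)
    records = [SpectrumRecord(timestamp=float(t), capacitance_pF_per_cm=row)
               for t, row in zip(times, values)]
    return records, freqs


def write_offline_csv(samples: list[OfflineSample], path, epoch: str = DEFAULT_EPOCH) -> None:
    df = pd.DataFrame({
        "timestamp": _to_iso([s.timestamp for s in samples], epoch),
        "vcc_cells_per_ml": [s.vcc_cells_per_mL for s in samples],
        "viability": [s.viability_fraction for s in samples],
        "diameter_um": [s.diameter_um for s in samples],
    })
    df.to_csv(path, index=False, float_format="%.17g")


def read_offline_csv(path) -> list[OfflineSample]:
    df = pd.read_csv(path, float_precision="round_trip")
    times = _from_iso(df["timestamp"])
    return [
        OfflineSample(timestamp=float(t), vcc_cells_per_mL=float(v),
                      viability_fraction=float(w), diameter_um=float(d))
        for t, v, w, d in zip(times, df["vcc_cells_per_ml"], df["viability"], df["diameter_um"])
    ]


def write_dataset_csv(dataset: CalibrationDataset, path, epoch: str = DEFAULT_EPOCH) -> None:
    cols = [frequency_column(f) for f in dataset.frequencies_kHz]
    df = pd.DataFrame(dataset.X, columns=cols)
    df.insert(0, "vcc_cells_per_ml", dataset.y)
    df.insert(0, "batch_id", dataset.batch_ids)
    df.insert(0, "timestamp", _to_iso(dataset.sample_timestamps, epoch))
    df.to_csv(path, index=False, float_format="%.17g")


def read_dataset_csv(path) -> CalibrationDataset:
    df = pd.read_csv(path, float_precision="round_trip")
    freq_cols = [c for c in df.columns if _FREQ_COL.match(c)]
    if not freq_cols:
        raise ValueError(f"{path}: no frequency columns (f_XXXXX) found")
    return CalibrationDataset(
        X=df[freq_cols].to_numpy(dtype=float),
        y=df["vcc_cells_per_ml"].to_numpy(dtype=float),
        sample_timestamps=_from_iso(df["timestamp"]),
        batch_ids=df["batch_id"].to_numpy(),
        frequencies_kHz=np.asarray([float(_FREQ_COL.match(c).group(1)) for c in freq_cols]),
    )


_MODEL_TYPES = {
    "opls": OPLSModel,
    "linear_equation": LinearizedModel,
    "single_frequency": SingleFreqModel,
}


def load_model(path):
    """Load any serialized model, dispatching on its ``type`` field."""
    with open(path) as fh:
        d = json.load(fh)
    kind = d.get("type")
    if kind not in _MODEL_TYPES:
        raise ValueError(f"{path}: unknown model type {kind!r}")
    return _MODEL_TYPES[kind].from_dict(d)


def save_model(model, path) -> None:
    model.save(path)


def load_run_config(path) -> tuple[ProcessConfig, DielectricParams]:
    """Read one YAML document holding ``process:`` and ``dielectric:`` maps."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    proc = dict(doc.get("process", {}))
    if "frequencies_kHz" in proc:
        proc["frequencies_kHz"] = tuple(float(f) for f in proc["frequencies_kHz"])
    if "pid_gains" in proc:
        proc["pid_gains"] = tuple(float(g) for g in proc["pid_gains"])
    if "diameter_ramp" in proc:
        proc["diameter_ramp"] = tuple(float(v) for v in proc["diameter_ramp"])
    if proc.get("offline_sampling_times") is not None:
        proc["offline_sampling_times"] = tuple(float(t) for t in proc["offline_sampling_times"])
    return ProcessConfig(**proc), DielectricParams(**dict(doc.get("dielectric", {})))


def _plain(value):
    if isinstance(value, (list, tuple)):
        return [_plain(v) for v in value]
    if isinstance(value, np.generic):
        return value.item()
    return value


def dump_run_config(config: ProcessConfig, params: DielectricParams, path) -> None:
    doc = {
        "process": {k: _plain(v) for k, v in asdict(config).items()},
        "dielectric": {k: _plain(v) for k, v in asdict(params).items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
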
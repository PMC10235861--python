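"""Online deployment loop: ingest scans, smooth causally, execute models.

Emulates the middleware that sits between the probe software and a SCADA
system: a client periodically receives capacitance scans, maintains a
trailing rolling-mean buffer, evaluates every registered model (exported
linear equation or native model) on the buffer mean, and emits timestamped
VCC predictions to a sink.  Transport is abstracted to source/sink
interfaces — file replay and in-process callables here — so a network
adapter (e.g. an OPC UA client) could be added without touching the loop.

Processing is purely causal: every emitted prediction depends only on scans
at or before its own timestamp, never on wall-clock pacing.  Predictions are
not clamped at zero; a negative output is emitted and logged, since clamping
would mask a failing calibration.
"""

from __future__ import annotations

import logging
import time
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from . import io as ssio
from .simulate import SpectrumRecord

__all__ = ["PredictionRecord", "StreamConfig", "StreamResult", "ReplaySource", "replay_source", "run_stream"]

logger = logging.getLogger(__name__)


@dataclass
class PredictionRecord:
    timestamp: float
    model_id: str
    predicted_vcc_cells_per_mL: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.predicted_vcc_cells_per_mL):
            raise ValueError("prediction must be finite")


@dataclass
class StreamConfig:
    poll_interval_s: float = 30.0
    window_s: float = 300.0
    max_skipped_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.poll_interval_s <= 0:
            raise ValueError("poll_interval_s must be > 0")
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")


@dataclass
class StreamResult:
    records: list[PredictionRecord]
    n_in: int = 0
    n_skipped: int = 0
    n_negative: int = 0

    @property
    def n_processed(self) -> int:
        return self.n_in - self.n_skipped


class ReplaySource:
    """Replays a spectra CSV (or in-memory records) in timestamp order.

    ``speed_factor = 0`` replays as fast as possible (the deterministic test
    mode); ``speed_factor = s > 0`` paces emission at s× real time.  Pacing
    never changes record contents.  Rows whose capacitance values failed to
    parse are yielded as-is (non-finite) so the consumer can apply its own
    robustness policy.
    """

    def __init__(self, records: list[SpectrumRecord], frequencies_kHz, speed_factor: float = 0.0):
        times = np.asarray([r.timestamp for r in records], dtype=float)
        if np.any(np.diff(times) < 0):
            raise ValueError("source timestamps must be non-decreasing")
        self.records = records
        self.frequencies_kHz = np.asarray(frequencies_kHz, dtype=float)
        self.speed_factor = speed_factor

    def __iter__(self):
        prev_t = None
        for rec in self.records:
            if self.speed_factor > 0 and prev_t is not None:
                time.sleep(max(rec.timestamp - prev_t, 0.0) / self.speed_factor)
            prev_t = rec.timestamp
            yield rec

    def __len__(self) -> int:
        return len(self.records)


def replay_source(spectra_csv, speed_factor: float = 0.0) -> ReplaySource:
    """Build a replay source from a spectra CSV file."""
    records = []
    import pandas as pd

    df = pd.read_csv(spectra_csv, float_precision="round_trip")
    freq_cols = [c for c in df.columns if ssio._FREQ_COL.match(c)]
    if not freq_cols:
        raise ValueError(f"{spectra_csv}: no frequency columns found")
    freqs = np.asarray([float(ssio._FREQ_COL.match(c).group(1)) for c in freq_cols])
    times = ssio._from_iso(df["timestamp"])
    values = df[freq_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    for t, row in zip(times, values):
        rec = object.__new__(SpectrumRecord)  # bypass finite check: malformed rows are the stream's problem
        rec.timestamp = float(t)
        rec.capacitance_pF_per_cm = row
        records.append(rec)
    return ReplaySource(records, freqs, speed_factor=speed_factor)


def run_stream(
    source: ReplaySource,
    models: dict[str, object],
    config: StreamConfig | None = None,
    sink=None,
) -> StreamResult:
    """Run the online prediction loop over a source.

    For each arriving scan: append to the buffer, evict scans older than
    ``window_s`` (trailing window, open on the left), average the buffer,
    and evaluate every model on the mean spectrum, emitting one
    ``PredictionRecord`` per model.  Malformed scans (wrong length or
    non-finite values) are skipped, counted and logged; the stream continues.

    ``sink`` may be a callable (receives each record) or a file path for an
    append-only CSV ``timestamp,model_id,vcc_pred``.
    """
    config = config or StreamConfig()
    if not models:
        raise ValueError("no models registered")
    freqs = source.frequencies_kHz
    for model_id, model in models.items():
        try:
            model.predict(np.zeros(len(freqs)), freqs)
        except ValueError as exc:
            raise ValueError(f"model {model_id!r} incompatible with source grid: {exc}") from exc

    close_sink = None
    if sink is None:
        emit = lambda rec: None
    elif callable(sink):
        emit = sink
    else:
        fh = open(sink, "w")
        fh.write("timestamp,model_id,vcc_pred\n")
        emit = lambda rec: fh.write(f"{rec.timestamp:.17g},{rec.model_id},{rec.predicted_vcc_cells_per_mL:.17g}\n")
        close_sink = fh.close

    buffer: deque[SpectrumRecord] = deque()
    result = StreamResult(records=[])
    try:
        for rec in source:
            result.n_in += 1
            x = np.asarray(rec.capacitance_pF_per_cm, dtype=float)
            if x.shape != (len(freqs),) or not np.all(np.isfinite(x)):
                result.n_skipped += 1
                logger.warning("skipped malformed scan at t=%.0f s", rec.timestamp)
                continue
            t = rec.timestamp
            buffer.append(rec)
            while buffer[0].timestamp <= t - config.window_s:
                buffer.popleft()
            mean = np.mean(np.stack([b.capacitance_pF_per_cm for b in buffer]), axis=0)
            for model_id, model in models.items():
                yhat = float(model.predict(mean, freqs))
                if yhat < 0:
                    result.n_negative += 1
                    logger.warning("negative VCC prediction %.3g from %s at t=%.0f s", yhat, model_id, t)
                out = PredictionRecord(timestamp=t, model_id=model_id, predicted_vcc_cells_per_mL=yhat)
                result.records.append(out)
                emit(out)
    finally:
        if close_sink:
            close_sink()
    return result
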
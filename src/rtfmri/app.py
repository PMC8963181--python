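"""Pipeline terminal: ROI feedback extraction, TCP signal exchange, and
online-vs-offline comparison utilities.

The neurofeedback value is the mean of the denoised volume inside an ROI
mask.  Each value becomes a :class:`SignalMessage` that is appended to the
run CSV and, optionally, sent over a line-based TCP protocol to an
external application: one UTF-8 line ``NF <vol_index> <onset_s> <value>``
per message, and a single ``END`` sentinel at end of run.
"""

from __future__ import annotations

import csv
import socket
import socketserver
import threading
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pipeline import ConfigError, Stage
from .volume import VolumeSample

__all__ = [
    "SignalMessage",
    "SignalStore",
    "SignalServer",
    "send_signal",
    "RoiFeedbackStage",
    "roi_feedback",
    "compare_series",
]


@dataclass(frozen=True)
class SignalMessage:
    """(volume index, onset seconds, feedback value) record."""

    vol_index: int
    onset_s: float
    value: float

    def serialize(self) -> str:
        return f"NF {self.vol_index} {self.onset_s:.6g} {self.value:.6g}\n"

    @classmethod
    def parse(cls, line: str) -> "SignalMessage":
        parts = line.strip().split()
        if len(parts) != 4 or parts[0] != "NF":
            raise ValueError(f"not a signal message: {line!r}")
        return cls(int(parts[1]), float(parts[2]), float(parts[3]))


@dataclass
class SignalStore:
    """Ordered record of received messages, queryable while receiving."""

    messages: list[SignalMessage] = field(default_factory=list)
    timestamps: list[float] = field(default_factory=list)
    _lock: threading.Lock = field(default_factory=threading.Lock, repr=False)

    def append(self, m: SignalMessage) -> None:
        with self._lock:
            self.messages.append(m)
            self.timestamps.append(time.time())

    def snapshot(self) -> list[SignalMessage]:
        with self._lock:
            return list(self.messages)

    def __len__(self) -> int:
        with self._lock:
            return len(self.messages)


class _Handler(socketserver.StreamRequestHandler):
    def handle(self) -> None:
        for raw in self.rfile:
            line = raw.decode("utf-8")
            if line.strip() == "END":
                self.server.store.ended = True
                continue
            if line.strip():
                self.server.store.append(SignalMessage.parse(line))


class SignalServer:
    """TCP receiver running in a background thread.

    Instantiating the class launches the server; received messages
    accumulate in :attr:`store`.
    """

    def __init__(self, host: str = "127.0.0.1", port: int = 0):
        self.store = SignalStore()
        self.store.ended = False
        self._srv = socketserver.ThreadingTCPServer((host, port), _Handler)
        self._srv.daemon_threads = True
        self._srv.store = self.store
        self.host, self.port = self._srv.server_address
        self._thread = threading.Thread(target=self._srv.serve_forever,
                                        daemon=True)
        self._thread.start()

    def close(self) -> None:
        self._srv.shutdown()
        self._srv.server_close()

    def __enter__(self) -> "SignalServer":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def send_signal(host: str, port: int, m: SignalMessage | str,
                retries: int = 3, retry_wait_s: float = 0.2) -> None:
    """Send one message (or the ``END`` sentinel) with connection retries."""
    payload = m.serialize() if isinstance(m, SignalMessage) else m
    last: Exception | None = None
    for _ in range(retries):
        try:
            with socket.create_connection((host, port), timeout=5.0) as s:
                s.sendall(payload.encode("utf-8"))
            return
        except OSError as exc:
            last = exc
            time.sleep(retry_wait_s)
    raise ConnectionError(f"could not reach {host}:{port}") from last


def roi_feedback(vol: VolumeSample, roi: np.ndarray) -> SignalMessage:
    """Mean denoised signal inside the ROI as a feedback message."""
    roi = np.asarray(roi).astype(bool)
    if not roi.any():
        raise ConfigError("ROI mask is empty")
    value = float(np.asarray(vol.data, float)[roi].mean())
    return SignalMessage(vol.index, vol.onset_s, value)


class RoiFeedbackStage(Stage):
    """Terminal stage: ROI-mean extraction, CSV logging, optional TCP send."""

    name = "app"

    def __init__(self, roi: np.ndarray, send_to: tuple[str, int] | None = None,
                 **kw):
        super().__init__(**kw)
        self.roi = np.asarray(roi).astype(bool)
        if not self.roi.any():
            raise ConfigError("ROI mask is empty")
        self.send_to = send_to
        self.signals: list[SignalMessage] = []

    def _reset(self) -> None:
        self.signals = []

    def _proc(self, vol: VolumeSample) -> list[VolumeSample]:
        m = roi_feedback(vol, self.roi)
        self.signals.append(m)
        if self.send_to is not None:
            send_signal(*self.send_to, m)
        return [vol]

    def _finalize(self, out_dir: Path) -> dict[str, Path]:
        if self.send_to is not None:
            send_signal(*self.send_to, "END\n")
        path = out_dir / "roi_signal.csv"
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["vol_index", "onset_s", "value"])
            for m in self.signals:
                w.writerow([m.vol_index, f"{m.onset_s:.6g}", f"{m.value:.6g}"])
        return {"roi_signal": path}


def compare_series(a, b) -> dict[str, float]:
    """Max absolute difference and Pearson correlation of two equal-length
    series (the online-vs-offline comparison statistic pair)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1D and equal length")
    if a.size < 3:
        raise ValueError("need at least 3 samples")
    return {
        "max_abs_diff": float(np.max(np.abs(a - b))),
        "pearson_r": float(np.corrcoef(a, b)[0, 1]),
    }
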
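"""File watching and replay sources.

A scanner exports one NIfTI file per acquired volume into a directory;
:func:`watch_volumes` polls that directory, waits for each new matching
file to finish writing (two identical sizes 50 ms apart), reads it once,
and yields :class:`VolumeSample` objects in creation order with the
acquisition index parsed from the filename.  Processing a run through the
watcher or by direct injection of the same volumes yields identical
pipeline outputs.
"""

from __future__ import annotations

import re
import time
import warnings
from pathlib import Path
from typing import Iterator

from .pipeline import Stage
from .volume import FormatError, RunMeta, VolumeSample, read_volume

__all__ = ["WatchStage", "watch_volumes", "replay"]


class WatchStage(Stage):
    """Head stage representing the volume source.

    In a live run the watcher (:func:`watch_volumes`) drives the pipeline
    through :meth:`observe`; in a simulation volumes are injected directly
    into ``do_proc`` and the stage passes them through unchanged."""

    name = "watch"

    def observe(self, dir_path, pattern=None, **kw) -> int:
        """Watch a directory and feed every new volume through the chain;
        returns the number of volumes processed."""
        n = 0
        kwargs = dict(kw)
        if pattern is not None:
            kwargs["pattern"] = pattern
        for vol in watch_volumes(dir_path, **kwargs):
            self.do_proc(vol)
            n += 1
        return n

DEFAULT_PATTERN = r".*\.nii(\.gz)?$"


def _stable_size(path: Path, interval_s: float = 0.05,
                 timeout_s: float = 2.0) -> bool:
    """True once two consecutive size probes agree (write finished)."""
    deadline = time.monotonic() + timeout_s
    prev = -1
    while time.monotonic() < deadline:
        try:
            size = path.stat().st_size
        except FileNotFoundError:
            return False
        if size == prev and size > 0:
            return True
        prev = size
        time.sleep(interval_s)
    return False


def watch_volumes(dir_path: str | Path, pattern: str = DEFAULT_PATTERN,
                  n_expected: int | None = None, timeout_s: float = 30.0,
                  poll_s: float = 0.02, tr_s: float | None = None,
                  ignore_init: int = 0) -> Iterator[VolumeSample]:
    """Yield newly created matching volumes from a watched directory.

    Each file is read exactly once; duplicates (re-seen paths) are ignored
    and non-matching names never emit.  Stops after ``n_expected``
    emissions or when ``timeout_s`` passes with no new file.  The first
    ``ignore_init`` volumes (by arrival) are discarded before emission.
    A file whose size never stabilizes raises :class:`FormatError`.
    """
    dir_path = Path(dir_path)
    if not dir_path.is_dir():
        raise FileNotFoundError(f"watch directory does not exist: {dir_path}")
    rx = re.compile(pattern)
    seen: set[str] = set()
    emitted = 0
    skipped = 0
    last_event = time.monotonic()
    last_index: int | None = None
    while True:
        new = sorted(
            (p for p in dir_path.iterdir()
             if p.name not in seen and rx.match(p.name)),
            key=lambda p: (p.stat().st_mtime_ns, p.name),
        )
        for p in new:
            if not _stable_size(p):
                raise FormatError(f"file never finished writing: {p}")
            seen.add(p.name)
            vol = read_volume(p, tr_s=tr_s)
            last_event = time.monotonic()
            if skipped < ignore_init:
                skipped += 1
                continue
            if last_index is not None and vol.index != last_index + 1:
                warnings.warn(
                    f"non-consecutive volume index {vol.index} after "
                    f"{last_index}; continuing"
                )
            last_index = vol.index
            emitted += 1
            yield vol
            if n_expected is not None and emitted >= n_expected:
                return
        if n_expected is None and time.monotonic() - last_event > timeout_s:
            return
        time.sleep(poll_s)


def replay(series_4d, affine, meta: RunMeta) -> Iterator[VolumeSample]:
    """Direct-injection source: iterate a 4D array volume-by-volume,
    honouring ``meta.ignore_init``."""
    for k in range(meta.ignore_init, series_4d.shape[-1]):
        yield VolumeSample(series_4d[..., k], affine, index=k,
                           onset_s=k * meta.tr_s)
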
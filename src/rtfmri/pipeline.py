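"""Module-chaining contract for the streaming pipeline.

Each processing step is a :class:`Stage`.  Stages are linked through the
``next_proc`` attribute; calling :meth:`Stage.do_proc` at the head of the
chain pushes the volume through every enabled stage in order.  A stage may
buffer volumes and later emit several at once (the regression stage does
this for its retrospective burn-in), so the internal hook ``_proc`` returns
a list of output volumes.

``ready()`` initializes the whole chain and must be called before feeding;
``end_run()`` finalizes it: stages flagged ``save_proc`` write a 4D NIfTI
of everything they emitted, and every stage resets so the pipeline can be
readied again for a new run.
"""

from __future__ import annotations

import time
import warnings
from pathlib import Path

import numpy as np

from .volume import VolumeSample, write_series

__all__ = ["Stage", "PipelineStateError", "ConfigError", "chain", "feed"]


class PipelineStateError(RuntimeError):
    """Feeding a pipeline that has not been readied (or was already closed)."""


class ConfigError(ValueError):
    """Invalid stage configuration or chain ordering."""


class Stage:
    """Base class for pipeline stages.

    Attributes
    ----------
    name : str
        Identifier used in logs and output file names.
    enabled : bool
        Disabled stages pass volumes through unchanged.
    next_proc : Stage or None
        Downstream stage.
    save_proc : bool
        Write the stage's emitted volumes as a 4D NIfTI at end_run.
    online_saving : bool
        Rewrite the saved 4D file after every volume (after downstream
        processing completes) instead of once at end_run.  Never changes
        the final file contents.
    """

    name = "stage"

    def __init__(self, name: str | None = None, enabled: bool = True,
                 save_proc: bool = False, online_saving: bool = False,
                 work_dir: str | Path | None = None):
        if name is not None:
            self.name = name
        self.enabled = enabled
        self.next_proc: Stage | None = None
        self.save_proc = save_proc
        self.online_saving = online_saving
        self.work_dir = Path(work_dir) if work_dir else None
        self._ready = False
        self._saved: list[VolumeSample] = []
        self.timings: list[tuple[int, str, float]] = []
        self._n_processed = 0

    # -- subclass hooks ------------------------------------------------
    def _proc(self, vol: VolumeSample) -> list[VolumeSample]:
        """Process one volume; return the volumes to emit downstream."""
        return [vol]

    def _reset(self) -> None:
        """Clear per-run state (subclasses extend)."""

    def _finalize(self, out_dir: Path) -> dict[str, Path]:
        """Write stage-specific artifacts; return {label: path}."""
        return {}

    # -- chain contract ------------------------------------------------
    def ready(self) -> "Stage":
        """Initialize this stage and everything downstream."""
        self._ready = True
        self._saved = []
        self.timings = []
        self._n_processed = 0
        self._reset()
        if self.next_proc is not None:
            self.next_proc.ready()
        return self

    def do_proc(self, vol: VolumeSample) -> None:
        if not self._ready:
            raise PipelineStateError(
                f"stage '{self.name}' received a volume before ready()"
            )
        t0 = time.perf_counter()
        outs = self._proc(vol) if self.enabled else [vol]
        self.timings.append((vol.index, self.name, (time.perf_counter() - t0) * 1e3))
        self._n_processed += 1
        if outs is None:
            outs = []
        for out in outs:
            if self.save_proc:
                self._saved.append(out)
            if self.next_proc is not None:
                self.next_proc.do_proc(out)
        # online saving happens only after downstream processing completed
        if self.save_proc and self.online_saving and outs and self.work_dir:
            self.work_dir.mkdir(parents=True, exist_ok=True)
            write_series(self._saved, self.work_dir / f"proc_{self.name}.nii")

    def end_run(self, out_dir: str | Path | None = None) -> dict[str, Path]:
        """Finalize the run from this stage downstream; returns artifact paths."""
        out_dir = Path(out_dir) if out_dir else (self.work_dir or Path("."))
        out_dir.mkdir(parents=True, exist_ok=True)
        artifacts: dict[str, Path] = {}
        if self._n_processed == 0:
            warnings.warn(f"stage '{self.name}': end_run with zero volumes processed")
        if self.save_proc:
            if self._saved:
                artifacts[f"proc_{self.name}"] = write_series(
                    self._saved, out_dir / f"proc_{self.name}.nii"
                )
            else:
                warnings.warn(f"stage '{self.name}': nothing to save")
        artifacts.update(self._finalize(out_dir))
        if self.next_proc is not None:
            artifacts.update(self.next_proc.end_run(out_dir))
        if self.timings:
            log = out_dir / f"timing_{self.name}.log"
            with open(log, "w") as fh:
                fh.write("# vol_index stage elapsed_ms\n")
                for idx, name, ms in self.timings:
                    fh.write(f"{idx} {name} {ms:.3f}\n")
            artifacts[f"timing_{self.name}"] = log
        self._ready = False
        self._saved = []
        return artifacts

    def __repr__(self) -> str:  # pragma: no cover
        return f"<{type(self).__name__} '{self.name}' enabled={self.enabled}>"


def chain(stages: list[Stage]) -> Stage:
    """Link stages into a simple chain; returns the head.

    Validates the ordering rule that a regression stage depending on motion
    parameters or unsmoothed tissue signals must have an enabled motion
    correction stage upstream, and wires the motion stage to push its
    per-volume estimates to the regression stage.
    """
    if not stages:
        raise ConfigError("cannot chain an empty stage list")
    for a, b in zip(stages, stages[1:]):
        a.next_proc = b
    stages[-1].next_proc = None

    # volreg-before-regress rule + subscription wiring
    from .volreg import VolregStage
    from .regress import RegressStage

    seen_volreg: VolregStage | None = None
    for st in stages:
        if isinstance(st, VolregStage) and st.enabled:
            seen_volreg = st
        if isinstance(st, RegressStage) and st.enabled:
            if st.needs_volreg and seen_volreg is None:
                raise ConfigError(
                    "regression with motion or tissue-mean regressors requires "
                    "an enabled motion-correction stage earlier in the chain"
                )
            if seen_volreg is not None:
                seen_volreg.subscribe(st)
    return stages[0]


def feed(head: Stage, vol: VolumeSample) -> None:
    """Push one volume through the chain (alias for head.do_proc)."""
    head.do_proc(vol)
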
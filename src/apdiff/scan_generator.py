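"""Conductance-scaling grid and labeled action-potential library.

One conductance at a time is multiplied by every factor on a symmetric
grid around 1.0 (1.0 itself excluded); the unmodified cell provides the
standard trace.  On the full-resolution grid (step 0.01, range 0.01-1.99)
this yields 198 scales x 10 channels = 1,980 variant traces plus one
standard trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .cell_model import (
    APTrace,
    CONDUCTANCE_NAMES,
    IntegrationError,
    ModelParameters,
    StimulusProtocol,
    run_paced,
)

__all__ = ["ScanCondition", "APLibrary", "build_grid", "generate_library",
           "save_library", "load_library"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanCondition:
    """A single perturbation: one channel, one scale factor."""

    channel_index: int   # 0-9, reference-table row order
    scale: float

    def __post_init__(self) -> None:
        if not 0 <= self.channel_index < len(CONDUCTANCE_NAMES):
            raise ValueError("channel_index must be 0-9")
        if self.scale <= 0:
            raise ValueError("scale must be strictly positive")
        if self.scale == 1.0:
            raise ValueError("scale 1.0 is the standard condition, not a variant")

    @property
    def channel_name(self) -> str:
        return CONDUCTANCE_NAMES[self.channel_index]


@dataclass
class APLibrary:
    """Standard trace plus labeled variant traces for one scan."""

    standard: APTrace
    variants: list[tuple[ScanCondition, APTrace]]
    step: float | None = None
    failures: list[tuple[ScanCondition, str]] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.failures

    def labels(self) -> np.ndarray:
        return np.array([c.channel_index for c, _ in self.variants])

    def __len__(self) -> int:
        return len(self.variants)


def build_grid(step: float = 0.01, lo: float = 0.01,
               hi: float = 1.99) -> list[ScanCondition]:
    """All (channel, scale) conditions with scales on a uniform grid.

    Scales are the multiples of ``step`` in [lo, hi], excluding 1.0;
    ordering is channel-major with ascending scale.  The full grid
    (step 0.01 over [0.01, 1.99]) gives 1,980 conditions.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    if lo <= 0:
        raise ValueError("grid scales must be strictly positive")
    k_lo = int(np.ceil(lo / step - 1e-9))
    k_hi = int(np.floor(hi / step + 1e-9))
    scales = [round(k * step, 12) for k in range(k_lo, k_hi + 1)]
    scales = [s for s in scales if abs(s - 1.0) > 1e-9]
    return [ScanCondition(ch, s)
            for ch in range(len(CONDUCTANCE_NAMES)) for s in scales]


def generate_library(grid: Sequence[ScanCondition],
                     protocol: StimulusProtocol | None = None,
                     params: ModelParameters | None = None,
                     sample_interval: float = 2.0,
                     dt: float = 0.02,
                     step: float | None = None,
                     out_path: str | Path | None = None,
                     progress: bool = False) -> APLibrary:
    """Run the paced protocol for the standard cell and every condition.

    Failed simulations are recorded in ``library.failures`` rather than
    raised, so a scan over extreme scales can complete.  If ``out_path``
    is given the library is written there incrementally (HDF5) and
    conditions already present in the file are not re-simulated.
    """
    protocol = protocol or StimulusProtocol()
    params = params or ModelParameters()

    existing: dict[tuple[int, float], np.ndarray] = {}
    if out_path is not None and Path(out_path).exists():
        prev = load_library(out_path)
        existing = {(c.channel_index, round(c.scale, 10)): t.vm
                    for c, t in prev.variants}

    standard = run_paced(params, protocol, sample_interval, dt)
    variants: list[tuple[ScanCondition, APTrace]] = []
    failures: list[tuple[ScanCondition, str]] = []
    iterator: Iterable[ScanCondition] = grid
    if progress:
        try:
            from tqdm import tqdm
            iterator = tqdm(grid, desc="scan")
        except ImportError:  # pragma: no cover
            pass
    for cond in iterator:
        key = (cond.channel_index, round(cond.scale, 10))
        if key in existing:
            trace = APTrace(time=standard.time, vm=existing[key],
                            protocol=protocol,
                            sample_interval=sample_interval,
                            channel_index=cond.channel_index,
                            scale=cond.scale)
            variants.append((cond, trace))
            continue
        try:
            trace = run_paced(params.scaled(cond.channel_index, cond.scale),
                              protocol, sample_interval, dt,
                              channel_index=cond.channel_index,
                              scale=cond.scale)
        except IntegrationError as exc:
            log.warning("simulation failed for %s x%.3f: %s",
                        cond.channel_name, cond.scale, exc)
            failures.append((cond, str(exc)))
            continue
        variants.append((cond, trace))

    library = APLibrary(standard=standard, variants=variants, step=step,
                        failures=failures)
    if failures:
        log.warning("library incomplete: %d failed conditions", len(failures))
    if out_path is not None:
        save_library(library, out_path)
    return library


# ---------------------------------------------------------------------------
# HDF5 persistence: /standard/vm, /variants/<channel>/<scale>/vm
# ---------------------------------------------------------------------------

def save_library(library: APLibrary, path: str | Path) -> None:
    import h5py

    protocol = library.standard.protocol
    with h5py.File(path, "w") as f:
        f.attrs["amplitude"] = protocol.amplitude
        f.attrs["duration"] = protocol.duration
        f.attrs["cycle_length"] = protocol.cycle_length
        f.attrs["n_beats"] = protocol.n_beats
        f.attrs["onset"] = protocol.onset
        f.attrs["sample_interval"] = library.standard.sample_interval
        if library.step is not None:
            f.attrs["step"] = library.step
        f.create_dataset("standard/vm", data=library.standard.vm)
        for cond, trace in library.variants:
            f.create_dataset(
                f"variants/{cond.channel_name}/{cond.scale:.6f}/vm",
                data=trace.vm)
        if library.failures:
            fail = np.array([[c.channel_index, c.scale]
                             for c, _ in library.failures])
            f.create_dataset("failures", data=fail)


def load_library(path: str | Path) -> APLibrary:
    import h5py

    with h5py.File(path, "r") as f:
        protocol = StimulusProtocol(
            amplitude=float(f.attrs["amplitude"]),
            duration=float(f.attrs["duration"]),
            cycle_length=float(f.attrs["cycle_length"]),
            n_beats=int(f.attrs["n_beats"]),
            onset=float(f.attrs["onset"]))
        si = float(f.attrs["sample_interval"])
        step = float(f.attrs["step"]) if "step" in f.attrs else None
        vm = f["standard/vm"][:]
        time = np.arange(vm.size) * si
        standard = APTrace(time=time, vm=vm, protocol=protocol,
                           sample_interval=si)
        variants = []
        if "variants" in f:
            for ch_name in f["variants"]:
                ch = CONDUCTANCE_NAMES.index(ch_name)
                for scale_key in f[f"variants/{ch_name}"]:
                    scale = float(scale_key)
                    v = f[f"variants/{ch_name}/{scale_key}/vm"][:]
                    variants.append((
                        ScanCondition(ch, scale),
                        APTrace(time=time, vm=v, protocol=protocol,
                                sample_interval=si, channel_index=ch,
                                scale=scale)))
        failures = []
        if "failures" in f:
            for ch_i, sc in f["failures"][:]:
                failures.append((ScanCondition(int(ch_i), float(sc)),
                                 "recorded failure"))
    variants.sort(key=lambda cv: (cv[0].channel_index, cv[0].scale))
    return APLibrary(standard=standard, variants=variants, step=step,
                     failures=failures)
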
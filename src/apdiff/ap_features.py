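"""AP difference shapes, APD measurement, and per-channel APD statistics.

The classifier input is the elementwise difference standard - variant on
the prediction window (the last paced beat, 500 samples at 2 ms for a
1,000-ms cycle).  APD is measured as APD90: time from maximum upstroke
velocity to 90% repolarization of the beat amplitude (peak minus
pre-stimulus diastolic potential), with linear interpolation of the
crossing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cell_model import APTrace, CONDUCTANCE_NAMES
from .scan_generator import APLibrary, ScanCondition

__all__ = ["DifferenceSample", "APDStatRow", "ap_difference", "measure_apd",
           "apd_statistics", "difference_dataset", "NO_AP"]

#: Sentinel returned by measure_apd when no action potential was elicited.
NO_AP = float("nan")

# Peak below this voltage means the stimulus failed to elicit an AP.
_UPSTROKE_THRESHOLD_MV = -20.0


@dataclass
class DifferenceSample:
    """Difference vector (standard - variant, mV) with its class label."""

    diff: np.ndarray
    label: int
    condition: ScanCondition | None = None

    def __post_init__(self) -> None:
        self.diff = np.asarray(self.diff, dtype=float)
        if not np.all(np.isfinite(self.diff)):
            raise ValueError("difference vector contains non-finite entries")
        if not 0 <= self.label <= 9:
            raise ValueError("label must be 0-9")


@dataclass(frozen=True)
class APDStatRow:
    """One row of the per-channel APD summary table."""

    channel: str
    mean_apd: float
    sd_apd: float
    p_value: float
    n_excluded: int = 0


def ap_difference(standard: APTrace, variant: APTrace,
                  window: str = "last_beat") -> DifferenceSample:
    """Elementwise standard - variant on the prediction window.

    ``window`` is ``"last_beat"`` (default) or ``"all"``.  Both traces
    must share the sampling grid; no resampling is performed.
    """
    if standard.sample_interval != variant.sample_interval \
            or standard.vm.shape != variant.vm.shape:
        raise ValueError("traces are on different sampling grids")
    if window == "last_beat":
        _, v_std = standard.last_beat()
        _, v_var = variant.last_beat()
    elif window == "all":
        v_std, v_var = standard.vm, variant.vm
    else:
        raise ValueError(f"unknown window {window!r}")
    cond = None
    label = 0
    if variant.channel_index is not None:
        label = variant.channel_index
        cond = ScanCondition(variant.channel_index, variant.scale)
    return DifferenceSample(diff=v_std - v_var, label=label, condition=cond)


def measure_apd(trace: APTrace, beat_index: int = -1,
                repol_fraction: float = 0.9) -> float:
    """APD of one beat: max-upstroke-velocity time to fractional repolarization.

    Returns the ``NO_AP`` sentinel (NaN) when the beat contains no
    upstroke (peak below -20 mV), so scans over extreme scales can
    tabulate loss-of-excitability conditions without raising.
    """
    if not 0 < repol_fraction < 1:
        raise ValueError("repol_fraction must be in (0, 1)")
    t, v = trace.beat(beat_index)
    onset = trace.protocol.onset
    si = trace.sample_interval
    peak_idx = int(np.argmax(v))
    peak = v[peak_idx]
    if peak < _UPSTROKE_THRESHOLD_MV:
        return NO_AP
    # diastolic level: mean of the pre-stimulus segment (or first sample
    # when the stimulus fires at the very start of the cycle)
    n_pre = int(onset / si)
    diastolic = float(np.mean(v[:n_pre])) if n_pre > 0 else float(v[0])
    amplitude = peak - diastolic
    if amplitude <= 0:
        return NO_AP
    v_repol = peak - repol_fraction * amplitude
    # upstroke: maximum dV/dt before (and including) the peak
    dv = np.gradient(v, t)
    t_up = t[int(np.argmax(dv[:peak_idx + 1]))]
    # first downward crossing of the repolarization level after the peak
    after = np.arange(peak_idx + 1, v.size)
    below = after[v[after] <= v_repol]
    if below.size == 0:
        return NO_AP
    i1 = below[0]
    i0 = i1 - 1
    if v[i1] == v[i0]:
        t_cross = t[i1]
    else:
        t_cross = t[i0] + (v_repol - v[i0]) * (t[i1] - t[i0]) / (v[i1] - v[i0])
    return float(t_cross - t_up)


def apd_statistics(library: APLibrary,
                   repol_fraction: float = 0.9) -> list[APDStatRow]:
    """Per-channel mean/SD of last-beat APD and p-value vs the standard.

    The p-value is a one-sample two-sided t-test of each channel's
    variant APDs against the standard APD value.  Failed-AP conditions
    are excluded from the statistics; their count is reported per row.
    """
    standard_apd = measure_apd(library.standard,
                               repol_fraction=repol_fraction)
    per_channel: dict[int, list[float]] = {i: [] for i in range(10)}
    excluded = {i: 0 for i in range(10)}
    for cond, trace in library.variants:
        apd = measure_apd(trace, repol_fraction=repol_fraction)
        if np.isnan(apd):
            excluded[cond.channel_index] += 1
        else:
            per_channel[cond.channel_index].append(apd)
    rows = []
    for ch, name in enumerate(CONDUCTANCE_NAMES):
        vals = np.array(per_channel[ch])
        if vals.size == 0:
            rows.append(APDStatRow(name, NO_AP, NO_AP, NO_AP, excluded[ch]))
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        if vals.size > 1 and sd > 0:
            p = float(stats.ttest_1samp(vals, standard_apd).pvalue)
        else:
            p = 1.0 if np.allclose(vals, standard_apd) else 0.0
        rows.append(APDStatRow(name, mean, sd, p, excluded[ch]))
    return rows


def difference_dataset(library: APLibrary,
                       window: str = "last_beat"
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Stack all library differences into (X, y) arrays for training."""
    X = []
    y = []
    for cond, trace in library.variants:
        sample = ap_difference(library.standard, trace, window=window)
        X.append(sample.diff)
        y.append(sample.label)
    return np.asarray(X), np.asarray(y, dtype=int)
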
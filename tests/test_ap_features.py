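"""Difference shapes, APD measurement and per-channel statistics."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apdiff.ap_features import (
    ap_difference,
    apd_statistics,
    difference_dataset,
    measure_apd,
)
from apdiff.cell_model import APTrace, StimulusProtocol
from apdiff.scan_generator import APLibrary, ScanCondition


def _synthetic_trace(vm, cl=1000.0, si=2.0, onset=50.0):
    prot = StimulusProtocol(cycle_length=cl, n_beats=1, onset=onset)
    time = np.arange(len(vm)) * si
    return APTrace(time=time, vm=np.asarray(vm, float), protocol=prot,
                   sample_interval=si)


def _triangle_trace():
    """Instantaneous rise -80 -> +40 mV at the stimulus, linear fall to
    -80 over 300 ms, flat elsewhere; 1,000-ms cycle sampled at 2 ms."""
    si = 2.0
    n = 500
    vm = np.full(n, -80.0)
    i0 = int(50 / si)
    fall = int(300 / si)
    vm[i0:i0 + fall] = np.linspace(40.0, -80.0, fall, endpoint=False)
    return _synthetic_trace(vm)


def test_triangle_apd90_is_270_ms():
    # 90% of the 120-mV amplitude is recovered at 0.9 x 300 ms
    apd = measure_apd(_triangle_trace())
    assert apd == pytest.approx(270.0, abs=2.0)


def test_flat_trace_returns_no_ap_sentinel():
    flat = _synthetic_trace(np.full(500, -86.0))
    assert np.isnan(measure_apd(flat))


def test_apd_invariant_under_constant_shift():
    tr = _triangle_trace()
    shifted = _synthetic_trace(tr.vm + 17.0)
    assert measure_apd(shifted) == pytest.approx(measure_apd(tr), abs=1e-9)


def test_apd_rejects_bad_fraction():
    with pytest.raises(ValueError):
        measure_apd(_triangle_trace(), repol_fraction=1.5)


def test_difference_identical_traces_is_zero(standard_trace_fixture):
    d = ap_difference(standard_trace_fixture, standard_trace_fixture)
    assert np.all(d.diff == 0.0)
    assert d.diff.size == standard_trace_fixture.samples_per_beat


def test_difference_constant_offset():
    tr = _triangle_trace()
    shifted = _synthetic_trace(tr.vm + 3.0)
    d = ap_difference(tr, shifted)
    assert np.allclose(d.diff, -3.0)


def test_difference_antisymmetry(standard_trace_fixture, fixture_library):
    _, variant = fixture_library.variants[7]
    ab = ap_difference(standard_trace_fixture, variant).diff
    ba = ap_difference(variant, standard_trace_fixture).diff
    assert np.allclose(ab, -ba)


@settings(deadline=None, max_examples=20)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_difference_antisymmetry_property(seed):
    rng = np.random.default_rng(seed)
    a = _synthetic_trace(rng.normal(-40, 30, 500))
    b = _synthetic_trace(rng.normal(-40, 30, 500))
    assert np.array_equal(ap_difference(a, b).diff,
                          -ap_difference(b, a).diff)


def test_difference_grid_mismatch_raises(standard_trace_fixture):
    other = _synthetic_trace(np.full(250, -80.0), si=4.0)
    with pytest.raises(ValueError):
        ap_difference(standard_trace_fixture, other)


def test_reduced_gna_difference_peaks_in_upstroke_window(fixture_library):
    # lowered Na+ conductance slows the upstroke: the difference shape is
    # dominated by a peak in the phase-0/1 region just after the stimulus
    cond = ScanCondition(3, 0.25)   # GNa x 0.25
    variant = next(t for c, t in fixture_library.variants if c == cond)
    d = ap_difference(fixture_library.standard, variant)
    t_rel = np.arange(d.diff.size) * 2.0
    onset = fixture_library.standard.protocol.onset
    peak_t = t_rel[int(np.argmax(np.abs(d.diff)))]
    assert onset <= peak_t <= onset + 50.0


def test_difference_dataset_shapes_and_labels(fixture_library):
    X, y = difference_dataset(fixture_library)
    assert X.shape == (60, fixture_library.standard.samples_per_beat)
    assert set(y) == set(range(10))


def test_apd_statistics_degenerate_library(standard_trace_fixture):
    # all variants identical to the standard: mean = standard APD, SD = 0
    variants = []
    for ch in range(10):
        for scale in (0.5, 1.5):
            tr = copy.copy(standard_trace_fixture)
            tr.channel_index = ch
            tr.scale = scale
            variants.append((ScanCondition(ch, scale), tr))
    lib = APLibrary(standard=standard_trace_fixture, variants=variants)
    rows = apd_statistics(lib)
    std_apd = measure_apd(standard_trace_fixture)
    for row in rows:
        assert row.mean_apd == pytest.approx(std_apd)
        assert row.sd_apd == 0.0
        assert row.n_excluded == 0


def test_apd_statistics_reports_exclusions(standard_trace_fixture):
    flat = _synthetic_trace(np.full(
        standard_trace_fixture.vm.size, -86.0),
        cl=standard_trace_fixture.protocol.cycle_length)
    flat.protocol = standard_trace_fixture.protocol
    flat.channel_index, flat.scale = 3, 0.01
    ok = copy.copy(standard_trace_fixture)
    ok.channel_index, ok.scale = 3, 0.5
    lib = APLibrary(standard=standard_trace_fixture,
                    variants=[(ScanCondition(3, 0.01), flat),
                              (ScanCondition(3, 0.5), ok)])
    rows = apd_statistics(lib)
    assert rows[3].n_excluded == 1
    assert np.isfinite(rows[3].mean_apd)
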
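"""Passive properties, spike detection, AP features, stimulus choice, QC."""

import math

import numpy as np
import pandas as pd
import pytest

from multipatch.errors import (
    FeatureUndefinedError,
    InvalidArgumentError,
    StimulusNotFoundError,
)
from multipatch.ephys import (
    ap_features,
    detect_spikes,
    measure_resistances,
    qc_filter,
    resting_potential,
    select_rheobase_stimulus,
)
from multipatch.synthgen import CellParams, Trace, ap_train, vc_test_pulse


def test_resting_potential_constant_and_noisy():
    flat = Trace(np.full(4000, -65.0))
    assert resting_potential(flat) == -65.0
    rng = np.random.default_rng(0)
    noisy = Trace(-65.0 + 0.2 * rng.standard_normal(4000))
    n = 2000  # 100 ms at 20 kHz
    assert resting_potential(noisy) == pytest.approx(-65.0, abs=3 * 0.2 / math.sqrt(n))


def test_resting_potential_window_validation():
    with pytest.raises(InvalidArgumentError):
        resting_potential(Trace(np.zeros(100)), baseline_ms=100.0)
    with pytest.raises(InvalidArgumentError):
        resting_potential(Trace(np.zeros(4000), clamp_mode="voltage"))


def test_resistances_recovered_from_noiseless_pulse():
    p = vc_test_pulse(CellParams(ra_mohm=10.0, rin_mohm=90.0, cm_pf=100.0))
    props = measure_resistances(p)
    assert props.ok
    assert props.ra_mohm == pytest.approx(10.0, rel=0.05)
    assert props.rin_mohm == pytest.approx(90.0, rel=0.02)


def test_resistances_series_correction_toggle():
    p = vc_test_pulse(CellParams(ra_mohm=10.0, rin_mohm=90.0, cm_pf=100.0))
    raw = measure_resistances(p, series_corrected=False)
    assert raw.rin_mohm == pytest.approx(100.0, rel=0.02)  # total = Ra + Rin


def test_resistances_degenerate_no_transient_flagged():
    # pure-resistor response: no charging transient, Ra/Rin not separable
    n = 2000
    samples = np.concatenate([np.zeros(n), np.full(4000, 1000.0), np.zeros(n)])
    from multipatch.synthgen import TestPulse

    pulse = TestPulse(Trace(samples, clamp_mode="voltage"), onset_s=n / 20000.0,
                      width_s=0.2, dv_mv=10.0)
    props = measure_resistances(pulse)
    assert "no_transient" in props.flags
    assert math.isinf(props.rin_mohm)


def test_resistances_nonphysical_flagged():
    n = 2000
    samples = np.concatenate([np.zeros(n), np.full(4000, -50.0), np.zeros(n)])
    from multipatch.synthgen import TestPulse

    pulse = TestPulse(Trace(samples, clamp_mode="voltage"), onset_s=0.1,
                      width_s=0.2, dv_mv=10.0)
    props = measure_resistances(pulse)
    assert "non_physical_steady_state" in props.flags
    assert math.isnan(props.ra_mohm)


def test_ra_degrades_as_tau_shrinks_below_sampling():
    """Peak sampling misses more of the transient the faster it decays."""
    errs = []
    for cm in (200.0, 50.0, 10.0, 2.0):
        p = vc_test_pulse(CellParams(ra_mohm=20.0, rin_mohm=100.0, cm_pf=cm),
                          noise_sd_pa=0.0)
        props = measure_resistances(p)
        errs.append(abs(props.ra_mohm - 20.0) / 20.0)
    assert errs == sorted(errs)


def test_detect_spikes_on_train(ap_slot):
    trace, spikes, _ = ap_slot
    idx = detect_spikes(trace)
    assert len(idx) == 4
    assert np.allclose(idx / trace.rate_hz, spikes, atol=1.0 / trace.rate_hz)


def test_detect_spikes_flat_and_subthreshold():
    assert detect_spikes(Trace(np.full(2000, -65.0))).size == 0
    # subthreshold PSP bumps peaking below 0 mV are not spikes
    from multipatch.synthgen import psp_kernel

    bump = np.full(4000, -65.0)
    bump[1000:1000 + 2000] += 10.0 * psp_kernel(2.0, 20.0, duration_ms=100.0).samples[:2000]
    assert detect_spikes(Trace(bump)).size == 0


def test_ap_features_match_generator_ground_truth(ap_slot):
    trace, _, gts = ap_slot
    idx = detect_spikes(trace)
    for spike_idx, gt in zip(idx, gts):
        f = ap_features(trace, int(spike_idx))
        assert abs(f.threshold_idx - gt["threshold_idx"]) <= 1
        assert f.threshold_mv == pytest.approx(gt["threshold_mv"], abs=1.0)
        assert f.half_width_ms == pytest.approx(gt["half_width_ms"],
                                                abs=1000.0 / trace.rate_hz)
        assert f.amplitude_mv == pytest.approx(f.peak_mv - f.threshold_mv)
        assert f.max_depol_rate_mv_ms > 0 > f.max_repol_rate_mv_ms


def test_ap_features_triangular_spike_closed_form():
    """Symmetric triangular spike: half-width equals half the base width."""
    rate = 20000.0
    up = np.linspace(-60.0, 40.0, 101)  # 5 ms rise at 20 mV/ms
    down = up[::-1][1:]
    v = np.concatenate([np.full(200, -60.0), up, down, np.full(200, -60.0)])
    trace = Trace(v, rate_hz=rate)
    peak_idx = int(np.argmax(v))
    f = ap_features(trace, peak_idx)
    # dV/dt = 20 mV/ms everywhere on the flank: threshold is the flank start
    assert f.threshold_mv == pytest.approx(-60.0, abs=2.0)
    base_ms = 200 / rate * 1000.0
    assert f.half_width_ms == pytest.approx(base_ms / 2.0, rel=0.05)


def test_ap_features_undefined_without_crossing():
    slow = Trace(np.concatenate([np.full(100, -60.0),
                                 np.linspace(-60, -50, 400),
                                 np.full(100, -50.0)]))
    with pytest.raises(FeatureUndefinedError):
        ap_features(slow, 350)


def grid(spiking):
    amps = np.arange(0.5, 4.01, 0.5)
    return {(round(float(a), 1), dur): bool(fn(a, dur))
            for a in amps for dur, fn in spiking.items()}


def test_rheobase_second_lowest_amplitude():
    g = grid({1.0: lambda a, d: a >= 2.0})
    assert select_rheobase_stimulus(g) == (2.5, 1.0)


def test_rheobase_caps_at_max_amplitude():
    g = grid({1.0: lambda a, d: a >= 4.0})
    assert select_rheobase_stimulus(g) == (4.0, 1.0)


def test_rheobase_duration_escalation():
    g = grid({1.0: lambda a, d: False, 2.0: lambda a, d: a >= 1.5})
    assert select_rheobase_stimulus(g) == (2.0, 2.0)


def test_rheobase_not_found():
    g = grid({1.0: lambda a, d: False})
    with pytest.raises(StimulusNotFoundError):
        select_rheobase_stimulus(g)


QC_TABLE = pd.DataFrame({
    "cell_id": list("abcde"),
    "rmp_mV": [-65.0, -58.0, -70.0, -61.0, -60.0],
    "ra_MOhm": [20.0, 20.0, 129.0, 39.0, 40.0],
})


def test_qc_boundary_semantics():
    report = qc_filter(QC_TABLE)
    t = report.table.set_index("cell_id")
    assert report.n_included == 2
    assert t.loc["a", "included"] and t.loc["d", "included"]
    assert t.loc["b", "exclusion_reason"] == "rmp_above_cutoff"
    assert t.loc["c", "exclusion_reason"] == "high_access_resistance"
    # rmp = -60 passes ("more positive than"), Ra = 40 fails ("below 40")
    assert t.loc["e", "exclusion_reason"] == "high_access_resistance"


def test_qc_idempotent_and_order_independent():
    once = qc_filter(QC_TABLE).table
    twice = qc_filter(once).table
    assert list(once["included"]) == list(twice["included"])
    shuffled = qc_filter(QC_TABLE.sample(frac=1.0, random_state=3)).table
    merged = shuffled.set_index("cell_id")["included"]
    for cid in QC_TABLE["cell_id"]:
        assert merged[cid] == once.set_index("cell_id")["included"][cid]


def test_qc_missing_columns_rejected():
    with pytest.raises(InvalidArgumentError):
        qc_filter(pd.DataFrame({"rmp_mV": [-65.0]}))


def test_threshold_recovery_across_cell_diversity():
    """10 mV/ms threshold and half-width match bookkeeping over 100 APs."""
    rng = np.random.default_rng(123)
    checked = 0
    while checked < 100:
        params = CellParams(
            ap_threshold_mv=float(rng.uniform(-48.0, -38.0)),
            ap_peak_mv=float(rng.uniform(25.0, 50.0)),
            tau_up_ms=float(rng.uniform(0.15, 0.3)),
            tau_down_ms=float(rng.uniform(0.4, 0.8)),
        )
        trace, _, gts = ap_train(params, n_pulses=1, duration_s=0.1)
        idx = detect_spikes(trace)
        assert len(idx) == 1
        f = ap_features(trace, int(idx[0]))
        assert abs(f.threshold_idx - gts[0]["threshold_idx"]) <= 1
        assert f.half_width_ms == pytest.approx(gts[0]["half_width_ms"],
                                                abs=1000.0 / trace.rate_hz)
        checked += 1
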
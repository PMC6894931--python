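"""Template-scaling detection, sweep averaging and connection calling."""

import numpy as np
import pytest

from multipatch.detect import (
    average_sweeps,
    build_connectivity,
    call_connection,
    cb_criterion,
    detect_spont_events,
    screen_connections,
)
from multipatch.errors import CoverageMismatchError, InvalidArgumentError
from multipatch.planner import SessionPlan
from multipatch.synthgen import Trace, psp_kernel, spont_trace, synth_cluster

TEMPLATE = psp_kernel(2.0, 20.0, duration_ms=25.0)


def lstsq_oracle(y, w, k):
    """Independent per-offset ordinary least squares fit."""
    N = w.size
    A = np.column_stack([w, np.ones(N)])
    coef, _, _, _ = np.linalg.lstsq(A, y[k : k + N], rcond=None)
    resid = y[k : k + N] - A @ coef
    sse = float(resid @ resid)
    se = np.sqrt(sse / (N - 1))
    return coef[0], coef[1], sse, coef[0] / se if se > 0 else np.inf


def test_cb_matches_regression_oracle_everywhere():
    rng = np.random.default_rng(5)
    y = -65.0 + 0.2 * rng.standard_normal(1500)
    tmpl = psp_kernel(2.0, 20.0, duration_ms=10.0)
    series = cb_criterion(Trace(y), tmpl)
    assert len(series) == 1500 - tmpl.samples.size + 1
    for k in range(0, len(series), 13):
        scale, offset, sse, crit = lstsq_oracle(y, tmpl.samples, k)
        assert series.scale[k] == pytest.approx(scale, rel=1e-9, abs=1e-12)
        assert series.offset[k] == pytest.approx(offset, rel=1e-9)
        assert series.sse[k] == pytest.approx(sse, rel=1e-9, abs=1e-12)
        assert series.criterion[k] == pytest.approx(crit, rel=1e-9)


def test_cb_recovers_scale_and_offset():
    w = TEMPLATE.samples
    y = np.concatenate([3.0 * w + 7.0, np.full(200, 7.0)])
    series = cb_criterion(Trace(y), TEMPLATE)
    assert series.scale[0] == pytest.approx(3.0, rel=1e-9)
    assert series.offset[0] == pytest.approx(7.0, rel=1e-9)
    # perfect fit: capped sentinel criterion, at the matching offset
    assert series.criterion[0] >= 1e11
    assert int(np.argmax(series.criterion)) == 0


def test_cb_template_longer_than_trace_rejected():
    with pytest.raises(InvalidArgumentError):
        cb_criterion(Trace(np.zeros(10)), TEMPLATE)


def test_cb_translation_equivariance():
    rng = np.random.default_rng(9)
    y = 0.3 * rng.standard_normal(3000)
    y[800:800 + TEMPLATE.samples.size] += TEMPLATE.samples
    shift = 250
    series_a = cb_criterion(Trace(y), TEMPLATE)
    series_b = cb_criterion(Trace(np.r_[np.zeros(shift), y]), TEMPLATE)
    assert np.allclose(series_b.criterion[shift:], series_a.criterion[: len(series_a)],
                       atol=1e-6)


def test_spont_detection_recall_and_precision():
    tr, events = spont_trace(5.0, seed=0, n_events=10, amp_min_mv=0.6,
                             min_separation_ms=20.0)
    found = detect_spont_events(tr, TEMPLATE)
    truth = np.array([t for t, _ in events])
    matched = sum(1 for t in truth if found.n_events
                  and np.abs(found.times_s - t).min() < 0.005)
    false_pos = sum(1 for t in found.times_s if not np.any(np.abs(truth - t) < 0.005))
    assert matched >= 9
    assert false_pos <= 1


def test_spont_detection_noise_only_quiet():
    tr, _ = spont_trace(0.0, seed=3)
    assert detect_spont_events(tr, TEMPLATE).n_events == 0


def test_spont_amplitudes_and_frequency_exact_without_noise():
    tr, events = spont_trace(0.0, n_events=3, amp_mean_mv=1.0, amp_sd_mv=0.0,
                             noise_sd_mv=0.0, min_separation_ms=100.0, seed=1)
    found = detect_spont_events(tr, TEMPLATE)
    assert found.n_events == 3
    assert np.allclose(found.amplitudes_mv, 1.0, atol=0.05)
    assert found.median_amplitude_mv == pytest.approx(1.0, abs=0.05)
    assert found.mean_frequency_hz == pytest.approx(1.5)


def test_average_sweeps_identities():
    data = np.stack([np.full((2, 100), v) for v in (1.0, 1.0, 1.0)])
    from multipatch.synthgen import StimProtocol, SweepSet

    proto = StimProtocol(n_cells=2, slot_ms=200.0, gap_ms=0.0)
    sw = SweepSet(data=data, rate_hz=20000.0, protocol=proto)
    assert np.allclose(average_sweeps(sw, 0).samples, 1.0)
    data2 = np.stack([np.full((2, 100), 1.0), np.full((2, 100), -1.0)])
    sw2 = SweepSet(data=data2, rate_hz=20000.0, protocol=proto)
    assert np.allclose(average_sweeps(sw2, 1).samples, 0.0)


def test_call_connection_flat_average_not_connected():
    avg = Trace(np.full(8000, -60.0))
    call = call_connection(avg, [0.2])
    assert not call.connected
    assert call.amplitude_mv == pytest.approx(0.0, abs=1e-9)


def test_call_connection_detects_psp_with_truthful_amplitude():
    rng = np.random.default_rng(2)
    rate = 20000.0
    avg = 0.05 * rng.standard_normal(8000)
    t_sp = 0.2
    lat = 1.5e-3
    i0 = int((t_sp + lat) * rate)
    k = psp_kernel(2.0, 20.0, duration_ms=60.0).samples
    avg[i0 : i0 + k.size] += 0.5 * k
    call = call_connection(Trace(avg), [t_sp])
    assert call.connected
    # the window extremum is positively biased by ~2 noise SDs (max statistic)
    assert call.amplitude_mv == pytest.approx(0.5, abs=0.15)
    assert call.latency_ms == pytest.approx(2.0, abs=0.7)  # latency + 10% rise
    assert call.snr >= call.k_sd


def test_call_connection_latency_gate_rejects_polysynaptic():
    rate = 20000.0
    avg = np.zeros(8000)
    t_sp = 0.2
    i0 = int((t_sp + 8e-3) * rate)  # 8 ms: outside the monosynaptic window
    k = psp_kernel(2.0, 20.0, duration_ms=60.0).samples
    avg[i0 : i0 + k.size] += 0.5 * k
    call = call_connection(Trace(avg), [t_sp])
    assert not call.connected
    assert call.latency_ms > 5.0


def test_call_connection_window_validation():
    avg = Trace(np.zeros(3000))
    with pytest.raises(InvalidArgumentError):
        call_connection(avg, [0.145])  # response window runs off the trace
    with pytest.raises(InvalidArgumentError):
        call_connection(avg, [])


def test_screen_connections_recovers_ground_truth(default_cluster):
    sweeps, gt = default_cluster
    calls = screen_connections(sweeps)
    called = np.zeros_like(gt.adjacency)
    for c in calls:
        called[c.pre, c.post] = c.connected
    assert np.array_equal(called, gt.adjacency)


def test_recall_improves_with_sweep_count():
    """More sweeps never hurt recall at fixed detection settings."""
    recalls = []
    for n_sweeps in (5, 15, 40):
        hits = total = 0
        for seed in range(4):
            sweeps, gt = synth_cluster(n_cells=4, p_conn=0.5, n_sweeps=n_sweeps,
                                       seed=seed, amp_min_mv=0.12,
                                       amp_dist=(0.15, 0.05), noise_sd_mv=0.3)
            calls = screen_connections(sweeps)
            for c in calls:
                if gt.adjacency[c.pre, c.post]:
                    total += 1
                    hits += bool(c.connected)
        recalls.append(hits / max(total, 1))
    assert recalls[0] <= recalls[1] + 0.1
    assert recalls[-1] >= recalls[0]
    # amplitudes sit deliberately near the detection floor; averaging 40
    # sweeps must still resolve the large majority
    assert recalls[-1] >= 0.8


def test_build_connectivity_counts_and_coverage(small_cluster):
    sweeps, gt = small_cluster
    calls = screen_connections(sweeps)
    plan = SessionPlan(((3, 0),), n_pipettes=3)
    result = build_connectivity(calls, plan, positions=gt.soma_positions_um)
    assert result.n_tested == 6
    assert np.all(result.connected <= result.tested)
    assert not np.any(np.diag(result.tested))
    df = result.to_edge_dataframe()
    assert len(df) == 6
    assert (df["distance_um"] >= 0).all()
    with pytest.raises(CoverageMismatchError) as err:
        build_connectivity(calls[:-1], plan)
    assert err.value.missing  # names the absent pair


def test_build_connectivity_multi_session_totals():
    plan = SessionPlan(((8, 0), (4, 4), (5, 3)))
    from multipatch.detect import ConnectionCall
    from multipatch.planner import plan_summary

    summary = plan_summary(plan)
    calls = [
        ConnectionCall(pre=i, post=j, connected=False, amplitude_mv=0.0,
                       latency_ms=np.nan, snr=0.0, baseline_sd_mv=0.01)
        for i, j in np.argwhere(summary.tested_mask)
    ]
    result = build_connectivity(calls, plan)
    assert result.n_tested == 150
    assert result.cell_ids == summary.cell_ids
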
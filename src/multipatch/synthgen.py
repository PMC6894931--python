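"""Seeded synthetic electrophysiology for testing the analysis pipeline.

Emulates the recording conditions of a multipatch connectivity screen:
current-clamp traces sampled at 20 kHz with cells held near -60 mV, a
stimulation slot per cell of 4 suprathreshold current pulses at 20 Hz
(1-4 nA, 1-3 ms), unitary postsynaptic potentials with double-exponential
kinetics and trial-to-trial amplitude variability over 30-50 sweeps,
spontaneous EPSPs in 2 s resting traces, and 200 ms / 10 mV voltage-clamp
test pulses from a single-compartment cell with known access and input
resistance.  Everything is reproducible from one root seed via per-component
child streams (numpy SeedSequence spawning, in a fixed documented order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

from .errors import InvalidArgumentError, InvalidKineticsError

__all__ = [
    "Trace",
    "StimProtocol",
    "CellParams",
    "TestPulse",
    "GroundTruthNetwork",
    "SweepSet",
    "psp_kernel",
    "psp_peak_time_ms",
    "vc_test_pulse",
    "ap_train",
    "spont_trace",
    "synth_cluster",
]

DEFAULT_RATE_HZ = 20000.0


@dataclass
class Trace:
    """A sampled recording: mV in current clamp, pA in voltage clamp."""

    samples: np.ndarray
    rate_hz: float = DEFAULT_RATE_HZ
    clamp_mode: str = "current"  # "current" | "voltage"
    t0_s: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate_hz <= 0:
            raise InvalidArgumentError("sampling rate must be > 0")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise InvalidArgumentError("trace must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidArgumentError("trace samples must be finite")
        if self.clamp_mode not in ("current", "voltage"):
            raise InvalidArgumentError(f"unknown clamp mode {self.clamp_mode!r}")

    @property
    def dt_s(self) -> float:
        return 1.0 / self.rate_hz

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.samples.size) / self.rate_hz

    def index_of(self, t_s: float) -> int:
        return int(round((t_s - self.t0_s) * self.rate_hz))

    def copy(self) -> "Trace":
        return replace(self, samples=self.samples.copy())


@dataclass(frozen=True)
class StimProtocol:
    """Per-cell stimulation slots for the connectivity screen."""

    n_cells: int
    n_pulses: int = 4
    pulse_rate_hz: float = 20.0
    amplitude_na: float = 2.0
    width_ms: float = 2.0
    slot_ms: float = 200.0  # window containing the 4-pulse train
    gap_ms: float = 250.0  # quiet interval between consecutive slots

    def __post_init__(self):
        if self.amplitude_na < 0 or self.width_ms <= 0:
            raise InvalidArgumentError("stimulus amplitude/width must be positive")
        if self.n_pulses * 1000.0 / self.pulse_rate_hz > self.slot_ms + 1e-9:
            raise InvalidArgumentError("pulse train does not fit in the slot")

    def slot_onset_s(self, cell: int) -> float:
        return cell * (self.slot_ms + self.gap_ms) / 1000.0

    def pulse_onsets_s(self, cell: int) -> np.ndarray:
        return self.slot_onset_s(cell) + np.arange(self.n_pulses) / self.pulse_rate_hz

    @property
    def sweep_duration_s(self) -> float:
        return self.n_cells * (self.slot_ms + self.gap_ms) / 1000.0


@dataclass(frozen=True)
class CellParams:
    """Single-compartment cell used by the generator."""

    rmp_mv: float = -65.0
    ra_mohm: float = 15.0
    rin_mohm: float = 100.0
    cm_pf: float = 120.0
    ap_threshold_mv: float = -42.0
    ap_peak_mv: float = 40.0
    ahp_mv: float = -68.0
    tau_up_ms: float = 0.2
    tau_down_ms: float = 0.5
    tau_recover_ms: float = 20.0
    holding_mv: float = -60.0
    rheobase_charge_na_ms: float = 2.0  # pulse fires iff amplitude*width >= this

    def __post_init__(self):
        if min(self.ra_mohm, self.rin_mohm, self.cm_pf) <= 0:
            raise InvalidArgumentError("Ra, Rin and Cm must be positive")
        if self.ap_threshold_mv >= self.ap_peak_mv:
            raise InvalidArgumentError("AP threshold must be below the peak")


def psp_kernel(
    rise_ms: float,
    decay_ms: float,
    rate_hz: float = DEFAULT_RATE_HZ,
    duration_ms: float | None = None,
) -> Trace:
    """Unit-peak difference-of-exponentials PSP kernel.

    k(t) = N * (exp(-t/decay) - exp(-t/rise)) with the analytic peak at
    t_peak = ln(decay/rise) * rise*decay / (decay - rise); the sampled
    waveform is normalised so its maximum is exactly 1.
    """
    if not 0 < rise_ms < decay_ms:
        raise InvalidKineticsError(f"need 0 < rise < decay, got {rise_ms}, {decay_ms}")
    if duration_ms is None:
        duration_ms = 10.0 * decay_ms
    n = max(int(round(duration_ms * rate_hz / 1000.0)), 2)
    t = np.arange(n) / rate_hz * 1000.0  # ms
    k = np.exp(-t / decay_ms) - np.exp(-t / rise_ms)
    k /= k.max()
    return Trace(k, rate_hz=rate_hz, clamp_mode="current")


def psp_peak_time_ms(rise_ms: float, decay_ms: float) -> float:
    """Closed-form time-to-peak of the double-exponential kernel, ms."""
    return math.log(decay_ms / rise_ms) * rise_ms * decay_ms / (decay_ms - rise_ms)


@dataclass
class TestPulse:
    """Voltage-clamp seal-test response with its pulse annotation."""

    trace: Trace
    onset_s: float
    width_s: float
    dv_mv: float
    params: CellParams | None = None


def vc_test_pulse(
    params: CellParams,
    dv_mv: float = 10.0,
    width_ms: float = 200.0,
    noise_sd_pa: float = 0.0,
    seed: int | None = None,
    rate_hz: float = DEFAULT_RATE_HZ,
    pre_ms: float = 50.0,
    post_ms: float = 50.0,
) -> TestPulse:
    """Current response (pA) of a single-compartment cell to a voltage step.

    With access resistance Ra in series with the membrane (Rin || Cm), a step
    of dV gives I(t) = dV/Ra * exp(-t/tau) + dV/(Ra+Rin) * (1 - exp(-t/tau)),
    tau = Cm * Ra*Rin/(Ra+Rin): an instantaneous Ohmic peak dV/Ra relaxing to
    the steady state dV/(Ra+Rin).  Units: mV/MOhm = nA, reported in pA.
    """
    dt_ms = 1000.0 / rate_hz
    n_pre = int(round(pre_ms / dt_ms))
    n_pulse = int(round(width_ms / dt_ms))
    n_post = int(round(post_ms / dt_ms))
    tau_ms = params.cm_pf * (params.ra_mohm * params.rin_mohm /
                             (params.ra_mohm + params.rin_mohm)) * 1e-3
    t = np.arange(n_pulse) * dt_ms
    i_peak_pa = 1000.0 * dv_mv / params.ra_mohm
    i_ss_pa = 1000.0 * dv_mv / (params.ra_mohm + params.rin_mohm)
    pulse = i_ss_pa + (i_peak_pa - i_ss_pa) * np.exp(-t / tau_ms)
    samples = np.concatenate([np.zeros(n_pre), pulse, np.zeros(n_post)])
    if noise_sd_pa > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, noise_sd_pa, samples.size)
    trace = Trace(samples, rate_hz=rate_hz, clamp_mode="voltage")
    return TestPulse(trace, onset_s=n_pre / rate_hz, width_s=n_pulse / rate_hz,
                     dv_mv=dv_mv, params=params)


# ---------------------------------------------------------------------------
# action potentials
# ---------------------------------------------------------------------------

def _ap_waveform(params: CellParams, rate_hz: float):
    """Stereotyped AP segment starting at baseline, plus analysis ground truth.

    Piecewise: an exponential foot whose dV/dt grows with voltage and equals
    10 mV/ms exactly when the voltage passes ``ap_threshold_mv``, a fast
    exponential upstroke to the peak, exponential repolarisation to the
    after-hyperpolarisation, and slow recovery toward baseline.  Ground
    truth (threshold sample by the 10 mV/ms rule, half-width at
    threshold + amplitude/2) is measured on this clean waveform with central
    differences, mirroring how an analysis routine sees the data.
    """
    dt_ms = 1000.0 / rate_hz
    v0 = params.holding_mv
    thr = params.ap_threshold_mv
    peak = params.ap_peak_mv
    # foot: dv/dt = k*(v - v_base), v_base slightly below holding so the foot
    # starts moving; k chosen so dv/dt = 10 mV/ms exactly at v = threshold
    delta = 2.0
    v_base = v0 - delta
    k = 10.0 / (thr - v_base)  # 1/ms
    t_foot = math.log((thr - v_base) / delta) / k
    n_foot = int(math.ceil(t_foot / dt_ms))
    tf = np.arange(n_foot) * dt_ms
    foot = v_base + delta * np.exp(k * tf)
    # upstroke: exponential approach to peak
    n_up = int(math.ceil(params.tau_up_ms * math.log((peak - thr) / 0.25) / dt_ms))
    tu = np.arange(1, n_up + 1) * dt_ms
    up = peak - (peak - thr) * np.exp(-tu / params.tau_up_ms)
    # repolarisation: exponential decay to AHP
    ahp = params.ahp_mv
    n_down = int(math.ceil(params.tau_down_ms * math.log((peak - ahp) / 0.25) / dt_ms))
    td = np.arange(1, n_down + 1) * dt_ms
    down = ahp + (peak - ahp) * np.exp(-td / params.tau_down_ms)
    # recovery back to holding
    n_rec = int(math.ceil(3.0 * params.tau_recover_ms / dt_ms))
    tr = np.arange(1, n_rec + 1) * dt_ms
    rec = v0 + (down[-1] - v0) * np.exp(-tr / params.tau_recover_ms)
    wave = np.concatenate([foot, up, down, rec])

    dvdt = np.gradient(wave, dt_ms)  # mV/ms, central differences
    peak_idx = int(np.argmax(wave))
    # first sample, walking back from the rising flank, at the start of the
    # contiguous run where dV/dt >= 10 mV/ms (start at the max-slope point:
    # the slope at the peak itself is ~0)
    i = int(np.argmax(dvdt[: peak_idx + 1]))
    while i > 0 and dvdt[i - 1] >= 10.0:
        i -= 1
    thr_idx = i
    thr_v = float(wave[thr_idx])
    amp = float(wave[peak_idx] - thr_v)
    half = thr_v + amp / 2.0
    above = np.nonzero(wave >= half)[0]
    half_width_ms = float((above[-1] - above[0] + 1) * dt_ms) if above.size else math.nan
    gt = {
        "threshold_idx": thr_idx,
        "threshold_mv": thr_v,
        "peak_idx": peak_idx,
        "peak_mv": float(wave[peak_idx]),
        "amplitude_mv": amp,
        "half_width_ms": half_width_ms,
    }
    return wave, gt


def ap_train(
    params: CellParams,
    n_pulses: int = 4,
    pulse_rate_hz: float = 20.0,
    amplitude_na: float = 2.0,
    width_ms: float = 2.0,
    onset_s: float = 0.025,
    duration_s: float = 0.25,
    rate_hz: float = DEFAULT_RATE_HZ,
    noise_sd_mv: float = 0.0,
    seed: int | None = None,
):
    """Current-clamp trace of the stimulation slot: one AP per effective pulse.

    A pulse elicits an AP iff its charge (amplitude * width) reaches the
    cell's rheobase charge; subthreshold stimuli leave the trace at holding.
    Returns ``(trace, spike_times_s, ground_truth)`` where the ground truth
    lists, per spike, the sample index at which dV/dt first reaches 10 mV/ms
    (the threshold by the slope rule) and the analytic feature values.
    """
    if amplitude_na < 0 or width_ms <= 0:
        raise InvalidArgumentError("stimulus amplitude/width must be valid")
    n = int(round(duration_s * rate_hz))
    v = np.full(n, params.holding_mv)
    spikes = []
    gts = []
    fires = amplitude_na * width_ms >= params.rheobase_charge_na_ms
    if fires and amplitude_na > 0:
        wave, gt = _ap_waveform(params, rate_hz)
        for p in range(n_pulses):
            t_on = onset_s + p / pulse_rate_hz
            i0 = int(round(t_on * rate_hz))
            seg = wave[: max(0, n - i0)]
            if seg.size == 0:
                continue
            v[i0 : i0 + seg.size] = seg
            spikes.append((i0 + gt["peak_idx"]) / rate_hz)
            g = dict(gt)
            g["threshold_idx"] = i0 + gt["threshold_idx"]
            g["peak_idx"] = i0 + gt["peak_idx"]
            gts.append(g)
    if noise_sd_mv > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd_mv, n)
    return Trace(v, rate_hz=rate_hz, clamp_mode="current"), np.array(spikes), gts


# ---------------------------------------------------------------------------
# spontaneous activity
# ---------------------------------------------------------------------------

def lowpass_6khz(samples: np.ndarray, rate_hz: float, cutoff_hz: float = 6000.0) -> np.ndarray:
    """Zero-phase low-pass mirroring the acquisition anti-alias filter.

    A symmetric (linear-phase) FIR applied with ``mode='same'`` keeps event
    timing exact while band-limiting the noise like the recording chain.
    """
    if cutoff_hz >= rate_hz / 2:
        return samples
    taps = _signal.firwin(81, cutoff_hz, fs=rate_hz).astype(samples.dtype)
    kernel = taps.reshape((1,) * (samples.ndim - 1) + (-1,))
    return _signal.oaconvolve(samples, kernel, mode="same", axes=-1)


def spont_trace(
    rate_hz_events: float,
    amp_mean_mv: float = 0.8,
    amp_sd_mv: float = 0.3,
    rise_ms: float = 2.0,
    decay_ms: float = 20.0,
    duration_s: float = 2.0,
    noise_sd_mv: float = 0.2,
    v_rest_mv: float = -65.0,
    seed: int | None = None,
    rate_hz: float = DEFAULT_RATE_HZ,
    lowpass: bool = True,
    n_events: int | None = None,
    amp_min_mv: float = 0.05,
    min_separation_ms: float = 0.0,
):
    """Resting-potential trace with Poisson spontaneous EPSPs.

    Event onsets are homogeneous Poisson at ``rate_hz_events``; each event
    adds a double-exponential kernel scaled by a positive normal amplitude
    (floored at ``amp_min_mv``).  ``n_events`` forces an exact event count
    and ``min_separation_ms`` a minimum onset spacing (for constructing
    resolvable-event test conditions).  Returns ``(trace, events)`` with
    events as (onset_s, amplitude_mv) pairs.
    """
    if rate_hz_events < 0:
        raise InvalidArgumentError("event rate must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    v = np.zeros(n)
    kernel = psp_kernel(rise_ms, decay_ms, rate_hz).samples
    if n_events is None:
        n_events = rng.poisson(rate_hz_events * duration_s)
    times = np.sort(rng.uniform(0.0, duration_s, n_events))
    if min_separation_ms > 0 and n_events > 1:
        for _ in range(1000):  # rejection sampling of the whole onset set
            if np.all(np.diff(times) >= min_separation_ms / 1000.0):
                break
            times = np.sort(rng.uniform(0.0, duration_s, n_events))
    amps = np.abs(rng.normal(amp_mean_mv, amp_sd_mv, n_events))
    for _ in range(1000):  # truncate by resampling (no atom at the floor)
        low = amps < amp_min_mv
        if not low.any():
            break
        amps[low] = np.abs(rng.normal(amp_mean_mv, amp_sd_mv, int(low.sum())))
    events = []
    for t_on, a in zip(times, amps):
        i0 = int(round(t_on * rate_hz))
        seg = kernel[: max(0, n - i0)]
        if seg.size == 0:
            continue
        v[i0 : i0 + seg.size] += a * seg
        events.append((float(t_on), float(a)))
    if noise_sd_mv > 0:
        v = v + rng.normal(0.0, noise_sd_mv, n)
        if lowpass:
            v = lowpass_6khz(v, rate_hz)
    return Trace(v + v_rest_mv, rate_hz=rate_hz, clamp_mode="current"), events


# ---------------------------------------------------------------------------
# full connectivity-screening clusters
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthNetwork:
    """Known directed connectivity behind a synthetic cluster."""

    adjacency: np.ndarray  # (n, n) bool, [pre, post], diagonal False
    amplitude_mv: np.ndarray  # PSP peak per edge, 0 where unconnected
    latency_ms: np.ndarray  # synaptic latency per edge
    rise_ms: float
    decay_ms: float
    trial_cv: float
    soma_positions_um: np.ndarray  # (n, 3)
    spike_times_s: list = field(default_factory=list)  # per presyn cell

    def __post_init__(self):
        n = self.adjacency.shape[0]
        if np.any(np.diag(self.adjacency)):
            raise InvalidArgumentError("self-connections are not modelled")
        on = self.adjacency
        if np.any(self.amplitude_mv[on] <= 0) or np.any(self.latency_ms[on] <= 0):
            raise InvalidArgumentError("connected edges need positive amplitude and latency")

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())


@dataclass
class SweepSet:
    """Rectangular grid of sweeps x channels from one recorded cluster."""

    data: np.ndarray  # (n_sweeps, n_channels, n_samples) mV
    rate_hz: float
    protocol: StimProtocol
    seed: int | None = None

    def __post_init__(self):
        if self.data.ndim != 3:
            raise InvalidArgumentError("sweep data must be (sweeps, channels, samples)")
        if self.data.shape[1] != self.protocol.n_cells:
            raise InvalidArgumentError("channel count must equal the cell count")

    @property
    def n_sweeps(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def trace(self, sweep: int, channel: int) -> Trace:
        return Trace(self.data[sweep, channel], rate_hz=self.rate_hz, clamp_mode="current")


def synth_cluster(
    n_cells: int = 8,
    p_conn: float = 0.15,
    amp_dist=(0.8, 0.3),
    latency_dist=(1.5, 0.3),
    rise_ms: float = 2.0,
    decay_ms: float = 20.0,
    trial_cv: float = 0.3,
    noise_sd_mv: float = 0.2,
    n_sweeps: int = 40,
    seed: int = 0,
    rate_hz: float = DEFAULT_RATE_HZ,
    protocol: StimProtocol | None = None,
    cell_params: CellParams | None = None,
    amp_min_mv: float = 0.2,
    lowpass: bool = True,
):
    """Generate a full connectivity-screening experiment with ground truth.

    Directed Erdos-Renyi adjacency at ``p_conn``; each presynaptic AP adds a
    latency-shifted PSP to every connected postsynaptic channel, scaled per
    sweep by a log-normal factor of coefficient of variation ``trial_cv``.
    Channels rest near -60 mV with white noise low-passed at 6 kHz.  Returns
    ``(SweepSet, GroundTruthNetwork)``, bit-reproducible from ``seed``.
    """
    if n_cells < 2:
        raise InvalidArgumentError("need at least 2 cells to probe a connection")
    if not 0.0 <= p_conn <= 1.0:
        raise InvalidArgumentError("p_conn must be in [0, 1]")
    protocol = protocol or StimProtocol(n_cells=n_cells)
    params = cell_params or CellParams()
    root = np.random.SeedSequence(seed)
    # fixed spawn order: adjacency, amplitudes/latencies, positions, trials, noise
    ss_adj, ss_edge, ss_pos, ss_trial, ss_noise = root.spawn(5)
    rng_adj = np.random.default_rng(ss_adj)
    rng_edge = np.random.default_rng(ss_edge)
    rng_pos = np.random.default_rng(ss_pos)
    rng_trial = np.random.default_rng(ss_trial)
    rng_noise = np.random.default_rng(ss_noise)

    adj = rng_adj.random((n_cells, n_cells)) < p_conn
    np.fill_diagonal(adj, False)
    amp = np.zeros((n_cells, n_cells))
    lat = np.zeros((n_cells, n_cells))
    amp_raw = np.abs(rng_edge.normal(amp_dist[0], amp_dist[1], (n_cells, n_cells)))
    for _ in range(1000):  # truncate by resampling (no atom at the floor)
        low = adj & (amp_raw < amp_min_mv)
        if not low.any():
            break
        amp_raw[low] = np.abs(rng_edge.normal(amp_dist[0], amp_dist[1], int(low.sum())))
    amp[adj] = amp_raw[adj]
    lat_raw = np.clip(rng_edge.normal(latency_dist[0], latency_dist[1], (n_cells, n_cells)),
                      0.8, 3.5)
    lat[adj] = lat_raw[adj]
    positions = np.column_stack([
        rng_pos.uniform(-100.0, 100.0, n_cells),
        rng_pos.uniform(-100.0, 100.0, n_cells),
        rng_pos.uniform(-80.0, -20.0, n_cells),
    ])

    n_samples = int(round(protocol.sweep_duration_s * rate_hz))
    kernel = psp_kernel(rise_ms, decay_ms, rate_hz).samples
    klen = kernel.size

    # presynaptic stimulation template per channel (deterministic)
    base = np.full((n_cells, n_samples), params.holding_mv)
    spike_times: list[np.ndarray] = []
    for c in range(n_cells):
        tr, st, _ = ap_train(
            params,
            n_pulses=protocol.n_pulses,
            pulse_rate_hz=protocol.pulse_rate_hz,
            amplitude_na=protocol.amplitude_na,
            width_ms=protocol.width_ms,
            onset_s=0.025,
            duration_s=(protocol.slot_ms + protocol.gap_ms) / 1000.0,
            rate_hz=rate_hz,
        )
        i0 = int(round(protocol.slot_onset_s(c) * rate_hz))
        seg = tr.samples[: n_samples - i0]
        base[c, i0 : i0 + seg.size] = seg
        spike_times.append(st + protocol.slot_onset_s(c))

    gt = GroundTruthNetwork(
        adjacency=adj, amplitude_mv=amp, latency_ms=lat,
        rise_ms=rise_ms, decay_ms=decay_ms, trial_cv=trial_cv,
        soma_positions_um=positions, spike_times_s=spike_times,
    )

    # log-normal multiplicative trial jitter with unit mean and CV trial_cv
    if trial_cv > 0:
        sigma = math.sqrt(math.log(1.0 + trial_cv**2))
        mu = -0.5 * sigma**2
    edges = np.argwhere(adj)
    data = np.tile(base, (n_sweeps, 1, 1))
    for s in range(n_sweeps):
        for pre, post in edges:
            for t_sp in spike_times[pre]:
                scale = amp[pre, post]
                if trial_cv > 0:
                    scale *= float(rng_trial.lognormal(mu, sigma))
                i0 = int(round((t_sp + lat[pre, post] / 1000.0) * rate_hz))
                seg = kernel[: max(0, n_samples - i0)]
                data[s, post, i0 : i0 + seg.size] += scale * seg
    if noise_sd_mv > 0:
        # single precision is ample for the noise floor and much faster
        noise = noise_sd_mv * rng_noise.standard_normal(data.shape, dtype=np.float32)
        if lowpass:
            noise = lowpass_6khz(noise, rate_hz)
        data += noise
    return SweepSet(data=data, rate_hz=rate_hz, protocol=protocol, seed=seed), gt
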
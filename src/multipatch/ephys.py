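"""Trace analysis: passive properties, AP detection/features, stimulus choice, QC.

Definitions follow standard whole-cell practice: resting potential is the
mean of a 100 ms baseline; access and input resistance come from the peak
and steady-state currents of a 200 ms / 10 mV voltage-clamp step; the AP
threshold is the voltage where dV/dt first exceeds 10 mV/ms relative to the
baseline slope; amplitude is peak minus threshold; half-width is the
duration above threshold + amplitude/2.  Quality control excludes cells
with resting potential more positive than -60 mV or access resistance not
below 40 MOhm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    FeatureUndefinedError,
    InvalidArgumentError,
    StimulusNotFoundError,
)
from .synthgen import TestPulse, Trace

__all__ = [
    "PassiveProps",
    "APFeatures",
    "QCReport",
    "resting_potential",
    "measure_resistances",
    "detect_spikes",
    "ap_features",
    "select_rheobase_stimulus",
    "qc_filter",
]


@dataclass
class PassiveProps:
    rmp_mv: float = math.nan
    ra_mohm: float = math.nan
    rin_mohm: float = math.nan
    flags: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


def resting_potential(trace: Trace, baseline_ms: float = 100.0) -> float:
    """Mean membrane voltage over the first ``baseline_ms`` of the trace."""
    if trace.clamp_mode != "current":
        raise InvalidArgumentError("resting potential needs a current-clamp trace")
    n = int(round(baseline_ms * trace.rate_hz / 1000.0))
    if n < 1 or n > trace.samples.size:
        raise InvalidArgumentError(
            f"baseline window {baseline_ms} ms exceeds trace of {trace.duration_s * 1e3:.1f} ms"
        )
    return float(trace.samples[:n].mean())


def measure_resistances(
    pulse: TestPulse,
    peak_window_ms: float = 10.0,
    ss_fraction: float = 0.2,
    series_corrected: bool = True,
) -> PassiveProps:
    """Access and input resistance from a voltage-clamp test pulse.

    Ra = dV / (I_peak - I_baseline) from the current extremum in the first
    ``peak_window_ms`` after pulse onset; total resistance from the mean
    current over the last ``ss_fraction`` of the pulse, and
    Rin = dV/(I_ss - I_baseline) - Ra (series-resistance corrected; set
    ``series_corrected=False`` for the raw total).  Units mV/pA -> MOhm.
    """
    trace = pulse.trace
    if trace.clamp_mode != "voltage":
        raise InvalidArgumentError("resistance measurement needs a voltage-clamp trace")
    i_on = trace.index_of(pulse.onset_s)
    i_off = trace.index_of(pulse.onset_s + pulse.width_s)
    if not (0 < i_on < i_off <= trace.samples.size):
        raise InvalidArgumentError("pulse annotation outside the trace")
    i_base = float(trace.samples[:i_on].mean())
    n_peak = max(int(round(peak_window_ms * trace.rate_hz / 1000.0)), 1)
    seg = trace.samples[i_on : min(i_on + n_peak, i_off)]
    i_peak = float(seg[np.argmax(np.abs(seg - i_base))])
    n_ss = max(int(round(ss_fraction * (i_off - i_on))), 1)
    i_ss = float(trace.samples[i_off - n_ss : i_off].mean())

    props = PassiveProps()
    dv = pulse.dv_mv
    if i_ss <= i_base:
        props.flags.append("non_physical_steady_state")
        return props
    r_total = 1000.0 * dv / (i_ss - i_base)  # MOhm
    if i_peak - i_base <= 0:
        props.flags.append("no_peak_transient")
        return props
    ra = 1000.0 * dv / (i_peak - i_base)
    if abs(i_peak - i_ss) < 1e-9 * max(abs(i_peak), 1.0):
        # no resolvable charging transient: Ra and Rin cannot be separated
        props.ra_mohm = ra
        props.rin_mohm = math.inf
        props.flags.append("no_transient")
        return props
    props.ra_mohm = ra
    props.rin_mohm = (r_total - ra) if series_corrected else r_total
    return props


def _dvdt(samples: np.ndarray, rate_hz: float) -> np.ndarray:
    """Central-difference derivative in mV/ms."""
    return np.gradient(samples, 1000.0 / rate_hz)


def detect_spikes(
    trace: Trace,
    peak_min_mv: float = 0.0,
    slope_min_mv_ms: float = 20.0,
    refractory_ms: float = 2.0,
) -> np.ndarray:
    """Indices of AP peaks: local maxima above 0 mV preceded by a fast upstroke."""
    if trace.clamp_mode != "current":
        raise InvalidArgumentError("spike detection needs a current-clamp trace")
    from scipy.signal import find_peaks

    distance = max(int(round(refractory_ms * trace.rate_hz / 1000.0)), 1)
    peaks, _ = find_peaks(trace.samples, height=peak_min_mv, distance=distance)
    if peaks.size == 0:
        return peaks
    dvdt = _dvdt(trace.samples, trace.rate_hz)
    look = max(int(round(2.0 * trace.rate_hz / 1000.0)), 1)  # 2 ms pre-peak
    keep = [p for p in peaks if dvdt[max(p - look, 0) : p + 1].max() >= slope_min_mv_ms]
    return np.asarray(keep, dtype=int)


@dataclass
class APFeatures:
    threshold_mv: float
    peak_mv: float
    amplitude_mv: float
    half_width_ms: float
    max_depol_rate_mv_ms: float
    max_repol_rate_mv_ms: float
    spike_time_s: float
    threshold_idx: int

    def __post_init__(self):
        assert abs(self.amplitude_mv - (self.peak_mv - self.threshold_mv)) < 1e-9


def ap_features(
    trace: Trace,
    spike_idx: int,
    baseline_slope_mv_ms: float = 0.0,
    slope_criterion_mv_ms: float = 10.0,
    search_ms: float = 10.0,
) -> APFeatures:
    """Features of one AP around ``spike_idx`` (a peak from :func:`detect_spikes`).

    The threshold is the first sample, searching backward from the peak, of
    the contiguous run where dV/dt >= baseline_slope + 10 mV/ms.  Half-width
    is measured at threshold + amplitude/2 with sub-sample interpolation of
    the crossings; depolarisation/repolarisation rates are the extremal
    dV/dt between threshold and peak, and peak and return-to-threshold.
    """
    v = trace.samples
    dvdt = _dvdt(v, trace.rate_hz)
    thr_eff = baseline_slope_mv_ms + slope_criterion_mv_ms
    lo = max(spike_idx - int(round(search_ms * trace.rate_hz / 1000.0)), 0)
    # walk back from the rising flank; start from the max-slope point so the
    # near-zero slope at the peak itself does not end the run immediately
    rise = dvdt[lo : spike_idx + 1]
    if rise.size == 0 or rise.max() < thr_eff:
        raise FeatureUndefinedError("no dV/dt crossing before the peak")
    i = lo + int(np.argmax(rise))
    while i > lo and dvdt[i - 1] >= thr_eff:
        i -= 1
    thr_idx = i
    thr_v = float(v[thr_idx])
    peak_v = float(v[spike_idx])
    amp = peak_v - thr_v
    half = thr_v + amp / 2.0

    # rising half-amplitude crossing (interpolated)
    j = thr_idx
    while j < spike_idx and v[j] < half:
        j += 1
    if j == thr_idx:
        t_rise = float(j)
    else:
        t_rise = (j - 1) + (half - v[j - 1]) / (v[j] - v[j - 1])
    # falling crossing
    k = spike_idx
    n = v.size
    while k < n - 1 and v[k] >= half:
        k += 1
    t_fall = (k - 1) + (v[k - 1] - half) / (v[k - 1] - v[k]) if v[k - 1] != v[k] else float(k)
    half_width_ms = (t_fall - t_rise) * 1000.0 / trace.rate_hz
    # return-to-threshold after the peak
    m = spike_idx
    while m < n - 1 and v[m] >= thr_v:
        m += 1
    depol = float(dvdt[thr_idx : spike_idx + 1].max())
    repol = float(dvdt[spike_idx : m + 1].min())
    return APFeatures(
        threshold_mv=thr_v,
        peak_mv=peak_v,
        amplitude_mv=peak_v - thr_v,
        half_width_ms=half_width_ms,
        max_depol_rate_mv_ms=depol,
        max_repol_rate_mv_ms=repol,
        spike_time_s=trace.t0_s + spike_idx / trace.rate_hz,
        threshold_idx=thr_idx,
    )


def select_rheobase_stimulus(
    responses: dict,
    amp_step_na: float = 0.5,
    amp_max_na: float = 4.0,
) -> tuple:
    """Pick the screening stimulus from a (amplitude, duration) -> spiked? grid.

    The scan raises amplitude 0.5..4 nA in 0.5 nA steps at 1 ms, escalating
    duration only when nothing fires.  At the first duration with a success,
    the chosen amplitude is one step above the lowest firing one (the
    second-lowest firing amplitude for a contiguous grid), capped at 4 nA.
    """
    durations = sorted({d for _, d in responses})
    for dur in durations:
        amps = sorted(a for (a, d), ok in responses.items() if d == dur and ok)
        if amps:
            return (min(amps[0] + amp_step_na, amp_max_na), dur)
    raise StimulusNotFoundError("no stimulus in the grid elicited an action potential")


@dataclass
class QCReport:
    table: pd.DataFrame  # input plus included / exclusion_reason columns
    rmp_cutoff_mv: float
    ra_cutoff_mohm: float

    @property
    def n_included(self) -> int:
        return int(self.table["included"].sum())

    @property
    def n_excluded(self) -> int:
        return int((~self.table["included"]).sum())


def qc_filter(
    cells: pd.DataFrame,
    rmp_cutoff_mv: float = -60.0,
    ra_cutoff_mohm: float = 40.0,
) -> QCReport:
    """Exclude cells with depolarised rest or high access resistance.

    Boundary semantics are verbatim: a resting potential *more positive
    than* the cutoff excludes (rmp == -60 passes); an access resistance
    *below* the cutoff is required (Ra == 40 fails).  Idempotent and
    order-independent.
    """
    required = {"rmp_mV", "ra_MOhm"}
    missing = required - set(cells.columns)
    if missing:
        raise InvalidArgumentError(f"cell table lacks columns {sorted(missing)}")
    table = cells.copy()
    reasons = []
    for _, row in table.iterrows():
        r = []
        if row["rmp_mV"] > rmp_cutoff_mv:
            r.append("rmp_above_cutoff")
        if not row["ra_MOhm"] < ra_cutoff_mohm:
            r.append("high_access_resistance")
        reasons.append(";".join(r))
    table["exclusion_reason"] = reasons
    table["included"] = [r == "" for r in reasons]
    return QCReport(table=table, rmp_cutoff_mv=rmp_cutoff_mv, ra_cutoff_mohm=ra_cutoff_mohm)
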
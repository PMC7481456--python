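"""Cardiorespiratory preprocessing: from R-peak annotations and a belt
waveform to analysis-ready 300-sample (RR, RESP) segment pairs.

The chain mirrors standard heart-rate-variability practice for neonatal
recordings: RR intervals are the successive R-peak differences; the
respiration waveform is band-pass filtered (0.05-3.5 Hz, zero phase) and
resampled at each R-peak onset so RR(n) and RESP(n) share a beat-indexed
time base; artifact rules reject implausible beats (RR outside
0.3-0.667 s, or >10 % change against the previous accepted beat) and
implausible breathing cycles (duration outside 0.5-2.5 s, or >40 % change
against the previous accepted cycle, measured between successive rising
zero crossings); windows of 300 consecutive beats within one sleep-state
bout become segments, discarded when more than 5 % of their samples are
rejected, and each kept segment is z-normalized per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "PhysioRecord",
    "SegmentPair",
    "ArtifactMask",
    "RR_MIN", "RR_MAX", "RR_MAX_CHANGE",
    "CYCLE_MIN", "CYCLE_MAX", "CYCLE_MAX_CHANGE",
    "rr_from_peaks",
    "bandpass_resp",
    "resample_resp_at_peaks",
    "resp_cycle_durations",
    "artifact_filter",
    "segment_and_normalize",
    "breathing_rate",
]

RR_MIN, RR_MAX = 0.3, 0.667          # s, RR acceptance band
RR_MAX_CHANGE = 0.10                 # relative change vs previous accepted
CYCLE_MIN, CYCLE_MAX = 0.5, 2.5      # s, breathing-cycle acceptance band
CYCLE_MAX_CHANGE = 0.40
SEGMENT_LENGTH = 300
MAX_REJECTED_FRACTION = 0.05


@dataclass
class PhysioRecord:
    """R-peak times, respiration waveform and provenance of one record."""

    rpeak_times: np.ndarray          # s, strictly increasing
    resp: np.ndarray                 # belt waveform
    resp_fs: float                   # Hz
    sleep_states: list = field(default_factory=list)  # (start, end, state)
    ga_group: str = "FT"
    covariates: dict = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)
    record_id: str = "record-0"

    def __post_init__(self):
        self.rpeak_times = np.asarray(self.rpeak_times, dtype=float)
        self.resp = np.asarray(self.resp, dtype=float)
        if self.rpeak_times.ndim != 1 or self.rpeak_times.size < 2:
            raise ValueError("need at least two R-peak times")
        if np.any(np.diff(self.rpeak_times) <= 0):
            raise ValueError("R-peak times must be strictly increasing")
        if self.resp_fs <= 0:
            raise ValueError("respiration sampling rate must be positive")


@dataclass
class SegmentPair:
    """One z-normalized 300-sample (RR, RESP) segment with provenance."""

    rr: np.ndarray
    resp: np.ndarray
    record_id: str = "record-0"
    sleep_state: str = ""
    start_index: int = 0
    n_rejected: int = 0
    ga_group: str = ""
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        self.rr = np.asarray(self.rr, dtype=float)
        self.resp = np.asarray(self.resp, dtype=float)
        for name, v in (("rr", self.rr), ("resp", self.resp)):
            if v.size != SEGMENT_LENGTH:
                raise ValueError(f"{name} must have exactly "
                                 f"{SEGMENT_LENGTH} samples, got {v.size}")
            if abs(v.mean()) >= 1e-8 or abs(v.std() - 1) >= 1e-6:
                raise ValueError(f"{name} is not z-normalized")


@dataclass
class ArtifactMask:
    """Per-sample accept/reject mask and the segment-level verdict."""

    accepted: np.ndarray             # bool, per RR sample
    rejected_fraction: float
    discard: bool                    # rejected fraction above 5 %


def rr_from_peaks(rpeak_times) -> np.ndarray:
    """RR series: RR(n) is the interval between peak n and peak n+1 (s)."""
    t = np.asarray(rpeak_times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("need at least two R-peak times")
    rr = np.diff(t)
    if np.any(rr <= 0):
        bad = int(np.flatnonzero(rr <= 0)[0])
        raise ValueError(f"non-monotone R-peak times at index {bad + 1}")
    return rr


def bandpass_resp(resp, rate: float) -> np.ndarray:
    """Zero-phase 0.05-3.5 Hz band-pass of the respiration waveform.

    Fourth-order Butterworth band-pass applied forward and backward
    (sosfiltfilt), so there is no group delay to bias the beat-indexed
    resampling.
    """
    if rate <= 7.0:
        raise ValueError("sampling rate must exceed 7 Hz (Nyquist above 3.5)")
    resp = np.asarray(resp, dtype=float)
    sos = signal.butter(2, [0.05, 3.5], btype="bandpass", fs=rate,
                        output="sos")
    return signal.sosfiltfilt(sos, resp)


def resample_resp_at_peaks(resp, rate: float, rpeak_times) -> np.ndarray:
    """Respiration value at each R-peak onset (linear interpolation).

    RESP(n) shares the time base of RR(n), so the output drops the final
    peak and has the same length as the RR series.
    """
    resp = np.asarray(resp, dtype=float)
    t = np.asarray(rpeak_times, dtype=float)
    t_grid = np.arange(resp.size) / rate
    if np.any(t < 0) or np.any(t > t_grid[-1]):
        raise ValueError("R-peak time outside the respiration waveform span")
    return np.interp(t[:-1], t_grid, resp)


def resp_cycle_durations(resp_filtered, rate: float):
    """Breathing-cycle onsets and durations from rising zero crossings.

    Returns (onset times, durations) in seconds; cycle i spans
    [onset_i, onset_i + duration_i).
    """
    x = np.asarray(resp_filtered, dtype=float)
    rising = np.flatnonzero((x[:-1] <= 0) & (x[1:] > 0))
    if rising.size < 2:
        return np.empty(0), np.empty(0)
    onsets = rising / rate
    return onsets[:-1], np.diff(onsets)


def _change_mask(values, lo, hi, max_change):
    accepted = np.ones(values.size, dtype=bool)
    prev = None
    for i, v in enumerate(values):
        ok = lo <= v <= hi
        # compare against the previous ACCEPTED value so one outlier
        # does not cascade into its neighbors
        if ok and prev is not None and abs(v - prev) / prev > max_change:
            ok = False
        accepted[i] = ok
        if ok:
            prev = v
    return accepted


def artifact_filter(rr, resp_cycle_info=None, rpeak_times=None) -> ArtifactMask:
    """Accept/reject mask over RR samples plus the segment verdict.

    A beat is rejected when its RR interval leaves the 0.3-0.667 s band or
    changes by more than 10 % against the previous accepted beat.  When
    ``resp_cycle_info = (onsets, durations)`` and the matching
    ``rpeak_times`` are given, beats falling inside a rejected breathing
    cycle (duration outside 0.5-2.5 s or >40 % change against the previous
    accepted cycle) are rejected as well.  The verdict discards a segment
    whose rejected fraction exceeds 5 %.
    """
    rr = np.asarray(rr, dtype=float)
    accepted = _change_mask(rr, RR_MIN, RR_MAX, RR_MAX_CHANGE)
    if resp_cycle_info is not None:
        if rpeak_times is None:
            raise ValueError("rpeak_times required to map cycles onto beats")
        onsets, durations = resp_cycle_info
        if len(onsets):
            cyc_ok = _change_mask(np.asarray(durations, dtype=float),
                                  CYCLE_MIN, CYCLE_MAX, CYCLE_MAX_CHANGE)
            t = np.asarray(rpeak_times, dtype=float)[:rr.size]
            idx = np.searchsorted(onsets, t, side="right") - 1
            ends = np.asarray(onsets) + np.asarray(durations)
            inside = (idx >= 0) & (t < ends[np.clip(idx, 0, len(ends) - 1)])
            bad = inside & ~cyc_ok[np.clip(idx, 0, len(cyc_ok) - 1)]
            accepted &= ~bad
    frac = float(1.0 - accepted.mean()) if rr.size else 0.0
    return ArtifactMask(accepted, frac, frac > MAX_REJECTED_FRACTION)


def _znorm(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot z-normalize a constant segment")
    return (v - v.mean()) / sd


def segment_and_normalize(record: PhysioRecord, sleep_state: str | None = None,
                          length: int = SEGMENT_LENGTH) -> list[SegmentPair]:
    """Non-overlapping segments of ``length`` beats within sleep-state bouts.

    Windows are tiled earliest-first inside each bout of the requested
    sleep state (all bouts when ``sleep_state`` is None); windows whose
    artifact-rejected fraction exceeds 5 % are discarded whole.  Each kept
    segment is z-normalized per channel.  Returns an empty list when no
    window qualifies.
    """
    rr = rr_from_peaks(record.rpeak_times)
    filtered = bandpass_resp(record.resp, record.resp_fs)
    resp_beat = resample_resp_at_peaks(filtered, record.resp_fs,
                                       record.rpeak_times)
    cycles = resp_cycle_durations(filtered, record.resp_fs)
    mask = artifact_filter(rr, cycles, record.rpeak_times)
    beat_t = record.rpeak_times[:-1]

    bouts = record.sleep_states or [(beat_t[0], record.rpeak_times[-1], "")]
    segments: list[SegmentPair] = []
    for start, end, state in bouts:
        if sleep_state is not None and state != sleep_state:
            continue
        in_bout = np.flatnonzero((beat_t >= start) & (beat_t < end))
        for w0 in range(0, in_bout.size - length + 1, length):
            idx = in_bout[w0:w0 + length]
            n_rej = int((~mask.accepted[idx]).sum())
            if n_rej / length > MAX_REJECTED_FRACTION:
                continue
            segments.append(SegmentPair(
                rr=_znorm(rr[idx]),
                resp=_znorm(resp_beat[idx]),
                record_id=record.record_id,
                sleep_state=state,
                start_index=int(idx[0]),
                n_rejected=n_rej,
                ga_group=record.ga_group,
                covariates=dict(record.covariates),
            ))
    return segments


def breathing_rate(resp, rate: float, window: float = 60.0) -> float:
    """Dominant respiratory frequency (Hz) from the Welch periodogram.

    The peak is searched in the 0.2-2.0 Hz band and must be prominent
    (peak power at least five times the median in-band power); a flat
    spectrum raises ``ValueError``.  Requires >= 60 s of signal.
    """
    resp = np.asarray(resp, dtype=float)
    if resp.size / rate < 60.0:
        raise ValueError("need at least 60 s of respiration signal")
    nperseg = min(resp.size, int(window * rate))
    freqs, psd = signal.welch(resp - resp.mean(), fs=rate, nperseg=nperseg)
    band = (freqs >= 0.2) & (freqs <= 2.0)
    f_band, p_band = freqs[band], psd[band]
    peak = int(np.argmax(p_band))
    if p_band[peak] < 5.0 * np.median(p_band):
        raise ValueError("no prominent respiratory peak in 0.2-2.0 Hz")
    return float(f_band[peak])
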
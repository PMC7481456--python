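"""Generators: coupled-AR validation system, null pairs, synthetic physiology.

The validation system is the bivariate stochastic process

    X_n = a1 X_{n-1} + a2 X_{n-2} + 0.07 Y_{n-1} + U_n
    Y_n = C1 X_{n-1} + C2 X_{n-2} + C3 X_{n-5} + V_n

with independent unit-variance white noises U, V.  X is a self-sustained
AR(2) oscillator (complex pole pair at normalized frequency f, modulus rho)
weakly and transiently driven by Y (coefficient 0.07 at delay 1), while Y
receives a lasting, strong drive from X at delays 1, 2 and 5.  The designed
asymmetry is what the lagged-TE validation study must recover.

The physiological generator emulates a neonatal cardiorespiratory record:
R-peak event times whose inter-beat (RR) intervals carry respiratory sinus
arrhythmia, a respiration belt waveform sampled at 200 Hz, sleep-state
dependent breathing rate, gestational-age-graded coupling gain, and
injected artifacts returned as ground truth.  It stands in for cohort data
that is not publicly deposited, and is the round-trip test surface for the
preprocessing rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._design import BivariateSeries
from ._rng import substream
from .preprocess import PhysioRecord

__all__ = [
    "ARSimSpec",
    "PhysioSimSpec",
    "ar_oscillator_coeffs",
    "simulate_coupled_ar",
    "simulate_null_pair",
    "simulate_physio",
]

GA_COUPLING_GAIN = {"LPT": 0.006, "ET": 0.009, "FT": 0.012}  # s per unit resp


def ar_oscillator_coeffs(f: float, rho: float) -> tuple[float, float]:
    """AR(2) coefficients of a complex pole pair at normalized frequency f.

    f is in cycles/sample (0 < f < 0.5), rho the pole modulus (0 < rho < 1):
    a1 = 2 rho cos(2 pi f), a2 = -rho^2.
    """
    if not 0 < f < 0.5:
        raise ValueError("f must be in (0, 0.5) cycles/sample")
    if not 0 < rho < 1:
        raise ValueError("rho must be in (0, 1)")
    return 2 * rho * np.cos(2 * np.pi * f), -rho ** 2


_A1_DEFAULT, _A2_DEFAULT = ar_oscillator_coeffs(0.1, 0.95)


@dataclass
class ARSimSpec:
    """Coefficients and size of the coupled-AR validation system."""

    a1: float = _A1_DEFAULT
    a2: float = _A2_DEFAULT
    b_yx: float = 0.07           # Y -> X coupling at delay 1
    c1: float = 0.5              # X -> Y at delay 1
    c2: float = 0.5              # X -> Y at delay 2
    c3: float = 0.5              # X -> Y at delay 5
    noise_sd_x: float = 1.0
    noise_sd_y: float = 1.0
    n: int = 300
    burn_in: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n < 100:
            raise ValueError("n must be >= 100")
        if self.noise_sd_x <= 0 or self.noise_sd_y <= 0:
            raise ValueError("noise SDs must be positive")

    def companion_matrix(self) -> np.ndarray:
        """Companion form of the joint system; state (X_n..X_{n-4}, Y_n)."""
        M = np.zeros((6, 6))
        M[0, 0] = self.a1
        M[0, 1] = self.a2
        M[0, 5] = self.b_yx
        for i in range(1, 5):
            M[i, i - 1] = 1.0
        M[5, 0] = self.c1
        M[5, 1] = self.c2
        M[5, 4] = self.c3
        return M

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion_matrix()))))


def simulate_coupled_ar(spec: ARSimSpec | None = None,
                        seed: int | None = None) -> BivariateSeries:
    """One realization of the coupled-AR system, burn-in discarded."""
    spec = spec or ARSimSpec()
    if seed is None:
        seed = spec.seed
    radius = spec.spectral_radius()
    if radius >= 1.0:
        raise ValueError(
            f"unstable coefficient set: companion spectral radius {radius:.3f}"
        )
    rng = substream(seed, "coupled-ar")
    total = spec.n + spec.burn_in
    u = rng.normal(0.0, spec.noise_sd_x, total)
    v = rng.normal(0.0, spec.noise_sd_y, total)
    x = np.zeros(total)
    y = np.zeros(total)
    for t in range(total):
        x1 = x[t - 1] if t >= 1 else 0.0
        x2 = x[t - 2] if t >= 2 else 0.0
        x5 = x[t - 5] if t >= 5 else 0.0
        y1 = y[t - 1] if t >= 1 else 0.0
        x[t] = spec.a1 * x1 + spec.a2 * x2 + spec.b_yx * y1 + u[t]
        y[t] = spec.c1 * x1 + spec.c2 * x2 + spec.c3 * x5 + v[t]
    return BivariateSeries(x[spec.burn_in:], y[spec.burn_in:], "X", "Y")


def simulate_null_pair(n: int = 300, seed: int = 0) -> BivariateSeries:
    """Two independent standard-normal series (type-I calibration input)."""
    if n < 100:
        raise ValueError("n must be >= 100")
    rng = substream(seed, "null-pair")
    return BivariateSeries(rng.standard_normal(n), rng.standard_normal(n),
                           "X", "Y")


@dataclass
class PhysioSimSpec:
    """Synthetic neonatal cardiorespiratory record parameters.

    Defaults emulate the study population: mean RR 0.45 s (heart rate
    ~133 bpm, inside the 0.3-0.667 s acceptance band), breathing near
    0.75 Hz in quiet sleep and 1.0 Hz in active sleep (periods well inside
    the 0.5-2.5 s band), respiration sampled at 200 Hz, and a
    respiration->RR (RSA) gain graded by gestational-age group.  Clean
    beats are clamped to stay within the artifact-acceptance rules, so
    every injected artifact is detectable by construction and the filter
    round trip is exact.
    """

    duration: float = 600.0          # s
    mean_rr: float = 0.45            # s
    rr_noise_sd: float = 0.003       # s, AR(1) beat-to-beat noise
    resp_rate_qs: float = 0.75       # Hz, quiet sleep
    resp_rate_as: float = 1.0        # Hz, active sleep
    resp_fs: float = 200.0           # Hz, belt sampling rate
    ga_group: str = "FT"             # LPT | ET | FT
    rsa_gain: float | None = None    # s per unit resp; None -> GA-graded
    rr_resp_gain: float = 0.15       # RR -> respiration amplitude gain
    artifact_rate: float = 0.0       # artifacts per beat
    bout_length: float = 200.0       # s per sleep-state bout (QS/AS alternate)
    seed: int = 0

    def __post_init__(self):
        if not 0.3 <= self.mean_rr <= 0.667:
            raise ValueError("mean RR must lie in the 0.3-0.667 s band")
        for r in (self.resp_rate_qs, self.resp_rate_as):
            if not 0.4 <= r <= 2.0:
                raise ValueError("respiratory period must lie in 0.5-2.5 s")
        if self.ga_group not in GA_COUPLING_GAIN:
            raise ValueError(f"ga_group must be one of {list(GA_COUPLING_GAIN)}")
        gain = self.rsa_gain if self.rsa_gain is not None \
            else GA_COUPLING_GAIN[self.ga_group]
        if gain * 1.5 + 6 * self.rr_noise_sd > 0.05:
            raise ValueError(
                "RSA gain / noise combination can push RR outside the "
                "clean acceptance margin"
            )


def _resp_phase(t: np.ndarray, states: list, rate_qs: float,
                rate_as: float) -> np.ndarray:
    rate = np.full(t.size, rate_qs)
    for start, end, state in states:
        if state == "AS":
            rate[(t >= start) & (t < end)] = rate_as
    dt = np.diff(t, prepend=0.0)
    return 2 * np.pi * np.cumsum(rate * dt)


def simulate_physio(spec: PhysioSimSpec | None = None,
                    seed: int | None = None) -> PhysioRecord:
    """Synthetic cardiorespiratory record with known artifact ground truth.

    The beat sequence integrates RR intervals; each clean RR is the mean
    plus the RSA term (gain times the respiration value at the beat) plus
    slow AR(1) noise, clamped so consecutive-change and range acceptance
    rules are never tripped by clean beats.  Injected artifacts (doubled
    "missed-beat" intervals or short ectopic-like intervals) violate the
    rules by construction; their beat indices are returned as ground truth.
    """
    spec = spec or PhysioSimSpec()
    if seed is None:
        seed = spec.seed
    rng = substream(seed, "physio")
    gain = spec.rsa_gain if spec.rsa_gain is not None \
        else GA_COUPLING_GAIN[spec.ga_group]

    # sleep-state bouts alternate QS/AS
    states = []
    t0, toggle = 0.0, True
    while t0 < spec.duration:
        t1 = min(t0 + spec.bout_length, spec.duration)
        states.append((t0, t1, "QS" if toggle else "AS"))
        t0, toggle = t1, not toggle

    # respiration waveform on the belt sampling grid
    n_resp = int(round(spec.duration * spec.resp_fs))
    t_resp = np.arange(n_resp) / spec.resp_fs
    phase = _resp_phase(t_resp, states, spec.resp_rate_qs, spec.resp_rate_as)
    amplitude = 1.0 + 0.05 * np.sin(2 * np.pi * 0.01 * t_resp)
    resp_clean = amplitude * np.sin(phase)

    def resp_at(t: float) -> float:
        return float(np.interp(t, t_resp, resp_clean))

    # beat-by-beat RR generation with clean-by-construction clamping
    times = [0.0]
    rr_values = []
    cardiac_drive = []
    noise = 0.0
    prev_rr = spec.mean_rr
    while times[-1] < spec.duration:
        noise = 0.95 * noise + rng.normal(0.0, spec.rr_noise_sd)
        rr = spec.mean_rr + gain * resp_at(times[-1]) + noise
        # consecutive clean-beat change capped at 4.5 % so that even the
        # two-step change across a rejected artifact stays below the 10 %
        # rule (the filter compares against the previous accepted beat)
        lo = max(0.36, prev_rr * 0.955)
        hi = min(0.60, prev_rr * 1.045)
        rr = float(np.clip(rr, lo, hi))
        rr_values.append(rr)
        cardiac_drive.append(rr - spec.mean_rr)
        times.append(times[-1] + rr)
        prev_rr = rr
    rpeaks = np.array(times)
    rr_values = np.array(rr_values)

    # RR -> RESP feedback: modulate the waveform with the smoothed cardiac drive
    if spec.rr_resp_gain:
        drive = np.interp(t_resp, rpeaks[:-1], cardiac_drive)
        resp = resp_clean * (1.0 + spec.rr_resp_gain * drive / max(
            1e-12, np.std(cardiac_drive)))
    else:
        resp = resp_clean.copy()

    # artifact injection into RR (re-timing subsequent peaks)
    artifact_idx: list[int] = []
    if spec.artifact_rate > 0:
        n_beats = rr_values.size
        n_art = rng.binomial(n_beats, spec.artifact_rate)
        candidates = rng.permutation(np.arange(2, n_beats - 2))
        chosen: list[int] = []
        for i in candidates:
            if len(chosen) >= n_art:
                break
            if all(abs(i - j) > 2 for j in chosen):
                chosen.append(int(i))
        rr_art = rr_values.copy()
        for i in sorted(chosen):
            if rng.random() < 0.5:
                rr_art[i] = rr_values[i] * 2.0       # missed beat: > 0.667 s
            else:
                rr_art[i] = rr_values[i] * 0.6       # ectopic: < 0.3 s
        rpeaks = np.concatenate([[0.0], np.cumsum(rr_art)])
        artifact_idx = sorted(chosen)

    # artifact re-timing can push trailing peaks past the waveform span;
    # drop them (and any trailing ground-truth indices) so every peak is
    # interpolable on the respiration grid
    span = (n_resp - 1) / spec.resp_fs
    rpeaks = rpeaks[rpeaks <= span]
    artifact_idx = [i for i in artifact_idx if i < rpeaks.size - 1]

    covariates = {
        "sex": int(rng.integers(0, 2)),
        "mode_of_delivery": int(rng.integers(0, 2)),
        "hours_of_life": float(rng.uniform(12, 84)),
    }
    return PhysioRecord(
        rpeak_times=rpeaks,
        resp=resp,
        resp_fs=spec.resp_fs,
        sleep_states=states,
        ga_group=spec.ga_group,
        covariates=covariates,
        ground_truth={
            "artifact_rr_indices": artifact_idx,
            "rsa_gain": gain,
            "resp_rate_qs": spec.resp_rate_qs,
            "resp_rate_as": spec.resp_rate_as,
        },
    )
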
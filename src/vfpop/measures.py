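"""Voice-source measures of the glottal flow waveform and the normal-phonation filter.

Extracts the standard clinical measures of the voice source from a simulated
glottal flow series: fundamental frequency (F0), mean/AC/maximum flow,
maximum flow declination rate (MFDR), harmonic richness factor (HRF), the
first-minus-second harmonic level difference (H1-H2), open quotient (OQ) and
speed quotient (SQ).  A parameter set is classified as exhibiting "normal
phonation" when all six clinically bounded measures fall inside the accepted
normal ranges (88-263 Hz, 50-420 cm^3/s mean flow, 40-800 cm^3/s AC flow,
100-1150 L/s^2 MFDR, -19-2.1 dB HRF, -24-11 dB H1-H2).

Harmonic conventions follow the clinical literature each bound comes from:
HRF is the harmonic power above the first relative to the first, read from
the spectrum of the glottal flow itself, while H1-H2 is the level difference
of the first two harmonics of the *radiated* voice source, i.e. the
time-derivative of the glottal flow (the +6 dB/octave lip-radiation
characteristic), as it is measured from microphone recordings.

The model works in g-cm-ms units; measures are converted to the clinical
units above on extraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .model import GlottalFlowSeries, SimConfig, simulate_flow

__all__ = [
    "VoiceMeasures",
    "NormalPhonationCriteria",
    "detect_cycles",
    "time_domain_measures",
    "spectral_measures",
    "extract_measures",
    "classify_normal",
    "convert_units",
    "evaluate_parameters",
    "OPEN_THRESHOLD",
    "MIN_CYCLES",
]

#: Relative threshold (fraction of max U) defining the open phase for cycle
#: detection, OQ and SQ.  Robust to floating-point leakage near closure.
OPEN_THRESHOLD = 0.01

#: Minimum number of complete cycles for a valid analysis.
MIN_CYCLES = 20

#: Floors/ceilings for degenerate spectra (e.g. a pure sine has no harmonics
#: above the first, so HRF would be -inf).
HRF_FLOOR_DB = -100.0
H1H2_CEILING_DB = 100.0


@dataclass
class VoiceMeasures:
    """Scalar voice-source measures in clinical units.

    All fields are NaN when ``oscillating`` is False (no sustained steady
    oscillation was detected).
    """

    f0: float = math.nan         # Hz
    mean_flow: float = math.nan  # cm^3/s
    ac_flow: float = math.nan    # cm^3/s
    max_flow: float = math.nan   # cm^3/s
    mfdr: float = math.nan       # L/s^2
    hrf: float = math.nan        # dB
    h1h2: float = math.nan       # dB
    oq: float = math.nan         # dimensionless, in [0, 1]
    sq: float = math.nan         # dimensionless, > 0
    oscillating: bool = False
    spectrum_flagged: bool = False  # True when HRF/H1-H2 hit the degeneracy floor
    period_cov: float = math.nan    # diagnostic: coefficient of variation of cycle periods


# Table of (low, high) bounds for normal phonation, clinical units.
@dataclass(frozen=True)
class NormalPhonationCriteria:
    f0: tuple[float, float] = (88.0, 263.0)         # Hz
    mean_flow: tuple[float, float] = (50.0, 420.0)  # cm^3/s
    ac_flow: tuple[float, float] = (40.0, 800.0)    # cm^3/s
    mfdr: tuple[float, float] = (100.0, 1150.0)     # L/s^2
    hrf: tuple[float, float] = (-19.0, 2.1)         # dB
    h1h2: tuple[float, float] = (-24.0, 11.0)       # dB

    def __post_init__(self) -> None:
        for f in fields(self):
            lo, hi = getattr(self, f.name)
            if not lo < hi:
                raise ValueError(f"criterion {f.name}: low must be < high")


#: A detected "cycle" whose peak is below this fraction of the typical pulse
#: amplitude is a secondary blip (e.g. the weak inter-pulse opening of a 2:1
#: regime grazing the open threshold), not a voice pulse; it is merged into
#: the preceding cycle so F0 tracks the fundamental.
BLIP_PEAK_FRACTION = 0.2


def detect_cycles(flow: GlottalFlowSeries, threshold: float = OPEN_THRESHOLD) -> np.ndarray:
    """Indices of cycle onsets: upward crossings of ``threshold * max(U)``.

    Spurious onsets caused by tiny secondary pulses that barely cross the
    threshold are merged into the preceding cycle (see
    ``BLIP_PEAK_FRACTION``).  Returns an empty array when no oscillation is
    present.
    """
    u = np.asarray(flow.u)
    umax = u.max() if u.size else 0.0
    if not (umax > 0):
        return np.array([], dtype=int)
    thr = threshold * umax
    below = u[:-1] < thr
    above = u[1:] >= thr
    onsets = np.nonzero(below & above)[0] + 1
    if onsets.size < 2:
        return np.array([], dtype=int)
    peaks = np.array([u[onsets[i]:onsets[i + 1]].max()
                      for i in range(onsets.size - 1)])
    ref = np.percentile(peaks, 75)
    blip = peaks < BLIP_PEAK_FRACTION * ref
    if blip.any():
        keep = np.ones(onsets.size, dtype=bool)
        keep[:-1][blip] = False  # drop the onset that starts each blip cycle
        onsets = onsets[keep]
    if onsets.size < 2:
        return np.array([], dtype=int)
    return onsets


def _period_stats(flow: GlottalFlowSeries, cycles: np.ndarray) -> tuple[float, float]:
    periods = np.diff(cycles) * flow.dt
    mean = periods.mean()
    cov = periods.std() / mean if mean > 0 else math.inf
    return mean, cov


def time_domain_measures(flow: GlottalFlowSeries, cycles: np.ndarray) -> VoiceMeasures:
    """F0, flow amplitudes, MFDR, OQ and SQ from cycle-segmented flow.

    Requires at least ``MIN_CYCLES`` complete cycles; otherwise the returned
    measures carry ``oscillating=False``.  The period coefficient of
    variation is reported as a steadiness diagnostic but does not invalidate
    the analysis (the symmetric model produces near-periodic waveforms; the
    normal-phonation filter is the Table of clinical bounds alone).
    """
    m = VoiceMeasures()
    cycles = np.asarray(cycles, dtype=int)
    if cycles.size < MIN_CYCLES + 1:
        return m
    mean_period_ms, cov = _period_stats(flow, cycles)
    if not (mean_period_ms > 0):
        return m
    m.period_cov = cov

    u = np.asarray(flow.u)
    dt = flow.dt
    thr = OPEN_THRESHOLD * u.max()
    span = u[cycles[0]:cycles[-1]]

    m.f0 = 1000.0 / mean_period_ms  # ms -> Hz
    m.mean_flow = convert_units(float(span.mean()), "cm3_per_ms_to_cm3_per_s")
    m.max_flow = convert_units(float(span.max()), "cm3_per_ms_to_cm3_per_s")

    # maximum flow declination rate: steepest negative slope of U(t),
    # centered finite differences, no smoothing
    du = np.gradient(u, dt)
    m.mfdr = convert_units(float(-du[cycles[0]:cycles[-1]].min()), "cm3_per_ms2_to_l_per_s2")

    ac = np.empty(cycles.size - 1)
    oq = np.empty(cycles.size - 1)
    sq = np.full(cycles.size - 1, math.nan)
    for i in range(cycles.size - 1):
        cyc = u[cycles[i]:cycles[i + 1]]
        ac[i] = cyc.max() - cyc.min()
        open_idx = np.nonzero(cyc >= thr)[0]
        oq[i] = open_idx.size / cyc.size
        if open_idx.size < 3:
            continue
        peak = int(np.argmax(cyc))
        rise = peak - open_idx[0]
        fall = open_idx[-1] - peak
        if rise > 0 and fall > 0:
            sq[i] = rise / fall
    m.ac_flow = convert_units(float(ac.mean()), "cm3_per_ms_to_cm3_per_s")
    m.oq = float(oq.mean())
    m.sq = float(np.nanmean(sq)) if np.any(np.isfinite(sq)) else math.nan
    m.oscillating = True
    return m


def spectral_measures(flow: GlottalFlowSeries, f0: float) -> tuple[float, float, bool]:
    """HRF and H1-H2 in dB from the harmonic spectrum of the flow.

    Harmonic amplitudes ``A_n`` are the Fourier-series coefficients of the
    period-averaged cycle: the largest integer number of cycles is resampled
    onto a common phase grid, averaged, and transformed (period-synchronous
    averaging; identical to an integer-cycle rectangular-window DFT for a
    periodic signal).

    HRF = 10*log10(sum_{n>=2} A_n^2 / A_1^2) on the flow spectrum.
    H1-H2 = 20*log10(A_1' / A_2') on the radiated-source spectrum, whose
    harmonic amplitudes are ``A_n' = n * A_n`` (ideal differentiation of the
    flow, the +6 dB/octave radiation characteristic).

    Returns ``(hrf_db, h1h2_db, flagged)`` where ``flagged`` marks a
    degenerate spectrum floored/ceilinged at +-100 dB.
    """
    if not (f0 > 0):
        raise ValueError("f0 must be positive")
    u = np.asarray(flow.u)
    period_samples = 1000.0 / (f0 * flow.dt)
    n_cycles = int(u.size / period_samples)
    if n_cycles < 1:
        return HRF_FLOOR_DB, H1H2_CEILING_DB, True
    # phase grid fine enough that all physically meaningful harmonics
    # resolve; 64 averaged cycles are ample for a near-periodic waveform
    m = 1024
    n_avg = min(n_cycles, 64)
    phase = np.arange(m) / m
    pos = (np.arange(n_avg)[:, None] + phase[None, :]) * period_samples
    cyc = np.interp(pos.ravel(), np.arange(u.size), u).reshape(n_avg, m)
    amp = np.abs(np.fft.rfft(cyc.mean(axis=0)))
    harm = amp[1:]
    tiny = 1e-12 * max(amp.max(), 1e-300)
    a1 = harm[0] if harm.size >= 1 else 0.0
    a2 = harm[1] if harm.size >= 2 else 0.0
    flagged = False
    if a1 <= tiny:
        return HRF_FLOOR_DB, H1H2_CEILING_DB, True
    # amplitudes below -80 dB re H1 are numerical noise, not harmonics
    rest = harm[1:]
    rest = rest[rest > 1e-4 * a1]
    power_ratio = float(np.sum(rest**2)) / a1**2
    if power_ratio <= 0.0:
        hrf = HRF_FLOOR_DB
        flagged = True
    else:
        hrf = max(10.0 * math.log10(power_ratio), HRF_FLOOR_DB)
    if a2 <= tiny:
        h1h2 = H1H2_CEILING_DB
        flagged = True
    else:
        # radiated spectrum: harmonic n is weighted by n
        h1h2 = min(20.0 * math.log10(a1 / (2.0 * a2)), H1H2_CEILING_DB)
    return hrf, h1h2, flagged


def extract_measures(flow: GlottalFlowSeries, spectral: bool = True) -> VoiceMeasures:
    """Full measure extraction: cycle detection, time-domain and spectral."""
    cycles = detect_cycles(flow)
    m = time_domain_measures(flow, cycles)
    if m.oscillating and spectral:
        m.hrf, m.h1h2, m.spectrum_flagged = spectral_measures(flow, m.f0)
    return m


def classify_normal(measures: VoiceMeasures,
                    criteria: NormalPhonationCriteria | None = None,
                    ) -> tuple[bool, dict[str, bool]]:
    """Normal-phonation filter: oscillating and all six bounds met inclusively."""
    criteria = criteria or NormalPhonationCriteria()
    flags: dict[str, bool] = {}
    for f in fields(criteria):
        lo, hi = getattr(criteria, f.name)
        v = getattr(measures, f.name)
        flags[f.name] = bool(np.isfinite(v) and lo <= v <= hi)
    ok = bool(measures.oscillating) and all(flags.values())
    return ok, flags


_CONVERSIONS = {
    # flow: cm^3/ms -> cm^3/s
    "cm3_per_ms_to_cm3_per_s": 1e3,
    # flow declination: cm^3/ms^2 -> L/s^2
    "cm3_per_ms2_to_l_per_s2": 1e3,
    # pressure: g/(cm*ms^2) -> cm H2O (via dyn/cm^2, g_n = 980.665 cm/s^2)
    "g_per_cm_ms2_to_cmh2o": 1e6 / 980.665,
}
_CONVERSIONS.update({
    "cm3_per_s_to_cm3_per_ms": 1.0 / _CONVERSIONS["cm3_per_ms_to_cm3_per_s"],
    "l_per_s2_to_cm3_per_ms2": 1.0 / _CONVERSIONS["cm3_per_ms2_to_l_per_s2"],
    "cmh2o_to_g_per_cm_ms2": 1.0 / _CONVERSIONS["g_per_cm_ms2_to_cmh2o"],
})


def convert_units(value: float, kind: str) -> float:
    """Scale ``value`` by the named unit conversion factor."""
    try:
        return value * _CONVERSIONS[kind]
    except KeyError:
        raise ValueError(f"unknown conversion {kind!r}") from None


def evaluate_parameters(params, config: SimConfig | None = None,
                        spectral: bool = True) -> VoiceMeasures:
    """Simulate one parameter set and extract its voice measures.

    This is the simulate -> measure step shared by population sampling,
    sensitivity perturbations and the designed-experiment methods.  A
    diverged simulation yields ``oscillating=False``.
    """
    flow, diverged = simulate_flow(params, config)
    if diverged:
        return VoiceMeasures()
    return extract_measures(flow, spectral=spectral)
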
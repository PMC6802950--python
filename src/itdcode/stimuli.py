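"""Binaural noise stimuli.

Generates the bandlimited noise tokens that drive both neural models and
the (simulated) behavioral experiments: uniformly distributed white noise,
bandpassed with a zero-phase Butterworth filter (36 dB/octave roll-off,
corners at 300 and 1200 Hz), 1 s long with 10 ms squared-cosine ramps.

Sign convention (used everywhere in this package): a *positive* ITD means
the sound in the **left** ear leads, i.e. the right channel is delayed;
perceptually this pulls the image toward the left, which maps onto
*negative* laterality scores on the [-1, +1] response scale.  The
convention is declared, not derived — the direction of "right" is
arbitrary until fixed.

ITDs are imposed as exact sub-sample delays via a frequency-domain phase
shift (a 20 µs grid is 3.84 samples at 192 kHz), so no resampling is ever
needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "BandSpec",
    "BinauralToken",
    "make_noise_token",
    "apply_itd",
    "inverse_a_weight",
    "a_weight",
    "a_weighting_db",
    "scale_db",
]


class ParameterError(ValueError):
    """Raised for invalid stimulus parameters."""


@dataclass(frozen=True)
class BandSpec:
    """Passband description: corner frequencies and roll-off steepness.

    ``rolloff_db_per_oct`` is the *net* asymptotic slope.  Realized as an
    order ``rolloff/12`` Butterworth applied forward-backward (filtfilt),
    each pass contributing half the slope — the only way to satisfy
    "zero-phase" and the quoted roll-off jointly.
    """

    low_hz: float = 300.0
    high_hz: float = 1200.0
    rolloff_db_per_oct: float = 36.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ParameterError(
                f"need 0 < low_hz < high_hz, got {self.low_hz}, {self.high_hz}"
            )
        if self.rolloff_db_per_oct <= 0:
            raise ParameterError("rolloff must be positive")
        if self.rolloff_db_per_oct % 12:
            raise ParameterError(
                "net rolloff must be a multiple of 12 dB/oct "
                "(6 dB/oct per Butterworth order, two passes)"
            )

    @property
    def order_per_pass(self) -> int:
        return int(self.rolloff_db_per_oct // 12)


@dataclass
class BinauralToken:
    """Two-channel noise token with its stimulus metadata.

    ``itd`` is in microseconds, positive = left channel leads.
    """

    left: np.ndarray
    right: np.ndarray
    sample_rate: float
    itd: float = 0.0
    duration: float = 1.0
    ramp: float = 0.01
    level_spl: float = 50.0
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.left.size

    def copy(self) -> "BinauralToken":
        return replace(self, left=self.left.copy(), right=self.right.copy(),
                       meta=dict(self.meta))

    def to_json_sidecar(self) -> str:
        return json.dumps(
            {
                "sample_rate": self.sample_rate,
                "itd_us": self.itd,
                "duration_s": self.duration,
                "ramp_s": self.ramp,
                "level_spl": self.level_spl,
            }
        )


def _cos_sq_ramp(n_total: int, n_ramp: int) -> np.ndarray:
    """Squared-cosine on/off envelope; unity in the steady-state portion."""
    env = np.ones(n_total)
    if n_ramp > 0:
        t = np.linspace(0.0, np.pi / 2, n_ramp, endpoint=False)
        env[:n_ramp] = np.sin(t) ** 2
        env[-n_ramp:] = env[:n_ramp][::-1]
    return env


def _bandpass_zero_phase(x: np.ndarray, band: BandSpec, sample_rate: float) -> np.ndarray:
    """Forward-backward Butterworth bandpass.

    Corners are pre-warped so the *net* (two-pass) response is 3 dB down at
    ``band.low_hz`` / ``band.high_hz``: a single Butterworth pass must then
    be 1.5 dB down at the corner, which for order n happens at
    (10**0.15 - 1)**(1/(2n)) times the -3 dB frequency.
    """
    n = band.order_per_pass
    stretch = (10 ** 0.15 - 1.0) ** (1.0 / (2 * n))  # < 1
    lo = band.low_hz * stretch
    hi = band.high_hz / stretch
    nyq = sample_rate / 2.0
    if hi >= nyq:
        raise ParameterError("band upper corner too close to Nyquist")
    sos = signal.butter(n, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    return signal.sosfiltfilt(sos, x)


def make_noise_token(
    duration: float = 1.0,
    sample_rate: float = 192_000.0,
    band: BandSpec | None = None,
    seed: int = 0,
    ramp: float = 0.01,
    level_spl: float = 50.0,
) -> BinauralToken:
    """Generate a diotic bandlimited noise token.

    A fresh token of uniformly distributed white noise is bandpassed with
    the zero-phase Butterworth filter described by ``band`` (default
    300-1200 Hz, 36 dB/oct), scaled to unit RMS, ramped, and duplicated
    into both channels (ITD = 0).

    Parameters
    ----------
    duration, sample_rate : token length (s) and rate (Hz); the rate must
        be at least four times the upper band corner.
    band : BandSpec, defaults to the experiment's 300-1200 Hz band.
    seed : RNG seed (numpy PCG64); identical seeds give identical tokens.
    """
    band = band or BandSpec()
    if duration <= 0:
        raise ParameterError("duration must be positive")
    if sample_rate < 4 * band.high_hz:
        raise ParameterError("sample_rate must be at least 4x the upper corner")
    n = int(round(duration * sample_rate))
    rng = np.random.default_rng(seed)
    x = rng.uniform(-1.0, 1.0, n)
    x = _bandpass_zero_phase(x, band, sample_rate)
    x /= np.sqrt(np.mean(x**2))
    x *= _cos_sq_ramp(n, int(round(ramp * sample_rate)))
    return BinauralToken(
        left=x, right=x.copy(), sample_rate=sample_rate, itd=0.0,
        duration=duration, ramp=ramp, level_spl=level_spl,
        meta={"seed": seed, "band": (band.low_hz, band.high_hz)},
    )


def _frac_delay(x: np.ndarray, delay_s: float, sample_rate: float) -> np.ndarray:
    """Exact (circular) fractional delay via frequency-domain phase shift."""
    n = x.size
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    spectrum = np.fft.rfft(x) * np.exp(-2j * np.pi * freqs * delay_s)
    return np.fft.irfft(spectrum, n)


def apply_itd(token: BinauralToken, itd_us: float) -> BinauralToken:
    """Impose an interaural time difference on a token.

    Positive ``itd_us`` delays the *right* channel (left leads).  The delay
    is applied in the frequency domain, so any microsecond value on any
    sample rate is represented exactly; channel RMS is preserved.
    """
    if abs(itd_us) > 1000:
        raise ParameterError("|ITD| must be at most 1000 us")
    out = token.copy()
    if itd_us != 0.0:
        out.right = _frac_delay(token.right, itd_us * 1e-6, token.sample_rate)
    out.itd = token.itd + itd_us
    return out


# --- A-weighting -----------------------------------------------------------

_A_POLES = (20.598997, 107.65265, 737.86223, 12194.217)


def a_weighting_db(freq_hz: np.ndarray | float) -> np.ndarray | float:
    """Standard A-weighting magnitude in dB (0 dB at 1 kHz by definition)."""
    f2 = np.asarray(freq_hz, dtype=float) ** 2
    p1, p2, p3, p4 = (p**2 for p in _A_POLES)
    num = p4 * f2**2
    den = (f2 + p1) * np.sqrt((f2 + p2) * (f2 + p3)) * (f2 + p4)
    with np.errstate(divide="ignore"):
        ra = np.where(f2 > 0, num / np.where(den > 0, den, 1.0), 0.0)
        db = 20.0 * np.log10(np.where(ra > 0, ra, np.finfo(float).tiny))
    return db - float(a_weighting_db.__dict__.setdefault("_ref", _a_ref()))


def _a_ref() -> float:
    f2 = 1000.0**2
    p1, p2, p3, p4 = (p**2 for p in _A_POLES)
    ra = (p4 * f2**2) / ((f2 + p1) * np.sqrt((f2 + p2) * (f2 + p3)) * (f2 + p4))
    return 20.0 * np.log10(ra)


def _spectral_weight(token: BinauralToken, gain_db_of_f, floor_hz: float = 150.0
                     ) -> BinauralToken:
    """Apply a zero-phase frequency-sampling gain curve to both channels.

    Below ``floor_hz`` the gain is held at its ``floor_hz`` value to avoid
    the unbounded low-frequency boost of the inverse A-curve; the token's
    own passband (>=300 Hz) is unaffected by the clamp.
    """
    n = token.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / token.sample_rate)
    f_eval = np.maximum(freqs, floor_hz)
    gain = 10.0 ** (np.asarray(gain_db_of_f(f_eval), dtype=float) / 20.0)
    out = token.copy()
    for ch in ("left", "right"):
        spec = np.fft.rfft(getattr(token, ch)) * gain
        setattr(out, ch, np.fft.irfft(spec, n))
    return out


def inverse_a_weight(token: BinauralToken, floor_hz: float = 150.0) -> BinauralToken:
    """Boost the spectrum by the inverse of the A-weighting curve.

    Inverse A-weighting raises each band roughly in proportion to the human
    detection threshold so all bands sit at about the same sensation level;
    gain is 0 dB at 1 kHz and applied with zero phase.
    """
    if token.sample_rate < 8000:
        raise ParameterError("sample rate too low for A-weighting inversion")
    out = _spectral_weight(token, lambda f: -a_weighting_db(f), floor_hz)
    out.meta["weighting"] = "inverse_a"
    return out


def a_weight(token: BinauralToken, floor_hz: float = 150.0) -> BinauralToken:
    """Apply the standard A-weighting curve (the inverse of inverse_a_weight)."""
    out = _spectral_weight(token, a_weighting_db, floor_hz)
    out.meta["weighting"] = "a"
    return out


def scale_db(token: BinauralToken, gain_db: float) -> BinauralToken:
    """Scale both channels by ``gain_db``; nominal level metadata follows."""
    g = 10.0 ** (gain_db / 20.0)
    out = token.copy()
    out.left = out.left * g
    out.right = out.right * g
    out.level_spl = token.level_spl + gain_db
    return out
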
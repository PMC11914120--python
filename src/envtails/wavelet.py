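"""Frequency-specific amplitude envelopes via complex Gaussian wavelets.

The analytic signal at each analysis frequency is reconstructed with the
continuous wavelet transform using the order-n complex Gaussian family
(``cgauN``: the n-th derivative of a complex-modulated Gaussian,
psi(t) = C_n d^n/dt^n (e^{-it} e^{-t^2})); the instantaneous amplitude is the
modulus of the complex coefficients.  The scale for a target frequency f is
a = fc / (f * dt), where the wavelet's intrinsic center frequency fc is
computed numerically as the spectral peak of psi rather than taken from a
table, so the pseudo-frequency calibration is convention-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pywt

from envtails.errors import ValidationError
from envtails.preprocess import Segment

DEFAULT_FREQUENCIES = (2.0, 6.0, 10.5, 22.0, 39.0)

# pywt provides the complex Gaussian family up to the 8th derivative
_MAX_ORDER = 8


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet family order, analysis frequencies and edge handling.

    ``edge_policy="keep"`` retains every time point (each sample enters the
    empirical amplitude distribution); ``"trim"`` drops
    ``trim_scales * max(scale)`` samples from both ends, where the cone of
    influence of the longest wavelet is widest.  The default trim width of 5
    scales is half the mother wavelet's effective support (it spans roughly
    +/-5 unit-scale time units), i.e. the full cone of influence.
    """

    order: int = 8
    center_frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    edge_policy: str = "keep"
    trim_scales: float = 5.0

    def __post_init__(self) -> None:
        if not (1 <= self.order <= _MAX_ORDER):
            raise ValidationError(f"wavelet order must be in 1..{_MAX_ORDER}")
        if len(self.center_frequencies) < 1:
            raise ValidationError("need at least one analysis frequency")
        if any(f <= 0 for f in self.center_frequencies):
            raise ValidationError("analysis frequencies must be positive")
        if self.edge_policy not in ("keep", "trim"):
            raise ValidationError(f"unknown edge_policy {self.edge_policy!r}")

    @property
    def fc(self) -> float:
        return wavelet_center_frequency(self.order)

    def wavelet_name(self) -> str:
        return f"cgau{self.order}"


@lru_cache(maxsize=None)
def wavelet_center_frequency(order: int) -> float:
    """Intrinsic center frequency of the order-n complex Gaussian wavelet.

    Computed as argmax over frequency of |FT(psi)| on a densely zero-padded
    FFT grid with parabolic refinement of the peak; the magnitude of the
    peak frequency is returned (the complex Gaussian passband is one-sided).
    Cached per order.
    """
    if order < 1:
        raise ValidationError("wavelet order must be >= 1")
    if order > _MAX_ORDER:
        raise ValidationError(f"wavelet order must be <= {_MAX_ORDER}")
    wav = pywt.ContinuousWavelet(f"cgau{order}")
    psi, t = wav.wavefun(level=14)
    dt = t[1] - t[0]
    n_fft = 1 << 20
    mag = np.abs(np.fft.fft(psi, n_fft))
    freqs = np.fft.fftfreq(n_fft, d=dt)
    i = int(np.argmax(mag))
    # parabolic interpolation around the discrete peak
    y0, y1, y2 = mag[i - 1], mag[i], mag[(i + 1) % n_fft]
    denom = y0 - 2 * y1 + y2
    shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    df = freqs[1] - freqs[0]
    return float(abs(freqs[i] + shift * df))


def scale_for_frequency(freq: float, fs: float, order: int = 8) -> float:
    """Wavelet scale whose pseudo-frequency fc/(a*dt) equals ``freq``."""
    if freq <= 0:
        raise ValidationError("frequency must be positive")
    return wavelet_center_frequency(order) * fs / freq


def pseudo_frequency(scale: float, fs: float, order: int = 8) -> float:
    """Signal frequency associated with a wavelet scale: f = fc/(a*dt)."""
    return wavelet_center_frequency(order) * fs / scale


def cwt_envelope(segment: Segment, spec: WaveletSpec) -> np.ndarray:
    """Instantaneous amplitude of the segment at each analysis frequency.

    Returns a nonnegative array of shape (channels, frequencies, time):
    the modulus of the complex wavelet coefficients, computed by FFT-based
    convolution at the scale matching each requested frequency.  Under
    ``edge_policy="keep"`` the time axis matches the segment length; under
    ``"trim"`` both ends are shortened by the largest scale's margin so the
    array stays rectangular across frequencies.
    """
    fs = segment.fs
    nyquist = fs / 2.0
    for f in spec.center_frequencies:
        if f >= nyquist:
            raise ValidationError(f"analysis frequency {f} Hz >= Nyquist {nyquist} Hz")
    if not segment.normalized:
        warnings.warn(
            "segment is not normalized; envelope scale will be arbitrary",
            stacklevel=2,
        )
    scales = np.array([scale_for_frequency(f, fs, spec.order) for f in spec.center_frequencies])
    coef, _ = pywt.cwt(
        segment.data,
        scales,
        spec.wavelet_name(),
        sampling_period=1.0 / fs,
        method="fft",
        axis=-1,
    )
    amplitude = np.abs(np.moveaxis(coef, 0, 1))  # (channels, freqs, time)
    if spec.edge_policy == "trim":
        margin = int(np.ceil(spec.trim_scales * scales.max()))
        if 2 * margin >= amplitude.shape[-1]:
            raise ValidationError(
                f"trim margin {margin} samples leaves no interior in a "
                f"{amplitude.shape[-1]}-sample segment"
            )
        amplitude = amplitude[..., margin:-margin]
    return amplitude


def envelope_tensor(segments: list[Segment], spec: WaveletSpec) -> np.ndarray:
    """Stack per-segment envelopes: (segments, channels, frequencies, time)."""
    return np.stack([cwt_envelope(s, spec) for s in segments])
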
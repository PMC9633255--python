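"""Dichotic stimulus construction: complementary spectral bands per ear.

The low-frequency (LF, left) ear receives the token low-pass filtered at a
fixed cutoff of 250, 500, 750 or 1,000 Hz; the high-frequency (HF, right)
ear receives the same token high-pass filtered at the adaptively tracked
cutoff.  Both filters are fifth-order Butterworth designs (30 dB/oct
nominal roll-off) applied forward-backward so the net group delay is zero.

The roll-off probe (:func:`measure_rolloff`) characterises the
continuous-time Butterworth prototype, whose stopband slope is exactly
6 x order dB/octave.  The filter actually applied to audio is the
pre-warped bilinear (digital) realisation, which shares the -3 dB point
but is steeper than the nominal slope close to Nyquist — a property of any
IIR implementation, noted here so the two are not conflated.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, freqs, sosfiltfilt

from .core import AudioToken, SAMPLE_RATE

__all__ = [
    "FilterSpec",
    "ButterworthFilter",
    "design_butterworth",
    "apply_zero_phase",
    "measure_rolloff",
    "make_dichotic",
    "DichoticStimulus",
    "LPF_CUTOFFS",
    "HPF_GRID_STEP",
    "HPF_START",
    "write_stereo_wav",
]

#: The four fixed LF-ear low-pass cutoffs, Hz.
LPF_CUTOFFS = (250, 500, 750, 1000)

#: Adaptive HF-ear high-pass grid step and starting cutoff, Hz.
HPF_GRID_STEP = 100
HPF_START = 7000


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth design request.

    ``rolloff_nominal`` is the asymptotic stopband slope of the Butterworth
    family, 6 dB/octave per order.
    """

    kind: str
    order: int
    cutoff: float

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass"):
            raise ValueError(f"kind must be 'lowpass' or 'highpass', got {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not (0.0 < self.cutoff < SAMPLE_RATE / 2):
            raise ValueError(
                f"cutoff must lie in (0, {SAMPLE_RATE / 2}) Hz, got {self.cutoff}"
            )

    @property
    def rolloff_nominal(self) -> float:
        """Nominal asymptotic slope, dB/octave."""
        return 6.0 * self.order


@dataclass(frozen=True)
class ButterworthFilter:
    """An opaque designed filter: digital SOS plus its design spec."""

    spec: FilterSpec
    sos: np.ndarray


@lru_cache(maxsize=64)
def _design_cached(kind: str, order: int, cutoff: float) -> ButterworthFilter:
    spec = FilterSpec(kind=kind, order=order, cutoff=cutoff)
    sos = butter(order, cutoff, btype=kind, fs=SAMPLE_RATE, output="sos")
    # stability: all poles strictly inside the unit circle
    for section in sos:
        poles = np.roots(section[3:])
        if np.any(np.abs(poles) >= 1.0):
            raise RuntimeError("designed filter is unstable")
    return ButterworthFilter(spec=spec, sos=sos)


def design_butterworth(spec: FilterSpec) -> ButterworthFilter:
    """Design a digital Butterworth filter (bilinear, pre-warped).

    The -3 dB point falls exactly at ``spec.cutoff``.  Designs are cached
    per (kind, order, cutoff).
    """
    return _design_cached(spec.kind, spec.order, float(spec.cutoff))


def _zero_phase_sos(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Forward-backward SOS filtering with reflected edge padding."""
    transient = 3 * 2 * sos.shape[0]
    if x.size <= transient:
        raise ValueError("signal too short for zero-phase filtering")
    padlen = min(transient * 4, x.size - 1)
    return sosfiltfilt(sos, x, padtype="even", padlen=padlen)


def apply_zero_phase(token: AudioToken, filt: ButterworthFilter) -> AudioToken:
    """Apply a designed filter forward-backward (zero net group delay).

    Length is preserved; the magnitude response is applied twice, so the
    effective attenuation is double the single-pass design value.
    """
    return token.with_samples(_zero_phase_sos(filt.sos, token.samples))


def measure_rolloff(filt: ButterworthFilter, f1: float, f2: float) -> float:
    """Single-pass stopband slope between ``f1`` and ``f2 = 2 x f1``, dB/oct.

    Evaluates the continuous-time Butterworth prototype magnitude, i.e. the
    design's nominal roll-off, at the two probe frequencies and returns
    ``|H(f1)|_dB - |H(f2)|_dB``.  Both probes must lie in the stopband
    asymptote region for the result to approximate 6 x order dB/octave.
    """
    nyquist = SAMPLE_RATE / 2
    if not (0.0 < f1 < nyquist and 0.0 < f2 <= 2 * nyquist):
        raise ValueError("probe frequencies must be positive and below Nyquist")
    if not np.isclose(f2, 2.0 * f1):
        raise ValueError("probes must be one octave apart (f2 = 2 * f1)")
    spec = filt.spec
    b, a = butter(spec.order, 2 * np.pi * spec.cutoff, btype=spec.kind, analog=True)
    _, h = freqs(b, a, worN=2 * np.pi * np.array([f1, f2]))
    mag_db = 20.0 * np.log10(np.abs(h))
    return float(mag_db[0] - mag_db[1])


@dataclass(frozen=True)
class DichoticStimulus:
    """Left (LF-ear) / right (HF-ear) channel pair with their cutoffs.

    ``left``/``right`` may be ``None`` for a cutoffs-only stimulus, used by
    the fast listener backend that reasons over delivered bands without
    synthesising audio.
    """

    lpf_cutoff: int
    hpf_cutoff: int
    left: AudioToken | None = None
    right: AudioToken | None = None

    def __post_init__(self) -> None:
        _validate_cutoffs(self.lpf_cutoff, self.hpf_cutoff)
        if (self.left is None) != (self.right is None):
            raise ValueError("left and right channels must both be set or both None")
        if self.left is not None and self.left.n_samples != self.right.n_samples:
            raise ValueError("left and right channels must have equal length")

    @property
    def has_audio(self) -> bool:
        return self.left is not None

    @classmethod
    def from_cutoffs(cls, lpf_cutoff: int, hpf_cutoff: int) -> "DichoticStimulus":
        """Lightweight stimulus carrying only the two filter cutoffs."""
        return cls(lpf_cutoff=lpf_cutoff, hpf_cutoff=hpf_cutoff)


def _validate_cutoffs(lpf_cutoff: int, hpf_cutoff: int) -> None:
    if lpf_cutoff not in LPF_CUTOFFS:
        raise ValueError(f"lpf_cutoff must be one of {LPF_CUTOFFS}, got {lpf_cutoff}")
    if hpf_cutoff % HPF_GRID_STEP != 0 or not (HPF_GRID_STEP <= hpf_cutoff <= HPF_START):
        raise ValueError(
            f"hpf_cutoff must lie on the {HPF_GRID_STEP}-Hz grid in "
            f"[{HPF_GRID_STEP}, {HPF_START}], got {hpf_cutoff}"
        )


def make_dichotic(processed: AudioToken, lpf_cutoff: int, hpf_cutoff: int) -> DichoticStimulus:
    """Build the dichotic stimulus from one processed token.

    Left channel: fifth-order zero-phase low-pass at ``lpf_cutoff``.
    Right channel: fifth-order zero-phase high-pass at ``hpf_cutoff``.
    """
    _validate_cutoffs(lpf_cutoff, hpf_cutoff)
    lpf = design_butterworth(FilterSpec("lowpass", 5, float(lpf_cutoff)))
    hpf = design_butterworth(FilterSpec("highpass", 5, float(hpf_cutoff)))
    return DichoticStimulus(
        lpf_cutoff=lpf_cutoff,
        hpf_cutoff=hpf_cutoff,
        left=apply_zero_phase(processed, lpf),
        right=apply_zero_phase(processed, hpf),
    )


def write_stereo_wav(path: str | Path, stimulus: DichoticStimulus) -> None:
    """Write a dichotic stimulus as stereo WAV (left = LF ear, right = HF ear)."""
    if not stimulus.has_audio:
        raise ValueError("stimulus carries no audio channels")
    stereo = np.stack(
        [stimulus.left.samples, stimulus.right.samples], axis=1
    ).astype(np.float32)
    wavfile.write(path, stimulus.left.sample_rate, stereo)
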
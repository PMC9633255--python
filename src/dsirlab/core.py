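"""Shared containers for the DSIR pipeline.

The two containers here are passed between every stage: :class:`AudioToken`
is a mono waveform with its consonant label, and :class:`TFRegion` is a
frequency-band x time-window rectangle on the spectro-temporal plane (the
unit in which target and conflicting consonant cues are tabulated).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Fixed sampling rate of all stimuli, Hz.
SAMPLE_RATE = 44_100

#: Upper edge of the analysis band, Hz.  All stimuli are band-limited to
#: 0-8 kHz and every band/percent metric is expressed relative to this.
BAND_TOP_HZ = 8_000.0


@dataclass(frozen=True)
class AudioToken:
    """A mono consonant-vowel waveform.

    Parameters
    ----------
    samples
        Amplitude samples (dimensionless, nominally within +-1 full scale).
    sample_rate
        Sampling rate in Hz; the pipeline is fixed at 44,100 Hz.
    label
        Consonant label (e.g. ``"ka"``) or ``"custom"`` for external audio.
    """

    samples: np.ndarray
    sample_rate: int = SAMPLE_RATE
    label: str = "custom"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioToken requires a mono (1-D) signal")
        if samples.size == 0:
            raise ValueError("AudioToken requires a non-empty signal")
        if not np.all(np.isfinite(samples)):
            raise ValueError("AudioToken samples must be finite")
        if self.sample_rate != SAMPLE_RATE:
            raise ValueError(f"sample_rate must be {SAMPLE_RATE} Hz")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_ms(self) -> float:
        """Token duration in milliseconds."""
        return 1000.0 * self.samples.size / self.sample_rate

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def rms(self) -> float:
        """Long-term root-mean-square amplitude."""
        return float(np.sqrt(np.mean(self.samples**2)))

    def with_samples(self, samples: np.ndarray) -> "AudioToken":
        """Return a copy carrying ``samples`` but the same metadata."""
        return replace(self, samples=samples)


@dataclass(frozen=True)
class TFRegion:
    """A rectangle on the time-frequency plane.

    Frequencies are in kHz and times in ms from token onset, matching the
    units in which consonant target/conflicting regions are tabulated.
    A region with ``t_lo is None`` has no time bounds and spans the full
    token duration (used for conflicting bands, which are tabulated as
    frequency intervals only).
    """

    f_lo: float
    f_hi: float
    t_lo: float | None = None
    t_hi: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_lo < self.f_hi <= BAND_TOP_HZ / 1000.0):
            raise ValueError(
                f"frequency band must satisfy 0 <= f_lo < f_hi <= 8 kHz, "
                f"got [{self.f_lo}, {self.f_hi}]"
            )
        if (self.t_lo is None) != (self.t_hi is None):
            raise ValueError("t_lo and t_hi must both be set or both be None")
        if self.t_lo is not None and not (0.0 <= self.t_lo < self.t_hi):
            raise ValueError(
                f"time window must satisfy 0 <= t_lo < t_hi, "
                f"got [{self.t_lo}, {self.t_hi}]"
            )

    @property
    def band_hz(self) -> tuple[float, float]:
        """Frequency interval in Hz."""
        return (self.f_lo * 1000.0, self.f_hi * 1000.0)

    @property
    def window_s(self) -> tuple[float, float] | None:
        """Time window in seconds, or None for the full duration."""
        if self.t_lo is None:
            return None
        return (self.t_lo / 1000.0, self.t_hi / 1000.0)
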
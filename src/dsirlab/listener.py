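"""Simulated forced-choice consonant listener.

The stand-in for human subjects: a psychometric observer whose probability
of naming the presented consonant correctly depends on how much of that
consonant's target frequency band the dichotic stimulus delivers.  The
response set has 15 options — the 14 consonant labels plus "none of these"
— mirroring the 15-alternative forced-choice paradigm; the guessing floor
defaults to 1/15.

P(correct) = gamma + (1 - gamma) * logistic(k * (coverage - theta))

where ``coverage`` is the delivered fraction of the target band, ``theta``
the consonant's coverage threshold and ``k`` the psychometric slope
(``inf`` gives a deterministic step observer).  On an incorrect draw a
foil is chosen among the 14 remaining options, uniformly or weighted by
target-band overlap (a crude confusability proxy).

Two coverage backends are provided.  The default ``"cutoff"`` backend
computes coverage by interval arithmetic on the filter cutoffs, which is
exact for ideal filters and fast enough for full simulated experiments.
The ``"waveform"`` backend estimates the same quantity from the delivered
audio as a band power ratio, exercising the DSP path end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.signal import welch

from .core import AudioToken, BAND_TOP_HZ
from .dichotic import DichoticStimulus
from .tokens import CONSONANT_LABELS, ConsonantSpec, get_spec, load_table

__all__ = [
    "RESPONSE_NONE",
    "response_options",
    "band_coverage",
    "coverage",
    "waveform_coverage",
    "ListenerModel",
    "respond",
]

#: The extra "none of these" response option.
RESPONSE_NONE = "none"


def response_options() -> tuple[str, ...]:
    """All 15 response options: the 14 consonants plus "none of these"."""
    return CONSONANT_LABELS + (RESPONSE_NONE,)


def _overlap(a_lo: float, a_hi: float, b_lo: float, b_hi: float) -> float:
    return max(0.0, min(a_hi, b_hi) - max(a_lo, b_lo))


def band_coverage(band_hz: tuple[float, float], lpf_cutoff: float, hpf_cutoff: float) -> float:
    """Delivered fraction of a frequency band under dichotic filtering.

    The LF ear delivers [0, lpf] and the HF ear [hpf, 8000]; coverage is
    the fraction of ``band_hz`` inside their union (the two intervals may
    themselves overlap, in which case the union is the full band).
    """
    lo, hi = band_hz
    if not (0.0 <= lo < hi <= BAND_TOP_HZ):
        raise ValueError("band must lie within 0-8000 Hz")
    low = _overlap(lo, hi, 0.0, lpf_cutoff)
    high = _overlap(lo, hi, hpf_cutoff, BAND_TOP_HZ)
    joint = _overlap(lo, hi, hpf_cutoff, lpf_cutoff)  # non-empty iff hpf < lpf
    return (low + high - joint) / (hi - lo)


def coverage(
    label: str,
    lpf_cutoff: float,
    hpf_cutoff: float,
    registry: Mapping[str, ConsonantSpec] | None = None,
) -> float:
    """Delivered fraction of ``label``'s target band, by interval arithmetic."""
    spec = get_spec(label, dict(registry) if registry is not None else None)
    return band_coverage(spec.target_region.band_hz, lpf_cutoff, hpf_cutoff)


def waveform_coverage(
    stimulus: DichoticStimulus,
    reference: AudioToken,
    band_hz: tuple[float, float],
) -> float:
    """Estimate delivered target-band coverage from the audio itself.

    Ratio of band power summed over the two delivered channels to the band
    power of the unfiltered reference token (Welch periodogram), clipped
    to [0, 1].
    """
    if not stimulus.has_audio:
        raise ValueError("waveform coverage requires audio channels")

    def band_power(x: np.ndarray) -> float:
        f, p = welch(x, fs=reference.sample_rate, nperseg=4096)
        sel = (f >= band_hz[0]) & (f <= band_hz[1])
        return float(np.trapezoid(p[sel], f[sel]))

    ref = band_power(reference.samples)
    if ref == 0.0:
        return 0.0
    delivered = band_power(stimulus.left.samples) + band_power(stimulus.right.samples)
    return float(np.clip(delivered / ref, 0.0, 1.0))


@dataclass(frozen=True)
class ListenerModel:
    """Parameterised psychometric observer.

    Parameters
    ----------
    guess_rate
        Floor probability of a correct response (chance), default 1/15.
    slope
        Logistic slope ``k``; ``np.inf`` yields a step observer.
    thresholds
        Coverage threshold theta, either one number for all consonants or
        a per-consonant mapping.
    confusion_mode
        ``"uniform"`` or ``"confusion_weighted"`` foil selection.
    backend
        ``"cutoff"`` (interval arithmetic, default) or ``"waveform"``.
    condition_offsets
        Optional additive theta offsets per processing condition name
        (e.g. lower theta under target processing to emulate the AI-Gram
        benefit); default none.
    seed
        Optional seed recorded with the model for bookkeeping; randomness
        is always drawn from the generator passed to :func:`respond`.
    """

    guess_rate: float = 1.0 / 15.0
    slope: float = 10.0
    thresholds: float | Mapping[str, float] = 0.5
    confusion_mode: str = "uniform"
    backend: str = "cutoff"
    condition_offsets: Mapping[str, float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.guess_rate < 1.0):
            raise ValueError("guess_rate must lie in (0, 1)")
        if self.confusion_mode not in ("uniform", "confusion_weighted"):
            raise ValueError(f"unknown confusion_mode {self.confusion_mode!r}")
        if self.backend not in ("cutoff", "waveform"):
            raise ValueError(f"unknown backend {self.backend!r}")
        thetas = (
            self.thresholds.values()
            if isinstance(self.thresholds, Mapping)
            else [self.thresholds]
        )
        for theta in thetas:
            if not (0.0 <= theta <= 1.0):
                raise ValueError("thresholds must lie in [0, 1]")

    def threshold_for(self, label: str, condition: str | None = None) -> float:
        theta = (
            self.thresholds.get(label, 0.5)
            if isinstance(self.thresholds, Mapping)
            else self.thresholds
        )
        if condition is not None and self.condition_offsets:
            theta += self.condition_offsets.get(str(condition), 0.0)
        return float(np.clip(theta, 0.0, 1.0))

    def p_correct(self, coverage_value: float, label: str, condition: str | None = None) -> float:
        """Psychometric probability of naming ``label`` correctly."""
        theta = self.threshold_for(label, condition)
        x = coverage_value - theta
        if np.isinf(self.slope):
            core = 1.0 if x > 0 else (0.5 if x == 0 else 0.0)
        else:
            core = 1.0 / (1.0 + np.exp(-self.slope * x))
        return self.guess_rate + (1.0 - self.guess_rate) * core


def _foil_weights(model: ListenerModel, label: str, foils: list[str]) -> np.ndarray:
    if model.confusion_mode == "uniform":
        return np.full(len(foils), 1.0 / len(foils))
    registry = load_table()
    t_lo, t_hi = registry[label].target_region.band_hz
    weights = []
    for foil in foils:
        if foil == RESPONSE_NONE:
            weights.append(0.5)  # "none" competes at a fixed small weight
        else:
            f_lo, f_hi = registry[foil].target_region.band_hz
            width = min(t_hi - t_lo, f_hi - f_lo)
            weights.append(0.1 + _overlap(t_lo, t_hi, f_lo, f_hi) / width)
    w = np.asarray(weights)
    return w / w.sum()


def respond(
    model: ListenerModel,
    label: str,
    stimulus: DichoticStimulus,
    rng: np.random.Generator,
    condition: str | None = None,
    reference: AudioToken | None = None,
) -> str:
    """Draw one forced-choice response to a dichotic presentation.

    With the ``"cutoff"`` backend only the stimulus's cutoffs are read;
    with the ``"waveform"`` backend the delivered audio is analysed
    (``reference`` must then be the processed pre-filtering token).
    """
    if label not in CONSONANT_LABELS:
        raise KeyError(f"unknown consonant label {label!r}")
    if model.backend == "waveform":
        if reference is None:
            raise ValueError("waveform backend requires the reference token")
        band = get_spec(label).target_region.band_hz
        cov = waveform_coverage(stimulus, reference, band)
    else:
        cov = coverage(label, stimulus.lpf_cutoff, stimulus.hpf_cutoff)

    if rng.random() < model.p_correct(cov, label, condition):
        return label
    foils = [opt for opt in response_options() if opt != label]
    return str(rng.choice(foils, p=_foil_weights(model, label, foils)))
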
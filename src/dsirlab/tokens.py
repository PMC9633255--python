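"""Synthetic consonant-vowel stimuli and their conditioning.

Fourteen American-English CV tokens (consonant + /a/) are emulated
parametrically: a voiced, formant-shaped vowel segment at a female mean F0
of 228 Hz, preceded by a consonant-cue segment whose energy is concentrated
inside the consonant's tabulated target frequency x time region.  The
recipe makes target-region energy coverage controllable, so the simulated
listener's information model is physically meaningful.

Conditioning mirrors the stimulus preparation used for the dichotic
experiment: 8-kHz band-limiting with a second-order zero-phase Butterworth
low-pass (12 dB/oct nominal roll-off) and long-term RMS equalisation.
Absolute SPL calibration is out of scope; the reference RMS is expressed in
digital full-scale units (default 0.05 FS).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .core import AudioToken, SAMPLE_RATE, TFRegion

__all__ = [
    "CONSONANT_LABELS",
    "ConsonantSpec",
    "load_table",
    "generate_token",
    "normalize_rms",
    "bandlimit_8k",
    "read_wav",
    "write_wav",
    "DEFAULT_REFERENCE_RMS",
]

#: Canonical consonant labels in table order.  The palatal fricatives are
#: transliterated to ASCII: ``sha`` = /ʃa/ and ``zha`` = /ʒa/.
CONSONANT_LABELS = (
    "pa", "ba", "ta", "da", "ka", "ga", "ma",
    "na", "fa", "va", "sa", "za", "sha", "zha",
)

#: Default long-term RMS after normalisation, in digital full-scale units.
DEFAULT_REFERENCE_RMS = 0.05

#: Mean fundamental frequency of the emulated female talker, Hz.
DEFAULT_F0 = 228.0

# /a/-like formant frequencies (Hz) and bandwidths (Hz) for the vowel
# segment's spectral envelope.
_FORMANTS = ((700.0, 110.0), (1200.0, 120.0), (2600.0, 160.0))


@dataclass(frozen=True)
class ConsonantSpec:
    """Generative recipe for one CV token.

    ``target_region`` is the frequency x time rectangle carrying the
    consonant's recognition cue; ``conflicting_band`` is the frequency
    interval (kHz, no time bounds) whose presence drives confusions.
    """

    label: str
    duration_ms: float
    target_region: TFRegion
    conflicting_band: tuple[float, float]
    f0: float = DEFAULT_F0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        lo, hi = self.conflicting_band
        if not (0.0 <= lo < hi <= 8.0):
            raise ValueError("conflicting band must lie within 0-8 kHz")


def _registry_rows(path: str | Path | None = None) -> list[dict[str, str]]:
    if path is None:
        source = resources.files("dsirlab.data").joinpath("consonant_regions.csv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    rows = list(csv.DictReader(text.splitlines()))
    required = {
        "label", "duration_ms", "target_f_lo_khz", "target_f_hi_khz",
        "conflicting_f_lo_khz", "conflicting_f_hi_khz",
        "target_t_lo_ms", "target_t_hi_ms",
    }
    for row in rows:
        if row.get("label") is None or not required.issubset(row):
            raise ValueError("malformed consonant registry row")
    return rows


def load_table(path: str | Path | None = None) -> dict[str, ConsonantSpec]:
    """Load the consonant registry (bundled CSV by default).

    Returns a mapping from consonant label to :class:`ConsonantSpec` with
    the tabulated duration, target region and conflicting band.
    """
    specs: dict[str, ConsonantSpec] = {}
    for row in _registry_rows(path):
        try:
            spec = ConsonantSpec(
                label=row["label"],
                duration_ms=float(row["duration_ms"]),
                target_region=TFRegion(
                    f_lo=float(row["target_f_lo_khz"]),
                    f_hi=float(row["target_f_hi_khz"]),
                    t_lo=float(row["target_t_lo_ms"]),
                    t_hi=float(row["target_t_hi_ms"]),
                ),
                conflicting_band=(
                    float(row["conflicting_f_lo_khz"]),
                    float(row["conflicting_f_hi_khz"]),
                ),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed consonant registry row: {row!r}") from exc
        specs[spec.label] = spec
    return specs


def get_spec(label: str, registry: dict[str, ConsonantSpec] | None = None) -> ConsonantSpec:
    """Look up one consonant's spec, raising ``KeyError`` for unknown labels."""
    registry = load_table() if registry is None else registry
    try:
        return registry[label]
    except KeyError:
        raise KeyError(f"unknown consonant label {label!r}") from None


def _raised_cosine_ramp(n_samples: int, ramp: int) -> np.ndarray:
    """Unit envelope with raised-cosine onset/offset ramps."""
    env = np.ones(n_samples)
    ramp = min(ramp, n_samples // 2)
    if ramp > 0:
        r = 0.5 - 0.5 * np.cos(np.pi * np.arange(ramp) / ramp)
        env[:ramp] = r
        env[-ramp:] = r[::-1]
    return env


def _vowel_segment(n_samples: int, f0: float, rng: np.random.Generator) -> np.ndarray:
    """Periodic /a/-like segment: harmonics of f0 under a formant envelope."""
    t = np.arange(n_samples) / SAMPLE_RATE
    x = np.zeros(n_samples)
    n_harm = int(7800.0 // f0)
    freqs = f0 * np.arange(1, n_harm + 1)
    # formant resonances on top of a -6 dB/oct glottal source tilt
    env = np.zeros_like(freqs)
    for fc, bw in _FORMANTS:
        env += 1.0 / (1.0 + ((freqs - fc) / bw) ** 2)
    env *= freqs[0] / freqs
    phases = rng.uniform(0, 2 * np.pi, size=n_harm)
    for a, f, ph in zip(env, freqs, phases):
        x += a * np.sin(2 * np.pi * f * t + ph)
    return x / np.sqrt(np.mean(x**2))


def _bandpass_noise(
    n_samples: int, band_hz: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS band-limited noise (4th-order zero-phase Butterworth)."""
    from .dichotic import _zero_phase_sos  # deferred: avoids an import cycle

    from scipy.signal import butter

    lo = max(band_hz[0], 30.0)
    hi = min(band_hz[1], 0.98 * SAMPLE_RATE / 2)
    noise = rng.standard_normal(n_samples)
    sos = butter(4, [lo, hi], btype="bandpass", fs=SAMPLE_RATE, output="sos")
    shaped = _zero_phase_sos(sos, noise)
    return shaped / np.sqrt(np.mean(shaped**2))


def generate_token(spec: ConsonantSpec, seed: int) -> AudioToken:
    """Synthesise one CV token from its spec, reproducibly.

    Layout: the consonant-cue segment (band-limited noise concentrated in
    ``spec.target_region``) occupies the tabulated target time window; the
    voiced vowel segment occupies the remainder of the token after the cue;
    a low-level breathy noise floor runs throughout so the token has no
    strictly silent samples (emulating recordings whose silent edges were
    trimmed).  The cue level is set well above the vowel so that most of
    the cue-window energy falls inside the target region.
    """
    if spec.duration_ms <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_ms / 1000.0 * SAMPLE_RATE))

    t_lo_s, t_hi_s = spec.target_region.window_s or (0.0, n / SAMPLE_RATE)
    i_lo = min(int(round(t_lo_s * SAMPLE_RATE)), n - 1)
    i_hi = min(int(round(t_hi_s * SAMPLE_RATE)), n)

    vowel_rms = 0.2
    cue_rms = 5.0 * vowel_rms
    floor_rms = 0.01 * vowel_rms

    x = floor_rms * rng.standard_normal(n)

    # vowel occupies the latter portion, from the end of the cue window
    v_start = min(i_hi, n - 1)
    n_vowel = n - v_start
    if n_vowel > 8:
        vowel = _vowel_segment(n_vowel, spec.f0, rng)
        vowel *= _raised_cosine_ramp(n_vowel, int(0.010 * SAMPLE_RATE))
        x[v_start:] += vowel_rms * vowel

    # consonant cue: band-limited noise inside the target region
    n_cue = i_hi - i_lo
    if n_cue > 8:
        cue = _bandpass_noise(n_cue, spec.target_region.band_hz, rng)
        cue *= _raised_cosine_ramp(n_cue, max(4, n_cue // 8))
        cue_rms_actual = np.sqrt(np.mean(cue**2))
        x[i_lo:i_hi] += cue_rms / cue_rms_actual * cue

    token = AudioToken(x, SAMPLE_RATE, spec.label)
    token = bandlimit_8k(token)
    return normalize_rms(token, DEFAULT_REFERENCE_RMS)


def make_token(
    label: str,
    seed: int,
    registry: dict[str, ConsonantSpec] | None = None,
) -> AudioToken:
    """Convenience wrapper: look up ``label`` and synthesise its token."""
    return generate_token(get_spec(label, registry), seed)


def normalize_rms(token: AudioToken, reference_rms: float = DEFAULT_REFERENCE_RMS) -> AudioToken:
    """Scale a token so its long-term RMS equals ``reference_rms``.

    Pure scaling: the waveform shape is unchanged.  Raises ``ValueError``
    for an all-zero (silent) token.
    """
    if reference_rms <= 0:
        raise ValueError("reference_rms must be positive")
    rms = token.rms()
    if rms == 0.0:
        raise ValueError("silent token: cannot normalise an all-zero signal")
    return token.with_samples(token.samples * (reference_rms / rms))


def bandlimit_8k(token: AudioToken) -> AudioToken:
    """Limit a token's spectrum to 0-8 kHz.

    Second-order Butterworth low-pass at 8 kHz (12 dB/oct nominal
    roll-off), applied in zero-phase (forward-backward) mode; length is
    preserved.
    """
    from .dichotic import FilterSpec, apply_zero_phase, design_butterworth

    filt = design_butterworth(FilterSpec(kind="lowpass", order=2, cutoff=8000.0))
    return apply_zero_phase(token, filt)


def read_wav(path: str | Path, label: str = "custom") -> AudioToken:
    """Read a mono 44.1-kHz WAV file (PCM 16/24/32-bit or float) as a token."""
    rate, data = wavfile.read(path)
    if rate != SAMPLE_RATE:
        raise ValueError(f"expected {SAMPLE_RATE} Hz audio, got {rate} Hz")
    if data.ndim != 1:
        raise ValueError("expected mono audio")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return AudioToken(data, rate, label)


def write_wav(path: str | Path, token: AudioToken, subtype: str = "float") -> None:
    """Write a token as a mono WAV file (``subtype``: ``float`` or ``pcm16``)."""
    if subtype == "float":
        wavfile.write(path, token.sample_rate, token.samples.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(token.samples, -1.0, 1.0)
        wavfile.write(path, token.sample_rate, (clipped * 32767).astype(np.int16))
    else:
        raise ValueError(f"unsupported WAV subtype {subtype!r}")
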
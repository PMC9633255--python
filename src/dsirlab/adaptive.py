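"""Adaptive tracking of the dichotic spectral integration range (DSIR).

One track measures one cell (consonant x processing condition x LF-ear
low-pass cutoff).  The HF-ear high-pass cutoff starts at 7,000 Hz; every
incorrect response resets the consecutive-correct counter and lowers the
cutoff by 100 Hz; correct responses leave the cutoff unchanged.  The track
converges when the consonant is named correctly three times in a row, and
the DSIR lower bound is the cutoff at convergence.  A track that reaches
the floor cutoff (default 100 Hz, the grid's last positive value) without
converging is flagged ``floored`` rather than assigned a fabricated DSIR.

The full-experiment runner replays the complete design — simulated
subjects x 3 conditions x 4 LPF cutoffs x 14 consonants — with blocked,
randomised consonant order and per-cell RNG substreams derived from one
master seed, so any single cell is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aigram import ProcessingCondition, process_condition
from .core import AudioToken
from .dichotic import (
    DichoticStimulus,
    HPF_GRID_STEP,
    HPF_START,
    LPF_CUTOFFS,
    make_dichotic,
)
from .listener import ListenerModel, respond
from .metrics import pct_of_band
from .tokens import CONSONANT_LABELS, make_token

__all__ = [
    "AdaptiveTrack",
    "DSIRResult",
    "run_track",
    "first_decrement_check",
    "ExperimentConfig",
    "run_experiment",
]

Responder = Callable[[str, DichoticStimulus, np.random.Generator], str]


@dataclass
class AdaptiveTrack:
    """State machine for one descending high-pass track."""

    label: str
    condition: str
    lpf_cutoff: int
    start_hpf: int = HPF_START
    step: int = HPF_GRID_STEP
    floor: int = HPF_GRID_STEP
    n_consecutive: int = 3
    current_hpf: int = field(init=False)
    consecutive_correct: int = field(init=False, default=0)
    trial_log: list[tuple[int, str, bool]] = field(init=False, default_factory=list)
    state: str = field(init=False, default="running")

    def __post_init__(self) -> None:
        if self.floor % self.step != 0 or self.floor < self.step:
            raise ValueError("floor must be a positive multiple of the grid step")
        if self.floor > self.start_hpf:
            raise ValueError("floor cannot exceed the starting cutoff")
        self.current_hpf = self.start_hpf

    @property
    def done(self) -> bool:
        return self.state != "running"

    @property
    def n_trials(self) -> int:
        return len(self.trial_log)

    def observe(self, response: str, correct: bool) -> None:
        """Record one response and update the cutoff/stopping state."""
        if self.done:
            raise RuntimeError("track already finished")
        self.trial_log.append((self.current_hpf, response, correct))
        if correct:
            self.consecutive_correct += 1
            if self.consecutive_correct >= self.n_consecutive:
                self.state = "converged"
        else:
            self.consecutive_correct = 0
            if self.current_hpf <= self.floor:
                self.state = "floored"
            else:
                self.current_hpf -= self.step


def first_decrement_check(track: AdaptiveTrack) -> int:
    """Cutoff scheduled for the trial following the responses so far."""
    if not track.trial_log:
        raise ValueError("no responses recorded yet")
    return track.current_hpf


@dataclass(frozen=True)
class DSIRResult:
    """Outcome of one adaptive track."""

    label: str
    condition: str
    lpf_cutoff: int
    dsir_low: int
    pct_of_band: float
    n_trials: int
    floored: bool


def _as_responder(
    listener: ListenerModel | Responder,
    condition: str,
    reference: AudioToken | None,
) -> Responder:
    if isinstance(listener, ListenerModel):
        def responder(label: str, stimulus: DichoticStimulus, rng: np.random.Generator) -> str:
            return respond(listener, label, stimulus, rng,
                           condition=condition, reference=reference)
        return responder
    return listener


def run_track(
    label: str,
    condition: ProcessingCondition | str,
    lpf_cutoff: int,
    listener: ListenerModel | Responder,
    rng: np.random.Generator,
    *,
    start_hpf: int = HPF_START,
    step: int = HPF_GRID_STEP,
    floor: int = HPF_GRID_STEP,
    n_consecutive: int = 3,
    audio: bool | None = None,
    token_seed: int | None = None,
    track_out: AdaptiveTrack | None = None,
) -> DSIRResult:
    """Run one adaptive track to convergence (or to the floor).

    With ``audio=False`` (the default for a cutoff-backend listener) the
    stimulus is represented by its filter cutoffs only; with ``audio=True``
    the token is synthesised once (``token_seed``), AI-Gram processed for
    ``condition``, and dichotically filtered anew at every presented
    cutoff.  ``track_out`` exposes the underlying state machine and trial
    log to the caller.
    """
    condition = ProcessingCondition(condition).value
    if audio is None:
        audio = isinstance(listener, ListenerModel) and listener.backend == "waveform"

    reference: AudioToken | None = None
    if audio:
        seed = int(rng.integers(2**31)) if token_seed is None else token_seed
        token = make_token(label, seed)
        reference = process_condition(token, label, condition)

    responder = _as_responder(listener, condition, reference)
    track = track_out if track_out is not None else AdaptiveTrack(
        label=label, condition=condition, lpf_cutoff=lpf_cutoff,
        start_hpf=start_hpf, step=step, floor=floor, n_consecutive=n_consecutive,
    )
    while not track.done:
        if audio:
            stimulus = make_dichotic(reference, lpf_cutoff, track.current_hpf)
        else:
            stimulus = DichoticStimulus.from_cutoffs(lpf_cutoff, track.current_hpf)
        response = responder(label, stimulus, rng)
        track.observe(response, response == label)

    return DSIRResult(
        label=label,
        condition=condition,
        lpf_cutoff=lpf_cutoff,
        dsir_low=track.current_hpf,
        pct_of_band=pct_of_band(track.current_hpf),
        n_trials=track.n_trials,
        floored=(track.state == "floored"),
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """Design and listener parameters for a full simulated experiment.

    Defaults replicate the study design: 14 simulated subjects x 3
    processing conditions x 4 LPF cutoffs x 14 consonants, one continuous
    track per cell.  ``n_repetitions > 1`` instead runs that many
    independent tracks per cell (the alternative reading of a repeated
    presentation schedule).
    """

    n_subjects: int = 14
    conditions: Sequence[str] = tuple(c.value for c in ProcessingCondition)
    lpf_cutoffs: Sequence[int] = LPF_CUTOFFS
    consonants: Sequence[str] = CONSONANT_LABELS
    seed: int = 0
    floor: int = HPF_GRID_STEP
    start_hpf: int = HPF_START
    step: int = HPF_GRID_STEP
    n_consecutive: int = 3
    n_repetitions: int = 1
    listener: ListenerModel = field(default_factory=ListenerModel)
    audio: bool = False

    @classmethod
    def from_dict(cls, data: Mapping) -> "ExperimentConfig":
        """Build a config from a plain mapping (e.g. parsed YAML).

        Unknown keys raise ``ValueError``; a ``listener`` sub-mapping is
        converted to a :class:`ListenerModel`.
        """
        data = dict(data)
        listener_cfg = data.pop("listener", None)
        valid = {f.name for f in fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"invalid config keys: {sorted(unknown)}")
        kwargs = dict(data)
        if listener_cfg is not None:
            kwargs["listener"] = (
                listener_cfg if isinstance(listener_cfg, ListenerModel)
                else ListenerModel(**listener_cfg)
            )
        for key in ("conditions", "lpf_cutoffs", "consonants"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def run_experiment(
    config: ExperimentConfig,
    trial_log: list[dict] | None = None,
) -> pd.DataFrame:
    """Run the complete simulated experiment; one row per track.

    Within each (subject, condition, LPF cutoff, repetition) block the
    consonant order is randomised; every track draws from its own RNG
    substream keyed by its design cell, so the table is reproducible from
    the master seed both as a whole and cell by cell.  When ``trial_log``
    is a list, one dict per presented trial (cell, HPF cutoff, response,
    correctness) is appended to it.
    """
    rows = []
    for subject in range(config.n_subjects):
        for c_idx, condition in enumerate(config.conditions):
            for lpf in config.lpf_cutoffs:
                for rep in range(config.n_repetitions):
                    block_ss = np.random.SeedSequence(
                        [config.seed, 1_000_003, subject, c_idx, int(lpf), rep]
                    )
                    order = np.random.default_rng(block_ss).permutation(
                        len(config.consonants)
                    )
                    for pos, k_idx in enumerate(order):
                        label = config.consonants[int(k_idx)]
                        cell_ss = np.random.SeedSequence(
                            [config.seed, subject, c_idx, int(lpf), int(k_idx), rep]
                        )
                        rng = np.random.default_rng(cell_ss)
                        track = AdaptiveTrack(
                            label=label, condition=condition, lpf_cutoff=int(lpf),
                            start_hpf=config.start_hpf, step=config.step,
                            floor=config.floor, n_consecutive=config.n_consecutive,
                        )
                        result = run_track(
                            label, condition, int(lpf), config.listener, rng,
                            start_hpf=config.start_hpf, step=config.step,
                            floor=config.floor, n_consecutive=config.n_consecutive,
                            audio=config.audio,
                            token_seed=int(cell_ss.generate_state(1)[0] % 2**31),
                            track_out=track,
                        )
                        if trial_log is not None:
                            for trial_idx, (hpf, response, correct) in enumerate(track.trial_log):
                                trial_log.append({
                                    "subject": subject,
                                    "condition": condition,
                                    "lpf_cutoff": int(lpf),
                                    "consonant": label,
                                    "repetition": rep,
                                    "trial": trial_idx,
                                    "hpf_cutoff": hpf,
                                    "response": response,
                                    "correct": correct,
                                })
                        rows.append({
                            "subject": subject,
                            "condition": condition,
                            "lpf_cutoff": int(lpf),
                            "consonant": label,
                            "repetition": rep,
                            "block_position": pos,
                            "dsir_low": result.dsir_low,
                            "pct_of_band": result.pct_of_band,
                            "n_trials": result.n_trials,
                            "floored": result.floored,
                        })
    return pd.DataFrame(rows)
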
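"""Sentence-reading trial paradigm: schedule generation.

Each trial has three phases: a preparation period (1.5-2.0 s), a reading
phase in which the sentence's syllables are uttered (bounded by a
maximum reading duration), and a rest period (2-3 s) before the next
trial. A session is ``n_sentences x n_repetitions`` trials in shuffled
order on one continuous timeline. Syllable counts are drawn once per
sentence (the same sentence keeps its length across repetitions) while
syllable and pause durations vary per repetition, as they do in real
read speech.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import Trial, TrialAnnotation


@dataclass
class ParadigmConfig:
    """Timing of the reading task.

    Defaults reproduce the study paradigm: 100 sentences x 3
    repetitions, 1.5-2.0 s preparation, reading capped at 10 s, 2-3 s
    rest, 2,000 Hz acquisition.
    """

    n_sentences: int = 100
    n_repetitions: int = 3
    prep_duration_range: tuple[float, float] = (1.5, 2.0)
    speech_max_duration: float = 10.0
    rest_duration_range: tuple[float, float] = (2.0, 3.0)
    syllables_per_sentence_range: tuple[int, int] = (8, 14)
    syllable_duration_range: tuple[float, float] = (0.15, 0.35)
    pause_probability: float = 0.3
    pause_duration_range: tuple[float, float] = (0.2, 0.6)
    sampling_rate: float = 2000.0

    def validate(self) -> None:
        if self.n_sentences < 1 or self.n_repetitions < 1:
            raise ValueError("sentence and repetition counts must be positive")
        for name in ("prep_duration_range", "rest_duration_range",
                     "syllable_duration_range", "pause_duration_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi, got ({lo}, {hi})")
        lo, hi = self.syllables_per_sentence_range
        if not (1 <= lo <= hi):
            raise ValueError("syllables_per_sentence_range must satisfy 1 <= lo <= hi")
        if self.speech_max_duration <= 0:
            raise ValueError("speech_max_duration must be positive")
        if not 0.0 <= self.pause_probability <= 1.0:
            raise ValueError("pause_probability must lie in [0, 1]")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


def generate_schedule(config: ParadigmConfig, seed: int) -> TrialAnnotation:
    """Lay out all trials of a session on a global timeline.

    Returns a :class:`TrialAnnotation` with ``n_sentences *
    n_repetitions`` trials in seeded-shuffled order. Phase durations are
    drawn uniformly within the configured ranges; intra-sentence pauses
    are inserted between syllables with probability
    ``pause_probability``; the reading phase is truncated at
    ``speech_max_duration``.
    """
    config.validate()
    rng = np.random.default_rng(seed)

    syllable_counts = rng.integers(
        config.syllables_per_sentence_range[0],
        config.syllables_per_sentence_range[1] + 1,
        size=config.n_sentences,
    )

    order = [(s, r) for s in range(config.n_sentences)
             for r in range(config.n_repetitions)]
    rng.shuffle(order)

    trials = []
    t = 0.0
    for trial_id, (sentence_id, repetition) in enumerate(order):
        prep_dur = rng.uniform(*config.prep_duration_range)
        prep = (t, t + prep_dur)
        cursor = prep[1]
        reading_start = cursor
        syllables: list[tuple[float, float]] = []
        for k in range(int(syllable_counts[sentence_id])):
            if k > 0 and rng.random() < config.pause_probability:
                cursor += rng.uniform(*config.pause_duration_range)
            dur = rng.uniform(*config.syllable_duration_range)
            if cursor + dur - reading_start > config.speech_max_duration:
                break
            syllables.append((cursor, cursor + dur))
            cursor += dur
        if not syllables:  # cannot happen with valid config, but stay safe
            dur = min(config.syllable_duration_range[0], config.speech_max_duration)
            syllables = [(cursor, cursor + dur)]
            cursor += dur
        rest_dur = rng.uniform(*config.rest_duration_range)
        rest = (cursor, cursor + rest_dur)
        trials.append(Trial(
            trial_id=trial_id, sentence_id=sentence_id, repetition=repetition,
            prep=prep, syllables=syllables, rest=rest,
        ))
        t = rest[1]
    return TrialAnnotation(trials=trials)
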
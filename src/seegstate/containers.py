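"""Core data containers and their on-disk formats.

A :class:`Recording` is a channels x samples matrix with a sampling rate
and per-channel anatomy. A :class:`TrialAnnotation` holds the per-trial
phase boundaries (preparation / reading / rest) and the syllable
onset/offset intervals from which binary rest/speech labels derive.
Recordings round-trip through an HDF5 container; annotations and channel
tables round-trip through tab-separated text.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .channels import ChannelSpec

Interval = tuple[float, float]


@dataclass
class Recording:
    """Multichannel electrophysiology signal with metadata.

    ``signal`` is (C, N) in microvolt-scale arbitrary units; rows align
    with ``channels``.
    """

    signal: np.ndarray
    sampling_rate: float
    channels: list[ChannelSpec]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.signal.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.signal.shape[0]} signal rows but {len(self.channels)} channel specs"
            )
        if self.signal.shape[0] < 1:
            raise ValueError("need at least one channel")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.signal.shape[1] < self.sampling_rate:
            raise ValueError("recording must span at least one second")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def subset(self, indices: np.ndarray | list[int]) -> "Recording":
        """New recording restricted to the given channel indices (order kept)."""
        idx = np.asarray(indices, dtype=int)
        if idx.size == 0:
            raise ValueError("channel subset is empty")
        return Recording(
            signal=self.signal[idx],
            sampling_rate=self.sampling_rate,
            channels=[self.channels[i] for i in idx],
        )


@dataclass
class Trial:
    """One sentence trial: preparation, syllable intervals, trailing rest.

    All times are seconds on the recording's global timeline.
    """

    trial_id: int
    sentence_id: int
    repetition: int
    prep: Interval
    syllables: list[Interval]
    rest: Interval

    @property
    def start(self) -> float:
        return self.prep[0]

    @property
    def end(self) -> float:
        return self.rest[1]

    @property
    def first_onset(self) -> float:
        return self.syllables[0][0]

    @property
    def last_offset(self) -> float:
        return self.syllables[-1][1]


@dataclass
class TrialAnnotation:
    """Ordered trial schedule / annotation for a whole session."""

    trials: list[Trial] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prev_end = -np.inf
        for tr in self.trials:
            if not tr.syllables:
                continue  # tolerated; segmentation skips such trials with a warning
            intervals = [tr.prep, *tr.syllables, tr.rest]
            for on, off in intervals:
                if off <= on:
                    raise ValueError(
                        f"trial {tr.trial_id}: interval ({on}, {off}) has non-positive length"
                    )
            for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
                if b0 < a1 - 1e-9:
                    raise ValueError(
                        f"trial {tr.trial_id}: overlapping intervals ({a0},{a1}) and ({b0},{b1})"
                    )
            if tr.first_onset <= tr.prep[0]:
                raise ValueError(
                    f"trial {tr.trial_id}: first syllable onset must follow trial start"
                )
            if tr.start < prev_end - 1e-9:
                raise ValueError(f"trial {tr.trial_id} overlaps the previous trial")
            prev_end = tr.end

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def sentence_ids(self) -> list[int]:
        return sorted({tr.sentence_id for tr in self.trials})

    @property
    def duration(self) -> float:
        return max(tr.end for tr in self.trials)

    def trials_for_sentences(self, sentence_ids) -> list[Trial]:
        wanted = set(int(s) for s in sentence_ids)
        return [tr for tr in self.trials if tr.sentence_id in wanted]

    def state_at(self, t: float) -> int:
        """Ground-truth binary state at time ``t``: 1 during speech.

        Speech spans [first syllable onset, last syllable offset) of each
        trial, intra-sentence pauses included; everything else is rest.
        """
        for tr in self.trials:
            if tr.syllables and tr.first_onset <= t < tr.last_offset:
                return 1
        return 0

    def state_vector(self, n_samples: int, sampling_rate: float) -> np.ndarray:
        """Per-sample binary state for the whole timeline (vectorized)."""
        state = np.zeros(n_samples, dtype=np.uint8)
        for tr in self.trials:
            if not tr.syllables:
                continue
            i0 = int(round(tr.first_onset * sampling_rate))
            i1 = int(round(tr.last_offset * sampling_rate))
            state[max(i0, 0):min(i1, n_samples)] = 1
        return state


@dataclass
class Segment:
    """Fixed-length labeled window: the classifier's unit of input."""

    data: np.ndarray  # (C, T)
    label: int  # 0 = rest, 1 = speech
    trial_id: int
    window_start: float  # seconds, global timeline

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (rest) or 1 (speech)")
        if self.data.ndim != 2:
            raise ValueError("segment data must be (C, T)")


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------

_CHANNEL_COLUMNS = ["name", "region", "domain", "tissue", "informative", "snr"]


def channel_table(channels: list[ChannelSpec]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(c) for c in channels],
                        columns=_CHANNEL_COLUMNS)


def channels_from_table(df: pd.DataFrame) -> list[ChannelSpec]:
    missing = [c for c in _CHANNEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"channel table missing columns: {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(ChannelSpec(
                name=str(row["name"]), region=str(row["region"]),
                domain=str(row["domain"]), tissue=str(row["tissue"]),
                informative=bool(row["informative"]), snr=float(row["snr"]),
            ))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"channel table row {i}: {exc}") from exc
    return out


def save_channel_table(path, channels: list[ChannelSpec]) -> None:
    channel_table(channels).to_csv(path, sep="\t", index=False)


def load_channel_table(path) -> list[ChannelSpec]:
    return channels_from_table(pd.read_csv(path, sep="\t"))


def save_recording(path, rec: Recording) -> None:
    """Write a recording to an HDF5 container (signal, rate, channel table)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal.astype(np.float32))
        f.attrs["sampling_rate"] = float(rec.sampling_rate)
        tbl = channel_table(rec.channels)
        grp = f.create_group("channels")
        str_dt = h5py.string_dtype()
        for col in _CHANNEL_COLUMNS:
            vals = tbl[col].to_numpy()
            if vals.dtype == object or col in ("name", "region", "domain", "tissue"):
                grp.create_dataset(col, data=[str(v) for v in vals], dtype=str_dt)
            else:
                grp.create_dataset(col, data=vals)


def load_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        if "signal" not in f or "channels" not in f:
            raise ValueError(f"{path}: not a recording container (missing 'signal'/'channels')")
        signal = f["signal"][()]
        rate = float(f.attrs["sampling_rate"])
        grp = f["channels"]
        data = {}
        for col in _CHANNEL_COLUMNS:
            if col not in grp:
                raise ValueError(f"{path}: channel table missing field {col!r}")
            vals = grp[col][()]
            if vals.dtype.kind in ("S", "O"):
                vals = np.array([v.decode() if isinstance(v, bytes) else str(v)
                                 for v in vals])
            data[col] = vals
        channels = channels_from_table(pd.DataFrame(data))
    return Recording(signal=signal, sampling_rate=rate, channels=channels)


def annotation_table(ann: TrialAnnotation) -> pd.DataFrame:
    rows = []
    for tr in ann.trials:
        rows.append((tr.prep[0], tr.prep[1], "prep", tr.trial_id,
                     tr.sentence_id, tr.repetition))
        for on, off in tr.syllables:
            rows.append((on, off, "syllable", tr.trial_id, tr.sentence_id,
                         tr.repetition))
        rows.append((tr.rest[0], tr.rest[1], "rest", tr.trial_id,
                     tr.sentence_id, tr.repetition))
    return pd.DataFrame(rows, columns=[
        "onset_s", "offset_s", "label", "trial_id", "sentence_id", "repetition"])


def save_annotation(path, ann: TrialAnnotation) -> None:
    annotation_table(ann).to_csv(path, sep="\t", index=False)


def load_annotation(path) -> TrialAnnotation:
    df = pd.read_csv(path, sep="\t")
    required = {"onset_s", "offset_s", "label", "trial_id", "sentence_id", "repetition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: annotation missing columns {sorted(missing)}")
    trials = []
    for trial_id, grp in df.groupby("trial_id", sort=True):
        grp = grp.sort_values("onset_s")
        prep = grp[grp.label == "prep"]
        rest = grp[grp.label == "rest"]
        syl = grp[grp.label == "syllable"]
        if len(prep) != 1 or len(rest) != 1:
            raise ValueError(
                f"{path}: trial {trial_id} needs exactly one prep and one rest interval")
        trials.append(Trial(
            trial_id=int(trial_id),
            sentence_id=int(grp.sentence_id.iloc[0]),
            repetition=int(grp.repetition.iloc[0]),
            prep=(float(prep.onset_s.iloc[0]), float(prep.offset_s.iloc[0])),
            syllables=[(float(a), float(b))
                       for a, b in zip(syl.onset_s, syl.offset_s)],
            rest=(float(rest.onset_s.iloc[0]), float(rest.offset_s.iloc[0])),
        ))
    return TrialAnnotation(trials=trials)
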
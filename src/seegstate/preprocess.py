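"""Signal conditioning and segmentation.

The chain mirrors standard intracranial practice: band limiting
(broadband low-pass at 200 Hz, or 75-150 Hz band-pass for high-gamma
activity), a powerline notch bank (50/100/150/200 Hz, Q=30), per-channel
z-scoring with statistics frozen on the training portion, integer-factor
decimation from 2,000 to 500 Hz, and slicing into non-overlapping
100 ms windows labeled rest/speech from the syllable annotations.

Filters are 4th-order Butterworth. Offline they are applied
forward-backward (zero phase); the streaming/continuous path uses the
same designs forward-only so no future samples influence a window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .containers import Recording, Segment, TrialAnnotation

logger = logging.getLogger(__name__)


@dataclass
class PreprocConfig:
    broadband_cutoff: float = 200.0
    hga_band: tuple[float, float] = (75.0, 150.0)
    notch_freqs: tuple[float, ...] = (50.0, 100.0, 150.0, 200.0)
    notch_q: float = 30.0
    target_rate: float = 500.0
    window_length: float = 0.100
    signal_mode: str = "broadband"  # or "hga"

    def validate(self, raw_rate: float | None = None) -> None:
        if self.signal_mode not in ("broadband", "hga"):
            raise ValueError(f"unknown signal_mode {self.signal_mode!r}")
        if self.window_length <= 0 or self.target_rate <= 0:
            raise ValueError("window_length and target_rate must be positive")
        if raw_rate is not None:
            nyq = raw_rate / 2.0
            if self.signal_mode == "broadband" and self.broadband_cutoff >= nyq:
                raise ValueError("broadband cutoff at or above Nyquist")
            if self.signal_mode == "hga" and self.hga_band[1] >= nyq:
                raise ValueError("high-gamma band edge at or above Nyquist")
            for f in self.notch_freqs:
                if f >= nyq:
                    raise ValueError(f"notch frequency {f} Hz at or above Nyquist")


def filter_signal(rec: Recording, cfg: PreprocConfig,
                  causal: bool = False) -> Recording:
    """Band-limit and notch a recording; shape and rate unchanged.

    ``causal=False`` applies every filter forward-backward (zero phase,
    offline use); ``causal=True`` applies them forward-only for the
    continuous-decoding path.
    """
    cfg.validate(raw_rate=rec.sampling_rate)
    fs = rec.sampling_rate
    x = np.asarray(rec.signal, dtype=np.float64)

    if cfg.signal_mode == "broadband":
        sos = sps.butter(4, cfg.broadband_cutoff, btype="lowpass", fs=fs,
                         output="sos")
    else:
        sos = sps.butter(4, cfg.hga_band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, x, axis=-1) if causal else sps.sosfiltfilt(sos, x, axis=-1)

    for f0 in cfg.notch_freqs:
        b, a = sps.iirnotch(f0, cfg.notch_q, fs=fs)
        x = sps.lfilter(b, a, x, axis=-1) if causal else sps.filtfilt(b, a, x, axis=-1)

    return Recording(signal=x.astype(np.float32), sampling_rate=fs,
                     channels=list(rec.channels))


@dataclass
class ZScoreStats:
    """Per-channel standardization statistics, keyed by channel name."""

    mean: np.ndarray
    sd: np.ndarray
    channel_names: list[str]
    excluded: list[str] = field(default_factory=list)  # zero-variance channels


def compute_zscore_stats(rec: Recording,
                         sample_mask: np.ndarray | None = None) -> ZScoreStats:
    """Means/SDs per channel, optionally over a boolean sample mask.

    In the experiment pipeline the mask selects the training-split
    trials so evaluation data never leaks into the statistics.
    """
    x = rec.signal if sample_mask is None else rec.signal[:, sample_mask]
    if x.shape[1] < 2:
        raise ValueError("not enough samples to estimate statistics")
    mean = x.mean(axis=1, dtype=np.float64)
    sd = x.std(axis=1, dtype=np.float64)
    names = rec.channel_names()
    excluded = [names[i] for i in np.nonzero(sd == 0)[0]]
    return ZScoreStats(mean=mean, sd=sd, channel_names=names, excluded=excluded)


def zscore_standardize(
    rec: Recording, stats: ZScoreStats | None = None,
) -> tuple[Recording, ZScoreStats]:
    """Standardize each channel to zero mean / unit SD.

    With ``stats=None`` the statistics are computed from the recording
    itself; otherwise the provided (frozen) statistics are applied.
    Zero-variance channels are flagged in ``stats.excluded`` and dropped
    from the returned recording rather than passed through silently.
    """
    if stats is None:
        stats = compute_zscore_stats(rec)
    else:
        if stats.channel_names != rec.channel_names():
            raise ValueError("provided statistics do not match recording channels")
    keep = [i for i, name in enumerate(rec.channel_names())
            if name not in stats.excluded]
    if not keep:
        raise ValueError("all channels have zero variance")
    if stats.excluded:
        logger.warning("excluding zero-variance channels: %s", stats.excluded)
    idx = np.asarray(keep)
    z = (rec.signal[idx] - stats.mean[idx, None]) / stats.sd[idx, None]
    out = Recording(signal=z.astype(np.float32), sampling_rate=rec.sampling_rate,
                    channels=[rec.channels[i] for i in keep])
    return out, stats


def trial_sample_mask(ann: TrialAnnotation, trial_ids, n_samples: int,
                      sampling_rate: float) -> np.ndarray:
    """Boolean mask covering the full spans of the given trials."""
    wanted = set(int(t) for t in trial_ids)
    mask = np.zeros(n_samples, dtype=bool)
    for tr in ann.trials:
        if tr.trial_id in wanted:
            i0 = max(int(round(tr.start * sampling_rate)), 0)
            i1 = min(int(round(tr.end * sampling_rate)), n_samples)
            mask[i0:i1] = True
    return mask


def downsample(rec: Recording, target_rate: float) -> Recording:
    """Decimate by the integer factor ``raw_rate / target_rate``.

    Assumes the anti-alias low-pass has already been applied (the
    200 Hz broadband cutoff leaves content below the 250 Hz Nyquist of
    the 500 Hz target); no additional filter is inserted.
    """
    factor = rec.sampling_rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"sampling rate {rec.sampling_rate} not an integer multiple of {target_rate}")
    factor = int(round(factor))
    if factor == 1:
        return rec
    return Recording(signal=rec.signal[:, ::factor], sampling_rate=target_rate,
                     channels=list(rec.channels))


def label_and_segment(rec: Recording, ann: TrialAnnotation,
                      cfg: PreprocConfig) -> list[Segment]:
    """Slice each trial into non-overlapping labeled windows.

    A window is *rest* if it lies entirely before the trial's first
    syllable onset or entirely after its last syllable offset (the
    trailing rest phase), *speech* if it lies entirely within
    [first onset, last offset] — intra-sentence pauses included — and is
    dropped if it straddles either boundary.
    """
    fs = rec.sampling_rate
    T = int(round(cfg.window_length * fs))
    if T < 1:
        raise ValueError("window shorter than one sample at this rate")
    segments: list[Segment] = []
    n = rec.n_samples
    for tr in ann.trials:
        if not tr.syllables:
            logger.warning("trial %d has no syllables; skipped", tr.trial_id)
            continue
        n_windows = int(np.floor((tr.end - tr.start) / cfg.window_length))
        for w in range(n_windows):
            start = tr.start + w * cfg.window_length
            end = start + cfg.window_length
            if end <= tr.first_onset + 1e-9 or start >= tr.last_offset - 1e-9:
                label = 0
            elif start >= tr.first_onset - 1e-9 and end <= tr.last_offset + 1e-9:
                label = 1
            else:
                continue  # straddles a state boundary
            i0 = int(round(start * fs))
            if i0 + T > n:
                break
            segments.append(Segment(data=rec.signal[:, i0:i0 + T], label=label,
                                    trial_id=tr.trial_id, window_start=start))
    return segments


def count_windows(ann: TrialAnnotation, window_length: float) -> int:
    """Total whole windows available across trials (labeled + dropped)."""
    return int(sum(np.floor((tr.end - tr.start) / window_length)
                   for tr in ann.trials if tr.syllables))


def audio_neural_independence_check(
    rec: Recording,
    audio_envelope: np.ndarray,
    epoch_length: float = 600.0,
    n_epochs: int = 10,
    seed: int = 0,
    threshold: float = 0.1,
):
    """Correlation screen between the audio envelope and every channel.

    Pearson correlations are computed over ``n_epochs`` randomly placed
    epochs of ``epoch_length`` seconds; per channel the maximum |r| is
    reported together with a pass flag (max |r| below ``threshold``).
    A contaminated channel (acoustic leakage) shows up as a high |r|.
    """
    import pandas as pd

    fs = rec.sampling_rate
    n_ep = int(round(epoch_length * fs))
    if n_ep > rec.n_samples:
        raise ValueError("epoch longer than the recording")
    if n_ep < 2:
        raise ValueError("epoch too short")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, rec.n_samples - n_ep + 1, size=n_epochs)
    max_abs_r = np.zeros(rec.n_channels)
    for s in starts:
        a = audio_envelope[s:s + n_ep].astype(np.float64)
        a = a - a.mean()
        denom_a = np.sqrt((a * a).sum())
        x = rec.signal[:, s:s + n_ep].astype(np.float64)
        x = x - x.mean(axis=1, keepdims=True)
        denom_x = np.sqrt((x * x).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (x @ a) / (denom_x * denom_a)
        r = np.nan_to_num(r)
        max_abs_r = np.maximum(max_abs_r, np.abs(r))
    return pd.DataFrame({
        "channel": rec.channel_names(),
        "max_abs_r": max_abs_r,
        "independent": max_abs_r < threshold,
    })
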
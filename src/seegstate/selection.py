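"""Speech-responsive channel selection.

Per channel, each trial contributes one paired observation: mean 4-150 Hz
Welch power during the utterance versus during the immediately preceding
silence (matched in duration, capped at the available pre-onset span).
A two-sided paired t-test across trials, Benjamini-Hochberg corrected
across channels, decides responsiveness; occipital and white-matter
contacts are then excluded regardless of significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as sstats

from .channels import OCCIPITAL, WHITE_MATTER, ChannelSpec
from .containers import Recording, TrialAnnotation


def welch_psd(signal: np.ndarray, sampling_rate: float,
              window_length: float = 1.0, overlap: float = 0.5):
    """One-sided Welch power spectral density (Hann window).

    ``signal`` may be 1-D or (C, N); the PSD is taken along the last
    axis. Density scaling is Parseval-consistent: integrating the PSD
    over frequency recovers the variance of a zero-mean input.
    """
    signal = np.asarray(signal)
    nper = int(round(window_length * sampling_rate))
    if nper > signal.shape[-1]:
        raise ValueError("Welch window longer than the signal")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    return sps.welch(signal, fs=sampling_rate, window="hann", nperseg=nper,
                     noverlap=int(round(overlap * nper)), axis=-1)


def mean_band_power(signal: np.ndarray, sampling_rate: float,
                    band: tuple[float, float] = (4.0, 150.0),
                    window_length: float = 1.0, overlap: float = 0.5):
    """Mean of the Welch PSD bins inside ``band`` (inclusive edges)."""
    nper = int(round(window_length * sampling_rate))
    nper = min(nper, signal.shape[-1])  # short intervals: shrink the window
    f, p = sps.welch(signal, fs=sampling_rate, window="hann", nperseg=nper,
                     noverlap=int(round(overlap * nper)), axis=-1)
    sel = (f >= band[0]) & (f <= band[1])
    if not sel.any():
        raise ValueError("no PSD bins inside the requested band")
    return p[..., sel].mean(axis=-1)


def fdr_bh(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up procedure.

    Returns ``(reject, p_adjusted)``. Rejections are all hypotheses with
    raw p at or below the largest p(i) satisfying p(i) <= i*alpha/m;
    adjusted p-values are the usual monotone min-over-tail of m*p(i)/i.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    p_adj = np.empty(m)
    p_adj[order] = adj
    thresh_ok = ranked <= np.arange(1, m + 1) * alpha / m
    if thresh_ok.any():
        cutoff = ranked[np.nonzero(thresh_ok)[0][-1]]
        reject = p <= cutoff
    else:
        reject = np.zeros(m, dtype=bool)
    return reject, p_adj


@dataclass
class ChannelSelectionResult:
    """Per-channel responsiveness statistics and selection flags."""

    table: pd.DataFrame  # channel, region, mean_speech_power, mean_silence_power,
    #                      t, p, p_adj, selected, reason
    alpha: float
    band: tuple[float, float]

    @property
    def selected_names(self) -> list[str]:
        return list(self.table.loc[self.table.selected, "channel"])

    def selected_indices(self) -> np.ndarray:
        return np.nonzero(self.table.selected.to_numpy())[0]


def speech_responsiveness_test(
    rec: Recording,
    ann: TrialAnnotation,
    band: tuple[float, float] = (4.0, 150.0),
    alpha: float = 0.05,
    welch_window: float = 1.0,
) -> ChannelSelectionResult:
    """Paired speech-vs-silence band-power contrast for every channel.

    The speech interval of a trial spans first syllable onset to last
    syllable offset; its paired silence interval immediately precedes
    the onset with matched duration (truncated at the trial start).
    Channels with identically zero paired differences get t=0, p=1.
    """
    fs = rec.sampling_rate
    trials = [tr for tr in ann.trials if tr.syllables]
    if len(trials) < 2:
        raise ValueError("need at least two trials for a paired test")

    speech_power = np.empty((len(trials), rec.n_channels))
    silence_power = np.empty((len(trials), rec.n_channels))
    n = rec.n_samples
    for k, tr in enumerate(trials):
        on, off = tr.first_onset, tr.last_offset
        dur = off - on
        sil_on = max(tr.start, on - dur)
        s0, s1 = int(round(on * fs)), min(int(round(off * fs)), n)
        q0, q1 = int(round(sil_on * fs)), int(round(on * fs))
        speech_power[k] = mean_band_power(rec.signal[:, s0:s1], fs, band,
                                          welch_window)
        silence_power[k] = mean_band_power(rec.signal[:, q0:q1], fs, band,
                                           welch_window)

    diffs = speech_power - silence_power
    t_stat = np.zeros(rec.n_channels)
    p_val = np.ones(rec.n_channels)
    sd = diffs.std(axis=0, ddof=1)
    nonzero = sd > 0
    if nonzero.any():
        res = sstats.ttest_rel(speech_power[:, nonzero], silence_power[:, nonzero],
                               axis=0)
        t_stat[nonzero] = res.statistic
        p_val[nonzero] = res.pvalue
    reject, p_adj = fdr_bh(p_val, alpha=alpha)

    table = pd.DataFrame({
        "channel": rec.channel_names(),
        "region": [c.region for c in rec.channels],
        "mean_speech_power": speech_power.mean(axis=0),
        "mean_silence_power": silence_power.mean(axis=0),
        "t": t_stat,
        "p": p_val,
        "p_adj": p_adj,
        "selected": reject,
        "reason": np.where(reject, "none", "not_significant"),
    })
    return ChannelSelectionResult(table=table, alpha=alpha, band=band)


def apply_exclusions(result: ChannelSelectionResult,
                     specs: list[ChannelSpec]) -> ChannelSelectionResult:
    """Unselect anatomically disallowed channels regardless of significance.

    White-matter contacts and channels in visual cortex (occipital) are
    removed; test statistics are left untouched.
    """
    table = result.table.copy()
    if len(table) != len(specs):
        raise ValueError("selection result and channel specs have different lengths")
    for i, spec in enumerate(specs):
        if table.at[i, "channel"] != spec.name:
            raise ValueError("selection result and channel specs are misaligned")
        if spec.tissue == "white" or spec.region == WHITE_MATTER:
            table.at[i, "selected"] = False
            table.at[i, "reason"] = "white_matter"
        elif spec.region == OCCIPITAL:
            table.at[i, "selected"] = False
            table.at[i, "reason"] = "visual_region"
    return ChannelSelectionResult(table=table, alpha=result.alpha, band=result.band)


def select_channels(rec: Recording, ann: TrialAnnotation,
                    band: tuple[float, float] = (4.0, 150.0),
                    alpha: float = 0.05) -> ChannelSelectionResult:
    """Responsiveness test followed by anatomical exclusions."""
    result = speech_responsiveness_test(rec, ann, band=band, alpha=alpha)
    return apply_exclusions(result, rec.channels)
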
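"""Synthetic SEEG-like signal generation.

Each channel is 1/f^alpha Gaussian background plus powerline harmonics
(50/100/150/200 Hz). Informative channels additionally carry two
speech-state-gated components, mimicking the dominant empirical
signatures of overt speech in intracranial recordings:

* a low-frequency (2-30 Hz) band-limited amplitude modulation, and
* a high-gamma (75-150 Hz) band-limited power increase,

both active only while the ground-truth state is "speech" (first
syllable onset through last syllable offset, pauses included), scaled
by the channel's ``snr`` and gated with 50 ms raised-cosine ramps so
state transitions are not step discontinuities. A syllable-locked audio
envelope is emitted alongside to exercise the audio-neural independence
screen and the labeling rule; no acoustic waveform is synthesized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as scipy_fft
from scipy import signal as sps

from .channels import ChannelSpec
from .containers import Recording, TrialAnnotation


@dataclass
class NoiseParams:
    """Background and nuisance-signal parameters.

    ``alpha`` is the 1/f^alpha spectral exponent of the background
    (power falls off as f^-alpha); ``background_std`` its standard
    deviation in the recording's arbitrary units. ``comp_std`` is the
    standard deviation each state-gated component contributes per unit
    snr while the gate is open.
    """

    alpha: float = 1.0
    background_std: float = 1.0
    line_freqs: tuple[float, ...] = (50.0, 100.0, 150.0, 200.0)
    line_amps: tuple[float, ...] = (0.5, 0.25, 0.12, 0.06)
    lowfreq_band: tuple[float, float] = (2.0, 30.0)
    hga_band: tuple[float, float] = (75.0, 150.0)
    comp_std: float = 0.7
    ramp: float = 0.05  # seconds, raised-cosine gate ramp


@dataclass
class SyntheticDataset:
    """A complete simulated session with ground truth."""

    recording: Recording
    annotation: TrialAnnotation
    audio_envelope: np.ndarray  # (N,) at recording rate, arbitrary units
    state: np.ndarray  # (N,) uint8 ground-truth state per sample
    seed: int

    @property
    def channel_specs(self) -> list[ChannelSpec]:
        return self.recording.channels

    @property
    def informative_mask(self) -> np.ndarray:
        return np.array([c.informative for c in self.recording.channels])


def one_over_f_noise(n: int, alpha: float, rng: np.random.Generator,
                     sampling_rate: float) -> np.ndarray:
    """Unit-variance 1/f^alpha Gaussian noise via spectral shaping.

    Synthesized at the next fast FFT length and truncated, which leaves
    the spectrum unchanged but keeps the transform O(n log n) for any n.
    """
    m = scipy_fft.next_fast_len(n, real=True)
    white = rng.standard_normal(m)
    if alpha == 0:
        return white[:n].astype(np.float32)
    spec = scipy_fft.rfft(white)
    f = scipy_fft.rfftfreq(m, d=1.0 / sampling_rate)
    f[0] = f[1]  # avoid division by zero; DC keeps the lowest-bin gain
    spec *= f ** (-alpha / 2.0)
    x = scipy_fft.irfft(spec, m)[:n]
    x /= x.std()
    return x.astype(np.float32)


def band_limited_noise(n: int, band: tuple[float, float],
                       rng: np.random.Generator,
                       sampling_rate: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed with a 4th-order Butterworth."""
    sos = sps.butter(4, band, btype="bandpass", fs=sampling_rate, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    x /= x.std()
    return x.astype(np.float32)


def _raised_cosine_gate(n: int, ann: TrialAnnotation, sampling_rate: float,
                        ramp: float) -> np.ndarray:
    """Speech-state gate in [0, 1] with raised-cosine on/off ramps."""
    gate = np.zeros(n, dtype=np.float32)
    n_ramp = max(int(round(ramp * sampling_rate)), 1)
    up = 0.5 * (1.0 - np.cos(np.linspace(0, np.pi, n_ramp, dtype=np.float32)))
    for tr in ann.trials:
        if not tr.syllables:
            continue
        i0 = int(round(tr.first_onset * sampling_rate))
        i1 = int(round(tr.last_offset * sampling_rate))
        i0, i1 = max(i0, 0), min(i1, n)
        if i1 <= i0:
            continue
        gate[i0:i1] = 1.0
        ramp_len = min(n_ramp, (i1 - i0) // 2)
        if ramp_len > 0:
            gate[i0:i0 + ramp_len] = up[:ramp_len]
            gate[i1 - ramp_len:i1] = up[:ramp_len][::-1]
    return gate


def _audio_envelope(n: int, ann: TrialAnnotation,
                    sampling_rate: float) -> np.ndarray:
    """Syllable-locked envelope surrogate: one Hann bump per syllable."""
    env = np.zeros(n, dtype=np.float32)
    for tr in ann.trials:
        for on, off in tr.syllables:
            i0 = max(int(round(on * sampling_rate)), 0)
            i1 = min(int(round(off * sampling_rate)), n)
            if i1 - i0 >= 2:
                env[i0:i1] = np.maximum(env[i0:i1],
                                        sps.windows.hann(i1 - i0).astype(np.float32))
    return env


def synthesize_recording(
    schedule: TrialAnnotation,
    specs: list[ChannelSpec],
    noise_params: NoiseParams | None = None,
    seed: int = 0,
    sampling_rate: float = 2000.0,
) -> SyntheticDataset:
    """Render a full multichannel recording for a trial schedule.

    Fully deterministic for a fixed ``seed``. Returns the recording,
    the annotation (unchanged), the audio-envelope surrogate and the
    per-sample ground-truth state.
    """
    if not schedule.trials:
        raise ValueError("schedule has no trials")
    if not specs:
        raise ValueError("no channel specs given")
    np_ = noise_params or NoiseParams()
    rng = np.random.default_rng(seed)

    n = int(np.ceil((schedule.duration + 0.5) * sampling_rate))
    t = np.arange(n, dtype=np.float64) / sampling_rate
    gate = _raised_cosine_gate(n, schedule, sampling_rate, np_.ramp)
    state = schedule.state_vector(n, sampling_rate)

    sig = np.empty((len(specs), n), dtype=np.float32)
    nyq = sampling_rate / 2.0
    for ci, spec in enumerate(specs):
        x = np_.background_std * one_over_f_noise(n, np_.alpha, rng, sampling_rate)
        for freq, amp in zip(np_.line_freqs, np_.line_amps):
            if freq >= nyq:
                continue
            phase = rng.uniform(0, 2 * np.pi)
            x += (amp * np.sin(2 * np.pi * freq * t + phase)).astype(np.float32)
        if spec.informative:
            scale = np.float32(spec.snr * np_.comp_std)
            lf = band_limited_noise(n, np_.lowfreq_band, rng, sampling_rate)
            hg = band_limited_noise(n, np_.hga_band, rng, sampling_rate)
            x += gate * scale * (lf + hg)
        sig[ci] = x

    rec = Recording(signal=sig, sampling_rate=sampling_rate, channels=list(specs))
    audio = _audio_envelope(n, schedule, sampling_rate)
    return SyntheticDataset(recording=rec, annotation=schedule,
                            audio_envelope=audio, state=state, seed=seed)
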
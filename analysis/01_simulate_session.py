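"""Simulate a sentence-reading SEEG session and inspect its structure.

Generates the demo session (12 sentences x 2 repetitions, 16 channels of
which 5 carry speech-state-dependent power), then reports the trial
bookkeeping a real session would have: phase durations, per-trial
syllable counts, and the montage's regional composition. Writes the
annotation and channel tables under results/simulation/.
"""

import sys
from pathlib import Path

import numpy as np

from seegstate import protocols
from seegstate.containers import save_annotation, save_channel_table
from seegstate.pipeline import build_dataset

OUT = Path("results/simulation")


def main(seed: int = 0) -> None:
    cfg = protocols.demo_config(seed)
    ds = build_dataset(cfg)
    ann = ds.annotation

    OUT.mkdir(parents=True, exist_ok=True)
    save_annotation(OUT / "annotation.tsv", ann)
    save_channel_table(OUT / "channels.tsv", ds.channel_specs)

    prep = [tr.prep[1] - tr.prep[0] for tr in ann.trials]
    speech = [tr.last_offset - tr.first_onset for tr in ann.trials]
    n_syll = [len(tr.syllables) for tr in ann.trials]
    print(f"session: {len(ann)} trials over {ann.duration:.1f} s "
          f"({ds.recording.n_channels} channels at "
          f"{ds.recording.sampling_rate:.0f} Hz)")
    print(f"preparation phase: {np.mean(prep):.2f} +- {np.std(prep):.2f} s")
    print(f"utterance span:    {np.mean(speech):.2f} +- {np.std(speech):.2f} s "
          f"({np.mean(n_syll):.1f} syllables/sentence)")
    speech_frac = ds.state.mean()
    print(f"speech-state fraction of the timeline: {speech_frac:.2f}")
    regions = {}
    for c in ds.channel_specs:
        regions.setdefault(c.region, []).append(c.informative)
    print("montage:")
    for region, flags in sorted(regions.items()):
        inf = sum(flags)
        print(f"  {region:<11} {len(flags)} channel(s)"
              + (f", {inf} informative" if inf else ""))
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
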
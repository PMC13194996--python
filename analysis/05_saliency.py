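"""Attribute the decoder's sensitivity to channels and regions.

Trains one model on the demo session and computes gradient saliency:
zeta(c) is the time-averaged absolute gradient of the training loss with
respect to channel c's input samples, averaged over held-out segments,
min-max normalized across channels and aggregated per anatomical region.
Channels that actually carry state-dependent power should dominate the
ranking. Writes the per-region table under results/saliency/.
"""

import sys
from pathlib import Path

import numpy as np

from seegstate import protocols
from seegstate.interpret import saliency
from seegstate.pipeline import (build_dataset, derive_seed,
                                prepare_recordings, run_split_experiment)

OUT = Path("results/saliency")


def main(seed: int = 0) -> None:
    cfg = protocols.demo_config(seed)
    cfg.evaluation.continuous = False
    ds = build_dataset(cfg)
    prepared = prepare_recordings(ds, cfg)
    run = run_split_experiment(prepared, cfg,
                               derive_seed(cfg.seed, "split-0"))
    specs = prepared.offline.channels
    rep = saliency(run.trained, run.eval_segments, specs)

    OUT.mkdir(parents=True, exist_ok=True)
    rep.region_contributions.to_csv(OUT / "region_contributions.tsv",
                                    sep="\t", index=False)
    print("regional contributions (normalized saliency, descending):")
    for _, row in rep.region_contributions.iterrows():
        print(f"  {row.region:<8} {row['mean']:.3f} +- {row.sd:.3f} "
              f"({int(row.n_channels)} ch)")
    inf = np.array([c.informative for c in specs])
    if inf.any() and (~inf).any():
        print(f"mean normalized saliency: informative {rep.zeta_normalized[inf].mean():.3f}"
              f" vs background {rep.zeta_normalized[~inf].mean():.3f}")
    print(f"table written to {OUT}/region_contributions.tsv")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
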
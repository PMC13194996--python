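"""Robustness ablations and gradient-saliency channel attribution.

Three ablation kinds probe how distributed the decodable information is:
random channel dropout (0/10/30/50%), wholesale exclusion of the
classical speech-region set, and restriction to a single anatomical
domain (cortical or subcortical). Each condition retrains the model from
scratch; split seeds are shared across conditions so comparisons are
paired.

Saliency: for channel c, zeta(c) is the time-averaged absolute gradient
of the BCE loss with respect to the input samples of that channel,
averaged over evaluation segments (both classes, dropout off), then
min-max normalized across channels and aggregated per anatomical region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channels import SPEECH_REGIONS, ChannelSpec
from .cnn import TrainedModel, segments_to_arrays
from .containers import Segment


@dataclass
class AblationSpec:
    kind: str  # random_dropout | region_exclusion | region_restricted
    dropout_fraction: float = 0.0
    excluded_regions: frozenset = field(default_factory=lambda: SPEECH_REGIONS)
    restriction: str = "all"  # all | cortical | subcortical
    n_seeds: int = 20

    def validate(self) -> None:
        if self.kind not in ("random_dropout", "region_exclusion",
                             "region_restricted"):
            raise ValueError(f"unknown ablation kind {self.kind!r}")
        if not 0.0 <= self.dropout_fraction < 1.0:
            raise ValueError("dropout_fraction must lie in [0, 1)")
        if self.restriction not in ("all", "cortical", "subcortical"):
            raise ValueError(f"unknown restriction {self.restriction!r}")


def ablated_channel_indices(specs: list[ChannelSpec], ablation: AblationSpec,
                            seed: int = 0) -> np.ndarray:
    """Indices of the channels retained under an ablation.

    ``random_dropout`` redraws the removed set per seed; the structural
    ablations are deterministic.
    """
    ablation.validate()
    n = len(specs)
    if ablation.kind == "random_dropout":
        n_drop = int(round(n * ablation.dropout_fraction))
        if n_drop >= n:
            raise ValueError("ablation would remove every channel")
        rng = np.random.default_rng(seed)
        dropped = set(rng.permutation(n)[:n_drop].tolist())
        keep = [i for i in range(n) if i not in dropped]
    elif ablation.kind == "region_exclusion":
        keep = [i for i, c in enumerate(specs)
                if c.region not in ablation.excluded_regions]
    else:  # region_restricted
        if ablation.restriction == "all":
            keep = list(range(n))
        else:
            keep = [i for i, c in enumerate(specs)
                    if c.domain == ablation.restriction]
    if not keep:
        raise ValueError(
            f"{ablation.kind} ablation leaves no channels (restriction="
            f"{ablation.restriction!r})")
    return np.asarray(keep, dtype=int)


def subset_segments(segments: list[Segment], indices: np.ndarray) -> list[Segment]:
    """Restrict every segment to the given channel rows."""
    return [Segment(data=s.data[indices], label=s.label, trial_id=s.trial_id,
                    window_start=s.window_start) for s in segments]


def run_ablation(prepared, cfg, ablation: AblationSpec,
                 split_seeds) -> "EvalResult":
    """Retrain under an ablation and collect per-seed held-out accuracies.

    ``prepared`` is the selected-channel recording bundle from
    :func:`seegstate.pipeline.prepare_recordings`; the same
    ``split_seeds`` should be reused across conditions so comparisons
    are paired. Random dropout redraws the removed channels per seed;
    the structural ablations are deterministic.
    """
    from .evaluate import EvalResult
    from .pipeline import derive_seed, run_split_experiment

    ablation.validate()
    specs = prepared.offline.channels
    accs = []
    for s in split_seeds:
        idx = ablated_channel_indices(
            specs, ablation,
            seed=derive_seed(s, f"ablate-{ablation.kind}-{ablation.dropout_fraction}"))
        run = run_split_experiment(prepared, cfg, s, channel_indices=idx,
                                   continuous=False)
        accs.append(run.discretized_accuracy)
    if ablation.kind == "random_dropout":
        condition = f"dropout_{ablation.dropout_fraction:g}"
    elif ablation.kind == "region_exclusion":
        condition = "region_exclusion"
    else:
        condition = f"restricted_{ablation.restriction}"
    return EvalResult(mode="discretized", accuracies=np.asarray(accs),
                      condition=condition)


@dataclass
class SaliencyReport:
    """Per-channel and per-region saliency attribution."""

    zeta: np.ndarray  # raw per-channel saliency, >= 0
    zeta_normalized: np.ndarray  # min-max scaled to [0, 1]
    channel_names: list[str]
    region_contributions: pd.DataFrame  # region, mean, sd, n_channels
    ranking: list[str]  # regions, descending mean contribution


def saliency(trained: TrainedModel, segments: list[Segment],
             specs: list[ChannelSpec] | None = None,
             batch_size: int = 128,
             class_filter: int | None = None) -> SaliencyReport:
    """Gradient saliency zeta(c) over labeled segments.

    zeta(c) = mean over segments of (1/T) * sum_t |dL/dx[t, c]|,
    computed in evaluation mode (dropout off). Requires labels: the
    gradient is of the loss, not the logit. By default segments of both
    classes enter the average; ``class_filter`` restricts it to one
    label (e.g. speech-only attribution).
    """
    if class_filter is not None:
        segments = [s for s in segments if s.label == class_filter]
    if not segments:
        raise ValueError("no segments given")
    if any(s.label is None for s in segments):
        raise ValueError("saliency requires labeled segments")
    X, y = segments_to_arrays(segments)
    per_channel = np.zeros(X.shape[1])
    for i in range(0, X.shape[0], batch_size):
        g = trained.model.input_gradient(X[i:i + batch_size], y[i:i + batch_size])
        per_channel += np.abs(g).mean(axis=2).sum(axis=0)  # time-avg, seg-sum
    zeta = per_channel / X.shape[0]

    span = zeta.max() - zeta.min()
    zeta_norm = (zeta - zeta.min()) / span if span > 0 else np.zeros_like(zeta)

    names = [c.name for c in specs] if specs else [
        f"ch{i}" for i in range(len(zeta))]
    if specs:
        if len(specs) != len(zeta):
            raise ValueError("channel specs do not match model input channels")
        df = pd.DataFrame({
            "region": [c.region for c in specs],
            "contribution": zeta_norm,
        })
        agg = df.groupby("region")["contribution"].agg(["mean", "std", "count"])
        agg = agg.rename(columns={"std": "sd", "count": "n_channels"})
        agg["sd"] = agg["sd"].fillna(0.0)
        agg = agg.sort_values("mean", ascending=False).reset_index()
        ranking = list(agg["region"])
    else:
        agg = pd.DataFrame(columns=["region", "mean", "sd", "n_channels"])
        ranking = []
    return SaliencyReport(zeta=zeta, zeta_normalized=zeta_norm,
                          channel_names=names, region_contributions=agg,
                          ranking=ranking)
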
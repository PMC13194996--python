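"""End-to-end experiment orchestration.

The canonical stage order is: generate -> filter -> select channels ->
(per split seed) standardize on the training portion -> downsample ->
segment -> balance -> train -> evaluate (discretized and, causally,
continuous) -> ablations -> saliency. Every randomized stage takes a
seed derived deterministically from the experiment's global seed and
the stage name, so re-running any stage reproduces the full-pipeline
behavior.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnn, evaluate, interpret, preprocess, selection
from .channels import generate_channel_specs
from .config import ExperimentConfig
from .containers import Recording, TrialAnnotation, save_annotation, \
    save_channel_table
from .interpret import AblationSpec
from .paradigm import generate_schedule
from .simulate import SyntheticDataset, synthesize_recording


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return zlib.crc32(f"{seed}:{stage}".encode()) % (2 ** 31)


def build_dataset(cfg: ExperimentConfig) -> SyntheticDataset:
    """Generate the synthetic session described by the configuration."""
    schedule = generate_schedule(cfg.paradigm, derive_seed(cfg.seed, "schedule"))
    specs = generate_channel_specs(
        cfg.channels.n_channels, cfg.channels.fraction_informative,
        seed=derive_seed(cfg.seed, "channels"), snr=cfg.channels.snr,
        informative_regions=cfg.channels.informative_regions)
    return synthesize_recording(schedule, specs, cfg.noise,
                                seed=derive_seed(cfg.seed, "signal"),
                                sampling_rate=cfg.paradigm.sampling_rate)


@dataclass
class PreparedRecordings:
    """Filtered (offline + causal) recordings restricted to selected channels."""

    offline: Recording
    causal: Recording | None
    annotation: TrialAnnotation
    selection: selection.ChannelSelectionResult


def prepare_recordings(dataset: SyntheticDataset, cfg: ExperimentConfig,
                       with_causal: bool | None = None) -> PreparedRecordings:
    """Filter, run channel selection and keep only selected channels."""
    pp = cfg.preprocessing
    rec_off = preprocess.filter_signal(dataset.recording, pp, causal=False)
    sel = selection.select_channels(rec_off, dataset.annotation)
    idx = sel.selected_indices()
    if idx.size == 0:
        raise RuntimeError("[select-channels] no channel passed selection")
    rec_off = rec_off.subset(idx)
    causal = None
    if with_causal if with_causal is not None else cfg.evaluation.continuous:
        causal = preprocess.filter_signal(dataset.recording, pp,
                                          causal=True).subset(idx)
    return PreparedRecordings(offline=rec_off, causal=causal,
                              annotation=dataset.annotation, selection=sel)


@dataclass
class SplitRunResult:
    split_seed: int
    trained: cnn.TrainedModel
    discretized_accuracy: float
    n_eval_segments: int
    continuous: pd.DataFrame | None = None
    eval_segments: list = field(default_factory=list)
    split: evaluate.SplitSpec | None = None


def run_split_experiment(
    prepared: PreparedRecordings,
    cfg: ExperimentConfig,
    split_seed: int,
    channel_indices: np.ndarray | None = None,
    continuous: bool | None = None,
) -> SplitRunResult:
    """One train/evaluate cycle for one sentence-level split seed.

    ``channel_indices`` further restricts the selected channels (used by
    the ablation experiments); indices refer to rows of the prepared
    recordings.
    """
    ann = prepared.annotation
    pp = cfg.preprocessing
    rec_off = prepared.offline
    rec_causal = prepared.causal
    if channel_indices is not None:
        rec_off = rec_off.subset(channel_indices)
        if rec_causal is not None:
            rec_causal = rec_causal.subset(channel_indices)

    split = evaluate.sentence_level_split(ann.sentence_ids,
                                          cfg.evaluation.eval_fraction,
                                          seed=split_seed)
    split.validate(ann.sentence_ids)  # leakage guard, every run
    # validation sentences carved from the training side for early stopping
    inner = evaluate.sentence_level_split(split.train_sentence_ids, 0.2,
                                          seed=derive_seed(split_seed, "val"))

    train_trials = [tr.trial_id for tr in
                    ann.trials_for_sentences(split.train_sentence_ids)]
    mask = preprocess.trial_sample_mask(ann, train_trials, rec_off.n_samples,
                                        rec_off.sampling_rate)
    stats = preprocess.compute_zscore_stats(rec_off, mask)
    rec_z, stats = preprocess.zscore_standardize(rec_off, stats)
    rec_ds = preprocess.downsample(rec_z, pp.target_rate)
    segments = preprocess.label_and_segment(rec_ds, ann, pp)

    train_all, eval_segs = evaluate.split_segments(segments, ann, split)
    train_segs, val_segs = evaluate.split_segments(train_all, ann, inner)
    train_segs = cnn.subsample_balanced(train_segs,
                                        derive_seed(split_seed, "bal-train"))
    val_segs = cnn.subsample_balanced(val_segs,
                                      derive_seed(split_seed, "bal-val"))
    eval_segs = cnn.subsample_balanced(eval_segs,
                                       derive_seed(split_seed, "bal-eval"))

    model = cnn.SpeechStateCNN(rec_ds.n_channels, cfg.model,
                               seed=derive_seed(split_seed, "init"))
    tcfg = cnn.TrainConfig(**{**cfg.training.__dict__,
                              "seed": derive_seed(split_seed, "train")})
    trained = cnn.train(model, train_segs, val_segs, tcfg)
    trained.zscore_stats = stats
    acc = evaluate.discretized_accuracy(trained, eval_segs)

    cont_df = None
    do_cont = continuous if continuous is not None else cfg.evaluation.continuous
    if do_cont:
        if rec_causal is None:
            raise RuntimeError("[continuous] causal recording not prepared")
        causal_z, _ = preprocess.zscore_standardize(rec_causal, stats)
        causal_ds = preprocess.downsample(causal_z, pp.target_rate)
        eval_trials = [tr.trial_id for tr in
                       ann.trials_for_sentences(split.eval_sentence_ids)]
        cont_df = evaluate.continuous_decode(
            trained, causal_ds, ann, eval_trials,
            window=cfg.evaluation.continuous_window,
            step=cfg.evaluation.continuous_step)

    return SplitRunResult(split_seed=split_seed, trained=trained,
                          discretized_accuracy=acc,
                          n_eval_segments=len(eval_segs), continuous=cont_df,
                          eval_segments=eval_segs, split=split)


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Full pipeline; writes artifacts under ``cfg.output_dir``.

    Returns (and writes as ``summary.json``) a report with segment
    counts, selected channels, per-seed accuracies, ablation results
    and the regional saliency ranking.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed}

    def stage(name):
        def wrap(fn, *a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise RuntimeError(f"[{name}] {exc}") from exc
        return wrap

    dataset = stage("generate")(build_dataset, cfg)
    save_annotation(out / "annotation.tsv", dataset.annotation)
    save_channel_table(out / "channels.tsv", dataset.channel_specs)
    report["n_trials"] = len(dataset.annotation)
    report["n_channels"] = dataset.recording.n_channels

    prepared = stage("preprocess")(prepare_recordings, dataset, cfg)
    prepared.selection.table.to_csv(out / "channel_selection.tsv", sep="\t",
                                    index=False)
    report["n_selected_channels"] = int(len(prepared.selection.selected_names))
    report["selected_channels"] = prepared.selection.selected_names

    split_seeds = [derive_seed(cfg.seed, f"split-{i}")
                   for i in range(cfg.evaluation.n_split_seeds)]
    runs = [stage("train-evaluate")(run_split_experiment, prepared, cfg, s)
            for s in split_seeds]
    report["discretized_accuracy"] = {
        "per_seed": [r.discretized_accuracy for r in runs],
        "mean": float(np.mean([r.discretized_accuracy for r in runs])),
        "sd": float(np.std([r.discretized_accuracy for r in runs], ddof=1))
        if len(runs) > 1 else 0.0,
    }
    report["n_eval_segments"] = [r.n_eval_segments for r in runs]
    if cfg.evaluation.continuous:
        cont = pd.concat([r.continuous.assign(split_seed=r.split_seed)
                          for r in runs if r.continuous is not None])
        cont.to_csv(out / "continuous_decoding.tsv", sep="\t", index=False)
        report["continuous_accuracy"] = {
            "per_sentence_mean": float(cont.accuracy.mean()),
            "n_sentence_trials": int(len(cont)),
        }

    specs_sel = prepared.offline.channels
    if cfg.ablation.run_dropout:
        drop_report = {}
        for frac in cfg.ablation.dropout_fractions:
            accs = []
            for i, s in enumerate(split_seeds):
                ab = AblationSpec(kind="random_dropout", dropout_fraction=frac)
                idx = interpret.ablated_channel_indices(
                    specs_sel, ab, seed=derive_seed(s, f"drop-{frac}"))
                r = run_split_experiment(prepared, cfg, s, channel_indices=idx,
                                         continuous=False)
                accs.append(r.discretized_accuracy)
            drop_report[str(frac)] = {"per_seed": accs,
                                      "mean": float(np.mean(accs))}
        report["random_dropout"] = drop_report
    if cfg.ablation.run_region_exclusion:
        ab = AblationSpec(kind="region_exclusion")
        idx = interpret.ablated_channel_indices(specs_sel, ab)
        accs = [run_split_experiment(prepared, cfg, s, channel_indices=idx,
                                     continuous=False).discretized_accuracy
                for s in split_seeds]
        report["region_exclusion"] = {"per_seed": accs,
                                      "mean": float(np.mean(accs))}

    if cfg.ablation.run_saliency:
        first = runs[0]
        rep = stage("saliency")(interpret.saliency, first.trained,
                                first.eval_segments, specs_sel)
        rep.region_contributions.to_csv(out / "saliency_regions.tsv", sep="\t",
                                        index=False)
        report["saliency_ranking"] = rep.ranking

    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
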
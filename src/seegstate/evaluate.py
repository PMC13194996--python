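"""Splitting, decoding metrics and statistical comparisons.

Data are split at the sentence level: all repetitions of a sentence land
on one side of the train/eval boundary, so no sentence content is shared
(the leakage guard enforces this at run time, not only in tests).
Discretized accuracy scores non-overlapping windows; continuous decoding
slides a 100 ms window in 5 ms steps over causally preprocessed signal
and scores each window against the ground-truth state at its final time
point, aggregated per sentence trial because adjacent windows overlap by
95% and are not independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .cnn import TrainedModel
from .containers import Recording, Segment, TrialAnnotation

logger = logging.getLogger(__name__)


@dataclass
class SplitSpec:
    train_sentence_ids: list[int]
    eval_sentence_ids: list[int]
    seed: int

    def validate(self, all_sentence_ids=None) -> None:
        train, ev = set(self.train_sentence_ids), set(self.eval_sentence_ids)
        if train & ev:
            raise ValueError(f"train/eval sentence leakage: {sorted(train & ev)}")
        if all_sentence_ids is not None and train | ev != set(all_sentence_ids):
            raise ValueError("split does not cover all sentences")


def sentence_level_split(sentence_ids, eval_fraction: float = 0.2,
                         seed: int = 0) -> SplitSpec:
    """Hold out ``round(eval_fraction * n)`` whole sentences."""
    ids = sorted(set(int(s) for s in sentence_ids))
    if len(ids) < 5:
        raise ValueError("need at least 5 sentences to split")
    if not 0.0 < eval_fraction < 1.0:
        raise ValueError("eval_fraction must lie strictly between 0 and 1")
    n_eval = int(round(eval_fraction * len(ids)))
    n_eval = min(max(n_eval, 1), len(ids) - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    eval_ids = sorted(ids[i] for i in perm[:n_eval])
    train_ids = sorted(ids[i] for i in perm[n_eval:])
    spec = SplitSpec(train_sentence_ids=train_ids, eval_sentence_ids=eval_ids,
                     seed=seed)
    spec.validate(ids)  # leakage guard runs on every split, by construction
    return spec


def split_segments(segments: list[Segment], ann: TrialAnnotation,
                   split: SplitSpec) -> tuple[list[Segment], list[Segment]]:
    """Partition segments by the sentence of their parent trial."""
    split.validate()
    trial_to_sentence = {tr.trial_id: tr.sentence_id for tr in ann.trials}
    train_set = set(split.train_sentence_ids)
    eval_set = set(split.eval_sentence_ids)
    train, ev = [], []
    for s in segments:
        sid = trial_to_sentence[s.trial_id]
        if sid in train_set:
            train.append(s)
        elif sid in eval_set:
            ev.append(s)
    return train, ev


@dataclass
class EvalResult:
    """Accuracy distribution for one condition (signal mode x channel set)."""

    mode: str  # "discretized" or "continuous"
    accuracies: np.ndarray  # per seed (discretized) or per sentence (continuous)
    condition: str = ""

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if self.mode not in ("discretized", "continuous"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if np.any((self.accuracies < 0) | (self.accuracies > 1)):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd(self) -> float:
        return float(self.accuracies.std(ddof=1)) if len(self.accuracies) > 1 else 0.0


def discretized_accuracy(trained: TrainedModel,
                         eval_segments: list[Segment]) -> float:
    """Fraction of correctly labeled non-overlapping windows."""
    if not eval_segments:
        raise ValueError("evaluation set is empty")
    probs = trained.predict(eval_segments)
    labels = np.array([s.label for s in eval_segments])
    return float(((probs >= 0.5).astype(int) == labels).mean())


def continuous_decode(
    trained: TrainedModel,
    rec: Recording,
    ann: TrialAnnotation,
    trial_ids,
    window: float = 0.100,
    step: float = 0.005,
) -> pd.DataFrame:
    """Sliding-window causal decoding, scored per sentence trial.

    ``rec`` must already be causally preprocessed at the model's input
    rate. Window start times lie on the ``step`` grid in seconds and are
    mapped to the nearest sample (5 ms at 500 Hz is 2.5 samples, so hops
    alternate between 2 and 3 samples). Each window is labeled with the
    ground-truth state at its final time point; no sample beyond the
    window end is read. Returns one row per trial with its accuracy.
    """
    fs = rec.sampling_rate
    T = int(round(window * fs))
    wanted = set(int(t) for t in trial_ids)
    rows = []
    for tr in ann.trials:
        if tr.trial_id not in wanted or not tr.syllables:
            continue
        if tr.end - tr.start < window:
            logger.warning("trial %d shorter than one window; skipped", tr.trial_id)
            continue
        n_steps = int(np.floor((tr.end - tr.start - window) / step)) + 1
        starts = tr.start + step * np.arange(n_steps)
        i0 = np.round(starts * fs).astype(int)
        valid = i0 + T <= rec.n_samples
        i0, starts = i0[valid], starts[valid]
        if i0.size == 0:
            continue
        X = np.stack([rec.signal[:, i:i + T] for i in i0]).astype(np.float64)
        preds = (trained.predict(X) >= 0.5).astype(int)
        # causal label: state at the final sample of each window
        t_end = (i0 + T - 1) / fs
        truth = np.array([
            1 if tr.first_onset <= te < tr.last_offset else 0 for te in t_end])
        rows.append({
            "trial_id": tr.trial_id,
            "sentence_id": tr.sentence_id,
            "repetition": tr.repetition,
            "n_windows": int(i0.size),
            "accuracy": float((preds == truth).mean()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Statistical comparisons
# ---------------------------------------------------------------------------

def one_way_anova(groups: dict[str, np.ndarray]) -> dict:
    """Omnibus one-way ANOVA with Tukey HSD post-hoc pairwise tests."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    f, p = sstats.f_oneway(*arrays)
    values = np.concatenate(arrays)
    labels = np.concatenate([[k] * len(a) for k, a in zip(names, arrays)])
    tk = pairwise_tukeyhsd(values, labels, alpha=0.05)
    idx1, idx2 = tk._multicomp.pairindices
    pairwise = [
        {"group1": str(tk.groupsunique[i]), "group2": str(tk.groupsunique[j]),
         "meandiff": float(md), "p_adj": float(pa), "reject": bool(rj)}
        for i, j, md, pa, rj in zip(idx1, idx2, tk.meandiffs, tk.pvalues,
                                    tk.reject)
    ]
    return {"design": "one_way", "F": float(f), "p": float(p),
            "pairwise": pairwise}


def two_way_anova(df: pd.DataFrame, dv: str, factor_a: str,
                  factor_b: str) -> dict:
    """Fixed-effects two-way ANOVA with interaction and Bonferroni simple effects.

    Simple effects compare the levels of ``factor_a`` within each level
    of ``factor_b`` (two levels of A assumed), Bonferroni-corrected
    across the levels of B.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = df.rename(columns={dv: "value", factor_a: "A", factor_b: "B"}).copy()
    counts = data.groupby(["A", "B"]).size()
    if counts.min() < 2:
        raise ValueError("each cell needs >= 2 observations")
    full = set((a, b) for a in data.A.unique() for b in data.B.unique())
    if set(counts.index) != full:
        raise ValueError("two-way design has empty cells")
    fit = smf.ols("value ~ C(A) * C(B)", data=data).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    b_levels = sorted(data.B.unique())
    a_levels = sorted(data.A.unique())
    if len(a_levels) != 2:
        raise ValueError("simple effects implemented for two levels of the first factor")
    m = len(b_levels)
    simple = []
    for b in b_levels:
        x = data.loc[(data.A == a_levels[0]) & (data.B == b), "value"]
        y = data.loc[(data.A == a_levels[1]) & (data.B == b), "value"]
        t, p = sstats.ttest_ind(x, y)
        simple.append({"level": str(b), "t": float(t),
                       "p_bonferroni": float(min(p * m, 1.0))})
    return {
        "design": "two_way",
        "anova": {str(idx): {"F": float(row["F"]), "p": float(row["PR(>F)"])}
                  for idx, row in table.iterrows() if np.isfinite(row["F"])},
        "simple_effects": simple,
    }


def t_test_vs_chance(values, chance: float = 0.5) -> dict:
    """One-sample two-sided t-test against the chance level.

    Zero-variance input is handled explicitly: p = 1 when the constant
    equals chance, p = 0 otherwise.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 observations")
    if x.std(ddof=1) == 0:
        p = 1.0 if x.mean() == chance else 0.0
        return {"design": "vs_chance", "t": 0.0 if p == 1.0 else np.inf, "p": p}
    t, p = sstats.ttest_1samp(x, chance)
    return {"design": "vs_chance", "t": float(t), "p": float(p)}


def two_group_t_test(x, y, paired: bool = False, bonferroni_m: int = 1) -> dict:
    """Two-group t-test (independent or paired) with optional Bonferroni."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observations per group")
    if paired:
        t, p = sstats.ttest_rel(x, y)
    else:
        t, p = sstats.ttest_ind(x, y)
    return {"design": "paired_two_group" if paired else "two_group",
            "t": float(t), "p": float(p),
            "p_bonferroni": float(min(p * bonferroni_m, 1.0))}


def compare_conditions(results, design: str, **kwargs) -> dict:
    """Dispatch to the named statistical procedure.

    ``results`` is a dict of name -> accuracy array (one_way), a tidy
    DataFrame (two_way; pass ``dv``, ``factor_a``, ``factor_b``), an
    array (vs_chance) or a pair of arrays (paired_two_group).
    """
    if design == "one_way":
        return one_way_anova(results)
    if design == "two_way":
        return two_way_anova(results, **kwargs)
    if design == "vs_chance":
        return t_test_vs_chance(results, **kwargs)
    if design == "paired_two_group":
        x, y = results
        return two_group_t_test(x, y, **kwargs)
    raise ValueError(f"unknown design {design!r}")
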
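"""Scoring predicted against observed fixation counts.

The headline measure is the weighted F1: each distinct observed count value
is a label; binary F1 is computed per label,

    F1 = TP / (TP + 0.5 * (FP + FN)),

and the per-label scores are averaged weighted by the number of true
instances of each label.  Because the weights come from the observed table,
a label that is predicted but never observed contributes only false
positives to the observed labels' scores and carries zero weight itself.
Scores are expressed in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence as TSequence

import numpy as np

from .core import Corpus, FixationTable
from .fixation_link import LABELS3, label3, predict_corpus_fixations
from . import lib_model


def binary_f1(tp: int, fp: int, fn: int) -> float:
    """Binary F1 from confusion counts; 0 when there are no hits at all."""
    if min(tp, fp, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    denom = tp + 0.5 * (fp + fn)
    if denom == 0:
        return 0.0
    return tp / denom


def _aligned_counts(
    observed: FixationTable, predicted: FixationTable
) -> tuple[list[int], list[int]]:
    obs_keys = set(observed.keys())
    pred_keys = set(predicted.keys())
    if obs_keys != pred_keys:
        missing = sorted(obs_keys ^ pred_keys)[:10]
        raise KeyError(f"observed/predicted key mismatch, e.g. {missing}")
    keys = sorted(obs_keys)
    return (
        [observed.get(*k) for k in keys],
        [predicted.get(*k) for k in keys],
    )


def weighted_f1(observed: FixationTable, predicted: FixationTable) -> float:
    """Weighted F1 over fixation-count labels, in percent."""
    obs, pred = _aligned_counts(observed, predicted)
    labels = sorted(set(obs))
    num = 0.0
    den = 0
    for c in labels:
        tp = sum(1 for o, p in zip(obs, pred) if o == c and p == c)
        fn = sum(1 for o, p in zip(obs, pred) if o == c and p != c)
        fp = sum(1 for o, p in zip(obs, pred) if o != c and p == c)
        weight = tp + fn
        num += weight * binary_f1(tp, fp, fn)
        den += weight
    return 100.0 * num / den


@dataclass
class EvalReport:
    """Per-label F1 scores, weights, weighted F1 (percent), and the 3-label
    Skip/One/More confusion summary."""

    weighted_f1: float
    per_label_f1: dict[int, float]
    label_weights: dict[int, int]
    confusion3: dict[tuple[str, str], int]
    observed_dist: dict[str, int]
    predicted_dist: dict[str, int]

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(f"weighted_f1\t{self.weighted_f1:.2f}\n")
            for c in sorted(self.per_label_f1):
                fh.write(
                    f"label_f1\t{c}\t{self.per_label_f1[c]:.4f}"
                    f"\t{self.label_weights[c]}\n"
                )
            for o in LABELS3:
                for p in LABELS3:
                    fh.write(f"confusion\t{o}\t{p}\t{self.confusion3[(o, p)]}\n")
            for lab in LABELS3:
                fh.write(
                    f"distribution\t{lab}\t{self.observed_dist[lab]}"
                    f"\t{self.predicted_dist[lab]}\n"
                )


def confusion_summary(
    observed: FixationTable, predicted: FixationTable
) -> EvalReport:
    """Full evaluation report: weighted F1, per-label F1, and the 3x3
    Skip/One/More confusion matrix with marginal distributions."""
    obs, pred = _aligned_counts(observed, predicted)
    labels = sorted(set(obs))
    per_label: dict[int, float] = {}
    weights: dict[int, int] = {}
    for c in labels:
        tp = sum(1 for o, p in zip(obs, pred) if o == c and p == c)
        fn = sum(1 for o, p in zip(obs, pred) if o == c and p != c)
        fp = sum(1 for o, p in zip(obs, pred) if o != c and p == c)
        per_label[c] = binary_f1(tp, fp, fn)
        weights[c] = tp + fn
    total_w = sum(weights.values())
    wf1 = 100.0 * sum(weights[c] * per_label[c] for c in labels) / total_w

    confusion = {(o, p): 0 for o in LABELS3 for p in LABELS3}
    obs_dist = {lab: 0 for lab in LABELS3}
    pred_dist = {lab: 0 for lab in LABELS3}
    for o, p in zip(obs, pred):
        lo, lp = label3(o), label3(p)
        confusion[(lo, lp)] += 1
        obs_dist[lo] += 1
        pred_dist[lp] += 1
    return EvalReport(wf1, per_label, weights, confusion, obs_dist, pred_dist)


def mean_token_length(results: TSequence) -> float:
    """Mean effective token length (characters; internal spaces included,
    trailing boundary space excluded) over a collection of segmentations."""
    total = 0
    n = 0
    for r in results:
        for t in r.tokens:
            total += t.effective_length
            n += 1
    if n == 0:
        raise ValueError("no tokens")
    return total / n


def mean_word_length(corpus: Corpus) -> float:
    words = [w for s in corpus for w in s.words]
    return sum(w.length for w in words) / len(words)


def only_length_score(
    observed: FixationTable,
    corpus: Corpus,
    n_shuffles: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and standard deviation of the Only-Length baseline's weighted F1
    over ``n_shuffles`` independent shuffles (``n_shuffles=1`` reproduces the
    single-shuffle protocol)."""
    from .baselines import predict_only_length

    seeds = np.random.SeedSequence(seed).generate_state(n_shuffles) % (2**31)
    scores = [
        weighted_f1(observed, predict_only_length(observed, corpus, int(s)))
        for s in seeds
    ]
    return float(np.mean(scores)), float(np.std(scores))


def length_sweep(
    corpus: Corpus,
    observed: FixationTable,
    limits: TSequence[int],
    config: lib_model.LiBConfig,
) -> tuple[list[tuple[int, float]], int]:
    """Weighted F1 as a function of the maximum unit length.

    For every limit a fresh LiB lexicon is trained (seed-derived stream per
    limit), the corpus is segmented with the frozen lexicon, and predictions
    are scored against ``observed``.  Returns the (limit, F1) curve and the
    argmax limit.
    """
    if not limits or any(l < 1 for l in limits):
        raise ValueError("limits must be positive")
    curve: list[tuple[int, float]] = []
    for limit in limits:
        seed = int(
            np.random.SeedSequence([config.seed, int(limit)]).generate_state(1)[0]
            % (2**31)
        )
        cfg = replace(config, max_unit_len=int(limit), seed=seed)
        lexicon, _ = lib_model.train(corpus, cfg)
        segs = lib_model.segment_corpus(lexicon, corpus, evaluate=True)
        predicted = predict_corpus_fixations(segs, corpus)
        curve.append((int(limit), weighted_f1(observed, predicted)))
    best_limit = max(curve, key=lambda t: t[1])[0]
    return curve, best_limit
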
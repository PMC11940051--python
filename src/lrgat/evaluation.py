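"""Negative sampling, train/validation splitting, and ACC/AUC scoring.

Negative ligand-receptor sets are formed by shuffling the gene lists of
the curated positives and re-pairing them, discarding anything that
collides with a known positive (or pairs a gene with itself), so the
negative class shares the gene vocabulary but not the pairing
structure.  An 80/20 train/validation split (stratified over the
two labels) supports leakage-free accuracy: the decision threshold is
chosen on the training split and applied to the validation split.  AUC
uses the Mann-Whitney convention (ties get half credit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "LabeledPairs",
    "make_negatives",
    "split_pairs",
    "auc_score",
    "best_threshold",
    "score_ranking",
    "evaluate_split",
]

Pair = tuple[str, str]


@dataclass(frozen=True)
class LabeledPairs:
    positives: frozenset[Pair]
    negatives: frozenset[Pair]
    split: dict  # pair -> "train" | "val"
    validation_fraction: float

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("positives and negatives overlap")

    def subset(self, which: str, label: int) -> set[Pair]:
        pool = self.positives if label == 1 else self.negatives
        return {p for p in pool if self.split[p] == which}


def make_negatives(
    positives: Iterable[Pair],
    n_neg: int,
    seed: int,
    forbidden: Iterable[Pair] = (),
    universe: Iterable[Pair] | None = None,
) -> set[Pair]:
    """Shuffled-pairing negatives disjoint from positives.

    ``forbidden`` lets callers exclude additional pairs (e.g. held-out
    evaluation positives) from the negative pool; ``universe`` restricts
    candidates to a given pair set (e.g. the rankable ligand x receptor
    grid).  Raises if fewer than ``n_neg`` legal pairs exist.
    """
    positives = set(positives)
    blocked = positives | set(forbidden)
    symbols = sorted({s for pair in positives for s in pair})
    legal = {
        (l, r) for l in symbols for r in symbols if l != r and (l, r) not in blocked
    }
    if universe is not None:
        legal &= set(universe)
        blocked |= {
            (l, r) for l in symbols for r in symbols if (l, r) not in legal
        }
    if len(legal) < n_neg:
        raise ValueError(
            f"cannot draw {n_neg} negatives: only {len(legal)} legal pairs exist"
        )
    rng = np.random.default_rng(seed)
    out: set[Pair] = set()
    for _ in range(200):
        ls = list(symbols)
        rs = list(symbols)
        rng.shuffle(ls)
        rng.shuffle(rs)
        for l, r in zip(ls, rs):
            if l != r and (l, r) not in blocked and (l, r) not in out:
                out.add((l, r))
                if len(out) == n_neg:
                    return out
    # tiny vocabularies can starve the shuffle; fill from the legal pool
    remaining = sorted(legal - out)
    extra = rng.choice(len(remaining), size=n_neg - len(out), replace=False)
    out |= {remaining[i] for i in extra}
    return out


def split_pairs(
    positives: Iterable[Pair],
    negatives: Iterable[Pair],
    validation_fraction: float = 0.2,
    seed: int = 0,
) -> LabeledPairs:
    """Stratified train/validation split, reproducible under ``seed``."""
    if not 0.0 <= validation_fraction < 1.0:
        raise ValueError("validation_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    split: dict[Pair, str] = {}
    for pool in (sorted(set(positives)), sorted(set(negatives))):
        n_val = int(round(validation_fraction * len(pool)))
        order = rng.permutation(len(pool))
        for k, i in enumerate(order):
            split[pool[i]] = "val" if k < n_val else "train"
    return LabeledPairs(
        positives=frozenset(positives),
        negatives=frozenset(negatives),
        split=split,
        validation_fraction=validation_fraction,
    )


def auc_score(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """P(random positive outranks random negative), ties count 1/2."""
    pos = np.asarray(pos_scores, float)
    neg = np.asarray(neg_scores, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative score")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def best_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximising accuracy of ``score >= t`` (deterministic)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    candidates = np.concatenate([np.unique(scores), [np.inf]])
    accs = [
        np.mean((scores >= t).astype(int) == labels) for t in candidates
    ]
    return float(candidates[int(np.argmax(accs))])


def _pair_scores(ranking: pd.DataFrame, pairs: Sequence[Pair]) -> np.ndarray:
    table = {(l, r): s for l, r, s in zip(ranking["ligand"], ranking["receptor"],
                                          ranking["score"])}
    out = np.empty(len(pairs))
    for i, pair in enumerate(pairs):
        if pair not in table:
            raise KeyError(f"labeled pair absent from ranking: {pair}")
        out[i] = table[pair]
    return out


def score_ranking(
    ranking: pd.DataFrame,
    labeled: LabeledPairs,
    threshold: float,
) -> dict:
    """ACC at a fixed threshold and tie-aware AUC over all labeled pairs."""
    pos = sorted(labeled.positives)
    neg = sorted(labeled.negatives)
    pos_s = _pair_scores(ranking, pos)
    neg_s = _pair_scores(ranking, neg)
    scores = np.concatenate([pos_s, neg_s])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    acc = float(np.mean((scores >= threshold).astype(int) == labels))
    return {
        "acc": acc,
        "auc": auc_score(pos_s, neg_s),
        "threshold": float(threshold),
        "n_pos": len(pos),
        "n_neg": len(neg),
    }


def evaluate_split(ranking: pd.DataFrame, labeled: LabeledPairs) -> dict:
    """Leakage-free protocol: threshold from train, metrics on validation.

    Falls back to all pairs when the validation split is empty (tiny
    inputs), which is reported via ``n_pos``/``n_neg``.
    """
    tr_pos = sorted(labeled.subset("train", 1))
    tr_neg = sorted(labeled.subset("train", 0))
    va_pos = sorted(labeled.subset("val", 1)) or sorted(labeled.positives)
    va_neg = sorted(labeled.subset("val", 0)) or sorted(labeled.negatives)
    tr_scores = np.concatenate(
        [_pair_scores(ranking, tr_pos), _pair_scores(ranking, tr_neg)]
    )
    tr_labels = np.concatenate([np.ones(len(tr_pos)), np.zeros(len(tr_neg))])
    thr = best_threshold(tr_scores, tr_labels)
    va_pos_s = _pair_scores(ranking, va_pos)
    va_neg_s = _pair_scores(ranking, va_neg)
    va_scores = np.concatenate([va_pos_s, va_neg_s])
    va_labels = np.concatenate([np.ones(len(va_pos)), np.zeros(len(va_neg))])
    return {
        "acc": float(np.mean((va_scores >= thr).astype(int) == va_labels)),
        "auc": auc_score(va_pos_s, va_neg_s),
        "threshold": float(thr),
        "n_pos": len(va_pos),
        "n_neg": len(va_neg),
    }
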
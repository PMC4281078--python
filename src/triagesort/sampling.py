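"""Stratified test-set creation and majority-class under-sampling.

The corpus is split once into a held-out test set that preserves the corpus
class distribution (a realistic ~90% negative / ~10% positive triage mix) and
a training pool.  Training sets are then derived from the pool by *progressive
random under-sampling*: the under-sampling factor (USF) subtracts percentage
points from the negative-class share, in steps of 5 from 0 to 40, so a 90/10
pool becomes 85/15, 80/20, ... down to a balanced 50/50 set.  Positive
documents are never removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus_io import Corpus
from .schema import NEGATIVE, POSITIVE

#: The nine under-sampling factors of the full experiment grid.
USF_GRID: tuple[int, ...] = tuple(range(0, 41, 5))


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.205
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class UnderSampleSpec:
    usf: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.usf % 5 != 0 or not 0 <= self.usf <= 40:
            raise ValueError("usf must be a multiple of 5 in [0, 40]")


def _ids_by_class(corpus: Corpus) -> dict[str, list[str]]:
    by_class: dict[str, list[str]] = {POSITIVE: [], NEGATIVE: []}
    for d in corpus.documents:
        if d.label not in by_class:
            raise ValueError(f"document {d.doc_id} has no valid label")
        by_class[d.label].append(d.doc_id)
    return by_class


def stratified_split(corpus: Corpus, spec: SplitSpec) -> tuple[Corpus, Corpus]:
    """Split into (train_pool, test_set) preserving class proportions.

    The test set holds ``round(test_fraction * N)`` documents, allocated to
    classes by largest remainder so each class's share matches the corpus
    within one document.  Selection within a class is seeded uniform sampling
    without replacement; the same seed always yields the same split.
    """
    by_class = _ids_by_class(corpus)
    for cls, ids in by_class.items():
        if not ids:
            raise ValueError(f"class {cls!r} has no documents; cannot stratify")
    n_total = len(corpus)
    n_test = int(round(spec.test_fraction * n_total))

    classes = sorted(by_class)  # deterministic order
    exact = {c: spec.test_fraction * len(by_class[c]) for c in classes}
    take = {c: int(np.floor(exact[c])) for c in classes}
    # distribute the remainder to the largest fractional parts
    short = n_test - sum(take.values())
    for c in sorted(classes, key=lambda c: exact[c] - take[c], reverse=True)[:short]:
        take[c] += 1

    rng = np.random.default_rng(spec.seed)
    test_ids: set[str] = set()
    for c in classes:
        ids = sorted(by_class[c])
        chosen = rng.choice(len(ids), size=min(take[c], len(ids)), replace=False)
        test_ids.update(ids[i] for i in chosen)

    train = corpus.subset(i for i in corpus.doc_ids() if i not in test_ids)
    test = corpus.subset(test_ids)
    return train, test


def undersample(train_pool: Corpus, spec: UnderSampleSpec) -> Corpus:
    """Randomly drop negatives so their share falls by ``usf`` points.

    The target negative share is the pool's actual share minus ``usf/100``,
    clamped at 0.5 (balance); the retained negative count is
    ``round(n_pos * p / (1 - p))``.  Positives are untouched; sampling is
    seeded and without replacement.
    """
    by_class = _ids_by_class(train_pool)
    n_pos = len(by_class[POSITIVE])
    n_neg = len(by_class[NEGATIVE])
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training pool must contain both classes")

    p0 = n_neg / (n_pos + n_neg)
    p = max(0.5, p0 - spec.usf / 100.0)
    n_neg_target = int(round(n_pos * p / (1.0 - p)))
    if n_neg_target > n_neg:
        raise ValueError(
            f"under-sampling target of {n_neg_target} negatives exceeds the "
            f"{n_neg} available"
        )

    rng = np.random.default_rng(spec.seed)
    neg_ids = sorted(by_class[NEGATIVE])
    keep_idx = rng.choice(len(neg_ids), size=n_neg_target, replace=False)
    keep = set(by_class[POSITIVE]) | {neg_ids[i] for i in keep_idx}
    return train_pool.subset(i for i in train_pool.doc_ids() if i in keep)


def write_split_manifest(
    path: str | Path, train: Corpus, test: Corpus
) -> None:
    """Audit TSV of (doc_id, partition, class) for a split."""
    lines = ["doc_id\tpartition\tclass"]
    for name, part in (("train", train), ("test", test)):
        for d in part.documents:
            lines.append(f"{d.doc_id}\t{name}\t{d.label}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
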
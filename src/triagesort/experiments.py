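"""The full experiment grid: classifiers x feature settings x USF values.

A full run covers 3 classifiers x 4 feature settings x 9 under-sampling
factors = 108 models.  The held-out test set is created once per corpus and
master seed and shared by every cell; each cell derives its own seed by
stable hashing of (classifier, setting, usf), so any cell is reproducible in
isolation.  Per cell: under-sample the training pool, build the vocabulary
from the resulting training set only, vectorize, fit, predict the test set,
and score the positive class.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd

from .classifiers import CLASSIFIER_KINDS, make_classifier
from .corpus_io import Corpus
from .evaluation import ConfusionMatrix, MetricsReport, confusion, metrics
from .features import Vocabulary, build_vocabulary, vectorize
from .sampling import USF_GRID, SplitSpec, UnderSampleSpec, stratified_split, undersample
from .schema import NEGATIVE, POSITIVE

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES = {"nb": "Naive Bayes", "lmt": "LMT", "svm": "SVM"}

#: Result-table column order.
REPORT_COLUMNS = [
    "Under-sampling (USF)",
    "Classifier",
    "Precision",
    "Recall",
    "F-measure",
    "MCC",
    "F-2",
]


@dataclass(frozen=True)
class ExperimentSpec:
    classifiers: tuple[str, ...] = tuple(CLASSIFIER_KINDS)
    settings: tuple[int, ...] = (1, 2, 3, 4)
    usfs: tuple[int, ...] = USF_GRID
    seed: int = 0
    test_fraction: float = 0.205
    min_count: int = 2
    min_len: int = 3
    beta: float = 2.0
    classifier_params: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.classifiers and self.settings and self.usfs):
            raise ValueError("classifiers, settings and usfs must be non-empty")
        for c in self.classifiers:
            if c not in CLASSIFIER_KINDS:
                raise ValueError(f"unknown classifier {c!r}")
        for s in self.settings:
            if s not in (1, 2, 3, 4):
                raise ValueError(f"unknown feature setting {s!r}")
        for u in self.usfs:
            UnderSampleSpec(usf=u)  # validates


@dataclass
class ResultRow:
    classifier: str
    setting: int
    usf: int
    vocab_size: int
    metrics: MetricsReport
    confusion: ConfusionMatrix
    n_train: int
    n_test: int
    seconds: float
    vocabulary: Vocabulary


def cell_seed(master_seed: int, classifier: str, setting: int, usf: int) -> int:
    """Stable per-cell seed derived from the master seed (< 2**31)."""
    key = f"{master_seed}|{classifier}|{setting}|{usf}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def plan_grid(spec: ExperimentSpec) -> list[tuple[str, int, int]]:
    """Deterministic Cartesian product of (classifier, setting, usf) cells."""
    return [
        (clf, setting, usf)
        for setting in sorted(set(spec.settings))
        for usf in sorted(set(spec.usfs))
        for clf in spec.classifiers
    ]


def run_cell(
    train_pool: Corpus,
    test_set: Corpus,
    classifier: str,
    setting: int,
    usf: int,
    spec: ExperimentSpec,
) -> ResultRow:
    seed = cell_seed(spec.seed, classifier, setting, usf)
    train = undersample(train_pool, UnderSampleSpec(usf=usf, seed=seed))
    vocab = build_vocabulary(
        train, setting, min_count=spec.min_count, min_len=spec.min_len
    )
    train_m = vectorize(train, vocab)
    test_m = vectorize(test_set, vocab)

    t0 = time.perf_counter()
    model = make_classifier(
        classifier, seed=seed, **spec.classifier_params.get(classifier, {})
    )
    model.fit(train_m.counts, train_m.y())
    pred = model.predict(test_m.counts)
    seconds = time.perf_counter() - t0

    pred_labels = [POSITIVE if v == 1 else NEGATIVE for v in pred]
    cm = confusion(pred_labels, [d.label for d in test_set.documents])
    report = metrics(cm, beta=spec.beta)
    return ResultRow(
        classifier=classifier,
        setting=setting,
        usf=usf,
        vocab_size=len(vocab),
        metrics=report,
        confusion=cm,
        n_train=len(train),
        n_test=len(test_set),
        seconds=seconds,
        vocabulary=vocab,
    )


def run_grid(corpus: Corpus, spec: ExperimentSpec) -> list[ResultRow]:
    """Run every grid cell; one cell's failure does not stop the rest."""
    train_pool, test_set = stratified_split(
        corpus, SplitSpec(test_fraction=spec.test_fraction, seed=spec.seed)
    )
    rows: list[ResultRow] = []
    cells = plan_grid(spec)
    for i, (clf, setting, usf) in enumerate(cells, start=1):
        try:
            row = run_cell(train_pool, test_set, clf, setting, usf, spec)
        except Exception:
            logger.exception(
                "cell %d/%d failed (classifier=%s setting=%d usf=%d)",
                i, len(cells), clf, setting, usf,
            )
            continue
        logger.info(
            "cell %d/%d: %s setting=%d usf=%d F=%.3f (%.2fs)",
            i, len(cells), clf, setting, usf, row.metrics.f_measure, row.seconds,
        )
        rows.append(row)
    return rows


def rows_to_frame(rows: list[ResultRow]) -> pd.DataFrame:
    """Full-precision flat table, one row per grid cell."""
    return pd.DataFrame(
        {
            "classifier": r.classifier,
            "setting": r.setting,
            "usf": r.usf,
            "vocab_size": r.vocab_size,
            "precision": r.metrics.precision,
            "recall": r.metrics.recall,
            "f_measure": r.metrics.f_measure,
            "mcc": r.metrics.mcc,
            "f_beta": r.metrics.f_beta,
            "tp": r.confusion.tp,
            "fp": r.confusion.fp,
            "fn": r.confusion.fn,
            "tn": r.confusion.tn,
            "n_train": r.n_train,
            "n_test": r.n_test,
            "seconds": r.seconds,
        }
        for r in rows
    )


def render_report(
    rows: list[ResultRow], by: str = "setting"
) -> dict[int | str, pd.DataFrame]:
    """Result tables in the standard layout, one per feature setting
    (or per classifier), values rounded to 3 decimals."""
    if not rows:
        raise ValueError("no result rows to render")
    if by not in ("setting", "classifier"):
        raise ValueError("by must be 'setting' or 'classifier'")
    clf_order = {k: i for i, k in enumerate(CLASSIFIER_KINDS)}
    groups: dict[int | str, list[ResultRow]] = {}
    for r in rows:
        groups.setdefault(getattr(r, by), []).append(r)
    out: dict[int | str, pd.DataFrame] = {}
    for key in sorted(groups, key=str):
        members = sorted(
            groups[key], key=lambda r: (r.usf, clf_order.get(r.classifier, 99))
        )
        out[key] = pd.DataFrame(
            {
                "Under-sampling (USF)": f"Training set with USF {r.usf}%",
                "Classifier": CLASSIFIER_NAMES.get(r.classifier, r.classifier),
                "Precision": round(r.metrics.precision, 3),
                "Recall": round(r.metrics.recall, 3),
                "F-measure": round(r.metrics.f_measure, 3),
                "MCC": round(r.metrics.mcc, 3),
                "F-2": round(r.metrics.f_beta, 3),
            }
            for r in members
        )[REPORT_COLUMNS]
    return out


def frame_to_markdown(df: pd.DataFrame) -> str:
    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "|".join(" --- " for _ in df.columns) + "|"
    lines = [header, sep]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines)


def write_report(rows: list[ResultRow], outdir: str | Path, by: str = "setting") -> None:
    """Write the flat CSV plus per-group CSV and markdown tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows_to_frame(rows).to_csv(outdir / "results_full.csv", index=False)
    md: list[str] = []
    for key, df in render_report(rows, by=by).items():
        df.to_csv(outdir / f"results_{by}_{key}.csv", index=False)
        md.append(f"## Results by {by} = {key}\n\n{frame_to_markdown(df)}\n")
    (outdir / "results.md").write_text("\n".join(md), encoding="utf-8")
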
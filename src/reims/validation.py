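"""Leave-one-patient-out cross-validation and diagnostic metrics.

Patient-wise cross-validation holds out every spectrum from one patient at a
time, so a classifier never sees any data from the patient it is judged on —
the leakage-safe way to estimate deployment accuracy when several spectra
come from the same tissue sample.  Predictions are accumulated into a
contingency table, summarised as the standard diagnostic metrics (disease is
the positive class), and optionally collapsed to the clinically relevant
binary task: disease (tumour or adenoma) versus no disease (normal mucosa).

``reconstruct_from_summary`` inverts rounded published sensitivity /
specificity plus class totals back into integer 2x2 cell counts, which
over-determines accuracy, PPV and NPV — useful for checking the internal
consistency of printed results.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .chemometrics import ClassPrediction, classify_mahalanobis, fit_oplsda, project
from .preprocess import preprocess
from .spectra import BinAxis, Spectrum

BINARY_CLASSES = ("disease", "no_disease")
_BINARY_MAP = {"tumour": "disease", "adenoma": "disease", "normal": "no_disease"}

__all__ = [
    "ContingencyTable",
    "DiagnosticMetrics",
    "lopo_cv",
    "collapse_binary",
    "tabulate",
    "metrics",
    "reconstruct_from_summary",
    "sample_level_rule",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Truth (rows) x predicted (columns) counts over an ordered class list."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        k = len(self.classes)
        if counts.shape != (k, k):
            raise ValueError("counts must be a square class x class table")
        if np.any(counts < 0):
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.classes, name="truth"),
            columns=pd.Index(self.classes, name="predicted"),
        )

    def accuracy(self) -> float:
        """Overall accuracy in percent (any number of classes)."""
        return 100.0 * np.trace(self.counts) / self.total

    def collapse(self, mapping: dict[str, str], classes: Sequence[str]) -> "ContingencyTable":
        """Merge rows/columns under a label mapping (e.g. to the binary task)."""
        k = len(classes)
        out = np.zeros((k, k), dtype=int)
        for i, ci in enumerate(self.classes):
            for j, cj in enumerate(self.classes):
                out[classes.index(mapping[ci]), classes.index(mapping[cj])] += self.counts[i, j]
        return ContingencyTable(tuple(classes), out)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Percent-scale diagnostic metrics of a 2x2 table (disease positive).

    Metrics whose denominator is empty are NaN ("undefined"), never 0.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    fnr: float

    def round1(self) -> dict[str, float]:
        return {
            k: round(v, 1)
            for k, v in self.__dict__.items()
        }


def collapse_binary(labels: Sequence[str]) -> list[str]:
    """Map three-class tissue labels onto {disease, no_disease}.

    tumour and adenoma become ``disease``; normal becomes ``no_disease``.
    Already-collapsed or unknown labels are rejected (strict domain check).
    """
    out = []
    for lab in labels:
        if lab not in _BINARY_MAP:
            raise ValueError(f"cannot collapse label {lab!r}")
        out.append(_BINARY_MAP[lab])
    return out


def tabulate(
    predictions: Sequence[str], truth: Sequence[str], classes: Sequence[str]
) -> ContingencyTable:
    """Count truth x predicted pairs over an ordered class list."""
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth must be aligned")
    classes = tuple(classes)
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for p, t in zip(predictions, truth):
        if p not in idx or t not in idx:
            raise ValueError(f"label outside class list: {t!r} -> {p!r}")
        counts[idx[t], idx[p]] += 1
    return ContingencyTable(classes, counts)


def metrics(table: ContingencyTable, positive: str = "disease") -> DiagnosticMetrics:
    """Standard diagnostic metrics of a 2x2 table, in percent."""
    if len(table.classes) != 2:
        raise ValueError("metrics requires a 2x2 table")
    if positive not in table.classes:
        raise ValueError(f"positive class {positive!r} not in table")
    i = table.classes.index(positive)
    j = 1 - i
    tp = table.counts[i, i]
    fn = table.counts[i, j]
    fp = table.counts[j, i]
    tn = table.counts[j, j]

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    sens = pct(tp, tp + fn)
    return DiagnosticMetrics(
        accuracy=pct(tp + tn, tp + tn + fp + fn),
        sensitivity=sens,
        specificity=pct(tn, tn + fp),
        ppv=pct(tp, tp + fp),
        npv=pct(tn, tn + fn),
        fnr=100.0 - sens if not math.isnan(sens) else float("nan"),
    )


def reconstruct_from_summary(
    n_pos: int,
    n_neg: int,
    sensitivity: float,
    specificity: float,
    classes: tuple[str, str] = BINARY_CLASSES,
) -> ContingencyTable:
    """Rebuild the integer 2x2 table behind printed summary percentages.

    ``TP = round(sensitivity/100 * n_pos)`` and ``TN = round(specificity/100
    * n_neg)`` with round-half-to-even (printed percentages are 1-dp
    roundings of integer ratios, so the rounded product recovers the cell
    count whenever the printed precision permits).
    """
    if not (0 <= sensitivity <= 100 and 0 <= specificity <= 100):
        raise ValueError("percentages must be in [0, 100]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class totals must be positive")
    # Python's round() is round-half-to-even
    tp = round(sensitivity / 100.0 * n_pos)
    tn = round(specificity / 100.0 * n_neg)
    fn = n_pos - tp
    fp = n_neg - tn
    pos, neg = classes
    return ContingencyTable(classes, np.array([[tp, fn], [fp, tn]]))


def sample_level_rule(
    predictions: Sequence[str], sample_ids: Sequence[str]
) -> dict[str, str]:
    """Per-sample call: disease iff any spectrum of the sample is disease.

    Takes binary ({disease, no_disease}) spectrum-level predictions.  This
    rule trades specificity for negative predictive value: one positive
    spectrum anywhere in a lesion flags the whole sample.
    """
    if len(predictions) != len(sample_ids):
        raise ValueError("predictions and sample_ids must be aligned")
    if not predictions:
        raise ValueError("empty prediction list")
    calls: dict[str, str] = {}
    for pred, sid in zip(predictions, sample_ids):
        if pred not in BINARY_CLASSES:
            raise ValueError(f"expected binary predictions, got {pred!r}")
        if pred == "disease":
            calls[sid] = "disease"
        else:
            calls.setdefault(sid, "no_disease")
    return calls


@dataclass(frozen=True)
class CvResult:
    """Predictions plus bookkeeping from a cross-validation run."""

    predictions: list[ClassPrediction]
    truth: list[str]
    sample_ids: list[str]
    patient_ids: list[str]
    fold_of_spectrum: dict[str, str]
    skipped_folds: list[str]

    def predicted_labels(self) -> list[str]:
        return [p.predicted_label for p in self.predictions]


def lopo_cv(
    spectra: Sequence[Spectrum],
    axis: BinAxis | None = None,
    n_pred: int | None = None,
    n_orth: int = 1,
    binary: bool = False,
    preprocessor: Callable[[Sequence[Spectrum], BinAxis | None], "object"] = None,
) -> CvResult:
    """Leave-one-patient-out cross-validation of the OPLS-DA classifier.

    For each patient, a model is fitted on every other patient's spectra
    (binning, TIC normalisation, log transform and centring are all
    recomputed inside the fold) and used to predict all of the held-out
    patient's spectra.  With ``binary=True`` labels are collapsed to
    disease / no_disease *before* fitting, i.e. a dedicated two-class model
    is trained per fold.

    Folds whose training set retains fewer than two classes are skipped with
    a warning; their spectra are simply absent from the output.
    """
    prep = preprocessor or preprocess
    patients = sorted({s.patient_id for s in spectra})
    if len(patients) < 2:
        raise ValueError("leave-one-patient-out needs >= 2 patients")
    predictions: list[ClassPrediction] = []
    truth: list[str] = []
    sample_ids: list[str] = []
    patient_ids: list[str] = []
    fold_of: dict[str, str] = {}
    skipped: list[str] = []
    for pid in patients:
        train = [s for s in spectra if s.patient_id != pid]
        test = [s for s in spectra if s.patient_id == pid]
        train_labels = [s.tissue_label for s in train]
        if binary:
            train_labels = collapse_binary(train_labels)
        if len(set(train_labels)) < 2:
            warnings.warn(
                f"fold {pid!r}: training set has < 2 classes; fold skipped"
            )
            skipped.append(pid)
            continue
        m = prep(train, axis)
        model = fit_oplsda(m, labels=train_labels, n_pred=n_pred, n_orth=n_orth)
        m_test = prep(test, m.axis)
        for i, s in enumerate(test):
            pred = classify_mahalanobis(model, m_test.X[i], spectrum_id=s.spectrum_id)
            predictions.append(pred)
            lab = s.tissue_label
            truth.append(_BINARY_MAP[lab] if binary else lab)
            sample_ids.append(s.sample_id)
            patient_ids.append(s.patient_id)
            fold_of[s.spectrum_id] = pid
    return CvResult(predictions, truth, sample_ids, patient_ids, fold_of, skipped)
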
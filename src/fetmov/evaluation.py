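"""Detector evaluation: confusion matrices, per-class rates, agreement tables.

Rates are one-vs-rest: for class c, TPR(c) = correct-c / all-true-c and
FPR(c) = other-class realizations predicted c / all-non-c realizations.
This is the only reading that reconciles a single "false positive rate"
figure with a 3-class confusion matrix, and it is the quantity a kick
counter cares about (false alarms among non-kick events).

The three-method agreement table compares fetal movements seen by an
ultrasound observer (ground truth), the device, and the mother's button
presses, using greedy one-to-one matching within a time tolerance;
percentages are shares of ultrasound-confirmed events, printed with
half-up 2-decimal rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .segmentation import LabeledDataset, MovementClass

__all__ = [
    "ConfusionMatrix3",
    "RateReport",
    "DetectionAgreement",
    "ClassCountTable",
    "confusion_matrix",
    "per_class_rates",
    "agreement_table",
    "class_count_table",
    "compare_algorithms",
    "AGE_BINS",
]


def compare_algorithms(corpus, algo_ids, scope="global", config=None, seed=0):
    """Run several pipeline variants under a shared split seed.

    Thin forwarding wrapper; see :func:`fetmov.pipeline.compare_algorithms`
    (defined there to avoid a circular import with the pipeline stage).
    """
    from .pipeline import compare_algorithms as _impl

    return _impl(corpus, algo_ids, scope=scope, config=config, seed=seed)

N_CLASSES = 3
AGE_BINS = ((27, 31), (32, 35), (36, 42))  # the 36+ band is open-ended
AGE_BIN_LABELS = ("27-31", "32-35", "36-40+")


@dataclass
class ConfusionMatrix3:
    """3x3 counts, rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CLASSES, N_CLASSES):
            raise ValueError("confusion matrix must be 3x3")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class RateReport:
    """One-vs-rest TPR/FPR per class; None marks an undefined rate."""

    tpr: list[float | None]
    fpr: list[float | None]
    support: list[int]


def confusion_matrix(true_labels, pred_labels) -> ConfusionMatrix3:
    """Tally counts[i][j] = #{true=i, pred=j} over the three classes."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(pred_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("label sequences must have equal length")
    for name, arr in (("true", t), ("pred", p)):
        if arr.size and (arr.min() < 0 or arr.max() >= N_CLASSES):
            raise ValueError(f"{name} labels outside the 3-class set")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix3(counts=counts)


def per_class_rates(cm: ConfusionMatrix3) -> RateReport:
    """One-vs-rest TPR and FPR from a confusion matrix.

    tpr(c) = cm[c,c] / row_sum(c);
    fpr(c) = (col_sum(c) - cm[c,c]) / (total - row_sum(c)).
    A zero denominator marks the rate as undefined (None), never NaN.
    """
    c = cm.counts
    total = cm.total
    tpr: list[float | None] = []
    fpr: list[float | None] = []
    support: list[int] = []
    for k in range(N_CLASSES):
        row = int(c[k].sum())
        col = int(c[:, k].sum())
        support.append(row)
        tpr.append(float(c[k, k] / row) if row > 0 else None)
        neg = total - row
        fpr.append(float((col - c[k, k]) / neg) if neg > 0 else None)
    return RateReport(tpr=tpr, fpr=fpr, support=support)


def _round_half_up(x: float, decimals: int = 2) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _greedy_match(truth: np.ndarray, events: np.ndarray, tol: float) -> np.ndarray:
    """One-to-one matching: for each truth time (in order), take the nearest
    unused event within ``tol`` seconds.  Returns a boolean matched-mask
    over truth."""
    matched = np.zeros(truth.size, dtype=bool)
    used = np.zeros(events.size, dtype=bool)
    for i, t in enumerate(truth):
        if events.size == 0:
            break
        d = np.abs(events - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol:
            matched[i] = True
            used[j] = True
    return matched


@dataclass
class DetectionAgreement:
    """Pattern counts keyed by (ultrasound, device, mother) flags."""

    pattern_counts: dict[tuple[int, int, int], int]
    percentages: dict[tuple[int, int, int], float]
    total_truth: int


def agreement_table(
    truth_events,
    device_events,
    mother_events,
    match_tol_s: float = 5.0,
) -> DetectionAgreement:
    """Tally (ultrasound, device, mother) detection patterns over truth events.

    ``truth_events`` play the ultrasound role (always 1); device and mother
    event times are matched one-to-one to truth within ``match_tol_s``.
    Percentages are 100 * count / n_truth with half-up 2-decimal rounding.
    """
    truth = np.asarray(sorted(truth_events), dtype=np.float64)
    if truth.size == 0:
        raise ValueError("truth event list must be non-empty")
    if match_tol_s <= 0:
        raise ValueError("match_tol_s must be positive")
    device = np.asarray(sorted(device_events), dtype=np.float64)
    mother = np.asarray(sorted(mother_events), dtype=np.float64)
    dev_hit = _greedy_match(truth, device, match_tol_s)
    mom_hit = _greedy_match(truth, mother, match_tol_s)
    counts: dict[tuple[int, int, int], int] = {}
    for d, m in zip(dev_hit, mom_hit):
        key = (1, int(d), int(m))
        counts[key] = counts.get(key, 0) + 1
    pct = {
        k: _round_half_up(100.0 * v / truth.size) for k, v in counts.items()
    }
    return DetectionAgreement(
        pattern_counts=counts, percentages=pct, total_truth=int(truth.size)
    )


@dataclass
class ClassCountTable:
    """Per-gestational-age-bin class counts with a totals row."""

    rows: np.ndarray          # 3 bins x 3 classes
    totals: np.ndarray        # 3 classes
    bin_labels: tuple[str, ...] = AGE_BIN_LABELS

    def __post_init__(self) -> None:
        if not np.array_equal(self.totals, self.rows.sum(axis=0)):
            raise ValueError("totals row must equal column sums")


def _age_bin(age: float) -> int:
    if not (26 <= age <= 42):
        raise ValueError(f"gestational age {age} outside [26, 42] weeks")
    if age <= 31:  # the 26-week lower bound folds into the first band
        return 0
    if age <= 35:
        return 1
    return 2


def class_count_table(dataset: LabeledDataset, age_of: dict[str, float]) -> ClassCountTable:
    """Tabulate realization counts per gestational-age band and class."""
    rows = np.zeros((3, 3), dtype=np.int64)
    for r in dataset.realizations:
        if r.subject_id not in age_of:
            raise ValueError(f"no gestational age for subject {r.subject_id!r}")
        if r.label == MovementClass.UNLABELED:
            raise ValueError("class_count_table requires labeled realizations")
        rows[_age_bin(age_of[r.subject_id]), int(r.label)] += 1
    return ClassCountTable(rows=rows, totals=rows.sum(axis=0))
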